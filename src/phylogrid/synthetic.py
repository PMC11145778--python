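"""Synthetic phylogenies, traits, landscapes and communities.

The generators emulate the statistical structure the spatial-diversity
analysis assumes: a birth-death phylogeny, Brownian (phylogenetically
autocorrelated) continuous traits, a rectangular grid landscape with a
monotone warm/wet -> cold/dry climate gradient along one diagonal, and
communities assembled by drawing a right-skewed (lognormal) range size per
species and growing a contiguous range around the cell whose environment
best matches the species' niche trait, with occupancy probability
proportional to exp(-phi * mismatch^2).  ``phi`` is the environmental
filtering strength: at 0 assembly ignores the environment; large values
produce trait (and, through Brownian signal, phylogenetic) clustering
within cells.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellEnvironment, DEFAULT_CATEGORIES, GridCell, OccurrenceMatrix
from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "LandscapeConfig", "AssemblyConfig", "simulate_tree", "simulate_traits",
    "simulate_landscape", "simulate_communities", "make_endemics", "simulate_dataset",
]

# per-variable (mean, trend along the warm/wet gradient, noise sd); positive
# trend = larger toward the warm/wet (southeast) corner
_ENV_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "AMT": (0.0, 8.0, 0.8),      # deg C, warmer in the SE
    "AP": (400.0, 300.0, 30.0),  # mm
    "PDM": (5.0, 4.0, 0.5),      # mm
    "PET": (800.0, -200.0, 25.0),
    "MDR": (13.0, -3.0, 0.4),    # seasonality variables increase to the NW
    "TS": (700.0, -150.0, 20.0),
    "PS": (90.0, -25.0, 3.0),
    "HF": (8.0, 6.0, 1.0),       # human footprint tracks the habitable SE
    "WA": (50.0, 0.0, 15.0),     # wetland area, patchy
    "EVC": (0.05, 0.04, 0.005),  # relief is highest in the SE mountains
    "Slope": (10.0, 8.0, 1.0),
}


@dataclass
class LandscapeConfig:
    """Grid landscape with a monotone climate gradient.

    ``gradient_axis`` fixes the warm/wet corner: "SE" (default) places it at
    (n_rows-1, n_cols-1) so temperature and rainfall decline toward the
    northwest corner (0, 0).  ``env_params`` maps variable -> (mean, trend,
    noise sd); trend is the expected change from the gradient midpoint to the
    warm/wet corner.  Elevation runs opposite to temperature.
    """

    n_rows: int = 10
    n_cols: int = 10
    gradient_axis: str = "SE"
    env_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_ENV_DEFAULTS))
    categories: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    elevation_mean: float = 4000.0
    elevation_trend: float = -1200.0   # toward the warm/wet corner
    elevation_noise_sd: float = 100.0
    cell_relief: float = 400.0         # elev_max - elev_min within a cell
    protected_fraction: float = 0.3

    def __post_init__(self):
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if any(sd < 0 for _, _, sd in self.env_params.values()):
            raise ValueError("noise sds must be nonnegative")


@dataclass
class AssemblyConfig:
    """Community assembly parameters.

    ``phi`` is the environmental-filtering strength (0 = neutral assembly);
    range sizes are drawn from lognormal(mu, sigma) in cells, clipped to
    [1, n_cells]; species with range <= ``endemic_threshold`` cells are
    flagged endemic.
    """

    n_species: int = 64
    birth: float = 1.0
    death: float = 0.0
    brownian_rate: float = 1.0
    trait_correlation: float = 0.8   # shared "size syndrome" factor loading
    growth_form_freqs: dict[str, float] = field(default_factory=lambda: {
        "hygrophyte": 0.90, "emergent": 0.04, "submerged": 0.03,
        "floating": 0.02, "floating-leaved": 0.01})
    fruit_type_freqs: dict[str, float] = field(default_factory=lambda: {
        "capsule": 0.35, "achene": 0.25, "nutlet": 0.15, "caryopsis": 0.10,
        "berry": 0.08, "legume": 0.07})
    flower_colour_freqs: dict[str, float] = field(default_factory=lambda: {
        "white": 0.25, "yellow": 0.22, "purple": 0.20, "red": 0.12,
        "green": 0.10, "blue": 0.06, "brown": 0.04, "black": 0.01})
    phi: float = 0.0
    niche_bias: float = 0.8    # niche optima lean toward the warm/wet end
    niche_scale: float = 0.6
    range_mu: float = 2.0
    range_sigma: float = 1.0
    endemic_threshold: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.birth > self.death >= 0:
            raise ValueError("require birth > death >= 0")
        if self.phi < 0:
            raise ValueError("phi must be nonnegative")


# ------------------------------------------------------------------ phylogeny

def simulate_tree(n_tips: int, birth: float, death: float, seed: int) -> Phylogeny:
    """Gillespie birth-death tree conditioned on ``n_tips`` extant lineages.

    Simulation starts from a crown split, runs until the extant count first
    reaches ``n_tips`` (restarting on total extinction), then extends all
    extant tip edges by an Exp(n_tips*(birth+death)) stem so terminal
    branches are strictly positive.  The result is rooted and ultrametric;
    tips are labelled ``sp0001`` ... in creation order.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not birth > death >= 0:
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    total_rate = birth + death
    for _ in range(10_000):
        parent = [-1, 0, 0]
        start = [0.0, 0.0, 0.0]
        end = [0.0, np.nan, np.nan]
        active = [1, 2]
        t = 0.0
        while 0 < len(active) < n_tips:
            t += rng.exponential(1.0 / (len(active) * total_rate))
            k = active[rng.integers(len(active))]
            if rng.random() < birth / total_rate:
                end[k] = t
                for _ in range(2):
                    parent.append(k)
                    start.append(t)
                    end.append(np.nan)
                    active.append(len(parent) - 1)
                active.remove(k)
            else:
                end[k] = t
                active.remove(k)
        if len(active) == n_tips:
            t_stop = t + rng.exponential(1.0 / (n_tips * total_rate))
            for k in active:
                end[k] = t_stop
            break
    else:  # pragma: no cover - requires pathological parameters
        raise RuntimeError("birth-death simulation failed to reach n_tips")

    return _prune_to_extant(parent, start, end, set(active))


def _prune_to_extant(parent: list[int], start: list[float], end: list[float],
                     extant: set[int]) -> Phylogeny:
    """Drop extinct lineages, splice unifurcations, relabel extant tips."""
    n = len(parent)
    keep = [False] * n
    for k in extant:
        i = k
        while i != -1 and not keep[i]:
            keep[i] = True
            i = parent[i]
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        if parent[i] != -1 and keep[i]:
            children[parent[i]].append(i)

    new_parent: list[int] = []
    new_length: list[float] = []
    tips: dict[int, str] = {}
    tip_counter = [0]

    def build(i: int, edge_len: float, new_par: int) -> None:
        kids = [c for c in children[i] if keep[c]]
        while len(kids) == 1:  # splice extinct-sided unifurcations
            c = kids[0]
            edge_len += end[c] - start[c]
            i = c
            kids = [k for k in children[i] if keep[k]]
        idx = len(new_parent)
        new_parent.append(new_par)
        new_length.append(edge_len)
        if not kids:
            tip_counter[0] += 1
            tips[idx] = f"sp{tip_counter[0]:04d}"
        for c in kids:
            build(c, end[c] - start[c], idx)

    root = 0
    kids = [c for c in children[root] if keep[c]]
    while len(kids) == 1:  # root itself may have lost one side entirely
        root = kids[0]
        kids = [c for c in children[root] if keep[c]]
    new_parent.append(-1)
    new_length.append(0.0)
    for c in kids:
        build(c, end[c] - start[c], 0)
    return Phylogeny(new_parent, new_length, tips)


# --------------------------------------------------------------------- traits

def simulate_traits(tree: Phylogeny, config: AssemblyConfig | None = None,
                    seed: int = 0) -> TraitTable:
    """Six mixed-type traits per tip, all carrying phylogenetic signal.

    Continuous traits evolve as Brownian motion on the tree and are mapped
    to positive scales.  Categorical traits use a Brownian threshold
    (liability) model: a latent Brownian trait is cut at the empirical
    quantiles given by the configured class frequencies, so close relatives
    share classes (growth form and fruit type are strongly conserved in real
    floras) while the marginal class frequencies match the configuration.
    """
    config = config or AssemblyConfig()
    if config.brownian_rate < 0:
        raise ValueError("Brownian rate must be nonnegative")
    rng = np.random.default_rng(seed)
    raw = brownian_on_tree(tree, config.brownian_rate, rng, k=7)
    # continuous traits share a common Brownian factor (the plant size
    # syndrome: tall species have large leaves and long flowering seasons)
    rho = config.trait_correlation
    if not 0 <= rho <= 1:
        raise ValueError("trait_correlation must be in [0, 1]")
    common = raw[:, 6]
    z = raw.copy()
    z[:, :3] = np.sqrt(rho) * common[:, None] + np.sqrt(1 - rho) * raw[:, :3]
    labels = tree.tip_labels
    df = pd.DataFrame(index=pd.Index(labels, name="species_id"))
    df["growth_form"] = _threshold_cat(config.growth_form_freqs, z[:, 3], rng)
    df["fruit_type"] = _threshold_cat(config.fruit_type_freqs, z[:, 4], rng)
    df["max_height"] = 50.0 * np.exp(0.5 * z[:, 0])          # cm
    df["max_leaf_size"] = 12.0 * np.exp(0.6 * z[:, 1])       # cm^2
    df["flower_colour"] = _threshold_cat(config.flower_colour_freqs, z[:, 5], rng)
    df["flowering_period_length"] = np.clip(3.0 + z[:, 2], 0.5, 12.0)  # months
    return TraitTable(df)


def brownian_on_tree(tree: Phylogeny, rate: float, rng: np.random.Generator,
                     k: int = 1) -> np.ndarray:
    """Sample ``k`` independent Brownian traits; returns (n_tips, k)."""
    if rate < 0:
        raise ValueError("Brownian rate must be nonnegative")
    B = tree.branch_tip_matrix.astype(np.float64)
    C = B.T @ (tree.length[:, None] * B)   # shared root-path covariance
    if rate == 0:
        return np.zeros((tree.n_tips, k))
    L = np.linalg.cholesky(rate * C + 1e-12 * np.eye(tree.n_tips))
    return L @ rng.standard_normal((tree.n_tips, k))


def _threshold_cat(freqs: dict[str, float], liability: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Cut a Brownian liability at empirical quantiles sized by ``freqs``.

    Degenerate liabilities (zero Brownian rate) fall back to iid draws so
    the marginal frequencies still hold.
    """
    names = list(freqs)
    p = np.asarray([freqs[c] for c in names], dtype=float)
    p = p / p.sum()
    n = liability.size
    if np.ptp(liability) == 0:
        return np.asarray(names, dtype=object)[rng.choice(len(names), size=n, p=p)]
    ranks = np.argsort(np.argsort(liability, kind="stable"), kind="stable")
    edges = np.floor(np.cumsum(p) * n + 1e-9).astype(int)
    out = np.empty(n, dtype=object)
    lo = 0
    for name, hi in zip(names, edges):
        out[(ranks >= lo) & (ranks < max(hi, lo + 1))] = name
        lo = max(hi, lo + 1)
    out[ranks >= lo] = names[-1]
    return out


# ------------------------------------------------------------------ landscape

def simulate_landscape(config: LandscapeConfig | None = None,
                       seed: int = 0) -> tuple[list[GridCell], CellEnvironment]:
    """Grid cells plus an 11-variable environment table with a monotone
    climate gradient and elevation running opposite to temperature."""
    config = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols),
                             indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    # gradient score in [-1, 1]: +1 at the warm/wet corner
    denom = (config.n_rows - 1) + (config.n_cols - 1)
    g = 2.0 * (rows + cols) / max(denom, 1) - 1.0
    if config.gradient_axis == "NW":
        g = -g

    cell_ids = [f"c{r:02d}_{c:02d}" for r, c in zip(rows, cols)]
    elev = (config.elevation_mean + config.elevation_trend * g
            + rng.normal(0.0, config.elevation_noise_sd, g.size))
    data = {}
    for var, (mean, trend, sd) in config.env_params.items():
        vals = mean + trend * g + rng.normal(0.0, sd, g.size)
        if var in ("AP", "PDM", "HF", "WA", "EVC", "Slope", "PET", "TS", "PS", "MDR"):
            vals = np.clip(vals, 0.0, None)
        data[var] = vals
    data["elevation"] = elev
    env = CellEnvironment(pd.DataFrame(data, index=pd.Index(cell_ids, name="cell_id")),
                          config.categories)

    protected = rng.random(g.size) < config.protected_fraction
    cells = [
        GridCell(cell_ids[i], int(rows[i]), int(cols[i]), land_fraction=1.0,
                 elev_min=float(elev[i] - config.cell_relief / 2),
                 elev_max=float(elev[i] + config.cell_relief / 2),
                 counties=frozenset({f"county_{cell_ids[i]}"}),
                 protected=bool(protected[i]))
        for i in range(g.size)
    ]
    return cells, env


# ---------------------------------------------------------------- communities

def simulate_communities(tree: Phylogeny, traits: TraitTable,
                         cells: list[GridCell], env: CellEnvironment,
                         config: AssemblyConfig) -> OccurrenceMatrix:
    """Assemble communities by niche-matched contiguous range growth.

    Each species' niche position is its (standardised, log-scale) maximum
    height -- a Brownian trait, so niche similarity carries phylogenetic
    signal.  A range size is drawn from the configured lognormal (min 1
    cell); the range seed cell and each growth step are sampled with
    probability proportional to exp(-phi * (niche - env)^2) over candidate
    cells, where env is the standardised annual mean temperature.  phi = 0
    gives environment-blind contiguous ranges.
    """
    if not cells:
        raise ValueError("empty grid")
    rng = np.random.default_rng(config.seed)
    species = tree.tip_labels
    if set(traits.species) < set(species):
        raise ValueError("trait table does not cover all tips")

    z_env = _zscore(env.table.loc[[c.cell_id for c in cells], "AMT"].to_numpy())
    # niche optima on the standardised temperature axis: every continuous
    # (Brownian) trait is under selection toward the local environment, so
    # filtering compresses the whole phenotype within a cell; optima are
    # biased toward the warm/wet corner so richness declines along the
    # cold/dry (high elevation) direction, as energy-water-limited floras do
    tt = traits.table.loc[species]
    phen = np.column_stack([
        _zscore(np.log(tt["max_height"].to_numpy(dtype=float))),
        _zscore(np.log(tt["max_leaf_size"].to_numpy(dtype=float))),
        _zscore(tt["flowering_period_length"].to_numpy(dtype=float)),
    ])
    niche = config.niche_bias + config.niche_scale * phen   # (n_species, 3)

    n_cells = len(cells)
    pos = {(c.row, c.col): i for i, c in enumerate(cells)}
    neighbours = [
        [pos[(c.row + dr, c.col + dc)]
         for dr in (-1, 0, 1) for dc in (-1, 0, 1)
         if (dr, dc) != (0, 0) and (c.row + dr, c.col + dc) in pos]
        for c in cells
    ]

    sizes = np.rint(rng.lognormal(config.range_mu, config.range_sigma, len(species)))
    sizes = np.clip(sizes, 1, n_cells).astype(int)

    inc = np.zeros((n_cells, len(species)), dtype=np.int8)
    for j, sp in enumerate(species):
        mismatch = ((z_env[:, None] - niche[j][None, :]) ** 2).mean(axis=1)
        logw = -config.phi * mismatch
        w = np.exp(logw - logw.max())           # shift avoids underflow at large phi
        start = rng.choice(n_cells, p=w / w.sum())
        occupied = {int(start)}
        frontier = set(neighbours[start])
        ref = logw.max()
        while len(occupied) < sizes[j] and frontier:
            cand = np.fromiter(frontier, dtype=int)
            lwf = logw[cand]
            nxt = int(cand[rng.choice(cand.size, p=_softmax(lwf))])
            frontier.discard(nxt)
            # establishment succeeds with the literal occupancy probability
            # (relative to the species' best-matched cell); failures shrink
            # the realised range below the drawn one in hostile terrain
            if rng.random() < np.exp(logw[nxt] - ref):
                occupied.add(nxt)
                frontier.update(k for k in neighbours[nxt] if k not in occupied)
        inc[list(occupied), j] = 1
    return OccurrenceMatrix([c.cell_id for c in cells], species, inc)


def make_endemics(matrix: OccurrenceMatrix, threshold: int) -> dict[str, bool]:
    """Flag species whose occupied-cell count is at most ``threshold``."""
    ranges = matrix.range_sizes()
    return {s: bool(0 < r <= threshold) for s, r in zip(matrix.species, ranges)}


def _softmax(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max())
    return w / w.sum()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# ------------------------------------------------------------------- pipeline

def simulate_dataset(landscape: LandscapeConfig | None = None,
                     assembly: AssemblyConfig | None = None,
                     seed: int = 0):
    """Generate a coherent dataset (tree, traits, cells, environment,
    occurrence matrix, endemic flags) from a single seed.

    Sub-seeds for the four generators are drawn from a seeded SeedSequence,
    so the whole dataset is a pure function of (configs, seed).
    """
    landscape = landscape or LandscapeConfig()
    assembly = assembly or AssemblyConfig()
    s_tree, s_traits, s_land, s_comm = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    tree = simulate_tree(assembly.n_species, assembly.birth, assembly.death, int(s_tree))
    traits = simulate_traits(tree, assembly, int(s_traits))
    cells, env = simulate_landscape(landscape, int(s_land))
    assembly_seeded = AssemblyConfig(**{**assembly.__dict__, "seed": int(s_comm)})
    matrix = simulate_communities(tree, traits, cells, env, assembly_seeded)
    endemics = make_endemics(matrix, assembly.endemic_threshold)
    return {
        "tree": tree, "traits": traits, "cells": cells, "env": env,
        "matrix": matrix, "endemics": endemics,
        "manifest": {"seed": seed, "landscape": landscape.__dict__,
                     "assembly": {**assembly.__dict__, "seed": int(s_comm)}},
    }
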