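"""Range-weighted endemism, CANAPE classification and hotspot/gap reporting.

Weighted endemism (WE) sums inverse range sizes of the species in a cell;
phylogenetic endemism (PE) does the same over the branches of the minimal
rooted spanning subtree, each branch weighted by 1/(number of cells holding
at least one of its descendants); functional endemism (FE) is PE on the
trait dendrogram.  CANAPE contrasts PE on the original tree with PE on an
equal-branch-length comparison tree of the same topology and total length,
against a fixed-margin (curveball) randomisation null, classifying cells as
non_significant / neo / paleo / mixed / super endemism centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GridCell, OccurrenceMatrix
from .tree import Phylogeny

__all__ = [
    "endemic_richness", "weighted_endemism", "phylogenetic_endemism",
    "functional_endemism", "comparison_tree", "curveball", "canape",
    "CanapeResult", "top_fraction_hotspots", "integrate_hotspots", "protection_gap",
    "CANAPE_CLASSES",
]

CANAPE_CLASSES = ("non_significant", "neo", "paleo", "mixed", "super")


def endemic_richness(matrix: OccurrenceMatrix, endemic: dict[str, bool]) -> pd.Series:
    """Per-cell count of species flagged endemic."""
    missing = set(matrix.species) - set(endemic)
    if missing:
        raise KeyError(f"endemic flags missing for: {sorted(missing)[:5]}")
    mask = np.asarray([bool(endemic[s]) for s in matrix.species])
    vals = matrix.incidence[:, mask].sum(axis=1)
    return pd.Series(vals, index=pd.Index(matrix.cells, name="cell_id"), name="endemic_SR")


def weighted_endemism(matrix: OccurrenceMatrix,
                      range_threshold: int | None = None) -> pd.Series:
    """WE(c) = sum over species present in c of 1/range_size.

    ``range_threshold`` optionally restricts the sum to species occupying at
    most that many cells (default: all species).  Without a threshold,
    summing WE over cells returns the number of occurring species exactly.
    """
    ranges = matrix.range_sizes().astype(float)
    weight = np.zeros_like(ranges)
    occ = ranges > 0
    weight[occ] = 1.0 / ranges[occ]
    if range_threshold is not None:
        weight[ranges > range_threshold] = 0.0
    vals = matrix.incidence @ weight
    return pd.Series(vals, index=pd.Index(matrix.cells, name="cell_id"), name="WE")


def _pe_values(tree: Phylogeny, incidence: np.ndarray, species: list[str],
               lengths: np.ndarray | None = None) -> np.ndarray:
    cols = tree.tip_index(species)
    B = tree.branch_tip_matrix[:, cols]
    lengths = tree.length if lengths is None else lengths
    presence = (incidence.astype(np.int64) @ B.T) > 0     # cells x branches
    range_size = presence.sum(axis=0).astype(float)
    weight = np.zeros_like(lengths)
    occ = range_size > 0
    weight[occ] = lengths[occ] / range_size[occ]
    return presence @ weight


def phylogenetic_endemism(tree: Phylogeny, matrix: OccurrenceMatrix) -> pd.Series:
    """PE(c) = sum over spanned branches of length / branch range size.

    Summed over all cells, PE returns the total branch length of the subtree
    spanned by occurring species (each branch contributes length exactly
    once)."""
    vals = _pe_values(tree, matrix.incidence, matrix.species)
    return pd.Series(vals, index=pd.Index(matrix.cells, name="cell_id"), name="PE")


def functional_endemism(dendrogram: Phylogeny, matrix: OccurrenceMatrix) -> pd.Series:
    """PE evaluated on the trait dendrogram."""
    return phylogenetic_endemism(dendrogram, matrix).rename("FE")


def comparison_tree(tree: Phylogeny) -> Phylogeny:
    """Same topology with every branch set to the same length, scaled to
    preserve the total tree length (the CANAPE comparison tree)."""
    n_edges = tree.parent.size - 1
    equal = np.full(tree.parent.size, tree.total_branch_length() / n_edges)
    equal[tree.root] = 0.0
    tips = {int(i): lab for i, lab in zip(tree._tip_nodes, tree.tip_labels)}
    return Phylogeny(tree.parent.copy(), equal, tips)


# ------------------------------------------------------------- randomisation

def curveball(incidence: np.ndarray, rng: np.random.Generator,
              n_steps: int) -> np.ndarray:
    """``n_steps`` curveball trades on a binary matrix (rows x columns).

    Each trade picks two rows, finds the columns unique to each, and swaps a
    random subset between them, preserving every row and column sum exactly.
    Returns a new matrix; the input is not modified.
    """
    rows = [set(np.flatnonzero(r)) for r in incidence]
    n = len(rows)
    for _ in range(n_steps):
        i, j = rng.choice(n, size=2, replace=False)
        only_i = list(rows[i] - rows[j])
        only_j = list(rows[j] - rows[i])
        if not only_i or not only_j:
            continue
        pool = only_i + only_j
        perm = rng.permutation(len(pool))
        new_i = {pool[k] for k in perm[:len(only_i)]}
        new_j = {pool[k] for k in perm[len(only_i):]}
        shared = rows[i] & rows[j]
        rows[i] = shared | new_i
        rows[j] = shared | new_j
    out = np.zeros_like(incidence)
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return out


@dataclass
class CanapeResult:
    """Per-cell CANAPE outputs (one row per cell in the table)."""

    table: pd.DataFrame     # PE_obs, PE_alt, RPE, p_PE_obs, p_PE_alt, p_RPE_low, p_RPE_high, canape_class
    n_reps: int

    def classes(self) -> pd.Series:
        return self.table["canape_class"]


def canape(tree: Phylogeny, matrix: OccurrenceMatrix, n_reps: int = 999,
           seed: int | None = None, alpha_sig: float = 0.05,
           alpha_super: float = 0.01, burn_in: int | None = None,
           thin: int | None = None) -> CanapeResult:
    """Categorical analysis of neo- and paleo-endemism.

    PE on the original tree (PE_obs), PE on the equal-branch comparison tree
    (PE_alt) and their ratio RPE are compared with ``n_reps`` curveball
    randomisations of the incidence matrix (all row and column sums
    preserved; seeded; ``burn_in`` initial trades, default 10 x n_cells,
    then ``thin`` trades between samples, default n_cells).  One-tailed rank
    p-values carry the +1 correction.  A cell is a candidate when either PE
    tail is significant at ``alpha_sig``; candidates split into neo (RPE
    significantly low) / paleo (RPE significantly high), each tail tested at
    ``alpha_sig/2``, otherwise mixed; mixed cells significant at
    ``alpha_super`` on both PE tails are super.
    """
    if n_reps < 99:
        raise ValueError("n_reps must be >= 99")
    rng = np.random.default_rng(seed)
    inc = matrix.incidence.astype(np.int8)
    n_cells = len(matrix.cells)
    burn_in = 10 * n_cells if burn_in is None else burn_in
    thin = n_cells if thin is None else thin

    alt = comparison_tree(tree)
    pe_obs = _pe_values(tree, inc, matrix.species)
    pe_alt = _pe_values(alt, inc, matrix.species)
    with np.errstate(invalid="ignore", divide="ignore"):
        rpe = np.where(pe_alt > 0, pe_obs / pe_alt, np.nan)

    ge_obs = np.zeros(n_cells)
    ge_alt = np.zeros(n_cells)
    ge_rpe = np.zeros(n_cells)
    le_rpe = np.zeros(n_cells)
    current = curveball(inc, rng, burn_in)
    identical = 0
    for _ in range(n_reps):
        current = curveball(current, rng, thin)
        identical += int(np.array_equal(current, inc))
        null_obs = _pe_values(tree, current, matrix.species)
        null_alt = _pe_values(alt, current, matrix.species)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_rpe = np.where(null_alt > 0, null_obs / null_alt, np.nan)
        ge_obs += null_obs >= pe_obs
        ge_alt += null_alt >= pe_alt
        with np.errstate(invalid="ignore"):
            ge_rpe += null_rpe >= rpe
            le_rpe += null_rpe <= rpe
    if identical == n_reps:
        warnings.warn("incidence matrix admits no curveball trade; "
                      "null distribution degenerate, all cells non_significant")

    p_obs = (1.0 + ge_obs) / (1.0 + n_reps)
    p_alt = (1.0 + ge_alt) / (1.0 + n_reps)
    p_rpe_hi = (1.0 + ge_rpe) / (1.0 + n_reps)
    p_rpe_lo = (1.0 + le_rpe) / (1.0 + n_reps)

    classes = []
    for c in range(n_cells):
        if not np.isfinite(rpe[c]):
            classes.append("non_significant")
            continue
        candidate = p_obs[c] < alpha_sig or p_alt[c] < alpha_sig
        if not candidate:
            classes.append("non_significant")
        elif p_rpe_lo[c] < alpha_sig / 2:
            classes.append("neo")
        elif p_rpe_hi[c] < alpha_sig / 2:
            classes.append("paleo")
        elif p_obs[c] < alpha_super and p_alt[c] < alpha_super:
            classes.append("super")
        else:
            classes.append("mixed")

    table = pd.DataFrame({
        "PE_obs": pe_obs, "PE_alt": pe_alt, "RPE": rpe,
        "p_PE_obs": p_obs, "p_PE_alt": p_alt,
        "p_RPE_low": p_rpe_lo, "p_RPE_high": p_rpe_hi,
        "canape_class": classes,
    }, index=pd.Index(matrix.cells, name="cell_id"))
    return CanapeResult(table, n_reps)


# ------------------------------------------------------------------ hotspots

def top_fraction_hotspots(values: pd.Series, fraction: float = 0.10) -> set[str]:
    """Cells in the top ``fraction`` of ``values``; ties at the cutoff are
    all included, so the set holds at least ceil(fraction * n) cells."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    v = values.to_numpy(dtype=float)
    n = v.size
    if np.allclose(v, v[0]):
        warnings.warn("all values equal; entire grid returned as hotspot")
        return set(values.index)
    k = int(np.ceil(fraction * n))
    cutoff = np.sort(v)[::-1][k - 1]
    return set(values.index[v >= cutoff])


def integrate_hotspots(top_sets: list[set[str]], canape_result: CanapeResult) -> set[str]:
    """Union of the top-fraction sets and all CANAPE cells with a
    significant class."""
    cls = canape_result.table["canape_class"]
    significant = set(cls.index[cls != "non_significant"])
    out: set[str] = set(significant)
    for s in top_sets:
        out |= s
    return out


def protection_gap(hotspots: set[str], cells: list[GridCell]) -> set[str]:
    """Hotspot cells not covered by a protected area."""
    protected = {c.cell_id for c in cells if c.protected}
    return {h for h in hotspots if h not in protected}
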