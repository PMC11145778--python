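"""Per-cell taxonomic, phylogenetic and functional alpha diversity.

Species richness (SR), Faith's PD (rooted convention: the spanning subtree
includes the path to the root), mean pairwise patristic distance (MPD), and
the null-standardised structure indices

    NRI = -1 x (MPD_observed - MPD_randomized) / sdMPD_randomized

against a null of uniform draws of k tips from the tip pool.  Positive NRI
means phylogenetic clustering, negative means overdispersion.  Run on the
trait dendrogram, the same machinery yields FD and NFRI.

The analytic null scheme is exact: for uniform k-subsets the null mean of
MPD is the grand mean of all pairwise tip distances, and the null variance
has a closed form driven by the inclusion probabilities of pairs of pairs
sharing 2, 1 or 0 tips.  Small problems (C(n,k) <= 1e5) are instead
enumerated outright; the two routes agree to machine precision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .core import OccurrenceMatrix
from .tree import Phylogeny

__all__ = [
    "UndefinedResult", "NullStandardization", "species_richness", "faith_pd",
    "mean_pairwise_distance", "null_standardized_index", "cell_diversity_profile",
]

ENUMERATION_LIMIT = 100_000


class UndefinedResult(ValueError):
    """Signals a metric that is undefined for the given input (e.g. MPD of a
    singleton, or a null with zero variance)."""


@dataclass
class NullStandardization:
    """Observed metric with its null moments and the sign-flipped SES."""

    observed: float
    null_mean: float
    null_sd: float
    n_reps: int | str        # replicate count, or "analytic"
    ses: float
    index: float             # -1 * ses (NRI / NFRI convention)


def species_richness(matrix: OccurrenceMatrix) -> pd.Series:
    """Per-cell species count (row sums of the incidence matrix)."""
    return pd.Series(matrix.richness(), index=pd.Index(matrix.cells, name="cell_id"),
                     name="SR")


def faith_pd(tree: Phylogeny, assemblage) -> float:
    """Faith's PD: branch-length sum of the minimal rooted subtree spanning
    the assemblage (root path included)."""
    labels = list(assemblage)
    if not labels:
        raise UndefinedResult("PD undefined for an empty assemblage")
    idx = tree.tip_index(labels)
    spanned = tree.branch_tip_matrix[:, idx].any(axis=1)
    return float(tree.length[spanned].sum())


def mean_pairwise_distance(tree: Phylogeny, assemblage) -> float:
    """Mean patristic distance over all unordered tip pairs."""
    labels = list(assemblage)
    if len(set(labels)) != len(labels):
        raise ValueError("assemblage contains duplicate species")
    if len(labels) < 2:
        raise UndefinedResult("MPD undefined for fewer than 2 species")
    idx = tree.tip_index(labels)
    D = tree.patristic_matrix[np.ix_(idx, idx)]
    k = len(idx)
    return float(D.sum() / (k * (k - 1)))


class NullMoments:
    """Exact moments of MPD under uniform k-subset sampling from a tip pool.

    Precomputes, from the pairwise distance matrix, the sums needed by the
    closed-form variance (pairs of pairs sharing 2/1/0 tips); per-k queries
    are then O(1).
    """

    def __init__(self, D: np.ndarray):
        D = np.asarray(D, dtype=float)
        self.n = D.shape[0]
        iu = np.triu_indices(self.n, 1)
        d = D[iu]
        self.sum_d = d.sum()
        self.sum_d2 = (d ** 2).sum()
        r = D.sum(axis=1)
        q = (D ** 2).sum(axis=1)
        self.s3_ordered = float((r ** 2 - q).sum())
        # ordered pairs of distinct unordered pairs, split by shared tips
        all_ordered = self.sum_d ** 2 - self.sum_d2
        self.s4_ordered = all_ordered - self.s3_ordered
        self.mean = self.sum_d / comb(self.n, 2)

    def variance(self, k: int) -> float:
        n = self.n
        if not 2 <= k <= n:
            raise ValueError("k must be in [2, n]")
        cnk = comb(n, k)
        p2 = comb(n - 2, k - 2) / cnk
        p3 = comb(n - 3, k - 3) / cnk if k >= 3 else 0.0
        p4 = comb(n - 4, k - 4) / cnk if k >= 4 else 0.0
        if k == n:
            return 0.0
        K = comb(k, 2)
        e2 = (p2 * self.sum_d2 + p3 * self.s3_ordered + p4 * self.s4_ordered) / K ** 2
        var = e2 - self.mean ** 2
        # guard against catastrophic cancellation (true zero-variance nulls)
        return var if var > 1e-12 * self.mean ** 2 else 0.0

    def sd(self, k: int) -> float:
        return float(np.sqrt(self.variance(k)))


def _enumerated_moments(D: np.ndarray, k: int) -> tuple[float, float]:
    """Null mean/sd of MPD by exhaustive enumeration of all k-subsets."""
    n = D.shape[0]
    subsets = np.fromiter(itertools.chain.from_iterable(
        itertools.combinations(range(n), k)), dtype=np.int64).reshape(-1, k)
    pair_i, pair_j = np.triu_indices(k, 1)
    vals = D[subsets[:, pair_i], subsets[:, pair_j]].mean(axis=1)
    return float(vals.mean()), float(vals.std(ddof=0))


def null_standardized_index(tree: Phylogeny, assemblage, scheme: str = "analytic",
                            n_reps: int = 999, seed: int | None = None,
                            pool=None) -> NullStandardization:
    """NRI-style null standardisation of MPD for one assemblage.

    ``scheme="analytic"`` uses the exact uniform-k-subset null (enumerated
    when C(n, k) <= 1e5, closed-form otherwise); ``scheme="montecarlo"``
    draws ``n_reps`` seeded uniform tip subsets.  ``pool`` optionally
    restricts the null tip pool (default: all tree tips).
    """
    labels = list(assemblage)
    pool_labels = list(pool) if pool is not None else tree.tip_labels
    if not set(labels) <= set(pool_labels):
        raise ValueError("assemblage must be a subset of the null pool")
    pool_idx = tree.tip_index(pool_labels)
    D = tree.patristic_matrix[np.ix_(pool_idx, pool_idx)]
    k = len(labels)
    if k < 2:
        raise UndefinedResult("null standardisation undefined for fewer than 2 species")
    obs = mean_pairwise_distance(tree, labels)
    n = len(pool_labels)
    if scheme == "analytic":
        if comb(n, k) <= ENUMERATION_LIMIT:
            mu, sd = _enumerated_moments(D, k)
        else:
            moments = NullMoments(D)
            mu, sd = moments.mean, moments.sd(k)
        reps: int | str = "analytic"
    elif scheme == "montecarlo":
        if n_reps < 99:
            raise ValueError("montecarlo scheme needs n_reps >= 99")
        rng = np.random.default_rng(seed)
        pair_i, pair_j = np.triu_indices(k, 1)
        vals = np.empty(n_reps)
        done = 0
        while done < n_reps:  # chunked vectorised uniform k-subset draws
            chunk = min(n_reps - done, 2000)
            subs = np.argpartition(rng.random((chunk, n)), k - 1, axis=1)[:, :k]
            vals[done:done + chunk] = D[subs[:, pair_i], subs[:, pair_j]].mean(axis=1)
            done += chunk
        mu, sd = float(vals.mean()), float(vals.std(ddof=1))
        reps = n_reps
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "analytic" and k == n:
        # the assemblage is the whole pool: observed equals the null mean
        return NullStandardization(obs, mu, 0.0, reps, 0.0, 0.0)
    if sd <= 0 or not np.isfinite(sd):
        raise UndefinedResult("null distribution of MPD has zero variance")
    ses = (obs - mu) / sd
    return NullStandardization(obs, mu, sd, reps, ses, -ses)


def cell_diversity_profile(matrix: OccurrenceMatrix, tree: Phylogeny,
                           trait_dendrogram: Phylogeny, scheme: str = "analytic",
                           n_reps: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Per-cell SR, PD, MPD, NRI (phylogeny) and FD, NFRI (trait dendrogram).

    The null tip pool is the matrix species list (both trees are restricted
    to it); cells with SR < 2 carry NaN for MPD/NRI/NFRI, empty cells also
    for PD/FD.  The analytic scheme uses the closed-form null moments (exact,
    equal to enumeration).
    """
    species = matrix.species
    for t, name in ((tree, "phylogeny"), (trait_dendrogram, "trait dendrogram")):
        missing = set(species) - set(t.tip_labels)
        if missing:
            raise KeyError(f"species absent from {name}: {sorted(missing)[:5]}")
    inc = matrix.incidence.astype(bool)
    out = pd.DataFrame(index=pd.Index(matrix.cells, name="cell_id"))
    out["SR"] = matrix.richness()

    rng = np.random.default_rng(seed)
    for label, t, pd_col, idx_col in ((0, tree, "PD", "NRI"),
                                      (1, trait_dendrogram, "FD", "NFRI")):
        cols = t.tip_index(species)
        B = t.branch_tip_matrix[:, cols]
        spanned = (inc @ B.T.astype(np.int64)) > 0          # cells x branches
        pd_vals = spanned @ t.length
        pd_vals[out["SR"].to_numpy() == 0] = np.nan
        out[pd_col] = pd_vals

        D = t.patristic_matrix[np.ix_(cols, cols)]
        k = out["SR"].to_numpy().astype(float)
        X = inc.astype(np.float64)
        quad = np.einsum("ij,jk,ik->i", X, D, X)
        with np.errstate(invalid="ignore", divide="ignore"):
            mpd = np.where(k >= 2, quad / (k * (k - 1)), np.nan)
        if label == 0:
            out["MPD"] = mpd
        if scheme == "analytic":
            moments = NullMoments(D)
            ses = np.full(len(k), np.nan)
            for i, ki in enumerate(k.astype(int)):
                if ki == moments.n:
                    ses[i] = 0.0
                elif ki >= 2:
                    sd = moments.sd(ki)
                    ses[i] = (mpd[i] - moments.mean) / sd if sd > 0 else np.nan
        else:
            ses = np.full(len(k), np.nan)
            for i, ki in enumerate(k.astype(int)):
                if ki < 2:
                    continue
                res = null_standardized_index(
                    t, [species[j] for j in np.flatnonzero(inc[i])],
                    scheme="montecarlo", n_reps=n_reps,
                    seed=int(rng.integers(2**31)), pool=species)
                ses[i] = res.ses
        out[idx_col] = -ses
    return out[["SR", "PD", "FD", "MPD", "NRI", "NFRI"]]
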