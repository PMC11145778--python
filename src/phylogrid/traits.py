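"""Trait preprocessing and the functional dendrogram.

Six mixed-type morphological traits per species (growth form, fruit type,
maximum height, maximum leaf size, flower colour, flowering-period length)
are combined into a Gower distance matrix and clustered with UPGMA into an
ultrametric trait tree.  Faith's PD, the net relatedness index and
phylogenetic endemism evaluated on that tree become FD, NFRI and FE.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .tree import Phylogeny

__all__ = [
    "TraitTable", "leaf_area_estimate", "gower_distance", "upgma_dendrogram",
    "CONTINUOUS_TRAITS", "CATEGORICAL_TRAITS",
]

CONTINUOUS_TRAITS = ("max_height", "max_leaf_size", "flowering_period_length")
CATEGORICAL_TRAITS = ("growth_form", "fruit_type", "flower_colour")

LEAF_AREA_COEF = {
    "entire_or_dentate": 2.0 / 3.0,
    "shallow_lobed": 1.0 / 2.0,
    "deep_lobed": 1.0 / 3.0,
}


class TraitTable:
    """Species x trait table with declared per-column types.

    ``types[col]`` is ``"continuous"`` or ``"categorical"``.  Missing values
    (NaN for continuous, NaN/empty for categorical) are permitted and handled
    by Gower's pairwise-weight scheme downstream.
    """

    def __init__(self, table: pd.DataFrame, types: dict[str, str] | None = None):
        if table.index.name != "species_id":
            table = table.copy()
            table.index.name = "species_id"
        if types is None:
            types = {c: ("continuous" if c in CONTINUOUS_TRAITS else "categorical")
                     for c in table.columns}
        unknown = set(table.columns) - set(types)
        if unknown:
            raise ValueError(f"columns without declared type: {sorted(unknown)}")
        for c, t in types.items():
            if t not in ("continuous", "categorical"):
                raise ValueError(f"column {c!r}: unknown type {t!r}")
        self.table = table
        self.types = {c: types[c] for c in table.columns}
        for c in self.continuous_columns:
            vals = pd.to_numeric(self.table[c], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"continuous trait {c!r} has negative values")

    @property
    def species(self) -> list[str]:
        return list(self.table.index.astype(str))

    @property
    def continuous_columns(self) -> list[str]:
        return [c for c, t in self.types.items() if t == "continuous"]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c, t in self.types.items() if t == "categorical"]

    def to_csv(self, path):
        """Write the table with a second header row declaring column types."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("species_id," + ",".join(self.table.columns) + "\n")
            fh.write("#type," + ",".join(self.types[c] for c in self.table.columns) + "\n")
            self.table.to_csv(fh, header=False)
        return path

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        head = pd.read_csv(path, nrows=1, header=0)
        first = head.iloc[0, 0] if len(head) else None
        if first == "#type":
            types_row = list(head.iloc[0, 1:])
            df = pd.read_csv(path, skiprows=[1], index_col=0)
            types = dict(zip(df.columns, types_row))
        else:
            df = pd.read_csv(path, index_col=0)
            types = None
        tt = cls(df, types)
        coerced = tt.table.copy()
        for c in tt.continuous_columns:
            coerced[c] = pd.to_numeric(coerced[c], errors="coerce")
        tt.table = coerced
        return tt


def leaf_area_estimate(length: float, breadth: float, lobe_class: str) -> float:
    """Estimated leaf area (cm^2) from length x breadth and a lobing class.

    Coefficients: 2/3 for entire or dentate leaves, 1/2 for shallow-lobed,
    1/3 for deep-lobed.  Compound leaves should be represented by their
    largest leaflet before calling.
    """
    if length <= 0 or breadth <= 0:
        raise ValueError("leaf length and breadth must be positive")
    try:
        k = LEAF_AREA_COEF[lobe_class]
    except KeyError:
        raise ValueError(f"unknown lobe class {lobe_class!r}; "
                         f"expected one of {sorted(LEAF_AREA_COEF)}") from None
    return length * breadth * k


def gower_distance(traits: TraitTable) -> pd.DataFrame:
    """Gower distance matrix over a mixed-type trait table.

    d(i,j) = sum_k w_ijk * delta_ijk / sum_k w_ijk, with delta the
    range-normalised absolute difference for continuous traits and 0/1
    mismatch for categorical ones; w_ijk = 0 when either value is missing.
    Zero-range continuous columns are dropped with a warning; a species pair
    with no jointly observed trait is an error.
    """
    sp = traits.species
    n = len(sp)
    if n < 2:
        raise ValueError("Gower distance needs at least two species")
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in traits.table.columns:
        if traits.types[col] == "continuous":
            x = pd.to_numeric(traits.table[col], errors="coerce").to_numpy(dtype=float)
            obs = np.isfinite(x)
            rng = (np.nanmax(x) - np.nanmin(x)) if obs.any() else 0.0
            if rng == 0 or not np.isfinite(rng):
                warnings.warn(f"continuous trait {col!r} has zero range; dropped from Gower")
                continue
            w = np.outer(obs, obs)
            d = np.abs(x[:, None] - x[None, :]) / rng
            d = np.where(w, d, 0.0)
        else:
            raw = traits.table[col].astype(object).to_numpy()
            obs = np.array([not (v is None or (isinstance(v, float) and np.isnan(v)) or v == "")
                            for v in raw])
            w = np.outer(obs, obs)
            d = np.where(w, (raw[:, None] != raw[None, :]).astype(float), 0.0)
        num += w * d
        den += w
    if (den == 0).any():
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(f"species pair ({sp[i]!r}, {sp[j]!r}) share no observed trait")
    D = num / den
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sp, columns=sp)


def upgma_dendrogram(distance: pd.DataFrame | np.ndarray,
                     labels: Sequence[str] | None = None) -> Phylogeny:
    """UPGMA (average-linkage) clustering into an ultrametric dendrogram.

    Node heights are half the merge distances, so cophenetic tip-tip
    distances reproduce the merged distances; branch lengths are differences
    of merge heights.  Ties are broken by merging the pair whose clusters
    have the lexicographically smallest (smallest-descendant-label) pair.
    """
    if isinstance(distance, pd.DataFrame):
        if labels is None:
            labels = list(distance.index.astype(str))
        D = distance.to_numpy(dtype=float).copy()
    else:
        D = np.asarray(distance, dtype=float).copy()
        if labels is None:
            labels = [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("distance must be a square matrix over >= 2 items")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    # active clusters: node id -> (size, smallest descendant label)
    node_of = list(range(n))          # active slot -> node id
    sizes = [1] * n
    min_label = [str(l) for l in labels]
    order = np.argsort(min_label, kind="stable")
    # reorder slots lexicographically so row-major argmin = lexicographic tie-break
    node_of = [node_of[i] for i in order]
    sizes = [1] * n
    min_label = [min_label[i] for i in order]
    D = D[np.ix_(order, order)]

    children: list[tuple[int, int] | None] = [None] * n
    heights = [0.0] * n
    np.fill_diagonal(D, np.inf)
    while len(node_of) > 1:
        m = len(node_of)
        flat = int(np.argmin(D))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        h = D[i, j] / 2.0
        new_id = len(children)
        children.append((node_of[i], node_of[j]))
        heights.append(h)
        si, sj = sizes[i], sizes[j]
        # average-linkage update into slot i
        newrow = (si * D[i, :] + sj * D[j, :]) / (si + sj)
        D[i, :] = newrow
        D[:, i] = newrow
        D[i, i] = np.inf
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        node_of[i] = new_id
        sizes[i] = si + sj
        min_label[i] = min(min_label[i], min_label[j])
        for lst in (node_of, sizes, min_label):
            del lst[j]
        # keep slots ordered by smallest descendant label for the tie-break
        ordr = np.argsort(min_label, kind="stable")
        node_of = [node_of[k] for k in ordr]
        sizes = [sizes[k] for k in ordr]
        min_label = [min_label[k] for k in ordr]
        D = D[np.ix_(ordr, ordr)]

    # leaf node ids are the original row indices, so labels map positionally
    return Phylogeny.from_children(children, heights, [str(l) for l in labels])


def cophenetic_matrix(dendrogram: Phylogeny) -> pd.DataFrame:
    """Tip-tip cophenetic (patristic) distances of an ultrametric dendrogram."""
    return pd.DataFrame(dendrogram.patristic_matrix,
                        index=dendrogram.tip_labels, columns=dendrogram.tip_labels)
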