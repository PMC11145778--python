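"""Environment-driver statistics for per-cell diversity indices.

Collinearity screening, standardised single-variable OLS, maximum-likelihood
spatial simultaneous autoregressive error (SAR) models on queen-contiguity
lattice weights, redundancy analysis (RDA), four-set variance partitioning
of adjusted R^2, exact Fisher-Jenks natural-breaks classing, and elevational
gradient fits.

Choices the source toolchains leave undocumented are fixed here and exposed:
spatial weights default to row-standardised queen contiguity; response and
predictors are z-scored before regression so coefficients are standardised;
the SAR pseudo-R^2 is the squared Pearson correlation between observations
and predictions (trend plus lambda-smoothed residual signal).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .core import GridCell

__all__ = [
    "collinearity_screen", "ols_single", "build_spatial_weights", "SpatialWeights",
    "sar_error_ml", "SarFit", "rda_fit", "RdaResult", "variance_partition4",
    "VariancePartition", "jenks_breaks", "elevation_gradient_fit",
]


# --------------------------------------------------------------- collinearity

def collinearity_screen(env: pd.DataFrame, threshold: float = 0.8,
                        keep_list: tuple[str, ...] = ()) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Flag variable pairs with |Pearson r| strictly above ``threshold`` and
    drop one member of each.

    The member named in ``keep_list`` survives; with neither (or both)
    listed, the alphabetically earlier variable is kept.  Constant columns
    are excluded up front (correlation undefined).  Returns (retained
    variables, flagged pairs with their r).
    """
    numeric = env.select_dtypes("number")
    if numeric.shape[1] < 2:
        raise ValueError("need at least two numeric variables")
    variables = []
    for c in numeric.columns:
        if numeric[c].std() == 0:
            warnings.warn(f"constant variable {c!r} excluded from screen")
        else:
            variables.append(c)
    corr = numeric[variables].corr()
    flagged = []
    retained = set(variables)
    for a, b in itertools.combinations(sorted(variables), 2):
        r = float(corr.loc[a, b])
        if abs(r) > threshold:
            flagged.append((a, b, r))
            if a in retained and b in retained:
                if a in keep_list and b not in keep_list:
                    retained.discard(b)
                elif b in keep_list and a not in keep_list:
                    retained.discard(a)
                else:
                    retained.discard(max(a, b))
    return [v for v in variables if v in retained], flagged


# ------------------------------------------------------------------------ OLS

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance input")
    return (x - x.mean()) / sd


def ols_single(y, x, standardize: bool = True) -> dict:
    """Single-predictor OLS; with ``standardize`` the slope equals Pearson r.

    Returns a dict with ``coef``, ``r2`` and the two-sided ``p`` of the
    slope t-test.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need n >= 3 matched observations")
    if not (np.isfinite(y).all() and np.isfinite(x).all()):
        raise ValueError("inputs must be finite")
    if standardize:
        y, x = _zscore(y), _zscore(x)
    elif y.std() == 0 or x.std() == 0:
        raise ValueError("zero-variance input")
    fit = stats.linregress(x, y)
    return {"coef": float(fit.slope), "r2": float(fit.rvalue ** 2),
            "p": float(fit.pvalue), "intercept": float(fit.intercept)}


def elevation_gradient_fit(index_values, elevation, standardize: bool = True) -> dict:
    """OLS of a diversity index against cell elevation (standardised slope)."""
    return ols_single(index_values, elevation, standardize=standardize)


# -------------------------------------------------------------------- weights

@dataclass
class SpatialWeights:
    """Row-standardised neighbour weights over grid cells."""

    W: sparse.csr_matrix                 # row-standardised
    adjacency: sparse.csr_matrix         # symmetric binary
    scheme: str
    row_standardized: bool
    islands: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardised W (via the similar
        symmetric matrix D^-1/2 A D^-1/2; isolated cells contribute 0)."""
        A = self.adjacency.toarray().astype(float)
        deg = A.sum(axis=1)
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        sym = inv_sqrt[:, None] * A * inv_sqrt[None, :]
        return np.linalg.eigvalsh(sym)


def build_spatial_weights(cells: list[GridCell], scheme: str = "queen",
                          distance_band: float | None = None) -> SpatialWeights:
    """Contiguity weights on the cell lattice.

    ``queen`` links the 8 surrounding cells, ``rook`` the 4 orthogonal ones;
    ``distance_band`` instead links cells within that Chebyshev radius.
    Rows are standardised to sum to 1; isolated cells are flagged.
    """
    if len(cells) < 2:
        raise ValueError("need at least two cells for spatial weights")
    pos = {(c.row, c.col): i for i, c in enumerate(cells)}
    n = len(cells)
    rows_idx, cols_idx = [], []
    if distance_band is not None:
        scheme = f"distance<={distance_band:g}"
        coords = np.array([(c.row, c.col) for c in cells], dtype=float)
        for i in range(n):
            cheb = np.abs(coords - coords[i]).max(axis=1)
            for j in np.flatnonzero((cheb > 0) & (cheb <= distance_band)):
                rows_idx.append(i)
                cols_idx.append(int(j))
    else:
        offsets = {
            "queen": [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)],
            "rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
        }
        if scheme not in offsets:
            raise ValueError(f"unknown scheme {scheme!r}")
        for (r, c), i in pos.items():
            for dr, dc in offsets[scheme]:
                j = pos.get((r + dr, c + dc))
                if j is not None:
                    rows_idx.append(i)
                    cols_idx.append(j)
    A = sparse.csr_matrix((np.ones(len(rows_idx)), (rows_idx, cols_idx)), shape=(n, n))
    A.setdiag(0)
    A.eliminate_zeros()
    deg = np.asarray(A.sum(axis=1)).ravel()
    islands = list(np.flatnonzero(deg == 0))
    if islands:
        warnings.warn(f"{len(islands)} isolated cell(s) with no neighbours")
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    W = sparse.diags(inv) @ A
    return SpatialWeights(W.tocsr(), A.tocsr(), scheme, True, islands)


# ------------------------------------------------------------------------ SAR

@dataclass
class SarFit:
    """Maximum-likelihood fit of the SAR error model y = Xb + u, u = lWu + e."""

    beta: np.ndarray
    beta_se: np.ndarray
    beta_p: np.ndarray
    lam: float
    loglik: float
    pseudo_r2: float
    sigma2: float
    meta: dict = field(default_factory=dict)


def sar_error_ml(y, X, weights: SpatialWeights, add_intercept: bool = True) -> SarFit:
    """Profile-likelihood SAR error fit.

    For each lambda the spatially filtered variables (I - lW)y, (I - lW)X
    give profiled beta and sigma^2 by OLS; log|I - lW| comes from the
    eigenvalues of W; lambda is found by bounded 1-D search on the feasible
    interval.  The pseudo-R^2 is corr(y, Xb + lW(y - Xb))^2 and is reported
    in ``meta`` alongside the weight scheme.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    W = weights.W
    eig = weights.eigenvalues()
    lo = 1.0 / eig.min() + 1e-6 if eig.min() < 0 else -0.999
    hi = 1.0 / eig.max() - 1e-6 if eig.max() > 0 else 0.999
    Wy = W @ y
    WX = W @ X

    def neg_conc_loglik(lam: float) -> float:
        ys = y - lam * Wy
        Xs = X - lam * WX
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        rss = float(((ys - Xs @ beta) ** 2).sum())
        logdet = float(np.log1p(-lam * eig).sum())
        if not np.isfinite(logdet):
            return 1e300
        return 0.5 * n * np.log(rss / n) - logdet

    res = optimize.minimize_scalar(neg_conc_loglik, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(res.x)
    ys = y - lam * Wy
    Xs = X - lam * WX
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid_s = ys - Xs @ beta
    sigma2 = float((resid_s ** 2).sum() / n)
    loglik = float(-0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
                   + np.log1p(-lam * weights.eigenvalues()).sum())
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    zvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    trend = X @ beta
    fitted = trend + lam * (W @ (y - trend))
    r = np.corrcoef(y, fitted)[0, 1] if np.std(fitted) > 0 else 0.0
    keep = slice(1, None) if add_intercept else slice(None)
    return SarFit(beta[keep], se[keep], pvals[keep], lam, loglik, float(r ** 2), sigma2,
                  meta={"scheme": weights.scheme,
                        "pseudo_r2_definition": "corr(y, Xb + lam*W*(y - Xb))^2",
                        "intercept": float(beta[0]) if add_intercept else 0.0})


# ------------------------------------------------------------------------ RDA

@dataclass
class RdaResult:
    eigenvalues: np.ndarray          # constrained axes
    proportions: np.ndarray          # eigenvalue / total variance of Y
    residual_eigenvalues: np.ndarray
    residual_proportions: np.ndarray
    site_scores: np.ndarray
    response_scores: np.ndarray
    constrained_proportion: float
    dropped_predictors: list[str] = field(default_factory=list)


def rda_fit(Y, X, predictor_names: list[str] | None = None) -> RdaResult:
    """Redundancy analysis of a response table on predictors.

    Columns of Y and X are z-scored internally; Y is regressed on X, the
    fitted values are eigen-decomposed (constrained axes), the residuals
    likewise (unconstrained axes); axis proportions are eigenvalues over the
    total variance of Y, so all proportions sum to 1.  Aliased predictor
    columns are dropped with a warning; each axis is signed so its
    largest-magnitude response loading is positive.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    n, m = Y.shape
    names = list(predictor_names) if predictor_names else [f"x{j}" for j in range(X.shape[1])]
    if n <= X.shape[1]:
        raise ValueError("need n > number of predictors")
    Ys = np.column_stack([_zscore(Y[:, j]) for j in range(m)])
    Xs = np.column_stack([_zscore(X[:, j]) for j in range(X.shape[1])])
    # drop aliased columns (rank-deficient design)
    _, R = np.linalg.qr(Xs, mode="reduced")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xs.shape) * np.finfo(float).eps if diag.size else 0
    dropped = []
    if (diag <= tol).any():
        keep_cols = []
        basis = np.empty((n, 0))
        for j in range(Xs.shape[1]):
            trial = np.column_stack([basis, Xs[:, j]])
            if np.linalg.matrix_rank(trial) > basis.shape[1]:
                basis = trial
                keep_cols.append(j)
            else:
                dropped.append(names[j])
        warnings.warn(f"dropped aliased predictor(s): {dropped}")
        Xs = Xs[:, keep_cols]
    B, *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
    fitted = Xs @ B
    resid = Ys - fitted
    total = float((Ys ** 2).sum()) / (n - 1)      # = m with z-scoring

    def _axes(M: np.ndarray, k_max: int):
        u, s, vt = np.linalg.svd(M / np.sqrt(n - 1), full_matrices=False)
        lams = s ** 2
        keep = min(k_max, int((lams > 1e-12).sum()))
        u, s, vt, lams = u[:, :keep], s[:keep], vt[:keep], lams[:keep]
        for a in range(keep):                    # sign convention
            load = vt[a]
            if load[np.argmax(np.abs(load))] < 0:
                vt[a] = -load
                u[:, a] = -u[:, a]
        return lams, u * s * np.sqrt(n - 1), vt.T

    rank_c = min(Xs.shape[1], m)
    lams_c, sites, resp = _axes(fitted, rank_c)
    lams_r, _, _ = _axes(resid, m)
    return RdaResult(
        eigenvalues=lams_c, proportions=lams_c / total,
        residual_eigenvalues=lams_r, residual_proportions=lams_r / total,
        site_scores=sites, response_scores=resp,
        constrained_proportion=float(lams_c.sum() / total),
        dropped_predictors=dropped)


# -------------------------------------------------------- variance partition

@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition over 4 predictor sets.

    ``fractions`` maps each non-empty combination of set names (as a sorted
    tuple) to its exclusive fraction; ``unique`` holds the 4 singleton
    fractions; ``marginal`` the adjusted R^2 of each set alone; ``full`` the
    adjusted R^2 of the full model; ``residual`` = 1 - full.  Fractions may
    be negative (adjusted R^2 is not monotone) and sum to ``full`` exactly.
    """

    fractions: dict[tuple[str, ...], float]
    unique: dict[str, float]
    marginal: dict[str, float]
    full: float
    residual: float


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel-adjusted R^2 of y (vector, univariate) or Y (matrix, via the
    RDA constrained proportion) on X."""
    n, p = X.shape[0], X.shape[1]
    if n - p - 1 <= 0:
        raise ValueError("insufficient df")
    if y.ndim == 1 or y.shape[1] == 1:
        yv = _zscore(y.ravel())
        Xs = np.column_stack([np.ones(n), X])
        beta, *_ = np.linalg.lstsq(Xs, yv, rcond=None)
        r2 = 1.0 - ((yv - Xs @ beta) ** 2).sum() / (yv ** 2).sum()
    else:
        r2 = rda_fit(y, X).constrained_proportion
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_partition4(y, groups: dict[str, "pd.DataFrame | np.ndarray"]) -> VariancePartition:
    """Partition the adjusted R^2 of ``y`` across 4 disjoint predictor sets.

    Adjusted R^2 is computed for all 15 non-empty unions of the sets and the
    15 exclusive fractions are recovered by solving the inclusion-exclusion
    system R(U) = sum of fractions of regions intersecting U.
    """
    if len(groups) != 4:
        raise ValueError("exactly 4 predictor sets required")
    names = list(groups)
    mats = {}
    for g, m in groups.items():
        arr = np.asarray(m, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[1] == 0:
            raise ValueError(f"set {g!r} is empty")
        mats[g] = arr
    y = np.asarray(y, dtype=float)
    subsets = [tuple(c) for r in range(1, 5) for c in itertools.combinations(names, r)]
    r2 = {}
    for sub in subsets:
        X = np.column_stack([mats[g] for g in sub])
        r2[sub] = _adjusted_r2(y, X)
    # membership system: R(U) = sum over regions T with T cap U nonempty
    M = np.array([[1.0 if set(t) & set(u) else 0.0 for t in subsets] for u in subsets])
    e = np.linalg.solve(M, np.array([r2[u] for u in subsets]))
    fractions = {t: float(v) for t, v in zip(subsets, e)}
    full = r2[tuple(names)]
    return VariancePartition(
        fractions=fractions,
        unique={g: fractions[(g,)] for g in names},
        marginal={g: r2[(g,)] for g in names},
        full=float(full),
        residual=float(1.0 - full))


# ---------------------------------------------------------------------- jenks

def jenks_breaks(values, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Exact Fisher-Jenks natural-breaks classification.

    Dynamic programming over the sorted values minimises the total
    within-class sum of squared deviations.  Returns ``(breaks, labels)``:
    the k-1 break points (upper value of each class but the last) and a
    0-based class label per input value; a value tied with a break falls in
    the lower class.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    n = v.size
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    order = np.argsort(v, kind="stable")
    x = v[order]
    # prefix sums for O(1) class SSE
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(i: int, j: int) -> float:  # class covering x[i..j] inclusive
        s, s2, m = c1[j + 1] - c1[i], c2[j + 1] - c2[i], j - i + 1
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for cls in range(1, k + 1):
        for j in range(cls, n - (k - cls) + 1):
            best, arg = np.inf, cls - 1
            for i in range(cls - 1, j):
                c = cost[cls - 1, i] + sse(i, j - 1)
                if c < best:
                    best, arg = c, i
            cost[cls, j] = best
            back[cls, j] = arg
    # recover class boundaries over sorted order
    bounds = [n]
    j = n
    for cls in range(k, 0, -1):
        j = back[cls, j]
        bounds.append(j)
    bounds = bounds[::-1]                       # 0 = b0 < b1 < ... < bk = n
    breaks = np.array([x[b - 1] for b in bounds[1:-1]])
    labels = np.empty(n, dtype=int)
    for cls in range(k):
        labels[order[bounds[cls]:bounds[cls + 1]]] = cls
    # ties spanning a break go to the lower class
    for b in breaks:
        tied = v == b
        if tied.any():
            labels[tied] = labels[tied].min()
    return breaks, labels
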