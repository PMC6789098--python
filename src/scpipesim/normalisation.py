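"""Count preprocessing and size-factor estimation.

Natively implemented normalisers: median-of-ratios (with a positive-counts
variant for sparse data), trimmed mean of M-values, pooling deconvolution
with optional pre-clustering, and spike-in totals.  Imputation is a plug-in
boundary: an imputer is any callable mapping a count matrix to a dense
matrix of the same shape, registered by name; imputed or filtered matrices
are used only to obtain size factors, never for DE testing.

All methods return factors standardised to geometric mean 1, the gauge in
which they are comparable with the simulated ground-truth factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from ._matrix import CountMatrix

PreprocessMode = Literal["none", "filter", "impute"]


class NormalisationError(ValueError):
    """Raised when a size-factor method cannot produce usable factors."""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

_IMPUTERS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def register_imputer(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a plug-in imputer (counts array -> dense array, same shape)."""
    _IMPUTERS[name] = fn


def registered_imputers() -> list[str]:
    return sorted(_IMPUTERS)


@dataclass(frozen=True)
class PreprocessSpec:
    mode: PreprocessMode = "none"
    filter_threshold: float = 0.8
    imputer: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.filter_threshold <= 1:
            raise ValueError("filter threshold must lie in (0, 1]")
        if self.mode not in ("none", "filter", "impute"):
            raise ValueError(f"unknown preprocessing mode {self.mode!r}")


def preprocess(cm: CountMatrix, spec: PreprocessSpec) -> CountMatrix:
    """Apply the preprocessing mode; the result feeds size-factor estimation only.

    ``filter`` drops genes whose zero fraction exceeds the threshold
    (all-zero genes are always dropped); ``impute`` delegates to a
    registered plug-in.
    """
    if spec.mode == "none":
        return cm
    if spec.mode == "filter":
        zero_frac = (cm.counts == 0).mean(axis=1)
        keep = (zero_frac <= spec.filter_threshold) & (cm.counts.sum(axis=1) > 0)
        return cm.subset_genes(keep)
    if spec.imputer not in _IMPUTERS:
        raise NormalisationError(
            f"unknown imputer {spec.imputer!r}; registered: {registered_imputers()}")
    imputed = np.asarray(_IMPUTERS[spec.imputer](cm.counts))
    if imputed.shape != cm.counts.shape:
        raise NormalisationError("imputer changed the matrix shape")
    return CountMatrix(imputed, cm.gene_ids.copy(), cm.cell_ids.copy(),
                       cm.is_spike.copy(), allow_float=True)


# ---------------------------------------------------------------------------
# size-factor results
# ---------------------------------------------------------------------------

@dataclass
class SizeFactorResult:
    method: str
    factors: np.ndarray
    clusters: np.ndarray | None = None
    used_spikes: bool = False
    failed_cells: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise NormalisationError(f"{self.method}: non-positive or non-finite factors")


def standardise(factors: np.ndarray) -> np.ndarray:
    """Rescale to geometric mean 1."""
    factors = np.asarray(factors, dtype=float)
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# median of ratios
# ---------------------------------------------------------------------------

def size_factors_mr(cm: CountMatrix, positive_only: bool = False) -> SizeFactorResult:
    """Median-of-ratios size factors.

    Strict variant: the reference is the per-gene geometric mean over cells,
    genes with any zero excluded.  ``positive_only`` ("Positive Counts"):
    the geometric mean is taken over positive entries only, and each cell's
    median runs over genes where both the cell's count and the reference
    are positive — usable for sparse single-cell data.
    """
    if cm.n_cells < 2:
        raise NormalisationError("need at least 2 cells")
    counts = cm.counts.astype(float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    if positive_only:
        pos = counts > 0
        n_pos = pos.sum(axis=1)
        with np.errstate(invalid="ignore"):
            log_ref = np.where(pos, logc, 0.0).sum(axis=1) / np.maximum(n_pos, 1)
        usable = n_pos > 0
    else:
        all_pos = (counts > 0).all(axis=1)
        log_ref = logc.mean(axis=1)
        usable = all_pos
    if not usable.any():
        raise NormalisationError("median-of-ratios: no usable reference genes")
    factors = np.empty(cm.n_cells)
    failed = []
    for j in range(cm.n_cells):
        if positive_only:
            sel = usable & (counts[:, j] > 0)
        else:
            sel = usable
        if not sel.any():
            factors[j] = np.nan
            failed.append(j)
            continue
        factors[j] = np.exp(np.median(logc[sel, j] - log_ref[sel]))
    if failed:
        if not positive_only:
            raise NormalisationError("median-of-ratios failed for some cells")
        fill = np.nanmedian(factors)
        factors[np.isnan(factors)] = fill if np.isfinite(fill) else 1.0
    return SizeFactorResult(
        method="poscounts" if positive_only else "mr",
        factors=standardise(factors),
        failed_cells=np.asarray(failed, dtype=int),
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Trimmed, precision-weighted mean of M-values for one library pair."""
    both = (obs > 0) & (ref > 0)
    if both.sum() < 10:
        warnings.warn("TMM: fewer than 10 doubly-positive genes; factor set to 1",
                      stacklevel=3)
        return 1.0
    o, r = obs[both], ref[both]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def size_factors_tmm(cm: CountMatrix, logratio_trim: float = 0.3,
                     sum_trim: float = 0.05) -> SizeFactorResult:
    """Trimmed-mean-of-M-values factors, combined with library size.

    The reference cell is the one whose upper quartile of count fractions is
    closest to the mean upper quartile.  The composition factor from the
    trimmed weighted mean of M-values is multiplied by library size to give
    effective size factors, standardised to geometric mean 1.
    """
    if cm.n_cells < 2:
        raise NormalisationError("need at least 2 cells")
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise NormalisationError("TMM: cell with zero library size")
    f75 = np.quantile(counts / lib[None, :], 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    comp = np.array([
        1.0 if j == ref_j else
        _tmm_pair(counts[:, j], counts[:, ref_j], lib[j], lib[ref_j],
                  logratio_trim, sum_trim)
        for j in range(cm.n_cells)
    ])
    return SizeFactorResult(method="tmm", factors=standardise(lib * comp))


# ---------------------------------------------------------------------------
# pooling deconvolution (with optional pre-clustering)
# ---------------------------------------------------------------------------

def cluster_cells(cm: CountMatrix, min_size: int = 100, n_pcs: int = 10,
                  n_top_genes: int = 2000) -> np.ndarray:
    """Ward clustering of cells on top principal components of log-CPM.

    The expression of the most variable genes is reduced to ``n_pcs``
    components; the Ward tree is cut into at most n_cells // min_size
    clusters, and clusters below the minimum size are merged into the
    cluster with the nearest centroid until every cluster is large enough
    for pool deconvolution.
    """
    n = cm.n_cells
    kmax = n // min_size
    if kmax < 2:
        return np.zeros(n, dtype=int)
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=0)
    y = np.log1p(counts / lib[None, :] * np.median(lib))
    var = y.var(axis=1)
    top = np.argsort(var)[::-1][:min(n_top_genes, len(var))]
    yc = y[top] - y[top].mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(yc.T, full_matrices=False)
    k = min(n_pcs, len(s))
    pcs = u[:, :k] * s[:k]
    z = linkage(pcs, method="ward")
    labels = fcluster(z, t=kmax, criterion="maxclust") - 1
    # merge undersized clusters into the nearest centroid
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        if len(ids) == 1 or sizes.min() >= min_size:
            break
        small = ids[np.argmin(sizes)]
        centroids = {i: pcs[labels == i].mean(axis=0) for i in ids}
        others = [i for i in ids if i != small]
        dists = [np.linalg.norm(centroids[small] - centroids[i]) for i in others]
        labels[labels == small] = others[int(np.argmin(dists))]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _ring_order(lib: np.ndarray) -> np.ndarray:
    """Order cells by library size, alternating up/down so the ring is smooth."""
    srt = np.argsort(lib, kind="stable")
    return np.concatenate([srt[::2], srt[1::2][::-1]])


def _deconvolve_cluster(counts: np.ndarray, pool_sizes, ridge: float = 1e-8,
                        ref_min: float = 0.1, anchor_weight: float = 2.0
                        ) -> tuple[np.ndarray, bool]:
    """Least-squares pool deconvolution within one homogeneous cluster.

    Ring-ordered pools of each size are summed; the median ratio of the pool
    profile to the cluster pseudo-cell (over genes with reference abundance
    >= ``ref_min``) gives one linear equation sum_{j in pool} sf_j = ratio.
    Low-weight per-cell anchor equations towards library-size ratios keep
    the system well conditioned (within a cluster there is no composition
    bias, so the anchor is unbiased).  Returns per-cell factors on the
    within-cluster scale (mean ~ 1) and a ridge flag.
    """
    n = counts.shape[1]
    sizes = sorted({min(int(s), n) for s in pool_sizes})
    ref = counts.mean(axis=1)
    use = ref >= ref_min
    if use.sum() < 50:
        use = ref > 0
    ref_u = ref[use]
    lib = counts.sum(axis=0)
    ring = _ring_order(lib)
    rows, b = [], []
    csum = np.cumsum(counts[:, ring][use], axis=1)
    csum = np.hstack([np.zeros((use.sum(), 1)), csum])
    total = csum[:, -1]
    for s in sizes:
        for i in range(n):
            j = i + s
            if j <= n:
                pool = csum[:, j] - csum[:, i]
            else:
                pool = total - (csum[:, i] - csum[:, j - n])
            row = np.zeros(n)
            members = ring[np.arange(i, j) % n]
            row[members] = 1.0
            rows.append(row)
            b.append(np.median(pool / ref_u))
    a = np.asarray(rows)
    b = np.asarray(b)
    if anchor_weight > 0:
        a = np.vstack([a, anchor_weight * np.eye(n)])
        b = np.concatenate([b, anchor_weight * lib / lib.mean()])
    ridged = False
    rank = np.linalg.matrix_rank(a)
    if rank < n:
        a = np.vstack([a, np.sqrt(ridge) * np.eye(n)])
        b = np.concatenate([b, np.zeros(n)])
        ridged = True
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol, ridged


def size_factors_deconvolution(cm: CountMatrix, cluster_first: bool = False,
                               pool_sizes=(21, 41, 61, 81, 101),
                               min_cluster_size: int = 100) -> SizeFactorResult:
    """Pooling-deconvolution size factors, optionally after pre-clustering.

    Within each cluster, summed ring pools are deconvolved into per-cell
    factors by least squares; cluster factors are then rescaled through
    median ratios of the cluster pseudo-cell to the global pseudo-cell.
    Non-positive solutions are floored and reported in ``failed_cells``.
    """
    counts = cm.counts.astype(float)
    n = cm.n_cells
    if n < min(pool_sizes):
        raise NormalisationError("fewer cells than the smallest pool size")
    labels = cluster_cells(cm, min_cluster_size) if cluster_first \
        else np.zeros(n, dtype=int)
    global_ref = counts.mean(axis=1)
    factors = np.empty(n)
    failed = []
    for lab in np.unique(labels):
        cells = np.flatnonzero(labels == lab)
        sub = counts[:, cells]
        sol, _ = _deconvolve_cluster(sub, pool_sizes)
        ref_c = sub.mean(axis=1)
        both = (ref_c > 0) & (global_ref > 0)
        scale = np.median(ref_c[both] / global_ref[both])
        factors[cells] = sol * scale
    bad = ~(factors > 0) | ~np.isfinite(factors)
    if bad.any():
        floor = max(np.min(factors[~bad]) * 1e-2, 1e-8) if (~bad).any() else 1.0
        factors[bad] = floor
        failed = np.flatnonzero(bad).tolist()
    return SizeFactorResult(
        method="deconvolution",
        factors=standardise(factors),
        clusters=labels if cluster_first else None,
        failed_cells=np.asarray(failed, dtype=int),
    )


# ---------------------------------------------------------------------------
# spike-in factors
# ---------------------------------------------------------------------------

def size_factors_spike(spike_cm: CountMatrix) -> SizeFactorResult:
    """Size factors proportional to each cell's total spike-in count.

    Cells with zero spike total get factor 1 and are flagged.
    """
    totals = spike_cm.counts.sum(axis=0).astype(float)
    if np.all(totals == 0):
        raise NormalisationError("all-zero spike-in matrix")
    failed = np.flatnonzero(totals == 0)
    if failed.size:
        totals[failed] = np.exp(np.mean(np.log(totals[totals > 0])))
    return SizeFactorResult(
        method="spike",
        factors=standardise(totals),
        used_spikes=True,
        failed_cells=failed,
    )


SIZE_FACTOR_METHODS = {
    "mr": lambda cm, **kw: size_factors_mr(cm, positive_only=False),
    "poscounts": lambda cm, **kw: size_factors_mr(cm, positive_only=True),
    "tmm": lambda cm, **kw: size_factors_tmm(cm),
    "deconvolution": lambda cm, **kw: size_factors_deconvolution(cm, **kw),
}
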