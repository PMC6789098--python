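"""Simulation-parameter estimation from raw count matrices.

Per-gene negative-binomial (or zero-inflated NB) parameters are estimated
from a genes x cells count matrix: mean expression on a common-depth scale,
overdispersion phi (variance = mu + phi mu^2), and dropout (observed zero
fraction).  A cubic smoothing spline of log2 dispersion on log2 mean with a
pointwise 95% variability band captures the protocol's mean-variance
relation and later drives simulation at shifted (differentially expressed)
means.

UMI-based protocols are well described by a plain NB; full-length read-level
protocols (Smart-seq2-like) additionally need per-gene zero inflation, which
is fitted by a small EM with the NB profile-likelihood step inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.special import psi

from ._matrix import CountMatrix, SplitCounts

DISPERSION_FLOOR = 1e-4
DISPERSION_CEIL = 1e4

Family = Literal["NB", "ZINB"]


class NoEstimableGenesError(ValueError):
    """All genes have zero counts in every cell."""


class AmplificationError(ValueError):
    """Read/UMI matrices are inconsistent (UMIs exceed reads somewhere)."""


# ---------------------------------------------------------------------------
# mean-dispersion trend
# ---------------------------------------------------------------------------

class MeanDispersionTrend:
    """Cubic smoothing spline of log2 dispersion on log2 mean.

    The smoothing parameter is chosen by generalised cross-validation.  The
    variability band is the fit +- 1.96 x a local (moving-window) residual SD.
    Evaluation outside the observed log2-mean range clamps to the nearest
    boundary, so simulation at extreme shifted means never extrapolates
    wildly.
    """

    def __init__(self, spline: BSpline, x_min: float, x_max: float,
                 band_x: np.ndarray, band_sd: np.ndarray,
                 y_min: float = -np.inf, y_max: float = np.inf):
        self._spline = spline
        self.x_min = float(x_min)
        self.x_max = float(x_max)
        self.y_min = float(y_min)
        self.y_max = float(y_max)
        self._band_x = np.asarray(band_x, dtype=float)
        self._band_sd = np.asarray(band_sd, dtype=float)

    @classmethod
    def fit(cls, log2_mean: np.ndarray, log2_disp: np.ndarray,
            band_window: int = 101, max_knot_sites: int = 400
            ) -> "MeanDispersionTrend":
        x = np.asarray(log2_mean, dtype=float)
        y = np.asarray(log2_disp, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 8:
            raise ValueError("need at least 8 genes to fit the mean-dispersion trend")
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # collapse to weighted bin means: the spline needs strictly increasing
        # abscissae, and GCV on thousands of near-duplicate sites is ill-posed
        ux, inv = np.unique(xs, return_inverse=True)
        if ux.size > max_knot_sites:
            edges = np.quantile(xs, np.linspace(0, 1, max_knot_sites + 1))
            inv = np.clip(np.searchsorted(edges, xs, side="right") - 1,
                          0, max_knot_sites - 1)
        counts = np.bincount(inv).astype(float)
        keep = counts > 0
        bx = (np.bincount(inv, weights=xs) / np.where(keep, counts, 1.0))[keep]
        by = (np.bincount(inv, weights=ys) / np.where(keep, counts, 1.0))[keep]
        bw = counts[keep]
        bx, uniq_idx = np.unique(bx, return_index=True)
        spline = make_smoothing_spline(bx, by[uniq_idx], w=bw[uniq_idx])
        resid = ys - spline(xs)
        w = min(band_window, xs.size)
        # moving-window residual SD in x-order
        sq = pd_rolling_sd(resid, w)
        # the trend must not exceed the raw dispersion range (no overshoot
        # where the abscissa is sparse)
        return cls(spline, xs[0], xs[-1], xs, sq,
                   y_min=float(ys.min()), y_max=float(ys.max()))

    def __call__(self, log2_mean) -> np.ndarray:
        x = np.clip(np.asarray(log2_mean, dtype=float), self.x_min, self.x_max)
        return np.clip(np.asarray(self._spline(x), dtype=float),
                       self.y_min, self.y_max)

    def band(self, log2_mean) -> tuple[np.ndarray, np.ndarray]:
        x = np.clip(np.asarray(log2_mean, dtype=float), self.x_min, self.x_max)
        fit = self(x)
        sd = np.interp(x, self._band_x, self._band_sd)
        return fit - 1.96 * sd, fit + 1.96 * sd

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "t": self._spline.t.tolist(),
            "c": np.asarray(self._spline.c).tolist(),
            "k": int(self._spline.k),
            "x_min": self.x_min,
            "x_max": self.x_max,
            "y_min": self.y_min,
            "y_max": self.y_max,
            "band_x": self._band_x.tolist(),
            "band_sd": self._band_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeanDispersionTrend":
        spline = BSpline(np.array(d["t"]), np.array(d["c"]), d["k"])
        return cls(spline, d["x_min"], d["x_max"],
                   np.array(d["band_x"]), np.array(d["band_sd"]),
                   y_min=d.get("y_min", -np.inf), y_max=d.get("y_max", np.inf))


def pd_rolling_sd(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving-window SD (window truncated at the edges)."""
    import pandas as pd

    s = pd.Series(values)
    sd = s.rolling(window, center=True, min_periods=max(2, window // 4)).std()
    return sd.bfill().ffill().to_numpy()


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Per-gene simulation parameters plus the mean-dispersion trend."""

    gene_ids: np.ndarray
    mean: np.ndarray              # expected counts at unit size factor
    dispersion: np.ndarray        # phi, variance = mu + phi mu^2
    dropout: np.ndarray           # observed zero fraction
    mean_disp_fit: MeanDispersionTrend
    family: Family = "NB"
    zi_prob: np.ndarray | None = None
    n_cells_fitted: int = 0
    mom_fallback: np.ndarray = field(default=None)  # type: ignore[assignment]
    floored: np.ndarray = field(default=None)       # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.mean)
        if self.mom_fallback is None:
            self.mom_fallback = np.zeros(n, dtype=bool)
        if self.floored is None:
            self.floored = np.zeros(n, dtype=bool)
        if np.any(self.mean <= 0):
            raise ValueError("mean must be positive for every retained gene")
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be positive")
        if np.any((self.dropout < 0) | (self.dropout > 1)):
            raise ValueError("dropout must lie in [0, 1]")
        if self.family == "ZINB":
            if self.zi_prob is None:
                raise ValueError("ZINB requires zi_prob")
            if np.any((self.zi_prob < 0) | (self.zi_prob >= 1)):
                raise ValueError("zi_prob must lie in [0, 1)")
        elif self.zi_prob is not None:
            raise ValueError("zi_prob is only valid for family ZINB")

    @property
    def n_genes(self) -> int:
        return len(self.mean)

    def disp_residual(self) -> np.ndarray:
        """Gene-level deviation of log2 dispersion from the fitted trend."""
        return np.log2(self.dispersion) - self.mean_disp_fit(np.log2(self.mean))

    # -- serialisation ---------------------------------------------------
    def to_json(self, path: str) -> None:
        d = {
            "family": self.family,
            "n_cells_fitted": self.n_cells_fitted,
            "gene_ids": self.gene_ids.tolist(),
            "mean": self.mean.tolist(),
            "dispersion": self.dispersion.tolist(),
            "dropout": self.dropout.tolist(),
            "zi_prob": None if self.zi_prob is None else self.zi_prob.tolist(),
            "mom_fallback": self.mom_fallback.astype(int).tolist(),
            "floored": self.floored.astype(int).tolist(),
            "mean_disp_fit": self.mean_disp_fit.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path: str) -> "SimParams":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            gene_ids=np.array(d["gene_ids"], dtype=str),
            mean=np.array(d["mean"], dtype=float),
            dispersion=np.array(d["dispersion"], dtype=float),
            dropout=np.array(d["dropout"], dtype=float),
            mean_disp_fit=MeanDispersionTrend.from_dict(d["mean_disp_fit"]),
            family=d["family"],
            zi_prob=None if d["zi_prob"] is None else np.array(d["zi_prob"], dtype=float),
            n_cells_fitted=d["n_cells_fitted"],
            mom_fallback=np.array(d["mom_fallback"], dtype=bool),
            floored=np.array(d["floored"], dtype=bool),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_genes_for_estimation(cm: CountMatrix) -> SplitCounts:
    """Keep genes with at least one count in at least one cell.

    Spike-in rows are separated out and returned alongside, never mixed into
    gene-level estimation.  Raises :class:`NoEstimableGenesError` if no
    biological gene survives.
    """
    genes, spikes = cm.split_spikes()
    keep = genes.counts.sum(axis=1) >= 1
    if not keep.any():
        raise NoEstimableGenesError("no estimable genes: all rows are zero")
    return SplitCounts(genes=genes.subset_genes(keep), spikes=spikes)


def _nb_score(r: np.ndarray, counts: np.ndarray, m: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """d/dr of the NB log-likelihood, summed over cells, vectorised over genes.

    ``r`` is the size parameter (1/phi), ``m`` the per-gene-per-cell mean.
    """
    rr = r[:, None]
    terms = (psi(counts + rr) - psi(rr) + np.log(rr / (rr + m))
             + 1.0 - (rr + counts) / (rr + m))
    if weights is not None:
        terms = terms * weights
    return terms.sum(axis=1)


def _fit_nb_dispersion(counts: np.ndarray, mu: np.ndarray, sf: np.ndarray,
                       phi_init: np.ndarray, weights: np.ndarray | None = None,
                       n_iter: int = 45) -> tuple[np.ndarray, np.ndarray]:
    """Profile ML for phi per gene (mu fixed), by bisection on the score in log r.

    Returns (phi, ml_failed).  Genes whose score has no sign change inside the
    bracket keep the boundary value and are flagged.
    """
    m = mu[:, None] * sf[None, :]
    r_init = 1.0 / phi_init
    lo = np.log(np.maximum(r_init / 400.0, 1.0 / DISPERSION_CEIL))
    hi = np.log(np.minimum(r_init * 400.0, 1.0 / DISPERSION_FLOOR))
    lo = np.minimum(lo, hi - 1e-6)
    s_lo = _nb_score(np.exp(lo), counts, m, weights)
    s_hi = _nb_score(np.exp(hi), counts, m, weights)
    # score is decreasing in r around the optimum: s_lo > 0 > s_hi is the good case
    failed = ~((s_lo > 0) & (s_hi < 0))
    # boundary resolution: score positive everywhere -> r at hi (phi floor-ish);
    # negative everywhere -> r at lo (phi ceiling-ish)
    theta_fixed = np.where(s_hi > 0, hi, lo)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        s_mid = _nb_score(np.exp(mid), counts, m, weights)
        take_hi = s_mid > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    theta = 0.5 * (lo + hi)
    theta = np.where(failed, theta_fixed, theta)
    phi = 1.0 / np.exp(theta)
    return np.clip(phi, DISPERSION_FLOOR, DISPERSION_CEIL), failed


def estimate_params(cm: CountMatrix, family: Family = "NB",
                    em_iterations: int = 8) -> SimParams:
    """Estimate per-gene NB/ZINB parameters and the mean-dispersion trend.

    Cells are rescaled to the median library size before mean estimation, so
    means are on a counts-per-typical-cell scale.  Dispersion comes from a
    per-gene profile maximum likelihood (method-of-moments initialised); for
    ``family="ZINB"`` a small EM alternates zero-inflation responsibilities
    with the weighted NB fit.  Genes whose ML step fails keep the
    method-of-moments value and are flagged; negative moment estimates are
    clamped to a small positive floor and flagged.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("cells with zero total counts cannot be depth-rescaled")
    sf = lib / np.median(lib)
    norm = counts / sf[None, :]
    mean = norm.mean(axis=1)
    if np.any(mean <= 0):
        raise ValueError("run filter_genes_for_estimation first (all-zero gene present)")
    var = norm.var(axis=1, ddof=1)
    dropout = (cm.counts == 0).mean(axis=1)

    phi_mom = (var - mean) / mean ** 2
    floored = phi_mom < DISPERSION_FLOOR
    phi_mom = np.clip(phi_mom, DISPERSION_FLOOR, DISPERSION_CEIL)

    zi = None
    if family == "NB":
        phi, ml_failed = _fit_nb_dispersion(counts, mean, sf, phi_mom)
    else:
        # EM for per-gene zero inflation with the NB profile step inside
        zero = counts == 0
        phi, ml_failed = _fit_nb_dispersion(counts, mean, sf, phi_mom)
        mu_g = mean.copy()
        # moment initialisation off the zi = 0 boundary: excess of observed
        # zeros over the NB zero probability at the current fit
        r0 = 1.0 / phi
        p0_init = np.power(r0 / (r0 + mu_g), r0)
        zero_frac = zero.mean(axis=1)
        zi = np.clip((zero_frac - p0_init) / np.maximum(1 - p0_init, 1e-8),
                     0.02, 0.95)
        for _ in range(em_iterations):
            m = mu_g[:, None] * sf[None, :]
            r = (1.0 / phi)[:, None]
            log_p0 = r * (np.log(r) - np.log(r + m))
            p0 = np.exp(np.clip(log_p0, -700, 0))
            with np.errstate(divide="ignore", invalid="ignore"):
                w_zero = zi[:, None] / (zi[:, None] + (1 - zi[:, None]) * p0)
            w_zero = np.where(zero, np.nan_to_num(w_zero), 0.0)
            zi = w_zero.mean(axis=1)
            zi = np.clip(zi, 0.0, 1.0 - 1e-6)
            weights = 1.0 - w_zero
            wsum = weights.sum(axis=1)
            mu_g = (weights * norm).sum(axis=1) / np.maximum(wsum, 1e-12)
            mu_g = np.maximum(mu_g, 1e-8)
            phi, ml_failed = _fit_nb_dispersion(counts, mu_g, sf, phi, weights)
        mean = mu_g

    phi = np.where(ml_failed, phi_mom, phi)
    trend = MeanDispersionTrend.fit(np.log2(mean), np.log2(phi))
    return SimParams(
        gene_ids=cm.gene_ids.copy(),
        mean=mean,
        dispersion=phi,
        dropout=dropout,
        mean_disp_fit=trend,
        family=family,
        zi_prob=zi,
        n_cells_fitted=cm.n_cells,
        mom_fallback=np.asarray(ml_failed, dtype=bool),
        floored=floored,
    )


def estimate_amplification(read_cm: CountMatrix, umi_cm: CountMatrix) -> np.ndarray:
    """Per-gene PCR amplification rate: total reads / total UMIs.

    Computed over cells where the gene has at least one UMI; genes never
    observed get the global median rate.  Raises
    :class:`AmplificationError` if any entry has more UMIs than reads.
    """
    if read_cm.counts.shape != umi_cm.counts.shape:
        raise AmplificationError("read and UMI matrices must share the gene/cell index")
    if not np.array_equal(read_cm.gene_ids, umi_cm.gene_ids) or \
            not np.array_equal(read_cm.cell_ids, umi_cm.cell_ids):
        raise AmplificationError("read and UMI matrices must share the gene/cell index")
    reads = read_cm.counts.astype(float)
    umis = umi_cm.counts.astype(float)
    if np.any(umis > reads):
        raise AmplificationError("UMI count exceeds read count for some gene/cell")
    observed = umis > 0
    umi_tot = np.where(observed, umis, 0.0).sum(axis=1)
    read_tot = np.where(observed, reads, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = read_tot / umi_tot
    seen = umi_tot > 0
    if not seen.any():
        raise AmplificationError("no gene with any UMI observed")
    fallback = np.median(rate[seen])
    rate = np.where(seen, rate, fallback)
    return rate
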