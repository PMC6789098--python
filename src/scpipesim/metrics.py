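"""Pipeline scoring against simulation ground truth.

Confusion-matrix derivatives at the nominal BH level, the TPR-vs-observed-FDR
curve over p-value cutoffs, partial AUC restricted to the FDR-controlled
region (normalised to [0, 1], not penalising over-conservative methods),
the maximal Matthews correlation coefficient under FDR control, and the
robust RMSE between estimated and simulated size factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import statsmodels.api as sm

from .normalisation import standardise


class Confusion(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fdr: float


def confusion(q: np.ndarray, is_de: np.ndarray, alpha: float = 0.10) -> Confusion:
    """Confusion counts and rates for discoveries at q < alpha.

    TPR = TP/(TP+FN) (0 when nothing is truly DE); FDR = FP/(FP+TP)
    (0 when nothing is discovered).
    """
    q = np.asarray(q)
    is_de = np.asarray(is_de, dtype=bool)
    if q.shape != is_de.shape:
        raise ValueError("length mismatch")
    called = q < alpha
    tp = int(np.sum(called & is_de))
    fp = int(np.sum(called & ~is_de))
    fn = int(np.sum(~called & is_de))
    tn = int(np.sum(~called & ~is_de))
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (fp + tp) if (fp + tp) else 0.0
    return Confusion(tp, fp, tn, fn, tpr, fdr)


class Curve(NamedTuple):
    fdr: np.ndarray
    tpr: np.ndarray


def tpr_fdr_curve(p: np.ndarray, is_de: np.ndarray) -> Curve:
    """Observed (FDR, TPR) at every distinct p-value cutoff (ties share a point)."""
    p = np.asarray(p, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    if p.shape != is_de.shape:
        raise ValueError("length mismatch")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    de = is_de[order]
    tp_cum = np.cumsum(de)
    n_cum = np.arange(1, p.size + 1)
    last = np.flatnonzero(np.r_[ps[1:] != ps[:-1], True])
    tp = tp_cum[last].astype(float)
    n = n_cum[last].astype(float)
    n_de = is_de.sum()
    tpr = tp / n_de if n_de else np.zeros_like(tp)
    fdr = (n - tp) / n
    return Curve(fdr, tpr)


def partial_auc(curve: Curve, fdr_max: float = 0.10, extend: bool = True) -> float:
    """Normalised area under TPR over observed FDR within the controlled region.

    The controlled region is the largest prefix of cutoffs whose running
    maximum observed FDR stays <= ``fdr_max``.  With ``extend`` the last
    attained TPR is carried at constant level out to ``fdr_max``, so
    over-conservative rankings are not penalised.  Result lies in [0, 1].
    """
    fdr, tpr = np.asarray(curve.fdr), np.asarray(curve.tpr)
    if fdr.size == 0:
        return 0.0
    run_max = np.maximum.accumulate(fdr)
    ok = run_max <= fdr_max
    if not ok.any():
        return 0.0
    k = int(np.flatnonzero(ok)[-1]) + 1
    x, y = fdr[:k], tpr[:k]
    area = float(np.trapezoid(y, x)) if x.size > 1 else 0.0
    if extend and x[-1] < fdr_max:
        area += (fdr_max - x[-1]) * y[-1]
    return area / fdr_max


def matthews(tp: float, fp: float, tn: float, fn: float) -> float:
    """MCC with the zero-denominator convention MCC = 0."""
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / denom)


class MccResult(NamedTuple):
    mcc_max: float
    mcc_rescaled: float
    controlled_region_empty: bool


def mcc_max(p: np.ndarray, is_de: np.ndarray, alpha: float = 0.10) -> MccResult:
    """Maximal MCC over p-value cutoffs whose observed FDR stays controlled.

    Only cutoffs in the controlled prefix (running-max observed FDR <=
    alpha) are considered; an empty controlled region reports 0 with a
    flag.  ``mcc_rescaled`` = (MCC + 1)/2; the sample-size transformation
    to the open interval is applied at regression time
    (:func:`scpipesim.contribution.transform_mcc`).
    """
    p = np.asarray(p, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    order = np.argsort(p, kind="stable")
    de = is_de[order]
    ps = p[order]
    tp_cum = np.cumsum(de).astype(float)
    n_cum = np.arange(1, p.size + 1, dtype=float)
    last = np.flatnonzero(np.r_[ps[1:] != ps[:-1], True])
    tp = tp_cum[last]
    n = n_cum[last]
    fp = n - tp
    n_de = float(is_de.sum())
    g = float(p.size)
    fn = n_de - tp
    tn = g - n_de - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = fp / n
    run_max = np.maximum.accumulate(fdr)
    ok = run_max <= alpha
    if not ok.any():
        return MccResult(0.0, 0.5, True)
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    best = float(np.max(mcc[ok]))
    return MccResult(best, (best + 1.0) / 2.0, False)


def size_factor_rmse(estimated: np.ndarray, simulated: np.ndarray) -> float:
    """Robust RMSE between estimated and simulated size factors.

    Both vectors are standardised to geometric mean 1; an intercept-only
    Huber M-estimator (tuning 1.345) is fitted to the differences and the
    RMSE is the Huber-weighted root-mean-square residual, so isolated gross
    failures do not dominate the score.
    """
    est = np.asarray(estimated, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if est.shape != sim.shape:
        raise ValueError("length mismatch")
    d = standardise(est) - standardise(sim)
    if np.allclose(d, d[0]):
        return float(np.sqrt(np.mean((d - d[0]) ** 2)))
    fit = sm.RLM(d, np.ones_like(d), M=sm.robust.norms.HuberT(t=1.345)).fit()
    resid = d - fit.params[0]
    w = fit.weights
    return float(np.sqrt(np.sum(w * resid ** 2) / np.sum(w)))


@dataclass
class PipelineScore:
    """All evaluation outputs for one (pipeline, setup, replicate) run."""

    pipeline_id: str = ""
    setup_id: str = ""
    replicate: int = 0
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    tpr: float = 0.0
    fdr: float = 0.0
    pauc: float = 0.0
    mcc_max: float = 0.0
    mcc_rescaled: float = 0.5
    sf_rmse: float = np.nan
    runtime_s: float = 0.0
    failed: bool = False
    failed_stage: str = ""
    curve: Curve | None = field(default=None, repr=False)

    def as_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "curve"}
        return d


def score_run(p: np.ndarray, q: np.ndarray, is_de: np.ndarray,
              estimated_sf: np.ndarray | None, true_sf: np.ndarray | None,
              alpha: float = 0.10, **labels) -> PipelineScore:
    """Assemble a PipelineScore from test output and ground truth."""
    conf = confusion(q, is_de, alpha)
    curve = tpr_fdr_curve(p, is_de)
    pauc = partial_auc(curve, alpha)
    mcc = mcc_max(p, is_de, alpha)
    rmse = np.nan
    if estimated_sf is not None and true_sf is not None:
        rmse = size_factor_rmse(estimated_sf, true_sf)
    return PipelineScore(
        tp=conf.tp, fp=conf.fp, tn=conf.tn, fn=conf.fn,
        tpr=conf.tpr, fdr=conf.fdr, pauc=pauc,
        mcc_max=mcc.mcc_max, mcc_rescaled=mcc.mcc_rescaled,
        sf_rmse=rmse, curve=curve, **labels,
    )
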