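"""Two-group differential-expression tests on normalised log expression.

Tests run on log2 counts-per-million computed from RAW counts and externally
supplied size factors — imputed or filtered matrices never reach this stage.
Provided tests: per-gene Welch t with Satterthwaite degrees of freedom, and
a trended empirical-Bayes moderated t in which per-gene residual variances
are shrunk towards a lowess trend of log variance on average expression,
with the prior degrees of freedom estimated by moment matching of the
scaled-F distribution of variance ratios.  p-values are Benjamini-Hochberg
adjusted; the nominal FDR level is 10% throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from ._matrix import CountMatrix
from .normalisation import SizeFactorResult


@dataclass
class DETestResult:
    statistic: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    log2fc_hat: np.ndarray
    df: np.ndarray
    method: str
    alpha: float = 0.10
    prior_df: float | None = None     # moderated test only
    prior_df_nonfinite: bool = False

    def __post_init__(self) -> None:
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p-values outside [0, 1]")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log_cpm(cm: CountMatrix, sf: SizeFactorResult | np.ndarray,
            prior_count: float = 0.5) -> np.ndarray:
    """log2 counts-per-million on effective depths.

    The effective depth of cell j is sf_j times the mean raw library size
    (factors are full size factors standardised to geometric mean 1):
    y_gj = log2((c_gj + prior) / (L_j + 2 prior) * 1e6).
    """
    factors = sf.factors if isinstance(sf, SizeFactorResult) else np.asarray(sf)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    eff = factors * cm.counts.sum(axis=0).mean()
    return np.log2((cm.counts + prior_count) / (eff + 2 * prior_count)[None, :] * 1e6)


def _group_stats(y: np.ndarray, group: np.ndarray):
    group = np.asarray(group)
    g1, g2 = y[:, group == 0], y[:, group == 1]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 cells per group")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    return n1, n2, m1, m2, v1, v2


def welch_t_test(y: np.ndarray, group: np.ndarray, alpha: float = 0.10
                 ) -> DETestResult:
    """Per-gene two-sided Welch t-test with Satterthwaite df."""
    n1, n2, m1, m2, v1, v2 = _group_stats(y, group)
    se2 = v1 / n1 + v2 / n2
    effect = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, n1 + n2 - 2, df)
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return DETestResult(t, p, bh_adjust(p), effect, df, "welch", alpha)


def _trigamma_inverse(x: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Solve polygamma(1, y) = x for y (Newton on the inverse scale)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(n_iter):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def moderated_t_trend(y: np.ndarray, group: np.ndarray, alpha: float = 0.10,
                      span: float = 0.4, prior_df: float | None = None
                      ) -> DETestResult:
    """Trended empirical-Bayes moderated t-test.

    A lowess trend of log residual variance on average expression defines a
    mean-dependent prior variance; the prior degrees of freedom d0 come from
    moment matching: the residual spread of log variances around the trend
    beyond the chi-square sampling spread determines trigamma(d0/2).
    Posterior variances (d0 s0^2 + d s^2)/(d0 + d) feed a t-statistic with
    d + d0 degrees of freedom.  ``prior_df`` overrides the estimate (0
    recovers the ordinary per-gene t, inf fully shrinks to the trend).
    """
    n1, n2, m1, m2, v1, v2 = _group_stats(y, group)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d
    abar = y.mean(axis=1)
    effect = m2 - m1

    positive = s2 > 0
    s2_safe = np.where(positive, s2, np.nan)
    z = np.log(s2_safe)
    zf = z[positive]
    trend_fit = lowess(zf, abar[positive], frac=span, return_sorted=False,
                       delta=0.01 * np.ptp(abar[positive]))
    trend = np.interp(abar, np.sort(abar[positive]),
                      trend_fit[np.argsort(abar[positive])])
    e = zf - trend[positive] - psi(d / 2.0) + np.log(d / 2.0)
    evar = np.var(e, ddof=1) - polygamma(1, d / 2.0)

    nonfinite_d0 = False
    if prior_df is not None:
        d0 = float(prior_df)
    elif evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar)[0])
    else:
        d0 = np.inf
        nonfinite_d0 = True

    if np.isfinite(d0) and d0 > 0:
        log_s02 = trend + np.mean(e) + psi(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        log_s02 = trend + (np.mean(e) if np.isfinite(evar) else 0.0)
    s02 = np.exp(log_s02)

    if d0 == 0:
        s2_post = np.where(positive, s2, 0.0)
        df_total = np.full_like(s2, float(d))
    elif np.isinf(d0):
        s2_post = s02
        df_total = np.full_like(s2, 1e9)
    else:
        s2_post = (d0 * s02 + d * np.where(positive, s2, 0.0)) / (d0 + d)
        df_total = np.full_like(s2, float(d + d0))

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    degenerate = se == 0
    t = np.where(degenerate, 0.0, t)
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)
    return DETestResult(t, p, bh_adjust(p), effect, df_total, "modt", alpha,
                        prior_df=d0, prior_df_nonfinite=nonfinite_d0)


DE_TEST_METHODS = {
    "welch": welch_t_test,
    "modt": moderated_t_trend,
}
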