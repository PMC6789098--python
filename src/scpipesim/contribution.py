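"""Pipeline-step contribution analysis via beta regression.

Rescaled MCC scores (in [0, 1]) are squeezed into the open interval with
the sample-size transformation y' = (y (n - 1) + 0.5)/n and modelled with a
beta regression using the log-log mean link g(mu) = -log(-log(mu)) and
constant precision.  The contribution of each pipeline step is the drop in
pseudo-R^2 when that covariate is left out, scaled to the full model's
explained variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.genmod.families.links import LogLog
from statsmodels.othermod.betareg import BetaModel


class RankDeficientDesignError(ValueError):
    """Dummy-coded design matrix is rank deficient (collinear covariates)."""


def transform_mcc(values: np.ndarray, n: int | None = None) -> np.ndarray:
    """Squeeze [0, 1] scores into (0, 1): (y (n - 1) + 0.5)/n.

    ``n`` defaults to the number of scores (the regression sample size).
    Strictly monotone; the identity in the n -> infinity limit.
    """
    v = np.asarray(values, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("values must lie in [0, 1]")
    if n is None:
        n = v.size
    if n < 1:
        raise ValueError("n must be >= 1")
    return (v * (n - 1) + 0.5) / n


def _loglog(mu: np.ndarray) -> np.ndarray:
    return -np.log(-np.log(mu))


class BetaRegression:
    """Beta regression with log-log mean link and constant precision.

    statsmodels-style: construct from arrays or a formula + dataframe, call
    :meth:`fit`, inspect the returned :class:`BetaRegressionResults`.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray,
                 exog_names: list[str] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError("response must lie strictly inside (0, 1); "
                             "apply transform_mcc first")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            names = exog_names or [f"x{i}" for i in range(self.exog.shape[1])]
            dup = _collinear_columns(self.exog, names)
            raise RankDeficientDesignError(
                f"design matrix is rank deficient; collinear columns: {dup}")
        self._model = BetaModel(self.endog, self.exog, link=LogLog())
        self.exog_names = exog_names

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "BetaRegression":
        from patsy import dmatrices

        y, x = dmatrices(formula, data, return_type="dataframe")
        return cls(y.to_numpy().ravel(), x.to_numpy(), list(x.columns))

    def fit(self, **kwargs) -> "BetaRegressionResults":
        kwargs.setdefault("disp", 0)
        kwargs.setdefault("maxiter", 500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = self._model.fit(**kwargs)
        mu_hat = np.clip(self._model.predict(res.params, exog=self.exog),
                         1e-12, 1 - 1e-12)
        converged = bool(res.mle_retvals.get("converged", False))
        g_y = _loglog(self.endog)
        g_mu = _loglog(mu_hat)
        if np.var(g_mu) > 0 and np.var(g_y) > 0:
            pseudo_r2 = float(np.corrcoef(g_y, g_mu)[0, 1] ** 2)
        else:
            pseudo_r2 = 0.0
        return BetaRegressionResults(
            params=np.asarray(res.params),
            pseudo_r2=pseudo_r2,
            converged=converged,
            llf=float(res.llf),
            fitted_mean=mu_hat,
            n_obs=self.endog.size,
            exog_names=self.exog_names,
            _sm_results=res,
        )


@dataclass
class BetaRegressionResults:
    params: np.ndarray
    pseudo_r2: float
    converged: bool
    llf: float
    fitted_mean: np.ndarray
    n_obs: int
    exog_names: list[str] | None = None
    _sm_results: object = field(default=None, repr=False)

    def bse(self) -> np.ndarray:
        return np.asarray(self._sm_results.bse)

    def summary(self) -> str:
        names = self.exog_names or [f"x{i}" for i in range(len(self.params) - 1)]
        names = list(names) + ["precision"]
        lines = ["Beta regression (log-log link, constant precision)",
                 f"n = {self.n_obs}, logLik = {self.llf:.3f}, "
                 f"pseudo-R2 = {self.pseudo_r2:.4f}, converged = {self.converged}",
                 f"{'term':<30}{'coef':>12}{'se':>12}"]
        bse = self.bse()
        for name, b, s in zip(names, self.params, bse):
            lines.append(f"{name:<30}{b:>12.4f}{s:>12.4f}")
        return "\n".join(lines)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    dup = []
    for i in range(x.shape[1]):
        for j in range(i + 1, x.shape[1]):
            if np.allclose(x[:, i], x[:, j]):
                dup.extend([names[i], names[j]])
    if dup:
        return sorted(set(dup))
    # generic: name columns whose removal restores full rank
    full = np.linalg.matrix_rank(x)
    for i in range(x.shape[1]):
        rest = np.delete(x, i, axis=1)
        if np.linalg.matrix_rank(rest) == full:
            dup.append(names[i])
    return sorted(set(dup))


@dataclass
class ContributionResult:
    full_r2: float
    delta_r2: dict          # step -> raw pseudo-R2 drop (NaN if non-convergent)
    delta_share: dict       # step -> 100 * drop / full_r2
    converged: dict         # model label -> bool
    n_obs: int
    negative_delta: list = field(default_factory=list)
    link: str = "log-log"


def delta_r2(scores: pd.DataFrame, steps: list[str],
             response: str = "mcc_rescaled") -> ContributionResult:
    """Leave-one-covariate-out pseudo-R^2 decomposition.

    Fits the full additive model of the transformed response on all step
    covariates and one reduced model per step; each step's contribution is
    the pseudo-R^2 drop, also reported as a percentage of the full model's
    pseudo-R^2.  Non-convergent reduced models yield a missing (NaN)
    contribution, never zero.  Negative drops are reported as-is and
    flagged.
    """
    for step in steps:
        if scores[step].nunique() < 2:
            raise ValueError(f"covariate {step!r} needs >= 2 levels")
    y = transform_mcc(scores[response].to_numpy())
    data = scores[steps].copy()
    data["_y"] = y

    def _fit(cols: list[str]):
        formula = "_y ~ " + " + ".join(f"C({c})" for c in cols)
        model = BetaRegression.from_formula(formula, data)
        return model.fit()

    full = _fit(steps)
    converged = {"full": full.converged}
    deltas, shares, negative = {}, {}, []
    for step in steps:
        reduced = _fit([s for s in steps if s != step])
        converged[step] = reduced.converged
        if not (full.converged and reduced.converged):
            warnings.warn(f"beta regression without {step!r} did not converge; "
                          "contribution reported as missing", stacklevel=2)
            deltas[step] = float("nan")
            shares[step] = float("nan")
            continue
        dr = full.pseudo_r2 - reduced.pseudo_r2
        if dr < 0:
            negative.append(step)
        deltas[step] = dr
        shares[step] = 100.0 * dr / full.pseudo_r2 if full.pseudo_r2 > 0 else float("nan")
    return ContributionResult(
        full_r2=full.pseudo_r2,
        delta_r2=deltas,
        delta_share=shares,
        converged=converged,
        n_obs=len(scores),
        negative_delta=negative,
    )
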