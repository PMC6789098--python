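"""Synthetic protocol-like parameter bundles.

Real protocol estimates are not required to build or test the framework:
these generators produce parameter sets with the qualitative structure of
UMI-based and full-length read-level single-cell protocols — log-normal
mean expression, overdispersion decreasing with mean around a fitted trend,
dropout implied by the NB zero probability (plus extra zeros for the
read-level family), and an ERCC-like 92-spike technical model.

Defaults (fixed once, see docs/methods.md): gene means log2-normal(1, 2.2);
UMI-like dispersion trend phi = 0.1 + 1.5/mu with log2-normal scatter
(sd 0.25); read-level trend phi = 0.3 + 3/mu with zero-inflation
zi = 0.6 exp(-mu/4); spikes in 23 log2-spaced concentration levels x 4,
capture mean 0.1 with 2% cell-to-cell CV, technical dispersion 0.005.
"""

from __future__ import annotations

from typing import Literal, NamedTuple

import numpy as np

from .estimation import DISPERSION_FLOOR, MeanDispersionTrend, SimParams

FixtureKind = Literal["umi_like", "readlevel_like"]


class PlantedScores(NamedTuple):
    scores: "pd.DataFrame"
    generative_r2: float
    planted_order: tuple


def planted_score_table(seed: int = 0,
                        effect_sizes: dict | None = None,
                        reps: int = 10,
                        precision: float = 100.0,
                        intercept: float = 0.3) -> PlantedScores:
    """Factorial synthetic score table with fixed planted step effects.

    Each step contributes fixed, centred level offsets scaled by its effect
    size on the log-log link scale; scores are beta-distributed around the
    implied mean.  Used to validate the leave-one-out pseudo-R^2
    decomposition: the planted ranking of effect sizes is the ground truth.
    ``generative_r2`` is the squared link-scale correlation between the
    noisy scores and the noiseless linear predictor.
    """
    import pandas as pd

    effects = effect_sizes or {"normalisation": 1.0, "de_tool": 0.4,
                               "annotation": 0.15}
    n_levels = {step: (3 if i == len(effects) - 1 else 4)
                for i, step in enumerate(effects)}
    rng = np.random.default_rng(seed)
    offsets = {step: np.linspace(-1.5, 1.5, n_levels[step]) * s
               for step, s in effects.items()}
    grids = np.meshgrid(*[np.arange(n_levels[s]) for s in effects], indexing="ij")
    rows, etas, ys = [], [], []
    for combo in zip(*[g.ravel() for g in grids]):
        eta = intercept + sum(offsets[s][c] for s, c in zip(effects, combo))
        mu = np.exp(-np.exp(-eta))
        for _ in range(reps):
            y = float(np.clip(rng.beta(mu * precision, (1 - mu) * precision),
                              1e-9, 1 - 1e-9))
            rows.append({s: f"{s}_{c}" for s, c in zip(effects, combo)}
                        | {"mcc_rescaled": y})
            etas.append(eta)
            ys.append(y)
    etas = np.asarray(etas)
    g_y = -np.log(-np.log(np.asarray(ys)))
    gen_r2 = float(np.corrcoef(g_y, etas)[0, 1] ** 2)
    order = tuple(sorted(effects, key=effects.get, reverse=True))
    return PlantedScores(pd.DataFrame(rows), gen_r2, order)


class Fixture(NamedTuple):
    params: SimParams
    spikes: "SpikeParams"


def ercc_like_molecules(n_levels: int = 23, per_level: int = 4,
                        lo_log2: float = -2.0, hi_log2: float = 11.0) -> tuple:
    """92 spike molecule counts in log2-spaced concentration groups."""
    levels = np.power(2.0, np.linspace(lo_log2, hi_log2, n_levels))
    return tuple(np.repeat(levels, per_level))


def make_fixture(kind: FixtureKind, n_genes: int = 10_000, seed: int = 0) -> Fixture:
    """Deterministic protocol-like SimParams + SpikeParams bundle."""
    from .simulation import SpikeParams

    if n_genes < 100:
        raise ValueError("need at least 100 genes")
    if kind not in ("umi_like", "readlevel_like"):
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    mean = np.power(2.0, rng.normal(1.0, 2.2, size=n_genes))
    mean = np.clip(mean, 2.0 ** -6, None)

    if kind == "umi_like":
        trend_phi = 0.1 + 1.5 / mean
        family = "NB"
        zi = None
    else:
        trend_phi = 0.3 + 3.0 / mean
        family = "ZINB"
        zi = np.clip(0.6 * np.exp(-mean / 4.0), 0.0, 0.9)
    log2_phi = np.log2(trend_phi) + rng.normal(0.0, 0.25, size=n_genes)
    phi = np.clip(np.power(2.0, log2_phi), DISPERSION_FLOOR, None)

    r = 1.0 / phi
    p0_nb = np.power(r / (r + mean), r)
    dropout = p0_nb if zi is None else zi + (1 - zi) * p0_nb

    trend = MeanDispersionTrend.fit(np.log2(mean), np.log2(phi))
    params = SimParams(
        gene_ids=np.array([f"gene{i}" for i in range(n_genes)]),
        mean=mean,
        dispersion=phi,
        dropout=np.clip(dropout, 0.0, 1.0),
        mean_disp_fit=trend,
        family=family,
        zi_prob=zi,
        n_cells_fitted=0,
    )
    spikes = SpikeParams(
        molecules=ercc_like_molecules(),
        capture_mean=0.1,
        capture_sd=0.002,
        tech_dispersion=0.005,
    )
    return Fixture(params=params, spikes=spikes)
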