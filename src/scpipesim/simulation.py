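"""Two-group experiment simulation with known ground truth.

Datasets are drawn from estimated (or fixture) NB/ZINB parameters: a chosen
fraction of genes is differentially expressed between two cell groups, with
log2 fold-change magnitudes from a narrow gamma distribution
Gamma(shape=1, rate=2) and a sign pattern that is symmetric (50% up),
asymmetric (75% up) or completely asymmetric (100% up).  Each cell receives
a size factor from a narrow normal N(1, 0.1) truncated to positive values.
Spike-in counts, binomial thinning of read counts, and UMI reconstruction
from amplification rates are also provided.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from ._matrix import CountMatrix
from .estimation import DISPERSION_CEIL, DISPERSION_FLOOR, SimParams

Pattern = Literal["symmetric", "asymmetric", "completely_asymmetric"]

UP_FRACTION = {
    "symmetric": 0.5,
    "asymmetric": 0.75,
    "completely_asymmetric": 1.0,
}


def derive_seed(*parts) -> int:
    """Deterministic sub-seed (< 2^31) from arbitrary hashable parts."""
    key = json.dumps([str(p) for p in parts]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# setup / dataset containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DESetup:
    """One point of the simulation grid."""

    n1: int = 384
    n2: int = 384
    n_genes: int = 10_000
    p_de: float = 0.05
    pattern: Pattern = "symmetric"
    lfc_shape: float = 1.0
    lfc_rate: float = 2.0
    sf_mean: float = 1.0
    sf_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 cells per group")
        if not 0 <= self.p_de < 1:
            raise ValueError("p_de must lie in [0, 1)")
        if self.pattern not in UP_FRACTION:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.sf_sd < 0:
            raise ValueError("sf_sd must be non-negative")
        if self.sf_mean <= 0:
            raise ValueError("sf_mean must be positive")

    @property
    def up_fraction(self) -> float:
        return UP_FRACTION[self.pattern]

    @property
    def n_cells(self) -> int:
        return self.n1 + self.n2

    def label(self) -> str:
        return (f"n{self.n1}v{self.n2}_pde{self.p_de:g}_{self.pattern}")


@dataclass
class SimulatedDataset:
    """One simulated replicate with full ground truth."""

    counts: CountMatrix
    group: np.ndarray          # 0/1 per cell
    true_lfc: np.ndarray       # log2 scale, 0 for non-DE genes
    is_de: np.ndarray
    true_sf: np.ndarray
    setup: DESetup
    replicate_id: int = 0
    spike_counts: CountMatrix | None = None
    true_mean: np.ndarray | None = None        # baseline (group-1) NB mean
    true_dispersion: np.ndarray | None = None  # baseline NB dispersion

    # -- serialisation ---------------------------------------------------
    def write_dir(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        self.counts.to_mtx(os.path.join(path, "counts"))
        gene_truth = {
            "gene_id": self.counts.gene_ids,
            "is_de": self.is_de.astype(int),
            "true_lfc": self.true_lfc,
        }
        if self.true_mean is not None:
            gene_truth["true_mean"] = self.true_mean
            gene_truth["true_dispersion"] = self.true_dispersion
        pd.DataFrame(gene_truth).to_csv(
            os.path.join(path, "truth.genes.tsv"), sep="\t", index=False,
            float_format="%.17g")
        pd.DataFrame({
            "cell_id": self.counts.cell_ids,
            "group": self.group,
            "true_sf": self.true_sf,
        }).to_csv(os.path.join(path, "truth.cells.tsv"), sep="\t", index=False,
                  float_format="%.17g")
        if self.spike_counts is not None:
            self.spike_counts.to_mtx(os.path.join(path, "spikes"))
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump({"setup": asdict(self.setup),
                       "replicate_id": self.replicate_id}, fh, indent=1)

    @classmethod
    def read_dir(cls, path: str) -> "SimulatedDataset":
        counts = CountMatrix.from_mtx(os.path.join(path, "counts"))
        genes = pd.read_csv(os.path.join(path, "truth.genes.tsv"), sep="\t",
                            float_precision="round_trip")
        cells = pd.read_csv(os.path.join(path, "truth.cells.tsv"), sep="\t",
                            float_precision="round_trip")
        spikes = None
        if os.path.exists(os.path.join(path, "spikes.mtx")):
            spikes = CountMatrix.from_mtx(os.path.join(path, "spikes"))
        with open(os.path.join(path, "manifest.json")) as fh:
            man = json.load(fh)
        return cls(
            counts=counts,
            group=cells["group"].to_numpy(),
            true_lfc=genes["true_lfc"].to_numpy(),
            is_de=genes["is_de"].astype(bool).to_numpy(),
            true_sf=cells["true_sf"].to_numpy(),
            setup=DESetup(**man["setup"]),
            replicate_id=man["replicate_id"],
            spike_counts=spikes,
            true_mean=genes["true_mean"].to_numpy() if "true_mean" in genes else None,
            true_dispersion=(genes["true_dispersion"].to_numpy()
                             if "true_dispersion" in genes else None),
        )


@dataclass(frozen=True)
class SpikeParams:
    """Technical spike-in model: known molecules, per-cell capture, NB noise."""

    molecules: tuple = ()
    capture_mean: float = 0.1
    capture_sd: float = 0.002
    tech_dispersion: float = 0.005

    def __post_init__(self) -> None:
        mols = np.asarray(self.molecules, dtype=float)
        if mols.size == 0 or np.any(mols <= 0):
            raise ValueError("molecules must be positive")
        if not 0 < self.capture_mean <= 1:
            raise ValueError("capture efficiency mean must lie in (0, 1]")
        if self.capture_sd < 0 or self.tech_dispersion < 0:
            raise ValueError("capture_sd and tech_dispersion must be non-negative")

    @property
    def n_spikes(self) -> int:
        return len(self.molecules)


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

class DEPattern(NamedTuple):
    is_de: np.ndarray
    true_lfc: np.ndarray


def draw_de_pattern(setup: DESetup, rng: np.random.Generator) -> DEPattern:
    """Flag round(p_de*G) genes as DE and draw signed gamma LFC magnitudes.

    Among DE genes, ceil(up_fraction * n_de) are up-regulated (positive log2
    fold change in group 2); gene assignment is randomised.
    """
    g = setup.n_genes
    n_de = int(round(setup.p_de * g))
    if setup.p_de > 0 and n_de == 0:
        warnings.warn("p_de * n_genes < 1: no DE genes drawn", stacklevel=2)
    is_de = np.zeros(g, dtype=bool)
    lfc = np.zeros(g)
    if n_de:
        idx = rng.choice(g, size=n_de, replace=False)
        is_de[idx] = True
        mags = rng.gamma(shape=setup.lfc_shape, scale=1.0 / setup.lfc_rate, size=n_de)
        n_up = int(np.ceil(setup.up_fraction * n_de))
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        lfc[idx] = mags * signs  # idx is already in random order
    return DEPattern(is_de, lfc)


def draw_size_factors(n_cells: int, mu: float = 1.0, sd: float = 0.1,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """i.i.d. N(mu, sd) truncated to (0, inf) by redrawing."""
    if mu <= 0:
        raise ValueError("size-factor mean must be positive")
    if sd < 0:
        raise ValueError("size-factor sd must be non-negative")
    rng = rng or np.random.default_rng()
    if sd == 0:
        return np.full(n_cells, mu)
    out = rng.normal(mu, sd, size=n_cells)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sd, size=bad.sum())
        bad = out <= 0
    return out


def _dispersion_at(params: SimParams, log2_mean: np.ndarray,
                   residual: np.ndarray) -> np.ndarray:
    """Dispersion from the fitted trend at a (shifted) mean plus the gene's
    own residual; non-finite values are clamped to the boundary."""
    log2_phi = params.mean_disp_fit(log2_mean) + residual
    phi = np.power(2.0, log2_phi)
    phi = np.where(np.isfinite(phi), phi, DISPERSION_CEIL)
    return np.clip(phi, DISPERSION_FLOOR, DISPERSION_CEIL)


def simulate_counts(params: SimParams, setup: DESetup,
                    rng: np.random.Generator | None = None,
                    spike_params: SpikeParams | None = None,
                    replicate_id: int = 0) -> SimulatedDataset:
    """Simulate a two-group NB/ZINB dataset with ground truth.

    Gene parameter tuples are sampled (with replacement if the estimate has
    fewer genes than requested).  For a cell j in group 2 and gene g the NB
    mean is sf_j * mu_g * 2^lfc_g; group 1 is at baseline.  The dispersion
    at a shifted mean is re-read from the mean-dispersion trend, offset by
    the gene's own residual from that trend.
    """
    rng = rng or np.random.default_rng(setup.seed)
    g = setup.n_genes
    if params.n_genes >= g:
        pick = rng.choice(params.n_genes, size=g, replace=False)
    else:
        pick = rng.choice(params.n_genes, size=g, replace=True)
    mu = params.mean[pick]
    resid = params.disp_residual()[pick]
    zi = params.zi_prob[pick] if params.family == "ZINB" else None

    is_de, lfc = draw_de_pattern(setup, rng)
    sf = draw_size_factors(setup.n_cells, setup.sf_mean, setup.sf_sd, rng)
    group = np.repeat([0, 1], [setup.n1, setup.n2])

    counts = np.empty((g, setup.n_cells), dtype=np.int64)
    for grp in (0, 1):
        cells = group == grp
        mu_grp = mu * np.power(2.0, lfc) if grp == 1 else mu
        phi = _dispersion_at(params, np.log2(mu_grp), resid)
        r = 1.0 / phi
        m = mu_grp[:, None] * sf[None, cells]
        p = r[:, None] / (r[:, None] + m)
        counts[:, cells] = rng.negative_binomial(r[:, None], p)
    if zi is not None:
        keep = rng.random(counts.shape) >= zi[:, None]
        counts *= keep

    cm = CountMatrix(
        counts,
        np.array([f"gene{i}" for i in range(g)]),
        np.array([f"cell{j}" for j in range(setup.n_cells)]),
    )
    spikes = None
    if spike_params is not None:
        spikes = simulate_spikes(spike_params, setup.n_cells, rng, size_factors=sf)
    phi_baseline = _dispersion_at(params, np.log2(mu), resid)
    return SimulatedDataset(
        counts=cm, group=group, true_lfc=lfc, is_de=is_de, true_sf=sf,
        setup=setup, replicate_id=replicate_id, spike_counts=spikes,
        true_mean=mu, true_dispersion=phi_baseline,
    )


def simulate_spikes(sp: SpikeParams, n_cells: int,
                    rng: np.random.Generator | None = None,
                    size_factors: np.ndarray | None = None) -> CountMatrix:
    """Purely technical spike-in counts.

    Per cell a capture efficiency is drawn log-normally around
    ``capture_mean`` (CV = capture_sd / capture_mean); when the spikes are
    simulated inside a dataset the capture is additionally scaled by the
    cell's true size factor, so spike totals carry the depth signal and
    nothing else.  Spike s in cell j is NB with mean molecules_s * c_j and
    dispersion ``tech_dispersion``.
    """
    rng = rng or np.random.default_rng()
    mols = np.asarray(sp.molecules, dtype=float)
    if sp.capture_sd == 0:
        capture = np.full(n_cells, sp.capture_mean)
    else:
        cv = sp.capture_sd / sp.capture_mean
        sigma = np.sqrt(np.log1p(cv ** 2))
        capture = rng.lognormal(np.log(sp.capture_mean) - sigma ** 2 / 2, sigma,
                                size=n_cells)
    if size_factors is not None:
        capture = capture * np.asarray(size_factors)
    m = mols[:, None] * capture[None, :]
    if sp.tech_dispersion == 0:
        counts = rng.poisson(m)
    else:
        r = 1.0 / sp.tech_dispersion
        counts = rng.negative_binomial(r, r / (r + m))
    return CountMatrix(
        counts.astype(np.int64),
        np.array([f"ERCC-{i:05d}" for i in range(len(mols))]),
        np.array([f"cell{j}" for j in range(n_cells)]),
        is_spike=np.ones(len(mols), dtype=bool),
    )


def thin_counts(cm: CountMatrix, p: float,
                rng: np.random.Generator | None = None) -> CountMatrix:
    """Binomial thinning: every read survives independently with probability p."""
    if not 0 <= p <= 1:
        raise ValueError("thinning probability must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    thinned = rng.binomial(cm.counts, p)
    return CountMatrix(thinned.astype(np.int64), cm.gene_ids.copy(),
                       cm.cell_ids.copy(), cm.is_spike.copy())


def umi_survival_probability(amp: np.ndarray, p: float,
                             model: str = "poisson") -> np.ndarray:
    """Probability that a UMI keeps >= 1 read after thinning reads at rate p.

    ``model="poisson"``: reads per UMI r ~ 1 + Poisson(amp - 1), giving
    1 - (1-p) * exp(-(amp-1) * p).  ``model="fixed"``: exactly ``amp`` reads
    per UMI, giving 1 - (1-p)^amp.
    """
    amp = np.asarray(amp, dtype=float)
    if model == "poisson":
        return 1.0 - (1.0 - p) * np.exp(-(amp - 1.0) * p)
    if model == "fixed":
        return 1.0 - np.power(1.0 - p, amp)
    raise ValueError(f"unknown reads-per-UMI model {model!r}")


def reconstruct_umis(umi_cm: CountMatrix, amp: np.ndarray, p: float,
                     rng: np.random.Generator | None = None,
                     model: str = "poisson") -> CountMatrix:
    """Downsample a UMI matrix to what read-thinning at rate p would retain.

    Each UMI of gene g survives independently with the closed-form
    probability from :func:`umi_survival_probability` at that gene's
    amplification rate.
    """
    amp = np.asarray(amp, dtype=float)
    if np.any(amp < 1):
        raise ValueError("amplification rates must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("read retention probability must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    surv = umi_survival_probability(amp, p, model=model)
    kept = rng.binomial(umi_cm.counts, surv[:, None])
    return CountMatrix(kept.astype(np.int64), umi_cm.gene_ids.copy(),
                       umi_cm.cell_ids.copy(), umi_cm.is_spike.copy())
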