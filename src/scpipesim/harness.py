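"""Benchmark grid runner: setups x pipelines x replicates.

The study design enumerates 27 DE-setups (3 sample-size configurations x 3
DE fractions x 3 asymmetry patterns) applied to the parameter bundles of
the estimable protocol/aligner/annotation count matrices with 20 replicates
each.  Every run is addressed by a deterministic sub-seed derived from the
master seed, so the entire score table is bit-identical across re-runs, and
stage failures become flagged score rows rather than crashes.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .detest import DE_TEST_METHODS, log_cpm
from .estimation import SimParams
from .metrics import PipelineScore, score_run
from .normalisation import (
    PreprocessSpec,
    SIZE_FACTOR_METHODS,
    preprocess,
    size_factors_deconvolution,
    size_factors_spike,
)
from .simulation import DESetup, SimulatedDataset, SpikeParams, derive_seed, simulate_counts

logger = logging.getLogger("scpipesim")

SAMPLE_SIZES = ((96, 96), (384, 384), (50, 200))
DE_FRACTIONS = (0.05, 0.20, 0.60)
PATTERNS = ("symmetric", "asymmetric", "completely_asymmetric")

PROTOCOLS = ("SCRB-seq", "Smart-seq2", "CEL-seq2", "Drop-seq", "10xGenomics")
ALIGNERS = ("STAR", "BWA", "kallisto")
ANNOTATIONS = ("GENCODE", "RefSeq", "Vega")


def default_setups(n_genes: int = 10_000) -> list[DESetup]:
    """The full 27-point DE-setup grid."""
    return [
        DESetup(n1=n1, n2=n2, n_genes=n_genes, p_de=p, pattern=pat)
        for (n1, n2), p, pat in itertools.product(SAMPLE_SIZES, DE_FRACTIONS, PATTERNS)
    ]


def count_matrix_labels(protocols: Sequence[str] = PROTOCOLS,
                        aligners: Sequence[str] = ALIGNERS,
                        annotations: Sequence[str] = ANNOTATIONS) -> list[str]:
    """Labels of the protocol x aligner x annotation count matrices."""
    return [f"{p}_{a}_{n}" for p, a, n in
            itertools.product(protocols, aligners, annotations)]


@dataclass(frozen=True)
class PipelineSpec:
    """One analysis pipeline: preprocessing -> normalisation -> DE test."""

    protocol_label: str = "umi_like"
    preprocessing: PreprocessSpec = field(default_factory=PreprocessSpec)
    normalisation: str = "mr"
    norm_options: tuple = ()          # sorted (key, value) pairs
    spikes: bool = False
    de_test: str = "modt"

    def __post_init__(self) -> None:
        if self.normalisation not in set(SIZE_FACTOR_METHODS) | {"spike", "true"}:
            raise ValueError(f"unknown normalisation {self.normalisation!r}")
        if self.de_test not in DE_TEST_METHODS:
            raise ValueError(f"unknown DE test {self.de_test!r}")

    @property
    def id(self) -> str:
        key = json.dumps({
            "protocol": self.protocol_label,
            "pre": [self.preprocessing.mode, self.preprocessing.filter_threshold,
                    self.preprocessing.imputer],
            "norm": [self.normalisation, list(self.norm_options)],
            "spikes": self.spikes,
            "test": self.de_test,
        }, sort_keys=True)
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class GridManifest:
    setups: list[DESetup]
    pipelines: list[PipelineSpec]
    replicates: int = 20
    master_seed: int = 0
    protocol_bundles: Sequence[str] = ("bundle0",)

    @property
    def n_datasets(self) -> int:
        return len(self.setups) * len(self.protocol_bundles) * self.replicates


class RunDescriptor(NamedTuple):
    setup: DESetup
    pipeline: PipelineSpec
    bundle: str
    replicate: int
    seed: int


def enumerate_grid(manifest: GridManifest) -> list[RunDescriptor]:
    """Cartesian product of setups x bundles x pipelines x replicates.

    Incompatible combinations (spike-based normalisation in a pipeline that
    carries no spikes) are excluded and logged; the exclusion count is
    visible via the returned list's length versus the full product.
    """
    runs = []
    for setup, bundle, pipe, rep in itertools.product(
            manifest.setups, manifest.protocol_bundles,
            manifest.pipelines, range(manifest.replicates)):
        if pipe.normalisation == "spike" and not pipe.spikes:
            logger.info("excluded: spike normalisation without spikes (%s)", pipe.id)
            continue
        seed = derive_seed(manifest.master_seed, setup.label(), bundle, rep)
        runs.append(RunDescriptor(setup, pipe, bundle, rep, seed))
    return runs


def estimate_size_factors(data: SimulatedDataset, pipeline: PipelineSpec):
    """Run the pipeline's preprocessing + normalisation stage."""
    if pipeline.normalisation == "true":
        from .normalisation import SizeFactorResult, standardise
        return SizeFactorResult("true", standardise(data.true_sf))
    if pipeline.normalisation == "spike":
        if data.spike_counts is None:
            raise ValueError("spike normalisation requested but no spikes simulated")
        return size_factors_spike(data.spike_counts)
    pre = preprocess(data.counts, pipeline.preprocessing)
    method = SIZE_FACTOR_METHODS[pipeline.normalisation]
    return method(pre, **dict(pipeline.norm_options))


def run_pipeline(params: SimParams, descriptor: RunDescriptor,
                 spike_params: SpikeParams | None = None,
                 alpha: float = 0.10) -> PipelineScore:
    """Simulate (from the descriptor's sub-seed) and score one pipeline run.

    The dataset is simulated on the fly; preprocessing and normalisation
    produce size factors which are applied to the RAW counts for DE
    testing.  Any stage failure yields a flagged score row.
    """
    setup, pipe = descriptor.setup, descriptor.pipeline
    t0 = time.perf_counter()
    labels = dict(pipeline_id=pipe.id, setup_id=setup.label(),
                  replicate=descriptor.replicate)
    stage = "simulate"
    try:
        rng = np.random.default_rng(descriptor.seed)
        need_spikes = pipe.spikes or pipe.normalisation == "spike"
        data = simulate_counts(params, setup, rng,
                               spike_params=spike_params if need_spikes else None,
                               replicate_id=descriptor.replicate)
        stage = "normalise"
        sf = estimate_size_factors(data, pipe)
        stage = "detest"
        y = log_cpm(data.counts, sf)
        res = DE_TEST_METHODS[pipe.de_test](y, data.group, alpha=alpha)
        stage = "score"
        score = score_run(res.p_value, res.q_value, data.is_de,
                          sf.factors, data.true_sf, alpha=alpha, **labels)
    except Exception as exc:  # noqa: BLE001 - failures are data, not crashes
        logger.warning("run failed at stage %s: %s", stage, exc)
        score = PipelineScore(failed=True, failed_stage=stage, **labels)
    score.runtime_s = time.perf_counter() - t0
    return score


def run_grid(params: SimParams, manifest: GridManifest,
             spike_params: SpikeParams | None = None) -> pd.DataFrame:
    """Run every descriptor in the grid and return the tidy score table."""
    rows = [run_pipeline(params, d, spike_params).as_row()
            for d in enumerate_grid(manifest)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def manifest_from_yaml(path: str) -> GridManifest:
    """Load a GridManifest from a YAML config (see docs/methods.md)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    setups = [DESetup(**s) for s in cfg.get("setups", [])] or default_setups()
    pipelines = []
    for p in cfg.get("pipelines", []):
        pre = PreprocessSpec(**p.pop("preprocessing", {}))
        norm_options = tuple(sorted(p.pop("norm_options", {}).items()))
        pipelines.append(PipelineSpec(preprocessing=pre,
                                      norm_options=norm_options, **p))
    return GridManifest(
        setups=setups,
        pipelines=pipelines,
        replicates=int(cfg.get("replicates", 20)),
        master_seed=int(cfg.get("master_seed", 0)),
        protocol_bundles=tuple(cfg.get("protocol_bundles", ["bundle0"])),
    )
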