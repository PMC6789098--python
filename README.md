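# scpipesim

Simulation-based benchmarking of single-cell RNA-seq analysis pipelines.

Single-cell DE analyses chain several choices — count preprocessing,
size-factor normalisation, DE test — and the end result depends on the
chain, not any link alone. `scpipesim` is for method developers and
analysts who want to measure that dependence: it simulates two-group
experiments with known ground truth from realistic negative-binomial (or
zero-inflated NB) gene parameters, runs native implementations of the
standard pipeline stages, and scores every pipeline x setup x replicate
combination.

The core model: gene g in cell j has counts
`c_gj ~ NB(mean = sf_j * mu_g * 2^(lfc_g * [j in group 2]), size = 1/phi_g)`
with cell size factors `sf_j ~ N(1, 0.1)` truncated positive, a chosen
fraction of genes DE with `|lfc| ~ Gamma(shape 1, rate 2)` and an
asymmetry pattern (50/75/100% up-regulated), and `phi_g` tied to the mean
through a GCV cubic smoothing spline of log2 dispersion on log2 mean.
Pipelines are scored by size-factor RMSE (robust intercept model on the
difference to the simulated factors), TPR and observed FDR at BH 10%,
partial AUC of the TPR-vs-FDR curve restricted to the FDR-controlled
region, and the maximal Matthews correlation under FDR control; pipeline
steps' contributions are decomposed by leave-one-out pseudo-R^2 of a beta
regression with log-log link. See `docs/methods.md` for the full model
and every numerical choice.

Implemented natively: median-of-ratios (strict + positive-counts), TMM,
pooling deconvolution with optional PCA/Ward pre-clustering, spike-in
factors; Welch t and trended empirical-Bayes moderated t; binomial
thinning and UMI reconstruction from PCR amplification rates. Imputers and
external DE tools attach through a plug-in registry.

## Worked example

```python
import numpy as np
import scpipesim as sps

# protocol-like parameter bundle (10,000 genes) + ERCC-style spike model
fx = sps.make_fixture("umi_like", n_genes=10_000, seed=1)

# 384 vs 384 cells, 60% of genes DE, all up-regulated in group 2
setup = sps.DESetup(n1=384, n2=384, p_de=0.60,
                    pattern="completely_asymmetric", seed=12)
data = sps.simulate_counts(fx.params, setup, np.random.default_rng(12),
                           spike_params=fx.spikes)

for name, sf in [
    ("median-of-ratios", sps.size_factors_mr(data.counts)),
    ("spike-in totals ", sps.size_factors_spike(data.spike_counts)),
]:
    rmse = sps.size_factor_rmse(sf.factors, data.true_sf)
    res = sps.moderated_t_trend(sps.log_cpm(data.counts, sf), data.group)
    score = sps.score_run(res.p_value, res.q_value, data.is_de,
                          sf.factors, data.true_sf)
    print(f"{name}  sf-RMSE {rmse:.3f}  TPR {score.tpr:.2f} "
          f"FDR {score.fdr:.2f}  pAUC {score.pauc:.2f}")
```

Output:

```
median-of-ratios  sf-RMSE 0.102  TPR 0.70 FDR 0.48  pAUC 0.10
spike-in totals   sf-RMSE 0.030  TPR 0.61 FDR 0.04  pAUC 0.62
```

This is the benchmark's central phenomenon in one screenful: with 60% of
genes shifted in one direction, median-of-ratios factors absorb the
composition change (RMSE 0.10), every non-DE gene inherits a spurious
shift, and the observed FDR at a nominal 10% explodes to 0.48 — the
FDR-controlled region collapses and the pAUC with it (0.10). Spike-in
factors see only depth, keep the FDR at 0.04, and retain a pAUC of 0.62.

A grid of pipelines is driven by a YAML manifest
(`scpipesim run-grid --config grid.yaml --out scores.tsv`), and
`scpipesim decompose --scores scores.tsv --steps ...` fits the
contribution decomposition. `estimate`, `simulate`, `normalise`, `detest`
and `make-fixture` subcommands expose the individual stages.

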