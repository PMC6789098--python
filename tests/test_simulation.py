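import numpy as np
import pytest
from scipy import stats

import scpipesim as sps
from scpipesim._matrix import simple_count_matrix
from scpipesim.simulation import (
    DESetup,
    SpikeParams,
    draw_de_pattern,
    draw_size_factors,
    reconstruct_umis,
    simulate_counts,
    simulate_spikes,
    thin_counts,
    umi_survival_probability,
)


class TestDEPattern:
    def test_symmetric_counts_exact(self):
        setup = DESetup(n_genes=10_000, p_de=0.05, pattern="symmetric")
        is_de, lfc = draw_de_pattern(setup, np.random.default_rng(0))
        assert is_de.sum() == 500
        assert (lfc > 0).sum() == 250
        assert (lfc < 0).sum() == 250
        assert np.all(lfc[~is_de] == 0)

    def test_no_de(self):
        setup = DESetup(n_genes=1000, p_de=0.0)
        is_de, lfc = draw_de_pattern(setup, np.random.default_rng(0))
        assert not is_de.any()
        assert np.all(lfc == 0)

    def test_completely_asymmetric_all_up(self):
        setup = DESetup(n_genes=1000, p_de=0.1, pattern="completely_asymmetric")
        is_de, lfc = draw_de_pattern(setup, np.random.default_rng(1))
        assert is_de.sum() == 100
        assert (lfc[is_de] > 0).all()

    @pytest.mark.parametrize("pattern,up", [("symmetric", 0.5),
                                            ("asymmetric", 0.75),
                                            ("completely_asymmetric", 1.0)])
    def test_up_fraction_accounting(self, pattern, up):
        setup = DESetup(n_genes=5000, p_de=0.2, pattern=pattern)
        is_de, lfc = draw_de_pattern(setup, np.random.default_rng(2))
        n_de = is_de.sum()
        assert (lfc > 0).sum() == int(np.ceil(up * n_de))

    def test_tiny_p_de_warns_and_yields_none(self):
        setup = DESetup(n_genes=1000, p_de=0.0004)
        with pytest.warns(UserWarning):
            is_de, _ = draw_de_pattern(setup, np.random.default_rng(0))
        assert is_de.sum() == 0

    def test_lfc_magnitudes_follow_gamma(self):
        setup = DESetup(n_genes=50_000, p_de=0.5, lfc_shape=1.0, lfc_rate=2.0)
        _, lfc = draw_de_pattern(setup, np.random.default_rng(3))
        mags = np.abs(lfc[lfc != 0])
        # Gamma(1, rate 2) = Exp(2): mean 0.5
        assert mags.mean() == pytest.approx(0.5, rel=0.03)


class TestSizeFactors:
    def test_narrow_normal_sample_sd(self):
        sf = draw_size_factors(768, 1.0, 0.1, np.random.default_rng(4))
        assert (sf > 0).all()
        assert sf.std(ddof=1) == pytest.approx(0.1, rel=0.2)
        assert abs(sf.mean() - 1.0) < 3 * 0.1 / np.sqrt(768)

    def test_degenerate_sd_zero(self):
        assert np.all(draw_size_factors(10, 1.0, 0.0) == 1.0)

    def test_truncation_matches_truncated_normal_oracle(self):
        # mu=1, sd=0.5: P(X<=0)=Phi(-2)~0.0228; redraws shift the mean up
        sf = draw_size_factors(100_000, 1.0, 0.5, np.random.default_rng(5))
        oracle = stats.truncnorm(-2.0, np.inf, loc=1.0, scale=0.5)
        assert (sf > 0).all()
        assert sf.mean() == pytest.approx(oracle.mean(), abs=0.01)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            draw_size_factors(5, 0.0, 0.1)


class TestSimulateCounts:
    def test_dimensions_and_ground_truth(self, umi_fixture):
        setup = DESetup(n1=50, n2=200, n_genes=2000, p_de=0.2, seed=6)
        data = simulate_counts(umi_fixture.params, setup, np.random.default_rng(6))
        assert data.counts.counts.shape == (2000, 250)
        assert data.is_de.sum() == 400
        assert (data.group == 0).sum() == 50
        assert len(data.true_sf) == 250

    def test_null_groups_exchangeable(self, null_dataset):
        """p_de=0: per-gene Welch t on log counts rejects at ~ nominal rate
        for well-expressed genes."""
        counts = null_dataset.counts.counts
        expressed = counts.mean(axis=1) >= 5
        y = np.log2(counts[expressed] + 0.5)
        res = stats.ttest_ind(y[:, null_dataset.group == 0],
                              y[:, null_dataset.group == 1],
                              axis=1, equal_var=False)
        frac = (res.pvalue < 0.05).mean()
        n = expressed.sum()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n) + 0.01

    def test_poisson_limit_variance_equals_mean(self, umi_fixture):
        """At the dispersion floor the NB draw is Poisson-like."""
        params = umi_fixture.params
        rng = np.random.default_rng(8)
        mu = np.full(200, 5.0)
        r = 1.0 / 1e-4
        draws = rng.negative_binomial(r, r / (r + mu[:, None]),
                                      size=(200, 1000))
        ratio = draws.var(axis=1, ddof=1) / draws.mean(axis=1)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.05)

    def test_group_mean_ratio_converges_to_fold_change(self, umi_fixture):
        setup = DESetup(n1=384, n2=384, n_genes=2000, p_de=0.2,
                        pattern="symmetric", seed=9)
        data = simulate_counts(umi_fixture.params, setup, np.random.default_rng(9))
        counts = data.counts.counts / data.true_sf[None, :]
        m1 = counts[:, data.group == 0].mean(axis=1)
        m2 = counts[:, data.group == 1].mean(axis=1)
        sel = data.is_de & (data.true_mean >= 5)
        observed = m2[sel] / m1[sel]
        expected = 2.0 ** data.true_lfc[sel]
        assert np.median(np.abs(observed / expected - 1)) < 0.10

    def test_seed_discipline_bit_identical(self, umi_fixture):
        setup = DESetup(n1=20, n2=20, n_genes=500, p_de=0.1, seed=10)
        d1 = simulate_counts(umi_fixture.params, setup, np.random.default_rng(10))
        d2 = simulate_counts(umi_fixture.params, setup, np.random.default_rng(10))
        assert np.array_equal(d1.counts.counts, d2.counts.counts)
        assert np.array_equal(d1.true_lfc, d2.true_lfc)
        assert np.array_equal(d1.true_sf, d2.true_sf)

    def test_serialisation_round_trip_bit_identical(self, de_dataset, tmp_path):
        de_dataset.write_dir(str(tmp_path / "ds"))
        back = sps.SimulatedDataset.read_dir(str(tmp_path / "ds"))
        assert np.array_equal(back.counts.counts, de_dataset.counts.counts)
        assert np.array_equal(back.is_de, de_dataset.is_de)
        assert np.array_equal(back.true_lfc, de_dataset.true_lfc)
        assert np.array_equal(back.true_sf, de_dataset.true_sf)
        assert back.setup == de_dataset.setup
        assert np.array_equal(back.spike_counts.counts,
                              de_dataset.spike_counts.counts)

    def test_zinb_family_adds_zeros(self, readlevel_fixture):
        setup = DESetup(n1=100, n2=100, n_genes=1500, p_de=0.0, seed=12)
        data = simulate_counts(readlevel_fixture.params, setup,
                               np.random.default_rng(12))
        params = readlevel_fixture.params
        # high zi genes should show more zeros than their NB expectation
        r = 1 / params.dispersion
        p0_nb = (r / (r + params.mean)) ** r
        excess = (params.zi_prob > 0.3) & (params.mean > 5)
        name_to_truth = dict(zip([f"gene{i}" for i in range(1500)],
                                 range(1500)))
        zero_frac = (data.counts.counts == 0).mean(axis=1)
        # dataset genes are a permutation of fixture genes; map via true_mean
        assert zero_frac.mean() > p0_nb.mean()


class TestSpikes:
    def test_poisson_limit(self):
        sp = SpikeParams(molecules=(1000.0,), capture_mean=0.1,
                         capture_sd=0.0, tech_dispersion=0.0)
        cm = simulate_spikes(sp, 500, np.random.default_rng(13))
        assert cm.counts.mean() == pytest.approx(100.0, rel=0.05)

    def test_92_spike_design(self, umi_fixture):
        cm = simulate_spikes(umi_fixture.spikes, 10, np.random.default_rng(14))
        assert cm.counts.shape == (92, 10)
        assert cm.is_spike.all()

    def test_no_capture_variation_gives_pure_nb_cv(self):
        sp = SpikeParams(molecules=(500.0,), capture_mean=0.2,
                         capture_sd=0.0, tech_dispersion=0.05)
        cm = simulate_spikes(sp, 4000, np.random.default_rng(15))
        counts = cm.counts[0].astype(float)
        m = 500 * 0.2
        expected_cv = np.sqrt(1 / m + 0.05)
        assert counts.std(ddof=1) / counts.mean() == pytest.approx(
            expected_cv, rel=0.1)

    def test_size_factor_scaling(self):
        sp = SpikeParams(molecules=(1000.0,), capture_mean=0.1,
                         capture_sd=0.0, tech_dispersion=0.0)
        sf = np.array([0.5, 2.0] * 200)
        cm = simulate_spikes(sp, 400, np.random.default_rng(16), size_factors=sf)
        lo = cm.counts[0, sf == 0.5].mean()
        hi = cm.counts[0, sf == 2.0].mean()
        assert hi / lo == pytest.approx(4.0, rel=0.1)


class TestThinning:
    def test_p_one_is_identity(self):
        cm = simple_count_matrix(np.arange(12).reshape(3, 4))
        out = thin_counts(cm, 1.0, np.random.default_rng(0))
        assert np.array_equal(out.counts, cm.counts)

    def test_p_zero_is_empty(self):
        cm = simple_count_matrix(np.arange(12).reshape(3, 4))
        assert thin_counts(cm, 0.0, np.random.default_rng(0)).counts.sum() == 0

    def test_binomial_moments(self):
        rng = np.random.default_rng(17)
        cm = simple_count_matrix(rng.poisson(100, size=(100, 100)))
        total = cm.counts.sum()
        out = thin_counts(cm, 0.1, rng)
        sd = np.sqrt(total * 0.1 * 0.9)
        assert abs(out.counts.sum() - 0.1 * total) < 4 * sd
        assert np.all(out.counts <= cm.counts)

    def test_composition_moments(self):
        """thin(thin(., p), q) has the moments of thin(., pq)."""
        rng = np.random.default_rng(18)
        cm = simple_count_matrix(rng.poisson(50, size=(200, 50)))
        twice = thin_counts(thin_counts(cm, 0.5, rng), 0.4, rng)
        once = thin_counts(cm, 0.2, rng)
        tot = cm.counts.sum()
        sd = np.sqrt(tot * 0.2 * 0.8)
        assert abs(twice.counts.sum() - once.counts.sum()) < 6 * sd

    def test_invalid_p_rejected(self):
        cm = simple_count_matrix([[1]])
        with pytest.raises(ValueError):
            thin_counts(cm, 1.5)


class TestUMIReconstruction:
    def test_p_one_is_identity(self):
        cm = simple_count_matrix([[5, 3], [2, 0]])
        out = reconstruct_umis(cm, np.array([4.0, 2.0]), 1.0,
                               np.random.default_rng(0))
        assert np.array_equal(out.counts, cm.counts)

    def test_amp_one_equals_plain_thinning(self):
        # one read per UMI: survival probability is exactly p in both models
        for model in ("poisson", "fixed"):
            assert umi_survival_probability(np.array([1.0]), 0.3, model
                                            )[0] == pytest.approx(0.3)

    def test_fixed_model_closed_form(self):
        # amp=10, p=0.1 -> 1 - 0.9^10 ~ 0.6513
        s = umi_survival_probability(np.array([10.0]), 0.1, model="fixed")[0]
        assert s == pytest.approx(1 - 0.9 ** 10)
        rng = np.random.default_rng(19)
        cm = simple_count_matrix(np.full((1, 100), 1000))
        out = reconstruct_umis(cm, np.array([10.0]), 0.1, rng, model="fixed")
        kept = out.counts.sum() / cm.counts.sum()
        assert kept == pytest.approx(s, abs=3 * np.sqrt(s * (1 - s) / 1e5))

    def test_poisson_model_closed_form(self):
        # r ~ 1 + Poisson(9): survival = 1 - 0.9 exp(-0.9)
        s = umi_survival_probability(np.array([10.0]), 0.1, model="poisson")[0]
        assert s == pytest.approx(1 - 0.9 * np.exp(-0.9))

    def test_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(20)
        cm = simple_count_matrix(rng.poisson(20, size=(50, 20)))
        amp = np.full(50, 5.0)
        lo = reconstruct_umis(cm, amp, 0.05, np.random.default_rng(1))
        hi = reconstruct_umis(cm, amp, 0.5, np.random.default_rng(1))
        assert lo.counts.sum() <= hi.counts.sum()
        assert np.all(hi.counts <= cm.counts)

    def test_amp_below_one_rejected(self):
        cm = simple_count_matrix([[1]])
        with pytest.raises(ValueError):
            reconstruct_umis(cm, np.array([0.5]), 0.5)
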