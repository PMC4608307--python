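import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blocknet import de
from blocknet.io import CONDITIONS, ValidationError, collapse_replicates
from blocknet.simulate import EffectClass, SimulationConfig, simulate_expression
from conftest import make_study
from oracles import lstsq_rcbd


class TestBonferroniThreshold:
    def test_paper_cutoff(self):
        exact = de.bonferroni_threshold(0.05, 6)
        assert exact == pytest.approx(0.05 / 6)
        assert round(exact, 3) == 0.008

    def test_identity_at_m1(self):
        assert de.bonferroni_threshold(0.05, 1) == 0.05

    def test_exact_division(self):
        assert de.bonferroni_threshold(0.01, 4) == 0.0025

    def test_m_zero_rejected(self):
        with pytest.raises(ValueError):
            de.bonferroni_threshold(0.05, 0)

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            de.bonferroni_threshold(1.5, 6)


class TestFitBlockAnova:
    def test_exactly_additive_gives_zero_mse(self):
        b, k = 4, 4
        block = np.array([0.0, 1.0, 2.0, 3.0])
        treat = np.array([0.0, 0.5, 1.0, 1.5])
        y = 2.0 ** (8.0 + block[:, None] + treat[None, :])  # linear intensities
        study = make_study(y.reshape(1, -1), n_donors=b)
        fit = de.fit_block_anova(study)
        assert fit.mse[0] == pytest.approx(0.0, abs=1e-20)
        assert fit.df_error == (b - 1) * (k - 1)

    def test_constant_input(self):
        study = make_study(np.full((2, 8), 100.0), n_donors=2)
        fit = de.fit_block_anova(study)
        assert np.allclose(fit.mse, 0.0)
        assert np.allclose(fit.cell_means, np.log2(100.0))
        assert np.allclose(fit.block_means, np.log2(100.0))

    def test_matches_lstsq_oracle(self, random_rcbd_study):
        fit = de.fit_block_anova(random_rcbd_study)
        y = np.log2(random_rcbd_study.intensities)
        for g in range(len(random_rcbd_study.genes)):
            table = y[g].reshape(8, 4)  # donor-major layout from make_study
            mse, df, est, t, p = lstsq_rcbd(table, (1, 0))
            assert fit.mse[g] == pytest.approx(mse, abs=1e-10)
            assert fit.df_error == df

    def test_incomplete_design_rejected(self, random_rcbd_study):
        study = random_rcbd_study
        keep = [s for s in study.samples if s != study.samples[0]]
        sub = make_study(np.ones((2, 32)), n_donors=8)
        sub.design = sub.design.drop(study.samples[0])
        sub.samples = keep
        sub.intensities = sub.intensities[:, 1:]
        with pytest.raises(ValidationError, match="missing"):
            de.fit_block_anova(sub)

    def test_too_few_blocks_rejected(self):
        study = make_study(np.ones((1, 4)), n_donors=1)
        with pytest.raises(ValidationError):
            de.fit_block_anova(study)


class TestContrastTest:
    def test_null_contrast_with_noise(self, rng):
        y = 2.0 ** rng.normal(8, 0.3, size=(1, 32))
        study = make_study(y, n_donors=8)
        fit = de.fit_block_anova(study)
        # force identical cell means
        fit.cell_means[:] = 8.0
        est, t, p = de.contrast_test(fit, ("IgG", "medium"))
        assert est[0] == 0.0
        assert p[0] == pytest.approx(1.0)

    def test_noiseless_planted_difference(self):
        y = np.tile([100.0, 300.0, 100.0, 100.0], (1, 8))
        study = make_study(y, n_donors=8)
        fit = de.fit_block_anova(study)
        est, t, p = de.contrast_test(fit, ("IgG", "medium"))
        assert p[0] == 0.0
        assert np.isinf(t[0]) and t[0] > 0

    def test_noiseless_zero_difference(self):
        study = make_study(np.full((1, 8), 50.0), n_donors=2)
        fit = de.fit_block_anova(study)
        est, t, p = de.contrast_test(fit, ("IgG", "medium"))
        assert p[0] == 1.0 and t[0] == 0.0

    def test_matches_lstsq_oracle(self, random_rcbd_study):
        fit = de.fit_block_anova(random_rcbd_study)
        y = np.log2(random_rcbd_study.intensities)
        conditions = fit.conditions
        for pair in de.CONTRAST_PAIRS:
            est, t, p = de.contrast_test(fit, pair)
            j = conditions.index(pair[0])
            jr = conditions.index(pair[1])
            for g in range(10):
                table = y[g].reshape(8, 4)
                _, _, oest, ot, op = lstsq_rcbd(table, (j, jr))
                assert est[g] == pytest.approx(oest, abs=1e-10)
                assert t[g] == pytest.approx(ot, abs=1e-10)
                assert p[g] == pytest.approx(op, abs=1e-10)

    def test_unknown_condition(self, random_rcbd_study):
        fit = de.fit_block_anova(random_rcbd_study)
        with pytest.raises(ValidationError):
            de.contrast_test(fit, ("IgG", "LPS"))

    def test_antisymmetry(self, random_rcbd_study):
        fit = de.fit_block_anova(random_rcbd_study)
        e1, t1, p1 = de.contrast_test(fit, ("IgG_IL12", "medium"))
        e2, t2, p2 = de.contrast_test(fit, ("medium", "IgG_IL12"))
        np.testing.assert_allclose(e1, -e2, rtol=1e-12)
        np.testing.assert_allclose(t1, -t2, rtol=1e-12)
        np.testing.assert_allclose(p1, p2, rtol=1e-12)


class TestFoldChangeStats:
    def test_constant_ratio(self):
        y = np.tile([100.0, 300.0, 100.0, 100.0], (1, 8))
        study = make_study(y, n_donors=8)
        fc, diff = de.fold_change_stats(study, ("IgG", "medium"))
        assert fc[0] == pytest.approx(3.0)
        assert diff[0] == pytest.approx(200.0)

    def test_identity_pair(self, random_rcbd_study):
        fc, diff = de.fold_change_stats(random_rcbd_study, ("medium", "medium"))
        assert np.allclose(fc, 1.0)
        assert np.allclose(diff, 0.0)

    def test_sort_based_median_oracle(self, rng):
        y = rng.uniform(10, 1000, size=(20, 32))
        study = make_study(y, n_donors=8)
        fc, diff = de.fold_change_stats(study, ("IL12", "IgG"))
        for g in range(20):
            ratios, diffs = [], []
            for d in study.donors:
                t = study.column(study.sample_ids(d, "IL12")[0])[g]
                r = study.column(study.sample_ids(d, "IgG")[0])[g]
                ratios.append(t / r)
                diffs.append(abs(t - r))

            def median(v):  # even-length: mean of the two central order stats
                v = sorted(v)
                m = len(v) // 2
                return (v[m - 1] + v[m]) / 2 if len(v) % 2 == 0 else v[m]

            assert fc[g] == pytest.approx(median(ratios), rel=1e-12)
            assert diff[g] == pytest.approx(median(diffs), rel=1e-12)

    def test_antisymmetry_reciprocal_odd_blocks(self, rng):
        # exact reciprocal identity requires an odd block count (the
        # even-b median interpolates two order statistics)
        y = rng.uniform(10, 1000, size=(20, 7 * 4))
        study = make_study(y, n_donors=7)
        fc_ab, _ = de.fold_change_stats(study, ("IgG", "medium"))
        fc_ba, _ = de.fold_change_stats(study, ("medium", "IgG"))
        np.testing.assert_allclose(fc_ab, 1.0 / fc_ba, rtol=1e-12)


class TestCallDifferentialGenes:
    def test_planted_combo_unique_recovery(self):
        config = SimulationConfig(
            n_genes=100,
            baseline_log2_mean=10.0,
            baseline_log2_sd=0.3,
            donor_sd=0.2,
            noise_sd=0.05,
            replicate_sd=0.0,
            effect_classes=[EffectClass("combo_up", 30, (0.0, 0.0, 0.0, np.log2(3.0)))],
            seed=7,
        )
        study, truth = simulate_expression(config)
        table = de.call_differential_genes(collapse_replicates(study))
        planted = truth.genes_of_class("combo_up")
        combo = table[(table["contrast"] == "IgG_IL12_vs_medium") & table["significant"]]
        assert planted <= set(combo["gene"])
        assert set(combo.loc[combo["gene"].isin(planted), "direction"]) == {"up"}
        for other in ("IgG_vs_medium", "IL12_vs_medium"):
            hits = table[(table["contrast"] == other) & table["significant"]]
            assert not (planted & set(hits["gene"]))

    def test_diff_filter_blocks_low_intensity(self):
        # 3-fold ratio but 10 vs 30: passes p and fc, fails diff
        y = np.tile([10.0, 30.0, 10.0, 10.0], (1, 8))
        study = make_study(y, n_donors=8)
        table = de.call_differential_genes(study)
        row = table[(table["contrast"] == "IgG_vs_medium")].iloc[0]
        assert row.pass_p and row.pass_fc and not row.pass_diff
        assert not row.significant

    def test_direction_flags_consistent(self, random_rcbd_study):
        thresholds = de.DEThresholds()
        table = de.call_differential_genes(random_rcbd_study, thresholds)
        sig = table[table["significant"]]
        assert (sig["pass_p"] & sig["pass_fc"] & sig["pass_diff"]).all()
        up = table[table["direction"] == "up"]
        down = table[table["direction"] == "down"]
        assert (up["median_fc"] > thresholds.fc_threshold).all()
        assert (down["median_fc"] < 1 / thresholds.fc_threshold).all()

    def test_scale_equivariance(self, random_rcbd_study):
        scaled = make_study(random_rcbd_study.intensities * 10.0, n_donors=8)
        # raise diff threshold so floor clamping never kicks in differently
        base = de.call_differential_genes(random_rcbd_study)
        other = de.call_differential_genes(scaled)
        np.testing.assert_allclose(base["t"], other["t"], rtol=1e-9)
        np.testing.assert_allclose(base["p"], other["p"], rtol=1e-9)
        np.testing.assert_allclose(base["median_fc"], other["median_fc"], rtol=1e-9)
        np.testing.assert_allclose(
            base["median_abs_diff"] * 10.0, other["median_abs_diff"], rtol=1e-9
        )

    def test_six_contrasts_per_gene(self, random_rcbd_study):
        table = de.call_differential_genes(random_rcbd_study)
        assert len(table) == 6 * len(random_rcbd_study.genes)
        assert table.groupby("contrast").size().nunique() == 1
        assert table["primary"].sum() == 3 * len(random_rcbd_study.genes)


@settings(max_examples=20, deadline=None)
@given(st.floats(0.01, 0.2), st.integers(1, 20))
def test_bonferroni_property(alpha, m):
    cutoff = de.bonferroni_threshold(alpha, m)
    assert cutoff == alpha / m
    assert cutoff <= alpha


def test_thresholds_validation():
    with pytest.raises(ValueError):
        de.DEThresholds(alpha_per_contrast=-0.1)
    with pytest.raises(ValueError):
        de.DEThresholds(alpha_per_contrast=0.5, family_alpha=0.05)
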