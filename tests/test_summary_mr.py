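"""Summary-MR estimators: Wald ratios, IVW, I2_GX, MR-Egger, weighted
median, sensitivity analyses and the assembled report."""

import numpy as np
import pytest

from mrcausal.summary_mr import (
    beta_to_or,
    funnel_outliers,
    i2_gx,
    ivw,
    leave_one_out,
    mr_egger,
    mr_report,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from tests.conftest import iset_from_arrays


class TestWaldRatios:
    def test_direct_formula(self):
        iset = iset_from_arrays([0.1], [0.01], [0.24], [0.05])
        row = wald_ratios(iset).table.iloc[0]
        assert row["ratio_beta"] == pytest.approx(2.4)
        assert row["ratio_se"] == pytest.approx(0.5)

    def test_sign_carried_from_negative_gamma(self):
        iset = iset_from_arrays([-0.1], [0.01], [0.24], [0.05])
        assert wald_ratios(iset).table["ratio_beta"].iloc[0] == pytest.approx(-2.4)

    def test_zero_gamma_excluded_with_reason(self):
        iset = iset_from_arrays([0.1, 0.0, 0.2], [0.01] * 3, [0.2, 0.1, 0.4], [0.05] * 3)
        ratios = wald_ratios(iset)
        assert ratios.k == 2
        assert list(ratios.excluded["snp_id"]) == ["rs2"]
        assert ratios.excluded["reason"].iloc[0] == "zero exposure association"

    def test_second_order_se_adds_exposure_uncertainty(self):
        iset = iset_from_arrays([0.1], [0.02], [0.24], [0.05])
        first = wald_ratios(iset).table["ratio_se"].iloc[0]
        second = wald_ratios(iset, second_order_se=True).table["ratio_se"].iloc[0]
        expected = np.sqrt(0.05**2 / 0.1**2 + 0.24**2 * 0.02**2 / 0.1**4)
        assert second == pytest.approx(expected, rel=1e-12)
        assert second > first


class TestIvw:
    def test_equal_weights_average(self):
        iset = iset_from_arrays([1.0, 1.0], [0.1, 0.1], [1.0, 3.0], [1.0, 1.0])
        est = ivw(wald_ratios(iset), model="fixed")
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(1 / np.sqrt(2))

    def test_single_snp_equals_wald_ratio(self):
        iset = iset_from_arrays([0.1], [0.01], [0.24], [0.05])
        ratios = wald_ratios(iset)
        est = ivw(ratios, model="fixed")
        assert est.beta == pytest.approx(2.4, rel=1e-12)
        assert est.se == pytest.approx(0.5, rel=1e-12)

    def test_random_effects_never_deflates_se(self):
        iset = iset_from_arrays([1.0, 1.0, 1.0], [0.1] * 3, [2.0, 2.0, 2.0], [0.5] * 3)
        ratios = wald_ratios(iset)
        assert ivw(ratios, "multiplicative_random").se >= ivw(ratios, "fixed").se

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_weighted_through_origin_regression(self, seed):
        """IVW must equal WLS of Gamma on gamma through the origin with
        weights 1/se(Gamma)^2 (independent normal-equation computation)."""
        rng = np.random.default_rng(seed)
        k = 10
        g = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
        sg = rng.uniform(0.005, 0.02, k)
        G = 2.0 * g + rng.normal(0, 0.05, k)
        sG = rng.uniform(0.02, 0.1, k)
        iset = iset_from_arrays(g, sg, G, sG)
        est = ivw(wald_ratios(iset), model="fixed")
        w = 1.0 / sG**2
        slope = float((w * g * G).sum() / (w * g * g).sum())
        assert est.beta == pytest.approx(slope, rel=1e-9)

    def test_empty_raises(self):
        iset = iset_from_arrays([0.0], [0.01], [0.1], [0.05])
        with pytest.raises(ValueError):
            ivw(wald_ratios(iset), model="fixed")


class TestI2Gx:
    def test_equal_gammas_clamp_to_zero(self):
        iset = iset_from_arrays([0.2, 0.2, 0.2], [0.01] * 3, [0.4] * 3, [0.05] * 3)
        assert i2_gx(iset) == 0.0

    def test_frozen_formula_fixture(self):
        # gamma (0.1, 0.2, 0.4), se 0.01: Q_GX = 466.666..., I2 = (Q-2)/Q
        iset = iset_from_arrays([0.1, 0.2, 0.4], [0.01] * 3, [0.2] * 3, [0.05] * 3)
        assert i2_gx(iset) == pytest.approx(0.9957142857142857, abs=1e-9)

    def test_monotone_in_precision(self):
        vals = []
        for se in (0.05, 0.02, 0.01, 0.005, 0.001):
            iset = iset_from_arrays([0.1, 0.2, 0.4], [se] * 3, [0.2] * 3, [0.05] * 3)
            vals.append(i2_gx(iset))
        assert vals == sorted(vals)
        assert vals[-1] > 0.999

    def test_uses_magnitudes_after_orientation(self):
        a = iset_from_arrays([0.1, 0.2, 0.4], [0.01] * 3, [0.2] * 3, [0.05] * 3)
        b = iset_from_arrays([-0.1, 0.2, -0.4], [0.01] * 3, [0.2] * 3, [0.05] * 3)
        assert i2_gx(a) == pytest.approx(i2_gx(b), rel=1e-12)

    def test_needs_two_instruments(self):
        with pytest.raises(ValueError):
            i2_gx(iset_from_arrays([0.1], [0.01], [0.2], [0.05]))


class TestMrEgger:
    def test_exact_line_recovered(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        G = 0.1 + 2.0 * g
        iset = iset_from_arrays(g, [0.01] * 4, G, [0.04, 0.05, 0.06, 0.07])
        res = mr_egger(iset)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)
        assert res.slope.beta == pytest.approx(2.0, abs=1e-12)

    def test_proportional_case_matches_ivw(self):
        g = np.array([0.05, 0.1, 0.2, 0.3])
        iset = iset_from_arrays(g, [0.01] * 4, 2.0 * g, [0.05] * 4)
        res = mr_egger(iset)
        est = ivw(wald_ratios(iset), model="fixed")
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope.beta == pytest.approx(est.beta, rel=1e-9)

    def test_validity_gate_follows_i2gx(self):
        g = np.array([0.1, 0.2, 0.4])
        tight = iset_from_arrays(g, [0.001] * 3, 2 * g, [0.05] * 3)
        loose = iset_from_arrays(g, [0.12] * 3, 2 * g, [0.05] * 3)
        assert mr_egger(tight).valid is True
        assert i2_gx(loose) < 0.90 and mr_egger(loose).valid is False

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(iset_from_arrays([0.1, 0.2], [0.01] * 2, [0.2] * 2, [0.05] * 2))


class TestWeightedMedian:
    def test_equal_weight_midpoint_lands_on_middle_value(self):
        assert weighted_median_point(np.array([1.0, 2.0, 9.0]), np.ones(3)) == pytest.approx(2.0)

    def test_majority_weight_pins_estimate(self):
        beta = np.array([-3.0, 2.0, 2.0, 2.0, 7.0])
        weight = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert weighted_median_point(beta, weight) == pytest.approx(2.0)
        # 60% of weight on the value 2, scatter below and above
        beta2 = np.array([-5.0, 0.0, 2.0, 2.0, 6.0, 8.0])
        weight2 = np.array([0.1, 0.1, 0.3, 0.3, 0.1, 0.1])
        assert weighted_median_point(beta2, weight2) == pytest.approx(2.0)

    def test_bootstrap_se_deterministic_and_stable(self, study_iset):
        iset, _ = study_iset
        ratios = wald_ratios(iset)
        a = weighted_median(ratios, iset=iset, n_boot=1000, seed=5)
        b = weighted_median(ratios, iset=iset, n_boot=1000, seed=5)
        c = weighted_median(ratios, iset=iset, n_boot=1000, seed=6)
        assert a.se == b.se
        assert abs(a.se - c.se) / a.se < 0.10

    def test_needs_three_instruments(self):
        iset = iset_from_arrays([0.1, 0.2], [0.01] * 2, [0.2] * 2, [0.05] * 2)
        with pytest.raises(ValueError):
            weighted_median(wald_ratios(iset))


class TestFunnelOutliers:
    def test_hand_computed_fences(self):
        # ratios (1,2,3,4,100): Q1=2, Q3=4, IQR=2, fences (-4, 10)
        iset = iset_from_arrays([1.0] * 5, [0.1] * 5, [1.0, 2.0, 3.0, 4.0, 100.0],
                                [1.0] * 5)
        outliers, applicable = funnel_outliers(wald_ratios(iset))
        assert applicable and outliers == ["rs5"]

    def test_no_outliers_when_all_equal(self):
        iset = iset_from_arrays([1.0] * 6, [0.1] * 6, [2.0] * 6, [0.5] * 6)
        outliers, applicable = funnel_outliers(wald_ratios(iset))
        assert applicable and outliers == []

    def test_below_five_snps_not_applicable(self):
        iset = iset_from_arrays([1.0] * 4, [0.1] * 4, [1.0, 2.0, 3.0, 100.0], [1.0] * 4)
        outliers, applicable = funnel_outliers(wald_ratios(iset))
        assert not applicable and outliers == []


class TestLeaveOneOut:
    def test_k2_rows_equal_single_wald_ratios(self):
        iset = iset_from_arrays([0.1, 0.2], [0.01] * 2, [0.24, 0.5], [0.05] * 2)
        loo = leave_one_out(iset, estimator="ivw")
        # excluding rs1 leaves only rs2's ratio, and vice versa
        assert loo.set_index("excluded_snp_id").loc["rs1", "beta"] == pytest.approx(0.5 / 0.2)
        assert loo.set_index("excluded_snp_id").loc["rs2", "beta"] == pytest.approx(2.4)

    def test_no_pleiotropy_fixture_is_stable(self, study_iset):
        iset, truth = study_iset
        loo = leave_one_out(iset, estimator="ivw", model="multiplicative_random")
        assert len(loo) == iset.k
        assert not loo["outside_full_ci"].any()

    def test_excluding_planted_outlier_moves_estimate_toward_truth(self):
        g = np.full(6, 0.1)
        G = np.array([0.24, 0.24, 0.24, 0.24, 0.24, 2.4])  # last SNP wildly pleiotropic
        iset = iset_from_arrays(g, [0.01] * 6, G, [0.05] * 6)
        full = ivw(wald_ratios(iset), model="fixed")
        loo = leave_one_out(iset, estimator="ivw")
        reduced = loo.set_index("excluded_snp_id").loc["rs6", "beta"]
        assert abs(reduced - 2.4) < abs(full.beta - 2.4)
        assert reduced == pytest.approx(2.4, rel=1e-12)


class TestBetaToOr:
    def test_identity_at_zero(self):
        assert beta_to_or(0.0, -0.1, 0.1)[0] == pytest.approx(1.0)

    def test_printed_worked_example(self):
        orr, lo, hi = beta_to_or(2.90, 0.90, 4.89)
        assert round(orr, 2) == pytest.approx(18.17, abs=0.02)
        assert round(lo, 2) == pytest.approx(2.46, abs=0.02)
        assert round(hi, 2) == pytest.approx(132.95, abs=0.02)


class TestMrReport:
    def test_structure_on_study_fixture(self, study_iset):
        iset, truth = study_iset
        report = mr_report(iset, n_boot=200, seed=3)
        assert len(report.headline()) == 3
        assert set(report.estimates) == {"ivw", "ivw_fixed", "mr_egger", "weighted_median"}
        assert len(report.sensitivity.leave_one_out) == iset.k
        assert len(report.forest) == iset.k
        assert report.ratio_orientation == "outcome_over_exposure"

    def test_planted_outlier_triggers_rerun_section(self):
        rng = np.random.default_rng(8)
        k = 18
        g = rng.uniform(0.05, 0.15, k)
        G = 2.4 * g + rng.normal(0, 0.01, k)
        G[0] = 40.0 * g[0]  # one wildly inconsistent SNP
        iset = iset_from_arrays(g, [0.01] * k, G, [0.03] * k)
        report = mr_report(iset, n_boot=100, seed=4)
        assert report.sensitivity.outlier_snp_ids == ["rs1"]
        assert report.excluding_outliers is not None
        assert report.excluding_outliers["ivw"].n_snps == k - 1

    def test_egger_gate_consistent_in_headline(self, study_iset):
        iset, _ = study_iset
        report = mr_report(iset, n_boot=100, seed=5)
        head = report.headline().set_index("method")
        egger_valid = bool(head.loc["mr_egger", "valid"])
        assert egger_valid == (report.egger.i2_gx >= 0.90)


class TestInvariances:
    def test_allele_orientation_flip_leaves_estimates_unchanged(self, study_iset):
        iset, _ = study_iset
        flipped = iset.table.copy()
        rng = np.random.default_rng(9)
        mask = rng.random(len(flipped)) < 0.5
        flipped.loc[mask, "gamma"] *= -1
        flipped.loc[mask, "big_gamma"] *= -1
        from mrcausal.datatypes import InstrumentSet

        other = InstrumentSet(table=flipped)
        for model in ("fixed", "multiplicative_random"):
            assert ivw(wald_ratios(iset), model).beta == pytest.approx(
                ivw(wald_ratios(other), model).beta, rel=1e-12
            )
        assert mr_egger(iset).slope.beta == pytest.approx(
            mr_egger(other).slope.beta, rel=1e-12
        )
        assert mr_egger(iset).intercept == pytest.approx(
            mr_egger(other).intercept, rel=1e-12
        )
        a = wald_ratios(iset)
        b = wald_ratios(other)
        assert weighted_median_point(
            a.table["ratio_beta"].to_numpy(), a.table["weight"].to_numpy()
        ) == pytest.approx(
            weighted_median_point(b.table["ratio_beta"].to_numpy(),
                                  b.table["weight"].to_numpy()),
            rel=1e-12,
        )

    def test_weight_rescaling_leaves_point_estimates_unchanged(self, study_iset):
        iset, _ = study_iset
        ratios = wald_ratios(iset)
        scaled = wald_ratios(iset)
        scaled.table["weight"] *= 37.5
        assert ivw(ratios, "fixed").beta == pytest.approx(
            ivw(scaled, "fixed").beta, rel=1e-12
        )
        assert weighted_median_point(
            ratios.table["ratio_beta"].to_numpy(), ratios.table["weight"].to_numpy()
        ) == pytest.approx(
            weighted_median_point(scaled.table["ratio_beta"].to_numpy(),
                                  scaled.table["weight"].to_numpy()),
            rel=1e-12,
        )

    def test_estimators_agree_without_pleiotropy(self, study_iset):
        iset, truth = study_iset
        ratios = wald_ratios(iset)
        est_ivw = ivw(ratios, "multiplicative_random")
        est_med = weighted_median(ratios, iset=iset, n_boot=300, seed=7)
        egger = mr_egger(iset)
        joint = np.sqrt(est_ivw.se**2 + est_med.se**2)
        assert abs(est_ivw.beta - est_med.beta) < 3 * joint
        assert abs(est_ivw.beta - truth.causal_beta) < 4 * est_ivw.se
        joint_e = np.sqrt(est_ivw.se**2 + egger.slope.se**2)
        assert abs(egger.slope.beta - est_ivw.beta) < 4 * joint_e
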