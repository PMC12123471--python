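import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairadmit.cohort import generate_cohort, perturb_scores
from fairadmit.groups import build_collection
from fairadmit.metrics import (BinningScheme, audit_multicalibration,
                               balanced_accuracy, expected_calibration_error,
                               false_negative_rate, false_positive_rate,
                               rank_metrics, subgroup_metric_table)
from fairadmit.presets import biased_cohort_config

from oracles import brute_auprc, brute_auroc, brute_balanced_accuracy, brute_ece


class TestECE:
    def test_perfect_binary_scores_have_zero_ece(self):
        y = np.array([0, 1, 1, 0, 1])
        assert expected_calibration_error(y.astype(float), y) == 0.0

    def test_two_bin_hand_example(self):
        scores = [0.05] * 4 + [0.95] * 4
        outcomes = [0, 0, 0, 1, 1, 1, 1, 0]
        # residual 0.2 in each occupied bin, equal weights
        assert expected_calibration_error(scores, outcomes) == pytest.approx(0.2)

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_binning(self, data):
        n = data.draw(st.integers(1, 40))
        scores = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
        outcomes = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        got = expected_calibration_error(scores, outcomes)
        assert got == pytest.approx(brute_ece(scores, outcomes), abs=1e-12)
        assert 0.0 <= got <= 1.0

    def test_rejects_empty_and_nan(self):
        with pytest.raises(ValueError):
            expected_calibration_error([], [])
        with pytest.raises(ValueError):
            expected_calibration_error([np.nan], [1])

    def test_max_aggregate_bounds_mean(self):
        rng = np.random.default_rng(0)
        s, y = rng.random(100), rng.integers(0, 2, 100)
        assert expected_calibration_error(s, y, aggregate="max") >= \
            expected_calibration_error(s, y)


class TestRates:
    def test_fnr_basic_cases(self):
        assert false_negative_rate([1.0, 1.0], [1, 1], 0.5) == 0.0
        assert false_negative_rate([0.6, 0.4], [1, 1], 0.5) == 0.5
        assert np.isnan(false_negative_rate([0.2, 0.9], [0, 0], 0.5))

    def test_fnr_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        s, y = rng.random(200), rng.integers(0, 2, 200)
        fnrs = [false_negative_rate(s, y, t) for t in np.linspace(0, 1, 11)]
        assert all(a <= b + 1e-12 for a, b in zip(fnrs, fnrs[1:]))

    def test_fnr_is_one_minus_sensitivity(self):
        rng = np.random.default_rng(2)
        s, y = rng.random(100), rng.integers(0, 2, 100)
        sens = ((s >= 0.5) & (y == 1)).sum() / (y == 1).sum()
        assert false_negative_rate(s, y, 0.5) == pytest.approx(1 - sens)

    def test_smoothed_fnr_uses_prior(self):
        # (FN + c*pi) / (P + c): one miss in two positives, prior 0.5, c=2
        got = false_negative_rate([0.6, 0.4], [1, 1], 0.5,
                                  prior_strength=2, prior_rate=0.5)
        assert got == pytest.approx((1 + 2 * 0.5) / (2 + 2))

    def test_balanced_accuracy_examples(self):
        assert balanced_accuracy([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0]) == 1.0
        assert balanced_accuracy([0.0, 0.0, 0.0], [1, 0, 0]) == 0.5
        # sensitivity 0.5, specificity 1.0
        assert balanced_accuracy([0.9, 0.1, 0.1, 0.1],
                                 [1, 1, 0, 0], 0.5) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            balanced_accuracy([0.5, 0.6], [1, 1])


class TestRankMetrics:
    def test_separated_and_tied_scores(self):
        auroc, _ = rank_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auroc == 1.0
        auroc, _ = rank_metrics([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auroc == 0.5

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pair_enumeration(self, data):
        n = data.draw(st.integers(4, 12))
        scores = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)))
        outcomes = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if outcomes.sum() in (0, n):
            outcomes[0], outcomes[-1] = 0, 1
        auroc, auprc = rank_metrics(scores, outcomes)
        assert auroc == pytest.approx(brute_auroc(scores, outcomes), abs=1e-12)
        assert auprc == pytest.approx(brute_auprc(scores, outcomes), abs=1e-9)


class TestSubgroupTable:
    def test_base_collection_gives_only_overall_row(self, toy_frame):
        coll = build_collection(toy_frame, ["race"], "base")
        table = subgroup_metric_table(np.full(8, 0.5), toy_frame["admitted"],
                                      coll)
        assert list(table.index) == ["overall"]

    def test_disjoint_groups_conserve_counts(self, preset_cohort,
                                             intersectional):
        table = subgroup_metric_table(preset_cohort["true_risk"],
                                      preset_cohort["admitted"], intersectional)
        groups = table.drop(index=["overall", "mean_over_groups",
                                   "max_over_groups"])
        assert groups["count"].sum() == table.loc["overall", "count"]
        assert groups["positives"].sum() == table.loc["overall", "positives"]

    def test_planted_shift_raises_group_ece(self, preset_cohort,
                                            intersectional):
        target = "ethnoracial=Asian; gender=Women"
        other = "ethnoracial=Asian; gender=Men"
        shifted = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                 intersectional, {target: 0.2})
        table = subgroup_metric_table(shifted, preset_cohort["admitted"],
                                      intersectional)
        assert table.loc[target, "ece"] > table.loc[other, "ece"]


class TestAudit:
    def test_oracle_scores_pass_audit_at_large_n(self):
        df = generate_cohort(biased_cohort_config(100_000, seed=5))
        coll = build_collection(df, ["ethnoracial", "gender"], "intersectional")
        # gamma 0.01 keeps cells of >=1000 records, where the binomial
        # noise on the cell mean is well below alpha=0.05
        report = audit_multicalibration(df["true_risk"], df["admitted"], coll,
                                        alpha=0.05, gamma=0.01)
        assert report.multicalibrated

    def test_planted_violation_is_detected(self, preset_cohort, intersectional):
        target = "ethnoracial=White; gender=Women"
        shifted = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                 intersectional, {target: 0.2})
        report = audit_multicalibration(shifted, preset_cohort["admitted"],
                                        intersectional, alpha=0.01, gamma=0.001)
        assert any(v["group"] == target for v in report.violations)
        assert all(v["prevalence"] >= 0.001 and abs(v["delta"]) > 0.01
                   for v in report.violations)

    def test_vacuous_alpha_never_flags(self, preset_cohort, intersectional):
        rng = np.random.default_rng(0)
        report = audit_multicalibration(rng.random(len(preset_cohort)),
                                        preset_cohort["admitted"],
                                        intersectional, alpha=0.999, gamma=0.0)
        assert report.violations == []

    def test_cell_prevalence_measured_against_full_set(self, toy_frame):
        # a 2-member cell out of 8 records has prevalence 0.25
        coll = build_collection(toy_frame, ["race"], "marginal")
        scores = np.where(toy_frame["race"] == "A", 0.05, 0.95)
        report = audit_multicalibration(scores, toy_frame["admitted"], coll,
                                        BinningScheme(10), 0.01, 0.3)
        assert all(v["prevalence"] >= 0.3 for v in report.violations)


def test_binning_scheme_places_one_in_last_bin():
    b = BinningScheme(10)
    idx = b.bin_index(np.array([0.0, 0.05, 0.1, 0.95, 1.0]))
    assert idx.tolist() == [0, 0, 1, 9, 9]
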