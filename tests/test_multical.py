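import numpy as np
import pandas as pd
import pytest

from fairadmit.cohort import generate_cohort, perturb_scores
from fairadmit.groups import build_collection, prevalence_filter
from fairadmit.metrics import BinningScheme, subgroup_metric_table
from fairadmit.multical import (MulticalibConfig, Postprocessor,
                                apply_postprocessor, fit_multicalibration)
from fairadmit.presets import biased_cohort_config


def one_group_frame(n, level="a"):
    return pd.DataFrame({"g": pd.Categorical([level] * n)})


class TestFit:
    def test_already_calibrated_scores_are_a_fixed_point(self, preset_cohort,
                                                         intersectional):
        df = preset_cohort
        # cells pass gamma at >=200 members, where binomial noise on the
        # cell mean is ~0.035; alpha=0.12 leaves >3 SDs of headroom
        cfg = MulticalibConfig(alpha=0.12, gamma=0.01)
        post, adj = fit_multicalibration(df["true_risk"], df["admitted"],
                                         intersectional, cfg)
        assert post.converged and post.updates == []
        assert np.array_equal(adj, df["true_risk"].to_numpy())

    def test_single_cell_update_equals_residual(self):
        # one group, all scores in one bin, mean outcome 0.5, mean score 0.3
        frame = one_group_frame(10)
        coll = build_collection(frame, ["g"], "marginal")
        scores = np.full(10, 0.3)
        outcomes = np.array([1, 0] * 5)
        post, adj = fit_multicalibration(scores, outcomes, coll,
                                         MulticalibConfig(alpha=0.01, gamma=0.0))
        assert len(post.updates) == 1
        up = post.updates[0]
        assert (up.group, up.bin) == ("g=a", 3)
        assert up.delta == pytest.approx(0.2)
        assert np.allclose(adj, 0.5)

    def test_empty_collection_returns_identity(self, preset_cohort):
        coll = build_collection(preset_cohort, ["gender"], "base")
        scores = preset_cohort["true_risk"].to_numpy()
        post, adj = fit_multicalibration(scores, preset_cohort["admitted"], coll)
        assert post.updates == [] and np.array_equal(adj, scores)

    def test_rejects_non_probability_scores(self, preset_cohort, intersectional):
        bad = np.full(len(preset_cohort), 1.5)
        with pytest.raises(ValueError):
            fit_multicalibration(bad, preset_cohort["admitted"], intersectional)

    def test_planted_bias_repair_lowers_subgroup_ece(self, preset_cohort,
                                                     intersectional):
        shifts = {"ethnoracial=Asian; gender=Women": -0.15,
                  "ethnoracial=Black or African American; gender=Men": 0.12}
        scores = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                intersectional, shifts)
        y = preset_cohort["admitted"].to_numpy()
        before = subgroup_metric_table(scores, y, intersectional)
        post, adj = fit_multicalibration(scores, y, intersectional,
                                         MulticalibConfig(alpha=0.01, gamma=0.001))
        after = subgroup_metric_table(adj, y, intersectional)
        assert post.converged
        assert post.fit_audit.multicalibrated
        assert after.loc["mean_over_groups", "ece"] < \
            before.loc["mean_over_groups", "ece"]

    def test_certificate_convergence_implies_clean_audit(self, preset_cohort):
        # marginal (overlapping) groups exercise the sweep interaction
        coll = prevalence_filter(build_collection(
            preset_cohort, ["ethnoracial", "gender"], "marginal"), 0.001)
        rng = np.random.default_rng(9)
        noisy = np.clip(preset_cohort["true_risk"].to_numpy()
                        + rng.normal(0, 0.05, len(preset_cohort)), 0, 1)
        post, adj = fit_multicalibration(noisy, preset_cohort["admitted"], coll)
        assert post.converged
        assert post.fit_audit.multicalibrated

    def test_scores_stay_in_unit_interval(self, preset_cohort, intersectional):
        scores = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                intersectional,
                                {"ethnoracial=White; gender=Women": 0.4})
        _, adj = fit_multicalibration(scores, preset_cohort["admitted"],
                                      intersectional)
        assert adj.min() >= 0.0 and adj.max() <= 1.0

    def test_refit_on_adjusted_scores_is_idempotent(self, preset_cohort,
                                                    intersectional):
        scores = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                intersectional,
                                {"ethnoracial=Hispanic or Latino; gender=Women": 0.1})
        _, adj = fit_multicalibration(scores, preset_cohort["admitted"],
                                      intersectional)
        post2, adj2 = fit_multicalibration(adj, preset_cohort["admitted"],
                                           intersectional)
        assert post2.updates == []
        assert np.array_equal(adj, adj2)

    def test_nonconvergence_is_reported_not_silent(self):
        frame = one_group_frame(10)
        coll = build_collection(frame, ["g"], "marginal")
        scores = np.full(10, 0.3)
        outcomes = np.array([1, 0] * 5)
        with pytest.warns(UserWarning, match="did not converge"):
            post, _ = fit_multicalibration(
                scores, outcomes, coll,
                MulticalibConfig(alpha=0.01, gamma=0.0, max_sweeps=1, step=0.5))
        assert not post.converged


class TestReplay:
    def test_replay_on_fit_data_is_bit_identical(self, preset_cohort,
                                                 intersectional):
        scores = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                intersectional,
                                {"ethnoracial=Asian; gender=Men": 0.18})
        post, adj = fit_multicalibration(scores, preset_cohort["admitted"],
                                         intersectional)
        replay = apply_postprocessor(post, scores, intersectional.membership)
        assert np.array_equal(replay, adj)

    def test_empty_update_list_is_identity(self, intersectional, preset_cohort):
        post = Postprocessor(MulticalibConfig())
        scores = preset_cohort["true_risk"].to_numpy()
        assert np.array_equal(
            apply_postprocessor(post, scores, intersectional.membership), scores)

    def test_unknown_group_label_raises(self):
        post = Postprocessor(MulticalibConfig())
        from fairadmit.multical import CalibrationUpdate
        post.updates.append(CalibrationUpdate("g=missing", 0, 0.1, 0))
        with pytest.raises(KeyError):
            apply_postprocessor(post, np.array([0.5]), {"g=present":
                                                        np.array([True])})

    def test_record_moved_out_of_bin_not_touched_by_stale_update(self):
        # update 1 moves the record from bin 3 to bin 6; update 2 targets
        # bin 3 and must no longer touch it
        from fairadmit.multical import CalibrationUpdate
        post = Postprocessor(MulticalibConfig())
        post.updates = [CalibrationUpdate("g=a", 3, 0.3, 0),
                        CalibrationUpdate("g=a", 3, 0.2, 0)]
        memb = {"g=a": np.array([True])}
        out = apply_postprocessor(post, np.array([0.35]), memb)
        assert out[0] == pytest.approx(0.65)  # second update was a no-op

    def test_serialization_round_trip(self, preset_cohort, intersectional):
        scores = perturb_scores(preset_cohort["true_risk"].to_numpy(),
                                intersectional,
                                {"ethnoracial=White; gender=Men": -0.12})
        post, adj = fit_multicalibration(scores, preset_cohort["admitted"],
                                         intersectional)
        revived = Postprocessor.from_json(post.to_json())
        replay = apply_postprocessor(revived, scores, intersectional.membership)
        assert np.array_equal(replay, adj)


def test_config_validation():
    with pytest.raises(ValueError):
        MulticalibConfig(alpha=0.0)
    with pytest.raises(ValueError):
        MulticalibConfig(gamma=1.5)
    with pytest.raises(ValueError):
        MulticalibConfig(step=0.0)
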