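"""Trial construction, leave-out scoring and the replicated condition runner."""

import numpy as np
import pandas as pd
import pytest

from phonlr.experiment import (
    CONDITIONS,
    CombinationModel,
    build_trials,
    run_condition,
    score_trials,
    summarize_condition,
)
from phonlr.synthetic_data import generate_dataset, reduced_config


@pytest.fixture(scope="module")
def table():
    t, _ = generate_dataset(reduced_config(n_speakers=6, n_tokens=20, seed=2024))
    return t


class TestTrials:
    def test_twenty_speakers_yield_190_plus_20(self):
        t, _ = generate_dataset(reduced_config(n_speakers=20, n_tokens=4, seed=0))
        plan = build_trials(t, CONDITIONS["dialogue"], seed=0)
        labels = [tr.label for tr in plan.trials]
        assert labels.count("different") == 190
        assert labels.count("same") == 20

    def test_three_speakers_yield_3_plus_3(self):
        t, _ = generate_dataset(reduced_config(n_speakers=3, n_tokens=4, seed=0))
        plan = build_trials(t, CONDITIONS["interview"], seed=0)
        labels = [tr.label for tr in plan.trials]
        assert labels.count("different") == 3 and labels.count("same") == 3

    def test_mismatched_condition_styles(self):
        cond = CONDITIONS["dialogue_vs_interview"]
        assert cond.reference_style == "interview"
        assert cond.questioned_style == "dialogue"
        assert not cond.matched

    def test_combination_parsing_validates_components(self):
        combo = CombinationModel.parse("F3+F4+vowel_dur")
        assert combo.components == ("F3", "F4", "vowel_dur")
        with pytest.raises(ValueError, match="unknown"):
            CombinationModel.parse("F3+flux")
        with pytest.raises(ValueError, match="at least 2"):
            CombinationModel("solo", ("F3",))


class TestScoring:
    def test_background_excludes_compared_speakers(self, table):
        plan = build_trials(table, CONDITIONS["dialogue"], seed=1)
        from phonlr.mvkd import fit_background  # noqa: F401 - used implicitly

        scores = score_trials(table, plan, "F3")
        assert scores.n_trials == len(plan.trials)
        # direction sanity on a well-separated spectral feature
        same = scores.log10_lr[scores.same_mask]
        diff = scores.log10_lr[~scores.same_mask]
        assert same.mean() > diff.mean()

    def test_fixed_seed_bit_identical_scores(self, table):
        plan = build_trials(table, CONDITIONS["dialogue"], seed=5)
        a = score_trials(table, plan, "f0_median")
        b = score_trials(table, plan, "f0_median")
        np.testing.assert_array_equal(a.log10_lr, b.log10_lr)

    def test_mismatched_same_speaker_uses_both_styles(self, table):
        plan = build_trials(table, CONDITIONS["dialogue_vs_interview"], seed=2)
        scores = score_trials(table, plan, "vowel_dur")
        assert scores.n_trials == len(plan.trials)
        assert set(scores.label) == {"same", "different"}

    def test_joint_multivariate_mode(self, table):
        plan = build_trials(table, CONDITIONS["interview"], seed=3)
        joint = score_trials(table, plan, ["F3", "F4"])
        assert joint.system == "F3+F4"
        with pytest.raises(ValueError, match="same unit"):
            score_trials(table, plan, ["F3", "f0_median"])

    def test_vowel_quality_grouping_returns_fused_stream(self):
        table, _ = generate_dataset(reduced_config(n_speakers=5, n_tokens=100, seed=8))
        plan = build_trials(table, CONDITIONS["dialogue"], seed=4)
        fused = score_trials(table, plan, "F1", group_vowel_quality=True)
        assert fused.n_trials == len(plan.trials)
        assert np.all(np.isfinite(fused.log10_lr))


class TestRunCondition:
    @pytest.fixture(scope="class")
    def results(self, table):
        return run_condition(
            table, "dialogue", ["F3", "vowel_dur", "F3+vowel_dur"], R=3, base_seed=10
        )

    def test_structure_is_table_shaped(self, results):
        assert set(results) == {"F3", "vowel_dur", "F3+vowel_dur"}
        for summary in results.values():
            assert summary.complete
            assert summary.n_replications == 3
            assert set(summary.metrics) == {"cllr", "eer"}
        wide = summarize_condition(results)
        assert wide.shape == (10, 3)  # 2 metrics x 5 aggregates, 3 systems

    def test_fusion_not_worse_than_components(self, results):
        fused = summarize_condition(results).loc[("cllr", "average"), "F3+vowel_dur"]
        best = min(
            summarize_condition(results).loc[("cllr", "average"), s]
            for s in ("F3", "vowel_dur")
        )
        assert fused <= best + 0.02

    def test_rerun_identical_under_base_seed(self, table, results):
        again = run_condition(table, "dialogue", ["F3"], R=3, base_seed=10)
        pd.testing.assert_frame_equal(
            again["F3"].per_replication, results["F3"].per_replication
        )


def test_plotting_smoke(table):
    import matplotlib

    matplotlib.use("Agg")
    from phonlr.plotting import plot_metric_boxes, plot_replication_curves

    results = run_condition(table, "interview", ["F3"], R=2, base_seed=0)
    fig1 = plot_replication_curves(results)
    fig2 = plot_metric_boxes(results, metric="eer")
    assert fig1 is not None and fig2 is not None
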