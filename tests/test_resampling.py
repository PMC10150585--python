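"""Balanced downsampling to the minority case and replication aggregation."""

import numpy as np
import pandas as pd
import pytest

from phonlr.data_model import TokenTable
from phonlr.resampling import (
    ReplicationSummary,
    balanced_downsample,
    balanced_downsample_all,
    replicate,
    summarize,
)


def _table(counts, unit_type="vowel", style="dialogue"):
    """counts: dict speaker -> n tokens of unit_type/style."""
    rows = []
    for spk, n in counts.items():
        for k in range(n):
            rows.append(
                {
                    "speaker": spk, "style": style, "unit_type": unit_type,
                    "vowel_quality": "a" if unit_type == "vowel" else "",
                    "chunk_id": "", "duration_ms": 50.0 + k,
                }
            )
    return TokenTable(pd.DataFrame(rows))


def test_every_speaker_keeps_the_minority_count(rng):
    counts = {f"s{i}": int(rng.integers(5, 40)) for i in range(8)}
    counts["s3"] = 5
    table = _table(counts)
    ds = balanced_downsample(table, "vowel", seed=1)
    per_speaker = ds.counts("vowel")
    assert (per_speaker == 5).all()
    assert len(ds.data) == 8 * 5  # total = m * n_min


def test_other_unit_types_untouched(small_table):
    before = small_table.data[small_table.data["unit_type"] != "vowel"]
    ds = balanced_downsample(small_table, "vowel", seed=0)
    after = ds.data[ds.data["unit_type"] != "vowel"]
    pd.testing.assert_frame_equal(
        after.reset_index(drop=True), before.reset_index(drop=True)
    )


def test_already_balanced_table_keeps_counts(small_table):
    ds = balanced_downsample(small_table, "vv_unit", seed=9)
    assert (ds.counts("vv_unit") == small_table.counts("vv_unit")).all()


def test_determinism_and_seed_sensitivity():
    counts = {f"s{i}": 30 + i for i in range(6)}
    table = _table(counts)
    a = balanced_downsample(table, "vowel", seed=11)
    b = balanced_downsample(table, "vowel", seed=11)
    c = balanced_downsample(table, "vowel", seed=12)
    pd.testing.assert_frame_equal(a.data, b.data)
    assert not a.data.equals(c.data)


def test_styles_balanced_independently_or_jointly():
    rows = pd.concat(
        [_table({"a": 10, "b": 20}).data, _table({"a": 4, "b": 8}, style="interview").data]
    )
    table = TokenTable(rows)
    per_style = balanced_downsample(table, "vowel", seed=0)
    g = per_style.data.groupby(["style", "speaker"]).size()
    assert g["dialogue"].tolist() == [10, 10] and g["interview"].tolist() == [4, 4]
    equalized = balanced_downsample(table, "vowel", seed=0, equalize_styles=True)
    assert (equalized.data.groupby(["style", "speaker"]).size() == 4).all()


def test_missing_speaker_is_named():
    rows = pd.concat(
        [_table({"a": 5, "b": 5}).data, _table({"a": 5}, style="interview").data]
    )
    with pytest.raises(ValueError, match="'b'"):
        balanced_downsample(TokenTable(rows), "vowel", seed=0)


def test_downsample_all_covers_every_unit(small_table):
    ds = balanced_downsample_all(small_table, seed=3)
    for unit in ("vowel", "vv_unit", "silent_pause", "chunk"):
        assert (ds.counts(unit, style="dialogue") == 6).all()


class TestReplicate:
    def test_single_replication_aggregates_trivially(self):
        summary = replicate(lambda seed: {"cllr": 0.5, "eer": 0.1}, R=1, base_seed=7)
        agg = summarize(summary)
        assert agg.loc["cllr", "average"] == 0.5
        assert agg.loc["cllr", "sd"] == 0.0
        assert summary.per_replication["seed"].tolist() == [7]

    def test_constant_experiment_has_zero_spread(self):
        summary = replicate(lambda seed: {"cllr": 0.42}, R=10, base_seed=0)
        agg = summarize(summary)
        assert agg.loc["cllr", "minima"] == agg.loc["cllr", "maxima"] == 0.42
        assert agg.loc["cllr", "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_aggregates(self):
        vals = iter([0.2, 0.4])
        summary = replicate(lambda seed: {"cllr": next(vals)}, R=2, base_seed=0)
        agg = summarize(summary)
        assert agg.loc["cllr", "average"] == pytest.approx(0.3)
        assert agg.loc["cllr", "minima"] == 0.2
        assert agg.loc["cllr", "maxima"] == 0.4
        assert agg.loc["cllr", "sd"] == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_aggregates_invariant_to_replication_order(self, rng):
        summary = replicate(lambda seed: {"m": float(np.sin(seed))}, R=12, base_seed=0)
        shuffled = ReplicationSummary(
            summary.per_replication.sample(frac=1, random_state=1).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(summarize(summary), summarize(shuffled))

    def test_failures_recorded_not_raised(self):
        def flaky(seed):
            if seed % 2:
                raise RuntimeError("boom")
            return {"cllr": 1.0}

        summary = replicate(flaky, R=6, base_seed=0)
        assert not summary.complete
        assert len(summary.failures) == 3
        assert summary.n_replications == 3

    def test_bit_reproducible_under_base_seed(self):
        def experiment(seed):
            r = np.random.default_rng(seed)
            return {"cllr": float(r.random())}

        a = replicate(experiment, R=5, base_seed=3).per_replication
        b = replicate(experiment, R=5, base_seed=3).per_replication
        pd.testing.assert_frame_equal(a, b)
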