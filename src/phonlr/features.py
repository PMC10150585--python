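"""Deterministic acoustic-parameter summaries.

Fundamental-frequency summaries are computed per connected-speech chunk
(roughly 3 s of speech between longer pauses): the chunk f0 *median* and
the chunk f0 *base value*, a low quantile (the 7.64th percentile) of the
f0 sample that estimates the stable floor of a speaker's f0 distribution.
Both are reported in Hz and in semitones relative to 1 Hz
(st = 12 * log2(f / 1 Hz)).

Raw pitch-tracker output is first restricted to a plausible extraction
range (60-300 Hz for adult male speech, inclusive at both ends), and
silent-pause durations below the 100 ms annotation threshold are excluded
from the pause-duration parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import F0SampleSet, TokenTable

__all__ = [
    "BASE_QUANTILE",
    "F0_FLOOR_HZ",
    "F0_CEILING_HZ",
    "PAUSE_MIN_MS",
    "F0Summary",
    "hz_to_semitones",
    "semitones_to_hz",
    "clip_f0_range",
    "chunk_f0_median",
    "chunk_f0_base",
    "filter_silent_pauses",
    "summarize_f0",
    "f0_summary_tokens",
]

logger = logging.getLogger(__name__)

#: Probability level of the f0 base value (the 7.64th percentile).
BASE_QUANTILE = 0.0764
F0_FLOOR_HZ = 60.0
F0_CEILING_HZ = 300.0
PAUSE_MIN_MS = 100.0


@dataclass(frozen=True)
class F0Summary:
    """Per-chunk f0 summaries in Hz and semitones re 1 Hz."""

    speaker: str
    style: str
    chunk_id: str
    median_hz: float
    median_st: float
    base_hz: float
    base_st: float


def hz_to_semitones(f: float | np.ndarray, ref: float = 1.0) -> float | np.ndarray:
    """Convert frequency to semitones relative to ``ref``: 12 * log2(f/ref)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or ref <= 0:
        raise ValueError("frequencies must be strictly positive")
    out = 12.0 * np.log2(f / ref)
    return float(out) if out.ndim == 0 else out


def semitones_to_hz(st: float | np.ndarray, ref: float = 1.0) -> float | np.ndarray:
    """Inverse of :func:`hz_to_semitones`."""
    st = np.asarray(st, dtype=float)
    out = ref * np.power(2.0, st / 12.0)
    return float(out) if out.ndim == 0 else out


def clip_f0_range(
    sample: F0SampleSet,
    floor: float = F0_FLOOR_HZ,
    ceiling: float = F0_CEILING_HZ,
) -> F0SampleSet:
    """Keep only f0 samples within [floor, ceiling] Hz (inclusive).

    Chunks whose samples are all out of range are dropped entirely and
    reported (they carry no usable f0 information).  The number of removed
    samples is logged.
    """
    if sample.n_samples == 0:
        raise ValueError("empty f0 sample set")
    df = sample.data
    keep = (df["f0_hz"] >= floor) & (df["f0_hz"] <= ceiling)
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "clip_f0_range: removed %d of %d samples outside [%g, %g] Hz",
            removed, len(df), floor, ceiling,
        )
    clipped = df[keep].reset_index(drop=True)
    before = df.groupby(["speaker", "style", "chunk_id"]).size()
    after = clipped.groupby(["speaker", "style", "chunk_id"]).size()
    lost = sorted(set(before.index) - set(after.index))
    if lost:
        logger.warning("clip_f0_range: %d chunk(s) unusable (all samples removed): %s",
                       len(lost), lost[:5])
    return F0SampleSet(clipped)


def chunk_f0_median(values: np.ndarray) -> float:
    """Median of one chunk's f0 sample (midpoint rule for even lengths)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty f0 sample")
    return float(np.median(values))


def chunk_f0_base(values: np.ndarray) -> float:
    """f0 base value: the 7.64th percentile of one chunk's f0 sample.

    Uses the linear-interpolation-between-order-statistics quantile
    convention, so the result is never larger than the median.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty f0 sample")
    return float(np.quantile(values, BASE_QUANTILE, method="linear"))


def filter_silent_pauses(durations_ms, threshold_ms: float = PAUSE_MIN_MS) -> np.ndarray:
    """Retain silent-pause durations at or above the annotation threshold."""
    durations_ms = np.asarray(durations_ms, dtype=float)
    return durations_ms[durations_ms >= threshold_ms]


def summarize_f0(
    sample: F0SampleSet,
    floor: float = F0_FLOOR_HZ,
    ceiling: float = F0_CEILING_HZ,
) -> pd.DataFrame:
    """Clip and summarize an f0 sample set into per-chunk medians/base values.

    Returns one row per usable chunk with columns ``speaker``, ``style``,
    ``chunk_id``, ``median_hz``, ``median_st``, ``base_hz``, ``base_st``.
    """
    clipped = clip_f0_range(sample, floor=floor, ceiling=ceiling)
    rows = []
    for (speaker, style, chunk_id), values in clipped.chunks():
        med = chunk_f0_median(values)
        base = chunk_f0_base(values)
        rows.append(
            {
                "speaker": speaker,
                "style": style,
                "chunk_id": chunk_id,
                "median_hz": med,
                "median_st": hz_to_semitones(med),
                "base_hz": base,
                "base_st": hz_to_semitones(base),
            }
        )
    return pd.DataFrame(rows)


def f0_summary_tokens(summary: pd.DataFrame) -> TokenTable:
    """Turn per-chunk f0 summaries into chunk-unit token rows.

    The semitone versions are the modeling scale; they are stored as the
    features ``f0_median_st`` and ``f0_base_st``.
    """
    df = pd.DataFrame(
        {
            "speaker": summary["speaker"],
            "style": summary["style"],
            "unit_type": "chunk",
            "vowel_quality": "",
            "chunk_id": summary["chunk_id"],
            "f0_median_st": summary["median_st"].astype(float),
            "f0_base_st": summary["base_st"].astype(float),
        }
    )
    return TokenTable(df)
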