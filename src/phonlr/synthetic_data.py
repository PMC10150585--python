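"""Synthetic token-table generator with two-level acoustic structure.

Emulates the statistical skeleton of a forensic speaker-comparison
corpus: 20 adult male speakers recorded in two speaking styles
(spontaneous telephone *dialogue* and researcher-led *interview*), with
nine acoustic-phonetic features spanning three classes — temporal
(silent-pause, vowel and V-V-unit durations), melodic (f0 median and f0
base value in semitones) and spectral (formants F1-F4 in Hz).

The generative model matches the modeling assumptions of the scoring
stage: speaker means are drawn once from a between-speaker Gaussian, and
tokens are drawn around them from a within-speaker Gaussian; durations
are generated on a log scale and exponentiated (positive support).  The
dialogue style differs from interview by an additive mean shift (delta)
and a within-speaker variance inflation (kappa >= 1) — the mechanism by
which style mismatch degrades comparisons.  Per-speaker token counts are
imbalanced, drawn from per-style ranges whose low endpoints equal the
study-scale minority counts, with one randomly chosen speaker pinned to
that minimum so the balanced-downsampling arithmetic is exact.

Population means and variance magnitudes are plausible-but-invented
implementation choices (no reference values exist for them); the knob
that drives everything downstream is the between/within variance ratio
per feature, ordered spectral (F3, F4 strongest) > melodic > temporal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import F0SampleSet, TokenTable, VOWEL_QUALITIES

__all__ = [
    "FeatureSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "reduced_config",
    "generate_dataset",
    "generate_f0_samples",
    "pooled_within_estimate",
]

ACOUSTIC_CLASSES = ("temporal", "melodic", "spectral")


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic acoustic feature.

    ``mean``, ``between_sd`` and ``within_sd`` live on the latent
    (generation) scale: log-milliseconds for ``log_scale`` features,
    the storage unit otherwise.  ``style_shift`` is added to the mean and
    ``within_inflation`` multiplies the within-speaker SD in the shifted
    style (dialogue by default).
    """

    name: str
    acoustic_class: str
    unit_type: str
    column: str
    mean: float
    between_sd: float
    within_sd: float
    style_shift: float = 0.0
    within_inflation: float = 1.0
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.acoustic_class not in ACOUSTIC_CLASSES:
            raise ValueError(f"unknown acoustic class {self.acoustic_class!r}")
        if self.between_sd <= 0 and self.between_sd != 0.0:
            raise ValueError(f"{self.name}: between_sd must be >= 0")
        if self.within_sd <= 0:
            raise ValueError(f"{self.name}: within_sd must be > 0")
        if self.within_inflation < 1.0:
            raise ValueError(f"{self.name}: within_inflation must be >= 1")


# Nine features; between/within ratios ordered spectral > melodic > temporal.
# Magnitudes are chosen so that, under the two-level iid-Gaussian model and
# the token counts used here, per-class Cllr/EER land in the ranges reported
# for conversational speech (iid tokens are individually more informative
# than real, serially correlated speech tokens, so the ratios are smaller
# than raw acoustic surveys would suggest).
_DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("silent_pause_dur", "temporal", "silent_pause", "duration_ms",
                mean=math.log(800.0), between_sd=0.500, within_sd=0.50,
                style_shift=-0.80, within_inflation=1.1, log_scale=True),
    FeatureSpec("vowel_dur", "temporal", "vowel", "duration_ms",
                mean=math.log(80.0), between_sd=0.180, within_sd=0.30,
                style_shift=-0.48, within_inflation=1.1, log_scale=True),
    FeatureSpec("vv_dur", "temporal", "vv_unit", "duration_ms",
                mean=math.log(180.0), between_sd=0.168, within_sd=0.28,
                style_shift=-0.45, within_inflation=1.1, log_scale=True),
    FeatureSpec("f0_median", "melodic", "chunk", "f0_median_st",
                mean=82.9, between_sd=2.08, within_sd=1.60,
                style_shift=1.92, within_inflation=1.4),
    FeatureSpec("f0_base", "melodic", "chunk", "f0_base_st",
                mean=78.8, between_sd=1.56, within_sd=1.30,
                style_shift=1.56, within_inflation=1.4),
    FeatureSpec("F1", "spectral", "vowel", "F1",
                mean=500.0, between_sd=121.0, within_sd=55.0,
                style_shift=66.0, within_inflation=1.4),
    FeatureSpec("F2", "spectral", "vowel", "F2",
                mean=1500.0, between_sd=252.0, within_sd=120.0,
                style_shift=144.0, within_inflation=1.4),
    FeatureSpec("F3", "spectral", "vowel", "F3",
                mean=2550.0, between_sd=286.0, within_sd=110.0,
                style_shift=132.0, within_inflation=1.4),
    FeatureSpec("F4", "spectral", "vowel", "F4",
                mean=3700.0, between_sd=312.0, within_sd=130.0,
                style_shift=156.0, within_inflation=1.4),
)

# Per-speaker token-count ranges (low, high) per (style, unit type).  Low
# endpoints are the study-scale per-speaker minority counts; highs are set
# so the per-style totals match the study-scale corpus magnitudes.
_DEFAULT_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("dialogue", "vowel"): (432, 564),
    ("dialogue", "vv_unit"): (393, 781),
    ("dialogue", "silent_pause"): (22, 63),
    ("dialogue", "chunk"): (60, 120),
    ("interview", "vowel"): (262, 428),
    ("interview", "vv_unit"): (362, 588),
    ("interview", "silent_pause"): (30, 60),
    ("interview", "chunk"): (40, 80),
}


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic corpus."""

    n_speakers: int = 20
    token_counts: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_COUNTS)
    )
    features: tuple[FeatureSpec, ...] = _DEFAULT_FEATURES
    #: correlation between features of the same class on the same unit
    within_class_corr: dict[str, float] = field(
        default_factory=lambda: {"melodic": 0.7, "spectral": 0.5, "temporal": 0.3}
    )
    #: correlation between co-located features of different classes
    cross_class_corr: float = 0.2
    #: style receiving the mean shift and within-variance inflation
    shifted_style: str = "dialogue"
    #: ln-scale SD of individual f0 samples around the chunk level
    f0_sample_sd: float = 0.10
    #: number of raw f0 samples per generated chunk
    samples_per_chunk: int = 200
    seed: int = 20230417

    def validate(self) -> None:
        problems = []
        if self.n_speakers < 3:
            problems.append("n_speakers must be >= 3")
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            problems.append("duplicate feature names")
        for (style, unit), (lo, hi) in self.token_counts.items():
            if lo < 2 or hi < lo:
                problems.append(f"bad count range for ({style}, {unit}): ({lo}, {hi})")
        for f in self.features:
            needed = [u for (s, u) in self.token_counts]
            if f.unit_type not in needed:
                problems.append(f"feature {f.name}: no token counts for unit {f.unit_type!r}")
        if problems:
            raise ValueError("invalid synthetic config: " + "; ".join(problems))

    def features_by_unit(self) -> dict[str, list[FeatureSpec]]:
        out: dict[str, list[FeatureSpec]] = {}
        for f in self.features:
            out.setdefault(f.unit_type, []).append(f)
        return out


def default_config(seed: int = 20230417) -> SyntheticConfig:
    """Study-scale conditions: 20 speakers, two styles, nine features."""
    return SyntheticConfig(seed=seed)


def reduced_config(
    n_speakers: int = 10, n_tokens: int = 60, seed: int = 20230417
) -> SyntheticConfig:
    """Desk-scale conditions for replication sweeps.

    Same feature structure as :func:`default_config` but with
    ``n_speakers`` speakers and per-speaker token counts in
    [n_tokens, 1.5 * n_tokens] for every unit type and style (minimum
    pinned as in the full config).
    """
    hi = int(round(n_tokens * 1.5))
    counts = {key: (n_tokens, hi) for key in _DEFAULT_COUNTS}
    return SyntheticConfig(n_speakers=n_speakers, token_counts=counts, seed=seed)


@dataclass
class GroundTruth:
    """What the generator actually drew, for parameter-recovery tests."""

    speaker_means: dict[str, pd.DataFrame]  # unit type -> (speaker x feature), latent scale
    between_cov: dict[str, np.ndarray]  # configured, latent scale
    within_cov: dict[str, np.ndarray]  # configured (uninflated style), latent scale
    config: SyntheticConfig


def _correlation_matrix(specs: list[FeatureSpec], config: SyntheticConfig) -> np.ndarray:
    k = len(specs)
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if specs[i].acoustic_class == specs[j].acoustic_class:
                r = config.within_class_corr.get(specs[i].acoustic_class, 0.0)
            else:
                r = config.cross_class_corr
            R[i, j] = R[j, i] = r
    return R


def _cov(specs: list[FeatureSpec], sds: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    R = _correlation_matrix(specs, config)
    return (sds[:, None] * R) * sds[None, :]


def generate_dataset(config: SyntheticConfig) -> tuple[TokenTable, GroundTruth]:
    """Draw a full synthetic token table (deterministic under config.seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    speakers = [f"spk{i:02d}" for i in range(config.n_speakers)]
    by_unit = config.features_by_unit()
    styles = sorted({s for (s, _) in config.token_counts})

    # 1. speaker means per unit group (latent scale)
    means: dict[str, np.ndarray] = {}
    b_cov: dict[str, np.ndarray] = {}
    w_cov: dict[str, np.ndarray] = {}
    for unit in sorted(by_unit):
        specs = by_unit[unit]
        mu = np.array([f.mean for f in specs])
        b_sds = np.array([f.between_sd for f in specs])
        cov_b = _cov(specs, b_sds, config)
        b_cov[unit] = cov_b
        w_cov[unit] = _cov(specs, np.array([f.within_sd for f in specs]), config)
        mm = mu + rng.multivariate_normal(
            np.zeros(len(specs)), cov_b, size=config.n_speakers
        )
        # speaker-level formant ordering: redraw mean vectors whose formant
        # means are closer than ~1 within-SD (rows could then never satisfy
        # per-token ordering at a useful rate)
        fidx = [k for k, f in enumerate(specs) if f.column in ("F1", "F2", "F3", "F4")]
        if len(fidx) >= 2:
            margin = 150.0
            bad = np.any(np.diff(mm[:, fidx], axis=1) < margin, axis=1)
            it = 0
            while bad.any() and it < 50:
                mm[bad] = mu + rng.multivariate_normal(
                    np.zeros(len(specs)), cov_b, size=int(bad.sum())
                )
                bad = np.any(np.diff(mm[:, fidx], axis=1) < margin, axis=1)
                it += 1
            if bad.any():  # pragma: no cover
                raise RuntimeError("could not draw ordered formant speaker means")
        means[unit] = mm

    # 2. per-speaker counts: uniform in [lo, hi], one random speaker at lo
    counts: dict[tuple[str, str], np.ndarray] = {}
    for style in styles:
        for unit in sorted(by_unit):
            lo, hi = config.token_counts[(style, unit)]
            n = rng.integers(lo, hi + 1, size=config.n_speakers)
            n[rng.integers(config.n_speakers)] = lo
            counts[(style, unit)] = n

    # 3. tokens
    frames: list[pd.DataFrame] = []
    for style in styles:
        shifted = style == config.shifted_style
        for unit in sorted(by_unit):
            specs = by_unit[unit]
            cols = [f.column for f in specs]
            shift = np.array([f.style_shift if shifted else 0.0 for f in specs])
            w_sds = np.array(
                [f.within_sd * (f.within_inflation if shifted else 1.0) for f in specs]
            )
            cov_w = _cov(specs, w_sds, config)
            for si, spk in enumerate(speakers):
                n = int(counts[(style, unit)][si])
                center = means[unit][si] + shift
                lat = rng.multivariate_normal(center, cov_w, size=n)
                lat = _repair_rows(lat, rng, center, cov_w, specs, unit)
                data = {}
                for k, f in enumerate(specs):
                    data[f.column] = np.exp(lat[:, k]) if f.log_scale else lat[:, k]
                df = pd.DataFrame(data)
                df.insert(0, "speaker", spk)
                df.insert(1, "style", style)
                df.insert(2, "unit_type", unit)
                if unit == "vowel":
                    df.insert(3, "vowel_quality", rng.choice(VOWEL_QUALITIES, size=n))
                else:
                    df.insert(3, "vowel_quality", "")
                if unit == "chunk":
                    df.insert(4, "chunk_id", [f"{spk}-{style}-c{i:03d}" for i in range(n)])
                else:
                    df.insert(4, "chunk_id", "")
                frames.append(df)

    all_cols = ["speaker", "style", "unit_type", "vowel_quality", "chunk_id"]
    for f in config.features:
        if f.column not in all_cols:
            all_cols.append(f.column)
    table = pd.concat(frames, ignore_index=True).reindex(columns=all_cols)
    truth = GroundTruth(
        speaker_means={
            unit: pd.DataFrame(
                means[unit], index=speakers, columns=[f.name for f in by_unit[unit]]
            )
            for unit in by_unit
        },
        between_cov=b_cov,
        within_cov=w_cov,
        config=config,
    )
    return TokenTable(table), truth


def _repair_rows(lat, rng, center, cov_w, specs, unit, max_iter: int = 200):
    """Redraw rows violating structural constraints.

    Vowel rows must keep F1 < F2 < F3 < F4 (violations are ~5-sigma tail
    events); silent pauses below the 100 ms annotation threshold do not
    occur in segmented corpora, so they are redrawn too.
    """
    def bad_mask(x):
        bad = np.zeros(len(x), dtype=bool)
        fidx = [k for k, f in enumerate(specs) if f.column in ("F1", "F2", "F3", "F4")]
        if len(fidx) >= 2:
            fm = x[:, fidx]
            bad |= np.any(np.diff(fm, axis=1) <= 0, axis=1)
        if unit == "silent_pause":
            k = next(k for k, f in enumerate(specs) if f.column == "duration_ms")
            bad |= np.exp(x[:, k]) < 100.0
        return bad

    bad = bad_mask(lat)
    it = 0
    while bad.any() and it < max_iter:
        lat[bad] = rng.multivariate_normal(center, cov_w, size=int(bad.sum()))
        bad = bad_mask(lat)
        it += 1
    if bad.any():  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not generate rows satisfying structural constraints")
    return lat


def generate_f0_samples(
    config: SyntheticConfig,
    speaker_levels_hz: Mapping[str, float] | None = None,
    seed=None,
) -> F0SampleSet:
    """Raw per-chunk f0 sample vectors (Hz) consistent with the config.

    Speaker f0 levels default to fresh draws from the ``f0_median``
    feature's between-speaker distribution; each chunk gets a log-normal
    excursion (the feature's within-speaker SD) and
    ``config.samples_per_chunk`` log-normal samples around it.  Values
    land almost entirely inside the 60-300 Hz extraction range; the few
    outside are what range clipping removes downstream.
    """
    config.validate()
    spec = next(f for f in config.features if f.name == "f0_median")
    st_to_ln = math.log(2.0) / 12.0  # semitones -> ln Hz
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    speakers = [f"spk{i:02d}" for i in range(config.n_speakers)]
    if speaker_levels_hz is None:
        lev_st = spec.mean + rng.normal(0.0, spec.between_sd, size=len(speakers))
        speaker_levels_hz = {s: 2.0 ** (st / 12.0) for s, st in zip(speakers, lev_st)}
    styles = sorted({s for (s, _) in config.token_counts})
    rows = []
    for style in styles:
        lo, hi = config.token_counts[(style, "chunk")]
        shifted = style == config.shifted_style
        for spk in sorted(speaker_levels_hz):
            n_chunks = int(rng.integers(lo, hi + 1))
            ln_level = math.log(speaker_levels_hz[spk])
            chunk_sd = spec.within_sd * (spec.within_inflation if shifted else 1.0)
            shift = spec.style_shift if shifted else 0.0
            for c in range(n_chunks):
                ln_mu = ln_level + (shift + rng.normal(0.0, chunk_sd)) * st_to_ln
                vals = np.exp(ln_mu + rng.normal(0.0, config.f0_sample_sd,
                                                 size=config.samples_per_chunk))
                rows.append(
                    pd.DataFrame(
                        {
                            "speaker": spk,
                            "style": style,
                            "chunk_id": f"{spk}-{style}-c{c:03d}",
                            "f0_hz": vals,
                        }
                    )
                )
    return F0SampleSet(pd.concat(rows, ignore_index=True))


def pooled_within_estimate(
    table: TokenTable, config: SyntheticConfig, unit_type: str, style: str
) -> np.ndarray:
    """Pooled within-speaker covariance of one unit's features, latent scale.

    Log-scale features are transformed back to the latent (log) scale
    before pooling, so the estimate is directly comparable to the
    configured within-speaker covariance.
    """
    specs = config.features_by_unit()[unit_type]
    cols = [f.column for f in specs]
    sub = table.subset(unit_type=unit_type, style=style).data
    X = sub[cols].to_numpy(dtype=float)
    for k, f in enumerate(specs):
        if f.log_scale:
            X[:, k] = np.log(X[:, k])
    scatter = np.zeros((len(cols), len(cols)))
    dof = 0
    for spk in sorted(sub["speaker"].unique()):
        xi = X[(sub["speaker"] == spk).to_numpy()]
        d = xi - xi.mean(axis=0)
        scatter += d.T @ d
        dof += len(xi) - 1
    return scatter / dof
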