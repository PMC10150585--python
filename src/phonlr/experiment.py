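"""Trial construction and scoring pipelines for the comparison conditions.

Three testing conditions are supported:

* ``dialogue`` and ``interview`` — matched-style comparisons.  Every
  unordered speaker pair yields one different-speaker trial (full token
  sets of each speaker); each speaker yields one same-speaker trial by a
  random half-split of their tokens into disjoint reference/questioned
  sets.
* ``dialogue_vs_interview`` — the mismatched condition: interview
  material is the reference, dialogue material the questioned side, for
  both trial kinds.

For every trial the background population is refitted on all speakers
except the one(s) directly compared (leave-out cross-validation), using
reference-style tokens.  Single acoustic parameters are scored with the
univariate kernel-density model; parameter combinations are, by default,
fusions of the per-parameter score streams via balanced logistic
regression (a joint multivariate kernel-density mode is available for
parameters measured on the same unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calfusion import calibrate_scores
from .data_model import STYLES, UNIT_TYPES, ScoreSet, TokenTable
from .metrics import cllr, eer
from .mvkd import fit_background
from .resampling import ReplicationSummary, balanced_downsample_all, summarize

__all__ = [
    "ParameterDef",
    "PARAMETERS",
    "Condition",
    "CONDITIONS",
    "CombinationModel",
    "Trial",
    "TrialPlan",
    "build_trials",
    "score_trials",
    "run_condition",
    "summarize_condition",
]


@dataclass(frozen=True)
class ParameterDef:
    name: str
    unit_type: str
    column: str
    acoustic_class: str


#: The nine acoustic-phonetic parameters under assessment.
PARAMETERS: dict[str, ParameterDef] = {
    p.name: p
    for p in (
        ParameterDef("silent_pause_dur", "silent_pause", "duration_ms", "temporal"),
        ParameterDef("vowel_dur", "vowel", "duration_ms", "temporal"),
        ParameterDef("vv_dur", "vv_unit", "duration_ms", "temporal"),
        ParameterDef("f0_median", "chunk", "f0_median_st", "melodic"),
        ParameterDef("f0_base", "chunk", "f0_base_st", "melodic"),
        ParameterDef("F1", "vowel", "F1", "spectral"),
        ParameterDef("F2", "vowel", "F2", "spectral"),
        ParameterDef("F3", "vowel", "F3", "spectral"),
        ParameterDef("F4", "vowel", "F4", "spectral"),
    )
}


@dataclass(frozen=True)
class Condition:
    """A testing condition: which style supplies each side of a trial."""

    name: str
    reference_style: str
    questioned_style: str

    def __post_init__(self) -> None:
        for s in (self.reference_style, self.questioned_style):
            if s not in STYLES:
                raise ValueError(f"unknown style {s!r}")

    @property
    def matched(self) -> bool:
        return self.reference_style == self.questioned_style


#: The three testing conditions; in the mismatched one the interview is
#: the reference material and the dialogue the questioned material.
CONDITIONS: dict[str, Condition] = {
    "dialogue": Condition("dialogue", "dialogue", "dialogue"),
    "interview": Condition("interview", "interview", "interview"),
    "dialogue_vs_interview": Condition("dialogue_vs_interview", "interview", "dialogue"),
}


@dataclass(frozen=True)
class CombinationModel:
    """A named fusion of two or more single parameters."""

    name: str
    components: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 2:
            raise ValueError("a combination needs at least 2 components")
        unknown = [c for c in self.components if c not in PARAMETERS]
        if unknown:
            raise ValueError(f"unknown parameters in combination: {unknown}")

    @classmethod
    def parse(cls, text: str) -> "CombinationModel":
        parts = tuple(p.strip() for p in text.split("+"))
        return cls(name="+".join(parts), components=parts)


@dataclass(frozen=True)
class Trial:
    reference_speaker: str
    questioned_speaker: str

    @property
    def label(self) -> str:
        return "same" if self.reference_speaker == self.questioned_speaker else "different"


@dataclass(frozen=True)
class TrialPlan:
    condition: Condition
    trials: tuple[Trial, ...]
    seed: int


def build_trials(table: TokenTable, condition: Condition, seed: int) -> TrialPlan:
    """All unordered different-speaker pairs plus one same-speaker trial each.

    The seed fixes the same-speaker half-splits materialized later by
    :func:`score_trials` (matched conditions only; in the mismatched
    condition the same-speaker trial compares the speaker's interview
    tokens against their own dialogue tokens).
    """
    speakers = table.speakers()
    if len(speakers) < 3:
        raise ValueError("need at least 3 speakers to build trials with a background")
    trials = [Trial(s, s) for s in speakers]
    trials += [Trial(a, b) for i, a in enumerate(speakers) for b in speakers[i + 1:]]
    return TrialPlan(condition=condition, trials=tuple(trials), seed=int(seed))


def _speaker_sets(
    table: TokenTable, unit_type: str, columns: Sequence[str], style: str
) -> dict[str, np.ndarray]:
    sub = table.subset(unit_type=unit_type, style=style).data
    out: dict[str, np.ndarray] = {}
    for spk, grp in sub.groupby("speaker", sort=True):
        out[str(spk)] = grp[list(columns)].to_numpy(dtype=float)
    return out


def _half_split(x: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if len(x) < 4:
        raise ValueError("need at least 4 tokens for a same-speaker half-split")
    perm = rng.permutation(len(x))
    half = len(x) // 2
    return x[perm[:half]], x[perm[half:]]


def score_trials(
    table: TokenTable,
    plan: TrialPlan,
    parameters: str | Sequence[str],
    group_vowel_quality: bool = False,
    prior: float = 0.5,
    ridge: float = 1e-3,
) -> ScoreSet:
    """Raw log10-LR scores for every trial of a plan.

    ``parameters`` may be one parameter name (univariate scoring) or a
    list of names sharing a unit type (joint multivariate scoring).  With
    ``group_vowel_quality=True``, vowel-borne parameters are scored
    separately per vowel quality and the per-quality streams fused into
    one calibrated stream (the returned scores are then calibrated).
    """
    if isinstance(parameters, str):
        names = [parameters]
    else:
        names = list(parameters)
    defs = [PARAMETERS[n] for n in names]
    units = {d.unit_type for d in defs}
    if len(units) != 1:
        raise ValueError("joint scoring requires parameters on the same unit type")
    unit = units.pop()
    columns = [d.column for d in defs]
    system = "+".join(names) if len(names) > 1 else names[0]

    if group_vowel_quality and unit == "vowel":
        vowels = table.subset(unit_type="vowel").data
        styles = {plan.condition.reference_style, plan.condition.questioned_style}
        streams = []
        for q in sorted(vowels["vowel_quality"].unique()):
            # a quality is usable only if every speaker has >= 4 tokens of it
            # in every style the condition draws from (half-splits need 4)
            sub = vowels[vowels["vowel_quality"] == q]
            per = sub.groupby(["style", "speaker"]).size()
            usable = all(
                per.get((st, spk), 0) >= 4
                for st in styles
                for spk in table.speakers()
            )
            if not usable:
                continue
            qtable = TokenTable(
                table.data[
                    (table.data["unit_type"] != "vowel")
                    | (table.data["vowel_quality"] == q)
                ].copy()
            )
            streams.append(_score_plain(qtable, plan, unit, columns, f"{system}[{q}]"))
        if not streams:
            raise ValueError("no vowel quality has enough tokens for every speaker")
        fused, _ = calibrate_scores(streams, prior=prior, ridge=ridge, system=system)
        return fused
    return _score_plain(table, plan, unit, columns, system)


def _score_plain(
    table: TokenTable,
    plan: TrialPlan,
    unit: str,
    columns: Sequence[str],
    system: str,
) -> ScoreSet:
    cond = plan.condition
    ref_sets = _speaker_sets(table, unit, columns, cond.reference_style)
    q_sets = (
        ref_sets
        if cond.matched
        else _speaker_sets(table, unit, columns, cond.questioned_style)
    )
    speakers = sorted(ref_sets)
    spk_index = {s: i for i, s in enumerate(speakers)}
    unit_code = UNIT_TYPES.index(unit)

    refs, quests, labels, scores = [], [], [], []
    for trial in plan.trials:
        a, b = trial.reference_speaker, trial.questioned_speaker
        for s in (a, b):
            if s not in ref_sets or s not in q_sets:
                raise ValueError(f"speaker {s!r} lacks {unit!r} tokens in a required style")
        if trial.label == "same" and cond.matched:
            rng = np.random.default_rng((plan.seed, spk_index[a], unit_code))
            ref_tokens, q_tokens = _half_split(ref_sets[a], rng)
        else:
            ref_tokens, q_tokens = ref_sets[a], q_sets[b]
        background = {
            s: ref_sets[s] for s in speakers if s not in (a, b)
        }
        if len(background) < 3:
            raise ValueError("background smaller than 3 speakers after exclusions")
        model = fit_background(background)
        result = model.log_lr(ref_tokens, q_tokens)
        refs.append(a)
        quests.append(b)
        labels.append(trial.label)
        scores.append(result.log10_lr)
    return ScoreSet(
        np.array(refs, dtype=object),
        np.array(quests, dtype=object),
        np.array(scores, dtype=float),
        np.array(labels, dtype=object),
        system=system,
    )


def _normalize_systems(
    systems: Iterable[str | CombinationModel],
) -> list[str | CombinationModel]:
    out: list[str | CombinationModel] = []
    for s in systems:
        if isinstance(s, CombinationModel):
            out.append(s)
        elif "+" in s:
            out.append(CombinationModel.parse(s))
        elif s in PARAMETERS:
            out.append(s)
        else:
            raise ValueError(f"unknown system {s!r}")
    return out


def run_condition(
    table: TokenTable,
    condition: Condition | str,
    systems: Sequence[str | CombinationModel],
    R: int = 200,
    base_seed: int = 0,
    prior: float = 0.5,
    ridge: float = 1e-3,
    group_vowel_quality: bool = False,
) -> dict[str, ReplicationSummary]:
    """Replicated downsample -> score -> calibrate -> Cllr/EER pipeline.

    Each replication r (seed = base_seed + r) balanced-downsamples every
    unit type per style (equalizing styles in the mismatched condition),
    builds trials, scores every needed single parameter once, then
    self-calibrates each single system and fuses each combination.
    Returns one :class:`ReplicationSummary` (cllr + eer per replication)
    per requested system.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    systems = _normalize_systems(systems)
    singles = {s for s in systems if isinstance(s, str)}
    for s in systems:
        if isinstance(s, CombinationModel):
            singles.update(s.components)
    needed = sorted(singles)

    rows: dict[str, list[dict]] = {name_of(s): [] for s in systems}
    failures: dict[str, list[tuple[int, str]]] = {name_of(s): [] for s in systems}
    for r in range(R):
        seed = base_seed + r
        try:
            ds = balanced_downsample_all(
                table, seed=seed, equalize_styles=not condition.matched
            )
            plan = build_trials(ds, condition, seed)
            raw = {
                p: score_trials(
                    ds, plan, p, group_vowel_quality=group_vowel_quality,
                    prior=prior, ridge=ridge,
                )
                for p in needed
            }
        except Exception as exc:  # noqa: BLE001 - fault isolation per replication
            for s in systems:
                failures[name_of(s)].append((r, repr(exc)))
            continue
        for s in systems:
            name = name_of(s)
            try:
                if isinstance(s, str):
                    cal, _ = calibrate_scores(raw[s], prior=prior, ridge=ridge)
                else:
                    cal, _ = calibrate_scores(
                        [raw[c] for c in s.components],
                        prior=prior, ridge=ridge, system=s.name,
                    )
                rows[name].append(
                    {
                        "replication": r,
                        "seed": seed,
                        "cllr": cllr(cal),
                        "eer": eer(cal),
                    }
                )
            except Exception as exc:  # noqa: BLE001
                failures[name].append((r, repr(exc)))
    return {
        name: ReplicationSummary(pd.DataFrame(data), failures[name])
        for name, data in rows.items()
    }


def name_of(system: str | CombinationModel) -> str:
    return system if isinstance(system, str) else system.name


def summarize_condition(results: Mapping[str, ReplicationSummary]) -> pd.DataFrame:
    """Wide summary table: one aggregate row block per metric, systems as columns."""
    blocks = []
    for metric in ("cllr", "eer"):
        cols = {}
        for system, summary in results.items():
            agg = summarize(summary)
            if metric in agg.index:
                cols[system] = agg.loc[metric]
        if cols:
            block = pd.DataFrame(cols)
            block.index = pd.MultiIndex.from_product([[metric], block.index])
            blocks.append(block)
    return pd.concat(blocks)
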