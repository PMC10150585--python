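"""Balanced downsampling to the minority case and replication protocol.

Spontaneous speech yields wildly imbalanced per-speaker token counts, so
before scoring, every speaker is randomly downsampled (without
replacement) to the smallest per-speaker count of the unit type at hand
— the "minority case" — separately within each speaking style.  Because
the selection is random, the whole experiment is repeated R times
(R = 200 in the reference protocol) with fresh selections, and Cllr/EER
are reported as average / median / minima / maxima / SD over the
replications, which exposes the selection-bias envelope of the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .data_model import TokenTable, UNIT_TYPES

__all__ = [
    "ReplicationSummary",
    "balanced_downsample",
    "balanced_downsample_all",
    "replicate",
    "summarize",
]


def balanced_downsample(
    table: TokenTable,
    unit_type: str,
    seed,
    equalize_styles: bool = False,
) -> TokenTable:
    """Downsample one unit type so every speaker keeps the minority count.

    Within each speaking style present for ``unit_type``, every speaker
    retains exactly n_min tokens (n_min = smallest per-speaker count in
    that style), selected uniformly at random without replacement.  With
    ``equalize_styles=True`` the minimum is taken over speakers *and*
    styles jointly, so both styles end up with identical per-speaker
    counts (used in the mismatched-style condition, where the number of
    observations per style must be kept constant).  Rows of other unit
    types are untouched.  Deterministic given ``seed``.
    """
    if unit_type not in UNIT_TYPES:
        raise ValueError(f"unknown unit type {unit_type!r}")
    rng = np.random.default_rng(seed)
    df = table.data
    mask = (df["unit_type"] == unit_type).to_numpy()
    if not mask.any():
        raise ValueError(f"table has no {unit_type!r} tokens")
    sub = df[mask]
    speakers = sorted(df["speaker"].unique())
    styles = sorted(sub["style"].unique())

    counts: dict[tuple[str, str], np.ndarray] = {}
    for style in styles:
        for spk in speakers:
            idx = sub.index[(sub["style"] == style) & (sub["speaker"] == spk)].to_numpy()
            if idx.size == 0:
                raise ValueError(
                    f"speaker {spk!r} has no {unit_type!r} tokens in style {style!r}"
                )
            counts[(style, spk)] = idx

    if equalize_styles:
        n_min_global = min(len(v) for v in counts.values())
    keep: list[np.ndarray] = []
    for style in styles:
        if equalize_styles:
            n_min = n_min_global
        else:
            n_min = min(len(counts[(style, spk)]) for spk in speakers)
        for spk in speakers:
            idx = counts[(style, spk)]
            sel = rng.choice(idx, size=n_min, replace=False)
            keep.append(np.sort(sel))

    keep_idx = np.concatenate(keep)
    out = pd.concat([df[~mask], df.loc[keep_idx]]).sort_index().reset_index(drop=True)
    return TokenTable(out)


def balanced_downsample_all(
    table: TokenTable, seed, equalize_styles: bool = False
) -> TokenTable:
    """Apply :func:`balanced_downsample` to every unit type present."""
    present = [u for u in UNIT_TYPES if (table.data["unit_type"] == u).any()]
    out = table
    for k, unit in enumerate(present):
        out = balanced_downsample(out, unit, seed=(seed, k), equalize_styles=equalize_styles)
    return out


@dataclass
class ReplicationSummary:
    """Per-replication metrics plus their aggregates.

    ``per_replication`` has one row per completed replication with columns
    ``replication``, ``seed`` and one column per metric (typically
    ``cllr`` and ``eer``).
    """

    per_replication: pd.DataFrame
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures

    @property
    def n_replications(self) -> int:
        return len(self.per_replication)

    @property
    def metrics(self) -> list[str]:
        return [c for c in self.per_replication.columns if c not in ("replication", "seed")]

    def aggregates(self) -> pd.DataFrame:
        return summarize(self)


def replicate(
    experiment: Callable[[int], Mapping[str, float]],
    R: int = 200,
    base_seed: int = 0,
) -> ReplicationSummary:
    """Run ``experiment(seed)`` R times with seeds base_seed + index.

    ``experiment`` returns a mapping of metric name to value (e.g.
    ``{"cllr": ..., "eer": ...}``).  Failed replications are recorded and
    the summary is marked incomplete rather than aborting the run.
    """
    if R < 1:
        raise ValueError("need at least one replication")
    rows = []
    failures: list[tuple[int, str]] = []
    for i in range(R):
        seed = base_seed + i
        try:
            out = experiment(seed)
        except Exception as exc:  # noqa: BLE001 - per-replication fault isolation
            failures.append((i, repr(exc)))
            continue
        rows.append({"replication": i, "seed": seed, **{k: float(v) for k, v in out.items()}})
    return ReplicationSummary(per_replication=pd.DataFrame(rows), failures=failures)


def summarize(summary: ReplicationSummary) -> pd.DataFrame:
    """Average/Median/Minima/Maxima/SD per metric over completed replications.

    Average is the arithmetic mean and SD the sample standard deviation
    (n-1 denominator; 0 for a single replication).
    """
    df = summary.per_replication
    if len(df) == 0:
        raise ValueError("no completed replications to summarize")
    rows = {}
    for metric in summary.metrics:
        v = df[metric].to_numpy(dtype=float)
        rows[metric] = {
            "average": float(np.mean(v)),
            "median": float(np.median(v)),
            "minima": float(np.min(v)),
            "maxima": float(np.max(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
    return pd.DataFrame(rows).T[["average", "median", "minima", "maxima", "sd"]]
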