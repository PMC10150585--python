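"""Validity metrics for likelihood-ratio systems: Cllr and EER.

Cllr (log-likelihood-ratio cost) is the strictly proper scoring rule

    Cllr = 1/2 * [ mean_same log2(1 + 1/LR) + mean_diff log2(1 + LR) ]

measuring both discrimination and calibration of a set of LRs: 0 is a
perfect system, 1 is an uninformative one (every LR = 1), and values
above 1 indicate actively misleading output.

EER (equal error rate) is the operating point where the false-rejection
rate (same-speaker trials scored below threshold) equals the
false-acceptance rate (different-speaker trials scored at or above it).
Thresholds are swept at midpoints between adjacent distinct scores and
the crossing is found by linear interpolation, which makes the value
reproducible and checkable against an exhaustive sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import ScoreSet

__all__ = ["MetricsSummary", "cllr", "eer", "summarize_scores"]

_LN10 = math.log(10.0)
_LN2 = math.log(2.0)


def _scores_and_mask(scores, labels):
    if isinstance(scores, ScoreSet):
        return scores.log10_lr, scores.same_mask
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    same = labels if labels.dtype == bool else labels == "same"
    if len(same) != len(s):
        raise ValueError("scores and labels have different lengths")
    return s, same


@dataclass(frozen=True)
class MetricsSummary:
    cllr: float
    eer: float
    n_target: int
    n_nontarget: int

    def __post_init__(self) -> None:
        if self.cllr < 0 or not 0 <= self.eer <= 1 or min(self.n_target, self.n_nontarget) < 1:
            raise ValueError("invalid metrics summary")


def cllr(scores, labels=None) -> float:
    """Log-likelihood-ratio cost of a set of log10 LRs.

    Raises if either trial class is absent or any LR is non-positive
    (i.e. any log-LR is non-finite).
    """
    s, same = _scores_and_mask(scores, labels)
    if not same.any() or same.all():
        raise ValueError("Cllr requires both same- and different-speaker trials")
    if not np.all(np.isfinite(s)):
        raise ValueError("Cllr requires finite, positive likelihood ratios")
    # log2(1 + 1/LR) = logaddexp(0, -ln LR)/ln 2 ; log2(1 + LR) likewise
    term_same = float(np.mean(np.logaddexp(0.0, -s[same] * _LN10))) / _LN2
    term_diff = float(np.mean(np.logaddexp(0.0, s[~same] * _LN10))) / _LN2
    return 0.5 * (term_same + term_diff)


def eer(scores, labels=None) -> float:
    """Equal error rate under the midpoint-threshold sweep convention.

    A trial is *accepted* (called same-speaker) when its score is >= the
    threshold.  FRR(t) is the fraction of same-speaker scores below t,
    FAR(t) the fraction of different-speaker scores at or above t; the
    crossing of the two piecewise curves is located by linear
    interpolation between adjacent thresholds.
    """
    s, same = _scores_and_mask(scores, labels)
    if not same.any() or same.all():
        raise ValueError("EER requires both same- and different-speaker trials")
    s_same = np.sort(s[same])
    s_diff = np.sort(s[~same])
    uniq = np.unique(s)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], 0.5 * (uniq[:-1] + uniq[1:]), [uniq[-1] + 1.0]]
    )
    frr = np.searchsorted(s_same, thresholds, side="left") / len(s_same)
    far = 1.0 - np.searchsorted(s_diff, thresholds, side="left") / len(s_diff)
    d = far - frr  # non-increasing: starts at +1, ends at -1
    i = int(np.argmax(d <= 0))
    if d[i] == 0:
        return float(frr[i])
    t = d[i - 1] / (d[i - 1] - d[i])
    return float(frr[i - 1] + t * (frr[i] - frr[i - 1]))


def summarize_scores(scores: ScoreSet) -> MetricsSummary:
    """Cllr and EER of one score set, with class counts."""
    same = scores.same_mask
    return MetricsSummary(
        cllr=cllr(scores),
        eer=eer(scores),
        n_target=int(same.sum()),
        n_nontarget=int((~same).sum()),
    )
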