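"""Logistic-regression calibration and fusion of likelihood-ratio scores.

Raw scores from one or more systems are mapped to calibrated log
likelihood ratios by an affine transform

    calibrated ln LR = a + sum_k b_k * s_k      (s_k in natural-log units)

whose offset a and weights b minimize the class-balanced (effective
target prior 0.5) regularized logistic cross-entropy over a set of
labeled same-/different-speaker trials.  Training and applying on the
same trial set ("self-calibration") is the default; the same machinery
fuses several systems into a single calibrated score stream.

Balancing to prior 0.5 matters because different-speaker trials vastly
outnumber same-speaker trials (all unordered speaker pairs vs. one trial
per speaker); an unbalanced fit would fold that ratio into the offset.
The small ridge on the weights (never on the offset) keeps the fit
finite on perfectly separated score sets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .data_model import ScoreSet

__all__ = [
    "CalibrationModel",
    "LogisticFusion",
    "train_logistic_fusion",
    "apply_fusion",
    "calibrate_scores",
]

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass
class CalibrationModel:
    """Fitted calibration/fusion map (results object of :class:`LogisticFusion`)."""

    offset: float  # natural-log-odds units
    weights: np.ndarray  # one per input system
    prior: float
    ridge: float
    n_same: int
    n_different: int
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not (math.isfinite(self.offset) and np.all(np.isfinite(self.weights))):
            raise ValueError("calibration parameters must be finite")

    @property
    def n_systems(self) -> int:
        return len(self.weights)

    def apply(self, scores_log10: np.ndarray) -> np.ndarray:
        """Map raw log10-LR score vectors to calibrated log10 LRs."""
        s = _score_matrix(scores_log10)
        if s.shape[1] != self.n_systems:
            raise ValueError(
                f"score matrix has {s.shape[1]} systems, model expects {self.n_systems}"
            )
        z = self.offset + (s * _LN10) @ self.weights
        return z / _LN10

    def summary(self) -> str:
        w = ", ".join(f"{v:.4f}" for v in self.weights)
        return (
            "Logistic calibration/fusion\n"
            f"  systems: {self.n_systems}\n"
            f"  offset (ln-odds): {self.offset:.4f}\n"
            f"  weights: [{w}]\n"
            f"  trained on: {self.n_same} same / {self.n_different} different trials\n"
            f"  effective prior: {self.prior}, ridge: {self.ridge}\n"
            f"  converged: {self.converged} ({self.n_iter} iterations)"
        )

    def to_dict(self) -> dict:
        return {
            "offset": self.offset,
            "weights": self.weights.tolist(),
            "prior": self.prior,
            "ridge": self.ridge,
            "n_same": self.n_same,
            "n_different": self.n_different,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationModel":
        return cls(
            offset=float(d["offset"]),
            weights=np.asarray(d["weights"], dtype=float),
            prior=float(d["prior"]),
            ridge=float(d["ridge"]),
            n_same=int(d["n_same"]),
            n_different=int(d["n_different"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _score_matrix(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    if s.ndim != 2:
        raise ValueError("scores must be a trials x systems matrix")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain missing or non-finite values")
    return s


class LogisticFusion:
    """Class-balanced logistic calibration/fusion model.

    Parameters
    ----------
    scores
        (trials, systems) matrix of raw log10 LRs.
    labels
        "same"/"different" per trial (or a boolean same-speaker mask).
    prior
        Effective target prior used to balance the two classes.
    ridge
        L2 penalty on the weights (the offset is unpenalized).
    """

    def __init__(self, scores, labels, prior: float = 0.5, ridge: float = 1e-3):
        self.scores = _score_matrix(scores)
        labels = np.asarray(labels)
        if labels.dtype == bool:
            same = labels
        else:
            same = labels == "same"
        if len(same) != len(self.scores):
            raise ValueError("labels and scores have different lengths")
        if same.all() or (~same).all():
            raise ValueError("training requires both same- and different-speaker trials")
        if not 0.0 < prior < 1.0:
            raise ValueError("prior must be in (0, 1)")
        self.same = same
        self.prior = float(prior)
        self.ridge = float(ridge)

    def fit(self) -> CalibrationModel:
        s = self.scores * _LN10  # natural-log internally
        y = np.where(self.same, 1.0, -1.0)
        n_same = int(self.same.sum())
        n_diff = int((~self.same).sum())
        w = np.where(self.same, self.prior / n_same, (1.0 - self.prior) / n_diff)
        k = s.shape[1]
        ridge = self.ridge

        def objective(x):
            a, b = x[0], x[1:]
            z = a + s @ b
            loss = float(np.sum(w * np.logaddexp(0.0, -y * z)))
            sig = expit(-y * z)
            ga = float(np.sum(w * (-y) * sig))
            gb = s.T @ (w * (-y) * sig) + 2.0 * ridge * b
            return loss + ridge * float(b @ b), np.concatenate([[ga], gb])

        res = minimize(
            objective,
            x0=np.zeros(k + 1),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norm > 1e-6:
            raise RuntimeError(
                f"calibration did not converge: {res.message} "
                f"(iterations={res.nit}, |grad|={grad_norm:.3g})"
            )
        offset, weights = float(res.x[0]), res.x[1:]
        if np.any(weights < 0):
            logger.warning(
                "calibration produced negative weight(s): %s",
                np.array2string(weights, precision=4),
            )
        return CalibrationModel(
            offset=offset,
            weights=weights,
            prior=self.prior,
            ridge=self.ridge,
            n_same=n_same,
            n_different=n_diff,
            n_iter=int(res.nit),
            converged=bool(res.success),
        )


def train_logistic_fusion(
    scores, labels, prior: float = 0.5, ridge: float = 1e-3
) -> CalibrationModel:
    """Fit the balanced logistic calibration/fusion map (see :class:`LogisticFusion`)."""
    return LogisticFusion(scores, labels, prior=prior, ridge=ridge).fit()


def apply_fusion(model: CalibrationModel, scores) -> np.ndarray:
    """Apply a fitted calibration/fusion map; returns calibrated log10 LRs."""
    return model.apply(scores)


def calibrate_scores(
    score_sets: list[ScoreSet] | ScoreSet,
    prior: float = 0.5,
    ridge: float = 1e-3,
    system: str | None = None,
) -> tuple[ScoreSet, CalibrationModel]:
    """Self-calibrate one system or fuse several into one calibrated stream.

    All input score sets must share the same trial list (same order).
    """
    if isinstance(score_sets, ScoreSet):
        score_sets = [score_sets]
    base = score_sets[0]
    for other in score_sets[1:]:
        if not (
            np.array_equal(other.reference, base.reference)
            and np.array_equal(other.questioned, base.questioned)
        ):
            raise ValueError("fused score sets must share an identical trial list")
    matrix = np.column_stack([s.log10_lr for s in score_sets])
    model = train_logistic_fusion(matrix, base.label, prior=prior, ridge=ridge)
    name = system or "+".join(s.system for s in score_sets)
    fused = base.with_scores(model.apply(matrix), system=name)
    return fused, model
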