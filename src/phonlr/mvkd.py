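"""Multivariate kernel-density likelihood ratios for speaker comparison.

The evidence-evaluation model is two-level: tokens of speaker *i* are
Gaussian around a speaker-specific mean with a common within-speaker
covariance U, and the population of speaker means is represented
non-parametrically by a kernel density g built from the background
speakers' observed means,

    g(theta) = (1/m) * sum_i N(theta; mean_i, h^2 C),

with C the between-speaker covariance and h a dimension- and
sample-size-dependent kernel bandwidth.  The likelihood ratio for a
suspect token set (mean ys, n1 tokens) versus a questioned set
(mean yq, n2 tokens) is

          integral N(ys; th, U/n1) N(yq; th, U/n2) g(th) dth
    LR = ---------------------------------------------------------
          [int N(ys; th, U/n1) g(th) dth] [int N(yq; th, U/n2) g(th) dth]

evaluated in closed form by Gaussian-product algebra, entirely in
natural-log space; scores are reported as log10 LR (forensic convention).

``MVKD`` is the model object (built from per-speaker token matrices);
``fit()`` returns a :class:`BackgroundModel` results object that carries
the estimates (speaker means, U, C, h) and does the scoring.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import dblquad, quad
from scipy.linalg import cho_factor, solve_triangular
from scipy.special import logsumexp

__all__ = [
    "MVKD",
    "BackgroundModel",
    "LrResult",
    "fit_background",
    "kernel_bandwidth",
    "log_lr",
    "numeric_lr_oracle",
]

_LN10 = math.log(10.0)
_LN2PI = math.log(2.0 * math.pi)

#: Relative eigenvalue floor applied to the between-speaker covariance.
C_EIGEN_FLOOR = 1e-10
#: Relative ridge added to a near-singular within-speaker covariance.
U_RIDGE = 1e-8


def kernel_bandwidth(m: int, p: int) -> float:
    """Kernel bandwidth h = (4 / ((2p + 1) m))^(1/(p+4)).

    Shrinks toward 0 as the number of background speakers m grows, so the
    kernel density tightens around the observed speaker means.
    """
    if m < 2 or p < 1:
        raise ValueError("need m >= 2 background speakers and p >= 1 dimensions")
    return float((4.0 / ((2.0 * p + 1.0) * m)) ** (1.0 / (p + 4.0)))


def _as_matrix(x: np.ndarray, p: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("token sets must be 1-D or 2-D arrays")
    if p is not None and x.shape[1] != p:
        raise ValueError(f"token matrix has {x.shape[1]} columns, model expects {p}")
    return x


def _mixture_logpdfs(x: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; mean_i, cov) for every row of ``means`` (shared covariance)."""
    p = cov.shape[0]
    try:
        c, lower = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"covariance not positive definite: {exc}") from exc
    diff = (means - x[None, :]).T  # (p, m)
    sol = solve_triangular(c, diff, lower=True)
    maha = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return -0.5 * (p * _LN2PI + logdet + maha)


@dataclass(frozen=True)
class LrResult:
    """One scored comparison: log10 LR plus trial bookkeeping."""

    log10_lr: float
    n_suspect: int
    n_questioned: int
    background_speakers: tuple[str, ...]

    @property
    def ln_lr(self) -> float:
        return self.log10_lr * _LN10


@dataclass
class BackgroundModel:
    """Fitted two-level background model (results object of :class:`MVKD`)."""

    speaker_ids: tuple[str, ...]
    speaker_means: np.ndarray  # (m, p)
    U: np.ndarray  # (p, p) pooled within-speaker covariance
    C: np.ndarray  # (p, p) between-speaker covariance
    h: float
    token_counts: tuple[int, ...]

    @property
    def m(self) -> int:
        return len(self.speaker_ids)

    @property
    def p(self) -> int:
        return self.speaker_means.shape[1]

    # -- scoring ---------------------------------------------------------
    def log_lr(self, suspect: np.ndarray, questioned: np.ndarray) -> LrResult:
        """Closed-form log10 likelihood ratio for two token sets."""
        suspect = _as_matrix(suspect, self.p)
        questioned = _as_matrix(questioned, self.p)
        if len(suspect) == 0 or len(questioned) == 0:
            raise ValueError("suspect and questioned token sets must be non-empty")
        n1, n2 = len(suspect), len(questioned)
        ys = suspect.mean(axis=0)
        yq = questioned.mean(axis=0)
        D1 = self.U / n1
        D2 = self.U / n2
        B = (self.h ** 2) * self.C

        ln_pair = float(_mixture_logpdfs(ys, yq[None, :], D1 + D2)[0])
        P1 = np.linalg.inv(D1)
        P2 = np.linalg.inv(D2)
        D12 = np.linalg.inv(P1 + P2)
        D12 = 0.5 * (D12 + D12.T)
        center = D12 @ (P1 @ ys + P2 @ yq)

        ln_m = math.log(self.m)
        ln_num = ln_pair + logsumexp(_mixture_logpdfs(center, self.speaker_means, D12 + B)) - ln_m
        ln_d1 = logsumexp(_mixture_logpdfs(ys, self.speaker_means, D1 + B)) - ln_m
        ln_d2 = logsumexp(_mixture_logpdfs(yq, self.speaker_means, D2 + B)) - ln_m
        ln_lr = ln_num - ln_d1 - ln_d2
        if not math.isfinite(ln_lr):
            raise FloatingPointError(
                f"non-finite log LR (num={ln_num}, den1={ln_d1}, den2={ln_d2})"
            )
        return LrResult(
            log10_lr=ln_lr / _LN10,
            n_suspect=n1,
            n_questioned=n2,
            background_speakers=self.speaker_ids,
        )

    def summary(self) -> str:
        lines = [
            "MVKD background model",
            f"  speakers (m): {self.m}",
            f"  dimension (p): {self.p}",
            f"  kernel bandwidth h: {self.h:.6f}",
            f"  tr(U)/p: {np.trace(self.U) / self.p:.6g}",
            f"  tr(C)/p: {np.trace(self.C) / self.p:.6g}",
            f"  tokens per speaker: min={min(self.token_counts)}, "
            f"max={max(self.token_counts)}",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "speaker_ids": list(self.speaker_ids),
            "speaker_means": self.speaker_means.tolist(),
            "U": self.U.tolist(),
            "C": self.C.tolist(),
            "h": self.h,
            "token_counts": list(self.token_counts),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BackgroundModel":
        return cls(
            speaker_ids=tuple(d["speaker_ids"]),
            speaker_means=np.asarray(d["speaker_means"], dtype=float),
            U=np.asarray(d["U"], dtype=float),
            C=np.asarray(d["C"], dtype=float),
            h=float(d["h"]),
            token_counts=tuple(int(n) for n in d["token_counts"]),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


class MVKD:
    """Two-level kernel-density model over background speakers' tokens.

    Parameters
    ----------
    groups
        Mapping from speaker id to an (n_i, p) token matrix (n_i >= 2).
    """

    def __init__(self, groups: Mapping[str, np.ndarray]):
        if len(groups) < 2:
            raise ValueError(f"need at least 2 background speakers, got {len(groups)}")
        ids = sorted(groups)
        mats = []
        p = None
        for sid in ids:
            x = _as_matrix(groups[sid])
            if p is None:
                p = x.shape[1]
            elif x.shape[1] != p:
                raise ValueError(f"speaker {sid!r}: dimension mismatch")
            if len(x) < 2:
                raise ValueError(f"speaker {sid!r} has fewer than 2 tokens")
            mats.append(x)
        self.speaker_ids = tuple(ids)
        self.matrices = mats
        self.p = p

    def fit(self) -> BackgroundModel:
        m = len(self.speaker_ids)
        p = self.p
        counts = np.array([len(x) for x in self.matrices])
        means = np.vstack([x.mean(axis=0) for x in self.matrices])

        scatter = np.zeros((p, p))
        for x in self.matrices:
            d = x - x.mean(axis=0)
            scatter += d.T @ d
        U = scatter / float(np.sum(counts - 1))
        U = 0.5 * (U + U.T)

        # between-speaker covariance of means, corrected for the within
        # contribution at the harmonic-mean token count
        n_tilde = m / float(np.sum(1.0 / counts))
        C_raw = np.atleast_2d(np.cov(means, rowvar=False, ddof=1)) - U / n_tilde
        C_raw = 0.5 * (C_raw + C_raw.T)

        # eigenvalue flooring: the within correction can push C indefinite
        evals, evecs = np.linalg.eigh(C_raw)
        floor = C_EIGEN_FLOOR * max(abs(np.trace(C_raw)) / p, 1e-12)
        if np.any(evals < floor):
            evals = np.maximum(evals, floor)
            C = (evecs * evals) @ evecs.T
        else:
            C = C_raw
        C = 0.5 * (C + C.T)

        # soft regularization of a (near-)singular within covariance
        tr_u = np.trace(U) / p
        if tr_u <= 0:
            scale = max(np.trace(C) / p, 1.0)
            warnings.warn(
                "within-speaker covariance is zero; substituting a tiny ridge",
                RuntimeWarning,
                stacklevel=2,
            )
            U = U_RIDGE * scale * np.eye(p)
        else:
            u_evals = np.linalg.eigvalsh(U)
            if u_evals.min() < 1e-12 * tr_u:
                warnings.warn(
                    "within-speaker covariance near-singular; adding ridge",
                    RuntimeWarning,
                    stacklevel=2,
                )
                U = U + U_RIDGE * tr_u * np.eye(p)
        if np.linalg.matrix_rank(U) < p:
            raise np.linalg.LinAlgError("within-speaker covariance singular after ridge")

        return BackgroundModel(
            speaker_ids=self.speaker_ids,
            speaker_means=means,
            U=U,
            C=C,
            h=kernel_bandwidth(m, p),
            token_counts=tuple(int(n) for n in counts),
        )


def fit_background(groups: Mapping[str, np.ndarray]) -> BackgroundModel:
    """Fit the two-level background model from per-speaker token matrices."""
    return MVKD(groups).fit()


def log_lr(model: BackgroundModel, suspect: np.ndarray, questioned: np.ndarray) -> LrResult:
    """Functional form of :meth:`BackgroundModel.log_lr`."""
    return model.log_lr(suspect, questioned)


# ---------------------------------------------------------------------------
# quadrature oracle
# ---------------------------------------------------------------------------


def _log_integrand_factory(model: BackgroundModel, terms: Sequence[tuple[np.ndarray, np.ndarray]]):
    B = (model.h ** 2) * model.C
    means = model.speaker_means
    ln_m = math.log(model.m)

    def log_f(theta: np.ndarray) -> float:
        total = logsumexp(_mixture_logpdfs(theta, means, B)) - ln_m
        for y, D in terms:
            total += float(_mixture_logpdfs(y, theta[None, :], D)[0])
        return total

    return log_f


def _log_integral_1d(log_f, lo: float, hi: float, peaks=()) -> float:
    grid = np.unique(np.concatenate([np.linspace(lo, hi, 201), np.asarray(peaks)]))
    shift = max(log_f(np.array([t])) for t in grid)
    breakpoints = sorted(p for p in peaks if lo < p < hi)
    val, _ = quad(
        lambda t: math.exp(log_f(np.array([t])) - shift), lo, hi,
        points=breakpoints or None, limit=500, epsabs=1e-13, epsrel=1e-12,
    )
    if val <= 0:
        raise FloatingPointError("quadrature produced a non-positive integral")
    return shift + math.log(val)


def _log_integral_2d(log_f, lo: np.ndarray, hi: np.ndarray) -> float:
    g = np.linspace(0, 1, 81)
    xs = lo[0] + g * (hi[0] - lo[0])
    ys = lo[1] + g * (hi[1] - lo[1])
    shift = max(log_f(np.array([x, y])) for x in xs for y in ys)
    val, _ = dblquad(
        lambda y, x: math.exp(log_f(np.array([x, y])) - shift),
        lo[0], hi[0], lambda x: lo[1], lambda x: hi[1],
        epsabs=1e-11, epsrel=1e-10,
    )
    if val <= 0:
        raise FloatingPointError("quadrature produced a non-positive integral")
    return shift + math.log(val)


def numeric_lr_oracle(
    model: BackgroundModel, suspect: np.ndarray, questioned: np.ndarray
) -> float:
    """log10 LR via adaptive numerical integration over the speaker mean.

    Practical for p <= 2 only; serves as an independent check of the
    closed-form scorer.
    """
    if model.p > 2:
        raise ValueError("numeric oracle supports p <= 2 only")
    suspect = _as_matrix(suspect, model.p)
    questioned = _as_matrix(questioned, model.p)
    n1, n2 = len(suspect), len(questioned)
    ys = suspect.mean(axis=0)
    yq = questioned.mean(axis=0)
    D1 = model.U / n1
    D2 = model.U / n2

    pts = np.vstack([model.speaker_means, ys[None, :], yq[None, :]])
    spread = math.sqrt(
        max(
            np.max(np.diag(model.U)),
            (model.h ** 2) * np.max(np.diag(model.C)),
            np.max(np.diag(model.C)),
        )
    )
    lo = pts.min(axis=0) - 12.0 * spread
    hi = pts.max(axis=0) + 12.0 * spread

    f_num = _log_integrand_factory(model, [(ys, D1), (yq, D2)])
    f_d1 = _log_integrand_factory(model, [(ys, D1)])
    f_d2 = _log_integrand_factory(model, [(yq, D2)])
    if model.p == 1:
        peaks = pts[:, 0].tolist()
        ln_lr = (
            _log_integral_1d(f_num, lo[0], hi[0], peaks)
            - _log_integral_1d(f_d1, lo[0], hi[0], peaks)
            - _log_integral_1d(f_d2, lo[0], hi[0], peaks)
        )
    else:
        ln_lr = (
            _log_integral_2d(f_num, lo, hi)
            - _log_integral_2d(f_d1, lo, hi)
            - _log_integral_2d(f_d2, lo, hi)
        )
    return ln_lr / _LN10
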