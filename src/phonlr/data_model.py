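"""Core data containers for acoustic-phonetic speaker comparison.

The package works on *tidy* token tables: one row per measured speech unit
(a vowel, a vowel-onset-to-vowel-onset interval, a silent pause, or a
connected-speech chunk), with the speaker label, the speaking style under
which it was produced, and the numeric acoustic features measured on it
(formant frequencies in Hz, durations in ms, f0 summaries in semitones).

Everything is plain delimited text (UTF-8 CSV) so tables exported by
annotation/extraction scripts round-trip losslessly through this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STYLES",
    "UNIT_TYPES",
    "VOWEL_QUALITIES",
    "ID_COLUMNS",
    "UNIT_FEATURES",
    "SchemaError",
    "TableValidationError",
    "Violation",
    "ValidationReport",
    "TokenTable",
    "F0SampleSet",
    "ScoreSet",
    "read_token_table",
    "write_token_table",
    "read_f0_samples",
    "write_f0_samples",
    "validate",
]

#: Closed vocabulary of speaking styles (spontaneous telephone dialogue vs.
#: researcher-led interview).
STYLES: tuple[str, ...] = ("dialogue", "interview")

#: Closed vocabulary of speech-unit types carried by a token table.
UNIT_TYPES: tuple[str, ...] = ("vowel", "vv_unit", "silent_pause", "chunk")

#: The seven oral monophthongs of Brazilian Portuguese.
VOWEL_QUALITIES: tuple[str, ...] = ("a", "e", "E", "i", "o", "O", "u")

#: Identifier (non-feature) columns of a token table.
ID_COLUMNS: tuple[str, ...] = ("speaker", "style", "unit_type", "vowel_quality", "chunk_id")

#: Which feature columns are meaningful for each unit type.  A feature column
#: is validated (finite, positive where required) only on the rows of unit
#: types it applies to; elsewhere it is expected to be empty.
UNIT_FEATURES: dict[str, tuple[str, ...]] = {
    "vowel": ("F1", "F2", "F3", "F4", "duration_ms"),
    "vv_unit": ("duration_ms",),
    "silent_pause": ("duration_ms",),
    "chunk": ("f0_median_st", "f0_base_st"),
}

_MANDATORY = ("speaker", "style", "unit_type")
_FORMANTS = ("F1", "F2", "F3", "F4")


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class TableValidationError(ValueError):
    """A token table violates one or more row-level invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__(str(report))


@dataclass(frozen=True)
class Violation:
    row: int
    column: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, column {self.column!r}: {self.message}"


@dataclass
class ValidationReport:
    """All invariant violations found in a table, with row indices."""

    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, row: int, column: str, message: str) -> None:
        self.violations.append(Violation(int(row), column, message))

    def __len__(self) -> int:
        return len(self.violations)

    def __str__(self) -> str:
        if self.ok:
            return "valid token table (no violations)"
        head = "\n".join(str(v) for v in self.violations[:20])
        more = len(self.violations) - 20
        if more > 0:
            head += f"\n... and {more} more"
        return f"{len(self.violations)} violation(s):\n{head}"


@dataclass
class TokenTable:
    """Tidy table of acoustic-phonetic tokens.

    ``data`` holds one row per token with the identifier columns of
    :data:`ID_COLUMNS` plus any number of numeric feature columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _MANDATORY:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        for col in ("vowel_quality", "chunk_id"):
            if col not in df.columns:
                df = df.assign(**{col: ""})
        # stable column order: ids first, then features in original order
        feats = [c for c in df.columns if c not in ID_COLUMNS]
        self.data = df[[*ID_COLUMNS, *feats]].reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def speakers(self) -> list[str]:
        return sorted(self.data["speaker"].unique())

    def subset(
        self,
        unit_type: str | None = None,
        style: str | None = None,
        speaker: str | None = None,
    ) -> "TokenTable":
        df = self.data
        if unit_type is not None:
            df = df[df["unit_type"] == unit_type]
        if style is not None:
            df = df[df["style"] == style]
        if speaker is not None:
            df = df[df["speaker"] == speaker]
        return TokenTable(df.copy())

    def counts(self, unit_type: str, style: str | None = None) -> pd.Series:
        """Per-speaker token counts for one unit type (optionally one style)."""
        sub = self.subset(unit_type=unit_type, style=style)
        return sub.data.groupby("speaker").size()

    def validate(self) -> ValidationReport:
        return validate(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TokenTable):
            return NotImplemented
        return self.data.equals(other.data)


def validate(table: TokenTable) -> ValidationReport:
    """Check every row-level invariant; return a report (never raises).

    Checked invariants: style and unit_type come from their closed
    vocabularies; vowel rows carry a vowel quality; all applicable feature
    values are present (non-NaN); durations and formants are strictly
    positive; formants are ordered F1 < F2 < F3 < F4 within a row.
    """
    report = ValidationReport()
    df = table.data
    present = set(table.feature_columns)

    style_bad = ~df["style"].isin(STYLES)
    for row in np.flatnonzero(style_bad.to_numpy()):
        report.add(row, "style", f"unknown style {df['style'].iat[row]!r}")
    unit_bad = ~df["unit_type"].isin(UNIT_TYPES)
    for row in np.flatnonzero(unit_bad.to_numpy()):
        report.add(row, "unit_type", f"unknown unit_type {df['unit_type'].iat[row]!r}")

    unit = df["unit_type"].to_numpy()
    vq = df["vowel_quality"].astype(str).to_numpy()
    for row in np.flatnonzero((unit == "vowel") & ((vq == "") | (vq == "nan"))):
        report.add(row, "vowel_quality", "vowel row without vowel quality")
    known_q = set(VOWEL_QUALITIES)
    for row in np.flatnonzero((unit == "vowel") & (vq != "") & (vq != "nan")):
        if vq[row] not in known_q:
            report.add(row, "vowel_quality", f"unknown vowel quality {vq[row]!r}")

    for utype, feats in UNIT_FEATURES.items():
        rows = np.flatnonzero(unit == utype)
        if rows.size == 0:
            continue
        for colname in feats:
            if colname not in present:
                continue
            vals = pd.to_numeric(df[colname].iloc[rows], errors="coerce").to_numpy(float)
            for i in np.flatnonzero(~np.isfinite(vals)):
                report.add(rows[i], colname, "missing or non-finite value")
            if colname == "duration_ms" or colname in _FORMANTS:
                for i in np.flatnonzero(np.isfinite(vals) & (vals <= 0)):
                    report.add(rows[i], colname, f"non-positive value {vals[i]!r}")

    # formant ordering on vowel rows, using whichever formants are present
    fcols = [c for c in _FORMANTS if c in present]
    if len(fcols) >= 2:
        vrows = np.flatnonzero(unit == "vowel")
        if vrows.size:
            fmat = df[fcols].iloc[vrows].apply(pd.to_numeric, errors="coerce").to_numpy(float)
            with np.errstate(invalid="ignore"):
                bad = np.any(np.diff(fmat, axis=1) <= 0, axis=1) & np.all(
                    np.isfinite(fmat), axis=1
                )
            for i in np.flatnonzero(bad):
                report.add(vrows[i], "F1..F4", "formants not strictly increasing")
    return report


def read_token_table(path: str | Path, schema: Mapping[str, str] | None = None) -> TokenTable:
    """Read and validate a delimited token table.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from file column names to canonical names
        (``speaker``, ``style``, ``unit_type``, feature names ...).

    Raises
    ------
    SchemaError
        If a mandatory column is absent or a numeric cell cannot be parsed
        (the error names the column and 1-based file line).
    TableValidationError
        If the parsed table violates row-level invariants.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        df = df.rename(columns=dict(schema))
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    for col in ("vowel_quality", "chunk_id"):
        if col not in df.columns:
            df[col] = ""
    feat_cols = [c for c in df.columns if c not in ID_COLUMNS]
    parse_errors: list[str] = []
    for col in feat_cols:
        raw = df[col].to_numpy()
        out = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                # +2: one for the header line, one for 1-based numbering
                parse_errors.append(f"line {i + 2}, column {col!r}: unparseable value {cell!r}")
        df[col] = out
    if parse_errors:
        raise SchemaError(f"{path}: " + "; ".join(parse_errors[:10]))
    table = TokenTable(df)
    report = table.validate()
    if not report.ok:
        raise TableValidationError(report)
    return table


def write_token_table(table: TokenTable, path: str | Path) -> Path:
    """Write a validated table as CSV readable by :func:`read_token_table`."""
    report = table.validate()
    if not report.ok:
        raise TableValidationError(report)
    path = Path(path)
    df = table.data.copy()
    # empty string (not "nan") for inapplicable feature cells
    df.to_csv(path, index=False, na_rep="")
    return path


# ---------------------------------------------------------------------------
# f0 sample vectors
# ---------------------------------------------------------------------------


@dataclass
class F0SampleSet:
    """Per-chunk fundamental-frequency sample vectors (Hz).

    ``data`` has one sample per row: columns ``speaker``, ``style``,
    ``chunk_id``, ``f0_hz``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("speaker", "style", "chunk_id", "f0_hz"):
            if col not in self.data.columns:
                raise SchemaError(f"missing f0-sample column {col!r}")
        self.data = self.data.reset_index(drop=True)
        self.data["f0_hz"] = self.data["f0_hz"].astype(float)

    def chunks(self) -> Iterable[tuple[tuple[str, str, str], np.ndarray]]:
        """Yield ((speaker, style, chunk_id), values) per chunk, sorted."""
        grouped = self.data.groupby(["speaker", "style", "chunk_id"], sort=True)
        for key, grp in grouped:
            yield key, grp["f0_hz"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.data)


def read_f0_samples(path: str | Path) -> F0SampleSet:
    df = pd.read_csv(path, dtype={"speaker": str, "style": str, "chunk_id": str})
    return F0SampleSet(df)


def write_f0_samples(samples: F0SampleSet, path: str | Path) -> Path:
    path = Path(path)
    samples.data.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# score sets
# ---------------------------------------------------------------------------


@dataclass
class ScoreSet:
    """Per-trial log10 likelihood ratios with same/different-speaker labels."""

    reference: np.ndarray
    questioned: np.ndarray
    log10_lr: np.ndarray
    label: np.ndarray  # "same" | "different"
    system: str = "system"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=object)
        self.questioned = np.asarray(self.questioned, dtype=object)
        self.log10_lr = np.asarray(self.log10_lr, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        n = len(self.log10_lr)
        if not (len(self.reference) == len(self.questioned) == len(self.label) == n):
            raise ValueError("ScoreSet fields have inconsistent lengths")
        bad = set(self.label) - {"same", "different"}
        if bad:
            raise ValueError(f"unknown trial labels: {sorted(bad)}")
        same = self.label == "same"
        if np.any(same & (self.reference != self.questioned)):
            raise ValueError("same-speaker trial with differing speaker ids")
        if not np.all(np.isfinite(self.log10_lr)):
            raise ValueError("non-finite log10 LR in score set")

    @property
    def n_trials(self) -> int:
        return len(self.log10_lr)

    @property
    def same_mask(self) -> np.ndarray:
        return self.label == "same"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reference": self.reference,
                "questioned": self.questioned,
                "system": self.system,
                "log10_lr": self.log10_lr,
                "label": self.label,
            }
        )

    def with_scores(self, log10_lr: Sequence[float], system: str | None = None) -> "ScoreSet":
        """Copy of this score set with replaced scores (same trials/labels)."""
        return ScoreSet(
            self.reference,
            self.questioned,
            np.asarray(log10_lr, dtype=float),
            self.label,
            system or self.system,
        )
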