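"""Domain types and tabular I/O for ROI-level %BOLD analyses.

The pipeline operates on long-format tables of percent BOLD signal change
extracted from 16 lateralized regions of interest (ROIs): pre-SMA and IFG
cortically, and striatum (STR), external/internal globus pallidus (GPe/GPi),
substantia nigra (SN), subthalamic nucleus (STN) and thalamus (THAL)
subcortically, each in the left and right hemisphere.  Every observation is
keyed by (participant, contrast, ROI); contrasts are assigned to one of three
behavioural conditions (response execution, proactive inhibition, reactive
inhibition) by a user-supplied table.

All tables are tab-separated UTF-8 with a mandatory header row.  Values are
stored as percent (0.15 means 0.15 %BOLD); no rescaling happens on ingest.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Structure",
    "Hemisphere",
    "Condition",
    "RoiId",
    "ALL_ROIS",
    "SUBCORTICAL_STRUCTURES",
    "SUBCORTICAL_ROIS",
    "BoldTable",
    "ContrastAssignment",
    "PriorSpec",
    "BayesResult",
    "DataError",
    "MissingColumnError",
    "RoiParseError",
    "NonNumericValueError",
    "DuplicateKeyError",
    "UnknownConditionError",
    "ConflictingAssignmentError",
    "EmptyTableError",
    "read_bold_table",
    "read_contrast_assignments",
    "write_stats_table",
    "read_stats_table",
]


class DataError(ValueError):
    """Base class for all tabular-input validation errors."""


class MissingColumnError(DataError):
    pass


class RoiParseError(DataError):
    pass


class NonNumericValueError(DataError):
    pass


class DuplicateKeyError(DataError):
    pass


class UnknownConditionError(DataError):
    pass


class ConflictingAssignmentError(DataError):
    pass


class EmptyTableError(DataError):
    pass


class Structure(enum.Enum):
    """Anatomical structure of an ROI (8 bilateral structures)."""

    preSMA = "preSMA"
    IFG = "IFG"
    STR = "STR"
    GPe = "GPe"
    GPi = "GPi"
    SN = "SN"
    STN = "STN"
    THAL = "THAL"


class Hemisphere(enum.Enum):
    L = "L"
    R = "R"

    @property
    def opposite(self) -> "Hemisphere":
        return Hemisphere.R if self is Hemisphere.L else Hemisphere.L


class Condition(enum.Enum):
    """Behavioural condition of a contrast, plus the pooled inhibition set.

    ``INHIBITION_ALL`` never appears in assignment tables; it is derived
    downstream as the union of the proactive and reactive contrast sets.
    """

    EXECUTION = "execution"
    INHIBITION_PRO = "inhibition_pro"
    INHIBITION_REAC = "inhibition_reac"
    INHIBITION_ALL = "inhibition_all"


#: Conditions a contrast may be assigned to (the pooled set is derived).
ASSIGNABLE_CONDITIONS = (
    Condition.EXECUTION,
    Condition.INHIBITION_PRO,
    Condition.INHIBITION_REAC,
)


@dataclass(frozen=True)
class RoiId:
    """A lateralized region of interest, e.g. the right subthalamic nucleus.

    The canonical string form is ``"<hemisphere>_<structure>"`` (``"R_STN"``);
    parsing is case-insensitive but writing always uses the canonical form.
    """

    hemisphere: Hemisphere
    structure: Structure

    def __str__(self) -> str:
        return f"{self.hemisphere.value}_{self.structure.value}"

    def __lt__(self, other: "RoiId") -> bool:  # sorted by canonical string
        if not isinstance(other, RoiId):
            return NotImplemented
        return str(self) < str(other)

    @classmethod
    def parse(cls, text: str) -> "RoiId":
        parts = str(text).strip().split("_", 1)
        if len(parts) != 2:
            raise RoiParseError(f"ROI string {text!r} is not of the form '<L|R>_<structure>'")
        hemi_s, struct_s = parts
        try:
            hemi = Hemisphere[hemi_s.upper()]
        except KeyError:
            raise RoiParseError(f"unknown hemisphere {hemi_s!r} in ROI {text!r}") from None
        matches = [s for s in Structure if s.value.lower() == struct_s.lower()]
        if not matches:
            raise RoiParseError(f"unknown structure {struct_s!r} in ROI {text!r}")
        return cls(hemi, matches[0])

    @property
    def is_subcortical(self) -> bool:
        return self.structure in SUBCORTICAL_STRUCTURES

    def mirrored(self) -> "RoiId":
        return RoiId(self.hemisphere.opposite, self.structure)


SUBCORTICAL_STRUCTURES = frozenset(
    {Structure.STR, Structure.GPe, Structure.GPi, Structure.SN, Structure.STN, Structure.THAL}
)

#: The 16 lateralized ROIs in canonical order (L then R, cortical then subcortical).
ALL_ROIS: tuple[RoiId, ...] = tuple(
    RoiId(h, s) for h in (Hemisphere.L, Hemisphere.R) for s in Structure
)

#: The 12 lateralized subcortical ROIs (pathway products run over these only).
SUBCORTICAL_ROIS: tuple[RoiId, ...] = tuple(r for r in ALL_ROIS if r.is_subcortical)


@dataclass(frozen=True)
class PriorSpec:
    """Cauchy prior on the standardized effect size delta for JZS tests.

    ``scale`` is the Cauchy scale r.  The default, sqrt(1/2) ~ 0.7071, is the
    common "default" (medium) scale and was fixed by calibration: published
    (t, df) pairs from the study this pipeline models reproduce their printed
    Bayes factors to within 0.3% under this scale and under no other of the
    candidate scales {1, sqrt 2, sqrt 12}.
    """

    scale: float = math.sqrt(0.5)

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"prior scale must be a positive finite number, got {self.scale}")


class EvidenceCategory(enum.Enum):
    """Verbal interpretation of a Bayes factor (thresholds 3 and 1/3)."""

    SUBSTANTIAL_H1 = "substantial_H1"
    SUBSTANTIAL_H0 = "substantial_H0"
    INSENSITIVE = "insensitive"
    INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class BayesResult:
    """A (t, df, p, BF10) bundle for a single t-test.

    ``n_eff`` is the effective sample size used to scale the noncentrality of
    the alternative (delta * sqrt(n_eff)); for a one-sample test it is the
    number of observations.
    """

    t: float
    df: float
    n_eff: float
    p: float
    bf10: float
    category: EvidenceCategory

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


class BoldTable:
    """Long-format %BOLD observations keyed by (participant, contrast, ROI).

    Wraps a pandas DataFrame with columns ``participant``, ``contrast``,
    ``roi`` (canonical ROI strings) and ``value``.  Keys must be unique and
    values finite; rectangular completeness is *not* required here — it is
    enforced by the operations that need it, with named errors.
    """

    REQUIRED_COLUMNS = ("participant", "contrast", "roi", "value")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise MissingColumnError(f"BoldTable is missing column(s) {missing}")
        df = frame.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        df["participant"] = df["participant"].astype(str)
        df["contrast"] = df["contrast"].astype(str)
        canonical = {r: str(RoiId.parse(r)) for r in df["roi"].unique()}
        df["roi"] = df["roi"].map(canonical)
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = df.loc[values.isna() | ~values.map(math.isfinite), :]
        if len(bad):
            raise NonNumericValueError(
                f"{len(bad)} non-numeric or non-finite %BOLD value(s); first offending row: "
                f"{bad.iloc[0].to_dict()}"
            )
        df["value"] = values.astype(float)
        dup = df.duplicated(subset=["participant", "contrast", "roi"])
        if dup.any():
            first = df.loc[dup].iloc[0]
            raise DuplicateKeyError(
                "duplicate (participant, contrast, roi) key: "
                f"({first['participant']}, {first['contrast']}, {first['roi']})"
            )
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._df["participant"]))

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._df["contrast"]))

    @property
    def rois(self) -> frozenset[RoiId]:
        return frozenset(RoiId.parse(r) for r in self._df["roi"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BoldTable):
            return NotImplemented
        a = self._df.sort_values(["participant", "contrast", "roi"]).reset_index(drop=True)
        b = other._df.sort_values(["participant", "contrast", "roi"]).reset_index(drop=True)
        return a.equals(b)

    def write(self, path: str | Path) -> None:
        # full-precision repr so read(write(x)) round-trips exactly
        self._df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ContrastAssignment:
    """Mapping from contrast identifier to behavioural condition."""

    mapping: Mapping[str, Condition]

    def __post_init__(self) -> None:
        for contrast, cond in self.mapping.items():
            if cond not in ASSIGNABLE_CONDITIONS:
                raise UnknownConditionError(
                    f"contrast {contrast!r} assigned to non-assignable condition {cond}"
                )

    def condition_of(self, contrast: str) -> Condition:
        return self.mapping[contrast]

    def contrasts_for(self, condition: Condition) -> frozenset[str]:
        if condition is Condition.INHIBITION_ALL:
            return self.contrasts_for(Condition.INHIBITION_PRO) | self.contrasts_for(
                Condition.INHIBITION_REAC
            )
        return frozenset(c for c, k in self.mapping.items() if k is condition)


def read_bold_table(path: str | Path) -> BoldTable:
    """Read a long-format %BOLD TSV (columns participant, contrast, roi, value)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return BoldTable(df)


def read_contrast_assignments(path: str | Path) -> ContrastAssignment:
    """Read a contrast → condition TSV (columns contrast, condition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("contrast", "condition"):
        if col not in df.columns:
            raise MissingColumnError(f"assignment table is missing column {col!r}")
    valid = {c.value: c for c in ASSIGNABLE_CONDITIONS}
    mapping: dict[str, Condition] = {}
    for _, row in df.iterrows():
        contrast = str(row["contrast"]).strip()
        label = str(row["condition"]).strip()
        if label not in valid:
            raise UnknownConditionError(
                f"unknown condition label {label!r} for contrast {contrast!r}; "
                f"expected one of {sorted(valid)}"
            )
        cond = valid[label]
        if contrast in mapping and mapping[contrast] is not cond:
            raise ConflictingAssignmentError(
                f"contrast {contrast!r} assigned to both "
                f"{mapping[contrast].value!r} and {cond.value!r}"
            )
        mapping[contrast] = cond
    return ContrastAssignment(mapping)


def write_stats_table(records, path: str | Path) -> None:
    """Write tabular results as TSV with full precision plus 2-dp display columns.

    ``records`` may be a DataFrame or an iterable of mappings/dataclass-likes.
    Float columns are written with 12 significant digits and mirrored by a
    ``<name>_2dp`` column rounded to two decimals, matching the display
    precision of published ROI tables.  Round-trips through
    :func:`read_stats_table`.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        if not rows:
            raise EmptyTableError("refusing to write an empty results table")
        df = pd.DataFrame(rows)
    if df.empty:
        raise EmptyTableError("refusing to write an empty results table")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        series = df[col]
        if pd.api.types.is_float_dtype(series):
            out[col] = [format(float(v), ".12g") for v in series]
            # 2-decimal display; scientific once fixed-point stops being readable
            out[f"{col}_2dp"] = [
                format(float(v), ".2f") if 1e-3 <= abs(v) < 1e6 or v == 0
                else format(float(v), ".2e")
                for v in series
            ]
        else:
            out[col] = series.astype(str)
    out.to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_stats_table`, dropping display columns."""
    df = pd.read_csv(path, sep="\t")
    keep = [c for c in df.columns if not c.endswith("_2dp")]
    return df.loc[:, keep]
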