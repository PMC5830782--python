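"""Data model and I/O for linear skeletal measurements of pouch-young specimens.

Measurements are stored in long (tidy) form: one row per specimen, trait and
side, with values in millimetres. Sparse museum series — a handful of litters,
not every trait measured on every specimen — arrive naturally in this shape,
and litter-level summaries fall out of a single group-by.

Derived quantities implemented here:

* bilateral means (length of a long bone as the mean of left and right),
* midshaft circumference from anterior–posterior and medial–lateral widths,
* forelimb/hindlimb lengths as sums of the three long-bone segments,
* trunk length as the sum of thoracic and lumbar vertebral lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "WIDTH_TRAITS",
    "FORELIMB_SEGMENTS",
    "HINDLIMB_SEGMENTS",
    "SchemaError",
    "ValidationError",
    "MissingDataError",
    "DomainError",
    "Specimen",
    "LinearMeasurement",
    "LitterSummary",
    "LongBoneRecord",
    "MeasurementTable",
    "read_measurements",
    "write_measurements",
    "litter_summary",
    "midshaft_circumference",
    "bilateral_mean",
    "BilateralMean",
    "limb_lengths",
    "trunk_length",
]

# ---------------------------------------------------------------------------
# Vocabulary

TRAITS = frozenset(
    {
        "crown_rump_length",
        "head_length",
        "condylobasal_length",
        "scapula_length",
        "pelvis_length",
        "thoracic_sum",
        "lumbar_sum",
        "humerus_length",
        "radius_length",
        "third_metacarpal_length",
        "femur_length",
        "tibia_length",
        "third_metatarsal_length",
        "stylopod_fore",
        "zeugopod_fore",
        "autopod_fore",
        "stylopod_hind",
        "zeugopod_hind",
        "autopod_hind",
        "midshaft_ap_width",
        "midshaft_ml_width",
    }
)

#: Width traits must say which long bone the midshaft belongs to.
WIDTH_TRAITS = frozenset({"midshaft_ap_width", "midshaft_ml_width"})

LONG_BONES = frozenset({"humerus", "radius", "femur", "tibia"})

SIDES = frozenset({"left", "right", "midline"})

UNITS = {"mm": 1.0, "um": 1e-3, "µm": 1e-3}

FORELIMB_SEGMENTS = ("humerus_length", "radius_length", "third_metacarpal_length")
HINDLIMB_SEGMENTS = ("femur_length", "tibia_length", "third_metatarsal_length")

MEASUREMENT_COLUMNS = [
    "specimen_id",
    "litter_id",
    "trait",
    "bone_context",
    "side",
    "value",
    "unit",
]


# ---------------------------------------------------------------------------
# Errors


class SchemaError(ValueError):
    """A table is missing required columns or uses unknown vocabulary."""


class ValidationError(ValueError):
    """A row violates an invariant (nonpositive value, bad enum, ...)."""


class MissingDataError(KeyError):
    """A required measurement is absent."""


class DomainError(ValueError):
    """An argument is outside the function's mathematical domain."""


# ---------------------------------------------------------------------------
# Record types


@dataclass(frozen=True)
class Specimen:
    """One museum specimen (e.g. NMV C5755) and its litter membership."""

    specimen_id: str
    institution: str = ""
    litter_id: str = ""
    sex: str = "unknown"
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        if self.sex not in {"male", "female", "unknown"}:
            raise ValidationError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class LinearMeasurement:
    """A single linear measurement in mm on one specimen."""

    specimen_id: str
    trait: str
    value: float
    side: str = "midline"
    litter_id: str = ""
    bone_context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValidationError(f"unknown trait {self.trait!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if not (isinstance(self.value, (int, float)) and math.isfinite(self.value)):
            raise ValidationError(f"non-numeric value {self.value!r}")
        if self.value <= 0:
            raise ValidationError(
                f"measurement value must be > 0 mm, got {self.value}"
            )
        if self.trait in WIDTH_TRAITS:
            if self.bone_context not in LONG_BONES:
                raise ValidationError(
                    f"width trait {self.trait!r} requires bone_context "
                    f"in {sorted(LONG_BONES)}"
                )
        elif self.bone_context is not None and self.bone_context not in LONG_BONES:
            raise ValidationError(f"unknown bone_context {self.bone_context!r}")


@dataclass(frozen=True)
class LitterSummary:
    """Mean and standard error of one trait within one litter.

    ``se`` is the standard error of the mean (sample sd / sqrt(n)).  For a
    singleton litter the sd is undefined; the summary reports ``se = 0`` and
    sets ``singleton`` so downstream code can tell "no spread" from
    "spread not estimable".
    """

    litter_id: str
    trait: str
    mean: float
    se: float
    n: int
    singleton: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("litter summary needs n >= 1")
        if self.se < 0:
            raise ValidationError("standard error cannot be negative")


@dataclass(frozen=True)
class LongBoneRecord:
    """Length/circumference pair for one long bone at one ontogenetic stage."""

    stage_id: str
    bone: str
    length: float
    circumference: float

    def __post_init__(self) -> None:
        if self.bone not in LONG_BONES:
            raise ValidationError(f"unknown bone {self.bone!r}")
        if self.length <= 0 or self.circumference <= 0:
            raise ValidationError("length and circumference must be > 0 mm")


class BilateralMean(NamedTuple):
    """Mean of left/right values; ``single_sided`` marks a one-sided mean."""

    value: float
    single_sided: bool


# ---------------------------------------------------------------------------
# Measurement table


@dataclass
class MeasurementTable:
    """Validated long-format table of :class:`LinearMeasurement` rows.

    Wraps a :class:`pandas.DataFrame` with columns
    ``specimen_id, litter_id, trait, bone_context, side, value`` (mm).
    """

    df: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_records(cls, records: Iterable[LinearMeasurement]) -> "MeasurementTable":
        rows = [
            {
                "specimen_id": m.specimen_id,
                "litter_id": m.litter_id,
                "trait": m.trait,
                "bone_context": m.bone_context,
                "side": m.side,
                "value": float(m.value),
            }
            for m in records
        ]
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS[:-1])
        return cls(df)

    def records(self) -> list[LinearMeasurement]:
        out = []
        for row in self.df.itertuples(index=False):
            ctx = row.bone_context
            if ctx is None or (isinstance(ctx, float) and math.isnan(ctx)) or ctx == "":
                ctx = None
            out.append(
                LinearMeasurement(
                    specimen_id=row.specimen_id,
                    litter_id=row.litter_id,
                    trait=row.trait,
                    side=row.side,
                    value=float(row.value),
                    bone_context=ctx,
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.df)

    def litters(self) -> list[str]:
        return sorted(self.df["litter_id"].unique())

    def values_for(
        self,
        trait: str,
        litter_id: Optional[str] = None,
        specimen_id: Optional[str] = None,
    ) -> np.ndarray:
        sel = self.df["trait"] == trait
        if litter_id is not None:
            sel &= self.df["litter_id"] == litter_id
        if specimen_id is not None:
            sel &= self.df["specimen_id"] == specimen_id
        return self.df.loc[sel, "value"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        write_measurements(self, path)


def read_measurements(path: str | Path, dialect: Optional[dict] = None) -> MeasurementTable:
    """Read a long-format measurement CSV and validate every row.

    The file must carry a header with columns ``specimen_id, litter_id,
    trait, bone_context, side, value`` and optionally ``unit`` (``mm`` or
    ``um``/``µm``; micrometre values are converted to mm).  Rows with
    nonpositive or non-numeric values raise :class:`ValidationError` naming
    the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **(dialect or {}))
    required = {"specimen_id", "litter_id", "trait", "side", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    if "bone_context" not in df.columns:
        df["bone_context"] = ""
    if "unit" not in df.columns:
        df["unit"] = "mm"

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        unit = row.unit or "mm"
        if unit not in UNITS:
            raise ValidationError(f"row {i}: unknown unit {unit!r}")
        try:
            value = float(row.value) * UNITS[unit]
        except ValueError:
            raise ValidationError(f"row {i}: non-numeric value {row.value!r}") from None
        try:
            records.append(
                LinearMeasurement(
                    specimen_id=row.specimen_id,
                    litter_id=row.litter_id,
                    trait=row.trait,
                    side=row.side or "midline",
                    value=value,
                    bone_context=row.bone_context or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return MeasurementTable.from_records(records)


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a measurement table as RFC-4180 CSV (values in mm)."""
    df = table.df.copy()
    df["bone_context"] = df["bone_context"].fillna("")
    df["unit"] = "mm"
    df.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Derived quantities


def litter_summary(table: MeasurementTable, trait: str) -> list[LitterSummary]:
    """Mean ± standard error of one trait per litter.

    Litters present in the table but lacking the trait are omitted with a
    warning.  Singleton litters get ``se = 0`` with ``singleton = True``.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}")
    summaries = []
    have = set()
    for litter_id in table.litters():
        values = table.values_for(trait, litter_id=litter_id)
        if values.size == 0:
            continue
        have.add(litter_id)
        n = int(values.size)
        mean = float(values.mean())
        if n == 1:
            summaries.append(
                LitterSummary(litter_id, trait, mean, 0.0, 1, singleton=True)
            )
        else:
            se = float(values.std(ddof=1) / math.sqrt(n))
            summaries.append(LitterSummary(litter_id, trait, mean, se, n))
    skipped = set(table.litters()) - have
    if skipped:
        warnings.warn(
            f"trait {trait!r} absent for litters {sorted(skipped)}; omitted",
            stacklevel=2,
        )
    return summaries


def midshaft_circumference(ap_width: float, ml_width: float) -> float:
    """Midshaft circumference from the two perpendicular midshaft widths.

    The shaft cross-section is treated as a circle whose diameter is the
    mean of the anterior–posterior and medial–lateral widths:
    ``pi * (ap + ml) / 2``.
    """
    if ap_width <= 0 or ml_width <= 0:
        raise DomainError("midshaft widths must be > 0 mm")
    return math.pi * (ap_width + ml_width) / 2.0


def bilateral_mean(
    left: Optional[float] = None, right: Optional[float] = None
) -> BilateralMean:
    """Mean of left and right measurements; one-sided values pass through.

    Returns the mean and a ``single_sided`` flag so consumers can note when
    a bone was measurable on one side only.
    """
    present = [v for v in (left, right) if v is not None]
    if not present:
        raise MissingDataError("both sides absent")
    for v in present:
        if v <= 0:
            raise ValidationError("bilateral measurements must be > 0 mm")
    return BilateralMean(float(np.mean(present)), single_sided=len(present) == 1)


def limb_lengths(table: MeasurementTable, specimen_id: str) -> dict[str, float]:
    """Total fore- and hindlimb lengths for one specimen.

    Forelimb = humerus + radius + third metacarpal; hindlimb = femur +
    tibia + third metatarsal.  Each segment is the bilateral mean of the
    available sides.  A missing segment raises :class:`MissingDataError`
    naming the segment.
    """

    def segment(trait: str) -> float:
        values = table.values_for(trait, specimen_id=specimen_id)
        if values.size == 0:
            raise MissingDataError(trait.replace("_length", ""))
        return float(values.mean())

    return {
        "forelimb": sum(segment(t) for t in FORELIMB_SEGMENTS),
        "hindlimb": sum(segment(t) for t in HINDLIMB_SEGMENTS),
    }


def trunk_length(table: MeasurementTable, specimen_id: str) -> float:
    """Trunk length (TL): thoracic vertebral sum + lumbar vertebral sum."""
    parts = []
    for trait in ("thoracic_sum", "lumbar_sum"):
        values = table.values_for(trait, specimen_id=specimen_id)
        if values.size == 0:
            raise MissingDataError(trait)
        parts.append(float(values.mean()))
    return sum(parts)
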