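"""Skeletal-count diagnosis: thylacine or other dasyurid?

The thylacine is separated from its dasyurid relatives (quolls, Tasmanian
devil) by three discrete postcranial characters:

==================  =================  ==================
character           thylacine          other dasyurids
==================  =================  ==================
sacral vertebrae    2                  3
caudal vertebrae    23–25              20–21
epipubic bones      absent (vestigial) present
==================  =================  ==================

``classify_specimen`` scores each *known* character against both columns
and returns a verdict only when every known character points the same
way; mixed or insufficient evidence is ``indeterminate`` with the
per-character evidence listed.  Unknown characters never count for or
against either taxon.  Neonatal sacral counts are unreliable (the sacrum
ossifies late and very young specimens can show an apparently contrary
count), so early-stage specimens should be scored ``None`` rather than
counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_data import ValidationError

__all__ = ["SkeletalCounts", "TaxonDiagnosis", "classify_specimen"]

THYLACINE_SACRAL = 2
THYLACINE_CAUDAL = (23, 25)
DASYURID_SACRAL = 3
DASYURID_CAUDAL = (20, 21)


@dataclass(frozen=True)
class SkeletalCounts:
    """Observed diagnostic counts for one specimen; ``None`` = unknown."""

    sacral_count: Optional[int] = None
    caudal_count: Optional[int] = None
    epipubic_present: str = "unknown"  # present | absent | unknown

    def __post_init__(self) -> None:
        for name, v in (("sacral_count", self.sacral_count), ("caudal_count", self.caudal_count)):
            if v is not None and (not isinstance(v, int) or v < 0):
                raise ValidationError(f"{name} must be a non-negative integer or None")
        if self.epipubic_present not in {"present", "absent", "unknown"}:
            raise ValidationError(
                f"epipubic_present must be present/absent/unknown, "
                f"got {self.epipubic_present!r}"
            )


@dataclass(frozen=True)
class TaxonDiagnosis:
    """Verdict with the per-character evidence that produced it."""

    verdict: str  # consistent_thylacine | other_dasyurid | indeterminate
    evidence: tuple[str, ...]


def _score(counts: SkeletalCounts) -> tuple[list[str], list[str], list[str]]:
    """Sort known characters into thylacine-like, dasyurid-like, neither."""
    thyl, dasy, neither = [], [], []

    if counts.sacral_count is not None:
        s = counts.sacral_count
        msg = f"sacral_count={s}"
        if s == THYLACINE_SACRAL:
            thyl.append(f"{msg} matches thylacine ({THYLACINE_SACRAL})")
        elif s == DASYURID_SACRAL:
            dasy.append(f"{msg} matches other dasyurids ({DASYURID_SACRAL})")
        else:
            neither.append(f"{msg} matches neither taxon")

    if counts.caudal_count is not None:
        c = counts.caudal_count
        msg = f"caudal_count={c}"
        if THYLACINE_CAUDAL[0] <= c <= THYLACINE_CAUDAL[1]:
            thyl.append(f"{msg} in thylacine range {THYLACINE_CAUDAL}")
        elif DASYURID_CAUDAL[0] <= c <= DASYURID_CAUDAL[1]:
            dasy.append(f"{msg} in other-dasyurid range {DASYURID_CAUDAL}")
        else:
            neither.append(f"{msg} outside both ranges")

    if counts.epipubic_present == "absent":
        thyl.append("epipubic bones absent (vestigial in thylacine)")
    elif counts.epipubic_present == "present":
        dasy.append("ossified epipubic bones present (other dasyurids)")

    return thyl, dasy, neither


def classify_specimen(counts: SkeletalCounts) -> TaxonDiagnosis:
    """Diagnose a specimen from its sacral/caudal counts and epipubic state.

    Pure function: the same counts always yield the same verdict.  All
    known characters on one side give that verdict; any conflict (characters
    on both sides, or a count matching neither taxon) or no known character
    at all gives ``indeterminate``.
    """
    thyl, dasy, neither = _score(counts)
    evidence = tuple(thyl + dasy + neither)
    if not evidence:
        return TaxonDiagnosis("indeterminate", ("no diagnostic character known",))
    if neither or (thyl and dasy):
        return TaxonDiagnosis("indeterminate", evidence)
    return TaxonDiagnosis("consistent_thylacine" if thyl else "other_dasyurid", evidence)
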