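"""Body proportions, limb heterochrony and reduced-major-axis allometry.

Three analyses of how pouch-young proportions change with growth:

* **%TL proportion series** — each skeletal component (skull, scapula,
  pelvis, fore-/hindlimb, limb segments) expressed as a percentage of
  trunk length at each developmental stage.
* **Heterochrony crossover** — the age at which the hindlimb series
  overtakes the forelimb series, solved by piecewise-linear interpolation
  between stages.
* **RMA allometry** — reduced major axis regression of ln(long-bone
  length) on ln(midshaft circumference).  RMA is the appropriate
  symmetric line fit when both variables carry measurement error; its
  slope is sign(r)·sd(y)/sd(x).  Confidence intervals come from a
  case-resampling bootstrap (default 10 000 resamples, percentile CI),
  and slopes are classified as positive allometry (slope and CI > 1:
  the bone elongates faster than it thickens), negative (< 1: grows more
  robust) or isometry (CI spans 1).

A packaged table of published RMA slopes for other marsupials and
placentals (possum, wallaby, opossum, coyote, tiger, black bear,
wildebeest, bison, elephant) supports cross-taxon comparison tables;
those literature rows keep their published allometry labels verbatim,
since some were computed from midshaft width rather than circumference
and lack CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import DomainError, ValidationError

__all__ = [
    "ProportionPoint",
    "RMAResult",
    "ComparisonRow",
    "Crossover",
    "percent_trunk_length",
    "crossover_time",
    "rma_fit",
    "rma_bootstrap",
    "classify_allometry",
    "build_comparison_table",
    "render_comparison_text",
    "literature_rows",
    "LITERATURE_ALLOMETRY",
]

PROPORTION_COMPONENTS = frozenset(
    {
        "skull",
        "scapula",
        "pelvis",
        "forelimb",
        "hindlimb",
        "stylopod_fore",
        "zeugopod_fore",
        "autopod_fore",
        "stylopod_hind",
        "zeugopod_hind",
        "autopod_hind",
    }
)


@dataclass(frozen=True)
class ProportionPoint:
    """One skeletal component's size at one stage, as a percentage of TL."""

    stage_age: float  # weeks
    component: str
    percent_tl: float

    def __post_init__(self) -> None:
        if self.component not in PROPORTION_COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if self.percent_tl <= 0:
            raise ValidationError("percent_tl must be > 0")


@dataclass(frozen=True)
class RMAResult:
    """Reduced-major-axis fit of ln(length) on ln(circumference).

    ``ci_source`` records whether the CI came from a bootstrap or is
    absent (point estimates quoted from the literature); classification
    is CI-based whenever a CI exists, slope-only otherwise.
    """

    bone: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_boot: int = 0
    ci_level: float = 0.95
    seed: Optional[int] = None
    allometry_class: str = ""
    ci_source: str = "absent"  # bootstrap | absent
    n_degenerate_redraws: int = 0

    def __post_init__(self) -> None:
        if self.ci_source == "bootstrap":
            if self.ci_low is None or self.ci_high is None:
                raise ValidationError("bootstrap result requires CI limits")
            if not (self.ci_low - 1e-9 <= self.slope <= self.ci_high + 1e-9):
                raise ValidationError(
                    f"slope {self.slope} outside its CI "
                    f"({self.ci_low}, {self.ci_high})"
                )


class Crossover(NamedTuple):
    """Crossing age of two proportion series; ``tangent`` marks a touch."""

    age: float
    tangent: bool


# ---------------------------------------------------------------------------
# Proportions and heterochrony


def percent_trunk_length(component_length: float, trunk_length: float) -> float:
    """Component length as a percentage of trunk length (%TL)."""
    if trunk_length <= 0:
        raise DomainError("trunk length must be > 0 mm")
    return 100.0 * component_length / trunk_length


def crossover_time(
    series_a: Sequence[ProportionPoint], series_b: Sequence[ProportionPoint]
) -> Optional[Crossover]:
    """Earliest age at which two %TL series cross, or None.

    Both series must be sampled at the same stage ages.  Between stages the
    series are interpolated linearly, so a sign change of their difference
    over an interval gives an exact crossing age.  If the difference
    reaches zero but does not change sign (the series touch and retreat)
    the touch age is returned flagged ``tangent``.
    """
    a = sorted(series_a, key=lambda p: p.stage_age)
    b = sorted(series_b, key=lambda p: p.stage_age)
    ages_a = [p.stage_age for p in a]
    ages_b = [p.stage_age for p in b]
    if ages_a != ages_b:
        raise ValidationError("series are sampled on different stage grids")
    if len(a) < 2:
        raise ValidationError("need at least 2 stages to interpolate")

    ages = np.asarray(ages_a, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValidationError("stage ages must be strictly increasing")
    diff = np.asarray([pa.percent_tl - pb.percent_tl for pa, pb in zip(a, b)])

    signs = np.sign(diff)
    nonzero = np.flatnonzero(signs)
    if nonzero.size == 0:
        return None  # identical series
    # earliest sign change between consecutive nonzero stages is the crossing
    prev = int(nonzero[0])
    for k in map(int, nonzero[1:]):
        if signs[k] != signs[prev]:
            if k == prev + 1:  # strict crossing inside one interval
                d0, d1 = diff[prev], diff[k]
                t = float(ages[prev] + (ages[k] - ages[prev]) * d0 / (d0 - d1))
            else:  # difference sat at zero through intermediate stages
                t = float(ages[prev + 1])
            return Crossover(t, tangent=False)
        prev = k
    # no sign change anywhere: a zero stage means the series touched
    zeros = np.flatnonzero(signs == 0)
    if zeros.size:
        return Crossover(float(ages[zeros[0]]), tangent=True)
    return None


# ---------------------------------------------------------------------------
# Reduced major axis regression


def _rma_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # ptp, not std: the mean of n identical floats can be off by an ulp,
    # leaving a spurious std of ~1e-16 on constant data
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in x or y; RMA undefined")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        raise DomainError("r = 0; RMA slope sign undefined")
    slope = math.copysign(sy / sx, r)
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept, r


def rma_fit(
    x: Sequence[float], y: Sequence[float], bone: str = "humerus"
) -> RMAResult:
    """Reduced-major-axis point estimate (no CI).

    ``x`` and ``y`` are natural-log measurements.  The slope is
    sign(r)·sd(y)/sd(x) with the intercept through the means; r² is the
    squared Pearson correlation.  Requires n >= 3 and spread in both axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("RMA needs at least 3 points")
    slope, intercept, r = _rma_slope_intercept(x, y)
    return RMAResult(
        bone=bone,
        slope=slope,
        intercept=intercept,
        r_squared=r * r,
        n=int(x.size),
        ci_source="absent",
    )


def _bootstrap_slopes(
    x: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Case-resampling bootstrap slopes; degenerate resamples are redrawn."""
    n = x.size
    slopes = np.empty(n_boot)
    filled = 0
    redraws = 0
    while filled < n_boot:
        draw = n_boot - filled
        idx = rng.integers(0, n, size=(draw, n))
        bx = x[idx]
        by = y[idx]
        sx = bx.std(axis=1, ddof=1)
        sy = by.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cx = bx - bx.mean(axis=1, keepdims=True)
            cy = by - by.mean(axis=1, keepdims=True)
            cov = (cx * cy).sum(axis=1)
            # ptp guards resamples of a single repeated point (see rma_fit)
            ok = (np.ptp(bx, axis=1) > 0) & (np.ptp(by, axis=1) > 0) & (cov != 0)
            s = np.where(cov >= 0, 1.0, -1.0) * sy / sx
        k = int(ok.sum())
        slopes[filled : filled + k] = s[ok]
        filled += k
        redraws += draw - k
    return slopes, redraws


def rma_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
    bone: str = "humerus",
    ci_method: str = "percentile",
) -> RMAResult:
    """RMA fit with a case-resampling bootstrap confidence interval.

    Specimens (x, y pairs) are resampled with replacement ``n_boot`` times
    and the RMA slope recomputed on each resample.  The CI is the
    percentile interval at ``ci_level`` by default; ``ci_method="bca"``
    applies the bias-corrected (BC) percentile adjustment instead.
    Resamples with zero variance on either axis cannot yield a slope and
    are redrawn; the number of redraws is reported on the result.
    Deterministic for a fixed ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("RMA bootstrap needs at least 3 points")
    if not (0.0 < ci_level < 1.0):
        raise ValidationError("ci_level must lie in (0, 1)")
    if ci_method not in {"percentile", "bca"}:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    point = rma_fit(x, y, bone=bone)

    if np.allclose(y, point.intercept + point.slope * x):
        # exactly collinear: every non-degenerate resample reproduces the slope
        slopes = np.full(n_boot, point.slope)
        redraws = 0
    else:
        rng = np.random.default_rng(seed)
        slopes, redraws = _bootstrap_slopes(x, y, n_boot, rng)

    alpha = 1.0 - ci_level
    if ci_method == "percentile" or np.ptp(slopes) == 0:
        lo, hi = np.quantile(slopes, [alpha / 2, 1 - alpha / 2])
    else:  # bias-corrected percentile
        from scipy import stats as _st

        prop = np.clip(np.mean(slopes < point.slope), 1e-12, 1 - 1e-12)
        z0 = _st.norm.ppf(prop)
        zlo, zhi = _st.norm.ppf([alpha / 2, 1 - alpha / 2])
        plo, phi = _st.norm.cdf([2 * z0 + zlo, 2 * z0 + zhi])
        lo, hi = np.quantile(slopes, [plo, phi])

    # the percentile interval always brackets the point estimate in practice;
    # guard tiny quantile-interpolation excursions on near-degenerate data
    lo = min(float(lo), point.slope)
    hi = max(float(hi), point.slope)
    result = replace(
        point,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        ci_level=ci_level,
        seed=seed,
        ci_source="bootstrap",
        n_degenerate_redraws=redraws,
    )
    return replace(result, allometry_class=classify_allometry(result))


def classify_allometry(result: RMAResult) -> str:
    """Classify an RMA slope as positive / negative allometry or isometry.

    With a CI: entirely above 1 is positive, entirely below 1 negative,
    spanning 1 isometry.  Without a CI (literature point estimates) the
    slope alone decides, and the result's ``ci_source = "absent"`` flags
    the weaker provenance.
    """
    if result.ci_source == "bootstrap":
        if result.ci_low > 1.0 and result.slope > 1.0:
            return "positive"
        if result.ci_high < 1.0 and result.slope < 1.0:
            return "negative"
        return "isometry"
    if result.slope > 1.0:
        return "positive"
    if result.slope < 1.0:
        return "negative"
    return "isometry"


# ---------------------------------------------------------------------------
# Cross-taxon comparison table


@dataclass(frozen=True)
class ComparisonRow:
    """One taxon × bone row of a cross-taxon allometry table."""

    taxon: str
    group: str  # e.g. "marsupial", "placental: Carnivora"
    bone: str
    n: Optional[int]
    intercept: Optional[float]
    slope: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    r_squared: Optional[float]
    allometry_class: str
    reference: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("taxon must be non-empty")


# Published RMA slopes for other taxa (length vs midshaft circumference,
# except rows noted "midshaft width").  Allometry labels are stored as
# published, not recomputed: several rows lack CIs and two published
# slope-only labels are mutually inconsistent, so recomputation cannot
# reproduce them all.
_LIT = [
    # taxon, group, bone, n, intercept, slope, ci_low, ci_high, r2, class, ref, note
    ("Trichosurus vulpecula", "marsupial", "humerus", 51, None, 0.887, None, None, 0.950, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Trichosurus vulpecula", "marsupial", "radius", 51, None, 0.780, None, None, 0.931, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Trichosurus vulpecula", "marsupial", "femur", 51, None, 0.922, None, None, 0.867, "positive", "Schmidt & Fischer 2009", "midshaft width"),
    ("Trichosurus vulpecula", "marsupial", "tibia", 51, None, 0.876, None, None, 0.944, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Macropus eugenii", "marsupial", "humerus", 25, None, 0.917, None, None, 0.957, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Macropus eugenii", "marsupial", "radius", 24, None, 0.620, None, None, 0.945, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Macropus eugenii", "marsupial", "femur", 25, None, 0.854, None, None, 0.965, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Macropus eugenii", "marsupial", "tibia", 22, None, 0.402, None, None, 0.716, "negative", "Schmidt & Fischer 2009", "midshaft width"),
    ("Monodelphis domestica", "marsupial", "humerus", None, None, 0.710, None, None, None, "negative", "Lammers & German 2002", "midshaft width"),
    ("Monodelphis domestica", "marsupial", "radius", None, None, 0.850, None, None, None, "isometry", "Lammers & German 2002", "midshaft width"),
    ("Monodelphis domestica", "marsupial", "femur", None, None, 0.890, None, None, None, "isometry", "Lammers & German 2002", "midshaft width"),
    ("Monodelphis domestica", "marsupial", "tibia", None, None, 0.890, None, None, None, "isometry", "Lammers & German 2002", "midshaft width"),
    ("Canis latrans", "placental: Carnivora", "humerus", 13, -1.183, 1.720, 1.601, 1.884, 0.974, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Canis latrans", "placental: Carnivora", "femur", 13, -0.788, 1.640, 1.457, 2.087, 0.949, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Canis latrans", "placental: Carnivora", "tibia", 9, -1.883, 1.980, 0.567, 2.263, 0.905, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Panthera tigris", "placental: Carnivora", "humerus", 13, -0.517, 1.360, 1.283, 1.473, 0.983, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Panthera tigris", "placental: Carnivora", "radius", 12, -0.002, 1.330, 1.245, 1.440, 0.986, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Panthera tigris", "placental: Carnivora", "femur", 15, -0.721, 1.460, 1.389, 1.581, 0.985, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Panthera tigris", "placental: Carnivora", "tibia", 12, -0.736, 1.450, 1.319, 1.651, 0.980, "positive", "Kilbourne & Makovicky 2012", ""),
    ("Ursus americanus", "placental: Carnivora", "humerus", 19, 0.095, 1.240, 0.974, 1.347, 0.966, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Ursus americanus", "placental: Carnivora", "radius", 16, 1.372, 1.370, 0.843, 1.161, 0.939, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Ursus americanus", "placental: Carnivora", "femur", 19, 0.266, 1.270, 0.965, 1.395, 0.959, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Ursus americanus", "placental: Carnivora", "tibia", 16, 1.091, 1.040, 0.863, 1.138, 0.950, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Connochaetes taurinus", "placental: Cetartiodactyla", "humerus", 15, 1.714, 0.800, 0.738, 0.875, 0.976, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Connochaetes taurinus", "placental: Cetartiodactyla", "radius", 13, 1.844, 0.860, 0.805, 0.924, 0.988, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Connochaetes taurinus", "placental: Cetartiodactyla", "femur", 15, 1.261, 0.960, 0.920, 1.017, 0.989, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Connochaetes taurinus", "placental: Cetartiodactyla", "tibia", 15, 1.851, 0.880, 0.8268, 0.9357, 0.989, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Bison bison", "placental: Cetartiodactyla", "humerus", 16, 1.785, 0.790, 0.707, 0.908, 0.958, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Bison bison", "placental: Cetartiodactyla", "radius", 12, 1.560, 0.870, 0.805, 0.995, 0.971, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Bison bison", "placental: Cetartiodactyla", "femur", 16, 1.427, 0.920, 0.8634, 0.9969, 0.975, "negative", "Kilbourne & Makovicky 2012", ""),
    ("Bison bison", "placental: Cetartiodactyla", "tibia", 17, 2.232, 0.750, 0.6370, 0.8947, 0.932, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Loxodonta africana", "placental: Proboscidea", "humerus", 11, 1.632, 0.900, 0.618, 1.038, 0.946, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Loxodonta africana", "placental: Proboscidea", "radius", 7, 1.849, 0.860, 0.632, 0.946, 0.984, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Loxodonta africana", "placental: Proboscidea", "femur", 11, 1.565, 0.950, 0.700, 1.069, 0.972, "isometry", "Kilbourne & Makovicky 2012", ""),
    ("Loxodonta africana", "placental: Proboscidea", "tibia", 10, 1.201, 0.970, 0.597, 1.096, 0.940, "isometry", "Kilbourne & Makovicky 2012", ""),
]

LITERATURE_ALLOMETRY: tuple[ComparisonRow, ...] = tuple(
    ComparisonRow(*row) for row in _LIT
)

#: Published thylacine RMA rows (ln length vs ln circumference, n = 13
#: ontogenetic stages from neonate to adult, 10 000 bootstraps).
THYLACINE_PUBLISHED: tuple[ComparisonRow, ...] = tuple(
    ComparisonRow("Thylacinus cynocephalus", "marsupial", bone, 13, yint, slope, lo, hi, r2, cls, "this study", "")
    for bone, yint, slope, lo, hi, r2, cls in [
        ("humerus", 0.648, 1.198, 1.154, 1.242, 0.997, "positive"),
        ("radius", 0.757, 1.403, 1.321, 1.486, 0.992, "positive"),
        ("femur", 0.660, 1.241, 1.179, 1.303, 0.994, "positive"),
        ("tibia", 0.690, 1.277, 1.211, 1.344, 0.994, "positive"),
    ]
)


def literature_rows(bone: Optional[str] = None) -> list[ComparisonRow]:
    """Packaged published comparison rows, optionally for one bone."""
    rows = list(LITERATURE_ALLOMETRY)
    if bone is not None:
        rows = [r for r in rows if r.bone == bone]
    return rows


def _own_row(result: RMAResult, taxon: str, group: str) -> ComparisonRow:
    cls = result.allometry_class or classify_allometry(result)
    return ComparisonRow(
        taxon=taxon,
        group=group,
        bone=result.bone,
        n=result.n,
        intercept=result.intercept,
        slope=result.slope,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        r_squared=result.r_squared,
        allometry_class=cls,
        reference="this study",
        note="" if result.ci_source == "bootstrap" else "slope_only",
    )


def build_comparison_table(
    own_results: Sequence[RMAResult],
    literature: Sequence[ComparisonRow] = (),
    taxon: str = "Thylacinus cynocephalus",
    group: str = "marsupial",
) -> pd.DataFrame:
    """Merge this study's RMA results with published rows into one table.

    Rows are sorted by group, then taxon, then bone; duplicate
    (taxon, bone) combinations are a collision error.  Renders to CSV via
    pandas and to aligned text via :func:`render_comparison_text`.
    """
    rows = [_own_row(r, taxon, group) for r in own_results] + list(literature)
    seen = set()
    for row in rows:
        key = (row.taxon, row.bone)
        if key in seen:
            raise ValidationError(f"duplicate comparison row for {key}")
        seen.add(key)
    df = pd.DataFrame(
        [
            {
                "group": r.group,
                "taxon": r.taxon,
                "bone": r.bone,
                "n": r.n,
                "intercept": r.intercept,
                "slope": r.slope,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "r_squared": r.r_squared,
                "allometry": r.allometry_class,
                "reference": r.reference,
                "note": r.note,
            }
            for r in rows
        ]
    )
    return df.sort_values(["group", "taxon", "bone"], kind="stable").reset_index(
        drop=True
    )


def render_comparison_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a comparison table."""

    def fmt(v, spec=".3f"):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "nd"
        if isinstance(v, float):
            return format(v, spec)
        return str(v)

    header = f"{'taxon':<28}{'bone':<10}{'n':>4}  {'Y-int':>7}  {'slope':>6}  {'95% CI':>16}  {'R2':>6}  allometry"
    lines = [header, "-" * len(header)]
    for row in table.itertuples(index=False):
        n = "nd" if row.n is None or (isinstance(row.n, float) and math.isnan(row.n)) else int(row.n)
        ci = (
            "nd"
            if row.ci_low is None or (isinstance(row.ci_low, float) and math.isnan(row.ci_low))
            else f"{row.ci_low:.3f}, {row.ci_high:.3f}"
        )
        lines.append(
            f"{row.taxon:<28}{row.bone:<10}{n:>4}  {fmt(row.intercept, '7.3f'):>7}  "
            f"{fmt(row.slope, '.3f'):>6}  {ci:>16}  {fmt(row.r_squared, '.3f'):>6}  {row.allometry}"
        )
    return "\n".join(lines)
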