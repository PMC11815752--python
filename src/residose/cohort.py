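"""Animal-cohort analytics.

Engraftment ("rooting") percentages per group and observation day, humane
endpoint detection (tumor volume and relative weight-loss cutoffs),
two-sample t comparisons of tumor growth, one-way-ANOVA power / sample
size via the noncentral F distribution, liver histology grade
distributions, and immunohistochemistry (IHC) field-count summaries.

Percentages are rounded half-up to one decimal only for display; counts
and means stay exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up

__all__ = [
    "CohortRecord",
    "EndpointFlags",
    "PowerSpec",
    "PowerResult",
    "TTestResult",
    "GradeDistribution",
    "IhcSummary",
    "load_cohort_table",
    "load_ihc_table",
    "rooting_percentages",
    "humane_endpoint_flags",
    "two_sample_t",
    "anova_power",
    "anova_power_n",
    "grade_distribution",
    "ihc_summary",
    "caliper_volume",
]

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
GROUPS = ("control", "sulfonamides", "chlortetracycline")


@dataclass
class CohortRecord:
    """One animal's time series: weights (g), tumor volumes (mm³) and
    engraftment status by observation day."""

    animal_id: str
    sex: str
    group: str
    weights: dict[int, float] = field(default_factory=dict)
    tumor_volumes: dict[int, float] = field(default_factory=dict)
    engrafted_by_day: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = dict(sorted(self.weights.items()))
        self.tumor_volumes = dict(sorted(self.tumor_volumes.items()))
        self.engrafted_by_day = dict(sorted(self.engrafted_by_day.items()))
        if any(v < 0 for v in self.tumor_volumes.values()):
            raise ValueError(f"{self.animal_id}: negative tumor volume")

    def engrafted_at(self, day: int) -> bool:
        """Status at ``day``: the most recent observation at or before it.

        Engraftment is monotone — once engrafted, always engrafted — so
        carrying the last observation forward is exact between visits.
        """
        status = None
        for d, flag in self.engrafted_by_day.items():
            if d > day:
                break
            status = flag
        if status is None:
            raise ValueError(
                f"{self.animal_id}: no engraftment observation at or before day {day}"
            )
        return status


@dataclass(frozen=True)
class EndpointFlags:
    """First day each humane-endpoint criterion is met (None if never)."""

    volume_day: int | None
    weight_day: int | None


@dataclass(frozen=True)
class PowerSpec:
    """One-way ANOVA power-analysis settings (fixed effects, omnibus)."""

    alpha: float = 0.05
    power: float = 0.8
    effect_f: float = 0.40
    k_groups: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.k_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.effect_f <= 0:
            raise ValueError("effect size f must be > 0")


@dataclass(frozen=True)
class PowerResult:
    n_per_group: int
    total_n: int
    achieved_power: float


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    variant: str


@dataclass(frozen=True)
class GradeDistribution:
    """Histology grade counts (grades 0-3) with display percentages."""

    counts: dict[int, int]
    percentages: dict[int, float]  # half-up, 1 decimal
    n: int


@dataclass(frozen=True)
class IhcSummary:
    """Per-animal mean field counts and per (group, marker) min/max."""

    animal_means: pd.DataFrame   # animal_id, group, marker, mean_count, n_fields
    group_ranges: pd.DataFrame   # group, marker, n, min_mean, max_mean


def rooting_percentages(
    cohort: Iterable[CohortRecord],
    days: Sequence[int],
    by: str = "group",
) -> pd.DataFrame:
    """Engraftment percentage per (group, day).

    ``by`` may be ``"group"`` or ``"group_sex"`` (Tables of rooting are
    typically reported per sex).  Percentages are half-up to 1 decimal.
    """
    records = list(cohort)
    if not records:
        raise ValueError("empty cohort")
    rows = []
    keys = sorted({(r.group, r.sex) if by == "group_sex" else (r.group,) for r in records})
    for key in keys:
        members = [
            r for r in records
            if (r.group, r.sex)[: len(key)] == key
        ]
        if not members:
            raise ValueError(f"empty group {key}")
        for day in days:
            n = len(members)
            count = sum(r.engrafted_at(day) for r in members)
            row = {"group": key[0], "day": day, "engrafted": count, "n": n,
                   "percentage": round_half_up(100.0 * count / n, 1)}
            if by == "group_sex":
                row["sex"] = key[1]
            rows.append(row)
    return pd.DataFrame(rows)


def humane_endpoint_flags(
    record: CohortRecord,
    volume_cutoff: float = 1500.0,
    weight_drop: float = 0.20,
) -> EndpointFlags:
    """First day tumor volume reaches ``volume_cutoff`` (mm³) and first day
    weight falls to or below (1 - ``weight_drop``) of the baseline (first
    recorded) weight."""
    if not record.weights:
        raise ValueError(f"{record.animal_id}: empty weight series")
    volume_day = next(
        (d for d, v in record.tumor_volumes.items() if v >= volume_cutoff), None
    )
    baseline = next(iter(record.weights.values()))
    weight_day = next(
        (d for d, w in record.weights.items() if w <= (1.0 - weight_drop) * baseline),
        None,
    )
    return EndpointFlags(volume_day=volume_day, weight_day=weight_day)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> TTestResult:
    """Two-sided two-sample t-test.

    ``variant="pooled"`` is the classic Student's test (equal variances);
    ``"welch"`` drops that assumption.  Degenerate input with zero variance
    in both samples and equal means returns (0, 1) by convention.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        logger.info("two_sample_t: degenerate zero-variance equal-mean input, p=1")
        return TTestResult(statistic=0.0, p_value=1.0, variant=variant)
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(statistic=float(res.statistic), p_value=float(res.pvalue), variant=variant)


def anova_power(effect_f: float, k_groups: int, n_per_group: int, alpha: float) -> float:
    """Power of a balanced one-way fixed-effects ANOVA.

    Noncentral-F formulation: with N = k*n, noncentrality λ = f²·N, the
    power is P(F' > F_crit) with df (k-1, N-k).
    """
    n_total = k_groups * n_per_group
    df1 = k_groups - 1
    df2 = n_total - k_groups
    if df2 < 1:
        return 0.0
    lam = effect_f**2 * n_total
    fcrit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def anova_power_n(spec: PowerSpec, n_cap: int = 10_000) -> PowerResult:
    """Smallest balanced per-group n reaching the requested power.

    Searches n upward from the smallest n with positive error df; raises
    if the effect is so small that n would exceed ``n_cap``.
    """
    n = max(2, math.ceil((spec.k_groups + 1) / spec.k_groups))
    while n <= n_cap:
        pw = anova_power(spec.effect_f, spec.k_groups, n, spec.alpha)
        if pw >= spec.power:
            return PowerResult(
                n_per_group=n, total_n=n * spec.k_groups, achieved_power=pw
            )
        n += 1
    raise ValueError(f"required n per group exceeds cap {n_cap}")


def grade_distribution(counts: Mapping[int, int]) -> GradeDistribution:
    """Percentage distribution over histology grades 0-3.

    Grades are opaque ordinal labels; missing grades count zero.
    """
    full = {g: int(counts.get(g, 0)) for g in range(4)}
    if any(v < 0 for v in full.values()):
        raise ValueError("grade counts must be >= 0")
    n = sum(full.values())
    if n == 0:
        raise ValueError("zero total count")
    pct = {g: round_half_up(100.0 * c / n, 1) for g, c in full.items()}
    return GradeDistribution(counts=full, percentages=pct, n=n)


def ihc_summary(
    field_counts: Mapping[str, Sequence[float]] | pd.DataFrame,
    groups: Mapping[str, tuple[str, str]] | None = None,
) -> IhcSummary:
    """Summarise IHC positive-cell field counts.

    Accepts either a long DataFrame with columns ``animal_id, group,
    marker, count`` (one row per field) or a mapping animal_id -> list of
    per-field counts together with ``groups`` mapping animal_id ->
    (group, marker).  Each animal's fields are averaged (counts per
    0.7 mm² field); per (group, marker) the minimum and maximum of the
    per-animal means are reported.
    """
    if isinstance(field_counts, pd.DataFrame):
        df = field_counts
    else:
        if groups is None:
            raise ValueError("groups mapping required with dict input")
        rows = []
        for animal, counts in field_counts.items():
            if len(counts) == 0:
                raise ValueError(f"{animal}: no field counts")
            grp, marker = groups[animal]
            rows.extend(
                {"animal_id": animal, "group": grp, "marker": marker, "count": c}
                for c in counts
            )
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("empty IHC table")

    means = (
        df.groupby(["animal_id", "group", "marker"], sort=True)["count"]
        .agg(mean_count="mean", n_fields="size")
        .reset_index()
    )
    ranges = (
        means.groupby(["group", "marker"], sort=True)
        .agg(
            n=("animal_id", "size"),
            min_mean=("mean_count", "min"),
            max_mean=("mean_count", "max"),
        )
        .reset_index()
    )
    return IhcSummary(animal_means=means, group_ranges=ranges)


def caliper_volume(length: float, width: float) -> float:
    """Ellipsoid approximation of tumor volume from caliper axes:
    length x width² / 2 (a convention, not tied to any single study)."""
    if length < 0 or width < 0:
        raise ValueError("caliper axes must be >= 0")
    return length * width * width / 2.0


def load_cohort_table(path: str | PathLike) -> list[CohortRecord]:
    """Read a long-format cohort file.

    Columns: ``animal_id, sex, group, day, weight_g, tumor_volume_mm3,
    engrafted`` (tab/comma autodetected; engrafted 0/1 or true/false).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    records: dict[str, CohortRecord] = {}
    for _, r in df.iterrows():
        aid = str(r["animal_id"])
        rec = records.get(aid)
        if rec is None:
            rec = CohortRecord(animal_id=aid, sex=str(r["sex"]), group=str(r["group"]))
            records[aid] = rec
        day = int(r["day"])
        if not pd.isna(r.get("weight_g")):
            rec.weights[day] = float(r["weight_g"])
        if not pd.isna(r.get("tumor_volume_mm3")):
            rec.tumor_volumes[day] = float(r["tumor_volume_mm3"])
        if not pd.isna(r.get("engrafted")):
            rec.engrafted_by_day[day] = str(r["engrafted"]).strip().lower() in ("1", "true", "yes")
    out = []
    for rec in records.values():
        rec.__post_init__()  # re-sort after incremental fill
        out.append(rec)
    return out


def load_ihc_table(path: str | PathLike) -> pd.DataFrame:
    """Read an IHC field-count file: ``animal_id, group, marker,
    field_index, count``."""
    df = pd.read_csv(path, sep=None, engine="python")
    needed = {"animal_id", "group", "marker", "count"}
    if missing := needed - set(df.columns):
        raise ValueError(f"missing IHC columns: {sorted(missing)}")
    return df
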