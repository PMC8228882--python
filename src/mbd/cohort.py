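"""Cohort-level analyses of per-subject density records.

Given one record per subject (age, BI-RADS density category, overall PD,
the three zonal PDs, Moran's I and its pattern label), this module runs
the study-level comparisons: Pearson correlation of overall PD with age,
chi-square tests of the spatial-pattern distribution across groups,
Kruskal-Wallis comparisons of zonal PD across BI-RADS groups, a
within-subject (Friedman) comparison of the three zones with pairwise
follow-ups, Mann-Whitney comparisons between the mature (<65) and older
(>=65) age groups, and per-group mean regional-PD heatmaps.

All tests are two-sided; the working significance level throughout is
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regional import ZONES, ZonalPD

__all__ = [
    "SubjectRecord",
    "CohortError",
    "AGE_CUTOFF",
    "age_group",
    "density_group",
    "records_to_frame",
    "correlate_age_pd",
    "pattern_by_group_table",
    "compare_zonal_across_groups",
    "compare_zonal_within_subject",
    "compare_zonal_between_age_groups",
    "mean_regional_heatmap",
]

AGE_CUTOFF = 65.0  # mature: 35-64, older: 65-90
BIRADS = ("A", "B", "C", "D")
LESS_DENSE = frozenset({"A", "B"})

_ZONE_PAIRS = (("anterior", "posterior"), ("anterior", "middle"), ("posterior", "middle"))


class CohortError(ValueError):
    """Raised for degenerate cohort inputs (empty groups, constant data)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's measured density summary."""

    subject_id: str
    age: float
    birads: str
    overall_pd: float
    zonal_pd: ZonalPD
    moran_i: float
    pattern: str
    regional: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.birads not in BIRADS:
            raise CohortError(f"birads must be one of {BIRADS}, got {self.birads!r}")


def age_group(age: float) -> str:
    return "mature" if age < AGE_CUTOFF else "older"


def density_group(birads: str) -> str:
    return "less_dense" if birads in LESS_DENSE else "denser"


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame with derived group columns."""
    return pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "birads": [r.birads for r in records],
            "overall_pd": [r.overall_pd for r in records],
            "posterior_pd": [r.zonal_pd.posterior for r in records],
            "middle_pd": [r.zonal_pd.middle for r in records],
            "anterior_pd": [r.zonal_pd.anterior for r in records],
            "moran_i": [r.moran_i for r in records],
            "pattern": [r.pattern for r in records],
            "age_group": [age_group(r.age) for r in records],
            "density_group": [density_group(r.birads) for r in records],
        }
    )


def _group_column(df: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping not in ("birads", "density_group", "age_group"):
        raise ValueError("grouping must be 'birads', 'density_group' or 'age_group'")
    return df[grouping]


def correlate_age_pd(records: list[SubjectRecord]) -> tuple[float, float]:
    """Pearson correlation of overall PD with age; returns (r, two-sided p)."""
    if len(records) < 3:
        raise CohortError("need at least 3 subjects for a correlation")
    age = np.array([r.age for r in records])
    pd_ = np.array([r.overall_pd for r in records])
    if np.ptp(age) == 0 or np.ptp(pd_) == 0:
        raise CohortError("correlation undefined: a variable is constant")
    res = stats.pearsonr(age, pd_)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class PatternTable:
    """Pattern-by-group contingency table with its chi-square test."""

    counts: pd.DataFrame  # groups x patterns
    row_percent: pd.DataFrame
    chi2: float
    p: float
    dof: int


def pattern_by_group_table(
    records: list[SubjectRecord], grouping: str = "density_group"
) -> PatternTable:
    """Cross-tabulate spatial pattern by group and test independence.

    Emits a warning (not a failure) when any expected cell count is below
    5, where the chi-square approximation is shaky.
    """
    df = records_to_frame(records)
    table = pd.crosstab(_group_column(df, grouping), df["pattern"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise CohortError(
            "chi-square needs at least two groups and two pattern categories; "
            f"observed table is {table.shape[0]}x{table.shape[1]}"
        )
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy())
    if (expected < 5).any():
        warnings.warn("some expected counts are below 5; chi-square is approximate")
    row_pct = table.div(table.sum(axis=1), axis=0) * 100.0
    return PatternTable(
        counts=table, row_percent=row_pct, chi2=float(chi2), p=float(p), dof=int(dof)
    )


def compare_zonal_across_groups(
    records: list[SubjectRecord], zone: str, grouping: str = "birads"
) -> tuple[float, float]:
    """Kruskal-Wallis comparison of one zone's PD across groups; (H, p).

    Returns (0.0, 1.0) on the all-values-identical boundary case.
    """
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {ZONES}")
    df = records_to_frame(records)
    col = f"{zone}_pd"
    groups = [g[col].to_numpy() for _, g in df.groupby(_group_column(df, grouping))]
    if len(groups) < 2:
        raise CohortError("need at least two groups")
    # all observations identical: zero rank variance, no group effect
    if np.ptp(df[col].to_numpy()) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class WithinSubjectResult:
    """Friedman omnibus over the three zones plus pairwise follow-ups.

    Pairwise zone contrasts are Wilcoxon signed-rank tests reported both
    raw and Bonferroni-adjusted (times 3, capped at 1).
    """

    statistic: float
    p: float
    pairwise_raw: dict[tuple[str, str], float]
    pairwise_bonferroni: dict[tuple[str, str], float]


def compare_zonal_within_subject(records: list[SubjectRecord]) -> WithinSubjectResult:
    """Within-subject comparison of posterior/middle/anterior zonal PDs."""
    if len(records) < 3:
        raise CohortError("need at least 3 subjects")
    cols = {}
    for zone in ZONES:
        vals = np.array([r.zonal_pd[zone] for r in records], dtype=float)
        if np.isnan(vals).any():
            bad = [r.subject_id for r, v in zip(records, vals) if np.isnan(v)]
            raise CohortError(f"missing {zone} zonal PD for subjects: {bad}")
        cols[zone] = vals
    if all(np.array_equal(cols[z], cols[ZONES[0]]) for z in ZONES):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*(cols[z] for z in ZONES))
    raw: dict[tuple[str, str], float] = {}
    for za, zb in _ZONE_PAIRS:
        diff = cols[za] - cols[zb]
        if np.all(diff == 0):
            raw[(za, zb)] = 1.0
        else:
            raw[(za, zb)] = float(stats.wilcoxon(cols[za], cols[zb]).pvalue)
    bonf = {k: min(1.0, 3.0 * v) for k, v in raw.items()}
    return WithinSubjectResult(
        statistic=float(stat), p=float(p), pairwise_raw=raw, pairwise_bonferroni=bonf
    )


def compare_zonal_between_age_groups(
    records: list[SubjectRecord], zone: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of one zone's PD, mature vs older; (U, p).

    Uses the exact null distribution for small samples and the
    tie-corrected normal approximation otherwise (scipy's automatic
    method selection).
    """
    if zone not in ZONES:
        raise ValueError(f"zone must be one of {ZONES}")
    mature = [r.zonal_pd[zone] for r in records if age_group(r.age) == "mature"]
    older = [r.zonal_pd[zone] for r in records if age_group(r.age) == "older"]
    if not mature or not older:
        missing = "mature" if not mature else "older"
        raise CohortError(f"age group {missing!r} is empty")
    res = stats.mannwhitneyu(mature, older, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def mean_regional_heatmap(
    records: list[SubjectRecord], grouping: str = "age_group"
) -> dict[str, np.ndarray]:
    """Cell-wise mean of the per-subject regional PD matrices, per group."""
    df = records_to_frame(records)
    grids = [r.regional for r in records]
    if any(g is None for g in grids):
        raise CohortError("records lack regional PD matrices")
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise CohortError("inconsistent regional grid shapes")
    out: dict[str, np.ndarray] = {}
    labels = _group_column(df, grouping)
    for label in sorted(labels.unique()):
        sel = [g for g, lab in zip(grids, labels) if lab == label]
        out[str(label)] = np.mean(np.stack(sel), axis=0)
    return out
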