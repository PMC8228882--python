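"""Cohort-level statistics on subject records."""

import numpy as np
import pytest

from conftest import make_null_records
from mbd.cohort import (
    CohortError,
    SubjectRecord,
    age_group,
    compare_zonal_across_groups,
    compare_zonal_between_age_groups,
    compare_zonal_within_subject,
    correlate_age_pd,
    density_group,
    mean_regional_heatmap,
    pattern_by_group_table,
    records_to_frame,
)
from mbd.regional import ZonalPD


def record(i, age=50.0, birads="B", overall=20.0, zones=(10.0, 20.0, 5.0),
           pattern="clustered", regional=None):
    return SubjectRecord(
        subject_id=f"S{i:03d}", age=age, birads=birads, overall_pd=overall,
        zonal_pd=ZonalPD(*zones), moran_i=0.1 if pattern == "clustered" else -0.1,
        pattern=pattern, regional=regional,
    )


class TestGrouping:
    def test_age_cutoff(self):
        assert age_group(64.9) == "mature"
        assert age_group(65.0) == "older"

    def test_density_group_pools_ab_vs_cd(self):
        assert density_group("A") == density_group("B") == "less_dense"
        assert density_group("C") == density_group("D") == "denser"


class TestCorrelateAgePD:
    def test_perfect_anticorrelation(self):
        recs = [record(i, age=a, overall=100.0 - a) for i, a in enumerate((40, 50, 60, 70))]
        r, p = correlate_age_pd(recs)
        assert r == pytest.approx(-1.0)

    def test_constant_pd_rejected(self):
        recs = [record(i, age=40 + i, overall=10.0) for i in range(5)]
        with pytest.raises(CohortError, match="constant"):
            correlate_age_pd(recs)

    def test_null_is_rarely_significant(self):
        hits = 0
        for seed in range(100):
            recs = make_null_records(500, seed)
            _, p = correlate_age_pd(recs)
            hits += p <= 0.05
        assert hits <= 10  # about 5% under the null


class TestPatternByGroup:
    def test_single_pattern_category_refused(self):
        recs = [record(i, birads=b, pattern="clustered")
                for i, b in enumerate("AABBCCDD")]
        with pytest.raises(CohortError, match="two groups and two pattern"):
            pattern_by_group_table(recs, "birads")

    def test_perfect_independence_gives_zero_statistic(self):
        recs = []
        for i in range(40):
            recs.append(record(i, birads="A" if i < 20 else "C",
                               pattern="clustered" if i % 2 == 0 else "scattered"))
        t = pattern_by_group_table(recs, "density_group")
        assert t.chi2 == pytest.approx(0.0)
        assert t.p == pytest.approx(1.0)

    def test_row_percentages_sum_to_100(self):
        recs = make_null_records(200, 3)
        t = pattern_by_group_table(recs, "birads")
        assert np.allclose(t.row_percent.sum(axis=1), 100.0)

    def test_planted_group_contrast_is_detected(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(500):
            birads = rng.choice(list("ABCD"))
            share = 0.75 if birads in "AB" else 0.45
            pat = "clustered" if rng.random() < share else "scattered"
            recs.append(record(i, birads=birads, pattern=pat))
        t = pattern_by_group_table(recs, "density_group")
        assert t.p < 0.05


class TestKruskal:
    def test_identical_constant_groups_boundary(self):
        recs = [record(i, birads=b, zones=(5.0, 5.0, 5.0))
                for i, b in enumerate("AABB")]
        h, p = compare_zonal_across_groups(recs, "middle")
        assert h == 0.0 and p == 1.0

    def test_large_location_shift_detected(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(120):
            birads = "A" if i % 2 == 0 else "D"
            mid = rng.normal(10 if birads == "A" else 30, 3)
            recs.append(record(i, birads=birads, zones=(10.0, mid, 5.0)))
        _, p = compare_zonal_across_groups(recs, "middle")
        assert p < 0.05

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError):
            compare_zonal_across_groups([record(0), record(1)], "lateral")


class TestWithinSubject:
    def test_identical_zones_give_unit_p(self):
        recs = [record(i, zones=(7.0, 7.0, 7.0)) for i in range(10)]
        res = compare_zonal_within_subject(recs)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_planted_middle_excess_found_in_pairs(self):
        rng = np.random.default_rng(2)
        recs = [
            record(i, zones=(rng.normal(10, 2), rng.normal(25, 2), rng.normal(10, 2)))
            for i in range(60)
        ]
        res = compare_zonal_within_subject(recs)
        assert res.p < 0.05
        assert res.pairwise_bonferroni[("posterior", "middle")] < 0.05
        # bonferroni never smaller than raw
        for k in res.pairwise_raw:
            assert res.pairwise_bonferroni[k] >= res.pairwise_raw[k]

    def test_missing_zone_names_subjects(self):
        recs = [record(0), record(1, zones=(1.0, float("nan"), 2.0)), record(2)]
        with pytest.raises(CohortError, match="S001"):
            compare_zonal_within_subject(recs)


class TestMannWhitney:
    def test_identical_samples_not_significant(self):
        recs = [record(i, age=50, zones=(1, float(i % 5), 2)) for i in range(10)]
        recs += [record(10 + i, age=70, zones=(1, float(i % 5), 2)) for i in range(10)]
        _, p = compare_zonal_between_age_groups(recs, "middle")
        assert p > 0.9

    def test_empty_age_group_rejected(self):
        recs = [record(i, age=50) for i in range(5)]
        with pytest.raises(CohortError, match="older"):
            compare_zonal_between_age_groups(recs, "middle")

    def test_planted_mature_excess_detected(self):
        rng = np.random.default_rng(3)
        recs = [record(i, age=rng.uniform(35, 64), zones=(10, rng.normal(25, 5), 5))
                for i in range(350)]
        recs += [record(400 + i, age=rng.uniform(65, 90), zones=(10, rng.normal(18, 5), 5))
                 for i in range(175)]
        _, p = compare_zonal_between_age_groups(recs, "middle")
        assert p < 0.05


class TestHeatmaps:
    def test_single_record_identity(self):
        g = np.arange(48, dtype=float).reshape(8, 6)
        recs = [record(0, regional=g)]
        out = mean_regional_heatmap(recs, "age_group")
        assert np.array_equal(out["mature"], g)

    def test_cellwise_linearity(self):
        g = np.arange(48, dtype=float).reshape(8, 6)
        recs = [record(0, regional=g), record(1, regional=2 * g)]
        out = mean_regional_heatmap(recs, "age_group")
        assert np.allclose(out["mature"], 1.5 * g)

    def test_records_without_grids_rejected(self):
        with pytest.raises(CohortError):
            mean_regional_heatmap([record(0)], "age_group")


def test_records_frame_has_derived_groups():
    df = records_to_frame([record(0, age=40, birads="A"), record(1, age=70, birads="D")])
    assert list(df["age_group"]) == ["mature", "older"]
    assert list(df["density_group"]) == ["less_dense", "denser"]
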