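"""Regional means, correlation classification, reliability screen, paired t."""

import math

import numpy as np
import pytest

from perisim.field_geometry import blind_spot_coords, grid_coords
from perisim.field_stats import (
    GHT_SECTOR_NAMES,
    HEMIFIELDS,
    QUADRANTS,
    build_default_sector_map,
    classification_grid,
    classify_r,
    cohort_correlations,
    comparison_report,
    paired_t,
    region_mean,
    region_points,
    reliability_filter,
)
from perisim.observer_sim import CohortRecord, make_paired_cohort


def make_record(eye_id, field_a, field_b=None, fl=0.0, fp=0.0, fn=0.0, laterality="OD"):
    return CohortRecord(
        eye_id=eye_id, laterality=laterality, sens_a=dict(field_a),
        sens_b=dict(field_b if field_b is not None else field_a),
        fl=fl, fp=fp, fn=fn, md=0.0, psd=0.0, vfi=100.0,
    )


class TestSectorMap:
    def test_hemifield_and_quadrant_cover_all_points(self, sector_map_od):
        assert set(sector_map_od.hemifield) == set(grid_coords("OD"))
        assert set(sector_map_od.quadrant) == set(grid_coords("OD"))

    def test_quadrant_labels_consistent_with_signs(self, sector_map_od):
        for (x, y), q in sector_map_od.quadrant.items():
            assert q[0] == ("S" if y > 0 else "I")
            assert q[1] == ("T" if x > 0 else "N")  # temporal = +x for OD

    def test_ght_sectors_mirror_symmetric(self, sector_map_od):
        ght = sector_map_od.ght
        for (x, y), label in ght.items():
            mirrored = ght.get((x, -y))
            assert mirrored is not None
            assert mirrored.split("-", 1)[1] == label.split("-", 1)[1]

    def test_ght_excludes_edge_ring_and_blind_spot(self, sector_map_od):
        for (x, y) in sector_map_od.ght:
            assert abs(x) != 27 and abs(y) != 27
            assert (x, y) not in blind_spot_coords("OD")

    def test_ght_sector_names(self, sector_map_od):
        names = {s.split("-", 1)[1] for s in sector_map_od.ght.values()}
        assert names == set(GHT_SECTOR_NAMES)
        assert len(set(sector_map_od.ght.values())) == 10  # five mirrored pairs

    def test_os_map_mirrors_od(self):
        od = build_default_sector_map("OD")
        os_ = build_default_sector_map("OS")
        assert {( -x, y): s for (x, y), s in od.ght.items()} == os_.ght


class TestRegionMean:
    def test_flat_field_any_region(self, sector_map_od):
        field = {c: 30.0 for c in grid_coords("OD")}
        for region in ["global", *HEMIFIELDS, *QUADRANTS]:
            assert region_mean(field, region, sector_map_od) == 30.0

    def test_single_point_perturbation_moves_global_mean_linearly(self, sector_map_od):
        field = {c: 30.0 for c in grid_coords("OD")}
        field[(3.0, 9.0)] -= 7.4  # 74 contributing points after blind-spot exclusion
        assert region_mean(field, "global", sector_map_od) == pytest.approx(30.0 - 0.1)

    def test_superior_mean_ignores_inferior_points(self, sector_map_od):
        field = {c: (30.0 if c[1] > 0 else 0.0) for c in grid_coords("OD")}
        oracle = np.mean([v for c, v in field.items()
                          if c[1] > 0 and c not in set(blind_spot_coords("OD"))])
        assert region_mean(field, "superior", sector_map_od) == pytest.approx(oracle)

    def test_blind_spot_exclusion_configurable(self, sector_map_od):
        field = {c: 30.0 for c in grid_coords("OD")}
        for bs in blind_spot_coords("OD"):
            field[bs] = 0.0
        assert region_mean(field, "global", sector_map_od) == 30.0
        assert region_mean(field, "global", sector_map_od, exclude_blind_spot=False) < 30.0

    def test_quadrants_recombine_to_global(self, sector_map_od):
        rng = np.random.default_rng(0)
        field = {c: float(rng.uniform(10, 40)) for c in grid_coords("OD")}
        total, count = 0.0, 0
        for q in QUADRANTS:
            pts = region_points(sector_map_od, q)
            total += region_mean(field, q, sector_map_od) * len(pts)
            count += len(pts)
        assert total / count == pytest.approx(region_mean(field, "global", sector_map_od))

    def test_unknown_region_rejected(self, sector_map_od):
        with pytest.raises(ValueError):
            region_mean({}, "equator", sector_map_od)


class TestClassifyR:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.81, "strong"), (0.7, "strong"), (0.4, "moderate"), (0.69, "moderate"),
         (0.39, "weak"), (-0.2, "weak"), (1.0, "strong")],
    )
    def test_cutoffs(self, r, expected):
        assert classify_r(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_r(1.2)


class TestCohortCorrelations:
    def test_identical_devices_all_strong(self, sector_map_od):
        rng = np.random.default_rng(1)
        records = [
            make_record(f"e{i}", {c: float(rng.uniform(10, 40)) for c in grid_coords("OD")})
            for i in range(5)
        ]
        report = cohort_correlations(records, sector_map_od)
        assert all(rc.r == pytest.approx(1.0) for rc in report.regions.values())
        assert all(rc.strength == "strong" for rc in report.points.values())

    def test_perfect_anticorrelation(self, sector_map_od):
        records = [
            make_record(f"e{i}", {c: a for c in grid_coords("OD")},
                        {c: b for c in grid_coords("OD")})
            for i, (a, b) in enumerate([(1.0, 3.0), (2.0, 2.0), (3.0, 1.0)])
        ]
        report = cohort_correlations(records, sector_map_od)
        assert report.regions["global"].r == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_coerced(self, sector_map_od):
        records = [make_record(f"e{i}", {c: 30.0 for c in grid_coords("OD")})
                   for i in range(4)]
        report = cohort_correlations(records, sector_map_od)
        assert all(rc.undefined and rc.r is None for rc in report.regions.values())

    def test_pearson_matches_sum_formula_oracle(self):
        from perisim.field_stats import _pearson

        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=30), rng.normal(size=30)
            n = len(a)
            num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
            den = math.sqrt(n * np.sum(a**2) - np.sum(a) ** 2) * math.sqrt(
                n * np.sum(b**2) - np.sum(b) ** 2
            )
            assert _pearson(a, b).r == pytest.approx(num / den, abs=1e-12)

    def test_fewer_than_three_eyes_rejected(self, sector_map_od):
        records = [make_record("a", {c: 1.0 for c in grid_coords("OD")})] * 2
        with pytest.raises(ValueError):
            cohort_correlations(records, sector_map_od)

    def test_recovers_generator_nominal_r(self, sector_map_od):
        from perisim.observer_sim import indep_sd_for_target_r, nominal_global_r

        for target in (0.3, 0.5, 0.8):
            sd = indep_sd_for_target_r(target)
            nominal = nominal_global_r(indep_sd_a=sd, indep_sd_b=sd)
            rs = [
                cohort_correlations(
                    make_paired_cohort(65, indep_sd_a=sd, indep_sd_b=sd, seed=seed),
                    sector_map_od,
                ).regions["global"].r
                for seed in range(50)
            ]
            assert np.mean(rs) == pytest.approx(nominal, abs=0.05)


class TestReliabilityFilter:
    def test_violations_excluded_with_reason(self):
        field = {c: 30.0 for c in grid_coords("OD")}
        records = [
            make_record("fl", field, fl=0.25, fp=0.05, fn=0.05),
            make_record("fp", field, fp=0.20),
            make_record("fn", field, fn=0.35),
            make_record("ok", field, fl=0.05),
        ]
        kept, excluded = reliability_filter(records)
        assert [r.eye_id for r in kept] == ["ok"]
        assert {rec.eye_id: reasons for rec, reasons in excluded} == {
            "fl": ["FL"], "fp": ["FP"], "fn": ["FN"]
        }

    def test_boundary_records_kept_under_strict_inequalities(self):
        field = {c: 30.0 for c in grid_coords("OD")}
        rec = make_record("edge", field, fl=0.20, fp=0.15, fn=0.30)
        kept, excluded = reliability_filter([rec])
        assert kept == [rec] and excluded == []

    def test_all_zero_indices_kept(self):
        rec = make_record("clean", {c: 1.0 for c in grid_coords("OD")})
        kept, _ = reliability_filter([rec])
        assert kept == [rec]

    def test_missing_index_is_an_error(self):
        rec = make_record("nan", {c: 1.0 for c in grid_coords("OD")}, fl=float("nan"))
        with pytest.raises(ValueError, match="fl"):
            reliability_filter([rec])


class TestPairedT:
    def test_textbook_example(self):
        # differences (-1, 0, -1, -1): mean -0.75, sd 0.5, t = -3.0, df 3
        res = paired_t([1, 2, 3, 4], [2, 2, 4, 5])
        assert res.t == pytest.approx(-3.0)
        assert res.df == 3
        # two-sided p from t with 3 df
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(3.0, 3), abs=1e-12)

    def test_identical_vectors_undefined(self):
        assert paired_t([1, 2, 3], [1, 2, 3]).undefined

    def test_constant_difference_undefined(self):
        assert paired_t([2, 3, 4, 5], [1, 2, 3, 4]).undefined

    def test_zero_mean_difference_with_variance(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert not res.undefined
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1, 2], [1, 2, 3])


class TestComparisonReport:
    def test_perfect_cohort_every_cell_strong(self, sector_map_od):
        rng = np.random.default_rng(5)
        records = [
            make_record(f"e{i}", {c: float(rng.uniform(15, 35)) for c in grid_coords("OD")})
            for i in range(6)
        ]
        report = comparison_report(records, sector_map_od)
        assert len(report["points"]) == 76
        assert report["point_strength_counts"]["strong"] == 76
        assert report["global_paired_t"]["undefined"]  # identical devices

    def test_classification_grid_has_76_cells(self, sector_map_od):
        records = make_paired_cohort(8, seed=1)
        report = comparison_report(records, sector_map_od)
        img = classification_grid(report, px_per_cell=1)
        assert img.shape == (10, 10)
        assert int((img > 0).sum()) == 76
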