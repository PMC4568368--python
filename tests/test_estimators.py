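"""Unit and property tests for the stereological estimator formulas."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stereoheal.estimators import (
    DissectorSpec,
    FieldCounts,
    PointGrid,
    StereologyError,
    estimate_area,
    estimate_length_density,
    estimate_mean_diameter,
    estimate_numerical_density,
    estimate_volume_density,
    summarize_animal,
)


def make_field(p_collagen=25, p_vessel=3, p_hair=2, p_dermis=100, q_minus=10,
               frame_area_mm2=0.01, height_mm=0.005, vessel_transects=2,
               diameters=(12.0, 15.0)):
    return FieldCounts(p_collagen=p_collagen, p_vessel=p_vessel, p_hair=p_hair,
                       p_dermis=p_dermis, q_minus=q_minus,
                       frame_area_mm2=frame_area_mm2, height_mm=height_mm,
                       vessel_transects=vessel_transects,
                       vessel_profile_diameters=list(diameters))


class TestPointGridArea:
    @pytest.mark.parametrize("points,spacing,expected", [
        (25, 2.0, 100.0),   # a/p = 4 mm²
        (0, 2.0, 0.0),
        (7, 1.0, 7.0),
    ])
    def test_direct_product(self, points, spacing, expected):
        assert estimate_area(points, PointGrid(spacing=spacing)) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(StereologyError):
            estimate_area(-1, PointGrid(spacing=1.0))

    def test_area_per_point_is_spacing_squared(self):
        assert PointGrid(spacing=0.5).area_per_point == 0.25

    def test_zero_spacing_rejected(self):
        with pytest.raises(StereologyError):
            PointGrid(spacing=0.0)

    def test_mask_counting_matches_pixel_area(self):
        """Grid counting over a rasterized disk recovers its pixel area."""
        mm_per_px = 0.02
        n = 600
        yy, xx = np.mgrid[:n, :n]
        cx = cy = n / 2 - 0.5
        r_px = 5.74 / mm_per_px
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        pixel_area = mask.sum() * mm_per_px ** 2
        grid = PointGrid(spacing=1.0)
        rng = np.random.default_rng(42)
        estimates = [estimate_area(grid.count_points_in_mask(mask, mm_per_px, rng), grid)
                     for _ in range(300)]
        assert abs(np.mean(estimates) - pixel_area) / pixel_area < 0.01


class TestVolumeDensity:
    def test_single_field_ratio(self):
        f = make_field(p_collagen=25, p_dermis=100)
        assert estimate_volume_density([f], "collagen") == 0.25

    def test_saturation(self):
        f = make_field(p_collagen=100, p_vessel=0, p_hair=0, p_dermis=100)
        assert estimate_volume_density([f], "collagen") == 1.0

    def test_ratio_of_sums_not_mean_of_ratios(self):
        fields = [make_field(p_collagen=10, p_dermis=20),
                  make_field(p_collagen=0, p_dermis=80)]
        # ratio of sums: 10/100; mean of ratios would be 0.25
        assert estimate_volume_density(fields, "collagen") == 0.1

    def test_zero_reference_rejected(self):
        f = make_field(p_collagen=0, p_vessel=0, p_hair=0, p_dermis=0)
        with pytest.raises(StereologyError, match="reference"):
            estimate_volume_density([f], "collagen")

    def test_unknown_phase_rejected(self):
        with pytest.raises(StereologyError):
            estimate_volume_density([make_field()], "bone")


class TestNumericalDensity:
    def test_direct_formula(self):
        # ΣQ=50, ΣA=0.1 mm², h=0.005 mm -> 100,000 per mm³
        fields = [make_field(q_minus=5, frame_area_mm2=0.01, height_mm=0.005)
                  for _ in range(10)]
        assert estimate_numerical_density(fields) == pytest.approx(100_000.0)

    def test_zero_counts(self):
        assert estimate_numerical_density([make_field(q_minus=0)]) == 0.0

    def test_mixed_heights_rejected(self):
        fields = [make_field(height_mm=0.005), make_field(height_mm=0.01)]
        with pytest.raises(StereologyError, match="height"):
            estimate_numerical_density(fields)

    def test_unit_roundtrip(self):
        """Cells/mm³ and the reporting unit ×10³/mm³ convert exactly."""
        fields = [make_field(q_minus=50, frame_area_mm2=0.1, height_mm=0.005)]
        nv = estimate_numerical_density(fields)
        assert nv / 1e3 == pytest.approx(100.0)


class TestLengthDensity:
    def test_zero_transects(self):
        assert estimate_length_density([make_field(vessel_transects=0)]) == 0.0

    def test_twice_qa(self):
        # Q_A = 8.6 / mm² -> Lv = 17.2 mm/mm³
        fields = [make_field(vessel_transects=86, frame_area_mm2=1.0)
                  for _ in range(10)]
        assert estimate_length_density(fields) == pytest.approx(2 * 86 * 10 / 10.0)
        single = [make_field(vessel_transects=86, frame_area_mm2=10.0)]
        assert estimate_length_density(single) == pytest.approx(17.2)


class TestMeanDiameter:
    def test_pooled_mean(self):
        f1 = make_field(diameters=(10.0, 12.0))
        f2 = make_field(diameters=(14.0,))
        assert estimate_mean_diameter([f1, f2]) == pytest.approx(12.0)

    def test_single_profile(self):
        assert estimate_mean_diameter([make_field(diameters=(11.7,))]) == 11.7

    def test_no_profiles_rejected(self):
        with pytest.raises(StereologyError, match="diameter"):
            estimate_mean_diameter([make_field(diameters=())])


class TestFieldCountsInvariants:
    def test_phase_sum_exceeding_reference_rejected(self):
        with pytest.raises(StereologyError, match="exceed"):
            make_field(p_collagen=60, p_vessel=30, p_hair=20, p_dermis=100)

    def test_negative_count_rejected(self):
        with pytest.raises(StereologyError):
            make_field(q_minus=-1)

    def test_guard_zones_must_leave_height(self):
        with pytest.raises(StereologyError):
            DissectorSpec(section_thickness=10.0, guard_top=5.0, guard_bottom=5.0)

    def test_default_dissector_height(self):
        spec = DissectorSpec()
        assert spec.height == 5.0
        assert spec.height_mm == pytest.approx(0.005)


class TestSummarizeAnimal:
    def test_all_zero_structures(self):
        f = make_field(p_collagen=0, p_vessel=0, p_hair=0, q_minus=0,
                       vessel_transects=0, diameters=())
        est = summarize_animal("a1", "control", [f])
        assert est.nv_fibroblast == 0.0
        assert est.vv_collagen == 0.0
        assert est.lv_vessel == 0.0
        assert np.isnan(est.vessel_diameter_mean)

    def test_reporting_scale(self):
        fields = [make_field(q_minus=50, frame_area_mm2=0.1, height_mm=0.005,
                             p_collagen=25, p_dermis=100)]
        est = summarize_animal("a1", "control", fields)
        assert est.nv_fibroblast == pytest.approx(100.0)   # ×10³/mm³
        assert est.vv_collagen == pytest.approx(25.0)      # percent

    @given(k=st.integers(min_value=2, max_value=5),
           data=st.lists(
               st.tuples(st.integers(0, 20), st.integers(0, 5), st.integers(0, 5),
                         st.integers(0, 30), st.integers(0, 8)),
               min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_replication_invariance(self, k, data):
        """Duplicating every field k times leaves ratio-of-sums estimates unchanged."""
        fields = []
        for pc, pv, ph, q, tr in data:
            fields.append(make_field(p_collagen=pc, p_vessel=pv, p_hair=ph,
                                     p_dermis=pc + pv + ph + 10, q_minus=q,
                                     vessel_transects=tr, diameters=(10.0,)))
        base = summarize_animal("a", "g", fields)
        repl = summarize_animal("a", "g", fields * k)
        for attr in ("nv_fibroblast", "vv_collagen", "vv_vessel", "vv_hair",
                     "lv_vessel", "vessel_diameter_mean"):
            assert getattr(base, attr) == pytest.approx(getattr(repl, attr))
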