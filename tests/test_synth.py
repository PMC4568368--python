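"""Tests of the synthetic-tissue and wound generators against their own
ground truth: seed determinism, calibration of the Boolean/segment models,
rendering consistency, and the wound trajectory closed forms."""

import numpy as np
import pytest

from stereoheal.estimators import DissectorSpec, PointGrid
from stereoheal.synth import (
    GroupProfile,
    PHASE_COLLAGEN,
    PHASE_VESSEL,
    SyntheticVolume,
    TissueParams,
    field_counts_at,
    iur_stack,
    render_field_counts,
    simulate_volume,
    simulate_wound_series,
)
from stereoheal.timecourse import closure_percent, closure_rate_per_day

CONTROL = dict(nv_fibroblast=284.5e3, vv_collagen=0.474, vv_hair=0.026,
               lv_vessel=17.2, vessel_diameter_mean=11.7, vessel_diameter_sd=3.1)


def empty_volume(extent=(500.0, 500.0, 500.0)):
    z3 = np.empty((0, 3))
    return SyntheticVolume(extent=extent, fibroblast_centers=z3.copy(),
                           collagen_centers=z3.copy(), collagen_radius=15.0,
                           hair_centers=z3.copy(), hair_radius=40.0,
                           vessel_p0=z3.copy(), vessel_p1=z3.copy(),
                           vessel_radii=np.empty(0))


class TestSimulateVolume:
    def test_seed_determinism_bitwise(self):
        p = TissueParams(**CONTROL, seed=11)
        a, b = simulate_volume(p), simulate_volume(p)
        for attr in ("fibroblast_centers", "collagen_centers", "hair_centers",
                     "vessel_p0", "vessel_p1", "vessel_radii"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_zero_intensity_gives_empty_process(self):
        p = TissueParams(nv_fibroblast=0.0, vv_collagen=0.0, vv_hair=0.0,
                         lv_vessel=0.0, vessel_diameter_mean=10.0,
                         vessel_diameter_sd=0.0, seed=0)
        v = simulate_volume(p)
        assert len(v.fibroblast_centers) == 0
        assert len(v.collagen_centers) == 0
        assert len(v.vessel_p0) == 0

    def test_oversolid_parameters_rejected(self):
        p = TissueParams(nv_fibroblast=0.0, vv_collagen=0.8, vv_hair=0.25,
                         lv_vessel=0.0, vessel_diameter_mean=10.0,
                         vessel_diameter_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="solid fraction"):
            simulate_volume(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TissueParams(nv_fibroblast=-1.0, vv_collagen=0.1, vv_hair=0.0,
                         lv_vessel=0.0, vessel_diameter_mean=10.0,
                         vessel_diameter_sd=0.0)

    def test_boolean_model_volume_fraction_calibrated(self):
        """Realized collagen fraction matches the requested Vv (Monte-Carlo)."""
        target = 0.30
        per_seed = []
        for s in range(40):
            p = TissueParams(nv_fibroblast=0.0, vv_collagen=target, vv_hair=0.0,
                             lv_vessel=0.0, vessel_diameter_mean=10.0,
                             vessel_diameter_sd=0.0,
                             volume_extent=(300.0, 300.0, 300.0), seed=s)
            v = simulate_volume(p)
            per_seed.append(v.phase_fraction_mc(PHASE_COLLAGEN, 30_000,
                                                np.random.default_rng(1000 + s)))
        per_seed = np.asarray(per_seed)
        se = per_seed.std(ddof=1) / np.sqrt(len(per_seed))
        assert abs(per_seed.mean() - target) < max(3 * se, 0.005)

    def test_precedence_compensation_keeps_all_phases_on_target(self):
        """With vessels and hair present, classified fractions still match."""
        per_seed = {"collagen": [], "hair": []}
        for s in range(25):
            p = TissueParams(**CONTROL, volume_extent=(300.0, 300.0, 300.0), seed=s)
            v = simulate_volume(p)
            rng = np.random.default_rng(2000 + s)
            pts = rng.uniform(0, 300, size=(30_000, 3))
            codes = v.phase_at(pts)
            per_seed["collagen"].append(np.mean(codes == PHASE_COLLAGEN))
            per_seed["hair"].append(np.mean(codes == 2))
        for phase, target in (("collagen", 0.474), ("hair", 0.026)):
            arr = np.asarray(per_seed[phase])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - target) < max(3 * se, 0.005)

    def test_segment_process_length_calibrated(self):
        target = 20.0
        vals = []
        for s in range(100):
            p = TissueParams(nv_fibroblast=0.0, vv_collagen=0.0, vv_hair=0.0,
                             lv_vessel=target, vessel_diameter_mean=11.7,
                             vessel_diameter_sd=3.1, seed=s)
            vals.append(simulate_volume(p).clipped_vessel_length_density())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se

    def test_phase_precedence_vessel_over_collagen(self):
        v = empty_volume()
        v.collagen_centers = np.array([[250.0, 250.0, 250.0]])
        v.vessel_p0 = np.array([[200.0, 250.0, 250.0]])
        v.vessel_p1 = np.array([[300.0, 250.0, 250.0]])
        v.vessel_radii = np.array([5.0])
        assert v.phase_at([[250.0, 250.0, 250.0]])[0] == PHASE_VESSEL
        assert v.phase_at([[250.0, 260.0, 250.0]])[0] == PHASE_COLLAGEN

    def test_json_roundtrip(self):
        p = TissueParams(**CONTROL, volume_extent=(200.0, 200.0, 200.0), seed=3)
        v = simulate_volume(p)
        w = SyntheticVolume.from_json(v.to_json())
        assert np.array_equal(v.fibroblast_centers, w.fibroblast_centers)
        assert np.array_equal(v.vessel_radii, w.vessel_radii)
        assert w.params == p


class TestRendering:
    def test_empty_volume_all_structure_counts_zero(self):
        v = empty_volume()
        rng = np.random.default_rng(0)
        stack = iur_stack(v, 15.0, 3, rng, spec=DissectorSpec())
        fields = render_field_counts(stack, PointGrid(0.01), DissectorSpec(), rng,
                                     fields_per_section=2)
        assert fields
        for f in fields:
            assert f.p_collagen == f.p_vessel == f.p_hair == 0
            assert f.q_minus == 0 and f.vessel_transects == 0
            assert f.p_dermis > 0

    def test_phase_counts_never_exceed_reference(self):
        p = TissueParams(**CONTROL, seed=5)
        v = simulate_volume(p)
        rng = np.random.default_rng(5)
        stack = iur_stack(v, 15.0, 4, rng, spec=DissectorSpec())
        fields = render_field_counts(stack, PointGrid(0.02), DissectorSpec(), rng,
                                     fields_per_section=3)
        assert fields
        for f in fields:
            assert f.p_collagen + f.p_vessel + f.p_hair <= f.p_dermis

    def test_single_nucleus_mid_dissector_counted_once(self):
        v = empty_volume()
        v.fibroblast_centers = np.array([[250.0, 250.0, 250.0]])
        rot = np.eye(3)
        rng = np.random.default_rng(0)
        f = field_counts_at(v, [250.0, 250.0, 250.0], rot, PointGrid(0.02),
                            DissectorSpec(), rng)
        assert f.q_minus == 1

    def test_nucleus_in_guard_zone_not_counted(self):
        v = empty_volume()
        v.fibroblast_centers = np.array([[250.0, 250.0, 254.0]])  # 4 µm above mid
        f = field_counts_at(v, [250.0, 250.0, 250.0], np.eye(3), PointGrid(0.02),
                            DissectorSpec(), np.random.default_rng(0))
        assert f.q_minus == 0

    def test_unbiased_frame_edges(self):
        """Left edge included, right edge excluded (half-open frame)."""
        spec = DissectorSpec()
        v = empty_volume()
        v.fibroblast_centers = np.array([[250.0 - spec.frame_width / 2, 250.0, 250.0],
                                         [250.0 + spec.frame_width / 2, 250.0, 250.0]])
        f = field_counts_at(v, [250.0, 250.0, 250.0], np.eye(3), PointGrid(0.02),
                            spec, np.random.default_rng(0))
        assert f.q_minus == 1

    def test_point_count_vv_converges_to_voxel_vv(self):
        """Fine point grid and dense 'voxel' sampling agree on the same plane."""
        p = TissueParams(**CONTROL, volume_extent=(400.0, 400.0, 400.0), seed=9)
        v = simulate_volume(p)
        spec = DissectorSpec(frame_width=200.0, frame_height=200.0)
        center, rot = [200.0, 200.0, 200.0], np.eye(3)
        rng = np.random.default_rng(0)
        f_grid = field_counts_at(v, center, rot, PointGrid(0.004), spec, rng)
        f_voxel = field_counts_at(v, center, rot, PointGrid(0.0015), spec, rng)
        vv_grid = f_grid.p_collagen / f_grid.p_dermis
        vv_voxel = f_voxel.p_collagen / f_voxel.p_dermis
        assert abs(vv_grid - vv_voxel) < 0.005

    def test_iur_sections_disjoint_and_ordered(self):
        v = empty_volume()
        stack = iur_stack(v, 15.0, 5, np.random.default_rng(4), spec=DissectorSpec())
        assert np.all(np.diff(stack.z_positions) >= 15.0)
        assert np.allclose(np.linalg.norm(stack.rotation @ stack.rotation.T - np.eye(3)), 0,
                           atol=1e-9)


class TestWoundGenerator:
    def test_deterministic_under_seed(self):
        prof = GroupProfile(name="hp5", final_closure_pct=99.0)
        a = simulate_wound_series(prof, 5, seed=7)
        b = simulate_wound_series(prof, 5, seed=7)
        assert all(x.areas == y.areas for x, y in zip(a, b))

    def test_noise_free_exponential_matches_closed_form(self):
        prof = GroupProfile(name="t", final_closure_pct=99.0, noise_sd=0.0)
        s = simulate_wound_series(prof, 1, seed=0)[0]
        a0 = s.areas[0]
        k = -np.log(1 - 0.99) / 15.0
        for d, a in zip(s.days, s.areas):
            assert a == pytest.approx(a0 * np.exp(-k * d))
        assert closure_percent(a0, s.areas[-1]) == pytest.approx(99.0)
        assert closure_rate_per_day(s) == pytest.approx(99.0 / 15.0)

    def test_untreated_profile_rises_then_falls(self):
        prof = GroupProfile(name="control", rise_until_day=3, rise_fraction=0.2,
                            final_closure_pct=66.3, noise_sd=0.0)
        s = simulate_wound_series(prof, 1, seed=1)[0]
        # closure at day 3 is negative (wound expanded), positive by day 15
        assert closure_percent(s.areas[0], s.areas[1]) == pytest.approx(-20.0)
        assert closure_percent(s.areas[0], s.areas[-1]) == pytest.approx(66.3)

    def test_day_grid_and_start(self):
        prof = GroupProfile(name="g")
        s = simulate_wound_series(prof, 1, seed=2)[0]
        assert s.days == [0, 3, 6, 9, 12, 15]

    def test_negative_areas_clipped_and_flagged(self):
        prof = GroupProfile(name="g", final_closure_pct=99.9, noise_sd=50.0)
        with pytest.warns(UserWarning, match="clipped"):
            series = simulate_wound_series(prof, 20, seed=3)
        assert any(s.clipped for s in series)
        assert all(min(s.areas) >= 0 for s in series)

    def test_treated_rate_near_analytic_over_many_seeds(self):
        """Mean per-day rate approaches 100·(1−f(15))/15 for the mean path."""
        prof = GroupProfile(name="t", final_closure_pct=99.0)
        rates = [closure_rate_per_day(s)
                 for s in simulate_wound_series(prof, 200, seed=11)]
        assert np.mean(rates) == pytest.approx(99.0 / 15.0, rel=0.02)
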