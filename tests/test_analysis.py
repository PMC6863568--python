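"""Registration, extraction, detection, estimators and plate analytics —
including the simulate -> analyze loop closures against simulator truth."""

import numpy as np
import pytest

from polirkit import analysis as an
from polirkit import instrument as inst
from polirkit import kinetics as kin
from polirkit.layout import ScanTile, plan_timelapse
from polirkit.optics import JitterModel, OpticsModel, calibrate_jitter, pixel_pitch
from polirkit.scenarios import reference_trace, strip_scene


@pytest.fixture(scope="module")
def trace():
    return reference_trace()


@pytest.fixture(scope="module")
def scene(trace):
    return strip_scene([(f"cap{i}", trace) for i in range(4)], origin_mm=(2.0, 2.8))


class TestRegistration:
    def test_zero_shift(self, small_optics, small_center, scene):
        img = inst.render_frame(scene, small_optics, t_min=0.0, center_mm=small_center)
        layout = an.ROILayout.from_scene(scene, small_center)
        reg = an.register_layout(img, layout, small_optics)
        assert abs(reg.col_px) <= 0.25 and abs(reg.row_px) <= 0.25

    @pytest.mark.parametrize("shift_px", [(2, -1), (-3, 2), (1, 3)])
    def test_injected_shift_recovered(self, small_optics, small_center, scene, shift_px):
        pitch = pixel_pitch(small_optics)[0]
        # camera error of +k px moves content -k px in x (and +k px in rows)
        err = (shift_px[0] * pitch, shift_px[1] * pitch)
        img = inst.render_frame(scene, small_optics, err, t_min=0.0, center_mm=small_center)
        layout = an.ROILayout.from_scene(scene, small_center)
        reg = an.register_layout(img, layout, small_optics)
        assert reg.col_px == pytest.approx(-shift_px[0], abs=0.5)
        assert reg.row_px == pytest.approx(shift_px[1], abs=0.5)
        assert reg.dx_um == pytest.approx(err[0], abs=0.5 * pitch)
        assert reg.dy_um == pytest.approx(err[1], abs=0.5 * pitch)

    def test_blank_image_fails(self, small_optics, small_center, scene):
        layout = an.ROILayout.from_scene(scene, small_center)
        blank = np.full((248, 328, 3), 0.9, dtype=np.float32)
        with pytest.raises(an.RegistrationError, match="registration failed"):
            an.register_layout(blank, layout, small_optics)


class TestExtraction:
    def test_corrected_zero_on_uniform_site(self, small_optics, small_center, tmp_path):
        """A blank lane reads the same as its flanking background."""
        scene_blank = strip_scene([("a", None)], origin_mm=(2.0, 3.6))
        plan = plan_timelapse([ScanTile(0, small_center)], 30.0, 1.5, homing="never")
        stack = inst.render_timelapse(
            plan, [scene_blank], small_optics, tmp_path / "s",
            jitter=JitterModel(0.0, 0.0), seed=1,
        )
        # blank site on the ribbon: compare against the ribbon, not the lumen
        layout = an.ROILayout.from_scene(scene_blank, small_center)
        series = an.extract_series(stack, layout, small_optics, register=False)["a"]
        assert np.abs(series.corrected[:, 1]).max() < 0.08

    def test_loopback_series_affine_in_truth(self, small_optics, small_center, tmp_path, trace):
        """Extracted fluorescence tracks the simulated F(t) with R^2 > 0.999."""
        scene_f = strip_scene([("a", trace)], origin_mm=(2.0, 3.6))
        plan = plan_timelapse([ScanTile(0, small_center)], 30.0, 12.0, homing="never")
        stack = inst.render_timelapse(
            plan, [scene_f], small_optics, tmp_path / "s",
            jitter=JitterModel(0.0, 0.0), seed=1, channels=("fluor",),
        )
        layout = an.ROILayout.from_scene(scene_f, small_center)
        series = an.extract_series(
            stack, layout, small_optics, channel="fluor", register=False
        )["a"]
        truth = np.interp(series.t_min, trace.t_min, trace.F)
        r = np.corrcoef(truth, series.corrected)[0, 1]
        assert r**2 > 0.999

    def test_replicate_sd_shrinks_with_root_n(self, rng):
        """Mean of n replicate noisy lanes has SD ~ 1/sqrt(n)."""
        t = np.arange(0, 721, 30.0)
        base = np.sin(t / 200.0) + 2.0
        reps = base + rng.normal(0.0, 0.1, (1000, 10, len(t)))
        sd1 = reps[:, :1].mean(axis=1).std(axis=0).mean()
        sd10 = reps.mean(axis=1).std(axis=0).mean()
        assert sd1 / sd10 == pytest.approx(np.sqrt(10), rel=0.1)


class TestDetectGrowth:
    T = np.arange(0, 301, 10.0)

    def test_flat_series_not_detected(self):
        call = an.detect_growth(self.T, np.ones_like(self.T), an.DetectionRule(mode="colorimetric"))
        assert not call.detected

    def test_step_ttp_between_frames(self):
        y = np.zeros_like(self.T)
        y[6:] = 1.0  # step between frames 5 (t=50) and 6 (t=60)
        call = an.detect_growth(self.T, y, an.DetectionRule(mode="colorimetric"))
        assert call.detected
        assert 50.0 < call.ttp_min < 60.0

    def test_min_range_floor_blocks_slow_drift(self):
        drift = np.linspace(0.0, 0.01, len(self.T))
        rule = an.DetectionRule(mode="colorimetric", min_range=0.05)
        assert not an.detect_growth(self.T, drift, rule).detected

    def test_fluorescence_relative_rule(self):
        y = np.ones_like(self.T)
        y[15:] = 2.0
        call = an.detect_growth(self.T, y, an.DetectionRule(mode="fluorescence"))
        assert call.detected and 140.0 < call.ttp_min < 150.0


class TestDoublingTime:
    def test_noiseless_reference_recovery(self):
        from polirkit.scenarios import dilution_series_estimate

        est = dilution_series_estimate("ecoli_25922", noise_sd=0.0)
        assert est.td_min == pytest.approx(16.0, abs=0.5)

    def test_slow_isolate_recovery(self):
        from polirkit.scenarios import dilution_series_estimate

        est = dilution_series_estimate("isolate22_kleb", noise_sd=0.0)
        assert est.td_min == pytest.approx(49.0, rel=0.10)

    def test_equal_ttps_degenerate_nd(self):
        est = an.estimate_doubling_time({0: 100.0, 1: 100.0, 2: 100.0, 3: 100.0})
        assert est.nd and est.td_min is None

    def test_fewer_than_three_dilutions_nd(self):
        est = an.estimate_doubling_time({0: 100.0, 1: 150.0, 2: None, 3: None})
        assert est.nd and est.n_dilutions == 2

    def test_exact_synthetic_slope(self):
        td = 20.0
        ttps = {d: 60.0 + d * td * np.log2(10) for d in range(4)}
        est = an.estimate_doubling_time(ttps)
        assert est.td_min == pytest.approx(td, rel=1e-9)
        assert est.stderr_min == pytest.approx(0.0, abs=1e-9)


class TestSusceptibility:
    def _call(self, detected):
        return an.GrowthCall(detected, 100.0 if detected else None, 0.5)

    def test_fully_susceptible_pattern(self):
        calls = an.call_susceptibility(
            [self._call(True)] * 6,
            {"gentamicin": [self._call(False)] * 2, "ampicillin": [self._call(False)] * 2},
        )
        assert [c.verdict for c in calls] == ["S", "S"]

    def test_single_resistance_pattern(self):
        calls = an.call_susceptibility(
            [self._call(True)] * 6,
            {"gentamicin": [self._call(False)] * 2, "ampicillin": [self._call(True), self._call(False)]},
        )
        assert {c.drug: c.verdict for c in calls} == {"gentamicin": "S", "ampicillin": "R"}

    def test_failed_control_nd(self):
        calls = an.call_susceptibility(
            [self._call(False)] * 6,
            {"gentamicin": [self._call(True)] * 2, "ampicillin": [self._call(False)] * 2},
        )
        assert all(c.verdict == "nd" for c in calls)

    def test_missing_control_error(self):
        with pytest.raises(ValueError, match="control"):
            an.call_susceptibility([], {"gentamicin": [self._call(True)]})


class TestColonies:
    def test_grid_colonies_counted_exactly(self, dish_optics):
        center = (9.65, 7.3)
        colonies = [
            dict(xc=5.0 + 2.2 * i, yc=4.0 + 2.2 * j, appear_min=60.0, rate_mm_min=0.2 / 60)
            for i in range(4)
            for j in range(3)
        ]
        scene = inst.Scene(
            variant="colony_plate",
            bodies=[inst.SceneBody({"kind": "disk", "xc": center[0], "yc": center[1], "d_mm": 14.0},
                                   tuple(inst.AGAR_TONE))],
            colonies=colonies,
        )
        img = inst.render_frame(scene, dish_optics, t_min=5 * 60, center_mm=center)
        df = an.count_colonies(img)
        assert len(df) == 12

    def test_blank_plate_zero(self, dish_optics):
        center = (9.65, 7.3)
        scene = inst.make_colony_scene(
            inst.ColonySceneParams(), center, 13.0, n_colonies=0
        )
        img = inst.render_frame(scene, dish_optics, t_min=300, center_mm=center)
        assert len(an.count_colonies(img)) == 0

    def test_counts_non_decreasing_before_merging(self, dish_optics):
        center = (9.65, 7.3)
        rng = np.random.default_rng(5)
        colonies = [
            dict(xc=5.0 + 2.2 * i, yc=4.0 + 2.2 * j,
                 appear_min=float(rng.uniform(60, 240)), rate_mm_min=0.18 / 60)
            for i in range(4)
            for j in range(3)
        ]
        scene = inst.Scene(
            variant="colony_plate",
            bodies=[inst.SceneBody({"kind": "disk", "xc": center[0], "yc": center[1], "d_mm": 14.0},
                                   tuple(inst.AGAR_TONE))],
            colonies=colonies,
        )
        counts = []
        for t_h in (1.5, 2.5, 3.5, 4.5, 5.5):
            img = inst.render_frame(scene, dish_optics, t_min=t_h * 60, center_mm=center)
            counts.append(len(an.count_colonies(img)))
        assert counts == sorted(counts)
        assert counts[-1] == 12


class TestMotility:
    def _stack(self, params, dish_optics, tmp_path, hours=5.0):
        center = (9.65, 7.3)
        scene = inst.make_motility_scene(params, center, 13.0)
        plan = plan_timelapse([ScanTile(0, center)], 60.0, hours, homing="never")
        stack = inst.render_timelapse(
            plan, [scene], dish_optics, tmp_path, jitter=JitterModel(0.0, 0.0), seed=2
        )
        return stack, center

    def test_motile_speed_within_ten_percent(self, dish_optics, tmp_path):
        stack, center = self._stack(
            inst.MotilitySceneParams(front_speed_mm_h=1.0), dish_optics, tmp_path / "m"
        )
        res = an.motility_analysis(stack, center, center, dish_optics, r_max_mm=6.3)
        assert res["motile"]
        assert res["front_speed_mm_h"] == pytest.approx(1.0, rel=0.10)

    def test_static_scene_not_motile(self, dish_optics, tmp_path):
        stack, center = self._stack(
            inst.MotilitySceneParams(motile=False, front_speed_mm_h=0.0),
            dish_optics, tmp_path / "n",
        )
        res = an.motility_analysis(stack, center, center, dish_optics, r_max_mm=6.3)
        assert not res["motile"]
        assert abs(res["front_speed_mm_h"]) < 0.1


class TestEndToEndLoopClosure:
    """Full-circle check: render a dilution series with stage jitter and
    sensor noise, analyse the stack and recover the simulated truth."""

    def test_doubling_time_recovered_from_images(self, small_optics, small_center, tmp_path):
        from polirkit.optics import NoiseModel, jitter_for_policy
        from polirkit.scenarios import reference_trace

        noisy = OpticsModel(
            sensor_px=small_optics.sensor_px, fov_mm=small_optics.fov_mm,
            noise=NoiseModel(read_sigma=1.0, shot_gain=20000.0),
        )
        t_grid = np.arange(0.0, 721.0, 1.0)
        lanes = [
            (f"dil{d}", reference_trace("ecoli_25922", mode="fluorescence",
                                        t_grid=t_grid, dilution=d))
            for d in range(4)
        ]
        scene = strip_scene(lanes, origin_mm=(2.0, 2.8))
        plan = plan_timelapse([ScanTile(0, small_center)], 30.0, 12.0, homing="once")
        stack = inst.render_timelapse(
            plan, [scene], noisy, tmp_path / "s", seed=3, channels=("fluor",)
        )
        layout = an.ROILayout.from_scene(scene, small_center)
        series = an.extract_series(stack, layout, noisy, channel="fluor")
        rule = an.DetectionRule(mode="fluorescence")
        ttps = {
            d: an.detect_growth_series(series[f"dil{d}"], rule).ttp_min for d in range(4)
        }
        est = an.estimate_doubling_time(ttps)
        assert not est.nd
        assert est.td_min == pytest.approx(16.0, rel=0.10)

    def test_jitter_recovered_within_one_pixel(self, small_optics, small_center, tmp_path):
        from polirkit.scenarios import reference_trace

        trace = reference_trace()
        scene = strip_scene([(f"c{i}", trace) for i in range(4)], origin_mm=(2.0, 2.8))
        plan = plan_timelapse([ScanTile(0, small_center)], 10.0, 2.0, homing="once")
        stack = inst.render_timelapse(plan, [scene], small_optics, tmp_path / "s", seed=6)
        layout = an.ROILayout.from_scene(scene, small_center)
        pitch = pixel_pitch(small_optics)[0]
        for _, row in stack.manifest.iterrows():
            reg = an.register_layout(stack.image(row), layout, small_optics)
            assert abs(reg.dx_um - row.true_dx_um) < pitch
            assert abs(reg.dy_um - row.true_dy_um) < pitch
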