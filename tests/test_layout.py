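"""Deck tiling, capacity arithmetic, time-lapse scheduling and G-code."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polirkit.layout import (
    BAR_TARGET,
    HomingPolicy,
    ImagingArea,
    LayoutError,
    MCF_COMB,
    PLATE12,
    PLATE96,
    ScanPlan,
    ScanTile,
    capacity,
    emit_gcode,
    parse_gcode,
    plan_timelapse,
    tile_area,
)

FOV = (96.5, 72.5)


class TestTileArea:
    def test_single_tile_identity(self):
        tiles = tile_area(ImagingArea(96.5, 72.5), FOV, 0.0)
        assert len(tiles) == 1
        assert tiles[0].center_mm == (96.5 / 2, 72.5 / 2)

    def test_full_deck_tile_count(self):
        # ceil(420/96.5) x ceil(300/72.5) = 5 x 5
        tiles = tile_area(ImagingArea(420, 300), FOV, 0.0)
        assert len(tiles) == 25

    def test_overlap_stride(self):
        tiles = tile_area(ImagingArea(193, 72.5), FOV, 0.5)
        xs = sorted(t.center_mm[0] for t in tiles)
        assert len(tiles) == 3
        # brute-force interval union covers the span
        covered = np.zeros(1931, dtype=bool)
        grid = np.linspace(0, 193, 1931)
        for x in xs:
            covered |= (grid >= x - FOV[0] / 2 - 1e-9) & (grid <= x + FOV[0] / 2 + 1e-9)
        assert covered.all()

    def test_fov_too_large_names_axis(self):
        with pytest.raises(LayoutError, match="x axis"):
            tile_area(ImagingArea(50, 300), FOV)
        with pytest.raises(LayoutError, match="y axis"):
            tile_area(ImagingArea(420, 50), FOV)

    def test_serpentine_ordering(self):
        tiles = tile_area(ImagingArea(420, 300), FOV, 0.0)
        rows = {}
        for t in tiles:
            rows.setdefault(round(t.center_mm[1], 3), []).append(t)
        for i, (_, row) in enumerate(sorted(rows.items())):
            xs = [t.center_mm[0] for t in sorted(row, key=lambda t: t.index)]
            assert xs == sorted(xs, reverse=bool(i % 2))

    @pytest.mark.parametrize("w,d", [(120, 90), (250, 160), (420, 300)])
    @pytest.mark.parametrize("overlap", [0.0, 0.2, 0.5])
    def test_coverage_dense_grid(self, w, d, overlap):
        """Every deck point lies inside at least one tile footprint."""
        tiles = tile_area(ImagingArea(w, d), FOV, overlap)
        gx = np.arange(0, w + 0.5, 1.0)
        gy = np.arange(0, d + 0.5, 1.0)
        cov = np.zeros((len(gy), len(gx)), dtype=bool)
        for t in tiles:
            cx, cy = t.center_mm
            in_x = np.abs(gx - cx) <= FOV[0] / 2 + 1e-9
            in_y = np.abs(gy - cy) <= FOV[1] / 2 + 1e-9
            cov |= np.outer(in_y, in_x)
        assert cov.all()

    def test_tile_count_monotone_in_area_and_overlap(self):
        counts_area = [
            len(tile_area(ImagingArea(w, 300), FOV)) for w in (100, 200, 300, 420)
        ]
        assert counts_area == sorted(counts_area)
        counts_ov = [
            len(tile_area(ImagingArea(420, 300), FOV, ov)) for ov in (0.0, 0.25, 0.5, 0.75)
        ]
        assert counts_ov == sorted(counts_ov)


class TestCapacity:
    def test_comb_deckload_sample_count(self):
        # 29 combs x 12 strips x 10 capillaries = 3480 one-microlitre samples
        assert capacity(MCF_COMB, 29).samples == 3480

    def test_strip_capillary_counts(self):
        strips = 216
        assert strips * MCF_COMB.subsites_per_site == 2160
        assert 432 * MCF_COMB.subsites_per_site == 4320

    def test_plates(self):
        assert capacity(PLATE96, 10).samples == 960
        assert capacity(PLATE12, 10).samples == 120

    def test_zero_placements(self):
        assert capacity(MCF_COMB, 0).samples == 0

    @pytest.mark.parametrize("n", [1, 3, 7, 29])
    def test_linear_scaling(self, n):
        assert capacity(MCF_COMB, n).samples == 120 * n

    def test_packing_estimate_flagged(self):
        rep = capacity(MCF_COMB, area=ImagingArea(420, 300))
        assert rep.estimated
        assert rep.placements > 0
        assert rep.samples == rep.placements * 120


class TestPlanTimelapse:
    def test_thirteen_tile_four_hour_run(self):
        tiles = [ScanTile(i, (10 + 30 * (i % 5), 10 + 60 * (i // 5))) for i in range(13)]
        plan = plan_timelapse(tiles, 10.0, 4.0)
        assert plan.n_cycles == 25
        assert plan.n_acquisitions == 325

    def test_short_duration_single_cycle(self):
        plan = plan_timelapse([ScanTile(0, (10, 10))], 30.0, 0.25)
        assert plan.n_cycles == 1
        assert plan.n_acquisitions == 1

    def test_empty_tiles_error(self):
        with pytest.raises(LayoutError):
            plan_timelapse([], 10.0, 4.0)

    def test_cycle_overrun_fails(self):
        tiles = [ScanTile(i, (5 + i * 2, 5)) for i in range(20)]
        with pytest.raises(LayoutError, match="exceeds"):
            plan_timelapse(tiles, 0.5, 2.0, per_tile_overhead_s=10.0)


def _random_plan(rng: np.random.Generator) -> ScanPlan:
    n_tiles = int(rng.integers(1, 8))
    tiles = [
        ScanTile(
            i,
            (float(np.round(rng.uniform(5, 415), 3)), float(np.round(rng.uniform(5, 295), 3))),
            z_mm=float(np.round(rng.uniform(10, 120), 3)),
            dwell_s=float(np.round(rng.uniform(0, 3), 3)),
        )
        for i in range(n_tiles)
    ]
    return ScanPlan(
        tiles=tuple(tiles),
        cycle_interval_min=float(np.round(rng.uniform(1, 60), 3)),
        n_cycles=int(rng.integers(1, 5)),
        homing_policy=rng.choice(list(HomingPolicy)),
        feedrate_mm_min=float(rng.integers(500, 6000)),
    )


class TestGcode:
    def test_homing_once_single_g28_at_top(self):
        plan = ScanPlan((ScanTile(0, (10, 20)),), 10.0, 3, HomingPolicy.ONCE)
        text = emit_gcode(plan)
        lines = text.splitlines()
        assert lines.count("G28") == 1
        assert lines[3] == "G28"  # after G21/G90/metadata header

    def test_homing_every_cycle_count(self):
        plan = ScanPlan((ScanTile(0, (10, 20)),), 10.0, 3, HomingPolicy.EVERY_CYCLE)
        assert emit_gcode(plan).splitlines().count("G28") == 3

    def test_out_of_travel_error_names_tile_and_axis(self):
        plan = ScanPlan((ScanTile(0, (500, 20)),), 10.0, 1)
        with pytest.raises(LayoutError, match=r"tile 0: X"):
            emit_gcode(plan)

    def test_parse_minimal(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = parse_gcode("G28\nG0 X10 Y20 F3000\n")
        assert plan.tiles[0].center_mm == (10.0, 20.0)
        assert plan.homing_policy is HomingPolicy.ONCE

    def test_no_triggers_warns(self):
        with pytest.warns(UserWarning, match="no trigger"):
            plan = parse_gcode("G21\nG90\nG0 X10 Y20 F3000\n")
        assert plan.n_cycles == 1

    def test_malformed_token_reports_line(self):
        with pytest.raises(Exception, match="line 2"):
            parse_gcode("G21\nG0 X1,5 Y2\n")

    def test_emit_parse_emit_fixed_point(self, rng):
        for _ in range(100):
            plan = _random_plan(rng)
            text = emit_gcode(plan)
            assert emit_gcode(parse_gcode(text)) == text

    def test_round_trip_semantics(self, rng):
        for _ in range(100):
            plan = _random_plan(rng)
            back = parse_gcode(emit_gcode(plan))
            assert back.n_acquisitions == plan.n_acquisitions
            assert [t.center_mm for t in back.tiles] == [t.center_mm for t in plan.tiles]
            assert [t.z_mm for t in back.tiles] == [t.z_mm for t in plan.tiles]
            assert [t.dwell_s for t in back.tiles] == [t.dwell_s for t in plan.tiles]

    @given(
        x=st.floats(0, 420), y=st.floats(0, 300), z=st.floats(0, 130),
        n_cycles=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_emitted_coordinates_within_travel(self, x, y, z, n_cycles):
        plan = ScanPlan(
            (ScanTile(0, (round(x, 3), round(y, 3)), z_mm=round(z, 3)),), 10.0, n_cycles
        )
        for line in emit_gcode(plan).splitlines():
            if line.startswith("G0"):
                for word in line.split()[1:]:
                    axis, val = word[0], float(word[1:])
                    lim = {"X": 420, "Y": 300, "Z": 130, "F": math.inf}[axis]
                    assert 0 <= val <= lim


def test_labware_site_grid_must_fit():
    from polirkit.layout import LabwareKind, LabwareSpec

    with pytest.raises(LayoutError, match="does not fit"):
        LabwareSpec(
            kind=LabwareKind.PLATE96, footprint_mm=(50.0, 50.0),
            site_grid=(8, 12, 9.0, 9.0),
        )


def test_placement_bounds():
    from polirkit.layout import Placement

    area = ImagingArea()
    Placement(MCF_COMB, (310.0, 260.0)).validate(area)
    with pytest.raises(LayoutError, match="exceeds"):
        Placement(MCF_COMB, (400.0, 280.0)).validate(area)
    # 90-degree rotation swaps the footprint
    p = Placement(MCF_COMB, (380.0, 180.0), rotation_deg=90)
    p.validate(area)
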