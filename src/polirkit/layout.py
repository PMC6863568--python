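"""Deck layout, scan tiling, time-lapse scheduling and G-code emission.

The imaging deck follows the CoreXY gantry convention: the coordinate origin
is the home position at the front-left corner, +x runs right, +y runs back,
all positions are absolute millimetres.  Labware is placed by the deck
coordinates of its front-left corner.  A scan covers the deck with
overlapping camera fields of view ("tiles") visited in serpentine order, and
a time-lapse repeats that tile sequence at a fixed cycle interval.  The whole
plan round-trips through a small, documented G-code dialect so that the same
program can drive a real Marlin/Repetier-style gantry or the virtual
instrument in :mod:`polirkit.instrument`.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "ImagingArea",
    "LabwareKind",
    "LabwareSpec",
    "Placement",
    "ScanTile",
    "HomingPolicy",
    "ScanPlan",
    "CapacityReport",
    "tile_area",
    "capacity",
    "plan_timelapse",
    "emit_gcode",
    "parse_gcode",
    "MCF_COMB",
    "PLATE96",
    "PLATE12",
    "PETRI",
    "BAR_TARGET",
]


class LayoutError(ValueError):
    """Raised for geometrically impossible layouts or out-of-travel poses."""


class GcodeError(ValueError):
    """Raised for malformed G-code input."""


@dataclass(frozen=True)
class ImagingArea:
    """x/y/z travel envelope of the gantry, in millimetres."""

    width_mm: float = 420.0
    depth_mm: float = 300.0
    z_travel_mm: float = 130.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "depth_mm", "z_travel_mm"):
            if getattr(self, name) <= 0:
                raise LayoutError(f"ImagingArea.{name} must be > 0")


class LabwareKind(str, Enum):
    MCF_COMB = "mcf_comb"
    PLATE96 = "plate96"
    PLATE12 = "plate12"
    PETRI = "petri"
    BAR_TARGET = "bar_target"


@dataclass(frozen=True)
class LabwareSpec:
    """Geometry of one piece of labware and its sample sites.

    ``site_grid`` is (rows, cols, pitch_x_mm, pitch_y_mm); a *site* is a
    strip (for comb holders) or a well.  ``subsites_per_site`` is the number
    of independent samples per site — the 10 parallel ~206 um capillaries of
    a microcapillary-film strip, or 1 for a well.
    """

    kind: LabwareKind
    footprint_mm: tuple[float, float]
    site_grid: tuple[int, int, float, float]
    subsites_per_site: int = 1
    site_geometry: dict = field(default_factory=dict)
    deck_height_mm: float = 0.0

    def __post_init__(self) -> None:
        rows, cols, px, py = self.site_grid
        if rows < 1 or cols < 1:
            raise LayoutError("site_grid must have at least one site")
        if self.subsites_per_site < 1:
            raise LayoutError("subsites_per_site must be >= 1")
        w, d = self.footprint_mm
        if (cols - 1) * px > w + 1e-9 or (rows - 1) * py > d + 1e-9:
            raise LayoutError(
                f"{self.kind.value}: site grid ({rows}x{cols} at {px}x{py} mm) "
                f"does not fit footprint {w}x{d} mm"
            )

    @property
    def sites(self) -> int:
        return self.site_grid[0] * self.site_grid[1]

    @property
    def samples(self) -> int:
        return self.sites * self.subsites_per_site


#: 'Lab-on-a-comb' holder: 12 microcapillary-film strips at 9 mm pitch
#: (microtitre-plate compatible); each strip is 33 x 4.5 mm with 10
#: capillaries of 206 um mean lumen diameter.
MCF_COMB = LabwareSpec(
    kind=LabwareKind.MCF_COMB,
    footprint_mm=(108.0, 36.0),
    site_grid=(1, 12, 9.0, 9.0),
    subsites_per_site=10,
    site_geometry={
        "strip_length_mm": 33.0,
        "strip_width_mm": 4.5,
        "capillaries_per_strip": 10,
        "lumen_diameter_um": 206.0,
        "capillary_pitch_um": 400.0,
    },
)

PLATE96 = LabwareSpec(
    kind=LabwareKind.PLATE96,
    footprint_mm=(127.8, 85.5),
    site_grid=(8, 12, 9.0, 9.0),
    site_geometry={"well_diameter_mm": 6.9},
)

PLATE12 = LabwareSpec(
    kind=LabwareKind.PLATE12,
    footprint_mm=(127.8, 85.5),
    site_grid=(3, 4, 26.0, 26.0),
    site_geometry={"well_diameter_mm": 22.1},
)

PETRI = LabwareSpec(
    kind=LabwareKind.PETRI,
    footprint_mm=(90.0, 90.0),
    site_grid=(1, 1, 0.0, 0.0),
    site_geometry={"dish_diameter_mm": 90.0, "agar_depth_mm": 4.0},
)

BAR_TARGET = LabwareSpec(
    kind=LabwareKind.BAR_TARGET,
    footprint_mm=(50.0, 50.0),
    site_grid=(1, 1, 0.0, 0.0),
    site_geometry={"max_lp_per_mm": 14.0},
)

LABWARE_LIBRARY: dict[str, LabwareSpec] = {
    "mcf_comb": MCF_COMB,
    "plate96": PLATE96,
    "plate12": PLATE12,
    "petri": PETRI,
    "bar_target": BAR_TARGET,
}


@dataclass(frozen=True)
class Placement:
    """A piece of labware on the deck: front-left corner + 0/90 deg rotation."""

    labware: LabwareSpec
    origin_mm: tuple[float, float]
    rotation_deg: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg not in (0, 90):
            raise LayoutError("rotation_deg must be 0 or 90")

    @property
    def footprint_mm(self) -> tuple[float, float]:
        w, d = self.labware.footprint_mm
        return (d, w) if self.rotation_deg == 90 else (w, d)

    def validate(self, area: ImagingArea) -> None:
        x0, y0 = self.origin_mm
        w, d = self.footprint_mm
        if x0 < -1e-9 or y0 < -1e-9 or x0 + w > area.width_mm + 1e-9 or y0 + d > area.depth_mm + 1e-9:
            raise LayoutError(
                f"placement of {self.labware.kind.value} at ({x0}, {y0}) "
                f"({w}x{d} mm) exceeds imaging area {area.width_mm}x{area.depth_mm} mm"
            )


@dataclass(frozen=True)
class ScanTile:
    index: int
    center_mm: tuple[float, float]
    z_mm: float = 80.0
    dwell_s: float = 0.5


class HomingPolicy(str, Enum):
    ONCE = "once"
    EVERY_CYCLE = "every_cycle"
    NEVER = "never"


@dataclass(frozen=True)
class ScanPlan:
    tiles: tuple[ScanTile, ...]
    cycle_interval_min: float
    n_cycles: int
    homing_policy: HomingPolicy = HomingPolicy.ONCE
    feedrate_mm_min: float = 3000.0
    trigger_template: str = "M118 SNAP {tile} {cycle}"

    def __post_init__(self) -> None:
        if not self.tiles:
            raise LayoutError("ScanPlan requires at least one tile")
        if self.n_cycles < 1:
            raise LayoutError("n_cycles must be >= 1")

    @property
    def n_acquisitions(self) -> int:
        return self.n_cycles * len(self.tiles)

    def acquisition_times_min(self) -> list[float]:
        """Nominal time of each acquisition: cycles anchored at k*interval,
        tiles spread by travel + dwell within a cycle."""
        times = []
        for c in range(self.n_cycles):
            t0 = c * self.cycle_interval_min
            t = t0
            prev = None
            for tile in self.tiles:
                if prev is not None:
                    dist = math.hypot(
                        tile.center_mm[0] - prev.center_mm[0],
                        tile.center_mm[1] - prev.center_mm[1],
                    )
                    t += dist / self.feedrate_mm_min
                t += tile.dwell_s / 60.0
                times.append(t)
                prev = tile
        return times


def tile_area(
    area: ImagingArea,
    fov_mm: tuple[float, float],
    overlap_frac: float = 0.0,
    z_mm: float = 80.0,
    dwell_s: float = 0.5,
) -> list[ScanTile]:
    """Cover the x/y travel area with camera fields of view.

    Tiles are spaced so adjacent footprints overlap by at least
    ``overlap_frac`` of the field of view in each axis, and ordered in a
    serpentine (boustrophedon) raster to minimise travel: rows of constant y,
    x direction alternating row to row.
    """
    if not 0 <= overlap_frac < 1:
        raise LayoutError("overlap_frac must be in [0, 1)")
    fw, fh = fov_mm
    if fw > area.width_mm + 1e-9:
        raise LayoutError(f"field of view width {fw} mm exceeds area width {area.width_mm} mm (x axis)")
    if fh > area.depth_mm + 1e-9:
        raise LayoutError(f"field of view height {fh} mm exceeds area depth {area.depth_mm} mm (y axis)")

    def centers(span: float, fov: float) -> list[float]:
        stride = fov * (1.0 - overlap_frac)
        if span <= fov + 1e-9:
            return [span / 2.0]
        n = math.ceil((span - fov) / stride - 1e-9) + 1
        # distribute evenly; actual stride <= nominal, so overlap >= requested
        step = (span - fov) / (n - 1)
        return [fov / 2.0 + i * step for i in range(n)]

    xs = centers(area.width_mm, fw)
    ys = centers(area.depth_mm, fh)
    tiles: list[ScanTile] = []
    for r, y in enumerate(ys):
        row_xs = xs if r % 2 == 0 else list(reversed(xs))
        for x in row_xs:
            tiles.append(ScanTile(index=len(tiles), center_mm=(x, y), z_mm=z_mm, dwell_s=dwell_s))
    return tiles


@dataclass(frozen=True)
class CapacityReport:
    placements: int
    sites: int
    samples: int
    estimated: bool = False


def capacity(
    labware: LabwareSpec,
    n_placements: int | None = None,
    area: ImagingArea | None = None,
    margin_mm: float = 2.0,
) -> CapacityReport:
    """Sample-count arithmetic for a deck full of one labware type.

    With ``n_placements`` given, this is exact bookkeeping:
    ``samples = n_placements x sites x subsites``.  With it omitted, a greedy
    axis-aligned grid packing of the (optionally rotated) footprint inside
    ``area`` with ``margin_mm`` on all sides is used and the report is
    flagged as an estimate.
    """
    if n_placements is not None:
        if n_placements < 0:
            raise LayoutError("n_placements must be >= 0")
        return CapacityReport(
            placements=n_placements,
            sites=n_placements * labware.sites,
            samples=n_placements * labware.samples,
        )
    if area is None:
        raise LayoutError("capacity estimate requires an ImagingArea")
    usable_w = area.width_mm - 2 * margin_mm
    usable_d = area.depth_mm - 2 * margin_mm
    best = 0
    for w, d in (labware.footprint_mm, labware.footprint_mm[::-1]):
        if usable_w >= w and usable_d >= d:
            n = math.floor((usable_w + margin_mm) / (w + margin_mm)) * math.floor(
                (usable_d + margin_mm) / (d + margin_mm)
            )
            best = max(best, n)
    return CapacityReport(
        placements=best, sites=best * labware.sites, samples=best * labware.samples, estimated=True
    )


def plan_timelapse(
    tiles: Sequence[ScanTile],
    interval_min: float,
    duration_h: float,
    homing: HomingPolicy | str = HomingPolicy.ONCE,
    feedrate_mm_min: float = 3000.0,
    per_tile_overhead_s: float = 2.0,
) -> ScanPlan:
    """Schedule a time-lapse: the tile sequence repeated every ``interval_min``
    for ``duration_h`` hours, the t=0 cycle included
    (``n_cycles = floor(duration/interval) + 1``).

    Cycles are anchored to ideal start times k*interval.  If one cycle's
    moves plus per-tile overhead cannot finish within the interval, planning
    fails rather than letting cycle starts drift.
    """
    if not tiles:
        raise LayoutError("plan_timelapse requires at least one tile")
    if interval_min <= 0 or duration_h <= 0:
        raise LayoutError("interval and duration must be > 0")
    homing = HomingPolicy(homing)
    n_cycles = math.floor(duration_h * 60.0 / interval_min + 1e-9) + 1

    travel = 0.0
    for a, b in zip(tiles, tiles[1:]):
        travel += math.hypot(b.center_mm[0] - a.center_mm[0], b.center_mm[1] - a.center_mm[1])
    cycle_min = travel / feedrate_mm_min + sum(t.dwell_s + per_tile_overhead_s for t in tiles) / 60.0
    if n_cycles > 1 and cycle_min > interval_min:
        raise LayoutError(
            f"one cycle takes {cycle_min:.1f} min (travel + dwell + overhead) "
            f"which exceeds the {interval_min:.1f} min interval"
        )
    return ScanPlan(
        tiles=tuple(tiles),
        cycle_interval_min=float(interval_min),
        n_cycles=n_cycles,
        homing_policy=homing,
        feedrate_mm_min=float(feedrate_mm_min),
    )


# ---------------------------------------------------------------------------
# G-code dialect
#
#   G21 / G90 header (millimetres, absolute), G28 homing, G0 moves with
#   X/Y/Z/F words (3 decimal places; F as integer), G4 S<dwell> before each
#   trigger, and per acquisition a comment marker `;SNAP tile=<i> cycle=<c>`
#   followed by the plan's raw trigger command (default `M118 SNAP <i> <c>`).
#   `;POLIRKIT interval_min=<v>` records the cycle interval so the plan
#   round-trips.  Unknown lines are preserved verbatim and warned about.
# ---------------------------------------------------------------------------

_NUM = r"[-+]?\d+(?:\.\d+)?"
_WORD_RE = re.compile(rf"^([XYZFS])({_NUM})$")


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def emit_gcode(plan: ScanPlan, area: ImagingArea | None = None) -> str:
    """Serialise a :class:`ScanPlan` to G-code text (LF line endings).

    Every emitted coordinate is checked against the travel limits of
    ``area`` (default deck) — an out-of-travel tile is a planning bug and
    raises rather than emitting a program that would crash the gantry.
    """
    area = area or ImagingArea()
    for tile in plan.tiles:
        x, y = tile.center_mm
        for axis, v, lim in (("X", x, area.width_mm), ("Y", y, area.depth_mm), ("Z", tile.z_mm, area.z_travel_mm)):
            if v < -1e-9 or v > lim + 1e-9:
                raise LayoutError(f"tile {tile.index}: {axis}={_fmt(v)} outside travel [0, {_fmt(lim)}]")

    lines = ["G21", "G90", f";POLIRKIT interval_min={_fmt(plan.cycle_interval_min)}"]
    if plan.homing_policy is HomingPolicy.ONCE:
        lines.append("G28")
    for c in range(plan.n_cycles):
        if plan.homing_policy is HomingPolicy.EVERY_CYCLE:
            lines.append("G28")
        for tile in plan.tiles:
            x, y = tile.center_mm
            lines.append(f"G0 X{_fmt(x)} Y{_fmt(y)} Z{_fmt(tile.z_mm)} F{int(round(plan.feedrate_mm_min))}")
            lines.append(f"G4 S{_fmt(tile.dwell_s)}")
            lines.append(f";SNAP tile={tile.index} cycle={c}")
            lines.append(plan.trigger_template.format(tile=tile.index, cycle=c))
    return "\n".join(lines) + "\n"


_SNAP_RE = re.compile(r"^;SNAP tile=(\d+) cycle=(\d+)$")
_META_RE = re.compile(rf"^;POLIRKIT interval_min=({_NUM})$")


def parse_gcode(text: str) -> ScanPlan:
    """Parse the dialect produced by :func:`emit_gcode` back into a plan.

    Unknown commands are kept as opaque lines (a warning is emitted); the
    returned plan reproduces poses, visiting order, dwells, homing events and
    trigger count of the source program.
    """
    interval_min = 10.0
    feedrate = 3000.0
    dwell = 0.0
    pos = {"X": 0.0, "Y": 0.0, "Z": 0.0}
    homings: list[int] = []  # acquisition index at which each homing occurred
    acquisitions: list[tuple[int, int, float, float, float, float]] = []
    trigger_template = "M118 SNAP {tile} {cycle}"
    unknown = 0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _META_RE.match(line)
        if m:
            interval_min = float(m.group(1))
            continue
        m = _SNAP_RE.match(line)
        if m:
            acquisitions.append(
                (int(m.group(1)), int(m.group(2)), pos["X"], pos["Y"], pos["Z"], dwell)
            )
            continue
        if line.startswith(";"):
            continue  # ordinary comment
        head, *words = line.split()
        if head == "G28":
            homings.append(len(acquisitions))
            continue
        if head in ("G21", "G90"):
            continue
        if head in ("G0", "G1"):
            for w in words:
                m = _WORD_RE.match(w)
                if not m:
                    raise GcodeError(f"line {lineno}: malformed coordinate token {w!r}")
                letter, value = m.group(1), float(m.group(2))
                if letter == "F":
                    feedrate = value
                else:
                    pos[letter] = value
            continue
        if head == "G4":
            for w in words:
                m = _WORD_RE.match(w)
                if not m or m.group(1) != "S":
                    raise GcodeError(f"line {lineno}: malformed dwell token {w!r}")
                dwell = float(m.group(2))
            continue
        if head == "M118":
            continue  # trigger raw command; the ;SNAP marker is authoritative
        unknown += 1

    if unknown:
        warnings.warn(f"{unknown} unrecognised G-code line(s) preserved as opaque", stacklevel=2)
    if not acquisitions:
        warnings.warn("G-code program contains no trigger lines (0 acquisitions)", stacklevel=2)
        return ScanPlan(
            tiles=(ScanTile(0, (pos["X"], pos["Y"]), pos["Z"], dwell),),
            cycle_interval_min=interval_min,
            n_cycles=1,
            homing_policy=HomingPolicy.ONCE if homings else HomingPolicy.NEVER,
            feedrate_mm_min=feedrate,
            trigger_template=trigger_template,
        )

    n_cycles = max(c for _, c, *_ in acquisitions) + 1
    first_cycle = [a for a in acquisitions if a[1] == 0]
    tiles = tuple(
        ScanTile(index=i, center_mm=(x, y), z_mm=z, dwell_s=dw)
        for i, _, x, y, z, dw in first_cycle
    )
    if len(homings) >= n_cycles and n_cycles > 1:
        policy = HomingPolicy.EVERY_CYCLE
    elif homings:
        policy = HomingPolicy.ONCE
    else:
        policy = HomingPolicy.NEVER
    return ScanPlan(
        tiles=tiles,
        cycle_interval_min=interval_min,
        n_cycles=n_cycles,
        homing_policy=policy,
        feedrate_mm_min=feedrate,
        trigger_template=trigger_template,
    )
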