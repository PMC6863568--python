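"""Virtual instrument: seeded synthetic time-lapse image stacks.

Renders what the gantry camera would see — microcapillary-film strips,
microtitre wells, colony and motility plates, and USAF-style three-bar
resolution targets — by composing the kinetic traces (colour/fluorescence
per site), the optics model (pixel pitch, defocus PSF, sensor noise) and the
stage jitter model, and writes ground-truth manifests alongside the frames.

Conventions: deck origin front-left, +x right, +y back (see
:mod:`polirkit.layout`); frame pixel (0,0) is top-left and maps to deck
point (pose_x - fov_x/2, pose_y + fov_y/2).  A positive camera pose error
therefore moves scene content left/down in the frame.  Colour frames are
8-bit RGB PNG; the fluorescence channel is 16-bit mono TIFF.  Identical
(inputs, seed) produce bit-identical stacks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .kinetics import BROTH, KineticTrace, MatrixModel, DYE_DEFAULT
from .layout import HomingPolicy, ImagingArea, ScanPlan
from .optics import JitterModel, OpticsModel, pixel_pitch, psf_sigma, jitter_for_policy

__all__ = [
    "SceneSite",
    "SceneBody",
    "ColonySceneParams",
    "MotilitySceneParams",
    "Scene",
    "FrameStack",
    "render_frame",
    "render_timelapse",
    "render_bar_target",
    "make_colony_scene",
    "make_motility_scene",
]

#: white backlight level (normalised) and labware body tones
BACKLIGHT = 0.95
RIBBON_TONE = 0.88
AGAR_TONE = np.array([0.82, 0.78, 0.68])
COLONY_RGB = np.array([0.55, 0.12, 0.10])   # TTC formazan red
STAIN_RGB = np.array([0.75, 0.25, 0.22])    # motility-front TTC stain
FLUOR_SITE_OFFSET = 0.01                    # reflection/autofluorescence floor
FLUOR_BACKGROUND = 0.002


@dataclass(frozen=True)
class SceneSite:
    """One sample site: a capillary lumen or a well, with its kinetics."""

    site_id: str
    shape: dict  # {'kind': 'capillary', 'x0','x1','yc','lumen_d_mm'} or {'kind':'well','xc','yc','d_mm'}
    trace: KineticTrace | None = None  # None => blank (no dye/no sample)
    matrix: MatrixModel = field(default_factory=MatrixModel)


@dataclass(frozen=True)
class SceneBody:
    """Non-sample geometry drawn at a fixed tone (ribbon, plate, agar)."""

    shape: dict
    rgb: tuple[float, float, float]


@dataclass(frozen=True)
class ColonySceneParams:
    expected_count: float = 12.0          # Poisson mean when sampling
    appearance_mean_h: float = 4.0
    appearance_sd_h: float = 1.0
    radial_rate_mm_h: float = 0.25
    stain_intensity: float = 1.0

    def __post_init__(self) -> None:
        if min(self.expected_count, self.appearance_mean_h, self.appearance_sd_h,
               self.radial_rate_mm_h, self.stain_intensity) < 0:
            raise ValueError("colony scene parameters must be >= 0")


@dataclass(frozen=True)
class MotilitySceneParams:
    motile: bool = True
    front_speed_mm_h: float = 1.0
    inoculation_mm: tuple[float, float] = (0.0, 0.0)
    edge_width_mm: float = 0.4

    def __post_init__(self) -> None:
        if self.front_speed_mm_h < 0:
            raise ValueError("front speed must be >= 0")
        if self.motile != (self.front_speed_mm_h > 0):
            raise ValueError("speed must be 0 iff non-motile")


@dataclass
class Scene:
    """Everything in front of the camera for one labware placement."""

    variant: str  # capillary_strip | plate_wells | colony_plate | motility_plate | bar_target
    sites: list[SceneSite] = field(default_factory=list)
    bodies: list[SceneBody] = field(default_factory=list)
    colonies: list[dict] = field(default_factory=list)  # {'xc','yc','appear_min','rate_mm_min'}
    motility: MotilitySceneParams | None = None
    z_offset_mm: float = 0.0
    colony_params: ColonySceneParams | None = None


# ---------------------------------------------------------------------------
# geometry rasterisation
# ---------------------------------------------------------------------------

def _grids(center_mm, optics: OpticsModel, supersample: int):
    """Deck-coordinate x (per column) and y (per row) of supersampled pixel
    centres for a frame whose camera centre is ``center_mm``."""
    w_px, h_px = optics.sensor_px
    fx, fy = optics.fov_mm
    s = supersample
    xs = center_mm[0] - fx / 2 + (np.arange(w_px * s) + 0.5) * (fx / (w_px * s))
    ys = center_mm[1] + fy / 2 - (np.arange(h_px * s) + 0.5) * (fy / (h_px * s))
    return xs, ys


def _coverage(shape: dict, xs: np.ndarray, ys: np.ndarray, supersample: int) -> np.ndarray:
    """Per-output-pixel area coverage (0..1) of a shape, via supersampling."""
    kind = shape["kind"]
    if kind == "capillary":
        in_x = (xs >= shape["x0"]) & (xs <= shape["x1"])
        in_y = np.abs(ys - shape["yc"]) <= shape["lumen_d_mm"] / 2.0
        mask = np.outer(in_y, in_x)
    elif kind == "rect":
        in_x = (xs >= shape["x0"]) & (xs <= shape["x1"])
        in_y = (ys >= shape["y0"]) & (ys <= shape["y1"])
        mask = np.outer(in_y, in_x)
    elif kind in ("well", "disk"):
        dx2 = (xs - shape["xc"]) ** 2
        dy2 = (ys - shape["yc"]) ** 2
        mask = dy2[:, None] + dx2[None, :] <= (shape["d_mm"] / 2.0) ** 2
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    s = supersample
    h, w = mask.shape[0] // s, mask.shape[1] // s
    return mask.reshape(h, s, w, s).mean(axis=(1, 3))


def _site_rgb(site: SceneSite, t_min: float) -> np.ndarray:
    """Transmitted RGB (0..1) of a site at time t: Beer-Lambert through the
    lumen/well pathlength plus the milk scattering veil."""
    from .kinetics import EPS_RESAZURIN, EPS_RESORUFIN

    if site.trace is None:
        return np.full(3, BACKLIGHT)
    tr = site.trace
    r = np.interp(t_min, tr.t_min, tr.R)
    f = np.interp(t_min, tr.t_min, tr.F)
    a = (EPS_RESAZURIN * r + EPS_RESORUFIN * f) * tr.pathlength_mm  # per channel, BGR order? no: RGB
    w = 1.0 - math.exp(
        -site.matrix.scatter_coeff_per_mm * site.matrix.milk_fraction * tr.pathlength_mm
    )
    trans = (1.0 - w) * np.exp(-a) + w
    return BACKLIGHT * trans


def _site_fluor(site: SceneSite, t_min: float) -> float:
    """Normalised fluorescence intensity of a site at time t."""
    if site.trace is None:
        return FLUOR_SITE_OFFSET
    tr = site.trace
    r = np.interp(t_min, tr.t_min, tr.R)
    f = np.interp(t_min, tr.t_min, tr.F)
    atten = math.exp(-site.matrix.fluor_attenuation * site.matrix.milk_fraction)
    return FLUOR_SITE_OFFSET + 0.92 * ((f + DYE_DEFAULT.phi_resazurin * r) / tr.R0_ug_ml) * atten


def _paint(img: np.ndarray, cov: np.ndarray, color) -> None:
    if img.ndim == 3:
        img += cov[:, :, None] * (np.asarray(color) - img)
    else:
        img += cov * (float(color) - img)


def render_frame(
    scene: Scene,
    optics: OpticsModel,
    pose_error_um: tuple[float, float] = (0.0, 0.0),
    t_min: float = 0.0,
    seed=None,
    center_mm: tuple[float, float] = (0.0, 0.0),
    channel: str = "rgb",
    supersample: int = 2,
    add_noise: bool = True,
) -> np.ndarray:
    """Render one frame (float32 in [0, 1]) of a scene at time ``t_min``.

    ``center_mm`` is the planned camera pose; the stage lands at
    pose + pose_error, which is where the field of view is actually taken.
    Deterministic given identical inputs and seed (noise is only added when
    the optics noise model is non-trivial).
    """
    eff_center = (
        center_mm[0] + pose_error_um[0] / 1000.0,
        center_mm[1] + pose_error_um[1] / 1000.0,
    )
    xs, ys = _grids(eff_center, optics, supersample)
    w_px, h_px = optics.sensor_px

    if channel == "rgb":
        img = np.full((h_px, w_px, 3), BACKLIGHT, dtype=np.float64)
        for body in scene.bodies:
            _paint(img, _coverage(body.shape, xs, ys, supersample), body.rgb)
        if scene.motility is not None:
            _paint_motility(img, scene, xs, ys, supersample, t_min)
        for col in scene.colonies:
            rad = col["rate_mm_min"] * max(0.0, t_min - col["appear_min"])
            if rad > 0:
                cov = _coverage(
                    {"kind": "disk", "xc": col["xc"], "yc": col["yc"], "d_mm": 2 * rad},
                    xs, ys, supersample,
                )
                _paint(img, cov, COLONY_RGB)
        for site in scene.sites:
            _paint(img, _coverage(site.shape, xs, ys, supersample), _site_rgb(site, t_min))
    elif channel == "fluor":
        img = np.full((h_px, w_px), FLUOR_BACKGROUND, dtype=np.float64)
        for site in scene.sites:
            _paint(img, _coverage(site.shape, xs, ys, supersample), _site_fluor(site, t_min))
    else:
        raise ValueError(f"unknown channel {channel!r}")

    sigma = psf_sigma(optics, scene.z_offset_mm)
    if sigma > 0:
        if img.ndim == 3:
            for c in range(3):
                img[:, :, c] = ndimage.gaussian_filter(img[:, :, c], sigma, mode="nearest")
        else:
            img = ndimage.gaussian_filter(img, sigma, mode="nearest")

    if add_noise:
        img = _apply_noise(img, optics, seed)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _apply_noise(img: np.ndarray, optics: OpticsModel, seed) -> np.ndarray:
    noise = optics.noise
    if noise.shot_gain > 0 or noise.read_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise.shot_gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * noise.shot_gain) / noise.shot_gain
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma / 255.0, img.shape)
    return img


def _paint_motility(img, scene: Scene, xs, ys, supersample, t_min) -> None:
    """Radial stained front: intensity falls off sigmoidally at the front
    radius r(t) = speed * t, so the half-maximum sits at the true front."""
    mp = scene.motility
    rad = mp.front_speed_mm_h * t_min / 60.0
    x0, y0 = mp.inoculation_mm
    dist = np.sqrt((ys - y0)[:, None] ** 2 + (xs - x0)[None, :] ** 2)
    if mp.motile and rad > 0:
        # amplitude ramps in with the front so nothing is stained at t = 0
        amp = 1.0 - math.exp(-rad / (2.0 * mp.edge_width_mm))
        stain = amp / (1.0 + np.exp((dist - rad) / mp.edge_width_mm))
    else:
        # non-motile: the inoculation stab stains a fixed ~1 mm spot
        stain = 1.0 / (1.0 + np.exp((dist - 1.0) / mp.edge_width_mm))
    s = supersample
    h, w = stain.shape[0] // s, stain.shape[1] // s
    cov = stain.reshape(h, s, w, s).mean(axis=(1, 3))
    # only stain on top of agar bodies
    agar = np.zeros_like(cov)
    for body in scene.bodies:
        agar = np.maximum(agar, _coverage(body.shape, xs, ys, supersample))
    _paint(img, cov * agar, STAIN_RGB)


# ---------------------------------------------------------------------------
# time-lapse stacks on disk
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """A rendered stack: directory of frames + manifest + ground truth."""

    directory: Path
    manifest: pd.DataFrame
    truth: dict

    @classmethod
    def load(cls, directory) -> "FrameStack":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.csv")
        truth = json.loads((directory / "truth.json").read_text())
        return cls(directory=directory, manifest=manifest, truth=truth)

    def image(self, row) -> np.ndarray:
        """Load one frame (manifest row or index) as float in [0, 1]."""
        if not hasattr(row, "path"):
            row = self.manifest.iloc[int(row)]
        path = self.directory / row.path
        if path.suffix == ".tif":
            arr = tifffile.imread(path)
            return arr.astype(np.float32) / 65535.0
        arr = iio.imread(path)
        return arr.astype(np.float32) / 255.0


def _write_frame(path: Path, img: np.ndarray) -> None:
    if path.suffix == ".tif":
        tifffile.imwrite(path, np.round(img * 65535.0).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(img * 255.0).astype(np.uint8))


def _scene_extent(scene: Scene) -> tuple[float, float, float, float]:
    xs0, xs1, ys0, ys1 = [], [], [], []
    shapes = [s.shape for s in scene.sites] + [b.shape for b in scene.bodies]
    for sh in shapes:
        if sh["kind"] in ("capillary",):
            xs0.append(sh["x0"]); xs1.append(sh["x1"])
            ys0.append(sh["yc"] - sh["lumen_d_mm"] / 2); ys1.append(sh["yc"] + sh["lumen_d_mm"] / 2)
        elif sh["kind"] == "rect":
            xs0.append(sh["x0"]); xs1.append(sh["x1"]); ys0.append(sh["y0"]); ys1.append(sh["y1"])
        else:
            r = sh["d_mm"] / 2
            xs0.append(sh["xc"] - r); xs1.append(sh["xc"] + r)
            ys0.append(sh["yc"] - r); ys1.append(sh["yc"] + r)
    return min(xs0), max(xs1), min(ys0), max(ys1)


def render_timelapse(
    plan: ScanPlan,
    scenes: list[Scene],
    optics: OpticsModel,
    out_dir,
    jitter: JitterModel | None = None,
    seed: int = 0,
    channels: tuple[str, ...] = ("rgb",),
    supersample: int = 2,
) -> FrameStack:
    """Render one frame per (cycle, tile, channel) and write the stack.

    Stage jitter is drawn independently per acquisition from ``jitter``
    (default: the shipped calibration for the plan's homing policy).  Every
    scene must fall inside at least one tile's field of view; an uncovered
    scene is an error naming its extent.  Frames are named
    ``c{cycle:04d}_t{tile:03d}_{channel}.{png|tif}``; ``manifest.csv`` holds
    one row per frame with the true (jittered) pose and ``truth.json`` the
    scene parameters and master seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if jitter is None:
        jitter = jitter_for_policy(plan.homing_policy.value)

    fx, fy = optics.fov_mm
    tile_of_scene: dict[int, list[int]] = {}
    for si, scene in enumerate(scenes):
        x0, x1, y0, y1 = _scene_extent(scene)
        covering = [
            t.index
            for t in plan.tiles
            if t.center_mm[0] - fx / 2 <= x0 and x1 <= t.center_mm[0] + fx / 2
            and t.center_mm[1] - fy / 2 <= y0 and y1 <= t.center_mm[1] + fy / 2
        ]
        if not covering:
            raise ValueError(
                f"scene {si} ({scene.variant}, x [{x0:.1f},{x1:.1f}] y [{y0:.1f},{y1:.1f}] mm) "
                "is not covered by any tile's field of view"
            )
        tile_of_scene[si] = covering

    times = plan.acquisition_times_min()
    ss = np.random.SeedSequence(seed)
    n_acq = plan.n_acquisitions
    child_seeds = ss.spawn(n_acq + 1)
    jitter_rng = np.random.default_rng(child_seeds[-1])

    rows = []
    frame_idx = 0
    acq = 0
    for cycle in range(plan.n_cycles):
        for k, tile in enumerate(plan.tiles):
            t_min = times[acq]
            dx = jitter_rng.normal(0.0, jitter.sigma_x_um) if jitter.sigma_x_um > 0 else 0.0
            dy = jitter_rng.normal(0.0, jitter.sigma_y_um) if jitter.sigma_y_um > 0 else 0.0
            tile_scenes = [s for si, s in enumerate(scenes) if tile.index in tile_of_scene[si]]
            for channel in channels:
                img = None
                combine = np.maximum if channel == "fluor" else np.minimum
                for scene in tile_scenes:
                    part = render_frame(
                        scene, optics, (dx, dy), t_min,
                        seed=child_seeds[acq], center_mm=tile.center_mm,
                        channel=channel, supersample=supersample, add_noise=False,
                    )
                    img = part if img is None else combine(img, part)
                if img is None:
                    img = render_frame(
                        Scene(variant="blank"), optics, (dx, dy), t_min,
                        seed=child_seeds[acq], center_mm=tile.center_mm,
                        channel=channel, supersample=supersample, add_noise=False,
                    )
                img = np.clip(
                    _apply_noise(img.astype(np.float64), optics, child_seeds[acq]), 0.0, 1.0
                ).astype(np.float32)
                ext = "tif" if channel == "fluor" else "png"
                name = f"c{cycle:04d}_t{tile.index:03d}_{channel}.{ext}"
                _write_frame(out_dir / name, img)
                rows.append(
                    dict(frame=frame_idx, cycle=cycle, tile=tile.index, t_min=round(t_min, 4),
                         true_dx_um=dx, true_dy_um=dy, channel=channel, path=name)
                )
                frame_idx += 1
            acq += 1

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth = {
        "seed": int(seed),
        "jitter_sigma_um": [jitter.sigma_x_um, jitter.sigma_y_um],
        "homing_policy": plan.homing_policy.value,
        "n_cycles": plan.n_cycles,
        "cycle_interval_min": plan.cycle_interval_min,
        "scenes": [_scene_truth(s) for s in scenes],
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return FrameStack(directory=out_dir, manifest=manifest, truth=truth)


def _scene_truth(scene: Scene) -> dict:
    d = {"variant": scene.variant, "z_offset_mm": scene.z_offset_mm,
         "sites": [{"site_id": s.site_id, "shape": s.shape, "blank": s.trace is None}
                   for s in scene.sites]}
    if scene.colonies:
        d["colonies"] = scene.colonies
    if scene.motility is not None:
        d["motility"] = {
            "motile": scene.motility.motile,
            "front_speed_mm_h": scene.motility.front_speed_mm_h,
            "inoculation_mm": list(scene.motility.inoculation_mm),
        }
    return d


# ---------------------------------------------------------------------------
# colony / motility scene factories (the synthetic ground truth generators)
# ---------------------------------------------------------------------------

def make_colony_scene(
    params: ColonySceneParams,
    dish_center_mm: tuple[float, float],
    dish_diameter_mm: float = 90.0,
    seed: int = 0,
    n_colonies: int | None = None,
) -> Scene:
    """Agar plate with colonies at Poisson-sampled positions/appearance times."""
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(params.expected_count)) if n_colonies is None else n_colonies
    r_max = dish_diameter_mm / 2.0 - max(1.0, 0.05 * dish_diameter_mm)
    colonies = []
    for _ in range(n):
        rad = r_max * math.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * math.pi)
        colonies.append(
            dict(
                xc=dish_center_mm[0] + rad * math.cos(ang),
                yc=dish_center_mm[1] + rad * math.sin(ang),
                appear_min=max(0.0, rng.normal(params.appearance_mean_h, params.appearance_sd_h)) * 60.0,
                rate_mm_min=params.radial_rate_mm_h / 60.0,
            )
        )
    body = SceneBody(
        shape={"kind": "disk", "xc": dish_center_mm[0], "yc": dish_center_mm[1], "d_mm": dish_diameter_mm},
        rgb=tuple(AGAR_TONE),
    )
    return Scene(variant="colony_plate", bodies=[body], colonies=colonies, colony_params=params)


def make_motility_scene(
    params: MotilitySceneParams,
    well_center_mm: tuple[float, float],
    well_diameter_mm: float = 22.1,
) -> Scene:
    body = SceneBody(
        shape={"kind": "disk", "xc": well_center_mm[0], "yc": well_center_mm[1], "d_mm": well_diameter_mm},
        rgb=tuple(AGAR_TONE),
    )
    if params.inoculation_mm == (0.0, 0.0):
        params = MotilitySceneParams(
            motile=params.motile,
            front_speed_mm_h=params.front_speed_mm_h,
            inoculation_mm=well_center_mm,
            edge_width_mm=params.edge_width_mm,
        )
    return Scene(variant="motility_plate", bodies=[body], motility=params)


# ---------------------------------------------------------------------------
# bar resolution target
# ---------------------------------------------------------------------------

def render_bar_target(
    optics: OpticsModel,
    z_offset_mm: float = 0.0,
    lp_groups: tuple[float, ...] = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0),
    supersample: int = 4,
    seed=None,
) -> tuple[np.ndarray, list[dict]]:
    """Render three-bar groups (dark bars on white) at each spatial frequency.

    Returns (image, groups): image is float32 in [0,1] covering just the
    target, groups records per-frequency pixel geometry for
    :func:`polirkit.qc.resolution_from_target`.  Groups beyond the sensor
    Nyquist frequency are rejected.
    """
    pitch_mm = pixel_pitch(optics)[0] / 1000.0
    nyquist = 1.0 / (2.0 * pitch_mm)
    for lp in lp_groups:
        if lp <= 0:
            raise ValueError("lp/mm must be > 0")
        if lp > nyquist:
            raise ValueError(f"group {lp} lp/mm beyond Nyquist {nyquist:.1f} lp/mm of the optics")

    s = supersample
    sub = pitch_mm / s
    margin_mm = 1.5
    heights = [5.0 / (2.0 * lp) for lp in lp_groups]
    height_mm = max(heights) + 2 * margin_mm
    group_w = [5.0 / (2.0 * lp) for lp in lp_groups]
    width_mm = sum(group_w) + margin_mm * (len(lp_groups) + 1)

    w_px = int(round(width_mm / pitch_mm))
    h_px = int(round(height_mm / pitch_mm))
    img_hi = np.ones((h_px * s, w_px * s), dtype=np.float64)
    xs = (np.arange(w_px * s) + 0.5) * sub
    ys = (np.arange(h_px * s) + 0.5) * sub

    groups: list[dict] = []
    x_cursor = margin_mm
    for lp, gw, gh in zip(lp_groups, group_w, heights):
        bar = 1.0 / (2.0 * lp)
        y0 = (height_mm - gh) / 2.0
        in_y = (ys >= y0) & (ys <= y0 + gh)
        bar_starts = [x_cursor + 2 * i * bar for i in range(3)]
        for bx in bar_starts:
            in_x = (xs >= bx) & (xs < bx + bar)
            img_hi[np.ix_(in_y, in_x)] = 0.0
        groups.append(
            dict(
                lp_per_mm=lp,
                x_first_bar_center_px=(bar_starts[0] + bar / 2) / pitch_mm,
                x_last_bar_center_px=(bar_starts[2] + bar / 2) / pitch_mm,
                y0_px=y0 / pitch_mm,
                y1_px=(y0 + gh) / pitch_mm,
                bar_period_px=2 * bar / pitch_mm,
            )
        )
        x_cursor += gw + margin_mm

    img = img_hi.reshape(h_px, s, w_px, s).mean(axis=(1, 3))
    sigma = psf_sigma(optics, z_offset_mm)
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma, mode="nearest")
    noise = optics.noise
    if noise.shot_gain > 0 or noise.read_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise.shot_gain > 0:
            img = rng.poisson(np.clip(img, 0, None) * noise.shot_gain) / noise.shot_gain
        if noise.read_sigma > 0:
            img = img + rng.normal(0.0, noise.read_sigma / 255.0, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), groups
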