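"""Camera optics and stage positional-error models.

The default optics reproduce the published instrument: an 8-megapixel
3280 x 2464 sensor focused at 80 mm working distance giving a
96.5 x 72.5 mm field of view (~29 um/pixel), a ~10 mm depth of focus over
which an 8 lp/mm bar target stays resolved, and defocus blur growing
linearly with z outside that flat region.

Stage repeatability is modelled as independent zero-mean Gaussian error per
axis, calibrated from the mean absolute deviation (MAD) statistics measured
on the real gantry: for a centred normal E|X| = sigma*sqrt(2/pi), so
sigma = MAD*sqrt(pi/2).  Two calibrations ship as defaults — homing once at
the start of a run (MAD 20, 26 um in x, y) and homing every cycle
(MAD 35, 29 um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticsModel",
    "NoiseModel",
    "JitterModel",
    "pixel_pitch",
    "mosaic_pixels",
    "calibrate_jitter",
    "sample_pose_errors",
    "psf_sigma",
    "DEFAULT_OPTICS",
    "JITTER_MAD_UM",
]

#: Per-axis mean absolute deviation (x_um, y_um) measured on the gantry for
#: each homing policy: homing once at the start of a run, homing before every
#: cycle, and never homing (taken equal to the homed-once run it continues).
JITTER_MAD_UM: dict[str, tuple[float, float]] = {
    "once": (20.0, 26.0),
    "every_cycle": (35.0, 29.0),
    "never": (20.0, 26.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise: Gaussian read noise (8-bit DN) + Poisson shot noise.

    ``shot_gain`` is photoelectrons per DN at full scale; 0 disables shot
    noise.  Both default off so renders are exactly reproducible unless
    noise is requested.
    """

    read_sigma: float = 0.0
    shot_gain: float = 0.0


@dataclass(frozen=True)
class OpticsModel:
    sensor_px: tuple[int, int] = (3280, 2464)
    fov_mm: tuple[float, float] = (96.5, 72.5)
    working_distance_mm: float = 80.0
    focus_z_mm: float = 80.0
    dof_mm: float = 10.0
    #: in-focus PSF sigma (px) and its growth (px per mm of defocus beyond
    #: the flat region); calibrated by scripts/calibrate.py so the rendered
    #: bar target resolves 8 lp/mm in focus and degrades outside the DOF.
    sigma_min_px: float = 1.28
    blur_slope_px_per_mm: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    channels: str = "rgb"

    def __post_init__(self) -> None:
        if self.dof_mm < 0:
            raise ValueError("dof_mm must be >= 0")
        px = self.fov_mm[0] / self.sensor_px[0]
        py = self.fov_mm[1] / self.sensor_px[1]
        if abs(px - py) > 0.01 * px:
            raise ValueError(
                f"non-square pixels: pitch {px * 1e3:.2f} vs {py * 1e3:.2f} um differ by >1%"
            )


DEFAULT_OPTICS = OpticsModel()


def pixel_pitch(optics: OpticsModel) -> tuple[float, int]:
    """(exact um/pixel, nearest-integer um/pixel) for the x axis.

    The constructor enforces square pixels to 1%, so this is the pitch for
    both axes; the default optics give 96.5 mm / 3280 px = 29.42 -> 29 um.
    """
    exact = 1000.0 * optics.fov_mm[0] / optics.sensor_px[0]
    return exact, int(round(exact))


def mosaic_pixels(span_mm: float, optics: OpticsModel) -> int:
    """Effective pixel count across a tiled span at the native pixel pitch."""
    if span_mm <= 0:
        raise ValueError("span_mm must be > 0")
    exact_um, _ = pixel_pitch(optics)
    return math.floor(span_mm / (exact_um / 1000.0))


#: E|X| = sigma*sqrt(2/pi) for X ~ N(0, sigma^2)
_MAD_TO_SIGMA = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class JitterModel:
    """Zero-mean Gaussian positional error, independent per axis."""

    sigma_x_um: float
    sigma_y_um: float
    family: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma_x_um < 0 or self.sigma_y_um < 0:
            raise ValueError("jitter sigma must be >= 0")

    @property
    def mad_x_um(self) -> float:
        return self.sigma_x_um / _MAD_TO_SIGMA

    @property
    def mad_y_um(self) -> float:
        return self.sigma_y_um / _MAD_TO_SIGMA


def calibrate_jitter(mad_x_um: float, mad_y_um: float) -> JitterModel:
    """Jitter model whose per-axis mean absolute deviation matches the
    measured values (sigma = MAD*sqrt(pi/2))."""
    if mad_x_um < 0 or mad_y_um < 0:
        raise ValueError("mean absolute deviation must be >= 0")
    return JitterModel(sigma_x_um=mad_x_um * _MAD_TO_SIGMA, sigma_y_um=mad_y_um * _MAD_TO_SIGMA)


def jitter_for_policy(policy: str) -> JitterModel:
    """Shipped calibration for a homing policy ('once'/'every_cycle'/'never')."""
    mad_x, mad_y = JITTER_MAD_UM[str(getattr(policy, "value", policy))]
    return calibrate_jitter(mad_x, mad_y)


def sample_pose_errors(model: JitterModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` (dx_um, dy_um) pose errors; shape (n, 2), reproducible
    given the seed (any ``np.random.default_rng`` seed type)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n, 2))
    out[:, 0] = rng.normal(0.0, model.sigma_x_um, n) if model.sigma_x_um > 0 else 0.0
    out[:, 1] = rng.normal(0.0, model.sigma_y_um, n) if model.sigma_y_um > 0 else 0.0
    return out


def psf_sigma(optics: OpticsModel, z_offset_mm: float) -> float:
    """Gaussian PSF sigma (pixels) at a height offset from best focus.

    Flat at ``sigma_min_px`` across the depth of focus (|z| <= dof/2), then
    growing linearly at ``blur_slope_px_per_mm``; even in z_offset.
    """
    excess = abs(z_offset_mm) - optics.dof_mm / 2.0
    if excess <= 0:
        return optics.sigma_min_px
    return optics.sigma_min_px + optics.blur_slope_px_per_mm * excess
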