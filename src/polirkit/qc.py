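"""Instrument QC: stage positional-accuracy statistics and optical
resolution from bar-target images.

Positional accuracy is summarised the way gantry repeatability is reported
in practice: the mean absolute deviation (MAD) of repeated localizations of
a fixed target from their mean, per axis, plus the fraction of acquisitions
landing within 100 um (Euclidean) of the 2-D mean.  The same statistics run
on simulator ground-truth poses or on registration-derived localizations.

Resolution follows the classic bar-target reading: a group of three bars at
f lp/mm is "resolved" when the Michelson contrast (Imax - Imin)/(Imax + Imin)
of the intensity profile across the bars is at least 0.1 (the criterion is
configurable; visual reading has no standard threshold).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "positional_stats",
    "resolution_from_target",
    "group_contrast",
    "dof_width",
    "line_width_from_lp",
]


def positional_stats(locs_um: np.ndarray, radius_um: float = 100.0) -> dict:
    """MAD per axis and the within-radius fraction for (n, 2) localizations.

    ``mad_*`` is mean |coordinate - mean coordinate|; ``frac_within`` uses
    Euclidean distance to the 2-D mean (the x-y scatter convention).
    """
    locs = np.asarray(locs_um, dtype=float)
    if locs.ndim != 2 or locs.shape[1] != 2 or len(locs) < 2:
        raise ValueError("need at least 2 (x, y) localizations")
    mean = locs.mean(axis=0)
    dev = locs - mean
    dist = np.hypot(dev[:, 0], dev[:, 1])
    return {
        "mad_x_um": float(np.abs(dev[:, 0]).mean()),
        "mad_y_um": float(np.abs(dev[:, 1]).mean()),
        "frac_within_100um": float((dist <= radius_um).mean()),
        "n": len(locs),
    }


def group_contrast(image: np.ndarray, group: dict) -> float:
    """Michelson contrast of one three-bar group.

    The profile runs perpendicular to the bars, averaged along their length,
    and is windowed from the first to the last bar centre so the bright
    surround does not inflate the maximum.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    y0 = int(math.floor(group["y0_px"])) + 1
    y1 = int(math.ceil(group["y1_px"])) - 1
    profile = img[max(y0, 0) : max(y1, y0 + 1)].mean(axis=0)
    x0 = int(round(group["x_first_bar_center_px"]))
    x1 = int(round(group["x_last_bar_center_px"]))
    window = profile[max(x0, 0) : min(x1 + 1, len(profile))]
    if len(window) < 3:
        return 0.0
    imax, imin = float(window.max()), float(window.min())
    if imax + imin <= 0:
        return 0.0
    return (imax - imin) / (imax + imin)


def resolution_from_target(
    image: np.ndarray,
    groups: list[dict],
    contrast_threshold: float = 0.1,
) -> float:
    """Finest resolvable spatial frequency (lp/mm) on a bar-target image.

    Returns 0 (with a warning) when no rendered group reaches the contrast
    threshold.
    """
    resolved = [
        g["lp_per_mm"] for g in groups if group_contrast(image, g) >= contrast_threshold
    ]
    if not resolved:
        import warnings

        warnings.warn("no bar group resolvable at the contrast threshold", stacklevel=2)
        return 0.0
    return float(max(resolved))


def dof_width(curve: pd.DataFrame) -> float:
    """Width (mm) of the contiguous z interval at maximal resolution.

    ``curve`` has columns ``z_mm`` (sorted) and ``lp_per_mm``.  The flat
    region's boundaries are placed by linear interpolation between the last
    sample at the maximum and its sub-maximal neighbour, at the halfway
    resolution level.  The flat region must be bracketed (sub-maximal
    samples on both sides).
    """
    z = curve["z_mm"].to_numpy(dtype=float)
    lp = curve["lp_per_mm"].to_numpy(dtype=float)
    if len(z) < 5:
        raise ValueError("need >= 5 z samples spanning the flat region")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z_mm must be strictly increasing")
    top = lp.max()
    at_max = np.where(lp >= top - 1e-9)[0]
    i0, i1 = at_max.min(), at_max.max()
    if i0 == 0 or i1 == len(z) - 1:
        raise ValueError("flat region not bracketed by sub-maximal samples")
    if not np.all(lp[i0 : i1 + 1] >= top - 1e-9):
        raise ValueError("maximal-resolution region is not contiguous")

    def _edge(i_in: int, i_out: int) -> float:
        lo = lp[i_out]
        if top - lo <= 1e-12:
            return z[i_out]
        half = (top + lo) / 2.0
        return z[i_in] + (z[i_out] - z[i_in]) * (top - half) / (top - lo)

    left = _edge(i0, i0 - 1)
    right = _edge(i1, i1 + 1)
    return float(right - left)


def line_width_from_lp(lp_per_mm: float) -> int:
    """Single-line width in integer um for a spatial frequency: one line is
    half a line pair, floored to whole micrometres (8 lp/mm -> 62 um)."""
    if lp_per_mm <= 0:
        raise ValueError("lp/mm must be > 0")
    return math.floor(1000.0 / (2.0 * lp_per_mm))
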