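"""Canned simulation scenarios: the study conditions used throughout the
tests, pipeline and reproduction script.

These builders wire the kinetics packs, matrix models and detection rules
into the standard assay formats: a ten-capillary susceptibility strip
(6 no-drug control lanes, 2 gentamicin, 2 ampicillin — the screening
layout), four-step ten-fold dilution series for doubling-time estimation,
and the fluorescence-vs-colour detection comparison.  Trace-level noise is
multiplicative Gaussian on the measured intensity (2% default), emulating
illumination and extraction noise without rendering images.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import kinetics as kin
from .analysis import (
    DetectionRule,
    DoublingTimeEstimate,
    GrowthCall,
    SusceptibilityCall,
    call_susceptibility,
    detect_growth,
    estimate_doubling_time,
)
from .instrument import Scene, SceneBody, SceneSite

__all__ = [
    "MCF_PATHLENGTH_MM",
    "MTP_PATHLENGTH_MM",
    "reference_trace",
    "detection_gap_hours",
    "dilution_series_ttps",
    "dilution_series_estimate",
    "susceptibility_panel",
    "milk_gentamicin_verdicts",
    "color_full_range",
    "strip_scene",
]

MCF_PATHLENGTH_MM = 0.206
MTP_PATHLENGTH_MM = 3.0
DEFAULT_NOISE_SD = 0.02
#: standard acquisition grids: colour runs overnight at 10 min frames,
#: fluorescence screening runs 12 h at 30 min frames
T_GRID_OVERNIGHT = np.arange(0.0, 960.0 + 1e-9, 10.0)
T_GRID_SCREEN = np.arange(0.0, 720.0 + 1e-9, 30.0)


def color_full_range(R0_ug_ml: float = 250.0, pathlength_mm: float = MTP_PATHLENGTH_MM) -> float:
    """Blue-to-pink index swing for complete conversion in clear broth —
    the reference scale for the colorimetric min_range floor."""
    d_f = kin.EPS_RESORUFIN[2] - kin.EPS_RESORUFIN[0]
    d_r = kin.EPS_RESAZURIN[2] - kin.EPS_RESAZURIN[0]
    return float((d_f - d_r) * R0_ug_ml * pathlength_mm)


def reference_trace(
    pack: str = "ecoli_25922",
    mode: str = "colorimetric",
    matrix: kin.MatrixModel = kin.BROTH,
    t_grid: np.ndarray | None = None,
    pathlength_mm: float = MCF_PATHLENGTH_MM,
    dilution: int = 0,
    exposure: kin.AntibioticExposure | None = None,
) -> kin.KineticTrace:
    """Simulate the shipped pack under standard conditions.

    ``mode`` selects the dye load (250 ug/mL colorimetric, 60 fluorescent);
    ``dilution`` divides the pack inoculum by 10^dilution.
    """
    growth = kin.GROWTH_PACKS[pack]["growth"]
    if dilution:
        growth = replace(growth, N0=growth.N0 / 10.0 ** dilution)
    if exposure is not None:
        growth = kin.apply_antibiotic(growth, exposure, matrix)
    dye = replace(
        kin.DYE_DEFAULT,
        R0_ug_ml=kin.R0_FLUORESCENT if mode == "fluorescence" else 250.0,
    )
    if t_grid is None:
        t_grid = T_GRID_OVERNIGHT
    return kin.simulate_dye(growth, dye, matrix, t_grid, pathlength_mm=pathlength_mm)


def detection_gap_hours(pack: str = "ecoli_25922") -> dict:
    """Fluorescence-vs-colour detection comparison on the default scenario.

    Simulates the pack in clear broth (capillary pathlength, overnight
    colour grid), applies the shipped colorimetric and fluorescence rules,
    and returns both TTPs plus the gap in hours (positive: fluorescence
    earlier).
    """
    trace = reference_trace(pack, mode="colorimetric")
    ab = kin.absorbance_signal(trace)
    fl = kin.fluorescence_signal(trace)
    c = detect_growth(trace.t_min, ab["B_index"].to_numpy(), DetectionRule(mode="colorimetric"))
    f = detect_growth(trace.t_min, fl["I_fluor"].to_numpy(), DetectionRule(mode="fluorescence"))
    gap = None
    if c.detected and f.detected:
        gap = (c.ttp_min - f.ttp_min) / 60.0
    return {
        "ttp_color_min": c.ttp_min,
        "ttp_fluor_min": f.ttp_min,
        "gap_h": gap,
    }


def dilution_series_ttps(
    pack: str = "ecoli_25922",
    n_dilutions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = 0,
    t_grid: np.ndarray | None = None,
) -> dict[int, float | None]:
    """Fluorescence TTP per ten-fold dilution (index 0 = pack inoculum)."""
    if t_grid is None:
        t_grid = T_GRID_SCREEN
    rng = np.random.default_rng(seed)
    rule = DetectionRule(mode="fluorescence")
    out: dict[int, float | None] = {}
    for d in range(n_dilutions):
        trace = reference_trace(pack, mode="fluorescence", t_grid=t_grid, dilution=d)
        sig = kin.fluorescence_signal(trace)["I_fluor"].to_numpy()
        if noise_sd > 0:
            sig = sig * (1.0 + rng.normal(0.0, noise_sd, sig.shape))
        call = detect_growth(t_grid, sig, rule)
        out[d] = call.ttp_min
    return out


def dilution_series_estimate(
    pack: str = "ecoli_25922",
    n_dilutions: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = 0,
) -> DoublingTimeEstimate:
    """Doubling time recovered from a simulated dilution series."""
    t_grid = T_GRID_SCREEN
    if kin.GROWTH_PACKS[pack]["growth"].doubling_time_min > 30:
        # slow packs need the overnight window for the most dilute lanes
        t_grid = T_GRID_OVERNIGHT
    return estimate_doubling_time(
        dilution_series_ttps(pack, n_dilutions, noise_sd, seed, t_grid)
    )


#: screening strip lane layout: 10 capillaries per strip
STRIP_LANES = ["control"] * 6 + ["gentamicin"] * 2 + ["ampicillin"] * 2


def susceptibility_panel(
    pack: str = "ecoli_25922",
    matrix: kin.MatrixModel = kin.BROTH,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    control_fails: bool = False,
    mode: str = "fluorescence",
    pathlength_mm: float = MCF_PATHLENGTH_MM,
    t_grid: np.ndarray | None = None,
) -> list[SusceptibilityCall]:
    """Simulate one screening strip and call susceptibility.

    Six no-drug control capillaries and duplicate gentamicin/ampicillin
    lanes; ``control_fails`` zeroes the inoculum (a non-viable sample) so
    the verdict degrades to nd.
    """
    info = kin.GROWTH_PACKS[pack]
    rng = np.random.default_rng(seed)
    if t_grid is None:
        t_grid = T_GRID_SCREEN if mode == "fluorescence" else T_GRID_OVERNIGHT
    if mode == "fluorescence":
        rule = DetectionRule(mode="fluorescence")
    else:
        rule = DetectionRule(
            mode="colorimetric",
            min_range=0.05 * color_full_range(250.0, pathlength_mm),
        )

    def lane_call(drug: str | None) -> GrowthCall:
        if control_fails:
            trace = _sterile_trace(mode, matrix, t_grid, pathlength_mm)
        else:
            exposure = None
            if drug is not None:
                exposure = kin.AntibioticExposure(
                    drug=drug, present=True, susceptible=info[f"{drug}_susceptible"]
                )
            trace = reference_trace(
                pack, mode=mode, matrix=matrix, t_grid=t_grid,
                pathlength_mm=pathlength_mm, exposure=exposure,
            )
        if mode == "fluorescence":
            sig = kin.fluorescence_signal(trace, matrix)["I_fluor"].to_numpy()
        else:
            sig = kin.absorbance_signal(trace, matrix)["B_index"].to_numpy()
        if noise_sd > 0:
            scale = np.abs(sig).max() or 1.0
            sig = sig + rng.normal(0.0, noise_sd * scale, sig.shape)
        return detect_growth(t_grid, sig, rule)

    control_calls = [lane_call(None) for _ in range(6)]
    drug_calls = {
        "gentamicin": [lane_call("gentamicin") for _ in range(2)],
        "ampicillin": [lane_call("ampicillin") for _ in range(2)],
    }
    return call_susceptibility(control_calls, drug_calls, isolate=pack)


def _sterile_trace(mode, matrix, t_grid, pathlength_mm):
    growth = kin.GrowthModel(N0=0.0, doubling_time_min=16.0, lag_min=0.0, K=1e9)
    dye = replace(
        kin.DYE_DEFAULT, R0_ug_ml=kin.R0_FLUORESCENT if mode == "fluorescence" else 250.0
    )
    return kin.simulate_dye(growth, dye, matrix, t_grid, pathlength_mm=pathlength_mm)


def milk_gentamicin_verdicts(
    pack: str = "ecoli_25922",
    milk_fractions=(0.0, 0.1, 0.5, 0.9),
) -> dict[float, str]:
    """Gentamicin verdict for a susceptible isolate across milk fractions.

    Reproduces the matrix-interference outcome: at low milk the drug
    suppresses growth (S); at high milk fractions the matrix inactivates
    the drug and the lane reads as apparent growth (R) — the reason
    undiluted milk samples cannot be tested directly.
    """
    out = {}
    for m in milk_fractions:
        calls = susceptibility_panel(
            pack,
            matrix=kin.MatrixModel(milk_fraction=m),
            mode="colorimetric",
            pathlength_mm=MTP_PATHLENGTH_MM,
        )
        out[m] = next(c.verdict for c in calls if c.drug == "gentamicin")
    return out


def strip_scene(
    traces: list[tuple[str, kin.KineticTrace | None]],
    origin_mm: tuple[float, float] = (1.0, 2.0),
    length_mm: float = 5.0,
    capillary_pitch_mm: float = 0.4,
    lumen_d_mm: float = 0.206,
    matrix: kin.MatrixModel = kin.BROTH,
    z_offset_mm: float = 0.0,
) -> Scene:
    """A microcapillary-film strip scene: parallel capillaries along x.

    ``traces`` maps site ids to kinetic traces (None = blank lane); the FEP
    ribbon is drawn as a light body behind the lumens.
    """
    x0, y0 = origin_mm
    sites = []
    for i, (site_id, trace) in enumerate(traces):
        yc = y0 + i * capillary_pitch_mm
        sites.append(
            SceneSite(
                site_id=site_id,
                shape={"kind": "capillary", "x0": x0, "x1": x0 + length_mm,
                       "yc": yc, "lumen_d_mm": lumen_d_mm},
                trace=trace,
                matrix=matrix,
            )
        )
    pad = capillary_pitch_mm
    body = SceneBody(
        shape={"kind": "rect", "x0": x0 - 0.5, "x1": x0 + length_mm + 0.5,
               "y0": y0 - pad, "y1": y0 + (len(traces) - 1) * capillary_pitch_mm + pad},
        rgb=(0.88, 0.88, 0.88),
    )
    return Scene(variant="capillary_strip", sites=sites, bodies=[body], z_offset_mm=z_offset_mm)
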