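"""Bacterial growth and resazurin redox kinetics per sample site.

Growth follows a lagged logistic: density holds at the inoculum N0 through
the lag, then grows at rate r = ln2/t_d towards carrying capacity K,

    N(t) = K / (1 + (K/N0 - 1) * exp(-r (t - lag))),   t > lag.

Metabolically active cells reduce the blue, weakly fluorescent dye resazurin
(R) to pink, strongly fluorescent resorufin (F), which can be further
reduced to colourless, non-fluorescent dihydroresorufin (D) — hence the
transient fluorescent signal seen in fast metabolisers.  The minimal
first-order per-cell scheme is

    dR/dt = -(k1 N(t) + k0 m) R
    dF/dt =  (k1 N(t) + k0 m) R - k2 N(t) F
    dD/dt =  k2 N(t) F

with m the milk fraction of the matrix: milk slowly converts the dye even
without bacteria (k0), scatters light (washing out colour contrast), and
inactivates antibiotics.  Total dye R + F + D is conserved exactly.

Optical signals derive from the concentrations: per-RGB-channel
Beer-Lambert absorbance over the sample pathlength (206 um capillary lumen
versus ~3 mm microtitre well — the short path is why capillary colour is
paler), a blue-to-pink colour index B = A_blue - A_red used for colorimetric
growth detection, and a fluorescence intensity proportional to
F + phi_R * R (resazurin itself is weakly fluorescent, giving the non-zero
baseline that relative detection rules normalise against).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GrowthModel",
    "DyeModel",
    "MatrixModel",
    "AntibioticExposure",
    "KineticTrace",
    "growth_curve",
    "simulate_dye",
    "absorbance_signal",
    "fluorescence_signal",
    "apply_antibiotic",
    "GROWTH_PACKS",
    "DYE_DEFAULT",
    "EPS_RESAZURIN",
    "EPS_RESORUFIN",
]


@dataclass(frozen=True)
class GrowthModel:
    """Lagged-logistic growth parameters (CFU/mL, minutes)."""

    N0: float
    doubling_time_min: float
    lag_min: float = 60.0
    K: float = 1e9
    #: fraction of cells metabolically active (scales per-cell dye reduction);
    #: bactericidal drug action drives this toward 0 along with the growth rate
    metabolic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.N0 < 0:
            raise ValueError("N0 must be >= 0")
        if self.doubling_time_min <= 0:
            raise ValueError("doubling_time_min must be > 0")
        if self.N0 > 0 and self.K < self.N0:
            raise ValueError("carrying capacity K must be >= N0")

    @property
    def rate_per_min(self) -> float:
        return math.log(2.0) / self.doubling_time_min


@dataclass(frozen=True)
class DyeModel:
    """Resazurin load and per-cell reduction rates.

    ``k1``/``k2`` are mL CFU^-1 min^-1; the shipped values were fixed once by
    scripts/calibrate.py so that the reference E. coli pack detects ~2 h
    earlier by fluorescence than by colour and is fully converted overnight.
    """

    R0_ug_ml: float = 250.0
    k1: float = 6.5e-12
    k2: float = 6.5e-13
    phi_resazurin: float = 0.001  # fluorescence yield of R relative to F

    def __post_init__(self) -> None:
        if self.R0_ug_ml <= 0:
            raise ValueError("R0 must be > 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rates must be >= 0")


#: fluorescent-mode dye load (ug/mL); colorimetric mode uses 250
R0_FLUORESCENT = 60.0


@dataclass(frozen=True)
class MatrixModel:
    """Sample-matrix (milk) effects, each with its own coefficient."""

    milk_fraction: float = 0.0
    scatter_coeff_per_mm: float = 0.4     # turbid veil: w = 1 - exp(-c*m*l)
    background_rate_k0: float = 2e-5      # min^-1 per unit milk fraction
    fluor_attenuation: float = 1.0        # exp(-a*m) on fluorescence

    def __post_init__(self) -> None:
        if not 0.0 <= self.milk_fraction <= 1.0:
            raise ValueError("milk_fraction must be in [0, 1]")
        if min(self.scatter_coeff_per_mm, self.background_rate_k0, self.fluor_attenuation) < 0:
            raise ValueError("matrix coefficients must be >= 0")


BROTH = MatrixModel()


@dataclass(frozen=True)
class AntibioticExposure:
    drug: str = "gentamicin"
    present: bool = True
    susceptible: bool = True           # simulation ground truth
    base_effect: float = 1.0           # 1 = complete growth suppression
    matrix_inactivation: float = 1.0   # drug effect lost as milk rises

    def __post_init__(self) -> None:
        if not 0.0 <= self.matrix_inactivation <= 1.0:
            raise ValueError("matrix_inactivation must be in [0, 1]")
        if not 0.0 <= self.base_effect <= 1.0:
            raise ValueError("base_effect must be in [0, 1]")


def growth_curve(growth: GrowthModel, t_min) -> np.ndarray:
    """Cell density N(t) in CFU/mL for scalar or array times (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if growth.N0 == 0 or not math.isfinite(growth.doubling_time_min):
        return np.broadcast_to(float(growth.N0), t.shape).copy()
    r = growth.rate_per_min
    tau = np.clip(t - growth.lag_min, 0.0, None)
    a = (growth.K / growth.N0) - 1.0
    n = growth.K / (1.0 + a * np.exp(-r * tau))
    return n


def apply_antibiotic(
    growth: GrowthModel, exposure: AntibioticExposure, matrix: MatrixModel = BROTH
) -> GrowthModel:
    """Growth model under drug exposure.

    A susceptible isolate's growth rate is multiplied by (1 - effect) with
    effect = base_effect * (1 - matrix_inactivation * milk_fraction): in
    clean broth the drug suppresses growth completely (flat N = N0), while a
    high milk fraction soaks up the drug and growth resumes — the false
    "resistant" readout that makes undiluted milk samples untestable.
    Resistant isolates are unchanged.
    """
    if not exposure.present or not exposure.susceptible:
        return growth
    effect = exposure.base_effect * (1.0 - exposure.matrix_inactivation * matrix.milk_fraction)
    remaining = 1.0 - effect
    if remaining <= 1e-12:
        return replace(growth, doubling_time_min=math.inf, metabolic_fraction=0.0)
    return replace(
        growth,
        doubling_time_min=growth.doubling_time_min / remaining,
        metabolic_fraction=growth.metabolic_fraction * remaining,
    )


@dataclass(frozen=True)
class KineticTrace:
    """Time series of densities/concentrations for one sample site."""

    t_min: np.ndarray
    N: np.ndarray
    R: np.ndarray
    F: np.ndarray
    D: np.ndarray
    pathlength_mm: float = 0.206
    R0_ug_ml: float = 250.0

    def __post_init__(self) -> None:
        n = len(self.t_min)
        if not (len(self.N) == len(self.R) == len(self.F) == len(self.D) == n):
            raise ValueError("trace series must have equal length")
        total = self.R + self.F + self.D
        if np.max(np.abs(total - self.R0_ug_ml)) > 1e-6 * self.R0_ug_ml:
            raise ValueError("dye mass conservation violated beyond 1e-6*R0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_min": self.t_min, "N": self.N, "R": self.R, "F": self.F, "D": self.D}
        )


def simulate_dye(
    growth: GrowthModel,
    dye: DyeModel,
    matrix: MatrixModel = BROTH,
    t_grid=None,
    pathlength_mm: float = 0.206,
    max_step_min: float = 1.0,
) -> KineticTrace:
    """Integrate the three-species dye system along ``t_grid`` (minutes).

    Fixed-step classical RK4 with steps no longer than ``max_step_min``
    (1 min default — the kinetics are minutes-scale and only mildly stiff).
    The right-hand side sums to zero exactly, so RK4 conserves R+F+D to
    rounding error; the trace constructor enforces 1e-6*R0.
    """
    if t_grid is None:
        t_grid = np.arange(0.0, 960.0 + 1e-9, 10.0)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")

    k0m = matrix.background_rate_k0 * matrix.milk_fraction

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = float(growth_curve(growth, t)) * growth.metabolic_fraction
        red = (dye.k1 * n + k0m) * y[0]
        over = dye.k2 * n * y[1]
        return np.array([-red, red - over, over])

    y = np.array([dye.R0_ug_ml, 0.0, 0.0])
    out = np.empty((len(t_grid), 3))
    out[0] = y
    for i in range(1, len(t_grid)):
        t0, t1 = t_grid[i - 1], t_grid[i]
        nsub = max(1, math.ceil((t1 - t0) / max_step_min - 1e-12))
        h = (t1 - t0) / nsub
        t = t0
        for _ in range(nsub):
            k1_ = rhs(t, y)
            k2_ = rhs(t + h / 2, y + h / 2 * k1_)
            k3_ = rhs(t + h / 2, y + h / 2 * k2_)
            k4_ = rhs(t + h, y + h * k3_)
            y = y + (h / 6.0) * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
            t += h
        y = np.clip(y, 0.0, None)
        y *= dye.R0_ug_ml / y.sum()  # renormalise rounding drift
        out[i] = y

    return KineticTrace(
        t_min=t_grid,
        N=growth_curve(growth, t_grid),
        R=out[:, 0],
        F=out[:, 1],
        D=out[:, 2],
        pathlength_mm=pathlength_mm,
        R0_ug_ml=dye.R0_ug_ml,
    )


# ---------------------------------------------------------------------------
# Optical signals
# ---------------------------------------------------------------------------

def _eps_from_color(rgb: tuple[int, int, int], conc: float, path_mm: float) -> np.ndarray:
    """Per-channel extinction (per ug/mL per mm) whose transmitted colour on a
    white backlight equals ``rgb`` at the reference concentration/path."""
    c = np.asarray(rgb, dtype=float) / 255.0
    return -np.log(c) / (conc * path_mm)


#: transmitted colours at 250 ug/mL through 1 mm: resazurin blue, resorufin pink
EPS_RESAZURIN = _eps_from_color((60, 80, 190), 250.0, 1.0)
EPS_RESORUFIN = _eps_from_color((230, 105, 160), 250.0, 1.0)


def chemical_absorbance(trace: KineticTrace) -> pd.DataFrame:
    """Beer-Lambert absorbance per RGB channel, A_c = (eps_cR R + eps_cF F) l."""
    conc = np.stack([trace.R, trace.F])  # (2, T)
    eps = np.stack([EPS_RESAZURIN, EPS_RESORUFIN])  # (2, 3)
    a = trace.pathlength_mm * (conc.T @ eps)  # (T, 3)
    return pd.DataFrame(a, columns=["A_red", "A_green", "A_blue"]).assign(t_min=trace.t_min)


def absorbance_signal(trace: KineticTrace, matrix: MatrixModel = BROTH) -> pd.DataFrame:
    """Apparent absorbance seen by the camera, with the milk scattering veil.

    Scattered light bypasses the dye, so the camera sees transmittance
    T_c = (1-w) exp(-A_c) + w with veil fraction w = 1 - exp(-c m l); the
    apparent absorbance is -ln T_c.  At milk = 0 this is plain Beer-Lambert,
    linear in pathlength; as milk rises the veil compresses every channel
    towards zero, shrinking the blue-to-pink index range the way an opaque
    milky sample washes out colour.  Columns: A_* (apparent, per channel) and
    the colour index B = A_blue - A_red.
    """
    chem = chemical_absorbance(trace)
    w = 1.0 - math.exp(
        -matrix.scatter_coeff_per_mm * matrix.milk_fraction * trace.pathlength_mm
    )
    out = {"t_min": trace.t_min}
    for c in ("A_red", "A_green", "A_blue"):
        out[c] = -np.log((1.0 - w) * np.exp(-chem[c].to_numpy()) + w)
    df = pd.DataFrame(out)
    df["B_index"] = df["A_blue"] - df["A_red"]
    return df


def fluorescence_signal(
    trace: KineticTrace,
    matrix: MatrixModel = BROTH,
    gain: float = 1000.0,
    phi_resazurin: float | None = None,
) -> pd.DataFrame:
    """Fluorescence intensity I = g (F + phi R) exp(-a m), plus the
    baseline-normalised variant I/I(0) used by relative detection rules."""
    atten = math.exp(-matrix.fluor_attenuation * matrix.milk_fraction)
    phi = DYE_DEFAULT.phi_resazurin if phi_resazurin is None else phi_resazurin
    intensity = gain * (trace.F + phi * trace.R) * atten
    i0 = intensity[0] if intensity[0] > 0 else 1.0
    return pd.DataFrame(
        {"t_min": trace.t_min, "I_fluor": intensity, "I_norm": intensity / i0}
    )


# ---------------------------------------------------------------------------
# Shipped parameter packs
# ---------------------------------------------------------------------------

#: Reference growth parameter packs.  Doubling times are the shipped ground
#: truths used throughout the tests: the E. coli ATCC 25922 reference strain
#: (16 min) and a slow Klebsiella mastitis isolate (49 min, ampicillin
#: resistant).  Inoculum 5e5 CFU/mL follows BSAC susceptibility practice.
GROWTH_PACKS: dict[str, dict] = {
    "ecoli_25922": {
        "growth": GrowthModel(N0=5e5, doubling_time_min=16.0, lag_min=60.0, K=1e9),
        "gentamicin_susceptible": True,
        "ampicillin_susceptible": True,
    },
    "isolate22_kleb": {
        "growth": GrowthModel(N0=5e5, doubling_time_min=49.0, lag_min=60.0, K=1e9),
        "gentamicin_susceptible": True,
        "ampicillin_susceptible": False,
    },
    "saureus_12600": {
        "growth": GrowthModel(N0=5e5, doubling_time_min=30.0, lag_min=90.0, K=5e8),
        "gentamicin_susceptible": True,
        "ampicillin_susceptible": True,
    },
}

DYE_DEFAULT = DyeModel()
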