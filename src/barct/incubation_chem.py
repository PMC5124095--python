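"""Chamber-incubation chemistry: alkalinity-anomaly calcification, O₂
fluxes, and a seawater carbonate-system solver.

Closed-chamber incubations measure community metabolism of a colonized
carbonate block: precipitation of 1 mol CaCO₃ removes 2 mol of total
alkalinity (A_T), so the blank-corrected A_T change over a run gives net
calcification (positive) or net dissolution (negative); the dissolved-O₂
change gives net photosynthesis (light) and respiration (dark). Rates are
normalized to the block's post-deployment surface area. A 24-h net
calcification combines light and dark rates weighted by 11 h of daylight
and 13 h of night.

The carbonate-system solver converts measured (A_T, DIC, T, S) into pH
(total scale), pCO₂ and the aragonite saturation state Ω_arag using a
standard seawater dissociation-constant set (documented in
:data:`CARBONATE_CONSTANTS_DOC`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SEAWATER_DENSITY_KG_L",
    "IncubationRecord",
    "ChamberRates",
    "CarbonateState",
    "blank_correct",
    "calcification_rate",
    "oxygen_flux",
    "net_daily_calcification",
    "chamber_rates",
    "rates_table",
    "records_to_frame",
    "frame_to_records",
    "carbonate_constants",
    "solve_carbonate_system",
]

#: Default seawater density (kg L⁻¹) at ~29 °C, S 35, used to convert the
#: chamber volume (litres) to the seawater mass that A_T (µmol kg⁻¹) refers to.
SEAWATER_DENSITY_KG_L = 1.023

#: Hours of daylight / night assumed when averaging calcification over 24 h.
DAYLIGHT_HOURS = 11.0
NIGHT_HOURS = 13.0

CARBONATE_CONSTANTS_DOC = (
    "pH on the total scale; K1/K2 from Lueker et al. (2000); KB from "
    "Dickson (1990); KW from Millero (1995, DOE handbook form); K0 from "
    "Weiss (1974); aragonite Ksp from Mucci (1983); borate from Uppström "
    "(1974); calcium from Riley & Tongudai (1967). Nutrient and fluoride "
    "alkalinity are neglected."
)


@dataclass
class IncubationRecord:
    """One closed-chamber run (or a paired blank chamber without a block)."""

    chamber_id: str
    is_blank: bool
    phase: str                       # "light" or "dark"
    at_initial: float                # µmol kg⁻¹
    at_final: float
    o2_initial: float                # mg L⁻¹
    o2_final: float
    chamber_volume_l: float
    duration_min: float
    surface_area_cm2: float | None   # post-deployment block area; None for blanks
    treatment_ph: float = float("nan")
    seawater_density_kg_l: float = SEAWATER_DENSITY_KG_L

    def __post_init__(self) -> None:
        if self.phase not in ("light", "dark"):
            raise ValueError(f"phase must be 'light' or 'dark', got {self.phase!r}")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.chamber_volume_l <= 0:
            raise ValueError("chamber volume must be positive")
        if not self.is_blank and (self.surface_area_cm2 is None or self.surface_area_cm2 <= 0):
            raise ValueError("non-blank records need a positive block surface area")

    @property
    def delta_at(self) -> float:
        """Final − initial total alkalinity (µmol kg⁻¹)."""
        return self.at_final - self.at_initial

    @property
    def delta_o2(self) -> float:
        """Final − initial dissolved O₂ (mg L⁻¹)."""
        return self.o2_final - self.o2_initial

    @property
    def seawater_mass_kg(self) -> float:
        return self.chamber_volume_l * self.seawater_density_kg_l


@dataclass(frozen=True)
class ChamberRates:
    """Per-block incubation rate estimates.

    Calcification in µmol CaCO₃ cm⁻² h⁻¹; O₂ fluxes in µg O₂ cm⁻² min⁻¹.
    ``r_dark`` is reported as O₂ consumption (positive magnitude); the
    signed dark flux is kept in ``dark_o2_flux``.
    """

    g_light: float
    g_dark: float
    g_24h: float
    p_net: float
    r_dark: float
    dark_o2_flux: float
    treatment_ph: float = float("nan")

    def __post_init__(self) -> None:
        lo, hi = sorted((self.g_light, self.g_dark))
        if not (lo - 1e-12 <= self.g_24h <= hi + 1e-12):
            raise ValueError("24-h calcification must lie between light and dark rates")


def blank_correct(sample_delta: float, blank_deltas: float | Iterable[float]) -> float:
    """Subtract the mean blank change from a sample change.

    Blanks must come from the same phase and pH level as the sample.
    """
    blanks = np.atleast_1d(np.asarray(blank_deltas, dtype=float))
    if blanks.size == 0 or not np.all(np.isfinite(blanks)):
        raise ValueError("no blank values available for this phase/level")
    return float(sample_delta - blanks.mean())


def calcification_rate(
    delta_at_umol_kg: float,
    seawater_mass_kg: float,
    surface_area_cm2: float,
    duration_h: float,
) -> float:
    """Net calcification G (µmol CaCO₃ cm⁻² h⁻¹) from the alkalinity anomaly.

    ``delta_at_umol_kg`` is the blank-corrected final − initial A_T.
    G = −(ΔA_T / 2)·mass / (area·duration): an alkalinity decline means
    CaCO₃ was precipitated (positive G); a rise means net dissolution.
    """
    if surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return float(-(delta_at_umol_kg / 2.0) * seawater_mass_kg / (surface_area_cm2 * duration_h))


def oxygen_flux(
    delta_o2_mg_l: float,
    chamber_volume_l: float,
    surface_area_cm2: float,
    duration_min: float,
) -> float:
    """O₂ flux (µg O₂ cm⁻² min⁻¹) from the blank-corrected ΔO₂.

    Positive in the light is net photosynthesis; negative in the dark is
    respiration (report magnitude separately if desired).
    """
    if surface_area_cm2 <= 0:
        raise ValueError("surface area must be positive")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return float(delta_o2_mg_l * 1000.0 * chamber_volume_l / (surface_area_cm2 * duration_min))


def net_daily_calcification(
    g_light: float,
    g_dark: float,
    daylight_h: float = DAYLIGHT_HOURS,
    night_h: float = NIGHT_HOURS,
) -> float:
    """24-h mean calcification assuming ``daylight_h`` light and ``night_h`` dark."""
    return (daylight_h * g_light + night_h * g_dark) / (daylight_h + night_h)


def chamber_rates(records: Sequence[IncubationRecord]) -> ChamberRates:
    """Reduce one block's records (light + dark runs + their blanks) to rates.

    Blanks are matched per phase and treatment pH level (the strictest
    reading of paired blank chambers); a phase without blanks is an error.
    """
    samples = {r.phase: r for r in records if not r.is_blank}
    if set(samples) != {"light", "dark"}:
        raise ValueError("need exactly one light and one dark non-blank record")
    g: dict[str, float] = {}
    flux: dict[str, float] = {}
    for phase, s in samples.items():
        blanks = [
            b.delta_at
            for b in records
            if b.is_blank and b.phase == phase and _same_level(b.treatment_ph, s.treatment_ph)
        ]
        blanks_o2 = [
            b.delta_o2
            for b in records
            if b.is_blank and b.phase == phase and _same_level(b.treatment_ph, s.treatment_ph)
        ]
        if not blanks:
            raise ValueError(f"no blank chambers for phase {phase!r} at pH {s.treatment_ph}")
        d_at = blank_correct(s.delta_at, blanks)
        d_o2 = blank_correct(s.delta_o2, blanks_o2)
        g[phase] = calcification_rate(
            d_at, s.seawater_mass_kg, s.surface_area_cm2, s.duration_min / 60.0
        )
        flux[phase] = oxygen_flux(d_o2, s.chamber_volume_l, s.surface_area_cm2, s.duration_min)
    return ChamberRates(
        g_light=g["light"],
        g_dark=g["dark"],
        g_24h=net_daily_calcification(g["light"], g["dark"]),
        p_net=flux["light"],
        r_dark=-flux["dark"],
        dark_o2_flux=flux["dark"],
        treatment_ph=samples["light"].treatment_ph,
    )


def _same_level(a: float, b: float) -> bool:
    return (np.isnan(a) and np.isnan(b)) or abs(a - b) < 1e-9


# --- tabular interface -----------------------------------------------------

_RECORD_COLS = [
    "chamber_id", "is_blank", "phase", "at_initial", "at_final", "o2_initial",
    "o2_final", "chamber_volume_l", "duration_min", "surface_area_cm2",
    "treatment_ph", "seawater_density_kg_l",
]


def records_to_frame(records: Sequence[IncubationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _RECORD_COLS} for r in records])


def frame_to_records(df: pd.DataFrame) -> list[IncubationRecord]:
    out = []
    for row in df.to_dict("records"):
        sa = row.get("surface_area_cm2")
        if sa is not None and isinstance(sa, float) and np.isnan(sa):
            row["surface_area_cm2"] = None
        out.append(IncubationRecord(**{c: row[c] for c in _RECORD_COLS if c in row}))
    return out


def rates_table(records: Sequence[IncubationRecord], by: str = "chamber_id") -> pd.DataFrame:
    """Rates for many blocks: records are grouped by sample chamber id prefix.

    Blanks (shared per phase/pH level) are matched to every sample at
    their level.
    """
    samples = [r for r in records if not r.is_blank]
    blanks = [r for r in records if r.is_blank]
    ids = sorted({s.chamber_id.rsplit("_", 1)[0] for s in samples})
    rows = []
    for cid in ids:
        mine = [s for s in samples if s.chamber_id.rsplit("_", 1)[0] == cid]
        level_blanks = [
            b for b in blanks if any(_same_level(b.treatment_ph, s.treatment_ph) for s in mine)
        ]
        cr = chamber_rates(mine + level_blanks)
        rows.append({"bar_id": cid, **cr.__dict__})
    return pd.DataFrame(rows)


# --- carbonate system ------------------------------------------------------

@dataclass(frozen=True)
class CarbonateState:
    """Equilibrium seawater CO₂-system state (total pH scale)."""

    ph_total: float
    a_t: float          # µmol kg⁻¹
    dic: float          # µmol kg⁻¹
    pco2: float         # µatm
    omega_arag: float
    co3: float          # µmol kg⁻¹ carbonate ion
    temperature_c: float
    salinity: float

    def __post_init__(self) -> None:
        if self.omega_arag <= 0:
            raise ValueError("aragonite saturation state must be positive")


def carbonate_constants(temperature_c: float, salinity: float) -> dict[str, float]:
    """Equilibrium constants (mol kg⁻¹, total pH scale) at 1 atm.

    See :data:`CARBONATE_CONSTANTS_DOC` for provenance.
    """
    T = temperature_c + 273.15
    S = salinity
    lnT = np.log(T)
    sqS = np.sqrt(S)

    # Lueker et al. (2000), total scale
    pK1 = 3633.86 / T - 61.2172 + 9.6777 * lnT - 0.011555 * S + 0.0001152 * S**2
    pK2 = 471.78 / T + 25.929 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2

    # Dickson (1990), boric acid, total scale
    lnKB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / T
        + 148.0248 + 137.1942 * sqS + 1.62142 * S
        - (24.4344 + 25.085 * sqS + 0.2474 * S) * lnT
        + 0.053105 * sqS * T
    )

    # Millero (1995) water dissociation (DOE handbook form)
    lnKW = (
        148.9802 - 13847.26 / T - 23.6521 * lnT
        + (118.67 / T - 5.977 + 1.0495 * lnT) * sqS - 0.01615 * S
    )

    # Weiss (1974) CO2 solubility, mol kg⁻¹ atm⁻¹
    T100 = T / 100.0
    lnK0 = (
        -60.2409 + 93.4517 / T100 + 23.3585 * np.log(T100)
        + S * (0.023517 - 0.023656 * T100 + 0.0047036 * T100**2)
    )

    # Mucci (1983) aragonite solubility product, (mol kg⁻¹)²
    log10Ksp = (
        -171.945 - 0.077993 * T + 2903.293 / T + 71.595 * np.log10(T)
        + (-0.068393 + 0.0017276 * T + 88.135 / T) * sqS
        - 0.10018 * S + 0.0059415 * S**1.5
    )

    return {
        "K1": 10.0**-pK1,
        "K2": 10.0**-pK2,
        "KB": float(np.exp(lnKB)),
        "KW": float(np.exp(lnKW)),
        "K0": float(np.exp(lnK0)),
        "Ksp_arag": 10.0**log10Ksp,
        "TB": 0.0004157 * S / 35.0,                  # Uppström (1974), mol kg⁻¹
        "Ca": 0.02128 / 40.087 * S / 1.80655,        # Riley & Tongudai (1967)
    }


def _total_alkalinity(h: float, dic: float, k: dict[str, float]) -> float:
    """A_T (mol kg⁻¹) at total-scale [H⁺] = h, for DIC in mol kg⁻¹."""
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    carb_alk = dic * (k["K1"] * h + 2.0 * k["K1"] * k["K2"]) / denom
    return carb_alk + k["TB"] * k["KB"] / (k["KB"] + h) + k["KW"] / h - h


def solve_carbonate_system(
    a_t: float,
    dic: float,
    temperature_c: float,
    salinity: float,
) -> CarbonateState:
    """Solve the seawater CO₂ system from measured A_T and DIC (µmol kg⁻¹).

    Finds the total-scale [H⁺] whose alkalinity balance (carbonate +
    borate + water) matches A_T by bracketed root-finding, then derives
    pCO₂ and Ω_aragonite.
    """
    if not (20.0 <= salinity <= 40.0):
        raise ValueError(f"salinity {salinity} outside supported seawater range 20–40")
    if not (15.0 <= temperature_c <= 35.0):
        raise ValueError(f"temperature {temperature_c} °C outside supported range 15–35")
    if a_t <= 0 or dic <= 0:
        raise ValueError("A_T and DIC must be positive")

    k = carbonate_constants(temperature_c, salinity)
    at = a_t * 1e-6
    c = dic * 1e-6
    f = lambda ph: _total_alkalinity(10.0 ** (-ph), c, k) - at
    lo, hi = 3.0, 12.0
    if f(lo) * f(hi) > 0:
        raise RuntimeError(
            "carbonate-system pH solve did not bracket a root for "
            f"A_T={a_t}, DIC={dic} (residuals {f(lo):.3e}, {f(hi):.3e})"
        )
    ph = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    h = 10.0**-ph
    denom = h * h + k["K1"] * h + k["K1"] * k["K2"]
    co2_star = c * h * h / denom
    co3 = c * k["K1"] * k["K2"] / denom
    return CarbonateState(
        ph_total=float(ph),
        a_t=float(a_t),
        dic=float(dic),
        pco2=float(co2_star / k["K0"] * 1e6),
        omega_arag=float(k["Ca"] * co3 / k["Ksp_arag"]),
        co3=float(co3 * 1e6),
        temperature_c=float(temperature_c),
        salinity=float(salinity),
    )
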