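"""Thermodynamic activities from measured chemistry (Davies activity model).

Reaction quotients need dimensionless activities on the molal standard state
for H⁺, H2, HCO3⁻, CH4, SO4²⁻ and HS⁻.  Ionic activity coefficients come
from the Davies equation

    log10 γ = −A·z²·(√I/(1+√I) − b·I),   b = 0.3,

with the Debye–Hückel A parameter interpolated over temperature through
(0 °C, 0.4918), (25 °C, 0.5085), (50 °C, 0.5319).  Neutral dissolved gases
(CH4, H2) take unit activity coefficient, a(H⁺) = 10^(−pH), and a(H2O) = 1
exactly.  No ion pairing or carbonate re-speciation is attempted: the
reaction quotients of interest span tens of orders of magnitude, so
Davies-level accuracy is immaterial to the ΔG/e⁻ patterns.

Dissolved H2 is rarely measured; three modes are offered (measured value,
assumed constant nanomolar level typical of sulfate-reducing zones, or
equilibrium with the SO4²⁻/HS⁻ couple at a configurable ΔG threshold).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import thermo
from .samples import WaterSample
from .species import get_species, mgL_to_molL, ugL_to_molL

logger = logging.getLogger(__name__)

DAVIES_B = 0.3
DAVIES_VALIDITY_I = 0.7  # mol/L; beyond this the Davies model is unreliable
_A_ANCHORS_T = np.array([0.0, 25.0, 50.0])
_A_ANCHORS_A = np.array([0.4918, 0.5085, 0.5319])

GYPSUM_LOG_KSP = -4.58  # CaSO4·2H2O at 25 °C

#: Ions contributing to ionic strength when present on a sample.
_IONIC_STRENGTH_SPECIES = (
    "Na", "K", "Ca", "Mg", "HCO3", "Cl", "Br", "SO4", "NO3", "HS", "Fe", "Mn",
)


class H2Mode(enum.Enum):
    MEASURED = "MEASURED"
    ASSUMED_CONSTANT = "ASSUMED_CONSTANT"
    REDOX_COUPLE = "REDOX_COUPLE"


@dataclass(frozen=True)
class H2Config:
    mode: H2Mode = H2Mode.ASSUMED_CONSTANT
    value_molL: float | None = 1e-9  # for ASSUMED_CONSTANT / MEASURED
    dg_threshold: float = 0.0  # kJ/mol, for REDOX_COUPLE


class SpeciationError(ValueError):
    pass


@dataclass
class ActivitySet:
    """Dimensionless activities for one sample; a(H2O) is fixed at exactly 1."""

    activities: dict[str, float]
    ionic_strength: float  # mol/L
    temperature: float  # °C
    h2_source: H2Mode | None = None

    def __post_init__(self) -> None:
        self.activities["H2O"] = 1.0
        for sp, a in self.activities.items():
            if a <= 0:
                raise SpeciationError(f"nonpositive activity {a} for {sp}")

    def get(self, species: str, default=None):
        return self.activities.get(species, default)

    def __getitem__(self, species: str) -> float:
        return self.activities[species]

    def __contains__(self, species: str) -> bool:
        return species in self.activities


def ionic_strength(conc_molL: Mapping[str, float]) -> float:
    """I = ½ Σ cᵢ zᵢ², mol/L."""
    total = 0.0
    for sp, c in conc_molL.items():
        if c < 0:
            raise ValueError(f"negative concentration for {sp}")
        total += c * get_species(sp).charge ** 2
    return 0.5 * total


def davies_a(temperature_c: float) -> float:
    """Debye–Hückel A at temperature, piecewise-linear through the anchors."""
    t = temperature_c
    if t <= _A_ANCHORS_T[0]:
        slope = (_A_ANCHORS_A[1] - _A_ANCHORS_A[0]) / (_A_ANCHORS_T[1] - _A_ANCHORS_T[0])
        return float(_A_ANCHORS_A[0] + slope * (t - _A_ANCHORS_T[0]))
    if t >= _A_ANCHORS_T[-1]:
        slope = (_A_ANCHORS_A[-1] - _A_ANCHORS_A[-2]) / (_A_ANCHORS_T[-1] - _A_ANCHORS_T[-2])
        return float(_A_ANCHORS_A[-1] + slope * (t - _A_ANCHORS_T[-1]))
    return float(np.interp(t, _A_ANCHORS_T, _A_ANCHORS_A))


def activity_coefficient(z: int, I: float, temperature_c: float = 25.0, b: float = DAVIES_B) -> float:
    """Davies activity coefficient γ for charge z at ionic strength I (mol/L)."""
    if I < 0:
        raise ValueError(f"ionic strength must be >= 0, got {I}")
    if I > DAVIES_VALIDITY_I:
        logger.warning(
            "ionic strength %.3g mol/L exceeds the Davies validity limit (%.1f); "
            "activity coefficients are extrapolated",
            I,
            DAVIES_VALIDITY_I,
        )
    if z == 0 or I == 0:
        return 1.0
    sqrt_i = math.sqrt(I)
    log10_gamma = -davies_a(temperature_c) * z * z * (sqrt_i / (1 + sqrt_i) - b * I)
    return 10.0 ** log10_gamma


def _molarities(sample: WaterSample) -> dict[str, float]:
    """Resolved molarities (mol/L) of all present, imputed ions."""
    conc: dict[str, float] = {}
    for sp in _IONIC_STRENGTH_SPECIES:
        cv = sample.ions.get(sp)
        if cv is None or cv.below_dl:
            continue
        conc[sp] = mgL_to_molL(cv.resolved, sp)
    return conc


def h2_activity(sample: WaterSample, config: H2Config | None = None) -> float:
    """Dissolved-H2 activity by mode.

    ``REDOX_COUPLE`` solves ΔG(SO4 reduction) = dg_threshold for a(H2):
    with Q = a(HS)/(a(SO4)·a(H⁺)·a(H2)⁴), a(H2) = (Q₀·exp(−lnQ*))^(1/4)
    where Q₀ omits H2 and lnQ* = (threshold − ΔG°_T)/(R·T).
    """
    config = config or H2Config()
    if config.mode in (H2Mode.MEASURED, H2Mode.ASSUMED_CONSTANT):
        if config.value_molL is None or config.value_molL <= 0:
            raise SpeciationError(f"h2 mode {config.mode.value} requires a positive value_molL")
        return config.value_molL

    # REDOX_COUPLE: needs SO4, HS activities and pH
    partial = species_activities(sample, h2_config=None, include_h2=False)
    for sp in ("SO4", "HS"):
        if sp not in partial:
            raise SpeciationError(f"REDOX_COUPLE h2 mode requires {sp} on sample {sample.sample_id}")
    t_k = sample.temperature + 273.15
    dg0 = thermo.delta_g0_T(thermo.Reaction.SO4_REDUCTION, sample.temperature)
    ln_q_target = (config.dg_threshold - dg0) / (thermo.R_KJ * t_k)
    ln_q0 = math.log(partial["HS"]) - math.log(partial["SO4"]) - math.log(partial["H"])
    # ln Q = ln Q0 - 4 ln a(H2)  =>  ln a(H2) = (ln Q0 - ln Q*) / 4
    return math.exp((ln_q0 - ln_q_target) / 4.0)


def species_activities(
    sample: WaterSample,
    h2_config: H2Config | None = None,
    include_h2: bool = True,
) -> ActivitySet:
    """Full activity set for one (already imputed) sample.

    Ionic species: a = γ(z, I, T)·molarity.  Neutral gases: a = molarity.
    a(H⁺) = 10^(−pH), a(H2O) = 1.  A sample without CH4 yields a set lacking
    CH4 so CH4-dependent reactions can be skipped cleanly.
    """
    if sample.pH is None:
        raise SpeciationError(f"{sample.sample_id}: pH is required for speciation")
    hco3 = sample.ions.get("HCO3")
    if hco3 is None:
        raise SpeciationError(f"{sample.sample_id}: HCO3 is required for speciation")
    if hco3.below_dl:
        raise SpeciationError(f"{sample.sample_id}: HCO3 is censored and unimputed")

    conc = _molarities(sample)
    I = ionic_strength(conc)
    acts: dict[str, float] = {"H": 10.0 ** (-sample.pH)}
    for sp, c in conc.items():
        if c == 0:
            continue
        z = get_species(sp).charge
        acts[sp] = activity_coefficient(z, I, sample.temperature) * c

    if sample.CH4_dissolved is not None and not sample.CH4_dissolved.below_dl:
        acts["CH4"] = ugL_to_molL(sample.CH4_dissolved.resolved, "CH4")

    h2_cfg = h2_config or H2Config()
    if include_h2:
        acts["H2"] = h2_activity(sample, h2_cfg)

    return ActivitySet(
        activities=acts,
        ionic_strength=I,
        temperature=sample.temperature,
        h2_source=h2_cfg.mode if include_h2 else None,
    )


def gypsum_si(sample: WaterSample) -> float:
    """Gypsum saturation index log10(a(Ca²⁺)·a(SO4²⁻)/Ksp), Ksp = 10^−4.58.

    Raises :class:`SpeciationError` if Ca or SO4 is absent or unimputed.
    """
    for sp in ("Ca", "SO4"):
        cv = sample.ions.get(sp)
        if cv is None or cv.below_dl:
            raise SpeciationError(f"{sample.sample_id}: {sp} absent or censored; no gypsum SI")
    conc = _molarities(sample)
    I = ionic_strength(conc)
    a_ca = activity_coefficient(2, I, sample.temperature) * conc["Ca"]
    a_so4 = activity_coefficient(-2, I, sample.temperature) * conc["SO4"]
    return math.log10(a_ca * a_so4) - GYPSUM_LOG_KSP
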