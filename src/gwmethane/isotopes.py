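"""Isotope fractionation factors, Rayleigh curves, pathway classification,
and the 1/CH4 mixing-line intercept diagnostic.

The fractionation factor between a source pool X (DIC for carbon, H2O for
hydrogen) and CH4 is

    α = (1000 + δX) / (1000 + δCH4),

with deltas in ‰.  Empirically, α_DIC-CH4 ≈ 1.07 with α_H2O-CH4 ≈ 1.2
indicates CO2-reduction (hydrogenotrophic) methanogenesis, while
α_DIC-CH4 ≈ 1.04 and α_H2O-CH4 ≈ 1.4 — or strongly depleted δ2H-CH4 below
about −310‰ — indicate acetoclastic methanogenesis or an oxidation pathway.
The classifier encodes these as configurable threshold rules and records
every rule that fired as evidence; sulfate is carried as context, never
decisive on its own.

Rayleigh curves are exposed for curve generation only (no sample is
force-fit to a Rayleigh model): the carbon orientation is R = R_i·f^(1−α)
and the hydrogen orientation is R = R_i·f^(α−1), so the two respond
reciprocally as the CH4 reservoir f shrinks.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


def fractionation_factor(delta_X: float, delta_CH4: float) -> float:
    """α = (1000 + δX)/(1000 + δCH4); deltas in ‰."""
    if delta_CH4 <= -1000 or delta_X <= -1000:
        raise ValueError("deltas must exceed −1000‰ (α undefined)")
    alpha = (1000.0 + delta_X) / (1000.0 + delta_CH4)
    if not 0.8 < alpha < 1.8:
        warnings.warn(
            f"fractionation factor {alpha:.3f} outside the (0.8, 1.8) sanity "
            "band for natural C/H systems",
            stacklevel=2,
        )
    return alpha


@dataclass(frozen=True)
class FractionationResult:
    """Per-sample carbon and hydrogen fractionation factors (either optional)."""

    alpha_DIC_CH4: float | None = None
    alpha_H2O_CH4: float | None = None


class RayleighOrientation(enum.Enum):
    CARBON = "CARBON"
    HYDROGEN = "HYDROGEN"


def rayleigh(
    R_i: float,
    f: float | np.ndarray,
    alpha: float,
    orientation: RayleighOrientation | str,
) -> float | np.ndarray:
    """Rayleigh fractionation of a residual reservoir fraction f ∈ (0, 1].

    CARBON: R = R_i·f^(1−α); HYDROGEN: R = R_i·f^(α−1).  f = 0 is a plotting
    limit, not an evaluable point.
    """
    orientation = RayleighOrientation(orientation)
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0) or np.any(f_arr > 1):
        raise ValueError("residual fraction f must lie in (0, 1]")
    if R_i <= 0:
        raise ValueError("initial ratio R_i must be positive")
    exponent = (1 - alpha) if orientation is RayleighOrientation.CARBON else (alpha - 1)
    out = R_i * f_arr ** exponent
    return float(out) if np.isscalar(f) else out


class Pathway(enum.Enum):
    CO2_REDUCTION = "CO2_REDUCTION"
    ACETOCLASTIC_OR_OXIDATION = "ACETOCLASTIC_OR_OXIDATION"
    MIXED = "MIXED"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class PathwayThresholds:
    """Configurable classification thresholds (see module docstring)."""

    alpha_c_center: float = 1.07
    alpha_c_halfwidth: float = 0.02
    alpha_h_center: float = 1.2
    alpha_h_halfwidth: float = 0.05
    alpha_c_aceto_min: float = 1.02  # below this no methanogenic C fractionation signal
    alpha_c_aceto_max: float = 1.05
    alpha_h_aceto_min: float = 1.35
    d2h_aceto_max: float = -310.0


@dataclass(frozen=True)
class PathwayCall:
    call: Pathway
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.call is not Pathway.INDETERMINATE and not self.evidence:
            raise ValueError("non-indeterminate calls require evidence")


def classify_pathway(
    fr: FractionationResult,
    d2H_CH4: float | None = None,
    SO4_meqL: float | None = None,
    thresholds: PathwayThresholds | None = None,
) -> PathwayCall:
    """Rule-based pathway attribution from fractionation factors and δ2H-CH4.

    Deterministic and order-independent: all rules are evaluated, then
    combined (both directions firing → MIXED; none → INDETERMINATE).
    Sulfate is appended to the evidence as context only.
    """
    th = thresholds or PathwayThresholds()
    a_c, a_h = fr.alpha_DIC_CH4, fr.alpha_H2O_CH4

    co2_evidence: list[str] = []
    if (
        a_c is not None
        and a_h is not None
        and abs(a_c - th.alpha_c_center) <= th.alpha_c_halfwidth
        and abs(a_h - th.alpha_h_center) <= th.alpha_h_halfwidth
    ):
        co2_evidence.append(
            f"alpha_DIC-CH4={a_c:.3f} within {th.alpha_c_center}±{th.alpha_c_halfwidth} "
            f"and alpha_H2O-CH4={a_h:.3f} within {th.alpha_h_center}±{th.alpha_h_halfwidth}"
        )

    aceto_evidence: list[str] = []
    if a_c is not None and th.alpha_c_aceto_min <= a_c <= th.alpha_c_aceto_max:
        aceto_evidence.append(
            f"alpha_DIC-CH4={a_c:.3f} in [{th.alpha_c_aceto_min}, {th.alpha_c_aceto_max}]"
        )
    if a_h is not None and a_h >= th.alpha_h_aceto_min:
        aceto_evidence.append(f"alpha_H2O-CH4={a_h:.3f} >= {th.alpha_h_aceto_min}")
    if d2H_CH4 is not None and d2H_CH4 <= th.d2h_aceto_max:
        aceto_evidence.append(f"d2H-CH4={d2H_CH4:.1f}‰ <= {th.d2h_aceto_max}‰")

    context: list[str] = []
    if SO4_meqL is not None:
        context.append(f"context: SO4={SO4_meqL:.3g} meq/L")

    if co2_evidence and aceto_evidence:
        call = Pathway.MIXED
        evidence = co2_evidence + aceto_evidence
    elif co2_evidence:
        call, evidence = Pathway.CO2_REDUCTION, co2_evidence
    elif aceto_evidence:
        call, evidence = Pathway.ACETOCLASTIC_OR_OXIDATION, aceto_evidence
    else:
        return PathwayCall(Pathway.INDETERMINATE, ())
    return PathwayCall(call, tuple(evidence + context))


@dataclass(frozen=True)
class MixingLine:
    slope: float  # ‰·(µg/L)
    intercept: float  # ‰ — inferred source end-member δ13C-CH4
    r_squared: float


def mixing_line_intercept(points: Sequence[tuple[float, float]]) -> MixingLine:
    """OLS of δ13C-CH4 on 1/CH4; the y-intercept is the source end-member δ.

    Requires at least 3 points with distinct, positive CH4 concentrations.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points, got {len(points)}")
    conc = np.array([p[0] for p in points], dtype=float)
    delta = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("all CH4 concentrations must be positive")
    x = 1.0 / conc
    if np.ptp(x) == 0:
        raise ValueError("zero variance in 1/CH4: degenerate design")
    res = stats.linregress(x, delta)
    return MixingLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
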