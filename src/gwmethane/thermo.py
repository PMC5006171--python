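"""Gibbs free energy of the microbial redox reactions.

Three reactions matter for methane attribution in these aquifers:

* CO2 reduction (hydrogenotrophic methanogenesis):
  HCO3⁻ + 4 H2 + H⁺ → CH4 + 3 H2O
* Sulfate reduction: SO4²⁻ + 4 H2 + H⁺ → HS⁻ + 4 H2O
* Anaerobic oxidation of methane (AOM): CH4 + SO4²⁻ → HCO3⁻ + HS⁻ + H2O

All three transfer 8 electrons, which allows direct comparison once ΔG is
normalised per electron.  Standard-state constants are aqueous (molal
standard state) and shipped in ``data/thermo_constants.yaml``; per-reaction
ΔH° and ΔS° are derived from per-species formation values at load time, and
the temperature correction is ΔG°_T = ΔH° − T·ΔS° with T in Kelvin.  In-situ
energies follow ΔG = ΔG°_T + R·T·ln Q over thermodynamic activities.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

R_KJ = 8.314e-3  # gas constant, kJ/(mol·K)
T0_K = 298.15


class Reaction(enum.Enum):
    CO2_REDUCTION = "CO2_REDUCTION"
    SO4_REDUCTION = "SO4_REDUCTION"
    AOM = "AOM"


class ReactionBalanceError(ValueError):
    pass


class MissingActivityError(KeyError):
    def __init__(self, reaction: str, species: str) -> None:
        self.reaction, self.species = reaction, species
        super().__init__(f"{reaction}: no activity for species {species!r}")


@dataclass(frozen=True)
class SpeciesThermo:
    """Standard aqueous formation free energy/enthalpy (kJ/mol) of a species."""

    name: str
    dGf: float
    dHf: float
    charge: int
    elements: Mapping[str, int]


@dataclass(frozen=True)
class ReactionSpec:
    """Stoichiometry (products +, reactants −) and derived thermodynamics."""

    name: str
    stoichiometry: Mapping[str, float]
    n_electrons: int
    delta_H0: float  # kJ/mol
    delta_S0: float  # kJ/(mol·K)

    @property
    def delta_G0_25C(self) -> float:
        return self.delta_H0 - T0_K * self.delta_S0


def _check_balance(name: str, stoich: Mapping[str, float], species: Mapping[str, SpeciesThermo]) -> None:
    elements: dict[str, float] = {}
    charge = 0.0
    for sp, nu in stoich.items():
        info = species[sp]
        charge += nu * info.charge
        for el, n in info.elements.items():
            elements[el] = elements.get(el, 0.0) + nu * n
    bad = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    if bad or abs(charge) > 1e-9:
        raise ReactionBalanceError(
            f"reaction {name} is unbalanced: element residuals {bad}, charge {charge}"
        )


def _build_reaction(
    name: str,
    stoich: Mapping[str, float],
    n_electrons: int,
    species: Mapping[str, SpeciesThermo],
) -> ReactionSpec:
    _check_balance(name, stoich, species)
    dG = sum(nu * species[sp].dGf for sp, nu in stoich.items())
    dH = sum(nu * species[sp].dHf for sp, nu in stoich.items())
    dS = (dH - dG) / T0_K
    return ReactionSpec(
        name=name,
        stoichiometry=dict(stoich),
        n_electrons=n_electrons,
        delta_H0=dH,
        delta_S0=dS,
    )


def load_constants(path: str | Path | None = None) -> tuple[dict[str, SpeciesThermo], dict[str, ReactionSpec]]:
    """Load species constants and reaction definitions from YAML.

    Users may point this at their own file using the same schema to define
    additional reactions.
    """
    if path is None:
        text = resources.files("gwmethane").joinpath("data/thermo_constants.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    species = {
        name: SpeciesThermo(
            name=name,
            dGf=float(d["dGf"]),
            dHf=float(d["dHf"]),
            charge=int(d["charge"]),
            elements=dict(d["elements"]),
        )
        for name, d in raw["species"].items()
    }
    reactions = {
        name: _build_reaction(name, d["stoichiometry"], int(d["n_electrons"]), species)
        for name, d in raw["reactions"].items()
    }
    return species, reactions


SPECIES_THERMO, REACTIONS = load_constants()


def get_reaction(reaction: Reaction | str) -> ReactionSpec:
    key = reaction.value if isinstance(reaction, Reaction) else reaction
    return REACTIONS[key]


def delta_g0_T(reaction: Reaction | str | ReactionSpec, temperature_c: float) -> float:
    """Temperature-corrected standard Gibbs free energy, kJ/mol.

    ΔG°_T = ΔH° − T·ΔS° with T in Kelvin; valid for groundwater temperatures
    (the constant-ΔH/ΔS approximation over 0–60 °C).
    """
    spec = reaction if isinstance(reaction, ReactionSpec) else get_reaction(reaction)
    if not 0 < temperature_c < 60:
        raise ValueError(f"temperature {temperature_c} °C outside (0, 60)")
    return spec.delta_H0 - (temperature_c + 273.15) * spec.delta_S0


def _activity_map(activities) -> Mapping[str, float]:
    return getattr(activities, "activities", activities)


def ln_reaction_quotient(reaction: Reaction | str | ReactionSpec, activities) -> float:
    """Natural log of the reaction quotient Q = Π a_i^{ν_i}.

    Computed in log space so that quotients spanning tens of orders of
    magnitude do not overflow.  The activity of H2O is fixed at exactly 1.
    """
    spec = reaction if isinstance(reaction, ReactionSpec) else get_reaction(reaction)
    acts = _activity_map(activities)
    ln_q = 0.0
    for sp, nu in spec.stoichiometry.items():
        if sp == "H2O":
            continue
        a = acts.get(sp)
        if a is None:
            raise MissingActivityError(spec.name, sp)
        if a <= 0:
            raise ValueError(f"{spec.name}: nonpositive activity {a} for {sp}")
        ln_q += nu * math.log(a)
    return ln_q


def reaction_quotient(reaction: Reaction | str | ReactionSpec, activities) -> float:
    """Reaction quotient Q (may be astronomically large; see ln_reaction_quotient)."""
    return math.exp(ln_reaction_quotient(reaction, activities))


def delta_g(
    reaction: Reaction | str | ReactionSpec,
    temperature_c: float,
    Q: float | None = None,
    ln_Q: float | None = None,
) -> float:
    """In-situ Gibbs free energy ΔG = ΔG°_T + R·T·ln Q, kJ/mol."""
    if ln_Q is None:
        if Q is None or Q <= 0:
            raise ValueError("provide Q > 0 or ln_Q")
        ln_Q = math.log(Q)
    t_k = temperature_c + 273.15
    return delta_g0_T(reaction, temperature_c) + R_KJ * t_k * ln_Q


def delta_g_per_electron(dg: float, reaction: Reaction | str | ReactionSpec) -> float:
    """ΔG normalised per electron transferred (8 for all shipped reactions)."""
    spec = reaction if isinstance(reaction, ReactionSpec) else get_reaction(reaction)
    if spec.n_electrons <= 0:
        raise ValueError("n_electrons must be positive")
    return dg / spec.n_electrons
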