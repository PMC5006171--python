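"""Chemical species registry and unit conversions.

Groundwater chemistry is reported in mg/L (µg/L for dissolved gases); the
thermodynamic and compositional machinery downstream needs mol/L and, for
ion-balance style reporting, meq/L. The registry pins the molar masses and
ionic charges used everywhere in the package so that every conversion is
traceable to one table.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnknownSpeciesError(KeyError):
    """Raised when a species id has no registry entry."""

    def __init__(self, species: str) -> None:
        super().__init__(species)
        self.species = species

    def __str__(self) -> str:  # pragma: no cover - trivial
        return (
            f"unknown species {self.species!r}: not in the registry; "
            f"known species: {sorted(SPECIES)}"
        )


@dataclass(frozen=True)
class SpeciesInfo:
    """Molar mass (g/mol) and signed ionic charge of one dissolved species."""

    name: str
    molar_mass: float
    charge: int


#: Registry of dissolved species. Molar masses are conventional values for the
#: reported analytes (e.g. SO4 as the sulfate ion, HCO3 as bicarbonate
#: alkalinity); charges are the dominant aqueous form.
SPECIES: dict[str, SpeciesInfo] = {
    s.name: s
    for s in [
        SpeciesInfo("Na", 22.990, +1),
        SpeciesInfo("K", 39.098, +1),
        SpeciesInfo("Ca", 40.078, +2),
        SpeciesInfo("Mg", 24.305, +2),
        SpeciesInfo("HCO3", 61.016, -1),
        SpeciesInfo("Cl", 35.453, -1),
        SpeciesInfo("Br", 79.904, -1),
        SpeciesInfo("SO4", 96.06, -2),
        SpeciesInfo("NO3", 62.004, -1),
        SpeciesInfo("S2", 32.06, -2),
        SpeciesInfo("HS", 33.073, -1),
        SpeciesInfo("Fe", 55.845, +2),
        SpeciesInfo("Mn", 54.938, +2),
        SpeciesInfo("CH4", 16.043, 0),
        SpeciesInfo("H2", 2.016, 0),
        SpeciesInfo("H", 1.008, +1),
    ]
}


def get_species(species: str) -> SpeciesInfo:
    try:
        return SPECIES[species]
    except KeyError:
        raise UnknownSpeciesError(species) from None


def mgL_to_meqL(conc: float, species: str) -> float:
    """Convert mg/L to milliequivalents per litre.

    meq/L = (mg/L) / molar_mass * |charge|.  Only defined for charged
    species; requesting a neutral gas raises ``UnknownSpeciesError``-style
    configuration errors would be misleading, so a ``ValueError`` names the
    problem.
    """
    if conc < 0:
        raise ValueError(f"negative concentration {conc} for {species}")
    info = get_species(species)
    if info.charge == 0:
        raise ValueError(f"{species} is uncharged; meq/L is undefined")
    return conc / info.molar_mass * abs(info.charge)


def mgL_to_molL(conc: float, species: str) -> float:
    """Convert mg/L to mol/L (divide by 1000 x molar mass)."""
    if conc < 0:
        raise ValueError(f"negative concentration {conc} for {species}")
    info = get_species(species)
    return conc / (1000.0 * info.molar_mass)


def ugL_to_molL(conc: float, species: str) -> float:
    """Convert µg/L to mol/L.

    Dissolved gases (CH4 here) are reported in µg/L; this is the conversion
    used upstream of activity calculation for them.
    """
    return mgL_to_molL(conc / 1000.0, species)
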