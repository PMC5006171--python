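"""Domain types and delimited-text I/O for groundwater sample tables.

One row of the input table is one well/sample: aquifer group, field
physico-chemistry, major/minor ion concentrations (possibly left-censored at
an analytical detection limit), dissolved CH4, and stable-isotope deltas.
Censoring is carried explicitly: a value below the detection limit (DL) is
never silently zeroed or replaced here — that is the censoring module's job.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class AquiferGroup(enum.Enum):
    ALLUVIUM = "ALLUVIUM"
    SHALLOW_COAL_MEASURES = "SHALLOW_COAL_MEASURES"
    GAS_RESERVOIR = "GAS_RESERVOIR"
    KUMBARILLA = "KUMBARILLA"


#: Default analytical detection limits, mg/L except CH4 (µg/L) and tritium (TU).
DEFAULT_DETECTION_LIMITS: dict[str, float] = {
    "Na": 1.0,
    "K": 1.0,
    "Ca": 1.0,
    "Mg": 1.0,
    "HCO3": 1.0,
    "Cl": 1.0,
    "Br": 0.01,
    "SO4": 1.0,
    "NO3": 0.01,
    "S2": 0.1,
    "HS": 0.1,
    "Fe": 0.05,
    "Mn": 0.001,
    "CH4": 10.0,
}


@dataclass(frozen=True)
class CensoredValue:
    """A concentration together with its detection limit and censoring flag.

    ``value`` is the measured concentration when above DL, the imputed
    concentration after imputation, or ``None`` for an unimputed censored
    observation.  ``imputed`` records that a censored observation has been
    replaced by a positive value (provenance survives imputation).
    """

    value: float | None
    detection_limit: float
    below_dl: bool = False
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ValueError(f"detection_limit must be > 0, got {self.detection_limit}")
        if self.value is not None and self.value < 0:
            raise ValueError(f"concentration must be >= 0, got {self.value}")
        if self.below_dl and self.value is not None and self.value > self.detection_limit:
            raise ValueError(
                f"below-DL value {self.value} exceeds its detection limit "
                f"{self.detection_limit}"
            )

    @classmethod
    def detected(cls, value: float, detection_limit: float) -> "CensoredValue":
        return cls(value=value, detection_limit=detection_limit, below_dl=False)

    @classmethod
    def censored(cls, detection_limit: float) -> "CensoredValue":
        return cls(value=None, detection_limit=detection_limit, below_dl=True)

    @property
    def resolved(self) -> float:
        """The usable concentration; raises if still censored and unimputed."""
        if self.value is None:
            raise ValueError("censored value has not been imputed")
        return self.value


_ISOTOPE_FIELDS = ("d13C_CH4", "d2H_CH4", "d13C_DIC", "d2H_H2O", "d18O_H2O", "d37Cl")


@dataclass
class WaterSample:
    """One well/sample: metadata, physico-chemistry, censored ions, isotopes."""

    sample_id: str
    aquifer_group: AquiferGroup
    temperature: float  # °C
    pH: float
    screen_depth: float | None = None  # m
    DO: float | None = None  # mg/L
    ions: dict[str, CensoredValue] = field(default_factory=dict)  # mg/L
    CH4_dissolved: CensoredValue | None = None  # µg/L
    DOC: float | None = None  # mg/L
    tritium: float | None = None  # TU
    d13C_CH4: float | None = None  # ‰ VPDB
    d2H_CH4: float | None = None  # ‰ VSMOW
    d13C_DIC: float | None = None  # ‰ VPDB
    d2H_H2O: float | None = None  # ‰ VSMOW
    d18O_H2O: float | None = None  # ‰ VSMOW
    d37Cl: float | None = None  # ‰ SMOC

    def __post_init__(self) -> None:
        if not 0 < self.temperature < 60:
            raise ValueError(
                f"{self.sample_id}: temperature {self.temperature} °C outside (0, 60)"
            )
        if not 2 < self.pH < 12:
            raise ValueError(f"{self.sample_id}: pH {self.pH} outside (2, 12)")
        for name in _ISOTOPE_FIELDS:
            v = getattr(self, name)
            if v is not None and not -1000 < v < 1000:
                raise ValueError(f"{self.sample_id}: {name} = {v}‰ outside (−1000, 1000)")


class MissingColumnsError(ValueError):
    def __init__(self, missing: list[str]) -> None:
        self.missing = missing
        super().__init__(f"input table is missing required columns: {missing}")


class RowParseError(ValueError):
    def __init__(self, line: int, column: str, cell: str) -> None:
        self.line = line
        super().__init__(
            f"line {line}: cannot parse {cell!r} in column {column!r} as a number"
        )


REQUIRED_COLUMNS = ("sample_id", "aquifer_group", "temperature_c", "ph")

#: CSV column -> registry species id for ion concentration columns (mg/L).
ION_COLUMNS: dict[str, str] = {
    "na_mgl": "Na",
    "k_mgl": "K",
    "ca_mgl": "Ca",
    "mg_mgl": "Mg",
    "hco3_mgl": "HCO3",
    "cl_mgl": "Cl",
    "br_mgl": "Br",
    "so4_mgl": "SO4",
    "no3_mgl": "NO3",
    "s2_mgl": "S2",
    "hs_mgl": "HS",
    "fe_mgl": "Fe",
    "mn_mgl": "Mn",
}

_SCALAR_COLUMNS: dict[str, str] = {
    "screen_depth_m": "screen_depth",
    "do_mgl": "DO",
    "doc_mgl": "DOC",
    "tritium_tu": "tritium",
    "d13c_ch4_permil": "d13C_CH4",
    "d2h_ch4_permil": "d2H_CH4",
    "d13c_dic_permil": "d13C_DIC",
    "d2h_h2o_permil": "d2H_H2O",
    "d18o_h2o_permil": "d18O_H2O",
    "d37cl_permil": "d37Cl",
}


def _parse_float(cell: str, line: int, column: str) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise RowParseError(line, column, cell) from None
    if math.isnan(v):
        raise RowParseError(line, column, cell)
    return v


def _parse_censored(
    cell: str, line: int, column: str, species: str, dl_defaults: Mapping[str, float]
) -> CensoredValue | None:
    """Parse one concentration cell.

    Empty -> absent (None, never zero).  ``<X`` -> censored at DL X.
    Plain number -> detected, with the species' default DL attached.
    """
    cell = cell.strip()
    if cell == "":
        return None
    if cell.startswith("<"):
        dl = _parse_float(cell[1:], line, column)
        return CensoredValue.censored(dl)
    value = _parse_float(cell, line, column)
    dl = dl_defaults.get(species, 1.0)
    return CensoredValue.detected(value, detection_limit=dl)


def read_samples(
    path: str | Path,
    dl_defaults: Mapping[str, float] | None = None,
) -> list[WaterSample]:
    """Read a CSV sample table into a list of :class:`WaterSample`.

    Censoring convention: a concentration cell ``<X`` marks a value below the
    detection limit X (e.g. ``<1`` for SO4).  Empty cells are absent fields,
    never zero.  A ``<species>_below_dl`` flag column (true/1) paired with the
    DL in the value cell is accepted as an alternative convention.
    """
    dl_defaults = dict(DEFAULT_DETECTION_LIMITS, **(dl_defaults or {}))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnsError(missing)

    samples: list[WaterSample] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        ions: dict[str, CensoredValue] = {}
        for col, sp in ION_COLUMNS.items():
            if col not in df.columns:
                continue
            flag_col = f"{col[:-4]}_below_dl"
            if flag_col in df.columns and row[flag_col].strip().lower() in ("1", "true", "yes"):
                dl = _parse_float(row[col], line, col) if row[col].strip() else dl_defaults.get(sp, 1.0)
                ions[sp] = CensoredValue.censored(dl)
                continue
            cv = _parse_censored(row[col], line, col, sp, dl_defaults)
            if cv is not None:
                ions[sp] = cv

        ch4 = None
        if "ch4_ugl" in df.columns:
            ch4 = _parse_censored(row["ch4_ugl"], line, "ch4_ugl", "CH4", dl_defaults)

        kwargs: dict = {}
        for col, attr in _SCALAR_COLUMNS.items():
            if col in df.columns and row[col].strip() != "":
                kwargs[attr] = _parse_float(row[col], line, col)

        samples.append(
            WaterSample(
                sample_id=row["sample_id"].strip(),
                aquifer_group=AquiferGroup(row["aquifer_group"].strip()),
                temperature=_parse_float(row["temperature_c"], line, "temperature_c"),
                pH=_parse_float(row["ph"], line, "ph"),
                ions=ions,
                CH4_dissolved=ch4,
                **kwargs,
            )
        )
    return samples


def _format_censored(cv: CensoredValue | None) -> str:
    if cv is None:
        return ""
    if cv.below_dl and cv.value is None:
        return f"<{cv.detection_limit!r}"
    return repr(cv.value)


def write_samples(samples: Iterable[WaterSample], path: str | Path) -> None:
    """Write samples back to CSV in the :func:`read_samples` schema.

    Floats are written with ``repr`` so a read/write/read cycle reproduces
    every numeric field bit-for-bit.
    """
    rows = []
    for s in samples:
        row: dict[str, str] = {
            "sample_id": s.sample_id,
            "aquifer_group": s.aquifer_group.value,
            "temperature_c": repr(s.temperature),
            "ph": repr(s.pH),
        }
        for col, attr in _SCALAR_COLUMNS.items():
            v = getattr(s, attr)
            row[col] = "" if v is None else repr(v)
        for col, sp in ION_COLUMNS.items():
            row[col] = _format_censored(s.ions.get(sp))
        row["ch4_ugl"] = _format_censored(s.CH4_dissolved)
        rows.append(row)
    cols = list(rows[0].keys()) if rows else list(REQUIRED_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def copy_sample(sample: WaterSample, **changes) -> WaterSample:
    """Shallow-copy a sample with replacements (ions dict is copied)."""
    if "ions" not in changes:
        changes["ions"] = dict(sample.ions)
    return replace(sample, **changes)
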