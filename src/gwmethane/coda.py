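"""Isometric log-ratio balances over reaction-species activities.

A sequential binary partition (SBP) of D parts defines D−1 orthonormal
balances.  For a row with r parts coded +1 and s parts coded −1, the balance
is

    b = sqrt(r·s/(r+s)) · ln( g(x₊) / g(x₋) )

with g the geometric mean over each group.  Balances are scale-invariant, so
they are applied here directly to unclosed activity vectors.  For each
microbial reaction the first balance separates products from reactants (and
therefore tracks the reaction quotient), while the remaining balances
partition the reactants into subcompositions describing reactant
availability.

This module is deliberately not a general CoDA toolbox: only the SBP/ilr
machinery the analysis needs is implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml


@dataclass(frozen=True)
class SBP:
    """A sequential binary partition: ordered parts + a (D−1)×D sign matrix."""

    parts: tuple[str, ...]
    matrix: tuple[tuple[int, ...], ...]  # rows of {+1, −1, 0}
    name: str = ""

    def __post_init__(self) -> None:
        report = validate_sbp(self)
        if not report.valid:
            raise ValueError(f"invalid SBP {self.name or self.parts}: {report.errors}")


@dataclass(frozen=True)
class SBPValidationReport:
    valid: bool
    errors: tuple[str, ...] = ()


def _validate(parts: Sequence[str], matrix: Sequence[Sequence[int]]) -> SBPValidationReport:
    errors: list[str] = []
    d = len(parts)
    if len(set(parts)) != d:
        errors.append("duplicate part names")
    if len(matrix) != d - 1:
        errors.append(f"expected {d - 1} rows for {d} parts, got {len(matrix)}")
    for i, row in enumerate(matrix):
        if len(row) != d:
            errors.append(f"row {i + 1}: expected {d} codes, got {len(row)}")
        elif any(c not in (-1, 0, 1) for c in row):
            errors.append(f"row {i + 1}: codes must be in {{+1, -1, 0}}")
        elif not any(c == 1 for c in row) or not any(c == -1 for c in row):
            errors.append(f"row {i + 1}: needs at least one +1 and one -1 code")
    if errors:
        return SBPValidationReport(False, tuple(errors))

    # hierarchy: each row must split exactly one group kept together so far
    groups: list[frozenset[int]] = [frozenset(range(d))]
    for i, row in enumerate(matrix):
        support = frozenset(j for j, c in enumerate(row) if c != 0)
        if support not in groups:
            errors.append(
                f"row {i + 1}: parts {sorted(parts[j] for j in support)} do not form "
                "a group kept together by previous rows"
            )
            continue
        groups.remove(support)
        plus = frozenset(j for j, c in enumerate(row) if c == 1)
        minus = support - plus
        if len(plus) > 1:
            groups.append(plus)
        if len(minus) > 1:
            groups.append(minus)
    return SBPValidationReport(not errors, tuple(errors))


def validate_sbp(sbp: "SBP | tuple") -> SBPValidationReport:
    """Check row count, sign presence, and the partition hierarchy."""
    if isinstance(sbp, SBP):
        return _validate(sbp.parts, sbp.matrix)
    parts, matrix = sbp
    return _validate(parts, matrix)


def balance_coefficient(r: int, s: int) -> float:
    """sqrt(r·s/(r+s)) for a row with r '+1' parts and s '−1' parts."""
    if r < 1 or s < 1:
        raise ValueError(f"r and s must be >= 1, got r={r}, s={s}")
    return math.sqrt(r * s / (r + s))


def ilr_transform(x: Sequence[float], sbp: SBP) -> np.ndarray:
    """The D−1 ilr balances of a strictly positive vector x over sbp.parts."""
    arr = np.asarray(x, dtype=float)
    if arr.shape != (len(sbp.parts),):
        raise ValueError(f"expected {len(sbp.parts)} components, got {arr.shape}")
    for part, v in zip(sbp.parts, arr):
        if v <= 0:
            raise ValueError(
                f"nonpositive component {v} for part {part!r}: "
                "imputation must precede log-ratio analysis"
            )
    log_x = np.log(arr)
    out = np.empty(len(sbp.matrix))
    for i, row in enumerate(sbp.matrix):
        plus = [j for j, c in enumerate(row) if c == 1]
        minus = [j for j, c in enumerate(row) if c == -1]
        coef = balance_coefficient(len(plus), len(minus))
        out[i] = coef * (log_x[plus].mean() - log_x[minus].mean())
    return out


def contrast_matrix(sbp: SBP) -> np.ndarray:
    """The orthonormal (D−1)×D ilr contrast matrix implied by the SBP."""
    d = len(sbp.parts)
    psi = np.zeros((d - 1, d))
    for i, row in enumerate(sbp.matrix):
        plus = [j for j, c in enumerate(row) if c == 1]
        minus = [j for j, c in enumerate(row) if c == -1]
        coef = balance_coefficient(len(plus), len(minus))
        psi[i, plus] = coef / len(plus)
        psi[i, minus] = -coef / len(minus)
    return psi


def load_sbp(path: str | Path) -> SBP:
    """Load an SBP from a YAML file with keys ``parts`` and ``matrix``."""
    raw = yaml.safe_load(Path(path).read_text())
    return SBP(
        parts=tuple(raw["parts"]),
        matrix=tuple(tuple(int(c) for c in row) for row in raw["matrix"]),
        name=str(raw.get("name", Path(path).stem)),
    )


def _load_shipped(name: str) -> SBP:
    text = resources.files("gwmethane").joinpath(f"data/sbp/{name}.yaml").read_text()
    raw = yaml.safe_load(text)
    return SBP(
        parts=tuple(raw["parts"]),
        matrix=tuple(tuple(int(c) for c in row) for row in raw["matrix"]),
        name=str(raw["name"]),
    )


#: Shipped SBPs, parts ordered as in each reaction's partition table.
PATHWAY_SBPS: dict[str, SBP] = {
    name: _load_shipped(fname)
    for name, fname in [
        ("CO2_REDUCTION", "co2_reduction"),
        ("SO4_REDUCTION", "so4_reduction"),
        ("AOM", "aom"),
    ]
}

#: Balance-name prefixes matching the conventional pathway labels.
_PREFIX = {"CO2_REDUCTION": "CO2_ilr", "SO4_REDUCTION": "SO4_ilr", "AOM": "AOM_ilr"}


def pathway_ilr(activities, reaction: str) -> dict[str, float]:
    """Named ilr balances (e.g. CO2_ilr.1..3) of a reaction's activity vector.

    ``activities`` is an ActivitySet or mapping; raises ``KeyError`` naming
    the missing species if the sample lacks one of the reaction's parts.
    """
    sbp = PATHWAY_SBPS[reaction]
    acts = getattr(activities, "activities", activities)
    vec = []
    for part in sbp.parts:
        a = acts.get(part)
        if a is None:
            raise KeyError(f"{reaction}: no activity for part {part!r}")
        vec.append(a)
    balances = ilr_transform(vec, sbp)
    prefix = _PREFIX[reaction]
    return {f"{prefix}.{i + 1}": float(b) for i, b in enumerate(balances)}
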