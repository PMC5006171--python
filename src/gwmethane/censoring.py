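"""Left-censored (below detection limit) concentration imputation.

Log-ratio and thermodynamic machinery require strictly positive
concentrations, so below-DL observations must be replaced by positive values
smaller than their detection limit before analysis.  Two schemes are offered:

* ``MULTIPLICATIVE_REPLACEMENT`` (default): the deterministic compositional
  convention of substituting a fixed fraction of the DL (0.65·DL by default).
* ``LOGRATIO_DATA_AUGMENTATION``: a seeded Monte-Carlo data-augmentation
  scheme on log concentrations.  Per species and aquifer group, censored
  values are drawn from a lognormal fitted to the observed values, truncated
  above at each observation's DL, iterating the fit over augmented data for a
  configurable number of sweeps.

Imputation is performed per aquifer group because the groups occupy distinct
compositional ranges; a species with no uncensored observations in any group
falls back to multiplicative replacement with a logged warning.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .samples import AquiferGroup, CensoredValue, WaterSample, copy_sample

logger = logging.getLogger(__name__)

#: Species considered for the covariance/augmentation pool.
DA_SPECIES = ("Na", "K", "Ca", "Mg", "HCO3", "Cl", "SO4")


class ImputationMethod(enum.Enum):
    MULTIPLICATIVE_REPLACEMENT = "MULTIPLICATIVE_REPLACEMENT"
    LOGRATIO_DATA_AUGMENTATION = "LOGRATIO_DATA_AUGMENTATION"


@dataclass(frozen=True)
class ImputationConfig:
    method: ImputationMethod = ImputationMethod.MULTIPLICATIVE_REPLACEMENT
    dl_fraction: float = 0.65
    n_chains: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dl_fraction < 1:
            raise ValueError(f"dl_fraction must be in (0, 1), got {self.dl_fraction}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be a positive integer")


@dataclass
class ImputationResult:
    samples: list[WaterSample]
    report: pd.DataFrame  # species, n_censored, method, seed, min/max imputed
    config: ImputationConfig = field(repr=False, default=None)


def _imputed(cv: CensoredValue, value: float) -> CensoredValue:
    # imputed values live strictly inside (0, DL); keep provenance
    value = min(max(value, np.nextafter(0.0, 1.0)), np.nextafter(cv.detection_limit, 0.0))
    return replace(cv, value=float(value), below_dl=False, imputed=True)


def _da_impute_species(
    dls: np.ndarray,
    observed_log: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Truncated-lognormal data augmentation for one species' censored cells.

    ``dls``: detection limits of the censored observations.  ``observed_log``:
    natural-log values of the uncensored observations in the same pool.
    Returns imputed concentrations in (0, DL) per censored cell.
    """
    mu = float(np.mean(observed_log))
    sigma = float(np.std(observed_log, ddof=1)) if observed_log.size > 1 else 0.5
    sigma = max(sigma, 1e-3)
    log_dls = np.log(dls)
    draws = np.empty_like(log_dls)
    for _ in range(n_sweeps):
        b = (log_dls - mu) / sigma
        draws = np.atleast_1d(
            stats.truncnorm.rvs(
                -np.inf, b, loc=mu, scale=sigma, size=log_dls.size, random_state=rng
            )
        )
        augmented = np.concatenate([observed_log, draws])
        mu = float(np.mean(augmented))
        sigma = max(float(np.std(augmented, ddof=1)), 1e-3)
    return np.exp(draws)


def impute_below_dl(
    samples: list[WaterSample], config: ImputationConfig | None = None
) -> ImputationResult:
    """Replace every below-DL concentration by a positive value < its DL.

    Uncensored values pass through untouched; the operation is idempotent
    (imputed cells carry ``imputed=True`` and are no longer flagged
    ``below_dl``).  Deterministic given (method, seed).
    """
    config = config or ImputationConfig()
    rng = np.random.default_rng(config.seed)
    out = [copy_sample(s) for s in samples]

    # collect censored cells: (sample index, kind, species)
    records: list[tuple[int, str, str]] = []
    for i, s in enumerate(out):
        for sp, cv in s.ions.items():
            if cv.below_dl:
                records.append((i, "ion", sp))
        if s.CH4_dissolved is not None and s.CH4_dissolved.below_dl:
            records.append((i, "ch4", "CH4"))

    report_rows: dict[str, dict] = {}

    def _note(sp: str, value: float, method: ImputationMethod) -> None:
        r = report_rows.setdefault(
            sp,
            {
                "species": sp,
                "n_censored": 0,
                "method": method.value,
                "seed": config.seed,
                "min_imputed": math.inf,
                "max_imputed": -math.inf,
            },
        )
        r["n_censored"] += 1
        r["min_imputed"] = min(r["min_imputed"], value)
        r["max_imputed"] = max(r["max_imputed"], value)

    def _get_cv(i: int, kind: str, sp: str) -> CensoredValue:
        return out[i].ions[sp] if kind == "ion" else out[i].CH4_dissolved

    def _set_cv(i: int, kind: str, sp: str, cv: CensoredValue) -> None:
        if kind == "ion":
            out[i].ions[sp] = cv
        else:
            out[i].CH4_dissolved = cv

    if config.method is ImputationMethod.MULTIPLICATIVE_REPLACEMENT:
        for i, kind, sp in records:
            cv = _get_cv(i, kind, sp)
            value = config.dl_fraction * cv.detection_limit
            _set_cv(i, kind, sp, _imputed(cv, value))
            _note(sp, value, config.method)
    else:
        # group censored cells by (aquifer group, species); draw jointly
        by_group: dict[tuple[AquiferGroup, str], list[tuple[int, str]]] = {}
        for i, kind, sp in records:
            by_group.setdefault((out[i].aquifer_group, sp), []).append((i, kind))
        for (group, sp), cells in sorted(
            by_group.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
        ):
            observed = _uncensored_log_values(out, sp, group)
            if observed.size == 0:
                observed = _uncensored_log_values(out, sp, None)
            if observed.size == 0:
                logger.warning(
                    "species %s entirely censored: falling back to multiplicative "
                    "replacement at %.2f·DL",
                    sp,
                    config.dl_fraction,
                )
                for i, kind in cells:
                    cv = _get_cv(i, kind, sp)
                    value = config.dl_fraction * cv.detection_limit
                    _set_cv(i, kind, sp, _imputed(cv, value))
                    _note(sp, value, ImputationMethod.MULTIPLICATIVE_REPLACEMENT)
                continue
            dls = np.array([_get_cv(i, kind, sp).detection_limit for i, kind in cells])
            values = _da_impute_species(dls, observed, config.n_chains, rng)
            for (i, kind), value in zip(cells, values):
                cv = _get_cv(i, kind, sp)
                _set_cv(i, kind, sp, _imputed(cv, value))
                _note(sp, float(value), config.method)

    report = pd.DataFrame(
        sorted(report_rows.values(), key=lambda r: r["species"]),
        columns=["species", "n_censored", "method", "seed", "min_imputed", "max_imputed"],
    )
    return ImputationResult(samples=out, report=report, config=config)


def _uncensored_log_values(
    samples: list[WaterSample], species: str, group: AquiferGroup | None
) -> np.ndarray:
    vals = []
    for s in samples:
        if group is not None and s.aquifer_group is not group:
            continue
        cv = s.CH4_dissolved if species == "CH4" else s.ions.get(species)
        if cv is not None and not cv.below_dl and not cv.imputed and cv.value and cv.value > 0:
            vals.append(math.log(cv.value))
    return np.asarray(vals)
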