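"""End-to-end analysis pipeline.

Order of stages: read → below-DL imputation → speciation (activities) →
thermodynamics (ΔG°_T, ΔG, ΔG/e⁻ per reaction) → ilr balances per pathway →
isotope fractionation factors and rule-based pathway classification.

Every number in the output tables is produced by an operation from the
library modules; the pipeline only sequences them, records skip reasons, and
writes tables.  Multiple reactions are always computed for every eligible
sample; the pathway call comes only from the isotope rules, with ΔG/e⁻
reported as context — the thermodynamics never picks "the" pathway.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coda, thermo
from .censoring import ImputationConfig, impute_below_dl
from .isotopes import (
    FractionationResult,
    Pathway,
    PathwayThresholds,
    classify_pathway,
    fractionation_factor,
)
from .samples import WaterSample, read_samples
from .speciation import H2Config, SpeciationError, gypsum_si, species_activities
from .species import mgL_to_meqL, mgL_to_molL

logger = logging.getLogger(__name__)

_REACTIONS = ("CO2_REDUCTION", "SO4_REDUCTION", "AOM")


@dataclass
class RunConfig:
    input_path: str | Path
    out_dir: str | Path | None = None
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    h2: H2Config = field(default_factory=H2Config)
    thresholds: PathwayThresholds = field(default_factory=PathwayThresholds)
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    per_sample: pd.DataFrame
    summary: pd.DataFrame
    imputation_report: pd.DataFrame
    log: list[str]


def _asdict_jsonable(obj) -> dict:
    def convert(v):
        if isinstance(v, enum.Enum):
            return v.value
        if isinstance(v, Path):
            return str(v)
        if dataclasses.is_dataclass(v):
            return {k: convert(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        return v

    return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}


def _safe_meq(sample: WaterSample, sp: str) -> float:
    cv = sample.ions.get(sp)
    if cv is None or cv.value is None:
        return np.nan
    return mgL_to_meqL(cv.value, sp)


def analyse_sample(
    sample: WaterSample,
    h2: H2Config,
    thresholds: PathwayThresholds,
    log: list[str],
) -> dict:
    """One output row for one imputed sample; NaN where data are absent."""
    row: dict = {
        "sample_id": sample.sample_id,
        "aquifer_group": sample.aquifer_group.value,
        "screen_depth_m": sample.screen_depth if sample.screen_depth is not None else np.nan,
        "temperature_c": sample.temperature,
        "ph": sample.pH,
    }
    for sp in ("Cl", "SO4", "NO3", "HCO3"):
        row[f"{sp.lower()}_meql"] = _safe_meq(sample, sp)

    br = sample.ions.get("Br")
    cl = sample.ions.get("Cl")
    if br is not None and cl is not None and br.value and cl.value:
        row["br_cl_molar"] = mgL_to_molL(br.value, "Br") / mgL_to_molL(cl.value, "Cl")
    else:
        row["br_cl_molar"] = np.nan

    # speciation
    try:
        acts = species_activities(sample, h2_config=h2)
    except SpeciationError as exc:
        log.append(f"{sample.sample_id}: speciation skipped ({exc})")
        acts = None
    if acts is not None:
        row["ionic_strength_moll"] = acts.ionic_strength
        for sp in ("H", "H2", "HCO3", "CH4", "SO4", "HS"):
            row[f"a_{sp.lower()}"] = acts.get(sp, np.nan)
        try:
            row["gypsum_si"] = gypsum_si(sample)
        except SpeciationError as exc:
            log.append(f"{sample.sample_id}: gypsum SI skipped ({exc})")
            row["gypsum_si"] = np.nan

        # thermodynamics + ilr per reaction
        for rxn in _REACTIONS:
            dg0 = thermo.delta_g0_T(rxn, sample.temperature)
            row[f"dg0_{rxn.lower()}"] = dg0
            try:
                ln_q = thermo.ln_reaction_quotient(rxn, acts)
            except (thermo.MissingActivityError, ValueError) as exc:
                log.append(f"{sample.sample_id}: {rxn} quotient skipped ({exc})")
                row[f"ln_q_{rxn.lower()}"] = np.nan
                row[f"dg_{rxn.lower()}"] = np.nan
                row[f"dg_per_e_{rxn.lower()}"] = np.nan
            else:
                dg = thermo.delta_g(rxn, sample.temperature, ln_Q=ln_q)
                row[f"ln_q_{rxn.lower()}"] = ln_q
                row[f"dg_{rxn.lower()}"] = dg
                row[f"dg_per_e_{rxn.lower()}"] = thermo.delta_g_per_electron(dg, rxn)
            try:
                row.update(coda.pathway_ilr(acts, rxn))
            except KeyError as exc:
                log.append(f"{sample.sample_id}: {rxn} ilr skipped ({exc.args[0]})")

    # isotopes
    alpha_c = alpha_h = None
    if sample.d13C_DIC is not None and sample.d13C_CH4 is not None:
        alpha_c = fractionation_factor(sample.d13C_DIC, sample.d13C_CH4)
    if sample.d2H_H2O is not None and sample.d2H_CH4 is not None:
        alpha_h = fractionation_factor(sample.d2H_H2O, sample.d2H_CH4)
    row["alpha_dic_ch4"] = alpha_c if alpha_c is not None else np.nan
    row["alpha_h2o_ch4"] = alpha_h if alpha_h is not None else np.nan
    row["d2h_h2o_permil"] = sample.d2H_H2O if sample.d2H_H2O is not None else np.nan
    row["d18o_h2o_permil"] = sample.d18O_H2O if sample.d18O_H2O is not None else np.nan
    row["d37cl_permil"] = sample.d37Cl if sample.d37Cl is not None else np.nan

    so4_meq = row["so4_meql"]
    call = classify_pathway(
        FractionationResult(alpha_DIC_CH4=alpha_c, alpha_H2O_CH4=alpha_h),
        d2H_CH4=sample.d2H_CH4,
        SO4_meqL=None if np.isnan(so4_meq) else so4_meq,
        thresholds=thresholds,
    )
    row["pathway_call"] = call.call.value
    row["evidence"] = "; ".join(call.evidence)
    return row


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; per-sample failures are logged, never fatal."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    samples = read_samples(config.input_path)
    if not samples:
        raise ValueError(f"empty input table: {config.input_path}")

    log: list[str] = []
    imputation = dataclasses.replace(config.imputation, seed=config.seed)
    imp = impute_below_dl(samples, imputation)
    log.append(
        f"imputed {int(imp.report['n_censored'].sum()) if len(imp.report) else 0} "
        f"censored cells ({imputation.method.value}, seed {imputation.seed})"
    )

    rows = [analyse_sample(s, config.h2, config.thresholds, log) for s in imp.samples]
    per_sample = pd.DataFrame(rows)

    numeric = per_sample.select_dtypes(include=[float, int]).columns
    summary = (
        per_sample.groupby("aquifer_group")[list(numeric)]
        .agg(["min", "median", "max"])
        .stack(level=0, future_stack=True)
        .rename_axis(["aquifer_group", "variable"])
        .reset_index()
        .sort_values(["aquifer_group", "variable"], kind="mergesort")
        .reset_index(drop=True)
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_sample.to_csv(out / "per_sample.csv", index=False)
        summary.to_csv(out / "aquifer_summary.csv", index=False)
        imp.report.to_csv(out / "imputation_report.csv", index=False)
        (out / "processing_log.txt").write_text("\n".join(log) + "\n")
        (out / "run_config.yaml").write_text(
            yaml.safe_dump(_asdict_jsonable(config), sort_keys=True)
        )

    return PipelineResult(
        per_sample=per_sample,
        summary=summary,
        imputation_report=imp.report,
        log=log,
    )
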