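"""Synthetic catchment generator.

No per-sample field data are published for the study system — only
per-aquifer ranges, detection rates and the qualitative structure (an
inverse SO4–CH4 relationship, pathway-consistent isotope pairing).  This
module generates virtual catchments with exactly that statistical structure
so every pipeline stage is testable offline:

* each aquifer has a profile whose bounds are the printed ranges (chloride,
  sulfate with censoring, CH4 detection rate and range, isotope deltas,
  temperature, pH, depth);
* CH4 detectability follows a logistic link in sulfate (meq/L, midpoint
  1 meq/L by default): high-sulfate waters rarely carry CH4, and detected
  CH4 concentrations decrease with sulfate;
* a latent methanogenic pathway (CO2 reduction vs acetoclastic) is drawn per
  CH4-bearing sample from the profile's mixture weights, and the CH4 isotope
  deltas are constructed by inverting the fractionation-factor definition:
  δCH4 = (1000 + δX)/α_true − 1000, with α_true = (1.07, 1.2) for CO2
  reduction and (1.04, 1.4) for acetoclastic methanogenesis, plus
  configurable ‰ noise.

Latent labels are returned (and written) separately from the sample table so
pipeline code cannot accidentally consume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .samples import AquiferGroup, CensoredValue, WaterSample, write_samples
from .species import mgL_to_meqL

#: True fractionation factors (carbon, hydrogen) per latent pathway.
PATHWAY_ALPHAS: dict[str, tuple[float, float]] = {
    "CO2_REDUCTION": (1.07, 1.2),
    "ACETOCLASTIC": (1.04, 1.4),
}


@dataclass(frozen=True)
class AquiferProfile:
    """Per-aquifer generator parameters; every printed bound appears verbatim."""

    aquifer: AquiferGroup
    cl_range: tuple[float, float]  # mg/L
    so4_range: tuple[float, float]  # mg/L (uncensored draws)
    so4_censor_prob: float  # P(SO4 < DL of 1 mg/L)
    ch4_detection_rate: float
    ch4_range: tuple[float, float]  # µg/L
    d13c_ch4_range: tuple[float, float]
    d2h_ch4_range: tuple[float, float]
    d13c_dic_range: tuple[float, float]
    d2h_h2o_range: tuple[float, float]
    d18o_h2o_range: tuple[float, float]
    temperature_range: tuple[float, float]
    ph_range: tuple[float, float]
    depth_range: tuple[float, float]
    pathway_weights: dict[str, float]
    ion_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    d37cl_range: tuple[float, float] = (-1.0, 1.0)
    doc_range: tuple[float, float] = (0.1, 2.0)
    do_range: tuple[float, float] = (0.0, 0.5)

    def __post_init__(self) -> None:
        for name in (
            "cl_range", "so4_range", "ch4_range", "d13c_ch4_range", "d2h_ch4_range",
            "d13c_dic_range", "d2h_h2o_range", "d18o_h2o_range", "temperature_range",
            "ph_range", "depth_range", "d37cl_range", "doc_range", "do_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{self.aquifer.value}: {name} bounds unordered ({lo} > {hi})")
        total = sum(self.pathway_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.aquifer.value}: pathway weights sum to {total}, not 1")


def default_profiles() -> dict[AquiferGroup, AquiferProfile]:
    """Profiles encoding the published per-aquifer ranges and detection rates."""
    return {
        AquiferGroup.GAS_RESERVOIR: AquiferProfile(
            aquifer=AquiferGroup.GAS_RESERVOIR,
            cl_range=(1000.0, 4500.0),
            so4_range=(1.0, 3.0),
            so4_censor_prob=0.95,
            ch4_detection_rate=1.0,
            ch4_range=(2000.0, 25000.0),
            d13c_ch4_range=(-58.0, -49.0),
            d2h_ch4_range=(-210.0, -198.0),
            d13c_dic_range=(9.0, 23.0),
            d2h_h2o_range=(-44.1, -33.1),
            d18o_h2o_range=(-7.2, -5.2),
            temperature_range=(25.0, 35.0),
            ph_range=(7.5, 8.8),
            depth_range=(200.0, 500.0),
            pathway_weights={"CO2_REDUCTION": 1.0},
            ion_ranges={
                "Na": (800.0, 3000.0),
                "K": (5.0, 30.0),
                "Ca": (2.0, 30.0),
                "Mg": (1.0, 30.0),
                "HCO3": (500.0, 1500.0),
            },
            d37cl_range=(-2.52, -0.1),
            doc_range=(0.1, 1.0),
            do_range=(0.0, 0.3),
        ),
        AquiferGroup.SHALLOW_COAL_MEASURES: AquiferProfile(
            aquifer=AquiferGroup.SHALLOW_COAL_MEASURES,
            cl_range=(82.0, 4680.0),
            so4_range=(0.1, 488.0),
            so4_censor_prob=0.3,
            ch4_detection_rate=7.0 / 14.0,
            ch4_range=(95.0, 18000.0),
            d13c_ch4_range=(-80.0, -50.0),
            d2h_ch4_range=(-310.0, -210.0),
            d13c_dic_range=(-15.9, -3.5),
            d2h_h2o_range=(-36.2, -28.2),
            d18o_h2o_range=(-5.5, -4.3),
            temperature_range=(20.0, 30.0),
            ph_range=(7.0, 8.5),
            depth_range=(20.0, 200.0),
            pathway_weights={"CO2_REDUCTION": 13.0 / 14.0, "ACETOCLASTIC": 1.0 / 14.0},
            ion_ranges={
                "Na": (100.0, 1500.0),
                "K": (2.0, 20.0),
                "Ca": (5.0, 150.0),
                "Mg": (5.0, 150.0),
                "HCO3": (300.0, 1200.0),
            },
            d37cl_range=(-1.11, 0.8),
            doc_range=(0.3, 1.6),
            do_range=(0.0, 0.5),
        ),
        AquiferGroup.ALLUVIUM: AquiferProfile(
            aquifer=AquiferGroup.ALLUVIUM,
            cl_range=(35.0, 8700.0),
            so4_range=(1.0, 988.0),
            so4_censor_prob=0.3,
            ch4_detection_rate=5.0 / 23.0,
            ch4_range=(10.0, 535.0),
            d13c_ch4_range=(-78.0, -49.0),
            d2h_ch4_range=(-315.0, -186.0),
            d13c_dic_range=(-15.3, -6.6),
            d2h_h2o_range=(-38.2, -26.8),
            d18o_h2o_range=(-5.9, -4.2),
            temperature_range=(18.0, 26.0),
            ph_range=(6.8, 8.2),
            depth_range=(18.0, 110.0),
            pathway_weights={"CO2_REDUCTION": 0.8, "ACETOCLASTIC": 0.2},
            ion_ranges={
                "Na": (50.0, 1500.0),
                "K": (1.0, 20.0),
                "Ca": (10.0, 200.0),
                "Mg": (5.0, 150.0),
                "HCO3": (200.0, 800.0),
            },
            d37cl_range=(-0.72, 0.89),
            doc_range=(0.1, 3.9),
            do_range=(0.0, 1.0),
        ),
        AquiferGroup.KUMBARILLA: AquiferProfile(
            aquifer=AquiferGroup.KUMBARILLA,
            cl_range=(100.0, 2000.0),
            so4_range=(0.1, 100.0),
            so4_censor_prob=0.4,
            ch4_detection_rate=1.0 / 3.0,
            ch4_range=(50.0, 5000.0),
            d13c_ch4_range=(-72.0, -64.0),
            d2h_ch4_range=(-230.0, -200.0),
            d13c_dic_range=(-15.0, -5.0),
            d2h_h2o_range=(-36.0, -28.0),
            d18o_h2o_range=(-5.5, -4.3),
            temperature_range=(20.0, 28.0),
            ph_range=(7.0, 8.5),
            depth_range=(85.0, 200.0),
            pathway_weights={"CO2_REDUCTION": 1.0},
            ion_ranges={
                "Na": (100.0, 1000.0),
                "K": (2.0, 20.0),
                "Ca": (5.0, 100.0),
                "Mg": (5.0, 100.0),
                "HCO3": (300.0, 1000.0),
            },
            d37cl_range=(-1.0, 0.8),
            doc_range=(0.1, 1.0),
            do_range=(0.0, 0.5),
        ),
    }


#: Wells sampled per aquifer in the emulated study design.
DEFAULT_N_PER_AQUIFER: dict[AquiferGroup, int] = {
    AquiferGroup.ALLUVIUM: 23,
    AquiferGroup.SHALLOW_COAL_MEASURES: 14,
    AquiferGroup.GAS_RESERVOIR: 21,
    AquiferGroup.KUMBARILLA: 3,
}

_ID_PREFIX = {
    AquiferGroup.ALLUVIUM: "AL",
    AquiferGroup.SHALLOW_COAL_MEASURES: "CM",
    AquiferGroup.GAS_RESERVOIR: "GR",
    AquiferGroup.KUMBARILLA: "KB",
}

SO4_DL_MGL = 1.0
NO3_DL_MGL = 0.01
HS_DL_MGL = 0.1
CH4_DL_UGL = 10.0


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def _loguniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if lo <= 0 or hi / lo < 10:
        return _uniform(rng, bounds)
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _detection_probability(
    so4_meq: float, base_rate: float, midpoint_meq: float, steepness: float
) -> float:
    """Logistic CH4-detectability link in sulfate (meq/L)."""
    p_hi = min(1.0, 2.0 * base_rate)
    return p_hi / (1.0 + math.exp(steepness * (math.log10(max(so4_meq, 1e-6)) - math.log10(midpoint_meq))))


def _ch4_given_so4(
    rng: np.random.Generator,
    so4_meq: float,
    profile: AquiferProfile,
    jitter_log10: float = 0.3,
) -> float:
    """Detected CH4 concentration decreasing in sulfate (log-log link)."""
    lo, hi = profile.ch4_range
    so4_lo = mgL_to_meqL(max(profile.so4_range[0], 0.1 * SO4_DL_MGL), "SO4")
    so4_hi = mgL_to_meqL(profile.so4_range[1], "SO4")
    x = (math.log10(max(so4_meq, so4_lo)) - math.log10(so4_lo)) / (
        math.log10(so4_hi) - math.log10(so4_lo)
    )
    x = min(max(x, 0.0), 1.0)
    log_ch4 = math.log10(hi) + (math.log10(lo) - math.log10(hi)) * x
    log_ch4 += rng.normal(0.0, jitter_log10)
    return float(10 ** min(max(log_ch4, math.log10(lo)), math.log10(hi)))


def generate_catchment(
    profiles: dict[AquiferGroup, AquiferProfile] | None = None,
    n_per_aquifer: dict[AquiferGroup, int] | None = None,
    seed: int = 0,
    noise_c_permil: float = 0.5,
    noise_h_permil: float = 1.5,
    so4_link_midpoint_meq: float = 1.0,
    so4_link_steepness: float = 4.0,
) -> tuple[list[WaterSample], pd.DataFrame]:
    """Generate a virtual catchment; returns (samples, latent-label table).

    Fully reproducible from ``seed``.  The label table has columns
    ``sample_id`` and ``pathway`` ("CO2_REDUCTION", "ACETOCLASTIC", or
    "NONE" for wells without detectable CH4).
    """
    profiles = profiles or default_profiles()
    n_per_aquifer = n_per_aquifer or DEFAULT_N_PER_AQUIFER
    rng = np.random.default_rng(seed)

    samples: list[WaterSample] = []
    labels: list[dict] = []

    for aquifer in sorted(n_per_aquifer, key=lambda a: a.value):
        n = n_per_aquifer[aquifer]
        if n < 1:
            raise ValueError(f"n_per_aquifer[{aquifer.value}] must be >= 1")
        profile = profiles.get(aquifer)
        if profile is None:
            raise ValueError(f"no profile configured for aquifer {aquifer.value}")
        pathways = sorted(profile.pathway_weights)
        weights = np.array([profile.pathway_weights[p] for p in pathways])

        for i in range(n):
            sid = f"{_ID_PREFIX[aquifer]}{i + 1:03d}"
            ions: dict[str, CensoredValue] = {}

            cl = _loguniform(rng, profile.cl_range)
            ions["Cl"] = CensoredValue.detected(cl, 1.0)
            ions["Br"] = CensoredValue.detected(cl * rng.uniform(0.002, 0.004), 0.01)

            if rng.uniform() < profile.so4_censor_prob:
                ions["SO4"] = CensoredValue.censored(SO4_DL_MGL)
                so4_meq = mgL_to_meqL(0.5 * SO4_DL_MGL, "SO4")
            else:
                so4 = _loguniform(rng, profile.so4_range)
                so4 = max(so4, SO4_DL_MGL)  # uncensored draws sit at/above DL
                ions["SO4"] = CensoredValue.detected(so4, SO4_DL_MGL)
                so4_meq = mgL_to_meqL(so4, "SO4")

            for sp, bounds in profile.ion_ranges.items():
                ions[sp] = CensoredValue.detected(_loguniform(rng, bounds), 1.0)
            if rng.uniform() < 0.3:
                ions["NO3"] = CensoredValue.detected(rng.uniform(NO3_DL_MGL, 0.37), NO3_DL_MGL)
            else:
                ions["NO3"] = CensoredValue.censored(NO3_DL_MGL)
            if rng.uniform() < 0.05:
                ions["HS"] = CensoredValue.detected(rng.uniform(HS_DL_MGL, 0.5), HS_DL_MGL)
            else:
                ions["HS"] = CensoredValue.censored(HS_DL_MGL)

            p_detect = _detection_probability(
                so4_meq, profile.ch4_detection_rate, so4_link_midpoint_meq, so4_link_steepness
            )
            ch4_detected = rng.uniform() < p_detect

            d2h_h2o = _uniform(rng, profile.d2h_h2o_range)
            d18o = _uniform(rng, profile.d18o_h2o_range)
            d13c_dic = _uniform(rng, profile.d13c_dic_range)

            if ch4_detected:
                pathway = str(rng.choice(pathways, p=weights / weights.sum()))
                alpha_c, alpha_h = PATHWAY_ALPHAS[pathway]
                ch4_conc = _ch4_given_so4(rng, so4_meq, profile)
                ch4 = CensoredValue.detected(ch4_conc, CH4_DL_UGL)
                d13c_ch4 = (1000.0 + d13c_dic) / alpha_c - 1000.0
                d2h_ch4 = (1000.0 + d2h_h2o) / alpha_h - 1000.0
                if noise_c_permil > 0:
                    d13c_ch4 += rng.normal(0.0, noise_c_permil)
                if noise_h_permil > 0:
                    d2h_ch4 += rng.normal(0.0, noise_h_permil)
                d37cl = _uniform(rng, profile.d37cl_range)
            else:
                pathway = "NONE"
                ch4 = CensoredValue.censored(CH4_DL_UGL)
                d13c_ch4 = d2h_ch4 = d37cl = None

            samples.append(
                WaterSample(
                    sample_id=sid,
                    aquifer_group=aquifer,
                    temperature=_uniform(rng, profile.temperature_range),
                    pH=_uniform(rng, profile.ph_range),
                    screen_depth=_uniform(rng, profile.depth_range),
                    DO=_uniform(rng, profile.do_range),
                    ions=ions,
                    CH4_dissolved=ch4,
                    DOC=_uniform(rng, profile.doc_range),
                    tritium=float(rng.uniform(0.02, 0.5)) if rng.uniform() < 0.1 else None,
                    d13C_CH4=d13c_ch4,
                    d2H_CH4=d2h_ch4,
                    d13C_DIC=d13c_dic,
                    d2H_H2O=d2h_h2o,
                    d18O_H2O=d18o,
                    d37Cl=d37cl,
                )
            )
            labels.append({"sample_id": sid, "pathway": pathway})

    return samples, pd.DataFrame(labels, columns=["sample_id", "pathway"])


def write_catchment(
    out_dir: str | Path,
    seed: int = 0,
    **kwargs,
) -> tuple[Path, Path]:
    """Generate and write samples.csv + labels.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, labels = generate_catchment(seed=seed, **kwargs)
    samples_path = out / "samples.csv"
    labels_path = out / "labels.csv"
    write_samples(samples, samples_path)
    labels.to_csv(labels_path, index=False)
    return samples_path, labels_path
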