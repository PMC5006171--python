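"""Synthetic catchment generator: printed bounds, determinism, structure."""

import numpy as np
import pytest
from scipy import stats

from gwmethane.isotopes import FractionationResult, Pathway, classify_pathway, fractionation_factor
from gwmethane.samples import AquiferGroup
from gwmethane.synthetic import (
    DEFAULT_N_PER_AQUIFER,
    default_profiles,
    generate_catchment,
)


class TestDefaultProfiles:
    def test_published_bounds_encoded_verbatim(self):
        p = default_profiles()
        gr = p[AquiferGroup.GAS_RESERVOIR]
        assert gr.ch4_range == (2000.0, 25000.0)
        assert gr.cl_range == (1000.0, 4500.0)
        assert gr.d13c_ch4_range == (-58.0, -49.0)
        assert gr.d2h_ch4_range == (-210.0, -198.0)
        assert gr.d13c_dic_range == (9.0, 23.0)
        scm = p[AquiferGroup.SHALLOW_COAL_MEASURES]
        assert scm.d13c_dic_range == (-15.9, -3.5)
        assert scm.ch4_range == (95.0, 18000.0)
        assert scm.ch4_detection_rate == pytest.approx(7 / 14)
        al = p[AquiferGroup.ALLUVIUM]
        assert al.ch4_detection_rate == pytest.approx(5 / 23)
        assert al.cl_range == (35.0, 8700.0)
        assert al.ch4_range == (10.0, 535.0)

    def test_mixture_weights_sum_to_one(self):
        for profile in default_profiles().values():
            assert sum(profile.pathway_weights.values()) == pytest.approx(1.0)


class TestGeneration:
    def test_same_seed_identical(self):
        a, la = generate_catchment(seed=7)
        b, lb = generate_catchment(seed=7)
        assert a == b
        assert la.equals(lb)

    def test_study_design_counts(self):
        samples, labels = generate_catchment(seed=0)
        assert len(samples) == sum(DEFAULT_N_PER_AQUIFER.values()) == len(labels)

    def test_drawn_values_inside_profile_bounds(self):
        profiles = default_profiles()
        samples, _ = generate_catchment(seed=3)
        for s in samples:
            p = profiles[s.aquifer_group]
            assert p.temperature_range[0] <= s.temperature <= p.temperature_range[1]
            assert p.ph_range[0] <= s.pH <= p.ph_range[1]
            assert p.depth_range[0] <= s.screen_depth <= p.depth_range[1]
            assert p.cl_range[0] <= s.ions["Cl"].value <= p.cl_range[1]
            assert p.d13c_dic_range[0] <= s.d13C_DIC <= p.d13c_dic_range[1]
            assert p.d2h_h2o_range[0] <= s.d2H_H2O <= p.d2h_h2o_range[1]
            ch4 = s.CH4_dissolved
            if not ch4.below_dl:
                assert p.ch4_range[0] <= ch4.value <= p.ch4_range[1]

    def test_gas_reservoir_sulfate_mostly_censored(self):
        samples, _ = generate_catchment(
            seed=5, n_per_aquifer={AquiferGroup.GAS_RESERVOIR: 200}
        )
        frac = np.mean([s.ions["SO4"].below_dl for s in samples])
        assert frac >= 0.9

    @pytest.mark.parametrize(
        "aquifer", [AquiferGroup.SHALLOW_COAL_MEASURES, AquiferGroup.ALLUVIUM]
    )
    def test_inverse_so4_ch4_relationship(self, aquifer):
        """Spearman correlation between SO4 and CH4 is negative (censored
        cells enter at their detection limits), averaged over seeds."""
        rhos = []
        for seed in (1, 2, 3):
            samples, _ = generate_catchment(seed=seed, n_per_aquifer={aquifer: 200})
            so4 = [
                s.ions["SO4"].value if not s.ions["SO4"].below_dl else s.ions["SO4"].detection_limit
                for s in samples
            ]
            ch4 = [
                s.CH4_dissolved.value
                if not s.CH4_dissolved.below_dl
                else s.CH4_dissolved.detection_limit
                for s in samples
            ]
            rhos.append(stats.spearmanr(so4, ch4).statistic)
        assert np.mean(rhos) < 0

    def test_noise_free_labels_recovered_exactly(self):
        """With zero isotope noise, inverting the fractionation definition is
        exact, so the rule classifier recovers every latent label."""
        samples, labels = generate_catchment(
            seed=11, noise_c_permil=0.0, noise_h_permil=0.0
        )
        truth = dict(zip(labels["sample_id"], labels["pathway"]))
        n_checked = 0
        for s in samples:
            if s.d13C_CH4 is None:
                assert truth[s.sample_id] == "NONE"
                continue
            call = classify_pathway(
                FractionationResult(
                    fractionation_factor(s.d13C_DIC, s.d13C_CH4),
                    fractionation_factor(s.d2H_H2O, s.d2H_CH4),
                ),
                d2H_CH4=s.d2H_CH4,
            )
            expected = {
                "CO2_REDUCTION": Pathway.CO2_REDUCTION,
                "ACETOCLASTIC": Pathway.ACETOCLASTIC_OR_OXIDATION,
            }[truth[s.sample_id]]
            assert call.call is expected, s.sample_id
            n_checked += 1
        assert n_checked > 0

    def test_empty_aquifer_request_rejected(self):
        with pytest.raises(ValueError, match="n_per_aquifer"):
            generate_catchment(n_per_aquifer={AquiferGroup.ALLUVIUM: 0})
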