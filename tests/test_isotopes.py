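"""Fractionation factors, Rayleigh curves, pathway rules, mixing lines."""

import itertools

import numpy as np
import pytest

from gwmethane.isotopes import (
    FractionationResult,
    Pathway,
    PathwayThresholds,
    RayleighOrientation,
    classify_pathway,
    fractionation_factor,
    mixing_line_intercept,
    rayleigh,
)


class TestFractionationFactor:
    def test_identical_pools_give_unity(self):
        assert fractionation_factor(-50.0, -50.0) == 1.0

    def test_reservoir_carbon_midpoints(self):
        # midpoint δ13C-DIC=+16‰ vs δ13C-CH4=−53.5‰ -> α ≈ 1.07
        assert fractionation_factor(16.0, -53.5) == pytest.approx(1.0734, abs=1e-4)

    def test_reservoir_hydrogen_midpoints(self):
        assert fractionation_factor(-38.6, -204.0) == pytest.approx(1.2078, abs=1e-4)

    def test_uses_1000_plus_delta_not_delta_ratio(self):
        # a delta-ratio implementation would return 16/-53.5 ≈ −0.3; adding a
        # common offset must change α except at offset 0
        a0 = fractionation_factor(16.0, -53.5)
        a_shift = fractionation_factor(16.0 + 10, -53.5 + 10)
        assert a0 != pytest.approx(a_shift)
        assert a0 > 1

    def test_undefined_at_minus_1000(self):
        with pytest.raises(ValueError):
            fractionation_factor(0.0, -1000.0)

    def test_sanity_band_warning(self):
        with pytest.warns(UserWarning, match="sanity"):
            fractionation_factor(900.0, -50.0)


class TestRayleigh:
    def test_no_reservoir_change(self):
        assert rayleigh(2.0, 1.0, 1.07, "CARBON") == pytest.approx(2.0)

    def test_no_fractionation(self):
        assert rayleigh(2.0, 0.3, 1.0, "HYDROGEN") == pytest.approx(2.0)

    def test_carbon_hand_value(self):
        assert rayleigh(1.0, 0.5, 1.07, RayleighOrientation.CARBON) == pytest.approx(
            0.5 ** (-0.07), rel=1e-12
        )

    @pytest.mark.parametrize("f", [0.9, 0.5, 0.1, 0.01])
    @pytest.mark.parametrize("alpha", [1.04, 1.07, 1.2, 1.4])
    def test_orientations_are_reciprocal(self, f, alpha):
        r_i = 3.7
        rc = rayleigh(r_i, f, alpha, "CARBON")
        rh = rayleigh(r_i, f, alpha, "HYDROGEN")
        assert rc * rh == pytest.approx(r_i**2, rel=1e-12)

    def test_f_zero_is_not_evaluable(self):
        with pytest.raises(ValueError):
            rayleigh(1.0, 0.0, 1.07, "CARBON")


class TestClassifier:
    def test_reservoir_signature_is_co2_reduction(self):
        call = classify_pathway(
            FractionationResult(1.07, 1.20), d2H_CH4=-204.0, SO4_meqL=0.01
        )
        assert call.call is Pathway.CO2_REDUCTION
        assert call.evidence

    def test_brackish_depleted_sample_is_acetoclastic(self):
        # alpha_C 1.04, alpha_H 1.42, δ2H −315‰ at 3 meq/L sulfate
        call = classify_pathway(
            FractionationResult(1.04, 1.42), d2H_CH4=-315.0, SO4_meqL=3.0
        )
        assert call.call is Pathway.ACETOCLASTIC_OR_OXIDATION
        assert len(call.evidence) >= 3  # all three depletion rules fire + context

    def test_no_rule_fires_is_indeterminate(self):
        call = classify_pathway(FractionationResult(1.00, 1.00))
        assert call.call is Pathway.INDETERMINATE
        assert call.evidence == ()

    def test_conflicting_rules_are_mixed(self):
        call = classify_pathway(FractionationResult(1.07, 1.20), d2H_CH4=-320.0)
        assert call.call is Pathway.MIXED

    def test_single_alpha_cannot_confirm_co2_reduction(self):
        call = classify_pathway(FractionationResult(alpha_DIC_CH4=1.07))
        assert call.call is Pathway.INDETERMINATE

    def test_so4_is_context_never_decisive(self):
        call = classify_pathway(FractionationResult(1.07, 1.20), SO4_meqL=50.0)
        assert call.call is Pathway.CO2_REDUCTION
        assert any("context" in e for e in call.evidence)

    def test_deterministic_and_threshold_configurable(self):
        th = PathwayThresholds(alpha_c_aceto_max=1.08)
        calls = {
            classify_pathway(FractionationResult(1.06, 1.5), thresholds=th).call
            for _ in range(5)
        }
        assert calls == {Pathway.ACETOCLASTIC_OR_OXIDATION}


class TestMixingLine:
    def test_perfect_line_recovery(self):
        conc = np.array([50.0, 100.0, 200.0, 400.0, 1000.0])
        delta = 100.0 / conc - 55.9
        fit = mixing_line_intercept(list(zip(conc, delta)))
        assert fit.intercept == pytest.approx(-55.9, abs=1e-9)
        assert fit.slope == pytest.approx(100.0, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mixing_line_intercept([(10.0, -50.0), (10.0, -51.0), (10.0, -52.0)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            mixing_line_intercept([(10.0, -50.0), (20.0, -51.0)])

    def test_two_end_member_mass_balance_oracle(self):
        """Mixtures of a constant background with increasing additions of a
        source gas lie exactly on a 1/CH4 line whose intercept is the source
        end-member delta (brute-force mass balance)."""
        c_bg, d_bg = 12.0, -47.0
        d_src = -68.5
        points = []
        for c_src in (30.0, 80.0, 150.0, 400.0, 900.0):
            c_tot = c_bg + c_src
            d_tot = (c_bg * d_bg + c_src * d_src) / c_tot
            points.append((c_tot, d_tot))
        fit = mixing_line_intercept(points)
        assert fit.intercept == pytest.approx(d_src, abs=1e-6)
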