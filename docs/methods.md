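# Methods

This note documents the models implemented in `gwmethane`, the defaults and
why they were chosen, what the synthetic catchment generator does and does
not emulate, and known limitations.

## Thermodynamic model

Standard-state constants are **aqueous** (molal standard state): per-species
formation free energies and enthalpies in
`src/gwmethane/data/thermo_constants.yaml`, taken from standard aqueous
thermodynamic compilations (H2(aq) ΔGf° = +17.57, CH4(aq) −34.33,
HCO3⁻ −586.8, SO4²⁻ −744.5, HS⁻ +12.05, H2O(l) −237.18 kJ/mol, and matching
enthalpies). Per-reaction ΔH° and ΔS° are assembled from these at load time
with an element/charge balance check, and the temperature correction is
ΔG°_T = ΔH° − T·ΔS° (constant ΔH/ΔS over the groundwater range 0–60 °C; the
error of that approximation is well below the Davies-model error). The
aqueous standard state was adopted because it reproduces the reference
ΔG°(25 °C) values of ≈ −229 (CO2 reduction), −262 (SO4 reduction) and −33
kJ/mol (AOM) to within 1 kJ/mol; a gas-phase convention for H2/CH4 does not.

In-situ energies use ΔG = ΔG°_T + R·T·ln Q with R = 8.314 J/(mol·K).
Q is accumulated in log space: the activity sets encountered here produce
quotients spanning ~40 orders of magnitude. ΔG is divided by 8 electrons for
cross-reaction comparison; 8 is verified from stoichiometry (4 H2 ⇒ 8 e⁻;
S(+6) → S(−2) in AOM).

## Activity model

The paper-grade alternative is a full speciation code; `gwmethane` instead
uses an in-house ionic-strength/Davies model, a deliberate design choice:
the ΔG/e⁻ patterns of interest are driven by activities varying over orders
of magnitude, so the few-percent accuracy difference between Davies and a
full ion-pairing model is immaterial, and the package stays dependency-free.

* I = ½ Σ cᵢ zᵢ² from all measured, imputed ions (mol/L).
* log10 γ = −A·z²·(√I/(1+√I) − 0.3·I). A(T) is piecewise-linear through
  (0 °C, 0.4918), (25 °C, 0.5085), (50 °C, 0.5319): a single least-squares
  line through the three anchors would give A(25) = 0.5107, so interpolation
  is used to honour the conventional 0.5085 at 25 °C exactly. Above
  I = 0.7 mol/L a validity warning is logged and the value still returned.
* a(H⁺) = 10^(−pH); neutral dissolved gases (CH4, H2) take γ = 1
  (Setchenow salting-out neglected below I ≈ 0.25); a(H2O) = 1 exactly.
* Gypsum SI = log10(a(Ca²⁺)·a(SO4²⁻)) + 4.58 (Ksp = 10^−4.58 at 25 °C;
  its temperature dependence is ignored).

**Dissolved H2** is rarely measured and none is assumed available by
default. Three modes: `MEASURED` (pass a molarity), `ASSUMED_CONSTANT`
(default, 10⁻⁹ mol/L — the nanomolar level typical of sulfate-reducing
zones), and `REDOX_COUPLE` (the a(H2) that puts sulfate reduction at a
configured ΔG threshold, solved in closed form from the fourth-power H2
stoichiometry and verified by substitution in tests). The mode is recorded
per run; none is claimed to reproduce any particular field study's choice.
With `ASSUMED_CONSTANT`, between-sample variation in the H2-bearing
balances and quotients comes from the other species only.

## Censored concentrations

Below-DL values are replaced before any log-ratio or quotient is formed;
uncensored values are never touched, missing fields stay absent (never 0),
and imputed cells carry an `imputed` provenance flag so the operation is
idempotent. Default: deterministic multiplicative replacement at 0.65·DL —
the standard compositional convention, chosen as default because it keeps
the whole pipeline bit-reproducible without a seed. Option: a seeded
Monte-Carlo data-augmentation imputer that, per species and aquifer group
(the groups occupy distinct compositional ranges), fits a lognormal to
observed values, draws censored cells from the DL-truncated fit, and
re-fits over the augmented data for `n_chains` sweeps (default 10; the fit
stabilises in 2–3). A species with no uncensored observations anywhere
falls back to multiplicative replacement with a logged warning. Tests check
the DA imputer beats DL substitution in mean absolute log-error when the
sub-DL truth is log-uniform on (0.1·DL, DL). Interval censoring (between
two DLs) is out of scope.

## ilr balances

Each reaction's species vector is mapped to D−1 = 3 balances by its shipped
sequential binary partition (YAML files under `data/sbp/`): row 1 splits
products from reactants, the remaining rows partition the reactants. The
balance is √(r·s/(r+s))·ln(g(x₊)/g(x₋)). Balances are computed on
**unclosed activity vectors** — sound because log-ratio balances are
scale-invariant, and it mirrors the use of activities rather than mass
fractions. Validation enforces the SBP hierarchy (each row must split a
group kept together by all previous rows). The implied contrast matrix is
orthonormal, so Euclidean distance in balance coordinates equals Aitchison
distance; tests verify this against a brute-force clr oracle at 1e-10.

## Isotope rules

α = (1000 + δX)/(1000 + δCH4). Classifier defaults (all configurable, in
config rather than code):

| rule | default | direction |
|---|---|---|
| α_DIC-CH4 window | 1.07 ± 0.02 | CO2 reduction (with H window) |
| α_H2O-CH4 window | 1.20 ± 0.05 | CO2 reduction (with C window) |
| α_DIC-CH4 band | [1.02, 1.05] | acetoclastic/oxidation |
| α_H2O-CH4 floor | ≥ 1.35 | acetoclastic/oxidation |
| δ2H-CH4 ceiling | ≤ −310‰ | acetoclastic/oxidation |

The CO2-reduction call requires **both** α windows; a single α is treated
as insufficient evidence. The acetoclastic carbon rule is a band, not a
one-sided cutoff: α_C near 1.00 carries no methanogenic fractionation
signal at all and must fall through to INDETERMINATE rather than fire a
depletion rule. Both directions firing yields MIXED. Sulfate (meq/L) is
recorded as context evidence but is never decisive. All rules are evaluated
before combination, so classification is deterministic and
order-independent. Half-widths were chosen so the canonical pathway
assignments for reservoir-type (1.07/1.2) and brackish acetoclastic-type
(1.04/1.4, δ2H ≈ −315‰) samples are reproduced.

Rayleigh curves are generation-only (no fitting): carbon R = R_i·f^(1−α),
hydrogen R = R_i·f^(α−1), so R_C·R_H = R_i² at equal α and f — the
reciprocal carbon/hydrogen response expected as a reservoir depletes. f = 0
is rejected as a plotting limit. The mixing-line device is an OLS of
δ13C-CH4 on 1/CH4 (scipy); its intercept is the inferred source end-member.

## Synthetic catchments

The generator encodes, per aquifer, the published bounds of a coal-seam-gas
system: gas reservoir (Cl 1000–4500 mg/L, SO4 censored in ~95% of wells,
CH4 2000–25000 µg/L always detected, δ13C-CH4 −58..−49‰, δ2H-CH4
−210..−198‰, δ13C-DIC +9..+23‰), shallow coal measures (CH4 95–18000 µg/L
detected in 7/14, δ13C-DIC −15.9..−3.5‰, …), alluvium (CH4 10–535 µg/L in
5/23, Cl 35–8700 mg/L, SO4 up to 988 mg/L), and a small third sedimentary
unit. Within-range draws are uniform, switching to log-uniform when a range
spans more than a decade. Values the source tables do not bound (Na, K, Ca,
Mg, HCO3, DO, DOC ranges; Br/Cl mass ratio 0.002–0.004; trace-tritium and
HS⁻ detection odds) were fixed once at field-realistic levels for
Na-HCO3-Cl type waters and are documented in `synthetic.py`.

Structure imposed on top of the ranges:

* CH4 detectability is logistic in log-sulfate (midpoint 1 meq/L,
  configurable), and detected concentrations follow an inverse log-log link
  to sulfate with lognormal jitter, clipped to the profile range — together
  these produce the negative SO4–CH4 rank correlation the analysis assumes.
* A latent pathway is drawn per CH4-bearing well from the profile mixture
  weights (reservoir 100% CO2 reduction; coal measures 13/14; alluvium
  0.8/0.2). CH4 deltas are constructed by inverting the fractionation
  definition with α_true = (1.07, 1.2) or (1.04, 1.4) plus Gaussian noise
  (defaults 0.5‰ C, 1.5‰ H, at the scale of analytical error plus natural
  variability).
* Latent labels go to a separate labels file.

What it does **not** emulate: spatial structure and transport (no
diffusion/advection, no δ37Cl systematics beyond range draws), tritium age
structure, per-site pairing quirks of real data, correlated analytical
error, interval censoring. Passing tests on this generator demonstrates the
machinery is correct and internally consistent under the assumed structure;
it does not validate the geochemical interpretation of any particular field
system. The per-sample pairing of isotope values is an assumption of the
generator (only ranges are published), stated as such.

## Numerical choices and degenerate inputs

* Energies in kJ; °C→K via 273.15 everywhere.
* Q and balances in natural-log space; quotients reported as ln Q.
* Imputed values are clamped strictly inside (0, DL) by one ulp.
* Zero-concentration ions are dropped from the activity set (activities
  must be strictly positive); missing CH4 yields an activity set without
  CH4 so CH4-dependent reactions and balances are skipped and logged,
  never zero-filled.
* read/write CSV round-trips are bit-exact (floats serialised with `repr`).
* Per-sample failures in the pipeline are logged and skipped; they never
  abort a run. End-to-end runs are byte-deterministic under a fixed seed
  and config.
* Problem sizes used in the test suite — 1000 random compositions for the
  isometry check, 200 synthetic samples for the balance/quotient
  correlation, ~900 (≥500 labelled) for classification recovery — were
  chosen as the smallest sizes at which the statistical properties are
  stable across seeds.

## Known limitations

* No carbonate-system re-speciation: HCO3 is taken as reported
  (bicarbonate alkalinity), so at pH ≫ 9 the HCO3⁻ activity would be
  overstated. No Pitzer model: hypersaline samples (I > 0.7) carry a
  warning.
* No kaolinite SI (requires Al, not typically measured), no quantitative
  δ37Cl diffusion model, no three-end-member mixing solver, no
  acetoclastic ΔG pathway (acetate is not measured).
* The acetoclastic-vs-oxidation ambiguity is inherent to the rule set
  (both depress α_C and can depress δ2H-CH4); the classifier therefore
  reports a single combined class for that direction.
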