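# Methods

## Model and assumptions

The package treats a bacterial promoter as an equilibrium system of
discrete occupancy states. For one TF site and one RNAP site the states
and Boltzmann weights are: unbound (1), TF-bound (*F*), RNAP-bound (*P*),
and — when the geometry permits co-occupancy — doubly bound (*αFP*).
Binding factors are dimensionless: F = [TF]·K_F = e^(−ΔG_F/k_BT) and
likewise for P. The observed transcription rate is the initiation-rate
average over states plus a background term:

- occlusion: only the RNAP-bound state initiates (rate t_sat); the TF
  site overlaps the RNAP site, so the doubly bound state is absent;
- stabilization: the doubly bound state also initiates at t_sat, and its
  weight carries the cooperativity α;
- acceleration: as stabilization, but the ternary complex initiates at
  β·t_sat.

Assumptions inherited from this model class: occupancies equilibrate fast
relative to initiation (thermodynamic, not kinetic, description); changing
the RNAP site sequence changes only *P*; t_bg and t_sat are shared by all
promoters of one architecture; rates are in the arbitrary units of the
reporter assay and are never converted to absolute transcript counts.

Energies are reported in kcal/mol with k_BT fixed by the rounded
convention 1 kcal/mol = 1.62 k_BT at 37 °C (k_BT = 0.6173 kcal/mol), so
that published two-decimal ΔG values are reproduced bit-for-bit;
`ThermoConstants` separately recomputes k_BT from the gas constant
(0.61631 kcal/mol at 310.15 K, i.e. 1.6225 k_BT per kcal/mol) for unit
sanity checks. Natural logarithms throughout.

## Fitting

For n promoters with paired measurements, the model has n + k parameters
(per-promoter P plus k architecture scalars), fitted to the 2n
measurements by least squares on log₁₀ rates. Choices, and why:

- **Log residuals.** Measurements span 4+ decades and replicate noise is
  multiplicative; squared log residuals make every decade count equally
  and correspond to a lognormal noise model.
- **Log parameterization.** All positive parameters are optimized as
  logarithms — positivity by construction, no active bounds, and scale-free
  steps. Levenberg–Marquardt (scipy `least_squares`, `method="lm"`) with
  tolerances 1e−14; the robust pass for outlier detection uses the
  trust-region solver with a soft-L1 loss (`f_scale` 0.1 in log₁₀ units).
- **Initialization.** P is started by inverting the unregulated rate law
  at the starting (t_sat, t_bg), clipped into the identifiable window;
  t_sat starts at 1.5× the largest t⁻, t_bg at half the smallest rate, and
  the coupling at the median t⁺/t⁻ ratio (inverted through α′ when F is
  known). Multistart: 10 starts by default — the data-driven start plus
  9 log-uniform draws with fixed sub-seeds; best loss wins, ties keep the
  first. One top-level seed fans out deterministically to multistart and
  bootstrap streams.
- **Identifiability.** Fits require n ≥ max(4, k+1) non-outlier promoters
  (2n > n + k). The acceleration model with *both* t_sat and β free is
  refused outright: eliminating P via y = t⁻ − t_bg gives
  t⁺ = β′t_sat·α′y/(t_sat + (α′−1)y), which constrains only β′α′ and
  (α′−1)/t_sat, so an exact degeneracy family exists. This is why β is
  inferred at a t_sat pinned from a saturating architecture (`fit_beta`),
  and why β is flagged as weakly identified when no fitted P reaches ~0.1.
- **Known TF factor.** For the activation mechanisms, F measured
  separately (by an occlusion fit) may be supplied as a fixed constant;
  α is then recovered from the fitted α′ exactly. Without it the fit
  returns the renormalized coupling (the F → ∞ limit), which is what the
  manifold geometry actually measures.
- **Joint fits.** `joint_fit` shares one t_sat across architectures
  (t_sat is a property of RNAP, not of TF placement) while each
  architecture keeps its own coupling, t_bg, and P values. Architectures
  that never reach saturation borrow t_sat from those that do. A shared
  t_sat is a constraint, so total joint loss can only exceed the sum of
  independent-fit losses; the two coincide on noiseless shared-t_sat data.
- **Bootstrap.** The resampling unit is the promoter — its (t⁻, t⁺) pair —
  resampled with replacement, each replicate warm-started at the full-data
  estimate. Intervals are percentile (16/84 for "68%", 2.5/97.5 for
  "95%"); replicate fit failures are dropped, counted, and an error is
  raised past 20%.
- **Outliers.** After the robust preliminary fit, a promoter whose larger
  absolute log₁₀ residual exceeds 0.5 (≈3.2-fold; configurable) is
  flagged — never silently dropped — and the plain fit reruns on the
  survivors. If more than 25% of promoters would be flagged, the data are
  declared not to collapse to a 1D manifold (`CollapseError`) rather than
  fitted anyway.
- **Titration.** Across inducer concentrations, t_sat and t_bg are pinned
  (they do not involve the inducer) and F is fitted per concentration; the
  power-law exponent is the OLS slope of ln F on ln c over the four
  largest concentrations by default (weak-induction conditions produce
  large asymmetric F uncertainties), with the regression's 95% CI. Fewer
  than three selected concentrations leaves the CI undefined and is an
  error.

## Regime analysis

Under scale separation (F ≫ 1 and t_bg ≪ t_sat for occlusion;
t_sat/t_bg ≫ α′ ≫ 1 for activation) the manifold splits into five
regimes. Boundaries are placed where adjacent approximate expressions
intersect (dominant-term crossovers): for occlusion at
P = t_bg/t_sat, (1+F)·t_bg/t_sat, 1, 1+F; for activation at
P = t_bg/(β′α′t_sat), t_bg/t_sat, 1/α′, 1. The ranges tile (0, ∞)
exactly; a strictness multiplier > 1 carves out symmetric crossover zones
for conservative classification. Deep inside a regime spanning ≥2 decades
the approximations hold to better than 15% and sharpen as the scale
separation grows. Parameter sets without the required separation raise an
explicit "regimes undefined" signal instead of returning a label.

## Synthetic data

The generator emulates the assay design the fits assume: P drawn
log-uniformly (or log-spaced) over a stated range, model rates from the
chosen mechanism, and observed rates multiplied by exp(ε) with
ε ~ N(0, ln(1+CV)) independently per promoter and per channel. Defaults
are the characteristic values of the CRP/σ70 system this package targets:
t_sat = 15.1 a.u., t_bg = 2.3×10⁻³ a.u., F = 23.9, α = 712, β = 1,
CV = 10%, P over [10⁻⁴, 3] (populating regimes 1–4; β inference tests
widen the range to reach saturation). Outlier promoters (optional
fraction) have only t⁺ corrupted — biologically, a stray mutation creating
a new TF site perturbs regulation, not basal transcription — by a
log-uniform factor between 2-fold and one decade, either direction.
Titration data share one promoter library across concentrations with
F(c) = F_ref·(c/c_ref)^exponent and condition-independent t⁻ model values.

What the generator does *not* emulate, and hence what passing tests do not
establish about real data: promoter-to-promoter variation in t_bg (real
background scatter in the weak-promoter regimes exceeds replicate noise),
replicate-level error structure (noise is attached per observation, not
per biological replicate), sequence-level effects (no mapping from
promoter sequence to P), and any systematic deviation from the assumed
manifold shape other than injected outliers.

## Numerical and statistical caveats

- Exact-recovery tests run at optimizer tolerance 1e−14 and verify
  parameters to 1e−6 relative on noiseless data for every identifiable
  fixed/free split of all three mechanisms.
- The percentile bootstrap undercovers at small n: at n = 20 promoters
  measured coverage of the nominal 68% interval was ~0.5–0.55 even though
  the bootstrap draw spread matches the true sampling spread; at n = 40
  (the design size used for the calibration and precision checks,
  200 datasets / 50 runs, n_boot = 100) coverage sits within 68±7%.
  Interpret CIs from very small promoter panels cautiously.
- Stochastic acceptance properties are asserted as majorities over
  independent seeds (e.g. ≥8/10 titration 95% CIs covering the true
  exponent) rather than on a single seed.
- Fits are invariant to promoter row order and to concentration unit
  rescaling (titration slope); seeded runs are bit-reproducible, and JSON
  summaries are byte-identical for identical inputs (floats at 12
  significant digits, sorted keys, no timestamps).

## Limitations

Equilibrium occupancy only — no kinetic proofreading of initiation steps,
no promoter-escape dynamics. One TF site and one RNAP site per promoter;
architectures whose variants modulate more than one biophysical quantity
(as failed-collapse class II data suggest) are detected as collapse
failures, not modeled. t_bg is one value per architecture. Measurement
error is attributed to the rates as observed (no errors-in-variables
treatment of the shared P between channels). No Bayesian posterior —
uncertainty is purely bootstrap-frequentist.
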