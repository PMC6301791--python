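# allelic-manifolds

Thermodynamic modeling of **allelic manifolds**: precise in vivo Gibbs free
energies of TF–DNA, TF–RNAP and RNAP–DNA interactions from paired reporter
measurements.

## The problem and who this is for

A standard way to probe cis-regulatory energetics in bacteria is to measure
transcription from a promoter in the presence (t⁺) and absence (t⁻) of an
active transcription factor (TF), across an *allelic series* of RNAP binding
sites that differ only in binding strength. Under an equilibrium
thermodynamic model, each variant promoter differs in a single quantity —
the dimensionless RNAP binding factor *P* = [RNAP]·K_P = e^(−ΔG_P/k_BT) —
so the points (t⁻, t⁺) collapse onto a one-dimensional curve (the allelic
manifold) whose shape is set by a handful of interaction energies. Fitting
that curve yields those energies with ~0.1 kcal/mol precision, without
modeling how sequence maps to affinity.

This package is for quantitative biologists analyzing such paired reporter
data (e.g. CRP/σ70 promoter variants in *E. coli*, or analogous MPRA
designs). It provides the rate laws, the manifold fits with bootstrap
uncertainty, regime classification, a CSV/CLI pipeline, and a synthetic-data
generator so every stage is testable without any external dataset.

## The models

With Boltzmann weights 1 (unbound), *F* (TF-bound), *P* (RNAP-bound), and
*αFP* (doubly bound), background rate t_bg, and saturated initiation rate
t_sat:

- **Occlusion (simple repression)** — the TF sterically excludes RNAP:

  t⁻ = t_sat · P/(1+P) + t_bg,  t⁺ = t_sat · P/(1+F+P) + t_bg

  In the parallel regime t⁺ ≈ t⁻/(1+F): the manifold's offset below the
  diagonal measures the TF–DNA binding factor *F*, hence
  ΔG_F = −k_BT ln F.

- **Stabilization (recruitment)** — the doubly bound state is favored
  α-fold:

  t⁺ = t_sat · α′P/(1+α′P) + t_bg,  α′ = (1+αF)/(1+F)

  The offset *above* the diagonal measures the renormalized cooperativity
  α′, and ΔG_α = −k_BT ln α is the TF–RNAP interaction energy.

- **Acceleration** — the ternary complex additionally initiates β-fold
  faster:

  t⁺ = β′ t_sat · α′P/(1+α′P) + t_bg,  β′ = (1+αβF)/(1+αF)

  t⁺ saturates at β′·t_sat while t⁻ saturates at t_sat, so strong-promoter
  (P ≳ 1) data discriminate acceleration from pure stabilization (β = 1).

Fitting n promoters means n+3 (or n+4) parameters against 2n measurements:
t_sat, t_bg, the regulatory coupling, and one *P* per promoter. Least
squares is done on log₁₀ rates (noise is multiplicative and the data span
decades), all positive parameters are optimized as logarithms, and 68%
confidence intervals come from refitting bootstrap-resampled promoters.
Energies are reported in kcal/mol with the convention
1 kcal/mol = 1.62 k_BT at 37 °C.

## Worked example

```python
import allelic_manifolds as am

# a 39-promoter occlusion series at 10% replicate noise
truth = am.SyntheticTruth(mechanism="repression", noise_cv=0.1,
                          p_range=(1e-3, 3.0), seed=7)
table, truth = am.simulate_allelic_series(truth, 39)

ens = am.bootstrap(table, "repression", n_boot=100, seed=7)
fit = ens.point
lo, hi = ens.ci("F", 0.68)
dlo, dhi = ens.ci("dg_F", 0.68)
print(f"n = {fit.n_used} promoters, loss = {fit.loss:.3f}")
print(f"F     = {fit.params['F']:.1f}  (68% CI {lo:.1f} .. {hi:.1f})")
print(f"dG_F  = {fit.dg_F:.2f} kcal/mol  (68% CI {dlo:.2f} .. {dhi:.2f})")
print(f"tsat  = {fit.params['tsat']:.1f} a.u.   tbg = {fit.params['tbg']:.2g} a.u.")
```

prints

```
n = 39 promoters, loss = 0.055
F     = 25.1  (68% CI 24.3 .. 26.0)
dG_F  = -1.99 kcal/mol  (68% CI -2.01 .. -1.97)
tsat  = 13.4 a.u.   tbg = 0.0026 a.u.
```

The generating truth was F = 23.9 (ΔG_F = −1.96 kcal/mol), t_sat = 15.1,
t_bg = 0.0023: the TF–DNA energy is recovered to a few hundredths of a
kcal/mol, while t_sat is softer because this P range barely reaches
saturation — exactly the anatomy real occlusion datasets show.

The same workflow runs from the shell:

```bash
allelic-manifolds simulate --mechanism repression --n 39 --seed 7 -o sim.csv
allelic-manifolds bootstrap sim.csv --mechanism repression --n-boot 100 --seed 7 -o out
allelic-manifolds titrate titration.csv --tsat 15.1 --tbg 0.0023 -o titr
```

Subcommands: `simulate`, `fit`, `jointfit` (shared t_sat across promoter
architectures), `fitbeta` (acceleration test at fixed t_sat), `bootstrap`,
`titrate` (power-law exponent of F versus inducer concentration), and
`regimes`.

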