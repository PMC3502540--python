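# fcshpa

Quantifying a peptide hormone at nanomolar levels with a fluorescence
correlation spectroscopy (FCS) sandwich immunoassay, and modeling what
those measurements reveal: the fast (non-genomic) and slow (genomic)
negative feedback of cortisol on ACTH secretion by anterior-pituitary
corticotrophs.

The package is for two audiences. Single-molecule spectroscopists get a
complete FCS immunoassay analysis chain — closed-form correlation
models, confocal-volume calibration, two-stage curve fitting, synthetic
data generators including a Brownian-dynamics oracle. Systems biologists
get two ODE models of the corticotroph feedback loop and a regularized
global/local fitting framework that reproduces, from packaged in-vitro
time courses, why a genomic-feedback-only model cannot explain both
feedback time scales while a model with a glucocorticoid membrane
receptor can.

## The models

**FCS.** Fluorophores diffusing through a 3D-Gaussian confocal volume
produce intensity fluctuations whose autocorrelation is

```
G(τ) = 1 + (1/N) (1 + τ/τ_D)⁻¹ (1 + τ/(s²τ_D))⁻¹ᐟ²,   τ_D = r²/(4D),
```

with `N` the mean particle number (amplitude law `G(0) − 1 = 1/N`) and
`s = z/r` the fixed structural parameter. A mixture of free labeled
antibody (τ_D1 ≈ 220 μs) and the slower antibody–ACTH–antibody
immunocomplex (τ_D2 ≈ 483 μs) follows the two-component form

```
G(τ) = 1 + (1/N′) [(1−Y) g_D1(τ) + Y g_D2(τ)],
```

and since each immunocomplex carries exactly one ACTH molecule,
`c_ACTH = Y·N′ / (N_A·V_eff)` with the calibrated effective volume
`V_eff = 5×10⁻¹⁶ l` (conversion factor 30.115×10⁷ particles per mol/l).

**Feedback ODEs.** In a closed in-vitro well with clamped CRH and
cortisol doses, supernatant ACTH accumulates from a releasable pool
whose secretion rate is stimulated by the occupied CRH receptor and — in
the extended model — divided by occupancy of a glucocorticoid membrane
receptor (fast feedback), while the nuclear glucocorticoid-receptor
dimer represses transcript production (slow feedback). Fitting uses a
Tikhonov objective, `Σ((model−data)/dev)² + α·Σ(ln p − ln p_ref)²`,
minimized by seeded differential evolution in log-parameter space plus
bounded local refinement. See `docs/methods.md` for the full equations,
parameters and assumptions.

## Worked example

End-to-end assay quantification of a synthetic 50×10-s measurement
series at a true concentration of 15 nM ACTH (60 nM labeled antibody):

```
$ fcshpa assay --c-acth-nm 15 --seed 7
{
  "seed": 7,
  "config_hash": "44136fa355b3",
  "n_runs": 50,
  "c_acth_nm": 14.917097866287902,
  "c_acth_halfwidth_nm": 0.3824571768557973,
  "tau_d2_us": 491.3993644374054,
  "tau_d2_halfwidth_us": 8.218455739008581,
  "alpha": 0.1
}
```

Each of the 50 curves was fitted with the two-component model (τ_D1
fixed at 220 μs); the series mean recovers the true 15 nM within
0.1 nM, with a Student-t (α = 0.1) half-width of ±0.38 nM — the
sub-nanomolar precision that makes minute-scale feedback experiments
possible — and the immunocomplex diffusion time 491 ± 8 μs against the
generating 483 μs. For the library equivalents see
`fcshpa.generate_assay_series`, `fcshpa.fit_two_component`,
`fcshpa.extract_assay_result` and `fcshpa.aggregate_series`.

On the modeling side,

```
$ fcshpa simulate-hpa --model extended --scenario crh_cortisol --t-max 120 --out traj.csv
$ fcshpa compare-models --population 64 --generations 40 --seed 1 --out report.json
```

simulate one arm and run the parsimonious-vs-extended comparison; the
report's verdicts show the parsimonious model fitting either arm alone
but failing the joint fit, and the extended model passing it.

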