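# Methods

`fcshpa` implements two connected analyses: quantification of
adrenocorticotropic hormone (ACTH) from fluorescence correlation
spectroscopy (FCS) sandwich-immunoassay curves, and ordinary-differential
equation (ODE) models of the fast (non-genomic) and slow (genomic)
negative feedback that cortisol exerts on ACTH secretion by
anterior-pituitary corticotrophs. This note records the models, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## FCS models and calibration

Intensity fluctuations of fluorophores diffusing through a 3D-Gaussian
confocal volume autocorrelate as

    G(τ) = 1 + (1/N) · (1 + τ/τ_D)^-1 · (1 + τ/(s²τ_D))^-1/2

with particle number `N`, diffusion time `τ_D = r²/(4D)` through the
radial 1/e² waist `r`, and structural parameter `s = z/r`. A two-species
mixture of equal molecular brightness adds the two decay factors with
mole fractions `(1-Y, Y)` under a common amplitude `1/N'`. The amplitude
law `G(0) - 1 = 1/N` holds for both models exactly.

Calibration conventions:

* The volume geometry is calibrated from a dye standard of known `D`
  (rhodamine 6G in water, `D = 2.8e-6 cm²/s`): `r = sqrt(4 D τ_D)`,
  `z = s·r`. The default geometry is `r = 0.17 μm`, `z = 0.88 μm`,
  `s = 5` (the ratio 0.88/0.17 = 5.18 is carried rounded, as instrument
  software does; `ConfocalVolume` accepts up to 5% discrepancy).
* The effective volume `V_eff = 5e-16 l` is an independent calibration
  constant, *not* derived from `r` and `z`: no standard Gaussian-volume
  convention (`π^{3/2} r² z ≈ 1.4e-16 l`) reproduces it from the printed
  geometry, and the concentration arithmetic
  `c = N / (N_A · V_eff)` (denominator `30.115e7` per mol/l) depends on
  the constant, so the two are deliberately decoupled. The Avogadro
  constant is kept at its historical `6.023e23` value for the same
  reason.
* The structural parameter is always fixed during fitting.
* `G` carries the +1 baseline and no offset, background, or
  triplet/blinking term; none is modelled anywhere in the package.

## Two-stage assay fitting

Free labeled antibody is fitted with the one-component model; sample
curves (antibody + immunocomplex) with the two-component model holding
the free-antibody time `τ_D1` fixed at its one-component estimate
(default 220 μs). Because the mAb(N)–ACTH–mAb(C) sandwich carries exactly
one analyte molecule, `Y·N'` counts ACTH particles and `(1-Y)·N'` free
labeled antibody.

Numerical contract of the fits (`lmfit` bounded least squares):

* weights: per-lag standard errors when present (zero-stderr channels are
  floored at the tightest real channel), uniform otherwise;
* bounds: `N' ∈ (0, 1e4]`, `Y ∈ [0, 1]`, `τ_D2 ∈ [τ_D1, 100 τ_D1]`
  (the bound complex cannot diffuse faster than the free antibody);
* multistart on `τ_D2 ∈ {1.5, 2.5, 5}·τ_D1`, best weighted residual
  wins — deterministic for a given curve;
* initial guesses: `N'` from the first-lag amplitude, `Y = 0.3`;
* parameter standard errors from the Gauss–Newton curvature at the
  optimum;
* a curve whose amplitude is below 10× the median stderr raises a
  no-signal error; a fit that pins `τ_D2` at its lower bound is flagged
  `component_collapse` (indistinguishable components, e.g. `Y ≈ 0`).

Series statistics follow the instrument convention everywhere: mean with
a two-sided Student-t confidence half-width, `α = 0.1` by default.

## Synthetic data

`generate_correlation_curve` draws `G(τ_i) + ε_i` on an ALV-style
quasi-logarithmic grid (16 channels per octave, 1 μs – 1 s) with
independent Gaussian noise of standard deviation
`noise_scale · ((G(τ_i) - 1) + sqrt(τ_i / T))` for measurement time `T`:
short-lag channels average many more fluctuations per run and are
correspondingly cleaner. The default `noise_scale = 0.01` was calibrated
once against the assay's reported precision — a 50-run series at 15 nM
ACTH then shows a concentration half-width of ≈ 0.5 nM (the instrument's
reported sub-nanomolar series deviations) and a free-antibody diffusion
time scatter of a few μs. The generator does **not** emulate detector
afterpulsing, dead time, triplet kinetics, photobleaching, or correlated
per-lag noise; recovery tests passing on it show the estimator chain is
consistent and well-calibrated for heteroscedastic white noise, not that
it is robust to every instrument artefact.

The assay-series generator encodes the sandwich stoichiometry: 60 nM
labeled + 60 nM unlabeled antibody, complete capture in the
antibody-excess regime, hence `Y = c_ACTH / c_labeled` and
`N'` from the labeled dose via the `V_eff` conversion (18.07 particles at
60 nM). Analyte above the labeled dose is refused (saturation).

As an independent oracle, `simulate_photon_trace` runs Brownian dynamics
of point emitters in a periodic box (each length ≥ 10× the matching 1/e²
radius), Gaussian steps of SD `sqrt(2 D Δt)` per axis with
`Δt ≤ τ_D/50`, Poisson emission from a molecular brightness weighted by
the Gaussian detection profile. Its multiple-tau correlator (symmetric
normalization, bin-doubling per octave) agrees with the closed-form
one-component model within 5% on `G - 1` over two decades of lag for the
default 60-s trace — the oracle never touches the analytic formula. For
amplitude checks the simulator's own effective volume is the Gaussian
profile integral `π^{3/2} r² z`, independent of the assay's `V_eff`
constant (see the calibration note above).

## Feedback models

Both models describe a closed in-vitro well: extracellular CRH and
cortisol are clamped at their doses from t = 0 (no hypothalamic or
adrenal production, no medium exchange), and secreted ACTH accumulates in
the supernatant with a small first-order loss `k_loss ∈ [1e-5, 1e-3]/min`
(default 5e-4; a strictly positive default keeps every parameter in the
log-space search and acknowledges aspecific losses — adsorption,
proteolysis — over a 22-h incubation). The observable is percent change
of supernatant ACTH against the basal reference 15.016 nM, the only
printed absolute basal concentration. Units are minutes and nM.

**Parsimonious model** (genomic feedback only): dynamic species are the
glucocorticoid receptor `r`, an intracellular releasable ACTH pool `a`,
and supernatant ACTH. CRH stimulates pool production `(b0 + b1·CRH)` and
secretion `(s0 + s1·CRH)·a`; the cortisol–GR activity `(cort·r)`
represses production with a Hill-2 law and up-regulates its own receptor
(Hill-2 in `(cort·r)`), the classical dimerized-transcription-factor
feedback. Cortisol does not touch the secretion step.

**Extended model** adds the fast branch and explicit compartments
(membrane / cytosol / nucleus): mass-action binding of CRH to a membrane
CRH receptor (CRHR) and of cortisol to a membrane G-protein-coupled
receptor (GPCR); first-order membrane passage of cortisol; GR binding,
dimerization, nuclear import, and export/recycling; POMC transcript
production stimulated by bound CRHR and repressed by the nuclear GR
dimer (Hill-2, constant `k_rep`) — the slow genomic branch; a releasable
ACTH pool filled from transcript and secreted at rate
`(v0 + v1·CRHR_b) / (1 + GPCR_b/k_inh)` — CRH-stimulated exocytosis
inhibited by the occupied GPCR, the fast non-genomic branch. Free + bound
receptor totals are structurally conserved, as is total GR across its
cytosolic, complexed, dimeric and nuclear forms.

The equations are this package's own transcription of that pathway
topology (mass-action binding, Hill-2 nuclear repression, first-order
transport and degradation throughout); defaults are order-of-magnitude
physiological choices — receptor equilibration within a minute, membrane
passage and nuclear translocation over tens of minutes, transcript
turnover ≈ 20 min, secretion gains sized so the basal flux accumulates a
few percent of the basal supernatant per day. They double as the
Tikhonov reference `p_ref`. The dynamics they produce explain the data's
shape: a CRH dose empties the pre-docked pool within minutes (the fast
rise), transcript-driven resupply sustains a slower climb over hours,
GPCR occupancy divides the early release under cortisol by a large
factor, and nuclear-dimer repression caps the 22-h level.

Initialization: the cellular states are solved to a basal (zero-dose)
steady state with the supernatant clamped at the reference concentration
— with negligible loss the supernatant itself has no steady state (basal
secretion accumulates), so its level is a datum, not an unknown. The
free-GR equation is replaced by the GR conservation constraint in that
solve because the conserved total makes the free level neutrally stable.
Residual norm below 1e-10 is enforced (short relaxation integration,
then a root polish).

Integration uses LSODA (stiff-capable, finite-difference Jacobian),
`rtol = 1e-8` for reported trajectories and `1e-6` inside optimization
loops (halving the tolerance moves observables by < 1e-4 relative).
Right-hand sides clip infinitesimally negative states; trajectories are
checked to stay above -1e-12 and observables are clipped at 0.

## Fitting the time-course data

The objective is Tikhonov-regularized weighted least squares on percent
change,

    J(p) = Σ_d Σ_i ((pct_model(t_i; p) - pct_i)/dev_i)² +
           α Σ_j (ln p_j - ln p_ref,j)² ,

with the printed per-point deviations as weights, `α = 1e-3` by default,
and log-space regularization toward the default parameter set. The FCS
columns are fitted; the ELISA columns ship as fixtures only. Failed
integrations return a large finite penalty (1e9) so population searches
can rank them.

Global search: differential evolution over log10-parameters within
bounds (generally ×30 around the default; totals ×10; `k_loss` capped at
1e-3/min), seeded and hence reproducible, population 200 × 100
generations by default — a desk-scale budget; larger populations are a
config knob. The reference individual is planted in the initial
population, so the returned optimum is never worse than `p_ref`. The
best individual then seeds a bounded trust-region least-squares polish
on the same residual vector, which does most of the fine work at reduced
budgets. Tests run the comparison at population 64 × 40 generations,
where the qualitative outcome is already stable for most seeds.

Model comparison: each model is fitted to the CRH arm alone, the
CRH+cortisol arm alone, and all three arms jointly. A fit is judged
adequate when the model lands within the printed deviation at ≥ 80% of
the fitted time points — an explicit operationalization of a qualitative
"good/poor fit" judgment. The parsimonious model fits either arm alone
but fails jointly for a structural reason: its early secretion burst is
pool-limited and cortisol-blind, so matching the suppressed 1–15 min
response under cortisol forces it to shrink the very burst the CRH-only
arm requires. The extended model's GPCR term acts on the release rate
directly and resolves the conflict.

Identifiability: the data are two short percent-change series and do not
pin down all ~20 parameters; no claim of parameter identification is
made. Receptor affinities in particular enter the observable only
through products with gain parameters. Recovery tests therefore fix all
but five sensitive, mutually identifiable parameters (secretion gain
`v1`, fast-feedback constant `k_inh`, repression constant `k_rep`,
transcript gain `a1`, transcript turnover `d_m`).

## Problem sizes used by tests and the acceptance script

Chosen as desk-scale defaults: 50-run assay series (the measurement
protocol); 100 × 12-run series for interval-coverage statistics; a 60-s
Brownian trace (32 particles, 3-μs steps) for the oracle comparison;
population 200 × 100 generations × 3 seeds for the joint data fit, and
population 64 × 40 generations × 3 seeds for the six-way model
comparison.

## Known limitations

* The direct curve generator's noise is an idealization; absolute noise
  magnitudes are calibrated to reported series deviations, not to a
  detector model.
* The Brownian oracle uses a truncated-Gaussian detection profile in a
  finite periodic box; residual systematic deviations of ~1–3% on `G-1`
  are visible at long lags.
* The ODE models omit receptor desensitization and trafficking, vesicle
  transport delays, CRH pulsatility, vasopressin, circadian input, and
  any adrenal or hypothalamic dynamics; the genomic branch beyond 22 h
  is outside scope.
* The two fitted arms cannot distinguish clamped from slowly decaying
  extracellular inputs; clamping is assumed.
* The model comparison verdict depends on the stated 80% threshold and
  on the reduced search budget; at that budget roughly one seed in three
  may fail to find an adequate joint fit for the extended model, which
  is why verdicts are reported over three seeds.
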