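# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Thermal-shift (DSF) analysis

A dye-based melt curve is modelled as a two-state unfolding equilibrium
between linear baselines:

    y(T) = y_F(T) + (y_U(T) - y_F(T)) / (1 + exp(ΔG_u(T) / (R T_K)))

with y_F(T) = aF + bF·T and y_U(T) = aU + bU·T in arbitrary fluorescence
units and T in °C (T_K = T + 273.15). The unfolding free energy is
parametrized van 't Hoff with zero heat-capacity change,
ΔG_u(T) = ΔH_u (1 − T_K/Tm_K): two parameters (Tm, ΔH_u) are identifiable
from a single ramp, whereas a ΔCp term is not. The gas constant is
R = 1.9872×10⁻³ kcal/(mol·K) throughout the package so melt free energies
and ITC thermodynamics share a scale.

All six parameters (Tm, ΔH_u, two baselines) are fitted jointly by
nonlinear least squares (`scipy.optimize.least_squares`, tight tolerances,
Tm bounded to the observed temperature window, ΔH_u ∈ (0, 5000] kcal/mol).
Baselines are *not* pre-fitted on fixed windows: joint fitting avoids
window arbitrariness. Initialisation: Tm from the maximum derivative of a
5-point moving-average smooth; ΔH_u = 100 kcal/mol; baselines from the
first/last 10 % of points. A fit is reported unconverged — never an
exception — when the optimizer fails, Tm leaves the window, or ΔH_u ≤ 0.

Degenerate inputs: curves with fewer than 10 points are rejected at
construction; a curve whose signal range is below 5× the median absolute
successive difference is flagged flat/unfittable (factor configurable).
The post-transition aggregation decay common in real DSF data is removed
by truncating after the *last* occurrence of the fluorescence maximum plus
a 2 °C margin (last occurrence so plateaus and flat curves are untouched).

ΔT_m: each sample replicate's shift is its Tm minus the mean reference Tm
of the same plate (references averaged per plate; per-column pairing is
not implemented). Replicates aggregate as mean ± sample SD (ddof = 1), SD
reported as missing for n = 1. The mean shift is computed as the
difference of means so a self-comparison is exactly zero.

An optimizer-independent check is provided by `grid_sse_minimum`: on a
(Tm, ΔH_u) grid (0.1 °C × 5 kcal/mol) the four baseline parameters enter
the model linearly and are profiled out by exact linear least squares, so
the grid minimum validates the nonlinear fit at grid resolution.

## Single-site ITC in reverse geometry

The titrations modelled are reverse: the compound sits in the cell
(13–25 µM) bearing N sites and the protein is injected (200–650 µM);
0.2003-ml cell, one 0.3-µl control injection + 38 × 1 µl, 15 °C. The
control injection is always discarded before fitting.

Finite-injection bookkeeping uses the standard instrument displacement
convention. After cumulative injected volume ΔV:

    [cell species] = L₀ (1 − ΔV/2V₀) / (1 + ΔV/2V₀)
    [titrant]      = P_syr (ΔV/V₀) / (1 + ΔV/2V₀)

(the exponential-dilution alternative is rejected; generator and fitter
share one convention so recovery tests are convention-invariant). Site
occupancy Θ is the smaller root of the 1:1 quadratic
N·cell·Θ² − (N·cell + titrant + 1/K_B)·Θ + titrant = 0, clipped to [0, 1]
with degenerate zeros returning 0. Cumulative heat
Q(i) = N Θᵢ [cell]ᵢ ΔH V₀; observed per-injection heat
ΔQ(i) = Q(i) − Q(i−1) + (dVᵢ/V₀)(Q(i)+Q(i−1))/2.

Dilution correction: the per-µl heats of the final `n_baseline` injections
(default 2; 1 reproduces the single-last-injection convention) estimate
the titrant dilution baseline, subtracted from every injection in
proportion to its volume. If the last raw heat still exceeds 25 % of the
largest heat a saturation warning is attached (warning, not error).

Fitting: least squares over (N, ln K_D, ΔH) plus a free volume-
proportional residual offset, with the identical correction operator
applied to model and data inside the residual. The free offset matters
statistically: the last-injection baseline estimate carries the noise of
those injections, and the oblique projection it induces roughly doubles
the K_D error if the offset is not refined. Three starts (c = 5, 50, 500)
guard against local minima; parameter SDs come from the Gauss–Newton
covariance at the solution (K_D's via the delta method from ln K_D).
Weak binding is flagged when fitted K_D > 50 µM, c = N[cell]/K_D < 1, or
the optimizer fails (all-zero heats included); the thresholds are
configurable. N is always free.

Derived quantities are exact by construction: ΔG = RT ln(K_D in molar),
TΔS = ΔH − ΔG, at the experiment temperature (288.15 K for the reference
panel; the buffer's 25 °C refers to pH calibration only).

Affinity classes bin K_D at (100 nM, 1 µM, 10 µM] with inclusive upper
edges; weak-binding fits are labelled "weak".

### Precision at the default noise level

A Cramér–Rao analysis of the forward model at the standard schedule shows
the relative K_D uncertainty of an efficient estimator is ~11–28 % across
c ∈ [5, 1000] at the package's default 0.1-µcal injection noise, so median
recovery errors near 10 % are the information-theoretic floor under these
conditions, not an optimizer artifact. (The reference panel's printed fit
SDs, e.g. ±2.8 nM on 41.8 nM, correspond to roughly 3× lower instrument
noise.) The 3-SD coverage of the reported uncertainties is ≥ 95 % in
simulation.

### Experimental design helper

`design_syringe_conc` reproduces panel practice: roughly a 12-fold syringe
excess over the cell concentration for tight binders, growing with K_D so
weak binders approach saturation before the final injection, capped at a
650 µM protein stock. It reproduces the panel's printed concentration
pairs (e.g. 260 vs 258 µM for the 41.8 nM / 20 µM condition; the 650 µM
cap against the 610/617 µM rows).

## FRAP

Normalization implements the double-normalization formula verbatim, with
prebleach averages taken over the `n_prebleach` (default 5) background-
subtracted frames before the bleach. The division by the whole-nucleus
channel cancels acquisition photobleaching applied jointly to both
channels above background (numerically exact to < 10⁻¹⁰); prebleach frames
of a noiseless trace map to exactly 1, and the subsequent affine rescale
(first post-bleach frame → 0, prebleach mean → 1) makes the prebleach
mean 1 for any trace up to double rounding.

The functional form of recovery is not dictated by the experiment; a
single exponential y(t) = A(1 − e^(−kt)) on the post-bleach frames is the
default (t_half = ln 2 / k, plateau A reported as the mobile fraction),
with a model-free alternative (`method="interpolation"`: plateau from the
final quarter of frames, half-time by linear interpolation of the first
A/2 crossing). Fits are performed in (A, ln k) with bounds; a
non-converged cell is flagged and excluded from group statistics.

Group comparison is a two-tailed t-test on half-times, unpaired by default
with a paired option (both are standard; the package exposes and logs the
choice rather than asserting one). Identical groups return (0, 1) by
convention since the t statistic is 0/0 there.

## Viability, synergy, qPCR

Survival = (raw − blank)/(vehicle mean − blank), clipped to [0, 1.5] with
clipping logged; fraction affected fa = 1 − survival (Chou–Talalay
convention). Single agents: a 4-parameter logistic on log dose (flat data
→ unconverged flag; EC50-within-range flag reported) and the median-effect
regression of log₁₀(fa/(1−fa)) on log₁₀ D, slope m and Dm from the
intercept −m·log₁₀ Dm. Points with fa outside [0.01, 0.99] diverge on the
logit scale and are excluded from the regression (logged); at least three
interior points are required.

Combination index at a checkerboard point with fraction affected fa:
Dxᵢ = Dmᵢ (fa/(1−fa))^(1/mᵢ), CI = d₁/Dx₁ + d₂/Dx₂ — the two-term
mutually exclusive form, matching the cited software's default for
non-constant-ratio designs; the mutually nonexclusive variant (adds
d₁d₂/(Dx₁Dx₂)) is available behind a flag. Points with fa at 0 or 1 are
skipped with a log. CI is scale-invariant and equals 1 identically for a
sham self-combination and for Loewe-additive constructions.

qPCR fold change is 2^−[(Ct_target,treated − Ct_ref,treated) −
(Ct_target,control − Ct_ref,control)] with 18S-type reference genes
handled via the `role` column of the Ct table.

## Synthetic data

All generators share additive Gaussian noise (heteroscedastic options are
out of scope) and a documented seed-splitting rule: dataset i uses
`numpy.random.SeedSequence(seed, spawn_key=(i,))`, so adding a dataset
never shifts existing noise, and identical (parameters, seed) regenerate
byte-identical files. Noise defaults — 1 % of a typical DSF signal window
(40 AU of 4000), 0.1 µcal per ITC injection, 0.03 normalized units per
FRAP frame — are package conventions exposed in the configuration, since
instrument noise magnitudes vary.

Defaults mirror the study conditions the analyses target: DSF ramp
25–96 °C (0.5 °C grid); ITC as above with panel concentration presets;
FRAP frames every 0.25 s, five prescans, n = 30 cells, with an optional
joint multiplicative acquisition drift to exercise the normalization;
8 × 8 dose checkerboards spanning 0.7–11,392 nM and 37–4,728 nM, with
`sham` (self-combination), `loewe` (additive by construction, solved by
bisection on the logit) and `bliss` (independent-action) interaction
rules.

What the generators do **not** emulate — and hence what passing recovery
tests do not establish about real data: baseline drift and temperature-
calibration error in DSF; heteroscedastic or correlated injection noise,
active-site titration error and competing equilibria in ITC; diffusion-
limited or binding–diffusion FRAP kinetics, ROI segmentation error and
incomplete bleaching profiles; edge effects and growth kinetics on
viability plates. The package validates the *analysis* chain, not the
instruments.

### Problem sizes

The test suite and the acceptance script use 50 synthetic titrations per
ITC ensemble, 20 melt curves for the grid cross-check, 10 for noiseless
recovery, 30 cells per FRAP group and single 8×8 checkerboards — sizes at
which every quantity is stable at the tolerances asserted while the whole
suite runs in well under a minute.

## Known limitations

- One transition per melt curve; no three-state models, no ΔCp.
- Single-site ITC only; no multi-site, sequential, competitive or global
  multi-experiment fitting; integrated heats are the input (no thermogram
  peak integration).
- FRAP is reaction-dominant single-exponential; no reaction–diffusion
  models or image processing.
- Synergy is Loewe/Chou–Talalay only (no Bliss/HSA/ZIP scores as outputs;
  Bliss exists only as a generator rule).
- The weak-binding rule (K_D > 50 µM or c < 1) is a documented convention;
  the panel's own criterion for "weak binding" rows is unstated.
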