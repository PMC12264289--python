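# Methods

`pulseco` studies whether cardiac output (CO) can be regressed from the
*shape* of a single peripheral arterial pressure cycle, how the answer
depends on the measurement site (left common carotid, left superficial
temporal, left radial), on amplitude calibration, and on measurement
noise. Because the reference virtual cohort it emulates is not
distributable, the package ships its own reduced-order cohort
generator, calibrated to the published group statistics of that cohort.

## The virtual cohort

### Hemodynamic model

Each subject is a 3-element Windkessel driven by a half-sine systolic
ejection:

    C dP_wk/dt = Q(t) − (P_wk − P_ven)/R,      P_ao = P_wk + Z_c Q(t)
    Q(t) = (π SV)/(2 T_ej) · sin(π t/T_ej)  for 0 ≤ t ≤ T_ej, else 0

integrated with RK4 at 512 steps per cycle, cycle-by-cycle until
periodic steady state (|P(0) − P(T)| < 0.01 mmHg, at most 50 cycles;
the affine cycle map makes convergence geometric at rate e^(−T/RC)).
The DC balance `mean(P_ao) − P_ven = (R + Z_c)·Q̄` holds to well under
1% and is asserted for every generated subject.

Peripheral sites are reached through a single-tube transmission line
(tube-load model) applied harmonic-by-harmonic to the pulsatile
component:

    H(ω) = (1+Γ) e^(−(jω/c + α)L) / (1 + Γ e^(−2(jω/c + α)L))

with path length L (carotid 20 cm, temporal 46 cm, radial 79 cm —
bifurcation counts 2/6/4 are carried as metadata only), wave speed
c = PWV ~ U(6, 10) m/s, terminal reflection coefficient Γ and
attenuation α per cm. The mean level drops by a site-specific
gradient. Γ and α defaults (carotid 0.55/0.001, temporal 0.40/0.004,
radial 0.50/0.002 cm⁻¹) were calibrated once so the default cohort
reproduces the reference pulse-pressure table: amplification ordering
radial > carotid > ascending aorta in both groups, radial PP ≈ 46/80
mmHg (normo/hyper) against aortic 33/63 mmHg.

### Parameter sampling

Two groups are planted by construction (the reference cohort's groups
were identified post hoc; a reduced-order generator cannot make them
emerge from anthropometry, a deliberate and documented difference):

| parameter | normodynamic (n = 2620) | hyperdynamic (n = 1198) |
|---|---|---|
| CO (L/min) | 5.5 ± 1.0 | 6.9 ± 1.0 |
| mean aortic pressure (mmHg) | 108.1 ± 20.2 | 85.8 ± 11.8 |
| heart rate (bpm), truncated | 81.9 ± 8.3 on [61.1, 101.6] | 83.9 ± 7.7 on [62.5, 101.6] |

(CO, MAP) are drawn from a correlated bivariate normal (within-group
correlation 0.95), rejection-truncated to a symmetric ±3.5 SD box so
the target means are preserved; HR is an independent truncated normal
on the printed min–max bounds. Derived quantities: SV = 1000·CO/HR,
total input resistance R_tot = (MAP − P_ven)/Q̄ with P_ven = 5 mmHg,
characteristic impedance Z_c = ζ·R_tot with ζ lognormal (median 0.03,
σ = 0.5, clipped to [0.01, 0.2]), peripheral R = R_tot − Z_c (so the
cycle mean hits the target MAP exactly).

Three couplings make the *normalized* waveform informative about CO.
They are modeling devices chosen at design time, each with a
physiological reading, and they are the crux of the generator:

1. **CO–MAP correlation (0.95).** Within a group, vasomotor tone varies
   much less than flow, so mean pressure tracks output.
2. **Pressure-dependent compliance.**
   `C = c_g · T/(0.06·(MAP − P_ven)) · e^ε`, ε ~ N(0, 0.05²). Arterial
   compliance falls with distending pressure; the chosen form makes the
   per-cycle diastolic decay exponent `T/(RC) = CO/(c_g e^ε)` — the
   waveform's most legible feature reads out CO directly. It also
   implies PP ∝ CO·(MAP − P_ven), which reproduces the reference
   pulse-pressure dispersions (σ_PP ≈ 11/16 mmHg vs published 12/18)
   with no extra tuning. The group constants c_g (14.6 normodynamic,
   5.8 hyperdynamic) were calibrated once against the group mean aortic
   PP targets 33/63 mmHg.
3. **Systolic time intervals.** Ejection time follows the classic
   left-ventricular ejection-time regression with its stroke-volume
   term, `T_ej = 0.413 − 0.0017·HR + 0.0010·(SV − 70)` s, so the
   systolic fraction of the cycle carries HR and SV. A fixed ejection
   *fraction* was rejected: amplitude normalization of a linear
   Windkessel cancels SV exactly, and with scale-free timing the
   normalized shape would provably contain no CO information — the
   emulated cohort would contradict the published finding it is meant
   to reproduce.

Implausible subjects (non-convergence, diastolic < 15 mmHg, PP outside
(5, 160) mmHg, systolic > 260 mmHg) are resampled; a resample rate
above 10% aborts as a generator mis-specification. In practice the
default configuration resamples none.

### What the generator does and does not emulate

It matches: group sizes and CO/MAP/HR moments, HR truncation ranges,
aortic and peripheral pressure summary levels and orderings,
pulse-pressure dispersion, group separability in the (CO, MAP) plane,
and the predictability of CO from calibrated and from shape-only
waveforms. It does not contain: anthropometric diversity, distributed
reflections from a full arterial tree (one lumped reflection site per
path), dicrotic-notch morphology from valve dynamics, or
hypodynamic/hypotensive states (absent from the reference cohort too).
Consequently, passing performance bounds here demonstrates that the
pipeline recovers the information the generator encodes, under the
published cohort's summary statistics — not clinical transferability.

## Preprocessing and noise

Every cycle is linearly interpolated onto 150 uniform points spanning
[0, T) (half-open grid, so the duplicated cycle endpoint is not double
counted); absolute timing is deliberately discarded. Uncalibrated
inputs are `(P − P_min)/(P_max − P_min)`. Noise adds n_i ~ N(μ, σ²)
to every point — (μ, σ) = (0.7, 1.0) mmHg calibrated, (0, 0.1)
normalized — plus spikes r_i ~ U(−A, A), A = 0.1·max(x), at a fresh
uniform random subset of round(0.2·150) = 30 indices per waveform.
Corrupted vectors are not re-normalized. Noise is injected after
resampling, and noisy conditions corrupt train, validation and test
sets alike.

## Group recovery

A two-component full-covariance Gaussian mixture is fitted to
(CO, MAP) by EM (k-means-style seeded initialization, 5 restarts, best
log-likelihood kept, covariance regularization at determinant
< 1e-12). The log-likelihood history is exposed and its monotonicity
asserted; scikit-learn's `GaussianMixture` is the independent
cross-check in the tests, never the implementation. The higher-CO
component is labelled hyperdynamic. Group differences are screened
with Shapiro–Wilk and compared with the two-sided Mann–Whitney U
(normal approximation, tie-corrected), α = 0.05.

## The regressor

A compact 1D CNN maps the 150-vector to CO (L/min):
conv(F, k) → batch-norm → ReLU → conv(F, k) → batch-norm → ReLU →
max-pool(2) → dropout → flatten → dense(U, ReLU) → dense(1). All
layers, Adam, and early stopping are implemented in numpy (im2col
convolutions; gradients verified against finite differences in the
tests). Training minimizes MSE with Adam; early stopping watches
validation loss (patience 40, best-epoch weights restored) and a
reduce-on-plateau schedule halves the learning rate when validation
loss stalls. Defaults: learning rate 1e-3, batch 16, F = 16, k = 9,
dropout 0.05, U = 64, ≤ 300 epochs. CO targets stay in physical
units so MAE and bias are directly interpretable.

The cohort splits 60/20/20 (train/validation/test), stratified by the
GMM-recovered group label — with n = 3818 the sizes are exactly
2290/764/764 — and the one split is shared by all twelve conditions,
which are evaluated against the same untouched test set.

Hyperparameter search, when enabled, is sequential model-based: a
Matern-5/2 Gaussian-process surrogate on the unit-cube-encoded space
(learning rate log-uniform [1e-4, 1e-2]; batch {16, 32, 64}; filters
{8, 16, 32, 64}; kernel {3, 5, 7, 9}; dropout [0.1, 0.5]; dense
{16, 32, 64, 128}) with expected-improvement acquisition over random
candidates, one third of trials as random warm-up. Each trial is
scored by mean validation MSE over stratified 5-fold CV (every point
validated exactly once). Noisy conditions always reuse their matched
clean condition's hyperparameters. The headline analyses use the fixed
defaults above rather than a per-condition search; the search
machinery is exercised at small scale in the tests.

## Agreement statistics

Per condition: Pearson r; RMSE; nRMSE = 100·RMSE/(y_max − y_min) over
the *reference* CO range; MAE; Bland–Altman bias and 95% limits of
agreement bias ± 1.96·SD(d) with the sample (n−1) SD and the
convention d = predicted − reference; OLS slope/intercept of predicted
on reference with the two-sided t-test of slope = 0. Paired
comparisons of correlation use the paired t-test on Fisher
z-transformed r values (identical lists return t = 0, p = 1 rather
than 0/0). Intersite variability is the coefficient of variation,
100·SD/mean with the sample SD — with that convention the published
clean-condition r columns give CoV 1.2% (calibrated) and 1.1%
(uncalibrated), which the tests reproduce; the published noisy
calibrated value (0.5%) is consistent only with a population-SD
convention and is documented here rather than reconciled. All
statistics are checked against independent brute-force formula
evaluation to 1e-9.

## Problem sizes and numerical choices

The analysis scripts and acceptance path use: the full n = 3818 cohort
for generator calibration, mixture recovery and the clean uncalibrated
performance bounds (three site models at fixed default
hyperparameters); a 1500-subject cohort for the six clean conditions;
and a 600-subject cohort, shortened training (≤ 80 epochs), over three
seeds for the 12-condition noise grid — sizes chosen so each analysis
re-runs from scratch in minutes on one CPU while leaving the measured
contrasts far larger than their seed-to-seed spread. Waveforms are
simulated at 512 samples/cycle (RK4; halving the step moves cycle
means by < 1e-4 relative). Float32 arithmetic in the CNN; float64
elsewhere. Every stochastic stage draws a child seed derived from the
global seed by hashing the stage name, so runs are reproducible and
stages are independently re-runnable.

## Known limitations

- The generator's shape-to-CO information channel is designed in, with
  its strength set by the compliance jitter (5%) and the LVET noise
  terms; model r on this cohort therefore has a designed ceiling
  (≈ 0.96 uncalibrated) and should not be read as a clinical accuracy
  claim.
- Groups are planted, not emergent; the mixture-recovery analysis
  demonstrates consistency, not discovery.
- One lumped reflection per arterial path; no notch morphology, no
  baseline wander or colored noise (only white noise + spikes).
- The published noisy-condition CoV convention discrepancy noted above.
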