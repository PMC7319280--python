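# Methods

## The network model

`p53pool` simulates the DNA-damage response of the p53 network with a
seven-variable ODE model: phosphorylated ATM (`S`), inactive and
transcriptionally active p53 (`Pi`, `Pa`), and the mRNAs and proteins of the
two negative feedback regulators Mdm2 (`Zm`, `M`) and Wip1 (`Zw`, `W`).

```
dS/dt  = beta_s E(t) - alpha_s S - alpha_ws W S
dPi/dt = beta_p - alpha_pi Pi - alpha_mpi M Pi - beta_sp Pi S/(T_s+S) + alpha_wpa W Pa
dPa/dt = beta_sp Pi S/(T_s+S) - alpha_wpa W Pa - alpha_mpa M Pa
dZm/dt = beta_mt + beta_pamt Pa^n/(T_pa^n+Pa^n) - alpha_mt Zm
dM/dt  = beta_mtm Zm - alpha_m M - alpha_sm S M
dZw/dt = beta_wt + beta_pawt Pa^n/(T_pa^n+Pa^n) - alpha_wt Zw
dW/dt  = beta_wtw Zw - alpha_w W
```

Degradation and translation are mass action; ATM-mediated p53 activation is
saturable with half-saturation `T_s`; p53-dependent transcription of both
target genes is cooperative (Hill exponent `n = 4`, fixed, so exactly 22
rate constants are fitted).  The damage input `E(t)` is a persistent unit
step at irradiation (`t = 0`); an optional first-order repair decay exists
but is off by default, matching the persistence of pulsing over 24 h under
high-dose irradiation.  Wip1 deactivates active p53 back into the inactive
pool (rather than degrading it) and shuts off ATM-P; these two delayed
negative feedbacks generate relaxation-type p53 pulses under sustained
damage.

Two open structural choices were resolved as follows: ATM activation is
linear in `E` and saturation is placed in the p53-activation step (`T_s`);
Wip1-mediated deactivation returns active p53 to the inactive pool, which
conserves p53 between the two forms and lets total p53 act as the
reporter-level observable.

### Reference parameter set

No published value table is bundled; the default `REFERENCE_PARAMETERS` is a
package fixture found by random search plus local refinement against the
documented qualitative behaviour: 4+ pulses in 24 h with inter-peak
intervals of 4–7 h (5.3–5.8 h at the fixture), near-uniform amplitude
(dampening factor ≤ 1.3 by pulse 4), low pre-damage p53, and ~8-fold
induction after damage.  The refinement also scored robustness: pulsing
must survive production-rate fold changes across the subpopulation band
(−0.46…+0.65 log10), which 14/16 random fold-change draws do.  Units are
1/h for first-order rates, conc/h for synthesis rates and arbitrary
concentration units for `T_s`, `T_pa`; reporter intensity is an affine map
`y = scale·(Pi+Pa) + offset` of total p53.

### Numerics

LSODA (scipy `solve_ivp`) with an analytic Jacobian and a numba-compiled
right-hand side; relative/absolute tolerances 1e-8/1e-10 for plain
simulation, relaxed to 1e-6/1e-8 inside optimization loops.  Integration is
restarted at the irradiation time and at every perturbation onset, so
parameter discontinuities are handled exactly.  The pre-damage steady state
(closed form at `E = 0`: ATM-P and active p53 vanish, the remaining
balances are linear) is the initial condition.  States are clipped to zero
below solver tolerance; deeper negativity raises an error.

## Trajectory features

Per-cell trajectories (15-min sampling, 0.5–24 h) are smoothed with a
Gaussian-weighted moving average (σ = 0.5 h, truncated at 3σ, endpoint
renormalised).  Pulse maxima require a prominence of at least 5% of the
cell's intensity range and 2 h separation; exactly one minimum (the segment
minimum) is emitted between consecutive maxima, and a trailing minimum only
when the signal demonstrably turns upward again.  Ten features are derived
per pulse `n`: timings of maxima/minima, inter-peak interval
`IPI_n = t_max[n+1] − t_max[n]`, absolute extrema values, dampening factor
`DF_n = F_max[1]/F_max[n]`, amplitude, width and rise/fall slopes — the
first four pulses by default.  For fitting, simulated extrema are refined
to sub-grid resolution by local quadratic interpolation so least-squares
residuals vary smoothly with parameters; at the 24 h window edge a target's
final minimum is paired with the simulated tail minimum even when the tail
does not rise again, which removes an otherwise flaky missing-peak penalty.

Feature distributions between conditions are compared with two-sided
Wilcoxon rank-sum tests (exact null for small untied samples) and
Bonferroni–Holm correction across the tested family.

## Subpopulations and peak-based means

Pairwise dissimilarity is the Euclidean distance between smoothed, per-cell
range-normalised trajectories on the common grid (a z-scored feature-vector
alternative is available).  Ward agglomeration is cut at each candidate K
and the Calinski–Harabasz index `CH = [B/(K−1)]/[W/(N−K)]` selects K over
2–15, ties toward smaller K.  Each cluster is summarised by its peak-based
mean: mean peak timings and values per pulse index over the members
possessing that pulse, with an index kept only at ≥ 50% coverage — this
preserves pulse shape that pointwise averaging would blur.

Perturbation-condition cells are assigned to calibration clusters by nine
direction criteria (later first/second maxima and minima, longer first two
IPIs, larger DF₂/DF₃, first-pulse amplitude within ±30%), with z-scored
feature distance breaking ties; cells without a detectable pulse land in an
explicit unassignable bucket.  The criteria encode the observed inhibition
response and are fully configurable; with no criteria the assignment
degenerates to nearest-centroid in feature space.

## Pool calibration

The pool couples 22 shared rate constants with a K×6 matrix of log10
fold-change modifiers on the six production rates (p53 synthesis, ATM
activation, Mdm2/Wip1 transcription and translation) — the entry points of
intrinsic noise — plus cell-count weights.  The objective is the weighted
sum of squared extrema residuals, timings scaled by σ_t = 0.25 h (one
frame) and values by σ_y = 5% of the cluster's first-peak value, an
initial-value residual, a penalty of 5 per unmatched extremum slot, and an
L1 term `λ Σ|Δ|` smoothed by an ε-Huber (ε = 1e-6) so a trust-region
least-squares solver applies.  Optimization runs in log10 space around the
nominal values (bounds ±3 for shared, ±1 for modifiers) with
Latin-hypercube multi-starts; each start first solves the cheap
modifier-only subproblem before the joint fit, which sharply reduces poor
local optima.  Everything is deterministic given the seed.

The L1 path refits along an ascending λ grid with warm starts; the selected
λ* is the largest one keeping the weighted SSR within 5% (plus an absolute
slack of 2 squared-sigma units, needed because the unpenalized SSR on
noiseless synthetic targets is essentially zero) of the unpenalized fit.
Modifiers below 1e-3 log10 are reported as exactly zero; the count of
surviving modifiers is the number of subpopulation-specific parameters.

## Perturbation screening

*Sensitivity analysis*: each shared parameter (singles, both directions) or
signed pair (C(22,2)·2 = 462 combinations; both-increase and
increase/decrease patterns — mirrors are first-order redundant) is nudged
by ±1% (±30% variants available) and the relative change
`s = (F′−F)/F` of the four perturbation-responsive features is computed
per pulse and subpopulation, then condensed: *no effect* if all |s| < 1e-4,
*increase*/*decrease* if all defined coefficients share a sign,
*inconsistent* otherwise; 1e-3 marks strong calls for display.  A
combination matches the expected inhibition pattern when all four features
condense to *increase* in at least 7 of 10 subpopulations (10/10 for
singles); an all-decrease pattern matches as the sign-flipped combination.

*Combination inference*: signed log10 fold changes (bounds ±1.5) on a pair
or triplet of shared parameters, applied identically to all subpopulations
from the inhibitor onset (default −1 h, pre-treatment), are fitted to the
perturbation-condition peak-based means with the calibrated pool frozen.
Candidates rank by weighted χ² (= the weighted extrema SSR); the top 30 are
validated on time-variant onset datasets (1.5/2.5/3/5 h), scored by the sum
of log10 group-χ², and filtered by population-readout plausibility: the
damage-kinase proxy AUC must not decrease, peak Mdm2 protein must stay
above 0.2× and peak Mdm2 mRNA below 5× the unperturbed level, and
Mdm2/Wip1 accumulation should be delayed (time-to-half-max).  Surviving
combinations merge into mechanism groups under the process identity of
`beta_sp` and `T_s` (both act on ATM-mediated p53 activation; raising the
half-saturation lowers activation, hence the direction flip).

## Synthetic data generator

The generator emulates the calibration and perturbation imaging
experiments: cells draw a subpopulation by weight, jitter the six
production rates lognormally (SD 0.1 log10 by default), are simulated,
observed on the 0.25-h grid from 0.5 to 24 h, and receive multiplicative
Gaussian noise (CV 5%).  The default ten-subpopulation fold-change fixture
spans the documented heterogeneity band (−0.46…+0.65 log10) with the Wip1
basal-transcription column planted at zero (one production rate carrying no
subpopulation structure); rows were chosen by greedy max–min separation of
the resulting normalised waveforms so the ten members are genuinely
distinct.  The default planted inhibition is the triplet
`alpha_mpi ↑, alpha_m ↑, beta_sp ↓` at onset −1 h with strength 0.5 log10,
which reproduces the inhibition phenotype (delayed maxima/minima, longer
IPIs, stronger dampening, Holm-significant at 200 cells per arm);
closed-loop recovery experiments plant |π| = 0.3.

A `LOW_NOISE` preset (jitter 0.005, noise CV 0.02) defines the
structure-recovery conditions: within-subpopulation scatter is then
dominated by isotropic measurement noise, which hierarchical clustering
cannot profitably split, so Calinski–Harabasz selection recovers the
planted cluster number; with realistic jitter the index creeps past the
true K by splitting the low-dimensional within-cluster parameter manifold.
Recovery experiments also skip smoothing when computing peak-based means,
because Gaussian smoothing biases peak amplitudes by ~10% and would
confound parameter-recovery checks against unsmoothed simulations.

What the generator does not emulate: segmentation/tracking artifacts,
division-induced intensity steps, mother/daughter lineage structure, and
intrinsic stochastic kinetics (trajectories are deterministic ODE solutions
plus observation noise).  Passing recovery tests therefore demonstrate the
correctness and identifiability of the procedures under the model's own
assumptions, not robustness to all real-data pathologies.

## Problem sizes used in tests and acceptance runs

Recovery experiments run at desk scale by design: two-subpopulation pools
for calibration recovery (joint fit of 22 shared + 12 modifier parameters,
3 multi-starts dispersed at 10% of the bounds), a 6-point λ path on the
sparse-support fixture, a 30-candidate triplet screen over 10 data seeds
(50 cells each) for closed-loop inference, and 200 cells for
cluster-number recovery and the phenotype comparison.  The full
1540-triplet screen and 50-start calibrations are available through the
same interfaces.

## Known limitations

- The reference parameter set is a behaviourally tuned fixture, not a
  published estimate; absolute concentrations are arbitrary.
- The nine assignment criteria and the dissimilarity measure are stand-ins
  for unavailable protocol details and are therefore configurable; outputs
  record the rule set used.
- Weighted χ² values depend on the σ conventions above; only comparisons
  under a fixed convention are meaningful.
- Practical identifiability of a few shared parameters (notably
  `alpha_pi`, `alpha_s` and `beta_wt`, which barely influence the features)
  is weak; the calibration reports their deviations rather than asserting
  recovery.
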