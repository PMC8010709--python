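# Methods

This note documents the models, default parameters, numerical choices, and
known limitations behind each `bindkit` stage, and states exactly what the
synthetic-data generators do and do not emulate.

## Adsorption isotherms

Three phenomenological models are fitted to pull-down (solid-depletion)
data of bound protein B (µmol/g cellulose) vs free protein F (µM):

- one-site Langmuir: `B = n_max F / (K_d + F)`
- two-site Langmuir: sum of two independent one-site terms
- Langmuir–Freundlich: `B = n_max F^m / (K_d^m + F^m)`, `m ∈ (0, 2]`

The Langmuir–Freundlich form was chosen so that K_d keeps concentration
units and `F = K_d` gives exact half-saturation; alternative
parameterizations (e.g. `(K F)^m`) rescale K_d but are otherwise
equivalent. Fitting is unweighted nonlinear least squares
(`scipy.optimize.curve_fit`) with eight log-spaced K_d starting values
spanning the observed concentration range and best-RMSE selection;
standard errors come from the covariance at the optimum. Two-site fits are
reported with the low-affinity site first (`K_d ≥ K_d_2`) to remove
label-switching ambiguity. All parameters are bounded positive. Datasets
with zero or constant bound values raise a non-identifiability error;
optimizer failure is reported as a flagged (non-converged) result, not an
exception.

The partition coefficient is the through-origin OLS slope of B vs F
restricted to `F ≤ max_free`. Its relative bias against the true
low-concentration limit `n_max/K_d` is approximately
`F_eff/(K_d + F_eff)` where F_eff is the (F²-weighted) mean of the
retained concentrations — about 4 % already at `max_free = 0.5 µM` for
K_d ≈ 8.7 µM. Users should pick `max_free ≲ K_d/50` when the limit itself
is the quantity of interest; the estimator is exact as `max_free → 0`
(verified by a convergence test).

Truncation sensitivity refits a model to sub-datasets `F ≤ cutoff`. For
data that are genuinely one-site this is unbiased and only inflates
standard errors; the characteristic *decrease* in apparent n_max under
truncation arises when the data deviate from one-site (multi-site or
heterogeneous), which the test suite reproduces by refitting one-site
models to two-site-generated data. The Scatchard diagnostic fits a
quadratic to B/F vs B; one-site data give zero curvature, multi-site data
concave-up (positive) curvature. The curvature sign is reported as 0 when
the quadratic coefficient is within 2 SE of zero.

## Motility traces

Step detection is greedy penalized change-point insertion on the
piecewise-constant model: at each round the single split that most reduces
the residual sum of squares is accepted if the reduction exceeds
`penalty · σ̂²` (default penalty 10), where σ̂ is the noise SD estimated
from 1.4826·MAD of the first differences divided by √2 — robust to the
steps themselves. Two post-passes follow: plateaus shorter than
`min_dwell` (default 50 ms) are merged into the neighbor with the closer
level, and adjacent plateaus whose level difference fails a z-test at
`z = sqrt(2 ln n)` are re-merged. The second pass controls the family-wise
false-step rate: featureless 100-s traces at 0.3 nm noise yield < 1 false
step (measured: 0 in 300 s). At the reference conditions (1 nm steps,
0.75 s dwells, 0.3 nm noise, 1 kHz) recall is ≈ 0.92 with mean absolute
size error ≈ 0.05 nm.

Dwells are the intervals between consecutive accepted steps; terminal
partial plateaus are excluded. Because dwells shorter than `min_dwell`
are structurally unobservable, the raw dwell mean is biased upward by
exactly `min_dwell` for an exponential law (memorylessness); the dwell
MLE accepts a `left_truncation` argument that subtracts it, and a
`censor_limit` for the standard right-censored exponential MLE
`τ̂ = Σ min(t, c) / n_uncensored`. A histogram least-squares mode exists
for parity with figure-style exponential-decay fits but is not the
default (it discretizes and weights arbitrarily).

Step sizes are fitted per sign with a two-component Gaussian mixture whose
second mean is constrained to twice the first (unresolved double
turnovers). The 2× weight is capped at 0.5: double steps are missed-event
artifacts and can never dominate, and the cap removes the exact
`µ → µ/2` relabeling degeneracy of the constrained mixture. EM runs from
two initializations (median and half-median) keeping the higher
likelihood.

Commitment classification is offset-invariant (baseline = median of the
first second). A trace is *unstable* if any excursion beyond
`excursion_threshold` (default 50 nm, half the ~100 nm detach spikes seen
experimentally) returns to the baseline band — transient attach/detach —
whether or not motility follows; *committed* if the position leaves the
baseline noise band permanently and the final sustained departure lasts at
least `motile_threshold` (default 10 s); otherwise *no binding*. The
instability fraction is computed over traces that showed any binding.

## Rupture events

Lifetimes are pooled into half-open 2.5-pN force bins (an event at an
interior edge goes to the upper bin). The Bell model
`τ(F) = τ0 exp(−F x‡ / k_BT)` is fitted to per-bin mean lifetimes by
weighted least squares with weights 1/SEM², in linear lifetime space
(a log-space weighted fit is available for comparison); bins with fewer
than 3 events are excluded, and k_BT defaults to 4.114 pN·nm (298 K).
x‡ is left unbounded in the fit so that a truly force-independent bond
(x‡ = 0) yields an estimate symmetrically distributed around zero.

Multimodality is tested with exponential-mixture EM fits of order
1..max_components and sequential parametric-bootstrap likelihood-ratio
tests (default 200 bootstrap draws): the null LRT distribution for mixture
order is non-standard, so it is simulated from the fitted smaller model.
The observed log-likelihoods entering the LRT are recomputed with the same
(vectorized, tolerance-limited) EM budget used for the bootstrap
replicates — without this exchangeability the test is anticonservative.
Measured calibration at n = 1000: type-I rate ≈ 0.0–0.03 at α = 0.05;
power for a 0.2 s / 5 s two-mode mixture ≈ 1.0.

## FRAP and QCM-D kinetics

FRAP uses the reaction-dominated model
`I(t) = baseline + F_M (1 − e^{−k_off t})`; diffusion is ignored, F_M is a
free fraction in [0, 1], and a fitted F_M ≈ 0 (flat curve) flags k_off
non-identifiable. QCM-D sensorgrams are converted from frequency shift to
adsorbed molecules with the Sauerbrey relation `Δm = −C Δf / n`
(C = 17.7 ng·cm⁻²·Hz⁻¹ for a 5 MHz sensor, overtone n = 3 by default) and
fitted jointly across the adsorption phase
`Γ(t) = Γ_eq (1 − e^{−(k_on* + k_off) t})`, `Γ_eq = A k_on*/(k_on*+k_off)`,
and the rinse phase `Γ ∝ e^{−k_off t}`. k_on* is pseudo-first-order (true
k_on times the free concentration); without a rinse phase only the sum
k_on* + k_off is identified and the result is flagged non-separable. The
molar mass of the protein construct (default 45 kDa, a GFP–CBM-fusion
scale) and sensor area (1 cm²) only set the amplitude scale and cancel in
rate estimates.

## Buffon needle orientation model

The planar aromatic binding motif is a needle of length L on parallel
lines spaced d (the surface chains of the hydrophobic crystal face), all
orientations energetically equivalent. Crossing probability in the
short-needle regime is `2L/(πd)`; the Monte-Carlo sampler (center offset
uniform on [0, d/2], acute angle uniform on [0, π/2]) works for any L.
"Along-axis" binding is the non-crossing outcome. Because no physical L
and d are established for real CBMs, the primary parameter is the
dimensionless ratio L/d and the package ships no biological defaults;
the mutant comparison only assumes the mutant needle is strictly shorter.

## XRD metrics

Segal crystallinity `CrI = (I_max − I_am)/I_max × 100` uses the main
crystalline reflection and the amorphous-angle intensity (18.0° 2θ for
cellulose I; 16.0° for cellulose III, a package default since no
convention exists for that allomorph — configurable). Scherrer size is
`Kλ/(β cos θ)` with Cu Kα λ = 0.15418 nm and K = 0.9 assumed. FWHM is
measured by a local Gaussian-plus-constant fit around the peak rather than
raw half-height crossings, for noise robustness. Peak matching screens
local maxima by prominence (≥ 2 % of the intensity range) to reject
counting-noise bumps.

## Synthetic data: what it emulates, and what a green test establishes

Generators are pure functions of their configs; per-stream seeds derive
from the master seed through a fixed SeedSequence spawn-key schedule, so
adding a generator never shifts another stream.

- Motility traces: exponential dwells, weighted step mixture, sign flips
  with the back-step probability, Gaussian position noise, optional
  exponential detachment, and pre-commitment instability spikes
  (triangular excursions, default 100 nm amplitude) that return to
  baseline. Defaults: 1 nm steps, 0.75 s dwells, 35 % back-steps, 1 kHz,
  σ = 0.3 nm. Sampling rate and noise floor are plausible placeholders —
  the instrument values are not published.
- Rupture events: Bell-model exponential lifetimes under forces uniform on
  [0, 20] pN (populating every 2.5-pN bin), optionally a mixture of
  binding modes.
- Isotherms: a 20-point serial-dilution grid (0.05–250 µM) with Gaussian
  noise (σ = 0.1 µmol/g) truncated at zero.
- FRAP / QCM-D: the exact fitted model plus noise, so noiseless round
  trips are machine-precision identities.
- XRD: Gaussian reflections over a broad amorphous Gaussian halo.

The generators reproduce the *statistical structure the analyses assume*,
not instrument physics: no bead–trap dynamics, drift, or low-frequency
noise in traces; no force-dependent loading-rate effects in rupture
events; no diffusive FRAP component; no viscoelastic (dissipation) QCM-D
effects; no XRD background beyond the single halo. A green
parameter-recovery test therefore establishes correctness and calibration
of the estimators under their stated model, and robustness to i.i.d.
Gaussian noise — not robustness to model misspecification. The demo
pipeline's per-substrate generator truths (adsorption constants, dwell
times, back-step fractions, instability counts, QCM-D rates, XRD
positions) are the reported per-substrate values; the rupture-stage τ0
values per substrate are synthetic stand-ins chosen once to echo the
observed lifetime ordering.

## Derived deltas

Velocity reduction is `(v_I − v_III)/v_I × 100`. Commitment reduction is
the relative change in the instability fraction,
`(f_III − f_I)/f_III × 100` — the only arithmetic consistent with
instability fractions of 12 % and 23 % yielding a ≈ 48 % reduction; from
the underlying counts (2/17 vs 3/13) the same expression gives 49 %.
Affinity fold changes are K_d ratios per fitted model (the high-affinity
site uses K_d_2 of the two-site fit). Whether the published instability
denominators include non-binding traces is not stated; the package
excludes them, which reproduces the printed fractions.

## Known limitations

- The step detector is a stand-in for the (unpublished) original
  procedure; thresholds were chosen for the reference noise regime and are
  configurable but not auto-tuned.
- Two-site isotherm fits on 20-point datasets are weakly identified when
  one K_d is far below the sampled concentrations; K_d_2 can collapse to
  its positive bound with an unreliable standard error (~6 % of seeds at
  the reference design). This mirrors the real over-parameterization
  hazard of multi-site models on such data.
- The exponential-mixture bootstrap trades a small conservative bias for
  speed (tolerance-limited EM); p-values near α should not be
  over-interpreted.
- No loading-rate (dynamic force spectroscopy) models, catch bonds,
  diffusion-coupled FRAP, or Rietveld-level XRD analysis.
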