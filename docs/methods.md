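# Methods

## The model

`incise` treats an elliptical-excision cut as a blade moving through a
Maxwell body — a spring (coefficient `E`, N cm⁻¹) in series with a damper
(coefficient `η`, N s cm⁻¹). The cutting force `f(t)` and the *virtual*
blade velocity `ẋ(t)` are related by

    η ẋ(t) = f(t) + (η/E) ḟ(t),

equivalently the displacement-to-force transfer function
`G(s) = ηs / ((η/E)s + 1)`. The system is high-pass: a unit step in
displacement produces a force decaying exponentially with time constant
`τ = η/E`, and a constant-velocity (ramp) displacement produces a
step-like force settling at `η·v`. The first-order state-space
realization of `G(s)` has constants `α = −E/η`, `β = 1`, `γ = −E²/η`,
`δ = E`; with the default `E = 1`, `η = 0.5` these are `(−2, 1, −2, 1)`.

"Virtual" matters: displacement and velocity here are the kinematics
*implied by the measured force under the Maxwell assumption*, not
measured quantities. We treat them as nominal cm and cm s⁻¹ without
asserting a physical calibration.

Switching structure: the velocity is piecewise-stationary, governed by a
discrete regime `s_t ∈ {L, U}` with a 2×2 row-stochastic transition
matrix `Q`, and within regime `k` the velocity is `N(v_k, σ²_k)` with
the canonical ordering `v_L < v_U`. Because the velocity is treated as
fully observable (it is computed deterministically from the force), the
switching linear dynamical system collapses to a Gaussian HMM over the
velocity sequence, fitted by EM. The long-run occupancy of the upper
regime is the stationary probability `π_U = q₁₂/(q₁₂+q₂₁)`; for two
states this is exact.

## Pipeline directions

*Fitting*: raw force → onset-aligned 120-sample crop at 30 Hz →
dataset-global normalization → virtual displacement
`x(t) = f(t)/E + (1/η)∫₀ᵗ f dτ` (cumulative trapezoid; second-order
accurate, checked against a 10×-resolution quadrature) → forward finite
differences at `dt = 1/30 s` (output one sample shorter, no padding) →
EM over all cuts of a trial as independent sequences.

*Generation*: sample a regime path and velocities from a `RegimeModel`
→ integrate the Maxwell ODE `ḟ = −(E/η)f + Eẋ` from rest.

## Numerical choices

- **Forward simulation** uses the exact zero-order-hold discretization
  `f[k+1] = φ f[k] + η(1−φ) v[k]`, `φ = e^(−dt/τ)`, as the default; it
  preserves the continuous decay rate at any sampling rate, so the
  free-decay log-slope equals `−E/η` to machine precision and the
  step-response plateau is exactly `η·v`. A forward-Euler option exists
  for comparison with naive discretizations (its decay rate at 30 Hz is
  ~3.5% fast for `τ = 0.5 s`). Output sample `k` is the state after
  integrating through velocity sample `k`, so round-trip comparisons
  align `simulate(...)` with `f[1:]`.
- **EM initialization** is deterministic: regime means start at the
  K-quantile-bin means of the pooled velocities, variances at the pooled
  variance, a sticky-diagonal (0.9) transition matrix, uniform start
  distribution. The `seed` argument therefore barely matters; it is kept
  for optional restarts and API stability. A variance floor of 1e-6
  prevents collapse on noiseless fixtures. EM monotonicity of the
  log-likelihood is checked on every fit; on degenerate input (fewer
  distinct values than regimes) hmmlearn's covariance prior/floor act as
  post-M-step projections that can lower the evaluated likelihood, which
  is tolerated with a warning there and an error anywhere else.
- **Stationary distribution** is obtained by a direct linear solve of
  `πQ = π, Σπ = 1` (fixed-point residual ≤ 1e-12); reducible or
  absorbing chains fall back to power iteration and are flagged
  `irreducible=False`.
- **Onset alignment** uses a threshold at 10% of the per-recording
  maximum. How the original recordings were aligned is not something the
  package asserts; the threshold method is a deterministic, testable
  stand-in and the fraction is configurable.
- **Descriptive integral/derivative**: the force integral is the
  trapezoid over the profile's spanned time `(n−1)/rate` (a 120-sample
  30 Hz profile spans 3.967 s, not 4.0); the force-derivative metric is
  the mean absolute forward-difference slope in profile units s⁻¹. Both
  are stated interpretations — reported study values for these metrics
  are not reproduced here because they require the measured dataset.

## Feature space

Per-trial parameter vectors are `(v_L, v_U, σ²_L, σ²_U, q₁₂, q₂₁)`;
`q₁₁, q₂₂` are excluded as exactly collinear (rows of `Q` sum to 1).
Vectors are z-scored per coordinate (variances, not standard deviations,
enter the vector; both are conventional and this choice is configurable
via the raw vectors), then PCA retains 3 components. Component signs are
deterministic: PC1 is oriented to load positively on `q₂₁`, PC2
positively on `q₁₂`, PC3 negatively on `v_U`, matching the documented
interpretation of the axes; if an anchor coordinate is constant and
dropped, the largest-magnitude loading is made positive instead. The
named axes are unit-normalized ±45° diagonals:
`abruptness = (PC1+PC2)/√2`, `energy = −(PC1+PC3)/√2`,
`confidence = (PC3−PC1)/√2`; energy ⟂ confidence by construction.
Score surfaces use Delaunay triangulation with barycentric (piecewise
linear) interpolation; values outside the convex hull are NaN, and
collinear point sets are rejected.

## Statistics

Implemented from their ANOVA-decomposition formulas (scipy and pingouin
serve as independent cross-checks in the test suite, not as the
implementation):

- **Levene**: one-way ANOVA on absolute deviations from the group mean
  (classic variant; `center="median"` gives Brown–Forsythe). The exact
  variant used in the original analysis is not specified; mean-centering
  is the documented default, not a claim about the authors' choice.
- **Welch ANOVA**: weights `wᵢ = nᵢ/sᵢ²`, Satterthwaite-type `df₂`.
- **Games–Howell**: pairwise Welch statistics referred to the
  studentized-range distribution with Welch df. Known to be mildly
  liberal at small per-group n; the calibration test therefore runs at
  n = 50 per group where the studentized-range approximation is in its
  stated validity range.
- **Spearman criticality**: rho is the Pearson correlation of midranks;
  the critical value is the empirical 95th percentile of rho under
  random permutations of y. This is one-sided α = 0.05 — the tabulated
  0.446 for N = 15 corresponds to one-tailed 0.05 (two-tailed 0.10).
  The permutation null at n = 15 is discrete (atoms spaced 1/280), so
  the empirical percentile settles on the atom 0.4393, one atom below
  the conservative table entry 0.446; both are reported by the
  calibration example.
- **ICC(2,1)**: two-way random effects, absolute agreement, single
  measures, `(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)`, returned
  together with its ANOVA table for audit.

## Synthetic cohorts

The generator emulates the study conditions: 120-sample profiles at
30 Hz; 12 profiles per trial (six excisions × upper/lower cuts);
within-regime velocity noise sd 0.35; regime mean velocities confined to
[0, 8]; Maxwell body `E = 1`, `η = 0.5`. Four named archetypes
(smooth_steady, steady_high_persistence, abrupt_with_recovery,
interrupted) span the qualitative range of behaviours; the two
"steady" archetypes use the published-style transition probabilities
(balanced 0.037/0.037 and asymmetric 0.124/0.028), while per-regime
variances and the remaining parameters are package choices — no
per-subject variances are available to copy. Synthetic expert scores
come from a deterministic base-score rule plus optional per-rater bias
and Gaussian noise, so agreement statistics have known targets (ICC = 1
for identical raters, ≈ 0 for independent ones).

What the generator does **not** emulate: sensor noise and hysteresis,
phantom-to-phantom variability, drift within a session, any kinematic
(motion-capture) channel, and the idiosyncratic non-stationarities of
human subjects. Passing tests therefore demonstrate correctness of the
algorithms under the model's own assumptions, not fidelity to any
particular measured cohort; fitting measured data remains subject to
model misfit that the synthetic route cannot expose.

## Problem sizes and determinism

Parameter-recovery checks run at the study geometry (12 × 119 velocity
samples); the sampling-moment and stationarity checks use 10⁵-step
chains; permutation criticality uses 10⁵–2×10⁵ permutations; null
calibrations of Welch/Games–Howell use 2000 replicates. All stochastic
paths take explicit integer seeds (NumPy `default_rng` /
`SeedSequence.spawn` for per-profile streams); reruns are bit-identical.

## Known limitations

- The measured study dataset and expert score tables are not bundled;
  headline study numbers that depend on them (per-subject fits, the
  0.45 inter-expert ICC, specific significance findings) are out of the
  test surface by design. A long-format CSV loader is provided so a
  local copy of such data can be run through the same pipeline.
- ±0.03-level recovery of strongly asymmetric transition matrices from
  a single 12-profile trial is at the edge of the information available
  in ~1400 samples; cohort-level conclusions should pool trials.
- The two-regime reduction assumes velocities are fully observable given
  the Maxwell parameters; misspecified `E, η` bias the velocity scale
  (and hence `v_k`) but leave `Q` largely intact.
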