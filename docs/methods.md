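# Methods

## Motion models and likelihood

All models treat a track as observed positions `c_0..c_n` in μm at unit
frame intervals; physical time enters only through the documentation-level
conversion `D = d² / (2 Δt_seconds)`. Axes are modeled independently with
shared parameters and their log-likelihoods summed; 1D, 2D and 3D tracks
are supported by the same rule.

Each family is a linear-Gaussian state-space model:

| family   | latent state | transition | parameters |
|----------|--------------|------------|------------|
| brownian | `z` | `z' = z + N(0, d²)` | `d, σ` |
| confined | `(z, h)` | `z' = (1−l) z + l h + N(0, d²)`; `h' = h + N(0, q²)` | `d, σ, l, q` |
| directed | `(r, w)` | `r' = r + w + N(0, d²)`; `w' = w + N(0, q²)` | `d, σ, v, q` |

Observations are the identity plus localization noise `N(0, σ²)`; in the
confined family the observation reads the *pre-transition* state
(`c_{i+1} = (1−l) z_i + l h_i + N(0, σ²)`, sharing the predicted point
with the transition but with independent noise).

**Conditioning contract.** The likelihood is a proper density of
`c_1..c_n` given `c_0`: the priors are `z_0 ~ N(c_0, d² + σ²)` (Brownian
and confined; the initial true position `r_0 ~ N(c_0, σ²)` convolved with
one diffusion step), `h_0 ~ N(c_0, q_0²)` with `q_0² = d²/(2l) + σ²`
(the stationary spread `ρ = d/√(2l)` plus localization error, centered on
the first observed position, never re-centered on the track mean), and
for the directed family `r_0 ~ N(c_0, σ²)`, `w_0 ~ N(0, v²)`. Unit
normalization is verified by numerical quadrature at n = 1 and n = 2 in
the test suite.

Because every factor is Gaussian, the marginal over all hidden variables
is computed exactly by a forward Kalman recursion over 1- or 2-dimensional
latent states, in O(n) per axis with hand-unrolled 2×2 algebra (numba).
Log-densities are accumulated directly, so no rescaling is needed even on
10⁴-step tracks. The recursion is certified to 1e-8 against an
independent dense construction (`mvn_oracle_loglik`) that composes the
linear updates into the joint observation covariance and evaluates the
multivariate normal density; the oracle itself is checked against direct
numerical integration of the hidden-variable product for a 1-step track.

Degenerate limits: `l < 1e-6` bypasses the well chain (the `l → 0` limit
is Brownian; `ρ = d/√(2l)` diverges); `v = q = 0` is a point mass at zero
velocity; any single parameter may be exactly 0, but `d = σ = 0` is
rejected as a density-free model.

## Fitting

Maximum likelihood per track (or per population) by L-BFGS-B on
transformed parameters — log for `d, σ, q, v` (bounds 1e-8..10 μm),
logit for `l` (≈1.6e-8..0.999) — from the single fixed initialization
`d = 0.1, σ = 0.02, l = 0.01, q = 0.01, v = 0.01`, convergence at
|ΔlogL| ≲ 1e-11 or 1000 iterations. Frozen parameters are held
bit-exactly. Standard errors come from the finite-difference observed
information at the MLE and are NaN at parameter boundaries.

The single near-null initialization is deliberate and is not just a
convenience. The alternative-family likelihood surfaces are multimodal on
some tracks, and exhaustive multistart maximization finds genuinely
higher optima *on plain Brownian tracks* (spurious velocity/confinement
structure); in a controlled experiment, replacing the single start by a
best-of-3 multistart raised individual log-likelihoods by a few nats but
collapsed the fBm classification accuracy (α=1.5 vs 1.0: 95% → 54%).
Starting every fit near the Brownian null acts as an implicit
regularizer and is part of the method.

Model nesting (confined and directed contain Brownian as a boundary
case) is enforced after fitting: if an alternative fit lands below the
Brownian optimum, it is refit from the Brownian solution and the better
optimum kept.

## Classification

`ρ_alt = exp(logL_B − logL_alt)`, clamped to ≤ 1. Under the Brownian
null, `ρ` is skewed toward 1 (the log-ratio statistic concentrates near
0 with an atom from boundary MLEs), so `ρ` upper-bounds the p-value and
`ρ < α` is a conservative level-α test — verified empirically (type-I
error ≈ 0.01 ≪ 0.05 at α = 0.05). Labels: `brownian` if neither test is
significant, otherwise the significant alternative with the larger
log-likelihood; ties break toward `directed`. Bonferroni (`α/N`) is the
only multiple-testing correction offered. A constant track with noise is
labeled `brownian` (with d → 0): immobility and very tight confinement
are not distinguishable and no claim is made. For tracks that change
behavior, `classify_by_segments` fits each hypothesis on consecutive
fixed-length segments and sums segment log-likelihoods per hypothesis
before forming `ρ`; trailing remainders shorter than one segment are
dropped. `calibrate_pvalue` replaces the conservative bound with a
parametric bootstrap under the fitted Brownian null; the resulting
p-value is valid but not exactly uniform under the null (boundary MLEs
give ρ = 1 with positive probability, an atom at p = 1).

## Derived quantities

* Confinement: stationary sd `ρ = d/√(2l)`, radius `3ρ`, diameter
  `u = 4ρ` (μm); undefined and flagged at `l = 0`.
* Speed: `k̂` is the RMS magnitude of the RTS-smoothed posterior mean
  velocities under the fitted directed model — unbiased within ~10% on
  constant-speed tracks at the validation settings (30 steps, v = 0.1
  μm/frame, σ = 0.02 μm).
* Orientation change per frame: the per-step velocity-chord relation for
  an isosceles step triangle gives `θ̂ = 2 arcsin(min(1, √dim·q̂ / (2 k̂)))`
  (`√dim·q̂` is the sd of the per-step velocity chord over independent
  axes); validated by recovery on rotational-diffusion simulations
  (median within 20% at θ = 0.2 rad/frame).
* Motion blur: full-frame exposure averages the within-frame path, which
  biases the fitted `d` by `√(2/3) ≈ 0.82` once `d > √6 σ` (the static
  error term cannot produce the resulting positive displacement
  autocorrelation). `blur_correct_d` multiplies by `√(3/2)` in that
  regime and flags the regime; below it, estimates are already accurate
  and are returned unchanged.

## Populations and state-count selection

The population log-likelihood is the sum over tracks; a K-state mixture
adds fractions `π_s` (`logL = Σ_t log Σ_s π_s exp(logL_ts)`).
Optimization is generalized EM: responsibilities in the E-step,
closed-form fraction updates, and warm-started L-BFGS passes per
component against its responsibility-weighted likelihood (component
updates that would lower the total are reverted, so the total never
decreases). A per-track × per-component log-likelihood matrix is cached,
which makes tentative deletions cheap.

Initialization overfits deliberately (default K_init = 20): every track
is fitted under all three families, a Gaussian mixture on the
log-transformed per-track parameter vectors yields K_init clusters, and
each cluster becomes a candidate state (majority family among its
members by the conservative ratio test, median parameters, occupancy
fraction). Pruning then repeatedly deletes the component whose
(renormalized) removal costs the least total log-likelihood — ties break
toward the smaller fraction; a removal costing < 0.01 nats skips the
refit — recording `(K, logL, P)` down to K = 1.

The state count maximizes `S(K) = logL(K) − β · P(K) · |logL(K)| / N`
with `P` the free-parameter count (family parameters + K−1 fractions)
and default `β = 0.01`: each parameter must buy at least 1% of the mean
per-track log-likelihood magnitude. Because the penalty scales with the
per-track log-likelihood, the selection is stable in N, unlike AIC/BIC
(also reported), whose fixed penalties are overwhelmed by likelihood
gains at large N when model and data are mismatched. β was fixed once on
the five-state recovery scenario and is a declared constant of the
package. With β = 0 the criterion degenerates to the largest K. At desk
scale a near-duplicate component occasionally survives on small
populations (the likelihood gain from splitting a state by chance can
exceed a few nats); the recovered parameters of the true states are
unaffected.

## Simulator

Tracks are generated in 20 substeps per frame (configurable):
diffusion `N(0, d²/K)` per substep; confinement pull `l/K` toward the
well center per substep, the well diffusing with `q/√K` per substep and
starting at the particle's initial position; directed motion as a shift
`v/K` along the current orientation, with orientation increments
`N(0, θ²/K)` per substep (2D), optional per-frame random-walk jitter of
the speed magnitude (`speed_jitter`) or of the per-axis velocity vector
(`velocity_jitter`, which matches the directed likelihood family
exactly). Localization error is added per frame; with `blur=True` the
observation is the mean of the frame's substep positions plus error.
Hard boundaries use Metropolis-style rejection (a substep leaving the
disk leaves the particle in place), which has exactly uniform
equilibrium on the disk; resampling rejected steps until they land
inside would equilibrate to a density proportional to the local
acceptance probability (≈½ at the wall) and is therefore not used.
Reflection is available as an alternative. Fractional Brownian motion
uses exact Davies–Harte circulant-embedding fGn with Hurst `H = α/2`.

**Continuous-vs-discrete mapping.** The substep simulator approximates
continuous dynamics, while the likelihood models are discrete-frame. For
confinement the frame-level process is AR(1) with decay `(1−l/K)^K ≈
e^(−l)`, so the discrete-model MLE recovers `l̂ ≈ 1 − e^(−l)` (0.221 for
l = 0.25) with a compensating upward bias of ~10–15% in `d̂`; the
stationary spread `d/√(2l)` is preserved. Tests assert this computed
mapping. With `substeps=1` the simulator matches the likelihood model
exactly and all parameters are recovered without bias.

**What the generator does not emulate:** photophysics (blinking,
detection gaps), non-Gaussian localization error, within-track state
switching, anisotropic 3D errors, and mislinking. Passing tests
demonstrate correctness of the inference under the stated generative
models, not robustness to these effects; the fBm, hard-boundary and
motion-blur benchmarks probe the three mismatches studied explicitly.

**Named validation designs** (`make_figure_dataset`): `fig2` (length ×
family grid for test-certainty curves), `fig3` (confinement-factor grid,
200-step tracks), `fig4` (velocity grid, 30-step tracks), `fig6b`
(4-class classification design: confined l=0.2; Brownian d=0.1;
diffusive+directed v=0.1; directed with angular diffusion 0.1 — all
σ=0.02, 100 steps), and `fig5` (five-state population design, 300-step
tracks). The five state parameter sets are stand-ins chosen for the same
qualitative separation as the original benchmark (slow/fast free
diffusion, confinement, diffusion+drift, directed with per-axis velocity
changes); the directed-with-changes state uses the per-axis velocity
random walk, because magnitude-jitter or rotational variants project
onto the per-axis model with track-specific effective parameters and a
shared-parameter mixture then legitimately splits one generative state
into several components.

## Problem sizes and numerical choices

Validation benchmarks run at reduced replicate counts chosen for a
desktop CPU: 500 tracks/class for the fBm and own-model accuracies
(sampling s.e. ≈ 0.3–1.2 points), 1000 tracks for the blur bias, 2000
for the type-I error, 100 tracks/state for the five-state selection.
Optimizer tolerances as above; mixture EM runs at most 10 sweeps
(4 during pruning) with 12 L-BFGS iterations per component M-step and a
responsibility-change threshold of 2e-3·N for skipping already-converged
components. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

* One motion state per track (or per segment); no HMM transitions or
  change-point detection.
* Immobile vs tightly confined tracks are not distinguishable in
  principle at realistic localization error.
* The conservative test trades power for validity; `calibrate_pvalue`
  recovers power at simulation cost.
* Sub-diffusive fractional Brownian motion is outside the model family;
  the likelihood-difference score separates it from Brownian motion at
  ~83–85% (100-step tracks) with the remainder genuinely ambiguous to
  the confined-model approximation (the exact fGn likelihood-ratio test
  reaches ~99.7% on the same data).
* Motion blur is corrected post hoc, not modeled in the likelihood.
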