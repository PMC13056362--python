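# sptmotion

Likelihood-based classification and characterization of single-particle
tracks.

Single-particle tracking experiments (SPT) produce noisy trajectories of
molecules, organelles, beads or nanoparticles. Deciding whether a given
track reflects free diffusion, confinement, or directed transport — and
extracting the physical parameters of that motion — is hard for short,
noisy tracks, where the classical MSD power-law fit is unreliable.
`sptmotion` addresses this for biologists and biophysicists analyzing
TrackMate-style trajectory tables: it computes **exact** likelihoods of a
track under three linear-Gaussian motion models with hidden states, fits
them by maximum likelihood, and turns the maximized likelihoods into a
conservative statistical test of anomalous motion.

## Models

Each coordinate axis of a track `c_0 .. c_n` (μm, one point per frame) is
modeled as a linear-Gaussian state-space process:

* **Brownian**: true positions `r` perform a random walk with per-frame
  step sd `d = sqrt(2 D Δt)`; observations add localization error
  `c_i = r_i + N(0, σ²)`.
* **Confined**: after each diffusion step the particle is pulled a
  fraction `l` of the way toward a potential-well center `h`, which may
  itself diffuse with per-frame sd `q`:
  `r_{i+1} = (1 − l) z_i + l h_i`, `z_i = r_i + N(0, d²)`,
  `h_{i+1} = h_i + N(0, q²)`. The stationary spread about a fixed well
  is `ρ = d / sqrt(2 l)`.
* **Directed**: the particle carries a hidden velocity
  `w_i` (`r_{i+1} = r_i + w_i + N(0, d²)`, `w_{i+1} = w_i + N(0, q²)`,
  initial prior `w_0 ~ N(0, v²)`), so persistent transport with slowly
  changing speed and direction is captured.

Because every factor is Gaussian, the marginal likelihood of the observed
positions (conditional on `c_0`) is computed exactly in O(n) by a
forward Gaussian-message (Kalman) recursion — no Monte Carlo, no MSD
binning. Classification uses the likelihood ratio
`ρ = exp(logL_Brownian − logL_alternative)`, which is skewed toward 1
under Brownian motion and therefore upper-bounds the p-value: `ρ < α`
rejects the Brownian null at level at most `α`. Populations of tracks
sharing states are handled by a mixture model with a penalized,
pruning-based choice of the number of states.

## Worked example

```python
from sptmotion import (SimConfig, simulate_confined, TrackMotionModel,
                       classify_track, derive_motion)

track = simulate_confined(SimConfig(n_steps=200, d=0.1, sigma=0.02, l=0.2, seed=7))
res = TrackMotionModel(track, "confined").fit()
print(res.summary())
```

```
Track motion fit (confined)
  track: sim0  n_steps=200  dim=2
  logL = 385.7726 nats   converged=True  n_iter=24
  parameter   estimate      std err
  d            0.097160    0.010272
  sigma        0.026359    0.011344
  l            0.128376    0.040488
  q            0.007592    0.009960
```

The fit recovers the diffusion length (`d ≈ 0.097` vs the true 0.1 μm)
and localization error (`σ ≈ 0.026` vs 0.02 μm); the fitted per-frame
confinement factor `l ≈ 0.13` reflects the simulator's continuous-time
dynamics (effective frame-level confinement `1 − e^(−l)` ≈ 0.18, see
`docs/methods.md`). Classification and derived quantities:

```python
cls = classify_track(track)
print(cls.label, cls.rho_confined, cls.rho_directed)
dm = derive_motion(res)
print(dm.conf_sd, dm.conf_radius_3sd)
```

```
confined 1.925e-04 1.000
0.1917 0.5752
```

`rho_confined ≈ 2e-4` means the Brownian null is rejected against
confinement with a p-value below 0.0002, while the directed test finds
nothing (`ρ = 1`); the estimated confinement region has standard
deviation 0.19 μm (3-sd radius 0.58 μm).

The same analyses run from the shell:

```
sptmotion simulate --name fig6b --scale 0.1 --seed 1 -o sim/
sptmotion classify -i sim/tracks.csv --alpha 0.05 -o results/
sptmotion population -i sim/tracks.csv --k-init 20 --seed 1 -o pop/
```

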