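"""Exact likelihoods of noisy tracks under linear-Gaussian motion models.

Three model families describe the observed positions ``c_0..c_n`` of a
track (per axis, axes independent with shared parameters):

* **brownian** — the true position performs a Gaussian random walk with
  per-frame step sd ``d``; observations add localization error sd ``sigma``.
* **confined** — a diffusing particle pulled each frame a fraction ``l``
  of the way toward a potential-well center, which itself may diffuse
  with per-frame sd ``q``. The stationary spread about a fixed well is
  ``d / sqrt(2 l)``.
* **directed** — the particle carries a hidden velocity ``w`` (initial
  prior sd ``v`` per axis) that performs a random walk with per-frame sd
  ``q``, superimposed on diffusion ``d``.

All likelihoods are proper densities of ``c_1..c_n`` conditional on the
first observed position ``c_0`` (the model is translation invariant), in
nats, summed over axes. The fast path is an O(n) Kalman recursion; the
dense multivariate-normal construction in :func:`mvn_oracle_loglik` is the
definitionally exact reference used to certify it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.stats import multivariate_normal

from . import _kalman
from .io import Track

__all__ = [
    "BrownianParams",
    "ConfinedParams",
    "DirectedParams",
    "GaussianMessage",
    "StateSpaceSpec",
    "DegenerateModelError",
    "gaussian_product",
    "loglik_brownian",
    "loglik_confined",
    "loglik_directed",
    "loglik",
    "mvn_oracle_loglik",
]


class DegenerateModelError(ValueError):
    """All noise scales are zero: the model has no density."""


@dataclass(frozen=True)
class BrownianParams:
    """Brownian motion: per-frame step sd ``d`` and localization error ``sigma`` (μm)."""

    d: float
    sigma: float

    def __post_init__(self):
        if not (self.d >= 0 and self.sigma >= 0):
            raise ValueError("d and sigma must be nonnegative")
        if self.d == 0 and self.sigma == 0:
            raise DegenerateModelError("d and sigma cannot both be zero")

    @property
    def family(self) -> str:
        return "brownian"


@dataclass(frozen=True)
class ConfinedParams:
    """Confined motion in a (possibly diffusing) quadratic potential well.

    ``l`` is the per-frame confinement factor (fraction of the distance to
    the well center recovered each frame, 0 <= l < 1); ``q`` the per-frame
    sd of the well-center random walk (μm).
    """

    d: float
    sigma: float
    l: float
    q: float

    def __post_init__(self):
        if not (self.d >= 0 and self.sigma >= 0 and self.q >= 0):
            raise ValueError("d, sigma, q must be nonnegative")
        if not 0 <= self.l < 1:
            raise ValueError("confinement factor l must satisfy 0 <= l < 1")
        if self.d == 0 and self.sigma == 0:
            raise DegenerateModelError("d and sigma cannot both be zero")

    @property
    def family(self) -> str:
        return "confined"


@dataclass(frozen=True)
class DirectedParams:
    """Directed motion with a hidden, diffusing velocity.

    ``v`` is the prior sd of the initial per-axis velocity (μm/frame);
    ``q`` the per-frame sd of velocity changes. ``v = q = 0`` is a point
    mass at zero velocity (reduces to Brownian).
    """

    d: float
    sigma: float
    v: float
    q: float

    def __post_init__(self):
        if not (self.d >= 0 and self.sigma >= 0 and self.v >= 0 and self.q >= 0):
            raise ValueError("parameters must be nonnegative")
        if self.d == 0 and self.sigma == 0:
            raise DegenerateModelError("d and sigma cannot both be zero")

    @property
    def family(self) -> str:
        return "directed"


@dataclass(frozen=True)
class GaussianMessage:
    """A scaled Gaussian: exp(log_scale) * N(mean, sd**2)."""

    log_scale: float
    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("sd must be positive")


def gaussian_product(mu_f: float, sd_f: float, mu_g: float, sd_g: float) -> GaussianMessage:
    """Product of two Gaussian densities as a scaled Gaussian.

    ``N(x; mu_f, sd_f^2) * N(x; mu_g, sd_g^2) = phi * N(x; mu_fg, sd_fg^2)``
    with ``phi`` returned in log space for numerical stability.
    """
    if not (sd_f > 0 and sd_g > 0):
        raise ValueError("standard deviations must be positive")
    vf = sd_f * sd_f
    vg = sd_g * sd_g
    vsum = vf + vg
    log_phi = -0.5 * (math.log(2 * math.pi * vsum) + (mu_f - mu_g) ** 2 / vsum)
    mean = (vf * mu_g + vg * mu_f) / vsum
    sd = math.sqrt(vf * vg / vsum)
    return GaussianMessage(log_phi, mean, sd)


def _positions(track: Track | np.ndarray) -> np.ndarray:
    if isinstance(track, Track):
        pos = track.positions
    else:
        pos = np.ascontiguousarray(track, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
    if pos.shape[0] < 2:
        raise ValueError("track must have at least 2 points")
    return np.ascontiguousarray(pos)


def _single_offsets(pos: np.ndarray) -> np.ndarray:
    return np.array([0, pos.shape[0]], dtype=np.int64)


def _check(ll: float) -> float:
    if not np.isfinite(ll):
        raise DegenerateModelError("zero predictive variance encountered")
    return float(ll)


def loglik_brownian(track: Track | np.ndarray, params: BrownianParams) -> float:
    """Exact log-likelihood (nats) of ``c_1..c_n | c_0`` under Brownian motion."""
    pos = _positions(track)
    out = _kalman.brownian_loglik_flat(pos, _single_offsets(pos), params.d, params.sigma)
    return _check(out[0])


def loglik_confined(track: Track | np.ndarray, params: ConfinedParams) -> float:
    """Exact log-likelihood under the diffusing-potential-well model.

    The well-center prior is centered on ``c_0`` with sd
    ``sqrt(rho^2 + sigma^2)`` where ``rho = d / sqrt(2 l)`` (the stationary
    spread). For ``l < 1e-6`` the well chain decouples and the Brownian
    recursion is used (continuity of the l -> 0 limit).
    """
    pos = _positions(track)
    out = _kalman.confined_loglik_flat(
        pos, _single_offsets(pos), params.d, params.sigma, params.l, params.q
    )
    return _check(out[0])


def loglik_directed(track: Track | np.ndarray, params: DirectedParams) -> float:
    """Exact log-likelihood under the hidden-velocity (directed) model."""
    pos = _positions(track)
    out = _kalman.directed_loglik_flat(
        pos, _single_offsets(pos), params.d, params.sigma, params.v, params.q
    )
    return _check(out[0])


def loglik(track, params) -> float:
    """Dispatch on the parameter family."""
    if isinstance(params, BrownianParams):
        return loglik_brownian(track, params)
    if isinstance(params, ConfinedParams):
        return loglik_confined(track, params)
    if isinstance(params, DirectedParams):
        return loglik_directed(track, params)
    raise TypeError(f"unknown params type {type(params)!r}")


# ---------------------------------------------------------------------------
# dense multivariate-normal oracle


@dataclass(frozen=True)
class StateSpaceSpec:
    """Declarative linear-Gaussian state-space layout for one model family.

    Used by :func:`mvn_oracle_loglik` to assemble the joint Gaussian of the
    observations by composing the latent linear updates, independently of
    the O(n) recursion. ``latent_names`` documents the state vector.
    """

    family: str
    params: dict

    @classmethod
    def for_params(cls, params) -> "StateSpaceSpec":
        return cls(params.family, asdict(params))

    @property
    def latent_names(self) -> list[str]:
        return {
            "brownian": ["z"],
            "confined": ["z", "h"],
            "directed": ["r", "w"],
        }[self.family]

    def matrices(self, c0: float, n: int):
        """(m0, P0, F, Q, H, R, obs_state_idx) for a track of n steps, one axis."""
        p = self.params
        d2 = p["d"] ** 2
        s2 = p["sigma"] ** 2
        if self.family == "brownian":
            m0 = np.array([c0])
            P0 = np.array([[d2 + s2]])
            F = np.array([[1.0]])
            Q = np.array([[d2]])
            H = np.array([1.0])
            idx = np.arange(n)  # obs c_{i+1} reads state z_i
        elif self.family == "confined":
            l = p["l"]
            q2 = p["q"] ** 2
            if l <= 0:
                raise ValueError("oracle confined layout requires l > 0 (use brownian)")
            q02 = d2 / (2 * l) + s2
            m0 = np.array([c0, c0])
            P0 = np.diag([d2 + s2, q02])
            F = np.array([[1 - l, l], [0.0, 1.0]])
            Q = np.diag([d2, q2])
            H = np.array([1 - l, l])
            idx = np.arange(n)  # obs c_{i+1} reads state (z_i, h_i)
        elif self.family == "directed":
            v2 = p["v"] ** 2
            q2 = p["q"] ** 2
            m0 = np.array([c0, 0.0])
            P0 = np.diag([s2, v2])
            F = np.array([[1.0, 1.0], [0.0, 1.0]])
            Q = np.diag([d2, q2])
            H = np.array([1.0, 0.0])
            idx = np.arange(1, n + 1)  # obs c_i reads state (r_i, w_i)
        else:
            raise ValueError(f"unknown family {self.family!r}")
        return m0, P0, F, Q, H, s2, idx

    def to_yaml(self) -> str:
        return yaml.safe_dump({"family": self.family, "params": self.params})

    @classmethod
    def from_yaml(cls, text: str) -> "StateSpaceSpec":
        data = yaml.safe_load(text)
        return cls(data["family"], {k: float(v) for k, v in data["params"].items()})


def _dense_axis_loglik(x: np.ndarray, spec: StateSpaceSpec) -> float:
    n = x.shape[0] - 1
    m0, P0, F, Q, H, R, idx = spec.matrices(x[0], n)
    T = int(idx.max()) + 1
    means = [m0]
    covs = [P0]
    for _ in range(1, T):
        means.append(F @ means[-1])
        covs.append(F @ covs[-1] @ F.T + Q)
    # cross-covariances cov(x_a, x_b) = covs[a] @ (F^(b-a)).T for b >= a
    k = idx.shape[0]
    mu = np.array([H @ means[i] for i in idx])
    Sig = np.empty((k, k))
    for a_i, a in enumerate(idx):
        Ca = covs[a]
        for b_i in range(a_i, k):
            b = idx[b_i]
            Sig[a_i, b_i] = H @ _propagate(Ca, F, b - a) @ H
            Sig[b_i, a_i] = Sig[a_i, b_i]
    Sig[np.diag_indices(k)] += R
    y = x[1:]
    try:
        return float(multivariate_normal(mean=mu, cov=Sig).logpdf(y))
    except (np.linalg.LinAlgError, ValueError) as e:
        raise DegenerateModelError(f"singular observation covariance: {e}") from e


def _propagate(C: np.ndarray, F: np.ndarray, steps: int) -> np.ndarray:
    out = C
    for _ in range(steps):
        out = out @ F.T
    return out


def mvn_oracle_loglik(track: Track | np.ndarray, spec: StateSpaceSpec) -> float:
    """Log-likelihood by dense joint-Gaussian construction (test oracle).

    Builds the covariance of ``(c_1..c_n | c_0)`` explicitly by composing
    the linear latent updates and evaluates the multivariate normal
    density. O(n^3); intended for small n.
    """
    pos = _positions(track)
    if pos.shape[0] > 64:
        raise ValueError("oracle is dense; use tracks of <= ~50 steps")
    if spec.family == "confined" and spec.params["l"] < 1e-6:
        spec = StateSpaceSpec(
            "brownian", {"d": spec.params["d"], "sigma": spec.params["sigma"]}
        )
    return sum(_dense_axis_loglik(np.ascontiguousarray(pos[:, a]), spec) for a in range(pos.shape[1]))
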