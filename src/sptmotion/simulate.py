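"""Synthetic track generators for every motion type used in validation.

Each frame interval is subdivided into ``substeps`` (default 20) so that
tracks approximate continuous motion; diffusion, confinement pull,
directed shifts, and rotational diffusion are applied per substep. The
particle position after each block of substeps defines the true frame
position; localization error (and optionally full-frame motion blur,
i.e. averaging of the within-frame substep positions) produces the
observed positions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import numpy as np
import pandas as pd
import yaml

from .io import Track, TrackSet

__all__ = [
    "SimConfig",
    "simulate_brownian",
    "simulate_confined",
    "simulate_directed",
    "simulate_hard_disk",
    "simulate_fbm",
    "apply_motion_blur",
    "make_figure_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters for the substep track simulator (lengths in μm, time in frames)."""

    n_steps: int = 100
    dim: int = 2
    substeps: int = 20
    seed: int | None = None
    d: float = 0.1            # per-frame diffusion length (per axis sd)
    sigma: float = 0.02       # localization error sd
    l: float = 0.0            # confinement factor per frame
    q: float = 0.0            # well-center diffusion length per frame
    v: float = 0.0            # directed speed magnitude per frame
    rot_angle_sd: float = 0.0  # sd of orientation change per frame (rad), 2D only
    speed_jitter: float = 0.0  # per-frame sd of speed-magnitude random walk
    velocity_jitter: float = 0.0  # per-frame per-axis sd of velocity-vector random walk
    hard_radius: float = 0.0  # hard-boundary disk radius
    blur: bool = False        # full-frame exposure averaging

    def __post_init__(self):
        if self.n_steps < 1 or self.substeps < 1:
            raise ValueError("n_steps and substeps must be >= 1")
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        for name in ("d", "sigma", "q", "v", "rot_angle_sd", "speed_jitter", "velocity_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 <= self.l < 1:
            raise ValueError("l must satisfy 0 <= l < 1")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self))

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls(**yaml.safe_load(text))


def _observe(true_sub: np.ndarray, K: int, n: int, sigma: float, blur: bool, rng) -> tuple[np.ndarray, np.ndarray]:
    """(observed, true_frame) from substep positions (n_tracks, total+1, dim)."""
    true_frames = true_sub[:, :: K][:, : n + 1]
    if blur:
        nt, _, dim = true_sub.shape
        obs = np.empty((nt, n + 1, dim))
        for i in range(n + 1):
            obs[:, i] = true_sub[:, i * K : (i + 1) * K].mean(axis=1)
    else:
        obs = true_frames.copy()
    if sigma > 0:
        obs = obs + rng.normal(0.0, sigma, obs.shape)
    return obs, true_frames


def _total_substeps(n: int, K: int, blur: bool) -> int:
    # blur needs substeps i*K .. (i+1)*K - 1 for the last frame i = n
    return (n + 1) * K - 1 if blur else n * K


def _brownian_substeps(nt: int, total: int, dim: int, d: float, K: int, rng) -> np.ndarray:
    steps = rng.normal(0.0, d / np.sqrt(K), (nt, total, dim))
    sub = np.zeros((nt, total + 1, dim))
    np.cumsum(steps, axis=1, out=sub[:, 1:])
    return sub


def _simulate_brownian_batch(nt: int, cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    total = _total_substeps(cfg.n_steps, cfg.substeps, cfg.blur)
    sub = _brownian_substeps(nt, total, cfg.dim, cfg.d, cfg.substeps, rng)
    return _observe(sub, cfg.substeps, cfg.n_steps, cfg.sigma, cfg.blur, rng)


def _simulate_confined_batch(nt: int, cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    K = cfg.substeps
    total = _total_substeps(cfg.n_steps, K, cfg.blur)
    lam = cfg.l / K
    sd_d = cfg.d / np.sqrt(K)
    sd_q = cfg.q / np.sqrt(K)
    r = np.zeros((nt, cfg.dim))
    h = np.zeros((nt, cfg.dim))  # well starts at the initial particle position
    sub = np.empty((nt, total + 1, cfg.dim))
    sub[:, 0] = r
    for s in range(total):
        z = r + rng.normal(0.0, sd_d, r.shape)
        r = z + lam * (h - z)
        if sd_q > 0:
            h = h + rng.normal(0.0, sd_q, h.shape)
        sub[:, s + 1] = r
    return _observe(sub, K, cfg.n_steps, cfg.sigma, cfg.blur, rng)


def _simulate_directed_batch(nt: int, cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    K = cfg.substeps
    n = cfg.n_steps
    total = _total_substeps(n, K, cfg.blur)
    if cfg.rot_angle_sd > 0 and cfg.dim != 2:
        raise ValueError("rotational diffusion is only defined for dim=2")
    if cfg.velocity_jitter > 0:
        if cfg.rot_angle_sd > 0 or cfg.speed_jitter > 0:
            raise ValueError("velocity_jitter excludes rot_angle_sd / speed_jitter")
        return _simulate_velocity_walk_batch(nt, cfg, rng)
    # per-frame speed magnitude: random walk with sd speed_jitter, clamped at 0
    n_frames = total // K + 1
    speeds = np.full((nt, n_frames), cfg.v)
    if cfg.speed_jitter > 0:
        jumps = rng.normal(0.0, cfg.speed_jitter, (nt, n_frames - 1))
        speeds[:, 1:] = cfg.v + np.cumsum(jumps, axis=1)
        np.clip(speeds, 0.0, None, out=speeds)
    if cfg.dim == 2:
        phi0 = rng.uniform(0.0, 2 * np.pi, nt)
        if cfg.rot_angle_sd > 0:
            dphi = rng.normal(0.0, cfg.rot_angle_sd / np.sqrt(K), (nt, total))
            phi = phi0[:, None] + np.concatenate(
                [np.zeros((nt, 1)), np.cumsum(dphi, axis=1)[:, :-1]], axis=1
            )
        else:
            phi = np.broadcast_to(phi0[:, None], (nt, total))
        u = np.stack([np.cos(phi), np.sin(phi)], axis=-1)
    else:
        if cfg.dim == 1:
            u0 = np.ones((nt, 1))
        else:
            u0 = rng.normal(size=(nt, cfg.dim))
            u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
        u = np.broadcast_to(u0[:, None, :], (nt, total, cfg.dim))
    frame_idx = np.minimum(np.arange(total) // K, n_frames - 1)
    drift = u * (speeds[:, frame_idx, None] / K)
    steps = drift
    if cfg.d > 0:
        steps = steps + rng.normal(0.0, cfg.d / np.sqrt(K), (nt, total, cfg.dim))
    sub = np.zeros((nt, total + 1, cfg.dim))
    np.cumsum(steps, axis=1, out=sub[:, 1:])
    return _observe(sub, K, n, cfg.sigma, cfg.blur, rng)


def _simulate_velocity_walk_batch(nt: int, cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Directed motion whose per-axis velocity performs a random walk.

    This matches the directed likelihood model's notion of speed/direction
    changes (each axis independent, per-frame velocity increment sd
    ``velocity_jitter``); the initial velocity has magnitude ``v`` and
    random orientation.
    """
    K = cfg.substeps
    n = cfg.n_steps
    total = _total_substeps(n, K, cfg.blur)
    n_frames = total // K + 1
    if cfg.dim == 1:
        u0 = np.ones((nt, 1))
    else:
        u0 = rng.normal(size=(nt, cfg.dim))
        u0 /= np.linalg.norm(u0, axis=1, keepdims=True)
    w = np.empty((nt, n_frames, cfg.dim))
    w[:, 0] = cfg.v * u0
    incr = rng.normal(0.0, cfg.velocity_jitter, (nt, n_frames - 1, cfg.dim))
    w[:, 1:] = w[:, :1] + np.cumsum(incr, axis=1)
    frame_idx = np.minimum(np.arange(total) // K, n_frames - 1)
    steps = w[:, frame_idx, :] / K
    if cfg.d > 0:
        steps = steps + rng.normal(0.0, cfg.d / np.sqrt(K), (nt, total, cfg.dim))
    sub = np.zeros((nt, total + 1, cfg.dim))
    np.cumsum(steps, axis=1, out=sub[:, 1:])
    return _observe(sub, K, n, cfg.sigma, cfg.blur, rng)


def _simulate_hard_disk_batch(
    nt: int, cfg: SimConfig, rng, boundary: str = "reject"
) -> tuple[np.ndarray, np.ndarray]:
    if cfg.hard_radius <= 0:
        raise ValueError("hard_radius must be positive")
    if boundary not in ("reject", "reflect"):
        raise ValueError("boundary must be 'reject' or 'reflect'")
    K = cfg.substeps
    R = cfg.hard_radius
    total = _total_substeps(cfg.n_steps, K, cfg.blur)
    sd = cfg.d / np.sqrt(K)
    r = np.zeros((nt, cfg.dim))  # disk centered on the start position
    sub = np.empty((nt, total + 1, cfg.dim))
    sub[:, 0] = r
    for s in range(total):
        prop = r + rng.normal(0.0, sd, r.shape)
        if boundary == "reject":
            # Metropolis-style hard wall: a substep that would leave the
            # disk is rejected and the particle stays put. This satisfies
            # detailed balance with the uniform density; resampling until
            # an inside point is drawn would equilibrate to a density
            # proportional to the local acceptance probability instead.
            bad = np.sum(prop**2, axis=1) > R * R
            prop[bad] = r[bad]
        else:
            rad = np.sqrt(np.sum(prop**2, axis=1))
            out = rad > R
            if out.any():
                prop[out] *= ((2 * R - rad[out]) / rad[out])[:, None]
                np.clip(prop, -R, R, out=prop)
        r = prop
        sub[:, s + 1] = r
    return _observe(sub, K, cfg.n_steps, cfg.sigma, cfg.blur, rng)


def _to_tracks(obs: np.ndarray, prefix: str = "sim") -> TrackSet:
    return TrackSet([Track(f"{prefix}{i}", obs[i]) for i in range(obs.shape[0])])


def _single(batch_fn, cfg: SimConfig, return_latent: bool, **kw):
    rng = np.random.default_rng(cfg.seed)
    obs, true = batch_fn(1, cfg, rng, **kw)
    track = Track("sim0", obs[0])
    if return_latent:
        return track, true[0]
    return track


def simulate_brownian(cfg: SimConfig, return_latent: bool = False):
    """Simulate one Brownian track; optionally also return true frame positions."""
    return _single(_simulate_brownian_batch, cfg, return_latent)


def simulate_confined(cfg: SimConfig, return_latent: bool = False):
    """Simulate one track in a (possibly diffusing) quadratic potential well."""
    return _single(_simulate_confined_batch, cfg, return_latent)


def simulate_directed(cfg: SimConfig, return_latent: bool = False):
    """Simulate one directed track (constant or jittered speed, optional rotational diffusion)."""
    return _single(_simulate_directed_batch, cfg, return_latent)


def simulate_hard_disk(cfg: SimConfig, return_latent: bool = False, boundary: str = "reject"):
    """Simulate a Brownian track confined by a hard circular boundary.

    ``boundary="reject"`` (default) rejects boundary-crossing substeps and
    leaves the particle in place (uniform equilibrium on the disk);
    ``"reflect"`` mirrors the excess displacement at the wall.
    """
    return _single(_simulate_hard_disk_batch, cfg, return_latent, boundary=boundary)


def _fgn_davies_harte(nt: int, n: int, hurst: float, rng) -> np.ndarray:
    """Exact fractional Gaussian noise (unit increment variance), (nt, n)."""
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
    )
    m = 2 * n
    c = np.concatenate([gamma, gamma[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # tiny negative round-off
    half = (nt + 1) // 2
    xi = (rng.normal(size=(half, m)) + 1j * rng.normal(size=(half, m))) / np.sqrt(2.0)
    y = np.fft.fft(np.sqrt(lam)[None, :] * xi, axis=1) / np.sqrt(m)
    out = np.empty((2 * half, n))
    out[0::2] = np.sqrt(2.0) * y.real[:, :n]
    out[1::2] = np.sqrt(2.0) * y.imag[:, :n]
    return out[:nt]


def simulate_fbm(
    n_steps: int,
    alpha: float,
    scale: float = 0.1,
    sigma: float = 0.0,
    seed: int | None = None,
    dim: int = 2,
    n_tracks: int | None = None,
):
    """Fractional Brownian motion tracks with anomalous exponent ``alpha``.

    Exact fGn increments via Davies–Harte circulant embedding with Hurst
    index ``H = alpha/2``; ``scale`` is the per-step per-axis increment sd
    (μm); ``alpha = 1`` reduces to Brownian motion. Returns a single
    :class:`Track` or, with ``n_tracks`` given, a :class:`TrackSet`.
    """
    if not 0 < alpha < 2:
        raise ValueError("alpha must lie in (0, 2)")
    if scale < 0 or sigma < 0:
        raise ValueError("scale and sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    nt = 1 if n_tracks is None else n_tracks
    incr = np.stack(
        [_fgn_davies_harte(nt, n_steps, alpha / 2.0, rng) for _ in range(dim)], axis=-1
    )
    pos = np.zeros((nt, n_steps + 1, dim))
    np.cumsum(scale * incr, axis=1, out=pos[:, 1:])
    if sigma > 0:
        pos = pos + rng.normal(0.0, sigma, pos.shape)
    ts = _to_tracks(pos, prefix="fbm")
    if n_tracks is None:
        return ts[0]
    return ts


def apply_motion_blur(
    substep_positions: np.ndarray, substeps: int, sigma: float = 0.0, seed: int | None = None
) -> np.ndarray:
    """Full-frame exposure: frame i = mean of substeps ``i*K .. (i+1)*K - 1``.

    ``substep_positions`` has shape (m, dim); the result has ``m // K``
    frames, each the average of its frame's substep true positions plus
    Gaussian localization error ``sigma``.
    """
    sub = np.asarray(substep_positions, dtype=float)
    if sub.ndim == 1:
        sub = sub[:, None]
    K = substeps
    n_frames = sub.shape[0] // K
    if n_frames < 1:
        raise ValueError("fewer substep positions than one frame")
    obs = sub[: n_frames * K].reshape(n_frames, K, -1).mean(axis=1)
    if sigma > 0:
        obs = obs + np.random.default_rng(seed).normal(0.0, sigma, obs.shape)
    return obs


# ---------------------------------------------------------------------------
# canonical validation datasets


#: Stand-in parameters for the five-state population benchmark (300-step
#: tracks): slow/fast free diffusion, confinement, diffusion with drift,
#: and directed motion with orientation and speed changes.
FIVE_STATE_PARAMS: list[dict] = [
    dict(family="brownian", d=0.02, sigma=0.02),
    dict(family="brownian", d=0.3, sigma=0.02),
    dict(family="confined", d=0.1, sigma=0.02, l=0.2, q=0.01),
    dict(family="directed", d=0.1, sigma=0.02, v=0.1, rot_angle_sd=0.0, speed_jitter=0.0),
    dict(family="directed", d=0.02, sigma=0.02, v=0.06, velocity_jitter=0.02),
]

FIG6B_PARAMS: list[dict] = [
    dict(family="confined", d=0.1, sigma=0.02, l=0.2, q=0.0),
    dict(family="brownian", d=0.1, sigma=0.02),
    dict(family="directed", d=0.1, sigma=0.02, v=0.1, rot_angle_sd=0.0),
    dict(family="directed", d=0.0, sigma=0.02, v=0.1, rot_angle_sd=0.1),
]


def make_figure_dataset(name: str, scale: float = 1.0, seed: int | None = None):
    """Emit a named validation simulation design with ground-truth labels.

    ``scale`` multiplies the full track counts (e.g. 0.1 keeps 10% of the
    tracks). Returns ``(TrackSet, labels)`` where ``labels`` is a DataFrame
    with one row per track carrying the generating family and parameters.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    specs: list[tuple[int, int, dict]] = []  # (count, n_steps, param dict)
    if name == "fig2":
        base = 10_000
        for n in (10, 30, 100):
            specs.append((base, n, dict(family="confined", d=0.1, sigma=0.02, l=0.25, q=0.0)))
            specs.append((base, n, dict(family="directed", d=0.0, sigma=0.02, v=0.02)))
            specs.append((base, n, dict(family="brownian", d=0.1, sigma=0.02)))
    elif name == "fig3":
        for l in (0.02, 0.05, 0.1, 0.25, 0.5):
            specs.append((10_000, 200, dict(family="confined", d=0.1, sigma=0.02, l=l, q=0.0)))
    elif name == "fig4":
        for v in (0.02, 0.05, 0.1, 0.2):
            specs.append((10_000, 30, dict(family="directed", d=0.0, sigma=0.02, v=v)))
    elif name == "fig5":
        for p in FIVE_STATE_PARAMS:
            specs.append((500, 300, dict(p)))
    elif name == "fig6b":
        for p in FIG6B_PARAMS:
            specs.append((5_000, 100, dict(p)))
    else:
        raise ValueError(f"unknown dataset name {name!r}")

    tracks: list[Track] = []
    rows: list[dict] = []
    for class_idx, (count, n_steps, p) in enumerate(specs):
        nt = max(1, int(round(count * scale)))
        p = dict(p)
        family = p.pop("family")
        cfg = SimConfig(n_steps=n_steps, dim=2, **p)
        if family == "brownian":
            obs = _simulate_brownian_batch(nt, cfg, rng)[0]
        elif family == "confined":
            obs = _simulate_confined_batch(nt, cfg, rng)[0]
        else:
            obs = _simulate_directed_batch(nt, cfg, rng)[0]
        for i in range(nt):
            tid = f"{name}_c{class_idx}_{i}"
            tracks.append(Track(tid, obs[i]))
            rows.append(dict(track_id=tid, class_idx=class_idx, family=family,
                             n_steps=n_steps, **p))
    labels = pd.DataFrame(rows)
    return TrackSet(tracks), labels
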