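"""Validation benchmarks: reproducible end-to-end performance measurements.

Each function simulates its own data, runs the full inference path, and
returns a scalar summary (an accuracy, a bias, a rejection rate, a state
count). They power both the test suite and the reproduction script, and
are deterministic given their seed.
"""

from __future__ import annotations

import math

import numpy as np

from .estimation import _fit_all, fit_model
from .io import Track
from .population import TrackPopulationModel
from .simulate import (
    SimConfig,
    _simulate_brownian_batch,
    make_figure_dataset,
    simulate_fbm,
)

__all__ = [
    "best_threshold_accuracy",
    "fbm_classification_accuracy",
    "own_model_classification_accuracy",
    "motion_blur_bias",
    "type_one_error",
    "five_state_selection",
]


def best_threshold_accuracy(scores_low: np.ndarray, scores_high: np.ndarray) -> float:
    """Accuracy of the single threshold that best divides two score sets.

    ``scores_low`` should fall below the threshold and ``scores_high``
    above it; both orientations of the rule are tried and the better one
    reported. Equivalent to 1 - the minimized total error over cutpoints.
    """
    lo = np.asarray(scores_low, float)
    hi = np.asarray(scores_high, float)
    allv = np.concatenate([lo, hi])
    labels = np.concatenate([np.zeros(lo.size), np.ones(hi.size)])
    order = np.argsort(allv, kind="stable")
    labels = labels[order]
    # threshold after position i: low-group = first i+1 items
    cum_ones = np.cumsum(labels)
    n_lo, n_hi = lo.size, hi.size
    idx = np.arange(allv.size)
    correct = (idx + 1 - cum_ones) + (n_hi - cum_ones)
    best = max(correct.max(), n_hi)  # threshold below everything
    acc = best / (n_lo + n_hi)
    return float(max(acc, 1 - acc))


def _loglik_diff_directed_confined(tracks) -> np.ndarray:
    """Fitted L_directed - L_confined per track (super- vs sub-diffusion score)."""
    out = np.empty(len(tracks))
    for i, t in enumerate(tracks):
        fc = fit_model(t, "confined")
        fd = fit_model(t, "directed")
        out[i] = fd.llf - fc.llf
    return out


def fbm_classification_accuracy(
    alpha: float,
    seed: int,
    n_tracks: int = 500,
    n_steps: int = 100,
    scale: float = 0.1,
) -> float:
    """Accuracy (%) distinguishing fBm at ``alpha`` from Brownian (alpha=1).

    Simulates ``n_tracks`` fractional-Brownian tracks at the given
    anomalous exponent and as many Brownian (alpha=1) tracks at the same
    per-step displacement scale, scores every track by the difference of
    the fitted directed- and confined-model log-likelihoods, and reports
    the best-dividing-threshold accuracy.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(2**31 - 1, size=2)
    anom = simulate_fbm(n_steps, alpha, scale=scale, seed=int(s1), n_tracks=n_tracks)
    brown = simulate_fbm(n_steps, 1.0, scale=scale, seed=int(s2), n_tracks=n_tracks)
    sc_anom = _loglik_diff_directed_confined(anom)
    sc_brown = _loglik_diff_directed_confined(brown)
    if alpha < 1.0:  # sub-diffusive scores fall below Brownian scores
        acc = best_threshold_accuracy(sc_anom, sc_brown)
    else:
        acc = best_threshold_accuracy(sc_brown, sc_anom)
    return 100.0 * acc


def own_model_classification_accuracy(seed: int, scale: float = 0.1) -> dict[str, float]:
    """Per-class accuracy (%) vs Brownian on the 4-class benchmark design.

    Classes (100-step tracks): confined (d=0.1, sigma=0.02, l=0.2),
    Brownian (d=0.1), diffusive+directed (d=0.1, v=0.1), directed
    (d=0, v=0.1, angular diffusion 0.1). Each anomalous class is scored
    against the Brownian class with the matching log-likelihood
    difference (confined: L_c - L_b; directed classes: L_d - L_b) at the
    best-dividing threshold.
    """
    tracks, labels = make_figure_dataset("fig6b", scale=scale, seed=seed)
    by_class: dict[int, list[Track]] = {}
    for t, ci in zip(tracks, labels["class_idx"]):
        by_class.setdefault(int(ci), []).append(t)

    def scores(tracks_, kind):
        out = np.empty(len(tracks_))
        for i, t in enumerate(tracks_):
            fits = _fit_all(t)
            if kind == "confined":
                out[i] = fits["confined"].llf - fits["brownian"].llf
            else:
                out[i] = fits["directed"].llf - fits["brownian"].llf
        return out

    acc = {}
    sc_b_conf = scores(by_class[1], "confined")
    sc_b_dir = scores(by_class[1], "directed")
    acc["confined"] = 100 * best_threshold_accuracy(sc_b_conf, scores(by_class[0], "confined"))
    acc["diffusive_directed"] = 100 * best_threshold_accuracy(sc_b_dir, scores(by_class[2], "directed"))
    acc["directed"] = 100 * best_threshold_accuracy(sc_b_dir, scores(by_class[3], "directed"))
    return acc


def motion_blur_bias(seed: int, n_tracks: int = 1000, n_steps: int = 100,
                     d: float = 0.2, sigma: float = 0.01) -> float:
    """mean(d_hat)/d for Brownian tracks observed with full-frame motion blur.

    With ``d > sqrt(6) sigma`` the expected ratio is sqrt(2/3) ~ 0.816:
    frame averaging shrinks the apparent displacement variance and the
    static-error term cannot compensate.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_steps=n_steps, d=d, sigma=sigma, blur=True)
    obs, _ = _simulate_brownian_batch(n_tracks, cfg, rng)
    d_hats = np.empty(n_tracks)
    for i in range(n_tracks):
        d_hats[i] = fit_model(obs[i], "brownian").params.d
    return float(np.mean(d_hats) / d)


def type_one_error(seed: int, n_tracks: int = 2000, n_steps: int = 100,
                   d: float = 0.1, sigma: float = 0.02, alpha: float = 0.05) -> dict[str, float]:
    """Empirical rejection rates of both ratio tests on Brownian tracks.

    The likelihood ratio rho upper-bounds the p-value, so the fraction of
    tracks with rho < alpha must not exceed alpha for either test.
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_steps=n_steps, d=d, sigma=sigma)
    obs, _ = _simulate_brownian_batch(n_tracks, cfg, rng)
    rej_c = rej_d = 0
    for i in range(n_tracks):
        fits = _fit_all(obs[i])
        ll_b = fits["brownian"].llf
        rej_c += math.exp(min(0.0, ll_b - fits["confined"].llf)) < alpha
        rej_d += math.exp(min(0.0, ll_b - fits["directed"].llf)) < alpha
    return {"confined": rej_c / n_tracks, "directed": rej_d / n_tracks}


def five_state_selection(seed: int, scale: float = 0.2, k_init: int = 20) -> int:
    """Selected state count on the five-state population benchmark."""
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(2**31 - 1, size=2)
    tracks, _ = make_figure_dataset("fig5", scale=scale, seed=int(s1))
    pop = TrackPopulationModel(tracks)
    curve = pop.fit_mixture(k_init=k_init, seed=int(s2))
    return curve.selected_k
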