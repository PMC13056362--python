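"""Population-level inference: shared-state fits, mixtures, state-count selection.

Tracks that share a motion state can be pooled: the population likelihood
is the product of the per-track likelihoods. With several states the
population is a mixture — each track belongs to one of K states with
fractions ``pi_s`` summing to 1 — and

    logL_total = sum_tracks log sum_s pi_s * exp(logL(track | state_s)).

The number of states is chosen by overfitting first (many states), then
iteratively removing the state whose removal costs the least likelihood,
refitting after each removal, and scoring the resulting curve with a small
penalty proportional to the parameter count and to the magnitude of the
per-track log-likelihood. Classical AIC/BIC are also reported but tend to
overestimate K when model and data are mismatched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .io import Track, TrackSet
from .estimation import (
    GLOBAL_INIT,
    _PARAM_CLS,
    _PARAM_NAMES,
    _bounds,
    _fit_all,
    _from_unconstrained,
    _loglik_kernel,
    _to_unconstrained,
)

__all__ = [
    "StateComponent",
    "MixtureModel",
    "SelectionCurve",
    "PopulationFitResults",
    "TrackPopulationModel",
    "fit_population_single_state",
    "init_mixture_from_tracks",
    "refit_mixture",
    "prune_states",
    "select_num_states",
    "DEFAULT_BETA",
]

#: Per-parameter penalty as a fraction of the mean per-track |logL|.
DEFAULT_BETA = 0.01


def _n_family_params(family: str) -> int:
    return len(_PARAM_NAMES[family])


@dataclass(frozen=True)
class StateComponent:
    """One motion state of a mixture: family, parameters, and fraction."""

    family: str
    params: object
    fraction: float

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")


@dataclass
class MixtureModel:
    """A weighted set of motion states fitted to a track population."""

    components: list[StateComponent]
    logL_total: float
    n_tracks: int

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def n_params(self) -> int:
        return sum(_n_family_params(c.family) for c in self.components) + (self.k - 1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.components:
            row = dict(family=c.family, fraction=c.fraction)
            row.update({n: getattr(c.params, n) for n in _PARAM_NAMES[c.family]})
            rows.append(row)
        return pd.DataFrame(rows, columns=["family", "fraction", "d", "sigma", "l", "q", "v"])


@dataclass
class SelectionCurve:
    """Likelihood-vs-K curve from pruning, with penalized scores.

    ``entries`` has columns K, logL, n_params, score, aic, bic; models_by_k
    keeps the fitted mixture at each K so the selected model can be
    returned without refitting.
    """

    entries: pd.DataFrame
    beta: float
    selected_k: int
    models_by_k: dict[int, MixtureModel] = field(default_factory=dict, repr=False)


@dataclass
class PopulationFitResults:
    """Single shared motion state fitted jointly to all tracks."""

    family: str
    params: object
    llf: float
    converged: bool
    n_iter: int
    frozen: frozenset
    n_tracks: int

    @property
    def params_dict(self) -> dict[str, float]:
        return {n: getattr(self.params, n) for n in _PARAM_NAMES[self.family]}

    def summary(self) -> str:
        lines = [
            f"Population fit ({self.family}), {self.n_tracks} tracks",
            f"  logL = {self.llf:.4f} nats  converged={self.converged}",
        ]
        for n, v in self.params_dict.items():
            tag = " (frozen)" if n in self.frozen else ""
            lines.append(f"  {n:<7}= {v:.6f}{tag}")
        return "\n".join(lines)


class TrackPopulationModel:
    """Mixture-of-motion-states model for a population of tracks."""

    def __init__(self, tracks: TrackSet | Sequence[Track]):
        if not isinstance(tracks, TrackSet):
            tracks = TrackSet(list(tracks))
        if len(tracks) == 0:
            raise ValueError("need at least one track")
        _ = tracks.dim  # uniform dimensionality required
        self.tracks = tracks
        self._pos = np.ascontiguousarray(
            np.concatenate([t.positions for t in tracks], axis=0)
        )
        lens = np.array([len(t) for t in tracks], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    # ------------------------------------------------------------------
    def loglik_tracks(self, family: str, params) -> np.ndarray:
        """Per-track log-likelihood under one parameter set (one kernel call)."""
        theta = [getattr(params, n) for n in _PARAM_NAMES[family]]
        return _loglik_kernel(family, self._pos, self._offsets, theta)

    def _optimize_family(
        self,
        family: str,
        weights: np.ndarray | None,
        init: Mapping[str, float],
        frozen: frozenset,
        maxiter: int,
    ):
        names = _PARAM_NAMES[family]
        free = [n for n in names if n not in frozen]
        fixed = {n: init[n] for n in frozen}

        def unpack(x):
            vals = dict(fixed)
            for n, xi in zip(free, x):
                vals[n] = _from_unconstrained(n, xi)
            return [vals[n] for n in names]

        def nll(x):
            ll = _loglik_kernel(family, self._pos, self._offsets, unpack(x))
            if not np.all(np.isfinite(ll)):
                return 1e12
            if weights is None:
                return -float(np.sum(ll))
            return -float(weights @ ll)

        if not free:
            th = unpack(np.empty(0))
            return th, -nll(np.empty(0)), True, 0
        x0 = np.array([_to_unconstrained(n, init[n]) for n in free])
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=[_bounds(n) for n in free],
            options=dict(maxiter=maxiter, ftol=1e-11, gtol=1e-7),
        )
        return unpack(res.x), -float(res.fun), bool(res.success), int(res.nit)

    def fit_single_state(
        self,
        family: str,
        frozen: Iterable[str] | None = None,
        init: Mapping[str, float] | None = None,
        maxiter: int = 1000,
    ) -> PopulationFitResults:
        """MLE of one shared parameter set over all tracks."""
        frozen = frozenset(frozen or ())
        init_all = dict(GLOBAL_INIT)
        if init:
            init_all.update(init)
        theta, llf, ok, nit = self._optimize_family(family, None, init_all, frozen, maxiter)
        params = _PARAM_CLS[family](**dict(zip(_PARAM_NAMES[family], theta)))
        if not ok:
            warnings.warn("population fit did not converge", stacklevel=2)
        return PopulationFitResults(family, params, llf, ok, nit, frozen, self.n_tracks)

    # ------------------------------------------------------------------
    def _loglik_matrix(self, components: list[StateComponent]) -> np.ndarray:
        L = np.empty((self.n_tracks, len(components)))
        for s, c in enumerate(components):
            L[:, s] = self.loglik_tracks(c.family, c.params)
        return L

    @staticmethod
    def _total(L: np.ndarray, fracs: np.ndarray) -> float:
        return float(np.sum(logsumexp(L + np.log(fracs)[None, :], axis=1)))

    def mixture_loglik(self, mixture: MixtureModel) -> float:
        L = self._loglik_matrix(mixture.components)
        return self._total(L, np.array([c.fraction for c in mixture.components]))

    def init_mixture(self, k_init: int = 20, seed: int | None = None) -> MixtureModel:
        """Overfitted starting mixture from clustered per-track fits.

        Each track is fitted individually under all three families; a
        Gaussian mixture on the (log-transformed) fitted parameter vectors
        yields ``k_init`` clusters, each summarized into a candidate state
        (majority family, median parameters, occupancy fraction).
        """
        if k_init < 1:
            raise ValueError("k_init must be >= 1")
        if k_init > self.n_tracks:
            warnings.warn("k_init > number of tracks; reducing", stacklevel=2)
            k_init = self.n_tracks
        fits = [_fit_all(t) for t in self.tracks]
        eps = 1e-4
        feats = np.array(
            [
                [
                    math.log(f["brownian"].params.d + eps),
                    math.log(f["brownian"].params.sigma + eps),
                    math.log(f["confined"].params.l + eps),
                    math.log(f["confined"].params.q + eps),
                    math.log(f["directed"].params.v + eps),
                    math.log(f["directed"].params.q + eps),
                ]
                for f in fits
            ]
        )
        # per-track preliminary family by the conservative ratio test
        prelim = []
        for f in fits:
            ll_b, ll_c, ll_d = f["brownian"].llf, f["confined"].llf, f["directed"].llf
            sig_c = ll_c - ll_b > math.log(1 / 0.05)
            sig_d = ll_d - ll_b > math.log(1 / 0.05)
            if sig_c or sig_d:
                prelim.append("confined" if (sig_c and ll_c >= ll_d) else "directed")
            else:
                prelim.append("brownian")
        gm = GaussianMixture(
            n_components=k_init, covariance_type="diag", reg_covar=1e-3,
            random_state=None if seed is None else int(seed) % (2**32 - 1), n_init=1,
        )
        assign = gm.fit_predict(feats)
        comps: list[StateComponent] = []
        for kk in range(k_init):
            mask = assign == kk
            if not mask.any():
                continue
            fams = [prelim[i] for i in np.where(mask)[0]]
            family = max(set(fams), key=fams.count)
            names = _PARAM_NAMES[family]
            med = {
                n: float(np.median([getattr(fits[i][family].params, n) for i in np.where(mask)[0]]))
                for n in names
            }
            if med["d"] == 0 and med["sigma"] == 0:
                med["sigma"] = 1e-4
            comps.append(
                StateComponent(family, _PARAM_CLS[family](**med), mask.mean())
            )
        total = self._total(
            self._loglik_matrix(comps), np.array([c.fraction for c in comps])
        )
        return MixtureModel(comps, total, self.n_tracks)

    def refit_mixture(
        self,
        mixture: MixtureModel,
        max_sweeps: int = 10,
        tol_per_track: float = 1e-5,
        mstep_maxiter: int = 12,
    ) -> MixtureModel:
        """Maximize the mixture likelihood by generalized EM.

        E-step: posterior state responsibilities per track. M-step:
        closed-form fraction update plus a warm-started L-BFGS pass on each
        component's parameters against its responsibility-weighted
        likelihood. The total log-likelihood never decreases (component
        updates that would lower it are reverted).
        """
        comps = list(mixture.components)
        fracs = np.array([c.fraction for c in comps], dtype=float)
        fracs = fracs / fracs.sum()
        L = self._loglik_matrix(comps)
        total = self._total(L, fracs)
        start_total = total
        gamma_at_opt: np.ndarray | None = None  # responsibilities when last optimized
        for _ in range(max_sweeps):
            prev = total
            # E-step
            logw = L + np.log(fracs)[None, :]
            lse = logsumexp(logw, axis=1, keepdims=True)
            gamma = np.exp(logw - lse)
            # fractions
            fracs = gamma.mean(axis=0)
            keep = fracs > 1e-6
            if not keep.all():
                warnings.warn("removing collapsed mixture component", stacklevel=2)
                comps = [c for c, k in zip(comps, keep) if k]
                L = L[:, keep]
                gamma = gamma[:, keep]
                if gamma_at_opt is not None:
                    gamma_at_opt = gamma_at_opt[:, keep]
                fracs = fracs[keep] / fracs[keep].sum()
            # M-step per component; skip components whose responsibilities
            # barely moved since their last parameter update
            if gamma_at_opt is None:
                gamma_at_opt = np.full_like(gamma, np.inf)
            for s, c in enumerate(comps):
                if np.abs(gamma[:, s] - gamma_at_opt[:, s]).sum() < 2e-3 * self.n_tracks:
                    continue
                gamma_at_opt[:, s] = gamma[:, s]
                init = {n: getattr(c.params, n) for n in _PARAM_NAMES[c.family]}
                theta, _, _, _ = self._optimize_family(
                    c.family, gamma[:, s], init, frozenset(), mstep_maxiter
                )
                params = _PARAM_CLS[c.family](**dict(zip(_PARAM_NAMES[c.family], theta)))
                new_col = self.loglik_tracks(c.family, params)
                old_col = L[:, s].copy()
                L[:, s] = new_col
                if self._total(L, fracs) >= prev - 1e-9:
                    comps[s] = StateComponent(c.family, params, fracs[s])
                else:  # revert a rare non-improving partial step
                    L[:, s] = old_col
            comps = [
                StateComponent(c.family, c.params, f) for c, f in zip(comps, fracs)
            ]
            total = self._total(L, fracs)
            if total - prev < tol_per_track * self.n_tracks:
                break
        if total < start_total - 1e-9:  # pragma: no cover - monotonicity guard
            return MixtureModel(list(mixture.components), start_total, self.n_tracks)
        return MixtureModel(comps, total, self.n_tracks)

    def prune(
        self,
        mixture: MixtureModel,
        beta: float = DEFAULT_BETA,
        refit_kwargs: dict | None = None,
    ) -> SelectionCurve:
        """Iteratively remove the least useful state down to K=1.

        At each K the component whose (fraction-renormalized) removal costs
        the least total log-likelihood is deleted, the mixture is refitted,
        and (K, logL, P) recorded. Ties are broken toward the
        smaller-fraction component.
        """
        refit_kwargs = refit_kwargs or {}
        prune_refit = dict(refit_kwargs)
        prune_refit.setdefault("max_sweeps", 4)  # warm-started refits converge fast
        current = self.refit_mixture(mixture, **refit_kwargs)
        rows = []
        models: dict[int, MixtureModel] = {}
        while True:
            rows.append(dict(K=current.k, logL=current.logL_total, n_params=current.n_params))
            models[current.k] = current
            if current.k == 1:
                break
            L = self._loglik_matrix(current.components)
            fracs = np.array([c.fraction for c in current.components])
            drops = np.empty(current.k)
            for s in range(current.k):
                keep = np.arange(current.k) != s
                drops[s] = self._total(L[:, keep], fracs[keep] / fracs[keep].sum())
            # highest remaining logL = smallest drop; tie -> smaller fraction
            order = np.lexsort((fracs, -drops))
            s_del = int(order[0])
            keep = [c for i, c in enumerate(current.components) if i != s_del]
            norm = sum(c.fraction for c in keep)
            keep = [StateComponent(c.family, c.params, c.fraction / norm) for c in keep]
            trimmed = MixtureModel(keep, drops[s_del], self.n_tracks)
            if current.logL_total - drops[s_del] < 1e-2:
                # removed a redundant duplicate: already at a maximum
                current = trimmed
            else:
                current = self.refit_mixture(trimmed, **prune_refit)
        df = pd.DataFrame(rows).sort_values("K", ignore_index=True)
        curve = SelectionCurve(df, beta, 0, models)
        curve.selected_k = select_num_states(curve, beta)
        return curve

    def fit_mixture(
        self,
        k_init: int = 20,
        seed: int | None = None,
        beta: float = DEFAULT_BETA,
        refit_kwargs: dict | None = None,
    ) -> "SelectionCurve":
        """Full pipeline: overfit, prune, select. Returns the selection curve;
        the chosen model is ``curve.models_by_k[curve.selected_k]``."""
        mix = self.init_mixture(k_init=k_init, seed=seed)
        return self.prune(mix, beta=beta, refit_kwargs=refit_kwargs)


def select_num_states(curve: SelectionCurve, beta: float = DEFAULT_BETA) -> int:
    """Penalized state-count choice.

    Maximizes ``S(K) = logL(K) - beta * P(K) * |logL(K)| / N`` where P is
    the free-parameter count. The per-parameter penalty scales with the
    mean per-track log-likelihood magnitude, which keeps the selection
    stable as the number of tracks grows (unlike AIC/BIC whose fixed
    penalties are overwhelmed by likelihood gains at large N). ``beta = 0``
    degenerates to picking the largest K.
    """
    df = curve.entries
    n_tracks = None
    for k, m in curve.models_by_k.items():
        n_tracks = m.n_tracks
        break
    if n_tracks is None:
        raise ValueError("curve has no attached models")
    score = df["logL"] - beta * df["n_params"] * df["logL"].abs() / n_tracks
    curve.entries = df.assign(
        score=score,
        aic=2 * df["n_params"] - 2 * df["logL"],
        bic=df["n_params"] * math.log(n_tracks) - 2 * df["logL"],
    )
    return int(df.loc[score.idxmax(), "K"])


# ---------------------------------------------------------------------------
# functional wrappers


def fit_population_single_state(tracks, family: str, frozen=None, **kw) -> PopulationFitResults:
    return TrackPopulationModel(tracks).fit_single_state(family, frozen=frozen, **kw)


def init_mixture_from_tracks(tracks, k_init: int = 20, seed: int | None = None) -> MixtureModel:
    return TrackPopulationModel(tracks).init_mixture(k_init=k_init, seed=seed)


def refit_mixture(tracks, mixture: MixtureModel, **kw) -> MixtureModel:
    return TrackPopulationModel(tracks).refit_mixture(mixture, **kw)


def prune_states(tracks, mixture: MixtureModel, beta: float = DEFAULT_BETA, **kw) -> SelectionCurve:
    return TrackPopulationModel(tracks).prune(mixture, beta=beta, **kw)
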