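"""Diffusive-state classification of 7-frame sub-tracks by perturbation EM.

Tracks are split into non-overlapping 7-frame sub-tracks (6 displacements
per axis), each modelled as a zero-mean Gaussian whose displacement
covariance has three bands determined by the state's diffusion coefficient
D and static localization noise sigma under motion blur R:

    band0 = 2 D dt + 2 sigma^2 - 4 R D dt     (lag-0, the variance)
    band1 = -(sigma^2 - 2 R D dt)             (lag-1, noise-induced)
    band2 = 0

A K-state mixture of such Gaussians is fitted by EM with random
reinitializations and post-convergence perturbation restarts; the number of
states is selected by BIC over K = 1..15. Sub-tracks are assigned to their
maximum-posterior state; ambiguous assignments (difference between the two
largest posteriors <= 0.2) are excluded from population-fraction and MSD
reporting, and states holding under 5% of sub-tracks are folded into an
"other" class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .acquisition import AcquisitionParams
from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "SubTrack",
    "CovarianceBands",
    "DiffusiveState",
    "StateModel",
    "Assignment",
    "EMOptions",
    "split_subtracks",
    "covariance_bands",
    "bands_to_params",
    "subtrack_loglik",
    "fit_states",
    "select_model",
    "assign_states",
    "filter_minor_states",
    "localization_precision",
]

SUBTRACK_LENGTH = 7
_D_FLOOR = 1e-9  # keeps the banded covariance positive definite


@dataclass(frozen=True)
class SubTrack:
    """Seven consecutive localizations of one parent track.

    A bridged blink inside the window makes one displacement span two
    frames; its lag is recorded in ``lags``.
    """

    track_id: int
    ordinal: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y)

    @property
    def lags(self) -> np.ndarray:
        return np.diff(self.frames)


@dataclass(frozen=True)
class CovarianceBands:
    """Stationary displacement covariance at lags 0, 1, 2 (um^2)."""

    band0: float
    band1: float
    band2: float = 0.0


@dataclass(frozen=True)
class DiffusiveState:
    """One mixture component: D (um^2/s), sigma (um), mixing fraction."""

    d: float
    sigma: float
    fraction: float


@dataclass
class StateModel:
    """Fitted K-state mixture with per-sub-track posteriors."""

    states: list[DiffusiveState]
    log_likelihood: float
    bic: float
    gamma: np.ndarray  # (n_subtracks, K) posterior matrix
    n_subtracks: int
    converged: bool = True
    n_iter: int = 0
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass
class Assignment:
    """Maximum-posterior state assignment with ambiguity filtering.

    ``state`` is the argmax state index (states ordered by increasing D);
    ``dpp`` the difference of the two largest posteriors; ``retained`` is
    dpp > cut. ``post_filter_state`` is filled by
    :func:`filter_minor_states` (-1 marks "other").
    """

    state: np.ndarray
    dpp: np.ndarray
    retained: np.ndarray
    dpp_cut: float = 0.2
    post_filter_state: np.ndarray | None = None
    kept_states: list[int] | None = None


@dataclass(frozen=True)
class EMOptions:
    """EM schedule: reinitializations, perturbation restarts, convergence."""

    n_reinit: int = 20
    n_perturb: int = 200
    tol: float = 1e-7
    max_iter: int = 10_000
    perturb_scale: float = 0.3
    init_sigma: float = 0.02
    seed: int = 0


# ---------------------------------------------------------------------------
# sub-track construction and band algebra

def split_subtracks(tracks: list[Track], length: int = SUBTRACK_LENGTH) -> list[SubTrack]:
    """Cut each track into consecutive non-overlapping ``length``-localization
    windows from its start; the trailing remainder is discarded."""
    subs: list[SubTrack] = []
    for t in tracks:
        n = len(t) // length
        for i in range(n):
            sl = slice(i * length, (i + 1) * length)
            subs.append(
                SubTrack(
                    track_id=t.track_id,
                    ordinal=i,
                    frames=t.frames[sl].copy(),
                    x=t.x[sl].copy(),
                    y=t.y[sl].copy(),
                )
            )
    return subs


def covariance_bands(
    d: float, sigma: float, r: float, dt: float
) -> CovarianceBands:
    """Model covariance bands of blurred, noisy Brownian displacements."""
    if d < 0 or sigma < 0:
        raise ValueError("D and sigma must be >= 0")
    band0 = 2 * d * dt + 2 * sigma**2 - 4 * r * d * dt
    band1 = -(sigma**2 - 2 * r * d * dt)
    return CovarianceBands(band0=band0, band1=band1, band2=0.0)


def bands_to_params(
    band0: float, band1: float, r: float, dt: float
) -> tuple[float, float]:
    """Invert the band model: D = (band0 + 2 band1) / (2 dt),
    sigma^2 = 2 R D dt - band1. Inadmissible values are clamped to 0."""
    d = (band0 + 2 * band1) / (2 * dt)
    if d < 0:
        logger.debug("bands_to_params: clamping D=%g to 0", d)
        d = 0.0
    sig2 = 2 * r * d * dt - band1
    if sig2 < 0:
        logger.debug("bands_to_params: clamping sigma^2=%g to 0", sig2)
        sig2 = 0.0
    return d, float(np.sqrt(sig2))


def _banded_cov(d: float, sigma: float, r: float, dt: float, lags: np.ndarray) -> np.ndarray:
    """Displacement covariance matrix for one sub-track lag pattern.

    Diagonal entries of gap-bridged (lag-2) displacements use the two-frame
    variance 2 D (2 dt) + 2 sigma^2 - 4 R D dt = band0 + 2 D dt.
    """
    b = covariance_bands(max(d, _D_FLOOR), sigma, r, dt)
    m = len(lags)
    c = np.zeros((m, m))
    diag = np.where(lags == 1, b.band0, b.band0 + 2 * max(d, _D_FLOOR) * dt)
    np.fill_diagonal(c, diag)
    for i in range(m - 1):
        c[i, i + 1] = c[i + 1, i] = b.band1
    return c


# ---------------------------------------------------------------------------
# vectorized likelihood over grouped lag patterns

class _SubTrackArrays:
    """Columnar view of a sub-track list, grouped by lag pattern."""

    def __init__(self, subtracks: list[SubTrack]):
        if not subtracks:
            raise ValueError("no sub-tracks supplied")
        self.n = len(subtracks)
        self.dx = np.array([s.dx for s in subtracks])
        self.dy = np.array([s.dy for s in subtracks])
        patterns: dict[tuple, list[int]] = {}
        for i, s in enumerate(subtracks):
            patterns.setdefault(tuple(int(v) for v in s.lags), []).append(i)
        self.groups = [(np.array(k), np.array(ix)) for k, ix in patterns.items()]
        # per-sub-track empirical moments for the M-step (lag-1 only for the
        # variance; all adjacent products for the lag-1 band)
        lag1 = np.array([s.lags == 1 for s in subtracks])
        n1 = lag1.sum(axis=1)
        sq = (self.dx**2 + self.dy**2) * lag1
        self.b0_hat = sq.sum(axis=1) / np.maximum(2 * n1, 1)
        prod = self.dx[:, :-1] * self.dx[:, 1:] + self.dy[:, :-1] * self.dy[:, 1:]
        self.b1_hat = prod.mean(axis=1) / 2.0

    def loglik(self, states: list[DiffusiveState], r: float, dt: float) -> np.ndarray:
        """(n, K) per-sub-track log-likelihood under each state."""
        out = np.empty((self.n, len(states)))
        for k, st in enumerate(states):
            for lags, ix in self.groups:
                c = _banded_cov(st.d, st.sigma, r, dt, lags)
                try:
                    chol = np.linalg.cholesky(c)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"non-positive-definite covariance for state {k} "
                        f"(D={st.d}, sigma={st.sigma})"
                    ) from exc
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                m = len(lags)
                zx = np.linalg.solve(chol, self.dx[ix].T)
                zy = np.linalg.solve(chol, self.dy[ix].T)
                quad = (zx**2).sum(axis=0) + (zy**2).sum(axis=0)
                out[ix, k] = -0.5 * quad - logdet - m * np.log(2 * np.pi)
        return out


def subtrack_loglik(
    sub: SubTrack, state: DiffusiveState, acq: AcquisitionParams
) -> float:
    """Log-likelihood of one sub-track under one state (both axes)."""
    arr = _SubTrackArrays([sub])
    return float(arr.loglik([state], acq.motion_blur_coefficient, acq.frame_interval)[0, 0])


# ---------------------------------------------------------------------------
# EM

def _em_run(
    arr: _SubTrackArrays,
    init_states: list[DiffusiveState],
    r: float,
    dt: float,
    opts: EMOptions,
) -> tuple[list[DiffusiveState], np.ndarray, float, bool, int]:
    """One EM run from the given initialization. Returns states, posteriors,
    log-likelihood, convergence flag and iteration count."""
    states = list(init_states)
    prev_ll = -np.inf
    converged = False
    it = 0
    trace: list[float] = []
    gamma = np.full((arr.n, len(states)), 1.0 / len(states))
    for it in range(1, opts.max_iter + 1):
        ll_mat = arr.loglik(states, r, dt)
        log_pi = np.log([max(s.fraction, 1e-300) for s in states])
        joint = ll_mat + log_pi
        norm = logsumexp(joint, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        gamma = np.exp(joint - norm[:, None])

        # drop collapsed states
        w = gamma.sum(axis=0)
        alive = w > 1e-8
        if not alive.all():
            logger.info("EM: dropping %d collapsed state(s)", (~alive).sum())
            states = [s for s, a in zip(states, alive) if a]
            if not states:
                raise RuntimeError("all states collapsed")
            gamma = gamma[:, alive]
            gamma /= gamma.sum(axis=1, keepdims=True)
            w = gamma.sum(axis=0)

        # M-step: posterior-weighted empirical bands -> (D, sigma)
        new_states = []
        for k in range(len(states)):
            wk = gamma[:, k]
            b0 = float(np.dot(wk, arr.b0_hat) / w[k])
            b1 = float(np.dot(wk, arr.b1_hat) / w[k])
            d, sigma = bands_to_params(b0, b1, r, dt)
            new_states.append(DiffusiveState(d=d, sigma=sigma, fraction=float(w[k] / arr.n)))
        states = new_states

        if abs(ll - prev_ll) < opts.tol:
            converged = True
            break
        prev_ll = ll
    ll_mat = arr.loglik(states, r, dt)
    joint = ll_mat + np.log([max(s.fraction, 1e-300) for s in states])
    norm = logsumexp(joint, axis=1)
    gamma = np.exp(joint - norm[:, None])
    return states, gamma, float(norm.sum()), converged, it, np.asarray(trace)


def _initial_states(
    arr: _SubTrackArrays, k: int, dt: float, opts: EMOptions, rng: np.random.Generator,
    deterministic: bool,
) -> list[DiffusiveState]:
    b0 = arr.b0_hat[arr.b0_hat > 0]
    lo = max(float(np.percentile(b0, 1)) / (2 * dt), 1e-6) if len(b0) else 1e-6
    hi = max(float(np.percentile(b0, 99)) / (2 * dt), 10 * lo)
    if deterministic:
        ds = np.geomspace(lo, hi, k) if k > 1 else np.array([np.sqrt(lo * hi)])
    else:
        ds = np.exp(rng.uniform(np.log(lo), np.log(hi), k))
        ds.sort()
    return [DiffusiveState(d=float(d), sigma=opts.init_sigma, fraction=1.0 / k) for d in ds]


def fit_states(
    subtracks: list[SubTrack],
    k: int,
    acq: AcquisitionParams,
    em_opts: EMOptions | None = None,
) -> StateModel:
    """Fit a K-state mixture by EM with reinitializations and perturbations.

    The best of ``n_reinit`` random initializations is refined by
    ``n_perturb`` restarts from log-normally perturbed parameters; the
    highest-likelihood solution is returned with states ordered by
    increasing D.
    """
    opts = em_opts or EMOptions()
    if k < 1:
        raise ValueError("K must be >= 1")
    if len(subtracks) < k:
        raise ValueError(f"need at least K={k} sub-tracks, got {len(subtracks)}")
    arr = _SubTrackArrays(subtracks)
    r = acq.motion_blur_coefficient
    dt = acq.frame_interval
    rng = np.random.default_rng(opts.seed + 104729 * k)

    best: tuple | None = None
    for rep in range(max(opts.n_reinit, 1)):
        init = _initial_states(arr, k, dt, opts, rng, deterministic=(rep == 0))
        try:
            result = _em_run(arr, init, r, dt, opts)
        except (RuntimeError, ValueError):
            continue
        if best is None or result[2] > best[2]:
            best = result
    if best is None:
        raise RuntimeError(f"no EM run converged for K={k}")

    for _ in range(opts.n_perturb):
        eps = lambda: float(np.exp(rng.uniform(-opts.perturb_scale, opts.perturb_scale)))
        perturbed = [
            DiffusiveState(d=max(s.d, _D_FLOOR) * eps(), sigma=max(s.sigma, 1e-4) * eps(),
                           fraction=s.fraction)
            for s in best[0]
        ]
        tot = sum(s.fraction for s in perturbed)
        perturbed = [replace(s, fraction=s.fraction / tot) for s in perturbed]
        try:
            result = _em_run(arr, perturbed, r, dt, opts)
        except (RuntimeError, ValueError):
            continue
        if result[2] > best[2]:
            best = result

    states, gamma, ll, converged, n_iter, trace = best
    order = np.argsort([s.d for s in states])
    states = [states[i] for i in order]
    gamma = gamma[:, order]
    k_eff = len(states)
    n = arr.n
    p = (k_eff - 1) + 2 * k_eff
    bic = -2.0 * ll + p * np.log(n)
    return StateModel(
        states=states, log_likelihood=ll, bic=bic, gamma=gamma,
        n_subtracks=n, converged=converged, n_iter=n_iter, ll_trace=trace,
    )


def select_model(
    subtracks: list[SubTrack],
    acq: AcquisitionParams,
    k_max: int = 15,
    em_opts: EMOptions | None = None,
    stop_after: int | None = None,
) -> StateModel:
    """Fit K = 1..k_max and return the BIC-minimizing model.

    ``stop_after`` optionally stops the scan after that many consecutive
    BIC increases (the full scan is the default).
    """
    best: StateModel | None = None
    n_worse = 0
    for k in range(1, k_max + 1):
        try:
            model = fit_states(subtracks, k, acq, em_opts)
        except (RuntimeError, ValueError) as exc:
            logger.info("select_model: K=%d failed (%s)", k, exc)
            continue
        logger.info("select_model: K=%d logL=%.3f BIC=%.3f", k, model.log_likelihood, model.bic)
        if best is None or model.bic < best.bic:
            best = model
            n_worse = 0
        else:
            n_worse += 1
            if stop_after is not None and n_worse >= stop_after:
                break
    if best is None:
        raise RuntimeError("no model converged for any K")
    return best


# ---------------------------------------------------------------------------
# assignment and filtering

def assign_states(model: StateModel, dpp_cut: float = 0.2) -> Assignment:
    """Maximum-posterior assignment with ambiguity (dpp) filtering.

    dpp is the difference between the two largest posteriors; sub-tracks
    with dpp <= ``dpp_cut`` are flagged as not retained. argmax ties break
    toward the lower-D state (states are D-ordered, so toward the lower
    index).
    """
    g = model.gamma
    state = np.argmax(g, axis=1)
    if g.shape[1] == 1:
        dpp = np.ones(len(g))
    else:
        part = np.partition(g, -2, axis=1)
        dpp = part[:, -1] - part[:, -2]
    return Assignment(state=state, dpp=dpp, retained=dpp > dpp_cut, dpp_cut=dpp_cut)


def filter_minor_states(
    model: StateModel, assignment: Assignment, floor: float = 0.05
) -> tuple[StateModel, Assignment]:
    """Fold states holding under ``floor`` of all sub-tracks into "other".

    Population fractions of the surviving states are recomputed over
    retained (unambiguous) sub-tracks and renormalized. The returned
    assignment carries ``post_filter_state``: the index into the kept-state
    list, or -1 for "other".
    """
    n = len(assignment.state)
    counts = np.bincount(assignment.state, minlength=model.k)
    kept = [k for k in range(model.k) if counts[k] / n >= floor]
    if not kept:
        raise RuntimeError("all states fall below the population floor; degenerate fit")
    retained_counts = np.bincount(
        assignment.state[assignment.retained], minlength=model.k
    ).astype(float)[kept]
    fractions = retained_counts / retained_counts.sum()
    new_states = [
        replace(model.states[k], fraction=float(f)) for k, f in zip(kept, fractions)
    ]
    remap = {k: i for i, k in enumerate(kept)}
    post = np.array([remap.get(s, -1) for s in assignment.state])
    new_model = StateModel(
        states=new_states,
        log_likelihood=model.log_likelihood,
        bic=model.bic,
        gamma=model.gamma,
        n_subtracks=model.n_subtracks,
        converged=model.converged,
        n_iter=model.n_iter,
    )
    new_assignment = replace(assignment, post_filter_state=post, kept_states=kept)
    return new_model, new_assignment


def localization_precision(sigma_band0: float, d: float, r: float, dt: float) -> float:
    """Static localization error from a fitted variance band:
    sigma = sqrt((band0 - 2 D dt (1 - 2R)) / 2). Raises if the bracket is
    negative (fit inconsistent with the band model)."""
    bracket = sigma_band0 - 2 * d * dt * (1 - 2 * r)
    if bracket < 0:
        raise ValueError(
            f"negative bracket {bracket:.3e}: band0={sigma_band0}, D={d} inconsistent"
        )
    return float(np.sqrt(bracket / 2.0))
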