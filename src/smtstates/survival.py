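"""Dwell-time survival analysis with photobleaching correction.

The raw survival distribution S(t) of track durations confounds unbinding
with photobleaching. The bleaching rate k_PB is estimated by fitting the
survival of a long-lived reference (histone H2B) to a triple exponential
and taking the slowest time constant; corrected survival is then
S_hat(t) = S(t) / exp(-k_PB t), renormalized at the first time point.
Permanently bound molecules yield a flat corrected curve; transiently
binding factors can show power-law decay, quantified by a log-log linear
fit over a stated range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalCurve",
    "BleachModel",
    "PowerLawFit",
    "survival_curve",
    "fit_triple_exponential",
    "bleach_correct",
    "fit_power_law",
    "confidence_band",
]


@dataclass
class SurvivalCurve:
    """S(t) = fraction of tracks with duration >= t, on frame multiples."""

    times: np.ndarray  # seconds
    s: np.ndarray
    n_tracks: int
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None
    corrected: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class BleachModel:
    """Triple-exponential fit of a raw survival curve.

    ``k_pb`` = 1 / max(tau): the slowest component is read as
    photobleaching when the underlying binding outlives the observation.
    """

    amplitudes: np.ndarray
    taus: np.ndarray
    residual: float = np.nan
    # components holding under this share of the total amplitude are fit
    # artifacts, not kinetic scales; they are ignored when reading k_PB
    amplitude_floor: float = 0.05

    def _significant(self) -> np.ndarray:
        w = self.amplitudes / self.amplitudes.sum()
        sig = w >= self.amplitude_floor
        return sig if sig.any() else np.ones_like(sig, dtype=bool)

    @property
    def k_pb(self) -> float:
        return 1.0 / self.slowest_tau

    @property
    def slowest_tau(self) -> float:
        return float(np.max(self.taus[self._significant()]))


@dataclass
class PowerLawFit:
    exponent: float
    stderr: float
    fit_range: tuple[float, float]
    intercept: float = np.nan


def _durations(tracks_or_durations, frame_interval: float) -> np.ndarray:
    if len(tracks_or_durations) and isinstance(tracks_or_durations[0], Track):
        return np.array([t.duration(frame_interval) for t in tracks_or_durations])
    return np.asarray(tracks_or_durations, dtype=float)


def survival_curve(
    tracks: list[Track] | np.ndarray, frame_interval: float = 0.2
) -> SurvivalCurve:
    """Empirical survival of track durations (first-to-last frame span,
    bridged gaps counted as bound time). Also accepts raw durations."""
    durations = _durations(tracks, frame_interval)
    if len(durations) == 0:
        raise ValueError("no tracks supplied")
    times = np.unique(durations)
    s = np.array([(durations >= t).mean() for t in times])
    return SurvivalCurve(times=times, s=s, n_tracks=len(durations))


def _multi_exp(t, *params):
    k = len(params) // 2
    amps = np.array(params[:k])
    taus = np.array(params[k:])
    return np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)


def fit_triple_exponential(
    curve: SurvivalCurve, n_starts: int = 8, seed: int = 0
) -> BleachModel:
    """Weighted nonlinear least squares of a1 e^-t/tau1 + a2 e^-t/tau2 +
    a3 e^-t/tau3 to S(t), with multi-start over log-spaced tau seeds.

    Weights are 1/sqrt(n at risk) to stabilize the sparse tail. The slowest
    tau defines the bleaching rate. If two time constants converge within
    5% of each other the model is refit with one fewer component (warned).
    """
    t, s = curve.times, curve.s
    if len(np.unique(t)) < 4:
        raise ValueError("insufficient support for a triple-exponential fit")
    n_risk = np.maximum(curve.n_tracks * s, 1.0)
    sigma = 1.0 / np.sqrt(n_risk)
    rng = np.random.default_rng(seed)
    t_span = (max(t[0], 1e-3), max(t[-1], 1.0))

    def _fit(k: int):
        best = None
        seeds = np.geomspace(t_span[0], t_span[1] * 2, max(n_starts, k))
        for trial in range(n_starts):
            if trial == 0:
                taus0 = np.geomspace(t_span[0], t_span[1], k)
            else:
                taus0 = np.sort(rng.choice(seeds, k, replace=False) * np.exp(rng.normal(0, 0.3, k)))
            p0 = list(np.full(k, 1.0 / k)) + list(taus0)
            try:
                popt, _ = optimize.curve_fit(
                    _multi_exp, t, s, p0=p0, sigma=sigma,
                    bounds=([0] * k + [t_span[0] / 10] * k,
                            [2] * k + [t_span[1] * 10] * k),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = float(np.sum(((s - _multi_exp(t, *popt)) / sigma) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        return best

    k = 3
    while k >= 1:
        best = _fit(k)
        if best is None:
            raise RuntimeError(f"triple-exponential fit failed at k={k}")
        popt, resid = best
        order = np.argsort(popt[k:])
        taus = np.asarray(popt[k:])[order]
        amps = np.asarray(popt[:k])[order]
        # prune numerically vanished components before judging degeneracy
        keep = amps > 1e-2 * amps.sum()
        if keep.any():
            taus, amps = taus[keep], amps[keep]
        # time constants within a factor of two are not resolvable scales
        # in a survival fit; merge by refitting with one fewer component
        if len(taus) > 1 and np.any(taus[1:] / taus[:-1] < 2.0):
            logger.warning(
                "fit_triple_exponential: unresolvable time constants %s; "
                "refitting with %d components", taus, k - 1,
            )
            k -= 1
            continue
        return BleachModel(amplitudes=amps, taus=taus, residual=resid)
    raise RuntimeError("no exponential model could be fit")


def bleach_correct(curve: SurvivalCurve, k_pb: float) -> SurvivalCurve:
    """Photobleaching-corrected survival S_hat(t) = S(t) / exp(-k_PB t),
    renormalized to 1 at the first time point.

    Monotonicity is no longer guaranteed. Where the corrected standard
    error (binomial, amplified by the same factor) exceeds the corrected
    value the curve is truncated, since the exponential amplification there
    outgrows the information content.
    """
    if k_pb < 0:
        raise ValueError("k_PB must be >= 0")
    factor = np.exp(k_pb * curve.times)
    s_hat = curve.s * factor
    se = np.sqrt(np.maximum(curve.s * (1 - curve.s), 0) / curve.n_tracks) * factor
    valid = np.ones(len(s_hat), dtype=bool)
    with np.errstate(invalid="ignore"):
        bad = (se > s_hat) & (np.arange(len(s_hat)) > 0)
    if bad.any():
        cut = int(np.argmax(bad))
        valid[cut:] = False
        logger.info("bleach_correct: truncated at t=%.2f s (noise exceeds value)", curve.times[cut])
    s_hat = s_hat[valid]
    s_hat = s_hat / s_hat[0]
    return SurvivalCurve(
        times=curve.times[valid], s=s_hat, n_tracks=curve.n_tracks,
        corrected=True, meta={"k_pb": k_pb},
    )


def fit_power_law(
    curve: SurvivalCurve, fit_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """Least-squares line on log S vs log t: slope = exponent beta."""
    t, s = curve.times, curve.s
    if fit_range is None:
        fit_range = (float(t[t > 0].min()), float(t.max()))
    sel = (t >= fit_range[0]) & (t <= fit_range[1]) & (s > 0) & (t > 0)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 usable points in the fit range")
    res = stats.linregress(np.log(t[sel]), np.log(s[sel]))
    return PowerLawFit(
        exponent=float(res.slope), stderr=float(res.stderr),
        fit_range=fit_range, intercept=float(res.intercept),
    )


def confidence_band(
    tracks: list[Track] | np.ndarray,
    level: float = 0.99,
    n_boot: int = 500,
    seed: int = 0,
    frame_interval: float = 0.2,
    k_pb: float = 0.0,
) -> SurvivalCurve:
    """Percentile bootstrap band (over tracks) around the (optionally
    bleach-corrected) survival curve."""
    durations = _durations(tracks, frame_interval)
    if len(durations) < 30:
        logger.warning("confidence_band: fewer than 30 tracks; band unreliable")
    base = survival_curve(durations, frame_interval)
    if k_pb > 0:
        base = bleach_correct(base, k_pb)
    rng = np.random.default_rng(seed)
    times = base.times
    samples = np.empty((n_boot, len(times)))
    for b in range(n_boot):
        d = rng.choice(durations, size=len(durations), replace=True)
        s = np.array([(d >= t).mean() for t in times])
        if k_pb > 0:
            s = s * np.exp(k_pb * times)
            s = s / s[0] if s[0] > 0 else s
        samples[b] = s
    alpha = (1.0 - level) / 2.0
    base.band_low = np.quantile(samples, alpha, axis=0)
    base.band_high = np.quantile(samples, 1.0 - alpha, axis=0)
    base.meta["n_boot"] = n_boot
    base.meta["seed"] = seed
    return base
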