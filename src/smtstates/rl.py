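"""Richardson-Lucy deconvolution of the displacement distribution into MSDs.

The self part of the van Hove correlation G_s(r, tau) — the radial density
of 2D displacement magnitudes at lag tau — is modelled as a superposition
of Gaussian kernels q(r, M) = (1 / (pi M)) exp(-r^2 / M), where M is the
MSD of a sub-population. The mixing distribution P(M, tau) is recovered by
the multiplicative Richardson-Lucy update

    P[n+1](M) = P[n](M) * Int d^2 r  q(r, M) G_s(r) / G_s[n](r)

starting from P0(M) proportional to exp(-M / M0), with every iterate kept
non-negative and normalized. Minima of P(M) define MSD thresholds that
classify whole tracks into mobility groups (RL groups) at a reference lag
of 0.8 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelmin

from .tracks import Track

logger = logging.getLogger(__name__)

__all__ = [
    "VanHove",
    "MSDDistribution",
    "RLGroups",
    "van_hove",
    "rl_deconvolve",
    "find_minima",
    "classify_rl_groups",
]


@dataclass
class VanHove:
    """Radial displacement density at one lag, normalized so that
    2 pi * sum(r * G * dr) = 1."""

    tau: float
    bin_edges: np.ndarray
    density: np.ndarray  # G_s at bin centers
    n_displacements: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class MSDDistribution:
    """Weights P(M) on a log-spaced MSD grid (um^2), summing to 1."""

    m_grid: np.ndarray
    weights: np.ndarray
    tau: float
    m0: float
    n_iter: int
    kl_trace: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class RLGroups:
    """Per-track mobility groups from MSD-distribution minima.

    ``group`` holds 1-based labels: 1 below the first threshold, 2 between
    the first and second, 3 above, etc. Tracks too short for the lag are
    excluded (label 0) and counted in ``n_excluded``.
    """

    tau: float
    thresholds: np.ndarray
    track_ids: np.ndarray
    track_msd: np.ndarray
    group: np.ndarray
    n_excluded: int = 0


def van_hove(
    tracks: list[Track],
    tau: float,
    frame_interval: float = 0.2,
    n_bins: int = 100,
    r_max: float | None = None,
) -> VanHove:
    """Self van Hove correlation of 2D displacement magnitudes at lag tau.

    Displacements are time-averaged within tracks (all frame pairs at the
    exact lag). Bins are equal-width to ``r_max`` (default the 99.9th
    displacement percentile).
    """
    lag = tau / frame_interval
    if abs(lag - round(lag)) > 1e-9:
        raise ValueError(f"tau={tau} is not a multiple of the frame interval")
    lag = int(round(lag))
    disp = np.concatenate([t.displacements(lag) for t in tracks] or [[]])
    if len(disp) == 0:
        raise ValueError(f"no displacements at lag {tau} s")
    if r_max is None:
        r_max = max(float(np.percentile(disp, 99.9)), 1e-6)
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist, _ = np.histogram(disp, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    # radial density: counts / (N * 2 pi r dr) so that Int d^2 r G_s = 1
    n_in = hist.sum()
    g = hist / (n_in * 2.0 * np.pi * centers * widths)
    return VanHove(tau=tau, bin_edges=edges, density=g, n_displacements=int(len(disp)))


def _kernel_matrix(r: np.ndarray, m_grid: np.ndarray) -> np.ndarray:
    """q(r, M) = exp(-r^2 / M) / (pi M), shape (n_bins, n_M)."""
    return np.exp(-np.square(r)[:, None] / m_grid[None, :]) / (np.pi * m_grid[None, :])


def rl_deconvolve(
    vh: VanHove,
    m_grid: np.ndarray | None = None,
    m0: float | None = None,
    n_iter: int = 500,
    stop_tol: float = 1e-8,
    p_init: np.ndarray | None = None,
) -> MSDDistribution:
    """Recover the MSD mixing distribution by Richardson-Lucy iteration.

    ``m_grid`` defaults to 200 log-spaced points on [1e-4, 1] um^2; ``m0``
    (the scale of the exponential initial distribution) defaults to the
    mean MSD implied by the van Hove data. Iteration stops at ``n_iter`` or
    when the L1 change in P falls below ``stop_tol``. The KL divergence
    between the data and its reconstruction is recorded per iterate.
    """
    if m_grid is None:
        m_grid = np.geomspace(1e-4, 1.0, 200)
    m_grid = np.asarray(m_grid, dtype=float)
    r = vh.bin_centers
    area = 2.0 * np.pi * r * vh.bin_widths  # d^2 r weights per bin
    g_data = vh.density
    if m0 is None:
        # mean squared displacement under the empirical density
        m0 = float(np.sum(area * g_data * r**2))
        m0 = min(max(m0, m_grid[0]), m_grid[-1])
    q = _kernel_matrix(r, m_grid)
    if p_init is not None:
        p = np.asarray(p_init, dtype=float).copy()
        if p.shape != m_grid.shape or np.any(p < 0):
            raise ValueError("p_init must be non-negative and match m_grid")
    else:
        p = np.exp(-m_grid / m0)
    p /= p.sum()
    eps = np.finfo(float).eps
    kl_trace = []
    pos = g_data > 0
    it = 0
    for it in range(1, n_iter + 1):
        g_model = q @ p  # reconstruction at bin centers
        g_model = np.maximum(g_model, eps)
        ratio = g_data / g_model
        update = (area * ratio) @ q  # Int d^2r q(r, M) G/G_n
        p_new = p * update
        s = p_new.sum()
        if s <= 0:
            logger.warning("rl_deconvolve: degenerate update at iteration %d", it)
            break
        p_new /= s
        kl = float(np.sum(area[pos] * g_data[pos] * np.log(g_data[pos] / g_model[pos])))
        kl_trace.append(kl)
        if np.abs(p_new - p).sum() < stop_tol:
            p = p_new
            break
        p = p_new
    return MSDDistribution(
        m_grid=m_grid, weights=p, tau=vh.tau, m0=m0, n_iter=it,
        kl_trace=np.array(kl_trace),
    )


def find_minima(dist: MSDDistribution, smooth: int = 3) -> np.ndarray:
    """Interior local minima of the (smoothed) MSD distribution, as MSD
    thresholds in increasing order. Empty for unimodal distributions."""
    w = dist.weights
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        w = np.convolve(w, kernel, mode="same")
    idx = argrelmin(w)[0]
    # a valid valley separates two genuine modes: each side must carry a
    # peak of meaningful height that rises clearly above the valley floor
    thresholds = []
    floor = 0.05 * w.max()
    for i in idx:
        left_peak = w[: i + 1].max()
        right_peak = w[i:].max()
        if (
            left_peak >= floor
            and right_peak >= floor
            and left_peak >= 1.5 * w[i]
            and right_peak >= 1.5 * w[i]
        ):
            thresholds.append(dist.m_grid[i])
    if not thresholds:
        logger.info("find_minima: distribution is unimodal (single group)")
    return np.asarray(thresholds)


def classify_rl_groups(
    tracks: list[Track],
    thresholds: np.ndarray,
    tau: float = 0.8,
    frame_interval: float = 0.2,
) -> RLGroups:
    """Classify whole tracks by their time-averaged MSD at lag tau.

    Group 1: below the first threshold; group 2: between the first and
    second; higher groups above. Tracks without a displacement at the lag
    are excluded (group label 0).
    """
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if len(thresholds) and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    lag = int(round(tau / frame_interval))
    ids, msds, groups = [], [], []
    n_excluded = 0
    for t in tracks:
        m = t.msd_at_lag(lag)
        ids.append(t.track_id)
        msds.append(m)
        if np.isnan(m):
            groups.append(0)
            n_excluded += 1
        else:
            groups.append(int(np.searchsorted(thresholds, m) + 1))
    return RLGroups(
        tau=tau,
        thresholds=thresholds,
        track_ids=np.array(ids),
        track_msd=np.array(msds),
        group=np.array(groups),
        n_excluded=n_excluded,
    )
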