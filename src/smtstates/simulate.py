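"""Ground-truth simulation of multi-state switching diffusion under slow SMT.

Emulates the statistical structure of a HILO acquisition of chromatin-bound
molecules: Markov switching between low-mobility diffusive states at frame
boundaries, motion blur from the finite exposure, per-state static
localization noise, photobleaching, one-frame blinking gaps, and
defocalization of fast molecules out of the ~400 nm detection slab.

The reported (observed) position of a molecule in a frame is the average of
its true Brownian path over the exposure window plus independent Gaussian
noise per axis, so the displacement covariance of a constant-state track
matches the banded model used by the state classifier:

    var(dx)           = 2 D dt + 2 sigma^2 - 4 R D dt      (lag 0 band)
    cov(dx_i, dx_i+1) = -(sigma^2 - 2 R D dt)              (lag 1 band)

with R = exposure / (6 dt) the motion blur coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .acquisition import AcquisitionParams
from .tracks import Track

__all__ = [
    "SimStateSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_tracks",
    "render_movie",
    "simulate_dwell_times",
]


@dataclass(frozen=True)
class SimStateSpec:
    """One diffusive state of the generator.

    diffusion_coefficient in um^2/s, localization_sigma in um per coordinate,
    initial_fraction the probability of starting in this state.
    """

    diffusion_coefficient: float
    localization_sigma: float
    initial_fraction: float

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.localization_sigma < 0:
            raise ValueError("localization sigma must be >= 0")
        if not 0 <= self.initial_fraction <= 1:
            raise ValueError("initial_fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Full description of a synthetic SMT experiment.

    ``states`` are the chromatin-bound switching states; ``switch_matrix``
    holds per-frame Markov transition probabilities between them. A
    ``free_fraction`` of molecules instead diffuses freely with ``free_d``
    (1.8 um^2/s, typical of an unbound nuclear receptor) and is lost to
    defocalization almost immediately at a 200 ms interval. ``bleach_time``
    is the exponential photobleaching time constant 1/k_PB in seconds.
    """

    states: list[SimStateSpec]
    switch_matrix: np.ndarray | None = None
    free_fraction: float = 0.0
    free_d: float = 1.8
    free_sigma: float = 0.07
    bleach_time: float = np.inf
    blink_gap_prob: float = 0.0
    n_molecules: int = 100
    seed: int = 0
    min_track_len: int = 6
    n_blur_substeps: int = 10

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("at least one state required")
        fr = sum(s.initial_fraction for s in self.states)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"initial fractions sum to {fr}, expected 1")
        k = len(self.states)
        if self.switch_matrix is None:
            self.switch_matrix = np.eye(k)
        self.switch_matrix = np.asarray(self.switch_matrix, dtype=float)
        if self.switch_matrix.shape != (k, k):
            raise ValueError("switch_matrix must be K x K")
        if np.any(self.switch_matrix < 0) or not np.allclose(
            self.switch_matrix.sum(axis=1), 1.0
        ):
            raise ValueError("switch_matrix rows must be probabilities summing to 1")
        if not self.bleach_time > 0:
            raise ValueError("bleach_time must be positive")
        if not 0 <= self.free_fraction <= 1:
            raise ValueError("free_fraction must be in [0, 1]")
        if not 0 <= self.blink_gap_prob < 1:
            raise ValueError("blink_gap_prob must be in [0, 1)")
        if self.n_blur_substeps < 1:
            raise ValueError("n_blur_substeps must be >= 1")


@dataclass
class GroundTruth:
    """Per-molecule per-frame truth table plus the generating config.

    ``table`` columns: molecule_id, frame, x_um, y_um (exposure-averaged true
    position), z_um (mid-exposure), state (-1 for the free population),
    bleached, in_focus, observed.
    """

    table: pd.DataFrame
    config: SimulationConfig
    acq: AcquisitionParams
    seed: int = 0
    meta: dict = field(default_factory=dict)


def _categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Sample one category per row of a row-stochastic matrix."""
    c = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > c).sum(axis=1)


def simulate_tracks(
    config: SimulationConfig, acq: AcquisitionParams
) -> tuple[GroundTruth, list[Track]]:
    """Simulate switching-diffusion molecules and extract observed tracks.

    Returns the full ground truth and the list of tracks a perfect linker
    would produce: contiguous runs of observed localizations, bridging
    single missing frames as gaps, split wherever the molecule is lost for
    two or more frames, and discarding runs shorter than
    ``config.min_track_len`` localizations.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    nf = acq.n_frames
    dt = acq.frame_interval
    te = acq.exposure
    k = len(config.states)
    fy, fx = acq.field_size[0] * acq.pixel_size, acq.field_size[1] * acq.pixel_size
    half_z = acq.depth_of_focus / 2.0

    is_free = rng.random(n) < config.free_fraction
    fractions = np.array([s.initial_fraction for s in config.states])
    state = _categorical_rows(rng, np.tile(fractions, (n, 1)))
    state[is_free] = -1

    d_by_state = np.array([s.diffusion_coefficient for s in config.states])

    x = rng.uniform(0, fx, n)
    y = rng.uniform(0, fy, n)
    z = rng.uniform(-half_z, half_z, n)
    bleach_at = rng.exponential(config.bleach_time, n) if np.isfinite(
        config.bleach_time
    ) else np.full(n, np.inf)

    nsub = config.n_blur_substeps
    # sample times within exposure at substep midpoints; average -> motion blur
    records: dict[str, list] = {c: [] for c in (
        "molecule_id", "frame", "x_um", "y_um", "z_um",
        "state", "bleached", "in_focus", "slab_exit", "observed",
    )}
    z_prev = z.copy()
    d_prev = np.zeros(n)

    mol_ids = np.arange(n)
    for f in range(nf):
        d = np.where(state >= 0, d_by_state[np.clip(state, 0, None)], config.free_d)
        step_sd = np.sqrt(2.0 * d * (te / nsub))

        bx = np.zeros(n)
        by = np.zeros(n)
        cx, cy, cz = x.copy(), y.copy(), z.copy()
        # first sample half a substep in, then full substeps
        first_sd = np.sqrt(2.0 * d * (te / nsub / 2.0))
        cx += rng.normal(0, 1, n) * first_sd
        cy += rng.normal(0, 1, n) * first_sd
        cz += rng.normal(0, 1, n) * np.sqrt(2.0 * d * (te / 2.0))  # mid-exposure z
        for _ in range(nsub):
            bx += cx
            by += cy
            if _ < nsub - 1:
                cx += rng.normal(0, 1, n) * step_sd
                cy += rng.normal(0, 1, n) * step_sd
        bx /= nsub
        by /= nsub
        z_mid = cz

        t_frame = f * dt
        bleached = t_frame > bleach_at
        in_focus = np.abs(z_mid) <= half_z
        # absorbing-slab exit between the previous and current frame: either
        # endpoint outside, or a Brownian-bridge crossing of +/- half_z
        if f == 0:
            slab_exit = ~in_focus
        else:
            slab_exit = ~in_focus | (np.abs(z_prev) > half_z)
            inside = ~slab_exit & (d_prev > 0)
            if inside.any():
                var = 2.0 * d_prev[inside] * dt
                up = np.exp(-2.0 * (half_z - z_prev[inside]) * (half_z - z_mid[inside]) / var)
                dn = np.exp(-2.0 * (half_z + z_prev[inside]) * (half_z + z_mid[inside]) / var)
                crossed = rng.random(inside.sum()) < np.clip(up + dn, 0.0, 1.0)
                tmp = slab_exit[inside]
                tmp |= crossed
                slab_exit[inside] = tmp
        z_prev = z_mid.copy()
        d_prev = d.copy()
        blink = rng.random(n) < config.blink_gap_prob
        observed = in_focus & ~bleached & ~blink

        records["molecule_id"].append(mol_ids.copy())
        records["frame"].append(np.full(n, f))
        records["x_um"].append(bx)
        records["y_um"].append(by)
        records["z_um"].append(z_mid)
        records["state"].append(state.copy())
        records["bleached"].append(bleached)
        records["in_focus"].append(in_focus)
        records["slab_exit"].append(slab_exit)
        records["observed"].append(observed)

        # propagate true position from last blur sample to next frame start
        rem = dt - te * (nsub - 0.5) / nsub
        rem_sd = np.sqrt(2.0 * d * rem)
        x = cx + rng.normal(0, 1, n) * rem_sd
        y = cy + rng.normal(0, 1, n) * rem_sd
        z = z_mid + rng.normal(0, 1, n) * np.sqrt(2.0 * d * (dt - te / 2.0))

        # state switching at the frame boundary
        bound = state >= 0
        if bound.any() and k > 0:
            nxt = _categorical_rows(rng, config.switch_matrix[state[bound]])
            state[bound] = nxt

    table = pd.DataFrame({c: np.concatenate(v) for c, v in records.items()})
    table = table.sort_values(["molecule_id", "frame"]).reset_index(drop=True)

    # observed localization = blurred truth + static noise
    truth = GroundTruth(table=table, config=config, acq=acq, seed=config.seed)
    tracks = _extract_tracks(truth, rng)
    return truth, tracks


def _extract_tracks(truth: GroundTruth, rng: np.random.Generator) -> list[Track]:
    cfg = truth.config
    s_by_state = np.array([s.localization_sigma for s in cfg.states])
    tracks: list[Track] = []
    tid = 0
    for _, g in truth.table.groupby("molecule_id", sort=True):
        obs = g[g["observed"]]
        if obs.empty:
            continue
        frames = obs["frame"].to_numpy()
        sig = np.where(
            obs["state"].to_numpy() >= 0,
            s_by_state[np.clip(obs["state"].to_numpy(), 0, None)],
            cfg.free_sigma,
        )
        xs = obs["x_um"].to_numpy() + rng.normal(0, 1, len(obs)) * sig
        ys = obs["y_um"].to_numpy() + rng.normal(0, 1, len(obs)) * sig
        # split wherever >1 frame is missing (a single miss is a bridged
        # gap) or the molecule left the detection slab in between
        # (re-entering molecules start new tracks)
        exit_cum = g["slab_exit"].to_numpy().cumsum()
        exit_at_obs = exit_cum[g["observed"].to_numpy()]
        breaks = np.where(
            (np.diff(frames) > 2) | (np.diff(exit_at_obs) > 0)
        )[0] + 1
        for seg in np.split(np.arange(len(frames)), breaks):
            if len(seg) < cfg.min_track_len:
                continue
            tracks.append(
                Track(
                    track_id=tid,
                    frames=frames[seg],
                    x=xs[seg],
                    y=ys[seg],
                    meta={"molecule_id": int(g["molecule_id"].iloc[0])},
                )
            )
            tid += 1
    return tracks


def render_movie(
    truth: GroundTruth,
    acq: AcquisitionParams,
    psf_sigma: float = 0.11,
    photon_budget: float = 2000.0,
    background: float = 10.0,
    shot_noise: bool = True,
) -> np.ndarray:
    """Render a ground truth as a synthetic image stack (frames, ny, nx).

    Each observed molecule is drawn as an isotropic 2D Gaussian of width
    ``psf_sigma`` (um) integrated over pixels with ``photon_budget`` expected
    photons, on a flat ``background`` (photons/pixel); per-pixel Poisson shot
    noise is applied unless disabled. Molecules outside the field are
    clipped. Output is uint16.
    """
    ny, nx = acq.field_size
    px = acq.pixel_size
    stack = np.full((acq.n_frames, ny, nx), float(background))
    xe = np.arange(nx + 1) * px
    ye = np.arange(ny + 1) * px
    s = psf_sigma * np.sqrt(2.0)
    obs = truth.table[truth.table["observed"]]
    n_clipped = 0
    for f, g in obs.groupby("frame"):
        img = stack[int(f)]
        for xc, yc in zip(g["x_um"], g["y_um"]):
            if not (0 <= xc <= nx * px and 0 <= yc <= ny * px):
                n_clipped += 1
                continue
            cx = 0.5 * (special.erf((xe[1:] - xc) / s) - special.erf((xe[:-1] - xc) / s))
            cy = 0.5 * (special.erf((ye[1:] - yc) / s) - special.erf((ye[:-1] - yc) / s))
            img += photon_budget * np.outer(cy, cx)
    if shot_noise:
        rng = np.random.default_rng(truth.seed + 1)
        stack = rng.poisson(stack).astype(float)
    truth.meta["n_clipped"] = n_clipped
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


def simulate_dwell_times(
    law: str,
    params: dict,
    n: int,
    seed: int = 0,
    frame_interval: float = 0.2,
) -> np.ndarray:
    """Draw i.i.d. dwell times, discretized to whole frame multiples.

    Laws
    ----
    ``triple_exponential``
        params: ``amplitudes`` (mixture weights, renormalized) and ``taus``
        (time constants, seconds). Fewer than three components are allowed
        by passing shorter arrays.
    ``power_law``
        params: ``beta`` (survival exponent, < 0) and ``t_min`` (lower
        cutoff, seconds). Survival S(t) = (t / t_min)^beta for t >= t_min.
    """
    rng = np.random.default_rng(seed)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.array([])
    if law == "triple_exponential":
        amps = np.asarray(params["amplitudes"], dtype=float)
        taus = np.asarray(params["taus"], dtype=float)
        if len(amps) != len(taus) or np.any(taus <= 0) or np.any(amps < 0):
            raise ValueError("amplitudes/taus malformed")
        amps = amps / amps.sum()
        comp = rng.choice(len(amps), size=n, p=amps)
        t = rng.exponential(taus[comp])
    elif law == "power_law":
        beta = float(params["beta"])
        t_min = float(params["t_min"])
        if beta >= 0:
            raise ValueError("power-law survival exponent must be negative")
        if t_min <= 0:
            raise ValueError("power-law lower cutoff must be positive")
        # inverse transform: S(t) = (t/t_min)^beta  =>  t = t_min * U^(1/beta)
        t = t_min * rng.random(n) ** (1.0 / beta)
    else:
        raise ValueError(f"unknown dwell-time law: {law!r}")
    # whole frame intervals spanned; dwells shorter than one interval are
    # never observed and are dropped
    obs = np.floor(t / frame_interval) * frame_interval
    return obs[obs > 0]
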