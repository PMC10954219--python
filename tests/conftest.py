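"""Shared fixtures: synthetic acquisitions reused across test modules.

Expensive simulations and EM fits are session-scoped; all randomness is
seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from smtstates import (
    AcquisitionParams,
    EMOptions,
    SimStateSpec,
    SimulationConfig,
    assign_states,
    select_model,
    simulate_tracks,
    split_subtracks,
)

# EM schedule used in tests: fewer restarts and a looser absolute tolerance
# than the production defaults, sized for suites that fit in minutes
FAST_EM = EMOptions(n_reinit=4, n_perturb=8, tol=1e-5, max_iter=3000, seed=0)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    """Canonical acquisition: 200 ms interval, 10 ms exposure, 104 nm px."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def static_mix(acq):
    """Static 50/50 two-state mixture (no switching): D = 0.002 / 0.02
    um^2/s, sigma = 0.02 / 0.04 um — the regime of the two low-mobility
    chromatin states. Returns truth, tracks, sub-tracks and the fitted
    model selected over K = 1..3."""
    sim_acq = AcquisitionParams(n_frames=300, field_size=(200, 200))
    cfg = SimulationConfig(
        states=[SimStateSpec(0.002, 0.02, 0.5), SimStateSpec(0.02, 0.04, 0.5)],
        n_molecules=150,
        seed=42,
    )
    truth, tracks = simulate_tracks(cfg, sim_acq)
    subs = split_subtracks(tracks)
    model = select_model(subs, sim_acq, k_max=3, em_opts=FAST_EM)
    return {
        "acq": sim_acq, "config": cfg, "truth": truth, "tracks": tracks,
        "subtracks": subs, "model": model, "assignment": assign_states(model),
    }


@pytest.fixture(scope="session")
def switching_sim(acq):
    """Two-state switching dynamics (stay probability 0.95 per frame, mean
    state dwell ~4 s) with a thin fast population, emulating a histone-like
    acquisition."""
    sim_acq = AcquisitionParams(n_frames=400, field_size=(200, 200))
    cfg = SimulationConfig(
        states=[SimStateSpec(0.002, 0.02, 0.5), SimStateSpec(0.02, 0.04, 0.5)],
        switch_matrix=np.array([[0.95, 0.05], [0.05, 0.95]]),
        free_fraction=0.05,
        bleach_time=13.03,
        blink_gap_prob=0.02,
        n_molecules=600,
        seed=7,
    )
    truth, tracks = simulate_tracks(cfg, sim_acq)
    subs = split_subtracks(tracks)
    model = select_model(subs, sim_acq, k_max=3, em_opts=FAST_EM)
    return {
        "acq": sim_acq, "config": cfg, "truth": truth, "tracks": tracks,
        "subtracks": subs, "model": model, "assignment": assign_states(model),
    }


def subtrack_true_states(fixture) -> np.ndarray:
    """Majority true state of each sub-track, looked up from ground truth.

    The honest generating truth for mixture fractions is the realized
    sub-track population (defocalization biases it away from the molecule
    split)."""
    truth = fixture["truth"].table
    state_lookup = {
        (int(m), int(f)): int(s)
        for m, f, s in zip(truth["molecule_id"], truth["frame"], truth["state"])
    }
    track_mol = {t.track_id: t.meta["molecule_id"] for t in fixture["tracks"]}
    out = []
    for sub in fixture["subtracks"]:
        mol = track_mol[sub.track_id]
        states = [state_lookup[(mol, int(f))] for f in sub.frames]
        out.append(np.bincount(np.asarray(states) + 1).argmax() - 1)
    return np.asarray(out)
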