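"""End-to-end orchestration of the mobility-state analysis.

``run_pipeline`` drives: simulate (or load tracks) -> sub-track EM state
classification -> assignment and minor-state filtering -> ensemble MSD,
exploration diameters and unbound fraction -> transition matrix with
permutation significance -> Richardson-Lucy MSD distribution and RL track
groups -> per-group photobleaching-corrected survival. Every stochastic
stage receives a sub-seed derived from the global seed, and every output
file records the config hash and seed in a manifest.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .acquisition import AcquisitionParams
from .mobility import ensemble_msd, exploration_diameter, jump_thresholds, unbound_fraction
from .rl import classify_rl_groups, find_minima, rl_deconvolve, van_hove
from .simulate import SimStateSpec, SimulationConfig, simulate_tracks
from .states import (
    EMOptions,
    assign_states,
    filter_minor_states,
    localization_precision,
    select_model,
    split_subtracks,
)
from .survival import bleach_correct, fit_triple_exponential, survival_curve
from .tracks import Track
from .transitions import permutation_test, state_sequences

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; see module docstring for stages."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    simulation: SimulationConfig | None = None
    tracks_path: str | None = None
    k_max: int = 15
    em: EMOptions = field(default_factory=EMOptions)
    dpp_cut: float = 0.2
    population_floor: float = 0.05
    min_sequence: int = 3
    n_perm: int = 1000
    rl_tau: float = 0.8
    seed: int = 0
    out_dir: str = "smtstates_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        acq = AcquisitionParams(**d.get("acquisition", {}))
        sim = None
        if "simulation" in d:
            s = dict(d["simulation"])
            s["states"] = [SimStateSpec(**st) for st in s["states"]]
            if "switch_matrix" in s and s["switch_matrix"] is not None:
                s["switch_matrix"] = np.asarray(s["switch_matrix"], dtype=float)
            sim = SimulationConfig(**s)
        em = EMOptions(**d.get("em", {}))
        kwargs = {
            k: d[k]
            for k in (
                "tracks_path", "k_max", "dpp_cut", "population_floor",
                "min_sequence", "n_perm", "rl_tau", "seed", "out_dir",
            )
            if k in d
        }
        return cls(acquisition=acq, simulation=sim, em=em, **kwargs)


def _sub_seed(seed: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2**31)
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full analysis; returns a machine-readable summary dict.

    With ``write_outputs`` the stage tables (tracks, model summary,
    assignments, MSD curves, transition matrices, MSD distribution, survival
    curves) and a manifest are written under ``config.out_dir``.
    """
    acq = config.acquisition
    out = Path(config.out_dir)
    artifacts: list[str] = []
    summary: dict = {"seed": config.seed}

    # --- input tracks -----------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        sim.seed = _sub_seed(config.seed, "simulate")
        truth, tracks = simulate_tracks(sim, acq)
        summary["n_molecules"] = sim.n_molecules
    elif config.tracks_path:
        tracks = sio.read_tracks(config.tracks_path)
        truth = None
    else:
        raise ValueError("config needs either a simulation block or tracks_path")
    if not tracks:
        raise RuntimeError("stage 'tracks': no tracks to analyze")
    summary["n_tracks"] = len(tracks)

    # --- state classification --------------------------------------------
    subtracks = split_subtracks(tracks)
    if not subtracks:
        raise RuntimeError("stage 'classify': no 7-frame sub-tracks")
    summary["n_subtracks"] = len(subtracks)
    em = EMOptions(**{**config.em.__dict__, "seed": _sub_seed(config.seed, "em")})
    model = select_model(subtracks, acq, k_max=config.k_max, em_opts=em)
    assignment = assign_states(model, config.dpp_cut)
    model_f, assignment_f = filter_minor_states(model, assignment, config.population_floor)
    r = acq.motion_blur_coefficient
    dt = acq.frame_interval
    summary["model"] = {
        "k": model.k,
        "bic": model.bic,
        "log_likelihood": model.log_likelihood,
        "states": [
            {"d_um2_s": s.d, "sigma_um": s.sigma, "fraction": s.fraction}
            for s in model.states
        ],
        "kept_states": assignment_f.kept_states,
        "population_fractions": [s.fraction for s in model_f.states],
    }

    # --- mobility ---------------------------------------------------------
    curves = ensemble_msd(subtracks, assignment_f, frame_interval=dt)
    lag_12 = int(round(1.2 / dt)) - 1
    summary["msd"] = {}
    for key, c in curves.items():
        entry = {"lag_s": c.lag_times.tolist(), "msd_um2": c.msd.tolist(), "sem": c.sem.tolist()}
        if 0 <= lag_12 < len(c.msd) and np.isfinite(c.msd[lag_12]):
            entry["exploration_diameter_um"] = exploration_diameter(float(c.msd[lag_12]))
        summary["msd"][str(key)] = entry
    thr = jump_thresholds(tracks)
    summary["bound_thresholds"] = {"r_min_um": thr.r_min, "r_max_um": thr.r_max}
    summary["unbound_fraction"] = unbound_fraction(tracks, thr)

    # --- transitions ------------------------------------------------------
    seqs, seq_report = state_sequences(subtracks, assignment_f, config.min_sequence)
    summary["sequences"] = seq_report
    if seqs:
        trans = permutation_test(seqs, n_perm=config.n_perm, seed=_sub_seed(config.seed, "perm"))
        summary["transitions"] = {
            "counts": trans.counts.tolist(),
            "probabilities": trans.probabilities.tolist(),
            "significance": trans.significance.tolist(),
        }
    else:
        trans = None
        logger.warning("no sequences with >= %d sub-tracks", config.min_sequence)

    # --- RL deconvolution and groups --------------------------------------
    try:
        vh = van_hove(tracks, config.rl_tau, frame_interval=dt)
        dist = rl_deconvolve(vh)
        thresholds = find_minima(dist)
        groups = classify_rl_groups(tracks, thresholds, tau=config.rl_tau, frame_interval=dt)
        summary["rl"] = {
            "tau_s": config.rl_tau,
            "thresholds_um2": thresholds.tolist(),
            "group_counts": {
                int(g): int((groups.group == g).sum()) for g in np.unique(groups.group)
            },
        }
    except ValueError as exc:
        raise RuntimeError(f"stage 'rl': {exc}") from exc

    # --- survival ---------------------------------------------------------
    surv_all = survival_curve(tracks, dt)
    summary["survival"] = {"n_tracks": surv_all.n_tracks}
    try:
        bleach = fit_triple_exponential(surv_all)
        summary["survival"]["slowest_tau_s"] = bleach.slowest_tau
        summary["survival"]["k_pb"] = bleach.k_pb
        per_group = {}
        for g in (1, 2):
            sel = [t for t, lab in zip(tracks, groups.group) if lab == g]
            if len(sel) >= 10:
                sc = bleach_correct(survival_curve(sel, dt), bleach.k_pb)
                per_group[g] = {"times": sc.times.tolist(), "s_hat": sc.s.tolist()}
        summary["survival"]["rl_groups"] = sorted(per_group)
    except (RuntimeError, ValueError) as exc:
        logger.warning("survival fitting skipped: %s", exc)
        bleach = None
        per_group = {}

    # --- outputs ----------------------------------------------------------
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        cfg_dict = _config_dict(config)
        chash = sio.config_hash(cfg_dict)
        summary["config_hash"] = chash

        sio.write_tracks(tracks, out / "tracks.csv")
        artifacts.append("tracks.csv")
        pd.DataFrame(
            [
                {"state": i + 1, "d_um2_s": s.d, "sigma_um": s.sigma,
                 "fraction": s.fraction, "bic": model.bic}
                for i, s in enumerate(model.states)
            ]
        ).to_csv(out / "model_summary.csv", index=False)
        artifacts.append("model_summary.csv")
        pd.DataFrame(
            {
                "track_id": [s.track_id for s in subtracks],
                "ordinal": [s.ordinal for s in subtracks],
                "state": assignment.state + 1,
                "dpp": assignment.dpp,
                "retained": assignment.retained,
                "post_filter_state": (
                    assignment_f.post_filter_state + 1
                    if assignment_f.post_filter_state is not None else None
                ),
            }
        ).to_csv(out / "assignments.csv", index=False)
        artifacts.append("assignments.csv")
        msd_rows = []
        for key, c in curves.items():
            for lt, m, se, nn in zip(c.lag_times, c.msd, c.sem, c.n):
                msd_rows.append({"state": key, "lag_s": lt, "msd_um2": m, "sem": se, "n": nn})
        pd.DataFrame(msd_rows).to_csv(out / "msd_curves.csv", index=False)
        artifacts.append("msd_curves.csv")
        if trans is not None:
            pd.DataFrame(trans.counts).to_csv(out / "transition_counts.csv", index=False)
            pd.DataFrame(trans.probabilities).to_csv(out / "transition_probabilities.csv", index=False)
            pd.DataFrame(trans.significance).to_csv(out / "transition_significance.csv", index=False)
            artifacts += [
                "transition_counts.csv", "transition_probabilities.csv",
                "transition_significance.csv",
            ]
        pd.DataFrame({"m_um2": dist.m_grid, "weight": dist.weights}).to_csv(
            out / "msd_distribution.csv", index=False
        )
        artifacts.append("msd_distribution.csv")
        pd.DataFrame(
            {"track_id": groups.track_ids, "msd_at_tau": groups.track_msd, "rl_group": groups.group}
        ).to_csv(out / "rl_groups.csv", index=False)
        artifacts.append("rl_groups.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        artifacts.append("summary.json")
        manifest = {"config_hash": chash, "seed": config.seed, "artifacts": artifacts}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        sio.save_config(cfg_dict, out / "config.yaml")
    return summary


def _config_dict(config: RunConfig) -> dict:
    d: dict = {
        "acquisition": config.acquisition.__dict__ | {"field_size": list(config.acquisition.field_size)},
        "k_max": config.k_max,
        "em": config.em.__dict__,
        "dpp_cut": config.dpp_cut,
        "population_floor": config.population_floor,
        "min_sequence": config.min_sequence,
        "n_perm": config.n_perm,
        "rl_tau": config.rl_tau,
        "seed": config.seed,
        "out_dir": str(config.out_dir),
    }
    if config.tracks_path:
        d["tracks_path"] = str(config.tracks_path)
    if config.simulation is not None:
        s = config.simulation
        d["simulation"] = {
            "states": [st.__dict__ for st in s.states],
            "switch_matrix": np.asarray(s.switch_matrix).tolist(),
            "free_fraction": s.free_fraction,
            "free_d": s.free_d,
            "bleach_time": float(s.bleach_time),
            "blink_gap_prob": s.blink_gap_prob,
            "n_molecules": s.n_molecules,
        }
    return d
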