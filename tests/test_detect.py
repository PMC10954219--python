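"""Detection, thresholding, linking, and tracking-error diagnostics."""

import numpy as np
import pytest

from smtstates import (
    AcquisitionParams,
    Localization,
    SimStateSpec,
    SimulationConfig,
    render_movie,
    simulate_tracks,
)
from smtstates.detect import (
    TrackingConfig,
    choose_intensity_threshold,
    detect_particles,
    estimate_misconnection_rate,
    filter_stack,
    link_tracks,
    second_neighbor_diagnostic,
)

CFG = TrackingConfig()


def _loc(frame, x, y, snr=10.0):
    return Localization(frame=frame, x=x, y=y, intensity=100.0, snr=snr)


# --- filtering -------------------------------------------------------------

def test_filter_constant_image_is_zeroed_by_tophat():
    stack = np.full((2, 32, 32), 50.0)
    out = filter_stack(stack)
    assert np.allclose(out, 0.0, atol=1e-9)


def test_filter_preserves_peak_location():
    stack = np.full((1, 32, 32), 5.0)
    stack[0, 12, 20] = 200.0
    out = filter_stack(stack)
    assert np.unravel_index(np.argmax(out[0]), out[0].shape) == (12, 20)


def test_filter_improves_spot_snr():
    """Peak-over-background-SD of a noisy rendered spot does not degrade."""
    acq = AcquisitionParams(n_frames=4, field_size=(48, 48))
    cfg = SimulationConfig(states=[SimStateSpec(0.0, 0.0, 1.0)], n_molecules=1, seed=1)
    truth, _ = simulate_tracks(cfg, acq)
    stack = render_movie(truth, acq, photon_budget=800, background=30).astype(float)

    def snr(img):
        bg = np.percentile(img, 50)
        noise = 1.4826 * np.median(np.abs(img - bg))
        return (img.max() - bg) / noise

    filt = filter_stack(stack)
    assert np.mean([snr(f) for f in filt]) >= np.mean([snr(f) for f in stack])


def test_filter_rejects_oversized_kernel():
    with pytest.raises(ValueError):
        filter_stack(np.zeros((1, 8, 8)), tophat_radius=10)


# --- detection -------------------------------------------------------------

def test_detect_recovers_subpixel_position_noiselessly():
    acq = AcquisitionParams(n_frames=1, field_size=(32, 32))
    cfg = SimulationConfig(states=[SimStateSpec(0.0, 0.0, 1.0)], n_molecules=1, seed=3)
    truth, _ = simulate_tracks(cfg, acq)
    stack = render_movie(truth, acq, photon_budget=5000, background=5, shot_noise=False)
    locs = detect_particles(stack.astype(float), threshold=50.0, cfg=CFG)
    assert len(locs) == 1
    row = truth.table[truth.table["observed"]].iloc[0]
    err = np.hypot(locs[0].x - row.x_um, locs[0].y - row.y_um)
    assert err < 0.05 * CFG.pixel_size


def test_detect_empty_frame_returns_nothing():
    assert detect_particles(np.zeros((2, 16, 16)), threshold=1.0, cfg=CFG) == []


def test_detect_two_separated_spots():
    frame = np.zeros((1, 40, 40))
    yy, xx = np.mgrid[0:40, 0:40]
    for cx, cy in [(10.3, 15.2), (20.3, 15.2)]:  # 10 px apart
        frame[0] += 500 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / 2.0)
    locs = detect_particles(frame, threshold=50.0, cfg=CFG)
    assert len(locs) == 2
    got = sorted((l.x / CFG.pixel_size, l.y / CFG.pixel_size) for l in locs)
    for (gx, gy), (tx, ty) in zip(got, [(10.8, 15.7), (20.8, 15.7)]):
        assert np.hypot(gx - tx, gy - ty) < 0.2  # pixel-center convention


def test_threshold_selection_recovers_rendered_spots():
    """The SNR-driven threshold recovers >= 95% of interior in-focus spots."""
    acq = AcquisitionParams(n_frames=15, field_size=(64, 64))
    cfg = SimulationConfig(states=[SimStateSpec(0.005, 0.0, 1.0)], n_molecules=12, seed=11)
    truth, _ = simulate_tracks(cfg, acq)
    stack = render_movie(truth, acq, photon_budget=5000, background=10)
    filt = filter_stack(stack)
    thr = choose_intensity_threshold(filt, CFG, n_grid=25)
    locs = detect_particles(filt, thr, CFG)
    margin = 3 * acq.pixel_size
    lim = 64 * acq.pixel_size - margin
    obs = truth.table[truth.table["observed"]]
    obs = obs[(obs.x_um > margin) & (obs.x_um < lim) & (obs.y_um > margin) & (obs.y_um < lim)]
    # drop spots with an overlapping neighbor (closer than ~the PSF extent):
    # two merged PSFs are not resolvable by single-emitter fitting
    resolvable = []
    for _, row in obs.iterrows():
        others = obs[(obs.frame == row.frame) & (obs.molecule_id != row.molecule_id)]
        dmin = np.hypot(others.x_um - row.x_um, others.y_um - row.y_um).min() if len(others) else np.inf
        resolvable.append(dmin > 0.5)
    obs = obs[np.asarray(resolvable)]
    n_hit = 0
    for _, row in obs.iterrows():
        d = [
            np.hypot(l.x - row.x_um, l.y - row.y_um)
            for l in locs
            if l.frame == row.frame
        ]
        if d and min(d) < acq.pixel_size:
            n_hit += 1
    assert n_hit / len(obs) >= 0.95


def test_threshold_selection_fails_loudly_when_unattainable():
    """With an unreachable SNR floor, no threshold can satisfy the rule and
    the failure reports the best achievable low-SNR fraction."""
    acq = AcquisitionParams(n_frames=2, field_size=(32, 32))
    cfg = SimulationConfig(states=[SimStateSpec(0.0, 0.0, 1.0)], n_molecules=3, seed=2)
    truth, _ = simulate_tracks(cfg, acq)
    stack = filter_stack(render_movie(truth, acq, photon_budget=2000, background=10).astype(float))
    strict = TrackingConfig(snr_floor=1e9)
    with pytest.raises(RuntimeError, match="fraction"):
        choose_intensity_threshold(stack, strict, n_grid=5)


# --- linking ---------------------------------------------------------------

def test_link_immobile_molecule_ten_frames():
    locs = [_loc(f, 1.0, 1.0) for f in range(10)]
    tracks = link_tracks(locs, CFG)
    assert len(tracks) == 1 and len(tracks[0]) == 10


def test_link_bridges_single_missing_frame():
    locs = [_loc(f, 1.0, 1.0) for f in range(10) if f != 5]
    tracks = link_tracks(locs, CFG)
    assert len(tracks) == 1
    t = tracks[0]
    assert len(t) == 9
    assert t.gap_flags[np.where(t.frames == 6)[0][0]]


def test_link_splits_on_two_missing_frames():
    locs = [_loc(f, 1.0, 1.0) for f in list(range(7)) + list(range(9, 16))]
    tracks = link_tracks(locs, CFG)
    assert len(tracks) == 2


def test_link_rejects_duplicate_coordinates():
    locs = [_loc(0, 1.0, 1.0), _loc(0, 1.0, 1.0)]
    with pytest.raises(ValueError, match="duplicate"):
        link_tracks(locs, CFG)


def test_link_respects_max_jump():
    locs = [_loc(f, 0.05 * f, 1.0) for f in range(6)]  # 50 nm steps: linked
    locs += [_loc(f, 3.0 + 0.5 * f, 3.0) for f in range(6)]  # 500 nm: broken
    tracks = link_tracks(locs, CFG)
    for t in tracks:
        d = np.hypot(np.diff(t.x), np.diff(t.y))
        assert np.all(d <= CFG.max_jump + 1e-12)


def test_link_matches_ground_truth_identity():
    """Sparse immobile molecules: >= 99% of links join the same molecule."""
    acq = AcquisitionParams(n_frames=40, field_size=(128, 128))
    cfg = SimulationConfig(
        states=[SimStateSpec(0.001, 0.02, 1.0)], n_molecules=50, seed=21
    )
    truth, true_tracks = simulate_tracks(cfg, acq)
    rng = np.random.default_rng(0)
    locs = []
    origin = []
    for t in true_tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            locs.append(_loc(int(f), x, y))
            origin.append(t.meta["molecule_id"])
    order = rng.permutation(len(locs))
    locs = [locs[i] for i in order]
    origin = [origin[i] for i in order]
    key = {(l.frame, round(l.x, 9), round(l.y, 9)): o for l, o in zip(locs, origin)}
    tracks = link_tracks(locs, CFG)
    good = bad = 0
    for t in tracks:
        mols = [key[(int(f), round(x, 9), round(y, 9))] for f, x, y in zip(t.frames, t.x, t.y)]
        for a, b in zip(mols[:-1], mols[1:]):
            good += a == b
            bad += a != b
    assert good / (good + bad) >= 0.99


def test_link_invariant_to_input_order():
    rng = np.random.default_rng(5)
    locs = []
    for m in range(8):
        x0, y0 = rng.uniform(1, 9, 2)
        locs += [_loc(f, x0 + rng.normal(0, 0.02), y0 + rng.normal(0, 0.02)) for f in range(8)]
    t1 = link_tracks(locs, CFG)
    t2 = link_tracks([locs[i] for i in rng.permutation(len(locs))], CFG)
    s1 = sorted(tuple(zip(t.frames, np.round(t.x, 9))) for t in t1)
    s2 = sorted(tuple(zip(t.frames, np.round(t.x, 9))) for t in t2)
    assert s1 == s2


# --- diagnostics -----------------------------------------------------------

def test_second_neighbor_single_molecule_is_zero():
    locs = [_loc(f, 1.0, 1.0) for f in range(5)]
    assert second_neighbor_diagnostic(locs) == 0.0


def test_second_neighbor_two_close_molecules_is_one():
    locs = []
    for f in range(5):
        locs += [_loc(f, 1.0, 1.0), _loc(f, 1.2, 1.0)]  # 0.2 um apart
    assert second_neighbor_diagnostic(locs) == 1.0


def test_second_neighbor_low_at_realistic_density():
    """At 10-40 localizations per frame over a nucleus-sized field the
    ambiguous fraction is of order a percent."""
    rng = np.random.default_rng(9)
    locs = []
    for f in range(50):
        n = rng.integers(10, 40)
        for x, y in rng.uniform(0, 13.0, (n, 2)):  # ~13 um field
            locs.append(_loc(f, x, y))
    frac = second_neighbor_diagnostic(locs)
    assert frac < 0.1


def test_misconnection_single_molecule_is_zero():
    locs = [_loc(f, 1.0, 1.0) for f in range(17)]
    assert estimate_misconnection_rate(locs, window=0.192, fast_interval=0.012) == 0.0


def test_misconnection_constructed_half_rate():
    """A second molecule crosses the radius in half the windows: E = 0.5."""
    locs = []
    span = 16  # fast frames per window at 12 ms
    for w in range(10):
        base = w * (span + 10)
        x0 = 2.0 * w  # blocks are spatially separated: windows never span blocks
        for f in range(base, base + span + 1):
            locs.append(_loc(f, x0, 1.0))
        if w % 2 == 0:  # intruder at a mid-window frame only
            locs.append(_loc(base + span // 2, x0 + 0.1, 1.0))
    e = estimate_misconnection_rate(locs, window=0.192, fast_interval=0.012)
    assert abs(e - 0.5) < 1e-12


def test_misconnection_requires_qualifying_windows():
    with pytest.raises(RuntimeError):
        estimate_misconnection_rate([_loc(0, 1.0, 1.0)])


def test_max_jump_unit_contract():
    """4 pixels at 104 nm = 416 nm, shared by linker and diagnostics."""
    assert CFG.max_jump == pytest.approx(4 * CFG.pixel_size)
    import inspect

    from smtstates import detect

    assert inspect.signature(detect.second_neighbor_diagnostic).parameters["radius"].default == 0.416
    assert inspect.signature(detect.estimate_misconnection_rate).parameters["radius"].default == 0.416
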