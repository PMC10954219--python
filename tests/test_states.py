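"""Sub-track splitting, covariance-band algebra, banded likelihood, EM
fitting with BIC selection, posterior assignment, and state filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from smtstates import (
    AcquisitionParams,
    DiffusiveState,
    EMOptions,
    SimStateSpec,
    SimulationConfig,
    StateModel,
    assign_states,
    bands_to_params,
    covariance_bands,
    filter_minor_states,
    fit_states,
    localization_precision,
    select_model,
    simulate_tracks,
    split_subtracks,
    subtrack_loglik,
)
from smtstates.states import SubTrack, _banded_cov, _em_run, _SubTrackArrays
from smtstates.tracks import Track

from conftest import FAST_EM, subtrack_true_states

ACQ = AcquisitionParams()
R = ACQ.motion_blur_coefficient
DT = ACQ.frame_interval


def _track(n, track_id=0, seed=0, d=0.005, sigma=0.02):
    rng = np.random.default_rng(seed)
    step = np.sqrt(2 * d * DT)
    x = np.cumsum(rng.normal(0, step, n)) + rng.normal(0, sigma, n)
    y = np.cumsum(rng.normal(0, step, n)) + rng.normal(0, sigma, n)
    return Track(track_id=track_id, frames=np.arange(n), x=x, y=y)


@pytest.mark.parametrize("n,expected", [(6, 0), (7, 1), (20, 2), (21, 3)])
def test_split_subtracks_window_counts(n, expected):
    subs = split_subtracks([_track(n)])
    assert len(subs) == expected
    for s in subs:
        assert len(s.frames) == 7 and len(s.dx) == 6


def test_split_subtracks_are_ordered_and_disjoint():
    subs = split_subtracks([_track(21)])
    assert [s.ordinal for s in subs] == [0, 1, 2]
    covered = np.concatenate([s.frames for s in subs])
    assert len(np.unique(covered)) == 21


# --- covariance bands ------------------------------------------------------

def test_covariance_bands_at_zero():
    b = covariance_bands(0.0, 0.0, R, DT)
    assert (b.band0, b.band1, b.band2) == (0.0, 0.0, 0.0)


def test_covariance_bands_worked_values():
    b = covariance_bands(0.01, 0.02, 1 / 120, 0.2)
    assert b.band0 == pytest.approx(0.0047333, abs=1e-7)
    assert b.band1 == pytest.approx(-0.0003667, abs=1e-7)


@given(
    d=st.floats(1e-5, 1.0),
    sigma=st.floats(1e-4, 0.2),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_bands_round_trip_is_identity(d, sigma):
    b = covariance_bands(d, sigma, R, DT)
    d2, s2 = bands_to_params(b.band0, b.band1, R, DT)
    assert d2 == pytest.approx(d, rel=1e-9)
    assert s2 == pytest.approx(sigma, rel=1e-9)


def test_bands_inverse_clamps_inadmissible():
    d, s = bands_to_params(-0.01, 0.0, R, DT)
    assert d == 0.0 and s == 0.0


# --- likelihood ------------------------------------------------------------

def test_banded_loglik_equals_dense_gaussian_oracle():
    """The banded evaluation must agree with a dense multivariate-normal
    density to 1e-10 on random admissible parameters."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        d = 10 ** rng.uniform(-3, -1)
        sigma = rng.uniform(0.005, 0.06)
        lags = rng.choice([1, 1, 1, 2], size=6)
        sub = SubTrack(
            track_id=0, ordinal=0, frames=np.concatenate([[0], np.cumsum(lags)]),
            x=rng.normal(0, 0.05, 7), y=rng.normal(0, 0.05, 7),
        )
        state = DiffusiveState(d=d, sigma=sigma, fraction=1.0)
        got = subtrack_loglik(sub, state, ACQ)
        c = _banded_cov(d, sigma, R, DT, lags)
        want = (
            stats.multivariate_normal.logpdf(sub.dx, mean=np.zeros(6), cov=c)
            + stats.multivariate_normal.logpdf(sub.dy, mean=np.zeros(6), cov=c)
        )
        assert got == pytest.approx(want, abs=1e-10)


def test_loglik_concentrates_as_sigma_shrinks_on_zero_displacements():
    sub = SubTrack(0, 0, np.arange(7), np.zeros(7), np.zeros(7))
    lls = [
        subtrack_loglik(sub, DiffusiveState(d=0.0, sigma=s, fraction=1.0), ACQ)
        for s in (0.05, 0.01, 0.002)
    ]
    assert lls[0] < lls[1] < lls[2]


def test_matched_state_has_higher_average_loglik():
    acq = AcquisitionParams(n_frames=400, field_size=(400, 400))
    cfg = SimulationConfig(states=[SimStateSpec(0.02, 0.04, 1.0)], n_molecules=60, seed=2)
    _, tracks = simulate_tracks(cfg, acq)
    subs = split_subtracks(tracks)[:2000]
    arr = _SubTrackArrays(subs)
    match = DiffusiveState(0.02, 0.04, 1.0)
    mismatch = DiffusiveState(0.002, 0.02, 1.0)
    ll = arr.loglik([match, mismatch], R, DT)
    assert ll[:, 0].mean() > ll[:, 1].mean()


def test_nonpositive_definite_covariance_is_reported():
    """An unphysical blur coefficient makes the band matrix indefinite;
    the error must name the offending state."""
    sub = SubTrack(0, 0, np.arange(7), np.zeros(7), np.zeros(7))
    arr = _SubTrackArrays([sub])
    with pytest.raises(ValueError, match="state 0"):
        arr.loglik([DiffusiveState(d=0.01, sigma=0.0, fraction=1.0)], 10.0, DT)


# --- EM fitting ------------------------------------------------------------

def test_fit_single_state_recovers_parameters(static_mix):
    acq = AcquisitionParams(n_frames=300, field_size=(200, 200))
    cfg = SimulationConfig(states=[SimStateSpec(0.005, 0.03, 1.0)], n_molecules=230, seed=3)
    _, tracks = simulate_tracks(cfg, acq)
    subs = split_subtracks(tracks)
    assert len(subs) >= 2000
    model = fit_states(subs, 1, acq, FAST_EM)
    assert model.states[0].d == pytest.approx(0.005, rel=0.10)
    assert model.states[0].sigma == pytest.approx(0.03, rel=0.10)


def test_fit_two_state_mixture_recovers_both_states(static_mix):
    model = static_mix["model"]
    assert model.k == 2
    d_true = (0.002, 0.02)
    sig_true = (0.02, 0.04)
    for st_fit, d0, s0 in zip(model.states, d_true, sig_true):
        assert st_fit.d == pytest.approx(d0, rel=0.15)
        assert st_fit.sigma == pytest.approx(s0, rel=0.20)
    # mixture fractions against the realized sub-track truth
    true_states = subtrack_true_states(static_mix)
    f0 = (true_states == 0).mean()
    assert model.states[0].fraction == pytest.approx(f0, abs=0.05)


def test_em_is_invariant_to_duplicating_the_dataset():
    acq = AcquisitionParams(n_frames=150, field_size=(200, 200))
    cfg = SimulationConfig(states=[SimStateSpec(0.01, 0.03, 1.0)], n_molecules=40, seed=4)
    _, tracks = simulate_tracks(cfg, acq)
    subs = split_subtracks(tracks)
    opts = EMOptions(n_reinit=1, n_perturb=0, tol=1e-8, max_iter=4000, seed=0)
    m1 = fit_states(subs, 1, acq, opts)
    m2 = fit_states(subs + subs, 1, acq, opts)
    assert m2.states[0].d == pytest.approx(m1.states[0].d, rel=1e-6)
    assert m2.states[0].sigma == pytest.approx(m1.states[0].sigma, rel=1e-6)


def test_em_posteriors_normalized_and_loglik_nondecreasing(static_mix):
    model = static_mix["model"]
    assert np.allclose(model.gamma.sum(axis=1), 1.0, atol=1e-12)
    increments = np.diff(model.ll_trace)
    assert np.all(increments > -1e-6 * np.abs(model.ll_trace[:-1]))


def test_select_model_single_state_data_picks_k1():
    acq = AcquisitionParams(n_frames=200, field_size=(200, 200))
    cfg = SimulationConfig(states=[SimStateSpec(0.008, 0.03, 1.0)], n_molecules=80, seed=5)
    _, tracks = simulate_tracks(cfg, acq)
    subs = split_subtracks(tracks)
    model = select_model(subs, acq, k_max=3, em_opts=FAST_EM)
    assert model.k == 1


def test_select_model_identical_states_collapse_to_k1():
    acq = AcquisitionParams(n_frames=200, field_size=(200, 200))
    cfg = SimulationConfig(
        states=[SimStateSpec(0.008, 0.03, 0.5), SimStateSpec(0.008, 0.03, 0.5)],
        n_molecules=80,
        seed=6,
    )
    _, tracks = simulate_tracks(cfg, acq)
    subs = split_subtracks(tracks)
    model = select_model(subs, acq, k_max=2, em_opts=FAST_EM)
    assert model.k == 1


def test_select_model_two_state_data_picks_k2(static_mix):
    assert static_mix["model"].k == 2


# --- assignment and filtering ----------------------------------------------

def _model_from_gamma(gamma):
    gamma = np.asarray(gamma, dtype=float)
    k = gamma.shape[1]
    states = [DiffusiveState(d=0.001 * (i + 1), sigma=0.02, fraction=1 / k) for i in range(k)]
    return StateModel(
        states=states, log_likelihood=0.0, bic=0.0,
        gamma=np.asarray(gamma, dtype=float), n_subtracks=len(gamma),
    )


def test_assignment_worked_examples():
    model = _model_from_gamma([[0.9, 0.05, 0.05], [0.5, 0.4, 0.1], [1.0, 0.0, 0.0]])
    a = assign_states(model)
    assert list(a.state) == [0, 0, 0]
    assert a.dpp == pytest.approx([0.85, 0.1, 1.0])
    assert list(a.retained) == [True, False, True]


def test_assignment_tie_breaks_to_lower_mobility_state():
    model = _model_from_gamma([[0.5, 0.5, 0.0]])
    a = assign_states(model)
    assert a.state[0] == 0


def test_filter_minor_states_drops_small_state():
    rng = np.random.default_rng(0)
    n = 1000
    labels = rng.choice(3, n, p=[0.55, 0.42, 0.03])
    gamma = np.full((n, 3), 0.05)
    gamma[np.arange(n), labels] = 0.9
    model = _model_from_gamma(gamma)
    a = assign_states(model)
    model_f, a_f = filter_minor_states(model, a, floor=0.05)
    assert a_f.kept_states == [0, 1]
    assert set(np.unique(a_f.post_filter_state[a.state == 2])) == {-1}
    assert sum(s.fraction for s in model_f.states) == pytest.approx(1.0)


def test_filter_minor_states_keeps_balanced_pair():
    gamma = np.tile([[1.0, 0.0], [0.0, 1.0]], (50, 1))
    model = _model_from_gamma(gamma)
    a = assign_states(model)
    model_f, a_f = filter_minor_states(model, a)
    assert a_f.kept_states == [0, 1]
    assert [s.fraction for s in model_f.states] == pytest.approx([0.5, 0.5])


def test_filter_minor_states_rejects_degenerate_fit():
    # 25 states each holding 4% of sub-tracks
    n, k = 1000, 25
    gamma = np.zeros((n, k))
    gamma[np.arange(n), np.arange(n) % k] = 1.0
    model = _model_from_gamma(gamma)
    with pytest.raises(RuntimeError, match="floor"):
        filter_minor_states(model, assign_states(model), floor=0.05)


def test_spurious_minor_state_is_removed_from_two_state_mixture(static_mix):
    """An H2B-like mixture with a thin spurious component keeps exactly
    the two major states after the 5% floor."""
    model = static_mix["model"]
    a = assign_states(model)
    model_f, a_f = filter_minor_states(model, a)
    assert len(model_f.states) == 2


# --- localization precision ------------------------------------------------

def test_localization_precision_immobile_limit():
    sigma = 0.025
    assert localization_precision(2 * sigma**2, 0.0, R, DT) == pytest.approx(sigma)


def test_localization_precision_round_trip():
    b = covariance_bands(0.01, 0.02, R, DT)
    assert localization_precision(b.band0, 0.01, R, DT) == pytest.approx(0.02, rel=1e-9)


def test_localization_precision_rejects_negative_bracket():
    with pytest.raises(ValueError, match="bracket"):
        localization_precision(1e-5, 0.05, R, DT)


def test_fitted_localization_precision_matches_truth(static_mix):
    """Recovered sigma via the band inversion lands within 20% of the
    simulated 20 / 40 nm noise levels."""
    model = static_mix["model"]
    for st_fit, sig_true in zip(model.states, (0.02, 0.04)):
        b = covariance_bands(st_fit.d, st_fit.sigma, R, DT)
        sigma_k = localization_precision(b.band0, st_fit.d, R, DT)
        assert sigma_k == pytest.approx(sig_true, rel=0.20)
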