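"""Hybrid simulator: driver laws, count statistics, autocorrelation."""

import numpy as np
import pytest
from scipy import stats

from txnoise import (
    CountData, ModelKind, ModelParams, ParamValidationError, SimProtocol,
    autocorrelation, empirical_autocorrelation, params_from_regime,
    sample_cir_path, sample_gou_path, simulate_cells, simulate_trajectories,
    steady_state_moments,
)
from conftest import max_moment_zscore

P_MID = params_from_regime(0.5, 0.5, 10.0, 1.2, 0.7)


def _thinning_reference(p, t_end, rng):
    """Independent oracle: Ogata thinning for the gamma-OU-driven reaction
    system (no flux inversion).  Returns final counts and the event log."""
    K = rng.gamma(p.a / p.kappa, p.theta)
    t = 0.0
    next_jump = rng.exponential(1.0 / p.a)
    xN = xM = 0
    events = []
    while True:
        # K only decays between jumps, so it bounds the transcription rate
        lam_max = K + p.beta * xN + p.gamma_ * xM
        dt = rng.exponential(1.0 / lam_max) if lam_max > 0 else np.inf
        t_prop = t + dt
        if t_prop >= next_jump:
            K = K * np.exp(-p.kappa * (next_jump - t))
            t = next_jump
            K += rng.exponential(p.theta)
            next_jump = t + rng.exponential(1.0 / p.a)
            if t >= t_end:
                break
            continue
        if t_prop >= t_end:
            break
        K_at = K * np.exp(-p.kappa * (t_prop - t))
        lam = K_at + p.beta * xN + p.gamma_ * xM
        if rng.random() < lam / lam_max:
            u = rng.random() * lam
            if u < K_at:
                xN += 1
                events.append(("transcribe", t_prop))
            elif u < K_at + p.beta * xN:
                xN -= 1
                xM += 1
                events.append(("splice", t_prop))
            else:
                xM -= 1
                events.append(("degrade", t_prop))
        K = K_at
        t = t_prop
    return xN, xM, events


def test_seed_determinism_bit_identical():
    for model in (ModelKind.GOU, ModelKind.CIR):
        proto = SimProtocol(n_reps=200, seed=9)
        a = simulate_cells(model, P_MID, proto)
        b = simulate_cells(model, P_MID, proto)
        assert np.array_equal(a.nascent, b.nascent)
        assert np.array_equal(a.mature, b.mature)


def test_gou_path_stationary_gamma_law():
    p = P_MID
    horizon = 3.0 / p.kappa * 5000
    path = sample_gou_path(p, horizon, seed=5)
    ts = np.linspace(5.0 / p.kappa, horizon, 5000)
    Ks = path.value(ts)
    assert Ks.mean() == pytest.approx(p.mean_rate, rel=0.05)
    ks = stats.kstest(
        Ks[::2], "gamma", args=(p.mixture_shape, 0, p.theta)
    )
    assert ks.pvalue > 0.01
    assert np.all(Ks >= 0)


def test_cir_path_stationary_law_and_autocovariance():
    p = P_MID
    dt = 3.0 / p.kappa
    path = sample_cir_path(p, horizon=dt * 10_000, dt=dt, seed=6)
    vals = path.values[1:]
    ks = stats.kstest(vals, "gamma", args=(p.mixture_shape, 0, p.theta))
    assert ks.pvalue > 0.01
    # exact transitions at any step: lag-1 autocorrelation is e^{-kappa dt}
    fine = sample_cir_path(p, horizon=0.3 / p.kappa * 20_000, dt=0.3 / p.kappa, seed=7)
    v = fine.values
    r1 = np.corrcoef(v[:-1], v[1:])[0, 1]
    assert r1 == pytest.approx(np.exp(-p.kappa * 0.3 / p.kappa), abs=0.03)
    assert np.all(v >= 0)


def test_vanishing_drive_gives_zero_counts():
    p = ModelParams(kappa=1.0, theta=1.0, a=1e-12, beta=1.2, gamma_=0.7)
    cd = simulate_cells(ModelKind.GOU, p, SimProtocol(n_reps=50, seed=1))
    assert cd.nascent.sum() == 0 and cd.mature.sum() == 0


def test_gou_counts_match_thinning_oracle():
    """The Lambert-W flux inversion agrees with an independent thinning
    simulation of the same process (moment comparison at small n)."""
    p = P_MID
    rng = np.random.default_rng(12)
    t_end = 15.0 / min(p.beta, p.gamma_)
    ref_n, ref_m = [], []
    for _ in range(1200):
        xN, xM, _ = _thinning_reference(p, t_end, rng)
        ref_n.append(xN)
        ref_m.append(xM)
    cd = simulate_cells(ModelKind.GOU, p, SimProtocol(n_reps=1200, seed=13))
    for ref, got in [(np.array(ref_n), cd.nascent), (np.array(ref_m), cd.mature)]:
        se = np.sqrt(ref.var() / ref.size + got.var() / got.size)
        assert abs(ref.mean() - got.mean()) < 4 * se


def test_species_conservation_in_event_log():
    """Every mature molecule was previously nascent: cumulative splice
    count never exceeds cumulative transcription, degradation never
    exceeds splicing."""
    p = P_MID
    rng = np.random.default_rng(3)
    _, _, events = _thinning_reference(p, 30.0, rng)
    n_tr = n_sp = n_de = 0
    for kind, _t in events:
        if kind == "transcribe":
            n_tr += 1
        elif kind == "splice":
            n_sp += 1
            assert n_sp <= n_tr
        else:
            n_de += 1
            assert n_de <= n_sp
    assert n_tr > 0


@pytest.mark.parametrize("model", [ModelKind.GOU, ModelKind.CIR])
def test_simulated_moments_match_closed_forms(model):
    cd = simulate_cells(model, P_MID, SimProtocol(n_reps=4000, seed=21))
    assert max_moment_zscore(cd, steady_state_moments(P_MID)) < 4.0


def test_cir_counts_invariant_to_grid_refinement():
    """Halving the CIR driver step leaves count statistics unchanged at
    the Monte Carlo level (the trapezoidal flux is converged)."""
    from txnoise.simulate import default_cir_dt

    p = P_MID
    dt = default_cir_dt(p)
    a = simulate_cells(ModelKind.CIR, p, SimProtocol(n_reps=3000, seed=31, dt_cir=dt))
    b = simulate_cells(ModelKind.CIR, p, SimProtocol(n_reps=3000, seed=32, dt_cir=dt / 2))
    for xa, xb in [(a.nascent, b.nascent), (a.mature, b.mature)]:
        se = np.sqrt(xa.var() / xa.size + xb.var() / xb.size)
        assert abs(xa.mean() - xb.mean()) < 3 * se


def test_autocorrelation_matches_closed_forms_for_both_models():
    """Empirical R(tau) from recorded trajectories tracks the closed-form
    curves, and the two SDE models agree with each other (the moment
    identity extends to autocorrelations)."""
    ests = {}
    for model, seed in [(ModelKind.GOU, 41), (ModelKind.CIR, 42)]:
        lags, xN, xM = simulate_trajectories(
            ModelKind(model), P_MID, SimProtocol(n_reps=2500, seed=seed),
            n_lags=10,
        )
        sel = np.array([0.0, lags[3], lags[6]])
        for sp, traj in (("nascent", xN), ("mature", xM)):
            est = empirical_autocorrelation(traj, lags, sel)
            ests[(model, sp)] = est
            theo = autocorrelation(P_MID, sp, sel)
            assert est[0] == pytest.approx(1.0, abs=1e-9)
            assert np.max(np.abs(est - theo)) < 0.06
    for sp in ("nascent", "mature"):
        assert np.max(np.abs(
            ests[(ModelKind.GOU, sp)] - ests[(ModelKind.CIR, sp)]
        )) < 0.08


def test_lag_bounds_and_protocol_validation():
    lags = np.linspace(0, 2, 5)
    traj = np.random.default_rng(0).poisson(4.0, (50, 5)).astype(float)
    with pytest.raises(ParamValidationError):
        empirical_autocorrelation(traj, lags, [3.0])
    with pytest.raises(ParamValidationError):
        SimProtocol(n_reps=0, seed=1)
    with pytest.raises(ParamValidationError):
        CountData(np.array([1, -2]), np.array([0, 0]))


def test_short_equilibration_warns():
    with pytest.warns(UserWarning, match="equilibration"):
        simulate_cells(
            ModelKind.GOU, P_MID, SimProtocol(n_reps=5, seed=2, t_ss=0.5)
        )
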