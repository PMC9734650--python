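"""Generating-function solver: closed forms, ODE oracles, iFFT recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

from txnoise import (
    GridSpec, ModelKind, ModelParams, ParamValidationError, joint_pmf,
    closed_form_pmf, default_grid, log_pgf_cir, log_pgf_gou, marginal_pmf,
    model_moments, params_from_regime, sample_counts_from_pmf,
    steady_state_moments, tv_distance, u0_gou_closed_form,
)
from txnoise.gf import _phi_cir_vec, _phi_gou_vec


def _ode_u0(u_N, u_M, p, s_grid, riccati=False):
    """Independent oracle: integrate the characteristic ODE cascade with
    scipy's adaptive solver (real/imaginary parts stacked)."""
    def rhs(s, y):
        U2 = y[0] + 1j * y[1]
        U1 = y[2] + 1j * y[3]
        U0 = y[4] + 1j * y[5]
        d2 = -p.gamma_ * U2
        d1 = p.beta * (U2 - U1)
        d0 = p.kappa * (U1 - U0)
        if riccati:
            d0 = d0 + p.theta * U0 * U0
        return [d2.real, d2.imag, d1.real, d1.imag, d0.real, d0.imag]

    y0 = [u_M.real, u_M.imag, u_N.real, u_N.imag, 0.0, 0.0]
    sol = integrate.solve_ivp(
        rhs, (0.0, s_grid[-1]), y0, t_eval=s_grid, rtol=1e-11, atol=1e-12,
        method="DOP853",
    )
    return sol.y[4] + 1j * sol.y[5]


def test_gou_characteristic_coefficients_example():
    """Direct substitution: u_M=1, beta=2, gamma=1, kappa=3, u_N=0 -> A2=3."""
    p = ModelParams(kappa=3, theta=1, a=1, beta=2, gamma_=1)
    sol = u0_gou_closed_form(0.0, 1.0, p)
    assert sol.A2 == pytest.approx(3.0)
    assert sol.A0 == pytest.approx(-(sol.A1 + sol.A2))
    assert sol.u0(0.0) == pytest.approx(0.0, abs=1e-14)


def test_zero_boundary_data_gives_identically_zero_flow():
    p = ModelParams(kappa=3, theta=1, a=1, beta=2, gamma_=1)
    sol = u0_gou_closed_form(0.0, 0.0, p)
    assert sol.A0 == sol.A1 == sol.A2 == 0.0
    assert np.allclose(sol.u0(np.linspace(0, 5, 11)), 0.0)


def test_gou_closed_form_matches_ode_oracle():
    """The three-exponential U0 agrees with adaptive ODE integration of the
    characteristic cascade to 1e-8 for random boundary data on the disc."""
    rng = np.random.default_rng(42)
    s_grid = np.linspace(0.0, 8.0, 25)
    for _ in range(5):
        p = ModelParams(
            kappa=rng.uniform(0.3, 5), theta=rng.uniform(0.2, 3),
            a=rng.uniform(0.2, 3), beta=rng.uniform(0.3, 3),
            gamma_=rng.uniform(0.3, 3),
        )
        ang_n, ang_m = rng.uniform(0, 2 * np.pi, 2)
        u_N = np.exp(1j * ang_n) - 1.0
        u_M = np.exp(1j * ang_m) - 1.0
        sol = u0_gou_closed_form(u_N, u_M, p)
        oracle = _ode_u0(u_N, u_M, p, s_grid)
        assert np.max(np.abs(sol.u0(s_grid) - oracle)) < 1e-8


def test_cir_riccati_integration_matches_adaptive_oracle():
    """The fixed-step RK4 phi integral agrees with an adaptive solver that
    carries Int U0 ds as an extra ODE state."""
    p = ModelParams(kappa=2.0, theta=3.0, a=1.5, beta=1.2, gamma_=0.7)
    rng = np.random.default_rng(3)
    smax = 28.0 / min(p.kappa, p.beta, p.gamma_)

    def rhs(s, y):
        U2 = y[0] + 1j * y[1]
        U1 = y[2] + 1j * y[3]
        U0 = y[4] + 1j * y[5]
        d2 = -p.gamma_ * U2
        d1 = p.beta * (U2 - U1)
        d0 = p.kappa * (U1 - U0) + p.theta * U0 * U0
        return [d2.real, d2.imag, d1.real, d1.imag, d0.real, d0.imag,
                U0.real, U0.imag]

    for _ in range(3):
        u_N = np.exp(1j * rng.uniform(0, 2 * np.pi)) - 1.0
        u_M = np.exp(1j * rng.uniform(0, 2 * np.pi)) - 1.0
        phi = log_pgf_cir(u_N, u_M, p)
        y0 = [u_M.real, u_M.imag, u_N.real, u_N.imag, 0.0, 0.0, 0.0, 0.0]
        sol = integrate.solve_ivp(
            rhs, (0.0, smax), y0, rtol=1e-11, atol=1e-13, method="DOP853"
        )
        oracle = p.mean_rate * (sol.y[6, -1] + 1j * sol.y[7, -1])
        # the graded RK4 scheme targets ~1e-6 relative accuracy
        assert abs(phi - oracle) < 2e-6 * (1.0 + abs(oracle))


@pytest.mark.parametrize("fn", [log_pgf_gou, log_pgf_cir])
def test_log_pgf_normalization(fn):
    p = ModelParams(kappa=1.9, theta=4.4, a=4.4, beta=1.2, gamma_=0.7)
    assert abs(fn(0.0, 0.0, p)) < 1e-12


@pytest.mark.parametrize("fn", [log_pgf_gou, log_pgf_cir])
def test_log_pgf_derivatives_reproduce_moments(fn):
    """d(phi)/du_N at 0 is mu_N = <K>/beta; the mixed second derivative is
    Cov(X_N, X_M); checked by central finite differences."""
    p = ModelParams(kappa=1.9, theta=4.4, a=4.4, beta=1.2, gamma_=0.7)
    m = steady_state_moments(p)
    # second-order backward stencils: the PGF is defined on |1+u| <= 1, so
    # all evaluation points sit inside the disc (u <= 0)
    h = 1e-3
    w = np.array([1.5, -2.0, 0.5])  # derivative weights at u = 0, -h, -2h
    vals_n = np.array([fn(-i * h, 0.0, p).real for i in range(3)])
    d_n = (w @ vals_n) / h
    assert d_n == pytest.approx(m.mu_N, rel=1e-4)
    grid_vals = np.array(
        [[fn(-i * h, -j * h, p).real for j in range(3)] for i in range(3)]
    )
    cross = (w @ grid_vals @ w) / (h * h)
    assert cross == pytest.approx(m.cov_NM, rel=1e-3)


def test_arguments_off_unit_disc_rejected():
    p = ModelParams(kappa=1, theta=1, a=1, beta=1.2, gamma_=0.7)
    with pytest.raises(ParamValidationError):
        log_pgf_gou(0.5, 0.0, p)


def test_constitutive_pmf_is_exact_product_of_poissons():
    p = ModelParams(kappa=1, theta=1, a=1, beta=1, gamma_=1)  # <K> = 1
    pmf = joint_pmf(ModelKind.CONSTITUTIVE, p, GridSpec(n_max=12, m_max=12))
    assert pmf.probs[0, 0] == pytest.approx(np.exp(-2.0), rel=1e-14)
    expected = np.outer(
        stats.poisson.pmf(np.arange(13), 1.0),
        stats.poisson.pmf(np.arange(13), 1.0),
    )
    assert np.allclose(pmf.probs, expected, rtol=1e-13)


def test_mixture_marginals_are_negative_binomial():
    p = ModelParams(kappa=0.5, theta=2.0, a=2.5, beta=1.2, gamma_=0.7)
    pmf = closed_form_pmf(ModelKind.MIXTURE, p)
    alpha = p.mixture_shape
    for species, rate in (("nascent", p.beta), ("mature", p.gamma_)):
        marg = marginal_pmf(pmf, species)
        succ = 1.0 / (1.0 + p.theta / rate)  # NB success probability
        expected = stats.nbinom.pmf(np.arange(marg.size), alpha, succ)
        assert np.max(np.abs(marg - expected)) < 1e-9


def test_mixture_pmf_matches_quadrature_over_rate_oracle():
    """Brute-force oracle: integrate the product-Poisson PMF against the
    gamma rate density; agrees with the iFFT mixture PMF to 1e-6."""
    p = ModelParams(kappa=0.5, theta=2.0, a=2.5, beta=1.2, gamma_=0.7)
    pmf = closed_form_pmf(ModelKind.MIXTURE, p)
    alpha = p.mixture_shape
    gam = stats.gamma(alpha, scale=p.theta)
    for (i, j) in [(0, 0), (1, 2), (4, 3), (8, 10)]:
        val, _ = integrate.quad(
            lambda K: (
                stats.poisson.pmf(i, K / p.beta)
                * stats.poisson.pmf(j, K / p.gamma_)
                * gam.pdf(K)
            ),
            0, np.inf, limit=200,
        )
        assert pmf.probs[i, j] == pytest.approx(val, abs=1e-6, rel=1e-6)


@pytest.mark.parametrize(
    "model", [ModelKind.GOU, ModelKind.CIR, ModelKind.MIXTURE, ModelKind.BURSTY]
)
def test_pmf_normalization_and_moment_agreement(model):
    """Every solved PMF is normalized and reproduces the closed-form
    means/variances/covariance to 1e-4 relative."""
    p = params_from_regime(0.5, 0.6, 8.0, 1.2, 0.7)
    pmf = joint_pmf(model, p)
    assert pmf.probs.sum() == pytest.approx(1.0, abs=1e-6)
    assert np.all(pmf.probs >= 0)
    m = model_moments(model, p)
    emp = pmf.moments()
    assert emp["mu_N"] == pytest.approx(m.mu_N, rel=1e-4)
    assert emp["mu_M"] == pytest.approx(m.mu_M, rel=1e-4)
    assert emp["var_N"] == pytest.approx(m.var_N, rel=1e-4)
    assert emp["var_M"] == pytest.approx(m.var_M, rel=1e-4)
    assert emp["cov_NM"] == pytest.approx(m.cov_NM, rel=1e-3, abs=1e-6)


def test_cir_small_gain_agrees_with_gou():
    """As theta -> 0 both SDE models approach the constitutive solution, so
    their PMFs coincide to o(theta)."""
    p = ModelParams(kappa=1.5, theta=1e-3, a=8e3, beta=1.2, gamma_=0.7)
    pg = joint_pmf(ModelKind.GOU, p)
    pc = joint_pmf(ModelKind.CIR, p)
    assert tv_distance(pg.probs, pc.probs) < 1e-4


def test_marginals_sum_to_joint_total():
    p = params_from_regime(0.5, 0.6, 8.0, 1.2, 0.7)
    pmf = joint_pmf(ModelKind.GOU, p)
    for sp in ("nascent", "mature"):
        assert marginal_pmf(pmf, sp).sum() == pytest.approx(
            pmf.probs.sum(), rel=1e-12
        )
    uniform = pmf.probs * 0 + 1.0 / pmf.probs.size
    j2 = type(pmf)(uniform, pmf.model, pmf.params, pmf.grid)
    assert np.allclose(marginal_pmf(j2, "nascent"), 1.0 / pmf.probs.shape[0])


def test_default_grid_scales_with_moments():
    p_small = params_from_regime(0.5, 0.2, 2.0, 1.2, 0.7)
    p_big = params_from_regime(0.5, 0.9, 30.0, 1.2, 0.7)
    g_small = default_grid(ModelKind.GOU, p_small)
    g_big = default_grid(ModelKind.GOU, p_big)
    assert g_big.n_max > g_small.n_max
    assert g_big.m_max > g_small.m_max
    with pytest.raises(ParamValidationError):
        GridSpec(n_max=1, m_max=10)


def test_count_sampling_is_seeded_and_on_grid():
    p = params_from_regime(0.5, 0.6, 8.0, 1.2, 0.7)
    pmf = joint_pmf(ModelKind.GOU, p)
    n1, m1 = sample_counts_from_pmf(pmf, 500, np.random.default_rng(5))
    n2, m2 = sample_counts_from_pmf(pmf, 500, np.random.default_rng(5))
    assert np.array_equal(n1, n2) and np.array_equal(m1, m2)
    assert n1.max() <= pmf.grid.n_max and m1.max() <= pmf.grid.m_max
    with pytest.raises(ParamValidationError):
        sample_counts_from_pmf(pmf, 0, np.random.default_rng(5))


def test_conjugate_symmetry_gives_real_pmf():
    """Imaginary parts of the recovered PMF vanish to round-off before
    clipping (checked indirectly: solver raises if they exceed 1e-8)."""
    p = params_from_regime(0.85, 0.85, 10.0, 1.2, 0.7)
    pmf = joint_pmf(ModelKind.GOU, p)
    assert np.isrealobj(pmf.probs)
    assert pmf.probs.min() >= 0.0
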