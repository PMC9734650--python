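"""Likelihoods, fitting, Bayes factors, Akaike weights."""

import numpy as np
import pytest

from txnoise import (
    CountData, FitResult, ModelKind, ModelParams, ParamValidationError,
    PMFCache, PriorSpec, akaike_weights, likelihood_ratio, log10_bayes_factor,
    loglik, mle_fit, params_from_regime, posterior_sample, sample_dataset,
)
from txnoise.inference import LOG10, grid_posterior, log_evidence

P_UNIT = ModelParams(kappa=1, theta=1, a=1, beta=1, gamma_=1)


def test_single_cell_constitutive_loglik():
    """One cell at (0,0) under the unit constitutive model: log e^{-2}."""
    d = CountData(np.array([0]), np.array([0]))
    assert loglik(d, ModelKind.CONSTITUTIVE, P_UNIT) == pytest.approx(-2.0)


def test_loglik_additivity_under_duplication():
    rng = np.random.default_rng(0)
    d = CountData(rng.poisson(1.0, 40), rng.poisson(1.0, 40))
    d2 = CountData(np.tile(d.nascent, 2), np.tile(d.mature, 2))
    ll = loglik(d, ModelKind.CONSTITUTIVE, P_UNIT)
    assert loglik(d2, ModelKind.CONSTITUTIVE, P_UNIT) == pytest.approx(2 * ll)


def test_marginal_data_modes_consistent_with_joint_grid():
    cache = PMFCache()
    p = params_from_regime(0.5, 0.6, 8.0, 1.2, 0.7)
    d = sample_dataset(ModelKind.GOU, p, 200, np.random.default_rng(1), cache)
    ll_n = loglik(d, ModelKind.GOU, p, cache=cache, data_mode="nascent_only")
    ll_m = loglik(d, ModelKind.GOU, p, cache=cache, data_mode="mature_only")
    ll_j = loglik(d, ModelKind.GOU, p, cache=cache)
    # marginal likelihoods bound the joint from above given positive
    # dependence is ignored; at least check finiteness and ordering scale
    assert np.isfinite([ll_n, ll_m, ll_j]).all()
    assert ll_j <= ll_n + 0.0  # joint cannot beat one marginal alone


def test_constitutive_mle_matches_closed_form():
    """MLE of the constant rate matches the closed-form estimator
    K_hat = (mean_N + mean_M) / (1/beta + 1/gamma) within 3 SE."""
    beta, gamma_ = 1.0, 1.7
    p_true = ModelParams(kappa=1, theta=1, a=10.0, beta=beta, gamma_=gamma_)
    rng = np.random.default_rng(2)
    d = sample_dataset(ModelKind.CONSTITUTIVE, p_true, 5000, rng)
    space = PriorSpec(
        bounds={"a": (-1, 3)},
        fixed={"kappa": 1.0, "theta": 1.0, "beta": beta, "gamma_": gamma_},
    )
    fit = mle_fit(d, ModelKind.CONSTITUTIVE, space, seed=3)
    k_hat = (d.nascent.mean() + d.mature.mean()) / (1 / beta + 1 / gamma_)
    se = np.sqrt(10.0 / 5000 / (1 / beta + 1 / gamma_))
    assert fit.converged
    assert abs(fit.params_hat.a - k_hat) < 3 * se


def test_fixing_all_parameters_returns_them_unchanged():
    d = CountData(np.array([1, 0, 2]), np.array([0, 1, 1]))
    space = PriorSpec(
        bounds={},
        fixed={"kappa": 1.0, "theta": 1.0, "a": 1.0, "beta": 1.0, "gamma_": 1.0},
    )
    fit = mle_fit(d, ModelKind.CONSTITUTIVE, space, seed=0)
    assert fit.params_hat == P_UNIT
    assert fit.loglik == pytest.approx(
        loglik(d, ModelKind.CONSTITUTIVE, P_UNIT)
    )


def test_gou_parameter_recovery_with_known_rates():
    """With beta, gamma and <K> known, the fitted (kappa, theta) land
    within the posterior's 95% region around the truth."""
    beta, gamma_, K = 1.0, 1.7, 10.0
    p = params_from_regime(0.5, 0.8, K, beta, gamma_)
    cache = PMFCache()
    d = sample_dataset(ModelKind.GOU, p, 1000, np.random.default_rng(4), cache)
    prior = PriorSpec.default(beta, gamma_, mean_rate=K)
    fit = mle_fit(d, ModelKind.GOU, prior, seed=5, cache=cache, n_restarts=2)
    gp = grid_posterior(d, ModelKind.GOU, prior, n_grid=15, cache=cache)
    assert fit.converged
    # the continuum optimum must be at least as good as the best grid node
    ll_fit = loglik(d, ModelKind.GOU, fit.params_hat, cache=cache)
    ll_grid_max = gp["logpost"].max() + (
        loglik(d, ModelKind.GOU, prior.to_params(gp["map"]), cache=cache)
        - gp["logpost"].max()
    )
    assert ll_fit >= ll_grid_max - 0.1
    # and the fit lands within the posterior spread of the truth
    x_fit = np.log10([fit.params_hat.kappa, fit.params_hat.theta])
    x_true = np.log10([p.kappa, p.theta])
    mean = gp["post"] @ gp["nodes"]
    sd = np.sqrt(gp["post"] @ (gp["nodes"] - mean) ** 2)
    assert np.all(np.abs(x_fit - x_true) < 3.0 * np.maximum(sd, 0.1))


def test_akaike_weights_edge_cases():
    def fr(ll, k=3, conv=True):
        return FitResult(ModelKind.BURSTY, None, ll, conv, 1, k)

    w = akaike_weights([fr(-100.0), fr(-100.0), fr(-100.0)])
    assert np.allclose(w, 1 / 3)
    # a 20-unit AIC deficit leaves negligible weight
    w = akaike_weights([fr(-100.0), fr(-110.0)])
    assert w[1] < 1e-4
    with pytest.warns(UserWarning):
        w = akaike_weights([fr(-100.0), fr(-90.0, conv=False)])
    assert w[1] == 0.0
    with pytest.raises(ParamValidationError):
        akaike_weights([fr(-1.0, conv=False)])


def test_likelihood_ratio_cap_rule():
    a = FitResult(ModelKind.CIR, None, 0.0, True, 1, 4)
    b = FitResult(ModelKind.GOU, None, -160.0 * LOG10, True, 1, 4)
    sel = likelihood_ratio(a, b)
    assert sel.log10_lr == pytest.approx(160.0)
    assert sel.capped
    sel2 = likelihood_ratio(a, FitResult(ModelKind.GOU, None, -10.0, True, 1, 4))
    assert not sel2.capped


def test_bayes_factor_self_comparison_and_antisymmetry():
    cache = PMFCache()
    p = params_from_regime(0.5, 0.6, 8.0, 1.2, 0.7)
    d = sample_dataset(ModelKind.GOU, p, 300, np.random.default_rng(6), cache)
    prior = PriorSpec.default(1.2, 0.7, mean_rate=8.0)
    same = log10_bayes_factor(d, ModelKind.GOU, ModelKind.GOU, prior,
                              n_quad=4, cache=cache)
    assert same.log10_bf == 0.0
    ab = log10_bayes_factor(d, ModelKind.GOU, ModelKind.MIXTURE, prior,
                            n_quad=4, cache=cache)
    ba = log10_bayes_factor(d, ModelKind.MIXTURE, ModelKind.GOU, prior,
                            n_quad=4, cache=cache)
    assert ab.log10_bf == pytest.approx(-ba.log10_bf, abs=1e-12)


def test_evidence_matches_hand_enumeration_on_tiny_grid():
    """With a 2-point prior grid the marginal likelihood is the plain
    average of the two likelihoods; checked by direct enumeration."""
    cache = PMFCache()
    d = CountData(np.array([0, 1, 0]), np.array([1, 0, 0]))
    prior = PriorSpec(
        bounds={"a": (np.log10(0.5), np.log10(8.0))},
        fixed={"kappa": 1.0, "theta": 1.0, "beta": 1.0, "gamma_": 1.0},
    )
    log_ev, _ = log_evidence(d, ModelKind.CONSTITUTIVE, prior, n_quad=2,
                             cache=cache)
    lo, hi = np.log10(0.5), np.log10(8.0)
    mids = [lo + (hi - lo) * 0.25, lo + (hi - lo) * 0.75]
    lls = []
    for m in mids:
        pm = ModelParams(kappa=1, theta=1, a=10.0**m, beta=1, gamma_=1)
        lls.append(loglik(d, ModelKind.CONSTITUTIVE, pm, cache=cache))
    expected = np.log(0.5 * (np.exp(lls[0]) + np.exp(lls[1])))
    assert log_ev == pytest.approx(expected, abs=1e-10)


def test_posterior_sampler_concentrates_on_constitutive_rate():
    """Short ensemble-MCMC run: the posterior median of the constant rate
    lands near the closed-form MLE for well-identified data."""
    beta, gamma_ = 1.0, 1.7
    p_true = ModelParams(kappa=1, theta=1, a=10.0, beta=beta, gamma_=gamma_)
    d = sample_dataset(ModelKind.CONSTITUTIVE, p_true, 2000,
                       np.random.default_rng(8))
    prior = PriorSpec(
        bounds={"a": (0.0, 2.0)},
        fixed={"kappa": 1.0, "theta": 1.0, "beta": beta, "gamma_": gamma_},
    )
    post = posterior_sample(
        d, ModelKind.CONSTITUTIVE, prior, n_chains=6, n_burn=200,
        n_iter=600, seed=9,
    )
    med = 10.0 ** np.median(post["samples"][:, 0])
    k_hat = (d.nascent.mean() + d.mature.mean()) / (1 / beta + 1 / gamma_)
    assert med == pytest.approx(k_hat, rel=0.05)
    assert post["r_hat"].shape == (1,)


def test_prior_spec_validation():
    with pytest.raises(ParamValidationError):
        PriorSpec(bounds={"kappa": (1.0, 0.0)})
    with pytest.raises(ParamValidationError):
        PriorSpec(bounds={"kappa": (0, 1)}, fixed={"kappa": 1.0})
    with pytest.raises(ParamValidationError):
        PriorSpec(bounds={"a": (0, 1)}, mean_rate=5.0)


def test_distinguishability_experiment_runs_on_tiny_lattice():
    """The lattice-experiment driver returns a finite mean log10 Bayes
    factor per lattice point (scaled-down sanity run)."""
    from txnoise import distinguishability_experiment, regime_lattice

    lattice = regime_lattice(1, lo=0.5, hi=0.5)
    out = distinguishability_experiment(
        lattice, ModelKind.CIR, cells_per_set=300, n_datasets=1,
        seed=11, mean_rate=8.0, beta=1.0, gamma_=1.7, n_quad=4,
    )
    assert out.shape == (1,)
    assert np.isfinite(out[0])
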