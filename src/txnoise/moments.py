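"""Closed-form steady-state moments, noise decomposition and autocorrelations.

Both SDE-driven models (gamma-OU and CIR) share the same stationary driver
law Gamma(a/kappa, theta) and, remarkably, the same first- and second-order
count moments and autocorrelation functions; only the full joint
distributions differ.  The forms implemented here are therefore
model-independent.

Notation: mu_N = <K>/beta and mu_M = <K>/gamma are the mean nascent and
mature counts; eta^2 = sigma^2/mu^2 is the squared coefficient of variation,
which splits into an intrinsic (reaction-timing, 1/mu) part and an extrinsic
(rate-variation) part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .models import ModelKind, ModelParams, ParamValidationError

__all__ = [
    "MomentSet",
    "NoiseDecomposition",
    "steady_state_moments",
    "noise_decomposition",
    "autocorrelation",
    "model_moments",
    "moments_bundle_json",
    "perturb_degenerate_rates",
]

#: relative gap below which two of (kappa, beta, gamma) are treated as
#: numerically degenerate and the smaller is nudged apart (the analytic
#: forms have removable singularities at equal rates)
DEGENERATE_RTOL = 1e-6


def perturb_degenerate_rates(
    kappa: float, beta: float, gamma_: float, rtol: float = DEGENERATE_RTOL
) -> tuple[float, float, float]:
    """Nudge near-equal rates apart so pairwise-distinct formulas apply.

    Whenever two rates agree to within relative ``rtol``, the smaller one is
    reduced by a relative ``rtol``; deterministic, and accurate to O(rtol)
    because the singularities are removable.
    """
    rates = [kappa, beta, gamma_]
    # repeat until pairwise distinct (at most a few passes)
    for _ in range(4):
        moved = False
        for i in range(3):
            for j in range(i + 1, 3):
                lo, hi = sorted((i, j), key=lambda k: rates[k])
                if abs(rates[i] - rates[j]) <= rtol * max(rates[i], rates[j]):
                    rates[lo] = rates[lo] * (1.0 - rtol)
                    moved = True
        if not moved:
            break
    return rates[0], rates[1], rates[2]


@dataclass(frozen=True)
class MomentSet:
    """Stationary moments of (X_N, X_M, K); identical for both SDE models."""

    mean_K: float
    mu_N: float
    mu_M: float
    var_N: float
    var_M: float
    cov_NK: float
    cov_MK: float
    cov_NM: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NoiseDecomposition:
    """Intrinsic/extrinsic split of the squared coefficient of variation."""

    eta2_N: float
    eta2_M: float
    intrinsic_N: float
    intrinsic_M: float
    extrinsic_N: float
    extrinsic_M: float
    extrinsic_fraction_N: float
    extrinsic_fraction_M: float

    def as_dict(self) -> dict:
        return asdict(self)


def steady_state_moments(p: ModelParams) -> MomentSet:
    """All stationary first/second moments of the SDE-driven models.

    mu_N = <K>/beta, mu_M = <K>/gamma, with overdispersion terms

        sigma_N^2 - mu_N = mu_N theta / (kappa+beta)
        sigma_M^2 - mu_M = mu_M theta/(kappa+gamma) * beta/(kappa+beta)
                           * (kappa+beta+gamma)/(beta+gamma)

    and covariances

        Cov(X_N, K)   = <K> theta / (kappa+beta)
        Cov(X_M, K)   = <K> theta/(kappa+gamma) * beta/(kappa+beta)
        Cov(X_N, X_M) = <K> theta / ((kappa+beta)(kappa+gamma))
                        * (kappa+beta+gamma)/(beta+gamma)
    """
    k, th, b, g = p.kappa, p.theta, p.beta, p.gamma_
    K = p.mean_rate
    mu_N = K / b
    mu_M = K / g
    var_N = mu_N + mu_N * th / (k + b)
    var_M = mu_M + mu_M * th / (k + g) * (b / (k + b)) * ((k + b + g) / (b + g))
    cov_NK = K * th / (k + b)
    cov_MK = K * th / (k + g) * (b / (k + b))
    cov_NM = K * th / ((k + b) * (k + g)) * ((k + b + g) / (b + g))
    return MomentSet(
        mean_K=K, mu_N=mu_N, mu_M=mu_M, var_N=var_N, var_M=var_M,
        cov_NK=cov_NK, cov_MK=cov_MK, cov_NM=cov_NM,
    )


def noise_decomposition(p: ModelParams) -> NoiseDecomposition:
    """Split eta^2 into intrinsic (1/mu) and extrinsic contributions.

        eta_N^2 = 1/mu_N + (theta/<K>) * (1/kappa) / (1/kappa + 1/beta)
        eta_M^2 = 1/mu_M + (theta/<K>) * (1/kappa)/(1/kappa + 1/beta)
                  * (1/kappa)/(1/kappa + 1/gamma)
                  * (1/kappa + 1/(beta+gamma)) / (1/kappa)

    The nascent extrinsic fraction simplifies to theta/(theta+kappa+beta).
    """
    k, th, b, g = p.kappa, p.theta, p.beta, p.gamma_
    K = p.mean_rate
    mu_N = K / b
    mu_M = K / g
    intr_N = 1.0 / mu_N
    intr_M = 1.0 / mu_M
    inv_k = 1.0 / k
    ext_N = (th / K) * inv_k / (inv_k + 1.0 / b)
    ext_M = (
        (th / K)
        * (inv_k / (inv_k + 1.0 / b))
        * (inv_k / (inv_k + 1.0 / g))
        * ((inv_k + 1.0 / (b + g)) / inv_k)
    )
    eta2_N = intr_N + ext_N
    eta2_M = intr_M + ext_M
    return NoiseDecomposition(
        eta2_N=eta2_N, eta2_M=eta2_M,
        intrinsic_N=intr_N, intrinsic_M=intr_M,
        extrinsic_N=ext_N, extrinsic_M=ext_M,
        extrinsic_fraction_N=ext_N / eta2_N,
        extrinsic_fraction_M=ext_M / eta2_M,
    )


def autocorrelation(p: ModelParams, species: str, tau) -> np.ndarray | float:
    """Stationary normalized autocorrelation R(tau) of a count species.

    species is "nascent" or "mature"; tau may be a scalar or array of
    nonnegative lags.  R(0) = 1 by construction (the bracketed
    three-exponential term of the mature form vanishes identically at
    tau = 0 via the partial-fractions identity
    sum_r 1/prod_{r'!=r}(r-r') = 0, so no additive constant is needed).
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ParamValidationError("autocorrelation lags must be nonnegative")
    # coarser split than elsewhere: the three-exponential bracket divides by
    # products of rate gaps, so 1e-6 gaps would amplify round-off to ~1e-4
    k, b, g = perturb_degenerate_rates(p.kappa, p.beta, p.gamma_, rtol=1e-4)
    m = steady_state_moments(p)
    if species == "nascent":
        r = (
            np.exp(-b * tau_arr)
            + (m.cov_NK / m.var_N)
            * (np.exp(-k * tau_arr) - np.exp(-b * tau_arr)) / (b - k)
        )
    elif species == "mature":
        bracket = (
            np.exp(-b * tau_arr) / ((b - g) * (b - k))
            + np.exp(-g * tau_arr) / ((g - b) * (g - k))
            + np.exp(-k * tau_arr) / ((k - b) * (k - g))
        )
        r = (
            np.exp(-g * tau_arr)
            + b * (m.cov_NM / m.var_M)
            * (np.exp(-b * tau_arr) - np.exp(-g * tau_arr)) / (g - b)
            + b * (m.cov_MK / m.var_M) * bracket
        )
    else:
        raise ParamValidationError(
            f"species must be 'nascent' or 'mature', got {species!r}"
        )
    if np.ndim(tau) == 0:
        return float(r)
    return r


def model_moments(kind: ModelKind, p: ModelParams) -> MomentSet:
    """Stationary count moments for any model variant (used for grid sizing).

    GOU and CIR share `steady_state_moments`; the limiting models have their
    own (simpler) forms obtained as the corresponding parameter limits.
    """
    K = p.mean_rate
    b, g = p.beta, p.gamma_
    mu_N, mu_M = K / b, K / g
    if kind in (ModelKind.GOU, ModelKind.CIR):
        return steady_state_moments(p)
    if kind is ModelKind.CONSTITUTIVE:
        return MomentSet(K, mu_N, mu_M, mu_N, mu_M, 0.0, 0.0, 0.0)
    if kind is ModelKind.MIXTURE:
        # K frozen per cell, K ~ Gamma(alpha, theta): Var(K) = alpha theta^2
        var_K = p.mixture_shape * p.theta**2
        return MomentSet(
            K, mu_N, mu_M,
            mu_N + var_K / b**2, mu_M + var_K / g**2,
            var_K / b, var_K / g, var_K / (b * g),
        )
    if kind in (ModelKind.BURSTY, ModelKind.CIR_LIMIT):
        # kappa -> inf limit of the Table forms with burst size bsz = theta/kappa
        # (identical second moments for both heavy-tail limits)
        bsz = p.burst_size
        return MomentSet(
            K, mu_N, mu_M,
            mu_N + mu_N * bsz,
            mu_M + mu_M * bsz * b / (b + g),
            K * bsz, 0.0,
            K * bsz / (b + g),
        )
    raise ParamValidationError(f"unknown model kind {kind!r}")


def moments_bundle_json(p: ModelParams) -> str:
    """JSON bundle of the moment set and noise decomposition for one gene."""
    import json

    return json.dumps(
        {
            "moments": steady_state_moments(p).as_dict(),
            "noise": noise_decomposition(p).as_dict(),
        },
        indent=2,
    )
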