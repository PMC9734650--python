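"""Shared fixtures: simulation-vs-theory validation runs and caches.

The six validation parameter sets place four points near the corners of the
qualitative-regime square and two at intermediate positions, with
beta = 1.2, gamma = 0.7 and mean transcription rate 10; 10^4 cells are
simulated per set per model.  These runs back the analytic-vs-simulation
agreement checks and are computed once per session.
"""

import warnings

import numpy as np
import pytest

from txnoise import (
    ModelKind, PMFCache, SimProtocol, joint_pmf, params_from_regime,
    simulate_cells,
)

# four near-corner + two intermediate regime coordinates
VALIDATION_COORDS = [
    (0.9, 0.1),   # fast reversion, low gain  (constitutive-like)
    (0.1, 0.1),   # slow reversion, low gain
    (0.9, 0.9),   # fast reversion, high gain (bursty/heavy-tail)
    (0.1, 0.9),   # slow reversion, high gain (mixture-like)
    (0.5, 0.5),   # intermediate
    (0.3, 0.7),   # intermediate
]
BETA, GAMMA, KMEAN = 1.2, 0.7, 10.0
N_VALIDATION_CELLS = 10_000


@pytest.fixture(scope="session")
def validation_params():
    return [
        params_from_regime(r, g, KMEAN, BETA, GAMMA)
        for r, g in VALIDATION_COORDS
    ]


@pytest.fixture(scope="session")
def validation_sims(validation_params):
    """10^4 simulated cells per parameter set per model."""
    out = {}
    for i, p in enumerate(validation_params):
        for j, model in enumerate((ModelKind.GOU, ModelKind.CIR)):
            proto = SimProtocol(
                n_reps=N_VALIDATION_CELLS, seed=20_000 + 37 * i + j
            )
            out[(i, model)] = simulate_cells(model, p, proto)
    return out


@pytest.fixture(scope="session")
def validation_pmfs(validation_params):
    """Exact joint PMFs for the six sets, both models."""
    out = {}
    for i, p in enumerate(validation_params):
        for model in (ModelKind.GOU, ModelKind.CIR):
            out[(i, model)] = joint_pmf(model, p)
    return out


@pytest.fixture(scope="session")
def shared_cache():
    return PMFCache()


@pytest.fixture(autouse=True)
def _quiet_numeric_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def max_moment_zscore(data, moments):
    """Largest |z| of empirical vs analytic mean/var/cov (normal-theory SE)."""
    n = data.n_cells
    xn = data.nascent.astype(float)
    xm = data.mature.astype(float)
    zs = []
    for emp, th, se in [
        (xn.mean(), moments.mu_N, xn.std(ddof=1) / np.sqrt(n)),
        (xm.mean(), moments.mu_M, xm.std(ddof=1) / np.sqrt(n)),
    ]:
        zs.append(abs(emp - th) / se)
    # variance SE via the fourth central moment
    for x, th in [(xn, moments.var_N), (xm, moments.var_M)]:
        m2 = x.var(ddof=1)
        m4 = ((x - x.mean()) ** 4).mean()
        se = np.sqrt(max(m4 - m2**2 * (n - 3) / (n - 1), 1e-12) / n)
        zs.append(abs(m2 - th) / se)
    # covariance SE via the delta method on the product moments
    prod = (xn - xn.mean()) * (xm - xm.mean())
    se = prod.std(ddof=1) / np.sqrt(n)
    zs.append(abs(np.cov(xn, xm)[0, 1] - moments.cov_NM) / se)
    return max(zs)
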