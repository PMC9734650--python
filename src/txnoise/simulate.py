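"""Hybrid stochastic simulation: continuous rate driver + discrete RNA events.

The transcription rate K(t) is simulated first (exactly: compound-Poisson
jumps with exponential decay for gamma-OU, exact noncentral-chi-squared
transitions for CIR), then the discrete transcription/splicing/degradation
reactions are generated by a time-varying variant of Gillespie's direct
method: an Exp(1) target is drawn for the integrated total propensity and
the firing time is recovered by inverting the accumulated reaction flux --
in closed form via the Lambert W function on each exponential-decay segment
of the gamma-OU driver, and by trapezoidal flux accumulation on the CIR
driver's time grid.  Splicing and degradation have count-proportional,
K-independent propensities, so only the transcription channel needs the
time-varying machinery.

K(0) is drawn from the exact stationary law Gamma(a/kappa, theta), so the
driver is stationary from t = 0 and only the counts need to equilibrate;
the default equilibration horizon is therefore set by RNA turnover
(15 / min(beta, gamma)) rather than by the driver's reversion time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import ModelKind, ModelParams, ParamValidationError
from ._kernels import gou_counts_kernel, cir_counts_kernel

__all__ = [
    "SimProtocol",
    "CountData",
    "GouRatePath",
    "CirRatePath",
    "sample_gou_path",
    "sample_cir_path",
    "simulate_cells",
    "simulate_trajectories",
    "empirical_autocorrelation",
    "default_t_ss",
    "default_cir_dt",
]


def default_t_ss(p: ModelParams) -> float:
    """Equilibration horizon: 15 count-turnover times (driver starts stationary)."""
    return 15.0 / min(p.beta, p.gamma_)


def default_cir_dt(p: ModelParams) -> float:
    """CIR driver grid step resolving both the driver and the reaction flux."""
    return 0.01 / max(p.kappa, p.mean_rate, p.beta, p.gamma_)


@dataclass(frozen=True)
class SimProtocol:
    """Simulation protocol: equilibration, recording horizon, replicates.

    t_ss/t_r/dt_cir of None select parameter-dependent defaults at run time.
    """

    n_reps: int
    seed: int
    t_ss: float | None = None
    t_r: float | None = None
    dt_cir: float | None = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ParamValidationError("n_reps must be >= 1")
        if self.t_ss is not None and self.t_ss <= 0:
            raise ParamValidationError("t_ss must be positive")
        if self.t_r is not None and self.t_r <= 0:
            raise ParamValidationError("t_r must be positive")


@dataclass(frozen=True)
class CountData:
    """Paired per-cell (nascent, mature) counts for one gene."""

    nascent: np.ndarray
    mature: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.nascent)
        m = np.asarray(self.mature)
        if n.shape != m.shape or n.ndim != 1:
            raise ParamValidationError("nascent/mature must be paired 1-d vectors")
        if np.any(n < 0) or np.any(m < 0):
            raise ParamValidationError("counts must be nonnegative")
        object.__setattr__(self, "nascent", n.astype(np.int64))
        object.__setattr__(self, "mature", m.astype(np.int64))

    @property
    def n_cells(self) -> int:
        return self.nascent.size


@dataclass(frozen=True)
class GouRatePath:
    """Piecewise gamma-OU rate path: exponential decay between positive jumps."""

    kappa: float
    k_init: float
    jump_times: np.ndarray
    jump_sizes: np.ndarray
    horizon: float

    def value(self, t) -> np.ndarray:
        """K(t) at arbitrary times (vectorized)."""
        t = np.asarray(t, dtype=float)
        # K right after each jump, by exact decay recurrence
        kt = np.concatenate(([0.0], self.jump_times))
        kv = np.empty(kt.size)
        kv[0] = self.k_init
        for i in range(1, kt.size):
            kv[i] = kv[i - 1] * np.exp(-self.kappa * (kt[i] - kt[i - 1])) \
                + self.jump_sizes[i - 1]
        idx = np.searchsorted(kt, t, side="right") - 1
        return kv[idx] * np.exp(-self.kappa * (t - kt[idx]))


@dataclass(frozen=True)
class CirRatePath:
    """CIR rate path on a uniform grid (exact transition sampling)."""

    dt: float
    values: np.ndarray
    horizon: float = field(default=0.0)

    def value(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.clip(np.round(t / self.dt).astype(int), 0, self.values.size - 1)
        return self.values[idx]


def sample_gou_path(p: ModelParams, horizon: float, seed: int) -> GouRatePath:
    """Sample a gamma-OU driver path: Poisson(a) jump times, Exp(theta) sizes,
    exponential decay at rate kappa, stationary initial value."""
    if horizon <= 0:
        raise ParamValidationError("horizon must be positive")
    rng = np.random.default_rng(seed)
    k0 = rng.gamma(p.mixture_shape, p.theta)
    times = []
    t = rng.exponential(1.0 / p.a)
    while t < horizon:
        times.append(t)
        t += rng.exponential(1.0 / p.a)
    times = np.array(times)
    sizes = rng.exponential(p.theta, size=times.size)
    return GouRatePath(
        kappa=p.kappa, k_init=k0, jump_times=times, jump_sizes=sizes,
        horizon=horizon,
    )


def sample_cir_path(p: ModelParams, horizon: float, dt: float, seed: int) -> CirRatePath:
    """Sample a CIR driver path by exact scaled noncentral-chi-squared
    transitions on a dt grid; nonnegative by construction."""
    if dt <= 0 or horizon <= 0:
        raise ParamValidationError("horizon and dt must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(horizon / dt))
    vals = np.empty(n_steps + 1)
    vals[0] = rng.gamma(p.mixture_shape, p.theta)
    e = np.exp(-p.kappa * dt)
    c = p.theta * (1.0 - e) / 2.0
    df = 2.0 * p.a / p.kappa
    for i in range(n_steps):
        nc = vals[i] * e / c
        vals[i + 1] = c * rng.noncentral_chisquare(df, nc)
    return CirRatePath(dt=dt, values=vals, horizon=n_steps * dt)


def _resolve_times(p: ModelParams, protocol: SimProtocol, n_lags: int):
    t_ss = protocol.t_ss if protocol.t_ss is not None else default_t_ss(p)
    if t_ss < 10.0 / min(p.beta, p.gamma_):
        warnings.warn(
            f"t_ss = {t_ss:.3g} is shorter than 10 count-turnover times; "
            "equilibration is suspect", stacklevel=3,
        )
    if n_lags == 0:
        return t_ss, np.array([t_ss])
    t_r = protocol.t_r if protocol.t_r is not None else 5.0 / min(p.beta, p.gamma_)
    lags = np.linspace(0.0, t_r, n_lags + 1)
    return t_ss, t_ss + lags


def _run_kernel(model: ModelKind, p: ModelParams, protocol: SimProtocol,
                sample_times: np.ndarray):
    if model is ModelKind.GOU:
        xN, xM = gou_counts_kernel(
            p.kappa, p.theta, p.a, p.beta, p.gamma_,
            np.ascontiguousarray(sample_times, dtype=np.float64),
            protocol.n_reps, protocol.seed,
        )
    elif model is ModelKind.CIR:
        dt = protocol.dt_cir if protocol.dt_cir is not None else default_cir_dt(p)
        # snap sample times to the driver grid so record boundaries align
        steps = np.maximum(np.round(sample_times / dt).astype(np.int64), 1)
        for i in range(1, steps.size):  # keep records strictly ordered
            if steps[i] <= steps[i - 1]:
                steps[i] = steps[i - 1] + 1
        xN, xM = cir_counts_kernel(
            p.kappa, p.theta, p.a, p.beta, p.gamma_, dt,
            np.ascontiguousarray(steps), protocol.n_reps, protocol.seed,
        )
    else:
        raise ParamValidationError(
            f"simulation is defined for the GOU and CIR models, got {model}"
        )
    return xN, xM


def simulate_cells(model: ModelKind, p: ModelParams, protocol: SimProtocol) -> CountData:
    """Simulate n_reps independent cells to steady state; record (x_N, x_M).

    Deterministic given (seed, protocol, params).
    """
    _, times = _resolve_times(p, protocol, n_lags=0)
    xN, xM = _run_kernel(model, p, protocol, times)
    return CountData(nascent=xN[:, -1], mature=xM[:, -1])


def simulate_trajectories(
    model: ModelKind, p: ModelParams, protocol: SimProtocol, n_lags: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate and record counts on a lag grid over [t_ss, t_ss + t_r].

    Returns (lag_times_relative_to_t_ss, x_N, x_M) with count arrays of
    shape (n_reps, n_lags + 1); used for autocorrelation estimation.
    """
    t_ss, times = _resolve_times(p, protocol, n_lags=n_lags)
    xN, xM = _run_kernel(model, p, protocol, times)
    return times - times[0], xN, xM


def empirical_autocorrelation(
    traj: np.ndarray, lag_times: np.ndarray, lags: np.ndarray
) -> np.ndarray:
    """Stationary normalized autocorrelation estimate from replicate trajectories.

    traj has shape (n_reps, n_times) sampled at lag_times (uniform spacing);
    the estimate at each requested lag pools all start-time pairs across
    replicates and normalizes by the pooled stationary variance.
    """
    traj = np.asarray(traj, dtype=float)
    lag_times = np.asarray(lag_times, dtype=float)
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if np.any(lags < 0) or np.any(lags > lag_times[-1] - lag_times[0] + 1e-12):
        raise ParamValidationError("lags must lie within the recorded horizon")
    dt = lag_times[1] - lag_times[0]
    mu = traj.mean()
    var = traj.var()
    if var == 0:
        raise ParamValidationError("trajectories are constant; autocorrelation undefined")
    out = np.empty(lags.size)
    for i, tau in enumerate(lags):
        L = int(round(tau / dt))
        x0 = traj[:, : traj.shape[1] - L] - mu
        x1 = traj[:, L:] - mu
        out[i] = float((x0 * x1).mean()) / var
    return out
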