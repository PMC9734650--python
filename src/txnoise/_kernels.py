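"""Numba kernels for the hybrid Gillespie simulation.

Reaction firing times are found by inverting the integrated total
propensity Lambda(t) = K(t) + beta*x_N + gamma*x_M against an Exp(1)
target.  On a gamma-OU decay segment starting at rate K0 the transcription
flux over tau is K0 (1 - e^{-kappa tau}) / kappa, and with the constant
count-dependent part c = beta x_N + gamma x_M the inversion

    c tau + (K0/kappa)(1 - e^{-kappa tau}) = E

is solved exactly with the principal Lambert W branch:
tau = (D + W0(B e^{-D})) / kappa, D = kappa (E - K0/kappa)/c, B = K0/c.
For the CIR driver the flux integral is accumulated trapezoidally on the
driver grid (K piecewise linear), giving a quadratic within-cell inversion.
"""

import numpy as np
from numba import njit

__all__ = ["gou_counts_kernel", "cir_counts_kernel"]


@njit(cache=True)
def _w0(x):
    """Principal Lambert W for x >= 0 (Halley iteration)."""
    if x <= 0.0:
        return 0.0
    if x < 1e-8:
        return x * (1.0 - x)
    if x > 1e100:
        return _w0_log(np.log(x))
    w = np.log(1.0 + x)
    for _ in range(50):
        ew = np.exp(w)
        f = w * ew - x
        w1 = w - f / (ew * (w + 1.0) - (w + 2.0) * f / (2.0 * w + 2.0))
        if abs(w1 - w) <= 1e-15 * (1.0 + abs(w1)):
            w = w1
            break
        w = w1
    return w


@njit(cache=True)
def _w0_log(lx):
    """Solve w + log(w) = lx (i.e. W0(e^lx)) for large lx without overflow."""
    w = lx - np.log(max(lx, 1.0))
    for _ in range(50):
        f = w + np.log(w) - lx
        w1 = w - f * w / (w + 1.0)
        if abs(w1 - w) <= 1e-15 * (1.0 + abs(w1)):
            w = w1
            break
        w = w1
    return w


@njit(cache=True)
def _gou_fire_time(K0, c, kappa, E):
    """Solve c*tau + (K0/kappa)(1 - e^{-kappa tau}) = E for tau."""
    if c <= 0.0:
        # transcription only; E < (K0/kappa)(1 - e^{-kappa dT}) is guaranteed
        return -np.log(1.0 - E * kappa / K0) / kappa
    D = kappa * (E - K0 / kappa) / c
    if K0 <= 0.0:
        return E / c
    lg = np.log(K0 / c) - D
    if lg > 690.0:
        w = _w0_log(lg)
    else:
        w = _w0(np.exp(lg))
    tau = (D + w) / kappa
    if tau < 0.0:
        tau = 0.0
    # one Newton polish on the flux balance
    f = c * tau + (K0 / kappa) * (1.0 - np.exp(-kappa * tau)) - E
    fp = c + K0 * np.exp(-kappa * tau)
    if fp > 0.0:
        tau -= f / fp
        if tau < 0.0:
            tau = 0.0
    return tau


@njit(cache=True)
def _pick_and_apply(K_now, xN, xM, beta, gamma_):
    tot = K_now + beta * xN + gamma_ * xM
    r = np.random.random() * tot
    if r < K_now:
        return xN + 1, xM
    elif r < K_now + beta * xN:
        return xN - 1, xM + 1
    else:
        return xN, xM - 1


@njit(cache=True)
def gou_counts_kernel(kappa, theta, a, beta, gamma_, sample_times, n_reps, seed):
    """Simulate n_reps gamma-OU-driven cells; record counts at sample_times."""
    np.random.seed(seed)
    n_t = sample_times.size
    outN = np.zeros((n_reps, n_t), np.int64)
    outM = np.zeros((n_reps, n_t), np.int64)
    shape = a / kappa
    for rep in range(n_reps):
        K = np.random.gamma(shape, theta)
        t = 0.0
        next_jump = np.random.exponential(1.0 / a)
        xN = 0
        xM = 0
        E = np.random.exponential(1.0)
        it = 0
        while it < n_t:
            # next boundary: driver jump or recording time
            t_rec = sample_times[it]
            if next_jump < t_rec:
                seg_end = next_jump
                is_jump = True
            else:
                seg_end = t_rec
                is_jump = False
            # consume events inside [t, seg_end)
            while True:
                dT = seg_end - t
                c = beta * xN + gamma_ * xM
                F = c * dT + (K / kappa) * (1.0 - np.exp(-kappa * dT))
                if E > F:
                    E -= F
                    K *= np.exp(-kappa * dT)
                    t = seg_end
                    break
                tau = _gou_fire_time(K, c, kappa, E)
                if tau > dT:
                    tau = dT
                K *= np.exp(-kappa * tau)
                t += tau
                xN, xM = _pick_and_apply(K, xN, xM, beta, gamma_)
                E = np.random.exponential(1.0)
            if is_jump:
                K += np.random.exponential(theta)
                next_jump = t + np.random.exponential(1.0 / a)
            else:
                outN[rep, it] = xN
                outM[rep, it] = xM
                it += 1
    return outN, outM


@njit(cache=True)
def cir_counts_kernel(kappa, theta, a, beta, gamma_, dt, sample_steps, n_reps, seed):
    """Simulate n_reps CIR-driven cells; record counts at grid steps
    sample_steps (indices on the dt grid)."""
    np.random.seed(seed)
    n_t = sample_steps.size
    outN = np.zeros((n_reps, n_t), np.int64)
    outM = np.zeros((n_reps, n_t), np.int64)
    shape = a / kappa
    e = np.exp(-kappa * dt)
    cpar = theta * (1.0 - e) / 2.0
    last_step = sample_steps[n_t - 1]
    for rep in range(n_reps):
        K0 = np.random.gamma(shape, theta)
        xN = 0
        xM = 0
        E = np.random.exponential(1.0)
        it = 0
        for step in range(last_step):
            # exact CIR transition: scaled noncentral chi-squared
            nc = K0 * e / cpar
            j = np.random.poisson(nc / 2.0)
            K1 = cpar * 2.0 * np.random.gamma(shape + j, 1.0)
            # events within this cell, K linear between K0 and K1
            slope = (K1 - K0) / dt
            tau0 = 0.0
            while True:
                c = beta * xN + gamma_ * xM
                Kt0 = K0 + slope * tau0
                rem = dt - tau0
                F = (c + Kt0) * rem + 0.5 * slope * rem * rem
                if E > F:
                    E -= F
                    break
                B = c + Kt0
                disc = B * B + 2.0 * slope * E
                if disc < 0.0:
                    disc = 0.0
                denom = B + np.sqrt(disc)
                if denom <= 0.0:
                    x = rem
                else:
                    x = 2.0 * E / denom
                if x > rem:
                    x = rem
                tau0 += x
                K_now = K0 + slope * tau0
                if K_now < 0.0:
                    K_now = 0.0
                xN, xM = _pick_and_apply(K_now, xN, xM, beta, gamma_)
                E = np.random.exponential(1.0)
            K0 = K1
            if it < n_t and step + 1 == sample_steps[it]:
                outN[rep, it] = xN
                outM[rep, it] = xM
                it += 1
    return outN, outM
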