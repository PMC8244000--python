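"""Numba kernels for the diffusion first-passage density, likelihood, and simulator.

Everything here works in the sigma = 1 scaling convention with absorbing
boundaries at 0 and ``a``; the upper boundary codes a correct response
(accuracy coding). Public wrappers with validation live in :mod:`readrisk.ddm`.
"""

from __future__ import annotations

import math

import numba as nb
import numpy as np

# Series truncation error for the zero-drift density kernel; small relative
# to the 1e-4 mass-conservation contract and the 1e-10 likelihood floor's
# resolution, while keeping term counts low.
_SERIES_EPS = 1e-7


@nb.njit(cache=True, fastmath=True)
def nf_density(tau: float, w: float) -> float:
    """Normalized lower-boundary first-passage density at scaled time tau.

    Density for a zero-drift unit-boundary diffusion started at relative
    position ``w``, evaluated with whichever of the small-time / large-time
    series needs fewer terms for truncation error below 1e-10.
    """
    if tau <= 0.0:
        return 0.0
    eps = _SERIES_EPS

    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tau)))
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
    else:
        ks = 2.0

    # terms needed by the large-time expansion
    if math.pi * tau * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * eps) / (math.pi * math.pi * tau))
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))

    if ks < kl:
        K = int(math.ceil(ks))
        acc = 0.0
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            acc += x * math.exp(-x * x / (2.0 * tau))
        return acc / math.sqrt(2.0 * math.pi * tau * tau * tau)
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@nb.njit(cache=True, fastmath=True)
def simple_density(t: float, v: float, a: float, w: float, upper: bool) -> float:
    """First-passage density of the simple diffusion at decision time ``t``.

    ``upper=True`` gives the density of absorption at the correct boundary.
    """
    if t <= 0.0:
        return 0.0
    if upper:
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    z = a * ww
    drift_factor = math.exp(-vv * z - vv * vv * t / 2.0)
    return drift_factor * nf_density(t / (a * a), ww) / (a * a)


@nb.njit(cache=True, fastmath=True)
def _density_sv(t: float, v: float, a: float, w: float, s_v: float, upper: bool) -> float:
    """Decision-time density with Gaussian across-trial drift variability.

    The drift-dependent factor of the lower-boundary density,
    exp(-v*z - v^2 t / 2), integrates in closed form against a
    Normal(v, s_v^2) drift distribution.
    """
    if t <= 0.0:
        return 0.0
    if upper:
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    z = a * ww
    g = 1.0 + s_v * s_v * t
    mix = math.exp((s_v * s_v * z * z - 2.0 * vv * z - vv * vv * t) / (2.0 * g)) / math.sqrt(g)
    return mix * nf_density(t / (a * a), ww) / (a * a)


@nb.njit(cache=True, fastmath=True)
def full_density(
    rt: float,
    upper: bool,
    v: float,
    a: float,
    z_rel: float,
    t_nd: float,
    s_t: float,
    s_z: float,
    s_v: float,
    gl_x: np.ndarray,
    gl_w: np.ndarray,
) -> float:
    """Full 9-parameter density of one (boundary, rt) observation.

    Uniform non-decision-time and starting-point variability are averaged by
    Gauss-Legendre quadrature; drift variability is handled in closed form.
    Reduces exactly to the shifted simple density when all variabilities are 0.
    """
    nq = gl_x.shape[0]
    z_mean = a * z_rel
    acc = 0.0
    for i in range(nq):
        t0 = t_nd + 0.5 * s_t * gl_x[i]
        t_dec = rt - t0
        if t_dec <= 0.0:
            continue
        inner = 0.0
        for j in range(nq):
            z = z_mean + 0.5 * s_z * gl_x[j]
            inner += 0.5 * gl_w[j] * _density_sv(t_dec, v, a, z / a, s_v, upper)
        acc += 0.5 * gl_w[i] * inner
    return acc


@nb.njit(cache=True, fastmath=True)
def nll(
    theta: np.ndarray,
    rt: np.ndarray,
    correct: np.ndarray,
    coh_idx: np.ndarray,
    z_rel: float,
    gl_x: np.ndarray,
    gl_w: np.ndarray,
    floor: float,
) -> float:
    """Negative log likelihood of a trial set under theta.

    theta = (v6, v12, v24, v48, a, t_nd, s_t, s_z, s_v); coh_idx maps each
    trial to its drift-rate slot. Per-trial densities are floored at ``floor``.
    """
    a = theta[4]
    t_nd = theta[5]
    s_t = theta[6]
    s_z = theta[7]
    s_v = theta[8]
    total = 0.0
    for n in range(rt.shape[0]):
        v = theta[coh_idx[n]]
        d = full_density(rt[n], correct[n], v, a, z_rel, t_nd, s_t, s_z, s_v, gl_x, gl_w)
        if d < floor:
            d = floor
        total -= math.log(d)
    return total


@nb.njit(cache=True, fastmath=True)
def simulate(
    n: int,
    v: float,
    a: float,
    z_rel: float,
    t_nd: float,
    s_t: float,
    s_z: float,
    s_v: float,
    dt: float,
    cap: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-Maruyama simulation of n trials at one drift rate.

    A Brownian-bridge crossing probability is applied within each step so the
    first-passage distribution is unbiased at first order in dt. Decision
    times exceeding ``cap`` are emitted at the cap and flagged.

    Returns (rt, correct, capped) arrays; rt includes non-decision time.
    """
    np.random.seed(seed)
    rts = np.empty(n)
    correct = np.empty(n, dtype=np.bool_)
    capped = np.zeros(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    z_mean = a * z_rel
    for i in range(n):
        vi = v + s_v * np.random.randn() if s_v > 0.0 else v
        x = z_mean + s_z * (np.random.rand() - 0.5) if s_z > 0.0 else z_mean
        t0 = t_nd + s_t * (np.random.rand() - 0.5) if s_t > 0.0 else t_nd
        t = 0.0
        # bridge probabilities are negligible (< e^-40) beyond this product
        gate = 20.0 * dt
        while True:
            x_new = x + vi * dt + sqdt * np.random.randn()
            t += dt
            if x_new >= a:
                correct[i] = True
                break
            if x_new <= 0.0:
                correct[i] = False
                break
            # bridge correction: crossing inside the step without ending outside
            du = (a - x) * (a - x_new)
            dd = x * x_new
            if du < gate or dd < gate:
                p_up = math.exp(-2.0 * du / dt) if du < gate else 0.0
                p_dn = math.exp(-2.0 * dd / dt) if dd < gate else 0.0
                u = np.random.rand()
                if u < p_up:
                    correct[i] = True
                    break
                if u > 1.0 - p_dn:
                    correct[i] = False
                    break
            x = x_new
            if t >= cap:
                capped[i] = True
                correct[i] = x >= z_mean
                break
        if capped[i]:
            rts[i] = cap
        else:
            rts[i] = t + t0
    return rts, correct, capped
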