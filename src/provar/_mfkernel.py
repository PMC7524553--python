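"""Numba inner loop for batched mean-field trial simulation.

Kept separate so that importing the public module stays cheap and the
pure-numpy path in :mod:`provar.meanfield` remains the readable
reference implementation (used whenever trajectories are recorded).

The background Ornstein-Uhlenbeck currents use the exact discretisation
I(t+D) = I(t)*exp(-D/tau) + sd*sqrt(1-exp(-2D/tau))*N(0,1), applied
every ``noise_stride`` integration steps and held in between; normals
come from a xorshift64* stream via the polar (Marsaglia) method, which
is what makes the fused loop faster than vectorised numpy.
"""

import math

import numpy as np
from numba import njit

_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _next_u53(state):
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x &= np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    state[0] = x
    y = (x * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return float(y >> np.uint64(11)) * _INV53


@njit(cache=True, inline="always")
def _polar_pair(state):
    while True:
        u = 2.0 * _next_u53(state) - 1.0
        v = 2.0 * _next_u53(state) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            f = math.sqrt(-2.0 * math.log(s) / s)
            return u * f, v * f


@njit(cache=True)
def mf_batch(
    i_l,
    i_r,
    n_steps,
    steps_per_sample,
    alpha1,
    alpha2,
    i0,
    a,
    b,
    d,
    inv_tau,
    gamma,
    dt,
    noise_decay,
    noise_amp,
    stat_noise,
    noise_stride,
    s_init,
    seed,
):
    """Integrate all trials jointly; returns final (r1, r2, s1, s2)."""
    n, n_samples = i_l.shape
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed * 2862933555777941757 + 3037000493) | np.uint64(1)
    s1 = np.full(n, s_init)
    s2 = np.full(n, s_init)
    no1 = np.empty(n)
    no2 = np.empty(n)
    for i in range(n):
        g1, g2 = _polar_pair(state)
        no1[i] = stat_noise * g1
        no2[i] = stat_noise * g2
    r1 = np.zeros(n)
    r2 = np.zeros(n)
    for step in range(n_steps):
        samp = step // steps_per_sample
        stim_on = samp < n_samples
        renew = step % noise_stride == 0
        for i in range(n):
            e1 = i_l[i, samp] if stim_on else 0.0
            e2 = i_r[i, samp] if stim_on else 0.0
            if renew:
                g1, g2 = _polar_pair(state)
                no1[i] = no1[i] * noise_decay + noise_amp * g1
                no2[i] = no2[i] * noise_decay + noise_amp * g2
            x1 = alpha1 * s1[i] + alpha2 * s2[i] + i0 + e1 + no1[i]
            x2 = alpha1 * s2[i] + alpha2 * s1[i] + i0 + e2 + no2[i]
            z1 = a * x1 - b
            z2 = a * x2 - b
            if abs(z1) < 1e-10:
                rr1 = 1.0 / d
            elif z1 < -1000.0:
                rr1 = 0.0
            else:
                rr1 = z1 / (1.0 - math.exp(-d * z1))
            if abs(z2) < 1e-10:
                rr2 = 1.0 / d
            elif z2 < -1000.0:
                rr2 = 0.0
            else:
                rr2 = z2 / (1.0 - math.exp(-d * z2))
            r1[i] = rr1
            r2[i] = rr2
            v1 = s1[i] + dt * (-s1[i] * inv_tau + (1.0 - s1[i]) * gamma * rr1)
            v2 = s2[i] + dt * (-s2[i] * inv_tau + (1.0 - s2[i]) * gamma * rr2)
            s1[i] = min(max(v1, 0.0), 1.0)
            s2[i] = min(max(v2, 0.0), 1.0)
    return r1, r2, s1, s2
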