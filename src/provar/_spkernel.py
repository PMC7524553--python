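"""Numba kernel for the leaky integrate-and-fire attractor network.

One call integrates a single trial of the two-population decision
circuit: conductance-based LIF neurons, all-to-all connectivity with
structured weights (w+ within a selective group, w- onto a selective
group from outside it), AMPA/NMDA recurrent excitation, GABA_A
inhibition, and independent Poisson background + stimulus input per
neuron.  Population connectivity is uniform within classes, so the
recurrent drive only needs per-class sums of the synaptic gating
variables — this is what makes the network tractable at desk scale.

Speed notes: uniforms come from a xorshift64* stream (much faster than
the interpreter-facing RNG), Poisson counts use the inversion method
(input rates per step are O(0.1)), and the NMDA magnesium block is a
precomputed voltage lookup table.

Neuron layout: [group A | group B | nonselective E | inhibitory].
"""

import math

import numpy as np
from numba import njit

_INV53 = 1.0 / 9007199254740992.0  # 2**-53
_V_LO = -0.095  # lookup-table voltage range (V)
_V_HI = -0.025
_V_N = 7001


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
def _poisson(lam, exp_neg_lam, state):
    # inversion method; lam is O(0.05-0.3) here so this terminates fast
    u = _next_u53(state)
    count = 0
    p = exp_neg_lam
    cum = p
    while u > cum:
        count += 1
        p *= lam / count
        cum += p
        if count > 100:
            break
    return count


@njit(cache=True)
def run_lif_trial(
    n_a,
    n_b,
    n_e,
    n_i,
    w_plus,
    w_minus,
    # membrane
    cm_e,
    gl_e,
    cm_i,
    gl_i,
    v_leak,
    v_thresh,
    v_reset,
    v_exc,
    v_inh,
    ref_steps_e,
    ref_steps_i,
    # synapses (recurrent conductances already rescaled for network size)
    g_ext_e,
    g_ext_i,
    g_ampa_ee,
    g_ampa_ei,
    g_nmda_ee,
    g_nmda_ei,
    g_gaba_e,
    g_gaba_i,
    tau_ampa,
    tau_nmda_rise,
    tau_nmda_decay,
    alpha_nmda,
    tau_gaba,
    mg,
    # inputs
    bg_rate,
    stim_a,  # per-step stimulus rate (Hz) for group A, 0 outside stimulus
    stim_b,
    dt,
    n_steps,
    bin_steps,  # steps per rate bin
    ext_stride,  # steps between external Poisson draws (counts exact)
    seed,
):
    """Returns per-bin spike counts (count_a, count_b) and a finite flag."""
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed * 2862933555777941757 + 3037000493) | np.uint64(1)

    # magnesium-block lookup table over the reachable voltage range
    mg_tab = np.empty(_V_N)
    dv = (_V_HI - _V_LO) / (_V_N - 1)
    for k in range(_V_N):
        vmv = (_V_LO + k * dv) * 1000.0
        mg_tab[k] = 1.0 / (1.0 + mg * math.exp(-0.062 * vmv) / 3.57)
    inv_dv = 1.0 / dv

    n_tot = n_e + n_i
    v = np.full(n_tot, v_leak)
    for i in range(n_tot):  # desynchronise initial conditions
        v[i] = v_leak + (v_thresh - v_leak) * 0.5 * _next_u53(state)
    ref = np.zeros(n_tot, dtype=np.int64)
    s_ext = np.zeros(n_tot)
    s_ampa = np.zeros(n_e)
    x_nmda = np.zeros(n_e)
    s_nmda = np.zeros(n_e)
    s_gaba = np.zeros(n_i)

    d_ampa = math.exp(-dt / tau_ampa)
    d_rise = math.exp(-dt / tau_nmda_rise)
    d_gaba = math.exp(-dt / tau_gaba)
    inv_tau_nmda = 1.0 / tau_nmda_decay

    n_bins = n_steps // bin_steps + 1
    count_a = np.zeros(n_bins)
    count_b = np.zeros(n_bins)

    # external spike counts are drawn every ext_stride steps with the
    # correspondingly larger rate — the counts stay exactly Poisson,
    # only their placement is coarsened (ext_stride*dt << tau_ampa)
    dt_ext = dt * ext_stride
    lam_bg = bg_rate * dt_ext
    p_bg = math.exp(-lam_bg)

    dt_cm_e = dt / cm_e
    dt_cm_i = dt / cm_i

    ok = True
    for step in range(n_steps):
        # synaptic gating decay (NMDA via Euler on its saturating ODE)
        s_na = 0.0
        s_nb = 0.0
        s_nn = 0.0
        s_aa = 0.0
        s_ab = 0.0
        s_an = 0.0
        for i in range(n_e):
            s_ampa[i] *= d_ampa
            s_nmda[i] += dt * (
                -s_nmda[i] * inv_tau_nmda + alpha_nmda * x_nmda[i] * (1.0 - s_nmda[i])
            )
            x_nmda[i] *= d_rise
            if i < n_a:
                s_na += s_nmda[i]
                s_aa += s_ampa[i]
            elif i < n_a + n_b:
                s_nb += s_nmda[i]
                s_ab += s_ampa[i]
            else:
                s_nn += s_nmda[i]
                s_an += s_ampa[i]
        s_g = 0.0
        for j in range(n_i):
            s_gaba[j] *= d_gaba
            s_g += s_gaba[j]

        # per-class recurrent drives (weighted presynaptic gating sums)
        nmda_on_a = w_plus * s_na + w_minus * (s_nb + s_nn)
        nmda_on_b = w_plus * s_nb + w_minus * (s_na + s_nn)
        nmda_on_n = s_na + s_nb + s_nn
        ampa_on_a = w_plus * s_aa + w_minus * (s_ab + s_an)
        ampa_on_b = w_plus * s_ab + w_minus * (s_aa + s_an)
        ampa_on_n = s_aa + s_ab + s_an

        draw_ext = step % ext_stride == 0
        lam_a = (bg_rate + stim_a[step]) * dt_ext
        lam_b = (bg_rate + stim_b[step]) * dt_ext
        p_a = math.exp(-lam_a)
        p_b = math.exp(-lam_b)

        bin_idx = step // bin_steps
        for i in range(n_tot):
            s_ext[i] *= d_ampa
            if draw_ext:
                if i < n_a:
                    s_ext[i] += _poisson(lam_a, p_a, state)
                elif i < n_a + n_b:
                    s_ext[i] += _poisson(lam_b, p_b, state)
                else:
                    s_ext[i] += _poisson(lam_bg, p_bg, state)

            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_reset
                continue

            vi = v[i]
            k = int((vi - _V_LO) * inv_dv + 0.5)
            if k < 0:
                k = 0
            elif k >= _V_N:
                k = _V_N - 1
            mg_block = mg_tab[k]
            if i < n_e:
                if i < n_a:
                    nmda_drive = nmda_on_a
                    ampa_drive = ampa_on_a
                elif i < n_a + n_b:
                    nmda_drive = nmda_on_b
                    ampa_drive = ampa_on_b
                else:
                    nmda_drive = nmda_on_n
                    ampa_drive = ampa_on_n
                i_syn = (
                    g_ext_e * s_ext[i] * (vi - v_exc)
                    + g_ampa_ee * ampa_drive * (vi - v_exc)
                    + g_nmda_ee * nmda_drive * mg_block * (vi - v_exc)
                    + g_gaba_e * s_g * (vi - v_inh)
                )
                vi += dt_cm_e * (-gl_e * (vi - v_leak) - i_syn)
            else:
                i_syn = (
                    g_ext_i * s_ext[i] * (vi - v_exc)
                    + g_ampa_ei * (s_aa + s_ab + s_an) * (vi - v_exc)
                    + g_nmda_ei * (s_na + s_nb + s_nn) * mg_block * (vi - v_exc)
                    + g_gaba_i * s_g * (vi - v_inh)
                )
                vi += dt_cm_i * (-gl_i * (vi - v_leak) - i_syn)

            if not math.isfinite(vi):
                ok = False
                vi = v_reset
            if vi >= v_thresh:
                vi = v_reset
                if i < n_e:
                    ref[i] = ref_steps_e
                    x_nmda[i] += 1.0
                    s_ampa[i] += 1.0
                    if i < n_a:
                        count_a[bin_idx] += 1.0
                    elif i < n_a + n_b:
                        count_b[bin_idx] += 1.0
                else:
                    ref[i] = ref_steps_i
                    s_gaba[i - n_e] += 1.0
            v[i] = vi
    return count_a, count_b, ok
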