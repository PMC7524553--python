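"""Two-variable mean-field reduction of the winner-take-all circuit.

The state is the pair of NMDA gating fractions (S1, S2) of the two
selective excitatory populations; firing rates follow quasi-statically
from an input-output transfer function with an expansive non-linearity
between threshold and linear regimes.  Gating dynamics:

    dS_i/dt = -S_i / tau_NMDA + (1 - S_i) * gamma * r_i

with effective inputs

    x_i = alpha1*S_i + alpha2*S_j + I0 + I_ext,i + I_noise,i

and r_i = (a*x_i - f(x_j) - b) / (1 - exp(-d*(a*x_i - f(x_j) - b))).

Constants default to the standard published values of this reduction
(a=270 /nC, b=108 Hz, d=0.154 s, gamma=0.641, tau_NMDA=100 ms,
self/cross NMDA couplings 0.2609/-0.0497 nA, baseline 0.3255 nA,
external 5.2e-4 nA/Hz); stochasticity enters through an
Ornstein-Uhlenbeck background current per population (tau=2 ms,
sigma=0.02 nA).  Stimulus currents use the same evidence-to-rate
mapping as the spiking circuit (30 Hz at h=50, 1 Hz per evidence unit,
250 ms per sample) converted to current through the external coupling.

Trial batches are simulated fully vectorised across trials, which makes
the published 94,000-trial run a desk-scale computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .trialgen import Trial, TrialSet, ChoiceSet, trial_evidence, correct_side

__all__ = [
    "MeanFieldParams",
    "MeanFieldState",
    "transfer_rates",
    "effective_inputs",
    "gating_derivative",
    "step_gating",
    "run_trial_meanfield",
    "run_trials_meanfield",
    "simulate_choices_meanfield",
    "nullclines",
    "net_drive_diagonal",
    "apply_meanfield_perturbation",
]


@dataclass(frozen=True)
class MeanFieldParams:
    """All constants of the reduced model (currents in nA, times in s)."""

    tau_nmda: float = 0.100
    gamma: float = 0.641
    alpha1: float = 0.2609  # self NMDA coupling (nA per gating unit)
    alpha2: float = -0.0497  # cross coupling (net inhibitory)
    beta1: float = 0.0  # self AMPA coupling (nA per Hz); absorbed by default
    beta2: float = 0.0  # cross AMPA coupling
    a: float = 270.0  # transfer gain (Hz per nA)
    b: float = 108.0  # transfer threshold (Hz)
    d: float = 0.154  # transfer curvature (s)
    f0: float = 0.0  # cross-input function f(x) = f0 + f1*x
    f1: float = 0.0
    i0: float = 0.3255  # common baseline current (nA)
    j_ext: float = 5.2e-4  # external coupling (nA per Hz of input rate)
    mu0: float = 30.0  # input rate at h=50 (Hz)
    mu_prime: float = 1.0  # input rate slope (Hz per evidence unit)
    sensory_deficit: float = 0.0
    sigma_noise: float = 0.007  # OU noise amplitude (nA)
    tau_noise: float = 0.002  # OU time constant (s)
    noise_stride: int = 4  # OU renewal every stride steps (exact discretisation)
    dt: float = 1e-4
    sample_duration: float = 0.25
    readout_delay: float = 2.0
    s_init: float = 0.1
    # decomposition of the NMDA couplings into an excitatory part and a
    # routed-inhibition part, used only by the E/I perturbation surrogate
    alpha_inh: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.tau_nmda <= 0:
            raise ValueError("tau_nmda must be positive")
        if self.dt >= self.tau_noise:
            raise ValueError("dt must resolve the noise process (dt < tau_noise)")


@dataclass
class MeanFieldState:
    s1: float
    s2: float
    i_noise1: float = 0.0
    i_noise2: float = 0.0


def _h(z, d):
    """Transfer function z / (1 - exp(-d*z)) with its removable
    singularity at z=0 replaced by the analytic limit 1/d."""
    z = np.asarray(z, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-d * z)
        out = np.where(np.abs(d * z) < 1e-10, 1.0 / d + z / 2.0, z / denom)
    # far below threshold the exponential overflows; the rate is 0 there
    return np.where(np.isfinite(out), out, 0.0)


def transfer_rates(x1, x2, params: MeanFieldParams):
    """Population rates (r1, r2) in Hz from effective inputs (nA).

    The cross-input function f enters with a minus sign; with the
    default f == 0 each rate depends on its own input only (the cross
    coupling being carried by alpha2).
    """
    f_of = lambda x: params.f0 + params.f1 * np.asarray(x, dtype=float)
    r1 = _h(params.a * np.asarray(x1, float) - f_of(x2) - params.b, params.d)
    r2 = _h(params.a * np.asarray(x2, float) - f_of(x1) - params.b, params.d)
    return r1, r2


def effective_inputs(s1, s2, i_ext1, i_ext2, params: MeanFieldParams, r1=0.0, r2=0.0):
    """x_i from gating variables, external currents and (optional) AMPA
    recurrence.  beta terms use the supplied rates (quasi-static)."""
    x1 = params.alpha1 * s1 + params.alpha2 * s2 + params.i0 + i_ext1
    x2 = params.alpha1 * s2 + params.alpha2 * s1 + params.i0 + i_ext2
    if params.beta1 or params.beta2:
        x1 = x1 + params.beta1 * r1 + params.beta2 * r2
        x2 = x2 + params.beta1 * r2 + params.beta2 * r1
    return x1, x2


def gating_derivative(s1, s2, i_ext1, i_ext2, params: MeanFieldParams):
    """(dS1/dt, dS2/dt, r1, r2) at the given state and external currents."""
    x1, x2 = effective_inputs(s1, s2, i_ext1, i_ext2, params)
    if params.beta1 or params.beta2:
        # self-consistent rates under AMPA recurrence
        r1 = r2 = np.zeros_like(np.asarray(s1, float))
        for _ in range(50):
            x1, x2 = effective_inputs(s1, s2, i_ext1, i_ext2, params, r1, r2)
            r1n, r2n = transfer_rates(x1, x2, params)
            if np.max(np.abs(r1n - r1)) < 1e-10 and np.max(np.abs(r2n - r2)) < 1e-10:
                r1, r2 = r1n, r2n
                break
            r1, r2 = r1n, r2n
    else:
        r1, r2 = transfer_rates(x1, x2, params)
    ds1 = -s1 / params.tau_nmda + (1.0 - s1) * params.gamma * r1
    ds2 = -s2 / params.tau_nmda + (1.0 - s2) * params.gamma * r2
    return ds1, ds2, r1, r2


def step_gating(
    state: MeanFieldState,
    i_ext: tuple[float, float],
    dt: float,
    params: MeanFieldParams,
    rng=None,
) -> MeanFieldState:
    """One forward-Euler step of the gating and noise dynamics.

    With ``rng=None`` the step is deterministic (noise currents decay
    only).  S is clamped to [0, 1] purely against floating-point
    overshoot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ds1, ds2, _, _ = gating_derivative(
        state.s1, state.s2, i_ext[0] + state.i_noise1, i_ext[1] + state.i_noise2, params
    )
    s1 = min(max(state.s1 + dt * float(ds1), 0.0), 1.0)
    s2 = min(max(state.s2 + dt * float(ds2), 0.0), 1.0)
    decay = np.exp(-dt / params.tau_noise)
    eta1 = eta2 = 0.0
    if rng is not None:
        eta1, eta2 = rng.standard_normal(2)
    amp = params.sigma_noise / np.sqrt(2.0) * np.sqrt(1.0 - decay**2)
    return MeanFieldState(
        s1,
        s2,
        state.i_noise1 * decay + amp * eta1,
        state.i_noise2 * decay + amp * eta2,
    )


# ---------------------------------------------------------------------------
# trial simulation


def _stimulus_currents(trials: Sequence[Trial], params: MeanFieldParams):
    """(n_trials, n_samples) external currents per side from the shared
    evidence-to-rate mapping, scaled into current via j_ext."""
    hl = np.array([trial_evidence(t)[0] for t in trials])
    hr = np.array([trial_evidence(t)[1] for t in trials])
    gain = params.mu_prime * (1.0 - params.sensory_deficit)
    i_l = params.j_ext * (params.mu0 + gain * (hl - 50.0))
    i_r = params.j_ext * (params.mu0 + gain * (hr - 50.0))
    return i_l, i_r


def run_trials_meanfield(
    trials,
    params: MeanFieldParams = MeanFieldParams(),
    rng=None,
    record: bool = False,
    record_stride: int = 10,
):
    """Simulate a batch of trials, vectorised across trials.

    Parameters
    ----------
    trials : TrialSet or sequence of Trial
    rng : numpy Generator or None
        None runs noiseless dynamics (useful for symmetry checks).
    record : bool
        If True also return the (decimated) S trajectories.

    Returns
    -------
    chose_left : boolean array (n_trials,)
    extras : dict with final rates, and trajectories when recorded.
    """
    trial_list = list(trials)
    n = len(trial_list)
    if n == 0:
        return np.zeros(0, bool), {}
    n_samples = trial_list[0].n_samples
    i_l, i_r = _stimulus_currents(trial_list, params)
    dt = params.dt
    t_stim = n_samples * params.sample_duration
    n_steps = int(round((t_stim + params.readout_delay) / dt))
    steps_per_sample = int(round(params.sample_duration / dt))

    simple = not (params.beta1 or params.beta2 or params.f0 or params.f1)
    if simple and not record and rng is not None:
        # fast path: fused numba loop, seeded from the caller's generator
        from ._mfkernel import mf_batch

        stat = params.sigma_noise / np.sqrt(2.0)
        decay = np.exp(-params.noise_stride * dt / params.tau_noise)
        r1, r2, s1, s2 = mf_batch(
            np.ascontiguousarray(i_l),
            np.ascontiguousarray(i_r),
            n_steps,
            steps_per_sample,
            params.alpha1,
            params.alpha2,
            params.i0,
            params.a,
            params.b,
            params.d,
            1.0 / params.tau_nmda,
            params.gamma,
            dt,
            decay,
            stat * np.sqrt(1.0 - decay**2),
            stat,
            params.noise_stride,
            params.s_init,
            int(rng.integers(2**31)),
        )
        if not np.all(np.isfinite(s1)) or not np.all(np.isfinite(s2)):
            raise FloatingPointError("mean-field integration diverged")
        tie = r1 == r2
        chose_left = np.where(tie, rng.random(n) < 0.5, r1 > r2)
        return chose_left, {"r1": r1, "r2": r2, "ties": tie}

    s1 = np.full(n, params.s_init)
    s2 = np.full(n, params.s_init)
    stat = params.sigma_noise / np.sqrt(2.0)
    if rng is None:
        no1 = np.zeros(n)
        no2 = np.zeros(n)
    else:
        # start the OU processes at stationarity
        no1 = stat * rng.standard_normal(n)
        no2 = stat * rng.standard_normal(n)
    decay = np.exp(-params.noise_stride * dt / params.tau_noise)
    amp = stat * np.sqrt(1.0 - decay**2)
    inv_tau = 1.0 / params.tau_nmda
    gam = params.gamma

    traj = []
    r1 = r2 = np.zeros(n)
    for step in range(n_steps):
        sample = step // steps_per_sample
        if sample < n_samples:
            e1 = i_l[:, sample]
            e2 = i_r[:, sample]
        else:
            e1 = e2 = 0.0  # stimulus off during the readout delay
        x1 = params.alpha1 * s1 + params.alpha2 * s2 + params.i0 + e1 + no1
        x2 = params.alpha1 * s2 + params.alpha2 * s1 + params.i0 + e2 + no2
        r1, r2 = transfer_rates(x1, x2, params)
        s1 += dt * (-s1 * inv_tau + (1.0 - s1) * gam * r1)
        s2 += dt * (-s2 * inv_tau + (1.0 - s2) * gam * r2)
        np.clip(s1, 0.0, 1.0, out=s1)
        np.clip(s2, 0.0, 1.0, out=s2)
        if step % params.noise_stride == 0:
            if rng is None:
                no1 = no1 * decay
                no2 = no2 * decay
            else:
                no1 = no1 * decay + amp * rng.standard_normal(n)
                no2 = no2 * decay + amp * rng.standard_normal(n)
        if record and step % record_stride == 0:
            traj.append((s1.copy(), s2.copy()))

    if rng is None:
        tie = r1 == r2
        chose_left = r1 > r2
    else:
        tie = r1 == r2
        chose_left = np.where(tie, rng.random(n) < 0.5, r1 > r2)
    if not np.all(np.isfinite(s1)) or not np.all(np.isfinite(s2)):
        raise FloatingPointError("mean-field integration diverged")
    extras = {"r1": r1, "r2": r2, "ties": tie}
    if record:
        extras["s1"] = np.array([t[0] for t in traj])
        extras["s2"] = np.array([t[1] for t in traj])
        extras["time"] = np.arange(len(traj)) * dt * record_stride
    return chose_left, extras


def run_trial_meanfield(trial: Trial, params: MeanFieldParams = MeanFieldParams(), rng=None):
    """Single-trial convenience wrapper: returns (trajectory, choice).

    choice is "left"/"right"; the trajectory dict has keys time, s1, s2.
    """
    chose_left, extras = run_trials_meanfield([trial], params, rng, record=True)
    traj = {
        "time": extras["time"],
        "s1": extras["s1"][:, 0],
        "s2": extras["s2"][:, 0],
    }
    return traj, "left" if chose_left[0] else "right"


def simulate_choices_meanfield(
    trials: TrialSet, params: MeanFieldParams = MeanFieldParams(), rng=None
) -> ChoiceSet:
    """Run the mean-field model over a TrialSet and package a ChoiceSet."""
    chose_left, _ = run_trials_meanfield(trials, params, rng)
    correct = np.array(
        [(correct_side(t) == "left") == c for t, c in zip(trials, chose_left)]
    )
    return ChoiceSet(trials, chose_left, correct)


# ---------------------------------------------------------------------------
# phase-plane analysis


def nullclines(
    params: MeanFieldParams,
    i_ext: tuple[float, float] = (0.0, 0.0),
    n_grid: int = 201,
    tol: float = 1e-12,
):
    """Sample the dS1/dt=0 and dS2/dt=0 loci on the unit square.

    For each value of the partner gating variable on a regular grid,
    sign changes of the drift are bracketed and refined with Brent's
    method.  Returns a dict with arrays ``s1``, ``s2``, ``branch``
    (1 or 2 for the dS1/dt=0 and dS2/dt=0 nullclines).

    Raises
    ------
    RuntimeError if the grid brackets no roots for either branch.
    """
    from scipy.optimize import brentq

    grid = np.linspace(0.0, 1.0, n_grid)
    pts_s1, pts_s2, branch = [], [], []

    def drift1(s1, s2):
        return gating_derivative(s1, s2, i_ext[0], i_ext[1], params)[0]

    def drift2(s1, s2):
        return gating_derivative(s1, s2, i_ext[0], i_ext[1], params)[1]

    for b, drift in ((1, drift1), (2, drift2)):
        for partner in grid:
            if b == 1:
                vals = np.array([drift(s, partner) for s in grid])
            else:
                vals = np.array([drift(partner, s) for s in grid])
            sign = np.sign(vals)
            idx = np.nonzero(np.diff(sign) != 0)[0]
            for j in idx:
                lo, hi = grid[j], grid[j + 1]
                if b == 1:
                    root = brentq(lambda s: drift(s, partner), lo, hi, xtol=tol)
                    pts_s1.append(root)
                    pts_s2.append(partner)
                else:
                    root = brentq(lambda s: drift(partner, s), lo, hi, xtol=tol)
                    pts_s1.append(partner)
                    pts_s2.append(root)
                branch.append(b)
    if not pts_s1:
        raise RuntimeError("nullcline grid too coarse: no roots bracketed")
    return {
        "s1": np.array(pts_s1),
        "s2": np.array(pts_s2),
        "branch": np.array(branch),
    }


def net_drive_diagonal(
    params: MeanFieldParams,
    i_ext: tuple[float, float],
    s_grid: Optional[np.ndarray] = None,
):
    """Net drive dS1/dt - dS2/dt along the diagonal S1 = S2.

    Positive values push the system toward the population receiving
    input ``i_ext[0]``.  Returns (s_grid, net_drive).
    """
    if s_grid is None:
        s_grid = np.linspace(0.0, 1.0, 101)
    ds1, ds2, _, _ = gating_derivative(s_grid, s_grid, i_ext[0], i_ext[1], params)
    return s_grid, ds1 - ds2


# ---------------------------------------------------------------------------
# E/I perturbation surrogate


def apply_meanfield_perturbation(params: MeanFieldParams, spec) -> MeanFieldParams:
    """Map circuit-level NMDA perturbations onto the reduced couplings.

    The NMDA couplings are split as alpha_i = (excitatory part) -
    alpha_inh, where alpha_inh models inhibition routed through the
    interneuron pool (which tracks S1 + S2).  A G_EE reduction scales
    the excitatory parts; a G_EI reduction scales alpha_inh; a sensory
    deficit scales the input slope mu_prime.  ``spec`` is any object
    with gEE_reduction / gEI_reduction / sensory_deficit attributes
    (e.g. spiking.PerturbationSpec).
    """
    exc1 = params.alpha1 + params.alpha_inh
    exc2 = params.alpha2 + params.alpha_inh
    inh = params.alpha_inh
    exc1 *= 1.0 - spec.gEE_reduction
    exc2 *= 1.0 - spec.gEE_reduction
    inh *= 1.0 - spec.gEI_reduction
    return replace(
        params,
        alpha1=exc1 - inh,
        alpha2=exc2 - inh,
        alpha_inh=inh,  # keep the decomposition consistent under chaining
        sensory_deficit=1.0 - (1.0 - params.sensory_deficit) * (1.0 - spec.sensory_deficit),
    )
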