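"""Spiking winner-take-all decision circuit.

A local cortical microcircuit of leaky integrate-and-fire neurons:
N_E excitatory pyramidal cells (two selective groups of N_group plus a
nonselective remainder) and N_I interneurons, all-to-all connected.
Recurrent excitation is AMPA+NMDA mediated, inhibition GABA_A; neurons
in the same selective group are potentiated by w+ > 1 and connections
onto a selective group from outside are depressed to w- < 1 so the
total recurrent weight is preserved.  Each selective group receives an
independent Poisson stimulus whose rate scales linearly with the
momentary context-mapped evidence h:

    mu = mu0 + mu_prime * (1 - sensory_deficit) * (h - 50)

with mu0 = 30 Hz at h = 50 and mu_prime = 1 Hz per evidence unit; each
evidence sample drives the circuit for 250 ms with no gap.  The choice
is read out 2 s after stimulus offset from the causally filtered
population rates (exponential kernel, tau = 20 ms, 1 ms bins).

Parameter values follow the canonical published set of this model
family (see docs/methods.md); perturbations reduce the NMDA
conductance onto excitatory cells (lowered E/I), onto interneurons
(elevated E/I), or the stimulus scaling (sensory deficit).

Full-size simulation is expensive; :func:`desk_config` returns a
reduced network (scaled neuron counts with conductance rescaling that
preserves the mean recurrent drive, coarser dt) for desk-scale work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .trialgen import Trial, TrialSet, ChoiceSet, trial_evidence, correct_side

__all__ = [
    "SpikingConfig",
    "PerturbationSpec",
    "PERTURBATION_PRESETS",
    "RateTrace",
    "stimulus_rates",
    "apply_perturbation",
    "filter_rates",
    "run_trial",
    "read_choice",
    "run_trials",
    "desk_config",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Fractional synaptic/sensory perturbations (0 = control)."""

    gEE_reduction: float = 0.0
    gEI_reduction: float = 0.0
    sensory_deficit: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.gEE_reduction < 1.0 or not 0.0 <= self.gEI_reduction < 1.0:
            raise ValueError("conductance reductions must lie in [0, 1)")
        if not 0.0 <= self.sensory_deficit < 1.0:
            raise ValueError("sensory deficit must lie in [0, 1)")


#: the three named perturbations studied alongside the control circuit
PERTURBATION_PRESETS = {
    "control": PerturbationSpec(),
    "lowered_ei": PerturbationSpec(gEE_reduction=0.013125),
    "elevated_ei": PerturbationSpec(gEI_reduction=0.02625),
    "sensory_deficit": PerturbationSpec(sensory_deficit=0.20),
}


@dataclass(frozen=True)
class SpikingConfig:
    """Complete parameter set of the circuit (SI units)."""

    n_e: int = 1600
    n_i: int = 400
    n_group: int = 240
    # slightly above the canonical 1.7, placing the circuit safely inside
    # the bistable regime so the choice attractor persists through the
    # 2 s readout delay
    w_plus: float = 1.75
    # membrane
    cm_e: float = 0.5e-9
    gl_e: float = 25e-9
    cm_i: float = 0.2e-9
    gl_i: float = 20e-9
    v_leak: float = -70e-3
    v_thresh: float = -50e-3
    v_reset: float = -55e-3
    v_exc: float = 0.0
    v_inh: float = -70e-3
    tau_ref_e: float = 2e-3
    tau_ref_i: float = 1e-3
    # synaptic conductances (per connection class, unscaled network)
    g_ext_ampa_e: float = 2.1e-9
    g_ext_ampa_i: float = 1.62e-9
    g_ampa_ee: float = 0.05e-9
    g_ampa_ei: float = 0.04e-9
    g_nmda_ee: float = 0.165e-9
    g_nmda_ei: float = 0.13e-9
    g_gaba_e: float = 1.3e-9
    g_gaba_i: float = 1.0e-9
    tau_ampa: float = 2e-3
    tau_nmda_rise: float = 2e-3
    tau_nmda_decay: float = 100e-3
    alpha_nmda: float = 500.0  # 1/s
    tau_gaba: float = 5e-3
    mg: float = 1.0  # mM
    # inputs
    background_rate: float = 2400.0
    mu0: float = 30.0
    mu_prime: float = 1.0
    sensory_deficit: float = 0.0
    # protocol
    sample_duration: float = 0.25
    pre_stimulus: float = 0.5
    readout_delay: float = 2.0
    filter_tau: float = 0.02
    rate_bin: float = 1e-3
    dt: float = 2e-5
    #: draw external Poisson counts every this many steps (counts exact,
    #: placement coarsened; keep ext_stride*dt well below tau_ampa)
    ext_stride: int = 1
    #: network scale relative to full size; recurrent conductances above
    #: are the full-size values and are divided by `scale` at run time
    scale: float = 1.0

    def __post_init__(self):
        if 2 * self.n_group > self.n_e:
            raise ValueError("selective groups exceed the excitatory population")
        if not self.w_plus > 1.0:
            raise ValueError("w_plus must exceed 1")
        for name in (
            "g_ext_ampa_e", "g_ext_ampa_i", "g_ampa_ee", "g_ampa_ei",
            "g_nmda_ee", "g_nmda_ei", "g_gaba_e", "g_gaba_i",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def w_minus(self) -> float:
        """Depression factor preserving total recurrent weight:
        w- = 1 - f(w+ - 1)/(1 - f), f = n_group / n_e."""
        f = self.n_group / self.n_e
        return 1.0 - f * (self.w_plus - 1.0) / (1.0 - f)

    def scaled(self, factor: float) -> "SpikingConfig":
        """Network reduced by ``factor`` with recurrent conductances
        rescaled (handled at run time through ``scale``) so the mean
        recurrent drive per neuron is preserved."""
        return replace(
            self,
            n_e=int(round(self.n_e * factor)),
            n_i=int(round(self.n_i * factor)),
            n_group=int(round(self.n_group * factor)),
            scale=self.scale * factor,
        )


def desk_config(factor: float = 0.125, dt: float = 1e-4, w_plus: float = 1.8) -> SpikingConfig:
    """The reduced configuration used for desk-scale runs and tests.

    Besides scaling neuron counts (with conductance rescaling), the
    within-group potentiation is raised slightly: with ~30 neurons per
    selective group, finite-size fluctuations destabilise the choice
    attractor at the full-size w+, and a modest increase restores the
    persistent state that carries the decision across the readout delay.
    """
    return replace(SpikingConfig().scaled(factor), dt=dt, w_plus=w_plus, ext_stride=2)


@dataclass
class RateTrace:
    """Causally filtered population rates of the two selective groups."""

    time: np.ndarray  # bin times (s), from trial start
    r_a: np.ndarray  # Hz
    r_b: np.ndarray
    t_offset: float  # stimulus offset time (s)

    def __post_init__(self):
        if np.any(self.r_a < 0) or np.any(self.r_b < 0):
            raise ValueError("population rates must be non-negative")


def stimulus_rates(trial: Trial, config: SpikingConfig) -> np.ndarray:
    """(n_samples, 2) Poisson input rates in Hz for groups A (left) and
    B (right), one row per 250 ms evidence sample."""
    ev_l, ev_r = trial_evidence(trial)
    gain = config.mu_prime * (1.0 - config.sensory_deficit)
    out = np.column_stack(
        [
            config.mu0 + gain * (ev_l - 50.0),
            config.mu0 + gain * (ev_r - 50.0),
        ]
    )
    return np.clip(out, 0.0, None)


def apply_perturbation(config: SpikingConfig, spec: PerturbationSpec) -> SpikingConfig:
    """New config with NMDA conductances and/or input scaling reduced;
    the input config is left untouched."""
    return replace(
        config,
        g_nmda_ee=config.g_nmda_ee * (1.0 - spec.gEE_reduction),
        g_nmda_ei=config.g_nmda_ei * (1.0 - spec.gEI_reduction),
        sensory_deficit=1.0
        - (1.0 - config.sensory_deficit) * (1.0 - spec.sensory_deficit),
    )


def filter_rates(counts: np.ndarray, n_neurons: int, config: SpikingConfig) -> np.ndarray:
    """Causal exponential filter of per-bin spike counts.

    Each spike contributes (1/tau_filter)*exp(-dt_since_spike/tau_filter)
    to later bins; dividing by the group size gives the population rate
    in Hz.
    """
    decay = np.exp(-config.rate_bin / config.filter_tau)
    out = np.empty_like(counts, dtype=float)
    acc = 0.0
    w = 1.0 / (config.filter_tau * n_neurons)
    for i, c in enumerate(counts):
        acc = acc * decay + c * w
        out[i] = acc
    return out


def _trial_duration(trial: Trial, config: SpikingConfig) -> float:
    return (
        config.pre_stimulus
        + trial.n_samples * config.sample_duration
        + config.readout_delay
    )


def run_trial(trial: Trial, config: SpikingConfig, rng) -> RateTrace:
    """Integrate the network for one trial and return the rate trace.

    Raises FloatingPointError on numerical divergence.
    """
    from ._spkernel import run_lif_trial

    dt = config.dt
    n_steps = int(round(_trial_duration(trial, config) / dt))
    bin_steps = max(1, int(round(config.rate_bin / dt)))
    rates = stimulus_rates(trial, config)
    stim_a = np.zeros(n_steps)
    stim_b = np.zeros(n_steps)
    pre = int(round(config.pre_stimulus / dt))
    per = int(round(config.sample_duration / dt))
    for k in range(trial.n_samples):
        stim_a[pre + k * per : pre + (k + 1) * per] = rates[k, 0]
        stim_b[pre + k * per : pre + (k + 1) * per] = rates[k, 1]

    inv_scale = 1.0 / config.scale
    count_a, count_b, ok = run_lif_trial(
        config.n_group,
        config.n_group,
        config.n_e,
        config.n_i,
        config.w_plus,
        config.w_minus,
        config.cm_e,
        config.gl_e,
        config.cm_i,
        config.gl_i,
        config.v_leak,
        config.v_thresh,
        config.v_reset,
        config.v_exc,
        config.v_inh,
        int(round(config.tau_ref_e / dt)),
        int(round(config.tau_ref_i / dt)),
        config.g_ext_ampa_e,
        config.g_ext_ampa_i,
        config.g_ampa_ee * inv_scale,
        config.g_ampa_ei * inv_scale,
        config.g_nmda_ee * inv_scale,
        config.g_nmda_ei * inv_scale,
        config.g_gaba_e * inv_scale,
        config.g_gaba_i * inv_scale,
        config.tau_ampa,
        config.tau_nmda_rise,
        config.tau_nmda_decay,
        config.alpha_nmda,
        config.tau_gaba,
        config.mg,
        config.background_rate,
        stim_a,
        stim_b,
        dt,
        n_steps,
        bin_steps,
        config.ext_stride,
        int(rng.integers(2**31)),
    )
    if not ok:
        raise FloatingPointError("membrane state diverged (non-finite)")
    r_a = filter_rates(count_a, config.n_group, config)
    r_b = filter_rates(count_b, config.n_group, config)
    time = np.arange(len(r_a)) * config.rate_bin
    t_offset = config.pre_stimulus + trial.n_samples * config.sample_duration
    return RateTrace(time, r_a, r_b, t_offset)


def read_choice(trace: RateTrace, config: SpikingConfig, rng=None) -> str:
    """"A"/"B" from the filtered rates at readout (2 s after offset);
    exact ties are broken uniformly at random."""
    t_read = trace.t_offset + config.readout_delay
    if trace.time[-1] + config.rate_bin < t_read - 1e-9:
        raise ValueError("trace does not extend to the readout instant")
    idx = min(int(round(t_read / config.rate_bin)), len(trace.time) - 1)
    ra, rb = trace.r_a[idx], trace.r_b[idx]
    if ra == rb:
        if rng is None:
            raise ValueError("tie at readout requires an rng")
        return "A" if rng.random() < 0.5 else "B"
    return "A" if ra > rb else "B"


def run_trials(
    trials,
    config: SpikingConfig,
    rng=None,
    seed: Optional[int] = None,
) -> ChoiceSet:
    """Simulate a TrialSet; one independent substream per trial.

    Provide ``seed`` (preferred: reproducible independently of execution
    order) or an ``rng`` from which a master seed is drawn.
    """
    if seed is None:
        if rng is None:
            raise ValueError("provide seed or rng")
        seed = int(rng.integers(2**31))
    trial_list = list(trials)
    chose_left = np.zeros(len(trial_list), dtype=bool)
    for i, trial in enumerate(trial_list):
        sub = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        trace = run_trial(trial, config, sub)
        chose_left[i] = read_choice(trace, config, sub) == "A"
    correct = np.array(
        [(correct_side(t) == "left") == c for t, c in zip(trial_list, chose_left)]
    )
    ts = trials if isinstance(trials, TrialSet) else TrialSet(trial_list, {}, seed)
    return ChoiceSet(ts, chose_left, correct)
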