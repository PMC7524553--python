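# Full-size spiking circuit parameter set (SI units).
# This file records the adopted constants; provar.spiking.SpikingConfig
# carries identical defaults and is the programmatic source of truth
# (a test asserts the two never drift apart).
n_e: 1600
n_i: 400
n_group: 240
w_plus: 1.75          # canonical 1.7 sits at the bistability edge here; see docs/methods.md
cm_e: 0.5e-9          # F
gl_e: 25.0e-9         # S
cm_i: 0.2e-9
gl_i: 20.0e-9
v_leak: -70.0e-3      # V
v_thresh: -50.0e-3
v_reset: -55.0e-3
v_exc: 0.0
v_inh: -70.0e-3
tau_ref_e: 2.0e-3     # s
tau_ref_i: 1.0e-3
g_ext_ampa_e: 2.1e-9  # S
g_ext_ampa_i: 1.62e-9
g_ampa_ee: 0.05e-9
g_ampa_ei: 0.04e-9
g_nmda_ee: 0.165e-9
g_nmda_ei: 0.13e-9
g_gaba_e: 1.3e-9
g_gaba_i: 1.0e-9
tau_ampa: 2.0e-3
tau_nmda_rise: 2.0e-3
tau_nmda_decay: 100.0e-3
alpha_nmda: 500.0     # 1/s
tau_gaba: 5.0e-3
mg: 1.0               # mM
background_rate: 2400.0  # Hz
mu0: 30.0             # Hz at h = 50
mu_prime: 1.0         # Hz per evidence unit
sensory_deficit: 0.0
sample_duration: 0.25 # s
pre_stimulus: 0.5
readout_delay: 2.0
filter_tau: 0.02
rate_bin: 1.0e-3
dt: 2.0e-5
ext_stride: 1
scale: 1.0
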