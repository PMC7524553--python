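# Mean-field reduction parameter set (currents in nA, times in s).
# provar.meanfield.MeanFieldParams carries identical defaults; a test
# asserts the two never drift apart.
tau_nmda: 0.100
gamma: 0.641
alpha1: 0.2609
alpha2: -0.0497
beta1: 0.0
beta2: 0.0
a: 270.0      # Hz per nA
b: 108.0      # Hz
d: 0.154      # s
f0: 0.0
f1: 0.0
i0: 0.3255
j_ext: 5.2e-4 # nA per Hz of input rate
mu0: 30.0
mu_prime: 1.0
sensory_deficit: 0.0
sigma_noise: 0.007   # OU amplitude; package choice, see docs/methods.md
tau_noise: 0.002
noise_stride: 4
dt: 1.0e-4
sample_duration: 0.25
readout_delay: 2.0
s_init: 0.1
alpha_inh: 0.1       # E/I-surrogate decomposition constant
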