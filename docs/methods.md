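# Methods

This note documents the models and procedures implemented in `provar`,
the parameter choices behind them, and what the synthetic-data tests do
and do not establish.

## Task and stimulus generation (`provar.trialgen`)

The task presents two streams of 4/6/8 bar heights (integer percentiles
1–99) and asks for the stream with the taller (ChooseTall) or shorter
(ChooseShort) average. All analyses operate on *context-mapped
evidence*: the bar height on ChooseTall trials, 100 − height on
ChooseShort trials, so both contexts share one pathway.

**Regular trials.** Each side independently draws a type (narrow,
σ = 12, or broad, σ = 24, with P(narrow) = 0.5, so ≈25% of trials are
narrow/narrow, ≈25% broad/broad, ≈50% mixed), a generative mean
μ = 50 + Z·σ with Z ~ U(−0.25, 0.25), and then heights from N(μ, σ).
A whole stream is rejected and redrawn unless every height lies in
[1, 99] and the realized sample SD is within 4 of σ. Rejection
regenerates the entire stream, which is unbiased within the constraint
set; the attempt cap (10,000) signals an infeasible configuration
rather than looping forever.

A consequence of this procedure worth stating explicitly: the *mean
realized sample SD* of accepted streams is below the generative σ —
the sample SD of n = 8 Gaussian draws is biased low (E[s] = c₄(8)·σ ≈
0.965·σ) and the [1, 99] range constraint preferentially rejects
broad streams with extreme samples. Direct simulation of the procedure
gives 11.66 (narrow) and 23.41 (broad); the tests assert these oracle
values, not the nominal 12/24.

**Narrow-Broad trials.** One narrow and one broad stream with
controlled mean offsets: NarrowCorrect (μ_N ~ U(48, 60), μ_B = μ_N − 8),
BroadCorrect (mirrored), Ambiguous (equal means, μ_B ~ U(44, 56)).
Realized mean differences are constrained to [2, 14] in favour of the
correct stream (NarrowCorrect/BroadCorrect) or |diff| < 4 (Ambiguous);
the ±4 SD constraint applies throughout. Streams are assigned to
left/right at random.

**Half-Half trials.** Both options share a base distribution
N(μ_HH, 12), μ_HH ~ U(40, 60). The TallFirst option draws its first
half from the base distribution truncated below at μ_HH − 0.5·12 and
its second half truncated above at μ_HH + 0.5·12; ShortFirst reverses
the order. The strong half must exceed the weak half by ≥ 7.5 on
average. Two genuinely open choices were resolved as follows: the
truncation bounds use the *generative* μ and σ (not realized sample
statistics of a particular draw), which makes the two options
exchangeable by construction; and the ±4 SD constraint is *not*
applied to Half-Half streams (it is stated only for Regular and
Narrow-Broad generation).

**Rounding.** Heights are rounded to integer percentiles *after* the
constraint checks (the display has integer resolution), so a rounded
trial can sit marginally outside the raw constraints — the same
order of operations the task's stimulus software used. Generators accept
`round_heights=False` for analyses that need the raw draws.

**Pharmacological variant.** 6 samples; Regular and Half-Half trials
must additionally have a mean-evidence difference > 4; of the
Narrow-Broad family only Ambiguous trials are produced, with no added
constraint.

**Synthetic choice agent.** A logistic chooser with
P(left) = λ + (1 − 2λ)·logistic(β₀ + β_mean·Δmean + β_sd·Δsd) on
context-mapped evidence (optionally per-sample weights in place of the
mean term). It exists to give the statistics pipeline a ground truth:
every fitter is validated by recovering the agent's parameters.

Contexts are assigned with equal probability per trial; the blocked
context schedule of the experiment is out of scope.

## Spiking circuit (`provar.spiking`)

A two-population winner-take-all attractor network of leaky
integrate-and-fire neurons: N_E = 1600 pyramidal cells (two selective
groups of 240 plus a nonselective remainder) and N_I = 400
interneurons, all-to-all connected; AMPA + NMDA recurrent excitation,
GABA_A inhibition, and independent external AMPA Poisson input per
neuron (2400 Hz background). Within-group connections are potentiated
by w⁺ and connections onto a selective group from outside depressed to
w⁻ = 1 − f(w⁺ − 1)/(1 − f), f = 240/1600, preserving total weight.
Membrane, synaptic and conductance constants are the canonical
published set of this model family, exposed in full on
`SpikingConfig` (conductances: external AMPA 2.1/1.62 nS on E/I,
recurrent AMPA 0.05/0.04 nS, NMDA 0.165/0.13 nS, GABA 1.3/1.0 nS;
NMDA kinetics τ_rise = 2 ms, τ_decay = 100 ms, α = 0.5 kHz, Mg²⁺ 1 mM).

One deliberate departure: w⁺ = 1.75 (canonical 1.7). At 1.7 this
implementation sits at the edge of the bistable regime — the choice
attractor decays during the 2 s post-stimulus delay — and a small
increase places it safely inside, restoring the persistent state
(> 30 Hz winner against a ~2 Hz baseline) that the readout depends
on. We treat this as one of the "minor modifications" any concrete
realisation of this architecture needs.

**Stimulus.** Each evidence sample drives its selective group with an
extra Poisson rate μ = μ₀ + μ′·(1 − sensory_deficit)·(h − 50), with
μ₀ = 30 Hz, μ′ = 1 Hz per evidence unit, held for 250 ms with no
inter-sample gap. Evidence h is identical for all neurons of a group;
the Poisson processes are independent across neurons.

**Readout.** Spikes of the two selective groups are binned at 1 ms and
causally filtered (kernel (1/τ)·e^{−Δt/τ}, τ = 20 ms); the choice is
the group with the higher filtered rate 2 s after stimulus offset,
exact ties broken uniformly at random.

**Perturbations.** Lowered E/I: G_NMDA(E→E) reduced by 1.3125%;
elevated E/I: G_NMDA(E→I) reduced by 2.625%; sensory deficit: μ′
reduced by 20%. `apply_perturbation` composes these functionally
(the input config is never mutated).

**Desk scaling.** Full-size simulation at dt = 0.02 ms costs tens of
seconds per trial; `desk_config()` provides the configuration used by
the test suite: neuron counts scaled by 1/8 (200/50, groups of 30)
with recurrent conductances rescaled by the inverse factor (preserving
the mean recurrent drive), dt = 0.1 ms, a 0.5 s pre-stimulus
settling period, and w⁺ = 1.8 — the finite-size analogue of the
full-size persistence adjustment above (group-sum fluctuations at 30
neurons/group destabilise the attractor at smaller w⁺). Desk scale is
substantially noisier than full size: accuracies and regression
coefficients are compressed, and full-scale test statistics are not
reproducible. The Ambiguous-trial broad preference survives the
reduction well (0.535 ± 0.010 at 1/8 scale, measured over 2,400
trials), but the Broad-correct vs Narrow-correct accuracy gap — which
scales roughly as β_mean × PVB index × Δsd and is therefore doubly
compressed — shrinks to an estimated 1–3 percentage points, below
what any desk-scale trial count can certify; demonstrating it needs
full-size runs through the runner/CLI. Integration is forward Euler; the NMDA gating ODE (with its
saturation term) is stepped explicitly, all linear synaptic decays
exactly.

## Mean-field reduction (`provar.meanfield`)

The two-variable reduction tracks the NMDA gating fractions S₁, S₂ of
the selective populations:

    dS_i/dt = −S_i/τ_NMDA + (1 − S_i)·γ·r_i,   τ_NMDA = 100 ms, γ = 0.641

with rates from the transfer function
r = (a·x − f(x_other) − b)/(1 − exp(−d·(a·x − f(x_other) − b))) and
effective inputs x_i = α₁S_i + α₂S_j + I₀ + I_ext,i + I_noise,i.
Constants are the standard published values of this reduction:
a = 270 Hz/nA, b = 108 Hz, d = 0.154 s, α₁ = 0.2609 nA,
α₂ = −0.0497 nA, I₀ = 0.3255 nA, external coupling
J_ext = 5.2·10⁻⁴ nA/Hz; the AMPA recurrence terms (β₁, β₂) and the
cross-transfer function f are exposed but default to zero, their
effect being absorbed into the NMDA couplings — the convention of the
reduction. The removable singularity of the transfer function at zero
is evaluated by its analytic limit 1/d; the expansive non-linearity
(positive second derivative between threshold and linear regimes) is
what generates the pro-variance bias.

**Stimulus and noise.** Stimulus currents reuse the spiking circuit's
evidence-to-rate mapping scaled by J_ext (0.0156 nA at h = 50),
250 ms per sample, stimulus off during the 2 s readout delay.
Stochasticity enters as an Ornstein–Uhlenbeck background current per
population, τ_noise = 2 ms, amplitude σ_noise = 0.007 nA (stationary
SD σ/√2). The amplitude is a package choice — the published run does
not print its noise parameters — selected once so the control model
sits in the published behavioural regime (accuracy ≈ 0.69, both
regression coefficients overwhelmingly significant at 94k trials,
PVB index ≈ 0.1); below ~0.01 nA the PVB index is insensitive to the
exact value.

**Integration.** Forward Euler at dt = 0.1 ms (halving dt leaves test
trajectories unchanged at the asserted tolerances). The OU noise uses
its exact discretisation, renewed every 4 steps (0.4 ms ≪ τ_noise)
and held in between; S is clipped to [0, 1] only against
floating-point overshoot. Batches are integrated with all trials in
parallel (a fused numba loop with a xorshift64* Gaussian stream),
which makes the 94,000-trial replication a ~2-minute computation; a
pure-numpy reference path (also used whenever trajectories are
recorded) implements the identical process.

**Phase-plane utilities.** `nullclines` brackets sign changes of each
drift on a grid and refines them with Brent's method (every returned
point satisfies |dS/dt| < 10⁻⁸); `net_drive_diagonal` evaluates
dS₁/dt − dS₂/dt along S₁ = S₂, the quantity that shows a momentarily
strong stimulus pulling the system toward its population more than a
weak one pushes it away.

**E/I surrogate.** `apply_meanfield_perturbation` maps conductance
perturbations onto the reduced couplings through the decomposition
α_i = (excitatory part) − α_inh, with α_inh = 0.1 nA modelling
inhibition routed through the interneuron pool. This surrogate is
provided for exploration only: its perturbation phenomenology differs
mechanistically from the spiking circuit's (in particular, small
reductions of the excitatory part initially *improve* performance
here), so perturbation conclusions in this package are drawn from the
spiking backend, and the mean-field model is used for the control
condition, which is also where this model family is on firmest
ground.

## Behavioural statistics (`provar.behavstats`)

Psychometric curves: accuracy P(x) = 0.5 + 0.5(1 − exp(−(x/α)^β)) of
evidence strength, and a signed, shifted variant for the probability
of choosing the higher-SD option, with an optional fixed lapse Y₀
bounding the asymptotes at Y₀ and 1 − Y₀. Both are fitted by
maximum likelihood (Nelder–Mead on log-transformed α, β with
restarts).

Choice regressions (context-mapped evidence throughout): temporal
weights (per-sample L−R differences), the mean/SD model (Δmean, Δsd —
the pro-variance model), a 12-regressor full model (per-side mean,
SD, max, min, first, last), the same without the SD terms (used
because SD, max and min are strongly correlated), and a local-wins
model. Sample SDs use the n−1 convention. Local wins: per sample the
side with strictly greater mapped evidence scores one win; ties score
neither side (symmetric and conservative; the defining example has no
ties). Plain fits use IRLS logistic regression (statsmodels) with
information-matrix SEs; perfect separation raises an error naming the
most suspicious column.

Lapse-augmented models fit P(left) = Y₀ + (1 − 2Y₀)·logistic(Xβ) by
penalised MLE: the objective is the negative log-likelihood plus
λ·(Σβ² + Y₀²) with λ = 0.01, minimised by Nelder–Mead (the simplex
method, the fitting convention for these lapse models) from 10 starts — the
first at the plain-GLM solution — followed by re-polish from the
incumbent until no improvement, tolerance 10⁻⁸. Y₀ is constrained to
[0, 0.5] via a sigmoid reparameterisation (the penalty applies to Y₀
itself). Standard errors for these fits come from the
case-resampling bootstrap only; penalisation invalidates asymptotic
SEs. A caution from the recovery tests: when evidence saturates
choice probabilities only mildly (|logit| ≲ 2–3), Y₀ and the slope
trade off along a flat likelihood ridge, so Y₀ is identified at
CI-scale rather than SE-scale precision.

The **PVB index** is β_sd/β_mean from the mean/SD model; it is
undefined (raised as an error) when β_mean ≤ 0. Model comparison uses
repeated 10-fold cross-validated held-out log-likelihood (100
repetitions averaged; unpenalised likelihoods for non-lapse models).

## Permutation inference (`provar.permtests`)

The PVB permutation test pools the trials of two conditions,
repeatedly reassigns them to groups of the original sizes, and
recomputes the index difference; p-values are two-sided via the
absolute difference with the add-one convention
p = (1 + #{|null| ≥ |observed|})/(1 + n_perm), which is strictly
positive and uniform under the null. Defaults: 10⁶ permutations for
scalar tests, 10⁴ for lapse-model and cluster tests (all
configurable; the tests here use smaller counts sized to their
assertions). A permutation whose refit fails (non-positive mean
coefficient) is redrawn and counted.

Time courses evaluate accuracy or the PVB index per session in 6 min
sliding windows stepped by 1 min around the injection; empty windows
are flagged missing (NaN), never imputed. The cluster test thresholds
the session-averaged |difference| series at 0.15, takes maximal
suprathreshold runs as clusters, and builds the null from the largest
cluster length under session-label permutation; a cluster is
significant when longer than the null's 95th percentile.

`split_total_evidence` median-splits trials by total context-mapped
evidence (ties to the low half, halves within one trial of each
other). `apply_downstream_lapse` replaces each choice with a fair
coin flip with probability λ; since random choices are correct half
the time, the fitted lapse of such data is ≈ λ/2.

## Comparison metrics (`provar.compare`)

Perturbation effects are summarised as relative coefficient changes
(δβ_mean, δβ_sd) against a reference fit, compared by cosine
similarity and Euclidean distance. The choice-probability divergence
Σ_x P(x)·log(P(x)/Q(x)) over x_HSD bins is implemented verbatim as the
default — note it is not a KL divergence over a normalised
distribution and can be negative — with a proper per-bin Bernoulli KL
(non-negative, zero iff equal) behind `variant="bernoulli"`. Binning
of x_HSD uses caller-supplied equal-width edges; empty bins and zero
model probabilities raise rather than being floored.
`parameter_scan_compare` evaluates these metrics over a perturbation
grid, tagging failures per grid point.

## Orchestration and problem sizes (`provar.runner`)

`run_control_replication` and `run_perturbation_suite` wire the
stages together (generation → simulation → fits → permutation tests)
with one master seed, per-stage derived substreams, per-stage wall
time and config-hash logging, and CSV/JSON outputs. Within a suite
every condition simulates the *identical* trial set (asserted by a
trial-table hash), the paired design used for perturbation
comparisons.

Problem sizes in the shipped test suite are desk-scale choices:
mean-field replication at the full 94,000 trials; spiking
Narrow-Broad behaviour at 2,000 trials on the 1/8-scale circuit;
statistics calibration at 20,000 agent trials with a 100-resample
bootstrap. Full-size spiking replications (tens of thousands of
trials) are long-running jobs to be launched through the runner/CLI,
not the test suite.

## What the synthetic data do and do not show

The generator reproduces the stimulus statistics of the task exactly
(by construction and by test), and the logistic agent gives the
statistics pipeline a known ground truth — so passing tests establish
correctness of the estimators, the permutation calibration, and the
circuit models' qualitative behaviour under the task's stimulus
distribution. They do not establish anything about real behavioural
data: the agent lapses independently of trial difficulty and time,
sessions are exchangeable by construction (no drift, no satiation, no
block structure), and evidence is used without sensory noise. The
deposited-data reader is exercised on synthetic stand-in sessions
only; reproducing the published subject-level indices requires
downloading the archive.

## Known limitations

- The spiking parameter table realises the cited model family; the
  published descriptions of this architecture leave room for "minor
  modifications" whose exact values are not printed, and w⁺ was adjusted (1.75 full-size, 1.8 at 1/8 scale) to
  keep the choice attractor persistent. Quantitative coefficient
  magnitudes at desk scale are therefore indicative, not calibrated.
- The mean-field noise amplitude is a package choice (see above);
  printed t-statistics are matched in order of magnitude, not value.
- The mean-field E/I surrogate does not reproduce the spiking
  circuit's perturbation phenomenology and is not used for
  perturbation claims.
- No reaction-time modelling (the task has none), no hierarchical
  pooling across sessions, no fitting of circuit parameters to data.
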