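"""Stimulus generation for the two-stream bar-height evidence task.

Each trial presents two streams of 4/6/8 bar heights (percentile units,
1-99).  Regular trials draw each stream independently from a Gaussian
whose mean is itself jittered (``mu = 50 + Z*sigma``, ``Z ~ U(-0.25,
0.25)``) and whose SD is either narrow (12) or broad (24).  Narrow-Broad
trials pit a narrow stream against a broad one with controlled mean
offsets; Half-Half trials manipulate the temporal order of strong/weak
evidence.  All generators use rejection sampling so that every emitted
trial satisfies the published constraints exactly.

A configurable logistic choice agent (optionally lapsing) is provided to
produce synthetic choice data for parameter-recovery tests of the
behavioural-statistics pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "NARROW_SD",
    "BROAD_SD",
    "HEIGHT_MIN",
    "HEIGHT_MAX",
    "SD_TOLERANCE",
    "AttemptCapExceeded",
    "GenerativeParams",
    "StimulusStream",
    "Trial",
    "TrialSet",
    "GenConfig",
    "AgentSpec",
    "ChoiceSet",
    "generate_regular_trial",
    "generate_narrow_broad_trial",
    "generate_half_half_trial",
    "generate_trialset",
    "evidence_for_context",
    "trial_evidence",
    "correct_side",
    "simulate_logistic_agent",
]

NARROW_SD = 12.0
BROAD_SD = 24.0
HEIGHT_MIN = 1.0
HEIGHT_MAX = 99.0
#: realized sample SD must be within this distance of the generative SD
SD_TOLERANCE = 4.0

REGULAR = "Regular"
NARROW_CORRECT = "NarrowCorrect"
BROAD_CORRECT = "BroadCorrect"
AMBIGUOUS = "Ambiguous"
HALF_HALF = "HalfHalf"
CONDITIONS = (REGULAR, NARROW_CORRECT, BROAD_CORRECT, AMBIGUOUS, HALF_HALF)

CHOOSE_TALL = "ChooseTall"
CHOOSE_SHORT = "ChooseShort"


class AttemptCapExceeded(RuntimeError):
    """Rejection sampling failed to produce a valid trial within the cap."""


@dataclass(frozen=True)
class GenerativeParams:
    """Generative parameters of one stimulus stream.

    ``stream_type`` is "narrow"/"broad" for Gaussian streams, or
    "tall_first"/"short_first" for the temporally structured Half-Half
    streams (which use the narrow SD).
    """

    mu: float
    sigma: float
    stream_type: str
    z: float = 0.0


@dataclass(frozen=True)
class StimulusStream:
    heights: np.ndarray
    params: GenerativeParams

    @property
    def mean(self) -> float:
        return float(np.mean(self.heights))

    @property
    def sd(self) -> float:
        return float(np.std(self.heights, ddof=1))


@dataclass(frozen=True)
class Trial:
    left: StimulusStream
    right: StimulusStream
    context: str
    condition: str

    @property
    def n_samples(self) -> int:
        return len(self.left.heights)


@dataclass
class TrialSet:
    trials: list[Trial]
    composition: dict[str, float]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i) -> Trial:
        return self.trials[i]


@dataclass(frozen=True)
class GenConfig:
    """Settings shared by all trial generators.

    ``pharma=True`` reproduces the modified task of the pharmacological
    sessions: 6 evidence samples, Regular and Half-Half trials must have
    a mean-evidence difference exceeding ``pharma_min_diff``, and of the
    Narrow-Broad family only Ambiguous trials are produced (with no
    added constraint).
    """

    n_samples: int = 8
    narrow_prob: float = 0.5  # per-side P(narrow) on Regular trials
    round_heights: bool = True
    pharma: bool = False
    pharma_min_diff: float = 4.0
    max_attempts: int = 10_000
    context_prob_tall: float = 0.5

    def __post_init__(self):
        if self.pharma and self.n_samples == 8:
            object.__setattr__(self, "n_samples", 6)
        if self.n_samples < 2:
            raise ValueError("need at least two evidence samples")


@dataclass(frozen=True)
class AgentSpec:
    """Synthetic logistic chooser.

    P(choose left) = lapse + (1 - 2*lapse) * logistic(beta0 +
    beta_mean*dmean + beta_sd*dsd), where dmean/dsd are the left-right
    differences of the context-mapped evidence mean and sample SD.  When
    ``sample_weights`` is given it replaces the beta_mean*dmean term by a
    per-sample weighted sum of evidence differences.
    """

    beta0: float = 0.0
    beta_mean: float = 0.1
    beta_sd: float = 0.02
    lapse: float = 0.0
    sample_weights: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")


@dataclass
class ChoiceSet:
    """Trials plus one binary choice per trial; the common currency of
    all downstream statistics."""

    trials: TrialSet
    chose_left: np.ndarray
    correct: np.ndarray
    epoch: Optional[np.ndarray] = None
    session_id: Optional[object] = None
    time_min: Optional[np.ndarray] = None

    def __post_init__(self):
        self.chose_left = np.asarray(self.chose_left, dtype=bool)
        self.correct = np.asarray(self.correct, dtype=bool)
        if len(self.chose_left) != len(self.trials):
            raise ValueError("one choice per trial required")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.correct))


# ---------------------------------------------------------------------------
# stream / trial construction


def _draw_stream(rng, mu, sigma, n, stream_type, z, cap) -> StimulusStream:
    # Constraints are checked on the raw (pre-rounding) draw; the whole
    # stream is regenerated on failure, keeping the Gaussian shape.
    for _ in range(cap):
        h = rng.normal(mu, sigma, n)
        if h.min() < HEIGHT_MIN or h.max() > HEIGHT_MAX:
            continue
        if abs(np.std(h, ddof=1) - sigma) > SD_TOLERANCE:
            continue
        return StimulusStream(h, GenerativeParams(mu, sigma, stream_type, z))
    raise AttemptCapExceeded(
        f"no valid stream after {cap} attempts (mu={mu}, sigma={sigma})"
    )


def _round_trial(trial: Trial) -> Trial:
    # Display rounding happens after the constraint checks (the screen
    # has integer percentile resolution), so a rounded trial may sit
    # marginally outside the raw constraints.
    def r(s: StimulusStream) -> StimulusStream:
        return StimulusStream(np.rint(s.heights), s.params)

    return replace(trial, left=r(trial.left), right=r(trial.right))


def _pick_context(rng, config: GenConfig) -> str:
    return CHOOSE_TALL if rng.random() < config.context_prob_tall else CHOOSE_SHORT


def generate_regular_trial(rng, config: GenConfig = GenConfig()) -> Trial:
    """Generate one Regular trial.

    Each side independently draws a narrow/broad type (P(narrow) =
    ``config.narrow_prob``), a generative mean ``mu = 50 + Z*sigma`` with
    ``Z ~ U(-0.25, 0.25)``, then samples heights with rejection until all
    lie in [1, 99] and the realized SD is within 4 of the generative SD.
    In pharma mode the two streams must additionally differ in mean
    evidence by more than ``config.pharma_min_diff``.
    """
    cap = config.max_attempts
    context = _pick_context(rng, config)
    for _ in range(cap):
        streams = []
        for _side in ("left", "right"):
            stype = "narrow" if rng.random() < config.narrow_prob else "broad"
            sigma = NARROW_SD if stype == "narrow" else BROAD_SD
            z = rng.uniform(-0.25, 0.25)
            streams.append(
                _draw_stream(rng, 50.0 + z * sigma, sigma, config.n_samples, stype, z, cap)
            )
        trial = Trial(streams[0], streams[1], context, REGULAR)
        if config.pharma:
            if abs(trial.left.mean - trial.right.mean) <= config.pharma_min_diff:
                continue
        return _round_trial(trial) if config.round_heights else trial
    raise AttemptCapExceeded(f"no valid Regular trial after {cap} attempts")


def generate_narrow_broad_trial(
    condition: str, rng, config: GenConfig = GenConfig()
) -> Trial:
    """Generate a NarrowCorrect / BroadCorrect / Ambiguous trial.

    NarrowCorrect: mu_N ~ U(48, 60), mu_B = mu_N - 8; the realized mean
    difference (correct minus incorrect stream) must lie in [2, 14].
    BroadCorrect mirrors this.  Ambiguous: mu_B ~ U(44, 56), mu_N =
    mu_B, realized |difference| < 4.  Streams are assigned to left/right
    at random.  In pharma mode only Ambiguous is available and the mean
    constraint is dropped.
    """
    if condition not in (NARROW_CORRECT, BROAD_CORRECT, AMBIGUOUS):
        raise ValueError(f"unknown Narrow-Broad condition: {condition}")
    if config.pharma and condition != AMBIGUOUS:
        raise ValueError("pharma sessions use only Ambiguous Narrow-Broad trials")
    cap = config.max_attempts
    context = _pick_context(rng, config)
    n = config.n_samples
    for _ in range(cap):
        if condition == NARROW_CORRECT:
            mu_n = rng.uniform(48.0, 60.0)
            mu_b = mu_n - 8.0
        elif condition == BROAD_CORRECT:
            mu_b = rng.uniform(48.0, 60.0)
            mu_n = mu_b - 8.0
        else:
            mu_b = rng.uniform(44.0, 56.0)
            mu_n = mu_b
        narrow = _draw_stream(rng, mu_n, NARROW_SD, n, "narrow", 0.0, cap)
        broad = _draw_stream(rng, mu_b, BROAD_SD, n, "broad", 0.0, cap)
        diff = narrow.mean - broad.mean  # narrow minus broad, raw heights
        if not config.pharma:
            if condition == NARROW_CORRECT and not 2.0 <= diff <= 14.0:
                continue
            if condition == BROAD_CORRECT and not 2.0 <= -diff <= 14.0:
                continue
            if condition == AMBIGUOUS and abs(diff) >= 4.0:
                continue
        if rng.random() < 0.5:
            trial = Trial(narrow, broad, context, condition)
        else:
            trial = Trial(broad, narrow, context, condition)
        return _round_trial(trial) if config.round_heights else trial
    raise AttemptCapExceeded(f"no valid {condition} trial after {cap} attempts")


def _draw_half_half_option(rng, mu, order, n, cap) -> StimulusStream:
    # Truncation bounds use the generative parameters: X_tall >= mu -
    # 0.5*sigma, X_short <= mu + 0.5*sigma, sigma = 12.
    lo = mu - 0.5 * NARROW_SD
    hi = mu + 0.5 * NARROW_SD
    half = n // 2
    for _ in range(cap):
        tall = np.empty(half)
        k = 0
        while k < half:
            x = rng.normal(mu, NARROW_SD)
            if x >= lo:
                tall[k] = x
                k += 1
        short = np.empty(half)
        k = 0
        while k < half:
            x = rng.normal(mu, NARROW_SD)
            if x <= hi:
                short[k] = x
                k += 1
        if tall.mean() - short.mean() < 7.5:
            continue
        h = np.concatenate([tall, short] if order == "tall_first" else [short, tall])
        if h.min() < HEIGHT_MIN or h.max() > HEIGHT_MAX:
            continue
        return StimulusStream(h, GenerativeParams(mu, NARROW_SD, order, 0.0))
    raise AttemptCapExceeded(f"no valid Half-Half option after {cap} attempts")


def generate_half_half_trial(rng, config: GenConfig = GenConfig()) -> Trial:
    """Generate a Half-Half trial probing temporal weighting.

    Both options share one base distribution N(mu_HH, 12), mu_HH ~
    U(40, 60).  One option is TallFirst (first half from the upper
    truncation, second half from the lower), the other ShortFirst.  The
    strong half must exceed the weak half by at least 7.5 on average.
    """
    if config.n_samples % 2:
        raise ValueError("Half-Half trials need an even number of samples")
    cap = config.max_attempts
    context = _pick_context(rng, config)
    for _ in range(cap):
        mu = rng.uniform(40.0, 60.0)
        a = _draw_half_half_option(rng, mu, "tall_first", config.n_samples, cap)
        b = _draw_half_half_option(rng, mu, "short_first", config.n_samples, cap)
        if config.pharma and abs(a.mean - b.mean) <= config.pharma_min_diff:
            continue
        if rng.random() < 0.5:
            a, b = b, a
        trial = Trial(a, b, context, HALF_HALF)
        return _round_trial(trial) if config.round_heights else trial
    raise AttemptCapExceeded(f"no valid Half-Half trial after {cap} attempts")


_GENERATORS = {
    REGULAR: generate_regular_trial,
    HALF_HALF: generate_half_half_trial,
}


def generate_trialset(
    n_trials: int,
    composition: Optional[dict[str, float]] = None,
    config: GenConfig = GenConfig(),
    seed: int = 0,
) -> TrialSet:
    """Generate ``n_trials`` trials with the given condition mixture.

    Every trial draws from its own deterministic substream of ``seed``
    (via ``numpy.random.SeedSequence`` spawn keys), so regeneration with
    the same seed is bit-identical and independent of chunking.
    """
    if composition is None:
        composition = {REGULAR: 1.0}
    total = sum(composition.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"composition fractions must sum to 1, got {total}")
    for cond in composition:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
    conds = sorted(composition)
    probs = np.array([composition[c] for c in conds])
    trials = []
    for i in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        cond = conds[rng.choice(len(conds), p=probs)]
        if cond in _GENERATORS:
            trials.append(_GENERATORS[cond](rng, config))
        else:
            trials.append(generate_narrow_broad_trial(cond, rng, config))
    return TrialSet(trials, dict(composition), seed)


# ---------------------------------------------------------------------------
# evidence mapping and choice agents


def evidence_for_context(trial: Trial, side: str) -> np.ndarray:
    """Map bar heights to momentary evidence h for the cued context.

    Evidence equals the bar height on ChooseTall trials and 100 minus
    the bar height on ChooseShort trials, mirroring the remapping
    assumed upstream of the decision circuit.
    """
    stream = trial.left if side == "left" else trial.right
    h = np.asarray(stream.heights, dtype=float)
    if trial.context == CHOOSE_TALL:
        return h.copy()
    if trial.context == CHOOSE_SHORT:
        return 100.0 - h
    raise ValueError(f"unknown context {trial.context!r}")


def trial_evidence(trial: Trial) -> tuple[np.ndarray, np.ndarray]:
    """(left, right) context-mapped evidence arrays for one trial."""
    return evidence_for_context(trial, "left"), evidence_for_context(trial, "right")


def correct_side(trial: Trial) -> str:
    """Side with the greater context-mapped mean evidence ("left"/"right").

    Exact ties are labelled "left" by convention (they are measure-zero
    for continuous heights and near-impossible after rounding).
    """
    ev_l, ev_r = trial_evidence(trial)
    return "left" if ev_l.mean() >= ev_r.mean() else "right"


def agent_choice_probability(trials: TrialSet, agent: AgentSpec) -> np.ndarray:
    """Closed-form P(choose left) of the logistic agent for each trial."""
    p = np.empty(len(trials))
    w = None if agent.sample_weights is None else np.asarray(agent.sample_weights, float)
    for i, trial in enumerate(trials):
        ev_l, ev_r = trial_evidence(trial)
        dsd = np.std(ev_l, ddof=1) - np.std(ev_r, ddof=1)
        if w is not None:
            drive = float(w @ (ev_l - ev_r))
        else:
            drive = agent.beta_mean * (ev_l.mean() - ev_r.mean())
        logit = agent.beta0 + drive + agent.beta_sd * dsd
        p[i] = agent.lapse + (1.0 - 2.0 * agent.lapse) * expit(logit)
    return p


def simulate_logistic_agent(trials: TrialSet, agent: AgentSpec, rng) -> ChoiceSet:
    """Draw one Bernoulli choice per trial from the logistic agent."""
    p_left = agent_choice_probability(trials, agent)
    chose_left = rng.random(len(trials)) < p_left
    correct = np.array(
        [(correct_side(t) == "left") == c for t, c in zip(trials, chose_left)]
    )
    return ChoiceSet(trials, chose_left, correct)
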