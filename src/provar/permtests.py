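"""Permutation inference and condition-contrast utilities.

Covers the nonparametric machinery used to compare behavioural
conditions: a permutation test on the difference of pro-variance-bias
indices between two trial sets, sliding-window time courses of
accuracy or PVB around an injection, a cluster-based permutation test
over time bins (maximal suprathreshold run length against a
session-label-shuffled null), a median split by total evidence, and
injection of a downstream lapse process into existing choices.

p-values use the add-one convention p = (1 + #{null >= observed}) /
(1 + n_perm), which keeps them strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .trialgen import ChoiceSet, TrialSet, correct_side
from .behavstats import (
    DesignSpec,
    build_design,
    fit_choice_glm,
    fit_lapse_mle,
    pvb_index,
    evidence_summary,
)

__all__ = [
    "PermutationResult",
    "TimecourseSeries",
    "permutation_test_pvb",
    "binned_timecourse",
    "cluster_permutation",
    "split_total_evidence",
    "apply_downstream_lapse",
]


@dataclass
class PermutationResult:
    observed_stat: float
    null_size: int
    p_value: float
    seed: Optional[int] = None
    n_refit_failures: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class TimecourseSeries:
    """Per-session sliding-window statistic around an injection.

    ``values`` has shape (n_sessions, n_bins); bins with no trials in a
    session are NaN (flagged missing, never imputed).  ``mean`` is the
    across-session average ignoring missing bins.
    """

    bin_centers: np.ndarray  # minutes relative to injection
    values: np.ndarray
    window: float = 6.0
    step: float = 1.0

    @property
    def mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)


def _pvb_from_design(Xm, y, names):
    import statsmodels.api as sm

    res = sm.Logit(y, Xm).fit(disp=0, maxiter=200)
    coefs = dict(zip(names, res.params))
    if coefs["dmean"] <= 0:
        raise ValueError("undefined PVB regime")
    return coefs["dsd"] / coefs["dmean"]


def permutation_test_pvb(
    data_a: ChoiceSet,
    data_b: ChoiceSet,
    n_perm: int = 10_000,
    rng=None,
    include_lapse: bool = False,
    max_refit: int = 100,
) -> PermutationResult:
    """Two-sided permutation test of PVB(A) - PVB(B).

    Trials from both sets are pooled; each permutation reassigns them
    to two groups of the original sizes and recomputes the index
    difference.  A permutation whose fit fails (e.g. a non-positive
    mean coefficient) is redrawn, up to ``max_refit`` times in total.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(0) if rng is None else rng
    spec = DesignSpec("pvb", include_lapse=include_lapse)

    def index_of(data: ChoiceSet) -> float:
        X, y = build_design(data, spec)
        if include_lapse:
            res = fit_lapse_mle(X, y, spec.l2_lambda, rng=rng, n_restarts=3)
        else:
            res = fit_choice_glm(X, y, "pvb")
        return pvb_index(res)

    observed = index_of(data_a) - index_of(data_b)

    # pool the designs once; permutations only reshuffle row labels
    Xa, ya = build_design(data_a, DesignSpec("pvb"))
    Xb, yb = build_design(data_b, DesignSpec("pvb"))
    names = list(Xa.columns)
    Xp = np.vstack([np.asarray(Xa, float), np.asarray(Xb, float)])
    yp = np.concatenate([ya, yb])
    na = len(ya)
    n = len(yp)

    import pandas as pd

    def index_rows(rows):
        Xr, yr = Xp[rows], yp[rows]
        if include_lapse:
            res = fit_lapse_mle(
                pd.DataFrame(Xr, columns=names), yr, spec.l2_lambda, rng=rng, n_restarts=2
            )
            return pvb_index(res)
        return _pvb_from_design(Xr, yr, names)

    null = np.empty(n_perm)
    failures = 0
    i = 0
    while i < n_perm:
        idx = rng.permutation(n)
        try:
            d = index_rows(idx[:na]) - index_rows(idx[na:])
        except Exception:  # noqa: BLE001 — resample this permutation
            failures += 1
            if failures > max_refit:
                raise RuntimeError("too many permutation refit failures")
            continue
        null[i] = d
        i += 1
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_perm)
    return PermutationResult(observed, n_perm, float(p), n_refit_failures=failures)


# ---------------------------------------------------------------------------
# time courses


def _stat_accuracy(data: ChoiceSet, idx: np.ndarray) -> float:
    return float(np.mean(data.correct[idx]))


def _stat_pvb(data: ChoiceSet, idx: np.ndarray) -> float:
    sub = ChoiceSet(
        TrialSet([data.trials[i] for i in idx], {}, 0),
        data.chose_left[idx],
        data.correct[idx],
    )
    X, y = build_design(sub, DesignSpec("pvb"))
    return _pvb_from_design(np.asarray(X, float), y, list(X.columns))


def binned_timecourse(
    sessions: Sequence[ChoiceSet],
    statistic: str = "accuracy",
    window: float = 6.0,
    step: float = 1.0,
    t_range: Optional[tuple[float, float]] = None,
    min_trials: int = 1,
) -> TimecourseSeries:
    """Sliding-window statistic per session on injection-relative time.

    Each session must carry ``time_min`` (minutes relative to
    injection).  The statistic ("accuracy" or "pvb") is evaluated on
    the trials within +-window/2 of each bin centre; empty (or
    sub-``min_trials``) windows are NaN.
    """
    if statistic not in ("accuracy", "pvb"):
        raise ValueError("statistic must be 'accuracy' or 'pvb'")
    stat = _stat_accuracy if statistic == "accuracy" else _stat_pvb
    for s in sessions:
        if s.time_min is None:
            raise ValueError("sessions must carry time_min timestamps")
    if t_range is None:
        lo = min(float(np.min(s.time_min)) for s in sessions)
        hi = max(float(np.max(s.time_min)) for s in sessions)
    else:
        lo, hi = t_range
    centers = np.arange(np.floor(lo), np.ceil(hi) + step / 2, step)
    values = np.full((len(sessions), len(centers)), np.nan)
    half = window / 2.0
    for si, s in enumerate(sessions):
        t = np.asarray(s.time_min, float)
        for bi, c in enumerate(centers):
            idx = np.nonzero(np.abs(t - c) <= half)[0]
            if len(idx) < min_trials:
                continue
            try:
                values[si, bi] = stat(s, idx)
            except Exception:  # noqa: BLE001 — undefined statistic in window
                values[si, bi] = np.nan
    return TimecourseSeries(centers, values, window, step)


def _clusters(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive True bins as (start, length)."""
    out = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(above) - start))
    return out


def cluster_permutation(
    series_a: TimecourseSeries,
    series_b: TimecourseSeries,
    threshold: float = 0.15,
    n_perm: int = 10_000,
    rng=None,
):
    """Cluster-based permutation test on two session-series.

    The statistic per bin is |mean_A - mean_B| of the session-averaged
    series; clusters are maximal runs of bins exceeding ``threshold``.
    The null permutes session condition labels and records the largest
    cluster length; a cluster is significant (p < 0.05) when its length
    exceeds the 95th percentile of that null.  Returns a dict with
    clusters [(start, length, p_value, significant)] and the null
    distribution.
    """
    if not np.allclose(series_a.bin_centers, series_b.bin_centers):
        raise ValueError("series must share a bin grid")
    rng = np.random.default_rng(0) if rng is None else rng
    pooled = np.vstack([series_a.values, series_b.values])
    na = series_a.values.shape[0]
    n_total = pooled.shape[0]

    def max_cluster_len(va, vb):
        with np.errstate(invalid="ignore"):
            diff = np.abs(np.nanmean(va, axis=0) - np.nanmean(vb, axis=0))
        above = np.where(np.isnan(diff), False, diff >= threshold)
        cl = _clusters(above)
        return cl, max((length for _, length in cl), default=0)

    observed_clusters, _ = max_cluster_len(series_a.values, series_b.values)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(n_total)
        _, null[i] = max_cluster_len(pooled[perm[:na]], pooled[perm[na:]])
    crit = np.percentile(null, 95)
    results = []
    for start, length in observed_clusters:
        p = (1.0 + np.sum(null >= length)) / (1.0 + n_perm)
        results.append(
            dict(start=start, length=length, p_value=float(p), significant=length > crit)
        )
    return {"clusters": results, "null_max_lengths": null, "critical_length": float(crit)}


# ---------------------------------------------------------------------------
# condition splits and lapse injection


def split_total_evidence(data: ChoiceSet) -> tuple[ChoiceSet, ChoiceSet]:
    """Median split by total context-mapped evidence (summed over both
    streams).  Ties at the median go to the low half; the halves differ
    in size by at most one trial."""
    total = evidence_summary(data.trials)["total"].to_numpy()
    order = np.argsort(total, kind="stable")
    n = len(order)
    low_idx = np.sort(order[: (n + 1) // 2])
    high_idx = np.sort(order[(n + 1) // 2 :])

    def take(idx):
        return ChoiceSet(
            TrialSet([data.trials[i] for i in idx], {}, 0),
            data.chose_left[idx],
            data.correct[idx],
            epoch=None if data.epoch is None else np.asarray(data.epoch)[idx],
            session_id=data.session_id,
            time_min=None if data.time_min is None else np.asarray(data.time_min)[idx],
        )

    return take(high_idx), take(low_idx)


def apply_downstream_lapse(data: ChoiceSet, lapse: float, rng=None) -> ChoiceSet:
    """Replace each choice, independently with probability ``lapse``,
    by a uniformly random one (a lapse process downstream of the
    decision circuit).  Correctness is recomputed."""
    if not 0.0 <= lapse <= 1.0:
        raise ValueError("lapse must lie in [0, 1]")
    if lapse == 0.0:
        return ChoiceSet(
            data.trials,
            data.chose_left.copy(),
            data.correct.copy(),
            epoch=data.epoch,
            session_id=data.session_id,
            time_min=data.time_min,
        )
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(data)
    lapse_mask = rng.random(n) < lapse
    random_choice = rng.random(n) < 0.5
    chose_left = np.where(lapse_mask, random_choice, data.chose_left)
    correct = np.array(
        [
            (correct_side(t) == "left") == c
            for t, c in zip(data.trials, chose_left)
        ]
    )
    return ChoiceSet(
        data.trials,
        chose_left,
        correct,
        epoch=data.epoch,
        session_id=data.session_id,
        time_min=data.time_min,
    )
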