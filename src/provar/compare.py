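"""Quantitative comparison of perturbed-model and drug-induced
behavioural change.

The effect of a perturbation (circuit or pharmacological) is summarised
as the 2-vector of relative changes of the mean-evidence and
evidence-SD regression coefficients,

    d_mean = (beta_mean^pert - beta_mean^ref) / beta_mean^ref
    d_sd   = (beta_sd^pert  - beta_sd^ref)  / beta_sd^ref,

and two such vectors (subject drug effect vs model perturbation) are
compared by cosine similarity and Euclidean distance.  Choice
behaviour itself is compared by a KL-style divergence of the
probability of choosing the higher-SD option across evidence bins; the
default form sums P*log(P/Q) over bins verbatim (note it is not a KL
divergence over a normalised distribution and can be negative), with a
proper per-bin Bernoulli KL available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .behavstats import RegressionResult

__all__ = [
    "CoefDelta",
    "ComparisonMetrics",
    "coef_delta",
    "similarity_metrics",
    "kl_choice_divergence",
    "binned_hsd_choice_prob",
    "parameter_scan_compare",
]


@dataclass(frozen=True)
class CoefDelta:
    """Relative coefficient changes of a perturbation."""

    d_mean: float
    d_sd: float
    source: str = "model"

    def as_vector(self) -> np.ndarray:
        return np.array([self.d_mean, self.d_sd])


@dataclass
class ComparisonMetrics:
    cs: float  # cosine similarity, in [-1, 1]; NaN when undefined
    ed: float  # Euclidean distance, >= 0
    kl: Optional[float] = None
    condition: Optional[object] = None


def coef_delta(
    perturbed: RegressionResult, reference: RegressionResult, source: str = "model"
) -> CoefDelta:
    """Relative changes (perturbed - reference)/reference of the mean
    and SD coefficients.  Raises on a zero reference coefficient."""
    bm_ref = reference.coefficients["dmean"]
    bs_ref = reference.coefficients["dsd"]
    if bm_ref == 0 or bs_ref == 0:
        raise ValueError("reference coefficients must be nonzero")
    return CoefDelta(
        d_mean=(perturbed.coefficients["dmean"] - bm_ref) / bm_ref,
        d_sd=(perturbed.coefficients["dsd"] - bs_ref) / bs_ref,
        source=source,
    )


def similarity_metrics(subject: CoefDelta, model: CoefDelta) -> tuple[float, float]:
    """(cosine similarity, Euclidean distance) between the two delta
    vectors.  CS is NaN (flagged undefined) when either vector has zero
    norm."""
    u = subject.as_vector()
    v = model.as_vector()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    cs = float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else float("nan")
    ed = float(np.linalg.norm(u - v))
    return cs, ed


def kl_choice_divergence(
    p_subject: np.ndarray,
    p_model: np.ndarray,
    variant: str = "as_printed",
) -> float:
    """Divergence of binned choice probabilities (natural log).

    ``as_printed``: sum_x P_subject(x) * log(P_subject(x)/P_model(x)).
    ``bernoulli``: adds the complementary (1-P) term per bin, a proper
    KL that is zero iff the probabilities agree on every bin.

    Model probabilities of exactly 0 or 1 (where the ratio is
    undefined) raise rather than being silently floored; empty bins
    (NaN) also raise.
    """
    p = np.asarray(p_subject, dtype=float)
    q = np.asarray(p_model, dtype=float)
    if p.shape != q.shape:
        raise ValueError("probability vectors must share binning")
    if np.any(np.isnan(p)) or np.any(np.isnan(q)):
        raise ValueError("empty bins in choice probabilities")
    if variant == "as_printed":
        if np.any(q <= 0):
            raise ValueError("model probability of 0 in a bin")
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p / q), 0.0)
        return float(np.sum(terms))
    if variant == "bernoulli":
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("model probability of 0 or 1 in a bin")
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(p > 0, p * np.log(p / q), 0.0)
            t2 = np.where(p < 1, (1 - p) * np.log((1 - p) / (1 - q)), 0.0)
        return float(np.sum(t1 + t2))
    raise ValueError("variant must be 'as_printed' or 'bernoulli'")


def binned_hsd_choice_prob(
    x_hsd: np.ndarray,
    chose_hsd: np.ndarray,
    edges: np.ndarray,
    min_trials: int = 1,
) -> np.ndarray:
    """P(choose higher-SD option) per x_HSD bin; NaN where a bin holds
    fewer than ``min_trials`` trials."""
    x = np.asarray(x_hsd, float)
    c = np.asarray(chose_hsd, float)
    out = np.full(len(edges) - 1, np.nan)
    which = np.digitize(x, edges) - 1
    for b in range(len(out)):
        sel = which == b
        if sel.sum() >= min_trials:
            out[b] = float(np.mean(c[sel]))
    return out


def parameter_scan_compare(
    grid: Sequence,
    simulate_and_fit: Callable[[object], RegressionResult],
    reference: RegressionResult,
    subject: CoefDelta,
) -> pd.DataFrame:
    """Evaluate similarity metrics across a perturbation grid.

    ``simulate_and_fit`` maps one grid point (e.g. a PerturbationSpec)
    to the fitted mean/SD regression of the perturbed model.
    Simulation or fit failures are recorded per grid point rather than
    aborting the scan.  Returns a flat table (condition, d_mean, d_sd,
    cs, ed, error).
    """
    rows = []
    for point in grid:
        row = {"condition": point}
        try:
            fitted = simulate_and_fit(point)
            delta = coef_delta(fitted, reference)
            cs, ed = similarity_metrics(subject, delta)
            row.update(d_mean=delta.d_mean, d_sd=delta.d_sd, cs=cs, ed=ed, error="")
        except Exception as err:  # noqa: BLE001 — tag and continue
            row.update(d_mean=np.nan, d_sd=np.nan, cs=np.nan, ed=np.nan, error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)
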