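"""Psychometric and logistic-regression analyses of choice behaviour.

All statistics operate on a :class:`~provar.trialgen.ChoiceSet` and on
context-mapped evidence (bar height on ChooseTall trials, 100 minus bar
height on ChooseShort trials), so both contexts share one analysis
path.

Models
------
* Accuracy psychometric: ``P(x) = 0.5 + 0.5*(1 - exp(-(x/alpha)**beta))``
  of the evidence strength x in favour of the correct option.
* Higher-SD psychometric: a shifted, signed variant of the same curve
  for the probability of choosing the option whose samples have the
  larger SD, optionally with a fixed lapse ``Y0`` bounding the
  asymptotes at Y0 and 1-Y0.
* Choice logistic regressions: temporal weights (one coefficient per
  sample pair), the mean/SD ("pro-variance") model, a full 12-regressor
  model with per-side mean, SD, max, min, first and last samples, the
  same without the SD terms, and a local-wins ("frequent winner")
  model.
* Lapse-augmented logistic models fitted by penalised maximum
  likelihood (L2, lambda = 0.01) with a derivative-free simplex search
  and multiple restarts; the lapse Y0 is constrained to [0, 0.5].

The pro-variance bias (PVB) index is the ratio of the evidence-SD
coefficient to the mean-evidence coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .trialgen import ChoiceSet, Trial, trial_evidence

__all__ = [
    "PsychometricFit",
    "DesignSpec",
    "RegressionResult",
    "SeparationError",
    "psychometric_curve",
    "hsd_curve",
    "fit_psychometric",
    "local_wins",
    "build_design",
    "fit_choice_glm",
    "fit_lapse_mle",
    "fit_pvb",
    "pvb_index",
    "bootstrap_se",
    "crossval_loglik",
    "evidence_summary",
]

MODELS = ("temporal", "pvb", "full", "full_no_sd", "frequent_winner")


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfectly separating column)."""


@dataclass
class PsychometricFit:
    alpha: float  # discrimination threshold (evidence units)
    beta_order: float
    delta: float = 0.0  # shift (hsd variant only)
    y0: float = 0.0  # lapse rate
    loglik: float = np.nan
    variant: str = "accuracy"
    n_trials: int = 0


@dataclass(frozen=True)
class DesignSpec:
    model: str = "pvb"
    include_lapse: bool = False
    l2_lambda: float = 0.01

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be non-negative")


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_stats: dict[str, float]
    loglik: float
    n_trials: int
    method: str  # "glm" or "lapse_mle"
    y0: Optional[float] = None
    model: str = "pvb"

    def coef_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.coefficients[n] for n in names])


# ---------------------------------------------------------------------------
# psychometric functions


def psychometric_curve(x, alpha, beta):
    """Accuracy as a function of evidence strength x >= 0; equals 0.5 at
    x = 0 for any (alpha, beta)."""
    x = np.asarray(x, dtype=float)
    return 0.5 + 0.5 * (1.0 - np.exp(-((x / alpha) ** beta)))


def hsd_curve(x, alpha, beta, delta=0.0, y0=0.0):
    """P(choose the higher-SD option) against signed evidence x_HSD.

    The curve is antisymmetric about -delta and, with a lapse y0,
    asymptotes at y0 and 1 - y0.
    """
    x = np.asarray(x, dtype=float)
    s = np.sign(x + delta)
    core = 1.0 - np.exp(-((np.abs(x + delta) / alpha) ** beta))
    return 0.5 + 0.5 * (1.0 - 2.0 * y0) * s * core


def _psychometric_nll(params, x, resp, variant, y0):
    if variant == "accuracy":
        alpha, beta = np.exp(params)
        p = psychometric_curve(x, alpha, beta)
    else:
        alpha, beta = np.exp(params[:2])
        delta = params[2]
        p = hsd_curve(x, alpha, beta, delta, y0)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(resp * np.log(p) + (1.0 - resp) * np.log(1.0 - p))


def fit_psychometric(
    data: ChoiceSet,
    variant: str = "accuracy",
    fixed_y0: Optional[float] = None,
    n_restarts: int = 10,
    rng=None,
) -> PsychometricFit:
    """Maximum-likelihood psychometric fit.

    variant "accuracy": response = correct, x = |mean-evidence
    difference|.  variant "hsd": response = chose the higher-SD option,
    x = signed mean-evidence difference in favour of the higher-SD
    option (context-mapped); a lapse may be supplied as ``fixed_y0``.
    """
    if variant not in ("accuracy", "hsd"):
        raise ValueError("variant must be 'accuracy' or 'hsd'")
    if len(data) < 50:
        raise ValueError("need at least 50 trials for a psychometric fit")
    if fixed_y0 is not None and not 0.0 <= fixed_y0 <= 0.5:
        raise ValueError("fixed_y0 must lie in [0, 0.5]")
    summ = evidence_summary(data.trials)
    if variant == "accuracy":
        x = np.abs(summ["dmean"])
        resp = data.correct.astype(float)
    else:
        hsd_sign = np.where(summ["dsd"] >= 0, 1.0, -1.0)
        x = hsd_sign * summ["dmean"]
        chose_hsd = np.where(summ["dsd"] >= 0, data.chose_left, ~data.chose_left)
        resp = chose_hsd.astype(float)
    if resp.min() == resp.max():
        raise ValueError("degenerate data: all responses identical")
    y0 = 0.0 if fixed_y0 is None else fixed_y0
    rng = np.random.default_rng(0) if rng is None else rng
    best = None
    for k in range(n_restarts):
        if k == 0:
            start = [np.log(10.0), np.log(1.3)]
        else:
            start = [np.log(rng.uniform(2, 40)), np.log(rng.uniform(0.5, 3))]
        if variant == "hsd":
            start = start + [0.0 if k == 0 else rng.normal(0, 3)]
        res = minimize(
            _psychometric_nll,
            np.array(start),
            args=(x, resp, variant, y0),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("psychometric fit did not converge")
    alpha, beta = np.exp(best.x[:2])
    delta = float(best.x[2]) if variant == "hsd" else 0.0
    return PsychometricFit(
        alpha=float(alpha),
        beta_order=float(beta),
        delta=delta,
        y0=y0,
        loglik=-float(best.fun),
        variant=variant,
        n_trials=len(data),
    )


# ---------------------------------------------------------------------------
# design matrices


def local_wins(trial: Trial) -> tuple[int, int]:
    """Per-sample comparison wins (left, right) on context-mapped
    evidence; exact ties score for neither side."""
    ev_l, ev_r = trial_evidence(trial)
    return int(np.sum(ev_l > ev_r)), int(np.sum(ev_r > ev_l))


def evidence_summary(trials) -> pd.DataFrame:
    """Per-trial context-mapped evidence statistics used by the designs."""
    rows = []
    for t in trials:
        ev_l, ev_r = trial_evidence(t)
        rows.append(
            dict(
                mean_l=ev_l.mean(),
                mean_r=ev_r.mean(),
                sd_l=np.std(ev_l, ddof=1),
                sd_r=np.std(ev_r, ddof=1),
                max_l=ev_l.max(),
                max_r=ev_r.max(),
                min_l=ev_l.min(),
                min_r=ev_r.min(),
                first_l=ev_l[0],
                first_r=ev_r[0],
                last_l=ev_l[-1],
                last_r=ev_r[-1],
                total=ev_l.sum() + ev_r.sum(),
            )
        )
    df = pd.DataFrame(rows)
    df["dmean"] = df.mean_l - df.mean_r
    df["dsd"] = df.sd_l - df.sd_r
    return df


def build_design(data: ChoiceSet, spec: DesignSpec):
    """(X, y): design DataFrame (with intercept) and chose-left response."""
    trials = list(data.trials)
    n_samples = trials[0].n_samples if trials else 0
    summ = evidence_summary(trials)
    model = spec.model
    if model == "temporal":
        cols = {}
        for t in trials:
            if t.n_samples != n_samples:
                raise ValueError("temporal design requires equal n_samples")
        ev = np.array([np.subtract(*trial_evidence(t)) for t in trials])
        for k in range(n_samples):
            cols[f"w{k + 1}"] = ev[:, k]
        X = pd.DataFrame(cols)
    elif model == "pvb":
        X = summ[["dmean", "dsd"]].copy()
    elif model in ("full", "full_no_sd"):
        names = [
            "mean_l", "sd_l", "max_l", "min_l", "first_l", "last_l",
            "mean_r", "sd_r", "max_r", "min_r", "first_r", "last_r",
        ]
        if model == "full_no_sd":
            names = [n for n in names if not n.startswith("sd")]
        X = summ[names].copy()
    elif model == "frequent_winner":
        wins = np.array([local_wins(t) for t in trials])
        X = summ[["dmean"]].copy()
        X["dwins"] = wins[:, 0] - wins[:, 1]
    else:  # pragma: no cover
        raise ValueError(model)
    X.insert(0, "intercept", 1.0)
    y = data.chose_left.astype(float)
    return X, y


# ---------------------------------------------------------------------------
# fitting


def fit_choice_glm(X: pd.DataFrame, y: np.ndarray, model: str = "pvb") -> RegressionResult:
    """Plain logistic regression (IRLS via statsmodels).

    Raises SeparationError naming the offending column when the
    likelihood is unbounded.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, Exception) as err:  # noqa: BLE001
            if "Separation" in type(err).__name__ or "separation" in str(err).lower():
                # identify the most suspicious column: largest |z| of a
                # univariate fit direction
                corr = {
                    c: abs(np.corrcoef(X[c], y)[0, 1])
                    for c in X.columns
                    if c != "intercept" and np.std(X[c]) > 0
                }
                worst = max(corr, key=corr.get) if corr else "?"
                raise SeparationError(
                    f"perfect separation detected (suspect column: {worst})"
                ) from err
            raise
    names = list(X.columns)
    return RegressionResult(
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        t_stats=dict(zip(names, res.tvalues)),
        loglik=float(res.llf),
        n_trials=len(y),
        method="glm",
        model=model,
    )


def _lapse_nll(theta, Xm, y, lam):
    beta = theta[:-1]
    y0 = 0.5 * expit(theta[-1])  # maps R -> (0, 0.5)
    p = y0 + (1.0 - 2.0 * y0) * expit(Xm @ beta)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    nll = -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return nll + lam * (np.sum(beta**2) + y0**2)


def fit_lapse_mle(
    X: pd.DataFrame,
    y: np.ndarray,
    l2_lambda: float = 0.01,
    rng=None,
    n_restarts: int = 10,
    model: str = "pvb",
    tol: float = 1e-8,
) -> RegressionResult:
    """Lapse-augmented logistic model by penalised MLE.

    P(left) = Y0 + (1 - 2*Y0) * logistic(X beta); the objective is the
    negative log-likelihood plus ``l2_lambda * (sum beta^2 + Y0^2)``,
    minimised with Nelder-Mead from multiple starts (the first start is
    the plain GLM solution when available).  Standard errors are not
    asymptotic here — use :func:`bootstrap_se`.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    k = Xm.shape[1]
    starts = []
    try:
        glm = fit_choice_glm(X, y, model)
        starts.append(np.concatenate([glm.coef_vector(list(X.columns)), [-4.0]]))
    except (SeparationError, Exception):  # noqa: BLE001
        starts.append(np.concatenate([np.zeros(k), [-4.0]]))
    for _ in range(n_restarts - 1):
        starts.append(
            np.concatenate([rng.normal(0, 0.3, k), [rng.uniform(-6.0, 0.0)]])
        )
    opts = {"xatol": tol, "fatol": tol, "maxiter": 20000, "maxfev": 20000}
    best = None
    for s0 in starts:
        res = minimize(_lapse_nll, s0, args=(Xm, y, l2_lambda), method="Nelder-Mead", options=opts)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("lapse MLE did not converge")
    # the simplex can stall on flat ridges; re-polish from the incumbent
    for _ in range(5):
        res = minimize(
            _lapse_nll, best.x, args=(Xm, y, l2_lambda), method="Nelder-Mead", options=opts
        )
        if res.fun >= best.fun - 1e-9:
            break
        best = res
    names = list(X.columns)
    beta = best.x[:-1]
    y0 = float(0.5 * expit(best.x[-1]))
    p = y0 + (1 - 2 * y0) * expit(Xm @ beta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    nan = float("nan")
    return RegressionResult(
        coefficients=dict(zip(names, beta)),
        standard_errors={n: nan for n in names},
        t_stats={n: nan for n in names},
        loglik=loglik,
        n_trials=len(y),
        method="lapse_mle",
        y0=y0,
        model=model,
    )


def fit_pvb(data: ChoiceSet, include_lapse: bool = False, rng=None) -> RegressionResult:
    """Convenience: fit the mean/SD choice regression on a ChoiceSet."""
    spec = DesignSpec("pvb", include_lapse=include_lapse)
    X, y = build_design(data, spec)
    if include_lapse:
        return fit_lapse_mle(X, y, spec.l2_lambda, rng=rng)
    return fit_choice_glm(X, y, "pvb")


def pvb_index(result: RegressionResult) -> float:
    """beta_sd / beta_mean, the pro-variance bias index.

    Raises ValueError when the mean-evidence coefficient is not
    positive (the ratio is not interpretable in that regime).
    """
    try:
        bm = result.coefficients["dmean"]
        bs = result.coefficients["dsd"]
    except KeyError as err:
        raise ValueError("result lacks dmean/dsd coefficients") from err
    if bm <= 0:
        raise ValueError(f"undefined regime: mean-evidence coefficient {bm:.4g} <= 0")
    return bs / bm


# ---------------------------------------------------------------------------
# uncertainty and model comparison


def bootstrap_se(
    fitter: Callable[[ChoiceSet], dict[str, float]],
    data: ChoiceSet,
    B: int = 10_000,
    rng=None,
    ci: float = 0.95,
):
    """Case-resampling bootstrap over trials.

    ``fitter`` maps a ChoiceSet to a dict of named statistics.  Returns
    a dict of {name: {"se", "ci_low", "ci_high", "samples"}}.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(data)
    trials = list(data.trials)
    samples: dict[str, list[float]] = {}
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sub = ChoiceSet(
            trials=type(data.trials)([trials[i] for i in idx], {}, 0)
            if hasattr(data.trials, "trials")
            else [trials[i] for i in idx],
            chose_left=data.chose_left[idx],
            correct=data.correct[idx],
        )
        for name, val in fitter(sub).items():
            samples.setdefault(name, []).append(val)
    lo = 100 * (1 - ci) / 2
    out = {}
    for name, vals in samples.items():
        arr = np.array(vals)
        out[name] = {
            "se": float(np.std(arr, ddof=1)),
            "ci_low": float(np.percentile(arr, lo)),
            "ci_high": float(np.percentile(arr, 100 - lo)),
            "samples": arr,
        }
    return out


def crossval_loglik(
    data: ChoiceSet,
    specs: Sequence[DesignSpec],
    k: int = 10,
    reps: int = 100,
    rng=None,
) -> dict[str, float]:
    """Repeated k-fold cross-validated held-out log-likelihood per spec.

    Each repetition draws a fresh random partition; held-out
    log-likelihoods are summed over folds and averaged over
    repetitions.  Folds whose training data have a single response
    class are skipped (and counted) rather than fitted.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(data)
    designs = [build_design(data, spec) for spec in specs]
    out = {self_key(spec): [] for spec in specs}
    skipped = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        totals = [0.0] * len(specs)
        for fold in folds:
            mask = np.ones(n, bool)
            mask[fold] = False
            for j, (X, y) in enumerate(designs):
                ytr = y[mask]
                if ytr.min() == ytr.max():
                    skipped += 1
                    continue
                res = fit_choice_glm(X[mask], ytr, specs[j].model)
                beta = res.coef_vector(list(X.columns))
                p = expit(np.asarray(X[~mask], float) @ beta)
                p = np.clip(p, 1e-12, 1 - 1e-12)
                yte = y[~mask]
                totals[j] += float(
                    np.sum(yte * np.log(p) + (1 - yte) * np.log(1 - p))
                )
        for j, spec in enumerate(specs):
            out[self_key(spec)].append(totals[j])
    return {key: float(np.mean(vals)) for key, vals in out.items()}


def self_key(spec: DesignSpec) -> str:
    return spec.model + ("+lapse" if spec.include_lapse else "")
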