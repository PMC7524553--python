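"""End-to-end experiment orchestration.

A plan names a simulation backend (logistic agent, mean-field, or
spiking circuit), trial composition and counts, perturbation presets,
and the analyses to run.  The runner generates trials, simulates
choices, fits the standard regressions, and writes coefficient tables
and test reports under an output directory, logging seeds and a
configuration hash per stage so any run can be reproduced exactly.

Within a perturbation suite every condition is simulated on the same
trial set (a paired design, asserted via a hash of the trial table).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .trialgen import (
    AgentSpec,
    ChoiceSet,
    GenConfig,
    TrialSet,
    generate_trialset,
    simulate_logistic_agent,
)
from .behavstats import (
    DesignSpec,
    RegressionResult,
    build_design,
    fit_choice_glm,
    fit_lapse_mle,
    pvb_index,
)
from .permtests import permutation_test_pvb

__all__ = ["ExperimentPlan", "run_control_replication", "run_perturbation_suite"]

BACKENDS = ("agent", "meanfield", "spiking")


@dataclass
class ExperimentPlan:
    backend: str = "meanfield"
    n_trials: int = 20_000
    composition: Optional[dict[str, float]] = None
    gen_config: GenConfig = field(default_factory=GenConfig)
    agent: AgentSpec = field(default_factory=AgentSpec)
    perturbations: dict[str, object] = field(default_factory=dict)
    models: tuple[str, ...] = ("pvb", "temporal", "full")
    include_lapse: bool = False
    n_perm: int = 1000
    seed: int = 0
    out_dir: Optional[str] = None
    #: spiking-only: network scale factor and integration step
    spiking_scale: float = 0.125
    spiking_dt: float = 1e-4

    def __post_init__(self):
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gen_config" in raw:
            raw["gen_config"] = GenConfig(**raw["gen_config"])
        if "agent" in raw:
            raw["agent"] = AgentSpec(**raw["agent"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _config_hash(obj) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(obj, default=default, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _trials_hash(ts: TrialSet) -> str:
    df = pio.trials_to_frame(ts)
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _simulate(plan: ExperimentPlan, trials: TrialSet, perturbation=None, tag="control") -> ChoiceSet:
    import zlib

    seed = int(
        np.random.default_rng(
            np.random.SeedSequence(plan.seed, spawn_key=(zlib.crc32(tag.encode()),))
        ).integers(2**31)
    )
    rng = np.random.default_rng(seed)
    if plan.backend == "agent":
        return simulate_logistic_agent(trials, plan.agent, rng)
    if plan.backend == "meanfield":
        from .meanfield import (
            MeanFieldParams,
            apply_meanfield_perturbation,
            simulate_choices_meanfield,
        )

        params = MeanFieldParams()
        if perturbation is not None:
            params = apply_meanfield_perturbation(params, perturbation)
        return simulate_choices_meanfield(trials, params, rng)
    from .spiking import apply_perturbation, desk_config, run_trials

    config = desk_config(plan.spiking_scale, plan.spiking_dt)
    if perturbation is not None:
        config = apply_perturbation(config, perturbation)
    return run_trials(trials, config, seed=seed)


def _fit_all(plan: ExperimentPlan, choices: ChoiceSet, rng) -> dict[str, RegressionResult]:
    out = {}
    for model in plan.models:
        spec = DesignSpec(model, include_lapse=plan.include_lapse)
        X, y = build_design(choices, spec)
        if plan.include_lapse:
            out[model] = fit_lapse_mle(X, y, spec.l2_lambda, rng=rng, model=model)
        else:
            out[model] = fit_choice_glm(X, y, model)
    return out


def _coef_table(fits: dict[str, RegressionResult], condition: str) -> pd.DataFrame:
    rows = []
    for model, res in fits.items():
        for term, est in res.coefficients.items():
            rows.append(
                dict(
                    condition=condition,
                    model_id=model,
                    term=term,
                    estimate=est,
                    se=res.standard_errors.get(term, float("nan")),
                    t=res.t_stats.get(term, float("nan")),
                    y0=res.y0,
                    loglik=res.loglik,
                    n=res.n_trials,
                )
            )
    return pd.DataFrame(rows)


def _log_stage(log: list, stage: str, t0: float, **extra):
    log.append(dict(stage=stage, wall_s=round(time.time() - t0, 3), **extra))


def _write_outputs(plan, trials, tables, report, log):
    if plan.out_dir is None:
        return
    out = Path(plan.out_dir)
    for sub in ("trials", "fits", "tests"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    pio.write_trials(trials, out / "trials" / "trials.csv")
    pd.concat(tables, ignore_index=True).to_csv(out / "fits" / "coefficients.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(out / "log.txt", "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec, default=str) + "\n")


def run_control_replication(plan: ExperimentPlan) -> dict:
    """Generate trials, simulate the control condition, fit the standard
    models, and report coefficients plus the PVB index."""
    log: list[dict] = []
    t0 = time.time()
    trials = generate_trialset(plan.n_trials, plan.composition, plan.gen_config, plan.seed)
    _log_stage(log, "generate", t0, n=len(trials), seed=plan.seed)
    t0 = time.time()
    choices = _simulate(plan, trials, None, "control")
    _log_stage(log, "simulate", t0, backend=plan.backend)
    t0 = time.time()
    rng = np.random.default_rng(plan.seed + 1)
    fits = _fit_all(plan, choices, rng)
    _log_stage(log, "fit", t0, models=list(plan.models))
    table = _coef_table(fits, "control")
    report = {
        "plan": _config_hash(asdict(plan)),
        "config": asdict(plan),
        "seed": plan.seed,
        "trials_hash": _trials_hash(trials),
        "backend": plan.backend,
        "n_trials": len(trials),
        "accuracy": choices.accuracy,
        "coefficients": {m: fits[m].coefficients for m in fits},
        "t_stats": {m: fits[m].t_stats for m in fits},
    }
    if "pvb" in fits:
        report["pvb_index"] = pvb_index(fits["pvb"])
    _write_outputs(plan, trials, [table], report, log)
    return {"report": report, "fits": fits, "table": table, "choices": choices, "log": log}


def run_perturbation_suite(plan: ExperimentPlan) -> dict:
    """Simulate an identical trial set under control + perturbations;
    fit, compute PVB indices, and run permutation tests against the
    control condition."""
    if not plan.perturbations:
        raise ValueError("plan.perturbations must name at least one condition")
    log: list[dict] = []
    t0 = time.time()
    trials = generate_trialset(plan.n_trials, plan.composition, plan.gen_config, plan.seed)
    thash = _trials_hash(trials)
    _log_stage(log, "generate", t0, n=len(trials), trials_hash=thash)

    conditions = {"control": None, **plan.perturbations}
    choice_sets: dict[str, ChoiceSet] = {}
    fits: dict[str, dict[str, RegressionResult]] = {}
    tables = []
    rng = np.random.default_rng(plan.seed + 1)
    for name, pert in conditions.items():
        t0 = time.time()
        # paired design: every condition sees the identical trial set
        assert _trials_hash(trials) == thash
        choice_sets[name] = _simulate(plan, trials, pert, name)
        _log_stage(log, f"simulate:{name}", t0)
        t0 = time.time()
        fits[name] = _fit_all(plan, choice_sets[name], rng)
        tables.append(_coef_table(fits[name], name))
        _log_stage(log, f"fit:{name}", t0)

    pvb = {name: pvb_index(f["pvb"]) for name, f in fits.items() if "pvb" in f}
    tests = {}
    for name in plan.perturbations:
        t0 = time.time()
        res = permutation_test_pvb(
            choice_sets[name],
            choice_sets["control"],
            n_perm=plan.n_perm,
            rng=np.random.default_rng(plan.seed + 2),
        )
        tests[name] = {
            "observed": res.observed_stat,
            "p_value": res.p_value,
            "n_perm": res.null_size,
        }
        _log_stage(log, f"permtest:{name}", t0)

    ordering = sorted(pvb, key=pvb.get, reverse=True)
    report = {
        "plan": _config_hash(asdict(plan)),
        "config": asdict(plan),
        "seed": plan.seed,
        "trials_hash": thash,
        "backend": plan.backend,
        "n_trials": len(trials),
        "pvb_index": pvb,
        "pvb_ordering": ordering,
        "permutation_tests": tests,
        "accuracy": {name: cs.accuracy for name, cs in choice_sets.items()},
    }
    _write_outputs(plan, trials, tables, report, log)
    return {
        "report": report,
        "fits": fits,
        "choices": choice_sets,
        "tables": tables,
        "log": log,
    }
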