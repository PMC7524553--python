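"""Optional reader for deposited behavioural session data.

The published behavioural database (Dryad, doi:10.5061/dryad.pnvx0k6k3)
is not bundled here; this module ingests per-session choice tables in
the package's own CSV schema (see :mod:`provar.io`) — one file per
session, named ``<subject>_<session>.csv`` — as produced by converting
the deposited MATLAB tables.  It then reproduces the pooled and
per-subject pro-variance statistics deterministically.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .trialgen import ChoiceSet, TrialSet
from .behavstats import fit_pvb, pvb_index

__all__ = ["load_sessions", "pooled_pvb"]


def load_sessions(directory) -> dict[str, list[ChoiceSet]]:
    """Load all ``<subject>_<session>.csv`` choice tables, grouped by
    subject."""
    out: dict[str, list[ChoiceSet]] = {}
    for path in sorted(Path(directory).glob("*.csv")):
        subject = path.stem.split("_")[0]
        cs = pio.read_choices(path)
        out.setdefault(subject, []).append(cs)
    if not out:
        raise FileNotFoundError(f"no session tables found under {directory}")
    return out


def _concat(sessions: list[ChoiceSet]) -> ChoiceSet:
    trials = [t for s in sessions for t in s.trials]
    return ChoiceSet(
        TrialSet(trials, {}, 0),
        np.concatenate([s.chose_left for s in sessions]),
        np.concatenate([s.correct for s in sessions]),
    )


def pooled_pvb(sessions_by_subject: dict[str, list[ChoiceSet]]) -> dict:
    """PVB index pooled across subjects and per subject (plain GLM fit
    of the mean/SD choice regression on Regular trials)."""
    def regular_only(cs: ChoiceSet) -> ChoiceSet:
        idx = [i for i, t in enumerate(cs.trials) if t.condition == "Regular"]
        return ChoiceSet(
            TrialSet([cs.trials[i] for i in idx], {}, 0),
            cs.chose_left[idx],
            cs.correct[idx],
        )

    per_subject = {}
    all_sessions = []
    for subject, sessions in sessions_by_subject.items():
        data = regular_only(_concat(sessions))
        per_subject[subject] = pvb_index(fit_pvb(data))
        all_sessions.extend(sessions)
    pooled = pvb_index(fit_pvb(regular_only(_concat(all_sessions))))
    return {"pooled": pooled, "per_subject": per_subject}
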