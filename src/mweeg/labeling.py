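"""Probe-based trial labeling and subject inclusion rules.

Probe responses map onto mental-state classes: 1-2 (concentrated / evaluating
the task) are on-task, 3 and 5 (personal matters / daydreaming) are
mind-wandering, and 4 and 6 (external distraction / mind-blanking) are
excluded because they are neither self-generated thought nor task focus. The
six trials immediately preceding a probe inherit its class — attentional
states persist across trials — and a subject enters the group analysis only
if every task x state cell retains at least 30 artifact-free labeled trials.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synth import (EXCLUDED_RESPONSES, MIND_WANDERING, MW_RESPONSES, ON_TASK,
                    ON_TASK_RESPONSES, PROBE_WINDOW, ProbeEvent, TaskDesign)

__all__ = ["map_probe_response", "select_trials", "label_counts",
           "apply_inclusion_criteria", "MIN_TRIALS_PER_CELL"]

#: minimum clean labeled trials per task x state cell for subject inclusion
MIN_TRIALS_PER_CELL = 30

_CLASS_OF = {**{r: ON_TASK for r in ON_TASK_RESPONSES},
             **{r: MIND_WANDERING for r in MW_RESPONSES},
             **{r: "excluded" for r in EXCLUDED_RESPONSES}}


def map_probe_response(code: int) -> str:
    """Mental-state class for one probe response code (1..6)."""
    try:
        return _CLASS_OF[int(code)]
    except (KeyError, ValueError):
        raise ValueError(f"probe response {code!r} outside 1..6") from None


def select_trials(design: TaskDesign, probes: list[ProbeEvent]) -> pd.DataFrame:
    """Label the six pre-probe trials with each probe's reported class.

    Returns one row per labeled trial with columns ``trial_id, state,
    source_probe``. Probes whose response falls in the excluded categories
    contribute no rows. Overlapping probe windows (impossible with the
    minimum 7-trial gap) or probes earlier than their own window raise.
    """
    rows = []
    claimed: dict[int, int] = {}
    for p in probes:
        if p.trial_index >= design.n_trials:
            raise ValueError(f"probe {p.probe_index} beyond session")
        if p.trial_index < PROBE_WINDOW - 1:
            raise ValueError(f"probe {p.probe_index} earlier than trial "
                             f"{PROBE_WINDOW} of the session")
        cls = map_probe_response(p.response)
        if cls == "excluded":
            continue
        for t in range(p.trial_index - PROBE_WINDOW + 1, p.trial_index + 1):
            if t in claimed:
                raise ValueError(f"trial {t} claimed by probes "
                                 f"{claimed[t]} and {p.probe_index}")
            claimed[t] = p.probe_index
            rows.append({"trial_id": t, "state": cls, "source_probe": p.probe_index})
    return pd.DataFrame(rows, columns=["trial_id", "state", "source_probe"])


def label_counts(labels: pd.DataFrame, trial_meta: pd.DataFrame | None = None
                 ) -> dict[str, int]:
    """Labeled-trial count per state, after dropping artifact-flagged trials.

    ``trial_meta`` (with ``trial_id`` and boolean ``artifact``) supplies the
    artifact flags; without it all labeled trials count as clean.
    """
    lab = labels
    if trial_meta is not None and "artifact" in trial_meta:
        clean = trial_meta.loc[~trial_meta["artifact"].astype(bool), "trial_id"]
        lab = labels[labels["trial_id"].isin(clean)]
    return {state: int((lab["state"] == state).sum())
            for state in (ON_TASK, MIND_WANDERING)}


def apply_inclusion_criteria(counts: dict, min_per_cell: int = MIN_TRIALS_PER_CELL,
                             report_path: str | Path | None = None) -> dict:
    """Retain subjects with >= ``min_per_cell`` clean trials in every cell.

    ``counts`` maps subject -> task -> state -> clean labeled-trial count.
    Returns a report dict with included/excluded subject lists and the
    offending cells; optionally written as JSON.
    """
    included, excluded = [], {}
    for subject, by_task in counts.items():
        bad = [f"{task}/{state}={n}" for task, by_state in by_task.items()
               for state, n in by_state.items() if n < min_per_cell]
        if bad:
            excluded[str(subject)] = bad
        else:
            included.append(subject)
    report = {"min_trials_per_cell": min_per_cell,
              "included": included, "excluded": excluded}
    if report_path is not None:
        Path(report_path).write_text(json.dumps(report, indent=1, default=str))
    return report
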