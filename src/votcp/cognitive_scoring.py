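"""Norm-referenced Z-scores, composite scores, and the letter-control exclusion.

Z-scores are computed against a reference population mean and SD per task.
For the phoneme-awareness tasks the reference is the current control group;
for reading and letter-report tasks the reference is the configured norm
table (standing in for external age norms).

Composites (all on the percent scale unless noted):

* ``pa_composite`` — mean percent correct of the three phoneme-awareness
  tasks (deletion, segmentation, acronyms),
* ``vas_composite`` — mean of the global-report and partial-report
  percentages (raw scores /100 and /50 converted to percent first),
* ``reading_accuracy`` — mean percent of the regular-word, irregular-word
  and pseudo-word accuracy scores (each /20),
* ``reading_speed`` — mean of the three reading-time Z-scores, sign
  preserved so larger = slower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from votcp.synthetic_cohort import (
    DEFAULT_NORMS,
    PA_TASKS,
    READING_SCORES,
    READING_TIMES,
    REPORT_TASKS,
    NormEntry,
)

LETTER_DURATIONS = (33, 50, 67, 84, 101)
LETTER_MAX_PER_DURATION = 10

ALL_TASKS = PA_TASKS + REPORT_TASKS + READING_SCORES + READING_TIMES


GLOBAL_REPORT_MAX = 100  # 20 strings x 5 letters
PARTIAL_REPORT_MAX = 50  # one cued letter per string


def report_percentages(global_raw: float, partial_raw: float) -> tuple[float, float]:
    """Convert raw report scores (/100 and /50) to percentages of maximum."""
    for name, raw, mx in (
        ("global", global_raw, GLOBAL_REPORT_MAX),
        ("partial", partial_raw, PARTIAL_REPORT_MAX),
    ):
        if not 0 <= raw <= mx:
            raise ValueError(f"{name} report score {raw} outside [0, {mx}]")
    return global_raw / GLOBAL_REPORT_MAX * 100.0, partial_raw / PARTIAL_REPORT_MAX * 100.0


def zscore(value: float, norm: NormEntry) -> float:
    """(value - reference mean) / reference SD."""
    if norm.sd <= 0:
        raise ValueError("norm SD must be positive")
    return (value - norm.mean) / norm.sd


def control_norms(participants: pd.DataFrame, tasks=PA_TASKS) -> dict[str, NormEntry]:
    """Reference norms computed from the cohort's own control group."""
    ctl = participants[participants["group"] == "CTL"]
    if len(ctl) < 2:
        raise ValueError("need at least 2 control participants to build norms")
    out = {}
    for task in tasks:
        sd = float(ctl[task].std(ddof=1))
        if sd <= 0:
            raise ValueError(f"control norm SD for {task} is not positive")
        out[task] = NormEntry(float(ctl[task].mean()), sd, source="current-controls")
    return out


def composites(record: pd.Series | dict, norms: dict[str, NormEntry]) -> dict:
    """Per-task Z-scores and the four composite scores for one participant."""
    rec = dict(record)
    missing = [t for t in ALL_TASKS if t not in rec or pd.isna(rec[t])]
    if missing:
        raise ValueError(f"missing component scores: {missing}")
    out: dict = {"participant_id": rec.get("participant_id")}
    for task in ALL_TASKS:
        out[f"z_{task}"] = zscore(float(rec[task]), norms[task])
    out["pa_composite"] = float(np.mean([rec[t] for t in PA_TASKS]))
    out["vas_composite"] = float(
        np.mean([rec["global_report_pct"], rec["partial_report_pct"]])
    )
    out["reading_accuracy"] = float(
        np.mean([rec[t] / 20.0 * 100.0 for t in READING_SCORES])
    )
    out["reading_speed"] = float(np.mean([out[f"z_{t}"] for t in READING_TIMES]))
    return out


def letter_control_exclusion(record: pd.Series | dict) -> bool:
    """True (exclude) when any presentation duration misses the 10/10 ceiling."""
    rec = dict(record)
    for d in LETTER_DURATIONS:
        key = f"letters_{d}ms"
        if key not in rec or pd.isna(rec[key]):
            raise ValueError(f"missing single-letter score: {key}")
        if rec[key] < LETTER_MAX_PER_DURATION:
            return True
    return False


def zprofile_table(
    participants: pd.DataFrame, norms: dict[str, NormEntry] | None = None
) -> pd.DataFrame:
    """Z-scores and composites for a whole cohort.

    Phoneme-awareness norms come from the cohort's control group; all other
    tasks use the supplied (or default) norm table.
    """
    base = dict(norms or DEFAULT_NORMS)
    base.update(control_norms(participants, PA_TASKS))
    rows = [composites(row, base) for _, row in participants.iterrows()]
    out = pd.DataFrame(rows)
    out["excluded_letter_control"] = [
        letter_control_exclusion(row) for _, row in participants.iterrows()
    ]
    meta = participants[["participant_id", "group", "age_months"]]
    return meta.merge(out, on="participant_id")
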