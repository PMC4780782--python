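"""Deficit subtyping of dyslexic participants and age-matching of controls.

A dyslexic child is phonologically impaired when any of the three
phoneme-awareness Z-scores falls strictly below -1.5, and visual-attention-
span impaired when any report-task Z-score does; the 2x2 of those flags
yields the labels PA_only / VAS_only / double / none.

Age matching removes controls one at a time, always the youngest (ties
broken by identifier), re-testing the group age difference with a one-way
ANOVA until p >= alpha.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from votcp.synthetic_cohort import PA_TASKS, REPORT_TASKS

PA_ONLY = "PA_only"
VAS_ONLY = "VAS_only"
DOUBLE = "double"
NONE = "none"

DEFICIT_THRESHOLD = -1.5

PA_Z_COLS = tuple(f"z_{t}" for t in PA_TASKS)
REPORT_Z_COLS = tuple(f"z_{t}" for t in REPORT_TASKS)


def classify(zprofile: pd.Series | dict) -> str:
    """Deficit label from the five Z-scores (strict -1.5 threshold)."""
    rec = dict(zprofile)
    for col in PA_Z_COLS + REPORT_Z_COLS:
        if col not in rec or pd.isna(rec[col]):
            raise ValueError(f"missing Z-score: {col}")
    pa_impaired = min(rec[c] for c in PA_Z_COLS) < DEFICIT_THRESHOLD
    vas_impaired = min(rec[c] for c in REPORT_Z_COLS) < DEFICIT_THRESHOLD
    if pa_impaired and vas_impaired:
        return DOUBLE
    if pa_impaired:
        return PA_ONLY
    if vas_impaired:
        return VAS_ONLY
    return NONE


def label_table(zprofiles: pd.DataFrame) -> pd.DataFrame:
    """Deficit labels for every dyslexic participant (controls get NA)."""
    labels = []
    for _, row in zprofiles.iterrows():
        labels.append(pd.NA if row["group"] == "CTL" else classify(row))
    out = zprofiles[["participant_id", "group"]].copy()
    out["deficit_label"] = labels
    return out


def age_match_controls(
    dys_group: pd.DataFrame,
    controls: pd.DataFrame,
    alpha: float = 0.10,
    min_controls: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Iteratively drop the youngest control until ages no longer differ.

    Both inputs need ``participant_id`` and ``age_months``. Returns the
    retained control subset and the number of removals. ``min_controls``
    defaults to twice the dyslexic group size (floored at 2); reaching it
    without a match raises ``ValueError``.
    """
    if dys_group.empty or controls.empty:
        raise ValueError("both groups must be non-empty")
    if min_controls is None:
        min_controls = max(2, 2 * len(dys_group))
    kept = controls.sort_values(
        ["age_months", "participant_id"], ascending=[True, True]
    ).reset_index(drop=True)
    removed = 0
    dys_ages = dys_group["age_months"].to_numpy(dtype=float)
    while True:
        f, p = stats.f_oneway(dys_ages, kept["age_months"].to_numpy(dtype=float))
        if p >= alpha:
            return kept.sort_values("participant_id").reset_index(drop=True), removed
        if len(kept) <= min_controls:
            raise ValueError(
                "age matching failed: control floor "
                f"{min_controls} reached with p = {p:.4f} "
                f"(dys mean {dys_ages.mean():.1f}, ctl mean {kept['age_months'].mean():.1f})"
            )
        kept = kept.iloc[1:].reset_index(drop=True)  # youngest first
        removed += 1
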