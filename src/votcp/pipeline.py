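"""End-to-end study pipeline: simulate -> score -> subgroup -> infer -> mediate.

A run is a pure function of its :class:`RunConfig`: the same config produces
byte-identical CSV outputs. File contracts (UTF-8, comma-separated, header
row, empty field = missing):

* ``participants.csv`` — one row per child: id, group, age, all task scores
* ``identification_trials.csv`` — participant_id, trial_index, vot_ms,
  response in {d, t}
* ``discrimination_trials.csv`` — participant_id, trial_index, vot_a_ms,
  vot_b_ms, response in {same, different}
* ``cp_derived.csv`` — boundary fit, observed/predicted d' per pair center,
  both peaks
* ``zprofiles.csv``, ``subgroups.csv``, ``anova_results.csv``,
  ``correlations.csv``, ``mediation.json``, ``run.log``
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import votcp
from votcp import (
    cognitive_scoring,
    cp_scoring,
    group_inference,
    mediation,
    subgrouping,
    synthetic_cohort,
)
from votcp.synthetic_cohort import CohortConfig

log = logging.getLogger("votcp")

PAIR_CENTER_COLS = ("-30", "+0", "+30")  # the three analysed VOT pair centers


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha: float = 0.05
    matching_alpha: float = 0.10
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        cohort = data.pop("cohort", {})
        cohort["age_range_months"] = tuple(cohort.get("age_range_months", (94, 153)))
        return cls(cohort=CohortConfig(**cohort), **data)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


REQUIRED_COLUMNS = {
    "identification": ("participant_id", "trial_index", "vot_ms", "response"),
    "discrimination": ("participant_id", "trial_index", "vot_a_ms", "vot_b_ms", "response"),
}


def validate_trials(df: pd.DataFrame, kind: str) -> None:
    """Schema check with actionable messages (missing columns by name)."""
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} trials file is missing columns: {missing}")


def analysis_table(
    participants: pd.DataFrame,
    derived: pd.DataFrame,
    zprofiles: pd.DataFrame,
) -> pd.DataFrame:
    """Participant-level table joining CP indices, composites and metadata."""
    keep = zprofiles[
        ["participant_id", "group", "age_months", "pa_composite", "vas_composite",
         "reading_accuracy", "reading_speed", "excluded_letter_control"]
    ]
    return keep.merge(derived, on="participant_id")


def long_dprime_table(derived_with_group: pd.DataFrame) -> pd.DataFrame:
    """Long-format d' at the three analysed centers for the mixed ANOVA."""
    rows = []
    for _, r in derived_with_group.iterrows():
        for center in PAIR_CENTER_COLS:
            for task, col in (("observed", "obs"), ("predicted", "pred")):
                rows.append(
                    {
                        "participant_id": r["participant_id"],
                        "group": r["group"],
                        "task": task,
                        "vot_center": int(center),
                        "dprime": r[f"{col}_dprime_{center}"],
                    }
                )
    return pd.DataFrame(rows)


def score_stage(
    participants: pd.DataFrame,
    identification_trials: pd.DataFrame,
    discrimination_trials: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scoring from trial-level data: CP derived table and z-profiles."""
    validate_trials(identification_trials, "identification")
    validate_trials(discrimination_trials, "discrimination")
    known = set(participants["participant_id"])
    for name, df in (
        ("identification", identification_trials),
        ("discrimination", discrimination_trials),
    ):
        orphans = sorted(set(df["participant_id"]) - known)
        if orphans:
            raise ValueError(f"{name} trials reference unknown participants: {orphans}")
    derived = cp_scoring.score_participants(identification_trials, discrimination_trials)
    zprofiles = cognitive_scoring.zprofile_table(participants)
    return derived, zprofiles


def analyze_stage(
    participants: pd.DataFrame,
    derived: pd.DataFrame,
    zprofiles: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """Group inference and mediation on scored data."""
    table = analysis_table(participants, derived, zprofiles)
    dys = table[table["group"] != "CTL"]
    if dys.empty:
        raise ValueError("no dyslexic participants: analysis stage cannot proceed")

    merged = derived.merge(
        participants[["participant_id", "group"]], on="participant_id"
    )
    long = long_dprime_table(merged)
    long["group_2"] = np.where(long["group"] == "CTL", "CTL", "DYS")
    anova = group_inference.mixed_anova(
        long,
        dv="dprime", subject="participant_id",
        between="group_2", within=["task", "vot_center"],
    )
    ancova = group_inference.ancova_peak(
        table.assign(group_2=np.where(table["group"] == "CTL", "CTL", "DYS")),
        group="group_2",
        amplitude="pred_peak_amplitude",
        location="pred_peak_center_ms",
    )

    corr_vars = [
        "reading_accuracy", "reading_speed", "vas_composite",
        "pa_composite", "pred_peak_amplitude",
    ]
    correlations = group_inference.correlation_matrix(dys, corr_vars, "age_months")

    med = mediation.causal_steps(dys, alpha=config.alpha)

    labels = subgrouping.label_table(zprofiles)
    pa_dys = zprofiles.merge(labels, on=["participant_id", "group"])
    pa_ids = pa_dys.loc[pa_dys["deficit_label"] == subgrouping.PA_ONLY, "participant_id"]
    controls = zprofiles[zprofiles["group"] == "CTL"]
    matching = {"removed": 0, "matched_controls": len(controls)}
    if len(pa_ids) >= 2:
        try:
            kept, removed = subgrouping.age_match_controls(
                zprofiles[zprofiles["participant_id"].isin(pa_ids)],
                controls,
                alpha=config.matching_alpha,
            )
            matching = {"removed": removed, "matched_controls": len(kept)}
        except ValueError as err:
            matching = {"removed": -1, "error": str(err)}
    return {
        "anova": anova,
        "ancova": ancova,
        "correlations": correlations,
        "mediation": med,
        "subgroups": labels,
        "matching": matching,
    }


def _anova_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def _mediation_json(med: mediation.MediationResult) -> dict:
    return {
        "paths": med.paths,
        "path_se": med.path_se,
        "sobel_z": med.sobel_z,
        "sobel_p_one_sided": med.sobel_p_one_sided,
        "steps": {k: bool(v) for k, v in med.steps.items()},
        "mediation_established": bool(med.mediation_established),
        "models": {
            name: dataclasses.asdict(m)
            for name, m in (("model1", med.model1), ("model2", med.model2), ("model3", med.model3))
        },
    }


def run_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and run the full analysis, writing all artifacts.

    On failure, partial outputs are removed and the exception re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        participants, id_trials, disc_trials = synthetic_cohort.simulate_study(cohort_cfg)
        _write_csv(participants, out / "participants.csv")
        _write_csv(id_trials, out / "identification_trials.csv")
        _write_csv(disc_trials, out / "discrimination_trials.csv")

        derived, zprofiles = score_stage(participants, id_trials, disc_trials)
        _write_csv(derived, out / "cp_derived.csv")
        _write_csv(zprofiles, out / "zprofiles.csv")

        results = analyze_stage(participants, derived, zprofiles, config)
        _write_csv(
            _anova_frame(results["anova"] + results["ancova"]),
            out / "anova_results.csv",
        )
        results["correlations"].to_csv(out / "correlations.csv", lineterminator="\n")
        _write_csv(results["subgroups"], out / "subgroups.csv")
        (out / "mediation.json").write_text(
            json.dumps(_mediation_json(results["mediation"]), indent=2) + "\n"
        )
        (out / "run.log").write_text(
            "\n".join(
                [
                    f"votcp {votcp.__version__}",
                    f"python {sys.version.split()[0]}",
                    f"seed {config.seed}",
                    f"age matching: {results['matching']}",
                    "config:",
                    config.to_json(),
                    "",
                ]
            )
        )
        (out / "config.json").write_text(config.to_json() + "\n")
        log.info("run complete: %s", out)
        return out
    except Exception:
        for f in out.glob("*"):
            if f.is_file():
                f.unlink()
        raise


def score_only(
    identification_path: str | Path,
    discrimination_path: str | Path,
    participants_path: str | Path,
    out_dir: str | Path,
) -> Path:
    """Score externally supplied trial-level files (same contracts as run_study)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(participants_path)
    id_trials = pd.read_csv(identification_path)
    disc_trials = pd.read_csv(discrimination_path)
    derived, zprofiles = score_stage(participants, id_trials, disc_trials)
    _write_csv(derived, out / "cp_derived.csv")
    _write_csv(zprofiles, out / "zprofiles.csv")
    return out
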