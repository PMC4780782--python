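"""Simulated cohorts of control and dyslexic children.

The generator plants the study's hypothesized structure:

* per-child identification governed by a logistic psychometric function with
  a participant-specific boundary ``boundary_mu_ms`` and slope scale
  ``precision_s_ms`` (smaller = sharper categorical perception),
* same-different responding driven by a true discriminability that combines a
  phonemic term (proportional to the difference in labeling probabilities)
  with optional allophonic bumps centered at -30 and +30 ms VOT,
* latent cognitive traits wired as a mediation: categorical-perception
  sharpness -> phoneme awareness (path a) -> reading accuracy (path b), with
  a direct path c' and an independent visual-attention-span -> reading path d;
  reading speed loads on VA span but not on phoneme awareness,
* deficit subtypes: DYS-PA children get a worse (larger) precision scale and a
  phoneme-awareness deficit shift with VA span untouched; DYS-VAS the
  converse; controls are unshifted.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from votcp.cp_scoring import (
    RESPONSE_D,
    RESPONSE_DIFFERENT,
    RESPONSE_SAME,
    RESPONSE_T,
)
from votcp.trial_designs import (
    DiscriminationDesign,
    IdentificationDesign,
    build_discrimination_design,
    build_identification_design,
)

GROUP_CONTROL = "CTL"
GROUP_DYS_PA = "DYS-PA"
GROUP_DYS_VAS = "DYS-VAS"
GROUP_DYS_DOUBLE = "DYS-DOUBLE"
GROUP_DYS_OTHER = "DYS-OTHER"

#: groups carrying a phoneme-awareness deficit (and the worse identification
#: slope that drives it) / a visual-attention-span deficit
PA_DEFICIT_GROUPS = frozenset({GROUP_DYS_PA, GROUP_DYS_DOUBLE})
VAS_DEFICIT_GROUPS = frozenset({GROUP_DYS_VAS, GROUP_DYS_DOUBLE})


@dataclass(frozen=True)
class NormEntry:
    mean: float
    sd: float
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("norm SD must be positive")


#: Default reference norms, on each task's printed scale. Magnitudes follow
#: the score ranges typical of ten-year-old readers on these batteries; they
#: are plausibility anchors, not published norm tables.
DEFAULT_NORMS: dict[str, NormEntry] = {
    "deletion_pct": NormEntry(83.4, 15.3),
    "segmentation_pct": NormEntry(61.0, 25.0),
    "acronyms_pct": NormEntry(82.0, 20.0),
    "global_report_pct": NormEntry(83.0, 11.0),
    "partial_report_pct": NormEntry(88.0, 11.0),
    "rw_score": NormEntry(19.0, 1.5),
    "iw_score": NormEntry(17.5, 3.2),
    "pw_score": NormEntry(17.8, 2.5),
    "rw_time_s": NormEntry(22.0, 8.0),
    "iw_time_s": NormEntry(26.0, 9.5),
    "pw_time_s": NormEntry(34.0, 9.0),
}

PA_TASKS = ("deletion_pct", "segmentation_pct", "acronyms_pct")
REPORT_TASKS = ("global_report_pct", "partial_report_pct")
READING_SCORES = ("rw_score", "iw_score", "pw_score")
READING_TIMES = ("rw_time_s", "iw_time_s", "pw_time_s")

SCORE_MAXIMA = {
    "deletion_pct": 100.0,
    "segmentation_pct": 100.0,
    "acronyms_pct": 100.0,
    "global_report_pct": 100.0,
    "partial_report_pct": 100.0,
    "rw_score": 20.0,
    "iw_score": 20.0,
    "pw_score": 20.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic study.

    Path coefficients are standardized: latent traits are built on a unit
    scale before the group deficit shifts, so ``path_a`` etc. are the
    population regression slopes among standardized variables.
    """

    n_control: int = 63
    n_dys_pa: int = 17
    n_dys_vas: int = 20
    n_dys_double: int = 7
    n_dys_other: int = 19
    age_range_months: tuple[int, int] = (94, 153)
    boundary_mean_ms: float = 5.0
    boundary_sd_ms: float = 11.0
    precision_mean_ms: float = 8.0
    precision_sd_ms: float = 3.0
    precision_dys_shift_ms: float = 4.0  # DYS-PA slope-scale worsening
    allophonic_weight: float = 0.0
    allophonic_width_ms: float = 10.0
    d_max: float = 3.5
    criterion_c: float = 0.5
    path_a: float = 0.4
    path_b: float = 0.4
    path_c_prime: float = 0.0
    path_d: float = 0.35
    pa_deficit_shift: float = -2.0  # applied to DYS-PA pa_ability
    vas_deficit_shift: float = -2.0  # applied to DYS-VAS vas_ability
    dys_reading_shift: float = -2.5  # reading deficit common to all DYS
    trait_noise_sd: float = 1.0
    task_noise_sd: float = 0.5
    id_reps: int = 10
    disc_reps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_dys_pa", "n_dys_vas", "n_dys_double", "n_dys_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("boundary_sd_ms", "precision_sd_ms", "trait_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.precision_mean_ms <= 0:
            raise ValueError("precision_mean_ms must be > 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        data = json.loads(text)
        data["age_range_months"] = tuple(data["age_range_months"])
        return cls(**data)


@dataclass(frozen=True)
class LatentProfile:
    participant_id: str
    group: str
    age_months: int
    boundary_mu_ms: float
    precision_s_ms: float
    pa_ability: float
    vas_ability: float
    reading_acc_latent: float
    reading_speed_latent: float


def _group_sizes(config: CohortConfig) -> list[tuple[str, int]]:
    return [
        (GROUP_CONTROL, config.n_control),
        (GROUP_DYS_PA, config.n_dys_pa),
        (GROUP_DYS_VAS, config.n_dys_vas),
        (GROUP_DYS_DOUBLE, config.n_dys_double),
        (GROUP_DYS_OTHER, config.n_dys_other),
    ]


def generate_cohort(config: CohortConfig) -> list[LatentProfile]:
    """Draw the latent profiles of one cohort, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    profiles: list[LatentProfile] = []
    counter = 0
    for group, n in _group_sizes(config):
        for _ in range(n):
            counter += 1
            pid = f"P{counter:04d}"
            age = int(rng.integers(config.age_range_months[0], config.age_range_months[1] + 1))
            mu = rng.normal(config.boundary_mean_ms, config.boundary_sd_ms)
            shift = (
                config.precision_dys_shift_ms if group in PA_DEFICIT_GROUPS else 0.0
            )
            s = -1.0
            while s <= 0.5:  # slope scale must stay positive
                s = rng.normal(config.precision_mean_ms + shift, config.precision_sd_ms)
            # standardized CP sharpness: sharper (smaller s) = higher
            cp_std = -(s - config.precision_mean_ms) / config.precision_sd_ms
            pa = config.path_a * cp_std + rng.normal(0.0, config.trait_noise_sd)
            if group in PA_DEFICIT_GROUPS:
                pa += config.pa_deficit_shift
            vas = rng.normal(0.0, config.trait_noise_sd)
            if group in VAS_DEFICIT_GROUPS:
                vas += config.vas_deficit_shift
            read_acc = (
                config.path_b * pa
                + config.path_c_prime * cp_std
                + config.path_d * vas
                + rng.normal(0.0, config.trait_noise_sd)
            )
            read_speed = config.path_d * vas + rng.normal(0.0, config.trait_noise_sd)
            if group != GROUP_CONTROL:
                read_acc += config.dys_reading_shift
                read_speed += config.dys_reading_shift
            profiles.append(
                LatentProfile(
                    participant_id=pid,
                    group=group,
                    age_months=age,
                    boundary_mu_ms=float(mu),
                    precision_s_ms=float(s),
                    pa_ability=float(pa),
                    vas_ability=float(vas),
                    reading_acc_latent=float(read_acc),
                    reading_speed_latent=float(read_speed),
                )
            )
    return profiles


def cp_sharpness(profile: LatentProfile, config: CohortConfig) -> float:
    """Standardized categorical-perception sharpness, -(s - mean) / sd.

    Higher = sharper identification; this is the latent trait behind path a.
    """
    return -(profile.precision_s_ms - config.precision_mean_ms) / config.precision_sd_ms


def labeling_probability(vot_ms, boundary_mu_ms: float, precision_s_ms: float):
    """P(/t/ | VOT) under the logistic identification model."""
    if precision_s_ms <= 0:
        raise ValueError("precision_s_ms must be > 0")
    vot = np.asarray(vot_ms, dtype=float)
    return 1.0 / (1.0 + np.exp(-(vot - boundary_mu_ms) / precision_s_ms))


def simulate_identification(
    profile: LatentProfile, design: IdentificationDesign, seed: int
) -> pd.DataFrame:
    """Bernoulli /d/-vs-/t/ responses for one identification block."""
    rng = np.random.default_rng(seed)
    p = labeling_probability(
        np.asarray(design.trials), profile.boundary_mu_ms, profile.precision_s_ms
    )
    is_t = rng.random(len(design.trials)) < p
    return pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "trial_index": np.arange(len(design.trials)),
            "vot_ms": design.trials,
            "response": np.where(is_t, RESPONSE_T, RESPONSE_D),
        }
    )


def true_discriminability(
    vot_a: float, vot_b: float, profile: LatentProfile, config: CohortConfig
) -> float:
    """Generative sensitivity for one AX pair.

    Phonemic component: ``d_max * |p_a - p_b|`` with p the labeling
    probabilities. Allophonic component: Gaussian bumps at pair centers
    -30 and +30 ms with width ``allophonic_width_ms``. Identical pairs have
    zero true discriminability by construction.
    """
    if vot_a == vot_b:
        return 0.0
    pa_, pb = (
        float(labeling_probability(v, profile.boundary_mu_ms, profile.precision_s_ms))
        for v in (vot_a, vot_b)
    )
    center = (vot_a + vot_b) / 2
    w = config.allophonic_width_ms
    allo = config.allophonic_weight * (
        np.exp(-((center + 30.0) ** 2) / (2 * w**2))
        + np.exp(-((center - 30.0) ** 2) / (2 * w**2))
    )
    return float(config.d_max * abs(pa_ - pb) + allo)


def different_response_probability(d_true: float, criterion_c: float) -> float:
    """P("different") under yes-no SDT with a single criterion."""
    return float(norm.cdf(d_true / np.sqrt(2.0) - criterion_c))


def simulate_discrimination(
    profile: LatentProfile,
    design: DiscriminationDesign,
    config: CohortConfig,
    seed: int,
) -> pd.DataFrame:
    """Same-different responses for one discrimination block."""
    rng = np.random.default_rng(seed)
    probs = np.array(
        [
            different_response_probability(
                true_discriminability(a, b, profile, config), config.criterion_c
            )
            for a, b in design.trials
        ]
    )
    diff = rng.random(len(design.trials)) < probs
    return pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "trial_index": np.arange(len(design.trials)),
            "vot_a_ms": [a for a, _ in design.trials],
            "vot_b_ms": [b for _, b in design.trials],
            "response": np.where(diff, RESPONSE_DIFFERENT, RESPONSE_SAME),
        }
    )


def _clip_score(task: str, value: float) -> float:
    hi = SCORE_MAXIMA.get(task)
    lo = 0.0
    if hi is None:  # reading times: bounded below only
        return max(1.0, value)
    return float(np.clip(value, lo, hi))


def simulate_task_scores(
    profile: LatentProfile,
    norms: dict[str, NormEntry] | None = None,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> dict:
    """Map latent traits to task scores on their printed scales.

    Each score is a clipped affine transform ``norm.mean + norm.sd * (latent +
    task noise)``. Reading times invert the speed latent (higher latent =
    faster = smaller time).
    """
    norms = norms or DEFAULT_NORMS
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    rec: dict = {
        "participant_id": profile.participant_id,
        "group": profile.group,
        "age_months": profile.age_months,
    }
    sd_n = config.task_noise_sd

    def noisy(latent: float) -> float:
        return latent + rng.normal(0.0, sd_n)

    for task in PA_TASKS:
        n = norms[task]
        rec[task] = _clip_score(task, n.mean + n.sd * noisy(profile.pa_ability))
    for task in REPORT_TASKS:
        n = norms[task]
        rec[task] = _clip_score(task, n.mean + n.sd * noisy(profile.vas_ability))
    for task in READING_SCORES:
        n = norms[task]
        rec[task] = _clip_score(task, n.mean + n.sd * noisy(profile.reading_acc_latent))
    for task in READING_TIMES:
        n = norms[task]
        rec[task] = _clip_score(task, n.mean - n.sd * noisy(profile.reading_speed_latent))
    # single-letter control scores: intact letter processing for everyone
    for d in (33, 50, 67, 84, 101):
        rec[f"letters_{d}ms"] = 10
    return rec


def simulate_study(
    config: CohortConfig, norms: dict[str, NormEntry] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: participants, identification and AX trial tables.

    Per-child seeds and design orders are derived from the config seed via
    ``numpy`` seed spawning, so the whole study is a pure function of the
    config.
    """
    norms = norms or DEFAULT_NORMS
    profiles = generate_cohort(config)
    root = np.random.SeedSequence(config.seed)
    records, id_frames, disc_frames = [], [], []
    for profile, child_seq in zip(profiles, root.spawn(len(profiles))):
        s_design, s_id, s_disc, s_scores = [
            int(s.generate_state(1)[0] % (2**31)) for s in child_seq.spawn(4)
        ]
        id_design = build_identification_design(reps=config.id_reps, seed=s_design)
        disc_design = build_discrimination_design(reps=config.disc_reps, seed=s_design)
        id_frames.append(simulate_identification(profile, id_design, s_id))
        disc_frames.append(simulate_discrimination(profile, disc_design, config, s_disc))
        records.append(simulate_task_scores(profile, norms, config, s_scores))
    participants = pd.DataFrame(records)
    return (
        participants,
        pd.concat(id_frames, ignore_index=True),
        pd.concat(disc_frames, ignore_index=True),
    )


def cohort_frame(profiles: list[LatentProfile]) -> pd.DataFrame:
    """Latent profiles as a DataFrame (one row per child)."""
    return pd.DataFrame([asdict(p) for p in profiles])
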