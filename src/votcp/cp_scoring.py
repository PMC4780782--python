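"""Per-participant categorical-perception scoring.

From identification trials: the labeling curve (proportion of /t/ responses
per VOT level) and the phonemic boundary, fitted by maximum-likelihood as a
logistic psychometric function

    P(/t/ | VOT) = 1 / (1 + exp(-(VOT - mu) / s))

where ``mu`` is the 50% crossing (the boundary, ms) and ``s`` the slope scale
(ms; smaller = sharper identification).

From discrimination trials: per-pair hit and false-alarm rates and d' for the
five adjacent VOT pairs (centers -60, -30, 0, +30, +60 ms), plus the
discrimination peak (largest d' and its center).

Predicted discrimination converts the identification curve into expected
same-different performance under a covert-labeling model: two stimuli are
judged "different" when they receive different covert phoneme labels, so

    predicted hit rate  H(i, j) = p_i (1 - p_j) + p_j (1 - p_i)
    predicted FA rate   F(i, j) = mean(2 p_i (1 - p_i), 2 p_j (1 - p_j))

with p the per-level /t/-labeling probabilities. Observed and predicted d'
share one transform: the log-linear (add 0.5 / add 1) rate correction is
applied always, followed by d' = z(H*) - z(F*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from votcp.trial_designs import VotContinuum

RESPONSE_T = "t"
RESPONSE_D = "d"
RESPONSE_DIFFERENT = "different"
RESPONSE_SAME = "same"


@dataclass(frozen=True)
class IdentificationCurve:
    """/t/-labeling counts per VOT level."""

    levels_ms: tuple[int, ...]
    n_t: tuple[int, ...]
    n_total: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.levels_ms) == len(self.n_t) == len(self.n_total)):
            raise ValueError("levels, counts and totals must align")
        if any(n <= 0 for n in self.n_total):
            raise ValueError("every level needs at least one trial")
        if any(k < 0 or k > n for k, n in zip(self.n_t, self.n_total)):
            raise ValueError("counts must satisfy 0 <= n_t <= n_total")

    @property
    def p_t(self) -> np.ndarray:
        return np.asarray(self.n_t, dtype=float) / np.asarray(self.n_total, dtype=float)


@dataclass(frozen=True)
class BoundaryFit:
    mu_ms: float  # NaN when not converged
    s_ms: float
    converged: bool
    method: str


@dataclass(frozen=True)
class PairScore:
    vot_a: int
    vot_b: int
    hit_rate: float
    fa_rate: float
    dprime: float
    kind: str  # "observed" | "predicted"

    @property
    def center_ms(self) -> float:
        return (self.vot_a + self.vot_b) / 2


@dataclass(frozen=True)
class DiscriminationProfile:
    scores: tuple[PairScore, ...]  # ordered by center
    peak_center_ms: float
    peak_amplitude: float
    kind: str


def tabulate_identification(
    trials: pd.DataFrame, continuum: VotContinuum | None = None
) -> IdentificationCurve:
    """Tally /t/ responses per VOT level from a trial table.

    ``trials`` needs columns ``vot_ms`` and ``response`` (values "d"/"t").
    Input order is irrelevant; every continuum level must be present.
    """
    continuum = continuum or VotContinuum()
    levels = continuum.levels_ms
    bad = set(trials["response"]) - {RESPONSE_D, RESPONSE_T}
    if bad:
        raise ValueError(f"unknown identification responses: {sorted(bad)}")
    n_t, n_total = [], []
    for v in levels:
        sub = trials.loc[trials["vot_ms"] == v, "response"]
        if sub.empty:
            raise ValueError(f"no identification trials at VOT level {v} ms")
        n_t.append(int((sub == RESPONSE_T).sum()))
        n_total.append(int(len(sub)))
    return IdentificationCurve(levels_ms=levels, n_t=tuple(n_t), n_total=tuple(n_total))


def _nll(params: np.ndarray, x: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    mu, log_s = params
    s = math.exp(log_s)
    eta = (x - mu) / s
    # log-likelihood of binomial counts under the logistic curve
    return float(np.sum(n * np.logaddexp(0.0, eta)) - np.sum(k * eta))


def fit_boundary(curve: IdentificationCurve) -> BoundaryFit:
    """Maximum-likelihood logistic fit of the identification boundary.

    The slope scale is constrained to at least one sixth of the grid spacing:
    on a 30 ms grid, slopes steeper than ~5 ms are not identifiable (no
    stimuli fall between levels) and the unconstrained likelihood degenerates
    into near-step interpolants of the raw proportions, which badly biases
    the crossing point.

    Degenerate data (all responses one label) carry no boundary information:
    ``converged`` is False and ``mu_ms`` NaN. Perfectly separated step data
    are fitted at the midpoint of the separating gap, which is the
    constrained maximum by symmetry (method "separation-midpoint").
    """
    x = np.asarray(curve.levels_ms, dtype=float)
    k = np.asarray(curve.n_t, dtype=float)
    n = np.asarray(curve.n_total, dtype=float)
    p = curve.p_t
    spacing = float(np.min(np.diff(x)))
    s_floor = spacing / 6.0
    span = float(x[-1] - x[0])
    if np.all(k == 0) or np.all(k == n):
        return BoundaryFit(math.nan, math.nan, False, "degenerate")
    # perfect step: all 0s strictly left of all 1s
    if np.all((p == 0) | (p == 1)) and np.all(np.diff(p) >= 0):
        last0 = x[p == 0][-1]
        first1 = x[p == 1][0]
        return BoundaryFit(
            float((last0 + first1) / 2), s_floor, True, "separation-midpoint"
        )

    bounds = [(x[0] - 2 * span, x[-1] + 2 * span), (math.log(s_floor), math.log(20 * span))]
    crossing = float(x[np.argmin(np.abs(p - 0.5))])  # rough start near 50%
    best = None
    for start in (
        np.array([crossing, math.log(10.0)]),
        np.array([0.0, math.log(spacing / 2)]),
        np.array([x.mean(), math.log(span)]),
    ):
        res = optimize.minimize(
            _nll, start, args=(x, k, n), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_s = best.x
    s = math.exp(log_s)
    # non-identifiable fits drift far off the stimulus grid
    if abs(mu - x.mean()) > 1.5 * span or s > 10 * span:
        return BoundaryFit(math.nan, math.nan, False, "mle-nonidentifiable")
    return BoundaryFit(float(mu), float(s), True, "mle")


def observed_pair_rates(
    trials: pd.DataFrame, pair: tuple[int, int]
) -> tuple[float, float]:
    """Hit and false-alarm rates for one adjacent pair from AX trials.

    Hits: "different" responses pooled over both orders (i,j) and (j,i).
    False alarms: mean of the "different" proportions on the two flanking
    identical pairs (i,i) and (j,j).
    """
    i, j = pair
    pairs = list(zip(trials["vot_a_ms"], trials["vot_b_ms"]))
    resp = np.asarray(trials["response"] == RESPONSE_DIFFERENT)

    def _prop(a: int, b: int) -> tuple[int, int]:
        idx = [t for t, p in enumerate(pairs) if p == (a, b)]
        return int(resp[idx].sum()), len(idx)

    h_num, h_den = 0, 0
    for a, b in ((i, j), (j, i)):
        s, m = _prop(a, b)
        h_num, h_den = h_num + s, h_den + m
    if h_den == 0:
        raise ValueError(f"no trials for different pair {i}/{j}")
    fas = []
    for v in (i, j):
        s, m = _prop(v, v)
        if m == 0:
            raise ValueError(f"no trials for identical pair {v}/{v}")
        fas.append(s / m)
    return h_num / h_den, float(np.mean(fas))


def loglinear_rate(rate: float, n_trials: int) -> float:
    """Log-linear correction: add 0.5 to the count, 1 to the denominator."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    return (rate * n_trials + 0.5) / (n_trials + 1)


def dprime(hit_rate: float, fa_rate: float, n_hit_trials: int, n_fa_trials: int) -> float:
    """Yes-no d' with the log-linear correction applied to both rates, always."""
    h = loglinear_rate(hit_rate, n_hit_trials)
    f = loglinear_rate(fa_rate, n_fa_trials)
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def predicted_different_prob(p_i: float, p_j: float) -> float:
    """Probability the two stimuli receive different covert labels."""
    for p in (p_i, p_j):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"labeling probability {p} outside [0, 1]")
    return p_i * (1.0 - p_j) + p_j * (1.0 - p_i)


def find_peak(scores: list[PairScore] | tuple[PairScore, ...]) -> tuple[float, float]:
    """Largest d' and its center; ties go to the smallest |center|, then negative."""
    best = max(scores, key=lambda s: (s.dprime, -abs(s.center_ms), -s.center_ms))
    return best.center_ms, best.dprime


def _profile(scores: list[PairScore], kind: str) -> DiscriminationProfile:
    scores = sorted(scores, key=lambda s: s.center_ms)
    center, amp = find_peak(scores)
    return DiscriminationProfile(
        scores=tuple(scores), peak_center_ms=center, peak_amplitude=amp, kind=kind
    )


def predicted_profile(
    curve: IdentificationCurve,
    n_hit_trials: int = 10,
    n_fa_trials: int = 10,
) -> DiscriminationProfile:
    """Predicted discrimination profile from the identification curve.

    Pseudo-trial counts default to the standard design: 10 different-pair
    trials (both orders) and 10 identical-pair trials (5 + 5) per pair, so
    the correction matches the observed-d' transform.
    """
    p = curve.p_t
    scores = []
    for idx in range(len(curve.levels_ms) - 1):
        i, j = curve.levels_ms[idx], curve.levels_ms[idx + 1]
        pi, pj = float(p[idx]), float(p[idx + 1])
        hit = predicted_different_prob(pi, pj)
        fa = float(np.mean([2 * pi * (1 - pi), 2 * pj * (1 - pj)]))
        scores.append(
            PairScore(i, j, hit, fa, dprime(hit, fa, n_hit_trials, n_fa_trials), "predicted")
        )
    return _profile(scores, "predicted")


def observed_profile(
    trials: pd.DataFrame, continuum: VotContinuum | None = None
) -> DiscriminationProfile:
    """Observed discrimination profile from a complete AX block."""
    continuum = continuum or VotContinuum()
    bad = set(trials["response"]) - {RESPONSE_SAME, RESPONSE_DIFFERENT}
    if bad:
        raise ValueError(f"unknown discrimination responses: {sorted(bad)}")
    have = set(zip(trials["vot_a_ms"], trials["vot_b_ms"]))
    needed = [(v, v) for v in continuum.levels_ms] + continuum.adjacent_pairs()
    missing = [p for p in needed if p not in have]
    if missing:
        raise ValueError(f"incomplete discrimination block; missing pairs: {missing}")
    scores = []
    for idx in range(len(continuum.levels_ms) - 1):
        i, j = continuum.levels_ms[idx], continuum.levels_ms[idx + 1]
        pairs = list(zip(trials["vot_a_ms"], trials["vot_b_ms"]))
        n_hit = sum(1 for p in pairs if p in {(i, j), (j, i)})
        n_fa = sum(1 for p in pairs if p in {(i, i), (j, j)})
        hit, fa = observed_pair_rates(trials, (i, j))
        scores.append(PairScore(i, j, hit, fa, dprime(hit, fa, n_hit, n_fa), "observed"))
    return _profile(scores, "observed")


def boundary_distribution_stats(boundaries) -> tuple[float, float, float]:
    """Mean, sample SD and bias-adjusted Fisher-Pearson skewness G1.

    Missing values (non-converged boundaries) are dropped; at least three
    finite boundaries are required.
    """
    b = np.asarray(boundaries, dtype=float)
    b = b[np.isfinite(b)]
    if b.size < 3:
        raise ValueError("need at least 3 non-missing boundaries")
    return (
        float(np.mean(b)),
        float(np.std(b, ddof=1)),
        float(stats.skew(b, bias=False)),
    )


def score_participants(
    identification_trials: pd.DataFrame,
    discrimination_trials: pd.DataFrame,
    continuum: VotContinuum | None = None,
) -> pd.DataFrame:
    """Per-participant derived-variable table.

    Both inputs carry a ``participant_id`` column. The output has one row per
    participant: boundary fit, observed and predicted d' at the five pair
    centers, and both peaks.
    """
    continuum = continuum or VotContinuum()
    centers = continuum.pair_centers()
    rows = []
    ids = sorted(set(identification_trials["participant_id"]))
    disc_ids = set(discrimination_trials["participant_id"])
    orphans = sorted(disc_ids - set(ids))
    if orphans:
        raise ValueError(f"discrimination trials for unknown participants: {orphans}")
    for pid in ids:
        id_t = identification_trials[identification_trials["participant_id"] == pid]
        disc_t = discrimination_trials[discrimination_trials["participant_id"] == pid]
        curve = tabulate_identification(id_t, continuum)
        fit = fit_boundary(curve)
        pred = predicted_profile(curve)
        obs = observed_profile(disc_t, continuum)
        row: dict = {
            "participant_id": pid,
            "boundary_mu_ms": fit.mu_ms,
            "boundary_s_ms": fit.s_ms,
            "boundary_converged": fit.converged,
        }
        for c, s in zip(centers, obs.scores):
            row[f"obs_dprime_{int(c):+d}"] = s.dprime
        for c, s in zip(centers, pred.scores):
            row[f"pred_dprime_{int(c):+d}"] = s.dprime
        row["obs_peak_center_ms"] = obs.peak_center_ms
        row["obs_peak_amplitude"] = obs.peak_amplitude
        row["pred_peak_center_ms"] = pred.peak_center_ms
        row["pred_peak_amplitude"] = pred.peak_amplitude
        rows.append(row)
    return pd.DataFrame(rows)
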