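"""Group-level inference: mixed repeated-measures ANOVA, ANCOVA on
discrimination peaks, and age-partialled correlations.

The mixed (split-plot) ANOVA takes one between-subjects factor and one or two
within-subject factors with a complete, balanced within design per subject.
Sums of squares are computed through orthonormal within-subject contrasts:
for each within effect the subject-by-cell matrix is projected onto the
effect's contrast space, the projected scores are analysed as a one-way
between-groups model, and the within main effect is the (Type III,
unweighted-means) test of a zero grand mean of the contrast scores. For
balanced group sizes this reproduces the classical split-plot decomposition
exactly; with unequal groups the main-effect test weights groups equally, as
mainstream ANOVA software does.

Sphericity is handled by the Greenhouse-Geisser correction: for a within
effect with contrast matrix C and pooled within-group covariance S of the
cell scores, epsilon = tr(CSC')^2 / (q * tr((CSC')^2)) with q the effect's
degrees of freedom, and the F test's degrees of freedom are multiplied by
epsilon. Effects with a single degree of freedom have epsilon = 1. Effect
sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p_uncorrected: float
    gg_epsilon: float
    p_gg: float
    partial_eta2: float
    ss_effect: float
    ss_error: float

    def report(self) -> str:
        """One line in the field's reporting style."""
        return (
            f"{self.effect}: F({self.df_num:g},{self.df_den:g}) = {self.F:.2f}, "
            f"p = {self.p_gg:.3f}, partial eta2 = {self.partial_eta2:.3f}"
        )


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    df: int
    p: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the unit vector."""
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    # Helmert-style, then orthonormalized
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def _cell_matrix(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> tuple[np.ndarray, np.ndarray, list[tuple], list[int]]:
    """Subjects-by-cells response matrix plus group codes and cell order."""
    levels = [sorted(table[w].unique()) for w in within]
    cells = list(itertools.product(*levels))
    subjects = sorted(table[subject].unique())
    groups_of = table.drop_duplicates(subject).set_index(subject)[between]
    y = np.full((len(subjects), len(cells)), np.nan)
    cell_index = {c: j for j, c in enumerate(cells)}
    for (sid, *wvals), sub in table.groupby([subject] + within):
        if len(sub) != 1:
            raise ValueError(
                f"within design unbalanced: subject {sid} has {len(sub)} rows in cell {tuple(wvals)}"
            )
        y[subjects.index(sid), cell_index[tuple(wvals)]] = sub[dv].iloc[0]
    if np.isnan(y).any():
        missing = [
            (subjects[i], cells[j]) for i, j in zip(*np.nonzero(np.isnan(y)))
        ]
        raise ValueError(f"within design incomplete; missing cells: {missing[:5]}")
    group_labels = sorted(set(groups_of))
    g = np.array([group_labels.index(groups_of[s]) for s in subjects])
    klevels = [len(lv) for lv in levels]
    return y, g, cells, klevels


def _f_p(ss_eff, df_eff, ss_err, df_err):
    if ss_err <= 0 or df_err <= 0:
        return float("nan"), float("nan")
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return f, float(stats.f.sf(f, df_eff, df_err))


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> list[AnovaResult]:
    """Split-plot ANOVA: one between factor, one or two within factors.

    Returns results for the between main effect, every within main effect,
    every within-by-between interaction, and (with two within factors) the
    within-by-within effects. Greenhouse-Geisser corrected p-values are
    reported for every within effect; epsilon is exactly 1 for 1-df effects.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("supply one or two within-subject factors")
    y, g, cells, klevels = _cell_matrix(table, dv, subject, between, within)
    n_subj, n_cells = y.shape
    n_groups = g.max() + 1
    if min(np.bincount(g)) < 2:
        raise ValueError("need at least 2 subjects per group")
    counts = np.bincount(g, minlength=n_groups).astype(float)

    # pooled within-group covariance of the cell scores (for GG epsilon)
    resid = y - np.vstack([y[g == j].mean(axis=0) for j in range(n_groups)])[g]
    pooled_cov = resid.T @ resid / (n_subj - n_groups)

    results: list[AnovaResult] = []

    # ---- between-subjects stratum (subject means) ----
    m = y.mean(axis=1)
    gm = np.array([m[g == j].mean() for j in range(n_groups)])
    grand_w = m.mean()
    ss_group = n_cells * float(np.sum(counts * (gm - grand_w) ** 2))
    ss_subj = n_cells * float(np.sum((m - gm[g]) ** 2))
    df_group, df_subj = n_groups - 1, n_subj - n_groups
    f, p = _f_p(ss_group, df_group, ss_subj, df_subj)
    results.append(
        AnovaResult(between, f, df_group, df_subj, p, 1.0, p,
                    ss_group / (ss_group + ss_subj) if ss_group + ss_subj > 0 else float("nan"),
                    ss_group, ss_subj)
    )

    # ---- within strata ----
    unit = [np.ones(k) / np.sqrt(k) for k in klevels]
    contr = [_orthonormal_contrasts(k) for k in klevels]

    def effect_contrast(which: tuple[bool, ...]) -> np.ndarray:
        parts = [contr[i] if flag else unit[i][None, :] for i, flag in enumerate(which)]
        c = parts[0]
        for nxt in parts[1:]:
            c = np.kron(c, nxt)
        return c

    if len(within) == 1:
        effect_specs = [((True,), within[0])]
    else:
        effect_specs = [
            ((True, False), within[0]),
            ((False, True), within[1]),
            ((True, True), f"{within[0]} x {within[1]}"),
        ]

    for which, name in effect_specs:
        c = effect_contrast(which)
        q = c.shape[0]
        z = y @ c.T  # subjects x q
        zg = np.vstack([z[g == j].mean(axis=0) for j in range(n_groups)])
        # error: pooled within-group SS of the contrast scores
        ss_err = float(np.sum((z - zg[g]) ** 2))
        df_err = (n_subj - n_groups) * q
        # main effect: unweighted grand mean of the contrast scores
        m_unw = zg.mean(axis=0)
        scale = n_groups**2 / float(np.sum(1.0 / counts))
        ss_main = scale * float(np.sum(m_unw**2))
        # interaction with the between factor: between-group SS per column
        zbar_w = (counts[:, None] * zg).sum(axis=0) / counts.sum()
        ss_int = float(np.sum(counts[:, None] * (zg - zbar_w) ** 2))

        msr = c @ pooled_cov @ c.T
        tr2 = float(np.trace(msr @ msr))
        if q == 1 or tr2 <= 0:  # 1-df effect, or degenerate (constant) data
            eps = 1.0
        else:
            eps = float(np.trace(msr) ** 2 / (q * tr2))
            eps = min(1.0, max(eps, 1.0 / q))

        for eff_name, ss_eff, df_eff in (
            (name, ss_main, q),
            (f"{name} x {between}", ss_int, (n_groups - 1) * q),
        ):
            f, p = _f_p(ss_eff, df_eff, ss_err, df_err)
            p_gg = (
                float(stats.f.sf(f, df_eff * eps, df_err * eps))
                if np.isfinite(f)
                else float("nan")
            )
            peta = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else float("nan")
            results.append(
                AnovaResult(eff_name, f, df_eff, df_err, p, eps, p_gg, peta, ss_eff, ss_err)
            )
    return results


def ancova_peak(
    table: pd.DataFrame,
    group: str = "group",
    amplitude: str = "peak_amplitude",
    location: str = "peak_location",
) -> list[AnovaResult]:
    """ANCOVA of peak amplitude on group with peak location as covariate.

    Fits ``amplitude ~ group + location + group:location`` by OLS and reports
    Type II F tests with partial eta squared for the group effect, the
    location effect and their interaction.
    """
    df = table[[group, amplitude, location]].dropna().copy()
    per_group = df.groupby(group).size()
    if (per_group < 3).any():
        raise ValueError("need at least 3 participants with peaks per group")
    if float(df[location].var(ddof=1)) == 0.0:
        raise ValueError("peak location has zero variance (collinear covariate)")
    df = df.rename(columns={group: "g", amplitude: "amp", location: "loc"})
    model = smf.ols("amp ~ C(g) + loc + C(g):loc", data=df).fit()
    tab = anova_lm(model, typ=2)
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    df_resid = float(tab.loc["Residual", "df"])
    out = []
    pretty = {"C(g)": group, "loc": location, "C(g):loc": f"{group} x {location}"}
    for term in ("C(g)", "loc", "C(g):loc"):
        ss = float(tab.loc[term, "sum_sq"])
        dfn = float(tab.loc[term, "df"])
        f = float(tab.loc[term, "F"])
        p = float(tab.loc[term, "PR(>F)"])
        out.append(
            AnovaResult(pretty[term], f, dfn, df_resid, p, 1.0, p,
                        ss / (ss + ss_resid), ss, ss_resid)
        )
    return out


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    x = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(x, v, rcond=None)
    return v - x @ beta


def partial_correlation(x, y, covariate) -> PartialCorrResult:
    """Pearson correlation of x and y with one covariate partialled out.

    Both variables are residualized on the covariate; the p-value uses a
    t distribution with n - 3 degrees of freedom (two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(cov)):
        raise ValueError("inputs must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(cov).any():
        raise ValueError("missing values must be removed upstream (pairwise deletion)")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    for name, r_, v in (("x", rx, x), ("y", ry, y)):
        total = float(np.sum((v - v.mean()) ** 2))
        if float(np.sum(r_**2)) <= max(1e-12 * total, 1e-300):
            raise ValueError(f"zero residual variance in {name}")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = len(x) - 3
    if abs(r) >= 1.0:
        return PartialCorrResult(r, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PartialCorrResult(r, df, p)


def correlation_matrix(
    table: pd.DataFrame, variables: list[str], covariate: str
) -> pd.DataFrame:
    """Lower-triangle-symmetric matrix of age-partialled correlations.

    Missing values are handled by pairwise deletion: each pair uses every
    row where both variables and the covariate are present.
    """
    out_r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            sub = table[[a, b, covariate]].dropna()
            res = partial_correlation(sub[a], sub[b], sub[covariate])
            out_r.loc[a, b] = out_r.loc[b, a] = res.r
    return out_r
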