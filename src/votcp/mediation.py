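"""Causal-steps mediation of categorical perception on reading accuracy
through phoneme awareness, with visual attention span and age as additional
regressors.

Three ordinary-least-squares models are fitted, in order:

1. phoneme awareness  = i1 + j1 age + a  cp_index
2. reading accuracy   = i2 + j2 age + c  cp_index + d  vas
3. reading accuracy   = i3 + j3 age + c' cp_index + b  phoneme awareness + d' vas

The causal-steps verdict requires a, c and b significant (two-sided, alpha
.05) and c' no longer significant. The indirect effect a*b is tested with the
Sobel statistic z = a b / sqrt(b^2 se_a^2 + a^2 se_b^2); the p-value is the
one-sided upper tail, matching the direction of the hypothesized positive
indirect effect.

All variables are standardized (z-scored over the analysis sample) before
fitting, so the reported paths are standardized regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class ModelFit:
    """Coefficients and standard errors of one OLS model, keyed by regressor."""

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    nobs: int


@dataclass(frozen=True)
class MediationResult:
    model1: ModelFit  # mediator ~ age + x
    model2: ModelFit  # outcome ~ age + x + vas
    model3: ModelFit  # outcome ~ age + x + mediator + vas
    paths: dict[str, float]  # a, b, c, c_prime, d, d_prime
    path_se: dict[str, float]
    sobel_z: float
    sobel_p_one_sided: float
    steps: dict[str, bool]
    alpha: float

    @property
    def mediation_established(self) -> bool:
        return all(self.steps.values())

    def path_diagram(self) -> str:
        """Text summary mirroring the usual X -> M -> Y diagram layout."""
        p, s = self.paths, self.steps
        flag = lambda ok: "*" if ok else "ns"
        return "\n".join(
            [
                "              phoneme awareness",
                f"        a = {p['a']:+.3f} ({flag(s['a_significant'])})"
                f"   b = {p['b']:+.3f} ({flag(s['b_significant'])})",
                "   CP index  ------------------>  reading accuracy",
                f"        c = {p['c']:+.3f} ({flag(s['c_significant'])})"
                f"   c' = {p['c_prime']:+.3f}"
                f" ({'ns' if s['c_prime_nonsignificant'] else '*'})",
                f"   VA span: d = {p['d']:+.3f}, d' = {p['d_prime']:+.3f}",
                f"   Sobel z = {self.sobel_z:.2f}, one-sided p = {self.sobel_p_one_sided:.3f}",
            ]
        )


def sobel(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel test of the indirect effect a*b.

    Returns (z, one-sided p). The p-value is the upper-tail probability
    1 - Phi(z), i.e. small when the indirect effect is reliably positive.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    se = np.sqrt(b**2 * se_a**2 + a**2 * se_b**2)
    if se == 0:  # a == b == 0
        return 0.0, 0.5
    z = a * b / se
    return float(z), float(stats.norm.sf(z))


def _zstd(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized")
    return (v - v.mean()) / sd


def _ols(y: np.ndarray, x_cols: dict[str, np.ndarray]) -> ModelFit:
    names = list(x_cols)
    x = sm.add_constant(np.column_stack([x_cols[n] for n in names]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, x).fit()
    keys = ["intercept"] + names
    return ModelFit(
        params=dict(zip(keys, fit.params)),
        bse=dict(zip(keys, fit.bse)),
        pvalues=dict(zip(keys, fit.pvalues)),
        nobs=int(fit.nobs),
    )


def causal_steps(
    table: pd.DataFrame,
    x: str = "pred_peak_amplitude",
    mediator: str = "pa_composite",
    outcome: str = "reading_accuracy",
    vas: str = "vas_composite",
    age: str = "age_months",
    alpha: float = 0.05,
    mediator_model_includes_vas: bool = False,
) -> MediationResult:
    """Three-step causal mediation analysis on complete cases.

    ``mediator_model_includes_vas`` adds the VA-span regressor to model 1 as
    well, which makes the exact decomposition c = c' + a*b hold (all three
    models then share one covariate set).
    """
    cols = [x, mediator, outcome, vas, age]
    data = table[cols].dropna()
    n = len(data)
    if n <= len(cols) + 2:
        raise ValueError(f"too few complete cases (n = {n}) for mediation")
    v = {c: _zstd(data[c].to_numpy(dtype=float)) for c in cols}

    m1_cols = {"age": v[age], "x": v[x]}
    if mediator_model_includes_vas:
        m1_cols["vas"] = v[vas]
    m1 = _ols(v[mediator], m1_cols)
    m2 = _ols(v[outcome], {"age": v[age], "x": v[x], "vas": v[vas]})
    m3 = _ols(
        v[outcome], {"age": v[age], "x": v[x], "mediator": v[mediator], "vas": v[vas]}
    )

    paths = {
        "a": m1.params["x"],
        "c": m2.params["x"],
        "d": m2.params["vas"],
        "c_prime": m3.params["x"],
        "b": m3.params["mediator"],
        "d_prime": m3.params["vas"],
    }
    path_se = {
        "a": m1.bse["x"],
        "c": m2.bse["x"],
        "d": m2.bse["vas"],
        "c_prime": m3.bse["x"],
        "b": m3.bse["mediator"],
        "d_prime": m3.bse["vas"],
    }
    z, p = sobel(paths["a"], path_se["a"], paths["b"], path_se["b"])
    steps = {
        "a_significant": m1.pvalues["x"] < alpha,
        "c_significant": m2.pvalues["x"] < alpha,
        "b_significant": m3.pvalues["mediator"] < alpha,
        "c_prime_nonsignificant": m3.pvalues["x"] >= alpha,
    }
    return MediationResult(
        model1=m1, model2=m2, model3=m3, paths=paths, path_se=path_se,
        sobel_z=z, sobel_p_one_sided=p, steps=steps, alpha=alpha,
    )


def select_cp_index(
    table: pd.DataFrame,
    candidates: list[str],
    mediator: str = "pa_composite",
    age: str = "age_months",
    alpha: float = 0.05,
) -> tuple[str | None, pd.DataFrame]:
    """Exploratory scan: which CP index relates to the mediator?

    Runs an age-partialled correlation between each candidate CP index and
    the mediator, and returns the significant candidate with the largest
    |r| (or None) together with the full scan log.
    """
    from votcp.group_inference import partial_correlation

    rows = []
    for cand in candidates:
        sub = table[[cand, mediator, age]].dropna()
        res = partial_correlation(sub[cand], sub[mediator], sub[age])
        rows.append({"candidate": cand, "r": res.r, "df": res.df, "p": res.p})
    log = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    sig = log[log["p"] < alpha]
    best = None if sig.empty else sig.iloc[sig["r"].abs().argmax()]["candidate"]
    return best, log
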