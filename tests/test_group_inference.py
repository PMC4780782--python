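"""Mixed ANOVA, ANCOVA and partial correlations against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from votcp import group_inference as gi


def make_long(y, groups, tasks=("observed", "predicted"), vots=(-30, 0, 30)):
    """y indexed [subject, task, vot]; groups one label per subject."""
    rows = []
    for i in range(y.shape[0]):
        for t_idx, t in enumerate(tasks):
            for v_idx, v in enumerate(vots):
                rows.append(
                    {"participant_id": f"S{i:03d}", "group": groups[i],
                     "task": t, "vot_center": v, "dprime": y[i, t_idx, v_idx]}
                )
    return pd.DataFrame(rows)


def split_plot_oracle(y, g):
    """Brute-force balanced split-plot SS decomposition from cell means.

    y: subjects x T x V array; g: integer group codes with equal group sizes.
    Returns dict of (ss_effect, df_effect, ss_error, df_error).
    """
    n, T, V = y.shape
    groups = sorted(set(g))
    G = len(groups)
    n_g = n // G
    gm = y.mean()
    m_g = {a: y[g == a].mean() for a in groups}
    m_gi = y.mean(axis=(1, 2))
    m_t = y.mean(axis=(0, 2))
    m_v = y.mean(axis=(0, 1))
    m_gt = {a: y[g == a].mean(axis=(0, 2)) for a in groups}
    m_gv = {a: y[g == a].mean(axis=(0, 1)) for a in groups}
    m_tv = y.mean(axis=0)
    m_gtv = {a: y[g == a].mean(axis=0) for a in groups}
    m_git = y.mean(axis=2)
    m_giv = y.mean(axis=1)

    ss_group = T * V * n_g * sum((m_g[a] - gm) ** 2 for a in groups)
    ss_subj = T * V * sum((m_gi[i] - m_g[g[i]]) ** 2 for i in range(n))
    ss_task = n * V * np.sum((m_t - gm) ** 2)
    ss_tg = V * n_g * sum(
        np.sum((m_gt[a] - m_g[a] - m_t + gm) ** 2) for a in groups
    )
    ss_ts = V * sum(
        np.sum((m_git[i] - m_gi[i] - m_gt[g[i]] + m_g[g[i]]) ** 2) for i in range(n)
    )
    ss_vot = n * T * np.sum((m_v - gm) ** 2)
    ss_vg = T * n_g * sum(
        np.sum((m_gv[a] - m_g[a] - m_v + gm) ** 2) for a in groups
    )
    ss_vs = T * sum(
        np.sum((m_giv[i] - m_gi[i] - m_gv[g[i]] + m_g[g[i]]) ** 2) for i in range(n)
    )
    ss_tv = n * np.sum((m_tv - m_t[:, None] - m_v[None, :] + gm) ** 2)
    ss_tvg = n_g * sum(
        np.sum(
            (m_gtv[a] - m_gt[a][:, None] - m_gv[a][None, :] - m_tv
             + m_g[a] + m_t[:, None] + m_v[None, :] - gm) ** 2
        )
        for a in groups
    )
    ss_tvs = sum(
        np.sum(
            (y[i] - m_git[i][:, None] - m_giv[i][None, :] + m_gi[i]
             - m_gtv[g[i]] + m_gt[g[i]][:, None] + m_gv[g[i]][None, :] - m_g[g[i]]) ** 2
        )
        for i in range(n)
    )
    dfs = n - G
    return {
        "group": (ss_group, G - 1, ss_subj, dfs),
        "task": (ss_task, T - 1, ss_ts, dfs * (T - 1)),
        "task x group": (ss_tg, (G - 1) * (T - 1), ss_ts, dfs * (T - 1)),
        "vot_center": (ss_vot, V - 1, ss_vs, dfs * (V - 1)),
        "vot_center x group": (ss_vg, (G - 1) * (V - 1), ss_vs, dfs * (V - 1)),
        "task x vot_center": (ss_tv, (T - 1) * (V - 1), ss_tvs, dfs * (T - 1) * (V - 1)),
        "task x vot_center x group": (
            ss_tvg, (G - 1) * (T - 1) * (V - 1), ss_tvs, dfs * (T - 1) * (V - 1)
        ),
    }


class TestMixedAnova:
    def run_both(self, seed=0, n_per_group=3):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        y = rng.normal(size=(n, 2, 3)) + rng.normal(size=(n, 1, 1))
        g = np.array([0] * n_per_group + [1] * n_per_group)
        table = make_long(y, ["CTL" if a == 0 else "DYS" for a in g])
        ours = {
            r.effect: r
            for r in gi.mixed_anova(
                table, "dprime", "participant_id", "group", ["task", "vot_center"]
            )
        }
        oracle = split_plot_oracle(y, g)
        return ours, oracle

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_ss_oracle(self, seed):
        ours, oracle = self.run_both(seed=seed)
        assert set(ours) == set(oracle)
        for name, (ss_e, df_e, ss_err, df_err) in oracle.items():
            r = ours[name]
            assert r.ss_effect == pytest.approx(ss_e, abs=1e-8), name
            assert r.ss_error == pytest.approx(ss_err, abs=1e-8), name
            assert (r.df_num, r.df_den) == (df_e, df_err), name
            f_oracle = (ss_e / df_e) / (ss_err / df_err)
            assert r.F == pytest.approx(f_oracle, abs=1e-8), name
            peta = ss_e / (ss_e + ss_err)
            assert r.partial_eta2 == pytest.approx(peta, abs=1e-10), name

    def test_two_level_within_epsilon_is_one(self):
        ours, _ = self.run_both(seed=3)
        assert ours["task"].gg_epsilon == 1.0
        assert ours["task x group"].gg_epsilon == 1.0

    def test_gg_correction_never_lowers_p_for_real_effects(self):
        # shrinking both df by epsilon raises p for clearly non-null F;
        # in the neighbourhood of F ~ 1 the tail mass can move either way,
        # so the monotonicity claim only applies away from it
        for seed in range(5):
            ours, _ = self.run_both(seed=seed, n_per_group=5)
            for r in ours.values():
                if np.isfinite(r.F) and r.F >= 2.0:
                    assert r.p_gg >= r.p_uncorrected - 1e-12

    def test_partial_eta2_from_f_identity(self):
        ours, _ = self.run_both(seed=4)
        for r in ours.values():
            from_f = r.F * r.df_num / (r.F * r.df_num + r.df_den)
            assert r.partial_eta2 == pytest.approx(from_f, abs=1e-10)

    def test_constant_response_flagged(self):
        y = np.ones((6, 2, 3))
        table = make_long(y, ["CTL"] * 3 + ["DYS"] * 3)
        res = gi.mixed_anova(
            table, "dprime", "participant_id", "group", ["task", "vot_center"]
        )
        assert all(np.isnan(r.F) for r in res)

    def test_unbalanced_within_design_rejected(self):
        y = np.zeros((4, 2, 3))
        table = make_long(y, ["CTL"] * 2 + ["DYS"] * 2)
        with pytest.raises(ValueError, match="(unbalanced|incomplete)"):
            gi.mixed_anova(
                table.iloc[:-1], "dprime", "participant_id", "group",
                ["task", "vot_center"],
            )

    def test_agrees_with_pingouin_one_within_factor(self):
        rng = np.random.default_rng(11)
        n = 16
        y = rng.normal(size=(n, 1, 3)) + rng.normal(size=(n, 1, 1))
        table = make_long(y, ["CTL"] * 8 + ["DYS"] * 8, tasks=("obs",))
        ours = {
            r.effect: r
            for r in gi.mixed_anova(
                table, "dprime", "participant_id", "group", ["vot_center"]
            )
        }
        ref = pg.mixed_anova(
            data=table, dv="dprime", within="vot_center",
            subject="participant_id", between="group", correction=True,
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours["vot_center"].F == pytest.approx(ref.loc["vot_center", "F"], rel=1e-9)
        assert ours["vot_center x group"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )
        assert ours["vot_center"].partial_eta2 == pytest.approx(
            float(ref.loc["vot_center", "np2"]), rel=1e-6
        )
        # pingouin estimates epsilon from the grand covariance; we pool it
        # within groups (the split-plot convention), so agreement is loose
        assert ours["vot_center"].gg_epsilon == pytest.approx(
            float(ref.loc["vot_center", "eps"]), abs=0.05
        )
        # exact double-entry check of the pooled-covariance epsilon
        wide = table.pivot(index="participant_id", columns="vot_center", values="dprime")
        glab = table.drop_duplicates("participant_id").set_index("participant_id")["group"]
        resid = wide - wide.groupby(glab).transform("mean")
        S = resid.T @ resid / (len(wide) - 2)
        k = S.shape[0]
        C = np.linalg.qr(
            np.vstack([np.ones(k) / np.sqrt(k), np.eye(k)[:-1]]).T
        )[0][:, 1:].T
        M = C @ S.to_numpy() @ C.T
        eps_oracle = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
        assert ours["vot_center"].gg_epsilon == pytest.approx(eps_oracle, abs=1e-10)

    def test_group_shift_power(self):
        # planted between-group shift of 0.5 within-cell SD is detected
        rng = np.random.default_rng(21)
        sig = 0
        runs = 50
        for _ in range(runs):
            n = 126
            subj = rng.normal(0, 1, size=(n, 1, 1))
            eps = rng.normal(0, 1, size=(n, 2, 3))
            shift = np.zeros((n, 1, 1))
            shift[63:] = 0.5 * np.sqrt(2)  # 0.5 of the cell SD sqrt(1+1)
            y = subj + eps + shift
            table = make_long(y, ["CTL"] * 63 + ["DYS"] * 63)
            res = {
                r.effect: r
                for r in gi.mixed_anova(
                    table, "dprime", "participant_id", "group",
                    ["task", "vot_center"],
                )
            }
            sig += res["group"].p_uncorrected < 0.05
        assert sig / runs > 0.8


def ols_rss(x_cols, y):
    x = np.column_stack(x_cols)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


class TestAncova:
    def toy_table(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1][:n])
        loc = rng.normal(0, 20, n)
        amp = 1.0 + 0.8 * g + 0.01 * loc + rng.normal(0, 0.3, n)
        return pd.DataFrame(
            {"group": np.where(g == 0, "CTL", "DYS"), "peak_amplitude": amp,
             "peak_location": loc}
        )

    def test_matches_normal_equations_oracle(self):
        df = self.toy_table()
        res = {r.effect: r for r in gi.ancova_peak(df)}
        y = df.peak_amplitude.to_numpy()
        one = np.ones(len(df))
        g = (df.group == "DYS").to_numpy(float)
        loc = df.peak_location.to_numpy()
        rss_full = ols_rss([one, g, loc, g * loc], y)
        df_resid = len(df) - 4
        # Type II sums of squares by explicit model comparison
        ss_group = ols_rss([one, loc], y) - ols_rss([one, loc, g], y)
        ss_loc = ols_rss([one, g], y) - ols_rss([one, g, loc], y)
        ss_int = ols_rss([one, g, loc], y) - rss_full
        for name, ss in (
            ("group", ss_group),
            ("peak_location", ss_loc),
            ("group x peak_location", ss_int),
        ):
            f = (ss / 1) / (rss_full / df_resid)
            assert res[name].F == pytest.approx(f, abs=1e-8), name
            assert res[name].ss_effect == pytest.approx(ss, abs=1e-8), name
            assert res[name].df_den == df_resid

    def test_orthogonal_covariate_leaves_group_ss_untouched(self):
        # location exactly balanced within groups and unrelated to amplitude
        df = pd.DataFrame(
            {
                "group": ["CTL"] * 4 + ["DYS"] * 4,
                "peak_amplitude": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 5.0, 5.0],
                "peak_location": [-1, 1, -1, 1, -1, 1, -1, 1],
            }
        )
        res = {r.effect: r for r in gi.ancova_peak(df)}
        amp = df.peak_amplitude.to_numpy()
        means = df.groupby("group").peak_amplitude.transform("mean").to_numpy()
        ss_between = float(np.sum((means - amp.mean()) ** 2))
        assert res["group"].ss_effect == pytest.approx(ss_between, abs=1e-8)
        assert res["peak_location"].ss_effect == pytest.approx(0.0, abs=1e-10)

    def test_identical_amplitudes_give_zero_f(self):
        # both groups carry the very same (amplitude, location) rows
        df = pd.DataFrame(
            {
                "group": ["CTL"] * 4 + ["DYS"] * 4,
                "peak_amplitude": [1.0, 2.0, 3.0, 4.5] * 2,
                "peak_location": [-10.0, -3.0, 4.0, 12.0] * 2,
            }
        )
        res = {r.effect: r for r in gi.ancova_peak(df)}
        assert res["group"].F == pytest.approx(0.0, abs=1e-8)

    def test_zero_variance_covariate_rejected(self):
        df = self.toy_table()
        df["peak_location"] = 0.0
        with pytest.raises(ValueError, match="zero variance"):
            gi.ancova_peak(df)


class TestPartialCorrelation:
    def test_closed_form_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        z = rng.normal(size=10)
        y = 0.5 * x + 0.3 * z + rng.normal(size=10)
        res = gi.partial_correlation(x, y, z)
        rxy = stats.pearsonr(x, y).statistic
        rxz = stats.pearsonr(x, z).statistic
        ryz = stats.pearsonr(y, z).statistic
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert res.r == pytest.approx(closed, abs=1e-10)
        assert res.df == 7

    def test_agrees_with_pingouin(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"x": rng.normal(size=30), "z": rng.normal(size=30)}
        )
        df["y"] = 0.4 * df.x + 0.2 * df.z + rng.normal(size=30)
        res = gi.partial_correlation(df.x, df.y, df.z)
        ref = pg.partial_corr(data=df, x="x", y="y", covar="z")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_unrelated_covariate_reduces_to_pearson(self):
        # covariate built exactly orthogonal to x, y and the intercept
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = 0.6 * x + rng.normal(size=12)
        basis = np.column_stack([np.ones(12), x, y])
        raw = rng.normal(size=12)
        z = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        res = gi.partial_correlation(x, y, z)
        assert res.r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-10)

    def test_perfect_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        z = np.array([0.1, 0.5, 0.2, 0.8, 0.3])
        res = gi.partial_correlation(x, x.copy(), z)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_zero_residual_variance_rejected(self):
        z = np.array([1.0, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="residual"):
            gi.partial_correlation(2 * z + 1, np.array([1.0, 3, 2, 5, 4]), z)
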