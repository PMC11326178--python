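"""Kaplan-Meier, Cox PH, quartile models and association panels."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spliceburden.survival_assoc import (
    compare_psi_groups,
    correlate_panel,
    cox_fit,
    km_logrank,
    quartile_model,
    quartile_strata,
)


def _ph_data(n=300, hr=2.0, censor=0.3, seed=0, baseline=1 / 365):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    t_event = rng.exponential(1.0 / (baseline * np.exp(np.log(hr) * x)))
    t_cens = rng.exponential((1 - censor) / (baseline * censor), size=n) \
        if censor > 0 else np.full(n, np.inf)
    return pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "x": x,
    })


class TestKaplanMeier:
    def test_equals_empirical_survival_without_censoring(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        df = pd.DataFrame({"time": times + [2.0], "event": 1,
                           "group": ["a"] * 6 + ["b"]})
        res = km_logrank(df, "time", "event", "group")
        sf = res.curves["a"]
        for t in sorted(set(times)):
            empirical = np.mean(np.array(times) > t)
            assert sf.loc[t].iloc[0] == pytest.approx(empirical)

    def test_identical_groups_statistic_zero(self):
        df = pd.DataFrame({
            "time": [1, 2, 3, 4] * 2, "event": [1, 1, 0, 1] * 2,
            "group": ["a"] * 4 + ["b"] * 4,
        })
        res = km_logrank(df, "time", "event", "group")
        assert res.logrank_p == pytest.approx(1.0, abs=1e-6)

    def test_all_censored_flagged(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": 0,
                           "group": ["a", "a", "b", "b"]})
        res = km_logrank(df, "time", "event", "group")
        assert np.isnan(res.logrank_p)

    def test_rate_ratio_three_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        for rep in range(20):
            n = 200
            df = pd.DataFrame({
                "time": np.concatenate([
                    rng.exponential(1.0, n), rng.exponential(1 / 3, n),
                ]),
                "event": 1,
                "group": ["lo"] * n + ["hi"] * n,
            })
            if km_logrank(df, "time", "event", "group").logrank_p < 0.01:
                detected += 1
        assert detected >= 19


class TestCoxFit:
    def test_planted_hazard_ratio_recovered(self):
        table = cox_fit(_ph_data(n=600, hr=2.0, seed=3), "time", "event", ["x"])
        row = table[table["term"] == "x"].iloc[0]
        assert 1.7 <= row["hazard_ratio"] <= 2.35
        assert row["ci_low"] <= 2.0 <= row["ci_high"]

    def test_null_covariate_ci_contains_one(self):
        cover = 0
        for rep in range(20):
            table = cox_fit(_ph_data(n=200, hr=1.0, seed=100 + rep),
                            "time", "event", ["x"])
            row = table[table["term"] == "x"].iloc[0]
            cover += int(row["ci_low"] <= 1.0 <= row["ci_high"])
        assert cover >= 17

    def test_invariant_to_time_rescaling_and_duplication(self):
        df = _ph_data(n=200, hr=2.0, seed=5)
        hr0 = cox_fit(df, "time", "event", ["x"]).iloc[0]["hazard_ratio"]
        months = df.assign(time=df["time"] / 30.44)
        hr1 = cox_fit(months, "time", "event", ["x"]).iloc[0]["hazard_ratio"]
        doubled = pd.concat([df, df], ignore_index=True)
        hr2 = cox_fit(doubled, "time", "event", ["x"]).iloc[0]["hazard_ratio"]
        assert hr1 == pytest.approx(hr0, rel=1e-6)
        # duplication introduces ties, so under Efron tie handling the
        # estimate is only approximately invariant
        assert hr2 == pytest.approx(hr0, rel=2e-2)

    def test_factor_reference_rows_emitted(self):
        df = _ph_data(n=200, hr=2.0, seed=6)
        df["grade"] = np.where(df["x"] == 1, "high", "low")
        table = cox_fit(df, "time", "event", ["grade"], factors={"grade": "low"})
        assert (table.loc[table["is_reference"], "term"] == "grade[low]").any()
        assert "grade[high]" in set(table["term"])

    def test_interaction_terms_present(self):
        rng = np.random.default_rng(7)
        df = _ph_data(n=300, hr=1.5, seed=7)
        df["score"] = rng.normal(size=len(df))
        table = cox_fit(df, "time", "event", ["x", "score"],
                        interactions=[("x", "score")])
        assert "x:score" in set(table["term"])

    def test_constant_covariate_rejected(self):
        df = _ph_data(n=50, seed=8)
        df["c"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "time", "event", ["c"])


class TestQuartileModel:
    def test_boundary_ties_assigned_to_lower_stratum(self):
        x = pd.Series([1, 1, 2, 2, 3, 3, 4, 4], dtype=float)
        strata = quartile_strata(x)
        q1 = np.percentile(x, 25)
        assert (strata[x <= q1] == "Q1").all()

    def test_protective_score_gives_hr_below_one(self):
        rng = np.random.default_rng(9)
        n = 400
        score = rng.uniform(0, 1, n)
        t_event = rng.exponential(1.0 / (0.01 * np.exp(-1.5 * score)))
        df = pd.DataFrame({"time": t_event, "event": 1, "score": score})
        table = quartile_model(df, "time", "event", "score")
        q4 = table[table["term"] == "score_quartile[Q4]"].iloc[0]
        assert q4["hazard_ratio"] < 1

    def test_independent_score_ci_contains_one(self):
        cover = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            n = 200
            df = pd.DataFrame({
                "time": rng.exponential(100, n), "event": 1,
                "score": rng.uniform(0, 1, n),
            })
            q4 = quartile_model(df, "time", "event", "score")
            row = q4[q4["term"] == "score_quartile[Q4]"].iloc[0]
            cover += int(row["ci_low"] <= 1.0 <= row["ci_high"])
        assert cover >= 17

    def test_collapsed_quartiles_rejected(self):
        df = pd.DataFrame({"time": np.arange(1, 21, dtype=float), "event": 1,
                           "score": 1.0})
        with pytest.raises(ValueError, match="quartile"):
            quartile_model(df, "time", "event", "score")


class TestCorrelatePanel:
    def test_duplicated_target_has_perfect_correlation(self):
        rng = np.random.default_rng(11)
        y = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        panel = pd.DataFrame(
            [y.to_numpy(), rng.normal(size=30)], index=["dup", "noise"],
            columns=y.index,
        )
        out = correlate_panel(panel, y)
        assert out.loc["dup", "r"] == pytest.approx(1.0)
        assert out.loc["dup", "fdr"] == out["fdr"].min()

    def test_hand_computed_pearson(self):
        y = pd.Series([2.0, 1.0, 4.0, 6.0], index=list("abcd"))
        panel = pd.DataFrame([[1.0, 2.0, 3.0, 5.0]], index=["g"],
                             columns=list("abcd"))
        out = correlate_panel(panel, y)
        expected, _ = stats.pearsonr([1, 2, 3, 5], [2, 1, 4, 6])
        assert out.loc["g", "r"] == pytest.approx(expected)

    def test_bh_stepup_matches_bruteforce(self):
        """BH on p = (.01, .02, .03, .04), m = 4 gives all 0.04."""
        rng = np.random.default_rng(12)
        y = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        panel = pd.DataFrame(rng.normal(size=(4, 50)),
                             index=list("wxyz"), columns=y.index)
        out = correlate_panel(panel, y)
        # oracle on the raw p-values via the step-up definition
        p = out["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        stepped = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(out["fdr"], expected, atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        fixed = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(fixed, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_zero_variance_gene_excluded(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        panel = pd.DataFrame([[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
                             index=["flat", "ok"], columns=list("abcd"))
        out = correlate_panel(panel, y)
        assert np.isnan(out.loc["flat", "r"])
        assert np.isnan(out.loc["flat", "fdr"])
        assert out.loc["ok", "fdr"] == pytest.approx(out.loc["ok", "p"])


class TestComparePsiGroups:
    def _series(self, arrays, names):
        vals, grp = [], []
        for arr, name in zip(arrays, names):
            vals.extend(arr)
            grp.extend([name] * len(arr))
        idx = [f"s{i}" for i in range(len(vals))]
        return pd.Series(vals, index=idx), pd.Series(grp, index=idx)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(20):
            a = rng.normal(0.5, 0.1, 30)
            b = rng.normal(0.3, 0.1, 30)
            psi, grp = self._series([a, b], ["young", "old"])
            table, _ = compare_psi_groups(psi, grp, ["young", "old"])
            hits += int(table["p"].iloc[0] < 0.05)
        assert hits >= 18

    def test_monotone_trend_summary(self):
        rng = np.random.default_rng(14)
        arrays = [rng.normal(0.8 - 0.2 * i, 0.05, 20) for i in range(3)]
        psi, grp = self._series(arrays, ["fetal", "child", "adult"])
        _, trend = compare_psi_groups(psi, grp, ["fetal", "child", "adult"])
        assert trend["spearman_rho"] < -0.8
        assert trend["trend_p"] < 1e-6

    def test_rank_sum_matches_exhaustive_enumeration(self):
        """3-vs-3 U statistic equals its definition over all pair comparisons."""
        a = np.array([0.1, 0.4, 0.9])
        b = np.array([0.2, 0.3, 0.8])
        u_direct = sum(int(x > y) + 0.5 * int(x == y) for x in a for y in b)
        u_scipy, _ = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert u_scipy == pytest.approx(u_direct)
        # and the exact p equals enumeration over all C(6,3) group splits
        pooled = np.concatenate([a, b])
        stats_all = []
        for idx in combinations(range(6), 3):
            aa = pooled[list(idx)]
            bb = pooled[[i for i in range(6) if i not in idx]]
            stats_all.append(sum(int(x > y) for x in aa for y in bb))
        u_obs = sum(int(x > y) for x in a for y in b)
        centered = np.abs(np.array(stats_all) - 4.5)
        p_exact = float(np.mean(centered >= abs(u_obs - 4.5) - 1e-12))
        _, p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact")
        assert p_scipy == pytest.approx(p_exact)

    def test_identical_constant_groups_p_one(self):
        psi, grp = self._series([[0.5] * 4, [0.5] * 4], ["a", "b"])
        table, _ = compare_psi_groups(psi, grp, ["a", "b"])
        assert table["p"].iloc[0] == pytest.approx(1.0)
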