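"""ANOVA routines against explicit sums-of-squares / model-comparison
oracles, effect-size coding, correlation, plausibility."""

import numpy as np
import pandas as pd
import pytest

from marathon_response.stats import (
    DegenerateInputError,
    effect_stars,
    one_way_anova,
    pearson,
    plausibility_report,
    rm_anova,
    two_way_anova,
    weekend_share,
)


def oneway_ss_oracle(values, groups):
    """Explicit between/within sums-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grand = values.mean()
    ss_b = ss_w = 0.0
    for g in np.unique(groups):
        y = values[groups == g]
        ss_b += len(y) * (y.mean() - grand) ** 2
        ss_w += ((y - y.mean()) ** 2).sum()
    return ss_b, ss_w


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def twoway_type2_oracle(df, dv, a, b):
    """Type II sums of squares by nested least-squares model comparison."""
    y = df[dv].to_numpy(dtype=float)
    one = np.ones((len(df), 1))
    A = pd.get_dummies(df[a], drop_first=True).to_numpy(dtype=float)
    B = pd.get_dummies(df[b], drop_first=True).to_numpy(dtype=float)
    AB = np.column_stack([
        A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])
    ])
    rss_b = _rss(np.hstack([one, B]), y)
    rss_a = _rss(np.hstack([one, A]), y)
    rss_ab = _rss(np.hstack([one, A, B]), y)
    rss_full = _rss(np.hstack([one, A, B, AB]), y)
    return {
        a: rss_b - rss_ab,
        b: rss_a - rss_ab,
        "interaction": rss_ab - rss_full,
        "error": rss_full,
    }


def rm_ss_oracle(wide):
    """Two-way (subject x condition) decomposition for a complete design."""
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    return ss_cond, ss_err


class TestOneWay:
    def test_matches_hand_computed_sums_of_squares(self):
        values = [1, 2, 3, 2, 3, 4, 3, 4, 5]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = one_way_anova(values, groups)
        ss_b, ss_w = oneway_ss_oracle(values, groups)
        assert res.ss_effect == pytest.approx(ss_b, abs=1e-9)
        assert res.ss_error == pytest.approx(ss_w, abs=1e-9)
        assert res.f == pytest.approx((ss_b / 2) / (ss_w / 6), abs=1e-9)
        assert res.partial_eta2 == pytest.approx(ss_b / (ss_b + ss_w), abs=1e-9)

    def test_random_instance_matches_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=24)
        groups = rng.choice(["a", "b", "c", "d"], size=24)
        res = one_way_anova(values, groups)
        ss_b, ss_w = oneway_ss_oracle(values, groups)
        assert res.ss_effect == pytest.approx(ss_b, rel=1e-9)
        assert res.ss_error == pytest.approx(ss_w, rel=1e-9)

    def test_identical_group_means_give_zero_f(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.partial_eta2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_variance_gives_eta_one(self):
        res = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res.partial_eta2 == pytest.approx(1.0)

    def test_zero_total_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([2.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestTwoWay:
    def _balanced(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a, ea in (("l", 0.0), ("m", 1.0), ("h", 2.0)):
            for b, eb in (("s", 0.0), ("f", 3.0)):
                for _ in range(3):
                    rows.append({"y": ea + eb + noise * rng.normal(), "a": a, "b": b})
        return pd.DataFrame(rows)

    def test_additive_means_give_zero_interaction(self):
        res = two_way_anova(self._balanced(), "y", "a", "b")
        assert res["interaction"].ss_effect == pytest.approx(0.0, abs=1e-9)

    def test_balanced_design_type2_equals_type1(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = self._balanced(noise=1.0, seed=5)
        res = two_way_anova(df, "y", "a", "b")
        t1 = anova_lm(smf.ols("y ~ C(a) * C(b)", data=df).fit(), typ=1)
        assert res["a"].ss_effect == pytest.approx(t1.loc["C(a)", "sum_sq"], abs=1e-8)
        assert res["b"].ss_effect == pytest.approx(t1.loc["C(b)", "sum_sq"], abs=1e-8)

    def test_unbalanced_matches_model_comparison_oracle(self):
        rng = np.random.default_rng(9)
        n = 28
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "a": rng.choice(["l", "m", "h"], size=n),
            "b": rng.choice(["s", "me", "f"], size=n),
        })
        # ensure no empty cell
        df = pd.concat([df, pd.DataFrame(
            [{"y": 0.0, "a": a, "b": b} for a in ("l", "m", "h") for b in ("s", "me", "f")]
        )], ignore_index=True)
        res = two_way_anova(df, "y", "a", "b")
        oracle = twoway_type2_oracle(df, "y", "a", "b")
        for key in ("a", "b", "interaction"):
            assert res[key].ss_effect == pytest.approx(oracle[key], abs=1e-8)
        assert res["a"].ss_error == pytest.approx(oracle["error"], abs=1e-8)
        for key in ("a", "b", "interaction"):
            want = oracle[key] / (oracle[key] + oracle["error"])
            assert res[key].partial_eta2 == pytest.approx(want, abs=1e-8)

    def test_empty_cell_raises_with_cell_name(self):
        df = self._balanced()
        df = df[~((df["a"] == "l") & (df["b"] == "f"))]
        with pytest.raises(DegenerateInputError, match="l"):
            two_way_anova(df, "y", "a", "b")


class TestRepeatedMeasures:
    def _long(self, wide):
        df = wide.reset_index().melt(id_vars="subject", var_name="block", value_name="y")
        return df

    def test_toy_table_matches_ss_oracle(self):
        wide = pd.DataFrame(
            {1: [0.5, 0.6, 0.4], 2: [0.45, 0.62, 0.41], 3: [0.40, 0.55, 0.35], 4: [0.35, 0.5, 0.3]},
        )
        wide.index.name = "subject"
        res = rm_anova(self._long(wide), "y", "block", "subject")
        ss_cond, ss_err = rm_ss_oracle(wide)
        assert res.ss_effect == pytest.approx(ss_cond, abs=1e-9)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-9)
        assert res.partial_eta2 == pytest.approx(ss_cond / (ss_cond + ss_err), abs=1e-9)

    def test_constant_profiles_give_zero_effect(self):
        wide = pd.DataFrame({1: [0.2, 0.5, 0.9], 2: [0.2, 0.5, 0.9],
                             3: [0.2, 0.5, 0.9], 4: [0.2, 0.5, 0.9]})
        wide.index.name = "subject"
        res = rm_anova(self._long(wide), "y", "block", "subject")
        assert res.ss_effect == pytest.approx(0.0, abs=1e-12)
        assert res.partial_eta2 == pytest.approx(0.0, abs=1e-12)

    def test_subject_offsets_leave_f_unchanged(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame(rng.normal(size=(6, 4)), columns=[1, 2, 3, 4])
        base.index.name = "subject"
        shifted = base.add(rng.normal(size=6) * 10, axis=0)
        shifted.index.name = "subject"
        r1 = rm_anova(self._long(base), "y", "block", "subject")
        r2 = rm_anova(self._long(shifted), "y", "block", "subject")
        assert r1.f == pytest.approx(r2.f, rel=1e-9)
        assert r1.partial_eta2 == pytest.approx(r2.partial_eta2, rel=1e-9)

    def test_incomplete_design_raises(self):
        df = pd.DataFrame({
            "subject": [0, 0, 0, 0, 1, 1, 1],
            "block": [1, 2, 3, 4, 1, 2, 3],
            "y": np.arange(7.0),
        })
        with pytest.raises(DegenerateInputError):
            rm_anova(df, "y", "block", "subject")

    def test_gg_corrected_p_reported(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(8, 4)), columns=[1, 2, 3, 4])
        wide.index.name = "subject"
        res = rm_anova(self._long(wide), "y", "block", "subject")
        assert res.p_gg is not None and 0.0 <= res.p_gg <= 1.0


class TestEffectStars:
    @pytest.mark.parametrize(
        "eta2, p, stars",
        [
            (0.136, 0.01, "***"),
            (0.12, 0.01, "***"),
            (0.05, 0.01, "**"),
            (0.119, 0.01, "**"),
            (0.01, 0.01, "*"),
            (0.049, 0.01, "*"),
            (0.005, 0.01, ""),
            (0.30, 0.20, ""),  # significance gate
            (0.30, 0.05, ""),  # alpha is strict
        ],
    )
    def test_band_coding(self, eta2, p, stars):
        assert effect_stars(eta2, p) == stars


class TestPearson:
    def test_exact_line(self):
        x = np.arange(10.0)
        r, slope, intercept = pearson(x, 2 * x + 1)
        assert (r, slope, intercept) == pytest.approx((1.0, 2.0, 1.0))

    def test_anticorrelation(self):
        x = np.arange(5.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = rng.normal(size=10) + 0.5 * x
        r, slope, intercept = pearson(x, y)
        want_r = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        want_slope = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
        assert r == pytest.approx(want_r, abs=1e-12)
        assert slope == pytest.approx(want_slope, abs=1e-12)
        assert intercept == pytest.approx(y.mean() - want_slope * x.mean(), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPlausibility:
    def test_weekend_classification(self):
        sunday = 1538902800  # 2018-10-07 09:00 UTC
        tuesday = sunday + 2 * 86_400
        saturday = sunday - 86_400
        assert weekend_share(np.array([sunday])) == 1.0
        assert weekend_share(np.array([tuesday])) == 0.0
        assert weekend_share(np.array([saturday, tuesday])) == 0.5

    def test_histograms_conserve_counts(self):
        rng = np.random.default_rng(0)
        n = 40
        rep = plausibility_report(
            t_mp=rng.uniform(11_000, 19_000, n),
            hr_max=rng.uniform(170, 205, n),
            delta_v10=rng.normal(0.1, 0.2, n),
            v10_overall=rng.uniform(3, 4, n),
            v_mp=rng.uniform(2.5, 3.5, n),
            marathon_starts=np.full(n, 1538902800),
        )
        assert rep.t_mp_hist[0].sum() == n
        assert rep.hr_max_hist[0].sum() == n
        assert len(rep.delta_v10_sorted) == n
        assert np.all(np.diff(rep.delta_v10_sorted) >= 0)
        assert rep.weekend_share == 1.0
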