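"""The Type-III ANOVA engine: closed forms, identities, reference agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import amputebias as ab
from amputebias.anova import ModelSpec, fit_anova, select_model, simple_effects
from amputebias.errors import InestimableTermError, ParameterError

from helpers import FULL_2x2x2_TERMS, random_unbalanced_table, statsmodels_type3


def _balanced_2x2(cell_means, reps=3, noise=0.0, rng=None):
    rows = {"subject_id": [], "a": [], "b": [], "y": []}
    i = 0
    for (la, lb), mu in cell_means.items():
        for _ in range(reps):
            rows["subject_id"].append(i)
            rows["a"].append(la)
            rows["b"].append(lb)
            eps = 0.0 if rng is None else noise * rng.standard_normal()
            rows["y"].append(mu + eps)
            i += 1
    return ab.make_table(rows, factors={"a": ["a1", "a2"], "b": ["b1", "b2"]})


class TestClosedForms:
    def test_balanced_2x2_zero_noise(self):
        """Cell means (0,0,0,delta): hand-derived balanced ANOVA gives main-effect
        marginal MDs of delta/2 and an infinite (guarded) interaction F."""
        delta = 2.0
        t = _balanced_2x2(
            {("a1", "b1"): 0, ("a1", "b2"): 0, ("a2", "b1"): 0, ("a2", "b2"): delta}
        )
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",), ("a", "b")))
        tab = fit_anova(t, spec)
        assert tab.ms_error == 0.0
        assert np.isinf(tab["a:b"].f_value)
        assert tab["a:b"].partial_eta_sq == 1.0
        assert tab["a"].mean_difference == pytest.approx(delta / 2)
        assert tab["b"].mean_difference == pytest.approx(delta / 2)

    def test_df_error_is_n_minus_rank(self, rng):
        t = random_unbalanced_table(rng)
        spec = ModelSpec("y", ("a", "b", "c"), FULL_2x2x2_TERMS)
        tab = fit_anova(t, spec)
        assert tab.df_error == tab.n_used - 8

    def test_eta_squared_identity_on_fits(self, rng):
        """partial eta^2 == F*df1/(F*df1+df2) on every fitted row, and equals the
        SS decomposition SS/(SS+SSE)."""
        for _ in range(5):
            t = random_unbalanced_table(rng)
            tab = fit_anova(t, ModelSpec("y", ("a", "b", "c"), FULL_2x2x2_TERMS))
            sse = tab.ms_error * tab.df_error
            for row in tab.rows:
                lhs = row.partial_eta_sq
                assert lhs == pytest.approx(
                    row.f_value * row.df_effect / (row.f_value * row.df_effect + row.df_error),
                    abs=1e-12,
                )
                assert lhs == pytest.approx(row.ss_effect / (row.ss_effect + sse), abs=1e-10)

    def test_type3_equals_sequential_when_balanced(self, rng):
        """On a balanced design the Type-III and sequential decompositions agree."""
        t = _balanced_2x2(
            {("a1", "b1"): 1, ("a1", "b2"): 2, ("a2", "b1"): 3, ("a2", "b2"): 7},
            reps=4,
            noise=1.0,
            rng=rng,
        )
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",), ("a", "b")))
        tab = fit_anova(t, spec)
        ref = statsmodels_type3(t, spec)  # typ=3 == typ=1 on balanced data
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        seq = anova_lm(
            smf.ols("y ~ C(a, Sum)*C(b, Sum)", data=t.data).fit(), typ=1
        )
        for row, seq_name in zip(tab.rows, seq.index[:-1]):
            assert row.ss_effect == pytest.approx(seq.loc[seq_name, "sum_sq"], abs=1e-10)

    def test_empty_cell_is_inestimable(self):
        t = _balanced_2x2({("a1", "b1"): 0, ("a1", "b2"): 0, ("a2", "b1"): 0, ("a2", "b2"): 1})
        t.data = t.data[~((t.data.a == "a2") & (t.data.b == "b2"))].copy()
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",), ("a", "b")))
        with pytest.raises(InestimableTermError) as err:
            fit_anova(t, spec)
        assert "a2" in str(err.value) and "b2" in str(err.value)

    def test_nonhierarchical_terms_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec("y", ("a", "b"), (("a", "b"),))


class TestOracleAgreement:
    def test_matches_reference_on_unbalanced_fixtures(self, rng):
        """Full agreement (MSe, SS, F, p) with the reference Type-III fit on 50
        random unbalanced factorial datasets."""
        spec = ModelSpec("y", ("a", "b", "c"), FULL_2x2x2_TERMS)
        for _ in range(50):
            t = random_unbalanced_table(rng)
            mine = fit_anova(t, spec)
            ref = statsmodels_type3(t, spec)
            assert mine.ms_error == pytest.approx(
                ref.loc["Residual", "sum_sq"] / ref.loc["Residual", "df"], abs=1e-8
            )
            for row in mine.rows:
                assert row.ss_effect == pytest.approx(ref.loc[row.term, "sum_sq"], abs=1e-8)
                assert row.f_value == pytest.approx(ref.loc[row.term, "F"], abs=1e-8)
                assert row.p_value == pytest.approx(ref.loc[row.term, "PR(>F)"], abs=1e-8)


class TestEffectSizeAndPower:
    def test_partial_eta_squared_basics(self):
        assert ab.partial_eta_squared(0.0, 1, 100) == 0.0
        with pytest.raises(ParameterError):
            ab.partial_eta_squared(-1.0, 1, 100)

    @given(
        f1=st.floats(0.0, 50.0),
        bump=st.floats(0.1, 50.0),
        df2=st.integers(5, 500),
    )
    def test_power_monotone_in_f(self, f1, bump, df2):
        p_lo = ab.observed_power(f1, 1, df2)
        p_hi = ab.observed_power(f1 + bump, 1, df2)
        assert p_hi >= p_lo - 1e-12
        assert ab.observed_power(0.0, 1, df2) == pytest.approx(0.05)

    def test_power_monotone_in_df_error(self):
        powers = [ab.observed_power(5.0, 1, d) for d in (10, 50, 200, 900)]
        assert powers == sorted(powers)
        assert all(0.05 <= p <= 1.0 for p in powers)


class TestChangeScores:
    def test_arithmetic_and_missingness(self, school_cohort):
        t = school_cohort.copy()
        t.data.loc[0, "post"] = np.nan
        ch = ab.change_scores(t, "post", "pre")
        assert np.isnan(ch.iloc[0])
        assert ch.iloc[1] == pytest.approx(t.data.post.iloc[1] - t.data.pre.iloc[1])
        same = ab.change_scores(school_cohort, "pre", "pre")
        assert (same == 0).all()

    def test_listwise_bookkeeping(self, school_cohort):
        mask = ab.ampute(school_cohort, ab.MechanismSpec("MCAR", 0.2), seed=0)
        avail = ab.apply_mask(school_cohort, mask)
        assert avail.listwise(["post"]).n_subjects == 915 - len(mask)


class TestSimpleEffects:
    def test_pooled_df_and_saturated_formula(self, rng):
        """In a saturated two-factor model the simple effect of a at b=w must
        equal the hand formula MD^2 / (MSe*(1/n1+1/n2)) with the pooled MSe."""
        t = random_unbalanced_table(rng)
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",), ("a", "b")))
        full = fit_anova(t, spec)
        simp = simple_effects(t, spec, "a", "b")
        for w in ("b1", "b2"):
            row = simp[f"a | b={w}"]
            assert row.df_error == full.df_error  # pooled error df
            sub = t.data[t.data.b == w]
            n1 = (sub.a == "a1").sum()
            n2 = (sub.a == "a2").sum()
            md = sub[sub.a == "a2"].y.mean() - sub[sub.a == "a1"].y.mean()
            f_hand = md**2 / (full.ms_error * (1 / n1 + 1 / n2))
            assert row.f_value == pytest.approx(f_hand, abs=1e-10)
            assert row.mean_difference == pytest.approx(abs(md), abs=1e-10)

    def test_collapses_to_main_effect_without_interaction(self, rng):
        """With a pure main-effect population the simple effects approximate the
        main effect in each slice."""
        n = 4000
        a = rng.choice(["a1", "a2"], n)
        b = rng.choice(["b1", "b2"], n)
        y = 1.0 * (a == "a2") + 0.05 * rng.standard_normal(n)
        t = ab.make_table(
            {"subject_id": np.arange(n), "a": a, "b": b, "y": y},
            factors={"a": ["a1", "a2"], "b": ["b1", "b2"]},
        )
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",), ("a", "b")))
        main_md = fit_anova(t, spec)["a"].mean_difference
        simp = simple_effects(t, spec, "a", "b")
        for w in ("b1", "b2"):
            assert simp[f"a | b={w}"].mean_difference == pytest.approx(main_md, abs=0.02)

    def test_requires_interaction_in_model(self, rng):
        t = random_unbalanced_table(rng)
        spec = ModelSpec("y", ("a", "b"), (("a",), ("b",)))
        with pytest.raises(ParameterError):
            simple_effects(t, spec, "a", "b")


class TestSelectModel:
    def _candidates(self):
        f = ("a", "b", "c")
        return [
            ModelSpec("y", f, ()),
            ModelSpec("y", f, (("a",),)),
            ModelSpec("y", f, (("a",), ("b",))),
            ModelSpec("y", f, (("a",), ("b",), ("c",))),
            ModelSpec("y", f, (("a",), ("c",), ("a", "c"))),
            ModelSpec("y", f, (("a",), ("b",), ("c",), ("a", "c"))),
        ]

    def test_strong_interaction_selected(self, rng):
        hits = 0
        for r in range(50):
            n = 240
            a = rng.choice(["a1", "a2"], n)
            b = rng.choice(["b1", "b2"], n)
            c = rng.choice(["c1", "c2"], n)
            y = (
                1.0 * (a == "a2")
                + 1.0 * (a == "a2") * (c == "c2")
                + rng.standard_normal(n)
            )
            t = ab.make_table(
                {"subject_id": np.arange(n), "a": a, "b": b, "c": c, "y": y},
                factors={"a": ["a1", "a2"], "b": ["b1", "b2"], "c": ["c1", "c2"]},
            )
            chosen = select_model(t, self._candidates())
            if ("a", "c") in chosen.terms:
                hits += 1
        assert hits >= 45  # > 90 percent at this effect size

    def test_null_data_selects_empty_model_at_alpha_rate(self, rng):
        """With no true effects the empty candidate wins at roughly the
        (1-alpha)^4 rate implied by four independent tests."""
        empty = 0
        reps = 200
        for r in range(reps):
            n = 80
            t = ab.make_table(
                {
                    "subject_id": np.arange(n),
                    "a": rng.choice(["a1", "a2"], n),
                    "b": rng.choice(["b1", "b2"], n),
                    "c": rng.choice(["c1", "c2"], n),
                    "y": rng.standard_normal(n),
                },
                factors={"a": ["a1", "a2"], "b": ["b1", "b2"], "c": ["c1", "c2"]},
            )
            if select_model(t, self._candidates()).terms == ():
                empty += 1
        expected = 0.95**4  # four tested terms in the encompassing model
        assert empty / reps == pytest.approx(expected, abs=0.08)
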