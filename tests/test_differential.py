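import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_design, make_matrix
from stoichiovar.differential import (
    bh_adjust,
    call_variable,
    ebayes_moderate,
    estimate_variance_prior,
    fisher_overlap,
    fit_condition_contrasts,
)
from stoichiovar.resource import ComplexDefinition, ComplexResource


def bh_oracle(p):
    """Literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestFitConditionContrasts:
    def test_all_equal_values_zero_effects(self):
        design = make_design(["A", "B", "C"], 2)
        m = make_matrix(np.full((3, 6), 2.0), ["P1", "P2", "P3"], design)
        fit = fit_condition_contrasts(m)
        np.testing.assert_allclose(fit.table["effect"], 0.0)

    def test_contrast_is_mean_minus_mean_of_other_means(self):
        design = make_design(["A", "B", "C"], 2)
        # condition means 4, 1, 1 -> contrast for A = 4 - 1 = 3
        values = np.array([[4.0, 4.0, 1.0, 1.0, 1.0, 1.0]])
        m = make_matrix(values, ["P1"], design)
        fit = fit_condition_contrasts(m)
        t = fit.table.set_index("condition")
        assert t.loc["A", "effect"] == pytest.approx(3.0)
        assert t.loc["B", "effect"] == pytest.approx(-1.5)

    def test_single_replicate_condition_uses_pooled_variance(self):
        design = make_design(["A", "B"], 2)
        extra = pd.DataFrame({"condition": ["C"], "replicate": [1]}, index=["C_r1"])
        design = pd.concat([design, extra])
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(5, 5)), [f"P{i}" for i in range(5)], design)
        fit = fit_condition_contrasts(m)
        c_rows = fit.table[fit.table["condition"] == "C"]
        assert len(c_rows) == 5
        assert np.isfinite(c_rows["effect"]).all()
        assert np.isfinite(c_rows["se_unit"]).all()

    def test_matches_ols_contrast(self):
        # oracle: per-protein one-way OLS on condition indicators
        design = make_design(["A", "B", "C", "D"], 3)
        rng = np.random.default_rng(1)
        values = rng.normal(size=(6, 12))
        m = make_matrix(values, [f"P{i}" for i in range(6)], design)
        fit = fit_condition_contrasts(m)
        cond = design["condition"].to_numpy()
        conds = ["A", "B", "C", "D"]
        for i in range(6):
            y = values[i]
            means = np.array([y[cond == c].mean() for c in conds])
            resid = y - np.array([means[conds.index(c)] for c in cond])
            s2 = (resid**2).sum() / (12 - 4)
            assert fit.s2.iloc[i] == pytest.approx(s2)
            row = fit.table[(fit.table["protein"] == f"P{i}") & (fit.table["condition"] == "A")]
            expected = means[0] - means[1:].mean()
            assert row["effect"].iloc[0] == pytest.approx(expected)


class TestEbayesModerate:
    def _fit(self, seed=0, n=40):
        design = make_design(["A", "B", "C"], 3)
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(n, 9)), [f"P{i}" for i in range(n)], design)
        return fit_condition_contrasts(m)

    def test_d0_zero_reproduces_ordinary_t(self):
        fit = self._fit()
        _, table = ebayes_moderate(fit, d0=0.0)
        s = np.sqrt(fit.s2.reindex(table["protein"]).to_numpy())
        df = fit.df.reindex(table["protein"]).to_numpy()
        t_ord = table["effect"].to_numpy() / (table["se_unit"].to_numpy() * s)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), df)
        np.testing.assert_allclose(table["t_mod"], t_ord, atol=1e-12)
        np.testing.assert_allclose(table["p"], p_ord, atol=1e-4)

    def test_infinite_d0_pools_variances(self):
        fit = self._fit(seed=1)
        eb, _ = ebayes_moderate(fit, d0=math.inf, s0_sq=0.7)
        np.testing.assert_allclose(eb.s_tilde_sq.to_numpy(), 0.7)

    def test_posterior_variance_interpolates(self):
        fit = self._fit(seed=2)
        eb, _ = ebayes_moderate(fit, d0=4.0, s0_sq=0.5)
        expected = (4.0 * 0.5 + fit.df * fit.s2) / (4.0 + fit.df)
        np.testing.assert_allclose(eb.s_tilde_sq.to_numpy(), expected.to_numpy())

    def test_hyperparameter_recovery(self):
        # variances drawn from the scaled inverse-chi-square model with known
        # (d0=4, s0_sq=0.05); moment matching must land near the truth
        rng = np.random.default_rng(7)
        d0_true, s0_true, d_g = 4.0, 0.05, 3.0
        n = 5000
        sigma2 = s0_true * d0_true / stats.chi2.rvs(d0_true, size=n, random_state=rng)
        s2 = sigma2 * stats.chi2.rvs(d_g, size=n, random_state=rng) / d_g
        d0_hat, s0_hat = estimate_variance_prior(s2, np.full(n, d_g))
        assert abs(d0_hat - d0_true) / d0_true < 0.2
        assert abs(s0_hat - s0_true) / s0_true < 0.1

    def test_identical_variances_give_infinite_prior_df(self):
        design = make_design(["A", "B"], 3)
        base = np.array([[0.0, 1.0, -1.0, 2.0, 0.5, -0.5]])
        values = np.vstack([base + i for i in range(12)])  # identical residuals
        m = make_matrix(values, [f"P{i}" for i in range(12)], design)
        fit = fit_condition_contrasts(m)
        eb, _ = ebayes_moderate(fit)
        assert math.isinf(eb.d0)


class TestBHAdjust:
    def test_worked_step_up_example(self):
        df = pd.DataFrame(
            {"p": [0.01, 0.02, 0.03, 0.04], "condition": "A"}
        )
        out = bh_adjust(df)
        np.testing.assert_allclose(out["p_adj"], 0.04)

    def test_single_and_tied_pvalues_unchanged(self):
        df = pd.DataFrame({"p": [0.3], "condition": "A"})
        assert bh_adjust(df)["p_adj"].iloc[0] == pytest.approx(0.3)
        df = pd.DataFrame({"p": [0.2, 0.2, 0.2], "condition": "A"})
        np.testing.assert_allclose(bh_adjust(df)["p_adj"], 0.2)

    def test_grouping_is_per_condition(self):
        df = pd.DataFrame(
            {"p": [0.01, 0.5, 0.01, 0.5], "condition": ["A", "A", "B", "B"]}
        )
        out = bh_adjust(df)
        np.testing.assert_allclose(out["p_adj"], [0.02, 0.5, 0.02, 0.5])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.random(size=int(rng.integers(1, 30)))
            df = pd.DataFrame({"p": p, "condition": "A"})
            np.testing.assert_allclose(bh_adjust(df)["p_adj"], bh_oracle(p), atol=1e-12)


class TestCallVariable:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["protein", "condition", "effect", "p", "p_adj"]
        )

    def _resource(self, members):
        return ComplexResource(
            [ComplexDefinition("C1", "C1", "user", frozenset(members))]
        )

    @pytest.mark.parametrize(
        "n_members,n_variable,verdict",
        [(10, 2, "variable"), (9, 1, "stable"), (5, 1, "variable")],
    )
    def test_twenty_percent_rule_with_boundary(self, n_members, n_variable, verdict):
        rows = []
        for i in range(n_members):
            p_adj = 0.01 if i < n_variable else 0.9
            rows.append((f"P{i}", "A", 1.0, p_adj, p_adj))
        calls = call_variable(self._table(rows), self._resource([f"P{i}" for i in range(n_members)]))
        assert calls.complexes["verdict"].iloc[0] == verdict

    def test_member_variable_requires_one_significant_condition(self):
        rows = [("P0", "A", 1.0, 0.5, 0.5), ("P0", "B", 1.0, 0.01, 0.04)]
        calls = call_variable(self._table(rows), self._resource(["P0", "P1"]))
        assert bool(calls.protein_variable["P0"]) is True


class TestFisherOverlap:
    def test_worked_hypergeometric_example(self):
        universe = {f"U{i}" for i in range(8)}
        a = {"U0", "U1", "U2", "U3"}  # |a|=4
        b = {"U0", "U1", "U2", "U4"}  # overlap 3 -> table [[3,1],[1,3]]
        odds, p, jaccard = fisher_overlap(a, b, universe)
        assert odds == pytest.approx(9.0)
        assert p == pytest.approx(34 / 70)
        assert jaccard == pytest.approx(3 / 5)

    def test_disjoint_cover_gives_zero_odds(self):
        universe = set(range(10))
        a, b = set(range(5)), set(range(5, 10))
        odds, _, jaccard = fisher_overlap(a, b, universe)
        assert odds == 0.0
        assert jaccard == 0.0

    def test_identical_sets_minimize_p(self):
        universe = set(range(12))
        a = set(range(5))
        _, p_equal, _ = fisher_overlap(a, a, universe)
        for k in range(len(a)):
            b = set(list(a)[: k]) | set(range(5, 5 + len(a) - k))
            _, p_other, _ = fisher_overlap(a, b, universe)
            assert p_equal <= p_other + 1e-12

    def test_matches_enumeration_oracle_on_small_universes(self):
        # exhaustive two-sided hypergeometric: sum P(table) over tables with
        # probability <= observed, margins fixed
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            universe = set(range(n))
            a = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False))
            b = set(rng.choice(n, size=int(rng.integers(1, n)), replace=False))
            _, p, _ = fisher_overlap(a, b, universe)
            K, n_draws, N = len(a), len(b), n
            obs = len(a & b)
            probs = [
                stats.hypergeom.pmf(k, N, K, n_draws)
                for k in range(max(0, K + n_draws - N), min(K, n_draws) + 1)
            ]
            p_obs = stats.hypergeom.pmf(obs, N, K, n_draws)
            expected = sum(q for q in probs if q <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(expected, abs=1e-9)
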