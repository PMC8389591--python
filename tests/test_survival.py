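"""Eigengene, Kaplan-Meier, log-rank: hand-worked examples and
brute-force oracle agreement."""

import numpy as np
import pandas as pd
import pytest

from naive_oracles import naive_km, naive_logrank
from survmod.modules import Module
from survmod.survival import (
    evaluate_modules,
    km_estimate,
    logrank_test,
    median_split,
    module_eigengene,
)


def _expr(X, genes=None, samples=None):
    n, m = np.asarray(X).shape
    return pd.DataFrame(
        X,
        index=genes or [f"g{i}" for i in range(n)],
        columns=samples or [f"s{i}" for i in range(m)],
    )


class TestModuleEigengene:
    def test_rank_one_matrix(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        X = np.vstack([2 * profile + 1, -3 * profile, 0.5 * profile - 2])
        me = module_eigengene(_expr(X), ["g0", "g1", "g2"])
        assert me.variance_explained == pytest.approx(1.0, abs=1e-12)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        cos = abs(me.sample_scores.to_numpy() @ z) / np.linalg.norm(z)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_profiles_split_variance(self):
        a = np.array([1.0, 1.0, -1.0, -1.0])
        b = np.array([1.0, -1.0, 1.0, -1.0])
        me = module_eigengene(_expr(np.vstack([a, b])), ["g0", "g1"])
        assert me.variance_explained == pytest.approx(0.5, abs=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        """ME equals the top eigenvector of the sample covariance of the
        standardised matrix (independent eigh route)."""
        for _ in range(100):
            X = rng.standard_normal((10, 50))
            me = module_eigengene(_expr(X), [f"g{i}" for i in range(10)])
            Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
            evals, evecs = np.linalg.eigh(Z.T @ Z)
            top = evecs[:, -1]
            cos = abs(me.sample_scores.to_numpy() @ top)
            assert cos > 1 - 1e-10
            assert me.variance_explained == pytest.approx(
                evals[-1] / evals.sum(), abs=1e-10
            )

    def test_scores_zero_mean_unit_norm(self, rng):
        X = rng.standard_normal((6, 30))
        me = module_eigengene(_expr(X), [f"g{i}" for i in range(6)])
        assert me.sample_scores.mean() == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.norm(me.sample_scores) == pytest.approx(1.0, abs=1e-10)

    def test_gene_order_invariance(self, rng):
        X = rng.standard_normal((8, 25))
        genes = [f"g{i}" for i in range(8)]
        df = _expr(X, genes)
        me1 = module_eigengene(df, genes)
        me2 = module_eigengene(df.iloc[::-1], genes[::-1])
        np.testing.assert_allclose(me1.sample_scores, me2.sample_scores, atol=1e-10)

    def test_constant_rows_dropped_then_error(self, rng):
        X = rng.standard_normal((3, 10))
        X[1] = 2.0
        df = _expr(X)
        me = module_eigengene(df, ["g0", "g1", "g2"])
        assert me.sign_anchor in {"g0", "g2"}
        X[2] = -1.0
        with pytest.raises(ValueError):
            module_eigengene(_expr(X), ["g0", "g1", "g2"])


class TestMedianSplit:
    def _me(self, scores):
        s = pd.Series(scores, index=[f"s{i}" for i in range(len(scores))])
        return type("ME", (), {"sample_scores": s})()

    def test_even_split(self):
        low, high = median_split(self._me([1.0, 2.0, 3.0, 4.0]))
        assert low == ["s0", "s1"] and high == ["s2", "s3"]

    def test_odd_n_median_goes_high(self):
        low, high = median_split(self._me([1.0, 2.0, 3.0]))
        assert low == ["s0"] and high == ["s1", "s2"]

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError):
            median_split(self._me([2.0, 2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_censored_middle_sample(self):
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_allclose(curve.event_times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0], atol=1e-12)
        assert curve.at_risk.tolist() == [3, 1]

    def test_no_events_flat_curve(self):
        curve = km_estimate([1.0, 2.0], [0, 0])
        assert curve.event_times.size == 0  # S stays at 1 throughout

    def test_survival_is_non_increasing(self, rng):
        t = rng.exponential(5, 100)
        e = rng.integers(0, 2, 100)
        if e.sum() == 0:
            e[0] = 1
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-15)
        assert curve.survival[0] <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_naive_loop(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            t = np.round(rng.exponential(5, n), 1)  # ties on purpose
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            curve = km_estimate(t, e)
            ref_t, ref_s = naive_km(t.tolist(), e.tolist())
            np.testing.assert_allclose(curve.event_times, ref_t, atol=1e-12)
            np.testing.assert_allclose(curve.survival, ref_s, atol=1e-10)


class TestLogRank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        res = logrank_test(t, e, t, e)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-12)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-12)

    def test_hand_worked_hypergeometric_table(self):
        """Group A events at 1, 2; group B events at 3, 4.  The explicit
        per-time table gives O_A - E_A = 2 - (1/2 + 1/3) = 7/6; variance
        accrues only while both groups are at risk: V = 1/4 + 2/9."""
        res = logrank_test([1.0, 2.0], [1, 1], [3.0, 4.0], [1, 1])
        v = 0.25 + 2 / 9
        expected_z = (7 / 6) / np.sqrt(v)
        assert res.z == pytest.approx(expected_z, abs=1e-12)
        assert res.chi2 == pytest.approx(expected_z**2, abs=1e-12)

    def test_label_swap_antisymmetry(self, rng):
        ta, ea = rng.exponential(2, 30), rng.integers(0, 2, 30)
        tb, eb = rng.exponential(4, 25), rng.integers(0, 2, 25)
        ea[0] = eb[0] = 1
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.z == pytest.approx(-r2.z, abs=1e-10)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)
        assert r1.hazard_ratio == pytest.approx(1 / r2.hazard_ratio, abs=1e-10)

    def test_matches_naive_loop_and_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for rep in range(50):
            na, nb = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            ta = np.round(rng.exponential(3, na), 1)
            tb = np.round(rng.exponential(5, nb), 1)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            res = logrank_test(ta, ea, tb, eb)
            chi2_ref, z_ref = naive_logrank(ta, ea, tb, eb)
            assert res.z == pytest.approx(z_ref, abs=1e-10)
            assert res.chi2 == pytest.approx(chi2_ref, abs=1e-10)
            ll = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert res.chi2 == pytest.approx(ll.test_statistic, abs=1e-8)
            assert res.p_two_sided == pytest.approx(ll.p_value, abs=1e-8)

    def test_report_schema_invariants(self, rng):
        ta, ea = rng.exponential(2, 40), np.ones(40, dtype=int)
        tb, eb = rng.exponential(6, 40), np.ones(40, dtype=int)
        res = logrank_test(ta, ea, tb, eb)
        assert res.chi2 == pytest.approx(res.z**2, abs=1e-12)
        assert res.ci95[0] < res.hazard_ratio < res.ci95[1]
        assert res.hazard_rate_high == pytest.approx(40 / ta.sum())
        assert res.hazard_rate_low == pytest.approx(40 / tb.sum())

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [0, 0], [3.0], [0])


class TestEvaluateModules:
    def test_empty_module_list(self):
        out = evaluate_modules([], None, None, None, None)
        assert len(out) == 0

    def test_planted_survival_module_detected(self, default_study):
        """The survival-linked planted module scores significant in both
        partitions; an unrelated module does not dominate it."""
        expr = default_study["expr"]
        surv = default_study["surv"].set_index("sample_id")
        truth = default_study["truth"]
        tumor = [s for s in expr.columns if s.startswith("T")]
        train, test = tumor[::2], tumor[1::2]
        mods = []
        for mid in (truth.survival_module_id, 2):
            genes = truth.module_genes(mid)
            mods.append(Module(id=mid, genes=frozenset(genes), edges=()))
        rep = evaluate_modules(
            mods,
            expr.loc[:, train],
            surv.loc[train],
            expr.loc[:, test],
            surv.loc[test],
        ).set_index("module_id")
        assert bool(rep.loc[truth.survival_module_id, "significant_both"])
        assert rep.loc[truth.survival_module_id, "train_p"] < 0.05
        assert rep.loc[2, "train_p"] > rep.loc[truth.survival_module_id, "train_p"]

    def test_module_with_missing_genes_skipped(self, default_study):
        expr = default_study["expr"]
        surv = default_study["surv"].set_index("sample_id")
        tumor = [s for s in expr.columns if s.startswith("T")]
        ghost = Module(id=99, genes=frozenset({"nope1", "nope2"}), edges=())
        out = evaluate_modules(
            [ghost], expr.loc[:, tumor], surv, expr.loc[:, tumor], surv
        )
        assert len(out) == 0
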