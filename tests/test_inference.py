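"""Profile MLE, LRT, fold change, variance-vs-depth slope and the t-test
gold standard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import depthbb as d
from depthbb.errors import ConfigurationError, InsufficientDataError
from depthbb.model import _bb_core, betabinom_logpmf


class TestEstimatePhat:
    def test_binomial_mle(self):
        assert d.estimate_phat(3, 7, 0.0) == pytest.approx(0.3, abs=1e-6)

    def test_symmetry_forces_half(self):
        for th in (0.0, 0.3, 1.0):
            assert d.estimate_phat(5, 5, th) == pytest.approx(0.5, abs=1e-6)

    def test_grid_oracle(self):
        # brute force the maximizer on a dense grid
        n, m, th = 8, 2, 0.3
        grid = np.linspace(1e-6, 1 - 1e-6, 100_001)
        oracle = grid[np.argmax(_bb_core(n, m, grid, th))]
        assert d.estimate_phat(n, m, th) == pytest.approx(oracle, abs=1e-5)

    def test_vectorized(self):
        out = d.estimate_phat(np.array([3, 5]), np.array([7, 5]), 0.0)
        assert out == pytest.approx([0.3, 0.5], abs=1e-6)


class TestLrt:
    def test_null_observation_gives_one(self):
        assert d.lrt_pvalue(5, 5, 0.2, 0.5) == pytest.approx(1.0)

    def test_chi2_reference(self):
        # an observation engineered to sit near the 5% boundary
        from scipy.stats import chi2

        pv = d.lrt_pvalue(60, 40, 0.0, 0.5)
        lam = 2 * (
            betabinom_logpmf(60, 40, 0.6, 0.0) - betabinom_logpmf(60, 40, 0.5, 0.0)
        )
        assert pv == pytest.approx(chi2.sf(lam, 1), abs=1e-9)

    def test_more_extreme_is_smaller(self):
        pvs = [d.lrt_pvalue(n, 100 - n, 0.1, 0.5) for n in (55, 65, 75, 85)]
        assert all(a > b for a, b in zip(pvs, pvs[1:]))


class TestFoldChange:
    def test_neutral_is_one(self):
        assert d.fold_change(0.37, 0.37) == pytest.approx(1.0)

    def test_odds_ratio(self):
        assert d.fold_change(2 / 3, 0.5) == pytest.approx(2.0)

    @given(p=st.floats(0.01, 0.99), pn=st.floats(0.01, 0.99))
    def test_swap_inverts(self, p, pn):
        fc = d.fold_change(p, pn)
        assert d.fold_change(1 - p, 1 - pn) == pytest.approx(1 / fc, rel=1e-9)

    def test_boundary_is_domain_error(self):
        with pytest.raises(ValueError):
            d.fold_change(0.0, 0.5)

    def test_pseudo_counts_keep_it_finite(self):
        fc = d.fold_change_counts(10, 0, 0.5)
        assert np.isfinite(fc) and fc > 1


class TestProfileLoglik:
    def test_single_gene_reduction(self):
        data = d.ReplicatePairSet(
            gene_ids=np.array(["g1"], dtype=object),
            n=np.array([[5]]),
            m=np.array([[5]]),
            pair_labels=["p1"],
        )
        ll, D = d.profile_loglik(data, gamma=0.3)
        # p_hat = 1/2 by symmetry and the mixture bound forces D to 0,
        # so the maximum is the binomial log pmf at its mode
        assert ll == pytest.approx(betabinom_logpmf(5, 5, 0.5, 0.0), abs=1e-6)
        assert D["g1"] == pytest.approx(0.0, abs=1e-6)

    def test_binomial_truth_fits_near_binomial(self):
        cfg = d.SimulationConfig(n_genes=200, n_pairs=3, d_scale=0.0, seed=13)
        pairs, _ = d.simulate_pairs(cfg)
        ll, D = d.profile_loglik(pairs, gamma=0.5)
        dvals = np.array(list(D.values()))
        assert np.mean(dvals <= 1e-6) > 0.5  # most genes at the D=0 boundary
        # binomial baseline: same shared-p profile with D forced to 0
        ll0, _ = d.profile_loglik(pairs, gamma=0.5, d_bounds=(1e-12, 1e-11))
        assert ll >= ll0 - 1e-6
        assert (ll - ll0) / cfg.n_genes < 0.5  # chance gain only

    def test_likelihood_dominance_at_truth(self, overdispersed_set):
        pairs, truth = overdispersed_set
        n, m, N = pairs.n, pairs.m, pairs.N
        valid = N >= 1

        def total_ll(scale):
            th = d.theta(truth.D_true.to_numpy()[:, None] * scale,
                         np.maximum(N, 1), 0.5)
            p = truth.p_true.to_numpy()[:, None]
            ll = _bb_core(n, m, p, th)
            return ll[valid].sum()

        assert total_ll(1.0) > total_ll(2.0)

    def test_excludes_empty_genes(self):
        data = d.ReplicatePairSet(
            gene_ids=np.array(["g1", "g2"], dtype=object),
            n=np.array([[5], [0]]),
            m=np.array([[5], [0]]),
            pair_labels=["p1"],
        )
        _, D = d.profile_loglik(data, gamma=0.0)
        assert "g2" not in D


class TestFitOverdispersion:
    def test_profile_curve_and_argmax(self, overdispersed_set):
        pairs, _ = overdispersed_set
        model = d.fit_overdispersion(pairs, gamma_grid=[0.0, 0.5, 1.0])
        assert [g for g, _ in model.gamma_grid] == [0.0, 0.5, 1.0]
        best = max(model.gamma_grid, key=lambda t: t[1])
        assert model.gamma == best[0]
        assert model.loglik == best[1]
        assert not model.near_binomial

    def test_gamma_recovery_coarse(self, overdispersed_set):
        pairs, _ = overdispersed_set
        model = d.fit_overdispersion(pairs)
        assert abs(model.gamma - 0.5) <= 0.2

    def test_binomial_truth_flags_near_binomial(self):
        cfg = d.SimulationConfig(n_genes=150, n_pairs=2, d_scale=0.0, seed=14)
        pairs, _ = d.simulate_pairs(cfg)
        model = d.fit_overdispersion(pairs, gamma_grid=[0.0, 0.6])
        assert model.near_binomial

    def test_rejects_bad_grid(self, overdispersed_set):
        with pytest.raises(ValueError):
            d.fit_overdispersion(overdispersed_set[0], gamma_grid=[])
        with pytest.raises(ValueError):
            d.fit_overdispersion(overdispersed_set[0], gamma_grid=[-0.1])


class TestVarianceTableAndSlope:
    def test_identical_pairs_have_zero_variance(self):
        data = d.ReplicatePairSet(
            gene_ids=np.array(["g1", "g2"], dtype=object),
            n=np.array([[30, 30], [50, 50]]),
            m=np.array([[30, 30], [50, 50]]),
            pair_labels=["p1", "p2"],
        )
        vt = d.variance_table(data, 0.5)
        assert np.allclose(vt.var_prop, 0.0)
        assert np.allclose(vt.mean_total, [60, 100])

    def test_binomial_variance_scale(self):
        cfg = d.SimulationConfig(
            n_genes=3000, n_pairs=3, d_scale=0.0, depth_log10_sd=0.0,
            pair_depth_log10_range=0.0, seed=15,
        )
        pairs, _ = d.simulate_pairs(cfg)
        vt = d.variance_table(pairs, 0.5)
        # all genes sit at N ~ 1000, so pool them against p(1-p)/N
        expected = 0.25 / vt.mean_total.mean()
        assert vt.var_prop.mean() == pytest.approx(expected, rel=0.1)

    def test_min_total_excludes(self):
        data = d.ReplicatePairSet(
            gene_ids=np.array(["lo", "hi"], dtype=object),
            n=np.array([[2], [500]]),
            m=np.array([[1], [480]]),
            pair_labels=["p1"],
        )
        vt = d.variance_table(data, 0.5, min_total=100)
        assert list(vt.gene_ids) == ["hi"]

    def test_slope_needs_enough_genes(self):
        vt = d.VarianceTable(
            gene_ids=np.array(["g"], dtype=object),
            mean_total=np.array([500.0]),
            var_prop=np.array([1e-3]),
        )
        with pytest.raises(InsufficientDataError):
            d.slope_gamma(vt)

    def test_overdispersed_exceeds_binomial_at_depth(self):
        cfg = d.SimulationConfig(n_genes=2000, n_pairs=3, gamma_true=0.5, seed=16)
        pairs, _ = d.simulate_pairs(cfg)
        vt = d.variance_table(pairs, 0.5)
        deep = vt.mean_total > 1000
        binom_expect = 0.25 / vt.mean_total[deep]
        assert vt.var_prop[deep].mean() > 3 * binom_expect.mean()


class TestTtestGold:
    def _matrix(self, rng, G=300, de=0.1, reps=4, fold=4.0):
        base = 10.0 ** rng.normal(2.0, 0.7, size=G)
        is_de = np.zeros(G, dtype=bool)
        is_de[rng.choice(G, int(G * de), replace=False)] = True
        mu_a = base * np.where(is_de, fold, 1.0)
        counts = np.column_stack(
            [rng.poisson(mu_a) for _ in range(reps)]
            + [rng.poisson(base) for _ in range(reps)]
        )
        runs = [f"a{i}" for i in range(reps)] + [f"b{i}" for i in range(reps)]
        cm = d.CountMatrix(
            gene_ids=np.array([f"g{i}" for i in range(G)], dtype=object),
            counts=counts,
            run_meta=pd.DataFrame(
                {"sample_id": ["A"] * reps + ["B"] * reps,
                 "library_id": runs},
                index=runs,
            ),
        )
        return cm, is_de, runs[:reps], runs[reps:]

    def test_identical_groups_find_nothing(self):
        rng = np.random.default_rng(17)
        cm, _, ga, gb = self._matrix(rng, de=0.0)
        res = d.ttest_gold(cm, ga, ga[::-1], min_count=20)
        assert not res["is_de"].any()

    def test_sensitivity_on_simulated_de(self):
        rng = np.random.default_rng(18)
        cm, is_de, ga, gb = self._matrix(rng)
        res = d.ttest_gold(cm, ga, gb, min_count=20)
        truth = pd.Series(is_de, index=cm.gene_ids).loc[res.index]
        assert res.loc[truth, "is_de"].mean() > 0.5

    def test_min_count_filter_is_exact(self):
        rng = np.random.default_rng(19)
        cm, _, ga, gb = self._matrix(rng)
        res = d.ttest_gold(cm, ga, gb, min_count=20)
        totals = pd.Series(cm.counts.sum(axis=1), index=cm.gene_ids)
        assert set(res.index) == set(totals.index[totals > 20])

    def test_fc_rule(self):
        rng = np.random.default_rng(20)
        cm, is_de, ga, gb = self._matrix(rng)
        res = d.ttest_gold(cm, ga, gb, fc_rule=2.0)
        assert res.loc[res["is_de"], "log2fc"].abs().min() > 1.0

    def test_small_group_rejected(self):
        rng = np.random.default_rng(21)
        cm, _, ga, gb = self._matrix(rng)
        with pytest.raises(ConfigurationError):
            d.ttest_gold(cm, ga[:1], gb)


class TestTestGenes:
    def test_binomial_and_betabinom_rows(self, binomial_pair):
        pair, _ = binomial_pair
        rows_bi = d.test_genes(pair, 0.5, method="binomial")
        model = d.OverdispersionModel(0.0, {}, 0.0)
        rows_bb = d.test_genes(pair, 0.5, method="betabinom", model=model)
        assert len(rows_bi) == len(rows_bb) == int((pair.N >= 1).sum())
        for r in rows_bi[:50]:
            assert 0 <= r.p_value <= 1 and r.fold_change > 0
        flags = {r.gene_id: r.passed_min_count for r in rows_bi}
        for gid, Ni in zip(pair.gene_ids, pair.N):
            if Ni >= 1:
                assert flags[gid] == (Ni > 20)

    def test_betabinom_requires_model(self, binomial_pair):
        with pytest.raises(ConfigurationError):
            d.test_genes(binomial_pair[0], 0.5, method="betabinom")

    def test_fold_change_equivariance_under_swap(self, binomial_pair):
        pair, _ = binomial_pair
        rows = d.test_genes(pair, 0.4, method="binomial")
        rows_sw = d.test_genes(pair.swapped(), 0.6, method="binomial")
        fc = {r.gene_id: r.fold_change for r in rows}
        fc_sw = {r.gene_id: r.fold_change for r in rows_sw}
        for gid in list(fc)[:100]:
            assert fc[gid] == pytest.approx(1.0 / fc_sw[gid], rel=1e-9)
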