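import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from scarsig.refit import normalise
from scarsig.screen import (benjamini_hochberg, fisher_exact_2x2,
                            gene_correlation, kendall_tau, ks_two_sample,
                            logistic_confounding, screen_signatures)
from scarsig.synthetic import SimulationConfig, simulate_activities


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_exact_p(self):
        # 2 of the C(6,3)=20 pooled orderings reach D=1
        d, p = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert abs(p - 0.1) < 1e-12

    def test_statistic_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 30))
            b = rng.normal(size=rng.integers(3, 30))
            d, _ = ks_two_sample(a, b)
            grid = np.concatenate([a, b])
            brute = max(abs((a <= t).mean() - (b <= t).mean()) for t in grid)
            assert abs(d - brute) < 1e-12

    def test_null_pvalues_super_uniform(self):
        """Under continuous i.i.d. data the rejection rate at 0.05 must not
        exceed 0.05 beyond Monte-Carlo error."""
        gen = np.random.default_rng(99)
        rejections = sum(
            ks_two_sample(gen.normal(size=25), gen.normal(size=25))[1] <= 0.05
            for _ in range(4000)
        )
        # 3 sigma above a binomial(4000, 0.05)
        assert rejections <= 4000 * 0.05 + 3 * np.sqrt(4000 * 0.05 * 0.95)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(benjamini_hochberg([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_degenerate_inputs(self):
        np.testing.assert_array_equal(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_array_equal(benjamini_hochberg([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_reference_and_step_up_rule(self, pvals):
        q = benjamini_hochberg(pvals)
        # monotone in p
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        # cross-check against statsmodels fdr_bh
        reject_sm, q_sm, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        # rejection at q <= alpha equals the classic step-up rule
        np.testing.assert_array_equal(q <= 0.05, reject_sm)


class TestKendallTau:
    def test_perfect_agreement_and_reversal(self):
        assert kendall_tau([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)
        assert kendall_tau([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_tie_corrected_value(self):
        tau, _ = kendall_tau([1, 1, 2], [1, 2, 2])
        assert tau == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 1, 1], [1, 2, 3])


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals the summed probability of all tables with the
        observed margins that are no more probable than the observed one."""
        for _ in range(10):
            t = rng.integers(0, 8, size=(2, 2))
            r1, r2 = t[0].sum(), t[1].sum()
            c1 = t[:, 0].sum()
            n = t.sum()
            probs = {}
            for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs[a] = scipy.stats.hypergeom.pmf(a, n, r1, c1)
            p_obs = probs[t[0, 0]]
            expected = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-9))
            assert fisher_exact_2x2(t) == pytest.approx(expected, rel=1e-9)

    def test_transpose_invariance(self, rng):
        t = rng.integers(0, 10, size=(2, 2))
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])


class TestScreenSignatures:
    def test_informative_signatures_flagged(self):
        """Exactly the two planted signatures survive B-H at m=400 (single
        seeded replicate of the power simulation; the full 50-replicate sweep
        runs in the acceptance suite)."""
        cfg = SimulationConfig(m_patients=400, p_signatures=20, seed=0)
        W, labels = simulate_activities(cfg, rng=np.random.default_rng(0))
        res = screen_signatures(normalise(W, cfg.coverage_mb),
                                labels.map({True: "yes", False: "no"}))
        assert set(res.significant) == {"SBS4", "SBS87"}

    def test_shuffled_labels_control_type_one_error(self):
        fracs = []
        for seed in range(10):
            cfg = SimulationConfig(m_patients=200, p_signatures=20, seed=seed)
            gen = np.random.default_rng(seed)
            W, labels = simulate_activities(cfg, rng=gen)
            shuffled = pd.Series(gen.permutation(
                labels.map({True: "yes", False: "no"}).to_numpy()), index=W.index)
            res = screen_signatures(normalise(W, cfg.coverage_mb), shuffled)
            fracs.append(len(res.significant) / cfg.p_signatures)
        assert np.mean(fracs) <= 0.05

    def test_identical_strata_not_flagged(self, rng):
        per_mb = pd.DataFrame({"S1": np.tile([0.5, 1.0, 1.5, 2.0], 4)},
                              index=[f"s{i}" for i in range(16)])
        labels = pd.Series(["yes", "no"] * 8, index=per_mb.index)
        res = screen_signatures(per_mb, labels)
        assert res.significant == []

    def test_empty_stratum_rejected(self, rng):
        per_mb = pd.DataFrame({"S1": rng.uniform(size=5)},
                              index=[f"s{i}" for i in range(5)])
        labels = pd.Series(["yes"] * 5, index=per_mb.index)
        with pytest.raises(ValueError):
            screen_signatures(per_mb, labels)


class TestGeneCorrelation:
    def test_non_mutated_genes_excluded(self, rng):
        sig = pd.Series(rng.uniform(0, 3, 30), index=[f"s{i}" for i in range(30)])
        genes = pd.DataFrame({
            "G1": rng.poisson(2, 30),
            "G0": np.zeros(30, dtype=int),
        }, index=sig.index)
        res = gene_correlation(sig, genes)
        assert "G0" not in res.table.index

    def test_planted_correlation_detected(self):
        gen = np.random.default_rng(31)
        m = 300
        sig = pd.Series(gen.exponential(50, m), index=[f"s{i}" for i in range(m)])
        genes = pd.DataFrame({
            "planted": gen.binomial(np.round(sig).astype(int), 0.05),
            "noise": gen.poisson(2, m),
        }, index=sig.index)
        res = gene_correlation(sig, genes)
        assert "planted" in res.significant
        assert res.table.loc["planted", "statistic"] > 0

    def test_independent_genes_rarely_flagged(self):
        flagged = 0
        for seed in range(20):
            gen = np.random.default_rng(200 + seed)
            m = 100
            sig = pd.Series(gen.exponential(50, m),
                            index=[f"s{i}" for i in range(m)])
            genes = pd.DataFrame(gen.poisson(2, (m, 10)), index=sig.index,
                                 columns=[f"G{j}" for j in range(10)])
            res = gene_correlation(sig, genes)
            flagged += bool(res.significant)
        assert flagged <= 1  # >= 95 % of runs clean

    def test_tmb_normalisation_path(self, rng):
        sig = pd.Series(rng.exponential(50, 30), index=[f"s{i}" for i in range(30)])
        tmb = pd.Series(rng.uniform(1, 10, 30), index=sig.index)
        genes = pd.DataFrame({"G1": rng.poisson(2, 30)}, index=sig.index)
        res = gene_correlation(sig, genes, tmb=tmb)
        assert "G1" in res.table.index


class TestLogisticConfounding:
    def test_independent_gene_changes_nothing(self):
        gen = np.random.default_rng(41)
        m = 10_000
        tmb = gen.exponential(5, m)
        y = (gen.random(m) < 1 / (1 + np.exp(-(0.15 * tmb - 1.0)))).astype(int)
        gene = gen.integers(0, 2, m)
        res = logistic_confounding(y, tmb, gene)
        assert res.converged
        assert res.change_ratio < 0.05
        assert not res.confounded

    def test_coefficients_match_direct_mle(self, rng):
        """The IRLS fit agrees with a generic optimiser on the same
        likelihood to 1e-6."""
        m = 60
        tmb = rng.exponential(5, m)
        gene = rng.integers(0, 2, m)
        y = (rng.random(m) < 0.4).astype(int)
        res = logistic_confounding(y, tmb, gene)

        X = np.column_stack([np.ones(m), tmb, gene])

        def nll(beta):
            eta = X @ beta
            return np.sum(np.logaddexp(0, eta)) - y @ eta

        opt = scipy.optimize.minimize(nll, np.zeros(3), method="BFGS",
                                      options={"gtol": 1e-10})
        assert abs(res.coef_with - opt.x[1]) < 1e-6

    def test_confounder_detected_when_gene_drives_outcome(self):
        gen = np.random.default_rng(43)
        m = 2000
        gene = gen.integers(0, 2, m)
        tmb = gen.exponential(3, m) + 4.0 * gene  # gene raises TMB
        y = (gen.random(m) < 1 / (1 + np.exp(-(2.0 * gene - 1.0)))).astype(int)
        res = logistic_confounding(y, tmb, gene)
        assert res.confounded
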