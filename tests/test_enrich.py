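import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primir import (
    ConfigError,
    ExpressionMatrix,
    SynthConfig,
    ValidationError,
    bh_fdr,
    enrichment_report,
    generate_world,
    hypergeom_tail,
    mann_whitney_u,
    pri_mature_correlation,
)


def exact_hypergeom_tail(N, M, n, m):
    """Independent oracle: exact rational upper tail via integer binomials."""
    total = math.comb(N, n)
    s = Fraction(0)
    for k in range(m, min(n, M) + 1):
        if n - k <= N - M:
            s += Fraction(math.comb(M, k) * math.comb(N - M, n - k), total)
    return float(s)


class TestHypergeomTail:
    def test_worked_example_vs_draw_enumeration(self):
        # N=10 genes, 4 targets, draw 3: P(at least one target)
        universe = range(10)
        targets = set(range(4))
        draws = list(itertools.combinations(universe, 3))
        frac = sum(1 for d in draws if len(targets & set(d)) >= 1) / len(draws)
        assert frac == pytest.approx(5 / 6)
        assert hypergeom_tail(10, 4, 3, 1) == pytest.approx(5 / 6, rel=1e-12)

    def test_degenerate_cases(self):
        assert hypergeom_tail(50, 10, 5, 0) == 1.0
        assert hypergeom_tail(10, 5, 10, 5) == 1.0  # drew everything

    def test_matches_scipy_on_moderate_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(20, 3000))
            M = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            m = int(rng.integers(max(0, n + M - N), min(n, M) + 1))
            ours = hypergeom_tail(N, M, n, m)
            ref = stats.hypergeom.sf(m - 1, N, M, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_exact_rational_oracle_small_sweep(self):
        for N in range(1, 13):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(max(0, n + M - N), min(n, M) + 1):
                        assert hypergeom_tail(N, M, n, m) == pytest.approx(
                            exact_hypergeom_tail(N, M, n, m), rel=1e-11), \
                            (N, M, n, m)

    def test_large_universe_is_finite_and_stable(self):
        # factorials at N=2312 overflow; log-space must not
        p = hypergeom_tail(2312, 150, 170, 30)
        assert 0.0 < p <= 1.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_tail(10, 11, 3, 1)
        with pytest.raises(ValidationError):
            hypergeom_tail(10, 4, 3, 4)


class TestEnrichmentReport:
    def test_full_overlap_and_disjoint(self):
        universe = {f"g{i}" for i in range(100)}
        assoc = {"mir": {f"g{i}" for i in range(5)}}
        records, summary = enrichment_report(assoc, {"mir": set(assoc["mir"])},
                                             universe)
        rec = records[0]
        assert (rec.N, rec.M, rec.n, rec.m) == (100, 5, 5, 5)
        assert rec.frac_assoc_in_targets == 1.0
        assert rec.frac_targets_in_assoc == 1.0
        assert rec.p_hyper < 1e-6

        records, _ = enrichment_report(
            assoc, {"mir": {f"g{i}" for i in range(50, 60)}}, universe)
        assert records[0].m == 0
        assert records[0].p_hyper == 1.0

    def test_toy_instance_matches_exhaustive_oracle(self):
        universe = {f"g{i}" for i in range(20)}
        assoc = {"mir": {"g0", "g1", "g2", "g3", "g4", "g5"}}
        targets = {"mir": {"g3", "g4", "g5", "g6", "g7"}}
        records, _ = enrichment_report(assoc, targets, universe)
        rec = records[0]
        assert rec.p_hyper == pytest.approx(
            exact_hypergeom_tail(20, 5, 6, 3), rel=1e-11)

    def test_genes_outside_universe_dropped(self):
        universe = {"a", "b", "c", "d"}
        records, _ = enrichment_report({"mir": {"a", "zzz"}},
                                       {"mir": {"a", "yyy"}}, universe)
        assert records[0].n == 1 and records[0].M == 1 and records[0].m == 1

    def test_empty_associated_set_flagged(self):
        records, summary = enrichment_report({"mir": set()},
                                             {"mir": {"a"}}, {"a", "b"})
        assert records[0].flagged and records[0].p_hyper is None
        assert summary["n_flagged"] == 1


class TestBhFdr:
    def test_step_up_hand_examples(self):
        reject, _ = bh_fdr([0.001, 0.008, 0.039, 0.041, 0.042, 0.06], q=0.05)
        assert reject.sum() == 2 and reject[0] and reject[1]
        reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert reject.sum() == 0
        reject, _ = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_order_restored_and_adjusted_monotone(self):
        p = [0.04, 0.001, 0.9, 0.02]
        reject, adj = bh_fdr(p, q=0.05)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert adj.max() <= 1.0
        # rejected entries are exactly those with adjusted p <= q
        np.testing.assert_array_equal(reject, adj <= 0.05)

    def test_matches_reference_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            reject, adj = bh_fdr(p, q=0.05)
            ref_rej, ref_adj, *_ = sm.multipletests(p, alpha=0.05,
                                                    method="fdr_bh")
            np.testing.assert_array_equal(reject, ref_rej)
            np.testing.assert_allclose(adj, ref_adj, rtol=1e-12)

    def test_false_discovery_proportion_controlled_under_null(self):
        rng = np.random.default_rng(2)
        q = 0.1
        fdp = [bh_fdr(rng.uniform(0, 1, 50), q=q)[0].any()
               for _ in range(400)]
        # under a full null FDP is 1{any rejection}; E[FDP] <= q
        assert np.mean(fdp) <= q + 3 * np.sqrt(q * (1 - q) / 400)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ConfigError):
            bh_fdr([0.5], q=0.0)


class TestMannWhitney:
    def test_separated_samples_exact_two_sided(self):
        # U=0; 2 * 1/C(6,3) = 0.1
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_no_evidence(self):
        assert mann_whitney_u([1.5, 2.5, 3.5], [1.5, 2.5, 3.5]) >= 0.99

    def test_exact_path_matches_independent_enumeration(self):
        rng = np.random.default_rng(3)
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (3, 5)]:
            vals = rng.standard_normal(n1 + n2)
            a, b = vals[:n1], vals[n1:]
            for alt, scipy_alt in [("two_sided", "two-sided"),
                                   ("greater", "greater"), ("less", "less")]:
                ours = mann_whitney_u(a, b, alternative=alt)
                ref = stats.mannwhitneyu(a, b, alternative=scipy_alt,
                                         method="exact").pvalue
                assert ours == pytest.approx(ref, rel=1e-12), (n1, n2, alt)

    def test_exact_and_normal_paths_agree_on_small_inputs(self):
        rng = np.random.default_rng(4)
        from primir.enrich import _normal_mw_pvalue, _u_statistic
        for _ in range(20):
            a = rng.standard_normal(5)
            b = rng.standard_normal(6)
            exact = mann_whitney_u(a, b)
            pooled = np.concatenate([a, b])
            approx = _normal_mw_pvalue(pooled, 5, 6, _u_statistic(a, b),
                                       "two_sided")
            assert abs(exact - approx) < 0.02

    def test_tied_large_samples_use_corrected_normal_path(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, 40).astype(float)
        b = rng.integers(1, 6, 45).astype(float)
        ours = mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestPriMatureCorrelation:
    def make_matrices(self):
        rng = np.random.default_rng(6)
        samples = [f"s{i}" for i in range(30)]
        y = rng.uniform(0, 50, 30)
        pri = ExpressionMatrix(
            pd.DataFrame([y], index=["mir1"], columns=samples))
        noisy = np.maximum(y + rng.normal(0, y.std() * 2.0, 30), 0)
        mature = ExpressionMatrix(
            pd.DataFrame([noisy, y], index=["m_low", "m_hi"], columns=samples))
        return pri, mature

    def test_max_over_matures_and_significance(self):
        pri, mature = self.make_matrices()
        records, _ = pri_mature_correlation(
            pri, mature, {"mir1": ["m_low", "m_hi"]}, fdr_q=0.01)
        rec = records[0]
        assert rec.best_mature_id == "m_hi"
        assert rec.max_pearson == pytest.approx(1.0)
        assert rec.low_correlation is False

    def test_unmapped_pri_flagged(self):
        pri, mature = self.make_matrices()
        records, summary = pri_mature_correlation(pri, mature, {}, fdr_q=0.01)
        assert records[0].flagged
        assert summary["n_flagged"] == 1

    def test_low_correlation_fraction_on_planted_world(self):
        fracs = []
        for seed in (51, 52, 53):
            world = generate_world(SynthConfig(
                n_samples=120, n_mrnas=40, n_primirnas=10, support_size=5,
                n_groups=30, frac_low_corr=0.5, mature_corr_low=0.1,
                mature_corr_high=0.9, seed=seed))
            _, summary = pri_mature_correlation(
                world.mirna_matrix(), world.mature_matrix,
                world.pri_to_mature, fdr_q=0.01)
            fracs.append(summary["low_correlation_fraction"])
        assert abs(np.mean(fracs) - 0.5) < 0.15

    def test_sample_mismatch_rejected(self):
        pri, mature = self.make_matrices()
        shifted = ExpressionMatrix(
            mature.data.rename(columns={"s0": "weird"}))
        with pytest.raises(ValidationError):
            pri_mature_correlation(pri, shifted, {"mir1": ["m_hi"]})
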