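import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primir import (
    ConfigError,
    ExpressionMatrix,
    SynthConfig,
    ValidationError,
    correlation_pvalue,
    correlation_report,
    crossval,
    generate_world,
    permutation_control,
    shared_fraction,
)


def matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    data = pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])])
    return ExpressionMatrix(data, transform="log1p")


class TestCorrelationPvalue:
    def test_symmetry_and_extremes(self):
        assert correlation_pvalue(0.0, 100) == pytest.approx(0.5)
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    def test_two_sided_doubles_one_sided(self):
        p1 = correlation_pvalue(0.5, 30, "one")
        p2 = correlation_pvalue(0.5, 30, "two")
        assert p2 == pytest.approx(2 * p1)

    def test_monotone_in_r_and_n(self):
        ps_r = [correlation_pvalue(r, 50) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps_r, ps_r[1:]))
        ps_n = [correlation_pvalue(0.4, n) for n in (10, 30, 100, 300)]
        assert all(a > b for a, b in zip(ps_n, ps_n[1:]))

    def test_matches_independent_t_distribution_oracle(self):
        # survival function of the t statistic, computed independently
        for r, n in [(0.3, 25), (0.65, 12), (0.85, 200)]:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            assert correlation_pvalue(r, n) == pytest.approx(
                stats.t.sf(t, n - 2), rel=1e-12)

    def test_argument_validation(self):
        with pytest.raises(ValidationError):
            correlation_pvalue(0.5, 2)
        with pytest.raises(ValidationError):
            correlation_pvalue(1.5, 10)
        with pytest.raises(ConfigError):
            correlation_pvalue(0.5, 10, sided="both")


class TestCorrelationReport:
    def test_perfect_and_affine_predictions(self):
        rng = np.random.default_rng(0)
        truth = matrix(rng.uniform(0, 10, (4, 12)))
        records, summary = correlation_report(truth, truth)
        assert all(r.pearson == pytest.approx(1.0) for r in records)
        affine = ExpressionMatrix(2.0 * truth.data + 5.0, transform="log1p")
        records, _ = correlation_report(truth, affine)
        assert all(r.pearson == pytest.approx(1.0) for r in records)
        assert all(r.spearman == pytest.approx(1.0) for r in records)

    def test_matches_brute_force_oracle_on_toy_matrices(self):
        rng = np.random.default_rng(1)
        truth = matrix(rng.uniform(0, 10, (4, 4)))
        pred = matrix(rng.uniform(0, 10, (4, 4)))
        for axis in ("per_gene", "per_sample"):
            records, _ = correlation_report(truth, pred, axis=axis)
            for i, rec in enumerate(records):
                a = truth.values[i] if axis == "per_gene" else truth.values[:, i]
                b = pred.values[i] if axis == "per_gene" else pred.values[:, i]
                assert rec.pearson == pytest.approx(stats.pearsonr(a, b).statistic)
                assert rec.spearman == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_constant_vectors_flagged_and_excluded(self):
        truth = matrix([[1, 2, 3, 4], [5, 5, 5, 5]])
        pred = matrix([[1, 2, 3, 4], [1, 2, 3, 4]])
        records, summary = correlation_report(truth, pred)
        assert records[1].defined is False
        assert summary["n_undefined"] == 1
        assert summary["pearson"]["n"] == 1

    def test_strata_partition_by_pearson_and_activity(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0, 30, 40)
        truth = matrix([base, base, rng.uniform(0, 2, 40)])
        noisy = base + rng.normal(0, base.std(), 40)
        pred = matrix([base, noisy, rng.uniform(0, 2, 40)])
        _, summary = correlation_report(truth, pred, axis="per_gene")
        strata = summary["strata"]
        assert strata["high"]["pearson"]["n"] >= 1
        assert (strata["high"]["pearson"]["n"] + strata["low"]["pearson"]["n"]
                == summary["pearson"]["n"])
        # "active" stratum keyed on the sd of the true expression
        assert strata["active"]["pearson"]["n"] == 2

    def test_misaligned_matrices_rejected(self):
        truth = matrix([[1, 2, 3]])
        pred = matrix([[1, 2, 3]], prefix="other")
        with pytest.raises(ValidationError):
            correlation_report(truth, pred)


class TestPermutationControl:
    def test_across_samples_preserves_row_multisets(self):
        rng = np.random.default_rng(3)
        expr = matrix(rng.uniform(0, 9, (6, 15)))
        ctrl = permutation_control(expr, "across_samples", seed=1)
        np.testing.assert_array_equal(np.sort(ctrl.values, axis=1),
                                      np.sort(expr.values, axis=1))
        assert not np.array_equal(ctrl.values, expr.values)

    def test_within_sample_preserves_column_multisets(self):
        rng = np.random.default_rng(4)
        expr = matrix(rng.uniform(0, 9, (15, 6)))
        ctrl = permutation_control(expr, "within_sample", seed=1)
        np.testing.assert_array_equal(np.sort(ctrl.values, axis=0),
                                      np.sort(expr.values, axis=0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            permutation_control(matrix([[1, 2]]), "shuffle_everything")


def cv_world(seed=17, **over):
    cfg = dict(n_samples=100, n_mrnas=50, n_primirnas=3, support_size=5,
               n_groups=50, seed=seed)
    cfg.update(over)
    return generate_world(SynthConfig(**cfg))


class TestCrossval:
    def run(self, world, mrna=None, **kw):
        args = dict(n_experiments=2, n_folds=2, seed=5, alpha=20.0,
                    tol=1e-4, max_sweeps=200)
        args.update(kw)
        return crossval(mrna or world.mrna_matrix(), world.mirna_matrix(),
                        world.sample_table.groups(), **args)

    def test_unique_groups_remove_no_test_samples(self):
        world = cv_world(n_groups=100)  # every sample its own group
        report = self.run(world)
        assert all(f.n_removed == 0 for f in report.folds)
        assert not any(f.flagged for f in report.folds)

    def test_single_group_flags_every_fold(self):
        world = cv_world(n_groups=1)
        report = self.run(world)
        assert all(f.flagged for f in report.folds)
        assert report.per_gene_pearson().size == 0

    def test_group_deduplication_invariant(self):
        world = cv_world(n_groups=20)
        report = self.run(world)
        groups = world.sample_table.groups()
        for f in report.folds:
            train_groups = {groups[s] for s in f.train_samples}
            assert all(groups[s] not in train_groups for s in f.test_samples)

    def test_deterministic_given_seed(self):
        world = cv_world()
        r1, r2 = self.run(world), self.run(world)
        np.testing.assert_array_equal(r1.per_gene_pearson(),
                                      r2.per_gene_pearson())

    def test_planted_world_beats_permuted_control(self):
        gaps = []
        for seed in (31, 32, 33):
            world = cv_world(seed=seed)
            real = self.run(world).per_gene_pearson().mean()
            ctrl_m = permutation_control(world.mrna_matrix(),
                                         "across_samples", seed=seed)
            ctrl = self.run(world, mrna=ctrl_m).per_gene_pearson().mean()
            gaps.append(real - ctrl)
        assert np.mean(gaps) >= 0.3

    def test_null_response_correlations_center_at_zero(self):
        world = cv_world(seed=41)
        rng = np.random.default_rng(8)
        null_mirna = ExpressionMatrix(
            pd.DataFrame(rng.uniform(0, 50, world.mirna_matrix().shape),
                         index=world.mirna_ids,
                         columns=world.cage_matrix.sample_ids),
            transform="raw_tpm")
        report = crossval(world.mrna_matrix(), null_mirna,
                          world.sample_table.groups(), n_experiments=3,
                          n_folds=2, seed=9, alpha=10.0, tol=1e-4,
                          max_sweeps=200)
        rs = report.per_gene_pearson()
        n_test = np.mean([len(f.test_samples) for f in report.folds])
        null_sd = 1.0 / np.sqrt(n_test - 1)
        assert abs(rs.mean()) < 4 * null_sd / np.sqrt(len(rs)) + 0.1

    def test_missing_group_label_rejected(self):
        world = cv_world()
        groups = world.sample_table.groups()
        groups.pop(next(iter(groups)))
        with pytest.raises(ValidationError):
            crossval(world.mrna_matrix(), world.mirna_matrix(), groups,
                     alpha=1.0)


class TestSharedFraction:
    def test_identical_and_disjoint_sets(self):
        sets = [{"mir": {"a", "b", "c"}} for _ in range(3)]
        out = shared_fraction(sets, reference={"mir": {"a", "b", "c"}},
                              min_other=2)
        assert out["ref_shared_mean"] == pytest.approx(1.0)
        assert out["multi_shared_mean"] == pytest.approx(1.0)
        disjoint = [{"mir": {"a"}}, {"mir": {"b"}}]
        out = shared_fraction(disjoint, reference={"mir": {"z"}}, min_other=1)
        assert out["ref_shared_mean"] == 0.0
        assert out["multi_shared_mean"] == 0.0

    def test_partial_overlap_fraction(self):
        sets = [{"mir": {"a", "b", "c"}}, {"mir": {"b", "c", "d"}}]
        out = shared_fraction(sets, reference={"mir": {"b", "c", "d"}},
                              min_other=1)
        # {a,b,c} vs reference {b,c,d}: 2/3; second set: 3/3
        per = out["per_pri"]["mir"]
        assert per["ref_shared_mean"] == pytest.approx((2 / 3 + 1.0) / 2)

    def test_empty_sets_flagged_not_averaged(self):
        sets = [{"mir": set()}, {"mir": {"a"}}]
        out = shared_fraction(sets, reference={"mir": {"a"}}, min_other=1)
        assert out["per_pri"]["mir"]["n_empty"] == 1
        assert out["ref_shared_mean"] == pytest.approx(1.0)

    def test_needs_two_collections(self):
        with pytest.raises(ValidationError):
            shared_fraction([{"mir": {"a"}}])
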