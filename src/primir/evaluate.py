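"""Scoring predictions and building negative controls.

Correlation significance uses the t statistic

    t = r * sqrt(n - 2) / sqrt(1 - r^2),   df = n - 2,

with a one-sided (positive association) upper-tail p-value by default; this
choice reproduces the analytic anchors p = 2.92e-5 at (r=0.75, n=22) and
p = 4.91e-10 at (r=0.42, n=195).  Spearman p-values apply the same
approximation to rho.

Cross-validation repeats a random halving of samples; test samples sharing a
group label (cell type) with any training sample are removed before scoring,
so a model never gets credit for memorizing a condition it saw in training.
The two permutation controls destroy the mRNA-pri-miRNA association while
preserving per-row (across-samples mode) or per-column (within-sample mode)
value multisets exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    AssociatedGeneSet,
    ConfigError,
    ExpressionMatrix,
    ValidationError,
)
from .model import associated_genes, fit_pri_mirna, predict

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation significance
# ---------------------------------------------------------------------------

def correlation_pvalue(r: float, n: int, sided: str = "one") -> float:
    """P-value of a correlation coefficient via the t approximation.

    One-sided is the upper-tail probability (positive association);
    two-sided doubles it for |r|.  |r| = 1 returns an exact 0.
    """
    if sided not in ("one", "two"):
        raise ConfigError(f"sided must be 'one' or 'two', got {sided!r}")
    if n < 3:
        raise ValidationError(f"need n >= 3 paired values, got {n}")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    if sided == "one":
        return float(stats.t.sf(t, df=n - 2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationRecord:
    """Pearson/Spearman agreement of one predicted-vs-true unit."""

    unit_id: str
    pearson: float
    spearman: float
    n: int
    p_pearson: float
    p_spearman: float
    defined: bool = True  # False when a constant vector made r undefined


def _correlate(unit_id: str, x: np.ndarray, y: np.ndarray,
               sided: str = "one") -> CorrelationRecord:
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationRecord(unit_id, np.nan, np.nan, n, np.nan, np.nan,
                                 defined=False)
    r = float(np.corrcoef(x, y)[0, 1])
    rho = float(stats.spearmanr(x, y).statistic)
    r = max(-1.0, min(1.0, r))
    rho = max(-1.0, min(1.0, rho))
    return CorrelationRecord(
        unit_id, r, rho, n,
        correlation_pvalue(r, n, sided), correlation_pvalue(rho, n, sided),
    )


def _summary_stats(values: list[float]) -> dict:
    if not values:
        return {"n": 0, "min": None, "max": None, "mean": None, "median": None}
    arr = np.asarray(values)
    return {"n": int(arr.size), "min": float(arr.min()),
            "max": float(arr.max()), "mean": float(arr.mean()),
            "median": float(np.median(arr))}


def correlation_report(truth: ExpressionMatrix, predicted: ExpressionMatrix,
                       axis: str = "per_gene", sided: str = "one",
                       active_sd: float = 3.0,
                       high_r: float = 0.9) -> tuple[list[CorrelationRecord], dict]:
    """Correlate predicted with true expression, per gene or per sample.

    Returns records plus a summary: min/mean/median of each statistic and a
    stratified view (per_gene only): "high" (Pearson > high_r), "low"
    (Pearson <= high_r), "active" (true-expression sd > active_sd).
    Undefined correlations (constant vectors) are flagged, excluded from
    summaries, and counted.
    """
    if axis not in ("per_gene", "per_sample"):
        raise ConfigError(f"axis must be per_gene or per_sample, got {axis!r}")
    if truth.gene_ids != predicted.gene_ids or \
            truth.sample_ids != predicted.sample_ids:
        raise ValidationError("truth and predicted matrices are not aligned")

    t_vals, p_vals = truth.values, predicted.values
    if axis == "per_sample":
        records = [
            _correlate(s, t_vals[:, i], p_vals[:, i], sided)
            for i, s in enumerate(truth.sample_ids)
        ]
    else:
        records = [
            _correlate(g, t_vals[i], p_vals[i], sided)
            for i, g in enumerate(truth.gene_ids)
        ]

    defined = [rec for rec in records if rec.defined]
    n_undefined = len(records) - len(defined)
    if n_undefined:
        logger.info("correlation_report: %d undefined correlation(s) excluded "
                    "from summaries", n_undefined)
    summary = {
        "axis": axis,
        "n_units": len(records),
        "n_undefined": n_undefined,
        "pearson": _summary_stats([rec.pearson for rec in defined]),
        "spearman": _summary_stats([rec.spearman for rec in defined]),
    }
    if axis == "per_gene":
        sd = {g: float(v) for g, v in zip(truth.gene_ids,
                                          t_vals.std(axis=1))}
        med = {g: float(v) for g, v in zip(truth.gene_ids,
                                           np.median(t_vals, axis=1))}
        strata = {
            "high": [rec for rec in defined if rec.pearson > high_r],
            "low": [rec for rec in defined if rec.pearson <= high_r],
            "active": [rec for rec in defined if sd[rec.unit_id] > active_sd],
        }
        summary["strata"] = {
            name: {
                "pearson": _summary_stats([rec.pearson for rec in recs]),
                "median_expression": _summary_stats(
                    [med[rec.unit_id] for rec in recs]),
            }
            for name, recs in strata.items()
        }
    return records, summary


# ---------------------------------------------------------------------------
# Permutation negative controls
# ---------------------------------------------------------------------------

PERMUTATION_MODES = ("across_samples", "within_sample")


def permutation_control(expr: ExpressionMatrix, mode: str,
                        seed: int = 0) -> ExpressionMatrix:
    """Destroy gene-gene association while conserving value multisets.

    across_samples: each row's values are independently permuted over the
    columns (each mRNA keeps its own distribution, sample identity is lost).
    within_sample: each column's values are independently permuted over the
    rows (each sample keeps its own distribution, gene identity is lost).
    """
    if mode not in PERMUTATION_MODES:
        raise ConfigError(f"mode {mode!r} not in {PERMUTATION_MODES}")
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    if mode == "across_samples":
        for i in range(values.shape[0]):
            values[i] = rng.permutation(values[i])
    else:
        for j in range(values.shape[1]):
            values[:, j] = rng.permutation(values[:, j])
    data = pd.DataFrame(values, index=expr.gene_ids, columns=expr.sample_ids)
    return ExpressionMatrix(data, transform=expr.transform)


# ---------------------------------------------------------------------------
# Cross-validation with group deduplication
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    experiment: int
    fold: int
    train_samples: list[str]
    test_samples: list[str]          # retained after group deduplication
    n_removed: int
    flagged: bool                    # too few test samples for correlations
    per_gene: list[CorrelationRecord] = field(default_factory=list)
    per_sample: list[CorrelationRecord] = field(default_factory=list)
    associated: dict[str, AssociatedGeneSet] = field(default_factory=dict)


@dataclass
class CvReport:
    folds: list[FoldResult]
    n_experiments: int
    n_folds: int
    seed: int

    def per_gene_pearson(self) -> np.ndarray:
        return np.array([rec.pearson for f in self.folds
                         for rec in f.per_gene if rec.defined])

    def per_gene_spearman(self) -> np.ndarray:
        return np.array([rec.spearman for f in self.folds
                         for rec in f.per_gene if rec.defined])

    def per_sample_pearson(self) -> np.ndarray:
        return np.array([rec.pearson for f in self.folds
                         for rec in f.per_sample if rec.defined])

    def associated_by_experiment(self) -> list[dict[str, AssociatedGeneSet]]:
        """Per experiment, the union-by-pri of its folds' associated sets
        (first fold wins on conflicts; folds are complementary halves)."""
        out: list[dict[str, AssociatedGeneSet]] = []
        for e in range(self.n_experiments):
            merged: dict[str, AssociatedGeneSet] = {}
            for f in self.folds:
                if f.experiment == e:
                    for pri, s in f.associated.items():
                        merged.setdefault(pri, s)
            out.append(merged)
        return out

    def summary(self) -> dict:
        return {
            "n_experiments": self.n_experiments,
            "n_folds": self.n_folds,
            "n_flagged_folds": sum(f.flagged for f in self.folds),
            "per_gene_pearson": _summary_stats(self.per_gene_pearson().tolist()),
            "per_gene_spearman": _summary_stats(self.per_gene_spearman().tolist()),
            "per_sample_pearson": _summary_stats(self.per_sample_pearson().tolist()),
        }


def crossval(expr_mrna: ExpressionMatrix, expr_mirna: ExpressionMatrix,
             sample_groups: dict[str, str], n_experiments: int = 10,
             n_folds: int = 2, seed: int = 0, alpha=1.0,
             tol: float = 1e-5, max_sweeps: int = 500,
             exclusions: dict[str, list[str]] | None = None,
             zero_tol: float = 1e-8, sided: str = "one",
             min_test: int = 3) -> CvReport:
    """Repeated random n-fold validation with group deduplication.

    Per experiment the samples are randomly split into ``n_folds`` parts;
    each part serves once as the test half while the rest trains.  Test
    samples whose group label occurs in training are removed before scoring
    (training is untouched).  Folds left with fewer than ``min_test``
    retained samples are flagged and contribute no correlations.

    ``alpha`` is either a single penalty or a mapping pri-miRNA id ->
    penalty.  Deterministic given ``seed``.
    """
    samples = expr_mrna.sample_ids
    if expr_mirna.sample_ids != samples:
        raise ValidationError("mRNA and pri-miRNA matrices disagree on samples")
    missing = [s for s in samples if s not in sample_groups]
    if missing:
        raise ValidationError(f"samples without group label: {missing[:10]}")
    exclusions = exclusions or {}

    mrna_ids = expr_mrna.gene_ids
    X_all = expr_mrna.values.T          # samples x genes
    Y_all = expr_mirna.values           # pri x samples
    groups = np.array([sample_groups[s] for s in samples], dtype=object)
    sample_arr = np.array(samples, dtype=object)
    col_of = {g: j for j, g in enumerate(mrna_ids)}

    folds: list[FoldResult] = []
    for e in range(n_experiments):
        rng = np.random.default_rng([seed, e])
        perm = rng.permutation(len(samples))
        parts = np.array_split(perm, n_folds)
        for fi in range(n_folds):
            test_idx = parts[fi]
            train_idx = np.concatenate([parts[k] for k in range(n_folds)
                                        if k != fi])
            train_groups = set(groups[train_idx])
            keep = np.array([groups[i] not in train_groups for i in test_idx])
            kept_idx = test_idx[keep]
            n_removed = int((~keep).sum())
            flagged = len(kept_idx) < min_test
            if flagged:
                logger.warning("experiment %d fold %d: only %d test samples "
                               "after group deduplication; correlations "
                               "omitted", e, fi, len(kept_idx))

            result = FoldResult(
                experiment=e, fold=fi,
                train_samples=sample_arr[train_idx].tolist(),
                test_samples=sample_arr[kept_idx].tolist(),
                n_removed=n_removed, flagged=flagged,
            )

            preds = {}
            for gi, pri in enumerate(expr_mirna.gene_ids):
                cols = np.array([col_of[g] for g in mrna_ids
                                 if g not in set(exclusions.get(pri, []))])
                gene_subset = [mrna_ids[c] for c in cols]
                a = alpha[pri] if isinstance(alpha, dict) else alpha
                try:
                    m = fit_pri_mirna(pri, X_all[train_idx][:, cols],
                                      gene_subset, Y_all[gi, train_idx],
                                      alpha=a, tol=tol, max_sweeps=max_sweeps)
                except ValidationError as err:
                    logger.warning("experiment %d fold %d: skipping %s (%s)",
                                   e, fi, pri, err)
                    continue
                result.associated[pri] = associated_genes(m, zero_tol=zero_tol)
                if not flagged:
                    preds[pri] = predict(m, X_all[kept_idx][:, cols])

            if not flagged and preds:
                pri_ids = list(preds)
                P = np.array([preds[p] for p in pri_ids])
                T = np.array([Y_all[expr_mirna.gene_ids.index(p), kept_idx]
                              for p in pri_ids])
                result.per_gene = [
                    _correlate(p, T[i], P[i], sided)
                    for i, p in enumerate(pri_ids)
                ]
                if len(pri_ids) >= 3:
                    result.per_sample = [
                        _correlate(str(sample_arr[s]), T[:, k], P[:, k], sided)
                        for k, s in enumerate(kept_idx)
                    ]
            folds.append(result)
    return CvReport(folds=folds, n_experiments=n_experiments,
                    n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# Stability of associated sets across experiments
# ---------------------------------------------------------------------------

def _as_set(obj) -> set[str]:
    return obj.gene_ids if isinstance(obj, AssociatedGeneSet) else set(obj)


def shared_fraction(collections: list[dict], reference: dict | None = None,
                    min_other: int = 4) -> dict:
    """Overlap statistics of associated-gene sets across experiments.

    Per pri-miRNA and per experiment: the fraction of that experiment's
    associated genes present in the reference (full-data) set, and the
    fraction present in at least ``min_other`` *other* experiments.  Empty
    sets yield undefined fractions (None) and are flagged, not averaged.
    """
    if len(collections) < 2:
        raise ValidationError("need at least 2 collections")
    pri_ids = sorted({p for c in collections for p in c})
    per_pri: dict[str, dict] = {}
    ref_means, multi_means = [], []
    for pri in pri_ids:
        sets = [_as_set(c[pri]) for c in collections if pri in c]
        ref_fracs: list[float] = []
        if reference is not None and pri in reference:
            ref_set = _as_set(reference[pri])
            for s in sets:
                if s:
                    ref_fracs.append(len(s & ref_set) / len(s))
        multi_fracs: list[float] = []
        for i, s in enumerate(sets):
            if not s:
                continue
            others = [t for j, t in enumerate(sets) if j != i]
            count = sum(1 for g in s
                        if sum(g in t for t in others) >= min_other)
            multi_fracs.append(count / len(s))
        entry = {
            "n_experiments": len(sets),
            "n_empty": sum(1 for s in sets if not s),
            "ref_shared_mean": float(np.mean(ref_fracs)) if ref_fracs else None,
            "multi_shared_mean": (float(np.mean(multi_fracs))
                                  if multi_fracs else None),
        }
        per_pri[pri] = entry
        if entry["ref_shared_mean"] is not None:
            ref_means.append(entry["ref_shared_mean"])
        if entry["multi_shared_mean"] is not None:
            multi_means.append(entry["multi_shared_mean"])
    return {
        "per_pri": per_pri,
        "min_other": min_other,
        "ref_shared_mean": float(np.mean(ref_means)) if ref_means else None,
        "multi_shared_mean": float(np.mean(multi_means)) if multi_means else None,
    }
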