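"""Target-set enrichment and pri- vs mature-miRNA correlation.

The enrichment question: given a universe of N consistent mRNAs of which M
are targets of a miRNA, and an associated set of n mRNAs containing m
targets, is m larger than chance?  The upper-tail hypergeometric probability

    P(X >= m) = sum_{k=m}^{n} C(M, k) C(N-M, n-k) / C(N, n)

is computed in log space (log-gamma binomials) because N in the thousands
overflows factorials.  FDR control uses the standard Benjamini-Hochberg
step-up rule; two-group comparisons use the Mann-Whitney U test with an
exact small-sample path.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .containers import ConfigError, ExpressionMatrix, ValidationError
from .evaluate import correlation_pvalue

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hypergeometric upper tail
# ---------------------------------------------------------------------------

def _log_comb(x: int, y: int) -> float:
    return float(gammaln(x + 1) - gammaln(y + 1) - gammaln(x - y + 1))


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Exact P(X >= m) for X hypergeometric(N, M, n), in log space.

    Infeasible terms (k > M or n - k > N - M) contribute zero.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric inputs N={N}, M={M}, n={n}")
    if not (0 <= m <= min(n, M)):
        raise ValidationError(
            f"observed overlap m={m} outside [0, min(n={n}, M={M})]"
        )
    if m <= max(0, n - (N - M)):
        return 1.0  # P(X >= m) covers the whole feasible range
    k_lo = max(m, 0, n - (N - M))
    k_hi = min(n, M)
    if k_lo > k_hi:
        return 1.0 if m <= max(0, n - (N - M)) else 0.0
    log_denom = _log_comb(N, n)
    log_terms = [
        _log_comb(M, k) + _log_comb(N - M, n - k) - log_denom
        for k in range(k_lo, k_hi + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class EnrichmentRecord:
    """Hypergeometric enrichment of target genes in one associated set."""

    pri_mirna_id: str
    N: int              # universe size
    M: int              # target genes in the universe
    n: int              # associated-set size
    m: int              # targets among the associated genes
    p_hyper: float | None
    frac_assoc_in_targets: float | None   # m / n
    frac_targets_in_assoc: float | None   # m / M
    flagged: bool = False


def enrichment_report(assoc: dict[str, set], targets: dict[str, set],
                      universe: set[str], p_cutoff: float = 0.01) -> tuple[
                          list[EnrichmentRecord], dict]:
    """Per-miRNA hypergeometric enrichment of targets in associated genes.

    Gene sets are intersected with the universe first (dropped ids logged).
    The summary reports the mean of both overlap fractions and how many
    miRNAs have p > ``p_cutoff`` (the 'not enriched' count).
    """
    universe = set(universe)
    N = len(universe)
    if N == 0:
        raise ValidationError("empty universe")
    records: list[EnrichmentRecord] = []
    n_dropped = 0
    for pri in sorted(assoc):
        a_raw = set(assoc[pri]) if not hasattr(assoc[pri], "gene_ids") \
            else assoc[pri].gene_ids
        t_raw = set(targets.get(pri, set()))
        a = a_raw & universe
        t = t_raw & universe
        n_dropped += len(a_raw - universe) + len(t_raw - universe)
        n, M, m = len(a), len(t), len(a & t)
        if n == 0:
            records.append(EnrichmentRecord(pri, N, M, n, m, None, None,
                                            m / M if M else None, flagged=True))
            continue
        records.append(EnrichmentRecord(
            pri, N, M, n, m,
            p_hyper=hypergeom_tail(N, M, n, m),
            frac_assoc_in_targets=m / n,
            frac_targets_in_assoc=m / M if M else None,
        ))
    if n_dropped:
        logger.info("enrichment_report: %d gene ids outside the universe "
                    "dropped", n_dropped)
    ok = [r for r in records if not r.flagged]
    pvals = [r.p_hyper for r in ok]
    summary = {
        "n_mirnas": len(records),
        "n_flagged": len(records) - len(ok),
        "mean_frac_assoc_in_targets": (
            float(np.mean([r.frac_assoc_in_targets for r in ok])) if ok else None),
        "mean_frac_targets_in_assoc": (
            float(np.mean([r.frac_targets_in_assoc for r in ok
                           if r.frac_targets_in_assoc is not None]))
            if ok else None),
        "p_cutoff": p_cutoff,
        "n_not_enriched": int(sum(p > p_cutoff for p in pvals)),
        "p_10th_percentile": (float(np.percentile(pvals, 10)) if pvals else None),
    }
    return records, summary


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Standard BH step-up: rejection flags and adjusted p-values.

    Sort ascending, find the largest i with p_(i) <= (i/m) q and reject all
    ranks <= i; adjusted values are the monotone cumulative minimum of
    p_(i) * m / i from the largest rank down.  Output is in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q <= 1:
        raise ConfigError(f"q must lie in (0, 1], got {q}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.nonzero(ranked <= thresholds)[0]
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing[-1] + 1] = True
    adjusted_sorted = np.minimum.accumulate(
        (ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adjusted_sorted
    return reject, adjusted


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

#: largest pooled size for which the exact null distribution is enumerated
EXACT_LIMIT = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j, ties 1/2."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(a, b, alternative: str = "two_sided") -> float:
    """Mann-Whitney U test p-value.

    Exact enumeration of all C(n1+n2, n1) group assignments when the pooled
    sample is small (<= 12) and tie-free; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    u = _u_statistic(a, b)
    if no_ties and n1 + n2 <= EXACT_LIMIT:
        return _exact_mw_pvalue(pooled, n1, u, alternative)
    return _normal_mw_pvalue(pooled, n1, n2, u, alternative)


def _exact_mw_pvalue(pooled: np.ndarray, n1: int, u_obs: float,
                     alternative: str) -> float:
    total = 0
    n_ge = 0
    n_le = 0
    idx = range(pooled.size)
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(comb)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        n_ge += u >= u_obs
        n_le += u <= u_obs
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    return min(1.0, 2.0 * min(n_ge, n_le) / total)


def _normal_mw_pvalue(pooled: np.ndarray, n1: int, n2: int, u_obs: float,
                      alternative: str) -> float:
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0  # all values identical: no evidence either way
    sd = math.sqrt(var_u)

    def upper(u):
        return float(stats.norm.sf((u - mean_u - 0.5) / sd))

    def lower(u):
        return float(stats.norm.cdf((u - mean_u + 0.5) / sd))

    if alternative == "greater":
        return upper(u_obs)
    if alternative == "less":
        return lower(u_obs)
    return min(1.0, 2.0 * min(upper(u_obs), lower(u_obs)))


# ---------------------------------------------------------------------------
# pri-miRNA vs mature-miRNA correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriMatureRecord:
    """Best pri-to-mature expression correlation for one pri-miRNA."""

    pri_mirna_id: str
    best_mature_id: str | None
    max_pearson: float | None
    max_spearman: float | None
    n: int
    p_pearson: float | None
    p_spearman: float | None
    low_correlation: bool | None   # not significant at the given FDR level
    flagged: bool = False          # no mapped mature miRNA


def pri_mature_correlation(pri_expr: ExpressionMatrix,
                           mature_expr: ExpressionMatrix,
                           pri_to_mature: dict[str, list[str]],
                           fdr_q: float = 0.01, sided: str = "one",
                           active_sd: float = 3.0) -> tuple[
                               list[PriMatureRecord], dict]:
    """Max correlation of each pri-miRNA with its mature miRNAs, with FDR.

    One pri-miRNA may produce several mature miRNAs; the largest correlation
    counts.  BH over the per-pri Pearson p-values at ``fdr_q`` labels the
    non-significant pri-miRNAs "low correlation".  The summary also compares
    (two-sided Mann-Whitney) the correlations of the high-expression /
    high-variance pri-miRNAs (expression sd > ``active_sd``) against the rest.
    """
    if pri_expr.sample_ids != mature_expr.sample_ids:
        raise ValidationError("pri and mature matrices disagree on samples")
    n = len(pri_expr.sample_ids)
    mature_index = {g: i for i, g in enumerate(mature_expr.gene_ids)}
    m_vals = mature_expr.values
    p_vals = pri_expr.values

    records: list[PriMatureRecord] = []
    for gi, pri in enumerate(pri_expr.gene_ids):
        matures = [m for m in pri_to_mature.get(pri, []) if m in mature_index]
        if not matures:
            records.append(PriMatureRecord(pri, None, None, None, n, None,
                                           None, None, flagged=True))
            continue
        y = p_vals[gi]
        best_r, best_rho, best_id = -np.inf, -np.inf, None
        for mid in matures:
            x = m_vals[mature_index[mid]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = float(np.clip(np.corrcoef(y, x)[0, 1], -1, 1))
            rho = float(np.clip(stats.spearmanr(y, x).statistic, -1, 1))
            if r > best_r:
                best_r, best_id = r, mid
            best_rho = max(best_rho, rho)
        if best_id is None:
            records.append(PriMatureRecord(pri, None, None, None, n, None,
                                           None, None, flagged=True))
            continue
        records.append(PriMatureRecord(
            pri, best_id, best_r, best_rho, n,
            correlation_pvalue(best_r, n, sided),
            correlation_pvalue(best_rho, n, sided),
            low_correlation=None,
        ))

    scored = [r for r in records if not r.flagged]
    if scored:
        reject, _ = bh_fdr([r.p_pearson for r in scored], q=fdr_q)
        by_id = {r.pri_mirna_id: bool(rej) for r, rej in zip(scored, reject)}
        records = [
            r if r.flagged else PriMatureRecord(
                r.pri_mirna_id, r.best_mature_id, r.max_pearson,
                r.max_spearman, r.n, r.p_pearson, r.p_spearman,
                low_correlation=not by_id[r.pri_mirna_id],
            )
            for r in records
        ]
        scored = [r for r in records if not r.flagged]

    low_frac = (sum(r.low_correlation for r in scored) / len(scored)
                if scored else None)
    sd = {g: float(v) for g, v in zip(pri_expr.gene_ids,
                                      p_vals.std(axis=1))}
    active = [r.max_pearson for r in scored if sd[r.pri_mirna_id] > active_sd]
    rest = [r.max_pearson for r in scored if sd[r.pri_mirna_id] <= active_sd]
    mw_p = (mann_whitney_u(active, rest, alternative="two_sided")
            if active and rest else None)
    summary = {
        "n_pri": len(records),
        "n_flagged": len(records) - len(scored),
        "fdr_q": fdr_q,
        "low_correlation_fraction": low_frac,
        "active_sd": active_sd,
        "mann_whitney_active_vs_rest_p": mw_p,
        "max_pearson": {
            "min": float(min((r.max_pearson for r in scored), default=np.nan)),
            "max": float(max((r.max_pearson for r in scored), default=np.nan)),
        },
    }
    return records, summary
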