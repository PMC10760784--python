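"""Gene selection rules applied before modeling.

Three rules:

* activity: drop pri-miRNAs with zero expression in more than a fraction
  (default 80%) of samples — genes inactive in most conditions cannot be
  modeled;
* cross-platform consistency: keep transcripts whose expression ranks agree
  between two platforms (Spearman > 0.75 across matched samples), one
  transcript per gene (the one with the largest correlation);
* proximal exclusion: for each pri-miRNA, drop mRNA predictors whose TSS
  lies within 100 bp of the pri-miRNA TSS — their CAGE signal is the same
  peak neighborhood, so they would predict the response trivially.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, TssRecord, ValidationError

logger = logging.getLogger(__name__)


def activity_filter(expr: ExpressionMatrix,
                    max_zero_frac: float = 0.8) -> ExpressionMatrix:
    """Keep rows whose zero fraction is <= max_zero_frac (strictly-greater
    rows are removed); columns are untouched.

    Idempotent: re-applying the filter changes nothing.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValidationError("activity_filter: empty expression matrix")
    zero_frac = (expr.values == 0.0).mean(axis=1)
    keep = zero_frac <= max_zero_frac
    removed = int((~keep).sum())
    if removed:
        logger.info("activity_filter: removed %d of %d genes "
                    "(zero fraction > %.2f)", removed, expr.shape[0],
                    max_zero_frac)
    return ExpressionMatrix(expr.data.loc[keep], transform=expr.transform)


@dataclass(frozen=True)
class ConsistencyRecord:
    """Cross-platform agreement of one transcript."""

    transcript_id: str
    gene_id: str
    cross_platform_spearman: float
    selected: bool


def consistency_filter(platform_a: ExpressionMatrix,
                       platform_b: ExpressionMatrix,
                       transcript_to_gene: dict[str, str] | None = None,
                       rho_min: float = 0.75) -> list[ConsistencyRecord]:
    """Mark transcripts consistent between two platforms; pick one per gene.

    Spearman correlation (average ranks on ties) is computed per transcript
    across the matched samples, which must be identical and identically
    ordered in both matrices.  Transcripts with rho > rho_min are consistent;
    per gene, the consistent transcript with the largest rho is selected.
    """
    if platform_a.sample_ids != platform_b.sample_ids:
        raise ValidationError(
            "consistency_filter: platforms disagree on the matched sample set"
        )
    if len(platform_a.sample_ids) < 5:
        raise ValidationError("consistency_filter: need >= 5 matched samples")
    shared = [t for t in platform_a.gene_ids if t in set(platform_b.gene_ids)]
    if not shared:
        raise ValidationError("consistency_filter: no shared transcripts")
    if transcript_to_gene is None:
        transcript_to_gene = {t: t for t in shared}

    a = platform_a.subset_genes(shared).values
    b = platform_b.subset_genes(shared).values
    records: list[ConsistencyRecord] = []
    rho_by_transcript: dict[str, float] = {}
    for i, t in enumerate(shared):
        if np.ptp(a[i]) == 0 or np.ptp(b[i]) == 0:
            rho = np.nan  # constant on one platform: undefined, not consistent
        else:
            rho = float(stats.spearmanr(a[i], b[i]).statistic)
        rho_by_transcript[t] = rho

    # per gene keep the consistent transcript with the largest rho
    best: dict[str, str] = {}
    for t in shared:
        rho = rho_by_transcript[t]
        if not np.isfinite(rho) or rho <= rho_min:
            continue
        g = transcript_to_gene.get(t, t)
        if g not in best or rho > rho_by_transcript[best[g]]:
            best[g] = t
    selected = set(best.values())

    for t in shared:
        rho = rho_by_transcript[t]
        records.append(ConsistencyRecord(
            transcript_id=t,
            gene_id=transcript_to_gene.get(t, t),
            cross_platform_spearman=float(rho) if np.isfinite(rho) else np.nan,
            selected=t in selected,
        ))
    logger.info("consistency_filter: %d of %d transcripts selected "
                "(rho > %.2f, one per gene)", len(selected), len(shared), rho_min)
    return records


def selected_genes(records: list[ConsistencyRecord]) -> list[str]:
    """Gene ids of the selected (consistent, best-per-gene) transcripts."""
    return [r.gene_id for r in records if r.selected]


def proximal_exclusion(mirna_tss: TssRecord, mrna_tss: list[TssRecord],
                       max_dist: int = 100) -> list[str]:
    """mRNAs whose TSS lies within max_dist bp (inclusive) of the miRNA TSS.

    Proximity is same-chromosome absolute distance; strand is ignored.  The
    returned genes are to be dropped from this miRNA's predictor set only.
    """
    return [
        t.gene_id for t in mrna_tss
        if t.chrom == mirna_tss.chrom and abs(t.pos - mirna_tss.pos) <= max_dist
    ]


def proximal_exclusion_map(mirna_tss: list[TssRecord],
                           mrna_tss: list[TssRecord],
                           max_dist: int = 100) -> dict[str, list[str]]:
    """Per-miRNA exclusion lists (only miRNAs with exclusions appear)."""
    out: dict[str, list[str]] = {}
    for mt in mirna_tss:
        excluded = proximal_exclusion(mt, mrna_tss, max_dist=max_dist)
        if excluded:
            out[mt.gene_id] = excluded
    return out
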