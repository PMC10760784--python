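"""Synthetic CAGE worlds with planted structure.

Every downstream stage (quantification, filtering, sparse modeling,
cross-validation, enrichment) can be exercised against a world whose ground
truth is known:

* mRNA expression is zero-inflated log-normal TPM — heavy right tail like
  CAGE tag counts, with an excess of exact zeros for inactive genes;
* each pri-miRNA's expression is a sparse non-negative linear combination of
  a planted support of mRNAs plus Gaussian noise, clamped at zero (TPM is
  non-negative);
* CAGE peaks (1-3 per gene) are placed inside each TSS neighborhood so that
  the per-sample maximum over a gene's peaks reconstructs its expression;
* samples carry group labels (repeated samples of the same cell type) used
  for cross-validation deduplication;
* mature-miRNA tracks are scaled pri-miRNA expression plus independent noise
  calibrated to a requested Pearson correlation;
* target-gene sets are random draws from the mRNA universe, so targets are
  *not* enriched in the planted support.

What this generator does not emulate: read-level CAGE tags, sequencing
error, genome sequence, or the mean-variance relationship of real CAGE
libraries; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    ExpressionMatrix,
    PeakTable,
    SampleTable,
    TssRecord,
    ValidationError,
)

#: spacing between neighboring gene TSSs; far beyond any quantification
#: window or proximal-exclusion distance so genes never cross-talk unless
#: a proximal pair is planted deliberately
GENE_SPACING = 10_000

#: genes are distributed round-robin over a few chromosomes
CHROMS = ("chr1", "chr2", "chr3")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of a synthetic CAGE world.

    The defaults describe a small but realistic desk-scale study: a few
    hundred samples of a few dozen cell types, a few hundred mRNAs, and
    pri-miRNAs each driven by a planted support of 10 mRNAs at a
    signal-to-noise ratio near R^2 = 0.8.
    """

    n_samples: int = 120
    n_mrnas: int = 150
    n_primirnas: int = 5
    support_size: int = 10
    coef_scale: float = 1.0
    noise_sd: float = 1.0
    target_r2: float | None = 0.8  # overrides noise_sd per pri-miRNA when set
    zero_inflation: float = 0.3
    n_groups: int = 40
    shared_support_frac: float = 0.0
    log_mean: float = 1.0   # mu of the log-normal TPM base distribution
    log_sd: float = 1.0     # sigma of the log-normal TPM base distribution
    mature_per_pri: int = 2
    mature_corr_low: float = 0.15
    mature_corr_high: float = 0.9
    frac_low_corr: float = 0.5  # fraction of pri-miRNAs with low mature corr
    target_set_size: int = 20
    n_proximal_pairs: int = 0   # mRNA TSSs planted within 100 bp of a miRNA TSS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size > self.n_mrnas:
            raise ConfigError(
                f"support_size={self.support_size} exceeds n_mrnas={self.n_mrnas}"
            )
        if self.n_groups > self.n_samples:
            raise ConfigError("n_groups cannot exceed n_samples")
        for name in ("zero_inflation", "shared_support_frac", "frac_low_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("coef_scale", "log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.target_r2 is not None and not 0.0 < self.target_r2 < 1.0:
            raise ConfigError("target_r2 must lie in (0, 1)")
        if self.n_proximal_pairs > min(self.n_primirnas, self.n_mrnas):
            raise ConfigError("n_proximal_pairs exceeds available genes")


@dataclass
class TruthTable:
    """Planted parameters of a synthetic world, keyed by gene id."""

    support: dict[str, list[str]]          # pri-miRNA -> planted mRNA ids
    coefficients: dict[str, dict[str, float]]
    noise_sd: dict[str, float]
    mature_target_corr: dict[str, float]   # mature id -> requested Pearson r

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticWorld:
    config: SynthConfig
    peak_table: PeakTable
    mirna_tss: list[TssRecord]
    mrna_tss: list[TssRecord]
    cage_matrix: ExpressionMatrix          # pri-miRNA + mRNA rows, raw TPM
    sample_table: SampleTable
    mature_matrix: ExpressionMatrix
    pri_to_mature: dict[str, list[str]]
    target_sets: dict[str, set[str]] = field(default_factory=dict)
    truth: TruthTable = None

    @property
    def mrna_ids(self) -> list[str]:
        return [t.gene_id for t in self.mrna_tss]

    @property
    def mirna_ids(self) -> list[str]:
        return [t.gene_id for t in self.mirna_tss]

    def mrna_matrix(self) -> ExpressionMatrix:
        return self.cage_matrix.subset_genes(self.mrna_ids)

    def mirna_matrix(self) -> ExpressionMatrix:
        return self.cage_matrix.subset_genes(self.mirna_ids)


def _lognormal_tpm(rng, shape, config: SynthConfig) -> np.ndarray:
    """Zero-inflated log-normal draws on the TPM scale."""
    x = np.exp(rng.normal(config.log_mean, config.log_sd, size=shape))
    if config.zero_inflation > 0:
        x[rng.random(shape) < config.zero_inflation] = 0.0
    return x


def _place_tss(gene_ids: list[str], rng) -> list[tuple[str, int, str]]:
    """Lay gene TSSs along chromosomes, GENE_SPACING apart, random strand."""
    out = []
    for i, gid in enumerate(gene_ids):
        chrom = CHROMS[i % len(CHROMS)]
        pos = GENE_SPACING * (1 + i // len(CHROMS))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((chrom, pos, strand))
    return out


def generate_world(config: SynthConfig) -> SyntheticWorld:
    """Generate a complete synthetic CAGE world; bit-identical given a seed."""
    rng = np.random.default_rng(config.seed)

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    mrna_ids = [f"GENE{i:04d}" for i in range(config.n_mrnas)]
    mirna_ids = [f"MIR{i:03d}" for i in range(config.n_primirnas)]

    # --- mRNA expression -------------------------------------------------
    mrna = _lognormal_tpm(rng, (config.n_mrnas, config.n_samples), config)

    # --- planted sparse linear maps --------------------------------------
    n_shared = int(round(config.shared_support_frac * config.support_size))
    shared = rng.choice(config.n_mrnas, size=n_shared, replace=False) \
        if n_shared else np.array([], dtype=int)
    support: dict[str, list[str]] = {}
    coefficients: dict[str, dict[str, float]] = {}
    noise_sds: dict[str, float] = {}
    pri_rows = np.zeros((config.n_primirnas, config.n_samples))
    for gi, mir in enumerate(mirna_ids):
        pool = np.setdiff1d(np.arange(config.n_mrnas), shared)
        own = rng.choice(pool, size=config.support_size - n_shared, replace=False)
        idx = np.concatenate([shared, own]).astype(int)
        # positive coefficients bounded away from zero keep the planted
        # combination non-negative and identifiable
        coefs = rng.uniform(0.5, 1.5, size=config.support_size) * config.coef_scale
        signal = coefs @ mrna[idx]
        if config.target_r2 is not None:
            sd_sig = float(signal.std())
            nsd = sd_sig * np.sqrt((1.0 - config.target_r2) / config.target_r2) \
                if sd_sig > 0 else config.noise_sd
        else:
            nsd = config.noise_sd
        pri_rows[gi] = np.maximum(signal + rng.normal(0.0, nsd, config.n_samples), 0.0)
        support[mir] = [mrna_ids[j] for j in idx]
        coefficients[mir] = {mrna_ids[j]: float(c) for j, c in zip(idx, coefs)}
        noise_sds[mir] = float(nsd)

    cage = pd.DataFrame(
        np.vstack([pri_rows, mrna]),
        index=mirna_ids + mrna_ids,
        columns=sample_ids,
    )
    cage_matrix = ExpressionMatrix(cage, transform="raw_tpm")

    # --- TSS annotation (optionally with planted proximal pairs) ---------
    mir_placed = _place_tss(mirna_ids, rng)
    mrna_placed = _place_tss(mrna_ids, rng)
    # shift mRNA coordinates to the second half of each chromosome
    offset = GENE_SPACING * (2 + config.n_primirnas)
    mrna_placed = [(c, p + offset, s) for c, p, s in mrna_placed]
    for k in range(config.n_proximal_pairs):
        mc, mp, _ = mir_placed[k]
        dist = int(rng.integers(10, 100))
        chrom, _, strand = mrna_placed[k]
        mrna_placed[k] = (mc, mp + dist, strand)
    mirna_tss = [TssRecord(g, "pri-miRNA", c, p, s)
                 for g, (c, p, s) in zip(mirna_ids, mir_placed)]
    mrna_tss = [TssRecord(g, "mRNA", c, p, s)
                for g, (c, p, s) in zip(mrna_ids, mrna_placed)]

    # --- peaks whose per-sample maxima reconstruct the matrix ------------
    peak_table = _peaks_from_matrix(cage_matrix, mirna_tss + mrna_tss, rng)

    # --- sample groups (contiguous blocks of repeated cell types) --------
    block_ids = np.array_split(np.arange(config.n_samples), config.n_groups)
    group = np.empty(config.n_samples, dtype=object)
    for g, idxs in enumerate(block_ids):
        group[idxs] = f"group{g:03d}"
    sample_table = SampleTable(pd.DataFrame(
        {"group": group, "platform": "cage"},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    # --- mature miRNA tracks ---------------------------------------------
    n_low = int(round(config.frac_low_corr * config.n_primirnas))
    mature_rows, mature_ids = [], []
    pri_to_mature: dict[str, list[str]] = {}
    mature_corr: dict[str, float] = {}
    for gi, mir in enumerate(mirna_ids):
        rho = config.mature_corr_low if gi < n_low else config.mature_corr_high
        pri_to_mature[mir] = []
        for k in range(config.mature_per_pri):
            mid = f"{mir}-mat{k}"
            pri = pri_rows[gi]
            sd = float(pri.std())
            if rho <= 0.0 or sd == 0.0:
                # uncorrelated track: independent draws from the TPM family
                mature_rows.append(
                    _lognormal_tpm(rng, (config.n_samples,), config))
            elif rho < 1.0:
                noise = rng.normal(0.0, sd * np.sqrt(1.0 / rho**2 - 1.0),
                                   config.n_samples)
                mature_rows.append(np.maximum(pri + noise, 0.0))
            else:
                mature_rows.append(pri.copy())
            mature_ids.append(mid)
            pri_to_mature[mir].append(mid)
            mature_corr[mid] = float(rho)
    mature_matrix = ExpressionMatrix(
        pd.DataFrame(np.array(mature_rows), index=mature_ids, columns=sample_ids),
        transform="raw_tpm",
    )

    # --- random target sets (null with respect to the planted support) ---
    target_sets = {
        mir: set(rng.choice(mrna_ids, size=min(config.target_set_size,
                                               config.n_mrnas),
                            replace=False).tolist())
        for mir in mirna_ids
    }

    truth = TruthTable(support=support, coefficients=coefficients,
                       noise_sd=noise_sds, mature_target_corr=mature_corr)
    return SyntheticWorld(
        config=config, peak_table=peak_table, mirna_tss=mirna_tss,
        mrna_tss=mrna_tss, cage_matrix=cage_matrix, sample_table=sample_table,
        mature_matrix=mature_matrix, pri_to_mature=pri_to_mature,
        target_sets=target_sets, truth=truth,
    )


def _peaks_from_matrix(expr: ExpressionMatrix, tss: list[TssRecord],
                       rng) -> PeakTable:
    """Place 1-3 peaks per gene inside its +/-50 bp TSS neighborhood.

    The first peak carries the gene's expression verbatim; extra peaks are
    scaled down by per-sample factors in [0, 1), so the per-sample maximum
    over a gene's peaks equals the expression matrix exactly.
    """
    by_id = {t.gene_id: t for t in tss}
    rows, tpm_rows = [], []
    for gid in expr.gene_ids:
        t = by_id[gid]
        n_peaks = int(rng.integers(1, 4))
        values = expr.data.loc[gid].to_numpy()
        offsets = rng.choice(np.arange(-50, 41, 10), size=n_peaks, replace=False)
        for k in range(n_peaks):
            start = max(t.pos + int(offsets[k]), 0)
            rows.append({
                "peak_id": f"{gid}_pk{k}", "chrom": t.chrom,
                "start": start, "end": start + 10, "strand": t.strand,
            })
            if k == 0:
                tpm_rows.append(values)
            else:
                tpm_rows.append(values * rng.uniform(0.0, 0.999,
                                                     size=values.shape))
    intervals = pd.DataFrame(rows).set_index("peak_id")
    tpm = pd.DataFrame(np.array(tpm_rows), index=intervals.index,
                       columns=expr.sample_ids)
    return PeakTable(intervals=intervals, tpm=tpm)


def world_truth(world: SyntheticWorld) -> TruthTable:
    """Pure accessor returning the planted parameters verbatim."""
    return world.truth


def generate_matched_platform_pair(
    world: SyntheticWorld, n_matched: int, rho_consistent: float,
    frac_consistent: float, seed: int,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two-platform expression over a shared subset of samples.

    Emulates matched CAGE / RNA-seq measurements: a designated fraction of
    genes is "consistent" — its platform-2 values share a latent Gaussian
    with platform 1 at correlation ``rho_consistent`` (so their cross-platform
    Spearman concentrates near the bivariate-normal value ~ (6/pi)
    asin(rho/2)); the remaining genes are independently resampled on
    platform 2, giving null cross-platform correlation.
    """
    if not -1.0 <= rho_consistent <= 1.0:
        raise ConfigError(f"rho_consistent={rho_consistent} outside [-1, 1]")
    if not 0.0 <= frac_consistent <= 1.0:
        raise ConfigError("frac_consistent outside [0, 1]")
    if n_matched < 5:
        raise ValidationError("need at least 5 matched samples")
    if n_matched > world.config.n_samples:
        raise ValidationError("n_matched exceeds the world's sample count")

    rng = np.random.default_rng(seed)
    cfg = world.config
    mrna = world.mrna_matrix()
    sample_ids = mrna.sample_ids[:n_matched]
    gene_ids = mrna.gene_ids
    n_genes = len(gene_ids)

    # regenerate platform 1 from its latent normal so the copula is exact
    z1 = rng.standard_normal((n_genes, n_matched))
    a = rng.standard_normal((n_genes, n_matched))
    n_cons = int(round(frac_consistent * n_genes))
    consistent = np.zeros(n_genes, dtype=bool)
    if n_cons:
        consistent[rng.choice(n_genes, size=n_cons, replace=False)] = True

    z2 = np.where(consistent[:, None],
                  rho_consistent * z1 + np.sqrt(max(0.0, 1 - rho_consistent**2)) * a,
                  rng.standard_normal((n_genes, n_matched)))

    def to_tpm(z):
        x = np.exp(cfg.log_mean + cfg.log_sd * z)
        return x

    p1 = pd.DataFrame(to_tpm(z1), index=gene_ids, columns=sample_ids)
    p2 = pd.DataFrame(to_tpm(z2), index=gene_ids, columns=sample_ids)
    p1.attrs["consistent_genes"] = [g for g, c in zip(gene_ids, consistent) if c]
    return (ExpressionMatrix(p1, transform="raw_tpm"),
            ExpressionMatrix(p2, transform="raw_tpm"))
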