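"""End-to-end orchestration: simulate/load -> quantify -> filter -> fit ->
evaluate (+ cross-validation and permutation controls) -> enrich -> primature.

One global seed deterministically derives a per-stage seed (CRC32 of the
stage name mixed with the global seed), so any stage can be rerun in
isolation and a rerun with the same config reproduces every output
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import ExpressionMatrix, PrimirError, ValidationError
from .evaluate import (
    correlation_report,
    crossval,
    permutation_control,
    shared_fraction,
)
from .enrich import enrichment_report, pri_mature_correlation
from .filters import (
    activity_filter,
    consistency_filter,
    proximal_exclusion_map,
    selected_genes,
)
from .model import (
    associated_genes,
    default_alpha_grid,
    fit_pri_mirna,
    predict,
    select_alpha,
)
from .quantify import QuantConfig, quantify
from .synth import SynthConfig, generate_matched_platform_pair, generate_world

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    With ``synth`` set, inputs are simulated; otherwise ``inputs`` must map
    the keys peaks / mirna_tss / mrna_tss / samples / mature /
    pri_to_mature / targets (and optionally platform_a / platform_b for the
    consistency filter) to file paths.
    """

    outdir: str = "primir_run"
    seed: int = 0
    synth: SynthConfig | None = field(default_factory=SynthConfig)
    inputs: dict | None = None
    # quantification; the synthetic generator plants a linear model on the
    # TPM scale, so the pipeline models raw-scale expression by default
    quant: QuantConfig = field(
        default_factory=lambda: QuantConfig(log_transform=False))
    # filters
    max_zero_frac: float = 0.8
    rho_min: float = 0.75
    max_dist: int = 100
    n_matched: int = 50
    rho_consistent: float = 0.95
    frac_consistent: float = 1.0
    use_consistency: bool = True
    # fitting
    alpha: float | None = None      # fixed-penalty override
    alpha_rule: str = "sparse"
    cv_slack: float = 1.5
    k_folds: int = 5
    n_alphas: int = 16
    grid_eps: float = 1e-2
    tol: float = 1e-5
    max_sweeps: int = 500
    zero_tol: float = 1e-8
    # evaluation
    n_experiments: int = 10
    n_cv_folds: int = 2
    sided: str = "one"
    fdr_q: float = 0.01
    run_controls: bool = True
    min_shared_other: int = 4

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = SynthConfig(**d["synth"])
        if d.get("quant") is not None and not isinstance(d["quant"], QuantConfig):
            d["quant"] = QuantConfig(**d["quant"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def _associated_tsv(sets: dict, path) -> None:
    rows = [
        {"pri_mirna_id": pri, "gene_id": g, "coefficient": w}
        for pri in sorted(sets)
        for g, w in sorted(sets[pri].coefficients.items())
    ]
    pd.DataFrame(rows, columns=["pri_mirna_id", "gene_id", "coefficient"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.12g")


def _records_tsv(records, path) -> None:
    pd.DataFrame([asdict(r) if hasattr(r, "__dataclass_fields__") else r
                  for r in records]).to_csv(path, sep="\t", index=False,
                                            float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to the outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer, *args) -> Path:
        path = outdir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(*args, path)
        artifacts[name] = str(path)
        return path

    # ---- stage: simulate or load ---------------------------------------
    try:
        if config.synth is not None:
            synth_cfg = replace(config.synth,
                                seed=stage_seed(config.seed, "simulate"))
            world = generate_world(synth_cfg)
            peaks = world.peak_table
            mirna_tss, mrna_tss = world.mirna_tss, world.mrna_tss
            samples = world.sample_table
            mature = world.mature_matrix
            pri_to_mature = world.pri_to_mature
            targets = world.target_sets
            save("inputs/peaks.tsv", io.write_peak_table, peaks)
            save("inputs/mirna_tss.bed", io.write_tss_bed, mirna_tss)
            save("inputs/mrna_tss.bed", io.write_tss_bed, mrna_tss)
            save("inputs/samples.tsv", io.write_sample_table, samples)
            save("inputs/mature.tsv", io.write_expression_tsv, mature)
            save("inputs/pri_to_mature.tsv", io.write_pri_mature_map,
                 pri_to_mature)
            save("inputs/targets.tsv", io.write_target_sets, targets)
            save("inputs/truth.json", io.write_json, world.truth.to_dict())
        else:
            if not config.inputs:
                raise ValidationError("neither synth config nor input paths given")
            paths = config.inputs
            world = None
            peaks = io.read_peak_table(paths["peaks"])
            mirna_tss = io.read_tss_bed(paths["mirna_tss"], "pri-miRNA")
            mrna_tss = io.read_tss_bed(paths["mrna_tss"], "mRNA")
            samples = io.read_sample_table(paths["samples"])
            mature = io.read_expression_tsv(paths["mature"])
            pri_to_mature = io.read_pri_mature_map(paths["pri_to_mature"])
            targets = io.read_target_sets(paths["targets"])
    except PrimirError as err:
        raise PrimirError(f"stage simulate/load failed: {err}") from err

    samples.validate_samples(peaks.sample_ids)

    # ---- stage: quantify -------------------------------------------------
    try:
        expr_all = quantify(peaks, mirna_tss + mrna_tss, config.quant)
        mirna_expr = expr_all.subset_genes([t.gene_id for t in mirna_tss])
        mrna_expr = expr_all.subset_genes([t.gene_id for t in mrna_tss])
        save("quantify/mirna_expr.tsv", io.write_expression_tsv, mirna_expr)
        save("quantify/mrna_expr.tsv", io.write_expression_tsv, mrna_expr)
    except PrimirError as err:
        raise PrimirError(f"stage quantify failed: {err}") from err

    # ---- stage: filters --------------------------------------------------
    try:
        mirna_expr = activity_filter(mirna_expr, config.max_zero_frac)
        if mirna_expr.shape[0] == 0:
            raise ValidationError("no pri-miRNA passed the activity filter")
        save("filters/active_mirnas.txt", _write_gene_list,
             mirna_expr.gene_ids)

        if config.use_consistency:
            if config.synth is not None:
                pa, pb = generate_matched_platform_pair(
                    world, config.n_matched, config.rho_consistent,
                    config.frac_consistent,
                    seed=stage_seed(config.seed, "platforms"))
            elif config.inputs and "platform_a" in config.inputs:
                pa = io.read_expression_tsv(config.inputs["platform_a"])
                pb = io.read_expression_tsv(config.inputs["platform_b"])
            else:
                pa = pb = None
            if pa is not None:
                records = consistency_filter(pa, pb, rho_min=config.rho_min)
                save("filters/consistency.tsv", _records_tsv, records)
                consistent = [g for g in selected_genes(records)
                              if g in set(mrna_expr.gene_ids)]
                if not consistent:
                    raise ValidationError(
                        "consistency filter removed every mRNA; nothing left "
                        "to model (rho_min too strict?)")
                mrna_expr = mrna_expr.subset_genes(consistent)

        exclusions = proximal_exclusion_map(mirna_tss, mrna_tss,
                                            max_dist=config.max_dist)
        exclusions = {p: [g for g in genes if g in set(mrna_expr.gene_ids)]
                      for p, genes in exclusions.items()}
        exclusions = {p: genes for p, genes in exclusions.items() if genes}
        save("filters/exclusions.json", io.write_json, exclusions)
    except PrimirError as err:
        raise PrimirError(f"stage filters failed: {err}") from err

    # ---- stage: fit ------------------------------------------------------
    try:
        fit_seed = stage_seed(config.seed, "fit")
        mrna_ids = mrna_expr.gene_ids
        X_full = mrna_expr.values.T
        col_of = {g: j for j, g in enumerate(mrna_ids)}
        models, assoc_sets, alphas = {}, {}, {}
        for gi, pri in enumerate(mirna_expr.gene_ids):
            cols = np.array([col_of[g] for g in mrna_ids
                             if g not in set(exclusions.get(pri, []))])
            if cols.size == 0:
                raise ValidationError(
                    f"no predictors left for {pri} after exclusions")
            gene_subset = [mrna_ids[c] for c in cols]
            X = X_full[:, cols]
            y = mirna_expr.values[gi]
            if config.alpha is not None:
                a = float(config.alpha)
            else:
                mu, sd = X.mean(axis=0), X.std(axis=0)
                keep = sd > 0
                Xs = (X[:, keep] - mu[keep]) / sd[keep]
                ys = (y - y.mean()) / y.std() if y.std() > 0 else y - y.mean()
                grid = np.sort(default_alpha_grid(
                    Xs, ys, n_alphas=config.n_alphas, eps=config.grid_eps))
                a = select_alpha(Xs, ys, grid, k_folds=config.k_folds,
                                 seed=fit_seed + gi, tol=max(config.tol, 1e-4),
                                 max_sweeps=min(config.max_sweeps, 300),
                                 rule=config.alpha_rule,
                                 cv_slack=config.cv_slack)
            m = fit_pri_mirna(pri, X, gene_subset, y, alpha=a,
                              tol=config.tol, max_sweeps=config.max_sweeps)
            models[pri] = m
            alphas[pri] = a
            assoc_sets[pri] = associated_genes(m, zero_tol=config.zero_tol)
        save("fit/alphas.json", io.write_json, alphas)
        save("fit/associated.tsv", _associated_tsv, assoc_sets)
        save("fit/models.json", io.write_json, {
            pri: {"alpha": m.alpha, "n_sweeps": m.n_sweeps,
                  "converged": m.converged, "objective": m.objective,
                  "kkt_violation": m.kkt_violation,
                  "n_associated": len(assoc_sets[pri])}
            for pri, m in models.items()
        })
    except PrimirError as err:
        raise PrimirError(f"stage fit failed: {err}") from err

    # ---- stage: evaluate -------------------------------------------------
    try:
        pred_rows = []
        for gi, pri in enumerate(mirna_expr.gene_ids):
            cols = np.array([col_of[g] for g in mrna_ids
                             if g not in set(exclusions.get(pri, []))])
            pred_rows.append(predict(models[pri], X_full[:, cols],
                                     destandardize=True))
        # linear predictions can dip below zero, so never label them raw_tpm
        predicted = ExpressionMatrix(
            pd.DataFrame(np.array(pred_rows), index=mirna_expr.gene_ids,
                         columns=mirna_expr.sample_ids),
            transform="log1p",
        )
        per_gene, pg_summary = correlation_report(
            mirna_expr, predicted, axis="per_gene", sided=config.sided)
        per_sample, ps_summary = correlation_report(
            mirna_expr, predicted, axis="per_sample", sided=config.sided)
        save("evaluate/per_gene.tsv", _records_tsv, per_gene)
        save("evaluate/per_sample.tsv", _records_tsv, per_sample)
        save("evaluate/summary.json", io.write_json,
             {"per_gene": pg_summary, "per_sample": ps_summary})

        groups = samples.groups()
        cv_seed = stage_seed(config.seed, "crossval")
        report = crossval(mrna_expr, mirna_expr, groups,
                          n_experiments=config.n_experiments,
                          n_folds=config.n_cv_folds, seed=cv_seed,
                          alpha=alphas, tol=config.tol,
                          max_sweeps=config.max_sweeps,
                          exclusions=exclusions, zero_tol=config.zero_tol,
                          sided=config.sided)
        save("evaluate/cv_summary.json", io.write_json, report.summary())
        shared = shared_fraction(report.associated_by_experiment(),
                                 reference=assoc_sets,
                                 min_other=config.min_shared_other)
        save("evaluate/shared.json", io.write_json, shared)

        control_summaries = {}
        if config.run_controls:
            for mode in ("across_samples", "within_sample"):
                ctrl = permutation_control(
                    mrna_expr, mode, seed=stage_seed(config.seed, mode))
                ctrl_report = crossval(
                    ctrl, mirna_expr, groups,
                    n_experiments=config.n_experiments,
                    n_folds=config.n_cv_folds, seed=cv_seed, alpha=alphas,
                    tol=config.tol, max_sweeps=config.max_sweeps,
                    exclusions=exclusions, zero_tol=config.zero_tol,
                    sided=config.sided)
                control_summaries[mode] = ctrl_report.summary()
            save("evaluate/control_summaries.json", io.write_json,
                 control_summaries)
    except PrimirError as err:
        raise PrimirError(f"stage evaluate failed: {err}") from err

    # ---- stage: enrich ---------------------------------------------------
    try:
        universe = set(mrna_expr.gene_ids)
        assoc_plain = {p: s.gene_ids for p, s in assoc_sets.items()}
        records, summary = enrichment_report(assoc_plain, targets, universe)
        save("enrich/enrichment.tsv", _records_tsv, records)
        save("enrich/enrichment_summary.json", io.write_json, summary)
    except PrimirError as err:
        raise PrimirError(f"stage enrich failed: {err}") from err

    # ---- stage: primature -------------------------------------------------
    try:
        mature_sub = mature.subset_samples(mirna_expr.sample_ids)
        pm_records, pm_summary = pri_mature_correlation(
            mirna_expr, mature_sub, pri_to_mature, fdr_q=config.fdr_q,
            sided=config.sided)
        save("enrich/primature.tsv", _records_tsv, pm_records)
        save("enrich/primature_summary.json", io.write_json, pm_summary)
    except PrimirError as err:
        raise PrimirError(f"stage primature failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s)
                        for s in ("simulate", "platforms", "fit", "crossval",
                                  "across_samples", "within_sample")},
        "artifacts": artifacts,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
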