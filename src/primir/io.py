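"""Readers and writers for the plain-text formats the pipeline touches.

BED6 for TSS and peak locations, TSV for matrices / sample tables / target
sets, JSON for reports and simulation truth.  All coordinates stay 0-based
half-open; a TSS is written as a 1-bp interval (end = start + 1).

Floats are written with 17 significant digits (shortest exact double
representation or better), so write -> read round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PEAK_BED_COLUMNS,
    ExpressionMatrix,
    ParseError,
    PeakTable,
    SampleTable,
    TssRecord,
    ValidationError,
)

FLOAT_FORMAT = "%.17g"


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def _parse_bed6_line(line: str, path, lineno: int) -> tuple:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 6:
        raise ParseError(
            f"{path}:{lineno}: expected 6 tab-separated columns, got {len(fields)}"
        )
    chrom, start_s, end_s, name, score, strand = fields
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0 or start >= end:
        raise ValidationError(
            f"{path}:{lineno}: invalid interval [{start}, {end})"
        )
    if strand not in ("+", "-"):
        raise ParseError(f"{path}:{lineno}: strand must be '+' or '-'")
    return chrom, start, end, name, score, strand


def read_bed6(path) -> list[tuple]:
    """Read a BED6 file into (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed6_line(line, path, lineno))
    return out


def read_tss_bed(path, gene_class: str) -> list[TssRecord]:
    """Read TSS annotations: BED6 with end = start + 1; name is the gene id."""
    records = []
    for chrom, start, end, name, _score, strand in read_bed6(path):
        if end != start + 1:
            raise ValidationError(
                f"{path}: TSS intervals must be 1 bp wide, got [{start}, {end}) "
                f"for {name!r}"
            )
        records.append(
            TssRecord(gene_id=name, gene_class=gene_class, chrom=chrom,
                      pos=start, strand=strand)
        )
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate gene ids in TSS file")
    return records


def write_tss_bed(records: list[TssRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Peak tables (BED6 columns followed by per-sample TPM columns)
# ---------------------------------------------------------------------------

def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in PEAK_BED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: peak table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in PEAK_BED_COLUMNS]
    if not sample_cols:
        raise ParseError(f"{path}: peak table has no sample columns")
    if df["peak_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate peak ids")
    df = df.set_index("peak_id")
    intervals = df[["chrom", "start", "end", "strand"]].copy()
    tpm = df[sample_cols].astype(float)
    return PeakTable(intervals=intervals, tpm=tpm)


def write_peak_table(peaks: PeakTable, path) -> None:
    df = peaks.intervals.reset_index()
    df["score"] = 0
    df = df[PEAK_BED_COLUMNS]
    df = pd.concat([df, peaks.tpm.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path, transform: str = "raw_tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids {dups[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nan_new = bad.isna() & df[col].notna()
        if nan_new.any():
            row = df.index[nan_new.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
    return ExpressionMatrix(df.astype(float), transform=transform)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id",
                     float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Sample tables and target sets
# ---------------------------------------------------------------------------

def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "platform"):
        if col not in df.columns:
            raise ParseError(f"{path}: sample table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups[:5]}")
    return SampleTable(df.set_index("sample_id")[["group", "platform"]])


def write_sample_table(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index_label="sample_id")


def read_target_sets(path) -> dict[str, set[str]]:
    """Read miRNA -> target-gene sets from a TSV (mirna_id, gene_id, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "gene_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: target table missing column {col!r}")
    out: dict[str, set[str]] = {}
    for mirna, sub in df.groupby("mirna_id"):
        out[str(mirna)] = set(sub["gene_id"])
    return out


def write_target_sets(targets: dict[str, set[str]], path,
                      source: str = "custom") -> None:
    rows = [
        {"mirna_id": m, "gene_id": g, "source": source}
        for m in sorted(targets) for g in sorted(targets[m])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_pri_mature_map(path) -> dict[str, list[str]]:
    """Read the pri-miRNA -> mature miRNA mapping (columns pri_id, mature_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pri_id", "mature_id"):
        if col not in df.columns:
            raise ParseError(f"{path}: mapping missing column {col!r}")
    out: dict[str, list[str]] = {}
    for pri, sub in df.groupby("pri_id", sort=False):
        out[str(pri)] = list(sub["mature_id"])
    return out


def write_pri_mature_map(mapping: dict[str, list[str]], path) -> None:
    rows = [{"pri_id": p, "mature_id": m}
            for p in sorted(mapping) for m in mapping[p]]
    pd.DataFrame(rows, columns=["pri_id", "mature_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable,
                                     sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
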