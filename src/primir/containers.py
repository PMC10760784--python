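"""Core data containers shared by every pipeline stage.

Conventions pinned here once:

* genomic coordinates are 0-based half-open (BED); a TSS is a single
  stranded position (the ``start`` of a 1-bp BED interval);
* expression matrices are genes x samples with unique ids on both axes;
* raw CAGE expression is in TPM (tags per million) and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class PrimirError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PrimirError):
    """A file could not be parsed; message carries path and line number."""


class ValidationError(PrimirError):
    """Inputs violate a documented contract."""


class ConfigError(PrimirError):
    """A configuration value is out of its documented range."""


GENE_CLASSES = ("pri-miRNA", "mRNA")
TRANSFORMS = ("raw_tpm", "log1p", "standardized")


@dataclass(frozen=True)
class TssRecord:
    """A single transcription start site: one stranded genomic position."""

    gene_id: str
    gene_class: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValidationError(
                f"gene_class {self.gene_class!r} not in {GENE_CLASSES}"
            )
        if self.pos < 0:
            raise ValidationError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale ('transform') flag.

    ``transform`` records what the values mean: ``raw_tpm`` (non-negative
    CAGE TPM), ``log1p`` (log(1+TPM)) or ``standardized`` (per-gene mean 0,
    sd 1).  Validation of non-negativity only applies to ``raw_tpm``.
    """

    data: pd.DataFrame
    transform: str = "raw_tpm"

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"transform {self.transform!r} not in {TRANSFORMS}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.transform == "raw_tpm" and values.size and (values < 0).any():
            raise ValidationError("raw_tpm expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        return replace(self, data=self.data.loc[list(gene_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        return replace(self, data=self.data[list(sample_ids)])

    def log1p(self) -> "ExpressionMatrix":
        if self.transform != "raw_tpm":
            raise ValidationError(
                f"log1p only applies to raw_tpm matrices, got {self.transform!r}"
            )
        return ExpressionMatrix(np.log1p(self.data), transform="log1p")


#: column order of the interval part of a peak table
PEAK_BED_COLUMNS = ["chrom", "start", "end", "peak_id", "score", "strand"]


@dataclass
class PeakTable:
    """CAGE peaks: BED-style intervals plus a per-sample TPM matrix.

    ``intervals`` is indexed by peak_id with columns chrom/start/end/strand;
    ``tpm`` is indexed by the same peak ids with sample columns.
    """

    intervals: pd.DataFrame
    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intervals.index.has_duplicates:
            raise ValidationError("duplicate peak ids in interval table")
        if not self.intervals.index.equals(self.tpm.index):
            raise ValidationError("interval and TPM tables disagree on peak ids")
        if self.tpm.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in peak TPM matrix")
        starts = self.intervals["start"].to_numpy()
        ends = self.intervals["end"].to_numpy()
        if (starts < 0).any():
            raise ValidationError("peak start coordinates must be >= 0")
        if (starts >= ends).any():
            bad = self.intervals.index[starts >= ends].tolist()
            raise ValidationError(f"peak intervals with start >= end: {bad[:5]}")
        bad_strand = ~self.intervals["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValidationError("peak strands must be '+' or '-'")
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("peak TPM values must be non-negative")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.intervals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class SampleTable:
    """Sample metadata: per-sample group label (cell type) and platform."""

    table: pd.DataFrame  # index sample_id, columns group, platform

    def __post_init__(self) -> None:
        for col in ("group", "platform"):
            if col not in self.table.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self) -> dict[str, str]:
        return self.table["group"].to_dict()

    def validate_samples(self, sample_ids) -> None:
        """Check that every expression-matrix sample is annotated."""
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(
                f"samples absent from sample table: {missing[:10]}"
            )


@dataclass
class AssociatedGeneSet:
    """The mRNAs retained with nonzero coefficient for one pri-miRNA."""

    pri_mirna_id: str
    coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.coefficients)

    def __len__(self) -> int:
        return len(self.coefficients)
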