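"""Shared data model: genomic intervals, expression matrices, methylation tables.

All interval coordinates are 0-based half-open on the internal side; the
only place 1-based closed coordinates exist is at the GFF3 boundary in
:mod:`hybepi.io`.  Unstranded features carry strand ``"."`` and participate
in overlap tests on both strands.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}
FEATURE_CLASSES = {
    "gene", "exon", "intron", "TE", "lncRNA", "siRNA_cluster", "ACR",
    "phasiRNA_locus", "region",
}
GENERATIONS = {"maternal", "paternal", "hybrid", "insilico"}
UNITS = {"TPM", "RPM", "count"}
CONTEXTS = ("CG", "CHG", "CHH")


class ValidationError(ValueError):
    """Raised when an input record violates a data-model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware 0-based half-open locus.

    Parameters
    ----------
    chrom : str
        Sequence (chromosome/scaffold) name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    feature_id : str
        Identifier, unique within a collection.
    feature_class : str
        One of gene/exon/intron/TE/lncRNA/siRNA_cluster/ACR/phasiRNA_locus/region.
    parent : str or None
        Parent feature id (exons reference their gene), optional.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    feature_class: str = "region"
    parent: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.feature_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValidationError(f"unknown feature class {self.feature_class!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp overlap, strand-blind."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int | None:
        """Closest-edge distance in half-open coordinates; 0 if overlapping,
        None for different chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end

    def same_strand(self, other: "GenomicInterval") -> bool:
        """Unstranded matches everything."""
        if self.strand == "." or other.strand == ".":
            return True
        return self.strand == other.strand

    def opposite_strand(self, other: "GenomicInterval") -> bool:
        if self.strand == "." or other.strand == ".":
            return False
        return self.strand != other.strand


def validate_collection(intervals: Sequence[GenomicInterval]) -> None:
    """Enforce collection-level invariants: unique ids; exons of a gene are
    pairwise non-overlapping and lie inside the gene interval."""
    seen: dict[str, GenomicInterval] = {}
    for iv in intervals:
        if iv.feature_id in seen:
            raise ValidationError(f"duplicate feature_id {iv.feature_id!r}")
        seen[iv.feature_id] = iv
    by_parent: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        if iv.feature_class == "exon" and iv.parent is not None:
            by_parent.setdefault(iv.parent, []).append(iv)
    for parent_id, exons in by_parent.items():
        gene = seen.get(parent_id)
        exons = sorted(exons, key=lambda e: e.start)
        for i, ex in enumerate(exons):
            if gene is not None and not (gene.start <= ex.start and ex.end <= gene.end):
                raise ValidationError(
                    f"exon {ex.feature_id!r} extends outside gene {parent_id!r}"
                )
            if i and exons[i - 1].end > ex.start:
                raise ValidationError(
                    f"overlapping exons under gene {parent_id!r}"
                )


def introns_of(gene: GenomicInterval, exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Gaps between sorted exons of a gene, as intron intervals."""
    exons = sorted((e for e in exons if e.parent == gene.feature_id), key=lambda e: e.start)
    out = []
    for a, b in zip(exons, exons[1:]):
        if a.end < b.start:
            out.append(GenomicInterval(
                gene.chrom, a.end, b.start, gene.strand,
                feature_id=f"{gene.feature_id}.intron{len(out) + 1}",
                feature_class="intron", parent=gene.feature_id,
            ))
    return out


class ExpressionMatrix:
    """Feature × sample abundance table with generation/replicate metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Non-negative, features as index, sample ids as columns.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``generation`` and ``replicate``.
    feature_meta : pandas.DataFrame
        Indexed by feature id; may carry a ``subgenome`` column (A/C/unknown).
    unit : str
        One of TPM / RPM / count.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        unit: str = "count",
        feature_meta: pd.DataFrame | None = None,
    ) -> None:
        if unit not in UNITS:
            raise ValidationError(f"unknown unit {unit!r}")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicated feature id {dup!r}")
        if values.columns.duplicated().any():
            raise ValidationError("duplicated sample ids")
        if values.isna().any().any():
            raise ValidationError("missing values in expression matrix")
        if (values.to_numpy() < 0).any():
            raise ValidationError("negative expression values")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        bad = set(samples["generation"]) - GENERATIONS
        if bad:
            raise ValidationError(f"unknown generation label(s): {sorted(bad)}")
        self.values = values.astype(float)
        self.samples = samples.loc[list(values.columns)]
        self.unit = unit
        if feature_meta is None:
            feature_meta = pd.DataFrame(index=values.index)
        self.feature_meta = feature_meta.reindex(values.index)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def samples_of(self, generation: str) -> list[str]:
        sel = self.samples.index[self.samples["generation"] == generation]
        return list(sel)

    def subset(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[ids], self.samples.loc[ids], self.unit, self.feature_meta
        )

    def median_ratio_normalized(self) -> "ExpressionMatrix":
        """DESeq2-style median-of-ratios normalization of a count matrix.

        Size factors are the per-sample median of count ratios to the
        geometric-mean reference over features positive in every sample;
        robust to asymmetric differential expression, unlike total-count
        scaling.  Falls back to counts-per-million when no feature is
        positive everywhere.  Identity for already-normalized units.
        """
        if self.unit != "count":
            return self
        x = self.values.to_numpy()
        allpos = (x > 0).all(axis=1)
        if not allpos.any():
            return self.cpm()
        logref = np.log(x[allpos]).mean(axis=1)
        factors = np.exp(np.median(np.log(x[allpos]) - logref[:, None], axis=0))
        vals = self.values / factors
        return ExpressionMatrix(vals, self.samples, "RPM", self.feature_meta)

    def cpm(self) -> "ExpressionMatrix":
        """Counts-per-million normalization (identity for TPM/RPM input)."""
        if self.unit != "count":
            return self
        tot = self.values.sum(axis=0)
        vals = self.values.divide(tot.replace(0, np.nan), axis=1) * 1e6
        out = ExpressionMatrix(vals.fillna(0.0), self.samples, "RPM", self.feature_meta)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.values.shape[0]} features × "
            f"{self.values.shape[1]} samples, unit={self.unit})"
        )


METHYLATION_COLUMNS = ["chrom", "position", "strand", "context", "meth", "total", "sample"]


def validate_methylation(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-cytosine count table (CX-report style, long format)."""
    missing = [c for c in METHYLATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"methylation table missing columns {missing}")
    if not table["context"].isin(CONTEXTS).all():
        raise ValidationError("methylation context must be CG/CHG/CHH")
    if ((table["meth"] < 0) | (table["meth"] > table["total"])).any():
        raise ValidationError("need 0 <= meth <= total per cytosine")
    if not table["strand"].isin(VALID_STRANDS).all():
        raise ValidationError("invalid strand in methylation table")
    return table
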