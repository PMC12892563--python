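"""Readers and writers for BED6, GFF3, expression TSV and CX-report tables.

Conventions
-----------
* BED stays 0-based half-open as on disk.
* GFF3 is converted between 1-based closed (disk) and 0-based half-open
  (memory) at this boundary only.
* GFF3 strand/BED strand ``.`` maps to the unstranded internal strand.
* The expression TSV is features × samples with a tab-separated header of
  sample ids; sample metadata (generation, replicate) lives in a sidecar
  TSV with columns ``sample``, ``generation``, ``replicate``.
"""
from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .core import (
    ExpressionMatrix,
    GenomicInterval,
    ValidationError,
    validate_collection,
    validate_methylation,
)


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def _bed_name(iv: GenomicInterval) -> str:
    # BED6 has no class column; encode a non-default class into the name so
    # the write/read cycle is lossless.
    if iv.feature_class == "region":
        return iv.feature_id or "."
    return f"{iv.feature_id}|{iv.feature_class}"


def _split_bed_name(name: str) -> tuple[str, str]:
    if "|" in name:
        fid, cls = name.split("|", 1)
        return fid, cls
    return ("" if name == "." else name), "region"


def read_intervals(path: str | os.PathLike, format: str) -> list[GenomicInterval]:
    """Read a BED6 or GFF3 file into a list of intervals.

    GFF3 ``start``/``end`` (1-based closed) become 0-based half-open;
    BED coordinates are kept as-is.
    """
    fmt = format.upper()
    if fmt not in {"BED6", "GFF3"}:
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED6":
                    if len(fields) < 6:
                        raise ParseError("expected 6 tab-separated BED fields")
                    chrom, start, end, name, _score, strand = fields[:6]
                    fid, cls = _split_bed_name(name)
                    iv = GenomicInterval(
                        chrom, int(start), int(end),
                        strand if strand in "+-" else ".",
                        feature_id=fid, feature_class=cls,
                    )
                else:
                    if len(fields) != 9:
                        raise ParseError("expected 9 tab-separated GFF3 fields")
                    chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
                    attr = dict(
                        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                    )
                    iv = GenomicInterval(
                        chrom, int(start) - 1, int(end),
                        strand if strand in "+-" else ".",
                        feature_id=attr.get("ID", ""),
                        feature_class=ftype,
                        parent=attr.get("Parent"),
                    )
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    validate_collection(out)
    return out


def write_intervals(
    intervals: Sequence[GenomicInterval], path: str | os.PathLike, format: str
) -> None:
    """Write intervals to BED6 or GFF3, preserving order."""
    fmt = format.upper()
    if fmt not in {"BED6", "GFF3"}:
        raise ValueError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        if fmt == "GFF3":
            fh.write("##gff-version 3\n")
        for iv in intervals:
            if fmt == "BED6":
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_bed_name(iv)}\t0\t{iv.strand}\n"
                )
            else:
                attrs = f"ID={iv.feature_id}" if iv.feature_id else "ID=."
                if iv.parent:
                    attrs += f";Parent={iv.parent}"
                fh.write(
                    f"{iv.chrom}\thybepi\t{iv.feature_class}\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


def read_expression(
    path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    unit: str = "count",
) -> ExpressionMatrix:
    """Read a feature × sample TSV plus its sample-metadata sidecar."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise ParseError(f"{metadata_path}: sidecar needs a 'sample' column")
    meta = meta.set_index("sample")
    feature_meta = None
    if "subgenome" in values.columns:
        feature_meta = values[["subgenome"]]
        values = values.drop(columns=["subgenome"])
    return ExpressionMatrix(values, meta, unit=unit, feature_meta=feature_meta)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    metadata_path: str | os.PathLike,
) -> None:
    values = matrix.values.copy()
    if "subgenome" in matrix.feature_meta.columns:
        values.insert(0, "subgenome", matrix.feature_meta["subgenome"])
    values.to_csv(path, sep="\t", index_label="feature")
    matrix.samples.to_csv(metadata_path, sep="\t", index_label="sample")


def read_methylation(path: str | os.PathLike) -> pd.DataFrame:
    """Read a CX-report-style per-cytosine count table.

    Expected columns (tab separated, with header): chrom, position, strand,
    context, meth, total, sample.  Positions are 0-based.
    """
    table = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "strand": str, "context": str, "sample": str},
    )
    return validate_methylation(table)


def write_methylation(table: pd.DataFrame, path: str | os.PathLike) -> None:
    validate_methylation(table).to_csv(path, sep="\t", index=False)
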