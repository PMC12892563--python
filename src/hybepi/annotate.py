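"""Positional classification and rule-based filtering of ncRNA features.

Implements the integration-layer annotation rules used when characterising
ncRNAs in an interspecific hybrid: lncRNA candidate filtering, lncRNA
positional classes (lincRNA / antisense / intronic / sense), the
genic / proximal (< 2 kb) / distal (> 2 kb) location scheme for siRNA
clusters, TE association, reproducible-ACR merging across replicates
(> 50 bp mutual overlap), ACR-lncRNA calling (> 50 % locus coverage in
≥ 2 replicates), hybrid-novel ACR-lncRNAs, and activated / silenced
phasiRNA calls.  Comparator strictness follows the stated rules exactly:
"longer than 200 nt" excludes 200, "over 50 bp" excludes 50, "more than
50 %" excludes 0.5, "reads > 1" excludes 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, ValidationError, introns_of

LNCRNA_CLASS_CODES = {"i", "u", "o", "x"}


@dataclass
class AnnotationConfig:
    """Thresholds for the annotation rules (defaults are the study's)."""

    proximal_distance: int = 2000          # strict <, bases
    acr_min_overlap_bases: int = 50        # strict >, replicate peak overlap
    acr_lncrna_coverage_fraction: float = 0.5   # strict >
    acr_min_replicates: int = 2
    acr_coverage_side: str = "lncrna"      # or "acr"; see docs/methods.md
    min_lncrna_length: int = 200           # strict >
    expression_floor_tpm: float = 0.5      # retained iff max TPM >= floor
    novel_hybrid_tpm: float = 0.5          # strict >
    novel_parent_tpm: float = 0.1          # strict <
    activation_read_floor: float = 1.0     # strict >
    constitutive_tpm: float = 0.5          # strict >

    def __post_init__(self) -> None:
        if not (0 < self.acr_lncrna_coverage_fraction <= 1):
            raise ValidationError("coverage fraction must be in (0, 1]")
        if self.acr_coverage_side not in {"lncrna", "acr"}:
            raise ValidationError("acr_coverage_side must be 'lncrna' or 'acr'")


@dataclass
class LncRnaCandidate:
    """A pre-filter lncRNA candidate with externally produced verdicts.

    The coding-potential verdicts (CNCI/CPC/PLEK-style) and the protein
    domain flag are consumed, never computed here.
    """

    interval: GenomicInterval
    length: int
    class_code: str
    noncoding_verdicts: tuple[bool | None, bool | None, bool | None]
    has_protein_domain: bool
    max_tpm: float


def filter_lncrna_candidates(
    candidates: Sequence[LncRnaCandidate], config: AnnotationConfig | None = None
) -> tuple[list[LncRnaCandidate], pd.DataFrame]:
    """Apply the high-confidence lncRNA filter chain.

    A candidate is retained iff its class code is one of i/u/o/x, all three
    coding-potential verdicts call it noncoding, it carries no known protein
    domain, it is longer than ``min_lncrna_length`` nt, and its maximal TPM
    across samples reaches ``expression_floor_tpm``.  The first failing rule
    is recorded per rejected candidate.
    """
    config = config or AnnotationConfig()
    retained: list[LncRnaCandidate] = []
    rows = []
    for cand in candidates:
        if any(v is None for v in cand.noncoding_verdicts):
            raise ValidationError(
                f"{cand.interval.feature_id}: missing coding-potential verdict"
            )
        reason = None
        if cand.class_code not in LNCRNA_CLASS_CODES:
            reason = "class_code"
        elif not all(cand.noncoding_verdicts):
            reason = "coding_potential"
        elif cand.has_protein_domain:
            reason = "protein_domain"
        elif not cand.length > config.min_lncrna_length:
            reason = "length"
        elif not cand.max_tpm >= config.expression_floor_tpm:
            reason = "expression_floor"
        if reason is None:
            retained.append(cand)
        rows.append({"feature": cand.interval.feature_id,
                     "retained": reason is None,
                     "reason": reason or ""})
    return retained, pd.DataFrame(rows, columns=["feature", "retained", "reason"])


def _gene_trees(genes: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    return trees


def classify_lncrna_locus(
    lncrna: GenomicInterval,
    genes: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval] = (),
) -> str:
    """Positional lncRNA class: AS-lncRNA, intronic, sense, or lincRNA.

    Priority when several genes conflict: antisense > intronic > sense.
    Unstranded lncRNAs cannot be assigned a strand-relative class and are
    returned as ``lincRNA`` (no gene overlap) or ``overlapping-unstranded``.
    """
    hits = [g for g in genes if g.overlaps(lncrna)]
    if not hits:
        return "lincRNA"
    if lncrna.strand == ".":
        return "overlapping-unstranded"
    if any(g.opposite_strand(lncrna) for g in hits):
        return "AS-lncRNA"
    for g in hits:
        if g.strand != lncrna.strand:
            continue
        for intron in introns_of(g, exons):
            if intron.start <= lncrna.start and lncrna.end <= intron.end:
                return "intronic"
    same = [g for g in hits if g.strand == lncrna.strand]
    gene_exons = {g.feature_id for g in same}
    if any(e.parent in gene_exons and e.overlaps(lncrna) for e in exons):
        return "sense"
    # same-strand gene overlap without exon overlap and not intron-contained
    # (e.g. spans a gene edge inside an intron): exonic structure is the
    # sense criterion, so fall back to sense for exhaustiveness
    return "sense" if same else "lincRNA"


def classify_lncrna_loci(
    lncrnas: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval] = (),
) -> pd.Series:
    """Vector version of :func:`classify_lncrna_locus`."""
    return pd.Series(
        {l.feature_id: classify_lncrna_locus(l, genes, exons) for l in lncrnas},
        name="lncrna_class",
    )


def categorize_location(
    feature: GenomicInterval,
    genes: Sequence[GenomicInterval],
    config: AnnotationConfig | None = None,
) -> str:
    """genic (≥1 bp gene-body overlap), proximal (< 2 kb), or distal."""
    config = config or AnnotationConfig()
    best: int | None = None
    for g in genes:
        if feature.overlaps(g):
            return "genic"
        d = feature.distance(g)  # touching intervals have distance 0, no overlap
        if d is None:
            continue
        best = d if best is None else min(best, d)
    if best is not None and best < config.proximal_distance:
        return "proximal"
    return "distal"


def categorize_locations(
    features: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    config: AnnotationConfig | None = None,
) -> pd.Series:
    return pd.Series(
        {f.feature_id: categorize_location(f, genes, config) for f in features},
        name="location",
    )


def te_association(
    features: Sequence[GenomicInterval],
    tes: Sequence[GenomicInterval],
    superfamilies: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-feature TE association (≥1 bp overlap) and the superfamily of the
    TE with maximal overlap; ties broken by first genomic position."""
    superfamilies = superfamilies or {}
    trees = _gene_trees(tes)
    rows = []
    for f in features:
        best_te: GenomicInterval | None = None
        best_ov = 0
        for hit in trees.get(f.chrom, IntervalTree()).overlap(f.start, f.end):
            te = hit.data
            ov = f.overlap_length(te)
            if ov > best_ov or (
                ov == best_ov and ov > 0 and best_te is not None
                and (te.chrom, te.start, te.end) < (best_te.chrom, best_te.start, best_te.end)
            ):
                best_ov, best_te = ov, te
        rows.append({
            "feature": f.feature_id,
            "te_associated": best_te is not None,
            "te_superfamily": (
                superfamilies.get(best_te.feature_id, "TE") if best_te else ""
            ),
            "te_overlap_bp": best_ov,
        })
    return pd.DataFrame(rows).set_index("feature")


def merge_replicate_acrs(
    replicate_sets: Sequence[Sequence[GenomicInterval]],
    config: AnnotationConfig | None = None,
) -> list[GenomicInterval]:
    """Merge replicate ATAC peak sets into reproducible ACRs.

    A region is kept iff peaks from at least two replicates overlap each
    other by more than ``acr_min_overlap_bases``.  The emitted interval is
    the union of all peaks connected through such cross-replicate overlaps.
    """
    config = config or AnnotationConfig()
    if len(replicate_sets) < 2:
        raise ValidationError("need at least two replicate peak sets")
    peaks = [(rep_i, p) for rep_i, reps in enumerate(replicate_sets) for p in reps]
    n = len(peaks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    supported = [False] * n
    trees: dict[str, IntervalTree] = {}
    for idx, (_, p) in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, idx)
    for i, (rep_i, p) in enumerate(peaks):
        for hit in trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end):
            j = hit.data
            rep_j, q = peaks[j]
            if j <= i or rep_j == rep_i:
                continue
            if p.overlap_length(q) > config.acr_min_overlap_bases:
                union(i, j)
                supported[i] = supported[j] = True
    groups: dict[int, list[int]] = {}
    for i in range(n):
        if supported[i]:
            groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        ivs = [peaks[i][1] for i in members]
        merged.append((ivs[0].chrom, min(p.start for p in ivs), max(p.end for p in ivs)))
    merged.sort()
    return [
        GenomicInterval(c, s, e, ".", feature_id=f"ACR{i + 1}", feature_class="ACR")
        for i, (c, s, e) in enumerate(merged)
    ]


def _covered_bases(target: GenomicInterval, peaks: Sequence[GenomicInterval]) -> int:
    segs = sorted(
        (max(target.start, p.start), min(target.end, p.end))
        for p in peaks
        if p.chrom == target.chrom and p.start < target.end and p.end > target.start
    )
    covered, cur_s, cur_e = 0, None, None
    for s, e in segs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def call_acr_lncrna(
    lncrnas: Sequence[GenomicInterval],
    acrs_by_replicate: Sequence[Sequence[GenomicInterval]],
    config: AnnotationConfig | None = None,
) -> pd.DataFrame:
    """Flag lncRNAs whose locus is majority-covered by ACRs reproducibly.

    Default reading: the fraction of the lncRNA locus covered by ACR bases
    must exceed ``acr_lncrna_coverage_fraction`` in at least
    ``acr_min_replicates`` replicates.  ``config.acr_coverage_side = "acr"``
    switches to the ACR-side reading (some ACR majority-covered by the
    lncRNA).
    """
    config = config or AnnotationConfig()
    rows = []
    for l in lncrnas:
        n_support = 0
        fracs = []
        for peaks in acrs_by_replicate:
            if config.acr_coverage_side == "lncrna":
                frac = _covered_bases(l, peaks) / len(l)
                ok = frac > config.acr_lncrna_coverage_fraction
            else:
                per_acr = [
                    _covered_bases(p, [l]) / len(p)
                    for p in peaks if p.overlaps(l)
                ]
                frac = max(per_acr, default=0.0)
                ok = frac > config.acr_lncrna_coverage_fraction
            fracs.append(frac)
            n_support += ok
        rows.append({
            "feature": l.feature_id,
            "acr_lncrna": n_support >= config.acr_min_replicates,
            "n_supporting_replicates": n_support,
            "max_coverage_fraction": max(fracs, default=0.0),
        })
    return pd.DataFrame(rows).set_index("feature")


def call_novel_acr_lncrna(
    hybrid_tpm: pd.Series,
    maternal_tpm: pd.Series,
    paternal_tpm: pd.Series,
    config: AnnotationConfig | None = None,
) -> pd.Series:
    """Hybrid-novel ACR-lncRNAs: expressed in the hybrid (TPM > 0.5) but in
    neither parent (both TPM < 0.1)."""
    config = config or AnnotationConfig()
    flag = (
        (hybrid_tpm > config.novel_hybrid_tpm)
        & (maternal_tpm < config.novel_parent_tpm)
        & (paternal_tpm < config.novel_parent_tpm)
    )
    flag.name = "novel_acr_lncrna"
    return flag


def call_activated_silenced(
    hybrid_reads: pd.Series,
    maternal_reads: pd.Series,
    paternal_reads: pd.Series,
    config: AnnotationConfig | None = None,
) -> pd.Series:
    """Per-locus activation call on raw read counts.

    activated: hybrid reads > 1 while both parents have 0 reads;
    silenced: hybrid has 0 reads while both parents have reads > 1;
    anything else: neither.
    """
    config = config or AnnotationConfig()
    floor = config.activation_read_floor
    activated = (hybrid_reads > floor) & (maternal_reads == 0) & (paternal_reads == 0)
    silenced = (hybrid_reads == 0) & (maternal_reads > floor) & (paternal_reads > floor)
    out = pd.Series("neither", index=hybrid_reads.index, name="activation")
    out[activated] = "activated"
    out[silenced] = "silenced"
    return out


def constitutive_flag(
    tpm: pd.DataFrame | pd.Series, config: AnnotationConfig | None = None
) -> pd.Series | bool:
    """Constitutively expressed: TPM > 0.5 in every sample."""
    config = config or AnnotationConfig()
    if isinstance(tpm, pd.Series):
        return bool((tpm > config.constitutive_tpm).all())
    out = (tpm > config.constitutive_tpm).all(axis=1)
    out.name = "constitutive"
    return out
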