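"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — quadratic loops, per-base counting,
direct formulas — and shares no code path with the package implementations
it checks.
"""
from __future__ import annotations

import numpy as np

from hybepi.core import GenomicInterval, introns_of


def brute_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return sum(
        1 for pos in range(a.start, a.end) if b.start <= pos < b.end
    )


def brute_distance(a: GenomicInterval, b: GenomicInterval):
    if a.chrom != b.chrom:
        return None
    if brute_overlap(a, b):
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def brute_lncrna_class(lnc, genes, exons):
    hits = [g for g in genes if brute_overlap(lnc, g) > 0]
    if not hits:
        return "lincRNA"
    if lnc.strand == ".":
        return "overlapping-unstranded"
    if any(g.strand in "+-" and g.strand != lnc.strand for g in hits):
        return "AS-lncRNA"
    for g in hits:
        if g.strand != lnc.strand:
            continue
        for intron in introns_of(g, exons):
            if intron.start <= lnc.start and lnc.end <= intron.end:
                return "intronic"
    same = [g for g in hits if g.strand == lnc.strand]
    if any(
        e.parent in {g.feature_id for g in same} and brute_overlap(e, lnc) > 0
        for e in exons
    ):
        return "sense"
    return "sense" if same else "lincRNA"


def brute_location(feature, genes, proximal=2000):
    dists = []
    for g in genes:
        if brute_overlap(feature, g) > 0:
            return "genic"
        d = brute_distance(feature, g)
        if d is not None:
            dists.append(d)
    if dists and min(dists) < proximal:
        return "proximal"
    return "distal"


def brute_te_best(feature, tes):
    best, best_ov = None, 0
    for te in sorted(tes, key=lambda t: (t.chrom, t.start, t.end)):
        ov = brute_overlap(feature, te)
        if ov > best_ov:
            best, best_ov = te, ov
    return best, best_ov


def brute_coverage_fraction(target, peaks) -> float:
    covered = 0
    for pos in range(target.start, target.end):
        if any(p.chrom == target.chrom and p.start <= pos < p.end for p in peaks):
            covered += 1
    return covered / (target.end - target.start)


def brute_bh(pvals):
    """Step-up Benjamini–Hochberg, written directly from the definition."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        value = min(p[i] * n / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def brute_fisher_two_sided(a, b, c, d) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by hypergeometric enumeration
    (sum of all table probabilities not exceeding the observed one)."""
    from scipy.stats import hypergeom

    n1, n2 = a + b, c + d
    k = a + c
    rv = hypergeom(n1 + n2, n1, k)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def brute_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def random_intervals(rng, n, chrom="chr1", max_pos=50_000, classes=("region",)):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, 1500))
        strand = rng.choice(["+", "-", "."])
        out.append(GenomicInterval(
            chrom, start, start + length, str(strand),
            feature_id=f"iv{i}", feature_class=str(rng.choice(classes)),
        ))
    return out
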