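"""Synthetic data with planted, exported ground truth.

Emulates the three-generation study design — an allotetraploid AACC
maternal line crossed with a diploid AA paternal line giving an AAC
hybrid — well enough that every downstream stage of the package has a
recovery test without any external download:

* an annotation with genes (and exon structure), TEs, lncRNAs placed to
  realize each positional class, and siRNA clusters placed genic /
  proximal / distal;
* count matrices with planted additive / ELD / transgressive patterns
  (negative-binomial noise, per-sample library-size factors);
* a dosage series whose dosage-dependent features scale (or inversely
  scale) with their subgenome's dosage vector;
* per-cytosine methylation counts with beta-binomial noise and planted
  DMR bins;
* replicate ACR peak sets with boundary jitter and single-replicate decoys.

Determinism: one RNG stream per sub-generator, spawned from the master
seed, so extending one generator never perturbs another's draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GenomicInterval, ValidationError

PATTERN_CYCLE = (
    "additive", "ELD-M", "ELD-P", "transgressive-up", "transgressive-down",
    "no-change",
)
#: planted class mix: transgression is rare in real hybrids, and a roughly
#: direction-balanced mix keeps depth normalization honest
PATTERN_PROPORTIONS = {
    "no-change": 0.32,
    "additive": 0.25,
    "ELD-M": 0.20,
    "ELD-P": 0.15,
    "transgressive-up": 0.04,
    "transgressive-down": 0.04,
}
DOSAGE_CYCLE = ("dd-positive", "dd-negative", "di")
LNCRNA_CYCLE = ("AS-lncRNA", "lincRNA", "intronic", "sense")
LOCATION_CYCLE = ("genic", "proximal", "distal")
TE_SUPERFAMILIES = ("DNA", "LTR", "LINE", "SINE")

_BLOCK = 20_000  # bases reserved per gene neighbourhood


class PackingError(ValidationError):
    """The requested features cannot be placed without forced overlap."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Counts and noise levels default to the desk-scale study conditions:
    3 replicates per generation, a planted log2 effect of 2.0, mildly
    overdispersed negative-binomial counts, ~30x methylation coverage with
    near-binomial per-site variation, and 10 bp ACR replicate jitter.
    """

    seed: int = 0
    n_genes: int = 60
    n_tes: int = 40
    n_lncrnas: int = 40
    n_clusters: int = 30
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    replicates: int = 3
    nb_dispersion: float = 0.05
    effect_log2fc: float = 2.0
    base_mean: float = 200.0
    library_cv: float = 0.1       # per-sample depth factor spread (clipped ±20 %)
    dosage_noise_sigma: float = 0.15  # log-normal replicate noise on the series
    methylation_baseline: dict = field(
        default_factory=lambda: {"CG": 0.6, "CHG": 0.3, "CHH": 0.1})
    dmr_delta: dict = field(
        default_factory=lambda: {"CG": 0.5, "CHG": 0.3, "CHH": 0.2})
    bb_concentration: float = 100.0   # beta-binomial per-site concentration
    coverage_mean: float = 30.0
    sites_per_bin: int = 12
    n_meth_bins: int = 90
    dmr_fraction: float = 0.2
    n_acrs: int = 16
    n_decoys_per_replicate: int = 6
    acr_replicates: int = 3
    acr_jitter: int = 10

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tes", "n_lncrnas", "n_clusters"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for d in (*self.methylation_baseline.values(), *self.dmr_delta.values()):
            if not (0 <= d <= 1):
                raise ValidationError("proportions must lie in [0, 1]")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams derived from the master seed."""
        names = ("annotation", "expression", "dosage", "methylation", "acr")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    # gamma-distributed depth factors, clipped to the stated ±20 % band
    shape = 1.0 / (cv * cv)
    return np.clip(rng.gamma(shape, 1.0 / shape, size=n), 0.8, 1.2)


def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Deterministically place genes, TEs, lncRNAs and siRNA clusters.

    Each gene owns a 20 kb neighbourhood; lncRNAs cycle through the four
    positional classes inside their host neighbourhood with margins that
    guarantee the planted class, siRNA clusters cycle genic / proximal /
    distal, and TEs alternate between intergenic gaps and lncRNA overlap.
    Raises :class:`PackingError` when the chromosome is too short or a
    class needs a host gene that does not exist.
    """
    rng = config.streams()["annotation"]
    if config.n_lncrnas > 0 and config.n_genes < config.n_lncrnas:
        raise PackingError("each lncRNA needs its own host gene neighbourhood")
    if config.n_clusters > 0 and config.n_genes < config.n_clusters:
        raise PackingError("each siRNA cluster needs its own gene neighbourhood")
    needed = config.n_genes * _BLOCK + _BLOCK
    if config.n_genes and config.chrom_length < needed:
        raise PackingError(
            f"chrom_length {config.chrom_length} < {needed} required for "
            f"{config.n_genes} gene neighbourhoods"
        )
    intervals: list[GenomicInterval] = []
    truth_rows: list[dict] = []
    gene_strands = []
    for i in range(config.n_genes):
        b = i * _BLOCK
        strand = "+" if i % 2 == 0 else "-"
        gene_strands.append(strand)
        gid = f"gene{i + 1:04d}"
        gene = GenomicInterval(config.chrom, b + 4000, b + 7000, strand,
                               feature_id=gid, feature_class="gene")
        intervals.append(gene)
        for k, (es, ee) in enumerate(((4000, 4600), (5200, 5800), (6400, 7000))):
            intervals.append(GenomicInterval(
                config.chrom, b + es, b + ee, strand,
                feature_id=f"{gid}.exon{k + 1}", feature_class="exon", parent=gid))
        truth_rows.append({"feature": gid, "feature_class": "gene",
                           "planted_label": ""})
    for j in range(config.n_lncrnas):
        b = j * _BLOCK
        cls = LNCRNA_CYCLE[j % len(LNCRNA_CYCLE)]
        host_strand = gene_strands[j]
        lid = f"lnc{j + 1:04d}"
        jit = int(rng.integers(-40, 41))
        if cls == "AS-lncRNA":
            strand = "-" if host_strand == "+" else "+"
            iv = GenomicInterval(config.chrom, b + 4100 + jit, b + 4500 + jit,
                                 strand, feature_id=lid, feature_class="lncRNA")
        elif cls == "intronic":
            iv = GenomicInterval(config.chrom, b + 4650 + jit, b + 5150 + jit,
                                 host_strand, feature_id=lid, feature_class="lncRNA")
        elif cls == "sense":
            iv = GenomicInterval(config.chrom, b + 5300 + jit, b + 5700 + jit,
                                 host_strand, feature_id=lid, feature_class="lncRNA")
        else:  # lincRNA, > 2 kb from any gene
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(config.chrom, b + 15000 + jit, b + 15500 + jit,
                                 strand, feature_id=lid, feature_class="lncRNA")
        intervals.append(iv)
        truth_rows.append({"feature": lid, "feature_class": "lncRNA",
                           "planted_label": cls})
    for j in range(config.n_clusters):
        b = j * _BLOCK
        loc = LOCATION_CYCLE[j % len(LOCATION_CYCLE)]
        cid = f"sirna{j + 1:04d}"
        jit = int(rng.integers(-40, 41))
        if loc == "genic":
            iv = GenomicInterval(config.chrom, b + 4200 + jit, b + 4550 + jit, ".",
                                 feature_id=cid, feature_class="siRNA_cluster")
        elif loc == "proximal":
            iv = GenomicInterval(config.chrom, b + 2500 + jit, b + 3000 + jit, ".",
                                 feature_id=cid, feature_class="siRNA_cluster")
        else:
            iv = GenomicInterval(config.chrom, b + 17000 + jit, b + 17400 + jit, ".",
                                 feature_id=cid, feature_class="siRNA_cluster")
        intervals.append(iv)
        truth_rows.append({"feature": cid, "feature_class": "siRNA_cluster",
                           "planted_label": loc})
    for t in range(config.n_tes):
        b = (t % max(config.n_genes, 1)) * _BLOCK
        tid = f"te{t + 1:04d}"
        jit = int(rng.integers(-40, 41))
        if t % 2 == 0 or config.n_lncrnas == 0:
            iv = GenomicInterval(config.chrom, b + 13000 + jit, b + 13800 + jit, "+",
                                 feature_id=tid, feature_class="TE")
        else:  # overlap the block's lncRNA slot region
            iv = GenomicInterval(config.chrom, b + 15100 + jit, b + 15600 + jit, "+",
                                 feature_id=tid, feature_class="TE")
        intervals.append(iv)
        truth_rows.append({
            "feature": tid, "feature_class": "TE",
            "planted_label": TE_SUPERFAMILIES[t % len(TE_SUPERFAMILIES)]})
    truth = pd.DataFrame(truth_rows, columns=["feature", "feature_class",
                                              "planted_label"])
    return intervals, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, var = mu + dispersion mu²); exact means in the noiseless limit."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return mu.copy()
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mu, 1e-12))
    return rng.negative_binomial(size, p).astype(float)


def simulate_expression(
    config: SimulationConfig,
    feature_ids: list[str] | None = None,
    n_features: int = 300,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Three-generation count matrix with planted additivity patterns.

    Patterns cycle through additive / ELD-M / ELD-P / transgressive-up /
    transgressive-down / no-change.  The hybrid mean is the mid-parent for
    additive features, the matching parent for ELD, and the more extreme
    parent shifted by ``effect_log2fc`` (log2 scale) for transgressive
    features.  Counts are negative-binomial with per-sample library-size
    factors; ``nb_dispersion = 0`` with ``library_cv = 0`` gives the exact
    noiseless limit.
    """
    rng = config.streams()["expression"]
    if feature_ids is None:
        feature_ids = [f"feat{i + 1:04d}" for i in range(n_features)]
    n = len(feature_ids)
    label_list: list[str] = []
    for cls in PATTERN_CYCLE:
        label_list.extend([cls] * int(round(PATTERN_PROPORTIONS[cls] * n)))
    label_list = (label_list + ["no-change"] * n)[:n]
    labels = pd.Series(label_list, index=pd.Index(feature_ids, name="feature"),
                       name="planted_pattern")
    base = rng.lognormal(np.log(config.base_mean), 0.4, size=n)
    eff = 2.0 ** config.effect_log2fc
    m_mean = np.empty(n)
    p_mean = np.empty(n)
    h_mean = np.empty(n)
    direction: dict[str, int] = {}
    for i, lab in enumerate(labels):
        lo, hi = base[i], base[i] * eff
        direction[lab] = direction.get(lab, 0) + 1
        # alternate the high parent within each class
        m, p = (lo, hi) if direction[lab] % 2 == 0 else (hi, lo)
        if lab == "no-change":
            m = p = h = base[i]
        elif lab == "additive":
            h = (m + p) / 2.0
        elif lab == "ELD-M":
            h = m
        elif lab == "ELD-P":
            h = p
        elif lab == "transgressive-up":
            h = max(m, p) * eff
        else:  # transgressive-down
            h = min(m, p) / eff
        m_mean[i], p_mean[i], h_mean[i] = m, p, h
    gens = (("maternal", m_mean), ("paternal", p_mean), ("hybrid", h_mean))
    factors = _library_factors(rng, 3 * config.replicates, config.library_cv)
    cols, meta = {}, []
    k = 0
    for gen, mu in gens:
        for rep in range(1, config.replicates + 1):
            name = f"{gen}_rep{rep}"
            cols[name] = _nb_draw(rng, mu * factors[k], config.nb_dispersion)
            meta.append({"sample": name, "generation": gen, "replicate": rep})
            k += 1
    values = pd.DataFrame(cols, index=labels.index)
    samples = pd.DataFrame(meta).set_index("sample")
    return ExpressionMatrix(values, samples, unit="count"), labels


def simulate_dosage_series(
    config: SimulationConfig,
    feature_ids: list[str] | None = None,
    n_features: int = 200,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression across the AACC/AAC/AA series with planted dosage labels.

    dd-positive features scale proportionally with their subgenome's dosage
    vector, dd-negative features scale with the reversed vector, and di
    features have a dosage-unrelated constant mean; replicate noise is
    multiplicative log-normal (``dosage_noise_sigma``).
    """
    from .dosage import DOSAGE_VECTORS, GENERATION_ORDER

    rng = config.streams()["dosage"]
    if feature_ids is None:
        feature_ids = [f"dfeat{i + 1:04d}" for i in range(n_features)]
    index = pd.Index(feature_ids, name="feature")
    labels = pd.Series(
        [DOSAGE_CYCLE[i % len(DOSAGE_CYCLE)] for i in range(len(index))],
        index=index, name="planted_dosage",
    )
    subgenomes = pd.Series(["A" if i % 2 == 0 else "C" for i in range(len(index))],
                           index=index, name="subgenome")
    base = rng.lognormal(np.log(20.0), 0.5, size=len(index))
    cols, meta = {}, []
    for gen_i, gen in enumerate(GENERATION_ORDER):
        for rep in range(1, config.replicates + 1):
            name = f"{gen}_rep{rep}"
            mu = np.empty(len(index))
            for i, lab in enumerate(labels):
                dvec = np.asarray(DOSAGE_VECTORS[subgenomes.iloc[i]])
                if lab == "dd-positive":
                    mu[i] = base[i] * dvec[gen_i]
                elif lab == "dd-negative":
                    mu[i] = base[i] * (dvec.max() + dvec.min() - dvec[gen_i])
                else:
                    mu[i] = base[i]
            if config.dosage_noise_sigma > 0:
                mu = mu * rng.lognormal(0.0, config.dosage_noise_sigma, len(index))
            cols[name] = mu
            meta.append({"sample": name, "generation": gen, "replicate": rep})
    values = pd.DataFrame(cols, index=index)
    samples = pd.DataFrame(meta).set_index("sample")
    matrix = ExpressionMatrix(values, samples, unit="TPM",
                              feature_meta=subgenomes.to_frame())
    return matrix, labels


def simulate_methylation(
    config: SimulationConfig,
    n_bins: int | None = None,
    dmr_fraction: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cytosine counts for two groups with planted DMR bins.

    200-bp bins cycle through CG/CHG/CHH; within a planted DMR bin the
    group-2 methylation proportion shifts by the context's ``dmr_delta``.
    Per-site proportions are Beta-distributed around the context baseline
    (``bb_concentration``), coverage is Poisson around ``coverage_mean``
    (so ≥5-read sites dominate), and methylated counts are binomial.
    """
    rng = config.streams()["methylation"]
    n_bins = config.n_meth_bins if n_bins is None else n_bins
    dmr_fraction = config.dmr_fraction if dmr_fraction is None else dmr_fraction
    contexts = ("CG", "CHG", "CHH")
    records, truth_rows = [], []
    period = max(int(round(1 / dmr_fraction)), 1) if dmr_fraction > 0 else 0
    for b in range(n_bins):
        ctx = contexts[b % 3]
        start = b * 200
        is_dmr = bool(period and (b // 3) % period == 0)
        delta = config.dmr_delta[ctx] if is_dmr else 0.0
        truth_rows.append({"chrom": config.chrom, "start": start,
                           "end": start + 200, "context": ctx,
                           "is_dmr": is_dmr, "planted_delta": delta})
        offsets = rng.choice(np.arange(4, 196), size=config.sites_per_bin,
                             replace=False)
        offsets.sort()
        for group_i, sample in enumerate(("group1", "group2")):
            p0 = config.methylation_baseline[ctx] + (delta if group_i == 1 else 0.0)
            p0 = min(max(p0, 0.02), 0.98)
            a = config.bb_concentration * p0
            bb = config.bb_concentration * (1 - p0)
            for off in offsets:
                cov = int(rng.poisson(config.coverage_mean))
                if cov == 0:
                    continue
                p_site = rng.beta(a, bb)
                meth = int(rng.binomial(cov, p_site))
                records.append({
                    "chrom": config.chrom, "position": int(start + off),
                    "strand": "+", "context": ctx, "meth": meth,
                    "total": cov, "sample": sample,
                })
    table = pd.DataFrame(records, columns=["chrom", "position", "strand",
                                           "context", "meth", "total", "sample"])
    return table, pd.DataFrame(truth_rows)


def simulate_acr_replicates(
    config: SimulationConfig,
    lncrnas: list[GenomicInterval] | None = None,
) -> tuple[list[list[GenomicInterval]], pd.DataFrame]:
    """Replicate ATAC peak sets with jittered true ACRs and decoys.

    True ACRs appear in every replicate with boundary jitter bounded by
    ``acr_jitter``; decoy peaks appear in exactly one replicate each.  When
    lncRNA loci are given, every other lncRNA gets a true ACR fully
    covering it (a planted ACR-lncRNA); the rest get none.
    """
    rng = config.streams()["acr"]
    true_acrs: list[tuple[int, int]] = []
    truth_rows = []
    if lncrnas:
        for i, l in enumerate(lncrnas):
            planted = i % 2 == 0
            if planted:
                true_acrs.append((l.start - 100, l.end + 100))
            truth_rows.append({"feature": l.feature_id, "kind": "lncRNA",
                               "acr_lncrna": planted})
    tail = config.chrom_length - 100_000
    for i in range(config.n_acrs):
        s = tail + i * 2000
        true_acrs.append((s, s + 600))
        truth_rows.append({"feature": f"true_acr{i + 1:03d}", "kind": "ACR",
                           "acr_lncrna": False})
    sets: list[list[GenomicInterval]] = []
    decoy_base = tail + config.n_acrs * 2000 + 10_000
    for rep in range(config.acr_replicates):
        peaks = []
        for k, (s, e) in enumerate(true_acrs):
            j1 = int(rng.integers(-config.acr_jitter, config.acr_jitter + 1)) \
                if config.acr_jitter else 0
            j2 = int(rng.integers(-config.acr_jitter, config.acr_jitter + 1)) \
                if config.acr_jitter else 0
            peaks.append(GenomicInterval(
                config.chrom, s + j1, e + j2, ".",
                feature_id=f"rep{rep + 1}_peak{k + 1:03d}",
                feature_class="ACR"))
        for d in range(config.n_decoys_per_replicate):
            s = decoy_base + (rep * config.n_decoys_per_replicate + d) * 2000
            peaks.append(GenomicInterval(
                config.chrom, s, s + 400, ".",
                feature_id=f"rep{rep + 1}_decoy{d + 1:03d}",
                feature_class="ACR"))
        sets.append(peaks)
    return sets, pd.DataFrame(truth_rows, columns=["feature", "kind", "acr_lncrna"])
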