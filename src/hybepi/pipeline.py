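"""File-based orchestration: simulate → annotate → patterns → dosage →
methylation → integrate.

Stages communicate only via TSV/BED/GFF3 files in the run directory, so
each stage is independently testable and any stage's inputs can be
substituted with real upstream-tool outputs.  A run manifest records the
seed, every threshold used, and a hash per output file; rerunning with the
same config and seed reproduces byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotationConfig,
    call_acr_lncrna,
    categorize_locations,
    classify_lncrna_loci,
    merge_replicate_acrs,
    te_association,
)
from .core import ExpressionMatrix
from .dosage import DosageDesign, DosageModel
from .integrate import cis_pairs, correlate_pairs, fuzzy_cmeans, standardize_profiles
from .io import read_expression, read_intervals, read_methylation, \
    write_expression, write_intervals, write_methylation
from .methylation import DmrConfig, call_dmrs
from .patterns import PatternModel
from .simulate import (
    SimulationConfig,
    generate_annotation,
    simulate_acr_replicates,
    simulate_dosage_series,
    simulate_expression,
    simulate_methylation,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    dmr: DmrConfig = field(default_factory=DmrConfig)
    dosage: DosageDesign = field(default_factory=DosageDesign)
    dosage_mode: str = "replicate"
    lfc_threshold: float = 1.5
    alpha: float = 0.05
    cis_max_distance: int = 5000
    n_clusters_fuzzy: int = 6

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "dosage_mode", "lfc_threshold", "alpha",
                    "cis_max_distance", "n_clusters_fuzzy"):
            if key in raw:
                kwargs[key] = raw[key]
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "annotation" in raw:
            kwargs["annotation"] = AnnotationConfig(**raw["annotation"])
        if "dmr" in raw:
            kwargs["dmr"] = DmrConfig(**raw["dmr"])
        if "dosage" in raw:
            kwargs["dosage"] = DosageDesign(**raw["dosage"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _confusion(truth: pd.Series, called: pd.Series) -> pd.DataFrame:
    joined = pd.concat([truth.rename("truth"), called.rename("called")],
                       axis=1, join="inner")
    return joined.groupby(["truth", "called"]).size().rename("n").reset_index()


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = config.simulation
    intervals, ann_truth = generate_annotation(sim)
    write_intervals(intervals, outdir / "annotation.gff3", "GFF3")
    write_intervals(intervals, outdir / "annotation.bed", "BED6")
    ann_truth.to_csv(outdir / "truth_annotation.tsv", sep="\t", index=False)

    feature_ids = list(ann_truth["feature"])
    expr, pattern_truth = simulate_expression(sim, feature_ids=feature_ids)
    write_expression(expr, outdir / "expression.tsv", outdir / "expression_samples.tsv")
    pattern_truth.to_csv(outdir / "truth_patterns.tsv", sep="\t", header=True)

    dosage_expr, dosage_truth = simulate_dosage_series(sim)
    write_expression(dosage_expr, outdir / "dosage_expression.tsv",
                     outdir / "dosage_samples.tsv")
    dosage_truth.to_csv(outdir / "truth_dosage.tsv", sep="\t", header=True)

    meth, meth_truth = simulate_methylation(sim)
    write_methylation(meth, outdir / "methylation.tsv")
    meth_truth.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)

    lncrnas = [iv for iv in intervals if iv.feature_class == "lncRNA"]
    acr_sets, acr_truth = simulate_acr_replicates(sim, lncrnas)
    for i, peaks in enumerate(acr_sets):
        write_intervals(peaks, outdir / f"acr_rep{i + 1}.bed", "BED6")
    acr_truth.to_csv(outdir / "truth_acr.tsv", sep="\t", index=False)


def stage_annotate(config: PipelineConfig, outdir: Path) -> None:
    intervals = read_intervals(outdir / "annotation.gff3", "GFF3")
    genes = [iv for iv in intervals if iv.feature_class == "gene"]
    exons = [iv for iv in intervals if iv.feature_class == "exon"]
    tes = [iv for iv in intervals if iv.feature_class == "TE"]
    lncrnas = [iv for iv in intervals if iv.feature_class == "lncRNA"]
    clusters = [iv for iv in intervals if iv.feature_class == "siRNA_cluster"]
    acr_sets = []
    i = 1
    while (outdir / f"acr_rep{i}.bed").exists():
        acr_sets.append(read_intervals(outdir / f"acr_rep{i}.bed", "BED6"))
        i += 1
    classes = classify_lncrna_loci(lncrnas, genes, exons)
    locations = categorize_locations(clusters, genes, config.annotation)
    te_table = te_association(lncrnas, tes)
    merged = merge_replicate_acrs(acr_sets, config.annotation)
    write_intervals(merged, outdir / "acrs_merged.bed", "BED6")
    acr_flags = call_acr_lncrna(lncrnas, acr_sets, config.annotation)
    out = pd.DataFrame({"lncrna_class": classes}).join(te_table).join(acr_flags)
    out.to_csv(outdir / "lncrna_annotation.tsv", sep="\t", index_label="feature")
    locations.to_frame().to_csv(outdir / "cluster_locations.tsv", sep="\t",
                                index_label="feature")

    ann_truth = pd.read_csv(outdir / "truth_annotation.tsv", sep="\t").set_index("feature")
    conf = pd.concat([
        _confusion(ann_truth.loc[classes.index, "planted_label"], classes),
        _confusion(ann_truth.loc[locations.index, "planted_label"], locations),
    ])
    conf.to_csv(outdir / "confusion_annotation.tsv", sep="\t", index=False)
    acr_truth = pd.read_csv(outdir / "truth_acr.tsv", sep="\t").set_index("feature")
    lnc_truth = acr_truth[acr_truth["kind"] == "lncRNA"]["acr_lncrna"]
    _confusion(lnc_truth, acr_flags["acr_lncrna"]).to_csv(
        outdir / "confusion_acr_lncrna.tsv", sep="\t", index=False)


def stage_patterns(config: PipelineConfig, outdir: Path) -> None:
    expr = read_expression(outdir / "expression.tsv",
                           outdir / "expression_samples.tsv")
    model = PatternModel(expr, lfc_threshold=config.lfc_threshold,
                         alpha=config.alpha)
    res = model.fit(seed=config.seed)
    res.calls.to_csv(outdir / "patterns.tsv", sep="\t", index_label="feature")
    res.de.to_csv(outdir / "patterns_de.tsv", sep="\t", index=False)
    res.summary().to_csv(outdir / "patterns_summary.tsv", sep="\t", index=False)
    truth = pd.read_csv(outdir / "truth_patterns.tsv", sep="\t", index_col=0)
    _confusion(truth["planted_pattern"], res.calls["pattern"]).to_csv(
        outdir / "confusion_patterns.tsv", sep="\t", index=False)


def stage_dosage(config: PipelineConfig, outdir: Path) -> None:
    expr = read_expression(outdir / "dosage_expression.tsv",
                           outdir / "dosage_samples.tsv", unit="TPM")
    res = DosageModel(expr, design=config.dosage, mode=config.dosage_mode).fit()
    res.table.to_csv(outdir / "dosage_calls.tsv", sep="\t", index_label="feature")
    res.summary().to_csv(outdir / "dosage_summary.tsv", sep="\t", index=False)
    truth = pd.read_csv(outdir / "truth_dosage.tsv", sep="\t", index_col=0)
    # planted dd labels collapse direction; compare on the full label
    _confusion(truth["planted_dosage"], res.labels).to_csv(
        outdir / "confusion_dosage.tsv", sep="\t", index=False)


def stage_methylation(config: PipelineConfig, outdir: Path) -> None:
    meth = read_methylation(outdir / "methylation.tsv")
    g1 = meth[meth["sample"] == "group1"]
    g2 = meth[meth["sample"] == "group2"]
    dmrs = call_dmrs(g1, g2, config.dmr)
    dmrs.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    truth = pd.read_csv(outdir / "truth_dmrs.tsv", sep="\t")
    key = ["chrom", "start", "end", "context"]
    called = dmrs[key + ["is_dmr"]].rename(columns={"is_dmr": "called_dmr"})
    joined = truth.merge(called, on=key, how="left")
    joined["called_dmr"] = joined["called_dmr"].fillna(False)
    _confusion(joined["is_dmr"], joined["called_dmr"]).to_csv(
        outdir / "confusion_dmrs.tsv", sep="\t", index=False)


def stage_integrate(config: PipelineConfig, outdir: Path) -> None:
    intervals = read_intervals(outdir / "annotation.gff3", "GFF3")
    genes = [iv for iv in intervals if iv.feature_class == "gene"]
    lncrnas = [iv for iv in intervals if iv.feature_class == "lncRNA"]
    expr = read_expression(outdir / "expression.tsv",
                           outdir / "expression_samples.tsv")
    pairs = cis_pairs(lncrnas, genes, config.cis_max_distance)
    scored, summary = correlate_pairs(pairs, expr)
    scored.to_csv(outdir / "cis_pairs.tsv", sep="\t", index=False)
    with open(outdir / "cis_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    acr_flags = pd.read_csv(outdir / "lncrna_annotation.tsv", sep="\t",
                            index_col="feature")
    acr_lnc = acr_flags.index[acr_flags["acr_lncrna"]]
    profiles = standardize_profiles(expr.cpm().values.loc[acr_lnc])
    c = min(config.n_clusters_fuzzy, max(len(profiles), 1))
    if len(profiles) >= c and len(profiles) > 0:
        fcm = fuzzy_cmeans(profiles, c=c, seed=config.seed)
        fcm["memberships"].assign(top_cluster=fcm["top_cluster"]).to_csv(
            outdir / "fuzzy_memberships.tsv", sep="\t", index_label="feature")


STAGES = [
    ("simulate", stage_simulate),
    ("annotate", stage_annotate),
    ("patterns", stage_patterns),
    ("dosage", stage_dosage),
    ("methylation", stage_methylation),
    ("integrate", stage_integrate),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, outdir: str | os.PathLike) -> Path:
    """Run every stage in dependency order and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        logger.info("stage %s", name)
        try:
            fn(config, outdir)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc
    cfg = config.to_dict()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return outdir
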