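"""Weighted methylation levels, metaprofiles, and 200-bp-bin DMR calling.

The weighted methylation level of a region is the total methylated read
count divided by the total read count over valid cytosines (per-site depth
of at least five reads) — not the mean of per-site ratios.  DMRs are called
on a 200-bp genome tiling per context (CG/CHG/CHH): bins need at least five
valid cytosines in both groups; pooled counts are compared by a two-sided
Fisher exact test with BH adjustment per context, and a DMR additionally
requires a methylation-level difference greater than 0.3 / 0.2 / 0.1 for
CG / CHG / CHH.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CONTEXTS, GenomicInterval, ValidationError, validate_methylation
from .dosage import bh_fdr

logger = logging.getLogger(__name__)

DEFAULT_DELTAS = {"CG": 0.3, "CHG": 0.2, "CHH": 0.1}


@dataclass
class DmrConfig:
    bin_size: int = 200
    min_cytosines: int = 5      # valid cytosines per bin, per group
    min_coverage: int = 5       # reads per cytosine for a valid site
    padj_threshold: float = 0.01   # strict <
    deltas: dict = field(default_factory=lambda: dict(DEFAULT_DELTAS))  # strict >
    merge_cg_strands: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValidationError("bin size must be positive")
        if any(not (0 < d < 1) for d in self.deltas.values()):
            raise ValidationError("deltas must lie in (0, 1)")


def _valid(records: pd.DataFrame, min_coverage: int) -> pd.DataFrame:
    return records[records["total"] >= min_coverage]


def merge_cg_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse symmetric CG sites: counts on the − strand are added to the
    + strand cytosine one base to the left; other contexts pass through."""
    cg = records["context"] == "CG"
    out = records.copy()
    out.loc[cg & (out["strand"] == "-"), "position"] -= 1
    grouped = (
        out.groupby(["chrom", "position", "context"], as_index=False)
        .agg(meth=("meth", "sum"), total=("total", "sum"))
    )
    grouped["strand"] = "+"
    if "sample" in records.columns and records["sample"].nunique() == 1:
        grouped["sample"] = records["sample"].iloc[0]
    return grouped


def weighted_level(
    records: pd.DataFrame,
    region: GenomicInterval,
    context: str,
    min_coverage: int = 5,
) -> dict:
    """Count-weighted methylation level of one region in one context.

    Returns ``{"level": float|nan, "n_sites": int, "meth": int, "total": int}``;
    the level is NaN when the region has no valid site.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    sel = records[
        (records["chrom"] == region.chrom)
        & (records["context"] == context)
        & (records["position"] >= region.start)
        & (records["position"] < region.end)
    ]
    sel = _valid(sel, min_coverage)
    meth, total = int(sel["meth"].sum()), int(sel["total"].sum())
    return {
        "level": meth / total if total else np.nan,
        "n_sites": len(sel),
        "meth": meth,
        "total": total,
    }


def metaprofile(
    regions: Sequence[GenomicInterval],
    records: pd.DataFrame,
    context: str,
    flank: int = 2000,
    flank_bin: int = 100,
    body_bins: int = 20,
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Flank/body/flank methylation profile pooled over regions.

    Layout: upstream ``flank`` bp in ``flank_bin``-bp bins, the body scaled
    to ``body_bins`` proportional bins, downstream ``flank`` bp.  Bins are
    strand-aware (upstream of a − region is its genomic right); per bin the
    level is the count-weighted pooled ratio across regions, so the
    count-weighted mean over all bins equals the global weighted level of
    the profiled windows.
    """
    n_flank = flank // flank_bin
    segments = (
        [("upstream", i) for i in range(n_flank)]
        + [("body", i) for i in range(body_bins)]
        + [("downstream", i) for i in range(n_flank)]
    )
    meth = {key: 0 for key in segments}
    total = {key: 0 for key in segments}
    ctx = _valid(
        records[records["context"] == context], min_coverage
    )
    by_chrom = dict(tuple(ctx.groupby("chrom")))
    for region in regions:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        minus = region.strand == "-"
        skip_body = len(region) < body_bins
        if skip_body:
            logger.info("region %s shorter than %d bp; flanks only",
                        region.feature_id, body_bins)
        window = sub[
            (sub["position"] >= region.start - flank)
            & (sub["position"] < region.end + flank)
        ]
        pos = window["position"].to_numpy()
        me = window["meth"].to_numpy()
        to = window["total"].to_numpy()
        for p, m_c, t_c in zip(pos, me, to):
            if p < region.start:
                off = p - (region.start - flank)
                seg, b = "upstream", off // flank_bin
            elif p >= region.end:
                off = p - region.end
                seg, b = "downstream", off // flank_bin
            else:
                if skip_body:
                    continue
                seg = "body"
                b = int((p - region.start) * body_bins // len(region))
            if minus:  # mirror the layout for − strand regions
                if seg == "upstream":
                    seg, b = "downstream", n_flank - 1 - b
                elif seg == "downstream":
                    seg, b = "upstream", n_flank - 1 - b
                else:
                    b = body_bins - 1 - b
            meth[(seg, b)] += m_c
            total[(seg, b)] += t_c
    rows = []
    for i, key in enumerate(segments):
        seg, b = key
        t = total[key]
        rows.append({
            "position": i, "segment": seg, "bin": b,
            "level": meth[key] / t if t else np.nan,
            "meth": meth[key], "total": t,
        })
    out = pd.DataFrame(rows)
    return out if regions else out.iloc[0:0]


def call_dmrs(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    config: DmrConfig | None = None,
) -> pd.DataFrame:
    """Call differentially methylated 200-bp bins between two groups.

    Returns one row per tested bin with pooled levels, the Fisher exact
    p-value, the BH-adjusted p-value (per context), the level difference,
    and the DMR verdict with its direction (hyper = group2 above group1).
    """
    config = config or DmrConfig()
    tabs = []
    for records in (group1, group2):
        validate_methylation(records) if "sample" in records.columns else None
        if config.merge_cg_strands:
            records = merge_cg_strands(records)
        v = _valid(records, config.min_coverage).copy()
        v["bin"] = v["position"] // config.bin_size
        tabs.append(
            v.groupby(["chrom", "bin", "context"]).agg(
                meth=("meth", "sum"), total=("total", "sum"), n=("position", "count")
            )
        )
    joined = tabs[0].join(tabs[1], how="inner", lsuffix="_1", rsuffix="_2")
    joined = joined[
        (joined["n_1"] >= config.min_cytosines)
        & (joined["n_2"] >= config.min_cytosines)
    ].reset_index()
    if joined.empty:
        return pd.DataFrame(columns=[
            "chrom", "start", "end", "context", "n_sites_1", "n_sites_2",
            "level_1", "level_2", "delta", "pvalue", "padj", "is_dmr", "direction",
        ])
    joined["level_1"] = joined["meth_1"] / joined["total_1"]
    joined["level_2"] = joined["meth_2"] / joined["total_2"]
    joined["delta"] = joined["level_2"] - joined["level_1"]
    pvals = np.empty(len(joined))
    for i, row in enumerate(joined.itertuples(index=False)):
        table = [
            [row.meth_1, row.total_1 - row.meth_1],
            [row.meth_2, row.total_2 - row.meth_2],
        ]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    joined["pvalue"] = pvals
    joined["padj"] = np.nan
    for ctx in joined["context"].unique():
        sel = joined["context"] == ctx
        joined.loc[sel, "padj"] = bh_fdr(joined.loc[sel, "pvalue"].to_numpy())
    delta_gate = joined["context"].map(config.deltas)
    joined["is_dmr"] = (
        (joined["padj"] < config.padj_threshold)
        & (joined["delta"].abs() > delta_gate)
    )
    joined["direction"] = np.where(joined["delta"] > 0, "hyper", "hypo")
    joined.loc[joined["delta"] == 0, "direction"] = "none"
    joined["start"] = joined["bin"] * config.bin_size
    joined["end"] = joined["start"] + config.bin_size
    out = joined.rename(columns={"n_1": "n_sites_1", "n_2": "n_sites_2"})
    return out[[
        "chrom", "start", "end", "context", "n_sites_1", "n_sites_2",
        "level_1", "level_2", "delta", "pvalue", "padj", "is_dmr", "direction",
    ]]


def compare_element_methylation(
    element_classes: Mapping[str, Sequence[GenomicInterval]],
    records: pd.DataFrame,
    min_coverage: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class, per-context region-level distributions plus a
    Kruskal–Wallis test across classes (skipped when < 2 classes have
    data)."""
    rows = []
    for cls, regions in element_classes.items():
        for region in regions:
            for ctx in CONTEXTS:
                res = weighted_level(records, region, ctx, min_coverage)
                if not np.isnan(res["level"]):
                    rows.append({"element_class": cls, "context": ctx,
                                 "region": region.feature_id, "level": res["level"]})
    levels = pd.DataFrame(rows, columns=["element_class", "context", "region", "level"])
    tests = []
    for ctx in CONTEXTS:
        sub = levels[levels["context"] == ctx]
        groups = [g["level"].to_numpy() for _, g in sub.groupby("element_class")]
        if len(groups) >= 2 and all(len(g) for g in groups):
            try:
                stat, p = stats.kruskal(*groups)
            except ValueError:  # all values identical across groups
                stat, p = np.nan, 1.0
            tests.append({"context": ctx, "statistic": stat, "pvalue": p})
    return levels, pd.DataFrame(tests, columns=["context", "statistic", "pvalue"])
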