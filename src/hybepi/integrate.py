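"""Cis/trans ncRNA–gene correlation layers, signal metaprofiles and fuzzy
c-means expression clustering.

Distance gates follow the stated phrasing: "within X kb" is inclusive
(edge distance <= X), the trans gate "> 5 kb" is strict (or a different
chromosome), and the trans co-expression gate is r² > 0.81 strict.  All
expression correlations are computed on log2(value + 1) across samples.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GenomicInterval, ValidationError


def cis_pairs(
    ncrnas: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    max_distance: int,
) -> pd.DataFrame:
    """All (ncRNA, gene) pairs with closest-edge distance <= max_distance
    on the same chromosome (0 when overlapping)."""
    rows = []
    for nc in ncrnas:
        for g in genes:
            d = nc.distance(g)
            if d is not None and d <= max_distance:
                rows.append({"ncrna": nc.feature_id, "gene": g.feature_id,
                             "distance": d})
    return pd.DataFrame(rows, columns=["ncrna", "gene", "distance"])


def _pair_correlations(
    pairs: pd.DataFrame,
    expression: ExpressionMatrix,
    left: str,
    right: str,
) -> pd.DataFrame:
    log = np.log2(expression.values + 1.0)
    out = pairs.copy()
    rs = []
    for row in pairs.itertuples(index=False):
        a, b = getattr(row, left), getattr(row, right)
        if a not in log.index or b not in log.index:
            raise ValidationError(f"pair ({a}, {b}) missing from expression matrix")
        x, y = log.loc[a].to_numpy(), log.loc[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(stats.pearsonr(x, y)[0]))
    out["r"] = rs
    out["r_squared"] = out["r"] ** 2
    return out


def correlate_pairs(
    pairs: pd.DataFrame, expression: ExpressionMatrix
) -> tuple[pd.DataFrame, dict]:
    """Pearson r per (ncrna, gene) pair plus a sign summary.

    The summary counts pairs with r > 0 and r < 0 (NaN r excluded) and the
    mean r over defined pairs.
    """
    scored = _pair_correlations(pairs, expression, "ncrna", "gene")
    defined = scored["r"].dropna()
    n = len(defined)
    summary = {
        "n_pairs": len(scored),
        "n_positive": int((defined > 0).sum()),
        "n_negative": int((defined < 0).sum()),
        "fraction_positive": float((defined > 0).sum() / n) if n else np.nan,
        "fraction_negative": float((defined < 0).sum() / n) if n else np.nan,
        "mean_r": float(defined.mean()) if n else np.nan,
    }
    return scored, summary


def trans_coexpression(
    lncrnas: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    expression: ExpressionMatrix,
    r2_min: float = 0.81,
    min_distance: int = 5000,
) -> pd.DataFrame:
    """Trans-regulatory candidates: pairs farther than ``min_distance``
    (strict, or on different chromosomes) with r² > ``r2_min`` (strict)."""
    rows = []
    for nc in lncrnas:
        for g in genes:
            d = nc.distance(g)
            if d is not None and d <= min_distance:
                continue
            rows.append({"ncrna": nc.feature_id, "gene": g.feature_id,
                         "distance": -1 if d is None else d})
    candidates = pd.DataFrame(rows, columns=["ncrna", "gene", "distance"])
    if candidates.empty:
        candidates["r"] = candidates["r_squared"] = []
        return candidates
    scored = _pair_correlations(candidates, expression, "ncrna", "gene")
    return scored[scored["r_squared"] > r2_min].reset_index(drop=True)


def signal_profile(
    targets: Sequence[GenomicInterval],
    signals: Sequence[tuple[GenomicInterval, float]],
    flank: int = 2000,
    flank_bin: int = 100,
    body_bins: int = 20,
) -> pd.DataFrame:
    """Flank/body/flank profile of weighted interval signal around targets.

    Each signal interval carries a weight (RPM/RPKM); the weight is split
    across bins proportionally to base overlap, so the total assigned
    weight equals the total signal weight falling inside the profiled
    windows.  Strand-aware like the methylation metaprofile.
    """
    n_flank = flank // flank_bin
    layout = (
        [("upstream", i) for i in range(n_flank)]
        + [("body", i) for i in range(body_bins)]
        + [("downstream", i) for i in range(n_flank)]
    )
    weight = {key: 0.0 for key in layout}
    for region in targets:
        minus = region.strand == "-"
        # genomic bin edges for this region's window
        edges: list[tuple[str, int, int, int]] = []
        for i in range(n_flank):
            s = region.start - flank + i * flank_bin
            edges.append(("upstream", i, s, s + flank_bin))
        for i in range(body_bins):
            s = region.start + i * len(region) // body_bins
            e = region.start + (i + 1) * len(region) // body_bins
            if e > s:
                edges.append(("body", i, s, e))
        for i in range(n_flank):
            s = region.end + i * flank_bin
            edges.append(("downstream", i, s, s + flank_bin))
        for sig, w in signals:
            if sig.chrom != region.chrom or len(sig) == 0:
                continue
            per_base = w / len(sig)
            for seg, b, s, e in edges:
                ov = max(0, min(e, sig.end) - max(s, sig.start))
                if not ov:
                    continue
                if minus:
                    if seg == "upstream":
                        key = ("downstream", n_flank - 1 - b)
                    elif seg == "downstream":
                        key = ("upstream", n_flank - 1 - b)
                    else:
                        key = ("body", body_bins - 1 - b)
                else:
                    key = (seg, b)
                weight[key] += per_base * ov
    rows = []
    for i, (seg, b) in enumerate(layout):
        rows.append({"position": i, "segment": seg, "bin": b,
                     "weight": weight[(seg, b)],
                     "mean_weight": weight[(seg, b)] / len(targets) if targets else np.nan})
    return pd.DataFrame(rows)


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardization (zero mean, unit variance) of an
    expression-profile matrix; zero-variance rows become all-zero."""
    x = profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((x - mu) / sd, index=profiles.index, columns=profiles.columns)


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 6,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
) -> dict:
    """Fuzzy c-means soft clustering (Bezdek) of expression profiles.

    Profiles should be standardized per feature beforehand
    (:func:`standardize_profiles`).  Memberships are initialized from a
    seeded random matrix; the objective Σ u_ij^m ||x_i − v_j||² is
    non-increasing across iterations.  Returns memberships (features × c,
    rows summing to 1), centroids (c × profile length), the objective
    history, and the top cluster per feature (ties broken by lowest
    cluster index).
    """
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if c < 1:
        raise ValidationError("need at least one cluster")
    if c > n:
        raise ValidationError(f"c={c} exceeds the number of features ({n})")
    if m <= 1:
        raise ValidationError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, c)) + 1e-9
    u /= u.sum(axis=1, keepdims=True)
    objective: list[float] = []
    for _ in range(max_iter):
        um = u ** m
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        objective.append(float((um * d2).sum()))
        d2c = np.maximum(d2, 1e-300)
        inv = d2c ** (-1.0 / (m - 1.0))
        new_u = inv / inv.sum(axis=1, keepdims=True)
        zero_hits = d2 <= 0
        rows_on_centroid = zero_hits.any(axis=1)
        if rows_on_centroid.any():
            new_u[rows_on_centroid] = 0.0
            for i in np.where(rows_on_centroid)[0]:
                hits = np.where(zero_hits[i])[0]
                new_u[i, hits] = 1.0 / len(hits)
        shift = np.abs(new_u - u).max()
        u = new_u
        if shift < tol:
            break
    um = u ** m
    centroids = (um.T @ x) / um.sum(axis=0)[:, None]
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    objective.append(float((um * d2).sum()))
    memberships = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster{j + 1}" for j in range(c)]
    )
    top = pd.Series(np.argmax(u, axis=1) + 1, index=profiles.index, name="top_cluster")
    return {
        "memberships": memberships,
        "centroids": centroids,
        "objective": objective,
        "top_cluster": top,
    }


def mirna_target_summary(
    target_pairs: pd.DataFrame, expression: ExpressionMatrix
) -> tuple[pd.DataFrame, dict]:
    """Correlate an externally predicted miRNA→target table.

    ``target_pairs`` needs columns ``mirna`` and ``target``; the table is
    consumed as given (prediction is out of scope here).
    """
    if target_pairs.empty:
        return target_pairs.assign(r=[], r_squared=[]), {
            "n_pairs": 0, "n_positive": 0, "n_negative": 0, "mean_r": np.nan,
        }
    pairs = target_pairs.rename(columns={"mirna": "ncrna", "target": "gene"})
    scored, summary = correlate_pairs(pairs, expression)
    scored = scored.rename(columns={"ncrna": "mirna", "gene": "target"})
    return scored, summary
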