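"""In-silico hybrids, pairwise differential tests, and additivity patterns.

Given maternal, paternal and hybrid expression with replicates, each feature
is classified into additive, maternal/paternal expression-level dominance
(ELD-M / ELD-P), transgressive-up/-down, no-change or ambiguous.  The call
is a pure function of four pairwise comparisons — hybrid vs maternal (HvsM),
hybrid vs paternal (HvsP), maternal vs paternal (MvsP), and hybrid vs the
mid-parent value (HvsMPV) — and a twelve-bin sign code over the first three
is always emitted so alternative groupings can be applied post hoc.

The built-in differential test is a two-sided Welch t-test on
log2(normalized value + 1) with Benjamini–Hochberg adjustment across
features; significance additionally requires |log2FC| at or above the
threshold (1.5 for transcripts/lncRNAs, 1.0 for small-RNA loci).
Externally produced DESeq2-style tables can be substituted through the same
record shape.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ValidationError

COMPARISONS = ("HvsM", "HvsP", "MvsP", "HvsMPV")

#: Rapp-style twelve-bin code from the sign triple
#: (sign HvsM, sign HvsP, sign MvsP), 0 meaning "not significant".
TWELVE_BINS = {
    (1, -1, -1): "I",    # M < H < P
    (0, -1, -1): "II",   # H = M < P
    (-1, -1, -1): "III",  # H < M < P
    (1, 0, -1): "IV",    # M < H = P
    (1, 1, -1): "V",     # H > both, M < P
    (1, 1, 0): "VI",     # H > both, M = P
    (-1, -1, 0): "VII",  # H < both, M = P
    (1, 1, 1): "VIII",   # H > both, M > P
    (-1, 0, 1): "IX",    # P = H < M
    (-1, -1, 1): "X",    # H < both, M > P
    (0, 1, 1): "XI",     # H = M > P
    (-1, 1, 1): "XII",   # P < H < M
}

PATTERN_LABELS = (
    "additive", "ELD-M", "ELD-P", "transgressive-up", "transgressive-down",
    "no-change", "ambiguous",
)


@dataclass(frozen=True)
class PatternCall:
    feature_id: str
    twelve_bin: str
    pattern: str


def make_insilico_hybrid(
    maternal: ExpressionMatrix,
    paternal: ExpressionMatrix,
    mode: str = "mean",
    seed: int | None = None,
    target_depth: int | None = None,
) -> ExpressionMatrix:
    """Build an in-silico hybrid by 1:1 merging of parental libraries.

    ``mean`` mode averages depth-normalized (counts-per-million) parental
    values per feature — the mid-parent value.  ``pooled-count`` mode
    subsamples each parental count library without replacement to half the
    target depth and sums them, so total depth is conserved exactly;
    deterministic given ``seed``.
    """
    if not maternal.values.index.equals(paternal.values.index):
        raise ValidationError("parental matrices must share the feature universe")
    m_samples = maternal.values.columns
    p_samples = paternal.values.columns
    n_pairs = min(len(m_samples), len(p_samples))
    cols, meta_rows = [], []
    if mode == "mean":
        m_norm = maternal.cpm().values
        p_norm = paternal.cpm().values
        for i in range(n_pairs):
            col = (m_norm[m_samples[i]] + p_norm[p_samples[i]]) / 2.0
            col.name = f"insilico_rep{i + 1}"
            cols.append(col)
            meta_rows.append({"generation": "insilico", "replicate": i + 1})
        unit = "RPM"
    elif mode == "pooled-count":
        if maternal.unit != "count" or paternal.unit != "count":
            raise ValidationError("pooled-count mode requires raw counts")
        rng = np.random.default_rng(seed)
        for i in range(n_pairs):
            m = maternal.values[m_samples[i]].round().astype(np.int64).to_numpy()
            p = paternal.values[p_samples[i]].round().astype(np.int64).to_numpy()
            depth = target_depth or min(int(m.sum()), int(p.sum()))
            half_m = depth // 2
            half_p = depth - half_m
            pooled = (
                rng.multivariate_hypergeometric(m, min(half_m, int(m.sum())))
                + rng.multivariate_hypergeometric(p, min(half_p, int(p.sum())))
            )
            col = pd.Series(pooled.astype(float), index=maternal.values.index,
                            name=f"insilico_rep{i + 1}")
            cols.append(col)
            meta_rows.append({"generation": "insilico", "replicate": i + 1})
        unit = "count"
    else:
        raise ValueError(f"unknown in-silico mode {mode!r}")
    values = pd.concat(cols, axis=1)
    meta = pd.DataFrame(meta_rows, index=values.columns)
    return ExpressionMatrix(values, meta, unit=unit, feature_meta=maternal.feature_meta)


def _log_values(matrix: ExpressionMatrix) -> pd.DataFrame:
    return np.log2(matrix.cpm().values + 1.0)


def pairwise_de(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    comparison: str = "AvsB",
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    moderate: bool = True,
) -> pd.DataFrame:
    """Two-group test per feature on log2(normalized value + 1).

    The default is a variance-moderated t-test (limma-style empirical
    Bayes: per-feature pooled variances are shrunk toward the across-
    feature mean with a fixed prior weight of 4 degrees of freedom), which
    stabilizes the few-replicate designs typical of these experiments;
    ``moderate=False`` gives a plain two-sided Welch test.  Returns a
    DESeq2-shaped table: feature, comparison, log2fc (A − B), pvalue,
    padj (BH across features) and a ``significant`` flag requiring both
    padj < alpha and |log2fc| ≥ lfc_threshold.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("built-in test needs >= 2 replicates per group")
    log = _log_values(matrix)
    a = log[group_a].to_numpy()
    b = log[group_b].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    if moderate:
        na, nb = a.shape[1], b.shape[1]
        da, db = na - 1, nb - 1
        s2 = (da * a.var(axis=1, ddof=1) + db * b.var(axis=1, ddof=1)) / (da + db)
        d0, s2_0 = 4.0, float(s2.mean())
        s2_tilde = (d0 * s2_0 + (da + db) * s2) / (d0 + da + db)
        se = np.sqrt(s2_tilde * (1.0 / na + 1.0 / nb))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = lfc / se
        pvals = 2.0 * stats.t.sf(np.abs(t), df=d0 + da + db)
        pvals = np.where(np.isnan(pvals), np.where(lfc == 0.0, 1.0, 0.0), pvals)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        # zero within-group variance: identical groups -> null; separated -> 0
        pvals = np.where(np.isnan(pvals), np.where(lfc == 0.0, 1.0, 0.0), pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "feature": matrix.features,
        "comparison": comparison,
        "log2fc": lfc,
        "pvalue": pvals,
        "padj": padj,
    })
    out["significant"] = (out["padj"] < alpha) & (out["log2fc"].abs() >= lfc_threshold)
    return out


def twelve_bin_code(s_hm: int, s_hp: int, s_mp: int) -> str:
    """Roman-numeral bin for a (HvsM, HvsP, MvsP) sign triple (0 = ns)."""
    return TWELVE_BINS.get((s_hm, s_hp, s_mp), "none")


def classify_pattern(
    feature_id: str,
    hvm: tuple[bool, float],
    hvp: tuple[bool, float],
    mvp: tuple[bool, float],
    hvmpv: tuple[bool, float],
    means: tuple[float, float, float] | None = None,
) -> PatternCall:
    """Grouped additivity pattern from four (significant, log2fc) verdicts.

    ``means`` is (hybrid, maternal, paternal) on the tested scale and is
    used for the between-parents check of the additive call; if omitted it
    is reconstructed from the comparison log-fold-changes.

    Precedence: no-change, transgressive (hybrid beyond both parents),
    ELD (hybrid matching exactly one parent), additive (parents differ,
    hybrid matches the mid-parent and lies between them), else ambiguous.
    ELD outranks additive because a hybrid sitting exactly on one parent
    can also be statistically compatible with the mid-parent when parental
    divergence is modest.
    """
    for name, v in (("HvsM", hvm), ("HvsP", hvp), ("MvsP", mvp), ("HvsMPV", hvmpv)):
        if v is None or len(v) != 2:
            raise ValidationError(f"{feature_id}: missing comparison {name}")
    sig_hm, lfc_hm = hvm
    sig_hp, lfc_hp = hvp
    sig_mp, lfc_mp = mvp
    sig_mpv, _ = hvmpv
    s_hm = int(np.sign(lfc_hm)) if sig_hm else 0
    s_hp = int(np.sign(lfc_hp)) if sig_hp else 0
    s_mp = int(np.sign(lfc_mp)) if sig_mp else 0
    code = twelve_bin_code(s_hm, s_hp, s_mp)

    if means is not None:
        h, m, p = means
    else:  # reconstruct relative positions from the log-fold-changes
        h, m, p = 0.0, -lfc_hm, -lfc_hp
    between = min(m, p) <= h <= max(m, p)

    if not (sig_hm or sig_hp or sig_mp):
        pattern = "no-change"
    elif sig_hm and sig_hp and s_hm == 1 and s_hp == 1:
        pattern = "transgressive-up"
    elif sig_hm and sig_hp and s_hm == -1 and s_hp == -1:
        pattern = "transgressive-down"
    elif not sig_hm and sig_hp:
        pattern = "ELD-M"
    elif not sig_hp and sig_hm:
        pattern = "ELD-P"
    elif sig_mp and not sig_mpv and between:
        pattern = "additive"
    else:
        pattern = "ambiguous"
    return PatternCall(feature_id, code, pattern)


def summarize_patterns(
    calls: pd.DataFrame, type_column: str | None = None
) -> pd.DataFrame:
    """Fraction of features per pattern (per feature type when given)."""
    if calls.empty:
        return pd.DataFrame(columns=["feature_type", "pattern", "count", "fraction"])
    df = calls.copy()
    df["feature_type"] = df[type_column] if type_column else "all"
    rows = []
    for ftype, grp in df.groupby("feature_type"):
        counts = grp["pattern"].value_counts()
        for pattern, count in counts.items():
            rows.append({
                "feature_type": ftype, "pattern": pattern,
                "count": int(count), "fraction": count / len(grp),
            })
    return pd.DataFrame(rows)


def hybrid_vs_insilico_correlation(
    hybrid: ExpressionMatrix,
    insilico: ExpressionMatrix,
    tpm_floor: float = 1.0,
) -> float:
    """Pearson r between hybrid and in-silico mean expression over expressed
    features (mean normalized value > tpm_floor in either matrix), computed
    on log2(value + 1)."""
    h = hybrid.cpm().values.mean(axis=1)
    i = insilico.cpm().values.mean(axis=1)
    common = h.index.intersection(i.index)
    h, i = h[common], i[common]
    expressed = (h > tpm_floor) | (i > tpm_floor)
    if expressed.sum() < 2:
        raise ValidationError("fewer than two expressed features")
    r, _ = stats.pearsonr(np.log2(h[expressed] + 1), np.log2(i[expressed] + 1))
    return float(r)


class PatternModel:
    """Additivity-pattern analysis of a three-generation expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Must contain maternal, paternal and hybrid samples with >= 2
        replicates each.
    lfc_threshold : float
        |log2FC| gate for significance (1.5 transcripts, 1.0 sRNA).
    alpha : float
        BH-adjusted p-value gate.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        lfc_threshold: float = 1.5,
        alpha: float = 0.05,
    ) -> None:
        self.matrix = matrix
        self.lfc_threshold = lfc_threshold
        self.alpha = alpha
        for gen in ("maternal", "paternal", "hybrid"):
            if len(matrix.samples_of(gen)) < 2:
                raise ValidationError(f"need >= 2 {gen} replicates")

    def fit(self, seed: int | None = None) -> "PatternResults":
        m = self.matrix
        mat, pat, hyb = (m.samples_of(g) for g in ("maternal", "paternal", "hybrid"))
        normed = m.median_ratio_normalized()
        insilico = make_insilico_hybrid(
            normed.subset(mat), normed.subset(pat), "mean", seed=seed
        )
        combined_values = pd.concat(
            [normed.cpm().values, insilico.values], axis=1
        )
        combined_meta = pd.concat([m.samples, insilico.samples])
        combined = ExpressionMatrix(combined_values, combined_meta, unit="RPM",
                                    feature_meta=m.feature_meta)
        ins = list(insilico.values.columns)
        de = pd.concat([
            pairwise_de(combined, hyb, mat, "HvsM", self.lfc_threshold, self.alpha),
            pairwise_de(combined, hyb, pat, "HvsP", self.lfc_threshold, self.alpha),
            pairwise_de(combined, mat, pat, "MvsP", self.lfc_threshold, self.alpha),
            pairwise_de(combined, hyb, ins, "HvsMPV", self.lfc_threshold, self.alpha),
        ], ignore_index=True)
        log = np.log2(combined.values + 1.0)
        means = pd.DataFrame({
            "hybrid": log[hyb].mean(axis=1),
            "maternal": log[mat].mean(axis=1),
            "paternal": log[pat].mean(axis=1),
        })
        wide = de.pivot(index="feature", columns="comparison",
                        values=["significant", "log2fc"])
        calls = []
        for fid in m.features:
            verdicts = {
                c: (bool(wide[("significant", c)][fid]), float(wide[("log2fc", c)][fid]))
                for c in COMPARISONS
            }
            mu = means.loc[fid]
            calls.append(classify_pattern(
                fid, verdicts["HvsM"], verdicts["HvsP"], verdicts["MvsP"],
                verdicts["HvsMPV"],
                means=(mu["hybrid"], mu["maternal"], mu["paternal"]),
            ))
        call_df = pd.DataFrame(
            [{"feature": c.feature_id, "twelve_bin": c.twelve_bin,
              "pattern": c.pattern} for c in calls]
        ).set_index("feature")
        return PatternResults(self, call_df, de, insilico)


class PatternResults:
    """Fitted pattern calls with the underlying differential tests."""

    def __init__(
        self,
        model: PatternModel,
        calls: pd.DataFrame,
        de: pd.DataFrame,
        insilico: ExpressionMatrix,
    ) -> None:
        self.model = model
        self.calls = calls
        self.de = de
        self.insilico = insilico

    def summary(self) -> pd.DataFrame:
        """Per-pattern counts and fractions."""
        return summarize_patterns(self.calls.reset_index())

    def __repr__(self) -> str:  # pragma: no cover
        top = self.calls["pattern"].value_counts().to_dict()
        return f"PatternResults({len(self.calls)} features: {top})"
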