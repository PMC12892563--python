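"""Annotation rules: boundary strictness and brute-force oracle agreement."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hybepi.annotate import (
    AnnotationConfig,
    LncRnaCandidate,
    call_acr_lncrna,
    call_activated_silenced,
    call_novel_acr_lncrna,
    categorize_location,
    classify_lncrna_locus,
    constitutive_flag,
    filter_lncrna_candidates,
    merge_replicate_acrs,
    te_association,
)
from hybepi.core import GenomicInterval, ValidationError

from _oracles import (
    brute_coverage_fraction,
    brute_location,
    brute_lncrna_class,
    brute_te_best,
    random_intervals,
)


def _candidate(**kw):
    defaults = dict(
        interval=GenomicInterval("chr1", 0, 500, "+", feature_id=kw.pop("fid", "c1"),
                                 feature_class="lncRNA"),
        length=500, class_code="u",
        noncoding_verdicts=(True, True, True),
        has_protein_domain=False, max_tpm=2.0,
    )
    defaults.update(kw)
    return LncRnaCandidate(**defaults)


class TestLncRnaFilter:
    def test_candidate_meeting_all_rules_is_retained(self):
        retained, report = filter_lncrna_candidates([_candidate()])
        assert len(retained) == 1
        assert report["retained"].all()

    @pytest.mark.parametrize("kw, reason", [
        (dict(class_code="="), "class_code"),
        (dict(noncoding_verdicts=(True, False, True)), "coding_potential"),
        (dict(has_protein_domain=True), "protein_domain"),
        (dict(length=200), "length"),  # rule is strictly "longer than 200"
        (dict(max_tpm=0.4), "expression_floor"),
    ])
    def test_first_failing_rule_is_recorded(self, kw, reason):
        retained, report = filter_lncrna_candidates([_candidate(**kw)])
        assert retained == []
        assert report.loc[0, "reason"] == reason

    def test_length_201_passes_the_length_gate(self):
        retained, _ = filter_lncrna_candidates([_candidate(length=201)])
        assert len(retained) == 1

    def test_missing_verdict_is_an_error(self):
        with pytest.raises(ValidationError, match="verdict"):
            filter_lncrna_candidates([_candidate(noncoding_verdicts=(True, None, True))])


def _gene_with_exons(start, strand="+", gid="g1"):
    gene = GenomicInterval("chr1", start, start + 3000, strand,
                           feature_id=gid, feature_class="gene")
    exons = [
        GenomicInterval("chr1", start + s, start + e, strand,
                        feature_id=f"{gid}.e{k}", feature_class="exon", parent=gid)
        for k, (s, e) in enumerate([(0, 600), (1200, 1800), (2400, 3000)])
    ]
    return gene, exons


class TestLncRnaClass:
    def test_opposite_strand_over_exon_is_antisense(self):
        gene, exons = _gene_with_exons(1000, "+")
        lnc = GenomicInterval("chr1", 1100, 1500, "-", feature_id="l",
                              feature_class="lncRNA")
        assert classify_lncrna_locus(lnc, [gene], exons) == "AS-lncRNA"

    def test_far_away_is_lincrna(self):
        gene, exons = _gene_with_exons(1000, "+")
        lnc = GenomicInterval("chr1", 14000, 14400, "+", feature_id="l",
                              feature_class="lncRNA")
        assert classify_lncrna_locus(lnc, [gene], exons) == "lincRNA"

    def test_inside_intron_same_strand_is_intronic(self):
        gene, exons = _gene_with_exons(1000, "-")
        lnc = GenomicInterval("chr1", 1650, 2150, "-", feature_id="l",
                              feature_class="lncRNA")
        assert classify_lncrna_locus(lnc, [gene], exons) == "intronic"

    def test_oracle_equivalence_on_random_loci(self, rng):
        genes, exons = [], []
        for i in range(20):
            g, ex = _gene_with_exons(int(rng.integers(0, 40000)),
                                     "+" if i % 2 else "-", gid=f"g{i}")
            genes.append(g)
            exons.extend(ex)
        lncs = random_intervals(rng, 200, classes=("lncRNA",))
        for lnc in lncs:
            assert classify_lncrna_locus(lnc, genes, exons) == \
                brute_lncrna_class(lnc, genes, exons)


class TestLocation:
    def test_one_bp_overlap_is_genic(self):
        gene = GenomicInterval("chr1", 100, 200, "+", feature_id="g",
                               feature_class="gene")
        f = GenomicInterval("chr1", 199, 300, ".", feature_id="f",
                            feature_class="siRNA_cluster")
        assert categorize_location(f, [gene]) == "genic"

    def test_gap_of_exactly_2000_is_distal(self):
        gene = GenomicInterval("chr1", 5000, 6000, "+", feature_id="g",
                               feature_class="gene")
        f = GenomicInterval("chr1", 2000, 3000, ".", feature_id="f",
                            feature_class="siRNA_cluster")
        assert categorize_location(f, [gene]) == "distal"
        nearer = GenomicInterval("chr1", 2001, 3001, ".", feature_id="f2",
                                 feature_class="siRNA_cluster")
        assert categorize_location(nearer, [gene]) == "proximal"

    def test_empty_gene_set_means_distal(self):
        f = GenomicInterval("chr1", 0, 10, ".", feature_id="f")
        assert categorize_location(f, []) == "distal"

    def test_oracle_equivalence_on_random_features(self, rng):
        genes = random_intervals(rng, 25, classes=("gene",))
        feats = random_intervals(rng, 500, classes=("siRNA_cluster",))
        for f in feats:
            assert categorize_location(f, genes) == brute_location(f, genes)


class TestTeAssociation:
    def test_no_tes_means_no_flags(self):
        feats = [GenomicInterval("chr1", 0, 100, "+", feature_id="f")]
        table = te_association(feats, [])
        assert not table["te_associated"].any()

    def test_largest_overlap_wins(self):
        f = GenomicInterval("chr1", 100, 300, "+", feature_id="f")
        dna = GenomicInterval("chr1", 80, 130, "+", feature_id="t1",
                              feature_class="TE")   # 30 bp overlap
        ltr = GenomicInterval("chr1", 200, 400, "+", feature_id="t2",
                              feature_class="TE")   # 100 bp overlap
        table = te_association([f], [dna, ltr], {"t1": "DNA", "t2": "LTR"})
        assert table.loc["f", "te_superfamily"] == "LTR"

    def test_oracle_equivalence_on_random_features(self, rng):
        tes = random_intervals(rng, 30, classes=("TE",))
        feats = random_intervals(rng, 300, classes=("lncRNA",))
        table = te_association(feats, tes)
        for f in feats:
            best, ov = brute_te_best(f, tes)
            assert table.loc[f.feature_id, "te_associated"] == (ov > 0)
            assert table.loc[f.feature_id, "te_overlap_bp"] == ov


def _peak(s, e, fid, rep=""):
    return GenomicInterval("chr1", s, e, ".", feature_id=f"{rep}{fid}",
                           feature_class="ACR")


class TestAcrMerge:
    def test_identical_replicates_reproduce_the_peaks(self):
        peaks = [_peak(100, 400, "a"), _peak(1000, 1600, "b")]
        rep2 = [_peak(100, 400, "a", "r2"), _peak(1000, 1600, "b", "r2")]
        merged = merge_replicate_acrs([peaks, rep2])
        assert [(m.start, m.end) for m in merged] == [(100, 400), (1000, 1600)]

    def test_overlap_of_exactly_50_bp_is_not_enough(self):
        a = [_peak(0, 100, "a")]
        b = [_peak(50, 200, "b")]       # overlap exactly 50 bp
        assert merge_replicate_acrs([a, b]) == []
        c = [_peak(49, 200, "c")]       # 51 bp
        assert len(merge_replicate_acrs([a, c])) == 1

    def test_single_replicate_decoys_are_dropped(self):
        shared = [_peak(0, 300, "s")]
        rep1 = shared + [_peak(5000, 5400, "decoy1")]
        rep2 = [_peak(10, 310, "s2"), _peak(9000, 9400, "decoy2")]
        merged = merge_replicate_acrs([rep1, rep2])
        assert len(merged) == 1
        assert merged[0].start == 0 and merged[0].end == 310

    def test_fewer_than_two_replicates_is_an_error(self):
        with pytest.raises(ValidationError):
            merge_replicate_acrs([[_peak(0, 100, "a")]])


class TestAcrLncrna:
    def test_fully_covered_in_all_replicates_is_flagged(self):
        lnc = GenomicInterval("chr1", 100, 300, "+", feature_id="l",
                              feature_class="lncRNA")
        reps = [[_peak(0, 500, "a", f"r{i}")] for i in range(3)]
        table = call_acr_lncrna([lnc], reps)
        assert bool(table.loc["l", "acr_lncrna"])

    def test_coverage_exactly_half_is_not_flagged(self):
        lnc = GenomicInterval("chr1", 0, 200, "+", feature_id="l",
                              feature_class="lncRNA")
        reps = [[_peak(0, 100, "a", f"r{i}")] for i in range(3)]  # exactly 50 %
        table = call_acr_lncrna([lnc], reps)
        assert not table.loc["l", "acr_lncrna"]

    def test_needs_two_supporting_replicates(self):
        lnc = GenomicInterval("chr1", 100, 300, "+", feature_id="l",
                              feature_class="lncRNA")
        reps = [[_peak(0, 500, "a", "r1")], [], []]
        table = call_acr_lncrna([lnc], reps)
        assert not table.loc["l", "acr_lncrna"]
        assert table.loc["l", "n_supporting_replicates"] == 1

    def test_coverage_fraction_matches_per_base_count(self, rng):
        for _ in range(100):
            start = int(rng.integers(0, 2000))
            lnc = GenomicInterval("chr1", start, start + int(rng.integers(50, 400)),
                                  "+", feature_id="l", feature_class="lncRNA")
            peaks = random_intervals(rng, 5, max_pos=3000, classes=("ACR",))
            table = call_acr_lncrna([lnc], [peaks, peaks])
            want = brute_coverage_fraction(lnc, peaks)
            assert np.isclose(table.loc["l", "max_coverage_fraction"], want)


class TestExpressionRules:
    def test_novel_acr_lncrna_boundaries(self):
        idx = ["a", "b", "c", "d"]
        hyb = pd.Series([0.6, 0.5, 0.6, 0.6], index=idx)
        mat = pd.Series([0.05, 0.05, 0.1, 0.05], index=idx)
        pat = pd.Series([0.02, 0.02, 0.02, 0.02], index=idx)
        flags = call_novel_acr_lncrna(hyb, mat, pat)
        # b: hybrid exactly 0.5 (strict >); c: maternal exactly 0.1 (strict <)
        assert flags.tolist() == [True, False, False, True]

    def test_activated_silenced_rules(self):
        idx = ["a", "b", "c", "d"]
        hyb = pd.Series([5, 1, 0, 3], index=idx)
        mat = pd.Series([0, 0, 3, 0], index=idx)
        pat = pd.Series([0, 0, 2, 1], index=idx)
        calls = call_activated_silenced(hyb, mat, pat)
        assert calls.tolist() == ["activated", "neither", "silenced", "neither"]

    def test_constitutive_requires_strictly_above_half(self):
        assert constitutive_flag(pd.Series([0.6, 0.6, 0.6])) is True
        assert constitutive_flag(pd.Series([0.6, 0.5, 0.6])) is False

    def test_constitutive_matches_row_min_oracle(self, rng):
        tpm = pd.DataFrame(rng.random((1000, 9)),
                           index=[f"g{i}" for i in range(1000)])
        flags = constitutive_flag(tpm)
        want = tpm.min(axis=1) > 0.5
        assert (flags == want).all()


@settings(deadline=None, derandomize=True)
@given(st.data())
def test_classifiers_are_exhaustive_and_exclusive(data):
    """Every lncRNA gets exactly one class, every feature one location."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    genes, exons = [], []
    for i in range(int(rng.integers(0, 6))):
        g, ex = _gene_with_exons(int(rng.integers(0, 20000)),
                                 "+" if i % 2 else "-", gid=f"g{i}")
        genes.append(g)
        exons.extend(ex)
    for lnc in random_intervals(rng, 10, max_pos=25000, classes=("lncRNA",)):
        cls = classify_lncrna_locus(lnc, genes, exons)
        assert cls in {"lincRNA", "AS-lncRNA", "intronic", "sense",
                       "overlapping-unstranded"}
        loc = categorize_location(lnc, genes)
        assert loc in {"genic", "proximal", "distal"}
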