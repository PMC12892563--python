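"""Cis/trans pairing, signal profiles, fuzzy c-means, miRNA summaries."""
import numpy as np
import pandas as pd
import pytest

from hybepi.core import GenomicInterval, ValidationError
from hybepi.integrate import (
    cis_pairs,
    correlate_pairs,
    fuzzy_cmeans,
    mirna_target_summary,
    signal_profile,
    standardize_profiles,
    trans_coexpression,
)

from _oracles import random_intervals
from conftest import make_matrix


def _iv(start, end, fid, cls="gene", strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand, feature_id=fid,
                           feature_class=cls)


def _expr(rows: dict, n_samples=6):
    values = {f"s{i}": [v[i] for v in rows.values()] for i in range(n_samples)}
    df = pd.DataFrame(values, index=list(rows))
    meta = pd.DataFrame({"generation": ["hybrid"] * n_samples,
                         "replicate": range(1, n_samples + 1)},
                        index=df.columns)
    from hybepi.core import ExpressionMatrix
    return ExpressionMatrix(df, meta, unit="TPM")


class TestCisPairs:
    def test_overlapping_pair_has_distance_zero(self):
        pairs = cis_pairs([_iv(100, 300, "n", "lncRNA")], [_iv(250, 500, "g")], 5000)
        assert pairs.loc[0, "distance"] == 0

    def test_distance_just_over_the_gate_is_excluded(self):
        nc = [_iv(0, 100, "n", "lncRNA")]
        assert len(cis_pairs(nc, [_iv(5100, 5200, "g")], 5000)) == 1  # gap 5000
        assert len(cis_pairs(nc, [_iv(5101, 5201, "g")], 5000)) == 0  # gap 5001

    def test_agreement_with_all_pairs_brute_force(self, rng):
        ncs = random_intervals(rng, 150, classes=("lncRNA",))
        genes = random_intervals(rng, 150, classes=("gene",))
        got = {(r.ncrna, r.gene) for r in
               cis_pairs(ncs, genes, 2000).itertuples(index=False)}
        want = set()
        for n in ncs:
            for g in genes:
                d = n.distance(g)
                if d is not None and d <= 2000:
                    want.add((n.feature_id, g.feature_id))
        assert got == want


class TestCorrelatePairs:
    def test_identical_rows_give_r_one(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6], "g": [1, 2, 3, 4, 5, 6]})
        pairs = pd.DataFrame({"ncrna": ["n"], "gene": ["g"], "distance": [0]})
        scored, summary = correlate_pairs(pairs, expr)
        assert scored.loc[0, "r"] == pytest.approx(1.0)
        assert summary["n_positive"] == 1

    def test_anti_ordered_rows_give_r_minus_one(self):
        up = [1.0, 3.0, 7.0, 15.0, 31.0, 63.0]       # log2(v+1) = 1..6
        down = up[::-1]
        expr = _expr({"n": up, "g": down})
        pairs = pd.DataFrame({"ncrna": ["n"], "gene": ["g"], "distance": [0]})
        scored, summary = correlate_pairs(pairs, expr)
        assert scored.loc[0, "r"] == pytest.approx(-1.0)
        assert summary["n_negative"] == 1

    def test_summary_matches_independent_tally(self, rng):
        rows = {f"f{i}": list(rng.random(6) * 10) for i in range(20)}
        expr = _expr(rows)
        pairs = pd.DataFrame({
            "ncrna": [f"f{i}" for i in range(10)],
            "gene": [f"f{i + 10}" for i in range(10)],
            "distance": 0,
        })
        scored, summary = correlate_pairs(pairs, expr)
        assert summary["n_positive"] == (scored["r"] > 0).sum()
        assert summary["n_negative"] == (scored["r"] < 0).sum()
        assert summary["mean_r"] == pytest.approx(scored["r"].mean())

    def test_missing_feature_is_an_error(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6]})
        pairs = pd.DataFrame({"ncrna": ["n"], "gene": ["absent"], "distance": [0]})
        with pytest.raises(ValidationError):
            correlate_pairs(pairs, expr)


class TestTransCoexpression:
    def test_perfectly_correlated_distant_pair_is_kept(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6], "g": [2, 4, 6, 8, 10, 12]})
        out = trans_coexpression([_iv(0, 100, "n", "lncRNA")],
                                 [_iv(20000, 20100, "g")], expr)
        assert len(out) == 1

    def test_r_squared_exactly_at_threshold_is_dropped(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6], "g": [2, 4, 6, 8, 10, 12]})
        out = trans_coexpression([_iv(0, 100, "n", "lncRNA")],
                                 [_iv(20000, 20100, "g")], expr, r2_min=1.0)
        assert out.empty  # r² == 1.0 is not > 1.0

    def test_nearby_pair_is_cis_territory(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6], "g": [2, 4, 6, 8, 10, 12]})
        out = trans_coexpression([_iv(0, 100, "n", "lncRNA")],
                                 [_iv(4100, 4200, "g")], expr)  # 4 kb away
        assert out.empty

    def test_different_chromosome_counts_as_trans(self):
        expr = _expr({"n": [1, 2, 3, 4, 5, 6], "g": [2, 4, 6, 8, 10, 12]})
        out = trans_coexpression([_iv(0, 100, "n", "lncRNA")],
                                 [_iv(0, 100, "g", chrom="chr2")], expr)
        assert len(out) == 1 and out.loc[0, "distance"] == -1


class TestSignalProfile:
    def test_uniform_signal_gives_flat_flanks(self):
        # one signal interval with uniform per-base weight across the window
        target = _iv(4000, 6000, "t", "lncRNA")
        sig = [(_iv(0, 10000, "s", "region"), 10000.0)]  # density 1 per base
        prof = signal_profile([target], sig)
        flanks = prof[prof["segment"] != "body"]
        assert np.allclose(flanks["weight"], 100.0)
        body = prof[prof["segment"] == "body"]
        assert np.allclose(body["weight"], 100.0)  # 2000/20 bases per bin

    def test_signal_only_upstream_leaves_body_and_downstream_empty(self):
        target = _iv(4000, 6000, "t", "lncRNA", strand="+")
        sig = [(_iv(2000, 4000, "s", "region"), 50.0)]
        prof = signal_profile([target], sig)
        assert prof.loc[prof["segment"] == "upstream", "weight"].sum() == \
            pytest.approx(50.0)
        assert prof.loc[prof["segment"] != "upstream", "weight"].sum() == 0

    def test_total_weight_is_conserved_inside_the_window(self, rng):
        targets = [_iv(10000, 13000, "t1", "lncRNA"),
                   _iv(30000, 31000, "t2", "lncRNA", strand="-")]
        signals = []
        for i in range(30):
            s = int(rng.integers(8000, 16000))
            signals.append((_iv(s, s + int(rng.integers(10, 400)), f"s{i}",
                                "region"), float(rng.random() * 20)))
        prof = signal_profile(targets, signals)
        want = 0.0
        for sig, w in signals:
            for t in targets:
                lo, hi = t.start - 2000, t.end + 2000
                ov = max(0, min(hi, sig.end) - max(lo, sig.start))
                want += w * ov / len(sig)
        assert prof["weight"].sum() == pytest.approx(want)


class TestFuzzyCmeans:
    def test_single_cluster_memberships_are_all_one(self, rng):
        profiles = pd.DataFrame(rng.random((10, 6)))
        out = fuzzy_cmeans(standardize_profiles(profiles), c=1, seed=0)
        assert np.allclose(out["memberships"].to_numpy(), 1.0)

    def test_two_separated_groups_are_recovered(self, rng):
        a = rng.normal(0, 0.1, size=(30, 8)) + np.linspace(-2, 2, 8)
        b = rng.normal(0, 0.1, size=(30, 8)) + np.linspace(2, -2, 8)
        profiles = pd.DataFrame(np.vstack([a, b]),
                                index=[f"f{i}" for i in range(60)])
        out = fuzzy_cmeans(standardize_profiles(profiles), c=2, seed=1)
        top = out["top_cluster"].to_numpy()
        agree = max((top[:30] == 1).sum() + (top[30:] == 2).sum(),
                    (top[:30] == 2).sum() + (top[30:] == 1).sum())
        assert agree >= 57  # >= 95 %

    def test_objective_is_monotone_non_increasing(self, rng):
        profiles = pd.DataFrame(rng.random((40, 9)))
        out = fuzzy_cmeans(standardize_profiles(profiles), c=4, seed=2)
        obj = np.array(out["objective"])
        assert (np.diff(obj) <= 1e-9).all()

    def test_memberships_are_a_partition(self, rng):
        profiles = pd.DataFrame(rng.random((25, 5)))
        out = fuzzy_cmeans(standardize_profiles(profiles), c=3, seed=3)
        u = out["memberships"].to_numpy()
        assert (u >= 0).all() and (u <= 1).all()
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_more_clusters_than_features_is_an_error(self, rng):
        profiles = pd.DataFrame(rng.random((3, 4)))
        with pytest.raises(ValidationError):
            fuzzy_cmeans(profiles, c=5, seed=0)

    def test_same_seed_reproduces_memberships(self, rng):
        profiles = standardize_profiles(pd.DataFrame(rng.random((20, 6))))
        a = fuzzy_cmeans(profiles, c=3, seed=42)
        b = fuzzy_cmeans(profiles, c=3, seed=42)
        assert np.array_equal(a["memberships"].to_numpy(),
                              b["memberships"].to_numpy())


class TestMirnaTargets:
    def test_empty_table_gives_empty_summary(self):
        expr = _expr({"m": [1, 2, 3, 4, 5, 6]})
        scored, summary = mirna_target_summary(
            pd.DataFrame(columns=["mirna", "target"]), expr)
        assert scored.empty and summary["n_pairs"] == 0

    def test_single_anticorrelated_pair_counts_negative(self):
        up = [1.0, 3.0, 7.0, 15.0, 31.0, 63.0]
        expr = _expr({"m": up, "g": up[::-1]})
        scored, summary = mirna_target_summary(
            pd.DataFrame({"mirna": ["m"], "target": ["g"]}), expr)
        assert summary["n_negative"] == 1
        assert scored.loc[0, "r"] == pytest.approx(-1.0)
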