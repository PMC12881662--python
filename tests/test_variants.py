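"""Variant filtering, SBS/DBS classification, weighted fractions, IMD, clusters."""

import numpy as np
import pandas as pd
import pytest

from uradna import variants
from uradna.variants import VARIANT_COLS

from conftest import make_track


def vset(*rows):
    """rows: (chrom, pos, ref, alt, af[, filter])"""
    rows = [r if len(r) == 6 else r + ("PASS",) for r in rows]
    return pd.DataFrame(rows, columns=VARIANT_COLS)


GENOME = {"c": "ACATGCAGTACCATGGACGTACGTTGCATCAA" * 10}


class TestFilter:
    def test_excluded_label_removed(self):
        v = vset(("c", 5, "C", "T", 0.5, "germline;slippage"))
        assert len(variants.filter_variants(v)) == 0

    def test_pass_kept(self):
        v = vset(("c", 5, "C", "T", 0.5, "PASS"))
        assert len(variants.filter_variants(v)) == 1

    def test_non_excluded_label_kept(self):
        v = vset(("c", 5, "C", "T", 0.5, "clustered_events"))
        assert len(variants.filter_variants(v)) == 1

    def test_hand_counted_fixture(self):
        rows = [("c", i, "C", "T", 0.5, f) for i, f in enumerate(
            ["PASS", "germline", "PASS", "base_qual;PASS", "PASS",
             "weak_evidence", "PASS", "PASS", "PASS", "PASS"])]
        out = variants.filter_variants(vset(*rows))
        assert len(out) == 7


class TestClassifySbs:
    def test_purine_ref_reverse_complemented(self):
        # genome ...T G C... at pos 3..5 -> G at 4; G>A collapses to C>T,
        # context TGC revcomps to GCA -> tri channel G[C>T]A
        genome = {"c": "AAATGCAAAA"}
        out = variants.classify_sbs(vset(("c", 4, "G", "A", 0.5)), genome)
        assert out["sbs_type"].iloc[0] == "C>T"
        assert out["tri"].iloc[0] == "GCA"

    def test_pyrimidine_ref_kept_forward(self):
        genome = {"c": "AAAACAAAAA"}
        out = variants.classify_sbs(vset(("c", 4, "C", "T", 0.5)), genome)
        assert out["sbs_type"].iloc[0] == "C>T"
        assert out["tri"].iloc[0] == "ACA"

    def test_reference_mismatch_raises(self):
        genome = {"c": "AAAACAAAAA"}
        with pytest.raises(ValueError, match="mismatch"):
            variants.classify_sbs(vset(("c", 4, "G", "A", 0.5)), genome)

    def test_strand_collapse_symmetry(self):
        """A record and its reverse-complement twin classify identically."""
        fwd = {"c": "AATTCAGGTT"}
        rev = {"c": "AACCTGAATT"}  # reverse complement sequence
        a = variants.classify_sbs(vset(("c", 4, "C", "G", 0.5)), fwd)
        b = variants.classify_sbs(vset(("c", 5, "G", "C", 0.5)), rev)
        assert a["sbs_type"].iloc[0] == b["sbs_type"].iloc[0]
        assert a["tri"].iloc[0] == b["tri"].iloc[0]
        assert a["penta"].iloc[0] == b["penta"].iloc[0]

    def test_chromosome_edge_keeps_type_drops_context(self):
        genome = {"c": "CAAAAAAAAA"}
        out = variants.classify_sbs(vset(("c", 0, "C", "T", 0.5)), genome)
        assert out["sbs_type"].iloc[0] == "C>T"
        assert out["tri"].iloc[0] is None


class TestWeightedFractions:
    def test_af_weighted_hand_value(self):
        v = vset(("c", 1, "C", "T", 0.5), ("c", 2, "C", "T", 0.3),
                 ("c", 3, "T", "A", 0.2))
        v["sbs_type"] = ["C>T", "C>T", "T>A"]
        out = variants.weighted_sbs_fractions(v)
        assert out.set_index("sbs_type").loc["C>T", "fraction"] == pytest.approx(0.8)

    def test_single_variant_fraction_one(self):
        v = vset(("c", 1, "C", "G", 0.1))
        v["sbs_type"] = ["C>G"]
        out = variants.weighted_sbs_fractions(v)
        assert out.set_index("sbs_type").loc["C>G", "fraction"] == 1.0

    def test_unweighted_mode_equals_count_fractions(self):
        rng = np.random.default_rng(0)
        v = vset(*[("c", i, "C", "T", rng.random()) for i in range(30)])
        v["sbs_type"] = rng.choice(variants.SBS_TYPES, 30)
        out = variants.weighted_sbs_fractions(v, weighted=False)
        counts = v["sbs_type"].value_counts()
        for rec in out.itertuples(index=False):
            assert rec.fraction == pytest.approx(counts.get(rec.sbs_type, 0) / 30)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        v = vset(*[("c", i, "C", "T", rng.random()) for i in range(50)])
        v["sbs_type"] = rng.choice(variants.SBS_TYPES, 50)
        assert variants.weighted_sbs_fractions(v)["fraction"].sum() == pytest.approx(1.0)

    def test_all_af_missing_raises(self):
        v = vset(("c", 1, "C", "T", np.nan))
        v["sbs_type"] = ["C>T"]
        with pytest.raises(ValueError):
            variants.weighted_sbs_fractions(v)


class TestIMD:
    def test_gaps_on_one_chromosome(self):
        v = vset(("c", 100, "C", "T", 0.5), ("c", 150, "C", "T", 0.5),
                 ("c", 1150, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        out = variants.intermutational_distances(v)
        assert out["imd"].tolist() == [50, 1000]

    def test_no_gap_across_chromosomes(self):
        v = vset(("c1", 100, "C", "T", 0.5), ("c2", 150, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        assert len(variants.intermutational_distances(v)) == 0

    def test_uniform_placement_mean_gap(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(10_000_000, 1000, replace=False))
        v = vset(*[("c", int(p), "C", "T", 0.5) for p in pos])
        v["sbs_type"] = "C>T"
        out = variants.intermutational_distances(v)
        assert out["imd"].mean() == pytest.approx(1e4, rel=0.1)


class TestClusters:
    def test_single_run_detected(self):
        v = vset(("c", 10, "C", "T", 0.5), ("c", 20, "C", "T", 0.5),
                 ("c", 30, "C", "T", 0.5), ("c", 5000, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        out = variants.cluster_variants(v, max_imd=100)
        assert out["pos"].tolist() == [10, 20, 30]
        assert out["cluster_id"].nunique() == 1

    def test_all_gaps_too_large(self):
        v = vset(("c", 0, "C", "T", 0.5), ("c", 500, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        assert len(variants.cluster_variants(v, max_imd=100)) == 0

    def test_infinite_imd_single_cluster_per_chromosome(self):
        v = vset(("c1", 0, "C", "T", 0.5), ("c1", 10**6, "C", "T", 0.5),
                 ("c2", 5, "C", "T", 0.5), ("c2", 10**7, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        out = variants.cluster_variants(v, max_imd=10**9)
        assert out["cluster_id"].nunique() == 2 and len(out) == 4

    def test_run_scan_oracle_on_random_positions(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(100_000, 300, replace=False))
        v = vset(*[("c", int(p), "C", "T", 0.5) for p in pos])
        v["sbs_type"] = "C>T"
        out = variants.cluster_variants(v, max_imd=150, min_size=2)
        # direct run-scan oracle
        member = set()
        run = [pos[0]]
        for p in pos[1:]:
            if p - run[-1] <= 150:
                run.append(p)
            else:
                if len(run) >= 2:
                    member.update(run)
                run = [p]
        if len(run) >= 2:
            member.update(run)
        assert set(out["pos"]) == member


class TestDBS:
    def test_cc_tt_doublet(self):
        genome = {"c": "AACCAAAAAA"}
        v = vset(("c", 2, "C", "T", 0.4), ("c", 3, "C", "T", 0.6))
        dbs, sbs_left = variants.detect_dbs(v)
        assert dbs["dbs_type"].tolist() == ["CC>TT"]
        assert len(sbs_left) == 0  # constituents removed in exclusive mode

    def test_gg_aa_collapses_to_cc_tt(self):
        v = vset(("c", 2, "G", "A", 0.4), ("c", 3, "G", "A", 0.6))
        dbs, _ = variants.detect_dbs(v)
        assert dbs["dbs_type"].tolist() == ["CC>TT"]

    def test_explicit_mnp_accepted(self):
        v = pd.DataFrame([("c", 2, "GG", "AA", 0.5, "PASS")], columns=VARIANT_COLS)
        dbs, _ = variants.detect_dbs(v)
        assert dbs["dbs_type"].tolist() == ["CC>TT"]

    def test_no_adjacent_pairs_empty(self):
        v = vset(("c", 2, "C", "T", 0.4), ("c", 10, "C", "T", 0.6))
        dbs, sbs_left = variants.detect_dbs(v)
        assert len(dbs) == 0 and len(sbs_left) == 2

    def test_triple_greedy_left_to_right(self):
        v = vset(("c", 2, "C", "T", 0.4), ("c", 3, "C", "T", 0.6),
                 ("c", 4, "C", "T", 0.2))
        dbs, sbs_left = variants.detect_dbs(v)
        assert len(dbs) == 1 and dbs["pos"].iloc[0] == 2
        assert sbs_left["pos"].tolist() == [4]

    def test_all_78_categories_canonical(self):
        # every doublet substitution maps into the canonical set, and the
        # map is invariant under reverse complement
        from itertools import product
        bases = "ACGT"
        n = 0
        for r1, r2 in product(bases, repeat=2):
            for a1, a2 in product(bases, repeat=2):
                if a1 == r1 or a2 == r2:
                    continue
                ref, alt = r1 + r2, a1 + a2
                lab = variants.canonical_dbs(ref, alt)
                rc = variants.canonical_dbs(variants.revcomp(ref),
                                            variants.revcomp(alt))
                assert lab in variants.DBS78_CATEGORIES and lab == rc
                n += 1
        assert n == 144  # 16 ref doublets x 9 alts


class TestStratifyByRt:
    def test_all_early(self):
        rt = make_track("c", [3.0] * 10, units="RT_score")
        v = vset(("c", 150, "C", "T", 0.5), ("c", 850, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        out = variants.stratify_by_rt(v, rt)
        assert set(out["rt_stratum"]) == {"early"}

    def test_boundary_value_is_middle(self):
        rt = make_track("c", [2.5, -2.5], units="RT_score")
        v = vset(("c", 50, "C", "T", 0.5), ("c", 150, "C", "T", 0.5))
        v["sbs_type"] = "C>T"
        out = variants.stratify_by_rt(v, rt)
        assert out["rt_stratum"].tolist() == ["middle", "middle"]

    def test_strata_partition_input(self):
        rng = np.random.default_rng(6)
        rt = make_track("c", rng.normal(0, 3, 100), units="RT_score")
        v = vset(*[("c", int(p), "C", "T", 0.5)
                   for p in rng.choice(20_000, 200, replace=False)])
        v["sbs_type"] = "C>T"
        out = variants.stratify_by_rt(v, rt)
        counts = out["rt_stratum"].value_counts()
        assert counts.sum() == 200
        assert set(counts.index) <= {"early", "middle", "late", "unassigned"}
        assert counts.get("unassigned", 0) == len(v[v["pos"] >= 10_000])


class TestFractionsBySegment:
    def test_single_label_reproduces_global(self):
        seg = pd.DataFrame([("c", 0, 10_000, "A")],
                           columns=["chrom", "start", "end", "label"])
        v = vset(("c", 10, "C", "T", 0.5), ("c", 20, "T", "A", 0.5))
        v["sbs_type"] = ["C>T", "T>A"]
        out = variants.fractions_by_segment(v, seg)
        assert out["C>T_fraction"].iloc[0] == pytest.approx(0.5)

    def test_label_restricted_target(self):
        seg = pd.DataFrame([("c", 0, 100, "A"), ("c", 100, 200, "B")],
                           columns=["chrom", "start", "end", "label"])
        v = vset(("c", 10, "C", "T", 0.5), ("c", 150, "T", "A", 0.5))
        v["sbs_type"] = ["C>T", "T>A"]
        out = variants.fractions_by_segment(v, seg).set_index("label")
        assert out.loc["A", "C>T_fraction"] == 1.0
        assert out.loc["B", "C>T_fraction"] == 0.0

    def test_unassigned_bucket(self):
        seg = pd.DataFrame([("c", 0, 100, "A")],
                           columns=["chrom", "start", "end", "label"])
        v = vset(("c", 500, "C", "T", 0.5))
        v["sbs_type"] = ["C>T"]
        out = variants.fractions_by_segment(v, seg)
        assert "unassigned" in set(out["label"])
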