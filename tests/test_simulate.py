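"""Synthetic-data generators: determinism, composition bounds, truth round trips."""

import io

import numpy as np
import pandas as pd
import pytest

from uradna import simulate, spectra, tracks, variants


class TestGenerateGenome:
    def test_length_contract(self):
        g = simulate.generate_genome({"chr1": 1_000_000, "chr2": 1_000_000},
                                     0.41, 0.0, seed=7)
        assert {c: len(s) for c, s in g.seqs.items()} == \
            {"chr1": 1_000_000, "chr2": 1_000_000}

    def test_seed_determinism_byte_identical(self, tmp_path):
        a = simulate.generate_genome({"chr1": 50_000}, 0.41, 0.05, seed=7)
        b = simulate.generate_genome({"chr1": 50_000}, 0.41, 0.05, seed=7)
        fa, fb = tmp_path / "a.fa", tmp_path / "b.fa"
        a.write_fasta(fa)
        b.write_fasta(fb)
        assert fa.read_bytes() == fb.read_bytes()

    def test_gc_fraction_within_binomial_bound(self):
        # 6 sigma at n=1e6, p=0.6: +-~0.003, spec band is +-0.02
        g = simulate.generate_genome({"chr1": 1_000_000}, 0.60, 0.0, seed=3)
        s = g["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert 0.58 <= gc <= 0.62

    def test_mask_runs_written_as_n(self):
        g = simulate.generate_genome({"chr1": 100_000}, 0.5, 0.1, seed=5)
        for rec in g.mask.itertuples(index=False):
            assert set(g[rec.chrom][rec.start:rec.end]) == {"N"}
        n_total = g["chr1"].count("N")
        assert n_total == (g.mask["end"] - g.mask["start"]).sum()
        assert n_total == pytest.approx(10_000, rel=0.05)

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            simulate.generate_genome({"chr1": 0}, 0.5, 0.0, seed=1)


class TestGenerateGenes:
    def test_count_and_bounds(self, small_genome):
        genes = simulate.generate_genes(small_genome, 30, (1000, 2000),
                                        1000, seed=3)
        assert len(genes) == 30
        sizes = small_genome.chrom_sizes
        for g in genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]

    def test_non_nested_gene_bodies(self, small_genome):
        genes = simulate.generate_genes(small_genome, 30, (1000, 2000),
                                        1000, seed=3)
        by_chrom = {}
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            prev = by_chrom.get(g.chrom)
            if prev is not None:
                assert g.start >= prev
            by_chrom[g.chrom] = g.end

    def test_single_class_weight(self, small_genome):
        genes = simulate.generate_genes(
            small_genome, 10, (1000, 2000), 1000,
            class_weights={"protein_coding": 1.0}, seed=4)
        assert {g.class_label for g in genes} == {"protein_coding"}

    def test_class_weight_binomial_bound(self):
        # 10,000 draws at weight 0.1: 5 sigma band is [850, 1150]
        big = simulate.generate_genome({"chr1": 200_000}, 0.5, 0.0, seed=9)
        rng = np.random.default_rng(10)
        # draw labels through the same categorical machinery at scale
        w = {"protein_coding": 0.9, "pseudogene": 0.1}
        classes = list(w)
        p = np.array(list(w.values()))
        draws = [classes[rng.choice(len(classes), p=p)] for _ in range(10_000)]
        count = draws.count("pseudogene")
        assert 850 <= count <= 1150

    def test_infeasible_request_rejected(self, small_genome):
        with pytest.raises(ValueError, match="fit"):
            simulate.generate_genes(small_genome, 10_000, (5000, 10_000),
                                    1000, seed=1)


class TestEnrichmentTracks:
    def test_single_label_cv_zero(self, small_genome):
        seg = pd.DataFrame([(c, 0, n, "A") for c, n in
                            small_genome.chrom_sizes.items()],
                           columns=["chrom", "start", "end", "label"])
        reps = simulate.generate_enrichment_tracks(
            {"A": 700.0}, seg, small_genome.chrom_sizes,
            n_replicates=1, replicate_cv=0.0, seed=2)
        r = reps[0]
        assert np.allclose(r.rate_track.values, 700.0)
        assert r.global_content == pytest.approx(700.0)
        assert np.allclose(r.ratio_track.values, 1.0)

    def test_two_equal_halves_mean(self):
        g = simulate.generate_genome({"chr1": 100_000}, 0.5, 0.0, seed=1)
        seg = pd.DataFrame([("chr1", 0, 50_000, "A"), ("chr1", 50_000, 100_000, "B")],
                           columns=["chrom", "start", "end", "label"])
        reps = simulate.generate_enrichment_tracks(
            {"A": 100.0, "B": 900.0}, seg, g.chrom_sizes,
            n_replicates=1, replicate_cv=0.0, seed=2)
        assert reps[0].global_content == pytest.approx(500.0)

    def test_replicate_cv_lognormal_moments(self):
        g = simulate.generate_genome({"chr1": 1_000_000}, 0.5, 0.0, seed=1)
        seg = pd.DataFrame([("chr1", 0, 1_000_000, "A")],
                           columns=["chrom", "start", "end", "label"])
        reps = simulate.generate_enrichment_tracks(
            {"A": 700.0}, seg, g.chrom_sizes, n_replicates=1,
            replicate_cv=0.2, seed=2)
        v = reps[0].rate_track.values
        assert v.std() / v.mean() == pytest.approx(0.2, abs=0.03)

    def test_content_equals_lengthweighted_mean_rate(self, small_genome, segmentation):
        reps = simulate.generate_enrichment_tracks(
            {"L0": 300.0, "L1": 700.0, "L2": 1100.0}, segmentation,
            small_genome.chrom_sizes, n_replicates=2, replicate_cv=0.1, seed=5)
        for r in reps:
            assert r.rate_track.weighted_mean() == pytest.approx(
                r.global_content, rel=1e-9)

    def test_ptrack_rescale_recovers_truth_rates(self, small_genome, segmentation):
        rep = simulate.generate_enrichment_tracks(
            {"L0": 300.0, "L1": 700.0, "L2": 1100.0}, segmentation,
            small_genome.chrom_sizes, n_replicates=1, replicate_cv=0.1, seed=6)[0]
        p = tracks.rescale_to_ptrack(rep.ratio_track, rep.global_content)
        assert np.allclose(p.values, rep.rate_track.values)


class TestRtTrack:
    def test_noise_free_label_means(self, small_genome, segmentation):
        rt = simulate.generate_rt_track(segmentation, {"L0": 3.0, "L1": 0.0,
                                                       "L2": -3.0},
                                        small_genome.chrom_sizes, 0.0, seed=1)
        assert set(np.round(rt.values, 9)) <= {3.0, 0.0, -3.0}

    def test_seed_determinism(self, small_genome, segmentation):
        kw = dict(noise_sd=0.5, bin_size=100, seed=4)
        a = simulate.generate_rt_track(segmentation, {"L0": 3.0, "L1": 0.0,
                                                      "L2": -3.0},
                                       small_genome.chrom_sizes, **kw)
        b = simulate.generate_rt_track(segmentation, {"L0": 3.0, "L1": 0.0,
                                                      "L2": -3.0},
                                       small_genome.chrom_sizes, **kw)
        assert a.bins.equals(b.bins)


@pytest.fixture(scope="module")
def comps():
    return {"ap": simulate.tc_biased_ct_spectrum(),
            "flat": simulate.flat_spectrum()}


class TestGenerateVariants:
    MIX = {"ap": 0.6, "flat": 0.4}

    def test_pure_ct_component_yields_only_ct(self, small_genome):
        comp = {"tcn": simulate.flat_spectrum("C>T")}
        vs = simulate.generate_variants(small_genome, 200, {"tcn": 1.0}, comp,
                                        seed=3)
        assert set(vs.truth["sbs_type"]) == {"C>T"}

    def test_unclustered_median_imd_large(self):
        g = simulate.generate_genome({"chr1": 10_000_000}, 0.45, 0.0, seed=2)
        vs = simulate.generate_variants(g, 1000, {"f": 1.0},
                                        {"f": simulate.flat_spectrum("C>T")},
                                        cluster_fraction=0.0, seed=4)
        pos = np.sort(vs.truth["pos"].to_numpy())
        assert np.median(np.diff(pos)) > 1000

    def test_truth_ref_matches_genome(self, small_genome, comps):
        vs = simulate.generate_variants(small_genome, 300, self.MIX, comps,
                                        cluster_fraction=0.2, seed=5)
        for rec in vs.truth.itertuples(index=False):
            assert small_genome[rec.chrom][rec.pos] == rec.ref

    def test_truth_channels_equal_sbs96_roundtrip(self, small_genome, comps):
        vs = simulate.generate_variants(small_genome, 300, self.MIX, comps,
                                        cluster_fraction=0.2, seed=5)
        sbs = variants.classify_sbs(vs.truth, small_genome)
        m = spectra.sbs96_matrix(sbs)
        truth_counts = np.zeros(96)
        for ch in vs.truth["channel"]:
            truth_counts[spectra.SBS96_CHANNELS.index(ch)] += 1
        assert np.array_equal(m.values, truth_counts)

    def test_vcf_round_trip(self, small_genome, comps, tmp_path):
        vs = simulate.generate_variants(small_genome, 100, self.MIX, comps,
                                        seed=6)
        path = tmp_path / "v.vcf"
        vs.write_vcf(path, small_genome.chrom_sizes)
        back = variants.read_vcf(path)
        assert back["pos"].tolist() == vs.truth["pos"].tolist()
        assert back["ref"].tolist() == vs.truth["ref"].tolist()
        assert np.allclose(back["af"], vs.truth["af"], atol=1e-6)
        assert (back["filter"] == "PASS").all()

    def test_cluster_gaps_within_imd(self, small_genome, comps):
        vs = simulate.generate_variants(small_genome, 400, self.MIX, comps,
                                        cluster_fraction=0.3, cluster_imd=80,
                                        seed=7)
        cl = vs.truth[vs.truth["in_cluster"]]
        assert len(cl) > 0
        sbs = cl.sort_values(["chrom", "pos"])
        # successive gaps inside each generated run are within [2, 80]
        for _, grp in sbs.groupby("chrom"):
            gaps = np.diff(grp["pos"].to_numpy())
            runs = gaps[gaps <= 80]
            assert (runs >= 2).all()

    def test_seed_determinism(self, small_genome, comps):
        a = simulate.generate_variants(small_genome, 150, self.MIX, comps, seed=8)
        b = simulate.generate_variants(small_genome, 150, self.MIX, comps, seed=8)
        assert a.truth.equals(b.truth)
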