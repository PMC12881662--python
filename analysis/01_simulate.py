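#!/usr/bin/env python
"""Generate the synthetic study dataset every later analysis step consumes.

Emulates the statistical structure of a two-treatment uracil-DNA-seq
experiment: a 700-kb two-chromosome genome (2% hard-masked), a 4-label
segmentation, two enrichment replicates per treatment where treatment A
doubles the uracilation rate of segment label L3, a replication-timing
track correlated with the labels, gene annotations, and ~3,000 somatic SBS
drawn 60:40 from an APOBEC-like TC-biased C>T signature and a flat
background, 15% of C>T events in kataegis-like clusters (gaps <= 80 bp).

Writes plain-text files under --datadir (default scratch/analysis_data).
"""

import argparse
import json
from pathlib import Path

from uradna import simulate, tracks

LABELS = ["L0", "L1", "L2", "L3"]
LABEL_RATES = {lab: 700.0 * (0.4 + 0.4 * i) for i, lab in enumerate(LABELS)}
RT_MEANS = {"L0": 3.0, "L1": 1.0, "L2": -1.0, "L3": -3.0}
BOOST_LABEL, BOOST_FACTOR = "L3", 2.0
MIX = {"apobec_like": 0.6, "flat": 0.4}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("scratch/analysis_data"))
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()
    d = args.datadir
    d.mkdir(parents=True, exist_ok=True)

    genome = simulate.generate_genome({"chr1": 400_000, "chr2": 300_000},
                                      gc_fraction=0.41, hardmask_fraction=0.02,
                                      seed=args.seed)
    genome.write_fasta(d / "genome.fa")
    genome.write_chrom_sizes(d / "chrom.sizes")
    genome.write_mask_bed(d / "hardmask.bed")

    seg = simulate.make_segmentation(genome.chrom_sizes, LABELS, seg_len=50_000,
                                     seed=args.seed + 1)
    seg.to_csv(d / "segmentation.bed", sep="\t", header=False, index=False)

    genes = simulate.generate_genes(genome, 100, (1500, 4000), 1000,
                                    class_weights={"protein_coding": 0.7,
                                                   "pseudogene": 0.15,
                                                   "lncRNA": 0.15},
                                    seed=args.seed + 2)
    simulate.write_gene_table(genes, d / "genes.tsv")

    boosted = dict(LABEL_RATES)
    boosted[BOOST_LABEL] *= BOOST_FACTOR
    contents = {}
    for name, rates, sub in (("A", boosted, 3), ("B", LABEL_RATES, 4)):
        reps = simulate.generate_enrichment_tracks(
            rates, seg, genome.chrom_sizes, n_replicates=2, replicate_cv=0.08,
            seed=args.seed + sub)
        for i, r in enumerate(reps, 1):
            tracks.write_bedgraph(r.ratio_track, d / f"ratio_{name}_rep{i}.bdg")
            contents[f"{name}_rep{i}"] = r.global_content
    with open(d / "global_content.json", "w") as fh:
        json.dump(contents, fh, indent=2)

    rt = simulate.generate_rt_track(seg, RT_MEANS, genome.chrom_sizes,
                                    noise_sd=0.3, seed=args.seed + 5)
    tracks.write_bedgraph(rt, d / "rt.bdg")

    comps = {"apobec_like": simulate.tc_biased_ct_spectrum(),
             "flat": simulate.flat_spectrum()}
    vsim = simulate.generate_variants(genome, 3000, MIX, comps,
                                      cluster_fraction=0.15, cluster_imd=80,
                                      seed=args.seed + 6)
    vsim.write_vcf(d / "variants.vcf", genome.chrom_sizes)
    vsim.write_truth(d / "variant_truth.tsv")

    print(f"dataset written to {d}")
    print(f"  genome: {sum(genome.chrom_sizes.values()):,} bp, "
          f"{len(genome.mask)} masked runs")
    print(f"  genes: {len(genes)}; segments: {len(seg)} ({len(LABELS)} labels)")
    print(f"  global uracil content (U/Mb): "
          + ", ".join(f"{k}={v:.0f}" for k, v in contents.items()))
    print(f"  variants: {len(vsim.truth)} "
          f"({int(vsim.truth.in_cluster.sum())} in clusters)")


if __name__ == "__main__":
    main()
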