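#!/usr/bin/env python
"""Somatic substitution spectra: AF-weighted fractions, stratification, refit.

Filters the called variants, collapses SBS onto the pyrimidine strand,
computes allele-frequency-weighted six-type fractions (globally, by
replication-timing stratum, and by segment label), builds the 96-channel
trinucleotide spectrum, and refits it as a non-negative mixture of the
known generator signatures, reporting contributions and cosine similarity.
"""

import argparse
from pathlib import Path

from pyfaidx import Fasta

from uradna import segments, simulate, spectra, tracks, variants
from uradna.spectra import SpectrumVector


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("scratch/analysis_data"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    genome = Fasta(str(args.datadir / "genome.fa"))
    vdf = variants.filter_variants(variants.read_vcf(args.datadir / "variants.vcf"))
    sbs = variants.classify_sbs(vdf, genome)

    frac = variants.weighted_sbs_fractions(sbs)
    frac.to_csv(args.results / "sbs_fractions.tsv", sep="\t", index=False)

    rt = tracks.read_bedgraph(args.datadir / "rt.bdg", units="RT_score")
    strat = variants.stratify_by_rt(sbs, rt)
    rows = []
    for stratum, grp in strat.groupby("rt_stratum"):
        f = variants.weighted_sbs_fractions(grp).set_index("sbs_type")
        rows.append((stratum, len(grp), f.loc["C>T", "fraction"]))
    import pandas as pd
    by_rt = pd.DataFrame(rows, columns=["rt_stratum", "n", "ct_fraction"])
    by_rt.to_csv(args.results / "ct_fraction_by_rt.tsv", sep="\t", index=False)

    seg = segments.read_segmentation(args.datadir / "segmentation.bed")
    by_seg = variants.fractions_by_segment(sbs, seg)
    by_seg.to_csv(args.results / "ct_fraction_by_segment.tsv", sep="\t",
                  index=False)

    m96 = spectra.sbs96_matrix(sbs, af_weighted=True)
    spectra.write_spectrum_tsv(m96, args.results / "spectrum_sbs96_weighted.tsv")
    dbs, _ = variants.detect_dbs(sbs)
    d78 = spectra.dbs78_matrix(dbs)

    comps = {"apobec_like": SpectrumVector("SBS96", simulate.tc_biased_ct_spectrum()),
             "flat": SpectrumVector("SBS96", simulate.flat_spectrum())}
    refit = spectra.refit_spectrum(m96, comps)
    refit.to_frame().to_csv(args.results / "refit_contributions.tsv", sep="\t",
                            index=False)

    print(f"filtered SBS: {len(sbs)}; doublets: {int(d78.values.sum())} "
          f"(top DBS channel: "
          f"{d78.channels[int(d78.values.argmax())] if d78.values.sum() else '-'})")
    print("AF-weighted six-type fractions:")
    print(frac.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nC>T fraction by replication-timing stratum:")
    print(by_rt.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("\nC>T fraction by segment label:")
    print(by_seg.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nrefit: contributions "
          + ", ".join(f"{n}={c:.3f}" for n, c in
                      zip(refit.component_names, refit.contributions))
          + f"; cosine measured~reconstituted = {refit.cosine:.4f}")


if __name__ == "__main__":
    main()
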