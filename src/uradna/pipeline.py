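"""End-to-end orchestration of the synthetic demonstration run.

``run_pipeline`` drives all stages on generated data: simulate -> tracks ->
U-scores -> differential calling -> variants -> spectra -> hairpins ->
segment statistics, writing TSV outputs and a JSON manifest (seed,
parameter echo, per-stage row counts) from which every output is
re-derivable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hairpin, segments, simulate, spectra, tracks, uscore, variants

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the demonstration pipeline with study-anchored defaults."""

    outdir: str = "uradna_run"
    seed: int = 0

    # genome / annotation
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 400_000, "chr2": 300_000})
    gc_fraction: float = 0.41
    hardmask_fraction: float = 0.02
    n_genes: int = 100
    gene_length_range: tuple = (1500, 4000)
    promoter_len: int = 1000

    # enrichment simulation
    n_labels: int = 4
    label_rates: dict | None = None     # label -> U/Mb; default spread around ~700
    replicate_cv: float = 0.08
    n_replicates: int = 2
    bin_size: int = 100
    boost_label: str | None = "L3"      # label uracilated k-fold in group A
    boost_factor: float = 2.0

    # variants
    n_variants: int = 3000
    cluster_fraction: float = 0.15
    cluster_imd: int = 80
    af_model: tuple = simulate.DEFAULT_AF_MODEL

    # analysis thresholds
    top_n: int = 50
    fc_thresh: float = 1.5
    p_thresh: float = 0.05
    rt_thresholds: tuple = (2.5, -2.5)
    max_imd: int = 100
    min_stem: int = 4
    loop_range: tuple = (3, 6)
    flank: int = 15
    excluded_labels: tuple = tuple(sorted(variants.EXCLUDED_LABELS))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic demonstration; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    manifest: dict = {"seed": rng_seed, "parameters": asdict(config), "stages": {}}

    current = ["simulate"]

    def begin(name: str):
        current[0] = name

    def stage(name, result: dict):
        manifest["stages"][name] = result
        log.info("stage %s: %s", name, result)

    try:
        return _run_stages(config, out, rng_seed, manifest, begin, stage)
    except Exception as exc:  # halt with the stage name attached
        raise RuntimeError(f"pipeline stage {current[0]!r} failed: {exc}") from exc


def _run_stages(config, out, rng_seed, manifest, begin, stage) -> dict:
    # --- simulate ----------------------------------------------------------
    begin("simulate")
    genome = simulate.generate_genome(config.chrom_lengths, config.gc_fraction,
                                      config.hardmask_fraction, seed=rng_seed)
    labels = [f"L{i}" for i in range(config.n_labels)]
    label_rates = config.label_rates or {
        lab: 700.0 * (0.4 + 0.4 * i) for i, lab in enumerate(labels)}
    seg = simulate.make_segmentation(genome.chrom_sizes, labels, seed=rng_seed + 1)
    genes = simulate.generate_genes(genome, config.n_genes,
                                    length_range=tuple(config.gene_length_range),
                                    promoter_len=config.promoter_len,
                                    class_weights={"protein_coding": 0.7,
                                                   "pseudogene": 0.15,
                                                   "lncRNA": 0.15},
                                    seed=rng_seed + 2)
    boosted = dict(label_rates)
    if config.boost_label and config.boost_label in boosted:
        boosted[config.boost_label] *= config.boost_factor
    reps_a = simulate.generate_enrichment_tracks(
        boosted, seg, genome.chrom_sizes, config.n_replicates,
        config.replicate_cv, config.bin_size, seed=rng_seed + 3)
    reps_b = simulate.generate_enrichment_tracks(
        label_rates, seg, genome.chrom_sizes, config.n_replicates,
        config.replicate_cv, config.bin_size, seed=rng_seed + 4)
    rt_means = {lab: 3.0 - 6.0 * i / max(1, len(labels) - 1)
                for i, lab in enumerate(labels)}
    rt_track = simulate.generate_rt_track(seg, rt_means, genome.chrom_sizes,
                                          noise_sd=0.3, bin_size=config.bin_size,
                                          seed=rng_seed + 5)
    mix = {"apobec_like": 0.6, "flat": 0.4}
    comps = {"apobec_like": simulate.tc_biased_ct_spectrum(),
             "flat": simulate.flat_spectrum()}
    vsim = simulate.generate_variants(genome, config.n_variants, mix, comps,
                                      config.cluster_fraction, config.cluster_imd,
                                      config.af_model, seed=rng_seed + 6)
    genome.write_fasta(out / "genome.fa")
    genome.write_mask_bed(out / "hardmask.bed")
    seg.to_csv(out / "segmentation.bed", sep="\t", header=False, index=False)
    simulate.write_gene_table(genes, out / "genes.tsv")
    vsim.write_vcf(out / "variants.vcf", genome.chrom_sizes)
    vsim.write_truth(out / "variant_truth.tsv")
    stage("simulate", {"n_genes": len(genes), "n_variants": len(vsim.truth),
                       "n_segments": len(seg)})

    # --- tracks: clean + rescale to p-tracks -------------------------------
    begin("tracks")
    ptracks_a, ptracks_b, ratio_a, ratio_b = [], [], [], []
    for reps, pt, rat in ((reps_a, ptracks_a, ratio_a), (reps_b, ptracks_b, ratio_b)):
        for r in reps:
            cleaned = tracks.clean_track(r.ratio_track, genome.mask)
            rat.append(cleaned)
            pt.append(tracks.rescale_to_ptrack(cleaned, r.global_content))
    tracks.write_bedgraph(ptracks_a[0], out / "ptrack_A_rep1.bdg")
    stage("tracks", {"n_bins_clean": ptracks_a[0].bins.shape[0],
                     "content_A": [r.global_content for r in reps_a],
                     "content_B": [r.global_content for r in reps_b]})

    # --- U-scores + differential calling -----------------------------------
    begin("uscore")
    gene_iv = uscore.build_gene_intervals(genes, genome.mask, config.promoter_len)
    tbl_a = uscore.uscore_table({
        f"A_rep{i+1}": uscore.compute_uscores(t, gene_iv, relative=True,
                                              sample=f"A_rep{i+1}")
        for i, t in enumerate(ratio_a)})
    tbl_b = uscore.uscore_table({
        f"B_rep{i+1}": uscore.compute_uscores(t, gene_iv, relative=True,
                                              sample=f"B_rep{i+1}")
        for i, t in enumerate(ratio_b)})
    diff = uscore.differential_uscore(tbl_a, tbl_b, config.fc_thresh, config.p_thresh)
    diff.to_csv(out / "differential_uscores.tsv", sep="\t", index=False)
    classes = {g.gene_id: g.class_label for g in genes}
    abs_scores = uscore.compute_uscores(ptracks_a[0], gene_iv, sample="A_rep1")
    enr = uscore.class_enrichment(abs_scores, classes, "A_rep1", top_n=config.top_n)
    enr.to_csv(out / "class_enrichment.tsv", sep="\t", index=False)
    stage("uscore", {"n_genes_scored": int(tbl_a.shape[0]),
                     "n_significant": int(diff["significant"].sum())})

    # --- variants -----------------------------------------------------------
    begin("variants")
    vdf = variants.read_vcf(out / "variants.vcf")
    vdf = variants.filter_variants(vdf, config.excluded_labels)
    sbs = variants.classify_sbs(vdf, genome)
    fr = variants.weighted_sbs_fractions(sbs)
    fr.to_csv(out / "sbs_fractions.tsv", sep="\t", index=False)
    imd = variants.intermutational_distances(sbs)
    imd.to_csv(out / "imd_ct.tsv", sep="\t", index=False)
    clusters = variants.cluster_variants(sbs, config.max_imd, type_filter="C>T")
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    strat = variants.stratify_by_rt(sbs, rt_track, config.rt_thresholds)
    strat.groupby("rt_stratum")["sbs_type"].value_counts().to_csv(
        out / "rt_strata_counts.tsv", sep="\t")
    per_seg = variants.fractions_by_segment(sbs, seg)
    per_seg.to_csv(out / "ct_by_segment.tsv", sep="\t", index=False)
    stage("variants", {"n_filtered": len(vdf), "n_sbs": len(sbs),
                       "n_clustered": len(clusters)})

    # --- spectra ------------------------------------------------------------
    begin("spectra")
    m96 = spectra.sbs96_matrix(sbs, af_weighted=True)
    spectra.write_spectrum_tsv(m96, out / "spectrum_sbs96.tsv")
    m1536 = spectra.sbs1536_matrix(sbs)
    dbs, _ = variants.detect_dbs(sbs)
    d78 = spectra.dbs78_matrix(dbs)
    refit = spectra.refit_spectrum(m96, {k: spectra.SpectrumVector("SBS96", v)
                                         for k, v in comps.items()})
    refit.to_frame().to_csv(out / "refit_contributions.tsv", sep="\t", index=False)
    stage("spectra", {"sbs96_total": float(m96.values.sum()),
                      "n_dbs": int(d78.values.sum()),
                      "refit_cosine": refit.cosine,
                      "contributions": dict(zip(refit.component_names,
                                                refit.contributions.round(4)))})

    # --- hairpin ------------------------------------------------------------
    begin("hairpin")
    ann = hairpin.annotate_hairpins(sbs, genome, config.flank, config.min_stem,
                                    config.loop_range)
    loops = hairpin.loop_context_fractions(ann, clusters)
    ann.to_csv(out / "hairpin_report.tsv", sep="\t", index=False)
    stage("hairpin", {k: (None if np.isnan(v) else round(v, 3))
                      for k, v in loops.items()})

    # --- segments -----------------------------------------------------------
    begin("segments")
    sig = segments.signal_distribution(
        {f"A_rep{i+1}": t for i, t in enumerate(ptracks_a)}, seg)
    sig.to_csv(out / "segment_signal.tsv", sep="\t", index=False)
    seg_rt = segments.segment_rt(seg, rt_track)
    seg_rt.to_csv(out / "segment_rt.tsv", sep="\t", index=False)
    at = segments.segment_at_content(seg, genome)
    at.to_csv(out / "segment_at.tsv", sep="\t", index=False)
    stage("segments", {"n_labels": int(sig["label"].nunique())})

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
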