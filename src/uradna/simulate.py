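"""Synthetic genomes, tracks, annotations, and somatic variant sets.

Every downstream stage of the pipeline is exercised on data from this
module, with full ground truth: i.i.d.-base genomes with hard-masked runs,
non-nested gene annotations with biotype labels, segmentation-driven
uracil-enrichment replicate tracks (lognormal replicate noise) with their
global uracil-content scalars, replication-timing tracks, and somatic SBS
sets drawn from known 96-channel signature mixtures with optional
kataegis-like C>T clusters at short intermutational distances and
Beta-distributed allele frequencies.

The generators emulate the *statistical structure* of drug-induced
uracilation/mutagenesis experiments (replication-timing-correlated
enrichment, APOBEC-like TC-context C>T clusters, replicate noise); none of
their parameter defaults is a claim about any particular dataset.  All
outputs are plain-text standard formats (FASTA, BED, bedGraph, VCF 4.2,
TSV) and are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import BinnedTrack
from .uscore import GENE_CLASSES, GeneModel
from .variants import SBS_TYPES, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
DEFAULT_AF_MODEL = (2.0, 8.0)  # Beta(2,8): low-frequency somatic-like AFs


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSim:
    """In-memory synthetic genome: sequences, sizes, and hard-mask intervals."""

    seqs: dict[str, str]
    mask: pd.DataFrame  # BED3 of N runs
    seed: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.seqs[chrom]

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, n in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{n}\n")

    def write_mask_bed(self, path) -> None:
        self.mask.to_csv(path, sep="\t", header=False, index=False)


def generate_genome(chrom_lengths: dict[str, int], gc_fraction: float = 0.41,
                    hardmask_fraction: float = 0.0, seed: int = 0,
                    mask_run_len: int = 200) -> GenomeSim:
    """I.i.d.-base genome at a target GC with hard-masked N runs.

    The mask covers ~``hardmask_fraction`` of each chromosome as
    ``mask_run_len``-bp runs on a non-overlapping grid; masked runs are
    written as N and returned as BED intervals.
    """
    if not 0 <= gc_fraction <= 1 or not 0 <= hardmask_fraction <= 1:
        raise ValueError("gc_fraction and hardmask_fraction must be in [0,1]")
    for chrom, n in chrom_lengths.items():
        if n <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
        if n < 10_000:
            raise ValueError(f"chromosome {chrom!r} shorter than 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    seqs = {}
    mask_rows = []
    for chrom in chrom_lengths:
        n = chrom_lengths[chrom]
        arr = rng.choice(_BASES, size=n, p=p)
        if hardmask_fraction > 0:
            n_slots = n // mask_run_len
            n_masked = int(round(n_slots * hardmask_fraction))
            slots = rng.choice(n_slots, size=n_masked, replace=False)
            for s in np.sort(slots):
                lo, hi = s * mask_run_len, (s + 1) * mask_run_len
                arr[lo:hi] = b"N"
                mask_rows.append((chrom, lo, hi))
        seqs[chrom] = arr.tobytes().decode()
    mask = pd.DataFrame(mask_rows, columns=["chrom", "start", "end"])
    return GenomeSim(seqs, mask, seed)


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------

def generate_genes(genome: GenomeSim, n_genes: int,
                   length_range: tuple[int, int] = (2000, 10000),
                   promoter_len: int = 1000,
                   class_weights: dict[str, float] | None = None,
                   seed: int = 0) -> list[GeneModel]:
    """Non-nested genes with biotype labels, placed left to right.

    Gene bodies never overlap and successive bodies are separated by at
    least ``promoter_len`` so every core promoter fits.  Genes are allotted
    to chromosomes proportionally to length; infeasible requests raise.
    """
    if class_weights is None:
        class_weights = {"protein_coding": 1.0}
    unknown = set(class_weights) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene classes: {sorted(unknown)}")
    lo, hi = length_range
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    total = sum(sizes.values())
    need = n_genes * (hi + 2 * promoter_len)
    if need > total:
        raise ValueError(
            f"{n_genes} genes of up to {hi} bp (+promoters) do not fit in "
            f"{total} bp of genome")
    classes = list(class_weights)
    w = np.array([class_weights[c] for c in classes], float)
    w = w / w.sum()

    # proportional allotment, remainder to the largest chromosome
    alloc = {c: int(n_genes * sizes[c] / total) for c in sizes}
    alloc[max(sizes, key=sizes.get)] += n_genes - sum(alloc.values())

    genes: list[GeneModel] = []
    gid = 0
    for chrom, k in alloc.items():
        if k == 0:
            continue
        clen = sizes[chrom]
        slack = clen - promoter_len - k * (hi + promoter_len)
        if slack < 0:
            raise ValueError(f"{k} genes infeasible on {chrom} ({clen} bp)")
        pos = promoter_len
        for _ in range(k):
            gap = promoter_len + int(rng.integers(0, max(1, slack // max(k, 1))))
            length = int(rng.integers(lo, hi + 1))
            start = min(pos + gap - promoter_len, clen - length - promoter_len)
            strand = "+" if rng.random() < 0.5 else "-"
            label = classes[rng.choice(len(classes), p=w)]
            genes.append(GeneModel(f"G{gid:05d}", chrom, start, start + length,
                                   strand, label))
            gid += 1
            pos = start + length
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = [(g.chrom, g.start, g.end, g.gene_id, g.class_label, g.strand)
            for g in genes]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Segmentation-driven tracks
# ---------------------------------------------------------------------------

def make_segmentation(chrom_lengths: dict[str, int], labels: list[str],
                      seg_len: int = 50_000, seed: int = 0) -> pd.DataFrame:
    """Random labeled partition of the genome into ~seg_len blocks."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, clen in chrom_lengths.items():
        pos = 0
        while pos < clen:
            end = min(pos + seg_len, clen)
            rows.append((chrom, pos, end, labels[rng.choice(len(labels))]))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def _bin_frame(chrom_lengths: dict[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, clen in chrom_lengths.items():
        starts = np.arange(0, clen, bin_size)
        ends = np.minimum(starts + bin_size, clen)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _bin_labels(bins: pd.DataFrame, segmentation: pd.DataFrame) -> np.ndarray:
    """Segment label at each bin start; None where uncovered."""
    per_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy(), g["label"].to_numpy())
                 for c, g in segmentation.groupby("chrom", sort=False)}
    out = np.empty(len(bins), dtype=object)
    for i, rec in enumerate(bins.itertuples(index=False)):
        tup = per_chrom.get(rec.chrom)
        out[i] = None
        if tup is not None:
            ss, se, sl = tup
            k = np.searchsorted(ss, rec.start, side="right") - 1
            if k >= 0 and rec.start < se[k]:
                out[i] = sl[k]
    return out


@dataclass
class EnrichmentSim:
    """One replicate of a simulated uracil-enrichment experiment."""

    ratio_track: BinnedTrack     # fold-change-over-control style, mean 1
    rate_track: BinnedTrack      # ground-truth absolute rate, U per Mb
    global_content: float        # length-weighted mean rate, U per Mb


def generate_enrichment_tracks(label_rates: dict[str, float],
                               segmentation: pd.DataFrame,
                               chrom_lengths: dict[str, int],
                               n_replicates: int = 2,
                               replicate_cv: float = 0.1,
                               bin_size: int = 100,
                               seed: int = 0) -> list[EnrichmentSim]:
    """Per-replicate enrichment ratio tracks plus global content scalars.

    Each bin's true rate is its segment label's mean rate times a lognormal
    noise factor of unit mean and coefficient of variation ``replicate_cv``
    (drawn independently per replicate).  The global content is the
    length-weighted mean rate; the emitted ratio track is the rate divided
    by that mean, so rescaling by the content recovers the rate exactly.
    Bins not covered by the segmentation get rate 0 with a warning.
    """
    if any(r <= 0 for r in label_rates.values()):
        raise ValueError("label mean rates must be positive")
    rng = np.random.default_rng(seed)
    bins = _bin_frame(chrom_lengths, bin_size)
    labels = _bin_labels(bins, segmentation)
    uncovered = np.array([l is None for l in labels])
    if uncovered.any():
        import warnings
        warnings.warn(f"{int(uncovered.sum())} bin(s) not covered by the "
                      "segmentation; rate set to 0")
    base = np.array([0.0 if l is None else label_rates[l] for l in labels])
    lens = (bins["end"] - bins["start"]).to_numpy(float)
    out = []
    for _ in range(n_replicates):
        if replicate_cv > 0:
            sigma = np.sqrt(np.log1p(replicate_cv ** 2))
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(bins))
        else:
            noise = np.ones(len(bins))
        rate = base * noise
        content = float(np.sum(rate * lens) / lens.sum())
        rate_df = bins.copy()
        rate_df["value"] = rate
        ratio_df = bins.copy()
        ratio_df["value"] = rate / content
        out.append(EnrichmentSim(BinnedTrack(ratio_df, units="ratio"),
                                 BinnedTrack(rate_df, units="U_per_Mb"),
                                 content))
    return out


def generate_rt_track(segmentation: pd.DataFrame, label_rt_means: dict[str, float],
                      chrom_lengths: dict[str, int], noise_sd: float = 0.0,
                      bin_size: int = 100, seed: int = 0) -> BinnedTrack:
    """Replication-timing track: per-bin segment-label mean + Gaussian noise."""
    rng = np.random.default_rng(seed)
    bins = _bin_frame(chrom_lengths, bin_size)
    labels = _bin_labels(bins, segmentation)
    vals = np.array([0.0 if l is None else label_rt_means[l] for l in labels])
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=len(bins))
    bins["value"] = vals
    return BinnedTrack(bins, units="RT_score")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_PYR_TRIS = [f + c + t for c in "CT" for f in "ACGT" for t in "ACGT"]


def _context_index(genome: GenomeSim) -> dict[str, list[tuple[str, np.ndarray]]]:
    """Positions of each pyrimidine-strand trinucleotide context per chromosome.

    A genomic position matches context X[P]Y if its forward trinucleotide is
    XPY (reference base is the pyrimidine P) or the reverse complement of it
    (reference base is the purine partner).
    """
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    index: dict[str, list] = {t: [] for t in _PYR_TRIS}
    for chrom, seq in genome.seqs.items():
        c = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = (c[:-2] >= 0) & (c[1:-1] >= 0) & (c[2:] >= 0)
        tri_code = c[:-2] * 16 + c[1:-1] * 4 + c[2:]
        for tri in _PYR_TRIS:
            codes = [sum(4 ** (2 - i) * "ACGT".index(b) for i, b in enumerate(t))
                     for t in (tri, revcomp(tri))]
            hit = valid & ((tri_code == codes[0]) | (tri_code == codes[1]))
            pos = np.nonzero(hit)[0] + 1  # center position
            index[tri].append((chrom, pos))
    return index


@dataclass
class VariantSim:
    """Synthetic somatic SBS set with full ground truth."""

    truth: pd.DataFrame  # chrom,pos,ref,alt,af,sbs_type,channel,in_cluster,component
    seed: int

    def write_vcf(self, path, chrom_sizes: dict[str, int]) -> None:
        df = self.truth.sort_values(["chrom", "pos"], kind="mergesort")
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                     'Description="Allele fraction">\n')
            fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
            for chrom, n in chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={n}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for rec in df.itertuples(index=False):
                fh.write(f"{rec.chrom}\t{rec.pos + 1}\t.\t{rec.ref}\t{rec.alt}"
                         f"\t.\tPASS\tAF={rec.af:.6f}\n")

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _channel_parts(channel: str) -> tuple[str, str, str]:
    """'A[C>T]G' -> (tri 'ACG', ref 'C', alt 'T')."""
    f, rest = channel.split("[")
    sub, t = rest.split("]")
    ref, alt = sub.split(">")
    return f + ref + t, ref, alt


def generate_variants(genome: GenomeSim, n_variants: int,
                      spectrum_mix: dict[str, float],
                      component_spectra: dict[str, np.ndarray],
                      cluster_fraction: float = 0.0,
                      cluster_imd: int = 100,
                      af_model: tuple[float, float] = DEFAULT_AF_MODEL,
                      seed: int = 0,
                      max_retries: int = 200) -> VariantSim:
    """Somatic SBS set drawn from a known mixture of 96-channel signatures.

    Per record a component is drawn from ``spectrum_mix`` and a channel from
    that component's 96-vector; a genomic site whose pyrimidine-strand
    trinucleotide matches the channel is sampled uniformly (purine-reference
    sites get the reverse-complemented alt).  A ``cluster_fraction`` of the
    C>T records is re-placed as kataegis-like runs of 2-6 consecutive C>T
    events with successive gaps drawn uniformly in [2, cluster_imd]; their
    recorded channel comes from the actual genomic context so the 96-matrix
    round trip stays exact.  Allele frequencies are Beta(af_model) draws.
    """
    from .spectra import SBS96_CHANNELS

    names = list(spectrum_mix)
    w = np.array([spectrum_mix[k] for k in names], float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("spectrum_mix weights must sum to 1")
    comp = {}
    for k in names:
        v = np.asarray(component_spectra[k], float)
        if len(v) != 96 or (v < 0).any() or not np.isclose(v.sum(), 1.0):
            raise ValueError(f"component {k!r} must be a 96-channel probability vector")
        comp[k] = v
    rng = np.random.default_rng(seed)
    ctx_index = _context_index(genome)

    comp_draw = rng.choice(len(names), size=n_variants, p=w)
    channels = [SBS96_CHANNELS[rng.choice(96, p=comp[names[k]])] for k in comp_draw]
    is_ct = np.array([_channel_parts(ch)[1:] == ("C", "T") for ch in channels])
    n_clustered = int(round(cluster_fraction * is_ct.sum()))
    cluster_slots = np.nonzero(is_ct)[0][:n_clustered]
    free_slots = [i for i in range(n_variants) if i not in set(cluster_slots)]

    used: set[tuple[str, int]] = set()
    rows: dict[int, tuple] = {}

    # dispersed events: exact channel-context placement
    for i in free_slots:
        tri, ref_p, alt_p = _channel_parts(channels[i])
        placed = False
        for _ in range(max_retries):
            pools = ctx_index[tri]
            sizes = np.array([len(p) for _, p in pools])
            if sizes.sum() == 0:
                break
            ci = rng.choice(len(pools), p=sizes / sizes.sum())
            chrom, pos_arr = pools[ci]
            pos = int(pos_arr[rng.integers(len(pos_arr))])
            if (chrom, pos) in used:
                continue
            base = genome.seqs[chrom][pos]
            if base == ref_p:
                ref, alt = ref_p, alt_p
            else:
                ref, alt = revcomp(ref_p), revcomp(alt_p)
            used.add((chrom, pos))
            rows[i] = (chrom, pos, ref, alt, f"{ref_p}>{alt_p}", channels[i],
                       False, names[comp_draw[i]])
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place a variant for context {tri!r} "
                               f"after {max_retries} retries")

    # clustered C>T runs: successive gaps in [2, cluster_imd] on C/G bases
    chroms = list(genome.seqs)
    clens = genome.chrom_sizes
    remaining = list(cluster_slots)
    while remaining:
        run_size = min(int(rng.integers(2, 7)), len(remaining))
        if len(remaining) - run_size == 1:  # never leave a singleton behind
            run_size = len(remaining)
        for _ in range(max_retries):
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(20, clens[chrom] - 20 - 6 * cluster_imd))
            run = _place_ct_run(genome.seqs[chrom], start, run_size,
                                cluster_imd, rng, used, chrom)
            if run is not None:
                break
        else:
            raise RuntimeError("could not place a C>T cluster run")
        for pos in run:
            i = remaining.pop(0)
            base = genome.seqs[chrom][pos]
            ref, alt = ("C", "T") if base == "C" else ("G", "A")
            tri_fwd = genome.seqs[chrom][pos - 1:pos + 2]
            tri_pyr = tri_fwd if base == "C" else revcomp(tri_fwd)
            used.add((chrom, pos))
            rows[i] = (chrom, pos, ref, alt, "C>T", f"{tri_pyr[0]}[C>T]{tri_pyr[2]}",
                       True, names[comp_draw[i]])

    truth = pd.DataFrame([rows[i] for i in sorted(rows)],
                         columns=["chrom", "pos", "ref", "alt", "sbs_type",
                                  "channel", "in_cluster", "component"])
    truth["af"] = rng.beta(af_model[0], af_model[1], size=len(truth))
    truth["filter"] = "PASS"
    truth = truth.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth = truth[["chrom", "pos", "ref", "alt", "af", "filter", "sbs_type",
                   "channel", "in_cluster", "component"]]
    return VariantSim(truth, seed)


def _place_ct_run(seq: str, start: int, run_size: int, cluster_imd: int,
                  rng, used: set, chrom: str) -> list[int] | None:
    """Find run_size C/G positions from `start` with successive gaps in
    [2, cluster_imd]; None if the local sequence cannot host the run."""
    positions = []
    pos = start
    for k in range(run_size):
        if k == 0:
            lo, hi = pos, pos + cluster_imd
        else:
            lo, hi = pos + 2, pos + cluster_imd
        target = int(rng.integers(lo, hi + 1))
        cand = [q for q in range(lo, min(hi + 1, len(seq) - 2))
                if seq[q] in "CG" and (chrom, q) not in used and q not in positions]
        if not cand:
            return None
        pos = min(cand, key=lambda q: abs(q - target))
        positions.append(pos)
    return positions


# ---------------------------------------------------------------------------
# Canned component spectra for demonstrations and tests
# ---------------------------------------------------------------------------

def tc_biased_ct_spectrum(tc_weight: float = 0.8) -> np.ndarray:
    """Synthetic APOBEC-like 96-vector: C>T mass biased to T[C>T]N channels.

    Not a published signature — a minimal stand-in with the canonical
    TC-context preference of APOBEC3 deamination.
    """
    from .spectra import SBS96_CHANNELS

    v = np.zeros(96)
    ct = [i for i, c in enumerate(SBS96_CHANNELS) if "[C>T]" in c]
    tc = [i for i in ct if SBS96_CHANNELS[i][0] == "T"]
    other = [i for i in ct if i not in tc]
    v[tc] = tc_weight / len(tc)
    v[other] = (1 - tc_weight) / len(other)
    return v


def flat_spectrum(subset: str | None = None) -> np.ndarray:
    """Uniform 96-vector, optionally restricted to one substitution class."""
    from .spectra import SBS96_CHANNELS

    if subset is None:
        return np.full(96, 1 / 96)
    idx = [i for i, c in enumerate(SBS96_CHANNELS) if f"[{subset}]" in c]
    v = np.zeros(96)
    v[idx] = 1 / len(idx)
    return v
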