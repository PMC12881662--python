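# Methods

## Coordinate and container conventions

All intervals are BED-style 0-based half-open and sorted; VCF positions are
converted to 0-based on read and back on write. Tracks (`BinnedTrack`) are
bedGraph-backed DataFrames with declared units (`ratio`, `U_per_Mb`,
`RT_score`); bin width is read from the file, not assumed, and mixed widths
are handled by length weighting throughout. Interval arithmetic
(merge/subtract/intersect/Jaccard/overlap) is implemented natively on
sorted numpy arrays with the merged-interval semantics of the classic
bedtools utilities (book-ended intervals fuse before set operations); the
test suite cross-checks Jaccard values against exhaustive per-base set
arithmetic.

## From enrichment ratios to absolute uracil probabilities

A uracil-enrichment ratio track (pulldown coverage / input coverage,
100-bp bins) is first cleaned: any bin overlapping a blacklist or hard-mask
interval is dropped whole. The cleaned track is rescaled by a single scalar
C = content / weighted-mean(r) so the length-weighted mean of p = C·r over
the *retained* bins equals the sample's measured global uracil content in
U/Mb. The excluded regions are assumed to carry the genome-mean uracil
frequency; they are simply not written, so they affect neither C nor any
downstream mean. The normalization is exact by construction:
Σ pᵢ·lenᵢ = content · retained bp, and rescaling is invariant to any
positive rescaling of the input ratios. Interval means
(`average_over_intervals`) use covered-base averaging: bases without track
coverage are excluded from the denominator rather than counted as zero,
with the covered bp reported so callers can filter; intervals beyond a
declared chromosome end are clipped with a warning.

## U-scores and differential uracilation

A gene's scoring interval is the union of its longest-isoform body
(introns included) and a 1,000-bp core promoter attached upstream of the
strand-aware 5′ end (clipped at the chromosome start), minus the
blacklist. The U-score is the coverage-weighted p-track mean over that
interval set; genes with zero coverage get a missing score and are
counted. *Relative* U-scores divide each replicate's gene means by that
replicate's genome-wide length-weighted cleaned-track mean, making
replicates unit-free; this is the minimal normalization that lets
replicates be compared without an absolute anchor.

Differential calling between two replicate groups computes per gene the
fold change as the ratio of the group sums (equivalently, of the group
means for equal replicate counts), a Welch unequal-variance t test on the
replicate values, and the combined ranking score log2(FC)·(−log10 p). The
significance flag requires p < 0.05 *and* fold change above 1.5 in either
direction; raw p-values drive the flag, because with two replicates per
group FDR correction is essentially powerless — a Benjamini–Hochberg
column is emitted for reference but deliberately not used. Degenerate
Welch inputs follow fixed conventions: both groups zero-variance with
equal means → p = 1; zero variance with unequal means → p = 0.

Class enrichment among the top-N scorers uses expected counts
N·(class size / scored genes); ties at the N boundary are broken by
gene_id so the selection is deterministic. Network summaries compute
average degree 2E/N directly and delegate the local clustering coefficient
to networkx, averaging over all N nodes with degree-<2 nodes contributing 0.

## Variant statistics

Multi-allelic records are split per alt allele before anything else.
Filtering removes a record iff its FILTER labels intersect
{weak_evidence, normal_artifact, slippage, germline, base_qual}. Allele
frequency is taken from INFO/AF, then FORMAT/AF (first sample), then
AD-derived alt/(ref+alt); records without AF are kept but excluded from
weighted statistics and counted. SBS classification collapses
purine-reference records by reverse complement onto the six
pyrimidine-strand classes; tri- and pentanucleotide contexts are reported
on the same strand, and the reference allele is verified against the
genome so coordinate-convention bugs fail loudly rather than silently
misclassifying. Contexts running off a chromosome end or containing N are
dropped from context matrices while the record keeps its class.

Occurrences are AF sums per class; fractions are occurrences over the
total and always sum to 1 over assigned records. Replication-timing strata
use early > 2.5, late < −2.5, with both boundary values assigned to
"middle" (inclusive reading of "between"); positions without RT coverage
go to an explicit unassigned bucket so the strata partition the input.

Intermutational distances are gaps between consecutive same-type events
per chromosome. Clusters are maximal runs of ≥ min_size (default 2)
consecutive same-chromosome variants with successive gaps ≤ max_imd. The
default max_imd = 100 bp reflects the observed short-IMD mode of
drug-induced C→T clustering; since no single threshold is canonical it is
an explicit parameter everywhere it is used. Doublet detection merges
adjacent SBS pairs (gap exactly 1 bp) and accepts explicit 2-bp MNPs,
collapsing into the 78 canonical strand-agnostic categories; runs of three
substituted bases are paired greedily left to right with the remainder
kept as SBS, and constituent SBS are removed from SBS-only tallies by
default.

## Spectra and signature refitting

Channel orders are the de-facto canonical ones (six substitution classes,
flanks lexicographic in A,C,G,T); every emitted spectrum carries explicit
channel names so no consumer needs to rely on position. The 1,536-channel
pentanucleotide spectrum marginalizes exactly onto the 96-channel spectrum
by summing over the outermost bases — an identity the tests assert on
generated data.

Refitting a measured spectrum against fixed reference signatures uses
non-negative least squares on probability-normalized vectors:
w = argmin ‖m − Cw‖₂ s.t. w ≥ 0; contributions are w/Σw, the
reconstituted spectrum is the renormalized Cw, and fit quality is the
cosine similarity to the measured spectrum. With the components known and
fixed, NNLS is the deterministic standard for this refit; no de-novo
extraction (NMF) is attempted. Duplicate components make weights
non-unique — the active-set order breaks the tie deterministically and a
warning is emitted. Reference signature spectra are user-supplied TSVs;
none are bundled, because published APOBEC3A/B/C spectra exist only as
figure data of varying provenance. The built-in `tc_biased_ct_spectrum` is
a clearly-labeled synthetic stand-in carrying only the canonical TC-context
C→T preference.

## Stem-loop search

For each SBS the ±15-nt window (31 nt, variant centered) is scanned
exhaustively: for every loop placement of 3–6 nt, the stem is extended
outward base by base while the arms pair, and the maximal extension is
reported once per loop placement if it reaches 4 nt — sub-stems are not
re-reported, which keeps loop-located fractions free of double counting.
Pairing is Watson–Crick only by default; G:T wobble sits behind a flag.
There is no thermodynamic model. A hairpin anywhere in the window is
reported; only `classify_loop_position` asks whether the variant itself
lies in a loop. Windows truncated by chromosome ends or containing N are
skipped and counted. The implementation is verified exactly against an
O(n³) string-comparison brute force on randomized windows.

## Segmentation summaries

Per-label signal summaries use base-weighted means but *between-interval*
SD (the SD of per-interval means), matching how segmentation heatmaps draw
their error bars; replication-timing summaries are two-stage by the same
logic (per-interval mean, then mean ± SD across a label's intervals). AT
content excludes N from numerator and denominator. Jaccard merges
book-ended intervals before intersect/union. Heatmap-style display
rescaling offers per-sample min–max (default) and z-score.

## Synthetic-data generators

The generators emulate the statistical *structure* of a two-treatment
uracil-sequencing experiment, not any particular dataset: i.i.d. bases at
a target GC (0.41 default, genome-like) with hard-masked N runs on a
non-overlapping grid; non-nested genes with biotype labels placed left to
right with promoter-sized clearances; segmentation-label-driven enrichment
rates with multiplicative lognormal replicate noise of unit mean and
configurable CV (0.08–0.1 default, replicate-level reproducibility);
RT tracks as label means plus Gaussian noise; and variant sets drawn from
known 96-channel signature mixtures by rejection-free context lookup, with
Beta(2, 8) allele frequencies (low-frequency somatic-like, so AF weighting
is exercised with non-degenerate weights). A configurable fraction of C→T
events is re-placed as kataegis-like runs of 2–6 events with successive
gaps uniform in [2, cluster_imd]; cluster members sit on actual C/G bases
and record their true genomic context, so the spectrum round trip
(truth channels ≡ 96-matrix of the emitted VCF against the emitted FASTA)
is exact, not approximate. All outputs are plain-text standard formats and
byte-identical under a fixed seed.

What passing tests on this data do *not* show: real enrichment tracks have
coverage-dependent noise, mappability artifacts and correlated bins; real
somatic calls carry caller-specific artifact structure; real genomes have
repeat-driven context composition far from i.i.d. The generators validate
the *statistics*, not the upstream measurement process (no reads,
alignment, pulldown chemistry, or segmentation training are simulated).

## Problem sizes

The demonstration and test configurations use sub-megabase genomes
(200–700 kb), ~100 genes, 10³–10⁴ variants and 2 replicates per group —
sizes at which every parameter-recovery check (mixture fractions within
3σ multinomial error, refit contributions within ±0.05, fold-change
recovery within replicate noise, cluster recall 1.0) is well-powered while
the whole suite runs in seconds. All statistics are length-weighted or
per-record, so nothing about them changes at chromosome scale except
runtime.

## Known limitations

- Cluster membership and the loop-located denominators depend on the
  max_imd and stem/loop parameters; there is no attempt to infer them.
- The NNLS refit is only as meaningful as the supplied reference spectra;
  with nearly collinear components the contributions split is unstable
  even though the reconstituted spectrum (and cosine) is not.
- Relative U-scores normalize by the cleaned-track genome mean; if a
  treatment changes total uracil load, relative fold changes are
  compressed relative to absolute (p-track) fold changes — the analysis
  drivers use absolute scores for fold-change recovery for this reason.
- `filter_variants` trusts the caller's FILTER labels; no re-genotyping.
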