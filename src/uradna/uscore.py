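"""Gene-level U-scores and differential uracilation calling.

A U-score is the coverage-weighted mean of the uracil p-track over a gene's
longest isoform (introns included) plus its 1,000-bp upstream core promoter,
with blacklisted regions excluded.  Differential uracilation between two
treatments is called from per-replicate *relative* U-scores with a
fold-change gate (>1.5 in either direction) and a Welch two-sample t test
(p < 0.05), and ranked by the combined score log2(FC) * -log10(p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import as_intervals, subtract_intervals
from .tracks import BinnedTrack, average_over_intervals

log = logging.getLogger(__name__)

DEFAULT_PROMOTER_LEN = 1000
FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05

GENE_CLASSES = (
    "protein_coding", "pseudogene", "lncRNA", "miRNA", "IG", "TR",
    "snRNA", "snoRNA", "sRNA", "other",
)


@dataclass(frozen=True)
class GeneModel:
    """Longest isoform of a gene with its biotype class label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    class_label: str = "protein_coding"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def read_gene_table(path) -> list[GeneModel]:
    """Read a BED6-like TSV: chrom start end gene_id class strand."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "class_label", "strand"],
                     dtype={"chrom": str})
    return [GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand, r.class_label)
            for r in df.itertuples(index=False)]


def build_gene_intervals(genes: list[GeneModel], blacklist: pd.DataFrame | None = None,
                         promoter_len: int = DEFAULT_PROMOTER_LEN) -> pd.DataFrame:
    """Per-gene scoring intervals: [promoter ∪ gene body] minus blacklist.

    The promoter is attached upstream of the strand-aware 5' end and clipped
    at the chromosome start.  Returns disjoint sorted intervals tagged with
    ``gene_id``.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate gene_id(s): {list(dup[dup > 1].index)}")
    rows = []
    for g in genes:
        if g.strand == "+":
            s, e = max(0, g.start - promoter_len), g.end
        else:
            s, e = g.start, g.end + promoter_len
        rows.append((g.chrom, s, e, g.gene_id))
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    iv = as_intervals(iv)
    if blacklist is not None and len(blacklist):
        iv = subtract_intervals(iv, blacklist)
    return iv.reset_index(drop=True)


def compute_uscores(ptrack: BinnedTrack, gene_intervals: pd.DataFrame,
                    relative: bool = False, sample: str = "uscore") -> pd.DataFrame:
    """Coverage-weighted mean of the p-track per gene (the U-score).

    In ``relative`` mode the input is the cleaned ratio track of a single
    replicate and each gene mean is divided by that replicate's genome-wide
    length-weighted mean, making replicates unit-free and comparable.
    Genes with zero track coverage get a missing score (logged).
    """
    per_iv = average_over_intervals(ptrack, gene_intervals)
    per_iv["wsum"] = per_iv["mean"].fillna(0.0) * per_iv["covered_bp"]
    agg = per_iv.groupby("gene_id", sort=True).agg(
        wsum=("wsum", "sum"), covered_bp=("covered_bp", "sum"))
    score = np.where(agg["covered_bp"] > 0, agg["wsum"] / agg["covered_bp"].replace(0, 1), np.nan)
    out = pd.DataFrame({"gene_id": agg.index, sample: score}).reset_index(drop=True)
    if relative:
        gmean = ptrack.weighted_mean()
        if gmean == 0:
            raise ValueError("genome-wide mean is zero; relative U-scores undefined")
        out[sample] = out[sample] / gmean
    n_missing = int(out[sample].isna().sum())
    if n_missing:
        log.info("%d gene(s) with zero track coverage -> missing U-score", n_missing)
    return out


def uscore_table(per_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample U-score frames on gene_id into one table."""
    it = iter(per_sample.items())
    _, merged = next(it)
    merged = merged.copy()
    for _, df in it:
        merged = merged.merge(df, on="gene_id", how="outer")
    return merged.sort_values("gene_id").reset_index(drop=True)


def welch_two_sample(a, b, tails: int = 2) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, p).

    Both groups zero-variance with equal means -> (0, nan, 1) by convention;
    zero variance with unequal means -> p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_two_sample needs >=2 finite values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float("nan"), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    df = (va / len(a) + vb / len(b)) ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    p = float(res.pvalue)
    if tails == 1:
        p = p / 2 if res.statistic > 0 else 1 - p / 2
    return float(res.statistic), float(df), p


def differential_uscore(group_a: pd.DataFrame, group_b: pd.DataFrame,
                        fc_thresh: float = FC_THRESHOLD,
                        p_thresh: float = P_THRESHOLD) -> pd.DataFrame:
    """Differentially uracilated genes between two replicate groups.

    Inputs are U-score tables (gene_id + one column per replicate); genes are
    matched by gene_id, unmatched genes are dropped and counted.  Per gene:
    fold change = sum(A replicates) / sum(B replicates) (ratio of the group
    means), p from Welch's two-sample t test on the replicate values,
    combined score = log2(FC) * -log10(p).  ``significant`` requires
    p < p_thresh and fold change > fc_thresh in either direction
    (|log2 FC| > log2(fc_thresh)).  A Benjamini-Hochberg column is emitted
    for reference but does not drive the flag.
    """
    a_cols = [c for c in group_a.columns if c != "gene_id"]
    b_cols = [c for c in group_b.columns if c != "gene_id"]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >=2 replicates per group")
    merged = group_a.merge(group_b, on="gene_id", how="inner", suffixes=("_A", "_B"))
    a_cols = [c if c in merged.columns else c + "_A" for c in a_cols]
    b_cols = [c if c in merged.columns else c + "_B" for c in b_cols]
    n_dropped = len(group_a) + len(group_b) - 2 * len(merged)
    if n_dropped:
        log.info("differential_uscore: %d unmatched gene rows dropped", n_dropped)
    merged = merged.dropna(subset=a_cols + b_cols).reset_index(drop=True)

    A = merged[a_cols].to_numpy(float)
    B = merged[b_cols].to_numpy(float)
    sum_a, sum_b = A.sum(axis=1), B.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(sum_b > 0, sum_a / sum_b, np.nan)
        log2_fc = np.log2(fc)
    pvals = np.empty(len(merged))
    tstats = np.empty(len(merged))
    for i in range(len(merged)):
        t, _, p = welch_two_sample(A[i], B[i])
        tstats[i], pvals[i] = t, p
    neg_log10_p = -np.log10(np.clip(pvals, 1e-300, None))
    out = pd.DataFrame({
        "gene_id": merged["gene_id"],
        "fold_change": fc,
        "log2_fc": log2_fc,
        "t": tstats,
        "p_value": pvals,
        "neg_log10_p": neg_log10_p,
        "combined_score": log2_fc * neg_log10_p,
    })
    out["p_bh"] = stats.false_discovery_control(pvals, method="bh")
    out["fc_undefined"] = ~np.isfinite(fc)
    out["significant"] = (
        (out["p_value"] < p_thresh)
        & np.isfinite(log2_fc)
        & (np.abs(log2_fc) > np.log2(fc_thresh))
    )
    return out


def class_enrichment(uscores: pd.DataFrame, gene_classes: dict[str, str],
                     sample: str, top_n: int = 2000) -> pd.DataFrame:
    """Gene-class (biotype) enrichment among the top_n highest U-scores.

    expected_c = top_n * N_c / N_total over scored genes; fold = observed /
    expected.  Ties at the top_n boundary are broken by gene_id so the
    selection is deterministic.
    """
    scored = uscores.dropna(subset=[sample]).copy()
    if top_n > len(scored):
        raise ValueError(f"top_n={top_n} exceeds {len(scored)} scored genes")
    scored["class_label"] = scored["gene_id"].map(gene_classes)
    scored = scored.sort_values([sample, "gene_id"], ascending=[False, True],
                                kind="mergesort")
    top = scored.head(top_n)
    totals = scored["class_label"].value_counts()
    observed = top["class_label"].value_counts()
    rows = []
    for cls in totals.index:
        exp = top_n * totals[cls] / len(scored)
        obs = int(observed.get(cls, 0))
        rows.append((cls, obs, exp, obs / exp if exp > 0 else np.nan))
    return pd.DataFrame(rows, columns=["class_label", "observed", "expected", "fold"])


def uscore_histogram(scores, lo: float, hi: float, bin_width: float):
    """Fixed-width histogram with an explicit overflow bucket.

    Bins are half-open [lo+k*w, lo+(k+1)*w); values >= hi land in the
    overflow count.  Returns (edges, counts, overflow).
    """
    if not hi > lo or not bin_width > 0:
        raise ValueError("need hi > lo and bin_width > 0")
    v = np.asarray(scores, float)
    v = v[np.isfinite(v)]
    if (v < lo).any():
        raise ValueError("scores below histogram lower bound")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    overflow = int((v >= hi).sum())
    counts, _ = np.histogram(v[v < hi], bins=edges)
    return edges, counts, overflow


def network_summary(edges, n_nodes: int) -> dict:
    """Summary statistics of an undirected gene network.

    avg_degree = 2E/N; the local clustering coefficient is 0 for nodes of
    degree < 2 and the average runs over all N nodes (isolated included).
    Duplicate edges are deduplicated with a warning; self-loops rejected.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    seen = set()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u}")
        key = (min(u, v), max(u, v))
        if key in seen:
            warnings.warn(f"duplicate edge {key} ignored")
            continue
        seen.add(key)
        g.add_edge(u, v)
    if g.number_of_nodes() > n_nodes:
        raise ValueError("edge endpoint outside declared node range")
    n_edges = g.number_of_edges()
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "avg_degree": 2 * n_edges / n_nodes,
        "avg_local_clustering": nx.average_clustering(g, count_zeros=True),
    }
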