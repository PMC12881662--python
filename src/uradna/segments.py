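"""Summary statistics over labeled genome segmentations.

A segmentation partitions the (non-masked) genome into labeled intervals
(12 labels at 100-bp resolution in the study design).  This module
re-implements the downstream summaries the segmentation consumers need:
per-label signal distributions (base-weighted mean, between-interval SD),
two-stage replication-timing statistics, AT content, interval-set Jaccard
similarity, and feature-overlap annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import intervals as iv
from .tracks import BinnedTrack, average_over_intervals


def read_segmentation(path) -> pd.DataFrame:
    """Read a BED4 segmentation (chrom, start, end, label); sorted, labeled."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "label"], dtype={"chrom": str})
    if df["label"].isna().any():
        raise ValueError(f"{path}: every segment interval must carry a label")
    df = iv.as_intervals(df)
    for chrom, grp in df.groupby("chrom", sort=False):
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"{path}: overlapping segments on {chrom}")
    return df


def signal_distribution(tracks: dict[str, BinnedTrack], seg: pd.DataFrame,
                        rescale: str | None = None) -> pd.DataFrame:
    """Label x sample matrix of (mean, sd) signal summaries.

    The mean is base-weighted over all bases of a label; the SD is taken
    across the label's intervals (per-interval means), matching the error
    bars of segmentation heatmaps.  ``rescale='minmax'`` or ``'zscore'``
    additionally emits per-sample display-rescaled means.
    """
    rows = []
    for sample, track in tracks.items():
        per_iv = average_over_intervals(track, seg)
        per_iv = per_iv[per_iv["covered_bp"] > 0]
        for label, grp in per_iv.groupby("label", sort=True):
            wmean = float(np.sum(grp["mean"] * grp["covered_bp"]) / grp["covered_bp"].sum())
            sd = float(grp["mean"].std(ddof=1)) if len(grp) > 1 else 0.0
            rows.append((label, sample, wmean, sd, int(grp["covered_bp"].sum())))
    out = pd.DataFrame(rows, columns=["label", "sample", "mean", "sd", "covered_bp"])
    if rescale is not None:
        scaled = []
        for sample, grp in out.groupby("sample", sort=False):
            m = grp["mean"]
            if rescale == "minmax":
                rng = m.max() - m.min()
                scaled.append((m - m.min()) / rng if rng > 0 else m * 0)
            elif rescale == "zscore":
                scaled.append((m - m.mean()) / m.std(ddof=0))
            else:
                raise ValueError(f"unknown rescale mode {rescale!r}")
        out["rescaled"] = pd.concat(scaled)
    return out


def segment_rt(seg: pd.DataFrame, rt_track: BinnedTrack) -> pd.DataFrame:
    """Per-label replication timing: two-stage mean +- SD.

    Stage 1 averages the RT track over each segment interval; stage 2 takes
    the plain mean and SD of those per-interval means within each label.
    Intervals without RT coverage are excluded and counted.
    """
    per_iv = average_over_intervals(rt_track, seg)
    n_uncovered = int((per_iv["covered_bp"] == 0).sum())
    per_iv = per_iv[per_iv["covered_bp"] > 0]
    rows = []
    for label, grp in per_iv.groupby("label", sort=True):
        rows.append((label, float(grp["mean"].mean()),
                     float(grp["mean"].std(ddof=1)) if len(grp) > 1 else 0.0,
                     len(grp)))
    out = pd.DataFrame(rows, columns=["label", "rt_mean", "rt_sd", "n_intervals"])
    out.attrs["n_uncovered_intervals"] = n_uncovered
    return out


def segment_at_content(seg: pd.DataFrame, genome) -> pd.DataFrame:
    """Per-label AT fraction (A+T)/(A+C+G+T); N bases excluded entirely."""
    counts: dict[str, np.ndarray] = {}
    for rec in seg.itertuples(index=False):
        s = str(genome[rec.chrom][rec.start:rec.end]).upper()
        c = counts.setdefault(rec.label, np.zeros(4, dtype=np.int64))
        for i, base in enumerate("ACGT"):
            c[i] += s.count(base)
    rows = []
    for label in sorted(counts):
        a, cc, g, t = counts[label]
        tot = a + cc + g + t
        rows.append((label, (a + t) / tot if tot else np.nan, int(tot)))
    return pd.DataFrame(rows, columns=["label", "at_fraction", "acgt_bp"])


def jaccard(seg_a: pd.DataFrame, seg_b: pd.DataFrame,
            per_label_pair: bool = False):
    """Jaccard similarity of two segmentations' interval sets.

    Scalar mode ignores labels; matrix mode returns a label-pair frame.
    Book-ended intervals are merged first (the cited utility's semantics).
    """
    if not per_label_pair:
        return iv.jaccard(seg_a, seg_b)
    rows = []
    for la in sorted(seg_a["label"].unique()):
        for lb in sorted(seg_b["label"].unique()):
            rows.append((la, lb, iv.jaccard(seg_a[seg_a["label"] == la],
                                            seg_b[seg_b["label"] == lb])))
    return pd.DataFrame(rows, columns=["label_a", "label_b", "jaccard"])


def annotate_overlap(seg: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Per-label fraction of segment bp covered by >=1 feature base."""
    rows = []
    for label, grp in seg.groupby("label", sort=True):
        rows.append((label, iv.covered_fraction(grp, features), iv.total_bp(grp)))
    return pd.DataFrame(rows, columns=["label", "overlap_fraction", "label_bp"])


def segment_lengths(seg: pd.DataFrame) -> pd.DataFrame:
    """Interval length listing per label (for external length-distribution plots)."""
    out = seg.copy()
    out["length"] = out["end"] - out["start"]
    return out[["label", "chrom", "start", "end", "length"]]
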