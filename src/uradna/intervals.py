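"""Native interval-set arithmetic on 0-based half-open genomic intervals.

All public functions accept and return pandas DataFrames with at least the
columns ``chrom``, ``start``, ``end``.  Interval sets are kept sorted by
(chrom, start); operations that require it merge book-ended/overlapping
intervals first, matching the semantics of the classic bedtools utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort an interval frame. Raises on malformed records."""
    missing = [c for c in BED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"interval frame missing columns: {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if (out["end"] <= out["start"]).any():
        bad = out[out["end"] <= out["start"]].iloc[0]
        raise ValueError(f"empty/inverted interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping and book-ended intervals are fused."""
    df = as_intervals(df)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # book-ended counts as touching
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLS)


def total_bp(df: pd.DataFrame) -> int:
    m = merge_intervals(df) if len(df) else df
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def _per_chrom(df: pd.DataFrame):
    for chrom, grp in df.groupby("chrom", sort=True):
        yield chrom, grp["start"].to_numpy(), grp["end"].to_numpy()


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total overlap in bp between the merged interval sets."""
    if not len(a) or not len(b):
        return 0
    am = {c: (s, e) for c, s, e in _per_chrom(merge_intervals(a))}
    bp = 0
    for chrom, bs, be in _per_chrom(merge_intervals(b)):
        if chrom not in am:
            continue
        as_, ae = am[chrom]
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if hi > lo:
                bp += hi - lo
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
    return int(bp)


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """|A ∩ B| / |A ∪ B| in bp over merged interval sets; 0 if both empty."""
    inter = intersect_bp(a, b)
    union = total_bp(a) + total_bp(b) - inter
    if union == 0:
        import warnings

        warnings.warn("jaccard of two empty interval sets; returning 0 by convention")
        return 0.0
    return inter / union


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """A minus B: parts of each A interval not covered by any B interval.

    Non-coordinate columns of ``a`` are propagated to the surviving pieces.
    """
    a = as_intervals(a)
    if not len(b):
        return a
    bm = {c: (s, e) for c, s, e in _per_chrom(merge_intervals(b))}
    rows = []
    for _, rec in a.iterrows():
        chrom, s, e = rec["chrom"], rec["start"], rec["end"]
        if chrom not in bm:
            rows.append(rec)
            continue
        bs, be = bm[chrom]
        # exclusion intervals overlapping [s, e)
        k = np.searchsorted(be, s, side="right")
        cur = s
        pieces = []
        while k < len(bs) and bs[k] < e:
            if bs[k] > cur:
                pieces.append((cur, bs[k]))
            cur = max(cur, be[k])
            k += 1
        if cur < e:
            pieces.append((cur, e))
        for ps, pe in pieces:
            r = rec.copy()
            r["start"], r["end"] = ps, pe
            rows.append(r)
    if not rows:
        return a.iloc[0:0]
    return pd.DataFrame(rows).reset_index(drop=True)


def overlaps_any(query: pd.DataFrame, exclusions: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each query interval overlap any exclusion interval."""
    query = as_intervals(query)
    mask = np.zeros(len(query), dtype=bool)
    if not len(exclusions):
        return mask
    em = {c: (s, e) for c, s, e in _per_chrom(merge_intervals(exclusions))}
    for idx, rec in query.iterrows():
        tup = em.get(rec["chrom"])
        if tup is None:
            continue
        es, ee = tup
        k = np.searchsorted(ee, rec["start"], side="right")
        mask[idx] = k < len(es) and es[k] < rec["end"]
    return mask


def covered_fraction(target: pd.DataFrame, features: pd.DataFrame) -> float:
    """Fraction of target bp covered by >=1 feature base."""
    t = total_bp(target)
    if t == 0:
        return float("nan")
    return intersect_bp(target, features) / t


def read_bed(path, names=None) -> pd.DataFrame:
    """Read BED3/BED4/BED6-like whitespace-separated file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    ncol = df.shape[1]
    if names is None:
        names = BED_COLS + ["name", "score", "strand"][: ncol - 3]
    df.columns = names[:ncol]
    return as_intervals(df)


def write_bed(df: pd.DataFrame, path, cols=None) -> None:
    cols = cols or [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)
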