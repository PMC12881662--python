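"""Binned genome tracks: bedGraph I/O, cleaning, absolute rescaling, averaging.

The central object is :class:`BinnedTrack`, a thin wrapper over a sorted
bedGraph-style DataFrame.  Uracil-enrichment ratio tracks (coverage in the
enriched sample over the input sample, 100-bp bins) are rescaled into
*p-tracks*: per-bin uracil probabilities on a quasi-absolute scale of
uracils per million base pairs, anchored to an independently measured
global uracil content per sample (~700 U/Mb for raltitrexed-treated,
UNG-inhibited cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import as_intervals, merge_intervals, overlaps_any

VALID_UNITS = ("ratio", "U_per_Mb", "RT_score")


@dataclass
class BinnedTrack:
    """Sorted, non-overlapping per-bin values over a genome.

    ``bins`` holds chrom/start/end/value; coordinates are 0-based half-open.
    ``units`` is one of ``ratio`` (enrichment over input), ``U_per_Mb``
    (absolute uracil probability) or ``RT_score`` (replication timing,
    higher = earlier).
    """

    bins: pd.DataFrame
    units: str = "ratio"

    def __post_init__(self):
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown track units {self.units!r}")
        df = as_intervals(self.bins)
        if "value" not in df.columns:
            raise ValueError("track frame needs a 'value' column")
        vals = df["value"].to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError("track values must be finite")
        if self.units in ("ratio", "U_per_Mb") and (vals < 0).any():
            i = int(np.argmax(vals < 0))
            raise ValueError(
                f"negative value {vals[i]} at {df.iloc[i]['chrom']}:{df.iloc[i]['start']} "
                f"is invalid for units {self.units!r}"
            )
        # no overlaps within chromosome
        for chrom, grp in df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            bad = np.nonzero(s[1:] < e[:-1])[0]
            if bad.size:
                k = bad[0]
                raise ValueError(
                    f"overlapping bins on {chrom}: [{s[k]},{e[k]}) and [{s[k+1]},{e[k+1]})"
                )
        self.bins = df

    # -- convenience accessors -------------------------------------------------
    @property
    def lengths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy(np.int64)

    @property
    def values(self) -> np.ndarray:
        return self.bins["value"].to_numpy(float)

    def weighted_mean(self) -> float:
        """Length-weighted genome-wide mean of the track."""
        L = self.lengths
        return float(np.sum(self.values * L) / np.sum(L))

    def total_bp(self) -> int:
        return int(self.lengths.sum())


def read_bedgraph(path, units: str = "ratio") -> BinnedTrack:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: malformed bedGraph near line {bad}")
    # report the first offending line for unsorted/overlapping input
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        bad = np.nonzero(s[1:] < e[:-1])[0]
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 1
            raise ValueError(f"{path}: unsorted or overlapping bins at line {line}")
    return BinnedTrack(df, units=units)


def write_bedgraph(track: BinnedTrack, path) -> None:
    df = track.bins.copy()
    df["value"] = [format(v, ".17g") for v in df["value"]]
    df.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "value"])


def clean_track(track: BinnedTrack, *exclusion_sets: pd.DataFrame) -> BinnedTrack:
    """Drop bins overlapping blacklist / hard-mask intervals.

    A bin is removed if it overlaps *any* exclusion interval by >=1 bp;
    surviving bins keep their values untouched.
    """
    parts = [as_intervals(x) for x in exclusion_sets if x is not None and len(x)]
    if not parts:
        return BinnedTrack(track.bins.copy(), units=track.units)
    excl = merge_intervals(pd.concat(parts, ignore_index=True)[["chrom", "start", "end"]])
    keep = ~overlaps_any(track.bins, excl)
    if not keep.any():
        raise ValueError("cleaning removed every bin; nothing left to normalize")
    return BinnedTrack(track.bins[keep].reset_index(drop=True), units=track.units)


def rescale_to_ptrack(ratio_track: BinnedTrack, content: float, sample: str | None = None) -> BinnedTrack:
    """Rescale a cleaned enrichment-ratio track to absolute U/Mb (p-track).

    A single scalar C is chosen so the length-weighted mean of p = C*r over
    the retained bins equals the sample's measured global uracil content
    (U per million bp).  Excluded (blacklisted/hard-masked) regions are
    assumed to carry the genome-mean uracil frequency and are simply not
    written, so they do not perturb C.

    Conservation: sum(p_i * len_i) == content * retained_bp exactly.
    """
    if content <= 0:
        raise ValueError(f"global uracil content must be positive, got {content}")
    if ratio_track.units != "ratio":
        raise ValueError("rescale_to_ptrack expects a ratio track")
    mean_r = ratio_track.weighted_mean()
    if mean_r == 0:
        raise ValueError("all-zero ratio track: scaling factor undefined")
    C = content / mean_r
    out = ratio_track.bins.copy()
    out["value"] = out["value"].to_numpy(float) * C
    return BinnedTrack(out, units="U_per_Mb")


def average_over_intervals(track: BinnedTrack, intervals: pd.DataFrame,
                           chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Base-pair-weighted track mean over each query interval.

    Returns a frame with the query's columns plus ``mean`` and ``covered_bp``.
    Bases not covered by any track bin are excluded from the mean (covered-base
    averaging, the reference utility's default); an interval with zero covered
    bases gets mean NaN.  Intervals running past a known chromosome end are
    clipped with a warning.
    """
    iv = as_intervals(intervals)
    if chrom_sizes:
        over = iv["end"] > iv["chrom"].map(chrom_sizes).fillna(np.inf)
        if over.any():
            warnings.warn(f"{int(over.sum())} interval(s) clipped at chromosome end")
            iv.loc[over, "end"] = iv.loc[over, "chrom"].map(chrom_sizes).astype(np.int64)
            iv = iv[iv["end"] > iv["start"]].reset_index(drop=True)

    per_chrom = {}
    for chrom, grp in track.bins.groupby("chrom", sort=False):
        per_chrom[chrom] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["value"].to_numpy(float),
        )

    means = np.full(len(iv), np.nan)
    covered = np.zeros(len(iv), dtype=np.int64)
    for i, rec in enumerate(iv.itertuples(index=False)):
        tup = per_chrom.get(rec.chrom)
        if tup is None:
            continue
        bs, be, bv = tup
        k = np.searchsorted(be, rec.start, side="right")
        acc = 0.0
        cov = 0
        while k < len(bs) and bs[k] < rec.end:
            lo = max(bs[k], rec.start)
            hi = min(be[k], rec.end)
            if hi > lo:
                acc += bv[k] * (hi - lo)
                cov += hi - lo
            k += 1
        covered[i] = cov
        if cov:
            means[i] = acc / cov
    out = iv.copy()
    out["mean"] = means
    out["covered_bp"] = covered
    return out
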