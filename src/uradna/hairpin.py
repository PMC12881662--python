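"""DNA stem-loop (hairpin) potential in the local context of substitutions.

Each SBS is examined in its +-15-nt genomic window (31 nt, variant at the
center).  A hairpin call is a loop of 3-6 nt flanked by two stem arms that
are exact reverse-complement matches of at least 4 nt; APOBEC3A in
particular prefers cytosines exposed in such loops, so C>T events are
classified by whether the substituted base sits inside a predicted loop.
No thermodynamic model is used — pairing is purely combinatorial
(Watson-Crick by default; G:T wobble behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import revcomp

DEFAULT_FLANK = 15
DEFAULT_MIN_STEM = 4
DEFAULT_LOOP_RANGE = (3, 6)

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = _WC | {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class HairpinCall:
    """One predicted stem-loop within a sequence window.

    ``loop_start``/``loop_len`` give the loop span in local window
    coordinates (0-based half-open [loop_start, loop_start+loop_len));
    the 5' stem arm occupies [loop_start-stem_len, loop_start) and the 3'
    arm [loop_start+loop_len, loop_start+loop_len+stem_len).
    """

    loop_start: int
    loop_len: int
    stem_len: int

    @property
    def loop_span(self) -> tuple[int, int]:
        return self.loop_start, self.loop_start + self.loop_len


def extract_context(variant, genome, flank: int = DEFAULT_FLANK) -> str | None:
    """Uppercase (2*flank+1)-nt window centered on the variant's ref base.

    Returns None (record skipped from hairpin analysis) when the position is
    closer than ``flank`` to a chromosome end or the window contains N.
    """
    chrom_seq = genome[variant.chrom]
    lo, hi = variant.pos - flank, variant.pos + flank + 1
    if lo < 0 or hi > len(chrom_seq):
        return None
    seq = str(chrom_seq[lo:hi]).upper()
    if "N" in seq:
        return None
    if seq[flank] != variant.ref:
        raise ValueError(f"window center {seq[flank]} != ref {variant.ref} "
                         f"at {variant.chrom}:{variant.pos}")
    return seq


def find_hairpins(seq: str, min_stem: int = DEFAULT_MIN_STEM,
                  loop_min: int = DEFAULT_LOOP_RANGE[0],
                  loop_max: int = DEFAULT_LOOP_RANGE[1],
                  wobble: bool = False) -> list[HairpinCall]:
    """Enumerate all stem-loops in a window: loop of loop_min..loop_max nt
    flanked by reverse-complementary arms of >= min_stem nt.

    For every candidate loop placement the stem is extended outward base by
    base as far as pairing allows; the maximal extension is reported once
    per (loop_start, loop_len), never its sub-stems.
    """
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T}")
    pairs = _WOBBLE if wobble else _WC
    n = len(seq)
    calls = []
    for loop_len in range(loop_min, loop_max + 1):
        for loop_start in range(min_stem, n - loop_len - min_stem + 1):
            stem = 0
            i = loop_start - 1
            j = loop_start + loop_len
            while i >= 0 and j < n and (seq[i], seq[j]) in pairs:
                stem += 1
                i -= 1
                j += 1
            if stem >= min_stem:
                calls.append(HairpinCall(loop_start, loop_len, stem))
    return calls


def classify_loop_position(center_idx: int, hairpins: list[HairpinCall]) -> bool:
    """True iff the window center lies inside the loop of any hairpin call."""
    return any(h.loop_span[0] <= center_idx < h.loop_span[1] for h in hairpins)


def annotate_hairpins(sbs: pd.DataFrame, genome, flank: int = DEFAULT_FLANK,
                      min_stem: int = DEFAULT_MIN_STEM,
                      loop_range: tuple[int, int] = DEFAULT_LOOP_RANGE,
                      wobble: bool = False) -> pd.DataFrame:
    """Per-variant hairpin report: n_hairpins, best stem/loop, in_loop flag.

    Records skipped for missing windows (chromosome edge, N) get
    ``window_ok = False`` and missing annotations.
    """
    rows = []
    for rec in sbs.itertuples(index=False):
        seq = extract_context(rec, genome, flank)
        if seq is None:
            rows.append((False, 0, np.nan, np.nan, False))
            continue
        hp = find_hairpins(seq, min_stem, loop_range[0], loop_range[1], wobble)
        best = max(hp, key=lambda h: (h.stem_len, -h.loop_len), default=None)
        rows.append((True, len(hp),
                     best.stem_len if best else np.nan,
                     best.loop_len if best else np.nan,
                     classify_loop_position(flank, hp)))
    ann = pd.DataFrame(rows, columns=["window_ok", "n_hairpins", "best_stem_len",
                                      "best_loop_len", "in_loop"])
    out = sbs.reset_index(drop=True).copy()
    return pd.concat([out, ann], axis=1)


def loop_context_fractions(annotated: pd.DataFrame,
                           cluster_table: pd.DataFrame | None = None) -> dict:
    """Percentage of C>T among all SBS, overall / loop-located / clustered.

    Each percentage uses as denominator all SBS of the corresponding context
    set (all records, loop-located records, cluster members); empty sets
    give a missing value.  ``cluster_table`` is cluster_variants output and
    is matched on (chrom, pos).
    """

    def pct(df: pd.DataFrame) -> float:
        if not len(df):
            return float("nan")
        return 100.0 * (df["sbs_type"] == "C>T").mean()

    out = {"pct_ct_all": pct(annotated)}
    loop = annotated[annotated["window_ok"] & annotated["in_loop"]]
    out["pct_ct_loop"] = pct(loop)
    if cluster_table is not None:
        keys = set(zip(cluster_table["chrom"], cluster_table["pos"]))
        clustered = annotated[[
            (c, p) in keys for c, p in zip(annotated["chrom"], annotated["pos"])]]
        out["pct_ct_clustered"] = pct(clustered)
    else:
        out["pct_ct_clustered"] = float("nan")
    return out
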