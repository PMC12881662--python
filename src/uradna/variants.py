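"""Somatic variant filtering, SBS/DBS classification, and weighted spectra inputs.

Variants come from a somatic caller (Mutect2-style VCFs with FILTER labels
and allele frequencies).  Records carrying any of the caller's soft-filter
labels {weak_evidence, normal_artifact, slippage, germline, base_qual} are
excluded; single-base substitutions are collapsed onto the pyrimidine
strand into the six classes C>A, C>G, C>T, T>A, T>C, T>G with tri- and
pentanucleotide contexts, and downstream statistics weight each record by
its allele frequency (AF): the occurrence of a class is the AF sum over its
records and its frequency is that occurrence over the total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

EXCLUDED_LABELS = frozenset(
    {"weak_evidence", "normal_artifact", "slippage", "germline", "base_qual"})
SBS_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = str.maketrans("ACGTN", "TGCAN")

VARIANT_COLS = ["chrom", "pos", "ref", "alt", "af", "filter"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _record_af(v, alt_index: int):
    """AF precedence: INFO/AF, else FORMAT/AF (first sample), else AD-derived."""
    af = v.INFO.get("AF")
    if af is not None:
        if isinstance(af, (tuple, list)):
            af = af[alt_index]
        return float(af)
    try:
        fmt = v.format("AF")
    except KeyError:
        fmt = None
    if fmt is not None:
        val = np.asarray(fmt, float).ravel()
        if alt_index < len(val) and np.isfinite(val[alt_index]):
            return float(val[alt_index])
    try:
        ad = v.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        ad = np.asarray(ad, float)[0]
        tot = np.nansum(ad)
        if tot > 0:
            return float(ad[alt_index + 1] / tot)
    return np.nan


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a variant frame; multi-allelic records are split.

    Positions are converted from VCF 1-based to 0-based on read.  FILTER is
    kept as a semicolon-joined label string ('PASS' when empty).
    """
    rows = []
    for v in VCF(str(path)):
        filt = v.FILTER if v.FILTER else "PASS"
        for i, alt in enumerate(v.ALT):
            rows.append((v.CHROM, v.POS - 1, v.REF, alt, _record_af(v, i), filt))
    df = pd.DataFrame(rows, columns=VARIANT_COLS)
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def filter_variants(variants: pd.DataFrame,
                    excluded_labels=EXCLUDED_LABELS) -> pd.DataFrame:
    """Drop records whose FILTER labels intersect the excluded set."""
    excluded = set(excluded_labels)

    def keep(filt: str) -> bool:
        return not (set(filt.split(";")) & excluded)

    out = variants[variants["filter"].map(keep)].reset_index(drop=True)
    n_noaf = int(out["af"].isna().sum())
    if n_noaf:
        log.info("%d filtered record(s) lack AF; retained but excluded from "
                 "weighted statistics", n_noaf)
    return out


def is_sbs(variants: pd.DataFrame) -> pd.Series:
    return (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1) \
        & variants["ref"].isin(list("ACGT")) & variants["alt"].isin(list("ACGT"))


def classify_sbs(variants: pd.DataFrame, genome) -> pd.DataFrame:
    """Annotate SBS records with pyrimidine-collapsed type and contexts.

    ``genome`` is a pyfaidx.Fasta.  The reference allele is checked against
    the genome (a mismatch means a coordinate-convention bug and raises).
    Purine-reference records are reverse-complemented so contexts are always
    reported on the pyrimidine strand; tri = -1..+1, penta = -2..+2 around
    the substituted base.  Records whose context runs off the chromosome end
    or contains N get a missing context but keep their type.
    """
    sbs = variants[is_sbs(variants)].copy()
    types, tris, pentas = [], [], []
    for rec in sbs.itertuples(index=False):
        chrom_seq = genome[rec.chrom]
        clen = len(chrom_seq)
        ref_g = str(chrom_seq[rec.pos]).upper()
        if ref_g != rec.ref:
            raise ValueError(
                f"reference mismatch at {rec.chrom}:{rec.pos} (0-based): "
                f"VCF says {rec.ref}, genome says {ref_g}")
        ref, alt = rec.ref, rec.alt
        lo2, hi2 = rec.pos - 2, rec.pos + 3
        if lo2 >= 0 and hi2 <= clen:
            penta = str(chrom_seq[lo2:hi2]).upper()
        else:
            penta = None
        if ref in "GA":  # collapse onto pyrimidine strand
            ref, alt = revcomp(ref), revcomp(alt)
            penta = revcomp(penta) if penta else None
        types.append(f"{ref}>{alt}")
        if penta and "N" not in penta:
            pentas.append(penta)
            tris.append(penta[1:4])
        elif penta:
            pentas.append(None)
            tris.append(penta[1:4] if "N" not in penta[1:4] else None)
        else:
            # retry the trinucleotide window alone near chromosome ends
            lo1, hi1 = rec.pos - 1, rec.pos + 2
            if lo1 >= 0 and hi1 <= clen:
                tri = str(chrom_seq[lo1:hi1]).upper()
                if rec.ref in "GA":
                    tri = revcomp(tri)
                tris.append(tri if "N" not in tri else None)
            else:
                tris.append(None)
            pentas.append(None)
    sbs["sbs_type"] = types
    sbs["tri"] = tris
    sbs["penta"] = pentas
    n_ctx = sum(t is None for t in tris)
    if n_ctx:
        log.info("%d SBS record(s) without usable context (chromosome edge or N)", n_ctx)
    return sbs.reset_index(drop=True)


def weighted_sbs_fractions(sbs: pd.DataFrame, weighted: bool = True) -> pd.DataFrame:
    """AF-weighted occurrence and fraction of the six SBS classes.

    occurrence_t = sum of AF over records of type t; fraction_t =
    occurrence_t / total occurrence.  ``weighted=False`` sets every AF to 1,
    reducing to plain count fractions.
    """
    df = sbs.copy()
    w = df["af"].to_numpy(float) if weighted else np.ones(len(df))
    df["_w"] = w
    df = df[np.isfinite(df["_w"])]
    if not len(df) or df["_w"].sum() == 0:
        raise ValueError("no records with usable allele frequency")
    occ = df.groupby("sbs_type")["_w"].sum()
    occ = occ.reindex(SBS_TYPES, fill_value=0.0)
    return pd.DataFrame({
        "sbs_type": SBS_TYPES,
        "occurrence": occ.to_numpy(),
        "fraction": (occ / occ.sum()).to_numpy(),
    })


def intermutational_distances(sbs: pd.DataFrame, type_filter: str | None = "C>T") -> pd.DataFrame:
    """Gaps between consecutive same-type events per chromosome.

    Chromosomes with fewer than two events contribute nothing.  Returns a
    frame (chrom, pos, imd) where imd is the distance to the previous event
    on the same chromosome.
    """
    df = sbs
    if type_filter is not None:
        df = df[df["sbs_type"] == type_filter]
    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        gaps = np.diff(pos)
        rows.extend(zip([chrom] * len(gaps), pos[1:], gaps))
    return pd.DataFrame(rows, columns=["chrom", "pos", "imd"])


def cluster_variants(sbs: pd.DataFrame, max_imd: int = 100,
                     min_size: int = 2, type_filter: str | None = None) -> pd.DataFrame:
    """Kataegis-style clusters: maximal runs with successive gaps <= max_imd.

    Scans position-sorted variants per chromosome; a run of >= min_size
    events whose consecutive gaps are all <= max_imd forms one cluster.
    Returns the input rows restricted to cluster members with an added
    ``cluster_id`` column; membership is deterministic.
    """
    df = sbs
    if type_filter is not None:
        df = df[df["sbs_type"] == type_filter]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cluster_id = np.full(len(df), -1, dtype=np.int64)
    next_id = 0
    for chrom, grp in df.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(np.int64)
        start = 0
        for k in range(1, len(pos) + 1):
            if k == len(pos) or pos[k] - pos[k - 1] > max_imd:
                if k - start >= min_size:
                    cluster_id[idx[start:k]] = next_id
                    next_id += 1
                start = k
    out = df.copy()
    out["cluster_id"] = cluster_id
    return out[out["cluster_id"] >= 0].reset_index(drop=True)


def stratify_by_rt(sbs: pd.DataFrame, rt_track, thresholds=(2.5, -2.5)) -> pd.DataFrame:
    """Assign variants to replication-timing strata by their bin's RT score.

    early: score > thresholds[0]; late: score < thresholds[1]; middle:
    in between, boundaries inclusive.  Positions not covered by the RT
    track go to 'unassigned'.  Returns the input with an ``rt_stratum``
    column; the strata plus unassigned partition the input.
    """
    hi, lo = thresholds
    per_chrom = {}
    for chrom, grp in rt_track.bins.groupby("chrom", sort=False):
        per_chrom[chrom] = (grp["start"].to_numpy(np.int64),
                            grp["end"].to_numpy(np.int64),
                            grp["value"].to_numpy(float))
    strata = []
    for rec in sbs.itertuples(index=False):
        tup = per_chrom.get(rec.chrom)
        label = "unassigned"
        if tup is not None:
            bs, be, bv = tup
            k = np.searchsorted(bs, rec.pos, side="right") - 1
            if k >= 0 and rec.pos < be[k]:
                score = bv[k]
                label = "early" if score > hi else ("late" if score < lo else "middle")
        strata.append(label)
    out = sbs.copy()
    out["rt_stratum"] = strata
    return out


def fractions_by_segment(sbs: pd.DataFrame, segmentation: pd.DataFrame,
                         target_type: str = "C>T") -> pd.DataFrame:
    """Per-segment-label AF-weighted fraction of one SBS class.

    Variants are assigned to the segment containing their position
    ('unassigned' if none); within each label the fraction is the AF sum of
    ``target_type`` records over the AF sum of all SBS records.  Labels with
    zero weighted occurrence report NaN.
    """
    per_chrom = {}
    for chrom, grp in segmentation.groupby("chrom", sort=False):
        per_chrom[chrom] = (grp["start"].to_numpy(np.int64),
                            grp["end"].to_numpy(np.int64),
                            grp["label"].to_numpy())
    labels = []
    for rec in sbs.itertuples(index=False):
        tup = per_chrom.get(rec.chrom)
        lab = "unassigned"
        if tup is not None:
            ss, se, sl = tup
            k = np.searchsorted(ss, rec.pos, side="right") - 1
            if k >= 0 and rec.pos < se[k]:
                lab = sl[k]
        labels.append(lab)
    df = sbs.copy()
    df["segment"] = labels
    df = df[np.isfinite(df["af"])]
    rows = []
    all_labels = sorted(set(segmentation["label"])) + (
        ["unassigned"] if "unassigned" in labels else [])
    for lab in all_labels:
        sub = df[df["segment"] == lab]
        tot = sub["af"].sum()
        target = sub.loc[sub["sbs_type"] == target_type, "af"].sum()
        rows.append((lab, len(sub), tot, target / tot if tot > 0 else np.nan))
    return pd.DataFrame(rows, columns=["label", "n_variants", "total_occurrence",
                                       f"{target_type}_fraction"])


# ---------------------------------------------------------------------------
# Doublet-base substitutions (DBS), 78 strand-agnostic categories
# ---------------------------------------------------------------------------

def _dbs78_categories() -> list[str]:
    """Canonical 78 strand-agnostic doublet categories (COSMIC DBS78 order)."""
    table = {
        "AC": ["CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"],
        "AT": ["CA", "CC", "CG", "GA", "GC", "TA"],
        "CC": ["AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"],
        "CG": ["AT", "GC", "GT", "TA", "TC", "TT"],
        "CT": ["AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"],
        "GC": ["AA", "AG", "AT", "CA", "CG", "TA"],
        "TA": ["AT", "CG", "CT", "GC", "GG", "GT"],
        "TC": ["AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"],
        "TG": ["AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"],
        "TT": ["AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"],
    }
    return [f"{r}>{a}" for r in sorted(table) for a in table[r]]


DBS78_CATEGORIES = _dbs78_categories()
_DBS78_SET = frozenset(DBS78_CATEGORIES)


def canonical_dbs(ref2: str, alt2: str) -> str:
    """Collapse a doublet substitution onto its canonical strand-agnostic label."""
    key = f"{ref2}>{alt2}"
    if key in _DBS78_SET:
        return key
    rc = f"{revcomp(ref2)}>{revcomp(alt2)}"
    if rc in _DBS78_SET:
        return rc
    raise ValueError(f"not a valid doublet substitution: {key}")


def detect_dbs(variants: pd.DataFrame, dbs_exclusive: bool = True):
    """Merge adjacent SBS pairs (gap 1 bp) into strand-agnostic doublets.

    Explicit 2-bp MNP records are accepted directly.  Three consecutive
    substituted bases are paired greedily left-to-right; the remainder stays
    an SBS (logged).  Returns (dbs_frame, sbs_frame) where the SBS frame has
    doublet constituents removed when ``dbs_exclusive``.
    """
    df = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    mnp2 = (df["ref"].str.len() == 2) & (df["alt"].str.len() == 2)
    sbs_mask = is_sbs(df).to_numpy()
    dbs_rows = []
    consumed = np.zeros(len(df), dtype=bool)
    for chrom, grp in df.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        for j, i in enumerate(idx):
            if consumed[i]:
                continue
            if mnp2[i]:
                dbs_rows.append((chrom, df.at[i, "pos"],
                                 canonical_dbs(df.at[i, "ref"], df.at[i, "alt"]),
                                 df.at[i, "af"]))
                consumed[i] = True
                continue
            if not sbs_mask[i] or j + 1 >= len(idx):
                continue
            nxt = idx[j + 1]
            if (sbs_mask[nxt] and not consumed[nxt]
                    and df.at[nxt, "pos"] == df.at[i, "pos"] + 1):
                ref2 = df.at[i, "ref"] + df.at[nxt, "ref"]
                alt2 = df.at[i, "alt"] + df.at[nxt, "alt"]
                afs = [df.at[i, "af"], df.at[nxt, "af"]]
                af = float(np.nanmean(afs)) if np.isfinite(afs).any() else np.nan
                dbs_rows.append((chrom, df.at[i, "pos"], canonical_dbs(ref2, alt2), af))
                consumed[i] = consumed[nxt] = True
    dbs = pd.DataFrame(dbs_rows, columns=["chrom", "pos", "dbs_type", "af"])
    if dbs_exclusive:
        sbs_out = df[sbs_mask & ~consumed].reset_index(drop=True)
    else:
        sbs_out = df[sbs_mask].reset_index(drop=True)
    n_runs = int(consumed.sum())
    if n_runs:
        log.info("detect_dbs: %d record(s) merged into %d doublet(s)", n_runs, len(dbs))
    return dbs, sbs_out
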