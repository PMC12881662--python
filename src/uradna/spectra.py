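"""Fixed-order mutational-spectrum vectors and NNLS signature refitting.

Spectra live in three canonical channel spaces: SBS96 (pyrimidine-strand
trinucleotide contexts), SBS1536 (pentanucleotide contexts) and DBS78
(strand-agnostic doublets).  A measured spectrum can be reconstituted as a
non-negative combination of reference signatures (e.g. APOBEC3A/B/C
deamination spectra plus a background) by non-negative least squares; fit
quality is the cosine similarity between measured and reconstituted
spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import DBS78_CATEGORIES, SBS_TYPES

_BASES = "ACGT"


def _sbs96_channels() -> list[str]:
    return [f"{f}[{sub}]{t}"
            for sub in SBS_TYPES for f in _BASES for t in _BASES]


def _sbs1536_channels() -> list[str]:
    return [f"{f2}{f1}[{sub}]{t1}{t2}"
            for sub in SBS_TYPES
            for f2, f1 in product(_BASES, repeat=2)
            for t1, t2 in product(_BASES, repeat=2)]


SBS96_CHANNELS = _sbs96_channels()
SBS1536_CHANNELS = _sbs1536_channels()
CHANNELS = {"SBS96": SBS96_CHANNELS, "SBS1536": SBS1536_CHANNELS,
            "DBS78": DBS78_CATEGORIES}


@dataclass
class SpectrumVector:
    """Counts or AF-weighted occurrences over a fixed canonical channel order."""

    kind: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        if self.kind not in CHANNELS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        self.values = np.asarray(self.values, float)
        if len(self.values) != len(CHANNELS[self.kind]):
            raise ValueError(
                f"{self.kind} spectrum needs {len(CHANNELS[self.kind])} channels, "
                f"got {len(self.values)}")
        if (self.values < 0).any():
            raise ValueError("spectrum values must be non-negative")
        if self.normalized and self.values.sum() > 0:
            if not np.isclose(self.values.sum(), 1.0):
                raise ValueError("normalized spectrum must sum to 1")

    @property
    def channels(self) -> list[str]:
        return CHANNELS[self.kind]

    def normalize(self) -> "SpectrumVector":
        s = self.values.sum()
        if s == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return SpectrumVector(self.kind, self.values / s, normalized=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": self.channels, "value": self.values})


def read_spectrum_tsv(path, kind: str) -> SpectrumVector:
    """Read a (channel, value) TSV; channels matched by name, any order."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    lut = dict(zip(df["channel"], df["value"]))
    missing = [c for c in CHANNELS[kind] if c not in lut]
    if missing:
        raise ValueError(f"{path}: missing channels, e.g. {missing[:3]}")
    return SpectrumVector(kind, [lut[c] for c in CHANNELS[kind]])


def write_spectrum_tsv(spec: SpectrumVector, path) -> None:
    spec.to_frame().to_csv(path, sep="\t", index=False)


def _context_matrix(sbs: pd.DataFrame, ctx_col: str, channels: list[str],
                    kind: str, af_weighted: bool) -> SpectrumVector:
    idx = {c: i for i, c in enumerate(channels)}
    vals = np.zeros(len(channels))
    skipped = 0
    flank = 1 if kind == "SBS96" else 2
    for rec in sbs.itertuples(index=False):
        ctx = getattr(rec, ctx_col)
        if ctx is None or (isinstance(ctx, float) and np.isnan(ctx)):
            skipped += 1
            continue
        channel = f"{ctx[:flank]}[{rec.sbs_type}]{ctx[flank + 1:]}"
        w = rec.af if af_weighted else 1.0
        if af_weighted and not np.isfinite(w):
            skipped += 1
            continue
        vals[idx[channel]] += w
    if skipped:
        warnings.warn(f"{kind}: {skipped} record(s) skipped (no context or AF)")
    return SpectrumVector(kind, vals)


def sbs96_matrix(sbs: pd.DataFrame, af_weighted: bool = False) -> SpectrumVector:
    """96-channel trinucleotide spectrum from classified SBS records."""
    return _context_matrix(sbs, "tri", SBS96_CHANNELS, "SBS96", af_weighted)


def sbs1536_matrix(sbs: pd.DataFrame, af_weighted: bool = False) -> SpectrumVector:
    """1,536-channel pentanucleotide spectrum from classified SBS records."""
    return _context_matrix(sbs, "penta", SBS1536_CHANNELS, "SBS1536", af_weighted)


def dbs78_matrix(dbs: pd.DataFrame, af_weighted: bool = False) -> SpectrumVector:
    """78-category strand-agnostic doublet spectrum from detect_dbs output."""
    idx = {c: i for i, c in enumerate(DBS78_CATEGORIES)}
    vals = np.zeros(78)
    for rec in dbs.itertuples(index=False):
        w = rec.af if af_weighted else 1.0
        if af_weighted and not np.isfinite(w):
            continue
        vals[idx[rec.dbs_type]] += w
    return SpectrumVector("DBS78", vals)


def collapse_1536_to_96(spec: SpectrumVector) -> SpectrumVector:
    """Marginalize the +-2 flanks of a 1,536 spectrum down to 96 channels."""
    if spec.kind != "SBS1536":
        raise ValueError("expects an SBS1536 spectrum")
    idx96 = {c: i for i, c in enumerate(SBS96_CHANNELS)}
    out = np.zeros(96)
    for channel, v in zip(SBS1536_CHANNELS, spec.values):
        inner = channel[1:-1]  # strip outermost flanking bases
        out[idx96[inner]] += v
    return SpectrumVector("SBS96", out)


def cosine_similarity(a: SpectrumVector, b: SpectrumVector) -> float:
    """a.b / (|a||b|); scale-invariant, in [0,1] for non-negative spectra."""
    if a.kind != b.kind:
        raise ValueError(f"kind mismatch: {a.kind} vs {b.kind}")
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(a.values, b.values) / (na * nb))


@dataclass
class RefitResult:
    """Non-negative decomposition of a measured spectrum into components."""

    component_names: list[str]
    weights: np.ndarray
    contributions: np.ndarray
    reconstituted: SpectrumVector
    cosine: float
    residual: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"component": self.component_names,
                             "weight": self.weights,
                             "contribution": self.contributions})


def refit_spectrum(measured: SpectrumVector,
                   components: dict[str, SpectrumVector] | list[SpectrumVector]) -> RefitResult:
    """Refit a measured spectrum as a non-negative mixture of fixed signatures.

    Both the measured spectrum and the components are normalized to
    probability vectors; weights solve argmin ||m - C w||_2 subject to
    w >= 0 (NNLS), contributions are the weights renormalized to sum 1, and
    the reconstituted spectrum is the renormalized weighted sum.  With
    duplicate components the solution is non-unique; NNLS's deterministic
    active-set order breaks the tie and a warning is emitted.
    """
    if isinstance(components, dict):
        names = list(components.keys())
        comps = list(components.values())
    else:
        names = [f"component_{i}" for i in range(len(components))]
        comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    m = measured.normalize().values
    C = np.column_stack([c.normalize().values for c in comps])
    for i in range(C.shape[1]):
        for j in range(i + 1, C.shape[1]):
            if np.allclose(C[:, i], C[:, j]):
                warnings.warn(f"components {names[i]!r} and {names[j]!r} are "
                              "identical; weights are non-unique (tie broken "
                              "by listing order)")
    w, rnorm = nnls(C, m)
    total = w.sum()
    if total > 0:
        contributions = w / total
        recon = SpectrumVector(measured.kind, C @ w).normalize()
        cos = cosine_similarity(measured, recon)
    else:
        contributions = np.zeros_like(w)
        recon = SpectrumVector(measured.kind, np.zeros_like(m))
        cos = float("nan")
    return RefitResult(names, w, contributions, recon, cos, float(rnorm))
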