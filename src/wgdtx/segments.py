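"""Allele-specific copy-number segments, WGD calling and timing.

A tumour is called whole-genome duplicated (WGD) when more than half of the
covered autosomal genome has a major (parental-allele) copy number of 2 or
more.  Among WGD tumours, timing relative to the bulk of chromosomal losses
is read from regions whose total copy number is 2: duplication before most
losses leaves those regions heterozygous (1+1), duplication after losses
doubles already-lost regions into homozygous (2+0) states.

Coordinates are 1-based, closed intervals throughout; a segment of
``start == end`` covers one basepair and lengths are ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AUTOSOMES",
    "Segment",
    "SegmentProfile",
    "WGDCall",
    "autosomal_mcn_fraction",
    "call_wgd",
    "classify_timing",
    "assign_gene_total_cn",
    "assign_gene_cnlr",
    "cnlr_from_total_cn",
    "tumor_ploidy",
    "read_segment_table",
    "profiles_from_table",
    "read_gene_table",
]

#: Autosome labels accepted after stripping any ``chr`` prefix.
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: Minimum tumour purity for a sample to enter the analysis.
DEFAULT_MIN_PURITY = 0.3


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based, closed)."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end < start: {self}")
        if not (self.major_cn >= self.minor_cn >= 0):
            raise ValueError(f"require major_cn >= minor_cn >= 0: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


@dataclass(frozen=True)
class SegmentProfile:
    """One sample's autosomal allele-specific copy-number profile.

    Non-autosomal segments are dropped at construction.  Segments must not
    overlap within a chromosome.
    """

    sample_id: str
    segments: tuple[Segment, ...]
    purity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        kept = tuple(
            s for s in self.segments if _norm_chrom(s.chrom) in AUTOSOMES
        )
        object.__setattr__(self, "segments", kept)
        by_chrom: dict[str, list[Segment]] = {}
        for s in kept:
            by_chrom.setdefault(_norm_chrom(s.chrom), []).append(s)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"{self.sample_id}: overlapping segments on chr{chrom} "
                        f"({a.start}-{a.end} and {b.start}-{b.end})"
                    )

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.segments)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "major_cn": [s.major_cn for s in self.segments],
                "minor_cn": [s.minor_cn for s in self.segments],
            }
        )


@dataclass(frozen=True)
class WGDCall:
    """WGD status and timing for one sample."""

    sample_id: str
    mcn_ge2_fraction: float
    is_wgd: bool
    timing: str  # "early", "late" or "none"
    het_cn2_len: int = 0
    hom_cn2_len: int = 0

    def __post_init__(self) -> None:
        if self.timing not in ("early", "late", "none"):
            raise ValueError(f"bad timing {self.timing!r}")
        if (self.timing == "none") == self.is_wgd:
            raise ValueError("timing must be early/late iff is_wgd")


def autosomal_mcn_fraction(profile: SegmentProfile) -> float:
    """Length-weighted fraction of covered autosomal bp with major CN >= 2.

    The denominator is the covered autosomal length of the profile, not the
    assembly length, so sparse profiles are not penalised.
    """
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: no autosomal segments")
    total = profile.covered_length
    qual = sum(s.length for s in profile.segments if s.major_cn >= 2)
    return qual / total


def classify_timing(profile: SegmentProfile, *, tie_break: str = "late") -> str:
    """Classify a WGD tumour's duplication as ``early`` or ``late``.

    Compares the aggregate length of heterozygous (1+1) versus homozygous
    (2+0) segments among regions with total copy number 2.  More
    heterozygous length means the duplication preceded the bulk of losses
    (early); otherwise it followed them (late).  Exact ties fall to
    ``tie_break`` (default ``"late"``, the conservative choice).
    """
    if tie_break not in ("early", "late"):
        raise ValueError("tie_break must be 'early' or 'late'")
    het = sum(
        s.length
        for s in profile.segments
        if s.total_cn == 2 and s.minor_cn == 1
    )
    hom = sum(
        s.length
        for s in profile.segments
        if s.total_cn == 2 and s.minor_cn == 0
    )
    if het == 0 and hom == 0:
        raise ValueError(
            f"{profile.sample_id}: timing undeterminable (no total-CN-2 segments)"
        )
    if het == hom:
        return tie_break
    return "early" if het > hom else "late"


def call_wgd(profile: SegmentProfile, *, tie_break: str = "late") -> WGDCall:
    """Call WGD status (strict ``> 0.5`` on the MCN>=2 fraction) and timing."""
    frac = autosomal_mcn_fraction(profile)
    is_wgd = frac > 0.5
    het = sum(
        s.length for s in profile.segments if s.total_cn == 2 and s.minor_cn == 1
    )
    hom = sum(
        s.length for s in profile.segments if s.total_cn == 2 and s.minor_cn == 0
    )
    timing = "none"
    if is_wgd:
        timing = classify_timing(profile, tie_break=tie_break)
    return WGDCall(
        sample_id=profile.sample_id,
        mcn_ge2_fraction=frac,
        is_wgd=is_wgd,
        timing=timing,
        het_cn2_len=het,
        hom_cn2_len=hom,
    )


def tumor_ploidy(profile: SegmentProfile) -> float:
    """Length-weighted mean total copy number over covered autosomes."""
    if not profile.segments:
        raise ValueError(f"{profile.sample_id}: no autosomal segments")
    num = sum(s.length * s.total_cn for s in profile.segments)
    return num / profile.covered_length


def cnlr_from_total_cn(total_cn, purity: float, ploidy: float = 2.0):
    """Copy-number log-ratio of a purity-mixed total copy number.

    Emulates a coverage-based per-gene log ratio: the purity-mixed copy
    number at the gene over the purity-mixed average copy number of the
    sample, log2((p * CN + 2(1-p)) / (p * ploidy + 2(1-p))).  Sequencing
    coverage measures relative abundance, so the ratio is referenced to the
    sample's own (purity-mixed) ploidy; for a diploid genome this reduces to
    log2 of the mixed copy number over 2, and is 0 for (1,1) regions at any
    purity.
    """
    total_cn = np.asarray(total_cn, dtype=float)
    mixed = purity * total_cn + 2.0 * (1.0 - purity)
    ref = purity * ploidy + 2.0 * (1.0 - purity)
    return np.log2(mixed / ref)


def assign_gene_total_cn(
    profile: SegmentProfile, genes: pd.DataFrame
) -> pd.Series:
    """Total copy number of the segment carrying each gene.

    ``genes`` needs columns ``chrom``, ``start``, ``end``, ``gene_id``
    (1-based closed intervals).  A gene spanning a segment boundary takes the
    total copy number of the segment with the largest overlap (first by
    coordinate on an exact tie); genes overlapping no segment get NaN.
    """
    seg_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for s in profile.segments:
        seg_by_chrom.setdefault(_norm_chrom(s.chrom), []).append(s)  # type: ignore[attr-defined]
    for chrom, segs in list(seg_by_chrom.items()):
        segs = sorted(segs, key=lambda s: s.start)
        seg_by_chrom[chrom] = (
            np.array([s.start for s in segs]),
            np.array([s.end for s in segs]),
            np.array([s.total_cn for s in segs], dtype=float),
        )

    cn = np.full(len(genes), np.nan)
    chroms = genes["chrom"].map(_norm_chrom).to_numpy()
    gstart = genes["start"].to_numpy()
    gend = genes["end"].to_numpy()
    for chrom in np.unique(chroms):
        if chrom not in seg_by_chrom:
            continue
        sstart, send, stot = seg_by_chrom[chrom]
        idx = np.flatnonzero(chroms == chrom)
        # closed-interval overlap in bp: may be <= 0 when disjoint
        ov = np.minimum(gend[idx, None], send[None, :]) - np.maximum(
            gstart[idx, None], sstart[None, :]
        ) + 1
        best = np.argmax(ov, axis=1)  # first maximum = leftmost segment on tie
        hit = ov[np.arange(len(idx)), best] > 0
        cn[idx[hit]] = stot[best[hit]]
    return pd.Series(
        cn,
        index=pd.Index(genes["gene_id"], name="gene_id"),
        name=profile.sample_id,
    )


def assign_gene_cnlr(
    profile: SegmentProfile, genes: pd.DataFrame
) -> pd.Series:
    """Per-gene copy-number log-ratio for one sample.

    Combines :func:`assign_gene_total_cn` (largest-overlap segment rule)
    with :func:`cnlr_from_total_cn` referenced to the sample's own
    length-weighted ploidy; genes with no overlapping segment get NaN.
    """
    cn = assign_gene_total_cn(profile, genes)
    return pd.Series(
        cnlr_from_total_cn(
            cn.to_numpy(), profile.purity, tumor_ploidy(profile)
        ),
        index=cn.index,
        name=profile.sample_id,
    )


# ---------------------------------------------------------------------------
# I/O


def read_segment_table(path) -> pd.DataFrame:
    """Read a segment TSV with columns sample, chrom, start, end, major_cn, minor_cn."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample", "chrom", "start", "end", "major_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def profiles_from_table(
    df: pd.DataFrame,
    purity: Mapping[str, float],
    *,
    min_purity: float = DEFAULT_MIN_PURITY,
) -> dict[str, SegmentProfile]:
    """Build per-sample profiles, excluding samples below the purity cutoff.

    Rows with missing allele-specific copy number are dropped.
    """
    df = df.dropna(subset=["major_cn", "minor_cn"])
    profiles: dict[str, SegmentProfile] = {}
    for sample, sub in df.groupby("sample", sort=True):
        if sample not in purity:
            raise KeyError(f"no purity for sample {sample!r}")
        p = float(purity[sample])
        if p < min_purity:
            continue
        segs = tuple(
            Segment(
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                major_cn=int(r.major_cn),
                minor_cn=int(r.minor_cn),
            )
            for r in sub.itertuples()
        )
        profiles[str(sample)] = SegmentProfile(str(sample), segs, p)
    return profiles


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene annotation TSV (chrom, start, end, gene_id; 1-based closed)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df
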