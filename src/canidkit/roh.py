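"""Runs of homozygosity: sliding-window detection, F_ROH, ROH-free regions.

The detector follows the PLINK ``--homozyg`` sliding-window scheme: a
window of ``window_snp`` consecutive SNPs passes if it holds at most
``window_het`` heterozygous and ``window_missing`` missing calls; a SNP is
a "hit" if at least ``hit_threshold`` of the windows overlapping it pass;
maximal runs of hit SNPs become segments after length, SNP-count, density
and gap filtering.  Defaults are the study parameters: density 50 kb/SNP,
gap 1000 kb, minimum length 200 kb, 100-SNP windows with 3 heterozygotes
and 2 missing calls tolerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import MISSING, CohortGenotypes
from canidkit.maskcall import GenomeMask


@dataclass
class RohParams:
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    min_length_kb: float = 200.0
    window_snp: int = 100
    window_het: int = 3
    window_missing: int = 2
    hit_threshold: float = 0.05
    min_snps: int = 100

    def __post_init__(self) -> None:
        for name in (
            "min_density_kb_per_snp",
            "max_gap_kb",
            "min_length_kb",
            "window_snp",
            "hit_threshold",
            "min_snps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start: int  # position of the first SNP (1-based, inclusive)
    end: int    # position of the last SNP
    n_snps: int
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def _hit_snps(genos: np.ndarray, params: RohParams) -> np.ndarray:
    """Boolean hit status per SNP from the sliding-window vote (vectorised)."""
    n = len(genos)
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    is_het = (genos == 1).astype(np.int64)
    is_mis = (genos == MISSING).astype(np.int64)
    ch = np.concatenate([[0], np.cumsum(is_het)])
    cm = np.concatenate([[0], np.cumsum(is_mis)])
    starts = np.arange(n - w + 1)
    passes = (
        (ch[starts + w] - ch[starts] <= params.window_het)
        & (cm[starts + w] - cm[starts] <= params.window_missing)
    ).astype(np.int64)
    cp = np.concatenate([[0], np.cumsum(passes)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(n - w, idx)
    n_windows = hi - lo + 1
    n_pass = cp[hi + 1] - cp[lo]
    return n_pass / n_windows >= params.hit_threshold


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start_index, end_index) inclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.view(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [len(mask) - 1]
    return list(zip(starts, ends))


def _segments_from_hits(
    hits: np.ndarray,
    pos: np.ndarray,
    genos: np.ndarray,
    chrom: str,
    sample: str,
    params: RohParams,
) -> list[RohSegment]:
    out = []
    max_gap = params.max_gap_kb * 1000
    for s0, e0 in _runs(hits):
        # split the candidate run at inter-SNP gaps exceeding the cap
        pieces = [(s0, e0)]
        gap_breaks = np.flatnonzero(np.diff(pos[s0 : e0 + 1]) > max_gap)
        if len(gap_breaks):
            pieces = []
            a = s0
            for gb in gap_breaks:
                pieces.append((a, s0 + gb))
                a = s0 + gb + 1
            pieces.append((a, e0))
        for s, e in pieces:
            n_snps = e - s + 1
            length = pos[e] - pos[s] + 1
            if length < params.min_length_kb * 1000:
                continue
            if n_snps < params.min_snps:
                continue
            if length / n_snps > params.min_density_kb_per_snp * 1000:
                continue
            n_het = int((genos[s : e + 1] == 1).sum())
            out.append(
                RohSegment(sample, chrom, int(pos[s]), int(pos[e]), n_snps, n_het)
            )
    return out


def detect_roh(
    cohort: CohortGenotypes,
    params: RohParams | None = None,
    include_x: bool = False,
) -> list[RohSegment]:
    """Per-sample ROH segments over autosomal (by default) diploid SNPs.

    Chromosomes carrying fewer SNPs than the window size yield no calls.
    """
    params = params or RohParams()
    region = cohort.region_classes()
    keep = region == "autosome"
    if include_x:
        keep |= np.isin(region, ("X_PAR", "X_nonPAR"))
    chroms = cohort.chroms()
    pos = cohort.positions()
    segments: list[RohSegment] = []
    for chrom in np.unique(chroms[keep]):
        sel = np.flatnonzero(keep & (chroms == chrom))
        sel = sel[np.argsort(pos[sel], kind="stable")]
        cpos = pos[sel]
        for i, sample in enumerate(cohort.samples):
            genos = cohort.dosage[i, sel]
            hits = _hit_snps(genos, params)
            segments.extend(
                _segments_from_hits(hits, cpos, genos, str(chrom), sample.id, params)
            )
    return segments


@dataclass
class FrohReport:
    total_roh_bp: dict[str, int] = field(default_factory=dict)
    froh: dict[str, float] = field(default_factory=dict)


def froh(
    segments: list[RohSegment],
    genome_size_bp: int,
    sample_ids: list[str] | None = None,
) -> FrohReport:
    """F_ROH per sample: total ROH length over the genome size."""
    rep = FrohReport()
    if sample_ids:
        for sid in sample_ids:
            rep.total_roh_bp[sid] = 0
    by_sample: dict[str, list[RohSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample, []).append(seg)
    for sid, segs in by_sample.items():
        by_chrom: dict[str, list[RohSegment]] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom_segs in by_chrom.values():
            chrom_segs.sort(key=lambda s: s.start)
            for a, b in zip(chrom_segs, chrom_segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping ROH segments for sample {sid}"
                    )
        rep.total_roh_bp[sid] = sum(s.length_bp for s in segs)
    for sid, tot in rep.total_roh_bp.items():
        f = tot / genome_size_bp
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"F_ROH outside [0, 1] for {sid}: check genome size")
        rep.froh[sid] = f
    return rep


@dataclass
class RohFreeRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    uncallable_overlap: float
    flag_80: bool
    flag_20: bool


def roh_free_regions(
    segments: list[RohSegment],
    chrom_lengths: dict[str, int],
    mask: GenomeMask | None = None,
) -> list[RohFreeRegion]:
    """Regions never covered by any sample's ROH, with uncallable overlap.

    The complement of the union of all segments is reported per chromosome;
    when a mask is given each region carries its fraction of overlap with
    uncallable intervals and flags at the 80% and 20% levels.
    """
    out = []
    for chrom, L in chrom_lengths.items():
        ivs = sorted(
            (s.start - 1, s.end) for s in segments if s.chrom == chrom
        )  # to 0-based half-open
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        holes = []
        prev = 0
        for s, e in merged:
            if s > prev:
                holes.append((prev, s))
            prev = max(prev, e)
        if prev < L:
            holes.append((prev, L))
        for s, e in holes:
            frac = 0.0
            if mask is not None and chrom in mask.chrom_lengths:
                unc = ~mask.is_callable(chrom, np.arange(s, min(e, mask.chrom_lengths[chrom])))
                frac = float(unc.mean()) if len(unc) else 0.0
            out.append(RohFreeRegion(chrom, s, e, frac, frac >= 0.80, frac >= 0.20))
    return out
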