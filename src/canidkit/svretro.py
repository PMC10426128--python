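"""Retrogene detection from deletion calls, SV-SNV LD, per-sample SV burden.

A retrogene leaves a characteristic footprint when the sequenced genome
carries the reference haplotype's processed copy: deletion calls that
reciprocally overlap annotated introns at >= 99%.  Calls are aggregated by
parent gene; a sample is a carrier if it carries the deletion at a quorum
of the gene's introns (2 by default for multi-intron genes, since a single
shared intron deletion is ambiguous with an ordinary deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import MISSING, CohortGenotypes, GeneModel, SvCall


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|) for 0-based half-open intervals."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


@dataclass
class RetrogeneCall:
    gene_id: str
    transcript_id: str
    n_introns_total: int
    matched_introns: dict[int, float]  # intron index -> best reciprocal overlap
    carriers: list[str]
    per_sample_matches: dict[str, int] = field(default_factory=dict)


def detect_retrogenes(
    deletions: list[SvCall],
    genes: list[GeneModel],
    sample_ids: list[str],
    ro_min: float = 0.99,
    carrier_quorum: int = 2,
) -> list[RetrogeneCall]:
    """Match deletions to introns at >= ``ro_min`` reciprocal overlap.

    Transcripts with fewer than two exons are skipped (no introns).  For
    genes with a single intron the quorum is one; otherwise a sample must
    carry matches at >= ``carrier_quorum`` distinct introns.
    """
    dels = [
        sv for sv in deletions if sv.svtype == "DEL"
    ]
    starts = np.array([sv.start for sv in dels])
    ends = np.array([sv.end for sv in dels])
    chroms = np.array([sv.chrom for sv in dels])

    out: list[RetrogeneCall] = []
    for gene in genes:
        introns = gene.introns
        if not introns:
            continue
        matched: dict[int, float] = {}
        sample_hits: dict[str, set[int]] = {}
        for ii, (istart, iend) in enumerate(introns):
            # candidate deletions must overlap the intron at all
            cand = np.flatnonzero(
                (chroms == gene.chrom) & (starts < iend) & (ends > istart)
            )
            for di in cand:
                ro = reciprocal_overlap(
                    (int(starts[di]), int(ends[di])), (istart, iend)
                )
                if ro >= ro_min:
                    matched[ii] = max(matched.get(ii, 0.0), ro)
                    gt = dels[di].genotypes
                    for si in np.flatnonzero(gt >= 1):
                        sample_hits.setdefault(sample_ids[si], set()).add(ii)
        if not matched:
            continue
        quorum = 1 if len(introns) == 1 else min(carrier_quorum, len(introns))
        carriers = sorted(
            s for s, hits in sample_hits.items() if len(hits) >= quorum
        )
        if not carriers:
            continue
        out.append(
            RetrogeneCall(
                gene.gene_id,
                gene.transcript_id,
                len(introns),
                matched,
                carriers,
                {s: len(h) for s, h in sample_hits.items()},
            )
        )
    return out


# ---------------------------------------------------------------------------
# SV-SNV linkage disequilibrium


@dataclass
class LdResult:
    sv_id: str
    best_snv_index: int | None
    r2: float | None
    distance_bp: int | None
    strong_ld: bool  # r2 > 0.8


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    use = (a != MISSING) & (b != MISSING)
    if use.sum() < 2:
        return None
    x, y = a[use].astype(float), b[use].astype(float)
    if x.std() == 0 or y.std() == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def sv_snv_ld(
    svs: list[SvCall],
    snv_cohort: CohortGenotypes,
    window_bp: int = 100_000,
) -> list[LdResult]:
    """Best flanking-SNV dosage r² per SV within ``window_bp`` of a breakpoint.

    r² is the squared Pearson correlation of genotype dosages over mutually
    non-missing samples (composite LD; phase is not assumed).  SVs with no
    genotype variance yield a null r².
    """
    pos = snv_cohort.positions()
    chroms = snv_cohort.chroms()
    out = []
    for sv in svs:
        lo = sv.start + 1 - window_bp  # VCF-style 1-based breakpoints
        hi = sv.end + window_bp
        cand = np.flatnonzero((chroms == sv.chrom) & (pos >= lo) & (pos <= hi))
        best = (None, None, None)
        for j in cand:
            r2 = _dosage_r2(sv.genotypes, snv_cohort.dosage[:, j])
            if r2 is None:
                continue
            if best[1] is None or r2 > best[1]:
                dist = int(
                    min(abs(pos[j] - (sv.start + 1)), abs(pos[j] - sv.end))
                )
                best = (int(j), r2, dist)
        out.append(
            LdResult(
                sv.id,
                best[0],
                best[1],
                best[2],
                best[1] is not None and best[1] > 0.8,
            )
        )
    return out


# ---------------------------------------------------------------------------
# per-sample burden


@dataclass
class SvSampleSummary:
    per_sample_counts: dict[str, dict[str, int]]  # sample -> svtype -> count
    per_sample_affected_bp: dict[str, dict[str, int]]
    category_mean_counts: dict[str, dict[str, float]]
    size_histogram: dict[str, np.ndarray]  # svtype -> counts in log2 bins
    size_bins: np.ndarray


def sv_sample_summary(
    svs: list[SvCall],
    sample_ids: list[str],
    category_of: dict[str, str] | None = None,
    n_bins: int = 24,
) -> SvSampleSummary:
    """Carried-variant counts and affected bp per sample, plus size spectra.

    A sample carries an SV if it has >= 1 alternate allele; affected bp
    sums deletion spans and, separately, inserted bp.  The size histogram
    uses log2-spaced bins from 50 bp to 10 Mb per SV type.
    """
    counts = {s: {} for s in sample_ids}
    affected = {s: {} for s in sample_ids}
    bins = np.geomspace(50, 10_000_000, n_bins + 1)
    hist: dict[str, np.ndarray] = {}
    for sv in svs:
        hist.setdefault(sv.svtype, np.zeros(n_bins, dtype=np.int64))
        b = int(np.clip(np.searchsorted(bins, sv.length, side="right") - 1, 0, n_bins - 1))
        hist[sv.svtype][b] += 1
        for si in np.flatnonzero(sv.genotypes >= 1):
            s = sample_ids[si]
            counts[s][sv.svtype] = counts[s].get(sv.svtype, 0) + 1
            affected[s][sv.svtype] = affected[s].get(sv.svtype, 0) + sv.length

    cat_means: dict[str, dict[str, float]] = {}
    if category_of:
        by_cat: dict[str, list[str]] = {}
        for s in sample_ids:
            by_cat.setdefault(category_of.get(s, "unknown"), []).append(s)
        svtypes = sorted({sv.svtype for sv in svs})
        for cat, members in by_cat.items():
            cat_means[cat] = {
                t: float(np.mean([counts[s].get(t, 0) for s in members]))
                for t in svtypes
            }
    return SvSampleSummary(counts, affected, cat_means, hist, bins)
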