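"""Genome callability mask and fraction-of-theoretical-variation report.

A position is uncallable iff it is N in the reference, has an MQ0 read
fraction >= 0.10, or a pooled depth more than 50% away from the median
depth; the median is computed separately for {autosomes + X-PAR} and
{X non-PAR} and over non-N positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import SiteRecord
from canidkit.synthio import Tracks

MQ0_CUT = 0.10
DEPTH_BAND = 0.50


class GenomeMask:
    """Per-chromosome callable/uncallable labeling of every position.

    Stored internally as boolean arrays (True = callable); exposed as
    sorted disjoint 0-based half-open intervals whose union covers each
    chromosome exactly once.
    """

    def __init__(self, callable_by_chrom: dict[str, np.ndarray]):
        self._callable = {c: np.asarray(v, dtype=bool) for c, v in callable_by_chrom.items()}

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self._callable.items()}

    def is_callable(self, chrom: str, pos0: int | np.ndarray) -> np.ndarray:
        """Callable status at 0-based position(s)."""
        return self._callable[chrom][pos0]

    def callable_bases(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self._callable[chrom].sum())
        return sum(int(v.sum()) for v in self._callable.values())

    def uncallable_bases(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int((~self._callable[chrom]).sum())
        return sum(int((~v).sum()) for v in self._callable.values())

    def intervals(self, chrom: str) -> list[tuple[int, int, str]]:
        """Merged (start, end, label) runs covering [0, chrom_length)."""
        v = self._callable[chrom]
        if len(v) == 0:
            return []
        change = np.flatnonzero(np.diff(v.view(np.int8))) + 1
        bounds = np.concatenate([[0], change, [len(v)]])
        return [
            (int(bounds[i]), int(bounds[i + 1]), "callable" if v[bounds[i]] else "uncallable")
            for i in range(len(bounds) - 1)
        ]

    def uncallable_intervals(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, lab in self.intervals(chrom) if lab == "uncallable"]

    # -- BED round trip --------------------------------------------------

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._callable):
                for start, end, label in self.intervals(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")

    @classmethod
    def from_bed(cls, path) -> "GenomeMask":
        spans: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, label = line.split()[:4]
                spans.setdefault(chrom, []).append((int(start), int(end), label))
        out = {}
        for chrom, ivs in spans.items():
            length = max(e for _, e, _ in ivs)
            v = np.zeros(length, dtype=bool)
            for s, e, lab in ivs:
                v[s:e] = lab == "callable"
            out[chrom] = v
        return cls(out)


def build_mask(tracks: Tracks) -> GenomeMask:
    """Label every position callable/uncallable from pooled tracks.

    Median depth is computed over non-N positions, pooled within the two
    region-class groups (autosome + X-PAR vs X non-PAR) so the haploid male
    X gets its own cutoff.
    """
    if not tracks.coverage:
        raise ValueError("empty track set")
    for chrom, cov in tracks.coverage.items():
        if len(cov) == 0:
            raise ValueError(f"empty coverage track for {chrom}")
        if len(tracks.mq0_fraction[chrom]) != len(cov):
            raise ValueError(f"track length mismatch on {chrom}")

    def group_of(chrom: str) -> str:
        return "X_nonPAR" if tracks.region_class.get(chrom) == "X_nonPAR" else "auto_par"

    n_mask = {}
    for chrom, cov in tracks.coverage.items():
        m = np.zeros(len(cov), dtype=bool)
        for s, e in tracks.n_runs.get(chrom, []):
            m[s:e] = True
        n_mask[chrom] = m

    medians: dict[str, float] = {}
    for grp in {group_of(c) for c in tracks.coverage}:
        pooled = np.concatenate(
            [
                tracks.coverage[c][~n_mask[c]]
                for c in tracks.coverage
                if group_of(c) == grp
            ]
        )
        medians[grp] = float(np.median(pooled)) if len(pooled) else 0.0

    out = {}
    for chrom, cov in tracks.coverage.items():
        med = medians[group_of(chrom)]
        bad_depth = np.abs(cov - med) > DEPTH_BAND * med
        bad_mq0 = tracks.mq0_fraction[chrom] >= MQ0_CUT
        out[chrom] = ~(n_mask[chrom] | bad_mq0 | bad_depth)
    return GenomeMask(out)


@dataclass
class TheoreticalFractionReport:
    """Observed variable callable positions over all callable positions.

    Complementary reference bases are collapsed (A/T and C/G), and the
    per-base-change classes keep the full bookkeeping; chromosome groups
    (autosomes vs X) are reported separately by the caller via masks.
    """

    callable_base_counts: dict[str, int] = field(default_factory=dict)
    observed_variant_counts: dict[str, int] = field(default_factory=dict)
    total_callable: int = 0
    total_observed: int = 0
    n_excluded: int = 0
    fraction_by_class: dict[str, float] = field(default_factory=dict)

    @property
    def fraction_overall(self) -> float:
        return self.total_observed / self.total_callable if self.total_callable else 0.0


_COLLAPSE = {"A": "A/T", "T": "A/T", "C": "C/G", "G": "C/G"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _collapse_change(ref: str, alt: str) -> str:
    """Base-change class with complementary strands combined (A>C == T>G)."""
    if ref in ("A", "C"):
        return f"{ref}>{alt}"
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"


def theoretical_fraction(
    variants: list[SiteRecord],
    mask: GenomeMask,
    reference: dict[str, str],
) -> TheoreticalFractionReport:
    """Fraction of callable positions observed to vary, overall and by class.

    The denominator is the number of callable positions of each collapsed
    reference-base class (one potential SNV per position); variants at
    uncallable positions are excluded from the numerator and counted.
    """
    rep = TheoreticalFractionReport()
    for chrom, seq in reference.items():
        if chrom not in mask.chrom_lengths:
            continue
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        call = mask.is_callable(chrom, np.arange(len(seq)))
        for base, cls in _COLLAPSE.items():
            n = int((call & (arr == base.encode())).sum())
            rep.callable_base_counts[cls] = rep.callable_base_counts.get(cls, 0) + n
    rep.total_callable = sum(rep.callable_base_counts.values())

    for v in variants:
        if v.chrom not in mask.chrom_lengths or not bool(
            mask.is_callable(v.chrom, v.pos - 1)
        ):
            rep.n_excluded += 1
            continue
        cls = _collapse_change(v.ref_allele.upper(), v.alt_allele.upper())
        rep.observed_variant_counts[cls] = rep.observed_variant_counts.get(cls, 0) + 1
    rep.total_observed = sum(rep.observed_variant_counts.values())

    for cls, n in rep.observed_variant_counts.items():
        denom = rep.callable_base_counts.get(cls.split(">")[0] + ("/T" if cls[0] == "A" else "/G"), 0)
        rep.fraction_by_class[cls] = n / denom if denom else 0.0
    return rep
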