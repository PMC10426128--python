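"""Circular mitochondrial coordinate handling, call merging and diversity.

The mitochondrial genome is circular but aligned against two linear
references, the second rotated to start at position 8000, so that variants
near the origin — lost at the linear ends of the primary reference — are
recovered from the rotated alignment.  Merging takes calls in the first
and last 4 kb of the primary coordinate system from the rotated call set
and everything else from the primary one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import MitoCall

DEFAULT_MASK_POSITIONS = tuple(range(15_512, 15_536)) + (15_990,)


def rotate_coord(pos: int, L: int, S: int, direction: str = "primary_to_rotated") -> int:
    """Map a 1-based circular coordinate between the two linear references.

    primary -> rotated: ((pos - S) mod L) + 1; the inverse map composes to
    the identity for every position.
    """
    if not 1 <= pos <= L:
        raise ValueError(f"position {pos} outside [1, {L}]")
    if not 1 <= S <= L:
        raise ValueError(f"rotation offset {S} outside [1, {L}]")
    if direction == "primary_to_rotated":
        return ((pos - S) % L) + 1
    if direction == "rotated_to_primary":
        return ((pos - 1 + S - 1) % L) + 1
    raise ValueError(f"unknown direction {direction!r}")


def merge_rotated_calls(
    primary_calls: list[MitoCall],
    rotated_calls: list[MitoCall],
    L: int,
    S: int,
    end_window: int = 4000,
) -> list[MitoCall]:
    """Merge per-reference call sets into primary coordinates.

    Positions in [1, end_window] or (L - end_window, L] come from the
    rotated call set (converted to primary coordinates); all other
    positions come from the primary set.  Each emitted call keeps its
    source provenance.  Duplicate positions are resolved strictly by
    window membership.
    """
    if L <= 2 * end_window:
        raise ValueError(
            f"reference length {L} must exceed twice the end window {end_window}"
        )

    def in_end_window(pos: int) -> bool:
        return pos <= end_window or pos > L - end_window

    merged: dict[int, MitoCall] = {}
    for call in primary_calls:
        if not in_end_window(call.pos):
            merged[call.pos] = call
    for call in rotated_calls:
        ppos = rotate_coord(call.pos, L, S, "rotated_to_primary")
        if in_end_window(ppos):
            merged[ppos] = MitoCall(
                ppos,
                call.ref,
                call.alt,
                call.allele_fraction,
                call.strand_bias_fail,
                call.depth,
                "rotated",
            )
    return [merged[p] for p in sorted(merged)]


@dataclass
class MitoGenome:
    """Circular consensus sequence with N-masked low-confidence positions."""

    sequence: str
    masked: np.ndarray  # boolean per position

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.masked):
            raise ValueError("sequence and mask length differ")

    @property
    def length(self) -> int:
        return len(self.sequence)


def filter_mito_calls(
    calls: list[MitoCall],
    reference: str,
    depth: np.ndarray,
    het_fraction_cut: float = 0.5,
    mask_positions: tuple[int, ...] = DEFAULT_MASK_POSITIONS,
    min_depth: int = 100,
) -> tuple[list[MitoCall], MitoGenome]:
    """Drop heteroplasmic/strand-biased calls and build a masked consensus.

    Calls with a strand-bias failure or an allele fraction strictly below
    0.5 are removed.  The consensus applies retained substitutions to the
    reference and sets positions with depth < 100 or in the reference-
    specific mask list to 'N'.  Retained calls at masked positions stay in
    the call list but do not reach the consensus.
    """
    L = len(reference)
    if len(depth) != L:
        raise ValueError("depth track must cover every reference position")
    kept = [
        c
        for c in calls
        if not c.strand_bias_fail and c.allele_fraction >= het_fraction_cut
    ]
    seq = list(reference.upper())
    masked = np.zeros(L, dtype=bool)
    masked[np.asarray(depth) < min_depth] = True
    for p in mask_positions:
        if 1 <= p <= L:
            masked[p - 1] = True
    for c in kept:
        if not masked[c.pos - 1]:
            seq[c.pos - 1] = c.alt
    for i in np.flatnonzero(masked):
        seq[i] = "N"
    return kept, MitoGenome("".join(seq), masked)


# ---------------------------------------------------------------------------
# haplogroups and diversity


@dataclass
class HaplogroupAssignment:
    sample: str
    best_reference: str
    haplogroup: str
    distance: int
    tie: bool


def _hamming_unmasked(a: MitoGenome, b: MitoGenome) -> int:
    aa = np.frombuffer(a.sequence.encode(), dtype="S1")
    bb = np.frombuffer(b.sequence.encode(), dtype="S1")
    ok = ~(a.masked | b.masked) & (aa != b"N") & (bb != b"N")
    return int(((aa != bb) & ok).sum())


def assign_haplogroup(
    sample_id: str,
    genome: MitoGenome,
    panel: dict[str, tuple[str, MitoGenome]],  # ref id -> (haplogroup, genome)
) -> HaplogroupAssignment:
    """Nearest labeled panel haplotype by Hamming distance over unmasked sites.

    Exact ties set the tie flag and report the lexicographically first
    haplogroup label.
    """
    if not panel:
        raise ValueError("empty reference panel")
    if genome.masked.all():
        raise ValueError("all positions masked: cannot assign a haplogroup")
    scored = []
    for ref_id, (group, ref_genome) in panel.items():
        if ref_genome.length != genome.length:
            raise ValueError("panel and query sequences must share a length")
        scored.append((_hamming_unmasked(genome, ref_genome), group, ref_id))
    scored.sort()
    best = scored[0]
    tie = len(scored) > 1 and scored[1][0] == best[0]
    return HaplogroupAssignment(sample_id, best[2], best[1], best[0], tie)


@dataclass
class DiversityReport:
    group: str
    n: int
    mean_pairwise_differences: float
    n_haplotypes: int


def pairwise_diversity(
    group_label: str, genomes: dict[str, MitoGenome]
) -> DiversityReport:
    """Mean pairwise Hamming differences within a group of >= 3 samples.

    Positions masked in either member of a pair are excluded for that pair;
    the distinct-haplotype count uses the unmasked sequence string.
    """
    if len(genomes) < 3:
        raise ValueError(
            f"group {group_label!r} has {len(genomes)} samples; need >= 3"
        )
    ids = sorted(genomes)
    diffs = [
        _hamming_unmasked(genomes[a], genomes[b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    ]
    haplotypes = {genomes[s].sequence for s in ids}
    return DiversityReport(
        group_label, len(ids), float(np.mean(diffs)), len(haplotypes)
    )
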