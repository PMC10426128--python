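"""Shared data model: samples, sites, genotype matrices and call records.

``CohortGenotypes`` is the hub type for all SNV stages: a sample-by-site
dosage matrix (0/1/2, -1 for missing) with optional per-genotype DP/GQ/AD
layers and per-genotype ploidy (1 on the male X outside the
pseudoautosomal region, 2 elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MISSING = -1

CATEGORIES = ("breed", "village", "wolf", "coyote", "mixed")
REGION_CLASSES = ("autosome", "X_PAR", "X_nonPAR", "MT")


@dataclass
class SampleRecord:
    """One cohort member: a breed dog, village dog, wolf, coyote or mix."""

    id: str
    category: str = "breed"
    breed_label: str | None = None
    sex: str = "F"
    group_label: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if (self.category == "breed") != (self.breed_label is not None):
            raise ValueError("breed_label must be set iff category == 'breed'")


@dataclass
class SiteRecord:
    """A biallelic variant site in 1-based reference coordinates."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    region_class: str = "autosome"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region_class {self.region_class!r}")


class EmptyCohortError(ValueError):
    """Raised when a cohort with zero samples or zero sites is constructed."""


class CohortGenotypes:
    """Sample x site dosage matrix with optional DP/GQ/AD quality layers.

    Parameters
    ----------
    samples, sites:
        Metadata rows matching the two matrix axes.
    dosage:
        Integer array ``(n_samples, n_sites)``; alternate-allele dosage in
        ``{0, 1, 2}`` for diploid entries, ``{0, 1}`` for haploid entries,
        ``-1`` for missing.
    ploidy:
        Same shape, entries in ``{1, 2}``.  Defaults to all-diploid except
        male samples at X_nonPAR sites, which are haploid.
    DP, GQ:
        Optional per-genotype read depth and phred genotype quality.
    AD:
        Optional ``(n_samples, n_sites, 2)`` array of (ref_reads, alt_reads).
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        sites: Sequence[SiteRecord],
        dosage: np.ndarray,
        ploidy: np.ndarray | None = None,
        DP: np.ndarray | None = None,
        GQ: np.ndarray | None = None,
        AD: np.ndarray | None = None,
    ) -> None:
        self.samples = list(samples)
        self.sites = list(sites)
        if len(self.samples) == 0 or len(self.sites) == 0:
            raise EmptyCohortError(
                f"cohort needs >=1 sample and >=1 site "
                f"(got {len(self.samples)} x {len(self.sites)})"
            )
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        self.dosage = np.asarray(dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if ploidy is None:
            ploidy = np.full(self.dosage.shape, 2, dtype=np.int8)
            male = np.array([s.sex == "M" for s in self.samples])
            nonpar = np.array([s.region_class == "X_nonPAR" for s in self.sites])
            if male.any() and nonpar.any():
                ploidy[np.ix_(male, nonpar)] = 1
        self.ploidy = np.asarray(ploidy, dtype=np.int8)
        if self.ploidy.shape != self.dosage.shape:
            raise ValueError("ploidy shape does not match dosage")
        called = self.dosage != MISSING
        if np.any(self.dosage[called] > self.ploidy[called]) or np.any(
            self.dosage[called] < 0
        ):
            raise ValueError("dosage must lie in [0, ploidy] or be missing")
        self.DP = None if DP is None else np.asarray(DP)
        self.GQ = None if GQ is None else np.asarray(GQ)
        self.AD = None if AD is None else np.asarray(AD)
        for name, layer in (("DP", self.DP), ("GQ", self.GQ)):
            if layer is not None and layer.shape != self.dosage.shape:
                raise ValueError(f"{name} shape does not match dosage")
        if self.AD is not None and self.AD.shape != self.dosage.shape + (2,):
            raise ValueError("AD must have shape (n_samples, n_sites, 2)")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def region_classes(self) -> np.ndarray:
        return np.array([s.region_class for s in self.sites])

    # -- derived quantities ---------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    def alt_allele_freq(self) -> np.ndarray:
        """Ploidy-aware per-site alternate allele frequency (NaN if no calls)."""
        called = self.called()
        alt = np.where(called, self.dosage, 0).sum(axis=0).astype(float)
        tot = np.where(called, self.ploidy, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan)

    def carriers(self) -> np.ndarray:
        """Boolean (n_samples, n_sites): sample carries >=1 alternate allele."""
        return self.dosage >= 1

    def site_missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)

    # -- restructuring ---------------------------------------------------

    def copy(self) -> "CohortGenotypes":
        return CohortGenotypes(
            list(self.samples),
            list(self.sites),
            self.dosage.copy(),
            self.ploidy.copy(),
            None if self.DP is None else self.DP.copy(),
            None if self.GQ is None else self.GQ.copy(),
            None if self.AD is None else self.AD.copy(),
        )

    def subset(
        self,
        sample_idx: Iterable[int] | np.ndarray | None = None,
        site_idx: Iterable[int] | np.ndarray | None = None,
    ) -> "CohortGenotypes":
        """Return a new cohort restricted to the given sample/site indices."""
        si = (
            np.arange(self.n_samples)
            if sample_idx is None
            else np.asarray(list(sample_idx))
        )
        vi = (
            np.arange(self.n_sites)
            if site_idx is None
            else np.asarray(list(site_idx))
        )
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return CohortGenotypes(
            [self.samples[i] for i in si],
            [self.sites[j] for j in vi],
            self.dosage[np.ix_(si, vi)],
            self.ploidy[np.ix_(si, vi)],
            None if self.DP is None else self.DP[np.ix_(si, vi)],
            None if self.GQ is None else self.GQ[np.ix_(si, vi)],
            None if self.AD is None else self.AD[np.ix_(si, vi)],
        )

    def samples_in_category(self, *categories: str) -> np.ndarray:
        return np.array([s.category in categories for s in self.samples])

    def samples_in_breed(self, breed_label: str) -> np.ndarray:
        return np.array([s.breed_label == breed_label for s in self.samples])


@dataclass
class SimTruth:
    """Ground truth recorded by the synthetic generators for recovery tests."""

    ancestral_freqs: np.ndarray | None = None
    population_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    per_population_fst: dict[str, float] = field(default_factory=dict)
    retrogene_truth: list[tuple[str, list[str]]] = field(default_factory=list)
    mito_truth: dict | None = None
    imputation_error_rates: dict[tuple[float, float], float] = field(
        default_factory=dict
    )
    uncallable_intervals: dict[str, list[tuple[int, int]]] = field(
        default_factory=dict
    )
    extra: dict = field(default_factory=dict)


@dataclass
class GeneModel:
    """A gene with one transcript, exon coordinates 0-based half-open."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    @property
    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    @property
    def span(self) -> tuple[int, int]:
        ex = sorted(self.exons)
        return ex[0][0], ex[-1][1]


SV_TYPES = ("DEL", "DUP", "INS", "INV")
MAX_SV_LENGTH = 10_000_000


@dataclass
class SvCall:
    """A structural variant record, 0-based half-open internally.

    For insertions ``end == start + 1`` (the anchor base) and ``length`` is
    the inserted length; for other types ``length == end - start``.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotypes: np.ndarray  # per-sample dosage, -1 missing

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype != "INS" and self.end <= self.start:
            raise ValueError("end must exceed start for non-insertion SVs")
        if self.length > MAX_SV_LENGTH:
            raise ValueError("SV length exceeds the 10 Mb cap")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass
class MitoCall:
    """A mitochondrial variant call with source-reference provenance."""

    pos: int  # 1-based, in the coordinates of `source` unless converted
    ref: str
    alt: str
    allele_fraction: float = 1.0
    strand_bias_fail: bool = False
    depth: int = 1000
    source: str = "primary"

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must be in [0, 1]")
        if self.source not in ("primary", "rotated"):
            raise ValueError("source must be 'primary' or 'rotated'")
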