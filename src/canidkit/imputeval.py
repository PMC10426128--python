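"""Imputation panel preparation and non-reference concordance evaluation.

NRC restricts the genotype comparison to entries where the truth or the
imputed call is non-reference — the standard accuracy metric for rare-
variant imputation, where raw concordance is dominated by easy homozygous-
reference calls.  Results are stratified by reference-panel MAF bin, INFO
score and chromosomal context (the male X outside the PAR is compared as
haploid and skips the INFO filter, which imputation software does not emit
for haploid genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import MISSING, CohortGenotypes

DEFAULT_MAF_BINS = ((0.0, 0.01), (0.01, 0.05), (0.05, 0.5))


@dataclass
class PanelSpec:
    sample_ids: list[str]
    n_sites: int
    filters: dict = field(default_factory=dict)


def prepare_panel(
    cohort: CohortGenotypes,
    max_missing: float = 0.05,
    multiallelic_sites: np.ndarray | None = None,
) -> tuple[CohortGenotypes, PanelSpec]:
    """Drop multiallelic sites and sites with missingness > ``max_missing``.

    The boundary is strict: a site at exactly the threshold is retained.
    """
    keep = cohort.site_missingness() <= max_missing
    if multiallelic_sites is not None:
        keep &= ~np.asarray(multiallelic_sites, dtype=bool)
    if not keep.any():
        raise ValueError("no sites survive panel filtering")
    panel = cohort.subset(site_idx=np.flatnonzero(keep))
    spec = PanelSpec(
        panel.sample_ids,
        panel.n_sites,
        {"max_missing": max_missing, "biallelic_only": True},
    )
    return panel, spec


def downsample_panels(
    panel: CohortGenotypes,
    sizes: tuple[int, ...] = (500, 1000, 1500),
    replicates: int = 10,
    seed: int = 0,
) -> list[tuple[int, int, list[str]]]:
    """Seeded random sample subsets: (size, replicate, sample ids) triples."""
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        if size > panel.n_samples:
            raise ValueError(
                f"requested panel size {size} exceeds {panel.n_samples} samples"
            )
        for rep in range(replicates):
            idx = sorted(rng.choice(panel.n_samples, size=size, replace=False))
            out.append((size, rep, [panel.sample_ids[i] for i in idx]))
    return out


@dataclass
class NrcStratum:
    maf_bin: tuple[float, float]
    region: str  # 'autosome+PAR' | 'X_nonPAR'
    n_considered: int = 0
    n_concordant: int = 0

    @property
    def nrc(self) -> float:
        return self.n_concordant / self.n_considered if self.n_considered else float("nan")


@dataclass
class NrcTable:
    strata: list[NrcStratum]
    n_imputed_sites: int
    n_missing_imputation: int
    info_cut: float

    def overall(self) -> tuple[int, int, float]:
        cons = sum(s.n_considered for s in self.strata)
        conc = sum(s.n_concordant for s in self.strata)
        return cons, conc, (conc / cons if cons else float("nan"))

    def nrc_for(self, maf_bin: tuple[float, float], region: str = "autosome+PAR") -> float:
        for s in self.strata:
            if s.maf_bin == maf_bin and s.region == region:
                return s.nrc
        return float("nan")


def nrc(
    truth: CohortGenotypes,
    imputed: CohortGenotypes,
    info_scores: np.ndarray,
    panel_maf: np.ndarray | None = None,
    maf_bins: tuple[tuple[float, float], ...] = DEFAULT_MAF_BINS,
    info_cut: float = 0.9,
) -> NrcTable:
    """Non-reference concordance stratified by panel MAF and region.

    Genotypes where both truth and imputed are homozygous reference are
    skipped; a considered genotype is concordant iff the calls match
    exactly (no partial credit for het vs hom-alt).  Sites failing
    INFO > ``info_cut`` are excluded, except on the haploid male X where
    no INFO filter applies.  Sites missing from the imputed set are
    counted separately.
    """
    if truth.sample_ids != imputed.sample_ids:
        raise ValueError("truth and imputed cohorts must share samples in order")
    truth_keys = {(s.chrom, s.pos): j for j, s in enumerate(truth.sites)}
    imp_keys = {(s.chrom, s.pos): j for j, s in enumerate(imputed.sites)}
    shared = [k for k in truth_keys if k in imp_keys]
    n_missing = len(truth_keys) - len(shared)

    t_idx = np.array([truth_keys[k] for k in shared], dtype=np.int64)
    i_idx = np.array([imp_keys[k] for k in shared], dtype=np.int64)
    if panel_maf is None:
        af = truth.alt_allele_freq()
        panel_maf = np.minimum(af, 1 - af)
    maf = np.asarray(panel_maf)[t_idx]
    info = np.asarray(info_scores)[i_idx]
    region = np.where(
        truth.region_classes()[t_idx] == "X_nonPAR", "X_nonPAR", "autosome+PAR"
    )

    keep = (info > info_cut) | (region == "X_nonPAR")
    t_idx, i_idx = t_idx[keep], i_idx[keep]
    maf, region = maf[keep], region[keep]
    n_sites_used = int(keep.sum())

    tG = truth.dosage[:, t_idx]
    iG = imputed.dosage[:, i_idx]
    called = (tG != MISSING) & (iG != MISSING)
    considered = called & ((tG != 0) | (iG != 0))
    concordant = considered & (tG == iG)

    strata = []
    for lo, hi in maf_bins:
        in_bin = (maf > lo) & (maf <= hi)
        for reg in ("autosome+PAR", "X_nonPAR"):
            sel = in_bin & (region == reg)
            if not sel.any():
                continue
            strata.append(
                NrcStratum(
                    (lo, hi),
                    reg,
                    int(considered[:, sel].sum()),
                    int(concordant[:, sel].sum()),
                )
            )
    return NrcTable(strata, n_sites_used, n_missing, info_cut)
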