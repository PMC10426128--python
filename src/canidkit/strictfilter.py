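"""Strict genotype-level filters, allele-frequency classes and the HWE screen.

The strict filters null individual genotypes on depth (DP < 5), genotype
quality (GQ < 20) and, for heterozygotes, allelic balance outside
[0.30, 0.70]; thresholds are inclusive (DP = 5, GQ = 20 and AB = 0.30 or
0.70 are retained).  Site- and sample-level missingness removal then
alternates until a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from canidkit.cohort import MISSING, CohortGenotypes


@dataclass
class FilterReport:
    genotypes_set_missing: dict[str, int] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # per-reason, input indices
    sites_removed: list[int] = field(default_factory=list)  # per iteration
    samples_removed: list[int] = field(default_factory=list)
    n_sites_final: int = 0
    n_samples_final: int = 0


def apply_strict_filters(
    cohort: CohortGenotypes,
    min_dp: int = 5,
    min_gq: int = 20,
    ab_low: float = 0.30,
    ab_high: float = 0.70,
    site_miss: float = 0.05,
    sample_miss: float = 0.10,
) -> tuple[CohortGenotypes, FilterReport]:
    """Null genotypes failing DP/GQ/AB, then iterate missingness removal.

    Heterozygous genotypes need an allelic balance alt/(ref+alt) inside
    [ab_low, ab_high]; a called het with zero AD reads is nulled and counted
    under AB.  Haploid genotypes (male X outside the PAR) skip the AB
    filter.  Sites with missingness > ``site_miss`` and then samples with
    missingness > ``sample_miss`` are dropped alternately until stable.
    """
    out = cohort.copy()
    rep = FilterReport()
    called = out.dosage != MISSING

    if out.DP is not None:
        bad = called & (out.DP < min_dp)
        rep.genotypes_set_missing["DP"] = int(bad.sum())
        rep.masks["DP"] = bad
        out.dosage[bad] = MISSING
        called &= ~bad
    if out.GQ is not None:
        bad = called & (out.GQ < min_gq)
        rep.genotypes_set_missing["GQ"] = int(bad.sum())
        rep.masks["GQ"] = bad
        out.dosage[bad] = MISSING
        called &= ~bad
    if out.AD is not None:
        het = called & (out.dosage == 1) & (out.ploidy == 2)
        tot = out.AD[..., 0] + out.AD[..., 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ab = np.where(tot > 0, out.AD[..., 1] / np.maximum(tot, 1), np.nan)
        bad = het & ((tot == 0) | (ab < ab_low) | (ab > ab_high))
        rep.genotypes_set_missing["AB"] = int(bad.sum())
        rep.masks["AB"] = bad
        out.dosage[bad] = MISSING

    # alternate site/sample missingness removal to a fixed point
    keep_sites = np.ones(out.n_sites, dtype=bool)
    keep_samples = np.ones(out.n_samples, dtype=bool)
    while True:
        miss = out.dosage == MISSING
        sub = miss[np.ix_(keep_samples, keep_sites)]
        site_frac = sub.mean(axis=0) if sub.shape[0] else np.zeros(sub.shape[1])
        drop_sites = site_frac > site_miss
        rep.sites_removed.append(int(drop_sites.sum()))
        keep_sites[np.flatnonzero(keep_sites)[drop_sites]] = False

        sub = miss[np.ix_(keep_samples, keep_sites)]
        samp_frac = sub.mean(axis=1) if sub.shape[1] else np.zeros(sub.shape[0])
        drop_samples = samp_frac > sample_miss
        rep.samples_removed.append(int(drop_samples.sum()))
        keep_samples[np.flatnonzero(keep_samples)[drop_samples]] = False

        if not drop_sites.any() and not drop_samples.any():
            break
        if not keep_sites.any() or not keep_samples.any():
            break

    out = out.subset(np.flatnonzero(keep_samples), np.flatnonzero(keep_sites))
    rep.n_sites_final = out.n_sites
    rep.n_samples_final = out.n_samples
    return out, rep


# ---------------------------------------------------------------------------
# allele-frequency classes

RARE_MAX = 0.01       # rare: AF <= 1%
COMMON_MIN = 0.05     # common: AF >= 5%


def af_class(af: float) -> str:
    if af <= RARE_MAX:
        return "rare"
    if af >= COMMON_MIN:
        return "common"
    return "intermediate"


def classify_af(cohort: CohortGenotypes):
    """Per-site AF (ploidy-aware) and class; all-missing sites are excluded.

    Returns a pandas DataFrame with columns site_index, chrom, pos, af,
    af_class, plus the list of excluded site indices.
    """
    import pandas as pd

    af = cohort.alt_allele_freq()
    ok = ~np.isnan(af)
    rows = [
        {
            "site_index": j,
            "chrom": cohort.sites[j].chrom,
            "pos": cohort.sites[j].pos,
            "af": float(af[j]),
            "af_class": af_class(float(af[j])),
        }
        for j in np.flatnonzero(ok)
    ]
    return pd.DataFrame(rows), list(np.flatnonzero(~ok))


# ---------------------------------------------------------------------------
# Hardy-Weinberg screen


@dataclass
class HweCandidate:
    site_index: int
    counts: tuple[int, int, int]  # hom_ref, het, hom_alt
    chi_square: float
    p_value: float
    bonferroni_threshold: float
    direction: str  # 'homozygote-depleted' | 'homozygote-excess'


def hwe_chi_square(hom_ref: int, het: int, hom_alt: int) -> tuple[float, float]:
    """1-df chi-square of observed genotype counts vs HWE expectation."""
    n = hom_ref + het + hom_alt
    p = (2 * hom_alt + het) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([hom_ref, het, hom_alt], dtype=float)
    chi2 = float((((obs - exp) ** 2) / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_screen(
    cohort: CohortGenotypes,
    site_idx: np.ndarray | None = None,
    alpha: float = 0.05,
) -> list[HweCandidate]:
    """Bonferroni-screened HWE deviations over autosomal diploid sites.

    Monomorphic sites are skipped (their expected heterozygote count is
    zero).  Candidates are labeled homozygote-depleted (het excess, the
    signature expected of recessive disease variants surviving in carriers)
    or homozygote-excess.
    """
    region = cohort.region_classes()
    if site_idx is None:
        site_idx = np.flatnonzero(region == "autosome")
    else:
        site_idx = np.asarray(site_idx)

    tested: list[tuple[int, int, int, int]] = []
    for j in site_idx:
        g = cohort.dosage[:, j]
        pl = cohort.ploidy[:, j]
        use = (g != MISSING) & (pl == 2)
        hom_ref = int((g[use] == 0).sum())
        het = int((g[use] == 1).sum())
        hom_alt = int((g[use] == 2).sum())
        n = hom_ref + het + hom_alt
        if n == 0:
            continue
        p = (2 * hom_alt + het) / (2 * n)
        if p in (0.0, 1.0):
            continue  # monomorphic
        tested.append((int(j), hom_ref, het, hom_alt))

    m = len(tested)
    if m == 0:
        return []
    cut = alpha / m
    out = []
    for j, hom_ref, het, hom_alt in tested:
        chi2, pval = hwe_chi_square(hom_ref, het, hom_alt)
        if pval < cut:
            n = hom_ref + het + hom_alt
            p = (2 * hom_alt + het) / (2 * n)
            exp_het = 2 * n * p * (1 - p)
            direction = (
                "homozygote-depleted" if het > exp_het else "homozygote-excess"
            )
            out.append(
                HweCandidate(j, (hom_ref, het, hom_alt), chi2, pval, cut, direction)
            )
    return out
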