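"""Allele sharing between sample categories, F2 rare-sharing, Patterson's D,
site frequency spectra and the linear-programming discovery projection.

"Presence" of an allele in a category or sample means >= 1 alternate
allele regardless of zygosity, the convention shared by the category
partition and the F2 definition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from canidkit.cohort import MISSING, CohortGenotypes

CATEGORY_GROUPS = {
    "breed": ("breed", "mixed"),  # breed and mixed/other samples combined
    "village": ("village",),
    "wolf": ("wolf",),
}


@dataclass
class CategoryPartition:
    """Counts of polymorphic autosomal sites by category-presence pattern."""

    cells: dict[frozenset, int] = field(default_factory=dict)
    total: int = 0
    n_excluded: int = 0  # alt absent everywhere

    def count(self, *groups: str) -> int:
        return self.cells.get(frozenset(groups), 0)


def category_partition(cohort: CohortGenotypes) -> CategoryPartition:
    """Assign every polymorphic autosomal site to one of 7 presence cells.

    A category "has" a site if any of its samples carries >= 1 alternate
    allele; mixed samples are pooled with breed dogs.  Sites with the
    alternate allele absent everywhere are excluded and counted.
    """
    auto = cohort.region_classes() == "autosome"
    part = CategoryPartition()
    masks = {
        g: cohort.samples_in_category(*cats) for g, cats in CATEGORY_GROUPS.items()
    }
    carriers = cohort.carriers()
    for j in np.flatnonzero(auto):
        present = frozenset(
            g for g, m in masks.items() if m.any() and carriers[m, j].any()
        )
        if not present:
            part.n_excluded += 1
            continue
        part.cells[present] = part.cells.get(present, 0) + 1
        part.total += 1
    return part


@dataclass
class F2Table:
    site_indices: list[int]
    carriers: list[tuple[str, str]]  # per F2 site, the two carrier sample ids
    per_sample_counts: dict[str, int]
    partner_category_fractions: dict[str, dict[str, float]]


def f2_analysis(cohort: CohortGenotypes) -> F2Table:
    """Sites carried by exactly two samples, with no missing genotype.

    Carriage ignores zygosity (a homozygous and a heterozygous carrier both
    count once).  For each sample the fraction of its F2 partners falling
    in each category group is reported.
    """
    auto = cohort.region_classes() == "autosome"
    carriers = cohort.carriers()
    fully_called = (cohort.dosage != MISSING).all(axis=0)
    n_carriers = carriers.sum(axis=0)
    f2 = auto & fully_called & (n_carriers == 2)

    ids = cohort.sample_ids
    cat_of = {}
    for s in cohort.samples:
        grp = next(
            (g for g, cats in CATEGORY_GROUPS.items() if s.category in cats),
            s.category,
        )
        cat_of[s.id] = grp

    site_indices = list(np.flatnonzero(f2))
    pairs = []
    counts = {sid: 0 for sid in ids}
    partner_tallies: dict[str, dict[str, int]] = {sid: {} for sid in ids}
    for j in site_indices:
        a, b = np.flatnonzero(carriers[:, j])
        pa, pb = ids[a], ids[b]
        pairs.append((pa, pb))
        counts[pa] += 1
        counts[pb] += 1
        partner_tallies[pa][cat_of[pb]] = partner_tallies[pa].get(cat_of[pb], 0) + 1
        partner_tallies[pb][cat_of[pa]] = partner_tallies[pb].get(cat_of[pa], 0) + 1
    fractions = {
        sid: {g: n / counts[sid] for g, n in t.items()} if counts[sid] else {}
        for sid, t in partner_tallies.items()
    }
    return F2Table(site_indices, pairs, counts, fractions)


# ---------------------------------------------------------------------------
# Patterson's D


@dataclass
class DStatResult:
    d: float
    abba: float
    baba: float
    se: float
    z: float
    n_blocks: int
    significant: bool  # |Z| >= 3


def _group_freq(cohort: CohortGenotypes, mask: np.ndarray) -> np.ndarray:
    sub = cohort.dosage[mask]
    pl = cohort.ploidy[mask]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=0).astype(float)
    tot = np.where(called, pl, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, alt / tot, np.nan)


def d_statistic(
    cohort: CohortGenotypes,
    w: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    block_size_bp: int = 5_000_000,
) -> DStatResult:
    """Patterson's D for the tree (W, X)(Y, Z) in allele-frequency form.

    Per site ABBA = (1-pW) pX pY (1-pZ) and BABA = pW (1-pX) pY (1-pZ);
    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA).  The standard error
    is a weighted delete-one block jackknife over contiguous genomic blocks,
    weighted by per-block site counts; Z = D / SE and |Z| >= 3 flags
    significance.
    """
    pw, px, py, pz = (_group_freq(cohort, m) for m in (w, x, y, z))
    ok = ~(np.isnan(pw) | np.isnan(px) | np.isnan(py) | np.isnan(pz))
    abba = (1 - pw) * px * py * (1 - pz)
    baba = pw * (1 - px) * py * (1 - pz)
    abba = np.where(ok, abba, 0.0)
    baba = np.where(ok, baba, 0.0)

    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    if tot_a + tot_b == 0:
        raise ZeroDivisionError("ABBA + BABA is zero: D undefined")
    d = (tot_a - tot_b) / (tot_a + tot_b)

    # contiguous blocks by chromosome and position
    chroms = cohort.chroms()
    pos = cohort.positions()
    block_ids = np.zeros(cohort.n_sites, dtype=np.int64)
    next_id = 0
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        bins = pos[sel] // block_size_bp
        _, labels = np.unique(bins, return_inverse=True)
        block_ids[sel] = labels + next_id
        next_id += labels.max() + 1

    n_blocks = int(next_id)
    m_j = np.bincount(block_ids, weights=ok.astype(float), minlength=n_blocks)
    a_j = np.bincount(block_ids, weights=abba, minlength=n_blocks)
    b_j = np.bincount(block_ids, weights=baba, minlength=n_blocks)
    use = m_j > 0
    m_j, a_j, b_j = m_j[use], a_j[use], b_j[use]
    n_blocks = len(m_j)
    n_tot = m_j.sum()

    # weighted delete-one jackknife (Busing-style pseudovalues)
    theta_j = np.array(
        [
            ((tot_a - a_j[jj]) - (tot_b - b_j[jj]))
            / max(1e-300, (tot_a - a_j[jj]) + (tot_b - b_j[jj]))
            for jj in range(n_blocks)
        ]
    )
    if n_blocks < 2:
        return DStatResult(d, tot_a, tot_b, float("nan"), 0.0, n_blocks, False)
    h_j = n_tot / m_j
    theta_dot = float(np.sum((1 - m_j / n_tot) * theta_j))
    theta_jack = n_blocks * d - theta_dot
    tau = h_j * d - (h_j - 1) * theta_j
    with np.errstate(divide="ignore", invalid="ignore"):
        var = float(np.sum((tau - theta_jack) ** 2 / np.maximum(h_j - 1, 1e-12)) / n_blocks)
    se = float(np.sqrt(max(var, 0.0)))
    zscore = d / se if se > 0 else 0.0
    return DStatResult(d, tot_a, tot_b, se, zscore, n_blocks, abs(zscore) >= 3)


# ---------------------------------------------------------------------------
# site frequency spectrum


@dataclass
class SFSpectrum:
    """Non-reference allele-count histogram over fully-called sites.

    ``counts[k - 1]`` is the number of sites with alternate allele count k,
    for k = 1 .. n_chrom (fixed-alternate sites included).
    """

    n_chrom: int
    counts: np.ndarray

    @property
    def n_observed(self) -> int:
        return int(self.counts.sum())


def sfs(cohort: CohortGenotypes, sample_mask: np.ndarray | None = None) -> SFSpectrum:
    """Spectrum of a population subset (needs >= 3 individuals).

    On the male X outside the PAR the chromosome count is 2 per female plus
    1 per male; only sites fully called in the subset contribute.
    """
    if sample_mask is None:
        sample_mask = np.ones(cohort.n_samples, dtype=bool)
    n_ind = int(np.asarray(sample_mask).sum())
    if n_ind < 3:
        raise ValueError("population must contain at least three individuals")
    sub = cohort.dosage[sample_mask]
    pl = cohort.ploidy[sample_mask]
    fully = (sub != MISSING).all(axis=0)
    n_chrom_per_site = pl.sum(axis=0)
    n_chrom = int(n_chrom_per_site.max())
    k = sub.astype(np.int64).sum(axis=0)[fully]
    k = k[k >= 1]
    counts = np.bincount(k.astype(np.int64), minlength=n_chrom + 1)[1 : n_chrom + 1]
    return SFSpectrum(n_chrom, counts.astype(np.int64))


# ---------------------------------------------------------------------------
# discovery projection by linear programming


@dataclass
class DiscoveryProjection:
    target_n: int
    grid: np.ndarray
    weights: np.ndarray  # minimum-residual feasible point estimate weights
    lower_bound: float
    upper_bound: float
    point_estimate: float
    fraction_discovered: float
    epsilon_scale: float  # 1.0 unless the LP had to be relaxed


def _binom_design(n_chrom: int, grid: np.ndarray) -> np.ndarray:
    """Matrix B[k-1, j] = P(Binomial(n_chrom, f_j) = k), k = 1..n_chrom."""
    k = np.arange(1, n_chrom + 1)
    return stats.binom.pmf(k[:, None], n_chrom, grid[None, :])


def expected_discovery(weights: np.ndarray, grid: np.ndarray, target_n: int) -> float:
    """Expected variants seen in target_n diploids for a frequency mixture."""
    return float(np.sum(weights * (1 - (1 - grid) ** (2 * target_n))))


def project_discovery(
    spectrum: SFSpectrum,
    target_n: int = 100,
    grid: np.ndarray | None = None,
    epsilon: np.ndarray | None = None,
    max_relax: int = 4,
) -> DiscoveryProjection:
    """Bound the variant count discoverable in ``target_n`` individuals.

    The observed spectrum is modeled as a mixture of binomial sampling from
    a grid of allele frequencies: E[c_k] = sum_j w_j Binom(k; 2n, f_j).
    Two linear programs minimise and maximise the expected discovery
    g(w) = sum_j w_j (1 - (1 - f_j)^(2N)) subject to w >= 0 and
    |B w - c|_k <= eps_k, with eps_k a per-bin Poisson 3-sigma tolerance
    (3 sqrt(max(c_k, 1))).  The point estimate evaluates g at the
    non-negative least-squares fit; fraction_discovered is the observed
    count over the point estimate.  If the LPs are infeasible the
    tolerance is doubled (with a recorded relaxation factor) a few times
    before giving up.
    """
    if spectrum.n_observed == 0:
        raise ValueError("empty spectrum: nothing to project")
    n_chrom = spectrum.n_chrom
    if grid is None:
        grid = np.geomspace(1.0 / (4 * 2 * target_n), 1.0, 64)
    grid = np.asarray(grid, dtype=float)
    c = spectrum.counts.astype(float)
    if epsilon is None:
        epsilon = 3.0 * np.sqrt(np.maximum(c, 1.0))
    B = _binom_design(n_chrom, grid)
    g = 1 - (1 - grid) ** (2 * target_n)

    # point estimate: non-negative least squares on the binomial design
    w_pt, _ = optimize.nnls(B, c)
    point = float(np.sum(w_pt * g))

    scale = 1.0
    for _ in range(max_relax + 1):
        A_ub = np.vstack([B, -B])
        b_ub = np.concatenate([c + scale * epsilon, -(c - scale * epsilon)])
        lo = optimize.linprog(g, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        hi = optimize.linprog(-g, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        if lo.success and hi.success:
            lower, upper = float(lo.fun), float(-hi.fun)
            point_clipped = min(max(point, lower), upper)
            frac = spectrum.n_observed / point_clipped if point_clipped > 0 else 0.0
            return DiscoveryProjection(
                target_n, grid, w_pt, lower, upper, point_clipped, frac, scale
            )
        scale *= 2.0
    raise RuntimeError("discovery projection infeasible even after relaxation")
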