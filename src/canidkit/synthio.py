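"""Seeded generators for every input the pipeline consumes.

The cohort generator uses a Balding-Nichols drift model: each population's
allele frequency at a site is drawn from a Beta distribution centred on the
ancestral frequency p with variance F_ST * p * (1 - p), which gives a
closed-form F_ST target for parameter-recovery tests.  Genotypes are then
binomial draws in the population frequency, so sites are exchangeable
(no linkage disequilibrium is simulated).

All generators are deterministic given (config, seed): the same inputs
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from canidkit.cohort import (
    MISSING,
    CohortGenotypes,
    EmptyCohortError,
    GeneModel,
    MitoCall,
    SampleRecord,
    SimTruth,
    SiteRecord,
    SvCall,
)

# ---------------------------------------------------------------------------
# cohort genotypes


@dataclass
class CohortConfig:
    """Parameters of the multi-population cohort simulation.

    Defaults give a small structured cohort: a handful of drifted breeds,
    a diverse village-dog population and a diverged wolf population, with
    per-genotype depth/quality layers resembling ~30x short-read calls.
    """

    n_breeds: int = 5
    samples_per_breed: int = 5
    n_village: int = 10
    n_wolf: int = 5
    n_sites: int = 5000
    fst_range: tuple[float, float] = (0.15, 0.30)
    village_fst: float = 0.05
    wolf_fst: float = 0.25
    admixed_breeds: int = 0
    admixture_fraction: float = 0.5
    mean_depth: float = 30.0
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    with_quality_layers: bool = True
    x_nonpar_fraction: float = 0.0
    male_fraction: float = 0.5
    chrom: str = "chr1"
    site_spacing: int = 1000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    ancestral_freq_distribution: str = "uniform"  # 'uniform' | 'loguniform'


def _balding_nichols(rng, p, fst, size):
    """Population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 -> p."""
    if fst <= 0:
        return np.broadcast_to(p, size).copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    q = rng.beta(a, b, size=size)
    return np.clip(q, 1e-9, 1 - 1e-9)


def generate_cohort(
    config: CohortConfig, seed: int
) -> tuple[CohortGenotypes, SimTruth]:
    """Simulate a structured canid cohort with known per-population drift.

    Returns the cohort plus a :class:`SimTruth` carrying the ancestral and
    per-population allele frequencies and each population's F_ST, for
    estimator-recovery tests.
    """
    cfg = config
    n_total = (
        cfg.n_breeds * cfg.samples_per_breed
        + cfg.n_village
        + cfg.n_wolf
        + cfg.admixed_breeds * cfg.samples_per_breed
    )
    if n_total == 0 or cfg.n_sites == 0:
        raise EmptyCohortError("cohort simulation needs >=1 sample and >=1 site")
    rng = np.random.default_rng(seed)

    lo, hi = cfg.ancestral_freq_range
    if cfg.ancestral_freq_distribution == "loguniform":
        p_anc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_sites))
    elif cfg.ancestral_freq_distribution == "uniform":
        p_anc = rng.uniform(lo, hi, size=cfg.n_sites)
    else:
        raise ValueError(
            f"unknown ancestral_freq_distribution {cfg.ancestral_freq_distribution!r}"
        )
    fsts = rng.uniform(*cfg.fst_range, size=cfg.n_breeds)

    pop_freqs: dict[str, np.ndarray] = {}
    per_pop_fst: dict[str, float] = {}
    samples: list[SampleRecord] = []
    sample_pop: list[str] = []

    for b in range(cfg.n_breeds):
        name = f"BREED{b:02d}"
        pop_freqs[name] = _balding_nichols(rng, p_anc, fsts[b], cfg.n_sites)
        per_pop_fst[name] = float(fsts[b])
        for i in range(cfg.samples_per_breed):
            samples.append(
                SampleRecord(
                    f"{name}_s{i}", "breed", breed_label=name, group_label=name
                )
            )
            sample_pop.append(name)

    # an "admixed breed" draws each sample's genotypes from one of two
    # hidden source populations, so its samples cannot be monophyletic
    for a in range(cfg.admixed_breeds):
        name = f"ADMIX{a:02d}"
        f1, f2 = rng.uniform(*cfg.fst_range, size=2)
        srcA = _balding_nichols(rng, p_anc, f1, cfg.n_sites)
        srcB = _balding_nichols(rng, p_anc, f2, cfg.n_sites)
        pop_freqs[name + "/A"] = srcA
        pop_freqs[name + "/B"] = srcB
        per_pop_fst[name + "/A"] = float(f1)
        per_pop_fst[name + "/B"] = float(f2)
        n_from_A = max(1, int(round(cfg.admixture_fraction * cfg.samples_per_breed)))
        for i in range(cfg.samples_per_breed):
            samples.append(
                SampleRecord(
                    f"{name}_s{i}", "breed", breed_label=name, group_label=name
                )
            )
            sample_pop.append(name + ("/A" if i < n_from_A else "/B"))

    if cfg.n_village:
        pop_freqs["VILLAGE"] = _balding_nichols(
            rng, p_anc, cfg.village_fst, cfg.n_sites
        )
        per_pop_fst["VILLAGE"] = float(cfg.village_fst)
        for i in range(cfg.n_village):
            samples.append(
                SampleRecord(f"VILLAGE_s{i}", "village", group_label="VILLAGE")
            )
            sample_pop.append("VILLAGE")
    if cfg.n_wolf:
        pop_freqs["WOLF"] = _balding_nichols(rng, p_anc, cfg.wolf_fst, cfg.n_sites)
        per_pop_fst["WOLF"] = float(cfg.wolf_fst)
        for i in range(cfg.n_wolf):
            samples.append(SampleRecord(f"WOLF_s{i}", "wolf", group_label="WOLF"))
            sample_pop.append("WOLF")

    sexes = np.where(
        rng.random(len(samples)) < cfg.male_fraction, "M", "F"
    )
    for s, sex in zip(samples, sexes):
        s.sex = str(sex)

    n_x = int(round(cfg.x_nonpar_fraction * cfg.n_sites))
    region = np.array(["autosome"] * cfg.n_sites)
    if n_x:
        region[-n_x:] = "X_nonPAR"
    bases = np.array(list("ACGT"))
    refs = bases[rng.integers(0, 4, cfg.n_sites)]
    alts = bases[(np.searchsorted(bases, refs) + rng.integers(1, 4, cfg.n_sites)) % 4]
    sites = [
        SiteRecord(
            "chrX" if region[j] == "X_nonPAR" else cfg.chrom,
            (j + 1) * cfg.site_spacing,
            str(refs[j]),
            str(alts[j]),
            str(region[j]),
        )
        for j in range(cfg.n_sites)
    ]

    n = len(samples)
    ploidy = np.full((n, cfg.n_sites), 2, dtype=np.int8)
    if n_x:
        male = sexes == "M"
        nonpar = region == "X_nonPAR"
        ploidy[np.ix_(male, nonpar)] = 1

    freq = np.stack([pop_freqs[p] for p in sample_pop])  # (n, n_sites)
    dosage = rng.binomial(ploidy, freq).astype(np.int8)

    if cfg.genotype_error_rate > 0:
        err = rng.random(dosage.shape) < cfg.genotype_error_rate
        # dosage swap: replace with a different value valid for the ploidy
        shift = rng.integers(1, np.where(ploidy == 2, 3, 2))
        dosage = np.where(err, (dosage + shift) % (ploidy + 1), dosage).astype(
            np.int8
        )

    DP = GQ = AD = None
    if cfg.with_quality_layers:
        DP = rng.poisson(cfg.mean_depth, size=dosage.shape).astype(np.int32)
        GQ = np.minimum(99, rng.poisson(55, size=dosage.shape)).astype(np.int32)
        alt_reads = np.zeros_like(DP)
        het = dosage == 1
        diploid_het = het & (ploidy == 2)
        alt_reads[diploid_het] = rng.binomial(DP[diploid_het], 0.5)
        hom_alt = (dosage == ploidy) & (dosage > 0)
        alt_reads[hom_alt] = DP[hom_alt]
        haploid_alt = het & (ploidy == 1)
        alt_reads[haploid_alt] = DP[haploid_alt]
        AD = np.stack([DP - alt_reads, alt_reads], axis=-1)

    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(miss, MISSING, dosage).astype(np.int8)

    cohort = CohortGenotypes(samples, sites, dosage, ploidy, DP, GQ, AD)
    truth = SimTruth(
        ancestral_freqs=p_anc,
        population_freqs=pop_freqs,
        per_population_fst=per_pop_fst,
        extra={"sample_population": sample_pop},
    )
    return cohort, truth


def hudson_fst(cohort: CohortGenotypes, pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Hudson's F_ST estimator between two sample subsets (ratio of averages).

    Used by recovery tests to check that the generator's drift parameter is
    identifiable from the genotypes it emits.
    """
    def freq_and_n(mask):
        sub = cohort.dosage[mask]
        pl = cohort.ploidy[mask]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        tot = np.where(called, pl, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / tot, np.nan), tot

    p1, n1 = freq_and_n(pop_a)
    p2, n2 = freq_and_n(pop_b)
    ok = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


@dataclass
class RohCohortConfig:
    """Cohort with planted autozygosity tracts for ROH-recovery tests.

    Outside tracts genotypes are drawn at a high heterozygosity rate;
    inside a tract the two haplotypes are identical by descent, so
    heterozygotes appear only at the residual error rate.
    """

    n_samples: int = 10
    n_sites: int = 20_000
    site_spacing: int = 2_000
    tract_fraction: float = 0.25
    mean_tract_snps: int = 1_000
    background_het_rate: float = 0.30
    tract_het_rate: float = 0.005
    missing_rate: float = 0.0
    chrom: str = "chr1"


def generate_roh_cohort(
    config: RohCohortConfig, seed: int
) -> tuple[CohortGenotypes, SimTruth]:
    """Plant per-sample homozygous tracts with known spans.

    Truth records each sample's tract intervals (1-based, inclusive SNP
    positions) and the implied F_ROH against ``n_sites * site_spacing``.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    pos = (np.arange(cfg.n_sites) + 1) * cfg.site_spacing
    samples = [SampleRecord(f"s{i:03d}", "village") for i in range(cfg.n_samples)]
    sites = [SiteRecord(cfg.chrom, int(p), "A", "G") for p in pos]
    dosage = np.empty((cfg.n_samples, cfg.n_sites), dtype=np.int8)
    tract_truth: dict[str, list[tuple[int, int]]] = {}
    genome_size = cfg.n_sites * cfg.site_spacing

    for i in range(cfg.n_samples):
        in_tract = np.zeros(cfg.n_sites, dtype=bool)
        target = int(cfg.tract_fraction * cfg.n_sites)
        placed = 0
        tracts: list[tuple[int, int]] = []
        guard = 0
        while placed < target and guard < 1000:
            guard += 1
            ln = max(200, int(rng.poisson(cfg.mean_tract_snps)))
            ln = min(ln, target - placed + 200)
            start = int(rng.integers(0, cfg.n_sites - ln))
            if in_tract[max(0, start - 1) : min(cfg.n_sites, start + ln + 1)].any():
                continue
            in_tract[start : start + ln] = True
            tracts.append((int(pos[start]), int(pos[start + ln - 1])))
            placed += ln
        het_rate = np.where(in_tract, cfg.tract_het_rate, cfg.background_het_rate)
        u = rng.random(cfg.n_sites)
        hom_alt = rng.random(cfg.n_sites) < 0.5
        dosage[i] = np.where(u < het_rate, 1, np.where(hom_alt, 2, 0))
        tract_truth[samples[i].id] = sorted(tracts)

    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = MISSING

    cohort = CohortGenotypes(samples, sites, dosage)
    froh_truth = {
        sid: sum(e - s + 1 for s, e in tr) / genome_size
        for sid, tr in tract_truth.items()
    }
    truth = SimTruth(
        extra={
            "tracts": tract_truth,
            "froh": froh_truth,
            "genome_size": genome_size,
        }
    )
    return cohort, truth


def generate_dstat_cohort(
    n_per_pop: int = 10,
    n_sites: int = 5000,
    fst: float = 0.1,
    outgroup_fst: float = 0.4,
    admixture: float = 0.0,
    seed: int = 0,
    site_spacing: int = 25_000,
) -> tuple[CohortGenotypes, SimTruth]:
    """Four-population cohort for Patterson's D: (W, X)(Y, Z).

    W, X and Y drift independently from a shared ancestral frequency (so W
    and X are exchangeable with respect to Y under the null); Z drifts
    further as the outgroup.  ``admixture`` mixes a fraction of Y's allele
    frequencies into X, the gene-flow signal D is designed to detect.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    freqs = {
        "W": _balding_nichols(rng, p_anc, fst, n_sites),
        "X": _balding_nichols(rng, p_anc, fst, n_sites),
        "Y": _balding_nichols(rng, p_anc, fst, n_sites),
        "Z": _balding_nichols(rng, p_anc, outgroup_fst, n_sites),
    }
    if admixture > 0:
        freqs["X"] = (1 - admixture) * freqs["X"] + admixture * freqs["Y"]

    samples, rows = [], []
    for pop in ("W", "X", "Y", "Z"):
        for i in range(n_per_pop):
            samples.append(SampleRecord(f"{pop}_s{i}", "village", group_label=pop))
            rows.append(freqs[pop])
    freq = np.stack(rows)
    dosage = rng.binomial(2, freq).astype(np.int8)
    sites = [
        SiteRecord("chr1", (j + 1) * site_spacing, "A", "G") for j in range(n_sites)
    ]
    cohort = CohortGenotypes(samples, sites, dosage)
    truth = SimTruth(ancestral_freqs=p_anc, population_freqs=freqs,
                     extra={"admixture": admixture})
    return cohort, truth


# ---------------------------------------------------------------------------
# structural variants and gene models


@dataclass
class SvConfig:
    n_genes: int = 20
    introns_per_gene: int = 4
    retrogene_parents: list[str] = field(default_factory=list)
    carriers_per_retrogene: int = 3
    background_sv_count: int = 200
    sine_peak_fraction: float = 0.3
    n_samples: int = 20
    exon_length: int = 150
    intron_length_range: tuple[int, int] = (500, 5000)
    intergenic_gap: int = 20000
    chrom: str = "chr1"
    background_af_range: tuple[float, float] = (0.02, 0.5)


def _draw_sv_size(rng, peak: bool, lo=50, hi=100_000):
    """SV length: the SINE peak is uniform on [180, 220]; background sizes
    are log-uniform on [lo, hi] excluding the peak window, so the peak
    fraction is exactly the configured binomial probability."""
    if peak:
        return int(rng.integers(180, 221))
    while True:
        s = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if not 180 <= s <= 220:
            return max(s, lo)


def _reciprocal_overlap(a_start, a_end, b_start, b_end):
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def generate_sv_inputs(
    config: SvConfig, seed: int
) -> tuple[list[GeneModel], list[SvCall], SimTruth]:
    """Gene models plus an SV call set with planted retrogene signatures.

    For each truth retrogene parent, every intron of its transcript is
    emitted as a deletion with >=99% reciprocal overlap, carried by the
    designated samples.  Background deletions/insertions are drawn from a
    size mixture with a mode at ~200 bp (the SINEC insertion peak) and are
    rejected if they would reciprocally overlap an annotated intron.
    """
    cfg = config
    rng = np.random.default_rng(seed)

    genes: list[GeneModel] = []
    pos = 10_000
    for g in range(cfg.n_genes):
        gene_id = f"gene{g:04d}"
        exons = []
        for e in range(cfg.introns_per_gene + 1):
            exons.append((pos, pos + cfg.exon_length))
            pos += cfg.exon_length
            if e < cfg.introns_per_gene:
                pos += int(rng.integers(*cfg.intron_length_range))
        genes.append(GeneModel(gene_id, gene_id + ".t1", cfg.chrom, "+", exons))
        pos += cfg.intergenic_gap
    chrom_end = pos + 100_000

    gene_by_id = {g.gene_id: g for g in genes}
    for pid in cfg.retrogene_parents:
        if pid not in gene_by_id:
            raise ValueError(f"retrogene parent {pid!r} is not a generated gene")
        if len(gene_by_id[pid].exons) < 2:
            raise ValueError(f"gene {pid!r} has no introns")

    sample_ids = [f"s{i:03d}" for i in range(cfg.n_samples)]
    svs: list[SvCall] = []
    truth_retro: list[tuple[str, list[str]]] = []
    k = 0

    for pid in cfg.retrogene_parents:
        gene = gene_by_id[pid]
        carrier_idx = rng.choice(
            cfg.n_samples, size=cfg.carriers_per_retrogene, replace=False
        )
        carriers = sorted(sample_ids[i] for i in carrier_idx)
        gt = np.zeros(cfg.n_samples, dtype=np.int8)
        gt[carrier_idx] = 1
        for start, end in gene.introns:
            svs.append(
                SvCall(
                    f"sv{k:05d}", cfg.chrom, start, end, "DEL", end - start, gt.copy()
                )
            )
            k += 1
        truth_retro.append((pid, carriers))

    all_introns = [iv for g in genes for iv in g.introns]
    peak = rng.random(cfg.background_sv_count) < cfg.sine_peak_fraction
    for i in range(cfg.background_sv_count):
        svtype = "DEL" if rng.random() < 0.6 else "INS"
        length = _draw_sv_size(rng, bool(peak[i]))
        while True:
            start = int(rng.integers(0, chrom_end - length - 1))
            end = start + length if svtype == "DEL" else start + 1
            if svtype == "INS":
                break
            if all(
                _reciprocal_overlap(start, end, a, b) < 0.99 for a, b in all_introns
            ):
                break
        af = rng.uniform(*cfg.background_af_range)
        gt = rng.binomial(2, af, size=cfg.n_samples).astype(np.int8)
        svs.append(SvCall(f"sv{k:05d}", cfg.chrom, start, end, svtype, length, gt))
        k += 1

    truth = SimTruth(
        retrogene_truth=truth_retro,
        extra={"sample_ids": sample_ids, "chrom_end": chrom_end},
    )
    return genes, svs, truth


# ---------------------------------------------------------------------------
# coverage / MQ0 / reference tracks


@dataclass
class Tracks:
    """Per-base pooled coverage and MQ0-fraction tracks plus reference N-runs."""

    coverage: dict[str, np.ndarray]
    mq0_fraction: dict[str, np.ndarray]
    n_runs: dict[str, list[tuple[int, int]]]  # 0-based half-open
    region_class: dict[str, str]  # chrom -> 'autosome' | 'X_PAR' | 'X_nonPAR'


def generate_tracks(
    genome_length_per_chrom: dict[str, int],
    median_depth: float = 30.0,
    uncallable_fraction: float = 0.05,
    seed: int = 0,
    region_class: dict[str, str] | None = None,
) -> tuple[Tracks, SimTruth]:
    """Coverage/MQ0/N tracks with planted uncallable spans.

    Truth-uncallable spans are given a violating signal (out-of-band depth,
    MQ0 >= 0.10, or reference N); everywhere else the depth is Poisson
    around the median but clipped inside the +/-50% callable band and MQ0
    is zero, so the mask builder should recover the planted spans exactly
    up to Monte-Carlo noise.
    """
    if not 0.0 <= uncallable_fraction < 1.0:
        raise ValueError("uncallable_fraction must be in [0, 1)")
    if median_depth <= 0:
        raise ValueError("median_depth must be positive")
    rng = np.random.default_rng(seed)
    coverage, mq0, n_runs, truth_unc = {}, {}, {}, {}
    rc = region_class or {c: "autosome" for c in genome_length_per_chrom}

    lo = int(np.ceil(0.5 * median_depth + 1e-9))
    hi = int(np.floor(1.5 * median_depth - 1e-9))
    for chrom, L in genome_length_per_chrom.items():
        depth = rng.poisson(median_depth, size=L)
        # keep callable background inside a band strictly within +/-50%
        # so the realised median cannot drag background positions out
        depth = np.clip(depth, int(0.6 * median_depth), int(1.4 * median_depth))
        frac = np.zeros(L)
        runs: list[tuple[int, int]] = []
        spans: list[tuple[int, int]] = []
        target = int(round(uncallable_fraction * L))
        placed = 0
        guard = 0
        while placed < target and guard < 10_000:
            guard += 1
            span_len = int(min(rng.integers(200, 2000), target - placed))
            if span_len <= 0:
                break
            start = int(rng.integers(0, L - span_len))
            end = start + span_len
            if any(s < end and start < e for s, e in spans):
                continue
            mode = rng.integers(0, 4)
            if mode == 0:
                runs.append((start, end))
                depth[start:end] = 0
            elif mode == 1:
                frac[start:end] = rng.uniform(0.10, 0.5)
            elif mode == 2:
                depth[start:end] = rng.integers(0, max(1, lo - 1))
            else:
                depth[start:end] = rng.integers(hi + 2, int(3 * median_depth))
            spans.append((start, end))
            placed += span_len
        coverage[chrom] = depth
        mq0[chrom] = frac
        n_runs[chrom] = sorted(runs)
        truth_unc[chrom] = sorted(spans)

    tracks = Tracks(coverage, mq0, n_runs, rc)
    truth = SimTruth(uncallable_intervals=truth_unc)
    return tracks, truth


# ---------------------------------------------------------------------------
# mitochondrial references and call sets


@dataclass
class MitoConfig:
    ref_length: int = 16_727
    rotation_offset: int = 8000
    n_haplogroups: int = 4
    haplotypes_per_group: int = 2
    n_samples: int = 12
    variants_near_origin: int = 4
    variants_per_haplotype: int = 10
    edge_loss: int = 300  # calls within this many bp of a linear end are lost
    n_heteroplasmic_artifacts: int = 0
    n_strand_bias_artifacts: int = 0
    end_window: int = 4000


@dataclass
class MitoSim:
    """Everything the mitochondrial pipeline consumes, with truth attached."""

    primary_ref: str
    rotated_ref: str
    primary_calls: dict[str, list[MitoCall]]  # sample -> calls (primary coords)
    rotated_calls: dict[str, list[MitoCall]]  # sample -> calls (rotated coords)
    truth_variants: dict[str, list[tuple[int, str, str]]]  # sample -> (pos,ref,alt)
    sample_haplogroup: dict[str, str]
    haplotype_variants: dict[str, list[tuple[int, str, str]]]  # hap id -> variants
    depth: dict[str, np.ndarray]  # per-sample per-position depth (1-based pos-1)


_BASES = "ACGT"


def _rotate_seq(seq: str, offset: int) -> str:
    return seq[offset - 1 :] + seq[: offset - 1]


def generate_mito(config: MitoConfig, seed: int) -> MitoSim:
    """Two rotated mitochondrial references plus per-reference call sets.

    A small haplotype tree is simulated (haplogroups A, B, ... each with a
    few derived haplotypes); per-sample truth variants are placed so that at
    least ``variants_near_origin`` of them fall in the first/last 4 kb of
    the primary coordinate system.  Calls against each linear reference lose
    variants within ``edge_loss`` bp of that reference's own ends, which is
    the failure mode the dual-reference merge exists to fix.
    """
    cfg = config
    L, S = cfg.ref_length, cfg.rotation_offset
    if not 1 <= S <= L:
        raise ValueError("rotation offset must be in [1, L]")
    if L <= 2 * cfg.end_window:
        raise ValueError(
            f"reference length {L} too short for {cfg.end_window}-bp merge windows"
        )
    rng = np.random.default_rng(seed)
    ref = "".join(rng.choice(list(_BASES), size=L))
    rotated_ref = _rotate_seq(ref, S)

    near = list(
        rng.choice(
            np.concatenate(
                [np.arange(1, cfg.end_window + 1), np.arange(L - cfg.end_window + 1, L + 1)]
            ),
            size=cfg.variants_near_origin,
            replace=False,
        )
    )
    interior_pool = np.arange(cfg.end_window + 1, L - cfg.end_window + 1)

    hap_variants: dict[str, list[tuple[int, str, str]]] = {}
    used = set(near)
    for g in range(cfg.n_haplogroups):
        group = chr(ord("A") + g) + "1"
        # group-defining variants shared by all haplotypes of the group
        shared = []
        for _ in range(cfg.variants_per_haplotype):
            while True:
                p = int(rng.choice(interior_pool))
                if p not in used:
                    used.add(p)
                    break
            r = ref[p - 1]
            a = rng.choice([b for b in _BASES if b != r])
            shared.append((p, r, str(a)))
        for h in range(cfg.haplotypes_per_group):
            extra = []
            for _ in range(2):
                while True:
                    p = int(rng.choice(interior_pool))
                    if p not in used:
                        used.add(p)
                        break
                r = ref[p - 1]
                a = rng.choice([b for b in _BASES if b != r])
                extra.append((p, r, str(a)))
            hap_variants[f"{group}.h{h}"] = sorted(shared + extra)

    hap_ids = sorted(hap_variants)
    sample_ids = [f"m{i:03d}" for i in range(cfg.n_samples)]
    assignment = {
        s: hap_ids[int(rng.integers(0, len(hap_ids)))] for s in sample_ids
    }

    # distribute the near-origin variants over samples (appended to their
    # haplotype variants so they are part of each carrier's truth)
    near_records = []
    for p in near:
        r = ref[int(p) - 1]
        a = rng.choice([b for b in _BASES if b != r])
        near_records.append((int(p), r, str(a)))

    truth: dict[str, list[tuple[int, str, str]]] = {}
    for i, s in enumerate(sample_ids):
        mine = list(hap_variants[assignment[s]])
        for j, recd in enumerate(near_records):
            if j % cfg.n_samples == i or cfg.n_samples == 1:
                mine.append(recd)
        truth[s] = sorted(set(mine))

    primary_calls: dict[str, list[MitoCall]] = {}
    rotated_calls: dict[str, list[MitoCall]] = {}
    depth = {}
    for s in sample_ids:
        depth[s] = rng.integers(400, 1200, size=L).astype(np.int64)
        pc, rc_ = [], []
        for p, r, a in truth[s]:
            af = 1.0
            if p > cfg.edge_loss and p <= L - cfg.edge_loss:
                pc.append(MitoCall(p, r, a, af, False, int(depth[s][p - 1]), "primary"))
            rp = ((p - S) % L) + 1
            if rp > cfg.edge_loss and rp <= L - cfg.edge_loss:
                rc_.append(MitoCall(rp, r, a, af, False, int(depth[s][p - 1]), "rotated"))
        for _ in range(cfg.n_heteroplasmic_artifacts):
            p = int(rng.choice(interior_pool))
            r = ref[p - 1]
            a = str(rng.choice([b for b in _BASES if b != r]))
            pc.append(
                MitoCall(p, r, a, float(rng.uniform(0.05, 0.49)), False, 500, "primary")
            )
        for _ in range(cfg.n_strand_bias_artifacts):
            p = int(rng.choice(interior_pool))
            r = ref[p - 1]
            a = str(rng.choice([b for b in _BASES if b != r]))
            pc.append(MitoCall(p, r, a, 1.0, True, 500, "primary"))
        primary_calls[s] = sorted(pc, key=lambda c: c.pos)
        rotated_calls[s] = sorted(rc_, key=lambda c: c.pos)

    return MitoSim(
        primary_ref=ref,
        rotated_ref=rotated_ref,
        primary_calls=primary_calls,
        rotated_calls=rotated_calls,
        truth_variants=truth,
        sample_haplogroup={s: assignment[s].split(".")[0] for s in sample_ids},
        haplotype_variants=hap_variants,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# imputation truth/imputed pairs


@dataclass
class ImputationConfig:
    """Corruption model for truth-vs-imputed genotype pairs.

    ``error_rates`` maps MAF bins (lo, hi] to a per-genotype corruption
    probability.  By default corruption targets genotypes whose truth call
    is non-reference ("nonref" mode), so the bin's error rate equals the
    expected non-reference discordance 1 - NRC; "all" mode corrupts every
    genotype independently instead.  Sites drawn as low-INFO carry an
    elevated corruption rate (``low_info_multiplier``).
    """

    error_rates: dict[tuple[float, float], float] = field(
        default_factory=lambda: {(0.0, 0.01): 0.10, (0.01, 0.05): 0.05, (0.05, 0.5): 0.02}
    )
    mode: str = "nonref"  # 'nonref' | 'all'
    low_info_fraction: float = 0.0
    low_info_multiplier: float = 5.0
    info_high_range: tuple[float, float] = (0.92, 1.0)
    info_low_range: tuple[float, float] = (0.5, 0.88)


def generate_imputation_pair(
    truth: CohortGenotypes, config: ImputationConfig, seed: int
) -> tuple[CohortGenotypes, np.ndarray]:
    """Corrupt a truth cohort into an 'imputed' one plus per-site INFO scores."""
    cfg = config
    bins = sorted(cfg.error_rates)
    if not bins or bins[0][0] > 0.0 or bins[-1][1] < 0.5:
        raise ValueError("error-rate MAF bins must cover (0, 0.5]")
    for lo, hi in bins:
        r = cfg.error_rates[(lo, hi)]
        if not 0.0 <= r <= 1.0:
            raise ValueError("error rates must be in [0, 1]")
    rng = np.random.default_rng(seed)

    af = truth.alt_allele_freq()
    maf = np.minimum(af, 1 - af)
    site_rate = np.zeros(truth.n_sites)
    for (lo, hi), r in cfg.error_rates.items():
        sel = (maf > lo) & (maf <= hi)
        site_rate[sel] = r
    site_rate[maf == 0.0] = cfg.error_rates[bins[0]]

    low_info = rng.random(truth.n_sites) < cfg.low_info_fraction
    info = np.where(
        low_info,
        rng.uniform(*cfg.info_low_range, size=truth.n_sites),
        rng.uniform(*cfg.info_high_range, size=truth.n_sites),
    )
    eff_rate = np.where(
        low_info, np.minimum(1.0, site_rate * cfg.low_info_multiplier), site_rate
    )

    dosage = truth.dosage.copy()
    called = dosage != MISSING
    corrupt = (rng.random(dosage.shape) < eff_rate[None, :]) & called
    if cfg.mode == "nonref":
        corrupt &= dosage >= 1
    elif cfg.mode != "all":
        raise ValueError(f"unknown corruption mode {cfg.mode!r}")
    shift = rng.integers(1, np.where(truth.ploidy == 2, 3, 2))
    dosage = np.where(corrupt, (dosage + shift) % (truth.ploidy + 1), dosage).astype(
        np.int8
    )
    imputed = CohortGenotypes(
        list(truth.samples), list(truth.sites), dosage, truth.ploidy.copy()
    )
    return imputed, info
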