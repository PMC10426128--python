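"""Generator correctness: determinism, range invariants, parameter recovery."""

import numpy as np
import pytest

from canidkit.cohort import MISSING, EmptyCohortError
from canidkit import synthio
from canidkit.synthio import (
    CohortConfig,
    ImputationConfig,
    MitoConfig,
    SvConfig,
    generate_cohort,
    generate_imputation_pair,
    generate_mito,
    generate_sv_inputs,
    generate_tracks,
    hudson_fst,
)


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self):
        cfg = CohortConfig(n_sites=2000, fst_range=(0.2, 0.2))
        a, _ = generate_cohort(cfg, seed=7)
        b, _ = generate_cohort(cfg, seed=7)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.DP, b.DP)
        assert np.array_equal(a.AD, b.AD)
        c, _ = generate_cohort(cfg, seed=8)
        assert not np.array_equal(a.dosage, c.dosage)

    def test_empty_cohort_raises(self):
        with pytest.raises(EmptyCohortError):
            generate_cohort(CohortConfig(n_breeds=0, n_village=0, n_wolf=0), seed=1)
        with pytest.raises(EmptyCohortError):
            generate_cohort(CohortConfig(n_sites=0), seed=1)

    def test_zero_fst_means_no_differentiation(self):
        cfg = CohortConfig(
            n_breeds=2, samples_per_breed=60, n_village=0, n_wolf=0,
            n_sites=20000, fst_range=(0.0, 0.0), with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=3)
        f = hudson_fst(
            cohort, cohort.samples_in_breed("BREED00"), cohort.samples_in_breed("BREED01")
        )
        assert abs(f) < 0.01

    def test_fst_recovery_within_tolerance(self):
        cfg = CohortConfig(
            n_breeds=2, samples_per_breed=50, n_village=0, n_wolf=0,
            n_sites=10000, fst_range=(0.2, 0.2), with_quality_layers=False,
        )
        cohort, truth = generate_cohort(cfg, seed=7)
        f = hudson_fst(
            cohort, cohort.samples_in_breed("BREED00"), cohort.samples_in_breed("BREED01")
        )
        assert f == pytest.approx(0.2, abs=0.03)

    def test_quality_layers_consistent(self):
        cohort, _ = generate_cohort(CohortConfig(n_sites=500), seed=5)
        assert (cohort.DP >= 0).all() and (cohort.GQ >= 0).all()
        tot = cohort.AD.sum(axis=-1)
        assert (tot <= cohort.DP).all()
        hom_alt = (cohort.dosage == cohort.ploidy) & (cohort.dosage > 0)
        assert (cohort.AD[..., 1][hom_alt] == cohort.DP[hom_alt]).all()
        hom_ref = cohort.dosage == 0
        assert (cohort.AD[..., 1][hom_ref] == 0).all()

    def test_male_x_nonpar_is_haploid(self):
        cfg = CohortConfig(n_sites=1000, x_nonpar_fraction=0.2, male_fraction=1.0)
        cohort, _ = generate_cohort(cfg, seed=2)
        nonpar = cohort.region_classes() == "X_nonPAR"
        assert nonpar.sum() == 200
        assert (cohort.ploidy[:, nonpar] == 1).all()
        assert (cohort.dosage[:, nonpar] <= 1).all()

    def test_missing_rate_applied(self):
        cfg = CohortConfig(n_sites=5000, missing_rate=0.1, with_quality_layers=False)
        cohort, _ = generate_cohort(cfg, seed=4)
        assert (cohort.dosage == MISSING).mean() == pytest.approx(0.1, abs=0.01)


class TestGenerateSvInputs:
    def test_planted_retrogene_emits_all_introns(self):
        cfg = SvConfig(
            n_genes=5, introns_per_gene=5, retrogene_parents=["gene0001"],
            carriers_per_retrogene=3, background_sv_count=0,
        )
        genes, svs, truth = generate_sv_inputs(cfg, seed=1)
        assert len(svs) == 5  # one deletion per intron
        gene = next(g for g in genes if g.gene_id == "gene0001")
        assert sorted((s.start, s.end) for s in svs) == sorted(gene.introns)
        (gid, carriers), = truth.retrogene_truth
        assert gid == "gene0001" and len(carriers) == 3
        for sv in svs:
            carried = {truth.extra["sample_ids"][i] for i in np.flatnonzero(sv.genotypes >= 1)}
            assert carried == set(carriers)

    def test_sine_peak_fraction(self):
        cfg = SvConfig(n_genes=2, background_sv_count=10_000, sine_peak_fraction=0.5)
        _, svs, _ = generate_sv_inputs(cfg, seed=9)
        sizes = np.array([sv.length for sv in svs])
        frac = ((sizes >= 180) & (sizes <= 220)).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="not a generated gene"):
            generate_sv_inputs(SvConfig(retrogene_parents=["nope"]), seed=0)

    def test_no_background_deletion_mimics_intron(self):
        from canidkit.svretro import reciprocal_overlap

        cfg = SvConfig(n_genes=10, background_sv_count=500, retrogene_parents=[])
        genes, svs, _ = generate_sv_inputs(cfg, seed=2)
        introns = [iv for g in genes for iv in g.introns]
        for sv in svs:
            if sv.svtype == "DEL":
                assert all(
                    reciprocal_overlap((sv.start, sv.end), iv) < 0.99 for iv in introns
                )


class TestGenerateTracks:
    def test_uncallable_fraction_zero_is_nearly_all_callable(self):
        from canidkit.maskcall import build_mask

        tracks, _ = generate_tracks({"chr1": 50_000}, 30.0, 0.0, seed=1)
        mask = build_mask(tracks)
        frac = mask.callable_bases() / 50_000
        assert frac >= 0.99

    def test_truth_fraction_recovered(self):
        from canidkit.maskcall import build_mask

        tracks, truth = generate_tracks({"chr1": 100_000}, 30.0, 0.05, seed=3)
        mask = build_mask(tracks)
        rec = mask.uncallable_bases() / 100_000
        planted = sum(e - s for s, e in truth.uncallable_intervals["chr1"]) / 100_000
        assert rec == pytest.approx(planted, abs=0.01)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            generate_tracks({"chr1": 1000}, median_depth=0.0, seed=1)
        with pytest.raises(ValueError):
            generate_tracks({"chr1": 1000}, uncallable_fraction=1.0, seed=1)


class TestGenerateMito:
    def test_rotated_coordinates_consistent(self):
        cfg = MitoConfig(n_samples=4, variants_near_origin=3, edge_loss=0)
        sim = generate_mito(cfg, seed=5)
        L, S = cfg.ref_length, cfg.rotation_offset
        for s, calls in sim.rotated_calls.items():
            truth_pos = {p for p, _, _ in sim.truth_variants[s]}
            for c in calls:
                assert ((c.pos - 1 + S - 1) % L) + 1 in truth_pos

    def test_rotated_reference_is_rotation(self):
        sim = generate_mito(MitoConfig(n_samples=2), seed=1)
        S = MitoConfig().rotation_offset
        assert sim.rotated_ref == sim.primary_ref[S - 1:] + sim.primary_ref[: S - 1]

    def test_near_origin_variants_present(self):
        cfg = MitoConfig(n_samples=3, variants_near_origin=4)
        sim = generate_mito(cfg, seed=8)
        L = cfg.ref_length
        near = {
            p
            for vs in sim.truth_variants.values()
            for p, _, _ in vs
            if p <= 4000 or p > L - 4000
        }
        assert len(near) >= 4

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="merge window"):
            generate_mito(MitoConfig(ref_length=7000, rotation_offset=3500), seed=0)


class TestGenerateImputationPair:
    @staticmethod
    def _truth(seed=11, n_sites=2000):
        cfg = CohortConfig(
            n_breeds=0, n_village=40, n_wolf=0, n_sites=n_sites,
            with_quality_layers=False,
        )
        return generate_cohort(cfg, seed=seed)[0]

    def test_zero_rates_identity(self):
        truth = self._truth()
        icfg = ImputationConfig(error_rates={(0.0, 0.5): 0.0})
        imputed, info = generate_imputation_pair(truth, icfg, seed=1)
        assert np.array_equal(imputed.dosage, truth.dosage)
        assert ((info >= 0) & (info <= 1)).all()

    def test_all_mode_overall_discordance(self):
        truth = self._truth(n_sites=1000)
        icfg = ImputationConfig(error_rates={(0.0, 0.5): 0.1}, mode="all")
        imputed, _ = generate_imputation_pair(truth, icfg, seed=2)
        disc = (imputed.dosage != truth.dosage).mean()
        assert disc == pytest.approx(0.1, abs=0.01)

    def test_bins_must_cover_half(self):
        truth = self._truth(n_sites=100)
        with pytest.raises(ValueError, match="cover"):
            generate_imputation_pair(
                truth, ImputationConfig(error_rates={(0.0, 0.2): 0.1}), seed=1
            )

    def test_rare_bin_less_concordant(self):
        from canidkit.imputeval import nrc

        rare_lt_common = 0
        for seed in range(10):
            truth = self._truth(seed=100 + seed, n_sites=4000)
            icfg = ImputationConfig(
                error_rates={(0.0, 0.05): 0.3, (0.05, 0.5): 0.05}
            )
            imputed, info = generate_imputation_pair(truth, icfg, seed=seed)
            table = nrc(
                truth, imputed, info,
                maf_bins=((0.0, 0.05), (0.05, 0.5)), info_cut=0.0,
            )
            if table.nrc_for((0.0, 0.05)) < table.nrc_for((0.05, 0.5)):
                rare_lt_common += 1
        assert rare_lt_common == 10
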