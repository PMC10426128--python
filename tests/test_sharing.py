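"""Category partition, F2, D-statistic, SFS and LP-projection behaviour."""

import numpy as np
import pytest

from canidkit.cohort import MISSING
from canidkit.sharing import (
    SFSpectrum,
    category_partition,
    d_statistic,
    expected_discovery,
    f2_analysis,
    project_discovery,
    sfs,
)
from canidkit.synthio import CohortConfig, generate_cohort
from tests.conftest import make_cohort


class TestCategoryPartition:
    def test_hand_constructed_cells(self):
        # samples: breed, mixed, village, wolf; 3 sites hitting the cells
        # {all three}, {village only}, {breed & wolf}
        dosage = np.array(
            [
                [1, 0, 1],
                [0, 0, 0],
                [1, 1, 0],
                [2, 0, 1],
            ],
            dtype=np.int8,
        )
        cohort = make_cohort(dosage, categories=["breed", "mixed", "village", "wolf"])
        part = category_partition(cohort)
        assert part.count("breed", "village", "wolf") == 1
        assert part.count("village") == 1
        assert part.count("breed", "wolf") == 1
        assert part.total == 3

    def test_mixed_pooled_with_breed(self):
        dosage = np.array([[0], [1], [0]], dtype=np.int8)
        cohort = make_cohort(dosage, categories=["breed", "mixed", "wolf"])
        part = category_partition(cohort)
        assert part.count("breed") == 1  # the mixed carrier lands in the breed cell

    def test_monomorphic_site_excluded(self):
        dosage = np.zeros((3, 2), dtype=np.int8)
        dosage[:, 0] = [1, 0, 0]
        cohort = make_cohort(dosage, categories=["breed", "village", "wolf"])
        part = category_partition(cohort)
        assert part.total == 1 and part.n_excluded == 1

    def test_cells_partition_polymorphic_sites(self, rng):
        dosage = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
        cats = (["breed"] * 4 + ["mixed"] * 2 + ["village"] * 3 + ["wolf"] * 3)
        cohort = make_cohort(dosage, categories=cats)
        part = category_partition(cohort)
        assert sum(part.cells.values()) == part.total
        assert part.total + part.n_excluded == 300


class TestF2:
    def test_zygosity_ignored(self):
        cohort = make_cohort(np.array([[1], [2], [0], [0]], dtype=np.int8))
        table = f2_analysis(cohort)
        assert table.site_indices == [0]
        assert table.carriers == [("s0", "s1")]

    def test_single_carrier_not_f2(self):
        cohort = make_cohort(np.array([[1], [0], [0], [0]], dtype=np.int8))
        assert f2_analysis(cohort).site_indices == []

    def test_missing_genotype_disqualifies(self):
        cohort = make_cohort(np.array([[1], [1], [MISSING], [0]], dtype=np.int8))
        assert f2_analysis(cohort).site_indices == []

    def test_brute_force_equivalence(self, rng):
        for _ in range(20):
            n, m = int(rng.integers(4, 30)), int(rng.integers(10, 400))
            dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            dosage[rng.random((n, m)) < 0.05] = MISSING
            cohort = make_cohort(dosage)
            got = set(f2_analysis(cohort).site_indices)
            expected = set()
            for j in range(m):
                col = dosage[:, j]
                if (col == MISSING).any():
                    continue
                if sum(1 for g in col if g >= 1) == 2:
                    expected.add(j)
            assert got == expected

    def test_partner_fractions(self):
        dosage = np.array(
            [[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.int8
        )
        cohort = make_cohort(
            dosage, categories=["breed", "breed", "wolf", "village"]
        )
        table = f2_analysis(cohort)
        assert table.per_sample_counts["s0"] == 2
        assert table.partner_category_fractions["s0"] == {"breed": 0.5, "wolf": 0.5}


class TestDStatistic:
    @staticmethod
    def _masks(cohort, *groups):
        out = []
        for g in groups:
            out.append(np.isin(np.arange(cohort.n_samples), g))
        return out

    def test_identical_wx_gives_zero(self, rng):
        dosage = rng.integers(0, 3, size=(8, 2000)).astype(np.int8)
        dosage[1] = dosage[0]  # X identical to W
        cohort = make_cohort(dosage, positions=np.arange(2000) * 10_000 + 1)
        w, x, y, z = self._masks(cohort, [0], [1], [2, 3], [4, 5])
        res = d_statistic(cohort, w, x, y, z)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_swapping_w_and_x_negates_d(self, rng):
        cfg = CohortConfig(
            n_breeds=4, samples_per_breed=5, n_village=0, n_wolf=0,
            n_sites=3000, with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=77)
        m = [cohort.samples_in_breed(f"BREED0{i}") for i in range(4)]
        r1 = d_statistic(cohort, m[0], m[1], m[2], m[3])
        r2 = d_statistic(cohort, m[1], m[0], m[2], m[3])
        assert r1.d == pytest.approx(-r2.d)

    def test_fixed_allele_toy_counts(self):
        # engineer sites contributing ABBA or BABA exactly 1 each:
        # ABBA site: W=0, X=2, Y=2, Z=0 -> abba=1; BABA: W=2, X=0, Y=2, Z=0
        abba_site = [0, 2, 2, 0]
        baba_site = [2, 0, 2, 0]
        cols = [abba_site] * 30 + [baba_site] * 10
        dosage = np.array(cols, dtype=np.int8).T
        cohort = make_cohort(dosage, positions=np.arange(40) * 1000 + 1)
        w, x, y, z = self._masks(cohort, [0], [1], [2], [3])
        res = d_statistic(cohort, w, x, y, z, block_size_bp=4000)
        assert res.abba == pytest.approx(30.0)
        assert res.baba == pytest.approx(10.0)
        assert res.d == pytest.approx(0.5)

    def test_zero_information_raises(self):
        dosage = np.zeros((4, 10), dtype=np.int8)
        cohort = make_cohort(dosage)
        w, x, y, z = self._masks(cohort, [0], [1], [2], [3])
        with pytest.raises(ZeroDivisionError):
            d_statistic(cohort, w, x, y, z)


class TestSfs:
    def test_all_singleton_hets(self):
        dosage = np.zeros((5, 20), dtype=np.int8)
        dosage[0] = 1
        spec = sfs(make_cohort(dosage))
        assert spec.counts[0] == 20
        assert spec.counts[1:].sum() == 0

    def test_hand_matrix_enumeration(self):
        dosage = np.array(
            [
                [0, 1, 2, 0, 2],
                [1, 1, 2, 0, 2],
                [0, 0, 2, 0, 2],
            ],
            dtype=np.int8,
        )
        spec = sfs(make_cohort(dosage))
        # alt counts per site: 1, 2, 6, 0, 6 -> c1=1, c2=1, c6=2
        assert spec.n_chrom == 6
        assert list(spec.counts) == [1, 1, 0, 0, 0, 2]

    def test_fixed_alt_included(self):
        dosage = np.full((4, 7), 2, dtype=np.int8)
        spec = sfs(make_cohort(dosage))
        assert spec.counts[spec.n_chrom - 1] == 7

    def test_mixed_ploidy_chromosome_count(self):
        dosage = np.zeros((4, 10), dtype=np.int8)
        ploidy = np.full((4, 10), 2, dtype=np.int8)
        ploidy[0] = 1  # one male on X non-PAR
        cohort = make_cohort(dosage, ploidy=ploidy, region="X_nonPAR")
        spec = sfs(cohort)
        assert spec.n_chrom == 7  # 2*3 females + 1 male

    def test_small_population_rejected(self):
        dosage = np.zeros((2, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="three individuals"):
            sfs(make_cohort(dosage))

    def test_site_with_missing_call_excluded(self):
        dosage = np.zeros((4, 2), dtype=np.int8)
        dosage[:, 0] = [2, 2, 2, 2]
        dosage[0, 1] = MISSING
        dosage[1, 1] = 2
        spec = sfs(make_cohort(dosage))
        assert spec.n_observed == 1  # the partially-missing site is dropped


class TestDiscoveryProjection:
    def test_fixed_alt_mass_projects_to_observed(self):
        n_chrom = 20
        counts = np.zeros(n_chrom, dtype=np.int64)
        counts[-1] = 500  # all sites fixed alternate: frequency-1 mass
        spec = SFSpectrum(n_chrom, counts)
        proj = project_discovery(spec, target_n=100)
        assert proj.lower_bound <= 500 <= proj.upper_bound
        assert proj.point_estimate == pytest.approx(500, rel=0.02)
        assert proj.fraction_discovered == pytest.approx(1.0, rel=0.02)

    def test_truth_mixture_bracketed_and_projection_at_n(self):
        # truth mixture on the LP grid: closed-form expected spectrum
        rng = np.random.default_rng(5)
        n = 25
        grid = np.geomspace(1.0 / 800, 1.0, 64)
        w_true = np.zeros(64)
        w_true[40] = 100.0  # some intermediate frequency
        w_true[55] = 50.0   # common frequency
        f1, f2 = grid[40], grid[55]
        draws = np.concatenate(
            [rng.binomial(2 * n, f1, 100), rng.binomial(2 * n, f2, 50)]
        )
        draws = draws[draws >= 1]
        counts = np.bincount(draws, minlength=2 * n + 1)[1:]
        spec = SFSpectrum(2 * n, counts)
        proj = project_discovery(spec, target_n=100, grid=grid)
        truth_discovery = expected_discovery(w_true, grid, 100)
        assert proj.lower_bound <= truth_discovery <= proj.upper_bound
        # projecting back to the observed sample size reproduces the count
        proj_n = project_discovery(spec, target_n=n, grid=grid)
        eps_total = (3 * np.sqrt(np.maximum(counts, 1))).sum()
        assert abs(proj_n.lower_bound - spec.n_observed) <= eps_total
        assert abs(proj_n.upper_bound - spec.n_observed) <= eps_total
        assert abs(proj_n.point_estimate - spec.n_observed) <= eps_total

    def test_drifted_breed_discovers_smaller_fraction(self):
        # deep drift pushes allele frequencies toward the extremes, so a
        # drifted breed carries extra rare mass that stays hidden at small n
        # and its observed set is a smaller fraction of the projection
        cfg_drift = CohortConfig(
            n_breeds=1, samples_per_breed=15, n_village=0, n_wolf=0,
            n_sites=20000, fst_range=(0.45, 0.45), with_quality_layers=False,
        )
        cfg_diverse = CohortConfig(
            n_breeds=1, samples_per_breed=15, n_village=0, n_wolf=0,
            n_sites=20000, fst_range=(0.01, 0.01), with_quality_layers=False,
        )
        fracs = {}
        for name, cfg in [("drift", cfg_drift), ("diverse", cfg_diverse)]:
            cohort, _ = generate_cohort(cfg, seed=21)
            spec = sfs(cohort)
            fracs[name] = project_discovery(spec, target_n=100).fraction_discovered
        assert fracs["drift"] < fracs["diverse"]

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            project_discovery(SFSpectrum(10, np.zeros(10, dtype=np.int64)))
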