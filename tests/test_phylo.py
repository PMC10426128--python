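"""1-IBS distances, NJ topology recovery, consensus supports, IBD sharing."""

import numpy as np
import pandas as pd
import pytest

from canidkit.cohort import MISSING
from canidkit.phylo import (
    DistanceMatrix,
    consensus_clades,
    haplotype_sharing_summary,
    ibs_distance,
    nj_tree,
)
from canidkit.synthio import CohortConfig, generate_cohort
from tests.conftest import make_cohort
from tests._treeutil import (
    enumerate_topologies,
    path_distance_matrix,
    random_binary_tree,
    splits_by_edge_deletion,
)


class TestIbsDistance:
    def test_identical_vectors_distance_zero(self):
        dosage = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (2, 1))
        dm = ibs_distance(make_cohort(dosage))
        assert dm.values[0, 1] == 0.0

    def test_hand_sum(self):
        dosage = np.array([[0, 2, 1], [0, 0, 1]], dtype=np.int8)
        dm = ibs_distance(make_cohort(dosage))
        assert dm.values[0, 1] == pytest.approx(2 / 6)

    def test_opposite_homozygotes_distance_one(self):
        dosage = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        dm = ibs_distance(make_cohort(dosage))
        assert dm.values[0, 1] == 1.0

    def test_missing_sites_excluded_pairwise(self):
        dosage = np.array([[0, 2, MISSING], [2, 2, 0]], dtype=np.int8)
        dm = ibs_distance(make_cohort(dosage))
        assert dm.n_sites[0, 1] == 2
        assert dm.values[0, 1] == pytest.approx(2 / 4)

    def test_no_shared_sites_rejected(self):
        dosage = np.array([[0, MISSING], [MISSING, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="shares no called sites"):
            ibs_distance(make_cohort(dosage))


class TestNeighborJoining:
    def test_four_taxon_quartet(self):
        ids = list("ABCD")
        D = np.array(
            [
                [0, 2, 4, 4],
                [2, 0, 4, 4],
                [4, 4, 0, 2],
                [4, 4, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(ids, D, np.full((4, 4), 100)))
        assert tree.topology_splits() == frozenset({frozenset("AB")})

    def test_three_taxa_closed_form(self):
        ids = list("ABC")
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, D, np.full((3, 3), 10)))
        hub = next(n for n in tree.adj if not isinstance(n, str))
        assert tree.adj["A"][hub] == pytest.approx(1.0)  # (3+4-5)/2
        assert tree.adj["B"][hub] == pytest.approx(2.0)
        assert tree.adj["C"][hub] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_exhaustive_topology_recovery(self, n_leaves):
        leaves = [f"t{i}" for i in range(n_leaves)]
        rng = np.random.default_rng(n_leaves)
        for adj in enumerate_topologies(leaves):
            # randomise branch lengths to make the metric generic
            for a in adj:
                for b in adj[a]:
                    if str(a) < str(b):
                        ln = float(rng.uniform(0.2, 1.0))
                        adj[a][b] = ln
                        adj[b][a] = ln
            D = path_distance_matrix(adj, leaves)
            tree = nj_tree(DistanceMatrix(leaves, D, np.full(D.shape, 10)))
            assert tree.topology_splits() == splits_by_edge_deletion(adj, leaves)

    def test_random_16_leaf_recovery(self):
        rng = np.random.default_rng(99)
        leaves = [f"t{i:02d}" for i in range(16)]
        for _ in range(10):
            adj = random_binary_tree(leaves, rng)
            D = path_distance_matrix(adj, leaves)
            tree = nj_tree(DistanceMatrix(leaves, D, np.full(D.shape, 10)))
            assert tree.topology_splits() == splits_by_edge_deletion(adj, leaves)

    def test_agrees_with_skbio_on_generic_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        n = 10
        ids = [f"t{i}" for i in range(n)]
        A = rng.random((n, n))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        mine = nj_tree(DistanceMatrix(ids, D, np.full(D.shape, 10)))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        ref_splits = set()
        full = frozenset(ids)
        for node in ref.non_tips(include_self=False):
            s = frozenset(t.name for t in node.tips())
            if 2 <= len(s) <= n - 2:
                ref_splits.add(min(s, full - s, key=lambda x: (len(x), sorted(x))))
        assert mine.topology_splits() == frozenset(ref_splits)

    def test_nonsymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(DistanceMatrix(list("ABC"), D, np.full((3, 3), 5)))


class TestConsensusClades:
    def test_strongly_drifted_breeds_fully_monophyletic(self):
        cfg = CohortConfig(
            n_breeds=4, samples_per_breed=5, n_village=0, n_wolf=0,
            n_sites=5000, fst_range=(0.25, 0.3), with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=11)
        res = consensus_clades(cohort, n_replicates=20, seed=1)
        assert all(v == 1.0 for v in res.breed_monophyly.values())

    def test_admixed_breed_fails_monophyly(self):
        cfg = CohortConfig(
            n_breeds=4, samples_per_breed=5, n_village=0, n_wolf=0,
            n_sites=5000, fst_range=(0.25, 0.3), admixed_breeds=1,
            with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=12)
        res = consensus_clades(cohort, n_replicates=20, seed=2)
        assert res.breed_monophyly["ADMIX00"] < 0.65
        for b, v in res.breed_monophyly.items():
            if b != "ADMIX00":
                assert v == 1.0

    def test_single_replicate_support_binary(self):
        cfg = CohortConfig(
            n_breeds=3, samples_per_breed=3, n_village=0, n_wolf=0,
            n_sites=2000, with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=3)
        res = consensus_clades(cohort, n_replicates=1, seed=5)
        assert set(res.breed_monophyly.values()) <= {0.0, 1.0}
        for call in res.clades:
            assert call.support in (0.0, 1.0)

    def test_supports_invariant_to_sample_order(self):
        cfg = CohortConfig(
            n_breeds=3, samples_per_breed=4, n_village=0, n_wolf=0,
            n_sites=3000, with_quality_layers=False,
        )
        cohort, _ = generate_cohort(cfg, seed=8)
        res1 = consensus_clades(cohort, n_replicates=10, seed=9)
        perm = np.random.default_rng(0).permutation(cohort.n_samples)
        shuffled = cohort.subset(sample_idx=perm)
        res2 = consensus_clades(shuffled, n_replicates=10, seed=9)
        assert res1.breed_monophyly == res2.breed_monophyly


class TestHaplotypeSharing:
    @staticmethod
    def _meta():
        breed_of = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        clade_of = {"a1": "K1", "a2": "K1", "b1": "K1", "c1": "K2"}
        return breed_of, clade_of

    def test_no_segments_all_zero(self):
        breed_of, clade_of = self._meta()
        seg = pd.DataFrame(columns=["sample1", "sample2", "chrom", "start", "end", "lod"])
        summ = haplotype_sharing_summary(seg, breed_of, clade_of)
        assert all(v == 0 for v in summ.pair_totals.values())

    def test_pair_total_sums_qualifying_segments(self):
        breed_of, clade_of = self._meta()
        seg = pd.DataFrame(
            {
                "sample1": ["a1", "a1", "a1"],
                "sample2": ["a2", "a2", "a2"],
                "chrom": ["chr1"] * 3,
                "start": [0, 1_000_000, 2_000_000],
                "end": [300_000, 1_250_000, 2_100_000],
                "lod": [4.0, 4.0, 4.0],
            }
        )
        summ = haplotype_sharing_summary(seg, breed_of, clade_of)
        # 300 kb + 250 kb qualify; the 100-kb segment is below the cutoff
        assert summ.pair_totals[("a1", "a2")] == 550_000

    def test_low_lod_segment_excluded(self):
        breed_of, clade_of = self._meta()
        seg = pd.DataFrame(
            {
                "sample1": ["a1"], "sample2": ["a2"], "chrom": ["chr1"],
                "start": [0], "end": [250_000], "lod": [2.5],
            }
        )
        summ = haplotype_sharing_summary(seg, breed_of, clade_of)
        assert summ.pair_totals[("a1", "a2")] == 0

    def test_unknown_sample_rejected(self):
        breed_of, clade_of = self._meta()
        seg = pd.DataFrame(
            {
                "sample1": ["zz"], "sample2": ["a2"], "chrom": ["chr1"],
                "start": [0], "end": [300_000], "lod": [5.0],
            }
        )
        with pytest.raises(ValueError, match="unknown samples"):
            haplotype_sharing_summary(seg, breed_of, clade_of)

    def test_group_mean_ordering_with_nested_structure(self):
        breed_of, clade_of = self._meta()
        seg = pd.DataFrame(
            {
                "sample1": ["a1", "a1", "a1"],
                "sample2": ["a2", "b1", "c1"],
                "chrom": ["chr1"] * 3,
                "start": [0, 0, 0],
                "end": [2_000_000, 800_000, 300_000],
                "lod": [5.0, 5.0, 5.0],
            }
        )
        summ = haplotype_sharing_summary(seg, breed_of, clade_of)
        assert summ.within_breed_mean > summ.within_clade_mean > summ.between_clade_mean
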