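"""1-IBS distances, neighbor joining, resampled breed consensus, IBD sharing.

The cladistics path mirrors the study design: pairwise 1-IBS genomic
distances, neighbor-joining trees per replicate over random 10% site
subsamples, and breed-level majority consensus where a cluster of breeds
is called a clade when it appears in more than 65% of replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from canidkit.cohort import MISSING, CohortGenotypes

# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    n_sites: np.ndarray  # per-pair mutually non-missing site counts

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.values[i])
                fh.write(f"{sid[:10]:<10s} {row}\n")


def ibs_distance(
    cohort: CohortGenotypes, sample_mask: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise 1-IBS distance: sum |g_a - g_b| / (2 M) over shared sites.

    Equivalent to 1 - (IBS2 + 0.5 IBS1) / M on diploid dosages.
    """
    if sample_mask is None:
        sample_mask = np.ones(cohort.n_samples, dtype=bool)
    idx = np.flatnonzero(np.asarray(sample_mask))
    if len(idx) < 2:
        raise ValueError("need at least two samples for a distance matrix")
    G = cohort.dosage[idx].astype(np.float64)
    called = G != MISSING
    G = np.where(called, G, 0.0)
    n = len(idx)
    D = np.zeros((n, n))
    M = np.zeros((n, n), dtype=np.int64)
    for a in range(n):
        both = called[a] & called
        diff = np.abs(G[a][None, :] - G) * both
        M[a] = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[a] = np.where(M[a] > 0, diff.sum(axis=1) / (2.0 * M[a]), np.nan)
    if np.isnan(D).any():
        raise ValueError("some sample pair shares no called sites")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return DistanceMatrix([cohort.samples[i].id for i in idx], D, M)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class Tree:
    """Unrooted tree as an adjacency map; leaves are sample ids."""

    adj: dict[object, dict[object, float]]
    leaves: list[str]
    negative_clamped: int = 0

    def _split_at_edge(self, a, b) -> frozenset:
        """Leaves on the `a` side of edge (a, b)."""
        seen = {b, a}
        stack = [a]
        side = set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nb in self.adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(side)

    def bipartition_sides(self, include_trivial: bool = False) -> set[frozenset]:
        """All bipartition sides (both orientations) over internal edges."""
        out: set[frozenset] = set()
        done = set()
        for a in self.adj:
            for b in self.adj[a]:
                key = tuple(sorted([str(a), str(b)]))
                if key in done:
                    continue
                done.add(key)
                side = self._split_at_edge(a, b)
                other = frozenset(self.leaves) - side
                for s in (side, other):
                    if include_trivial or 2 <= len(s) <= len(self.leaves) - 2:
                        out.add(s)
        if include_trivial:
            for leaf in self.leaves:
                out.add(frozenset({leaf}))
        return out

    def has_cluster(self, leafset: frozenset) -> bool:
        """True if the leaf set hangs off one branch of the tree."""
        if len(leafset) in (1, len(self.leaves)):
            return True
        return leafset in self.bipartition_sides(include_trivial=True)

    def topology_splits(self) -> frozenset:
        """Canonical set of non-trivial splits for topology comparison."""
        full = frozenset(self.leaves)
        canon = set()
        for s in self.bipartition_sides():
            comp = full - s
            canon.add(min(s, comp, key=lambda x: (len(x), sorted(x))))
        return frozenset(canon)

    def newick(self) -> str:
        # root arbitrarily at the first internal node (or a leaf for tiny trees)
        root = next((n for n in self.adj if not isinstance(n, str)), self.leaves[0])

        def render(node, parent) -> str:
            children = [nb for nb in self.adj[node] if nb != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:{self.adj[node][c]:.6g}" for c in children
            )
            return f"({inner})"

        return render(root, None) + ";"


def nj_tree(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining, deterministic with lowest-index ties.

    Negative branch lengths are clamped to zero and counted.
    """
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    D = dist.values.astype(float).copy()
    nodes: list[object] = list(ids)
    adj: dict[object, dict[object, float]] = {x: {} for x in ids}
    clamped = 0
    next_internal = 0

    def connect(a, b, length):
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        adj.setdefault(a, {})[b] = length
        adj.setdefault(b, {})[a] = length

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # lowest flat index on ties
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        new = ("int", next_internal)
        next_internal += 1
        connect(nodes[i], new, li)
        connect(nodes[j], new, lj)
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = dnew[keep]
        D2[: m - 2, m - 2] = dnew[keep]
        D2[m - 2, m - 2] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D2

    # final three nodes: closed-form three-point branch lengths
    a, b, c = nodes
    hub = ("int", next_internal)
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    connect(a, hub, la)
    connect(b, hub, lb)
    connect(c, hub, lc)
    return Tree(adj, ids, clamped)


# ---------------------------------------------------------------------------
# resampled breed consensus


@dataclass
class CladeCall:
    breeds: frozenset
    support: float
    is_clade: bool  # support > the 65% rule


@dataclass
class ConsensusResult:
    clades: list[CladeCall]
    breed_monophyly: dict[str, float]
    consensus_clusters: list[CladeCall]  # compatible set used for the tree
    n_replicates: int


def _breed_clusters(tree: Tree, breed_of: dict[str, str]) -> set[frozenset]:
    """Bipartition sides that are unions of complete breeds, as breed sets."""
    members: dict[str, set[str]] = {}
    for sid, b in breed_of.items():
        members.setdefault(b, set()).add(sid)
    out: set[frozenset] = set()
    for side in tree.bipartition_sides(include_trivial=True):
        bs = {breed_of[s] for s in side}
        if all(members[b] <= side for b in bs):
            out.add(frozenset(bs))
    return out


def consensus_clades(
    cohort: CohortGenotypes,
    n_replicates: int = 100,
    snv_fraction: float = 0.10,
    support_cut: float = 0.65,
    seed: int = 0,
    sample_mask: np.ndarray | None = None,
    with_replacement: bool = False,
) -> ConsensusResult:
    """Replicated site-subsampled NJ trees and breed-cluster supports.

    Each replicate draws ``snv_fraction`` of the sites (without replacement
    by default; a bootstrap-with-replacement variant is available), builds
    a 1-IBS NJ tree, and records which breed clusters appear.  Clusters of
    two or more breeds with support above ``support_cut`` are clades.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    if sample_mask is None:
        sample_mask = np.array([s.breed_label is not None for s in cohort.samples])
    idx = np.flatnonzero(np.asarray(sample_mask))
    breed_of = {
        cohort.samples[i].id: (cohort.samples[i].breed_label or cohort.samples[i].id)
        for i in idx
    }
    breeds = sorted(set(breed_of.values()))
    n_take = max(1, int(round(snv_fraction * cohort.n_sites)))

    cluster_hits: dict[frozenset, int] = {}
    mono_hits = {b: 0 for b in breeds}
    for _ in range(n_replicates):
        for _attempt in range(2):
            if with_replacement:
                sites = rng.integers(0, cohort.n_sites, size=n_take)
            else:
                sites = rng.choice(cohort.n_sites, size=n_take, replace=False)
            sub = cohort.subset(idx, sites)
            if (sub.dosage.max(axis=0) != sub.dosage.min(axis=0)).any():
                break
        else:
            raise RuntimeError("replicate drew no polymorphic sites twice")
        tree = nj_tree(ibs_distance(sub))
        clusters = _breed_clusters(tree, breed_of)
        for c in clusters:
            if 2 <= len(c) < len(breeds):
                cluster_hits[c] = cluster_hits.get(c, 0) + 1
        for b in breeds:
            if frozenset({b}) in clusters:
                mono_hits[b] += 1

    mono = {b: mono_hits[b] / n_replicates for b in breeds}
    calls = [
        CladeCall(c, k / n_replicates, k / n_replicates > support_cut)
        for c, k in sorted(
            cluster_hits.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        )
    ]
    # extended majority rule: greedily keep mutually compatible clusters
    accepted: list[CladeCall] = []
    for call in calls:
        ok = all(
            call.breeds.isdisjoint(a.breeds)
            or call.breeds <= a.breeds
            or a.breeds <= call.breeds
            for a in accepted
        )
        if ok:
            accepted.append(call)
    return ConsensusResult(
        [c for c in calls if c.is_clade], mono, accepted, n_replicates
    )


# ---------------------------------------------------------------------------
# IBD haplotype sharing

LOD_MIN = 3.0
MIN_SEGMENT_BP = 250_000


@dataclass
class HaplotypeSharingSummary:
    pair_totals: dict[tuple[str, str], int]
    within_breed_mean: float
    within_clade_mean: float
    between_clade_mean: float
    background_p95: float
    significant_pairs: list[tuple[str, str]]


def haplotype_sharing_summary(
    segments: pd.DataFrame,
    breed_of: dict[str, str],
    clade_of: dict[str, str],
) -> HaplotypeSharingSummary:
    """Aggregate IBD segments into per-pair sharing and group means.

    Segments need columns sample1, sample2, start, end, lod; only segments
    with LOD > 3.0 and length >= 250 kb count.  The background is the
    between-clade distribution of pair totals and its 95th percentile is
    the significance threshold.
    """
    known = set(breed_of)
    for col in ("sample1", "sample2"):
        bad = set(segments[col]) - known
        if bad:
            raise ValueError(f"segments reference unknown samples: {sorted(bad)}")
    seg = segments[
        (segments["lod"] > LOD_MIN)
        & ((segments["end"] - segments["start"]) >= MIN_SEGMENT_BP)
    ]
    samples = sorted(known)
    pair_totals = {
        (a, b): 0 for i, a in enumerate(samples) for b in samples[i + 1 :]
    }
    for _, row in seg.iterrows():
        a, b = sorted((row["sample1"], row["sample2"]))
        pair_totals[(a, b)] += int(row["end"] - row["start"])

    within_breed, within_clade, between = [], [], []
    for (a, b), tot in pair_totals.items():
        if breed_of[a] == breed_of[b]:
            within_breed.append(tot)
        elif clade_of.get(a) is not None and clade_of.get(a) == clade_of.get(b):
            within_clade.append(tot)
        else:
            between.append(tot)

    p95 = float(np.percentile(between, 95)) if between else 0.0
    sig = [pair for pair, tot in pair_totals.items() if tot > p95]
    mean = lambda xs: float(np.mean(xs)) if xs else 0.0
    return HaplotypeSharingSummary(
        pair_totals, mean(within_breed), mean(within_clade), mean(between), p95, sig
    )
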