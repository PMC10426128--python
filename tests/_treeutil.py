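"""Independent tree helpers for oracle tests: random/exhaustive unrooted
binary topologies, additive distance matrices, and split extraction by
edge deletion (deliberately not sharing code with the package)."""

import itertools

import numpy as np


def random_binary_tree(leaves, rng, min_bl=0.1, max_bl=1.0):
    """Random unrooted binary tree as {node: {nbr: length}}; leaves are strings."""
    leaves = list(leaves)
    adj = {}
    nxt = [0]

    def connect(a, b, ln):
        adj.setdefault(a, {})[b] = ln
        adj.setdefault(b, {})[a] = ln

    def bl():
        return float(rng.uniform(min_bl, max_bl))

    connect(leaves[0], leaves[1], bl())
    for leaf in leaves[2:]:
        edges = []
        seen = set()
        for a in adj:
            for b in adj[a]:
                key = (min(str(a), str(b)), max(str(a), str(b)))
                if key not in seen:
                    seen.add(key)
                    edges.append((a, b))
        a, b = edges[int(rng.integers(0, len(edges)))]
        mid = ("x", nxt[0])
        nxt[0] += 1
        old = adj[a].pop(b)
        adj[b].pop(a)
        connect(a, mid, old * 0.5)
        connect(b, mid, old * 0.5)
        connect(leaf, mid, bl())
    return adj


def enumerate_topologies(leaves):
    """Yield every unrooted binary topology on the given leaves (adjacency,
    unit branch lengths).  3: 1 topology, 4: 3, 5: 15, 6: 105, 8: 10395."""
    leaves = list(leaves)

    def edges_of(adj):
        seen, out = set(), []
        for a in adj:
            for b in adj[a]:
                key = (min(str(a), str(b)), max(str(a), str(b)))
                if key not in seen:
                    seen.add(key)
                    out.append((a, b))
        return out

    def clone(adj):
        return {k: dict(v) for k, v in adj.items()}

    base = {leaves[0]: {("x", 0): 1.0},
            leaves[1]: {("x", 0): 1.0},
            leaves[2]: {("x", 0): 1.0},
            ("x", 0): {leaves[0]: 1.0, leaves[1]: 1.0, leaves[2]: 1.0}}
    trees = [base]
    counter = [1]
    for leaf in leaves[3:]:
        new_trees = []
        for adj in trees:
            for a, b in edges_of(adj):
                t = clone(adj)
                mid = ("x", counter[0])
                counter[0] += 1
                t[a].pop(b)
                t[b].pop(a)
                t.setdefault(mid, {})[a] = 1.0
                t[mid][b] = 1.0
                t[a][mid] = 1.0
                t[b][mid] = 1.0
                t[leaf] = {mid: 1.0}
                t[mid][leaf] = 1.0
                new_trees.append(t)
        trees = new_trees
    return trees


def path_distance_matrix(adj, leaves):
    """Additive matrix of path lengths between leaves (Dijkstra-free BFS
    accumulation works because the graph is a tree)."""
    n = len(leaves)
    D = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for j, dst in enumerate(leaves):
            D[i, j] = dist[dst]
    return D


def splits_by_edge_deletion(adj, leaves):
    """Canonical non-trivial splits: delete each internal edge, collect the
    smaller leaf side."""
    full = frozenset(leaves)
    out = set()
    seen = set()
    for a in adj:
        for b in adj[a]:
            key = (min(str(a), str(b)), max(str(a), str(b)))
            if key in seen:
                continue
            seen.add(key)
            side = set()
            stack, visited = [a], {a, b}
            while stack:
                u = stack.pop()
                if isinstance(u, str):
                    side.add(u)
                for v in adj[u]:
                    if v not in visited:
                        visited.add(v)
                        stack.append(v)
            s = frozenset(side)
            comp = full - s
            if 2 <= len(s) <= len(leaves) - 2:
                out.add(min(s, comp, key=lambda x: (len(x), sorted(x))))
    return frozenset(out)
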