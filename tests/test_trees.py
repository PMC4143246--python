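"""Neighbor joining and locus bootstrap: additive recovery, least-squares
oracle, determinism, Newick round trips."""

from itertools import combinations

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from polydonor.distance import DistanceMatrix
from polydonor.trees import (
    bootstrap_support,
    neighbor_joining,
    read_newick,
    tree_bipartitions,
    write_newick,
)


def dm(d, labels):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(labels=list(labels), d=d,
                          n_loci_used=np.ones_like(d, dtype=int))


# ---------------------------------------------------------------------------
# oracle helpers: random additive matrices and exhaustive topology search
# ---------------------------------------------------------------------------


def random_unrooted_topology(rng, labels):
    """Random unrooted binary tree as a dict node -> neighbours list; leaves
    are the labels, internal nodes are ints."""
    edges = []
    nxt = [0]

    def new_internal():
        nxt[0] += 1
        return nxt[0] - 1

    # start from a 3-star
    center = new_internal()
    edges = [(center, labels[0]), (center, labels[1]), (center, labels[2])]
    for leaf in labels[3:]:
        a, b = edges[rng.integers(len(edges))]
        edges.remove((a, b))
        mid = new_internal()
        edges += [(a, mid), (mid, b), (mid, leaf)]
    return edges


def all_topologies(labels):
    """Every unrooted binary topology over the labels (sequential insertion)."""
    topos = [[(0, labels[0]), (0, labels[1]), (0, labels[2])]]
    nxt = 1
    for leaf in labels[3:]:
        new_topos = []
        for edges in topos:
            for k in range(len(edges)):
                a, b = edges[k]
                mid = nxt
                new_edges = edges[:k] + edges[k + 1:] + [(a, mid), (mid, b), (mid, leaf)]
                new_topos.append(new_edges)
        nxt += 1
        topos = new_topos
    return topos


def edges_with_lengths_to_distances(edges, lengths, labels):
    """Path-metric matrix over leaves from an edge list."""
    adj = {}
    for (a, b), w in zip(edges, lengths):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    n = len(labels)
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    return D


def topology_bipartitions(edges, labels):
    """Bipartitions (frozensets of labels, side not containing labels[0])."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    label_set = frozenset(labels)
    out = set()
    for a, b in edges:
        if isinstance(a, str) or isinstance(b, str):
            continue  # pendant edge
        # leaves on b's side when edge (a, b) is removed
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                if isinstance(v, str):
                    side.add(v)
                else:
                    stack.append(v)
        side = frozenset(side)
        if labels[0] in side:
            side = label_set - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def least_squares_fit(edges, labels, D):
    """Ordinary least-squares branch lengths for a fixed topology; returns
    the residual sum of squares."""
    pairs = list(combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    adj = {}
    for k, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, k))
        adj.setdefault(b, []).append((a, k))

    def path_edges(src, dst):
        prev = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            if u == dst:
                break
            for v, k in adj[u]:
                if v not in prev:
                    prev[v] = (u, k)
                    stack.append(v)
        out = []
        u = dst
        while prev[u] is not None:
            u, k = prev[u]
            out.append(k)
        return out

    for r, (i, j) in enumerate(pairs):
        for k in path_edges(labels[i], labels[j]):
            A[r, k] = 1.0
    y = np.array([D[i, j] for i, j in pairs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = [[0, 3, 4], [3, 0, 5], [4, 5, 0]]
        tree = neighbor_joining(dm(d, ["a", "b", "c"]))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree: ((a:1,b:2):1,(c:3,d:4)) with internal edge 1
        labels = ["a", "b", "c", "d"]
        D = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ], dtype=float)
        D[2, 3] = D[3, 2] = 7.0
        tree = neighbor_joining(dm(D, labels))
        bps = tree_bipartitions(tree, labels)
        assert bps == {frozenset({"c", "d"})}
        # branch lengths: tip-to-tip path distances reproduce the matrix
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    ta = tree.find(a)
                    tb = tree.find(b)
                    assert ta.distance(tb) == pytest.approx(D[i, j])

    def test_fewer_than_three_labels_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm([[0, 1], [1, 0]], ["a", "b"]))

    def test_random_additive_matrices_recovered(self, rng):
        for n in (5, 8, 12):
            for _ in range(3):
                labels = [f"t{i:02d}" for i in range(n)]
                edges = random_unrooted_topology(rng, labels)
                lengths = rng.uniform(0.1, 1.0, size=len(edges))
                D = edges_with_lengths_to_distances(edges, lengths, labels)
                tree = neighbor_joining(dm(D, labels))
                assert tree_bipartitions(tree, labels) == topology_bipartitions(edges, labels)

    def test_matches_exhaustive_least_squares_search(self, rng):
        for n in (5, 6, 7):
            labels = [f"t{i}" for i in range(n)]
            edges = random_unrooted_topology(rng, labels)
            lengths = rng.uniform(0.2, 1.0, size=len(edges))
            D = edges_with_lengths_to_distances(edges, lengths, labels)
            best, best_sse = None, np.inf
            for cand in all_topologies(labels):
                sse = least_squares_fit(cand, labels, D)
                if sse < best_sse - 1e-12:
                    best, best_sse = cand, sse
            assert best_sse == pytest.approx(0.0, abs=1e-10)
            tree = neighbor_joining(dm(D, labels))
            assert tree_bipartitions(tree, labels) == topology_bipartitions(best, labels)

    def test_label_order_invariance(self, rng):
        n = 9
        labels = [f"t{i}" for i in range(n)]
        edges = random_unrooted_topology(rng, labels)
        lengths = rng.uniform(0.1, 1.0, size=len(edges))
        D = edges_with_lengths_to_distances(edges, lengths, labels)
        perm = rng.permutation(n)
        D2 = D[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        t1 = neighbor_joining(dm(D, labels))
        t2 = neighbor_joining(dm(D2, labels2))
        assert tree_bipartitions(t1, labels) == tree_bipartitions(t2, labels)

    def test_agrees_with_skbio_on_random_matrix(self, rng):
        n = 10
        labels = [f"t{i}" for i in range(n)]
        X = rng.uniform(0, 1, size=(n, 4))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        ours = neighbor_joining(dm(D, labels), clamp_negative=False)
        theirs = skbio_nj(SkbioDM(D, ids=labels))
        ours_bps = tree_bipartitions(ours, labels)
        theirs_bps = tree_bipartitions(theirs, labels)
        assert ours_bps == theirs_bps

    def test_negative_branch_clamping(self):
        # triangle-inequality-violating matrix: a's closed-form terminal
        # branch (d_ab + d_ac - d_bc) / 2 is negative
        labels = ["a", "b", "c"]
        D = np.array([
            [0.0, 0.1, 0.1],
            [0.1, 0.0, 0.9],
            [0.1, 0.9, 0.0],
        ])
        clamped = neighbor_joining(dm(D, labels), clamp_negative=True)
        assert min(t.length for t in clamped.traverse(include_self=False)) == 0.0
        free = neighbor_joining(dm(D, labels), clamp_negative=False)
        assert min(t.length for t in free.traverse(include_self=False)) < 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _spectra_private_alleles():
    """Two clans fixed for private alleles at every locus; the clan split is
    invariant under any locus resample."""
    spectra = {}
    for i in range(3):
        spectra[f"x{i}"] = {f"L{l}": {100 + 4 * l: 1.0} for l in range(6)}
    for i in range(3):
        spectra[f"y{i}"] = {f"L{l}": {300 + 4 * l: 1.0} for l in range(6)}
    # slight within-clan variation so the tree is not a star
    spectra["x1"]["L0"] = {100: 0.5, 104: 0.5}
    spectra["y1"]["L0"] = {300: 0.5, 304: 0.5}
    return spectra


class TestBootstrap:
    def test_invariant_clade_gets_full_support(self):
        spectra = _spectra_private_alleles()
        tree, supp = bootstrap_support(spectra, n_reps=50, seed=1)
        clan = frozenset({"y0", "y1", "y2"})
        assert supp[clan] == 100.0

    def test_seed_reproducibility(self):
        spectra = _spectra_private_alleles()
        _, s1 = bootstrap_support(spectra, n_reps=40, seed=7)
        _, s2 = bootstrap_support(spectra, n_reps=40, seed=7)
        assert s1 == s2
        _, s3 = bootstrap_support(spectra, n_reps=40, seed=8)
        assert s3.keys() == s1.keys()

    def test_locus_order_invariance(self):
        spectra = _spectra_private_alleles()
        shuffled = {
            lab: dict(reversed(list(per.items()))) for lab, per in spectra.items()
        }
        _, s1 = bootstrap_support(spectra, n_reps=30, seed=3)
        _, s2 = bootstrap_support(shuffled, n_reps=30, seed=3)
        assert s1 == s2

    def test_invalid_rep_count(self):
        with pytest.raises(ValueError):
            bootstrap_support(_spectra_private_alleles(), n_reps=0, seed=1)

    def test_interleaved_identical_groups_lack_certain_clades(self):
        spectra = {}
        for i in range(4):
            spectra[f"p{i}"] = {
                f"L{l}": {100 + 4 * ((i + l) % 4): 1.0} for l in range(8)
            }
        _, supp = bootstrap_support(spectra, n_reps=60, seed=5)
        assert all(v <= 100.0 for v in supp.values())


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


class TestNewick:
    def test_round_trip_with_supports(self, tmp_path, rng):
        spectra = _spectra_private_alleles()
        tree, supp = bootstrap_support(spectra, n_reps=20, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        labels = sorted(spectra)
        assert tree_bipartitions(back, labels) == tree_bipartitions(tree, labels)
        # branch lengths and internal support labels survive
        for tip in tree.tips():
            assert back.find(tip.name).length == pytest.approx(tip.length, abs=1e-9)
        internal_names = {
            n.name for n in back.non_tips(include_self=False) if n.name
        }
        assert internal_names == {
            n.name for n in tree.non_tips(include_self=False) if n.name
        }

    def test_zero_length_branch_serialised(self, tmp_path):
        d = [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        tree = neighbor_joining(dm(d, ["a", "b", "c"]))
        path = tmp_path / "z.nwk"
        write_newick(tree, path)
        text = path.read_text()
        assert ":0.0" in text or ":0;" in text or ":0," in text
        back = read_newick(path)
        assert {t.name for t in back.tips()} == {"a", "b", "c"}
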