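"""Neighbor-joining trees with locus-bootstrap support.

Standard NJ agglomeration (Saitou-Nei Q criterion with Studier-Keppler
distance updates), which recovers additive distance matrices exactly.  Ties
in Q are broken by the lexicographically smallest label pair (a cluster is
labelled by the smallest leaf label it contains), so the topology is
deterministic and independent of input label order.  Negative branch
lengths are clamped to zero by default (display convention; the topology is
unaffected).

Bootstrap support resamples loci (not accessions) with replacement,
recomputes DA and NJ per replicate, and reports for each internal edge of
the original tree the percentage of replicate trees containing the same
bipartition of the label set.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

from .distance import (
    DistanceMatrix,
    SpectraByLocus,
    _da_from_arrays,
    _locus_arrays,
)

Bipartition = frozenset


def _pick_pair(Q: np.ndarray, labs: Sequence[str]) -> tuple[int, int]:
    """Indices (i, j), i < j, of the minimal Q entry; exact ties between
    distinct pairs resolved by the lexicographically smallest (sorted) label
    pair.  Q need not be exactly symmetric (float summation order); the two
    mirror entries of one pair identify the same join either way."""
    m = Q.shape[0]
    flat = int(np.argmin(Q))
    qmin = Q.flat[flat]
    if np.count_nonzero(Q == qmin) <= 2:
        i, j = divmod(flat, m)
        return (i, j) if i < j else (j, i)
    cand = np.argwhere(Q == qmin)
    best: Optional[tuple[tuple[str, str], int, int]] = None
    for i, j in cand:
        if i >= j:
            continue
        key = tuple(sorted((labs[i], labs[j])))
        if best is None or key < best[0]:
            best = (key, int(i), int(j))
    assert best is not None
    return best[1], best[2]


def _nj_core(
    d: np.ndarray,
    labels: Sequence[str],
    clamp_negative: bool = True,
    build_tree: bool = True,
):
    """Run NJ; returns (root TreeNode or None, merges).

    ``merges`` is a list of (leafset, node) for every internal cluster
    created, where leafset is the frozenset of original leaf indices below
    it; these are exactly the internal-edge bipartitions of the unrooted
    tree.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    # branch lengths are only needed when a tree is built; the bipartition-only
    # path (bootstrap replicates) runs in single precision for speed
    dtype = np.float64 if build_tree else np.float32
    D = np.array(d, dtype=dtype, copy=True)
    Q = np.empty((n, n), dtype=dtype)
    B = np.empty((n, n), dtype=dtype)
    labs = list(labels)  # tie-break label of each active cluster
    nodes: list[Optional[TreeNode]] = [
        TreeNode(name=lab) if build_tree else None for lab in labels
    ]
    leafsets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges: list[tuple[frozenset[int], Optional[TreeNode]]] = []
    m = n
    while m > 3:
        Dm = D[:m, :m]
        Qm, Bm = Q[:m, :m], B[:m, :m]
        R = Dm.sum(axis=1)
        np.multiply(Dm, m - 2, out=Qm)
        Qm -= R[:, None]
        Qm -= R[None, :]
        # exact symmetry despite float summation order
        np.minimum(Qm, Qm.T, out=Bm)
        np.fill_diagonal(Bm, np.inf)
        i, j = _pick_pair(Bm, labs[:m])
        dij = Dm[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (m - 2))
        lj = dij - li
        if clamp_negative:
            li, lj = max(li, 0.0), max(lj, 0.0)
        newd = 0.5 * (Dm[i, :] + Dm[j, :] - dij)
        node = None
        if build_tree:
            ci, cj = nodes[i], nodes[j]
            ci.length, cj.length = float(li), float(lj)
            node = TreeNode(children=[ci, cj])
        leafset = leafsets[i] | leafsets[j]
        merges.append((leafset, node))
        # replace cluster i with the merged cluster
        D[i, :m] = newd
        D[:m, i] = newd
        D[i, i] = 0.0
        labs[i] = min(labs[i], labs[j])
        nodes[i] = node
        leafsets[i] = leafset
        # move last active cluster into slot j
        last = m - 1
        if j != last:
            D[j, :m] = D[last, :m]
            D[:m, j] = D[:m, last]
            D[j, j] = 0.0
            labs[j] = labs[last]
            nodes[j] = nodes[last]
            leafsets[j] = leafsets[last]
        m -= 1

    root = None
    if build_tree:
        Dm = D[:3, :3]
        lengths = [
            0.5 * (Dm[0, 1] + Dm[0, 2] - Dm[1, 2]),
            0.5 * (Dm[0, 1] + Dm[1, 2] - Dm[0, 2]),
            0.5 * (Dm[0, 2] + Dm[1, 2] - Dm[0, 1]),
        ]
        children = []
        for k in range(3):
            lk = max(lengths[k], 0.0) if clamp_negative else lengths[k]
            nodes[k].length = float(lk)
            children.append(nodes[k])
        root = TreeNode(children=children)
    return root, merges


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = True
) -> TreeNode:
    """NJ tree for a labelled distance matrix (unrooted; represented with a
    trifurcating root)."""
    root, _ = _nj_core(dm.d, dm.labels, clamp_negative=clamp_negative)
    return root


def _normalize(leafset: frozenset[int], n: int) -> frozenset[int]:
    """Canonical side of a bipartition: the side not containing index 0."""
    if 0 in leafset:
        return frozenset(range(n)) - leafset
    return leafset


def nj_bipartitions(
    d: np.ndarray, labels: Sequence[str], clamp_negative: bool = True
) -> set[frozenset[int]]:
    """Non-trivial bipartitions (as canonical index sets) of the NJ tree,
    without building tree objects (fast path for bootstrapping)."""
    n = len(labels)
    _, merges = _nj_core(d, labels, clamp_negative=clamp_negative, build_tree=False)
    return {
        _normalize(ls, n)
        for ls, _ in merges
        if 2 <= len(ls) <= n - 2
    }


def tree_bipartitions(tree: TreeNode, labels: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree as label sets,
    normalised to the side not containing the first label."""
    n = len(labels)
    all_labels = frozenset(labels)
    first = labels[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if first in side:
            side = all_labels - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def bootstrap_support(
    spectra_by_label: Mapping[str, SpectraByLocus],
    n_reps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    clamp_negative: bool = True,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree over DA distances with locus-bootstrap support.

    Loci are resampled with replacement ``n_reps`` times; each replicate's
    DA matrix and NJ tree are recomputed and bipartition frequencies
    tallied.  Supports (percent) are attached to the internal nodes of the
    original tree via ``node.bootstrap`` and as node names, and returned as a
    map from bipartition (label frozenset, normalised to exclude the first
    sorted label) to percent.  Reproducible for a fixed seed; loci are used
    in sorted order so the result is invariant to input ordering.  Replicate
    pairs left with no shared loci are set to the maximal distance 1.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels, loci, P, present = _locus_arrays(spectra_by_label)
    L = len(loci)
    if L < 2:
        raise ValueError("locus bootstrap requires at least 2 loci")
    d0, _ = _da_from_arrays(P, present)
    root, merges = _nj_core(d0, labels, clamp_negative=clamp_negative)
    n = len(labels)
    counts: dict[frozenset[int], int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        w = np.bincount(idx, minlength=L).astype(float)
        d, _ = _da_from_arrays(P, present, weights=w)
        for bp in nj_bipartitions(d, labels, clamp_negative=clamp_negative):
            counts[bp] = counts.get(bp, 0) + 1

    support: dict[frozenset[str], float] = {}
    for leafset, node in merges:
        side = _normalize(leafset, n)
        if not (2 <= len(side) <= n - 2) or node is None:
            continue
        pct = 100.0 * counts.get(side, 0) / n_reps
        node.bootstrap = pct
        node.name = f"{pct:.1f}"
        support[frozenset(labels[i] for i in side)] = pct
    return root, support


def write_newick(tree: TreeNode, path) -> None:
    """Serialise with branch lengths and support values as internal-node
    labels; zero-length branches are written explicitly."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
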