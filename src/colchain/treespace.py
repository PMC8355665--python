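"""Tree-space congruence and visualisation utilities.

Congruence between a collagen-derived tree and a reference genomic tree is
measured on shared leaf sets, via bipartition comparison (node congruence)
and the quartet distance (number of 4-leaf subsets whose induced topologies
differ).  A sample of trees is embedded for visualisation by computing the
pairwise quartet distance matrix, making it Euclidean with Cailliez's
additive correction, and projecting with classical multidimensional scaling
(eigendecomposition of the double-centred matrix) or nonmetric MDS (SMACOF
with an isotonic fit of disparities, reporting Kruskal stress-1).

Trees are :class:`dendropy.Tree` objects; quartet topologies are derived
from the four-point condition on unit-branch-length path distances, which
handles polytomies (a star quartet is *unresolved*) and is insensitive to
rooting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)


class TreeSpaceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree I/O and pruning

def read_trees(path, schema: str = "newick") -> list[dendropy.Tree]:
    """Read a tree sample (newick or nexus) into one shared taxon namespace."""
    tns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList.get(path=str(path), schema=schema, taxon_namespace=tns)
    return list(trees)


def parse_tree(newick: str, tns: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns or dendropy.TaxonNamespace()
    )


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _common_namespace(trees: list[dendropy.Tree]) -> list[dendropy.Tree]:
    """Clone trees into one shared taxon namespace (required by dendropy ops)."""
    tns = dendropy.TaxonNamespace()
    out = []
    for t in trees:
        out.append(
            dendropy.Tree.get(
                data=t.as_string(schema="newick"), schema="newick", taxon_namespace=tns
            )
        )
    return out


def prune_to_common(trees: list[dendropy.Tree]) -> list[dendropy.Tree]:
    """Prune every tree to the leaf set shared by all trees.

    Degree-2 nodes created by pruning are suppressed and branch lengths along
    the suppressed path are summed (dendropy semantics).
    """
    if len(trees) < 2:
        raise TreeSpaceError("need at least two trees to prune to a common leaf set")
    shared = set.intersection(*(leaf_labels(t) for t in trees))
    if not shared:
        raise TreeSpaceError("trees share no taxa")
    out = []
    for t in _common_namespace(trees):
        pruned = t.clone(depth=1)
        pruned.retain_taxa_with_labels(sorted(shared))
        out.append(pruned)
    return out


# ---------------------------------------------------------------------------
# bipartition congruence

def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Unrooted non-trivial bipartitions as frozensets of leaf-label sets."""
    labels = frozenset(leaf_labels(tree))
    out = set()
    tree.encode_bipartitions()
    for bip in tree.bipartition_encoding:
        side = frozenset(
            taxon.label
            for taxon in tree.taxon_namespace.bitmask_taxa_list(bip.leafset_bitmask)
        )
        if 1 < len(side) < len(labels) - 1:
            out.add(frozenset({side, labels - side}))
    return out


def _clades(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Rooted internal clades (excluding leaves and the root)."""
    labels = leaf_labels(tree)
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < len(labels):
            out.add(clade)
    return out


def congruence(
    tree_a: dendropy.Tree, tree_b: dendropy.Tree, rooted: bool = False
) -> dict:
    """Count shared and incongruent node positions between two trees.

    In unrooted mode (default) node positions are non-trivial leaf
    bipartitions; in rooted mode they are internal clades.  Because the two
    trees may resolve different numbers of nodes, counts are reported in
    both directions: ``a_in_b`` uses tree A's nodes as the denominator,
    ``b_in_a`` tree B's.
    """
    if leaf_labels(tree_a) != leaf_labels(tree_b):
        raise TreeSpaceError("leaf sets differ; prune to a common set first")
    if rooted:
        set_a, set_b = _clades(tree_a), _clades(tree_b)
    else:
        ta, tb = _common_namespace([tree_a, tree_b])
        set_a, set_b = _nontrivial_bipartitions(ta), _nontrivial_bipartitions(tb)
    shared = set_a & set_b
    result = {"shared_nodes": len(shared)}
    for key, ref in (("a_in_b", set_a), ("b_in_a", set_b)):
        incongruent = len(ref) - len(shared)
        result[key] = {
            "total_nodes": len(ref),
            "incongruent_nodes": incongruent,
            "fraction_congruent": len(shared) / len(ref) if ref else 1.0,
        }
    return result


# ---------------------------------------------------------------------------
# quartet distances

def _topological_leaf_distances(tree: dendropy.Tree, order: list[str]) -> np.ndarray:
    """Pairwise leaf path lengths counting every edge as 1."""
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for nd in nodes:
        for ch in nd.child_nodes():
            i, j = index[id(nd)], index[id(ch)]
            adj[i].append(j)
            adj[j].append(i)
    leaf_idx = {}
    for lf in tree.leaf_node_iter():
        leaf_idx[lf.taxon.label] = index[id(lf)]
    n = len(order)
    D = np.zeros((n, n), dtype=np.int32)
    for a, label in enumerate(order):
        start = leaf_idx[label]
        dist = np.full(len(nodes), -1, dtype=np.int32)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            queue = nxt
        for b, other in enumerate(order):
            D[a, b] = dist[leaf_idx[other]]
    return D


def _quartet_index_arrays(n: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)


def quartet_labels(tree: dendropy.Tree, order: list[str]) -> np.ndarray:
    """Induced topology label for every 4-leaf subset.

    Labels 0/1/2 encode the pairing with the smallest path-length sum
    (``ij|kl``, ``ik|jl``, ``il|jk`` for indices i<j<k<l); 3 marks an
    unresolved (star) quartet.  By the four-point condition the smallest of
    the three sums identifies the induced topology; a tie of all three
    occurs exactly at a polytomy.
    """
    D = _topological_leaf_distances(tree, order)
    q = _quartet_index_arrays(len(order))
    i, j, k, l = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    sums = np.stack([D[i, j] + D[k, l], D[i, k] + D[j, l], D[i, l] + D[j, k]], axis=1)
    label = np.argmin(sums, axis=1).astype(np.int8)
    smallest = np.take_along_axis(sums, label[:, None].astype(np.int64), axis=1)[:, 0]
    ties = (sums == smallest[:, None]).sum(axis=1)
    label[ties == 3] = 3
    return label


def quartet_distance(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    unresolved_policy: str = "differ",
) -> int:
    """Number of 4-leaf subsets whose induced topologies differ.

    ``unresolved_policy='differ'`` (default) counts a quartet resolved in one
    tree but unresolved in the other as different; ``'ignore'`` skips any
    quartet unresolved in either tree.
    """
    labels_a = set(leaf_labels(tree_a))
    if labels_a != leaf_labels(tree_b):
        raise TreeSpaceError("leaf sets differ; prune to a common set first")
    if len(labels_a) < 4:
        raise TreeSpaceError("quartet distance needs at least 4 shared leaves")
    order = sorted(labels_a)
    la = quartet_labels(tree_a, order)
    lb = quartet_labels(tree_b, order)
    return _label_distance(la, lb, unresolved_policy)


def _label_distance(la: np.ndarray, lb: np.ndarray, unresolved_policy: str) -> int:
    if unresolved_policy == "differ":
        return int(np.count_nonzero(la != lb))
    if unresolved_policy == "ignore":
        keep = (la != 3) & (lb != 3)
        return int(np.count_nonzero(la[keep] != lb[keep]))
    raise ValueError(f"unknown unresolved_policy {unresolved_policy!r}")


# ---------------------------------------------------------------------------
# distance matrices and embeddings

@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with Euclidean-embeddability status."""

    labels: list[str]
    values: np.ndarray
    is_euclidean: str = "unknown"  # yes | no | unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise TreeSpaceError("matrix shape does not match label count")
        if not np.array_equal(self.values, self.values.T):
            raise TreeSpaceError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise TreeSpaceError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise TreeSpaceError("distance matrix entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class Embedding:
    """Low-dimensional configuration of a tree (or taxon) distance matrix."""

    coordinates: np.ndarray
    method: str  # cmds | nmds
    labels: list[str]
    stress: float | None = None
    eigenvalues: np.ndarray | None = None
    variance_explained: np.ndarray | None = None
    stress_trace: list[float] = field(default_factory=list)
    converged: bool = True


def pairwise_quartet_matrix(
    trees: list[dendropy.Tree],
    labels: list[str] | None = None,
    unresolved_policy: str = "differ",
) -> tuple[DistanceMatrix, np.ndarray]:
    """Quartet distances between every pair of trees in a sample.

    Returns the distance matrix and, for duplicate-density shading, a vector
    giving for each tree the number of trees in the sample (itself included)
    at quartet distance zero from it.
    """
    if len(trees) < 2:
        raise TreeSpaceError("need at least two trees")
    shared = set.intersection(*(leaf_labels(t) for t in trees))
    if len(shared) < 4:
        raise TreeSpaceError("trees share fewer than 4 leaves")
    if any(leaf_labels(t) != shared for t in trees):
        raise TreeSpaceError("leaf sets differ; prune to a common set first")
    order = sorted(shared)
    label_arrays = [quartet_labels(t, order) for t in trees]
    m = len(trees)
    values = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            d = _label_distance(label_arrays[a], label_arrays[b], unresolved_policy)
            values[a, b] = values[b, a] = d
    duplicates = (values == 0).sum(axis=1).astype(int)
    names = labels if labels is not None else [f"tree_{i}" for i in range(m)]
    return DistanceMatrix(labels=list(names), values=values), duplicates


def mean_distance_to_reference(matrix: DistanceMatrix, reference_label: str,
                               group: list[str] | None = None) -> float:
    """Mean distance from a (sub)sample of trees to one designated tree."""
    ref = matrix.labels.index(reference_label)
    rows = [i for i, lab in enumerate(matrix.labels)
            if i != ref and (group is None or lab in group)]
    if not rows:
        raise TreeSpaceError("no trees in the requested group")
    return float(matrix.values[rows, ref].mean())


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.ones((n, n)) / n


def _gram_from_distances(values: np.ndarray) -> np.ndarray:
    J = _centering(values.shape[0])
    return -0.5 * J @ (values**2) @ J


def is_euclidean(values: np.ndarray, tol: float = 1e-8) -> bool:
    """Whether the dissimilarities embed exactly in Euclidean space."""
    eig = np.linalg.eigvalsh(_gram_from_distances(values))
    return bool(eig.min() >= -tol * max(1.0, eig.max()))


def cailliez(D: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant making the dissimilarities Euclidean.

    Adding ``c`` to every off-diagonal entry must make the double-centred
    Gram matrix positive semi-definite.  The minimal such ``c`` is the
    largest real eigenvalue of the standard 2n×2n companion linearisation of
    the quadratic eigenproblem in ``c``; ``c = 0`` when the input is already
    Euclidean.
    """
    V = D.values
    n = D.n
    if is_euclidean(V):
        out = DistanceMatrix(labels=list(D.labels), values=V.copy())
        out.is_euclidean = "yes"
        return out, 0.0
    J = _centering(n)
    B2 = -0.5 * J @ (V**2) @ J
    B1 = -0.5 * J @ V @ J
    companion = np.block(
        [[np.zeros((n, n)), np.eye(n)], [-2.0 * B2, -4.0 * B1]]
    )
    eigvals = np.linalg.eigvals(companion)
    c = float(max(eigvals.real))
    c = max(c, 0.0)
    corrected = V + c * (1 - np.eye(n))
    if not is_euclidean(corrected, tol=1e-6):
        # guard against round-off right at the PSD boundary
        corrected = V + (c + 1e-9 * max(1.0, c)) * (1 - np.eye(n))
    out = DistanceMatrix(labels=list(D.labels), values=corrected)
    out.is_euclidean = "yes"
    return out, c


def classical_mds(D: DistanceMatrix, k: int = 2) -> Embedding:
    """Classical (metric) MDS by eigendecomposition of the Gram matrix.

    Coordinates are the top-``k`` eigenvector axes scaled by the square
    roots of their eigenvalues; ``variance_explained`` is each eigenvalue
    over the sum of positive eigenvalues.  Apply :func:`cailliez` first if
    the matrix is not Euclidean.
    """
    B = _gram_from_distances(D.values)
    eigval, eigvec = np.linalg.eigh(B)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    tol = 1e-9 * max(1.0, abs(eigval[0]))
    n_pos = int((eigval > tol).sum())
    if k > n_pos:
        raise TreeSpaceError(
            f"requested {k} axes but only {n_pos} positive eigenvalues"
        )
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_sum = eigval[eigval > tol].sum()
    return Embedding(
        coordinates=coords,
        method="cmds",
        labels=list(D.labels),
        eigenvalues=eigval,
        variance_explained=eigval[:k] / pos_sum,
    )


def _stress1(dhat: np.ndarray, dist: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> Embedding:
    """Nonmetric MDS by SMACOF with isotonic disparities.

    Minimises Kruskal stress-1 over configurations in ``k`` dimensions; the
    disparities are a monotone (isotonic) transform of the input
    dissimilarity ranks.  The first start is the classical-MDS
    configuration; the remaining ``restarts - 1`` are seeded random starts.
    Returns the best configuration, its final stress in ``[0, 1]`` and the
    per-iteration stress trace (non-increasing over accepted iterations).
    """
    n = D.n
    iu = np.triu_indices(n, 1)
    diss = D.values[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    try:
        cm, _ = cailliez(D)
        starts.append(classical_mds(cm, k).coordinates)
    except TreeSpaceError:
        pass
    scale = diss.max() if diss.max() > 0 else 1.0
    while len(starts) < max(1, restarts):
        starts.append(rng.normal(scale=scale / 2, size=(n, k)))

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    best: Embedding | None = None
    for X0 in starts:
        X = X0.copy()
        trace: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dist_mat = np.sqrt((diff**2).sum(-1))
            dist = dist_mat[iu]
            dhat = np.empty_like(dist)
            dhat[order] = iso.fit_transform(np.arange(len(order)), dist[order])
            stress = _stress1(dhat, dist)
            trace.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform
            W = np.zeros((n, n))
            W[iu] = np.where(dist > 0, dhat / np.maximum(dist, 1e-12), 0.0)
            W = W + W.T
            B = -W
            np.fill_diagonal(B, W.sum(axis=1))
            X = (B @ X) / n
        cand = Embedding(
            coordinates=X,
            method="nmds",
            labels=list(D.labels),
            stress=trace[-1],
            stress_trace=trace,
            converged=converged,
        )
        if best is None or cand.stress < best.stress:
            best = cand
    if not best.converged:
        logger.warning("NMDS did not converge within %d iterations", max_iter)
    return best
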