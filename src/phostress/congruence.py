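"""Tree-distance machinery: patristic matrices, Robinson–Foulds, congruence.

An auxiliary metabolic gene acquired vertically should produce a gene tree
whose leaf–leaf distances track the core-genome tree; horizontal transfer
between phages erodes that relationship.  This module quantifies it three
ways:

* patristic distance matrices (sum of branch lengths on the leaf–leaf path);
* unweighted Robinson–Foulds distance (symmetric difference of non-trivial
  bipartitions of the unrooted trees) and its weighted counterpart (L1
  difference of split lengths over all splits, an absent split contributing
  its full length — the branch-score style weighted RF);
* a congruence test: Pearson correlation between the upper-triangle
  patristic vectors of the two trees over their shared leaves, with the
  plain regression p-value, optionally backed by a Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, InsufficientDataError, UnknownGeneError
from .formats import write_newick


@dataclass
class DistanceMatrix:
    """Symmetric leaf-by-leaf distance matrix with an ordered label list."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T) or (np.diag(v) != 0).any() or (v < 0).any():
            raise ValueError("distance matrix must be symmetric, zero-diagonal, >= 0")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def restrict(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class RFResult:
    unweighted: int
    weighted: float
    normalized: float
    shared_splits: int


@dataclass
class CongruenceResult:
    n_pairs: int
    pearson_r: float | None
    p_value: float | None
    slope: float | None
    intercept: float | None
    degenerate: bool = False
    permutation_p: float | None = None


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def patristic_matrix(
    tree: dendropy.Tree,
    leaf_subset: list[str] | None = None,
    *,
    metric: str = "patristic",
) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree.

    ``metric="patristic"`` sums branch lengths along the unique path;
    ``metric="nodal"`` counts edges instead.  ``leaf_subset`` restricts (and
    orders) the output; unknown labels raise.
    """
    labels = leaf_labels(tree)
    if leaf_subset is not None:
        missing = set(leaf_subset) - set(labels)
        if missing:
            raise UnknownGeneError(f"labels not in tree: {sorted(missing)}")
        labels = list(leaf_subset)
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 leaves for a distance matrix")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "patristic":
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            else:
                d = pdm.path_edge_count(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels, out)


def _splits(tree: dendropy.Tree) -> tuple[dict[int, float], set[int], int]:
    """(split -> length) over all splits, the non-trivial split set, and n."""
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True)
    lengths: dict[int, float] = {}
    nontrivial: set[int] = set()
    n_leaves = len(tree.taxon_namespace)
    full = tree.taxon_namespace.all_taxa_bitmask()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None or edge.head_node is tree.seed_node:
            continue
        mask = edge.bipartition.split_bitmask
        if mask == 0 or mask == full:
            continue
        lengths[mask] = lengths.get(mask, 0.0) + (edge.length or 0.0)
        size = bin(mask).count("1")
        if 1 < size < n_leaves - 1:
            nontrivial.add(mask)
    return lengths, nontrivial, n_leaves


def _common_namespace(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[dendropy.Tree, dendropy.Tree, list[str]]:
    shared = sorted(set(leaf_labels(t1)) & set(leaf_labels(t2)))
    if len(shared) < 4:
        raise InsufficientDataError(
            f"only {len(shared)} shared leaves; need >= 4 for tree comparison"
        )
    tns = dendropy.TaxonNamespace()
    out = []
    for t in (t1, t2):
        c = dendropy.Tree.get(
            data=write_newick(t),
            schema="newick",
            taxon_namespace=tns,
            preserve_underscores=True,
        )
        c = c.extract_tree_with_taxa_labels(shared)
        c.migrate_taxon_namespace(tns)
        for e in c.preorder_edge_iter():
            if e.length is None:
                e.length = 0.0
        out.append(c)
    return out[0], out[1], shared


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> RFResult:
    """Unweighted and weighted RF distance between two trees.

    Both trees are first restricted to their shared leaf set (>= 4 leaves
    required) and treated as unrooted.  ``normalized`` divides the unweighted
    distance by the total number of non-trivial splits in the two trees
    (2(n−3) for a pair of binary trees).
    """
    a, b, _ = _common_namespace(t1, t2)
    len1, nt1, _ = _splits(a)
    len2, nt2, _ = _splits(b)
    unweighted = len(nt1 ^ nt2)
    weighted = 0.0
    for mask in set(len1) | set(len2):
        weighted += abs(len1.get(mask, 0.0) - len2.get(mask, 0.0))
    denom = len(nt1) + len(nt2)
    return RFResult(
        unweighted=unweighted,
        weighted=weighted,
        normalized=(unweighted / denom) if denom else 0.0,
        shared_splits=len(nt1 & nt2),
    )


def congruence_test(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    leaf_subset: list[str] | None = None,
    permutations: int = 0,
    *,
    seed: int | None = None,
    metric: str = "patristic",
) -> CongruenceResult:
    """Correlate leaf–leaf distances of two trees over their shared leaves.

    Pearson r between the upper-triangle patristic vectors, with the plain
    regression p-value treating pairs as independent.  ``permutations > 0``
    adds a Mantel permutation p (joint row/column label permutations of the
    second matrix), the statistically defensible alternative when pairwise
    distances are autocorrelated.
    """
    shared = sorted(set(leaf_labels(t1)) & set(leaf_labels(t2)))
    if leaf_subset is not None:
        shared = [l for l in leaf_subset if l in shared]
    if len(shared) < 4:
        raise InsufficientDataError("need >= 4 shared leaves for a congruence test")
    m1 = patristic_matrix(t1, shared, metric=metric)
    m2 = patristic_matrix(t2, shared, metric=metric)
    x, y = m1.upper_triangle(), m2.upper_triangle()
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CongruenceResult(n, None, None, None, None, degenerate=True)
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    result = CongruenceResult(n, float(r), float(p), float(slope), float(intercept))
    if permutations > 0:
        rng = np.random.default_rng(seed)
        k = len(shared)
        iu = np.triu_indices(k, 1)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(k)
            yp = m2.values[np.ix_(perm, perm)][iu]
            rp = np.corrcoef(x, yp)[0, 1]
            if abs(rp) >= abs(r) - 1e-12:
                hits += 1
        result.permutation_p = (hits + 1) / (permutations + 1)
    return result
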