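"""Distance trees on core-domain rows: NJ, bootstrap, extended consensus.

Distances are normalised BLOSUM62 score distances over co-occupied core
columns: ``d = 1 - (S - S_rand) / (S_max - S_rand)`` clipped at zero,
where ``S_rand`` is the expected random score under the background
frequencies and ``S_max`` the average of the two self-scores.  Trees are
built by neighbor joining with deterministic tie-breaking; bootstrap
replicates resample core columns (columns more than half gapped are
excluded from the resampling pool); and replicate trees are summarised by
the extended majority rule: every bipartition above 50 % support enters
the consensus, then the remaining bipartitions are admitted greedily in
frequency order whenever compatible with everything already accepted.
"""
from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .alphabet import AA_INDEX, BACKGROUND, GAP, blosum62_matrix
from .core import CoreAlignment


def score_distance(a: str, b: str, matrix: np.ndarray | None = None) -> float:
    """Normalised substitution-score distance between two aligned rows."""
    if len(a) != len(b):
        raise ValueError("rows differ in core column count")
    B = blosum62_matrix() if matrix is None else matrix
    s_rand_col = float(BACKGROUND @ B @ BACKGROUND)
    S = S_max = S_rand = 0.0
    shared = 0
    for x, y in zip(a, b):
        i, j = AA_INDEX.get(x), AA_INDEX.get(y)
        if i is None or j is None:
            continue
        shared += 1
        S += B[i, j]
        S_max += 0.5 * (B[i, i] + B[j, j])
        S_rand += s_rand_col
    if shared == 0:
        raise ValueError("no co-occupied columns")
    if S_max - S_rand <= 0:
        return 0.0
    return max(0.0, 1.0 - (S - S_rand) / (S_max - S_rand))


def distance_matrix(
    alignment: CoreAlignment, matrix: np.ndarray | None = None
) -> np.ndarray:
    n = len(alignment)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = score_distance(
                alignment.rows[i], alignment.rows[j], matrix
            )
    return D


def neighbor_joining(
    D: np.ndarray, labels: list[str] | None = None
) -> dendropy.Tree:
    """Standard neighbor joining; deterministic, negative lengths clamped.

    Requires a symmetric zero-diagonal matrix with non-negative entries
    and at least three taxa.  Ties in the Q criterion break toward the
    lexicographically smallest index pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("need at least three taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("negative distances")
    labels = labels or [f"t{i}" for i in range(n)]
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, vi)
        nodes[j].edge.length = max(0.0, vj)
        # distances from the new node
        newd = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newd
        D[active, i] = newd
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for idx, v in ((i, vi), (j, vj), (k, vk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, v)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path distances in ``labels`` order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return out


def bootstrap_trees(
    alignment: CoreAlignment,
    n_reps: int,
    rng_seed: int = 0,
    matrix: np.ndarray | None = None,
) -> list[dendropy.Tree]:
    """NJ trees from column-resampled replicates of the alignment."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    n = len(alignment)
    L = alignment.core_length
    pool = [
        c
        for c in range(L)
        if sum(1 for r in alignment.rows if r[c] == GAP) <= 0.5 * n
    ]
    if not pool:
        raise ValueError("no columns eligible for resampling")
    trees = []
    for _ in range(n_reps):
        cols = rng.choice(pool, size=len(pool), replace=True)
        rows = ["".join(r[c] for c in cols) for r in alignment.rows]
        rep = CoreAlignment(alignment.ids, rows)
        trees.append(neighbor_joining(distance_matrix(rep, matrix), alignment.ids))
    return trees


# ---------------------------------------------------------------------------
# Extended majority-rule consensus
# ---------------------------------------------------------------------------
def _tree_bipartitions(tree: dendropy.Tree, ref: str) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the side excluding ``ref``."""
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Public helper: normalised non-trivial bipartitions of a tree."""
    ref = sorted(t.label for t in tree.taxon_namespace)[0]
    return _tree_bipartitions(tree, ref)


def _compatible(a: frozenset, b: frozenset) -> bool:
    # both sides exclude the reference taxon: compatible iff nested or disjoint
    inter = a & b
    return not inter or inter == a or inter == b


def extended_majority_consensus(
    trees: list[dendropy.Tree],
) -> dendropy.Tree:
    """Extended majority-rule consensus with percent support labels.

    Bipartitions are ranked by frequency (ties by first occurrence);
    those above 50 % are always included, and the remainder are admitted
    greedily whenever compatible with everything already accepted.
    Internal node labels carry the support percentage.
    """
    if not trees:
        raise ValueError("need at least one tree")
    label_sets = [
        frozenset(t.label for t in tr.taxon_namespace) for tr in trees
    ]
    if len(set(label_sets)) != 1:
        raise ValueError("trees are not on the same taxon set")
    labels = sorted(label_sets[0])
    ref = labels[0]

    counts: dict[frozenset, int] = {}
    order: dict[frozenset, int] = {}
    for tr in trees:
        for side in _tree_bipartitions(tr, ref):
            if side not in counts:
                order[side] = len(order)
            counts[side] = counts.get(side, 0) + 1
    ntrees = len(trees)
    ranked = sorted(counts, key=lambda s: (-counts[s], order[s]))

    accepted: list[frozenset] = []
    for side in ranked:
        if counts[side] * 2 > ntrees:
            accepted.append(side)
        elif all(_compatible(side, other) for other in accepted):
            accepted.append(side)

    # Build the consensus rooted at the reference taxon's side.
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    clades = sorted(accepted, key=len, reverse=True)
    node_of: dict[frozenset, dendropy.Node] = {}

    def enclosing(target: frozenset) -> dendropy.Node:
        best = None
        for clade in clades:
            if target < clade and (best is None or len(clade) < len(best)):
                best = clade
        return node_of[best] if best is not None else root

    for clade in clades:
        nd = dendropy.Node()
        nd.label = f"{100.0 * counts[clade] / ntrees:g}"
        parent = enclosing(clade)
        parent.add_child(nd)
        node_of[clade] = nd
    for lab in labels:
        target = frozenset([lab])
        best = None
        for clade in clades:
            if lab in clade and (best is None or len(clade) < len(best)):
                best = clade
        parent = node_of[best] if best is not None else root
        leaf = dendropy.Node(taxon=taxa.get_taxon(lab))
        parent.add_child(leaf)
    tree.is_rooted = False
    return tree


def consensus_supports(trees: list[dendropy.Tree]) -> dict[frozenset, float]:
    """Support percentages of the bipartitions in the consensus tree."""
    cons = extended_majority_consensus(trees)
    ref = sorted(t.label for t in cons.taxon_namespace)[0]
    all_labels = frozenset(t.label for t in cons.taxon_namespace)
    out = {}
    for node in cons.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        out[side] = float(node.label)
    return out


@dataclass
class TreeResult:
    tree: dendropy.Tree
    bootstrap: list[dendropy.Tree]
    consensus: dendropy.Tree


def build_tree(
    alignment: CoreAlignment,
    n_bootstrap: int = 100,
    rng_seed: int = 0,
    matrix: np.ndarray | None = None,
) -> TreeResult:
    """NJ tree + bootstrap replicates + extended majority-rule consensus."""
    D = distance_matrix(alignment, matrix)
    tree = neighbor_joining(D, alignment.ids)
    reps = bootstrap_trees(alignment, n_bootstrap, rng_seed, matrix)
    cons = extended_majority_consensus(reps)
    return TreeResult(tree, reps, cons)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_phylip_distances(
    alignment: CoreAlignment, path, matrix: np.ndarray | None = None
) -> None:
    """PHYLIP-style square distance matrix export."""
    D = distance_matrix(alignment, matrix)
    with open(path, "w") as fh:
        fh.write(f"{len(alignment)}\n")
        for i, sid in enumerate(alignment.ids):
            row = " ".join(f"{v:.6f}" for v in D[i])
            fh.write(f"{sid:<12}{row}\n")


def write_relaxed_phylip(alignment: CoreAlignment, path) -> None:
    """Relaxed-PHYLIP export of the core columns (for external ML tools)."""
    with open(path, "w") as fh:
        fh.write(f"{len(alignment)} {alignment.core_length}\n")
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f"{sid}  {row}\n")
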