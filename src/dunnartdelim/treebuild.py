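"""Tree construction and tree distances without external inference tools.

Neighbor-joining from a distance matrix, outgroup rooting, and patristic
(path-length) distances. Trees from external maximum-likelihood or Bayesian
runs can be supplied as Newick anywhere a tree is consumed; NJ is the
in-package builder for when no tree is given.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "root_by_outgroup",
    "patristic_distances",
]

log = logging.getLogger(__name__)


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration.

    Deterministic: when two pairs tie on the Q-criterion, the
    lexicographically smallest label pair is merged (internal nodes carry
    the smallest descendant label for this purpose). Negative branch
    lengths are clamped to zero with the deficit logged. The returned tree
    is unrooted (trifurcating seed node).
    """
    if matrix.n < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    if np.isnan(matrix.values).any():
        raise ValueError(
            "matrix contains undefined cells; prune those labels first"
        )
    tns = dendropy.TaxonNamespace(list(matrix.labels))
    nodes: list[dendropy.Node] = []
    names: list[str] = []  # tie-break key: min descendant label
    for lab in matrix.labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)
        names.append(lab)
    D = matrix.values.astype(float).copy()
    active = list(range(matrix.n))
    deficit = 0.0

    def _clamp(v: float) -> float:
        nonlocal deficit
        if v < 0:
            deficit += -v
            return 0.0
        return v

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai, aj in itertools.combinations(range(m), 2):
            q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
            pair_names = tuple(sorted((names[active[ai]], names[active[aj]])))
            key = (q, pair_names)
            if best is None or key < best[0]:
                best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        vi = _clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2)))
        vj = _clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        # new row: reuse slot i
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - dij)
            D[i, k] = D[k, i] = dk
        nodes[i] = parent
        names[i] = min(names[i], names[j])
        active.remove(j)

    # terminal three-node star: lengths from the three-point formulas
    i, j, k = active
    seed = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        v = _clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
        seed.add_child(nodes[a])
        nodes[a].edge.length = v
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=seed)
    tree.is_rooted = False
    if deficit > 0:
        log.info("neighbor_joining: clamped %.6g of negative branch length", deficit)
    return tree


def _leafsets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    out: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            out[nd] = frozenset([nd.taxon.label])
        else:
            out[nd] = frozenset().union(*(out[c] for c in nd.child_nodes()))
    return out


def root_by_outgroup(tree: dendropy.Tree, outgroup_tips: set[str]) -> dendropy.Tree:
    """Root an (unrooted) tree on the edge separating *outgroup_tips* from
    the rest, splitting that edge's length equally.

    Raises ``ValueError`` if the outgroup is not edge-separable
    ("outgroup not monophyletic in unrooted tree").
    """
    outgroup_tips = set(outgroup_tips)
    tree = tree.clone(depth=1)
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = outgroup_tips - all_tips
    if missing:
        raise KeyError(f"outgroup tips not in tree: {sorted(missing)}")
    if outgroup_tips == all_tips:
        raise ValueError("outgroup cannot be the full tip set")
    sets = _leafsets(tree)
    target = frozenset(outgroup_tips)
    complement = frozenset(all_tips - outgroup_tips)
    edge = None
    for nd, ls in sets.items():
        if nd.parent_node is None:
            continue
        if ls == target or ls == complement:
            edge = nd.edge
            break
    if edge is None:
        raise ValueError("outgroup not monophyletic in unrooted tree")
    length = edge.length if edge.length is not None else 0.0
    tree.reroot_at_edge(
        edge, length1=length / 2.0, length2=length / 2.0,
        update_bipartitions=False, suppress_unifurcations=True,
    )
    tree.is_rooted = True
    return tree


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length distances between all tip pairs (mode ``patristic``)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    # root-to-tip accumulation; missing lengths are an error
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(labels)
    vals = np.zeros((n, n))
    taxa = {t.label: t for t in tns}
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(tuple(labels), vals, "patristic")
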