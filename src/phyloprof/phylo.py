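"""Gene trees for paralog screening and species-tree gene-loss mapping."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

MAX_DISTANCE = 10.0


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no non-gap columns."""


@dataclass
class DistanceMatrix:
    ids: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


def pairwise_distance(msa, max_distance: float = MAX_DISTANCE) -> DistanceMatrix:
    """Poisson-corrected p-distances over mutually non-gap columns."""
    if msa.n_rows < 2:
        raise ValueError("need at least two rows")
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            shared = mismatch = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    shared += 1
                    if x != y:
                        mismatch += 1
            if shared == 0:
                raise UndefinedDistanceError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no columns")
            p = mismatch / shared
            if p >= 1.0:
                dist = max_distance
            else:
                dist = min(-math.log(1.0 - p), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=list(msa.ids), matrix=d)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Standard NJ agglomeration with lexicographic tie-breaking.

    Returns an unrooted dendropy tree (trifurcating seed node for >= 3 taxa);
    recovers the generating topology exactly on additive matrices.
    """
    ids = list(D.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    ns = dendropy.TaxonNamespace()
    nodes: Dict[str, dendropy.Node] = {}
    for name in ids:
        taxon = dendropy.Taxon(label=name)
        ns.add_taxon(taxon)
        nodes[name] = dendropy.Node(taxon=taxon)
    dist: Dict[Tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                dist[(a, b)] = dist[(b, a)] = float(D.matrix[i, j])
    active = sorted(ids)
    counter = 0
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                q = (r - 2) * dist[(a, b)] - totals[a] - totals[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        la = 0.5 * dist[(a, b)] + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dist[(a, b)] - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_id = f"_nj{counter}|{min(a, b)}"
        counter += 1
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = la
        parent.add_child(nodes[b])
        nodes[b].edge.length = lb
        nodes[new_id] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[(new_id, c)] = dist[(c, new_id)] = max(
                0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)]), 0.0)
        active = sorted(x for x in active if x not in (a, b))
        active.append(new_id)
        active.sort()
    root = dendropy.Node()
    if len(active) == 2:
        a, b = active
        root = nodes[a]
        root.add_child(nodes[b])
        nodes[b].edge.length = dist[(a, b)]
    else:
        a, b, c = active
        root = dendropy.Node()
        for x, other1, other2 in ((a, b, c), (b, a, c), (c, a, b)):
            lx = 0.5 * (dist[(x, other1)] + dist[(x, other2)] - dist[(other1, other2)])
            root.add_child(nodes[x])
            nodes[x].edge.length = max(lx, 0.0)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def screen_paralogs(gene_tree: dendropy.Tree, reference_ids: Iterable[str]) -> Set[str]:
    """Leaf set of the smallest midpoint-rooted clade holding all references.

    A single reference expands to its parent clade (the cherry or larger).
    Leaves outside the returned set are paralogs/contaminants.
    """
    refs = sorted(set(reference_ids))
    if not refs:
        raise ValueError("reference_ids must be non-empty")
    tree = gene_tree.clone(depth=1)
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [r for r in refs if r not in leaf_labels]
    if missing:
        raise ValueError(f"reference ids not in tree: {missing}")
    if len(tree.leaf_nodes()) > 2:
        tree.reroot_at_midpoint(update_bipartitions=True)
    taxa = [tree.taxon_namespace.get_taxon(r) for r in refs]
    node = tree.mrca(taxa=taxa)
    if node.is_leaf():
        node = node.parent_node or node
    return {lf.taxon.label for lf in node.leaf_iter()}


@dataclass
class LossMap:
    """Dollo loss reconstruction for one family on a rooted species tree."""

    family: str
    gain_node: str
    loss_branches: List[str]  # child-node ids of the lost subtrees

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "n") -> dendropy.Tree:
    """Assign deterministic preorder labels to unlabeled internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"{prefix}{k}"
        k += 1
    return tree


def _node_id(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def dollo_losses(species_tree: dendropy.Tree, presence: Mapping[str, int],
                 family: str = "family", gain_at_root: bool = True) -> LossMap:
    """Map losses as the maximal all-absent subtrees under a single gain.

    With ``gain_at_root`` (default) the gain is fixed at the root; otherwise
    it is placed at the MRCA of the present taxa and losses are reported
    within that subtree only.
    """
    leaves = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    missing = [t for t in leaves if t not in presence]
    if missing:
        raise ValueError(f"presence undefined for taxa: {missing}")
    present = [t for t in leaves if presence[t]]
    if not present:
        raise ValueError("all-absent family: gain placement undefined")
    label_internal_nodes(species_tree)
    if gain_at_root:
        gain = species_tree.seed_node
    else:
        taxa = [species_tree.taxon_namespace.get_taxon(t) for t in present]
        gain = species_tree.mrca(taxa=taxa)
    all_absent: Dict[int, bool] = {}
    for node in gain.postorder_iter():
        if node.is_leaf():
            all_absent[id(node)] = not presence[node.taxon.label]
        else:
            all_absent[id(node)] = all(all_absent[id(c)] for c in node.child_nodes())
    losses: List[str] = []
    for node in gain.preorder_iter():
        if node is gain:
            continue
        if all_absent[id(node)] and not all_absent[id(node.parent_node)]:
            losses.append(_node_id(node))
    return LossMap(family=family, gain_node=_node_id(gain) or "root",
                   loss_branches=sorted(losses))


def apply_losses(species_tree: dendropy.Tree, loss_branches: Iterable[str],
                 gain_node: Optional[str] = None) -> Dict[str, int]:
    """Forward-simulate a presence vector from a gain node and loss set."""
    label_internal_nodes(species_tree)
    losses = set(loss_branches)
    presence: Dict[str, int] = {}
    start = species_tree.seed_node
    if gain_node is not None:
        for node in species_tree.preorder_node_iter():
            if _node_id(node) == gain_node:
                start = node
                break
    in_gain: Dict[int, bool] = {id(n): False for n in species_tree.preorder_node_iter()}
    for node in start.preorder_iter():
        in_gain[id(node)] = True
    state: Dict[int, int] = {}
    for node in species_tree.preorder_node_iter():
        if not in_gain[id(node)]:
            state[id(node)] = 0
            continue
        parent_state = 1 if node is start else state[id(node.parent_node)]
        state[id(node)] = 0 if (_node_id(node) in losses or parent_state == 0) else 1
        if node.is_leaf():
            presence[node.taxon.label] = state[id(node)]
    return presence
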