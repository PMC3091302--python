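"""Dollo parsimony reconstruction of ancestral domain repertoires.

Under Dollo parsimony a domain arises exactly once on the tree — at the
most recent common ancestor (MRCA) of all genomes carrying it — and may
subsequently be lost any number of times, but never regained. For a
binary presence column this yields a unique minimum-loss history: within
the gain clade, a node is present iff its subtree contains at least one
presence leaf, and each edge from a present node into a maximal
presence-free subtree is one loss event.

Aggregating histories over all domains gives an event ledger: per-branch
gained/lost sets, per-node present sets, and a whole-tree cost of one
gain per domain plus all inferred losses. Costs rank alternative
topologies — a tree that groups genomes sharing derived repertoires
requires fewer losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .domainome import Domainome, PresenceMatrix
from .tree import RootedTree, TreeNode

__all__ = [
    "DomainHistory",
    "EventLedger",
    "CladeSummary",
    "infer_history",
    "reconstruct",
    "tree_cost",
    "compare_topologies",
    "clade_summary",
]


@dataclass(frozen=True)
class DomainHistory:
    """Single-gain / multi-loss history of one domain on a rooted tree.

    ``loss_edges`` identifies each loss by the child node of the edge on
    which it occurs; ``present_nodes`` are exactly the nodes reachable
    from ``gain_node`` without crossing a loss edge.
    """

    domain_acc: str
    gain_node: str
    loss_edges: frozenset[str]
    present_nodes: frozenset[str]

    @property
    def cost(self) -> int:
        return 1 + len(self.loss_edges)


class EventLedger:
    """Per-branch gains/losses and per-node present sets for a whole matrix.

    Branches are keyed by their child node. Domains originating at the
    root form the ``root_present`` ancestral stock (the root has no
    parent branch to charge a gain to).
    """

    def __init__(self, tree: RootedTree):
        self.tree = tree
        self.gained: dict[str, set[str]] = {
            n.name: set() for n in tree.preorder() if n.parent is not None
        }
        self.lost: dict[str, set[str]] = {
            n.name: set() for n in tree.preorder() if n.parent is not None
        }
        self.present: dict[str, set[str]] = {n.name: set() for n in tree.preorder()}
        self.histories: dict[str, DomainHistory] = {}

    def add(self, history: DomainHistory) -> None:
        self.histories[history.domain_acc] = history
        if history.gain_node != self.tree.root.name:
            self.gained[history.gain_node].add(history.domain_acc)
        for child in history.loss_edges:
            self.lost[child].add(history.domain_acc)
        for node in history.present_nodes:
            self.present[node].add(history.domain_acc)

    @property
    def root_present(self) -> set[str]:
        """Domains in the root's repertoire (the ancestral stock)."""
        return self.present[self.tree.root.name]

    @property
    def n_domains(self) -> int:
        return len(self.histories)

    @property
    def total_losses(self) -> int:
        return sum(len(h.loss_edges) for h in self.histories.values())

    @property
    def cost(self) -> int:
        """Total Dollo event count: one gain per domain plus all losses."""
        return self.n_domains + self.total_losses

    def node_domainome(self, node: str) -> Domainome:
        return Domainome(node, set(self.present[node]))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"EventLedger({self.n_domains} domains, cost={self.cost}, "
            f"root={len(self.root_present)})"
        )


@dataclass(frozen=True)
class CladeSummary:
    """Gain/loss/present counts at a clade's root plus extant-size statistics.

    ``extant_sd`` is the sample standard deviation (n-1 denominator) of the
    clade's leaf repertoire sizes; undefined for a single genome and then
    reported as 0.0 with ``sd_defined=False``.
    """

    clade: str
    gains: int
    losses: int
    present: int
    extant_mean: float
    extant_sd: float
    n_genomes: int
    sd_defined: bool = True


def infer_history(tree: RootedTree, column: Mapping[str, int], domain_acc: str = "") -> DomainHistory:
    """Minimum-loss single-gain history for one presence/absence column.

    The gain node is the MRCA of all presence leaves. A node inside the
    gain clade is present iff its subtree contains a presence leaf; each
    edge from a present node to an absent child is a loss. The number of
    losses is the minimum achievable under the single-gain constraint.
    """
    leaf_names = set(tree.leaf_names())
    missing = leaf_names - set(column)
    if missing:
        raise ValueError(f"column lacks states for leaves: {sorted(missing)}")
    present_leaves = {name for name in leaf_names if column[name]}
    if not present_leaves:
        raise ValueError(
            f"all-absent column for {domain_acc or 'domain'}: no gain to place"
        )

    gain = tree.mrca(present_leaves)

    # Postorder sweep inside the gain clade: present iff a presence leaf
    # lies in the node's subtree.
    has_presence: dict[str, bool] = {}
    order = []
    stack = [gain]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in reversed(order):
        if node.is_leaf:
            has_presence[node.name] = node.name in present_leaves
        else:
            has_presence[node.name] = any(
                has_presence[c.name] for c in node.children
            )

    present_nodes = {name for name, ok in has_presence.items() if ok}
    loss_edges = {
        child.name
        for node in order
        if has_presence[node.name]
        for child in node.children
        if not has_presence[child.name]
    }
    return DomainHistory(
        domain_acc=domain_acc,
        gain_node=gain.name,
        loss_edges=frozenset(loss_edges),
        present_nodes=frozenset(present_nodes),
    )


def _check_labels(tree: RootedTree, matrix: PresenceMatrix) -> None:
    tree_leaves = set(tree.leaf_names())
    matrix_taxa = set(matrix.taxa)
    if tree_leaves != matrix_taxa:
        only_tree = sorted(tree_leaves - matrix_taxa)
        only_matrix = sorted(matrix_taxa - tree_leaves)
        raise ValueError(
            "leaf labels differ between tree and matrix; "
            f"tree-only={only_tree}, matrix-only={only_matrix}"
        )


def reconstruct(tree: RootedTree, matrix: PresenceMatrix) -> EventLedger:
    """Dollo reconstruction over every matrix column -> event ledger."""
    _check_labels(tree, matrix)
    ledger = EventLedger(tree)
    for acc in matrix.domains:
        ledger.add(infer_history(tree, matrix.column(acc), acc))
    return ledger


def tree_cost(tree: RootedTree, matrix: PresenceMatrix) -> int:
    """Total Dollo event count (gains + losses) of the matrix on the tree."""
    _check_labels(tree, matrix)
    cost = 0
    for acc in matrix.domains:
        cost += infer_history(tree, matrix.column(acc), acc).cost
    return cost


def compare_topologies(
    trees: Sequence[RootedTree], matrix: PresenceMatrix
) -> list[tuple[RootedTree, int]]:
    """Rank candidate topologies by Dollo cost (ascending, stable)."""
    if not trees:
        return []
    ref = set(trees[0].leaf_names())
    for t in trees[1:]:
        if set(t.leaf_names()) != ref:
            raise ValueError("all trees must share the same leaf set")
    costs = [(t, tree_cost(t, matrix)) for t in trees]
    return sorted(costs, key=lambda tc: tc[1])


def clade_summary(
    tree: RootedTree,
    ledger: EventLedger,
    domainomes: Sequence[Domainome],
    clade_root: str,
) -> CladeSummary:
    """Summarize one clade: events on its root branch and extant-size stats."""
    node = tree.node(clade_root)  # raises KeyError for unknown nodes
    gains = len(ledger.gained.get(clade_root, set()))
    losses = len(ledger.lost.get(clade_root, set()))
    present = len(ledger.present[clade_root])

    leaf_set = set(tree.subtree_leaves(clade_root))
    sizes = [len(d) for d in domainomes if d.label in leaf_set]
    if not sizes:
        raise ValueError(f"no domainomes supplied for leaves of clade {clade_root!r}")
    mean = sum(sizes) / len(sizes)
    if len(sizes) > 1:
        var = sum((s - mean) ** 2 for s in sizes) / (len(sizes) - 1)
        sd, sd_defined = math.sqrt(var), True
    else:
        sd, sd_defined = 0.0, False
    return CladeSummary(
        clade=clade_root,
        gains=gains,
        losses=losses,
        present=present,
        extant_mean=mean,
        extant_sd=sd,
        n_genomes=len(sizes),
        sd_defined=sd_defined,
    )
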