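"""GO-based functional characterization of domain repertoires.

Domains are mapped to Gene Ontology terms through a domain->GO mapping
(pfam2go style). Annotations are propagated to ancestors along ``is_a``
and ``part_of`` edges (the true-path rule), after which the module
computes:

* functional profiles — for selected GO terms, the percentage of a
  repertoire's annotated domains carrying each term;
* per-branch category flux — how many gained/lost domains on a lineage
  belong to a functional category (e.g. biological regulation vs
  metabolic process);
* 2-D profile coordinates (e.g. signal transduction % vs catalytic
  activity %) for scatter plots of extant and ancestral repertoires;
* average-linkage clustering of profiles and its Robinson-Foulds
  congruence with a reference species tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from scipy.cluster import hierarchy

from .dollo import EventLedger
from .domainome import Domainome
from .tree import RootedTree

logger = logging.getLogger(__name__)

__all__ = [
    "GoTerm",
    "GoDag",
    "DomainGoMap",
    "FunctionalProfile",
    "FluxResult",
    "ClusterResult",
    "propagate",
    "profile",
    "category_flux",
    "profile_coordinates",
    "cluster_profiles",
    "normalized_rf",
]

# default axis / category terms; ids configurable everywhere they are used
SIGNAL_TRANSDUCTION = "GO:0007165"
CATALYTIC_ACTIVITY = "GO:0003824"
BIOLOGICAL_REGULATION = "GO:0065007"
METABOLIC_PROCESS = "GO:0008152"


@dataclass(frozen=True)
class GoTerm:
    id: str
    name: str = ""
    namespace: str = "biological_process"
    obsolete: bool = False


class GoDag:
    """Acyclic GO graph with child->parent ``is_a``/``part_of`` edges."""

    def __init__(
        self,
        terms: Iterable[GoTerm],
        edges: Iterable[tuple[str, str]],
    ):
        """``edges`` are (child_id, parent_id) pairs, already restricted to
        is_a/part_of relationships."""
        self.terms: dict[str, GoTerm] = {t.id: t for t in terms}
        self.parents: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge {child}->{parent} references unknown term")
            if self.terms[child].obsolete or self.terms[parent].obsolete:
                raise ValueError(f"obsolete term in edge {child}->{parent}")
            self.parents[child].add(parent)
        self._check_acyclic()
        self._ancestors_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    def _check_acyclic(self) -> None:
        # iterative three-color DFS; reports one cycle explicitly
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {tid: WHITE for tid in self.terms}
        for start in self.terms:
            if color[start] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(start, iter(self.parents[start]))]
            color[start] = GRAY
            path = [start]
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    color[node] = BLACK
                    stack.pop()
                    path.pop()
                    continue
                if color[nxt] == GRAY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise ValueError(
                        "cyclic ontology: " + " -> ".join(cycle)
                    )
                if color[nxt] == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(self.parents[nxt])))
                    path.append(nxt)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def ancestors(self, term_id: str, reflexive: bool = False) -> frozenset[str]:
        """All terms reachable by following parent edges (cached)."""
        if term_id not in self.terms:
            raise KeyError(f"unknown GO term {term_id!r}")
        cached = self._ancestors_cache.get(term_id)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents[term_id])
            while stack:
                t = stack.pop()
                if t not in out:
                    out.add(t)
                    stack.extend(self.parents[t])
            cached = frozenset(out)
            self._ancestors_cache[term_id] = cached
        return cached | {term_id} if reflexive else cached

    def children_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for child, parents in self.parents.items():
            for p in parents:
                out[p].add(child)
        return out

    def depth(self, term_id: str) -> int:
        """Longest path length from the term up to a root (0 for roots)."""
        if term_id in self._depth_cache:
            return self._depth_cache[term_id]
        # memoized recursion via explicit stack (DAG, so terminates)
        stack = [term_id]
        while stack:
            t = stack[-1]
            if t in self._depth_cache:
                stack.pop()
                continue
            pending = [p for p in self.parents[t] if p not in self._depth_cache]
            if pending:
                stack.extend(pending)
                continue
            self._depth_cache[t] = (
                1 + max(self._depth_cache[p] for p in self.parents[t])
                if self.parents[t]
                else 0
            )
            stack.pop()
        return self._depth_cache[term_id]

    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if not self.parents[t])


class DomainGoMap:
    """Direct domain accession -> GO term annotations.

    Terms missing from the DAG are dropped with a warning at
    construction; domains may be unannotated.
    """

    def __init__(self, annotations: Mapping[str, Iterable[str]], dag: GoDag):
        self.annotations: dict[str, frozenset[str]] = {}
        dropped = 0
        for acc, terms in annotations.items():
            known = frozenset(t for t in terms if t in dag)
            dropped += len(set(terms)) - len(known)
            self.annotations[acc] = known
        if dropped:
            logger.warning("dropped %d annotation(s) to unknown GO terms", dropped)
        self.dag = dag

    def terms_for(self, accession: str) -> frozenset[str]:
        return self.annotations.get(accession, frozenset())

    def __len__(self) -> int:
        return len(self.annotations)

    def annotated_domains(self) -> set[str]:
        return {acc for acc, terms in self.annotations.items() if terms}


@dataclass
class FunctionalProfile:
    """Per-term percentages for one repertoire.

    ``fractions[t]`` is 100 * (annotated domains carrying t) /
    (domains with any annotation in t's namespace); ``None`` when the
    denominator is zero (``defined[t]`` is then False).
    """

    label: str
    fractions: dict[str, float | None]
    denominators: dict[str, int]
    defined: dict[str, bool]


def propagate(dag: GoDag, gomap: DomainGoMap) -> DomainGoMap:
    """Close every domain's term set under is_a/part_of ancestry (idempotent)."""
    closed = {
        acc: set().union(*(dag.ancestors(t, reflexive=True) for t in terms))
        if terms
        else set()
        for acc, terms in gomap.annotations.items()
    }
    return DomainGoMap(closed, dag)


def profile(
    domainome: Domainome,
    dag: GoDag,
    gomap: DomainGoMap,
    terms: Sequence[str],
    propagated: bool = False,
) -> FunctionalProfile:
    """Functional profile of one repertoire over the selected GO terms."""
    for t in terms:
        if t not in dag:
            raise KeyError(f"unknown GO term {t!r}")
    pmap = gomap if propagated else propagate(dag, gomap)
    # denominator per namespace: domains with >=1 annotation in it
    ns_denominator: dict[str, int] = {}
    fractions: dict[str, float | None] = {}
    denominators: dict[str, int] = {}
    defined: dict[str, bool] = {}
    for t in terms:
        ns = dag.namespace(t)
        if ns not in ns_denominator:
            ns_denominator[ns] = sum(
                1
                for acc in domainome.domains
                if any(dag.namespace(x) == ns for x in pmap.terms_for(acc))
            )
        denom = ns_denominator[ns]
        denominators[t] = denom
        if denom == 0:
            fractions[t] = None
            defined[t] = False
        else:
            count = sum(1 for acc in domainome.domains if t in pmap.terms_for(acc))
            fractions[t] = 100.0 * count / denom
            defined[t] = True
    return FunctionalProfile(domainome.label, fractions, denominators, defined)


@dataclass
class FluxResult:
    """Per-branch gained/lost counts for one category along a lineage path."""

    category: str
    branches: list[str]          # child-node names, root-ward to leaf-ward
    gains_per_branch: list[int]
    losses_per_branch: list[int]

    @property
    def mean_gains(self) -> float:
        return sum(self.gains_per_branch) / len(self.branches) if self.branches else 0.0

    @property
    def mean_losses(self) -> float:
        return sum(self.losses_per_branch) / len(self.branches) if self.branches else 0.0

    @property
    def net_per_branch(self) -> float:
        """Mean net change (gains minus losses) per branch."""
        return self.mean_gains - self.mean_losses


def category_flux(
    ledger: EventLedger,
    path: Sequence[str],
    dag: GoDag,
    gomap: DomainGoMap,
    category: str,
    propagated: bool = False,
) -> FluxResult:
    """Gained/lost domains annotated to a category, per branch on a lineage.

    ``path`` is a connected chain of node names from an ancestor toward a
    descendant; the branches considered are those entering path[1:].
    Each domain counts once per category regardless of how many of its
    terms fall under it.
    """
    if category not in dag:
        raise KeyError(f"unknown GO term {category!r}")
    tree = ledger.tree
    for anc, child in zip(path, path[1:]):
        child_node = tree.node(child)
        if child_node.parent is None or child_node.parent.name != anc:
            raise ValueError(
                f"path is not a connected parent->child chain at {anc!r}->{child!r}"
            )
    pmap = gomap if propagated else propagate(dag, gomap)

    def count(domains: set[str]) -> int:
        return sum(1 for acc in domains if category in pmap.terms_for(acc))

    branches = list(path[1:])
    gains = [count(ledger.gained[b]) for b in branches]
    losses = [count(ledger.lost[b]) for b in branches]
    return FluxResult(category, branches, gains, losses)


def profile_coordinates(
    profiles: Sequence[FunctionalProfile], x_term: str, y_term: str
) -> list[tuple[str, float, float]]:
    """Extract (label, x%, y%) rows for a 2-D functional scatter."""
    rows = []
    for p in profiles:
        for t in (x_term, y_term):
            if t not in p.fractions or p.fractions[t] is None:
                raise ValueError(f"profile {p.label!r} lacks a defined value for {t}")
        rows.append((p.label, p.fractions[x_term], p.fractions[y_term]))
    return rows


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    newick: str
    congruence: float  # normalized Robinson-Foulds distance in [0, 1]


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    node, _ = hierarchy.to_tree(Z, rd=True)

    def fmt(n) -> str:
        if n.is_leaf():
            return labels[n.id].replace(" ", "_")
        return f"({fmt(n.left)},{fmt(n.right)})"

    return fmt(node) + ";"


def normalized_rf(newick_a: str, newick_b: str) -> float:
    """Unrooted Robinson-Foulds distance normalized to [0, 1].

    Normalization divides the symmetric bipartition difference by the
    total number of non-trivial bipartitions in both trees.
    """
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    leaves_a = {l.taxon.label for l in ta.leaf_node_iter()}
    leaves_b = {l.taxon.label for l in tb.leaf_node_iter()}
    common = leaves_a & leaves_b
    if not common:
        raise ValueError("trees share no leaves")
    if leaves_a != common:
        ta.retain_taxa_with_labels(common)
    if leaves_b != common:
        tb.retain_taxa_with_labels(common)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    sd = dendropy.calculate.treecompare.symmetric_difference(ta, tb)

    def n_internal(tree: dendropy.Tree) -> int:
        return sum(
            1
            for e in tree.preorder_edge_iter()
            if e.head_node.parent_node is not None and not e.head_node.is_leaf()
        )

    denom = n_internal(ta) + n_internal(tb)
    return sd / denom if denom else 0.0


def cluster_profiles(
    profiles: Sequence[FunctionalProfile], reference: RootedTree
) -> ClusterResult:
    """Average-linkage clustering of percentage vectors vs a reference tree.

    Profiles must share a common, fully defined term vector. Congruence
    is the normalized Robinson-Foulds distance between the dendrogram
    topology and the reference tree restricted to the profile labels
    (0 = identical topology).
    """
    if len(profiles) < 3:
        raise ValueError("clustering needs at least 3 profiles")
    term_vec = sorted(profiles[0].fractions)
    for p in profiles[1:]:
        if sorted(p.fractions) != term_vec:
            raise ValueError(
                f"profile {p.label!r} has a different term vector than {profiles[0].label!r}"
            )
    for p in profiles:
        undef = [t for t in term_vec if p.fractions[t] is None]
        if undef:
            raise ValueError(f"profile {p.label!r} has undefined fractions: {undef}")
    ref_leaves = set(reference.leaf_names())
    labels = [p.label for p in profiles]
    if not ref_leaves <= set(labels):
        raise ValueError("reference leaf set must be a subset of profile labels")
    X = np.array([[p.fractions[t] for t in term_vec] for p in profiles], dtype=float)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    newick = _linkage_to_newick(Z, labels)
    congruence = normalized_rf(newick, reference.to_newick(include_internal_names=False))
    return ClusterResult(Z, labels, newick, congruence)
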