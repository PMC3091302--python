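"""Synthetic data with the generative structure the reconstruction assumes.

Three generators, all seeded and deterministic:

* ``simulate_domain_evolution`` — single-origin / branch-wise-loss domain
  histories on a rooted tree, with full ground truth (origin node, loss
  edges, leaf presence) and the derived presence matrix;
* ``simulate_hit_table`` — noisy per-protein domain-hit tables around a
  known repertoire: true hits plus overlapping, weak-scoring, or
  excluded-accession decoys, with bookkeeping of which hits must survive
  filtering;
* ``simulate_go`` — a small layered GO-like DAG with uniform background
  annotations and a study set carrying planted term enrichment.

Every simulator can write the same on-disk formats the real pipeline
reads, so end-to-end runs need no external genomes or ontologies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .domainome import Domainome, PresenceMatrix, build_matrix
from .enrich import StudySet
from .gofunc import DomainGoMap, GoDag, GoTerm, propagate
from .hitfilter import DomainHit, ExclusionList
from .tree import RootedTree, TreeNode

__all__ = [
    "SimConfig",
    "SimTruth",
    "HitTableTruth",
    "random_tree",
    "spr_perturb",
    "simulate_domain_evolution",
    "simulate_hit_table",
    "simulate_go",
]


def random_tree(n_leaves: int, seed: int, prefix: str = "L") -> RootedTree:
    """Random rooted binary tree shape on ``n_leaves`` labelled leaves.

    Built by repeatedly joining two uniformly chosen lineages
    (coalescent-style), which covers all binary shapes with positive
    probability.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    lineages: list[TreeNode] = [TreeNode(f"{prefix}{i + 1}") for i in range(n_leaves)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = TreeNode("")
        parent.children = [a, b]
        a.parent = b.parent = parent
        lineages[i] = parent
        lineages.pop(j)
    return RootedTree(lineages[0])


def spr_perturb(tree: RootedTree, seed: int, n_moves: int = 1) -> RootedTree:
    """Random subtree-prune-and-regraft perturbation(s) of a rooted tree.

    A non-root subtree is detached and reattached onto a uniformly
    chosen edge outside it; internal nodes are renamed afresh so the
    result is a valid tree with the same leaf set.
    """
    rng = np.random.default_rng(seed)
    current = tree.copy()
    for _ in range(n_moves):
        nodes = list(current.preorder())
        candidates = [
            n for n in nodes if n.parent is not None and n.parent.parent is not None
        ]
        if not candidates:
            break
        prune = candidates[rng.integers(len(candidates))]
        parent = prune.parent
        grandparent = parent.parent
        # detach: splice parent out (parent keeps its other children)
        parent.children.remove(prune)
        if len(parent.children) == 1:
            only = parent.children[0]
            gp_children = grandparent.children
            gp_children[gp_children.index(parent)] = only
            only.parent = grandparent
        forbidden = set()
        stack = [prune]
        while stack:
            n = stack.pop()
            forbidden.add(id(n))
            stack.extend(n.children)
        # recompute node list after detachment
        attach_edges = [
            n
            for n in _iter_subtree(current.root)
            if n.parent is not None and id(n) not in forbidden
        ]
        target = attach_edges[rng.integers(len(attach_edges))]
        new_parent = TreeNode("")
        tparent = target.parent
        tparent.children[tparent.children.index(target)] = new_parent
        new_parent.parent = tparent
        new_parent.children = [target, prune]
        target.parent = new_parent
        prune.parent = new_parent
        # strip internal names and rebuild indices
        for n in _iter_subtree(current.root):
            if not n.is_leaf:
                n.name = ""
        current = RootedTree(current.root)
    return current


def _iter_subtree(root: TreeNode):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


@dataclass
class SimConfig:
    """Conditions for domain-history simulation.

    ``origin_weights`` maps node names to relative origin probabilities;
    the default is root-weighted: probability 0.5 at the root, the rest
    uniform over non-root nodes — emulating a large ancestral stock plus
    lineage-specific gains. ``loss_prob`` is a global per-branch loss
    probability or a per-branch map keyed by child node name.
    """

    tree: RootedTree
    n_domains: int
    loss_prob: float | Mapping[str, float] = 0.1
    origin_weights: Mapping[str, float] | None = None
    seed: int = 0
    domain_prefix: str = "PF"

    def branch_loss(self, child: str) -> float:
        p = (
            self.loss_prob.get(child, 0.0)
            if isinstance(self.loss_prob, Mapping)
            else self.loss_prob
        )
        if not (0.0 <= p < 1.0):
            raise ValueError(f"loss probability for branch into {child!r} not in [0,1)")
        return p

    def validate(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be positive")
        for node in self.tree.preorder():
            if node.parent is not None:
                self.branch_loss(node.name)
        if self.origin_weights is not None:
            for name, w in self.origin_weights.items():
                if name not in self.tree:
                    raise ValueError(f"origin weight for unknown node {name!r}")
                if w < 0:
                    raise ValueError(f"negative origin weight for {name!r}")


@dataclass
class SimTruth:
    """Ground truth of a domain-evolution simulation."""

    tree: RootedTree
    origin: dict[str, str]                 # domain -> origin node
    loss_edges: dict[str, frozenset[str]]  # domain -> loss edges (child names)
    leaf_presence: dict[str, frozenset[str]]  # domain -> presence leaves
    unobservable: set[str]                 # domains with zero surviving leaves

    @property
    def observable_domains(self) -> list[str]:
        return sorted(set(self.origin) - self.unobservable)

    def event_count(self, domain: str) -> int:
        return 1 + len(self.loss_edges[domain])

    @property
    def total_events(self) -> int:
        """Events of observable domains only (what reconstruction can see)."""
        return sum(self.event_count(d) for d in self.observable_domains)

    def matrix(self) -> PresenceMatrix:
        leaves = self.tree.leaf_names()
        domes = {l: set() for l in leaves}
        for d in self.observable_domains:
            for leaf in self.leaf_presence[d]:
                domes[leaf].add(d)
        return build_matrix([Domainome(l, s) for l, s in domes.items()])

    def leaf_domainomes(self) -> list[Domainome]:
        leaves = self.tree.leaf_names()
        domes = {l: set() for l in leaves}
        for d in self.observable_domains:
            for leaf in self.leaf_presence[d]:
                domes[leaf].add(d)
        return [Domainome(l, domes[l]) for l in leaves]


def simulate_domain_evolution(cfg: SimConfig) -> SimTruth:
    """Single-gain / branch-loss evolution of ``n_domains`` on the tree.

    Each domain originates at a node drawn from the origin distribution
    and is then propagated leaf-ward; on every branch inside the origin
    clade a loss occurs with the branch's loss probability, after which
    the whole subtree is absent (no regain). Domains losing all leaves
    are retained but flagged unobservable.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nodes = [n.name for n in cfg.tree.preorder()]
    if cfg.origin_weights is not None:
        weights = np.array([cfg.origin_weights.get(n, 0.0) for n in nodes], float)
        if weights.sum() <= 0:
            raise ValueError("origin weights sum to zero")
    else:
        root = cfg.tree.root.name
        others = len(nodes) - 1
        weights = np.array(
            [0.5 if n == root else (0.5 / others if others else 0.0) for n in nodes]
        )
        if others == 0:
            weights = np.array([1.0])
    probs = weights / weights.sum()

    width = max(5, len(str(cfg.n_domains)))
    origin: dict[str, str] = {}
    loss_edges: dict[str, frozenset[str]] = {}
    leaf_presence: dict[str, frozenset[str]] = {}
    unobservable: set[str] = set()
    for i in range(cfg.n_domains):
        acc = f"{cfg.domain_prefix}{i + 1:0{width}d}"
        origin_node = nodes[rng.choice(len(nodes), p=probs)]
        losses: set[str] = set()
        present_leaves: set[str] = set()
        stack = [(cfg.tree.node(origin_node), True)]
        while stack:
            node, alive = stack.pop()
            if alive and node.is_leaf:
                present_leaves.add(node.name)
            for child in node.children:
                # descend only while alive; a lost subtree contributes nothing
                if alive and rng.random() < cfg.branch_loss(child.name):
                    losses.add(child.name)
                elif alive:
                    stack.append((child, True))
        origin[acc] = origin_node
        loss_edges[acc] = frozenset(losses)
        leaf_presence[acc] = frozenset(present_leaves)
        if not present_leaves:
            unobservable.add(acc)
    return SimTruth(cfg.tree, origin, loss_edges, leaf_presence, unobservable)


@dataclass
class HitTableTruth:
    """Bookkeeping of a simulated hit table."""

    hits_by_protein: dict[str, list[DomainHit]]
    surviving_domains: set[str]     # accessions that must survive filtering
    decoy_hits: list[DomainHit]
    excluded_accessions: set[str]


def simulate_hit_table(
    domainome: Domainome,
    seed: int,
    decoy_count: int = 0,
    overlap_rate: float = 0.5,
    excluded_injection: int = 0,
    ga_threshold: float = 25.0,
    true_logE: tuple[float, float] = (-12.0, 2.0),
    decoy_logE: tuple[float, float] = (-2.0, 1.0),
    domains_per_protein: tuple[int, int] = (1, 3),
) -> HitTableTruth:
    """Noisy hit table around a known repertoire.

    True hits get E-values from ``10**Normal(true_logE)`` (clipped below
    the decoy regime) and bit scores above the GA threshold, arranged
    non-overlapping on synthetic proteins of 1-3 domains. Decoys either
    overlap a true hit with a higher E-value / sub-GA score, or are
    placed apart with failing scores; ``excluded_injection`` additional
    strong hits carry accessions meant for an exclusion list.
    """
    if not (0.0 <= overlap_rate <= 1.0):
        raise ValueError("overlap_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    domains = sorted(domainome.domains)
    hits_by_protein: dict[str, list[DomainHit]] = {}
    true_hits: list[tuple[str, DomainHit]] = []
    pid = 0
    i = 0
    lo, hi = domains_per_protein
    while i < len(domains):
        pid += 1
        protein = f"prot{pid:05d}"
        k = int(rng.integers(lo, hi + 1))
        batch = domains[i : i + k]
        i += k
        hits = []
        pos = 1
        for acc in batch:
            length = int(rng.integers(60, 200))
            ev = 10.0 ** float(rng.normal(*true_logE))
            ev = min(ev, 1e-6)  # keep true hits comfortably significant
            hit = DomainHit(
                protein_id=protein,
                domain_acc=acc,
                env_start=pos,
                env_end=pos + length - 1,
                i_evalue=ev,
                bit_score=float(ga_threshold + rng.uniform(10.0, 200.0)),
                ga=ga_threshold,
                nc=ga_threshold - 5.0,
                tc=ga_threshold + 5.0,
            )
            hits.append(hit)
            true_hits.append((protein, hit))
            pos = hit.env_end + int(rng.integers(2, 30))
        hits_by_protein[protein] = hits

    decoys: list[DomainHit] = []
    for j in range(decoy_count):
        protein, anchor = true_hits[int(rng.integers(len(true_hits)))]
        acc = f"DECOY{j + 1:04d}"
        ev = 10.0 ** float(rng.normal(*decoy_logE))
        ev = max(ev, anchor.i_evalue * 10.0)  # decoy never beats the true hit
        if rng.random() < overlap_rate:
            start = max(1, anchor.env_start + int(rng.integers(-10, 10)))
            end = max(start, anchor.env_end + int(rng.integers(-10, 10)))
            bit = float(ga_threshold + rng.uniform(1.0, 50.0))  # passes GA, loses on overlap
        else:
            start = anchor.env_end + 1000 + j * 500
            end = start + int(rng.integers(40, 120))
            bit = float(ga_threshold - rng.uniform(5.0, 20.0))  # fails GA
            ev = max(ev, 1e-3)
        decoy = DomainHit(
            protein_id=protein,
            domain_acc=acc,
            env_start=start,
            env_end=end,
            i_evalue=ev,
            bit_score=bit,
            ga=ga_threshold,
            nc=ga_threshold - 5.0,
            tc=ga_threshold + 5.0,
        )
        decoys.append(decoy)
        hits_by_protein[protein].append(decoy)

    excluded: set[str] = set()
    for j in range(excluded_injection):
        protein, anchor = true_hits[int(rng.integers(len(true_hits)))]
        acc = f"VIRAL{j + 1:04d}"
        excluded.add(acc)
        start = anchor.env_end + 5000 + j * 500
        hit = DomainHit(
            protein_id=protein,
            domain_acc=acc,
            env_start=start,
            env_end=start + 80,
            i_evalue=1e-30,
            bit_score=300.0,
            ga=ga_threshold,
            nc=ga_threshold - 5.0,
            tc=ga_threshold + 5.0,
        )
        hits_by_protein[protein].append(hit)

    return HitTableTruth(
        hits_by_protein=hits_by_protein,
        surviving_domains=set(domainome.domains),
        decoy_hits=decoys,
        excluded_accessions=excluded,
    )


def choose_plantable_term(dag: GoDag, gomap: DomainGoMap, min_pool: int = 15) -> str:
    """Pick the term best suited for planting a specific enrichment signal.

    Enrichment of a *specific* term means the signal concentrates in that
    term and not in its parents, so the chosen term is childless (most
    specific), has an annotation pool of at least ``min_pool`` domains
    (so a study can be drawn from it), and maximizes the ratio of its
    smallest parent's propagated pool to its own — i.e. its parents
    annotate much more than it does, leaving room for refinement.
    """
    pmap = propagate(dag, gomap)
    pool: dict[str, set[str]] = {}
    for d, ts in pmap.annotations.items():
        for t in ts:
            pool.setdefault(t, set()).add(d)
    kids = dag.children_map()
    candidates = []
    for t in dag.terms:
        if kids[t] or not dag.parents[t]:
            continue
        own = len(pool.get(t, ()))
        if own < min_pool:
            continue
        ratio = min(len(pool.get(p, ())) for p in dag.parents[t]) / own
        candidates.append((ratio, t))
    if not candidates:
        raise ValueError("no childless term with a large enough annotation pool")
    return max(candidates)[1]


def simulate_go(
    n_terms: int,
    depth: int,
    n_domains: int,
    planted: Mapping[str, float] | None = None,
    seed: int = 0,
    study_size: int = 30,
    background_rate: float = 0.05,
    namespace: str = "biological_process",
) -> tuple[GoDag, DomainGoMap, StudySet]:
    """Layered random DAG + uniform background annotations + planted study.

    The DAG has one namespace root and ``depth`` layers; every non-root
    term has 1-2 parents in earlier layers, so acyclicity holds by
    construction. Each non-root term annotates each domain directly with
    probability ``background_rate``. The study set of ``study_size``
    domains is drawn so that each planted term t receives a fraction
    ``planted[t]`` of study members from t's (propagated) annotation
    pool, the remainder uniformly from the population.
    """
    if n_terms < 2 or depth < 1:
        raise ValueError("need n_terms >= 2 and depth >= 1")
    planted = dict(planted or {})
    for t, f in planted.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"planted fraction for {t} must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    root = "GO:0000001"
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    layers: list[list[str]] = [[root]]
    rest = term_ids[1:]
    per_layer = max(1, math.ceil(len(rest) / depth))
    for d in range(depth):
        layer = rest[d * per_layer : (d + 1) * per_layer]
        if layer:
            layers.append(layer)
    terms = [GoTerm(t, name=f"term {t}", namespace=namespace) for t in term_ids]
    edges = []
    for li in range(1, len(layers)):
        pool = [t for lay in layers[:li] for t in lay]
        for t in layers[li]:
            n_par = int(rng.integers(1, 3)) if len(pool) > 1 else 1
            parents = rng.choice(len(pool), size=min(n_par, len(pool)), replace=False)
            for p in parents:
                edges.append((t, pool[int(p)]))
    dag = GoDag(terms, edges)
    for t in planted:
        if t not in dag:
            raise ValueError(f"planted term {t!r} not in generated DAG")

    domains = [f"PF{i + 1:05d}" for i in range(n_domains)]
    annotations: dict[str, set[str]] = {d: set() for d in domains}
    non_root = term_ids[1:]
    for d in domains:
        mask = rng.random(len(non_root)) < background_rate
        annotations[d] = {t for t, m in zip(non_root, mask) if m}
        if not annotations[d]:
            annotations[d] = {non_root[int(rng.integers(len(non_root)))]}
    gomap = DomainGoMap(annotations, dag)
    pmap = propagate(dag, gomap)

    pools = {
        t: sorted(d for d in domains if t in pmap.terms_for(d)) for t in planted
    }
    for t, pool in pools.items():
        if not pool:
            raise ValueError(f"planted term {t} annotates no domains; infeasible")

    study: list[str] = []
    chosen: set[str] = set()
    quota = {t: int(round(f * study_size)) for t, f in planted.items()}
    if sum(quota.values()) > study_size:
        raise ValueError("planted fractions sum to more than 1 study")
    for t in sorted(quota):
        pool = [d for d in pools[t] if d not in chosen]
        if len(pool) < quota[t]:
            raise ValueError(f"planted term {t} pool too small for its quota")
        pick = rng.choice(len(pool), size=quota[t], replace=False)
        for idx in pick:
            study.append(pool[int(idx)])
            chosen.add(pool[int(idx)])
    remaining = [d for d in domains if d not in chosen]
    n_fill = study_size - len(study)
    pick = rng.choice(len(remaining), size=n_fill, replace=False)
    for idx in pick:
        study.append(remaining[int(idx)])
    return dag, gomap, StudySet("synthetic study", study)
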