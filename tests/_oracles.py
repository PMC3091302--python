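"""Independent reference implementations used to check the package.

These are deliberately naive (enumeration, quadratic scans, log-space
summation) and share no code with the implementations they validate.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from domevol.tree import RootedTree, TreeNode


# -- Dollo brute force ---------------------------------------------------


def dollo_min_losses(tree: RootedTree, column: dict[str, int]) -> int:
    """Minimum loss count over ALL single-gain state assignments.

    Enumerates every assignment of presence states to internal nodes
    (leaves fixed by the column), keeps those with exactly one 0->1
    transition (counting an edge into the root's present state as the
    gain), and returns the minimal number of 1->0 transitions.
    """
    nodes = list(tree.preorder())
    index = {n.name: i for i, n in enumerate(nodes)}
    parent = [index[n.parent.name] if n.parent else -1 for n in nodes]
    leaf_bits = 0
    fixed_mask = 0
    for n in nodes:
        if n.is_leaf:
            fixed_mask |= 1 << index[n.name]
            if column[n.name]:
                leaf_bits |= 1 << index[n.name]
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf]
    best = None
    for bits in range(1 << len(internal)):
        mask = leaf_bits
        for j, i in enumerate(internal):
            if bits >> j & 1:
                mask |= 1 << i
        gains = losses = 0
        for i in range(len(nodes)):
            present = mask >> i & 1
            parent_present = mask >> parent[i] & 1 if parent[i] >= 0 else 0
            if present and not parent_present:
                gains += 1
            if parent_present and not present:
                losses += 1
        if gains == 1:
            if best is None or losses < best:
                best = losses
    assert best is not None, "no valid single-gain assignment found"
    return best


# -- rooted tree shape enumeration --------------------------------------


@lru_cache(maxsize=None)
def _shapes(n: int) -> tuple:
    """All rooted multifurcating tree shapes with n leaves, canonically
    encoded as nested sorted tuples ('leaf' for a single leaf)."""
    if n == 1:
        return ("leaf",)
    out = set()
    for parts in _partitions(n, n):
        if len(parts) < 2:
            continue
        for combo in itertools.product(*(_shapes(p) for p in parts)):
            out.add(tuple(sorted(combo, key=repr)))
    return tuple(sorted(out, key=repr))


def _partitions(n: int, cap: int):
    """Integer partitions of n with parts <= cap, non-increasing."""
    if n == 0:
        yield ()
        return
    for first in range(min(n, cap), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def all_tree_shapes(n_leaves: int) -> list[RootedTree]:
    """Every rooted (multifurcating) tree shape with exactly n labelled
    leaves, leaves labelled L1.. in a fixed traversal order."""
    trees = []
    for shape in _shapes(n_leaves):
        if shape == "leaf":
            continue
        counter = itertools.count(1)

        def build(s, parent):
            node = TreeNode("", parent)
            if s == "leaf":
                node.name = f"L{next(counter)}"
            else:
                node.children = [build(c, node) for c in s]
            return node

        trees.append(RootedTree(build(shape, None)))
    return trees


# -- overlap resolution, quadratic --------------------------------------


def resolve_overlaps_reference(hits):
    """Repeated-scan overlap resolution with the same priority order."""
    remaining = sorted(
        hits, key=lambda h: (h.i_evalue, -h.bit_score, h.domain_acc, h.env_start)
    )
    accepted = []
    while remaining:
        best = remaining.pop(0)
        accepted.append(best)
        remaining = [
            h
            for h in remaining
            if not (h.env_start <= best.env_end and best.env_start <= h.env_end)
        ]
    return sorted(accepted, key=lambda h: (h.env_start, h.env_end, h.domain_acc))


# -- hypergeometric tail in log space ------------------------------------


def hypergeom_sf_logspace(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by summation of exact pmf terms computed via lgamma."""

    def log_comb(a, b):
        if b < 0 or b > a:
            return -math.inf
        return (
            math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
        )

    denom = log_comb(N, n)
    total = 0.0
    for x in range(k, min(n, K) + 1):
        lp = log_comb(K, x) + log_comb(N - K, n - x) - denom
        if lp > -math.inf:
            total += math.exp(lp)
    return min(total, 1.0)


# -- BH step-up, quadratic ------------------------------------------------


def bh_reference(pvalues):
    """Benjamini-Hochberg adjusted p-values, direct step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


# -- transitive reachability on a DAG ------------------------------------


def reachable_ancestors(parents: dict[str, set[str]], start: str) -> set[str]:
    """All nodes reachable by repeatedly following parent links."""
    out, frontier = set(), {start}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    nxt.add(p)
        frontier = nxt
    return out
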