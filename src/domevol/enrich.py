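"""GO term enrichment of gained/lost domain sets.

Implements the exact one-sided hypergeometric (term-for-term) test and
two families of DAG-aware procedures:

* **elim** — terms are visited most-specific first; once a term is found
  significant, its annotated domains are removed from all of its
  ancestors' annotation sets before those are tested, so general terms
  are not dragged along by a specific signal below them.
* **parent-child** (union / intersection) — each term is tested against
  the annotation set of its parents rather than the whole population,
  asking whether the term is enriched *given* its parents.

The population defaults to all annotated domains present anywhere in the
analysis (restricted to those with GO annotations before any sizes are
computed); enrichment is conventionally run per namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gofunc import DomainGoMap, GoDag, propagate

__all__ = [
    "StudySet",
    "EnrichmentResult",
    "hypergeom_test",
    "term_for_term",
    "topology_elim",
    "parent_child",
    "adjust",
]

DEFAULT_ELIM_THRESHOLD = 0.01


@dataclass(frozen=True)
class StudySet:
    """A labelled set of domains whose functional makeup is being tested,
    e.g. the domains gained on one branch."""

    label: str
    domains: frozenset[str]

    def __init__(self, label: str, domains: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "domains", frozenset(domains))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    study_count: int
    population_count: int
    study_size: int
    population_size: int
    p_value: float
    adjusted_p: float | None = None
    method: str = "term_for_term"


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` study hits out of a study of size ``n``, drawn without
    replacement from a population of size ``N`` containing ``K`` hits.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _prepare(
    study: StudySet,
    population: Iterable[str],
    dag: GoDag,
    gomap: DomainGoMap,
    namespace: str | None,
    propagated: bool,
):
    """Propagate annotations, restrict study/population to annotated domains,
    and build term -> annotated-domain index."""
    pmap = gomap if propagated else propagate(dag, gomap)
    pop = {
        d
        for d in population
        if any(
            namespace is None or dag.namespace(t) == namespace
            for t in pmap.terms_for(d)
        )
        and pmap.terms_for(d)
    }
    stud = set(study.domains) & pop
    term_domains: dict[str, set[str]] = {}
    for d in pop:
        for t in pmap.terms_for(d):
            if namespace is None or dag.namespace(t) == namespace:
                term_domains.setdefault(t, set()).add(d)
    return pmap, stud, pop, term_domains


def _result(dag, t, k, K, n, N, p, method):
    return EnrichmentResult(
        term_id=t,
        term_name=dag.terms[t].name,
        study_count=k,
        population_count=K,
        study_size=n,
        population_size=N,
        p_value=p,
        method=method,
    )


def _sorted(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def term_for_term(
    study: StudySet,
    population: Iterable[str],
    dag: GoDag,
    gomap: DomainGoMap,
    namespace: str | None = None,
    propagated: bool = False,
) -> list[EnrichmentResult]:
    """Exact one-sided test of every term with population count >= 1."""
    _, stud, pop, term_domains = _prepare(
        study, population, dag, gomap, namespace, propagated
    )
    n, N = len(stud), len(pop)
    results = []
    for t, domains in term_domains.items():
        K = len(domains)
        k = len(domains & stud)
        results.append(
            _result(dag, t, k, K, n, N, hypergeom_test(k, n, K, N), "term_for_term")
        )
    return _sorted(results)


def topology_elim(
    study: StudySet,
    population: Iterable[str],
    dag: GoDag,
    gomap: DomainGoMap,
    sig_threshold: float = DEFAULT_ELIM_THRESHOLD,
    namespace: str | None = None,
    propagated: bool = False,
) -> list[EnrichmentResult]:
    """Elim procedure: specific-first testing with ancestor decontamination.

    Terms are processed in order of decreasing longest-path depth (ties
    broken by term id). A term found significant at ``sig_threshold``
    has its current annotated domains removed from every ancestor's
    annotation set before the ancestors are tested.
    """
    if not (0 < sig_threshold < 1):
        raise ValueError("sig_threshold must lie strictly in (0, 1)")
    _, stud, pop, term_domains = _prepare(
        study, population, dag, gomap, namespace, propagated
    )
    n, N = len(stud), len(pop)
    current = {t: set(d) for t, d in term_domains.items()}
    order = sorted(current, key=lambda t: (-dag.depth(t), t))
    results = []
    for t in order:
        domains = current[t]
        K = len(domains)
        k = len(domains & stud)
        p = hypergeom_test(k, n, K, N)
        results.append(_result(dag, t, k, K, n, N, p, "elim"))
        if p < sig_threshold:
            removed = set(term_domains[t])  # the term's own (original) annotations
            for anc in dag.ancestors(t):
                if anc in current:
                    current[anc] -= removed
    return _sorted(results)


def parent_child(
    study: StudySet,
    population: Iterable[str],
    dag: GoDag,
    gomap: DomainGoMap,
    mode: str = "union",
    namespace: str | None = None,
    propagated: bool = False,
) -> list[EnrichmentResult]:
    """Parent-child conditional test (union or intersection of parents).

    For a term with parents, the sampling universe is the set of domains
    annotated to the union (or intersection) of its parents; the test
    asks whether the term's annotations are over-represented in the
    study restricted to that universe. Root terms fall back to the
    term-for-term test.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    _, stud, pop, term_domains = _prepare(
        study, population, dag, gomap, namespace, propagated
    )
    n_all, N_all = len(stud), len(pop)
    method = "parent_child_union" if mode == "union" else "parent_child_intersection"
    results = []
    for t, domains in term_domains.items():
        parents = [p for p in dag.parents[t] if p in term_domains]
        if not parents:
            K = len(domains)
            k = len(domains & stud)
            p = hypergeom_test(k, n_all, K, N_all)
            results.append(_result(dag, t, k, K, n_all, N_all, p, method))
            continue
        parent_sets = [term_domains[p] for p in parents]
        if mode == "union":
            condition = set().union(*parent_sets)
        else:
            condition = set.intersection(*map(set, parent_sets))
        N = len(condition)
        K = len(condition & stud)
        n = len(domains & condition)
        k = len(domains & stud & condition)
        p = hypergeom_test(k, n, K, N) if N else 1.0
        results.append(_result(dag, t, k, n, K, N, p, method))
    return _sorted(results)


def adjust(
    results: Sequence[EnrichmentResult], method: str = "none"
) -> list[EnrichmentResult]:
    """Attach multiple-testing-adjusted p-values (none | bonferroni | bh)."""
    if method == "none":
        return [replace(r, adjusted_p=r.p_value) for r in results]
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction method {method!r}")
    if not results:
        return []
    raw = [r.p_value for r in results]
    sm_method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    _, adjusted, _, _ = multipletests(raw, method=sm_method)
    return [replace(r, adjusted_p=float(a)) for r, a in zip(results, adjusted)]
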