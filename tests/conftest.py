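import numpy as np
import pytest

from domevol.gofunc import GoDag, GoTerm
from domevol.hitfilter import DomainHit
from domevol.tree import RootedTree


@pytest.fixture
def quartet():
    """((A,B),(C,D)) with internal nodes N1 (root), N2, N3."""
    return RootedTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def small_dag():
    """Chain-plus-branch DAG:  root <- a <- b ;  root <- c ; a <- d (part_of)."""
    terms = [
        GoTerm("GO:0000001", "root"),
        GoTerm("GO:0000002", "a"),
        GoTerm("GO:0000003", "b"),
        GoTerm("GO:0000004", "c"),
        GoTerm("GO:0000005", "d"),
    ]
    edges = [
        ("GO:0000002", "GO:0000001"),
        ("GO:0000003", "GO:0000002"),
        ("GO:0000004", "GO:0000001"),
        ("GO:0000005", "GO:0000002"),
    ]
    return GoDag(terms, edges)


def make_hit(
    protein="p1",
    acc="PF00001",
    start=1,
    end=100,
    evalue=1e-10,
    bit=50.0,
    ga=25.0,
    nc=20.0,
    tc=30.0,
):
    return DomainHit(protein, acc, start, end, evalue, bit, ga, nc, tc)


def random_hits(rng, n, protein="p1", span=1000):
    hits = []
    for i in range(n):
        start = int(rng.integers(1, span))
        length = int(rng.integers(10, 120))
        hits.append(
            make_hit(
                protein=protein,
                acc=f"PF{int(rng.integers(1, 30)):05d}",
                start=start,
                end=start + length,
                evalue=float(10.0 ** rng.uniform(-20, 0)),
                bit=float(rng.uniform(5, 300)),
            )
        )
    return hits
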