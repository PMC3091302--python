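"""Domain repertoires and the taxon x domain presence/absence matrix.

A *domainome* is the set of distinct domain types encoded by a genome —
extant, ancestral, or a merged "meta-organism" (e.g. a host genome pooled
with its gut symbionts). Repertoires across genomes are assembled into a
binary presence matrix that drives ancestral reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Domainome", "PresenceMatrix", "build_matrix", "merge"]


@dataclass
class Domainome:
    """A labelled set of distinct domain accessions."""

    label: str
    domains: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.domains = set(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __contains__(self, accession: str) -> bool:
        return accession in self.domains

    def __or__(self, other: "Domainome") -> "Domainome":
        return Domainome(self.label, self.domains | other.domains)


class PresenceMatrix:
    """Binary taxon x domain matrix; columns absent everywhere are dropped.

    Backed by a pandas DataFrame (taxa as index, accessions as columns,
    int8 0/1 cells). Column order is lexicographic by accession; row
    order follows construction order.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate taxon labels: {dups}")
        vals = frame.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix cells must be 0 or 1")
        empty = [c for c in frame.columns if frame[c].sum() == 0]
        if empty:
            logger.warning(
                "dropping %d all-absent domain column(s): %s%s",
                len(empty),
                ", ".join(empty[:5]),
                "..." if len(empty) > 5 else "",
            )
            frame = frame.drop(columns=empty)
        self.frame = frame[sorted(frame.columns)].astype(np.int8)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    @property
    def domains(self) -> list[str]:
        return list(self.frame.columns)

    def column(self, accession: str) -> dict[str, int]:
        """Leaf -> 0/1 state for one domain."""
        return {t: int(v) for t, v in self.frame[accession].items()}

    def row_domainome(self, taxon: str) -> Domainome:
        row = self.frame.loc[taxon]
        return Domainome(taxon, set(row.index[row == 1]))

    def domainomes(self) -> list[Domainome]:
        return [self.row_domainome(t) for t in self.taxa]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        return cls(frame)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PresenceMatrix({len(self.taxa)} taxa x {len(self.domains)} domains)"


def build_matrix(domainomes: Sequence[Domainome]) -> PresenceMatrix:
    """Assemble repertoires into a presence/absence matrix.

    Taxon labels must be unique; domains present in no input are
    impossible by construction (every column comes from some repertoire).
    """
    labels = [d.label for d in domainomes]
    if len(set(labels)) != len(labels):
        seen, dups = set(), set()
        for lab in labels:
            (dups if lab in seen else seen).add(lab)
        raise ValueError(f"duplicate domainome labels: {sorted(dups)}")
    all_domains = sorted(set().union(*(d.domains for d in domainomes)) if domainomes else set())
    data = np.zeros((len(domainomes), len(all_domains)), dtype=np.int8)
    col_idx = {acc: j for j, acc in enumerate(all_domains)}
    for i, dome in enumerate(domainomes):
        for acc in dome.domains:
            data[i, col_idx[acc]] = 1
    frame = pd.DataFrame(data, index=labels, columns=all_domains)
    return PresenceMatrix(frame)


def merge(domainomes: Sequence[Domainome], label: str) -> Domainome:
    """Union of repertoires — a 'meta-organism' pooling host and symbionts."""
    if not domainomes:
        raise ValueError("merge requires at least one domainome")
    return Domainome(label, set().union(*(d.domains for d in domainomes)))
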