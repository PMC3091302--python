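"""Filtering of raw domain-hit tables into clean per-genome repertoires.

A genome's domain repertoire is obtained from a scored domain-hit table in
three stages: (1) significance filtering by a cutoff policy — either the
model-specific gathering (GA), noise (NC) or trusted (TC) bit-score
thresholds curated by the domain database, or a uniform independent
E-value threshold; (2) removal of accessions on an exclusion list
(typically domains of viral, phage or transposon origin); (3) per-protein
overlap resolution, keeping the lowest-E-value hit among mutually
overlapping matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .domainome import Domainome

__all__ = [
    "DomainHit",
    "CutoffMode",
    "CutoffPolicy",
    "ExclusionList",
    "strip_version",
    "apply_cutoffs",
    "remove_excluded",
    "resolve_overlaps",
    "build_domainome",
]

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(accession: str) -> str:
    """Drop a trailing ``.NN`` version suffix (``PF00069.21`` -> ``PF00069``)."""
    return _VERSION_RE.sub("", accession)


@dataclass(frozen=True)
class DomainHit:
    """One scored match of a domain model to a protein.

    Envelope coordinates are 1-based inclusive residue positions on the
    protein. ``ga``/``nc``/``tc`` are the optional per-domain bit-score
    thresholds (the domain-level member of each threshold pair).
    """

    protein_id: str
    domain_acc: str
    env_start: int
    env_end: int
    i_evalue: float
    bit_score: float
    ga: float | None = None
    nc: float | None = None
    tc: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "domain_acc", strip_version(self.domain_acc))
        if self.env_start < 1:
            raise ValueError(
                f"env_start must be >= 1, got {self.env_start} "
                f"({self.protein_id}/{self.domain_acc})"
            )
        if self.env_end < self.env_start:
            raise ValueError(
                f"env_end < env_start for {self.protein_id}/{self.domain_acc}"
            )
        if self.i_evalue < 0:
            raise ValueError(
                f"negative E-value for {self.protein_id}/{self.domain_acc}"
            )

    def overlaps(self, other: "DomainHit") -> bool:
        """True iff the envelopes share at least one residue position."""
        return self.env_start <= other.env_end and other.env_start <= self.env_end


class CutoffMode(str, Enum):
    GA = "GA"
    NC = "NC"
    TC = "TC"
    EVALUE = "EVALUE"


@dataclass(frozen=True)
class CutoffPolicy:
    """Hit significance policy: a per-domain score cutoff or a uniform E-value.

    ``evalue_threshold`` is required iff ``mode`` is EVALUE; thresholds
    anywhere in (0, inf) are accepted, covering the 1e-18..1e-4 grid and
    1e-8 commonly used in repertoire robustness scans.
    """

    mode: CutoffMode
    evalue_threshold: float | None = None

    def __post_init__(self):
        mode = CutoffMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is CutoffMode.EVALUE:
            if self.evalue_threshold is None:
                raise ValueError("EVALUE mode requires evalue_threshold")
            if self.evalue_threshold <= 0:
                raise ValueError("evalue_threshold must be positive")
        elif self.evalue_threshold is not None:
            raise ValueError(f"evalue_threshold is meaningless in {mode.value} mode")

    @classmethod
    def parse(cls, text: str) -> "CutoffPolicy":
        """Parse ``GA``/``NC``/``TC`` or ``evalue:<x>`` CLI syntax."""
        text = text.strip()
        if text.upper() in ("GA", "NC", "TC"):
            return cls(CutoffMode(text.upper()))
        if text.lower().startswith("evalue:"):
            return cls(CutoffMode.EVALUE, float(text.split(":", 1)[1]))
        raise ValueError(f"unrecognized cutoff spec {text!r}")


class ExclusionList:
    """Set of domain accessions to drop, with an optional reason per entry.

    Membership is exact string match on version-stripped accessions.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[str] = ()):
        if isinstance(entries, Mapping):
            items = entries.items()
        else:
            items = ((acc, "") for acc in entries)
        self.reasons: dict[str, str] = {
            strip_version(acc): reason for acc, reason in items
        }

    def __contains__(self, accession: str) -> bool:
        return strip_version(accession) in self.reasons

    def __len__(self) -> int:
        return len(self.reasons)

    def __iter__(self):
        return iter(self.reasons)


def apply_cutoffs(
    hits: Sequence[DomainHit], policy: CutoffPolicy
) -> list[DomainHit]:
    """Keep exactly the hits passing the policy, preserving input order.

    GA/NC/TC modes keep a hit iff its bit score is >= the hit's
    domain-level threshold of that kind; EVALUE mode keeps a hit iff its
    independent E-value is <= the threshold.
    """
    if policy.mode is CutoffMode.EVALUE:
        thr = policy.evalue_threshold
        return [h for h in hits if h.i_evalue <= thr]
    attr = policy.mode.value.lower()
    kept = []
    for h in hits:
        cutoff = getattr(h, attr)
        if cutoff is None:
            raise ValueError(
                f"hit {h.protein_id}/{h.domain_acc} lacks a {policy.mode.value} "
                f"threshold required by the cutoff policy"
            )
        if cutoff < 0:
            raise ValueError(
                f"negative {policy.mode.value} threshold for "
                f"{h.protein_id}/{h.domain_acc}"
            )
        if h.bit_score >= cutoff:
            kept.append(h)
    return kept


def remove_excluded(
    hits: Sequence[DomainHit], excl: ExclusionList
) -> list[DomainHit]:
    """Drop hits whose accession is on the exclusion list (order preserved)."""
    return [h for h in hits if h.domain_acc not in excl]


def _priority(hit: DomainHit):
    return (hit.i_evalue, -hit.bit_score, hit.domain_acc, hit.env_start)


def resolve_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy overlap resolution within one protein: lowest E-value wins.

    Candidates are ranked by (E-value asc, bit score desc, accession asc,
    start asc) and accepted iff they overlap no already-accepted hit, so
    the result is independent of input order. Returned hits are sorted by
    envelope start.
    """
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(
            f"resolve_overlaps expects hits from one protein, got {sorted(proteins)}"
        )
    accepted: list[DomainHit] = []
    for hit in sorted(hits, key=_priority):
        if not any(hit.overlaps(a) for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: (h.env_start, h.env_end, h.domain_acc))
    return accepted


def build_domainome(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    policy: CutoffPolicy,
    excl: ExclusionList | None = None,
    label: str = "genome",
) -> Domainome:
    """Full per-genome filtering pipeline -> set of distinct accessions.

    Applies cutoff filtering, exclusion removal and per-protein overlap
    resolution, then collapses surviving hits to the set of distinct
    domain accessions (copy number is discarded).
    """
    excl = excl if excl is not None else ExclusionList()
    domains: set[str] = set()
    for protein_id, hits in hits_by_protein.items():
        try:
            clean = apply_cutoffs(hits, policy)
            clean = remove_excluded(clean, excl)
            clean = resolve_overlaps(clean)
        except ValueError as exc:
            raise ValueError(f"protein {protein_id!r}: {exc}") from exc
        domains.update(h.domain_acc for h in clean)
    return Domainome(label, domains)
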