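"""Readers and writers for the pipeline's on-disk formats.

Formats covered: HMMER3 per-domain tabular output (domtblout) and a
minimal 7-column TSV hit dialect; exclusion lists; per-genome domainome
files and presence-matrix TSV; Newick and property-annotated phyloXML
trees; OBO 1.2 ontologies; pfam2go-style external2go mappings; ledger,
profile, flux and enrichment TSV exports.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import obonet
import pandas as pd
from Bio import Phylo
from Bio.Phylo import PhyloXML

from .dollo import EventLedger
from .domainome import Domainome
from .enrich import EnrichmentResult
from .gofunc import DomainGoMap, FluxResult, FunctionalProfile, GoDag, GoTerm
from .hitfilter import DomainHit, ExclusionList, strip_version
from .tree import RootedTree

logger = logging.getLogger(__name__)

__all__ = [
    "read_domtbl",
    "read_hits_tsv",
    "write_hits_tsv",
    "read_exclusion_list",
    "read_domainome",
    "write_domainome",
    "read_newick",
    "write_newick",
    "write_phyloxml",
    "read_obo",
    "read_external2go",
    "write_external2go",
    "write_ledger_tsv",
    "write_profiles_tsv",
    "write_flux_tsv",
    "write_enrichment_tsv",
]


def _open(path, mode="r"):
    return open(path, mode, encoding="utf-8")


# -- hit tables ----------------------------------------------------------


def read_domtbl(path) -> dict[str, list[DomainHit]]:
    """Parse HMMER3 per-domain tabular output (hmmscan domtblout dialect).

    Column layout (0-based): 0 target name, 1 target accession, 3 query
    name, 12 independent E-value, 13 domain score, 19-20 envelope
    from/to. With hmmscan the target is the domain model and the query
    is the protein. GA/NC/TC thresholds are not part of domtblout.
    """
    hits: dict[str, list[DomainHit]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 22 domtblout columns, "
                    f"got {len(fields)}"
                )
            try:
                acc = fields[1] if fields[1] != "-" else fields[0]
                hit = DomainHit(
                    protein_id=fields[3],
                    domain_acc=strip_version(acc),
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                    i_evalue=float(fields[12]),
                    bit_score=float(fields[13]),
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            hits.setdefault(hit.protein_id, []).append(hit)
    return hits


_TSV_COLUMNS = (
    "protein_id",
    "domain_acc",
    "env_start",
    "env_end",
    "i_evalue",
    "bit_score",
    "ga_dom",
)


def read_hits_tsv(path) -> dict[str, list[DomainHit]]:
    """Minimal hit TSV: 7 required columns plus optional nc_dom / tc_dom.

    A header line naming the columns is accepted and skipped; threshold
    fields may be empty or '-' for unavailable.
    """

    def opt(v: str) -> float | None:
        return None if v in ("", "-", "NA", "nan") else float(v)

    hits: dict[str, list[DomainHit]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "protein_id":
                continue
            if len(fields) < 7:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 7 tab-separated columns"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain_acc=fields[1],
                    env_start=int(fields[2]),
                    env_end=int(fields[3]),
                    i_evalue=float(fields[4]),
                    bit_score=float(fields[5]),
                    ga=opt(fields[6]),
                    nc=opt(fields[7]) if len(fields) > 7 else None,
                    tc=opt(fields[8]) if len(fields) > 8 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
            hits.setdefault(hit.protein_id, []).append(hit)
    return hits


def write_hits_tsv(hits_by_protein: dict[str, list[DomainHit]], path) -> None:
    with _open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS + ("nc_dom", "tc_dom")) + "\n")
        for protein in sorted(hits_by_protein):
            for h in sorted(
                hits_by_protein[protein], key=lambda h: (h.env_start, h.domain_acc)
            ):
                row = [
                    h.protein_id,
                    h.domain_acc,
                    str(h.env_start),
                    str(h.env_end),
                    repr(h.i_evalue),
                    repr(h.bit_score),
                    "-" if h.ga is None else repr(h.ga),
                    "-" if h.nc is None else repr(h.nc),
                    "-" if h.tc is None else repr(h.tc),
                ]
                fh.write("\t".join(row) + "\n")


def read_exclusion_list(path) -> ExclusionList:
    """One accession per line, optional tab-separated reason, '#' comments."""
    entries: dict[str, str] = {}
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            entries[parts[0]] = parts[1] if len(parts) > 1 else ""
    return ExclusionList(entries)


# -- domainomes ----------------------------------------------------------


def read_domainome(path, label: str | None = None) -> Domainome:
    """One accession per line; label defaults to the file stem."""
    path = Path(path)
    domains = set()
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                domains.add(strip_version(line.split("\t")[0]))
    return Domainome(label or path.stem, domains)


def write_domainome(domainome: Domainome, path) -> None:
    with _open(path, "w") as fh:
        for acc in sorted(domainome.domains):
            fh.write(acc + "\n")


# -- trees ---------------------------------------------------------------


def read_newick(path) -> RootedTree:
    with _open(path) as fh:
        return RootedTree.from_newick(fh.read())


def write_newick(tree: RootedTree, path) -> None:
    with _open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_phyloxml(
    tree: RootedTree,
    ledger: EventLedger,
    path,
    include_domain_lists: bool = False,
) -> None:
    """Annotated phyloXML export: per-node present counts and per-branch
    gained/lost counts (optionally full domain lists) as property elements,
    viewable in Archaeopteryx-style browsers."""

    def prop(name: str, value, datatype="xsd:int") -> PhyloXML.Property:
        return PhyloXML.Property(
            value=str(value),
            ref=f"domevol:{name}",
            applies_to="clade",
            datatype=datatype,
        )

    def convert(node) -> PhyloXML.Clade:
        clade = PhyloXML.Clade(name=node.name)
        props = [prop("present_count", len(ledger.present[node.name]))]
        if node.parent is not None:
            props.append(prop("gained_count", len(ledger.gained[node.name])))
            props.append(prop("lost_count", len(ledger.lost[node.name])))
            if include_domain_lists:
                # empty text elements are invalid for some phyloXML parsers
                if ledger.gained[node.name]:
                    props.append(
                        prop(
                            "gained_domains",
                            " ".join(sorted(ledger.gained[node.name])),
                            datatype="xsd:string",
                        )
                    )
                if ledger.lost[node.name]:
                    props.append(
                        prop(
                            "lost_domains",
                            " ".join(sorted(ledger.lost[node.name])),
                            datatype="xsd:string",
                        )
                    )
        clade.properties = props
        clade.clades = [convert(c) for c in node.children]
        return clade

    phylo = PhyloXML.Phylogeny(root=convert(tree.root), rooted=True)
    phylo.name = "domain gains and losses"
    with _open(path, "w") as fh:
        Phylo.write([phylo], fh, "phyloxml")


def read_phyloxml_properties(path) -> dict[str, dict[str, str]]:
    """Read back clade-name -> {property ref suffix: value} from phyloXML."""
    phylo = Phylo.read(str(path), "phyloxml")
    out: dict[str, dict[str, str]] = {}
    for clade in phylo.find_clades():
        if clade.name is None:
            continue
        props = {}
        for p in getattr(clade, "properties", []) or []:
            props[p.ref.split(":", 1)[1]] = p.value
        out[clade.name] = props
    return out


# -- ontology & mapping --------------------------------------------------


def read_obo(path) -> GoDag:
    """Minimal OBO 1.2 ontology load: id, name, namespace, is_a,
    relationship: part_of, is_obsolete. Cycles raise at load."""
    graph = obonet.read_obo(str(path))
    terms = []
    edges = []
    for node, data in graph.nodes(data=True):
        terms.append(
            GoTerm(
                id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", "biological_process"),
                obsolete=data.get("is_obsolete", "false") in ("true", True),
            )
        )
    for child, parent, key in graph.edges(keys=True):
        if key in ("is_a", "part_of"):
            edges.append((child, parent))
    return GoDag(terms, edges)


def read_external2go(path, dag: GoDag) -> DomainGoMap:
    """pfam2go/external2go line format:
    ``Pfam:PF00069 Pkinase > GO:protein kinase activity ; GO:0004672``."""
    annotations: dict[str, set[str]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            try:
                left, right = line.split(">", 1)
                acc = strip_version(left.split()[0].split(":", 1)[1])
                term = right.rsplit(";", 1)[1].strip()
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed mapping line") from exc
            annotations.setdefault(acc, set()).add(term)
    return DomainGoMap(annotations, dag)


def write_external2go(gomap: DomainGoMap, path) -> None:
    with _open(path, "w") as fh:
        fh.write("!generated mapping\n")
        for acc in sorted(gomap.annotations):
            for term in sorted(gomap.annotations[acc]):
                name = gomap.dag.terms[term].name or term
                fh.write(f"Pfam:{acc} {acc} > GO:{name} ; {term}\n")


# -- tabular exports -----------------------------------------------------


def write_ledger_tsv(ledger: EventLedger, out_prefix) -> list[Path]:
    """Write per-branch events and per-node sizes; returns written paths.

    ``<prefix>_branches.tsv``: child node, gained/lost counts, domain lists.
    ``<prefix>_nodes.tsv``: node, present count.
    ``<prefix>_root.tsv``: the root's ancestral-stock domain list.
    """
    out_prefix = Path(out_prefix)
    branches = out_prefix.parent / (out_prefix.name + "_branches.tsv")
    nodes = out_prefix.parent / (out_prefix.name + "_nodes.tsv")
    rootf = out_prefix.parent / (out_prefix.name + "_root.tsv")
    order = [n.name for n in ledger.tree.preorder()]
    with _open(branches, "w") as fh:
        fh.write("branch_child\tn_gained\tn_lost\tgained\tlost\n")
        for name in order:
            if name not in ledger.gained:
                continue
            fh.write(
                "\t".join(
                    [
                        name,
                        str(len(ledger.gained[name])),
                        str(len(ledger.lost[name])),
                        ",".join(sorted(ledger.gained[name])),
                        ",".join(sorted(ledger.lost[name])),
                    ]
                )
                + "\n"
            )
    with _open(nodes, "w") as fh:
        fh.write("node\tn_present\n")
        for name in order:
            fh.write(f"{name}\t{len(ledger.present[name])}\n")
    with _open(rootf, "w") as fh:
        for acc in sorted(ledger.root_present):
            fh.write(acc + "\n")
    return [branches, nodes, rootf]


def write_profiles_tsv(profiles: Sequence[FunctionalProfile], path) -> None:
    terms = sorted(profiles[0].fractions) if profiles else []
    with _open(path, "w") as fh:
        fh.write("label\t" + "\t".join(terms) + "\n")
        for p in profiles:
            cells = [
                "NA" if p.fractions[t] is None else f"{p.fractions[t]:.6f}"
                for t in terms
            ]
            fh.write(p.label + "\t" + "\t".join(cells) + "\n")


def write_flux_tsv(flux: FluxResult, path) -> None:
    with _open(path, "w") as fh:
        fh.write("branch_child\tcategory\tgained\tlost\n")
        for b, g, l in zip(flux.branches, flux.gains_per_branch, flux.losses_per_branch):
            fh.write(f"{b}\t{flux.category}\t{g}\t{l}\n")
        fh.write(
            f"#mean\t{flux.category}\t{flux.mean_gains:.6f}\t{flux.mean_losses:.6f}\n"
        )


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with _open(path, "w") as fh:
        fh.write(
            "term_id\tterm_name\tstudy_count\tpopulation_count\t"
            "study_size\tpopulation_size\tp_value\tadjusted_p\tmethod\n"
        )
        for r in results:
            adj = "NA" if r.adjusted_p is None else f"{r.adjusted_p:.6g}"
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.study_count}\t{r.population_count}\t"
                f"{r.study_size}\t{r.population_size}\t{r.p_value:.6g}\t{adj}\t{r.method}\n"
            )
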