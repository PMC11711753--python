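"""KEGG KGML import: parse pathway XML and normalize into a PathwaySkeleton.

KGML distinguishes four node types (gene, ortholog, compound, map) and two
edge classes: *relations* (exactly two endpoints, with subtypes such as
activation or phosphorylation) and *reactions* (many-to-many, with substrate
and product lists).  Normalization collapses gene and ortholog into a single
``gene_protein`` node type, renames map to ``pathway``, expands every
reaction into one edge per substrate-product pair, and merges the
indirect/indirect-effect and inhibition/repression subtype pairs.

Identifier mapping (KEGG id -> UniProt accession -> gene name) is a purely
offline, two-stage lookup table so imports are hermetic; missing keys leave a
node with empty accessions and a KEGG-id label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Union
from xml.etree.ElementTree import ParseError

from Bio.KEGG.KGML.KGML_parser import read as _kgml_read

from .model import (
    PathwaySkeleton,
    SkeletonEdge,
    SkeletonNode,
    SkippedPathway,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Vocabulary tables

#: KGML relation subtype -> unified subtype.  The two documented merges are
#: indirect/"indirect effect" -> indirect and inhibition/repression ->
#: inhibition; every other subtype passes through verbatim.  19 entries
#: mapping onto 17 unified subtypes.
KGML_RELATION_SUBTYPES: dict[str, str] = {
    "compound": "compound",
    "hidden compound": "hidden compound",
    "activation": "activation",
    "inhibition": "inhibition",
    "repression": "inhibition",
    "expression": "expression",
    "indirect": "indirect",
    "indirect effect": "indirect",
    "state change": "state change",
    "binding/association": "binding/association",
    "dissociation": "dissociation",
    "missing interaction": "missing interaction",
    "phosphorylation": "phosphorylation",
    "dephosphorylation": "dephosphorylation",
    "glycosylation": "glycosylation",
    "ubiquitination": "ubiquitination",
    "methylation": "methylation",
    "demethylation": "demethylation",
    "sumoylation": "sumoylation",
}

#: KGML entry type -> unified node type.  gene and ortholog collapse into
#: gene_protein; map becomes pathway; compound is unchanged.
KGML_NODE_TYPES: dict[str, str] = {
    "gene": "gene_protein",
    "ortholog": "gene_protein",
    "compound": "compound",
    "map": "pathway",
    "group": "group",
}


def map_kegg_types(
    kegg_node_type: str | None = None, kegg_relation_subtype: str | None = None
) -> tuple[str | None, str | None]:
    """Map a KGML node type and/or relation subtype into the unified vocabulary.

    Unknown node types normalize to ``misc``; unknown relation subtypes are
    retained verbatim (they will render with the generic edge style), both
    with a logged warning.
    """
    node_type = None
    if kegg_node_type is not None:
        node_type = KGML_NODE_TYPES.get(kegg_node_type)
        if node_type is None:
            logger.warning("unknown KGML entry type %r; recording as misc", kegg_node_type)
            node_type = "misc"
    subtype = None
    if kegg_relation_subtype is not None:
        subtype = KGML_RELATION_SUBTYPES.get(kegg_relation_subtype)
        if subtype is None:
            logger.warning(
                "unknown KGML relation subtype %r; retained verbatim", kegg_relation_subtype
            )
            subtype = kegg_relation_subtype
    return node_type, subtype


# ---------------------------------------------------------------------------
# Identifier mapping


@dataclass
class IdMappingTable:
    """Two-stage offline identifier mapping.

    ``to_uniprot`` maps a source identifier (KEGG gene id, Entrez, Ensembl,
    HGNC symbol, ...) to one or more UniProt accessions; ``uniprot_to_gene``
    maps an accession to its primary gene name.  Lookups are total: a missing
    key yields an empty result, never an exception, and no network access
    ever happens.
    """

    to_uniprot: dict[str, list[str]] = field(default_factory=dict)
    uniprot_to_gene: dict[str, str] = field(default_factory=dict)

    def accessions(self, source_id: str) -> list[str]:
        return list(self.to_uniprot.get(source_id, ()))

    def gene_name(self, accession: str) -> str | None:
        return self.uniprot_to_gene.get(accession)

    def map_id(self, source_id: str) -> tuple[list[str], list[str]]:
        """Return (accessions, gene names) for one source identifier."""
        accs = self.accessions(source_id)
        genes = []
        for acc in accs:
            g = self.gene_name(acc)
            if g and g not in genes:
                genes.append(g)
        return accs, genes

    @classmethod
    def from_tsv(
        cls,
        to_uniprot: Union[str, Path, IO[str], None] = None,
        uniprot_to_gene: Union[str, Path, IO[str], None] = None,
    ) -> "IdMappingTable":
        """Load from two 2-column TSV files (source_id<TAB>uniprot and
        uniprot<TAB>gene_name); multiple accessions per id appear as
        repeated rows."""
        table = cls()
        if to_uniprot is not None:
            for sid, acc in _iter_tsv(to_uniprot):
                table.to_uniprot.setdefault(sid, []).append(acc)
        if uniprot_to_gene is not None:
            for acc, gene in _iter_tsv(uniprot_to_gene):
                table.uniprot_to_gene[acc] = gene
        return table


def _iter_tsv(source: Union[str, Path, IO[str]]):
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        for line_no, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"mapping TSV line {line_no}: expected 2 tab-separated columns")
            yield parts[0], parts[1]
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Intermediate KGML records


@dataclass(frozen=True)
class KgmlEntry:
    entry_id: str
    kegg_type: str  # gene | ortholog | compound | map | group | other
    kegg_ids: tuple[str, ...] = ()
    label: str = ""
    x: float | None = None
    y: float | None = None
    components: tuple[str, ...] = ()


@dataclass(frozen=True)
class KgmlReaction:
    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool = False


def expand_reaction(reaction: KgmlReaction, edge_id_prefix: str = "") -> list[SkeletonEdge]:
    """Replace a many-to-many reaction with one edge per substrate-product pair.

    Emits exactly ``|substrates| x |products|`` directed edges
    (substrate -> product).  Reversible reactions keep a single edge per pair
    carrying a ``reversible`` marker in relation_types rather than a
    duplicate back-edge.
    """
    types = frozenset({"reaction", "reversible"} if reaction.reversible else {"reaction"})
    edges = []
    n = 0
    for s in reaction.substrates:
        for p in reaction.products:
            edges.append(
                SkeletonEdge(
                    edge_id=f"{edge_id_prefix}{reaction.reaction_id}_{n}",
                    source=s,
                    target=p,
                    relation_types=types,
                )
            )
            n += 1
    return edges


# ---------------------------------------------------------------------------
# Parsing


class KgmlParseError(ValueError):
    """Malformed KGML input (with line information where available)."""


def parse_kgml(
    document: Union[str, Path, IO[str]], mapping: IdMappingTable | None = None
) -> PathwaySkeleton | SkippedPathway:
    """Parse one KGML document into a PathwaySkeleton.

    Pathways without any gene or gene-product node are not imported; they
    yield a :class:`SkippedPathway` outcome rather than an error.
    """
    mapping = mapping or IdMappingTable()
    text = _read_text(document)
    try:
        pathway = _kgml_read(StringIO(text))
    except ParseError as exc:
        raise KgmlParseError(f"malformed KGML at line {exc.position[0]}: {exc}") from exc

    entries = _collect_entries(pathway)
    reactions = _collect_reactions(pathway)

    nodes: list[SkeletonNode] = []
    for entry in entries:
        nodes.append(_entry_to_node(entry, mapping))

    edges: list[SkeletonEdge] = []
    for i, rel in enumerate(pathway.relations):
        subtypes = [name for name, _value in getattr(rel, "subtypes", [])]
        unified = frozenset(map_kegg_types(None, s)[1] for s in subtypes) or frozenset({"relation"})
        edges.append(
            SkeletonEdge(
                edge_id=f"rel{i}",
                source=str(rel.entry1.id),
                target=str(rel.entry2.id),
                relation_types=unified,
            )
        )
    for reaction in reactions:
        edges.extend(expand_reaction(reaction, edge_id_prefix="rxn_"))

    name = getattr(pathway, "title", "") or ""
    pathway_id = (pathway.name or "").removeprefix("path:")
    skeleton = PathwaySkeleton(
        pathway_id=pathway_id,
        name=name,
        organism=pathway.org or "",
        source_db="kegg",
        nodes=nodes,
        edges=edges,
    )
    if not skeleton.gene_protein_nodes():
        return SkippedPathway(pathway_id=pathway_id, name=name)
    return skeleton


def _read_text(document: Union[str, Path, IO[str]]) -> str:
    if isinstance(document, Path):
        return document.read_text()
    if isinstance(document, str):
        return document if document.lstrip().startswith("<") else Path(document).read_text()
    return document.read()


def _collect_entries(pathway) -> list[KgmlEntry]:
    entries = []
    for eid in sorted(pathway.entries):
        e = pathway.entries[eid]
        graphics = e.graphics[0] if e.graphics else None
        with warnings.catch_warnings():
            # Biopython warns when graphics coordinates are absent
            warnings.simplefilter("ignore")
            x = getattr(graphics, "x", None) if graphics is not None else None
            y = getattr(graphics, "y", None) if graphics is not None else None
        label = getattr(graphics, "name", "") if graphics is not None else ""
        entries.append(
            KgmlEntry(
                entry_id=str(e.id),
                kegg_type=e.type,
                kegg_ids=tuple((e.name or "").split()),
                label=label or "",
                x=float(x) if x is not None else None,
                y=float(y) if y is not None else None,
                components=tuple(str(c.id) for c in getattr(e, "components", [])),
            )
        )
    return entries


def _collect_reactions(pathway) -> list[KgmlReaction]:
    reactions = []
    for rx in pathway.reactions:
        reactions.append(
            KgmlReaction(
                reaction_id=str(rx.id),
                substrates=tuple(str(s.id) for s in rx.substrates),
                products=tuple(str(p.id) for p in rx.products),
                reversible=(rx.type == "reversible"),
            )
        )
    return reactions


def _entry_to_node(entry: KgmlEntry, mapping: IdMappingTable) -> SkeletonNode:
    node_type, _ = map_kegg_types(entry.kegg_type, None)
    if node_type == "group":
        return SkeletonNode(node_id=entry.entry_id, node_type="group", members=entry.components)

    accessions: list[str] = []
    genes: list[str] = []
    for kegg_id in entry.kegg_ids:
        accs, gns = mapping.map_id(kegg_id)
        for a in accs:
            if a not in accessions:
                accessions.append(a)
        for g in gns:
            if g not in genes:
                genes.append(g)
    # one node per entry even if it lists several KEGG gene ids: the node
    # carries all accessions/gene names; label = first mapped gene name with
    # graceful fallbacks to the KGML graphics label or raw KEGG id.
    if genes:
        label = genes[0]
    elif entry.label:
        label = entry.label.split(",")[0].strip().removeprefix("TITLE:")
    elif entry.kegg_ids:
        label = entry.kegg_ids[0]
    else:
        label = entry.entry_id
    return SkeletonNode(
        node_id=entry.entry_id,
        node_type=node_type or "misc",
        label=label,
        uniprot_accessions=tuple(accessions),
        gene_names=tuple(genes),
        x=entry.x,
        y=entry.y,
    )
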