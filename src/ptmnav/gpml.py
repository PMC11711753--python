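"""WikiPathways GPML import: parse, resolve anchors, normalize node/edge types.

GPML pathways are community-curated and far less standardized than KEGG's.
The importer maps the 13 GPML node kinds onto the four unified node types
(gene_protein, compound, pathway, plus ``misc`` for everything that fits no
other category), converts 10 of the 24 GPML edge types into KEGG-derived
relation subtypes and retains the other 14 verbatim, and replaces GPML
*anchor* constructs (an interaction terminating on another interaction) with
edges whose endpoint is an edge id.

The mapping tables below follow the GPML 2013a schema vocabulary; exact
membership of the mapped-versus-retained partition is a documented design
choice of this package (see docs/methods.md).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

from .kgml import IdMappingTable
from .model import PathwaySkeleton, SkeletonEdge, SkeletonNode, SkippedPathway

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Vocabulary tables

#: 13 GPML node kinds -> 4 unified node types.
GPML_NODE_TYPES: dict[str, str] = {
    "GeneProduct": "gene_protein",
    "Protein": "gene_protein",
    "Rna": "gene_protein",
    "Metabolite": "compound",
    "Pathway": "pathway",
    "Complex": "misc",
    "Unknown": "misc",
    "CellularComponent": "misc",
    "Event": "misc",
    "Organelle": "misc",
    "Cell": "misc",
    "Label": "misc",
    "Shape": "misc",
}

#: 24 GPML edge (arrowhead) types: 10 convert into KEGG-derived subtypes,
#: 14 are retained verbatim as additional subtypes.
GPML_EDGE_TYPES: dict[str, str] = {
    # mapped onto KEGG-derived subtypes (10)
    "Arrow": "activation",
    "mim-stimulation": "activation",
    "mim-necessary-stimulation": "activation",
    "TBar": "inhibition",
    "mim-inhibition": "inhibition",
    "mim-binding": "binding/association",
    "mim-covalent-bond": "binding/association",
    "mim-transcription-translation": "expression",
    "mim-modification": "state change",
    "mim-conversion": "state change",
    # retained verbatim (14)
    "Line": "Line",
    "GraphicalLine": "GraphicalLine",
    "Receptor": "Receptor",
    "LigandSquare": "LigandSquare",
    "ReceptorSquare": "ReceptorSquare",
    "LigandRound": "LigandRound",
    "ReceptorRound": "ReceptorRound",
    "mim-catalysis": "mim-catalysis",
    "mim-cleavage": "mim-cleavage",
    "mim-branching-left": "mim-branching-left",
    "mim-branching-right": "mim-branching-right",
    "mim-gap": "mim-gap",
    "mim-translocation": "mim-translocation",
    "mim-dissociation": "mim-dissociation",
}

#: retained (non-KEGG) edge types, i.e. table values outside the KEGG-derived
#: subtype vocabulary.
GPML_RETAINED_EDGE_TYPES = frozenset(k for k, v in GPML_EDGE_TYPES.items() if k == v)


def map_gpml_types(
    gpml_node_type: str | None = None, gpml_edge_type: str | None = None
) -> tuple[str | None, str | None]:
    """Map a GPML node kind and/or edge type into the unified vocabulary.

    Unknown node kinds become ``misc``; unknown edge types are retained
    verbatim, both with a logged warning.
    """
    node_type = None
    if gpml_node_type is not None:
        node_type = GPML_NODE_TYPES.get(gpml_node_type)
        if node_type is None:
            logger.warning("unknown GPML node kind %r; recording as misc", gpml_node_type)
            node_type = "misc"
    subtype = None
    if gpml_edge_type is not None:
        subtype = GPML_EDGE_TYPES.get(gpml_edge_type)
        if subtype is None:
            logger.warning("unknown GPML edge type %r; retained verbatim", gpml_edge_type)
            subtype = gpml_edge_type
    return node_type, subtype


# ---------------------------------------------------------------------------
# Intermediate records


@dataclass(frozen=True)
class GpmlElement:
    graph_id: str
    gpml_node_type: str
    label: str = ""
    xref: tuple[str, str] | None = None  # (database, identifier)
    x: float | None = None
    y: float | None = None
    group_ref: str | None = None


@dataclass(frozen=True)
class GpmlInteraction:
    edge_id: str
    start_ref: str | None  # node graph_id or anchor id
    end_ref: str | None
    arrowhead: str = "Line"
    anchor_ids: tuple[str, ...] = ()  # anchors declared on this interaction


def resolve_anchors(interactions: list[GpmlInteraction]) -> list[SkeletonEdge]:
    """Convert interactions into skeleton edges, replacing anchors with
    edge-on-edge endpoint references.

    An endpoint that names an anchor declared on interaction *I* becomes an
    endpoint reference to *I*'s edge id; the anchor construct itself
    disappears.  Edge count is preserved.  An anchor reference that names no
    known interaction raises ``ValueError``.
    """
    anchor_owner: dict[str, str] = {}
    for inter in interactions:
        for aid in inter.anchor_ids:
            anchor_owner[aid] = inter.edge_id

    edges = []
    for inter in interactions:
        endpoints = []
        for ref in (inter.start_ref, inter.end_ref):
            if ref is None:
                endpoints.append(None)
            else:
                endpoints.append(anchor_owner.get(ref, ref))
        _, subtype = map_gpml_types(None, inter.arrowhead)
        edges.append(
            SkeletonEdge(
                edge_id=inter.edge_id,
                source=endpoints[0] if endpoints[0] is not None else "",
                target=endpoints[1] if endpoints[1] is not None else "",
                relation_types=frozenset({subtype}),
            )
        )
    return edges


# ---------------------------------------------------------------------------
# Parsing


class GpmlParseError(ValueError):
    """Malformed GPML input."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


#: xref database priority for UniProt unification; anything else falls back
#: to a plain table lookup of the raw identifier.
_XREF_PRIORITY = ("uniprot", "entrez", "ensembl", "hgnc")


def parse_gpml(
    document: Union[str, Path, IO[str]], mapping: IdMappingTable | None = None
) -> PathwaySkeleton | SkippedPathway:
    """Parse one GPML document into a PathwaySkeleton.

    DataNodes, Labels, Shapes and Groups become nodes; Interactions (and
    GraphicalLines) become edges; anchors are resolved into edge-on-edge
    references.  Pathways without a gene_protein node are reported as
    skipped.  GPML ``State`` decorations are ignored: PTMs enter the graph
    from experimental data during projection, not from the diagram.
    """
    mapping = mapping or IdMappingTable()
    text = _read_text(document)
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise GpmlParseError(f"malformed GPML at line {exc.position[0]}: {exc}") from exc

    name = root.get("Name", "")
    organism = root.get("Organism", "")
    pathway_id = _pathway_id(root)

    auto = _IdAllocator()
    elements: list[GpmlElement] = []
    group_graph_ids: dict[str, str] = {}  # GroupId -> node id used in skeleton
    group_members: dict[str, list[str]] = {}

    for child in root:
        tag = _local(child.tag)
        if tag == "DataNode":
            elements.append(_parse_datanode(child, auto))
        elif tag in ("Label", "Shape"):
            gid = child.get("GraphId") or auto.next(tag.lower())
            gfx = child.find("./{*}Graphics")
            elements.append(
                GpmlElement(
                    graph_id=gid,
                    gpml_node_type=tag,
                    label=child.get("TextLabel", ""),
                    x=_fget(gfx, "CenterX"),
                    y=_fget(gfx, "CenterY"),
                    group_ref=child.get("GroupRef"),
                )
            )
        elif tag == "Group":
            group_id = child.get("GroupId") or child.get("GraphId") or auto.next("group")
            node_id = child.get("GraphId") or group_id
            group_graph_ids[group_id] = node_id
            group_members.setdefault(group_id, [])

    for el in elements:
        if el.group_ref is not None and el.group_ref in group_members:
            group_members[el.group_ref].append(el.graph_id)

    interactions: list[GpmlInteraction] = []
    for child in root:
        if _local(child.tag) in ("Interaction", "GraphicalLine"):
            interactions.append(_parse_interaction(child, auto))

    nodes = [_element_to_node(el, mapping) for el in elements]
    for group_id, node_id in group_graph_ids.items():
        members = tuple(group_members.get(group_id, ()))
        if not members:
            logger.warning("GPML group %r has no members; dropped", group_id)
            continue
        nodes.append(SkeletonNode(node_id=node_id, node_type="group", members=members))

    edges = resolve_anchors(interactions)
    unconnected = [e for e in edges if not e.source or not e.target]
    if unconnected:
        logger.warning(
            "%d GPML interaction(s) without graph references dropped", len(unconnected)
        )
        edges = [e for e in edges if e.source and e.target]
    # endpoints referencing a GroupId rather than the group's GraphId
    rewrite = {gid: nid for gid, nid in group_graph_ids.items() if gid != nid}
    if rewrite:
        edges = [
            SkeletonEdge(
                edge_id=e.edge_id,
                source=rewrite.get(e.source, e.source),
                target=rewrite.get(e.target, e.target),
                relation_types=e.relation_types,
            )
            for e in edges
        ]

    skeleton = PathwaySkeleton(
        pathway_id=pathway_id,
        name=name,
        organism=organism,
        source_db="wikipathways",
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


def _pathway_id(root) -> str:
    for child in root:
        if _local(child.tag) == "Xref" and child.get("Database", "") == "WikiPathways":
            return child.get("ID", "")
    # fall back to a name-derived id for community files without a
    # WikiPathways xref
    return root.get("Name", "unnamed").replace(" ", "_")


class _IdAllocator:
    def __init__(self):
        self._n = 0

    def next(self, prefix: str) -> str:
        self._n += 1
        return f"_{prefix}{self._n}"


def _fget(gfx, attr: str) -> float | None:
    if gfx is None:
        return None
    value = gfx.get(attr)
    return float(value) if value is not None else None


def _parse_datanode(child, auto: _IdAllocator) -> GpmlElement:
    gid = child.get("GraphId") or auto.next("dn")
    gfx = child.find("./{*}Graphics")
    xref_el = child.find("./{*}Xref")
    xref = None
    if xref_el is not None and xref_el.get("ID"):
        xref = (xref_el.get("Database", ""), xref_el.get("ID", ""))
    return GpmlElement(
        graph_id=gid,
        gpml_node_type=child.get("Type", "Unknown"),
        label=child.get("TextLabel", ""),
        xref=xref,
        x=_fget(gfx, "CenterX"),
        y=_fget(gfx, "CenterY"),
        group_ref=child.get("GroupRef"),
    )


def _parse_interaction(child, auto: _IdAllocator) -> GpmlInteraction:
    edge_id = child.get("GraphId") or auto.next("edge")
    gfx = child.find("./{*}Graphics")
    points = list(gfx.findall("./{*}Point")) if gfx is not None else []
    anchors = list(gfx.findall("./{*}Anchor")) if gfx is not None else []
    start_ref = points[0].get("GraphRef") if points else None
    end_ref = points[-1].get("GraphRef") if points else None
    arrowhead = "Line"
    for pt in reversed(points):
        if pt.get("ArrowHead"):
            arrowhead = pt.get("ArrowHead")
            break
    return GpmlInteraction(
        edge_id=edge_id,
        start_ref=start_ref,
        end_ref=end_ref,
        arrowhead=arrowhead,
        anchor_ids=tuple(a.get("GraphId") for a in anchors if a.get("GraphId")),
    )


def _element_to_node(el: GpmlElement, mapping: IdMappingTable) -> SkeletonNode:
    node_type, _ = map_gpml_types(el.gpml_node_type, None)
    accessions: list[str] = []
    genes: list[str] = []
    if el.xref is not None:
        database, identifier = el.xref
        db = database.lower()
        if db.startswith("uniprot"):
            accessions = [identifier]
        else:
            accessions = mapping.accessions(identifier)
        for acc in accessions:
            g = mapping.gene_name(acc)
            if g and g not in genes:
                genes.append(g)
    return SkeletonNode(
        node_id=el.graph_id,
        node_type=node_type or "misc",
        label=el.label or (genes[0] if genes else ""),
        uniprot_accessions=tuple(accessions),
        gene_names=tuple(genes),
        x=el.x,
        y=el.y,
    )
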