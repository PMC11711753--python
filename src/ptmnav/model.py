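"""Unified pathway-skeleton data model and its JSON serialization.

A pathway skeleton is a mixed graph: typed nodes with 2-D pixel coordinates
(origin top-left, y increasing downward, matching the KGML/GPML drawing
convention), typed edges that may terminate on other *edges* rather than
nodes, and group nodes defined solely by their member nodes.  Both the KEGG
and the WikiPathways importer normalize into this one representation, and
every downstream step (projection, layout, rendering, enrichment-driven
ranking) consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Union

FORMAT_VERSION = 1

NODE_TYPES = ("gene_protein", "compound", "pathway", "misc", "group")
VISUAL_CLASSES = ("activation", "inhibition", "binding_association", "indirect", "other")
SOURCE_DBS = ("kegg", "wikipathways", "custom")

#: relation subtypes that map onto a dedicated visual edge style; everything
#: else is drawn with the shared "other" style.
_VISUAL_FOR_SUBTYPE = {
    "activation": "activation",
    "inhibition": "inhibition",
    "binding/association": "binding_association",
    "indirect": "indirect",
}

#: tie-break priority when an edge carries several relation subtypes.
_VISUAL_PRIORITY = ("inhibition", "activation", "indirect", "binding_association", "other")


def visual_class_for(relation_types: Iterable[str]) -> str:
    """Deterministic visual class for a set of relation subtypes.

    Multi-type edges resolve by the fixed priority
    inhibition > activation > indirect > binding/association > other.
    """
    classes = {_VISUAL_FOR_SUBTYPE.get(t, "other") for t in relation_types}
    for cls in _VISUAL_PRIORITY:
        if cls in classes:
            return cls
    return "other"


@dataclass(frozen=True)
class SkeletonNode:
    node_id: str
    node_type: str
    label: str = ""
    uniprot_accessions: tuple[str, ...] = ()
    gene_names: tuple[str, ...] = ()
    x: float | None = None
    y: float | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "uniprot_accessions", tuple(self.uniprot_accessions))
        object.__setattr__(self, "gene_names", tuple(self.gene_names))
        object.__setattr__(self, "members", tuple(self.members))


@dataclass(frozen=True)
class SkeletonEdge:
    edge_id: str
    source: str  # node_id or edge_id
    target: str  # node_id or edge_id
    relation_types: frozenset[str] = frozenset()
    visual_class: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "relation_types", frozenset(self.relation_types))
        if self.visual_class is None:
            object.__setattr__(self, "visual_class", visual_class_for(self.relation_types))


@dataclass
class PathwaySkeleton:
    pathway_id: str
    name: str = ""
    organism: str = ""
    source_db: str = "custom"
    nodes: list[SkeletonNode] = field(default_factory=list)
    edges: list[SkeletonEdge] = field(default_factory=list)

    def node_map(self) -> dict[str, SkeletonNode]:
        return {n.node_id: n for n in self.nodes}

    def edge_map(self) -> dict[str, SkeletonEdge]:
        return {e.edge_id: e for e in self.edges}

    def gene_protein_nodes(self) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.node_type == "gene_protein"]

    def canonical(self) -> "PathwaySkeleton":
        """Copy with nodes/edges sorted by id (order-insensitive comparisons)."""
        return replace(
            self,
            nodes=sorted(self.nodes, key=lambda n: n.node_id),
            edges=sorted(self.edges, key=lambda e: e.edge_id),
        )

    def equals(self, other: "PathwaySkeleton") -> bool:
        a, b = self.canonical(), other.canonical()
        return (
            (a.pathway_id, a.name, a.organism, a.source_db) == (b.pathway_id, b.name, b.organism, b.source_db)
            and a.nodes == b.nodes
            and a.edges == b.edges
        )


class SkeletonFormatError(ValueError):
    """Raised when a skeleton JSON document violates the documented schema."""


def validate_skeleton(skeleton: PathwaySkeleton) -> list[str]:
    """Check every structural invariant; returns human-readable violations.

    Validation is total: it never raises, and running it twice yields the
    same report.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for node in skeleton.nodes:
        if node.node_id in seen:
            violations.append(f"node {node.node_id!r}: duplicate node_id")
        seen.add(node.node_id)
        if node.node_type not in NODE_TYPES:
            violations.append(f"node {node.node_id!r}: unknown node_type {node.node_type!r}")
        if node.node_type == "group":
            if not node.members:
                violations.append(f"group node {node.node_id!r}: empty member list")
            if node.x is not None or node.y is not None:
                violations.append(f"group node {node.node_id!r}: group nodes carry no coordinates")
        else:
            if node.members:
                violations.append(f"node {node.node_id!r}: members only allowed on group nodes")

    node_ids = {n.node_id for n in skeleton.nodes}
    non_group = {n.node_id for n in skeleton.nodes if n.node_type != "group"}
    edge_ids = {e.edge_id for e in skeleton.edges}
    if len(edge_ids) != len(skeleton.edges):
        counts: dict[str, int] = {}
        for e in skeleton.edges:
            counts[e.edge_id] = counts.get(e.edge_id, 0) + 1
        for eid, c in counts.items():
            if c > 1:
                violations.append(f"edge {eid!r}: duplicate edge_id")

    for node in skeleton.nodes:
        if node.node_type == "group":
            for member in node.members:
                if member not in node_ids:
                    violations.append(f"group node {node.node_id!r}: member {member!r} does not exist")
                elif member not in non_group:
                    violations.append(f"group node {node.node_id!r}: member {member!r} is itself a group")

    endpoints = node_ids | edge_ids
    for edge in skeleton.edges:
        if not edge.relation_types:
            violations.append(f"edge {edge.edge_id!r}: empty relation_types")
        for end, ref in (("source", edge.source), ("target", edge.target)):
            if ref not in endpoints:
                violations.append(f"edge {edge.edge_id!r}: {end} {ref!r} does not resolve to a node or edge")
        if edge.visual_class != visual_class_for(edge.relation_types):
            violations.append(
                f"edge {edge.edge_id!r}: visual_class {edge.visual_class!r} "
                f"inconsistent with relation_types"
            )

    if skeleton.source_db not in SOURCE_DBS:
        violations.append(f"pathway {skeleton.pathway_id!r}: unknown source_db {skeleton.source_db!r}")
    if not any(n.node_type == "gene_protein" for n in skeleton.nodes):
        violations.append(f"pathway {skeleton.pathway_id!r}: no gene_protein node")
    return violations


def _round(value: float | None) -> float | None:
    # coordinates serialize at 2-decimal precision; a second round-trip is
    # therefore byte-stable.
    return None if value is None else round(float(value), 2)


def _node_to_json(node: SkeletonNode) -> dict:
    doc: dict = {"nodeId": node.node_id, "nodeType": node.node_type, "label": node.label}
    if node.node_type == "group":
        doc["members"] = list(node.members)
    else:
        doc["uniprotAccessions"] = list(node.uniprot_accessions)
        doc["geneNames"] = list(node.gene_names)
        if node.x is not None:
            doc["x"] = _round(node.x)
        if node.y is not None:
            doc["y"] = _round(node.y)
    return doc


def _edge_to_json(edge: SkeletonEdge) -> dict:
    return {
        "edgeId": edge.edge_id,
        "source": edge.source,
        "target": edge.target,
        "relationTypes": sorted(edge.relation_types),
        "visualClass": edge.visual_class,
    }


def skeleton_to_json(skeleton: PathwaySkeleton) -> dict:
    return {
        "formatVersion": FORMAT_VERSION,
        "pathwayId": skeleton.pathway_id,
        "name": skeleton.name,
        "organism": skeleton.organism,
        "sourceDb": skeleton.source_db,
        "nodes": [_node_to_json(n) for n in skeleton.nodes],
        "edges": [_edge_to_json(e) for e in skeleton.edges],
    }


def save_skeleton(skeleton: PathwaySkeleton, destination: Union[str, Path, IO[str], None] = None) -> str:
    """Serialize to the skeleton JSON format; rejects invalid skeletons.

    Returns the JSON text; if ``destination`` is given it is also written
    there (path or text stream).
    """
    violations = validate_skeleton(skeleton)
    if violations:
        raise ValueError(
            "cannot save invalid skeleton:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    text = json.dumps(skeleton_to_json(skeleton), indent=1, sort_keys=False)
    if destination is not None:
        if isinstance(destination, (str, Path)):
            Path(destination).write_text(text)
        else:
            destination.write(text)
    return text


def _expect(doc: dict, key: str, types, path: str):
    if key not in doc:
        raise SkeletonFormatError(f"{path}.{key}: missing required field")
    value = doc[key]
    if not isinstance(value, types):
        raise SkeletonFormatError(f"{path}.{key}: expected {types}, got {type(value).__name__}")
    return value


def load_skeleton(source: Union[str, Path, IO[str]]) -> PathwaySkeleton:
    """Parse a skeleton JSON document; raises SkeletonFormatError naming the
    first offending path on schema violations."""
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        text = source if source.lstrip().startswith("{") else Path(source).read_text()
    else:
        text = source.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SkeletonFormatError(f"$: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SkeletonFormatError("$: expected a JSON object")

    nodes = []
    for i, nd in enumerate(_expect(doc, "nodes", list, "$")):
        path = f"$.nodes[{i}]"
        if not isinstance(nd, dict):
            raise SkeletonFormatError(f"{path}: expected an object")
        node_type = _expect(nd, "nodeType", str, path)
        nodes.append(
            SkeletonNode(
                node_id=_expect(nd, "nodeId", str, path),
                node_type=node_type,
                label=nd.get("label", ""),
                uniprot_accessions=tuple(nd.get("uniprotAccessions", ())),
                gene_names=tuple(nd.get("geneNames", ())),
                x=nd.get("x"),
                y=nd.get("y"),
                members=tuple(nd.get("members", ())),
            )
        )
    edges = []
    for i, ed in enumerate(_expect(doc, "edges", list, "$")):
        path = f"$.edges[{i}]"
        if not isinstance(ed, dict):
            raise SkeletonFormatError(f"{path}: expected an object")
        edges.append(
            SkeletonEdge(
                edge_id=_expect(ed, "edgeId", str, path),
                source=_expect(ed, "source", str, path),
                target=_expect(ed, "target", str, path),
                relation_types=frozenset(_expect(ed, "relationTypes", list, path)),
            )
        )
    return PathwaySkeleton(
        pathway_id=_expect(doc, "pathwayId", str, "$"),
        name=doc.get("name", ""),
        organism=doc.get("organism", ""),
        source_db=_expect(doc, "sourceDb", str, "$"),
        nodes=nodes,
        edges=edges,
    )


@dataclass(frozen=True)
class SkippedPathway:
    """Import outcome for pathways that contain no gene or gene-product node.

    Such diagrams (purely metabolic maps, drawings without gene entries) are
    deliberately not imported; this is a reportable outcome, not an error.
    """

    pathway_id: str
    name: str
    reason: str = "no gene_protein node"
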