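"""KGML pathway parsing and graph serialisation.

KEGG distributes each metabolic map as a KGML (KEGG Markup Language) XML
document: ``entry`` elements declare the participants (compounds, genes or
orthologs, links to other maps) and ``reaction`` elements connect substrate
compounds to product compounds.  This module turns such a document into a
:class:`PathwayGraph` — compound nodes joined by reaction edges, each edge
carrying the identifiers of the genes that catalyse it — and writes graphs
back out as KGML, GraphML or a plain JSON schema, optionally annotated with
module detection results.

Both reference maps (``map…``, catalysts are KO/EC identifiers) and
organism-specific maps (catalysts are locus tags such as ``b2049``) are
accepted; the organism prefix (``eco:``) and database prefixes (``cpd:``,
``rn:``, ``ko:``) are stripped on ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
from lxml import etree

__all__ = [
    "CompoundNode",
    "ReactionEdge",
    "PathwayGraph",
    "KGMLError",
    "parse_kgml",
    "write_kgml",
    "to_edge_list",
    "export_annotated_graph",
]


class KGMLError(ValueError):
    """Raised for malformed or semantically invalid KGML input."""


def _strip_prefix(token: str) -> str:
    """Drop a single leading ``db:`` prefix from a KEGG identifier token."""
    return token.split(":", 1)[1] if ":" in token else token


@dataclass
class CompoundNode:
    """One compound participating in a pathway map.

    ``external`` marks entries of KGML type ``map`` — links to other
    pathways.  They are retained in the graph but excluded from community
    detection by default, because constitutive sub-pathways referenced from
    inside a map otherwise blur module boundaries.
    """

    compound_id: str
    display_name: str = ""
    synonyms: list[str] = field(default_factory=list)
    external: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass
class ReactionEdge:
    """A substrate → product conversion catalysed by zero or more genes.

    A reversible reaction is a single edge with ``reversible=True`` (never
    two antiparallel edges): downstream community detection treats the
    pathway as an undirected graph, so direction only matters for ordering
    compounds inside a module.
    """

    reaction_id: str
    substrate_id: str
    product_id: str
    reversible: bool = False
    catalyst_gene_ids: set[str] = field(default_factory=set)
    catalyst_pfams: set[str] = field(default_factory=set)
    self_loop: bool = False


@dataclass
class PathwayGraph:
    """Compound/reaction graph for one KEGG-style pathway map."""

    map_id: str
    nodes: dict[str, CompoundNode] = field(default_factory=dict)
    edges: list[ReactionEdge] = field(default_factory=list)
    organism_code: str | None = None

    def add_node(self, node: CompoundNode) -> None:
        existing = self.nodes.get(node.compound_id)
        if existing is None:
            self.nodes[node.compound_id] = node
        else:
            # duplicate compound entries with the same accession merge
            existing.synonyms = sorted(
                set(existing.synonyms) | set(node.synonyms)
            )
            if not existing.display_name:
                existing.display_name = node.display_name

    def add_edge(self, edge: ReactionEdge) -> None:
        for endpoint in (edge.substrate_id, edge.product_id):
            if endpoint not in self.nodes:
                raise KGMLError(
                    f"reaction {edge.reaction_id!r} references undeclared "
                    f"compound {endpoint!r}"
                )
        key = (edge.reaction_id, edge.substrate_id, edge.product_id)
        if key in {(e.reaction_id, e.substrate_id, e.product_id) for e in self.edges}:
            return
        self.edges.append(edge)

    def internal_node_ids(self) -> list[str]:
        return sorted(c for c, n in self.nodes.items() if not n.external)

    def to_networkx(self, include_external: bool = False) -> nx.Graph:
        """Undirected simple graph; parallel edges collapse, weight = multiplicity."""
        g = nx.Graph()
        for cid, node in sorted(self.nodes.items()):
            if node.external and not include_external:
                continue
            g.add_node(cid)
        for e in self.edges:
            if e.substrate_id not in g or e.product_id not in g or e.self_loop:
                continue
            if g.has_edge(e.substrate_id, e.product_id):
                g[e.substrate_id][e.product_id]["weight"] += 1.0
                g[e.substrate_id][e.product_id]["reactions"].append(e.reaction_id)
            else:
                g.add_edge(
                    e.substrate_id, e.product_id,
                    weight=1.0, reactions=[e.reaction_id],
                )
        return g


def parse_kgml(kgml_text: str | bytes, relations_as_edges: bool = False) -> PathwayGraph:
    """Parse a KGML document into a :class:`PathwayGraph`.

    Every ``entry`` of type ``compound`` becomes a node (type ``map``
    entries become ``external`` nodes); every ``reaction`` yields one edge
    per (substrate, product) pair, reversible reactions yielding a single
    edge with ``reversible=True``.  Gene/ortholog entries whose ``reaction``
    attribute names a reaction contribute their identifiers to that edge's
    ``catalyst_gene_ids``.

    ``relation`` elements (compound–compound links without a reaction) do
    not contribute edges unless ``relations_as_edges`` is set; KGML uses
    them mainly for layout and cross-map wiring.
    """
    if isinstance(kgml_text, str):
        kgml_text = kgml_text.encode()
    try:
        root = etree.fromstring(
            kgml_text, parser=etree.XMLParser(resolve_entities=False)
        )
    except etree.XMLSyntaxError as exc:
        raise KGMLError(f"malformed KGML XML: {exc}") from exc

    map_name = root.get("name", "")
    map_id = _strip_prefix(map_name) if map_name else root.get("number", "unknown")
    org = root.get("org")
    graph = PathwayGraph(
        map_id=map_id, organism_code=None if org in (None, "map") else org
    )

    entry_by_id: dict[str, etree._Element] = {}
    # entry name token -> compound ids (an entry may alias several compounds)
    compound_ids_of_entry: dict[str, list[str]] = {}
    # reaction name -> catalyst gene ids, from gene/ortholog/enzyme entries
    catalysts: dict[str, set[str]] = {}

    n_compounds = 0
    for entry in root.iter("entry"):
        eid = entry.get("id", "")
        etype = entry.get("type", "")
        names = [_strip_prefix(t) for t in entry.get("name", "").split() if t]
        entry_by_id[eid] = entry
        if etype in ("compound", "map"):
            graphics = entry.find("graphics")
            display = graphics.get("name", "") if graphics is not None else ""
            display = display.rstrip(".")
            for name in names:
                graph.add_node(
                    CompoundNode(
                        compound_id=name,
                        display_name=display,
                        external=(etype == "map"),
                    )
                )
            compound_ids_of_entry[eid] = names
            if etype == "compound":
                n_compounds += 1
        elif etype in ("gene", "ortholog", "enzyme"):
            for rxn_token in entry.get("reaction", "").split():
                catalysts.setdefault(_strip_prefix(rxn_token), set()).update(names)

    if n_compounds == 0:
        raise KGMLError(f"pathway {map_id!r} declares no compound entries")

    for rxn in root.iter("reaction"):
        rxn_names = [_strip_prefix(t) for t in rxn.get("name", "").split() if t]
        rxn_id = rxn_names[0] if rxn_names else rxn.get("id", "")
        reversible = rxn.get("type", "irreversible") == "reversible"
        genes: set[str] = set()
        for name in rxn_names:
            genes |= catalysts.get(name, set())
        # KGML also ties reactions to catalysing entries via the reaction's
        # numeric id matching a gene entry id
        rid = rxn.get("id", "")
        owner = entry_by_id.get(rid)
        if owner is not None and owner.get("type") in ("gene", "ortholog", "enzyme"):
            genes |= {
                _strip_prefix(t) for t in owner.get("name", "").split() if t
            }

        def _resolve(el: etree._Element) -> list[str]:
            ref, name = el.get("id", ""), el.get("name", "")
            if ref in compound_ids_of_entry:
                return compound_ids_of_entry[ref]
            if ref and ref in entry_by_id:
                return [_strip_prefix(t) for t in entry_by_id[ref].get("name", "").split()]
            if name:
                return [_strip_prefix(name)]
            raise KGMLError(
                f"reaction {rxn_id!r} references undeclared entry id {ref!r}"
            )

        substrates = [c for el in rxn.findall("substrate") for c in _resolve(el)]
        products = [c for el in rxn.findall("product") for c in _resolve(el)]
        for s in substrates:
            for p in products:
                graph.add_edge(
                    ReactionEdge(
                        reaction_id=rxn_id,
                        substrate_id=s,
                        product_id=p,
                        reversible=reversible,
                        catalyst_gene_ids=set(genes),
                        self_loop=(s == p),
                    )
                )

    if relations_as_edges:
        for rel in root.iter("relation"):
            e1, e2 = rel.get("entry1", ""), rel.get("entry2", "")
            c1 = compound_ids_of_entry.get(e1, [])
            c2 = compound_ids_of_entry.get(e2, [])
            for s in c1:
                for p in c2:
                    if s != p:
                        graph.add_edge(
                            ReactionEdge(
                                reaction_id=f"rel_{e1}_{e2}",
                                substrate_id=s,
                                product_id=p,
                            )
                        )
    return graph


def write_kgml(graph: PathwayGraph) -> str:
    """Serialise a graph back to minimal, re-parseable KGML."""
    root = etree.Element(
        "pathway",
        name=f"path:{graph.map_id}",
        org=graph.organism_code or "map",
        number=graph.map_id.lstrip("map"),
    )
    eid = 0
    entry_of_compound: dict[str, str] = {}
    for cid, node in sorted(graph.nodes.items()):
        eid += 1
        entry = etree.SubElement(
            root,
            "entry",
            id=str(eid),
            name=("path:" if node.external else "cpd:") + cid,
            type="map" if node.external else "compound",
        )
        etree.SubElement(entry, "graphics", name=node.display_name or cid)
        entry_of_compound[cid] = str(eid)
    gene_reactions: dict[str, list[str]] = {}
    for e in graph.edges:
        for g in sorted(e.catalyst_gene_ids):
            gene_reactions.setdefault(g, []).append(e.reaction_id)
    gene_prefix = f"{graph.organism_code}:" if graph.organism_code else "ko:"
    for g, rxns in sorted(gene_reactions.items()):
        eid += 1
        etree.SubElement(
            root,
            "entry",
            id=str(eid),
            name=gene_prefix + g,
            type="gene" if graph.organism_code else "ortholog",
            reaction=" ".join("rn:" + r for r in sorted(set(rxns))),
        )
    for i, e in enumerate(graph.edges, 1):
        rxn = etree.SubElement(
            root,
            "reaction",
            id=str(eid + i),
            name="rn:" + e.reaction_id,
            type="reversible" if e.reversible else "irreversible",
        )
        etree.SubElement(
            rxn, "substrate", id=entry_of_compound[e.substrate_id],
            name="cpd:" + e.substrate_id,
        )
        etree.SubElement(
            rxn, "product", id=entry_of_compound[e.product_id],
            name="cpd:" + e.product_id,
        )
    return etree.tostring(root, pretty_print=True).decode()


def to_edge_list(graph: PathwayGraph) -> list[tuple[str, str, str]]:
    """Deterministic (substrate, product, reaction) rows, one per edge.

    Reversible edges are emitted once; rows sort by reaction id, then
    substrate, then product, so the output is invariant under input
    element reordering.
    """
    rows = [(e.substrate_id, e.product_id, e.reaction_id) for e in graph.edges]
    return sorted(rows, key=lambda r: (r[2], r[0], r[1]))


def _annotated_networkx(graph: PathwayGraph, calls) -> nx.Graph:
    import warnings

    g = graph.to_networkx(include_external=True)
    for n in g.nodes:
        g.nodes[n]["present"] = False
        g.nodes[n]["module_id"] = ""
    for u, v, data in g.edges(data=True):
        data["present"] = False
        data["module_id"] = ""
        data["reactions"] = ";".join(data.pop("reactions"))
    present_compounds: dict[str, set[str]] = {}
    for call in calls:
        if not call.present:
            continue
        present_compounds.setdefault(call.gcm_id, set()).update(
            getattr(call, "compound_ids", ()) or ()
        )
    for gcm_id, compounds in sorted(present_compounds.items()):
        for c in sorted(compounds):
            if c not in g:
                warnings.warn(
                    f"detection call for {gcm_id} references unknown compound {c}",
                    stacklevel=2,
                )
                continue
            g.nodes[c]["present"] = True
            prior = g.nodes[c]["module_id"]
            g.nodes[c]["module_id"] = f"{prior};{gcm_id}" if prior else gcm_id
        for u, v, data in g.edges(data=True):
            if u in compounds and v in compounds:
                data["present"] = True
                prior = data["module_id"]
                data["module_id"] = f"{prior};{gcm_id}" if prior else gcm_id
    return g


def export_annotated_graph(graph: PathwayGraph, calls, format: str = "graphml") -> str:
    """Export the pathway graph with per-node/edge module presence flags.

    ``calls`` are detection calls (see :mod:`gcmkit.detector`); each call
    that is present marks the compounds of its module (the call's
    ``compound_ids``) with ``present=True`` and the module id.  GraphML
    output round-trips through any standard GraphML reader; the JSON form
    carries the same node/edge attribute multiset.
    """
    g = _annotated_networkx(graph, calls)
    if format == "graphml":
        return "\n".join(nx.generate_graphml(g, named_key_ids=True))
    if format == "json":
        payload = {
            "map_id": graph.map_id,
            "nodes": [
                {"id": n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])}}
                for n in sorted(g.nodes)
            ],
            "edges": [
                {
                    "source": min(u, v),
                    "target": max(u, v),
                    **{k: d[k] for k in sorted(d)},
                }
                for u, v, d in sorted(
                    g.edges(data=True), key=lambda t: (min(t[0], t[1]), max(t[0], t[1]))
                )
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    raise ValueError(f"unsupported export format: {format!r}")
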