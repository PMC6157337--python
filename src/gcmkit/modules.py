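"""Module records (IRM / IM / GCM) and their catalog serialisation.

A *module* is a sub-pathway: an ordered list of compounds, the protein
domain families (Pfams) of the catalysing genes, and — per genome — the
locus tags assigned to it.  Three kinds exist, reflecting the stages of the
pipeline:

IRM
    Initial Reference Module: a community of compounds obtained purely from
    edge connectivity of the pathway graph.
IM
    Intermediate Module: an IRM-derived module after its genes were
    re-clustered by genomic proximity (IRMs may merge or split).
GCM
    Gene Context based Module: a literature-validated IM with a designated
    source and target compound and attached PubMed evidence.

Catalogs serialise to TSV (one row per module) and JSON; a curation overlay
file records manual add/remove/rename interventions as explicit records so
curation is reproducible rather than baked into code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "Module",
    "CatalogError",
    "modules_to_tsv",
    "modules_from_tsv",
    "modules_to_json",
    "modules_from_json",
    "apply_curation",
]

_KINDS = ("IRM", "IM", "GCM")

_TSV_COLUMNS = [
    "module_id", "kind", "map_id", "compounds", "source", "target",
    "pfams", "gene_ids", "linker_flags", "flags", "evidence_pmids",
    "gene_assignments",
]


class CatalogError(ValueError):
    """Raised for schema-invalid module catalogs."""


@dataclass
class Module:
    """One IRM, IM or GCM record."""

    module_id: str
    kind: str
    map_id: str
    compound_ids: list[str]
    pfam_set: set[str] = field(default_factory=set)
    source_compound: str | None = None
    target_compound: str | None = None
    gene_ids: set[str] = field(default_factory=set)
    gene_assignments: dict[str, set[str]] = field(default_factory=dict)
    linker_flags: set[str] = field(default_factory=set)
    evidence: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise CatalogError(f"{self.module_id}: unknown module kind {self.kind!r}")
        if not self.compound_ids:
            raise CatalogError(f"{self.module_id}: compound_ids must be non-empty")
        if self.kind == "GCM":
            if not self.pfam_set:
                raise CatalogError(f"{self.module_id}: a GCM requires a Pfam set")
            for which, c in (("source", self.source_compound),
                             ("target", self.target_compound)):
                if c is None or c not in self.compound_ids:
                    raise CatalogError(
                        f"{self.module_id}: GCM {which} compound {c!r} not among "
                        f"compounds {self.compound_ids}"
                    )

    def genes_on(self, genome_id: str) -> set[str]:
        return set(self.gene_assignments.get(genome_id, set()))


def _join(values) -> str:
    return ";".join(values)


def _split(text: str) -> list[str]:
    return [t for t in text.split(";") if t]


def modules_to_tsv(modules: list[Module]) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for m in sorted(modules, key=lambda m: m.module_id):
        assignments = _join(
            f"{g}:{','.join(sorted(loci))}"
            for g, loci in sorted(m.gene_assignments.items())
        )
        lines.append("\t".join([
            m.module_id, m.kind, m.map_id, _join(m.compound_ids),
            m.source_compound or "", m.target_compound or "",
            _join(sorted(m.pfam_set)), _join(sorted(m.gene_ids)),
            _join(sorted(m.linker_flags)), _join(sorted(m.flags)),
            _join(m.evidence), assignments,
        ]))
    return "\n".join(lines) + "\n"


def modules_from_tsv(text: str) -> list[Module]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    if header != _TSV_COLUMNS:
        raise CatalogError(f"unexpected catalog columns: {header}")
    modules = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(_TSV_COLUMNS):
            raise CatalogError(f"bad catalog row (wrong field count): {ln!r}")
        assignments = {}
        for chunk in _split(f[11]):
            genome, loci = chunk.split(":", 1)
            assignments[genome] = set(loci.split(","))
        modules.append(Module(
            module_id=f[0], kind=f[1], map_id=f[2], compound_ids=_split(f[3]),
            source_compound=f[4] or None, target_compound=f[5] or None,
            pfam_set=set(_split(f[6])), gene_ids=set(_split(f[7])),
            linker_flags=set(_split(f[8])), flags=set(_split(f[9])),
            evidence=_split(f[10]), gene_assignments=assignments,
        ))
    _check_unique(modules)
    return modules


def modules_to_json(modules: list[Module]) -> str:
    payload = [
        {
            "module_id": m.module_id,
            "kind": m.kind,
            "map_id": m.map_id,
            "compounds": m.compound_ids,
            "source": m.source_compound,
            "target": m.target_compound,
            "pfams": sorted(m.pfam_set),
            "gene_ids": sorted(m.gene_ids),
            "linker_flags": sorted(m.linker_flags),
            "flags": sorted(m.flags),
            "evidence_pmids": m.evidence,
            "gene_assignments": {
                g: sorted(loci) for g, loci in sorted(m.gene_assignments.items())
            },
        }
        for m in sorted(modules, key=lambda m: m.module_id)
    ]
    return json.dumps(payload, indent=2)


def modules_from_json(text: str) -> list[Module]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"invalid catalog JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise CatalogError("catalog JSON must be a list of module objects")
    modules = []
    for rec in payload:
        missing = {"module_id", "kind", "map_id", "compounds"} - set(rec)
        if missing:
            raise CatalogError(
                f"module record {rec.get('module_id', '?')!r} missing "
                f"fields {sorted(missing)}"
            )
        modules.append(Module(
            module_id=rec["module_id"], kind=rec["kind"], map_id=rec["map_id"],
            compound_ids=list(rec["compounds"]),
            source_compound=rec.get("source"), target_compound=rec.get("target"),
            pfam_set=set(rec.get("pfams", [])),
            gene_ids=set(rec.get("gene_ids", [])),
            linker_flags=set(rec.get("linker_flags", [])),
            flags=set(rec.get("flags", [])),
            evidence=list(rec.get("evidence_pmids", [])),
            gene_assignments={
                g: set(loci) for g, loci in rec.get("gene_assignments", {}).items()
            },
        ))
    _check_unique(modules)
    return modules


def _check_unique(modules: list[Module]) -> None:
    seen: set[str] = set()
    for m in modules:
        if m.module_id in seen:
            raise CatalogError(f"duplicate module_id {m.module_id!r} in catalog")
        seen.add(m.module_id)


def apply_curation(modules: list[Module], overlay_tsv: str) -> list[Module]:
    """Apply a curation overlay: TSV rows of (action, module_id, field, value).

    Actions: ``remove`` (drop the module), ``rename`` (field=module_id,
    value=new id), ``add_pfam`` / ``remove_pfam``, ``set`` (replace a
    scalar field).  Unknown module ids raise, so stale overlays surface.
    """
    by_id = {m.module_id: m for m in modules}
    for ln in overlay_tsv.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 4:
            raise CatalogError(f"bad curation row: {ln!r}")
        action, mid, fld, value = parts
        if mid not in by_id:
            raise CatalogError(f"curation refers to unknown module {mid!r}")
        m = by_id[mid]
        if action == "remove":
            del by_id[mid]
        elif action == "rename":
            del by_id[mid]
            m.module_id = value
            by_id[value] = m
        elif action == "add_pfam":
            m.pfam_set.add(value)
        elif action == "remove_pfam":
            m.pfam_set.discard(value)
        elif action == "set":
            if fld not in ("source_compound", "target_compound", "map_id"):
                raise CatalogError(f"curation cannot set field {fld!r}")
            setattr(m, fld, value)
        else:
            raise CatalogError(f"unknown curation action {action!r}")
    return sorted(by_id.values(), key=lambda m: m.module_id)
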