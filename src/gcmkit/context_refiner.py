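"""Genomic-context refinement: IRMs → Intermediate Modules → GCMs.

Edge-connectivity communities (IRMs) need not correspond to co-located
gene clusters on a genome.  This stage pools the genes of all IRMs of a
pathway on one genome, clusters them by genomic proximity — two genes
join a cluster when connected by a chain of steps of at most
``distance_threshold`` intervening gene ranks (single-linkage, the "minimum
distance score", default 10) — and re-cuts the modules along the resulting
clusters.  An Intermediate Module (IM) may therefore equal one IRM, merge
several, or be one shard of a split IRM.  Linker genes (assigned to two
IRMs at build time) are resolved to the module of their nearest non-linker
neighbour gene, or kept duplicated on an exact tie.

An IM becomes a Gene Context based Module (GCM) only with literature
evidence attached and a designated source/target compound pair.

All distances are in gene-rank units; distances across replicons are
infinite, so no module ever spans a chromosome/plasmid boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genome_catalog import GenomeCatalog
from .modules import Module

__all__ = [
    "INF",
    "RefinementParams",
    "assign_genome_genes",
    "gene_distance",
    "pairwise_module_distances",
    "cluster_genes_by_context",
    "consensus_ims",
    "refine_modules",
    "compile_gcm",
]

INF = math.inf


@dataclass(frozen=True)
class RefinementParams:
    """Knobs of the proximity-clustering stage.

    distance_threshold
        Maximum gene-rank gap joining two genes into one cluster
        (single-linkage chaining).  Default 10.
    max_iterations
        Safety bound on the merge/split recursion; single-linkage reaches
        its fixed point immediately, so this only guards pathological
        custom subclasses.
    linker_resolution
        ``nearest``: a linker gene's module attribution follows its
        closest non-linker module gene (exact ties keep both);
        ``duplicate``: linkers always contribute to all their modules.
    """

    distance_threshold: int = 10
    max_iterations: int = 20
    linkage: str = "single"
    linker_resolution: str = "nearest"

    def __post_init__(self) -> None:
        if self.distance_threshold < 1:
            raise ValueError("distance_threshold must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.linkage != "single":
            raise ValueError("only single linkage is supported")
        if self.linker_resolution not in ("nearest", "duplicate"):
            raise ValueError("linker_resolution must be 'nearest' or 'duplicate'")


def assign_genome_genes(
    irms: list[Module],
    catalog: GenomeCatalog,
    genome_id: str | None = None,
    by: str = "locus",
) -> list[Module]:
    """Fill ``gene_assignments`` for one genome, in place.

    ``by='locus'`` matches module ``gene_ids`` directly against the
    catalog's locus tags (the organism-specific-KGML case, where catalyst
    identifiers already are locus tags).  ``by='pfam'`` assigns every
    catalog gene carrying at least one of the module's Pfams (the
    reference-map case, where catalysts are KO/EC strings and homology is
    carried by the domain annotation).
    """
    genome_id = genome_id or catalog.genome_id
    if by not in ("locus", "pfam"):
        raise ValueError("by must be 'locus' or 'pfam'")
    for m in irms:
        if by == "locus":
            loci = {g for g in m.gene_ids if g in catalog}
        else:
            loci = {
                rec.locus_tag
                for records in catalog.replicons.values()
                for rec in records
                if rec.pfams & m.pfam_set
            }
        m.gene_assignments[genome_id] = loci
    return irms


def gene_distance(catalog: GenomeCatalog, a: str, b: str) -> float:
    """Rank distance between two genes; INF across replicons.

    On a circular replicon of n genes the distance wraps:
    ``min(d, n − d)``.
    """
    ga, gb = catalog.gene(a), catalog.gene(b)
    if ga.replicon_id != gb.replicon_id:
        return INF
    d = abs(ga.rank - gb.rank)
    if catalog.is_circular(ga.replicon_id):
        n = catalog.n_genes(ga.replicon_id)
        d = min(d, n - d)
    return float(d)


def pairwise_module_distances(
    catalog: GenomeCatalog, modules: list[Module], genome_id: str
):
    """Inter-module minimum distances for all module pairs, plus intra gaps.

    Returns ``(inter, intra)``:

    * ``inter[(id1, id2)]`` (id1 < id2, all nC2 pairs) — the minimum rank
      distance over cross-module gene pairs; INF when either module has no
      genes on this genome (such modules are also listed under intra with
      value INF, flagging absence).
    * ``intra[id]`` — the largest single-linkage gap inside the module's
      own gene set (0 for ≤1 gene): the distance one must tolerate for the
      module's genes to chain into one cluster.

    Mean distances are diagnostics only; merging decisions downstream use
    the minimum.
    """
    gene_sets = {m.module_id: sorted(m.genes_on(genome_id)) for m in modules}

    inter: dict[tuple[str, str], float] = {}
    ids = sorted(gene_sets)
    for i, id1 in enumerate(ids):
        for id2 in ids[i + 1:]:
            g1, g2 = gene_sets[id1], gene_sets[id2]
            if not g1 or not g2:
                inter[(id1, id2)] = INF
                continue
            inter[(id1, id2)] = min(
                gene_distance(catalog, a, b) for a in g1 for b in g2
            )

    intra: dict[str, float] = {}
    for mid, genes in gene_sets.items():
        if not genes:
            intra[mid] = INF
        elif len(genes) == 1:
            intra[mid] = 0.0
        else:
            # largest merge height of single-linkage = max over the
            # minimum-spanning chain; equivalently the biggest gap that
            # must be bridged (computed per replicon on sorted ranks)
            intra[mid] = _max_single_linkage_gap(catalog, genes)
    return inter, intra


def _max_single_linkage_gap(catalog: GenomeCatalog, genes: list[str]) -> float:
    by_rep: dict[str, list[int]] = {}
    for g in genes:
        rec = catalog.gene(g)
        by_rep.setdefault(rec.replicon_id, []).append(rec.rank)
    if len(by_rep) > 1:
        return INF
    (rep, ranks), = by_rep.items()
    ranks = sorted(ranks)
    if len(ranks) == 1:
        return 0.0
    gaps = [b - a for a, b in zip(ranks, ranks[1:])]
    if catalog.is_circular(rep):
        n = catalog.n_genes(rep)
        wrap = ranks[0] + n - ranks[-1]
        # on a circle the chain may skip the single largest arc
        gaps.append(wrap)
        gaps.remove(max(gaps))
        if not gaps:
            return 0.0
    return float(max(gaps))


def cluster_genes_by_context(
    catalog: GenomeCatalog, genes: set[str], params: RefinementParams
) -> list[list[str]]:
    """Single-linkage proximity clusters of a gene set.

    Two genes share a cluster iff a chain of genes from the set joins
    them with every consecutive step at most ``distance_threshold`` ranks.
    On a sorted rank line this reduces to cutting at gaps larger than the
    threshold; circular replicons additionally join across the origin.
    Clusters are ordered by (replicon, leftmost rank); members by rank.
    """
    t = params.distance_threshold
    by_rep: dict[str, list[tuple[int, str]]] = {}
    for g in sorted(genes):
        rec = catalog.gene(g)
        by_rep.setdefault(rec.replicon_id, []).append((rec.rank, g))

    clusters: list[list[str]] = []
    for rep in sorted(by_rep):
        items = sorted(by_rep[rep])
        runs: list[list[tuple[int, str]]] = [[items[0]]]
        for prev, cur in zip(items, items[1:]):
            if cur[0] - prev[0] <= t:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        if (
            catalog.is_circular(rep)
            and len(runs) > 1
            and items[0][0] + catalog.n_genes(rep) - items[-1][0] <= t
        ):
            runs[0] = runs.pop() + runs[0]
        clusters.extend([g for _, g in run] for run in runs)

    clusters.sort(key=lambda c: (catalog.gene(c[0]).replicon_id,
                                 min(catalog.gene(g).rank for g in c)))
    return clusters


def refine_modules(
    irms: list[Module],
    catalog: GenomeCatalog,
    genome_id: str,
    params: RefinementParams | None = None,
) -> list[Module]:
    """Re-cut IRMs along genomic proximity clusters into IMs.

    Pools every gene assigned to any input module on ``genome_id``,
    clusters the pool by context, and emits one IM per cluster.  Each IM
    inherits the union of compounds and Pfams of the modules whose genes
    it contains — after linker resolution, so a linker gene pulls in only
    its nearest module's identity (both on an exact tie).  Clusters of one
    gene become singleton IMs flagged ``unclustered``; an IM built from
    several IRMs is flagged ``merged`` and the shards of a split IRM are
    flagged ``split``.  Re-clustering is repeated to a fixed point (single
    linkage converges immediately; ``max_iterations`` guards the loop).
    """
    params = params or RefinementParams()

    modules_of_gene: dict[str, set[str]] = {}
    for m in irms:
        for g in m.genes_on(genome_id):
            modules_of_gene.setdefault(g, set()).add(m.module_id)
    pool = set(modules_of_gene)
    if not pool:
        return []

    by_id = {m.module_id: m for m in irms}
    linkers = {g for g, mods in modules_of_gene.items() if len(mods) > 1}

    attribution = {
        g: set(mods) for g, mods in modules_of_gene.items()
    }
    if params.linker_resolution == "nearest":
        for g in sorted(linkers):
            best_d, best_mods = INF, set()
            for other, mods in modules_of_gene.items():
                if other == g or other in linkers:
                    continue
                d = gene_distance(catalog, g, other)
                if d < best_d - 1e-9:
                    best_d, best_mods = d, set(mods)
                elif d <= best_d + 1e-9:
                    best_mods |= mods
            if best_mods:
                # keep only the nearest module(s); an exact tie across
                # modules keeps the gene attributed to all tied modules
                attribution[g] = attribution[g] & best_mods or attribution[g]

    clusters = cluster_genes_by_context(catalog, pool, params)
    for _ in range(params.max_iterations):
        reclustered = cluster_genes_by_context(
            catalog, {g for c in clusters for g in c}, params
        )
        if reclustered == clusters:
            break
        clusters = reclustered
    else:
        raise RuntimeError(
            "context clustering did not converge within "
            f"{params.max_iterations} iterations"
        )

    # count shards per IRM to set split flags
    shard_count: dict[str, int] = {}
    cluster_sources: list[set[str]] = []
    for cluster in clusters:
        sources: set[str] = set()
        for g in cluster:
            sources |= attribution[g]
        cluster_sources.append(sources)
        for mid in sources:
            shard_count[mid] = shard_count.get(mid, 0) + 1

    ims = []
    for idx, (cluster, sources) in enumerate(zip(clusters, cluster_sources)):
        source_modules = [by_id[mid] for mid in sorted(sources)]
        compounds: list[str] = []
        for m in source_modules:
            compounds.extend(c for c in m.compound_ids if c not in compounds)
        pfams = set()
        for m in source_modules:
            pfams |= m.pfam_set
        for g in cluster:
            pfams |= catalog.gene(g).pfams
        flags: set[str] = set()
        if len(cluster) == 1:
            flags.add("unclustered")
        if len(sources) > 1:
            flags.add("merged")
        if any(shard_count[mid] > 1 for mid in sources):
            flags.add("split")
        map_id = source_modules[0].map_id if source_modules else "unknown"
        ims.append(Module(
            module_id=f"{map_id}_{genome_id}_IM{idx:03d}",
            kind="IM",
            map_id=map_id,
            compound_ids=compounds,
            pfam_set=pfams,
            gene_ids=set(cluster),
            gene_assignments={genome_id: set(cluster)},
            linker_flags=set(cluster) & linkers,
            flags=flags,
        ))
    return ims


def consensus_ims(
    im_sets: dict[str, list[Module]], min_support: int = 1
) -> list[Module]:
    """Cross-genome consolidation of per-genome IMs.

    Refinement runs independently per genome; this step retains an IM
    *pattern* — its map, its compound list and its Pfam set — only when
    it was observed in at least ``min_support`` genomes.  Gene
    assignments of all supporting genomes are merged onto one
    representative module per pattern (the representative keeps the
    module id of the lexicographically first supporting genome's IM).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    patterns: dict[tuple, list[tuple[str, Module]]] = {}
    for genome_id in sorted(im_sets):
        for im in im_sets[genome_id]:
            key = (im.map_id, tuple(im.compound_ids), frozenset(im.pfam_set))
            patterns.setdefault(key, []).append((genome_id, im))
    out: list[Module] = []
    for key in sorted(patterns, key=str):
        support = patterns[key]
        genomes = {g for g, _ in support}
        if len(genomes) < min_support:
            continue
        _, rep = support[0]
        merged = Module(
            module_id=rep.module_id,
            kind="IM",
            map_id=rep.map_id,
            compound_ids=list(rep.compound_ids),
            pfam_set=set(rep.pfam_set),
            gene_ids=set().union(*(im.gene_ids for _, im in support)),
            linker_flags=set().union(*(im.linker_flags for _, im in support)),
            flags=set().union(*(im.flags for _, im in support)),
        )
        for genome_id, im in support:
            for g, loci in im.gene_assignments.items():
                merged.gene_assignments.setdefault(g, set()).update(loci)
        out.append(merged)
    return out


def compile_gcm(
    im: Module, evidence: list[str], source: str, target: str
) -> Module:
    """Promote a literature-validated IM to a GCM.

    Requires non-empty PubMed evidence and a source/target compound pair
    drawn from the IM's compounds.  The compound list is oriented so the
    source comes before the target (reversed if needed); the Pfam set is
    carried over and must be non-empty.
    """
    if not evidence:
        raise ValueError(
            f"{im.module_id}: a GCM requires literature evidence (no PMIDs given)"
        )
    for which, c in (("source", source), ("target", target)):
        if c not in im.compound_ids:
            raise ValueError(
                f"{im.module_id}: {which} compound {c!r} not in module; "
                f"valid compounds: {im.compound_ids}"
            )
    compounds = list(im.compound_ids)
    if compounds.index(source) > compounds.index(target):
        compounds.reverse()
    return Module(
        module_id=im.module_id.replace("_IM", "_GCM")
        if "_IM" in im.module_id else f"{im.module_id}_GCM",
        kind="GCM",
        map_id=im.map_id,
        compound_ids=compounds,
        pfam_set=set(im.pfam_set),
        source_compound=source,
        target_compound=target,
        gene_ids=set(im.gene_ids),
        gene_assignments={g: set(v) for g, v in im.gene_assignments.items()},
        linker_flags=set(im.linker_flags),
        evidence=list(evidence),
        flags=set(im.flags),
    )
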