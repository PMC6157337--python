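"""Synthetic input generators: genomes, pathways, hit lists.

Everything the pipeline consumes can be generated here with no network
access: PTT protein tables and HMMER3 domtblout text with *planted* gene
clusters at known ranks, toy KGML pathway maps, and 6Q hit-list files.
Two curated scenario suites emulate the canonical benchmark situations:

* the four-genome suite (:func:`make_four_genome_suite`): a six-Pfam module that
  is genuinely present (all six genes juxtaposed) in exactly one genome,
  while the others carry all the Pfams dispersed — the homology-only
  false-positive scenario;
* the mannose suite (:func:`make_man_suite`): the conserved *man* gene
  cluster converting D-mannose 6-phosphate to GDP-L-fucose, present as a
  contiguous cluster in an *E. coli*-like genome and as dispersed lone
  homologs in a *B. thetaiotaomicron*-like genome.

All generators are deterministic: a fixed seed yields byte-identical
files.  Background domain annotations are drawn from a pool that never
overlaps planted Pfams, so fixture false positives can only come from
deliberately planted homologs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .genome_catalog import GeneRecord, GenomeCatalog, build_catalog, read_ptt
from .modules import Module
from .pathway_io import PathwayGraph, parse_kgml

__all__ = [
    "PlantedCluster",
    "GenomeSpec",
    "make_genome",
    "make_four_genome_suite",
    "make_man_suite",
    "make_hitlists",
    "write_hitlists",
    "random_genome_spec",
    "write_fixture_tree",
    "MAN_PFAMS",
    "SIX_GENE_PFAMS",
]

# real Pfam families of the man-route enzymes (manB, manC, gmd, fcl)
MAN_PFAMS = ["PF01050", "PF00483", "PF16363", "PF01370"]
# synthetic namespace for the four-genome scenario suite
SIX_GENE_PFAMS = [f"PF9000{i}" for i in range(1, 7)]
_BACKGROUND_POOL = [f"PF98{i:03d}" for i in range(40)]


@dataclass(frozen=True)
class PlantedCluster:
    """Genes to plant: pfams[i] at rank start_rank + i*spacing."""

    pfams: tuple[str, ...]
    replicon: str
    start_rank: int
    spacing: int = 1
    locus_tags: tuple[str, ...] | None = None

    def ranks(self) -> list[int]:
        return [self.start_rank + i * self.spacing for i in range(len(self.pfams))]


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic genome."""

    genome_id: str
    replicons: tuple[tuple[str, int, bool], ...]  # (id, n_genes, circular)
    planted_clusters: tuple[PlantedCluster, ...] = ()
    background_pfam_pool: tuple[str, ...] = tuple(_BACKGROUND_POOL)
    background_density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {rid: n for rid, n, _ in self.replicons}
        occupied: dict[tuple[str, int], PlantedCluster] = {}
        for pc in self.planted_clusters:
            if pc.replicon not in sizes:
                raise ValueError(f"planted cluster on unknown replicon {pc.replicon!r}")
            for r in pc.ranks():
                if not 0 <= r < sizes[pc.replicon]:
                    raise ValueError(
                        f"planted rank {r} outside replicon {pc.replicon!r} "
                        f"(size {sizes[pc.replicon]})"
                    )
                if (pc.replicon, r) in occupied:
                    raise ValueError(
                        f"planted clusters overlap at {pc.replicon}:{r}"
                    )
                occupied[(pc.replicon, r)] = pc


def make_genome(spec: GenomeSpec) -> tuple[dict[str, str], str, GenomeCatalog]:
    """Build (PTT text per replicon, domtblout text, in-memory catalog).

    The texts and the catalog are constructed from the same gene plan by
    separate code paths, so parsing the texts back must reproduce the
    catalog exactly (a round-trip invariant the tests enforce).
    """
    rng = random.Random(spec.seed)
    planted_pfams = {p for pc in spec.planted_clusters for p in pc.pfams}
    pool = [p for p in spec.background_pfam_pool if p not in planted_pfams]

    plan: dict[str, list[tuple[int, int, str, str, str, list[str]]]] = {}
    for rep_id, n, _circ in spec.replicons:
        planted_at: dict[int, tuple[str, str | None]] = {}
        for pc in spec.planted_clusters:
            if pc.replicon != rep_id:
                continue
            for i, r in enumerate(pc.ranks()):
                tag = pc.locus_tags[i] if pc.locus_tags else None
                planted_at[r] = (pc.pfams[i], tag)
        genes = []
        for i in range(n):
            start = 1 + i * 1000
            end = start + 899
            strand = rng.choice("+-")
            pfams: list[str] = []
            if i in planted_at:
                pfam, tag = planted_at[i]
                pfams.append(pfam)
                locus = tag or f"{spec.genome_id}_{rep_id}_{i:04d}"
                product = "planted module enzyme"
            else:
                locus = f"{spec.genome_id}_{rep_id}_{i:04d}"
                product = "hypothetical protein"
                if pool and rng.random() < spec.background_density:
                    pfams.append(rng.choice(pool))
            genes.append((start, end, strand, locus, product, pfams))
        plan[rep_id] = genes

    ptt_texts = {rep: _ptt_text(spec.genome_id, rep, genes)
                 for rep, genes in plan.items()}
    domtbl_text = _domtbl_text(plan)

    replicons = {}
    for rep_id, genes in plan.items():
        replicons[rep_id] = [
            GeneRecord(
                replicon_id=rep_id, rank=i, start_bp=s, end_bp=e, strand=st,
                locus_tag=locus, product=product, pfams=frozenset(pfams),
            )
            for i, (s, e, st, locus, product, pfams) in enumerate(genes)
        ]
    catalog = GenomeCatalog(
        genome_id=spec.genome_id,
        replicons=replicons,
        circular={rid: circ for rid, _n, circ in spec.replicons},
    )
    return ptt_texts, domtbl_text, catalog


def _ptt_text(genome_id: str, rep_id: str, genes) -> str:
    lines = [
        f"{genome_id} {rep_id}, synthetic genome - 1..{genes[-1][1]}",
        f"{len(genes)} proteins",
        "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct",
    ]
    for i, (s, e, st, locus, product, _pfams) in enumerate(genes):
        aa_len = (e - s + 1) // 3 - 1
        lines.append("\t".join([
            f"{s}..{e}", st, str(aa_len), str(90000000 + i), "-", locus,
            "-", "-", product,
        ]))
    return "\n".join(lines) + "\n"


def _domtbl_text(plan) -> str:
    lines = [
        "#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for rep_id in plan:
        for _s, _e, _st, locus, _product, pfams in plan[rep_id]:
            for k, pfam in enumerate(pfams, 1):
                lines.append(
                    f"{'DUF_model':<20} {pfam + '.12':<10} {200:>5} "
                    f"{locus:<20} {'-':<10} {300:>5} "
                    f"{'1e-30':>9} {99.9:>6} {0.1:>5} {k:>3} {len(pfams):>3} "
                    f"{'1e-32':>9} {'1e-30':>9} {98.7:>6} {0.1:>5} "
                    f"{1:>5} {200:>5} {10:>5} {210:>5} {5:>5} {215:>5} 0.98 synthetic hit"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scenario suites


def make_four_genome_suite(seed: int = 42):
    """Four genomes probing the operon model of module presence.

    Returns ``(catalogs, gcm)``: a dict of four 500-gene catalogs and one
    six-Pfam module.  Genome 1 and 2 carry all six Pfams dispersed (two
    different dispersals), genome 3 carries two dispersed homologs of each
    Pfam, genome 4 carries all six on contiguous genes.  Only genome 4 has
    the genes in context.
    """
    pf = SIX_GENE_PFAMS
    specs = {
        "genome1": GenomeSpec(
            "genome1", (("chr", 500, False),),
            (PlantedCluster(tuple(pf), "chr", 30, spacing=50),), seed=seed,
        ),
        "genome2": GenomeSpec(
            "genome2", (("chr", 500, False),),
            (PlantedCluster(tuple(pf), "chr", 10, spacing=71),), seed=seed + 1,
        ),
        "genome3": GenomeSpec(
            "genome3", (("chr", 500, False),),
            (
                PlantedCluster(tuple(pf), "chr", 5, spacing=40),
                PlantedCluster(tuple(pf), "chr", 25, spacing=40),
            ),
            seed=seed + 2,
        ),
        "genome4": GenomeSpec(
            "genome4", (("chr", 500, False),),
            (PlantedCluster(tuple(pf), "chr", 200, spacing=1),), seed=seed + 3,
        ),
    }
    catalogs = {gid: make_genome(s)[2] for gid, s in specs.items()}
    gcm = Module(
        module_id="map90001_GCM000",
        kind="GCM",
        map_id="map90001",
        compound_ids=[f"C9000{i}" for i in range(1, 8)],
        pfam_set=set(pf),
        source_compound="C90001",
        target_compound="C90007",
        evidence=["20000001"],
    )
    return catalogs, gcm


_MAN_KGML = """<?xml version="1.0"?>
<pathway name="path:map00051" org="syn" number="00051" title="Fructose and mannose metabolism (fragment)">
  <entry id="1" name="cpd:C00275" type="compound"><graphics name="D-Mannose 6-phosphate"/></entry>
  <entry id="2" name="cpd:C00636" type="compound"><graphics name="D-Mannose 1-phosphate"/></entry>
  <entry id="3" name="cpd:C00096" type="compound"><graphics name="GDP-mannose"/></entry>
  <entry id="4" name="cpd:C01222" type="compound"><graphics name="GDP-4-dehydro-6-deoxy-D-mannose"/></entry>
  <entry id="5" name="cpd:C00325" type="compound"><graphics name="GDP-L-fucose"/></entry>
  <entry id="6" name="syn:B2049" type="gene" reaction="rn:R01818"><graphics name="manB"/></entry>
  <entry id="7" name="syn:B2048" type="gene" reaction="rn:R00885"><graphics name="manC"/></entry>
  <entry id="8" name="syn:B2053" type="gene" reaction="rn:R00888"><graphics name="gmd"/></entry>
  <entry id="9" name="syn:B2052" type="gene" reaction="rn:R05692"><graphics name="fcl"/></entry>
  <reaction id="6" name="rn:R01818" type="reversible">
    <substrate id="1" name="cpd:C00275"/><product id="2" name="cpd:C00636"/>
  </reaction>
  <reaction id="7" name="rn:R00885" type="irreversible">
    <substrate id="2" name="cpd:C00636"/><product id="3" name="cpd:C00096"/>
  </reaction>
  <reaction id="8" name="rn:R00888" type="irreversible">
    <substrate id="3" name="cpd:C00096"/><product id="4" name="cpd:C01222"/>
  </reaction>
  <reaction id="9" name="rn:R05692" type="irreversible">
    <substrate id="4" name="cpd:C01222"/><product id="5" name="cpd:C00325"/>
  </reaction>
</pathway>
"""


def make_man_suite(seed: int = 7):
    """The *man* cluster scenario: contiguous vs dispersed homologs.

    Returns ``(catalogs, gcm, kgml_text)``: an ``ecoli_like`` catalog with
    the four man-route Pfams on contiguous genes (locus tags B2048, B2049,
    B2053, B2052) and a ``btheta_like`` catalog with the same Pfams on
    genes at least 50 ranks apart (BT3950, BT2781, BT1224, BT1225), plus
    the module record and a KGML fragment encoding the four-reaction
    conversion of D-mannose 6-phosphate to GDP-L-fucose.
    """
    manc, manb, gmd, fcl = (
        MAN_PFAMS[1], MAN_PFAMS[0], MAN_PFAMS[2], MAN_PFAMS[3]
    )
    ecoli = GenomeSpec(
        "ecoli_like", (("chromosome", 400, True),),
        (PlantedCluster(
            (manc, manb, gmd, fcl), "chromosome", 150, spacing=1,
            locus_tags=("B2048", "B2049", "B2053", "B2052"),
        ),),
        seed=seed,
    )
    btheta = GenomeSpec(
        "btheta_like", (("chromosome", 400, True),),
        (
            PlantedCluster((gmd,), "chromosome", 40, locus_tags=("BT3950",)),
            PlantedCluster((fcl,), "chromosome", 130, locus_tags=("BT2781",)),
            PlantedCluster((manb,), "chromosome", 230, locus_tags=("BT1224",)),
            PlantedCluster((manc,), "chromosome", 330, locus_tags=("BT1225",)),
        ),
        seed=seed + 1,
    )
    catalogs = {
        "ecoli_like": make_genome(ecoli)[2],
        "btheta_like": make_genome(btheta)[2],
    }
    gcm = Module(
        module_id="map00051_GCM_man",
        kind="GCM",
        map_id="map00051",
        compound_ids=["C00275", "C00636", "C00096", "C01222", "C00325"],
        pfam_set=set(MAN_PFAMS),
        source_compound="C00275",
        target_compound="C00325",
        gene_ids={"B2048", "B2049", "B2052", "B2053"},
        gene_assignments={"ecoli_like": {"B2048", "B2049", "B2052", "B2053"}},
        evidence=["20000002"],
    )
    return catalogs, gcm, _MAN_KGML


def man_pathway_graph() -> PathwayGraph:
    return parse_kgml(_MAN_KGML)


# ---------------------------------------------------------------------------
# hit lists and randomized specs


def make_hitlists(
    module_id: str, design: dict[str, set[int]], seed: int = 0
) -> list[list[str]]:
    """Six hit lists: list i contains exactly the PMIDs whose design set
    includes query number i (1-based).  Independent of ``seed`` — the
    argument exists only for interface symmetry with the other makers.
    """
    for pmid, queries in design.items():
        if not queries <= set(range(1, 7)):
            raise ValueError(f"design for PMID {pmid} names queries outside 1..6")
    return [
        sorted(pmid for pmid, queries in design.items() if i in queries)
        for i in range(1, 7)
    ]


def write_hitlists(
    directory: str | Path, module_id: str, design: dict[str, set[int]]
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, lst in enumerate(make_hitlists(module_id, design), 1):
        path = directory / f"{module_id}.q{i}.txt"
        path.write_text("".join(f"{p}\n" for p in lst))
        paths.append(path)
    return paths


def random_genome_spec(
    seed: int,
    max_genes: int = 500,
    pfams: list[str] | None = None,
) -> GenomeSpec:
    """A randomized single-replicon spec with one planted cluster.

    Used by the property tests and the acceptance checks: cluster
    position, spacing, circularity and background density vary with the
    seed.
    """
    rng = random.Random(seed)
    n = rng.randint(60, max_genes)
    pfams = pfams or rng.sample(SIX_GENE_PFAMS, rng.randint(2, 6))
    spacing = rng.choice([1, 1, 2, 3, 25, 60])
    if len(pfams) > 1:
        spacing = min(spacing, (n - 1) // (len(pfams) - 1))
    spacing = max(spacing, 1)
    span = (len(pfams) - 1) * spacing
    start = rng.randint(0, max(0, n - span - 1))
    return GenomeSpec(
        genome_id=f"rand{seed}",
        replicons=(("chr", n, rng.random() < 0.5),),
        planted_clusters=(
            PlantedCluster(tuple(pfams), "chr", start, spacing=spacing),
        ),
        background_pfam_pool=tuple(_BACKGROUND_POOL),
        background_density=rng.uniform(0.1, 0.5),
        seed=seed,
    )


def write_fixture_tree(directory: str | Path, seed: int = 42) -> list[Path]:
    """Materialise every scenario suite as plain-text files."""
    from .genome_catalog import catalog_to_tsv
    from .modules import modules_to_json

    directory = Path(directory)
    written: list[Path] = []

    def _write(path: Path, text: str) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        written.append(path)

    four_genome_catalogs, four_genome_gcm = make_four_genome_suite(seed=seed)
    man_catalogs, man_gcm, kgml = make_man_suite()

    for gid, cat in four_genome_catalogs.items():
        _write(directory / "four_genome" / f"{gid}.catalog.tsv", catalog_to_tsv(cat))
    _write(directory / "four_genome" / "gcm.json", modules_to_json([four_genome_gcm]))

    for gid, cat in man_catalogs.items():
        _write(directory / "man" / f"{gid}.catalog.tsv", catalog_to_tsv(cat))
    # raw PTT/domtblout for one man genome, exercising the parsers
    ecoli_ptt, ecoli_dom, _ = make_genome(GenomeSpec(
        "ecoli_like", (("chromosome", 400, True),),
        (PlantedCluster(
            (MAN_PFAMS[1], MAN_PFAMS[0], MAN_PFAMS[2], MAN_PFAMS[3]),
            "chromosome", 150, spacing=1,
            locus_tags=("B2048", "B2049", "B2053", "B2052"),
        ),),
        seed=7,
    ))
    _write(directory / "man" / "ecoli_like.chromosome.ptt",
           ecoli_ptt["chromosome"])
    _write(directory / "man" / "ecoli_like.domtblout", ecoli_dom)
    _write(directory / "man" / "map00051.kgml", kgml)
    _write(directory / "man" / "gcm.json", modules_to_json([man_gcm]))

    write_hitlists(
        directory / "hitlists", man_gcm.module_id,
        {
            "20000002": {1, 2, 3, 4, 5, 6},
            "20000003": {1, 2, 3, 4},
            "20000004": {1, 2, 3},
        },
    )
    written.extend(sorted((directory / "hitlists").glob("*.txt")))
    _write(
        directory / "hitlists" / "pmid_organisms.tsv",
        "20000002\tEscherichia coli\n20000003\tHaemophilus influenzae\n",
    )
    return written
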