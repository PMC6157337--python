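# gcmkit

Gene-context-based module definition and detection in bacterial metabolic
pathways.

## The problem

Homology-based pathway annotation (KEGG-style mapping of genes to
reference pathways) tells you which enzymes a bacterium *encodes*, not
which pathways it actually *runs*: homologs of the same enzyme family
serve different pathways, so the mere presence of every constituent gene
somewhere on a genome is weak evidence. Bacterial sub-pathways, however,
are typically encoded by co-regulated genes in juxtaposed arrangement
(operons and conserved gene clusters). `gcmkit` exploits that genomic
context: a sub-pathway is called present only when enough of its protein
domain families co-occur within a bounded stretch of consecutive genes.

The classic example is the *man* gene cluster (*manB*, *manC*, *gmd*,
*fcl*) converting D-mannose 6-phosphate to GDP-L-fucose. *Escherichia
coli* carries the four genes side by side and runs the conversion;
*Bacteroides thetaiotaomicron* carries dispersed homologs of all four
enzymes and does not. Homology-only annotation maps the pathway to both.

## The method

1. **Pathway graph** — a KGML map is parsed into a graph with compounds
   as nodes and reactions as edges (`gcmkit.pathway_io`).
2. **Initial Reference Modules (IRMs)** — the graph is partitioned by
   modularity maximisation; each community of compounds is one IRM.
   A gene catalysing a reaction that bridges two communities (a *linker
   gene*) is assigned to both (`gcmkit.irm_builder`).
3. **Genome catalog** — per genome, genes are ordered along each replicon
   (rank = position in gene order) and annotated with Pfam domain
   families from HMMER3 `--domtblout` output; coordinates and strand come
   from NCBI PTT tables (`gcmkit.genome_catalog`).
4. **Context refinement** — the genes of all IRMs of a pathway are pooled
   on one genome and clustered by single-linkage on rank distance with a
   minimum distance score of 10 intervening genes: clusters closer than
   the threshold merge, distant shards split. Each resulting cluster is
   an Intermediate Module (IM), which may equal one IRM, merge several,
   or split one (`gcmkit.context_refiner`).
5. **Literature validation (6Q)** — each IM, viewed as a
   reactant → product conversion, is probed with six structured queries
   (reactant; product; both; + *bacteria*; + *operon*; + *"gene
   cluster"*) against offline PubMed hit lists; PMIDs found in ≥ 4 of the
   6 lists form the consensus, and an offline PMID → organism table
   supplies reference organisms (`gcmkit.litmine`). A validated IM with a
   designated source/target compound pair becomes a **Gene Context based
   Module (GCM)**.
6. **Detection** — a genome is scanned for each GCM: for window size *w*
   (flanking genes per side) every stretch of ≤ 2*w* + 1 consecutive
   genes is scored by the percentage of the GCM's distinct Pfams it
   contains; the GCM is present where coverage reaches the chosen cutoff
   (`gcmkit.detector`).

All inputs can be generated synthetically (`gcmkit.fixtures`), including
the two benchmark suites: a four-genome suite where only one genome has
a six-gene module in context, and the *man* suite described above.

## Worked example

```python
from gcmkit.fixtures import make_man_suite
from gcmkit.detector import DetectionParams, scan_genome

catalogs, gcm, kgml = make_man_suite()
params = DetectionParams(window_size=5, cutoff_percent=100)
for gid in ("ecoli_like", "btheta_like"):
    for call in scan_genome(catalogs[gid], gcm, params):
        print(f"{gid}: present={call.present} "
              f"coverage={call.coverage_percent:.0f}% "
              f"genes {call.rank_span[0]}..{call.rank_span[1]} "
              f"missing={sorted(call.missing_pfams)}")
```

prints

```
ecoli_like: present=True coverage=100% genes 143..160 missing=[]
btheta_like: present=False coverage=25% genes 30..40 missing=['PF00483', 'PF01050', 'PF01370']
```

The *E. coli*-like genome shows all four man-route Pfams (PF01050,
PF00483, PF16363, PF01370) inside one 11-gene window, so the GCM is
present at 100% coverage. The *B. thetaiotaomicron*-like genome never
exceeds 25% — each window holds at most one lone homolog — so at full
stringency the module is correctly absent, and the reported best window
shows *how much* of it is there. Dropping the cutoff to 25 would accept
each homolog individually (four present calls at exactly 25% coverage).

The same analysis is available from the shell:

```sh
gcmkit fixtures --out fixtures
gcmkit build catalog --ptt fixtures/man/ecoli_like.chromosome.ptt \
    --domtbl fixtures/man/ecoli_like.domtblout \
    --genome-id ecoli_like --circular chromosome --out ecoli.catalog.tsv
gcmkit scan --kgml fixtures/man/map00051.kgml --genome ecoli.catalog.tsv \
    --gcms fixtures/man/gcm.json --window 5 --cutoff 100 --out results/
```

which writes `detections.tsv`, an annotated `annotated_graph.graphml`
(nodes carry `present`/`module_id` attributes) and a JSON run log.

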