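# Methods

## Model

A metabolic pathway map is treated as an undirected graph of compounds
joined by reactions. The working hypothesis is the operon model of
bacterial sub-pathways: a biologically real functional unit is encoded by
genes that lie close together on the genome, so a sub-pathway's presence
in a genome should be judged by *juxtaposed* occurrence of the catalysing
genes' protein domain families (Pfams), not by homology alone. The
pipeline has three layers: network structure (edge-connectivity
communities → IRMs), genomic context (proximity re-clustering → IMs), and
literature validation (6Q consensus → GCMs); detection then asks, per
genome and per GCM, whether enough of the module's Pfams co-occur within
a bounded gene window.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| `distance_threshold` | intervening gene ranks | 10 | single-linkage merge radius for context clustering |
| `window_size` | flanking genes per side | 5 | half-width of the detection window (stretch ≤ 2w+1 genes) |
| `cutoff_percent` | % of the GCM's distinct Pfams | 100 | minimum window coverage for a present call; ≥ comparison, so exact equality passes |
| `e_threshold` | independent-domain E-value | 1e-5 | HMMER3 domain-hit inclusion; set to `inf` to trust upstream gathering-threshold filtering |
| `consensus_k` | lists (of 6) | 4 | minimum number of query hit lists a PMID must appear in |

Distance and window arithmetic is done in *gene-rank* units (position in
the coordinate-sorted gene order of a replicon), because the window is
defined as a number of flanking genes; base-pair distances would conflate
gene length with spacing. Distances across replicons are infinite, so no
module or window ever spans a chromosome/plasmid boundary. Circular
replicons wrap: distance is `min(d, n − d)` and windows cross the origin.

## Community detection

The default method maximises Newman modularity on the undirected simple
graph (reversible reactions count once; parallel reactions collapse to a
weighted edge; compound entries that link out to other maps are excluded
as `external`). Because the partition seeds everything downstream,
determinism is non-negotiable: ties are broken lexicographically on
compound ids. For graphs of ≤ 10 non-external compounds — every bundled
fixture and most single-map compound graphs — the optimum is found
exactly by enumerating all set partitions (Bell(10) ≈ 1.2 × 10⁵, trivial
at this size); larger graphs use greedy agglomeration followed by a
deterministic best-improvement local search over single-node moves,
community merges and exhaustive small-community splits. The exact small-
graph path exists because greedy agglomeration demonstrably locks into
local optima even on 8-node graphs; exactness at fixture scale is what
the test oracles assume. Girvan–Newman edge-betweenness (best-modularity
cut along the divisive hierarchy) is selectable as an alternative.
Isolated compounds form singleton communities. A community's compounds
are ordered topologically along its internal reactions when acyclic,
lexicographically (flagged `cyclic`) otherwise.

## Context refinement

Genes of all IRMs of a pathway on one genome are pooled and clustered by
single-linkage: two genes share a cluster iff a chain of pool genes
connects them with every step ≤ `distance_threshold`. Single linkage is
the right reading of a *minimum* distance merge score; it also makes the
procedure idempotent, so the prescribed "repeat until stable" loop
converges immediately (a `max_iterations = 20` bound guards the loop
regardless). Mean inter/intra-module distances are computed as
diagnostics but never drive merging. Each cluster becomes an IM
inheriting the union of compounds and Pfams of the IRMs whose genes it
contains; one-gene clusters are flagged `unclustered`, multi-IRM clusters
`merged`, shards of a split IRM `split`. Linker genes are resolved to the
module of their nearest non-linker pool gene (`nearest`, the default;
exact ties keep both; `duplicate` keeps both always). Manual curation is
represented as an explicit overlay file of add/remove/rename records
rather than code, so curation is reproducible and auditable.

## Detection

For window size w, every contiguous interval of ≤ 2w+1 genes (clipped at
linear ends, wrapped on circular replicons) is scored by the percentage
of the GCM's *distinct* Pfams present on its genes: a Pfam on several
genes counts once, one gene carrying several module Pfams contributes all
of them. The scan skips intervals containing no module Pfam — purely an
optimisation; results equal exhaustive interval scoring, and the tests
hold the scan to an independent brute-force oracle. Deliberately, windows
are *not* centered on anchor genes only: two anchor genes 2w ranks apart
share a qualifying interval that no centered window contains, so centered
scanning would under-call. Overlapping qualifying windows merge into one
maximal call (union of ranks, best single-window coverage and matched
set). When nothing qualifies, the single best-coverage window is still
reported with `present = False`, so the extent of partial presence is
always visible. Strand is recorded but not constrained: operons are
strand-coherent in practice, but imposing strandedness would be an
additional assumption the method does not need.

## Literature consensus (6Q)

Queries are serialised in plain quoted boolean form, synonym lists sorted
before OR-expansion so strings are order-independent; field tags are left
to the search engine. Live PubMed/Pubtator access is deliberately out of
scope — result drift would make runs irreproducible — so hit lists and
the PMID → organism map are ingested from offline files. "At least 4 of
6" is inclusive: membership in exactly 4 lists qualifies. Consensus
PMIDs absent from both the *operon* and *gene cluster* lists are flagged
context-unverified: they support the chemical conversion but not the gene
arrangement, and need genome-side confirmation.

## Synthetic data

The generators emulate the structural features the method reads — gene
order, spacing, strand, domain annotations — and nothing else: gene
lengths are uniform (900 bp on a 1 kb grid), there are no sequences, no
overlapping genes, no operon-length distribution, and background domain
annotations are drawn independently per gene (density 0.3, a round figure
in the range of typical annotation coverage) from a pool disjoint from
all planted Pfams. Passing tests therefore demonstrate the *logic* of
context scoring — planted clusters are found, dispersed homologs are
rejected, oracles agree — not performance on real annotation noise,
promiscuous domains, or mis-called gene boundaries. Scenario geometry:
the four-genome suite uses 500-gene genomes with six-Pfam plants
(dispersed at spacings ≥ 40, or contiguous); the *man* suite uses
400-gene circular genomes with the four real man-route Pfam accessions
(PF01050, PF00483, PF16363, PF01370) and the reference locus tags, with
dispersed homologs ≥ 50 ranks apart. Randomized property fixtures use up
to 500 genes; these sizes keep the full suite and the acceptance script
in seconds while exercising every code path.

## Numerical and degenerate-input choices

- Coverage comparison is `>=` at the cutoff; modularity improvements use
  a 1e-12 strict-improvement margin to keep tie-breaking deterministic.
- Nested genes order by (start, end, locus tag); duplicate locus tags are
  a hard error, duplicate compound entries merge.
- `window_size = 0` means a single gene must carry the required Pfams;
  a window larger than a circular replicon means the whole replicon.
- Empty gene pools refine to zero IMs; empty GCM Pfam sets are rejected
  rather than scored.
- Pfam accession versions (`PF00483.23`) are stripped on ingest;
  stripping is idempotent.

## Known limitations

- Domain-composition ambiguity: isofunctional clusters sharing the same
  Pfam composition (e.g. branched-chain keto-acid vs pyruvate
  dehydrogenase complexes) cannot be distinguished; resolving them needs
  active-site-level specificity, which is out of scope.
- Coverage is unweighted: a hit is a hit regardless of domain E-value or
  of whether the window's genes appear in pathway order.
- Cross-genome consolidation of IMs is represented by a per-genome
  refinement plus a minimum-support consensus knob, not by the original
  corpus-scale consolidation over thousands of genomes.
- The 6Q stage validates only against the hit lists it is given; it
  inherits whatever biases produced them.
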