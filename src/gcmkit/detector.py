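"""Windowed detection of gene-context modules on a genome.

A GCM is called *present* on a genome when a sufficient percentage of its
distinct Pfam families co-occur within a bounded stretch of consecutive
genes.  Two knobs control stringency: the window size w (number of
flanking genes on each side of a focal gene, so an examined stretch spans
at most 2w+1 genes) and the coverage cutoff (minimum percentage of the
module's Pfams that must appear inside one stretch).

The scan examines every contiguous gene interval of length 2w+1 (clipped
at linear replicon ends, wrapping on circular replicons).  Intervals
containing no module Pfam at all score zero and are skipped — an
optimisation only; results are identical to exhaustive interval scoring,
and the test suite holds the scan to an independent brute-force oracle.
A Pfam present on several genes in a window counts once; a single gene
carrying several module Pfams contributes all of them.  Strand is
recorded in the catalog but deliberately not constrained here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_catalog import GenomeCatalog
from .modules import Module
from .pathway_io import PathwayGraph, export_annotated_graph

__all__ = [
    "DetectionParams",
    "DetectionCall",
    "scan_genome",
    "scan_pathway",
    "calls_to_tsv",
]

_TSV_COLUMNS = [
    "gcm_id", "genome_id", "replicon", "start_rank", "end_rank",
    "start_bp", "end_bp", "matched_pfams", "missing_pfams",
    "coverage_percent", "present",
]


@dataclass(frozen=True)
class DetectionParams:
    """Stringency of the context query.

    window_size
        Flanking genes on each side of a focal gene; the examined stretch
        is at most ``2*window_size + 1`` consecutive genes.
    cutoff_percent
        Minimum percentage of the module's distinct Pfams that must occur
        inside one stretch; coverage exactly equal to the cutoff passes.
        Lower cutoffs admit partial modules.
    """

    window_size: int = 5
    cutoff_percent: float = 100.0

    def __post_init__(self) -> None:
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")
        if not 0 < self.cutoff_percent <= 100:
            raise ValueError("cutoff_percent must be in (0, 100]")


@dataclass
class DetectionCall:
    """One (merged) window hit of a GCM on a replicon.

    ``rank_span`` is inclusive; on a circular replicon ``start > end``
    means the span wraps through the origin.  ``coverage_percent`` is
    100 × |matched| / |module Pfams| of the best single window inside the
    span; ``matched ∪ missing`` always equals the module's Pfam set.
    """

    gcm_id: str
    genome_id: str
    replicon_id: str
    rank_span: tuple[int, int]
    matched_pfams: set[str]
    missing_pfams: set[str]
    coverage_percent: float
    present: bool
    compound_ids: list[str] = field(default_factory=list)

    @property
    def bp_span(self) -> tuple[int, int]:
        return self._bp  # set by scan_genome

    def _span_ranks(self, n: int) -> list[int]:
        s, e = self.rank_span
        if s <= e:
            return list(range(s, e + 1))
        return list(range(s, n)) + list(range(0, e + 1))


def _windows(n: int, w: int, circular: bool):
    """Yield (start, ranks) for every maximal interval of length <= 2w+1."""
    length = min(2 * w + 1, n)
    if circular and 2 * w + 1 >= n:
        yield 0, list(range(n))
        return
    if circular:
        for s in range(n):
            yield s, [(s + k) % n for k in range(length)]
    else:
        for s in range(n - length + 1):
            yield s, list(range(s, s + length))


def scan_genome(
    catalog: GenomeCatalog, gcm: Module, params: DetectionParams
) -> list[DetectionCall]:
    """Scan every replicon of a genome for one module.

    Overlapping qualifying windows merge into one maximal call spanning
    their union of ranks and reporting the best individual window's
    coverage and matched set.  When no window reaches the cutoff, the
    single best-coverage window of the genome is still reported with
    ``present=False`` so the *extent* of domain presence is visible; an
    entirely Pfam-free genome yields one zero-coverage call over an empty
    span of the first replicon.
    """
    if not gcm.pfam_set:
        raise ValueError(f"{gcm.module_id}: GCM has an empty Pfam set")
    target = set(gcm.pfam_set)
    calls: list[DetectionCall] = []
    best_fallback: DetectionCall | None = None

    for rep_id in sorted(catalog.replicons):
        records = catalog.replicons[rep_id]
        n = len(records)
        if n == 0:
            continue
        circular = catalog.is_circular(rep_id)
        anchor_ranks = {r.rank for r in records if r.pfams & target}

        qualifying: list[tuple[list[int], set[str], float]] = []
        rep_best: tuple[float, list[int], set[str]] | None = None
        for _, ranks in _windows(n, params.window_size, circular):
            if not anchor_ranks.intersection(ranks):
                matched: set[str] = set()
            else:
                matched = set()
                for r in ranks:
                    matched |= records[r].pfams & target
            coverage = 100.0 * len(matched) / len(target)
            if rep_best is None or coverage > rep_best[0]:
                rep_best = (coverage, ranks, matched)
            if coverage >= params.cutoff_percent:
                qualifying.append((ranks, matched, coverage))

        if qualifying:
            calls.extend(
                _merge_windows(qualifying, gcm, catalog, rep_id, n, circular)
            )
        if rep_best is not None:
            cand = _make_call(
                gcm, catalog, rep_id,
                _ranks_to_span(rep_best[1], n), rep_best[2], rep_best[0],
                present=False,
            )
            if best_fallback is None or cand.coverage_percent > best_fallback.coverage_percent:
                best_fallback = cand

    if calls:
        calls.sort(key=lambda c: (c.replicon_id, c.rank_span[0]))
        return calls
    if best_fallback is not None:
        return [best_fallback]
    return []


def _ranks_to_span(ranks: list[int], n: int) -> tuple[int, int]:
    """Inclusive span of a rank list; detects wrap on circular windows."""
    s = set(ranks)
    if len(s) == n:
        return (0, n - 1)
    lo, hi = min(s), max(s)
    if hi - lo + 1 == len(s):
        return (lo, hi)
    # wrapped: find the gap and span the complement
    present = sorted(s)
    for a, b in zip(present, present[1:]):
        if b - a > 1:
            return (b, a)
    return (lo, hi)


def _merge_windows(qualifying, gcm, catalog, rep_id, n, circular):
    """Union-merge overlapping qualifying windows; keep best coverage each."""
    groups: list[tuple[set[int], set[str], float]] = []
    for ranks, matched, coverage in qualifying:
        rset = set(ranks)
        merged_into = None
        i = 0
        while i < len(groups):
            gset, gmatched, gcov = groups[i]
            if gset & rset:
                if merged_into is None:
                    groups[i] = (
                        gset | rset,
                        matched if coverage > gcov else gmatched,
                        max(gcov, coverage),
                    )
                    merged_into = i
                else:
                    # window bridges two existing groups — fuse them
                    tgt = groups[merged_into]
                    groups[merged_into] = (
                        tgt[0] | gset,
                        tgt[1] if tgt[2] >= gcov else gmatched,
                        max(tgt[2], gcov),
                    )
                    groups.pop(i)
                    continue
            i += 1
        if merged_into is None:
            groups.append((rset, set(matched), coverage))
    calls = []
    for gset, gmatched, gcov in groups:
        calls.append(_make_call(
            gcm, catalog, rep_id,
            _ranks_to_span(sorted(gset), n), gmatched, gcov, present=True,
        ))
    return calls


def _make_call(gcm, catalog, rep_id, span, matched, coverage, present):
    records = catalog.replicons[rep_id]
    call = DetectionCall(
        gcm_id=gcm.module_id,
        genome_id=catalog.genome_id,
        replicon_id=rep_id,
        rank_span=span,
        matched_pfams=set(matched),
        missing_pfams=set(gcm.pfam_set) - set(matched),
        coverage_percent=coverage,
        present=present,
        compound_ids=list(gcm.compound_ids),
    )
    s, e = span
    call._bp = (records[s].start_bp, records[e].end_bp)
    return call


def scan_pathway(
    catalog: GenomeCatalog,
    gcm_catalog: list[Module],
    graph: PathwayGraph,
    params: DetectionParams,
    graph_format: str = "graphml",
) -> tuple[list[DetectionCall], str, str]:
    """Scan all GCMs of one pathway map against a genome.

    Returns ``(calls, table_tsv, annotated_graph_text)``.  GCMs whose
    ``map_id`` differs from the graph's are ignored; with no applicable
    GCM the table carries a status comment instead of rows.
    """
    applicable = sorted(
        (m for m in gcm_catalog if m.kind == "GCM" and m.map_id == graph.map_id),
        key=lambda m: m.module_id,
    )
    calls: list[DetectionCall] = []
    for gcm in applicable:
        calls.extend(scan_genome(catalog, gcm, params))
    if applicable:
        table = calls_to_tsv(calls)
    else:
        table = (
            "# no GCMs in the catalog apply to pathway "
            f"{graph.map_id}; nothing scanned\n" + "\t".join(_TSV_COLUMNS) + "\n"
        )
    annotated = export_annotated_graph(graph, calls, format=graph_format)
    return calls, table, annotated


def calls_to_tsv(calls: list[DetectionCall]) -> str:
    lines = ["\t".join(_TSV_COLUMNS)]
    for c in sorted(calls, key=lambda c: (c.gcm_id, c.replicon_id, c.rank_span)):
        bp = getattr(c, "_bp", ("", ""))
        lines.append("\t".join([
            c.gcm_id, c.genome_id, c.replicon_id,
            str(c.rank_span[0]), str(c.rank_span[1]), str(bp[0]), str(bp[1]),
            ";".join(sorted(c.matched_pfams)), ";".join(sorted(c.missing_pfams)),
            f"{c.coverage_percent:.6g}", "1" if c.present else "0",
        ]))
    return "\n".join(lines) + "\n"
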