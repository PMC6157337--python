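"""The genome–Pfam map: ordered per-replicon gene catalogs (DB1).

Gene-context analysis needs, for every genome, the genes of each replicon
in genomic order together with the Pfam domain families each gene encodes.
This module reads NCBI PTT protein tables (gene coordinates, strand, locus
tags) and HMMER3 ``--domtblout`` tables (per-domain Pfam hits) and merges
them into a :class:`GenomeCatalog`.  All context arithmetic downstream is
done in *rank* units — a gene's 0-based position in the coordinate-sorted
gene order of its replicon — because the detection window is defined as a
number of flanking genes, not base pairs.

Genes with no Pfam hit are retained with an empty domain set, so rank
distances reflect true gene spacing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "GeneRecord",
    "GenomeCatalog",
    "PTTError",
    "strip_pfam_version",
    "read_ptt",
    "read_domtbl",
    "build_catalog",
    "catalog_to_tsv",
    "catalog_from_tsv",
]

_PFAM_RE = re.compile(r"^PF\d{5}$")


class PTTError(ValueError):
    """Raised for malformed PTT input."""


def strip_pfam_version(accession: str) -> str:
    """``PF00483.23`` → ``PF00483``; idempotent."""
    return accession.split(".", 1)[0]


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a replicon.

    ``rank`` is the 0-based index in coordinate order along the replicon;
    ``start_bp``/``end_bp`` are 1-based inclusive (PTT convention).
    """

    replicon_id: str
    rank: int
    start_bp: int
    end_bp: int
    strand: str
    locus_tag: str
    product: str = ""
    pfams: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"{self.locus_tag}: start_bp {self.start_bp} > end_bp {self.end_bp}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be + or -")


@dataclass
class GenomeCatalog:
    """Ordered gene catalog of one genome, one rank space per replicon."""

    genome_id: str
    replicons: dict[str, list[GeneRecord]] = field(default_factory=dict)
    circular: dict[str, bool] = field(default_factory=dict)
    _index: dict[str, GeneRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        for records in self.replicons.values():
            for rec in records:
                if rec.locus_tag in self._index:
                    raise ValueError(
                        f"duplicate locus_tag {rec.locus_tag!r} in genome "
                        f"{self.genome_id!r}"
                    )
                self._index[rec.locus_tag] = rec

    def gene(self, locus_tag: str) -> GeneRecord:
        try:
            return self._index[locus_tag]
        except KeyError:
            raise KeyError(
                f"locus_tag {locus_tag!r} not in genome {self.genome_id!r}"
            ) from None

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._index

    def locus_tags(self) -> list[str]:
        return sorted(self._index)

    def n_genes(self, replicon_id: str | None = None) -> int:
        if replicon_id is not None:
            return len(self.replicons[replicon_id])
        return sum(len(r) for r in self.replicons.values())

    def is_circular(self, replicon_id: str) -> bool:
        return bool(self.circular.get(replicon_id, False))


def read_ptt(text: str, replicon_id: str) -> list[GeneRecord]:
    """Parse one PTT protein table into coordinate-sorted gene records.

    The PTT dialect: a free-text description line, a ``N proteins`` line,
    a column-title line (``Location\\tStrand\\t…``), then one tab-separated
    row per protein with ``Location`` as ``start..end`` and the ``Synonym``
    column holding the locus tag.  Rows are re-sorted by start coordinate
    (ties broken by end, then locus tag, so nested genes order stably) and
    ranks assigned 0..n−1.  Pfams are left empty here.
    """
    lines = text.splitlines()
    rows = []
    data_started = False
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip():
            continue
        if not data_started:
            # skip the description and count lines; the column-title line
            # marks the start of data
            if ln.startswith("Location"):
                data_started = True
            continue
        fields = ln.split("\t")
        if len(fields) < 9:
            raise PTTError(f"line {lineno}: expected 9 PTT columns, got {len(fields)}")
        loc, strand, _length, _pid, _gene, synonym, _code, _cog, product = fields[:9]
        m = re.match(r"^(\d+)\.\.(\d+)$", loc.strip())
        if not m:
            raise PTTError(f"line {lineno}: malformed Location field {loc!r}")
        rows.append((int(m.group(1)), int(m.group(2)), strand.strip(),
                     synonym.strip(), product.strip()))
    if not data_started:
        raise PTTError("no PTT column-title line found (expected 'Location...')")

    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    seen: set[str] = set()
    records = []
    for rank, (start, end, strand, locus, product) in enumerate(rows):
        if locus in seen:
            raise PTTError(f"duplicate locus_tag {locus!r} in PTT table")
        seen.add(locus)
        records.append(GeneRecord(
            replicon_id=replicon_id, rank=rank, start_bp=start, end_bp=end,
            strand=strand, locus_tag=locus, product=product,
        ))
    return records


def read_domtbl(text: str, e_threshold: float = 1e-5) -> dict[str, set[str]]:
    """Parse HMMER3 ``--domtblout`` output into locus_tag → Pfam set.

    Assumes hmmscan against Pfam: the target accession column holds the
    Pfam accession (version suffix stripped) and the query name is the
    locus tag.  A domain hit counts iff its independent (per-domain)
    E-value is at or below ``e_threshold``; pass ``float('inf')`` to trust
    upstream gathering-threshold filtering.
    """
    hits: dict[str, set[str]] = {}
    for lineno, ln in enumerate(text.splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        fields = ln.split()
        if len(fields) < 13:
            warnings.warn(f"domtblout line {lineno}: too few columns, skipped")
            continue
        accession, query = fields[1], fields[3]
        try:
            i_evalue = float(fields[12])
        except ValueError:
            warnings.warn(
                f"domtblout line {lineno}: unparseable i-Evalue "
                f"{fields[12]!r}, skipped"
            )
            continue
        if i_evalue <= e_threshold:
            acc = strip_pfam_version(accession)
            if _PFAM_RE.match(acc):
                hits.setdefault(query, set()).add(acc)
            else:
                warnings.warn(
                    f"domtblout line {lineno}: accession {accession!r} is not "
                    f"a Pfam accession, skipped"
                )
    return hits


def build_catalog(
    genome_id: str,
    ptt_records: dict[str, list[GeneRecord]],
    pfam_map: dict[str, set[str]],
    circular_flags: dict[str, bool] | None = None,
) -> GenomeCatalog:
    """Merge PTT gene records with Pfam annotations into one catalog.

    ``ptt_records`` maps replicon id to that replicon's gene records (as
    from :func:`read_ptt`).  Genes missing from ``pfam_map`` keep an empty
    Pfam set; map keys with no matching gene draw a warning.
    """
    circular_flags = circular_flags or {}
    known = {rec.locus_tag for recs in ptt_records.values() for rec in recs}
    orphans = sorted(set(pfam_map) - known)
    if orphans:
        warnings.warn(
            f"{len(orphans)} Pfam-annotated loci not in the PTT tables "
            f"(first: {orphans[0]!r})"
        )
    replicons: dict[str, list[GeneRecord]] = {}
    for rep_id, records in ptt_records.items():
        ordered = sorted(records, key=lambda r: (r.start_bp, r.end_bp, r.locus_tag))
        replicons[rep_id] = [
            replace(
                rec,
                rank=rank,
                pfams=frozenset(
                    strip_pfam_version(p) for p in pfam_map.get(rec.locus_tag, ())
                ),
            )
            for rank, rec in enumerate(ordered)
        ]
    return GenomeCatalog(
        genome_id=genome_id,
        replicons=replicons,
        circular={r: bool(circular_flags.get(r, False)) for r in replicons},
    )


def catalog_to_tsv(catalog: GenomeCatalog) -> str:
    lines = ["\t".join([
        "genome_id", "replicon_id", "circular", "rank", "start", "end",
        "strand", "locus_tag", "product", "pfams",
    ])]
    for rep_id in sorted(catalog.replicons):
        for rec in catalog.replicons[rep_id]:
            lines.append("\t".join([
                catalog.genome_id, rep_id,
                "1" if catalog.is_circular(rep_id) else "0",
                str(rec.rank), str(rec.start_bp), str(rec.end_bp), rec.strand,
                rec.locus_tag, rec.product, ";".join(sorted(rec.pfams)),
            ]))
    return "\n".join(lines) + "\n"


def catalog_from_tsv(text: str) -> GenomeCatalog:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty catalog TSV")
    genome_id = None
    replicons: dict[str, list[GeneRecord]] = {}
    circular: dict[str, bool] = {}
    for ln in lines[1:]:
        f = ln.split("\t")
        genome_id = f[0]
        rep = f[1]
        circular[rep] = f[2] == "1"
        replicons.setdefault(rep, []).append(GeneRecord(
            replicon_id=rep, rank=int(f[3]), start_bp=int(f[4]), end_bp=int(f[5]),
            strand=f[6], locus_tag=f[7], product=f[8] if len(f) > 8 else "",
            pfams=frozenset(p for p in (f[9] if len(f) > 9 else "").split(";") if p),
        ))
    if genome_id is None:
        raise ValueError("catalog TSV has no data rows")
    for rep in replicons:
        replicons[rep].sort(key=lambda r: r.rank)
    return GenomeCatalog(genome_id=genome_id, replicons=replicons, circular=circular)
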