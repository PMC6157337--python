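"""Literature consensus over six structured queries (the 6Q strategy).

Each module is a reactant → product conversion; its literature support is
probed with six boolean queries of increasing specificity:

1. the reactant (OR-expanded over its synonyms)
2. the product (likewise)
3. reactant AND product
4. reactant AND product AND ``bacteria``
5. reactant AND product AND ``operon``
6. reactant AND product AND ``"gene cluster"``

Query execution against PubMed/Pubtator is out of scope here — result
drift would make runs irreproducible — so hit lists are ingested from
plain files (one PMID per line, six per module).  A PMID found in at
least ``k`` of the six lists (default 4) counts as consensus evidence;
consensus PMIDs are then mapped to reference organisms through an offline
PMID → organism table.  A consensus PMID appearing in neither the
``operon`` nor the ``gene cluster`` list supports the *conversion* but
not the *gene context*, and is flagged accordingly: such modules need
genome-side verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "QuerySet",
    "EvidenceRecord",
    "build_queries",
    "consensus_pmids",
    "attach_organisms",
    "read_hitlists",
    "read_pmid_organism_table",
]

_KEYWORD_QUERIES = {5: "operon", 6: "gene cluster"}


@dataclass(frozen=True)
class QuerySet:
    """The six query strings for one reactant/product pair."""

    module_id: str
    reactant_string: str
    product_string: str
    reactant_synonyms: tuple[str, ...]
    product_synonyms: tuple[str, ...]
    queries: tuple[str, ...]
    consensus_k: int = 4

    def __post_init__(self) -> None:
        if len(self.queries) != 6:
            raise ValueError("a QuerySet holds exactly 6 queries")
        if not 1 <= self.consensus_k <= 6:
            raise ValueError("consensus_k must be in 1..6")


@dataclass
class EvidenceRecord:
    """Consensus PMIDs for a module, with organisms and keyword support."""

    module_id: str
    consensus_pmids: set[str]
    pmid_organisms: dict[str, list[str]] = field(default_factory=dict)
    unmapped_pmids: set[str] = field(default_factory=set)
    keyword_support: dict[str, set[str]] = field(default_factory=dict)

    @property
    def context_verified(self) -> bool:
        """True if any consensus PMID hit an operon/gene-cluster query."""
        return any(self.keyword_support.values())


def _term(name: str) -> str:
    return f'"{name}"' if " " in name else name


def _or_clause(primary: str, synonyms) -> str:
    names = [primary] + sorted(set(synonyms) - {primary})
    if len(names) == 1:
        return _term(names[0])
    return "(" + " OR ".join(_term(n) for n in names) + ")"


def build_queries(
    reactant: str,
    product: str,
    reactant_synonyms: list[str] | None = None,
    product_synonyms: list[str] | None = None,
    module_id: str = "",
    consensus_k: int = 4,
) -> QuerySet:
    """Construct the six query strings for a reactant/product pair.

    Synonym lists OR-expand the compound names (multiword names quoted);
    the expansion sorts synonyms internally so the emitted strings do not
    depend on input order.
    """
    if not reactant or not product:
        raise ValueError("reactant and product must be non-empty")
    q1 = _or_clause(reactant, reactant_synonyms or [])
    q2 = _or_clause(product, product_synonyms or [])
    q3 = f"{q1} AND {q2}"
    return QuerySet(
        module_id=module_id,
        reactant_string=reactant,
        product_string=product,
        reactant_synonyms=tuple(sorted(reactant_synonyms or [])),
        product_synonyms=tuple(sorted(product_synonyms or [])),
        queries=(
            q1,
            q2,
            q3,
            f"{q3} AND bacteria",
            f"{q3} AND operon",
            f'{q3} AND "gene cluster"',
        ),
        consensus_k=consensus_k,
    )


def consensus_pmids(hit_lists: list[list[str]], k: int = 4) -> set[str]:
    """PMIDs appearing in at least ``k`` of the six hit lists.

    Duplicates within one list count once; ``k`` is inclusive ("at least
    4 of the 6": membership in exactly 4 lists qualifies, exactly 3 does
    not).
    """
    if len(hit_lists) != 6:
        raise ValueError(f"expected exactly 6 hit lists, got {len(hit_lists)}")
    if not 1 <= k <= 6:
        raise ValueError("k must be in 1..6")
    counts: dict[str, int] = {}
    for lst in hit_lists:
        for pmid in set(lst):
            counts[pmid] = counts.get(pmid, 0) + 1
    return {pmid for pmid, c in counts.items() if c >= k}


def attach_organisms(
    module_id: str,
    consensus: set[str],
    pmid_organism_table: dict[str, list[str]],
    hit_lists: list[list[str]] | None = None,
) -> EvidenceRecord:
    """Map consensus PMIDs to reference organisms from an offline table.

    PMIDs missing from the table land in ``unmapped_pmids`` (reported,
    never fatal).  When the six hit lists are provided, each consensus
    PMID records which of the context-keyword queries (``operon``,
    ``gene cluster``) it appeared in; an empty support set for all PMIDs
    marks the module as context-unverified in the literature.
    """
    organisms = {
        pmid: sorted(set(pmid_organism_table[pmid]))
        for pmid in sorted(consensus)
        if pmid in pmid_organism_table
    }
    support: dict[str, set[str]] = {pmid: set() for pmid in consensus}
    if hit_lists is not None:
        if len(hit_lists) != 6:
            raise ValueError("expected exactly 6 hit lists")
        for qnum, keyword in _KEYWORD_QUERIES.items():
            members = set(hit_lists[qnum - 1])
            for pmid in consensus:
                if pmid in members:
                    support[pmid].add(keyword)
    return EvidenceRecord(
        module_id=module_id,
        consensus_pmids=set(consensus),
        pmid_organisms=organisms,
        unmapped_pmids=set(consensus) - set(organisms),
        keyword_support=support,
    )


def read_hitlists(directory: str | Path, module_id: str) -> list[list[str]]:
    """Read ``<module_id>.q1.txt`` … ``.q6.txt`` (one PMID per line)."""
    directory = Path(directory)
    lists = []
    for i in range(1, 7):
        path = directory / f"{module_id}.q{i}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing hit-list file: {path}")
        lists.append([
            ln.strip() for ln in path.read_text().splitlines() if ln.strip()
        ])
    return lists


def read_pmid_organism_table(text: str) -> dict[str, list[str]]:
    """Parse a two-column PMID → organism TSV (one row per pair)."""
    table: dict[str, list[str]] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        pmid, organism = ln.split("\t", 1)
        table.setdefault(pmid.strip(), []).append(organism.strip())
    return table
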