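"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles — naive
enumeration, from-definition formulas — and shares no code path with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# modularity maximisation by exhaustive set-partition enumeration


def modularity_by_definition(edges: list[tuple[str, str]], blocks) -> float:
    """Q = sum over communities of [ L_c/m - (d_c / 2m)^2 ].

    ``edges`` is a simple undirected edge list (no weights); ``blocks``
    a partition of the node set.
    """
    m = len(edges)
    degree: dict[str, int] = {}
    for u, v in edges:
        degree[u] = degree.get(u, 0) + 1
        degree[v] = degree.get(v, 0) + 1
    q = 0.0
    for block in blocks:
        bset = set(block)
        l_c = sum(1 for u, v in edges if u in bset and v in bset)
        d_c = sum(degree.get(n, 0) for n in bset)
        q += l_c / m - (d_c / (2 * m)) ** 2
    return q


def all_partitions(items):
    """Every set partition of ``items`` (recursive first-element scheme)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def max_modularity(edges: list[tuple[str, str]], nodes) -> float:
    return max(
        modularity_by_definition(edges, p) for p in all_partitions(list(nodes))
    )


# ---------------------------------------------------------------------------
# single-linkage proximity clustering by pairwise union-find


def single_linkage_clusters(catalog, genes, threshold: int) -> set[frozenset]:
    """O(n^2) connected components under step distance <= threshold."""
    genes = sorted(genes)
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(genes, 2):
        ra, rb = catalog.gene(a), catalog.gene(b)
        if ra.replicon_id != rb.replicon_id:
            continue
        d = abs(ra.rank - rb.rank)
        if catalog.is_circular(ra.replicon_id):
            n = catalog.n_genes(ra.replicon_id)
            d = min(d, n - d)
        if d <= threshold:
            parent[find(a)] = find(b)

    clusters: dict[str, set[str]] = {}
    for g in genes:
        clusters.setdefault(find(g), set()).add(g)
    return {frozenset(c) for c in clusters.values()}


# ---------------------------------------------------------------------------
# exhaustive interval scan


def brute_force_scan(catalog, pfam_set, window_size: int, cutoff: float):
    """Score every contiguous interval of length <= 2w+1 on every replicon.

    Returns ``(best_coverage, qualifying)`` where ``qualifying`` maps
    replicon id to the list of rank-frozensets of maximal-length windows
    meeting the cutoff.
    """
    target = set(pfam_set)
    best = 0.0
    qualifying: dict[str, list[frozenset]] = {}
    for rep_id in sorted(catalog.replicons):
        records = catalog.replicons[rep_id]
        n = len(records)
        if n == 0:
            continue
        length = min(2 * window_size + 1, n)
        if catalog.is_circular(rep_id):
            if 2 * window_size + 1 >= n:
                starts = [0]
            else:
                starts = range(n)
        else:
            starts = range(n - length + 1)
        for s in starts:
            ranks = [(s + k) % n for k in range(length)]
            found = set()
            for r in ranks:
                found |= set(records[r].pfams) & target
            cov = 100.0 * len(found) / len(target)
            best = max(best, cov)
            if cov >= cutoff:
                qualifying.setdefault(rep_id, []).append(frozenset(ranks))
    return best, qualifying


def consensus_by_counting(hit_lists, k):
    """Membership-count consensus: a PMID counts once per list it is in."""
    universe = set().union(*[set(l) for l in hit_lists]) if hit_lists else set()
    return {
        p for p in universe
        if sum(1 for lst in hit_lists if p in set(lst)) >= k
    }


def assert_scan_matches_oracle(catalog, gcm, params, scan_genome):
    """Shared assertion: scan_genome agrees with the exhaustive oracle."""
    calls = scan_genome(catalog, gcm, params)
    best, qualifying = brute_force_scan(
        catalog, gcm.pfam_set, params.window_size, params.cutoff_percent
    )
    present_calls = [c for c in calls if c.present]
    assert bool(present_calls) == bool(qualifying)
    if present_calls:
        # best merged coverage equals the oracle's best window coverage
        assert math.isclose(max(c.coverage_percent for c in present_calls), best)
        # the union of called ranks equals the union of qualifying windows
        called: dict[str, set[int]] = {}
        for c in present_calls:
            n = catalog.n_genes(c.replicon_id)
            called.setdefault(c.replicon_id, set()).update(c._span_ranks(n))
        oracle_union = {
            rep: set().union(*windows) for rep, windows in qualifying.items()
        }
        assert called == oracle_union
    else:
        assert len(calls) == 1
        assert math.isclose(calls[0].coverage_percent, best)
    return calls
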