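"""Directional UMI clustering within genomic-boundary partitions.

Sequencing errors inside a UMI would otherwise split one molecule's reads
into several tag families. The directional network method merges a
low-count UMI ``b`` into a high-count UMI ``a`` when the two are within a
small edit distance and ``count(a) >= 2 * count(b) - 1``; the asymmetric
count rule keeps genuinely distinct molecules with similar UMIs apart.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

import edlib


@dataclass
class UmiCorrectionParams:
    max_edit_distance: int = 3
    metric: str = "levenshtein"  # or "hamming"

    def __post_init__(self):
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")
        if self.metric not in ("levenshtein", "hamming"):
            raise ValueError("metric must be 'levenshtein' or 'hamming'")


def edit_distance(a: str, b: str, metric: str = "levenshtein",
                  limit: int = -1) -> int:
    """Levenshtein (via edlib) or Hamming distance; N counts as a mismatch."""
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming distance requires equal lengths")
        return sum(x != y for x, y in zip(a, b))
    d = edlib.align(a, b, task="distance", k=limit)["editDistance"]
    return d if d >= 0 else limit + 1


@dataclass
class UmiClusterMap:
    """Per-partition mapping raw UMI -> canonical UMI."""

    mapping: Dict[str, str]
    cluster_sizes: Dict[str, int]  # canonical -> total read count absorbed

    def canonical(self, umi: str) -> str:
        return self.mapping.get(umi, umi)


def directional_cluster(umi_counts: Mapping[str, int],
                        params: UmiCorrectionParams | None = None) -> UmiClusterMap:
    """Greedy directional network clustering of UMIs.

    UMIs are visited in descending count order (ties broken lexicographically
    for determinism). From each unassigned UMI a breadth-first search follows
    directed edges a->b (distance <= max_edit_distance and
    count(a) >= 2*count(b) - 1); every node reached is assigned to the root.
    """
    params = params or UmiCorrectionParams()
    if not umi_counts:
        return UmiClusterMap({}, {})
    nodes = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    counts = dict(umi_counts)
    neg_counts = [-counts[u] for u in nodes]  # ascending, for bisect
    assigned: Dict[str, str] = {}
    sizes: Dict[str, int] = {}
    d = params.max_edit_distance
    from bisect import bisect_left
    for root in nodes:
        if root in assigned:
            continue
        assigned[root] = root
        total = counts[root]
        queue = [root]
        while queue:
            a = queue.pop()
            # the count rule prunes most distance computations: only nodes
            # with count <= (count(a) + 1) // 2 can be absorbed
            cap = (counts[a] + 1) // 2
            for b in nodes[bisect_left(neg_counts, -cap):]:
                if b in assigned:
                    continue
                if edit_distance(a, b, params.metric, limit=d) <= d:
                    assigned[b] = root
                    total += counts[b]
                    queue.append(b)
        sizes[root] = total
    return UmiClusterMap(assigned, sizes)


@dataclass
class CorrectionStats:
    n_records: int = 0
    n_corrected: int = 0
    n_missing: int = 0  # UMIs absent from the map, left unchanged


def apply_correction(records: Iterable, cluster_map: UmiClusterMap
                     ) -> CorrectionStats:
    """Replace each record's combined UMI by its canonical form in place."""
    stats = CorrectionStats()
    mapping = cluster_map.mapping
    for r in records:
        stats.n_records += 1
        canon = mapping.get(r.umi_combined)
        if canon is None:
            stats.n_missing += 1
            continue
        if canon != r.umi_combined:
            r.umi_combined = canon
            stats.n_corrected += 1
    return stats


def correct_umis(records: List, params: UmiCorrectionParams | None = None
                 ) -> CorrectionStats:
    """Cluster combined UMIs within each (chrom, fragment_start,
    fragment_end) partition and canonicalize records in place.

    Clustering happens per boundary because downstream grouping is
    boundary-first: two reads can only share a tag family if they already
    share a fragment boundary.
    """
    params = params or UmiCorrectionParams()
    partitions: Dict[Tuple[str, int, int], List] = defaultdict(list)
    for r in records:
        partitions[(r.chrom, r.fragment_start, r.fragment_end)].append(r)
    total = CorrectionStats()
    for recs in partitions.values():
        counts = Counter(r.umi_combined for r in recs)
        cmap = directional_cluster(counts, params)
        s = apply_correction(recs, cmap)
        total.n_records += s.n_records
        total.n_corrected += s.n_corrected
        total.n_missing += s.n_missing
    return total
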