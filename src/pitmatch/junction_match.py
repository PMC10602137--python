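"""Edit-distance matching of junctions between repertoires.

The Levenshtein index between two junctions is the minimum number of
single-residue substitutions, insertions and deletions transforming one
into the other.  A blood-query junction is called a tissue (PIT) match when
its minimum distance to the tissue repertoire is 0 or 1.

``match_junctions`` prunes candidate pairs by length difference and uses a
banded dynamic program with a distance cutoff; its results are identical to
an all-pairs full-matrix computation (property-tested).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from pitmatch.errors import ContractError
from pitmatch.repertoire_io import (
    Repertoire,
    TcrChainRecord,
    normalize_gene,
)

NO_MATCH = None  # sentinel min-distance for queries beyond the cutoff


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance by the full dynamic program.

    Case-insensitive (junctions are canonicalized to uppercase).
    """
    a, b = a.upper(), b.upper()
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1,          # deletion from a
                         cur[j - 1] + 1,       # insertion into a
                         prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def banded_levenshtein(a: str, b: str, k: int) -> int | None:
    """Edit distance if it is <= ``k``; None otherwise.

    Restricts the dynamic program to a diagonal band of half-width ``k``,
    so the cost is O(k * len(a)) instead of O(len(a) * len(b)).
    """
    a, b = a.upper(), b.upper()
    if abs(len(a) - len(b)) > k:
        return None
    if a == b:
        return 0
    if k == 0:
        return None
    big = k + 1
    prev = {j: j for j in range(0, min(len(b), k) + 1)}
    for i in range(1, len(a) + 1):
        cur: dict[int, int] = {}
        lo, hi = max(0, i - k), min(len(b), i + k)
        for j in range(lo, hi + 1):
            if j == 0:
                cur[j] = i
                continue
            best = prev.get(j - 1, big) + (a[i - 1] != b[j - 1])
            best = min(best, prev.get(j, big) + 1, cur.get(j - 1, big) + 1)
            cur[j] = best
        if min(cur.values()) > k:
            return None
        prev = cur
    d = prev.get(len(b), big)
    return d if d <= k else None


@dataclass(frozen=True)
class MatchResult:
    """A query junction paired with one subject hit."""

    query_junction: str
    subject_junction: str
    distance: int
    mismatch_positions: tuple[int, ...] = ()
    v_gene_identical: bool | None = None
    j_gene_identical: bool | None = None

    def __post_init__(self):
        same = self.query_junction == self.subject_junction
        if (self.distance == 0) != same:
            raise ContractError("distance 0 iff junctions identical")
        if len(self.mismatch_positions) > self.distance:
            raise ContractError("more mismatch positions than distance")


@dataclass
class MatchTable:
    """Per-query minimum distances and all hits within the cutoff.

    ``min_distance[q]`` is None (no-match sentinel) when the query's
    distance to every subject junction exceeds ``max_distance``.
    """

    max_distance: int
    min_distance: dict[str, int | None]
    hits: dict[str, list[MatchResult]]

    def matched_at(self, threshold: int) -> set[str]:
        """Unique query junctions with min distance <= threshold."""
        if threshold > self.max_distance:
            raise ContractError(
                f"threshold {threshold} exceeds table cutoff "
                f"{self.max_distance}")
        return {q for q, d in self.min_distance.items()
                if d is not None and d <= threshold}

    def counts_per_threshold(self) -> dict[int, int]:
        """Cumulative unique-query match counts at 0..max_distance."""
        return {t: len(self.matched_at(t))
                for t in range(self.max_distance + 1)}


def match_junctions(query: Repertoire, subject: Repertoire,
                    max_distance: int = 1) -> MatchTable:
    """Match every unique query junction against the subject repertoire.

    Candidate subject junctions are bucketed by length and only lengths
    within ``max_distance`` of the query length are examined; distance 0 is
    resolved by hashing.  A query matching several subjects still counts
    once in per-junction tallies.
    """
    if max_distance < 0:
        raise ContractError("max_distance must be >= 0")
    q_junctions = list(query.unique_junctions)
    s_junctions = list(subject.unique_junctions)
    s_set = set(s_junctions)
    by_len: dict[int, list[str]] = defaultdict(list)
    for s in s_junctions:
        by_len[len(s)].append(s)

    min_distance: dict[str, int | None] = {}
    hits: dict[str, list[MatchResult]] = {}
    for q in q_junctions:
        best: int | None = None
        found: list[MatchResult] = []
        if q in s_set:
            best = 0
            found.append(MatchResult(q, q, 0))
        if max_distance >= 1:
            for length in range(len(q) - max_distance,
                                len(q) + max_distance + 1):
                for s in by_len.get(length, ()):
                    if s == q:
                        continue
                    d = banded_levenshtein(q, s, max_distance)
                    if d is None:
                        continue
                    pos = (tuple(mismatch_position(q, s)[0]) if d == 1
                           else ())
                    found.append(MatchResult(q, s, d, pos))
                    if best is None or d < best:
                        best = d
        min_distance[q] = best
        hits[q] = sorted(found, key=lambda m: (m.distance, m.subject_junction))
    return MatchTable(max_distance=max_distance, min_distance=min_distance,
                      hits=hits)


def match_junctions_bruteforce(query: Repertoire, subject: Repertoire,
                               max_distance: int = 1) -> MatchTable:
    """All-pairs full-matrix reference for :func:`match_junctions`."""
    if max_distance < 0:
        raise ContractError("max_distance must be >= 0")
    min_distance: dict[str, int | None] = {}
    hits: dict[str, list[MatchResult]] = {}
    for q in query.unique_junctions:
        best: int | None = None
        found: list[MatchResult] = []
        for s in subject.unique_junctions:
            d = levenshtein(q, s)
            if d <= max_distance:
                pos = tuple(mismatch_position(q, s)[0]) if d == 1 else ()
                found.append(MatchResult(q, s, d, pos))
                if best is None or d < best:
                    best = d
        min_distance[q] = best
        hits[q] = sorted(found, key=lambda m: (m.distance, m.subject_junction))
    return MatchTable(max_distance=max_distance, min_distance=min_distance,
                      hits=hits)


def classify_pit_match(table: MatchTable) -> dict[str, bool]:
    """Tissue-match flag per query junction: min distance 0 or 1."""
    if table.max_distance < 1:
        raise ContractError(
            "classify_pit_match requires a table built with max_distance >= 1")
    return {q: (d is not None and d <= 1)
            for q, d in table.min_distance.items()}


def extend_match_genes(result: MatchResult, query_rec: TcrChainRecord,
                       subject_rec: TcrChainRecord) -> MatchResult:
    """Annotate a match with V/J gene name identity (allele-stripped)."""
    return replace(
        result,
        v_gene_identical=(normalize_gene(query_rec.v_gene)
                          == normalize_gene(subject_rec.v_gene)),
        j_gene_identical=(normalize_gene(query_rec.j_gene)
                          == normalize_gene(subject_rec.j_gene)),
    )


def mismatch_position(a: str, b: str) -> tuple[list[int], list[float]]:
    """Locate the single difference between two junctions at distance 1.

    Returns (positions, normalized positions): 1-based on ``a``, and the
    same divided by len(a).  For a substitution this is the differing
    index; for an indel it is the leftmost position at which optimal
    alignments disagree (an insertion at the very end of ``a`` is anchored
    at len(a), keeping the position on the query).
    """
    a, b = a.upper(), b.upper()
    if levenshtein(a, b) != 1:
        raise ContractError("mismatch_position requires distance exactly 1")
    if len(a) == len(b):
        pos = next(i + 1 for i in range(len(a)) if a[i] != b[i])
    else:
        i = 0
        while i < min(len(a), len(b)) and a[i] == b[i]:
            i += 1
        pos = min(i + 1, len(a))
    return [pos], [pos / len(a)]


_REGION_LABELS = ("v_region", "nj_recombination_region", "j_region")


def localize_mismatches(positions, features) -> list[str]:
    """Assign each 1-based junction position to a germline-derived region.

    Positions within the first ``v3_len_aa`` residues are germline V;
    positions within the last ``j5_len_aa`` residues are germline J;
    everything between is the (non-templated) recombination region.
    ``features`` must expose ``v3_len_aa``, ``j5_len_aa`` and ``length_aa``
    for the query junction.
    """
    v3 = features.v3_len_aa
    j5 = features.j5_len_aa
    n = features.length_aa
    out = []
    for p in positions:
        if not (1 <= p <= n):
            raise ContractError(f"position {p} outside junction of {n} AA")
        if p <= v3:
            out.append("v_region")
        elif p > n - j5:
            out.append("j_region")
        else:
            out.append("nj_recombination_region")
    return out
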