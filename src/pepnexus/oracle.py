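"""Exhaustive merge-order assembler used as an independent reference.

The greedy longest-overlap-first heuristic can be suboptimal: committing
to the longest overlap early may block a merge order that reconstructs
more of the source sequence. For small peptide sets (up to ~8 sequences)
this module enumerates *every* merge order and every admissible overlap
length, and reports the best source coverage any order achieves. It is
deliberately independent of the production assembler: it shares no merge
code, only the definition of a valid exact overlap.
"""

from __future__ import annotations

from functools import lru_cache


def coverage_of_source(contigs, source: str) -> float:
    """Fraction of source positions covered by exact substring occurrences
    of the given contig sequences (L/I-sensitive)."""
    if not source:
        raise ValueError("source must be non-empty")
    covered = [False] * len(source)
    for contig in contigs:
        seq = contig if isinstance(contig, str) else contig.sequence
        start = source.find(seq)
        while start != -1:
            for i in range(start, start + len(seq)):
                covered[i] = True
            start = source.find(seq, start + 1)
    return sum(covered) / len(source)


def _moves(state: frozenset[str], min_overlap: int):
    """All single-merge successors of a set of sequences."""
    seqs = sorted(state)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            # containment absorption
            if a in b:
                yield state - {a}
                continue
            if b in a:
                yield state - {b}
                continue
            limit = min(len(a), len(b)) - 1
            for t in range(min_overlap, limit + 1):
                if a[-t:] == b[:t]:
                    yield (state - {a, b}) | {a + b[t:]}
                if b[-t:] == a[:t]:
                    yield (state - {a, b}) | {b + a[t:]}


def best_coverage(
    peptides, source: str, min_overlap: int = 3, max_states: int = 200_000
) -> float:
    """Best source coverage over all merge orders and overlap choices.

    Explores the full state space of sequence sets reachable by merging,
    scoring every intermediate state (stopping early is always allowed).
    Intended for small inputs only; raises if the state space exceeds
    ``max_states``.
    """
    start = frozenset(p for p in peptides if p)
    if not start:
        return 0.0
    seen: set[frozenset[str]] = set()
    best = 0.0
    stack = [start]
    while stack:
        state = stack.pop()
        if state in seen:
            continue
        seen.add(state)
        if len(seen) > max_states:
            raise RuntimeError(f"state space exceeds {max_states} states")
        best = max(best, _cached_coverage(tuple(sorted(state)), source))
        for nxt in _moves(state, min_overlap):
            if nxt not in seen:
                stack.append(nxt)
    return best


@lru_cache(maxsize=200_000)
def _cached_coverage(seqs: tuple[str, ...], source: str) -> float:
    return coverage_of_source(seqs, source)
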