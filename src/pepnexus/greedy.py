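"""Greedy suffix-prefix overlap assembly of peptides into contigs.

The assembler repeatedly merges the pair of sequences with the longest
exact overlap (longest-overlap-first), where an overlap is either a
suffix-prefix match of at least ``min_overlap`` residues or full
containment of one sequence in another. Containments are absorbed with
priority, since a contained sequence contributes no new residues. After
contig formation an iterative scaffolding step re-runs assembly and
deduplication for up to ``max_scaffold_rounds`` rounds until the contig
set reaches a fixed point.

Overlaps are exact character matches: no mismatches are tolerated, and
leucine/isoleucine are distinct during assembly (their isobaric
equivalence applies only when mapping to a reference). All tie-breaks are
deterministic, so the output is independent of input order.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence


class OverlapKind(Enum):
    AB = "suffix_prefix_a_to_b"  # suffix of a == prefix of b
    BA = "suffix_prefix_b_to_a"
    A_IN_B = "a_contained_in_b"
    B_IN_A = "b_contained_in_a"


@dataclass(frozen=True)
class Overlap:
    kind: OverlapKind
    length: int

    @property
    def is_containment(self) -> bool:
        return self.kind in (OverlapKind.A_IN_B, OverlapKind.B_IN_A)


@dataclass
class Contig:
    """An assembled amino-acid sequence with its supporting evidence."""

    sequence: str
    support_ids: list[str] = field(default_factory=list)
    n_peptides: int = 1


@dataclass
class GreedyParams:
    """Knobs of the greedy assembler.

    ``min_overlap`` below 3 residues invites spurious joins between
    unrelated peptides (a 2-residue match occurs by chance every ~400
    positions), hence the warning.
    """

    min_overlap: int = 3
    max_scaffold_rounds: int = 10

    def __post_init__(self) -> None:
        if self.min_overlap < 3:
            warnings.warn(
                f"min_overlap={self.min_overlap} < 3 risks erroneous contigs",
                stacklevel=2,
            )


def find_overlap(a: str, b: str, min_overlap: int) -> Overlap | None:
    """Longest exact overlap between two sequences, or None.

    Containment is reported with length equal to the shorter sequence and
    takes precedence over suffix-prefix overlaps (it is always at least as
    long). For equal-length suffix-prefix overlaps in both orientations,
    a→b is preferred. Overlaps shorter than ``min_overlap`` are ignored.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(b) <= len(a) and b in a:
        if len(b) >= min_overlap:
            return Overlap(OverlapKind.B_IN_A, len(b))
        return None
    if len(a) < len(b) and a in b:
        if len(a) >= min_overlap:
            return Overlap(OverlapKind.A_IN_B, len(a))
        return None
    limit = min(len(a), len(b)) - 1
    for t in range(limit, min_overlap - 1, -1):
        if a[-t:] == b[:t]:
            return Overlap(OverlapKind.AB, t)
        if b[-t:] == a[:t]:
            return Overlap(OverlapKind.BA, t)
    return None


# ---------------------------------------------------------------------------
# generic longest-overlap-first merge engine
#
# Shared by peptide->contig assembly and by the higher-order OLC refinement
# of de Bruijn contigs; only the merge/absorb callbacks differ.


def _merge_contigs(left: Contig, right: Contig, overlap_len: int) -> Contig:
    seq = left.sequence + right.sequence[overlap_len:]
    return Contig(
        sequence=seq,
        support_ids=left.support_ids + right.support_ids,
        n_peptides=left.n_peptides + right.n_peptides,
    )


def _absorb_contig(container: Contig, contained: Contig) -> Contig:
    return Contig(
        sequence=container.sequence,
        support_ids=container.support_ids + contained.support_ids,
        n_peptides=container.n_peptides + contained.n_peptides,
    )


def greedy_merge_engine(
    items: Sequence,
    min_overlap: int,
    seq_of: Callable[[object], str],
    merge: Callable[[object, object, int], object],
    absorb: Callable[[object, object], object],
) -> list:
    """Run longest-overlap-first merging to a fixed point.

    Candidate moves are ordered by: containment before suffix-prefix, then
    longer overlap, then longer merged result, then lexicographic
    (left sequence, right sequence). A lazy heap with liveness checks keeps
    the loop at O(n^2) overlap computations.
    """
    alive: dict[int, object] = {}
    counter = itertools.count()

    def _new_id() -> int:
        return next(counter)

    for it in items:
        alive[_new_id()] = it

    heap: list[tuple] = []

    def _push_pair(ia: int, ib: int) -> None:
        a, b = alive[ia], alive[ib]
        ov = find_overlap(seq_of(a), seq_of(b), min_overlap)
        if ov is None:
            return
        if ov.kind is OverlapKind.B_IN_A:
            key = (0, -ov.length, -len(seq_of(a)), seq_of(a), seq_of(b))
            heapq.heappush(heap, (*key, ia, ib, "absorb"))
        elif ov.kind is OverlapKind.A_IN_B:
            key = (0, -ov.length, -len(seq_of(b)), seq_of(b), seq_of(a))
            heapq.heappush(heap, (*key, ib, ia, "absorb"))
        elif ov.kind is OverlapKind.AB:
            merged_len = len(seq_of(a)) + len(seq_of(b)) - ov.length
            key = (1, -ov.length, -merged_len, seq_of(a), seq_of(b))
            heapq.heappush(heap, (*key, ia, ib, ov.length))
        else:  # BA: b is the left partner
            merged_len = len(seq_of(a)) + len(seq_of(b)) - ov.length
            key = (1, -ov.length, -merged_len, seq_of(b), seq_of(a))
            heapq.heappush(heap, (*key, ib, ia, ov.length))

    ids = sorted(alive)
    for i, ia in enumerate(ids):
        for ib in ids[i + 1 :]:
            _push_pair(ia, ib)

    while heap:
        *_, i_left, i_right, action = heapq.heappop(heap)
        if i_left not in alive or i_right not in alive:
            continue
        left, right = alive.pop(i_left), alive.pop(i_right)
        if action == "absorb":
            new_item = absorb(left, right)
        else:
            new_item = merge(left, right, action)
        new_id = _new_id()
        alive[new_id] = new_item
        for other in sorted(alive):
            if other != new_id:
                _push_pair(new_id, other)

    return [alive[i] for i in sorted(alive)]


# ---------------------------------------------------------------------------
# public operations


def greedy_assemble(
    peptides: Sequence[str],
    params: GreedyParams | None = None,
    support_ids: Sequence[str] | None = None,
) -> list[Contig]:
    """Assemble peptides into contigs by longest-overlap-first merging.

    Exact duplicate peptides are collapsed first, with multiplicity
    recorded in ``n_peptides``. Every input peptide ends up as an exact
    substring of exactly one output contig.
    """
    params = params or GreedyParams()
    if not peptides:
        return []
    if support_ids is None:
        support_ids = [f"pep{i}" for i in range(len(peptides))]
    dedup: dict[str, Contig] = {}
    for pep, sid in zip(peptides, support_ids):
        if not pep:
            continue
        if pep in dedup:
            dedup[pep].support_ids.append(sid)
            dedup[pep].n_peptides += 1
        else:
            dedup[pep] = Contig(sequence=pep, support_ids=[sid], n_peptides=1)
    items = [dedup[s] for s in sorted(dedup)]
    merged = greedy_merge_engine(
        items,
        params.min_overlap,
        seq_of=lambda c: c.sequence,
        merge=_merge_contigs,
        absorb=_absorb_contig,
    )
    return sort_contigs(merged)


def sort_contigs(contigs: Sequence[Contig]) -> list[Contig]:
    """Descending length, ties broken lexicographically."""
    return sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence))


def deduplicate_contigs(contigs: Sequence[Contig]) -> list[Contig]:
    """Drop exact duplicates and contigs contained in a longer contig.

    Support evidence of an absorbed contig is folded into its container.
    Output is sorted by descending length, ties lexicographic.
    """
    kept: list[Contig] = []
    for c in sort_contigs(contigs):
        container = next((k for k in kept if c.sequence in k.sequence), None)
        if container is None:
            kept.append(
                Contig(
                    sequence=c.sequence,
                    support_ids=list(c.support_ids),
                    n_peptides=c.n_peptides,
                )
            )
        else:
            container.support_ids += c.support_ids
            container.n_peptides += c.n_peptides
    return kept


@dataclass
class ScaffoldingResult:
    contigs: list[Contig]
    rounds_used: int
    converged: bool


def iterative_scaffold(
    contigs: Sequence[Contig], params: GreedyParams | None = None
) -> ScaffoldingResult:
    """Re-assemble and deduplicate the contig set until it stops changing.

    Each round runs the greedy merger over the current contig sequences and
    deduplicates the result. The loop stops at a fixed point or after
    ``max_scaffold_rounds`` rounds; ``converged`` reports which.
    """
    params = params or GreedyParams()
    current = deduplicate_contigs(contigs)
    rounds = 0
    converged = False
    for _ in range(params.max_scaffold_rounds):
        rounds += 1
        merged = greedy_merge_engine(
            sort_contigs(current),
            params.min_overlap,
            seq_of=lambda c: c.sequence,
            merge=_merge_contigs,
            absorb=_absorb_contig,
        )
        nxt = deduplicate_contigs(merged)
        if [c.sequence for c in nxt] == [c.sequence for c in current]:
            current = nxt
            converged = True
            break
        current = nxt
    return ScaffoldingResult(contigs=current, rounds_used=rounds, converged=converged)


def assemble_and_scaffold(
    peptides: Sequence[str],
    params: GreedyParams | None = None,
    support_ids: Sequence[str] | None = None,
) -> ScaffoldingResult:
    """Full greedy route: peptides -> contigs -> scaffolds."""
    params = params or GreedyParams()
    contigs = greedy_assemble(peptides, params, support_ids)
    return iterative_scaffold(contigs, params)
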