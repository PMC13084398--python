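"""Weighted de Bruijn graph assembly of peptides into ranked scaffolds.

Every peptide of length >= k is decomposed into its k-mers; k-mers are
graph nodes and a directed edge joins two k-mers that overlap by k-1
residues inside some peptide. Edge weights count the occurrences of the
spanning (k+1)-mer over all peptides, so a peptide observed by several
spectra (or by several proteases) reinforces its path. Assembly proceeds
hierarchically:

1. unambiguous unitigs (maximal non-branching paths) become contigs;
2. contigs are merged by exact suffix-prefix overlaps in a higher-order
   overlap-layout-consensus (OLC) round, yielding scaffolds;
3. scaffolds are scored with ``S = alpha*ln(L) + beta*w_mean + 0.2*w_min``
   and returned as a ranked list.

The logarithmic length term damps the reward for sheer length (guarding
against chimeric giants), the mean path weight rewards abundant spectral
support, and the fixed 0.2 penalty coefficient on the minimum edge weight
demotes scaffolds that rely on a single tenuous junction.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .greedy import greedy_merge_engine

logger = logging.getLogger(__name__)

#: fixed coefficient of the minimum-edge-weight term in the scaffold score
W_MIN_COEFF = 0.2


@dataclass
class DbgParams:
    """Parameters of the de Bruijn graph route.

    k defaults to 7 (6 performs comparably; other sizes degrade sharply
    for peptide-length inputs). ``min_edge_weight`` prunes low-evidence
    junctions before unitig extraction, ``size_threshold`` drops short
    contigs, and ``olc_min_overlap`` governs the contig-merging round.
    alpha and beta are the length and mean-coverage coefficients of the
    scaffold score; only the 0.2 minimum-weight coefficient is fixed.
    """

    k: int = 7
    min_edge_weight: int = 1
    size_threshold: int = 15
    olc_min_overlap: int = 5
    olc_rounds: int = 10
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


@dataclass
class KmerGraph:
    """Directed weighted de Bruijn graph over peptide k-mers."""

    k: int
    graph: nx.DiGraph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_weight(self, u: str, v: str) -> int:
        return self.graph.edges[u, v]["weight"]

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges.data("weight"))


@dataclass
class PathContig:
    """A contig spelled from a graph path, carrying its edge weights."""

    sequence: str
    weights: list[int] = field(default_factory=list)


@dataclass
class Scaffold:
    """A refined assembly with its path-weight statistics and score."""

    sequence: str
    weights: list[int] = field(default_factory=list)
    score: float = float("nan")

    @property
    def L(self) -> int:
        return len(self.sequence)

    @property
    def w_mean(self) -> float:
        return sum(self.weights) / len(self.weights) if self.weights else 0.0

    @property
    def w_min(self) -> float:
        return float(min(self.weights)) if self.weights else 0.0


def build_graph(peptides, k: int) -> KmerGraph:
    """Build the weighted de Bruijn graph from peptide sequences.

    Peptides shorter than k cannot contribute a node and are skipped (a
    count is logged); padding them would fabricate sequence. The result is
    independent of peptide order.
    """
    g = nx.DiGraph()
    spanning: Counter[str] = Counter()
    skipped = 0
    for pep in peptides:
        if len(pep) < k:
            skipped += 1
            continue
        for i in range(len(pep) - k + 1):
            g.add_node(pep[i : i + k])
        for i in range(len(pep) - k):
            spanning[pep[i : i + k + 1]] += 1
    for span, count in spanning.items():
        g.add_edge(span[:-1], span[1:], weight=count)
    if skipped:
        logger.info("skipped %d peptides shorter than k=%d", skipped, k)
    return KmerGraph(k=k, graph=g)


def filter_edges(kg: KmerGraph, min_edge_weight: int) -> KmerGraph:
    """Remove edges with weight below the threshold (nodes are kept)."""
    g = kg.graph.copy()
    drop = [
        (u, v) for u, v, w in g.edges.data("weight") if w < min_edge_weight
    ]
    g.remove_edges_from(drop)
    return KmerGraph(k=kg.k, graph=g)


def extract_unitigs(kg: KmerGraph, size_threshold: int = 0) -> list[PathContig]:
    """Spell maximal non-branching paths into contigs.

    A unitig extends through nodes with in-degree 1 and out-degree 1;
    branch nodes terminate it (and may anchor several unitigs). Cycles of
    purely non-branching nodes are traversed once, terminating at the
    first revisited node. Contigs shorter than ``size_threshold`` are
    dropped. Output order is deterministic (sorted by sequence).
    """
    g = kg.graph
    k = kg.k

    def _simple(n: str) -> bool:
        return g.in_degree(n) == 1 and g.out_degree(n) == 1

    contigs: list[PathContig] = []
    used_edges: set[tuple[str, str]] = set()

    # paths anchored at non-simple nodes
    for u in sorted(g.nodes):
        if _simple(u):
            continue
        for v in sorted(g.successors(u)):
            if (u, v) in used_edges:
                continue
            nodes = [u, v]
            weights = [g.edges[u, v]["weight"]]
            used_edges.add((u, v))
            cur = v
            while _simple(cur):
                nxt = next(iter(g.successors(cur)))
                if (cur, nxt) in used_edges:
                    break
                used_edges.add((cur, nxt))
                weights.append(g.edges[cur, nxt]["weight"])
                nodes.append(nxt)
                cur = nxt
            contigs.append(_spell(nodes, weights))

    # cycles made only of simple nodes
    for u in sorted(g.nodes):
        if not _simple(u):
            continue
        v = next(iter(g.successors(u)))
        if (u, v) in used_edges:
            continue
        nodes = [u]
        weights = []
        cur = u
        seen = {u}
        while True:
            nxt = next(iter(g.successors(cur)))
            if (cur, nxt) in used_edges:
                break
            used_edges.add((cur, nxt))
            weights.append(g.edges[cur, nxt]["weight"])
            if nxt in seen:  # close the cycle at the first revisit
                break
            nodes.append(nxt)
            seen.add(nxt)
            cur = nxt
            if not _simple(cur):
                break
        contigs.append(_spell(nodes, weights[: max(len(nodes) - 1, 0)]))

    # isolated nodes
    for u in sorted(g.nodes):
        if g.in_degree(u) == 0 and g.out_degree(u) == 0:
            contigs.append(PathContig(sequence=u, weights=[]))

    contigs = [c for c in contigs if len(c.sequence) >= size_threshold]
    return sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence))


def _spell(nodes: list[str], weights: list[int]) -> PathContig:
    seq = nodes[0] + "".join(n[-1] for n in nodes[1:])
    return PathContig(sequence=seq, weights=list(weights))


def _merge_path(left: PathContig, right: PathContig, overlap_len: int) -> PathContig:
    return PathContig(
        sequence=left.sequence + right.sequence[overlap_len:],
        weights=left.weights + right.weights,
    )


def _absorb_path(container: PathContig, contained: PathContig) -> PathContig:
    # a contained contig adds no new path edges; its weights are redundant
    return PathContig(sequence=container.sequence, weights=list(container.weights))


def olc_refine(
    contigs, olc_min_overlap: int, max_rounds: int = 10
) -> list[Scaffold]:
    """Higher-order overlap-layout-consensus merge of contigs.

    Contigs are treated as nodes of an overlap stage with the same
    longest-overlap-first mechanics and tie-breaks as the greedy peptide
    assembler, iterated to a fixed point (or ``max_rounds``). Suffix-prefix
    merges concatenate the constituent weight lists; w_mean and w_min are
    recomputed over the combined list.
    """
    current = [PathContig(c.sequence, list(c.weights)) for c in contigs]
    for _ in range(max_rounds):
        before = sorted(c.sequence for c in current)
        current = greedy_merge_engine(
            sorted(current, key=lambda c: (-len(c.sequence), c.sequence)),
            olc_min_overlap,
            seq_of=lambda c: c.sequence,
            merge=_merge_path,
            absorb=_absorb_path,
        )
        if sorted(c.sequence for c in current) == before:
            break
    return [Scaffold(sequence=c.sequence, weights=list(c.weights)) for c in current]


def score_scaffold(
    L: int, w_mean: float, w_min: float, alpha: float = 1.0, beta: float = 1.0
) -> float:
    """Post-assembly scaffold score S = alpha*ln(L) + beta*w_mean + 0.2*w_min."""
    if L < 1:
        raise ValueError(f"scaffold length must be >= 1, got {L}")
    return alpha * math.log(L) + beta * w_mean + W_MIN_COEFF * w_min


def rank_scaffolds(scaffolds) -> list[Scaffold]:
    """Descending score; ties by descending length, then sequence."""
    return sorted(scaffolds, key=lambda s: (-s.score, -s.L, s.sequence))


def assemble_dbg(peptides, params: DbgParams | None = None) -> list[Scaffold]:
    """Full de Bruijn route: graph -> unitigs -> OLC -> scored ranked list."""
    params = params or DbgParams()
    kg = build_graph(peptides, params.k)
    kg = filter_edges(kg, params.min_edge_weight)
    contigs = extract_unitigs(kg, params.size_threshold)
    scaffolds = olc_refine(contigs, params.olc_min_overlap, params.olc_rounds)
    for s in scaffolds:
        s.score = score_scaffold(s.L, s.w_mean, s.w_min, params.alpha, params.beta)
    return rank_scaffolds(scaffolds)
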