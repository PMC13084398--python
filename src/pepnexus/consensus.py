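"""Clustering of near-identical scaffolds and consensus generation.

Assemblies from multiprotease data are redundant: the two assembly routes
and overlapping digests produce many near-identical scaffolds. This module
groups scaffolds sharing at least 85% identity over their aligned region
(greedy centroid clustering, longest scaffold first), aligns each cluster
against its representative (star progressive alignment), derives a
position-specific scoring matrix (PSSM) of per-column residue frequencies
with gaps excluded, and emits the argmax consensus sequence per cluster.

Clustering and alignment are deterministic internal implementations so the
whole pipeline is hermetic; external clusterers/aligners can be swapped in
through the ``align_fn`` hook of :func:`align_cluster`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class ClusterParams:
    """Identity threshold 0.85 merges near-identical sequences while
    preserving specificity; min_coverage is the fraction of the shorter
    sequence that must be inside the aligned region."""

    identity_threshold: float = 0.85
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError(f"identity_threshold must be in (0,1], got {self.identity_threshold}")


@dataclass
class Cluster:
    members: list = field(default_factory=list)

    @property
    def representative(self):
        return self.members[0]

    @property
    def member_sequences(self) -> list[str]:
        return [_seq(m) for m in self.members]


@dataclass
class Pssm:
    """Per-position residue frequencies over an alignment.

    ``frequencies`` has one row per alignment column and one column per
    canonical residue; gap characters are excluded from the denominator.
    Rows for all-gap columns are flagged in ``all_gap`` and hold zeros.
    """

    frequencies: pd.DataFrame
    all_gap: np.ndarray


def _seq(x) -> str:
    return x if isinstance(x, str) else x.sequence


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # free end gaps: semi-global behaviour for partially overlapping scaffolds
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_identity_and_coverage(query: str, target: str) -> tuple[float, float]:
    """Identity over the aligned region and coverage of the target.

    The two sequences are aligned globally with free end gaps. Identity is
    matches divided by aligned (non-gap-pair) columns; coverage is the
    number of aligned target residues divided by the target length.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    aln = _global_aligner().align(target, query)[0]
    matches = 0
    aligned_cols = 0
    aligned_target = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        aligned_target += t1 - t0
        aligned_cols += t1 - t0
        for ti, qi in zip(range(t0, t1), range(q0, q1)):
            if target[ti] == query[qi]:
                matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = aligned_target / len(target)
    return identity, coverage


def cluster_scaffolds(scaffolds: Sequence, params: ClusterParams | None = None) -> list[Cluster]:
    """Greedy centroid clustering, longest scaffold first.

    Scaffolds are processed in descending length (ties lexicographic);
    each joins the first cluster whose representative it matches at
    identity >= threshold with coverage >= min_coverage of the shorter of
    the two sequences, else founds a new cluster. Every scaffold lands in
    exactly one cluster.
    """
    params = params or ClusterParams()
    ordered = sorted(scaffolds, key=lambda s: (-len(_seq(s)), _seq(s)))
    clusters: list[Cluster] = []
    for s in ordered:
        seq = _seq(s)
        placed = False
        for cl in clusters:
            rep = _seq(cl.representative)
            shorter, longer = (seq, rep) if len(seq) <= len(rep) else (rep, seq)
            identity, coverage = pairwise_identity_and_coverage(longer, shorter)
            if identity >= params.identity_threshold and coverage >= params.min_coverage:
                cl.members.append(s)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(members=[s]))
    return clusters


def align_cluster(
    cluster: Cluster, align_fn: Callable[[list[str]], list[str]] | None = None
) -> list[str]:
    """Multiple sequence alignment of a cluster (representative first).

    The default is a star progressive alignment: each member is aligned
    pairwise (globally, free end gaps) to the representative, and the
    pairwise alignments are merged on representative coordinates, padding
    insertions to the maximum observed per slot. ``align_fn`` may replace
    this with an external aligner taking and returning sequence lists.
    """
    seqs = cluster.member_sequences
    if align_fn is not None:
        return align_fn(seqs)
    if len(seqs) == 1:
        return list(seqs)
    rep = seqs[0]
    aligner = _global_aligner()

    # for each member: per-rep-position residue (or gap) + insertions keyed
    # by the rep position they precede (len(rep) = trailing insertions)
    per_member: list[tuple[list[str], dict[int, str]]] = []
    for member in seqs[1:]:
        aln = aligner.align(rep, member)[0]
        cols = [GAP] * len(rep)
        inserts: dict[int, str] = {}
        t_prev, q_prev = 0, 0
        blocks = list(zip(*aln.aligned))
        for (t0, t1), (q0, q1) in blocks:
            if q0 > q_prev:  # member residues not aligned to rep: insertion
                inserts[t0] = inserts.get(t0, "") + member[q_prev:q0]
            for ti, qi in zip(range(t0, t1), range(q0, q1)):
                cols[ti] = member[qi]
            t_prev, q_prev = t1, q1
        if q_prev < len(member):
            inserts[len(rep)] = inserts.get(len(rep), "") + member[q_prev:]
        per_member.append((cols, inserts))

    slot_width = {
        j: max((len(ins.get(j, "")) for _, ins in per_member), default=0)
        for j in range(len(rep) + 1)
    }

    def _build_row(cols: list[str], inserts: dict[int, str]) -> str:
        out = []
        for j in range(len(rep)):
            ins = inserts.get(j, "")
            out.append(ins.ljust(slot_width[j], GAP))
            out.append(cols[j])
        out.append(inserts.get(len(rep), "").ljust(slot_width[len(rep)], GAP))
        return "".join(out)

    rows = [_build_row([c for c in rep], {})]
    rows += [_build_row(cols, ins) for cols, ins in per_member]
    return rows


def build_pssm(msa: Sequence[str]) -> Pssm:
    """Per-column relative residue frequencies, gaps excluded.

    All rows must have equal length. Columns containing only gaps are
    flagged rather than dropped, so positions stay addressable.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment rows")
    freq = np.zeros((width, len(RESIDUES)))
    res_index = {r: i for i, r in enumerate(RESIDUES)}
    for row in msa:
        for j, c in enumerate(row):
            if c != GAP:
                freq[j, res_index[c]] += 1
    totals = freq.sum(axis=1)
    all_gap = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(all_gap[:, None], 0.0, freq / np.where(totals == 0, 1, totals)[:, None])
    return Pssm(
        frequencies=pd.DataFrame(freq, columns=list(RESIDUES)),
        all_gap=all_gap,
    )


def consensus_from_pssm(pssm: Pssm) -> str:
    """Argmax residue per non-empty column; ties break alphabetically
    (first residue in A..Y order); all-gap columns are omitted."""
    out = []
    values = pssm.frequencies.to_numpy()
    for j in range(values.shape[0]):
        if pssm.all_gap[j]:
            continue
        out.append(RESIDUES[int(np.argmax(values[j]))])
    return "".join(out)


@dataclass
class ConsensusResult:
    cluster: Cluster
    msa: list[str]
    pssm: Pssm
    sequence: str
    support: int


def cluster_consensus(
    scaffolds: Sequence, params: ClusterParams | None = None
) -> list[ConsensusResult]:
    """Cluster scaffolds and emit one consensus per cluster.

    Results are ranked by member count (descending), then by summed
    scaffold score when available, then by consensus sequence.
    """
    results = []
    for cl in cluster_scaffolds(scaffolds, params):
        msa = align_cluster(cl)
        pssm = build_pssm(msa)
        results.append(
            ConsensusResult(
                cluster=cl,
                msa=msa,
                pssm=pssm,
                sequence=consensus_from_pssm(pssm),
                support=len(cl.members),
            )
        )

    def _score_sum(res: ConsensusResult) -> float:
        total = 0.0
        for m in res.cluster.members:
            s = getattr(m, "score", 0.0)
            if isinstance(s, (int, float)) and np.isfinite(s):
                total += float(s)
        return total

    return sorted(results, key=lambda r: (-r.support, -_score_sum(r), r.sequence))
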