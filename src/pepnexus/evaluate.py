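"""Assembly quality metrics against a reference protein.

Scaffolds are mapped to the reference by semi-global alignment — the whole
scaffold is aligned against the best-fitting reference window, with
reference overhangs free — under a fixed, documented scoring scheme
(match +2 including the isobaric L/I pair, mismatch -1, gap open -4, gap
extend -1). An assembled scaffold is a hypothesis about a stretch of the
protein, so it is scored end to end rather than trimmed to its best local
segment; a purely local alignment would discard mismatching flanks and
inflate identity. Leucine and isoleucine have
identical mass and are indistinguishable in standard fragmentation
spectra, so they count as matches at mapping time. Deamidation — the
chemical conversion N→D and Q→E that accumulates during sample handling —
is a systematic substitution in MS data: such columns count as mismatches
for identity but are reported in their own class so they can be annotated
separately.

Metric definitions:

* high-confidence coverage — fraction of reference residues covered by the
  union of spans of scaffolds mapping at >= 90% identity;
* N50 — the shortest scaffold length at which the cumulative (descending)
  length sum reaches half the total assembled length;
* precision — fraction of scaffolds mapping at >= 40% identity (excludes
  spurious alignments while keeping homologous segments);
* mean identity — average identity over scaffolds mapping at >= 70%
  identity (0 when none qualify);
* composite score — min-max-normalised weighted sum 0.35*coverage +
  0.25*N50 + 0.25*(1 - scaffold_count) + 0.15*mean_identity, the scaffold
  count entering inverted so fewer fragments score higher;
* AQS — 100 * (C * I * P) / log10(N + 9), rewarding accuracy and
  penalising fragmentation; the +9 makes a single-scaffold assembly incur
  a penalty divisor of exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

#: mapping alignment constants (config-overridable via ``make_local_aligner``)
MATCH_SCORE = 2.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

MATCH = "match"
MISMATCH = "mismatch"
DEAMIDATION_SUB = "deamidation_sub"

#: reference residue -> scaffold residue pairs explained by deamidation
DEAMIDATION_PAIRS = {("N", "D"), ("Q", "E")}


def _is_match(ref_char: str, scaffold_char: str) -> bool:
    return ref_char == scaffold_char or {ref_char, scaffold_char} == {"I", "L"}


def make_mapping_aligner(
    match: float = MATCH_SCORE,
    mismatch: float = MISMATCH_SCORE,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Align.PairwiseAligner:
    """Semi-global aligner with L/I treated as a match.

    Target (the reference) end gaps are free, so the scaffold slides to
    its best window; scaffold end gaps pay the normal gap penalties, so
    the scaffold always aligns in full.
    """
    mat = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            mat[a, b] = match if _is_match(a, b) else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # reference overhangs are free (gap columns in the query row)
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class MappingResult:
    """Local alignment of one scaffold onto the reference."""

    scaffold_id: str
    span: tuple[int, int]  # 0-based half-open interval on the reference
    identity: float
    column_classes: list[tuple[int, str, str]] = field(default_factory=list)
    #: each entry: (reference position, scaffold residue, class label)

    @property
    def n_deamidation(self) -> int:
        return sum(1 for _, _, c in self.column_classes if c == DEAMIDATION_SUB)


def map_to_reference(
    scaffold: str,
    reference: str,
    scaffold_id: str = "",
    aligner: Align.PairwiseAligner | None = None,
) -> MappingResult:
    """Best semi-global alignment of a scaffold onto the reference.

    Among co-optimal alignments the one with the most aligned columns is
    taken (leftmost on the reference as the final tie-break). Identity
    counts L/I pairs as matches; deamidation columns count as mismatches
    but are labelled ``deamidation_sub``.
    """
    if not scaffold or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = aligner or make_mapping_aligner()
    alignments = aligner.align(reference, scaffold)
    if len(alignments) == 0:
        return MappingResult(scaffold_id=scaffold_id, span=(0, 0), identity=0.0)

    def _cols(aln) -> int:
        return sum(t1 - t0 for (t0, t1), _ in zip(*aln.aligned))

    best = None
    for i, aln in enumerate(alignments):
        key = (_cols(aln), -aln.aligned[0][0][0])
        if best is None or key > best[0]:
            best = (key, aln)
        if i >= 31:  # cap enumeration of co-optimal alignments
            break
    aln = best[1]

    classes: list[tuple[int, str, str]] = []
    matches = 0
    aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for ti, qi in zip(range(t0, t1), range(q0, q1)):
            r, s = reference[ti], scaffold[qi]
            aligned_cols += 1
            if _is_match(r, s):
                matches += 1
                classes.append((ti, s, MATCH))
            elif (r, s) in DEAMIDATION_PAIRS:
                classes.append((ti, s, DEAMIDATION_SUB))
            else:
                classes.append((ti, s, MISMATCH))
    ref_blocks = aln.aligned[0]
    if len(ref_blocks) == 0:
        return MappingResult(scaffold_id=scaffold_id, span=(0, 0), identity=0.0)
    span = (int(ref_blocks[0][0]), int(ref_blocks[-1][1]))
    identity = matches / aligned_cols if aligned_cols else 0.0
    return MappingResult(
        scaffold_id=scaffold_id, span=span, identity=identity, column_classes=classes
    )


def reference_coverage(
    mappings: Iterable[MappingResult], reference_length: int, min_identity: float
) -> float:
    """Fraction of the reference covered by the union of qualifying spans."""
    if reference_length < 1:
        raise ValueError("reference_length must be >= 1")
    spans = sorted(
        m.span for m in mappings if m.identity >= min_identity and m.span[1] > m.span[0]
    )
    covered = 0
    cur_start, cur_end = None, None
    for start, end in spans:
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / reference_length


def n50(lengths: Sequence[int]) -> int:
    """Shortest length needed to cover 50% of the total assembled length."""
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]  # unreachable


def precision(
    mappings: Iterable[MappingResult], n_scaffolds: int, min_identity: float = 0.40
) -> float:
    """Fraction of all scaffolds mapping at >= min_identity."""
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    return sum(1 for m in mappings if m.identity >= min_identity) / n_scaffolds


def mean_identity(
    mappings: Iterable[MappingResult], min_identity: float = 0.70
) -> float:
    """Mean identity over mappings at >= min_identity; 0 when none qualify."""
    qualifying = [m.identity for m in mappings if m.identity >= min_identity]
    return float(np.mean(qualifying)) if qualifying else 0.0


def min_max_normalize(values: Sequence[float]) -> list[float]:
    """Linear rescale to [0, 1]; a constant set maps to all ones."""
    if len(values) == 0:
        raise ValueError("cannot normalize an empty set")
    lo, hi = min(values), max(values)
    if hi == lo:
        return [1.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


@dataclass
class CompositeWeights:
    coverage: float = 0.35
    n50: float = 0.25
    scaffold_count: float = 0.25
    mean_identity: float = 0.15

    def __post_init__(self) -> None:
        total = self.coverage + self.n50 + self.scaffold_count + self.mean_identity
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"composite weights must sum to 1, got {total}")


def composite_score(
    coverage: float,
    n50_norm: float,
    scaffold_count_norm: float,
    mean_identity_norm: float,
    weights: CompositeWeights | None = None,
) -> float:
    """Weighted sum of normalised metrics; scaffold count enters inverted."""
    weights = weights or CompositeWeights()
    vals = (coverage, n50_norm, scaffold_count_norm, mean_identity_norm)
    if any(not (0.0 <= v <= 1.0) for v in vals):
        raise ValueError(f"normalized inputs must be in [0,1], got {vals}")
    return (
        weights.coverage * coverage
        + weights.n50 * n50_norm
        + weights.scaffold_count * (1.0 - scaffold_count_norm)
        + weights.mean_identity * mean_identity_norm
    )


def aqs(c_norm: float, i_norm: float, p_norm: float, n_scaffolds: int) -> float:
    """Assembly quality score: 100 * (C*I*P) / log10(N + 9)."""
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    for v in (c_norm, i_norm, p_norm):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"normalized inputs must be in [0,1], got {v}")
    return 100.0 * (c_norm * i_norm * p_norm) / math.log10(n_scaffolds + 9)


@dataclass
class AssemblyMetrics:
    """All reference-based quality metrics for one assembly."""

    coverage: float
    high_conf_coverage: float
    n50: int
    n_scaffolds: int
    mean_identity: float
    precision: float
    aqs: float
    composite: float | None = None
    mappings: list[MappingResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "high_conf_coverage": self.high_conf_coverage,
            "n50": self.n50,
            "n_scaffolds": self.n_scaffolds,
            "mean_identity": self.mean_identity,
            "precision": self.precision,
            "aqs": self.aqs,
            "composite": self.composite,
        }


def evaluate_assembly(
    scaffold_sequences: Sequence[str],
    reference: str,
    high_conf_identity: float = 0.90,
    precision_identity: float = 0.40,
    mean_identity_threshold: float = 0.70,
) -> AssemblyMetrics:
    """Map every scaffold to the reference and compute the metric suite.

    ``coverage`` uses the precision threshold (any credible mapping);
    ``high_conf_coverage`` restricts to >= 90% identity mappings. AQS is
    computed from high-confidence coverage, mean identity and precision
    (all already on the 0-1 scale).
    """
    if not scaffold_sequences:
        raise ValueError("no scaffolds to evaluate")
    mappings = [
        map_to_reference(seq, reference, scaffold_id=f"s{i}")
        for i, seq in enumerate(scaffold_sequences)
    ]
    n = len(scaffold_sequences)
    cov = reference_coverage(mappings, len(reference), precision_identity)
    hc_cov = reference_coverage(mappings, len(reference), high_conf_identity)
    ident = mean_identity(mappings, mean_identity_threshold)
    prec = precision(mappings, n, precision_identity)
    return AssemblyMetrics(
        coverage=cov,
        high_conf_coverage=hc_cov,
        n50=n50([len(s) for s in scaffold_sequences]),
        n_scaffolds=n,
        mean_identity=ident,
        precision=prec,
        aqs=aqs(hc_cov, ident, prec, n),
        mappings=mappings,
    )


def compare_assemblies(
    metrics: Sequence[AssemblyMetrics], weights: CompositeWeights | None = None
) -> list[AssemblyMetrics]:
    """Fill composite scores across a set of assemblies compared jointly.

    Min-max normalisation of coverage, N50, scaffold count and mean
    identity is computed over the comparison set, then combined with the
    composite weights. Returns the same metric objects, mutated.
    """
    if not metrics:
        return []
    cov = min_max_normalize([m.coverage for m in metrics])
    n50s = min_max_normalize([float(m.n50) for m in metrics])
    counts = min_max_normalize([float(m.n_scaffolds) for m in metrics])
    idents = min_max_normalize([m.mean_identity for m in metrics])
    for m, c, n_, s, i in zip(metrics, cov, n50s, counts, idents):
        m.composite = composite_score(c, n_, s, i, weights)
    return list(metrics)
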