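# Methods

## Problem setting

Bottom-up direct protein sequencing digests a purified protein with several
proteases in parallel, acquires MS/MS spectra, and decodes each spectrum
into a candidate peptide with a de novo model. The decoding step is outside
this package: our input is the resulting PSM table — peptide string,
log-confidence, q-value, protease label, spectrum id. The task is to
reassemble the protein from these short (7–20 residue), overlapping, noisy
fragments and to quantify how good the reconstruction is.

## Preprocessing

Log confidences are exponentiated to probabilities (values marginally above
0 from upstream rounding are clamped to 1 with a warning, not rejected).
Modification tokens in both `(...)` and `[...]` dialects are stripped.
Records are kept when all mandatory fields are present, the stripped
peptide is 7–20 canonical residues, the q-value is at most the FDR
threshold (default 0.10 — permissive enough to retain coverage, tight
enough to bound the false-positive load on the assembler), an optional
confidence gate passes (disabled by default; FDR is the primary filter),
and the peptide is not an L/I-insensitive substring of any contaminant
sequence. A missing q-value column is a hard error unless explicitly waived
(`--no-fdr`), because silently skipping FDR control would change results.
The bundled contaminant FASTA contains short *synthetic* stand-ins for
albumin-, collagen- and keratin-like sequences; real analyses should
substitute a curated contaminant database.

## Greedy assembly

Overlaps are exact character matches only: either a suffix–prefix overlap
of at least `min_overlap` residues (default 3 — a 2-residue match arises by
chance every ~400 positions in a 20-letter alphabet) or containment of one
sequence in another (counted with the shorter sequence's full length).
Merging is longest-overlap-first with fully deterministic tie-breaks:
containments are absorbed before suffix–prefix merges; among equal overlap
lengths the merge producing the longer result wins; remaining ties break
lexicographically on (left sequence, right sequence). Consequently the
output is independent of input order. After contig formation, scaffolding
re-runs the merger plus deduplication until the set stops changing, capped
at 10 rounds, and reports whether it converged. L and I are distinct
characters *during assembly*; their isobaric equivalence applies only when
mapping to a reference.

The greedy heuristic can be suboptimal: committing to the longest overlap
may block a better merge order. `pepnexus.oracle` provides an exhaustive
assembler that enumerates every merge order and admissible overlap length
for small inputs (≤ ~8 peptides) and reports the best achievable source
coverage. It shares no code with the production merger and is used in tests
to bound the greedy result; over 200 random non-adversarial trials the two
agree on every trial.

## De Bruijn graph assembly

Nodes are the observed k-mers (default k = 7; 6 performs comparably and
both are exposed; other sizes degrade sharply at peptide-scale inputs).
Peptides shorter than k are excluded, with a logged count — padding would
fabricate sequence. An edge joins two k-mers overlapping by k−1 and its
weight is the **total number of occurrences of the spanning (k+1)-mer over
all peptides**. Counting occurrences (rather than distinct peptides) makes
the graph's total weight exactly the number of (k+1)-mer positions in the
input, a conserved quantity the tests verify, and gives path statistics a
direct spectral-abundance reading.

Edges below `min_edge_weight` are pruned first; this is the only error
correction performed (no tip clipping or bubble popping). Unitigs —
maximal paths whose interior nodes have in- and out-degree 1 — are spelled
into contigs carrying their edge-weight lists; cycles (from sequence
repeats) are traversed once and terminate at the first revisited node.
Contigs shorter than `size_threshold` (default 15) are dropped. The OLC
round then merges contigs with the same mechanics and tie-breaks as the
greedy module (default minimum overlap 5, up to 10 rounds). Suffix–prefix
merges concatenate the constituents' weight lists; a contained contig
contributes no new path edges, so its (redundant) weights are dropped on
absorption. Scaffolds are scored

    S = alpha * ln(L) + beta * w_mean + 0.2 * w_min

with alpha = beta = 1 by default (only the 0.2 coefficient of the minimum
edge weight is fixed; alpha and beta are exposed in the configuration).
The logarithm damps the reward for sheer length, guarding against chimeric
giants; w_mean rewards abundant support; the w_min term demotes scaffolds
that rely on a single tenuous junction. Note that with the default
coefficients the ranking is abundance-dominated on deeply sampled data: a
short, heavily covered scaffold can outrank a longer, thinner one. Ranking
ties break by descending length, then lexicographically. A contig that is a
single isolated k-mer has an empty weight list; its w_mean and w_min are
defined as 0.

## Clustering and consensus

Scaffolds are clustered greedily in descending length order: a scaffold
joins the first cluster whose representative (the founding, longest member)
it matches at ≥ 85% identity over the aligned region with ≥ 0.8 coverage of
the shorter of the two sequences, else it founds a new cluster. Identity
and coverage come from a global alignment with free end gaps (match +1,
mismatch −1, gap open −2, extend −0.5); identity is matches over non-gap
columns, coverage is aligned target residues over target length. The 0.85
identity threshold preserves specificity while merging near-identical
variants; the 0.8 coverage fraction is a configurable default. Clustering
and the per-cluster star alignment (members aligned pairwise to the
representative and merged on its coordinates, insertions padded per slot)
are deterministic internal implementations so the pipeline is hermetic; an
`align_fn` hook accepts an external aligner.

The PSSM records per-column relative residue frequencies among non-gap
characters; all-gap columns are flagged, not dropped. The consensus takes
the argmax residue per non-empty column, breaking ties alphabetically
(A before C before D …), and omits all-gap columns. Frequencies are plain
counts — scaffolds are not weighted by abundance or score. Consensus
sequences are ranked by cluster size, then by summed scaffold score.

## Reference mapping and metrics

Scaffolds are mapped by **semi-global** alignment: the whole scaffold
aligns against the best-fitting reference window, reference overhangs are
free, scaffold end gaps pay normal penalties (match +2, mismatch −1, gap
open −4, gap extend −1; all overridable). An assembled scaffold is a
hypothesis about a contiguous stretch of the protein, so it is scored end
to end; a purely local alignment would trim mismatching flanks — and with
these scoring constants can never extend through two adjacent mismatches at
all, since the local score path resets at zero — silently inflating
identity. Leucine and isoleucine are isobaric and indistinguishable in
standard fragmentation, so L/I pairs count as matches. Columns where the
reference has N against scaffold D, or Q against E, are the signature of
deamidation; they count as mismatches for identity but carry their own
class label so they can be annotated separately. Among co-optimal
alignments the one with the most aligned columns is chosen (leftmost start
as final tie-break). Coordinates are 0-based half-open.

Metric conventions: coverage metrics are unions of qualifying mapping
spans over the reference length, with "qualifying" at ≥ 40% identity for
plain coverage and ≥ 90% for high-confidence coverage; N50 is the shortest
length at which the descending cumulative length sum reaches half the total
assembled length; precision is the fraction of scaffolds mapping at ≥ 40%
identity; mean identity averages over ≥ 70% mappings and is defined as 0
when none qualify (keeping the composite total; flagged in output).
Min-max normalisation maps a constant set to all ones (degenerate rule).
The composite score uses weights 0.35 (coverage), 0.25 (N50), 0.25
(scaffold count, inverted so fewer fragments score higher), 0.15 (mean
identity), and is computed across the set of assemblies compared in one
invocation. AQS = 100·(C·I·P)/log10(N+9) takes C from high-confidence
coverage, I from mean identity, P from precision (all already 0–1) and the
total scaffold count N; the +9 regulariser makes the single-scaffold
divisor exactly 1.

## Grid search

The six tunable parameters (k, OLC minimum overlap, size threshold, minimum
edge weight, FDR, refinement rounds) are searched exhaustively over finite
user-provided lists (the shipped default grid is illustrative, not
canonical). Each configuration runs filter → de Bruijn assembly →
evaluation; composite normalisation spans the whole grid; ranking is by
composite descending, then fewer scaffolds, then higher coverage, then
enumeration order. The pipeline is deterministic, so the grid needs no
seed and results are identical at any worker count; a simulator seed is
recorded in each result for provenance. Failing configurations record
their traceback and rank last.

## Synthetic data generator

The simulator emulates what the upstream decoding step hands to this
pipeline. Cleavage rules are textbook specificities: trypsin after K/R
unless before P, LysC after K, GluC after E, chymotrypsin after F/W/Y
unless before P, elastase after A/V/S/G/L/I, thermolysin before
I/L/V/A/M/F, pepsin after F/L; the broad enzymes papain, proteinase K and
legumain are modelled through a per-site nonspecific cleavage probability
(0.20 / 0.25 / 0.05, legumain additionally after N). All rules are
overridable. Two missed cleavages are allowed by default. Because a digest
acts on a *population* of molecules, the fragment pool for a
nonspecific protease aggregates 20 independent cleavage realisations;
fully specific enzymes are deterministic and need one. Fragments are
restricted to 5–25 residues — deliberately wider than the 7–20 filter
window so length filtering is exercised — and sampled with replacement to
create the multiplicity that de Bruijn edge weights rely on
(`psms_per_protease=None` emits each pool fragment once, the exhaustive
digest).

Noise: each N/Q deamidates (N→D, Q→E) with probability 0.05, each residue
substitutes to a random different residue with probability 0.01, and 10% of
emitted PSMs are random sequences — illustrative desk-scale defaults, as no
quantitative error rates are available for real digests. True PSMs draw
confidence from Beta(8, 2), false from Beta(2, 6). q-values are *generated,
not rescored*: the posterior false-probability of each confidence under the
known mixture is averaged cumulatively in descending-confidence order
(with a running maximum enforcing monotonicity), which makes them
calibrated at bin level for large n. Ground truth (source protein, span,
false flag, every applied mutation) is recorded per PSM.

What the simulator does **not** capture: spectrum-level physics (m/z,
intensities, retention time), position-dependent decoding error profiles,
correlated errors between PSMs of the same precursor, ragged semi-tryptic
termini beyond the nonspecific model, and PTMs other than oxidation tokens
and deamidation. Passing tests on synthetic data therefore demonstrate the
correctness of the assembly and scoring machinery under the stated error
model, not performance on real instrument output.

## Problem sizes and default study conditions used in tests

Tests and the end-to-end guarantees run on 120–150-residue random
references that are repeat-free at k = 6, digested by a 4-protease panel
(trypsin, chymotrypsin, elastase, proteinase K — three specific cutters
plus one broad enzyme, which together tile random sequences densely), with
500 PSMs per protease in noisy runs and the exhaustive digest in noiseless
runs. For noisy data the recommended de Bruijn setting is
`min_edge_weight = 3`: with hundreds of PSMs per protease, true junctions
accumulate weights far above 3 while error k-mers rarely recur, so pruning
at 3 removes noise branches without fragmenting the backbone. The
noiseless reconstruction and greedy-versus-oracle checks complete in
seconds; the full suite runs in well under a minute on one CPU.

## Known limitations

* L/I ambiguity is intrinsic to the data; assembled candidates may differ
  from the truth at any L/I position, and only mapping-time equivalence
  hides this.
* Low-complexity and repetitive stretches (His-tags, short internal
  repeats) create cycles and branch collapses in the graph; unitig
  traversal stops there, so such regions assemble as fragments.
* The scaffold score with default alpha = beta = 1 is abundance-dominated
  on deeply sampled data; ranking by score is not ranking by length.
* Greedy assembly is order-optimal only heuristically; the exhaustive
  oracle bounds it in tests but is infeasible beyond ~8 sequences.
* The evaluator requires a reference; identity-bearing metrics are
  undefined without ground truth.
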