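"""Exhaustive grid search over assembly hyperparameters.

Every combination of k-mer size, OLC minimum overlap, contig size
threshold, minimum edge weight, FDR threshold and refinement rounds is run
through the full pipeline (filter -> de Bruijn assembly -> evaluation) and
ranked by composite score, with min-max normalisation computed across the
whole grid. The pipeline is deterministic, so results are identical
regardless of worker count; parallelism only changes wall time.
"""

from __future__ import annotations

import itertools
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

from .dbg import DbgParams, assemble_dbg
from .evaluate import AssemblyMetrics, CompositeWeights, compare_assemblies, evaluate_assembly
from .preprocess import FilterConfig, PsmRecord, filter_psms


@dataclass
class ParamGrid:
    """Finite value lists for the six tunable pipeline parameters.

    The shipped defaults are an illustrative small grid, not a canonical
    one; pass your own lists for a real search.
    """

    k_values: list[int] = field(default_factory=lambda: [6, 7])
    min_overlap_values: list[int] = field(default_factory=lambda: [4, 5])
    size_threshold_values: list[int] = field(default_factory=lambda: [10, 15])
    min_edge_weight_values: list[int] = field(default_factory=lambda: [1, 2])
    fdr_values: list[float] = field(default_factory=lambda: [0.05, 0.10])
    refinement_round_values: list[int] = field(default_factory=lambda: [10])

    def __post_init__(self) -> None:
        for name in (
            "k_values",
            "min_overlap_values",
            "size_threshold_values",
            "min_edge_weight_values",
            "fdr_values",
            "refinement_round_values",
        ):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @property
    def n_configs(self) -> int:
        return (
            len(self.k_values)
            * len(self.min_overlap_values)
            * len(self.size_threshold_values)
            * len(self.min_edge_weight_values)
            * len(self.fdr_values)
            * len(self.refinement_round_values)
        )


@dataclass(frozen=True)
class GridConfig:
    k: int
    min_overlap: int
    size_threshold: int
    min_edge_weight: int
    fdr: float
    refinement_rounds: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "min_overlap": self.min_overlap,
            "size_threshold": self.size_threshold,
            "min_edge_weight": self.min_edge_weight,
            "fdr": self.fdr,
            "refinement_rounds": self.refinement_rounds,
        }


@dataclass
class GridResult:
    config: GridConfig
    metrics: AssemblyMetrics | None
    composite: float | None
    rank: int | None = None
    error: str | None = None
    seed: int | None = None  # simulator seed, recorded for provenance


def enumerate_configs(grid: ParamGrid) -> list[GridConfig]:
    """Cartesian product in the declared field order (deterministic)."""
    return [
        GridConfig(*combo)
        for combo in itertools.product(
            grid.k_values,
            grid.min_overlap_values,
            grid.size_threshold_values,
            grid.min_edge_weight_values,
            grid.fdr_values,
            grid.refinement_round_values,
        )
    ]


def run_config(
    records: list[PsmRecord],
    reference: str,
    config: GridConfig,
    base_filter: FilterConfig | None = None,
) -> AssemblyMetrics:
    """Run filter -> de Bruijn assembly -> evaluation for one config."""
    base = base_filter or FilterConfig()
    cfg = FilterConfig(
        min_len=base.min_len,
        max_len=base.max_len,
        fdr_threshold=config.fdr,
        contaminant_sequences=base.contaminant_sequences,
        min_confidence=base.min_confidence,
    )
    peptides = [r.peptide for r in filter_psms(records, cfg)]
    params = DbgParams(
        k=config.k,
        min_edge_weight=config.min_edge_weight,
        size_threshold=config.size_threshold,
        olc_min_overlap=config.min_overlap,
        olc_rounds=config.refinement_rounds,
    )
    scaffolds = assemble_dbg(peptides, params)
    if not scaffolds:
        raise RuntimeError("configuration produced no scaffolds")
    return evaluate_assembly([s.sequence for s in scaffolds], reference)


def _run_one(args) -> tuple[int, AssemblyMetrics | None, str | None]:
    idx, records, reference, config, base_filter = args
    try:
        return idx, run_config(records, reference, config, base_filter), None
    except Exception:
        return idx, None, traceback.format_exc(limit=3)


def run_grid(
    records: list[PsmRecord],
    reference: str,
    grid: ParamGrid,
    parallel_workers: int = 1,
    base_filter: FilterConfig | None = None,
    weights: CompositeWeights | None = None,
    seed: int | None = None,
) -> list[GridResult]:
    """Run every grid configuration and rank by composite score.

    Normalisation for the composite is computed across all successful
    configs. Failing configs record their error and rank last. The output
    is byte-identical for any worker count.
    """
    configs = enumerate_configs(grid)
    jobs = [(i, records, reference, c, base_filter) for i, c in enumerate(configs)]
    outcomes: list[tuple[AssemblyMetrics | None, str | None]] = [None] * len(jobs)  # type: ignore[list-item]
    if parallel_workers <= 1:
        for job in jobs:
            idx, metrics, err = _run_one(job)
            outcomes[idx] = (metrics, err)
    else:
        with ProcessPoolExecutor(max_workers=parallel_workers) as pool:
            for idx, metrics, err in pool.map(_run_one, jobs):
                outcomes[idx] = (metrics, err)

    results = [
        GridResult(config=c, metrics=m, composite=None, error=e, seed=seed)
        for c, (m, e) in zip(configs, outcomes)
    ]
    ok = [r for r in results if r.metrics is not None]
    if ok:
        compare_assemblies([r.metrics for r in ok], weights)
        for r in ok:
            r.composite = r.metrics.composite

    def _key(r: GridResult):
        if r.metrics is None:
            return (1, 0.0, 0, 0.0, configs.index(r.config))
        return (
            0,
            -r.composite,
            r.metrics.n_scaffolds,
            -r.metrics.coverage,
            configs.index(r.config),
        )

    ranked = sorted(results, key=_key)
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


def mean_top_config(results: list[GridResult], top_n: int = 3) -> dict:
    """Per-field mean of the top-ranked configs (a transfer convenience)."""
    top = [r for r in results if r.metrics is not None][:top_n]
    if not top:
        raise ValueError("no successful configurations")
    fields = ["k", "min_overlap", "size_threshold", "min_edge_weight", "fdr", "refinement_rounds"]
    return {
        f: sum(getattr(r.config, f) for r in top) / len(top) for f in fields
    }
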