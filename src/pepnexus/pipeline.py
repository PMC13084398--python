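"""End-to-end orchestration: preprocess -> assemble -> consensus -> evaluate.

Every stage writes plain text artifacts (CSV / FASTA / JSON) into the run
directory, plus a manifest with a config hash and input checksums so reruns
are verifiable byte-wise. Both assembly routes can run in one invocation
("both"), in which case their metrics are evaluated jointly so composite
normalisation spans the pair.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consensus import ClusterParams, ConsensusResult, cluster_consensus
from .dbg import DbgParams, assemble_dbg
from .evaluate import AssemblyMetrics, compare_assemblies, evaluate_assembly
from .greedy import GreedyParams, assemble_and_scaffold
from .preprocess import (
    FilterConfig,
    filter_psms,
    load_contaminants,
    read_psm_table,
    records_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``method`` selects the assembler: "greedy", "dbg" or "both".
    ``seed`` is recorded for provenance only (it matters when the input
    table came from the simulator); the pipeline itself is deterministic.
    """

    psms: str
    reference: str | None = None
    contaminants: str | None = None
    method: str = "dbg"
    filter: FilterConfig = field(default_factory=FilterConfig)
    greedy: GreedyParams = field(default_factory=GreedyParams)
    dbg: DbgParams = field(default_factory=DbgParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    require_q_value: bool = True
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.method not in ("greedy", "dbg", "both"):
            raise ValueError(f"method must be greedy|dbg|both, got {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        for key, klass in (
            ("filter", FilterConfig),
            ("greedy", GreedyParams),
            ("dbg", DbgParams),
            ("cluster", ClusterParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def to_jsonable(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                v = {
                    k: (sorted(val) if isinstance(val, (set, frozenset)) else val)
                    for k, val in dataclasses.asdict(v).items()
                }
            out[f.name] = v
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fasta(path: Path, entries: list[tuple[str, str]]) -> None:
    with path.open("w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n{seq}\n")


def _read_reference(path: str) -> str:
    from Bio import SeqIO

    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no sequences in reference FASTA {path}")
    return str(records[0].seq)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline, writing artifacts into ``outdir``.

    Returns the manifest dict. Stage failures raise with the stage name;
    a partial manifest is written before the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pepnexus")
    root.addHandler(handler)
    root.setLevel(config.log_level)

    manifest: dict = {
        "tool": "pepnexus",
        "version": __version__,
        "config": config.to_jsonable(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_jsonable(), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": [],
    }
    stage = "setup"
    try:
        psm_path = Path(config.psms)
        manifest["inputs"]["psms"] = _sha256(psm_path)
        if config.reference:
            manifest["inputs"]["reference"] = _sha256(Path(config.reference))

        stage = "preprocess"
        records = read_psm_table(psm_path, require_q_value=config.require_q_value)
        cfg = config.filter
        if not cfg.contaminant_sequences:
            cfg = dataclasses.replace(
                cfg, contaminant_sequences=load_contaminants(config.contaminants)
            )
        kept = filter_psms(records, cfg)
        records_to_frame(kept).to_csv(outdir / "clean.csv", index=False)
        logger.info("preprocess: %d of %d PSMs retained", len(kept), len(records))
        manifest["stages"].append({"stage": stage, "n_in": len(records), "n_out": len(kept)})
        peptides = [r.peptide for r in kept]
        support = [r.spectrum_id for r in kept]

        assemblies: dict[str, list[str]] = {}
        if config.method in ("greedy", "both"):
            stage = "assemble_greedy"
            result = assemble_and_scaffold(peptides, config.greedy, support)
            seqs = [c.sequence for c in result.contigs]
            _write_fasta(
                outdir / "scaffolds_greedy.fasta",
                [
                    (f"greedy_{i} n_peptides={c.n_peptides}", c.sequence)
                    for i, c in enumerate(result.contigs)
                ],
            )
            (outdir / "greedy_support.json").write_text(
                json.dumps(
                    {f"greedy_{i}": c.support_ids for i, c in enumerate(result.contigs)},
                    indent=1,
                )
            )
            assemblies["greedy"] = seqs
            manifest["stages"].append(
                {
                    "stage": stage,
                    "n_scaffolds": len(seqs),
                    "rounds_used": result.rounds_used,
                    "converged": result.converged,
                }
            )
        if config.method in ("dbg", "both"):
            stage = "assemble_dbg"
            scaffolds = assemble_dbg(peptides, config.dbg)
            _write_fasta(
                outdir / "scaffolds_dbg.fasta",
                [
                    (
                        f"dbg_{i} score={s.score:.4f} w_mean={s.w_mean:.3f} w_min={s.w_min:g}",
                        s.sequence,
                    )
                    for i, s in enumerate(scaffolds)
                ],
            )
            assemblies["dbg"] = [s.sequence for s in scaffolds]
            manifest["stages"].append({"stage": stage, "n_scaffolds": len(scaffolds)})
            dbg_scaffold_objs = scaffolds

        stage = "consensus"
        consensus_by_method: dict[str, list[ConsensusResult]] = {}
        for method, seqs in assemblies.items():
            inputs = dbg_scaffold_objs if method == "dbg" else seqs
            results = cluster_consensus(inputs, config.cluster) if seqs else []
            consensus_by_method[method] = results
            _write_fasta(
                outdir / f"consensus_{method}.fasta",
                [
                    (f"{method}_consensus_{i} support={r.support}", r.sequence)
                    for i, r in enumerate(results)
                ],
            )
        manifest["stages"].append(
            {
                "stage": stage,
                "n_consensus": {m: len(r) for m, r in consensus_by_method.items()},
            }
        )

        if config.reference:
            stage = "evaluate"
            reference = _read_reference(config.reference)
            metric_objs: dict[str, AssemblyMetrics] = {}
            for method, seqs in assemblies.items():
                if seqs:
                    metric_objs[method] = evaluate_assembly(seqs, reference)
            compare_assemblies(list(metric_objs.values()))
            metrics_out = {m: obj.to_dict() for m, obj in metric_objs.items()}
            (outdir / "metrics.json").write_text(json.dumps(metrics_out, indent=1))
            manifest["stages"].append({"stage": stage, "metrics": metrics_out})

        manifest["status"] = "ok"
        return manifest
    except Exception:
        manifest["status"] = f"failed at stage {stage}"
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        root.removeHandler(handler)
        handler.close()
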