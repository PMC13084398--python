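"""Parsing, normalisation and filtering of de novo peptide-spectrum match tables.

De novo sequencing models emit one candidate peptide per MS/MS spectrum
together with a log-scale confidence and (after FDR calibration) a q-value.
Before assembly the table is cleaned: confidences are exponentiated to the
[0, 1] scale, modification tokens such as ``(ox)`` are stripped from the
peptide strings, rows with missing mandatory fields are dropped, peptides
outside the 7-20 residue window are removed, PSMs above the FDR threshold
are discarded, and peptides matching known contaminant proteins (albumin,
collagen, keratins from sample handling) are excluded.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: matches one parenthesised or bracketed modification token, e.g. ``(ox)``,
#: ``[+57.02]``, ``(+.98)``
_MOD_TOKEN = re.compile(r"\(([^()]*)\)|\[([^\[\]]*)\]")


class PsmParseError(ValueError):
    """Raised when a PSM table row or peptide string cannot be parsed."""


@dataclass
class PsmRecord:
    """A single de novo peptide prediction.

    ``confidence`` is ``exp(log_confidence)``; one may be derived from the
    other at construction time.
    """

    spectrum_id: str
    peptide: str
    log_confidence: float
    q_value: float
    confidence: float = None  # type: ignore[assignment]
    protease: str = ""
    source_file: str = ""

    def __post_init__(self) -> None:
        if self.confidence is None:
            self.confidence = exponentiate_confidence(self.log_confidence)


@dataclass
class FilterConfig:
    """Filtering thresholds applied to a PSM table.

    Parameters
    ----------
    min_len, max_len : int
        Inclusive bounds on stripped peptide length. Peptides shorter than
        7 residues carry too little overlap information; longer than 20 are
        rarely confidently predicted de novo.
    fdr_threshold : float
        Maximum accepted q-value. A permissive 10% keeps coverage high
        while bounding the false-positive load on the assembler.
    contaminant_sequences : dict[str, str]
        Named reference sequences; a peptide matching any of them as an
        L/I-insensitive substring is excluded.
    min_confidence : float or None
        Optional extra gate on the exponentiated confidence; disabled by
        default (FDR filtering is the primary gate).
    """

    min_len: int = 7
    max_len: int = 20
    fdr_threshold: float = 0.10
    contaminant_sequences: dict[str, str] = field(default_factory=dict)
    min_confidence: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(
                f"require 1 <= min_len <= max_len, got [{self.min_len}, {self.max_len}]"
            )
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError(f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}")


def exponentiate_confidence(log_confidence: float) -> float:
    """Convert a natural-log confidence to a probability in [0, 1].

    Small positive inputs (floating-point round-off from an upstream tool)
    trigger a warning and are clamped to 1.0 rather than rejected.
    """
    try:
        x = float(log_confidence)
    except (TypeError, ValueError) as exc:
        raise PsmParseError(f"non-numeric log confidence: {log_confidence!r}") from exc
    if math.isnan(x):
        raise PsmParseError("log confidence is NaN")
    if x > 0:
        warnings.warn(
            f"log confidence {x} > 0; clamping probability to 1.0", stacklevel=2
        )
    try:
        p = math.exp(x)
    except OverflowError:
        p = math.inf
    return min(max(p, 0.0), 1.0)


def strip_modifications(peptide: str) -> str:
    """Remove parenthesised/bracketed modification tokens from a peptide.

    Both ``(...)`` and ``[...]`` dialects are stripped, so ``SEQM(ox)K``
    and ``SEQM[+15.99]K`` both become ``SEQMK``. Residue order is
    unchanged. Unbalanced delimiters raise :class:`PsmParseError`.
    """
    stripped = _MOD_TOKEN.sub("", peptide)
    if any(c in "()[]" for c in stripped):
        raise PsmParseError(f"unbalanced modification delimiters in peptide {peptide!r}")
    return stripped


def _li_collapse(seq: str) -> str:
    """Collapse isobaric leucine/isoleucine to a single letter."""
    return seq.replace("I", "L")


def is_contaminant(peptide: str, contaminants: dict[str, str]) -> bool:
    """True if the stripped peptide is an L/I-insensitive substring of any
    contaminant sequence."""
    probe = _li_collapse(peptide)
    return any(probe in _li_collapse(seq) for seq in contaminants.values())


def filter_psms(records: Sequence[PsmRecord], cfg: FilterConfig) -> list[PsmRecord]:
    """Apply the standard post-inference filters, preserving input order.

    A record survives when all of its mandatory fields are present, its
    stripped peptide length lies in ``[min_len, max_len]`` and contains only
    canonical residues, its q-value is at most ``fdr_threshold``, it passes
    the optional confidence gate, and it matches no contaminant. An empty
    result is legitimate; downstream stages handle zero peptides.
    """
    kept: list[PsmRecord] = []
    for rec in records:
        if rec.peptide is None or rec.q_value is None or rec.confidence is None:
            continue
        pep = rec.peptide
        if (
            not pep
            or pd.isna(rec.q_value)
            or pd.isna(rec.confidence)
            or not CANONICAL_RESIDUES.issuperset(pep)
        ):
            continue
        if not (cfg.min_len <= len(pep) <= cfg.max_len):
            continue
        if rec.q_value > cfg.fdr_threshold:
            continue
        if cfg.min_confidence is not None and rec.confidence < cfg.min_confidence:
            continue
        if is_contaminant(pep, cfg.contaminant_sequences):
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# table I/O


def read_psm_table(path: str | Path, require_q_value: bool = True) -> list[PsmRecord]:
    """Read a PSM table (CSV or TSV by extension) into records.

    The table needs columns ``peptide`` and either ``log_confidence`` or
    ``confidence``; ``q_value`` is mandatory unless *require_q_value* is
    False (then missing q-values are set to 0 so the FDR gate passes
    everything). Peptides are modification-stripped on load.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    return records_from_frame(df, require_q_value=require_q_value, source=path.name)


def records_from_frame(
    df: pd.DataFrame, require_q_value: bool = True, source: str = ""
) -> list[PsmRecord]:
    """Convert a dataframe with PSM columns to :class:`PsmRecord` objects."""
    cols = set(df.columns)
    if "peptide" not in cols:
        raise PsmParseError("PSM table lacks a 'peptide' column")
    if "log_confidence" not in cols and "confidence" not in cols:
        raise PsmParseError("PSM table lacks 'log_confidence' or 'confidence'")
    if "q_value" not in cols:
        if require_q_value:
            raise PsmParseError(
                "PSM table lacks a 'q_value' column; pass require_q_value=False "
                "(CLI: --no-fdr) to proceed without FDR filtering"
            )
        df = df.assign(q_value=0.0)

    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw_pep = getattr(row, "peptide")
        if pd.isna(raw_pep):
            pep = ""
        else:
            pep = strip_modifications(str(raw_pep))
        if "log_confidence" in cols and not pd.isna(getattr(row, "log_confidence")):
            try:
                logc = float(getattr(row, "log_confidence"))
            except (TypeError, ValueError) as exc:
                raise PsmParseError(f"row {i}: non-numeric log_confidence") from exc
            conf = exponentiate_confidence(logc)
        elif "confidence" in cols and not pd.isna(getattr(row, "confidence")):
            conf = float(getattr(row, "confidence"))
            logc = math.log(conf) if conf > 0 else -math.inf
        else:
            conf = float("nan")
            logc = float("nan")
        records.append(
            PsmRecord(
                spectrum_id=str(getattr(row, "spectrum_id", i)),
                peptide=pep,
                log_confidence=logc,
                confidence=conf,
                q_value=float(getattr(row, "q_value")),
                protease=str(getattr(row, "protease", "")),
                source_file=source,
            )
        )
    return records


def records_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    """Serialise records back to a dataframe (the CSV output schema)."""
    return pd.DataFrame(
        [
            {
                "spectrum_id": r.spectrum_id,
                "peptide": r.peptide,
                "log_confidence": r.log_confidence,
                "confidence": r.confidence,
                "q_value": r.q_value,
                "protease": r.protease,
                "source_file": r.source_file,
            }
            for r in records
        ],
        columns=[
            "spectrum_id",
            "peptide",
            "log_confidence",
            "confidence",
            "q_value",
            "protease",
            "source_file",
        ],
    )


def load_contaminants(path: str | Path | None = None) -> dict[str, str]:
    """Load contaminant sequences from a FASTA file.

    With no path, the bundled default is used: short synthetic stand-ins
    for the ubiquitous sample-handling contaminants (serum albumin,
    collagen, keratin). Users with a real contaminant database should point
    this at their own FASTA.
    """
    if path is None:
        ref = resources.files("pepnexus.data") / "contaminants_synthetic.fasta"
        with resources.as_file(ref) as p:
            return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
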