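"""In-silico multiprotease digestion with a noise model.

Emulates the input that a de novo sequencing model would produce from a
multiprotease digest: overlapping peptides from enzymes with complementary
cleavage specificities, missed cleavages, amino-acid substitution errors,
deamidation artefacts (N→D, Q→E), spurious (false-positive) peptide calls,
and per-PSM confidences with calibrated q-values. Ground truth is recorded
per PSM so downstream filters and assemblers can be validated exactly.

The shipped cleavage table uses textbook specificities (trypsin after K/R
except before P, GluC after E, chymotrypsin after F/W/Y, ...); the broad
proteases papain, proteinase K and legumain are modelled as low-specificity
cutters through a per-site nonspecific cleavage probability. All rules are
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: peptide length window sampled by the simulator, deliberately wider than
#: the 7-20 filter window so length filtering is exercised downstream
MIN_PEPTIDE_LEN = 5
MAX_PEPTIDE_LEN = 25


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity of one protease.

    ``cleave_after`` cuts C-terminally of the listed residues unless the
    next residue is in ``blocked_next``; ``cleave_before`` cuts
    N-terminally of the listed residues. ``nonspecific_rate`` adds random
    cleavage sites with the given per-position probability, modelling
    broad-specificity enzymes.
    """

    name: str
    cleave_after: frozenset = frozenset()
    cleave_before: frozenset = frozenset()
    blocked_next: frozenset = frozenset()
    nonspecific_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.cleave_after and not self.cleave_before and self.nonspecific_rate <= 0:
            raise ValueError(f"protease {self.name!r} has no cleavage specificity")


def _rule(name, after="", before="", blocked="", nonspecific=0.0) -> ProteaseRule:
    return ProteaseRule(
        name=name,
        cleave_after=frozenset(after),
        cleave_before=frozenset(before),
        blocked_next=frozenset(blocked),
        nonspecific_rate=nonspecific,
    )


#: the 10-enzyme panel; keys usable in configs and the CLI
PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": _rule("trypsin", after="KR", blocked="P"),
    "lysc": _rule("lysc", after="K"),
    "gluc": _rule("gluc", after="E"),
    "chymotrypsin": _rule("chymotrypsin", after="FWY", blocked="P"),
    "elastase": _rule("elastase", after="AVSGLI"),
    "thermolysin": _rule("thermolysin", before="ILVAMF"),
    "pepsin": _rule("pepsin", after="FL"),
    "papain": _rule("papain", nonspecific=0.20),
    "proteinase_k": _rule("proteinase_k", nonspecific=0.25),
    "legumain": _rule("legumain", after="N", nonspecific=0.05),
}


@dataclass
class NoiseModel:
    """Error structure of simulated PSM tables.

    Defaults are illustrative desk-scale rates: 1% random residue
    substitutions, 5% deamidation per N/Q, 10% spurious PSMs. True PSMs
    draw confidence from a high Beta distribution and false ones from a
    low Beta; q-values are the running mean of the posterior
    false-probability in descending-confidence order, which makes them
    monotone and calibrated at bin level for large n.
    """

    substitution_rate: float = 0.01
    deamidation_rate: float = 0.05
    false_psm_rate: float = 0.10
    true_conf_beta: tuple[float, float] = (8.0, 2.0)
    false_conf_beta: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.deamidation_rate, self.false_psm_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rates must be in [0,1], got {r}")

    def noiseless(self) -> "NoiseModel":
        return replace(
            self, substitution_rate=0.0, deamidation_rate=0.0, false_psm_rate=0.0
        )


@dataclass
class PsmOrigin:
    """Ground truth for one simulated PSM."""

    spectrum_id: str
    protein: str | None
    span: tuple[int, int] | None  # 0-based half-open on the source protein
    is_false: bool
    mutations: list[tuple[int, str, str, str]] = field(default_factory=list)
    #: (position in peptide, original residue, emitted residue, kind)


@dataclass
class SyntheticTruth:
    references: dict[str, str]
    psms: list[PsmOrigin] = field(default_factory=list)

    def by_id(self) -> dict[str, PsmOrigin]:
        return {p.spectrum_id: p for p in self.psms}


def digest(
    protein: str,
    rule: ProteaseRule,
    missed_cleavages: int = 2,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Enzymatic fragments of a protein allowing up to ``missed_cleavages``.

    Deterministic when ``nonspecific_rate`` is 0; otherwise ``rng`` drives
    the extra random sites (a fixed default generator is used if omitted).
    Fragments are returned in positional order, one entry per
    (start, missed-count) combination.
    """
    return [
        protein[a:b] for a, b in digest_spans(protein, rule, missed_cleavages, rng)
    ]


def digest_spans(
    protein: str,
    rule: ProteaseRule,
    missed_cleavages: int = 2,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """(start, end) spans of the fragments :func:`digest` would return."""
    if not protein:
        raise ValueError("protein must be non-empty")
    sites = set()
    for i in range(1, len(protein)):
        prev_res, res = protein[i - 1], protein[i]
        if prev_res in rule.cleave_after and res not in rule.blocked_next:
            sites.add(i)
        if res in rule.cleave_before:
            sites.add(i)
    if rule.nonspecific_rate > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        draws = rng.random(len(protein) - 1)
        sites |= {i for i in range(1, len(protein)) if draws[i - 1] < rule.nonspecific_rate}
    bounds = [0] + sorted(sites) + [len(protein)]
    spans = []
    for a in range(len(bounds) - 1):
        for miss in range(missed_cleavages + 1):
            b = a + miss + 1
            if b >= len(bounds):
                break
            spans.append((bounds[a], bounds[b]))
    return spans


def digest_pool(
    references: dict[str, str],
    rule: ProteaseRule,
    missed_cleavages: int = 2,
    rng: np.random.Generator | None = None,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[tuple[str, int, str]]:
    """(protein name, start, peptide) fragments inside the length window."""
    pool = []
    for name in sorted(references):
        protein = references[name]
        for start, end in digest_spans(protein, rule, missed_cleavages, rng):
            if min_len <= end - start <= max_len:
                pool.append((name, start, protein[start:end]))
    return pool


def random_protein(
    length: int,
    rng: np.random.Generator | int | None = None,
    unique_kmer: int | None = None,
    max_tries: int = 1000,
) -> str:
    """Random canonical-residue protein; optionally repeat-free at k.

    ``unique_kmer=k`` resamples until no k-mer occurs twice, giving a
    reference whose de Bruijn graph at that k is branch-free.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    letters = np.array(list(CANONICAL))
    for _ in range(max_tries):
        seq = "".join(rng.choice(letters, size=length))
        if unique_kmer is None:
            return seq
        kmers = [seq[i : i + unique_kmer] for i in range(length - unique_kmer + 1)]
        if len(set(kmers)) == len(kmers):
            return seq
    raise RuntimeError(f"no repeat-free sequence of length {length} found")


def _apply_noise(
    peptide: str, noise: NoiseModel, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str, str]]]:
    out = list(peptide)
    mutations = []
    for i, res in enumerate(out):
        if res in "NQ" and rng.random() < noise.deamidation_rate:
            new = "D" if res == "N" else "E"
            mutations.append((i, res, new, "deamidation"))
            out[i] = new
    for i, res in enumerate(out):
        if rng.random() < noise.substitution_rate:
            choices = [c for c in CANONICAL if c != res]
            new = choices[rng.integers(len(choices))]
            mutations.append((i, peptide[i], new, "substitution"))
            out[i] = new
    return "".join(out), mutations


def simulate_psm_table(
    references: dict[str, str],
    proteases: list[ProteaseRule] | None = None,
    noise: NoiseModel | None = None,
    psms_per_protease: int | None = 500,
    missed_cleavages: int = 2,
    digest_replicates: int = 20,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a PSM table across a protease panel, with ground truth.

    Peptides are sampled with replacement from each protease's in-window
    digest pool (replacement creates realistic multiplicity for de Bruijn
    edge weights); ``psms_per_protease=None`` emits every pool fragment
    exactly once instead (the exhaustive digest). A digest acts on a
    population of protein molecules, so for broad-specificity proteases
    (``nonspecific_rate > 0``) the pool aggregates ``digest_replicates``
    independent cleavage realisations; fully specific enzymes are
    deterministic and use a single realisation. Noise is applied per the
    model; q-values are calibrated against the generative confidence
    mixture. The output columns match the preprocessing input schema, and
    everything is reproducible from ``noise.seed``.
    """
    proteases = proteases or list(PROTEASES.values())
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    truth = SyntheticTruth(references=dict(references))
    rows = []

    for rule in proteases:
        reps = digest_replicates if rule.nonspecific_rate > 0 else 1
        pool = []
        for _ in range(reps):
            pool.extend(digest_pool(references, rule, missed_cleavages, rng))
        if not pool:
            continue
        if psms_per_protease is None:
            picks = list(range(len(pool)))
            false_flags = [False] * len(pool)
        else:
            picks = rng.integers(len(pool), size=psms_per_protease).tolist()
            false_flags = (rng.random(psms_per_protease) < noise.false_psm_rate).tolist()
        for j, (pick, is_false) in enumerate(zip(picks, false_flags)):
            sid = f"{rule.name}_{j:06d}"
            if is_false:
                length = int(rng.integers(MIN_PEPTIDE_LEN, MAX_PEPTIDE_LEN + 1))
                pep = "".join(rng.choice(list(CANONICAL), size=length))
                conf = float(stats.beta.rvs(*noise.false_conf_beta, random_state=rng))
                truth.psms.append(
                    PsmOrigin(spectrum_id=sid, protein=None, span=None, is_false=True)
                )
            else:
                name, start, frag = pool[pick]
                pep, mutations = _apply_noise(frag, noise, rng)
                conf = float(stats.beta.rvs(*noise.true_conf_beta, random_state=rng))
                truth.psms.append(
                    PsmOrigin(
                        spectrum_id=sid,
                        protein=name,
                        span=(start, start + len(frag)),
                        is_false=False,
                        mutations=mutations,
                    )
                )
            conf = min(max(conf, 1e-12), 1.0)
            rows.append(
                {
                    "spectrum_id": sid,
                    "peptide": pep,
                    "log_confidence": float(np.log(conf)),
                    "q_value": np.nan,  # filled below
                    "protease": rule.name,
                    "source_file": "synthetic",
                }
            )

    df = pd.DataFrame(
        rows,
        columns=[
            "spectrum_id",
            "peptide",
            "log_confidence",
            "q_value",
            "protease",
            "source_file",
        ],
    )
    if len(df):
        df["q_value"] = _calibrated_q_values(
            np.exp(df["log_confidence"].to_numpy()), noise
        )
    return df, truth


def _calibrated_q_values(conf: np.ndarray, noise: NoiseModel) -> np.ndarray:
    """q-values from the generative mixture.

    The posterior probability that a PSM with confidence c is false is
    computed from the two Beta densities and the false-PSM prior; sorting
    by confidence (descending) and taking the running mean of that
    posterior gives the expected false fraction among everything at least
    as confident — an oracle q-value. A running maximum enforces
    monotonicity in rank.
    """
    fp = noise.false_psm_rate
    if fp <= 0.0:
        return np.zeros_like(conf)
    if fp >= 1.0:
        return np.ones_like(conf)
    f_true = stats.beta.pdf(conf, *noise.true_conf_beta)
    f_false = stats.beta.pdf(conf, *noise.false_conf_beta)
    post = fp * f_false / (fp * f_false + (1 - fp) * f_true)
    order = np.argsort(-conf, kind="stable")
    running = np.cumsum(post[order]) / np.arange(1, len(conf) + 1)
    running = np.maximum.accumulate(running)
    q = np.empty_like(conf)
    q[order] = running
    return np.clip(q, 0.0, 1.0)
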