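import numpy as np
import pytest

from pepnexus.preprocess import FilterConfig, filter_psms, records_from_frame
from pepnexus.simulate import PROTEASES, NoiseModel, random_protein, simulate_psm_table

#: a panel mixing specific cutters with one broad protease, giving dense
#: overlapping fragments on random sequences
FOUR_PROTEASES = ["trypsin", "chymotrypsin", "elastase", "proteinase_k"]


@pytest.fixture(scope="session")
def reference_150():
    """Random 150-residue protein, repeat-free at k=6 (hence also k=7)."""
    return random_protein(150, rng=11, unique_kmer=6)


@pytest.fixture(scope="session")
def noiseless_digest(reference_150):
    """Exhaustive noiseless 4-protease digest of the session reference."""
    rules = [PROTEASES[n] for n in FOUR_PROTEASES]
    table, truth = simulate_psm_table(
        {"ref": reference_150}, rules, NoiseModel(seed=11).noiseless(), psms_per_protease=None
    )
    return table, truth


@pytest.fixture(scope="session")
def noiseless_peptides(noiseless_digest):
    table, _ = noiseless_digest
    records = filter_psms(records_from_frame(table), FilterConfig())
    return [r.peptide for r in records]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
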