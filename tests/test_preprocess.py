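import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepnexus.preprocess import (
    CANONICAL_RESIDUES,
    FilterConfig,
    PsmParseError,
    PsmRecord,
    exponentiate_confidence,
    filter_psms,
    is_contaminant,
    load_contaminants,
    records_from_frame,
    strip_modifications,
)


def make_record(peptide="PEPTIDEK", q=0.01, logc=-0.1, **kw):
    return PsmRecord(
        spectrum_id=kw.get("spectrum_id", "s1"),
        peptide=peptide,
        log_confidence=logc,
        q_value=q,
        protease=kw.get("protease", "trypsin"),
    )


class TestExponentiateConfidence:
    @pytest.mark.parametrize(
        "logc,expected",
        [(0.0, 1.0), (-0.2231435513, 0.8), (-709.0, 0.0)],
    )
    def test_values(self, logc, expected):
        assert exponentiate_confidence(logc) == pytest.approx(expected, abs=1e-9)

    def test_result_clamped_to_unit_interval(self):
        with pytest.warns(UserWarning):
            assert exponentiate_confidence(1e-12) <= 1.0
        assert exponentiate_confidence(-1e6) >= 0.0

    def test_non_numeric_raises(self):
        with pytest.raises(PsmParseError):
            exponentiate_confidence("high")


class TestStripModifications:
    @pytest.mark.parametrize(
        "raw,clean",
        [
            ("SEQM(ox)K", "SEQMK"),
            ("PEPTIDE", "PEPTIDE"),
            ("M(ox)N(+.98)K", "MNK"),
            ("M[+15.99]NK", "MNK"),
        ],
    )
    def test_tokens_removed(self, raw, clean):
        assert strip_modifications(raw) == clean

    def test_unbalanced_delimiters_raise(self):
        with pytest.raises(PsmParseError):
            strip_modifications("PEP(oxTIDE")


class TestFilterPsms:
    def test_length_window_bounds_are_inclusive(self):
        recs = [make_record("A" * n) for n in (6, 7, 20, 21)]
        kept = filter_psms(recs, FilterConfig())
        assert [len(r.peptide) for r in kept] == [7, 20]

    def test_fdr_threshold(self):
        recs = [make_record(q=q) for q in (0.005, 0.09, 0.2)]
        kept = filter_psms(recs, FilterConfig(fdr_threshold=0.10))
        assert [r.q_value for r in kept] == [0.005, 0.09]

    def test_empty_input_gives_empty_output(self):
        assert filter_psms([], FilterConfig()) == []

    def test_contaminant_matching_is_li_insensitive(self):
        contaminants = {"c1": "GGGPEPTIDEKGGG"}
        cfg = FilterConfig(contaminant_sequences=contaminants)
        # L in the peptide matches I in the contaminant
        assert filter_psms([make_record("PEPTLDEK")], cfg) == []
        assert is_contaminant("PEPTLDEK", contaminants)
        kept = filter_psms([make_record("WWWWYYYY")], cfg)
        assert len(kept) == 1

    def test_noncanonical_and_missing_fields_dropped(self):
        recs = [make_record("PEPTIXEK"), make_record("PEPTIDEK", q=float("nan"))]
        assert filter_psms(recs, FilterConfig()) == []

    def test_optional_confidence_gate(self):
        recs = [make_record(logc=-0.01), make_record(logc=-3.0)]
        kept = filter_psms(recs, FilterConfig(min_confidence=0.5))
        assert len(kept) == 1

    def test_idempotent(self):
        recs = [make_record("A" * n, q=q) for n, q in [(7, 0.01), (9, 0.5), (25, 0.01)]]
        cfg = FilterConfig()
        once = filter_psms(recs, cfg)
        assert filter_psms(once, cfg) == once

    @given(
        fdr=st.floats(0.01, 1.0),
        tighter=st.floats(0.0, 1.0),
        qs=st.lists(st.floats(0, 1), min_size=1, max_size=30),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_retained_set_monotone_in_fdr(self, fdr, tighter, qs):
        recs = [make_record(q=q) for q in qs]
        loose = filter_psms(recs, FilterConfig(fdr_threshold=fdr))
        tight_thr = max(fdr * tighter, 1e-9)
        tight = filter_psms(recs, FilterConfig(fdr_threshold=tight_thr))
        assert len(tight) <= len(loose)
        assert all(r in loose for r in tight)

    def test_retained_peptides_canonical(self, noiseless_digest):
        table, _ = noiseless_digest
        kept = filter_psms(records_from_frame(table), FilterConfig())
        assert kept and all(CANONICAL_RESIDUES.issuperset(r.peptide) for r in kept)


class TestTableParsing:
    def test_missing_q_value_fails_loudly(self):
        df = pd.DataFrame({"peptide": ["PEPTIDEK"], "log_confidence": [-0.1]})
        with pytest.raises(PsmParseError, match="q_value"):
            records_from_frame(df)
        recs = records_from_frame(df, require_q_value=False)
        assert recs[0].q_value == 0.0

    def test_confidence_column_accepted_instead_of_log(self):
        df = pd.DataFrame({"peptide": ["PEPTIDEK"], "confidence": [0.8], "q_value": [0.01]})
        rec = records_from_frame(df)[0]
        assert rec.confidence == pytest.approx(0.8)
        assert rec.log_confidence == pytest.approx(math.log(0.8))

    def test_confidence_consistent_with_log(self):
        rec = make_record(logc=-1.5)
        assert rec.confidence == pytest.approx(math.exp(-1.5), abs=1e-9)

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(min_len=10, max_len=7)
        with pytest.raises(ValueError):
            FilterConfig(fdr_threshold=0.0)


def test_default_contaminants_load():
    contams = load_contaminants()
    assert contams and all(CANONICAL_RESIDUES.issuperset(s) for s in contams.values())
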