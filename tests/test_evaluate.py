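import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepnexus.evaluate import (
    DEAMIDATION_SUB,
    MATCH,
    AssemblyMetrics,
    CompositeWeights,
    MappingResult,
    aqs,
    compare_assemblies,
    composite_score,
    evaluate_assembly,
    map_to_reference,
    mean_identity,
    min_max_normalize,
    n50,
    precision,
    reference_coverage,
)
from pepnexus.simulate import random_protein


def mapping(identity, span=(0, 10)):
    return MappingResult(scaffold_id="s", span=span, identity=identity)


class TestMapToReference:
    def test_leucine_isoleucine_equivalence(self):
        m = map_to_reference("PEPTLDE", "PEPTIDE")
        assert m.identity == pytest.approx(1.0)
        assert all(cls == MATCH for _, _, cls in m.column_classes)

    def test_exact_match(self):
        m = map_to_reference("PEPTIDE", "PEPTIDE")
        assert m.identity == 1.0 and m.span == (0, 7)

    def test_deamidation_columns(self):
        m = map_to_reference("ADEA", "ANQA")
        assert m.identity == pytest.approx(0.5)
        assert m.n_deamidation == 2
        classes = {pos: cls for pos, _, cls in m.column_classes}
        assert classes[1] == DEAMIDATION_SUB and classes[2] == DEAMIDATION_SUB

    def test_span_reported_on_reference(self):
        ref = random_protein(100, 2)
        m = map_to_reference(ref[30:60], ref)
        assert m.span == (30, 60) and m.identity == 1.0


class TestReferenceCoverage:
    def test_full_perfect_mapping(self):
        assert reference_coverage([mapping(1.0, (0, 100))], 100, 0.9) == 1.0

    def test_overlapping_spans_union(self):
        maps = [mapping(0.95, (0, 50)), mapping(0.95, (25, 75))]
        assert reference_coverage(maps, 100, 0.9) == pytest.approx(0.75)

    def test_nothing_qualifies(self):
        assert reference_coverage([mapping(0.5, (0, 50))], 100, 0.9) == 0.0

    def test_monotone_in_identity_threshold(self):
        maps = [mapping(0.95, (0, 40)), mapping(0.7, (50, 90)), mapping(0.3, (90, 100))]
        covs = [reference_coverage(maps, 100, thr) for thr in (0.9, 0.6, 0.2)]
        assert covs == sorted(covs)
        assert all(c <= 1.0 for c in covs)


class TestN50:
    @pytest.mark.parametrize(
        "lengths,expected", [([5, 4, 3, 2, 1], 4), ([10], 10), ([2, 2, 2, 2], 2)]
    )
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            n50([])


class TestPrecisionAndMeanIdentity:
    def test_precision_counts_forty_percent_mappers(self):
        maps = [mapping(i) for i in (0.9, 0.5, 0.41, 0.1)]
        assert precision(maps, 4) == pytest.approx(0.75)
        assert precision([mapping(0.9)], 1) == 1.0
        assert precision([mapping(0.1)], 1) == 0.0

    def test_mean_identity_filters_at_seventy(self):
        assert mean_identity([mapping(i) for i in (0.95, 0.75, 0.30)]) == pytest.approx(0.85)
        assert mean_identity([mapping(1.0)]) == 1.0
        assert mean_identity([mapping(i) for i in (0.5, 0.6)]) == 0.0


class TestNormalizeAndComposite:
    def test_min_max_examples(self):
        assert min_max_normalize([1, 3, 5]) == [0, 0.5, 1]
        assert min_max_normalize([4, 4]) == [1.0, 1.0]
        assert min_max_normalize([0, 1]) == [0, 1]

    def test_composite_extremes(self):
        assert composite_score(1, 1, 0, 1) == pytest.approx(1.0)
        assert composite_score(0, 0, 1, 0) == pytest.approx(0.0)

    def test_coverage_weight_is_035(self):
        hi = composite_score(1, 0.4, 0.6, 0.2)
        lo = composite_score(0, 0.4, 0.6, 0.2)
        assert hi - lo == pytest.approx(0.35)

    def test_inputs_validated(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0, 0, 0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CompositeWeights(coverage=0.5, n50=0.5, scaffold_count=0.5, mean_identity=0.5)
        w = CompositeWeights()
        assert w.coverage + w.n50 + w.scaffold_count + w.mean_identity == pytest.approx(1.0)

    @given(
        c=st.floats(0, 1), n=st.floats(0, 1), s=st.floats(0, 1), i=st.floats(0, 1)
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_composite_bounded(self, c, n, s, i):
        assert 0.0 <= composite_score(c, n, s, i) <= 1.0


class TestAqs:
    def test_ideal_single_scaffold(self):
        assert aqs(1, 1, 1, 1) == pytest.approx(100.0)

    def test_ninety_one_scaffolds_halve_the_score(self):
        assert aqs(1, 1, 1, 91) == pytest.approx(50.0)

    def test_zero_factor_zeroes_score(self):
        assert aqs(0, 1, 1, 5) == 0.0

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            aqs(1, 1, 1, 0)

    @given(st.integers(1, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_strictly_decreasing_in_scaffold_count(self, n):
        assert aqs(0.9, 0.9, 0.9, n + 1) < aqs(0.9, 0.9, 0.9, n)


class TestEvaluateAssembly:
    def test_perfect_single_scaffold(self):
        ref = random_protein(120, 5)
        metrics = evaluate_assembly([ref], ref)
        assert metrics.high_conf_coverage == 1.0
        assert metrics.precision == 1.0
        assert metrics.mean_identity == 1.0
        assert metrics.aqs == pytest.approx(100.0)
        assert metrics.n50 == 120

    def test_compare_assemblies_fills_composites(self):
        ref = random_protein(120, 5)
        good = evaluate_assembly([ref], ref)
        frag = evaluate_assembly([ref[:40], ref[50:90], random_protein(30, 6)], ref)
        compare_assemblies([good, frag])
        assert good.composite == pytest.approx(1.0)
        assert 0.0 <= frag.composite < good.composite

    def test_n50_never_exceeds_longest_scaffold(self):
        ref = random_protein(100, 7)
        m = evaluate_assembly([ref[:60], ref[40:80]], ref)
        assert m.n50 <= 60
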