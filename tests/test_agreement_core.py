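"""Union-reference construction, agreement taxonomy and coverage."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from annoconcord.agreement_core import (
    COMBINED,
    GENE_MODELS,
    MODEL_CATEGORY_LABELS,
    TOOL_CATEGORY_LABELS,
    TOOLS,
    ScopeMismatchError,
    Strategy,
    classify_model_pattern,
    classify_tool_pattern,
    classify_variant,
    coverage,
    integrate,
    reference_set,
    source_status,
    strategy_grid,
)

ABC = frozenset("ABC")
WORKED = {  # the three-tool worked example
    "ANNOVAR": frozenset("AB"),
    "SnpEff": frozenset("AC"),
    "VEP": frozenset("ABC"),
}


class TestWorkedExample:
    def test_reference_is_union(self):
        assert reference_set(WORKED, "v1").accessions == ABC

    def test_statuses(self):
        ref = reference_set(WORKED)
        assert source_status(WORKED["ANNOVAR"], ref) == "partial"
        assert source_status(WORKED["SnpEff"], ref) == "partial"
        assert source_status(WORKED["VEP"], ref) == "full"

    def test_snpeff_coverage_pair(self):
        assert coverage(WORKED["SnpEff"], ABC) == (2, 3)

    def test_category_label(self):
        res = classify_variant(WORKED, "v1")
        assert res.category_label == "VEP; ANNOVAR subset; SnpEff subset"
        assert res.coverage["VEP"] == (3, 3)


@pytest.mark.parametrize(
    "sets, expected",
    [
        (({"A"}, set(), set()), "ANNOVAR"),  # lone nonempty source is full
        ((set(), {"A", "B"}, {"A", "B"}), "SnpEff and VEP"),
        (({"A", "B", "C"},) * 3, "Exact Match"),
        # two tools full, third a nested subset
        (({"A", "B", "C"}, {"A", "B", "C"}, {"A", "B"}),
         "ANNOVAR and SnpEff; VEP subset"),
        (({"A", "B"}, {"A", "B"}, set()), "ANNOVAR and SnpEff"),
        (({"A"}, {"B"}, set()), "No full match; ANNOVAR subset; SnpEff subset"),
    ],
)
def test_label_grammar(sets, expected):
    per_source = dict(zip(TOOLS, map(frozenset, sets)))
    assert classify_variant(per_source).category_label == expected


def brute_force_tool_labels():
    """Oracle: classify every triple of subsets of a 3-element universe."""
    subsets = [frozenset(s) for r in range(4)
               for s in itertools.combinations("abc", r)]
    labels = set()
    for triple in itertools.product(subsets, repeat=3):
        if not any(triple):
            continue
        labels.add(
            classify_variant(dict(zip(TOOLS, triple))).category_label
        )
    return labels


def test_tool_taxonomy_exactly_23_labels():
    labels = brute_force_tool_labels()
    assert len(labels) == 23
    assert labels == set(TOOL_CATEGORY_LABELS)


def test_single_nonempty_source_is_never_partial():
    # a lone nonempty source equals the union, so "lone partial" patterns
    # are unrealizable and excluded from the taxonomy
    for label in TOOL_CATEGORY_LABELS:
        assert not (label.startswith("No full match")
                    and label.count("subset") == 1)


def test_model_taxonomy_exactly_7_labels():
    subsets = [frozenset(s) for r in range(4)
               for s in itertools.combinations("abc", r)]
    labels = set()
    for ens, ref in itertools.product(subsets, repeat=2):
        if not ens and not ref:
            continue
        labels.add(classify_model_pattern(ens, ref))
    assert labels == set(MODEL_CATEGORY_LABELS)
    assert len(labels) == 7


@pytest.mark.parametrize(
    "ens, refseq, expected",
    [
        ({"P1", "P2"}, {"P1", "P2"}, "Exact Match"),
        ({"P1"}, {"P1", "P2"}, "RefSeq with Ensembl Subset"),
        ({"P1", "P2"}, {"P1"}, "Ensembl with RefSeq Subset"),
        (set(), {"P1"}, "RefSeq only"),
        ({"P1"}, set(), "Ensembl only"),
        ({"P1", "P2"}, {"P2", "P3"}, "Partial Overlap"),
        ({"P1"}, {"P2"}, "Fully Disjoint"),
    ],
)
def test_model_pattern_cases(ens, refseq, expected):
    assert classify_model_pattern(ens, refseq) == expected


def test_model_pattern_both_empty_raises():
    with pytest.raises(ValueError):
        classify_model_pattern(set(), set())


def test_all_none_raises():
    with pytest.raises(ValueError):
        classify_tool_pattern({t: "none" for t in TOOLS})


def test_scope_mismatch_raises():
    with pytest.raises(ScopeMismatchError):
        source_status({"Z"}, ABC)


class TestIntegrate:
    per_source = {
        (t, m): s
        for (t, s) in WORKED.items()
        for m in GENE_MODELS
    }

    def test_full_equals_global_reference(self):
        assert integrate(Strategy.full(), self.per_source) == ABC

    def test_single_is_identity(self):
        s = Strategy("ANNOVAR", "Ensembl")
        assert integrate(s, self.per_source) == WORKED["ANNOVAR"]

    def test_empty_scope_raises(self):
        with pytest.raises(ValueError):
            integrate(Strategy("ANNOVAR", "Ensembl"), {("VEP", "RefSeq"): ABC})

    def test_grid_is_12_strategies(self):
        grid = strategy_grid()
        assert len(grid) == 12
        assert Strategy(COMBINED, COMBINED) in grid


@st.composite
def per_source_sets(draw):
    universe = "ABCDE"
    sets = {}
    for t in TOOLS:
        for m in GENE_MODELS:
            sets[(t, m)] = frozenset(
                draw(st.sets(st.sampled_from(universe), max_size=5))
            )
    return sets


@settings(max_examples=200, deadline=None)
@given(per_source_sets())
def test_enlarging_scope_never_decreases_numerator(per_source):
    """Monotonicity: a union over a superset scope captures at least as much."""
    if not any(per_source.values()):
        return
    ref = frozenset().union(*per_source.values())
    for tool in TOOLS:
        for model in GENE_MODELS:
            single = coverage(integrate(Strategy(tool, model), per_source), ref)
            both_models = coverage(
                integrate(Strategy(tool, COMBINED), per_source), ref
            )
            all_tools = coverage(
                integrate(Strategy(COMBINED, model), per_source), ref
            )
            assert both_models[0] >= single[0]
            assert all_tools[0] >= single[0]
    full = coverage(integrate(Strategy.full(), per_source), ref)
    assert full == (len(ref), len(ref))


@settings(max_examples=200, deadline=None)
@given(per_source_sets())
def test_union_of_captured_sets_is_reference(per_source):
    """Scope consistency: per-source contributions together tile the union."""
    if not any(per_source.values()):
        return
    ref = frozenset().union(*per_source.values())
    captured = frozenset().union(*(s & ref for s in per_source.values()))
    assert captured == ref
    assert sum(len(s & ref) for s in per_source.values()) >= len(ref)
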