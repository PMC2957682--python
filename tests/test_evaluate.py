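"""Categorization against truth, specificity tiers and summary arithmetic."""

import pytest

from mpabin.core import ASSIGNED, NO_HITS, UNASSIGNED, Assignment
from mpabin.errors import UnknownTaxidError, UsageError
from mpabin.evaluate import (
    CATEGORY_CORRECT,
    CATEGORY_WRONG,
    EvaluationRecord,
    SPEC_HIGHER,
    SPEC_INTERMEDIATE,
    SPEC_NA,
    SPEC_SPECIFIC,
    categorize,
    category_percentages,
    coverage,
    specificity_class,
    summarize,
)

AMMD = 339670           # strain-level leaf
TRUE = AMMD


def assign(taxid):
    return Assignment("r", ASSIGNED, taxid, "MPA", "species")


class TestCategorize:
    @pytest.mark.parametrize("taxid", [
        1, 131567, 2, 1224, 28216, 80840, 119060, 32008, 87882, 152480, AMMD,
    ])
    def test_every_node_on_the_true_path_is_correct(self, burk_tree, taxid):
        rec = categorize(burk_tree, assign(taxid), TRUE)
        assert rec.category == CATEGORY_CORRECT

    def test_family_assignment_correct(self, burk_tree):
        rec = categorize(burk_tree, assign(119060), TRUE)
        assert (rec.category, rec.specificity) == (CATEGORY_CORRECT, SPEC_SPECIFIC)

    @pytest.mark.parametrize("taxid", [48736, 305, 1236, 562])
    def test_off_path_is_wrong(self, burk_tree, taxid):
        rec = categorize(burk_tree, assign(taxid), TRUE)
        assert rec.category == CATEGORY_WRONG
        assert rec.specificity == SPEC_NA

    def test_root_is_correct_and_higher(self, burk_tree):
        rec = categorize(burk_tree, assign(1), TRUE)
        assert (rec.category, rec.specificity) == (CATEGORY_CORRECT, SPEC_HIGHER)

    def test_statuses_pass_through(self, burk_tree):
        assert categorize(burk_tree, Assignment("r", UNASSIGNED), TRUE) \
            .category == UNASSIGNED
        assert categorize(burk_tree, Assignment("r", NO_HITS), TRUE) \
            .category == NO_HITS

    def test_unknown_truth_taxid(self, burk_tree):
        with pytest.raises(UnknownTaxidError):
            categorize(burk_tree, assign(1), 424242)

    def test_correct_means_on_root_path(self, burk_tree):
        path = set(burk_tree.path_to_root(TRUE))
        for taxid in burk_tree.nodes:
            rec = categorize(burk_tree, assign(taxid), TRUE)
            assert (rec.category == CATEGORY_CORRECT) == (taxid in path)


class TestSpecificityClass:
    @pytest.mark.parametrize("taxid,expected", [
        (1, SPEC_HIGHER),            # root
        (131567, SPEC_HIGHER),       # cellular organisms
        (2, SPEC_HIGHER),            # superkingdom
        (1224, SPEC_INTERMEDIATE),   # phylum
        (28216, SPEC_INTERMEDIATE),  # class
        (80840, SPEC_INTERMEDIATE),  # order
        (119060, SPEC_SPECIFIC),     # family
        (32008, SPEC_SPECIFIC),      # genus
        (152480, SPEC_SPECIFIC),     # species
    ])
    def test_canonical_tiers(self, burk_tree, taxid, expected):
        assert specificity_class(burk_tree, taxid) == expected

    def test_non_canonical_defers_to_canonical_ancestor(self, burk_tree):
        # a species complex sits below the genus: Specific
        assert specificity_class(burk_tree, 87882) == SPEC_SPECIFIC
        # a strain below the species: Specific
        assert specificity_class(burk_tree, AMMD) == SPEC_SPECIFIC


class TestSummarize:
    def rec(self, category, spec=SPEC_NA, i=[0]):
        i[0] += 1
        return EvaluationRecord(f"r{i[0]}", TRUE, category, spec)

    def test_degenerate_all_correct_specific(self):
        records = [self.rec(CATEGORY_CORRECT, SPEC_SPECIFIC) for _ in range(10)]
        pct = category_percentages(records)
        assert pct[CATEGORY_CORRECT] == 100.0
        df = summarize(records)
        spec_row = df[(df.group == "specificity") & (df.label == SPEC_SPECIFIC)]
        assert float(spec_row["percent"].iloc[0]) == 100.0

    def test_half_and_half(self):
        records = ([self.rec(CATEGORY_CORRECT, SPEC_SPECIFIC)] * 5
                   + [self.rec(CATEGORY_WRONG)] * 5)
        pct = category_percentages(records)
        assert pct[CATEGORY_CORRECT] == pct[CATEGORY_WRONG] == 50.0

    def test_percentages_sum_to_100(self):
        import random

        rng = random.Random(2)
        cats = [CATEGORY_CORRECT, CATEGORY_WRONG, UNASSIGNED, NO_HITS]
        records = [self.rec(rng.choice(cats)) for _ in range(137)]
        assert sum(category_percentages(records).values()) == pytest.approx(100.0)

    def test_empty_is_an_error(self):
        with pytest.raises(UsageError):
            summarize([])


class TestReclassifyVersusDiscard:
    """End-to-end on clade-deletion scenarios: promoting reads out of
    isolated bins must not add wrong assignments, and must leave fewer reads
    unassigned than the alternative of discarding the isolated bins
    (a synthetic-scenario property, not a claim about real data)."""

    @pytest.mark.parametrize("mode,seed", [
        ("known", 0), ("species-unknown", 1), ("species-unknown", 2),
        ("genus-unknown", 3),
    ])
    def test_wrong_and_unassigned_never_increase(self, mode, seed):
        from dataclasses import replace

        from mpabin.core import assign_all
        from mpabin.evaluate import categorize_all
        from mpabin.fixtures import BitscoreModel, ScenarioSpec, make_scenario
        from mpabin.reclassify import (
            IsolationPolicy,
            build_bin_table,
            isolated_taxon_size,
            reclassify,
        )

        spec = ScenarioSpec(reads_per_species=30, seed=seed, unknown_mode=mode,
                            bitscore_model=BitscoreModel(noise_sd=15.0))
        tree, bundle = make_scenario(spec)
        raw = assign_all(tree, bundle.read_hit_sets)
        size = isolated_taxon_size(len(raw))
        promoted = reclassify(tree, raw, IsolationPolicy(size))
        bins = build_bin_table(tree, raw)
        isolated = {t for t, n in bins.direct_count.items() if n < size}
        discarded = [
            replace(a, status=UNASSIGNED, taxid=None, old_taxid=a.taxid)
            if a.status == ASSIGNED and a.taxid in isolated else a
            for a in raw
        ]
        p_raw = category_percentages(categorize_all(tree, raw, bundle.truth))
        p_pro = category_percentages(categorize_all(tree, promoted, bundle.truth))
        p_dis = category_percentages(categorize_all(tree, discarded, bundle.truth))
        assert p_pro[CATEGORY_WRONG] <= p_raw[CATEGORY_WRONG]
        assert p_pro[UNASSIGNED] <= p_dis[UNASSIGNED]


class TestCoverage:
    @pytest.mark.parametrize("read_length,expected", [
        (1000, 0.5),
        (400, 0.2),
        (250, 0.13),   # 0.125 rounds to two decimals
        (100, 0.05),
    ])
    def test_low_coverage_examples_for_small_genomes(self, read_length, expected):
        # 300 reads from a 0.6 Mb genome: the isolated-taxon cap is sized so
        # that organisms this rare never count as isolated
        assert coverage(300, read_length, 600_000) == expected

    def test_zero_reads(self):
        assert coverage(0, 1000, 600_000) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            coverage(10, 0, 100)
        with pytest.raises(ValueError):
            coverage(-1, 10, 100)
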