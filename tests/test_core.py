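"""Candidate-ancestor enumeration, ratio scoring and MPA selection."""

import networkx as nx
import pytest

from mpabin.core import (
    ASSIGNED,
    NO_HITS,
    ROUTE_MPA,
    ROUTE_SINGLE_HIT,
    ROUTE_TWO_HIT_LCA,
    UNASSIGNED,
    Assignment,
    CandidateAncestor,
    assign_read,
    enumerate_candidate_ancestors,
    plain_lca_assign,
    score_candidates,
    select_mpa,
)
from mpabin.errors import UsageError
from mpabin.fixtures import (
    ScenarioSpec,
    make_scenario,
    make_stray_hit_scenario,
)
from mpabin.hits import AlignmentHit, ReadHitSet, filter_valid_hits, make_read_hit_set
from mpabin.taxonomy import RANK_INDEX
from mpabin.tl import determine_tl, substitute_at_tl

from conftest import tree_from_rows


def hit(taxid, bit, qid="r"):
    return AlignmentHit(qid, f"s{taxid}_{bit}", taxid, float(bit), 100, 100, 100)


def sub(pairs):
    """[(taxid, bit)] -> substituted list as produced by substitute_at_tl."""
    return [(hit(t, b), t) for t, b in pairs]


@pytest.fixture(scope="module")
def tree():
    # two sister genera inside one family, plus a second family in the order
    return tree_from_rows([
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "sk"),
        (3, 2, "phylum", "p"),
        (4, 3, "class", "c"),
        (5, 4, "order", "o"),
        (6, 5, "family", "famA"),
        (7, 6, "genus", "gA1"),
        (8, 6, "genus", "gA2"),
        (9, 7, "species", "spA1a"),
        (10, 7, "species", "spA1b"),
        (11, 8, "species", "spA2a"),
        (12, 5, "family", "famB"),
        (13, 12, "genus", "gB1"),
        (14, 13, "species", "spB1a"),
    ])


class TestEnumerate:
    def test_identical_taxa_single_candidate(self, tree):
        chain = enumerate_candidate_ancestors(tree, sub([(9, 90), (9, 80), (9, 70)]))
        assert [c.taxid for c in chain] == [9]

    def test_sister_genera_then_other_family(self, tree):
        # species of two sister genera meet at the family; adding the other
        # family's species pushes the running LCA to the order
        chain = enumerate_candidate_ancestors(
            tree, sub([(9, 90), (11, 80), (14, 70)]))
        assert [(c.taxid, c.introduced_at) for c in chain] == [(6, 1), (5, 2)]

    def test_chain_is_rootward_and_ends_at_global_lca(self, tree):
        import random

        ids = [9, 10, 11, 14]
        rng = random.Random(1)
        for _ in range(50):
            taxa = [rng.choice(ids) for _ in range(rng.randint(3, 8))]
            bits = sorted((rng.uniform(40, 200) for _ in taxa), reverse=True)
            substituted = sub(list(zip(taxa, bits)))
            chain = enumerate_candidate_ancestors(tree, substituted)
            for earlier, later in zip(chain, chain[1:]):
                assert tree.is_ancestor(later.taxid, earlier.taxid)
                assert later.taxid != earlier.taxid
            assert chain[-1].taxid == tree.lca_set(taxa)
            assert chain[0].taxid == tree.lca(taxa[0], taxa[1])

    def test_requires_three_hits(self, tree):
        with pytest.raises(UsageError):
            enumerate_candidate_ancestors(tree, sub([(9, 90), (11, 80)]))


class TestScoring:
    def test_zero_distance_uses_offset_denominator(self, tree):
        substituted = sub([(9, 60), (9, 50), (9, 40)])
        [cand] = score_candidates(tree, substituted,
                                  [CandidateAncestor(9, 1)])
        assert cand.ratio_sum == pytest.approx(60 + 50 + 40)

    def test_distance_one_halves_the_bit_score(self, tree):
        [cand] = score_candidates(tree, sub([(9, 70)]),
                                  [CandidateAncestor(7, 0)])
        assert cand.ratio_sum == pytest.approx(35.0)

    def test_matches_bfs_distance_brute_force(self, tree):
        import random

        g = nx.Graph()
        for node in tree.nodes.values():
            if node.tax_id != tree.root_id:
                g.add_edge(node.tax_id, node.parent_id)
        ids = [9, 10, 11, 14]
        rng = random.Random(3)
        for _ in range(25):
            taxa = [rng.choice(ids) for _ in range(rng.randint(3, 7))]
            bits = sorted((rng.uniform(40, 200) for _ in taxa), reverse=True)
            substituted = sub(list(zip(taxa, bits)))
            chain = enumerate_candidate_ancestors(tree, substituted)
            score_candidates(tree, substituted, chain)
            for cand in chain:
                dist = nx.single_source_shortest_path_length(g, cand.taxid)
                expect = sum(b / (dist[t] + 1) for t, b in zip(taxa, bits))
                assert cand.ratio_sum == pytest.approx(expect)


class TestSelectMpa:
    def test_argmax(self):
        assert select_mpa([CandidateAncestor(5, 1, 110.0),
                           CandidateAncestor(3, 2, 90.0)]) == 5

    def test_tie_goes_to_the_deeper_candidate(self):
        # the chain is ordered deepest-first: a child/parent tie keeps the child
        assert select_mpa([CandidateAncestor(9, 1, 50.0),
                           CandidateAncestor(7, 2, 50.0)]) == 9

    def test_exhaustive_argmax_oracle(self):
        import random

        rng = random.Random(11)
        for _ in range(50):
            sums = [rng.choice([10.0, 20.0, 30.0]) for _ in range(rng.randint(1, 6))]
            chain = [CandidateAncestor(i, i, s) for i, s in enumerate(sums)]
            best = max(sums)
            assert chain[sums.index(best)].taxid == select_mpa(chain)

    def test_empty_is_an_error(self):
        with pytest.raises(UsageError):
            select_mpa([])


class TestAssignRead:
    def test_no_blast_rows(self, tree):
        a = assign_read(tree, ReadHitSet("r"))
        assert a.status == NO_HITS and a.taxid is None

    def test_all_hits_invalid(self, tree):
        rhs = make_read_hit_set("r", [
            AlignmentHit("r", "s", 9, 30.0, 100, 100, 100)])
        assert assign_read(tree, rhs).status == UNASSIGNED

    def test_single_hit_route(self, tree):
        rhs = make_read_hit_set("r", [hit(9, 120)])
        a = assign_read(tree, rhs)
        assert (a.status, a.route, a.taxid) == (ASSIGNED, ROUTE_SINGLE_HIT, 9)

    def test_two_hit_lca_route(self, tree):
        rhs = make_read_hit_set("r", [hit(9, 120), hit(11, 100)])
        a = assign_read(tree, rhs)
        assert (a.route, a.taxid) == (ROUTE_TWO_HIT_LCA, 6)

    def test_assignment_never_deeper_than_tl(self):
        spec = ScenarioSpec(reads_per_species=5, seed=9)
        t, bundle = make_scenario(spec)
        for rhs in bundle.read_hit_sets:
            a = assign_read(t, rhs)
            if a.status != ASSIGNED:
                continue
            valid = filter_valid_hits(rhs)
            tl = determine_tl(valid.best_hit)
            best_at_tl = substitute_at_tl(t, valid, tl)[0][1]
            # assigned node is an ancestor-or-self of the best hit's projection
            assert t.is_ancestor(a.taxid, best_at_tl)
            rank = t.rank(a.taxid)
            if rank in RANK_INDEX:
                assert RANK_INDEX[rank] <= RANK_INDEX[tl]

    def test_mpa_is_always_an_enumerated_candidate(self):
        spec = ScenarioSpec(reads_per_species=5, seed=13,
                            unknown_mode="genus-unknown")
        t, bundle = make_scenario(spec)
        checked = 0
        for rhs in bundle.read_hit_sets:
            valid = filter_valid_hits(rhs)
            if len(valid.hits) < 3:
                continue
            tl = determine_tl(valid.best_hit)
            substituted = substitute_at_tl(t, valid, tl)
            if len({x for _, x in substituted}) == 1:
                continue
            chain = enumerate_candidate_ancestors(t, substituted)
            a = assign_read(t, rhs)
            assert a.taxid in {c.taxid for c in chain}
            checked += 1
        assert checked > 50

    def test_stray_hits_genus_vs_phylum(self):
        """Strong within-genus hits plus two distant strays: ratio scoring
        assigns the genus where the plain LCA collapses to the phylum."""
        t, rhs, true_taxid = make_stray_hit_scenario()
        mpa = assign_read(t, rhs)
        lca = plain_lca_assign(t, rhs)
        assert t.rank(mpa.taxid) == "genus"
        assert t.is_ancestor(mpa.taxid, true_taxid)
        assert t.rank(lca.taxid) == "phylum"

    def test_status_taxid_consistency_enforced(self):
        with pytest.raises(UsageError):
            Assignment("r", ASSIGNED)
        with pytest.raises(UsageError):
            Assignment("r", UNASSIGNED, taxid=5)
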