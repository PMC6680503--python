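"""Per-family consensus class and score."""

import math
import random

import pytest

from netenhance import (
    CandidateStructure,
    ChemTaxonomy,
    NetworkValidationError,
    build_network,
    classify_network,
    family_classification,
    node_votes,
)
from netenhance._bruteforce import count_node_votes, score_family

TERMS = ["cinnamaldehydes", "coumarins and derivatives", "flavonoids",
         "macrolactames", "prenol lipids", "peptidomimetics"]


def tax(term):
    return ChemTaxonomy(kingdom="organic compounds", superclass="s", class_=term)


class TestNodeVotes:
    def test_fractional_split(self):
        v = node_votes(1, [tax("flavonoids")] * 3 + [tax("coumarins and derivatives")],
                       "class")
        assert v.votes == {"coumarins and derivatives": 0.25, "flavonoids": 0.75}

    def test_single_candidate_gets_full_vote(self):
        v = node_votes(1, [tax("flavonoids")], "class")
        assert v.votes == {"flavonoids": 1.0}

    def test_record_without_term_votes_unclassified(self):
        shallow = ChemTaxonomy(kingdom="organic compounds")
        v = node_votes(1, [shallow, tax("flavonoids")], "class")
        assert v.votes == {"flavonoids": 0.5, "unclassified": 0.5}

    def test_no_candidates_means_unannotated(self):
        assert not node_votes(1, [], "class").annotated

    def test_explicit_weights_normalize_to_unit_mass(self):
        from fractions import Fraction

        v = node_votes(1, [tax("flavonoids"), tax("coumarins and derivatives")],
                       "class", weights=[Fraction(3), Fraction(1)])
        assert v.votes == {"coumarins and derivatives": 0.25, "flavonoids": 0.75}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_counting_oracle(self, seed):
        rng = random.Random(seed)
        terms = [rng.choice(TERMS + [None]) for _ in range(rng.randrange(0, 9))]
        v = node_votes(1, [tax(t) if t else ChemTaxonomy() for t in terms], "class")
        expected = count_node_votes(terms)
        assert set(v.votes) == set(expected)
        for t in expected:
            assert math.isclose(float(v.votes[t]), expected[t], abs_tol=1e-12)
        # vote mass of an annotated node sums to 1
        if terms:
            assert math.isclose(sum(float(x) for x in v.votes.values()), 1.0,
                                abs_tol=1e-9)


def votes_for(per_node_terms, level="class"):
    out = []
    for i, terms in enumerate(per_node_terms, start=1):
        out.append(node_votes(i, [tax(t) if t else ChemTaxonomy() for t in terms],
                              level))
    return out


class TestFamilyClassification:
    def test_six_node_worked_example_scores_0_375(self):
        per_node = [
            ["flavonoids"] * 4,
            ["flavonoids", "coumarins and derivatives", "cinnamaldehydes",
             "macrolactames"],
            ["flavonoids", "flavonoids"],
            ["coumarins and derivatives", "coumarins and derivatives"],
            [],
            [],
        ]
        fc = family_classification(1, votes_for(per_node), "class")
        assert fc.top_class == "flavonoids"
        assert fc.score == pytest.approx(0.375, abs=1e-12)
        assert fc.vote_totals["flavonoids"] == pytest.approx(2.25)
        assert (fc.n_nodes, fc.n_annotated) == (6, 4)

    def test_singleton_with_one_match_scores_1(self):
        fc = family_classification("S9", votes_for([["flavonoids"]]), "class")
        assert (fc.top_class, fc.score) == ("flavonoids", 1.0)

    def test_unanimity_scores_1(self):
        fc = family_classification(1, votes_for([["flavonoids"]] * 5), "class")
        assert fc.score == 1.0

    def test_empty_family_rejected(self):
        with pytest.raises(NetworkValidationError):
            family_classification(1, [], "class")

    def test_unclassified_wins_only_without_real_support(self):
        fc = family_classification(1, votes_for([[None, None], []]), "class")
        assert (fc.top_class, fc.score) == ("unclassified", 0.5)
        fc2 = family_classification(1, votes_for([[None, "flavonoids"]]), "class")
        assert fc2.top_class == "flavonoids"

    def test_tie_breaks_by_supporting_nodes_then_alphabet(self):
        # flavonoids: 1 node with full vote; coumarins: 2 nodes with halves
        per_node = [["flavonoids"],
                    ["coumarins and derivatives", None],
                    ["coumarins and derivatives", None]]
        fc = family_classification(1, votes_for(per_node), "class")
        assert fc.top_class == "coumarins and derivatives"
        # exact tie on mass and supporters -> alphabetical
        fc2 = family_classification(1, votes_for([["flavonoids"], ["cinnamaldehydes"]]),
                                    "class")
        assert fc2.top_class == "cinnamaldehydes"

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_enumeration_oracle(self, seed):
        rng = random.Random(1000 + seed)
        per_node = [
            [rng.choice(TERMS + [None]) for _ in range(rng.randrange(0, 9))]
            for _ in range(rng.randrange(1, 11))
        ]
        fc = family_classification(1, votes_for(per_node), "class")
        top, score = score_family(per_node)
        assert fc.top_class == top
        assert fc.score == pytest.approx(score, abs=1e-9)
        assert 0.0 <= fc.score <= 1.0
        # conservation: total vote mass equals the number of annotated nodes
        assert sum(fc.vote_totals.values()) == pytest.approx(
            sum(1 for t in per_node if t), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_candidate_order_never_changes_the_result(self, seed):
        rng = random.Random(seed)
        per_node = [[rng.choice(TERMS) for _ in range(rng.randrange(1, 6))]
                    for _ in range(4)]
        fc1 = family_classification(1, votes_for(per_node), "class")
        shuffled = [sorted(t, key=lambda _: rng.random()) for t in per_node]
        fc2 = family_classification(1, votes_for(shuffled), "class")
        assert (fc1.top_class, fc1.score) == (fc2.top_class, fc2.score)


class TestClassifyNetwork:
    def _setup(self, toy_network):
        cands = {
            1: [CandidateStructure(cluster_id=1, source="library", rank=1,
                                   smiles="CCO", structure_key="K1")],
        }
        taxonomies = {(1, "library", 1): tax("flavonoids")}
        return cands, taxonomies

    def test_one_row_per_family_and_level(self, toy_network):
        cands, taxonomies = self._setup(toy_network)
        table, _ = classify_network(toy_network, cands, taxonomies)
        assert len(table) == len(toy_network.families) * 5

    def test_family_without_candidates_is_unclassified(self, toy_network):
        cands, taxonomies = self._setup(toy_network)
        table, _ = classify_network(toy_network, cands, taxonomies)
        row = table[(table.family_id == 2) & (table.level == "class")].iloc[0]
        assert (row.top_class, row.score) == ("unclassified", 0.0)

    def test_disjoint_id_spaces_rejected(self, toy_network):
        cands = {99: [CandidateStructure(cluster_id=99, source="library", rank=1,
                                         smiles="CCO", structure_key="K1")]}
        with pytest.raises(NetworkValidationError, match="share no cluster ids"):
            classify_network(toy_network, cands, {(99, "library", 1): tax("x")})

    def test_rank_weighting_favours_top_candidates(self, toy_network):
        cands = {1: [
            CandidateStructure(cluster_id=1, source="insilico_fusion", rank=1,
                               smiles="CCO", structure_key="K1"),
            CandidateStructure(cluster_id=1, source="insilico_fusion", rank=2,
                               smiles="CCN", structure_key="K2"),
        ]}
        taxonomies = {(1, "insilico_fusion", 1): tax("flavonoids"),
                      (1, "insilico_fusion", 2): tax("macrolactames")}
        flat, _ = classify_network(toy_network, cands, taxonomies)
        weighted, _ = classify_network(toy_network, cands, taxonomies,
                                       rank_weighted=True)
        f_flat = flat[(flat.family_id == 1) & (flat.level == "class")].iloc[0]
        f_w = weighted[(weighted.family_id == 1) & (weighted.level == "class")].iloc[0]
        assert f_flat.score == pytest.approx(0.5 / 4)       # tie split 50/50
        assert f_w.top_class == "flavonoids"
        assert f_w.score == pytest.approx((2 / 3) / 4)      # 1 : 1/2 weights

    def test_fixture_scores_match_manifest(self, bundle):
        from netenhance import (
            TaxonomyCache, assign_structure_keys, classify_candidates,
            read_edge_table, read_insilico_candidates, read_library_hits,
            read_node_table, read_peptidic_annotations, unify_candidates,
        )
        out, manifest = bundle
        net = build_network(read_node_table(out / "nodes.tsv"),
                            read_edge_table(out / "edges.tsv"))
        pooled = (read_library_hits(out / "library.tsv")
                  + read_insilico_candidates(out / "insilico_fusion.tsv",
                                             source="insilico_fusion")
                  + read_insilico_candidates(out / "insilico_consensus.tsv",
                                             source="insilico_consensus")
                  + read_peptidic_annotations(out / "peptidic.tsv"))
        keyed, _ = assign_structure_keys(pooled)
        cands = unify_candidates([keyed])
        cache = TaxonomyCache.from_tsv(out / "taxonomy_cache.tsv")
        res = classify_candidates(cands, cache)
        table, _ = classify_network(net, cands, res.taxonomies)
        for fid, levels in manifest["classifications"].items():
            key = fid if fid.startswith("S") else int(fid)
            for level, gt in levels.items():
                row = table[(table.family_id == key) & (table.level == level)].iloc[0]
                assert row.top_class == gt["top_class"]
                assert row.score == pytest.approx(gt["score"], abs=1e-9)
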