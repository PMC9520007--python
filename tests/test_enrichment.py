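import math
from fractions import Fraction

import numpy as np
import pytest

from scpdyn.enrichment import (
    assemble_timelines,
    build_scp_network,
    dynamic_enrichment,
    fisher_scp_test,
    generate_combinations,
    standard_enrichment,
)
from scpdyn.ontology import SCP, ConfigurationError, HorizontalInteraction, OntologyGraph


def hypergeom_upper_tail(overlap, list_size, unit_size, background_size):
    """Independent oracle: exact rational tail sum over the hypergeometric support."""
    total = Fraction(math.comb(background_size, list_size))
    tail = Fraction(0)
    for k in range(overlap, min(list_size, unit_size) + 1):
        tail += Fraction(
            math.comb(unit_size, k) * math.comb(background_size - unit_size, list_size - k)
        )
    return tail / total


class TestFisher:
    def test_matches_enumeration_oracle(self):
        background = [f"G{i}" for i in range(100)]
        unit = set(background[:20])
        gene_list = set(background[15:25])  # overlap 5, list 10
        p, overlap = fisher_scp_test(gene_list, unit, background)
        assert overlap == 5
        assert p == pytest.approx(float(hypergeom_upper_tail(5, 10, 20, 100)), abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        background = [f"G{i}" for i in range(50)]
        p, overlap = fisher_scp_test(set(background[:5]), set(background[10:20]), background)
        assert overlap == 0
        assert p == pytest.approx(1.0)

    def test_saturated_table_gives_p_one(self):
        background = [f"G{i}" for i in range(10)]
        p, _ = fisher_scp_test(background, background, background)
        assert p == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            fisher_scp_test({"A"}, {"A"}, set())


class TestStandardEnrichment:
    def test_planted_scp_flagged_significant(self):
        background = frozenset(f"G{i}" for i in range(1000))
        scp_genes = frozenset(f"G{i}" for i in range(10))
        scps = {"S": SCP("S", "planted", 2, scp_genes)}
        graph = OntologyGraph(scps, (), background)
        gene_list = {f"G{i}" for i in range(8)} | {f"G{i}" for i in range(500, 542)}  # 8/10, list 50
        results = standard_enrichment({(4.0, "up"): gene_list}, graph, levels=(2,))
        assert len(results) == 1
        assert results[0].significant
        assert results[0].overlap == 8

    def test_disjoint_list_not_significant(self, toy_ontology):
        results = standard_enrichment({(2.0, "up"): {"G20", "G21"}}, toy_ontology, levels=(2,))
        assert results and not any(r.significant for r in results)

    def test_null_calibration_is_conservative(self, toy_ontology):
        # fraction of single-SCP tests with p <= alpha stays at or below alpha
        rng = np.random.default_rng(0)
        background = sorted(toy_ontology.background)
        hits = trials = 0
        for _ in range(400):
            gene_list = set(rng.choice(background, 8, replace=False))
            for r in standard_enrichment({(2.0, "up"): gene_list}, toy_ontology, levels=(2,)):
                trials += 1
                hits += r.p_value <= 0.05
        assert hits / trials <= 0.05 + 0.02

    def test_empty_stratum_skipped(self, toy_ontology):
        assert standard_enrichment({(2.0, "up"): set()}, toy_ontology) == []


class TestCombinations:
    def test_toy_graph_pairs_and_connected_triple(self, toy_ontology):
        combos = generate_combinations({"A", "B", "C"}, toy_ontology, top_fraction=0.5)
        ids = {c.unit_id for c in combos}
        # strong edges A-B and B-C: pairs AB and BC, triple ABC connected via B
        assert ids == {"A+B", "B+C", "A+B+C"}
        abc = next(c for c in combos if c.unit_id == "A+B+C")
        assert abc.genes == toy_ontology.genes_of(("A", "B", "C"))

    def test_no_strong_edges_yields_nothing(self, toy_ontology):
        assert generate_combinations({"A", "D"}, toy_ontology, top_fraction=0.5) == []

    def test_below_cutoff_edge_respected(self, toy_ontology):
        # A-C exists but is weak: no combination at a stringent cutoff
        assert generate_combinations({"A", "C"}, toy_ontology, top_fraction=0.25) == []

    def test_all_pairs_flag_requires_clique(self, toy_ontology):
        combos = generate_combinations(
            {"A", "B", "C"}, toy_ontology, top_fraction=0.5, require_all_pairs=True
        )
        assert {c.unit_id for c in combos} == {"A+B", "B+C"}

    def test_mixed_levels_rejected(self, toy_ontology):
        with pytest.raises(ConfigurationError):
            generate_combinations({"ROOT", "A"}, toy_ontology)


def weak_pair_ontology():
    """Two interacting SCPs, each with weak individual overlap, plus distractors."""
    background = frozenset(f"G{i}" for i in range(2000)) | frozenset(
        f"X{i}" for i in range(80)
    )
    scps = {
        "P1": SCP("P1", "p1", 2, frozenset(f"X{i}" for i in range(20))),
        "P2": SCP("P2", "p2", 2, frozenset(f"X{i}" for i in range(20, 40))),
        "N1": SCP("N1", "n1", 2, frozenset(f"X{i}" for i in range(40, 60))),
        "N2": SCP("N2", "n2", 2, frozenset(f"X{i}" for i in range(60, 80))),
    }
    interactions = (
        HorizontalInteraction("P1", "P2", 0.95),
        HorizontalInteraction("N1", "N2", 0.4),
        HorizontalInteraction("P1", "N1", 0.3),
        HorizontalInteraction("P2", "N2", 0.2),
    )
    return OntologyGraph(scps, interactions, background)


class TestDynamicEnrichment:
    def test_combination_outranks_weak_singles(self):
        graph = weak_pair_ontology()
        # 3 list genes in each of P1, P2: individually weak, jointly strong
        gene_list = {"X0", "X1", "X2", "X20", "X21", "X22"}
        predictions = dynamic_enrichment(gene_list, graph, level=2, top_fraction=0.25)
        assert predictions[0].unit_id == "P1+P2"
        p_by_unit = {r.unit_id: r.p_value for r in dynamic_enrichment(
            gene_list, graph, level=2, top_fraction=0.25, top_k=10)}
        assert p_by_unit["P1+P2"] < p_by_unit["P1"]
        assert p_by_unit["P1+P2"] < p_by_unit["P2"]

    def test_list_inside_single_scp_ranks_first(self, toy_ontology):
        predictions = dynamic_enrichment({"G1", "G2", "G3"}, toy_ontology, level=2,
                                         top_fraction=0.5)
        assert predictions[0].unit_id == "A"

    def test_tie_breaks_toward_fewer_members(self):
        # unit genes identical => identical Fisher table => p tie; single must win
        background = frozenset(f"G{i}" for i in range(100))
        scps = {
            "S": SCP("S", "s", 2, frozenset({"G0", "G1", "G2", "G3"})),
            "T": SCP("T", "t", 2, frozenset({"G0", "G1"})),
            "U": SCP("U", "u", 2, frozenset({"G2", "G3"})),
        }
        interactions = (HorizontalInteraction("T", "U", 1.0),)
        graph = OntologyGraph(scps, interactions, background)
        predictions = dynamic_enrichment({"G0", "G1", "G2", "G3"}, graph, level=2,
                                         top_fraction=1.0, top_k=5)
        assert predictions[0].unit_id == "S"
        assert predictions[1].unit_id == "T+U"
        assert predictions[0].p_value == predictions[1].p_value

    def test_no_seed_overlap_gives_empty(self, toy_ontology):
        assert dynamic_enrichment({"G20"}, toy_ontology, level=2) == []

    def test_deterministic(self):
        graph = weak_pair_ontology()
        gene_list = {"X0", "X1", "X21", "X40", "X60"}
        first = dynamic_enrichment(gene_list, graph, level=2)
        second = dynamic_enrichment(set(sorted(gene_list, reverse=True)), graph, level=2)
        assert [r.unit_id for r in first] == [r.unit_id for r in second]


class TestNetwork:
    def test_pair_prediction_makes_single_edge(self):
        graph = weak_pair_ontology()
        preds = dynamic_enrichment({"X0", "X1", "X2", "X20", "X21", "X22"}, graph,
                                   level=2, top_fraction=0.25)
        net = build_scp_network({(6.0, "up"): preds})
        assert net.has_edge("P1", "P2")
        assert ("P1+P2", 6.0, "up") in net.edges["P1", "P2"]["predictions"]

    def test_triple_prediction_makes_clique(self, toy_ontology):
        preds = dynamic_enrichment(
            {"G1", "G5", "G9"}, toy_ontology, level=2, top_fraction=0.5, top_k=1
        )
        triple = [p for p in preds if len(p.member_ids) == 3]
        if triple:  # clique over members
            net = build_scp_network({(2.0, "up"): triple})
            assert net.number_of_edges() == 3

    def test_every_edge_certified_by_a_prediction(self):
        graph = weak_pair_ontology()
        preds = dynamic_enrichment({"X0", "X1", "X2", "X20", "X21", "X22"}, graph,
                                   level=2, top_fraction=0.25, top_k=5)
        net = build_scp_network({(6.0, "up"): preds})
        pred_ids = {p.unit_id for p in preds}
        for _, _, data in net.edges(data=True):
            assert all(uid in pred_ids for uid, _, _ in data["predictions"])

    def test_disjoint_singles_make_edgeless_network(self, toy_ontology):
        preds = dynamic_enrichment({"G1", "G13"}, toy_ontology, level=2, top_fraction=0.25)
        net = build_scp_network({(2.0, "up"): preds})
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() >= 1


class TestTimelines:
    def test_neg_log10_transform_and_absents(self, toy_ontology):
        results = standard_enrichment(
            {(2.0, "up"): {"G1", "G2"}, (6.0, "up"): {"G1", "G2"}},
            toy_ontology,
            levels=(2,),
        )
        frame = assemble_timelines(results)
        # tested at 2 of 2 time points for "up" but never for "down"
        a_up = frame[(frame.scp_id == "A") & (frame.direction == "up")]
        a_down = frame[(frame.scp_id == "A") & (frame.direction == "down")]
        assert len(a_up) == 2 and a_up.neg_log10_p.notna().all()
        assert len(a_down) == 2 and a_down.neg_log10_p.isna().all()
        assert frame.attrs["significance_line"] == pytest.approx(-math.log10(0.05))

    def test_p_of_alpha_maps_to_significance_line(self):
        background = frozenset(f"G{i}" for i in range(40))
        scps = {"S": SCP("S", "s", 2, frozenset({"G0", "G1"}))}
        graph = OntologyGraph(scps, (), background)
        results = standard_enrichment({(4.0, "up"): {"G0", "G1"}}, graph, levels=(2,))
        frame = assemble_timelines(results)
        value = frame.dropna().neg_log10_p.iloc[0]
        assert value == pytest.approx(-math.log10(results[0].p_value))
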