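"""Null-model generators, FDR tables and termination-level selection."""

import math

import numpy as np
import pandas as pd
import pytest

from gocoll import (
    FixtureSpec,
    MiningConfig,
    TerminationLevels,
    fdr_table,
    gen_random_by_ontology,
    gen_sampling_replacement,
    gen_uniform_random,
    level_distribution,
    level_gof_pvalue,
    termination_levels,
)
from gocoll.montecarlo import FDRTable, transaction_shape

from conftest import B1, B2, C0, M1, M2, transactions


class TestLevelDistribution:
    def test_single_cell(self, chains_graph):
        t = transactions({"g1": {M2}, "g2": {M2}}, chains_graph)
        d = level_distribution(t, chains_graph)
        assert d.p_level() == {3: 1.0}
        assert d.p_ns_given_level(3) == {"MF": 1.0}

    def test_hand_counted_mixture(self, chains_graph):
        # two level-3 MF instances, two level-2 BP instances
        t = transactions(
            {"g1": {M2, B1}, "g2": {M2, B1}}, chains_graph
        )
        d = level_distribution(t, chains_graph)
        assert d.p_level() == {2: 0.5, 3: 0.5}
        assert d.p_ns_given_level(2) == {"BP": 1.0}

    def test_repeats_across_transactions_counted(self, chains_graph):
        t = transactions({"g1": {M2}, "g2": {M2}, "g3": {B1}}, chains_graph)
        d = level_distribution(t, chains_graph)
        assert d.level_counts[3] == 2 and d.total == 3

    def test_probabilities_sum_to_one(self, chains_graph):
        t = transactions({"g1": {M2, B1, C0}, "g2": {B2}}, chains_graph)
        d = level_distribution(t, chains_graph)
        assert math.isclose(sum(d.p_level().values()), 1.0, abs_tol=1e-12)
        for lv in d.p_level():
            assert math.isclose(sum(d.p_ns_given_level(lv).values()), 1.0,
                                abs_tol=1e-12)


@pytest.fixture(scope="module")
def toy_graph():
    from gocoll import make_toy_ontology
    g, _ = make_toy_ontology(FixtureSpec(depth=4, branching=2, seed=7))
    return g


class TestGenerators:
    def test_uniform_marginals_within_binomial_bound(self, chains_graph):
        # single-item transactions so the in-transaction dedup is inert
        shape = [1] * 10000
        t = gen_uniform_random(chains_graph, shape, seed=1)
        n_terms = len(chains_graph.terms)
        counts = {}
        for term in t.annotation_instances():
            counts[term] = counts.get(term, 0) + 1
        p = 1 / n_terms
        sigma = math.sqrt(10000 * p * (1 - p))
        for term in chains_graph.terms:
            assert abs(counts.get(term, 0) - 10000 * p) < 3 * sigma + 1

    def test_replacement_marginals_follow_background(self, chains_graph):
        # background multiset {M2, M2, B1}: P(M2) = 2/3
        target = transactions({"g1": {M2}, "g2": {M2}, "g3": {B1}}, chains_graph)
        t = gen_sampling_replacement(target, chains_graph, [1] * 10000, seed=2)
        n_m2 = sum(term == M2 for term in t.annotation_instances())
        sigma = math.sqrt(10000 * (2 / 3) * (1 / 3))
        assert abs(n_m2 - 10000 * 2 / 3) < 3 * sigma

    def test_replacement_vocabulary_subset_of_target(self, chains_graph):
        target = transactions({"g1": {M2, B1}}, chains_graph)
        t = gen_sampling_replacement(target, chains_graph, [1] * 50, seed=3)
        assert set(t.annotation_instances()) <= {M2, B1}

    def test_by_ontology_concentrated_distribution(self, chains_graph):
        target = transactions({"g1": {M2}, "g2": {M2}}, chains_graph)
        d = level_distribution(target, chains_graph)
        t = gen_random_by_ontology(chains_graph, d, [1] * 100, seed=4)
        for term in t.annotation_instances():
            assert chains_graph.find_level(term) == 3
            assert chains_graph.namespace(term) == "MF"

    @pytest.mark.parametrize("gen", ["uniform", "by-ontology", "replacement"])
    def test_determinism_and_shape(self, chains_graph, gen):
        target = transactions(
            {"g1": {M2, B1}, "g2": {B2}, "g3": {M1, C0, B2}}, chains_graph
        )
        shape = transaction_shape(target)
        from gocoll.montecarlo import make_generator
        f = make_generator(gen, chains_graph, target)
        t1, t2 = f(shape, 5), f(shape, 5)
        assert t1.transactions == t2.transactions
        assert sorted(len(s) for s in t1.transactions.values()) == sorted(shape)

    def test_itemset_larger_than_vocabulary_errors(self, chains_graph):
        with pytest.raises(ValueError, match="vocabulary"):
            gen_uniform_random(chains_graph, [100], seed=0)

    def test_by_ontology_passes_gof_uniform_fails(self, toy_graph):
        """Shape-aware null keeps the target's level profile; the uniform
        null does not, on a target skewed toward the leaves."""
        from gocoll import build_transactions, make_toy_annotations, read_gaf
        import io
        spec = FixtureSpec(depth=4, branching=2, n_genes=120,
                           annotations_per_gene=5, noise=1.0, seed=7)
        gaf = make_toy_annotations(toy_graph, spec)
        target = build_transactions(read_gaf(io.StringIO(gaf)), toy_graph)
        d = level_distribution(target, toy_graph)
        shape = [1] * 2000
        by_ont = gen_random_by_ontology(toy_graph, d, shape, seed=11)
        uni = gen_uniform_random(toy_graph, shape, seed=11)
        assert level_gof_pvalue(by_ont, toy_graph, d) > 0.01
        assert level_gof_pvalue(uni, toy_graph, d) < 0.01


class TestFdrTable:
    def test_values_nonnegative_and_zero_without_rules(self, chains_graph):
        target = transactions(
            {f"g{i}": {M2, B2} for i in range(6)} | {"g9": {C0}}, chains_graph
        )
        # thresholds nothing can meet -> R_i = 0 at every level -> fdr 0
        strict = MiningConfig(min_support=1.0, min_confidence=1.0,
                              p_threshold=1e-12)
        table = fdr_table(chains_graph, target, strict, generator="replacement",
                          n_datasets=2, seed=30)
        assert (table.fdr.values >= 0).all()
        assert (table.fdr.values == 0).all()

    def test_single_replicate_deterministic(self, chains_graph):
        target = transactions(
            {f"g{i}": {M2, B2} for i in range(6)} | {"g9": {C0}}, chains_graph
        )
        cfg = MiningConfig(0.1, 0.5, 1.0)
        t1 = fdr_table(chains_graph, target, cfg, generator="replacement",
                       n_datasets=1, seed=9)
        t2 = fdr_table(chains_graph, target, cfg, generator="replacement",
                       n_datasets=1, seed=9)
        pd.testing.assert_frame_equal(t1.fdr, t2.fdr)

    def test_averaging_is_linear(self, chains_graph):
        target = transactions(
            {f"g{i}": {M2, B2} for i in range(6)} | {"g9": {C0}}, chains_graph
        )
        cfg = MiningConfig(0.1, 0.5, 1.0)
        combined = fdr_table(chains_graph, target, cfg, generator="replacement",
                             n_datasets=4, seed=20)
        singles = [
            fdr_table(chains_graph, target, cfg, generator="replacement",
                      n_datasets=1, seed=20 + i).fdr
            for i in range(4)
        ]
        mean = sum(
            s.reindex(combined.fdr.index).fillna(0.0) for s in singles
        ) / 4
        pd.testing.assert_frame_equal(combined.fdr, mean)


class TestTerminationLevels:
    def test_crossing_selects_level_above(self):
        df = pd.DataFrame(
            {"mf_cc": [0.0, 0.0, 0.05, 0.2],
             "bp_mf": [0.0, 0.0, 0.0, 0.0],
             "cc_bp": [0.0, 0.01, 0.0, 0.3]},
            index=[6, 5, 4, 3],
        )
        t = termination_levels(FDRTable(fdr=df, n_datasets=1), threshold=0.01)
        assert t.mf_cc == 5     # first crossing at 4 -> one level deeper
        assert t.bp_mf == 3     # never crosses -> shallowest level
        assert t.cc_bp == 6     # value exactly at threshold crosses (>=)
        assert t.minlevel == 3

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            termination_levels(FDRTable(fdr=pd.DataFrame(), n_datasets=0))

    def test_huge_threshold_gives_shallowest_level(self):
        df = pd.DataFrame({"mf_cc": [5.0, 9.0], "bp_mf": [1.0, 2.0],
                           "cc_bp": [0.5, 3.0]}, index=[4, 3])
        t = termination_levels(FDRTable(fdr=df, n_datasets=1), threshold=1e9)
        assert (t.mf_cc, t.bp_mf, t.cc_bp) == (3, 3, 3)
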