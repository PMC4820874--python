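from __future__ import annotations

import math
import random
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phenosim as ps
from oracles import hypergeom_tail_fraction


class TestReadGmt:
    def test_two_line_gmt(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tGENEA\tGENEB\nS2\tdesc\tGENEC\n")
        coll = ps.read_gmt(p)
        assert set(coll.sets) == {"S1", "S2"}
        assert coll.sets["S1"] == {"GENEA", "GENEB"}

    def test_duplicate_gene_within_set_counted_once(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tGENEA\tgenea\tGENEB\n")
        assert len(ps.read_gmt(p).sets["S1"]) == 2

    def test_short_line_error_names_line(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tGENEA\nS2\tonlytwo\n")
        with pytest.raises(ValueError, match="line 2"):
            ps.read_gmt(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("")
        with pytest.raises(ValueError):
            ps.read_gmt(p)


class TestFisherEnrichment:
    def test_no_overlap_is_never_significant(self):
        universe = {f"G{i}" for i in range(10)}
        r = ps.fisher_enrichment({"G0", "G1"}, {"G8", "G9"}, universe)
        assert r.p_value == 1.0
        assert r.table == (0, 2, 2, 6)

    def test_set_equal_seeds_equal_universe(self):
        uni = {"A", "B", "C"}
        assert ps.fisher_enrichment(uni, uni, uni).p_value == 1.0

    def test_exact_combinatorial_value(self):
        # M=20, K=5, n=5, k=4: sum_{i>=4} C(5,i) C(15,5-i) / C(20,5)
        universe = {f"G{i}" for i in range(20)}
        gene_set = {f"G{i}" for i in range(5)}
        seeds = {f"G{i}" for i in range(4)} | {"G10"}
        expected = sum(
            Fraction(math.comb(5, i) * math.comb(15, 5 - i), math.comb(20, 5))
            for i in range(4, 6)
        )
        r = ps.fisher_enrichment(gene_set, seeds, universe)
        assert r.p_value == pytest.approx(float(expected), abs=1e-15)

    def test_genes_outside_universe_dropped(self, caplog):
        universe = {"A", "B", "C", "D"}
        with caplog.at_level("WARNING"):
            r = ps.fisher_enrichment({"A", "ZZ"}, {"A", "B"}, universe)
        assert r.table[0] + r.table[1] == 1  # ZZ was dropped from the set
        assert "ZZ" in caplog.text

    @pytest.mark.parametrize(
        "gene_set, seeds, universe",
        [(set(), {"A"}, set()), ({"A"}, set(), {"A", "B"}), ({"A"}, {"Z"}, {"A", "B"})],
    )
    def test_degenerate_inputs_rejected(self, gene_set, seeds, universe):
        with pytest.raises(ValueError):
            ps.fisher_enrichment(gene_set, seeds, universe)

    @given(st.integers(0, 400))
    def test_tail_matches_exact_oracle(self, seed):
        rng = random.Random(seed)
        M = rng.randint(2, 60)
        K = rng.randint(0, M)
        n = rng.randint(1, M)
        k = rng.randint(max(0, K + n - M), min(K, n))
        assert ps.hypergeometric_tail(k, M, K, n) == pytest.approx(
            float(hypergeom_tail_fraction(k, M, K, n)), abs=1e-12
        )

    @given(st.integers(0, 200))
    def test_p_monotone_nonincreasing_in_k(self, seed):
        rng = random.Random(seed)
        M = rng.randint(4, 50)
        K = rng.randint(1, M)
        n = rng.randint(1, M)
        ps_ = [
            ps.hypergeometric_tail(k, M, K, n)
            for k in range(max(0, K + n - M), min(K, n) + 1)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(ps_, ps_[1:]))

    @given(st.integers(0, 100))
    def test_unrelated_universe_gene_changes_p_only_through_M(self, seed):
        rng = random.Random(seed)
        universe = {f"G{i}" for i in range(rng.randint(4, 30))}
        genes = sorted(universe)
        gene_set = set(rng.sample(genes, rng.randint(1, len(genes) // 2)))
        seeds = set(rng.sample(genes, rng.randint(1, len(genes) // 2)))
        r1 = ps.fisher_enrichment(gene_set, seeds, universe)
        r2 = ps.fisher_enrichment(gene_set, seeds, universe | {"UNRELATED"})
        assert r2.table[0] == r1.table[0]  # k unchanged
        expected = float(
            hypergeom_tail_fraction(
                r1.table[0], len(universe) + 1, len(gene_set), len(seeds)
            )
        )
        assert r2.p_value == pytest.approx(expected, abs=1e-12)


class TestPpiFeature:
    def test_seed_adjacent_gene_beats_distant_gene(self, toy_network):
        seeds = {"S1", "S2", "S3", "S4"}
        p_cand = ps.ppi_feature(toy_network, seeds, "CAND")
        p_far = ps.ppi_feature(toy_network, seeds, "FAR")
        assert p_cand < p_far
        # oracle: CAND has 3 neighbors, all seeds, in a 12-node universe
        expected = float(hypergeom_tail_fraction(3, 12, 3, 4))
        assert p_cand == pytest.approx(expected, abs=1e-12)

    def test_isolated_gene_gets_p_one(self, toy_network):
        assert ps.ppi_feature(toy_network, {"S1"}, "LONER") == 1.0

    def test_absent_gene_gets_p_one(self, toy_network):
        assert ps.ppi_feature(toy_network, {"S1"}, "NOT_A_GENE") == 1.0

    def test_seeds_covering_whole_network_uninformative(self, toy_network):
        seeds = set(toy_network.nodes)
        assert ps.ppi_feature(toy_network, seeds, "CAND") == 1.0


class TestCollectionGsea:
    def test_set_equal_to_seeds_ranked_first(self):
        coll = ps.GeneSetCollection(
            "c",
            {
                "HIT": frozenset({"A", "B"}),
                "MISS": frozenset({"X", "Y", "Z"}),
                "PART": frozenset({"A", "X"}),
            },
        )
        universe = {"A", "B", "X", "Y", "Z", "W"}
        results = ps.collection_gsea(coll, {"A", "B"}, universe)
        assert results[0].set_id == "HIT"
        assert results[0].p_value < results[-1].p_value

    def test_disjoint_sets_all_p_one_sorted_by_id(self):
        coll = ps.GeneSetCollection(
            "c", {"B_SET": frozenset({"X"}), "A_SET": frozenset({"Y"})}
        )
        results = ps.collection_gsea(coll, {"A"}, {"A", "X", "Y"})
        assert [r.set_id for r in results] == ["A_SET", "B_SET"]
        assert all(r.p_value == 1.0 for r in results)

    def test_gene_feature_is_minimum_over_membership(self):
        coll = ps.GeneSetCollection(
            "c", {"S1": frozenset({"A"}), "S2": frozenset({"A", "B"})}
        )
        results = [
            ps.EnrichmentResult("S1", 0.3, (0, 0, 0, 0)),
            ps.EnrichmentResult("S2", 0.01, (0, 0, 0, 0)),
        ]
        assert ps.gene_collection_feature(results, coll, "A") == 0.01
        assert ps.gene_collection_feature(results, coll, "B") == 0.01
        assert ps.gene_collection_feature(results, coll, "ZZ") == 1.0


class TestFeatureMatrix:
    def _collections(self, n=7):
        return [
            ps.GeneSetCollection(
                f"coll{i}", {f"SET{i}": frozenset({"S1", "S2", "CAND"})}
            )
            for i in range(n)
        ]

    def test_unknown_gene_row_is_all_ones(self, toy_network):
        fm = ps.build_feature_matrix(
            toy_network, self._collections(), {"S1", "S2"}, ["NOWHERE"]
        )
        assert np.allclose(fm.row("NOWHERE"), 1.0)

    def test_transform_neg_log10(self, toy_network):
        fm = ps.build_feature_matrix(
            toy_network, self._collections(), {"S1", "S2"}, ["CAND"],
            transform="neg_log10_p",
        )
        assert np.allclose(fm.values(), np.minimum(-np.log10(fm.pvalues), 300))
        assert fm.values().shape[1] == 8

    def test_matrix_matches_entrywise_oracle(self, toy_network):
        # 3 collections of 2 sets; remaining features padded at p=1
        rng = random.Random(1)
        nodes = sorted(toy_network.nodes)
        colls = []
        for i in range(3):
            colls.append(
                ps.GeneSetCollection(
                    f"c{i}",
                    {
                        f"c{i}s{j}": frozenset(rng.sample(nodes, rng.randint(2, 6)))
                        for j in range(2)
                    },
                )
            )
        seeds = {"S1", "S2", "S3"}
        candidates = ["CAND", "FAR", "B1", "LONER"]
        fm = ps.build_feature_matrix(
            toy_network, colls, seeds, candidates, allow_fewer_collections=True
        )
        for gene in candidates:
            row = fm.row(gene)
            assert row[0] == pytest.approx(
                ps.ppi_feature(toy_network, seeds, gene), abs=1e-15
            )
            for ci, coll in enumerate(colls):
                universe = coll.all_genes() | seeds
                expected = min(
                    (
                        ps.fisher_enrichment(genes, seeds, universe).p_value
                        for sid, genes in coll.sets.items()
                        if gene in genes
                    ),
                    default=1.0,
                )
                assert row[1 + ci] == pytest.approx(expected, abs=1e-15)
            assert np.allclose(row[4:], 1.0)

    def test_duplicate_candidates_collapsed(self, toy_network, caplog):
        with caplog.at_level("WARNING"):
            fm = ps.build_feature_matrix(
                toy_network, self._collections(), {"S1"}, ["CAND", "cand", "FAR"]
            )
        assert fm.genes == ["CAND", "FAR"]

    def test_fewer_collections_require_explicit_flag(self, toy_network):
        with pytest.raises(ValueError, match="collections"):
            ps.build_feature_matrix(toy_network, self._collections(3), {"S1"}, ["CAND"])

    def test_tsv_round_trip(self, toy_network, tmp_path):
        fm = ps.build_feature_matrix(
            toy_network, self._collections(), {"S1", "S2"}, ["CAND", "FAR"]
        )
        p = tmp_path / "features.tsv"
        fm.to_tsv(p)
        back = ps.FeatureMatrix.from_tsv(p)
        assert back.genes == fm.genes
        assert np.allclose(back.pvalues, fm.pvalues, atol=1e-10)
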