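"""Regulatory network: edge screens, NES enrichment, triples, PageRank."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mc3net import grn


class TestFinalScore:
    def test_fixed_point(self):
        assert grn.final_score(0.5, 0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_fourth_root_arithmetic(self):
        assert grn.final_score(0.9, 0.1, 0.9, 0.9) == pytest.approx(0.5196, abs=1e-4)

    def test_permutation_invariant_and_bounded(self, rng):
        vals = rng.uniform(-1, 1, 4)
        scores = {grn.final_score(*perm) for perm in itertools.permutations(vals)}
        assert len({round(s, 12) for s in scores}) == 1
        assert grn.final_score(*vals) <= max(abs(v) for v in vals) + 1e-12


class TestClassifyTriple:
    @pytest.mark.parametrize(
        "signs, expected",
        [
            ((1, 1, 1), "Model 1"),
            ((1, -1, -1), "Model 2"),
            ((-1, -1, 1), "Model 3"),
            ((-1, 1, -1), "Model 4"),
        ],
    )
    def test_four_models(self, signs, expected):
        sa, sb, sc = (0.5 * s for s in signs)
        assert grn.classify_triple(sa, sb, sc) == expected

    def test_sign_inconsistent_combinations_unknown(self):
        # models 1-4 are exactly the sign patterns with product +1
        for signs in itertools.product((1, -1), repeat=3):
            cls = grn.classify_triple(*(0.5 * s for s in signs))
            if signs[0] * signs[1] * signs[2] == 1:
                assert cls.startswith("Model")
            else:
                assert cls == "Unknown"

    def test_zero_correlation_unknown(self):
        assert grn.classify_triple(0.0, 0.5, 0.5) == "Unknown"


class TestMotifEnrichment:
    def _scores(self, rng, n_dmrs=100, n_motifs=20):
        return pd.DataFrame(
            rng.exponential(1.0, size=(n_dmrs, n_motifs)),
            index=[f"d{i}" for i in range(n_dmrs)],
            columns=[f"m{j}" for j in range(n_motifs)],
        )

    def test_perfect_motif_has_highest_nes(self, rng):
        scores = self._scores(rng)
        query = [f"d{i}" for i in range(5)]
        scores.loc[query, "m0"] = 100.0  # top ranks are exactly the query
        res = grn.motif_enrichment_nes(scores, query, rank_fraction=0.3)
        by_nes = sorted(res, key=lambda r: -r.nes)
        assert by_nes[0].motif == "m0"
        assert set(by_nes[0].leading_edge) == set(query)

    def test_decoy_nes_standardized(self, rng):
        scores = self._scores(rng, n_dmrs=200, n_motifs=60)
        query = [f"d{i}" for i in range(0, 40)]
        res = grn.motif_enrichment_nes(scores, query, rank_fraction=0.3)
        nes = np.array([r.nes for r in res])
        assert abs(nes.mean()) < 1e-9 and nes.std() == pytest.approx(1.0)

    def test_leading_edge_subset_of_query(self, rng):
        scores = self._scores(rng)
        query = [f"d{i}" for i in range(10, 30)]
        for r in grn.motif_enrichment_nes(scores, query, rank_fraction=0.5):
            assert set(r.leading_edge) <= set(query)

    def test_small_collection_rejected(self, rng):
        with pytest.raises(ValueError):
            grn.motif_enrichment_nes(self._scores(rng, n_motifs=5), ["d0"])

    def test_empty_query_rejected(self, rng):
        with pytest.raises(ValueError):
            grn.motif_enrichment_nes(self._scores(rng), ["nope"])


class TestEdgesOnPlantedData:
    @pytest.fixture(scope="class")
    def screens(self, small_genome, small_truth):
        from mc3net.synthetic import simulate_motif_db

        methylome, truth = small_truth
        db = simulate_motif_db(small_genome, truth, n_decoy_motifs=30, seed=3)
        tf_ids = [g.id for g in small_genome.tf_genes()]
        tt = grn.tf_target_edges(methylome.gene_mch, tf_ids, q_max=2.0, n_shuffles=300, seed=4)
        td = grn.tf_dmr_edges(
            methylome.gene_mch, tf_ids, methylome.dmr_mcg, db, q_max=0.05,
            nes_min=3.0, n_shuffles=300, seed=5,
        )
        return methylome, truth, tt, td

    def test_self_pairs_excluded(self, screens):
        _, _, tt, _ = screens
        assert not (tt["tf"] == tt["gene"]).any()

    def test_planted_pairs_have_extreme_correlations(self, screens):
        # 6 subclasses cannot reach FDR 1e-3, but the planted Sc values
        # must sit at the intended sign and magnitude
        _, truth, tt, _ = screens
        tt = tt.set_index(["tf", "gene"])
        for t in truth.triples:
            sc = tt.loc[(t.tf_id, t.gene_id), "sc"]
            assert np.sign(sc) == t.signs[2]
            assert abs(sc) > 0.6

    def test_tf_dmr_edges_exceed_nes_cutoff_strictly(self, screens):
        _, truth, _, td = screens
        for r in td.itertuples():
            assert r.nes > 3.0

    def test_unreachable_nes_cutoff_yields_no_edges(self, small_genome, small_truth):
        from mc3net.synthetic import simulate_motif_db

        methylome, truth = small_truth
        db = simulate_motif_db(small_genome, truth, n_decoy_motifs=30, seed=3)
        tf_ids = [g.id for g in small_genome.tf_genes()]
        td = grn.tf_dmr_edges(
            methylome.gene_mch, tf_ids, methylome.dmr_mcg, db, q_max=0.05,
            nes_min=1e9, n_shuffles=100, seed=5,
        )
        assert len(td) == 0


class TestAssembleTriples:
    def _edges(self):
        dt = pd.DataFrame(
            {"dmr": ["d1"], "gene": ["g1"], "sa": [0.9], "p": [1e-5], "q": [1e-4],
             "sd": [0.8], "bin_i": [5], "bin_j": [20]}
        )
        tt = pd.DataFrame({"tf": ["f1"], "gene": ["g1"], "sc": [0.9], "p": [1e-5], "q": [1e-4]})
        td = pd.DataFrame(
            {"tf": ["f1"], "dmr": ["d1"], "sb": [0.1], "p": [1e-3], "q": [1e-3],
             "motif": ["m"], "nes": [4.0], "sign": ["positive"]}
        )
        return dt, tt, td

    def test_intersection_and_score(self):
        dt, tt, td = self._edges()
        out = grn.assemble_triples(dt, tt, td)
        assert len(out) == 1
        r = out.iloc[0]
        assert r["s_all"] == pytest.approx((0.9 * 0.1 * 0.9 * 0.8) ** 0.25)
        assert r["model"] == "Model 1"

    def test_missing_edge_no_triple(self):
        dt, tt, td = self._edges()
        td = td.iloc[0:0]
        assert len(grn.assemble_triples(dt, tt, td)) == 0

    def test_mismatched_gene_no_triple(self):
        dt, tt, td = self._edges()
        tt.loc[0, "gene"] = "other"
        assert len(grn.assemble_triples(dt, tt, td)) == 0


class TestPageRank:
    def test_inverted_weight_formula(self):
        # scaled values (0.2, 0.8, 0.5) -> W = (1, 0, 0.5)
        x = np.array([0.2, 0.8, 0.5])
        mx, mn = x.max(), x.min()
        np.testing.assert_allclose((mx - x) / (mx - mn), [1.0, 0.0, 0.5])

    def test_inverted_weights_in_unit_interval(self, rng):
        m = pd.DataFrame(rng.random((20, 6)), columns=[f"s{i}" for i in range(6)])
        W = grn.inverted_weights(m)
        assert W.to_numpy().min() >= 0 and W.to_numpy().max() <= 1

    def test_uniform_toy_graph_matches_unweighted_pagerank(self, rng):
        triples = pd.DataFrame(
            {
                "tf": ["f1", "f1", "f2"],
                "gene": ["g1", "g2", "g1"],
                "dmr": ["d1", "d2", "d3"],
                "s_all": [1.0, 1.0, 1.0],
            }
        )
        subclasses = ["a", "b", "c"]
        gene_mch = pd.DataFrame(
            rng.random((4, 3)), index=["f1", "f2", "g1", "g2"], columns=subclasses
        )
        dmr_mcg = pd.DataFrame(
            rng.random((3, 3)), index=["d1", "d2", "d3"], columns=subclasses
        )
        res = grn.pagerank_scores(triples, gene_mch, dmr_mcg)
        raw = res["raw"]
        # per-subclass scores are probability distributions
        np.testing.assert_allclose(raw.sum(axis=0), 1.0)
        assert (raw.to_numpy() >= 0).all()
        # independent reference: networkx on the equivalently weighted graph
        V = grn.inverted_weights(dmr_mcg)
        W = grn.inverted_weights(gene_mch)
        s = subclasses[0]
        G = nx.DiGraph()
        G.add_nodes_from(raw.index)
        for r in triples.itertuples():
            G.add_edge(r.gene, r.tf, weight=float(r.s_all * V.loc[r.dmr, s]))
        pers = {n: float(W.loc[n, s]) for n in raw.index}
        ref = nx.pagerank(G, alpha=0.85, personalization=pers, weight="weight", tol=1e-9)
        for n in raw.index:
            assert raw.loc[n, s] == pytest.approx(ref[n], abs=1e-6)

    def test_normalized_scores_minmax_per_node(self, rng):
        triples = pd.DataFrame(
            {"tf": ["f1", "f2"], "gene": ["g1", "g1"], "dmr": ["d1", "d2"], "s_all": [0.7, 0.5]}
        )
        gene_mch = pd.DataFrame(rng.random((3, 4)), index=["f1", "f2", "g1"], columns=list("abcd"))
        dmr_mcg = pd.DataFrame(rng.random((2, 4)), index=["d1", "d2"], columns=list("abcd"))
        res = grn.pagerank_scores(triples, gene_mch, dmr_mcg)
        norm = res["normalized"]
        assert norm.to_numpy().min() >= 0 and norm.to_numpy().max() <= 1
        varying = res["raw"].std(axis=1) > 0
        np.testing.assert_allclose(norm.loc[varying].max(axis=1), 1.0)
        np.testing.assert_allclose(norm.loc[varying].min(axis=1), 0.0)

    def test_empty_triples_rejected(self):
        with pytest.raises(ValueError):
            grn.pagerank_scores(pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
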