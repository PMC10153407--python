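"""TopDom boundary calls, probability tracks, differential tests."""

import numpy as np
import pandas as pd
import pytest

from mc3net import boundaries as bnd
from mc3net import workflow


def _two_block_matrix(n=30, junction=15, within=1.0, between=0.0, noise=0.0, rng=None):
    M = np.full((n, n), between)
    M[:junction, :junction] = within
    M[junction:, junction:] = within
    if rng is not None and noise:
        M = M + noise * rng.random((n, n))
        M = (M + M.T) / 2
    return M


class TestTopDom:
    def test_two_block_matrix_single_boundary_at_junction(self, rng):
        M = _two_block_matrix(noise=0.05, rng=rng)
        calls = bnd.topdom_boundaries(M, w=5)
        called = np.flatnonzero(calls)
        assert len(called) == 1
        assert called[0] == 14  # binSignal minimum spans the 14|15 junction

    def test_uniform_banded_matrix_no_boundaries(self):
        n = 40
        idx = np.arange(n)
        M = (np.abs(idx[:, None] - idx[None, :]) <= 6).astype(float)
        assert not bnd.topdom_boundaries(M, w=5).any()

    def test_blacklisted_minimum_suppressed(self, rng):
        M = _two_block_matrix(noise=0.05, rng=rng)
        mask = np.zeros(30, dtype=bool)
        mask[13:17] = True
        assert not bnd.topdom_boundaries(M, w=5, blacklist_mask=mask).any()

    def test_scale_invariant(self, rng):
        M = _two_block_matrix(noise=0.05, rng=rng)
        np.testing.assert_array_equal(
            bnd.topdom_boundaries(M, w=5), bnd.topdom_boundaries(10.0 * M, w=5)
        )

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            bnd.topdom_boundaries(np.ones((6, 6)), w=5)


class TestBoundaryProbability:
    def test_fraction_of_calling_cells(self):
        calls = np.zeros((10, 4), dtype=bool)
        calls[:3, 1] = True
        track = bnd.boundary_probability(calls, ["g"] * 10)
        assert track.prob.loc["g", 1] == pytest.approx(0.3)

    def test_all_cells_call_gives_one(self):
        calls = np.ones((5, 2), dtype=bool)
        track = bnd.boundary_probability(calls, ["g"] * 5)
        assert (track.prob.to_numpy() == 1.0).all()

    def test_invariant_to_duplicating_cells(self, rng):
        calls = rng.random((8, 6)) < 0.4
        labels = ["a"] * 4 + ["b"] * 4
        t1 = bnd.boundary_probability(calls, labels)
        t2 = bnd.boundary_probability(np.vstack([calls, calls]), labels * 2)
        np.testing.assert_allclose(t1.prob.to_numpy(), t2.prob.to_numpy())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bnd.boundary_probability(np.ones((0, 3), dtype=bool), [])


class TestDifferentialBoundaryTest:
    def test_two_by_two_chi_square_by_hand(self):
        # table [[10, 90], [30, 70]] -> N(ad-bc)^2/(r1 r2 c1 c2) = 12.5
        calls = np.zeros((200, 1), dtype=bool)
        calls[:10, 0] = True
        calls[100:130, 0] = True
        labels = ["a"] * 100 + ["b"] * 100
        res = bnd.differential_boundary_test(calls, labels)
        assert res.loc[0, "chi2"] == pytest.approx(12.5)

    def test_identical_proportions_give_zero(self):
        calls = np.zeros((40, 1), dtype=bool)
        calls[:5, 0] = True
        calls[20:25, 0] = True
        res = bnd.differential_boundary_test(calls, ["a"] * 20 + ["b"] * 20)
        assert res.loc[0, "chi2"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_planted_differential_boundaries_rank_top(self, small_truth, small_features):
        # few cells per subclass: check ranking by chi-square rather than
        # the full-scale FDR cut (exercised at scale in the acceptance suite)
        _, truth = small_truth
        res = bnd.differential_boundary_test(small_features.calls25, small_features.labels)
        planted = truth.differential_boundary_bins("chr1")
        top = set(res.nlargest(4 * len(planted), "chi2")["bin"].tolist())
        hits = sum(any(b + o in top for o in (-1, 0, 1)) for b in planted)
        assert hits / len(planted) >= 0.8

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bnd.differential_boundary_test(np.ones((4, 2), dtype=bool), ["a"] * 4)


class TestCollapseTranscripts:
    def test_high_overlap_pair_collapses_to_union(self):
        recs = [
            ("t1", "g", "chr1", 1000, 10_000, "+"),
            ("t2", "g", "chr1", 1200, 10_400, "+"),  # 95% of the shorter
        ]
        out = bnd.collapse_transcripts(recs)
        assert len(out) == 1
        assert (out[0][3], out[0][4]) == (1000, 10_400)

    def test_low_overlap_kept_separate(self):
        recs = [
            ("t1", "g", "chr1", 1000, 10_000, "+"),
            ("t2", "g", "chr1", 8000, 30_000, "+"),
        ]
        assert len(bnd.collapse_transcripts(recs)) == 2

    def test_different_genes_never_merge(self):
        recs = [
            ("t1", "g1", "chr1", 1000, 10_000, "+"),
            ("t2", "g2", "chr1", 1000, 10_000, "-"),
        ]
        assert len(bnd.collapse_transcripts(recs)) == 2


class TestTranscriptBoundaryCorrelation:
    def test_window_excludes_distant_bins(self, rng):
        mc = pd.DataFrame(
            rng.normal(size=(3, 6)), index=["t1", "t2", "t3"], columns=[f"s{i}" for i in range(6)]
        )
        prob = pd.DataFrame(
            rng.random((6, 400)), index=mc.columns
        )
        track = bnd.BoundaryProbabilityTrack(prob=prob, n_cells=pd.Series(5, index=mc.columns))
        recs = [("t1", "t1", "chr1", 4_000_000, 4_100_000, "+")]
        res = bnd.transcript_boundary_correlation(
            mc, track, recs, variable_bins=np.array([100, 164, 200, 245, 300]), chrom="chr1",
            n_shuffles=50, seed=0,
        )
        # 2 Mb window at 25 kb: bins 80..244 qualify; 245 and 300 do not
        assert set(res["bin"]) == {100, 164, 200}

    def test_planted_tss_boundary_coupling_negative(self, small_genome, small_truth, small_features):
        # probe the planted coupled bins directly (the chi-square gate is
        # exercised at full scale in the acceptance suite)
        methylome, truth = small_truth
        if not truth.boundary_couplings:
            pytest.skip("no boundary coupling planted in this draw")
        track = bnd.boundary_probability(small_features.calls25, small_features.labels)
        recs = workflow.transcript_records(small_genome)
        coupled_bins = np.array([bc.bin25 for bc in truth.boundary_couplings])
        corr = bnd.transcript_boundary_correlation(
            methylome.gene_mch, track, recs, coupled_bins, "chr1", n_shuffles=200, seed=1
        )
        corr = corr.set_index(["transcript", "bin"])
        found = 0
        for bc in truth.boundary_couplings:
            key = (bc.gene_id, bc.bin25)
            if key in corr.index:
                found += 1
                assert corr.loc[key, "pcc"] < -0.5
        assert found >= 1

    def test_no_variable_bins_no_records(self, rng):
        mc = pd.DataFrame(rng.normal(size=(1, 4)), index=["t1"], columns=list("abcd"))
        prob = pd.DataFrame(rng.random((4, 50)), index=list("abcd"))
        track = bnd.BoundaryProbabilityTrack(prob=prob, n_cells=pd.Series(3, index=list("abcd")))
        res = bnd.transcript_boundary_correlation(
            mc, track, [("t1", "t1", "chr1", 0, 100_000, "+")], np.array([]), "chr1", n_shuffles=10
        )
        assert len(res) == 0


def test_boundary_probability_elevated_at_long_gene_ends(small_genome, small_truth, small_features):
    """Planted gene-body domains put boundary probability peaks at the
    TSS/TTS of long genes relative to the genomic background."""
    _, truth = small_truth
    track = bnd.boundary_probability(small_features.calls25, small_features.labels)
    mean_prob = track.prob.mean(axis=0).to_numpy()
    boundary_bins = sorted({b for _, b, _ in truth.boundary_presence})
    long_end_bins = set()
    for g in small_genome.genes:
        if g.is_long:
            long_end_bins.update((g.tss // 25_000, g.tts // 25_000))
    at_gene = [b for b in boundary_bins if any(abs(b - e) <= 1 for e in long_end_bins)]
    if not at_gene:
        pytest.skip("no planted boundary at a long-gene end in this draw")
    background = np.delete(mean_prob, [x for b in boundary_bins for x in (b - 1, b, b + 1)])
    assert mean_prob[at_gene].mean() > 3 * background.mean()
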