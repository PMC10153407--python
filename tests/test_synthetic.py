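"""The planted-truth generator: determinism, invariants, planted effects."""

import numpy as np
import pytest
from scipy import stats as sps

from mc3net.synthetic import (
    GenomeConfig,
    TruthConfig,
    simulate_base_counts,
    simulate_contact_cells,
    simulate_genome,
    simulate_methylomes,
    simulate_motif_db,
)
from mc3net.synthetic.cells import expected_pixel_rates


class TestGenome:
    def test_bin_count_is_ceiling_of_length_over_resolution(self, small_genome):
        assert small_genome.n_bins("chr1", 10_000) == 800
        g = simulate_genome(GenomeConfig(chromosomes=(("chrX", 20_000_000),)), seed=0)
        assert g.n_bins("chrX", 10_000) == 2000

    def test_deterministic_for_seed(self):
        cfg = GenomeConfig()
        g1 = simulate_genome(cfg, seed=5)
        g2 = simulate_genome(cfg, seed=5)
        assert [(x.id, x.start, x.end, x.strand, x.is_tf) for x in g1.genes] == [
            (x.id, x.start, x.end, x.strand, x.is_tf) for x in g2.genes
        ]
        np.testing.assert_array_equal(g1.cpg_density["chr1"], g2.cpg_density["chr1"])

    def test_long_gene_flag_above_100kb(self, small_genome):
        for g in small_genome.genes:
            assert g.is_long == (g.end - g.start > 100_000)
        assert any(g.is_long for g in small_genome.genes)

    def test_gene_intervals_within_chromosome(self, small_genome):
        for g in small_genome.genes:
            assert 0 <= g.start < g.end <= small_genome.chrom_length(g.chrom)

    def test_every_motif_maps_to_a_tf(self, small_genome):
        tf_ids = {g.id for g in small_genome.tf_genes()}
        assert small_genome.motifs
        for m in small_genome.motifs:
            assert set(m.tfs) & tf_ids

    def test_empty_configuration_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(GenomeConfig(chromosomes=()), seed=0)
        with pytest.raises(ValueError):
            simulate_genome(GenomeConfig(n_genes=0), seed=0)


class TestMethylome:
    def test_truth_invariants(self, small_genome, small_truth):
        _, truth = small_truth
        truth.validate(small_genome)

    def test_fractions_in_unit_interval(self, small_truth):
        methylome, _ = small_truth
        for frame in (methylome.gene_mch, methylome.bin_mcg, methylome.dmr_mcg):
            v = frame.to_numpy()
            assert v.min() >= 0 and v.max() <= 1

    def test_master_gene_mch_minimal_in_hub_subclass(self, small_truth):
        # planted "active in subclass s" forces the latent mCH minimum at s
        _, truth = small_truth
        for tf, s in truth.master_tfs.items():
            profile = truth.latent_gene_mch.loc[tf]
            assert profile.idxmin() == s

    def test_high_coverage_fraction_converges_to_latent(self, small_genome):
        cfg = TruthConfig(gene_mch_cov=100_000, dmr_cov=100_000)
        methylome, truth = simulate_methylomes(small_genome, cfg, n_subclasses=4, seed=3)
        np.testing.assert_allclose(
            methylome.gene_mch.to_numpy(), truth.latent_gene_mch.to_numpy(), atol=0.01
        )

    def test_flat_latent_variance_matches_binomial_sampling(self):
        # all-equal latent activities: between-subclass variance of the
        # sampled fraction equals p(1-p)/coverage
        rng = np.random.default_rng(0)
        p, cov, n = 0.3, 200, 1000
        frac = rng.binomial(cov, p, size=(n, 6)) / cov
        observed = frac.var(axis=1, ddof=1).mean()
        expected = p * (1 - p) / cov
        assert observed == pytest.approx(expected, rel=0.1)

    def test_single_subclass_rejected(self, small_genome):
        with pytest.raises(ValueError):
            simulate_methylomes(small_genome, TruthConfig(), n_subclasses=1, seed=0)


class TestContactCells:
    def test_pairs_are_cis_and_in_bounds(self, small_genome, small_cells):
        L = small_genome.chrom_length("chr1")
        for cell in small_cells:
            assert set(cell.pairs) <= {"chr1"}
            a, b = cell.pairs["chr1"]
            assert a.min() >= 0 and b.min() >= 0 and max(a.max(), b.max()) < L

    def test_contact_count_fixed_per_cell(self, small_cells):
        assert {c.n_contacts for c in small_cells} == {40_000}

    def test_loop_pixel_exceeds_distance_matched_background(self, small_genome, small_truth, small_cells):
        _, truth = small_truth
        loops = [l for l in truth.loops if np.ptp(l.enrichment) > 0]
        loop = loops[0]
        s = truth.subclasses[int(np.argmax(loop.enrichment))]
        counts, bg = [], []
        d = loop.bin_j - loop.bin_i
        for cell in small_cells:
            if cell.subclass != s:
                continue
            a, b = cell.pairs["chr1"]
            bi, bj = a // 10_000, b // 10_000
            lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
            counts.append(int(((lo == loop.bin_i) & (hi == loop.bin_j)).sum()))
            same_d = (hi - lo) == d
            bg.append(same_d.sum() / max(small_genome.n_bins("chr1", 10_000) - d, 1))
        assert np.mean(counts) > 2 * np.mean(bg)

    def test_expected_rate_table_matches_raw_counts(self, small_genome, small_truth, small_cells):
        # the generator's own rate table is the oracle for pixel means
        _, truth = small_truth
        s = truth.subclasses[0]
        rows, cols, w = expected_pixel_rates(small_genome, truth, s, "chr1")
        p = w / w.sum()
        top = np.argsort(p)[-5:]
        cells = [c for c in small_cells if c.subclass == s]
        n_contacts = sum(c.n_contacts for c in cells)
        n_bins = small_genome.n_bins("chr1", 10_000)
        for k in top:
            observed = 0
            for c in cells:
                a, b = c.pairs["chr1"]
                bi, bj = a // 10_000, b // 10_000
                lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
                observed += int(((lo == rows[k]) & (hi == cols[k])).sum())
            expected = n_contacts * p[k]
            assert observed == pytest.approx(expected, abs=4 * np.sqrt(expected) + 3)

    def test_null_configuration_counts_exchangeable_at_fixed_distance(self):
        from mc3net.synthetic import null_config

        gcfg, tcfg = null_config(chrom_mb=5)
        genome = simulate_genome(gcfg, seed=1)
        _, truth = simulate_methylomes(genome, tcfg, n_subclasses=2, seed=2)
        cells = simulate_contact_cells(genome, truth, 10, 50_000, seed=3, compartment_delta=0.0)
        d = 20
        n = genome.n_bins("chr1", 10_000)
        counts = np.zeros(n - d)
        for c in cells:
            a, b = c.pairs["chr1"]
            bi, bj = a // 10_000, b // 10_000
            lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
            sel = (hi - lo) == d
            counts += np.bincount(lo[sel], minlength=n - d)[: n - d]
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = sps.chi2.sf(chi2, df=counts.size - 1)
        assert p > 0.01

    def test_unknown_subclass_rejected(self, small_genome, small_truth):
        _, truth = small_truth
        with pytest.raises(ValueError):
            simulate_contact_cells(small_genome, truth, 1, 1000, subclasses=["nope"])

    def test_too_few_contacts_rejected(self, small_genome, small_truth):
        _, truth = small_truth
        with pytest.raises(ValueError):
            simulate_contact_cells(small_genome, truth, 1, 50)


class TestBaseCounts:
    def test_strand_pairing_and_conservation(self, small_genome, small_truth):
        _, truth = small_truth
        table = simulate_base_counts(small_genome, truth, seed=4)
        plus = table.xs("+", level="strand")
        minus = table.xs("-", level="strand")
        assert len(plus) == len(minus) == len(truth.dms_sites)
        np.testing.assert_array_equal(
            plus.index.get_level_values("pos") + 1, minus.index.get_level_values("pos")
        )

    @staticmethod
    def _site_rows(table, chrom, pos):
        idx = table.index
        mask = (idx.get_level_values("chrom") == chrom) & idx.get_level_values("pos").isin(
            [pos, pos + 1]
        )
        return table[mask]

    def test_null_site_fraction_within_binomial_error(self, small_genome, small_truth):
        _, truth = small_truth
        table = simulate_base_counts(small_genome, truth, mean_cov=80, seed=5)
        site = truth.dms_sites[~truth.dms_sites["is_dms"]].iloc[0]
        level_cols = [c for c in truth.dms_sites.columns if c.startswith("level_")]
        level = site[level_cols[0]]
        rows = self._site_rows(table, site["chrom"], site["pos"])
        mc = rows.xs("mc", level="field", axis=1).to_numpy().sum()
        cov = rows.xs("cov", level="field", axis=1).to_numpy().sum()
        se = np.sqrt(level * (1 - level) / cov)
        assert mc / cov == pytest.approx(level, abs=3 * se)

    def test_planted_dms_fractions_separate(self, small_genome):
        cfg = TruthConfig(dms_fraction=0.5, dms_delta=0.8, n_cpg_sites=200)
        _, truth = simulate_methylomes(small_genome, cfg, n_subclasses=4, seed=6)
        table = simulate_base_counts(small_genome, truth, mean_cov=120, seed=7)
        level_cols = [c for c in truth.dms_sites.columns if c.startswith("level_")]
        site = truth.dms_sites[truth.dms_sites["is_dms"]].iloc[0]
        rows = self._site_rows(table, site["chrom"], site["pos"])
        mc = rows.xs("mc", level="field", axis=1).to_numpy().sum(axis=0)
        cov = rows.xs("cov", level="field", axis=1).to_numpy().sum(axis=0)
        frac = mc / cov
        hi = site[level_cols].to_numpy(dtype=float) > site[level_cols].to_numpy(dtype=float).mean()
        assert frac[hi].min() > frac[~hi].max()


class TestMotifDb:
    def test_planted_motif_above_threshold_in_its_dmr(self, small_genome, small_truth):
        _, truth = small_truth
        db = simulate_motif_db(small_genome, truth, n_decoy_motifs=20, seed=8)
        for t in truth.triples:
            motifs = db.motifs_for_tf(t.tf_id)
            assert any(db.scores.loc[t.dmr_id, m] >= db.thresholds[m] for m in motifs)

    def test_zero_decoys_gives_one_motif_per_planted_tf(self, small_genome, small_truth):
        _, truth = small_truth
        db = simulate_motif_db(small_genome, truth, n_decoy_motifs=0, seed=9)
        planted_tfs = {t.tf_id for t in truth.triples}
        assert db.scores.shape[1] == len(planted_tfs)

    def test_decoy_ranks_uniform(self, small_genome, small_truth):
        # a fixed DMR's rank across decoy motifs is exchangeable
        _, truth = small_truth
        db = simulate_motif_db(small_genome, truth, n_decoy_motifs=150, seed=10)
        decoys = [m for m in db.scores.columns if m.startswith("decoy")]
        ranks = db.scores[decoys].rank(axis=0).iloc[0] / len(db.scores)
        assert sps.kstest(ranks, "uniform").pvalue > 0.01


def test_identical_seed_identical_outputs(small_genome):
    cfg = TruthConfig()
    m1, t1 = simulate_methylomes(small_genome, cfg, n_subclasses=4, seed=42)
    m2, t2 = simulate_methylomes(small_genome, cfg, n_subclasses=4, seed=42)
    np.testing.assert_array_equal(m1.gene_mch.to_numpy(), m2.gene_mch.to_numpy())
    assert [l.__dict__.keys() for l in t1.loops] == [l.__dict__.keys() for l in t2.loops]
    for l1, l2 in zip(t1.loops, t2.loops):
        assert (l1.chrom, l1.bin_i, l1.bin_j, l1.kind) == (l2.chrom, l2.bin_i, l2.bin_j, l2.kind)
        np.testing.assert_array_equal(l1.enrichment, l2.enrichment)
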