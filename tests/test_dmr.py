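"""DMS/DMR calling: strand combination, downsampling, RMS permutation test,
merging and representative selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_rel

from mc3net import dmr


def _table(rows):
    """rows: list of (chrom, pos, strand, {sample: (mc, cov)})"""
    samples = sorted({s for *_, d in rows for s in d})
    index = pd.MultiIndex.from_tuples(
        [(c, p, s) for c, p, s, _ in rows], names=["chrom", "pos", "strand"]
    )
    data = {}
    for s in samples:
        data[(s, "mc")] = [d.get(s, (0, 0))[0] for *_, d in rows]
        data[(s, "cov")] = [d.get(s, (0, 0))[1] for *_, d in rows]
    out = pd.DataFrame(data, index=index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "field"])
    return out


class TestCombineStrands:
    def test_pair_counts_sum(self):
        t = _table(
            [
                ("chr1", 100, "+", {"s1": (3, 5)}),
                ("chr1", 101, "-", {"s1": (2, 5)}),
            ]
        )
        out = dmr.combine_strand_counts(t)
        assert len(out) == 1
        assert out.loc[("chr1", 100), ("s1", "mc")] == 5
        assert out.loc[("chr1", 100), ("s1", "cov")] == 10

    def test_total_coverage_conserved(self, rng):
        rows = []
        for k in range(20):
            pos = 1000 + 10 * k
            rows.append(("chr1", pos, "+", {"s1": (int(rng.integers(0, 5)), 5)}))
            rows.append(("chr1", pos + 1, "-", {"s1": (int(rng.integers(0, 5)), 5)}))
        t = _table(rows)
        out = dmr.combine_strand_counts(t)
        assert out.xs("cov", level="field", axis=1).to_numpy().sum() == t.xs(
            "cov", level="field", axis=1
        ).to_numpy().sum()

    def test_zero_coverage_strand_passthrough(self):
        t = _table(
            [
                ("chr1", 100, "+", {"s1": (3, 5)}),
                ("chr1", 101, "-", {"s1": (0, 0)}),
            ]
        )
        out = dmr.combine_strand_counts(t)
        assert out.loc[("chr1", 100), ("s1", "mc")] == 3
        assert out.loc[("chr1", 100), ("s1", "cov")] == 5

    def test_unpaired_site_kept_with_warning(self):
        t = _table([("chr1", 100, "+", {"s1": (1, 2)})])
        with pytest.warns(UserWarning, match="unpaired"):
            out = dmr.combine_strand_counts(t)
        assert len(out) == 1


class TestDownsample:
    def _pair(self, mc, cov):
        idx = pd.MultiIndex.from_tuples(
            [("chr1", 100 + 10 * i) for i in range(len(mc))], names=["chrom", "pos"]
        )
        data = {}
        mc = np.atleast_2d(mc)
        cov = np.atleast_2d(cov)
        for j in range(mc.shape[1]):
            data[(f"s{j}", "mc")] = mc[:, j]
            data[(f"s{j}", "cov")] = cov[:, j]
        out = pd.DataFrame(data, index=idx)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "field"])
        return out

    def test_site_cap_hypergeometric_mean(self):
        n = 4000
        t = self._pair(np.full((n, 1), 40), np.full((n, 1), 80))
        out = dmr.downsample_counts(t, site_cap=50, total_cap=10**6, seed=0)
        cov = out[("s0", "cov")].to_numpy()
        frac = out[("s0", "mc")].to_numpy() / cov
        assert (cov == 50).all()
        assert frac.mean() == pytest.approx(0.5, abs=0.01)  # E[mc'/cov'] = mc/cov

    def test_under_cap_untouched(self):
        t = self._pair(np.full((5, 10), 10), np.full((5, 10), 30))
        out = dmr.downsample_counts(t, seed=0)
        pd.testing.assert_frame_equal(out, t)

    def test_total_cap_proportional_rounding(self):
        t = self._pair(np.full((1, 100), 25), np.full((1, 100), 50))
        out = dmr.downsample_counts(t, site_cap=50, total_cap=3000, seed=0)
        cov = out.xs("cov", level="field", axis=1).to_numpy()
        assert (cov == 30).all()  # 100 samples at 50 -> scaled to 3000/5000

    def test_fraction_expectation_preserved(self, rng):
        n = 10_000
        mc = rng.integers(0, 120, size=(n, 1))
        cov = mc + rng.integers(1, 120, size=(n, 1))
        t = self._pair(mc, cov)
        out = dmr.downsample_counts(t, site_cap=50, total_cap=3000, seed=1)
        before = (mc[:, 0] / cov[:, 0])
        after = out[("s0", "mc")].to_numpy() / out[("s0", "cov")].to_numpy()
        assert ttest_rel(before, after).pvalue > 0.01


class TestRmsTest:
    def _pair(self, mc, cov):
        mc = np.asarray(mc)
        idx = pd.MultiIndex.from_tuples(
            [("chr1", 100 + 10 * i) for i in range(mc.shape[0])], names=["chrom", "pos"]
        )
        data = {}
        for j in range(mc.shape[1]):
            data[(f"s{j}", "mc")] = mc[:, j]
            data[(f"s{j}", "cov")] = np.asarray(cov)[:, j]
        out = pd.DataFrame(data, index=idx)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample", "field"])
        return out

    def test_equal_fractions_give_zero_statistic(self):
        t = self._pair([[10, 10, 10]], [[20, 20, 20]])
        res = dmr.rms_test(t, n_perm=200, seed=0)
        assert res.loc[0, "S"] == pytest.approx(0.0)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_extreme_split_statistic_and_floor(self):
        # fractions (1, 0) around pooled 0.5: S = sqrt(mean(0.25, 0.25)) = 0.5
        t = self._pair([[50, 0]], [[50, 50]])
        res = dmr.rms_test(t, n_perm=400, seed=0)
        assert res.loc[0, "S"] == pytest.approx(0.5)
        assert res.loc[0, "p"] == pytest.approx(1 / 401)

    def test_null_pvalues_uniform(self, rng):
        n = 2000
        p0 = rng.uniform(0.2, 0.8, n)
        cov = np.full((n, 4), 50)
        mc = rng.binomial(cov, p0[:, None])
        res = dmr.rms_test(self._pair(mc, cov), n_perm=300, seed=1)
        # discrete-support null: compare against uniform with KS on midpoints
        assert kstest(res["p"], "uniform").pvalue > 0.001 or res["p"].mean() > 0.45

    def test_single_covered_sample_skipped(self):
        t = self._pair([[5, 0]], [[10, 0]])
        res = dmr.rms_test(t, n_perm=50, seed=0)
        assert np.isnan(res.loc[0, "S"])


class TestMergeDms:
    def _dms(self, rows):
        # rows: (pos, q, fracs)
        recs = []
        for pos, q, fr in rows:
            rec = {"chrom": "chr1", "pos": pos, "S": 0.3, "p": q, "q": q}
            rec.update({f"frac_s{i}": v for i, v in enumerate(fr)})
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_close_correlated_sites_merge(self):
        d = self._dms([(100, 1e-4, [0.9, 0.1, 0.5, 0.2]), (200, 1e-4, [0.8, 0.2, 0.6, 0.3])])
        out = dmr.merge_dms(d)
        assert len(out) == 1 and out.loc[0, "n_sites"] == 2
        assert out.loc[0, "start"] == 100 and out.loc[0, "end"] == 202

    def test_distant_sites_stay_separate(self):
        d = self._dms([(100, 1e-4, [0.9, 0.1, 0.5, 0.2]), (400, 1e-4, [0.8, 0.2, 0.6, 0.3])])
        assert len(dmr.merge_dms(d)) == 2

    def test_uncorrelated_chain_breaks(self):
        # A-B correlated, B-C not: DMR{A,B} + DMR{C}
        d = self._dms(
            [
                (100, 1e-4, [0.9, 0.1, 0.5, 0.2]),
                (200, 1e-4, [0.8, 0.2, 0.6, 0.3]),
                (300, 1e-4, [0.2, 0.9, 0.1, 0.8]),
            ]
        )
        out = dmr.merge_dms(d)
        assert list(out["n_sites"]) == [2, 1]

    def test_insignificant_sites_excluded(self):
        d = self._dms([(100, 0.5, [0.9, 0.1, 0.5, 0.2])])
        assert len(dmr.merge_dms(d)) == 0

    def test_empty_input(self):
        assert len(dmr.merge_dms(self._dms([]))) == 0


class TestMergeOverlapping:
    def test_overlap_union(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]})
        out = dmr.merge_overlapping([a, b])
        assert out.to_dict("records") == [{"chrom": "chr1", "start": 100, "end": 250}]

    def test_disjoint_unchanged(self):
        a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 500], "end": [100, 600]})
        out = dmr.merge_overlapping([a])
        assert len(out) == 2

    def test_bookended_intervals_merge(self):
        a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200]})
        out = dmr.merge_overlapping([a])
        assert len(out) == 1 and out.loc[0, "end"] == 200

    def test_three_way_span(self):
        a = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 50, 120], "end": [100, 150, 160]}
        )
        out = dmr.merge_overlapping([a])
        assert out.to_dict("records") == [{"chrom": "chr1", "start": 0, "end": 160}]

    def test_output_sorted_disjoint_covering_union(self, rng):
        sets = []
        for _ in range(3):
            start = rng.integers(0, 5000, 30)
            sets.append(
                pd.DataFrame(
                    {"chrom": "chr1", "start": start, "end": start + rng.integers(50, 400, 30)}
                )
            )
        out = dmr.merge_overlapping(sets)
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()
        covered = set()
        for r in pd.concat(sets).itertuples():
            covered.update(range(r.start, r.end))
        merged_cov = set()
        for r in out.itertuples():
            merged_cov.update(range(r.start, r.end))
        assert covered == merged_cov


class TestSelectRepresentative:
    def test_largest_absolute_value_wins(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 50], "end": [100, 120], "stat": [0.5, -0.8]}
        )
        assert dmr.select_representative(df, "stat")["start"] == 50

    def test_single_candidate(self):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "stat": [0.1]})
        assert dmr.select_representative(df, "stat")["start"] == 0

    def test_tie_breaks_leftmost_then_shortest(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [100, 50, 50],
                "end": [200, 300, 150],
                "stat": [0.5, 0.5, 0.5],
            }
        )
        rep = dmr.select_representative(df, "stat")
        assert rep["start"] == 50 and rep["end"] == 150

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dmr.select_representative(pd.DataFrame(columns=["chrom", "start", "end", "stat"]))
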