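import numpy as np
import pandas as pd
import pytest

from admixscan.genotype_io import HaplotypePanel, make_marker_table
from admixscan.selection import (
    bh_qvalues,
    build_regions,
    calibrate,
    dcms,
    dcms_weights,
    ehh_decay,
    ihh12,
    ihs,
    nsl,
    rank_pvalues,
)

from .oracles import (
    bh_oracle,
    dcms_oracle,
    ehh12_oracle,
    ehh_oracle,
    mean_shared_length_oracle,
    rank_pvalue_oracle,
)


def _panel(haps, chrom_len=10_000_000, seed=0):
    haps = np.asarray(haps, dtype=np.uint8)
    n = haps.shape[1]
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_len), size=n, replace=False))
    return HaplotypePanel(make_marker_table(["1"] * n, pos), haps)


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.zeros((8, 20), dtype=np.uint8)
        haps[:, 10] = 1  # derived core allele on every haplotype
        p = _panel(haps)
        dec = ehh_decay(p, 10, "derived", max_gap_bp=None)
        assert np.all(dec.ehh == 1.0)
        assert dec.truncation_left == dec.truncation_right == "chromosome_end"

    def test_two_equal_extended_haplotypes(self):
        # K carriers split into two groups identical within, different between
        K = 10
        haps = np.zeros((K, 5), dtype=np.uint8)
        haps[:, 2] = 1
        haps[: K // 2, 3] = 1  # split one step to the right
        p = _panel(haps)
        dec = ehh_decay(p, 2, "derived", cutoff=0.0, max_gap_bp=None)
        expected = 2 * (K // 2) * (K // 2 - 1) / (K * (K - 1))
        right = dec.ehh[dec.d > 0]
        assert right[0] == pytest.approx(expected)

    def test_matches_pairwise_identity_oracle(self, rng):
        haps = (rng.random((20, 50)) < 0.5).astype(np.uint8)
        p = _panel(haps)
        for core in (5, 25, 44):
            for cls, want in (("ancestral", 0), ("derived", 1)):
                rows = np.flatnonzero(haps[:, core] == want)
                if len(rows) < 2:
                    continue
                dec = ehh_decay(p, core, cls, cutoff=0.0, max_gap_bp=None)
                pos = p.markers["pos_bp"].to_numpy()
                cm = p.markers["cm"].to_numpy()
                for d, e in zip(dec.d, dec.ehh):
                    if d == 0:
                        continue
                    # recover the site index from the cM distance
                    x = int(np.argmin(np.abs((cm - cm[core]) - d))) if d > 0 else \
                        int(np.argmin(np.abs((cm[core] - cm) - (-d))))
                    assert e == pytest.approx(ehh_oracle(haps, rows, core, x), abs=1e-12)

    def test_ehh_non_increasing(self, rng):
        haps = (rng.random((16, 40)) < 0.5).astype(np.uint8)
        p = _panel(haps)
        dec = ehh_decay(p, 20, "ancestral", cutoff=0.0, max_gap_bp=None)
        left = dec.ehh[dec.d <= 0]
        right = dec.ehh[dec.d >= 0]
        assert np.all(np.diff(left) >= 0)  # increasing toward the core
        assert np.all(np.diff(right) <= 0)

    def test_single_carrier_returns_none(self):
        haps = np.zeros((6, 10), dtype=np.uint8)
        haps[0, 5] = 1
        assert ehh_decay(_panel(haps), 5, "derived") is None

    def test_pooled_matches_oracle(self, rng):
        haps = (rng.random((12, 30)) < 0.5).astype(np.uint8)
        p = _panel(haps)
        core = 15
        dec = ehh_decay(p, core, "pooled-top2", cutoff=0.0, max_gap_bp=None)
        cm = p.markers["cm"].to_numpy()
        for d, e in zip(dec.d, dec.ehh):
            if d == 0:
                continue
            x = int(np.argmin(np.abs(np.abs(cm - cm[core]) - abs(d)) + 1e9 * ((cm - cm[core] > 0) != (d > 0))))
            assert e == pytest.approx(ehh12_oracle(haps, core, x), abs=1e-12)


class TestIhs:
    def test_mirror_panel_gives_zero(self):
        # ancestral and derived classes with identical internal structure
        rng = np.random.default_rng(3)
        block = (rng.random((6, 21)) < 0.5).astype(np.uint8)
        haps = np.vstack([block, block])
        haps[:6, 10] = 0
        haps[6:, 10] = 1
        p = _panel(haps)
        out = ihs(p, maf_cutoff=0.05)
        assert out["ihs_raw"][10] == pytest.approx(0.0, abs=1e-12)

    def test_standardisation_contract(self, swept_study):
        panel = swept_study.dataset.haplotype_panel("HYB")
        out = ihs(panel)
        ok = ~out["ihs_raw"].isna()
        from admixscan.selection import _freq_bins

        groups = _freq_bins(out["freq_derived"].to_numpy())
        for g in np.unique(groups[ok]):
            sel = ok & (groups == g)
            vals = out.loc[sel, "ihs_std"]
            if sel.sum() >= 2 and vals.notna().all():
                assert vals.mean() == pytest.approx(0.0, abs=1e-8)
                assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_sweep_in_top_percentile(self, swept_study):
        panel = swept_study.dataset.haplotype_panel("HYB")
        out = ihs(panel)
        pos = panel.markers["pos_bp"].to_numpy()
        on1 = (panel.markers["chrom"] == "1").to_numpy()
        near = on1 & (np.abs(pos - 5_000_000) < 250_000)
        score = np.abs(out["ihs_std"].to_numpy())
        thresh = np.nanpercentile(score, 95)
        assert np.nanmax(score[near]) > thresh


class TestIhh12:
    def test_identical_panel_spans_map(self):
        haps = np.zeros((8, 30), dtype=np.uint8)
        p = _panel(haps)
        # pooled curve of an all-identical panel never decays: the integral
        # equals the covered map length (up to the extension cap)
        dec = ehh_decay(p, 15, "pooled-top2", max_gap_bp=None)
        cm = p.markers["cm"].to_numpy()
        assert dec.integrate() == pytest.approx(cm[-1] - cm[0])

    def test_two_pooled_classes_start_at_one(self):
        haps = np.zeros((10, 11), dtype=np.uint8)
        haps[:5, 5] = 1
        dec = ehh_decay(_panel(haps), 5, "pooled-top2", max_gap_bp=None)
        assert dec.ehh[dec.d == 0][0] == 1.0

    def test_soft_sweep_scores_high(self):
        # two donor haplotypes at ~40% each: pooled statistic is sensitive
        from admixscan.synthetic_admix import SimConfig, SweepSpec, simulate_study

        spec = SweepSpec(chrom="1", pos_bp=5_000_000, carrier_fraction=0.8,
                         core_span_bp=500_000, target_pop="HYB", n_donors=2)
        st = simulate_study(SimConfig(n_snps=1000, n_chrom=1, n_per_pop=25,
                                      seed=77, sweep_specs=[spec]))
        panel = st.dataset.haplotype_panel("HYB")
        out = ihh12(panel)
        pos = panel.markers["pos_bp"].to_numpy()
        near = np.abs(pos - 5_000_000) < 250_000
        assert np.nanmax(out["ihh12_std"][near]) > np.nanpercentile(out["ihh12_std"], 95)


class TestNsl:
    def test_mirror_panel_gives_zero(self):
        rng = np.random.default_rng(4)
        block = (rng.random((5, 15)) < 0.5).astype(np.uint8)
        haps = np.vstack([block, block])
        haps[:5, 7] = 0
        haps[5:, 7] = 1
        out = nsl(_panel(haps), maf_cutoff=0.05)
        assert out["nsl_raw"][7] == pytest.approx(0.0, abs=1e-12)

    def test_matches_shared_length_oracle(self, rng):
        haps = (rng.random((10, 50)) < 0.5).astype(np.uint8)
        p = _panel(haps)
        out = nsl(p, maf_cutoff=0.05, max_snp_span=None)
        freqs = p.freqs()
        for core in range(50):
            if not 0.05 <= freqs[core] <= 0.95 or np.isnan(out["sl_a"][core]):
                continue
            for col, want in (("sl_a", 0), ("sl_d", 1)):
                rows = np.flatnonzero(haps[:, core] == want)
                if len(rows) < 2:
                    continue
                assert out[col][core] == pytest.approx(
                    mean_shared_length_oracle(haps, rows, core), abs=1e-10
                )

    def test_rank_correlated_with_ihs_on_uniform_map(self, swept_study):
        from scipy.stats import spearmanr

        panel = swept_study.dataset.haplotype_panel("HYB")
        a = ihs(panel)["ihs_raw"]
        b = nsl(panel)["nsl_raw"]
        ok = a.notna() & b.notna()
        rho = spearmanr(a[ok], b[ok]).statistic
        assert rho > 0.7


class TestRankPvalues:
    def test_distinct_values(self):
        p = rank_pvalues(np.array([5.0, 4.0, 3.0, 2.0, 1.0]))
        assert p[0] == pytest.approx(0.1)
        assert p[-1] == pytest.approx(0.9)

    def test_all_tied(self):
        assert rank_pvalues(np.full(7, 2.0)) == pytest.approx(np.full(7, 0.5))

    def test_matches_count_oracle(self, rng):
        v = rng.normal(size=1000).round(2)  # rounding forces ties
        assert rank_pvalues(v) == pytest.approx(rank_pvalue_oracle(v), abs=1e-12)

    def test_strictly_inside_unit_interval(self, rng):
        p = rank_pvalues(rng.normal(size=500))
        assert (p > 0).all() and (p < 1).all()


class TestDcms:
    def test_single_statistic_at_half(self, rng):
        x = rng.normal(size=(10, 1))
        out = dcms(np.full((10, 1), 0.5), x)
        assert out == pytest.approx(np.zeros(10))

    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=50)
        stat = np.column_stack([x, 2 * x + 3])
        p = np.column_stack([rank_pvalues(x)] * 2)
        w = dcms_weights(stat)
        assert w == pytest.approx([0.5, 0.5])
        single = np.log((1 - p[:, 0]) / p[:, 0])
        assert dcms(p, stat) == pytest.approx(single, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        stat = rng.normal(size=(100, 3))
        p = np.column_stack([rank_pvalues(stat[:, t]) for t in range(3)])
        assert dcms(p, stat) == pytest.approx(dcms_oracle(p, stat), abs=1e-12)

    def test_constant_statistic_rejected(self, rng):
        stat = np.column_stack([rng.normal(size=20), np.full(20, 1.0)])
        p = np.full((20, 2), 0.5)
        with pytest.raises(ValueError, match="stat1"):
            dcms(p, stat)

    def test_weights_within_stated_range(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            stat = rng.normal(size=(60, k))
            w = dcms_weights(stat)
            assert np.all(w >= 1.0 / k - 1e-12) and np.all(w <= 1.0 + 1e-12)


class TestCalibration:
    def test_recovers_standard_normal(self, rng):
        v = rng.normal(size=10_000)
        mu, sigma, _ = calibrate(v)
        assert mu == pytest.approx(0.0, abs=0.05)
        assert sigma == pytest.approx(1.0, abs=0.05)

    def test_robust_to_gross_outliers(self, rng):
        v = rng.normal(size=2000)
        mu_clean, _, _ = calibrate(v)
        vo = v.copy()
        vo[:100] = 20.0
        mu_out, _, _ = calibrate(vo)
        assert abs(mu_out - mu_clean) < 0.1

    def test_center_maps_to_half(self, rng):
        v = rng.normal(size=5000)
        mu, sigma, _ = calibrate(v)
        from scipy.stats import norm

        assert norm.sf(mu, loc=mu, scale=sigma) == pytest.approx(0.5)


class TestBhQvalues:
    def test_toy_vector(self):
        q = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_equal(self):
        assert bh_qvalues(np.full(5, 0.3)) == pytest.approx(np.full(5, 0.3))

    def test_matches_step_up_oracle_and_dominates_p(self, rng):
        for _ in range(10):
            p = rng.random(100)
            q = bh_qvalues(p)
            assert q == pytest.approx(bh_oracle(p), abs=1e-12)
            assert np.all(q >= p - 1e-15)


class TestBuildRegions:
    def _records(self, q, pos_mb=None, chrom="1"):
        pos = pos_mb or list(range(1, len(q) + 1))
        return pd.DataFrame(
            {"chrom": [chrom] * len(q), "pos_bp": [int(p * 1e6) for p in pos], "q": q}
        )

    def test_flanking_rule_on_toy(self):
        regions = build_regions(self._records([0.2, 0.08, 0.04, 0.09, 0.2]))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (1_000_000, 5_000_000)
        assert r.min_q == pytest.approx(0.04)

    def test_no_significant_snps(self):
        assert build_regions(self._records([0.2, 0.3, 0.4])) == []

    def test_shared_flank_merges(self):
        regions = build_regions(self._records([0.2, 0.01, 0.07, 0.01, 0.2]))
        assert len(regions) == 1
        assert len(regions[0].member_snps) == 2

    def test_truncates_at_chromosome_end(self):
        regions = build_regions(self._records([0.01, 0.2, 0.3]))
        assert regions[0].start_bp == 1_000_000

    def test_regions_never_cross_chromosomes(self):
        df = pd.concat(
            [self._records([0.01, 0.06], chrom="1"), self._records([0.06, 0.2], chrom="2")],
            ignore_index=True,
        )
        regions = build_regions(df)
        assert all(r.chrom == "1" for r in regions)
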