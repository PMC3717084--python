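import numpy as np
import pandas as pd
import pytest

from spectroqtl import qtl
from spectroqtl.errors import InsufficientDataError
from spectroqtl.geno import MISSING, GenotypePanel
from spectroqtl.synthetic import PanelDesign, PlantedQTL, simulate_amplitudes, simulate_ri_genotypes


def make_panel(genos, chrom="1", spacing=10.0):
    """Panel from a list of per-marker genotype strings like 'BBBBDDDD'."""
    n = len(genos[0])
    strains = [f"S{i}" for i in range(n)]
    code = {"B": 1, "D": -1, "U": MISSING}
    calls = np.array([[code[c] for c in row] for row in genos], dtype=np.int8)
    markers = pd.DataFrame({
        "chrom": chrom, "locus": [f"m{i}" for i in range(len(genos))],
        "cm": np.arange(len(genos)) * spacing,
        "mb": np.arange(len(genos)) * spacing / 2,
    })
    return GenotypePanel(markers, strains, calls)


def series(values, panel):
    return pd.Series(values, index=panel.strains, dtype=float)


class TestConversion:
    def test_zero(self):
        assert qtl.lod_to_lrs(0.0) == 0.0

    def test_1p5_lod_displays_6p9(self):
        assert round(qtl.lod_to_lrs(1.5), 1) == 6.9

    def test_display_factor(self):
        assert qtl.display_lrs_per_lod() == 4.6

    def test_roundtrip_identity(self):
        for v in (0.1, 6.9, 123.0):
            assert qtl.lrs_to_lod(qtl.lod_to_lrs(v)) == pytest.approx(v, rel=1e-15)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            qtl.lod_to_lrs(-1.0)
        with pytest.raises(ValueError):
            qtl.lrs_to_lod(-1.0)


class TestMarkerRegression:
    def test_equal_class_means_zero_lrs(self):
        panel = make_panel(["BBBBDDDD"])
        y = series([1.0, 2, 3, 4, 1, 2, 3, 4], panel)
        scan = qtl.marker_regression_scan(panel, y)
        assert scan.table["lrs"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_matches_correlation_identity_and_lstsq_oracle(self):
        panel = make_panel(["BBBBDDDD"])
        rng = np.random.default_rng(1)
        y = series(rng.normal(size=8), panel)
        scan = qtl.marker_regression_scan(panel, y)
        x = panel.allele_codes()[0]
        r = np.corrcoef(x, y.to_numpy())[0, 1]
        assert scan.table["lrs"].iloc[0] == pytest.approx(-8 * np.log(1 - r**2), abs=1e-9)
        # brute-force least-squares oracle
        A = np.column_stack([np.ones(8), x])
        rss1 = np.sum((y.to_numpy() - A @ np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]) ** 2)
        rss0 = np.sum((y.to_numpy() - y.mean()) ** 2)
        assert scan.table["lrs"].iloc[0] == pytest.approx(8 * np.log(rss0 / rss1), abs=1e-9)

    def test_perfect_fit_capped_and_flagged(self):
        panel = make_panel(["BBBBDDDD"])
        y = series([1.0, 1, 1, 1, -1, -1, -1, -1], panel)
        scan = qtl.marker_regression_scan(panel, y)
        assert scan.table["lrs"].iloc[0] == qtl.DEFAULT_LRS_CAP
        assert scan.table["perfect_fit"].iloc[0]

    def test_additive_effect_and_increasing_allele(self):
        panel = make_panel(["BBBBDDDD"])
        y = series([5.0, 5, 5, 5, 1, 1, 1, 3], panel)
        scan = qtl.marker_regression_scan(panel, y)
        row = scan.table.iloc[0]
        assert row["additive"] == pytest.approx((5 - 1.5) / 2)
        assert row["increasing_allele"] == "B6"
        y2 = -y
        row2 = qtl.marker_regression_scan(panel, y2).table.iloc[0]
        assert row2["increasing_allele"] == "D2"
        assert row2["additive"] == row["additive"]

    def test_affine_invariance_of_lrs(self):
        panel = make_panel(["BBBDDDBD", "BDBDBDBD"])
        rng = np.random.default_rng(2)
        y = series(rng.normal(size=8), panel)
        s1 = qtl.marker_regression_scan(panel, y)
        s2 = qtl.marker_regression_scan(panel, 3.7 * y - 11.0)
        assert np.allclose(s1.table["lrs"], s2.table["lrs"], atol=1e-9)

    def test_allele_swap_invariance(self):
        panel = make_panel(["BBBDDDBD", "BDBDBDBD"])
        rng = np.random.default_rng(3)
        y = series(rng.normal(size=8), panel)
        swapped = GenotypePanel(panel.markers.copy(), panel.strains,
                                (-panel.calls).astype(np.int8))
        s1 = qtl.marker_regression_scan(panel, y)
        s2 = qtl.marker_regression_scan(swapped, y)
        assert np.allclose(s1.table["lrs"], s2.table["lrs"], atol=1e-12)
        flip = {"B6": "D2", "D2": "B6"}
        assert [flip[a] for a in s1.table["increasing_allele"]] == list(
            s2.table["increasing_allele"])

    def test_missing_genotypes_dropped_per_marker(self):
        panel = make_panel(["BBUBDDDD"])
        y = series(np.arange(8.0), panel)
        scan = qtl.marker_regression_scan(panel, y)
        assert scan.table["n"].iloc[0] == 7
        # oracle on the 7 informative strains
        x = panel.allele_codes()[0]
        use = ~np.isnan(x)
        r = np.corrcoef(x[use], y.to_numpy()[use])[0, 1]
        assert scan.table["lrs"].iloc[0] == pytest.approx(-7 * np.log(1 - r**2), abs=1e-9)

    def test_marker_with_small_class_skipped(self):
        panel = make_panel(["BDDDDDDD", "BBBBDDDD"])
        y = series(np.arange(8.0), panel)
        scan = qtl.marker_regression_scan(panel, y)
        assert scan.table["skipped"].iloc[0]
        assert not scan.table["skipped"].iloc[1]

    def test_too_few_strains_errors(self):
        panel = make_panel(["BD"])
        with pytest.raises(InsufficientDataError):
            qtl.marker_regression_scan(panel, pd.Series([1.0, 2.0], index=panel.strains))


class TestPermutationThresholds:
    def test_suggestive_le_significant_and_order_statistic_oracle(self, small_panel):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=small_panel.n_strains), index=small_panel.strains)
        thr = qtl.permutation_thresholds(small_panel, y, n_perm=1000, seed=5)
        assert thr.suggestive <= thr.significant
        # sort-based oracle on the retained null sample
        srt = np.sort(thr.max_lrs_sample)
        assert thr.significant == srt[int(np.ceil(0.95 * 1000)) - 1]
        assert thr.suggestive == srt[int(np.ceil(0.37 * 1000)) - 1]

    def test_seed_reproducibility(self, small_panel):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(size=small_panel.n_strains), index=small_panel.strains)
        t1 = qtl.permutation_thresholds(small_panel, y, n_perm=200, seed=9)
        t2 = qtl.permutation_thresholds(small_panel, y, n_perm=200, seed=9)
        assert np.array_equal(t1.max_lrs_sample, t2.max_lrs_sample)

    def test_low_n_perm_warns_but_computes(self, small_panel, caplog):
        import logging
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=small_panel.n_strains), index=small_panel.strains)
        with caplog.at_level(logging.WARNING):
            thr = qtl.permutation_thresholds(small_panel, y, n_perm=50, seed=1)
        assert "noisy" in caplog.text
        assert thr.significant >= thr.suggestive


def triangle_scan():
    table = pd.DataFrame({
        "chrom": "1", "locus": [f"m{i}" for i in range(5)],
        "cm": [0.0, 10, 20, 30, 40], "mb": [0.0, 5, 10, 15, 20],
        "lrs": [0.0, 10, 20, 10, 0],
        "lod": np.array([0.0, 10, 20, 10, 0]) / qtl.LRS_PER_LOD,
        "additive": 1.0, "additive_signed": 1.0, "increasing_allele": "B6",
        "n": 8, "skipped": False, "perfect_fit": False,
    })
    return qtl.ScanResult("t", table, n_strains=8)


class TestSupportInterval:
    def test_triangular_profile_hand_oracle(self):
        ci = qtl.support_interval(triangle_scan(), "1", drop=6.9)
        # level 13.1; crossings interpolated between (10,10)-(20,20) and
        # (20,20)-(30,10): left = 10 + (20-13.1)/(20-10)*(10-20) shifted, i.e. 13.1
        assert ci.left_cm == pytest.approx(13.1)
        assert ci.right_cm == pytest.approx(26.9)
        assert ci.left_mb == pytest.approx(13.1 / 2)
        assert ci.right_mb == pytest.approx(26.9 / 2)

    def test_peak_inside_interval(self):
        ci = qtl.support_interval(triangle_scan(), "1", drop=6.9)
        assert ci.left_cm <= ci.peak_cm <= ci.right_cm

    def test_drop_exceeding_peak_spans_chromosome(self):
        ci = qtl.support_interval(triangle_scan(), "1", drop=25.0)
        assert ci.left_cm == 0.0
        assert ci.right_cm == 40.0

    def test_all_skipped_returns_none(self):
        scan = triangle_scan()
        scan.table["skipped"] = True
        assert qtl.support_interval(scan, "1") is None


class TestSummarize:
    def test_flat_scan_empty_report(self):
        scan = triangle_scan()
        scan.table["lrs"] = 0.0
        thr = qtl.Thresholds(significant=15.0, suggestive=9.0, n_perm=1000, seed=0)
        report = qtl.summarize_qtls({"t": scan}, {"t": thr})
        assert report.empty

    def test_classification_stars(self):
        scan = triangle_scan()
        thr = qtl.Thresholds(significant=15.0, suggestive=9.0, n_perm=1000, seed=0)
        report = qtl.summarize_qtls({"t": scan}, {"t": thr})
        assert len(report) == 1
        assert report["significance"].iloc[0] == "**"
        thr2 = qtl.Thresholds(significant=25.0, suggestive=9.0, n_perm=1000, seed=0)
        report2 = qtl.summarize_qtls({"t": scan}, {"t": thr2})
        assert report2["significance"].iloc[0] == "*"

    def test_planted_qtl_recovered(self, small_panel):
        design = PanelDesign(n_strains=30, males_per_strain=4,
                             chrom_lengths_cm={"1": 60.0, "2": 60.0, "3": 60.0},
                             marker_spacing_cm=5.0, strain_sd=0.05, env_sd=0.05, seed=11)
        amps, truth = simulate_amplitudes(
            small_panel, [PlantedQTL("2", 30.0, "lipid_CH", 0.6)], design,
            {"lipid_CH": 3.0})
        means = amps.groupby("strain")["lipid_CH"].mean()
        scan = qtl.marker_regression_scan(small_panel, means, trait="lip")
        thr = qtl.permutation_thresholds(small_panel, means, n_perm=1000, seed=11)
        report = qtl.summarize_qtls({"lip": scan}, {"lip": thr})
        sig = report[report["significance"] == "**"]
        assert len(sig) == 1
        assert str(sig["chrom"].iloc[0]) == "2"
        assert sig["ci_left_cm"].iloc[0] <= 30.0 <= sig["ci_right_cm"].iloc[0]

    def test_pleiotropy_shared_truth_overlapping_intervals(self, small_panel):
        design = PanelDesign(n_strains=30, males_per_strain=4,
                             chrom_lengths_cm={"1": 60.0, "2": 60.0, "3": 60.0},
                             marker_spacing_cm=5.0, strain_sd=0.05, env_sd=0.05, seed=12)
        scans, thrs = {}, {}
        for i, comp in enumerate(["lipid_CH", "ester"]):
            amps, _ = simulate_amplitudes(
                small_panel, [PlantedQTL("2", 30.0, comp, 0.6)], design,
                {comp: 3.0}, rng=np.random.default_rng(100 + i))
            means = amps.groupby("strain")[comp].mean()
            scans[comp] = qtl.marker_regression_scan(small_panel, means, trait=comp)
            thrs[comp] = qtl.permutation_thresholds(small_panel, means, n_perm=500,
                                                    seed=100 + i)
        report = qtl.summarize_qtls(scans, thrs)
        on2 = report[(report["chrom"] == "2") & (report["significance"] == "**")]
        assert set(on2["trait"]) == {"lipid_CH", "ester"}
        a, b = on2.iloc[0], on2.iloc[1]
        assert max(a["ci_left_cm"], b["ci_left_cm"]) <= min(a["ci_right_cm"], b["ci_right_cm"])
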