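import numpy as np
import pandas as pd
import pytest

from nfatseq.integration import (bound_indicator, call_direct_targets,
                                 distance_vs_foldchange,
                                 height_strata_report,
                                 match_peaks_across_conditions,
                                 occupancy_curve)
from nfatseq.io_formats import GeneModel, Peak, RunConfig, ValidationError
from nfatseq.synthetic import (SimParams, simulate_bound_coupling,
                               simulate_dataset,
                               simulate_height_activation_coupling)


def peak(pid, summit, height=10.0, chrom="chr1", cond=""):
    return Peak(pid, chrom, max(0, summit - 100), summit + 101, summit, height, cond)


GENE = GeneModel("g1", "chr1", "+", 50_000, 60_000)  # TSS = 50000


class TestBoundIndicator:
    @pytest.mark.parametrize("summit,expected", [
        (69_999, True), (70_000, True), (70_001, False),
        (30_000, True), (29_999, False),
    ])
    def test_boundary_inclusive(self, summit, expected):
        assert bound_indicator(GENE, [peak("p", summit)], 20_000) is expected

    def test_no_peaks(self):
        assert bound_indicator(GENE, [], 20_000) is False


class TestOccupancyCurve:
    def make_fixture(self, seed, n=200):
        return simulate_bound_coupling(n, seed)

    def test_all_genes_bound_gives_constant_one(self, config):
        genes, _, de = self.make_fixture(0, n=120)
        peaks = [peak(f"q{i}", g.tss) for i, g in enumerate(genes)]
        curve = occupancy_curve(de, genes, peaks, config)
        assert (curve["fraction_bound"] == 1.0).all()
        assert len(curve) == 120 - config.occupancy_window_genes + 1

    def test_matches_brute_force_window_recount(self, config):
        genes, peaks, de = self.make_fixture(13, n=300)
        curve = occupancy_curve(de, genes, peaks, config)
        # independent recount: sort, then average the bound flags per window
        gm = {g.gene_id: g for g in genes}
        order = sorted(de.index, key=lambda g: (-de.at[g, "log2fc"], g))
        w = config.occupancy_window_genes
        flags = []
        for gid in order:
            tss = gm[gid].tss
            flags.append(any(abs(p.summit - tss) <= config.occupancy_distance_bp
                             for p in peaks if p.chrom == gm[gid].chrom))
        for i in range(len(order) - w + 1):
            expect = sum(flags[i:i + w]) / w
            assert curve["fraction_bound"].iat[i] == pytest.approx(expect)

    def test_planted_coupling_elevates_upregulated_end(self, config):
        genes, peaks, de = simulate_bound_coupling(500, seed=7)
        curve = occupancy_curve(de, genes, peaks, config)
        n_top = 50  # windows fully inside the planted top decile
        top = curve["fraction_bound"].iloc[:n_top - config.occupancy_window_genes + 1]
        rest = curve["fraction_bound"].iloc[len(curve) // 2:]
        assert top.mean() - rest.mean() > 0.3

    def test_window_larger_than_gene_set_rejected(self, config):
        genes, peaks, de = self.make_fixture(0, n=20)
        with pytest.raises(ValidationError):
            occupancy_curve(de, genes, peaks, config)


class TestMatchPeaks:
    def test_identity_matching_by_shared_ids(self):
        pbc = {
            "untreated": [peak("p1", 1000, 5), peak("p2", 9000, 7)],
            "curdlan": [peak("p1", 1000, 20), peak("p2", 9000, 8)],
            "curdlan_fk506": [peak("p1", 1000, 6), peak("p2", 9000, 7)],
        }
        m = match_peaks_across_conditions(pbc).set_index("peak_id")
        assert len(m) == 2
        assert m.at["p1", "height_curdlan"] == 20

    def test_jittered_summits_within_tolerance_match(self):
        pbc = {
            "curdlan": [peak("a", 5000, 20)],
            "untreated": [peak("b", 5030, 5)],
        }
        m = match_peaks_across_conditions(pbc)
        assert len(m) == 1
        row = m.iloc[0]
        assert row["height_curdlan"] == 20 and row["height_untreated"] == 5

    def test_nearer_candidate_wins(self):
        pbc = {
            "curdlan": [peak("near", 1000, 10), peak("far", 1130, 10)],
            "untreated": [peak("x", 1050, 3)],
        }
        m = match_peaks_across_conditions(pbc).set_index("peak_id")
        assert m.at["near", "height_untreated"] == 3
        assert m.at["far", "height_untreated"] == 0.0

    def test_beyond_tolerance_stays_unmatched(self):
        pbc = {
            "curdlan": [peak("a", 1000, 10)],
            "untreated": [peak("b", 1500, 3)],
        }
        m = match_peaks_across_conditions(pbc)
        assert len(m) == 2
        assert set(m["height_untreated"]) == {0.0, 3.0}

    def test_single_condition_rejected(self):
        with pytest.raises(ValidationError):
            match_peaks_across_conditions({"curdlan": []})


def matched_row(summit, hu, hc, hf):
    return pd.DataFrame([{"peak_id": "p1", "chrom": "chr1", "summit": summit,
                          "height_untreated": hu, "height_curdlan": hc,
                          "height_curdlan_fk506": hf}])


class TestCallDirectTargets:
    def test_pseudocount_ratio_arithmetic(self, config):
        calls = call_direct_targets([GENE], matched_row(60_000, 10, 30, 12), config)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["ratio_stim"] == pytest.approx(31 / 11)
        assert row["ratio_inhib"] == pytest.approx(13 / 31)
        assert row["tss_distance_bp"] == 10_000

    def test_distance_bound_excludes(self, config):
        calls = call_direct_targets([GENE], matched_row(81_000, 10, 30, 12), config)
        assert calls.empty  # 31 kb from the TSS

    def test_flat_heights_excluded(self, config):
        calls = call_direct_targets([GENE], matched_row(60_000, 30, 30, 30), config)
        assert calls.empty

    def test_scale_invariance_of_called_set(self, config):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(50):
            hu = rng.uniform(5, 40)
            rows.append({"peak_id": f"p{i}", "chrom": "chr1",
                         "summit": int(rng.integers(20_000, 80_000)),
                         "height_untreated": hu,
                         "height_curdlan": hu * rng.uniform(1, 4),
                         "height_curdlan_fk506": hu * rng.uniform(0.2, 3)})
        m = pd.DataFrame(rows)
        m10 = m.copy()
        for c in m.columns:
            if c.startswith("height"):
                m10[c] = m10[c] * 1000  # pseudocount becomes negligible
        calls = call_direct_targets([GENE], m10, config)
        # ratio thresholds applied to pure ratios (no pseudocount effect)
        pure = m.assign(rs=m["height_curdlan"] / m["height_untreated"],
                        ri=m["height_curdlan_fk506"] / m["height_curdlan"])
        expected = pure[(pure["rs"] >= config.binding_up_ratio)
                        & (pure["ri"] <= config.binding_down_ratio)
                        & ((pure["summit"] - GENE.tss).abs()
                           <= config.direct_target_distance_bp)]
        assert set(calls["supporting_peak_id"]) == set(expected["peak_id"])

    def test_noiseless_planted_recovery(self, config):
        params = SimParams(n_genes=400, n_chroms=4, chrom_length_bp=10_000_000,
                           n_peaks=800, n_direct_targets=12, noise_sd_log2=0.0,
                           de_cardinalities={"dectin_up": 30, "dectin_down": 20,
                                             "nfat_up": 15, "nfat_down": 8,
                                             "common_up": 12, "common_down": 5},
                           rng_seed=17)
        _, genes, peaks, _, _, manifest = simulate_dataset(params, config)
        matched = match_peaks_across_conditions(peaks)
        calls = call_direct_targets(genes, matched, config)
        assert set(calls["gene_id"]) == manifest.direct_target_ids

    def test_jittered_summits_still_recover(self, config):
        params = SimParams(n_genes=200, n_chroms=2, chrom_length_bp=10_000_000,
                           n_peaks=300, n_direct_targets=8, noise_sd_log2=0.0,
                           jitter_summits=True,
                           de_cardinalities={"dectin_up": 20, "dectin_down": 10,
                                             "nfat_up": 10, "nfat_down": 5,
                                             "common_up": 8, "common_down": 3},
                           rng_seed=23)
        _, genes, peaks, _, _, manifest = simulate_dataset(params, config)
        matched = match_peaks_across_conditions(peaks)
        calls = call_direct_targets(genes, matched, config)
        assert set(calls["gene_id"]) == manifest.direct_target_ids


class TestHeightStrata:
    def test_boundary_heights_assigned_half_open(self, config):
        genes = [GENE]
        peaks = [peak("a", 50_000, 20.0), peak("b", 50_100, 19.99),
                 peak("c", 50_200, 100.0), peak("d", 50_300, 50.0)]
        rep = height_strata_report(peaks, genes, set(), config).set_index("stratum")
        assert rep.at["medium", "n_peaks"] == 1    # height 20
        assert rep.at["low", "n_peaks"] == 1       # 19.99
        assert rep.at["very_high", "n_peaks"] == 2  # 50 and closed upper 100

    def test_overflow_stratum_warns(self, config, caplog):
        rep = height_strata_report([peak("a", 50_000, 250.0)], [GENE], set(), config)
        assert rep.set_index("stratum").at["overflow", "n_peaks"] == 1
        assert any("outside all strata" in r.message for r in caplog.records)

    def test_strata_partition_all_peaks(self, config):
        genes, peaks, activated = simulate_height_activation_coupling(500, seed=3)
        rep = height_strata_report(peaks, genes, activated, config)
        assert rep["n_peaks"].sum() == len(peaks)

    def test_empty_stratum_reports_na(self, config):
        rep = height_strata_report([peak("a", 50_000, 5.0)], [GENE], set(), config)
        rep = rep.set_index("stratum")
        assert rep.at["medium", "n_peaks"] == 0
        assert np.isnan(rep.at["medium", "fraction_activated"])

    def test_planted_monotone_coupling_detected(self, config):
        genes, peaks, activated = simulate_height_activation_coupling(5000, seed=1)
        pooled_cfg = config.with_overrides(height_strata=((0, 20), (20, 100)))
        rep = height_strata_report(peaks, genes, activated, pooled_cfg
                                   ).set_index("stratum")
        low = rep.at["stratum_0", "fraction_activated"]
        rest = rep.at["stratum_1", "fraction_activated"]
        assert rest >= 2 * low


class TestDistanceVsFoldChange:
    def test_signed_distance_and_nearest_selection(self, config):
        de = pd.DataFrame({"log2fc": [2.0]}, index=pd.Index(["g1"], name="gene_id"))
        peaks = [peak("up2k", 48_000), peak("down3k", 47_000)]
        rec = distance_vs_foldchange([GENE], peaks, de, config)
        assert len(rec) == 1
        assert rec.iloc[0]["signed_tss_distance_bp"] == -2000
        rec = distance_vs_foldchange(
            [GENE], [peak("m3k", 47_000), peak("p1k", 51_000)], de, config)
        assert rec.iloc[0]["signed_tss_distance_bp"] == 1000
        assert rec.iloc[0]["nearest_peak_id"] == "p1k"

    def test_genes_without_nearby_peaks_omitted(self, config):
        de = pd.DataFrame({"log2fc": [2.0]}, index=pd.Index(["g1"], name="gene_id"))
        rec = distance_vs_foldchange([GENE], [peak("far", 200_000)], de, config)
        assert rec.empty

    def test_planted_upstream_proximity_correlates_with_fold_change(self, config):
        # strongest up-regulated genes get the closest upstream sites
        rng = np.random.default_rng(4)
        genes, peaks, rows = [], [], []
        for i in range(300):
            start = 200_000 * i + 100_000
            g = GeneModel(f"g{i:03d}", "chr1", "+", start, start + 2_000)
            genes.append(g)
            l2fc = float(rng.uniform(0, 4))
            dist = int(1_000 + (4 - l2fc) * 20_000 + rng.integers(0, 2_000))
            peaks.append(peak(f"p{i:03d}", g.tss - dist))
            rows.append({"gene_id": g.gene_id, "log2fc": l2fc})
        de = pd.DataFrame(rows).set_index("gene_id")
        rec = distance_vs_foldchange(genes, peaks, de, config)
        from scipy import stats
        rho = stats.spearmanr(rec["signed_tss_distance_bp"].abs(), rec["log2fc"]).statistic
        assert rho < -0.8
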