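"""Window aggregation, fold change, anchoring, ratios, cohort statistics."""

import numpy as np
import pandas as pd
import pytest

import cooccupy as cp
from test_peaks import make_peakset


def constant_track(value=3.0, nbins=1000, bin_size=10, chrom="chr1"):
    return cp.SignalTrack({chrom: np.full(nbins, float(value))}, bin_size)


class TestWindowSignal:
    def test_constant_track_gives_constant_means(self):
        tr = constant_track(3.0)
        ps = make_peakset([10.0, 20.0], spacing=3000)
        ws = cp.window_signal(tr, ps, 300)
        assert (ws == 3.0).all()

    def test_gaussian_bump_matches_closed_form(self):
        bin_size, sd, amp, summit = 10, 75.0, 40.0, 5000
        nbins = 1000
        centers = (np.arange(nbins) + 0.5) * bin_size
        vals = amp * np.exp(-((centers - summit) ** 2) / (2 * sd * sd))
        tr = cp.SignalTrack({"chr1": vals}, bin_size)
        h = 300
        in_win = (centers >= summit - h) & (centers < summit + h)
        expected = vals[in_win].sum() / in_win.sum()
        assert tr.window_mean("chr1", summit, h) == pytest.approx(expected)

    def test_window_off_chromosome_errors(self):
        tr = constant_track(nbins=100)
        with pytest.raises(ValueError, match="off the chromosome"):
            tr.window_mean("chr1", 5000, 300)

    def test_subbin_window_uses_summit_bin(self):
        tr = cp.SignalTrack({"chr1": np.arange(100, dtype=float)}, 10)
        assert tr.window_mean("chr1", 555, 2) == 55.0

    def test_partial_edge_window(self):
        tr = cp.SignalTrack({"chr1": np.full(100, 7.0)}, 10)
        assert tr.window_mean("chr1", 5, 300) == 7.0

    def test_bedgraph_round_trip(self, tracks, config, genome):
        tr = tracks[("gfi1", "ntc")]
        import io, tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "t.bedGraph")
            tr.to_bedgraph(path)
            back = cp.SignalTrack.from_bedgraph(path, genome.lengths, config.bin_size)
        for c in genome.lengths:
            np.testing.assert_array_equal(back.data[c], tr.data[c])


def toy_cohorts(values_by_cohort, rng=None):
    """Build per-peak values and a CohortTable from per-cohort value arrays."""
    names, vals, assign = [], [], {}
    for k, arr in enumerate(values_by_cohort, start=1):
        for i, v in enumerate(arr):
            name = f"c{k}_{i}"
            names.append(name)
            vals.append(v)
            assign[name] = k
    table = cp.CohortTable(pd.Series(assign), len(values_by_cohort),
                           len(values_by_cohort[0]), [])
    return pd.Series(vals, index=names), table


class TestCohortSummary:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        vals, ct = toy_cohorts([rng.normal(10, 1, 50) for _ in range(10)])
        summ = cp.cohort_summary(vals, ct)
        assert summ.anova_p > 0.01
        assert summ.significant_vs_bottom() == []

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(15 if k < 3 else 10, 1, 50) for k in range(10)]
        vals, ct = toy_cohorts(groups)
        summ = cp.cohort_summary(vals, ct)
        assert summ.anova_p < 1e-6
        assert summ.significant_vs_bottom(direction="greater") == [1, 2, 3]

    def test_missing_peaks_rejected(self):
        vals, ct = toy_cohorts([np.ones(3) for _ in range(10)])
        with pytest.raises(ValueError, match="missing"):
            cp.cohort_summary(vals.iloc[:-2], ct)


class TestFoldChange:
    def test_identity_conditions_give_unit_fc(self):
        rng = np.random.default_rng(1)
        vals, ct = toy_cohorts([rng.uniform(5, 50, 30) for _ in range(10)])
        fc, summ = cp.fold_change(vals, vals, ct)
        assert np.allclose(fc, 1.0)
        assert np.allclose(summ.table["mean"], 1.0)

    def test_mismatched_universe_rejected(self):
        vals, ct = toy_cohorts([np.ones(3) for _ in range(10)])
        other = vals.copy()
        other.index = [f"z{i}" for i in range(len(other))]
        with pytest.raises(ValueError):
            cp.fold_change(vals, other, ct)


class TestAnchor:
    def test_identical_signals_factor_one(self):
        s = pd.Series([1.0, 2, 3], index=list("abc"))
        assert cp.gfi1_anchor_factor(s, s) == 1.0

    def test_halved_signal_factor_two(self):
        s = pd.Series([1.0, 2, 3], index=list("abc"))
        assert cp.gfi1_anchor_factor(s * 0.5, s) == pytest.approx(2.0)

    def test_zero_kd_signal_rejected(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            cp.gfi1_anchor_factor(s * 0, s)

    def test_anchored_gfi1_cohort_ratio_is_one_without_noise(self):
        """Self-consistency: after anchoring, GFI1 KD/NTC is 1 everywhere."""
        cfg = cp.SimulationConfig(seed=13, chrom_lengths={"chr1": 1_000_000},
                                  n_sites=100, n_control_sites=0, n_genes=0,
                                  noise=False)
        g = cp.generate_genome(cfg)
        truth = cp.plant_sites(g, cfg)
        tracks = cp.render_tracks(truth, g, cfg)
        hp = cp.emit_peaks(truth, g, cfg)["hmg20b"]
        ct = cp.assign_cohorts(hp, 10)
        kd = cp.window_signal(tracks[("gfi1", "kd")], hp, 300)
        ntc = cp.window_signal(tracks[("gfi1", "ntc")], hp, 300)
        anchor = cp.gfi1_anchor_factor(kd, ntc)
        _, summ = cp.fold_change(cp.apply_anchor(kd, anchor), ntc, ct)
        assert np.allclose(summ.table["mean"], 1.0, atol=1e-6)


class TestRatio:
    def test_equal_tracks_unit_ratio(self):
        rng = np.random.default_rng(2)
        vals, ct = toy_cohorts([rng.uniform(5, 50, 20) for _ in range(10)])
        frame, summ = cp.lsd1_gfi1_ratio(vals, vals, vals, vals, ct)
        assert np.allclose(frame["change"], 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals, ct = toy_cohorts([rng.uniform(5, 50, 20) for _ in range(10)])
        other = vals * 1.7
        f1, _ = cp.lsd1_gfi1_ratio(vals, vals, other, other, ct, pseudocount=0.0)
        f2, _ = cp.lsd1_gfi1_ratio(vals * 2, vals * 2, other * 2, other * 2, ct,
                                   pseudocount=0.0)
        np.testing.assert_allclose(f1["change"], f2["change"])


class TestLossCorrelation:
    def test_equal_losses_r_one(self):
        loss = pd.Series(np.arange(10, dtype=float) + 1)
        r, p = cp.loss_correlation(loss, loss)
        assert r == pytest.approx(1.0)

    def test_uncoupled_retention_breaks_correlation(self):
        """With no planted LSD1 knockdown response, cohort LSD1 losses are
        pure noise and do not track the HMG20B losses."""
        cfg = cp.SimulationConfig(seed=17, chrom_lengths={"chr1": 2_000_000,
                                                          "chr2": 2_000_000},
                                  n_sites=800, n_control_sites=0, n_genes=0,
                                  lsd1_coupled=False)
        g = cp.generate_genome(cfg)
        truth = cp.plant_sites(g, cfg)
        tracks = cp.render_tracks(truth, g, cfg)
        hp = cp.emit_peaks(truth, g, cfg)["hmg20b"]
        ct = cp.assign_cohorts(hp, 10)
        ws = lambda key: cp.window_signal(tracks[key], hp, 300)
        anchor = cp.gfi1_anchor_factor(ws(("gfi1", "kd")), ws(("gfi1", "ntc")))
        loss_l = cp.cohort_loss(ws(("lsd1", "ntc")),
                                cp.apply_anchor(ws(("lsd1", "kd")), anchor), ct)
        loss_h = cp.cohort_loss(ws(("hmg20b", "ntc")),
                                cp.apply_anchor(ws(("hmg20b", "kd")), anchor), ct)
        r, _ = cp.loss_correlation(loss_l, loss_h)
        assert abs(r) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cp.loss_correlation(pd.Series([1.0, 2]), pd.Series([1.0, 2]))


class TestStrengthSignalRelation:
    def test_constant_mark_equal_medians(self):
        vals, ct = toy_cohorts([np.full(20, 4.0) for _ in range(10)])
        rel = cp.strength_signal_relation(vals, ct)
        assert (rel.table["median"] == 4.0).all()

    def test_inverse_relation_recovered(self, tracks, peaksets, hmg20b_cohorts):
        k27 = cp.window_signal(tracks[("h3k27ac", "ntc")], peaksets["hmg20b"], 1000)
        rel = cp.strength_signal_relation(k27, hmg20b_cohorts)
        med = rel.table["median"]
        assert med[1] < med[2] < med[3]  # depressed acetylation at strong peaks

    def test_flat_mark_shows_no_relation(self, tracks, peaksets, hmg20b_cohorts):
        k4 = cp.window_signal(tracks[("h3k4me1", "ntc")], peaksets["hmg20b"], 1000)
        rel = cp.strength_signal_relation(k4, hmg20b_cohorts)
        assert rel.spearman_p > 0.05
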