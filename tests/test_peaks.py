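"""Peak I/O dialects, threshold filtering, strength cohorts, annotation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cooccupy as cp
from cooccupy.peaks import PEAK_COLUMNS


def make_peakset(pileups, fes=None, chrom="chr1", spacing=1000, factor="x"):
    pileups = np.asarray(pileups, float)
    n = len(pileups)
    fes = np.full(n, 10.0) if fes is None else np.asarray(fes, float)
    starts = np.arange(n) * spacing
    df = pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + 200,
        "summit": starts + 100, "pileup": pileups, "fold_enrichment": fes,
        "name": [f"{factor}{i}" for i in range(n)],
    })
    return cp.PeakSet(df, factor=factor)


class TestNarrowPeakIO:
    def test_summit_and_pileup_from_dialect(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t0\t.\t8.0\t5.0\t3.0\t50\n")
        ps = cp.read_narrowpeak(f)
        assert len(ps) == 1
        p = next(iter(ps))
        assert (p.summit, p.pileup) == (150, 8.0)
        assert math.isinf(p.fold_enrichment)

    def test_missing_summit_offset_uses_midpoint(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t201\tp1\t0\t.\t8.0\t5.0\t3.0\t-1\n")
        assert next(iter(cp.read_narrowpeak(f))).summit == (100 + 201) // 2

    def test_wrong_column_count_reports_line(self, tmp_path):
        f = tmp_path / "a.narrowPeak"
        f.write_text("chr1\t100\t200\tp1\t0\t.\t8.0\t5.0\t3.0\n")
        with pytest.raises(ValueError, match=":1:"):
            cp.read_narrowpeak(f)

    def test_round_trip_preserves_summits_and_pileups(self, tmp_path, peaksets):
        ps = peaksets["hmg20b"]
        f = tmp_path / "h.narrowPeak"
        cp.write_narrowpeak(ps, f)
        back = cp.read_narrowpeak(f, factor="hmg20b")
        assert back.df["summit"].tolist() == ps.df["summit"].tolist()
        assert back.df["pileup"].tolist() == ps.df["pileup"].tolist()


class TestMacs2XlsIO:
    def test_one_based_summit_converted(self, tmp_path):
        f = tmp_path / "a.xls"
        f.write_text(
            "# comment\nchr\tstart\tend\tlength\tabs_summit\tpileup\t"
            "-log10(pvalue)\tfold_enrichment\t-log10(qvalue)\tname\n"
            "chr1\t101\t200\t100\t151\t60\t10\t6.5\t8\tp1\n"
        )
        p = next(iter(cp.read_macs2_xls(f)))
        assert (p.start, p.end, p.summit) == (100, 200, 150)
        assert (p.pileup, p.fold_enrichment) == (60.0, 6.5)

    def test_comment_only_file_is_empty_set(self, tmp_path):
        f = tmp_path / "a.xls"
        f.write_text("# nothing\n# here\n")
        assert len(cp.read_macs2_xls(f)) == 0

    def test_missing_column_errors(self, tmp_path):
        f = tmp_path / "a.xls"
        f.write_text("chr\tstart\tend\tpileup\nchr1\t1\t10\t5\n")
        with pytest.raises(ValueError, match="abs_summit"):
            cp.read_macs2_xls(f)

    def test_xls_narrowpeak_round_trip(self, tmp_path, peaksets):
        """xls -> internal -> narrowPeak -> internal keeps summit/pileup."""
        ps = peaksets["gfi1"]
        xls = tmp_path / "g.xls"
        npk = tmp_path / "g.narrowPeak"
        cp.write_macs2_xls(ps, xls)
        mid = cp.read_macs2_xls(xls)
        assert mid.df["summit"].tolist() == ps.df["summit"].tolist()
        assert mid.df["fold_enrichment"].tolist() == ps.df["fold_enrichment"].tolist()
        cp.write_narrowpeak(mid, npk)
        back = cp.read_narrowpeak(npk, sidecar_xls=xls)
        assert back.df["summit"].tolist() == ps.df["summit"].tolist()
        assert back.df["pileup"].tolist() == ps.df["pileup"].tolist()
        assert back.df["fold_enrichment"].tolist() == ps.df["fold_enrichment"].tolist()


class TestFilterPeaks:
    def test_joint_thresholds(self):
        ps = make_peakset([60, 40, 55], fes=[6, 6, 4])
        kept = cp.filter_peaks(ps, min_pileup=50, min_fe=5)
        assert kept.df["name"].tolist() == ["x0"]

    def test_no_thresholds_is_identity(self):
        ps = make_peakset([1, 2, 3])
        kept = cp.filter_peaks(ps, blacklist=None, min_pileup=0, min_fe=0)
        assert kept.df["name"].tolist() == ps.df["name"].tolist()

    def test_single_base_blacklist_overlap_excludes(self):
        ps = make_peakset([100.0])  # interval [0, 200)
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [199], "end": [300]})
        assert len(cp.filter_peaks(ps, blacklist=bl, min_pileup=0, min_fe=0)) == 0
        bl_adjacent = pd.DataFrame({"chrom": ["chr1"], "start": [200], "end": [300]})
        assert len(cp.filter_peaks(ps, blacklist=bl_adjacent, min_pileup=0, min_fe=0)) == 1

    @settings(deadline=None, max_examples=25)
    @given(
        pileups=st.lists(st.floats(0, 500, allow_nan=False), min_size=1, max_size=40),
        thr1=st.floats(0, 300),
        thr2=st.floats(0, 300),
    )
    def test_monotone_and_idempotent(self, pileups, thr1, thr2):
        ps = make_peakset(pileups)
        lo, hi = sorted([thr1, thr2])
        n_lo = len(cp.filter_peaks(ps, min_pileup=lo, min_fe=0))
        n_hi = len(cp.filter_peaks(ps, min_pileup=hi, min_fe=0))
        assert n_hi <= n_lo
        once = cp.filter_peaks(ps, min_pileup=lo, min_fe=0)
        twice = cp.filter_peaks(once, min_pileup=lo, min_fe=0)
        assert once.df.equals(twice.df)


class TestSelectTop:
    def test_strong_fraction_worked_examples(self):
        # 18,385 peaks of which 3,797 at pileup >= 110 -> 20.7%
        pil = np.concatenate([np.linspace(110, 900, 3797), np.linspace(50, 109.9, 18385 - 3797)])
        kept, frac = cp.select_top(make_peakset(pil), 110)
        assert (len(kept), frac) == (3797, 20.7)
        # 12,221 peaks of which 2,479 at pileup >= 135 -> 20.3%
        pil = np.concatenate([np.linspace(135, 900, 2479), np.linspace(50, 134.9, 12221 - 2479)])
        kept, frac = cp.select_top(make_peakset(pil), 135)
        assert (len(kept), frac) == (2479, 20.3)

    def test_zero_threshold_keeps_all(self):
        kept, frac = cp.select_top(make_peakset([1, 2, 3]), 0)
        assert (len(kept), frac) == (3, 100.0)

    def test_empty_input_errors(self):
        empty = cp.PeakSet(pd.DataFrame(columns=PEAK_COLUMNS))
        with pytest.raises(ValueError):
            cp.select_top(empty, 10)


class TestAssignCohorts:
    def test_ten_cohorts_of_1838_with_5_discarded(self):
        rng = np.random.default_rng(0)
        ps = make_peakset(rng.uniform(50, 1000, 18385))
        ct = cp.assign_cohorts(ps, 10)
        assert ct.cohort_size == 1838
        assert len(ct.discarded) == 5
        assert all(len(ct.members(k)) == 1838 for k in range(1, 11))

    def test_singleton_cohorts_in_strength_order(self):
        ps = make_peakset([5, 9, 1, 7, 3, 8, 2, 6, 4, 10])
        ct = cp.assign_cohorts(ps, 10)
        strongest = ct.members(1)[0]
        assert ps.df.set_index("name").loc[strongest, "pileup"] == 10

    def test_floor_rule(self):
        ct = cp.assign_cohorts(make_peakset(np.arange(23) + 1.0), 10)
        assert ct.cohort_size == 2 and len(ct.discarded) == 3

    def test_too_few_peaks_errors(self):
        with pytest.raises(ValueError):
            cp.assign_cohorts(make_peakset([1, 2]), 10)

    def test_partition_and_strength_ordering(self):
        rng = np.random.default_rng(1)
        ps = make_peakset(rng.uniform(0, 100, 97))
        ct = cp.assign_cohorts(ps, 10)
        assert set(ct.retained) | set(ct.discarded) == set(ps.df["name"])
        by_name = ps.df.set_index("name")["pileup"]
        for k in range(1, 10):
            assert by_name[ct.members(k)].min() >= by_name[ct.members(k + 1)].max()
        assert by_name[ct.discarded].max() <= by_name[ct.members(10)].min()


def simple_gene_table():
    return pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "strand": ["+", "-"],
        "tss": [10_000, 50_000],
        "tes": [15_000, 45_000],
    })


class TestAnnotatePeaks:
    def test_upstream_summit_is_promoter(self):
        ps = make_peakset([10.0], spacing=0)
        ps.df.loc[0, ["start", "end", "summit"]] = [9600, 9800, 9700]  # 300 bp upstream
        res = cp.annotate_peaks(ps, simple_gene_table())
        assert res.categories.iloc[0] == "promoter"

    def test_far_summit_is_intergenic(self):
        ps = make_peakset([10.0])
        ps.df.loc[0, ["start", "end", "summit"]] = [99_000, 99_400, 99_200]
        res = cp.annotate_peaks(ps, simple_gene_table())
        assert res.categories.iloc[0] == "intergenic"

    def test_counts_match_constructed_placements(self):
        genes = pd.DataFrame({
            "gene_id": ["gA"], "chrom": ["chr1"], "strand": ["+"],
            "tss": [10_000], "tes": [20_000],
            "exon_starts": ["10000,19700"], "exon_ends": ["10300,20000"],
            "cds_lo": [10_250], "cds_hi": [19_900],
        })
        placements = {  # summit -> planted category
            9_500: "promoter", 10_150: "5'UTR", 19_950: "3'UTR",
            10_270: "exon", 15_000: "intron", 20_500: "TTS", 40_000: "intergenic",
        }
        df = pd.DataFrame({
            "chrom": "chr1",
            "start": [s - 50 for s in placements],
            "end": [s + 50 for s in placements],
            "summit": list(placements),
            "pileup": 10.0, "fold_enrichment": 10.0,
            "name": [f"p{s}" for s in placements],
        })
        res = cp.annotate_peaks(cp.PeakSet(df), genes)
        assert list(res.categories) == list(placements.values())
        assert res.counts.sum() == len(placements)

    def test_unknown_chromosome_warns(self):
        ps = make_peakset([10.0], chrom="chrUn")
        with pytest.warns(UserWarning, match="chrUn"):
            res = cp.annotate_peaks(ps, simple_gene_table())
        assert res.categories.iloc[0] == "intergenic"
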