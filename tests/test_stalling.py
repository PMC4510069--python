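import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stallkit.annotation import Transcript
from stallkit.intervals import ReadAlignment
from stallkit.peaks import Peak
from stallkit.quantify import InMemoryReadSource
from stallkit.stalling import (
    compute_stalling_table,
    results_to_frame,
    si_distribution_summary,
    stalling_index,
    travelling_ratio,
    write_stalling_tsv,
)

from conftest import gi


class TestRatios:
    @pytest.mark.parametrize(
        "tss, gb, expected_si", [(100, 50, 2.0), (0, 50, 0.0), (3, 4, 0.75)]
    )
    def test_stalling_index(self, tss, gb, expected_si):
        assert stalling_index(tss, gb) == pytest.approx(expected_si)

    def test_si_undefined_when_gb_zero(self):
        assert math.isnan(stalling_index(10, 0))

    def test_tr_is_reciprocal_convention(self):
        assert travelling_ratio(100, 50) == pytest.approx(0.5)
        assert math.isnan(travelling_ratio(0, 50))

    def test_width_normalized_mode(self):
        # densities: (100/601) / (50/4700)
        si = stalling_index(100, 50, normalize_by_width=True, widths=(601, 4700))
        assert si == pytest.approx((100 / 601) / (50 / 4700))
        with pytest.raises(ValueError):
            stalling_index(100, 50, normalize_by_width=True)

    def test_pseudocount_defines_zero_denominator(self):
        assert stalling_index(10, 0, pseudocount=1) == pytest.approx(11.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            stalling_index(-1, 5)
        with pytest.raises(ValueError):
            travelling_ratio(5, -1)

    @settings(max_examples=200, deadline=None)
    @given(tss=st.integers(0, 10_000), gb=st.integers(0, 10_000))
    def test_reciprocal_identity(self, tss, gb):
        si, tr = stalling_index(tss, gb), travelling_ratio(tss, gb)
        if not math.isnan(si) and not math.isnan(tr) and si > 0:
            assert abs(si * tr - 1) < 1e-12

    @settings(max_examples=100, deadline=None)
    @given(tss=st.integers(0, 1000), gb=st.integers(1, 1000), scale=st.integers(1, 50))
    def test_scale_invariance(self, tss, gb, scale):
        assert stalling_index(tss * scale, gb * scale) == pytest.approx(
            stalling_index(tss, gb)
        )

    @settings(max_examples=100, deadline=None)
    @given(tss=st.integers(0, 1000), gb=st.integers(1, 1000))
    def test_monotone_in_tss_count(self, tss, gb):
        assert stalling_index(tss + 1, gb) > stalling_index(tss, gb)


def toy_transcripts():
    """Lengths 500 / 601 / 2000 / 2000; well-separated on one chromosome."""
    return [
        Transcript("t_short", "g1", gi("chr1", 10_000, 10_500, "+")),
        Transcript("t_601", "g2", gi("chr1", 50_000, 50_601, "+")),
        Transcript("t_peakless", "g3", gi("chr1", 100_000, 102_000, "-")),
        Transcript("t_long", "g4", gi("chr1", 150_000, 152_000, "+")),
    ]


def tss_peak(t):
    tss = t.interval.start if t.strand == "+" else t.interval.end - 1
    return Peak(gi(t.chrom, tss - 50, tss + 50), 0.0, 10.0)


class TestFilterCascade:
    def test_toy_filters_leave_exactly_two(self):
        """Length filter drops the 500 bp transcript, short one passes at 601;
        peak filter drops the peakless transcript; 2 transcripts get an SI."""
        txs = toy_transcripts()
        peaks = [tss_peak(txs[0]), tss_peak(txs[1]), tss_peak(txs[3])]
        source = InMemoryReadSource(
            [ReadAlignment(gi("chr1", 10_000 + i, 10_050 + i, "+")) for i in range(5)]
        )
        results = compute_stalling_table(source, txs, peaks)
        by_id = {r.transcript_id: r for r in results}
        assert len(results) == 4
        assert [r.transcript_id for r in results] == sorted(by_id)  # deterministic
        assert not by_id["t_short"].passed_length and by_id["t_short"].passed_peak
        assert by_id["t_peakless"].passed_length and not by_id["t_peakless"].passed_peak
        assert sum(r.passed_length and r.passed_peak for r in results) == 2
        for r in results:
            if not (r.passed_length and r.passed_peak):
                assert math.isnan(r.si) and math.isnan(r.tr)

    def test_empty_peak_list_yields_no_si(self):
        source = InMemoryReadSource([])
        results = compute_stalling_table(source, toy_transcripts(), [])
        assert all(math.isnan(r.si) for r in results)

    def test_hand_placed_reads_give_exact_ratios(self):
        """Five transcripts with hand-placed reads; SI matches manual counts."""
        txs = [
            Transcript(f"tx{i}", f"g{i}", gi("chr1", 100_000 * (i + 1),
                                             100_000 * (i + 1) + 2000, "+"))
            for i in range(5)
        ]
        peaks = [tss_peak(t) for t in txs]
        reads = []
        # transcript i gets 2*i reads in its TSS window and 4 in its GB interior
        for i, t in enumerate(txs):
            tss = t.interval.start
            reads += [
                ReadAlignment(gi("chr1", tss - 20 + j, tss + 30 + j, "+"))
                for j in range(2 * i)
            ]
            reads += [
                ReadAlignment(gi("chr1", tss + 1000 + 40 * j, tss + 1050 + 40 * j, "+"))
                for j in range(4)
            ]
        results = compute_stalling_table(InMemoryReadSource(reads), txs, peaks)
        expected_si = {f"tx{i}": (2 * i) / 4 for i in range(5)}
        for r in results:
            assert r.si == pytest.approx(expected_si[r.transcript_id])
            assert (r.tss_count, r.gb_count) == (2 * int(r.transcript_id[2]), 4)


class TestSummary:
    def _results(self, sis):
        from stallkit.stalling import StallingResult

        return [
            StallingResult(f"t{i}", 10, 10, si, 1 / si if si else math.nan, True, True)
            for i, si in enumerate(sis)
        ]

    def test_median(self):
        summary = si_distribution_summary(self._results([1.0, 2.0, 3.0]))
        assert summary["quantiles"].loc["q50", "si"] == pytest.approx(2.0)

    def test_single_result_degenerate_quantiles(self):
        summary = si_distribution_summary(self._results([2.5]))
        assert (summary["quantiles"]["si"] == 2.5).all()

    def test_all_undefined_gives_empty_summary(self, caplog):
        summary = si_distribution_summary(self._results([math.nan]))
        assert summary["quantiles"].empty and summary["histograms"].empty

    def test_si_histogram_bins_are_log_spaced(self):
        summary = si_distribution_summary(self._results([0.1, 1.0, 10.0] * 10))
        si_bins = summary["histograms"].query("metric == 'si'")
        edges = si_bins["bin_left"].to_numpy()
        ratios = edges[1:] / edges[:-1]
        assert np.allclose(ratios, ratios[0])
        assert int(si_bins["count"].sum()) == 30

    def test_simulated_cohort_median_near_binomial_expectation(self, small_cohort):
        source = InMemoryReadSource(small_cohort["reads"])
        from stallkit.peaks import pool_replicates

        peaks = pool_replicates(small_cohort["replicate_peaks"], "union")
        results = compute_stalling_table(
            source, small_cohort["transcripts"], peaks, mode="five_prime"
        )
        summary = si_distribution_summary(results)
        p = small_cohort["config"].pause_fraction
        median = summary["quantiles"].loc["q50", "si"]
        # 1000 reads/transcript: generous band around p/(1-p)
        assert median == pytest.approx(p / (1 - p), rel=0.15)


class TestOutput:
    def test_tsv_roundtrip_columns(self, tmp_path):
        import pandas as pd

        txs = toy_transcripts()
        results = compute_stalling_table(
            InMemoryReadSource([]), txs, [tss_peak(txs[1])]
        )
        path = tmp_path / "si.tsv"
        write_stalling_tsv(results, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == [
            "transcript_id", "tss_count", "gb_count", "si", "tr",
            "passed_length", "passed_peak",
        ]
        assert len(df) == 4

    def test_frame_flags_match_results(self):
        txs = toy_transcripts()
        results = compute_stalling_table(InMemoryReadSource([]), txs, [])
        df = results_to_frame(results)
        assert not df["passed_peak"].any()
        assert df["passed_length"].sum() == 3
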