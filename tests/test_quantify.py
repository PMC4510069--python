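import numpy as np
import pytest

from stallkit.intervals import GenomicInterval, ReadAlignment, overlaps
from stallkit.quantify import (
    BamReadSource,
    InMemoryReadSource,
    count_reads_in_window,
    tss_gb_counts,
)
from stallkit.simulate import write_bam

from conftest import gi


def read(start, end, strand="+", mapq=60):
    return ReadAlignment(gi("chr1", start, end, strand), mapq)


def brute_force_count(reads, window, mode="overlap", min_mapq=0):
    n = 0
    for r in reads:
        if r.mapping_quality < min_mapq:
            continue
        if mode == "overlap":
            n += overlaps(r.interval, window)
        else:
            n += window.chrom == r.interval.chrom and (
                window.start <= r.five_prime < window.end
            )
    return n


class TestCountModes:
    def test_overlap_counts_span_touches(self):
        reads = [read(100, 150), read(120, 170), read(180, 199), read(250, 300)]
        window = gi("chr1", 100, 200)
        assert count_reads_in_window(InMemoryReadSource(reads), window) == 3

    def test_five_prime_uses_strand_aware_end(self):
        window = gi("chr1", 100, 200)
        spanning_fwd = read(95, 105, "+")  # 5' end 95, outside
        spanning_rev = read(95, 105, "-")  # 5' end 104, inside
        src = InMemoryReadSource([spanning_fwd, spanning_rev])
        assert count_reads_in_window(src, window, "overlap") == 2
        assert count_reads_in_window(src, window, "five_prime") == 1

    def test_mapq_filter(self):
        src = InMemoryReadSource([read(100, 150, mapq=5), read(100, 150, mapq=60)])
        assert count_reads_in_window(src, gi("chr1", 0, 1000), min_mapq=30) == 1

    def test_dedup_collapses_identical_spans(self):
        src = InMemoryReadSource([read(100, 150)] * 4 + [read(100, 150, "-")])
        window = gi("chr1", 0, 1000)
        assert count_reads_in_window(src, window) == 5
        assert count_reads_in_window(src, window, dedup=True) == 2

    def test_unknown_chromosome_counts_zero(self):
        src = InMemoryReadSource([read(100, 150)])
        assert count_reads_in_window(src, gi("chrZ", 0, 1000)) == 0

    def test_overlap_count_dominates_five_prime(self):
        rng = np.random.default_rng(5)
        reads = [
            read(int(s), int(s) + 50, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 3000, size=300)
        ]
        src = InMemoryReadSource(reads)
        for _ in range(20):
            s = int(rng.integers(0, 2900))
            w = gi("chr1", s, s + int(rng.integers(1, 200)))
            assert count_reads_in_window(src, w, "overlap") >= count_reads_in_window(
                src, w, "five_prime"
            )


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["overlap", "five_prime"])
    def test_random_reads_match_brute_force(self, mode):
        rng = np.random.default_rng(42)
        reads = [
            read(int(s), int(s) + int(w), "+" if rng.random() < 0.5 else "-")
            for s, w in zip(
                rng.integers(0, 5000, size=800), rng.integers(20, 120, size=800)
            )
        ]
        src = InMemoryReadSource(reads)
        for _ in range(50):
            s = int(rng.integers(0, 4900))
            window = gi("chr1", s, s + int(rng.integers(1, 400)))
            assert count_reads_in_window(src, window, mode) == brute_force_count(
                reads, window, mode
            )

    def test_count_invariant_under_read_permutation(self):
        rng = np.random.default_rng(0)
        reads = [read(int(s), int(s) + 40) for s in rng.integers(0, 2000, size=200)]
        window = gi("chr1", 500, 900)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert count_reads_in_window(
            InMemoryReadSource(reads), window
        ) == count_reads_in_window(InMemoryReadSource(shuffled), window)


class TestBamSource:
    def test_bam_counts_match_in_memory(self, tmp_path):
        rng = np.random.default_rng(9)
        reads = [
            ReadAlignment(
                GenomicInterval(
                    "chrS", int(s), int(s) + 50, "+" if rng.random() < 0.5 else "-"
                ),
                60,
            )
            for s in rng.integers(0, 9000, size=500)
        ]
        path = write_bam(reads, 10_000, tmp_path / "r.bam")
        mem = InMemoryReadSource(reads)
        with BamReadSource(path) as bam:
            for _ in range(25):
                s = int(rng.integers(0, 8900))
                w = GenomicInterval("chrS", s, s + int(rng.integers(1, 500)))
                for mode in ("overlap", "five_prime"):
                    assert count_reads_in_window(bam, w, mode) == count_reads_in_window(
                        mem, w, mode
                    )

    def test_missing_index_raises(self, tmp_path):
        path = write_bam([ReadAlignment(GenomicInterval("chrS", 0, 50, "+"))], 100,
                         tmp_path / "r.bam")
        (tmp_path / "r.bam.bai").unlink()
        with pytest.raises(FileNotFoundError):
            BamReadSource(path)

    def test_unknown_chromosome_zero(self, tmp_path):
        path = write_bam([ReadAlignment(GenomicInterval("chrS", 0, 50, "+"))], 100,
                         tmp_path / "r.bam")
        with BamReadSource(path) as bam:
            assert count_reads_in_window(bam, gi("chr9", 0, 100)) == 0


class TestTssGbCounts:
    def test_constructed_fixture(self, plus_transcript):
        # TSS window [9700,10301), GB [10300,15000)
        reads = (
            [read(9800 + i * 10, 9850 + i * 10) for i in range(10)]  # 10 in TSS
            + [read(11000 + i * 100, 11050 + i * 100) for i in range(5)]  # 5 in GB
            + [read(20000, 20050)]  # elsewhere
        )
        wc = tss_gb_counts(InMemoryReadSource(reads), plus_transcript)
        assert (wc.tss_count, wc.gb_count) == (10, 5)
        assert (wc.tss_width, wc.gb_width) == (601, 4700)

    def test_zero_coverage(self, plus_transcript):
        wc = tss_gb_counts(InMemoryReadSource([read(0, 50)]), plus_transcript)
        assert (wc.tss_count, wc.gb_count) == (0, 0)

    def test_shared_base_policy(self, plus_transcript):
        # read covering only the shared base 10300
        shared_read = read(10300, 10301)
        src = InMemoryReadSource([shared_read])
        both = tss_gb_counts(src, plus_transcript)
        assert (both.tss_count, both.gb_count) == (1, 1)
        # disjoint mode attributes the boundary base to the gene body
        disjoint = tss_gb_counts(src, plus_transcript, disjoint=True)
        assert (disjoint.tss_count, disjoint.gb_count) == (0, 1)
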