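"""Synthetic annotations, RNAPII reads and replicate peak sets.

The simulator emulates the statistical structure the stalling index
quantifies — promoter-proximal RNAPII accumulation versus gene-body
travel — not the sequencing process.  Each transcript gets
``reads_per_transcript`` reads; each read independently lands in the
TSS window with probability ``pause_fraction`` (otherwise in the gene
body), with its 5' position uniform within the chosen window.  The TSS
count is therefore Binomial(n, p), and under 5'-end counting the
stalling index X/(n-X) concentrates around ``p / (1 - p)`` — an exact
analytic surface for end-to-end recovery tests.  There is no read-level
noise model (no sequencing errors, duplicates, GC bias or background
reads), and no between-replicate variability in true peak positions.

Transcripts are placed on a single chromosome so that no two gene-body
footprints (TSS flank through TES + tail) overlap; about half land on
each strand.  Peak replicates share TSS peaks on a random
``peak_fraction`` subset of transcripts and differ only by
replicate-private decoy peaks placed in the gaps between transcripts,
so that support-based pooling provably removes every decoy.

All randomness flows from ``SimulationConfig.seed`` through one
``numpy`` generator; identical configs give identical outputs, BAM
files included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .annotation import (
    DEFAULT_GB_OFFSET,
    DEFAULT_GB_TAIL,
    DEFAULT_TSS_FLANK,
    Transcript,
    derive_genebody_window,
    derive_tss_window,
)
from .intervals import STRAND_FWD, STRAND_REV, GenomicInterval, ReadAlignment
from .peaks import Peak

SIM_CHROM = "chrS"
#: clearance between consecutive transcript footprints; decoy peaks live here
_GAP = 1200
_DECOY_WIDTH = 400


@dataclass(frozen=True, slots=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a paused cohort.

    ``pause_fraction`` 0.8 reflects a strongly paused gene (4 TSS reads
    per gene-body read); ``reads_per_transcript`` 10,000 makes the
    binomial noise on the per-transcript SI about 1% so recovery tests
    measure bias, not sampling error.
    """

    n_transcripts: int = 200
    chrom_length: int | None = None  # derived from placement when None
    length_min: int = 1000
    length_max: int = 8000
    pause_fraction: float = 0.8
    reads_per_transcript: int = 10_000
    read_length: int = 50
    peak_fraction: float = 1.0
    n_replicates: int = 2
    decoys_per_replicate: int = 20
    seed: int = 0
    tss_flank: int = DEFAULT_TSS_FLANK
    gb_offset: int = DEFAULT_GB_OFFSET
    gb_tail: int = DEFAULT_GB_TAIL

    def __post_init__(self) -> None:
        if not 0 <= self.pause_fraction <= 1:
            raise ValueError("pause_fraction must be in [0, 1]")
        if not 0 <= self.peak_fraction <= 1:
            raise ValueError("peak_fraction must be in [0, 1]")
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        if self.n_transcripts < 0 or self.n_replicates < 1:
            raise ValueError("n_transcripts >= 0 and n_replicates >= 1 required")


def _margin(config: SimulationConfig) -> int:
    # room a transcript needs on BOTH genomic sides: the TSS flank on its
    # 5' side and the gene-body tail on its 3' side, whichever side each
    # falls on depends on strand, so reserve the larger of the two on both
    return max(config.tss_flank, config.gb_tail)


def simulate_annotation(config: SimulationConfig) -> tuple[list[Transcript], int]:
    """Place transcripts left-to-right; returns (transcripts, chrom_length).

    Each transcript occupies a private slot of ``margin + length + margin``
    bases, so no two derived windows can overlap regardless of strand.
    Deterministic given the seed; strands alternate via fair coin flips.
    Raises if an explicit ``chrom_length`` cannot host all transcripts.
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(config.length_min, config.length_max + 1,
                           size=config.n_transcripts)
    strands = rng.choice([STRAND_FWD, STRAND_REV], size=config.n_transcripts)
    margin = _margin(config)
    transcripts = []
    cursor = _GAP
    for i in range(config.n_transcripts):
        length = int(lengths[i])
        start = cursor + margin
        iv = GenomicInterval(SIM_CHROM, start, start + length, str(strands[i]))
        transcripts.append(Transcript(f"tx{i:04d}", f"gene{i:04d}", iv))
        cursor = start + length + margin + _GAP
    needed = cursor + _GAP
    if config.chrom_length is not None:
        if config.chrom_length < needed:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small; need >= {needed} "
                "to place all transcripts without overlapping windows"
            )
        needed = config.chrom_length
    return transcripts, needed


def _windows(t: Transcript, config: SimulationConfig) -> tuple[GenomicInterval, GenomicInterval]:
    return (
        derive_tss_window(t, config.tss_flank),
        derive_genebody_window(t, config.gb_offset, config.gb_tail),
    )


def simulate_rnapii_reads(
    transcripts: list[Transcript], config: SimulationConfig
) -> list[ReadAlignment]:
    """Draw reads per transcript; 5' positions are uniform in the chosen window.

    Reads align to their transcript's strand, so a forward read spans
    ``[pos, pos + read_length)`` and a reverse read ``[pos - read_length + 1,
    pos + 1)`` where ``pos`` is the sampled 5' coordinate.  All reads are
    single-end with mapping quality 60.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    reads: list[ReadAlignment] = []
    L = config.read_length
    for t in transcripts:
        tss_w, gb_w = _windows(t, config)
        in_tss = rng.random(config.reads_per_transcript) < config.pause_fraction
        n_tss = int(in_tss.sum())
        pos_tss = rng.integers(tss_w.start, tss_w.end, size=n_tss)
        pos_gb = rng.integers(gb_w.start, gb_w.end,
                              size=config.reads_per_transcript - n_tss)
        for pos in np.concatenate([pos_tss, pos_gb]):
            pos = int(pos)
            if t.strand == STRAND_FWD:
                iv = GenomicInterval(t.chrom, pos, pos + L, STRAND_FWD)
            else:
                iv = GenomicInterval(t.chrom, pos - L + 1, pos + 1, STRAND_REV)
            reads.append(ReadAlignment(iv, 60))
    return reads


def write_bam(
    reads: list[ReadAlignment], chrom_length: int, path, chrom: str = SIM_CHROM
) -> Path:
    """Write reads as a coordinate-sorted, indexed BAM (plus .bai)."""
    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_length}]}
    ordered = sorted(enumerate(reads), key=lambda ir: ir[1].interval.start)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in ordered:
            a = pysam.AlignedSegment()
            a.query_name = f"read{i:08d}"
            a.reference_id = 0
            a.reference_start = max(r.interval.start, 0)
            a.mapping_quality = r.mapping_quality
            a.is_reverse = r.interval.strand == STRAND_REV
            span = r.interval.end - max(r.interval.start, 0)
            a.cigarstring = f"{span}M"
            a.query_sequence = "A" * span
            a.query_qualities = pysam.qualitystring_to_array("I" * span)
            a.flag |= 0  # mapped, primary
            bam.write(a)
    pysam.index(str(path))
    return path


def simulate_peak_replicates(
    transcripts: list[Transcript],
    config: SimulationConfig,
) -> tuple[list[list[Peak]], dict[str, bool]]:
    """Replicate peak sets plus per-transcript truth of peak presence.

    A ``peak_fraction`` subset of transcripts receives, in *every*
    replicate, a peak covering its whole TSS window (significance
    -log10 p uniform in [6, 20]).  Each replicate additionally gets
    ``decoys_per_replicate`` private decoy peaks in inter-transcript
    gaps (significance uniform in [1, 6]); being private, decoys vanish
    under support pooling with k = n_replicates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(transcripts)
    has_peak = rng.random(n) < config.peak_fraction
    truth = {t.transcript_id: bool(h) for t, h in zip(transcripts, has_peak)}

    # the _GAP stretch between consecutive transcript slots hosts decoys
    margin = _margin(config)
    gaps = []
    prev_slot_end = 0
    for t in transcripts:
        slot_start = t.interval.start - margin
        gaps.append((prev_slot_end + 100, slot_start - _DECOY_WIDTH - 100))
        prev_slot_end = t.interval.end + margin
    usable_gaps = [(a, b) for a, b in gaps if b > a]

    replicates: list[list[Peak]] = []
    placed_decoys: list[tuple[int, int]] = []  # (replicate, start)
    for rep in range(config.n_replicates):
        label = f"rep{rep + 1}"
        peaks: list[Peak] = []
        for t, h in zip(transcripts, has_peak):
            if not h:
                continue
            w = derive_tss_window(t, config.tss_flank)
            sig = float(rng.uniform(6, 20))
            peaks.append(Peak(GenomicInterval(t.chrom, w.start, w.end), 0.0, sig, label))
        if usable_gaps:
            for _ in range(config.decoys_per_replicate):
                # decoys must stay private to their replicate: reject
                # positions overlapping another replicate's decoys
                for _attempt in range(50):
                    a, b = usable_gaps[int(rng.integers(len(usable_gaps)))]
                    s = int(rng.integers(a, b + 1))
                    if all(
                        rep_j == rep or s + _DECOY_WIDTH <= o or o + _DECOY_WIDTH <= s
                        for rep_j, o in placed_decoys
                    ):
                        break
                else:  # pragma: no cover - pathological decoy density
                    continue
                placed_decoys.append((rep, s))
                sig = float(rng.uniform(1, 6))
                peaks.append(
                    Peak(GenomicInterval(SIM_CHROM, s, s + _DECOY_WIDTH), 0.0, sig, label)
                )
        replicates.append(peaks)
    return replicates, truth


def write_truth_tsv(truth: dict[str, bool], config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tpause_fraction\thas_peak\n")
        for tid in sorted(truth):
            fh.write(f"{tid}\t{config.pause_fraction}\t{truth[tid]}\n")


def write_gtf(transcripts: list[Transcript], path) -> None:
    """Write transcripts as GTF (1-based closed coordinates on output)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\tstallkit_sim\ttranscript\t{t.interval.start + 1}"
                f"\t{t.interval.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


def simulate_cohort(config: SimulationConfig, out_dir=None):
    """One-call end-to-end simulation; optionally writes all files.

    Returns ``(transcripts, chrom_length, reads, replicate_peaks, truth)``;
    when ``out_dir`` is given also writes annotation.gtf, reads.bam(+bai),
    repN.narrowPeak and truth.tsv there.
    """
    transcripts, chrom_length = simulate_annotation(config)
    reads = simulate_rnapii_reads(transcripts, config)
    replicate_peaks, truth = simulate_peak_replicates(transcripts, config)
    if out_dir is not None:
        from .peaks import write_narrowpeak

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(transcripts, out / "annotation.gtf")
        write_bam(reads, chrom_length, out / "reads.bam")
        for i, rep in enumerate(replicate_peaks):
            write_narrowpeak(rep, out / f"rep{i + 1}.narrowPeak")
        write_truth_tsv(truth, config, out / "truth.tsv")
    return transcripts, chrom_length, reads, replicate_peaks, truth
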