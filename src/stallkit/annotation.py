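"""Transcript models and promoter / gene-body window derivation.

The stalling index compares RNAPII ChIP-seq signal in two windows per
transcript, defined in transcript orientation around the transcription
start site (TSS) and transcription end site (TES):

* **TSS window** — the closed genomic span ``[tss - flank, tss + flank]``
  (default flank 300 bp, width 601 bp).  It is symmetric around the TSS,
  so its genomic footprint does not depend on strand.
* **gene-body (GB) window** — from ``offset`` bases downstream of the TSS
  (default 300) through ``tail`` bases past the TES (default 3000),
  endpoints inclusive, mapped to genomic coordinates with a strand flip
  for minus-strand transcripts.

Because both windows are closed, they share exactly one base: the base
``offset`` bp downstream of the TSS.  A read overlapping only that base
is counted in both windows.  For users who want partition semantics,
``disjoint=True`` on :func:`derive_tss_window` makes the promoter window
half-open in transcription direction, ``[tss - flank, tss + flank)``, so
the boundary base belongs to the gene body alone (where elongation
begins) and every base is counted exactly once.

Transcript "length" throughout is the genomic span ``end - start``, not
the spliced mature length: the stalling index operates on genomic read
counts over genomic windows and never references exon structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .intervals import (
    STRAND_FWD,
    STRAND_REV,
    GenomicInterval,
    clamp,
    write_bed6,
)

DEFAULT_TSS_FLANK = 300
DEFAULT_GB_OFFSET = 300
DEFAULT_GB_TAIL = 3000
DEFAULT_MIN_LENGTH = 600


@dataclass(frozen=True, slots=True)
class Transcript:
    """One annotated transcript; the unit the stalling index is computed on."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in (STRAND_FWD, STRAND_REV):
            raise ValueError(
                f"transcript {self.transcript_id} must be stranded (+ or -)"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        """Genomic span in bp (end - start)."""
        return self.interval.width


class AnnotationParseError(ValueError):
    """Raised for malformed annotation records, carrying the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> list[Transcript]:
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    path, lineno, f"expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "transcript":
                continue
            if strand not in (STRAND_FWD, STRAND_REV):
                raise AnnotationParseError(
                    path, lineno, f"unstranded or invalid strand {strand!r}"
                )
            try:
                # GTF is 1-based closed; internal is 0-based half-open
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                raise AnnotationParseError(path, lineno, "missing transcript_id attribute")
            transcripts.append(
                Transcript(attr["transcript_id"], attr.get("gene_id", attr["transcript_id"]), iv)
            )
    return transcripts


def _parse_bed12(path: Path) -> list[Transcript]:
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationParseError(
                    path, lineno, f"expected >= 6 BED fields, got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in (STRAND_FWD, STRAND_REV):
                raise AnnotationParseError(
                    path, lineno, f"unstranded or invalid strand {strand!r}"
                )
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise AnnotationParseError(path, lineno, str(exc)) from exc
            transcripts.append(Transcript(name, name, iv))
    return transcripts


def read_transcripts(
    annotation_file, format: Literal["gtf", "bed12"] = "gtf"
) -> list[Transcript]:
    """Read transcript records from a GTF or BED12 file.

    GTF ``transcript`` feature lines are used (exon lines are ignored);
    1-based closed GTF coordinates are converted to the internal 0-based
    half-open convention.  BED12 names become both transcript and gene id.
    Unstranded records are rejected.
    """
    path = Path(annotation_file)
    if format == "gtf":
        return _parse_gtf(path)
    if format == "bed12":
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation format {format!r}")


def tss_position(t: Transcript) -> int:
    """0-based genomic coordinate of the first transcribed base."""
    return t.interval.start if t.strand == STRAND_FWD else t.interval.end - 1


def tes_position(t: Transcript) -> int:
    """0-based genomic coordinate of the last transcribed base."""
    return t.interval.end - 1 if t.strand == STRAND_FWD else t.interval.start


def derive_tss_window(
    t: Transcript,
    flank: int = DEFAULT_TSS_FLANK,
    chrom_length: int | None = None,
    disjoint: bool = False,
) -> GenomicInterval:
    """Closed window ``[tss - flank, tss + flank]`` as a half-open interval.

    Width is ``2 * flank + 1`` before any clamping; the genomic footprint
    is strand-symmetric.  With ``disjoint=True`` the downstream-most base
    (the one shared with the gene-body window) is dropped, width
    ``2 * flank``.
    """
    if flank < 1:
        raise ValueError("flank must be positive")
    tss = tss_position(t)
    if t.strand == STRAND_FWD:
        window = GenomicInterval(
            t.chrom, tss - flank, tss + flank + (0 if disjoint else 1), t.strand
        )
    else:
        window = GenomicInterval(
            t.chrom, tss - flank + (1 if disjoint else 0), tss + flank + 1, t.strand
        )
    if chrom_length is not None:
        window = clamp(window, chrom_length)
    elif window.start < 0:
        window = GenomicInterval(t.chrom, 0, window.end, t.strand)
    return window


def derive_genebody_window(
    t: Transcript,
    offset: int = DEFAULT_GB_OFFSET,
    tail: int = DEFAULT_GB_TAIL,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Closed window from ``tss + offset`` to ``tes + tail`` (transcript direction).

    Unclamped width is ``length - offset + tail``; the upstream end is the
    single base shared with the default TSS window.

    Raises
    ------
    ValueError
        If the transcript is not longer than ``offset`` (empty gene body).
    """
    if offset < 1 or tail < 1:
        raise ValueError("offset and tail must be positive")
    if t.length <= offset:
        raise ValueError(
            f"transcript {t.transcript_id} (length {t.length}) has no gene body "
            f"beyond offset {offset}"
        )
    if t.strand == STRAND_FWD:
        tss, tes = t.interval.start, t.interval.end - 1
        window = GenomicInterval(t.chrom, tss + offset, tes + tail + 1, t.strand)
    else:
        tss, tes = t.interval.end - 1, t.interval.start
        window = GenomicInterval(t.chrom, tes - tail, tss - offset + 1, t.strand)
    if chrom_length is not None:
        window = clamp(window, chrom_length)
    elif window.start < 0:
        window = GenomicInterval(t.chrom, 0, window.end, t.strand)
    return window


def passes_length_filter(t: Transcript, min_length: int = DEFAULT_MIN_LENGTH) -> bool:
    """True iff the transcript's genomic span is strictly above ``min_length``."""
    return t.length > min_length


def write_windows_bed6(
    transcripts: Iterable[Transcript],
    path,
    flank: int = DEFAULT_TSS_FLANK,
    offset: int = DEFAULT_GB_OFFSET,
    tail: int = DEFAULT_GB_TAIL,
) -> None:
    """Dump derived TSS and GB windows as BED6 for visual inspection."""
    rows = []
    for t in transcripts:
        rows.append((derive_tss_window(t, flank), f"{t.transcript_id}|TSS", 0.0))
        if t.length > offset:
            rows.append(
                (derive_genebody_window(t, offset, tail), f"{t.transcript_id}|GB", 0.0)
            )
    write_bed6(rows, path)
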