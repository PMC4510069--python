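"""Peak lists: loading, significance filtering, replicate pooling, TSS overlap.

Peak calls arrive as narrowPeak (10-column BED variant whose column 8 is
-log10 of the peak p-value) or plain BED.  Significance is kept on the
-log10(p) scale throughout — it is the narrowPeak native scale and avoids
underflow for very significant peaks; helpers convert raw p-value cutoffs.

Replicate pooling offers the two conventional rules:

* ``union`` — merge every replicate's peaks into one disjoint set; a base
  is pooled if any replicate called it.
* ``support_k`` — keep maximal regions covered by peaks from at least
  ``k`` distinct replicates (k = number of replicates gives the strict
  intersection; k = 1 reduces to union).

Pooled peaks carry the maximum -log10(p) over the contributing peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .annotation import DEFAULT_TSS_FLANK, Transcript, derive_tss_window
from .intervals import GenomicInterval, merge_intervals, overlaps

logger = logging.getLogger(__name__)

#: default significance cutoff: raw p <= 1e-5, i.e. -log10(p) >= 5
DEFAULT_MIN_NEG_LOG10_P = 5.0


@dataclass(frozen=True, slots=True)
class Peak:
    """A called enriched region with its significance.

    ``score`` is the display score (BED column 5); ``neg_log10_p`` is
    -log10 of the peak p-value (narrowPeak column 8).
    """

    interval: GenomicInterval
    score: float = 0.0
    neg_log10_p: float = 0.0
    replicate_label: str | None = None

    def __post_init__(self) -> None:
        if self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


class PeakParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def p_value_to_neg_log10(p: float) -> float:
    """Convert a raw p-value cutoff to the -log10 scale used internally."""
    if not 0 < p <= 1:
        raise ValueError("p-value must be in (0, 1]")
    return -math.log10(p)


def read_peaks(
    path, format: Literal["narrowPeak", "bed"] = "narrowPeak",
    replicate_label: str | None = None,
) -> list[Peak]:
    """Read a narrowPeak or BED peak file (coordinates already half-open).

    Plain BED files carry no significance column; their peaks default to
    ``neg_log10_p = 0`` with a logged warning, so every downstream filter
    with a positive threshold will drop them unless re-scored.
    """
    path = Path(path)
    peaks: list[Peak] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            min_cols = 10 if format == "narrowPeak" else 3
            if len(fields) < min_cols:
                raise PeakParseError(
                    path, lineno,
                    f"expected >= {min_cols} columns for {format}, got {len(fields)}",
                )
            try:
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                if format == "narrowPeak":
                    neg_log10_p = float(fields[7])
                else:
                    neg_log10_p = 0.0
                    if not warned:
                        logger.warning(
                            "%s: plain BED has no significance column; "
                            "neg_log10_p defaults to 0", path,
                        )
                        warned = True
            except ValueError as exc:
                raise PeakParseError(path, lineno, str(exc)) from exc
            peaks.append(Peak(iv, score, neg_log10_p, replicate_label))
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    """Write peaks as 10-column narrowPeak; provenance goes in the name column."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.replicate_label or f"peak_{i}"
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{p.score:g}\t{iv.strand}"
                f"\t0\t{p.neg_log10_p:g}\t-1\t-1\n"
            )


def filter_peaks(peaks: Sequence[Peak], min_neg_log10_p: float) -> list[Peak]:
    """Keep peaks with ``neg_log10_p >= min_neg_log10_p``; order preserved."""
    if min_neg_log10_p < 0:
        raise ValueError("min_neg_log10_p must be >= 0")
    return [p for p in peaks if p.neg_log10_p >= min_neg_log10_p]


def _max_significance_over(region: GenomicInterval, peaks: Sequence[Peak]) -> float:
    best = 0.0
    for p in peaks:
        if overlaps(region, p.interval):
            best = max(best, p.neg_log10_p)
    return best


def pool_replicates(
    replicate_peak_lists: Sequence[Sequence[Peak]],
    mode: Literal["union", "support_k"] = "union",
    k: int = 2,
) -> list[Peak]:
    """Pool peak calls across replicate experiments.

    See the module docstring for the two rules.  The pooled peak's
    ``neg_log10_p`` is the maximum over the peaks overlapping it, and its
    ``replicate_label`` records how many replicates were pooled.
    """
    if not replicate_peak_lists:
        raise ValueError("need at least one replicate peak list")
    n_rep = len(replicate_peak_lists)
    all_peaks = [p for rep in replicate_peak_lists for p in rep]

    if mode == "union":
        regions = merge_intervals(p.interval for p in all_peaks)
    elif mode == "support_k":
        if not 1 <= k <= n_rep:
            raise ValueError(f"k={k} must be in 1..{n_rep} (number of replicates)")
        regions = _support_regions(replicate_peak_lists, k)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")

    label = f"pooled_{mode}" + (f"_k{k}" if mode == "support_k" else "") + f"_n{n_rep}"
    return [
        Peak(r, 0.0, _max_significance_over(r, all_peaks), label) for r in regions
    ]


def _support_regions(
    replicate_peak_lists: Sequence[Sequence[Peak]], k: int
) -> list[GenomicInterval]:
    """Maximal regions where >= k distinct replicates have peak coverage.

    Sweep-line over per-replicate merged intervals: merging first makes
    each replicate contribute at most +1 to the depth at any base.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in replicate_peak_lists:
        for iv in merge_intervals(p.interval for p in rep):
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    regions: list[GenomicInterval] = []
    for chrom in sorted(events):
        depth = 0
        region_start: int | None = None
        # at equal positions apply closings before openings so that a
        # bookended end/start does not fake depth k across the junction
        for pos, delta in sorted(events[chrom], key=lambda e: (e[0], e[1])):
            new_depth = depth + delta
            if region_start is None and new_depth >= k > depth:
                region_start = pos
            elif region_start is not None and new_depth < k <= depth:
                regions.append(GenomicInterval(chrom, region_start, pos))
                region_start = None
            depth = new_depth
    # merge bookended fragments produced by coincident event positions
    return merge_intervals(regions) if regions else []


def has_peak_at_tss(
    t: Transcript,
    peaks: Iterable[Peak],
    flank: int = DEFAULT_TSS_FLANK,
    point: bool = False,
) -> bool:
    """True iff any peak overlaps the transcript's TSS window.

    By default "on the TSS" means overlapping the closed +/- ``flank``
    window around the TSS; with ``point=True`` the peak must cover the
    single TSS base itself.
    """
    if point:
        from .annotation import tss_position

        tss = tss_position(t)
        window = GenomicInterval(t.chrom, tss, tss + 1)
    else:
        window = derive_tss_window(t, flank)
    return any(overlaps(window, p.interval) for p in peaks)
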