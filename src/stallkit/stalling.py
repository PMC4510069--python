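"""The stalling index and travelling ratio, with the standard filters.

For a transcript with TSS-window read count ``TSS`` and gene-body count
``GB``:

* stalling index ``SI = TSS / GB`` — high values mean RNAPII accumulates
  at the promoter relative to the body (promoter-proximal pausing);
* travelling ratio ``TR = GB / TSS`` — the reciprocal convention, which
  parts of the literature also call the travelling ratio with the
  opposite orientation.  Both are emitted and labelled so downstream
  users never have to guess which convention a column holds.

A transcript receives an SI only if it passes both filters:

1. genomic length strictly above 600 bp (so the gene body is non-empty
   and well separated from the promoter window), and
2. an RNAPII peak overlapping its TSS window (so the ratio is computed
   where there is evidence of engaged polymerase at all).

``GB = 0`` leaves SI undefined (NaN) rather than infinite; a pseudocount
added to both windows is available but opt-in, because it changes
rankings.  SI uses raw read counts by default; width-normalised mode
``(TSS/width_TSS) / (GB/width_GB)`` is available where read *density*
is wanted instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_GB_OFFSET,
    DEFAULT_GB_TAIL,
    DEFAULT_MIN_LENGTH,
    DEFAULT_TSS_FLANK,
    Transcript,
    passes_length_filter,
)
from .peaks import Peak, has_peak_at_tss
from .quantify import CountMode, tss_gb_counts

logger = logging.getLogger(__name__)

SUMMARY_QUANTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True, slots=True)
class StallingResult:
    """Per-transcript counts, SI, TR and the filter flags that gate them.

    ``si`` / ``tr`` are NaN when undefined: for transcripts failing a
    filter (no counts computed) or with a zero denominator.
    """

    transcript_id: str
    tss_count: int
    gb_count: int
    si: float
    tr: float
    passed_length: bool
    passed_peak: bool

    @property
    def si_defined(self) -> bool:
        return not math.isnan(self.si)


def stalling_index(
    tss_count: float,
    gb_count: float,
    normalize_by_width: bool = False,
    widths: tuple[int, int] | None = None,
    pseudocount: float = 0.0,
) -> float:
    """SI = TSS / GB (raw counts), or a density ratio when width-normalised.

    Returns NaN when the (pseudocounted) gene-body count is zero.
    """
    if tss_count < 0 or gb_count < 0:
        raise ValueError("counts must be >= 0")
    tss = tss_count + pseudocount
    gb = gb_count + pseudocount
    if normalize_by_width:
        if widths is None:
            raise ValueError("normalize_by_width requires (tss_width, gb_width)")
        tss_w, gb_w = widths
        if gb == 0:
            return math.nan
        return (tss / tss_w) / (gb / gb_w)
    return tss / gb if gb > 0 else math.nan


def travelling_ratio(tss_count: float, gb_count: float, pseudocount: float = 0.0) -> float:
    """TR = GB / TSS; NaN when the (pseudocounted) TSS count is zero."""
    if tss_count < 0 or gb_count < 0:
        raise ValueError("counts must be >= 0")
    tss = tss_count + pseudocount
    gb = gb_count + pseudocount
    return gb / tss if tss > 0 else math.nan


def compute_stalling_table(
    alignments,
    transcripts: Sequence[Transcript],
    rnapii_peaks: Sequence[Peak],
    flank: int = DEFAULT_TSS_FLANK,
    gb_offset: int = DEFAULT_GB_OFFSET,
    gb_tail: int = DEFAULT_GB_TAIL,
    min_length: int = DEFAULT_MIN_LENGTH,
    mode: CountMode = "overlap",
    min_mapq: int = 0,
    dedup: bool = False,
    normalize_by_width: bool = False,
    pseudocount: float = 0.0,
    chrom_length: int | None = None,
    disjoint: bool = False,
) -> list[StallingResult]:
    """Apply the filter cascade and compute SI / TR for every transcript.

    Every input transcript appears in the output with its filter flags,
    sorted by transcript_id; counts and ratios are computed only for
    transcripts passing both the length and the peak-at-TSS filter
    (``rnapii_peaks`` should already be significance-filtered / pooled).
    """
    results: list[StallingResult] = []
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        ok_len = passes_length_filter(t, min_length)
        ok_peak = has_peak_at_tss(t, rnapii_peaks, flank)
        if ok_len and ok_peak:
            wc = tss_gb_counts(
                alignments, t, flank, gb_offset, gb_tail,
                mode, min_mapq, dedup, chrom_length, disjoint,
            )
            si = stalling_index(
                wc.tss_count, wc.gb_count, normalize_by_width,
                (wc.tss_width, wc.gb_width), pseudocount,
            )
            tr = travelling_ratio(wc.tss_count, wc.gb_count, pseudocount)
            results.append(
                StallingResult(t.transcript_id, wc.tss_count, wc.gb_count,
                               si, tr, True, True)
            )
        else:
            results.append(
                StallingResult(t.transcript_id, 0, 0, math.nan, math.nan,
                               ok_len, ok_peak)
            )
    return results


def results_to_frame(results: Iterable[StallingResult]) -> pd.DataFrame:
    """Tabulate results; the canonical on-disk TSV layout."""
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "tss_count": r.tss_count,
                "gb_count": r.gb_count,
                "si": r.si,
                "tr": r.tr,
                "passed_length": r.passed_length,
                "passed_peak": r.passed_peak,
            }
            for r in results
        ]
    )


def write_stalling_tsv(results: Iterable[StallingResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, na_rep="NA")


def si_distribution_summary(
    results: Sequence[StallingResult], n_bins: int = 25
) -> dict[str, pd.DataFrame]:
    """Quantiles and histograms of TSS counts, GB counts and SI.

    Only transcripts with a defined SI contribute.  SI histogram bins are
    log10-spaced (SI spans orders of magnitude); count histograms use
    linear bins.  Returns ``{"quantiles": ..., "histograms": ...}``; an
    all-undefined input yields empty frames with a logged warning.
    """
    defined = [r for r in results if r.si_defined]
    if not defined:
        logger.warning("no transcripts with a defined SI; empty summary")
        return {"quantiles": pd.DataFrame(), "histograms": pd.DataFrame()}

    series = {
        "tss_count": np.array([r.tss_count for r in defined], dtype=float),
        "gb_count": np.array([r.gb_count for r in defined], dtype=float),
        "si": np.array([r.si for r in defined], dtype=float),
    }
    quantiles = pd.DataFrame(
        {
            name: np.percentile(values, SUMMARY_QUANTILES)
            for name, values in series.items()
        },
        index=[f"q{q}" for q in SUMMARY_QUANTILES],
    )
    quantiles.index.name = "quantile"

    hist_rows = []
    for name, values in series.items():
        if name == "si":
            positive = values[values > 0]
            if positive.size == 0:
                continue
            lo, hi = np.log10(positive.min()), np.log10(positive.max())
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            edges = np.logspace(lo, hi, n_bins + 1)
        else:
            edges = np.histogram_bin_edges(values, bins=n_bins)
        counts, edges = np.histogram(values, bins=edges)
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append(
                {"metric": name, "bin_left": left, "bin_right": right, "count": int(c)}
            )
    return {"quantiles": quantiles, "histograms": pd.DataFrame(hist_rows)}


def plot_si_distributions(results: Sequence[StallingResult], path) -> None:
    """Three-panel figure: TSS counts, GB counts, SI (log-x), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    defined = [r for r in results if r.si_defined]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    panels = [
        ("TSS reads", [r.tss_count for r in defined], False),
        ("GB reads", [r.gb_count for r in defined], False),
        ("SI = TSS/GB", [r.si for r in defined if r.si > 0], True),
    ]
    for ax, (label, values, logx) in zip(axes, panels):
        if values:
            if logx:
                lo, hi = min(values), max(values)
                bins = np.logspace(np.log10(lo) - 0.01, np.log10(hi) + 0.01, 30)
                ax.set_xscale("log")
            else:
                bins = 30
            ax.hist(values, bins=bins, color="steelblue", edgecolor="none")
        ax.set_xlabel(label)
        ax.set_ylabel("transcripts")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
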