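"""Filter peak calls by significance and pool replicates two ways.

Two replicate peak lists disagree on exact boundaries and each carries
a private low-significance decoy.  Union pooling keeps everything any
replicate saw; support-based pooling (k=2) keeps only regions both
replicates support, which removes the decoys.
"""

from stallkit import GenomicInterval, Peak, filter_peaks, pool_replicates

rep1 = [
    Peak(GenomicInterval("chr1", 1000, 1600), neg_log10_p=12.0),
    Peak(GenomicInterval("chr1", 5000, 5400), neg_log10_p=9.0),
    Peak(GenomicInterval("chr1", 9000, 9300), neg_log10_p=6.5),   # rep1-only
    Peak(GenomicInterval("chr1", 20000, 20200), neg_log10_p=2.0),  # weak
]
rep2 = [
    Peak(GenomicInterval("chr1", 1100, 1700), neg_log10_p=11.0),
    Peak(GenomicInterval("chr1", 4900, 5300), neg_log10_p=10.0),
    Peak(GenomicInterval("chr1", 15000, 15350), neg_log10_p=7.0),  # rep2-only
]

# raw p <= 1e-5 means -log10(p) >= 5: drops the weak rep1 peak
replicates = [filter_peaks(r, min_neg_log10_p=5.0) for r in (rep1, rep2)]
print(f"peaks per replicate after p-filter: {[len(r) for r in replicates]}")

for mode, kwargs in [("union", {}), ("support_k", {"k": 2})]:
    pooled = pool_replicates(replicates, mode, **kwargs)
    spans = [f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
             f" (-log10p={p.neg_log10_p:g})" for p in pooled]
    print(f"{mode}: {len(pooled)} pooled peaks")
    for s in spans:
        print(f"  {s}")
# union keeps the replicate-private peaks; support_k=2 retains only the
# two regions covered by both replicates, trimmed to the shared bases,
# each carrying the best significance among its contributing peaks.
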