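"""Window derivation and counting semantics on a hand-built example.

Shows the strand-aware TSS/gene-body window arithmetic and the
difference between overlap counting and 5'-end counting for a read
straddling a window edge.
"""

from stallkit import (
    GenomicInterval,
    InMemoryReadSource,
    ReadAlignment,
    Transcript,
    count_reads_in_window,
    derive_genebody_window,
    derive_tss_window,
)

plus = Transcript("txP", "geneP", GenomicInterval("chr1", 10_000, 12_000, "+"))
minus = Transcript("txM", "geneM", GenomicInterval("chr1", 5_000, 8_000, "-"))

for t in (plus, minus):
    tss_w = derive_tss_window(t)
    gb_w = derive_genebody_window(t)
    print(f"{t.transcript_id} ({t.strand} strand, {t.length} bp): "
          f"TSS window [{tss_w.start},{tss_w.end}) width {tss_w.width}, "
          f"GB window [{gb_w.start},{gb_w.end}) width {gb_w.width}")
# widths: TSS is always 2*300+1 = 601; GB is length - 300 + 3000.
# The windows share exactly one base (300 bp downstream of the TSS).

edge_read = ReadAlignment(GenomicInterval("chr1", 9_690, 9_740, "+"))  # 5' end 9690
src = InMemoryReadSource([edge_read])
window = derive_tss_window(plus)  # [9700, 10301)
print(f"\nread [9690,9740) vs TSS window [{window.start},{window.end}):")
print("  overlap mode:   ", count_reads_in_window(src, window, "overlap"))
print("  five_prime mode:", count_reads_in_window(src, window, "five_prime"))
# the span overlaps the window (counted) but its 5'-most base 9690 lies
# upstream of it (not counted): 1 vs 0.
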