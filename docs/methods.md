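# Methods

## Model and definitions

For each transcript the stalling index is a ratio of RNAPII ChIP-seq
read counts in two windows defined in transcript orientation:

* promoter window (TSS): the closed interval `[tss − f, tss + f]` with
  flank `f = 300 bp`; width `2f + 1 = 601 bp`, strand-symmetric in its
  genomic footprint.
* gene-body window (GB): the closed interval from `tss + o`
  (`o = 300 bp`) to `TES + τ` (`τ = 3000 bp`), mapped to genomic
  coordinates with a strand flip for minus-strand transcripts; width
  `L − o + τ` for a transcript of genomic span `L`.

`SI = TSS/GB`; the travelling ratio `TR = GB/TSS` is its reciprocal and
both are reported, since the literature attaches the name "travelling
ratio" to both orientations. Where both are defined and nonzero,
`SI · TR = 1` holds to floating-point precision and is asserted in the
tests.

An SI is assigned only to transcripts with `L > 600 bp` (strict
inequality; at the 601 bp boundary the GB window is 3301 bp) and with at
least one peak overlapping the TSS window. Transcripts failing either
filter are retained in the output with their flags, not dropped, so the
filter cascade is auditable.

### Coordinate and boundary conventions

All internal coordinates are 0-based half-open (BED); GTF's 1-based
closed coordinates are converted at parse time. Overlap requires at
least one shared base — bookended intervals do not overlap. Because the
two windows are printed as closed intervals, they share the single base
`o` bp downstream of the TSS; a read overlapping only that base counts
in both windows by default. A `disjoint` option reassigns that base to
the gene body by making the promoter window half-open in transcript
direction (`[tss − f, tss + f)`), giving strict partition semantics;
this choice (rather than shifting the gene body) keeps the gene-body
window — the SI denominator and the larger, less noisy count —
identical across modes. Windows that run past a contig edge are clamped
to the contig, not dropped, preserving transcripts near edges;
intervals may carry transiently negative starts before clamping.
Transcript "length" is the genomic span, not the spliced mature length:
the SI operates on genomic windows and never references exon structure.

### Counting

Two read-counting modes share one contract: `overlap` counts a read if
its aligned span shares ≥ 1 base with the window (the common ChIP-seq
convention and the default); `five_prime` counts it if its 5′-most
aligned base lies in the window, so each read is attributed to exactly
one window of a disjoint partition. Secondary and supplementary
alignments are always excluded; duplicates are kept unless an opt-in
dedup flag collapses identical (start, end, strand) spans; a mapping
quality floor is available. No depth normalisation is applied anywhere:
SI is a within-sample ratio and is scale-invariant. SI uses raw counts
by default — a width-normalised variant `(TSS/601)/(GB/w_GB)` is
available where a read-density ratio is wanted instead, exposed as an
explicit option because the two differ by the constant window-width
ratio and change absolute (not relative) SI values. `GB = 0` yields an
undefined SI (NaN), excluded from summaries, rather than an infinity; a
pseudocount on both counts is opt-in since it perturbs rankings.

### Peaks

Significance is stored as −log10(p) (the narrowPeak convention; robust
to underflow). The significance cutoff and pooling rule are
configuration, defaulting to raw p ≤ 1e−5 (−log10 p ≥ 5) and union
pooling — conventional choices, both overridable, since no single
standard exists. Union pooling merges all replicates' peaks into
disjoint regions; support-k pooling keeps maximal regions covered by
≥ k distinct replicates, implemented as a sweep-line over per-replicate
merged intervals (merging first caps each replicate's contribution at
+1 per base; closings are applied before openings at equal positions so
bookended peaks cannot fake support). Pooled peaks carry the maximum
−log10(p) of their contributing peaks. "Peak on the TSS" means overlap
with the 601 bp TSS window (a point-overlap variant is available).

## The simulator

The simulator reproduces the *statistical* structure the SI measures,
not the sequencing process. Transcripts (default 200, lengths uniform
in 1–8 kb, strands by fair coin) are placed on one synthetic chromosome
in private slots with a margin of `max(f, τ)` on both sides plus a
1.2 kb inter-slot gap, so derived windows can never overlap. Each
transcript receives `n` single-end 50 bp reads (mapq 60, aligned to the
transcript strand); each read independently lands in the TSS window
with probability `p` (`pause_fraction`), else in the GB window, with
its 5′ position uniform in the chosen window. The TSS count is thus
Binomial(n, p) and, under 5′-end counting, `SI = X/(n − X)` with median
→ `p/(1 − p)` — an exact analytic target. Defaults `p = 0.8`,
`n = 10,000` put the per-transcript binomial noise near 1 %, so
recovery tests measure bias rather than sampling error; cohorts in the
test suite are scaled to 15–200 transcripts depending on what the test
needs to resolve. Peak replicates share true TSS peaks (covering the
full TSS window, −log10 p ∈ [6, 20]) on a `peak_fraction` subset of
transcripts and differ only by replicate-private decoy peaks placed in
the inter-slot gaps (−log10 p ∈ [1, 6], rejection-sampled so decoys
from different replicates never overlap) — hence support-k pooling at
k = n_replicates provably removes every decoy.

What the simulator does **not** model: background/nonspecific reads,
sequencing error, GC or mappability bias, fragment-length effects,
overlapping genes, isoform structure, or replicate-to-replicate
variation in true peak boundaries. Passing recovery tests therefore
demonstrates that the window arithmetic, strand handling, counting and
filter logic are correct — not that the SI is robust to the noise
sources of real ChIP-seq.

One consequence of the closed-window default is visible at high
precision: a GB-assigned read whose 5′ end falls on the shared boundary
base also lies in the closed TSS window, inflating the TSS count by
≈ `(1 − p)/w_GB` per read. At the default window sizes this is < 0.1 %
of the expected SI and well inside the recovery tolerance; `disjoint`
mode removes it entirely.

## Sample-sheet model

The metadata module models a multi-assay sequencing inventory: GSM
accession, sample name, replicate index/total (split from "2/3"-style
fields), assay type, target, organism (mmu → mm9, hsa → hg18),
biological model, and input/baseline links. Baseline cells may be a
single accession or a dash-truncated range (`GSM1234734-7` expands by
replacing the trailing digits, giving GSM1234734…GSM1234737).
Validation reports duplicate accessions and unresolvable baselines as
errors; replicate sets whose observed membership disagrees with the
declared total, and input rows that nonetheless declare a target, as
warnings. Replicate sets are identified by stripping a trailing
replicate decoration (`_N`, `.N`, `N`, or `.B`) from the sample name,
and only rows declaring a total > 1 are grouped — rows declared `1/1`
are independent samples (e.g. tumours from different animals), not
broken replicate sets. The packaged 94-row sheet (the GSE51011
inventory) is transcribed verbatim, including its en-dash/hyphen
no-value markers and the two input rows that list an antibody target;
those oddities parse cleanly and surface as warnings. Model names with
non-ASCII characters (Eμ-myc) are preserved but matched through an
ASCII alias (Eu-myc).

## Numerical and design notes

* Interval counting uses an interval tree per chromosome; the in-memory
  read source uses binary search over sorted starts with a
  maximum-span lookback. Both are property-tested against all-pairs
  brute-force oracles.
* `merge_intervals` also merges bookended intervals, so its output is
  disjoint *and* non-adjacent; it is idempotent.
* All stochastic components draw from `numpy.random.default_rng` seeded
  from a single config seed (sub-streams via `SeedSequence`), so every
  output — BAM files included — is bit-reproducible given the seed.
* Output tables are sorted by transcript id and written atomically
  (temp file + rename) by the CLI; effective parameters are echoed as
  `#` header lines.
* Per-transcript SI is computed per isoform; no gene-level aggregation
  or cross-condition statistics are provided.
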