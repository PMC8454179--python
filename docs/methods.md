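# Methods

This note documents the models, parameters and numerical choices behind
each analysis stage, what the simulator does and does not emulate, and the
known limitations.

## Coordinates and sequence alphabet

All intervals are 0-based half-open internally. Human-facing output
(reports, GFF3) is 1-based inclusive; BED output stays 0-based half-open.
Sequences are restricted to the A/C/G/T/N alphabet: IUPAC ambiguity codes
other than N are accepted on read but normalized to N with a logged
warning, because the GC arithmetic downstream is defined only on the
5-letter alphabet.

## GC content and profiles

`gc_content` returns 100·(G+C)/denominator. The default N policy
(`exclude-N`) removes N from the denominator; an all-N sequence has no
defined value and is reported as NaN ("missing"), which windowed profiles
propagate. `windowed_gc` uses fixed-size windows (default 25 bp,
non-overlapping) computed from cumulative sums; the trailing partial
window is dropped rather than rescaled so all windows stay comparable —
at 25 bp the edge loss is negligible. `summarize_bins` aggregates window
values into per-bin min/mean/max tracks for display.

`find_gc_islands` looks for elevated-GC islands inside an (AT-rich)
region: windows whose GC exceeds the region mean by `min_contrast`
(default 10 points) are flagged, flagged runs separated by ≤ `merge_gap`
(500 bp) are merged, and a merged run is kept when it is ≥ `min_len`
(5 kb) **and** its overall GC still clears the contrast margin — the
second check discards chains of borderline noise windows. Island scanning
uses a 200 bp window rather than 25 bp: at centromeric base composition a
25 bp window has a GC standard deviation near 8 points, which breaks up
genuine islands and flags noise; 200 bp brings the per-window noise to
~2.7 points so a 45%-GC island against a 17% background separates
cleanly. These defaults recover a 7 kb island at 45% GC inside a 90 kb
region at 17% GC with boundary error below one window.

## Centromere scan

The scan models a fungal centromere as a long AT-rich ORF desert and
works in three resolutions:

1. **Coarse detection** — 1 kb non-overlapping windows flag GC below
   `gc_threshold` (default 30%). The threshold sits between the
   centromeric range the scan targets (17–19%) and the genomic background
   (~50%); at 1 kb the backbone GC standard deviation is ~1.6 points, so
   the two classes are ~12 standard deviations apart and
   misclassification is effectively impossible. Flagged runs separated by
   ≤ `merge_gap` (2 kb) are merged.
2. **Boundary refinement** — run edges move in 25 bp steps, deciding on
   the mean GC of a 100 bp lookahead span (single 25 bp windows at ~50%
   GC cross the threshold by chance ~2.5% of the time, which caused
   boundary overshoots of several windows; the 100 bp span brings the
   error rate below 10⁻⁴). Boundaries typically land within ~100–400 bp
   of a planted transition, well inside one detection window.
3. **ORF filter** — annotated features overlapping a run split it, except
   that up to `max_small_orfs` (1) ORFs of ≤ `small_orf_max_len` (300 bp)
   are tolerated and reported in `contained_orfs`; this admits the
   single-short-ORF mobile-element case without admitting gene-dense
   regions. If a run holds more short ORFs than tolerated it is split at
   every ORF. Pieces ≥ `min_len` (80 kb) are emitted.

The reported candidate interval is the refined low-GC run trimmed to
exclude disallowed ORFs. The surrounding ORF desert — the gap between the
nearest annotated features on either side — is reported separately as
`flanking_orf_bounds` rather than replacing the GC-derived boundaries:
the inter-ORF gap is typically much wider than the AT-rich tract (genes
thin out before base composition shifts), and conflating the two would
make candidate length depend on annotation density rather than on the
centromere itself. Each candidate also carries mean/min/max GC (25 bp
windows) and any elevated-GC islands found inside it. Without an
annotation the ORF filter is skipped and candidates are labelled
`gc_only`. Note that an island above `gc_threshold` and longer than
`merge_gap` splits the low-GC run; scanning genomes with embedded
high-GC elements therefore needs `merge_gap` raised above the island
length (the island-bearing test uses 8 kb).

## Local alignment engine

`smith_waterman` is an exact Smith–Waterman with affine gaps: a gap of
length L costs `gap_open + L·gap_extend`. Nucleotide defaults
(+2/−3, 5/2) follow common blast-like practice; N never matches,
including N–N. Protein alignment uses BLOSUM62 with gap costs 11/1.
The DP fill runs as a numba kernel over three int32 matrices (H/E/F);
traceback is deterministic with tie order diagonal > up > left, closing
a gap when scores tie, and among equal-scoring end cells the first in
row-major order wins. Two independent oracles check the engine in tests:
a brute-force per-cell gap-scan DP without the E/F optimization, and
Biopython's `PairwiseAligner` in local mode.

`anchor_markers` places marker genes by seed-and-extend: exact k-mer
seeds (k = 16 nt, or 5 aa on six-frame translations for protein markers)
located by rolling base-5 (base-25 for protein) hashes narrow the contig
to candidate windows of about twice the marker length, and the exact DP
runs inside each window. Hits are accepted at ≥ `min_score_fraction`
(default 0.5) of the marker self-score — tolerant far beyond the ~5%
divergence the panel classifier is specified for, while random hits on
unrelated sequence stay near zero. At 5% divergence a 1 kb marker still
contains ~28 intact 16-mers in expectation, so seeding loss is
negligible. Protein hits are mapped back to nucleotide coordinates
through the frame offset. One best hit per marker is kept by default;
`report_all` exposes secondary hits (used for homothallic and duplicated
loci). A contig shorter than the seed length yields an empty result, not
an error.

## MAT locus classification

Idiomorph: MAT1-1 if only the α-box marker passes threshold, MAT1-2 if
only the HMG marker, `both` if both, `none` otherwise. When the two MAT
markers hit overlapping intervals (>50% of the shorter), the higher
score fraction wins and a `chimeric-mat-hit` flag is set.

Orientation is decided purely positionally, on hit midpoints, after
normalizing each contig so that adeA precedes slaB (mirroring
coordinates when needed — assembly strand is arbitrary, and every
"between" relation used is mirror-invariant, so the call does not depend
on which flank came first in the assembly):

* **conserved** requires MAT strictly between apnB and slaB, with adeA
  (if anchored) outside that span. slaB is mandatory: deleting it
  degrades a conserved locus to `undetermined`, never to `flipped`.
* **flipped** requires MAT strictly between adeA and apnB, with slaB
  (if anchored) closer to apnB than to adeA.
* anything else, missing anchors (MAT, apnB and at least one flank), or
  anchors spread over multiple contigs → `undetermined`, with
  `missing-markers` / `multi-scaffold` / `anchor-order-unrecognized`
  flags.

The ORF directions of apnB/coxM/apcE corroborate but never determine the
call: in the conserved layout the cassette genes share the flank genes'
strand, in the flipped layout the cassette has been reverse-complemented
so they oppose it. The check is a majority vote of the anchored cassette
genes' strands relative to adeA (or slaB); a contradiction sets
`direction-inconsistent`. Relative strands are unchanged by
reverse-complementing the contig, so the check is mirror-invariant like
the positional rule.

`call_mat_locus` anchors the panel on every contig, keeps the best hit
per marker genome-wide, classifies, and reports the locus interval from
the outermost of {adeA, apnB} through slaB. A locus wider than
`max_span` (default 100 kb, roughly 2–3× a typical intact span) is
demoted to `undetermined` with a `locus-span-exceeded` flag — beyond
that the anchors more likely reflect misassembly or paralogy than one
locus. `classify_panel` tabulates per-strain calls and
(idiomorph, orientation) counts; multi-scaffold strains land in the
`undetermined` orientation cell.

## Locus comparison

Homology blocks come from exact k-mer anchors (k = 20; at that length
two unrelated 40 kb sequences share no k-mer with probability ≈ 1)
computed on both strands, merged along diagonals, and chained greedily in
order of position: an anchor joins a chain when its gap on both loci is
≤ `chain_gap` (2 kb, matching the gene-scale unique insertions expected
between conserved genes) and the diagonal shift is within the same
bound; order conflicts start new chains. Chains scoring below
`min_block_score` (100, i.e. ≥ 50 matched bp) are dropped; surviving
blocks are made non-overlapping per locus by trimming lower-scoring
blocks at the ends. Full quadratic DP is not run on whole loci — the
exact engine remains the small-scale oracle in tests.

`detect_inverted_mat_block` reports the orientation of the block
containing the MAT position on both loci (`co-oriented` / `inverted`),
or `not-covered` when the MAT gene falls in an unaligned gap — which is
the expected outcome when comparing opposite idiomorphs, whose MAT genes
are not homologous; inversion detection across idiomorphs should
therefore anchor on a shared cassette gene such as apnB.

Breakpoints are emitted per locus at transitions between adjacent blocks
of different orientation (position: junction midpoint) and at unaligned
gaps — internal or terminal — longer than `min_gap` (200 bp, placed at
the gap midpoint). Gaps at or below `min_gap` are chaining slack, not
evidence of a break; this keeps a self-comparison with near-total
coverage at zero breakpoints.

`motif_scan` reports every exact occurrence of the motif (default
`TTACACT`), overlapping ones included, on the forward strand and — by
default — its reverse complement, each tagged with strand so a
single-strand analysis can filter. `annotate_motif_breakpoint_proximity`
adds each site's distance (site midpoint to breakpoint) to the nearest
same-locus breakpoint and a `proximal` flag at ≤ 1 kb.

## Simulator

`simulate_genome` draws i.i.d. bases per region at the region's target
GC: backbone 49.6%, one planted centromere per chromosome with length
uniform in 88–100 kb and GC uniform in 17.1–18.4%. Annotated filler
genes (default 60 per 1 Mb chromosome, 0.9–3 kb) are placed uniformly,
non-overlapping, and at least `min_gap` (10 kb) clear of planted
centromeres; an optional short ORF (e.g. 219 bp) can be planted inside
the centromere, optionally wrapped in a 7 kb elevated-GC island.
`simulate_mat_locus` assembles a locus from the marker panel —
adeA, then the cassette [apnB, MAT gene(s), coxM, apcE, 5 anonymous
fillers], then slaB, with 1.5 kb spacers (seven genes between MAT and
slaB in the conserved layout); the flipped layout reverse-complements
the cassette in place. Chance occurrences of the motif outside marker
genes are scrubbed before the planned copies are planted at the cassette
joints, so planted motif counts are exact. `simulate_isolate_panel`
embeds each isolate's template locus in an independent backbone (60 kb
default), applies i.i.d. substitutions at the divergence rate (2% for
the reference panel; no indels, keeping coordinate truth exact — an
indel model is deliberately absent), and can split an isolate's contig
between MAT and apnB to produce the multi-scaffold case.

All randomness flows through one `numpy.random.Generator` (PCG64, the
algorithm echoed in the config output), so a fixed config yields
byte-identical outputs across runs and platforms. The default marker
panel is generated from a fixed internal seed and is therefore a stable
reference object; it is purely synthetic (~1 kb, ~50% GC, motif-free)
and ships for testing and demos — real analyses should supply a real
panel as FASTA.

What the simulator does **not** emulate — and what passing tests
therefore do not show about real data: repeat families and transposons
(real centromeres are repeat-rich, which challenges assembly rather than
this scan), dinucleotide and codon structure, indel divergence,
assembly gaps/N-runs inside centromeres, paralogous marker copies, and
annotation error in the GFF. Recovery rates on simulated panels are
upper bounds for real panels in these respects.

## Numerical and degenerate-input choices

* N50 ties resolve by the plain cumulative-sum definition; no special
  casing.
* All-N windows are "missing", not low-GC: a centromere call never rests
  on N-runs alone.
* Empty inputs raise (`read_fasta` on an empty file, `assembly_stats` on
  an empty collection, `smith_waterman` on an empty sequence); an
  absent marker or a too-short contig yields an empty result instead,
  since it is an expected analysis outcome.
* `interval_length` refuses reversed intervals rather than silently
  returning negative lengths.
* Alignment traceback and end-cell selection are fully deterministic
  (tie order above), so identical inputs give identical hit coordinates.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise the documented study
conditions directly: 8 × 1 Mb chromosomes for centromere recovery
(20 seeds in the suite) and a 24-isolate panel at 2% divergence for MAT
classification, with smaller genomes (300–400 kb chromosomes, 2-isolate
panels across 20 seeds) for the per-module tests. These sizes were chosen
as the smallest at which the detection regime matches the full-scale
problem — window statistics, seed densities and threshold separations are
scale-free above ~100 kb, so nothing about the method changes at larger n.
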