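# Methods

`rnpchip` analyses ChIP-seq read placements on a multi-replicon circular
bacterial genome to locate and characterise the binding sites of an intron
ribonucleoprotein (RNP). The biological question it serves: does the RNP
bind DNA preferentially near the bidirectional replication origin of each
replicon, and on genes whose strand is the template of lagging-strand
synthesis — the transiently single-stranded substrate an endonuclease-less
group II intron invades during retrohoming?

## Experimental design the package models

Three expression constructs are assayed, each with three input and three IP
(immunoprecipitated) libraries — 18 libraries in all:

| construct      | expresses                     | role |
|----------------|-------------------------------|------|
| `pKG4_FlagIEP` | FLAG-tagged active RNPs       | signal |
| `pKG_FlagIEP`  | FLAG-tagged IEP, no ribozyme  | protein-only control |
| `pKGEMA4`      | untagged active RNPs          | IP-specificity control |

Binding sites specific to the functional tagged RNP are the peaks called in
`pKG4_FlagIEP` that overlap no peak of either control (bedtools
`intersect -v` semantics, two subtractions in sequence).

## Coordinate conventions

All in-memory intervals are 0-based, half-open, on circular replicons.
GFF3 is converted at the I/O boundary; BED is native. No stored coordinate
leaves `[0, L)` on disk: a feature crossing the circular seam is split into
two BED records sharing a name. In-memory tables use `end > L` as a compact
wrap notation, which writers split. For a minus-strand read, the 5' end is
the interval's right edge; fragment extension always proceeds from the 5'
end in read orientation.

## Peak calling

A transparent reimplementation of the windowed-Poisson enrichment model
used by MACS2-class callers, specialised to circular replicons:

1. Reads are extended to the fragment length `d` (default 300 bp, the
   midpoint of the 0.2–0.5 kb shearing range; no model building).
   Duplicates are kept — there is no deduplication stage at all.
2. Each replicon is tiled into bins of width `w` (default 50 bp). The IP
   statistic per bin is the number of extended-fragment **midpoints** in
   the bin. Under a uniform fragment model these counts are independent
   Poisson variables across bins, so the multiple-testing correction is
   exactly calibrated. (Counting fragment *overlaps* per bin — an
   alternative statistic — couples neighbouring bins over the fragment
   length and was rejected for that reason.)
3. The background rate is
   `lambda_local = r * max(lambda_BG, lambda_1k, lambda_5k, lambda_10k) * w/d`,
   where `r` is the IP/input fragment-count ratio, `lambda_span` is the
   circular mean of the input coverage in a window of that span around the
   bin centre, and `lambda_BG = N_input * d / g` with `g` the effective
   genome size (default: total replicon length). The max rule makes the
   test conservative wherever the input is locally elevated.
4. Upper-tail Poisson p-values are corrected by Benjamini–Hochberg across
   **all bins of all replicons in one pass** (the analogue of analysing the
   pooled replicates in a single execution; pooling replicates by
   concatenation is the default calling mode). Bins with `q <= 0.001` are
   kept.
5. Significant bins separated by at most `merge_gap` (100 bp) merge;
   the first and last runs join across the circular seam. Peaks shorter
   than `min_peak_len` (200 bp, matching the observed 200–800 bp peak size
   range) are dropped. The summit is the maximum of the IP pileup within
   the peak; fold enrichment is IP pileup at the summit over the local
   background coverage there; the reported p/q come from the best bin.

Divergences from MACS2 are deliberate: no shifting model, no lambda from
the IP itself, no broad-peak mode. The caller does not aim to reproduce
MACS2's numeric output on real data; peak counts from the original
sequencing runs depend on those internals and are out of scope.

## Fork-orientation annotation

On a circular replicon with a bidirectional origin, the clockwise
(coordinate-increasing) fork runs along the ori→ter arc. For that fork the
plus strand runs 5'→3' in the fork direction and therefore cannot template
continuous synthesis: **the plus strand is the lagging-strand template
under a CW fork**, and the minus strand under a CCW fork. A peak is LAG
when the strand of its overlapping gene(s) — which must be unique and
consistent — equals the local lagging template, LEAD otherwise, and ND when
no gene overlaps, strands disagree, the peak spans ori or ter, or its
midpoint sits exactly on a landmark. ChIP peaks are unstranded, so using
the host-gene strand is a proxy; it is the simplest rule consistent with an
ND category and is isolated in one function so alternatives can be swapped.
The peak midpoint (not the summit) fixes the fork direction.

Context categories follow the usual vocabulary (CDS, IR, IR_5CDS, IR_3CDS,
CDS5_IR_CDS3, OTHER). Upstream/downstream are coordinate-based; 5'/3' ends
are strand-based per gene. A peak covering a gene's 3' end plus the IR is
IR_3CDS and is never promoted into CDS5_IR_CDS3; peaks engulfing whole
genes or lying across overlapping genes are OTHER.

## Origin-proximity statistics

For a peak at circular distance `d` from ori on a replicon of length `L`,
`u = d/(L/2)` is exactly Uniform(0,1) when peak positions are uniform on
the circle — the bidirectional origin makes the two arms exchangeable.
Clustering around ori is tested two ways: a one-sample KS test of `u`
against Uniform(0,1) and a two-sided binomial test of `#{u <= tau}` versus
`n*tau` (default `tau = 0.1`). Fewer than 5 peaks are refused.

## GC skew and ori/ter localisation

GC skew per tiling window is `(G-C)/(G+C)` (0 where `G+C = 0`). The skew
values are mean-centred before cumulating so the circular walk closes;
otherwise the extrema drift with overall base composition. Ori is the
window start minimising the exclusive-prefix cumulative walk, ter the one
maximising it. The default window is 10,000 bp at any scale: with skew
amplitude `s = 0.05` and GC fraction 0.62, the per-window skew noise is
`sigma ~ 1/sqrt(0.62 W)`, and reliable single-window localisation needs
`s/sigma >~ 3`, i.e. `W >~ 6 kb`. Narrower windows (say 100 bp) have
`sigma >> s` and an argmin error of many windows. A constant-zero skew
yields an explicit undetermined result.

## Site-occupancy scan

Three printed 25-nt queries — the intron insertion site within its natural
IS-element target and two controls located 50 nt upstream and downstream —
are counted per library as reads containing the query or its reverse
complement as an exact substring (a read counts once per query; a
mismatch-tolerant mode up to a configurable edit count exists). Counts are
normalised to CPM (`count * 1e6 / library total`). For synthetic reads,
which are error-free genome substrings, substring matching is equivalent to
the read's circular window covering a genomic occurrence of the query; the
pipeline uses that interval-cover fast path, and the two routes are checked
against each other in the tests. The depletion contrast compares the
insertion-site IP/input CPM ratio of the active-RNP construct against the
IEP-only control, plus a Welch test on replicate IP CPMs.

## Input-vs-IP coverage comparison

Mean coverage is compared between the 9 input and 9 IP libraries (or 3v3
per construct on request) by Welch's t-test, in two scopes per replicon:
the whole replicon and all positions within `ori_window` (default 1,000 bp)
circular distance of ori — the window covers both arms because replication
is bidirectional. Each library's coverage is first normalised to
genome-wide mean 1, so depth differences cancel and only the spatial
distribution is compared; the genome-pooled whole-genome test is then p = 1
by construction and the pooled ori-window test carries the signal.
Genome-pooled rows are emitted alongside per-replicon rows because a
pooled-vs-stratified choice is a genuine degree of freedom; both are
reported. Degenerate inputs (zero variance in both groups with equal
means) give p = 1 by convention.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions:

* **Scale**: 1/10 of the real tripartite genome — chromosome 365 kb,
  megaplasmid 147 kb, chromid 161 kb — preserving the geometry while the
  full pipeline runs in seconds. GC content 0.62.
* **Skew**: base composition with skew `+0.05` on the ori→ter clockwise arm
  and `-0.05` on the return arm of every replicon.
* **Genes**: non-overlapping, both strands, mean length 800 bp at ~85%
  coding density; none crosses the seam.
* **Planted peaks** (default 300; width 200–500 bp): circular distance to
  ori drawn from Exponential(30 kb), arm by fair coin, hosted inside a
  gene whose strand is set to the local lagging template with probability
  `p_lag = 0.70` (so LEAD/LAG truth labels are consistent with fork
  geometry by construction). Genes near ori/ter are excluded as hosts so
  planted fork labels are always determinate. When near-ori genes are
  exhausted the sampler falls back to any free gene, flattening the decay
  at high peak densities.
* **Enrichment**: default 8x. The real experiment's enrichment was far
  weaker (signal-to-noise around 1.1); the default is set high for
  testability, and a weak-enrichment or null mode (`peak_enrichment=1`) is
  a config value away for power and calibration studies.
* **Decoys**: 40 per control construct (~1/10 of the real-scale control
  peak counts), placed disjoint from the true peaks and from each other
  with 1 kb clearance, so the expected unique-peak set equals the planted
  set exactly and the subtraction filter has a well-defined truth.
* **IS cassettes**: 13 copies of a 125-bp cassette — upstream 25-mer,
  25 random nt, insertion-site 25-mer, 25 random nt, downstream 25-mer —
  so the two flanking queries sit at −50/+50 relative to the site.
* **Reads**: 75-bp single-end placements derived from 300-bp fragments
  with random read strand; input libraries uniform at 10x coverage, IP at
  50x plus enriched fragments over the construct's own planted intervals.
* **Depletion**: a fraction (default 0.5) of reads overlapping the
  insertion-site 25-mer is removed from the IP libraries of the two
  active-RNP constructs, emulating loss of intact insertion sites to
  retrohoming. Depletion is applied to the IP fraction only: applying it
  to inputs as well would cancel in the IP/input ratio and erase the very
  contrast the scan is designed to detect.
* One seeded RNG drives everything; genome and read generation use split
  child streams of the same seed, and identical config+seed reruns are
  byte-identical.

What passing tests on this generator do **not** show: robustness to
sequencing error, mappability artefacts, GC-coverage bias, PCR
duplication, replicate overdispersion, or enrichment as weak as the real
experiment's. The generator's value is exact planted truth for every
signal the pipeline claims to measure.

## Problem sizes used in the checks

The acceptance-style studies run at the generator's default scale: the
FDR study uses 500 planted peaks at 50x IP depth across tens of seeds;
fork recovery uses 300 genic peaks; KS calibration uses hundreds of null
draws at n = 100; skew localisation uses 10–20 genomes at a 10 kb window;
the depletion and null-coverage rates use tens of seeds. These sizes give
Monte-Carlo error comfortably below the margins being tested while keeping
a full run in minutes on one CPU.

## Known limitations

* The caller is not MACS2 and does not reproduce its real-data peak counts.
* The LEAD/LAG rule depends on host-gene strand; peaks in intergenic
  regions are always ND.
* Ori/ter must be supplied for real data (the skew estimator is a coarse
  10-kb-resolution fallback, not a replacement for curated annotations).
* The printed context-category counts from the original study sum to fewer
  peaks than the unique set; the OTHER category absorbs configurations the
  enumeration does not name.
* Interval algebra assumes genes do not cross the circular seam (true of
  the generator; real annotations with seam-crossing genes would need the
  wrap-split convention applied upstream).
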