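# Methods

## Site model and coordinate convention

A poly(A) site is operationalized as the boundary between the last
transcript-templated base (the *tail attachment position*, coordinate −1)
and the genomic base corresponding to the first tail adenosine (the *tail
starting position*, coordinate +1).  Coordinates are signed and skip zero;
the analyzed region spans −100…−1 (upstream, mostly 3′UTR), +1 (the site
base, reported as-is from the genome, whatever its identity), and +2…+101
(the cleaved-off region), 201 nt in transcription orientation.  Genomic
coordinates are 1-based inclusive; minus-strand regions are
reverse-complemented before analysis.

This convention has one inherent ambiguity: when the genome carries
adenosines immediately 5′ of the true cleavage point, they are
indistinguishable from tail adenosines in the read.  The tail is therefore
defined as the *maximal* terminal A-run, and everything downstream
(uniqueness, mapping, region assembly) is defined relative to that
operational tail start.  The synthetic generator records both the designed
and the *effective* (post-absorption) anchor so round-trip tests are exact
even under this ambiguity.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `min_tail` | 12 nt | minimum uninterrupted terminal A-run to call a transcript poly(A)-tailed |
| `anchor_len` | 100 nt | upstream window used for dedup, uniqueness, and zero-mismatch mapping |
| region width | 201 nt | anchor + site base + 100 nt cleaved-off region |
| `min_orf_aa` | 110 aa | smallest ORF (stop excluded) that determines the 3′UTR |
| hexamer window | first base in [−50, −1] | upstream hexamer counting |
| pentamer window | first base in [−50, −3] | the 48-nt window ending two bases upstream of the tail start; this first-base reading is the only one under which the region is exactly 48 nt |
| site tetramer | positions −3…+1 | the 4-mer whose last base covers the tail start |
| downstream window | first base in [2, 51] | known-element scans |

Window membership is judged on the motif's **first base only**, so
footprints may cross the site or extend past the window's right edge (but
not past the region).  At-least-one-copy counting is per site: a site with
two copies of a motif in the window contributes one.

Mapping is exact-substring search on both strands (`str.find` scanning,
which is C-speed at the package's problem sizes); anchors containing N
never match, and anchors mapping to multiple loci are retained by default
(all their loci collapse to one unique site anyway, since uniqueness is
defined on the upstream 100 nt; the locus count is recorded as
`multiplicity`, and a `--drop-multi-locus` filter is available).  The
unique-site representative is the lexicographically smallest
(chrom, coordinate, strand); collapsed source counts are summed, so for a
multi-locus anchor the collapsed `n_source_mrnas` counts transcript×locus
pairs.  Sites with fewer than 101 genomic bases after the anchor are
dropped and counted (`n_edge_dropped`), keeping all matrices fixed-width.

3′UTR length is `tailstart − stop_last − 1` for the last-ending
ATG-initiated sense ORF with ≥ 110 residues (first in-frame stop
terminates an ORF; ties on the stop coordinate break toward the latest
start).  "Last" is read as last-*ending*, the reading consistent with
measuring the distance from "the stop codon" to the site; a
`require_atg=False` mode substitutes the longest stop-free reading frames.
A stop codon may borrow its final one or two bases from the tail
(TG+A → TGA, T+AA → TAA, TA+A → TAA), yielding UTR lengths of −1 or −2.
Note that a TA+A borrow is reported as −2, not −1: the templated A is
absorbed into the maximal terminal run before ORF analysis, so only TGA
borrows are observable as −1.

## Statistics

* **Information content** (bits): `log2(4) + Σ p log2 p` with
  `0·log2 0 := 0`; letter heights are `p × IC`.  Values are clamped to ≥ 0
  against floating-point underflow.  No small-sample correction or
  pseudocounts are applied — peak *positions*, not absolute heights, are
  the quantities of interest, and corrections would shift heights
  unevenly across species with different site counts.
* **Peaks** are single-position argmaxes with no smoothing (peak positions
  are reported at single-base resolution, which smoothing would blur);
  ties break toward the position nearest the site.  A window whose max
  exceeds its median by less than 5 percentage points (configurable) is
  flagged as a *plateau* — U-rich without a sharp peak, the typical plant
  downstream profile.
* **U-A-U-A-U summary** default search windows: far-upstream U [−100,−35],
  upstream A [−30,−10], upstream U [−15,−2], downstream U [2,40].  The A
  and second-U windows overlap by design: they bracket the reported peak
  positions of both default templates (−21/−18 for A, −9/−7 for U)
  with margin.  All windows are configurable.
* **Group averaging** offers both an unweighted mean of per-species
  frequency matrices (`species_mean`) and element-wise count pooling
  (`pooled`); which one a published group figure used is often ambiguous,
  so both are first-class.
* **Genome baselines** use overlapping sliding-window counts, which
  conflate homopolymers (seven A's count as two AAAAAA copies); this
  matches how whole-genome motif tables are traditionally computed, and a
  non-overlapping mode is provided.  Windows containing N are skipped in
  the numerator.
* **Known-element enrichment**: each element's with-copy count is tested
  two-sided exact binomial against the mean with-copy probability of all
  same-length k-mers in the same window, α = 0.01 — the simplest
  defensible null for "more frequent than the k-mer average".
* **Run comparison** uses the Pearson two-proportion chi-square (df = 1,
  no continuity correction — the uncorrected statistic is the common
  default and the implementation is pinned to an independent reference in
  the tests).

## Synthetic data

The generator emulates a curated poly(A)-tailed mRNA collection mapped to
an assembled genome.  Each gene's 201-nt window is drawn independently per
position from a probability template; a signal hexamer overwrites its
footprint in a configurable fraction of genes (default AATAAA at −21 in
55% of genes, the neighbourhood of upstream-hexamer frequencies observed
in animal mRNA collections); transcripts are the gene body plus a uniform
20–40 nt tail (well above the 12-nt screen); genes are placed
non-overlapping on both strands with ≥ 250 nt contig clearance so edge
dropping never confounds recovery tests.

Default templates:

* **plant-like** — upstream baseline (A,C,G,T) = (.26,.14,.13,.47), A peak
  0.41 at −21, U peak 0.56 at −7, site-A 0.85, flat U-rich downstream;
* **animal-like** — baseline (.28,.19,.18,.35), A peak 0.54 at −18, U peak
  0.43 at −9, pointed downstream U peak 0.52 near +19.

Peak heights follow the published per-group peak-frequency neighbourhood
(≈ 35–56%); bumps use a sharp discrete kernel (1.0, 0.4, 0.15 over 0, ±1,
±2 offsets) so the planted argmax is recoverable at ~2000 sites (the
neighbour gap is ≥ 4 binomial SE).  The attachment base (−1) has zero A
probability — real attachment bases are predominantly U or C — which makes
the designed tail exactly the maximal terminal run.

ORF genes plant an ATG + non-stop codons + stop layout with per-gene UTR
lengths (−2 upward).  The codon fill is rejection-sampled against a small
generator-internal ORF scan so that no alternative qualifying ORF ends
after the planted stop; this guarantees exact planted-UTR recovery rather
than recovery with rare random exceptions.

The internal-priming channel emulates oligo(dT) priming inside a
genomically A-rich stretch: a 10-nt A-run is planted in each gene's 5′ pad,
and for a selected fraction of genes the transcript is truncated at the
run and given an artificial tail.  Truncation starts at the run's leftmost
adenosine (absorbing chance background A's) so the artifact's observed
anchor is well-defined.  Selection walks a fixed seed-derived permutation,
making the selected sets nested across rates — the monotone A-enrichment
check compares like with like.  Artifact sites have genomic A at positions
+1…+6 with probability 1 by construction.

What the generator does **not** emulate: splicing, expression-level
weighting, sequencing errors, alternative/heterogeneous cleavage within a
gene, and genome repetitiveness (anchors are effectively unique by
construction).  Passing recovery tests therefore demonstrates correctness
of the measurement machinery under the stated model, not robustness to
repeat-rich genomes or noisy reads.

## Problem sizes and numerical choices

Recovery tests run at 2000 genes (≈ 0.8 Mb genome), the scale at which
planted 35–56% peaks separate from their neighbours by ≥ 4 binomial SE;
monotonicity and comparison checks use 400–500 genes, and structural
checks 30–300.  Probability-vector validation uses a 1e-9 sum tolerance.
Motif rank ties break lexicographically (stable sort over the
lexicographically ordered k-mer index).  An undefined enrichment ratio
(zero genome frequency) returns NaN rather than raising.  Duplicate FASTA
ids are a hard error: downstream dedup logic assumes set semantics on ids.

## Known limitations

* Exact-match anchoring cannot place transcripts whose genome differs from
  the reference by even one base in the anchor; this is by design
  (ambiguity avoidance) and mirrors the screening counts reported by the
  pipeline rather than being silently tolerated.
* Species-level motif tables from public databases depend on database
  snapshots; the package reproduces the machinery and verifies it on
  synthetic truth, not on any particular snapshot's numbers.
* The logo rendering draws stacked bars of letter heights rather than
  glyph-shaped letters.
* ANOVA/multiple-range testing across species groups is out of scope;
  group means and the two-proportion chi-square are provided.
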