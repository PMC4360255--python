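# polyamap

Mapping mRNA polyadenylation sites to a reference genome and profiling the
signal motifs, motif locations, and base-composition patterns in the 201-nt
region around each unique poly(A) site.

## The problem

When a pre-mRNA is cleaved and polyadenylated, the sequence around the
cleavage point — the poly(A) signal hexamer (AAUAAA and its variants), the
U-rich and A-rich elements flanking it, and the base under the first tail
adenosine — determines where the poly(A) machinery cuts.  Characterizing
these signals requires anchoring observed poly(A) tails precisely onto the
genome and tallying k-mers and base frequencies position by position.
`polyamap` implements that workflow for anyone analyzing poly(A)-tailed
transcript collections (curated mRNA sets, EST sets, or 3′-end reads)
against an assembled genome:

1. **Tail screen** — a transcript qualifies when it ends in ≥ 12
   uninterrupted adenosines; the tail is the maximal terminal A-run.
2. **Anchor dedup** — the 100 nt immediately upstream of the tail (the
   *anchor*) identify a site; identical anchors are collapsed.
3. **Zero-mismatch mapping** — anchors are located on either genome strand
   with no mismatches or indels tolerated.
4. **201-nt region** — each site's region is the anchor (positions
   −100…−1), the tail-start base (position +1, the genomic base under the
   first tail A), and 100 nt of the cleaved-off region (+2…+101).
   There is no position 0.
5. **Unique-site catalog** — sites sharing an identical upstream-100
   sequence count once, regardless of downstream differences.
6. **Profiling** — per-position base frequencies and sequence-logo
   information content, windowed k-mer tables (hexamers starting within 50
   nt upstream, pentamers in the 48-nt window ending 2 nt upstream, the
   tetramer covering positions −3…+1, known downstream elements),
   per-position motif location profiles, whole-genome k-mer baselines and
   enrichment ratios, and 3′UTR lengths from the last ORF encoding ≥ 110
   amino acids (stop/tail overlaps give UTR lengths of −1 or −2).

Per-position information content follows the standard sequence-logo
measure: for base probabilities $p_{jw}$ at position $w$ over a $J=4$
letter alphabet,

$$\mathrm{IC}_w = \log_2 J + \sum_{j=1}^{J} p_{jw}\log_2 p_{jw} \in [0,2],$$

with letter heights $p_{jw}\cdot \mathrm{IC}_w$.

A synthetic-data generator (`polyamap.simulate`) produces genome +
transcript FASTA pairs with known truth — positional composition templates
shaped like real plant or animal poly(A) regions (the conserved
U-rich — A-rich — U-rich — site-A — U-rich pattern), planted signal
hexamers, ORF/UTR layouts, transcript redundancy, and an internal-priming
artifact channel — so every pipeline stage is verifiable without any
external downloads.

## Worked example

Simulate 500 genes carrying a plant-like composition template with AATAAA
planted at position −21 in 55% of genes, run the pipeline, and profile the
catalog:

```
$ polyamap simulate --seed 7 --n-genes 500 --outdir sim
wrote 500 transcripts, 206000 nt genome -> sim

$ polyamap run --transcripts sim/transcripts.fa --genome sim/genome.fa --outdir out
n_input=500 n_tailed=500 n_no_tail=0 n_short_body=0 n_distinct_anchors=500
n_unmapped=0 n_multi_locus=0 n_edge_dropped=0 n_mapped_regions=500 n_unique_sites=500
UAR peak -21, 2nd UUR peak -7, site A 86.2%

$ polyamap profile out/site_table.tsv
1st UUR: T peak at -53 (51.6%) (plateau)
UAR: A peak at -21 (76.2%)
2nd UUR: T peak at -7 (53.0%)
DUR: T peak at 33 (50.0%) (plateau)
site A: 86.2%

$ polyamap motifs out/site_table.tsv -k 6 --top-n 5
       motif_rna  n_sites_with_copy  pct_sites  rank
motif
AATAAA    AAUAAA                295       59.0     1
ATAAAT    AUAAAU                146       29.2     2
TAATAA    UAAUAA                145       29.0     3
TTTTTA    UUUUUA                114       22.8     4
AAATAA    AAAUAA                113       22.6     5
```

Reading the output: all 500 transcripts pass the tail screen, map to
exactly one locus each, and yield 500 unique sites.  The upstream A-rich
element (UAR) peaks at −21 and the upstream U-rich element at −7 — exactly
the planted template positions — while the two long U-rich flanks are
plateaus (U-rich without a sharp peak).  86.2% of sites have a genomic A
under the first tail base.  AAUAAA ranks first among all 4096 hexamers at
59% of sites: the planted 55% plus chance occurrences; the next-ranked
motifs are its overlaps with the A-rich element.

The same operations are available as library calls
(`polyamap.run_pipeline`, `polyamap.motifs.count_sites_with_motif`,
`polyamap.composition.summarize_uauau`, …) returning dataclasses and
pandas DataFrames.

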