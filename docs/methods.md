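# Methods

## The phasing model

A PHAS locus produces small RNAs whose 5′ ends recur every *c* nucleotides
(*c* = 21 or 24) downstream of a miRNA-guided cleavage that sets the phase.
Dicer processing of the double-stranded precursor leaves 2-nt 3′ overhangs,
so the minus-strand member of a phasiRNA duplex whose plus-strand member
starts at *p* has leftmost genomic coordinate *p* − 2. All statistics
therefore operate on the *effective position*: the leftmost coordinate for
plus-strand reads, leftmost + 2 for minus-strand reads. A perfect duplex
pair then shares one effective position and one register (congruence class
modulo *c*).

### Occupancy and the window test

The scan window spans *W* = 10 *c* nt (210 nt for 21-nt scans, 240 nt for
24-nt scans). The occupancy universe of a window is the *N* = 2 *W* slots
(effective position × strand); *K* = 2 *W*/*c* = 20 of those lie in the
register fixed by the window anchor. Occupancy is counted per slot: *n*
distinct occupied slots, *k* of them in register. Counting slots rather than
pooled positions is what makes a fully duplexed 10-cycle locus reach
*k* = *n* = 20 and is required for the *N* = 2*W*, *K* = 2*m*
parametrisation to be coherent.

The window P-value is the exact upper tail P(X ≥ *k*) for
X ~ Hypergeometric(*N*, *K*, *n*), evaluated with integer binomial
coefficients and `fractions.Fraction` (no normal approximation, no floating
point until the final conversion). Windows are anchored at every occupied
effective position; a window whose register holds no read at its anchor
cannot beat the same register anchored at an occupied position, so this
candidate set covers the exhaustive per-nucleotide scan at a fraction of
the cost.

### Phase score

Every occupied position receives
score = (*k* − 2) · ln(1 + 10 *P* / (1 + *U*)) for *k* ≥ 3, else 0, where
*P* and *U* sum the per-library read counts at in-register and
out-of-register slots inside a *W*-window centred on the scored position
(truncated at contig edges, window re-aligned so its width stays *W* where
possible). *k* counts distinct occupied in-register slots in that window.
Reads of length ≠ *c* are excluded from *n*, *k*, *P* and *U*; multi-mapping
reads contribute at every placement; abundance is the sum over all
libraries (a `unique_reads_only` switch counts each distinct read once
instead). A window's reported score is the maximum over its in-register
occupied positions.

### From windows to loci

Windows with raw P < 0.05 are extended by 100 bp on each side (clamped to
the contig), overlap-merged transitively within a (contig, cycle) class, and
the minimum member P is kept as the representative. The register of a merged
interval follows its minimal-P member window (ties: smaller coordinate).

Multiple-testing correction is Benjamini–Hochberg, applied per cycle class.
The multiplicity universe is the **full window-test family**: every
anchorable genomic position is one test, and positions with no read
contribute p = 1 (their windows have *k* = 0). The occupied-anchor scan is a
lazy evaluation of exactly that family, so each merged interval inherits the
BH-adjusted value of its minimal-P member computed against the padded
p-value vector. Correcting only over the intervals that already survived
the raw p < 0.05 gate would condition on significance and then correct
within the survivors — in background-only simulations that variant calls a
false locus in roughly one genome in five, whereas the full-family
correction leaves background genomes clean without costing any sensitivity
(implanted loci sit 20+ orders of magnitude below the threshold).

A locus is called when its maximum phase score exceeds 5 **strictly** and
its adjusted P is below 0.05. Loci are named `PHAS_<contig>_<serial>` with
serials consecutive per contig in coordinate order; phasiRNAs are the
occupied in-register slots inside the locus, named `<locus>_siR<serial>`
densely in coordinate order (a register-indexed D-notation such as
`PHAS_c1_1_D8(+)` is attached as an alternative label).

### Permutation false-positive rate

For each merged interval, slot positions are resampled uniformly within the
interval (strands redrawn, abundance multiset preserved) and the best
window P within the interval is recomputed; the FPR is the fraction of
permutations at or below the observed representative P. It is a report
column, never a filter. Default 1000 permutations for the standalone
operation, 200 in the pipeline (the estimate only needs to distinguish
"never beaten" from "routinely beaten"); the operation refuses fewer
than 100.

## Degradome analysis

Binding sites are exhaustive ungapped antiparallel alignments of an sRNA
against a transcript: sRNA position *i* pairs transcript position
*t_end* − *i* + 1. G:U wobbles count as full mismatches (a flag can relax
them to weight 0.5 for exploration). The expected cleavage position is
*t_end* − 9 (opposite sRNA position 10); a valid degradome read is a 5′ end
in {*t_end* − 10, *t_end* − 9, *t_end* − 8} (opposite positions 9–11). Two
retention policies are kept as named rules because they are genuinely
different: triggers need ≥ 1 valid read in any profile **or** < 4
mismatches; targets need (≥ 1 valid read **and** ≤ 4 mismatches) **or** 0
mismatches. When a locus is interrogated for triggers, both strands of its
genomic interval are searched (loci are unstranded); degradome counts are
lifted from transcript coordinates to the genome and onto the locus, which
supports plus-strand transcripts — minus-strand sites are still searched
but see zero degradome evidence.

## TAS3 annotation

Conserved tasiARFs (shipped set: the 21-nt tasiARF core conserved between
Arabidopsis and rice, user-overridable) are scanned against the genome on
both strands with ≤ 2 mismatches. Each match is flanked by ±250 nt (clamped)
and miR390 complementary sites are predicted on both strands of the flank;
a site on each side of the tasiARF (sides defined relative to the match
strand) yields the TAS3-like label, reflecting the two-hit trigger
architecture. Matches are linked to overlapping called loci.

## Cis/trans classification and network

A retained target is *cis* when the target transcript overlaps the
phasiRNA's generating locus, *same_family* when locus and target share a
user-supplied family label, else *other*; cis takes precedence. The network
export is a plain edge table (locus —generates→ phasiRNA —targets⊣ gene,
with the target class) loadable by standard network tools.

## The synthetic-data generator

The generator emulates the statistical structure the detector assumes:

- random genome (default 100 kb over 2 contigs, GC 0.40 — the free
  parameters of a composition-only null genome);
- implanted PHAS loci (default five 21-nt and two 24-nt, 10 cycles each)
  with phased reads on the plus strand **and** exact duplex partners at
  leftmost − 2 on the minus strand; per-position per-library counts are
  log-normal (meanlog = ln 20, sdlog = 0.5) — heavy-tailed abundance is
  typical of sRNA libraries;
- one trigger miRNA (22 nt) per locus whose complementary site is written
  into the genome so that the inferred cleavage position (*t_end* − 9)
  coincides exactly with phased position 1, plus degradome signal (default
  50 reads in each of two profiles, leaf and root) at that position;
- TAS3-like implants with two miR390-style sites flanking a tasiARF copy
  taken from the shipped tasiARF file, the tasiARF placed on an in-register
  phased position;
- unphased background: 50 unique reads per kb of genome (21 or 24 nt,
  uniform position and strand), counts Poisson(3) clipped to ≥ 1 — the mean
  matches the ~2.5 total-to-unique read ratio typical of deeply sequenced
  sRNA sets and is the simplest exchangeable null for the window test; 10%
  of background reads are copied from the repeat set so the repeat filter
  has work to do;
- degradome noise at 5 positions per kb of transcript;
- nine libraries, triplicates of root/leaf/flower.

What the generator does **not** model: sequencing error, adapters, quality
scores, genome repeat structure beyond the explicit repeat FASTA, RNA
secondary structure, or realistic transcript annotation. Passing tests on
this generator therefore demonstrate the correctness of the statistics and
plumbing under the stated model — not performance on real libraries, where
mapping ambiguity, expression skew and incomplete genomes add error modes
the simulation deliberately leaves out.

All simulation and permutation randomness flows from single integer seeds;
identical configurations reproduce byte-identical output files.

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED export is 0-based
  half-open, GFF3 stays 1-based.
- The repeat filter is exact full-length substring matching on both strands:
  deterministic and conservative where aligner settings are unspecified.
- The internal mapper reports all exact full-length matches on both strands;
  SAM import (ungapped, full-length, NM = 0 records only) serves users who
  prefer an external aligner that tolerates mismatches.
- Merge ties and naming are pure functions of coordinates, so re-running
  yields identical names; tie-break for the interval register is the
  smaller anchor.
- Degenerate inputs: empty read sets produce valid empty outputs; an empty
  repeat file is an identity filter with a warning; a transcript shorter
  than the sRNA yields no sites; permutation FPR on an empty interval is 1.
- Problem sizes in tests and the acceptance script (100-kb genomes, ~5 000
  background reads, 1000-window calibrations, 20-genome specificity panels)
  were chosen so the whole suite completes in well under a minute while
  every window statistic still operates in its intended regime.

## Known limitations

- Degradome lifting onto loci assumes plus-strand transcript coordinates;
  minus-strand transcript support would require strand-aware cleavage
  mapping.
- 22-nt phasiRNA scans and hc-siRNA/NAT-siRNA classification are out of
  scope, as are differential expression, clustering and enrichment analyses
  downstream of the exported count matrix.
- The `--threads` CLI option is accepted for interface stability but the
  implementation is single-threaded; results are independent of it by
  construction.
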