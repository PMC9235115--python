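# Methods

## Model of duplex sequencing data

A duplex molecule is a fragment `[start, end)` of a single reference
contig. Each end carries a random UMI (default 6 bases, alphabet `{C,G,T}` —
adapters omit dA so that the barcode cannot terminate the extension step
they are designed around). The top strand is sequenced starting from the
left end (its read 1 carries the left UMI), the bottom strand from the
right end, so the two strands' read pairs carry the two UMI halves in
swapped order. Each surviving strand yields a number of read pairs drawn
from a shifted Poisson (`min + Poisson(mean − min)`, default mean 5, min 1;
the minimum-3 family filter is therefore exercised by real mass in the
family-size distribution). Read pairs are convergent (FR for top-strand
molecules, RF for bottom-strand ones, labelling by read 1's strand).

### Error channels

Three channels are injected at the stage where the corresponding physical
process acts, which is exactly what makes them separable by consensus:

* **Sequencing error** (`seq_error_rate`, per base per read copy): each
  read copy independently; also applied to the UMI bases (so UMI correction
  has real work to do) unless `umi_seq_errors=False`. Erroneous template
  bases receive Q20 with probability 0.5 (Q37 otherwise) so the Phred-30
  pileup filter is exercisable; correct bases are Q37.
* **Single-strand damage** (`ss_damage_rate`, per base per molecule): the
  damaged base is placed on exactly **one** strand, chosen uniformly. This
  is deliberate: if the two strands were damaged independently, coincident
  hits at one position with complementary alternate bases would occur at
  rate ≈ r²/3 per base and leak into the duplex consensus, making the
  channel-separation property (below) only approximate. One-strand-per-hit
  matches the truth-record invariant (an `ss_damage` event has a single
  strand) and makes the property exact by construction.
* **Double-strand artifact** (`ds_artifact_rate`, per base per molecule):
  both strands changed consistently — the fragmentase/nick-translation
  regime. These survive duplex consensus by design.

Spike-in variants model known SNPs: a molecule overlapping a spiked
position carries the alternate allele with probability equal to the allele
fraction; with `heterozygous_spike` the molecule is drawn from the carrier
genotype with probability 2 × allele fraction (a heterozygous genome
contributes two alleles by mass but only one carries the variant) and then
transmits the variant with probability 1/2. Per-strand dropout is a
Bernoulli per strand (a scalar probability, or a `(top, bottom)` pair for
asymmetric designs).

### What the simulator does not model

Capture-enrichment efficiency, adapter base sequences, indels, polymerase-
specific error spectra, chimeric molecules, position-dependent quality
decay, and PCR jackpotting (family sizes are i.i.d.). Passing tests
therefore demonstrate the correctness of the collapse logic and the
statistics under the stated generative model — not performance on any
particular instrument's error profile.

## Consensus rules and numerical choices

* **Agreement threshold.** "More than two thirds" is a strict inequality on
  a rational threshold: a base is called iff `count · 3 > 2 · k` (general:
  `count · den > num · k` with the threshold stored as a `fractions.Fraction`,
  default 2/3). Floating-point thresholds would misjudge the decisive
  2-of-3 case, which must give `N`.
* **N handling.** `N` in member reads counts in the denominator and can
  never be emitted as a winning base (if no base exceeds the threshold the
  output is `N` regardless). Family padding places each read at its genomic
  offset within the family footprint and fills uncovered positions with
  `N`, so reverse-strand families (which share their genomic *end*) pad on
  the genomic left.
* **Duplex pairing.** The partner of family
  `(boundary, αβ, orientation, read r)` is
  `(boundary, βα, swapped FR/RF label, read 3−r)`: read 1 of one strand
  covers the same fragment end as read 2 of the other. The rule is
  validated against simulator truth (an error-free duplex yields exactly
  two DCS whose sequences equal the reference over their footprints).
  Because tag-family keys are exact tuples, each SSCS has at most one
  partner; duplicate keys are counted as ambiguous and skipped
  deterministically.
* **Recovery units.** DCS recovery = `n_DCS / (n_SSCS / 2)` with both
  levels counted as consensus *read records* (read 1 and read 2 separately),
  so perfect pairing gives exactly 1.0 and per-strand survival `s` gives
  expected recovery `s`.
* **UMI clustering.** Directional network clustering with Levenshtein
  distance (edlib; `N` is an ordinary mismatch; Hamming available), count
  rule `count(a) ≥ 2·count(b) − 1`, visiting UMIs in descending-count order
  with lexicographic tie-breaks for determinism. Clustering runs inside
  each fragment-boundary partition, since reads in different partitions can
  never share a family. The count rule is also used to prune candidate
  pairs, so partitions whose UMIs all have similar counts need no distance
  computations at all.
* **Degenerate inputs.** Empty UMI input → empty map; zero SSCS → recovery
  undefined (NaN, flagged); zero pileup coverage → VAF NaN; zero-median
  coverage → normalization flagged undefined; fragments shorter than the
  UMI window are skipped and counted.

## Statistics

Per-position tests use a 2×2 Pearson χ² (no continuity correction —
the common default; configurable) on (ref, var) × (test, background)
counts, restricted to (position, alt) pairs where the test VAF exceeds the
background VAF and both samples have coverage; Benjamini–Hochberg
adjustment (statsmodels) is applied over all tested pairs and significance
means q ≤ FDR. Multiple alternate alleles at one position are tested
separately and share the BH pool. Degenerate contingency tables (an all-zero
margin) get p = 1.

Variant incidence removes excluded positions (spiked and known germline)
entirely, then divides non-reference calls by total calls. Base counting
assigns each aligned, non-N, quality-passing base (Phred ≥ 30 at the
`filtered` level only; consensus calls carry no meaningful qualities) to
its reference position; CIGARs from real alignments are projected onto the
reference (deletions become `N`, insertions and clips are dropped), and
end-trimming (default 0; 7 for sonication libraries, where damage
concentrates within 7 bp of read ends) masks aligned bases at both read
ends. Coverage QC assigns a read to the bin containing its leftmost aligned
position — a single-assignment rule that keeps bin totals exactly
conservative — and reports `log2(count / median(count))` with per-bin GC.

## Canonical experiments and problem sizes

`opusdup.scenarios` fixes the simulated study conditions used by the test
suite and `scripts/acceptance.py`:

* **Error regime** for the separation experiments: 10⁴ duplexes over a
  432-base contig (the size of an HRAS exon target), 150 ± 10 bp fragments,
  100-base reads, 0.3% per-read error, 0.5% single-strand damage, and 0 or
  0.1% double-strand artifacts. With single-strand channels only, the DCS
  table must contain **exactly zero** non-reference calls over ≳10⁶ DCS
  bases. With the 0.1% double-strand channel added, DCS incidence estimates
  0.001 within 3 binomial sd; the effective sample size is half the DCS
  base count because the read-1 and read-2 consensus footprints of one
  molecule overlap and are not independent draws.
* **Dilution series**: spike levels 1%, 0.1%, 0.05% and 0.01% VAF on a
  shared 90-base reference, 16 000 duplexes per level (100 000 at 0.01%)
  and a 60 000-duplex variant-free background, with 3 read pairs per strand
  guaranteed. Sizes follow a power calculation done at design time: the
  lowest level needs ≈10 expected alternate molecules for the χ²/BH call to
  succeed with high probability (an alternate count ≥ 4 at these depths
  gives p < 0.05), and duplex coverage at every level exceeds 30 000.
  Observed VAF bands again use molecule-level effective n (coverage / 2).
* **Dropout**: 4 000 duplexes at 60% per-strand survival; recovery is a
  (paired) binomial proportion over surviving strands, so the test band is
  3·√(2·s(1−s)/n_strands).

These sizes keep the whole suite and the acceptance script to a few minutes
on a single CPU while leaving every statistical band at 3 sd.

## Known limitations

* Consensus is substitution-only; indel-aware collapse is out of scope.
* Clipped-base semantics: boundaries use aligned ends; soft-clipped
  portions are dropped rather than reconstructed.
* Re-mapping of consensus FASTQs is external; in simulator mode coordinates
  are propagated directly.
* The family-size distribution is a configurable stand-in (shifted
  Poisson); empirical distributions from real libraries are typically
  overdispersed.
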