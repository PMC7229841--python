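# Methods

## Scope and model

`tebase` quantifies large-scale base editing at repetitive elements
(LINE-1, Alu, HERV-family transposons). A single guide RNA matching a
TE consensus addresses thousands to hundreds of thousands of loci at
once; the pipeline covers the five quantitative stages of such an
experiment:

1. **Guide design** — enumerate protospacers adjacent to a PAM on the
   consensus and flag those whose C→T deamination inside the editing
   window converts a sense codon to TAA/TAG/TGA (a CBE knockout guide),
   plus those with ≥1 window adenine (reusable with an ABE).
2. **Target census** — count genomic matches of the protospacer within
   a Hamming-distance budget, classified by PAM (NGG / NAG / other).
3. **Copy number** — invert qPCR Ct values against a single-copy
   control with the efficiency-corrected ΔCt model.
4. **Amplicon quantification** — align 150 nt paired-end amplicon reads
   and report windowed indel frequency, per-position deamination, and
   dual-guide deletion frequency.
5. **Edit scaling** — convert a conversion frequency f and a copy
   number C into an expected `f × C` edited loci per haploid genome.

## Key conventions and parameters

* **Editing window**: 1-based protospacer positions counted from the
  PAM-distal (5′) end, inclusive `[3, 9]` by default; configurable per
  editor generation. Stop-codon annotation edits **all** window Cs
  simultaneously by default (adjacent Cs are efficiently co-edited by
  CBEs); a per-C mode exists for conservative screening.
* **Analysis window**: from the protospacer 5′ start through the PAM
  plus 7 nt — 30 nt for a 20 nt SpCas9 guide. For a − strand guide the
  window is mirrored on the forward strand so it still extends past the
  PAM in the guide's own 3′ direction. All indel, conversion and purity
  frequencies are computed over this window.
* **Coordinates**: 0-based, half-open, forward-strand throughout
  (including BED export). A guide or census hit stores the *leftmost*
  coordinate of its protospacer interval regardless of strand; the
  protospacer string is always 5′→3′ on its own strand. This keeps
  re-extraction (`seq[start:start+20]`, reverse-complemented for −)
  trivially correct and interval arithmetic convention-free.
* **Mismatch counting**: over the 20 nt protospacer only. The PAM is
  classified but not required by default (`require_pam=False`), since a
  census tabulated by PAM class must retain non-PAM hits; N in the
  genome never matches a concrete guide base and so always counts as a
  mismatch. IUPAC codes other than N are rejected in references.
* **Alignment**: Gotoh affine-gap DP (numba kernel), match +2,
  mismatch −4, gap open −10 (first gap base), extension −1. Reads use
  *fitting* mode — free reference end gaps, full read consumption —
  because a 150 nt read is an infix of the amplicon; a true global mode
  drives the oracle cross-checks. Sequencing orientation is
  auto-detected by aligning both the read and its reverse complement.
  Ties are resolved deterministically and indels are then left-shifted
  through homopolymer runs, so equal inputs give equal CIGARs. Reads
  under 50% identity are flagged unaligned and leave all denominators.
* **Indel frequency**: a pair enters the denominator when ≥1 aligned
  mate fully spans an analysis window; it counts as edited when an
  I/D operation overlaps the window in *every* spanning mate
  (mate-concordance default, matching how paired amplicon data is
  usually filtered) or in *any* mate (`require_both_mates=False`,
  single-end degradable). Relaxing concordance can only increase the
  frequency; a property test pins this monotonicity.
* **Deamination report**: only reads fully spanning the window count
  (partial overlaps excluded — the denominator must be constant across
  positions); one mate per pair. Editable positions are all window
  positions whose reference base is C (CBE) or A (ABE), reported on the
  protospacer strand. Conversion at a position = intended-base reads /
  coverage; the headline number is the mean over editable positions and
  the per-position maximum is also reported. Purity at a position =
  intended reads / all non-reference reads there (NaN when nothing is
  non-reference); a read-level purity (edited reads whose only window
  deviations are intended conversions) is reported alongside, with the
  per-position value primary.
* **Dual-guide deletions**: classification is by exact containment of
  two auto-derived 20-mers — one from the centre of the inter-guide
  region (wild type only) and one spanning the predicted cut-to-cut
  junction (deletion only), with the blunt cut fixed 3 nt 5′ of the
  PAM. Exact matching is deliberate: at amplicon scale a 20-mer with
  sequencing error rates ≲1% misclassifies ≪1% of reads into
  `unclassified`, never across classes, and the frequency denominator
  excludes unclassified reads. Non-diagnostic probes raise an error
  demanding manual probes.
* **qPCR**: copies per haploid = `E^(Ct_ref − Ct_target)` with E ∈
  (1, 2], default 2.0 (100% efficiency). Replicates average on the Ct
  scale. Ploidy multiplies to a per-cell count but is metadata only:
  downstream loci arithmetic uses per-haploid constants (26 000 for
  293T LINE-1, 19 000 for iPSC LINE-1), which is the scale the
  published counts are on.
* **Rounding**: loci estimates are rounded only on explicit request
  (`none`, `nearest_10`, `nearest_100`, `sig3`; halves round up), and
  the mode is recorded in the output. Published counts round
  inconsistently across magnitudes, so silent rounding would be a trap;
  a couple of published pairs (e.g. 4.94% of 26 000 printed as ∼1290)
  are only consistent with unrounded source frequencies and are
  therefore not asserted anywhere.

## What the simulators emulate — and what they do not

`simulate_amplicon_reads` draws molecules i.i.d.: allele (deletion
fraction), per-position intended conversions, per-position bystander
substitutions, at most one window indel per molecule, then 150 nt
paired reads from the molecule ends with uniform per-base substitution
error. `simulate_te_genome` plants consensus copies at non-overlapping
random slots on uniform-random background with i.i.d. divergence.
`simulate_qpcr` generates Cts from the exact ΔCt model plus Gaussian
cycle noise. All three are byte-deterministic given a seed, and each
emits a truth table the estimators are checked against.

Not modeled: quality-score-correlated errors, PCR duplicates and
chimeras, subfamily structure/polymorphism of real TEs (the reason real
Alu amplicons can be unanalyzable), alignment-reference bias, and
coverage variation. Passing tests therefore demonstrate estimator
correctness under clean generative assumptions, not robustness to every
artefact of real libraries.

## Problem sizes and numerical choices

The test suite and the reproduction script use 4 000 read pairs for
conversion recovery (binomial 3-SD check at p = 0.25), 2 000 reads at a
40% deletion fraction, a constructed 100-pair indel fixture with known
10%/15% answers, 1 Mb planted genomes for census/oracle equivalence,
500 random ≤40 nt pairs for the aligner oracle, and a noiseless ΔCt
round trip at 26 000 copies — sizes at which the statistical tolerances
are tight enough to catch real defects while the whole suite stays
interactive. Stochastic checks use 3 binomial SDs; exact checks use
machine precision or printed precision. The DP kernel uses float64
scores with a −1e18 sentinel; `scan_pams` discards (never clips) guides
overlapping reference ends and skips protospacers containing N.

## External validation (not run here)

Against hg38 the published census total for the canonical LINE-1 ORF2
guide at ≤2 mismatches is 12 657 (about half the qPCR copy estimate —
reference assemblies systematically undercount repeats). Reproducing
it needs the ~3 GB reference and depends on unstated analysis settings
(strand handling, N policy, PAM requirement), so it is not part of the
automated suite. To run it manually: download the Ensembl hg38
toplevel FASTA and call

```python
from tebase import enumerate_matches, summarize_census
from tebase.io import read_fasta
hits = enumerate_matches(read_fasta("hg38.fa"), "<ORF2 protospacer>", 2)
print(summarize_census(hits).total)
```

Both `require_pam` modes should be inspected, since reference
undercounting of repeats and settings ambiguity both shift the total.

## Known limitations

* The aligner is amplicon-scale (O(read × reference) per read); it is
  not a genome-scale mapper and does not model quality scores.
* Census matching is substitution-only (no bulges), matching the
  Hamming-distance definition of the copy-number census; it is not an
  off-target activity model and computes no CFD/MIT scores.
* Indel events are catalogued per (position, size, type) after
  left-shift normalisation; biological micro-homology resolution may
  place the same physical event differently in other tools.
* The per-C stop-annotation mode enumerates single-C edits only, not
  all 2^k subsets of window Cs; with the default all-Cs mode this
  brackets the realistic co-editing regimes.
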