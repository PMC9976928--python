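# Methods

This note records the models, numerical choices and known limitations behind
`passerpipe`, in the spirit of the methods documentation of simulation and
annotation packages.

## Coordinates and orientation

All coordinates are 0-based half-open in memory.  BLAST tabular input is 1-based
inclusive and converted on read; BED output follows BED conventions.  Minus-strand
loci are reverse-complemented into transposase-sense orientation at flank
extraction, with flanks swapped, so every downstream step (ORF finding, consensus,
divergence) sees a single orientation.  Reported element coordinates are always
plus-strand genomic.

## Boundary calling

A candidate locus is scanned over all (start, end) pairs within ± 30 bp (the
`boundary_slop`) of the merged homology core; the slop must exceed the TIR length
because protein-level homology hits begin inside the coding sequence, not at the
element termini.

For each pair the best terminal inverted repeat is sought under a substitution-only
model (lengths 10–40 bp, mismatch fraction ≤ 0.2, termini offsets ≤ 5 bp), scored as
matched positions minus twice the mismatches.  Gapped TIR alignment is deliberately
not modelled: PS TIRs are short (< 30 bp) and indel tolerance adds ambiguity without
adding signal at this scale.  Ambiguity characters count as mismatches and can never
form a TSD — the conservative reading.

The pair score is

    tir_score − 2·(left_offset + right_offset) + 10·[TA TSD] + tsd_length

Three interacting design choices deserve explanation, all driven by the fact that
the TA dinucleotide is its own reverse complement:

1. **Offset charge (2/bp).**  The TA TSD extends any terminal inverted repeat by two
   perfectly pairing positions, so without a charge stronger than 1 per offset bp,
   boundary pairs shifted onto nearby spurious TAs tie with or beat the true pair.
   A TIR flush with the termini is the hallmark of a real boundary.
2. **TSD-class prior.**  PS integrates exclusively into TA.  Whenever any candidate
   pair exhibits a TA TSD the selection is restricted to those candidates; the
   class maximum wins.  Pairs with non-TA duplications (random flank word matches)
   cannot then displace a TA-consistent parse.
3. **Outermost preference within a margin of 3.**  A TIR that itself contains a TA
   at offset *j* mirrors it (inverted repeat) into an exact internal TSD + TIR decoy
   at (start + j, end − j).  Decoys of a real element always lie inside it, never
   outside, so among TA-class candidates scoring within 3 of the class maximum the
   longest element is taken.  The margin tolerates one extra mismatch in the outer
   TIR fragment; during development, margins 0/3/7 recovered 198/199/194 of 200
   planted copies within ± 2 bp, and 3 was adopted.

If no inverted repeat is found anywhere, the copy keeps the homology-core boundaries
with a score of 0, mirroring the fallback of manual curation when termini are
unresolvable.

**Limitations.**  Boundaries are decided per copy from sequence evidence alone; no
family-level TIR consensus is fed back.  Two situations are genuinely unresolvable
at the single-copy level: (i) a second TA within a few bp of the duplicated one
makes two parses structurally identical (both TIR + TA-TSD elements); (ii) a TIR
whose within-copy comparison divergence exceeds the 0.2 mismatch bound (≈ 1 % of
copies at K = 0.05, since the comparison sees mutations of both TIRs) offers no
anchorable repeat, and the boundary falls to an internal decoy or the core.  The
synthetic generator therefore plants only at TA sites isolated by ≥ 12 bp from any
other TA — unidentifiable truths make no benchmark — while case (ii) remains as an
irreducible tail.

## Annotation rules

ORFs are ATG-to-stop over the three forward frames (the element is in sense
orientation; PS transposases are encoded by a single intronless gene).  The ≥ 300 aa
rule is applied inclusively.  The DD35D triad requires D–D spacing within a broad
configurable 50–250 residues (the family definition fixes only the 35-residue
second spacer); the DDE variant (E as third residue) is available but off by
default.  DBD motifs are detected by position-weight-matrix scanning with a
threshold — a deliberately self-contained stand-in for profile-HMM domain search;
the shipped Brk/HTH-like matrices are synthetic test profiles matching the planted
ancestor, not natural motif models, and users supply their own matrices for real
data.  Copy counting applies strict `coverage > 0.40 and identity > 0.80` against
the consensus.

## Consensus and divergence

Pairwise global alignment uses match +1 / mismatch −1 / gap −2 (linear gaps),
delegated to Biopython's `PairwiseAligner`; the optimal score is what the tests pin
against an independent dynamic-programming oracle.  Consensus building is
center-star: every copy is aligned to a reference, per-reference-column base counts
are accumulated, gap-majority columns are dropped, and ties resolve in fixed
A < C < G < T order (logged).  Families with more than five intact copies get a true
consensus; smaller families are represented by an intact copy with complete TIRs.

K2P uses pairwise deletion (gap or ambiguous columns leave the P/Q denominators) and
flags saturation when either log argument is non-positive; saturated copies are
excluded from landscapes.  No CpG adjustment is applied.  Divergence is measured
copy-versus-consensus, not all-pairs, matching standard repeat-landscape practice;
"transposase identity" reports the all-pairs mean (the consensus-anchored
alternative is a config switch).  The young threshold is a strict K < 0.02; a family
is called recently active at ≥ 5 young copies or a ≥ 10 % young fraction.

## Integration-site statistics

Feature categories use promoter = 1 kb upstream of the TSS and downstream = 1 kb
past the TES (the category names are standard; their extents are package defaults,
configurable and logged).  Precedence is promoter > exon > intron >
genic-unresolved > downstream > intergenic, with nearest-TSS tie-break — a
deterministic single label per site.  Expression groups are equal-count octiles of
expression-ranked genes; frequency is insertions per Mb of group gene length, which
is simultaneously per-gene normalization because the groups hold equal counts.
Fisher's exact test is two-sided by point-probability summation: exact rational
arithmetic for tables with total ≤ 500 (the comparison "pmf ≤ observed pmf" is then
free of floating-point tie artifacts), scipy's implementation of the same definition
for larger tables.  Raw p-values are reported with the four-threshold star mapping;
no multiple-testing correction is applied by default (a deliberate mirror of the
star-annotation convention; a Benjamini–Hochberg option would be a thin wrapper).
Random backgrounds come in two modes — uniform over the genome, and TA-matched
(uniform over TA dinucleotide starts); the TA-matched null is the fairer background
for motif and fold questions about a TA-targeting element, and analyses report which
null they used.

## Synthetic-data generator

The generator's job is construction by contract: every planted feature must be
recoverable by the package's own detectors at mutation load zero.

- Background genomes are i.i.d. at 41 % GC — vertebrate-like composition, and the
  simplest null that exercises TA-site logic.  Real genomes' repeats, isochores and
  CpG depletion are *not* emulated; passing tests demonstrate correctness of the
  machinery, not performance on real genomic complexity.
- The ancestral element defaults mirror the most active natural family member:
  28-bp TIRs, TA TSD, a 425-aa transposase, 2 388 bp total.  The bases immediately
  inside the TIRs are pinned non-complementary so the planted inverted repeat is
  exactly its nominal length, and an in-frame stop is placed just before the ATG so
  the ORF call is exact.
- `mutate_to_k` solves K(P, Q) = K_target with P/Q fixed at 2.0 (a conventional
  transition bias) by 1-D root finding (residual ≤ 1e-9), then applies independent
  per-site substitutions; measured K is unbiased for the target (round-trip checked
  to ± 0.01 on 20-replicate means).  Substitution-only by design: K2P ignores gaps.
- Burst ages are expressed directly as K targets — truth lives on the same scale as
  the measured landscapes, with no molecular-clock conversion.
- Insertion-site simulation samples TA positions with weight
  genic × TSS × expression × context.  The genic weight is derived from the
  *target observed fold* g as r = g(1−f)/(1−gf) for genic TA fraction f, so a
  TA-matched background comparison recovers g in expectation (a bare weight ratio
  of g would recover a smaller fold whenever genes cover a non-negligible genome
  fraction).  The TSS term is 1 + A·exp(−d²/2σ²) — additive around 1, so distant
  sites keep non-zero probability.  Sampling is with replacement, seeded, and the
  truth table records every generative weight.

## Problem sizes

Tests and the acceptance script use genomes of 0.12–1.3 Mb, families of 8–60
copies, and site sets of 400–2 000 against 3 000–20 000 random loci — sizes at which
every recovery experiment completes in seconds while keeping binomial counting error
well inside the asserted tolerances (e.g. the null-calibration genome is gene-dense
so the genic-fraction standard error at n = 2 000 sits ≈ 3 σ inside the ± 0.1 fold
band).

## Known limitations

- The homology search itself (TblastN) is external; the pipeline starts from its
  tabular hits, and the 1e-100 e-value cut is applied as a filter default.
- No gapped TIR model, no LINE/Helitron-type elements, no HMM domain search, no
  phylogenetic tree inference.
- Boundary calling is per-copy (see above); a family-consensus-TIR refinement pass
  is the natural extension for real-data work.
- The chromatin-state module assumes non-conflicting segmentations and reports
  states absent from the background as fold-undefined rather than inventing a
  pseudocount.
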