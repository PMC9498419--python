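# Methods

## Problem and scope

`gedscreen` implements the downstream analysis of a gene-doping screening
test for thoroughbred horses based on targeted amplicon resequencing. The
package begins where the upstream read pipeline (QC, alignment, GATK
variant calling) ends: its inputs are VCF variant calls with GT/AD/DP, a
per-base depth table standing in for BAM-derived depth, target regions in
BED, a catalogue of variants known in the thoroughbred population, and a
panel of parentage SNVs with population REF-allele frequencies. It covers
two linked analyses:

1. **Edit screening** — find INDEL genotypes plausibly produced by
   CRISPR/Cas9 knockout (homozygous-alternative or compound-heterozygous
   ALT1/ALT2) and filter them against the population catalogue and a depth
   floor.
2. **Parentage verification** — Mendelian-consistency checks of foals
   against alleged parents on a 120-SNV panel, with per-locus and combined
   exclusion-power statistics, to detect surrogate (non-biological) dams.

Read-level work, primer design, functional annotation and Sanger
confirmation are out of scope by design.

## Genotype calling and the depth gate

Variant callers emit only sites that differ from the reference, so the
absence of a panel locus from a VCF is ambiguous: the sample may be
homozygous reference, or the site may simply not have been sequenced.
The package resolves this with a depth gate: a missing record is called
HomoREF only when the site's depth **strictly exceeds** `call_depth`
(default 50x); otherwise it is a NoCall. The same strict threshold is
applied to called genotypes. Depth 50 exactly is a NoCall — the boundary
is tested explicitly. When both a VCF `DP` and a depth-table entry exist,
the depth table wins (it is the BAM surrogate and includes reference-only
sites).

Called genotypes are trusted as emitted. A call whose allele-depth split
contradicts its class (a heterozygote with minor-allele fraction below
`min_minor_allele_fraction = 0.10`, or a homozygote above it) is flagged
`allele-imbalance` but never re-called: the flag feeds panel pruning
without inventing a re-genotyper the evidence does not support.

## The three-stage edit screen

Stage 1 selects INDEL calls with zygosity HomoALT or CompoundHet. Both
classes can arise when Cas9 cuts both chromosomes; heterozygous REF/ALT
variants are indistinguishable from natural variation and are deliberately
never selected (a documented sensitivity limit, not an oversight). SNVs
are never selected. Callers occasionally emit a compound heterozygote as
two overlapping heterozygous records; such pairs are included at stage 1
flagged `possible-compound` (conservative screening).

Stage 2 excludes candidates already present in the population catalogue.
Matching is exact on normalized `(chrom, pos, ref, alt)` keys —
suffix-then-prefix trimming with no reference-genome context, idempotent
by construction. A compound heterozygote is excluded only when *both* of
its alleles are catalogued. Stage 3 excludes candidates whose site depth
is not strictly above `min_candidate_depth` (default 50x, the same
standard as genotype calling — one coherent depth rule across the
pipeline; the threshold is a package decision, surfaced as
`--min-candidate-depth`). Stages run in fixed order 1→2→3 and each
candidate records the first applicable exclusion, so the report conserves
counts: stage-1 = known-excluded + depth-excluded + final.

Coding status (exon overlap) is annotated but does not gate candidacy;
`--coding-only` reproduces the narrower reading. Large INDELs
(> 50 bp) whose span lies within 25 bp of an amplicon boundary are
annotated `amplicon-end blind spot`: soft clipping of read ends makes such
variants prone to being missed upstream, so an annotation (never a filter)
documents reduced sensitivity there. The 25-bp default derives from the
observed failure case — a heterozygous 77-bp deletion starting 22 bp from
its amplicon end that the upstream caller dropped entirely.

## Parentage statistics

For a biallelic locus with REF frequency p and q = 1 − p:

- He = 2pq,
- PE1 = pq(1 − pq) — probability the locus excludes a random non-parent
  when the other parent is known (trio test),
- PE2 = 2p²q² — probability for a lone alleged parent (duo test), where
  only opposite homozygotes exclude,
- combined PE = 1 − Π(1 − PEᵢ) across loci.

PE1 was verified against exact enumeration over all genotype
configurations under HWE, and both formulas are validated by Monte-Carlo
in the test suite (10,000 replicates, 3-standard-error bands). Combined
values are reported **truncated toward zero** at the requested precision
(10 decimals for PE1, 6 for PE2): truncation is the conservative choice
for an exclusion-power claim.

The trio checker declares a child consistent iff its two alleles can be
partitioned as one transmissible by the sire and one by the dam; the duo
checker requires a shared allele. Both are tested against brute-force
enumeration of all 27 trio / 9 duo biallelic genotype combinations.
NoCalls propagate: any NoCall member makes the locus a `no_call`, which is
tallied separately and never counted as an exclusion.

Panel pruning removes a locus on **any** inconsistency in any true trio
(zero tolerance) — the only policy under which pruning leaves zero
inconsistencies across all trios, as the published tallies show.
Declaring a non-parent from k ≥ 1 inconsistent loci is report-level
policy, configurable; the package reports raw counts.

## Synthetic data

The generator stands in for the study's horses and edited cell lines; all
outputs are deterministic under a seed.

- **Genotypes**: founders i.i.d. under HWE at the packaged panel's 120
  published REF frequencies; offspring by uniform Mendelian transmission.
  Pseudo-relatives (pseudo-sire/dam/parent) are fresh unrelated HWE draws.
  The default pedigree design is 29 true trios plus 5 pseudo-trios, 5
  half-pseudo-trios, 5 true duos and 5 pseudo-duos.
- **Depths**: per-amplicon lognormal draws (default mean 200x, log-sd
  0.5), constant across an amplicon's bases — coverage in amplicon data
  varies between amplicons (primer efficiency) far more than within. A
  designated low-coverage stratum (default mean 15x) is capped at 45x and
  the high stratum floored at 60x, so planted pass/fail fractions are
  recovered exactly under any seed. The distributional family is
  illustrative; nothing downstream depends on it beyond the strata.
- **Edits**: the four documented myostatin edits (three homozygous 1-bp
  insertions at chr18:66607750, 66607753, 66609936; one heterozygous
  77-bp deletion at chr18:66605475, 22 bp from its amplicon end) are
  packaged as `EditSpec` presets. Injection is idempotent and refuses
  sites outside every amplicon. The deleted 77-bp sequence is synthetic
  (only coordinates are published; the package deliberately has no
  reference-FASTA dependency).
- **Faults**: each designated fault locus gets one targeted corruption
  that provably creates a mis-inheritance — a heterozygous trio member is
  flipped to a homozygote chosen to break consistency. `low_depth` faults
  record depth just above the call gate with one-allele reads (shallow
  coverage sampling a single allele) and additionally push a few random
  samples below the gate into NoCall; `allele_bias` faults keep normal
  depth with skewed allele depths (PCR bias) and carry the
  `allele-imbalance` flag. The targeted (rather than unconditionally
  random) flip makes the 144 → 120 pruning outcome reproducible under any
  seed; the mechanisms mirror the two observed causes of mis-inheritance.
- **Presets**: `validation-2022` (20 horses + 4 edited cell lines, a
  catalogue containing 4 HomoALT and 1 compound-het INDEL, 3 novel INDELs
  in low-coverage amplicons, and the 4 edits — 11 stage-1 loci → 5 known
  → 3 low-depth → 3 final) and `casework-2022` (20 horses, 7 stage-1
  loci, 6 catalogued, 1 low-coverage → 0 final). Variant-pool sizes are
  scaled down from the study's hundreds of loci; the stage-by-stage
  structure of the filter is preserved exactly. The validation preset
  keeps the 77-bp deletion in the emitted calls so the screen report can
  annotate it as a non-candidate in the blind-spot zone;
  `apply_amplicon_end_dropout` reproduces the "not detected" behaviour
  when enabled.

What passing tests on synthetic data do **not** show: robustness to real
amplicon artifacts (chimeric reads, index hopping, WGA artifacts — the
latter deliberately unmodeled, as no statistical description exists),
population structure or linkage between panel SNVs (loci are simulated
independently; combined PE likewise assumes independence), or upstream
caller behaviour beyond the modelled blind spot.

## Numerical conventions

- Report rounding is decimal **half-up** (0.1875 → 0.188 at 3 dp), not
  Python's banker's rounding; combined PE uses truncation toward zero.
- Percentages are reported half-up at 1 decimal.
- Coverage "greater than t×" is strict at every threshold (50/20/10).
- Phased and unphased genotypes are treated identically; chromosome names
  are exact strings (a warning fires when panel and VCF share none).
- Multi-allelic records are kept whole (compound-het detection needs both
  ALTs at one site); normalization trims jointly across all alleles.

## Known limitations

- Heterozygous artificial edits cannot be distinguished from natural
  heterozygous variation; the screen does not attempt it.
- Re-computing He/PE from the published panel's 3-dp frequencies
  reproduces the published per-locus columns only to ±0.001 (those columns
  were evidently computed from unrounded frequencies); the combined PE
  figures reproduce exactly after truncation.
- Exclusion matching compares allele identity only, not zygosity, and
  uses exact normalized keys — a catalogued variant represented
  differently by an upstream caller would not match without prior
  normalization (the package normalizes its own inputs).
- Diploid autosomal loci only; no sex chromosomes, no likelihood-based
  paternity index, no mitochondrial or microsatellite support.
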