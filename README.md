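# gedscreen

Gene-editing (gene-doping) screening and SNV parentage verification for
targeted amplicon resequencing of thoroughbred horses.

Creating genetically modified racehorses is prohibited, and CRISPR/Cas9
knockouts — typically short INDELs from non-homologous end joining in
performance genes such as myostatin (*MSTN*) — leave no transgene to detect.
`gedscreen` implements the variant-level analysis of a screening test for
such edits, plus the companion SNV parentage panel that flags foals carried
by surrogate dams. It is written for screening labs and for anyone studying
the statistics of exclusion-based parentage testing.

## What it computes

**Edit screen** — from VCF calls (GT/AD/DP), a per-base depth table, BED
targets and a population-variant catalogue, candidates are filtered in
three stages:

1. select homozygous-alternative (ALT/ALT) or compound-heterozygous
   (ALT1/ALT2) INDEL genotypes — the classes biallelic Cas9 editing
   produces;
2. exclude variants already known in the thoroughbred population (exact
   normalized-key match);
3. exclude variants whose site depth is not strictly above 50×.

Heterozygous REF/ALT variants are never candidates (indistinguishable from
natural variation), and large INDELs near amplicon ends are annotated as a
soft-clipping blind spot.

**Parentage** — Mendelian consistency of foal/sire/dam trios and
single-parent duos over a packaged 120-SNV panel, pruning of misbehaving
loci, and exclusion power per locus and combined. For REF frequency p
(q = 1 − p):

    He  = 2pq
    PE1 = pq(1 − pq)          (trio: one parent known)
    PE2 = 2p²q²               (duo: opposite homozygotes exclude)
    PE  = 1 − Π(1 − PEᵢ)      (combined across loci, truncated toward zero)

**Synthetic data** — a seeded generator emulating the study designs:
Hardy–Weinberg genotypes at the panel's published frequencies, true and
pseudo pedigrees, per-amplicon depth strata, injected myostatin edits,
amplicon-end dropout and genotyping faults. See `docs/methods.md`.

## Worked example

Simulate the edited-cell validation design and screen it:

```sh
$ gedscreen simulate --preset validation-2022 --seed 1 --out demo
wrote validation-2022 dataset (seed 1) to demo
$ gedscreen run --dataset demo
{
  "regions": 12,
  "pass_gt50": 9,
  "pct_gt50": 75.0,
  ...
}
edit screen: 3 final candidate(s)
candidates found; flagging for follow-up
$ echo $?
2
```

Nine of twelve amplicons exceed 50× mean depth (three are deliberately
low-coverage). The screen starts from 11 HomoALT/ALT1-ALT2 INDEL loci,
excludes 5 as known population variants and 3 for low depth, and reports
the 3 planted homozygous 1-bp *MSTN* insertions:

```
EC2 chr18 66607750 C>CT HomoALT depth 208
EC3 chr18 66607753 T>TA HomoALT depth 203
EC4 chr18 66609936 T>TA HomoALT depth 178
```

The fourth edited line (EC1, heterozygous 77-bp deletion 22 bp from the
amplicon end) is correctly *not* a candidate and appears in the report's
annotations as `amplicon-end blind spot / non-candidate (Het)` — exactly
the documented sensitivity limit of the method. Exit code 2 means
"candidates found, follow up" (0 clean, 1 error).

Panel statistics from the library:

```python
>>> from gedscreen.formats_io import load_packaged_panel
>>> from gedscreen.parentage import panel_report
>>> stats, pe1_combined, pe2_combined = panel_report(load_packaged_panel())
>>> stats[0].locus.id, round(stats[0].he, 3), round(stats[0].pe1, 3), round(stats[0].pe2, 3)
('BIEC2-11336', 0.487, 0.184, 0.118)
>>> pe1_combined, pe2_combined
(0.9999999998, 0.999997)
```

A random non-parent is excluded by at least one panel locus with
probability 0.9999999998 in a trio test and 0.999997 in a duo test.

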