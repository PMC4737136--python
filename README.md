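# starpap

Cis-element analysis of poly(A) site selection by the non-canonical
nuclear poly(A) polymerase **Star-PAP**.

Almost every mRNA 3′-end is made by cleavage at the 3′-UTR followed by
poly(A) addition. Canonical poly(A) polymerases (PAPα/γ) are recruited
through the CPSF/CstF cleavage complex: CPSF recognises the AAUAAA
poly(A) signal (PAS) and CstF-64 binds a U/GU-rich **downstream
sequence element (DSE)**. Star-PAP instead binds its target 3′-UTRs
directly, through an AUA-core motif in the **upstream sequence element
(USE)**, and processes them independently of PAPα — even though the
targets carry a perfectly canonical AAUAAA. The resolution of that
puzzle is in the DSE: Star-PAP targets have a *suboptimal* (U-poor)
DSE that cannot load CstF-64, which excludes the canonical machinery.

This package implements that analysis as a tested, reusable pipeline
for anyone studying 3′-end processing cis-elements or alternative
polyadenylation:

- **Motif discovery.** Enumerate every 5-mer carrying a complete AUA
  triplet (48 placements, 47 distinct words), mask AAUAAA-like
  sequence (Hamming distance ≤ 1), count gene-level occurrence in the
  USE window (default upstream distances [−150, −50) of the cleavage
  site) of knockdown-down-regulated "target" genes (fold change
  > 1.8) versus background genes, test each word with a one-sided
  Fisher's exact test (p < 0.05; BH q-values reported), keep words
  present in > 55% of target genes, map them onto 7-mers with AUA at
  the central position, and summarise the most-occurring 7-mers as a
  position weight matrix `M[b][j] = Σ w·1[word_j = b] / Σ w`, with a
  positional histogram of occurrences relative to the cleavage site.
- **DSE profiling.** U fraction, longest U run, most U-rich 10-nt
  sub-window and GU/UG dinucleotide fraction per DSE, called `U_RICH`
  (run ≥ 4, or window U ≥ 0.5, or GU/UG ≥ 0.4) or `SUBOPTIMAL`.
- **PAP-selection classifier.** The joint USE × DSE truth table:
  (motif+, suboptimal) → `STAR_PAP`; (motif+, U-rich) → `BOTH`;
  (motif−, U-rich) → `PAP_ALPHA`; (motif−, suboptimal) → `NONE`;
  with in-silico reporter edits (AUA → GGG; UUUUUU into the DSE).
- **Synthetic cohorts.** A seeded generator that emits FASTA/BED6/
  fold-change files plus ground truth, so the whole pipeline is
  exercisable and testable at desk scale.

## Worked example

```python
from starpap import CohortConfig, generate_cohort, run_analysis

cohort = generate_cohort(CohortConfig(seed=7))
result = run_analysis(cohort.sequences, cohort.sites, cohort.fold_changes)
print(result.frequent_words)        # ['ACAUA', 'AUAUA', 'CAUAU']
print(result.sevenmer_counts[:2])   # [('ACAUAUA', 83), ('AUAUACG', 10)]
print(result.pwm.consensus())       # ACAUAUA
print(result.histogram.mode_center())  # -95.0
```

The cohort embeds the 7-mer `ACAUAUA` in 90/100 target USEs between
−120 and −60 nt upstream of the cleavage site. The analysis recovers
its three AUA-core 5-mers as the frequent set (each in 83% of target
genes vs ≤ 13% of background, Fisher p ≤ 10⁻²⁴), ranks `ACAUAUA`
first among central-AUA 7-mer candidates (83 genes vs 10 for the
runner-up), and places the positional mode at −95 nt — inside the
embedding window. Running `python examples/04_reporter_mutants.py`
walks one wild-type site through the reporter mutant series:

```
variant  USE motif    DSE call  predicted PAP
WT            True  SUBOPTIMAL       STAR_PAP
U-Mut        False  SUBOPTIMAL           NONE
D-Mut         True      U_RICH           BOTH
DU-Mut       False      U_RICH      PAP_ALPHA
```

i.e. killing the AUA motif abolishes Star-PAP-dependent processing,
inserting a U-rich DSE admits the canonical polymerase, and doing both
converts a Star-PAP site into a canonical PAPα site.

The `examples/` scripts cover each capability; the `starpap` CLI
(`simulate`, `extract`, `enrich`, `pwm`, `positions`, `dse`,
`classify`, `run-all`) exposes the same stages on files:

```sh
starpap run-all --out-dir results_dir --seed 7
```

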