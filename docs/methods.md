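# Methods

## The model

Two cis-element readouts jointly determine which nuclear poly(A)
polymerase (PAP) processes a cleavage site:

1. **USE motif.** Star-PAP binds its target 3′-UTRs directly through
   an AUA-core motif located in the upstream sequence element (USE),
   the region roughly −150..−50 nt upstream of the cleavage junction.
   Motif evidence is treated as presence/absence — the biochemical
   evidence it models (band shifts, footprints) is binary — with an
   optional graded PWM log-odds route.
2. **DSE richness.** The canonical machinery requires CstF-64 loaded
   on a U/GU-rich downstream sequence element (DSE). A DSE without
   discernible U/GU-richness ("suboptimal") excludes CstF-64 and with
   it PAPα.

Crossing the two binary readouts yields the four-state site call:
`STAR_PAP` (motif+, suboptimal), `BOTH` (motif+, U-rich), `PAP_ALPHA`
(motif−, U-rich), `NONE` (motif−, suboptimal). `NONE` predicts that no
modelled polymerase engages the site — a prediction of
non-processing, not a degradation mechanism.

## Motif discovery procedure

- **Candidate space.** All 5-letter RNA words carrying a complete AUA
  triplet: 3 offsets × 16 flank combinations = 48 placements over 47
  distinct words (`AUAUA` admits the triplet at offsets 0 and 2). The
  enumeration API exposes both counts; gene-level statistics use the
  distinct-word universe. 7-mer refinement restricts to the 256 words
  with AUA at the central position (offset 2).
- **Windows.** USE = upstream distances [−use_far, −use_near), default
  [−150, −50), i.e. a half-open 100-nt window; DSE = downstream
  distances [+1, +dse_len], default 50 nt. The literature quotes
  "−50 to −150" without stating endpoint inclusivity, so both
  endpoints are parameters rather than constants.
- **PAS masking.** Before any counting, every 6-nt USE window within
  Hamming distance 1 of AAUAAA is masked (replaced by N); no k-mer
  occurrence overlapping a masked base is counted. Distance-1
  variants are the standard degenerate-PAS set; the distance is a
  parameter. Masking only ever removes occurrences (monotonicity is
  property-tested).
- **Counting.** Occurrence is gene-level: a gene counts once if the
  word occurs unmasked in at least one of its analysed USE windows
  (genes with several poly(A) sites contribute one window per site,
  OR-combined).
- **Testing.** Per word, the 2×2 gene-count table (target
  with/without vs background with/without) is tested one-sided toward
  enrichment in targets: p = P(X ≥ a | margins), the hypergeometric
  tail, computed via scipy (`hypergeom.sf`). The unit and acceptance
  suites verify it against an independently coded exact-fraction tail
  sum to 1e-12 over every table with group sizes ≤ 30. Raw p < 0.05
  is the significance filter, mirroring the analysis this pipeline
  reproduces; Benjamini–Hochberg q-values (scipy
  `false_discovery_control`) are reported alongside for modern
  practice but gate nothing by default.
- **Frequent words and PWM.** 5-mers present in strictly more than
  55% of target genes are "frequent" (sorted by fraction, then
  lexicographically). Candidate 7-mers are the central-AUA words
  containing a frequent 5-mer; those present in more than 30% of
  target genes (a conservative default — the source analysis prints
  no threshold for "most occurring" — exposed as
  `sevenmer_fraction`) support the PWM, weighted by gene count, with
  zero pseudocount by default so the central columns are exact A/U/A
  indicators.
- **Positions.** Occurrences of frequent words are binned by the
  upstream distance of the occurrence midpoint (bin width 10 nt,
  required to divide the window). The histogram mode is reported as
  the centre of the most-populated bin, first bin on ties.

## DSE call

The qualitative notion "no discernible U/GU-rich sequence" is
operationalised as an explicit rule: `U_RICH` iff max U run ≥ 4, or
max U fraction over any 10-nt sub-window ≥ 0.5, or GU/UG overlapping
dinucleotide fraction ≥ 0.4; else `SUBOPTIMAL`. Every threshold is a
config key. The thresholds were chosen so that substituting the
literal UUUUUU element anywhere in a window always produces `U_RICH`
— the defining property of the U-rich reporter edit. The three U
scores are monotone under non-U→U substitution; note the
GU-dinucleotide clause alone is not (substituting U for the G of a GU
pair can destroy the pair), so a site called rich purely by GU content
can in principle revert under a U substitution. The U-run and
windowed-U clauses never revert.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes, as
ground truth for recovery testing:

- **Targets** (default n = 100): 200-nt upstream + 100-nt downstream
  of a junction annotated in BED6. USE drawn i.i.d. with G+C mass 0.60
  (split equally; A = U = 0.20); AAUAAA pasted with its start 20 nt
  upstream; with probability 0.9 one embedded 7-mer (`ACAUAUA`,
  central-AUA; alternatively sampled per gene from a supplied PWM)
  overwrites the background at a uniform position in the upstream
  window [60, 120], redrawn if it would overlap the pasted PAS.
  DSE drawn with per-base U probability 0.15 (other bases equal).
  Fold reductions uniform in [2.0, 5.0] — entirely above the 1.8
  selection cutoff.
- **Background** (default n = 100): uniform USE with the same AAUAAA
  placement, no enforced motif; uniform DSE carrying an explicit
  poly-U run (length 5–8, start at downstream distance 5–25); fold
  changes uniform in [0.8, 1.5].

Two truth-consistency rules are enforced by construction: the
embedded word is verifiably present at its recorded coordinate, and a
target's emitted downstream region must actually profile `SUBOPTIMAL`
— U-rich target draws (a ~13% event at U = 0.15, mostly via the
windowed-U clause) are rejected and redrawn with bounded retries, so
the class labels are true of the sequences, not merely intended.
Embedding replaces rather than inserts, keeping all records the same
length and the coordinate frame fixed. Incidental AAUAAA-like
hexamers arising from random draws are left in place, as in real
UTRs; the masking stage neutralises them — which also means a small
fraction of embedded motifs is legitimately lost when flanking bases
happen to complete a degenerate PAS over the motif (~5% of embedded
targets at the defaults).

Identical seeds give byte-identical output files (single numpy
`default_rng` stream consumed in fixed order).

**What the cohorts do not emulate:** genome-scale gene universes,
dinucleotide/Markov composition structure, heterogeneous UTR lengths,
multiple poly(A) sites per gene (supported by the pipeline, not
emitted by the generator), measurement noise in fold changes, or any
sequence determinants of CstF-64 affinity beyond composition. Passing
recovery tests therefore demonstrates correctness of the machinery
under the assumed cis-element architecture, not performance on real
microarray-plus-genome inputs, where background AUA prevalence and
motif dispersion differ. Cohort sizes (100 + 100) were chosen so the
full 20-cohort acceptance battery runs in seconds while keeping the
per-word binomial noise on gene fractions near 4 percentage points.

## Numerical and design notes

- Internal alphabet is RNA; DNA input is transcribed on read; every
  motif is written with U. BED is 0-based half-open; the junction is
  the boundary between the last transcribed base and the cleaved-off
  downstream sequence (chromStart on +, chromEnd−1 on −). Minus-strand
  windows are mirrored and reverse-complemented into sense
  orientation; extraction refuses (with the available extent) rather
  than pads when a flank is short.
- Target selection is strictly greater than the fold-change cutoff
  (1.8): a gene at exactly 1.8 is excluded.
- Fisher alternative defaults to one-sided "greater" — the scientific
  question is enrichment in targets; two-sided (point-probability
  rule) is available.
- PWM columns must sum to 1 within 1e-9 to be serialised (MEME
  minimal, RNA alphabet, 6 decimals; round-trips at 1e-6).
- The PWM log-odds classifier route (threshold 0 bits against a
  uniform or supplied background) is off unless a PWM is passed;
  presence/absence of frequent words is the default motif rule.
- USE GC-richness is reported but never gates the motif call; the GC
  context is treated as an accessory feature.
- Degenerate inputs: empty cohorts are valid (empty outputs);
  all-zero contingency margins, empty PWM support, non-positive
  weights, mixed window parameters and sub-subwindow DSEs all raise.

## Known limitations

- The frequent-word and 7-mer-support thresholds (0.55, 0.30) are
  sensible defaults, not fitted quantities; real cohorts may need
  different values (both exposed).
- The DSE rule is a composition heuristic; it does not model CstF-64
  binding energetics, and its GU clause is non-monotone as noted.
- The classifier treats the paralogs (PAPγ, CstF-64τ) as covered by
  their family labels and does not model CPSF-160 competition.
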