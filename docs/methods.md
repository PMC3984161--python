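# Methods

This package implements an interactome-scale analysis of intrinsic protein
disorder of the kind applied to ion-channel splice-variant families and
their interaction partners.  It consumes predictor output (per-residue
disorder propensities, 3-state secondary structure, predicted binding
regions), a multiple sequence alignment of variants, PSI-BLAST profile
data, and a function-labelled disordered-segment library; the predictors
and aligners themselves are out of scope and are consumed as files.  A
seeded synthetic-data module emulates every input class with planted ground
truth so that the full pipeline is testable without external tools.

## Disorder calls and segments

A residue is disordered when its propensity score is **≥ 0.5**.  The
literature convention says "above 0.5"; the tie at exactly 0.5 is resolved
inclusively so that predictors emitting 0.5 for ambiguous residues count
them as disordered (configurable).  Predictors that emit binary calls
bypass thresholding.  A *disordered segment* is a maximal run of at least
**4** consecutive disordered residues; a *long* segment has at least
**30** (a commonly used alternative of 50 is available via
`Config.long_segment_len`).  Disorder *content* is the fraction of
disordered calls over the chain — computed from the calls, not the
segments, so sub-threshold runs still count.  Per-protein summaries carry
content, segment counts, segment lengths and a fully-disordered flag
(content = 1).  No smoothing or merging of nearby segments is applied.

Hub proteins are interactome nodes with degree ≥ 6; the hub table reports
counts and 1-based locations of predicted disorder-based binding regions
(MoRFs and ANCHOR-style binding sites) per hub, with explicit missing
markers when a protein lacks tracks.

## MoRF typing

Molecular recognition features (MoRFs) are short (5–25 residue) disordered
regions that fold on binding.  Each region is typed from the 3-state
secondary structure (H/E/C) predicted over its residues: **alpha**, **beta**
or **gamma** when helix, strand or coil covers strictly more than half of
the region, **complex** otherwise.  The dominance rule is a design choice —
the four-way typing convention does not publish a numeric rule — and the
fraction is configurable (`dominance_fraction`).  A region at exactly 50%
of one state is complex.  Regions outside the 5–25 length range are typed
but warned about, since predicted regions may deviate.  8-state secondary
structure must be collapsed to H/E/C by the caller.

## Variant-family profiles

Per-chain annotation tracks are lifted into alignment-column space through
the gapped rows (1-based closed intervals externally, one central 0-based
conversion internally; lift∘project is the identity on every chain).
Columns are classified: a column containing a gap is an **insertion** site
(splice cassette); a gap-free column with one residue letter is
**identical**; a gap-free column with several letters is a **mutation**
site; a gapped column whose non-gap residues differ is *both* insertion and
mutation, so class fractions may total more than 100% while identical +
gap-free-mutation + insertion always tile the columns exactly.

A **majority-vote profile** keeps columns where an annotation is present in
at least 50% of variants.  The vote denominator is all variants in the
alignment by default: an annotation on a cassette carried by 6 of 22 chains
must not become "majority" merely because 16 chains are gapped there.  A
present-chains-only denominator is available and is the right choice when
asking questions *about* cassette columns themselves — e.g. the overlap of
insertion sites with disorder — where the all-variants rule would
structurally zero out minority cassettes.

Overlap statistics report |A ∩ B| / |A| as a percentage (NA when A is
empty).  Linear-motif (ELM) censuses count intervals per type (CLV, LIG,
MOD, TRG); adjacent intervals of different types are never merged.
Variants are grouped by the last three residues of their C-terminus.

## Conservation

Per-residue conservation is the relative entropy (Kullback–Leibler
divergence) D(p‖q) = Σₐ pₐ ln(pₐ/qₐ) between the residue's weighted
observed percentages (WOP, the second 20-column block of the PSI-BLAST
ASCII PSSM, row-normalised) and a background distribution q.  The
background defaults to the Robinson–Robinson frequencies (the BLAST null
model) and the logarithm is natural; both are parameters, since published
applications of the score state neither.  WOP rows summing to zero —
PSI-BLAST emits such rows for residues without weighted observations — get
an NA score and are excluded from all averages, with a flagged count
available.  Family-level conservation averages per-column scores over the
chains that have a residue there (gaps excluded from numerator and
denominator); region means ignore NA positions and an empty region is NA.
Region means over a partition of a chain, weighted by region size,
recombine exactly to the global mean.

## Function transfer

Disordered query segments are annotated by Smith–Waterman local alignment
against a function-labelled segment library (DisProt-style; the 19-label
controlled vocabulary plus "other").  Alignment uses BLOSUM62 with EMBOSS
`water` default gaps: **open 10 charged on the first gap residue, extend
0.5 on each subsequent one**.  The backend is biopython's PairwiseAligner,
whose gap model was verified against these semantics; the test suite checks
scores against an independent explicit three-matrix affine-gap dynamic
program.  Sequence similarity is

    identities / max(alignment_length, min(len_query, len_library))

and a label transfers when similarity **strictly exceeds 0.8**.  All
library entries above threshold transfer (a best-only switch exists); the
per-function census counts distinct (segment, function) pairs, so a
segment supported by many entries of one function counts once for it.
Identity requires exact letter match (X–X counts); X scores via the
matrix's X row.  Among co-optimal alignments the first traceback is taken
deterministically; co-optimal tracebacks can differ in identity count on
unrelated sequence pairs, but in the ≥75%-identity regime where transfer
decisions are made the optimum is effectively unique and similarity is
exactly symmetric.

## Statistical protocol

Two groups of per-protein values are compared with a two-sample t-test
(pooled variance) when both pass the Anderson–Darling normality test at
α = 0.05, otherwise with the two-sided Wilcoxon rank-sum test — exact
enumeration when both groups have n ≤ 8 without ties, normal approximation
with continuity correction otherwise.  Groups below 4 observations are
rejected (the AD gate is unstable there).  Population-level measures (e.g.
fraction of fully disordered proteins) are evaluated on **10** random
subsets containing **50%** of each cohort — drawn without replacement
within a subset, independently across subsets, so a protein may recur —
and the two 10-vectors are compared with the same gated protocol;
comparisons are bit-reproducible given the seed.  Zero-variance vectors
short-circuit to a flagged degenerate result instead of a test.  Medians
with 25th/75th centiles (linear-interpolation, type 7) are always
reported; significance tiers (\*: p < 0.01, \*\*: p < 0.001) derive from p
at print time.  No multiple-testing correction is applied; p-values are
raw.

## Synthetic data: what it emulates, what it does not

Generator defaults encode the study conditions: 22 channel-like variants of
~1100 residues in three C-terminal groups (DEC 6, VYR 9, ERL 7); partner
cohorts of 64 and 97 shorter chains; disorder content 18% (channel) vs 10%
and 14% (partners) with long-segment weight 0.65 vs 0.38 and a 4% rate of
fully disordered partners; column classes 78.3% identical, 16.4%
insertion, 8.1% mutation with overlap; 73% of insertion columns
disordered; planted linear-motif counts LIG 42, MOD 34, TRG 16, CLV 12;
helix-heavy MoRF types (α .87 / γ .13) for the channel; an 862-entry
library with 441 queries of which 89 are planted homologs at 85% identity
against decoys at 40%.

Mechanics and the numerical choices behind them:

- **Scores.**  Disordered residues draw from 0.5 + 0.5·Beta(8, 2), ordered
  ones from 0.5·Beta(2, 8), so thresholding at 0.5 recovers planted calls
  *exactly*; recovery tests exercise segment logic, not noise robustness.
- **Segment mixture.**  Each planted segment's long/short class is an
  independent Bernoulli draw, never conditioned on the remaining
  disorder budget (conditioning deflates the long fraction); the final
  draw's overshoot is trimmed within class bounds so content matches the
  target while classes stay intact.  Verified unbiased to within ~0.005.
- **Variant families.**  Insertion sites are contiguous cassette blocks,
  each carried by a random proper subset of chains; column-class counts
  are allocated exactly, so the planted fractions are deterministic up to
  rounding.  Cassette disorder covers a contiguous sub-block of each
  cassette at the target overlap.  Domains are placed first; motifs,
  MoRFs and background disorder avoid them (motifs occur outside globular
  domains); intervals within one track keep a 1-column gap so counts
  survive majority voting.  The *true* alignment is emitted; no aligner
  runs, so there is no aligner error to confound column statistics.
- **WOP.**  Per-residue distributions draw from Dirichlet(20·c·q); the
  true divergence is computed before integer-percent rounding
  (largest-remainder, rows sum to 100).  The default c = 0.25 puts
  per-residue conservation near 1 nat, typical of moderately conserved
  families; c may be a per-residue array to plant conserved regions.
  Rounding perturbs sharp rows by up to ~0.1 nat — the recovery tests
  bound the median error at 0.05.
- **Libraries.**  Planted queries are point-mutated copies (no indels) of
  library entries; at 85% identity the full-length local alignment keeps
  similarity near 0.85, safely above the 0.8 threshold, while 40%-identity
  decoys stay far below it.

What passing these tests does *not* show about real data: predictor error
structure (scores here are cleanly separated around 0.5, real predictors
are not), aligner artefacts (real column statistics inherit ClustalW's
choices), phylogenetically realistic sequence evolution, and any biological
coupling beyond the planted ones.  Parameter-recovery results certify the
analysis machinery, not predictor accuracy.

## Problem sizes and determinism

Every generator requires an explicit seed and is bit-reproducible.
Recovery suites run at 300-protein cohorts (tight sampling error on
content and the long fraction) and single default-size families; the
statistical calibration uses 1000 null replications (three-sigma binomial
band around 0.05) and 200 replications for power.  The acceptance script
derives per-stage seeds from one root seed and recomputes all reported
quantities from scratch; the full-scale transfer census (441 × 862
alignments) is its slowest stage at about 1.5 minutes.

## Known limitations

- The conservation background and log base are conventions, not fitted:
  reported conservation magnitudes depend on them.
- Exact-0.5 disorder scores count as disordered; predictors that emit
  exact ties in bulk would shift content slightly versus a strict-">"
  reading.
- The "complex" MoRF rule is a strict-majority fallback; conventions
  requiring two states above a floor would type borderline regions
  differently.
- Transfer similarity depends on the chosen traceback among co-optimal
  alignments for distantly related pairs; decisions at the 0.8 threshold
  are unaffected.
- `read_score_table` loads whole tables into memory; chains beyond ~10⁶
  residues per file would need a chunked reader.
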