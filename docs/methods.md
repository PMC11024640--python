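# Methods

## Problem setting

Given assembled plant transcripts, decide which are long non-coding RNAs
(lncRNAs: > 200 nt, no protein-coding capacity) and characterize the
survivors by genomic position and transposable-element (TE) origin. The
package retrains classic coding-potential model families on user-supplied
plant data rather than shipping fixed animal-trained models, and combines
the two complementary ones as a stringent ensemble.

Throughout, the lncRNA is the positive class: training sets are given as a
lncRNA FASTA (positives) and an mRNA FASTA (negatives), and sensitivity,
precision etc. are defined with respect to lncRNA detection.

## Feature schemas

### ORF features

ORFs are ATG-initiated, in-frame, forward-strand spans. The standalone
`find_longest_orf` requires a stop codon by default (the length then
includes the stop) and exposes `require_stop=False` and `reverse=True`
flags. Feature extraction always uses `require_stop=False`, the convention
of coding-potential tools for truncated assemblies: an ORF running off the
3′ end still counts. Ties are resolved longest → smallest start → smallest
frame, making extraction deterministic. ORF coverage is ORF length divided
by transcript length.

### Fickett TESTCODE

For each base, a position value (max/(min+1) of its three codon-position
counts) and a content value (its overall fraction) are looked up in the
published 10-bin probability tables and combined with the published
per-base weights; the score is the sum of the eight weighted probabilities.
The tables are embedded constants (position bins step 0.1 over [1.1, 1.9],
content bins step 0.02 over [0.17, 0.33], plus catch-all bins). `N`
residues are ignored; fewer than 3 informative residues is an error.

### Hexamer usage bias

Two background distributions over all 4096 hexamers: the coding background
counts in-frame (step-3) hexamers of each mRNA's longest ORF — falling back
to frame-0 step-3 counting over the whole sequence when no ORF spans a
hexamer, the convention of table builders fed CDS directly — and the
noncoding background counts all overlapping (step-1) hexamers of each
lncRNA. Counts get a pseudocount (default 1.0), are normalized, and stored
as natural logs. A transcript's score is the mean log-ratio over its
in-frame ORF hexamers (step-1 over the whole sequence when the ORF spans
none); hexamers containing N are skipped; no scorable hexamer gives 0.

### k-mer profile (`plek` schema)

Frequencies of all k-mers for k = 1..5 (1364 features), counted with step 1
and divided by the number of valid windows, then scaled by
`w_k = 1/4^(k_max−k)` so sparser long k-mers contribute on the same order
as dense short ones. The weighting constant is exposed and overridable.
N-containing windows are excluded from counts and denominator.

### EIIP spectrum (`lncfinder-lite` schema)

Residues map to their electron–ion interaction pseudopotentials (A 0.1260,
C 0.1340, G 0.0806, T 0.1335; N to the mean). Features: power of the
discrete Fourier spectrum at the period-3 position (index round(L/3)), its
SNR against the mean power over nonzero frequencies, and the
0.25/0.50/0.75 quantiles of the normalized spectrum. The full LncFinder
feature set includes RNA secondary-structure features that require a
folding engine; this schema deliberately replaces them with the EIIP
physicochemical subset, and `extract_features(..., extra=...)` accepts
externally computed structure features for users who have them. Results on
this schema therefore characterize the sequence-intrinsic subset, not
structure-augmented classification.

## Classifiers

Features are z-scored with training-set statistics; constant features are
dropped and recorded. Two kinds:

- **Logistic** (used with the `cpat` schema): maximizes the L2-penalized
  Bernoulli likelihood (λ default 1.0; λ=0 disables the penalty) to tight
  gradient tolerance. The contract is on the optimum, not the algorithm;
  the fit is checked in the tests against an independent gradient-descent
  oracle on the same objective.
- **SVM-RBF** (used with `plek` / `lncfinder-lite`): soft-margin dual with
  C = 1 and the standard gamma heuristic 1/(n_features · var) by default.
  Scores are probabilities via a Platt sigmoid fitted on out-of-fold
  decision values (3-fold, stratified, seeded); with fewer than 3 samples
  per class the calibration falls back to held-in decision values.

A transcript is called lncRNA when its score is ≥ the model threshold
(boundary counts as lncRNA). The default threshold is 0.5 for both kinds;
an optional Youden-J policy picks the cutoff maximizing TPR − FPR on
3-fold out-of-fold scores. Models serialize to a single JSON archive
(spec, scaling, parameters, hexamer table, threshold, format-version
string), so prediction from raw FASTA needs nothing else.

**Cross-validation** is stratified k-fold with a seeded shuffle. Hexamer
tables and standardization are rebuilt from each training partition only —
the held-out fold never influences the features it is scored with. For
speed, the table-independent feature blocks are computed once per sequence
and only the hexamer log-frequency means are recomputed per fold; this is
an exact optimization, not an approximation.

**Ensemble**: lncRNA iff both members call lncRNA, i.e. the ensemble
positive set is the intersection of the member positive sets. Disagreement
resolves to mRNA — the stringent choice, since the ensemble's purpose is
reducing false-positive lncRNA calls. By construction FP_ens ≤
min(FP_a, FP_b) and TP_ens ≤ min(TP_a, TP_b).

## Evaluation

The five metrics follow the standard confusion-matrix fractions; a metric
whose denominator is zero is reported as an explicit undefined marker
(`None` / `NA`), never silently 0. ROC thresholds are the unique scores in
descending order with a +∞ sentinel (the curve starts at (0,0)); tied
scores are grouped at one threshold; AUC is the trapezoidal integral,
which equals the Mann–Whitney pairwise statistic with ties counted ½.
When several species' predictions are evaluated, pooling before computing
metrics is the default; per-set metrics can be computed by calling
`evaluate` per set and averaging.

## Annotation pipeline

Coordinates are 0-based half-open internally; GTF/GFF3 I/O converts from
and to 1-based inclusive, BED is read natively. Stage order: candidate
filter → ensemble prediction → homology filter → positional classification
→ TE origin. Counts conserve: every input transcript is either kept or
appears exactly once in the removal log.

- **Candidate filter**: exonic length < 200 nt removed; monoexonic
  transcripts per mode (`antisense_only` default: kept only when an exon
  overlaps a reference exon on the opposite strand; also `keep_all` /
  `discard_all`); ≥ 1 bp same-strand exon–exon overlap with a known mRNA
  removed. Antisense exon overlap is *not* a removal cause — it is a
  positional class. One reason per removed transcript, first failing rule
  in the order length → monoexonic → sense-overlap. Transcripts on
  chromosomes absent from the reference get a warning and no reference
  context.
- **Homology filter**: a candidate is flagged coding iff any hit has
  identity strictly > 80 and e-value strictly < 1e−5 (both comparisons
  strict by design); candidates without hits are kept.
- **Positional classification**, first match wins: (1) ANTISENSE_EXONIC —
  exon–exon overlap with an opposite-strand gene; (2) INTRONIC — span
  overlap without exon–exon overlap on either strand; (3) BIDIRECTIONAL —
  non-overlapping, opposite strand, lncRNA wholly on the gene's 5′ side
  (head-to-head, divergent) with TSS-to-TSS distance ≤ 2000 bp; (4)
  UPSTREAM — wholly 5′ of a gene, lncRNA 3′ end to gene TSS ≤ 2000 bp; (5)
  DOWNSTREAM — wholly 3′, gene TTS to lncRNA 5′ end ≤ 2000 bp; (6)
  INTERGENIC. Overlap classes precede proximal classes and BIDIRECTIONAL
  precedes UPSTREAM so that the divergent promoter-sharing case is not
  absorbed by plain proximity. Proximity rules accept partners on either
  strand (the divergent case is consumed by rule 3 first). The partner is
  chosen by smallest distance, then lexicographic gene id; the window is
  configurable. Rule 3 requires divergent geometry with *some* gene within
  the window, not that this gene be the globally nearest feature — with
  realistic gene spacing the two coincide.
- **TE origin**: total exonic bp intersecting the union of TE intervals
  (strand-agnostic), the distinct families hit, and a TE-derived flag at a
  1 bp default minimum; the overlap fraction is reported so users can
  re-threshold without recomputing.
- **Redundancy removal**: greedy incremental clustering in decreasing
  length order (ties by id); a sequence joins the first representative
  whose pairwise identity exceeds the threshold (default 0.80, strict >).
  Identity = identical columns of the best local alignment (match +1,
  mismatch −1, gap open −2, gap extend −1) divided by the shorter
  sequence's length — the CD-HIT-EST denominator convention.

## Synthetic data generators

All generators are pure functions of their config; the seed lives in the
config and every byte of output is reproducible. Defaults: 1000 transcripts
per class, lengths uniform on 400–3000 nt for both classes (so length alone
is not a giveaway), GC 0.45, mRNA ORF coverage uniform on [0.5, 0.9] with
codons drawn from a skewed usage table (a fixed 20-codon subset preferred
8:1) — this codon bias is what creates a learnable hexamer signal rather
than the labels alone. lncRNA-like sequences are GC-matched random sequence
constrained to longest ORF < 120 nt: plain rejection sampling is tried
first, but a random 3000-nt sequence almost surely contains a ≥ 120 nt ORF,
so after a bounded number of rejections the remaining long ORFs are
disrupted by replacing a randomly chosen in-frame codon with a stop until
the constraint holds (the random position prevents two overlapping-frame
ORFs from repeatedly undoing each other's fix). The substitution touches
well under 1% of positions and leaves GC essentially unchanged.

The toy genome plants, per replicate, one lncRNA locus satisfying each
class's defining geometry next to its own host gene (e.g. a divergent
opposite-strand locus with TSS 300 bp from the gene TSS for BIDIRECTIONAL;
500/600 bp offsets for UPSTREAM/DOWNSTREAM), placed with ≥ 5 kb gaps so
units cannot interact across the 2 kb window, plus decoys exercising every
removal branch: a 150-nt transcript, a monoexonic intergenic transcript, a
same-strand exon-overlapping transcript, an mRNA-like candidate (removed
by the ensemble), a candidate with a planted strong protein hit (removed by
homology; two other planted hits sit exactly at the identity threshold and
above the e-value cutoff to exercise strictness), and a 97%-identity
duplicate of the intergenic lncRNA. Planted loci are ≥ 400 exonic nt so
they lie inside the classifiers' training length distribution. Sequences
are written into the genome strand-aware, so extracting any candidate's
exon chain reproduces the planted sequence exactly. The truth table lists
every candidate's intended fate, class and TE flag.

What the generators do *not* emulate: splice-site motifs, expression
levels, assembly artifacts, sequencing error, genome-scale repeat
structure, and real lncRNA/mRNA compositional subtleties beyond codon
bias, GC and ORF structure. Passing tests therefore demonstrate that the
machinery is correct and self-consistent, not that any particular accuracy
will transfer to real plant data.

## Problem sizes and numerical choices

The acceptance script and test suite use 1000 + 1000 training transcripts,
700 + 700 / 300 + 300 train/held-out splits, 10-fold CV, a ~100 kb planted
genome with 12 candidates, and a 50-sequence duplicate fixture — sizes at
which every check runs in seconds while each rule branch is still
exercised. Logistic fits run to gradient tolerance 1e−10 (the symmetry
and oracle tests require agreement to 1e−6); Platt calibration uses an
effectively unpenalized logistic fit on decision values; AUC uses exact
trapezoids; the dedup aligner scores are integers, so identities are exact
rationals. Degenerate inputs are defined, not silently coerced: empty
hexamer sets score 0, flat spectra have SNR 0, zero-denominator metrics
are undefined markers, and an all-N or too-short sequence raises.

## Known limitations

- The `lncfinder-lite` schema omits folding-based structure features;
  transcripts whose discriminative signal is purely structural will not be
  separated.
- The RBF-SVM extrapolates poorly outside its training feature range
  (scores collapse toward the calibration intercept); very short
  transcripts should be covered by the training length range.
- Positional classification reports one class per lncRNA by precedence; a
  locus that is simultaneously antisense to one gene and bidirectional to
  another reports only the higher-precedence class (the partner gene makes
  this auditable).
- The greedy dedup is order-dependent by design (length-descending, the
  CD-HIT convention); it is deterministic but not a globally optimal
  clustering.
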