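# plantlnc

Trainable identification and characterization of plant long non-coding RNAs
(lncRNAs) — transcripts longer than 200 nt with no protein-coding capacity.
Most coding-potential classifiers ship with models trained on human or mouse
data; on plant transcriptomes they lose accuracy because codon usage, ORF
structure and sequence composition differ. `plantlnc` lets you retrain the
classic model families on your own plant data and then run the full
downstream annotation workflow, so the whole stack is reproducible from two
FASTA files and a genome annotation.

For bioinformaticians annotating plant transcriptome assemblies: input is a
set of assembled transcripts (GTF + FASTA), a reference gene annotation, and
optionally protein-homology hits and a transposable-element (TE) annotation;
output is a filtered, classified lncRNA set.

## What's inside

**Feature schemas** (`plantlnc.features`) — three numeric representations of
a transcript:

- `cpat`: maximum ORF length, ORF coverage, the Fickett TESTCODE statistic,
  and hexamer usage bias — the mean log-likelihood ratio
  `(1/n) Σᵢ log[ f_coding(hᵢ) / f_noncoding(hᵢ) ]` over the in-frame
  hexamers hᵢ of the longest ORF, with the background tables trained from
  your mRNA/lncRNA sets.
- `plek`: a 1364-dimensional k-mer frequency profile (k = 1..5), each scale
  weighted by `w_k = 1/4^(k_max−k)`.
- `lncfinder-lite`: ORF and hexamer features plus GC content and
  electron–ion interaction pseudopotential (EIIP) power-spectrum features
  that capture the period-3 signal of coding sequence. (A hook accepts
  externally computed secondary-structure features; none are required.)

**Classifiers** (`plantlnc.classifiers`) — an L2-penalized logistic
regression and an RBF-kernel SVM with Platt-calibrated probabilities, either
trained on z-scored features with lncRNAs as the positive class; stratified
k-fold cross-validation that rebuilds hexamer tables per fold; and the
**intersection ensemble**: a transcript is called lncRNA only when *both*
models call it lncRNA, which can only reduce false positives relative to
either member.

**Evaluation** (`plantlnc.evaluation`) — sensitivity, specificity, accuracy,
precision, F1 (TP = lncRNA called lncRNA), and ROC/AUC by trapezoidal
integration (identical to the Mann–Whitney statistic).

**Annotation pipeline** (`plantlnc.pipeline`) — candidate filtering
(exonic length ≥ 200 nt; monoexonic transcripts kept only when antisense to
a reference exon; same-strand exon overlap with known mRNAs removed),
ensemble prediction, protein-homology filtering (flag when identity > 80
and e-value < 1e−5), six-way positional classification (intergenic,
intronic, antisense exonic, upstream, downstream, bidirectional; 2000 bp
windows), TE-origin annotation, and CD-HIT-style greedy redundancy removal
at 80% identity.

**Synthetic data** (`plantlnc.simulate`) — seeded generators for mRNA-like
transcripts (codon-biased ORFs), lncRNA-like transcripts (no ORF ≥ 120 nt),
and a planted-truth toy genome with one locus per positional class plus
decoys for every removal rule, so the entire stack is testable without
downloads.

## Worked example

Train both models on synthetic data, then annotate a planted toy genome:

```bash
plantlnc simulate lncrna --seed 7 --n 200 --outdir fixtures
plantlnc simulate mrna   --seed 7 --n 200 --outdir fixtures
plantlnc train --pos fixtures/lncrna.fa --neg fixtures/mrna.fa \
    --schema cpat --kind logistic --seed 7 --out cpat.json
plantlnc train --pos fixtures/lncrna.fa --neg fixtures/mrna.fa \
    --schema lncfinder-lite --kind svm_rbf --seed 7 --out lncfinder.json
plantlnc simulate genome --seed 11 --outdir fixtures/genome
plantlnc pipeline --gtf fixtures/genome/candidates.gtf \
    --fasta fixtures/genome/candidates.fa --ref fixtures/genome/reference.gtf \
    --model cpat.json --model2 lncfinder.json \
    --hits fixtures/genome/hits.tsv --te fixtures/genome/te.bed --outdir out
```

The pipeline logs its stage counts:

```
== candidate_filter: in=12 kept=9 removed=3
== coding_potential: in=9 kept=8 removed=1
== homology_filter: in=8 kept=7 removed=1
```

Twelve assembled candidates enter; the filter removes a sub-200-nt
transcript, a monoexonic intergenic transcript and a transcript overlapping
a known mRNA on the same strand; the ensemble removes an mRNA-like
candidate; the homology filter removes a candidate with a strong protein
hit. The seven survivors land in `out/classification.tsv`:

```
transcript_id        class             partner_gene          distance_bp  te_overlap_bp  te_fraction  te_families
lnc_intergenic_0     INTERGENIC                              0            80             0.16         LTR/Copia
dup_intergenic_0     INTERGENIC                              0            0              0.0
lnc_intronic_0       INTRONIC          gene_intronic_0       0            0              0.0
lnc_antisense_0      ANTISENSE_EXONIC  gene_antisense_0      0            0              0.0
lnc_upstream_0       UPSTREAM          gene_upstream_0       500          0              0.0
lnc_downstream_0     DOWNSTREAM        gene_downstream_0     600          0              0.0
lnc_bidirectional_0  BIDIRECTIONAL     gene_bidirectional_0  300          0              0.0
```

Each row gives the positional class, the partner gene that triggered it,
the distance to that gene (0 for overlapping classes; here 500 bp from the
upstream lncRNA's 3′ end to its gene's TSS), and the TE intersection — the
intergenic lncRNA overlaps an LTR/Copia element over 16% of its length and
is therefore flagged TE-derived.

Other commands: `plantlnc features` (feature matrices as TSV),
`plantlnc hexamer` (background tables), `plantlnc predict` (scores and
calls; two models trigger the ensemble rule), `plantlnc cv` (k-fold
cross-validation), `plantlnc evaluate` (metrics + ROC against a truth
table).

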