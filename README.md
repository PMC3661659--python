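# seqfunc

Feature-based Gene Ontology (GO) term prediction for protein
sequences: a reusable framework for building per-term SVM classifier
libraries from sequence-derived features, with homology-aware
cross-validation, posterior calibration and the standard
function-prediction assessment suite.

## The problem

Roughly a third of human proteins carry no functional annotation, and
many have no characterised homologue to transfer annotations from.
Feature-based predictors side-step homology entirely: each protein is
described by a vector of sequence-derived attributes — amino-acid
composition, global physicochemical properties, and the outputs of
secondary-structure / disorder / localization / modification
predictors, organised into 14 named feature groups — and one binary
SVM is trained per GO term to decide whether a query protein carries
that molecular function (MF) or participates in that biological
process (BP).

The package implements the full training and evaluation methodology:

* **Eligibility rules** — a term is trainable when it occurs in a
  curated vocabulary, has ≥ 150 positive proteins (annotated with the
  term or a descendant, following both `is_a` and `part_of`), and
  ≥ 500 negatives that lie outside the term's lineage yet bear at
  least 2 MF and 2 BP annotations with evidence codes other than
  IC/NAS/TAS/IEA.  Sequences are capped at 1,500 residues and made
  non-redundant at 90% identity.
* **Homology-aware partitioning** — 30% of each set is held out; the
  rest is split into the largest number *k* of equal-size groups of
  ≥ 35 proteins (shared between positives and negatives) by a
  capacity-constrained K-medoids on pairwise minimum-alignment-E-value
  distances, so CV folds do not share close homologues.
* **Model selection** — an exhaustive grid search over linear and RBF
  kernels (C, γ) combined with backward feature-group elimination,
  all driven by the cross-validated Matthews correlation coefficient
  (MCC), with errors on positives weighted by the negative/positive
  ratio (the SVM-Light `j` rule).
* **Discard and reliability rules** — a term whose holdout MCC falls
  below 0.05 is dropped from the vocabulary; surviving models are
  tiered H (high reliability) when MCC > 0.3, sensitivity > 0.3,
  specificity > 0.7 and precision > 0.3, else L.
* **Platt calibration** — after a final refit on all examples, a
  sigmoid `P(y=1|f) = 1 / (1 + exp(A·f + B))` is fitted to the
  *cross-validated* decision values by the damped-Newton method, so
  the reported posteriors are not biased by resubstitution.
  Predictions are displayed when the posterior exceeds 0.5.
* **Assessment** — CAFA-style precision/recall and Fmax over
  propagated term sets, a relaxed variant crediting ancestor or
  descendant matches, and information-content scores: simGIC
  (IC-weighted Jaccard of propagated sets, with IC(y) = −log f(y))
  and COGIC, a weighted combination of simGIC at four confidence
  strata (≥ 0.75, 0.50, 0.25, 0) that is 1 iff every predicted term is
  validated at confidence ≥ 0.75 and 0 iff only the root is shared.

Everything external — the third-party feature predictors, CD-HIT-style
clustering, BLAST alignment — is a pluggable interface; the
`seqfunc.fixtures` module generates complete synthetic inputs
(ontology, proteome, annotations, feature matrices with planted
signal, block-structured homology) so the whole pipeline runs and is
testable without any download.

## Worked example

Generate a synthetic study (700 proteins, 3 GO terms with planted
feature signal, 1 pure-noise term), train the library, and score a
query:

```text
$ seqfunc make-fixtures --out demo --seed 7
fixtures written to demo

$ seqfunc train --config demo/run.cfg
... trained GO:1000008: k=3 kernel=rbf holdout_mcc=1.000 reliability=H discarded=False
... trained GO:1000009: k=3 kernel=linear holdout_mcc=1.000 reliability=H discarded=False
... trained GO:2000008: k=3 kernel=linear holdout_mcc=1.000 reliability=H discarded=False
... term GO:2000010 discarded (holdout mcc -0.056)
trained 3 models (1 discarded) -> demo/models.json

$ seqfunc predict --config demo/run.cfg demo/query.fasta
wrote 6 posterior rows (1 displayed) to demo
```

`demo/predictions.tsv` then contains, for a planted positive of
GO:1000008 (P000014) and a background protein (P000003):

```text
protein       term      name          namespace  posterior reliability  displayed
P000014 GO:1000008 MF term 8 molecular_function      1.000           H       True
P000014 GO:1000009 MF term 9 molecular_function      0.001           H      False
P000014 GO:2000008 BP term 8 biological_process      0.000           H      False
P000003 GO:1000008 MF term 8 molecular_function      0.000           H      False
...
```

The three planted-signal terms train to perfect holdout MCC and tier
H; the noise term's holdout MCC (−0.056) falls below the 0.05 discard
threshold and it is dropped from the library.  The query's posterior
is above the 0.5 display threshold only for the term whose signal was
planted in its features.

The same workflow is available as a library: build a
`seqfunc.TermClassifier` from a training set, feature matrix and
distance matrix, call `.fit(seed)`, and inspect the returned results
object (`.summary()`, `.holdout`, `.model`).  `seqfunc evaluate`
scores any prediction TSV against reference annotations (Fmax, relaxed
PR, per-protein COGIC and its median).

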