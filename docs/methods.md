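# Methods

This note documents the models and procedures implemented in
`seqfunc`, the defaults they ship with, the numerical choices made
where the method leaves room, and what the synthetic test data does
and does not establish about behaviour on real proteomes.

## Ontology handling and information content

The ontology is a typed DAG over the molecular-function and
biological-process namespaces with `is_a` and `part_of` edges
(child → parent).  Parsing consumes only `[Term]` stanzas (tags: `id`,
`name`, `namespace`, `is_a`, `relationship: part_of`, `is_obsolete`,
`replaced_by`, `alt_id`); cellular-component terms are dropped;
obsolete MF/BP terms are retained so that old annotations can be
remapped when a unique replacement exists via `replaced_by` or a
reverse `alt_id` lookup, and discarded otherwise.  Cycles and live
terms without a namespace are hard errors.

Training-set construction follows **both** relations when collecting
ancestors and descendants; assessment propagation follows **`is_a`
only**, mirroring the distinct conventions of the training and
CAFA-style evaluation procedures.  Cross-namespace `part_of` edges are
kept in the graph but are only reached when the caller asks for that
relation.

Information content is `ic(y) = −log f(y)`, where `f(y)` is the
fraction of corpus proteins annotated with *y* or any descendant among
proteins with ≥ 1 annotation in *y*'s namespace.  Choices:

* **Log base**: natural log.  simGIC and COGIC consume IC only through
  ratios of IC sums, so the base cancels; the constant is recorded as
  `ontology.IC_LOG_BASE`.
* **Denominator**: per-namespace protein counts, which pins
  `f(root) = 1` and hence `ic(root) = 0` exactly.
* **Unobserved terms** carry a `+inf` sentinel and are excluded from
  simGIC sums rather than silently treated as 0 — an unobserved term
  should neither add nor subtract evidence.

## Dataset construction

Defaults (all configurable in `RunConfig`): maximum sequence length
1,500 residues; redundancy reduction at 90% identity; ≥ 150 positives
and ≥ 500 negatives; negative-evidence exclusion set {IC, NAS, TAS,
IEA}.  The redundancy reducer is an interface; the built-in greedy
exact-k-mer-containment clusterer (k = 5, longest-first) is adequate
for fixtures and small corpora, and production users plug an external
clusterer through the same `cluster(sequences, threshold) →
representatives` contract.

Two points the eligibility rules leave open were resolved as follows:

* The "≥ 2 MF and ≥ 2 BP terms" requirement for negatives counts
  **direct** annotations (distinct term ids per namespace), not
  propagated ones: the requirement is a proxy for how well-studied a
  protein is, and propagation would let a single deep annotation
  masquerade as several.
* GAF input may be the minimal 3-column dialect or full GAF 2.x; rows
  with a `NOT` qualifier are dropped in either case, since they would
  poison positive sets.

## Feature space

Features are grouped into 14 named blocks; model selection removes or
keeps whole blocks.  Composition (20 values) and global sequence
features (length, molecular weight, mean Kyte–Doolittle hydropathy,
Henderson–Hasselbalch net charge at pH 7, fraction of D/E/K/R) are
computed natively; non-standard residues (X/B/Z/U) are tolerated and
excluded from denominators.  The twelve predictor-derived groups are
provider contracts (`(accession, sequence) → vector`); their
dimensions default to 4 and are configurable, since the exact upstream
feature lists belong to the external predictors.

Scaling is per-feature min–max to [0, 1], fitted on training rows only
inside each CV fold; unseen values are clipped and degenerate
(constant) features map to 0.  Min–max scaling is the convention of
the SVM tooling family this follows; clipping keeps holdout and query
vectors inside the training range instead of extrapolating.

## Homology partitioning

Distances are minimum pairwise alignment E-values, taken over both
orderings and all reported alignments, symmetrised by the minimum and
capped at 10 (weaker hits and missing alignments count as the cap;
the diagonal is 0).  The 30% holdout is drawn uniformly at random
(deterministic per seed); the remainder is split into the largest *k*
with `floor(n/k) ≥ 35` on both the positive and negative side.  When
no `k ≥ 2` qualifies the code falls back to `k = 1` with a warning:
the term trains with default parameters but is not cross-validatable.
Eligibility thresholds make this unreachable for compliant inputs, but
the path exists and is tested.

The equal-size grouping is a capacity-constrained K-medoids:

1. farthest-first seeding after a seeded random first medoid;
2. greedy assignment to the nearest non-full medoid, visiting points
   in descending assignment margin (distance to second-nearest minus
   nearest), ties broken by accession order;
3. improving pair-swaps between groups until none remains, then medoid
   updates; repeat to stability or 100 passes.

Group sizes differ by at most one (larger groups take the remainder).
The result is deterministic given the seed and locally stable: no
single swap of two members between two groups lowers the total
within-group distance to medoid.  Positives and negatives are
clustered **separately** on their own distance submatrices with the
shared *k* — the two sets never mix inside a fold anyway, and joint
clustering could not guarantee per-set equal sizes.

## Training

The per-term procedure (exposed as `TermClassifier.fit()` returning a
results object):

1. **Grid search** over linear (C) and RBF (C, γ) kernels; defaults
   C ∈ {2⁻⁵, 2⁻³, …, 2⁷}, γ ∈ {2⁻⁹, 2⁻⁷, …, 2¹}.  The CV statistic is
   the MCC of the **pooled** fold confusion counts (stable when folds
   are small; per-fold averages are noisy at 35 proteins per group).
   Ties break to linear before RBF, then smaller C, then smaller γ —
   the simplest adequate model wins.
2. **Group elimination**: one backward pass over the groups in
   registry order; a group stays removed only when the best grid MCC
   **strictly** improves without it, so the returned configuration is
   never worse than the all-groups baseline and ties never shrink the
   feature space.  Each candidate removal re-runs the full grid (no
   warm start): the optimum can move between kernels when a group
   leaves.
3. **Class imbalance**: errors on positives are weighted by
   `n_neg_train / n_pos_train` in every fit (the `j` rule).
4. **Holdout test**: the selected configuration is retrained on all k
   groups pooled and scored on the untouched 30%.  MCC < 0.05 discards
   the term; H-tier requires MCC > 0.3, sensitivity > 0.3, specificity
   > 0.7, precision > 0.3 (strict inequalities).
5. **Final refit**: all examples (holdout included) are pooled,
   re-partitioned into k homology groups, kernel parameters re-tuned
   at fixed kernel type and feature list, and the final classifier is
   trained on everything.  Its accuracy cannot be measured on fresh
   data, so the earlier holdout metrics are carried over unchanged.
6. **Calibration**: the Platt sigmoid is fitted to the decision values
   of the **final k-fold cross-validation** (each protein scored by
   the fold that did not train on it), with the smoothed targets
   `t₊ = (N₊+1)/(N₊+2)`, `t₋ = 1/(N₋+2)`, by damped Newton with a
   backtracking (Armijo) line search, Hessian regularisation 1e−12,
   gradient tolerance 1e−5, ≤ 100 iterations.  Resubstitution values
   would bias the sigmoid optimistically steep.

The margin classifier behind steps 1–5 is an interface (`fit(X, y,
kernel, positive-error weight) → decision function`); the default
backend is scikit-learn's SVC with per-class cost weighting.  Trained
models serialise to JSON as plain arrays (support vectors, dual
coefficients, intercept, scaler bounds, Platt A/B), and the decision
function is re-evaluated with numpy at prediction time, so a library
file is self-contained and portable.

Per-term seeds are derived as `crc32(term_id:master_seed)` (< 2³¹), so
adding or removing terms never perturbs another term's randomness.

## Assessment

* **CAFA-style PR**: both sides propagated over `is_a` with roots
  excluded, ancestors inheriting the maximum descendant confidence.
  At threshold v, precision is averaged over the n_v proteins with ≥ 1
  prediction scored ≥ v; recall is averaged over all reference
  proteins; thresholds sweep the distinct confidence values plus
  {0, 1}; Fmax maximises 2pr/(p+r).  A protein with no prediction at v
  contributes zero recall and is excluded from n_v.
* **Relaxed PR**: no propagation; a prediction is correct iff it
  equals, or is an ancestor or descendant of, a reference term.  False
  positives are the scored-above-threshold complement of the matches;
  false negatives are the references no scored prediction matches.
  A prediction matching several references still counts once
  (set semantics).
* **simGIC**: IC-weighted Jaccard of propagated sets (roots included
  at IC 0); returns 0 on zero union mass; infinite-IC terms excluded.
* **COGIC**: strata ≥ 0.75 / 0.50 / 0.25 / 0; default weights
  (8, 4, 2, 1)/15 — positive, strictly decreasing, normalised — so
  confident correct predictions earn more credit.  The weighted sum is
  divided by the weight total, which keeps the boundary identities
  exact in floating point (all-strata similarity 1 scores exactly 1;
  root-only overlap scores exactly 0).  The weight vector is
  configurable; every stated contract holds for any positive strictly
  decreasing normalised choice, and the tests assert exactly that.
* **Summaries**: median and quartiles use the lower-interpolation
  convention (an observed value is always reported).

## Synthetic data

`seqfunc.fixtures` generates every input format the pipeline reads.
Defaults define the study conditions used by the end-to-end tests:
two 12-term namespaces (a near-balanced `is_a` tree with one diamond
motif and a `part_of` edge), 700 proteins, 3 signal terms and 1 noise
term with 150 planted positives each (sampled independently per term,
so noise-term labels are independent of every feature channel), 3
homology blocks with near-zero within-block distances, an evidence mix
containing 5% IEA to exercise the negative-evidence filter, and 14
feature groups (predictor groups of dimension 4).

Each signal term owns one predictor group whose values for planted
positives are shifted by `signal_strength × (1+ε)` above a U(0, 1)
base, so strength 1 yields disjoint ranges — linear separability by
construction — and strength 0 yields label-independent features.
Background annotations (three distinct terms per namespace, drawn
outside all modelled lineages) make most proteins eligible negatives
while the IEA fraction knocks a few out.

What passing tests show — and what they do not: the pipeline
recovers planted, linearly separable signal essentially perfectly and
rejects label-independent noise near the MCC ≈ 0 boundary.  Real
sequence features are weaker, correlated across groups, and not
separable; real holdout MCCs populate the whole (0.05, 1) range.  The
synthetic results validate the machinery (selection, partitioning,
calibration, scoring), not the attainable accuracy on real proteomes.
One statistical caveat is inherent to the discard rule itself: for a
classifier trained on label-independent features the holdout MCC is
approximately N(0, 1/n) with n ≈ 200 at the default fixture size
(sd ≈ 0.07), so single noise terms land above the 0.05 cutoff in a
substantial minority of runs — the rule prunes the vocabulary
stochastically rather than acting as a sharp filter.

## Problem sizes in the test suite

The default test run trains the full 700-protein fixture across 20
seeds with a linear-kernel, single-C grid (the planted signal is
linearly separable, so richer grids change nothing but runtime), and
uses 150-protein bundles with reduced eligibility thresholds for the
CLI round-trip tests.  Oracle-equivalence suites use 1,000 random
confusion tables, random DAGs of ≤ 50 nodes, and ≤ 5-protein PR
instances; calibration recovery uses 10,000 synthetic decision values;
clustering recovery uses 100 seeded runs for k ∈ {2, 3, 4}.

## Known limitations

* The predictor-derived feature groups are contracts; no external
  predictor is bundled, so real-data runs require user-supplied
  feature tables or providers.
* The built-in k-mer redundancy reducer under-merges distant homologues
  compared to a proper clustering tool; it is a fixture-scale default,
  not a CD-HIT replacement.
* Pairwise distance matrices are dense; proteome-scale inputs need a
  sparse external pipeline.
* Posteriors are calibrated per term and are not made hierarchically
  consistent across the DAG (a child may outscore its parent), which
  matches the method being implemented.
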