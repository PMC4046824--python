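# Methods

This note documents the models and procedures implemented in `pdzfam`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Domain clustering

**Model.** Binding specificity of a PDZ domain is assumed to be shared by
domains with high global sequence identity, so domains are partitioned into
specificity families from the pairwise-identity graph rather than modelled
individually.

Pairwise identity is computed from Needleman–Wunsch global alignment.
Neither the substitution matrix nor the gap costs nor the identity
denominator are canonical choices fixed by the problem, and family counts
are sensitive to all three; we pin:

- **BLOSUM62** with affine gap costs **10 (open) / 0.5 (extend)** — the
  standard protein setting; configurable via `AlignmentScoring`.
- **Identity denominator = full alignment length including gap columns**,
  the most common convention for NW identity. The alternative
  (shorter-sequence length) is available via
  `percent_identity(..., denominator="shorter")`. The denominator interacts
  directly with the 50% cutoff, hence it must be pinned.
- Among co-optimal alignments the aligner's first (deterministic) traceback
  is used; identity, not the alignment path, is what feeds clustering.

Edges below **50% identity** are discarded (pairs at exactly 50% are kept:
only *less than* 50% is noise); edge weights are the raw identity
percentages, unrescaled.

**MCL.** The Markov cluster algorithm is implemented from scratch on a
dense stochastic matrix: self-loops (weight = each node's maximum incident
edge weight, 1 for isolated nodes), column normalisation, then iterated
expansion (matrix squaring) and inflation (elementwise power **1.4**, the
granularity setting, followed by column renormalisation), pruning entries
below 1e-5, until the matrix changes by less than 1e-6 or 100 iterations
(non-convergence warns and interprets the current matrix). Clusters are
read off attractor rows; overlapping attractor systems merge; a node
attracted to several clusters goes to the one with the larger attraction
mass (ties to the cluster with the lexicographically smallest member, for
determinism). Families need ≥ 2 members; singletons and isolated nodes are
reported unclassified. Family ids are assigned by size (descending) then
smallest member, so membership is invariant under input reordering.

## Feature encoding

Peptides are exactly the **five C-terminal residues**, positions P-4…P0
with P0 the extreme C-terminus — the positions that dominate PDZ binding
specificity. The sequence encoding reserves 20 alphabetically-indexed bits
per position (100 bits, exactly five ones). The combined encoding appends,
per contact pair, a 400-bit block with one bit at
20·idx(domain residue) + idx(peptide residue).

Contacts come from one reference complex structure per family: a
(domain residue, peptide residue) pair is a contact iff the **minimum
heavy-atom distance is strictly below 4.5 Å** (first model, non-hetero
residues; `atom_mode` offers all-atom and Cβ-only variants). The strict
inequality and the heavy-atom convention are pinned choices — the
literature convention this follows does not state them unambiguously.
Domain residue indices are mapped to columns of the family multiple
alignment (consumed as aligned FASTA from any external aligner; the MSA is
deliberately not computed internally) so the same contact features apply to
all members. A family member with a gap at a contact column gets an
all-zero pair block rather than an error, keeping feature dimensionality
constant within a family.

## Negative-class enrichment

Screens yield few trustworthy negatives. Two provenance-flagged routes:

- **Self-training** (families with measured negatives): an RBF-SVM base
  classifier with Platt-calibrated probabilities is trained on the labeled
  records, scores the deduplicated C-terminal 5-mers of the proteome
  (labeled peptides excluded), and candidates with negative-class
  probability in **[0.5, 0.8]** (inclusive endpoints) are sampled uniformly
  without replacement until negatives total **5x** the positives.
  Candidates above 0.8 are excluded deliberately: peptides the base model
  already considers far from the positive class add no boundary
  information and can degrade the model. One round
  (train → label → sample → retrain) is performed.
- **Random draws** (positive-only families): uniform samples from the same
  per-organism pool at the same 5:1 ratio.

Both routes cap at pool size with a warning. Records carry provenance
`ssl` or `random` and are excluded from every test fold by construction;
the procedural invariants (window membership under the stored base
classifier, leak-proof folds, seed determinism) are asserted in tests. No
biological guarantee is claimed that a generated negative is truly
non-binding — only that it is confidently scored and not a labeled
positive.

## Family models and evaluation

One **Gaussian-kernel soft-margin SVM per family**. Eligibility mirrors
the data reality: ≥ 10 experimental positives to model at all; ≥ 10
experimental positives *and* negatives to cross-validate, so each of the 5
stratified folds holds at least 2 of each.

Evaluation is **5-fold stratified CV, nested**: within each outer fold,
generated negatives are rebuilt from the training portion only (the pool
additionally excludes the fold's test peptides), and (C, γ) are chosen by
an exhaustive inner 5-fold grid search on the training portion. The
default grid spans C ∈ 2^-5…2^15, γ ∈ 2^-15…2^3 in powers of 4 (a
compact 4-point subgrid, `SMALL_GRID`, is the pipeline default to keep
runs fast; both are configurable). The inner selection criterion is mean
AUC-ROC — accuracy would be distorted by the deliberate 5:1 imbalance —
with ties broken toward the smallest C, then the smallest γ (mildest
model). Test folds contain exclusively experimental records.

Metrics: sensitivity, specificity and precision at the fixed decision
threshold **0** (the published binder rule); AUC-ROC by trapezoidal sweep
(equal to Mann–Whitney pair counting with half credit for ties — asserted
against a brute-force oracle in tests); AUC-PR by integrating the
precision–recall sweep over recall. Precision with no positive calls is
reported as 0. Calibrated probabilities come from a Platt sigmoid fitted
on out-of-fold decision scores of the final hyperparameters, which makes
the probability a monotone function of the decision score.

Beyond the 5:1 data ratio no class weighting is applied: the ratio itself
is the imbalance remedy, and stacking a second correction on top would
double-count it.

## Proteome scan

Candidate peptides are every protein's last five residues. Two filters
encode prior biology before any scoring: PDZ ligands tend to lie in
intrinsically disordered tails, so the **mean per-residue disorder score
of the last five residues must be ≥ 0.4** (scores are consumed from file —
any IUPred-style predictor can supply them; computing disorder internally
is out of scope); and an interaction requires the two proteins to
plausibly meet, so the peptide's protein must share **≥ 1 GO
cellular-component term** with the domain's protein. Proteins lacking
disorder or GO data are skipped with a logged count by default
(`missing_data_policy="pass"` lets them through the affected filter
instead — which policy the original analyses used is not recoverable).
Survivors are scored and ranked per domain by decision score, ties broken
by protein id for determinism.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not their
biology:

- **Families**: an 85-residue random ancestor, each member mutated at
  ⌊L·(1-t/100)/2⌋ positions so every pair is *guaranteed* ≥ t% identity
  (measured identities are re-checked through the alignment module;
  a violated target raises). Independent ancestors put inter-family
  identity near the ~5–15% random baseline, far below the 50% cutoff.
  No indels are simulated, so the family MSA is trivial — real families
  need a real aligner.
- **Interactions**: positives drawn from the class I/II/III grammars with
  the hydrophobic set pinned to {A,V,I,L,F,M,W,Y}; negatives uniform over
  non-grammar 5-mers; a noise fraction of labels flipped per class.
  Defaults (30 positives, 5:1 negatives) mirror a well-populated family.
- **Structures**: minimal two-chain ATOM-only PDB files (CA + CB per
  residue) with scripted inter-residue distances — exact at the requested
  pairs, > 6 Å everywhere else; infeasible layouts (reused residues,
  distances outside (0, 6) Å) are rejected rather than approximated.
- **Proteomes**: planted binders (motif tail, disordered terminus, shared
  GO term), decoys violating *exactly one* filter each (recorded in a
  manifest), and background proteins whose tails have a non-hydrophobic P0
  — breaking all three motif grammars at their shared strongest feature —
  so that a well-trained model separates planted binders from every
  background by construction. Background disorder and GO terms are random,
  so some backgrounds do reach scoring: the filters, not the generator,
  must remove the rest.

A green test on these fixtures establishes that the machinery is correct
(encodings, folds, filters, ranking, determinism); it does not establish
predictive performance on real screens, where motifs are degenerate,
negatives are biased, and families share peptides.

## Numerical and degenerate-case choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); equal seeds give byte-identical outputs.
- MCL columns are renormalised after pruning; the stochasticity deviation
  is tracked and stays ≤ 1e-9 in tests.
- The SSL window endpoints are inclusive; window membership is asserted to
  ±1e-9 under the stored base classifier.
- Grid-search AUC ties use a 1e-12 tolerance before the (C, γ) tie-break.
- A fold whose inner classes are too small shrinks the inner fold count
  (≥ 2) with a warning rather than failing the whole evaluation.
- Peptides shorter than 5 residues, and tails with non-standard residues,
  are skipped and counted, never silently dropped.

## Known limitations

- Published family counts (e.g. how many families a given domain release
  yields) depend on the database snapshot and on unstated alignment
  parameters; they are not reproduction targets.
- The label-noise recovery margin is information-theoretically tight: with
  symmetric 5% label flips, flipped negatives are indistinguishable from
  true negatives and cap the achievable AUC-ROC at ≈ 0.899 on this
  generator. Class II models are additionally harder to fit than class I
  (the motif spreads over 8 hydrophobic residues at two positions), even
  noise-free.
- Contact-based and sequence-based models share one code path; no claim is
  made that contacts improve accuracy (on the original data they did not).
- The scan ranks candidates; it does not estimate interaction probability
  beyond the per-family Platt calibration, which is only as good as the
  family's training data.
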