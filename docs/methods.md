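# Methods

`mortcode` implements an automated underlying-cause-of-death (UCD) coding
system for ICD-10-coded death certificates: a probabilistic neural coder, a
synthetic certificate simulator with a deterministic rule-based coding
oracle that provides verifiable ground truth, a reject-aware evaluation
suite, and a year-harmonized recoding workflow for cause-of-death time
series. This note records the models, the assumptions behind them, the
defaults and why they were chosen, and what the synthetic experiments do
and do not demonstrate.

## The coding problem

A death certificate carries the causal chain of death in Part I (up to 4
lines, written in inverse causal order: the immediate cause on line 1 and
the underlying cause on the last used line) and up to 2 lines of other
significant conditions in Part II. Each line is a sequence of ICD-10 codes
(one letter + 2–3 digits, 22 chapters). National statistics offices select
a single UCD per certificate by applying WHO selection rules — including
rules that promote a Part II condition to UCD (the classic example: a
certificate with Kaposi's sarcoma in Part I and HIV disease in Part II is
coded to HIV), rules specific to neonatal deaths (<28 days), and rules that
change over calendar years. Production rule-based coders reject
certificates they deem too complex; humans complete those.

`mortcode` casts UCD selection as conditional density estimation:

    P(UCD | CCD, A, Y, G; Θ) = f_Θ(CCD, A, Y, G)

where CCD is the grid-encoded causal chain, A the factorized age (25 bins),
Y the year of death (16 states, 2000–2015 by default), G the gender (2
states), and f_Θ a convolutional neural network over the code grid.

## Certificate encoding

The six lines are laid out as a padded L×W integer grid (default 6×20; 20
accommodates the longest code lines seen in practice, and W is a config
value — wider certificates simply use a larger W). Part I occupies rows
0–3 and Part II rows 4–5; fixing the rows per part lets the model
distinguish Part II, which the promotion rules require. Two reserved
indices follow the V in-vocabulary codes: padding (`V`) and unknown
(`V+1`); unknown codes at inference map to the unknown index rather than
erroring, since real corpora contain codes unseen in training.

Age bins: 0–27 days (the neonatal period, which its own coding rules make
a semantically distinct class), 28 days–<1 year, 1–4 years, then 5-year
bins 5–9 … 105–109, and 110+ — 25 bins tiling [0, ∞). Gender is coded
0=male, 1=female from CSV tokens {M, F, 1, 2}.

A one-hot ("dummy variable") encoding of codes followed by a shared linear
projection is mathematically identical to an embedding-table lookup; the
implementation uses the lookup and the test suite certifies the
equivalence numerically for all four input variables. Three- and
four-character codes are distinct vocabulary entries; no hierarchical
structure is imposed (flat dummy-variable encodings have been reported to
outperform character-hierarchical ones on this task).

## Neural architecture

In order: (1) a shared linear projection (embedding) of every grid cell's
code; (2) linear projections of age, year and gender added to every
non-padding cell; (3) a stack of ReLU convolution blocks; (4) global max
pooling; (5) softmax regression over the V codes. Training minimizes
mini-batch cross-entropy with Adam, retaining the parameters of the best
validation-accuracy epoch.

Numerical and design choices:

- **Desk defaults**: embed_dim 32, two 3×3 conv blocks (64 then 128
  channels), global max pooling, Adam lr 1e-3, batch 256, 8 epochs. These
  are sized so the full desk experiment (20k training certificates,
  200-code vocabulary) trains in a few minutes on one CPU core with the
  NumPy implementation; on larger corpora one would scale embed_dim and
  channels up (the architecture is defined entirely by the config).
- **Padding neutrality**: the padding embedding is frozen at the zero
  vector and demographic projections are added to non-padding cells only.
  Together with "same" zero-padded convolutions and max pooling, this
  makes predictions exactly invariant to widening the grid with padding
  columns (translation invariance in W), which the suite checks at widths
  20 vs 30. The alternative — broadcasting demographics onto padding too —
  would break this exactness; the choice is behaviorally immaterial
  otherwise.
- **Zero-initialized softmax head**: the untrained model outputs the exact
  uniform distribution, a convenient known state for tests; gradients flow
  normally.
- **Determinism**: all initialization and batch shuffling flows through
  seeded NumPy generators; single-threaded runs are bit-reproducible.
  Argmax ties break toward the lowest vocabulary index.
- The network is implemented directly in NumPy (convolutions as sums of
  kernel-offset BLAS matrix products, hand-written backward passes,
  Adam). At desk scale this trains at roughly 0.3 s per 256-certificate
  batch on one core.

The gender variable is retained by default but can be ablated
(`use_gender=false` removes its parameters entirely); gender is not known
to influence any coding rule, and the synthetic generator gives it no
effect on labels.

## The synthetic certificate simulator and rule oracle

Real multiple-cause mortality microdata are restricted, so the package
ships a generator whose ground truth is produced by a deterministic
miniature rule system with the same structural properties a learned coder
must master. It is an intentional simplification of the WHO instruction
volume, not a reimplementation of it.

A seeded `CauseModel` holds:

- an acyclic causal-transition graph over the vocabulary, stratified into
  4 levels from eligible underlying causes (roots) to immediate causes,
  each non-terminal code linking to 2–4 successors with random weights;
- a UCD prior over roots (gamma-distributed weights, giving the skewed
  cause prevalences real data shows);
- 2 promotion pairs (Part II trigger + Part I pattern → the trigger
  becomes UCD). Patterns are the highest-marginal-probability intermediate
  causes under the chain distribution — the promotion rule matters
  precisely because the Part I manifestation is common in the trigger
  population, and this choice realizes promotion cases at ~2 % of
  certificates (~9 % carry the pattern, half of those the trigger), enough
  to train on and to measure;
- a neonatal remap over 25 % of roots, active only in age bin 0;
- a year rule change: from 2012 (the default threshold), ~10 % of roots
  are remapped to dedicated codes — the source of the harmonization
  experiment's discontinuity;
- a reject predicate: more than one "competing origin" in Part I (a code
  with no written cause among the other Part I codes) marks the
  certificate too complex, mirroring rule-based coders' reject behaviour.

Certificate sampling walks a chain forward from a sampled root (depth 1–4
with probabilities 0.15/0.35/0.35/0.15, so Part I line 4 is used ~15 % of
the time, under the <20 % seen in practice), writes it in inverse causal
order, one code per line, then adds Part II comorbidity lines
(probability 0.3, second line 0.3 conditional) from a comorbidity-only
pool, the promotion trigger (probability 0.5 when a pattern is present),
and a spurious noise code appended to a random Part I line (probability
0.1). Demographics oversample neonatal (5 %) and infant (2 %) deaths
relative to real mortality so the age-dependent rules are observable at
desk-scale corpus sizes; adult ages are normal around 76 (SD 14), years
uniform 2000–2015.

The oracle applies, in order: the general principle (the single condition
on the lowest used Part I line becomes UCD if the transition graph links
it, directly or transitively, to every condition above); otherwise a
fallback selecting the origin of the first-mentioned causal sequence
(greedy walk from the first code of line 1 to its written causes,
preferring the lowest line, then the leftmost code); Part II promotion;
the neonatal remap; the year remap; then the reject predicate. Rejected
certificates still receive the full-pipeline label with the reject
disabled — mirroring corpora in which rejects are completed by human
coders — and carry a reject flag. Labels are therefore a deterministic,
learnable function of the certificate and demographics (Bayes accuracy 1),
which is what makes held-out agreement a clean measure of rule recovery.

With these defaults the reject fraction comes out near 10 %: almost every
inserted noise code creates a second competing origin. Because the noise
code rarely changes the fallback origin, the gold label of a rejected
certificate usually equals the clean chain's root, so rejects are not
systematically harder for the learned coder — unlike real corpora, where
rejected certificates are genuinely ambiguous.

**What the simulator does not emulate**: real ICD-10 semantics and the
actual WHO decision tables; multi-code lines as the norm (lines carry one
chain code plus at most one noise code, far below the W=20 bound);
correlations between cause, age profile and gender; secular trends in
cause prevalence; and human coder noise (labels are noiseless). Passing
the desk experiments therefore shows that the architecture can recover
rule systems of this structure from labeled certificates at this scale —
not that it attains any particular accuracy on real mortality data.

## Evaluation suite

- **Accuracy** is exact-match fraction; its 95 % CI is a seeded percentile
  bootstrap with B=1000 replicates (the method and count are package
  choices; coverage is verified empirically at 93–97 % on
  Bernoulli(0.9) flags, n=2000, and the half-width tracks
  1.96·√(p(1−p)/n)).
- **Reject-aware baseline comparison**: the rule oracle with rejects
  enabled is scored twice on the test set — overall (rejects count as
  errors) and on nonrejected certificates only — next to the model's
  accuracy on the identical certificates. By construction the oracle is
  perfect on certificates it does not reject; in real corpora the
  rule-based baseline is imperfect also on accepted cases.
- **Per-chapter tables**: prevalence (gold share) and error rate per
  ICD-10 chapter, with never-observed chapters flagged; error rates
  recompose to global accuracy under prevalence weighting.
- **Chapter confusion on errors**: a chapter-level confusion matrix
  restricted to mispredictions (diagonal mass = errors staying in the
  gold chapter).
- **Top-k and second choice**: top-k accuracy with the coder's tie-break
  (reported for k∈{1,2} by default — short cause chains make large-k
  figures uninformative); second-choice accuracy on errors, satisfying
  top-2 = accuracy + (1−accuracy)·second-choice exactly.
- **Calibration**: argmax probability as the confidence score,
  histogrammed in 10 bins separately for correct and incorrect
  predictions, with group means.

## Harmonized recoding

`recode` predicts a UCD for every certificate with the year covariate
overridden to a fixed reference year (certificates are not mutated),
applying one year's coding rules uniformly across the whole period.
Cause groups are prefix sets over normalized dotless tokens ("F11" covers
F110–F119), as in the published overdose grouping (F11–F12, F14–F16, F19,
X42, X62, Y12 — F13 deliberately excluded); `overdose_groups()` returns
them. Per-year group counts de-duplicate at certificate level in the
total. The smoothness surrogate is the maximum absolute year-over-year
change of the grouped total: on the synthetic corpus the
original-coding series of the rule-change group jumps at the threshold
year, while the series recoded at 2015 is flat up to noise.

## Experiment protocol and problem sizes

The desk experiment uses a 200-code vocabulary (20 chapters × 10 codes)
and 16 years × 1450 certificates; per year, 75 go to validation and 125
to test (the per-year exclusion keeps the year covariate identically
distributed across splits), giving 20,000 / 1,200 / 2,000
train/val/test. At these sizes the full pipeline — simulation, training,
evaluation, bootstrap calibration, harmonized recoding — runs in under
ten minutes on one CPU core, and the trained coder reaches ~0.99
held-out agreement with the oracle (including ≥0.95 on the promotion
subset), against a baseline overall accuracy of ~0.90 at a ~10 % reject
fraction. Training-set size sweeps use 2k/5k/20k subsets of the same
split.

## Known limitations

- The NumPy implementation targets desk scale; corpus sizes in the
  millions would need a GPU framework and a larger architecture.
- The output layer spans the training vocabulary only; a UCD never seen
  in training cannot be predicted (rule remap targets are guaranteed to
  appear in training by construction of the simulator).
- The oracle's general principle checks graph reachability against the
  full transition graph, not the written sequence only; certificates
  whose written order contradicts the graph fall to the fallback rule.
  Real WHO rules are far richer (modification tables, linkage rules,
  duplicate handling).
- Bootstrap CIs treat test certificates as i.i.d.; the per-year
  stratified split makes this a good approximation for the synthetic
  corpus but it would understate uncertainty under temporal drift.
- Empty trailing lines and absent lines are indistinguishable (both are
  all-padding rows), which loses nothing under the one-code-per-line
  generator but is a representational choice.
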