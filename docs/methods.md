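# Methods

This note records the modelling choices behind `dtilink`, their
defaults, and what the synthetic benchmark does and does not
demonstrate.

## Model overview

The pipeline treats typed drug–target interaction (DTI) prediction as
link classification on a three-layer heterogeneous graph:

* **Nodes** — drugs, proteins, diseases (identifiers namespaced
  `drug::`, `protein::`, `disease::` so layers can never collide).
* **Edges** — four types: DDS (drug–drug Tanimoto similarity over
  MACCS keys), PPS (protein–protein normalised local-alignment
  similarity), DDis and DisP (curated disease associations, unit
  weight).  Known DTI edges are excluded from the graph by
  construction; they are the prediction target, and including them
  would leak labels into the features.

The key assumption is the similarity principle: similar drugs
(structurally) acting in similar disease contexts tend to engage
similar proteins in similar ways.  Embedding the graph turns that
relational signal into geometry; the classifiers then only need to
carve up embedding space.

## Similarity layers

* **MACCS/Tanimoto.**  The 166 structural keys are taken from the
  fingerprinting backend as an external constant catalogue (bit 0 of
  the 167-bit vector is a placeholder and is dropped).  Tanimoto of two
  empty fingerprints is 0/0; we define it as 1.0 (identical objects)
  and warn, so degenerate molecules cannot crash a matrix build.
* **Alignment similarity.**  Local alignment with BLOSUM62, gap open
  10, gap extend 0.5 — the common defaults of the alignment-tool
  family; all three are configurable.  Raw Smith–Waterman scores grow
  with length, so scores are normalised by the geometric mean of the
  two self-scores, which is symmetric, equals 1 for identical
  sequences, and is clipped into [0, 1] (a pair with no
  positive-scoring local alignment scores 0).  The parallel matrix
  builder partitions the pair list into fixed blocks, so the result is
  bit-identical for any worker count.

## Graph construction

`sim_threshold` defaults to 0.0: every strictly positive off-diagonal
similarity becomes an edge.  Dense similarity layers are deliberate —
thresholding is exposed as a flag but the default keeps the full
signal, and the walk bias already down-weights weak edges.  Association
edges carry weight 1.0 (no curated evidence weighting is modelled).
Self-similarities never become self-loops; isolated nodes are retained
so that every node receives an embedding.

## Embedding

Second-order biased walks with return parameter p and in–out parameter
q; a neighbour x of the current node v, with previous node t, is drawn
proportionally to `w(v,x) · (1/p if x=t; 1 if x~t; 1/q otherwise)` —
edge weights multiply the bias because the graph is weighted by
construction.  Defaults (p = q = 1, 10 walks per node, walk length 80,
window 10, 5 negatives, 5 epochs, dimension 100) are the canonical
walk-embedding defaults; all are configurable and logged.

The skip-gram-with-negative-sampling trainer is a compact, fully
seeded, single-threaded numpy implementation:

* negative targets drawn from the unigram distribution to the 3/4;
* learning rate decays linearly from 0.025 to 1e-4 across batches;
* pairs are processed in minibatches of 2048; within a batch each
  embedding row takes the **mean** of its accumulated gradient (not the
  sum), which bounds the step size by the learning rate no matter how
  often a node recurs in a batch — summed updates diverge on small,
  dense vocabularies;
* scores saturate at |6| (zero gradient beyond), the classic sigmoid
  cut-off, which prevents runaway norms;
* arithmetic is float32 for speed, cast to float64 on output.

Walk generation caches the cumulative transition distribution per
(prev, cur) pair, and a walk stops early only at a dead end (an
isolated start node yields a single-node walk).

## Dataset handling

The six-label vocabulary is ordered as first introduced: increases^/
decreases^expression, decreases^/increases^reaction, increases^/
decreases^activity.  Rows of one pair merge into a label set; a pair
both positive and 'inactive' is a hard error; a positive set containing
both degrees of one action (e.g. increases^expression +
decreases^expression) is ambiguous and removed before modelling
(idempotent filter).  More than three labels on a training pair is
allowed with a warning.

Splitting is **pair-level** (all labels of a pair travel together):
external test = round(0.1·n), validation = round(0.1·n), remainder
train.  Per repeat the split is re-drawn with a derived child seed.  No
label stratification is applied; imbalance is handled by SMOTE
downstream.  Cross-validation is k-fold (k = 10) over the training
rows only.

## Classifiers

Gradient-boosted trees with the fixed protocol: subsample 1, gamma 1,
min child weight 2, learning rate 0.01, early stopping 20 rounds,
up to 300 boosting rounds (our choice; enough for the slow learning
rate to produce confident probabilities, which the 0.95 screening
threshold requires).  The only grid-searched quantity is maximum tree
depth, default grid {3, 5, 7}, selected per label by mean
cross-validation F1 (ties break toward the smaller depth).  SMOTE
(interpolation between a minority sample and one of its k = 5 nearest
minority neighbours) is applied to the training part of each fold only,
never to the fold's test rows, and never alters an original sample; k
shrinks with a warning when the minority is smaller than k + 1.  The
final model per label is refit on the full training split with early
stopping on the validation split.  A label without at least two
training samples of each class is marked untrainable, warned about, and
excluded from macro averages.

Evaluation uses decision threshold 0.5.  Per label we report accuracy,
F1 and precision; the "Total" row is the **unweighted (macro) mean**
over trainable labels, and across repeats the mean and population
variance of every cell are reported.  Precision with zero predicted
positives is undefined; it is reported as 0 with a warning so macro
rows stay comparable across repeats.

## Two-step prediction

Candidates are the drug × protein product minus known (positive or
negative) pairs, in lexicographic order so results are independent of
input order.  Step 1 keeps candidates with binary probability ≥ 0.95
(the high-confidence screen); step 2 assigns every label with type
probability ≥ 0.5.  Survivors with zero or more than three labels are
excluded as ambiguous (their label sets are cleared, scores retained).
Contradictory degree pairs (increases^A + decreases^A) in predictions
are retained but flagged — the ambiguity filter of the training data is
not silently applied to outputs.  Ranking per label sorts by type
score, then binary score, then pair identifier.

## Synthetic world

The generator emulates the five input tables with planted, recoverable
structure.  Defaults: 3 drug clusters × 3 protein clusters, 15 drugs
and 20 proteins per cluster, 30 diseases, fingerprint bit-flip noise
0.05, sequence point-mutation rate 0.10.  Choices made here:

* centroid fingerprints have bit density 0.25 (sparse, MACCS-like),
  giving within-cluster Tanimoto ≈ 0.7–0.9 vs ≈ 0.15 between clusters;
* protein ancestors are length-120 uniform random sequences; 10%
  point mutations keep within-family normalised similarity ≈ 0.8 while
  unrelated families sit near 0;
* each disease picks one (drug cluster, protein cluster) cell and
  links to 5 drugs and 5 proteins of that cell, bridging the layers;
* the default type rule assigns the six labels row-major over cluster
  cells and leaves one cell per drug-cluster row untyped; positives are
  sampled from typed cells at rate 0.25, validated negatives from
  untyped cells at rate 0.05 (negatives ≈ 9% of labelled rows,
  matching the strong positive skew of curated interaction data).

Everything is deterministic per seed, down to byte-identical output
files.

**What passing shows / does not show.**  Recovery of planted types
demonstrates that every stage transmits the relational signal
faithfully — similarity computation, graph assembly, walk statistics,
embedding geometry, fold hygiene, thresholding.  It does *not*
demonstrate performance on real pharmacology: real fingerprints are
correlated (not independent bit flips), real interaction types are not
a clean function of structural clusters, real association data is
biased and incomplete, and real negatives are scarcer and harder.  The
synthetic world has single-label positives; multi-label handling is
exercised by unit tests rather than by the generator.

## Problem sizes and runtime

The default world (135 nodes, ≈ 3,000 edges, ≈ 480 labelled pairs) runs
the full pipeline in a few minutes on one CPU: embedding ≈ 1.5 min
(1,350 walks × 80 steps, 5 epochs), model fitting ≈ 2 min (6 labels ×
10 folds × 3 depths plus the binary screen), prediction over ≈ 2,200
candidates in seconds.  These sizes were chosen so a full
recovery-plus-control experiment stays desk-scale; the harness scales
to larger worlds by configuration.

## Known limitations

* The skip-gram trainer is minibatched for vectorisation; its learning
  dynamics differ slightly from per-pair SGD (canonical word2vec), and
  embeddings are reproducible only in single-worker mode.
* One embedding is trained per world; the 5-repeat protocol re-draws
  splits and model seeds but not walks (embedding variance is not
  separated from classifier variance).
* The binary screen and the type models are trained on the same split;
  the screen's 0.95 threshold is a confidence cut-off, not a calibrated
  probability.
* Tanimoto on near-empty fingerprints is noisy; the 1.0 convention for
  two empty fingerprints is a pragmatic, logged choice.
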