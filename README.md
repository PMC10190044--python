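# dtilink

Predicting drug–target interactions **and their mode of action** from a
heterogeneous drug–protein–disease graph.

## The problem

In drug repurposing it is not enough to know *that* a drug touches a
protein — the therapeutic consequence depends on *how*: does the drug
increase or decrease the target's expression, its reaction rate, or its
activity?  `dtilink` addresses this as a two-step, multi-label link
classification task over six interaction types

```
L6 = { increases^expression, decreases^expression,
       decreases^reaction,  increases^reaction,
       increases^activity,  decreases^activity }
```

It is aimed at computational drug-discovery practitioners who have
(i) a drug table with structures, (ii) target protein sequences,
(iii) curated drug–disease and protein–disease associations, and
(iv) a labelled drug–target interaction table with validated negatives,
and who want a ranked shortlist of novel, typed drug–target candidates.

## The method

1. **Similarity layers.**  Drug–drug similarity M_DDS is the Tanimoto
   coefficient c/(a+b−c) over 166-bit MACCS structural keys; protein–
   protein similarity M_PPS is the Smith–Waterman local-alignment score
   normalised by the geometric mean of the self-alignment scores,
   S(a,b)/√(S(a,a)·S(b,b)) (BLOSUM62, gap open 10 / extend 0.5).
2. **Heterogeneous graph.**  M_DDS and M_PPS edges (weight = similarity)
   are integrated with disease–drug (DDis) and disease–protein (DisP)
   association edges (weight = 1) over three node layers.  Known
   drug–target edges are *excluded* so the classifier never sees its
   answer encoded in the graph.
3. **Node embedding.**  Second-order biased random walks (node2vec;
   return parameter p, in–out parameter q, weighted by edge weight)
   feed a skip-gram model with negative sampling; every node maps to a
   100-dimensional vector.
4. **Two-step classification.**  Each (drug, target) pair becomes the
   200-dimensional concatenation [v_drug ; v_protein].  A binary
   XGBoost screen separates active from inactive pairs; six
   one-vs-rest XGBoost models assign the interaction types.  Training
   folds are balanced with SMOTE, tree depth is grid-searched inside
   each cross-validation fold, and performance is reported as per-label
   accuracy / F1 / precision on an 80/10/10 train–validation–external
   split, repeatable k-fold (k = 10) times r repeats.
5. **Repurposing scan.**  All unknown pairs are screened at probability
   ≥ 0.95, survivors are typed (label threshold 0.5), predictions with
   zero or more than three labels are excluded as ambiguous, and the
   rest are ranked per label.

## Worked example

The package ships a synthetic-world generator that plants recoverable
structure: drugs fall into fingerprint clusters, proteins into sequence
families, diseases bridge specific cluster pairs, and the interaction
type of a pair is a fixed function of its (drug cluster, protein
cluster) cell.

```python
from dtilink import WorldConfig, PipelineConfig
from dtilink.synthetic import recovery_harness

report = recovery_harness(WorldConfig(seed=42), PipelineConfig(seed=42))
print(report)
```

prints (exactly reproducible for this seed):

```
{'macro_accuracy': 0.9878048780487805, 'macro_f1': 0.9663865546218489,
 'macro_precision': 0.9761904761904763, 'binary_accuracy': 1.0,
 'n_interactions': 485, 'n_positive': 440, 'n_negative': 45}
```

i.e. on the held-out external 10% of labelled pairs the six
interaction-type models reach macro precision ≈ 0.98 and the binary
active/inactive screen is perfect — the planted modes of action are
recovered from graph structure alone.  Shuffling the labels among pairs
(the permutation control) collapses macro precision to the ~1/6 chance
band.

The same pipeline is scriptable from the shell:

```bash
dtilink synth --out world --seed 42
dtilink all --world world --out run --seed 42   # similarity → graph → embed → train → predict
```

`run/metrics.tsv` mirrors the per-label metric table (six label rows, a
macro "Total" row and a "Binary (active/inactive)" row) and
`run/top_predictions/` contains the per-label top-20 candidate tables.

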