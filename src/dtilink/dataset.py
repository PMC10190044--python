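"""Labelled interaction table handling, features, and data splitting.

The six-type mode-of-action vocabulary combines a degree
(increases/decreases) with an action (expression, reaction, activity).
A drug-protein pair is either positive with 1-3 labels or a validated
negative ('inactive').  Pairs whose label set contains both degrees of
the same action are ambiguous and removed before modelling.

Splitting is pair-level: all labels of a pair travel together into one
of train (80%), validation (10%) or external test (10%), so no pair
identity leaks across partitions.  Cross-validation is k-fold over the
training rows, repeated with distinct derived seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .embedding import EmbeddingTable
from .exceptions import LabelConflictError, MissingEmbeddingError, VocabularyError
from .graph import namespaced

#: the six interaction-type labels, in the order they are first introduced
L6 = (
    "increases^expression",
    "decreases^expression",
    "decreases^reaction",
    "increases^reaction",
    "increases^activity",
    "decreases^activity",
)

NEGATIVE_LABEL = "inactive"

_ACTIONS = ("expression", "reaction", "activity")


@dataclass(frozen=True)
class InteractionRow:
    drug_id: str
    protein_id: str
    labels: frozenset[str]

    @property
    def is_negative(self) -> bool:
        return not self.labels

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.protein_id)


@dataclass
class InteractionTable:
    """Deduplicated drug-protein rows, each positive (1-3 labels) or negative."""

    rows: list[InteractionRow]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def positives(self) -> list[InteractionRow]:
        return [r for r in self.rows if not r.is_negative]

    @property
    def negatives(self) -> list[InteractionRow]:
        return [r for r in self.rows if r.is_negative]

    def pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.rows}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\tprotein_id\tlabel\n")
            for r in self.rows:
                if r.is_negative:
                    fh.write(f"{r.drug_id}\t{r.protein_id}\t{NEGATIVE_LABEL}\n")
                else:
                    for lab in sorted(r.labels, key=L6.index):
                        fh.write(f"{r.drug_id}\t{r.protein_id}\t{lab}\n")


def load_interactions(path) -> InteractionTable:
    """Read ``drug_id<TAB>protein_id<TAB>label`` rows, merging labels per pair.

    'inactive' rows become negatives; a pair recorded both positive and
    'inactive' is a contradiction and raises.  Unknown label strings
    raise naming the offending row.  Pairs with more than three labels
    are kept but flagged with a warning.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    negative: dict[tuple[str, str], bool] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0].lower() == "drug_id":
                continue
            drug_id, protein_id, label = parts[0], parts[1], parts[2]
            pair = (drug_id, protein_id)
            if label == NEGATIVE_LABEL:
                negative[pair] = True
                merged.setdefault(pair, set())
            elif label in L6:
                merged.setdefault(pair, set()).add(label)
            else:
                raise VocabularyError(
                    f"line {lineno}: unknown label {label!r} for pair {pair}"
                )
    rows = []
    for pair in sorted(merged):
        labels = merged[pair]
        if negative.get(pair) and labels:
            raise LabelConflictError(
                f"pair {pair} recorded both as positive ({sorted(labels)}) and '{NEGATIVE_LABEL}'"
            )
        if len(labels) > 3:
            warnings.warn(
                f"pair {pair} carries {len(labels)} labels (more than 3)", stacklevel=2
            )
        rows.append(InteractionRow(pair[0], pair[1], frozenset(labels)))
    return InteractionTable(rows)


def _is_ambiguous(labels: frozenset[str]) -> bool:
    return any(
        f"increases^{a}" in labels and f"decreases^{a}" in labels for a in _ACTIONS
    )


def remove_ambiguous(table: InteractionTable) -> InteractionTable:
    """Drop positive rows containing both degrees of the same action (idempotent)."""
    return InteractionTable([r for r in table.rows if not _is_ambiguous(r.labels)])


def one_hot(labels: Iterable[str]) -> np.ndarray:
    """Encode a label subset as a 6-bit vector in L6 order."""
    labels = set(labels)
    bad = labels - set(L6)
    if bad:
        raise VocabularyError(f"labels outside the six-type vocabulary: {sorted(bad)}")
    return np.array([1 if lab in labels else 0 for lab in L6], dtype=np.int8)


def labels_from_one_hot(bits: Sequence[int]) -> frozenset[str]:
    if len(bits) != len(L6):
        raise VocabularyError("label vector must have length 6")
    return frozenset(lab for lab, b in zip(L6, bits) if b)


def pair_features(emb: EmbeddingTable, drug_id: str, protein_id: str) -> np.ndarray:
    """Concatenate drug then protein embedding (length 2*dim, 200 at default)."""
    d_node = namespaced("drug", drug_id)
    p_node = namespaced("protein", protein_id)
    for node in (d_node, p_node):
        if node not in emb:
            raise MissingEmbeddingError(f"no embedding for {node!r}")
    return np.concatenate([emb.get(d_node), emb.get(p_node)])


def feature_matrix(
    emb: EmbeddingTable, pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    return np.stack([pair_features(emb, d, p) for d, p in pairs]) if pairs else np.empty((0, 2 * emb.dim))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Pair-level 80/10/10 partition of an interaction table."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    external_idx: np.ndarray
    seed: int = 0

    def partition_of(self, idx: int) -> str:
        if idx in set(self.train_idx.tolist()):
            return "train"
        if idx in set(self.validation_idx.tolist()):
            return "validation"
        return "external_test"

    def to_tsv(self, path, table: InteractionTable) -> None:
        with open(path, "w") as fh:
            fh.write("drug_id\tprotein_id\tpartition\n")
            for name, idxs in (
                ("train", self.train_idx),
                ("validation", self.validation_idx),
                ("external_test", self.external_idx),
            ):
                for i in idxs:
                    r = table.rows[int(i)]
                    fh.write(f"{r.drug_id}\t{r.protein_id}\t{name}\n")


def split_dev(table: InteractionTable, seed: int = 0) -> SplitAssignment:
    """Disjoint 80/10/10 split: external = round(0.1 n), validation = round(0.1 n)."""
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    n_ext = round(0.10 * n)
    n_val = round(0.10 * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return SplitAssignment(
        external_idx=np.sort(order[:n_ext]),
        validation_idx=np.sort(order[n_ext : n_ext + n_val]),
        train_idx=np.sort(order[n_ext + n_val :]),
        seed=seed,
    )


def derive_seeds(seed: int, count: int) -> list[int]:
    """Distinct child seeds below 2**31, deterministic in the parent seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=count)]


def make_cv_folds(
    n_rows: int, k: int = 10, repeats: int = 5, seed: int = 0
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Repeated k-fold assignments: ``repeats`` lists of k (train, test) index pairs.

    Fold sizes differ by at most one; every row tests exactly once per
    repeat; each repeat shuffles with its own derived seed.
    """
    if k > n_rows:
        raise ValueError(f"k={k} exceeds row count {n_rows}")
    out = []
    for child in derive_seeds(seed, repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=child % (2**31 - 1))
        out.append([(tr, te) for tr, te in kf.split(np.arange(n_rows))])
    return out
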