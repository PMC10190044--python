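"""Two-step screening and mode-of-action assignment for unknown pairs.

Step 1 scores every candidate pair with the binary active/inactive
model and keeps only high-confidence actives (probability >= 0.95 by
default).  Step 2 scores survivors with the six per-label models and
assigns every label whose probability reaches 0.5.  Survivors with no
assigned label or more than three are excluded as ambiguous.  Remaining
predictions can be ranked per label for repurposing shortlists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import L6, InteractionTable, feature_matrix
from .embedding import EmbeddingTable
from .exceptions import VocabularyError
from .model import ModelBundle

STATUS_SCREENED_OUT = "screened_out"
STATUS_PREDICTED = "predicted"
STATUS_AMBIGUOUS = "ambiguous_excluded"

_ACTIONS = ("expression", "reaction", "activity")


@dataclass
class PredictionRecord:
    drug_id: str
    protein_id: str
    binary_score: float
    type_scores: np.ndarray | None  # length 6 in L6 order; None when screened out
    assigned_labels: frozenset[str] = frozenset()
    status: str = STATUS_SCREENED_OUT
    contradictory: bool = False  # both degrees of one action assigned

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.protein_id)


def enumerate_candidates(
    drugs: Sequence[str], proteins: Sequence[str], known: InteractionTable
) -> list[tuple[str, str]]:
    """Cartesian product minus known (positive or negative) pairs, sorted."""
    known_pairs = known.pairs()
    return [
        (d, p)
        for d in sorted(drugs)
        for p in sorted(proteins)
        if (d, p) not in known_pairs
    ]


def _has_contradiction(labels: frozenset[str]) -> bool:
    return any(
        f"increases^{a}" in labels and f"decreases^{a}" in labels for a in _ACTIONS
    )


def two_step_predict(
    bundle: ModelBundle,
    emb: EmbeddingTable,
    candidates: Sequence[tuple[str, str]],
    threshold: float = 0.95,
    label_threshold: float = 0.5,
) -> list[PredictionRecord]:
    """Screen candidates with the binary model, then type the survivors.

    Candidates below the binary threshold are ``screened_out`` with no
    type scores.  Survivors get six type scores and every label scoring
    at least ``label_threshold``; contradictory degree pairs are kept
    but flagged.  Output order follows sorted candidate order, so the
    result is invariant to input ordering.
    """
    ordered = sorted(candidates)
    if not ordered:
        return []
    X = feature_matrix(emb, ordered)
    binary = bundle.binary_scores(X)
    survivors = np.flatnonzero(binary >= threshold)
    type_scores = np.zeros((len(ordered), len(L6)))
    if len(survivors):
        type_scores[survivors] = bundle.label_scores(X[survivors])

    records: list[PredictionRecord] = []
    survivor_set = set(survivors.tolist())
    for i, (d, p) in enumerate(ordered):
        if i not in survivor_set:
            records.append(
                PredictionRecord(d, p, float(binary[i]), None, frozenset(), STATUS_SCREENED_OUT)
            )
            continue
        scores = type_scores[i]
        labels = frozenset(
            lab for j, lab in enumerate(L6) if scores[j] >= label_threshold
        )
        records.append(
            PredictionRecord(
                d,
                p,
                float(binary[i]),
                scores.copy(),
                labels,
                STATUS_PREDICTED,
                contradictory=_has_contradiction(labels),
            )
        )
    return records


def filter_ambiguous_predictions(
    records: Sequence[PredictionRecord],
) -> list[PredictionRecord]:
    """Exclude survivors with no assigned label or more than three.

    Excluded records keep their type scores but lose their label set,
    so a non-empty label set implies status ``predicted``.
    """
    out = []
    for r in records:
        if r.status == STATUS_PREDICTED and (
            len(r.assigned_labels) == 0 or len(r.assigned_labels) > 3
        ):
            out.append(
                PredictionRecord(
                    r.drug_id,
                    r.protein_id,
                    r.binary_score,
                    r.type_scores,
                    frozenset(),
                    STATUS_AMBIGUOUS,
                    contradictory=r.contradictory,
                )
            )
        else:
            out.append(r)
    return out


def rank_top(
    records: Sequence[PredictionRecord], label: str, n: int = 20
) -> list[PredictionRecord]:
    """Top-n predicted records for one label, by that label's score.

    Ties break by binary score, then lexicographic (drug_id,
    protein_id).
    """
    if label not in L6:
        raise VocabularyError(f"unknown label {label!r}")
    j = L6.index(label)
    qualifying = [
        r for r in records if r.status == STATUS_PREDICTED and label in r.assigned_labels
    ]
    qualifying.sort(
        key=lambda r: (-r.type_scores[j], -r.binary_score, r.drug_id, r.protein_id)
    )
    return qualifying[:n]


def status_counts(records: Sequence[PredictionRecord]) -> dict[str, int]:
    counts = {STATUS_SCREENED_OUT: 0, STATUS_PREDICTED: 0, STATUS_AMBIGUOUS: 0}
    for r in records:
        counts[r.status] += 1
    return counts


def write_predictions(records: Sequence[PredictionRecord], path, header_comments=()) -> None:
    """TSV with pair ids, binary score, six type scores, labels, status, flag."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        cols = ["drug_id", "protein_id", "binary_score"] + [f"score:{lab}" for lab in L6]
        cols += ["assigned_labels", "status", "contradictory"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            scores = (
                "\t".join(f"{s:.6f}" for s in r.type_scores)
                if r.type_scores is not None
                else "\t".join("" for _ in L6)
            )
            labels = ";".join(sorted(r.assigned_labels, key=L6.index))
            fh.write(
                f"{r.drug_id}\t{r.protein_id}\t{r.binary_score:.6f}\t{scores}\t"
                f"{labels}\t{r.status}\t{int(r.contradictory)}\n"
            )
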