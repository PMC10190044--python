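"""Two-step prediction, ambiguity filtering, and ranking."""

import numpy as np
import pytest

from dtilink.dataset import L6, InteractionRow, InteractionTable
from dtilink.embedding import EmbeddingTable
from dtilink.exceptions import VocabularyError
from dtilink.model import ModelBundle, TrainConfig
from dtilink.predict import (
    STATUS_AMBIGUOUS,
    STATUS_PREDICTED,
    STATUS_SCREENED_OUT,
    PredictionRecord,
    enumerate_candidates,
    filter_ambiguous_predictions,
    rank_top,
    status_counts,
    two_step_predict,
    write_predictions,
)


class _PairScorer:
    """Scores each feature row by a lookup on its first coordinate."""

    def __init__(self, score_map, default=0.0):
        self.score_map = score_map
        self.default = default

    def predict_proba(self, X):
        p = np.array([self.score_map.get(round(float(x[0]), 3), self.default) for x in X])
        return np.column_stack([1 - p, p])


def make_embeddings(drugs, proteins, dim=2):
    """Each drug's first coordinate encodes its index (for stub lookups)."""
    ids, vecs = [], []
    for i, d in enumerate(drugs):
        ids.append(f"drug::{d}")
        vecs.append([float(i), 0.0])
    for j, p in enumerate(proteins):
        ids.append(f"protein::{p}")
        vecs.append([100.0 + j, 0.0])
    return EmbeddingTable(ids, np.array(vecs))


def make_bundle(binary_map, label_maps=None, default=0.0):
    label_maps = label_maps or {}
    return ModelBundle(
        label_models={
            lab: _PairScorer(label_maps.get(lab, {}), default) for lab in L6
        },
        binary_model=_PairScorer(binary_map, default),
        depths={lab: 3 for lab in L6},
        binary_depth=3,
        config=TrainConfig(),
    )


def known_table(pairs):
    return InteractionTable(
        [InteractionRow(d, p, frozenset({L6[0]})) for d, p in pairs]
    )


class TestEnumerate:
    def test_product_minus_known(self):
        known = known_table([("d1", "p1"), ("d2", "p3")])
        cands = enumerate_candidates(["d1", "d2", "d3"], ["p1", "p2", "p3", "p4"], known)
        assert len(cands) == 12 - 2
        assert ("d1", "p1") not in cands

    def test_no_known_pairs_gives_full_product(self):
        cands = enumerate_candidates(["d1", "d2"], ["p1", "p2"], InteractionTable([]))
        assert cands == [("d1", "p1"), ("d1", "p2"), ("d2", "p1"), ("d2", "p2")]

    def test_all_known_gives_empty(self):
        known = known_table([("d1", "p1"), ("d1", "p2")])
        assert enumerate_candidates(["d1"], ["p1", "p2"], known) == []


class TestTwoStep:
    def test_below_threshold_screened_out_without_type_scores(self):
        emb = make_embeddings(["d1"], ["p1"])
        bundle = make_bundle({0.0: 0.10})
        (rec,) = two_step_predict(bundle, emb, [("d1", "p1")])
        assert rec.status == STATUS_SCREENED_OUT
        assert rec.type_scores is None and rec.assigned_labels == frozenset()

    def test_survivors_respect_default_threshold(self):
        emb = make_embeddings(["d1", "d2"], ["p1"])
        bundle = make_bundle({0.0: 0.94, 1.0: 0.96}, {L6[1]: {1.0: 0.8}})
        recs = two_step_predict(bundle, emb, [("d1", "p1"), ("d2", "p1")])
        by_drug = {r.drug_id: r for r in recs}
        assert by_drug["d1"].status == STATUS_SCREENED_OUT
        assert by_drug["d2"].status == STATUS_PREDICTED
        assert by_drug["d2"].binary_score >= 0.95
        assert by_drug["d2"].assigned_labels == frozenset({L6[1]})

    def test_result_invariant_to_candidate_order(self):
        emb = make_embeddings(["d1", "d2"], ["p1", "p2"])
        bundle = make_bundle({0.0: 0.99, 1.0: 0.2}, {L6[0]: {0.0: 0.9}})
        cands = [("d2", "p1"), ("d1", "p2"), ("d1", "p1"), ("d2", "p2")]
        r1 = two_step_predict(bundle, emb, cands)
        r2 = two_step_predict(bundle, emb, list(reversed(cands)))
        assert [(r.pair, r.status) for r in r1] == [(r.pair, r.status) for r in r2]

    def test_raising_threshold_never_grows_predicted_set(self):
        emb = make_embeddings(["d1", "d2", "d3"], ["p1"])
        bundle = make_bundle({0.0: 0.90, 1.0: 0.96, 2.0: 0.99}, default=0.6)
        cands = [("d1", "p1"), ("d2", "p1"), ("d3", "p1")]
        sizes = []
        for thr in (0.5, 0.9, 0.95, 0.97, 1.0):
            recs = two_step_predict(bundle, emb, cands, threshold=thr)
            sizes.append(sum(r.status == STATUS_PREDICTED for r in recs))
        assert sizes == sorted(sizes, reverse=True)

    def test_contradictory_label_pair_flagged_but_kept(self):
        emb = make_embeddings(["d1"], ["p1"])
        bundle = make_bundle(
            {0.0: 0.99},
            {"increases^expression": {0.0: 0.9}, "decreases^expression": {0.0: 0.9}},
        )
        (rec,) = two_step_predict(bundle, emb, [("d1", "p1")])
        assert rec.contradictory
        assert rec.status == STATUS_PREDICTED


def rec(drug, prot, binary, scores, labels, status=STATUS_PREDICTED):
    return PredictionRecord(
        drug, prot, binary, np.asarray(scores, dtype=float), frozenset(labels), status
    )


class TestFilterAmbiguous:
    def test_zero_labels_excluded(self):
        (out,) = filter_ambiguous_predictions([rec("d", "p", 0.99, [0.1] * 6, [])])
        assert out.status == STATUS_AMBIGUOUS

    def test_four_labels_excluded_and_labels_cleared(self):
        labels = [L6[0], L6[2], L6[4], L6[5]]
        (out,) = filter_ambiguous_predictions([rec("d", "p", 0.99, [0.9] * 6, labels)])
        assert out.status == STATUS_AMBIGUOUS
        assert out.assigned_labels == frozenset()

    def test_two_labels_pass_unchanged(self):
        (out,) = filter_ambiguous_predictions(
            [rec("d", "p", 0.99, [0.9] * 6, [L6[0], L6[4]])]
        )
        assert out.status == STATUS_PREDICTED
        assert out.assigned_labels == frozenset({L6[0], L6[4]})

    def test_screened_out_records_pass_through(self):
        r = PredictionRecord("d", "p", 0.1, None, frozenset(), STATUS_SCREENED_OUT)
        (out,) = filter_ambiguous_predictions([r])
        assert out.status == STATUS_SCREENED_OUT

    def test_conservation_of_record_counts(self):
        records = [
            rec("d1", "p", 0.99, [0.9] * 6, [L6[0]]),
            rec("d2", "p", 0.99, [0.1] * 6, []),
            PredictionRecord("d3", "p", 0.1, None, frozenset(), STATUS_SCREENED_OUT),
        ]
        counts = status_counts(filter_ambiguous_predictions(records))
        assert sum(counts.values()) == len(records)
        assert counts == {
            STATUS_SCREENED_OUT: 1,
            STATUS_PREDICTED: 1,
            STATUS_AMBIGUOUS: 1,
        }


class TestRankTop:
    def _records(self):
        def scores(v):
            s = [0.0] * 6
            s[0] = v
            return s

        return [
            rec("dB", "p1", 0.97, scores(0.8), [L6[0]]),
            rec("dA", "p1", 0.99, scores(0.8), [L6[0]]),  # tie on type, higher binary
            rec("dC", "p1", 0.99, scores(0.9), [L6[0]]),
            rec("dD", "p1", 0.99, scores(0.7), [L6[1]]),  # different label
        ]

    def test_sorted_by_type_score_then_binary_then_pair(self):
        top = rank_top(self._records(), L6[0], n=20)
        assert [r.drug_id for r in top] == ["dC", "dA", "dB"]

    def test_n_caps_output(self):
        top = rank_top(self._records(), L6[0], n=2)
        assert len(top) == 2

    def test_fewer_qualifying_than_n(self):
        assert len(rank_top(self._records(), L6[1], n=20)) == 1

    def test_unknown_label_rejected(self):
        with pytest.raises(VocabularyError):
            rank_top([], "binds")


class TestWritePredictions:
    def test_tsv_layout(self, tmp_path):
        records = filter_ambiguous_predictions(
            [
                rec("d1", "p1", 0.99, [0.9, 0, 0, 0, 0, 0], [L6[0]]),
                PredictionRecord("d2", "p1", 0.1, None, frozenset(), STATUS_SCREENED_OUT),
            ]
        )
        path = tmp_path / "pred.tsv"
        write_predictions(records, path, header_comments=["artifact"])
        lines = path.read_text().strip().split("\n")
        assert lines[0].startswith("#")
        header = lines[1].split("\t")
        assert header[:3] == ["drug_id", "protein_id", "binary_score"]
        assert len([ln for ln in lines if not ln.startswith("#")]) == 3
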