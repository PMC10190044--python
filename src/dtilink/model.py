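"""Interaction-type and activity classifiers over pair embeddings.

Six one-vs-rest gradient-boosted classifiers (one per mode-of-action
label) plus one binary active/inactive classifier are trained on
concatenated drug+protein embedding vectors.  Each training fold is
balanced with SMOTE before fitting; the only grid-searched quantity is
the maximum tree depth, selected by mean validation F1 across the
cross-validation folds.  Fixed hyperparameters: subsample ratio 1,
gamma 1, minimum child weight 2, early stopping 20 rounds, learning
rate 0.01.

The statsmodels-style entry point is :class:`DrugTargetModel`, built
from an :class:`~dtilink.embedding.EmbeddingTable` and an
:class:`~dtilink.dataset.InteractionTable`; ``fit()`` returns a
:class:`DrugTargetResults` carrying per-label metrics, the fitted model
bundle and a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, precision_score
from sklearn.neighbors import NearestNeighbors

from . import dataset as ds
from .dataset import L6, InteractionTable, SplitAssignment
from .embedding import EmbeddingTable


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the boosted-tree protocol."""

    learning_rate: float = 0.01
    subsample: float = 1.0
    gamma: float = 1.0
    min_child_weight: int = 2
    early_stopping_rounds: int = 20
    n_estimators: int = 300
    depth_grid: tuple[int, ...] = (3, 5, 7)
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not self.depth_grid:
            raise ValueError("depth_grid must be non-empty")


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary problem by synthetic minority oversampling.

    Each synthetic sample is x_i + lam * (x_nn - x_i) for a random
    minority sample x_i, one of its k nearest minority neighbours x_nn,
    and lam ~ U[0, 1].  Originals are returned unchanged (prepended).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("SMOTE requires both classes to be present")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    if n_min <= k:
        warnings.warn(
            f"minority count {n_min} <= k={k}; reducing k to {n_min - 1}", stacklevel=2
        )
        k = n_min - 1

    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, nbr_idx = nn.kneighbors(Xmin)  # column 0 is the point itself

    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    lam = rng.random(n_new)
    neighbours = Xmin[nbr_idx[base, pick]]
    synthetic = Xmin[base] + lam[:, None] * (neighbours - Xmin[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=int)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# XGBoost helpers
# ---------------------------------------------------------------------------

def _make_classifier(depth: int, cfg: TrainConfig, use_early_stopping: bool):
    from xgboost import XGBClassifier

    return XGBClassifier(
        max_depth=depth,
        learning_rate=cfg.learning_rate,
        n_estimators=cfg.n_estimators,
        subsample=cfg.subsample,
        gamma=cfg.gamma,
        min_child_weight=cfg.min_child_weight,
        early_stopping_rounds=cfg.early_stopping_rounds if use_early_stopping else None,
        random_state=cfg.seed % (2**31 - 1),
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
        verbosity=0,
    )


def _fit_binary(
    X_tr, y_tr, X_eval, y_eval, depth: int, cfg: TrainConfig
):
    """Fit one boosted tree with early stopping on (X_eval, y_eval)."""
    use_es = len(np.unique(y_eval)) == 2
    clf = _make_classifier(depth, cfg, use_early_stopping=use_es)
    if use_es:
        clf.fit(X_tr, y_tr, eval_set=[(X_eval, y_eval)], verbose=False)
    else:
        clf.fit(X_tr, y_tr, verbose=False)
    return clf


def _grid_search_depth(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[int, dict[int, float]]:
    """Select tree depth by mean validation F1 over the CV folds.

    SMOTE is applied to the training part of each fold only; test folds
    are scored untouched.
    """
    scores: dict[int, list[float]] = {d: [] for d in cfg.depth_grid}
    for fold_no, (tr, te) in enumerate(folds):
        X_tr, y_tr = X[tr], y[tr]
        if len(np.unique(y_tr)) < 2 or min(np.bincount(y_tr)) < 2:
            continue  # fold degenerate for this label; skip
        X_bal, y_bal = smote_oversample(
            X_tr, y_tr, k=cfg.smote_k, seed=cfg.seed + fold_no
        )
        for depth in cfg.depth_grid:
            clf = _fit_binary(X_bal, y_bal, X[te], y[te], depth, cfg)
            pred = clf.predict_proba(X[te])[:, 1] >= 0.5
            scores[depth].append(f1_score(y[te], pred.astype(int), zero_division=0))
    means = {
        d: float(np.mean(v)) if v else 0.0 for d, v in scores.items()
    }
    # deterministic tie-break: smallest depth among the best
    best = min(cfg.depth_grid, key=lambda d: (-means[d], d))
    return best, means


class _BoosterScorer:
    """Probability scorer over a bare serialized booster (for loaded bundles)."""

    def __init__(self, booster):
        self.booster = booster

    def predict_proba(self, X) -> np.ndarray:
        p = self.booster.inplace_predict(np.ascontiguousarray(X, dtype=np.float32))
        return np.column_stack([1 - p, p])


def _save_booster(clf, path) -> None:
    booster = clf.get_booster()
    best = getattr(clf, "best_iteration", None)
    if best is not None:
        booster = booster[: best + 1]
    booster.save_model(path)


def _load_booster(path) -> _BoosterScorer:
    import xgboost as xgb

    booster = xgb.Booster()
    booster.load_model(path)
    return _BoosterScorer(booster)


@dataclass
class ModelBundle:
    """The 6 fitted per-label classifiers (L6 order) plus the binary screen."""

    label_models: dict[str, object]  # label -> fitted classifier or None
    binary_model: object
    depths: dict[str, int]
    binary_depth: int
    config: TrainConfig

    @property
    def trainable_labels(self) -> list[str]:
        return [lab for lab in L6 if self.label_models.get(lab) is not None]

    def label_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 6) matrix of per-label probabilities; untrainable labels score 0."""
        out = np.zeros((len(X), len(L6)))
        for j, lab in enumerate(L6):
            clf = self.label_models.get(lab)
            if clf is not None:
                out[:, j] = clf.predict_proba(X)[:, 1]
        return out

    def binary_scores(self, X: np.ndarray) -> np.ndarray:
        return self.binary_model.predict_proba(X)[:, 1]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "label_order": list(L6),
            "depths": self.depths,
            "binary_depth": self.binary_depth,
            "seed": self.config.seed,
            "trainable": self.trainable_labels,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for j, lab in enumerate(L6):
            clf = self.label_models.get(lab)
            if clf is not None:
                _save_booster(clf, directory / f"label_{j}.json")
        _save_booster(self.binary_model, directory / "binary.json")

    @classmethod
    def load(cls, directory, config: TrainConfig | None = None) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        label_models: dict[str, object] = {}
        for j, lab in enumerate(L6):
            path = directory / f"label_{j}.json"
            label_models[lab] = _load_booster(path) if path.exists() else None
        binary = _load_booster(directory / "binary.json")
        return cls(
            label_models=label_models,
            binary_model=binary,
            depths={k: int(v) for k, v in manifest["depths"].items()},
            binary_depth=int(manifest["binary_depth"]),
            config=config or TrainConfig(),
        )


def train_one_vs_rest(
    features: np.ndarray,
    label_vectors: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    val_features: np.ndarray | None = None,
    val_label_vectors: np.ndarray | None = None,
) -> tuple[dict[str, object], dict[str, int], dict[str, dict[int, float]]]:
    """Train the six per-label one-vs-rest classifiers.

    Per label: the binary target is that label's bit; depth is grid
    searched within the CV folds (SMOTE on fold-train only); the final
    model is refit on all training rows with early stopping on the
    validation split when given.  A label absent from the training data
    is marked untrainable (None) with a warning.
    """
    models: dict[str, object] = {}
    depths: dict[str, int] = {}
    cv_scores: dict[str, dict[int, float]] = {}
    for j, lab in enumerate(L6):
        y = label_vectors[:, j].astype(int)
        if y.sum() < 2 or y.sum() > len(y) - 2:
            warnings.warn(f"label {lab!r} lacks two training samples of each class; skipping")
            models[lab] = None
            depths[lab] = -1
            cv_scores[lab] = {}
            continue
        best, means = _grid_search_depth(features, y, folds, cfg)
        X_bal, y_bal = smote_oversample(features, y, k=cfg.smote_k, seed=cfg.seed + 1000 + j)
        if val_features is not None and len(val_features):
            y_val = val_label_vectors[:, j].astype(int)
            clf = _fit_binary(X_bal, y_bal, val_features, y_val, best, cfg)
        else:
            clf = _make_classifier(best, cfg, use_early_stopping=False)
            clf.fit(X_bal, y_bal, verbose=False)
        models[lab] = clf
        depths[lab] = best
        cv_scores[lab] = means
    return models, depths, cv_scores


def train_binary(
    features_pos: np.ndarray,
    features_neg: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    val_features: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[object, int, dict[int, float]]:
    """Train the active/inactive screen with the same SMOTE/grid protocol.

    ``folds`` index into the stacked [positives; negatives] matrix.
    """
    if len(features_pos) < 2 or len(features_neg) < 2:
        raise ValueError("need at least two samples of each class for the binary screen")
    X = np.vstack([features_pos, features_neg])
    y = np.concatenate([np.ones(len(features_pos)), np.zeros(len(features_neg))]).astype(int)
    best, means = _grid_search_depth(X, y, folds, cfg)
    X_bal, y_bal = smote_oversample(X, y, k=cfg.smote_k, seed=cfg.seed + 2000)
    if val_features is not None and len(val_features):
        clf = _fit_binary(X_bal, y_bal, val_features, val_labels.astype(int), best, cfg)
    else:
        clf = _make_classifier(best, cfg, use_early_stopping=False)
        clf.fit(X_bal, y_bal, verbose=False)
    return clf, best, means


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-label accuracy/F1/precision with a macro ('Total') row.

    The Total row is the unweighted mean over the trainable labels.
    ``aggregate`` combines reports across repeats into mean and
    variance per cell.
    """

    per_label: dict[str, dict[str, float]]  # label -> metric -> value
    binary: dict[str, float] = field(default_factory=dict)

    @property
    def macro(self) -> dict[str, float]:
        labels = [lab for lab in L6 if lab in self.per_label]
        out = {}
        for metric in ("accuracy", "f1", "precision"):
            vals = [self.per_label[lab][metric] for lab in labels]
            out[metric] = float(np.mean(vals)) if vals else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in L6:
            if lab in self.per_label:
                rows.append({"label": lab, **self.per_label[lab]})
        rows.append({"label": "Total", **self.macro})
        if self.binary:
            rows.append({"label": "Binary (active/inactive)", **self.binary})
        return pd.DataFrame(rows).set_index("label")

    def to_tsv(self, path, header_comments: Sequence[str] = ()) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write("label\taccuracy\tf1\tprecision\n")
            for label, row in frame.iterrows():
                fh.write(
                    f"{label}\t{row['accuracy']:.6f}\t{row['f1']:.6f}\t{row['precision']:.6f}\n"
                )

    @staticmethod
    def aggregate(reports: Sequence["MetricsReport"]) -> pd.DataFrame:
        """Mean and variance of every metric cell across repeats."""
        frames = [r.to_frame() for r in reports]
        stacked = pd.concat(frames, keys=range(len(frames)))
        mean = stacked.groupby(level=1, sort=False).mean()
        var = stacked.groupby(level=1, sort=False).var(ddof=0)
        out = mean.copy()
        for col in mean.columns:
            out[f"{col}_var"] = var[col]
        return out


def _safe_precision(y_true, y_pred) -> float:
    if np.sum(y_pred) == 0:
        warnings.warn("no predicted positives; precision reported as 0", stacklevel=2)
        return 0.0
    return float(precision_score(y_true, y_pred, zero_division=0))


def evaluate(
    bundle: ModelBundle,
    test_features: np.ndarray,
    test_label_vectors: np.ndarray,
    binary_test_features: np.ndarray | None = None,
    binary_test_labels: np.ndarray | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Per-label accuracy, F1 and precision at the 0.5 decision threshold."""
    scores = bundle.label_scores(test_features)
    per_label = {}
    for j, lab in enumerate(L6):
        if bundle.label_models.get(lab) is None:
            continue
        y_true = test_label_vectors[:, j].astype(int)
        y_pred = (scores[:, j] >= threshold).astype(int)
        per_label[lab] = {
            "accuracy": float(accuracy_score(y_true, y_pred)),
            "f1": float(f1_score(y_true, y_pred, zero_division=0)),
            "precision": _safe_precision(y_true, y_pred),
        }
    binary = {}
    if binary_test_features is not None and len(binary_test_features):
        b_pred = (bundle.binary_scores(binary_test_features) >= threshold).astype(int)
        b_true = binary_test_labels.astype(int)
        binary = {
            "accuracy": float(accuracy_score(b_true, b_pred)),
            "f1": float(f1_score(b_true, b_pred, zero_division=0)),
            "precision": _safe_precision(b_true, b_pred),
        }
    return MetricsReport(per_label=per_label, binary=binary)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class DrugTargetModel:
    """Two-step drug-target interaction model over pair embeddings.

    Parameters
    ----------
    embeddings : EmbeddingTable
        Node embeddings of the heterogeneous graph (namespaced ids).
    interactions : InteractionTable
        Cleaned labelled pairs (positives with 1-3 labels, negatives).
    config : TrainConfig, optional
        Boosted-tree protocol parameters.
    """

    def __init__(
        self,
        embeddings: EmbeddingTable,
        interactions: InteractionTable,
        config: TrainConfig | None = None,
        cv_k: int = 10,
    ):
        self.embeddings = embeddings
        self.interactions = remove_ambiguous_safe(interactions)
        self.config = config or TrainConfig()
        self.cv_k = cv_k

    @classmethod
    def from_tables(
        cls, embeddings_path, interactions_path, config: TrainConfig | None = None
    ) -> "DrugTargetModel":
        emb = EmbeddingTable.from_tsv(embeddings_path)
        table = ds.remove_ambiguous(ds.load_interactions(interactions_path))
        return cls(emb, table, config=config)

    def fit(self, repeats: int = 1, seed: int | None = None) -> "DrugTargetResults":
        """Run the repeated split/CV/train/evaluate protocol.

        Each repeat re-draws the 80/10/10 split with its own derived
        seed, trains the six one-vs-rest models and the binary screen,
        and evaluates on that repeat's external test split.
        """
        seed = self.config.seed if seed is None else seed
        reports: list[MetricsReport] = []
        bundles: list[ModelBundle] = []
        splits: list[SplitAssignment] = []
        repeat_seeds = ds.derive_seeds(seed, repeats)
        for rep_seed in repeat_seeds:
            report, bundle, split = self._fit_once(rep_seed)
            reports.append(report)
            bundles.append(bundle)
            splits.append(split)
        return DrugTargetResults(self, reports, bundles, splits, seed=seed)

    # -- internals ---------------------------------------------------------

    def _features_labels(self, rows):
        pairs = [r.pair for r in rows]
        X = ds.feature_matrix(self.embeddings, pairs)
        Y = (
            np.stack([ds.one_hot(r.labels) for r in rows])
            if rows
            else np.empty((0, len(L6)), dtype=np.int8)
        )
        return X, Y

    def _fit_once(self, seed: int):
        table = self.interactions
        split = ds.split_dev(table, seed=seed)
        rows = table.rows
        tr_rows = [rows[i] for i in split.train_idx]
        va_rows = [rows[i] for i in split.validation_idx]
        ex_rows = [rows[i] for i in split.external_idx]

        cfg = TrainConfig(**{**self.config.__dict__, "seed": seed})

        # type task: positives only
        tr_pos = [r for r in tr_rows if not r.is_negative]
        va_pos = [r for r in va_rows if not r.is_negative]
        ex_pos = [r for r in ex_rows if not r.is_negative]
        X_tr, Y_tr = self._features_labels(tr_pos)
        X_va, Y_va = self._features_labels(va_pos)
        X_ex, Y_ex = self._features_labels(ex_pos)
        folds = ds.make_cv_folds(len(tr_pos), k=min(self.cv_k, len(tr_pos)), repeats=1, seed=seed)[0]
        label_models, depths, _ = train_one_vs_rest(
            X_tr, Y_tr, folds, cfg, val_features=X_va, val_label_vectors=Y_va
        )

        # binary task: positives vs negatives across the same split
        def stack(rows_):
            pos = [r for r in rows_ if not r.is_negative]
            neg = [r for r in rows_ if r.is_negative]
            Xp, _ = self._features_labels(pos)
            Xn, _ = self._features_labels(neg)
            return Xp, Xn

        Xp_tr, Xn_tr = stack(tr_rows)
        Xp_va, Xn_va = stack(va_rows)
        Xp_ex, Xn_ex = stack(ex_rows)
        n_bin = len(Xp_tr) + len(Xn_tr)
        bin_folds = ds.make_cv_folds(n_bin, k=min(self.cv_k, n_bin), repeats=1, seed=seed + 1)[0]
        X_bin_va = np.vstack([Xp_va, Xn_va]) if len(Xn_va) or len(Xp_va) else np.empty((0, X_tr.shape[1]))
        y_bin_va = np.concatenate([np.ones(len(Xp_va)), np.zeros(len(Xn_va))])
        binary_model, binary_depth, _ = train_binary(
            Xp_tr, Xn_tr, bin_folds, cfg, val_features=X_bin_va, val_labels=y_bin_va
        )

        bundle = ModelBundle(
            label_models=label_models,
            binary_model=binary_model,
            depths=depths,
            binary_depth=binary_depth,
            config=cfg,
        )
        X_bin_ex = np.vstack([Xp_ex, Xn_ex]) if len(Xp_ex) or len(Xn_ex) else np.empty((0, X_tr.shape[1]))
        y_bin_ex = np.concatenate([np.ones(len(Xp_ex)), np.zeros(len(Xn_ex))])
        report = evaluate(
            bundle, X_ex, Y_ex, binary_test_features=X_bin_ex, binary_test_labels=y_bin_ex
        )
        return report, bundle, split


def remove_ambiguous_safe(table: InteractionTable) -> InteractionTable:
    return ds.remove_ambiguous(table)


class DrugTargetResults:
    """Fit results: per-repeat metric reports, fitted bundles, splits."""

    def __init__(self, model, reports, bundles, splits, seed: int):
        self.model = model
        self.reports = reports
        self.bundles = bundles
        self.splits = splits
        self.seed = seed

    @property
    def bundle(self) -> ModelBundle:
        """Bundle of the last repeat (used for downstream prediction)."""
        return self.bundles[-1]

    @property
    def metrics(self) -> pd.DataFrame:
        """Mean (and variance across repeats) of every metric."""
        return MetricsReport.aggregate(self.reports)

    @property
    def macro_precision(self) -> float:
        return float(np.mean([r.macro["precision"] for r in self.reports]))

    @property
    def macro_f1(self) -> float:
        return float(np.mean([r.macro["f1"] for r in self.reports]))

    @property
    def macro_accuracy(self) -> float:
        return float(np.mean([r.macro["accuracy"] for r in self.reports]))

    @property
    def binary_accuracy(self) -> float:
        return float(np.mean([r.binary.get("accuracy", np.nan) for r in self.reports]))

    def predict(self, candidates, threshold: float = 0.95, label_threshold: float = 0.5):
        """Two-step prediction on candidate pairs (delegates to the predict module)."""
        from .predict import two_step_predict

        return two_step_predict(
            self.bundle,
            self.model.embeddings,
            candidates,
            threshold=threshold,
            label_threshold=label_threshold,
        )

    def summary(self) -> str:
        frame = self.metrics
        lines = [
            "Drug-target interaction type model",
            f"  repeats: {len(self.reports)}   seed: {self.seed}",
            f"  labels trained: {len(self.bundle.trainable_labels)} of {len(L6)}",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)
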