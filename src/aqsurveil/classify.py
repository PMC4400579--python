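"""Cascade text classification: relevance first, then firsthand experience.

Both stages are L2-regularized logistic regressions over contiguous word
n-gram features (orders 1–3 by default, binary presence weighting). The
cascade evaluates the firsthand model only on messages the relevance model
accepts, so no message can be labeled firsthand yet irrelevant. Evaluation
is stratified k-fold cross-validation with metrics from pooled out-of-fold
confusion counts (per-fold averages are also reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateLabelsError, InsufficientDataError, InvalidConfigError

logger = logging.getLogger(__name__)

LABELS = ("irrelevant", "relevant", "firsthand")

TokenLists = Sequence[Sequence[str]]


@dataclass(frozen=True)
class FeatureSpec:
    """Word n-gram feature configuration."""

    orders: tuple[int, ...] = (1, 2, 3)
    min_count: int = 1
    binary: bool = True

    def __post_init__(self):
        if not self.orders:
            raise InvalidConfigError("n-gram orders must be non-empty")
        if any(o not in (1, 2, 3) for o in self.orders):
            raise InvalidConfigError(f"orders must be within {{1,2,3}}: {self.orders}")
        if self.min_count < 1:
            raise InvalidConfigError("min_count must be >= 1")


def _ngrams(tokens: Sequence[str], orders: tuple[int, ...]) -> list[str]:
    out = []
    for n in sorted(orders):
        for i in range(len(tokens) - n + 1):
            out.append("␟".join(tokens[i : i + n]))  # ␟ joiner, not a token char
    return out


def make_vectorizer(spec: FeatureSpec) -> CountVectorizer:
    return CountVectorizer(
        analyzer=lambda tokens: _ngrams(tokens, spec.orders),
        min_df=spec.min_count,
        binary=spec.binary,
    )


def featurize(
    docs: TokenLists, spec: FeatureSpec, vectorizer: Optional[CountVectorizer] = None
) -> tuple[sparse.csr_matrix, CountVectorizer]:
    """Document × n-gram matrix; messages shorter than an order get no such
    features (an all-short corpus still yields rows, possibly all-zero)."""
    if vectorizer is None:
        vectorizer = make_vectorizer(spec)
        X = vectorizer.fit_transform(docs)
    else:
        X = vectorizer.transform(docs)
    return X, vectorizer


def train_stage(
    X: sparse.spmatrix, y: np.ndarray, C: float = 1.0, seed: int = 0
) -> LogisticRegression:
    """One penalized logistic stage; requires both classes present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("training data contains a single class")
    clf = LogisticRegression(
        C=C, solver="liblinear", random_state=seed, max_iter=1000
    )
    clf.fit(X, y)
    return clf


class CascadeClassifier(BaseEstimator, ClassifierMixin):
    """Two-stage relevance → firsthand classifier.

    Parameters
    ----------
    orders : tuple of int
        n-gram orders (⊆ {1, 2, 3}).
    min_count : int
        Frequency floor for the n-gram vocabulary.
    binary : bool
        Presence/absence weighting rather than counts.
    C : float
        Inverse L2 regularization strength of both stages.
    random_state : int
        Seed for the solvers.

    Attributes
    ----------
    spec_ : FeatureSpec
    vec_rel_, clf_rel_ : stage-1 vectorizer and model (relevance, all data)
    vec_fh_, clf_fh_ : stage-2 vectorizer and model (firsthand, trained only
        on the relevance-positive labeled subset)
    """

    def __init__(
        self,
        orders: tuple[int, ...] = (1, 2, 3),
        min_count: int = 1,
        binary: bool = True,
        C: float = 1.0,
        random_state: int = 0,
    ):
        self.orders = orders
        self.min_count = min_count
        self.binary = binary
        self.C = C
        self.random_state = random_state

    def fit(self, X: TokenLists, y) -> "CascadeClassifier":
        """Fit both stages.

        ``y`` is an (n, 2) array-like: column 0 the relevance label (0/1),
        column 1 the firsthand label (0/1, ignored where relevance is 0).
        """
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise InvalidConfigError("y must have two columns: relevant, firsthand")
        docs = [list(d) for d in X]
        self.spec_ = FeatureSpec(tuple(self.orders), self.min_count, self.binary)

        Xr, self.vec_rel_ = featurize(docs, self.spec_)
        self.clf_rel_ = train_stage(
            Xr, y[:, 0].astype(int), C=self.C, seed=self.random_state
        )

        rel_mask = y[:, 0].astype(int) == 1
        fh_docs = [d for d, keep in zip(docs, rel_mask) if keep]
        fh_y = y[rel_mask, 1].astype(int)
        Xf, self.vec_fh_ = featurize(fh_docs, self.spec_)
        self.clf_fh_ = train_stage(Xf, fh_y, C=self.C, seed=self.random_state)
        return self

    def predict(self, X: TokenLists) -> np.ndarray:
        """Labels in {irrelevant, relevant, firsthand}; stage 2 is evaluated
        only where stage 1 predicts positive."""
        docs = [list(d) for d in X]
        out = np.array(["irrelevant"] * len(docs), dtype=object)
        if not docs:
            return out
        Xr, _ = featurize(docs, self.spec_, self.vec_rel_)
        rel = self.clf_rel_.predict(Xr).astype(bool)
        if rel.any():
            rel_docs = [d for d, keep in zip(docs, rel) if keep]
            Xf, _ = featurize(rel_docs, self.spec_, self.vec_fh_)
            fh = self.clf_fh_.predict(Xf).astype(bool)
            labels = np.where(fh, "firsthand", "relevant")
            out[np.flatnonzero(rel)] = labels
        return out


def cascade_predict(model: CascadeClassifier, docs: TokenLists) -> np.ndarray:
    return model.predict(docs)


@dataclass
class EvalReport:
    """Cross-validation report for one binary stage."""

    k: int
    n: int
    n_positive: int
    fold_assignment: np.ndarray
    confusion: np.ndarray  # pooled 2×2: rows truth (pos, neg), cols predicted
    fold_metrics: list[dict] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def precision(self) -> float:
        pred_pos = self.confusion[:, 0].sum()
        return float(self.confusion[0, 0] / pred_pos) if pred_pos else float("nan")

    @property
    def recall(self) -> float:
        actual_pos = self.confusion[0, :].sum()
        return float(self.confusion[0, 0] / actual_pos) if actual_pos else float("nan")

    @property
    def fold_averaged(self) -> dict:
        keys = ("accuracy", "precision", "recall")
        return {
            k: float(np.nanmean([m[k] for m in self.fold_metrics])) for k in keys
        }


def cross_validate(
    docs: TokenLists,
    labels,
    spec: FeatureSpec = FeatureSpec(),
    k: int = 10,
    seed: int = 0,
    C: float = 1.0,
    max_redraws: int = 20,
) -> EvalReport:
    """Stratified k-fold CV of one logistic stage over n-gram features.

    The vectorizer is refit on each training split. Folds are redrawn (with
    a logged warning and an advanced seed) in the unlikely event a training
    split is single-class. Metrics come from pooled out-of-fold confusion
    counts; per-fold metrics are kept alongside.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < k:
        raise InsufficientDataError(f"n={n} < k={k}")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("labels contain a single class")
    docs = [list(d) for d in docs]

    for attempt in range(max_redraws):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(n), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            if attempt:
                logger.warning("folds redrawn %d time(s) for class coverage", attempt)
            break
    else:
        raise DegenerateLabelsError("could not draw folds with both classes")

    assignment = np.empty(n, dtype=int)
    confusion = np.zeros((2, 2), dtype=np.int64)
    fold_metrics = []
    for fold_idx, (train, test) in enumerate(folds):
        assignment[test] = fold_idx
        Xtr, vec = featurize([docs[i] for i in train], spec)
        clf = train_stage(Xtr, y[train], C=C, seed=seed)
        Xte, _ = featurize([docs[i] for i in test], spec, vec)
        pred = clf.predict(Xte)
        cm = np.zeros((2, 2), dtype=np.int64)
        for truth, p in zip(y[test], pred):
            cm[0 if truth == 1 else 1, 0 if p == 1 else 1] += 1
        confusion += cm
        pred_pos = cm[:, 0].sum()
        act_pos = cm[0, :].sum()
        fold_metrics.append(
            {
                "accuracy": float(np.trace(cm) / cm.sum()),
                "precision": float(cm[0, 0] / pred_pos) if pred_pos else np.nan,
                "recall": float(cm[0, 0] / act_pos) if act_pos else np.nan,
            }
        )

    return EvalReport(
        k=k,
        n=n,
        n_positive=int(y.sum()),
        fold_assignment=assignment,
        confusion=confusion,
        fold_metrics=fold_metrics,
    )
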