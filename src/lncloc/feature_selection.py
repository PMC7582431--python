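"""Feature selection and learning: binomial/IFS, autoencoders, RFE, scaling.

The raw 8-mer block is filtered by a binomial-distribution confidence
ranking.  With q_j = m_j / M the prior share of class j in the total 8-mer
mass, an 8-mer i seen N_i times overall and n_ij times in class j has upper
tail probability

    p(n_ij) = P(X >= n_ij),  X ~ Binomial(N_i, q_j),

confidence C_ij = 1 - p(n_ij), and aggregated confidence
C_i = max_j C_ij.  Small p (high C) means the 8-mer is concentrated in one
class far beyond its prior share.  Iterative feature selection (IFS) then
adds features in descending-confidence order until cross-validated accuracy
stops improving.

The remaining (biological/spectral/structural) block is standardized,
re-encoded by two symmetric autoencoders with 32- and 64-unit bottlenecks
(concatenated to 96 dimensions), and reduced to 32 features by recursive
feature elimination under a gradient-boosted-tree ranker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import binom
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import NotFittedError


@dataclass
class BinomialRanking:
    """Per-feature binomial confidences and the induced ordering.

    ``order`` sorts features by ascending minimum tail probability (i.e.
    descending confidence), ties broken by feature index, so the ranking is
    stable even when many confidences round to 1.0 in double precision.
    """

    q: np.ndarray                 # class priors, sum to 1
    confidence: np.ndarray        # C_i = max_j C_ij
    per_class: np.ndarray         # C_ij, features x classes
    pvalue: np.ndarray            # min_j p(n_ij)
    order: np.ndarray             # permutation of feature indices


def binomial_confidence(counts) -> BinomialRanking:
    """Rank features by binomial tail confidence from a feature x class count matrix."""
    c = np.asarray(
        counts.toarray() if sparse.issparse(counts) else counts, dtype=float
    )
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValueError("need a 2-D count matrix with at least 2 classes")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    m_j = c.sum(axis=0)
    if np.any(m_j == 0):
        bad = np.nonzero(m_j == 0)[0]
        raise ValueError(f"class column(s) {bad.tolist()} have zero total counts")
    big_m = m_j.sum()
    q = m_j / big_m
    n_i = c.sum(axis=1, keepdims=True)
    # Upper tail P(X >= n_ij) = sf(n_ij - 1); zero-count cells give p = 1.
    p = binom.sf(c - 1, n_i, q[None, :])
    p[np.broadcast_to(n_i == 0, p.shape)] = 1.0
    conf = 1.0 - p
    pmin = p.min(axis=1)
    order = np.lexsort((np.arange(pmin.size), pmin))
    return BinomialRanking(q, conf.max(axis=1), conf, pmin, order)


@dataclass
class SelectionResult:
    """IFS outcome: selected prefix, accuracy trace, stopping step."""

    selected: np.ndarray
    trace: list[float]
    stopping_step: int
    best_step: int


def default_ifs_evaluator(cv_folds: int = 5, seed: int = 0) -> Callable:
    """Stratified-CV mean accuracy of a linear-kernel SVM."""

    def evaluate(x: np.ndarray, y: np.ndarray) -> float:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        return float(cross_val_score(SVC(kernel="linear", C=1.0), x, y, cv=cv).mean())

    return evaluate


def ifs_select(
    ranking: BinomialRanking,
    x,
    y: np.ndarray,
    evaluator: Callable | None = None,
    batch_size: int = 50,
    patience: int = 3,
    cv_folds: int = 5,
    seed: int = 0,
    max_features: int | None = None,
) -> SelectionResult:
    """Incremental feature selection along the confidence ordering.

    Features are added ``batch_size`` at a time in descending-confidence
    order; each prefix is scored by the evaluator (default: stratified-CV
    linear SVM accuracy).  Selection stops once the score has failed to
    improve for max(1, patience) consecutive steps and returns the
    best-scoring prefix (smallest on ties).
    """
    if evaluator is None:
        evaluator = default_ifs_evaluator(cv_folds, seed)
    order = ranking.order
    limit = order.size if max_features is None else min(max_features, order.size)
    trace: list[float] = []
    best_score, best_upto = -np.inf, 0
    no_improve = 0
    threshold = max(1, patience)
    step = 0
    upto = 0
    while upto < limit:
        step += 1
        upto = min(step * batch_size, limit)
        sub = x[:, order[:upto]]
        if sparse.issparse(sub):
            sub = sub.toarray()
        try:
            score = float(evaluator(sub, y))
        except Exception as exc:
            raise RuntimeError(f"IFS evaluator failed at step {step}") from exc
        trace.append(score)
        if score > best_score:
            best_score, best_upto = score, upto
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= threshold:
                break
    return SelectionResult(order[:best_upto].copy(), trace, len(trace), int(np.ceil(best_upto / batch_size)))


def _relu_forward(mlp: MLPRegressor, x: np.ndarray, n_layers: int) -> np.ndarray:
    h = np.asarray(x, dtype=float)
    for i in range(n_layers):
        h = h @ mlp.coefs_[i] + mlp.intercepts_[i]
        np.maximum(h, 0.0, out=h)
    return h


@dataclass
class EncoderPair:
    """Two symmetric autoencoders with 32- and 64-unit bottlenecks.

    The 32-encoder is 70->64->32->64->70 and the 64-encoder 70->64->64->70;
    bottleneck activations are read off by a manual forward pass through the
    encoding layers.  ``encode`` concatenates both codes into 96 features.
    """

    mlp32: MLPRegressor
    mlp64: MLPRegressor
    seed: int

    def encode32(self, x: np.ndarray) -> np.ndarray:
        return _relu_forward(self.mlp32, x, 2)

    def encode64(self, x: np.ndarray) -> np.ndarray:
        return _relu_forward(self.mlp64, x, 2)

    def encode(self, x: np.ndarray) -> np.ndarray:
        return np.hstack([self.encode32(x), self.encode64(x)])

    @property
    def loss_curves(self) -> tuple[list[float], list[float]]:
        return self.mlp32.loss_curve_, self.mlp64.loss_curve_


def train_autoencoders(
    x: np.ndarray, seed: int = 0, max_iter: int = 500
) -> EncoderPair:
    """Fit the two reconstruction autoencoders on standardized features.

    ReLU hidden units, linear output, Adam with a fixed seed, mean-squared
    reconstruction loss with plateau-based early stopping; the two encoders
    are trained independently.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("autoencoder input contains non-finite values")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples to train the autoencoders")
    common = dict(
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        tol=1e-6,
        n_iter_no_change=25,
        early_stopping=False,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        mlp32 = MLPRegressor(
            hidden_layer_sizes=(64, 32, 64), random_state=seed, **common
        ).fit(x, x)
        mlp64 = MLPRegressor(
            hidden_layer_sizes=(64, 64), random_state=seed + 1, **common
        ).fit(x, x)
    return EncoderPair(mlp32, mlp64, seed)


def rfe_select(
    z: np.ndarray,
    y: np.ndarray,
    n_keep: int = 32,
    learning_rate: float = 0.1,
    n_estimators: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, list[int]]:
    """Recursive feature elimination under a gradient-boosted-tree ranker.

    One feature (the lowest-importance one) is removed per round until
    ``n_keep`` remain.  Returns the kept indices (ascending) and the full
    elimination order — dropped features first, then the survivors from
    least to most important under the final fit.
    """
    z = np.asarray(z, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("RFE needs at least 2 classes")
    if n_keep >= z.shape[1]:
        raise ValueError("n_keep must be smaller than the feature count")
    y_enc = LabelEncoder().fit_transform(y)

    def _fit_importances(cols: list[int]) -> np.ndarray:
        clf = XGBClassifier(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        clf.fit(z[:, cols], y_enc)
        return clf.feature_importances_

    remaining = list(range(z.shape[1]))
    elimination: list[int] = []
    while len(remaining) > n_keep:
        imp = _fit_importances(remaining)
        drop = int(np.argmin(imp))  # ties: smallest index
        elimination.append(remaining.pop(drop))
    final_imp = _fit_importances(remaining)
    elimination.extend(np.array(remaining)[np.argsort(final_imp, kind="stable")].tolist())
    return np.array(sorted(remaining)), elimination


class FeatureScaler:
    """Per-feature standardization with training-time statistics.

    Zero-variance features map to 0.  Applying before fitting is an error;
    held-out rows are always scaled with the stored training statistics.
    """

    def __init__(self) -> None:
        self._scaler: StandardScaler | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        self._scaler = StandardScaler().fit(np.asarray(x, dtype=float))
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            raise NotFittedError("scaler used before fitting")
        return self._scaler.transform(np.asarray(x, dtype=float))

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
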