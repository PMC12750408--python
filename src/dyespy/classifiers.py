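"""Model zoo: pathway classifiers, the multi-label network, and CSNNC.

Phase I (oxidative vs nonoxidative) offers six interchangeable binary
classifiers, each an sklearn-style estimator built with its tuned
hyperparameters:

=======  =====================================================  ============
kind     realization                                            key params
=======  =====================================================  ============
LRDA     logistic regression                                    C=100, L2,
                                                                max_iter=500
PLSDA    PLS2 regression on one-hot targets, argmax decision    17 latent
                                                                variables
RFDA     random forest                                          depth 5,
                                                                min split 10,
                                                                100 trees
XGBDA    gradient-boosted trees (xgboost)                       eta 0.05,
                                                                depth 1,
                                                                500 rounds
ANNDA    feed-forward network, sigmoid output                   per config
CSNNC    cosine-similarity nearest neighbor                     none
=======  =====================================================  ============

Phase II mixture identification uses a multi-label feed-forward network
(per-colorant sigmoid outputs, strict > 0.5 decision threshold).  The
network is a compact NumPy implementation: ReLU hidden layers, inverted
dropout, RMSprop or SGD updates, optional L1/L2 penalties, fixed epoch
budget, fully deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import LabelBinarizer

from .exceptions import DataError, TrainingError, UsageError
from .library import MixtureLabel

#: Multi-label decision threshold: a colorant is called iff score > 0.5.
MULTILABEL_THRESHOLD = 0.5


@dataclass
class DecisionConfig:
    multilabel_threshold: float = MULTILABEL_THRESHOLD

    def __post_init__(self):
        if not 0.0 < self.multilabel_threshold < 1.0:
            raise UsageError("multilabel_threshold must be in (0, 1)")


@dataclass
class ANNConfig:
    """Feed-forward network hyperparameters."""

    layers: tuple[int, ...] = (512, 256)
    dropout: float = 0.3
    optimizer: str = "rmsprop"
    eta: float = 0.0005
    batch_size: int = 16
    l2: float = 0.001
    l1: float = 0.000001
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if any(w <= 0 for w in self.layers):
            raise UsageError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise UsageError("dropout must be in [0, 1)")
        if self.eta <= 0:
            raise UsageError("eta must be positive")
        if self.optimizer not in ("rmsprop", "sgd"):
            raise UsageError("optimizer must be 'rmsprop' or 'sgd'")


#: Network configuration used for the nonoxidative mixture model.
NONOX_ANN_CONFIG = ANNConfig(
    layers=(512, 256), dropout=0.3, optimizer="rmsprop",
    eta=0.0005, batch_size=16, l2=0.001, l1=0.000001,
)

#: Network configuration used for the oxidative mixture model.
OX_ANN_CONFIG = ANNConfig(
    layers=(1024, 512), dropout=0.0, optimizer="rmsprop",
    eta=0.001, batch_size=32, l1=0.0, l2=0.0,
)

#: Phase I ANNDA configuration.
ANNDA_CONFIG = ANNConfig(
    layers=(512, 256), dropout=0.0, optimizer="sgd",
    eta=0.01, batch_size=32, l1=0.0, l2=0.0,
)


class _FeedForwardNet:
    """Minimal dense network with sigmoid outputs (binary cross-entropy)."""

    def __init__(self, n_in: int, n_out: int, cfg: ANNConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [n_in, *cfg.layers, n_out]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._rng = rng
        self._cache_W = [np.zeros_like(w) for w in self.W]
        self._cache_b = [np.zeros_like(b) for b in self.b]
        self.loss_curve_: list[float] = []

    # -- forward / backward ------------------------------------------------
    def _forward(self, X, train: bool):
        acts = [X]
        masks = []
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < last:
                a = np.maximum(z, 0.0)
                if train and self.cfg.dropout > 0.0:
                    keep = 1.0 - self.cfg.dropout
                    m = (self._rng.random(a.shape) < keep) / keep
                    a = a * m
                    masks.append(m)
                else:
                    masks.append(None)
            else:
                a = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            acts.append(a)
        return acts, masks

    def _step(self, X, Y):
        cfg = self.cfg
        acts, masks = self._forward(X, train=True)
        out = acts[-1]
        n = X.shape[0]
        delta = (out - Y) / n  # d(BCE)/dz for sigmoid output
        for i in reversed(range(len(self.W))):
            gW = acts[i].T @ delta + cfg.l2 * self.W[i] + cfg.l1 * np.sign(self.W[i])
            gb = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * (acts[i] > 0.0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
            if cfg.optimizer == "rmsprop":
                self._cache_W[i] = 0.9 * self._cache_W[i] + 0.1 * gW**2
                self._cache_b[i] = 0.9 * self._cache_b[i] + 0.1 * gb**2
                self.W[i] -= cfg.eta * gW / (np.sqrt(self._cache_W[i]) + 1e-8)
                self.b[i] -= cfg.eta * gb / (np.sqrt(self._cache_b[i]) + 1e-8)
            else:
                self.W[i] -= cfg.eta * gW
                self.b[i] -= cfg.eta * gb
        eps = 1e-12
        return float(
            -np.mean(Y * np.log(out + eps) + (1 - Y) * np.log(1 - out + eps))
        )

    def fit(self, X, Y):
        cfg = self.cfg
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                losses.append(self._step(X[idx], Y[idx]))
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def predict_scores(self, X):
        acts, _ = self._forward(np.asarray(X, dtype=float), train=False)
        return acts[-1]


# ---------------------------------------------------------------------------
# Phase I estimators
# ---------------------------------------------------------------------------

def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise DataError("X must be 2-D (n_spectra, n_features)")
    if y.shape[0] != X.shape[0]:
        raise DataError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise TrainingError("training data must contain both classes")
    return X, y


class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS discriminant analysis: PLS2 on one-hot targets, argmax decision.

    The latent-variable count is capped at min(n_features, n_samples - 1)
    with a warning when the requested number exceeds what the data support.
    """

    def __init__(self, n_components: int = 17):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        self._binarizer = LabelBinarizer()
        Y = self._binarizer.fit_transform(y)
        if Y.shape[1] == 1:  # binary: expand to two columns
            Y = np.hstack([1 - Y, Y])
        cap = min(self.n_components, X.shape[1], X.shape[0] - 1)
        if cap < self.n_components:
            warnings.warn(
                f"n_components capped from {self.n_components} to {cap}",
                stacklevel=2,
            )
        self.n_components_ = cap
        self._pls = PLSRegression(n_components=cap, scale=False)
        self._pls.fit(X, Y)
        self.classes_ = self._binarizer.classes_
        return self

    def decision_scores(self, X):
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X):
        s = self.decision_scores(X)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


class CosineNearestNeighborClassifier(ClassifierMixin, BaseEstimator):
    """CSNNC: label of the training spectrum with highest cosine similarity.

    Scale-invariant by construction; exact similarity ties resolve to the
    earliest-indexed reference (logged via ``warnings``).
    """

    def __init__(self, require_multiclass: bool = False):
        self.require_multiclass = require_multiclass

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0:
            raise DataError("X must be a non-empty 2-D matrix")
        if y.shape[0] != X.shape[0]:
            raise DataError("X and y length mismatch")
        if self.require_multiclass and len(np.unique(y)) < 2:
            raise TrainingError("training data must contain both classes")
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0.0):
            raise DataError("zero-vector reference: similarity undefined")
        self._refs = X / norms[:, None]
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def similarity_matrix(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0.0):
            raise DataError("zero-vector query: similarity undefined")
        return (X / norms[:, None]) @ self._refs.T

    def classify(self, x):
        """(label, best cosine similarity) for a single spectrum."""
        sims = self.similarity_matrix(np.atleast_2d(x))[0]
        best = int(np.argmax(sims))
        ties = np.flatnonzero(sims == sims[best])
        if ties.size > 1 and len(set(self.y_[ties])) > 1:
            warnings.warn(
                "cosine-similarity tie across labels; keeping earliest reference",
                stacklevel=2,
            )
        return self.y_[best], float(sims[best])

    def predict(self, X):
        sims = self.similarity_matrix(X)
        return self.y_[np.argmax(sims, axis=1)]


class NeuralNetworkClassifier(ClassifierMixin, BaseEstimator):
    """Binary/multiclass wrapper over the NumPy feed-forward network."""

    def __init__(self, config: ANNConfig | None = None, random_state: int = 0):
        self.config = config
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        cfg = self.config or ANNDA_CONFIG
        cfg = ANNConfig(**{**cfg.__dict__, "seed": self.random_state})
        self._binarizer = LabelBinarizer()
        Y = self._binarizer.fit_transform(y)
        if Y.shape[1] == 1:
            Y = np.hstack([1 - Y, Y])
        self.net_ = _FeedForwardNet(X.shape[1], Y.shape[1], cfg).fit(X, Y)
        self.classes_ = self._binarizer.classes_
        self.loss_curve_ = self.net_.loss_curve_
        return self

    def predict_proba(self, X):
        s = self.net_.predict_scores(X)
        total = s.sum(axis=1, keepdims=True)
        total[total == 0.0] = 1.0
        return s / total

    def predict(self, X):
        return self.classes_[np.argmax(self.net_.predict_scores(X), axis=1)]


def make_phase1_model(kind: str, seed: int = 0):
    """Factory for the six Phase I model kinds with tuned hyperparameters."""
    kind = kind.upper()
    if kind == "LRDA":
        # sklearn's default penalty is already the L2 the tuning calls for
        return LogisticRegression(C=100.0, max_iter=500)
    if kind == "PLSDA":
        return PLSDAClassifier(n_components=17)
    if kind == "RFDA":
        return _ValidatedForest(
            max_depth=5, min_samples_split=10, n_estimators=100, random_state=seed
        )
    if kind == "XGBDA":
        from xgboost import XGBClassifier

        return _LabelEncodedXGB(
            learning_rate=0.05, max_depth=1, n_estimators=500, random_state=seed
        )
    if kind == "ANNDA":
        return NeuralNetworkClassifier(config=ANNDA_CONFIG, random_state=seed)
    if kind == "CSNNC":
        return CosineNearestNeighborClassifier(require_multiclass=True)
    raise UsageError(f"unknown Phase I model kind {kind!r}")


class _ValidatedForest(RandomForestClassifier):
    """Random forest that refuses single-class training data."""

    def fit(self, X, y, **kwargs):
        _check_Xy(X, y)
        return super().fit(X, y, **kwargs)


class _LabelEncodedXGB(ClassifierMixin, BaseEstimator):
    """xgboost with string-label handling to match the other estimators."""

    def __init__(self, learning_rate=0.05, max_depth=1, n_estimators=500,
                 random_state=0):
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        from xgboost import XGBClassifier

        X, y = _check_Xy(X, y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        self._clf = XGBClassifier(
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            n_jobs=1,
            verbosity=0,
        )
        self._clf.fit(X, codes)
        return self

    def predict(self, X):
        return self.classes_[self._clf.predict(np.asarray(X, dtype=float))]

    def predict_proba(self, X):
        return self._clf.predict_proba(np.asarray(X, dtype=float))


def train_phase1(X, y, kind: str = "PLSDA", seed: int = 0):
    """Fit one Phase I pathway classifier on a (n, 1201) matrix."""
    model = make_phase1_model(kind, seed)
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


# ---------------------------------------------------------------------------
# multi-label mixture model
# ---------------------------------------------------------------------------

class MultilabelANN(ClassifierMixin, BaseEstimator):
    """Multi-label colorant model: per-colorant sigmoid outputs.

    ``fit`` takes an indicator matrix over a colorant vocabulary; a colorant
    is predicted present iff its score strictly exceeds the 0.5 threshold
    (an all-below-threshold row is a legitimate 'No Match').
    """

    def __init__(
        self,
        vocabulary=None,
        config: ANNConfig | None = None,
        random_state: int = 0,
        threshold: float = MULTILABEL_THRESHOLD,
    ):
        self.vocabulary = vocabulary
        self.config = config
        self.random_state = random_state
        self.threshold = threshold

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise TrainingError("X (n, d) and indicator Y (n, k) must align")
        if np.unique(Y, axis=0).shape[0] < 2:
            raise TrainingError("need >= 2 distinct label vectors")
        dead = np.flatnonzero(Y.sum(axis=0) == 0)
        if dead.size:
            names = (
                [self.vocabulary[j] for j in dead] if self.vocabulary else list(dead)
            )
            warnings.warn(
                f"colorants never positive in training: {names}; "
                "they can never be predicted",
                stacklevel=2,
            )
        cfg = self.config or NONOX_ANN_CONFIG
        cfg = ANNConfig(**{**cfg.__dict__, "seed": self.random_state})
        self.vocabulary_ = (
            list(self.vocabulary)
            if self.vocabulary is not None
            else [str(j) for j in range(Y.shape[1])]
        )
        if len(self.vocabulary_) != Y.shape[1]:
            raise TrainingError("vocabulary length must match Y columns")
        self.net_ = _FeedForwardNet(X.shape[1], Y.shape[1], cfg).fit(X, Y)
        self.loss_curve_ = self.net_.loss_curve_
        return self

    def predict_scores(self, X):
        return self.net_.predict_scores(np.atleast_2d(np.asarray(X, dtype=float)))

    def predict(self, X):
        return (self.predict_scores(X) > self.threshold).astype(int)

    def predict_mixtures(self, X) -> list[MixtureLabel]:
        out = []
        for row in self.predict_scores(X):
            codes = [
                self.vocabulary_[j]
                for j in np.flatnonzero(row > self.threshold)
            ]
            out.append(MixtureLabel.of(*codes))
        return out


def predict_multilabel(
    model: MultilabelANN, x, cfg: DecisionConfig | None = None
) -> MixtureLabel:
    """Mixture call for one spectrum under the strict > threshold rule."""
    threshold = (cfg or DecisionConfig()).multilabel_threshold
    scores = model.predict_scores(np.atleast_2d(x))[0]
    codes = [model.vocabulary_[j] for j in np.flatnonzero(scores > threshold)]
    return MixtureLabel.of(*codes)


def csnnc_classify(query, references_X, reference_labels):
    """(label, best cosine similarity) of a query against references."""
    clf = CosineNearestNeighborClassifier().fit(
        np.asarray(references_X, dtype=float), np.asarray(reference_labels)
    )
    return clf.classify(query)
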