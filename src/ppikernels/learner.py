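"""Gram-matrix computation and max-margin learning with precomputed kernels.

The kernel function is handed to the SVM as a precomputed Gram matrix of
pairwise instance similarities.  Convolution-kernel sums vary over orders of
magnitude with sentence length, so Gram normalization
K'(x,y) = K(x,y)/sqrt(K(x,x) K(y,y)) is on by default.  Some of the
similarities here (tolerant matching, exponentiated edit distance) are not
provably positive semidefinite; instead of failing or clipping eigenvalues,
training adds a small logged ridge to the Gram diagonal and the minimum
eigenvalue is recorded as a diagnostic.

Classification is by the sign of the SVM decision value (exactly 0 counts as
negative); decision values themselves are kept so that threshold-free
ranking metrics (AUC) can be computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .kernels import PairwiseKernel, make_kernel
from .model import CandidateInstance

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


class DegenerateTrainingError(ValueError):
    """Raised when a training set contains a single class only."""


@dataclass
class GramMatrix:
    values: np.ndarray
    ids: list[str]
    kernel_name: str
    kernel_params: dict
    normalized: bool

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("Gram matrix must be square")
        if len(self.ids) != values.shape[0]:
            raise ValueError("instance ids must align with Gram rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("instance ids must be unique")
        if values.size and np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
            raise ValueError("Gram matrix must be symmetric")
        self.values = values

    @property
    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue; diagnostic for indefinite similarities."""
        if not self.values.size:
            return 0.0
        return float(np.linalg.eigvalsh(self.values)[0])


def normalize_gram(values: np.ndarray) -> np.ndarray:
    """Unit-diagonal normalization; rows/columns with zero self-similarity
    (e.g. disconnected instances) are left at 0."""
    diagonal = np.diag(values).copy()
    scale = np.sqrt(np.outer(diagonal, diagonal))
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(scale > 0, values / np.where(scale > 0, scale, 1.0), 0.0)
    return normalized


def compute_gram(
    instances: Sequence[CandidateInstance],
    kernel: PairwiseKernel | str,
    normalize: bool = True,
) -> GramMatrix:
    """Pairwise kernel matrix, computed once per unordered instance pair."""
    kernel = make_kernel(kernel)
    reps = [kernel.prepare(instance) for instance in instances]
    n = len(instances)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            value = kernel.similarity(reps[i], reps[j])
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite kernel value for instance pair "
                    f"({instances[i].id}, {instances[j].id})"
                )
            values[i, j] = values[j, i] = value
    if normalize:
        values = normalize_gram(values)
    return GramMatrix(
        values=values,
        ids=[instance.id for instance in instances],
        kernel_name=kernel.name,
        kernel_params=kernel.get_params(),
        normalized=normalize,
    )


def cross_gram(
    test_instances: Sequence[CandidateInstance],
    train_instances: Sequence[CandidateInstance],
    kernel: PairwiseKernel | str,
    normalize: bool = True,
) -> np.ndarray:
    """Kernel rows of test instances against training instances."""
    kernel = make_kernel(kernel)
    train_reps = [kernel.prepare(instance) for instance in train_instances]
    test_reps = [kernel.prepare(instance) for instance in test_instances]
    rows = np.zeros((len(test_reps), len(train_reps)))
    for i, rx in enumerate(test_reps):
        for j, ry in enumerate(train_reps):
            rows[i, j] = kernel.similarity(rx, ry)
    if normalize:
        train_self = np.array([kernel.similarity(r, r) for r in train_reps])
        test_self = np.array([kernel.similarity(r, r) for r in test_reps])
        scale = np.sqrt(np.outer(test_self, train_self))
        with np.errstate(divide="ignore", invalid="ignore"):
            rows = np.where(scale > 0, rows / np.where(scale > 0, scale, 1.0), 0.0)
    return rows


@dataclass
class LearnerConfig:
    """Max-margin learner settings.

    ``positive_class_weight`` defaults to the negative/positive ratio of the
    training fold, counteracting the heavy class skew of PPI corpora;
    ``epsilon`` is the diagonal ridge added to (possibly indefinite) Grams,
    defaulting to 1e-8 * trace / n.
    """

    C: float = 1.0
    positive_class_weight: Optional[float] = None
    epsilon: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.C) or self.C <= 0:
            raise ValueError("regularization C must be finite and positive")


@dataclass
class TrainedModel:
    svc: SVC
    train_ids: list[str]
    config: LearnerConfig
    ridge: float
    min_eigenvalue: float

    def to_json(self) -> str:
        payload = {
            "train_ids": self.train_ids,
            "support_ids": [self.train_ids[i] for i in self.svc.support_],
            "dual_coef": self.svc.dual_coef_.ravel().tolist(),
            "bias": float(self.svc.intercept_[0]),
            "config": {
                "C": self.config.C,
                "positive_class_weight": self.config.positive_class_weight,
                "epsilon": self.config.epsilon,
            },
            "ridge": self.ridge,
            "min_eigenvalue": self.min_eigenvalue,
        }
        return json.dumps(payload, indent=2)


def train(
    gram: GramMatrix | np.ndarray,
    labels: Sequence[bool],
    config: LearnerConfig | None = None,
    ids: Optional[list[str]] = None,
) -> TrainedModel:
    """Fit a max-margin classifier on a precomputed Gram matrix."""
    config = config or LearnerConfig()
    if isinstance(gram, GramMatrix):
        values, ids = gram.values, gram.ids
    else:
        values = np.asarray(gram, dtype=float)
        ids = ids if ids is not None else [str(i) for i in range(len(values))]
    y = np.asarray(labels, dtype=int)
    if len(y) != len(values):
        raise ValueError("Gram size and label count differ")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingError("degenerate training set: single class")

    pos_weight = config.positive_class_weight
    if pos_weight is None:
        pos_weight = n_neg / n_pos
    epsilon = config.epsilon
    if epsilon is None:
        epsilon = 1e-8 * np.trace(values) / len(values)
    if epsilon:
        logger.debug("adding diagonal ridge %.3g to training Gram", epsilon)
    train_values = values + epsilon * np.eye(len(values))

    min_eig = float(np.linalg.eigvalsh(values)[0]) if len(values) else 0.0
    svc = SVC(kernel="precomputed", C=config.C, class_weight={1: pos_weight})
    svc.fit(train_values, y)
    return TrainedModel(
        svc=svc,
        train_ids=list(ids),
        config=config,
        ridge=float(epsilon),
        min_eigenvalue=min_eig,
    )


def predict(
    model: TrainedModel, gram_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values for kernel rows against the training set.

    A positive label is assigned iff the decision value is strictly positive.
    """
    gram_rows = np.asarray(gram_rows, dtype=float)
    if gram_rows.ndim != 2 or gram_rows.shape[1] != len(model.train_ids):
        raise ValueError(
            f"kernel rows must have {len(model.train_ids)} columns aligned "
            "with the model's training instances"
        )
    scores = model.svc.decision_function(gram_rows)
    return scores > 0, scores


class PPIClassifier(BaseEstimator, ClassifierMixin):
    """Kernel SVM over candidate instances, scikit-learn estimator style.

    ``fit`` takes a sequence of :class:`CandidateInstance` and boolean
    labels, computes the (optionally normalized) Gram matrix of the
    configured kernel, and trains a precomputed-kernel SVM;
    ``decision_function`` and ``predict`` evaluate kernel rows of new
    instances against the stored training instances.
    """

    def __init__(
        self,
        kernel: PairwiseKernel | str = "kbsps",
        C: float = 1.0,
        positive_class_weight: Optional[float] = None,
        normalize: bool = True,
        epsilon: Optional[float] = None,
    ):
        self.kernel = kernel
        self.C = C
        self.positive_class_weight = positive_class_weight
        self.normalize = normalize
        self.epsilon = epsilon

    def fit(self, X: Sequence[CandidateInstance], y):
        kernel = make_kernel(self.kernel)
        gram = compute_gram(X, kernel, normalize=self.normalize)
        config = LearnerConfig(
            C=self.C,
            positive_class_weight=self.positive_class_weight,
            epsilon=self.epsilon,
        )
        self.kernel_ = kernel
        self.train_instances_ = list(X)
        self.gram_ = gram
        self.model_ = train(gram, y, config)
        self.classes_ = np.array([False, True])
        return self

    def decision_function(self, X: Sequence[CandidateInstance]) -> np.ndarray:
        rows = cross_gram(X, self.train_instances_, self.kernel_, self.normalize)
        return self.model_.svc.decision_function(rows)

    def predict(self, X: Sequence[CandidateInstance]) -> np.ndarray:
        return self.decision_function(X) > 0


class CooccurrenceBaseline(BaseEstimator, ClassifierMixin):
    """Predict an interaction for every co-occurring candidate pair.

    Recall is 1 by construction and precision equals the corpus positive
    fraction; decision values are a constant, so the baseline carries no
    ranking information.
    """

    def fit(self, X, y=None):
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        return np.ones(len(X), dtype=bool)

    def decision_function(self, X) -> np.ndarray:
        return np.ones(len(X))


def write_gram_tsv(gram: GramMatrix, path) -> None:
    """Tab-separated Gram file with an id header row and id-leading rows."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("id\t" + "\t".join(gram.ids) + "\n")
        for row_id, row in zip(gram.ids, gram.values):
            handle.write(row_id + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_gram_tsv(path) -> tuple[np.ndarray, list[str]]:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in handle:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return np.asarray(rows), header
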