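"""Evaluation protocols: cross-validation, cross-learning, cross-corpus.

Fold assignment is document-level: all candidate instances of a document
travel together, so replicated (differently labeled) instances of one
multi-entity sentence can never straddle the train/test split.  An
instance-level fold generator is also provided, solely to demonstrate the
information leakage that document-level splitting prevents.

Metrics are precision, recall and F1 over the positive class at the
candidate-pair level, plus AUC from the SVM decision values (rank/
Mann-Whitney formulation, invariant to the class ratio).  Cross-validation
reports per-fold values with their mean and standard deviation; AUC is
computed per fold and averaged, consistent with the per-fold deviations.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from .io import corpus_instances
from .kernels import make_kernel
from .learner import (
    DegenerateTrainingError,
    LearnerConfig,
    compute_gram,
    predict,
    train,
)
from .model import CandidateInstance, Corpus


@dataclass
class FoldAssignment:
    assignment: dict[str, int]
    n_folds: int
    seed: Optional[int]
    provenance: str = "generated"

    def documents_in_fold(self, fold: int) -> list[str]:
        return sorted(d for d, f in self.assignment.items() if f == fold)


def document_folds(corpus: Corpus, n_folds: int, seed: int) -> FoldAssignment:
    """Seeded document partition; generated folds differ in size by <= 1."""
    doc_ids = sorted(
        {instance.document_id for instance in corpus_instances(corpus)}
        | {f"{corpus.name}.{d.id}" for d in corpus.documents}
    )
    if n_folds > len(doc_ids):
        raise ValueError(
            f"cannot split {len(doc_ids)} documents into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(doc_ids)))
    assignment = {doc_ids[j]: i % n_folds for i, j in enumerate(order)}
    return FoldAssignment(assignment=assignment, n_folds=n_folds, seed=seed)


def instance_level_folds(
    instances: Sequence[CandidateInstance], n_folds: int, seed: int
) -> list[np.ndarray]:
    """Partition instances directly, ignoring document boundaries.

    Provided only to operationalize the leakage argument against
    instance-level splitting: on multi-entity corpora it places instances of
    one sentence on both sides of the split.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(instances))
    return [order[f::n_folds] for f in range(n_folds)]


def read_split_file(path, n_folds: Optional[int] = None) -> FoldAssignment:
    """External two-column (document id, fold index) split file."""
    assignment: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            doc_id, fold = line.split()
            assignment[doc_id] = int(fold)
    folds = n_folds if n_folds is not None else max(assignment.values()) + 1
    return FoldAssignment(
        assignment=assignment, n_folds=folds, seed=None, provenance="external"
    )


def same_sentence_comembership(
    train_instances: Sequence[CandidateInstance],
    test_instances: Sequence[CandidateInstance],
) -> int:
    """Number of test instances whose sentence also feeds training instances."""
    train_sentences = {instance.sentence_id for instance in train_instances}
    return sum(1 for i in test_instances if i.sentence_id in train_sentences)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def precision_recall_f1(
    predictions: Sequence[bool], gold: Sequence[bool]
) -> tuple[float, float, float]:
    predictions = np.asarray(predictions, dtype=bool)
    gold = np.asarray(gold, dtype=bool)
    if predictions.shape != gold.shape:
        raise ValueError("predictions and gold labels are misaligned")
    tp = int(np.sum(predictions & gold))
    fp = int(np.sum(predictions & ~gold))
    fn = int(np.sum(~predictions & gold))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def auc(scores: Sequence[float], gold: Sequence[bool]) -> float:
    """Area under the ROC curve (rank formulation with tie averaging)."""
    gold = np.asarray(gold, dtype=bool)
    if gold.all() or not gold.any():
        raise ValueError("AUC is undefined for single-class gold labels")
    return float(roc_auc_score(gold.astype(int), np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class MetricBlock:
    unit: str
    n_train: int
    n_test: int
    precision: float
    recall: float
    f1: float
    auc: Optional[float]


@dataclass
class EvaluationReport:
    protocol: str
    blocks: list[MetricBlock]
    config: dict
    seed: Optional[int] = None
    skipped: list[str] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        values = [
            getattr(b, metric) for b in self.blocks if getattr(b, metric) is not None
        ]
        return float(np.mean(values)) if values else float("nan")

    def sd(self, metric: str) -> float:
        values = [
            getattr(b, metric) for b in self.blocks if getattr(b, metric) is not None
        ]
        return float(np.std(values)) if values else float("nan")

    def summary(self) -> dict:
        return {
            metric: {"mean": self.mean(metric), "sd": self.sd(metric)}
            for metric in ("precision", "recall", "f1", "auc")
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "protocol": self.protocol,
                "blocks": [asdict(b) for b in self.blocks],
                "summary": self.summary(),
                "config": self.config,
                "seed": self.seed,
                "skipped": self.skipped,
            },
            indent=2,
            sort_keys=True,
        )


#: registry name of the co-occurrence baseline (predict every pair positive)
COOC = "cooc"


def _is_baseline(kernel) -> bool:
    return isinstance(kernel, str) and kernel == COOC


def _config_echo(kernel, learner_config: LearnerConfig, normalize: bool) -> dict:
    if _is_baseline(kernel):
        return {"kernel": COOC, "kernel_params": {}, "learner": {}, "normalize": False}
    return {
        "kernel": kernel.name,
        "kernel_params": kernel.get_params(),
        "learner": {
            "C": learner_config.C,
            "positive_class_weight": learner_config.positive_class_weight,
            "epsilon": learner_config.epsilon,
        },
        "normalize": normalize,
    }


def _baseline_block(test_labels: np.ndarray, n_train: int, unit: str) -> MetricBlock:
    predictions = np.ones(len(test_labels), dtype=bool)
    precision, recall, f1 = precision_recall_f1(predictions, test_labels)
    block_auc = None
    if test_labels.any() and not test_labels.all():
        block_auc = auc(np.ones(len(test_labels)), test_labels)
    return MetricBlock(
        unit=unit,
        n_train=n_train,
        n_test=len(test_labels),
        precision=precision,
        recall=recall,
        f1=f1,
        auc=block_auc,
    )


def _evaluate_split(
    gram_values: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    learner_config: LearnerConfig,
    unit: str,
) -> MetricBlock:
    model = train(gram_values[np.ix_(train_idx, train_idx)], labels[train_idx],
                  learner_config)
    predictions, scores = predict(model, gram_values[np.ix_(test_idx, train_idx)])
    gold = labels[test_idx]
    precision, recall, f1 = precision_recall_f1(predictions, gold)
    block_auc = None
    if gold.any() and not gold.all():
        block_auc = auc(scores, gold)
    return MetricBlock(
        unit=unit,
        n_train=len(train_idx),
        n_test=len(test_idx),
        precision=precision,
        recall=recall,
        f1=f1,
        auc=block_auc,
    )


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


def run_cv(
    corpus: Corpus,
    kernel="kbsps",
    learner_config: LearnerConfig | None = None,
    folds: FoldAssignment | None = None,
    n_folds: int = 10,
    seed: int = 0,
    normalize: bool = True,
) -> EvaluationReport:
    """Document-level cross-validation on a single corpus.

    The Gram matrix is computed once over the full corpus and sliced per
    fold.  Folds whose training side contains a single class are skipped
    with a warning and listed in the report.
    """
    baseline = _is_baseline(kernel)
    if not baseline:
        kernel = make_kernel(kernel)
    learner_config = learner_config or LearnerConfig()
    instances = corpus_instances(corpus)
    if folds is None:
        folds = document_folds(corpus, n_folds, seed)
    labels = np.array([instance.label for instance in instances], dtype=bool)
    gram = None if baseline else compute_gram(instances, kernel, normalize=normalize)
    doc_fold = np.array(
        [folds.assignment[instance.document_id] for instance in instances]
    )
    blocks: list[MetricBlock] = []
    skipped: list[str] = []
    for fold in range(folds.n_folds):
        test_idx = np.flatnonzero(doc_fold == fold)
        train_idx = np.flatnonzero(doc_fold != fold)
        if not len(test_idx):
            continue
        if baseline:
            blocks.append(
                _baseline_block(labels[test_idx], len(train_idx), unit=f"fold{fold}")
            )
            continue
        try:
            blocks.append(
                _evaluate_split(
                    gram.values, labels, train_idx, test_idx, learner_config,
                    unit=f"fold{fold}",
                )
            )
        except DegenerateTrainingError:
            warnings.warn(f"fold {fold}: single-class training data, skipped",
                          stacklevel=2)
            skipped.append(f"fold{fold}")
    report = EvaluationReport(
        protocol="CV",
        blocks=blocks,
        config=_config_echo(kernel, learner_config, normalize),
        seed=seed,
        skipped=skipped,
    )
    return report


def run_cl(
    corpora: dict[str, Corpus],
    held_out_name: str,
    kernel="kbsps",
    learner_config: LearnerConfig | None = None,
    normalize: bool = True,
) -> EvaluationReport:
    """Cross-learning: train on the pooled other corpora, test on one."""
    if held_out_name not in corpora:
        raise ValueError(f"unknown held-out corpus {held_out_name!r}")
    if len(corpora) < 2:
        raise ValueError("cross-learning needs at least two corpora")
    if not _is_baseline(kernel):
        kernel = make_kernel(kernel)
    learner_config = learner_config or LearnerConfig()
    train_instances = [
        instance
        for name, corpus in sorted(corpora.items())
        if name != held_out_name
        for instance in corpus_instances(corpus)
    ]
    test_instances = corpus_instances(corpora[held_out_name])
    block = _train_test_block(
        train_instances, test_instances, kernel, learner_config, normalize,
        unit=held_out_name,
    )
    return EvaluationReport(
        protocol="CL",
        blocks=[block],
        config=_config_echo(kernel, learner_config, normalize),
    )


def run_cc(
    train_corpus: Corpus,
    test_corpora: dict[str, Corpus],
    kernel="kbsps",
    learner_config: LearnerConfig | None = None,
    normalize: bool = True,
) -> EvaluationReport:
    """Cross-corpus: train on one corpus, test on each of the others.

    The decision threshold stays at 0: no adaptation to the test-corpus
    class ratio is performed.
    """
    if not _is_baseline(kernel):
        kernel = make_kernel(kernel)
    learner_config = learner_config or LearnerConfig()
    train_instances = corpus_instances(train_corpus)
    blocks = [
        _train_test_block(
            train_instances,
            corpus_instances(corpus),
            kernel,
            learner_config,
            normalize,
            unit=name,
        )
        for name, corpus in sorted(test_corpora.items())
    ]
    return EvaluationReport(
        protocol="CC",
        blocks=blocks,
        config=_config_echo(kernel, learner_config, normalize),
    )


def _train_test_block(
    train_instances, test_instances, kernel, learner_config, normalize, unit
) -> MetricBlock:
    if _is_baseline(kernel):
        test_labels = np.array([i.label for i in test_instances], dtype=bool)
        return _baseline_block(test_labels, len(train_instances), unit=unit)
    combined = list(train_instances) + list(test_instances)
    labels = np.array([instance.label for instance in combined], dtype=bool)
    gram = compute_gram(combined, kernel, normalize=normalize)
    train_idx = np.arange(len(train_instances))
    test_idx = np.arange(len(train_instances), len(combined))
    return _evaluate_split(
        gram.values, labels, train_idx, test_idx, learner_config, unit=unit
    )


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def grid_search(
    corpus: Corpus,
    kernel,
    param_grid: dict[str, Sequence],
    learner_config: LearnerConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
    normalize: bool = True,
) -> tuple[dict, list[dict]]:
    """Coarse grid search under document-level CV on the given corpus.

    The grid may include kernel parameters and the special key ``C``.  Every
    grid point is evaluated; the winner has the highest mean F1, ties broken
    by mean AUC, then by smallest C, then by grid order.  Returns the winning
    configuration and the full results table.  Grid search never sees test
    data of an outer CL/CC protocol: it is run on training material only.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    base_kernel = make_kernel(kernel)
    learner_config = learner_config or LearnerConfig()
    keys = sorted(param_grid)
    table: list[dict] = []
    folds = document_folds(corpus, n_folds, seed)
    for values in itertools.product(*(param_grid[k] for k in keys)):
        point = dict(zip(keys, values))
        cfg = LearnerConfig(
            C=point.get("C", learner_config.C),
            positive_class_weight=learner_config.positive_class_weight,
            epsilon=learner_config.epsilon,
        )
        kernel_point = clone(base_kernel)
        kernel_point.set_params(
            **{k: v for k, v in point.items() if k != "C"}
        )
        report = run_cv(
            corpus, kernel_point, cfg, folds=folds, seed=seed, normalize=normalize
        )
        table.append(
            {
                "params": point,
                "mean_f1": report.mean("f1"),
                "mean_auc": report.mean("auc"),
                "sd_f1": report.sd("f1"),
                "C": cfg.C,
            }
        )
    best = max(
        enumerate(table),
        key=lambda item: (
            round(item[1]["mean_f1"], 12),
            round(0.0 if np.isnan(item[1]["mean_auc"]) else item[1]["mean_auc"], 12),
            -item[1]["C"],
            -item[0],
        ),
    )[1]
    return best["params"], table
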