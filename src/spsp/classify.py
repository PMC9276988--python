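"""Template construction, cosine-similarity classification, and LOSO.

Each class gets an *index* vector: the elementwise mean of the training
symbol sequences carrying that label (symbols enter as their raw integer
values, which preserves the ordinal meaning of radial shells).  A test
sequence is assigned to the class whose index it resembles most under
cosine similarity.  Leave-one-subject-out (LOSO) evaluation rebuilds the
indices without the held-out subject for every fold and accumulates a
confusion matrix across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, ProtocolError
from .symbolize import SymbolSequence


@dataclass
class ClassIndex:
    """Per-class template: mean of the class's training symbol vectors."""

    label: str
    template: np.ndarray
    n_contributors: int

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        if self.template.ndim != 1:
            raise DomainError("template must be a 1-D vector")
        if self.n_contributors < 1:
            raise DomainError("a class index needs at least one contributor")


@dataclass
class SimilarityScores:
    """Cosine similarity to every class template plus the argmax decision."""

    per_label: dict[str, float]
    predicted: str
    tie_flag: bool


@dataclass
class EvaluationReport:
    """Confusion counts and accuracies from a LOSO run.

    ``confusion[i, j]`` counts trials of true class ``labels[i]`` predicted
    as ``labels[j]``.  Both the mean-over-subjects accuracy and the pooled
    (micro) accuracy are reported; they coincide when every subject
    contributes the same number of test trials.
    """

    labels: list[str]
    confusion: np.ndarray
    per_class_accuracy: list[Optional[float]]
    per_subject_accuracy: dict[str, float]
    total_accuracy_mean_subject: float
    total_accuracy_micro: float
    n_folds: int
    tie_count: int = 0

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        k = len(self.labels)
        if self.confusion.shape != (k, k):
            raise DomainError(
                f"confusion must be {k}x{k}, got {self.confusion.shape}"
            )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": [
                None if a is None else float(a) for a in self.per_class_accuracy
            ],
            "per_subject_accuracy": {
                k: float(v) for k, v in sorted(self.per_subject_accuracy.items())
            },
            "total_accuracy_mean_subject": float(self.total_accuracy_mean_subject),
            "total_accuracy_micro": float(self.total_accuracy_micro),
            "n_folds": int(self.n_folds),
            "tie_count": int(self.tie_count),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationReport":
        return cls(
            labels=list(doc["labels"]),
            confusion=np.asarray(doc["confusion"], dtype=int),
            per_class_accuracy=list(doc["per_class_accuracy"]),
            per_subject_accuracy=dict(doc["per_subject_accuracy"]),
            total_accuracy_mean_subject=doc["total_accuracy_mean_subject"],
            total_accuracy_micro=doc["total_accuracy_micro"],
            n_folds=doc["n_folds"],
            tie_count=doc.get("tie_count", 0),
        )


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Inner product of the two vectors divided by the product of their norms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError(
            f"cosine similarity needs equal-length 1-D vectors, "
            f"got shapes {a.shape} and {b.shape}"
        )
    norm_a = float(np.linalg.norm(a))
    norm_b = float(np.linalg.norm(b))
    if norm_a == 0.0 or norm_b == 0.0:
        raise DomainError("cosine similarity is undefined for zero vectors")
    # clamp: rounding (or underflow on near-denormal inputs) can push the
    # quotient marginally outside the mathematical range
    return float(min(1.0, max(-1.0, np.dot(a, b) / (norm_a * norm_b))))


# ---------------------------------------------------------------------------
# templates and classification
# ---------------------------------------------------------------------------


def build_class_indices(
    training: Sequence[SymbolSequence],
    class_labels: Optional[Sequence[str]] = None,
    weighting: str = "per_trial",
) -> dict[str, ClassIndex]:
    """Elementwise-mean templates, one per class label.

    ``weighting='per_trial'`` pools all training trials of a label with
    equal weight; ``'per_subject'`` first averages within each subject and
    then across subjects.  Raises on mixed sequence lengths or on a class
    with no training sequences.
    """
    if weighting not in ("per_trial", "per_subject"):
        raise DomainError(f"unknown index weighting {weighting!r}")
    if not training:
        raise DomainError("no training sequences supplied")
    lengths = {len(s) for s in training}
    if len(lengths) != 1:
        raise DomainError(f"mixed sequence lengths in training set: {sorted(lengths)}")
    if class_labels is None:
        class_labels = sorted({s.label for s in training if s.label is not None})
    indices: dict[str, ClassIndex] = {}
    for label in class_labels:
        members = [s for s in training if s.label == label]
        if not members:
            raise DomainError(f"no training sequences for class {label!r}")
        if weighting == "per_trial":
            template = np.mean([s.symbols for s in members], axis=0)
        else:
            subjects = sorted({s.subject_id for s in members})
            subject_means = [
                np.mean(
                    [s.symbols for s in members if s.subject_id == subj], axis=0
                )
                for subj in subjects
            ]
            template = np.mean(subject_means, axis=0)
        indices[label] = ClassIndex(
            label=label, template=template, n_contributors=len(members)
        )
    return indices


def classify_sequence(
    seq: SymbolSequence,
    indices: dict[str, ClassIndex],
    label_order: Optional[Sequence[str]] = None,
) -> SimilarityScores:
    """Assign ``seq`` to the class template with the highest cosine similarity.

    Exact ties are broken toward the label earliest in ``label_order`` (the
    insertion order of ``indices`` by default) and flagged.
    """
    if len(indices) < 2:
        raise DomainError("classification needs at least two class indices")
    order = list(label_order) if label_order is not None else list(indices)
    scores: dict[str, float] = {}
    for label in order:
        template = indices[label].template
        if template.shape[0] != len(seq):
            raise DomainError(
                f"sequence length {len(seq)} does not match template "
                f"length {template.shape[0]} for class {label!r}"
            )
        scores[label] = cosine_similarity(
            seq.symbols.astype(float), template
        )
    best = max(scores.values())
    winners = [label for label in order if scores[label] == best]
    return SimilarityScores(
        per_label=scores, predicted=winners[0], tie_flag=len(winners) > 1
    )


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation
# ---------------------------------------------------------------------------


def loso_evaluate(
    sequences: Sequence[SymbolSequence],
    class_labels: Sequence[str],
    weighting: str = "per_trial",
) -> EvaluationReport:
    """Leave-one-subject-out evaluation over labeled symbol sequences.

    For every subject, class indices are built from all *other* subjects'
    trials and each of the held-out subject's trials is classified.  Trials
    whose label is not in ``class_labels`` are ignored.  Every subject must
    contribute at least one trial of every class.
    """
    class_labels = list(class_labels)
    if len(class_labels) < 2:
        raise ProtocolError("need at least two class labels")
    pool = [s for s in sequences if s.label in class_labels]
    subjects = sorted({s.subject_id for s in pool})
    if len(subjects) < 2:
        raise ProtocolError(
            f"leave-one-subject-out needs >= 2 subjects, got {len(subjects)}"
        )
    for subj in subjects:
        have = {s.label for s in pool if s.subject_id == subj}
        for label in class_labels:
            if label not in have:
                raise ProtocolError(
                    f"subject {subj!r} has no trial of class {label!r}"
                )

    label_pos = {label: i for i, label in enumerate(class_labels)}
    confusion = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    per_subject_accuracy: dict[str, float] = {}
    tie_count = 0
    for subj in subjects:
        train = [s for s in pool if s.subject_id != subj]
        test = [s for s in pool if s.subject_id == subj]
        indices = build_class_indices(train, class_labels, weighting=weighting)
        correct = 0
        for seq in test:
            scores = classify_sequence(seq, indices, label_order=class_labels)
            if scores.tie_flag:
                tie_count += 1
            confusion[label_pos[seq.label], label_pos[scores.predicted]] += 1
            if scores.predicted == seq.label:
                correct += 1
        per_subject_accuracy[subj] = correct / len(test)

    per_class, micro = accuracy_from_confusion(confusion)
    return EvaluationReport(
        labels=class_labels,
        confusion=confusion,
        per_class_accuracy=per_class,
        per_subject_accuracy=per_subject_accuracy,
        total_accuracy_mean_subject=float(
            np.mean(list(per_subject_accuracy.values()))
        ),
        total_accuracy_micro=micro,
        n_folds=len(subjects),
        tie_count=tie_count,
    )


def accuracy_from_confusion(
    confusion: np.ndarray,
) -> tuple[list[Optional[float]], float]:
    """Per-class (diagonal/row-sum) and micro (trace/total) accuracy.

    A class with zero test trials gets ``None`` for its per-class accuracy.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise DomainError(f"confusion matrix must be square, got {confusion.shape}")
    if np.any(confusion < 0) or not np.issubdtype(confusion.dtype, np.integer):
        raise DomainError("confusion matrix must hold nonnegative integers")
    total = int(confusion.sum())
    if total == 0:
        raise DomainError("confusion matrix has no counts")
    per_class: list[Optional[float]] = []
    for i in range(confusion.shape[0]):
        row_sum = int(confusion[i].sum())
        per_class.append(None if row_sum == 0 else confusion[i, i] / row_sum)
    micro = float(np.trace(confusion) / total)
    return per_class, micro
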