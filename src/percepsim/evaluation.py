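"""Classification performance of perception models: correct-count,
ROC AUC, and the per-subset error breakdown.

Truth labels come from the expert majority: a pair is truly "similar"
when pxp >= 0.5.  ROC AUC is computed from the predicted-probability
ranking with midrank handling of ties (the Mann-Whitney estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .chem_io import ExpertVotes
from .exceptions import EvaluationError
from .perception_model import PerceptionPrediction
from .subset_design import SubsetLabel

__all__ = ["EvaluationReport", "evaluate"]


@dataclass(frozen=True)
class EvaluationReport:
    n_correct: int
    n_total: int
    roc_auc: float
    per_subset_percent_correct: dict[str, float] = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def evaluate(
    predictions: list[PerceptionPrediction],
    truth: list[ExpertVotes],
    subsets: list[SubsetLabel | str] | None = None,
) -> EvaluationReport:
    """Score predictions against expert majority labels.

    ``n_correct`` counts pairs whose predicted label matches the
    majority label; ``roc_auc`` ranks pairs by predicted probability
    against the same labels.  When ``subsets`` is given, the percentage
    of correct predictions is additionally reported per subset.
    """
    if len(predictions) != len(truth):
        raise EvaluationError(
            f"length mismatch: {len(predictions)} predictions vs "
            f"{len(truth)} truth entries"
        )
    if subsets is not None and len(subsets) != len(truth):
        raise EvaluationError("subset labels must align with predictions")
    if not predictions:
        raise EvaluationError("nothing to evaluate")

    y_true = np.array([1 if v.pxp >= 0.5 else 0 for v in truth])
    y_pred = np.array([1 if p.label == "similar" else 0 for p in predictions])
    scores = np.array([p.p_hat for p in predictions])

    n_correct = int(np.sum(y_true == y_pred))
    if len(np.unique(y_true)) < 2:
        raise EvaluationError(
            "ROC AUC undefined: truth labels contain a single class"
        )
    auc = float(roc_auc_score(y_true, scores))

    per_subset: dict[str, float] = {}
    if subsets is not None:
        labels = np.array([str(s) for s in subsets])
        for name in sorted(set(labels)):
            mask = labels == name
            per_subset[name] = float(
                100.0 * np.mean(y_true[mask] == y_pred[mask])
            )
    return EvaluationReport(
        n_correct=n_correct,
        n_total=len(predictions),
        roc_auc=auc,
        per_subset_percent_correct=per_subset,
    )
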