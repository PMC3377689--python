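"""Fully equivalent operational models (FEOMs): the fitted expansions used as
forward predictors of an unmeasured node and as inverse classifiers of the
experimental condition from the observed network state.

Forward use: predict one node's level from the other nodes in the same sample
and score the predictions by Pearson correlation and by the fraction of points
falling within given relative-error ranges of the observed values.

Inverse use: a model fitted on a pairwise-comparison dataset (Boolean
perturbation output) produces a continuous score for each sample; scores above
0.5 are grouped as class 1.  Clear separation of the two class-conditional
score distributions indicates the perturbation measurably shifts the network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DataTable, PairwiseTable
from .model_fit import HDMRModel, predict

__all__ = [
    "PredictionMetrics",
    "ClassificationResult",
    "evaluate_prediction",
    "classify_inverse",
    "roc_points",
]

CLASSIFICATION_THRESHOLD = 0.5


@dataclass
class PredictionMetrics:
    """Held-out forward-prediction quality for one output node.

    ``within_tolerance`` maps relative-error tolerance -> fraction of test
    points whose |pred - obs| / |obs| (original measurement scale) does not
    exceed it; rows with observed value 0 are excluded from the fractions and
    counted in ``n_zero_excluded``.  ``R`` is the Pearson correlation between
    predicted and observed (NaN with ``r_undefined`` set when the observations
    have zero variance).
    """

    output_id: str
    R: float
    within_tolerance: dict[float, float]
    n_test: int
    n_zero_excluded: int = 0
    r_undefined: bool = False

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "output_id": self.output_id,
                "R": None if self.r_undefined else self.R,
                "r_undefined": self.r_undefined,
                "within_tolerance": {str(k): v for k, v in self.within_tolerance.items()},
                "n_test": self.n_test,
                "n_zero_excluded": self.n_zero_excluded,
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


@dataclass
class ClassificationResult:
    """Inverse-FEOM output: continuous scores, hard labels, and accuracy."""

    scores: np.ndarray
    labels: np.ndarray
    accuracy: float | None = None
    true_labels: np.ndarray | None = None
    threshold: float = CLASSIFICATION_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        d = {"score": self.scores, "label": self.labels}
        if self.true_labels is not None:
            d["true_label"] = self.true_labels
        return pd.DataFrame(d)


def evaluate_prediction(
    model: HDMRModel,
    test: DataTable,
    tolerances: list[float] = (0.01, 0.05, 0.10, 0.20),
) -> PredictionMetrics:
    """Score forward predictions on a held-out table.

    Predictions and observations are compared on the original (denormalized)
    measurement scale.  Relative error uses the observed value as denominator;
    observed-zero rows are excluded from the tolerance fractions and reported
    separately.
    """
    if test.n_samples < 2:
        raise ValueError("need at least 2 test samples")
    if model.output_id not in test.node_names:
        raise KeyError(f"test table lacks output {model.output_id!r}")

    obs = test.values[model.output_id].to_numpy(dtype=float)
    if test.normalized:
        from .data_io import denormalize_column

        obs = denormalize_column(obs, model.transforms[model.output_id])
    pred = predict(model, test, denormalize=True)

    r_undefined = bool(np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0)
    R = float("nan") if r_undefined else float(np.corrcoef(pred, obs)[0, 1])

    nonzero = obs != 0.0
    n_zero = int(np.sum(~nonzero))
    rel_err = np.abs(pred[nonzero] - obs[nonzero]) / np.abs(obs[nonzero])
    within = {
        float(tol): (float(np.mean(rel_err <= tol)) if rel_err.size else float("nan"))
        for tol in sorted(tolerances)
    }
    return PredictionMetrics(
        output_id=model.output_id,
        R=R,
        within_tolerance=within,
        n_test=test.n_samples,
        n_zero_excluded=n_zero,
        r_undefined=r_undefined,
    )


def classify_inverse(
    model: HDMRModel,
    samples: DataTable | pd.DataFrame,
    true_labels: np.ndarray | None = None,
) -> ClassificationResult:
    """Infer the perturbation condition of each sample from its network state.

    The model must have been fitted on a pairwise-comparison dataset with the
    perturbed node as output; its continuous prediction is thresholded at 0.5
    (score > 0.5 -> class 1).  When true labels are supplied (or the samples
    are themselves a PairwiseTable) the fraction correctly grouped is reported.
    """
    scores = predict(model, samples)
    labels = (scores > CLASSIFICATION_THRESHOLD).astype(int)
    if true_labels is None and isinstance(samples, PairwiseTable):
        true_labels = samples.class_labels
    accuracy = None
    tl = None
    if true_labels is not None:
        tl = np.asarray(true_labels).astype(int)
        if tl.shape != labels.shape:
            raise ValueError("true_labels length does not match samples")
        accuracy = float(np.mean(labels == tl))
    return ClassificationResult(
        scores=scores, labels=labels, accuracy=accuracy, true_labels=tl
    )


def roc_points(scores: np.ndarray, true_labels: np.ndarray) -> pd.DataFrame:
    """(threshold, TPR, FPR) over all distinct score thresholds."""
    scores = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels).astype(int)
    pos, neg = int(np.sum(t == 1)), int(np.sum(t == 0))
    if pos == 0 or neg == 0:
        raise ValueError("ROC needs both classes present")
    rows = []
    for thr in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        pred = scores > thr
        rows.append(
            {
                "threshold": thr,
                "tpr": float(np.sum(pred & (t == 1))) / pos,
                "fpr": float(np.sum(pred & (t == 0))) / neg,
            }
        )
    return pd.DataFrame(rows)
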