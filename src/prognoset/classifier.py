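"""Linear soft-margin maximum-margin classifier over a gene subset.

The decision function is ``score(s) = w . z(s) + b`` where ``z`` is the
per-gene z-score transform learned on the training cohort.  The recurrence
class is mapped to +1, so a positive weight means higher expression of that
gene is associated with higher recurrence risk.  Weights are reported in
standardized feature space; the (center, scale) transform is carried on the
classifier so raw-space weights are recoverable as ``w / scale``.

Training solves the usual hinge-loss + L2 primal at a given cost via
liblinear's dual coordinate descent (deterministic configuration, tolerance
1e-6).  The intercept is made effectively unregularized by a large
intercept-scaling factor, matching the standard SVM formulation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm._base import _fit_liblinear

from .io import ExpressionMatrix
from .cohorts import CohortLabeling

__all__ = ["LinearClassifier", "train_linear_svm", "decision_scores",
           "fit_svm_arrays", "solve_svm"]

logger = logging.getLogger(__name__)

_TOL = 1e-6
_MAX_ITER = 200_000
_INTERCEPT_SCALING = 1.0


@dataclass
class LinearClassifier:
    gene_ids: list[str]
    weights: np.ndarray  # standardized-space weights, one per gene
    bias: float
    center: np.ndarray  # per-gene training means
    scale: np.ndarray  # per-gene training standard deviations (1 where zero-variance)
    cost: float
    training_cohort: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (len(self.gene_ids) == self.weights.size == self.center.size
                == self.scale.size):
            raise ValueError("gene_ids, weights and standardization sizes disagree")

    def scores_array(self, x: np.ndarray) -> np.ndarray:
        """Decision scores for raw feature rows ordered like ``gene_ids``."""
        z = (np.asarray(x, dtype=float) - self.center) / self.scale
        return z @ self.weights + self.bias

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "gene_ids": list(self.gene_ids),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "standardization": {
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
            },
            "cost": self.cost,
            "training_cohort": self.training_cohort,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LinearClassifier":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        doc = json.loads(text)
        return cls(
            gene_ids=doc["gene_ids"],
            weights=np.array(doc["weights"]),
            bias=float(doc["bias"]),
            center=np.array(doc["standardization"]["center"]),
            scale=np.array(doc["standardization"]["scale"]),
            cost=float(doc["cost"]),
            training_cohort=doc.get("training_cohort"),
        )


def fit_svm_arrays(
    x: np.ndarray,
    y: np.ndarray,
    cost: float = 1.0,
    standardize: bool = True,
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Fit the soft-margin linear SVM on raw features and ±1 labels.

    Returns (weights, bias, center, scale) with weights in standardized space.
    This array-level entry point exists so the Monte Carlo permutation stages
    can retrain without DataFrame overhead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise ValueError("labels must be -1 (event-free) / +1 (recurrence)")
    if np.bincount((y > 0).astype(int)).min() < 2:
        raise ValueError("need at least 2 samples per class")
    if standardize:
        center = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
        zero_var = scale == 0.0
        if zero_var.any():
            logger.warning("zero-variance feature(s) at columns %s; scale set to 1",
                           np.flatnonzero(zero_var).tolist())
            scale = np.where(zero_var, 1.0, scale)
    else:
        center = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    z = (x - center) / scale
    w, b = solve_svm(z, y, cost)
    return w, b, center, scale


def solve_svm(z: np.ndarray, y: np.ndarray, cost: float) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM on already-standardized features and ±1 labels.

    liblinear dual coordinate descent, called at the solver level: identical
    output to ``LinearSVC(loss="hinge", ...)`` with these settings (asserted in
    the test suite) but without per-fit estimator overhead, which matters in
    the 10k-permutation Monte Carlo stages.  Orientation: the positive class
    is max(classes) == +1 (recurrence).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coef, intercept, _ = _fit_liblinear(
            z, y, C=cost, fit_intercept=True,
            intercept_scaling=_INTERCEPT_SCALING, class_weight=None,
            penalty="l2", dual=True, verbose=0, max_iter=_MAX_ITER, tol=_TOL,
            random_state=0, multi_class="ovr", loss="hinge",
        )
    return np.asarray(coef).ravel().copy(), float(np.asarray(intercept).ravel()[0])


def train_linear_svm(
    x: ExpressionMatrix,
    labels: CohortLabeling,
    cost: float = 1.0,
    training_cohort: str | None = None,
) -> LinearClassifier:
    """Train on the classified samples of one cohort.

    ``x`` must already be restricted to the gene subset of interest (subset
    choice is the caller's job); its rows become the classifier's genes in
    order.  Recurrence samples (``labels.positives``) are the +1 class.
    """
    samples = sorted(labels.positives) + sorted(labels.negatives)
    missing = [s for s in samples if s not in set(x.sample_ids)]
    if missing:
        raise ValueError(f"classified samples missing from expression: {missing[:5]}")
    xm = x.values[samples].to_numpy(dtype=float).T  # samples × genes
    y = np.array([1] * len(labels.positives) + [-1] * len(labels.negatives))
    w, b, center, scale = fit_svm_arrays(xm, y, cost=cost)
    return LinearClassifier(
        gene_ids=list(x.values.index),
        weights=w,
        bias=b,
        center=center,
        scale=scale,
        cost=cost,
        training_cohort=training_cohort,
    )


def decision_scores(c: LinearClassifier, x: ExpressionMatrix) -> pd.Series:
    """Score every sample of ``x`` with the frozen training standardization.

    Higher score = higher predicted recurrence risk.
    """
    missing = [g for g in c.gene_ids if g not in set(x.gene_ids)]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")
    sub = x.values.loc[c.gene_ids].to_numpy(dtype=float).T
    return pd.Series(c.scores_array(sub), index=x.sample_ids, name="score")
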