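"""Neuron labeling and max-voting prediction for trained competitive models.

A competitive layer is turned into a classifier in two supervised-free
steps of the standard CSNN recipe: (1) present labeled samples with all
plasticity frozen and accumulate each neuron's response per class, then
assign each neuron the class it responded to most; (2) predict a new
sample's class as the label group with the highest *average* response
(averaging, not summing, so classes represented by more neurons are not
favored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CRBAConfig, firing_rates

__all__ = ["NeuronLabeling", "label_neurons", "predict", "predict_votes", "evaluate",
           "confusion_matrix", "per_class_accuracy"]


@dataclass
class NeuronLabeling:
    """Per-neuron class assignment plus the activity matrix behind it.

    ``activity[j, c]`` is neuron j's accumulated response to class
    ``classes[c]`` over the labeling set; ``labels[j]`` is the argmax
    class (ties -> lowest class id).
    """

    labels: np.ndarray
    activity: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.activity = np.asarray(self.activity, dtype=float)
        self.classes = np.asarray(self.classes, dtype=int)


def _responses(W: np.ndarray, theta: np.ndarray, X: np.ndarray,
               config: CRBAConfig) -> np.ndarray:
    """Per-neuron activity proxy for each sample: predicted spike count.

    alpha_s * t * rate, with thresholds frozen — the rate is the model's
    activity readout, no plasticity is applied.
    """
    rates = (X @ W) / np.maximum(theta, config.theta_floor)
    return config.alpha_s * config.t * rates


def label_neurons(W: np.ndarray, theta: np.ndarray, X: np.ndarray,
                  y: np.ndarray, config: CRBAConfig) -> NeuronLabeling:
    """Assign each neuron the class it is most active for.

    Accumulates responses per class over all labeling samples with no
    learning updates; classes absent from the labeling set trigger a
    warning (they can never be predicted).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    m = W.shape[1]
    resp = _responses(W, theta, X, config)  # (n, m)
    activity = np.zeros((m, len(classes)))
    for c_idx, c in enumerate(classes):
        mask = y == c
        if not mask.any():  # pragma: no cover - unique() precludes this
            warnings.warn(f"class {c} has no labeling samples; unassignable")
            continue
        activity[:, c_idx] = resp[mask].sum(axis=0)
    labels = classes[np.argmax(activity, axis=1)]  # argmax ties -> lowest class id
    return NeuronLabeling(labels=labels, activity=activity, classes=classes)


def predict_votes(W: np.ndarray, theta: np.ndarray, labeling: NeuronLabeling,
                  X: np.ndarray, config: CRBAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Max-voting prediction; returns (predicted classes, per-class vote matrix).

    The vote for a class is the mean response over the neurons carrying
    that label.  Samples that elicit no response anywhere fall back to the
    most common neuron label (flagged via a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    resp = _responses(W, theta, X, config)  # (n, m)
    votes = np.full((X.shape[0], len(labeling.classes)), -np.inf)
    for c_idx, c in enumerate(labeling.classes):
        group = labeling.labels == c
        if group.any():
            votes[:, c_idx] = resp[:, group].mean(axis=1)
    pred = labeling.classes[np.argmax(votes, axis=1)]
    dead = ~np.any(resp > 0, axis=1)
    if dead.any():
        counts = np.array([(labeling.labels == c).sum() for c in labeling.classes])
        fallback = labeling.classes[np.argmax(counts)]
        warnings.warn(f"{int(dead.sum())} sample(s) produced no evidence; "
                      f"falling back to majority label {fallback}")
        pred[dead] = fallback
    return pred, votes


def predict(W: np.ndarray, theta: np.ndarray, labeling: NeuronLabeling,
            X: np.ndarray, config: CRBAConfig) -> np.ndarray:
    """Predicted class per sample (see :func:`predict_votes`)."""
    return predict_votes(W, theta, labeling, X, config)[0]


def evaluate(W: np.ndarray, theta: np.ndarray, labeling: NeuronLabeling,
             X: np.ndarray, y: np.ndarray, config: CRBAConfig) -> float:
    """Fraction of correctly predicted samples, in [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred = predict(W, theta, labeling, X, config)
    return float(np.mean(pred == np.asarray(y, dtype=int)))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Confusion matrix (rows = true class, cols = predicted), CSV-exportable."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    classes = np.unique(np.concatenate([y_true, y_pred]))
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    lut = {c: i for i, c in enumerate(classes)}
    for t, q in zip(y_true, y_pred):
        mat[lut[t], lut[q]] += 1
    return pd.DataFrame(mat, index=classes, columns=classes)


def per_class_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> pd.Series:
    """Recall per true class (diagonal of the row-normalised confusion matrix)."""
    cm = confusion_matrix(y_true, y_pred)
    totals = cm.sum(axis=1)
    return pd.Series(np.diag(cm) / totals.where(totals > 0, 1), index=cm.index,
                     name="accuracy")
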