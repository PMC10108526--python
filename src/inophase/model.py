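"""Fully connected per-read editing classifier.

The network maps a window feature vector to the probability that the
read is edited at the site: three fully connected layers of 1024, 512
and 64 ReLU units followed by a single sigmoid output (a one-unit
softmax head is degenerate; the sigmoid is its two-unit equivalent).
Training uses inverted dropout on the hidden layers, Adam on a
class-weighted binary cross-entropy, an internal stratified 80/20
train/held-out split, and early stopping on held-out loss. All
arithmetic is float32 and fully determined by ``random_state``.

The estimator follows scikit-learn conventions (``fit`` /
``predict_proba`` / ``get_params``), composes with sklearn model
selection, and serializes to a portable JSON container with an embedded
parameter hash and feature-layout descriptor.
"""

from __future__ import annotations

import hashlib
import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import LayoutError, ValidationError
from .features import FeatureMatrix

_EPS = 1e-7


def evaluate_auc(y_true: Sequence[int], y_score: Sequence[float]) -> float:
    """Area under the ROC curve (midrank tie handling).

    Equals the normalized Mann-Whitney U statistic: the probability that
    a random positive outscores a random negative, counting ties as 1/2.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValidationError("evaluate_auc requires both classes in y_true")
    return float(roc_auc_score(y_true, y_score))


class ReadEditingClassifier(BaseEstimator, ClassifierMixin):
    """Per-read editing probability from window signal features.

    Parameters
    ----------
    hidden_layer_sizes:
        Widths of the fully connected layers before the sigmoid output;
        the default (1024, 512, 64) is the published architecture.
    dropout:
        Inverted-dropout rate applied to every hidden activation during
        training.
    train_fraction:
        Fraction of the data used for gradient updates; the stratified
        remainder is held out for early stopping and the reported
        ``heldout_auc_``.
    class_weight:
        "balanced" re-weights the binary cross-entropy by inverse class
        frequency; None trains unweighted.
    random_state:
        Seeds the split, initialization, shuffling and dropout masks;
        two fits with the same data and seed produce identical weights.
    """

    def __init__(
        self,
        hidden_layer_sizes: Tuple[int, ...] = (1024, 512, 64),
        dropout: float = 0.5,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 50,
        patience: int = 5,
        min_delta: float = 1e-4,
        train_fraction: float = 0.8,
        class_weight: Optional[str] = "balanced",
        random_state: Optional[int] = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.train_fraction = train_fraction
        self.class_weight = class_weight
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params(self) -> None:
        if any(w <= 0 for w in self.hidden_layer_sizes):
            raise ValidationError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must be in (0, 1)")

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        n_hidden = len(self.coefs_) - 1
        for i in range(n_hidden):
            a = np.maximum(a @ self.coefs_[i] + self.intercepts_[i], 0.0)
        z = a @ self.coefs_[-1] + self.intercepts_[-1]
        return 1.0 / (1.0 + np.exp(-z[:, 0]))

    def fit(self, X, y, feature_layout: Optional[Sequence[str]] = None):
        """Train on labeled feature vectors (y in {0, 1})."""
        self._validate_params()
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValidationError("training data must contain both classes")
        if len(classes) > 2 or not np.isin(classes, [0, 1]).all():
            raise ValidationError("labels must be binary 0/1")
        if feature_layout is not None and len(feature_layout) != X.shape[1]:
            raise LayoutError(
                f"feature_layout has {len(feature_layout)} names for "
                f"{X.shape[1]} columns"
            )
        rng = np.random.default_rng(self.random_state)
        split_seed = int(rng.integers(2**31 - 1))
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            train_size=self.train_fraction,
            stratify=y,
            random_state=split_seed,
            shuffle=True,
        )
        X_tr = X_tr.astype(np.float32)
        X_val = X_val.astype(np.float32)
        y_tr32 = y_tr.astype(np.float32)
        y_val32 = y_val.astype(np.float32)

        if self.class_weight == "balanced":
            n, n_pos = len(y_tr), float(y_tr.sum())
            w_pos, w_neg = n / (2.0 * n_pos), n / (2.0 * (n - n_pos))
        elif self.class_weight is None:
            w_pos = w_neg = 1.0
        else:
            raise ValidationError("class_weight must be 'balanced' or None")
        sw_tr = np.where(y_tr32 == 1.0, np.float32(w_pos), np.float32(w_neg))
        sw_val = np.where(y_val32 == 1.0, np.float32(w_pos), np.float32(w_neg))

        widths = [X.shape[1], *self.hidden_layer_sizes, 1]
        coefs: List[np.ndarray] = []
        intercepts: List[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            scale = np.sqrt(2.0 / fan_in)
            coefs.append(
                (rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32)
            )
            intercepts.append(np.zeros(fan_out, dtype=np.float32))

        m = [np.zeros_like(w) for w in coefs] + [np.zeros_like(b) for b in intercepts]
        v = [np.zeros_like(w) for w in coefs] + [np.zeros_like(b) for b in intercepts]
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        t_step = 0
        keep = 1.0 - self.dropout
        n_layers = len(coefs)

        def val_loss_and_probs(Xv, yv, sw):
            self.coefs_, self.intercepts_ = coefs, intercepts
            p = self._forward(Xv).astype(np.float64)
            p = np.clip(p, _EPS, 1.0 - _EPS)
            loss = -np.average(
                yv * np.log(p) + (1.0 - yv) * np.log(1.0 - p), weights=sw
            )
            return float(loss), p

        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        loss_curve: List[float] = []
        val_curve: List[float] = []
        n_tr = len(X_tr)

        for epoch in range(self.max_epochs):
            order = rng.permutation(n_tr)
            epoch_loss = 0.0
            epoch_weight = 0.0
            for start in range(0, n_tr, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = X_tr[idx], y_tr32[idx], sw_tr[idx]
                # forward with inverted dropout on hidden activations
                acts = [xb]
                a = xb
                masks = []
                for i in range(n_layers - 1):
                    a = np.maximum(a @ coefs[i] + intercepts[i], 0.0)
                    if keep < 1.0:
                        mask = (rng.random(a.shape) < keep).astype(np.float32) / keep
                        a = a * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    acts.append(a)
                z = a @ coefs[-1] + intercepts[-1]
                p = 1.0 / (1.0 + np.exp(-z[:, 0]))
                pc = np.clip(p, _EPS, 1.0 - _EPS)
                wsum = float(wb.sum())
                epoch_loss += float(
                    -(wb * (yb * np.log(pc) + (1 - yb) * np.log(1 - pc))).sum()
                )
                epoch_weight += wsum
                # backward: d(loss)/dz for sigmoid + weighted BCE
                delta = ((p - yb) * wb / wsum)[:, None].astype(np.float32)
                grads_w = [None] * n_layers
                grads_b = [None] * n_layers
                for i in range(n_layers - 1, -1, -1):
                    grads_w[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ coefs[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0.0)
                t_step += 1
                params = coefs + intercepts
                grads = grads_w + grads_b
                lr_t = self.learning_rate * np.sqrt(1 - beta2**t_step) / (1 - beta1**t_step)
                for k, (prm, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    prm -= (lr_t * m[k] / (np.sqrt(v[k]) + adam_eps)).astype(np.float32)
            loss_curve.append(epoch_loss / max(epoch_weight, 1e-12))
            vloss, _ = val_loss_and_probs(X_val, y_val32, sw_val)
            val_curve.append(vloss)
            if vloss < best_loss - self.min_delta:
                best_loss = vloss
                best_epoch = epoch
                best_weights = (
                    [w.copy() for w in coefs],
                    [b.copy() for b in intercepts],
                )
            if epoch - best_epoch >= self.patience:
                break

        if best_weights is not None:
            coefs, intercepts = best_weights
        self.coefs_ = coefs
        self.intercepts_ = intercepts
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.loss_curve_ = loss_curve
        self.validation_loss_curve_ = val_curve
        self.n_epochs_ = len(loss_curve)
        self.feature_layout_ = tuple(feature_layout) if feature_layout else None
        _, p_val = val_loss_and_probs(X_val, y_val32, sw_val)
        self.heldout_auc_ = evaluate_auc(y_val.astype(int), p_val)
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[0] == 0:
            if X.shape[1] != self.n_features_in_:
                raise LayoutError(
                    f"model expects {self.n_features_in_} features, got {X.shape[1]}"
                )
            return np.empty((0, 2), dtype=np.float64)
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise LayoutError(
                f"model expects {self.n_features_in_} features, got {X.shape[1]}"
            )
        p = self._forward(X.astype(np.float32)).astype(np.float64)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def editing_probability(self, X) -> np.ndarray:
        """Probability that each read is edited (positive-class column)."""
        return self.predict_proba(X)[:, 1]

    # ------------------------------------------------------------------
    def config_hash(self) -> str:
        payload = {
            "params": self.get_params(),
            "feature_layout": list(self.feature_layout_ or []),
            "n_features": int(getattr(self, "n_features_in_", 0)),
        }
        payload["params"]["hidden_layer_sizes"] = list(
            payload["params"]["hidden_layer_sizes"]
        )
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()

    def weights_hash(self) -> str:
        check_is_fitted(self, "coefs_")
        h = hashlib.sha256()
        for arr in [*self.coefs_, *self.intercepts_]:
            h.update(np.ascontiguousarray(arr, dtype=np.float32).tobytes())
        return h.hexdigest()

    def save(self, path) -> None:
        """Serialize to a portable JSON container.

        Weights are stored as exact decimal representations of their
        float32 values, so load() reproduces predictions bit for bit.
        """
        check_is_fitted(self, "coefs_")
        params = self.get_params()
        params["hidden_layer_sizes"] = list(params["hidden_layer_sizes"])
        doc = {
            "format": "inophase-model",
            "format_version": 1,
            "params": params,
            "config_hash": self.config_hash(),
            "weights_hash": self.weights_hash(),
            "n_features": int(self.n_features_in_),
            "feature_layout": list(self.feature_layout_ or []) or None,
            "coefs": [w.astype(np.float64).tolist() for w in self.coefs_],
            "intercepts": [b.astype(np.float64).tolist() for b in self.intercepts_],
            "metrics": {
                "heldout_auc": float(self.heldout_auc_),
                "loss_curve": [float(x) for x in self.loss_curve_],
                "validation_loss_curve": [float(x) for x in self.validation_loss_curve_],
                "n_epochs": int(self.n_epochs_),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "ReadEditingClassifier":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "inophase-model":
            raise ValidationError(f"{path} is not an inophase model container")
        params = dict(doc["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        model.coefs_ = [np.asarray(w, dtype=np.float32) for w in doc["coefs"]]
        model.intercepts_ = [
            np.asarray(b, dtype=np.float32) for b in doc["intercepts"]
        ]
        model.n_features_in_ = int(doc["n_features"])
        model.classes_ = np.array([0, 1])
        layout = doc.get("feature_layout")
        model.feature_layout_ = tuple(layout) if layout else None
        metrics = doc.get("metrics", {})
        model.heldout_auc_ = metrics.get("heldout_auc", float("nan"))
        model.loss_curve_ = metrics.get("loss_curve", [])
        model.validation_loss_curve_ = metrics.get("validation_loss_curve", [])
        model.n_epochs_ = metrics.get("n_epochs", len(model.loss_curve_))
        if doc.get("weights_hash") and doc["weights_hash"] != model.weights_hash():
            raise ValidationError("stored weights hash does not match contents")
        return model


def train(
    features: FeatureMatrix, labels: Sequence[int], **params
) -> ReadEditingClassifier:
    """Fit a classifier on a FeatureMatrix; labels are 0/1 per row."""
    y = np.asarray(labels)
    if len(y) != len(features):
        raise ValidationError("labels and feature rows differ in length")
    model = ReadEditingClassifier(**params)
    return model.fit(features.X, y, feature_layout=features.layout)


def predict(model: ReadEditingClassifier, features: FeatureMatrix):
    """Per-(read, site) editing probabilities, batch order preserved."""
    import pandas as pd

    if model.feature_layout_ is not None and features.layout != model.feature_layout_:
        raise LayoutError(
            "feature layout does not match the layout stored in the model"
        )
    out = features.index.reset_index(drop=True).copy()
    if len(features) == 0:
        out["probability"] = np.empty(0, dtype=np.float64)
        return out
    out["probability"] = model.editing_probability(features.X)
    return out
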