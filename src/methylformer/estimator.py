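"""Scikit-learn-style estimator wrapping the NumPy transformer.

`MethylationTransformer` is a binary classifier over event windows: ``X`` is
either a 3-D array of shape (n_windows, window, 7) or its 2-D flattened form
(n_windows, window * 7); ``y`` holds 0/1 methylation labels.  ``fit``
accepts an optional ``groups`` array of per-window site keys and then splits
train/validation by site (GroupShuffleSplit), so validation sites are never
seen in training — the leakage-free protocol used throughout the package.
Model selection keeps the epoch with the best validation F1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GroupShuffleSplit, ShuffleSplit

from .metrics import confusion as _confusion, metrics as _metrics_fn, roc_auc as _roc_auc
from .features import N_EVENT_FEATURES
from .model import Adam, ModelConfig, TransformerNet
from .positional import PEConfig


class MethylationTransformer(ClassifierMixin, BaseEstimator):
    """Transformer encoder classifier for centre-event 5mC calling.

    Parameters mirror the architecture and training knobs: ``window`` (odd
    number of events per input, default 21), ``d_model`` (even, multiple of
    ``n_heads``), ``pe_mode`` ("concat" appends an ``n_pe``-wide sinusoidal
    embedding with ``d_model = n_pe + 7``; "sum" projects the 7 features to
    ``d_model`` and adds the embedding), minibatch size / learning rate /
    epoch count for Adam on the cross-entropy loss.

    Fitted attributes: ``net_`` (the trained network), ``history_``
    (per-epoch DataFrame of losses and validation metrics), ``best_epoch_``,
    ``classes_``, ``n_features_in_``.
    """

    def __init__(
        self,
        window: int = 21,
        d_model: int = 16,
        n_heads: int = 2,
        n_layers: int = 2,
        d_ff: Optional[int] = None,
        pe_mode: str = "concat",
        pe_w0: float = 1e-4,
        dropout: float = 0.05,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        epochs: int = 50,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.window = window
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.pe_mode = pe_mode
        self.pe_w0 = pe_w0
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ utils

    def _model_config(self) -> ModelConfig:
        pe = PEConfig(
            mode=self.pe_mode,
            n_pe=self.d_model - N_EVENT_FEATURES if self.pe_mode == "concat" else self.d_model,
            d_model=self.d_model,
            w0=self.pe_w0,
        )
        return ModelConfig(
            d_model=self.d_model,
            n_heads=self.n_heads,
            n_layers=self.n_layers,
            d_ff=self.d_ff,
            window=self.window,
            pe=pe,
            dropout=self.dropout,
            seed=self.random_state,
        )

    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != self.window * N_EVENT_FEATURES:
                raise ValueError(
                    f"2-D input must have {self.window * N_EVENT_FEATURES} columns "
                    f"(window {self.window} x 7), got {X.shape[1]}"
                )
            X = X.reshape(X.shape[0], self.window, N_EVENT_FEATURES)
        if X.ndim != 3 or X.shape[1:] != (self.window, N_EVENT_FEATURES):
            raise ValueError(
                f"expected windows of shape (n, {self.window}, 7), got {X.shape}"
            )
        return X

    # -------------------------------------------------------------------- fit

    def fit(self, X, y, groups: Optional[np.ndarray] = None) -> "MethylationTransformer":
        X = self._coerce_X(X)
        y = np.asarray(y, dtype=int)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different lengths")
        classes = np.unique(y)
        if not set(classes.tolist()) <= {0, 1}:
            raise ValueError("labels must be 0 (unmethylated) or 1 (methylated)")
        if classes.size < 2:
            raise ValueError("training labels contain a single class; need both")

        cfg = self._model_config()
        net = TransformerNet(cfg)
        rng = np.random.default_rng(self.random_state)
        opt = Adam(net.params, lr=self.learning_rate)

        n = X.shape[0]
        if self.validation_fraction > 0.0:
            if groups is not None:
                splitter = GroupShuffleSplit(
                    n_splits=1, test_size=self.validation_fraction,
                    random_state=self.random_state,
                )
                train_idx, val_idx = next(splitter.split(X, y, groups))
            else:
                splitter = ShuffleSplit(
                    n_splits=1, test_size=self.validation_fraction,
                    random_state=self.random_state,
                )
                train_idx, val_idx = next(splitter.split(X, y))
        else:
            train_idx, val_idx = np.arange(n), np.array([], dtype=int)
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("training split contains a single class; need both")

        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        # fix the input standardization from the training windows
        flat = Xtr.reshape(-1, N_EVENT_FEATURES)
        scale = flat.std(axis=0)
        scale[scale == 0.0] = 1.0
        net.set_input_stats(flat.mean(axis=0), scale)

        rows = []
        best_f1 = -np.inf
        best_params = net.copy_params()
        best_epoch = 0
        for epoch in range(1, self.epochs + 1):
            perm = rng.permutation(Xtr.shape[0])
            losses, weights = [], []
            for start in range(0, Xtr.shape[0], self.batch_size):
                idx = perm[start : start + self.batch_size]
                loss, grads = net.loss_and_grads(Xtr[idx], ytr[idx], rng=rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                opt.step(net.params, grads)
                losses.append(loss)
                weights.append(idx.size)
            train_loss = float(np.average(losses, weights=weights))
            row = {"epoch": epoch, "train_loss": train_loss}
            if val_idx.size:
                probs = net.predict_proba(Xval)[:, 1]
                eps = 1e-12
                val_loss = float(
                    -np.mean(
                        np.where(yval == 1, np.log(probs + eps), np.log(1 - probs + eps))
                    )
                )
                calls = (probs > 0.5).astype(int)
                rep = _metrics_fn(_confusion(yval, calls))
                try:
                    auc = _roc_auc(yval, probs)
                except ValueError:
                    auc = float("nan")
                row.update(
                    val_loss=val_loss,
                    val_accuracy=rep.accuracy,
                    val_precision=rep.precision,
                    val_recall=rep.recall,
                    val_f1=rep.f1,
                    val_auc=auc,
                )
                if rep.f1 > best_f1:
                    best_f1 = rep.f1
                    best_params = net.copy_params()
                    best_epoch = epoch
            else:
                best_params = net.copy_params()
                best_epoch = epoch
            rows.append(row)

        net.set_params_(best_params)
        self.net_ = net
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.window * N_EVENT_FEATURES
        self.train_indices_ = train_idx
        self.validation_indices_ = val_idx
        return self

    # ---------------------------------------------------------------- predict

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.net_.predict_proba(self._coerce_X(X))

    def predict(self, X) -> np.ndarray:
        """Hard calls: 1 iff p_methylated > 0.5 (ties are unmethylated)."""
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit first")
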