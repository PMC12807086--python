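"""Training, evaluation and ablation harness over labeled feature windows.

Thin orchestration over :class:`~methylformer.estimator.MethylationTransformer`:
``train`` fits a model from a :class:`~methylformer.features.WindowSet` and
returns the best-validation-F1 network plus its per-epoch trace; ``evaluate``
scores predictions against labels; ``ablate`` runs the position-embedding
(sum vs concat) and window-size grids on one dataset with shared seeds and
emits a tidy per-epoch table, so all the tuning experiments come from a
single code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricReport as _MetricReport, confusion as _confusion, metrics as _metrics_fn, roc_auc as _roc_auc
from .estimator import MethylationTransformer
from .features import WindowSet, build_window_set
from .io import Event, LabeledSite
from .model import ModelConfig, TransformerNet

logger = logging.getLogger(__name__)

ABLATION_COLUMNS = [
    "mode_or_param", "seed", "epoch", "train_loss", "val_loss", "val_f1", "val_auc",
]


@dataclass
class TrainConfig:
    """Optimization knobs: Adam on 2-class cross-entropy."""

    batch_size: int = 256
    learning_rate: float = 1e-3
    epochs: int = 50
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainResult:
    estimator: MethylationTransformer
    trace: pd.DataFrame
    best_epoch: int

    @property
    def net(self) -> TransformerNet:
        return self.estimator.net_


def _estimator_from_configs(
    model_cfg: ModelConfig, train_cfg: TrainConfig
) -> MethylationTransformer:
    return MethylationTransformer(
        window=model_cfg.window,
        d_model=model_cfg.d_model,
        n_heads=model_cfg.n_heads,
        n_layers=model_cfg.n_layers,
        d_ff=model_cfg.d_ff,
        pe_mode=model_cfg.pe.mode,
        pe_w0=model_cfg.pe.w0,
        dropout=model_cfg.dropout,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        epochs=train_cfg.epochs,
        validation_fraction=train_cfg.validation_fraction,
        random_state=train_cfg.seed,
    )


def train(
    windows: WindowSet,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    group_by_site: bool = True,
) -> TrainResult:
    """Fit the classifier on a labeled window set.

    The validation split is grouped by genomic site by default, so the same
    site never appears on both sides.  Raises on unlabeled input, a
    single-class label set, or a non-finite loss.
    """
    if windows.y is None:
        raise ValueError("window set carries no labels")
    mask = windows.y >= 0
    X, y = windows.X[mask], windows.y[mask]
    groups = windows.groups[mask] if group_by_site else None
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    if model_cfg.window != windows.window:
        raise ValueError(
            f"model window {model_cfg.window} does not match window set "
            f"width {windows.window}"
        )
    est = _estimator_from_configs(model_cfg, train_cfg)
    est.fit(X, y, groups=groups)
    for row in est.history_.itertuples(index=False):
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%s val_f1=%s",
            row.epoch, row.train_loss,
            getattr(row, "val_loss", None), getattr(row, "val_f1", None),
        )
    return TrainResult(estimator=est, trace=est.history_, best_epoch=est.best_epoch_)


def evaluate(
    labels: Sequence[int],
    probabilities: Optional[Sequence[float]] = None,
    calls: Optional[Sequence[int]] = None,
) -> _MetricReport:
    """Score predictions: Eqs.-style metrics from hard calls, AUC from probabilities."""
    labels = np.asarray(labels, dtype=int)
    if calls is None:
        if probabilities is None:
            raise ValueError("provide probabilities and/or calls")
        calls = (np.asarray(probabilities, dtype=float) > 0.5).astype(int)
    auc = None
    if probabilities is not None:
        try:
            auc = _roc_auc(labels, probabilities)
        except ValueError:
            auc = None
    return _metrics_fn(_confusion(labels, calls), auc=auc)


def ablate(
    events_by_read: Mapping[str, Sequence[Event]],
    labels: Iterable[LabeledSite],
    pe_modes: Sequence[str] = ("sum", "concat"),
    window_sizes: Sequence[int] = (),
    seeds: Sequence[int] = (0,),
    d_model: int = 16,
    n_heads: int = 2,
    n_layers: int = 2,
    epochs: int = 10,
    batch_size: int = 256,
    learning_rate: float = 1e-3,
    validation_fraction: float = 0.2,
    window: int = 21,
) -> pd.DataFrame:
    """Run the embedding-strategy and window-size grids on one dataset.

    Each grid point is trained per seed on identically featurized data and
    contributes one row per epoch with columns ``mode_or_param, seed, epoch,
    train_loss, val_loss, val_f1, val_auc``.
    """
    labels = list(labels)
    rows = []

    def run(ws: WindowSet, tag: str, pe_mode: str, w: int, seed: int) -> None:
        est = MethylationTransformer(
            window=w, d_model=d_model, n_heads=n_heads, n_layers=n_layers,
            pe_mode=pe_mode, batch_size=batch_size, learning_rate=learning_rate,
            epochs=epochs, validation_fraction=validation_fraction,
            random_state=seed,
        )
        mask = ws.y >= 0
        est.fit(ws.X[mask], ws.y[mask], groups=ws.groups[mask])
        for r in est.history_.itertuples(index=False):
            rows.append(
                {
                    "mode_or_param": tag,
                    "seed": seed,
                    "epoch": r.epoch,
                    "train_loss": r.train_loss,
                    "val_loss": r.val_loss,
                    "val_f1": r.val_f1,
                    "val_auc": r.val_auc,
                }
            )

    base_ws = build_window_set(events_by_read, w=window, labels=labels)
    for mode in pe_modes:
        for seed in seeds:
            run(base_ws, f"pe={mode}", mode, window, seed)
    for w in window_sizes:
        ws = base_ws if w == window else build_window_set(events_by_read, w=w, labels=labels)
        for seed in seeds:
            run(ws, f"window={w}", "concat", w, seed)
    return pd.DataFrame(rows, columns=ABLATION_COLUMNS)
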