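"""Sinusoidal position embeddings and the two attachment strategies.

Self-attention is order-agnostic, so the position of each event inside its
window is injected explicitly.  Component ``2j`` of the embedding of window
row ``i`` is ``sin(i * w0^(2j/n))`` and component ``2j + 1`` is
``cos(i * w0^(2j/n))``, with base frequency ``w0 = 1/10000`` and ``n`` the
embedding width; for odd ``n`` the final unpaired component is the sine
term.  Positions are window-relative (0 .. w-1), never genomic.

Two attachment modes are supported and compared in the ablation harness:

* ``concat`` — the n-component embedding is appended to the 7 event
  features, giving ``d_model = n + 7`` (e.g. n = 9 -> 16);
* ``sum`` — the 7-feature vector is first mapped through a learned affine
  projection to ``d_model`` and the ``d_model``-wide embedding is added
  elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .features import N_EVENT_FEATURES

DEFAULT_W0 = 1.0 / 10_000.0

PE_MODES = ("sum", "concat")


class ConfigError(ValueError):
    """Invalid model or embedding configuration."""


@dataclass
class PEConfig:
    """Position-embedding configuration.

    In ``concat`` mode ``d_model = n_pe + 7``; in ``sum`` mode the embedding
    width equals ``d_model`` and ``n_pe`` is ignored.
    """

    mode: str = "concat"
    n_pe: int = 9
    d_model: int = 16
    w0: float = DEFAULT_W0

    def __post_init__(self) -> None:
        if self.mode not in PE_MODES:
            raise ConfigError(f"pe.mode must be one of {PE_MODES}, got {self.mode!r}")
        if self.mode == "concat":
            if self.n_pe < 1:
                raise ConfigError("concat mode requires n_pe >= 1")
            if self.n_pe + N_EVENT_FEATURES != self.d_model:
                raise ConfigError(
                    f"concat mode requires d_model = n_pe + 7; got n_pe={self.n_pe}, "
                    f"d_model={self.d_model}"
                )
        if self.d_model % 2 != 0:
            raise ConfigError(f"d_model must be an even integer, got {self.d_model}")

    @property
    def pe_width(self) -> int:
        return self.n_pe if self.mode == "concat" else self.d_model


def sinusoidal_pe(position: int, width: int, w0: float = DEFAULT_W0) -> np.ndarray:
    """Sinusoidal embedding vector of one position."""
    if position < 0:
        raise ValueError(f"position must be non-negative, got {position}")
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    cols = np.arange(width)
    freqs = w0 ** ((2 * (cols // 2)) / width)
    angles = position * freqs
    return np.where(cols % 2 == 0, np.sin(angles), np.cos(angles))


def positional_encoding(length: int, width: int, w0: float = DEFAULT_W0) -> np.ndarray:
    """(length x width) matrix of sinusoidal embeddings for positions 0..length-1."""
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    pos = np.arange(length, dtype=float)[:, None]
    cols = np.arange(width)
    # paired frequency ladder: columns 2j and 2j+1 share exponent 2j/width
    freqs = w0 ** ((2 * (cols // 2)) / width)
    angles = pos * freqs[None, :]
    pe = np.where(cols % 2 == 0, np.sin(angles), np.cos(angles))
    return pe


def attach_pe(
    window: np.ndarray,
    cfg: PEConfig,
    projection: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    zero_pe: bool = False,
) -> np.ndarray:
    """Attach position information to a (w x 7) feature window.

    ``concat`` mode appends the embedding, preserving the 7 event features
    verbatim in columns 0-6.  ``sum`` mode requires the model's learned
    input projection ``(W, b)`` with ``W`` of shape (7, d_model).  With
    ``zero_pe`` the embedding block is replaced by zeros — a diagnostic
    probe that makes the downstream encoder order-agnostic.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != N_EVENT_FEATURES:
        raise ValueError(f"window must be (w x 7), got {window.shape}")
    w = window.shape[0]
    pe = positional_encoding(w, cfg.pe_width, cfg.w0)
    if zero_pe:
        pe = np.zeros_like(pe)
    if cfg.mode == "concat":
        return np.concatenate([window, pe], axis=1)
    if projection is None:
        raise ConfigError("sum mode requires the learned input projection (W, b)")
    W, b = projection
    if W.shape != (N_EVENT_FEATURES, cfg.d_model):
        raise ConfigError(
            f"input projection must be (7 x {cfg.d_model}), got {W.shape}"
        )
    return window @ W + b + pe
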