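"""Signal normalization, per-event features, and context-window assembly.

Each event is summarized as a 7-feature vector
``<f_m, f_sd, f_l, f_A, f_C, f_G, f_T>``: the normalized signal mean, the
population standard deviation, the number of raw samples, and a one-hot
encoding of the reference base in A, C, G, T order.  Candidate sites are
presented to the classifier as a window of ``w`` consecutive events
(``w`` odd, default 21) centred on the event of interest; windows whose
centre lies within ``⌊w/2⌋`` events of a read end are skipped rather than
padded, so every emitted window is fully observed.

Normalization is per read: all raw samples of a read are pooled, centred on
their median, scaled by 1.4826 x the median absolute deviation (a robust
sigma estimate), and clipped to [-5, 5].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import Event

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: number of per-event features (mean, sd, length, 4x one-hot)
N_EVENT_FEATURES = 7

SIGNAL_CLIP = 5.0
MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian data


def normalize_read(
    samples_per_event: Sequence[np.ndarray],
) -> List[np.ndarray]:
    """Median/MAD-standardize all samples of one read, clipping to [-5, 5].

    The location and scale are estimated on the pooled samples of the whole
    read, then applied to every event, so per-event structure is preserved.
    A constant read (MAD = 0) falls back to unit scale with a warning.
    """
    if len(samples_per_event) == 0:
        raise ValueError("read contains no events")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples_per_event])
    if pooled.size == 0:
        raise ValueError("read contains no signal samples")
    med = float(np.median(pooled))
    mad = float(np.median(np.abs(pooled - med)))
    scale = MAD_SCALE * mad
    if scale == 0.0:
        warnings.warn(
            "constant signal in read (MAD = 0); falling back to unit scale",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = 1.0
    return [
        np.clip((np.asarray(s, dtype=float) - med) / scale, -SIGNAL_CLIP, SIGNAL_CLIP)
        for s in samples_per_event
    ]


def one_hot(base: str) -> np.ndarray:
    """One-hot encode a reference base in fixed A, C, G, T order."""
    try:
        idx = _BASE_INDEX[base]
    except KeyError:
        raise ValueError(f"invalid base {base!r}; expected one of A, C, G, T") from None
    vec = np.zeros(4)
    vec[idx] = 1.0
    return vec


def featurize_samples(samples: np.ndarray, base: str) -> np.ndarray:
    """7-feature vector from (already normalized) samples and a reference base.

    f_m is the arithmetic mean, f_sd the population (ddof = 0) standard
    deviation, f_l the sample count.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot featurize an event with no samples")
    out = np.empty(N_EVENT_FEATURES)
    out[0] = samples.mean()
    out[1] = samples.std(ddof=0)
    out[2] = float(samples.size)
    out[3:7] = one_hot(base)
    return out


def featurize_event(event: Event) -> np.ndarray:
    """7-feature vector of one event whose samples are already normalized."""
    return featurize_samples(event.samples, event.ref_base)


@dataclass
class FeatureWindow:
    """A w x 7 feature matrix labeled at its centre event."""

    center: Tuple[str, str, str, int]  # (read_id, chrom, strand, ref_pos)
    matrix: np.ndarray
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        w = self.matrix.shape[0]
        if w % 2 == 0 or self.matrix.ndim != 2 or self.matrix.shape[1] != N_EVENT_FEATURES:
            raise ValueError(f"window matrix must be (odd w) x 7, got {self.matrix.shape}")


def extract_windows(
    events: Sequence[Event],
    candidate_positions: Iterable[int],
    w: int = 21,
    labels: Optional[Mapping[int, int]] = None,
    features: Optional[np.ndarray] = None,
) -> Tuple[List[FeatureWindow], int]:
    """Assemble centre-event context windows for one read.

    ``events`` must be sorted by reference position (the reader's contract);
    rows are ordered by event order within the read.  ``candidate_positions``
    are reference positions; candidates without ``⌊w/2⌋`` events on both
    sides are skipped and counted in the second return value.  ``labels``
    optionally maps candidate ref_pos -> {0,1}.  ``features`` may carry a
    precomputed (n_events x 7) matrix (e.g. from normalized samples) to
    avoid re-featurizing.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be a positive odd integer, got {w}")
    half = w // 2
    if features is None:
        normed = normalize_read([e.samples for e in events])
        features = np.stack(
            [featurize_samples(s, e.ref_base) for s, e in zip(normed, events)]
        ) if events else np.empty((0, N_EVENT_FEATURES))
    pos_to_idx = {e.ref_pos: i for i, e in enumerate(events)}
    windows: List[FeatureWindow] = []
    skipped = 0
    for pos in sorted(set(candidate_positions)):
        idx = pos_to_idx.get(pos)
        if idx is None:
            continue
        if idx < half or idx >= len(events) - half:
            skipped += 1
            continue
        e = events[idx]
        label = labels.get(pos) if labels is not None else None
        windows.append(
            FeatureWindow(
                center=(e.read_id, e.chrom, e.strand, e.ref_pos),
                matrix=features[idx - half : idx + half + 1],
                label=label,
            )
        )
    return windows, skipped


def find_cpg_candidates(sequence: str, strand_mode: str = "forward"):
    """Locate CpG candidate positions in an uppercase reference sequence.

    ``forward`` mode returns 0-based positions ``p`` with ``seq[p] == 'C'``
    and ``seq[p+1] == 'G'``.  ``both`` mode additionally returns ``p + 1``
    flagged minus-strand — the cytosine of the palindromic CpG on the
    reverse complement — as ``(pos, strand)`` tuples.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    fwd = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    if strand_mode == "forward":
        return [int(p) for p in fwd]
    if strand_mode == "both":
        out = [(int(p), "+") for p in fwd]
        out += [(int(p) + 1, "-") for p in fwd]
        return sorted(out)
    raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")


@dataclass
class WindowSet:
    """A batch of feature windows as dense arrays plus a site index.

    ``X`` has shape (n_windows, w, 7); ``y`` is None when unlabeled.  The
    index carries (read_id, chrom, strand, ref_pos) per window; ``groups``
    gives a site key per window, used for leakage-free grouped splits.
    """

    X: np.ndarray
    index: pd.DataFrame
    y: Optional[np.ndarray] = None
    n_edge_skipped: int = 0

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def window(self) -> int:
        return self.X.shape[1]

    @property
    def groups(self) -> np.ndarray:
        idx = self.index
        return (
            idx["chrom"].astype(str)
            + ":"
            + idx["ref_pos"].astype(str)
            + ":"
            + idx["strand"].astype(str)
        ).to_numpy()


def build_window_set(
    events_by_read: Mapping[str, Sequence[Event]],
    w: int = 21,
    candidates: Optional[Mapping[Tuple[str, str], Iterable[int]]] = None,
    labels: Optional[Iterable] = None,
) -> WindowSet:
    """Normalize, featurize and window every read of an event table.

    ``candidates`` maps (chrom, strand) to candidate reference positions
    (e.g. from :func:`find_cpg_candidates`).  ``labels`` is an iterable of
    :class:`~methylformer.io.LabeledSite`; when given, labeled positions
    define the candidates for each read and windows carry labels.
    """
    label_map: Dict[Tuple[str, str, str], Dict[int, int]] = {}
    if labels is not None:
        for s in labels:
            label_map.setdefault((s.read_id, s.chrom, s.strand), {})[s.ref_pos] = s.label
    if candidates is not None:
        cand_sets = {key: set(vals) for key, vals in candidates.items()}

    mats, rows, ys = [], [], []
    skipped = 0
    for read_id, events in events_by_read.items():
        if not events:
            continue
        chrom, strand = events[0].chrom, events[0].strand
        read_labels = label_map.get((read_id, chrom, strand))
        if labels is not None:
            if not read_labels:
                continue
            cand = read_labels.keys()
        elif candidates is not None:
            cand = cand_sets.get((chrom, strand), ())
        else:
            raise ValueError("either candidates or labels must be provided")
        windows, n_skip = extract_windows(events, cand, w=w, labels=read_labels)
        skipped += n_skip
        for win in windows:
            mats.append(win.matrix)
            rows.append(win.center)
            ys.append(win.label)

    X = np.stack(mats) if mats else np.empty((0, w, N_EVENT_FEATURES))
    index = pd.DataFrame(rows, columns=["read_id", "chrom", "strand", "ref_pos"])
    y = None
    if labels is not None:
        y = np.array([-1 if v is None else v for v in ys], dtype=int)
    return WindowSet(X=X, index=index, y=y, n_edge_skipped=skipped)
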