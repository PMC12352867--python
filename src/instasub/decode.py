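"""Sliding-subspace decoding of object identity from trajectory segments.

Single-trial 100 ms segments clipped at one behavioral event are projected
into the time series of instantaneous 3D subspaces on a 50 ms grid; at each
grid time a fresh bidirectional LSTM classifier (3 inputs, 20 hidden units
per direction, softmax over the 4 objects) is trained on 40% of a
class-balanced trial sample and scored on the held-out 60%.  Ten folds give
the mean +/- SD accuracy curve; projecting the same segments into randomly
drawn 3D subspaces instead calibrates the chance band.

Class balancing follows the minimum-trial rule: each object contributes
exactly the minimum per-object trial count, drawn with replacement.  To keep
the train/test split disjoint at the trial level, each object's available
trials are first partitioned 40/60 and the balanced resamples are then drawn
within each partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from ._rng import substream
from .core_io import OBJECTS
from .lstm import BiLSTMClassifier
from .preprocess import AlignedTensor
from .segments import SEGMENT_LEN, clip_segments
from .subspace import SubspaceSeries, random_frame

__all__ = [
    "DecodeCurve",
    "balance_trials",
    "default_grid",
    "slide_decode",
    "chance_decode",
    "cross_project_decode",
]


@dataclass
class DecodeCurve:
    """Classification-accuracy time course on the 50 ms subspace grid."""

    segment_event: str
    pairing: str  # "within" | "cross"
    grid_columns: np.ndarray  # (G,) column indices into the aligned axis
    events: np.ndarray  # (G,)
    offsets: np.ndarray  # (G,)
    accuracy: np.ndarray  # (folds, G)
    accuracy_mean: np.ndarray = field(init=False)
    accuracy_sd: np.ndarray = field(init=False)
    chance_mean: float = np.nan
    chance_sd: float = np.nan

    def __post_init__(self):
        self.accuracy_mean = self.accuracy.mean(axis=0)
        self.accuracy_sd = self.accuracy.std(axis=0, ddof=0)


def balance_trials(
    counts: Dict[str, int], rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Minimum-count balanced resample: each object contributes min(counts)
    trial indices sampled with replacement from its available trials."""
    if min(counts.values()) < 1:
        raise ValueError("every object needs at least one trial")
    m = min(counts.values())
    return {o: rng.integers(0, counts[o], size=m) for o in OBJECTS}


def _balanced_split(
    counts: Dict[str, int], rng: np.random.Generator, train_frac: float = 0.4
):
    """Disjoint 40/60 trial-level split, then balanced with-replacement
    resamples within each side."""
    m = min(counts.values())
    m_train = max(1, int(round(train_frac * m)))
    m_test = max(1, m - m_train)
    train, test = {}, {}
    for o in OBJECTS:
        perm = rng.permutation(counts[o])
        n_tr = max(1, int(round(train_frac * counts[o])))
        if n_tr >= counts[o]:
            n_tr = counts[o] - 1
        pool_tr, pool_te = perm[:n_tr], perm[n_tr:]
        train[o] = pool_tr[rng.integers(0, pool_tr.size, size=m_train)]
        test[o] = pool_te[rng.integers(0, pool_te.size, size=m_test)]
    return train, test


def default_grid(tensor: AlignedTensor, step: int = 50) -> np.ndarray:
    """Grid columns at ``step`` ms spacing, anchored at each block's start."""
    cols = []
    ev = tensor.events
    boundaries = np.flatnonzero(np.r_[True, ev[1:] != ev[:-1]])
    block_edges = list(boundaries) + [tensor.T]
    for a, b in zip(block_edges[:-1], block_edges[1:]):
        cols.extend(range(a, b, step))
    return np.array(cols, dtype=int)


def _single_trial_segments(tensor: AlignedTensor, event: str):
    segs = clip_segments(tensor, event, level="single-trial")
    return {o: segs[o].data for o in OBJECTS}  # (K, 100, N)


def _evaluate_frame(
    data: Dict[str, np.ndarray],
    train: Dict[str, np.ndarray],
    test: Dict[str, np.ndarray],
    basis: np.ndarray,
    center: np.ndarray,
    rng: np.random.Generator,
    n_hidden: int,
    max_epochs: int,
    lr: float,
    batch_size: int,
) -> float:
    def project(idx_map):
        X, y = [], []
        for ci, o in enumerate(OBJECTS):
            lat = (data[o][idx_map[o]] - center) @ basis  # (k, 100, 3)
            X.append(lat)
            y.extend([ci] * len(idx_map[o]))
        return np.concatenate(X), np.array(y, dtype=int)

    Xtr, ytr = project(train)
    Xte, yte = project(test)
    clf = BiLSTMClassifier(n_inputs=3, n_hidden=n_hidden, n_classes=4, rng=rng)
    clf.fit(Xtr, ytr, max_epochs=max_epochs, lr=lr, batch_size=batch_size, rng=rng)
    return clf.score(Xte, yte)


def slide_decode(
    tensor: AlignedTensor,
    series: SubspaceSeries,
    segment_event: str,
    folds: int = 10,
    grid_step: int = 50,
    grid_columns: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_hidden: int = 20,
    max_epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 16,
    pairing: str = "within",
    rng_label: str = "decode",
) -> DecodeCurve:
    """Accuracy of the event's segments projected along the subspace series.

    The balanced trial sample and its 40/60 split are drawn once per fold and
    reused at every grid time, so grid times are comparable within a fold.
    """
    if series.T != tensor.T:
        raise ValueError("subspace series does not cover the tensor's time base")
    grid = (
        np.asarray(grid_columns, dtype=int)
        if grid_columns is not None
        else default_grid(tensor, grid_step)
    )
    data = _single_trial_segments(tensor, segment_event)
    counts = {o: data[o].shape[0] for o in OBJECTS}
    acc = np.empty((folds, grid.size))
    for f in range(folds):
        rng = substream(seed, rng_label, segment_event, f)
        train, test = _balanced_split(counts, rng)
        for gi, t in enumerate(grid):
            acc[f, gi] = _evaluate_frame(
                data,
                train,
                test,
                series.bases[t],
                series.centroid(t),
                substream(seed, rng_label, segment_event, f, int(t)),
                n_hidden,
                max_epochs,
                lr,
                batch_size,
            )
    return DecodeCurve(
        segment_event=segment_event,
        pairing=pairing,
        grid_columns=grid,
        events=tensor.events[grid],
        offsets=tensor.offsets[grid],
        accuracy=acc,
    )


def chance_decode(
    tensor: AlignedTensor,
    segment_event: str,
    n_rand: int = 500,
    seed: int = 0,
    n_hidden: int = 20,
    max_epochs: int = 100,
    lr: float = 1e-3,
    batch_size: int = 16,
):
    """Accuracy distribution over randomly drawn 3D projection subspaces.

    Returns (mean, sd) of test accuracy across ``n_rand`` random 3-frames
    (Gaussian-QR); each repetition redraws the balanced trial sample.
    """
    data = _single_trial_segments(tensor, segment_event)
    counts = {o: data[o].shape[0] for o in OBJECTS}
    n = tensor.n_units
    grand = np.mean([data[o].mean(axis=(0, 1)) for o in OBJECTS], axis=0)
    accs = np.empty(n_rand)
    for r in range(n_rand):
        rng = substream(seed, "chance_decode", segment_event, r)
        train, test = _balanced_split(counts, rng)
        frame = random_frame(n, rng)
        accs[r] = _evaluate_frame(
            data, train, test, frame, grand, rng, n_hidden, max_epochs, lr, batch_size
        )
    return float(accs.mean()), float(accs.std(ddof=0))


def cross_project_decode(
    tensor_a: AlignedTensor,
    series_b: SubspaceSeries,
    segment_event: str,
    **kwargs,
) -> DecodeCurve:
    """Segments from one context decoded in the other context's subspaces."""
    if series_b.T != tensor_a.T or not np.array_equal(series_b.events, tensor_a.events):
        raise ValueError("mismatched time bases between segments and subspace series")
    kwargs.setdefault("pairing", "cross")
    kwargs.setdefault("rng_label", "decode")
    return slide_decode(tensor_a, series_b, segment_event, **kwargs)
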