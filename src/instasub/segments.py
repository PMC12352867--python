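"""Trajectory segments: 100 ms clips at behavioral events, their projection
into instantaneous subspaces, and the cumulative-separation statistic.

A segment is the population trajectory over the 100 ms immediately following
one of the events I, G, M, or H (rows = 1 ms steps).  Projected into a 3D
instantaneous subspace, the four object segments form four low-dimensional
trajectories whose spread is summarized by the cumulative separation

    CS = (1/T) * sum_t sum_{i<j} d_ij(t),        T = 100,

the time-averaged sum of the six pairwise 3D Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .core_io import OBJECTS
from .preprocess import AlignedTensor
from .subspace import SubspaceSeries, instantaneous_subspaces

__all__ = [
    "SEGMENT_LEN",
    "TrajectorySegment",
    "SeparationResult",
    "clip_segments",
    "project_segment",
    "cumulative_separation",
    "separation_grid",
]

SEGMENT_LEN = 100


@dataclass
class TrajectorySegment:
    """100 x N (trial-averaged) or K x 100 x N (single-trial) event-aligned clip."""

    event: str
    object: str
    level: str  # "trial-averaged" | "single-trial"
    data: np.ndarray

    def __post_init__(self):
        rows = self.data.shape[0] if self.level == "trial-averaged" else self.data.shape[1]
        if rows != SEGMENT_LEN:
            raise ValueError(f"segment must have {SEGMENT_LEN} rows, got {rows}")


@dataclass
class SeparationResult:
    CS: float
    D: np.ndarray  # (100,) total pairwise distance per time step
    d_ij: np.ndarray  # (100, 6) the six unordered pairwise distances


def _segment_columns(tensor: AlignedTensor, event: str) -> np.ndarray:
    """Column indices of offsets [0, 100) after ``event`` on the concatenated axis.

    If the event's own block is shorter than 100 ms past the event (possible
    for G when median_reaction/2 < 100), the clip continues into the next
    block, which is contiguous with it in real time.
    """
    start = tensor.column_of(event, 0)
    stop = start + SEGMENT_LEN
    if stop > tensor.T:
        raise ValueError(f"segment at {event} truncated by the end of the axis")
    # Within the block, offsets must advance by 1 ms per column.
    block = tensor.events[start:stop]
    if not np.all(np.diff(tensor.offsets[start:stop][block == event]) == 1):
        raise ValueError(f"non-contiguous columns after event {event}")
    return np.arange(start, stop)


def clip_segments(
    tensor: AlignedTensor, event: str, level: str = "trial-averaged"
) -> Dict[str, TrajectorySegment]:
    """Clip the per-object 100 ms segments starting at ``event``."""
    if level not in ("trial-averaged", "single-trial"):
        raise ValueError(f"unknown level {level!r}")
    cols = _segment_columns(tensor, event)
    out = {}
    for o in OBJECTS:
        x = tensor.tensors[o][:, :, cols]  # (N, K, 100)
        if level == "trial-averaged":
            data = x.mean(axis=1).T  # (100, N)
        else:
            data = np.transpose(x, (1, 2, 0))  # (K, 100, N)
        out[o] = TrajectorySegment(event=event, object=o, level=level, data=data)
    return out


def project_segment(
    seg: TrajectorySegment, basis: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Project a segment into a 3D subspace: L = (X - center) W.

    ``center`` should be the condition-mean centroid of the subspace's time
    step so that latent coordinates are displacements from the instantaneous
    population centroid.
    """
    n = basis.shape[0]
    if seg.data.shape[-1] != n or center.shape[-1] != n:
        raise ValueError("dimension mismatch between segment, basis, and center")
    return (seg.data - center) @ basis


def cumulative_separation(latents: Dict[str, np.ndarray]) -> SeparationResult:
    """Cumulative separation of the four projected object trajectories."""
    segs = [np.asarray(latents[o], dtype=float) for o in OBJECTS]
    T = segs[0].shape[0]
    if any(s.shape != segs[0].shape for s in segs):
        raise ValueError("the four latent segments must share one shape")
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    d = np.empty((T, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        d[:, k] = np.linalg.norm(segs[i] - segs[j], axis=1)
    D = d.sum(axis=1)
    return SeparationResult(CS=float(D.mean()), D=D, d_ij=d)


def separation_grid(tensor: AlignedTensor, series: SubspaceSeries = None) -> pd.DataFrame:
    """CS for every (segment event x subspace event) combination.

    Reproduces the 4 x 4 layout: rows are the events at which segments were
    clipped, columns the events whose instantaneous subspace they were
    projected into; the diagonal is each segment in its own subspace.
    """
    if series is None:
        series = instantaneous_subspaces(tensor)
    events = ("I", "G", "M", "H")
    grid = pd.DataFrame(index=list(events), columns=list(events), dtype=float)
    for seg_ev in events:
        segs = clip_segments(tensor, seg_ev, level="trial-averaged")
        for sub_ev in events:
            t = series.column_of(sub_ev, 0)
            basis, center = series.bases[t], series.centroid(t)
            lat = {o: project_segment(segs[o], basis, center) for o in OBJECTS}
            grid.loc[seg_ev, sub_ev] = cumulative_separation(lat).CS
    grid.index.name = "segment_event"
    return grid
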