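"""Spike times -> event-aligned, smoothed, transformed rate tensors.

The pipeline follows the field's standard single-unit preprocessing: spike
trains are binned at 1 ms, smoothed with a unit-area Gaussian kernel
(sigma = 50 ms by default), and square-root transformed so that the
trial-to-trial variance of the resulting rate estimate is comparable at low
and high firing rates (variance stabilization for Poisson-like counts).

Each trial then contributes four event-aligned snippets that are concatenated
into a single per-trial time axis:

=====  =======================================  ============================
event  window (ms, half-open)                   length
=====  =======================================  ============================
I      [-500, +500) around instruction onset    1000
G      [-median_delay, +median_reaction/2)      md + mr2
M      [-median_reaction/2, +200)               mr2 + 200
H      [-200, +200) around final-hold start     400
=====  =======================================  ============================

so T = 1600 + median_delay + 2*round(median_reaction/2).  The medians are
session-level (pooled over objects) so that all four objects, and both
behavioral contexts of a session, share one time base; this is required for
instantaneous subspace identification, which needs the four object condition
means at every column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core_io import EVENTS, OBJECTS, EpochStats, SessionBundle

__all__ = [
    "SmoothedRates",
    "AlignedTensor",
    "ConditionSplit",
    "bin_and_smooth",
    "sqrt_transform",
    "align_concatenate",
    "condition_split",
    "build_time_map",
    "preprocess_bundle",
    "save_tensor",
    "load_tensor",
    "subset_units",
]

#: Short event codes used on the concatenated axis.
EVENT_CODES = ("I", "G", "M", "H")
_EVENT_FIELD = {"I": "instruction_on", "G": "go", "M": "move_on", "H": "hold_on"}

# Real-time margins binned around each trial so that smoothing near snippet
# edges uses real data; beyond them the kernel sees zeros.
_PAD_PRE = 800
_PAD_POST = 400


@dataclass
class SmoothedRates:
    """Per-trial continuous firing-rate courses (spikes/s) on 1 ms bins.

    ``rates[trial_id]`` is an (n_units, L) array starting at real time
    ``t0[trial_id]`` ms.
    """

    unit_ids: List[str]
    rates: Dict[str, np.ndarray]
    t0: Dict[str, int]
    sigma_ms: float
    sqrt_applied: bool = False


@dataclass
class AlignedTensor:
    """Per-object (N, K, T) rate tensors on the concatenated event axis.

    ``events`` / ``offsets`` map each of the T columns back to
    (event in {I, G, M, H}, offset in ms relative to that event).
    """

    tensors: Dict[str, np.ndarray]
    events: np.ndarray  # (T,) of "I"/"G"/"M"/"H"
    offsets: np.ndarray  # (T,) int ms
    stats: EpochStats
    unit_ids: List[str]
    sigma_ms: float
    sqrt_applied: bool
    trial_ids: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def T(self) -> int:
        return int(self.events.size)

    def column_of(self, event: str, offset: int) -> int:
        """Index of the column at (event, offset); raises if absent."""
        hits = np.flatnonzero((self.events == event) & (self.offsets == offset))
        if hits.size != 1:
            raise KeyError(f"no unique column at ({event}, {offset} ms)")
        return int(hits[0])

    def condition_means(self) -> np.ndarray:
        """Trial-averaged activity per object, shape (4, N, T)."""
        return np.stack([self.tensors[o].mean(axis=1) for o in OBJECTS])

    def same_time_base(self, other: "AlignedTensor") -> bool:
        return (
            self.T == other.T
            and np.array_equal(self.events, other.events)
            and np.array_equal(self.offsets, other.offsets)
        )


@dataclass
class ConditionSplit:
    """Condition-independent course and per-object condition-dependent residuals."""

    ci_course: np.ndarray  # (N, T)
    cd_courses: Dict[str, np.ndarray]  # object -> (N, T)


def build_time_map(median_delay: float, median_reaction: float) -> Tuple[np.ndarray, np.ndarray]:
    """Events and offsets of the concatenated axis for the given medians."""
    md = int(round(median_delay))
    mr2 = int(round(median_reaction / 2.0))
    blocks = [
        ("I", -500, 500),
        ("G", -md, mr2),
        ("M", -mr2, 200),
        ("H", -200, 200),
    ]
    events, offsets = [], []
    for code, a, b in blocks:
        events.extend([code] * (b - a))
        offsets.extend(range(a, b))
    return np.array(events), np.array(offsets, dtype=int)


def bin_and_smooth(bundle: SessionBundle, sigma: float = 50.0) -> SmoothedRates:
    """Bin each unit's spikes at 1 ms and smooth with a Gaussian kernel.

    The kernel has unit area so spike mass is conserved away from edges; the
    output is in spikes/s.  Rates are computed per trial on a window padded
    beyond the trial bounds so that smoothing at snippet edges uses real data
    where it exists.

    Parameters
    ----------
    sigma : float
        Gaussian kernel width in ms; must be positive.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0 ms, got {sigma}")
    unit_ids = [u.unit_id for u in bundle.units]
    spike_arrays = [u.spike_times for u in bundle.units]
    rates: Dict[str, np.ndarray] = {}
    t0s: Dict[str, int] = {}
    for trial in bundle.trials:
        a = trial.event_times["start"] - _PAD_PRE
        b = trial.event_times["end"] + _PAD_POST
        L = b - a
        counts = np.zeros((len(unit_ids), L))
        for i, st in enumerate(spike_arrays):
            lo, hi = np.searchsorted(st, [a, b])
            if hi > lo:
                idx = np.floor(st[lo:hi] - a).astype(int)
                np.add.at(counts[i], np.clip(idx, 0, L - 1), 1.0)
        smoothed = gaussian_filter1d(counts, sigma=sigma, axis=1, mode="constant")
        rates[trial.trial_id] = smoothed * 1000.0  # counts/ms -> spikes/s
        t0s[trial.trial_id] = a
    return SmoothedRates(unit_ids=unit_ids, rates=rates, t0=t0s, sigma_ms=float(sigma))


def sqrt_transform(smoothed: SmoothedRates) -> SmoothedRates:
    """Element-wise square root of the smoothed rates (variance stabilization)."""
    if smoothed.sqrt_applied:
        raise ValueError("sqrt transform already applied")
    out = {}
    for tid, r in smoothed.rates.items():
        if np.any(r < 0):
            raise ValueError(f"negative rate in trial {tid}; upstream bug")
        out[tid] = np.sqrt(r)
    return replace(smoothed, rates=out, sqrt_applied=True)


def align_concatenate(smoothed: SmoothedRates, bundle: SessionBundle, stats: EpochStats) -> AlignedTensor:
    """Clip the four event-aligned snippets per trial and concatenate them.

    Only successful trials enter the tensor.  A trial whose padded rate window
    cannot supply a snippet is excluded with a warning.
    """
    events, offsets = build_time_map(stats.median_delay, stats.median_reaction)
    md = int(round(stats.median_delay))
    mr2 = int(round(stats.median_reaction / 2.0))
    windows = {"I": (-500, 500), "G": (-md, mr2), "M": (-mr2, 200), "H": (-200, 200)}

    per_obj: Dict[str, list] = {o: [] for o in OBJECTS}
    trial_ids: Dict[str, list] = {o: [] for o in OBJECTS}
    for trial in bundle.successful_trials():
        r = smoothed.rates[trial.trial_id]
        t0 = smoothed.t0[trial.trial_id]
        pieces = []
        ok = True
        for code in EVENT_CODES:
            ev_t = trial.event_times[_EVENT_FIELD[code]]
            a, b = windows[code]
            i0, i1 = ev_t + a - t0, ev_t + b - t0
            if i0 < 0 or i1 > r.shape[1]:
                warnings.warn(
                    f"trial {trial.trial_id}: {code} snippet outside rate "
                    "window; trial excluded",
                    stacklevel=2,
                )
                ok = False
                break
            pieces.append(r[:, i0:i1])
        if ok:
            per_obj[trial.object].append(np.concatenate(pieces, axis=1))
            trial_ids[trial.object].append(trial.trial_id)

    tensors = {}
    for o in OBJECTS:
        if not per_obj[o]:
            raise ValueError(f"object {o!r} contributed no trials to the tensor")
        tensors[o] = np.stack(per_obj[o], axis=1)  # (N, K_o, T)
    return AlignedTensor(
        tensors=tensors,
        events=events,
        offsets=offsets,
        stats=stats,
        unit_ids=list(smoothed.unit_ids),
        sigma_ms=smoothed.sigma_ms,
        sqrt_applied=smoothed.sqrt_applied,
        trial_ids=trial_ids,
    )


def condition_split(tensor: AlignedTensor) -> ConditionSplit:
    """Split trial-averaged activity into CI and per-object CD components.

    CI is the unweighted mean of the four object condition means; each CD
    course is that object's condition mean minus CI, so the four CD courses
    sum to zero at every (unit, time) by construction.
    """
    means = tensor.condition_means()  # (4, N, T)
    ci = means.mean(axis=0)
    cd = {o: means[i] - ci for i, o in enumerate(OBJECTS)}
    return ConditionSplit(ci_course=ci, cd_courses=cd)


def save_tensor(tensor: AlignedTensor, path) -> None:
    """Persist an aligned tensor (HDF5: per-object datasets + time map)."""
    import h5py

    with h5py.File(path, "w") as f:
        for o in OBJECTS:
            f.create_dataset(f"tensor/{o}", data=tensor.tensors[o])
            f.create_dataset(
                f"trial_ids/{o}",
                data=np.array(tensor.trial_ids.get(o, []), dtype="S"),
            )
        f.create_dataset("events", data=tensor.events.astype("S1"))
        f.create_dataset("offsets", data=tensor.offsets)
        f.create_dataset("unit_ids", data=np.array(tensor.unit_ids, dtype="S"))
        f.attrs["sigma_ms"] = tensor.sigma_ms
        f.attrs["sqrt_applied"] = tensor.sqrt_applied
        f.attrs["median_delay"] = tensor.stats.median_delay
        f.attrs["median_reaction"] = tensor.stats.median_reaction
        f.attrs["median_movement"] = tensor.stats.median_movement


def load_tensor(path) -> AlignedTensor:
    import h5py

    with h5py.File(path, "r") as f:
        tensors = {o: f[f"tensor/{o}"][...] for o in OBJECTS}
        trial_ids = {
            o: [s.decode() for s in f[f"trial_ids/{o}"][...]] for o in OBJECTS
        }
        return AlignedTensor(
            tensors=tensors,
            events=f["events"][...].astype("U1"),
            offsets=f["offsets"][...],
            stats=EpochStats(
                median_delay=float(f.attrs["median_delay"]),
                median_reaction=float(f.attrs["median_reaction"]),
                median_movement=float(f.attrs["median_movement"]),
            ),
            unit_ids=[s.decode() for s in f["unit_ids"][...]],
            sigma_ms=float(f.attrs["sigma_ms"]),
            sqrt_applied=bool(f.attrs["sqrt_applied"]),
            trial_ids=trial_ids,
        )


def subset_units(tensor: AlignedTensor, indices) -> AlignedTensor:
    """Restrict a tensor to a unit subset (e.g. the MN population)."""
    idx = np.asarray(indices, dtype=int)
    return AlignedTensor(
        tensors={o: tensor.tensors[o][idx] for o in OBJECTS},
        events=tensor.events.copy(),
        offsets=tensor.offsets.copy(),
        stats=tensor.stats,
        unit_ids=[tensor.unit_ids[i] for i in idx],
        sigma_ms=tensor.sigma_ms,
        sqrt_applied=tensor.sqrt_applied,
        trial_ids=tensor.trial_ids,
    )


def preprocess_bundle(
    bundle: SessionBundle,
    stats: EpochStats,
    sigma: float = 50.0,
    sqrt: bool = True,
) -> AlignedTensor:
    """Convenience: bin, smooth, (optionally) sqrt-transform, and align."""
    sm = bin_and_smooth(bundle, sigma=sigma)
    if sqrt:
        sm = sqrt_transform(sm)
    return align_concatenate(sm, bundle, stats)
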