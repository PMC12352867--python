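"""Session data model and on-disk session-bundle format.

A *session bundle* holds everything one recording session contributes to the
analysis: per-unit spike times, per-trial behavioral event markers, the object
grasped on each trial, and whether the trial succeeded.  One bundle covers one
behavioral context (execution or observation).

On disk a bundle is a directory::

    <bundle>/
      meta.json    session_id, context, optional monkey, unit metadata (area)
      trials.csv   trial_id, object, success, one column per event time (ms)
      spikes.csv   unit_id, spike_time_ms

All times are milliseconds on a common session clock starting at 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

__all__ = [
    "EVENTS",
    "OBJECTS",
    "CONTEXTS",
    "AREAS",
    "UnitRecord",
    "TrialRecord",
    "SessionBundle",
    "EpochStats",
    "ValidationError",
    "read_session",
    "write_session",
    "compute_epoch_stats",
]

#: Behavioral events in their within-trial order.
EVENTS = (
    "start",
    "instruction_on",
    "instruction_off",
    "go",
    "move_on",
    "hold_on",
    "hold_off",
    "end",
)

#: The four target objects of the reach-grasp-manipulate task.
OBJECTS = ("sphere", "button", "coax", "perp")

CONTEXTS = ("execution", "observation")
AREAS = ("PMv", "PMd")


class ValidationError(ValueError):
    """A bundle violated a structural invariant (bad ordering, label, ...)."""


@dataclass
class UnitRecord:
    """One sorted unit: identifier, cortical area, and its spike times (ms)."""

    unit_id: str
    area: str
    spike_times: np.ndarray

    def __post_init__(self):
        if self.area not in AREAS:
            raise ValidationError(
                f"unit {self.unit_id}: area {self.area!r} not in {AREAS}"
            )
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if st.size and np.any(np.diff(st) < 0):
            warnings.warn(
                f"unit {self.unit_id}: spike times were unsorted; sorting",
                stacklevel=2,
            )
            st = np.sort(st)
        if st.size and st[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        self.spike_times = st

    def __eq__(self, other):
        return (
            isinstance(other, UnitRecord)
            and self.unit_id == other.unit_id
            and self.area == other.area
            and np.array_equal(self.spike_times, other.spike_times)
        )


@dataclass
class TrialRecord:
    """One behavioral trial: object, success flag, and the eight event times."""

    trial_id: str
    object: str
    success: bool
    event_times: Dict[str, int]

    def __post_init__(self):
        if self.object not in OBJECTS:
            raise ValidationError(
                f"trial {self.trial_id}: object {self.object!r} not in {OBJECTS}"
            )
        missing = [e for e in EVENTS if e not in self.event_times]
        if missing:
            raise ValidationError(f"trial {self.trial_id}: missing events {missing}")
        times = [self.event_times[e] for e in EVENTS]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"trial {self.trial_id}: event times not strictly increasing "
                f"in the order {EVENTS}"
            )
        self.event_times = {e: int(self.event_times[e]) for e in EVENTS}


@dataclass
class SessionBundle:
    """All units and trials of one session in one behavioral context."""

    session_id: str
    context: str
    units: List[UnitRecord]
    trials: List[TrialRecord]
    monkey: str = ""

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise ValidationError(f"context {self.context!r} not in {CONTEXTS}")
        if self.trials:
            session_end = max(t.event_times["end"] for t in self.trials)
            for u in self.units:
                if u.spike_times.size and u.spike_times[-1] > session_end:
                    raise ValidationError(
                        f"unit {u.unit_id}: spike at {u.spike_times[-1]:.1f} ms "
                        f"beyond session end {session_end} ms"
                    )

    @property
    def n_units(self) -> int:
        return len(self.units)

    def successful_trials(self) -> List[TrialRecord]:
        return [t for t in self.trials if t.success]

    def trials_by_object(self, successful_only: bool = True) -> Dict[str, List[TrialRecord]]:
        out: Dict[str, List[TrialRecord]] = {o: [] for o in OBJECTS}
        for t in self.trials:
            if successful_only and not t.success:
                continue
            out[t.object].append(t)
        return out


@dataclass
class EpochStats:
    """Per-session median epoch durations (ms), pooled and per object.

    delay = go - instruction_off, reaction = move_on - go,
    movement = hold_on - move_on; medians over successful trials.
    """

    median_delay: float
    median_reaction: float
    median_movement: float
    per_object_medians: Dict[str, tuple] = field(default_factory=dict)


def compute_epoch_stats(bundle: SessionBundle) -> EpochStats:
    """Median delay, reaction, and movement durations of successful trials.

    Raises
    ------
    ValidationError
        If some object has no successful trial.
    """
    by_obj = bundle.trials_by_object(successful_only=True)
    for obj, trials in by_obj.items():
        if not trials:
            raise ValidationError(f"object {obj!r} has no successful trial")

    def durations(trials):
        d = np.array([t.event_times["go"] - t.event_times["instruction_off"] for t in trials], float)
        r = np.array([t.event_times["move_on"] - t.event_times["go"] for t in trials], float)
        m = np.array([t.event_times["hold_on"] - t.event_times["move_on"] for t in trials], float)
        return d, r, m

    all_trials = bundle.successful_trials()
    d, r, m = durations(all_trials)
    per_obj = {}
    for obj, trials in by_obj.items():
        od, orr, om = durations(trials)
        per_obj[obj] = (float(np.median(od)), float(np.median(orr)), float(np.median(om)))
    return EpochStats(
        median_delay=float(np.median(d)),
        median_reaction=float(np.median(r)),
        median_movement=float(np.median(m)),
        per_object_medians=per_obj,
    )


def write_session(bundle: SessionBundle, path) -> Path:
    """Write ``bundle`` to directory ``path`` in the standard bundle layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": bundle.session_id,
        "context": bundle.context,
        "monkey": bundle.monkey,
        "units": [{"unit_id": u.unit_id, "area": u.area} for u in bundle.units],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    rows = []
    for t in bundle.trials:
        row = {"trial_id": t.trial_id, "object": t.object, "success": int(t.success)}
        row.update({f"{e}_ms": t.event_times[e] for e in EVENTS})
        rows.append(row)
    cols = ["trial_id", "object", "success"] + [f"{e}_ms" for e in EVENTS]
    pd.DataFrame(rows, columns=cols).to_csv(path / "trials.csv", index=False)

    sp_rows = []
    for u in bundle.units:
        sp_rows.append(
            pd.DataFrame({"unit_id": u.unit_id, "spike_time_ms": u.spike_times})
        )
    if sp_rows:
        spikes = pd.concat(sp_rows, ignore_index=True)
    else:
        spikes = pd.DataFrame(columns=["unit_id", "spike_time_ms"])
    # %.17g guarantees exact float64 round-trip through the text format
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.17g")
    return path


def read_session(path) -> SessionBundle:
    """Read and validate a session bundle directory written by `write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no session bundle at {path} (missing meta.json)")
    meta = json.loads(meta_path.read_text())

    trials_df = pd.read_csv(path / "trials.csv")
    trials = []
    for _, row in trials_df.iterrows():
        trials.append(
            TrialRecord(
                trial_id=str(row["trial_id"]),
                object=str(row["object"]),
                success=bool(int(row["success"])),
                event_times={e: int(row[f"{e}_ms"]) for e in EVENTS},
            )
        )

    spikes_df = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    by_unit = {}
    if len(spikes_df):
        for unit_id, grp in spikes_df.groupby("unit_id", sort=False):
            by_unit[str(unit_id)] = grp["spike_time_ms"].to_numpy(dtype=float)
    units = [
        UnitRecord(
            unit_id=str(u["unit_id"]),
            area=str(u["area"]),
            spike_times=by_unit.get(str(u["unit_id"]), np.empty(0)),
        )
        for u in meta["units"]
    ]
    return SessionBundle(
        session_id=str(meta["session_id"]),
        context=str(meta["context"]),
        units=units,
        trials=trials,
        monkey=str(meta.get("monkey", "")),
    )
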