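"""Unit classification: mirror (MN), execution-only (AE), observation-only
(AO), or not significant (NS).

Each unit's spike counts are extracted from eleven 200 ms windows anchored to
the behavioral events of every successful trial:

  (i)    before instruction onset        (vii)  before movement onset
  (ii)   after instruction onset         (viii) after movement onset
  (iii)  before instruction offset       (ix)   before movement ended
  (iv)   after instruction offset        (x)    after movement ended
  (v)    before delay ended (go)         (xi)   before hold ended
  (vi)   after delay ended (go)

("before" = [event-200, event), "after" = [event, event+200), half-open, so a
spike exactly at the event time counts in the "after" window only).  Per
context, a two-way fixed-effects ANOVA with interaction (object x period,
trials as replicates) tests for modulation; a unit is modulated in a context
if any of the three p-values falls below alpha = 0.0083 (0.05 Bonferroni-
corrected for the six tests across the two contexts).  MN = modulated in both
contexts, AE = execution only, AO = observation only, NS = neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core_io import SessionBundle, UnitRecord

__all__ = [
    "ALPHA",
    "WINDOWS",
    "UnitClassification",
    "epoch_counts",
    "anova_pvalues",
    "classify",
    "classify_session",
]

#: Bonferroni-corrected per-test significance criterion (< 0.05 / 6).
ALPHA = 0.0083

#: The eleven (event, side) anchors of the 200 ms count windows, in order.
WINDOWS = (
    ("instruction_on", "before"),
    ("instruction_on", "after"),
    ("instruction_off", "before"),
    ("instruction_off", "after"),
    ("go", "before"),
    ("go", "after"),
    ("move_on", "before"),
    ("move_on", "after"),
    ("hold_on", "before"),
    ("hold_on", "after"),
    ("hold_off", "before"),
)


@dataclass
class UnitClassification:
    unit_id: str
    area: str
    unit_class: str  # MN | AE | AO | NS
    p_values: Dict[str, Tuple[float, float, float]]  # context -> (object, period, interaction)
    alpha: float = ALPHA


def epoch_counts(bundle: SessionBundle, unit: UnitRecord) -> pd.DataFrame:
    """Spike counts of one unit in the 11 windows of each successful trial.

    Returns a tidy frame with columns trial_id, object, period (0..10), count.
    Trials whose windows would exceed the trial bounds are dropped with a
    warning (cannot happen for well-formed event sequences, where every
    window lies between trial start and end).
    """
    st = unit.spike_times
    rows = []
    for trial in bundle.successful_trials():
        ev = trial.event_times
        bounds = []
        ok = True
        for event, side in WINDOWS:
            a = ev[event] - 200 if side == "before" else ev[event]
            b = a + 200
            if a < ev["start"] - 800 or b > ev["end"] + 800:
                ok = False
                break
            bounds.append((a, b))
        if not ok:
            warnings.warn(
                f"trial {trial.trial_id}: count window outside trial bounds; "
                "trial dropped",
                stacklevel=2,
            )
            continue
        for k, (a, b) in enumerate(bounds):
            lo, hi = np.searchsorted(st, [a, b])
            rows.append((trial.trial_id, trial.object, k, int(hi - lo)))
    return pd.DataFrame(rows, columns=["trial_id", "object", "period", "count"])


def anova_pvalues(counts: pd.DataFrame) -> Tuple[float, float, float]:
    """Two-way fixed-effects ANOVA p-values (object, period, interaction).

    Trial-level counts are the response; object (4 levels) and period
    (11 levels) are crossed factors.  Degenerate inputs (zero variance)
    yield p-values of 1.
    """
    if counts["count"].var() == 0 or counts["object"].nunique() < 2:
        return (1.0, 1.0, 1.0)
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("count ~ C(object) * C(period)", data=counts).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    p_obj = float(table.loc["C(object)", "PR(>F)"])
    p_per = float(table.loc["C(period)", "PR(>F)"])
    p_int = float(table.loc["C(object):C(period)", "PR(>F)"])
    return tuple(1.0 if np.isnan(x) else x for x in (p_obj, p_per, p_int))


def classify(
    counts_by_context: Dict[str, pd.DataFrame],
    unit_id: str = "",
    area: str = "PMv",
    alpha: float = ALPHA,
) -> UnitClassification:
    """Assign MN/AE/AO/NS from per-context 11-window counts.

    A context counts as modulated if any of its three ANOVA p-values is below
    ``alpha``.  Degenerate (zero-variance) counts yield NS with a warning.
    """
    pvals = {}
    modulated = {}
    for ctx in ("execution", "observation"):
        counts = counts_by_context[ctx]
        if counts.empty or counts["count"].var() == 0:
            warnings.warn(
                f"unit {unit_id}: degenerate counts in {ctx}; treated as "
                "unmodulated",
                stacklevel=2,
            )
            pvals[ctx] = (1.0, 1.0, 1.0)
            modulated[ctx] = False
            continue
        for obj, grp in counts.groupby("object"):
            if grp["trial_id"].nunique() < 2:
                raise ValueError(
                    f"unit {unit_id}: need >= 2 trials per object in {ctx}"
                )
        pvals[ctx] = anova_pvalues(counts)
        modulated[ctx] = min(pvals[ctx]) < alpha
    if modulated["execution"] and modulated["observation"]:
        cls = "MN"
    elif modulated["execution"]:
        cls = "AE"
    elif modulated["observation"]:
        cls = "AO"
    else:
        cls = "NS"
    return UnitClassification(
        unit_id=unit_id, area=area, unit_class=cls, p_values=pvals, alpha=alpha
    )


def classify_session(
    exec_bundle: SessionBundle,
    obs_bundle: SessionBundle,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Classify every unit of a session; returns the units_classified table.

    Columns: unit_id, area, class, and the six p-values
    (p_object/p_period/p_interaction per context).
    """
    obs_units = {u.unit_id: u for u in obs_bundle.units}
    rows = []
    for unit in exec_bundle.units:
        if unit.unit_id not in obs_units:
            raise ValueError(f"unit {unit.unit_id} missing from observation bundle")
        counts = {
            "execution": epoch_counts(exec_bundle, unit),
            "observation": epoch_counts(obs_bundle, obs_units[unit.unit_id]),
        }
        c = classify(counts, unit_id=unit.unit_id, area=unit.area, alpha=alpha)
        pe, po = c.p_values["execution"], c.p_values["observation"]
        rows.append(
            {
                "unit_id": c.unit_id,
                "area": c.area,
                "class": c.unit_class,
                "p_object_exec": pe[0],
                "p_period_exec": pe[1],
                "p_interaction_exec": pe[2],
                "p_object_obs": po[0],
                "p_period_obs": po[1],
                "p_interaction_obs": po[2],
            }
        )
    return pd.DataFrame(rows)
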