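"""Canonical-correlation alignment of latent trajectory segments.

Two sets of four trial-averaged 100 ms object segments, each in its own
3D instantaneous subspace, are stacked (fixed object order sphere, button,
coax, perp) into 3 x 400 latent matrices L_A and L_B.  CCA then finds
invertible 3 x 3 transforms M_A, M_B maximizing the per-dimension correlation
of the aligned latents: with column-centered L^T = Q R (economy QR) and
Q_A^T Q_B = U S V^T, the transforms are M_A = R_A^{-1} U, M_B = R_B^{-1} V
and the canonical coefficients CC1 >= CC2 >= CC3 are the singular values S.

Bootstrapping (20 trials per object with replacement, 500 iterations)
produces a distribution of the three coefficients for each comparison:
between sessions, between contexts, between neuron populations, or within a
group (two independent resamples of the same dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .core_io import OBJECTS
from .preprocess import AlignedTensor
from .segments import SEGMENT_LEN, project_segment
from .subspace import instantaneous_subspaces

__all__ = [
    "CCAOutcome",
    "cca_align",
    "SegmentSource",
    "bootstrap_cca",
    "within_group_cca",
    "permutation_null_cca",
    "compare_outcomes",
    "check_cca_eligibility",
]


@dataclass
class CCAOutcome:
    """Bootstrap distribution of the three canonical coefficients."""

    label: str
    segment_event: str
    coefficients: np.ndarray  # (n_iter, 3), sorted descending per row
    M_A: np.ndarray = None  # transforms from the last iteration, for inspection
    M_B: np.ndarray = None

    @property
    def mean(self) -> np.ndarray:
        return self.coefficients.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.coefficients.std(axis=0, ddof=0)

    def summary_row(self) -> dict:
        m, s = self.mean, self.sd
        return {
            "label": self.label,
            "event": self.segment_event,
            "cc1_mean": m[0], "cc1_sd": s[0],
            "cc2_mean": m[1], "cc2_sd": s[1],
            "cc3_mean": m[2], "cc3_sd": s[2],
        }


def cca_align(L_A: np.ndarray, L_B: np.ndarray):
    """Align two 3 x T latent matrices; returns (ccs, M_A, M_B, La_t, Lb_t).

    Columns of L^T are centered before the QR step so the coefficients are
    correlations rather than uncentered cosines.  Raises on rank-deficient
    R factors (collinear latents) -- resample or regularize upstream.
    """
    L_A = np.asarray(L_A, dtype=float)
    L_B = np.asarray(L_B, dtype=float)
    if L_A.shape != L_B.shape or L_A.shape[0] != 3:
        raise ValueError(f"expected matching 3 x T latents, got {L_A.shape} / {L_B.shape}")
    At = L_A.T - L_A.T.mean(axis=0, keepdims=True)
    Bt = L_B.T - L_B.T.mean(axis=0, keepdims=True)
    Qa, Ra = np.linalg.qr(At)
    Qb, Rb = np.linalg.qr(Bt)
    for name, R in (("A", Ra), ("B", Rb)):
        if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
            raise np.linalg.LinAlgError(
                f"rank-deficient latents in dataset {name}; resample or regularize"
            )
    U, S, Vt = np.linalg.svd(Qa.T @ Qb)
    M_A = np.linalg.solve(Ra, U)
    M_B = np.linalg.solve(Rb, Vt.T)
    La_aligned = (At @ M_A).T
    Lb_aligned = (Bt @ M_B).T
    ccs = np.clip(S, -1.0, 1.0)
    return ccs, M_A, M_B, La_aligned, Lb_aligned


@dataclass
class SegmentSource:
    """One dataset for CCA: a tensor plus its own all-trial event-time subspace.

    Trial-averaged segments are projected into the dataset's instantaneous
    subspace at the segment event (computed from all trials once, here at
    construction) before alignment.
    """

    tensor: AlignedTensor
    segment_event: str
    label: str = ""
    basis: np.ndarray = field(init=False)
    center: np.ndarray = field(init=False)
    _cols: np.ndarray = field(init=False)

    def __post_init__(self):
        series = instantaneous_subspaces(self.tensor)
        t = series.column_of(self.segment_event, 0)
        self.basis = series.bases[t]
        self.center = series.centroid(t)
        start = self.tensor.column_of(self.segment_event, 0)
        if start + SEGMENT_LEN > self.tensor.T:
            raise ValueError(f"segment at {self.segment_event} truncated")
        self._cols = np.arange(start, start + SEGMENT_LEN)

    def counts(self) -> Dict[str, int]:
        return {o: self.tensor.tensors[o].shape[1] for o in OBJECTS}

    def latents(self, subset: Dict[str, np.ndarray]) -> np.ndarray:
        """3 x 400 stacked latent segments, trial-averaged over ``subset``.

        ``subset`` maps each of the four slots to (object, trial indices)
        pairs or plain index arrays; a plain array draws from that slot's own
        object (the usual case), while a list of (object, index) tuples mixes
        trials across objects (used by the label-shuffling null).
        """
        pieces = []
        for o in OBJECTS:
            sel = subset[o]
            if isinstance(sel, np.ndarray) or (sel and not isinstance(sel[0], tuple)):
                x = self.tensor.tensors[o][:, np.asarray(sel, dtype=int), :]
                avg = x.mean(axis=1)
            else:
                trials = [self.tensor.tensors[obj][:, k, :] for obj, k in sel]
                avg = np.mean(trials, axis=0)
            avg = avg[:, self._cols].T  # (100, N)
            pieces.append((avg - self.center) @ self.basis)  # (100, 3)
        # Remove the across-object mean at each time point: alignment should
        # compare the *relations among objects*, not the condition-independent
        # drift common to all four segments, which would correlate between any
        # two datasets and saturate the leading coefficient.
        stacked = np.stack(pieces)  # (4, 100, 3)
        stacked = stacked - stacked.mean(axis=0, keepdims=True)
        return np.concatenate(list(stacked), axis=0).T  # (3, 400)


def check_cca_eligibility(source: SegmentSource, trials_per_object: int = 20) -> None:
    """Sessions with fewer successful trials than the resample size for any
    object are excluded from CCA analyses."""
    for o, k in source.counts().items():
        if k < trials_per_object:
            raise ValueError(
                f"dataset {source.label or '?'} excluded from CCA: object {o!r} "
                f"has {k} < {trials_per_object} successful trials"
            )


def _bootstrap(
    src_a: SegmentSource,
    src_b: SegmentSource,
    label: str,
    trials_per_object: int,
    n_iter: int,
    seed: int,
    independent_b: bool = True,
    permute_b: bool = False,
) -> CCAOutcome:
    check_cca_eligibility(src_a, trials_per_object)
    check_cca_eligibility(src_b, trials_per_object)
    ca, cb = src_a.counts(), src_b.counts()
    ccs = np.empty((n_iter, 3))
    M_A = M_B = None
    for it in range(n_iter):
        rng = substream(seed, "cca", label, src_a.segment_event, it)
        sub_a = {o: rng.integers(0, ca[o], size=trials_per_object) for o in OBJECTS}
        if permute_b:
            # Label-shuffling null: each of B's four slots averages a
            # resample with *exactly* one quarter of its trials drawn from
            # each object, so the condition-dependent structure of B cancels
            # in expectation and in composition, while its noise level and
            # smoothness are preserved.  (An unbalanced shuffle would leave a
            # composition residue that lies in the planted latent family and
            # spuriously aligns.)
            per_obj = max(1, trials_per_object // 4)
            sub_b = {
                slot: [
                    (o, int(rng.integers(0, cb[o])))
                    for o in OBJECTS
                    for _ in range(per_obj)
                ]
                for slot in OBJECTS
            }
        elif independent_b:
            sub_b = {o: rng.integers(0, cb[o], size=trials_per_object) for o in OBJECTS}
        else:
            sub_b = sub_a
        ccs[it], M_A, M_B, _, _ = cca_align(src_a.latents(sub_a), src_b.latents(sub_b))
    return CCAOutcome(
        label=label,
        segment_event=src_a.segment_event,
        coefficients=ccs,
        M_A=M_A,
        M_B=M_B,
    )


def bootstrap_cca(
    src_a: SegmentSource,
    src_b: SegmentSource,
    label: str = "custom",
    trials_per_object: int = 20,
    n_iter: int = 500,
    seed: int = 0,
    shared_resample: bool = False,
) -> CCAOutcome:
    """Bootstrap CCA between two datasets (sessions, contexts, or populations).

    Per iteration, each dataset is resampled independently (20 trials per
    object, with replacement), trial-averaged, projected into its own
    event-time subspace, and aligned.  ``shared_resample=True`` applies the
    same trial indices to both datasets (meaningful only when they index the
    same trials, e.g. two populations recorded simultaneously).
    """
    if src_a.segment_event != src_b.segment_event:
        raise ValueError("datasets must use the same segment event")
    return _bootstrap(
        src_a, src_b, label, trials_per_object, n_iter, seed,
        independent_b=not shared_resample,
    )


def within_group_cca(
    src: SegmentSource,
    label: str = "within",
    trials_per_object: int = 20,
    n_iter: int = 500,
    seed: int = 0,
) -> CCAOutcome:
    """CCA between two independent resamples of the same dataset.

    Measures the consistency of the latent relations across repeated trial
    samplings from one population, context, and session.
    """
    return _bootstrap(src, src, label, trials_per_object, n_iter, seed)


def permutation_null_cca(
    src_a: SegmentSource,
    src_b: SegmentSource,
    label: str = "permutation-null",
    trials_per_object: int = 20,
    n_iter: int = 500,
    seed: int = 0,
) -> CCAOutcome:
    """Null distribution: dataset B's object labels shuffled per iteration,
    destroying any shared object-to-object latent relations while keeping
    each dataset's internal geometry."""
    if src_a.segment_event != src_b.segment_event:
        raise ValueError("datasets must use the same segment event")
    return _bootstrap(
        src_a, src_b, label, trials_per_object, n_iter, seed, permute_b=True
    )


def compare_outcomes(outcomes: List[CCAOutcome]) -> pd.DataFrame:
    """Kruskal-Wallis + Tukey-HSD comparison of coefficient distributions.

    For each canonical coefficient, a Kruskal-Wallis test across the outcome
    groups' iteration values, followed by pairwise Tukey honestly-significant-
    difference tests.  Returns a tidy table of p-values.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes to compare")
    event = outcomes[0].segment_event
    if any(o.segment_event != event for o in outcomes):
        raise ValueError("outcomes compare different segment events")
    rows = []
    for k in range(3):
        groups = [o.coefficients[:, k] for o in outcomes]
        kw_stat, kw_p = sps.kruskal(*groups)
        rows.append(
            {
                "coefficient": f"CC{k + 1}",
                "test": "kruskal-wallis",
                "group_a": "all",
                "group_b": "all",
                "statistic": float(kw_stat),
                "p_value": float(kw_p),
            }
        )
        tk = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    {
                        "coefficient": f"CC{k + 1}",
                        "test": "tukey-hsd",
                        "group_a": outcomes[i].label,
                        "group_b": outcomes[j].label,
                        "statistic": float(tk.statistic[i, j]),
                        "p_value": float(tk.pvalue[i, j]),
                    }
                )
    return pd.DataFrame(rows)
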