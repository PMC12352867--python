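"""Instantaneous condition-dependent subspaces and principal angles.

At each 1 ms column of the aligned tensor, the four object condition means
form four points in the N-dimensional population state space.  PCA on those
four centered points yields at most three non-trivial directions; the leading
three (completed deterministically when rank-deficient) define the
*instantaneous subspace* at that time.  Because the subspace is a snapshot, it
captures condition-dependent structure while being blind to the shared,
condition-independent trajectory.

Two subspaces are compared by their principal angles: the arccosines of the
singular values of W_a^T W_b, ranked ascending from 0 deg (identical) to
90 deg (orthogonal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import OBJECTS
from ._rng import substream
from .preprocess import AlignedTensor

__all__ = [
    "SubspaceSeries",
    "AngleCourse",
    "instantaneous_subspaces",
    "principal_angles",
    "angle_course",
    "cross_context_angles",
    "chance_angles",
    "random_frame",
]

_GRAM_TOL = 1e-8


@dataclass
class SubspaceSeries:
    """Per-time orthonormal N x 3 bases with condition means and variance."""

    bases: np.ndarray  # (T, N, 3)
    condition_means: np.ndarray  # (T, 4, N)
    explained_variance: np.ndarray  # (T, 3)
    events: np.ndarray
    offsets: np.ndarray

    @property
    def T(self) -> int:
        return self.bases.shape[0]

    def column_of(self, event: str, offset: int) -> int:
        hits = np.flatnonzero((self.events == event) & (self.offsets == offset))
        if hits.size != 1:
            raise KeyError(f"no unique column at ({event}, {offset} ms)")
        return int(hits[0])

    def centroid(self, t: int) -> np.ndarray:
        """Centroid of the four condition means at column ``t``."""
        return self.condition_means[t].mean(axis=0)


@dataclass
class AngleCourse:
    """Bootstrap mean +/- SD principal-angle time course vs one reference."""

    reference_event: str
    reference_context: str
    moving_context: str
    angles_mean: np.ndarray  # (T, 3) degrees, ascending per row
    angles_sd: np.ndarray  # (T, 3)
    events: np.ndarray
    offsets: np.ndarray
    chance_mean: float = np.nan
    chance_m3sd: float = np.nan


def _complete_frame(V: np.ndarray, n: int) -> np.ndarray:
    """Complete V (N x r, orthonormal columns, r <= 3) to N x 3.

    Missing directions are filled with the lowest-index canonical basis
    vectors orthogonalized against the current span (deterministic).
    """
    cols = [V[:, i] for i in range(V.shape[1])]
    i = 0
    while len(cols) < 3:
        if i >= n:
            raise ValueError("ambient dimension too small to complete a 3-frame")
        e = np.zeros(n)
        e[i] = 1.0
        for c in cols:
            e = e - (c @ e) * c
        nrm = np.linalg.norm(e)
        if nrm > 1e-10:
            cols.append(e / nrm)
        i += 1
    return np.column_stack(cols)


def _subspace_at(points: np.ndarray) -> tuple:
    """PCA basis of 4 centered N-dim points -> (N x 3 basis, 3 variances)."""
    n = points.shape[1]
    centered = points - points.mean(axis=0, keepdims=True)
    # SVD of the 4 x N centered matrix; right singular vectors span the points.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / points.shape[0]
    tol = 1e-12 * max(1.0, s[0]) if s.size else 1e-12
    rank = int(np.sum(s > tol))
    V = vt[: min(3, rank)].T
    if V.shape[1] < 3:
        V = _complete_frame(V, n)
    # Deterministic sign: largest-magnitude entry of each column positive.
    for j in range(3):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    ev = np.zeros(3)
    m = min(3, rank)
    ev[:m] = var[:m]
    return V, ev


def instantaneous_subspaces(
    tensor: AlignedTensor,
    trial_subset: Optional[dict] = None,
) -> SubspaceSeries:
    """Identify the 1 ms time series of instantaneous 3D subspaces.

    Parameters
    ----------
    trial_subset : dict, optional
        object -> integer trial indices (with repeats allowed) to average;
        by default all trials are used.
    """
    n = tensor.n_units
    if n < 3:
        raise ValueError(f"need at least 3 units, got {n}")
    means = []
    for o in OBJECTS:
        x = tensor.tensors[o]
        if trial_subset is not None:
            x = x[:, np.asarray(trial_subset[o], dtype=int), :]
        if x.shape[1] == 0:
            raise ValueError(f"object {o!r}: empty trial subset")
        means.append(x.mean(axis=1))  # (N, T)
    cond = np.stack(means)  # (4, N, T)
    T = tensor.T
    bases = np.empty((T, n, 3))
    ev = np.empty((T, 3))
    for t in range(T):
        bases[t], ev[t] = _subspace_at(cond[:, :, t].copy())
    return SubspaceSeries(
        bases=bases,
        condition_means=np.transpose(cond, (2, 0, 1)),
        explained_variance=ev,
        events=tensor.events.copy(),
        offsets=tensor.offsets.copy(),
    )


def _check_frame(A: np.ndarray, name: str) -> None:
    g = A.T @ A
    if np.max(np.abs(g - np.eye(A.shape[1]))) > _GRAM_TOL:
        raise ValueError(f"{name} is not orthonormal (Gram deviation > {_GRAM_TOL})")


def principal_angles(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between two orthonormal frames.

    The cosines are the singular values of ``A.T @ B``, clipped to [0, 1]
    before arccos as a floating-point guard.
    """
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    _check_frame(A, "A")
    _check_frame(B, "B")
    inner = A.T @ B
    s = np.clip(np.sort(np.linalg.svd(inner, compute_uv=False))[::-1], 0.0, 1.0)
    theta = np.arccos(s)
    # arccos is ill-conditioned near 1; recompute small angles from the sine
    # (singular values of the residual B - A (A^T B)), as in standard
    # subspace-angle algorithms
    small = s**2 >= 0.5
    if np.any(small):
        sines = np.sort(np.linalg.svd(B - A @ inner, compute_uv=False))
        theta[small] = np.arcsin(np.clip(sines[: small.sum()], 0.0, 1.0))
    return np.degrees(theta)


def _angles_vs_reference(series: SubspaceSeries, ref: np.ndarray) -> np.ndarray:
    """(T, 3) ascending principal angles of every basis in ``series`` vs ref."""
    # svd of 3x3 products, batched
    prods = np.einsum("nk,tnm->tkm", ref, series.bases)
    s = np.linalg.svd(prods, compute_uv=False)
    s = np.clip(np.sort(s, axis=1)[:, ::-1], 0.0, 1.0)
    return np.degrees(np.arccos(s))


def angle_course(
    tensor: AlignedTensor,
    reference_event: str,
    n_folds: int = 10,
    trials_per_object: int = 20,
    seed: int = 0,
    reference_tensor: Optional[AlignedTensor] = None,
    reference_context: str = "",
    moving_context: str = "",
    rng_label: str = "angles",
) -> AngleCourse:
    """Bootstrap time course of principal angles vs one reference subspace.

    The reference subspace is computed from *all* trials at the reference
    event's time (offset 0).  Each of ``n_folds`` folds resamples
    ``trials_per_object`` trials per object with replacement, rebuilds the
    instantaneous subspace series from that 80-trial sample, and measures the
    angles of every time step against the reference; the mean and SD across
    folds are reported.  Because the reference uses all trials while the
    moving series uses resamples, the mean does not reach zero even at the
    reference time.
    """
    if reference_event not in ("I", "G", "M", "H"):
        raise ValueError(f"unknown reference event {reference_event!r}")
    ref_tensor = reference_tensor if reference_tensor is not None else tensor
    if not ref_tensor.same_time_base(tensor):
        raise ValueError("reference and moving tensors have mismatched time bases")
    ref_series_all = instantaneous_subspaces(ref_tensor)
    t_ref = ref_series_all.column_of(reference_event, 0)
    ref_basis = ref_series_all.bases[t_ref]

    counts = {o: tensor.tensors[o].shape[1] for o in OBJECTS}
    for o, k in counts.items():
        if k < trials_per_object:
            import warnings

            warnings.warn(
                f"object {o!r} has only {k} trials; resampling with "
                f"replacement to {trials_per_object}",
                stacklevel=2,
            )
    folds = np.empty((n_folds, tensor.T, 3))
    for f in range(n_folds):
        rng = substream(seed, rng_label, reference_event, moving_context, f)
        subset = {
            o: rng.integers(0, counts[o], size=trials_per_object) for o in OBJECTS
        }
        series = instantaneous_subspaces(tensor, trial_subset=subset)
        folds[f] = _angles_vs_reference(series, ref_basis)
    return AngleCourse(
        reference_event=reference_event,
        reference_context=reference_context,
        moving_context=moving_context,
        angles_mean=folds.mean(axis=0),
        angles_sd=folds.std(axis=0, ddof=0),
        events=tensor.events.copy(),
        offsets=tensor.offsets.copy(),
    )


def cross_context_angles(
    exec_tensor: AlignedTensor,
    obs_tensor: AlignedTensor,
    reference_event: str,
    reference_context: str = "execution",
    n_folds: int = 10,
    trials_per_object: int = 20,
    seed: int = 0,
) -> AngleCourse:
    """Angle course with the reference in one context, the moving series in the other."""
    if not exec_tensor.same_time_base(obs_tensor):
        raise ValueError("execution and observation tensors have mismatched time bases")
    if reference_context == "execution":
        ref, moving, mov_ctx = exec_tensor, obs_tensor, "observation"
    elif reference_context == "observation":
        ref, moving, mov_ctx = obs_tensor, exec_tensor, "execution"
    else:
        raise ValueError(f"unknown context {reference_context!r}")
    return angle_course(
        moving,
        reference_event,
        n_folds=n_folds,
        trials_per_object=trials_per_object,
        seed=seed,
        reference_tensor=ref,
        reference_context=reference_context,
        moving_context=mov_ctx,
        rng_label="xangles",
    )


def random_frame(n_dim: int, rng: np.random.Generator, k: int = 3) -> np.ndarray:
    """Uniformly random orthonormal ``n_dim x k`` frame (Gaussian + QR, Haar)."""
    q, r = np.linalg.qr(rng.standard_normal((n_dim, k)))
    return q * np.sign(np.diag(r))


def chance_angles(n_dim: int, n_draws: int = 5000, seed: int = 0):
    """First-principal-angle chance statistics for random 3D subspaces.

    A fixed random 3-frame is compared against ``n_draws`` independent
    uniformly random 3-frames in ``n_dim`` dimensions; returns
    (mean, sd, mean - 3 sd) of the first principal angle in degrees.
    """
    if n_dim < 3:
        raise ValueError(f"need n_dim >= 3, got {n_dim}")
    rng = substream(seed, "chance_angles", n_dim)
    fixed = random_frame(n_dim, rng)
    theta1 = np.empty(n_draws)
    for i in range(n_draws):
        s = np.linalg.svd(fixed.T @ random_frame(n_dim, rng), compute_uv=False)
        theta1[i] = np.degrees(np.arccos(np.clip(s.max(), 0.0, 1.0)))
    mean = float(theta1.mean())
    sd = float(theta1.std(ddof=0))
    return mean, sd, mean - 3.0 * sd
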