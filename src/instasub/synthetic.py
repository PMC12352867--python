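"""Synthetic session generator with planted low-dimensional structure.

The generator emulates one premotor recording session of the delayed
reach-grasp-manipulate task: 4 objects x ~20 successful trials per object and
per context, randomized 500-2000 ms delay epochs, a few-hundred-ms reaction
and movement epochs, and Poisson spiking.  Each unit's intensity is

    lambda_n(t) = base
                + ci * f(a(t))                          (condition-independent)
                + amp_ctx * c_n * [B_ctx(a(t)) z_obj(a(t))]_n       (condition-dependent)
                + slow drift noise,   rectified at zero,

where ``a(t)`` maps real trial time onto a canonical event-aligned axis
(anchored at instruction onset I, go cue G, movement onset M, and hold start
H), ``f`` is a shared multiphasic envelope identical across objects,
``z_obj(tau)`` is one of four zero-sum latent trajectories (a static
asymmetric core plus smooth per-object harmonic curves, spanning exactly 3
dimensions at every time), and ``B_ctx(tau)`` is a planted orthonormal N x 3
basis that rotates at a constant rate within a 6-dimensional ambient subspace
(Givens-style, each basis column paired with an orthogonal partner).

The observation basis is ``cos(phi) B_exec + sin(phi) C`` with ``C`` rotating
in a disjoint 6-dimensional ambient block, so the principal angles between the
execution and observation condition-dependent subspaces all equal
``phi = arccos(context_overlap)`` while both contexts share the *same* object
latent relations ``z_obj(tau)`` -- distinct subspaces, alignable dynamics.

Unit classes: MN units carry the condition-dependent and condition-independent
signal in both contexts; AE units only during execution; AO units only during
observation; NS units fire at the base rate throughout.

The returned :class:`GroundTruth` carries the *effective* planted bases (the
orthonormalized image of ``diag(c) B_ctx(tau)``, which is the subspace the
condition means actually span) and noise-free condition-mean rate courses on
the canonical axis, both usable as oracles for every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._rng import substream
from .core_io import AREAS, OBJECTS, EpochStats, SessionBundle, TrialRecord, UnitRecord
from .preprocess import AlignedTensor, build_time_map
from .subspace import principal_angles

__all__ = ["SyntheticConfig", "GroundTruth", "generate_session", "planted_first_angle"]

_CLASSES = ("MN", "AE", "AO", "NS")

# Planted latent trajectories: z_o(tau) = (v_o + kappa * zeta_o(tau)) * e(tau)
# / sqrt(1 + kappa^2).  The static core v_o (below) is zero-mean and
# deliberately asymmetric -- all six pairwise distances distinct -- so the
# relations among objects carry information (a symmetric configuration would
# be invariant under label permutation up to rotation, degenerating
# relation-based nulls).  The dynamic part zeta_o is a smooth per-object
# two-harmonic curve (periods below, ms; closed form, so evaluable on any
# per-trial warped time grid); the four curves sum to zero at every time so
# the centered condition means span exactly 3 dimensions.  kappa balances
# within-segment dynamics (needed for alignment comparisons to be
# non-trivial) against the guaranteed rank margin of the static core.
_OBJECT_CORE = np.array(
    [
        [1.3, 0.4, 0.2],
        [-0.9, 1.0, -0.5],
        [0.3, -1.2, -0.8],
        [-0.7, -0.2, 1.1],
    ]
)
_LATENT_PERIODS = (900.0, 400.0)
_LATENT_KAPPA = 0.6

#: minimum acceptable third singular value of the centered 4-object latent
#: configuration over time; enforced at generation by redrawing the curves.
_LATENT_MARGIN = 0.2


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic session (both contexts share the geometry).

    Rates are in spikes/s, durations in ms.  ``subspace_rotation_rate`` is the
    constant rotation rate of the planted condition-dependent basis in
    degrees per aligned ms.  ``context_overlap`` in [0, 1] sets the cosine of
    the planted principal angles between the execution and observation bases
    (0 = orthogonal, 1 = identical).  ``cd_onset="instruction"`` makes the
    condition-dependent envelope zero before instruction onset (the monkey
    cannot know the object earlier); ``cd_onset=None`` keeps it on throughout.
    """

    n_units: int = 50
    n_mn: int = 30
    n_ae: int = 14
    n_ao: int = 2
    n_ns: int = 4
    trials_per_object: int = 20
    n_failed: int = 2
    delay_range: tuple = (500, 2000)
    reaction_mean: float = 250.0
    reaction_sd: float = 30.0
    movement_mean: float = 400.0
    movement_sd: float = 50.0
    base_rate: float = 20.0
    ci_amplitude: float = 10.0
    cd_amplitude_exec: float = 5.0
    cd_amplitude_obs: float = 2.5
    subspace_rotation_rate: float = 0.03
    context_overlap: float = 0.2
    cd_gain_spread: float = 0.5
    cd_onset: Optional[str] = "instruction"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_mn + self.n_ae + self.n_ao + self.n_ns != self.n_units:
            raise ValueError("class counts must sum to n_units")
        if min(self.n_mn, self.n_ae, self.n_ao, self.n_ns, self.trials_per_object) < 0:
            raise ValueError("counts must be non-negative")
        for a in (self.base_rate, self.ci_amplitude, self.cd_amplitude_exec,
                  self.cd_amplitude_obs, self.noise_sd):
            if a < 0:
                raise ValueError("rates/amplitudes must be >= 0")
        if not 0.0 <= self.context_overlap <= 1.0:
            raise ValueError("context_overlap must be in [0, 1]")
        if not 0.0 <= self.cd_gain_spread < 1.0:
            raise ValueError("cd_gain_spread must be in [0, 1)")
        need = 6 if self.context_overlap >= 1.0 else 12
        if self.n_units < need:
            raise ValueError(
                f"n_units={self.n_units} too small for the planted geometry "
                f"(need >= {need})"
            )
        if self.cd_onset not in (None, "none", "instruction"):
            raise ValueError(f"unknown cd_onset {self.cd_onset!r}")

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "delay_range" in data:
            data["delay_range"] = tuple(data["delay_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delay_range"] = list(d["delay_range"])
        return d


@dataclass
class GroundTruth:
    """Planted structure on the canonical aligned axis (oracle for recovery tests)."""

    events: np.ndarray
    offsets: np.ndarray
    #: context -> (T, N, 3) orthonormal effective condition-dependent bases
    bases: Dict[str, np.ndarray]
    #: context -> (4, 3, T) object latent courses (amp * e(tau) * v_obj)
    latents: Dict[str, np.ndarray]
    #: context -> (4, N, T) noise-free condition-mean rate courses
    mean_rates: Dict[str, np.ndarray]
    unit_classes: list = field(default_factory=list)
    unit_cd_gains: np.ndarray = None
    config: SyntheticConfig = None

    @property
    def T(self) -> int:
        return self.events.size

    def column_of(self, event: str, offset: int) -> int:
        hits = np.flatnonzero((self.events == event) & (self.offsets == offset))
        if hits.size != 1:
            raise KeyError(f"no unique column at ({event}, {offset} ms)")
        return int(hits[0])

    def epoch_stats(self) -> EpochStats:
        cfg = self.config
        md = round((cfg.delay_range[0] + cfg.delay_range[1]) / 2.0)
        return EpochStats(
            median_delay=float(md),
            median_reaction=float(round(cfg.reaction_mean)),
            median_movement=float(round(cfg.movement_mean)),
        )

    def to_aligned_tensor(self, context: str, sqrt: bool = False) -> AlignedTensor:
        """Noise-free condition means packaged as a 1-trial-per-object tensor."""
        rates = self.mean_rates[context]
        tensors = {
            o: (np.sqrt(rates[i]) if sqrt else rates[i])[:, None, :]
            for i, o in enumerate(OBJECTS)
        }
        return AlignedTensor(
            tensors=tensors,
            events=self.events.copy(),
            offsets=self.offsets.copy(),
            stats=self.epoch_stats(),
            unit_ids=[f"u{i:03d}" for i in range(rates.shape[1])],
            sigma_ms=0.0,
            sqrt_applied=sqrt,
        )


def planted_first_angle(gt: GroundTruth, t_ref: int, t: int, context: str = "execution") -> float:
    """First principal angle (deg) between planted bases at columns t_ref and t.

    Uses the same SVD definition as :func:`instasub.subspace.principal_angles`
    but on the noise-free planted bases.
    """
    bases = gt.bases[context]
    for x in (t_ref, t):
        if not 0 <= x < bases.shape[0]:
            raise IndexError(f"time {x} outside [0, {bases.shape[0]})")
    return float(principal_angles(bases[t_ref], bases[t])[0])


# ---------------------------------------------------------------------------
# internals


def _class_vector(cfg: SyntheticConfig, rng: np.random.Generator) -> list:
    labels = (["MN"] * cfg.n_mn + ["AE"] * cfg.n_ae + ["AO"] * cfg.n_ao
              + ["NS"] * cfg.n_ns)
    perm = rng.permutation(cfg.n_units)
    return [labels[i] for i in np.argsort(perm)]


def _gates(classes, context: str) -> np.ndarray:
    """Per-unit 0/1 participation of the CD (and CI) signal in a context."""
    on = {"execution": ("MN", "AE"), "observation": ("MN", "AO")}[context]
    return np.array([1.0 if c in on else 0.0 for c in classes])


def _structure(cfg: SyntheticConfig):
    """Geometry shared by both contexts: ambient frame, gains, classes."""
    rng = substream(cfg.seed, "structure")
    n = cfg.n_units
    k = 6 if cfg.context_overlap >= 1.0 else 12
    U, r = np.linalg.qr(rng.standard_normal((n, k)))
    U = U * np.sign(np.diag(r))
    if k == 6:  # identical contexts: reuse the execution ambient block
        U = np.concatenate([U, U], axis=1)
    s = cfg.cd_gain_spread
    c = rng.uniform(1.0 - s, 1.0 + s, size=n)
    classes = _class_vector(cfg, rng)
    return U, c, classes, _draw_latent_coeffs(cfg)


def _eval_latents(C: np.ndarray, idx, tau: np.ndarray, a_i: float) -> np.ndarray:
    """Latent curves for objects ``idx``: (len(idx), 3, len(tau))."""
    x = np.asarray(tau, dtype=float) - a_i
    zeta = np.zeros((len(idx), 3, x.size))
    for k, period in enumerate(_LATENT_PERIODS):
        zeta += np.imag(
            C[idx, :, k][:, :, None] * np.exp(2j * np.pi * x / period)[None, None, :]
        )
    core = _OBJECT_CORE[idx][:, :, None]
    return (core + _LATENT_KAPPA * zeta) / np.sqrt(1.0 + _LATENT_KAPPA**2)


def _latent_margin(C: np.ndarray) -> float:
    tau = np.arange(0.0, 3700.0, 7.0)  # covers one full joint period
    z = _eval_latents(C, range(4), tau, 0.0).transpose(2, 0, 1)  # (L, 4, 3)
    z = z - z.mean(axis=1, keepdims=True)
    return float(np.linalg.svd(z, compute_uv=False)[:, -1].min())


def _draw_latent_coeffs(cfg: SyntheticConfig) -> np.ndarray:
    """Complex harmonic coefficients (4, 3, n_harmonics) of the dynamic part:
    zero-sum across objects, unit per-entry RMS, redrawn deterministically
    until the centered configuration keeps a rank-3 margin at all times."""
    for attempt in range(64):
        rng = substream(cfg.seed, "latents", attempt)
        amp = rng.uniform(0.3, 1.0, size=(4, 3, len(_LATENT_PERIODS)))
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(4, 3, len(_LATENT_PERIODS)))
        C = amp * np.exp(1j * phase)
        C = C - C.mean(axis=0, keepdims=True)
        power = (np.abs(C) ** 2).sum(axis=(1, 2)) / 2.0  # E_t |zeta_o(t)|^2
        C = C / np.sqrt(power.mean())
        if _latent_margin(C) >= _LATENT_MARGIN:
            return C
    raise RuntimeError("could not draw well-conditioned latent curves")


def _canonical_axis(cfg: SyntheticConfig):
    md = round((cfg.delay_range[0] + cfg.delay_range[1]) / 2.0)
    mr = round(cfg.reaction_mean)
    events, offsets = build_time_map(md, mr)
    anchors = {}
    for code in ("I", "G", "M", "H"):
        anchors[code] = int(np.flatnonzero((events == code) & (offsets == 0))[0])
    return events, offsets, anchors


def _ci_envelope(T: int, anchors: dict) -> np.ndarray:
    """Shared multiphasic envelope: small post-instruction blip, movement peak."""
    tau = np.arange(T, dtype=float)
    f = (
        0.2 * np.exp(-0.5 * ((tau - anchors["I"] - 150) / 150.0) ** 2)
        + 1.0 * np.exp(-0.5 * ((tau - anchors["M"] - 150) / 300.0) ** 2)
    )
    return f


def _cd_envelope(cfg: SyntheticConfig, tau: np.ndarray, a_i: float) -> np.ndarray:
    if cfg.cd_onset in (None, "none"):
        return np.ones_like(tau, dtype=float)
    # smooth ramp from 0 at instruction onset to 1 over 200 ms
    x = (tau - a_i) / 200.0
    return np.clip(x, 0.0, 1.0)


def _theta(cfg: SyntheticConfig, tau: np.ndarray, a_i: float) -> np.ndarray:
    return np.radians(cfg.subspace_rotation_rate * (tau - a_i))


def _context_mix(cfg: SyntheticConfig):
    phi = np.arccos(np.clip(cfg.context_overlap, 0.0, 1.0))
    return np.cos(phi), np.sin(phi)


def _basis_courses(cfg: SyntheticConfig, U: np.ndarray, theta: np.ndarray):
    """(T, N, 3) rotating planted bases for both contexts."""
    cth, sth = np.cos(theta), np.sin(theta)
    b_exec = cth[:, None, None] * U[None, :, 0:3] + sth[:, None, None] * U[None, :, 3:6]
    c_part = cth[:, None, None] * U[None, :, 6:9] + sth[:, None, None] * U[None, :, 9:12]
    cphi, sphi = _context_mix(cfg)
    b_obs = cphi * b_exec + sphi * c_part
    return {"execution": b_exec, "observation": b_obs}


def _effective_bases(raw: np.ndarray, c_ctx: np.ndarray) -> np.ndarray:
    """Orthonormalize diag(c) B(tau) per time step -> effective planted bases."""
    mapped = raw * c_ctx[None, :, None]
    q, r = np.linalg.qr(mapped)
    return q * np.sign(np.einsum("tii->ti", r))[:, None, :]


def _latent_courses(
    cfg: SyntheticConfig, C: np.ndarray, idx, tau: np.ndarray, a_i: float
) -> np.ndarray:
    """(len(idx), 3, len(tau)) planted latent trajectories (unit RMS scale)."""
    e = _cd_envelope(cfg, np.asarray(tau, dtype=float), a_i)
    return e[None, None, :] * _eval_latents(C, idx, tau, a_i)


def _ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    U, c, classes, C = _structure(cfg)
    events, offsets, anchors = _canonical_axis(cfg)
    T = events.size
    tau = np.arange(T, dtype=float)
    theta = _theta(cfg, tau, anchors["I"])
    raw = _basis_courses(cfg, U, theta)
    f_ci = _ci_envelope(T, anchors)
    z = _latent_courses(cfg, C, range(4), tau, anchors["I"])  # (4, 3, T)
    scale = np.sqrt(cfg.n_units)  # per-unit modulation is O(cd_amplitude)
    amps = {"execution": cfg.cd_amplitude_exec, "observation": cfg.cd_amplitude_obs}

    bases, latents, mean_rates = {}, {}, {}
    for ctx in ("execution", "observation"):
        gate = _gates(classes, ctx)
        c_ctx = c * gate
        bases[ctx] = _effective_bases(raw[ctx], c_ctx)
        latents[ctx] = amps[ctx] * z
        # condition-mean rates: base + CI + CD, rectified
        proj = np.einsum("tnm,omt->otn", raw[ctx], scale * z)  # (4, T, N)
        cd = amps[ctx] * c_ctx[None, None, :] * proj
        lam = cfg.base_rate + gate[None, None, :] * cfg.ci_amplitude * f_ci[None, :, None] + cd
        mean_rates[ctx] = np.maximum(lam, 0.0).transpose(0, 2, 1)  # (4, N, T)
    return GroundTruth(
        events=events,
        offsets=offsets,
        bases=bases,
        latents=latents,
        mean_rates=mean_rates,
        unit_classes=classes,
        unit_cd_gains=c,
        config=cfg,
    )


def _draw_trials(cfg: SyntheticConfig, rng: np.random.Generator):
    """Block-design trial sequence with event times; returns TrialRecords."""
    n_success = cfg.trials_per_object * 4
    seq = []
    for _ in range(cfg.trials_per_object):
        block = list(OBJECTS)
        rng.shuffle(block)
        seq.extend((o, True) for o in block)
    fail_pos = sorted(rng.integers(0, len(seq) + 1, size=cfg.n_failed))
    for j, p in enumerate(fail_pos):
        obj = OBJECTS[int(rng.integers(0, 4))]
        seq.insert(min(p + j, len(seq)), (obj, False))

    trials = []
    t = 1000
    for i, (obj, ok) in enumerate(seq):
        inithold = int(rng.integers(500, 1001))
        delay = int(rng.integers(cfg.delay_range[0], cfg.delay_range[1] + 1))
        reaction = int(max(150, round(rng.normal(cfg.reaction_mean, cfg.reaction_sd))))
        movement = int(max(200, round(rng.normal(cfg.movement_mean, cfg.movement_sd))))
        ev = {}
        ev["start"] = t
        ev["instruction_on"] = ev["start"] + inithold
        ev["instruction_off"] = ev["instruction_on"] + 500
        ev["go"] = ev["instruction_off"] + delay
        ev["move_on"] = ev["go"] + reaction
        ev["hold_on"] = ev["move_on"] + movement
        ev["hold_off"] = ev["hold_on"] + 1000
        ev["end"] = ev["hold_off"] + 300
        trials.append(
            TrialRecord(trial_id=f"t{i:03d}", object=obj, success=ok, event_times=ev)
        )
        t = ev["end"] + 1200  # inter-trial interval
    return trials


def _aligned_coordinate(trial: TrialRecord, anchors: dict, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear map from real trial time to the canonical axis."""
    ev = trial.event_times
    xs = [ev["instruction_on"], ev["go"], ev["move_on"], ev["hold_on"]]
    ys = [float(anchors[c]) for c in ("I", "G", "M", "H")]
    a = np.interp(t, xs, ys)
    before = t < xs[0]
    after = t > xs[-1]
    a[before] = ys[0] + (t[before] - xs[0])
    a[after] = ys[-1] + (t[after] - xs[-1])
    return a


def generate_session(cfg: SyntheticConfig, context: str):
    """Simulate one session in one context.

    Returns
    -------
    (SessionBundle, GroundTruth)
        The bundle contains inhomogeneous-Poisson spike trains; the ground
        truth carries the planted bases, latents, and noise-free condition
        means for both contexts (the geometry is shared).  Deterministic
        given ``cfg.seed`` and ``context``.
    """
    if context not in ("execution", "observation"):
        raise ValueError(f"unknown context {context!r}")
    gt = _ground_truth(cfg)
    U, c, classes, C = _structure(cfg)
    _, _, anchors = _canonical_axis(cfg)
    gate = _gates(classes, context)
    c_ctx = c * gate
    amp = {"execution": cfg.cd_amplitude_exec, "observation": cfg.cd_amplitude_obs}[context]
    obj_index = {o: i for i, o in enumerate(OBJECTS)}
    cphi, sphi = _context_mix(cfg)

    rng = substream(cfg.seed, "session", context)
    trials = _draw_trials(cfg, rng)
    n = cfg.n_units
    spikes = [[] for _ in range(n)]
    margin = 400
    for trial in trials:
        t0 = trial.event_times["start"] - margin
        t1 = trial.event_times["end"]
        t = np.arange(t0, t1, dtype=float)
        a = _aligned_coordinate(trial, anchors, t)
        theta = _theta(cfg, a, anchors["I"])
        cth, sth = np.cos(theta), np.sin(theta)
        o = obj_index[trial.object]
        z = np.sqrt(cfg.n_units) * _latent_courses(cfg, C, [o], a, anchors["I"])[0]  # (3, L)
        exec_part = cth[None, :] * (U[:, 0:3] @ z) + sth[None, :] * (U[:, 3:6] @ z)
        if context == "execution":
            bv = exec_part
        else:
            obs_part = cth[None, :] * (U[:, 6:9] @ z) + sth[None, :] * (U[:, 9:12] @ z)
            bv = cphi * exec_part + sphi * obs_part
        f = (
            0.2 * np.exp(-0.5 * ((a - anchors["I"] - 150) / 150.0) ** 2)
            + 1.0 * np.exp(-0.5 * ((a - anchors["M"] - 150) / 300.0) ** 2)
        )
        lam = (
            cfg.base_rate
            + gate[:, None] * cfg.ci_amplitude * f[None, :]
            + amp * c_ctx[:, None] * bv
        )
        if cfg.noise_sd > 0:
            drift = gaussian_filter1d(
                rng.standard_normal((n, t.size)), sigma=100.0, axis=1
            )
            sd = drift.std()
            if sd > 0:
                lam = lam + cfg.noise_sd / sd * drift
        lam = np.maximum(lam, 0.0)
        counts = rng.poisson(lam / 1000.0)
        for i in range(n):
            nz = np.flatnonzero(counts[i])
            if nz.size:
                reps = counts[i][nz]
                times = np.repeat(t[nz], reps) + rng.random(int(reps.sum()))
                spikes[i].append(times)

    units = []
    for i in range(n):
        st = np.sort(np.concatenate(spikes[i])) if spikes[i] else np.empty(0)
        st = np.clip(st, 0.0, trials[-1].event_times["end"])
        units.append(
            UnitRecord(
                unit_id=f"u{i:03d}",
                area=AREAS[0] if i < n // 2 else AREAS[1],
                spike_times=st,
            )
        )
    bundle = SessionBundle(
        session_id=f"synthetic-seed{cfg.seed}",
        context=context,
        units=units,
        trials=trials,
        monkey="S",
    )
    return bundle, gt
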