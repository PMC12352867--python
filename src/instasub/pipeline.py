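"""End-to-end orchestration: simulate -> preprocess -> classify -> angles /
segments -> decode -> align, with a run manifest and per-stage CSV outputs.

A pipeline run is configured by a :class:`PipelineConfig` (loadable from JSON
or YAML).  One global seed fans out into named substreams per stage, context,
fold, and iteration, so re-running the same config reproduces every
stochastic output byte for byte, and any single stage can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .align import SegmentSource, bootstrap_cca, within_group_cca
from .classify import ALPHA, classify_session
from .core_io import CONTEXTS, EpochStats, SessionBundle, read_session, write_session
from .decode import chance_decode, default_grid, slide_decode
from .preprocess import (
    AlignedTensor,
    load_tensor,
    preprocess_bundle,
    save_tensor,
    subset_units,
)
from .segments import separation_grid
from .subspace import angle_course, chance_angles, instantaneous_subspaces
from .synthetic import SyntheticConfig, generate_session

__all__ = ["PipelineConfig", "run_pipeline", "pooled_epoch_stats"]

log = logging.getLogger("instasub")

_STAGES = ("simulate", "preprocess", "classify", "angles", "segments", "decode", "align")


@dataclass
class PipelineConfig:
    """What to run, on what, with which parameters."""

    out_dir: str = "instasub_out"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(_STAGES))
    #: synthetic-session parameters; ignored when ``bundles`` is given
    synthetic: Optional[dict] = None
    #: context -> path of an existing session bundle directory
    bundles: Optional[Dict[str, str]] = None
    sigma_ms: float = 50.0
    sqrt: bool = True
    alpha: float = ALPHA
    angle_refs: List[str] = field(default_factory=lambda: ["I", "G", "M", "H"])
    n_folds: int = 10
    trials_per_object: int = 20
    n_chance_angles: int = 5000
    decode_events: List[str] = field(default_factory=lambda: ["M"])
    decode_grid_step: int = 50
    n_chance_decode: int = 0
    max_epochs: int = 100
    align_events: List[str] = field(default_factory=lambda: ["H"])
    n_iter: int = 500

    def __post_init__(self):
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.synthetic is None and self.bundles is None and "simulate" in self.stages:
            self.synthetic = {}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def pooled_epoch_stats(bundles: List[SessionBundle]) -> EpochStats:
    """Session epoch medians pooled over several bundles' successful trials.

    Used to put both behavioral contexts of a session on one time base, which
    the cross-context comparisons require.
    """
    d, r, m = [], [], []
    for b in bundles:
        for t in b.successful_trials():
            ev = t.event_times
            d.append(ev["go"] - ev["instruction_off"])
            r.append(ev["move_on"] - ev["go"])
            m.append(ev["hold_on"] - ev["move_on"])
    return EpochStats(
        median_delay=float(np.median(d)),
        median_reaction=float(np.median(r)),
        median_movement=float(np.median(m)),
    )


def _angle_course_frame(course) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_ms": np.arange(course.events.size),
            "event": course.events,
            "offset_ms": course.offsets,
            "theta1_mean": course.angles_mean[:, 0],
            "theta1_sd": course.angles_sd[:, 0],
            "theta2_mean": course.angles_mean[:, 1],
            "theta2_sd": course.angles_sd[:, 1],
            "theta3_mean": course.angles_mean[:, 2],
            "theta3_sd": course.angles_sd[:, 2],
            "chance_mean": course.chance_mean,
            "chance_m3sd": course.chance_m3sd,
        }
    )


def _decode_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "grid_time_ms": curve.grid_columns,
            "event": curve.events,
            "offset_ms": curve.offsets,
            "acc_mean": curve.accuracy_mean,
            "acc_sd": curve.accuracy_sd,
            "chance_mean": curve.chance_mean,
            "chance_sd": curve.chance_sd,
        }
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    param_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "param_hash": param_hash,
        "config": cfg_dict,
        "stages": {},
    }
    stages = [s for s in _STAGES if s in cfg.stages]

    def record(stage, t0, **outputs):
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "wall_s": round(time.time() - t0, 2),
        }
        log.info("stage=%s hash=%s wall=%.1fs", stage, param_hash, time.time() - t0)

    bundles: Dict[str, SessionBundle] = {}

    if "simulate" in stages:
        t0 = time.time()
        syn = SyntheticConfig(**{**(cfg.synthetic or {}), "seed": cfg.seed})
        paths = {}
        for ctx in CONTEXTS:
            bundle, _ = generate_session(syn, ctx)
            p = out / "bundles" / ctx
            write_session(bundle, p)
            bundles[ctx] = bundle
            paths[ctx] = p
        record("simulate", t0, **paths)
    elif cfg.bundles:
        for ctx, p in cfg.bundles.items():
            bundles[ctx] = read_session(p)

    tensors: Dict[str, AlignedTensor] = {}
    if "preprocess" in stages:
        t0 = time.time()
        if not bundles:
            raise RuntimeError(
                "preprocess requires session bundles (enable 'simulate' or set 'bundles')"
            )
        stats = pooled_epoch_stats(list(bundles.values()))
        paths = {}
        for ctx, b in bundles.items():
            tensors[ctx] = preprocess_bundle(b, stats, sigma=cfg.sigma_ms, sqrt=cfg.sqrt)
            p = out / f"tensor_{ctx}.h5"
            save_tensor(tensors[ctx], p)
            paths[ctx] = p
        record("preprocess", t0, **paths)
    else:
        for ctx in CONTEXTS:
            p = out / f"tensor_{ctx}.h5"
            if p.exists():
                tensors[ctx] = load_tensor(p)

    def need_tensors(stage):
        if not tensors:
            raise RuntimeError(
                f"stage '{stage}' requires aligned tensors: enable 'preprocess' "
                f"or provide cached tensor_<context>.h5 in {out}"
            )

    classification = None
    if "classify" in stages:
        t0 = time.time()
        if set(bundles) < set(CONTEXTS):
            raise RuntimeError("classify requires bundles for both contexts")
        classification = classify_session(
            bundles["execution"], bundles["observation"], alpha=cfg.alpha
        )
        p = out / "units_classified.csv"
        classification.to_csv(p, index=False)
        record("classify", t0, table=p)
    else:
        p = out / "units_classified.csv"
        if p.exists():
            classification = pd.read_csv(p)

    def population(tensor, cls):
        """Restrict to one unit class when a classification is available."""
        if classification is None:
            return tensor
        idx = [
            i
            for i, u in enumerate(tensor.unit_ids)
            if classification.set_index("unit_id")["class"].get(u) == cls
        ]
        if len(idx) >= 3:
            return subset_units(tensor, idx)
        return tensor

    if "angles" in stages:
        t0 = time.time()
        need_tensors("angles")
        n = min(t.n_units for t in tensors.values())
        ch_mean, _, ch_m3 = chance_angles(
            n, n_draws=cfg.n_chance_angles, seed=cfg.seed
        )
        paths = {}
        for ctx, tensor in tensors.items():
            for ref in cfg.angle_refs:
                course = angle_course(
                    tensor,
                    ref,
                    n_folds=cfg.n_folds,
                    trials_per_object=cfg.trials_per_object,
                    seed=cfg.seed,
                    moving_context=ctx,
                )
                course.chance_mean, course.chance_m3sd = ch_mean, ch_m3
                p = out / f"angles_{ref}_{ctx}.csv"
                _angle_course_frame(course).to_csv(p, index=False)
                paths[f"{ref}_{ctx}"] = p
        record("angles", t0, **paths)

    if "segments" in stages:
        t0 = time.time()
        need_tensors("segments")
        paths = {}
        for ctx, tensor in tensors.items():
            p = out / f"separation_grid_{ctx}.csv"
            separation_grid(tensor).to_csv(p)
            paths[ctx] = p
        record("segments", t0, **paths)

    if "decode" in stages:
        t0 = time.time()
        need_tensors("decode")
        paths = {}
        for ctx, tensor in tensors.items():
            series = instantaneous_subspaces(tensor)
            for ev in cfg.decode_events:
                curve = slide_decode(
                    tensor,
                    series,
                    ev,
                    folds=cfg.n_folds,
                    grid_step=cfg.decode_grid_step,
                    seed=cfg.seed,
                    max_epochs=cfg.max_epochs,
                )
                if cfg.n_chance_decode:
                    curve.chance_mean, curve.chance_sd = chance_decode(
                        tensor,
                        ev,
                        n_rand=cfg.n_chance_decode,
                        seed=cfg.seed,
                        max_epochs=cfg.max_epochs,
                    )
                p = out / f"decode_{ev}_within_{ctx}.csv"
                _decode_frame(curve).to_csv(p, index=False)
                paths[f"{ev}_{ctx}"] = p
        record("decode", t0, **paths)

    if "align" in stages:
        t0 = time.time()
        need_tensors("align")
        if set(tensors) < set(CONTEXTS):
            raise RuntimeError("align requires tensors for both contexts")
        paths = {}
        summaries = []
        for ev in cfg.align_events:
            src_e = SegmentSource(
                population(tensors["execution"], "MN"), ev, label="MN:E"
            )
            src_o = SegmentSource(
                population(tensors["observation"], "MN"), ev, label="MN:O"
            )
            outcomes = [
                bootstrap_cca(
                    src_e, src_o, label="MN:E/O",
                    trials_per_object=cfg.trials_per_object,
                    n_iter=cfg.n_iter, seed=cfg.seed,
                ),
                within_group_cca(
                    src_e, label="MN:E/E",
                    trials_per_object=cfg.trials_per_object,
                    n_iter=cfg.n_iter, seed=cfg.seed,
                ),
                within_group_cca(
                    src_o, label="MN:O/O",
                    trials_per_object=cfg.trials_per_object,
                    n_iter=cfg.n_iter, seed=cfg.seed,
                ),
            ]
            for oc in outcomes:
                p = out / f"cca_{oc.label.replace('/', '-').replace(':', '_')}_{ev}.csv"
                pd.DataFrame(
                    oc.coefficients, columns=["cc1", "cc2", "cc3"]
                ).rename_axis("iteration").to_csv(p)
                paths[f"{oc.label}_{ev}"] = p
                summaries.append(oc.summary_row())
        p = out / "cca_summary.csv"
        pd.DataFrame(summaries).to_csv(p, index=False)
        paths["summary"] = p
        record("align", t0, **paths)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
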