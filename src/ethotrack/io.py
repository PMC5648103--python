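"""Readers, writers and the experiment result store.

Frames travel as PNG image sequences with a CSV timestamp sidecar
(``timestamps.csv``: frame_index, t_seconds) because real-time tracking has a
variable frame clock that the container format cannot carry.  Trajectories,
behavior tables and event logs are plain CSV at fixed (6-decimal) precision —
and optionally HDF5 — grouped in a result-store directory stamped with a
hash of the run configuration so results can always be traced to the exact
settings and seed that produced them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import FrameSequence, Trajectory, TRAJECTORY_COLUMNS

__all__ = [
    "SCHEMA_VERSION",
    "IntegrityError",
    "write_frames",
    "read_frames",
    "ExperimentConfig",
    "ResultStore",
    "write_results",
    "read_results",
]

SCHEMA_VERSION = "1"
FLOAT_FMT = "%.6f"


class IntegrityError(RuntimeError):
    """Stored results do not match their recorded configuration or schema."""


# --- frames -----------------------------------------------------------------


def write_frames(seq: FrameSequence, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for i in range(len(seq)):
        iio.imwrite(out / f"frame_{i:06d}.png", seq.frames[i])
    pd.DataFrame(
        {"frame_index": np.arange(len(seq)), "t_seconds": seq.timestamps}
    ).to_csv(out / "timestamps.csv", index=False, float_format=FLOAT_FMT)
    return out


def read_frames(path: str | Path, fallback_fps: float = 2.0) -> FrameSequence:
    """Load a frame sequence from a PNG directory or a video container.

    A directory must contain ``frame_NNNNNN.png`` files with a
    ``timestamps.csv`` sidecar and no gaps in the index.  A video container
    without a sidecar gets timestamps synthesized from its FPS metadata (or
    ``fallback_fps``) with a warning — variable-rate timing is lost.
    """
    p = Path(path)
    if p.is_dir():
        sidecar = p / "timestamps.csv"
        if not sidecar.exists():
            raise FileNotFoundError(f"missing timestamp sidecar {sidecar}")
        ts = pd.read_csv(sidecar)
        frames = []
        for i in ts["frame_index"].astype(int):
            f = p / f"frame_{i:06d}.png"
            if not f.exists():
                raise FileNotFoundError(f"missing frame index {i} ({f.name})")
            img = iio.imread(f)
            if img.ndim == 3:
                img = img[..., 0]
            frames.append(img)
        return FrameSequence(frames=np.stack(frames), timestamps=ts["t_seconds"].to_numpy(float))
    frames = iio.imread(p)
    if frames.ndim == 4:
        frames = frames[..., 0]
    try:
        meta = iio.immeta(p)
        fps = float(meta.get("fps", fallback_fps))
    except Exception:
        fps = fallback_fps
    warnings.warn(
        f"{p.name}: no timestamp sidecar; synthesizing uniform timestamps at {fps} FPS",
        stacklevel=2,
    )
    t = np.arange(len(frames)) / fps
    return FrameSequence(frames=np.asarray(frames), timestamps=t)


# --- configuration ----------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run: paths, parameters and the seed."""

    template_path: str
    seed: int = 0
    tracker: dict = field(default_factory=dict)       # TrackerParams overrides
    classifier: dict = field(default_factory=dict)    # t_move / t_walk / window_s
    trigger: dict | None = None                       # trigger JSON grammar
    schedule: list[list[float]] | None = None
    mask_s: float = 5.0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return {
            "template_path": self.template_path,
            "seed": self.seed,
            "tracker": self.tracker,
            "classifier": self.classifier,
            "trigger": self.trigger,
            "schedule": self.schedule,
            "mask_s": self.mask_s,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        cfg = cls.from_dict(json.loads(Path(path).read_text()))
        if not Path(cfg.template_path).exists():
            raise FileNotFoundError(f"arena template {cfg.template_path} not found")
        return cfg

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @property
    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# --- result store -----------------------------------------------------------


@dataclass
class ResultStore:
    """In-memory bundle of a run's tables, keyed by ROI."""

    config: ExperimentConfig
    trajectories: dict[int, Trajectory] = field(default_factory=dict)
    behavior: pd.DataFrame | None = None
    events: pd.DataFrame | None = None


def _round_trip_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(6)
    return out


def write_results(store: ResultStore, path: str | Path, hdf5: bool = False) -> Path:
    out = Path(path)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    store.config.save(out / "config.json")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": store.config.hash,
        "rois": sorted(store.trajectories),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    for roi, traj in store.trajectories.items():
        df = traj.df.copy()
        df.to_csv(
            out / "trajectories" / f"roi_{roi:03d}.csv", index=False, float_format=FLOAT_FMT
        )
        if hdf5:
            df.to_hdf(out / "trajectories.h5", key=f"roi_{roi:03d}", mode="a")
        (out / "trajectories" / f"roi_{roi:03d}.meta.json").write_text(
            json.dumps(
                {
                    "roi_index": traj.roi_index,
                    "mm_per_px": traj.mm_per_px,
                    "crop_origin": list(traj.crop_origin),
                }
            )
        )
    if store.behavior is not None:
        store.behavior.to_csv(out / "behavior.csv", index=False, float_format=FLOAT_FMT)
    if store.events is not None:
        store.events.to_csv(out / "events.csv", index=False, float_format=FLOAT_FMT)
    return out


def read_results(path: str | Path) -> ResultStore:
    out = Path(path)
    meta = json.loads((out / "metadata.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise IntegrityError(
            f"schema version mismatch: store has {meta.get('schema_version')!r}, "
            f"reader expects {SCHEMA_VERSION!r}"
        )
    config = ExperimentConfig.from_dict(json.loads((out / "config.json").read_text()))
    if config.hash != meta["config_hash"]:
        raise IntegrityError("config hash does not match the stored metadata")
    store = ResultStore(config=config)
    for roi in meta["rois"]:
        df = pd.read_csv(out / "trajectories" / f"roi_{roi:03d}.csv")
        df["is_inferred"] = df["is_inferred"].astype(bool)
        tmeta = json.loads((out / "trajectories" / f"roi_{roi:03d}.meta.json").read_text())
        store.trajectories[roi] = Trajectory(
            df[TRAJECTORY_COLUMNS],
            roi_index=tmeta["roi_index"],
            mm_per_px=tmeta["mm_per_px"],
            crop_origin=tuple(tmeta["crop_origin"]),
        )
    if (out / "behavior.csv").exists():
        store.behavior = pd.read_csv(out / "behavior.csv")
    if (out / "events.csv").exists():
        store.events = pd.read_csv(out / "events.csv")
    return store
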