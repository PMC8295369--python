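"""File formats for the pipeline stages.

Stages communicate through plain containers: RF frames and parametric
maps in HDF5, label maps in HDF5, cohorts and feature tables as CSV,
models and metrics as JSON, configurations as YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .segmentation import HMRFModel
from .spectral import ParametricMapSet, PhantomSpec, RFFrame

__all__ = [
    "save_rf_container",
    "load_rf_container",
    "save_maps",
    "load_maps",
    "save_labels",
    "load_labels",
    "save_model",
    "load_model",
    "save_json",
    "load_yaml",
    "file_sha256",
]


def _frame_to_group(g: h5py.Group, frame: RFFrame) -> None:
    g.create_dataset("rf", data=frame.samples)
    g.attrs.update({
        "sampling_rate": frame.sampling_rate,
        "lateral_spacing": frame.lateral_spacing,
        "sound_speed": frame.sound_speed,
        "band_low": frame.band[0],
        "band_high": frame.band[1],
        "center_frequency": frame.center_frequency,
    })


def _frame_from_group(g: h5py.Group) -> RFFrame:
    return RFFrame(
        samples=g["rf"][()],
        sampling_rate=float(g.attrs["sampling_rate"]),
        lateral_spacing=float(g.attrs["lateral_spacing"]),
        sound_speed=float(g.attrs["sound_speed"]),
        band=(float(g.attrs["band_low"]), float(g.attrs["band_high"])),
        center_frequency=float(g.attrs["center_frequency"]),
    )


def save_rf_container(
    path: str | Path, frames: list[RFFrame], phantom: PhantomSpec | None = None
) -> None:
    """RF frames (+ optional reference-phantom frames) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for i, frame in enumerate(frames):
            _frame_to_group(f.create_group(f"plane_{i:03d}"), frame)
        if phantom is not None:
            pg = f.create_group("phantom")
            pg.attrs["attenuation"] = phantom.attenuation
            pg.attrs["sound_speed"] = phantom.sound_speed
            for i, frame in enumerate(phantom.frames):
                _frame_to_group(pg.create_group(f"frame_{i:03d}"), frame)


def load_rf_container(path: str | Path) -> tuple[list[RFFrame], PhantomSpec | None]:
    with h5py.File(path, "r") as f:
        frames = [
            _frame_from_group(f[k]) for k in sorted(f) if k.startswith("plane_")
        ]
        phantom = None
        if "phantom" in f:
            pg = f["phantom"]
            phantom = PhantomSpec(
                attenuation=float(pg.attrs["attenuation"]),
                sound_speed=float(pg.attrs["sound_speed"]),
                frames=[_frame_from_group(pg[k]) for k in sorted(pg)],
            )
    return frames, phantom


def save_maps(path: str | Path, maps: ParametricMapSet) -> None:
    with h5py.File(path, "w") as f:
        for name, arr in maps.channels.items():
            f.create_dataset(name, data=arr)
        f.create_dataset("valid", data=maps.valid)
        f.create_dataset("axial_centers", data=maps.axial_centers)
        f.create_dataset("lateral_centers", data=maps.lateral_centers)


def load_maps(path: str | Path) -> ParametricMapSet:
    with h5py.File(path, "r") as f:
        channels = {
            name: f[name][()] for name in ParametricMapSet.CHANNEL_NAMES if name in f
        }
        return ParametricMapSet(
            channels=channels,
            valid=f["valid"][()].astype(bool),
            axial_centers=f["axial_centers"][()],
            lateral_centers=f["lateral_centers"][()],
        )


def save_labels(path: str | Path, labels: list[np.ndarray]) -> None:
    with h5py.File(path, "w") as f:
        for i, lab in enumerate(labels):
            f.create_dataset(f"labels_{i:03d}", data=lab.astype(np.int16))


def load_labels(path: str | Path) -> list[np.ndarray]:
    with h5py.File(path, "r") as f:
        return [f[k][()].astype(int) for k in sorted(f)]


def save_model(path: str | Path, model: HMRFModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path) -> HMRFModel:
    return HMRFModel.from_dict(json.loads(Path(path).read_text()))


def save_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_cohort(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
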