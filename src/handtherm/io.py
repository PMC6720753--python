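"""Interchange formats and run configuration.

A thermal sequence is stored as a directory: ``manifest.json`` (frame rate,
phase boundaries, timestamps, emissivity, ambient temperature, units) plus one
single-channel 32-bit-float TIFF per frame (row-major, °C).  The camera-native
radiometric format is proprietary and undeposited, so this portable layout is
the package's interchange format.  Masks/skeletons export as PNG, ROIs and
metrics as CSV; every artifact can carry the configuration hash of the run
that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from handtherm.preprocessing import DEFAULT_WINDOW
from handtherm.segmentation import FingerROI, SegmentationResult
from handtherm.synthetic import ThermalSequence, Thermogram

__all__ = [
    "RunConfig",
    "write_sequence",
    "read_sequence",
    "write_rois",
    "read_rois",
    "write_segmentation_images",
    "SequenceFormatError",
]


class SequenceFormatError(ValueError):
    """The on-disk sequence directory violates the manifest contract."""


@dataclasses.dataclass
class RunConfig:
    """Serializable configuration of one pipeline run.

    Defaults mirror the acquisition protocol (5 s cooling, 180 s rewarming,
    emissivity 0.98, ambient 23 °C); every field is written with the run so
    outputs are reproducible from the config alone.
    """

    preset: str = "moderate"
    frame_rate: float = 1.0
    cooling_duration: float = 5.0
    rewarming_duration: float = 180.0
    emissivity: float = 0.98
    ambient: float = 23.0
    noise_sd: float = 0.0
    t_min: float = DEFAULT_WINDOW[0]
    t_max: float = DEFAULT_WINDOW[1]
    steps: tuple = ("average", "median", ("gamma", 0.8))
    min_branch_length: int = 10
    max_restarts: int = 2
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "handtherm-out"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "steps" in raw:
            raw["steps"] = tuple(tuple(s) if isinstance(s, list) else s
                                 for s in raw["steps"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# sequence round trip


def write_sequence(sequence: ThermalSequence, path) -> Path:
    """Write a sequence directory: manifest.json + frame_####.tif (float32 °C)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = dict(sequence.manifest)
    manifest["frames"] = []
    for i, frame in enumerate(sequence.frames):
        name = f"frame_{i:04d}.tif"
        tifffile.imwrite(path / name, frame.temperature.astype(np.float32))
        manifest["frames"].append(
            {"file": name, "phase": frame.phase, "time_s": frame.time_s})
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_sequence(path) -> ThermalSequence:
    """Read a sequence directory back; validates units, frame count, ordering."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SequenceFormatError(f"missing manifest.json in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("units") != "degC":
        raise SequenceFormatError(
            f"unsupported units {manifest.get('units')!r}; expected 'degC'")
    entries = manifest.get("frames", [])
    if manifest.get("n_frames") != len(entries):
        raise SequenceFormatError(
            f"manifest n_frames={manifest.get('n_frames')} but "
            f"{len(entries)} frame entries listed")
    frames: list[Thermogram] = []
    last = {}
    for entry in entries:
        fp = path / entry["file"]
        if not fp.exists():
            raise SequenceFormatError(f"missing frame file {entry['file']}")
        phase = entry["phase"]
        t = float(entry["time_s"])
        if phase in last and t <= last[phase]:
            raise SequenceFormatError(
                f"non-monotone timestamps within phase {phase!r}")
        last[phase] = t
        frames.append(Thermogram(temperature=tifffile.imread(fp).astype(np.float32),
                                 time_s=t, phase=phase))
    for phase, spec in manifest.get("phases", {}).items():
        n = sum(1 for f in frames if f.phase == phase)
        if n != spec.get("n_frames"):
            raise SequenceFormatError(
                f"phase {phase!r}: manifest says {spec.get('n_frames')} frames, "
                f"found {n}")
    return ThermalSequence(frames=frames, manifest=manifest)


# ---------------------------------------------------------------------------
# ROI / image exports


def write_rois(rois: list[FingerROI], path) -> Path:
    path = Path(path)
    rows = [
        {"finger": roi.label, "path_index": i, "row": r, "col": c}
        for roi in rois
        for i, (r, c) in enumerate(roi.path)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_rois(path) -> list[FingerROI]:
    df = pd.read_csv(path)
    rois = []
    for label, grp in df.groupby("finger", sort=False):
        grp = grp.sort_values("path_index")
        rois.append(FingerROI(label=str(label),
                              path=tuple(zip(grp["row"].astype(int),
                                             grp["col"].astype(int)))))
    return rois


def write_segmentation_images(result: SegmentationResult, out_dir) -> None:
    """Mask and skeleton as 8-bit PNGs for visual inspection."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "mask.png",
                (result.mask.data.astype(np.uint8) * 255))
    iio.imwrite(out_dir / "skeleton.png",
                (result.skeleton.data.astype(np.uint8) * 255))
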