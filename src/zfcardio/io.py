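"""Calibrated image containers and file I/O.

Conventions fixed once, package-wide:

* image axis order is ``(time_or_z, row, column)``; row 0 is the top of the
  image and x increases with column index;
* all lengths are µm, areas µm², volumes µm³ internally; reports additionally
  carry volumes in nL (1 nL = 1e6 µm³) and cardiac output in nL/min;
* the timestamp of frame ``i`` is ``i / fps`` seconds (constant-rate camera);
* calibration is never inferred from pixel data — fps, pixel size and z-step
  are always user-supplied and must be strictly positive.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import FormatError

__all__ = [
    "Calibration",
    "VideoSequence",
    "VoxelStack",
    "read_video",
    "read_stack",
    "write_video",
    "write_stack",
    "write_report",
    "read_report",
    "load_config",
]

NL_PER_UM3 = 1e-6  # 1 nL = 1e6 µm³


@dataclass(frozen=True)
class Calibration:
    """Acquisition calibration. ``z_step`` only applies to confocal stacks."""

    fps: float | None = None
    pixel_size: float | None = None
    z_step: float | None = None

    def __post_init__(self) -> None:
        for name in ("fps", "pixel_size", "z_step"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"Calibration.{name} must be > 0, got {v!r}")

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise ValueError(
                    f"calibration field {name!r} is required and has no default; "
                    "it must be supplied explicitly"
                )


@dataclass
class VideoSequence:
    """A calibrated T×H×W grayscale movie."""

    frames: np.ndarray
    fps: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3D (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("video must contain at least one frame")
        if not self.fps > 0 or not self.pixel_size > 0:
            raise ValueError("fps and pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Total covered time in seconds (T / fps)."""
        return self.n_frames / self.fps

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class VoxelStack:
    """A calibrated 3D image, axis order (z, y, x), voxel_size = (µm_z, µm_y, µm_x)."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got shape {self.voxels.shape}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(not v > 0 for v in vs):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size!r}")
        self.voxel_size = vs

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        z, y, x = self.voxel_size
        return z * y * x


def _read_pages(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) == 0:
                raise FormatError(f"{path}: TIFF contains zero pages")
            for page in tf.pages:
                if page.samplesperpixel != 1:
                    raise FormatError(
                        f"{path}: page has {page.samplesperpixel} samples per pixel; "
                        "only grayscale TIFFs are supported"
                    )
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise FormatError(f"{path}: ragged pages with shapes {sorted(shapes)}")
            arr = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises several internal types
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected multi-page grayscale TIFF, got array of shape {arr.shape} "
            "(RGB or higher-dimensional data is not supported)"
        )
    if arr.shape[0] == 0:
        raise FormatError(f"{path}: TIFF contains zero pages")
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: expected unsigned 8- or 16-bit data, got {arr.dtype}")
    return arr


def read_video(path: str | Path, calib: Calibration) -> VideoSequence:
    """Read a multi-page grayscale TIFF as a time-lapse video.

    Pages are taken in file order as consecutive frames. ``calib`` must carry
    ``fps`` and ``pixel_size``; calibration is never guessed from the file.
    """
    calib.require("fps", "pixel_size")
    frames = _read_pages(path)
    return VideoSequence(frames=frames, fps=calib.fps, pixel_size=calib.pixel_size)


def read_stack(path: str | Path, calib: Calibration) -> VoxelStack:
    """Read a multi-page grayscale TIFF as a z-stack (pages ordered by z)."""
    calib.require("z_step", "pixel_size")
    voxels = _read_pages(path)
    return VoxelStack(voxels=voxels, voxel_size=(calib.z_step, calib.pixel_size, calib.pixel_size))


def write_video(video: VideoSequence, path: str | Path) -> None:
    tifffile.imwrite(path, video.frames)


def write_stack(stack: VoxelStack, path: str | Path) -> None:
    tifffile.imwrite(path, stack.voxels)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _flatten(record: dict) -> dict:
    """Keep scalar fields only; nested/per-item detail goes to the JSON sidecar."""
    return {
        k: v
        for k, v in record.items()
        if isinstance(v, (int, float, str, bool)) or v is None
    }


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(reports, path: str | Path, columns: list[str] | None = None) -> None:
    """Write reports as a flat CSV plus a JSON sidecar with full detail.

    ``reports`` is a report dataclass or a list of them. The CSV holds one row
    per report with scalar fields only; the sidecar ``<path>.json`` keeps every
    field including per-beat / per-track arrays. Floats are written with
    shortest-repr so a read-back reproduces them bit-exactly.
    """
    if dataclasses.is_dataclass(reports) and not isinstance(reports, type):
        reports = [reports]
    records = [_jsonable(r) for r in reports]
    flat = [_flatten(r) for r in records]

    if columns is None:
        columns = list(flat[0].keys()) if flat else []
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
        writer.writeheader()
        for row in flat:
            writer.writerow({k: repr(v) if isinstance(v, float) else v for k, v in row.items()})
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(records, fh, indent=2)


def read_report(path: str | Path) -> list[dict]:
    """Read back the JSON sidecar of :func:`write_report` (full precision)."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        return json.load(fh)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
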