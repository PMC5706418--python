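"""Volumetric image I/O and the coordinate/metadata contract.

A z-stack is a 3-D grid of fluorescence intensities indexed ``(z, y, x)``
(0-based, bounding boxes half-open) with an anisotropic physical voxel size
``(dz, dy, dx)`` in micrometres.  Confocal acquisitions of cells on polymer
scaffolds are stored as multi-page 16-bit TIFF files, one page per z-frame;
in memory intensities are floating point.  Voxel size is carried as metadata
and never triggers implicit resampling — physical units enter only where a
measurement requires them (plane residuals, fiber radii).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

#: Acquisition default for the confocal setup this package targets:
#: (dz, dy, dx) = (0.462, 0.12, 0.12) micrometres.
DEFAULT_VOXEL_SIZE = (0.462, 0.12, 0.12)

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class ZStack:
    """A single-channel 3-D image with physical voxel size metadata.

    Parameters
    ----------
    voxels
        3-D array in ``(z, y, x)`` order; nonnegative finite intensities.
    voxel_size
        ``(dz, dy, dx)`` in micrometres, all positive.
    channel_name
        Free-text channel label (e.g. ``"cell"`` or ``"scaffold"``).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3-D (z,y,x) array, got ndim={self.voxels.ndim}")
        if min(self.voxels.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)  # type: ignore[assignment]
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dz, dy, dx)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def astype(self, dtype) -> "ZStack":
        return replace(self, voxels=self.voxels.astype(dtype))


@dataclass
class ZStackPair:
    """Co-registered cell and scaffold channels of one field of view."""

    cell: ZStack
    scaffold: ZStack

    def __post_init__(self) -> None:
        if self.cell.shape != self.scaffold.shape:
            raise ValueError(
                f"channels are not co-registered: {self.cell.shape} vs {self.scaffold.shape}"
            )
        if not np.allclose(self.cell.voxel_size, self.scaffold.voxel_size):
            raise ValueError("channels must share one voxel size")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cell.shape


def _voxel_size_from_sidecar(path: Path) -> tuple[float, float, float] | None:
    """Look for ``<stem>.json`` or ``<stem>.yaml`` next to a TIFF."""
    for suffix in (".json", ".yaml", ".yml"):
        sidecar = path.with_suffix(suffix)
        if sidecar.exists():
            if suffix == ".json":
                meta = json.loads(sidecar.read_text())
            else:
                import yaml

                meta = yaml.safe_load(sidecar.read_text())
            if meta and "voxel_size" in meta:
                return tuple(float(v) for v in meta["voxel_size"])  # type: ignore[return-value]
    return None


def read_zstack(
    path: str | Path | Sequence[str | Path],
    voxel_size: tuple[float, float, float] | None = None,
    channel_name: str = "",
) -> ZStack:
    """Read a multi-page TIFF (or an ordered list of 2-D TIFF frames).

    Frames are stacked in z order.  Voxel size is taken from, in priority
    order: the ``voxel_size`` argument, a JSON/YAML sidecar with a
    ``voxel_size`` key, or :data:`DEFAULT_VOXEL_SIZE`.  NIfTI volumes
    (``.nii``/``.nii.gz``) are also accepted for interoperability.
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if "".join(p.suffixes).lower() in (".nii", ".nii.gz"):
            import nibabel as nib

            img = nib.load(str(p))
            data = np.asarray(img.dataobj).T  # (x,y,z) -> (z,y,x)
            if voxel_size is None:
                zooms = img.header.get_zooms()[:3]
                voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
            return ZStack(np.atleast_3d(data), voxel_size or DEFAULT_VOXEL_SIZE, channel_name)
        arr = tifffile.imread(str(p))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"{p}: expected a 2-D or 3-D TIFF, got ndim={arr.ndim}")
        if voxel_size is None:
            voxel_size = _voxel_size_from_sidecar(p)
        return ZStack(arr, voxel_size or DEFAULT_VOXEL_SIZE, channel_name)

    frames = []
    for frame_path in path:
        frame = tifffile.imread(str(frame_path))
        if frame.ndim != 2:
            raise ValueError(f"{frame_path}: frame is not 2-D")
        frames.append(frame)
    if not frames:
        raise ValueError("empty frame list")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
    return ZStack(np.stack(frames), voxel_size or DEFAULT_VOXEL_SIZE, channel_name)


def write_zstack(stack: ZStack, path: str | Path, dtype=np.uint16) -> Path:
    """Write a z-stack as a multi-page TIFF plus a JSON metadata sidecar.

    16-bit unsigned is the canonical on-disk intensity type; pass
    ``dtype=np.float32`` to persist probability volumes losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.voxels
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        data = np.clip(np.rint(data), info.min, info.max)
    tifffile.imwrite(str(path), data.astype(dtype))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"voxel_size": list(stack.voxel_size), "channel_name": stack.channel_name})
    )
    return path


def max_projection(stack: ZStack | np.ndarray, axis: str = "z") -> np.ndarray:
    """Maximum-intensity projection along one axis.

    Collapsing ``z`` yields the familiar top view; the ``y`` projection is the
    ``[X, Z]`` side view used for z-profile analysis.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of z, y, x; got {axis!r}")
    voxels = stack.voxels if isinstance(stack, ZStack) else np.asarray(stack)
    return voxels.max(axis=_AXIS_INDEX[axis])
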