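"""Background modeling, simplified cell segmentation, and ROI cropping.

Contact points occur only in a one-voxel neighborhood of the cell surface,
so each [cell, scaffold] pair is cropped to the cell bounding box expanded
by a 10% margin per x/y side; the z extent is chosen from the scaffold
channel's z-intensity profile (inflection analysis of the smoothed profile).
The background intensity model (mean, std) is estimated from the first or
last z-frame, which images medium/substrate rather than the stained cell.

Cell segmentation here is a deliberately simple pipeline — max-entropy
threshold, largest 26-connected component, per-slice hole filling and one
morphological closing — sufficient to produce the single compact cell mask
the cropping and contact stages require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume_io import ZStack, ZStackPair

MARGIN_FRACTION = 0.10  # x/y bounding-box margin per side
ZPROFILE_GAUSSIAN_LEN = 21  # smoothing kernel length for the z-profile
ZPROFILE_GAUSSIAN_SIGMA = 5.0
MIN_Z_FRAMES_FOR_PROFILE = 25
_MIN_BBOX_EXTENT = 8  # voxels, for degenerate (near-point) cell masks


@dataclass
class BackgroundModel:
    """First/last-frame background intensity statistics."""

    mean: float
    std: float
    source_frame: str = "first"

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be nonnegative")


@dataclass
class RegionOfInterest:
    """Half-open (z, y, x) index intervals of a crop box."""

    z_range: tuple[int, int]
    y_range: tuple[int, int]
    x_range: tuple[int, int]

    def __post_init__(self) -> None:
        for lo, hi in (self.z_range, self.y_range, self.x_range):
            if hi <= lo:
                raise ValueError("ROI intervals must be nonempty half-open ranges")

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.z_range), slice(*self.y_range), slice(*self.x_range))


def estimate_background(stack: ZStack, frame: str = "first") -> BackgroundModel:
    """Mean/std over all pixels of the first or last z-frame.

    Emits a warning when the chosen frame appears to contain foreground
    (>= 1% of pixels above 10x the frame median).
    """
    if frame not in ("first", "last"):
        raise ValueError("frame must be 'first' or 'last'")
    if stack.shape[0] < 2:
        raise ValueError("background estimation needs at least 2 z-frames")
    plane = stack.voxels[0 if frame == "first" else -1].astype(float)
    median = float(np.median(plane))
    if median > 0 and float((plane > 10 * median).mean()) >= 0.01:
        warnings.warn(f"{frame} frame looks saturated/foreground-contaminated")
    return BackgroundModel(mean=float(plane.mean()), std=float(plane.std()), source_frame=frame)


def segment_cell(
    cell_stack: ZStack, background: BackgroundModel | None = None
) -> tuple[np.ndarray, str]:
    """Simplified single-cell segmentation.

    Max-entropy threshold on intensities, keep the largest 26-connected
    component, fill holes per z-slice, one binary closing.  Returns the mask
    and a status, ``"ok"`` or ``"missed"`` (empty foreground).
    """
    from .statistical import max_entropy_threshold

    values = np.asarray(cell_stack.voxels, dtype=float)
    if np.ptp(values) == 0:
        return np.zeros(values.shape, dtype=bool), "missed"
    _, mask = max_entropy_threshold(values)
    if not mask.any():
        return mask, "missed"
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        return np.zeros_like(mask), "missed"
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    for z in range(mask.shape[0]):
        mask[z] = ndi.binary_fill_holes(mask[z])
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3, 3)), iterations=1)
    if not mask.any():
        return mask, "missed"
    return mask, "ok"


def _profile_inflection_bounds(profile: np.ndarray) -> tuple[int, int, bool]:
    """Zero-crossings of the smoothed profile's second derivative nearest
    below/above the argmax.  Returns (lo, hi_exclusive, warned)."""
    n = len(profile)
    radius = ZPROFILE_GAUSSIAN_LEN // 2
    t = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (t / ZPROFILE_GAUSSIAN_SIGMA) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(profile.astype(float), radius, mode="reflect")
    smooth = np.convolve(padded, kernel, mode="valid")
    d2 = np.gradient(np.gradient(smooth))
    peak = int(np.argmax(smooth))
    sign = np.sign(d2)
    crossings = np.where(np.diff(sign) != 0)[0]  # crossing between i and i+1
    warned = False
    below = crossings[crossings < peak]
    above = crossings[crossings >= peak]
    if below.size:
        lo = int(below.max())
    else:
        lo, warned = 0, True
    if above.size:
        hi = int(above.min()) + 1
    else:
        hi, warned = n - 1, True
    return lo, min(hi + 1, n), warned


def select_z_bounds(scaffold: ZStack) -> tuple[int, int]:
    """Z crop interval from the scaffold channel's intensity profile.

    The z-profile is the per-frame maximum of the [X, Z] max projection,
    smoothed with a length-21 Gaussian (sigma 5, reflected boundaries); the
    crop bounds are the second-derivative zero-crossings nearest below and
    above the profile maximum.  Stacks with fewer than 25 frames, constant
    profiles, or a side with no zero-crossing fall back to the volume edge.
    """
    n = scaffold.shape[0]
    if n < MIN_Z_FRAMES_FOR_PROFILE:
        return 0, n
    profile = scaffold.voxels.max(axis=(1, 2)).astype(float)
    if np.ptp(profile) == 0:
        warnings.warn("constant z-profile; returning the full z range")
        return 0, n
    lo, hi, warned = _profile_inflection_bounds(profile)
    if warned:
        warnings.warn("no inflection found on one side; bound fell back to the volume edge")
    return lo, hi


def crop_roi(
    pair: ZStackPair,
    cell_mask: np.ndarray,
    margin_fraction: float = MARGIN_FRACTION,
) -> tuple[ZStackPair, RegionOfInterest]:
    """Crop both channels to the margined cell bounding box.

    x/y intervals are the cell bounding box expanded by ``margin_fraction``
    of its width/height on each side (clipped to the volume); the z interval
    comes from :func:`select_z_bounds` on the scaffold channel, widened if
    needed to cover the cell in z.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != pair.shape:
        raise ValueError("mask shape does not match the pair")
    if not cell_mask.any():
        raise ValueError("empty cell mask")

    zs, ys, xs = np.nonzero(cell_mask)
    bounds = []
    for coords, dim, use_margin in ((ys, pair.shape[1], True), (xs, pair.shape[2], True)):
        lo, hi = int(coords.min()), int(coords.max()) + 1
        extent = hi - lo
        if extent < _MIN_BBOX_EXTENT:
            warnings.warn("degenerate cell bounding box; expanding to minimum extent")
            pad = (_MIN_BBOX_EXTENT - extent + 1) // 2
            lo, hi = lo - pad, hi + pad
            extent = hi - lo
        margin = int(round(margin_fraction * extent))
        bounds.append((max(0, lo - margin), min(dim, hi + margin)))
    (y_lo, y_hi), (x_lo, x_hi) = bounds

    z_lo, z_hi = select_z_bounds(pair.scaffold)
    z_lo = min(z_lo, int(zs.min()))
    z_hi = max(z_hi, int(zs.max()) + 1)

    roi = RegionOfInterest((z_lo, z_hi), (y_lo, y_hi), (x_lo, x_hi))
    sl = roi.slices()
    cropped = ZStackPair(
        cell=ZStack(pair.cell.voxels[sl], pair.cell.voxel_size, pair.cell.channel_name),
        scaffold=ZStack(
            pair.scaffold.voxels[sl], pair.scaffold.voxel_size, pair.scaffold.channel_name
        ),
    )
    return cropped, roi
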