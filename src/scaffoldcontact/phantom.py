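"""Synthetic two-channel confocal phantoms with known ground truth.

The generator emulates the image-formation chain of a dual-stain confocal
acquisition of a cell on a polymer scaffold: analytic geometry (a flat
spun-coat slab, cylindrical electrospun fibers of known radius, an
ellipsoidal cell draped near the scaffold) is rasterized on the voxel grid,
blurred by an anisotropic Gaussian standing in for the point-spread
function, mixed across channels to mimic fluorophore bleed-through, and
finally corrupted by a background offset plus i.i.d. Gaussian noise.

Rasterization rule: a voxel is foreground iff its *center* lies inside the
analytic solid — no antialiasing, so analytic volume/position oracles are
exact; partial-volume effects come from the blur step instead.  Geometry is
specified in micrometres and mapped through the anisotropic voxel size.

Default dimensions follow the study design the package targets: large
microfibers (MF) of diameter 2.6 um, medium microfibers (MMF) of diameter
1.1 um, voxel size (0.462, 0.12, 0.12) um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .volume_io import DEFAULT_VOXEL_SIZE, ZStack, ZStackPair

# Nominal fiber radii (um) for the two electrospun scaffold classes.
MF_RADIUS_UM = 2.6 / 2
MMF_RADIUS_UM = 1.1 / 2


@dataclass
class Fiber:
    """A cylinder: point on axis + unit direction (both in um), radius in um."""

    point_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius_um: float
    intensity: float = 3000.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("fiber radius must be positive")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("fiber direction must be nonzero")
        self.direction = tuple(d / n)  # type: ignore[assignment]


@dataclass
class Cell:
    """An ellipsoidal cell body: center and semi-axes in um (z, y, x order)."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    intensity: float = 5000.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic [cell, scaffold] pair.

    ``kind`` selects the scaffold geometry: ``spun_coat`` is a slab bounded
    by the plane a*x + b*y + c*z + d = 0 (coordinates in um) and thickness
    ``slab_thickness_um``; ``fiber_bundle`` is a union of cylinders.
    """

    kind: str = "fiber_bundle"  # {"spun_coat", "fiber_bundle"}
    plane_coeffs: tuple[float, float, float, float] = (0.0, 0.0, 1.0, -5.0)
    slab_thickness_um: float = 2.0
    slab_intensity: float = 3000.0
    fibers: Sequence[Fiber] = field(default_factory=list)
    cell: Cell | None = None
    background_offset: float = 200.0
    noise_sigma: float = 30.0
    bleed_alpha: float = 0.0
    blur_sigma_um: tuple[float, float, float] = (0.6, 0.2, 0.2)  # (z,y,x); zeros = off
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed_alpha < 1.0:
            raise ValueError("bleed_alpha must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.kind not in ("spun_coat", "fiber_bundle"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def _physical_grids(dims, voxel_size):
    """Voxel-center coordinates in um, broadcastable (z, y, x)."""
    dz, dy, dx = voxel_size
    z = np.arange(dims[0])[:, None, None] * dz
    y = np.arange(dims[1])[None, :, None] * dy
    x = np.arange(dims[2])[None, None, :] * dx
    return z, y, x


def _rasterize_scaffold(spec: PhantomSpec, dims, voxel_size):
    z, y, x = _physical_grids(dims, voxel_size)
    mask = np.zeros(dims, dtype=bool)
    intensity = np.zeros(dims, dtype=float)
    if spec.kind == "spun_coat":
        a, b, c, d = spec.plane_coeffs
        norm = np.hypot(np.hypot(a, b), c)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        dist = (a * x + b * y + c * z + d) / norm
        mask = np.abs(dist) <= spec.slab_thickness_um / 2
        intensity[mask] = spec.slab_intensity
    else:
        for fiber in spec.fibers:
            pz, py, px = fiber.point_um
            uz, uy, ux = fiber.direction
            rz, ry, rx = z - pz, y - py, x - px
            t = rz * uz + ry * uy + rx * ux
            d2 = (rz - t * uz) ** 2 + (ry - t * uy) ** 2 + (rx - t * ux) ** 2
            fmask = d2 <= fiber.radius_um**2
            mask |= fmask
            intensity = np.maximum(intensity, np.where(fmask, fiber.intensity, 0.0))
    return mask, intensity


def _rasterize_cell(cell: Cell, dims, voxel_size):
    z, y, x = _physical_grids(dims, voxel_size)
    cz, cy, cx = cell.center_um
    az, ay, ax_ = cell.semi_axes_um
    mask = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0
    return mask, np.where(mask, cell.intensity, 0.0)


def ground_truth_contact(
    cell_mask: np.ndarray, scaffold_mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Contact voxels: co-occurrence of both labels or 1-voxel adjacency."""
    from .geometrical import binary_contact

    return binary_contact(cell_mask, scaffold_mask, connectivity=connectivity)


def render_phantom(
    spec: PhantomSpec,
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
) -> tuple[ZStackPair, dict[str, np.ndarray]]:
    """Render a [cell, scaffold] pair plus ground-truth masks.

    Image formation per channel: rasterized intensity -> Gaussian blur
    (``blur_sigma_um`` converted to voxels per axis) -> add background
    offset -> linear symmetric bleed-through mixing with coefficient
    ``bleed_alpha`` -> additive Gaussian noise (``noise_sigma``).

    Returns the pair and ``{"cell", "scaffold", "contact"}`` boolean masks;
    the contact mask is derived from the pre-blur geometry.
    """
    if min(dims) < 1:
        raise ValueError("dims must be positive")
    scaffold_mask, scaffold_fg = _rasterize_scaffold(spec, dims, voxel_size)
    if spec.cell is not None:
        cell_mask, cell_fg = _rasterize_cell(spec.cell, dims, voxel_size)
    else:
        cell_mask = np.zeros(dims, dtype=bool)
        cell_fg = np.zeros(dims, dtype=float)
    if not scaffold_mask.any() and not cell_mask.any():
        raise ValueError("phantom geometry does not intersect the volume")

    sigma_vox = tuple(s / v for s, v in zip(spec.blur_sigma_um, voxel_size))
    cell_img, scaffold_img = cell_fg, scaffold_fg
    if any(s > 0 for s in sigma_vox):
        cell_img = ndi.gaussian_filter(cell_img, sigma=sigma_vox)
        scaffold_img = ndi.gaussian_filter(scaffold_img, sigma=sigma_vox)

    cell_img = cell_img + spec.background_offset
    scaffold_img = scaffold_img + spec.background_offset
    if spec.bleed_alpha > 0:
        # Symmetric linear mixing of the background-subtracted signals.
        a = spec.bleed_alpha
        cell_sig = cell_img - spec.background_offset
        scaf_sig = scaffold_img - spec.background_offset
        cell_img = cell_sig + a * scaf_sig + spec.background_offset
        scaffold_img = scaf_sig + a * cell_sig + spec.background_offset

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        cell_img = cell_img + rng.normal(0.0, spec.noise_sigma, dims)
        scaffold_img = scaffold_img + rng.normal(0.0, spec.noise_sigma, dims)
    cell_img = np.clip(cell_img, 0.0, None)
    scaffold_img = np.clip(scaffold_img, 0.0, None)

    pair = ZStackPair(
        cell=ZStack(cell_img, voxel_size, "cell"),
        scaffold=ZStack(scaffold_img, voxel_size, "scaffold"),
    )
    truth = {
        "cell": cell_mask,
        "scaffold": scaffold_mask,
        "contact": ground_truth_contact(cell_mask, scaffold_mask),
    }
    return pair, truth


def sample_fixture_suite(
    seed: int = 0, voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
) -> dict[str, tuple[ZStackPair, dict[str, np.ndarray], PhantomSpec]]:
    """A deterministic suite of small (<= 64^3) phantoms with ground truth.

    Covers: a spun-coat slab, a single fiber, two crossing fibers, a cell
    resting on the slab, a cell on a fiber, a cell far (>= 3 voxels) from any
    scaffold (empty true contact), and a strong bleed-through case.
    """
    dims = (24, 64, 64)
    dz, dy, dx = voxel_size
    cz = dims[0] * dz / 2  # mid-plane height in um
    cy = dims[1] * dy / 2
    cx = dims[2] * dx / 2
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)

    def fiber_along_x(y_um, z_um, radius, intensity=3000.0):
        return Fiber((z_um, y_um, 0.0), (0.0, 0.0, 1.0), radius, intensity)

    suite: dict[str, tuple[ZStackPair, dict[str, np.ndarray], PhantomSpec]] = {}

    specs = {
        "spun_coat": PhantomSpec(
            kind="spun_coat",
            plane_coeffs=(0.0, 0.0, 1.0, -cz),
            slab_thickness_um=4 * dz,
            seed=int(seeds[0]),
        ),
        "single_fiber": PhantomSpec(
            kind="fiber_bundle",
            fibers=[fiber_along_x(cy, cz, MF_RADIUS_UM)],
            seed=int(seeds[1]),
        ),
        "crossing_fibers": PhantomSpec(
            kind="fiber_bundle",
            fibers=[
                fiber_along_x(cy, cz, MF_RADIUS_UM),
                Fiber((cz, 0.0, cx), (0.0, 1.0, 0.0), MF_RADIUS_UM),
            ],
            seed=int(seeds[2]),
        ),
        "cell_on_plane": PhantomSpec(
            kind="spun_coat",
            plane_coeffs=(0.0, 0.0, 1.0, -(cz - 1.5)),
            slab_thickness_um=4 * dz,
            cell=Cell((cz + 1.0, cy, cx), (1.8, 3.0, 3.0)),
            seed=int(seeds[3]),
        ),
        "cell_on_fiber": PhantomSpec(
            kind="fiber_bundle",
            fibers=[fiber_along_x(cy, cz - 1.2, MF_RADIUS_UM)],
            cell=Cell((cz + 0.8, cy, cx), (1.8, 3.0, 3.0)),
            seed=int(seeds[4]),
        ),
        "cell_far_from_scaffold": PhantomSpec(
            kind="fiber_bundle",
            fibers=[fiber_along_x(cy, 2 * dz, MMF_RADIUS_UM)],
            cell=Cell((dims[0] * dz - 3.0, cy, cx), (1.5, 2.0, 2.0)),
            seed=int(seeds[5]),
        ),
        "bleed_through": PhantomSpec(
            kind="fiber_bundle",
            fibers=[fiber_along_x(cy - 3.0, cz, MF_RADIUS_UM)],
            cell=Cell((cz, cy + 2.0, cx), (1.8, 2.5, 2.5)),
            bleed_alpha=0.3,
            seed=int(seeds[6]),
        ),
    }
    for name, spec in specs.items():
        pair, truth = render_phantom(spec, dims, voxel_size)
        suite[name] = (pair, truth, spec)
    return suite
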