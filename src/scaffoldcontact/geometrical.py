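"""Geometry-based scaffold models and binary contact extraction.

Spun-coat (SC) scaffolds are flat polymer films modeled as planes: a
weighted least-squares plane f(x,y,z) = ax + by + cz + d (unit normal) is
fitted to the upper or lower film surface, with goodness-of-fit reported as
the residual standard deviation per stack,

    STD_k^RES = sqrt( sum_i w_ki f_k(x_i,y_i,z_i)^2 / (sum_i w_ki - wbar_k p) ),

p = 3 plane parameters, and pooled over K stacks as

    STD^POOLED = sqrt( sum_k (n_k - 1) (STD_k^RES)^2 / (sum_k n_k - K) ).

Fiber scaffolds (MF/MMF) are modeled as tubes: a Frangi vesselness filter
(Hessian eigenvalue analysis at scale sigma; sigma = 1.0 for method A6,
1.5 for A7) enhances tubular structure, and the enhanced, cell-masked
volume is binarized by the maximum-entropy criterion.  A8 is the ad-hoc
baseline: raw-intensity threshold, median filtering and small-component
removal.  Binary contact is co-occurrence or one-voxel adjacency of cell
and scaffold labels; the contact surface is the nonzero-gradient support
of the cell-masked scaffold segment.

All residual statistics are reported in nanometres; voxel indices are
mapped through the anisotropic voxel size where physical units matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume_io import ZStack

SIGMA_BY_METHOD = {"A6": 1.0, "A7": 1.5}
MIN_COMPONENT_VOXELS = 27  # A8 small-component removal


@dataclass
class PlaneFit:
    """Unit-normal plane ax + by + cz + d = 0 fitted to weighted points."""

    coeffs: tuple[float, float, float, float]
    n_points: int
    residual_std_nm: float
    surface: str = "upper"
    p: int = 3  # independent plane parameters

    @property
    def normal(self) -> np.ndarray:
        return np.asarray(self.coeffs[:3])


@dataclass
class VesselnessParams:
    """Frangi filter constants at one Gaussian scale."""

    sigma: float = 1.0
    alpha: float = 0.5
    beta: float = 0.5
    c: float | None = None  # None: half the maximum Hessian Frobenius norm

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ContactSurface:
    """Voxel set of contact-surface points with provenance."""

    mask: np.ndarray
    provenance: str = "geometrical"


# ---------------------------------------------------------------------------
# Plane fitting (spun coat)


def fit_plane_points(
    points_um: np.ndarray, weights: np.ndarray, surface: str = "upper"
) -> PlaneFit:
    """Weighted total-least-squares plane through physical-space points.

    Minimizes sum w (a x + b y + c z + d)^2 subject to ||(a,b,c)|| = 1 via
    the weighted covariance's smallest eigenvector.  ``points_um`` is
    (n, 3) in (x, y, z) order, micrometres.
    """
    points_um = np.asarray(points_um, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    points_um, weights = points_um[keep], weights[keep]
    n = len(points_um)
    if n < 4:
        raise ValueError("plane fit needs at least 4 points with positive weight")
    wsum = weights.sum()
    centroid = (weights[:, None] * points_um).sum(axis=0) / wsum
    centered = points_um - centroid
    cov = (weights[:, None] * centered).T @ centered / wsum
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise ValueError("rank-deficient point set: points are collinear or coincident")
    normal = evecs[:, 0]
    if normal[2] < 0:  # orient +z for a stable sign convention
        normal = -normal
    d = -float(normal @ centroid)
    residuals_um = centered @ normal
    p = 3
    wbar = wsum / n
    denom = wsum - wbar * p
    if denom <= 0:
        raise ValueError("too few effective points for a residual estimate")
    std_um = float(np.sqrt((weights * residuals_um**2).sum() / denom))
    return PlaneFit(
        coeffs=(float(normal[0]), float(normal[1]), float(normal[2]), d),
        n_points=n,
        residual_std_nm=std_um * 1000.0,
        surface=surface,
    )


def _surface_points(
    stack: ZStack, weights: np.ndarray, surface: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(y,x)-column extreme-z surface voxel, in um.

    The surface sample of a column is its extreme voxel with weight at
    least half the column maximum — the half-maximum crossing marks the
    physical edge of a blurred film, whereas the outermost above-noise
    voxel would ride the blur tail.
    """
    if surface not in ("upper", "lower"):
        raise ValueError("surface must be 'upper' or 'lower'")
    w = np.asarray(weights, dtype=float)
    colmax = w.max(axis=0, keepdims=True)
    support = (w > 0) & (w >= 0.5 * colmax)
    cols = support.any(axis=0)
    ys, xs = np.nonzero(cols)
    zidx = np.where(support, np.arange(stack.shape[0])[:, None, None], -1)
    if surface == "upper":
        zsel = zidx.max(axis=0)[ys, xs]
    else:
        zidx_lo = np.where(support, np.arange(stack.shape[0])[:, None, None], stack.shape[0])
        zsel = zidx_lo.min(axis=0)[ys, xs]
    dz, dy, dx = stack.voxel_size
    points = np.column_stack([xs * dx, ys * dy, zsel * dz])
    return points, w[zsel, ys, xs]


def fit_plane_wls(
    stack: ZStack, weights: np.ndarray, surface: str = "upper"
) -> PlaneFit:
    """Fit the upper/lower film surface of a spun-coat z-stack.

    ``weights`` marks film voxels (e.g. normalized intensity above
    background; unit weights recover the ordinary least-squares residual).
    The extreme-z supported voxel of each (y, x) column defines the surface
    sample; the fit runs in physical micrometres.
    """
    points, w = _surface_points(stack, weights, surface)
    return fit_plane_points(points, w, surface)


def intensity_weights(
    stack: ZStack, background_mean: float, background_std: float = 0.0
) -> np.ndarray:
    """Default plane-fit weights: normalized intensity above background.

    Intensities below ``background_mean + 3 * background_std`` get zero
    weight so noise fluctuations do not masquerade as film voxels.
    """
    values = np.asarray(stack.voxels, dtype=float)
    floor = background_mean + 3.0 * background_std
    excess = np.where(values > floor, values - background_mean, 0.0)
    peak = excess.max()
    return excess / peak if peak > 0 else excess


def pooled_std(fits: list[PlaneFit]) -> float:
    """Pooled residual standard deviation over K plane fits (nm)."""
    if not fits:
        raise ValueError("need at least one plane fit")
    n = np.array([f.n_points for f in fits], dtype=float)
    if np.any(n < 2):
        raise ValueError("each fit must have n_k >= 2")
    k = len(fits)
    if n.sum() <= k:
        raise ValueError("sum of n_k must exceed K")
    s = np.array([f.residual_std_nm for f in fits])
    return float(np.sqrt(((n - 1) * s**2).sum() / (n.sum() - k)))


# ---------------------------------------------------------------------------
# Vesselness (fiber scaffolds)


def _hessian(volume: np.ndarray, sigma: float, z_scale: float) -> np.ndarray:
    """Gaussian-scale Hessian; sigma in voxels of the finest axis, z
    derivatives taken at sigma/z_scale voxels so the physical scale is
    isotropic."""
    sigmas = (sigma / z_scale, sigma, sigma)
    h = np.empty(volume.shape + (3, 3))
    scale = np.array([1.0 / z_scale, 1.0, 1.0])  # z index -> finest-axis units
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            d = ndi.gaussian_filter(volume, sigmas, order=order, mode="nearest")
            d *= sigma**2 * scale[i] * scale[j]  # gamma-normalized, physical axes
            h[..., i, j] = d
            h[..., j, i] = d
    return h


def vesselness(
    stack: ZStack | np.ndarray, params: VesselnessParams | float = 1.0
) -> np.ndarray:
    """Frangi vesselness response for bright tubes at one scale.

    Hessian eigenvalues |l1| <= |l2| <= |l3| feed the standard response
    R_A = |l2|/|l3| (plate vs tube), R_B = |l1|/sqrt(|l2 l3|) (blob),
    S = Frobenius norm, with bright-tube polarity (l2, l3 < 0).  The
    anisotropic z spacing is handled by scaling z derivatives to the finest
    axis, so ``sigma`` is a dimensionless scale in x/y voxel units.
    """
    if not isinstance(params, VesselnessParams):
        params = VesselnessParams(sigma=float(params))
    if isinstance(stack, ZStack):
        volume = np.asarray(stack.voxels, dtype=float)
        dz, dy, dx = stack.voxel_size
        z_scale = dz / min(dy, dx)
    else:
        volume = np.asarray(stack, dtype=float)
        z_scale = 1.0
    if np.ptp(volume) == 0:
        return np.zeros_like(volume)

    h = _hessian(volume, params.sigma, z_scale)
    evals = np.linalg.eigvalsh(h)  # ascending by value
    order = np.argsort(np.abs(evals), axis=-1)
    evals = np.take_along_axis(evals, order, axis=-1)
    l1, l2, l3 = evals[..., 0], evals[..., 1], evals[..., 2]

    eps = 1e-10
    ra2 = (l2 / (l3 + np.where(l3 >= 0, eps, -eps))) ** 2
    rb2 = l1**2 / (np.abs(l2 * l3) + eps)
    s2 = l1**2 + l2**2 + l3**2
    c = params.c if params.c is not None else 0.5 * np.sqrt(s2.max())
    c2 = max(c, eps) ** 2
    response = (
        (1 - np.exp(-ra2 / (2 * params.alpha**2)))
        * np.exp(-rb2 / (2 * params.beta**2))
        * (1 - np.exp(-s2 / (2 * c2)))
    )
    response[(l2 > 0) | (l3 > 0)] = 0.0  # dark-tube / non-tube polarity
    return response


# ---------------------------------------------------------------------------
# Segmentation methods and contact


def adhoc_segment(stack: ZStack | np.ndarray) -> np.ndarray:
    """A8 baseline: max-entropy threshold, 3x3x3 median filter, and removal
    of connected components smaller than 27 voxels."""
    from .statistical import max_entropy_threshold

    values = stack.voxels if isinstance(stack, ZStack) else np.asarray(stack)
    _, mask = max_entropy_threshold(values)
    mask = ndi.median_filter(mask.astype(np.uint8), size=3).astype(bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    if n:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        small = np.nonzero(sizes < MIN_COMPONENT_VOXELS)[0] + 1
        mask[np.isin(labels, small)] = False
    return mask


def plane_surface_mask(stack: ZStack, fit: PlaneFit, tol_voxels: float = 1.0) -> np.ndarray:
    """Voxels within ``tol_voxels`` (along z) of the fitted plane surface."""
    a, b, c, d = fit.coeffs
    dz, dy, dx = stack.voxel_size
    Z, Y, X = stack.shape
    z = np.arange(Z)[:, None, None] * dz
    y = np.arange(Y)[None, :, None] * dy
    x = np.arange(X)[None, None, :] * dx
    dist_um = np.abs(a * x + b * y + c * z + d)  # unit normal: signed distance
    return dist_um <= tol_voxels * dz


def geometric_scaffold_segment(
    stack: ZStack,
    scaffold_type: str = "MF",
    method: str = "A6",
    cell_mask: np.ndarray | None = None,
    background_mean: float | None = None,
    background_std: float = 0.0,
) -> np.ndarray:
    """Scaffold segmentation by geometry class.

    SC: weighted plane fit to the film surface nearer the cell, voxels
    within one z-voxel of the plane.  MF/MMF with A6/A7: max-entropy
    threshold of the vesselness response (sigma 1.0 / 1.5), restricted to
    the cell neighborhood when a cell mask is given (the threshold is
    learned on the full response so a scaffold-free cell neighborhood stays
    empty instead of thresholding noise).  A8: ad-hoc thresholding +
    filtering on raw intensities.
    """
    from .statistical import max_entropy_threshold

    if method == "A8":
        return adhoc_segment(stack)
    if method not in SIGMA_BY_METHOD:
        raise ValueError(f"method must be A6, A7 or A8, got {method!r}")

    if scaffold_type == "SC":
        if background_mean is None:
            background_mean = float(np.median(stack.voxels[0]))
            background_std = float(stack.voxels[0].std())
        weights = intensity_weights(stack, background_mean, background_std)
        surface = "upper"
        if cell_mask is not None and cell_mask.any():
            cell_z = np.nonzero(cell_mask)[0].mean()
            film_z = np.nonzero(weights > 0.5)[0]
            if film_z.size and cell_z < film_z.mean():
                surface = "lower"
        fit = fit_plane_wls(stack, weights, surface)
        return plane_surface_mask(stack, fit)

    response = vesselness(stack, SIGMA_BY_METHOD[method])
    if np.ptp(response) == 0:
        return np.zeros(response.shape, dtype=bool)
    _, mask = max_entropy_threshold(response)
    if cell_mask is not None:
        mask &= np.asarray(cell_mask, dtype=bool)
    return mask


def _dilate(mask: np.ndarray, connectivity: int) -> np.ndarray:
    structure = ndi.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    return ndi.binary_dilation(mask, structure=structure)


def binary_contact(
    cell_mask: np.ndarray, scaffold_mask: np.ndarray, connectivity: int = 26
) -> np.ndarray:
    """Contact voxels: cell/scaffold label co-occurrence or 1-voxel adjacency.

    A voxel is contact iff it carries both labels, or carries one label and
    has a voxel with the other label in its 1-voxel neighborhood
    (``connectivity`` in {6, 18, 26}).  Symmetric in its arguments.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    scaffold_mask = np.asarray(scaffold_mask, dtype=bool)
    if cell_mask.shape != scaffold_mask.shape:
        raise ValueError("mask shapes differ")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    return (cell_mask & _dilate(scaffold_mask, connectivity)) | (
        scaffold_mask & _dilate(cell_mask, connectivity)
    )


def contact_surface(segment: np.ndarray, provenance: str = "geometrical") -> ContactSurface:
    """Nonzero-gradient support of a (cell-masked, thresholded) segment.

    Central-difference 3-D gradient of the binary segment; surface voxels
    are segment voxels with nonzero gradient magnitude (so the surface is a
    subset of the segment boundary).  Volume-border voxels are excluded
    (replicate padding would yield zero gradient at a constant border, and
    the crop boundary is not a physical surface).
    """
    segment = np.asarray(segment, dtype=float)
    if not segment.any():
        return ContactSurface(np.zeros(segment.shape, dtype=bool), provenance)
    grads = np.gradient(segment)
    magnitude = np.sqrt(sum(g**2 for g in grads))
    surface = (magnitude > 0) & (segment > 0)
    for axis in range(3):
        if segment.shape[axis] > 2:
            idx = [slice(None)] * 3
            idx[axis] = 0
            surface[tuple(idx)] = False
            idx[axis] = -1
            surface[tuple(idx)] = False
    return ContactSurface(surface, provenance)
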