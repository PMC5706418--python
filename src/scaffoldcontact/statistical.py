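"""Statistical scaffold/cell foreground models and the contact probability.

Five per-voxel foreground models (A1-A5) turn an intensity z-stack into a
probability volume P(Contact|Cell) or P(Contact|Scaffold):

* A1 — single-pixel model: Gaussian upper-tail posterior against the
  background intensity model, P = Phi((I - mu_BKG) / sigma_BKG).
* A2 — mixed-pixel spatial model: partial-volume (mixed foreground /
  background) fraction per voxel, mean-pooled over an in-plane 3x3
  neighborhood.
* A3 — mixed-pixel channel model: estimates the cross-channel bleed-through
  coefficient by least squares on pure-partner voxels, subtracts the leaked
  signal, then applies A2.
* A4 — additive-noise model: two-component Gaussian mixture (background
  component pinned to the background model), posterior responsibility.
* A5 — Markov-random-field model: Ising-regularized A1 posterior (iterated
  conditional modes, 6-neighborhood), returned as a soft posterior.

Class priors P(Cell), P(Scaffold), P(BKG) come from K-means (K=3) on the
per-voxel (cell intensity, scaffold intensity) scatter, converted to
probabilities by inverse-distance weighting so they sum to one.  The total
probability of contact combines conditionals and priors voxelwise:

    P(Contact) = P(Contact|Cell) P(Cell) + P(Contact|Scaffold) P(Scaffold)

Probability (or intensity) volumes are binarized by the maximum-entropy
criterion: the threshold maximizing the summed Shannon entropies of the
renormalized foreground and background histogram halves,
T_opt = argmax_T { H_FRG(T) + H_BKG(T) }.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.special import ndtr  # Gaussian CDF, vectorized
from sklearn.cluster import KMeans

from .preprocessing import BackgroundModel, estimate_background
from .volume_io import ZStack, ZStackPair

MODELS = ("A1", "A2", "A3", "A4", "A5")

# Clustering on more voxels than this uses a seeded uniform subsample.
_KMEANS_SUBSAMPLE_LIMIT = 2**24


@dataclass
class ProbabilityVolume:
    """Per-voxel probabilities in [0, 1] with a semantic tag."""

    values: np.ndarray
    semantics: str = "P(Contact)"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ClusterModel:
    """K=3 centroids in (cell, scaffold) intensity space with class identity."""

    centroids: np.ndarray  # (3, 2) rows ordered (background, cell, scaffold)
    labels: tuple[str, str, str] = ("background", "cell", "scaffold")
    seed: int = 0


@dataclass
class EntropyThreshold:
    """Maximum-entropy threshold with its criterion trace over candidates."""

    t_opt: float
    criterion: np.ndarray  # H_FRG(T) + H_BKG(T) per candidate cut
    candidates: np.ndarray  # threshold value per candidate cut
    bin_edges: np.ndarray


# ---------------------------------------------------------------------------
# Maximum-entropy (Kapur) binarization — Eq.-style criterion


def _half_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a renormalized histogram half (0 if empty)."""
    total = p.sum()
    if total <= 0:
        return 0.0
    q = p[p > 0] / total
    return float(-(q * np.log(q)).sum())


def max_entropy_threshold(
    volume: np.ndarray | ZStack, n_bins: int = 256
) -> tuple[EntropyThreshold, np.ndarray]:
    """Adaptive binarization maximizing H_FRG(T) + H_BKG(T).

    The intensity histogram (``n_bins`` over [min, max]) is split at every
    interior bin edge; both halves are renormalized and their Shannon
    entropies summed.  Returns the argmax threshold (first of ties) and the
    mask ``volume >= t_opt``.
    """
    values = volume.voxels if isinstance(volume, ZStack) else np.asarray(volume)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("no valid threshold: volume is constant")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    candidates = edges[1:-1]  # interior bin edges: cut below/at-or-above
    criterion = np.empty(len(candidates))
    for s in range(1, n_bins):
        criterion[s - 1] = _half_entropy(hist[:s]) + _half_entropy(hist[s:])
    best = int(np.argmax(criterion))
    t_opt = float(candidates[best])
    thr = EntropyThreshold(t_opt=t_opt, criterion=criterion, candidates=candidates, bin_edges=edges)
    return thr, values >= t_opt


# ---------------------------------------------------------------------------
# Foreground models A1-A5


def _a1(values: np.ndarray, background: BackgroundModel) -> np.ndarray:
    if background.std == 0:
        if np.ptp(values) == 0:
            warnings.warn("zero background spread on a constant stack; returning zeros")
            return np.zeros_like(values, dtype=float)
        return (values > background.mean).astype(float)
    return ndtr((values - background.mean) / background.std)


def _a1_positive_mask(values: np.ndarray, background: BackgroundModel) -> np.ndarray:
    """Foreground support for parameter estimation: max-entropy cut of A1."""
    p = _a1(values, background)
    if np.ptp(p) == 0:
        return np.zeros(values.shape, dtype=bool)
    _, mask = max_entropy_threshold(p)
    return mask


def _a2(values: np.ndarray, background: BackgroundModel) -> np.ndarray:
    positive = _a1_positive_mask(values, background)
    if not positive.any():
        return np.zeros_like(values, dtype=float)
    i_frg = float(np.percentile(values[positive], 99))
    if i_frg <= background.mean:
        return np.zeros_like(values, dtype=float)
    alpha = np.clip((values - background.mean) / (i_frg - background.mean), 0.0, 1.0)
    # In-plane 3x3 mean pooling: z slices are far coarser than x/y.
    return ndi.uniform_filter(alpha, size=(1, 3, 3), mode="nearest")


def estimate_bleed_coefficient(
    target: np.ndarray,
    partner: np.ndarray,
    target_background: BackgroundModel,
    partner_background: BackgroundModel,
) -> float:
    """Bleed-through slope of target signal on partner signal.

    Estimated over partner-foreground voxels.  Voxels where the partner
    structure genuinely co-occurs with target structure have an inflated
    target/partner signal ratio, so the slope is read as the median of the
    per-voxel ratios — a robust regression that recovers the mixing
    coefficient whenever bleed-only voxels are the majority of the
    partner-foreground set.  (Flagging "pure partner" voxels with the
    target channel's own foreground detector fails here: the leaked signal
    itself triggers the detector.)
    """
    partner_fg = _a1_positive_mask(partner, partner_background)
    strong = partner_fg & (
        partner > partner_background.mean + 5 * max(partner_background.std, 1e-6)
    )
    if strong.sum() < 10:
        return 0.0
    x = partner[strong] - partner_background.mean
    y = target[strong] - target_background.mean
    return float(np.clip(np.median(y / x), 0.0, 1.0))


def _a3(
    values: np.ndarray,
    background: BackgroundModel,
    partner: np.ndarray,
    partner_background: BackgroundModel,
) -> np.ndarray:
    alpha = estimate_bleed_coefficient(values, partner, background, partner_background)
    corrected = values - alpha * (partner - partner_background.mean)
    return _a2(np.clip(corrected, 0.0, None), background)


def _a4(values: np.ndarray, background: BackgroundModel, max_iter: int = 50) -> np.ndarray:
    """Two-Gaussian mixture with the background component held fixed."""
    positive = _a1_positive_mask(values, background)
    if not positive.any():
        return np.zeros_like(values, dtype=float)
    flat = values.ravel()
    mu_b, sd_b = background.mean, max(background.std, 1e-6)
    mu_f = float(values[positive].mean())
    sd_f = float(max(values[positive].std(), sd_b))
    pi_f = float(positive.mean())
    for _ in range(max_iter):
        log_b = -0.5 * ((flat - mu_b) / sd_b) ** 2 - np.log(sd_b)
        log_f = -0.5 * ((flat - mu_f) / sd_f) ** 2 - np.log(sd_f)
        num = pi_f * np.exp(log_f - np.maximum(log_b, log_f))
        den = num + (1 - pi_f) * np.exp(log_b - np.maximum(log_b, log_f))
        resp = num / den
        w = resp.sum()
        if w < 1e-9:
            break
        mu_new = float((resp @ flat) / w)
        sd_new = float(np.sqrt((resp @ (flat - mu_new) ** 2) / w))
        pi_new = float(w / flat.size)
        if abs(mu_new - mu_f) < 1e-6 * max(1.0, abs(mu_f)):
            mu_f, sd_f, pi_f = mu_new, max(sd_new, 1e-6), pi_new
            break
        mu_f, sd_f, pi_f = mu_new, max(sd_new, 1e-6), pi_new
    return resp.reshape(values.shape)


def _neighbor_field(labels: np.ndarray) -> np.ndarray:
    """Sum of (2*label - 1) over the 6-neighborhood (replicated borders)."""
    spins = 2.0 * labels - 1.0
    kernel = np.zeros((3, 3, 3))
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1.0
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1.0
    return ndi.correlate(spins, kernel, mode="nearest")


def _a5(
    values: np.ndarray,
    background: BackgroundModel,
    beta: float = 1.0,
    max_iter: int = 10,
) -> np.ndarray:
    """Ising-smoothed A1 posterior via ICM, returned as a soft posterior."""
    p1 = np.clip(_a1(values, background), 1e-6, 1 - 1e-6)
    logit = np.log(p1 / (1 - p1))
    labels = (p1 > 0.5).astype(float)
    for _ in range(max_iter):
        new_labels = (logit + beta * _neighbor_field(labels) > 0).astype(float)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    # soft readout of the converged field
    return 1.0 / (1.0 + np.exp(-(logit + beta * _neighbor_field(labels))))


def foreground_probability(
    stack: ZStack,
    background: BackgroundModel,
    model: str = "A2",
    partner: ZStack | None = None,
    partner_background: BackgroundModel | None = None,
) -> ProbabilityVolume:
    """Per-voxel foreground (conditional contact) probability under one model.

    ``partner`` is required for A3 (the joint two-channel bleed-through
    model); its background model is estimated from its first frame when not
    supplied.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    values = np.asarray(stack.voxels, dtype=float)
    if background.std == 0 and np.ptp(values) == 0:
        warnings.warn("constant stack with zero background spread; probability is zero")
        return ProbabilityVolume(np.zeros_like(values), f"{model}")
    if model == "A1":
        p = _a1(values, background)
    elif model == "A2":
        p = _a2(values, background)
    elif model == "A3":
        if partner is None:
            raise ValueError("A3 (mixed-pixel channel model) requires the partner channel")
        if partner_background is None:
            partner_background = estimate_background(partner, "first")
        p = _a3(values, background, np.asarray(partner.voxels, dtype=float), partner_background)
    elif model == "A4":
        p = _a4(values, background)
    else:
        p = _a5(values, background)
    return ProbabilityVolume(np.clip(p, 0.0, 1.0), model)


# ---------------------------------------------------------------------------
# K-means class priors


def _assign_classes(centroids: np.ndarray) -> np.ndarray:
    """Order raw centroids as (background, cell, scaffold).

    Background is the centroid closest to the origin; of the remaining two,
    the one with the larger cell-channel coordinate is the cell.
    """
    order = np.empty(3, dtype=int)
    norms = np.linalg.norm(centroids, axis=1)
    order[0] = int(np.argmin(norms))
    rest = [i for i in range(3) if i != order[0]]
    if centroids[rest[0], 0] >= centroids[rest[1], 0]:
        order[1], order[2] = rest[0], rest[1]
    else:
        order[1], order[2] = rest[1], rest[0]
    return order


def kmeans_priors(
    pair: ZStackPair, seed: int = 0, subsample_limit: int = _KMEANS_SUBSAMPLE_LIMIT
) -> tuple[ClusterModel, dict[str, np.ndarray]]:
    """Class priors from K-means (K=3) on the 2-D intensity scatterplot.

    Every voxel contributes a point (cell intensity, scaffold intensity).
    Per-voxel probabilities are relative inverse distances to the three
    centroids, P_c = (1/d_c) / sum_j (1/d_j), with an exact-hit
    short-circuit, so P(Cell) + P(Scaffold) + P(BKG) = 1 voxelwise.
    """
    cell = np.asarray(pair.cell.voxels, dtype=float).ravel()
    scaffold = np.asarray(pair.scaffold.voxels, dtype=float).ravel()
    points = np.column_stack([cell, scaffold])
    if np.unique(points, axis=0).shape[0] < 3:
        raise ValueError("need at least 3 distinct (cell, scaffold) intensity pairs")

    fit_points = points
    if points.shape[0] > subsample_limit:
        rng = np.random.default_rng(seed)
        idx = rng.choice(points.shape[0], size=subsample_limit, replace=False)
        fit_points = points[idx]

    last_err: Exception | None = None
    for attempt in range(5):
        km = KMeans(n_clusters=3, n_init=10, random_state=seed + attempt)
        km.fit(fit_points)
        if len(np.unique(km.labels_)) == 3:
            break
        last_err = ValueError("K-means produced an empty cluster")
    else:
        raise last_err  # pragma: no cover - 5 failed re-seeds

    order = _assign_classes(km.cluster_centers_)
    centroids = km.cluster_centers_[order]
    model = ClusterModel(centroids=centroids, seed=seed)

    d = np.linalg.norm(points[:, None, :] - centroids[None, :, :], axis=2)  # (N, 3)
    probs = np.empty_like(d)
    exact = d == 0
    hit_any = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[hit_any] = 0.0
    probs[~hit_any] = inv[~hit_any] / inv[~hit_any].sum(axis=1, keepdims=True)
    probs[hit_any] = exact[hit_any] / exact[hit_any].sum(axis=1, keepdims=True)

    shape = pair.shape
    priors = {
        "P(BKG)": probs[:, 0].reshape(shape),
        "P(Cell)": probs[:, 1].reshape(shape),
        "P(Scaffold)": probs[:, 2].reshape(shape),
    }
    return model, priors


def contact_probability(
    p_cell_cond: ProbabilityVolume,
    p_scaffold_cond: ProbabilityVolume,
    priors: dict[str, np.ndarray],
) -> ProbabilityVolume:
    """Total-probability contact map:
    P(Contact) = P(Contact|Cell) P(Cell) + P(Contact|Scaffold) P(Scaffold)."""
    pc, ps = p_cell_cond.values, p_scaffold_cond.values
    if pc.shape != ps.shape or pc.shape != priors["P(Cell)"].shape:
        raise ValueError("probability grids are not congruent")
    values = pc * priors["P(Cell)"] + ps * priors["P(Scaffold)"]
    return ProbabilityVolume(values, "P(Contact)")
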