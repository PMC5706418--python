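"""End-to-end orchestration: preprocess -> contact models -> evaluation.

``run_pair`` executes the full measurement chain on one co-registered
[cell, scaffold] pair: background estimation, cell segmentation, ROI
cropping, the chosen statistical contact model (priors from K-means,
conditionals from the per-channel foreground model, total-probability
combination, max-entropy binarization) and the chosen geometrical method,
then reports both contact masks, their surfaces, and the normalized
Euclidean distance between the statistical and geometrical contact maps.
Every report embeds the effective configuration and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, geometrical, preprocessing, statistical
from .volume_io import ZStackPair, ZStack, write_zstack

logger = logging.getLogger("scaffoldcontact")


@dataclass
class RunConfig:
    """Effective parameters of one measurement run.

    Defaults follow the package's model down-selection: mixed-pixel
    statistical model A2 and vesselness geometrical method A6.
    """

    scaffold_type: str = "MF"  # {SC, MF, MMF}
    statistical_model: str = "A2"  # {A1..A5}
    geometrical_method: str = "A6"  # {A6, A7, A8}
    background_frame: str = "first"
    margin_fraction: float = preprocessing.MARGIN_FRACTION
    connectivity: int = 26
    n_bins: int = 256
    seed: int = 0
    crop: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PairResult:
    """Everything ``run_pair`` measures on one [cell, scaffold] pair."""

    config: RunConfig
    roi: preprocessing.RegionOfInterest | None
    cell_mask: np.ndarray
    statistical_probability: statistical.ProbabilityVolume
    statistical_contact: np.ndarray
    geometrical_scaffold: np.ndarray
    geometrical_contact: np.ndarray
    contact_surface: geometrical.ContactSurface
    t_opt: float
    report: dict


def run_pair(
    pair: ZStackPair, config: RunConfig | None = None, ground_truth: dict | None = None
) -> PairResult:
    """Run the full contact measurement on one pair.

    ``ground_truth`` (optional ``{"cell", "scaffold", "contact"}`` masks,
    e.g. from a rendered phantom) adds Jaccard scores to the report.
    """
    config = config or RunConfig()
    logger.info("run_pair: model=%s method=%s type=%s", config.statistical_model,
                config.geometrical_method, config.scaffold_type)

    cell_bkg = preprocessing.estimate_background(pair.cell, config.background_frame)
    scaf_bkg = preprocessing.estimate_background(pair.scaffold, config.background_frame)
    cell_mask_full, status = preprocessing.segment_cell(pair.cell, cell_bkg)
    if status == "missed":
        raise RuntimeError("cell segmentation missed: no foreground found")

    roi = None
    truth = dict(ground_truth) if ground_truth else None
    if config.crop:
        pair, roi = preprocessing.crop_roi(pair, cell_mask_full, config.margin_fraction)
        sl = roi.slices()
        cell_mask = cell_mask_full[sl]
        if truth:
            truth = {k: v[sl] for k, v in truth.items()}
    else:
        cell_mask = cell_mask_full

    # statistical contact
    _, priors = statistical.kmeans_priors(pair, seed=config.seed)
    p_cell = statistical.foreground_probability(pair.cell, cell_bkg, config.statistical_model,
                                                partner=pair.scaffold,
                                                partner_background=scaf_bkg)
    p_scaf = statistical.foreground_probability(pair.scaffold, scaf_bkg, config.statistical_model,
                                                partner=pair.cell,
                                                partner_background=cell_bkg)
    p_contact = statistical.contact_probability(p_cell, p_scaf, priors)
    if np.ptp(p_contact.values) > 0:
        thr, _ = statistical.max_entropy_threshold(p_contact.values, config.n_bins)
        t_opt = thr.t_opt
    else:
        t_opt = float("nan")

    # categorical cell/scaffold labels from the conditional probability maps,
    # then contact = co-occurrence or 1-voxel adjacency of the labels
    def _binarize(p: statistical.ProbabilityVolume) -> np.ndarray:
        if np.ptp(p.values) == 0:
            return np.zeros(pair.shape, dtype=bool)
        _, m = statistical.max_entropy_threshold(p.values, config.n_bins)
        return m

    stat_contact = geometrical.binary_contact(
        _binarize(p_cell), _binarize(p_scaf), config.connectivity
    )

    # geometrical contact
    geo_mask = geometrical.geometric_scaffold_segment(
        pair.scaffold, config.scaffold_type, config.geometrical_method,
        cell_mask=geometrical._dilate(cell_mask, config.connectivity),
        background_mean=scaf_bkg.mean,
        background_std=scaf_bkg.std,
    )
    geo_contact = geometrical.binary_contact(cell_mask, geo_mask, config.connectivity)
    surface = geometrical.contact_surface(geo_mask & geometrical._dilate(cell_mask,
                                                                         config.connectivity))

    distance = evaluation.probability_distance(
        p_contact.values * 1.0, geo_contact.astype(float)
    )

    report = {
        "config": config.to_dict(),
        "t_opt": t_opt,
        "statistical_contact_voxels": int(stat_contact.sum()),
        "geometrical_contact_voxels": int(geo_contact.sum()),
        "stat_geom_distance": distance,
    }
    if truth:
        def jaccard(a, b):
            union = (a | b).sum()
            return float((a & b).sum() / union) if union else 1.0

        report["cell_jaccard"] = jaccard(cell_mask, truth["cell"])
        report["stat_contact_jaccard"] = jaccard(stat_contact, truth["contact"])
        report["geom_contact_jaccard"] = jaccard(geo_contact, truth["contact"])
        tc = truth["contact"].sum()
        report["geom_contact_recall"] = (
            float((geo_contact & truth["contact"]).sum() / tc) if tc else 1.0
        )

    return PairResult(
        config=config,
        roi=roi,
        cell_mask=cell_mask,
        statistical_probability=p_contact,
        statistical_contact=stat_contact,
        geometrical_scaffold=geo_mask,
        geometrical_contact=geo_contact,
        contact_surface=surface,
        t_opt=t_opt,
        report=report,
    )


def save_result(result: PairResult, out_dir: str | Path) -> Path:
    """Persist contact masks (TIFF), probability map and the JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = (0.462, 0.12, 0.12)
    write_zstack(ZStack(result.statistical_probability.values, vs, "P(Contact)"),
                 out_dir / "contact_probability.tif", dtype=np.float32)
    write_zstack(ZStack(result.statistical_contact.astype(np.uint16), vs, "stat_contact"),
                 out_dir / "contact_statistical.tif")
    write_zstack(ZStack(result.geometrical_contact.astype(np.uint16), vs, "geom_contact"),
                 out_dir / "contact_geometrical.tif")
    write_zstack(ZStack(result.contact_surface.mask.astype(np.uint16), vs, "surface"),
                 out_dir / "contact_surface.tif")
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(result.report, indent=2, default=float))
    return report_path
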