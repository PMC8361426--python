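"""Per-ROI activation summaries: percent BOLD signal and volume of activation.

The motor-network ROI set mirrors the study's: four lateralized cortical
regions (M1, S1, SMA, PMC) summarized on the hemisphere contralateral to
the tapping hand, and four bilateral subcortical regions (cerebellum,
putamen, caudate, thalamus).

Percent BOLD is averaged over the suprathreshold (cluster-surviving)
voxels inside the ROI; the whole-ROI mean is also emitted for sensitivity.
Volume of activation (VOA) counts suprathreshold voxels inside the ROI.
An empty ROI ∩ active intersection yields 0 with a flag, so every subject
contributes a value to the cohort correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cordbold.glm import ClusterResult, StatMap

__all__ = [
    "CORTICAL_ROIS",
    "SUBCORTICAL_ROIS",
    "RoiSet",
    "RoiMetrics",
    "threshold_probabilistic_roi",
    "roi_percent_bold",
    "roi_voa",
    "extract_all",
    "metrics_to_frame",
]

CORTICAL_ROIS = ("M1", "S1", "SMA", "PMC")
SUBCORTICAL_ROIS = ("cerebellum", "putamen", "caudate", "thalamus")


@dataclass(frozen=True)
class RoiSet:
    """Named binary ROI masks on the stat-map grid.

    Cortical ROIs are stored per hemisphere under ``"<name>_left"`` /
    ``"<name>_right"``; subcortical ROIs under their bare bilateral name.
    """

    masks: dict
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"ROI masks are on different grids: {shapes}")
        empties = [n for n, m in self.masks.items() if not np.asarray(m).any()]
        if empties:
            raise ValueError(f"empty ROI masks: {empties}")
        object.__setattr__(
            self, "masks", {n: np.asarray(m, dtype=bool) for n, m in self.masks.items()}
        )


@dataclass(frozen=True)
class RoiMetrics:
    roi_name: str
    hand: str
    laterality: str  # 'contralateral' or 'bilateral'
    percent_bold: float
    percent_bold_whole_roi: float
    voa_voxels: int
    voa_mm3: float
    n_suprathreshold: int
    empty_intersection: bool


def threshold_probabilistic_roi(prob_map: np.ndarray, threshold: float = 25.0) -> np.ndarray:
    """Binarize a probabilistic atlas map at a percent threshold."""
    prob = np.asarray(prob_map, dtype=float)
    if prob.min() < 0 or prob.max() > 100:
        raise ValueError("probabilities must lie in [0, 100]")
    mask = prob >= threshold
    if not mask.any():
        raise ValueError(
            f"thresholding at {threshold}% leaves an empty mask (map max {prob.max():.1f})"
        )
    return mask


def roi_percent_bold(
    stat: StatMap, cluster: ClusterResult, roi: np.ndarray
) -> tuple[float, bool]:
    """Mean percent signal over ROI ∩ active voxels; (0.0, True) if empty."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stat.percent_signal.shape:
        raise ValueError("ROI grid does not match stat map")
    sel = roi & cluster.active_mask
    if not sel.any():
        return 0.0, True
    return float(stat.percent_signal[sel].mean()), False


def roi_voa(cluster: ClusterResult, roi: np.ndarray, voxel_volume_mm3: float) -> tuple[int, float]:
    """Suprathreshold voxel count inside the ROI and its volume in mm³."""
    roi = np.asarray(roi, dtype=bool)
    n = int((roi & cluster.active_mask).sum())
    return n, n * voxel_volume_mm3


def _required_names(hand: str) -> dict:
    if hand not in ("left", "right"):
        raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")
    contra = "right" if hand == "left" else "left"
    names = {name: f"{name}_{contra}" for name in CORTICAL_ROIS}
    names.update({name: name for name in SUBCORTICAL_ROIS})
    return names


def extract_all(
    stat: StatMap, cluster: ClusterResult, rois: RoiSet, hand: str
) -> list[RoiMetrics]:
    """All eight ROI summaries for one run.

    Cortical metrics come from the hemisphere contralateral to the tapping
    hand; subcortical metrics from the bilateral masks.
    """
    mapping = _required_names(hand)
    missing = [key for key in mapping.values() if key not in rois.masks]
    if missing:
        raise ValueError(f"ROI set missing required masks: {missing}")
    voxel_volume = float(np.prod(stat.voxel_dims))
    out = []
    for name, key in mapping.items():
        roi = rois.masks[key]
        psc, empty = roi_percent_bold(stat, cluster, roi)
        voa_vox, voa_mm3 = roi_voa(cluster, roi, voxel_volume)
        out.append(
            RoiMetrics(
                roi_name=name,
                hand=hand,
                laterality="contralateral" if name in CORTICAL_ROIS else "bilateral",
                percent_bold=psc,
                percent_bold_whole_roi=float(stat.percent_signal[roi].mean()),
                voa_voxels=voa_vox,
                voa_mm3=voa_mm3,
                n_suprathreshold=voa_vox,
                empty_intersection=empty,
            )
        )
    return out


def metrics_to_frame(metrics: list[RoiMetrics], subject: str = "") -> pd.DataFrame:
    df = pd.DataFrame([vars(m) for m in metrics])
    if subject:
        df.insert(0, "subject", subject)
    return df
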