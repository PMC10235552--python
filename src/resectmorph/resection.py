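"""Resection-cavity estimation from paired CSF probability maps.

The cavity appears as tissue that was GM/WM preoperatively and CSF
postoperatively.  The estimator: (1) Gaussian-smooths both CSF probability
maps (sigma in voxels, default 2); (2) takes the voxelwise difference
post - pre; (3) keeps voxels whose absolute CSF probability increase
exceeds the threshold (default 0.25); (4) intersects with voxels whose
preoperative argmax class is GM or WM; (5) retains the largest connected
component (26-neighborhood default).  An empty mask is a valid outcome.
Cohort-level resection probability maps are voxelwise mask averages in
percent.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .tissue_seg import classify
from .volumes import (
    GridMismatchError,
    PipelineConfig,
    Tissue,
    TissueProbabilitySet,
    read_volume,
)

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class ResectionMask:
    """Binary resection mask on the (co-registered) postoperative grid."""

    mask: np.ndarray
    affine: np.ndarray
    provenance: str = "automated"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("resection mask must be 3D")
        if self.provenance not in ("automated", "manually_corrected"):
            raise ValueError("provenance must be automated or manually_corrected")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self):
        return self.mask.shape

    @property
    def data(self):  # grid-compat shim for require_same_grid
        return self.mask


@dataclasses.dataclass
class ResectionProbabilityMap:
    """Voxelwise resection frequency in percent for one (procedure, hemisphere)."""

    values: np.ndarray  # [0, 100]
    affine: np.ndarray
    group: Tuple[str, str]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("probability map values must lie in [0, 100]")


def candidate_voxels(
    pre_probs: TissueProbabilitySet,
    post_probs: TissueProbabilitySet,
    config: PipelineConfig,
) -> np.ndarray:
    """Steps 1-4: thresholded smoothed CSF increase inside preop GM/WM."""
    if not pre_probs.same_grid(post_probs):
        raise GridMismatchError("pre and post probability sets are not co-registered")
    pre_csf = np.asarray(pre_probs.maps["CSF"], dtype=np.float64)
    post_csf = np.asarray(post_probs.maps["CSF"], dtype=np.float64)
    if config.smoothing_sigma > 0:
        pre_csf = ndimage.gaussian_filter(pre_csf, config.smoothing_sigma)
        post_csf = ndimage.gaussian_filter(post_csf, config.smoothing_sigma)
    delta = post_csf - pre_csf
    candidates = delta > config.csf_increase_threshold
    pre_labels = classify(pre_probs)
    gmwm = (pre_labels == Tissue.GM) | (pre_labels == Tissue.WM)
    return candidates & gmwm


def largest_component(
    mask: np.ndarray, connectivity: int, tie_break: Optional[np.ndarray] = None
) -> np.ndarray:
    """Largest connected component; ties resolved by larger summed tie_break."""
    structure = _STRUCTURES[connectivity]
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labeled.ravel())[1:]  # skip background
    best = counts.max()
    winners = np.flatnonzero(counts == best) + 1
    if len(winners) > 1 and tie_break is not None:
        sums = ndimage.sum_labels(tie_break, labeled, index=winners)
        winners = [winners[int(np.argmax(sums))]]
    return labeled == winners[0]


def estimate_resection(
    pre_probs: TissueProbabilitySet,
    post_probs: TissueProbabilitySet,
    config: Optional[PipelineConfig] = None,
) -> ResectionMask:
    """Automated resection-zone estimate from pre/post tissue posteriors.

    The caller guarantees the two sets are rigidly co-registered on one
    grid.  Returns an (possibly empty) single-component binary mask.
    """
    config = config or PipelineConfig()
    candidates = candidate_voxels(pre_probs, post_probs, config)
    # tie-break between equal-size components: larger summed CSF increase
    pre_csf = ndimage.gaussian_filter(
        np.asarray(pre_probs.maps["CSF"], dtype=np.float64), config.smoothing_sigma
    ) if config.smoothing_sigma > 0 else np.asarray(pre_probs.maps["CSF"], float)
    post_csf = ndimage.gaussian_filter(
        np.asarray(post_probs.maps["CSF"], dtype=np.float64), config.smoothing_sigma
    ) if config.smoothing_sigma > 0 else np.asarray(post_probs.maps["CSF"], float)
    mask = largest_component(
        candidates, config.connectivity, tie_break=post_csf - pre_csf
    )
    result = ResectionMask(mask=mask, affine=pre_probs.affine)
    logger.info(
        "automated resection mask: %d voxels (%d candidates)",
        result.n_voxels,
        int(candidates.sum()),
    )
    return result


def apply_manual_correction(auto: ResectionMask, edited_path) -> ResectionMask:
    """Adopt an externally edited mask, flipping provenance.

    The edited volume must be binary and on the automated mask's grid; the
    voxel-count delta versus the automated mask is logged.
    """
    edited = read_volume(edited_path)
    values = np.unique(edited.data)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError("mask must be binary (values 0/1)")
    if edited.shape != auto.shape or not np.allclose(
        edited.affine, auto.affine, atol=1e-4
    ):
        raise GridMismatchError("edited mask is not on the automated mask's grid")
    corrected = ResectionMask(
        mask=edited.data > 0, affine=auto.affine, provenance="manually_corrected"
    )
    logger.info(
        "manual correction: %+d voxels (auto %d -> corrected %d)",
        corrected.n_voxels - auto.n_voxels,
        auto.n_voxels,
        corrected.n_voxels,
    )
    return corrected


def build_probability_map(
    masks_in_template: Sequence[ResectionMask],
    group: Tuple[str, str],
) -> ResectionProbabilityMap:
    """Average resection masks (template space) into a percent frequency map."""
    if len(masks_in_template) == 0:
        raise ValueError("need at least one mask")
    ref = masks_in_template[0]
    stack = []
    for m in masks_in_template:
        if m.shape != ref.shape or not np.allclose(m.affine, ref.affine, atol=1e-4):
            raise GridMismatchError("masks are not on a common template grid")
        stack.append(m.mask.astype(np.float64))
    values = np.mean(stack, axis=0) * 100.0
    return ResectionProbabilityMap(
        values=values,
        affine=ref.affine,
        group=tuple(group),
        n_subjects=len(masks_in_template),
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary volumes (1.0 when both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
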