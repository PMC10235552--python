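"""Cortical thickness by the Laplacian (potential-field) method, with
atlas aggregation and annualization.

The GM domain is the posterior-argmax gray matter.  Laplace's equation is
solved over GM with potential 0 on the white-matter side (WM, deep GM,
cerebellum, brainstem) and 1 on the CSF side (CSF and outside-brain),
by Jacobi iteration.  Thickness at a GM voxel is the streamline length
through the potential field, computed Eulerian-style as the sum of two
first-order upwind length fields (distance from the inner boundary along
the normalized gradient, plus distance to the outer boundary), so no
explicit streamline tracing is needed.  Tissue interfaces are taken to lie
midway between a GM voxel center and its non-GM 6-neighbor center: without
this half-voxel correction a slab of n voxels reads n+1 voxel widths.

GM voxels with a vanishing potential gradient (not bounded by both
interfaces) get thickness 0 and are excluded from regional means.
"""

from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .resection import ResectionMask
from .tissue_seg import classify
from .volumes import (
    AtlasLabels,
    GridMismatchError,
    ImageVolume,
    Tissue,
    TissueProbabilitySet,
)

logger = logging.getLogger(__name__)

INNER_CLASSES: Tuple[str, ...] = ("WM", "DGM", "CBM", "BST")

_GRAD_EPS = 1e-8


def _replicate_faces(arr: np.ndarray) -> None:
    """Copy the first/last interior planes into the 1-voxel pad (Neumann)."""
    arr[0, :, :] = arr[1, :, :]
    arr[-1, :, :] = arr[-2, :, :]
    arr[:, 0, :] = arr[:, 1, :]
    arr[:, -1, :] = arr[:, -2, :]
    arr[:, :, 0] = arr[:, :, 1]
    arr[:, :, -1] = arr[:, :, -2]


def _solve_laplace(
    gm: np.ndarray,
    inner: np.ndarray,
    spacing: np.ndarray,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """Jacobi solution of Laplace's equation on the GM domain.

    Dirichlet values sit at neighbor voxel centers: 0 on inner-class
    voxels, 1 everywhere else outside GM (CSF and background).  Volume
    faces are zero-flux (pad replicated each sweep) so a slab touching the
    grid edge behaves as if laterally infinite.
    """
    U = np.ones(np.asarray(gm.shape) + 2, dtype=np.float64)
    core = (slice(1, -1),) * 3
    U[core][inner] = 0.0
    U[core][gm] = 0.5
    w = 1.0 / spacing.astype(np.float64) ** 2
    denom = 2.0 * w.sum()
    sl = {-1: slice(0, -2), 0: slice(1, -1), 1: slice(2, None)}

    def shifted(axis: int, step: int):
        idx = [sl[0]] * 3
        idx[axis] = sl[step]
        return U[tuple(idx)]

    for it in range(max_iter):
        _replicate_faces(U)
        nb = (
            w[0] * (shifted(0, -1) + shifted(0, 1))
            + w[1] * (shifted(1, -1) + shifted(1, 1))
            + w[2] * (shifted(2, -1) + shifted(2, 1))
        )
        new = nb[gm] / denom
        delta = np.abs(new - U[core][gm]).max() if new.size else 0.0
        U[core][gm] = new
        if delta < tol:
            break
    else:
        logger.warning("Laplace solver hit iteration cap (residual %.2e)", delta)
    _replicate_faces(U)  # keep the pad consistent for gradient evaluation
    return U


def _upwind_length(
    gm: np.ndarray,
    N: np.ndarray,
    spacing: np.ndarray,
    downstream: bool,
    tol: float,
    max_iter: int,
) -> np.ndarray:
    """First-order upwind solve of |N . grad L| = 1 over GM.

    ``downstream=False`` gives L0 (arc length from the inner boundary,
    integrating along +N); ``downstream=True`` gives L1 (to the outer
    boundary, along -N).  A non-GM upwind neighbor contributes value 0 at
    distance h/2 (the interface half-voxel correction).

    Returns ``(L, converged)``.  Voxels caught in a cyclic upwind
    dependency (possible where the noisy gradient field circulates) never
    settle; they are reported unconverged and must be excluded — they are
    not on a genuine inner-to-outer streamline.
    """
    shape = gm.shape
    L = np.zeros(np.asarray(shape) + 2, dtype=np.float64)
    G = np.zeros(np.asarray(shape) + 2, dtype=bool)
    core = (slice(1, -1),) * 3
    G[core] = gm
    _replicate_faces(G)  # zero-flux at volume faces, as in the Laplace solve
    sl = {-1: slice(0, -2), 0: slice(1, -1), 1: slice(2, None)}

    def view(arr, axis, step):
        idx = [sl[0]] * 3
        idx[axis] = sl[step]
        return arr[tuple(idx)]

    sign = 1 if downstream else -1  # upwind neighbor offset = sign * sgn(N)
    absN = np.abs(N)
    moving = absN.sum(axis=0) > _GRAD_EPS
    active = gm & moving
    # per-axis precomputation of neighbor-selection masks
    axis_terms = []
    for d in range(3):
        take_plus = (N[d] >= 0) if sign == 1 else (N[d] < 0)
        axis_terms.append((take_plus, absN[d], spacing[d]))

    for it in range(max_iter):
        _replicate_faces(L)
        num = np.ones(shape, dtype=np.float64)
        den = np.zeros(shape, dtype=np.float64)
        for d, (take_plus, a, h) in enumerate(axis_terms):
            nb_val = np.where(take_plus, view(L, d, 1), view(L, d, -1))
            nb_gm = np.where(take_plus, view(G, d, 1), view(G, d, -1))
            dist = np.where(nb_gm, h, h / 2.0)
            val = np.where(nb_gm, nb_val, 0.0)
            coeff = a / dist
            num += coeff * val
            den += coeff
        new = num[active] / den[active]
        deltas = np.abs(new - L[core][active]) if new.size else np.zeros(0)
        L[core][active] = new
        if deltas.size == 0 or deltas.max() < tol:
            break
    converged = np.ones(shape, dtype=bool)
    if deltas.size and deltas.max() >= tol:
        still_moving = np.zeros(shape, dtype=bool)
        still_moving[active] = deltas >= tol
        converged &= ~still_moving
        logger.info(
            "length PDE: %d voxels on cyclic/unterminated streamlines flagged",
            int(still_moving.sum()),
        )
    return L[core], converged


def estimate_thickness(
    probs: TissueProbabilitySet,
    laplace_tol: float = 1e-5,
    laplace_max_iter: int = 5000,
    length_tol: float = 1e-4,
    length_max_iter: int = 200,
) -> ImageVolume:
    """Laplacian cortical thickness map (mm) on GM voxels, 0 elsewhere."""
    labels = classify(probs)
    gm = labels == Tissue.GM
    if not gm.any():
        raise ValueError("no GM voxels in segmentation")
    inner = np.isin(labels, [Tissue[c] for c in INNER_CLASSES if c in probs.classes])
    struct = ndimage.generate_binary_structure(3, 1)
    outer = ~gm & ~inner  # CSF and outside-brain
    touches_inner = gm & ndimage.binary_dilation(inner, structure=struct)
    touches_outer = gm & ndimage.binary_dilation(outer, structure=struct)
    if not touches_inner.any():
        raise ValueError("GM has no WM-side interface anywhere")
    if not touches_outer.any():
        raise ValueError("GM has no CSF-side interface anywhere")

    vol_spacing = np.sqrt((np.asarray(probs.affine)[:3, :3] ** 2).sum(axis=0))
    U = _solve_laplace(gm, inner, vol_spacing, laplace_tol, laplace_max_iter)
    core = (slice(1, -1),) * 3
    u = U[core]
    if gm.any():
        umin, umax = u[gm].min(), u[gm].max()
        if umin < -1e-9 or umax > 1 + 1e-9:
            raise AssertionError("Laplace solution escaped [0, 1]")

    N = np.zeros((3,) + gm.shape, dtype=np.float64)
    sl = {-1: slice(0, -2), 0: slice(1, -1), 1: slice(2, None)}
    for d in range(3):
        idx_p = [sl[0]] * 3
        idx_m = [sl[0]] * 3
        idx_p[d] = sl[1]
        idx_m[d] = sl[-1]
        N[d] = (U[tuple(idx_p)] - U[tuple(idx_m)]) / (2.0 * vol_spacing[d])
    norm = np.sqrt((N**2).sum(axis=0))
    ok = norm > _GRAD_EPS
    N[:, ok] /= norm[ok]

    L0, conv0 = _upwind_length(gm, N, vol_spacing, False, length_tol,
                               length_max_iter)
    L1, conv1 = _upwind_length(gm, N, vol_spacing, True, length_tol,
                               length_max_iter)
    thickness = np.zeros(gm.shape, dtype=np.float32)
    valid = gm & ok & conv0 & conv1
    thickness[valid] = (L0 + L1)[valid]
    n_flagged = int(gm.sum() - valid.sum())
    if n_flagged:
        logger.info("%d GM voxels not bounded by both interfaces (thickness 0)",
                    n_flagged)
    return ImageVolume(data=thickness, affine=np.asarray(probs.affine).copy())


def regional_means(
    tmap: ImageVolume,
    atlas: AtlasLabels,
    resection: Optional[ResectionMask] = None,
    seizure_side: Optional[str] = None,
    min_voxels: int = 10,
) -> pd.DataFrame:
    """Mean thickness per atlas region.

    Averages GM voxels with nonzero thickness, excluding resected voxels.
    With ``seizure_side`` given, ipsilateral mesial temporal regions are
    dropped and a laterality column is added.  Regions with fewer than
    ``min_voxels`` contributing voxels are flagged ``low_coverage`` (a
    region with no support keeps a row with NaN mean).
    """
    if atlas.labels.shape != tmap.shape or not np.allclose(
        atlas.affine, tmap.affine, atol=1e-4
    ):
        raise GridMismatchError("atlas is not on the thickness map grid")
    valid = np.asarray(tmap.data) > 0
    if resection is not None:
        if resection.shape != tmap.shape:
            raise GridMismatchError("resection mask is not on the thickness grid")
        valid &= ~resection.mask
    sel = valid & (atlas.labels > 0)
    grouped = (
        pd.DataFrame(
            {"label": atlas.labels[sel], "thickness": np.asarray(tmap.data)[sel]}
        )
        .groupby("label")["thickness"]
        .agg(mean_thickness_mm="mean", n_voxels="size")
        .reset_index()
    )
    out = atlas.table.merge(grouped, on="label", how="left")
    out["n_voxels"] = out["n_voxels"].fillna(0).astype(int)
    out["low_coverage"] = out["n_voxels"] < min_voxels
    if seizure_side is not None:
        out = lateralize(out, seizure_side)
        drop = (out["laterality"] == "ipsi") & out["region"].isin(
            atlas.excluded_mesial
        )
        out = out.loc[~drop].reset_index(drop=True)
    return out


def lateralize(table: pd.DataFrame, seizure_side: str) -> pd.DataFrame:
    """Tag each region ipsi/contra (midline -> 'mid') to the seizure side."""
    if seizure_side not in ("L", "R"):
        raise ValueError("seizure side must be 'L' or 'R'")
    table = table.copy()
    hemi = table["hemisphere"]
    table["laterality"] = np.where(
        hemi == "midline", "mid", np.where(hemi == seizure_side, "ipsi", "contra")
    )
    return table


def annualize(
    pre_means: pd.DataFrame,
    post_means: pd.DataFrame,
    interval_years: float,
) -> pd.DataFrame:
    """Per-region annualized thickness change (mm/yr, negative = thinning)."""
    if interval_years <= 0:
        raise ValueError("interscan interval must be positive")
    keys = ["label", "region", "hemisphere"]
    keys = [k for k in keys if k in pre_means.columns and k in post_means.columns]
    pre_set = set(map(tuple, pre_means[keys].itertuples(index=False)))
    post_set = set(map(tuple, post_means[keys].itertuples(index=False)))
    if pre_set != post_set:
        raise ValueError("pre and post region sets do not match")
    carry = [c for c in ("laterality", "low_coverage") if c in pre_means.columns]
    merged = pre_means[keys + carry + ["mean_thickness_mm", "n_voxels"]].merge(
        post_means[keys + ["mean_thickness_mm"]],
        on=keys,
        suffixes=("_pre", "_post"),
    )
    merged = merged.rename(
        columns={
            "mean_thickness_mm_pre": "thickness_pre",
            "mean_thickness_mm_post": "thickness_post",
        }
    )
    merged["annualized_change"] = (
        merged["thickness_post"] - merged["thickness_pre"]
    ) / interval_years
    return merged
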