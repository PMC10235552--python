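"""Synthetic pre/postoperative MRI phantoms with analytic ground truth.

The phantom is a sphere-in-sphere head model: a white-matter core wrapped in
a cortical gray-matter shell whose width varies by angular sector (one
sector per atlas region, 12 per hemisphere including the four mesial
temporal structures), surrounded by CSF inside a spherical brain mask.
Three small interior spheres stand in for deep gray matter, cerebellum, and
brainstem so that all six tissue classes exist.  Geometry is analytic, so
per-region thickness, thinning, and resection masks are known exactly.

A postoperative volume applies per-region cortical thinning (the outer GM
surface moves inward by rate x interval) and, optionally, a spherical
resection cavity that converts GM/WM to CSF.  Intensities are class means
weighted by sub-voxel partial-volume fractions (2x supersampling) plus
Gaussian noise, which dithers tissue interfaces across voxels and lets
downstream thickness estimates resolve sub-voxel change.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .volumes import AtlasLabels, ImageVolume, Tissue

logger = logging.getLogger(__name__)

#: Sector order around the shell; the last four are the mesial structures.
REGION_NAMES: Tuple[str, ...] = (
    "superiortemporal",
    "middletemporal",
    "inferiortemporal",
    "fusiform",
    "insula",
    "supramarginal",
    "pericalcarine",
    "lateraloccipital",
    "amygdala",
    "hippocampus",
    "entorhinal",
    "parahippocampal",
)

#: Class mean intensities (arbitrary units).  Adjacent class means are 30
#: apart at the narrowest gap, so noise_sigma = 6 gives class SNR = 5.
DEFAULT_INTENSITIES: Dict[str, float] = {
    "CSF": 10.0,
    "GM": 70.0,
    "DGM": 100.0,
    "WM": 130.0,
    "CBM": 160.0,
    "BST": 190.0,
}

#: Class names sorted by DEFAULT_INTENSITIES, darkest first.
DEFAULT_ORDERING: Tuple[str, ...] = ("CSF", "GM", "DGM", "WM", "CBM", "BST")


def default_thickness() -> Dict[str, float]:
    """Per-region cortical thickness (mm), 2.6-3.4 mm as in adult cortex."""
    values = [3.0, 3.2, 2.8, 3.4, 3.0, 2.6, 3.2, 2.8, 3.0, 3.0, 3.0, 3.0]
    return dict(zip(REGION_NAMES, values))


@dataclasses.dataclass
class ResectionSpec:
    """Spherical resection cavity descriptor.

    kind "ATL" is a large lateral+mesial cavity (radius 16 mm at the 96 mm
    reference scale), "SAH" a small mesial one (radius 10 mm); "sphere"
    places an explicit center/radius (mm, world coordinates).
    """

    kind: str = "ATL"
    side: str = "R"
    radius: Optional[float] = None
    center: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("ATL", "SAH", "sphere"):
            raise ValueError("resection kind must be ATL, SAH or sphere")
        if self.side not in ("L", "R"):
            raise ValueError("resection side must be L or R")
        if self.kind == "sphere" and (self.radius is None or self.center is None):
            raise ValueError("kind 'sphere' requires explicit center and radius")


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one pre/post phantom pair."""

    shape: Tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0  # mm, isotropic
    thickness: Optional[Dict[str, float]] = None  # mm per region
    thinning: Optional[Dict[str, float]] = None  # mm/yr per region, + = thinning
    interval_years: float = 2.0
    resection: Optional[ResectionSpec] = None
    noise_sigma: float = 6.0  # intensity units
    rigid_offset: Optional[Tuple[float, ...]] = None  # rx,ry,rz deg, tx,ty,tz mm
    seed: int = 0
    intensities: Optional[Dict[str, float]] = None
    supersample: int = 2

    def __post_init__(self) -> None:
        self.thickness = dict(self.thickness or default_thickness())
        self.thinning = dict(self.thinning or {n: 0.0 for n in REGION_NAMES})
        self.intensities = dict(self.intensities or DEFAULT_INTENSITIES)
        for name in REGION_NAMES:
            self.thickness.setdefault(name, 3.0)
            self.thinning.setdefault(name, 0.0)
            if self.thickness[name] <= 0:
                raise ValueError(f"thickness of {name} must be > 0")
        if self.interval_years <= 0:
            raise ValueError("interval_years must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rigid_offset is not None and len(self.rigid_offset) != 6:
            raise ValueError("rigid_offset must have 6 parameters")
        for name in REGION_NAMES:
            post = self.thickness[name] - self.thinning[name] * self.interval_years
            if post <= 0:
                raise ValueError(
                    f"thinning would drive region {name} thickness to {post:.2f} mm"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.spacing
        return aff

    @property
    def scale(self) -> float:
        """Geometry scale factor relative to the 96 mm reference extent."""
        return min(s * self.spacing for s in self.shape) / 96.0

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) / 2.0 * self.spacing

    def post_thickness(self) -> Dict[str, float]:
        return {
            n: self.thickness[n] - self.thinning[n] * self.interval_years
            for n in REGION_NAMES
        }


@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a phantom pair."""

    label_pre: np.ndarray
    label_post: np.ndarray
    brain_mask: np.ndarray
    resection_mask: np.ndarray
    affine: np.ndarray
    region_table: pd.DataFrame  # region, hemisphere, thickness pre/post, rate
    atlas: AtlasLabels
    applied_offset: Optional[Tuple[float, ...]]


class _Geometry:
    """Analytic anatomy of one phantom, evaluated at arbitrary points."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        s = spec.scale
        self.r_brain = 40.0 * s
        self.r_wm = 28.0 * s
        self.sub_structs = [  # (class, center offset mm, radius mm)
            (Tissue.DGM, np.array([0.0, 9.0, 0.0]) * s, 5.0 * s),
            (Tissue.CBM, np.array([0.0, -9.0, 0.0]) * s, 5.0 * s),
            (Tissue.BST, np.array([0.0, 0.0, -11.0]) * s, 5.0 * s),
        ]
        self.thick_pre = np.array([spec.thickness[n] for n in REGION_NAMES])
        self.thick_post = np.array([spec.post_thickness()[n] for n in REGION_NAMES])
        self.cavity = self._cavity_sphere()

    def _cavity_sphere(self):
        res = self.spec.resection
        if res is None:
            return None
        s = self.spec.scale
        if res.kind == "sphere":
            return np.asarray(res.center, dtype=float), float(res.radius)
        sx = -1.0 if res.side == "L" else 1.0
        # direction through the hippocampal sector (theta = pi/2), tilted
        # into the resected hemisphere
        u = np.array([sx, 0.0, 1.0]) / np.sqrt(2.0)
        if res.kind == "ATL":
            center_r, radius = 24.0 * s, (res.radius or 16.0 * s)
        else:  # SAH
            center_r, radius = 26.0 * s, (res.radius or 10.0 * s)
        return self.spec.center_mm + center_r * u, radius

    def sector_index(self, dx, dy, dz):
        """(hemisphere 0=L/1=R, sector 0..11) for offsets from center (mm)."""
        width = 2.0 * np.pi / len(REGION_NAMES)
        theta = np.arctan2(dz, dy)
        sector = np.floor((theta + np.pi) / width).astype(np.int8)
        np.clip(sector, 0, len(REGION_NAMES) - 1, out=sector)
        hemi = (dx >= 0).astype(np.int8)
        return hemi, sector

    def labels_at(self, X, Y, Z, timepoint: str) -> np.ndarray:
        """Hard tissue labels at physical points (mm); 0 = background."""
        c = self.spec.center_mm
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        out = np.zeros(X.shape, dtype=np.int8)
        brain = r < self.r_brain
        out[brain] = Tissue.CSF
        _, sector = self.sector_index(dx, dy, dz)
        thick = self.thick_pre if timepoint == "pre" else self.thick_post
        t_local = thick[sector]
        out[(r >= self.r_wm) & (r < self.r_wm + t_local)] = Tissue.GM
        out[r < self.r_wm] = Tissue.WM
        for cls, offset, radius in self.sub_structs:
            d2 = (dx - offset[0]) ** 2 + (dy - offset[1]) ** 2 + (dz - offset[2]) ** 2
            out[d2 < radius**2] = cls
        if timepoint == "post" and self.cavity is not None:
            cc, cr = self.cavity
            in_cav = (X - cc[0]) ** 2 + (Y - cc[1]) ** 2 + (Z - cc[2]) ** 2 < cr**2
            gmwm = (out == Tissue.GM) | (out == Tissue.WM)
            out[in_cav & gmwm] = Tissue.CSF
        return out

    def atlas_wedge(self, X, Y, Z) -> np.ndarray:
        """Region labels over a radial wedge bracketing the GM shell."""
        c = self.spec.center_mm
        dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        hemi, sector = self.sector_index(dx, dy, dz)
        labels = np.zeros(X.shape, dtype=np.int16)
        s = self.spec.scale
        wedge = (r >= self.r_wm - 4.0 * s) & (r <= self.r_wm + 6.0 * s)
        labels[wedge] = 1 + sector[wedge] + 12 * hemi[wedge]
        return labels


def _voxel_center_grids(spec: PhantomSpec):
    sp = spec.spacing
    ax = [np.arange(n, dtype=np.float32) * sp for n in spec.shape]
    return np.meshgrid(*ax, indexing="ij")


def _offset_matrix(spec: PhantomSpec) -> Optional[np.ndarray]:
    """World map of the optional rigid offset (rotation about grid center)."""
    if spec.rigid_offset is None:
        return None
    rx, ry, rz = np.deg2rad(spec.rigid_offset[:3])
    t = np.asarray(spec.rigid_offset[3:], dtype=float)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    M = np.eye(4)
    M[:3, :3] = R
    c = spec.center_mm
    M[:3, 3] = t + c - R @ c
    return M


def _synthesize(spec: PhantomSpec, geo: _Geometry, timepoint: str, rng) -> np.ndarray:
    """Partial-volume intensity image for one timepoint."""
    X, Y, Z = _voxel_center_grids(spec)
    M = _offset_matrix(spec) if timepoint == "post" else None
    ss = max(1, int(spec.supersample))
    offsets = (np.arange(ss) + 0.5) / ss - 0.5  # sub-voxel offsets in voxels
    intensity = np.array(
        [0.0] + [spec.intensities[n] for n in DEFAULT_ORDERING], dtype=np.float32
    )  # index 0 = background; then by intensity order
    to_rank = np.zeros(7, dtype=np.int8)  # tissue id -> intensity rank + 1
    for rank, name in enumerate(DEFAULT_ORDERING):
        to_rank[Tissue[name]] = rank + 1
    acc = np.zeros(spec.shape, dtype=np.float32)
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                Xs = X + np.float32(ox * spec.spacing)
                Ys = Y + np.float32(oy * spec.spacing)
                Zs = Z + np.float32(oz * spec.spacing)
                if M is not None:
                    Xs, Ys, Zs = (
                        M[0, 0] * Xs + M[0, 1] * Ys + M[0, 2] * Zs + M[0, 3],
                        M[1, 0] * Xs + M[1, 1] * Ys + M[1, 2] * Zs + M[1, 3],
                        M[2, 0] * Xs + M[2, 1] * Ys + M[2, 2] * Zs + M[2, 3],
                    )
                lab = geo.labels_at(Xs, Ys, Zs, timepoint)
                acc += intensity[to_rank[lab]]
    img = acc / float(ss**3)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, spec.shape).astype(np.float32)
    return img.astype(np.float32)


def generate_phantom(
    spec: PhantomSpec,
) -> Tuple[ImageVolume, ImageVolume, PhantomTruth]:
    """Generate a pre/post volume pair and its ground truth.

    Deterministic given ``spec.seed``; pre and post receive independent
    noise draws (two scans).
    """
    rng = np.random.default_rng(spec.seed)
    geo = _Geometry(spec)
    pre_img = _synthesize(spec, geo, "pre", rng)
    post_img = _synthesize(spec, geo, "post", rng)

    X, Y, Z = _voxel_center_grids(spec)
    label_pre = geo.labels_at(X, Y, Z, "pre")
    label_post = geo.labels_at(X, Y, Z, "post")
    brain = label_pre > 0
    if geo.cavity is not None:
        cc, cr = geo.cavity
        in_cav = (X - cc[0]) ** 2 + (Y - cc[1]) ** 2 + (Z - cc[2]) ** 2 < cr**2
        resection = in_cav & ((label_pre == Tissue.GM) | (label_pre == Tissue.WM))
    else:
        resection = np.zeros(spec.shape, dtype=bool)

    atlas_labels = geo.atlas_wedge(X, Y, Z)
    rows = []
    post_t = spec.post_thickness()
    for hemi_idx, hemi in enumerate("LR"):
        for i, name in enumerate(REGION_NAMES):
            rows.append(
                {
                    "label": 1 + i + 12 * hemi_idx,
                    "region": name,
                    "hemisphere": hemi,
                    "thickness_pre": spec.thickness[name],
                    "thickness_post": post_t[name],
                    "thinning_rate": spec.thinning[name],
                }
            )
    table = pd.DataFrame(rows)
    atlas = AtlasLabels(
        labels=atlas_labels,
        affine=spec.affine,
        table=table[["label", "region", "hemisphere"]].copy(),
    )
    truth = PhantomTruth(
        label_pre=label_pre,
        label_post=label_post,
        brain_mask=brain,
        resection_mask=resection,
        affine=spec.affine,
        region_table=table,
        atlas=atlas,
        applied_offset=spec.rigid_offset,
    )
    pre = ImageVolume(data=pre_img, affine=spec.affine)
    post = ImageVolume(data=post_img, affine=spec.affine)
    return pre, post, truth


def tissue_priors(truth: PhantomTruth, sigma: float = 3.0) -> Dict[str, np.ndarray]:
    """Soft spatial tissue priors from the preoperative label volume.

    Smoothed one-hot maps of the six classes, renormalized inside the
    brain — the stand-in for the registered template priors a real
    segmentation pipeline would supply.  The smoothing keeps them
    uninformative near interfaces (where thickness is decided by
    intensity) while pinning the intensity-overlapping deep structures.
    """
    from scipy.ndimage import gaussian_filter

    maps = {}
    total = np.zeros(truth.label_pre.shape, dtype=np.float32)
    for cls in Tissue:
        m = gaussian_filter((truth.label_pre == cls).astype(np.float32), sigma)
        maps[cls.name] = m
        total += m
    total = np.maximum(total, 1e-6)
    for name in maps:
        maps[name] = maps[name] / total
    return maps


# --- cohort generation -----------------------------------------------------

#: Group thinning-rate distributions (mm/yr): mean, SD.
GROUP_RATES = {"ATL": (0.08, 0.11), "SAH": (0.01, 0.02)}

#: Interscan-interval uniform ranges (years); means 1.7 / 2.95 yr.
GROUP_INTERVALS = {"ATL": (0.5, 2.9), "SAH": (1.0, 4.9)}

#: Minimum admissible postoperative thickness (mm) for truncated rate draws.
MIN_POST_THICKNESS = 0.5


def draw_subject_rate(
    rng, procedure: str, min_thickness: float, interval: float
) -> float:
    """Truncated-normal thinning rate: post thickness stays above 0.5 mm."""
    mean, sd = GROUP_RATES[procedure]
    upper = (min_thickness - MIN_POST_THICKNESS) / interval
    for _ in range(1000):
        rate = rng.normal(mean, sd)
        if rate <= upper:
            return float(rate)
    return float(upper)


@dataclasses.dataclass
class CohortSubject:
    subject_id: str
    spec: PhantomSpec
    metadata: Dict


def plan_cohort(
    n_atl: int,
    n_sah: int,
    template_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
) -> Tuple[List[CohortSubject], pd.DataFrame]:
    """Draw per-subject specs and metadata without synthesizing volumes.

    Thinning rates come from the group normal distributions (ATL
    0.08 +/- 0.11, SAH 0.01 +/- 0.02 mm/yr, truncated), applied uniformly
    across that subject's regions; intervals from per-group uniform ranges.
    """
    if n_atl <= 0 or n_sah <= 0:
        raise ValueError("group sizes must be positive")
    if n_atl + n_sah < 2:
        raise ValueError("need at least two subjects")
    template_spec = template_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: List[CohortSubject] = []
    rows = []
    procedures = ["ATL"] * n_atl + ["SAH"] * n_sah
    min_thick = min(template_spec.thickness.values())
    for i, proc in enumerate(procedures):
        lo, hi = GROUP_INTERVALS[proc]
        interval = float(rng.uniform(lo, hi))
        rate = draw_subject_rate(rng, proc, min_thick, interval)
        side = "L" if rng.uniform() < 1.0 / 3.0 else "R"  # Table-1 L:R = 12:24
        gender = "F" if rng.uniform() < 22.0 / 36.0 else "M"
        age = float(np.clip(rng.normal(37.6, 13.0), 18.0, 75.0))
        has_onset = rng.uniform() < 22.0 / 36.0  # clinical subset
        onset = float(np.clip(rng.normal(19.4, 12.0), 1.0, age - 1.0))
        engel = rng.choice(["I", "II", "III", "IV"], p=[0.6, 0.2, 0.1, 0.1])
        sid = f"sub-{i + 1:03d}"
        spec = dataclasses.replace(
            template_spec,
            thinning={n: rate for n in REGION_NAMES},
            interval_years=interval,
            resection=ResectionSpec(kind=proc, side=side),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            CohortSubject(
                subject_id=sid,
                spec=spec,
                metadata={"true_rate": rate},
            )
        )
        rows.append(
            {
                "subject": sid,
                "procedure": proc,
                "site": "SYN",
                "gender": gender,
                "seizure_side": side,
                "age_at_surgery": round(age, 1),
                "age_at_onset": round(onset, 1) if has_onset else np.nan,
                "duration_years": round(age - onset, 1) if has_onset else np.nan,
                "interscan_interval_years": round(interval, 3),
                "engel": engel if has_onset else "",
                "true_rate": round(rate, 5),
            }
        )
    return subjects, pd.DataFrame(rows)


def generate_cohort(
    n_atl: int,
    n_sah: int,
    template_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
):
    """Generate a full synthetic cohort.

    Returns ``(subjects, cohort_table)`` where each subject entry is
    ``(subject_id, pre, post, truth)`` and the table carries the metadata
    driving group statistics (plus the hidden ``true_rate`` column used only
    for validation).
    """
    planned, table = plan_cohort(n_atl, n_sah, template_spec, seed)
    out = []
    for subj in planned:
        pre, post, truth = generate_phantom(subj.spec)
        out.append((subj.subject_id, pre, post, truth))
        logger.info("generated phantom subject %s", subj.subject_id)
    return out, table
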