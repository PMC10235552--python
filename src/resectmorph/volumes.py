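"""Core spatial data types and I/O shared by every pipeline stage.

All volumes live on a 3D voxel grid with a NIfTI-style 4x4 grid-to-world
affine (0-based voxel indices, RAS world coordinates).  Two volumes are on
the "same grid" when their shapes match and their affines agree within a
small absolute tolerance; every downstream operation checks this and raises
:class:`GridMismatchError` rather than resampling silently.
"""

from __future__ import annotations

import dataclasses
import logging
from enum import IntEnum
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Absolute tolerance for comparing affines of two grids.
GRID_ATOL = 1e-4

#: Tolerance on the per-voxel sum of tissue class probabilities.
PROB_SUM_TOL = 1e-3


class Tissue(IntEnum):
    """Tissue classes of the six-class segmentation; values are label ids."""

    CSF = 1
    GM = 2
    WM = 3
    DGM = 4  # deep gray matter
    CBM = 5  # cerebellum
    BST = 6  # brainstem


#: Canonical class order; also the tie-break order for classification.
CLASS_NAMES: Tuple[str, ...] = tuple(t.name for t in Tissue)

#: Mesial temporal structures removed (entirely or nearly so) by surgery;
#: dropped from ipsilateral regional statistics.
MESIAL_REGIONS: FrozenSet[str] = frozenset(
    {"amygdala", "hippocampus", "entorhinal", "parahippocampal"}
)


class GridMismatchError(ValueError):
    """Raised when inputs that must share one voxel grid do not."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image with its grid-to-world affine.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units) or labels.
    affine:
        4x4 grid-to-world (RAS) transform; must be invertible.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if not np.isfinite(self.affine).all():
            raise ValueError("affine contains non-finite values")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "ImageVolume", atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """A new volume on this grid carrying ``data``."""
        return ImageVolume(data=data, affine=self.affine.copy())

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def require_same_grid(*volumes, what: str = "inputs", atol: float = GRID_ATOL) -> None:
    """Raise :class:`GridMismatchError` unless all volumes share one grid."""
    shapes = [np.shape(v.data) if hasattr(v, "data") else v.shape for v in volumes]
    affines = [v.affine for v in volumes]
    ref_shape, ref_aff = shapes[0], affines[0]
    for shape, aff in zip(shapes[1:], affines[1:]):
        if tuple(shape) != tuple(ref_shape) or not np.allclose(aff, ref_aff, atol=atol):
            raise GridMismatchError(
                f"{what} are not on the same grid "
                f"(shapes {tuple(ref_shape)} vs {tuple(shape)})"
            )


def read_volume(path) -> ImageVolume:
    """Read a 3D NIfTI-1 volume (.nii or .nii.gz).

    NaNs in the file are rejected; 4D files raise ``expected 3D volume``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {img.shape} in {path.name}")
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating) and not np.isfinite(data).all():
        raise ValueError(f"{path.name} contains non-finite values")
    return ImageVolume(data=data, affine=np.asarray(img.affine))


def write_volume(vol: ImageVolume, path, dtype=None) -> Path:
    """Write a volume as NIfTI-1; returns the path written.

    Data are stored in ``dtype`` (default: the array's own dtype) with no
    intensity rescaling, so round-trips are bit-identical.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.data, dtype=dtype) if dtype is not None else vol.data
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))
    return path


@dataclasses.dataclass
class TissueProbabilitySet:
    """Per-class posterior probability maps on one grid.

    ``maps`` is keyed by class name (a subset of :data:`CLASS_NAMES`); inside
    ``brain_mask`` the per-voxel sum over classes must be 1 within
    :data:`PROB_SUM_TOL`.
    """

    maps: Dict[str, np.ndarray]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if not self.maps:
            raise ValueError("probability set has no maps")
        unknown = set(self.maps) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown tissue classes: {sorted(unknown)}")
        shape = self.brain_mask.shape
        for name, arr in self.maps.items():
            arr = np.asarray(arr)
            self.maps[name] = arr
            if arr.shape != shape:
                raise GridMismatchError(f"map {name} shape {arr.shape} != {shape}")
            if arr.min() < -1e-6 or arr.max() > 1 + 1e-6:
                raise ValueError(f"map {name} has values outside [0, 1]")
        if self.brain_mask.any():
            total = self.stack().sum(axis=0)[self.brain_mask]
            if np.abs(total - 1.0).max() > PROB_SUM_TOL:
                raise ValueError("class probabilities do not sum to 1 in brain mask")

    @property
    def classes(self) -> Tuple[str, ...]:
        """Present classes in canonical (tie-break) order."""
        return tuple(n for n in CLASS_NAMES if n in self.maps)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.brain_mask.shape  # type: ignore[return-value]

    def stack(self) -> np.ndarray:
        """(K, nx, ny, nz) array of the maps in canonical class order."""
        return np.stack([self.maps[n] for n in self.classes], axis=0)

    def same_grid(self, other, atol: float = GRID_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def write_probability_set(probs: TissueProbabilitySet, out_dir, prefix: str = "prob"):
    """Write one NIfTI per class (``<prefix>_<CLASS>.nii.gz``) plus the mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in probs.classes:
        p = out_dir / f"{prefix}_{name}.nii.gz"
        write_volume(ImageVolume(probs.maps[name].astype(np.float32), probs.affine), p)
        paths.append(p)
    mask_path = out_dir / f"{prefix}_brainmask.nii.gz"
    write_volume(
        ImageVolume(probs.brain_mask.astype(np.uint8), probs.affine), mask_path
    )
    return paths + [mask_path]


def read_probability_set(in_dir, prefix: str = "prob") -> TissueProbabilitySet:
    """Read the per-class maps written by :func:`write_probability_set`."""
    in_dir = Path(in_dir)
    maps = {}
    affine = None
    for name in CLASS_NAMES:
        p = in_dir / f"{prefix}_{name}.nii.gz"
        if p.exists():
            vol = read_volume(p)
            maps[name] = vol.data.astype(float)
            affine = vol.affine
    if not maps:
        raise FileNotFoundError(f"no {prefix}_<CLASS>.nii.gz maps under {in_dir}")
    mask_path = in_dir / f"{prefix}_brainmask.nii.gz"
    if mask_path.exists():
        mask = read_volume(mask_path).data > 0
    else:
        mask = sum(maps.values()) > 0.5
    return TissueProbabilitySet(maps=maps, affine=affine, brain_mask=mask)


@dataclasses.dataclass
class AtlasLabels:
    """Integer parcellation volume with a region lookup table.

    ``table`` columns: ``label`` (int, nonzero), ``region`` (str),
    ``hemisphere`` in {L, R, midline}.  ``excluded_mesial`` holds the mesial
    temporal region names dropped ipsilaterally from regional statistics;
    names not present in the table are silently irrelevant unless supplied
    explicitly, in which case they must exist.
    """

    labels: np.ndarray
    affine: np.ndarray
    table: pd.DataFrame
    excluded_mesial: FrozenSet[str] = MESIAL_REGIONS
    _explicit_exclusions: dataclasses.InitVar[bool] = False

    def __post_init__(self, _explicit_exclusions: bool) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.round(self.labels)
            if not np.allclose(self.labels, rounded, atol=1e-6):
                raise ValueError("atlas label volume is not integer-valued")
            self.labels = rounded.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=float)
        required = {"label", "region", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"atlas table must have columns {sorted(required)}")
        if self.table["label"].duplicated().any():
            dup = self.table.loc[self.table["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate labels in atlas table: {dup}")
        bad_hemi = set(self.table["hemisphere"]) - {"L", "R", "midline"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere tags: {sorted(bad_hemi)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["label"].astype(int))
        missing = sorted(present - known)
        if missing:
            raise ValueError(f"label(s) {missing} present in volume but not in table")
        regions = set(self.table["region"])
        if _explicit_exclusions:
            unknown = set(self.excluded_mesial) - regions
            if unknown:
                raise ValueError(f"excluded regions not in atlas: {sorted(unknown)}")
        else:
            self.excluded_mesial = frozenset(self.excluded_mesial) & regions

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def label_to_region(self) -> Dict[int, Tuple[str, str]]:
        """Map label id -> (region name, hemisphere)."""
        return {
            int(r.label): (r.region, r.hemisphere) for r in self.table.itertuples()
        }


def load_atlas(labels_path, table_path, excluded_mesial=None) -> AtlasLabels:
    """Load an atlas from a NIfTI label volume and a TSV lookup table."""
    vol = read_volume(labels_path)
    table = pd.read_csv(table_path, sep="\t")
    kwargs = {}
    if excluded_mesial is not None:
        kwargs = {
            "excluded_mesial": frozenset(excluded_mesial),
            "_explicit_exclusions": True,
        }
    return AtlasLabels(labels=vol.data, affine=vol.affine, table=table, **kwargs)


def save_atlas(atlas: AtlasLabels, labels_path, table_path) -> None:
    write_volume(
        ImageVolume(atlas.labels.astype(np.int16), atlas.affine), labels_path
    )
    atlas.table.to_csv(table_path, sep="\t", index=False)


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the pipeline.

    smoothing_sigma is in voxel units (equal to mm at the nominal 1 mm
    isotropic resolution); csf_increase_threshold is an absolute CSF
    probability increase; connectivity is the 3D neighborhood (6/18/26) that
    defines "contiguous" for the largest-cluster rule.
    """

    smoothing_sigma: float = 2.0
    csf_increase_threshold: float = 0.25
    connectivity: int = 26
    random_seed: int = 0
    thickness_tolerance: float = 0.2  # mm; flags unreliable regional means
    n_classes: int = 6
    t_test_variant: str = "pooled"
    assume_aligned: bool = False
    template_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.csf_increase_threshold < 1.0):
            raise ValueError("csf_increase_threshold must be in (0, 1)")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")
        if self.t_test_variant not in ("pooled", "welch"):
            raise ValueError("t_test_variant must be 'pooled' or 'welch'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
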