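"""Core in-memory containers shared across pipeline stages.

The pipeline passes 3-D statistical volumes around as :class:`VolumetricMap`
objects (a value lattice plus a voxel-index -> world-mm affine, the same
convention NIfTI uses) and group-contrast output as :class:`ContrastResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


@dataclass
class VolumetricMap:
    """A 3-D scalar lattice in a world coordinate frame.

    Parameters
    ----------
    values
        3-D array of voxel values.
    affine
        4x4 invertible matrix mapping voxel indices (i, j, k, 1) to world
        millimetre coordinates (RAS orientation for all maps produced here).
    mask
        Optional boolean in-brain lattice of the same shape. ``None`` means
        every voxel is in-mask.
    """

    values: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask and values shapes differ")
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ValueError("non-finite values inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.mask

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, source: str | Path | nib.Nifti1Image,
                   mask: np.ndarray | None = None) -> "VolumetricMap":
        img = source if isinstance(source, nib.spatialimages.SpatialImage) \
            else nib.load(str(source))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask)


@dataclass
class ContrastResult:
    """Voxelwise two-group GLM t-map with optional cluster-corrected masks.

    ``t_map.values`` holds the t statistic of the group-indicator
    coefficient (positive t = group A > group B). ``residuals`` keeps the
    subject-wise GLM residual volumes (n_subjects x grid) needed for field
    smoothness estimation; it is dropped once correction has run.
    """

    name: str
    t_map: VolumetricMap
    df: int
    n_subjects: int
    residuals: np.ndarray | None = None
    cluster_table: pd.DataFrame | None = None
    mask_neg: np.ndarray | None = None
    mask_pos: np.ndarray | None = None
    fwhm_mm: np.ndarray | None = None

    def corrected_mask(self, sign: str) -> np.ndarray:
        """Return the cluster-corrected binary mask for 'neg' or 'pos' t."""
        m = {"neg": self.mask_neg, "pos": self.mask_pos}.get(sign)
        if m is None:
            raise ValueError(
                f"no corrected {sign!r} mask; run grf_cluster_correct first")
        return m


@dataclass
class RegionalProfile:
    """Per-tissue-sample regional t values (sphere means around each sample).

    ``table`` is indexed by sample (well) ID with columns ``t_mean`` and
    ``n_voxels``; ``dropped`` lists samples whose sphere contained no
    in-mask voxel (these must also be dropped from the expression matrix).
    """

    table: pd.DataFrame
    radius_mm: float
    dropped: list = field(default_factory=list)

    @property
    def t(self) -> pd.Series:
        return self.table["t_mean"]

    def __len__(self) -> int:
        return len(self.table)
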