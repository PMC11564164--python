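"""Sphere-based extraction of regional t values at tissue-sample coordinates.

Each tissue sample's regional T is the mean of the contrast t statistic
over in-mask voxels whose center lies within ``radius_mm`` (Euclidean
distance in world mm, boundary inclusive) of the sample's MNI coordinate.
The default radius of 4.5 mm is three times the 1.5 mm voxel size.
Out-of-mask voxels are excluded from the mean rather than zero-filled;
samples whose sphere contains no in-mask voxel are dropped with a
warning and must be dropped from the expression matrix as well (joins
downstream are by sample ID).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import RegionalProfile, VolumetricMap


def sphere_mean_t(t_map: VolumetricMap, coords: np.ndarray | pd.DataFrame,
                  radius_mm: float = 4.5,
                  sample_ids: np.ndarray | None = None) -> RegionalProfile:
    """Mean t within a sphere around each coordinate.

    Parameters
    ----------
    t_map
        Contrast t-map; its mask defines which voxels may contribute.
    coords
        (n, 3) world-mm coordinates, or a DataFrame with mni_x/y/z columns
        (its index then provides the sample IDs).
    radius_mm
        Inclusive sphere radius in mm.
    sample_ids
        Explicit sample IDs aligned with ``coords`` rows.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    if isinstance(coords, pd.DataFrame):
        if sample_ids is None:
            sample_ids = coords.index.to_numpy()
        coords = coords[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords must be finite")
    if sample_ids is None:
        sample_ids = np.arange(len(coords))

    mask = t_map.effective_mask()
    shape = np.asarray(t_map.shape)
    inv_rows = np.linalg.inv(t_map.affine)[:3, :3]
    # bounding half-width of the world-mm ball in index space, per axis
    halfwidth = radius_mm * np.sqrt((inv_rows ** 2).sum(axis=1))

    means = np.full(len(coords), np.nan)
    counts = np.zeros(len(coords), dtype=int)
    for s, c in enumerate(coords):
        ctr = t_map.world_to_voxel(c)
        lo = np.maximum(np.floor(ctr - halfwidth).astype(int), 0)
        hi = np.minimum(np.ceil(ctr + halfwidth).astype(int), shape - 1)
        if np.any(lo > hi):
            continue  # entirely outside the volume bounding box
        grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                            indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        world = t_map.voxel_to_world(idx)
        d2 = ((world - c) ** 2).sum(axis=1)
        inside = d2 <= radius_mm ** 2 + 1e-9
        idx = idx[inside]
        if len(idx) == 0:
            continue
        sel = mask[tuple(idx.T)]
        idx = idx[sel]
        if len(idx) == 0:
            continue
        counts[s] = len(idx)
        means[s] = t_map.values[tuple(idx.T)].mean()

    keep = counts > 0
    dropped = list(np.asarray(sample_ids)[~keep])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} samples with no in-mask "
                      f"voxels within {radius_mm} mm")
    table = pd.DataFrame({"t_mean": means[keep], "n_voxels": counts[keep]},
                         index=pd.Index(np.asarray(sample_ids)[keep],
                                        name="sample_id"))
    return RegionalProfile(table=table, radius_mm=radius_mm, dropped=dropped)
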