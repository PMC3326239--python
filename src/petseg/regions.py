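"""Region utilities shared by all segmenters.

Connected components use 26-connectivity.  The lesion "search region" is
the subvolume within which the lesion maximum and all clustering/threshold
statistics are computed; the benchmark derives it from the ground-truth
bounding box, a user would draw it around the hot spot.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume

__all__ = [
    "EmptyMaskError",
    "mask_from_threshold",
    "select_component",
    "suv_max",
    "isocontour_mean",
    "default_seed_point",
    "box_region",
    "background_shell",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class EmptyMaskError(RuntimeError):
    """Signal (not a hard error) that no voxel satisfies the threshold."""


def default_seed_point(img: ImageVolume, region: np.ndarray | None = None):
    """Voxel index of the intensity maximum inside the search region."""
    vals = img.values
    if region is not None:
        vals = np.where(region, vals, -np.inf)
    return tuple(int(i) for i in np.unravel_index(np.argmax(vals), vals.shape))


def select_component(binary: np.ndarray, seed_point) -> np.ndarray:
    """The 26-connected component containing (or nearest to) seed_point."""
    labels, n = ndimage.label(binary, structure=_CONN26)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    seed = tuple(int(round(c)) for c in seed_point)
    seed = tuple(np.clip(s, 0, d - 1) for s, d in zip(seed, binary.shape))
    lab = labels[seed]
    if lab == 0:
        # nearest supra-threshold voxel decides the component
        idx = np.argwhere(binary)
        d2 = ((idx - np.asarray(seed)) ** 2).sum(axis=1)
        lab = labels[tuple(idx[np.argmin(d2)])]
    return labels == lab


def mask_from_threshold(
    img: ImageVolume,
    threshold: float,
    seed_point=None,
    region: np.ndarray | None = None,
) -> BinaryMask:
    """Voxels >= threshold, restricted to the seed's connected component.

    Returns an empty mask (the empty-mask signal) when no voxel reaches the
    threshold.  When a search region is given, thresholding is confined to
    it.
    """
    binary = img.values >= threshold
    if region is not None:
        binary &= region
    if not binary.any():
        return BinaryMask(np.zeros(img.shape, dtype=bool), img.spacing)
    if seed_point is None:
        seed_point = default_seed_point(img, region)
    return BinaryMask(select_component(binary, seed_point), img.spacing)


def suv_max(img: ImageVolume, region: np.ndarray | None = None) -> float:
    vals = img.values if region is None else img.values[region]
    if vals.size == 0:
        raise ValueError("empty search region")
    return float(vals.max())


def isocontour_mean(
    img: ImageVolume,
    fraction: float,
    seed_point=None,
    region: np.ndarray | None = None,
) -> float:
    """Mean intensity inside the ``fraction * I_max`` isocontour of the
    lesion component (e.g. fraction=0.70 for the 70% isocontour)."""
    t = fraction * suv_max(img, region)
    iso = mask_from_threshold(img, t, seed_point, region)
    if iso.is_empty():
        raise EmptyMaskError(f"empty {100 * fraction:.0f}% isocontour")
    return float(img.values[iso.values].mean())


def _bbox_mask(truth: np.ndarray) -> np.ndarray:
    idx = np.argwhere(truth)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    m = np.zeros_like(truth, dtype=bool)
    m[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = True
    return m


def box_region(truth: BinaryMask, margin_mm: float = 16.0) -> BinaryMask:
    """Truth bounding box dilated by ``margin_mm``: the lesion search region."""
    if truth.is_empty():
        raise ValueError("truth mask is empty")
    idx = np.argwhere(truth.values)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    m = np.zeros(truth.shape, dtype=bool)
    sl = tuple(
        slice(
            max(0, int(l - np.ceil(margin_mm / h))),
            min(n, int(u + np.ceil(margin_mm / h)) + 1),
        )
        for l, u, n, h in zip(lo, hi, truth.shape, truth.spacing)
    )
    m[sl] = True
    return BinaryMask(m, truth.spacing)


def background_shell(
    truth: BinaryMask, inner_mm: float = 15.0, outer_mm: float = 25.0
) -> BinaryMask:
    """Background ROI: a shell ``inner_mm``-``outer_mm`` outside the truth
    bounding box, standing in for a neighbouring organ far from the target."""
    box = _bbox_mask(truth.values)
    dist = ndimage.distance_transform_edt(~box, sampling=truth.spacing)
    shell = (dist >= inner_mm) & (dist <= outer_mm)
    if not shell.any():
        raise ValueError("grid too small for a background shell")
    return BinaryMask(shell, truth.spacing)
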