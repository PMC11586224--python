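"""Whole-spheroid mask creation from the nuclear channel.

The nuclear stain gives consistent, reliable signal across conditions, so
the spheroid mask is always built from it — this removes any bias from
intensity changes in the channels being quantified.  Two modes are
provided:

* **2D**: maximum intensity projection → Gaussian pre-filter (σ = 3 px
  default) → HK-means intensity thresholding → minimum-object-size filter
  (10,000 px default) → fill holes → keep largest component.  This is the
  mask used by the cortical-actin ring analysis.
* **3D**: per-volume pre-filter → HK-means on the full 3D histogram →
  3D size filter (the 2D minimum scaled by the object's z-extent) →
  slice-wise hole fill → largest component.  This is the mask used for
  morphometry.

HK-means here is k-means on the 1D intensity histogram; for the two-class
use of this pipeline the hierarchical variant collapses to exactly that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .stack import ChannelStack

__all__ = [
    "SegmentationParams",
    "SpheroidMask",
    "SpheroidNotFoundError",
    "max_project",
    "gaussian_prefilter",
    "hkmeans_threshold",
    "fill_holes",
    "keep_largest_component",
    "segment_spheroid",
]


class SpheroidNotFoundError(RuntimeError):
    """Raised when segmentation finds no spheroid in the field."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the mask pipeline.

    ``sigma`` is the Gaussian pre-filter width in pixels (applied per axis
    in voxel units in 3D mode).  ``min_object_size`` is the minimum
    connected-component size in pixels on the 2D projection; in 3D mode
    the default threshold is ``min_object_size`` scaled by the candidate
    object's z-extent in voxels unless ``min_object_size_3d`` overrides it.
    """

    sigma: float = 3.0
    sigma_um_3d: float = 4.0
    n_classes: int = 2
    min_object_size: int = 10_000
    min_object_size_3d: Optional[int] = None
    mode: str = "2d"

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_um_3d < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.min_object_size < 0:
            raise ValueError("min_object_size must be >= 0")
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")


@dataclass
class SpheroidMask:
    """A finalised binary spheroid region plus full provenance.

    ``data`` is 2D ``(y, x)`` or 3D ``(z, y, x)``; ``spacing`` carries the
    matching physical pixel/voxel sizes in µm.  ``provenance`` records the
    smoothing σ, threshold method and value, size filter, number of
    components removed and whether holes were filled.
    """

    data: np.ndarray
    spacing: Tuple[float, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing length must match mask dimensionality")


def max_project(stack: ChannelStack, channel: str) -> np.ndarray:
    """Maximum intensity projection (MIP) of one channel over z."""
    return stack.channel(channel).max(axis=0)


def gaussian_prefilter(image: np.ndarray, sigma: float | Sequence[float]) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; σ = 0 is the identity."""
    sig = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(sig < 0):
        raise ValueError("sigma must be >= 0")
    if np.all(sig == 0):
        return np.asarray(image, dtype=float).copy()
    return ndi.gaussian_filter(np.asarray(image, dtype=float), sigma=sigma,
                               mode="reflect")


def _kmeans_1d(values: np.ndarray, weights: np.ndarray, k: int,
               max_iter: int = 200) -> np.ndarray:
    """Weighted Lloyd's algorithm on sorted 1D values; returns class means.

    Initialised at evenly spaced weighted quantiles, so the result is
    deterministic.  For 1D data each class is a contiguous interval, which
    makes this equivalent to optimal histogram thresholding when it
    converges to the global optimum (checked against an exhaustive-search
    oracle in the test suite for the two-class case).
    """
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    total = cw[-1]
    qs = (np.arange(k) + 0.5) / k
    centers = np.array([v[np.searchsorted(cw, q * total)] for q in qs], dtype=float)
    centers = np.unique(centers)
    while len(centers) < k:  # duplicate quantiles on coarse histograms
        centers = np.append(centers, centers[-1] + 1.0)
    for _ in range(max_iter):
        # assignment: nearest centre == thresholding at midpoints
        bounds = (centers[:-1] + centers[1:]) / 2.0
        assign = np.searchsorted(bounds, v, side="right")
        new = centers.copy()
        for j in range(k):
            sel = assign == j
            if w[sel].sum() > 0:
                new[j] = np.average(v[sel], weights=w[sel])
        if np.allclose(new, centers):
            break
        centers = np.sort(new)
    return centers


def hkmeans_threshold(
    image: np.ndarray,
    n_classes: int = 2,
    min_object_size: int = 10_000,
    n_bins: int = 256,
) -> Tuple[np.ndarray, dict]:
    """Histogram k-means thresholding plus minimum-object-size filtering.

    The intensity histogram is partitioned into ``n_classes`` by k-means;
    foreground is the union of every class above the lowest-mean class.
    Connected components smaller than ``min_object_size`` are removed.
    Returns ``(mask, info)`` where ``info`` records the threshold(s) and
    the number of components removed.  A constant (zero-contrast) image
    yields an empty mask with a warning.
    """
    image = np.asarray(image, dtype=float)
    info: dict = {"method": "hkmeans", "n_classes": n_classes,
                  "min_object_size": int(min_object_size)}
    vmin, vmax = float(image.min()), float(image.max())
    if vmax <= vmin:
        warnings.warn("constant image: no contrast, returning empty mask")
        info.update(threshold=None, components_removed=0)
        return np.zeros(image.shape, dtype=bool), info
    hist, edges = np.histogram(image, bins=n_bins, range=(vmin, vmax))
    mids = (edges[:-1] + edges[1:]) / 2.0
    nz = hist > 0
    centers = _kmeans_1d(mids[nz], hist[nz].astype(float), n_classes)
    # threshold between the lowest-mean class and the next one
    bounds = (centers[:-1] + centers[1:]) / 2.0
    threshold = float(bounds[0])
    info["threshold"] = threshold
    info["class_means"] = [float(c) for c in centers]
    fg = image > threshold
    if min_object_size > 0:
        lab, n = ndi.label(fg, structure=np.ones((3,) * image.ndim, dtype=int))
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_size
        keep[0] = False
        kept = keep[lab]
        info["components_removed"] = int((~keep[1:][sizes[1:] > 0]).sum())
        fg = kept
    else:
        info["components_removed"] = 0
    return fg, info


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components (full connectivity) below ``min_size``."""
    lab, _ = ndi.label(mask, structure=np.ones((3,) * mask.ndim, dtype=int))
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Set background regions not connected to the image border to
    foreground ("fill-holes in ROI"); foreground never shrinks."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def keep_largest_component(mask: np.ndarray) -> np.ndarray:
    """Retain only the largest connected component (8-connectivity in 2D,
    26 in 3D); ties break to the component whose first voxel in scan order
    (lexicographically smallest index) comes first."""
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=np.ones((3,) * mask.ndim, dtype=int))
    if n == 0:
        warnings.warn("empty mask: no components to keep")
        return mask.copy()
    sizes = np.bincount(lab.ravel())[1:]
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        # ndi.label numbers components in scan order, so the smallest label
        # among the tied candidates contains the lexicographically smallest
        # seed voxel
        chosen = candidates.min()
    return lab == chosen


def segment_spheroid(
    stack: ChannelStack,
    channel: str = "dapi",
    params: Optional[SegmentationParams] = None,
) -> SpheroidMask:
    """Full mask pipeline on the nuclear channel, 2D or 3D.

    Raises :class:`SpheroidNotFoundError` if the final mask is empty.
    """
    if params is None:
        params = SegmentationParams()
    prov: dict = {"channel": channel, "sigma": params.sigma, "mode": params.mode}

    if params.mode == "2d":
        img = max_project(stack, channel)
        img = gaussian_prefilter(img, params.sigma)
        fg, info = hkmeans_threshold(img, params.n_classes, params.min_object_size)
        prov.update(info)
        fg = fill_holes(fg)
        prov["holes_filled"] = True
        if fg.any():
            fg = keep_largest_component(fg)
        spacing = tuple(stack.spacing[1:])
    else:
        # 3D smoothing works in physical units so anisotropic voxels are
        # smoothed isotropically in µm
        sigma_vox = params.sigma_um_3d / np.asarray(stack.spacing)
        vol = gaussian_prefilter(stack.channel(channel), sigma_vox)
        prov["sigma_um_3d"] = params.sigma_um_3d
        fg, info = hkmeans_threshold(vol, params.n_classes, min_object_size=0)
        prov.update(info)
        min3d = params.min_object_size_3d
        if min3d is None:
            # scale the 2D pixel threshold into a voxel threshold by the
            # candidate object's z-extent; the extra factor 1/4 keeps a
            # convex body (volume ~ 2/3 of its bounding cylinder) with a
            # projected area near the 2D minimum safely above threshold
            if fg.any():
                lab, _ = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=int))
                sizes = np.bincount(lab.ravel())
                sizes[0] = 0
                big = lab == sizes.argmax()
                z_any = np.flatnonzero(big.any(axis=(1, 2)))
                z_extent = int(z_any[-1] - z_any[0] + 1) if len(z_any) else 1
            else:
                z_extent = 1
            min3d = params.min_object_size * max(1, z_extent) // 4
        prov["min_object_size"] = int(min3d)
        if min3d > 0 and fg.any():
            fg = _remove_small(fg, min3d)
        # lumen-like voids along z should survive: fill holes slice-wise
        fg = np.stack([fill_holes(sl) for sl in fg], axis=0)
        prov["holes_filled"] = "slicewise_xy"
        if fg.any():
            fg = keep_largest_component(fg)
        spacing = tuple(stack.spacing)

    if not fg.any():
        raise SpheroidNotFoundError(
            f"no spheroid detected in channel {channel!r} ({params.mode} mode)"
        )
    return SpheroidMask(data=fg, spacing=spacing, provenance=prov)
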