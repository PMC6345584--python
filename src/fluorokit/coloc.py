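"""Colocalization and receptor-level quantification.

Covers the fixed-cell measurements around receptor trafficking: Pearson
correlation of two channels inside a cell or leading-edge ROI, the fraction of
one channel's vesicle pixels overlapping the other channel's vesicles,
surface/total intensity levels relative to a control group, and
flow-cytometry background subtraction using a secondary-antibody-only sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .spotdetect import PixelImage, VesicleSet

__all__ = [
    "RegionMask",
    "ColocResult",
    "OverlapResult",
    "IntensityLevels",
    "FacsLevel",
    "pearson_coloc",
    "leading_edge_roi",
    "membrane_band",
    "intensity_levels",
    "vesicle_overlap",
    "facs_surface_level",
]


@dataclass
class RegionMask:
    """Boolean ROI aligned to an image grid."""

    mask: np.ndarray
    kind: str = "custom"
    band_width: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int
    roi_kind: str


@dataclass
class OverlapResult:
    """Asymmetric overlap of channel-A vesicle pixels into channel-B vesicles."""

    overlap_fraction: float
    n_vesicles_a: int
    per_vesicle: pd.DataFrame  # columns: label, overlap_fraction


@dataclass
class IntensityLevels:
    total_mean: float
    surface_mean: float
    normalized_total: float | None = None
    normalized_surface: float | None = None


@dataclass
class FacsLevel:
    level: float
    n_sample: int
    n_background: int
    statistic: str


def _as_array(img: PixelImage | np.ndarray) -> np.ndarray:
    return img.values if isinstance(img, PixelImage) else np.asarray(img, float)


def pearson_coloc(
    img_a: PixelImage | np.ndarray,
    img_b: PixelImage | np.ndarray,
    roi: RegionMask,
) -> ColocResult:
    """Pearson correlation of paired pixel intensities within an ROI.

    Computed on raw intensities with no thresholding (the headline statistic
    of pixel-based colocalization plugins).
    """
    a = _as_array(img_a)
    b = _as_array(img_b)
    if a.shape != b.shape or a.shape != roi.mask.shape:
        raise ValueError("images and ROI mask must share a shape")
    xa = a[roi.mask]
    xb = b[roi.mask]
    if xa.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    for name, x in (("A", xa), ("B", xb)):
        if np.ptp(x) == 0:
            raise ValueError(f"channel {name} has zero variance inside the ROI")
    r = float(np.corrcoef(xa, xb)[0, 1])
    return ColocResult(pearson_r=r, n_pixels=xa.size, roi_kind=roi.kind)


def leading_edge_roi(
    path: Sequence[tuple[float, float]],
    width: float,
    shape: tuple[int, int],
) -> RegionMask:
    """Band of given width along a polyline (e.g. a traced leading edge).

    The mask contains every pixel centre within width/2 Euclidean distance of
    the path, so a straight segment yields a stadium-shaped region.
    """
    verts = np.asarray(path, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 2:
        raise ValueError("path must contain at least 2 (row, col) vertices")
    if np.allclose(verts, verts[0]):
        raise ValueError("degenerate path: all vertices coincide")
    if width < 1:
        raise ValueError("width must be >= 1 pixel")
    if (verts < 0).any() or (verts[:, 0] >= shape[0]).any() or (verts[:, 1] >= shape[1]).any():
        raise ValueError("path vertices must lie inside the image bounds")

    rr, cc = np.indices(shape, dtype=float)
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    min_d2 = np.full(pts.shape[0], np.inf)
    for p0, p1 in zip(verts[:-1], verts[1:]):
        seg = p1 - p0
        seg_len2 = float(seg @ seg)
        rel = pts - p0
        if seg_len2 == 0.0:
            d2 = np.einsum("ij,ij->i", rel, rel)
        else:
            t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
            diff = rel - t[:, None] * seg
            d2 = np.einsum("ij,ij->i", diff, diff)
        np.minimum(min_d2, d2, out=min_d2)
    mask = (min_d2 <= (width / 2.0) ** 2).reshape(shape)
    return RegionMask(mask=mask, kind="leading_edge_line", band_width=width)


def membrane_band(cell_mask: RegionMask, width: int) -> RegionMask:
    """Peripheral band of a cell mask: the mask minus its inward erosion.

    Erosion is by a Euclidean disk of radius ``width`` (a pixel survives iff
    its distance to the mask complement exceeds width); the band is what the
    erosion removed. Rejects cells thinner than the band.
    """
    if width < 1:
        raise ValueError("band width must be >= 1 pixel")
    m = cell_mask.mask
    if not m.any():
        raise ValueError("cell mask is empty")
    dist = ndimage.distance_transform_edt(m)
    eroded = dist > width
    if not eroded.any():
        raise ValueError("erosion empties the mask: cell thinner than the band")
    return RegionMask(mask=m & ~eroded, kind="membrane_band", band_width=width)


def intensity_levels(
    image: PixelImage | np.ndarray,
    cell_mask: RegionMask,
    band: RegionMask,
    control_means: tuple[float, float] | None = None,
) -> IntensityLevels:
    """Total and surface (membrane-band) mean intensities per cell area.

    When control_means = (total, surface) of a control group is supplied,
    normalized levels relative to those controls are reported as well.
    """
    arr = _as_array(image)
    cm = cell_mask.mask
    bm = band.mask
    if arr.shape != cm.shape or arr.shape != bm.shape:
        raise ValueError("image and masks must share a shape")
    if not cm.any() or not bm.any():
        raise ValueError("masks must be non-empty")
    if (bm & ~cm).any():
        raise ValueError("band mask is not a subset of the cell mask")
    total_mean = float(arr[cm].mean())
    surface_mean = float(arr[bm].mean())
    norm_t = norm_s = None
    if control_means is not None:
        ct, cs = control_means
        if ct <= 0 or cs <= 0:
            raise ValueError("control means must be positive for normalization")
        norm_t = total_mean / ct
        norm_s = surface_mean / cs
    return IntensityLevels(
        total_mean=total_mean,
        surface_mean=surface_mean,
        normalized_total=norm_t,
        normalized_surface=norm_s,
    )


def vesicle_overlap(vesicles_a: VesicleSet, vesicles_b: VesicleSet) -> OverlapResult:
    """Fraction of A-vesicle pixels falling inside B-vesicle pixels.

    Asymmetric by design: A is the receptor channel, B the reference
    compartment (e.g. lysosomes). Also reported per A-vesicle.
    """
    la = vesicles_a.label_map
    lb = vesicles_b.label_map
    if la.shape != lb.shape:
        raise ValueError("label maps must share a shape")
    in_a = la > 0
    if not in_a.any():
        raise ValueError("undefined overlap: channel A has no labelled pixels")
    in_b = lb > 0
    overall = float((in_a & in_b).sum() / in_a.sum())

    n_labels = int(la.max())
    sizes = np.bincount(la.ravel(), minlength=n_labels + 1)[1:]
    hits = np.bincount(la[in_b].ravel(), minlength=n_labels + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sizes > 0, hits / np.maximum(sizes, 1), np.nan)
    per = pd.DataFrame(
        {"label": np.arange(1, n_labels + 1), "overlap_fraction": frac}
    )
    per = per[sizes > 0].reset_index(drop=True)
    return OverlapResult(
        overlap_fraction=overall,
        n_vesicles_a=len(per),
        per_vesicle=per,
    )


def facs_surface_level(
    sample_events: np.ndarray,
    background_events: np.ndarray,
    statistic: str = "mean",
) -> FacsLevel:
    """Background-subtracted fluorescence level from per-event readings.

    The background population (secondary-antibody-only control) sets the
    autofluorescence level; the reported level is sample minus background,
    floored at zero. Mean by default, median by flag.
    """
    s = np.asarray(sample_events, dtype=float).ravel()
    b = np.asarray(background_events, dtype=float).ravel()
    if s.size == 0 or b.size == 0:
        raise ValueError("event sets must be non-empty")
    if statistic == "mean":
        level = float(s.mean() - b.mean())
    elif statistic == "median":
        level = float(np.median(s) - np.median(b))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return FacsLevel(
        level=max(level, 0.0),
        n_sample=s.size,
        n_background=b.size,
        statistic=statistic,
    )
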