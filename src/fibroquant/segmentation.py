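"""SHG collagen segmentation and TPEF tissue/lumen masking.

The SHG channel is thresholded with Otsu's method restricted to tissue;
connected collagen components smaller than 15 um^2 are discarded as noise
and small interior gaps (<= 2 px) are filled.  The TPEF channel is Otsu
thresholded and only tissue components larger than 0.1 mm^2 are kept.
Holes inside the tissue mask become lumen candidates (vessels, bile ducts,
sinusoids, fissures) with shape and collagen-collar features for downstream
landmark classification.

Conventions (configurable): collagen and lumens use 8-connectivity, tissue
uses 4-connectivity; the collagen area filter is a strict ``< 15 um^2``
removal, the tissue filter a strict ``> 0.1 mm^2`` retention, both as their
conventional statements.  Processing order: threshold -> area filter ->
gap fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .datatypes import LumenObject, MultiphotonImage

__all__ = [
    "otsu_threshold",
    "segment_tissue",
    "segment_collagen",
    "detect_lumens",
    "SegmentationResult",
    "MIN_COLLAGEN_AREA_UM2",
    "MIN_TISSUE_AREA_MM2",
]

MIN_COLLAGEN_AREA_UM2 = 15.0
MIN_TISSUE_AREA_MM2 = 0.1
DEFAULT_MIN_LUMEN_UM2 = 100.0


@dataclass
class SegmentationResult:
    """Binary mask plus the ordered provenance of steps that produced it."""

    mask: np.ndarray
    provenance: list[str] = field(default_factory=list)


def otsu_threshold(histogram: np.ndarray) -> float:
    """Otsu threshold from a 256-bin intensity histogram.

    Returns the bin boundary (upper edge of the background class, i.e. a
    value ``t`` such that pixels with bin index > t are foreground) that
    maximises the between-class variance.  Ties go to the smallest such
    boundary.

    Raises
    ------
    ValueError
        If the histogram is empty or all mass sits in a single bin (zero
        between-class variance everywhere: no threshold exists).
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array of bin counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has zero total count")
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: all mass in one bin")

    bins = np.arange(counts.size, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]  # mass of class {0..t}
    w1 = total - w0
    m0 = np.cumsum(counts * bins)[:-1]
    mu_total = (counts * bins).sum()
    # between-class variance for every candidate split t in [0, nbins-2]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return float(np.argmax(sigma_b))


def _image_histogram(values: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Histogram of [0, 1] intensities into ``nbins`` equal bins."""
    idx = np.clip((values * nbins).astype(np.int64), 0, nbins - 1)
    return np.bincount(idx.ravel(), minlength=nbins)


def _otsu_binary(values: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Foreground mask of a [0,1] intensity array by Otsu on 256 bins."""
    hist = _image_histogram(values, nbins)
    t = otsu_threshold(hist)
    return (np.clip((values * nbins), 0, nbins - 1).astype(np.int64)) > t


def segment_tissue(
    img: MultiphotonImage,
    min_area_mm2: float = MIN_TISSUE_AREA_MM2,
    connectivity: int = 1,
) -> SegmentationResult:
    """Tissue mask from the TPEF channel.

    Otsu thresholds the TPEF channel and keeps connected components whose
    physical area strictly exceeds ``min_area_mm2``.  An empty mask is a
    valid result (e.g. a background-only field of view).
    """
    prov = [f"otsu(tpef,256)"]
    try:
        fg = _otsu_binary(img.tpef)
    except ValueError:
        return SegmentationResult(np.zeros(img.shape, dtype=bool), prov + ["degenerate->empty"])
    min_px = min_area_mm2 * 1e6 / img.pixel_area_um2
    labels, n = ndimage.label(fg, structure=ndimage.generate_binary_structure(2, connectivity))
    if n == 0:
        return SegmentationResult(np.zeros(img.shape, dtype=bool), prov)
    sizes = np.bincount(labels.ravel())
    keep = sizes > min_px  # strict: area must exceed the floor
    keep[0] = False
    mask = keep[labels]
    prov.append(f"area_filter(> {min_area_mm2} mm^2 = {min_px:g} px, conn={connectivity})")
    return SegmentationResult(mask, prov)


def segment_collagen(
    img: MultiphotonImage,
    tissue: np.ndarray,
    min_area_um2: float = MIN_COLLAGEN_AREA_UM2,
    fill_hole_px: int = 2,
    connectivity: int = 2,
    lumen_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Collagen mask from the SHG channel, restricted to tissue.

    Otsu on SHG within the tissue mask; 8-connected components with
    physical area strictly below ``min_area_um2`` are removed as noise;
    interior holes of at most ``fill_hole_px`` pixels are then filled.
    Components whose pixels touch a lumen boundary (vessel walls) are always
    retained regardless of later pruning, when ``lumen_mask`` is given.
    """
    if not np.any(tissue):
        raise ValueError("tissue mask is empty; collagen segmentation undefined")
    prov = ["otsu(shg|tissue,256)"]
    vals = img.shg[tissue]
    try:
        hist = _image_histogram(vals)
        t = otsu_threshold(hist)
    except ValueError:
        return SegmentationResult(np.zeros(img.shape, dtype=bool), prov + ["degenerate->empty"])
    fg = np.zeros(img.shape, dtype=bool)
    fg[tissue] = np.clip(img.shg[tissue] * 256, 0, 255).astype(np.int64) > t

    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(fg, structure=structure)
    min_px = min_area_um2 / img.pixel_area_um2
    if n:
        sizes = np.bincount(labels.ravel())
        keep = sizes.astype(np.float64) * img.pixel_area_um2 >= min_area_um2
        keep[0] = False
        if lumen_mask is not None and np.any(lumen_mask):
            ring = ndimage.binary_dilation(lumen_mask, structure=morphology.disk(1)) & ~lumen_mask
            touched = np.unique(labels[ring & fg])
            keep[touched[touched > 0]] = True
        fg = keep[labels]
    prov.append(f"area_filter(< {min_area_um2} um^2 = {min_px:g} px removed, conn={connectivity})")
    if fill_hole_px > 0 and np.any(fg):
        fg = morphology.remove_small_holes(fg, max_size=fill_hole_px)
        prov.append(f"fill_holes(<= {fill_hole_px} px)")
    fg &= tissue
    return SegmentationResult(fg, prov)


def _boundary_smoothness(region_mask: np.ndarray) -> float:
    """Perimeter of the filled region divided by the perimeter of a circle
    of equal area (>= 1; 1 = perfectly smooth disc)."""
    area = region_mask.sum()
    if area == 0:
        return float("nan")
    perim = measure.perimeter(region_mask, neighborhood=8)
    circle_perim = 2.0 * np.sqrt(np.pi * area)
    return float(max(perim / circle_perim, 1.0)) if circle_perim > 0 else float("nan")


def detect_lumens(
    tissue: np.ndarray,
    collagen: np.ndarray,
    pixel_pitch_um: float,
    min_lumen_um2: float = DEFAULT_MIN_LUMEN_UM2,
    collar_width_um: float = 4.0,
    neighbor_radius_um: float = 50.0,
) -> tuple[list[LumenObject], np.ndarray]:
    """Detect holes inside tissue as lumens and compute their features.

    A lumen is a connected background region (8-connected) enclosed by
    tissue (not touching the image border) with area >= ``min_lumen_um2``.
    Features: physical area, centroid, eccentricity, boundary smoothness,
    the fraction of a ``collar_width_um`` morphological ring around the
    lumen occupied by collagen, and the number of other lumens with centroid
    within ``neighbor_radius_um``.

    Returns the list of :class:`LumenObject` ordered by centroid (row, col)
    and the lumen label image (0 = not lumen).
    """
    if not np.any(tissue):
        raise ValueError("tissue mask is empty")
    px_area = pixel_pitch_um**2
    filled = ndimage.binary_fill_holes(tissue)
    holes = filled & ~tissue
    labels, n = ndimage.label(holes, structure=ndimage.generate_binary_structure(2, 2))
    out: list[LumenObject] = []
    lumen_img = np.zeros_like(labels)
    if n == 0:
        return out, lumen_img

    collar_px = max(1, int(round(collar_width_um / pixel_pitch_um)))
    selem = morphology.disk(collar_px)
    props = measure.regionprops(labels)
    tmp = []
    for rp in props:
        area_um2 = rp.area * px_area
        if area_um2 < min_lumen_um2:
            continue
        rmin, cmin, rmax, cmax = rp.bbox
        pad = collar_px + 1
        r0, c0 = max(0, rmin - pad), max(0, cmin - pad)
        r1 = min(labels.shape[0], rmax + pad)
        c1 = min(labels.shape[1], cmax + pad)
        sub = labels[r0:r1, c0:c1] == rp.label
        ring = ndimage.binary_dilation(sub, structure=selem) & ~sub
        ring &= tissue[r0:r1, c0:c1] | collagen[r0:r1, c0:c1]
        ring_n = ring.sum()
        collar_frac = (
            float((collagen[r0:r1, c0:c1] & ring).sum()) / ring_n if ring_n else 0.0
        )
        tmp.append(
            (
                rp.centroid,
                LumenObject(
                    label=0,
                    area_um2=float(area_um2),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                    eccentricity=float(rp.eccentricity),
                    collagen_collar_fraction=collar_frac,
                    boundary_smoothness=_boundary_smoothness(rp.image),
                    pixel_labels=rp.label,
                ),
            )
        )
    tmp.sort(key=lambda t: t[0])  # stable (row, col) ordering contract
    centroids = np.array([t[0] for t in tmp]) if tmp else np.empty((0, 2))
    rad_px = neighbor_radius_um / pixel_pitch_um
    for i, (_, lum) in enumerate(tmp):
        lum.label = i + 1
        if len(tmp) > 1:
            d = np.hypot(*(centroids - centroids[i]).T)
            lum.neighbor_lumen_count = int(((d > 0) & (d <= rad_px)).sum())
        lumen_img[labels == lum.pixel_labels] = lum.label
        out.append(lum)
    return out, lumen_img
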