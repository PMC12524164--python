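"""Shared domain containers for the imaging pipeline.

All coordinates are 0-based (row, col); all physical areas are in square
micrometres computed as ``pixel count * pitch**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Integer codes of the zone-map label image.  ``lumen`` covers every hole in
#: the tissue regardless of class; portal/central-vein stromal regions carry
#: their own codes so that the tissue labels partition the tissue mask.
ZONE_LABELS = {
    "background": 0,
    "lumen": 1,
    "portal": 2,
    "periportal": 3,
    "zone2": 4,
    "pericentral": 5,
    "central_vein": 6,
}

ZONE_NAMES = {v: k for k, v in ZONE_LABELS.items()}

#: Zone codes that count as tissue (everything but background and lumen).
TISSUE_ZONE_CODES = (2, 3, 4, 5, 6)


@dataclass
class MultiphotonImage:
    """Registered SHG + TPEF channel pair with physical pixel pitch.

    Parameters
    ----------
    shg : ndarray
        Second-harmonic generation channel (collagen signal), float in [0, 1].
    tpef : ndarray
        Two-photon excitation fluorescence channel (tissue autofluorescence),
        float in [0, 1], same shape as ``shg``.
    pixel_pitch_um : float
        Physical edge length of one pixel in micrometres.
    """

    shg: np.ndarray
    tpef: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        if self.shg.shape != self.tpef.shape:
            raise ValueError(
                f"SHG and TPEF shapes differ: {self.shg.shape} vs {self.tpef.shape}"
            )
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch_um**2

    @property
    def shape(self) -> tuple[int, int]:
        return self.shg.shape

    def save(self, path) -> None:
        """Write as a 2-page grayscale TIFF (page 1 = SHG, page 2 = TPEF)."""
        stack = np.stack(
            [
                np.clip(self.shg * 255, 0, 255).astype(np.uint8),
                np.clip(self.tpef * 255, 0, 255).astype(np.uint8),
            ]
        )
        # resolution tag in pixels per centimetre
        px_per_cm = 1e4 / self.pixel_pitch_um
        tifffile.imwrite(
            path,
            stack,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
            metadata={"pixel_pitch_um": self.pixel_pitch_um, "pages": ["SHG", "TPEF"]},
        )

    @classmethod
    def load(cls, path, pixel_pitch_um: float | None = None) -> "MultiphotonImage":
        """Read a 2-page TIFF written by :meth:`save` (or compatible)."""
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            if pixel_pitch_um is None:
                meta = tf.shaped_metadata or tf.imagej_metadata
                if isinstance(meta, (list, tuple)) and meta:
                    meta = meta[0]
                if meta and "pixel_pitch_um" in meta:
                    pixel_pitch_um = float(meta["pixel_pitch_um"])
        if pixel_pitch_um is None:
            raise ValueError("pixel_pitch_um not stored in TIFF and not given")
        if pages.ndim != 3 or pages.shape[0] < 2:
            raise ValueError("expected a 2-page TIFF (SHG, TPEF)")
        shg = pages[0].astype(np.float64) / 255.0
        tpef = pages[1].astype(np.float64) / 255.0
        return cls(shg=shg, tpef=tpef, pixel_pitch_um=pixel_pitch_um)


@dataclass
class LumenObject:
    """One luminal structure (vessel, bile duct, sinusoid, fissure) detected
    as a hole in the tissue mask."""

    label: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col), 0-based
    eccentricity: float
    collagen_collar_fraction: float
    boundary_smoothness: float
    neighbor_lumen_count: int = 0
    lumen_class: str | None = None  # portal_tract | central_vein | other
    pixel_labels: int | None = None  # label id in the lumen label image


@dataclass
class CollagenString:
    """One connected collagen object with ribbon-model morphometrics.

    ``width_um`` is derived as ``area / length`` (ribbon model).  When the
    skeleton is shorter than the implied width (compact blob), the object is
    reclassified: ``length := sqrt(area)`` so that width <= length holds.
    """

    id: int
    region: str
    area_um2: float
    length_um: float
    width_um: float
    is_thick: bool = False
    is_long: bool = False
    is_aggregated: bool = False
    is_chickenwire: bool = False
    component_label: int = 0


@dataclass
class ZoneMap:
    """Per-pixel lobular zone labels plus the band widths used to build them."""

    labels: np.ndarray  # int array coded by ZONE_LABELS
    periportal_band_um: float
    pericentral_band_um: float
    pixel_pitch_um: float
    lumen_labels: np.ndarray | None = None  # per-lumen label image
    notes: list[str] = field(default_factory=list)

    def zone_mask(self, name: str) -> np.ndarray:
        return self.labels == ZONE_LABELS[name]

    def tissue_mask(self) -> np.ndarray:
        return np.isin(self.labels, TISSUE_ZONE_CODES)

    def zone_area_um2(self, name: str) -> float:
        return float(self.zone_mask(name).sum()) * self.pixel_pitch_um**2

    def save(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint8))
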