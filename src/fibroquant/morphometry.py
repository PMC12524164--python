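"""Collagen string morphometry and the named q-FP table.

Each 8-connected component of the collagen mask is one "string".  Length
is the arc length of its morphological skeleton (straight steps 1 px,
diagonal steps sqrt(2), plus one pixel for the endpoint extent), width is
``area / length`` (ribbon model); a compact blob whose implied width would
exceed its length is reclassified with ``length := sqrt(area)``.  Strings
are assigned to the zone holding the majority of their pixels (a bridging
septum belongs to its majority zone), and thresholded into thin/thick,
short/long and aggregated/distributed classes.

The emitted parameter grid follows the conventional naming:
``<metric><region>`` with metrics ``#Str, #ShortStr, #LongStr, #ThinStr,
#ThickStr, StrArea, StrLength, StrWidth, %Area, %Agg, %Dis`` and regions
``'' (overall), PT, PeriPortal, ChickenWire, Zone2, CV, PeriCentral``,
plus ``%SHG`` (collagen pixel fraction of tissue) — 78 names.  Percentage
metrics for a region use that region's tissue area as denominator
(ChickenWire, an overlay over the perisinusoidal compartment, uses the
combined Zone2 + PeriCentral tissue area).  Count metrics are additionally
emitted as per-mm^2 densities under ``<name>_per_mm2``; density versions
are the size-invariant inputs downstream modelling should use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .datatypes import ZONE_LABELS, CollagenString, ZoneMap

__all__ = [
    "extract_strings",
    "classify_strings",
    "classify_aggregation",
    "compute_qfp_table",
    "QFPTable",
    "QFP_NAMES",
    "QFP_REGIONS",
    "DEFAULT_THRESHOLDS",
]

#: region suffix -> zone-map label name (ChickenWire is a string-level flag).
QFP_REGIONS = {
    "": None,
    "PT": "portal",
    "PeriPortal": "periportal",
    "ChickenWire": None,
    "Zone2": "zone2",
    "CV": "central_vein",
    "PeriCentral": "pericentral",
}

_COUNT_METRICS = ("#Str", "#ShortStr", "#LongStr", "#ThinStr", "#ThickStr")

DEFAULT_THRESHOLDS = {
    "thick_um": 3.0,
    "long_um": 40.0,
    "close_radius_um": 5.0,
    "agg_area_um2": 200.0,
}

# tie-break priority for majority-zone assignment
_REGION_PRIORITY = ("periportal", "portal", "pericentral", "zone2", "central_vein")


def _qfp_names() -> list[str]:
    names = []
    for region in QFP_REGIONS:
        for metric in _COUNT_METRICS:
            names.append(f"{metric}{region}")
        names.append(f"StrArea{region}")
        names.append(f"StrLength{region}")
        names.append(f"StrWidth{region}")
        names.append(f"%{region}" if region else "%Area")
        names.append(f"%{region}Agg" if region else "%Agg")
        names.append(f"%{region}Dis" if region else "%Dis")
    names.append("%SHG")
    return names


#: The 78 canonical q-FP names (11 metrics x 7 regions + %SHG).
QFP_NAMES: tuple[str, ...] = tuple(_qfp_names())


@dataclass
class QFPTable:
    """Named q-FP vector for one specimen plus the configuration used."""

    values: dict
    thresholds: dict
    bands: dict
    region_present: dict
    tissue_area_um2: float

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values)


def _skeleton_lengths(collagen: np.ndarray, comp_labels: np.ndarray, n: int) -> np.ndarray:
    """Per-component skeleton arc length in pixels (index 0 unused)."""
    lengths = np.zeros(n + 1)
    if n == 0 or not collagen.any():
        return lengths
    skel = morphology.skeletonize(collagen)
    sl = np.where(skel, comp_labels, 0)

    def _edge_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        both = (a > 0) & (a == b)
        return np.bincount(a[both], minlength=n + 1)

    straight = _edge_counts(sl[:, 1:], sl[:, :-1]) + _edge_counts(sl[1:, :], sl[:-1, :])
    diag = _edge_counts(sl[1:, 1:], sl[:-1, :-1]) + _edge_counts(sl[1:, :-1], sl[:-1, 1:])
    lengths += straight + math.sqrt(2.0) * diag
    # one pixel for the endpoint extent; guarantees positive length even for
    # a single-pixel skeleton
    has_skel = np.bincount(sl[sl > 0], minlength=n + 1) > 0
    lengths[has_skel] += 1.0
    # components whose skeleton vanished entirely (can happen for tiny blobs)
    lengths[(lengths == 0)] = 1.0
    lengths[0] = 0.0
    return lengths


def extract_strings(
    collagen: np.ndarray,
    zone_map: ZoneMap,
    pixel_pitch_um: float,
) -> tuple[list[CollagenString], np.ndarray]:
    """Decompose the collagen mask into strings with morphometrics.

    Returns the string list and the component label image.  Region = zone
    label holding the majority of the component's pixels; ties resolved by
    the priority periportal > portal > pericentral > zone2 > central vein.
    """
    structure = ndimage.generate_binary_structure(2, 2)
    comp, n = ndimage.label(collagen, structure=structure)
    if n == 0:
        return [], comp
    px_area = pixel_pitch_um**2
    areas_px = np.bincount(comp.ravel(), minlength=n + 1)
    lengths_px = _skeleton_lengths(collagen, comp, n)

    # majority zone per component via a joint (component, zone) histogram
    zcodes = zone_map.labels.astype(np.int64)
    joint = np.bincount((comp.ravel() * 8 + zcodes.ravel()), minlength=(n + 1) * 8)
    joint = joint.reshape(n + 1, 8)
    prio_codes = [ZONE_LABELS[r] for r in _REGION_PRIORITY]
    zone_counts = joint[:, prio_codes]  # columns ordered by priority
    # argmax returns the first (= highest priority) column on ties
    best = np.argmax(zone_counts, axis=1)

    strings: list[CollagenString] = []
    for i in range(1, n + 1):
        area = float(areas_px[i]) * px_area
        length = float(lengths_px[i]) * pixel_pitch_um
        width = area / length
        if width > length:  # compact blob: reclassify
            length = math.sqrt(area)
            width = area / length
        region = _REGION_PRIORITY[best[i]] if zone_counts[i].sum() else "zone2"
        strings.append(
            CollagenString(
                id=i,
                region=region,
                area_um2=area,
                length_um=length,
                width_um=width,
                component_label=i,
            )
        )
    return strings, comp


def classify_strings(
    strings: list[CollagenString],
    thick_um: float = DEFAULT_THRESHOLDS["thick_um"],
    long_um: float = DEFAULT_THRESHOLDS["long_um"],
) -> list[CollagenString]:
    """Set ``is_thick`` (width >= thick_um) and ``is_long`` (length >= long_um)."""
    if thick_um <= 0 or long_um <= 0:
        raise ValueError("thresholds must be positive")
    for s in strings:
        s.is_thick = s.width_um >= thick_um
        s.is_long = s.length_um >= long_um
    return strings


def classify_aggregation(
    strings: list[CollagenString],
    collagen: np.ndarray,
    comp_labels: np.ndarray,
    pixel_pitch_um: float,
    close_radius_um: float = DEFAULT_THRESHOLDS["close_radius_um"],
    agg_area_um2: float = DEFAULT_THRESHOLDS["agg_area_um2"],
) -> list[CollagenString]:
    """Set ``is_aggregated`` from morphological clustering.

    Closing the collagen mask with a disc of ``close_radius_um`` merges
    nearby strings into clusters; a string is aggregated iff the summed
    collagen area of its cluster reaches ``agg_area_um2``.
    """
    if close_radius_um <= 0 or agg_area_um2 <= 0:
        raise ValueError("radii/areas must be positive")
    if not strings:
        return strings
    r_px = max(1, int(round(close_radius_um / pixel_pitch_um)))
    # disk closing via two distance-transform thresholds (dilate then erode)
    dilated = ndimage.distance_transform_edt(~collagen) <= r_px
    closed = ndimage.distance_transform_edt(dilated) > r_px
    closed |= collagen
    clusters, nc = ndimage.label(closed, structure=ndimage.generate_binary_structure(2, 2))
    px_area = pixel_pitch_um**2
    # collagen area per cluster
    cluster_area = np.bincount(clusters[collagen].ravel(), minlength=nc + 1) * px_area
    # cluster id of each component (any pixel will do: take component maxima)
    comp_cluster = ndimage.maximum(clusters, labels=comp_labels,
                                   index=[s.component_label for s in strings])
    for s, cid in zip(strings, np.asarray(comp_cluster, dtype=int)):
        s.is_aggregated = bool(cluster_area[cid] >= agg_area_um2)
    return strings


def compute_qfp_table(
    strings: list[CollagenString],
    zone_map: ZoneMap,
    tissue_area_um2: float | None = None,
    collagen_area_um2: float | None = None,
    thresholds: dict | None = None,
) -> QFPTable:
    """Aggregate strings into the named q-FP vector.

    ``StrLength``/``StrWidth`` are means over the region's strings (0 when
    the region holds none, with ``region_present`` flagging absence);
    ``StrArea`` is the summed string area; percentage metrics are collagen
    area over region tissue area x 100.
    """
    if tissue_area_um2 is None:
        tissue_area_um2 = zone_map.tissue_mask().sum() * zone_map.pixel_pitch_um**2
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive")
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))

    zone2_pc_area = zone_map.zone_area_um2("zone2") + zone_map.zone_area_um2("pericentral")
    values: dict[str, float] = {}
    present: dict[str, bool] = {}
    for region, zone_name in QFP_REGIONS.items():
        if region == "":
            sel = strings
            denom = tissue_area_um2
        elif region == "ChickenWire":
            sel = [s for s in strings if s.is_chickenwire]
            denom = zone2_pc_area
        else:
            sel = [s for s in strings if s.region == zone_name]
            denom = zone_map.zone_area_um2(zone_name)
        present[region] = bool(sel) and denom > 0
        n = len(sel)
        n_long = sum(s.is_long for s in sel)
        n_thick = sum(s.is_thick for s in sel)
        area = sum(s.area_um2 for s in sel)
        agg_area = sum(s.area_um2 for s in sel if s.is_aggregated)
        values[f"#Str{region}"] = n
        values[f"#ShortStr{region}"] = n - n_long
        values[f"#LongStr{region}"] = n_long
        values[f"#ThinStr{region}"] = n - n_thick
        values[f"#ThickStr{region}"] = n_thick
        values[f"StrArea{region}"] = area
        values[f"StrLength{region}"] = (
            sum(s.length_um for s in sel) / n if n else 0.0
        )
        values[f"StrWidth{region}"] = sum(s.width_um for s in sel) / n if n else 0.0
        pct = 100.0 * area / denom if denom > 0 else 0.0
        pct_agg = 100.0 * agg_area / denom if denom > 0 else 0.0
        values[f"%{region}" if region else "%Area"] = pct
        values[f"%{region}Agg" if region else "%Agg"] = pct_agg
        values[f"%{region}Dis" if region else "%Dis"] = pct - pct_agg
        denom_mm2 = denom / 1e6 if denom > 0 else float("nan")
        for metric in _COUNT_METRICS:
            name = f"{metric}{region}"
            values[f"{name}_per_mm2"] = (
                values[name] / denom_mm2 if denom > 0 else 0.0
            )
    if collagen_area_um2 is None:
        collagen_area_um2 = sum(s.area_um2 for s in strings)
    values["%SHG"] = 100.0 * collagen_area_um2 / tissue_area_um2
    return QFPTable(
        values=values,
        thresholds=thresholds,
        bands={
            "periportal_band_um": zone_map.periportal_band_um,
            "pericentral_band_um": zone_map.pericentral_band_um,
        },
        region_present=present,
        tissue_area_um2=float(tissue_area_um2),
    )
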