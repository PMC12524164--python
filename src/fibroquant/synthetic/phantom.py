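"""Stage-conditional SHG/TPEF tissue phantoms with exact ground truth.

A phantom is a wobbly-boundary tissue blob on a dark background carrying
portal tracts (irregular lumen + thick collagen collar + satellite
bile-duct lumens) and central veins (round lumen + sparse thin collar).
Collagen strings are planted per lobular region to a requested areal
density; advanced-stage phantoms add portal-portal bridging septa; the
perisinusoidal compartment receives thin "chicken-wire" strings.  Channel
intensities are well-separated Gaussians so Otsu thresholding recovers the
planted masks essentially exactly — the phantoms benchmark the geometry
pipeline, not the optics (no PSF or photon-noise model).

All randomness flows from one integer seed; the same spec and seed give a
bit-identical phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from ..datatypes import ZONE_LABELS, LumenObject, MultiphotonImage, ZoneMap
from ..zonation import build_zone_map

__all__ = [
    "PlantedString",
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomSizingError",
    "generate_phantom",
    "STAGE_DENSITY_DEFAULTS",
]


class PhantomSizingError(ValueError):
    """Canvas too small to host the requested landmark layout."""


#: Default planted collagen areal density (fraction of region tissue area)
#: per fibrosis stage.  Periportal fibrosis grows monotonically from
#: scattered wisps (F0) to dense septation (F4); perisinusoidal zone-2
#: fibrosis rises into the steatohepatitis range (F1-F2) and partially
#: regresses as architecture collapses into bridging; pericentral density
#: rises slowly.
STAGE_DENSITY_DEFAULTS: dict[int, dict[str, float]] = {
    0: {"periportal": 0.006, "zone2": 0.002, "pericentral": 0.003},
    1: {"periportal": 0.040, "zone2": 0.008, "pericentral": 0.010},
    2: {"periportal": 0.090, "zone2": 0.012, "pericentral": 0.020},
    3: {"periportal": 0.160, "zone2": 0.009, "pericentral": 0.035},
    4: {"periportal": 0.240, "zone2": 0.006, "pericentral": 0.060},
}

#: Parenchymal string geometry per stage: (length_lo, length_hi) um and
#: (width_lo, width_hi) um for periportal/pericentral strings.  Widths and
#: lengths grow with stage (fibre maturation/condensation).
_STAGE_STRING_GEOM = {
    0: ((18.0, 35.0), (1.3, 1.8)),
    1: ((22.0, 45.0), (1.5, 2.2)),
    2: ((28.0, 55.0), (1.8, 2.8)),
    3: ((35.0, 70.0), (2.2, 3.5)),
    4: ((45.0, 90.0), (2.8, 4.5)),
}

#: Thin perisinusoidal strings stay below the thick-string threshold at
#: every stage.
_CHICKENWIRE_GEOM = ((14.0, 28.0), (1.0, 1.7))

#: Portal-tract stromal collar thickness (um) per stage: the portal plate
#: expands as fibrosis progresses.
_COLLAR_WIDTH_UM = {
    0: (2.5, 3.5),
    1: (3.5, 5.0),
    2: (5.0, 7.0),
    3: (7.0, 9.5),
    4: (9.5, 13.0),
}

#: Radial fibrous spurs sprouting from the portal collar: (count per tract,
#: length range um).  Spur number and reach grow with stage.
_SPUR_SPEC = {
    0: (2, (8.0, 16.0)),
    1: (4, (12.0, 24.0)),
    2: (6, (18.0, 34.0)),
    3: (8, (26.0, 46.0)),
    4: (10, (36.0, 60.0)),
}


@dataclass
class PlantedString:
    """Requested rectangular string: nominal geometry in one region."""

    region: str
    length_um: float
    width_um: float


@dataclass
class PlantedStringRecord:
    """One planted string as realised on the pixel grid."""

    region: str
    length_um: float
    width_um: float
    area_um2: float  # nominal length x width
    pixel_area_um2: float  # realised rasterised area
    center_rc: tuple[float, float]
    angle_rad: float


@dataclass
class PhantomSpec:
    """Parameters of one synthetic two-channel phantom.

    ``collagen_density_by_region`` maps region name (``periportal``,
    ``zone2``, ``pericentral``) to an areal fraction in [0, 1]; ``None``
    takes the stage default.  ``bridging=None`` defaults to ``stage >= 3``.
    ``explicit_strings`` are placed exactly (unclipped) before density
    filling — handy for planting known geometries in tests.
    """

    stage: int = 0
    canvas_px: int = 1024
    pixel_pitch_um: float = 0.390625
    n_portal_tracts: int = 2
    n_central_veins: int = 2
    collagen_density_by_region: dict | None = None
    bridging: bool | None = None
    explicit_strings: tuple = ()
    seed: int = 0
    periportal_band_um: float = 100.0
    pericentral_band_um: float = 100.0
    noise_sigma: float = 0.015

    def __post_init__(self) -> None:
        if not 0 <= self.stage <= 4:
            raise ValueError("stage must be 0..4")
        if self.canvas_px <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("canvas_px and pixel_pitch_um must be positive")
        if self.n_portal_tracts < 0 or self.n_central_veins < 0:
            raise ValueError("landmark counts must be non-negative")
        dens = self.resolved_densities()
        for k, v in dens.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"density for {k} outside [0, 1]: {v}")

    def resolved_densities(self) -> dict[str, float]:
        if self.collagen_density_by_region is not None:
            return dict(self.collagen_density_by_region)
        return dict(STAGE_DENSITY_DEFAULTS[self.stage])

    @property
    def canvas_um(self) -> float:
        return self.canvas_px * self.pixel_pitch_um

    def resolved_bridging(self) -> bool:
        return self.stage >= 3 if self.bridging is None else self.bridging


@dataclass
class PhantomGroundTruth:
    """Exact per-pixel and per-object truth of one phantom."""

    tissue_mask: np.ndarray
    collagen_mask: np.ndarray
    zone_map: ZoneMap
    lumen_label_img: np.ndarray
    lumen_classes: dict  # lumen label -> portal_tract | central_vein | other
    string_inventory: list  # PlantedStringRecord
    bridge_mask: np.ndarray
    collar_mask: np.ndarray

    def collagen_fraction_by_region(self) -> dict:
        """Planted parenchymal-string area fraction per region (collars and
        bridges are landmark structures and excluded)."""
        out = {}
        strings = self.collagen_mask & ~self.bridge_mask & ~self.collar_mask
        for region in ("periportal", "zone2", "pericentral"):
            zm = self.zone_map.zone_mask(region)
            area = zm.sum()
            out[region] = float((strings & zm).sum()) / area if area else 0.0
        return out


def _tissue_blob(n: int, rng: np.random.Generator) -> np.ndarray:
    """Wobbly quasi-circular tissue mask covering ~70% of the canvas."""
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    p1, p2 = rng.uniform(0, 2 * math.pi, 2)
    wob = 1.0 + 0.04 * np.sin(3 * theta + p1) + 0.025 * np.sin(5 * theta + p2)
    return r <= 0.485 * n * wob


def _irregular_disc(radius_px: float, rng: np.random.Generator,
                    wobble: float = 0.18, n_lobes: int = 5) -> np.ndarray:
    """Small irregular disc mask (odd-sized window), for portal lumens."""
    rmax = int(math.ceil(radius_px * (1 + wobble))) + 1
    size = 2 * rmax + 1
    yy, xx = np.mgrid[0:size, 0:size] - rmax
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    p = rng.uniform(0, 2 * math.pi)
    edge = radius_px * (1 + wobble * np.sin(n_lobes * theta + p))
    return r <= edge


def _smooth_disc(radius_px: float) -> np.ndarray:
    rmax = int(math.ceil(radius_px)) + 1
    size = 2 * rmax + 1
    yy, xx = np.mgrid[0:size, 0:size] - rmax
    return np.hypot(yy, xx) <= radius_px


def _paste(mask: np.ndarray, stamp: np.ndarray, center_rc: tuple[int, int]) -> None:
    """OR a small stamp into a large mask, clipping at the border."""
    h, w = stamp.shape
    r0 = center_rc[0] - h // 2
    c0 = center_rc[1] - w // 2
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + h, mask.shape[0]), min(c0 + w, mask.shape[1])
    if re <= rs or ce <= cs:
        return
    mask[rs:re, cs:ce] |= stamp[rs - r0 : re - r0, cs - c0 : ce - c0]


def _rect_pixels(center_rc, length_px, width_px, angle, shape):
    """Pixel coordinates of a rotated rectangle clipped to the canvas."""
    dl = np.array([math.cos(angle), math.sin(angle)]) * length_px / 2.0
    dw = np.array([-math.sin(angle), math.cos(angle)]) * width_px / 2.0
    c = np.asarray(center_rc, dtype=float)
    corners = np.array([c - dl - dw, c - dl + dw, c + dl + dw, c + dl - dw])
    rr, cc = skdraw.polygon(corners[:, 0], corners[:, 1], shape=shape)
    return rr, cc


def _place_landmarks(spec: PhantomSpec, tissue: np.ndarray,
                     rng: np.random.Generator) -> list[dict]:
    """Choose landmark centres inside tissue with separation constraints."""
    n_lm = spec.n_portal_tracts + spec.n_central_veins
    if n_lm == 0:
        return []
    pitch = spec.pixel_pitch_um
    margin_um = 35.0
    margin_px = min(int(round(margin_um / pitch)), 60)
    interior = ndimage.distance_transform_edt(tissue) >= margin_px
    cand = np.argwhere(interior)
    if cand.size == 0:
        raise PhantomSizingError("tissue too small for landmark margin")
    min_sep_um = min(120.0, 0.8 * spec.canvas_um / max(1, n_lm))
    min_sep_px = min_sep_um / pitch
    kinds = ["portal_tract"] * spec.n_portal_tracts + ["central_vein"] * spec.n_central_veins
    for _attempt in range(200):
        idx = rng.choice(len(cand), size=n_lm, replace=False) if len(cand) >= n_lm else None
        if idx is None:
            raise PhantomSizingError("not enough interior pixels for landmarks")
        pts = cand[idx].astype(float)
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_sep_px:
            break
        if _attempt >= 100:
            min_sep_px *= 0.95  # relax gradually rather than fail outright
    else:
        raise PhantomSizingError(
            f"cannot place {n_lm} landmarks with {min_sep_um:.0f} um separation "
            f"on a {spec.canvas_um:.0f} um canvas"
        )
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    # keep the kind assignment independent of the sort for variety
    return [{"kind": k, "rc": (int(p[0]), int(p[1]))} for k, p in zip(kinds, pts)]


def _plant_density(
    region_name: str,
    target: float,
    allowed: np.ndarray,
    region_mask: np.ndarray,
    collagen: np.ndarray,
    inventory: list,
    geom: tuple,
    pitch: float,
    rng: np.random.Generator,
) -> None:
    """Plant random strings in ``region_mask`` until the areal density of
    planted pixels reaches ``target``."""
    region_area = int(region_mask.sum())
    if region_area == 0 or target <= 0:
        return
    (l_lo, l_hi), (w_lo, w_hi) = geom
    px_area = pitch**2
    target_px = target * region_area
    planted_px = 0
    cand = np.argwhere(allowed & region_mask)
    if len(cand) == 0:
        return
    min_keep_um2 = 16.0  # never plant fragments the noise filter would eat
    budget = 40 * int(target_px / max((l_lo * w_lo) / px_area, 1)) + 200
    while planted_px < target_px and budget > 0:
        budget -= 1
        center = cand[rng.integers(len(cand))]
        length = rng.uniform(l_lo, l_hi)
        width = rng.uniform(w_lo, w_hi)
        angle = rng.uniform(0, math.pi)
        rr, cc = _rect_pixels(center, length / pitch, width / pitch,
                              angle, region_mask.shape)
        if rr.size == 0:
            continue
        keep = allowed[rr, cc] & region_mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        nominal_px = (length * width) / px_area
        if rr.size < 0.55 * nominal_px or rr.size * px_area < min_keep_um2:
            continue
        new = ~collagen[rr, cc]
        collagen[rr, cc] = True
        planted_px += int(new.sum())
        inventory.append(
            PlantedStringRecord(
                region=region_name,
                length_um=length,
                width_um=width,
                area_um2=length * width,
                pixel_area_um2=rr.size * px_area,
                center_rc=(float(center[0]), float(center[1])),
                angle_rad=angle,
            )
        )


def _draw_bridge(collagen, bridge_mask, p0, p1, width_px, rng, allowed):
    """Slightly curved septum between two landmark centres."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    mid = (p0 + p1) / 2.0
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    norm = np.linalg.norm(normal)
    if norm == 0:
        return
    normal /= norm
    bow = rng.uniform(-0.12, 0.12) * np.linalg.norm(p1 - p0)
    ctrl = mid + bow * normal
    t = np.linspace(0, 1, 200)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1
    stamp = _smooth_disc(width_px / 2.0)
    for rc in pts:
        _paste(bridge_mask, stamp, (int(round(rc[0])), int(round(rc[1]))))
    bridge_mask &= allowed
    collagen |= bridge_mask


def generate_phantom(spec: PhantomSpec) -> tuple[MultiphotonImage, PhantomGroundTruth]:
    """Generate one two-channel phantom and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.canvas_px
    pitch = spec.pixel_pitch_um
    px_area = pitch**2

    tissue = _tissue_blob(n, rng)
    landmarks = _place_landmarks(spec, tissue, rng)

    lumen_mask = np.zeros((n, n), dtype=bool)
    lumen_label_img = np.zeros((n, n), dtype=np.int32)
    lumen_classes: dict[int, str] = {}
    collar_mask = np.zeros((n, n), dtype=bool)
    collagen = np.zeros((n, n), dtype=bool)
    gt_lumens: list[LumenObject] = []
    next_label = 1

    def add_lumen(stamp: np.ndarray, rc, cls: str):
        nonlocal next_label
        local = np.zeros((n, n), dtype=bool)
        _paste(local, stamp, rc)
        local &= tissue
        if not local.any():
            return None
        lumen_mask[local] = True
        lumen_label_img[local] = next_label
        lumen_classes[next_label] = cls
        ys, xs = np.nonzero(local)
        gt_lumens.append(
            LumenObject(
                label=next_label,
                area_um2=float(local.sum()) * px_area,
                centroid=(float(ys.mean()), float(xs.mean())),
                eccentricity=0.0,
                collagen_collar_fraction=0.0,
                boundary_smoothness=1.0,
                lumen_class={"portal_tract": "portal_tract",
                             "central_vein": "central_vein"}.get(cls, "other"),
                pixel_labels=next_label,
            )
        )
        next_label += 1
        return local

    def ring(lumen_local: np.ndarray, width_um: float) -> np.ndarray:
        w_px = max(1, int(round(width_um / pitch)))
        # EDT on a padded bounding box (full-canvas dilation is wasteful)
        rs, cs = np.nonzero(lumen_local)
        pad = w_px + 2
        r0, r1 = max(rs.min() - pad, 0), min(rs.max() + pad + 1, n)
        c0, c1 = max(cs.min() - pad, 0), min(cs.max() + pad + 1, n)
        sub = lumen_local[r0:r1, c0:c1]
        near = ndimage.distance_transform_edt(~sub) <= w_px
        out = np.zeros((n, n), dtype=bool)
        out[r0:r1, c0:c1] = near & ~sub
        return out

    collar_lo, collar_hi = _COLLAR_WIDTH_UM[spec.stage]
    n_spurs, spur_len = _SPUR_SPEC[spec.stage]
    for lm in landmarks:
        rc = lm["rc"]
        if lm["kind"] == "portal_tract":
            r_um = rng.uniform(10.0, 16.0)
            stamp = _irregular_disc(r_um / pitch, rng, wobble=0.25)
            local = add_lumen(stamp, rc, "portal_tract")
            if local is None:
                continue
            collar_w = rng.uniform(collar_lo, collar_hi)
            collar = ring(local, collar_w) & tissue
            collar_mask |= collar
            # radial fibrous spurs from the portal plate into the parenchyma
            for _ in range(n_spurs):
                ang = rng.uniform(0, 2 * math.pi)
                slen = rng.uniform(*spur_len)
                swid = rng.uniform(2.5, 4.0)
                start = (r_um + collar_w) / pitch
                mid_d = start + slen / (2 * pitch)
                mid = (rc[0] + mid_d * math.sin(ang), rc[1] + mid_d * math.cos(ang))
                # rectangle long axis along the radial direction (sin, cos)
                rr, cc = _rect_pixels(mid, slen / pitch + 3, swid / pitch,
                                      math.pi / 2 - ang, (n, n))
                if rr.size:
                    keep = tissue[rr, cc] & ~lumen_mask[rr, cc]
                    collar_mask[rr[keep], cc[keep]] = True
            # satellite bile-duct lumens inside the portal stroma
            for _ in range(rng.integers(1, 3)):
                ang = rng.uniform(0, 2 * math.pi)
                d_px = (r_um + rng.uniform(10.0, 18.0)) / pitch
                src = (int(rc[0] + d_px * math.sin(ang)), int(rc[1] + d_px * math.cos(ang)))
                sat_r = rng.uniform(6.0, 7.0) / pitch
                sat = add_lumen(_smooth_disc(sat_r), src, "other")
                if sat is not None:
                    collar_mask |= ring(sat, 1.5) & tissue
        else:
            r_um = rng.uniform(10.0, 16.0)
            local = add_lumen(_smooth_disc(r_um / pitch), rc, "central_vein")
            if local is None:
                continue
            # sparse perivenular collagen: thin partial arcs only, so the
            # collar fraction stays far below the portal tract's
            full = ring(local, 1.2) & tissue
            ys, xs = np.nonzero(full)
            if ys.size:
                ang0 = np.arctan2(ys - rc[0], xs - rc[1])
                a_start = rng.uniform(-math.pi, math.pi)
                span = math.radians(100.0)
                rel = np.mod(ang0 - a_start, 2 * math.pi)
                keep = rel <= span
                collar_mask[ys[keep], xs[keep]] = True
    collar_mask &= ~lumen_mask
    collagen |= collar_mask

    # ground-truth zone map from the true landmark classes
    zone_map = build_zone_map(
        tissue & ~lumen_mask,
        collagen,
        gt_lumens,
        lumen_label_img,
        pitch,
        periportal_band_um=spec.periportal_band_um,
        pericentral_band_um=spec.pericentral_band_um,
    )

    # region where parenchymal strings may go: tissue, away from lumens and
    # from the landmark cores (3 um buffer keeps planted strings from being
    # absorbed into the portal/central stroma by the pipeline)
    core = zone_map.zone_mask("portal") | zone_map.zone_mask("central_vein")
    buffer_px = max(1, int(round(3.0 / pitch)))

    # bridging septa go in before parenchymal strings so the strings keep a
    # clearance from them (otherwise the pipeline would absorb touching
    # strings into the landmark-attached stroma)
    bridge_mask = np.zeros((n, n), dtype=bool)
    if spec.resolved_bridging():
        portal_rcs = [lm["rc"] for lm in landmarks if lm["kind"] == "portal_tract"]
        other_rcs = [lm["rc"] for lm in landmarks if lm["kind"] == "central_vein"]
        pairs = []
        if len(portal_rcs) >= 2:
            pairs.append((portal_rcs[0], portal_rcs[1]))
        if spec.stage >= 4 and portal_rcs and other_rcs:
            pairs.append((portal_rcs[0], other_rcs[0]))
        width_um = rng.uniform(5.0, 9.0) if spec.stage < 4 else rng.uniform(8.0, 14.0)
        for p0, p1 in pairs:
            _draw_bridge(collagen, bridge_mask, p0, p1, width_um / pitch,
                         rng, tissue & ~lumen_mask)

    blocked = (
        ndimage.distance_transform_edt(~(core | lumen_mask | bridge_mask)) <= buffer_px
    )
    allowed = tissue & ~blocked

    inventory: list[PlantedStringRecord] = []

    # explicit strings first: exact, unclipped placement
    for req in spec.explicit_strings:
        region_mask = zone_map.zone_mask(req.region)
        placed = False
        for _ in range(500):
            cand = np.argwhere(allowed & region_mask)
            if len(cand) == 0:
                break
            center = cand[rng.integers(len(cand))]
            angle = rng.uniform(0, math.pi)
            rr, cc = _rect_pixels(center, req.length_um / pitch,
                                  req.width_um / pitch, angle, (n, n))
            nominal_px = (req.length_um * req.width_um) / px_area
            if rr.size and np.all(allowed[rr, cc] & region_mask[rr, cc]) and rr.size >= 0.9 * nominal_px:
                collagen[rr, cc] = True
                inventory.append(
                    PlantedStringRecord(
                        region=req.region,
                        length_um=req.length_um,
                        width_um=req.width_um,
                        area_um2=req.length_um * req.width_um,
                        pixel_area_um2=rr.size * px_area,
                        center_rc=(float(center[0]), float(center[1])),
                        angle_rad=angle,
                    )
                )
                placed = True
                break
        if not placed:
            raise PhantomSizingError(
                f"could not place explicit {req.length_um}x{req.width_um} um "
                f"string in region {req.region!r}"
            )

    densities = spec.resolved_densities()
    geom = _STAGE_STRING_GEOM[spec.stage]
    for region in ("periportal", "pericentral"):
        _plant_density(region, densities.get(region, 0.0), allowed,
                       zone_map.zone_mask(region), collagen, inventory,
                       geom, pitch, rng)
    _plant_density("zone2", densities.get("zone2", 0.0), allowed,
                   zone_map.zone_mask("zone2"), collagen, inventory,
                   _CHICKENWIRE_GEOM, pitch, rng)

    # ---- render channels -------------------------------------------------
    sigma = spec.noise_sigma
    tpef = np.full((n, n), 0.04)
    tpef[tissue] = 0.55
    tpef[lumen_mask] = 0.04
    tpef = tpef + rng.normal(0.0, sigma, (n, n))
    # collagen is dim on TPEF (autofluorescence comes from hepatocytes)
    tpef[collagen] *= 0.8

    shg = np.full((n, n), 0.04)
    shg[collagen] = 0.72
    shg = shg + rng.normal(0.0, sigma, (n, n))
    shg[collagen] += rng.normal(0.0, 0.04, int(collagen.sum()))

    img = MultiphotonImage(
        shg=np.clip(shg, 0.0, 1.0),
        tpef=np.clip(tpef, 0.0, 1.0),
        pixel_pitch_um=pitch,
    )
    gt = PhantomGroundTruth(
        tissue_mask=tissue & ~lumen_mask,
        collagen_mask=collagen,
        zone_map=zone_map,
        lumen_label_img=lumen_label_img,
        lumen_classes=lumen_classes,
        string_inventory=inventory,
        bridge_mask=bridge_mask,
        collar_mask=collar_mask,
    )
    return img, gt
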