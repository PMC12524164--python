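"""Morphometry tests: string extraction, classification, q-FP table."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from fibroquant.datatypes import ZONE_LABELS, ZoneMap
from fibroquant.morphometry import (
    QFP_NAMES,
    classify_aggregation,
    classify_strings,
    compute_qfp_table,
    extract_strings,
)

PITCH = 0.390625

# frozen reference: skeleton arc length of a 128 x 4 px rectangle computed
# with the reference skeletonization (125 skeleton px, 124 straight steps)
RECT_128x4_LENGTH_UM = 48.99
RECT_128x4_AREA_UM2 = 78.125


def _uniform_zone_map(shape, zone="zone2", pitch=PITCH):
    labels = np.full(shape, ZONE_LABELS[zone], dtype=np.uint8)
    return ZoneMap(labels=labels, periportal_band_um=100.0,
                   pericentral_band_um=100.0, pixel_pitch_um=pitch)


def test_extract_empty_mask():
    zm = _uniform_zone_map((64, 64))
    strings, comp = extract_strings(np.zeros((64, 64), bool), zm, PITCH)
    assert strings == [] and comp.max() == 0


def test_extract_two_components_two_strings():
    mask = np.zeros((64, 64), bool)
    mask[10:12, 5:30] = True
    mask[40:42, 5:30] = True
    zm = _uniform_zone_map((64, 64))
    strings, _ = extract_strings(mask, zm, PITCH)
    assert len(strings) == 2


def test_extract_rectangle_matches_frozen_skeleton_oracle():
    mask = np.zeros((40, 160), bool)
    mask[18:22, 10:138] = True  # 128 x 4 px
    zm = _uniform_zone_map((40, 160))
    strings, _ = extract_strings(mask, zm, PITCH)
    (s,) = strings
    assert s.area_um2 == pytest.approx(RECT_128x4_AREA_UM2)
    assert s.length_um == pytest.approx(RECT_128x4_LENGTH_UM, rel=0.10)
    assert s.width_um == pytest.approx(s.area_um2 / s.length_um)


def test_blob_reclassified_width_le_length():
    mask = np.zeros((64, 64), bool)
    mask[20:40, 20:40] = True  # compact square blob
    zm = _uniform_zone_map((64, 64))
    strings, _ = extract_strings(mask, zm, PITCH)
    (s,) = strings
    assert s.width_um <= s.length_um
    assert s.length_um == pytest.approx(np.sqrt(s.area_um2))


def test_majority_region_assignment_with_priority_tiebreak():
    labels = np.full((64, 64), ZONE_LABELS["zone2"], dtype=np.uint8)
    labels[:, :32] = ZONE_LABELS["periportal"]
    zm = ZoneMap(labels=labels, periportal_band_um=100, pericentral_band_um=100,
                 pixel_pitch_um=PITCH)
    mask = np.zeros((64, 64), bool)
    mask[10:12, 28:36] = True  # exactly half in each zone -> tie -> periportal
    strings, _ = extract_strings(mask, zm, PITCH)
    assert strings[0].region == "periportal"
    mask2 = np.zeros((64, 64), bool)
    mask2[10:12, 30:40] = True  # majority zone2
    strings2, _ = extract_strings(mask2, zm, PITCH)
    assert strings2[0].region == "zone2"


def test_classify_threshold_boundary_closed_lower_bound():
    mask = np.zeros((32, 128), bool)
    mask[10:18, 10:110] = True  # 100 x 8 px ribbon
    zm = _uniform_zone_map((32, 128))
    strings, _ = extract_strings(mask, zm, PITCH)
    (s,) = strings
    classify_strings(strings, thick_um=s.width_um, long_um=s.length_um)
    assert s.is_thick and s.is_long  # exact threshold counts as thick/long
    classify_strings(strings, thick_um=s.width_um + 1e-9, long_um=s.length_um + 1e-9)
    assert not s.is_thick and not s.is_long


def test_classification_partitions_on_random_masks():
    """thin+thick = all and short+long = all for every region, exactly."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        mask = np.zeros((128, 128), bool)
        for _k in range(rng.integers(1, 12)):
            r, c = rng.integers(5, 110, 2)
            mask[r : r + rng.integers(2, 8), c : c + rng.integers(5, 18)] = True
        labels = np.full((128, 128), ZONE_LABELS["zone2"], dtype=np.uint8)
        labels[:, :64] = ZONE_LABELS["periportal"]
        zm = ZoneMap(labels=labels, periportal_band_um=100,
                     pericentral_band_um=100, pixel_pitch_um=PITCH)
        strings, comp = extract_strings(mask, zm, PITCH)
        classify_strings(strings)
        classify_aggregation(strings, mask, comp, PITCH)
        table = compute_qfp_table(strings, zm)
        for region in ("", "PT", "PeriPortal", "Zone2", "CV", "PeriCentral", "ChickenWire"):
            n = table[f"#Str{region}"]
            assert table[f"#ThinStr{region}"] + table[f"#ThickStr{region}"] == n
            assert table[f"#ShortStr{region}"] + table[f"#LongStr{region}"] == n
            assert table[f"%{region}Agg" if region else "%Agg"] + table[
                f"%{region}Dis" if region else "%Dis"
            ] == pytest.approx(table[f"%{region}" if region else "%Area"])


def test_scale_equivariance_of_pitch():
    mask = np.zeros((64, 200), bool)
    mask[30:34, 20:180] = True
    zm1 = _uniform_zone_map((64, 200), pitch=PITCH)
    zm2 = _uniform_zone_map((64, 200), pitch=2 * PITCH)
    (s1,), _ = extract_strings(mask, zm1, PITCH)
    (s2,), _ = extract_strings(mask, zm2, 2 * PITCH)
    assert s2.length_um == pytest.approx(2 * s1.length_um)
    assert s2.area_um2 == pytest.approx(4 * s1.area_um2)


def test_aggregation_cluster_rule():
    mask = np.zeros((256, 256), bool)
    # dense bundle: three long ribbons 2 um apart -> one cluster, large area
    for k in range(3):
        mask[50 + 7 * k : 54 + 7 * k, 20:220] = True
    # one tiny isolated string far away
    mask[200:202, 20:40] = True
    zm = _uniform_zone_map((256, 256))
    strings, comp = extract_strings(mask, zm, PITCH)
    classify_aggregation(strings, mask, comp, PITCH,
                         close_radius_um=5.0, agg_area_um2=200.0)
    big = [s for s in strings if s.area_um2 > 50]
    small = [s for s in strings if s.area_um2 <= 50]
    assert all(s.is_aggregated for s in big)
    assert all(not s.is_aggregated for s in small)


def test_qfp_table_empty_collagen():
    zm = _uniform_zone_map((64, 64))
    table = compute_qfp_table([], zm)
    assert table["#Str"] == 0 and table["%SHG"] == 0.0
    assert table["StrLength"] == 0.0 and table["StrWidth"] == 0.0
    assert not table.region_present[""]


def test_qfp_names_complete_grid():
    assert len(QFP_NAMES) == 78  # 11 metrics x 7 regions + %SHG
    assert "%SHG" in QFP_NAMES and "StrWidthPT" in QFP_NAMES
    assert "#ShortStrZone2" in QFP_NAMES and "%PeriPortalAgg" in QFP_NAMES
    zm = _uniform_zone_map((64, 64))
    table = compute_qfp_table([], zm)
    for name in QFP_NAMES:
        assert name in table.values


def test_qfp_shg_fraction_matches_planted(pipeline_config, landmark_model):
    from fibroquant.pipeline import process_image
    from fibroquant.synthetic import PhantomSpec, generate_phantom

    img, gt = generate_phantom(PhantomSpec(stage=2, canvas_px=512, seed=31))
    table, _ = process_image(img, landmark_model, pipeline_config)
    planted_pct = 100.0 * gt.collagen_mask.sum() / gt.tissue_mask.sum()
    assert table["%SHG"] == pytest.approx(planted_pct, abs=0.5)


def test_roundtrip_collagen_jaccard(pipeline_config):
    """Segmentation recovers planted collagen nearly exactly at default noise."""
    from fibroquant.segmentation import segment_collagen, segment_tissue
    from fibroquant.synthetic import PhantomSpec, generate_phantom

    for stage, seed in ((0, 41), (2, 42), (4, 43)):
        img, gt = generate_phantom(PhantomSpec(stage=stage, canvas_px=512, seed=seed))
        tissue = segment_tissue(img, min_area_mm2=0.02).mask
        mask = segment_collagen(img, tissue).mask
        inter = (mask & gt.collagen_mask).sum()
        union = (mask | gt.collagen_mask).sum()
        assert inter / union >= 0.95
        assert inter / gt.collagen_mask.sum() >= 0.99  # pixel recall


def test_monotone_fibrosis_response(staged_run):
    """Top periportal/portal parameters rise monotonically with stage."""
    qfp, stages = staged_run
    for name in ("StrWidthPT", "StrLengthPT", "%PeriPortal"):
        rho = spearmanr(qfp[name], stages).statistic
        assert rho >= 0.9, name
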