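"""End-to-end orchestration: simulate -> segment -> zonate -> quantify ->
fit/score -> evaluate, as one reproducible, seeded run.

The module-level helpers (``process_image``, ``train_landmark_model_from_phantoms``,
``staged_phantom_study``) are the building blocks; :func:`run_pipeline`
wires them into a run directory with JSON/CSV artifacts and a summary
report.  One top-level seed is fanned out to every stochastic stage via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import nit_scores
from .datatypes import MultiphotonImage
from .morphometry import (
    DEFAULT_THRESHOLDS,
    classify_aggregation,
    classify_strings,
    compute_qfp_table,
    extract_strings,
)
from .qfibrosis import QFibrosisModel
from .segmentation import detect_lumens, segment_collagen, segment_tissue
from .synthetic import CohortSpec, PhantomSpec, generate_phantom
from .zonation import (
    LandmarkModel,
    assign_chickenwire,
    build_zone_map,
    classify_lumens,
    lumen_feature_vector,
    train_landmark_classifier,
)

logger = logging.getLogger("fibroquant")

__all__ = [
    "RunConfig",
    "process_image",
    "train_landmark_model_from_phantoms",
    "staged_phantom_study",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 0
    canvas_px: int = 512
    pixel_pitch_um: float = 0.390625
    min_tissue_area_mm2: float = 0.02
    min_lumen_um2: float = 100.0
    periportal_band_um: float = 100.0
    pericentral_band_um: float = 100.0
    attach_dist_um: float = 10.0
    thick_um: float = DEFAULT_THRESHOLDS["thick_um"]
    long_um: float = DEFAULT_THRESHOLDS["long_um"]
    close_radius_um: float = DEFAULT_THRESHOLDS["close_radius_um"]
    agg_area_um2: float = DEFAULT_THRESHOLDS["agg_area_um2"]
    landmark_max_depth: int = 4
    n_training_phantoms: int = 6
    n_per_stage: int = 5
    k_max: int = 17
    cv_folds: int = 5
    n_boot: int = 200
    nit_config: dict = field(default_factory=dict)
    version: str = "1"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def process_image(
    img: MultiphotonImage,
    landmark_model: LandmarkModel | None,
    config: RunConfig,
):
    """Run segmentation -> zonation -> morphometry on one image.

    Returns ``(qfp_table, intermediates)`` where intermediates carries the
    masks, lumens, zone map and strings for QC.  With ``landmark_model``
    None, lumens stay unclassified and the parenchyma is zone 2.
    """
    tissue_res = segment_tissue(img, min_area_mm2=config.min_tissue_area_mm2)
    tissue = tissue_res.mask
    if not tissue.any():
        raise ValueError("no tissue component passed the area filter")
    lumens, lumen_img = detect_lumens(
        tissue, np.zeros_like(tissue), img.pixel_pitch_um,
        min_lumen_um2=config.min_lumen_um2,
    )
    collagen_res = segment_collagen(img, tissue, lumen_mask=lumen_img > 0)
    collagen = collagen_res.mask
    # collar features need the collagen mask: recompute lumen features
    lumens, lumen_img = detect_lumens(
        tissue, collagen, img.pixel_pitch_um, min_lumen_um2=config.min_lumen_um2
    )
    if landmark_model is not None:
        classify_lumens(landmark_model, lumens)
    zone_map = build_zone_map(
        tissue, collagen, lumens, lumen_img, img.pixel_pitch_um,
        periportal_band_um=config.periportal_band_um,
        pericentral_band_um=config.pericentral_band_um,
    )
    strings, comp = extract_strings(collagen, zone_map, img.pixel_pitch_um)
    classify_strings(strings, thick_um=config.thick_um, long_um=config.long_um)
    classify_aggregation(
        strings, collagen, comp, img.pixel_pitch_um,
        close_radius_um=config.close_radius_um, agg_area_um2=config.agg_area_um2,
    )
    assign_chickenwire(
        strings, collagen, comp, zone_map,
        attach_dist_um=config.attach_dist_um, thick_um=config.thick_um,
    )
    table = compute_qfp_table(
        strings, zone_map,
        thresholds={
            "thick_um": config.thick_um,
            "long_um": config.long_um,
            "close_radius_um": config.close_radius_um,
            "agg_area_um2": config.agg_area_um2,
        },
    )
    inter = {
        "tissue": tissue,
        "collagen": collagen,
        "lumens": lumens,
        "lumen_img": lumen_img,
        "zone_map": zone_map,
        "strings": strings,
        "components": comp,
        "provenance": tissue_res.provenance + collagen_res.provenance,
    }
    return table, inter


def _phantom_lumen_training_data(img, gt, config: RunConfig):
    """Pipeline-detected lumen features labelled by phantom ground truth."""
    tissue = segment_tissue(img, min_area_mm2=config.min_tissue_area_mm2).mask
    if not tissue.any():
        return np.empty((0, 5)), []
    collagen = segment_collagen(img, tissue).mask
    lumens, lumen_img = detect_lumens(
        tissue, collagen, img.pixel_pitch_um, min_lumen_um2=config.min_lumen_um2
    )
    X, y = [], []
    for lum in lumens:
        pix = lumen_img == lum.label
        gt_labels = gt.lumen_label_img[pix]
        gt_labels = gt_labels[gt_labels > 0]
        if gt_labels.size == 0:
            cls = "other"
        else:
            maj = np.bincount(gt_labels).argmax()
            cls = gt.lumen_classes.get(int(maj), "other")
        X.append(lumen_feature_vector(lum))
        y.append(cls)
    return (np.vstack(X) if X else np.empty((0, 5))), y


def train_landmark_model_from_phantoms(
    config: RunConfig, seed: int, n_phantoms: int | None = None
) -> LandmarkModel:
    """Train the CART landmark classifier on ground-truth-labelled lumens
    detected in freshly generated phantoms (mixed stages)."""
    n_phantoms = n_phantoms or config.n_training_phantoms
    seeds = np.random.SeedSequence(seed).generate_state(n_phantoms)
    Xs, ys = [], []
    for i in range(n_phantoms):
        spec = PhantomSpec(
            stage=i % 5,
            canvas_px=config.canvas_px,
            pixel_pitch_um=config.pixel_pitch_um,
            seed=int(seeds[i] % (2**31)),
        )
        img, gt = generate_phantom(spec)
        X, y = _phantom_lumen_training_data(img, gt, config)
        if len(y):
            Xs.append(X)
            ys.extend(y)
    X = np.vstack(Xs)
    return train_landmark_classifier(X, ys, max_depth=config.landmark_max_depth, seed=seed)


def staged_phantom_study(
    config: RunConfig,
    n_per_stage: int | None = None,
    seed: int | None = None,
    landmark_model: LandmarkModel | None = None,
    progress: bool = False,
):
    """Generate and process ``n_per_stage`` phantoms per stage F0-F4.

    Returns ``(qfp_frame, stages)``: a DataFrame of q-FP vectors (one row
    per phantom) and the matching true-stage array.
    """
    n_per_stage = n_per_stage or config.n_per_stage
    seed = config.seed if seed is None else seed
    if landmark_model is None:
        landmark_model = train_landmark_model_from_phantoms(config, seed + 1)
    child = np.random.SeedSequence(seed).generate_state(5 * n_per_stage)
    rows, stages = [], []
    k = 0
    for stage in range(5):
        for _ in range(n_per_stage):
            spec = PhantomSpec(
                stage=stage,
                canvas_px=config.canvas_px,
                pixel_pitch_um=config.pixel_pitch_um,
                seed=int(child[k] % (2**31)),
            )
            k += 1
            img, _ = generate_phantom(spec)
            table, _ = process_image(img, landmark_model, config)
            rows.append(table.values)
            stages.append(stage)
            if progress and k % 25 == 0:
                logger.info("processed %d phantoms", k)
    return pd.DataFrame(rows), np.asarray(stages)


#: q-FP features offered to the qFibrosis selection step: size-invariant
#: densities, mean geometries and percentages (raw counts are excluded so a
#: fitted model transfers across tissue sizes).
def modelling_features(qfp: pd.DataFrame) -> pd.DataFrame:
    keep = [
        c
        for c in qfp.columns
        if c.endswith("_per_mm2")
        or c.startswith(("StrLength", "StrWidth"))
        or c.startswith("%")
    ]
    return qfp[keep]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Full reproducible run; writes artifacts under ``out_dir``.

    Stages: landmark training, staged phantom study, qFibrosis fit and
    scoring, synthetic cohort + NIT panels, diagnostic evaluation.  Returns
    the summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()
    timings = {}

    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)

    t = time.time()
    landmark_model = train_landmark_model_from_phantoms(config, int(seeds[0]))
    timings["train_landmarks"] = time.time() - t

    t = time.time()
    qfp, stages = staged_phantom_study(
        config, seed=int(seeds[1]), landmark_model=landmark_model
    )
    qfp.to_csv(out / "qfp_tables.csv", index=False)
    timings["phantom_study"] = time.time() - t

    t = time.time()
    model = QFibrosisModel(
        modelling_features(qfp), stages,
        k_max=config.k_max, cv_folds=config.cv_folds, seed=int(seeds[2]),
    )
    res = model.fit()
    qf_values = res.fittedvalues.to_numpy()
    (out / "qf_model.json").write_text(json.dumps(res.to_json_dict(), indent=2))
    pd.DataFrame({"stage": stages, "qF": qf_values}).to_csv(
        out / "qf_scores.csv", index=False
    )
    timings["fit_qf"] = time.time() - t

    t = time.time()
    cohort = _make_cohort(config, int(seeds[3]))
    panels = nit_scores.compute_panel_frame(cohort, config.nit_config)
    scored = pd.concat([cohort, panels.drop(columns=["MRE_LSM", "VCTE_LSM"])], axis=1)
    scored.to_csv(out / "cohort_scored.csv", index=False)
    timings["cohort"] = time.time() - t

    t = time.time()
    comparisons = {
        "F0_vs_F1-4": scored["stage"] >= 1,
        "F0-1_vs_F2-4": scored["stage"] >= 2,
        "F0-2_vs_F3-4": scored["stage"] >= 3,
        "F0-3_vs_F4": scored["stage"] >= 4,
    }
    score_cols = ["qF", "MRE_LSM", "VCTE_LSM", "MAST", "FAST", "FIB4", "APRI", "AAR", "NFS"]
    rows = []
    for comp_name, labels in comparisons.items():
        y = labels.astype(int).to_numpy()
        if y.min() == y.max():
            continue
        for col in score_cols:
            s = scored[col].to_numpy(dtype=float)
            ok = np.isfinite(s)
            if y[ok].min() == y[ok].max():
                continue
            result = dx.evaluate_score(
                s[ok], y[ok], comparison=comp_name,
                n_boot=config.n_boot, seed=int(seeds[4]),
            )
            for r in result.to_rows():
                r["score"] = col
                rows.append(r)
    auc_table = pd.DataFrame(rows)
    auc_table.to_csv(out / "diagnostics.csv", index=False)
    timings["diagnostics"] = time.time() - t

    t = time.time()
    sig = modelling_features(qfp)
    keep = [c for c in sig.columns if sig[c].std() > 0][:20]
    imp = dx.rf_importance(qfp[keep], stages, n_trees=100, seed=int(seeds[5]))
    imp.to_csv(out / "rf_importance.csv", index=False)
    timings["importance"] = time.time() - t

    # report figures: qF distribution, ROC overlay, q-FP vs NIT heatmap.
    # Cohort patients have no images, so each is paired with a q-FP row
    # sampled from the phantoms of the same stage (synthetic pairing).
    t = time.time()
    from .plotting import plot_correlation_heatmap, plot_qf_by_stage, plot_roc_curves

    plot_qf_by_stage(qf_values, stages, out / "qf_by_stage.png")
    y34 = (scored["stage"] >= 3).astype(int).to_numpy()
    if y34.min() != y34.max():
        plot_roc_curves(
            {c: scored[c] for c in score_cols if c in scored},
            y34, out / "roc_f0-2_vs_f3-4.png", title="F0-2 vs F3-4",
        )
    rng_pair = np.random.default_rng(int(seeds[6]))
    rows = []
    for s in scored["stage"]:
        pool = np.flatnonzero(stages == s)
        rows.append(qfp.iloc[rng_pair.choice(pool)])
    qfp_per_patient = pd.DataFrame(rows).reset_index(drop=True)
    rank = sig.corrwith(pd.Series(stages, index=sig.index), method="spearman").abs()
    top_qfp = rank.sort_values(ascending=False).head(12).index.tolist()
    corr = dx.spearman_matrix(
        qfp_per_patient[top_qfp],
        scored[["MRE_LSM", "VCTE_LSM", "MAST", "FAST", "FIB4", "APRI", "AAR", "NFS"]],
    )
    corr["rho"].to_csv(out / "qfp_nit_spearman.csv")
    plot_correlation_heatmap(corr["rho"], out / "qfp_nit_heatmap.png")
    timings["report_figures"] = time.time() - t

    stage_medians = {
        f"F{s}": float(np.median(qf_values[stages == s])) for s in range(5)
    }
    rho = float(pd.Series(qf_values).corr(pd.Series(stages), method="spearman"))
    summary = {
        "config_seed": config.seed,
        "n_phantoms": int(len(stages)),
        "qf_median_by_stage": stage_medians,
        "spearman_qf_stage": rho,
        "selected_features": res.selected_features,
        "cohort_n": int(len(scored)),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _make_cohort(config: RunConfig, seed: int) -> pd.DataFrame:
    from .synthetic import generate_cohort

    return generate_cohort(CohortSpec(seed=seed))
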