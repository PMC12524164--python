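"""Non-invasive fibrosis score calculators.

Implements the six composite serum/imaging scores used alongside
elastography in MASLD fibrosis work-up: APRI, AAR, FIB-4, NFS, FAST and
MAST.  MRE-LSM and VCTE-LSM are measured quantities and pass through
unchanged.

Two of the published formula families circulate in slightly different
printed forms, so each ambiguous score takes a ``variant`` switch:

* ``fib4``: the established form divides by sqrt(ALT) (``"standard"``,
  default); ``"as_printed"`` divides by ALT.
* ``nfs``: the established form multiplies the 1.13 coefficient by a binary
  impaired-fasting-glycaemia/diabetes indicator (``"indicator"``, default);
  ``"as_printed"`` multiplies by glucose in mmol/L.
* ``fast`` / ``mast``: the linear predictors are mapped through a logistic
  by default (their published ranges are probabilities in (0, 1)); pass
  ``logistic=False`` for the raw linear predictor.  MAST uses base-10 logs.

Albumin is accepted in g/dL; cohort files that store g/L (the common lab
convention) should be divided by 10 at ingest — :func:`compute_panel` does
this when the column is named ``ALB_gL``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "apri",
    "aar",
    "fib4",
    "nfs",
    "fast",
    "mast",
    "compute_panel",
    "NITPanel",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")


def apri(ast: float, ast_uln: float = 40.0, platelets: float = None) -> float:
    """AST-to-platelet ratio index: ``(AST/AST_ULN) * 100 / platelets``.

    ``platelets`` in 10^9/L, ``ast`` and ``ast_uln`` in U/L.
    """
    if platelets is None:
        raise ValueError("platelets is required")
    _require_positive(ast_uln=ast_uln, platelets=platelets)
    return (ast / ast_uln) * 100.0 / platelets


def aar(ast: float, alt: float) -> float:
    """AST-to-ALT ratio."""
    _require_positive(alt=alt)
    return ast / alt


def fib4(
    age: float,
    ast: float,
    alt: float,
    platelets: float,
    variant: str = "standard",
) -> float:
    """Fibrosis-4 index.

    ``"standard"``: age * AST / (platelets * sqrt(ALT));
    ``"as_printed"``: age * AST / (platelets * ALT).
    """
    _require_positive(alt=alt, platelets=platelets)
    if variant == "standard":
        return age * ast / (platelets * math.sqrt(alt))
    if variant == "as_printed":
        return age * ast / (platelets * alt)
    raise ValueError(f"unknown fib4 variant {variant!r}")


def nfs(
    age: float,
    bmi: float,
    glucose_or_flag: float,
    ast: float,
    alt: float,
    platelets: float,
    albumin_gdl: float,
    variant: str = "indicator",
) -> float:
    """NAFLD fibrosis score.

    ``-1.675 + 0.037*age + 0.094*BMI + 1.13*G + 0.99*AST/ALT
    - 0.013*platelets - 0.66*albumin``, where G is the binary
    hyperglycaemia indicator (``"indicator"``, default) or glucose in
    mmol/L (``"as_printed"``).
    """
    _require_positive(alt=alt)
    if variant == "indicator":
        g = glucose_or_flag
        if g is None or (isinstance(g, float) and math.isnan(g)):
            raise ValueError("hyperglycemia flag required under indicator variant")
        g = float(bool(g)) if g in (0, 1, True, False) else float(g)
        if g not in (0.0, 1.0):
            raise ValueError("indicator variant expects a binary flag")
    elif variant == "as_printed":
        g = float(glucose_or_flag)
    else:
        raise ValueError(f"unknown nfs variant {variant!r}")
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * g
        + 0.99 * (ast / alt)
        - 0.013 * platelets
        - 0.66 * albumin_gdl
    )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def fast(vcte_lsm: float, cap: float, ast: float, logistic: bool = True) -> float:
    """FibroScan-AST score.

    Linear predictor ``-1.65 + 1.07*ln(LSM) + 2.66e-8*CAP^3 - 63.3/AST``;
    returned through a logistic by default.
    """
    _require_positive(vcte_lsm=vcte_lsm, ast=ast)
    x = -1.65 + 1.07 * math.log(vcte_lsm) + 2.66e-8 * cap**3 - 63.3 / ast
    return _logistic(x) if logistic else x


def mast(
    mre_lsm: float,
    pdff: float,
    ast: float,
    logistic: bool = True,
    log_base: float = 10.0,
) -> float:
    """MRI-AST score.

    Linear predictor ``-12.17 + 7.07*log(MRE) + 0.037*PDFF + 3.55*log(AST)``
    with base-10 logs by default; returned through a logistic by default.
    """
    _require_positive(mre_lsm=mre_lsm, ast=ast)
    lg = math.log(log_base)
    x = (
        -12.17
        + 7.07 * math.log(mre_lsm) / lg
        + 0.037 * pdff
        + 3.55 * math.log(ast) / lg
    )
    return _logistic(x) if logistic else x


@dataclass
class NITPanel:
    """The eight non-invasive tests for one patient (NaN = not computable)."""

    MAST: float = float("nan")
    FAST: float = float("nan")
    FIB4: float = float("nan")
    APRI: float = float("nan")
    AAR: float = float("nan")
    NFS: float = float("nan")
    MRE_LSM: float = float("nan")
    VCTE_LSM: float = float("nan")
    missing: list = field(default_factory=list)
    variants: dict = field(default_factory=dict)


_DEFAULT_CONFIG = {
    "fib4_variant": "standard",
    "nfs_variant": "indicator",
    "fast_logistic": True,
    "mast_logistic": True,
    "mast_log_base": 10.0,
    "ast_uln": 40.0,
}


def _get(record, key):
    try:
        v = record[key]
    except (KeyError, IndexError):
        return None
    if v is None:
        return None
    try:
        if isinstance(v, (bool, np.bool_)):
            return float(v)
        v = float(v)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def compute_panel(record, config: dict | None = None) -> NITPanel:
    """Compute all eight NITs for one patient record (mapping-like).

    Recognised keys: ``age, BMI, AST, ALT, PLT, ALB`` (g/dL) or ``ALB_gL``,
    ``glucose, hyperglycemia, CAP, VCTE_LSM, MRE_LSM, PDFF, AST_ULN``.
    A score whose inputs are missing is NaN and listed in ``panel.missing``
    rather than raising.
    """
    cfg = dict(_DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    panel = NITPanel(variants={k: cfg[k] for k in sorted(cfg)})

    age = _get(record, "age")
    bmi = _get(record, "BMI")
    ast = _get(record, "AST")
    alt = _get(record, "ALT")
    plt = _get(record, "PLT")
    alb = _get(record, "ALB")
    if alb is None:
        alb_gl = _get(record, "ALB_gL")
        alb = alb_gl / 10.0 if alb_gl is not None else None
    glucose = _get(record, "glucose")
    flag = _get(record, "hyperglycemia")
    cap = _get(record, "CAP")
    vcte = _get(record, "VCTE_LSM")
    mre = _get(record, "MRE_LSM")
    pdff = _get(record, "PDFF")
    ast_uln = _get(record, "AST_ULN") or cfg["ast_uln"]

    if mre is not None:
        panel.MRE_LSM = mre
    else:
        panel.missing.append("MRE_LSM")
    if vcte is not None:
        panel.VCTE_LSM = vcte
    else:
        panel.missing.append("VCTE_LSM")

    if None not in (ast, plt):
        panel.APRI = apri(ast, ast_uln, plt)
    else:
        panel.missing.append("APRI")
    if None not in (ast, alt):
        panel.AAR = aar(ast, alt)
    else:
        panel.missing.append("AAR")
    if None not in (age, ast, alt, plt):
        panel.FIB4 = fib4(age, ast, alt, plt, cfg["fib4_variant"])
    else:
        panel.missing.append("FIB4")

    g = flag if cfg["nfs_variant"] == "indicator" else glucose
    if None not in (age, bmi, g, ast, alt, plt, alb):
        panel.NFS = nfs(age, bmi, g, ast, alt, plt, alb, cfg["nfs_variant"])
    else:
        panel.missing.append("NFS")

    if None not in (vcte, cap, ast):
        panel.FAST = fast(vcte, cap, ast, cfg["fast_logistic"])
    else:
        panel.missing.append("FAST")
    if None not in (mre, pdff, ast):
        panel.MAST = mast(mre, pdff, ast, cfg["mast_logistic"], cfg["mast_log_base"])
    else:
        panel.missing.append("MAST")
    return panel


def compute_panel_frame(cohort: pd.DataFrame, config: dict | None = None) -> pd.DataFrame:
    """Vectorised panel over a cohort DataFrame; returns one column per score."""
    rows = [compute_panel(rec, config) for rec in cohort.to_dict("records")]
    return pd.DataFrame(
        {
            name: [getattr(p, name) for p in rows]
            for name in ("MAST", "FAST", "FIB4", "APRI", "AAR", "NFS", "MRE_LSM", "VCTE_LSM")
        },
        index=cohort.index,
    )
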