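"""Diagnostic-performance statistics for fibrosis scores.

ROC analysis with three cutoff strategies (Youden index, fixed 90%
sensitivity, fixed 90% specificity) and the four predictive values;
Spearman correlation matrices between morphometric parameters and
non-invasive tests; stage-wise Kruskal-Wallis / Mann-Whitney tests with
Bonferroni post hoc; weighted kappa for ordinal agreement; and
random-forest variable importance (out-of-bag permutation MSE increase and
total node-purity gain).

Conventions: a case is called positive when its score is >= the cutoff;
candidate cutoffs are the observed score values; AUC is the Mann-Whitney
probability with ties counted 1/2; confidence intervals use a seeded,
class-stratified bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "roc_auc",
    "cutoff_youden",
    "cutoff_at_sensitivity",
    "cutoff_at_specificity",
    "diagnostic_metrics",
    "evaluate_score",
    "DiagnosticResult",
    "spearman_matrix",
    "group_tests",
    "weighted_kappa",
    "rf_importance",
]


def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def _auc_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (mid-ranks for ties)."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(
    scores,
    labels,
    ci: bool = True,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """AUC with optional class-stratified bootstrap percentile CI."""
    scores, labels = _validate_binary(scores, labels)
    auc = _auc_point(scores, labels)
    if not ci:
        return auc, None
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        reps[b] = _auc_point(scores[idx], labels[idx])
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return auc, (float(lo), float(hi))


def _confusion_at(scores, labels, cutoff):
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return tp, fp, fn, tn


def _se_sp(scores, labels, cutoff):
    tp, fp, fn, tn = _confusion_at(scores, labels, cutoff)
    return tp / (tp + fn), tn / (tn + fp)


def cutoff_youden(scores, labels) -> float:
    """Smallest observed cutoff maximising Youden's J = Se + Sp - 1."""
    scores, labels = _validate_binary(scores, labels)
    best_c, best_j = None, -np.inf
    for c in np.unique(scores):
        se, sp = _se_sp(scores, labels, c)
        j = se + sp - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def cutoff_at_sensitivity(scores, labels, target: float = 0.90):
    """Largest observed cutoff with Se >= target (maximises Sp subject to it).

    Returns ``(cutoff, attained)``; ``attained`` is False when even the
    minimum positive score misses the target (then the least-bad cutoff,
    the minimum observed score, is returned flagged).
    """
    scores, labels = _validate_binary(scores, labels)
    best = None
    for c in np.unique(scores):
        se, _ = _se_sp(scores, labels, c)
        if se >= target:
            best = c  # unique() is sorted: keep the largest satisfying
    if best is None:
        return float(np.min(scores)), False
    return float(best), True


def cutoff_at_specificity(scores, labels, target: float = 0.90):
    """Smallest observed cutoff with Sp >= target (maximises Se subject to it)."""
    scores, labels = _validate_binary(scores, labels)
    for c in np.unique(scores):
        _, sp = _se_sp(scores, labels, c)
        if sp >= target:
            return float(c), True
    return float(np.max(scores)), False


def diagnostic_metrics(scores, labels, cutoff: float) -> dict:
    """Se/Sp/PPV/NPV in % from the 2x2 table at ``score >= cutoff``.

    Undefined cells (no predicted positives/negatives) are NaN and listed
    under ``undefined``.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    tp, fp, fn, tn = _confusion_at(scores, labels, cutoff)
    undefined = []
    se = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    sp = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    if tp + fp:
        ppv = 100.0 * tp / (tp + fp)
    else:
        ppv, _ = np.nan, undefined.append("PPV")
    if tn + fn:
        npv = 100.0 * tn / (tn + fn)
    else:
        npv, _ = np.nan, undefined.append("NPV")
    return {"Se": se, "Sp": sp, "PPV": ppv, "NPV": npv, "undefined": undefined,
            "table": {"TP": tp, "FP": fp, "FN": fn, "TN": tn}}


@dataclass
class DiagnosticResult:
    """AUC with CI and the three cutoff strategies for one comparison."""

    comparison: str
    auc: float
    ci: tuple[float, float] | None
    cutoffs: dict = field(default_factory=dict)  # strategy -> cutoff
    metrics: dict = field(default_factory=dict)  # strategy -> Se/Sp/PPV/NPV
    flags: dict = field(default_factory=dict)  # strategy -> attained bool

    def to_rows(self) -> list[dict]:
        rows = []
        for strat, cut in self.cutoffs.items():
            m = self.metrics[strat]
            rows.append(
                {
                    "comparison": self.comparison,
                    "strategy": strat,
                    "cutoff": cut,
                    "AUC": self.auc,
                    "CI_lower": self.ci[0] if self.ci else np.nan,
                    "CI_upper": self.ci[1] if self.ci else np.nan,
                    "Se": m["Se"],
                    "Sp": m["Sp"],
                    "PPV": m["PPV"],
                    "NPV": m["NPV"],
                    "attained": self.flags.get(strat, True),
                }
            )
        return rows


def evaluate_score(
    scores,
    labels,
    comparison: str = "",
    target: float = 0.90,
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiagnosticResult:
    """Full ROC work-up of one score for one binary staging comparison."""
    auc, ci_pair = roc_auc(scores, labels, ci=ci, n_boot=n_boot, seed=seed)
    c_y = cutoff_youden(scores, labels)
    c_se, ok_se = cutoff_at_sensitivity(scores, labels, target)
    c_sp, ok_sp = cutoff_at_specificity(scores, labels, target)
    res = DiagnosticResult(comparison=comparison, auc=auc, ci=ci_pair)
    for strat, cut, ok in (
        ("youden", c_y, True),
        ("se90", c_se, ok_se),
        ("sp90", c_sp, ok_sp),
    ):
        res.cutoffs[strat] = cut
        res.metrics[strat] = diagnostic_metrics(scores, labels, cut)
        res.flags[strat] = ok
    return res


# ---------------------------------------------------------------------------
# correlation / group tests / agreement


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n (<= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ry_c @ rx_c) / denom
    return float((np.abs(rhos) >= abs(rho) - 1e-12).mean())


def spearman_matrix(
    left: pd.DataFrame,
    right: pd.DataFrame,
    adjust: str | None = "bonferroni",
    min_n: int = 3,
    exact_below_n: int = 10,
) -> dict:
    """Spearman rho/p between every column of ``left`` and of ``right``.

    Mid-rank (tie-aware) rho; p from the t approximation, or the exact
    permutation distribution for n < ``exact_below_n``.  Cells with fewer
    than ``min_n`` complete pairs are NaN and flagged.
    Returns dict of DataFrames: rho, p, p_adjusted, n, flagged.
    """
    rho = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    pval = rho.copy()
    nmat = rho.copy()
    flagged = []
    for a in left.columns:
        for b in right.columns:
            pair = pd.concat([left[a], right[b]], axis=1).dropna()
            n = len(pair)
            nmat.loc[a, b] = n
            if n < min_n:
                flagged.append((a, b))
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            r, p = stats.spearmanr(x, y)
            if n < exact_below_n and np.isfinite(r):
                p = _spearman_exact_p(x, y, r)
            rho.loc[a, b] = r
            pval.loc[a, b] = p
    out = {"rho": rho, "p": pval, "n": nmat, "flagged": flagged}
    if adjust == "bonferroni":
        m = int(pval.notna().sum().sum())
        out["p_adjusted"] = (pval * m).clip(upper=1.0)
    elif adjust is None:
        out["p_adjusted"] = pval.copy()
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def group_tests(values, groups) -> dict:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise Mann-Whitney.

    Groups with fewer than 2 observations are dropped with a warning entry.
    Returns ``{"omnibus": {...}, "pairwise": DataFrame, "dropped": [...]}``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keys = [k for k in np.unique(groups)]
    samples = {k: values[groups == k] for k in keys}
    dropped = [k for k, v in samples.items() if len(v) < 2]
    samples = {k: v for k, v in samples.items() if len(v) >= 2}
    if len(samples) < 2:
        raise ValueError("need at least two groups with >= 2 observations")
    ordered = list(samples)
    if all(np.ptp(np.concatenate(list(samples.values()))) == 0 for _ in [0]):
        omnibus = {"statistic": 0.0, "p": 1.0}
    else:
        h, p = stats.kruskal(*samples.values())
        omnibus = {"statistic": float(h), "p": float(p)}
    pairs = list(itertools.combinations(ordered, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        u, p = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(u),
                "p_raw": float(p),
                "p_bonferroni": float(min(p * m, 1.0)),
            }
        )
    return {"omnibus": omnibus, "pairwise": pd.DataFrame(rows), "dropped": dropped}


def weighted_kappa(
    stages_a,
    stages_b,
    weights: str = "linear",
    categories=None,
) -> float:
    """Weighted kappa for ordinal agreement (linear weights by default)."""
    a = np.asarray(stages_a)
    b = np.asarray(stages_b)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    if weights not in ("linear", "quadratic"):
        raise ValueError("weights must be 'linear' or 'quadratic'")
    labels = categories if categories is not None else sorted(set(a) | set(b))
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k = float(cohen_kappa_score(a, b, weights=weights, labels=labels))
    if math.isnan(k):
        # degenerate marginals (e.g. both raters constant): fall back to the
        # definition 1 - sum(w*O)/sum(w*E) with explicit conventions
        idx = {l: i for i, l in enumerate(labels)}
        m = len(labels)
        O = np.zeros((m, m))
        for x, y in zip(a, b):
            O[idx[x], idx[y]] += 1
        O /= O.sum()
        E = np.outer(O.sum(1), O.sum(0))
        d = np.abs(np.subtract.outer(np.arange(m), np.arange(m))).astype(float)
        w = d if weights == "linear" else d**2
        we = (w * E).sum()
        wo = (w * O).sum()
        if we == 0:
            return 1.0 if wo == 0 else 0.0
        k = 1.0 - wo / we
    return k


def rf_importance(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float | str = 1.0 / 3.0,
) -> pd.DataFrame:
    """Random-forest regression importance of each feature for ``y``.

    ``mse_increase`` is the out-of-bag permutation importance (mean over
    trees of the OOB MSE increase when the feature is permuted, the
    classical forest importance); ``node_purity`` is the total (unnormalized)
    impurity decrease attributable to the feature, summed over trees.
    Rows are sorted by decreasing ``mse_increase`` with a ``rank`` column.
    """
    X = pd.DataFrame(X)
    yv = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 observations")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if np.ptp(yv) == 0:
        raise ValueError("constant target")
    Xv = X.to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        random_state=seed,
        max_features=max_features,
        bootstrap=True,
        oob_score=False,
    )
    rf.fit(Xv, yv)

    n, p = Xv.shape
    rng = np.random.default_rng(seed + 1)
    mse_inc = np.zeros(p)
    counts = np.zeros(p)
    node_purity = np.zeros(p)
    for est in rf.estimators_:
        node_purity += est.tree_.compute_feature_importances(normalize=False) * n
        oob = np.ones(n, dtype=bool)
        sample_idx = _tree_sample_indices(est, n)
        oob[sample_idx] = False
        if oob.sum() < 2:
            continue
        Xo, yo = Xv[oob], yv[oob]
        base = float(((est.predict(Xo) - yo) ** 2).mean())
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = float(((est.predict(Xp) - yo) ** 2).mean())
            mse_inc[j] += perm - base
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        mse_inc = np.where(counts > 0, mse_inc / np.maximum(counts, 1), 0.0)
    out = pd.DataFrame(
        {"feature": X.columns, "mse_increase": mse_inc, "node_purity": node_purity}
    ).sort_values("mse_increase", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _tree_sample_indices(estimator, n: int) -> np.ndarray:
    """Bootstrap sample indices used by one fitted forest tree."""
    import inspect

    from sklearn.ensemble._forest import _generate_sample_indices

    if "sample_weight" in inspect.signature(_generate_sample_indices).parameters:
        return _generate_sample_indices(estimator.random_state, n, n, None)
    return _generate_sample_indices(estimator.random_state, n, n)
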