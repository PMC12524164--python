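"""The continuous qFibrosis score.

The score is built in three steps on a training set of specimens with
histological stages: (1) every q-FP is divided by its training-set maximum
(so all features live in [0, 1] in-sample; all-zero columns are dropped);
(2) forward sequential feature selection against stage, adding at each step
the feature that most reduces stage-stratified cross-validated residual sum
of squares of the linear fit, stopping when CV error stops improving or at
``k_max``; (3) ordinary least squares of stage (treated as numeric 0-4) on
the selected, normalized features.  Scoring a new specimen applies the
stored training maxima and the linear model; the output is dimensionless,
continuous and not clamped (out-of-sample features may exceed 1).

Usage mirrors the common modelling idiom::

    model = QFibrosisModel(features_df, stages, k_max=17, seed=0)
    res = model.fit()
    print(res.summary())
    qf = res.predict(new_features_df)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["normalize_qfp", "select_features", "QFibrosisModel", "QFibrosisResults"]


def normalize_qfp(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Divide each feature column by its maximum over the training set.

    Returns the normalized matrix, the per-feature maxima, and the names of
    dropped all-zero (or non-finite-max) columns.  Normalization is a
    monotone per-column rescaling, so within-column orderings survive, and
    re-normalizing an already normalized matrix is the identity.
    """
    if len(X) == 0:
        raise ValueError("empty feature table")
    X = X.astype(float)
    maxima = X.abs().max(axis=0)
    dropped = [c for c in X.columns if not np.isfinite(maxima[c]) or maxima[c] == 0]
    kept = [c for c in X.columns if c not in dropped]
    Xn = X[kept] / maxima[kept]
    return Xn, maxima[kept], dropped


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS with intercept via lstsq; returns (coefs, intercept)."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return beta[1:], float(beta[0])


def _cv_rss(X: np.ndarray, y: np.ndarray, folds) -> float:
    rss = 0.0
    for train, test in folds:
        A = np.column_stack([np.ones(train.size), X[train]])
        beta, _, _, _ = np.linalg.lstsq(A, y[train], rcond=None)
        pred = np.column_stack([np.ones(test.size), X[test]]) @ beta
        rss += float(((y[test] - pred) ** 2).sum())
    return rss


def select_features(
    X: pd.DataFrame,
    stages,
    k_max: int = 17,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], list[dict]]:
    """Forward sequential selection minimising cross-validated RSS.

    At each step every remaining feature is tried in combination with the
    already selected set; the one with the lowest stage-stratified
    ``cv_folds``-fold CV residual sum of squares is added.  Selection stops
    at ``k_max`` features or as soon as the best candidate no longer
    improves CV error.  Returns the ordered feature list and a trace of
    per-step criteria.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = np.asarray(stages, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and stages length mismatch")
    if len(y) <= cv_folds or cv_folds < 2:
        raise ValueError("need n > cv_folds >= 2")
    Xv = X.to_numpy(dtype=float)
    cols = list(X.columns)
    try:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(Xv, np.asarray(stages))]
    except ValueError:
        # continuous target or a class thinner than the fold count:
        # plain shuffled K-fold
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in kf.split(Xv)]

    selected: list[int] = []
    trace: list[dict] = []
    best_rss = float(((y - y.mean()) ** 2).sum())  # intercept-only baseline
    while len(selected) < min(k_max, len(cols)):
        candidates = [j for j in range(len(cols)) if j not in selected]
        scores = np.full(len(cols), np.inf)
        for j in candidates:
            trial = Xv[:, selected + [j]]
            try:
                scores[j] = _cv_rss(trial, y, folds)
            except np.linalg.LinAlgError:
                continue
        j_best = int(np.argmin(scores))
        # require a real improvement: a numerically identical RSS (e.g. a
        # collinear duplicate of an already selected feature) must not count
        if not np.isfinite(scores[j_best]) or scores[j_best] >= best_rss * (1 - 1e-6):
            break
        selected.append(j_best)
        trace.append({"feature": cols[j_best], "cv_rss": float(scores[j_best])})
        best_rss = float(scores[j_best])
    return [cols[j] for j in selected], trace


class QFibrosisModel:
    """Linear qFibrosis model over max-normalized, selected q-FPs.

    Parameters
    ----------
    features : DataFrame
        One row per specimen, named q-FP columns (raw scale).
    stages : array-like of int
        Histological fibrosis stage 0-4 per specimen.
    k_max : int
        Upper bound on the number of selected features (default 17, the
        size of the established international collagen-parameter panel).
    cv_folds, seed : int
        Stage-stratified CV configuration for the selection step.
    """

    def __init__(self, features: pd.DataFrame, stages, k_max: int = 17,
                 cv_folds: int = 5, seed: int = 0):
        self.features = pd.DataFrame(features).astype(float)
        self.stages = np.asarray(stages, dtype=float)
        if len(self.features) != len(self.stages):
            raise ValueError("features and stages length mismatch")
        self.k_max = k_max
        self.cv_folds = cv_folds
        self.seed = seed

    @classmethod
    def from_tables(cls, tables, stages, feature_names=None, **kwargs) -> "QFibrosisModel":
        """Build from a list of :class:`~fibroquant.morphometry.QFPTable`."""
        rows = [t.values for t in tables]
        df = pd.DataFrame(rows)
        if feature_names is not None:
            df = df[list(feature_names)]
        return cls(df, stages, **kwargs)

    def fit(self) -> "QFibrosisResults":
        Xn, maxima, dropped = normalize_qfp(self.features)
        selected, trace = select_features(
            Xn, self.stages, self.k_max, self.cv_folds, self.seed
        )
        if not selected:
            raise ValueError("no feature improved cross-validated error")
        Xs = Xn[selected].to_numpy()
        try:
            coefs, intercept = _ols(Xs, self.stages)
        except np.linalg.LinAlgError:
            corr = np.corrcoef(Xs, rowvar=False)
            pairs = [
                (selected[i], selected[j])
                for i in range(len(selected))
                for j in range(i + 1, len(selected))
                if abs(corr[i, j]) > 0.999999
            ]
            raise ValueError(f"rank-deficient design; collinear features: {pairs}")
        fitted = intercept + Xs @ coefs
        return QFibrosisResults(
            model=self,
            selected_features=list(selected),
            params=pd.Series(coefs, index=selected),
            intercept=intercept,
            maxima=maxima[selected],
            dropped_features=dropped,
            selection_trace=trace,
            fittedvalues=pd.Series(fitted, index=self.features.index),
        )


@dataclass
class QFibrosisResults:
    """Fitted qFibrosis model: coefficients, normalization maxima, trace."""

    model: QFibrosisModel
    selected_features: list[str]
    params: pd.Series
    intercept: float
    maxima: pd.Series
    dropped_features: list[str]
    selection_trace: list[dict]
    fittedvalues: pd.Series = field(repr=False, default=None)

    @property
    def resid(self) -> pd.Series:
        return pd.Series(self.model.stages, index=self.fittedvalues.index) - self.fittedvalues

    def predict(self, features) -> pd.Series:
        """qFibrosis value for new specimens (DataFrame or QFPTable list)."""
        if isinstance(features, (list, tuple)):
            features = pd.DataFrame([t.values for t in features])
        missing = [c for c in self.selected_features if c not in features.columns]
        if missing:
            raise KeyError(f"missing selected features: {missing}")
        Xn = features[self.selected_features].astype(float) / self.maxima
        return Xn @ self.params + self.intercept

    def score_table(self, table) -> float:
        """qFibrosis value of a single q-FP table."""
        row = pd.DataFrame([table.values])
        return float(self.predict(row).iloc[0])

    def to_json_dict(self) -> dict:
        return {
            "version": 1,
            "selected_features": self.selected_features,
            "coefficients": self.params.tolist(),
            "intercept": self.intercept,
            "maxima": self.maxima.tolist(),
            "selection_trace": self.selection_trace,
            "k_max": self.model.k_max,
            "cv_folds": self.model.cv_folds,
            "seed": self.model.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "QFibrosisResults":
        sel = d["selected_features"]
        return cls(
            model=None,
            selected_features=sel,
            params=pd.Series(d["coefficients"], index=sel),
            intercept=float(d["intercept"]),
            maxima=pd.Series(d["maxima"], index=sel),
            dropped_features=[],
            selection_trace=d.get("selection_trace", []),
        )

    def summary(self) -> str:
        lines = [
            "qFibrosis linear model",
            "=" * 46,
            f"{'n specimens':<28}{len(self.model.stages) if self.model else 'n/a'}",
            f"{'features selected':<28}{len(self.selected_features)}",
            f"{'intercept':<28}{self.intercept: .4f}",
            "-" * 46,
            f"{'feature':<24}{'coef':>10}{'max':>10}",
        ]
        for name in self.selected_features:
            lines.append(f"{name:<24}{self.params[name]:>10.4f}{self.maxima[name]:>10.4g}")
        if self.model is not None and self.fittedvalues is not None:
            ss_res = float((self.resid**2).sum())
            y = self.model.stages
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1 - ss_res / ss_tot if ss_tot else float("nan")
            lines += ["-" * 46, f"{'R-squared (vs stage)':<28}{r2:.4f}"]
        return "\n".join(lines)
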