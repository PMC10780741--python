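"""Ensemble feature selection (EFS).

Six per-feature scoring algorithms are run on the training data, each score
vector is min-max rescaled to [0, 1], the rescaled vectors are averaged

    A_d = (1/N) * sum_i FS_i(d),        N = 6 selectors,

and the Q features with the highest average A_d form the selected set.  The
selectors deliberately span three families:

* univariate statistics — normalized mutual information (NMI) and the
  univariate regression F-statistic;
* penalized / ordinary linear fits — LASSO (coefficients of an L1 fit at a
  cross-validated penalty) and multiple linear regression (absolute OLS
  weights on standardized inputs);
* impurity-based tree ensembles — mean decrease in impurity from a random
  forest (MDI-RF) and from extremely randomized trees (MDI-ET), 500
  estimators each, squared-error impurity.

Q can be fixed a priori or tuned by inner cross-validation of the
downstream regressor's mean absolute error (smallest Q wins ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .core_data import FeatureTable, ModalitySchema, standardize

__all__ = [
    "SelectorScores",
    "EFSResult",
    "score_nmi",
    "score_fstat",
    "score_lasso",
    "score_lr",
    "score_mdi",
    "run_selectors",
    "ensemble_average",
    "select_top_q",
    "run_efs",
    "tune_q",
]

F_STAT_CAP = 1e15  # returned when a feature is perfectly correlated with the target


@dataclass(frozen=True)
class SelectorScores:
    """Raw and min-max rescaled per-feature scores of one selector."""

    selector_name: str
    feature_names: list[str]
    raw_scores: np.ndarray
    scaled_scores: np.ndarray

    @classmethod
    def from_raw(cls, name: str, feature_names: list[str], raw: np.ndarray) -> "SelectorScores":
        raw = np.asarray(raw, dtype=float)
        if not np.all(np.isfinite(raw)):
            raise ValueError(f"selector {name!r} produced non-finite scores")
        span = raw.max() - raw.min()
        if span == 0:
            # A selector with no preference contributes nothing, not
            # everything: constant raw vectors rescale to all zeros.
            warnings.warn(f"selector {name!r} returned constant scores; rescaled to zeros")
            scaled = np.zeros_like(raw)
        else:
            scaled = (raw - raw.min()) / span
        return cls(name, list(feature_names), raw, scaled)


@dataclass(frozen=True)
class EFSResult:
    """Outcome of the full ensemble selection."""

    selector_scores: list[SelectorScores]
    feature_names: list[str]
    averaged_scores: np.ndarray
    q: int
    selected_features: list[str]

    def contributions(self) -> dict[str, np.ndarray]:
        """Per-selector scaled scores keyed by selector, for stacked reporting."""
        return {s.selector_name: s.scaled_scores for s in self.selector_scores}


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency discretization; discrete inputs keep their codes."""
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x, side="right")


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def score_nmi(table: FeatureTable, n_bins: int = 10) -> SelectorScores:
    """Normalized mutual information of each feature with the target.

    Continuous variables are discretized into ``n_bins`` equal-frequency
    bins; MI is normalized by the arithmetic mean of the marginal
    entropies, giving a score in [0, 1].
    """
    if table.n_samples < 10:
        raise ValueError("NMI estimation needs at least 10 samples")
    yb = _quantile_bins(table.target, n_bins)
    hy = _entropy(np.bincount(yb))
    raw = np.empty(table.n_features)
    for j in range(table.n_features):
        xb = _quantile_bins(table.values[:, j], n_bins)
        hx = _entropy(np.bincount(xb))
        joint = np.zeros((xb.max() + 1, yb.max() + 1))
        np.add.at(joint, (xb, yb), 1.0)
        hxy = _entropy(joint.ravel())
        mi = max(hx + hy - hxy, 0.0)
        denom = (hx + hy) / 2.0
        raw[j] = mi / denom if denom > 0 else 0.0
    return SelectorScores.from_raw("NMI", table.feature_names, raw)


def score_fstat(table: FeatureTable) -> SelectorScores:
    """Univariate regression F-statistic, F = r^2/(1-r^2) * (n-2)."""
    n = table.n_samples
    if n < 3:
        raise ValueError("F-statistic needs at least 3 samples")
    y = table.target - table.target.mean()
    x = table.values - table.values.mean(axis=0)
    denom = np.sqrt((x**2).sum(axis=0) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, x.T @ y / denom, 0.0)
    r2 = np.clip(r**2, 0.0, 1.0)
    raw = np.empty_like(r2)
    perfect = r2 >= 1.0 - 1e-15
    if perfect.any():
        warnings.warn("perfectly correlated feature; F-statistic capped")
    raw[perfect] = F_STAT_CAP
    raw[~perfect] = r2[~perfect] / (1.0 - r2[~perfect]) * (n - 2)
    return SelectorScores.from_raw("F-Statistic", table.feature_names, raw)


def score_lasso(
    table: FeatureTable, seed: int = 0, n_alphas: int = 50, cv: int = 5
) -> SelectorScores:
    """|coefficients| of an L1-penalized linear fit at a cross-validated penalty.

    The penalty is chosen over a 50-point logarithmic grid by 5-fold CV;
    non-relevant variables get exactly zero weight.  Features are
    standardized internally so the penalty treats them comparably.
    """
    if table.n_samples < 2:
        raise ValueError("LASSO needs at least 2 samples")
    std, _ = standardize(table)
    model = LassoCV(
        alphas=n_alphas,
        cv=KFold(n_splits=cv, shuffle=True, random_state=seed),
        max_iter=50000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(std.values, std.target)
    return SelectorScores.from_raw("LASSO", table.feature_names, np.abs(model.coef_))


def score_lr(table: FeatureTable) -> SelectorScores:
    """|weights| of the joint ordinary-least-squares fit on standardized inputs.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning (duplicated columns split their weight).
    """
    std, _ = standardize(table)
    x = np.column_stack([np.ones(std.n_samples), std.values])
    coef, _, rank, _ = np.linalg.lstsq(x, std.target, rcond=None)
    if rank < x.shape[1]:
        warnings.warn("rank-deficient design; minimum-norm least-squares weights used")
    return SelectorScores.from_raw("LR", table.feature_names, np.abs(coef[1:]))


def score_mdi(
    table: FeatureTable, variant: str = "random_forest", seed: int = 0, n_estimators: int = 500
) -> SelectorScores:
    """Mean decrease in squared-error impurity over a 500-tree ensemble."""
    cls = {"random_forest": RandomForestRegressor, "extra_trees": ExtraTreesRegressor}
    if variant not in cls:
        raise ValueError(f"unknown MDI variant {variant!r}")
    if table.n_samples < 10:
        raise ValueError("MDI needs at least 10 samples")
    model = cls[variant](
        n_estimators=n_estimators,
        criterion="squared_error",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(table.values, table.target)
    name = "MDI-RF" if variant == "random_forest" else "MDI-ET"
    return SelectorScores.from_raw(name, table.feature_names, model.feature_importances_)


def run_selectors(table: FeatureTable, seed: int = 0) -> list[SelectorScores]:
    """Run the default six-selector battery."""
    return [
        score_nmi(table),
        score_fstat(table),
        score_lasso(table, seed=seed),
        score_lr(table),
        score_mdi(table, "random_forest", seed=seed),
        score_mdi(table, "extra_trees", seed=seed),
    ]


def ensemble_average(scores: list[SelectorScores]) -> np.ndarray:
    """Elementwise mean of the selectors' rescaled score vectors."""
    if not scores:
        raise ValueError("need at least one selector")
    names = scores[0].feature_names
    for s in scores[1:]:
        if s.feature_names != names:
            raise ValueError("selectors scored different feature sets")
    return np.mean([s.scaled_scores for s in scores], axis=0)


def select_top_q(averaged: np.ndarray, feature_names: list[str], q: int) -> list[str]:
    """The Q features with the largest averaged score.

    Ties at the cutoff are broken by original column order (stable sort),
    so repeated runs select the same set.
    """
    d = len(feature_names)
    if not 1 <= q <= d:
        raise ValueError(f"Q must be in [1, {d}], got {q}")
    order = np.argsort(-np.asarray(averaged), kind="stable")
    return [feature_names[i] for i in order[:q]]


def run_efs(table: FeatureTable, q: int, seed: int = 0) -> EFSResult:
    """Score with all six selectors and select the top-Q set."""
    scores = run_selectors(table, seed=seed)
    averaged = ensemble_average(scores)
    selected = select_top_q(averaged, table.feature_names, q)
    return EFSResult(
        selector_scores=scores,
        feature_names=list(table.feature_names),
        averaged_scores=averaged,
        q=q,
        selected_features=selected,
    )


def tune_q(
    table: FeatureTable,
    schema: ModalitySchema,
    regressor_config=None,
    q_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
) -> EFSResult:
    """Choose Q by inner cross-validated MAE of the downstream regressor.

    Selector scores are computed once on *table* (the training data — the
    hold-out must never reach this function); then each candidate Q is
    scored by ``cv_folds``-fold CV of the regressor trained on the top-Q
    features.  The MAE-minimizing Q is returned, smallest Q on ties.

    ``regressor_config`` is a callable ``(train_table, train_schema) ->
    predictor`` where the predictor maps a table to predicted targets; the
    default is a single-configuration multiple-kernel SVR.
    """
    if q_grid is None:
        q_grid = range(1, table.n_features + 1)
    q_grid = sorted(set(int(q) for q in q_grid))
    if not q_grid:
        raise ValueError("q_grid must be non-empty")
    if q_grid[0] < 1 or q_grid[-1] > table.n_features:
        raise ValueError("q_grid outside [1, d]")
    if regressor_config is None:
        from .mkl import default_single_config_fitter

        regressor_config = default_single_config_fitter(seed=seed)

    scores = run_selectors(table, seed=seed)
    averaged = ensemble_average(scores)

    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    ids = np.array(table.sample_ids)
    best_q, best_mae = None, np.inf
    for q in q_grid:
        selected = select_top_q(averaged, table.feature_names, q)
        sub_schema = schema.restrict(selected)
        errs = []
        for tr, va in kf.split(ids):
            train = table.subset(list(ids[tr])).select_features(selected)
            valid = table.subset(list(ids[va])).select_features(selected)
            predictor = regressor_config(train, sub_schema)
            pred = predictor(valid)
            errs.append(float(np.mean(np.abs(valid.target - pred))))
        mae = float(np.mean(errs))
        if mae < best_mae - 1e-12:
            best_q, best_mae = q, mae
    selected = select_top_q(averaged, table.feature_names, best_q)
    return EFSResult(
        selector_scores=scores,
        feature_names=list(table.feature_names),
        averaged_scores=averaged,
        q=best_q,
        selected_features=selected,
    )
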