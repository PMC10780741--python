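"""Validation protocol, error metrics and baseline comparison harness.

The protocol mirrors a 578-subject study design: a seeded random subset
(default 500 records) is used for five-fold cross-validation, the remainder
(78 records) is a hold-out touched exactly once, for the final test.  Errors
are reported as mean absolute error in grams,

    MAE = (1/S) * sum_i |y_i - y_hat_i|,

and mean absolute percentage error,

    MAPE = (100/S) * sum_i |y_i - y_hat_i| / y_i,

per fold (mean +/- sd) and on the hold-out.  Every model is evaluated under
a feature *condition*: one modality alone, all features, or the subset
chosen by ensemble feature selection inside each training fold (selection on
the full CV set is available behind an explicit flag, with a leakage
warning, because running selection once globally is a common but optimistic
shortcut).

Baselines — random forest, RBF-kernel SVR and a multilayer perceptron — are
standard library estimators behind a grid search; they are comparison
plumbing, not the contribution.  An audit log records which sample ids each
stage consumed and raises if any hold-out row reaches a training stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR as SkSVR

from .core_data import FeatureTable, ModalitySchema
from .mkl import SearchGrid, fit_mkl, grid_search_fit, predict
from .selection import run_efs, tune_q

__all__ = [
    "SplitPlan",
    "EvalReport",
    "AuditLog",
    "mae",
    "mape",
    "make_split",
    "fit_baseline",
    "run_protocol",
    "BASELINE_GRIDS",
]


def mae(y, y_hat) -> float:
    """Mean absolute error, in the target's units (grams)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch between targets and predictions")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.mean(np.abs(y - y_hat)))


def mape(y, y_hat) -> float:
    """Mean absolute percentage error, in percent; requires positive targets."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("length mismatch between targets and predictions")
    if y.size < 1:
        raise ValueError("need at least one sample")
    if np.any(y <= 0):
        raise ValueError("MAPE requires strictly positive targets")
    return float(100.0 * np.mean(np.abs(y - y_hat) / y))


@dataclass(frozen=True)
class SplitPlan:
    """CV/hold-out partition with per-sample fold assignment."""

    cv_ids: list[str]
    holdout_ids: list[str]
    fold_of: dict[str, int]
    n_folds: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s in self.cv_ids if self.fold_of[s] == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s in self.cv_ids if self.fold_of[s] != fold]


def make_split(table: FeatureTable, cv_size: int = 500, folds: int = 5, seed: int = 0) -> SplitPlan:
    """Seeded random CV/hold-out split with balanced folds (sizes differ <= 1)."""
    n = table.n_samples
    if cv_size >= n:
        raise ValueError("cv_size must be smaller than the number of samples")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = np.array(table.sample_ids)
    cv_ids = list(ids[perm[:cv_size]])
    holdout_ids = list(ids[perm[cv_size:]])
    fold_of = {s: (i % folds) + 1 for i, s in enumerate(cv_ids)}
    return SplitPlan(cv_ids=cv_ids, holdout_ids=holdout_ids, fold_of=fold_of,
                     n_folds=folds, seed=seed)


class AuditLog:
    """Records the sample ids consumed by each pipeline stage.

    ``record`` notes an access; ``assert_clean`` raises if any id in the
    protected set was consumed by a stage other than the permitted ones.
    """

    def __init__(self) -> None:
        self.entries: list[tuple[str, frozenset]] = []

    def record(self, stage: str, sample_ids) -> None:
        self.entries.append((stage, frozenset(sample_ids)))

    def assert_clean(self, protected_ids, allowed_stages=("final_evaluation",)) -> None:
        protected = frozenset(protected_ids)
        for stage, seen in self.entries:
            if stage not in allowed_stages and seen & protected:
                raise RuntimeError(
                    f"leakage: stage {stage!r} touched {len(seen & protected)} hold-out samples"
                )


@dataclass
class EvalReport:
    """Fold-wise and hold-out errors for one condition, several models."""

    condition: str
    fold_mae: dict[str, list[float]] = field(default_factory=dict)
    fold_mape: dict[str, list[float]] = field(default_factory=dict)
    holdout_mae: dict[str, float] = field(default_factory=dict)
    holdout_mape: dict[str, float] = field(default_factory=dict)
    selected_features: dict[int, list[str]] = field(default_factory=dict)
    audit: AuditLog = field(default_factory=AuditLog)
    seed: int = 0

    def cv_mean_mae(self, model: str) -> float:
        return float(np.mean(self.fold_mae[model]))

    def cv_sd_mae(self, model: str) -> float:
        return float(np.std(self.fold_mae[model], ddof=1))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "seed": self.seed,
            "models": {
                m: {
                    "fold_mae_g": [round(v, 4) for v in self.fold_mae[m]],
                    "fold_mape_pct": [round(v, 4) for v in self.fold_mape[m]],
                    "cv_mae_g": round(self.cv_mean_mae(m), 1),
                    "cv_mae_sd_g": round(self.cv_sd_mae(m), 1),
                    "cv_mape_pct": round(float(np.mean(self.fold_mape[m])), 2),
                    "holdout_mae_g": (
                        round(self.holdout_mae[m], 1) if m in self.holdout_mae else None
                    ),
                    "holdout_mape_pct": (
                        round(self.holdout_mape[m], 2) if m in self.holdout_mape else None
                    ),
                }
                for m in self.fold_mae
            },
        }

    def to_text(self) -> str:
        lines = [f"condition: {self.condition}",
                 f"{'model':<6} {'CV MAE (g)':>16} {'CV MAPE (%)':>14} "
                 f"{'hold-out MAE':>14} {'hold-out MAPE':>14}"]
        for m in self.fold_mae:
            ho_mae = self.holdout_mae.get(m)
            ho_mape = self.holdout_mape.get(m)
            lines.append(
                f"{m:<6} {self.cv_mean_mae(m):9.1f} ± {self.cv_sd_mae(m):<4.1f} "
                f"{np.mean(self.fold_mape[m]):13.2f} "
                f"{'' if ho_mae is None else f'{ho_mae:14.1f}'}"
                f"{'' if ho_mape is None else f'{ho_mape:15.2f}'}"
            )
        return "\n".join(lines)


# Compact defaults for the baseline hyperparameter searches; the full search
# spaces can be passed explicitly through the ``grids`` argument.
BASELINE_GRIDS: dict[str, dict] = {
    "RF": {
        "model__n_estimators": [200],
        "model__criterion": ["squared_error"],
        "model__max_depth": [None, 10],
    },
    "SVR": {
        "model__kernel": ["rbf"],
        "model__gamma": ["scale", 0.1],
        "model__C": [1.0, 10.0, 100.0],
    },
    "ANN": {
        "model__activation": ["relu"],
        "model__solver": ["adam"],
        "model__alpha": [1e-3],
        "model__hidden_layer_sizes": [(50,)],
    },
}


def fit_baseline(name: str, train: FeatureTable, grid: dict | None = None, seed: int = 0):
    """Grid-search-tuned standard estimator; returns a predictor callable.

    ``name`` is one of RF (random forest), SVR (RBF support vector
    regression) or ANN (multilayer perceptron).  Inputs are standardized
    inside the pipeline with training statistics only.
    """
    if name not in BASELINE_GRIDS:
        raise ValueError(f"unknown baseline {name!r}")
    grid = BASELINE_GRIDS[name] if grid is None else grid
    if not grid:
        raise ValueError("baseline grid must be non-empty")
    if name == "RF":
        est = RandomForestRegressor(random_state=seed, n_jobs=1)
    elif name == "SVR":
        est = SkSVR()
    elif name == "ANN":
        for sizes in grid.get("model__hidden_layer_sizes", [(50,)]):
            if not sizes or any(h < 1 for h in sizes):
                raise ValueError("ANN hidden layers must each have >= 1 neuron")
        est = MLPRegressor(random_state=seed, max_iter=3000)
    else:
        raise ValueError(f"unknown baseline {name!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    search = GridSearchCV(
        pipe,
        grid,
        scoring="neg_mean_absolute_error",
        cv=KFold(n_splits=5, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(train.values, train.target)

    feature_names = list(train.feature_names)

    def predictor(table: FeatureTable) -> np.ndarray:
        return search.predict(table.select_features(feature_names).values)

    return predictor


def _condition_features(
    condition: str,
    train: FeatureTable,
    schema: ModalitySchema,
    efs_q,
    seed: int,
) -> list[str]:
    if condition == "all_features":
        return list(train.feature_names)
    if condition == "efs_selected":
        if efs_q == "tune":
            return tune_q(train, schema, seed=seed).selected_features
        return run_efs(train, int(efs_q), seed=seed).selected_features
    if condition in schema.modalities:
        feats = [f for f in train.feature_names if schema.assignment.get(f) == condition]
        if not feats:
            raise ValueError(f"modality {condition!r} has no features in the table")
        return feats
    raise ValueError(f"unknown condition {condition!r}")


def run_protocol(
    table: FeatureTable,
    schema: ModalitySchema,
    condition: str,
    models=("MKL",),
    plan: SplitPlan | None = None,
    grids: dict | None = None,
    seed: int = 0,
    efs_q=8,
    mkl_grid: SearchGrid | None = None,
    global_selection: bool = False,
    holdout: bool = True,
) -> EvalReport:
    """Run the CV + hold-out protocol for one feature condition.

    Per fold: (optionally) select features on the training rows, tune and
    fit each model on them, evaluate on the validation fold.  The final
    hold-out model is refit on the full CV set — the multiple-kernel model
    at its most frequently winning fold configuration (ties broken by the
    best inner CV MAE), the baselines by re-running their grid search.

    ``efs_q`` is the selected-set size for the ``efs_selected`` condition,
    or ``"tune"`` to choose Q by inner CV.  ``global_selection=True``
    reproduces the optimistic variant that selects features once on the
    whole CV set (warned, because fold errors then share selection
    information).
    """
    schema.validate_against(table)
    if plan is None:
        plan = make_split(table, cv_size=max(table.n_samples - max(table.n_samples // 7, 1), 2),
                          folds=5, seed=seed)
    grids = grids or {}
    mkl_grid = mkl_grid or SearchGrid.compact(seed=seed)
    report = EvalReport(condition=condition, seed=seed)
    audit = report.audit

    global_features = None
    if global_selection and condition == "efs_selected":
        warnings.warn(
            "global selection: features chosen once on the full CV set; "
            "fold errors are optimistically biased"
        )
        cv_table = table.subset(plan.cv_ids)
        audit.record("global_selection", plan.cv_ids)
        global_features = _condition_features(condition, cv_table, schema, efs_q, seed)

    mkl_fold_configs: list[tuple] = []
    fold_models: dict[str, list] = {m: [] for m in models}
    for fold in range(1, plan.n_folds + 1):
        tr_ids, va_ids = plan.train_ids(fold), plan.fold_ids(fold)
        train, valid = table.subset(tr_ids), table.subset(va_ids)
        audit.record(f"fold{fold}_train", tr_ids)
        if global_features is not None:
            feats = global_features
        else:
            feats = _condition_features(condition, train, schema, efs_q, seed)
        report.selected_features[fold] = feats
        train_f, valid_f = train.select_features(feats), valid.select_features(feats)
        sub_schema = schema.restrict(feats)
        for name in models:
            if name == "MKL":
                model = grid_search_fit(train_f, sub_schema, feats, mkl_grid)
                pred = predict(model, valid_f)
                cfg = (
                    tuple(sorted((m, s.label()) for m, s in model.kernel_specs.items())),
                    model.weights.eta,
                    model.c,
                    model.eps,
                )
                mkl_fold_configs.append((cfg, model.cv_mae_, model, feats))
            else:
                predictor = fit_baseline(name, train_f, grids.get(name), seed=seed)
                pred = predictor(valid_f)
            report.fold_mae.setdefault(name, []).append(mae(valid.target, pred))
            report.fold_mape.setdefault(name, []).append(mape(valid.target, pred))

    if holdout and plan.holdout_ids:
        cv_table = table.subset(plan.cv_ids)
        audit.record("final_train", plan.cv_ids)
        if global_features is not None:
            final_feats = global_features
        else:
            final_feats = _condition_features(condition, cv_table, schema, efs_q, seed)
        test = table.subset(plan.holdout_ids)
        audit.record("final_evaluation", plan.holdout_ids)
        for name in models:
            if name == "MKL":
                cfg, feats = _modal_config(mkl_fold_configs)
                train_f = cv_table.select_features(feats)
                sub_schema = schema.restrict(feats)
                kernel_labels, eta, c, eps = cfg
                # recover the KernelSpec objects from a fold model that won
                # with this configuration
                specs = next(
                    m.kernel_specs
                    for c_, _, m, _ in mkl_fold_configs
                    if c_ == cfg
                )
                from .mkl import KernelWeights

                model = fit_mkl(train_f, sub_schema, specs, KernelWeights(eta), c, eps)
                pred = predict(model, test.select_features(feats))
            else:
                train_f = cv_table.select_features(final_feats)
                predictor = fit_baseline(name, train_f, grids.get(name), seed=seed)
                pred = predictor(test.select_features(final_feats))
            report.holdout_mae[name] = mae(test.target, pred)
            report.holdout_mape[name] = mape(test.target, pred)
            sd = report.cv_sd_mae(name)
            if sd > 0 and abs(report.holdout_mae[name] - report.cv_mean_mae(name)) > 3 * sd:
                warnings.warn(
                    f"{name}: hold-out MAE {report.holdout_mae[name]:.1f} g is more than "
                    f"3 fold-sds from the CV mean {report.cv_mean_mae(name):.1f} g"
                )

    audit.assert_clean(plan.holdout_ids)
    return report


def _modal_config(fold_configs: list[tuple]) -> tuple:
    """Most frequently winning fold configuration; ties -> best inner MAE."""
    if not fold_configs:
        raise ValueError("no fold configurations recorded")
    counts: dict = {}
    for cfg, inner_mae, _, feats in fold_configs:
        key = cfg
        entry = counts.setdefault(key, {"n": 0, "best": np.inf, "feats": feats})
        entry["n"] += 1
        if inner_mae < entry["best"]:
            entry["best"] = inner_mae
            entry["feats"] = feats
    best_key = min(counts, key=lambda k: (-counts[k]["n"], counts[k]["best"]))
    return best_key, counts[best_key]["feats"]
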