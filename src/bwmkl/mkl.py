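"""Weighted multiple-kernel epsilon-SVR.

The regressor predicts a continuous outcome as

    y_hat(x) = sum_i beta_i * K_eta(x, x_i) + b,      beta_i = alpha_i* - alpha_i,

where the Gram matrix is a weighted linear sum of per-modality kernels

    K_eta(x, x') = sum_m eta_m * k_m(x_m, x'_m),      eta_m >= 0, sum eta_m = 1,

each k_m acting only on the feature block of modality m.  One kernel family
(linear, polynomial or radial basis) with its parameters is chosen per
modality; kernels, their parameters, the weights eta, the box constraint C
and the tube width epsilon are all picked by exhaustive grid search scored
with inner cross-validated MAE.

The dual coefficients solve the standard epsilon-insensitive SVR problem

    max_beta  -1/2 beta' K beta - eps * ||beta||_1 + y' beta
    s.t.      sum_i beta_i = 0,   -C <= beta_i <= C,

via a sequential-minimal-optimization loop on maximal-violating pairs; the
one-dimensional pair subproblem is piecewise quadratic (the L1 term kinks
where a coefficient crosses zero) and is solved exactly on each segment.
Targets are standardized internally for conditioning — epsilon and C are
expressed on the standardized target scale — and predictions are returned
in the original units (grams).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import (
    FeatureTable,
    ModalitySchema,
    StandardizationParams,
    standardize,
)

__all__ = [
    "KernelSpec",
    "KernelWeights",
    "MKLModel",
    "SearchGrid",
    "kernel_matrix",
    "combine_kernels",
    "fit_svr_dual",
    "fit_mkl",
    "predict",
    "grid_search_fit",
    "simplex_grid",
    "default_single_config_fitter",
]

_FAMILY_COMPLEXITY = {"linear": 0, "polynomial": 1, "rbf": 2}


@dataclass(frozen=True)
class KernelSpec:
    """One kernel family with its parameters.

    linear:      k(x, x') = x . x'
    polynomial:  k(x, x') = (gamma * x . x' + coef0) ** degree
    rbf:         k(x, x') = exp(-gamma * ||x - x'||^2)
    """

    family: str
    gamma: float | None = None
    degree: int | None = None
    coef0: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_COMPLEXITY:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("rbf kernel requires gamma > 0")
        if self.family == "polynomial":
            if self.degree is None or self.degree < 1:
                raise ValueError("polynomial kernel requires degree >= 1")

    @property
    def complexity(self) -> int:
        return _FAMILY_COMPLEXITY[self.family]

    def label(self) -> str:
        if self.family == "linear":
            return "linear"
        if self.family == "rbf":
            return f"rbf(gamma={self.gamma:g})"
        return f"poly(deg={self.degree},gamma={self.gamma or 1.0:g},coef0={self.coef0 or 0.0:g})"


@dataclass(frozen=True)
class KernelWeights:
    """Nonnegative per-modality weights on the unit simplex."""

    eta: tuple[float, ...]

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if np.any(eta < 0):
            raise ValueError("kernel weights must be nonnegative")
        total = eta.sum()
        if total <= 0:
            raise ValueError("at least one kernel weight must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("kernel weights must sum to 1")


def kernel_matrix(spec: KernelSpec, x, x2=None) -> np.ndarray:
    """Gram matrix k(x_i, x2_j); the square case is symmetric PSD."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x2 = x if x2 is None else np.atleast_2d(np.asarray(x2, dtype=float))
    if x.shape[1] != x2.shape[1]:
        raise ValueError("feature dimensions of the two blocks differ")
    if spec.family == "linear":
        return x @ x2.T
    if spec.family == "polynomial":
        gamma = 1.0 if spec.gamma is None else spec.gamma
        coef0 = 0.0 if spec.coef0 is None else spec.coef0
        return (gamma * (x @ x2.T) + coef0) ** spec.degree
    sq = cdist(x, x2, metric="sqeuclidean")
    return np.exp(-spec.gamma * sq)


def combine_kernels(grams: list[np.ndarray], weights: KernelWeights) -> np.ndarray:
    """K_eta = sum_m eta_m K_m; PSD is preserved for nonnegative weights."""
    if len(grams) != len(weights.eta):
        raise ValueError("number of Gram matrices does not match number of weights")
    shape = grams[0].shape
    for g in grams[1:]:
        if g.shape != shape:
            raise ValueError("Gram matrices have mismatched shapes")
    out = np.zeros(shape)
    for eta_m, g in zip(weights.eta, grams):
        out += eta_m * g
    return out


def _check_psd_with_jitter(k: np.ndarray) -> np.ndarray:
    """Symmetrize, verify PSD, and add a single tiny diagonal jitter.

    Violations beyond the jitter tolerance are errors rather than silent
    repairs: a substantially indefinite matrix means a broken kernel.
    """
    n = k.shape[0]
    if k.shape != (n, n):
        raise ValueError("Gram matrix must be square")
    if np.abs(k - k.T).max() > 1e-8 * max(1.0, np.abs(k).max()):
        raise ValueError("Gram matrix is not symmetric")
    k = (k + k.T) / 2.0
    scale = max(np.trace(k) / n, 1e-12)
    lam_min = float(np.linalg.eigvalsh(k)[0])
    if lam_min < -1e-6 * scale:
        raise ValueError(f"Gram matrix is not PSD (min eigenvalue {lam_min:.3e})")
    return k + (1e-10 * scale) * np.eye(n)


def fit_svr_dual(
    k: np.ndarray,
    y: np.ndarray,
    c: float,
    eps: float,
    tol: float = 1e-6,
    max_iter: int | None = None,
    assume_psd: bool = False,
) -> tuple[np.ndarray, float]:
    """Solve the epsilon-SVR dual on a precomputed Gram matrix.

    Returns ``(beta, b)`` with ``beta_i = alpha_i* - alpha_i`` satisfying
    ``sum_i beta_i = 0`` and ``|beta_i| <= C``.  The bias is the average of
    the KKT values ``y_i - (K beta)_i - eps*sign(beta_i)`` over free support
    vectors (0 < |beta_i| < C); with no free vector it falls back to the
    median KKT residual over support vectors, and with no support vector at
    all (every target inside the tube) to the midpoint of the feasible
    interval for a constant predictor.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if c <= 0 or eps < 0:
        raise ValueError("require C > 0 and eps >= 0")
    k = np.asarray(k, dtype=float)
    if assume_psd:
        # caller guarantees PSD (e.g. a nonnegative combination of Gram
        # matrices); still apply the one-shot jitter for conditioning
        k = (k + k.T) / 2.0
        k = k + (1e-10 * max(np.trace(k) / n, 1e-12)) * np.eye(n)
    else:
        k = _check_psd_with_jitter(k)
    if max_iter is None:
        max_iter = max(20000, 200 * n)

    beta = np.zeros(n)
    f = y.copy()  # f_i = y_i - (K beta)_i, kept incrementally

    def _pair_step(i: int, j: int) -> float:
        """Exact maximizer of the pair subproblem; returns the step t."""
        eta_q = k[i, i] + k[j, j] - 2.0 * k[i, j]
        eta_q = max(eta_q, 1e-12)
        g0 = f[i] - f[j]
        lo = max(-c - beta[i], beta[j] - c)
        hi = min(c - beta[i], beta[j] + c)
        if hi <= lo:
            return 0.0
        # kinks of the L1 term: beta_i + t = 0 and beta_j - t = 0
        pts = sorted({lo, hi, min(max(-beta[i], lo), hi), min(max(beta[j], lo), hi)})
        best_t, best_gain = 0.0, 0.0
        for a, b_ in zip(pts[:-1], pts[1:]):
            if b_ - a <= 0:
                continue
            mid = (a + b_) / 2.0
            s_i = np.sign(beta[i] + mid) or 1.0
            s_j = np.sign(beta[j] - mid) or -1.0
            t_star = (g0 - eps * s_i + eps * s_j) / eta_q
            for t in (min(max(t_star, a), b_), a, b_):
                gain = (
                    t * g0
                    - 0.5 * eta_q * t * t
                    - eps * (abs(beta[i] + t) - abs(beta[i]))
                    - eps * (abs(beta[j] - t) - abs(beta[j]))
                )
                if gain > best_gain:
                    best_t, best_gain = t, gain
        return best_t

    diag = np.diag(k).copy()

    def _kkt_gap() -> float:
        sign_up = np.where(beta != 0, np.sign(beta), 1.0)
        sign_dn = np.where(beta != 0, np.sign(beta), -1.0)
        g_up = np.where(beta < c - 1e-12 * c, f - eps * sign_up, -np.inf)
        g_dn = np.where(beta > -c + 1e-12 * c, f - eps * sign_dn, np.inf)
        return float(np.max(g_up) - np.min(g_dn))

    def _smo_sweep(iters: int) -> bool:
        """Second-order working-pair SMO; True when the KKT gap closes."""
        nonlocal f
        for _ in range(iters):
            sign_up = np.where(beta != 0, np.sign(beta), 1.0)
            sign_dn = np.where(beta != 0, np.sign(beta), -1.0)
            g_up_m = np.where(beta < c - 1e-12 * c, f - eps * sign_up, -np.inf)
            g_dn_m = np.where(beta > -c + 1e-12 * c, f - eps * sign_dn, np.inf)
            i = int(np.argmax(g_up_m))
            if g_up_m[i] - np.min(g_dn_m) <= tol:
                return True
            # maximize the estimated gain (g_up_i - g_dn_j)^2 / curvature
            diff = g_up_m[i] - g_dn_m
            curv = np.maximum(diag[i] + diag - 2.0 * k[:, i], 1e-12)
            with np.errstate(invalid="ignore"):
                gain = np.where(diff > 0, diff * diff / curv, -np.inf)
            gain[i] = -np.inf
            j = int(np.argmax(gain))
            if not np.isfinite(gain[j]):
                return True
            t = _pair_step(i, j)
            if t == 0.0:
                return True  # numerically stuck at the optimum
            beta[i] += t
            beta[j] -= t
            f -= t * (k[:, i] - k[:, j])
        return False

    def _newton_polish(rounds: int) -> None:
        """Equality-constrained Newton steps on the free support vectors.

        SMO alone crawls on (near) low-rank Gram matrices; solving the
        smooth subproblem on the current free set — signs and bounds held
        fixed along the step — closes the tail in a few linear solves.
        """
        nonlocal f
        for _ in range(rounds):
            free = (np.abs(beta) > 1e-10 * c) & (np.abs(beta) < c * (1 - 1e-10))
            idx = np.flatnonzero(free)
            if len(idx) < 2:
                return
            s = np.sign(beta[idx])
            g = f[idx] - eps * s  # gradient of the smooth part on the free set
            kff = k[np.ix_(idx, idx)]
            m = len(idx)
            ridge = 1e-10 * max(np.trace(kff) / m, 1e-12)
            kkt = np.zeros((m + 1, m + 1))
            kkt[:m, :m] = kff + ridge * np.eye(m)
            kkt[:m, m] = 1.0
            kkt[m, :m] = 1.0
            rhs = np.concatenate([g, [0.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            d = sol[:m]
            denom = float(d @ kff @ d)
            if denom <= 0 or not np.all(np.isfinite(d)):
                return
            # largest step keeping every free coefficient inside its
            # sign-consistent box (no kink or bound crossing)
            upper = np.where(s > 0, c - beta[idx], -beta[idx])
            lower = np.where(s > 0, -beta[idx], -c - beta[idx])
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, upper / d, np.where(d < 0, lower / d, np.inf))
            t_max = float(np.min(ratio)) if len(ratio) else 0.0
            t = min(max(float(d @ g) / denom, 0.0), max(t_max, 0.0))
            if t <= 0:
                return
            beta[idx] += t * d
            f -= t * (k[:, idx] @ d)

    converged = False
    chunk = max(100, n)
    spent = 0
    while spent < max_iter:
        iters = min(chunk, max_iter - spent)
        if _smo_sweep(iters):
            converged = True
            break
        spent += iters
        _newton_polish(rounds=10)
        if _kkt_gap() <= tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"SVR dual did not converge in {max_iter} iterations "
            f"(KKT gap {_kkt_gap():.3e}, n={n}, C={c}, eps={eps})"
        )

    sv = np.abs(beta) > 1e-8 * c
    free = sv & (np.abs(beta) < c * (1 - 1e-8))
    if free.any():
        b = float(np.mean(f[free] - eps * np.sign(beta[free])))
    elif sv.any():
        b = float(np.median(f[sv]))
    else:
        b = float((y.max() + y.min()) / 2.0)
    return beta, b


@dataclass(frozen=True)
class SearchGrid:
    """Candidate space for the exhaustive kernel/weight/C/epsilon search.

    ``rbf_gamma`` entries may be the string ``"auto"``, resolved per
    modality to 1/d_m where d_m is the width of that modality's feature
    block.  ``eps_grid`` is expressed as a fraction of the target standard
    deviation (the tube width on the standardized target scale).
    ``eta_step`` is the simplex resolution for the weight candidates.
    """

    families: tuple[str, ...] = ("linear", "polynomial", "rbf")
    rbf_gamma: tuple = (0.01, 0.1, "auto", 1.0)
    poly_degree: tuple[int, ...] = (2, 3)
    poly_coef0: tuple[float, ...] = (0.0, 1.0)
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    eps_grid: tuple[float, ...] = (0.01, 0.1, 0.2)
    eta_step: float | None = 0.25
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("families", "c_grid", "eps_grid"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if "rbf" in self.families and not self.rbf_gamma:
            raise ValueError("rbf_gamma must be non-empty when rbf is searched")
        if "polynomial" in self.families and not (self.poly_degree and self.poly_coef0):
            raise ValueError("polynomial grids must be non-empty")

    def kernel_candidates(self, block_width: int) -> list[KernelSpec]:
        out: list[KernelSpec] = []
        for fam in self.families:
            if fam == "linear":
                out.append(KernelSpec("linear"))
            elif fam == "polynomial":
                for deg in self.poly_degree:
                    for c0 in self.poly_coef0:
                        out.append(KernelSpec("polynomial", gamma=1.0, degree=deg, coef0=c0))
            elif fam == "rbf":
                gammas = []
                for g in self.rbf_gamma:
                    gammas.append(1.0 / block_width if g == "auto" else float(g))
                for g in dict.fromkeys(gammas):
                    out.append(KernelSpec("rbf", gamma=g))
        return out

    @classmethod
    def compact(cls, seed: int = 0) -> "SearchGrid":
        """A small grid for quick experiments and nested protocols."""
        return cls(
            families=("linear", "rbf"),
            rbf_gamma=("auto",),
            c_grid=(1.0, 10.0),
            eps_grid=(0.1,),
            eta_step=0.5,
            cv_folds=5,
            seed=seed,
        )


def simplex_grid(p: int, step: float) -> list[tuple[float, ...]]:
    """All nonnegative weight vectors on the unit simplex with the given step."""
    if p == 1:
        return [(1.0,)]
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1 exactly")
    out = []
    for combo in itertools.product(range(k + 1), repeat=p):
        if sum(combo) == k:
            out.append(tuple(c / k for c in combo))
    return out


@dataclass(frozen=True)
class MKLModel:
    """A trained multiple-kernel epsilon-SVR.

    Stores everything needed for prediction: per-modality feature blocks
    and kernel specs, the simplex weights, the dual coefficients and bias,
    the standardized training inputs and the standardization parameters
    (targets are modeled on the standardized scale; predictions are mapped
    back to grams).
    """

    modalities: tuple[str, ...]
    features_by_modality: dict[str, tuple[str, ...]]
    kernel_specs: dict[str, KernelSpec]
    weights: KernelWeights
    beta: np.ndarray
    bias: float
    c: float
    eps: float
    x_train: np.ndarray  # standardized, columns in self.feature_order
    standardization: StandardizationParams

    @property
    def feature_order(self) -> list[str]:
        return [f for m in self.modalities for f in self.features_by_modality[m]]

    def _block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for m in self.modalities:
            width = len(self.features_by_modality[m])
            out[m] = slice(start, start + width)
            start += width
        return out

    def combined_kernel(self, x: np.ndarray, x2: np.ndarray | None = None) -> np.ndarray:
        blocks = self._block_slices()
        grams = [
            kernel_matrix(self.kernel_specs[m], x[:, blocks[m]],
                          None if x2 is None else x2[:, blocks[m]])
            for m in self.modalities
        ]
        return combine_kernels(grams, self.weights)

    def to_dict(self) -> dict:
        return {
            "format": "bwmkl-model",
            "version": 1,
            "modalities": list(self.modalities),
            "features_by_modality": {m: list(v) for m, v in self.features_by_modality.items()},
            "kernel_specs": {
                m: {"family": s.family, "gamma": s.gamma, "degree": s.degree, "coef0": s.coef0}
                for m, s in self.kernel_specs.items()
            },
            "eta": list(self.weights.eta),
            "beta": self.beta.tolist(),
            "bias": self.bias,
            "C": self.c,
            "eps": self.eps,
            "x_train": self.x_train.tolist(),
            "standardization": {
                "feature_names": list(self.standardization.feature_names),
                "location": self.standardization.location.tolist(),
                "scale": self.standardization.scale.tolist(),
                "target_location": self.standardization.target_location,
                "target_scale": self.standardization.target_scale,
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MKLModel":
        if doc.get("format") != "bwmkl-model" or doc.get("version") != 1:
            raise ValueError("not a recognized model document")
        std = doc["standardization"]
        return cls(
            modalities=tuple(doc["modalities"]),
            features_by_modality={m: tuple(v) for m, v in doc["features_by_modality"].items()},
            kernel_specs={m: KernelSpec(**s) for m, s in doc["kernel_specs"].items()},
            weights=KernelWeights(tuple(doc["eta"])),
            beta=np.asarray(doc["beta"], dtype=float),
            bias=float(doc["bias"]),
            c=float(doc["C"]),
            eps=float(doc["eps"]),
            x_train=np.asarray(doc["x_train"], dtype=float),
            standardization=StandardizationParams(
                feature_names=list(std["feature_names"]),
                location=np.asarray(std["location"], dtype=float),
                scale=np.asarray(std["scale"], dtype=float),
                target_location=float(std["target_location"]),
                target_scale=float(std["target_scale"]),
            ),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MKLModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _layout(schema: ModalitySchema, feature_names: list[str]) -> tuple[tuple[str, ...], dict]:
    """Modalities (with >= 1 selected feature) and their feature blocks."""
    schema = schema.restrict(feature_names)
    modalities = tuple(schema.modalities)
    blocks = {m: tuple(schema.features_of(m)) for m in modalities}
    return modalities, blocks


def fit_mkl(
    table: FeatureTable,
    schema: ModalitySchema,
    kernel_specs: dict[str, KernelSpec],
    weights: KernelWeights,
    c: float,
    eps: float,
) -> MKLModel:
    """Train at one fixed configuration on all rows of *table*.

    ``eps`` is the tube width on the standardized target scale (a fraction
    of the training target sd).
    """
    modalities, blocks = _layout(schema, table.feature_names)
    ordered = [f for m in modalities for f in blocks[m]]
    ordered_table = table.select_features(ordered)
    std_table, params = standardize(ordered_table)
    y_std = (table.target - params.target_location) / params.target_scale

    model = MKLModel(
        modalities=modalities,
        features_by_modality=blocks,
        kernel_specs={m: kernel_specs[m] for m in modalities},
        weights=weights,
        beta=np.zeros(table.n_samples),
        bias=0.0,
        c=c,
        eps=eps,
        x_train=std_table.values,
        standardization=params,
    )
    k = model.combined_kernel(std_table.values)
    beta, b = fit_svr_dual(k, y_std, c, eps, assume_psd=True)
    object.__setattr__(model, "beta", beta)
    object.__setattr__(model, "bias", b)
    return model


def predict(model: MKLModel, table: FeatureTable | np.ndarray) -> np.ndarray:
    """Predicted targets (grams) for new samples.

    A :class:`FeatureTable` may carry extra columns; the model's selected
    columns are extracted by name.  A bare matrix must already use the
    model's feature order.
    """
    params = model.standardization
    if isinstance(table, FeatureTable):
        missing = [f for f in model.feature_order if f not in table.feature_names]
        if missing:
            raise ValueError(f"input lacks model features: {missing}")
        x = table.select_features(model.feature_order).values
    else:
        x = np.atleast_2d(np.asarray(table, dtype=float))
        if x.shape[1] != len(model.feature_order):
            raise ValueError("matrix width does not match model features")
    x_std = (x - params.location) / params.scale
    k_cross = model.combined_kernel(x_std, model.x_train)
    y_std = k_cross @ model.beta + model.bias
    return y_std * params.target_scale + params.target_location


def grid_search_fit(
    table: FeatureTable,
    schema: ModalitySchema,
    selected_features: list[str] | None = None,
    grid: SearchGrid | None = None,
) -> MKLModel:
    """Exhaustive search over kernels x weights x C x epsilon, then refit.

    Every configuration is scored by inner ``grid.cv_folds``-fold CV MAE on
    *table* (training data only); the winner is refit on all rows.  Ties
    are broken toward simpler kernels (linear < polynomial < rbf) and then
    smaller C.  The full search table is attached as ``model.search_log_``.
    """
    from sklearn.model_selection import KFold

    grid = grid or SearchGrid()
    if selected_features is None:
        selected_features = list(table.feature_names)
    if not selected_features:
        raise ValueError("selected_features must be non-empty")
    modalities, blocks = _layout(schema, selected_features)
    ordered = [f for m in modalities for f in blocks[m]]
    work = table.select_features(ordered)
    std_work, params = standardize(work)
    y_std = (work.target - params.target_location) / params.target_scale

    # Per-(modality, kernel) Grams are computed once on the full training
    # set; fold and configuration loops only slice and weight them.
    starts, pos = {}, 0
    for m in modalities:
        starts[m] = slice(pos, pos + len(blocks[m]))
        pos += len(blocks[m])
    candidates = {m: grid.kernel_candidates(len(blocks[m])) for m in modalities}
    grams = {
        m: [kernel_matrix(s, std_work.values[:, starts[m]]) for s in candidates[m]]
        for m in modalities
    }
    p = len(modalities)
    if grid.eta_step is None:
        etas = [tuple(np.full(p, 1.0 / p))]
    else:
        etas = simplex_grid(p, grid.eta_step)
    kf = KFold(n_splits=grid.cv_folds, shuffle=True, random_state=grid.seed)
    folds = list(kf.split(np.arange(work.n_samples)))

    def sort_key(cfg):
        spec_idx, eta, c, eps = cfg
        complexity = tuple(candidates[m][i].complexity for m, i in zip(modalities, spec_idx))
        return (complexity, c, eps, eta, spec_idx)

    configs = sorted(
        itertools.product(
            itertools.product(*[range(len(candidates[m])) for m in modalities]),
            etas,
            grid.c_grid,
            grid.eps_grid,
        ),
        key=sort_key,
    )

    log = []
    best, best_mae = None, np.inf
    for spec_idx, eta, c, eps in configs:
        active = [m for m, w in zip(modalities, eta) if w > 0]
        if not active:
            continue
        k_full = np.zeros((work.n_samples, work.n_samples))
        for m, i, w in zip(modalities, spec_idx, eta):
            if w > 0:
                k_full += w * grams[m][i]
        errs = []
        try:
            for tr, va in folds:
                # model-selection fits use a looser KKT tolerance; the
                # winning configuration is refit at full precision
                beta, b = fit_svr_dual(
                    k_full[np.ix_(tr, tr)], y_std[tr], c, eps, tol=1e-3, assume_psd=True
                )
                pred = k_full[np.ix_(va, tr)] @ beta + b
                errs.append(float(np.mean(np.abs(y_std[va] - pred))))
        except RuntimeError as exc:
            log.append({"config": (spec_idx, eta, c, eps), "error": str(exc)})
            continue
        mae = float(np.mean(errs)) * params.target_scale
        log.append(
            {
                "kernels": {m: candidates[m][i].label() for m, i in zip(modalities, spec_idx)},
                "eta": eta,
                "C": c,
                "eps": eps,
                "cv_mae": mae,
            }
        )
        if mae < best_mae - 1e-12:
            best, best_mae = (spec_idx, eta, c, eps), mae
    if best is None:
        raise RuntimeError("grid search failed: no configuration could be trained")

    spec_idx, eta, c, eps = best
    model = fit_mkl(
        work,
        schema.restrict(ordered),
        {m: candidates[m][i] for m, i in zip(modalities, spec_idx)},
        KernelWeights(eta),
        c,
        eps,
    )
    object.__setattr__(model, "search_log_", log)
    object.__setattr__(model, "cv_mae_", best_mae)
    return model


def default_single_config_fitter(seed: int = 0):
    """A cheap fixed-configuration MKL fitter for inner tuning loops.

    Linear kernel per modality, uniform weights, C = 10, eps = 0.1 target
    sd.  Returns a callable ``(train_table, schema) -> predictor`` whose
    predictor maps a table to predicted targets.
    """

    def fitter(train: FeatureTable, schema: ModalitySchema):
        modalities, _ = _layout(schema, train.feature_names)
        specs = {m: KernelSpec("linear") for m in modalities}
        eta = KernelWeights(tuple(np.full(len(modalities), 1.0 / len(modalities))))
        model = fit_mkl(train, schema, specs, eta, c=10.0, eps=0.1)
        return lambda tbl: predict(model, tbl)

    return fitter
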