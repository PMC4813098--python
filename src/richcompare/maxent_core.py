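"""Presence/background maximum-entropy species distribution model.

Fits the least-informative (maximum-entropy) density over a background
sample subject to soft moment constraints from the presence sample.
Equivalently, maximizes the L1-penalized log-linear likelihood

    J(lambda) = mean_presence lambda . f(x)  -  log Z(lambda)
                - sum_j beta_j |lambda_j|,
    Z(lambda) = sum_background exp(lambda . f(x)),

with per-feature penalties beta_j = beta * s_j / sqrt(m) (s_j the
background scale of feature j, m the presence count, beta the global
regularization multiplier, default 2).  Features are linear and quadratic
terms of the continuous layers (standardized on the background) plus one
indicator per categorical code, which keeps the problem convex.

The raw output exp(lambda . f)/Z sums to 1 over the background; the
logistic output e^H r / (1 + e^H r), with H the entropy of the raw
distribution over the background, maps it to an interpretable suitability
in (0, 1) — the transform used by the classic Maxent 3.3 logistic output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .raster import RasterGrid
from .synthetic_world import Landscape

DEFAULT_BETA = 2.0
DEFAULT_TOL = 1e-5
DEFAULT_BACKGROUND_N = 10_000


# ---------------------------------------------------------------------------
# variable selection


def select_variables(
    layers: dict[str, RasterGrid],
    background_idx: np.ndarray,
    threshold: float = 0.8,
) -> tuple[list[str], list[dict]]:
    """Greedy collinearity filter on the background sample.

    Repeatedly finds the pair of retained layers with background
    |Pearson r| > ``threshold`` and drops the member with the larger mean
    absolute correlation to all other retained layers (ties broken by layer
    order).  Constant layers are dropped up front with a warning.  Returns
    (retained layer names, report of drops with their triggering pair).
    """
    names = list(layers)
    report: list[dict] = []
    cols = {}
    for name in list(names):
        v = layers[name].values.ravel()[background_idx]
        if np.std(v) == 0:
            warnings.warn(f"layer '{name}' is constant on the background; dropped")
            report.append({"dropped": name, "reason": "constant", "pair": None})
            names.remove(name)
        else:
            cols[name] = v
    while True:
        if len(names) < 2:
            break
        mat = np.corrcoef(np.stack([cols[n] for n in names]))
        absr = np.abs(mat)
        np.fill_diagonal(absr, 0.0)
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= threshold:
            break
        # drop the more globally collinear member of the worst pair
        mean_i = absr[i].sum() / (len(names) - 1)
        mean_j = absr[j].sum() / (len(names) - 1)
        drop = i if mean_i >= mean_j else j
        if mean_i == mean_j:
            drop = min(i, j)
        report.append(
            {
                "dropped": names[drop],
                "reason": f"|r|={absr[i, j]:.3f}",
                "pair": (names[i], names[j]),
            }
        )
        names.pop(drop)
    return names, report


# ---------------------------------------------------------------------------
# features


@dataclass
class FeatureSet:
    """Feature matrix over all landscape cells, standardized on background.

    ``matrix`` is (n_cells, n_features) with continuous features scaled to
    background mean 0 / sd 1; categorical indicators are left as 0/1.
    ``scales`` holds each feature's background standard deviation *after*
    standardization (1 for continuous, the indicator sd for categories) and
    enters the per-feature regularization schedule.
    """

    names: list[str]
    matrix: np.ndarray
    scales: np.ndarray

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def build_features(
    landscape: Landscape,
    retained_layers: list[str],
    background_idx: np.ndarray,
) -> FeatureSet:
    """Linear + quadratic features per retained layer, plus substrate indicators."""
    names: list[str] = []
    raw_cols: list[np.ndarray] = []
    continuous: list[bool] = []
    for lname in retained_layers:
        v = landscape.continuous_layers[lname].values.ravel()
        names += [f"{lname}:linear", f"{lname}:quadratic"]
        raw_cols += [v, v**2]
        continuous += [True, True]
    codes = landscape.categorical_layer.values.ravel().astype(int)
    for code in landscape.categorical_codes:
        names.append(f"substrate=={code}")
        raw_cols.append((codes == code).astype(float))
        continuous.append(False)
    matrix = np.column_stack(raw_cols)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite feature values")
    scales = np.empty(matrix.shape[1])
    for j, is_cont in enumerate(continuous):
        bg = matrix[background_idx, j]
        sd = bg.std()
        if is_cont:
            if sd == 0:
                matrix[:, j] = 0.0
                scales[j] = 1.0
            else:
                matrix[:, j] = (matrix[:, j] - bg.mean()) / sd
                scales[j] = 1.0
        else:
            scales[j] = sd if sd > 0 else 1.0
    return FeatureSet(names, matrix, scales)


def sample_background(
    n_cells: int, n_background: int = DEFAULT_BACKGROUND_N, seed: int = 0
) -> np.ndarray:
    """Uniform background cell indices, without replacement (all cells if fewer)."""
    rng = np.random.default_rng(seed)
    if n_cells <= n_background:
        return np.arange(n_cells)
    return np.sort(rng.choice(n_cells, size=n_background, replace=False))


# ---------------------------------------------------------------------------
# model fitting


@dataclass
class MaxentModel:
    features: FeatureSet
    lam: np.ndarray
    background_idx: np.ndarray
    log_z: float
    entropy: float  # H of the raw distribution over background, in [0, log n_bg]
    beta: float
    objective: float
    n_iter: int
    converged: bool


def _objective_parts(
    lam: np.ndarray, f_pres: np.ndarray, f_bg: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """(smooth objective value, gradient, log Z)."""
    eta_bg = f_bg @ lam
    log_z = logsumexp(eta_bg)
    q = np.exp(eta_bg - log_z)
    mean_pres = f_pres.mean(axis=0)
    value = float(mean_pres @ lam - log_z)
    grad = mean_pres - q @ f_bg
    return value, grad, float(log_z)


def fit_maxent(
    presence_idx: np.ndarray,
    background_idx: np.ndarray,
    features: FeatureSet,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = 5000,
) -> MaxentModel:
    """Fit by proximal-gradient (soft-threshold) ascent with backtracking.

    The penalized objective is concave, so the first-order method converges
    to the global optimum; iteration stops when the objective improves by
    less than ``tol``.
    """
    presence_idx = np.asarray(presence_idx, dtype=int)
    background_idx = np.asarray(background_idx, dtype=int)
    if presence_idx.size == 0:
        raise ValueError("at least one presence is required")
    f_pres = features.matrix[presence_idx]
    f_bg = features.matrix[background_idx]
    if not (np.all(np.isfinite(f_pres)) and np.all(np.isfinite(f_bg))):
        raise ValueError("non-finite feature values")
    m = presence_idx.size
    beta_j = beta * features.scales / np.sqrt(m)

    lam = np.zeros(features.n_features)
    value, grad, log_z = _objective_parts(lam, f_pres, f_bg)
    pen_obj = value - beta_j @ np.abs(lam)
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        while True:
            cand = lam + step * grad
            # soft threshold (the proximal map of the L1 penalty)
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta_j, 0.0)
            delta = cand - lam
            cand_value, cand_grad, cand_log_z = _objective_parts(cand, f_pres, f_bg)
            # backtracking: require the quadratic upper model to hold
            if cand_value >= value + grad @ delta - (delta @ delta) / (2 * step) - 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        new_pen_obj = cand_value - beta_j @ np.abs(cand)
        if new_pen_obj < pen_obj - 1e-12 and step < 1e-12:
            break  # cannot make progress
        lam, value, grad, log_z = cand, cand_value, cand_grad, cand_log_z
        improvement = new_pen_obj - pen_obj
        pen_obj = new_pen_obj
        step *= 1.3
        if 0 <= improvement < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"maxent fit did not converge within {max_iter} iterations")
    eta_bg = f_bg @ lam
    log_q = eta_bg - logsumexp(eta_bg)
    entropy = float(-np.sum(np.exp(log_q) * log_q))
    return MaxentModel(
        features=features,
        lam=lam,
        background_idx=background_idx,
        log_z=log_z,
        entropy=entropy,
        beta=beta,
        objective=pen_obj,
        n_iter=it,
        converged=converged,
    )


def predict_raw(model: MaxentModel, cell_idx: np.ndarray | None = None) -> np.ndarray:
    """Raw (exponential-family) density; sums to 1 over the background set."""
    if cell_idx is None:
        eta = model.features.matrix @ model.lam
    else:
        eta = model.features.matrix[np.asarray(cell_idx, int)] @ model.lam
    return np.exp(eta - model.log_z)


def raw_to_logistic(model: MaxentModel, raw: np.ndarray) -> np.ndarray:
    """Entropy-calibrated logistic suitability in (0, 1).

    A cell with typical (uniform-level) raw density maps to 0.5; the
    transform is strictly increasing in raw.
    """
    scaled = np.exp(model.entropy) * np.asarray(raw, float)
    return scaled / (1.0 + scaled)


def predict_logistic(model: MaxentModel, cell_idx: np.ndarray | None = None) -> np.ndarray:
    return raw_to_logistic(model, predict_raw(model, cell_idx))


# ---------------------------------------------------------------------------
# evaluation


def auc_score(positive_scores: np.ndarray, negative_scores: np.ndarray) -> float:
    """AUC as P(positive outscores negative), ties counted half.

    Rank-based (Mann-Whitney U), exactly equal to the exhaustive pairwise
    comparison with half credit for ties.
    """
    pos = np.asarray(positive_scores, float)
    neg = np.asarray(negative_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one positive and one negative score")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class CVResult:
    fold_aucs: list[float]
    mean_auc: float
    mean_logistic: np.ndarray  # average of the fold models' logistic surfaces
    k: int


def cv_auc(
    presence_idx: np.ndarray,
    background_idx: np.ndarray,
    features: FeatureSet,
    k: int = 10,
    seed: int = 0,
    beta: float = DEFAULT_BETA,
    tol: float = DEFAULT_TOL,
) -> CVResult:
    """k-fold cross-validated AUC with background points as negatives.

    Presences are shuffled (seeded) into k folds; each fold model is trained
    on the remaining presences and scored with the held-out presences as
    positives versus the shared background as negatives.  The returned
    surface is the mean of the k fold models' logistic grids — the averaged
    "final model".
    """
    presence_idx = np.asarray(presence_idx, int)
    if presence_idx.size < 2:
        raise ValueError("cross-validated AUC needs at least 2 presences")
    if presence_idx.size < k:
        warnings.warn(
            f"only {presence_idx.size} presences; reducing folds from {k}"
        )
        k = presence_idx.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(presence_idx.size)
    folds = np.array_split(perm, k)
    fold_aucs: list[float] = []
    mean_logistic = np.zeros(features.matrix.shape[0])
    for fold in folds:
        test_idx = presence_idx[fold]
        train_mask = np.ones(presence_idx.size, dtype=bool)
        train_mask[fold] = False
        train_idx = presence_idx[train_mask]
        model = fit_maxent(train_idx, background_idx, features, beta=beta, tol=tol)
        logistic_all = predict_logistic(model)
        fold_aucs.append(
            auc_score(logistic_all[test_idx], logistic_all[background_idx])
        )
        mean_logistic += logistic_all
    mean_logistic /= k
    return CVResult(fold_aucs, float(np.mean(fold_aucs)), mean_logistic, k)
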