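"""Feature standardization, LASSO selection, class-weighted SVM and metrics.

The selector minimizes the L1-penalized least-squares objective

    f(theta) = 1/2 ||y - X theta||_2^2 + lam ||theta||_1

over subject feature matrices X (rows = subjects) with labels y in {-1, +1},
via cyclic coordinate descent with soft-thresholding; the nonzero
coefficients define the selected feature subset.  lam >= lam_max =
max_j |X_j . y| provably yields the empty support.  The classifier is a
soft-margin SVM, sign[w . phi(x) + b], with per-class weights (inverse class
frequency by default) rescaling the slack penalty c; hyperparameters are
chosen by exhaustive grid search with inner cross-validation on training
subjects only.  Reported metrics are accuracy, sensitivity, specificity and
AUC, in percent, with EMCI (+1) as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an install-time dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardizer:
    """Per-feature affine transform to zero mean, unit standard deviation.

    Statistics come from the training matrix only (population, divide-by-N,
    standard deviation); zero-variance columns are mapped to zero.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.mean.shape[0]:
            raise ValueError(f"feature matrix with {X.shape} does not match standardizer dim {self.mean.shape[0]}")
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        Z = (X - self.mean) / safe_sd
        Z[:, self.sd == 0] = 0.0
        return Z


def fit_standardizer(train_features: np.ndarray) -> Standardizer:
    X = np.asarray(train_features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a nonempty 2D training matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to estimate spread")
    return Standardizer(mean=X.mean(axis=0), sd=X.std(axis=0))


def apply_standardizer(standardizer: Standardizer, features: np.ndarray) -> np.ndarray:
    return standardizer.transform(features)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LassoFit:
    theta: np.ndarray
    lam: float
    support: np.ndarray  # sorted indices of nonzero coefficients
    n_samples: int
    n_features: int

    @property
    def mask(self) -> np.ndarray:
        mask = np.zeros(self.n_features, dtype=bool)
        mask[self.support] = True
        return mask

    def select(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.support]


def lasso_objective(theta: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """The penalized objective 1/2 ||y - X theta||^2 + lam ||theta||_1.

    ``X`` has one row per subject (the N x d transpose of the d x N design
    convention); the value is identical either way.
    """
    theta = np.asarray(theta, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0] or X.shape[1] != theta.shape[0]:
        raise ValueError(f"inconsistent dims: X {X.shape}, y {y.shape}, theta {theta.shape}")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    resid = y - X @ theta
    return 0.5 * float(resid @ resid) + lam * float(np.abs(theta).sum())


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lam for which the all-zero coefficient vector is optimal."""
    return float(np.abs(np.asarray(X, dtype=np.float64).T @ np.asarray(y, dtype=np.float64)).max())


@njit(cache=False)
def _cd_lasso(X, y, lam, max_iter, tol, theta0):  # pragma: no cover - exercised via lasso_select
    n, d = X.shape
    theta = theta0.copy()
    resid = y - X @ theta
    col_sq = np.zeros(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        col_sq[j] = s
    for _it in range(max_iter):
        max_delta = 0.0
        for j in range(d):
            if col_sq[j] == 0.0:
                continue
            old = theta[j]
            rho = old * col_sq[j]
            for i in range(n):
                rho += X[i, j] * resid[i]
            if rho > lam:
                new = (rho - lam) / col_sq[j]
            elif rho < -lam:
                new = (rho + lam) / col_sq[j]
            else:
                new = 0.0
            delta = new - old
            if delta != 0.0:
                for i in range(n):
                    resid[i] -= X[i, j] * delta
                theta[j] = new
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
        if max_delta < tol:
            break
    return theta


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 2000,
    tol: float = 1e-9,
    warm_start: np.ndarray | None = None,
) -> LassoFit:
    """Minimize the L1-penalized objective by cyclic coordinate descent.

    Returns the fit with its support (nonzero-coefficient indices), which acts
    as a column mask on feature matrices.  ``warm_start`` seeds the iteration
    (useful along a descending lam path); the minimizer is unaffected.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"inconsistent dims: X {X.shape}, y {y.shape}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError(f"lam must be nonnegative, got {lam}")
    theta0 = np.zeros(X.shape[1]) if warm_start is None else np.asarray(warm_start, dtype=np.float64)
    if theta0.shape != (X.shape[1],):
        raise ValueError("warm_start dimension mismatch")
    theta = _cd_lasso(X, y, float(lam), int(max_iter), float(tol), theta0)
    # snap numerically-dead coordinates to exact zero
    theta[np.abs(theta) < 1e-12] = 0.0
    support = np.flatnonzero(theta)
    return LassoFit(theta=theta, lam=float(lam), support=support, n_samples=X.shape[0], n_features=X.shape[1])


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 30, min_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from min_ratio * lam_max up to lam_max (descending)."""
    lmax = lambda_max(X, y)
    if lmax == 0:
        return np.zeros(1)
    return np.geomspace(lmax, min_ratio * lmax, n_lambdas)


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

#: modest exhaustive-search grid: kernel x c x RBF width
DEFAULT_SVM_GRID: tuple[dict, ...] = tuple(
    [{"kernel": "linear", "C": c} for c in (0.1, 1.0, 10.0, 100.0)]
    + [
        {"kernel": "rbf", "C": c, "gamma": g}
        for c in (0.1, 1.0, 10.0, 100.0)
        for g in ("scale", 1e-3, 1e-4)
    ]
)


def inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    """Class weights proportional to inverse class frequency, normalized to sum 1.

    A 70:50 EMCI:NC cohort yields weights 50/120 for EMCI and 70/120 for NC.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    inv = 1.0 / counts
    inv = inv / inv.sum()
    return {int(c): float(w) for c, w in zip(classes, inv)}


@dataclass
class SvmFit:
    estimator: SVC
    kernel: str
    C: float
    gamma: object
    class_weights: dict[int, float]
    n_features: int


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[dict] = DEFAULT_SVM_GRID,
    class_weights: dict[int, float] | None = None,
    seed: int = 0,
    inner_cv_folds: int = 3,
) -> SvmFit:
    """Exhaustive hyperparameter search with inner CV on training data only."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if class_weights is None:
        class_weights = inverse_frequency_weights(y)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    def make(params: dict) -> SVC:
        return SVC(class_weight=class_weights, random_state=seed, **params)

    best_params, best_score = None, -np.inf
    if len(grid) > 1:
        n_splits = min(inner_cv_folds, int(np.bincount(np.searchsorted(classes, y)).min()))
        n_splits = max(n_splits, 2)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        for params in grid:
            scores = []
            for tr, te in folds:
                if np.unique(y[tr]).size < 2:
                    continue
                clf = make(params).fit(X[tr], y[tr])
                scores.append(float((clf.predict(X[te]) == y[te]).mean()))
            score = float(np.mean(scores)) if scores else -np.inf
            if score > best_score:
                best_score, best_params = score, params
    else:
        best_params = dict(grid[0])
    estimator = make(best_params).fit(X, y)
    return SvmFit(
        estimator=estimator,
        kernel=best_params["kernel"],
        C=float(best_params["C"]),
        gamma=best_params.get("gamma", "scale"),
        class_weights=class_weights,
        n_features=X.shape[1],
    )


def predict(fit: SvmFit, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+1/-1) and decision scores; a score of exactly 0 maps to +1."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != fit.n_features:
        raise ValueError(f"feature dim {X.shape} does not match fit dim {fit.n_features}")
    scores = fit.estimator.decision_function(X)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


def svm_primal_objective(
    w: np.ndarray,
    b: float,
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    class_weights: dict[int, float] | None = None,
) -> float:
    """Soft-margin primal objective 1/2 w.w + c sum_k weight_k xi_k (linear kernel).

    Slacks are xi_k = max(0, 1 - y_k (w . x_k + b)); used to verify trained
    solutions against random feasible points, not for training.
    """
    w = np.asarray(w, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    margins = y * (X @ w + b)
    xi = np.maximum(0.0, 1.0 - margins)
    if class_weights is not None:
        weights = np.array([class_weights[int(t)] for t in y])
        xi = xi * weights
    return 0.5 * float(w @ w) + c * float(xi.sum())


# ---------------------------------------------------------------------------
# lambda sweep
# ---------------------------------------------------------------------------


def sweep_alpha(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    lam_grid: Sequence[float] | None = None,
    inner_cv_folds: int = 3,
    seed: int = 0,
    max_features: int | None = None,
    n_lambdas: int = 30,
    svm_grid: Sequence[dict] = ({"kernel": "linear", "C": 1.0},),
) -> tuple[float, pd.DataFrame]:
    """Pick the regularization strength by inner-CV accuracy on training data.

    For each lam the LASSO -> SVM pipeline (standardize, select, classify) is
    scored by stratified inner cross-validation over training subjects only.
    lam values whose selected-feature count exceeds ``max_features`` (default:
    the number of training subjects — an overfitting guard) or select nothing
    are discarded.  Ties break toward the larger lam (sparser model).
    Returns the winning lam and the accuracy-vs-lam curve.
    """
    X = np.asarray(train_features, dtype=np.float64)
    y = np.asarray(train_labels, dtype=int)
    if lam_grid is None:
        std = fit_standardizer(X)
        lam_grid = default_lambda_grid(std.transform(X), y, n_lambdas=n_lambdas)
    lam_grid = sorted(set(float(l) for l in lam_grid), reverse=True)
    if not lam_grid:
        raise ValueError("empty lam grid")
    if max_features is None:
        max_features = X.shape[0]
    classes = np.unique(y)
    n_splits = max(2, min(inner_cv_folds, int(np.bincount(np.searchsorted(classes, y)).min())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    std_full = fit_standardizer(X)
    Z_full = std_full.transform(X)
    fold_data = []
    for tr, te in folds:
        std = fit_standardizer(X[tr])
        fold_data.append((std.transform(X[tr]), std.transform(X[te]), y[tr], y[te]))
    # warm starts along the descending lam path, one per design matrix
    warm_full = np.zeros(X.shape[1])
    warm_folds = [np.zeros(X.shape[1]) for _ in folds]
    rows = []
    for lam in lam_grid:
        fit_full = lasso_select(Z_full, y, lam, warm_start=warm_full)
        warm_full = fit_full.theta
        n_sel_full = fit_full.support.size
        if n_sel_full == 0 or n_sel_full > max_features:
            rows.append({"lam": lam, "n_selected": n_sel_full, "accuracy": np.nan, "retained": False})
            continue
        accs = []
        for fi, (Ztr, Zte, ytr, yte) in enumerate(fold_data):
            fit = lasso_select(Ztr, ytr, lam, warm_start=warm_folds[fi])
            warm_folds[fi] = fit.theta
            if fit.support.size == 0:
                continue
            svm = train_svm(fit.select(Ztr), ytr, grid=svm_grid, seed=seed)
            labels, _ = predict(svm, fit.select(Zte))
            accs.append(float((labels == yte).mean()))
        if not accs:
            rows.append({"lam": lam, "n_selected": n_sel_full, "accuracy": np.nan, "retained": False})
            continue
        rows.append({"lam": lam, "n_selected": n_sel_full, "accuracy": float(np.mean(accs)), "retained": True})
    curve = pd.DataFrame(rows)
    retained = curve[curve["retained"]]
    if retained.empty:
        raise ValueError("every lam in the grid was discarded by the overfit guard")
    # idxmax returns the first maximum; the grid is descending, so ties break
    # toward the larger (sparser) lam
    best_lam = float(retained.loc[retained["accuracy"].idxmax(), "lam"])
    return best_lam, curve


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None, positive: int = 1
) -> dict[str, float]:
    """ACC, SEN, SPE and AUC in percent; sensitivity is the EMCI-detection rate.

    AUC is the rank statistic on decision scores (tied scores earn half
    credit); it requires ``scores`` and both classes present in ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if np.unique(y_true).size < 2:
        raise ValueError("both classes must be present to compute SEN/SPE/AUC")
    pos = y_true == positive
    tp = int(np.sum(pos & (y_pred == positive)))
    tn = int(np.sum(~pos & (y_pred != positive)))
    fp = int(np.sum(~pos & (y_pred == positive)))
    fn = int(np.sum(pos & (y_pred != positive)))
    metrics = {
        "ACC": 100.0 * (tp + tn) / y_true.size,
        "SEN": 100.0 * tp / (tp + fn),
        "SPE": 100.0 * tn / (tn + fp),
    }
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != y_true.shape:
            raise ValueError("scores must parallel y_true")
        metrics["AUC"] = 100.0 * float(roc_auc_score(pos.astype(int), scores))
    return metrics


@dataclass
class MetricsReport:
    """Per-fold and mean ACC/SEN/SPE/AUC (percent) for one configuration."""

    name: str
    per_fold: pd.DataFrame  # columns: fold, ACC, SEN, SPE, AUC, ...

    def mean(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in ("ACC", "SEN", "SPE", "AUC")}

    def to_frame(self) -> pd.DataFrame:
        mean_row = {"fold": "mean", **self.mean()}
        return pd.concat([self.per_fold, pd.DataFrame([mean_row])], ignore_index=True)
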