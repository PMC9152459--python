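"""Wrapper-selected linear support-vector regression with fold bootstrap.

Each HRV metric is estimated from the thermal predictors by an
epsilon-insensitive linear-kernel SVR.  Because 30 candidate predictors
rival the 32 subjects, a greedy forward wrapper (scored by cross-validated
Spearman correlation) first reduces the predictor set.  Stability against
the arbitrary choice of cross-validation folds is quantified by re-running
the fivefold CV over many random fold partitions ("fold bootstrap") and
reporting the distribution of correlation coefficients; the iteration
closest to the mean is kept as the representative model.

The core lives in :class:`WrapperLinearSVR`, a scikit-learn compatible
estimator (``fit``/``predict``/``get_params``); the module-level functions
are thin wrappers over it and over the fold machinery.

Normalization is MATLAB-style z-scoring (ddof=1) of both predictors and
target, fit on training rows only inside every fold so that held-out rows
never influence the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .signals import DegenerateInputError

__all__ = [
    "ModelConfig",
    "ScalingRecord",
    "FittedModel",
    "BootstrapResult",
    "WrapperLinearSVR",
    "zscore_features",
    "wrapper_select",
    "fit_linear_svr",
    "crossval_predict",
    "bootstrap_cv",
    "weights_report",
    "random_fold_assignment",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the SVR + selection + bootstrap machinery.

    The kernel is fixed to linear.  C and epsilon apply in z-scored target
    units; ``max_features`` caps the wrapper at 12 predictors (the largest
    per-metric predictor count the selection is expected to need).

    ``improvement_tol`` is the minimum gain in CV Spearman r required to
    accept another predictor; ``None`` (default) uses the adaptive rule
    ``1/sqrt(n - 1)`` — one standard error of a null Spearman estimate at
    the cohort size — so that statistically meaningless gains, which pure
    chance supplies in abundance when 30 candidates rival 32 subjects, do
    not grow the model.
    """

    C: float = 1.0
    epsilon: float = 0.1
    k_folds: int = 5
    n_bootstrap: int = 1000
    rng_seed: int = 0
    max_features: int = 12
    improvement_tol: float | None = None
    select_n_splits: int = 5
    select_per_fold: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")
        if self.k_folds < 2 or self.n_bootstrap < 1 or self.max_features < 1:
            raise ValueError("invalid fold/bootstrap/cap configuration")


@dataclass(frozen=True)
class ScalingRecord:
    """Column means/SDs (ddof=1) sufficient to z-score new data."""

    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[list(self.columns)] - self.mean) / self.sd


@dataclass(frozen=True)
class FittedModel:
    """A fitted linear SVR in z-score space, with its scaling records.

    ``weights`` act on z-scored selected features to produce a z-scored
    target; ``predict`` maps back to physical units.
    """

    selected_features: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        xz = (X[list(self.selected_features)].to_numpy(dtype=float) - self.x_mean) / self.x_sd
        return (xz @ self.weights + self.intercept) * self.y_sd + self.y_mean


@dataclass(frozen=True)
class BootstrapResult:
    """Distribution of CV correlations over random fold partitions."""

    r_per_iteration: np.ndarray
    r_mean: float
    r_sd: float
    representative_model: FittedModel
    representative_predictions: np.ndarray
    representative_iteration: int


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def zscore_features(X) -> tuple[pd.DataFrame, ScalingRecord]:
    """Z-score each column (ddof=1); constant columns are dropped with a warning."""
    X = _as_frame(X)
    if len(X) < 2:
        raise DegenerateInputError("z-scoring needs at least two rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all predictor columns are constant")
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping constant predictor column(s): {dropped}", stacklevel=2)
    cols = tuple(X.columns[keep])
    record = ScalingRecord(
        columns=cols,
        mean=mean[keep].to_numpy(),
        sd=sd[keep].to_numpy(),
    )
    return record.transform(X), record


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    r = stats.spearmanr(a, b).statistic
    return float(r) if np.isfinite(r) else -2.0  # constant input: worst score


def random_fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """A near-equal-size k-fold partition of n rows via a seeded shuffle.

    For n=32, k=5 the fold sizes are {7, 7, 6, 6, 6}.
    """
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} non-empty folds")
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, idx in enumerate(np.array_split(perm, k)):
        assignment[idx] = fold
    return assignment


class WrapperLinearSVR(RegressorMixin, BaseEstimator):
    """Greedy-forward-selected linear-kernel SVR, scikit-learn style.

    ``fit`` z-scores predictors and target (MATLAB convention, ddof=1),
    runs sequential forward selection scored by cross-validated Spearman
    correlation on a seeded fold partition, then refits the SVR on all
    rows using the selected predictors.  ``predict`` returns values in the
    target's physical units.

    Parameters
    ----------
    C, epsilon : float
        SVR regularization and insensitive-tube width (z-scored units).
    k_folds : int
        Folds used by the selection criterion.
    max_features : int
        Cap on the selected predictor count.
    improvement_tol : float
        Minimum CV-Spearman gain to accept another predictor.
    random_state : int
        Seeds the selection fold partition.

    Attributes
    ----------
    selected_features_ : tuple of str
    coef_ : ndarray, weights in z-score space (one per selected feature)
    intercept_ : float, in z-score space
    model_ : FittedModel, the full serializable fit
    """

    def __init__(
        self,
        C: float = 1.0,
        epsilon: float = 0.1,
        k_folds: int = 5,
        max_features: int = 12,
        improvement_tol: float | None = None,
        random_state: int = 0,
    ):
        self.C = C
        self.epsilon = epsilon
        self.k_folds = k_folds
        self.max_features = max_features
        self.improvement_tol = improvement_tol
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            C=self.C,
            epsilon=self.epsilon,
            k_folds=self.k_folds,
            rng_seed=self.random_state,
            max_features=self.max_features,
            improvement_tol=self.improvement_tol,
        )

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(X.to_numpy())) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in X or y")
        cfg = self._config()
        selected = wrapper_select(X, y, cfg)
        self.selected_features_ = tuple(selected)
        self.model_ = fit_linear_svr(X[selected], y, cfg)
        self.coef_ = self.model_.weights
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(_as_frame(X))

    def bootstrap(self, X, y, n_bootstrap: int = 1000) -> BootstrapResult:
        """Fold-bootstrap stability analysis using this estimator's config."""
        cfg = ModelConfig(
            C=self.C,
            epsilon=self.epsilon,
            k_folds=self.k_folds,
            n_bootstrap=n_bootstrap,
            rng_seed=self.random_state,
            max_features=self.max_features,
            improvement_tol=self.improvement_tol,
        )
        return bootstrap_cv(X, y, cfg)


def _fit_svr_z(Xz: np.ndarray, yz: np.ndarray, cfg: ModelConfig) -> SVR:
    svr = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
    svr.fit(Xz, yz)
    return svr


def fit_linear_svr(X, y, cfg: ModelConfig | None = None) -> FittedModel:
    """Fit the epsilon-insensitive linear SVR on all rows.

    Predictors and target are z-scored internally (ddof=1); the returned
    :class:`FittedModel` carries the scalings so predictions come back in
    physical units.  Deterministic for fixed input.
    """
    cfg = cfg or ModelConfig()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        warnings.warn(
            f"fitting {X.shape[1]} predictors with only {X.shape[0]} rows",
            stacklevel=2,
        )
    Xz, record = zscore_features(X)
    y_mean, y_sd = float(np.mean(y)), float(np.std(y, ddof=1))
    if y_sd == 0.0:
        # constant target: trivial model, no scaling of y
        return FittedModel(
            selected_features=record.columns,
            weights=np.zeros(len(record.columns)),
            intercept=0.0,
            x_mean=record.mean,
            x_sd=record.sd,
            y_mean=y_mean,
            y_sd=1.0,
        )
    yz = (y - y_mean) / y_sd
    svr = _fit_svr_z(Xz.to_numpy(), yz, cfg)
    return FittedModel(
        selected_features=record.columns,
        weights=svr.coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        x_mean=record.mean,
        x_sd=record.sd,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def crossval_predict(
    X, y, fold_assignment: np.ndarray, cfg: ModelConfig | None = None
) -> np.ndarray:
    """Out-of-fold SVR predictions under a given fold partition.

    For each fold, feature/target z-scoring and the SVR fit use training
    rows only; every row is predicted exactly once, in physical units.
    """
    cfg = cfg or ModelConfig()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    fold_assignment = np.asarray(fold_assignment)
    folds = np.unique(fold_assignment)
    if folds.size < 2:
        raise ValueError("need at least two non-empty folds")
    preds = np.empty(y.size, dtype=float)
    for fold in folds:
        test = fold_assignment == fold
        train = ~test
        if not test.any() or not train.any():
            raise ValueError(f"fold {fold} leaves an empty train or test set")
        model = fit_linear_svr(X.iloc[train], y[train], cfg)
        preds[test] = model.predict(X.iloc[test])
    return preds


def _cv_predict_np(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, cfg: ModelConfig
) -> np.ndarray:
    """Out-of-fold predictions on plain arrays (fast path; same math as
    :func:`crossval_predict`: per-fold z-scoring of features and target on
    training rows only)."""
    preds = np.empty(y.size)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        Xtr = X[train]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        keep = sd > 0
        ym, ysd = y[train].mean(), y[train].std(ddof=1)
        if not keep.any() or ysd == 0:
            preds[test] = ym
            continue
        svr = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
        svr.fit((Xtr[:, keep] - mu[keep]) / sd[keep], (y[train] - ym) / ysd)
        z = (X[test][:, keep] - mu[keep]) / sd[keep]
        preds[test] = svr.predict(z) * ysd + ym
    return preds


def _cv_spearman_np(
    X: np.ndarray, y: np.ndarray, folds: np.ndarray, cfg: ModelConfig
) -> float:
    return _spearman(_cv_predict_np(X, y, folds, cfg), y)


def wrapper_select(X, y, cfg: ModelConfig | None = None) -> list[str]:
    """Greedy sequential forward selection scored by CV Spearman r.

    Starting from the empty set, each step adds the feature that maximizes
    the out-of-fold Spearman correlation of the SVR, averaged over
    ``select_n_splits`` seeded random fold partitions (averaging damps the
    fold-to-fold noise that a single split would reward); selection stops
    when no candidate improves the score by more than ``improvement_tol``
    or ``max_features`` is reached.  Ties go to the lowest column index.
    """
    cfg = cfg or ModelConfig()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1 or X.shape[0] < 2 * cfg.k_folds:
        raise ValueError("need >= 1 column and >= 2*k_folds rows for selection")
    if np.std(y, ddof=1) == 0.0:
        raise DegenerateInputError("constant target: feature selection impossible")
    tol = (
        cfg.improvement_tol
        if cfg.improvement_tol is not None
        else 1.0 / np.sqrt(len(X) - 1)
    )
    rng = np.random.default_rng(cfg.rng_seed)
    splits = [
        random_fold_assignment(len(X), cfg.k_folds, rng)
        for _ in range(cfg.select_n_splits)
    ]
    Xnp = X.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(X.columns)}
    selected: list[str] = []
    remaining = list(X.columns)
    best_score = -np.inf
    while remaining and len(selected) < cfg.max_features:
        step_best: tuple[float, str] | None = None
        base = [col_idx[c] for c in selected]
        for col in remaining:  # column order breaks ties (strict > keeps first best)
            cols = base + [col_idx[col]]
            score = float(
                np.mean([_cv_spearman_np(Xnp[:, cols], y, f, cfg) for f in splits])
            )
            if step_best is None or score > step_best[0]:
                step_best = (score, col)
        score, col = step_best
        if selected and score <= best_score + tol:
            break
        selected.append(col)
        remaining.remove(col)
        best_score = score
    return selected


def bootstrap_cv(X, y, cfg: ModelConfig | None = None) -> BootstrapResult:
    """Fold-bootstrap: CV Spearman r over ``n_bootstrap`` random partitions.

    Feature selection runs once on the full dataset before the bootstrap
    (one fixed predictor set per metric); set ``cfg.select_per_fold`` to
    re-select inside every training fold instead, trading the selection
    optimism of the default ordering for a heavier, fully nested run.

    The representative iteration is the one whose r is closest to the mean
    (ties: lowest index); its out-of-fold predictions are returned along
    with the model refit on all rows.
    """
    cfg = cfg or ModelConfig()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if cfg.select_per_fold:
        selected = list(X.columns)  # selection happens inside each training fold
    else:
        selected = wrapper_select(X, y, cfg)
    rng = np.random.default_rng(cfg.rng_seed)
    r_values = np.empty(cfg.n_bootstrap)
    all_preds = np.empty((cfg.n_bootstrap, y.size))
    Xsel = X[selected].to_numpy(dtype=float)
    for i in range(cfg.n_bootstrap):
        folds = random_fold_assignment(len(X), cfg.k_folds, rng)
        if cfg.select_per_fold:
            preds = _per_fold_selected_predict(X, y, folds, cfg)
        else:
            preds = _cv_predict_np(Xsel, y, folds, cfg)
        all_preds[i] = preds
        r_values[i] = _spearman(preds, y)
    r_mean = float(np.mean(r_values))
    r_sd = float(np.std(r_values, ddof=1)) if cfg.n_bootstrap > 1 else 0.0
    rep = int(np.argmin(np.abs(r_values - r_mean)))
    rep_model = fit_linear_svr(X[selected] if not cfg.select_per_fold else X, y, cfg)
    return BootstrapResult(
        r_per_iteration=r_values,
        r_mean=r_mean,
        r_sd=r_sd,
        representative_model=rep_model,
        representative_predictions=all_preds[rep].copy(),
        representative_iteration=rep,
    )


def _per_fold_selected_predict(
    X: pd.DataFrame, y: np.ndarray, folds: np.ndarray, cfg: ModelConfig
) -> np.ndarray:
    preds = np.empty(y.size, dtype=float)
    inner = ModelConfig(
        C=cfg.C,
        epsilon=cfg.epsilon,
        k_folds=cfg.k_folds,
        rng_seed=cfg.rng_seed,
        max_features=cfg.max_features,
        improvement_tol=cfg.improvement_tol,
    )
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        cols = wrapper_select(X.iloc[train], y[train], inner)
        model = fit_linear_svr(X.iloc[train][cols], y[train], inner)
        preds[test] = model.predict(X.iloc[test])
    return preds


def weights_report(model: FittedModel) -> pd.DataFrame:
    """Named weight table of a fitted model, sorted by |weight| descending.

    Columns: roi, feature, weight (z-score space), sign.  Feature names of
    the ``{roi}_{feature}`` pattern are split; other names keep the full
    name in ``feature`` with an empty roi.
    """
    rows = []
    for name, w in zip(model.selected_features, model.weights):
        roi, _, feat = name.partition("_")
        if roi not in ("G", "NT", "N"):
            roi, feat = "", name
        rows.append(
            {
                "roi": roi,
                "feature": feat,
                "weight": float(w),
                "sign": "+" if w >= 0 else "-",
            }
        )
    table = pd.DataFrame(rows, columns=["roi", "feature", "weight", "sign"])
    return table.reindex(
        table["weight"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
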