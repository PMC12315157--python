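"""Chemometric calibration machinery and baseline wavelength selectors.

Contains the SPXY calibration/prediction split, PLSR with its latent-
variable count chosen by RMSECV, grid-searched SVR, the five-fold
comparison protocol producing the six-number metrics record
(Rc2/MSEc, Rcv2/MSEcv, Rp2/MSEp), and the three classic wavelength
selectors the evolved trees are benchmarked against: the successive
projections algorithm (SPA), competitive adaptive reweighted sampling
(CARS) and regression-coefficient ranking with non-maximum suppression
(RC).

Selectors are scikit-learn transformers (``fit`` / ``get_support`` /
``transform``) so they compose with pipelines; module-level functions are
thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold, cross_val_predict
from sklearn.svm import SVR

__all__ = [
    "DatasetSplit",
    "ModelMetrics",
    "SelectedWavelengths",
    "spxy_split",
    "PLSRCV",
    "GridSVR",
    "plsr_fit",
    "svr_fit",
    "crossval_protocol",
    "SPASelector",
    "CARSSelector",
    "RCSelector",
    "spa_select",
    "cars_select",
    "rc_select",
]


@dataclass
class DatasetSplit:
    """Disjoint calibration/prediction index sets at a fixed ratio."""

    calibration: np.ndarray
    prediction: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration.tolist()), set(self.prediction.tolist())
        if cal & pred:
            raise ValueError("calibration and prediction sets overlap")


@dataclass
class ModelMetrics:
    """Six-number evaluation record averaged over cross-validation folds."""

    r2_cal: float
    mse_cal: float
    r2_cv: float
    mse_cv: float
    r2_pred: float
    mse_pred: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Rc2": self.r2_cal,
            "MSEc": self.mse_cal,
            "Rcv2": self.r2_cv,
            "MSEcv": self.mse_cv,
            "Rp2": self.r2_pred,
            "MSEp": self.mse_pred,
        }


@dataclass
class SelectedWavelengths:
    method: str
    indices: np.ndarray

    @property
    def n(self) -> int:
        return int(len(self.indices))


def spxy_split(X: np.ndarray, y: np.ndarray, ratio: float = 2 / 3) -> DatasetSplit:
    """Sample-set partitioning based on joint x-y distances.

    Greedy Kennard-Stone-style selection on the joint distance
    ``d = dX / max(dX) + dy / max(dy)``: the most distant pair seeds the
    calibration set, then the sample with the largest minimum joint
    distance to the already-selected set is added until the calibration
    set holds ``round(ratio * n)`` samples. The calibration set therefore
    spans the extremes of both the spectra and the reference values.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    diff = X[:, None, :] - X[None, :, :]
    dx = np.sqrt((diff**2).sum(axis=2))
    dy = np.abs(y[:, None] - y[None, :])
    if dx.max() == 0 and dy.max() == 0:
        raise ValueError("all samples identical: SPXY distances degenerate")
    d = np.zeros_like(dx)
    if dx.max() > 0:
        d += dx / dx.max()
    if dy.max() > 0:
        d += dy / dy.max()
    n_cal = int(round(ratio * n))
    n_cal = min(max(n_cal, 2), n - 1)
    first = np.unravel_index(np.argmax(d), d.shape)
    selected = [int(first[0]), int(first[1])]
    remaining = [i for i in range(n) if i not in selected]
    while len(selected) < n_cal:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]
        selected.append(pick)
        remaining.remove(pick)
    return DatasetSplit(
        calibration=np.asarray(sorted(selected)),
        prediction=np.asarray(sorted(remaining)),
        ratio=ratio,
    )


class PLSRCV(BaseEstimator, RegressorMixin):
    """PLS regression with the latent-variable count chosen by RMSECV.

    RMSECV is computed by five-fold cross-validation with two repeats for
    each candidate component count; the minimiser is refitted on all rows.

    Attributes (after fit): ``n_components_``, ``rmsecv_``,
    ``rmsecv_path_`` (RMSECV per candidate LV count), ``model_``.
    """

    def __init__(self, max_lv: int = 20, n_splits: int = 5, n_repeats: int = 2,
                 random_state: int | None = 0):
        self.max_lv = max_lv
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSRCV":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        cv = RepeatedKFold(
            n_splits=min(self.n_splits, X.shape[0]),
            n_repeats=self.n_repeats,
            random_state=self.random_state,
        )
        folds = list(cv.split(X))
        min_train = min(len(train) for train, _ in folds)
        limit = min(self.max_lv, min_train - 1, X.shape[1])
        if limit < 1:
            raise ValueError("degenerate input: no latent variable is fittable")
        path = []
        for lv in range(1, limit + 1):
            sq_errors = []
            for train, test in folds:
                m = PLSRegression(n_components=lv).fit(X[train], y[train])
                resid = y[test] - m.predict(X[test]).ravel()
                sq_errors.append(resid**2)
            path.append(float(np.sqrt(np.concatenate(sq_errors).mean())))
        self.rmsecv_path_ = np.asarray(path)
        self.n_components_ = int(np.argmin(self.rmsecv_path_)) + 1
        self.rmsecv_ = float(self.rmsecv_path_[self.n_components_ - 1])
        self.model_ = PLSRegression(n_components=self.n_components_).fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=np.float64)).ravel()


class GridSVR(BaseEstimator, RegressorMixin):
    """SVR with hyperparameters chosen by cross-validated grid search.

    Default grid: C in {0.1, 1, 10, 100}, epsilon in {0.01, 0.1, 1} and,
    for the RBF kernel, gamma in the 'scale' heuristic times {0.1, 1, 10}.

    Attributes (after fit): ``best_params_``, ``model_``.
    """

    def __init__(self, kernel: str = "linear", grid: dict | None = None,
                 n_splits: int = 5, random_state: int | None = 0):
        self.kernel = kernel
        self.grid = grid
        self.n_splits = n_splits
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GridSVR":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        grid = self.grid
        if grid is None:
            grid = {"C": [0.1, 1.0, 10.0, 100.0], "epsilon": [0.01, 0.1, 1.0]}
            if self.kernel == "rbf":
                var = X.var()
                g_scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
                grid["gamma"] = [0.1 * g_scale, g_scale, 10.0 * g_scale]
        cv = KFold(
            n_splits=min(self.n_splits, X.shape[0]),
            shuffle=True,
            random_state=self.random_state,
        )
        search = GridSearchCV(
            SVR(kernel=self.kernel),
            grid,
            scoring="neg_mean_squared_error",
            cv=cv,
        )
        search.fit(X, y)
        self.best_params_ = search.best_params_
        self.cv_mse_ = -float(search.best_score_)
        self.model_ = search.best_estimator_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=np.float64))


def plsr_fit(X: np.ndarray, y: np.ndarray, max_lv: int = 20, **kwargs) -> PLSRCV:
    return PLSRCV(max_lv=max_lv, **kwargs).fit(X, y)


def svr_fit(X: np.ndarray, y: np.ndarray, kernel: str = "linear",
            grid: dict | None = None, **kwargs) -> GridSVR:
    return GridSVR(kernel=kernel, grid=grid, **kwargs).fit(X, y)


def crossval_protocol(
    model,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    k: int = 5,
    random_state: int | None = 0,
) -> ModelMetrics:
    """Five-fold comparison protocol over the calibration set.

    For each fold the model is fitted on the other four segments;
    training metrics (Rc2, MSEc) come from those segments, held-out
    metrics (Rcv2, MSEcv) from the fold, and prediction metrics
    (Rp2, MSEp) from the full prediction set. All six are averaged over
    the folds. ``model`` is any fitted-from-scratch sklearn-style
    estimator; it is cloned per fold.
    """
    X_cal = np.asarray(X_cal, dtype=np.float64)
    y_cal = np.asarray(y_cal, dtype=np.float64).ravel()
    if X_cal.shape[0] < k:
        raise ValueError("calibration set smaller than the fold count")
    cv = KFold(n_splits=k, shuffle=True, random_state=random_state)
    rows = []
    for train, test in cv.split(X_cal):
        m = clone(model).fit(X_cal[train], y_cal[train])
        p_train = m.predict(X_cal[train])
        p_test = m.predict(X_cal[test])
        p_pred = m.predict(X_pred)
        rows.append(
            (
                r2_score(y_cal[train], p_train),
                mean_squared_error(y_cal[train], p_train),
                r2_score(y_cal[test], p_test),
                mean_squared_error(y_cal[test], p_test),
                r2_score(y_pred, p_pred),
                mean_squared_error(y_pred, p_pred),
            )
        )
    means = np.asarray(rows).mean(axis=0)
    return ModelMetrics(*[float(v) for v in means])


class _BaseSelector(SelectorMixin, BaseEstimator):
    def _get_support_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask


class SPASelector(_BaseSelector):
    """Successive projections algorithm: forward selection by projections.

    From every starting wavelength a candidate chain is grown by
    repeatedly projecting the remaining columns onto the orthogonal
    complement of the selected ones and taking the column of largest
    residual norm (minimising collinearity). Every (start, size) subset is
    then scored by cross-validated RMSE of an ordinary least-squares model
    and the best subset wins.

    Attributes (after fit): ``selected_idx_``, ``best_rmse_``.
    """

    def __init__(self, max_vars: int = 10, min_vars: int = 1, cv: int = 5,
                 random_state: int | None = 0):
        self.max_vars = max_vars
        self.min_vars = min_vars
        self.cv = cv
        self.random_state = random_state

    @staticmethod
    def projection_chain(X: np.ndarray, start: int, length: int) -> list[int]:
        """The SPA chain from one starting column: successive orthogonal
        projections, each step picking the largest-residual column."""
        Xc = X - X.mean(axis=0)
        n, p = Xc.shape
        chain = [start]
        residual = Xc.copy()
        for _ in range(length - 1):
            v = residual[:, chain[-1]]
            denom = v @ v
            if denom <= 1e-300:
                break
            proj = np.outer(v, (v @ residual) / denom)
            residual = residual - proj
            residual[:, chain] = 0.0
            norms = np.linalg.norm(residual, axis=0)
            nxt = int(np.argmax(norms))
            if norms[nxt] <= 1e-12:
                break
            chain.append(nxt)
        return chain

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SPASelector":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, p = X.shape
        self.n_features_in_ = p
        max_vars = min(self.max_vars, n - 1, p)
        cv = KFold(
            n_splits=min(self.cv, n), shuffle=True, random_state=self.random_state
        )
        best: tuple[float, list[int]] | None = None
        for start in range(p):
            chain = self.projection_chain(X, start, max_vars)
            for size in range(self.min_vars, len(chain) + 1):
                subset = chain[:size]
                pred = cross_val_predict(LinearRegression(), X[:, subset], y, cv=cv)
                rmse = float(np.sqrt(mean_squared_error(y, pred)))
                if best is None or rmse < best[0]:
                    best = (rmse, subset)
        self.best_rmse_ = best[0]
        self.selected_idx_ = np.asarray(sorted(best[1]))
        return self


class CARSSelector(_BaseSelector):
    """Competitive adaptive reweighted sampling.

    Each Monte-Carlo iteration fits a PLS model on a random row subset,
    enforces an exponentially decreasing retention ratio on the
    wavelengths ranked by absolute regression coefficient, then applies
    adaptive reweighted sampling with selection probability proportional
    to those coefficients. The subset with the lowest five-fold RMSECV
    over all iterations is returned.

    Attributes (after fit): ``selected_idx_``, ``best_rmsecv_``,
    ``retention_path_`` (enforced ratio per iteration, decreasing).
    """

    def __init__(self, n_mc: int = 50, sample_frac: float = 0.8, max_lv: int = 10,
                 cv: int = 5, random_state: int | None = 0):
        self.n_mc = n_mc
        self.sample_frac = sample_frac
        self.max_lv = max_lv
        self.cv = cv
        self.random_state = random_state

    def _rmsecv(self, X: np.ndarray, y: np.ndarray, cols: np.ndarray,
                cv: KFold) -> float:
        folds = list(cv.split(X))
        min_train = min(len(train) for train, _ in folds)
        lv = max(1, min(self.max_lv, len(cols), min_train - 1))
        pred = cross_val_predict(
            PLSRegression(n_components=lv), X[:, cols], y, cv=cv
        )
        return float(np.sqrt(mean_squared_error(y, pred)))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CARSSelector":
        if self.n_mc < 2:
            raise ValueError("n_mc must be at least 2")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, p = X.shape
        self.n_features_in_ = p
        rng = np.random.default_rng(self.random_state)
        cv = KFold(n_splits=min(self.cv, n), shuffle=True,
                   random_state=self.random_state)
        # exponential schedule: ratio 1 at iteration 1 down to 2/p at n_mc
        kdecay = np.log(p / 2.0) / (self.n_mc - 1)
        a = np.exp(kdecay)
        retained = np.arange(p)
        best: tuple[float, np.ndarray] | None = None
        path = []
        n_rows = max(3, int(round(self.sample_frac * n)))
        for it in range(1, self.n_mc + 1):
            ratio = min(1.0, a * np.exp(-kdecay * it))
            path.append(ratio)
            rows = rng.choice(n, size=min(n_rows, n), replace=False)
            lv = max(1, min(self.max_lv, len(retained), len(rows) - 2))
            pls = PLSRegression(n_components=lv).fit(X[np.ix_(rows, retained)], y[rows])
            coef = np.abs(np.asarray(pls.coef_).ravel())
            keep = max(2, int(round(ratio * p)))
            keep = min(keep, len(retained))
            order = np.argsort(coef)[::-1]
            forced = retained[order[:keep]]
            forced_coef = coef[order[:keep]]
            # adaptive reweighted sampling among the forced survivors
            prob = forced_coef / forced_coef.sum() if forced_coef.sum() > 0 else None
            sampled = np.unique(rng.choice(forced, size=keep, replace=True, p=prob))
            if sampled.size < 2:
                sampled = forced[:2]
            retained = np.sort(sampled)
            rmsecv = self._rmsecv(X, y, retained, cv)
            if best is None or rmsecv < best[0]:
                best = (rmsecv, retained.copy())
        self.retention_path_ = np.asarray(path)
        self.best_rmsecv_ = best[0]
        self.selected_idx_ = best[1]
        return self


class RCSelector(_BaseSelector):
    """Regression-coefficient ranking with non-maximum suppression.

    Bands are ranked by the absolute value of the PLS regression
    coefficients; local maxima within a +/- ``nms_window`` band
    neighbourhood are kept if they reach ``threshold_frac`` of the global
    maximum.

    Attributes (after fit): ``selected_idx_``, ``coef_abs_``.
    """

    def __init__(self, nms_window: int = 5, threshold_frac: float = 0.2,
                 max_lv: int = 20, random_state: int | None = 0):
        self.nms_window = nms_window
        self.threshold_frac = threshold_frac
        self.max_lv = max_lv
        self.random_state = random_state

    @staticmethod
    def non_maximum_suppression(values: np.ndarray, window: int,
                                threshold: float) -> np.ndarray:
        """Indices of local maxima under +/-window suppression, at or
        above threshold. Plateau ties keep the leftmost index."""
        values = np.asarray(values, dtype=np.float64)
        keep = []
        for i in range(len(values)):
            if values[i] < threshold:
                continue
            lo, hi = max(0, i - window), min(len(values), i + window + 1)
            segment = values[lo:hi]
            if values[i] == segment.max() and i - lo == int(np.argmax(segment)):
                keep.append(i)
        return np.asarray(keep, dtype=int)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RCSelector":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        self.n_features_in_ = X.shape[1]
        pls = PLSRCV(max_lv=self.max_lv, random_state=self.random_state).fit(X, y)
        self.coef_abs_ = np.abs(np.asarray(pls.model_.coef_).ravel())
        threshold = self.threshold_frac * self.coef_abs_.max()
        self.selected_idx_ = self.non_maximum_suppression(
            self.coef_abs_, self.nms_window, threshold
        )
        return self


def spa_select(X, y, max_vars: int = 10, **kwargs) -> SelectedWavelengths:
    sel = SPASelector(max_vars=max_vars, **kwargs).fit(X, y)
    return SelectedWavelengths("SPA", sel.selected_idx_)


def cars_select(X, y, n_mc: int = 50, **kwargs) -> SelectedWavelengths:
    sel = CARSSelector(n_mc=n_mc, **kwargs).fit(X, y)
    return SelectedWavelengths("CARS", sel.selected_idx_)


def rc_select(X, y, nms_window: int = 5, **kwargs) -> SelectedWavelengths:
    sel = RCSelector(nms_window=nms_window, **kwargs).fit(X, y)
    return SelectedWavelengths("RC", sel.selected_idx_)
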