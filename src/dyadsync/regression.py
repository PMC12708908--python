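"""Feature selection and the four estimators.

Selectors: greedy maximum-relevance-minimum-redundancy (F-statistic
relevance, absolute-correlation redundancy) and unsupervised Laplacian
scores on a nearest-neighbour heat-kernel graph (locality-preserving
features first).

Estimators share a train/predict contract: median imputation and input
standardization are learned on training rows only, predictions are clipped
to the 1-9 rating scale.

* ``mlp`` — single-hidden-layer (default 10 tanh units) network trained by
  Levenberg-Marquardt (damping schedule 0.001 x/÷ 10, stop at mu > 1e10 or
  gradient < 1e-7, at most ``epochs`` iterations) or, in ``gradient`` mode,
  full-batch gradient descent with the configured learning rate (default
  0.1) for exactly ``epochs`` epochs.
* ``linear`` — least squares, optionally lasso/ridge regularized.
* ``svm`` — epsilon-SVR with Gaussian kernel; kernel width defaults to the
  median-pairwise-distance heuristic.
* ``mbe`` — the median-based estimator; ignores inputs entirely.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.feature_selection import f_regression
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.svm import SVR

from .errors import ConfigurationError, DataError

RATING_RANGE = (1.0, 9.0)


@dataclass(frozen=True)
class SelectorConfig:
    method: str  # "mrmr" | "laplacian" | "none"
    k: int

    def __post_init__(self) -> None:
        if self.method not in ("mrmr", "laplacian", "none"):
            raise ConfigurationError(f"unknown selector {self.method!r}")
        if self.method != "none" and self.k < 1:
            raise ConfigurationError("k must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    method: str  # "mlp" | "linear" | "svm" | "mbe"
    hidden_units: int = 10
    epochs: int = 1000
    learning_rate: float = 0.1
    optimizer: str = "levenberg-marquardt"  # or "gradient"
    #: LM convergence: stop once an accepted step improves the SSE by less
    #: than this relative amount (far below the 1-9 rating resolution)
    mlp_ftol: float = 1e-5
    penalty: str = "none"  # linear: "none" | "lasso" | "ridge"
    alpha: float = 1.0  # penalty strength
    svm_c: float = 1.0
    svm_epsilon: float = 0.1
    svm_gamma: float | None = None  # None -> median-distance heuristic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("mlp", "linear", "svm", "mbe"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.epochs <= 0:
            raise ConfigurationError("epochs must be > 0")
        if self.alpha < 0 or self.svm_c <= 0:
            raise ConfigurationError("penalties must be >= 0")


# ---------------------------------------------------------------------------
# feature selection

def mrmr_rank(X: pd.DataFrame, y: np.ndarray, k: int) -> list[str]:
    """Greedy MRMR ordering: maximize F-statistic relevance to the label
    minus mean absolute correlation with already-selected features."""
    if len(X) < 2:
        raise DataError("MRMR needs at least 2 rows")
    if k > X.shape[1]:
        raise ConfigurationError(f"k={k} exceeds {X.shape[1]} candidate features")
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = f_regression(Xv, y)[0]
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    # map F onto the correlation scale (|r| = sqrt(F/(F+dof))) so relevance
    # and redundancy are commensurate in the difference criterion
    dof = max(len(Xv) - 2, 1)
    relevance = np.sqrt(f_stat / (f_stat + dof))
    sd = Xv.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (Xv - Xv.mean(axis=0)) / sd_safe
    corr = np.abs(Z.T @ Z / len(Xv))
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    names = list(X.columns)
    selected: list[int] = [int(np.argmax(relevance))]
    while len(selected) < k:
        remaining = [i for i in range(len(names)) if i not in selected]
        redundancy = corr[np.ix_(remaining, selected)].mean(axis=1)
        scores = relevance[remaining] - redundancy
        selected.append(remaining[int(np.argmax(scores))])
    return [names[i] for i in selected]


def laplacian_scores(X: pd.DataFrame, k_graph: int = 5) -> pd.Series:
    """Laplacian score per feature (smaller = smoother on the neighbour graph).

    Heat-kernel weights exp(-d^2/t) on a symmetrized k-nearest-neighbour
    graph with t = mean squared neighbour distance.  Constant features get
    +inf (ranked last by construction).
    """
    if len(X) < 3:
        raise DataError("Laplacian scores need at least 3 rows")
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (Xv - Xv.mean(axis=0)) / sd_safe
    n = len(Z)
    d2 = squareform(pdist(Z, "sqeuclidean"))
    kg = min(k_graph, n - 1)
    nbr = np.argsort(d2, axis=1, kind="stable")[:, 1:kg + 1]
    mask = np.zeros_like(d2, dtype=bool)
    rows = np.arange(n)[:, None]
    mask[rows, nbr] = True
    mask |= mask.T
    t = float(d2[mask].mean()) or 1.0
    W = np.where(mask, np.exp(-d2 / t), 0.0)
    D = W.sum(axis=1)
    scores = {}
    for j, name in enumerate(X.columns):
        f = Xv[:, j]
        if sd[j] == 0:
            scores[name] = float("inf")
            continue
        f_t = f - float(f @ D) / float(D.sum())
        num = float(f_t @ (np.diag(D) - W) @ f_t)
        den = float((f_t**2) @ D)
        scores[name] = num / den if den > 0 else float("inf")
    return pd.Series(scores)


def laplacian_rank(X: pd.DataFrame, k: int, k_graph: int = 5) -> list[str]:
    """Features ordered by ascending Laplacian score; first ``k`` returned."""
    if k > X.shape[1]:
        raise ConfigurationError(f"k={k} exceeds {X.shape[1]} candidate features")
    scores = laplacian_scores(X, k_graph=k_graph)
    order = scores.sort_values(kind="stable").index.tolist()
    return order[:k]


def select_features(selector: SelectorConfig, X: pd.DataFrame,
                    y: np.ndarray) -> list[str]:
    if selector.method == "none":
        return list(X.columns)
    if selector.method == "mrmr":
        return mrmr_rank(X, y, selector.k)
    return laplacian_rank(X, selector.k)


# ---------------------------------------------------------------------------
# the Levenberg-Marquardt MLP

class _MLP:
    """Single-hidden-layer perceptron with linear output."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(max(n_in, 1))
        self.W1 = rng.normal(0.0, scale, (n_in, hidden))
        self.b1 = rng.normal(0.0, 0.1, hidden)
        self.w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), hidden)
        self.b2 = 0.0

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        H = np.tanh(X @ self.W1 + self.b1)
        return H @ self.w2 + self.b2, H

    # parameter vector packing -------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    def set_params(self, theta: np.ndarray) -> None:
        n_in, h = self.W1.shape
        i = n_in * h
        self.W1 = theta[:i].reshape(n_in, h)
        self.b1 = theta[i:i + h]
        self.w2 = theta[i + h:i + 2 * h]
        self.b2 = float(theta[-1])

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """d yhat / d theta, shape (N, P)."""
        H = np.tanh(X @ self.W1 + self.b1)
        dH = (1.0 - H**2) * self.w2  # (N, h)
        JW1 = X[:, :, None] * dH[:, None, :]  # (N, n_in, h)
        n = len(X)
        return np.concatenate([JW1.reshape(n, -1), dH, H,
                               np.ones((n, 1))], axis=1)


def _train_mlp_lm(net: _MLP, X: np.ndarray, y: np.ndarray, epochs: int,
                  mu0: float = 1e-3, mu_max: float = 1e10,
                  min_grad: float = 1e-7, ftol: float = 1e-9) -> None:
    """Levenberg-Marquardt on the sum of squared errors.

    Runs at most ``epochs`` iterations; like standard LM trainers it also
    stops when the damping factor exceeds ``mu_max``, the error-gradient
    infinity norm falls below ``min_grad``, or an accepted step improves
    the SSE by less than ``ftol`` relatively (converged).
    """
    mu = mu0
    theta = net.get_params()
    pred, _ = net.forward(X)
    sse = float(((y - pred) ** 2).sum())
    eye = np.eye(len(theta))
    for _ in range(epochs):
        J = net.jacobian(X)
        r = y - net.forward(X)[0]
        g = J.T @ r
        if np.max(np.abs(g)) < min_grad:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * eye, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            net.set_params(theta + delta)
            new_sse = float(((y - net.forward(X)[0]) ** 2).sum())
            if new_sse < sse:
                theta = theta + delta
                rel_gain = (sse - new_sse) / max(sse, 1e-300)
                sse = new_sse
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                converged = rel_gain < ftol
                break
            mu *= 10.0
        if not accepted:
            net.set_params(theta)
            break
        if converged:
            break


def _train_mlp_gd(net: _MLP, X: np.ndarray, y: np.ndarray, epochs: int,
                  lr: float) -> None:
    n = len(X)
    for _ in range(epochs):
        pred, H = net.forward(X)
        err = pred - y
        dH = (1.0 - H**2) * net.w2
        grad_w2 = H.T @ err / n
        grad_b2 = float(err.mean())
        grad_W1 = X.T @ (err[:, None] * dH) / n
        grad_b1 = (err[:, None] * dH).mean(axis=0)
        net.w2 -= lr * grad_w2
        net.b2 -= lr * grad_b2
        net.W1 -= lr * grad_W1
        net.b1 -= lr * grad_b1


# ---------------------------------------------------------------------------
# fitted-model contract

@dataclass
class FittedModel:
    method: str
    selected_features: list[str]
    impute_medians: pd.Series
    center: np.ndarray
    scale: np.ndarray
    predictor: object  # _MLP | sklearn regressor | float constant
    constant: float | None = None
    train_ma: float = float("nan")
    train_rms: float = float("nan")
    config: ModelConfig | None = None

    def _prepare(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in rows.columns]
        if missing:
            raise DataError(f"rows lack selected features: {missing}")
        X = rows[self.selected_features].copy()
        X = X.fillna(self.impute_medians)
        return (X.to_numpy(dtype=float) - self.center) / self.scale

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        if self.constant is not None:
            return np.full(len(rows), self.constant)
        Z = self._prepare(rows)
        if isinstance(self.predictor, _MLP):
            raw = self.predictor.forward(Z)[0]
        else:
            raw = self.predictor.predict(Z)
        return np.clip(raw, *RATING_RANGE)


def fit(model: ModelConfig, selector: SelectorConfig, X: pd.DataFrame,
        y: np.ndarray | pd.Series) -> FittedModel:
    """Fit one estimator with selection, imputation and standardization all
    learned on the training rows only."""
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise DataError("X and y must have equal length")
    if model.method == "mbe":
        raise ConfigurationError("the median-based estimator is fit per fold "
                                 "via mbe_dyad_specific / mbe_dyad_nonspecific")
    medians = X.median(numeric_only=True)
    medians = medians.fillna(0.0)
    X_imp = X.fillna(medians)

    if np.all(y == y[0]):  # degenerate labels: predict the constant
        out = FittedModel(method=model.method, selected_features=list(X.columns),
                          impute_medians=medians, center=np.zeros(X.shape[1]),
                          scale=np.ones(X.shape[1]), predictor=None,
                          constant=float(y[0]), config=model)
        out.train_ma, out.train_rms = 0.0, 0.0
        return out

    names = select_features(selector, X_imp, y)
    Xs = X_imp[names].to_numpy(dtype=float)
    center = Xs.mean(axis=0)
    scale = Xs.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (Xs - center) / scale

    rng = np.random.default_rng(model.seed)
    if model.method == "mlp":
        net = _MLP(Z.shape[1], model.hidden_units, rng)
        if model.optimizer == "gradient":
            _train_mlp_gd(net, Z, y, model.epochs, model.learning_rate)
        else:
            _train_mlp_lm(net, Z, y, model.epochs, ftol=model.mlp_ftol)
        predictor: object = net
    elif model.method == "linear":
        if model.penalty == "lasso":
            predictor = Lasso(alpha=model.alpha, max_iter=5000)
        elif model.penalty == "ridge":
            predictor = Ridge(alpha=model.alpha)
        else:
            predictor = LinearRegression()
        predictor.fit(Z, y)
    elif model.method == "svm":
        gamma = model.svm_gamma
        if gamma is None:
            sub = Z[rng.choice(len(Z), min(len(Z), 400), replace=False)]
            med = float(np.median(pdist(sub))) if len(sub) > 1 else 1.0
            gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
        predictor = SVR(kernel="rbf", C=model.svm_c, epsilon=model.svm_epsilon,
                        gamma=gamma)
        predictor.fit(Z, y)

    fitted = FittedModel(method=model.method, selected_features=names,
                         impute_medians=medians[names], center=center,
                         scale=scale, predictor=predictor, config=model)
    train_pred = fitted.predict(X)
    err = train_pred - y
    fitted.train_ma = float(np.mean(np.abs(err)))
    fitted.train_rms = float(np.sqrt(np.mean(err**2)))
    return fitted


# ---------------------------------------------------------------------------
# fitted-model serialization (JSON-ready container)

class _LinearPredictor:
    def __init__(self, coef: np.ndarray, intercept: float):
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = float(intercept)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.coef_ + self.intercept_


class _RBFPredictor:
    """Gaussian-kernel SVR decision function from its fitted arrays."""

    def __init__(self, support_vectors, dual_coef, intercept, gamma):
        self.support_vectors_ = np.asarray(support_vectors, dtype=float)
        self.dual_coef_ = np.asarray(dual_coef, dtype=float).ravel()
        self.intercept_ = float(intercept)
        self.gamma = float(gamma)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self.support_vectors_[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma * d2) @ self.dual_coef_ + self.intercept_


def fitted_to_dict(model: FittedModel) -> dict:
    """Serialize a fitted model: feature names, imputation medians,
    standardization constants and learned parameters."""
    out = {
        "method": model.method,
        "selected_features": list(model.selected_features),
        "impute_medians": {k: float(v) for k, v in model.impute_medians.items()},
        "center": np.asarray(model.center).tolist(),
        "scale": np.asarray(model.scale).tolist(),
        "constant": model.constant,
        "train_ma": model.train_ma,
        "train_rms": model.train_rms,
    }
    p = model.predictor
    if model.constant is not None:
        out["params"] = {}
    elif isinstance(p, _MLP):
        out["params"] = {"W1": p.W1.tolist(), "b1": p.b1.tolist(),
                         "w2": p.w2.tolist(), "b2": p.b2}
    elif isinstance(p, (LinearRegression, Ridge, Lasso, _LinearPredictor)):
        out["params"] = {"coef": np.asarray(p.coef_).tolist(),
                         "intercept": float(np.atleast_1d(p.intercept_)[0])}
    elif isinstance(p, (SVR, _RBFPredictor)):
        gamma = p.gamma if isinstance(p, _RBFPredictor) else p._gamma
        out["params"] = {"support_vectors": np.asarray(p.support_vectors_).tolist(),
                         "dual_coef": np.asarray(p.dual_coef_).ravel().tolist(),
                         "intercept": float(np.atleast_1d(p.intercept_)[0]),
                         "gamma": float(gamma)}
    else:  # pragma: no cover
        raise ConfigurationError(f"cannot serialize predictor {type(p).__name__}")
    return out


def fitted_from_dict(d: dict) -> FittedModel:
    """Rebuild a predict-capable model from :func:`fitted_to_dict` output."""
    names = list(d["selected_features"])
    params = d.get("params", {})
    predictor: object | None = None
    if d.get("constant") is None:
        if d["method"] == "mlp":
            net = _MLP(len(names), len(params["b1"]), np.random.default_rng(0))
            net.W1 = np.asarray(params["W1"], dtype=float)
            net.b1 = np.asarray(params["b1"], dtype=float)
            net.w2 = np.asarray(params["w2"], dtype=float)
            net.b2 = float(params["b2"])
            predictor = net
        elif d["method"] == "linear":
            predictor = _LinearPredictor(params["coef"], params["intercept"])
        elif d["method"] == "svm":
            predictor = _RBFPredictor(params["support_vectors"],
                                      params["dual_coef"], params["intercept"],
                                      params["gamma"])
        else:
            raise ConfigurationError(f"unknown method {d['method']!r}")
    return FittedModel(method=d["method"], selected_features=names,
                       impute_medians=pd.Series(d["impute_medians"]),
                       center=np.asarray(d["center"], dtype=float),
                       scale=np.asarray(d["scale"], dtype=float),
                       predictor=predictor, constant=d.get("constant"),
                       train_ma=d.get("train_ma", float("nan")),
                       train_rms=d.get("train_rms", float("nan")))


# ---------------------------------------------------------------------------
# median-based estimators

def mbe_dyad_specific(own_ratings: np.ndarray | list, held_out_index: int) -> float:
    """Median of the participant's ratings in the other 9 intervals."""
    ratings = np.asarray(own_ratings, dtype=float)
    if np.any(np.isnan(ratings)):
        raise DataError("missing rating in dyad-specific MBE input")
    if held_out_index < 0 or held_out_index >= len(ratings):
        raise DataError("held-out index outside rating range")
    rest = np.delete(ratings, held_out_index)
    if len(rest) == 0:
        raise DataError("no ratings left after exclusion")
    return float(np.median(rest))


def mbe_dyad_nonspecific(pooled_ratings: np.ndarray | list) -> float:
    """Median over all per-interval ratings of the other dyads (even count:
    mean of the two central values)."""
    pool = np.asarray(pooled_ratings, dtype=float)
    pool = pool[~np.isnan(pool)]
    if len(pool) == 0:
        raise DataError("empty rating pool for dyad-nonspecific MBE")
    return float(np.median(pool))
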