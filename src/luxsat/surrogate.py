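"""Photosynthetic-rate surrogate models: epsilon-SVR (primary), RBF and BP nets.

All models map raw (temperature, CO2, PPFD) to net photosynthetic rate Pn.
Inputs and the target are min-max normalized onto [0.2, 0.9] with statistics
computed on the training split only; predictions are de-normalized back to
µmol CO2 m-2 s-1.  The SVR prediction path is an explicit kernel expansion

    f(x) = sum_i (a_i - a_i*) exp(-g ||x_i - x||^2) + b

over the extracted support vectors, so a JSON round trip reproduces
predictions exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "FEATURES",
    "TARGET",
    "NormalizationSpec",
    "SvmConfig",
    "MetricsReport",
    "SurrogateModel",
    "SvmModel",
    "RbfNetModel",
    "BpNetModel",
    "normalize",
    "denormalize",
    "split_train_test",
    "fit_svm",
    "tune_svm",
    "fit_rbf_net",
    "fit_bp_net",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]

FEATURES = ("temp_c", "co2_umol_mol", "ppfd_umol_m2_s")
TARGET = "pn_umol_m2_s"


# ---------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormalizationSpec:
    """Per-variable min-max mapping onto [lo, hi] (default [0.2, 0.9])."""

    x_min: np.ndarray
    x_max: np.ndarray
    lo: float = 0.2
    hi: float = 0.9

    def __post_init__(self):
        x_min = np.atleast_1d(np.asarray(self.x_min, dtype=float))
        x_max = np.atleast_1d(np.asarray(self.x_max, dtype=float))
        if x_min.shape != x_max.shape:
            raise ValueError("x_min and x_max must have the same shape")
        if np.any(x_max <= x_min):
            raise ValueError("degenerate range: x_max must exceed x_min per variable")
        if not self.lo < self.hi:
            raise ValueError("lo must be < hi")
        object.__setattr__(self, "x_min", x_min)
        object.__setattr__(self, "x_max", x_max)

    @classmethod
    def fit(cls, x: np.ndarray, lo: float = 0.2, hi: float = 0.9) -> "NormalizationSpec":
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return cls(x.min(axis=0), x.max(axis=0), lo, hi)


def normalize(x, spec: NormalizationSpec):
    """y = lo + (hi - lo) * (x - x_min) / (x_max - x_min), per variable."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("normalize: inputs must be finite")
    return spec.lo + (spec.hi - spec.lo) * (x - spec.x_min) / (spec.x_max - spec.x_min)


def denormalize(y, spec: NormalizationSpec):
    """Inverse of :func:`normalize`; recovers x to machine precision."""
    y = np.asarray(y, dtype=float)
    return spec.x_min + (y - spec.lo) * (spec.x_max - spec.x_min) / (spec.hi - spec.lo)


# ---------------------------------------------------------------------------
# train/test split

def split_train_test(samples: pd.DataFrame, train_frac: float, seed: int):
    """Random disjoint, exhaustive split; |train| = round(train_frac * n)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(int(seed))
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return samples.iloc[train_idx].reset_index(drop=True), samples.iloc[test_idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# model configs and containers

@dataclass(frozen=True)
class SvmConfig:
    """epsilon-SVR hyperparameters; kernel K(xi,x) = exp(-g ||xi - x||^2).

    The default epsilon (0.001 in normalized target units, ~0.03 µmol CO2
    m-2 s-1 on a typical Pn range) is sized to resolve the Pn variation
    across the light-saturation region, which is of the same order; a wider
    tube leaves the curve's argmax unidentified inside it.
    """

    c: float = 2.82
    g: float = 0.50
    epsilon: float = 0.001

    def __post_init__(self):
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    mre: float  # percent
    rmse: float
    r2: float
    slope: float
    intercept: float


class SurrogateModel:
    """Common interface: raw-unit prediction on top of normalized internals."""

    kind: str = "base"

    def __init__(self, x_norm: NormalizationSpec, y_norm: NormalizationSpec):
        self.x_norm = x_norm
        self.y_norm = y_norm

    def _predict_norm(self, xn: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, temp, co2, ppfd):
        """Pn prediction in raw units; vectorizes over broadcastable queries."""
        temp, co2, ppfd = np.broadcast_arrays(
            np.asarray(temp, dtype=float),
            np.asarray(co2, dtype=float),
            np.asarray(ppfd, dtype=float),
        )
        shape = temp.shape
        x = np.column_stack([temp.ravel(), co2.ravel(), ppfd.ravel()])
        yn = self._predict_norm(normalize(x, self.x_norm))
        y = denormalize(yn, self.y_norm)
        y = np.asarray(y, dtype=float).reshape(shape)
        return y if shape else float(y)


class SvmModel(SurrogateModel):
    kind = "svm"

    def __init__(self, x_norm, y_norm, support_vectors, dual_coef, bias, config: SvmConfig):
        super().__init__(x_norm, y_norm)
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.dual_coef = np.asarray(dual_coef, dtype=float).ravel()
        self.bias = float(bias)
        self.config = config
        if len(self.dual_coef) != len(self.support_vectors):
            raise ValueError("one dual coefficient per support vector required")

    @property
    def nsv(self) -> int:
        return len(self.support_vectors)

    def _predict_norm(self, xn: np.ndarray) -> np.ndarray:
        if self.nsv == 0:
            return np.full(len(xn), self.bias)
        sq = ((xn[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.config.g * sq) @ self.dual_coef + self.bias


class RbfNetModel(SurrogateModel):
    """Gaussian radial-basis hidden layer with a linear output layer."""

    kind = "rbf_net"

    def __init__(self, x_norm, y_norm, centers, weights, bias, spread, converged=True):
        super().__init__(x_norm, y_norm)
        self.centers = np.asarray(centers, dtype=float)
        self.weights = np.asarray(weights, dtype=float).ravel()
        self.bias = float(bias)
        self.spread = float(spread)
        self.converged = bool(converged)

    def _predict_norm(self, xn: np.ndarray) -> np.ndarray:
        if len(self.centers) == 0:
            return np.full(len(xn), self.bias)
        sq = ((xn[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-sq / self.spread**2) @ self.weights + self.bias


class BpNetModel(SurrogateModel):
    """3-h-1 feed-forward net, tanh hidden layer, linear output."""

    kind = "bp_net"

    def __init__(self, x_norm, y_norm, w1, b1, w2, b2, converged=True):
        super().__init__(x_norm, y_norm)
        self.w1 = np.asarray(w1, dtype=float)
        self.b1 = np.asarray(b1, dtype=float).ravel()
        self.w2 = np.asarray(w2, dtype=float).ravel()
        self.b2 = float(b2)
        self.converged = bool(converged)

    def _predict_norm(self, xn: np.ndarray) -> np.ndarray:
        h = np.tanh(xn @ self.w1.T + self.b1)
        return h @ self.w2 + self.b2


# ---------------------------------------------------------------------------
# fitting

def _design(train: pd.DataFrame):
    x = train.loc[:, list(FEATURES)].to_numpy(dtype=float)
    y = train.loc[:, TARGET].to_numpy(dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")
    return x, y


def _fit_norms(x, y):
    x_norm = NormalizationSpec.fit(x)
    lo, hi = y.min(), y.max()
    if hi <= lo:  # constant target: widen artificially so the map is defined
        hi = lo + 1.0
    y_norm = NormalizationSpec(np.array([lo]), np.array([hi]))
    return x_norm, y_norm


def fit_svm(train: pd.DataFrame, config: SvmConfig = SvmConfig()) -> SvmModel:
    """Fit an epsilon-SVR with the RBF kernel on normalized data.

    Support vectors, dual coefficients and bias are extracted from the
    scikit-learn solution; prediction runs through the explicit kernel
    expansion, in raw units.
    """
    x, y = _design(train)
    if len(x) < 2:
        raise ValueError("need at least 2 training samples")
    x_norm, y_norm = _fit_norms(x, y)
    xn = normalize(x, x_norm)
    yn = normalize(y[:, None], y_norm).ravel()
    svr = SVR(kernel="rbf", C=config.c, gamma=config.g, epsilon=config.epsilon, tol=1e-6)
    svr.fit(xn, yn)
    return SvmModel(
        x_norm, y_norm,
        support_vectors=svr.support_vectors_,
        dual_coef=svr.dual_coef_.ravel(),
        bias=float(svr.intercept_[0]),
        config=config,
    )


def tune_svm(train: pd.DataFrame, c_grid, g_grid, k_folds: int = 5, seed: int = 0) -> SvmConfig:
    """Grid search (c, g) minimizing mean k-fold CV RMSE on normalized data.

    Ties are broken toward smaller c, then smaller g.  Normalization
    statistics are computed once on the full training set and shared across
    folds.
    """
    c_grid = [float(c) for c in c_grid]
    g_grid = [float(g) for g in g_grid]
    if not c_grid or not g_grid:
        raise ValueError("c_grid and g_grid must be non-empty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    x, y = _design(train)
    if k_folds > len(x):
        raise ValueError(f"k_folds={k_folds} exceeds training size {len(x)}")
    x_norm, y_norm = _fit_norms(x, y)
    xn = normalize(x, x_norm)
    yn = normalize(y[:, None], y_norm).ravel()
    folds = list(KFold(n_splits=k_folds, shuffle=True, random_state=int(seed)).split(xn))
    best = None
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            sq_errs = []
            for tr, te in folds:
                svr = SVR(kernel="rbf", C=c, gamma=g, epsilon=0.01, tol=1e-6)
                svr.fit(xn[tr], yn[tr])
                sq_errs.append(np.mean((svr.predict(xn[te]) - yn[te]) ** 2))
            rmse = float(np.sqrt(np.mean(sq_errs)))
            if best is None or rmse < best[0] - 1e-15:
                best = (rmse, c, g)
    return SvmConfig(c=best[1], g=best[2])


def fit_rbf_net(
    train: pd.DataFrame,
    spread: float = 0.30,
    goal: float = 1e-4,
    max_centers: int | None = None,
) -> RbfNetModel:
    """Greedy RBF network: add the worst-fit training point as a center until
    the training MSE (normalized units) reaches ``goal`` or the center cap.

    The output layer (weights + bias) is re-solved by linear least squares
    after every addition.  ``spread`` is the Gaussian width in normalized
    input units.
    """
    if spread <= 0:
        raise ValueError("spread must be > 0")
    x, y = _design(train)
    x_norm, y_norm = _fit_norms(x, y)
    xn = normalize(x, x_norm)
    yn = normalize(y[:, None], y_norm).ravel()
    n = len(xn)
    cap = n if max_centers is None else min(max_centers, n)

    center_idx: list[int] = []
    weights = np.zeros(0)
    bias = float(yn.mean())
    pred = np.full(n, bias)
    converged = float(np.mean((pred - yn) ** 2)) <= goal
    while not converged and len(center_idx) < cap:
        taken = set(center_idx)
        order = np.argsort(-np.abs(pred - yn))
        worst = next((int(i) for i in order if int(i) not in taken), None)
        if worst is None:
            break
        center_idx.append(worst)
        centers = xn[center_idx]
        sq = ((xn[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-sq / spread**2)
        a = np.column_stack([phi, np.ones(n)])
        coef, *_ = np.linalg.lstsq(a, yn, rcond=None)
        weights, bias = coef[:-1], float(coef[-1])
        pred = a @ coef
        converged = float(np.mean((pred - yn) ** 2)) <= goal
    return RbfNetModel(x_norm, y_norm, xn[center_idx], weights, bias, spread, converged)


def _bp_unpack(theta: np.ndarray, h: int):
    w1 = theta[: 3 * h].reshape(h, 3)
    b1 = theta[3 * h : 4 * h]
    w2 = theta[4 * h : 5 * h]
    b2 = theta[5 * h]
    return w1, b1, w2, b2


def fit_bp_net(
    train: pd.DataFrame,
    hidden_units: int = 5,
    goal: float = 1e-4,
    max_epochs: int = 1000,
    seed: int = 0,
) -> BpNetModel:
    """Train a 3-h-1 tanh/linear net by Levenberg-Marquardt.

    One epoch is one LM step (damped Gauss-Newton on the full batch with an
    analytic Jacobian).  Training stops when the normalized-unit MSE reaches
    ``goal`` or after ``max_epochs`` epochs; the returned model carries a
    ``converged`` flag.  Fully deterministic given ``seed``.
    """
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    x, y = _design(train)
    x_norm, y_norm = _fit_norms(x, y)
    xn = normalize(x, x_norm)
    yn = normalize(y[:, None], y_norm).ravel()
    h = int(hidden_units)
    rng = np.random.default_rng(int(seed))
    theta = rng.normal(0.0, 0.5, size=5 * h + 1)

    def forward(th):
        w1, b1, w2, b2 = _bp_unpack(th, h)
        hidden = np.tanh(xn @ w1.T + b1)
        return hidden, hidden @ w2 + b2

    def jacobian(th, hidden):
        w1, b1, w2, b2 = _bp_unpack(th, h)
        n = len(xn)
        jac = np.empty((n, len(th)))
        dtanh = (1.0 - hidden**2) * w2  # (n, h)
        for j in range(h):
            for k in range(3):
                jac[:, 3 * j + k] = dtanh[:, j] * xn[:, k]
        jac[:, 3 * h : 4 * h] = dtanh
        jac[:, 4 * h : 5 * h] = hidden
        jac[:, 5 * h] = 1.0
        return jac

    hidden, pred = forward(theta)
    mse = float(np.mean((pred - yn) ** 2))
    lam = 1e-2
    epochs = 0
    while mse > goal and epochs < max_epochs:
        jac = jacobian(theta, hidden)
        resid = pred - yn
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        step_ok = False
        for _ in range(30):
            try:
                delta = np.linalg.solve(jtj + lam * np.eye(len(theta)), -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + delta
            hid_c, pred_c = forward(cand)
            mse_c = float(np.mean((pred_c - yn) ** 2))
            if mse_c < mse:
                theta, hidden, pred, mse = cand, hid_c, pred_c, mse_c
                lam = max(lam / 10.0, 1e-12)
                step_ok = True
                break
            lam *= 10.0
        epochs += 1
        if not step_ok:
            break  # LM stalled; no descent direction at any damping
    w1, b1, w2, b2 = _bp_unpack(theta, h)
    return BpNetModel(x_norm, y_norm, w1, b1, w2, b2, converged=mse <= goal)


# ---------------------------------------------------------------------------
# prediction and evaluation

def predict(model: SurrogateModel, temp, co2, ppfd):
    """Module-level convenience wrapper around ``model.predict``."""
    if not isinstance(model, SurrogateModel):
        raise TypeError("predict requires a fitted SurrogateModel")
    return model.predict(temp, co2, ppfd)


def evaluate(model: SurrogateModel, test: pd.DataFrame, mre_min_abs: float = 0.1) -> MetricsReport:
    """MAE, MRE (%), RMSE, R2 and the measured-vs-predicted OLS line.

    MRE excludes observations with |Pn| < ``mre_min_abs`` (relative error is
    unstable near zero); if every observation is excluded MRE is NaN and a
    warning is issued.  The slope/intercept regress predicted on measured.
    """
    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    x, obs = _design(test)
    pred = np.asarray(model.predict(x[:, 0], x[:, 1], x[:, 2]), dtype=float)
    err = pred - obs
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    keep = np.abs(obs) >= mre_min_abs
    if keep.any():
        mre = float(100.0 * np.mean(np.abs(err[keep]) / np.abs(obs[keep])))
    else:
        warnings.warn("MRE undefined: all observations below |Pn| threshold")
        mre = float("nan")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    if sst > 0:
        slope, intercept = np.polyfit(obs, pred, 1)
    else:
        slope, intercept = float("nan"), float("nan")
    return MetricsReport(mae=mae, mre=mre, rmse=rmse, r2=r2,
                         slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# persistence (plain JSON, bit-exact prediction round trip)

def _norm_to_dict(spec: NormalizationSpec) -> dict:
    return {"x_min": spec.x_min.tolist(), "x_max": spec.x_max.tolist(),
            "lo": spec.lo, "hi": spec.hi}


def _norm_from_dict(d: dict) -> NormalizationSpec:
    return NormalizationSpec(np.asarray(d["x_min"]), np.asarray(d["x_max"]),
                             float(d["lo"]), float(d["hi"]))


def model_to_dict(model: SurrogateModel) -> dict:
    d = {"kind": model.kind,
         "x_norm": _norm_to_dict(model.x_norm),
         "y_norm": _norm_to_dict(model.y_norm)}
    if isinstance(model, SvmModel):
        d.update(
            support_vectors=model.support_vectors.tolist(),
            dual_coef=model.dual_coef.tolist(),
            bias=model.bias,
            config={"c": model.config.c, "g": model.config.g, "epsilon": model.config.epsilon},
        )
    elif isinstance(model, RbfNetModel):
        d.update(centers=model.centers.tolist(), weights=model.weights.tolist(),
                 bias=model.bias, spread=model.spread, converged=model.converged)
    elif isinstance(model, BpNetModel):
        d.update(w1=model.w1.tolist(), b1=model.b1.tolist(), w2=model.w2.tolist(),
                 b2=model.b2, converged=model.converged)
    else:
        raise TypeError(f"cannot serialize model kind {model.kind!r}")
    return d


def model_from_dict(d: dict) -> SurrogateModel:
    x_norm = _norm_from_dict(d["x_norm"])
    y_norm = _norm_from_dict(d["y_norm"])
    kind = d["kind"]
    if kind == "svm":
        cfg = SvmConfig(**d["config"])
        sv = np.asarray(d["support_vectors"], dtype=float)
        if sv.size == 0:
            sv = sv.reshape(0, len(x_norm.x_min))
        return SvmModel(x_norm, y_norm, sv, np.asarray(d["dual_coef"]), d["bias"], cfg)
    if kind == "rbf_net":
        centers = np.asarray(d["centers"], dtype=float)
        if centers.size == 0:
            centers = centers.reshape(0, len(x_norm.x_min))
        return RbfNetModel(x_norm, y_norm, centers, np.asarray(d["weights"]),
                           d["bias"], d["spread"], d.get("converged", True))
    if kind == "bp_net":
        return BpNetModel(x_norm, y_norm, np.asarray(d["w1"]), np.asarray(d["b1"]),
                          np.asarray(d["w2"]), d["b2"], d.get("converged", True))
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model: SurrogateModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> SurrogateModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))
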