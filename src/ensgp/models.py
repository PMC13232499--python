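"""The six individual genomic prediction models behind one fit/predict
contract, plus their specification vocabulary.

Conventional group: rrBLUP (Bayesian ridge over all markers), BayesB
(point mass at zero + scaled-t slab) and RKHS (Gaussian kernel on squared
Euclidean genotype distance, sampled on the kernel eigenbasis). Machine
learning group: random forest (1,000 trees), epsilon-insensitive RBF
support vector regression at library defaults, and a single-hidden-layer
ReLU multi-layer perceptron with two presets:

* ``teonam``  — 50 hidden units, dropout 0.0, 200 epochs, AdamW, lr 0.005;
* ``maizenam`` — 10 hidden units, dropout 0.1, 2,500 epochs, RMSprop, lr 0.005.

Every model is deterministic given (data, hyperparameters, seed). MCMC
models default to 12,000 iterations with 2,000 burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR as _SkSVR

from . import samplers

__all__ = [
    "MODEL_GROUPS",
    "CONVENTIONAL_MODELS",
    "MACHINE_LEARNING_MODELS",
    "ModelSpec",
    "make_model",
    "RRBlupModel",
    "BayesBModel",
    "RKHSModel",
    "RandomForestModel",
    "SVRModel",
    "MLPModel",
]

CONVENTIONAL_MODELS = ("rrBLUP", "BayesB", "RKHS")
MACHINE_LEARNING_MODELS = ("RF", "SVR", "MLP")
MODEL_GROUPS = {
    **{m: "conventional" for m in CONVENTIONAL_MODELS},
    **{m: "machine_learning" for m in MACHINE_LEARNING_MODELS},
}

MIN_TRAIN_RECORDS = 5


@dataclass
class ModelSpec:
    """Identifier + hyperparameters of one member model."""

    model_id: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_GROUPS:
            raise ValueError(
                f"unknown model {self.model_id!r}; choose from {sorted(MODEL_GROUPS)}"
            )

    @property
    def group(self) -> str:
        return MODEL_GROUPS[self.model_id]


class BaseModel:
    """Uniform fit/predict contract shared by all six models."""

    model_id: str = "?"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._n_features: int | None = None

    @property
    def group(self) -> str:
        return MODEL_GROUPS[self.model_id]

    def _check_fit_inputs(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n, p) aligned with y")
        if np.isnan(X).any():
            raise ValueError("missing values in the training genotypes")
        if len(y) < MIN_TRAIN_RECORDS:
            raise ValueError(
                f"need at least {MIN_TRAIN_RECORDS} training records, got {len(y)}"
            )
        self._n_features = X.shape[1]
        return X, y

    def _check_predict_inputs(self, X: np.ndarray) -> np.ndarray:
        if self._n_features is None:
            raise RuntimeError(f"{self.model_id}: predict before fit")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (X.size and X.shape[1] != self._n_features):
            raise ValueError(
                f"{self.model_id}: test marker set ({X.shape[1] if X.ndim == 2 else '?'}) "
                f"does not match training ({self._n_features})"
            )
        return X

    def fit(self, X, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class RRBlupModel(BaseModel):
    """Ridge-regression BLUP via Gibbs sampling: every marker effect is
    normally distributed with a common variance. Posterior-mean effects are
    retained for allele-substitution-effect extraction."""

    model_id = "rrBLUP"

    def __init__(
        self,
        n_iter: int = 12_000,
        burn_in: int = 2_000,
        seed: int = 0,
        fixed_variances: tuple[float, float] | None = None,
    ):
        super().__init__(seed)
        self.n_iter, self.burn_in = n_iter, burn_in
        self.fixed_variances = fixed_variances
        self.mu_: float | None = None
        self.effects_: np.ndarray | None = None

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        post = samplers.gibbs_brr(
            X, y, self.n_iter, self.burn_in, self.seed, self.fixed_variances
        )
        self.mu_, self.effects_ = float(post["mu"]), post["b"]
        self.s2_marker_, self.s2_resid_ = post["s2_marker"], post["s2_resid"]
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        return self.mu_ + X @ self.effects_


class BayesBModel(BaseModel):
    """BayesB via Gibbs sampling: per-marker point mass at zero (prior
    exclusion probability pi = 0.5 under a flat Beta hyperprior) with a
    scaled-t slab. Posterior-mean effects and inclusion frequencies are
    retained."""

    model_id = "BayesB"

    def __init__(
        self,
        n_iter: int = 12_000,
        burn_in: int = 2_000,
        seed: int = 0,
        pi: float = 0.5,
        update_pi: bool = True,
    ):
        super().__init__(seed)
        self.n_iter, self.burn_in = n_iter, burn_in
        self.pi, self.update_pi = pi, update_pi
        self.mu_: float | None = None
        self.effects_: np.ndarray | None = None
        self.inclusion_: np.ndarray | None = None

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        post = samplers.gibbs_bayesb(
            X, y, self.n_iter, self.burn_in, self.seed, self.pi, self.update_pi
        )
        self.mu_, self.effects_ = float(post["mu"]), post["b"]
        self.inclusion_ = post["inclusion"]
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        return self.mu_ + X @ self.effects_


class RKHSModel(BaseModel):
    """Reproducing kernel Hilbert space regression.

    Gaussian kernel K_ij = exp(-d2_ij / (bandwidth * mean(d2))) on squared
    Euclidean genotype distances (the mean over training pairs sets the
    scale). The Bayesian fit runs the ridge Gibbs sampler on the kernel
    eigenbasis; test points map through the cross-kernel.
    """

    model_id = "RKHS"

    def __init__(
        self,
        n_iter: int = 12_000,
        burn_in: int = 2_000,
        bandwidth: float = 1.0,
        seed: int = 0,
        eig_tol: float = 1e-10,
        fixed_variances: tuple[float, float] | None = None,
    ):
        super().__init__(seed)
        self.n_iter, self.burn_in = n_iter, burn_in
        self.bandwidth = bandwidth
        self.eig_tol = eig_tol
        self.fixed_variances = fixed_variances

    @staticmethod
    def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        aa = (A * A).sum(axis=1)[:, None]
        bb = (B * B).sum(axis=1)[None, :]
        return np.maximum(aa + bb - 2.0 * A @ B.T, 0.0)

    def kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return np.exp(-self._sq_dists(A, B) / (self.bandwidth * self.mean_d2_))

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        d2 = self._sq_dists(X, X)
        off = d2[~np.eye(len(y), dtype=bool)]
        if off.size == 0 or off.max() == 0:
            raise ValueError("RKHS kernel degenerate: all training genotypes identical")
        self.mean_d2_ = float(off.mean())
        self.X_train_ = X
        K = np.exp(-d2 / (self.bandwidth * self.mean_d2_))
        vals, vecs = np.linalg.eigh(K)
        keep = vals > self.eig_tol * vals.max()
        self._vals, self._vecs = vals[keep], vecs[:, keep]
        phi = self._vecs * np.sqrt(self._vals)  # n x r feature map
        post = samplers.gibbs_brr(
            phi, y, self.n_iter, self.burn_in, self.seed, self.fixed_variances
        )
        self.mu_, self.alpha_ = float(post["mu"]), post["b"]
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        if X.shape[0] == 0:
            return np.empty(0)
        K_cross = self.kernel(X, self.X_train_)
        phi_test = K_cross @ (self._vecs / np.sqrt(self._vals))
        return self.mu_ + phi_test @ self.alpha_


class RandomForestModel(BaseModel):
    """Bagged regression trees with impurity recording; 1,000 trees by
    default, one third of the markers tried per split, unlimited depth."""

    model_id = "RF"

    def __init__(self, n_trees: int = 1_000, seed: int = 0, max_features: float = 1 / 3):
        super().__init__(seed)
        self.n_trees = n_trees
        self.max_features = max_features
        self.forest_: RandomForestRegressor | None = None

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.forest_.predict(X)


class SVRModel(BaseModel):
    """Epsilon-insensitive RBF support vector regression at library
    defaults (C = 1, epsilon = 0.1, gamma = 'scale')."""

    model_id = "SVR"

    def __init__(self, C: float = 1.0, epsilon: float = 0.1, seed: int = 0):
        super().__init__(seed)
        self.C, self.epsilon = C, epsilon
        self.svr_: _SkSVR | None = None

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        self.svr_ = _SkSVR(kernel="rbf", C=self.C, epsilon=self.epsilon).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self.svr_.predict(X)


MLP_PRESETS = {
    "teonam": {"hidden": 50, "dropout": 0.0, "epochs": 200, "optimizer": "adamw"},
    "maizenam": {"hidden": 10, "dropout": 0.1, "epochs": 2_500, "optimizer": "rmsprop"},
}


class MLPModel(BaseModel):
    """Single-hidden-layer ReLU perceptron, trained full-batch on
    standardized inputs (training-split statistics only).

    Presets fix architecture and optimizer: 'teonam' = 50 units, no
    dropout, 200 epochs of AdamW; 'maizenam' = 10 units, dropout 0.1,
    2,500 epochs of RMSprop. Learning rate 0.005 in both. Seeded init and
    dropout make training deterministic.
    """

    model_id = "MLP"

    def __init__(self, preset: str = "teonam", seed: int = 0, lr: float = 0.005,
                 weight_decay: float = 0.01):
        super().__init__(seed)
        if preset not in MLP_PRESETS:
            raise ValueError(f"unknown MLP preset {preset!r}")
        self.preset = preset
        self.lr = lr
        self.weight_decay = weight_decay

    def fit(self, X, y):
        X, y = self._check_fit_inputs(X, y)
        cfg = MLP_PRESETS[self.preset]
        rng = np.random.default_rng(self.seed)
        self._x_mean = X.mean(axis=0)
        self._x_std = X.std(axis=0)
        self._x_std[self._x_std == 0] = 1.0
        Z = (X - self._x_mean) / self._x_std
        n, p = Z.shape
        h = cfg["hidden"]
        # He init for the ReLU layer, small init for the head
        W1 = rng.normal(0, np.sqrt(2.0 / p), size=(p, h))
        b1 = np.zeros(h)
        W2 = rng.normal(0, np.sqrt(1.0 / h), size=(h, 1))
        b2 = np.zeros(1)
        params = [W1, b1, W2, b2]
        m = [np.zeros_like(q) for q in params]
        v = [np.zeros_like(q) for q in params]
        yv = y[:, None]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        drop = cfg["dropout"]
        for t in range(1, cfg["epochs"] + 1):
            A = Z @ W1 + b1
            H = np.maximum(A, 0.0)
            if drop > 0:
                mask = (rng.random(H.shape) >= drop) / (1.0 - drop)
                Hd = H * mask
            else:
                mask = None
                Hd = H
            out = Hd @ W2 + b2
            err = out - yv  # d(MSE)/d(out) up to 2/n
            g_out = 2.0 * err / n
            gW2 = Hd.T @ g_out
            gb2 = g_out.sum(axis=0)
            gH = g_out @ W2.T
            if mask is not None:
                gH = gH * mask
            gA = gH * (A > 0)
            gW1 = Z.T @ gA
            gb1 = gA.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            if cfg["optimizer"] == "adamw":
                for k, (q, g) in enumerate(zip(params, grads)):
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mhat = m[k] / (1 - beta1**t)
                    vhat = v[k] / (1 - beta2**t)
                    q -= self.lr * (mhat / (np.sqrt(vhat) + eps))
                    if q.ndim == 2:  # decoupled weight decay on weights only
                        q -= self.lr * self.weight_decay * q
            else:  # rmsprop
                alpha = 0.99
                for k, (q, g) in enumerate(zip(params, grads)):
                    v[k] = alpha * v[k] + (1 - alpha) * g * g
                    q -= self.lr * g / (np.sqrt(v[k]) + eps)
        self._W1, self._b1, self._W2, self._b2 = W1, b1, W2, b2
        return self

    def predict(self, X) -> np.ndarray:
        X = self._check_predict_inputs(X)
        if X.shape[0] == 0:
            return np.empty(0)
        Z = (X - self._x_mean) / self._x_std
        H = np.maximum(Z @ self._W1 + self._b1, 0.0)
        return (H @ self._W2 + self._b2).ravel()


_MODEL_CLASSES = {
    "rrBLUP": RRBlupModel,
    "BayesB": BayesBModel,
    "RKHS": RKHSModel,
    "RF": RandomForestModel,
    "SVR": SVRModel,
    "MLP": MLPModel,
}


def make_model(spec: ModelSpec) -> BaseModel:
    """Instantiate a member model from its spec."""
    cls = _MODEL_CLASSES[spec.model_id]
    return cls(seed=spec.seed, **spec.hyperparameters)
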