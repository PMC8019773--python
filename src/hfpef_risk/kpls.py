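"""Kernel partial least squares (KPLS) classification with a Gaussian kernel.

PLS regression is carried out in the feature space induced by
K(xi, xj) = exp(-||xi - xj||^2 / (2 sigma^2)) using the dual (kernel) NIPALS
algorithm: components are score vectors t_a extracted from the centered
training kernel, with symmetric two-sided deflation
K <- (I - t t') K (I - t t') and response deflation y <- y - t (t'y).
Predictions are linear in the centered test kernel through the dual
regression coefficients B = U (T' K U)^{-1} T' y, so a fitted model is a
small bundle of training-kernel statistics and dense vectors.

The binary outcome is coded {0, 1} (poor = 1) and the continuous predicted
response is thresholded at 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from hfpef_risk.config import KernelConfig

logger = logging.getLogger(__name__)

_NORM_TOL = 1e-10


def gaussian_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between the rows of A (m x p) and B (k x p)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"feature-count mismatch: {A.shape[1]} vs {B.shape[1]}")
    d2 = squared_distances(A, B)
    return np.exp(-d2 / (2.0 * sigma**2))


def squared_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0 for roundoff."""
    sq_a = (A**2).sum(axis=1)[:, None]
    sq_b = (B**2).sum(axis=1)[None, :]
    d2 = sq_a + sq_b - 2.0 * (A @ B.T)
    return np.maximum(d2, 0.0)


def center_train_kernel(K: np.ndarray) -> np.ndarray:
    """Feature-space centering Kc = (I - J/n) K (I - J/n)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("training kernel must be square")
    row_means = K.mean(axis=1, keepdims=True)
    grand = K.mean()
    return K - row_means - row_means.T + grand


def center_test_kernel(K_test: np.ndarray, K_train: np.ndarray) -> np.ndarray:
    """Center a test kernel (m x n) with the training kernel's statistics."""
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    K_train = np.asarray(K_train, dtype=float)
    n = K_train.shape[0]
    if K_test.shape[1] != n:
        raise ValueError(f"test kernel has {K_test.shape[1]} columns; expected {n}")
    train_means = K_train.mean(axis=0)  # = row means by symmetry
    test_row_means = K_test.mean(axis=1, keepdims=True)
    return K_test - train_means[None, :] - test_row_means + train_means.mean()


@dataclass
class KPLSModel:
    """Fitted KPLS model (training references + dual coefficients)."""

    sigma: float | None
    threshold: float
    n_components: int  # actually extracted
    dual_coef: np.ndarray  # (n_train,)
    y_mean: float
    scores: np.ndarray  # (n_train, n_components), orthonormal columns
    X_train: np.ndarray | None = None
    K_train: np.ndarray | None = field(default=None, repr=False)  # centered
    K_train_raw: np.ndarray | None = field(default=None, repr=False)  # uncentered

    def to_json_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "threshold": self.threshold,
            "n_components": self.n_components,
            "dual_coef": self.dual_coef.tolist(),
            "y_mean": self.y_mean,
            "scores": self.scores.tolist(),
            "X_train": None if self.X_train is None else self.X_train.tolist(),
            "K_train": None if self.K_train is None else self.K_train.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "KPLSModel":
        return cls(
            sigma=d["sigma"],
            threshold=d["threshold"],
            n_components=d["n_components"],
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            y_mean=d["y_mean"],
            scores=np.asarray(d["scores"], dtype=float),
            X_train=None if d["X_train"] is None else np.asarray(d["X_train"]),
            K_train=None if d["K_train"] is None else np.asarray(d["K_train"]),
        )


def fit_kpls(Kc: np.ndarray, y: np.ndarray, cfg: KernelConfig) -> KPLSModel:
    """Fit KPLS on a centered training kernel and {0,1} responses.

    Components are extracted by dual NIPALS; extraction stops early (with a
    warning) if the requested count exceeds the numerical rank, and the
    actual count is recorded on the model.
    """
    cfg.validate()
    Kc = np.asarray(Kc, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = Kc.shape[0]
    if Kc.shape != (n, n):
        raise ValueError("centered kernel must be square")
    if y.shape[0] != n:
        raise ValueError("y length must match kernel size")
    y_mean = y.mean()
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        raise ValueError("response has zero variance (single-class y)")
    max_comp = min(cfg.n_components, n - 1)

    K_res = Kc.copy()
    y_res = yc.copy()
    ts, us = [], []
    for _ in range(max_comp):
        u = y_res.copy()
        t = K_res @ u
        norm = np.linalg.norm(t)
        if norm < _NORM_TOL:
            logger.warning(
                "component extraction stopped at %d of %d (score norm below tolerance)",
                len(ts), max_comp,
            )
            break
        t /= norm
        ts.append(t)
        us.append(u)
        # symmetric two-sided deflation
        Kt = K_res @ t
        K_res -= np.outer(t, Kt) + np.outer(Kt, t) - (t @ Kt) * np.outer(t, t)
        y_res -= t * (t @ y_res)
    if not ts:
        raise ValueError("no component could be extracted (degenerate kernel)")
    T = np.column_stack(ts)
    U = np.column_stack(us)
    M = T.T @ Kc @ U
    dual_coef = U @ np.linalg.solve(M, T.T @ yc)
    return KPLSModel(
        sigma=cfg.sigma,
        threshold=cfg.threshold,
        n_components=T.shape[1],
        dual_coef=dual_coef,
        y_mean=y_mean,
        scores=T,
        K_train=Kc,
    )


def predict_kpls(model: KPLSModel, Kc_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous response scores and thresholded {0,1} labels for a centered test kernel."""
    Kc_test = np.atleast_2d(np.asarray(Kc_test, dtype=float))
    if Kc_test.shape[1] != model.dual_coef.shape[0]:
        raise ValueError(
            f"test kernel has {Kc_test.shape[1]} columns; model expects {model.dual_coef.shape[0]}"
        )
    scores = Kc_test @ model.dual_coef + model.y_mean
    labels = (scores >= model.threshold).astype(int)
    return scores, labels


def train_kpls(X_train: np.ndarray, y_train: np.ndarray, cfg: KernelConfig) -> KPLSModel:
    """Convenience: build + center the Gaussian kernel and fit on raw features."""
    if cfg.sigma is None:
        raise ValueError("cfg.sigma must be set (tune it first)")
    X_train = np.asarray(X_train, dtype=float)
    K = gaussian_kernel(X_train, X_train, cfg.sigma)
    model = fit_kpls(center_train_kernel(K), y_train, cfg)
    model.X_train = X_train
    model.K_train_raw = K  # uncentered, needed for test centering
    return model


def predict_features(model: KPLSModel, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: predict raw feature rows with a model from :func:`train_kpls`."""
    if model.X_train is None or model.sigma is None:
        raise ValueError("model was not fitted on raw features")
    K_test = gaussian_kernel(np.atleast_2d(X_test), model.X_train, model.sigma)
    Kc_test = center_test_kernel(K_test, model.K_train_raw)
    return predict_kpls(model, Kc_test)
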