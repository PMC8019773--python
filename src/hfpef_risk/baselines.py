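"""The five comparison classifiers, with their tuning contracts pinned.

- lasso / ridge: L1- / L2-penalized logistic regression with the penalty
  strength chosen by 10-fold CV over a 100-value log-spaced grid running four
  decades down from lambda_max (the smallest penalty that zeroes every LASSO
  coefficient).
- svm: soft-margin RBF support vector machine at library defaults
  (C = 1, gamma = 1/p on standardized features); scores are signed decision
  values.
- rf: 500 bootstrap trees, mtry = floor(sqrt(p)), unlimited depth,
  majority-vote labels with vote-fraction scores.
- logit: unpenalized logistic regression, falling back to a negligible ridge
  penalty (1e-8) when complete separation prevents convergence (logged).

All backends are scikit-learn; the parameters above are pinned explicitly so
results do not drift with library defaults.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.svm import SVC

from hfpef_risk.config import BaselineConfig

logger = logging.getLogger(__name__)

METHODS = ("lasso", "ridge", "svm", "rf", "logit")


def _lambda_grid(X: np.ndarray, y: np.ndarray, size: int) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down four decades.

    lambda_max = max_j |x_j' (y - ybar)| / n is the smallest L1 penalty at
    which every LASSO coefficient is zero (KKT condition at beta = 0).
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = float(np.max(np.abs(X.T @ resid)) / n)
    lam_max = max(lam_max, 1e-8)
    return np.logspace(math.log10(lam_max), math.log10(lam_max) - 4.0, size)


def fit_predict_baseline(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: BaselineConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one baseline on the training part and score the test part.

    Returns continuous scores (for AUC) and {0,1} labels (probability cut at
    0.5, margin cut at 0).
    """
    cfg = cfg or BaselineConfig()
    cfg.validate()
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train).astype(int)
    if y_train.min() == y_train.max():
        raise ValueError("y_train must contain both classes")
    seed = int(cfg.seed) % (2**31)

    if method in ("lasso", "ridge"):
        lams = _lambda_grid(X_train, y_train, cfg.lambda_grid_size)
        # sklearn C = 1 / (n * lambda) for penalized logistic loss
        Cs = 1.0 / (len(y_train) * lams)
        clf = LogisticRegressionCV(
            Cs=Cs,
            cv=min(cfg.cv_folds, int(np.bincount(y_train).min())),
            penalty="l1" if method == "lasso" else "l2",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, 1]
        labels = (scores >= 0.5).astype(int)
    elif method == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma=1.0 / X_train.shape[1], random_state=seed)
        clf.fit(X_train, y_train)
        scores = clf.decision_function(X_test)
        labels = (scores >= 0.0).astype(int)
    elif method == "rf":
        clf = RandomForestClassifier(
            n_estimators=cfg.rf_n_trees,
            max_features="sqrt",
            max_depth=None,
            random_state=seed,
        )
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, 1]  # vote fraction
        labels = (scores >= 0.5).astype(int)
    elif method == "logit":
        clf = LogisticRegression(penalty=None, max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X_train, y_train)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        if not converged:
            logger.info("logit did not converge (separation?); ridge fallback 1e-8")
            clf = LogisticRegression(penalty="l2", C=1e8, max_iter=2000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_test)[:, 1]
        labels = (scores >= 0.5).astype(int)
    else:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    return np.asarray(scores, dtype=float), labels


def lasso_coefficients(
    X: np.ndarray, y: np.ndarray, lam: float, seed: int = 0
) -> np.ndarray:
    """LASSO-logistic coefficient vector at a single penalty value."""
    clf = LogisticRegression(
        penalty="l1",
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        max_iter=2000,
        random_state=int(seed) % (2**31),
    )
    clf.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    return clf.coef_.ravel()
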