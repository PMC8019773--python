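"""Classifier metrics, the repeated 80:20 holdout protocol, and model comparison.

Metrics are computed on the positive = poor-outcome (minority death) class:
Se, Sp, ACC, Youden = Se+Sp-1, F-measure, MCC, G-means = sqrt(Se*Sp), and AUC
by the rank (Mann-Whitney) formula with midranks for ties. The protocol
splits the cohort 80:20 (train size = ceil(0.8 n), stratified by outcome),
fits every model on the training part and scores the held-out part, repeated
n_repeats times; per-model summaries are arithmetic means over repeats.
Models are compared by one-way ANOVA on the per-repeat AUC columns followed
by Dunnett's many-to-one test against the control model, with adjusted
p-values from seeded Monte Carlo integration of the equicorrelated
(correlation 1/2) multivariate t distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from hfpef_risk.config import GAConfig, KernelConfig, PipelineConfig, stage_rng

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["se", "sp", "auc", "acc", "youden", "f_measure", "mcc", "g_means"]


@dataclass
class MetricReport:
    se: float
    sp: float
    auc: float
    acc: float
    youden: float
    f_measure: float
    mcc: float
    g_means: float

    def as_dict(self) -> dict:
        return asdict(self)


def auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC = P(random positive outscores a random negative), ties counted 1/2."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def mcc_from_labels(y_true: np.ndarray, labels: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when any confusion marginal is zero."""
    y = np.asarray(y_true).astype(int)
    lab = np.asarray(labels).astype(int)
    tp = int(((y == 1) & (lab == 1)).sum())
    tn = int(((y == 0) & (lab == 0)).sum())
    fp = int(((y == 0) & (lab == 1)).sum())
    fn = int(((y == 1) & (lab == 0)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def confusion_metrics(y_true, labels, scores) -> MetricReport:
    """Full metric report for one model on one split."""
    y = np.asarray(y_true).astype(int)
    lab = np.asarray(labels).astype(int)
    if y.min() == y.max():
        raise ValueError("y_true must contain both classes")
    tp = int(((y == 1) & (lab == 1)).sum())
    tn = int(((y == 0) & (lab == 0)).sum())
    fp = int(((y == 0) & (lab == 1)).sum())
    fn = int(((y == 1) & (lab == 0)).sum())
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / len(y)
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f = 2 * prec * se / (prec + se) if (prec + se) > 0 else 0.0
    return MetricReport(
        se=se,
        sp=sp,
        auc=auc_rank(y, scores),
        acc=acc,
        youden=se + sp - 1.0,
        f_measure=f,
        mcc=mcc_from_labels(y, lab),
        g_means=math.sqrt(se * sp),
    )


def split_indices(
    n: int,
    train_fraction: float,
    rng: np.random.Generator,
    y: np.ndarray | None = None,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One random train/test partition with train size = ceil(train_fraction * n).

    When ``y`` is given and ``stratify`` is on, each class is split as close
    to the ratio as rounding allows (largest-remainder apportionment of the
    overall ceil-sized training set).
    """
    if n < 5:
        raise ValueError("need n >= 5 to split")
    n_train = math.ceil(train_fraction * n)
    if y is None or not stratify:
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 members for a stratified split")
    exact = train_fraction * counts
    base = np.floor(exact).astype(int)
    extra = n_train - base.sum()
    order = np.argsort(-(exact - base))  # largest remainders first
    sizes = base.copy()
    sizes[order[:extra]] += 1
    train_parts, test_parts = [], []
    for cls, sz in zip(classes, sizes):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        train_parts.append(perm[:sz])
        test_parts.append(perm[sz:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignment as (train_idx, test_idx) pairs."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class RepeatTable:
    """Per-repeat, per-model metric reports plus per-model mean summaries."""

    per_repeat: pd.DataFrame  # MultiIndex (repeat, model) x METRIC_COLUMNS

    def summary(self) -> pd.DataFrame:
        out = self.per_repeat.groupby(level="model", sort=False).mean()
        return out.loc[self.models()]

    def auc_matrix(self) -> pd.DataFrame:
        return self.per_repeat["auc"].unstack(level="model")[self.models()]

    def models(self) -> list[str]:
        return list(self.per_repeat.index.get_level_values("model").unique())


def repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    models: list[str],
    cfg: PipelineConfig,
) -> RepeatTable:
    """Run the repeated-holdout benchmark on a screened feature matrix.

    Each repeat draws a fresh stratified 80:20 split, fits every model on the
    training part (the GA re-tunes the KPLS bandwidth inside each repeat's
    training data only), and records the held-out metric report. Splits whose
    test part lacks a class are redrawn (logged); more than 100 consecutive
    failures abort.
    """
    from hfpef_risk.baselines import fit_predict_baseline
    from hfpef_risk.ga import optimize_sigma
    from hfpef_risk.kpls import predict_features, train_kpls
    from hfpef_risk.preprocessing import sis_dimension, sis_screen

    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    rng = stage_rng(cfg.seed, "evaluation")
    rows, index = [], []
    for rep in range(cfg.n_repeats):
        for attempt in range(101):
            tr, te = split_indices(len(y), cfg.train_fraction, rng, y=y,
                                   stratify=cfg.stratify)
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
            logger.info("repeat %d: degenerate split, redrawing", rep)
        else:
            raise RuntimeError("over 100 consecutive degenerate splits")
        rep_seed = int(rng.integers(0, 2**31))
        if cfg.screen_within_split:
            # leakage-free variant: screen on this repeat's training part only
            d = sis_dimension(len(tr), cfg.screen, n_genes=X.shape[1])
            idx = sis_screen(X[tr], y[tr], d, cfg.screen)
            X_rep = X[:, idx]
        else:
            X_rep = X
        for model_name in models:
            if model_name == "ga_kpls":
                gcfg = GAConfig(**{**vars(cfg.ga), "seed": rep_seed})
                ga_res = optimize_sigma(X_rep[tr], y[tr], cfg.kernel, gcfg)
                kcfg = KernelConfig(
                    sigma=ga_res.best_sigma,
                    n_components=cfg.kernel.n_components,
                    threshold=cfg.kernel.threshold,
                )
                model = train_kpls(X_rep[tr], y[tr], kcfg)
                scores, labels = predict_features(model, X_rep[te])
            else:
                from hfpef_risk.config import BaselineConfig

                bcfg = BaselineConfig(**{**vars(cfg.baselines), "seed": rep_seed})
                scores, labels = fit_predict_baseline(
                    model_name, X_rep[tr], y[tr], X_rep[te], bcfg
                )
            rows.append(confusion_metrics(y[te], labels, scores).as_dict())
            index.append((rep, model_name))
    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["repeat", "model"])
    )[METRIC_COLUMNS]
    return RepeatTable(per_repeat=table)


def dunnett_compare(
    auc_matrix: pd.DataFrame,
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA plus Dunnett many-to-one comparison against ``control``.

    Adjusted p-values are two-sided max-|t| tail probabilities of the
    balanced-design equicorrelated (rho = 1/2) multivariate t, estimated by
    seeded Monte Carlo with ``n_draws`` draws.
    """
    if control not in auc_matrix.columns:
        raise ValueError(f"control model {control!r} not among {list(auc_matrix.columns)}")
    others = [c for c in auc_matrix.columns if c != control]
    if not others:
        raise ValueError("need at least two models")
    if len(auc_matrix) < 3:
        raise ValueError("need at least 3 repeats")
    cols = [auc_matrix[c].to_numpy(dtype=float) for c in auc_matrix.columns]
    F, p_anova = stats.f_oneway(*cols)

    k = len(others)
    n_per = len(auc_matrix)
    N = n_per * (k + 1)
    df = N - (k + 1)
    sp2 = float(np.mean([np.var(c, ddof=1) for c in cols]))
    mu_c = float(auc_matrix[control].mean())
    if sp2 == 0.0:  # all columns constant and equal-mean checks below still apply
        t_obs = {
            m: (0.0 if float(auc_matrix[m].mean()) == mu_c else math.inf)
            for m in others
        }
    else:
        t_obs = {
            m: (float(auc_matrix[m].mean()) - mu_c) / math.sqrt(sp2 * 2.0 / n_per)
            for m in others
        }

    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n_draws)
    xj = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    max_abs_t = np.abs((xj - x0[:, None]) / math.sqrt(2.0)) / s[:, None]
    max_abs_t = max_abs_t.max(axis=1)
    adjusted = {m: float(np.mean(max_abs_t >= abs(t))) for m, t in t_obs.items()}
    return {
        "anova_F": float(F) if np.isfinite(F) else 0.0,
        "anova_p": float(p_anova) if np.isfinite(p_anova) else 1.0,
        "control": control,
        "t": t_obs,
        "adjusted_p": adjusted,
        "significant": {m: adjusted[m] < alpha for m in others},
        "n_draws": n_draws,
    }
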