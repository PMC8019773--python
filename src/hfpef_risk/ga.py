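"""Genetic-algorithm tuning of the Gaussian kernel bandwidth.

Chromosomes are real-valued log10 multipliers of the median pairwise
Euclidean distance of the training data (the median heuristic), so the search
range is scale-free. Fitness is the mean cross-validated classification
metric (MCC by default) of a KPLS model fitted at that bandwidth, over
stratified folds whose assignment is fixed per optimizer call — fitness is a
deterministic function of a chromosome within one call, so generations are
comparable. Selection is by tournament, crossover is arithmetic blending,
mutation is Gaussian on the log scale, and the top ``elitism`` chromosomes
are carried over unchanged, which makes the best-fitness trace
non-decreasing. Repeated chromosomes hit a fitness cache.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hfpef_risk.config import GAConfig, KernelConfig
from hfpef_risk.evaluation import auc_rank, mcc_from_labels, stratified_folds
from hfpef_risk.kpls import (
    center_test_kernel,
    center_train_kernel,
    fit_kpls,
    predict_kpls,
    squared_distances,
)


@dataclass
class GAResult:
    best_sigma: float
    best_fitness: float
    history: list[tuple[float, float]]  # per-generation (best, mean)
    evaluations: int
    median_distance: float


def cv_fitness(
    D2: np.ndarray,
    y: np.ndarray,
    sigma: float,
    folds: list[tuple[np.ndarray, np.ndarray]],
    kcfg: KernelConfig,
    metric: str = "mcc",
) -> float:
    """Mean CV metric of KPLS at a given bandwidth, from precomputed distances."""
    K = np.exp(-D2 / (2.0 * sigma**2))
    vals = []
    for tr, te in folds:
        K_tr = K[np.ix_(tr, tr)]
        cfg = KernelConfig(sigma=sigma, n_components=kcfg.n_components,
                           threshold=kcfg.threshold)
        model = fit_kpls(center_train_kernel(K_tr), y[tr], cfg)
        Kc_te = center_test_kernel(K[np.ix_(te, tr)], K_tr)
        scores, labels = predict_kpls(model, Kc_te)
        if metric == "mcc":
            vals.append(mcc_from_labels(y[te], labels))
        elif metric == "accuracy":
            vals.append(float((labels == y[te]).mean()))
        else:  # auc
            vals.append(auc_rank(y[te], scores))
    return float(np.mean(vals))


def grid_search_sigma(
    X: np.ndarray,
    y: np.ndarray,
    kcfg: KernelConfig,
    gcfg: GAConfig,
    n_points: int = 50,
) -> tuple[float, float]:
    """Brute-force log-grid search over the same range and CV folds as the GA.

    Returns (best_sigma, best_cv_fitness); used as the independent benchmark
    for the GA's optimum.
    """
    X = np.asarray(X, dtype=float)
    D2 = squared_distances(X, X)
    med = _median_distance(D2)
    folds = stratified_folds(np.asarray(y), gcfg.cv_folds, gcfg.seed)
    lo, hi = gcfg.sigma_log10_range
    best = (np.nan, -np.inf)
    for g in np.linspace(lo, hi, n_points):
        sigma = med * 10.0**g
        f = cv_fitness(D2, np.asarray(y, dtype=float), sigma, folds, kcfg,
                       gcfg.fitness_metric)
        if f > best[1]:
            best = (sigma, f)
    return best


def _median_distance(D2: np.ndarray) -> float:
    iu = np.triu_indices_from(D2, k=1)
    med = float(np.median(np.sqrt(D2[iu])))
    if med <= 0:
        raise ValueError("zero pairwise distances: degenerate training data")
    return med


def optimize_sigma(
    X_train: np.ndarray,
    y_train: np.ndarray,
    kcfg: KernelConfig,
    gcfg: GAConfig,
) -> GAResult:
    """Tune the Gaussian bandwidth sigma by a real-coded genetic algorithm."""
    gcfg.validate()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    D2 = squared_distances(X, X)
    med = _median_distance(D2)
    folds = stratified_folds(y, gcfg.cv_folds, gcfg.seed)
    rng = np.random.default_rng(gcfg.seed)
    lo, hi = gcfg.sigma_log10_range

    cache: dict[float, float] = {}
    evaluations = 0

    def fitness(g: float) -> float:
        nonlocal evaluations
        key = round(float(g), 12)
        if key not in cache:
            sigma = med * 10.0**g
            cache[key] = cv_fitness(D2, y, sigma, folds, kcfg, gcfg.fitness_metric)
            evaluations += 1
        return cache[key]

    pop = rng.uniform(lo, hi, size=gcfg.population_size)
    fits = np.array([fitness(g) for g in pop])
    history: list[tuple[float, float]] = [(float(fits.max()), float(fits.mean()))]
    best_g, best_f = float(pop[fits.argmax()]), float(fits.max())
    stall = 0

    for _ in range(1, gcfg.n_generations):
        order = np.argsort(-fits)
        elite = pop[order[: gcfg.elitism]]
        children = list(elite)
        while len(children) < gcfg.population_size:
            # tournament selection for two parents
            parents = []
            for _ in range(2):
                idx = rng.integers(0, gcfg.population_size, size=gcfg.tournament_size)
                parents.append(pop[idx[np.argmax(fits[idx])]])
            p1, p2 = parents
            if rng.random() < gcfg.crossover_rate:
                alpha = rng.random()
                c1 = alpha * p1 + (1 - alpha) * p2
                c2 = alpha * p2 + (1 - alpha) * p1
            else:
                c1, c2 = p1, p2
            for c in (c1, c2):
                if len(children) >= gcfg.population_size:
                    break
                if rng.random() < gcfg.mutation_rate:
                    c = c + rng.normal(0.0, gcfg.mutation_sd)
                children.append(float(np.clip(c, lo, hi)))
        pop = np.array(children)
        fits = np.array([fitness(g) for g in pop])
        gen_best = float(fits.max())
        history.append((max(gen_best, best_f), float(fits.mean())))
        if gen_best > best_f + 1e-12:
            best_g, best_f = float(pop[fits.argmax()]), gen_best
            stall = 0
        else:
            stall += 1
            if stall >= gcfg.patience:
                break

    return GAResult(
        best_sigma=med * 10.0**best_g,
        best_fitness=best_f,
        history=history,
        evaluations=evaluations,
        median_distance=med,
    )
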