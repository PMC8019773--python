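"""SAM-style differential expression between outcome groups.

The per-gene statistic is a moderated t, d_i = (mean_poor,i - mean_good,i) /
(s_i + s0), where s_i is the pooled standard error of the mean difference and
s0 is a global "fudge factor" that damps the statistic for genes with tiny
variance. s0 is chosen as the percentile of {s_i} (searched over
0, 5, ..., 100) that minimizes the coefficient of variation of the median
absolute deviation of d across s-quantile bins, the classic stabilization
criterion.

q-values come from a permutation null: the outcome labels are permuted
n_perm times (s0 held fixed at its observed-data value), and each gene's q is
the median count of null |d| values at or above its observed |d|, divided by
the observed count at or above it — a permutation FDR — then monotonized so q
never decreases as |d| decreases. The good-outcome group is the control, so
direction "up" means elevated expression in poor-outcome patients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SamResult:
    table: pd.DataFrame  # per-gene: d, s, q, direction, called
    s0: float
    n_permutations: int
    threshold: float

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]

    def counts(self) -> dict:
        calls = self.called
        return {
            "n_deg": int(len(calls)),
            "n_up": int((calls["direction"] == "up").sum()),
            "n_down": int((calls["direction"] == "down").sum()),
        }


def _diff_and_se(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene poor-minus-good mean difference and its pooled SE.

    X is genes x samples; y is 0 (good) / 1 (poor).
    """
    y = np.asarray(y).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs >= 2 samples")
    Xp = X[:, y == 1]
    Xg = X[:, y == 0]
    diff = Xp.mean(axis=1) - Xg.mean(axis=1)
    ss = ((Xp - Xp.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (Xg - Xg.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n0) * ss / (n1 + n0 - 2))
    return diff, s


def sam_d_statistics(X: np.ndarray, y: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Moderated d statistics and pooled SEs for every gene."""
    diff, s = _diff_and_se(np.asarray(X, dtype=float), y)
    return diff / (s + s0), s


def choose_s0(d_num: np.ndarray, s: np.ndarray, n_bins: int = 100) -> float:
    """SAM fudge factor: the s-percentile stabilizing |d|'s spread.

    Searches s0 over the 0th, 5th, ..., 100th percentiles of {s_i}; for each
    candidate, genes are cut into s-quantile bins and the candidate minimizing
    the coefficient of variation of the per-bin MAD of d wins.
    """
    d_num = np.asarray(d_num, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(s) < 20:
        raise ValueError("need >= 20 genes for stable quantile bins")
    if np.allclose(s, s[0]):
        return 0.0
    n_bins = min(n_bins, max(2, len(s) // 5))
    bins = pd.qcut(s, q=n_bins, labels=False, duplicates="drop")
    best_s0, best_cv = 0.0, math.inf
    for alpha in range(0, 101, 5):
        s0 = float(np.percentile(s, alpha))
        d = d_num / (s + s0)
        mads = (
            pd.Series(d).groupby(bins).apply(lambda v: np.median(np.abs(v - np.median(v))))
        ).to_numpy()
        mean = mads.mean()
        cv = mads.std(ddof=1) / mean if mean > 0 else math.inf
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def sam_qvalues(
    X,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = 0.05,
) -> SamResult:
    """Permutation-FDR q-values and DEG calls for a genes x samples matrix."""
    if isinstance(X, pd.DataFrame):
        gene_ids = list(X.index)
        V = X.to_numpy(dtype=float)
    else:
        V = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(V.shape[0])]
    y = np.asarray(y).astype(int)
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 (or exact enumeration)")
    n = len(y)
    n_distinct = math.comb(n, int(y.sum()))
    exact = n_perm >= n_distinct
    if exact:
        logger.info("n_perm >= %d distinct label permutations: exact enumeration", n_distinct)

    diff, s = _diff_and_se(V, y)
    s0 = choose_s0(diff, s)
    d_obs = diff / (s + s0)
    abs_d = np.abs(d_obs)

    rng = np.random.default_rng(seed)
    if exact:
        from itertools import combinations

        perms = []
        for pos in combinations(range(n), int(y.sum())):
            yp = np.zeros(n, dtype=int)
            yp[list(pos)] = 1
            perms.append(yp)
    else:
        perms = [rng.permutation(y) for _ in range(n_perm)]

    order = np.argsort(abs_d)  # ascending
    sorted_abs = abs_d[order]
    # observed count at or above each gene's |d|
    obs_exceed = len(abs_d) - np.searchsorted(sorted_abs, abs_d, side="left")
    null_counts = np.empty((len(perms), len(abs_d)))
    for b, yp in enumerate(perms):
        diff_b, s_b = _diff_and_se(V, yp)
        abs_null = np.sort(np.abs(diff_b / (s_b + s0)))
        null_counts[b] = len(abs_null) - np.searchsorted(abs_null, abs_d, side="left")
    med_null = np.median(null_counts, axis=0)
    q = np.clip(med_null / np.maximum(obs_exceed, 1), 0.0, 1.0)

    # monotonize: q non-increasing as |d| increases (each gene takes the
    # smallest raw FDR among genes no more extreme than itself, BH-style)
    q_sorted = np.minimum.accumulate(q[order])
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    direction = np.where(diff > 0, "up", "down")
    table = pd.DataFrame(
        {
            "d": d_obs,
            "s": s,
            "q": q_mono,
            "direction": direction,
            "called": q_mono < threshold,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    ).sort_values(["called", "d"], key=lambda c: np.abs(c) if c.name == "d" else c,
                  ascending=[False, False])
    return SamResult(
        table=table, s0=s0, n_permutations=len(perms), threshold=threshold
    )
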