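"""Kaplan-Meier estimation and log-rank comparison of risk groups.

The product-limit estimator and the two-group log-rank test are computed with
lifelines; this module fixes the conventions used throughout the pipeline
(right-continuous steps at event times, censoring ties at an event time
treated as at-risk through that time — lifelines' standard behaviour) and
returns plain arrays/JSON-ready structures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


def km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Returns a DataFrame with columns ``time`` and ``survival`` giving the
    right-continuous step function (including the t=0 point, S=1).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if len(time) == 0:
        raise ValueError("need at least one record")
    if (time < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                         "survival": sf.iloc[:, 0].to_numpy(dtype=float)})


def survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_curve step function at time t (right-continuous)."""
    mask = curve["time"].to_numpy() <= t
    if not mask.any():
        return 1.0
    return float(curve["survival"].to_numpy()[mask][-1])


def logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank chi-squared statistic (1 df) and p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("need at least one event")
    a = group == labels[0]
    res = logrank_test(time[a], time[~a], event_observed_A=event[a],
                       event_observed_B=event[~a])
    return float(res.test_statistic), float(res.p_value)


def km_summary(pheno: pd.DataFrame, group_col: str = "outcome") -> dict:
    """JSON-ready KM step coordinates per group plus the log-rank comparison."""
    groups = {}
    for label, sub in pheno.groupby(group_col):
        curve = km_curve(sub["time"].to_numpy(), sub["event"].to_numpy())
        name = {0: "good", 1: "poor"}.get(label, str(label))
        groups[name] = {
            "time": curve["time"].tolist(),
            "survival": curve["survival"].tolist(),
            "n": int(len(sub)),
            "events": int(sub["event"].sum()),
        }
    stat, p = logrank(
        pheno["time"].to_numpy(), pheno["event"].to_numpy(),
        pheno[group_col].to_numpy(),
    )
    return {"groups": groups, "logrank_statistic": stat, "logrank_p": p}
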