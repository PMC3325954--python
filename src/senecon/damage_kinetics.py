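"""Comet-assay tail-DNA summaries, group comparisons, and recovery fitting.

Percent tail DNA is summarized as a five-number (median / quartile /
5th-95th percentile) box-plot table per group and timepoint, groups are
compared by a two-sample t-test (rank-sum as a secondary check), and
post-damage recovery is fit to a single-exponential decay to a plateau,

    D(t) = D_inf + (D0 - D_inf) * exp(-k t).

The kinetic fit is a modeling extension over per-timepoint testing and is
labeled as such in its report output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RecoveryFit",
    "tail_summary",
    "compare_tail_distributions",
    "recovery_model",
    "fit_recovery_curve",
]

#: minimum cells per condition before a summary warns
MIN_CELLS = 50


@dataclass(frozen=True)
class RecoveryFit:
    """Fitted exponential-recovery parameters for a comet time-course."""

    d0: float
    d_inf: float
    k: float
    rss: float
    stderr: dict[str, float]
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.d_inf > self.d0 + 1e-9:
            raise ValueError("fitted d_inf must not exceed d0")
        if self.k < 0:
            raise ValueError("fitted k must be >= 0")

    def to_dict(self) -> dict:
        return {
            "model": "D(t) = D_inf + (D0 - D_inf)*exp(-k*t)  [kinetic extension]",
            "d0": self.d0,
            "d_inf": self.d_inf,
            "k_per_min": self.k,
            "rss": self.rss,
            "stderr": self.stderr,
            "n_timepoints": self.n_timepoints,
        }


def _five_number(x: np.ndarray) -> dict[str, float]:
    # linear interpolation between order statistics ("inclusive" rule)
    q = np.percentile(x, [5, 25, 50, 75, 95], method="linear")
    return {"p5": q[0], "q25": q[1], "median": q[2], "q75": q[3], "p95": q[4]}


def tail_summary(
    records: pd.DataFrame, by: tuple[str, ...] = ("group", "time_min")
) -> pd.DataFrame:
    """Five-number summary of percent tail DNA per group x timepoint cell."""
    _validate_tail(records)
    rows = []
    cols = [c for c in by if c in records.columns]
    if not cols:
        raise ValueError(f"none of the grouping columns {by} present")
    for keys, sub in records.groupby(list(cols), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        x = np.asarray(sub["tail_percent"], float)
        if len(x) < MIN_CELLS:
            warnings.warn(
                f"cell-group {dict(zip(cols, keys))} has only {len(x)} cells "
                f"(< {MIN_CELLS})",
                stacklevel=2,
            )
        row = dict(zip(cols, keys))
        row.update(_five_number(x))
        row["n"] = len(x)
        rows.append(row)
    return pd.DataFrame(rows)


def _validate_tail(records: pd.DataFrame) -> None:
    x = np.asarray(records["tail_percent"], float)
    if ((x < 0) | (x > 100)).any():
        raise ValueError("tail_percent must lie in [0, 100]")
    if "time_min" in records.columns and (np.asarray(records["time_min"], float) < 0).any():
        raise ValueError("time_min must be >= 0")


def compare_tail_distributions(
    a: pd.DataFrame | np.ndarray, b: pd.DataFrame | np.ndarray, *, equal_var: bool = True
) -> dict[str, float]:
    """Two-sided t-test (primary) and rank-sum (secondary) on tail percent."""
    xa = np.asarray(a["tail_percent"] if isinstance(a, pd.DataFrame) else a, float)
    xb = np.asarray(b["tail_percent"] if isinstance(b, pd.DataFrame) else b, float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 records per group")
    diff = float(xa.mean() - xb.mean())
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        p_t = 1.0 if diff == 0 else float(np.finfo(float).tiny)
    else:
        p_t = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
    try:
        p_rank = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
    except ValueError:  # all values identical
        p_rank = 1.0
    return {"p_ttest": p_t, "p_ranksum": p_rank, "mean_difference": diff}


def recovery_model(t: np.ndarray, d0: float, d_inf: float, k: float) -> np.ndarray:
    return d_inf + (d0 - d_inf) * np.exp(-k * np.asarray(t, float))


def fit_recovery_curve(records: pd.DataFrame) -> RecoveryFit:
    """Least-squares exponential-recovery fit to per-timepoint means.

    Parameters are bounded (0 <= D_inf <= D0 <= 100, k >= 0) via the
    reparameterization ``D0 = D_inf + delta`` with ``delta >= 0``.
    Initialization is deterministic: D0 from the earliest timepoint mean,
    D_inf from the latest, and k from a half-life guess at the timepoint whose
    mean is nearest the midpoint.
    """
    _validate_tail(records)
    means = records.groupby("time_min")["tail_percent"].mean()
    t = np.asarray(means.index, float)
    y = np.asarray(means, float)
    if len(t) < 3:
        raise ValueError(f"need >= 3 distinct timepoints, got {len(t)}")

    d0_init = y[np.argmin(t)]
    dinf_init = y[np.argmax(t)]
    mid = 0.5 * (d0_init + dinf_init)
    pos = np.argsort(np.abs(y - mid))
    t_half = next((t[i] for i in pos if t[i] > 0), max(t.max(), 1.0))
    k_init = np.log(2) / t_half
    dinf_init = float(np.clip(dinf_init, 0, 100))
    delta_init = float(np.clip(d0_init - dinf_init, 0, 100 - dinf_init))

    def residuals(theta: np.ndarray) -> np.ndarray:
        d_inf, delta, k = theta
        return recovery_model(t, d_inf + delta, d_inf, k) - y

    sol = optimize.least_squares(
        residuals,
        x0=[dinf_init, delta_init, k_init],
        bounds=([0.0, 0.0, 0.0], [100.0, 100.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"recovery fit did not converge: {sol.message}")
    d_inf, delta, k = sol.x
    rss = float((sol.fun**2).sum())

    # approximate parameter SEs from the Jacobian at the solution
    dof = max(len(t) - 3, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        # delta-method: var(d0) = var(d_inf) + var(delta) + 2 cov
        se_d0 = float(np.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0)))
        stderr = {"d0": se_d0, "d_inf": float(se[0]), "k": float(se[2])}
    except np.linalg.LinAlgError:
        stderr = {"d0": float("nan"), "d_inf": float("nan"), "k": float("nan")}
    return RecoveryFit(
        d0=float(d_inf + delta), d_inf=float(d_inf), k=float(k),
        rss=rss, stderr=stderr, n_timepoints=len(t),
    )
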