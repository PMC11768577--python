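"""Subgroup summaries of individual PK parameters and terminal-phase curves.

Reports geometric means and geometric SDs of individual parameter
estimates (EBEs or simulated truths) across subgroups defined by
covariate categories or ranges, and per-group mean log-concentration
curves over a terminal time window for visual clearance comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubgroupSummary",
    "geometric_stats",
    "summarize_subgroups",
    "terminal_phase_curves",
]


@dataclass(frozen=True)
class SubgroupSummary:
    subgroup: str
    parameter: str
    geometric_mean: float | None
    geometric_sd: float | None
    n: int


def geometric_stats(values) -> tuple:
    """``(geometric mean, geometric SD)``: exp of the log-domain moments."""
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("geometric statistics require strictly positive values")
    logs = np.log(v)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if len(v) > 1 else 1.0
    return gm, gsd


def _apply_filters(df: pd.DataFrame, filters: dict | None) -> pd.DataFrame:
    if not filters:
        return df
    out = df
    for col, cond in filters.items():
        if isinstance(cond, (list, tuple)) and len(cond) == 2 and all(
            isinstance(x, (int, float)) for x in cond
        ):
            out = out[(out[col] >= cond[0]) & (out[col] <= cond[1])]
        elif isinstance(cond, (list, tuple, set)):
            out = out[out[col].isin(list(cond))]
        else:
            out = out[out[col] == cond]
    return out


def summarize_subgroups(
    params: pd.DataFrame,
    covariates: pd.DataFrame,
    grouping: list,
    parameters: list | None = None,
    filters: dict | None = None,
) -> list:
    """Geometric stats of individual parameters per subgroup.

    ``grouping`` is a list of ``(name, {col: condition})`` pairs, each
    condition either a (lo, hi) numeric range, a category set, or a single
    value. ``filters`` restrict the whole analysis first (e.g. healthy
    adults). Empty subgroups are reported with ``n = 0`` and missing stats.
    """
    merged = params.merge(covariates, on="ID")
    merged = _apply_filters(merged, filters)
    if parameters is None:
        parameters = [c for c in params.columns if c != "ID" and not c.startswith("eta_")]
    for _, cond in grouping:
        for col in cond:
            if col not in merged.columns:
                raise KeyError(f"grouping references unknown covariate {col!r}")
    out = []
    for name, cond in grouping:
        sub = _apply_filters(merged, cond)
        for p in parameters:
            if len(sub) == 0:
                out.append(SubgroupSummary(name, p, None, None, 0))
                continue
            gm, gsd = geometric_stats(sub[p].to_numpy())
            out.append(SubgroupSummary(name, p, gm, gsd, len(sub)))
    return out


def subgroup_table(summaries: list) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def terminal_phase_curves(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    grouping: list,
    t_window: tuple,
    filters: dict | None = None,
) -> pd.DataFrame:
    """Per-group mean log-concentration vs time over a terminal window.

    ``observations`` needs ID/TIME/DV columns (DV > 0 rows are used).
    Returns a long table (group, TIME, mean_log_conc, n); raises if a
    group has no observations in the window or the window is empty.
    """
    lo, hi = t_window
    if hi <= lo:
        raise ValueError("empty terminal window")
    obs = observations[(observations["TIME"] >= lo) & (observations["TIME"] <= hi)]
    obs = obs[obs["DV"] > 0]
    merged = obs.merge(covariates, on="ID")
    merged = _apply_filters(merged, filters)
    rows = []
    for name, cond in grouping:
        sub = _apply_filters(merged, cond)
        if len(sub) == 0:
            raise ValueError(f"group {name!r} has no observations in the window")
        g = sub.groupby("TIME")["DV"].agg([("mean_log_conc", lambda v: float(np.mean(np.log(v)))),
                                           ("n", "size")]).reset_index()
        g.insert(0, "group", name)
        rows.append(g)
    return pd.concat(rows, ignore_index=True)
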