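"""Non-compartmental analysis and fold-error validation arithmetic.

AUC uses the linear trapezoidal rule with equal weighting. The terminal
slope lambda_z is selected by log-linear regression over all contiguous
terminal windows of at least three post-peak points, maximizing adjusted
R^2 (ties broken toward more points). Fold-error is the directional ratio
``max(observed/predicted, predicted/observed)`` with the <2-fold
reliability rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

__all__ = [
    "NCAResult",
    "auc_trapezoid",
    "fit_lambda_z",
    "nca_summary",
    "fold_error",
    "round_half_up",
]


@dataclass(frozen=True)
class NCAResult:
    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float | None
    lambda_z: float | None
    lambda_z_adj_r2: float | None
    t_half: float | None
    cl_over_f: float | None
    vz_over_f: float | None
    n_terminal_points: int


def auc_trapezoid(times, conc) -> float:
    """Linear-trapezoidal AUC over the full observation range."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for trapezoidal AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return float(np.trapezoid(c, t))


def _adjusted_r2(r2: float, m: int) -> float:
    return 1.0 - (1.0 - r2) * (m - 1) / (m - 2)


def fit_lambda_z(times, conc) -> tuple:
    """Terminal-slope fit: ``(lambda_z, adjusted_r2, n_points)``.

    Candidate windows end at the last observation and start after tmax
    (the peak itself is excluded); points with non-positive concentration
    are excluded from the log regression. Raises ``ValueError`` when no
    window of >= 3 positive post-peak points with a negative slope exists.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    i_max = int(np.argmax(c))
    mask = (np.arange(len(t)) > i_max) & (c > 0)
    tt, cc = t[mask], np.log(c[mask])
    m = len(tt)
    if m < 3:
        raise ValueError("need >= 3 positive post-peak points for lambda_z")
    best = None
    for start in range(0, m - 2):
        w_t, w_c = tt[start:], cc[start:]
        res = stats.linregress(w_t, w_c)
        if res.slope >= 0:
            continue
        adj = _adjusted_r2(res.rvalue**2, len(w_t))
        npts = len(w_t)
        if best is None or adj > best[1] + 1e-12 or (abs(adj - best[1]) <= 1e-12 and npts > best[2]):
            best = (-res.slope, adj, npts)
    if best is None:
        raise ValueError("no admissible terminal window (non-negative slopes)")
    return best


def nca_summary(times, conc, dose: float) -> NCAResult:
    """Full NCA for one profile. ``dose`` in mg, conc in ug/mL, times in h.

    ``auc_inf = auc_last + c_last / lambda_z``; ``cl_over_f = dose / auc_inf``
    (mg per ug/mL.h = L scale consistent when conc is in mg/L = ug/mL).
    Extrapolated fields are ``None`` when the terminal fit is unavailable.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    auc_last = auc_trapezoid(t, c)
    try:
        lam, adj, npts = fit_lambda_z(t, c)
    except ValueError:
        return NCAResult(cmax, tmax, auc_last, None, None, None, None, None, None, 0)
    c_last = float(c[-1])
    auc_inf = auc_last + c_last / lam
    t_half = math.log(2.0) / lam
    cl_f = dose / auc_inf
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        lambda_z=lam,
        lambda_z_adj_r2=adj,
        t_half=t_half,
        cl_over_f=cl_f,
        vz_over_f=cl_f / lam,
        n_terminal_points=npts,
    )


def fold_error(observed: float, predicted: float) -> float:
    """Directional fold-error: the larger of the two ratios (always >= 1)."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold-error requires strictly positive values")
    return max(observed / predicted, predicted / observed)


def is_reliable(observed: float, predicted: float) -> bool:
    """The <2-fold acceptance rule for PBPK predictions."""
    return fold_error(observed, predicted) < 2.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching printed-table conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
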