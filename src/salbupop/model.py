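"""Population PK structural and statistical model.

Structure: two-compartment disposition with linear elimination and
first-order absorption preceded by a transit-compartment chain. The chain
is implemented in closed form as a gamma-density dose-input rate

    rate(t) = F D Ktr (Ktr t)^n exp(-Ktr t) / Gamma(n+1),   n = Ktr Mtt - 1,

which integrates to the bioavailable dose and supports non-integer transit
numbers. Parameters are apparent (``/F``): bioavailability is absorbed into
Cl/F, V/F, so ``bio_f`` is fixed at 1 in prediction.

Statistics: individual parameters are normal, ``p_i = theta + X beta + eta``
with additive covariate effects (continuous covariates centered, categorical
effects per non-reference category) and diagonal-covariance eta. Residual
error is combined, ``sd = sqrt(a^2 + b^2 f^2)`` (combined2 default).

Two prediction paths are provided: a reference ODE integration
(:func:`predict_conc`, ``method='ode'``) and a fast batched semi-analytic
convolution of the gamma input with the analytic three-exponential
disposition impulse response on a uniform grid (``method='conv'``,
:func:`conc_profiles_batch`), used by the estimation and simulation engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import gammainc, gammaln

__all__ = [
    "PARAM_NAMES",
    "StructuralParams",
    "ErrorModel",
    "CovariateLink",
    "PopulationModel",
    "PKDataset",
    "transit_input_rate",
    "predict_conc",
    "conc_profiles_batch",
    "individual_params",
    "residual_sd",
    "simulate_dataset",
    "default_population_model",
]

PARAM_NAMES = ("Mtt", "Ktr", "ka", "Cl", "V1", "Q", "V2")

#: categorical covariate encodings used in event-record datasets
CATEGORICAL_CODES = {
    "SEX": {"male": 0, "female": 1},
    "RACE": {"american": 0, "asian": 1, "chinese": 2},
    "HEALTH": {"healthy": 0, "obese": 1, "cirrhosis_a": 2},
}


@dataclass(frozen=True)
class StructuralParams:
    Mtt: float   # h
    Ktr: float   # 1/h
    ka: float    # 1/h
    Cl: float    # L/h (apparent)
    V1: float    # L (apparent)
    Q: float     # L/h (apparent)
    V2: float    # L (apparent)

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals <= 0):
            raise ValueError("all structural parameters must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StructuralParams":
        return cls(**dict(zip(PARAM_NAMES, np.asarray(arr, dtype=float))))

    @property
    def n_transit(self) -> float:
        return self.Ktr * self.Mtt - 1.0


@dataclass(frozen=True)
class ErrorModel:
    a: float            # additive, DV units (ug/mL)
    b: float            # proportional
    form: str = "combined2"

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or (self.a == 0 and self.b == 0):
            raise ValueError("error constants must be >= 0 and not both zero")
        if self.form not in ("combined2", "combined1"):
            raise ValueError(f"unknown error-model form {self.form!r}")

    def sd(self, f):
        f = np.asarray(f, dtype=float)
        if self.form == "combined1":
            return self.a + self.b * np.abs(f)
        return np.sqrt(self.a**2 + (self.b * f) ** 2)


def residual_sd(f, error: ErrorModel):
    """Residual standard deviation at predicted concentration(s) ``f``."""
    return error.sd(f)


@dataclass(frozen=True)
class CovariateLink:
    """Additive covariate effect on one structural parameter.

    Continuous: contribution ``beta * (cov - reference)``. Categorical:
    ``beta`` per non-reference ``category`` (one link per category).
    """

    parameter: str
    covariate: str
    kind: str                    # 'continuous' | 'categorical'
    beta: float = 0.0
    reference: float | str = 0.0
    category: str | int | None = None   # categorical only

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError("kind must be continuous or categorical")
        if self.kind == "categorical" and self.category is None:
            raise ValueError("categorical link needs a category")

    @property
    def label(self) -> str:
        if self.kind == "categorical":
            return f"beta_{self.parameter}_{self.covariate}_{self.category}"
        return f"beta_{self.parameter}_{self.covariate}"

    def contribution(self, value) -> float:
        if self.kind == "continuous":
            return self.beta * (float(value) - float(self.reference))
        return self.beta if _cat_matches(self.covariate, value, self.category) else 0.0


def _cat_matches(covariate: str, value, category) -> bool:
    codes = CATEGORICAL_CODES.get(covariate.upper(), {})
    if isinstance(value, str):
        value = codes.get(value, value)
    if isinstance(category, str):
        category = codes.get(category, category)
    return value == category


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, IIV standard deviations, covariate links and error."""

    theta: dict
    omega: dict
    error: ErrorModel
    links: tuple = ()
    dv_unit: str = "ug/mL"

    def __post_init__(self) -> None:
        StructuralParams(**{p: self.theta[p] for p in PARAM_NAMES})
        if any(self.omega.get(p, 0.0) < 0 for p in PARAM_NAMES):
            raise ValueError("omega values must be non-negative")

    def theta_array(self) -> np.ndarray:
        return np.array([self.theta[p] for p in PARAM_NAMES])

    def omega_array(self) -> np.ndarray:
        return np.array([self.omega.get(p, 0.0) for p in PARAM_NAMES])

    def with_links(self, links) -> "PopulationModel":
        return replace(self, links=tuple(links))


def default_population_model() -> PopulationModel:
    """The packaged final-model parameter set."""
    from . import defaults

    d = defaults.final_model_dict()
    return PopulationModel(
        theta={p: float(d["theta"][p]) for p in PARAM_NAMES},
        omega={p: float(d["omega"][p]) for p in PARAM_NAMES},
        error=ErrorModel(
            a=float(d["error"]["a"]), b=float(d["error"]["b"]), form=d["error"].get("form", "combined2")
        ),
        links=tuple(d.get("links") or ()),
        dv_unit=d.get("dv_unit", "ug/mL"),
    )


# ---------------------------------------------------------------------------
# transit input and prediction
# ---------------------------------------------------------------------------

def transit_input_rate(t, dose: float, bio_f: float, mtt: float, ktr: float):
    """Dose-input rate (ug/h) of the gamma transit chain at time(s) ``t``."""
    n = ktr * mtt - 1.0
    if n <= -1.0:
        raise ValueError("transit number n = Ktr*Mtt - 1 must exceed -1")
    t = np.asarray(t, dtype=float)
    rate = np.zeros_like(t)
    pos = t > 0
    x = ktr * t[pos]
    rate[pos] = bio_f * dose * ktr * np.exp(n * np.log(x) - x - gammaln(n + 1.0))
    if n == 0:
        rate[t == 0] = bio_f * dose * ktr
    return rate if rate.ndim else float(rate)


def _disposition_modes(params: StructuralParams | np.ndarray):
    """Eigen-rates and central-concentration coefficients of the linear
    depot -> two-compartment system.

    For a unit bolus into the depot, ``C(t) = sum_i B_i exp(-lam_i t)`` with
    ``lam = (alpha, beta, ka)``. Inputs may be a (B, 7) parameter matrix.
    """
    if isinstance(params, StructuralParams):
        arr = params.as_array()[None, :]
    else:
        arr = np.atleast_2d(np.asarray(params, dtype=float))
    mtt, ktr, ka, cl, v1, q, v2 = (arr[:, i] for i in range(7))
    ke = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = ke + k12 + k21
    disc = np.sqrt(np.maximum(s**2 - 4.0 * ke * k21, 0.0))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    # nudge coincident rates apart to keep the partial fractions finite
    lam = np.stack([alpha, beta, ka], axis=1)
    for i in range(3):
        for j in range(i + 1, 3):
            close = np.abs(lam[:, i] - lam[:, j]) < 1e-8 * np.maximum(lam[:, i], lam[:, j])
            lam[close, j] *= 1.0 + 1e-6
    alpha, beta, ka = lam[:, 0], lam[:, 1], lam[:, 2]
    coef = np.empty_like(lam)
    coef[:, 0] = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    coef[:, 1] = (k21 - beta) / ((ka - beta) * (alpha - beta))
    coef[:, 2] = (k21 - ka) / ((alpha - ka) * (beta - ka))
    coef *= (ka / v1)[:, None]
    return lam, coef


def conc_profiles_batch(
    params: np.ndarray,
    dose_times: np.ndarray,
    dose_amounts: np.ndarray,
    grid_end: float,
    dt: float = 0.0625,
    obs_times: np.ndarray | None = None,
) -> np.ndarray:
    """Concentration (ug/mL) for a batch of parameter vectors.

    ``params`` is (B, 7) in PARAM_NAMES order; doses are shared across the
    batch (amounts in ug). The gamma transit input is discretized by exact
    interval masses (regularized incomplete gamma differences) as a
    piecewise-constant rate on a uniform grid, then convolved with the
    analytic disposition modes by an exact one-step recurrence. Returns
    (B, len(obs_times)) if ``obs_times`` given, else (B, K+1) grid values.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    params = np.maximum(params, 1e-6)  # estimation-time guard (flagged upstream)
    B = params.shape[0]
    K = int(np.ceil(grid_end / dt + 1e-9))
    tg = np.arange(K + 1) * dt
    mtt, ktr = params[:, 0], params[:, 1]
    n = ktr * mtt - 1.0
    n = np.maximum(n, -1.0 + 1e-9)
    shape = n + 1.0

    # cumulative input fraction for a dose at t=0, per batch member
    cum = gammainc(shape[:, None], ktr[:, None] * tg[None, :])   # (B, K+1)
    seg = np.diff(cum, axis=1)                                    # (B, K)
    rate = np.zeros((B, K))
    for t_d, amt in zip(np.atleast_1d(dose_times), np.atleast_1d(dose_amounts)):
        off = int(round(t_d / dt))
        if abs(off * dt - t_d) > 1e-9:
            raise ValueError("dose times must lie on the prediction grid")
        if off >= K:
            continue
        rate[:, off:] += amt * seg[:, : K - off] / dt

    lam, coef = _disposition_modes(params)        # (B, 3) each
    E = np.exp(-lam * dt)                         # decay over one step
    W = np.where(lam > 0, (1.0 - E) / np.where(lam > 0, lam, 1.0), dt)
    y = np.zeros((B, 3))
    out = np.zeros((B, K + 1))
    for k in range(K):
        y = y * E + rate[:, k][:, None] * W
        out[:, k + 1] = np.sum(coef * y, axis=1)
    out /= 1000.0  # ug/L -> ug/mL
    if obs_times is None:
        return out
    obs_times = np.asarray(obs_times, dtype=float)
    # shared-grid linear interpolation, vectorized across the batch
    pos = np.clip(np.searchsorted(tg, obs_times, side="right") - 1, 0, K - 1)
    w = (obs_times - tg[pos]) / dt
    return out[:, pos] * (1.0 - w) + out[:, pos + 1] * w


def predict_conc(
    params: StructuralParams,
    doses,
    times,
    bio_f: float = 1.0,
    method: str = "ode",
    rtol: float = 1e-8,
    dt: float = 0.0125,
) -> np.ndarray:
    """Plasma concentration (ug/mL) at ``times`` for one parameter set.

    ``doses`` is a ``DoseRegimen`` or a list of ``(time_h, amount_ug)``.
    ``method='ode'`` integrates the depot/central/peripheral system with
    the gamma-rate forcing at tight tolerance; ``method='conv'`` uses the
    fast convolution path (shared with the estimation engine).
    """
    from .pbpk import DoseRegimen  # local import to avoid a cycle

    if isinstance(doses, DoseRegimen):
        dose_list = [(float(t), doses.dose_ug) for t in doses.dose_times]
    else:
        dose_list = [(float(t), float(a)) for t, a in doses]
    times = np.asarray(times, dtype=float)
    if len(dose_list) == 0 or all(a == 0 for _, a in dose_list):
        return np.zeros_like(times)
    t_end = max(times.max(), max(t for t, _ in dose_list))

    if method == "conv":
        dtimes = np.array([t for t, _ in dose_list])
        damts = np.array([a * bio_f for _, a in dose_list])
        return conc_profiles_batch(params.as_array(), dtimes, damts, t_end, dt=dt, obs_times=times)[0]

    mtt, ktr, ka = params.Mtt, params.Ktr, params.ka
    ke, k12, k21 = params.Cl / params.V1, params.Q / params.V1, params.Q / params.V2

    def rate_in(t):
        total = 0.0
        for td, amt in dose_list:
            if t > td:
                total += transit_input_rate(t - td, amt, bio_f, mtt, ktr)
        return total

    def rhs(t, y):
        aa, ac, ap = y
        return [
            rate_in(t) - ka * aa,
            ka * aa - (ke + k12) * ac + k21 * ap,
            k12 * ac - k21 * ap,
        ]

    t_eval = np.unique(np.concatenate([times, [0.0, t_end]]))
    # cap the step to resolve sharply peaked transit inputs (small Mtt)
    max_step = min(1.0, max(mtt / 4.0, 1e-3))
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=1e-12,
        max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"prediction ODE failed: {sol.message}")
    conc = sol.y[1] / params.V1 / 1000.0  # ug/mL
    return np.interp(times, sol.t, conc)


# ---------------------------------------------------------------------------
# individual parameters & dataset simulation
# ---------------------------------------------------------------------------

def individual_params(
    pop: PopulationModel,
    covariates: dict,
    eta: dict | np.ndarray,
    clip: bool = True,
) -> StructuralParams:
    """Individual parameters ``theta + covariate effects + eta``.

    Non-positive results are clipped to 1e-6 when ``clip`` (estimation
    convention); simulation uses rejection-resampling instead.
    """
    if not isinstance(eta, dict):
        eta = dict(zip(PARAM_NAMES, np.asarray(eta, dtype=float)))
    vals = {}
    for p in PARAM_NAMES:
        v = pop.theta[p] + eta.get(p, 0.0)
        for link in pop.links:
            if link.parameter != p:
                continue
            if link.covariate not in covariates:
                raise KeyError(f"covariate {link.covariate!r} missing for link {link.label}")
            v += link.contribution(covariates[link.covariate])
        if v <= 0:
            if not clip:
                raise ValueError(f"non-positive individual parameter {p}")
            v = 1e-6
        vals[p] = v
    return StructuralParams(**vals)


@dataclass
class PKDataset:
    """NONMEM-style event-record dataset (EVID 0 observations, EVID 1 doses).

    ``DV`` is in ug/mL; ``AMT`` in mg. Covariate columns are constant within
    subject: AGE, WT, HT, BSA, BMI, SEX, RACE, HEALTH, CYP2D6, CYP2C19 (any
    subset).
    """

    frame: pd.DataFrame

    REQUIRED = ("ID", "TIME", "DV", "AMT", "EVID")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        if "MDV" not in df.columns:
            df = df.copy()
            df["MDV"] = (df["EVID"] != 0).astype(int)
            self.frame = df
        if (df["TIME"] < 0).any():
            raise ValueError("negative TIME values")
        for sid, g in df.groupby("ID"):
            if not (g["EVID"] == 1).any():
                raise ValueError(f"subject {sid} has no dose record")
            if not (g["EVID"] == 0).any():
                raise ValueError(f"subject {sid} has no observation record")
        covcols = self.covariate_columns
        nun = df.groupby("ID")[covcols].nunique() if covcols else None
        if covcols and (nun > 1).any().any():
            raise ValueError("covariates must be constant within subject")

    @property
    def covariate_columns(self) -> list:
        known = ("AGE", "WT", "HT", "BSA", "BMI", "SEX", "RACE", "HEALTH", "CYP2D6", "CYP2C19")
        return [c for c in known if c in self.frame.columns]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_observations(self) -> int:
        return int((self.frame["EVID"] == 0).sum())

    def observations(self, subject_id) -> pd.DataFrame:
        g = self.frame[(self.frame["ID"] == subject_id) & (self.frame["EVID"] == 0)]
        return g.sort_values("TIME")

    def doses(self, subject_id) -> pd.DataFrame:
        g = self.frame[(self.frame["ID"] == subject_id) & (self.frame["EVID"] == 1)]
        return g.sort_values("TIME")

    def covariates(self, subject_id) -> dict:
        row = self.frame[self.frame["ID"] == subject_id].iloc[0]
        return {c: row[c] for c in self.covariate_columns}

    def covariate_frame(self) -> pd.DataFrame:
        cols = ["ID"] + self.covariate_columns
        return self.frame[cols].groupby("ID", as_index=False).first()


def _draw_eta(pop: PopulationModel, covs: dict, rng, max_tries: int = 1000) -> np.ndarray:
    """Draw eta with rejection of non-positive individual parameters."""
    omega = pop.omega_array()
    for _ in range(max_tries):
        eta = omega * rng.standard_normal(len(PARAM_NAMES))
        try:
            individual_params(pop, covs, eta, clip=False)
            return eta
        except ValueError:
            continue
    raise RuntimeError("could not draw positive individual parameters")


def simulate_dataset(
    pop: PopulationModel,
    subjects: pd.DataFrame,
    schedule: np.ndarray,
    regimen,
    seed: int,
    dt: float = 0.0625,
    return_truth: bool = False,
):
    """Simulate an event-record dataset under the population model.

    ``subjects`` is a covariate frame with an ``ID`` column; ``schedule``
    holds shared observation times (h); ``regimen`` is a ``DoseRegimen``.
    Per-subject eta are rejection-resampled to keep parameters positive;
    residual noise is drawn per observation. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) == 0:
        raise ValueError("design has no observations")
    dose_times = np.asarray(regimen.dose_times, dtype=float)
    dose_amts = np.full(len(dose_times), regimen.dose_ug)
    rows = []
    truth = []
    covcols = [c for c in subjects.columns if c != "ID"]
    for _, srow in subjects.iterrows():
        sid = srow["ID"]
        covs = {c: srow[c] for c in covcols}
        eta = _draw_eta(pop, covs, rng)
        p_i = individual_params(pop, covs, eta, clip=False)
        f = conc_profiles_batch(
            p_i.as_array(), dose_times, dose_amts, float(schedule.max()), dt=dt, obs_times=schedule
        )[0]
        eps = rng.standard_normal(len(schedule))
        dv = f + pop.error.sd(f) * eps
        for td, amt in zip(dose_times, dose_amts):
            rows.append({"ID": sid, "TIME": td, "DV": np.nan, "AMT": amt / 1000.0, "EVID": 1, "MDV": 1, **covs})
        for t_o, y in zip(schedule, dv):
            rows.append({"ID": sid, "TIME": t_o, "DV": y, "AMT": 0.0, "EVID": 0, "MDV": 0, **covs})
        truth.append({"ID": sid, **dict(zip(PARAM_NAMES, p_i.as_array()))})
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
    ds = PKDataset(frame.reset_index(drop=True))
    if return_truth:
        return ds, pd.DataFrame(truth)
    return ds
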