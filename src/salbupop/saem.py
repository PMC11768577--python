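"""SAEM estimation for the population PK model.

Implements stochastic-approximation EM with Metropolis-within-Gibbs
conditional sampling of the individual random effects, an
importance-sampling marginal log-likelihood, the corrected BIC with
separate subject-level and observation-level penalties, empirical Bayes
estimates (MAP eta), and relative standard errors from a numeric Hessian
of the smoothed importance-sampled log-likelihood.

Algorithm outline per iteration:

* E-step: for each subject, (1) an independence kernel proposing from the
  prior ``N(0, omega^2)``, (2) adaptive full-vector random-walk kernels,
  (3) a component-wise random-walk sweep; proposal scales adapt toward a
  0.3-0.4 acceptance rate.
* M-step: stochastic-approximation averages of the individual parameters
  feed closed-form updates of the fixed effects / covariate coefficients
  (per-parameter least squares) and of the diagonal omega; the residual
  error constants (a, b) are re-optimized on the current complete-data
  sample and stochastically smoothed. During the exploratory phase
  (``k1`` iterations, step size 1) a simulated-annealing floor keeps
  omega and the error constants from collapsing; the smoothing phase uses
  step size ``(k - k1)^{-0.7}``.

Subjects are processed in sorted-ID order and all draws are arrays over
that order, so estimates are invariant to row permutations of the dataset
and bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import t as t_dist

from .model import (
    PARAM_NAMES,
    CovariateLink,
    ErrorModel,
    PKDataset,
    PopulationModel,
    conc_profiles_batch,
    individual_params,
)
from . import nca as _nca

__all__ = [
    "SaemSettings",
    "FitResult",
    "saem_fit",
    "loglik_importance",
    "bicc",
    "compute_ebes",
    "standard_errors",
    "initial_estimates",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SaemSettings:
    k1: int = 300               # exploratory iterations (step size 1)
    k2: int = 150               # smoothing iterations (step size (k-k1)^-0.7)
    n_rw_kernels: int = 2       # full-vector random-walk sweeps per iteration
    componentwise: bool = True  # add one component-wise sweep per iteration
    seed: int = 0
    dt: float = 0.0625          # prediction grid step (h)
    anneal: bool = True
    anneal_tau: float = 0.90    # max per-iteration shrink of omega^2 / error^2
    is_draws: int = 1000        # importance-sampling draws per subject
    is_df: int = 4              # t-proposal degrees of freedom
    keep_chain: int = 100       # conditional draws retained for COSSAC/IS
    error_form: str = "combined2"


# ---------------------------------------------------------------------------
# dataset evaluator (shared fast prediction/likelihood backend)
# ---------------------------------------------------------------------------

class DatasetEvaluator:
    """Vectorized per-subject prediction and likelihood on a shared grid."""

    def __init__(self, dataset: PKDataset, dt: float = 0.0625):
        self.dataset = dataset
        self.dt = dt
        ids = np.sort(np.unique(dataset.frame["ID"].to_numpy()))
        self.ids = ids
        self.n = len(ids)
        obs_t, obs_y, doses = [], [], []
        for sid in ids:
            og = dataset.observations(sid)
            obs_t.append(og["TIME"].to_numpy(dtype=float))
            obs_y.append(og["DV"].to_numpy(dtype=float))
            dg = dataset.doses(sid)
            doses.append(
                (dg["TIME"].to_numpy(dtype=float), dg["AMT"].to_numpy(dtype=float) * 1000.0)
            )
        self.t_end = float(max(t.max() for t in obs_t))
        self.K = int(np.ceil(self.t_end / dt + 1e-9))
        self.grid = np.arange(self.K + 1) * dt
        L = max(len(t) for t in obs_t)
        self.L = L
        self.obs_mask = np.zeros((self.n, L), dtype=bool)
        self.obs_pos = np.zeros((self.n, L), dtype=int)
        self.obs_w = np.zeros((self.n, L))
        self.y = np.zeros((self.n, L))
        for i, (tt, yy) in enumerate(zip(obs_t, obs_y)):
            m = len(tt)
            pos = np.clip(np.searchsorted(self.grid, tt, side="right") - 1, 0, self.K - 1)
            self.obs_mask[i, :m] = True
            self.obs_pos[i, :m] = pos
            self.obs_w[i, :m] = (tt - self.grid[pos]) / dt
            self.y[i, :m] = yy
        self.n_obs_per_subject = self.obs_mask.sum(axis=1)
        self.n_obs = int(self.n_obs_per_subject.sum())
        # group subjects by identical dose pattern
        self.dose_patterns = []
        self.pattern_of = np.zeros(self.n, dtype=int)
        for i, (dt_i, da_i) in enumerate(doses):
            key = (tuple(np.round(dt_i, 9)), tuple(np.round(da_i, 6)))
            for j, (k2, _, _) in enumerate(self.dose_patterns):
                if k2 == key:
                    self.pattern_of[i] = j
                    break
            else:
                self.pattern_of.flat[i] = len(self.dose_patterns)
                self.dose_patterns.append((key, dt_i, da_i))

    def predict(self, params: np.ndarray, subject_idx: np.ndarray) -> np.ndarray:
        """Predicted conc (ug/mL), shape (R, L); masked entries are junk."""
        params = np.atleast_2d(params)
        subject_idx = np.asarray(subject_idx, dtype=int)
        R = params.shape[0]
        out_grid = np.zeros((R, self.K + 1))
        pat = self.pattern_of[subject_idx]
        for j, (_, d_t, d_a) in enumerate(self.dose_patterns):
            rows = np.where(pat == j)[0]
            if len(rows) == 0:
                continue
            out_grid[rows] = conc_profiles_batch(
                params[rows], d_t, d_a, self.t_end, dt=self.dt, obs_times=None
            )
        pos = self.obs_pos[subject_idx]           # (R, L)
        w = self.obs_w[subject_idx]
        r_idx = np.arange(R)[:, None]
        return out_grid[r_idx, pos] * (1.0 - w) + out_grid[r_idx, pos + 1] * w

    def loglik(self, params: np.ndarray, subject_idx: np.ndarray, error: ErrorModel,
               return_pred: bool = False):
        """Per-row observation log-likelihood ``log p(y_i | params_row)``."""
        f = self.predict(params, subject_idx)
        y = self.y[subject_idx]
        mask = self.obs_mask[subject_idx]
        sd = error.sd(f)
        with np.errstate(divide="ignore"):
            ll_obs = -0.5 * ((y - f) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
        ll = np.where(mask, ll_obs, 0.0).sum(axis=1)
        if return_pred:
            return ll, f
        return ll


# ---------------------------------------------------------------------------
# free-parameter bookkeeping
# ---------------------------------------------------------------------------

class _Design:
    """Per-parameter design matrices for theta + covariate coefficients."""

    def __init__(self, pop: PopulationModel, dataset: PKDataset, ids: np.ndarray):
        covf = dataset.covariate_frame().set_index("ID").loc[ids]
        self.links = []
        resolved = []
        for link in pop.links:
            ref = link.reference
            if link.kind == "continuous" and (ref is None or (isinstance(ref, float) and np.isnan(ref))):
                ref = float(np.median(covf[link.covariate].to_numpy(dtype=float)))
                link = replace(link, reference=ref)
            resolved.append(link)
        self.resolved_links = tuple(resolved)
        self.X = {}
        self.link_cols = {p: [] for p in PARAM_NAMES}
        for p in PARAM_NAMES:
            cols = [np.ones(len(ids))]
            for link in resolved:
                if link.parameter != p:
                    continue
                vals = covf[link.covariate].to_numpy()
                if link.kind == "continuous":
                    col = vals.astype(float) - float(link.reference)
                else:
                    col = np.array(
                        [1.0 if _match(link, v) else 0.0 for v in vals]
                    )
                cols.append(col)
                self.link_cols[p].append(link)
            self.X[p] = np.column_stack(cols)

    def gamma_init(self, pop: PopulationModel) -> dict:
        g = {}
        for p in PARAM_NAMES:
            betas = [l.beta for l in self.link_cols[p]]
            g[p] = np.array([pop.theta[p]] + betas)
        return g

    def mu(self, gamma: dict) -> np.ndarray:
        """Population-predicted individual parameters, (N, 7)."""
        return np.column_stack([self.X[p] @ gamma[p] for p in PARAM_NAMES])

    def links_from_gamma(self, gamma: dict) -> tuple:
        out = []
        for p in PARAM_NAMES:
            for j, link in enumerate(self.link_cols[p]):
                out.append(replace(link, beta=float(gamma[p][j + 1])))
        return tuple(out)


def _match(link: CovariateLink, value) -> bool:
    from .model import _cat_matches

    return _cat_matches(link.covariate, value, link.category)


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    pop: PopulationModel
    dataset: PKDataset = field(repr=False)
    trace: pd.DataFrame = field(repr=False)
    eta: np.ndarray = field(repr=False)          # (N, 7) final conditional draw
    cond_mean: np.ndarray = field(repr=False)    # (N, 7) smoothed conditional mean
    cond_sd: np.ndarray = field(repr=False)      # (N, 7) smoothed conditional SD
    cond_draws: np.ndarray = field(repr=False)   # (M, N, 7) retained chain tail
    ids: np.ndarray = field(repr=False)
    converged: bool = True
    seed: int = 0
    settings: SaemSettings = None
    minus2ll: float | None = None
    minus2ll_se: float | None = None
    bicc: float | None = None
    rse_percent: dict | None = None
    ebes: pd.DataFrame | None = None
    clipped_fraction: float = 0.0

    @property
    def free_omega(self) -> np.ndarray:
        return self.pop.omega_array() > 0

    def evaluator(self, dt: float | None = None) -> DatasetEvaluator:
        return DatasetEvaluator(self.dataset, dt=dt or self.settings.dt)

    def estimates_table(self) -> pd.DataFrame:
        rows = []
        for p in PARAM_NAMES:
            rows.append({"parameter": p, "estimate": self.pop.theta[p],
                         "rse_percent": (self.rse_percent or {}).get(p)})
        for link in self.pop.links:
            rows.append({"parameter": link.label, "estimate": link.beta,
                         "rse_percent": (self.rse_percent or {}).get(link.label)})
        for p in PARAM_NAMES:
            if self.pop.omega.get(p, 0.0) > 0:
                rows.append({"parameter": f"omega_{p}", "estimate": self.pop.omega[p],
                             "rse_percent": (self.rse_percent or {}).get(f"omega_{p}")})
        rows.append({"parameter": "a", "estimate": self.pop.error.a,
                     "rse_percent": (self.rse_percent or {}).get("a")})
        rows.append({"parameter": "b", "estimate": self.pop.error.b,
                     "rse_percent": (self.rse_percent or {}).get("b")})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# initial estimates
# ---------------------------------------------------------------------------

def initial_estimates(dataset: PKDataset, refine: bool = True) -> PopulationModel:
    """Initial values: NCA heuristics refined by a pooled population fit.

    Cl/F from total dose over extrapolated AUC, V1 from Cl and the pooled
    terminal half-life, Mtt from the median individual tmax, ka = 1,
    Q = Cl/3, V2 = V1. With ``refine`` (default) these seed a naive-pooled
    least-squares fit of the structural model to the per-time mean
    log-concentrations over all individuals, which becomes the initial
    population estimate. Omega starts at 30% of each theta; the error
    model at 10% additive / 20% proportional scale of the median
    observation.
    """
    cls, tmaxes, thalves = [], [], []
    for sid in dataset.subject_ids:
        og = dataset.observations(sid)
        t, y = og["TIME"].to_numpy(dtype=float), np.clip(og["DV"].to_numpy(dtype=float), 0, None)
        dose_mg = dataset.doses(sid)["AMT"].sum()
        if len(t) < 3 or y.max() <= 0:
            continue
        tmaxes.append(t[np.argmax(y)] % 24.0)
        auc = _nca.auc_trapezoid(t, y)
        lam = None
        try:
            lam, _, _ = _nca.fit_lambda_z(t, y)
            thalves.append(math.log(2.0) / lam)
        except ValueError:
            pass
        extrap = (y[-1] / lam) if lam else 3.0 * y[-1]
        cls.append(dose_mg / max(auc + extrap, 1e-12))
    cl = float(np.median(cls)) if cls else 50.0
    t_half = float(np.median(thalves)) if thalves else 3.0
    mtt = float(np.median(tmaxes)) if tmaxes else 2.0
    mtt = max(mtt, 0.5)
    v1 = cl * t_half / math.log(2.0)
    theta = {"Mtt": mtt, "Ktr": 2.0 / mtt, "ka": 1.0, "Cl": cl, "V1": v1, "Q": cl / 3.0, "V2": v1}
    omega = None
    if refine:
        theta = _pooled_refine(dataset, theta)
        theta, omega = _subject_refine(dataset, theta)
    if omega is None:
        omega = {p: 0.3 * theta[p] for p in PARAM_NAMES}
    dv_med = float(np.median(np.abs(dataset.frame.loc[dataset.frame.EVID == 0, "DV"])))
    error = ErrorModel(a=0.05 * dv_med, b=0.1)
    return PopulationModel(theta=theta, omega=omega, error=error)


def _init_box(cl0: float) -> tuple:
    """Physiologically shaped parameter box for the initialization fits.

    The box (notably intercompartmental clearance capped at a few times the
    systemic clearance) keeps the weakly identified distribution parameters
    out of the degenerate one-compartment limit (Q -> infinity); it
    constrains only the initial-estimate search, never the SAEM fit.
    """
    lo = np.array([0.05, 0.01, 0.05, cl0 / 10, 2.0, cl0 / 20, 2.0])
    hi = np.array([50.0, 50.0, 50.0, cl0 * 10, 3000.0, cl0 * 3, 3000.0])
    return lo, hi


def _fit_curve_ml(times, y, d_t, d_a, starts, n_rounds: int = 3, dt: float = 0.0625,
                  bounds: tuple | None = None):
    """Weighted least-squares curve fit with alternating error-model updates.

    Minimizes the combined-error Gaussian deviance in log-parameters:
    rounds alternate a trust-region fit of the structural parameters
    (residuals weighted by ``sd = sqrt(a^2 + b^2 f^2)``) with re-estimation
    of (a, b) on the current residuals. Returns ``(theta_array, cost, a, b)``
    for the best start or ``None``.
    """
    from scipy.optimize import least_squares

    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    t_end = float(times.max())
    ymax = float(np.max(np.abs(y)))
    best = None
    for th_s in starts:
        th_s = np.maximum(np.asarray(th_s, dtype=float), 1e-6)
        if bounds is not None:
            lo_n, hi_n = bounds
            th_s = np.clip(th_s, lo_n * 1.001, hi_n * 0.999)
        x = np.log(th_s)
        a_e, b_e = 0.02 * ymax, 0.1
        res = None
        for _ in range(n_rounds):
            def resid(logth, a_e=a_e, b_e=b_e):
                th = np.exp(np.clip(logth, -20, 20))
                f = conc_profiles_batch(th, d_t, d_a, t_end, dt=dt, obs_times=times)[0]
                sd = np.sqrt(a_e**2 + (b_e * f) ** 2)
                return (f - y) / sd

            if bounds is not None:
                blo, bhi = np.log(bounds[0]), np.log(bounds[1])
            else:
                blo, bhi = x - math.log(100.0), x + math.log(100.0)
            try:
                res = least_squares(
                    resid, np.clip(x, blo, bhi), method="trf",
                    bounds=(blo, bhi),
                    diff_step=1e-4, max_nfev=300,
                )
            except Exception:
                res = None
                break
            x = res.x
            th = np.exp(x)
            f = conc_profiles_batch(th, d_t, d_a, t_end, dt=dt, obs_times=times)[0]
            opt = minimize(
                _error_nll, [math.log(max(a_e, 1e-10)), math.log(max(b_e, 1e-10))],
                args=((y - f) ** 2, f**2, "combined2"),
                method="Nelder-Mead", options={"maxiter": 80},
            )
            a_e, b_e = math.exp(opt.x[0]), math.exp(opt.x[1])
        if res is None:
            continue
        # compare starts on the full deviance at their own (a, b)
        th = np.exp(x)
        f = conc_profiles_batch(th, d_t, d_a, t_end, dt=dt, obs_times=times)[0]
        dev = _error_nll([math.log(max(a_e, 1e-12)), math.log(max(b_e, 1e-12))],
                         (y - f) ** 2, f**2, "combined2")
        if best is None or dev < best[1]:
            best = (th, dev, a_e, b_e)
    return best


def _pooled_refine(dataset: PKDataset, theta0: dict) -> dict:
    """Naive-pooled fit of the mean concentration-time profile.

    Multi-start (the absorption delay of oral salbutamol can be
    rate-limiting — flip-flop kinetics — so starts cover fast- and
    slow-absorption basins).
    """
    obs = dataset.frame[dataset.frame.EVID == 0]
    prof = obs.groupby("TIME")["DV"].mean()
    prof = prof[prof > 0]
    times = prof.index.to_numpy(dtype=float)
    yv = prof.to_numpy(dtype=float)
    first = dataset.subject_ids[0]
    dg = dataset.doses(first)
    d_t = dg["TIME"].to_numpy(dtype=float)
    d_a = dg["AMT"].to_numpy(dtype=float) * 1000.0

    cl0, v10 = theta0["Cl"], theta0["V1"]
    order = PARAM_NAMES
    starts = [
        [theta0[p] for p in order],
        [8.0, 0.3, 2.0, cl0, 0.5 * cl0, cl0 / 3, cl0],      # transit-limited
        [1.0, 3.0, 1.0, cl0, v10, cl0 / 2, 2 * v10],        # absorption fast
    ]
    best = _fit_curve_ml(times, yv, d_t, d_a, starts, bounds=_init_box(cl0))
    if best is None:
        return dict(theta0)
    return dict(zip(PARAM_NAMES, best[0]))


def _subject_refine(dataset: PKDataset, theta0: dict, n_subjects: int = 5) -> tuple:
    """Individual maximum-likelihood fits on a few subjects.

    The pooled mean profile leaves absorption-vs-distribution trade-offs
    nearly flat, but individual concentration-time curves identify all
    seven parameters; fitting a handful of subjects and taking robust
    moments gives initial theta and omega in the correct basin.
    """
    ids = dataset.subject_ids
    sel = ids[np.unique(np.linspace(0, len(ids) - 1, min(n_subjects, len(ids))).astype(int))]
    fits = []
    for sid in sel:
        og = dataset.observations(sid)
        t = og["TIME"].to_numpy(dtype=float)
        y = og["DV"].to_numpy(dtype=float)
        if len(t) < 8:
            continue
        dg = dataset.doses(sid)
        d_t = dg["TIME"].to_numpy(dtype=float)
        d_a = dg["AMT"].to_numpy(dtype=float) * 1000.0
        best = _fit_curve_ml(
            t, y, d_t, d_a, [[theta0[p] for p in PARAM_NAMES]], n_rounds=2,
            bounds=_init_box(theta0["Cl"]),
        )
        if best is not None:
            fits.append(best[0])
    if len(fits) < 3:
        return dict(theta0), None
    arr = np.array(fits)
    med = np.median(arr, axis=0)
    mad = 1.4826 * np.median(np.abs(arr - med), axis=0)
    theta = dict(zip(PARAM_NAMES, med))
    # MAD across a handful of individual fits mixes true IIV with fit noise;
    # discount it but keep a floor so the chain can explore
    omega = {p: float(max(0.5 * mad[j], 0.05 * med[j])) for j, p in enumerate(PARAM_NAMES)}
    return theta, omega


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

def individual_fit_init(
    dataset: PKDataset,
    theta0: dict | None = None,
    dt: float = 0.0625,
) -> tuple:
    """Full per-subject initialization for hard, information-rich datasets.

    Fits every subject's curve by weighted least squares (bounded to the
    physiological box), then assembles the initial population model from
    the individual estimates: theta = median, omega = SD, residual-error
    constants from the pooled fit residuals. Also returns the matching
    per-subject eta start values (sorted-ID order) so the SAEM chain can
    begin at the joint conditional mode.
    """
    if theta0 is None:
        # heuristics + pooled refinement only; the per-subject stage below
        # supersedes the small-sample subject refinement
        theta0 = _pooled_refine(dataset, initial_estimates(dataset, refine=False).theta)
    ids = np.sort(np.unique(dataset.frame["ID"].to_numpy()))
    box = _init_box(theta0["Cl"])
    phi, resid2_all, f2_all = [], [], []
    start = [theta0[p] for p in PARAM_NAMES]
    for sid in ids:
        og = dataset.observations(sid)
        t = og["TIME"].to_numpy(dtype=float)
        y = og["DV"].to_numpy(dtype=float)
        dg = dataset.doses(sid)
        d_t = dg["TIME"].to_numpy(dtype=float)
        d_a = dg["AMT"].to_numpy(dtype=float) * 1000.0
        best = _fit_curve_ml(t, y, d_t, d_a, [start], n_rounds=2, dt=dt, bounds=box)
        if best is None:
            phi.append(np.array(start, dtype=float))
            continue
        phi.append(best[0])
        f = conc_profiles_batch(best[0], d_t, d_a, float(t.max()), dt=dt, obs_times=t)[0]
        resid2_all.append((y - f) ** 2)
        f2_all.append(f**2)
    phi = np.array(phi)
    theta = {p: float(np.median(phi[:, j])) for j, p in enumerate(PARAM_NAMES)}
    omega = {
        p: float(max(np.std(phi[:, j], ddof=1), 1e-3 * abs(theta[p])))
        for j, p in enumerate(PARAM_NAMES)
    }
    r2 = np.concatenate(resid2_all) if resid2_all else np.array([1e-6])
    f2 = np.concatenate(f2_all) if f2_all else np.array([1.0])
    dv_med = float(np.median(np.abs(dataset.frame.loc[dataset.frame.EVID == 0, "DV"])))
    opt = minimize(
        _error_nll, [math.log(0.05 * dv_med + 1e-300), math.log(0.1)],
        args=(r2, f2, "combined2"), method="Nelder-Mead", options={"maxiter": 200},
    )
    error = ErrorModel(a=max(math.exp(opt.x[0]), 1e-12), b=max(math.exp(opt.x[1]), 1e-12))
    pop = PopulationModel(theta=theta, omega=omega, error=error)
    eta0 = phi - np.array([theta[p] for p in PARAM_NAMES])[None, :]
    return pop, eta0


def _laplace_chol(ev: DatasetEvaluator, phi: np.ndarray, error: ErrorModel,
                  omega: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Per-subject Cholesky factors of the Laplace conditional covariance.

    Gauss-Newton curvature of the weighted residuals at the current
    individual parameters, plus the prior precision; used to shape the
    random-walk proposals (the conditional posteriors of the distribution
    parameters are strongly correlated).
    """
    N = ev.n
    sidx = np.arange(N)
    nf = int(free.sum())
    if nf == 0:
        return np.zeros((N, 0, 0))
    fidx = np.where(free)[0]
    f0 = ev.predict(phi, sidx)
    sd = np.maximum(error.sd(f0), 1e-300)
    J = np.zeros((N, ev.L, nf))
    for jj, j in enumerate(fidx):
        h = np.maximum(1e-4 * np.abs(phi[:, j]), 1e-8)
        pp = phi.copy()
        pp[:, j] += h
        fp = ev.predict(pp, sidx)
        J[:, :, jj] = (fp - f0) / h[:, None] / sd
    J = np.where(ev.obs_mask[:, :, None], J, 0.0)
    prior_prec = np.diag(1.0 / np.maximum(omega[fidx] ** 2, 1e-300))
    chols = np.zeros((N, nf, nf))
    for i in range(N):
        F = J[i].T @ J[i] + prior_prec
        # ridge for safety
        F += 1e-10 * np.eye(nf) * max(np.trace(F) / nf, 1.0)
        cov = np.linalg.inv(F)
        try:
            chols[i] = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chols[i] = np.diag(np.sqrt(np.maximum(np.diag(cov), 1e-300)))
    return chols


def _error_nll(log_ab, resid2, f2, form):
    a = math.exp(log_ab[0])
    b = math.exp(log_ab[1])
    if form == "combined1":
        sd = a + b * np.sqrt(f2)
        v = sd**2
    else:
        v = a**2 + b**2 * f2
    return float(np.sum(0.5 * np.log(v) + resid2 / (2.0 * v)))


def saem_fit(
    dataset: PKDataset,
    init: PopulationModel | None = None,
    settings: SaemSettings | None = None,
    eta0: np.ndarray | None = None,
) -> FitResult:
    """Fit the population model to an event-record dataset by SAEM.

    ``eta0`` optionally seeds the conditional chain (N x 7, sorted-ID
    order), e.g. from :func:`individual_fit_init`.
    """
    settings = settings or SaemSettings()
    if init is None:
        init = initial_estimates(dataset)
    rng = np.random.default_rng(settings.seed)
    ev = DatasetEvaluator(dataset, dt=settings.dt)
    N = ev.n
    design = _Design(init, dataset, ev.ids)
    gamma = design.gamma_init(init)
    omega = init.omega_array().astype(float).copy()
    free_om = omega > 0
    err_a, err_b = float(init.error.a), float(init.error.b)
    form = init.error.form
    sidx = np.arange(N)

    eta = np.zeros((N, 7))
    if eta0 is not None:
        eta = np.asarray(eta0, dtype=float).copy()
        eta[:, ~free_om] = 0.0
    rw_scale = np.full(N, 1.0)
    rwc_scale = np.full((N, 7), 0.3)
    lap_chol = None
    mu = design.mu(gamma)

    def make_error():
        return ErrorModel(a=max(err_a, 1e-12), b=max(err_b, 1e-12), form=form)

    def cond_loglik(eta_mat, mu_mat, error):
        params = mu_mat + eta_mat
        return ev.loglik(params, sidx, error)

    error = make_error()
    ll_cur, f_cur = ev.loglik(mu + eta, sidx, error, return_pred=True)

    # SA state
    H = (mu + eta).copy()          # E[phi]
    G = H**2                       # E[phi^2]
    cond_m = eta.copy()
    cond_s2 = np.ones_like(eta)
    # slow-moving conditional moments driving the independence kernel
    mix_m = eta.copy()
    mix_s2 = eta**2 + np.tile(omega**2, (N, 1))
    n_iter = settings.k1 + settings.k2
    trace_rows = []
    chain_tail = []
    clip_events = 0
    eval_events = 0

    for k in range(1, n_iter + 1):
        gam_k = 1.0 if k <= settings.k1 else (k - settings.k1) ** -0.7
        error = make_error()

        def mh_step(eta_prop):
            nonlocal eta, ll_cur, f_cur, eval_events
            lp_cur = -0.5 * np.sum((eta[:, free_om] / omega[free_om]) ** 2, axis=1)
            lp_prop = -0.5 * np.sum((eta_prop[:, free_om] / omega[free_om]) ** 2, axis=1)
            ll_prop, f_prop = ev.loglik(mu + eta_prop, sidx, error, return_pred=True)
            eval_events += 1
            log_r = (ll_prop + lp_prop) - (ll_cur + lp_cur)
            acc = np.log(rng.uniform(size=N)) < log_r
            eta[acc] = eta_prop[acc]
            ll_cur = np.where(acc, ll_prop, ll_cur)
            f_cur[acc] = f_prop[acc]
            return acc

        # kernel 1: independence proposal from the prior
        eta_prop = np.zeros_like(eta)
        eta_prop[:, free_om] = omega[free_om] * rng.standard_normal((N, int(free_om.sum())))
        # independence kernel: prior terms cancel against the proposal
        ll_prop, f_prop = ev.loglik(mu + eta_prop, sidx, error, return_pred=True)
        eval_events += 1
        acc = np.log(rng.uniform(size=N)) < (ll_prop - ll_cur)
        eta[acc] = eta_prop[acc]
        ll_cur = np.where(acc, ll_prop, ll_cur)
        f_cur[acc] = f_prop[acc]

        # kernel 2: adaptive random walk shaped by the per-subject Laplace
        # conditional covariance (refreshed periodically)
        if lap_chol is None or k % 25 == 1:
            lap_chol = _laplace_chol(ev, mu + eta, error, omega, free_om)
        nf = int(free_om.sum())
        for _ in range(settings.n_rw_kernels):
            z = rng.standard_normal((N, nf))
            step = np.zeros_like(eta)
            step[:, free_om] = rw_scale[:, None] * np.einsum("nij,nj->ni", lap_chol, z)
            acc = mh_step(eta + step)
            rw_scale *= np.exp(0.3 * (acc.astype(float) - 0.35))
            rw_scale = np.clip(rw_scale, 1e-3, 50.0)

        # kernel 2b: adaptive Gaussian independence proposal centered on the
        # smoothed conditional mean (sharpens mixing when residual error is
        # small and the conditional mass sits far from the prior mode)
        if k > 5:
            prop_sd = np.maximum(1.5 * np.sqrt(np.maximum(mix_s2 - mix_m**2, 0.0)),
                                 0.05 * omega[None, :])
            eta_prop = np.zeros_like(eta)
            z = rng.standard_normal((N, int(free_om.sum())))
            eta_prop[:, free_om] = mix_m[:, free_om] + prop_sd[:, free_om] * z
            lp_cur = -0.5 * np.sum((eta[:, free_om] / omega[free_om]) ** 2, axis=1)
            lp_prop = -0.5 * np.sum((eta_prop[:, free_om] / omega[free_om]) ** 2, axis=1)
            lq_cur = -0.5 * np.sum(
                ((eta[:, free_om] - mix_m[:, free_om]) / prop_sd[:, free_om]) ** 2, axis=1
            )
            lq_prop = -0.5 * np.sum(z**2, axis=1)
            ll_prop, f_prop = ev.loglik(mu + eta_prop, sidx, error, return_pred=True)
            eval_events += 1
            log_r = (ll_prop + lp_prop - lq_prop) - (ll_cur + lp_cur - lq_cur)
            acc = np.log(rng.uniform(size=N)) < log_r
            eta[acc] = eta_prop[acc]
            ll_cur = np.where(acc, ll_prop, ll_cur)
            f_cur[acc] = f_prop[acc]

        # kernel 3: component-wise random walk
        if settings.componentwise:
            for j in np.where(free_om)[0]:
                step = np.zeros_like(eta)
                step[:, j] = rwc_scale[:, j] * omega[j] * rng.standard_normal(N)
                acc = mh_step(eta + step)
                rwc_scale[:, j] *= np.exp(0.3 * (acc.astype(float) - 0.35))
            rwc_scale = np.clip(rwc_scale, 1e-3, 10.0)

        phi = mu + eta
        n_clip = int(np.sum(phi <= 0))
        clip_events += n_clip
        mix_m = 0.9 * mix_m + 0.1 * eta
        mix_s2 = 0.9 * mix_s2 + 0.1 * eta**2

        # --- M-step -------------------------------------------------------
        H = (1 - gam_k) * H + gam_k * phi
        G = (1 - gam_k) * G + gam_k * phi**2
        cond_m = (1 - gam_k) * cond_m + gam_k * eta
        cond_s2 = (1 - gam_k) * cond_s2 + gam_k * eta**2

        for j, p in enumerate(PARAM_NAMES):
            X = design.X[p]
            g_new, *_ = np.linalg.lstsq(X, H[:, j], rcond=None)
            if g_new[0] <= 0:
                g_new[0] = gamma[p][0]  # keep the previous (positive) intercept
            gamma[p] = g_new
            if free_om[j]:
                mu_j = X @ gamma[p]
                om2 = float(np.mean(G[:, j] - 2.0 * mu_j * H[:, j] + mu_j**2))
                om2 = max(om2, 1e-12)
                if settings.anneal and k <= settings.k1:
                    om2 = max(om2, settings.anneal_tau * omega[j] ** 2)
                omega[j] = math.sqrt(om2)
        # the chain state is the individual parameter phi = mu + eta; keep it
        # invariant under the mu update (otherwise rejected subjects drift
        # with the population mean and theta random-walks)
        mu_new = design.mu(gamma)
        eta = eta + (mu - mu_new)
        mu = mu_new

        # residual-error update on the current complete-data sample
        resid2 = np.where(ev.obs_mask, (ev.y - f_cur) ** 2, 0.0)[ev.obs_mask]
        f2 = np.where(ev.obs_mask, f_cur**2, 0.0)[ev.obs_mask]
        res = minimize(
            _error_nll,
            x0=[math.log(max(err_a, 1e-10)), math.log(max(err_b, 1e-10))],
            args=(resid2, f2, form),
            method="Nelder-Mead",
            options={"maxiter": 60, "xatol": 1e-4, "fatol": 1e-8},
        )
        a_new, b_new = math.exp(res.x[0]), math.exp(res.x[1])
        a_sm = math.sqrt((1 - gam_k) * err_a**2 + gam_k * a_new**2)
        b_sm = math.sqrt((1 - gam_k) * err_b**2 + gam_k * b_new**2)
        if settings.anneal and k <= settings.k1:
            a_sm = max(a_sm, math.sqrt(settings.anneal_tau) * err_a)
            b_sm = max(b_sm, math.sqrt(settings.anneal_tau) * err_b)
        err_a, err_b = a_sm, b_sm

        row = {"iteration": k, "phase": 1 if k <= settings.k1 else 2,
               "a": err_a, "b": err_b}
        for j, p in enumerate(PARAM_NAMES):
            row[p] = gamma[p][0]
            row[f"omega_{p}"] = omega[j]
        for p in PARAM_NAMES:
            for jj, link in enumerate(design.link_cols[p]):
                row[link.label] = gamma[p][jj + 1]
        trace_rows.append(row)
        if k > n_iter - settings.keep_chain:
            chain_tail.append(eta.copy())

    trace = pd.DataFrame(trace_rows)
    # convergence: relative theta movement over the last 20% of smoothing
    tail = trace.iloc[-max(int(0.2 * settings.k2), 2):]
    converged = True
    for p in PARAM_NAMES:
        lo, hi = tail[p].min(), tail[p].max()
        if abs(hi - lo) > 0.05 * max(abs(tail[p].iloc[-1]), 1e-12):
            converged = False
    degenerate = bool(np.any(omega[free_om] < 1e-6))

    theta = {p: float(gamma[p][0]) for p in PARAM_NAMES}
    links = design.links_from_gamma(gamma)
    pop = PopulationModel(
        theta=theta,
        omega=dict(zip(PARAM_NAMES, omega)),
        error=make_error(),
        links=links,
    )
    cond_sd = np.sqrt(np.maximum(cond_s2 - cond_m**2, 1e-12))
    return FitResult(
        pop=pop,
        dataset=dataset,
        trace=trace,
        eta=eta,
        cond_mean=cond_m,
        cond_sd=cond_sd,
        cond_draws=np.array(chain_tail) if chain_tail else np.zeros((0, N, 7)),
        ids=ev.ids,
        converged=converged and not degenerate,
        seed=settings.seed,
        settings=settings,
        clipped_fraction=clip_events / max(eval_events * N * 7, 1),
    )


# ---------------------------------------------------------------------------
# marginal likelihood, BICc, EBEs, standard errors
# ---------------------------------------------------------------------------

def _pop_mu(pop: PopulationModel, dataset: PKDataset, ids: np.ndarray) -> np.ndarray:
    rows = []
    covf = dataset.covariate_frame().set_index("ID").loc[ids]
    for sid in ids:
        covs = covf.loc[sid].to_dict()
        p = individual_params(pop, covs, np.zeros(7), clip=True)
        rows.append(p.as_array())
    return np.array(rows)


def loglik_importance(
    pop: PopulationModel,
    dataset: PKDataset,
    n_draws: int = 1000,
    seed: int = 0,
    dt: float = 0.0625,
    df: int = 4,
    cond_mean: np.ndarray | None = None,
    cond_sd: np.ndarray | None = None,
    evaluator: DatasetEvaluator | None = None,
) -> tuple:
    """Importance-sampled ``-2 log L`` and its Monte-Carlo SE.

    The proposal is a per-subject location-scale t(df) centered at the
    conditional mean with the conditional SD (from a SAEM chain or an EBE
    pass); with no random effects the marginal likelihood is exact.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ev = evaluator or DatasetEvaluator(dataset, dt=dt)
    N = ev.n
    omega = pop.omega_array()
    free = omega > 0
    mu_pop = _pop_mu(pop, dataset, ev.ids)
    sidx = np.arange(N)
    if not np.any(free):
        ll = ev.loglik(mu_pop, sidx, pop.error)
        return float(-2.0 * ll.sum()), 0.0

    if cond_mean is None:
        cond_mean = np.zeros((N, 7))
    if cond_sd is None:
        cond_sd = np.tile(omega, (N, 1))
    scale = np.maximum(cond_sd, 0.2 * omega[None, :])
    scale = np.where(free[None, :], scale, 0.0)

    rng = np.random.default_rng(seed)
    B = n_draws
    nf = int(free.sum())
    z = t_dist.rvs(df, size=(N, B, nf), random_state=rng)
    eta = np.zeros((N, B, 7))
    eta[:, :, free] = cond_mean[:, None, free] + scale[:, None, free] * z

    params = mu_pop[:, None, :] + eta                        # (N, B, 7)
    flat = params.reshape(N * B, 7)
    flat_idx = np.repeat(sidx, B)
    ll_y = ev.loglik(flat, flat_idx, pop.error).reshape(N, B)
    log_prior = -0.5 * np.sum(
        (eta[:, :, free] / omega[free]) ** 2 + np.log(2 * np.pi * omega[free] ** 2),
        axis=2,
    )
    log_q = np.sum(
        t_dist.logpdf(z, df) - np.log(scale[:, None, free]),
        axis=2,
    )
    lw = ll_y + log_prior - log_q                            # (N, B)
    li = logsumexp(lw, axis=1) - math.log(B)
    minus2ll = float(-2.0 * li.sum())
    # per-subject MC variance of the log estimate (delta method)
    w_norm = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    ess = 1.0 / np.sum(w_norm**2, axis=1)
    if np.mean(ess) < 0.05 * B:
        import warnings

        warnings.warn(
            f"importance-sampling ESS low ({np.mean(ess):.1f} of {B} draws); "
            "the marginal likelihood may be underestimated",
            RuntimeWarning,
            stacklevel=2,
        )
    var_log = np.clip(1.0 / ess - 1.0 / B, 0.0, None)
    se = float(2.0 * math.sqrt(np.sum(var_log)))
    return minus2ll, se


def bicc(minus2ll: float, n_subjects: int, n_obs: int, p_subject: int, p_obs: int) -> float:
    """Corrected BIC: subject-level parameters penalized by ``log N``,
    observation-level (residual-error) parameters by ``log n_obs``."""
    if n_subjects <= 0 or n_obs <= 0:
        raise ValueError("counts must be positive")
    return minus2ll + p_subject * math.log(n_subjects) + p_obs * math.log(n_obs)


def parameter_counts(pop: PopulationModel) -> tuple:
    """(subject-level, observation-level) free-parameter counts."""
    p_sub = 7 + len(pop.links) + int(np.sum(pop.omega_array() > 0))
    p_obs = int(pop.error.a > 0) + int(pop.error.b > 0)
    return p_sub, p_obs


def compute_ebes(
    pop: PopulationModel,
    dataset: PKDataset,
    dt: float = 0.0625,
    starts: np.ndarray | None = None,
    evaluator: DatasetEvaluator | None = None,
) -> pd.DataFrame:
    """Empirical Bayes estimates: per-subject MAP eta and parameters."""
    ev = evaluator or DatasetEvaluator(dataset, dt=dt)
    omega = pop.omega_array()
    free = omega > 0
    nf = int(free.sum())
    mu_pop = _pop_mu(pop, dataset, ev.ids)
    rows = []
    for i, sid in enumerate(ev.ids):
        if ev.n_obs_per_subject[i] == 0:
            raise ValueError(f"subject {sid} has no observations")

        # optimize in prior-scaled coordinates x = eta / omega for conditioning
        def neg_post(x, i=i):
            eta = np.zeros(7)
            eta[free] = x * omega[free]
            ll = ev.loglik((mu_pop[i] + eta)[None, :], np.array([i]), pop.error)[0]
            return -(ll - 0.5 * float(x @ x))

        start_list = [np.zeros(nf)]
        if starts is not None:
            start_list.append(starts[i][free] / omega[free])
        start_list.append(np.full(nf, 0.5))
        best = None
        for x0 in start_list:
            res = minimize(neg_post, x0, method="L-BFGS-B",
                           options={"maxiter": 300, "ftol": 1e-14, "gtol": 1e-10,
                                    "eps": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
        eta = np.zeros(7)
        eta[free] = best.x * omega[free]
        row = {"ID": sid}
        row.update({f"eta_{p}": eta[j] for j, p in enumerate(PARAM_NAMES)})
        params = np.maximum(mu_pop[i] + eta, 1e-6)
        row.update(dict(zip(PARAM_NAMES, params)))
        rows.append(row)
    return pd.DataFrame(rows)


def _pack_free(pop: PopulationModel):
    """Free-parameter vector and an unpacker, for Hessian-based SEs."""
    names, x0 = [], []
    for p in PARAM_NAMES:
        names.append(p)
        x0.append(pop.theta[p])
    for link in pop.links:
        names.append(link.label)
        x0.append(link.beta)
    for p in PARAM_NAMES:
        if pop.omega[p] > 0:
            names.append(f"omega_{p}")
            x0.append(pop.omega[p])
    names += ["a", "b"]
    x0 += [pop.error.a, pop.error.b]

    def unpack(x):
        i = 0
        theta = {}
        for p in PARAM_NAMES:
            theta[p] = max(float(x[i]), 1e-9)
            i += 1
        links = []
        for link in pop.links:
            links.append(replace(link, beta=float(x[i])))
            i += 1
        omega = {}
        for p in PARAM_NAMES:
            if pop.omega[p] > 0:
                omega[p] = abs(float(x[i]))
                i += 1
            else:
                omega[p] = 0.0
        a, b = abs(float(x[i])), abs(float(x[i + 1]))
        return replace(pop, theta=theta, links=tuple(links),
                       omega=omega, error=replace(pop.error, a=max(a, 1e-14), b=max(b, 1e-14)))

    return names, np.array(x0, dtype=float), unpack


def standard_errors(
    fit: FitResult,
    n_draws: int = 200,
    seed: int = 12345,
    rel_step: float = 0.02,
    include: list | None = None,
) -> dict:
    """RSE (%) per free parameter from a numeric Hessian of the
    importance-sampled log-likelihood (fixed IS seed for smoothness).

    ``include`` restricts the Hessian to a parameter block (the rest held
    at their estimates) — useful when structurally flat directions (e.g.
    deep-distribution parameters without washout data) would otherwise
    dominate the conditioning. Directions of negative curvature yield NaN
    entries; a singular information matrix returns NaN for the affected
    parameters.
    """
    pop = fit.pop
    ev = fit.evaluator()
    all_names, x_full, unpack_full = _pack_free(pop)
    if include is not None:
        keep = [i for i, n in enumerate(all_names) if n in include]
    else:
        keep = list(range(len(all_names)))
    names = [all_names[i] for i in keep]
    x0 = x_full[keep]

    def unpack(x_sub):
        x = x_full.copy()
        x[keep] = x_sub
        return unpack_full(x)

    d = len(x0)

    def m2ll(x):
        p = unpack(x)
        val, _ = loglik_importance(
            p, fit.dataset, n_draws=n_draws, seed=seed,
            cond_mean=fit.cond_mean, cond_sd=fit.cond_sd, evaluator=ev,
        )
        return val

    h = np.maximum(np.abs(x0) * rel_step, 1e-10)
    f0 = m2ll(x0)
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = m2ll(x0 + e)
        fm[i] = m2ll(x0 - e)
    H = np.zeros((d, d))
    for i in range(d):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            fpp = m2ll(x0 + ei + ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / (h[i] * h[j])
    rse = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        diag = np.diag(cov)
        for i, name in enumerate(names):
            if diag[i] > 0 and H[i, i] > 0:
                rse[name] = 100.0 * math.sqrt(diag[i]) / max(abs(x0[i]), 1e-300)
            else:
                rse[name] = float("nan")
    except np.linalg.LinAlgError:
        rse = {name: float("nan") for name in names}
    return rse
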