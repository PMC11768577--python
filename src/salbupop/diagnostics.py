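"""Model qualification: IWRES, NPDE, VPC and goodness-of-fit tables.

All diagnostics are simulation-based where needed and fully deterministic
under a seed. Numeric tables are the tested surface; plotting is left to
the caller (the tables carry everything a GOF figure shows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_NAMES, PKDataset, PopulationModel
from .saem import DatasetEvaluator, compute_ebes, _pop_mu

__all__ = ["VPCResult", "NPDEResult", "iwres", "npde", "vpc", "gof_tables"]


@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame       # columns p10/p50/p90 per bin
    band_low: pd.DataFrame       # 5th pct of simulated percentile per bin
    band_high: pd.DataFrame      # 95th pct of simulated percentile per bin
    outliers: pd.DataFrame       # bool per bin x percentile
    n_simulations: int
    seed: int

    @property
    def outlier_fraction(self) -> float:
        return float(self.outliers.to_numpy().mean())


@dataclass
class NPDEResult:
    table: pd.DataFrame          # ID, TIME, DV, npde
    decorrelation_ok: pd.Series  # per subject
    n_simulations: int
    seed: int

    @property
    def values(self) -> np.ndarray:
        return self.table["npde"].to_numpy(dtype=float)


def _ebe_predictions(pop: PopulationModel, dataset: PKDataset, ebes: pd.DataFrame,
                     dt: float = 0.0625):
    """Individual predictions f_i at the observation rows (sorted IDs)."""
    ev = DatasetEvaluator(dataset, dt=dt)
    params = ebes.set_index("ID").loc[ev.ids][list(PARAM_NAMES)].to_numpy(dtype=float)
    f = ev.predict(params, np.arange(ev.n))
    return ev, f


def iwres(pop: PopulationModel, dataset: PKDataset, ebes: pd.DataFrame | None = None,
          dt: float = 0.0625) -> pd.DataFrame:
    """Individual weighted residuals ``(y - f_i) / sd(f_i)`` per observation."""
    if ebes is None:
        ebes = compute_ebes(pop, dataset, dt=dt)
    ev, f = _ebe_predictions(pop, dataset, ebes, dt=dt)
    rows = []
    for i, sid in enumerate(ev.ids):
        m = ev.obs_mask[i]
        fi = f[i, m]
        yi = ev.y[i, m]
        t = ev.grid[ev.obs_pos[i, m]] + ev.obs_w[i, m] * ev.dt
        sd = pop.error.sd(fi)
        for tt, yy, ff, rr in zip(t, yi, fi, (yi - fi) / sd):
            rows.append({"ID": sid, "TIME": tt, "DV": yy, "IPRED": ff, "IWRES": rr})
    return pd.DataFrame(rows)


def _simulate_replicates(pop: PopulationModel, ev: DatasetEvaluator,
                         n_sim: int, rng: np.random.Generator,
                         mu_pop: np.ndarray) -> np.ndarray:
    """(n_sim, N, L) simulated DV matrices at the observed design."""
    N, L = ev.n, ev.L
    omega = pop.omega_array()
    free = omega > 0
    sims = np.empty((n_sim, N, L))
    for r in range(n_sim):
        eta = np.zeros((N, 7))
        if np.any(free):
            # rejection-resample rows with non-positive parameters
            todo = np.arange(N)
            for _ in range(1000):
                eta[todo][:, free] = 0.0
                draw = omega[free] * rng.standard_normal((len(todo), int(free.sum())))
                eta[np.ix_(todo, np.where(free)[0])] = draw
                bad = np.any(mu_pop[todo] + eta[todo] <= 0, axis=1)
                todo = todo[bad]
                if len(todo) == 0:
                    break
            else:
                raise RuntimeError("could not draw positive parameters")
        f = ev.predict(mu_pop + eta, np.arange(N))
        eps = rng.standard_normal((N, L))
        sims[r] = f + pop.error.sd(f) * eps
    return sims


def npde(pop: PopulationModel, dataset: PKDataset, n_sim: int = 500,
         seed: int = 0, dt: float = 0.0625) -> NPDEResult:
    """Normalized prediction distribution errors.

    Simulates ``n_sim`` replicates at the observed design, decorrelates
    observed and simulated vectors per subject with the empirical mean and
    Cholesky factor of the simulated covariance, converts rank-based
    prediction discrepancies to normal scores (ties jittered with the
    seeded RNG). Subjects whose simulated covariance is singular fall back
    to the marginal (undecorrelated) discrepancy and are flagged.
    """
    if n_sim < 50:
        raise ValueError("n_sim must be >= 50 for NPDE")
    rng = np.random.default_rng(seed)
    ev = DatasetEvaluator(dataset, dt=dt)
    mu_pop = _pop_mu(pop, dataset, ev.ids)
    sims = _simulate_replicates(pop, ev, n_sim, rng, mu_pop)
    rows = []
    ok = {}
    for i, sid in enumerate(ev.ids):
        m = ev.obs_mask[i]
        yi = ev.y[i, m]
        si = sims[:, i, m]                       # (n_sim, n_i)
        mean_s = si.mean(axis=0)
        cov_s = np.cov(si, rowvar=False)
        cov_s = np.atleast_2d(cov_s)
        try:
            Lc = np.linalg.cholesky(cov_s + 1e-12 * np.eye(cov_s.shape[0]))
            y_dec = np.linalg.solve(Lc, yi - mean_s)
            s_dec = np.linalg.solve(Lc, (si - mean_s).T).T
            ok[sid] = True
        except np.linalg.LinAlgError:
            y_dec = (yi - mean_s) / np.maximum(si.std(axis=0), 1e-300)
            s_dec = (si - mean_s) / np.maximum(si.std(axis=0), 1e-300)
            ok[sid] = False
        below = (s_dec < y_dec).sum(axis=0)
        ties = (s_dec == y_dec).sum(axis=0)
        u = (below + rng.uniform(size=len(yi)) * (ties + 1.0)) / (n_sim + 1.0)
        u = np.clip(u, 1.0 / (2 * (n_sim + 1)), 1.0 - 1.0 / (2 * (n_sim + 1)))
        nde = stats.norm.ppf(u)
        t = ev.grid[ev.obs_pos[i, m]] + ev.obs_w[i, m] * ev.dt
        for tt, yy, vv in zip(t, yi, nde):
            rows.append({"ID": sid, "TIME": tt, "DV": yy, "npde": vv})
    return NPDEResult(
        table=pd.DataFrame(rows),
        decorrelation_ok=pd.Series(ok),
        n_simulations=n_sim,
        seed=seed,
    )


def vpc(pop: PopulationModel, dataset: PKDataset, n_sim: int = 500,
        n_bins: int = 8, seed: int = 0, dt: float = 0.0625,
        percentiles: tuple = (10.0, 50.0, 90.0)) -> VPCResult:
    """Visual predictive check with a 90% prediction band per percentile.

    Observations are binned by time quantiles (bins with fewer than three
    observations are merged with their neighbor); for each bin the
    observed 10/50/90th percentiles are compared with the 5th-95th
    percentile band of the same statistic over simulated replicates.
    """
    rng = np.random.default_rng(seed)
    ev = DatasetEvaluator(dataset, dt=dt)
    mu_pop = _pop_mu(pop, dataset, ev.ids)
    sims = _simulate_replicates(pop, ev, n_sim, rng, mu_pop)

    mask = ev.obs_mask
    times = (ev.grid[ev.obs_pos] + ev.obs_w * ev.dt)[mask]
    y_obs = ev.y[mask]
    sim_flat = sims[:, mask]                     # (n_sim, n_obs)

    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(times, qs))
    # merge bins with < 3 observations
    while len(edges) > 2:
        counts, _ = np.histogram(times, bins=edges)
        small = np.where(counts < 3)[0]
        if len(small) == 0:
            break
        j = small[0]
        edges = np.delete(edges, j + 1 if j + 1 < len(edges) - 1 else j)
    binned = np.clip(np.digitize(times, edges[1:-1]), 0, len(edges) - 2)

    obs_rows, lo_rows, hi_rows, out_rows, mids = [], [], [], [], []
    for b in range(len(edges) - 1):
        sel = binned == b
        mids.append(float(times[sel].mean()))
        obs_p = {f"p{int(p)}": float(np.percentile(y_obs[sel], p)) for p in percentiles}
        sim_p = np.percentile(sim_flat[:, sel], list(percentiles), axis=1)  # (3, n_sim)
        lo = {f"p{int(p)}": float(np.percentile(sim_p[k], 5)) for k, p in enumerate(percentiles)}
        hi = {f"p{int(p)}": float(np.percentile(sim_p[k], 95)) for k, p in enumerate(percentiles)}
        out = {f"p{int(p)}": bool(obs_p[f"p{int(p)}"] < lo[f"p{int(p)}"]
                                  or obs_p[f"p{int(p)}"] > hi[f"p{int(p)}"])
               for p in percentiles}
        obs_rows.append(obs_p); lo_rows.append(lo); hi_rows.append(hi); out_rows.append(out)
    return VPCResult(
        bin_edges=edges,
        bin_mid=np.array(mids),
        observed=pd.DataFrame(obs_rows),
        band_low=pd.DataFrame(lo_rows),
        band_high=pd.DataFrame(hi_rows),
        outliers=pd.DataFrame(out_rows),
        n_simulations=n_sim,
        seed=seed,
    )


def gof_tables(pop: PopulationModel, dataset: PKDataset,
               ebes: pd.DataFrame | None = None, dt: float = 0.0625) -> dict:
    """Observed-vs-predicted and residual tables plus the outlier proportion.

    ``outlier_proportion`` is the fraction of observations outside the 90%
    individual prediction interval, i.e. ``|y - f_i| > z_0.95 sd(f_i)``.
    """
    if ebes is None:
        ebes = compute_ebes(pop, dataset, dt=dt)
    res = iwres(pop, dataset, ebes=ebes, dt=dt)
    ev = DatasetEvaluator(dataset, dt=dt)
    mu_pop = _pop_mu(pop, dataset, ev.ids)
    f_pop = ev.predict(mu_pop, np.arange(ev.n))
    ppred = []
    for i in range(ev.n):
        ppred.extend(f_pop[i, ev.obs_mask[i]])
    obs_pred = res[["ID", "TIME", "DV", "IPRED"]].copy()
    obs_pred["PRED"] = np.array(ppred)

    z95 = stats.norm.ppf(0.95)
    sd_i = pop.error.sd(res["IPRED"].to_numpy())
    outliers = np.abs(res["DV"].to_numpy() - res["IPRED"].to_numpy()) > z95 * sd_i
    grid = np.linspace(-4, 4, 161)
    iw = res["IWRES"].to_numpy()
    kde = stats.gaussian_kde(iw) if len(iw) > 1 and iw.std() > 0 else None
    density = pd.DataFrame({
        "x": grid,
        "normal_pdf": stats.norm.pdf(grid),
        "iwres_density": kde(grid) if kde else np.full_like(grid, np.nan),
    })
    return {
        "observed_vs_predicted": obs_pred,
        "residual_table": res,
        "iwres_density": density,
        "outlier_proportion": float(outliers.mean()),
    }
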