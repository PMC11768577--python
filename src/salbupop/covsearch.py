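"""Covariate screening and stepwise model selection.

Screening follows the classical EBE-based recipe: Pearson and Spearman
correlations of per-subject random effects against continuous covariates,
one-way ANOVA against categorical covariates, flagging pairs with
min-p < alpha. Collinear continuous covariates are filtered by variance
inflation factor (VIF > 15 excludes the member of the offending set with
the less significant screening p-value). Model building combines forward
selection (accept when -2LL drops by more than the chi-square 0.05
quantile, 3.84) with backward elimination (remove unless -2LL rises by at
least the 0.001 quantile, 10.83); a COSSAC-like variant ranks
relationships by correlation tests on conditional-distribution samples
instead of EBEs and additionally requires a BICc improvement.

Likelihood differences between nested models are computed with a shared
importance-sampling seed so Monte-Carlo noise largely cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_NAMES, CovariateLink, PKDataset
from .saem import (
    FitResult,
    SaemSettings,
    bicc,
    loglik_importance,
    parameter_counts,
    saem_fit,
)

__all__ = [
    "screen_covariates",
    "vif_filter",
    "lrt_threshold",
    "stepwise_search",
    "cossac_search",
    "wald_tests",
    "candidate_links",
    "DEFAULT_CLINICAL_PRIORITY",
]

#: clinically motivated candidate ordering (ties in screening p-values)
DEFAULT_CLINICAL_PRIORITY = (
    "WT", "BSA", "SEX", "HEALTH", "AGE", "RACE", "CYP2D6", "CYP2C19",
)

CONTINUOUS_COVARIATES = ("AGE", "WT", "HT", "BSA", "BMI", "CYP2D6", "CYP2C19")
CATEGORICAL_COVARIATES = ("SEX", "RACE", "HEALTH")


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Chi-square upper-``alpha`` quantile, rounded to 2 decimals for
    reporting (0.05 -> 3.84, 0.001 -> 10.83)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    from .nca import round_half_up

    return round_half_up(float(stats.chi2.ppf(1.0 - alpha, df)), 2)


def _lrt_raw(alpha: float, df: int = 1) -> float:
    return float(stats.chi2.ppf(1.0 - alpha, df))


def screen_covariates(
    eta_table: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Statistical screening of random effects against covariates.

    ``eta_table``: per-subject random effects (columns ``eta_<param>`` or
    parameter names); ``covariates``: per-subject covariate frame (ID plus
    covariate columns). Returns one row per (parameter, covariate, test)
    with the statistic and p-value, plus a ``flagged`` column
    (min p < alpha over the tests of the pair). Constant covariates and
    categorical covariates without replication are skipped with a note.
    """
    cov = covariates.set_index("ID") if "ID" in covariates.columns else covariates
    if "ID" in eta_table.columns:
        eta_table = eta_table.set_index("ID")
    eta_table = eta_table.loc[cov.index.intersection(eta_table.index)]
    cov = cov.loc[eta_table.index]
    rows = []
    for p in PARAM_NAMES:
        col = f"eta_{p}" if f"eta_{p}" in eta_table.columns else p
        if col not in eta_table.columns:
            continue
        e = eta_table[col].to_numpy(dtype=float)
        if np.allclose(e.std(), 0.0):
            continue
        for c in cov.columns:
            vals = cov[c].to_numpy()
            if c in CONTINUOUS_COVARIATES:
                v = vals.astype(float)
                if np.allclose(v.std(), 0.0):
                    rows.append({"parameter": p, "covariate": c, "test": "skipped",
                                 "statistic": np.nan, "p_value": np.nan,
                                 "note": "constant covariate"})
                    continue
                r_p, p_p = stats.pearsonr(v, e)
                r_s, p_s = stats.spearmanr(v, e)
                rows.append({"parameter": p, "covariate": c, "test": "pearson",
                             "statistic": r_p, "p_value": p_p, "note": ""})
                rows.append({"parameter": p, "covariate": c, "test": "spearman",
                             "statistic": r_s, "p_value": p_s, "note": ""})
            elif c in CATEGORICAL_COVARIATES:
                groups = [e[vals == lev] for lev in pd.unique(vals)]
                groups = [g for g in groups if len(g) > 0]
                if len(groups) < 2 or all(len(g) < 2 for g in groups):
                    rows.append({"parameter": p, "covariate": c, "test": "skipped",
                                 "statistic": np.nan, "p_value": np.nan,
                                 "note": "insufficient degrees of freedom"})
                    continue
                F, p_a = stats.f_oneway(*groups)
                rows.append({"parameter": p, "covariate": c, "test": "anova",
                             "statistic": F, "p_value": p_a, "note": ""})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out
    flagged = (
        out[out.test != "skipped"]
        .groupby(["parameter", "covariate"])["p_value"]
        .min()
        .rename("min_p")
        .reset_index()
    )
    flagged["flagged"] = flagged["min_p"] < alpha
    return out.merge(flagged, on=["parameter", "covariate"], how="left")


def vif_filter(
    covariates: pd.DataFrame,
    threshold: float = 15.0,
    p_values: dict | None = None,
) -> tuple:
    """Iteratively exclude collinear continuous covariates by VIF.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing covariate j on the others.
    While any VIF exceeds ``threshold``, the offender with the least
    significant screening p-value (largest; from ``p_values``, default
    alphabetical last) is dropped. Returns ``(retained, excluded,
    vif_table)``.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    cols = [c for c in covariates.columns if c != "ID"]
    X0 = covariates[cols].to_numpy(dtype=float)
    if X0.shape[1] < 2:
        raise ValueError("need at least two continuous covariates")
    if X0.shape[0] <= X0.shape[1]:
        raise ValueError("need more subjects than covariates")
    retained = list(cols)
    excluded = []
    history = []
    while True:
        vifs = {}
        if len(retained) == 1:
            vifs[retained[0]] = 1.0
        else:
            X = sm.add_constant(covariates[retained].to_numpy(dtype=float))
            with np.errstate(divide="ignore", invalid="ignore"):
                for j, c in enumerate(retained):
                    v = variance_inflation_factor(X, j + 1)
                    vifs[c] = float(v) if np.isfinite(v) else np.inf
        history.append(dict(vifs))
        over = [c for c in retained if vifs[c] > threshold]
        if not over or len(retained) <= 1:
            break
        if p_values:
            drop = max(over, key=lambda c: p_values.get(c, 1.0))
        else:
            drop = sorted(over)[-1]
        retained.remove(drop)
        excluded.append(drop)
    vif_table = pd.DataFrame(history)
    return retained, excluded, vif_table


def candidate_links(
    screening: pd.DataFrame,
    retained_continuous: list | None = None,
    priority: tuple = DEFAULT_CLINICAL_PRIORITY,
) -> list:
    """Ordered candidate links from a screening table.

    Flagged (parameter, covariate) pairs become additive links; ordering is
    by clinical priority rank then smallest screening p-value. Categorical
    covariates expand to one link per non-reference category present.
    """
    if len(screening) == 0:
        return []
    flags = (
        screening[screening.get("flagged", False) == True]  # noqa: E712
        .groupby(["parameter", "covariate"])["min_p"]
        .min()
        .reset_index()
    )
    cands = []
    for _, row in flags.iterrows():
        c = row["covariate"]
        if retained_continuous is not None and c in CONTINUOUS_COVARIATES:
            if c not in retained_continuous:
                continue
        rank = priority.index(c) if c in priority else len(priority)
        if c in CATEGORICAL_COVARIATES:
            n_levels = {"SEX": [1], "RACE": [1, 2], "HEALTH": [1, 2]}[c]
            for lev in n_levels:
                cands.append(
                    (rank, row["min_p"],
                     CovariateLink(parameter=row["parameter"], covariate=c,
                                   kind="categorical", beta=0.0, reference=0,
                                   category=lev))
                )
        else:
            cands.append(
                (rank, row["min_p"],
                 CovariateLink(parameter=row["parameter"], covariate=c,
                               kind="continuous", beta=0.0, reference=None))
            )
    cands.sort(key=lambda t: (t[0], t[1]))
    return [c for _, _, c in cands]


@dataclass
class SelectionStep:
    action: str                # 'add' | 'remove'
    link_label: str
    minus2ll_before: float
    minus2ll_after: float
    accepted: bool
    reason: str


def _refit_with_links(
    dataset: PKDataset,
    base_fit: FitResult,
    links,
    settings: SaemSettings,
    ll_seed: int,
    is_draws: int,
):
    """Warm-started refit with a given link set; returns (fit, -2LL, BICc)."""
    init = base_fit.pop.with_links(links)
    fit = saem_fit(dataset, init, settings, eta0=base_fit.eta)
    m2ll, _ = loglik_importance(
        fit.pop, dataset, n_draws=is_draws, seed=ll_seed,
        cond_mean=fit.cond_mean, cond_sd=fit.cond_sd,
        evaluator=fit.evaluator(),
    )
    p_sub, p_obs = parameter_counts(fit.pop)
    crit = bicc(m2ll, fit.dataset.n_subjects, dataset.n_observations, p_sub, p_obs)
    fit.minus2ll = m2ll
    fit.bicc = crit
    return fit, m2ll, crit


def _dedupe(links) -> list:
    seen, out = set(), []
    for l in links:
        if l.label not in seen:
            seen.add(l.label)
            out.append(l)
    return out


def stepwise_search(
    dataset: PKDataset,
    base_fit: FitResult,
    candidates: list,
    settings: SaemSettings | None = None,
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.001,
    is_draws: int = 300,
    ll_seed: int = 777,
    require_bicc: bool = False,
    max_forward: int | None = None,
) -> tuple:
    """Forward selection / backward elimination over candidate links.

    Returns ``(final_fit, trace)``; -2LL differences use a shared
    importance-sampling seed across nested models.
    """
    settings = settings or base_fit.settings
    candidates = _dedupe(candidates)
    fwd_thr = _lrt_raw(forward_alpha, 1)
    bwd_thr = _lrt_raw(backward_alpha, 1)
    cur_links: list = list(base_fit.pop.links)
    cur_fit, cur_m2ll, cur_bicc = _refit_with_links(
        dataset, base_fit, cur_links, settings, ll_seed, is_draws
    )
    trace: list = []
    added = True
    n_added = 0
    while added:
        added = False
        for cand in list(candidates):
            if any(c.label == cand.label for c in cur_links):
                candidates.remove(cand)
                continue
            try:
                fit_new, m2ll_new, bicc_new = _refit_with_links(
                    dataset, cur_fit, cur_links + [cand], settings, ll_seed, is_draws
                )
            except Exception as exc:  # refit failure: skip and log
                trace.append(SelectionStep("add", cand.label, cur_m2ll, math.nan,
                                           False, f"refit failed: {exc}"))
                candidates.remove(cand)
                continue
            drop = cur_m2ll - m2ll_new
            ok = drop > fwd_thr and (not require_bicc or bicc_new < cur_bicc)
            trace.append(SelectionStep("add", cand.label, cur_m2ll, m2ll_new, ok,
                                       f"delta -2LL = {drop:.2f} vs {fwd_thr:.2f}"))
            if ok:
                cur_links.append(cand)
                cur_fit, cur_m2ll, cur_bicc = fit_new, m2ll_new, bicc_new
                candidates.remove(cand)
                added = True
                n_added += 1
                if max_forward is not None and n_added >= max_forward:
                    added = False
                    candidates = []
                break

    # backward elimination, least significant (largest Wald p) first
    while cur_links:
        wald = wald_tests(cur_fit, is_draws=max(is_draws // 2, 100), seed=ll_seed + 1)
        order = sorted(cur_links, key=lambda l: -(wald.get(l.label, (np.nan, 1.0))[1]
                                                  if not math.isnan(wald.get(l.label, (0, 1.0))[1])
                                                  else 1.0))
        removed = False
        for link in order:
            reduced = [l for l in cur_links if l.label != link.label]
            fit_red, m2ll_red, bicc_red = _refit_with_links(
                dataset, cur_fit, reduced, settings, ll_seed, is_draws
            )
            rise = m2ll_red - cur_m2ll
            remove = rise < bwd_thr
            trace.append(SelectionStep("remove", link.label, cur_m2ll, m2ll_red,
                                       remove, f"delta -2LL = {rise:.2f} vs {bwd_thr:.2f}"))
            if remove:
                cur_links = reduced
                cur_fit, cur_m2ll, cur_bicc = fit_red, m2ll_red, bicc_red
                removed = True
                break
        if not removed:
            break

    trace_df = pd.DataFrame([s.__dict__ for s in trace])
    return cur_fit, trace_df


def cossac_search(
    dataset: PKDataset,
    base_fit: FitResult,
    covariates: list | None = None,
    settings: SaemSettings | None = None,
    alpha: float = 0.05,
    is_draws: int = 300,
    ll_seed: int = 777,
    max_forward: int | None = None,
) -> tuple:
    """COSSAC-like search: rank random-effect/covariate relationships by
    correlation tests on conditional-distribution samples (not EBEs), then
    run the stepwise procedure requiring both the -2LL drop and a BICc
    improvement for acceptance.
    """
    if base_fit.cond_draws.shape[0] == 0:
        raise ValueError("base fit retained no conditional draws")
    omega = base_fit.pop.omega_array()
    if not np.any(omega > 0):
        return base_fit, pd.DataFrame([{"action": "none", "link_label": "",
                                        "reason": "zero-IIV model: conditional samples degenerate",
                                        "accepted": False}])
    # average conditional draws per subject (posterior-mean eta sample)
    eta_mean = base_fit.cond_draws.mean(axis=0)
    eta_df = pd.DataFrame(
        {f"eta_{p}": eta_mean[:, j] for j, p in enumerate(PARAM_NAMES)}
    )
    eta_df.insert(0, "ID", base_fit.ids)
    covf = dataset.covariate_frame()
    if covariates is not None:
        covf = covf[["ID"] + [c for c in covariates if c in covf.columns]]
    screening = screen_covariates(eta_df, covf, alpha=alpha)
    cands = candidate_links(screening)
    return stepwise_search(
        dataset, base_fit, cands, settings=settings,
        is_draws=is_draws, ll_seed=ll_seed, require_bicc=True,
        max_forward=max_forward,
    )


def wald_tests(fit: FitResult, is_draws: int = 200, seed: int = 999,
               rel_step: float = 0.05) -> dict:
    """Wald z-tests for covariate coefficients.

    SEs come from the beta-block of a numeric Hessian of the
    importance-sampled -2LL with the remaining parameters held at their
    estimates (used for backward-elimination ordering). Returns
    ``{label: (z, p)}``; missing SEs give ``(nan, nan)``.
    """
    links = fit.pop.links
    if not links:
        return {}
    ev = fit.evaluator()
    betas = np.array([l.beta for l in links], dtype=float)
    labels = [l.label for l in links]

    def m2ll(bvec):
        new_links = tuple(
            CovariateLink(l.parameter, l.covariate, l.kind, float(b), l.reference, l.category)
            for l, b in zip(links, bvec)
        )
        pop = fit.pop.with_links(new_links)
        val, _ = loglik_importance(
            pop, fit.dataset, n_draws=is_draws, seed=seed,
            cond_mean=fit.cond_mean, cond_sd=fit.cond_sd, evaluator=ev,
        )
        return val

    d = len(betas)
    h = np.maximum(np.abs(betas) * rel_step, 1e-6)
    f0 = m2ll(betas)
    H = np.zeros((d, d))
    fp = np.zeros(d)
    fm = np.zeros(d)
    for i in range(d):
        e = np.zeros(d); e[i] = h[i]
        fp[i] = m2ll(betas + e)
        fm[i] = m2ll(betas - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = h[i]
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (m2ll(betas + ei + ej) - fp[i] - fp[j] + f0) / (h[i] * h[j])
    out = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(d, np.nan)
    for lab, b, s in zip(labels, betas, se):
        if not np.isfinite(s) or s <= 0:
            out[lab] = (float("nan"), float("nan"))
        else:
            z = b / s
            out[lab] = (float(z), float(2.0 * stats.norm.sf(abs(z))))
    return out
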