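"""Dataset and configuration I/O, the end-to-end pipeline, and fixtures.

Interchange format: NONMEM-style event-record CSV with columns
ID, TIME, DV, AMT, EVID (MDV inferred when absent) plus covariate
columns. DV is in ug/mL, AMT in mg. Categorical encodings: SEX 0=male /
1=female; RACE 0=american / 1=asian / 2=chinese; HEALTH 0=healthy /
1=obese / 2=cirrhosis_a.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import nca, pbpk
from .model import (
    CATEGORICAL_CODES,
    PARAM_NAMES,
    PKDataset,
    default_population_model,
    simulate_dataset,
)

logger = logging.getLogger("salbupop")

__all__ = [
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "simulate_pbpk_dataset",
    "run_pipeline",
    "make_fixtures",
    "default_schedule",
]

REQUIRED_COLUMNS = ("ID", "TIME", "DV", "AMT", "EVID")


def default_schedule(n_samples: int = 21, duration: float = 24.0) -> np.ndarray:
    """The packaged ~21-point observation schedule over one day.

    Dense early sampling (absorption phase of the first dose), moderate
    mid-interval coverage and trough samples around later doses — the
    standard rich-design layout for an oral q6h regimen. For other
    ``n_samples``/``duration`` the layout is rescaled by quantile
    interpolation.
    """
    base = np.array([
        0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0,
        6.5, 7.0, 8.0, 10.0, 12.0, 12.5, 14.0, 16.0, 18.0, 21.0, 24.0,
    ])
    if n_samples == len(base) and duration == 24.0:
        return base
    q = np.linspace(0.0, 1.0, n_samples)
    return np.round(np.interp(q, np.linspace(0, 1, len(base)), base * duration / 24.0), 4)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (all stages seeded)."""

    out_dir: str = "salbupop_run"
    seed: int = 20250101
    n_samples: int = 21
    duration_h: float = 24.0
    dose_mg: float = 4.0
    interval_h: float = 6.0
    n_doses: int = 4
    cohort_spec: str | None = None       # YAML path; packaged default if None
    saem_k1: int = 200
    saem_k2: int = 100
    is_draws: int = 500
    covsearch_method: str = "stepwise"   # 'stepwise' | 'cossac' | 'none'
    n_sim_diag: int = 200
    lloq: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.cohort_spec and not Path(cfg.cohort_spec).exists():
            raise FileNotFoundError(cfg.cohort_spec)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def read_dataset(path) -> PKDataset:
    """Read and validate an event-record CSV (units: DV ug/mL, AMT mg)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing required columns: {missing}")
    bad = df[df["TIME"].isna() | df["ID"].isna()]
    if len(bad):
        raise ValueError(f"malformed rows (missing ID/TIME) at lines: "
                         f"{[int(i) + 2 for i in bad.index[:10]]}")
    for sid, g in df.groupby("ID"):
        t = g["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            logger.warning("non-monotone times for subject %s: sorting", sid)
            df = df.sort_values(["ID", "TIME"]).reset_index(drop=True)
            break
    return PKDataset(df)


def write_dataset(dataset: PKDataset, path) -> None:
    dataset.frame.to_csv(path, index=False)


def _subject_covariate_row(s: cohort_mod.VirtualSubject) -> dict:
    return {
        "AGE": s.age,
        "WT": s.weight,
        "HT": s.height,
        "BSA": s.bsa,
        "BMI": s.bmi,
        "SEX": CATEGORICAL_CODES["SEX"]["male" if s.gender == "male" else "female"],
        "RACE": CATEGORICAL_CODES["RACE"][s.race],
        "HEALTH": CATEGORICAL_CODES["HEALTH"][s.health_status],
        "CYP2D6": s.cyp2d6_expr,
        "CYP2C19": s.cyp2c19_expr,
    }


def simulate_pbpk_dataset(
    subjects: list,
    regimen: pbpk.DoseRegimen,
    schedule: np.ndarray,
    lloq: float = 0.0,
    noise: tuple | None = None,
    seed: int = 0,
) -> PKDataset:
    """PBPK-simulate every subject and assemble the event-record dataset.

    Concentrations are extracted noiselessly by default (matching the
    study workflow of reading simulated profiles); ``noise=(a, b)`` adds
    combined residual noise in ug/L before unit conversion.
    """
    compound = pbpk.default_compound()
    kps = pbpk.default_kp_set()
    t_grid = np.unique(np.concatenate([
        np.linspace(0.0, float(schedule.max()), int(schedule.max() * 20) + 1),
        schedule,
        regimen.dose_times,
    ]))
    rows = []
    rng = np.random.default_rng(seed)
    for s in subjects:
        phys = cohort_mod.scale_physiology(s)
        prof = pbpk.simulate_pbpk(phys, compound, kps, regimen, t_grid)
        obs = pbpk.sample_observations(prof, schedule, lloq=lloq * 1000.0,
                                       noise=noise, rng=rng)
        covs = _subject_covariate_row(s)
        for td in regimen.dose_times:
            rows.append({"ID": s.id, "TIME": float(td), "DV": np.nan,
                         "AMT": regimen.dose_amount, "EVID": 1, "MDV": 1, **covs})
        for _, orow in obs.iterrows():
            rows.append({"ID": s.id, "TIME": float(orow["time"]),
                         "DV": float(orow["conc"]) / 1000.0,  # ug/L -> ug/mL
                         "AMT": 0.0, "EVID": 0, "MDV": 0, **covs})
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                           ascending=[True, True, False])
    return PKDataset(frame.reset_index(drop=True))


def make_fixtures(seed: int = 20250101) -> dict:
    """Programmatic test datasets.

    Returns a dict with: ``pbpk_dataset`` — the 40-subject PBPK-derived
    study emulation; ``parametric_dataset`` — simulated directly from the
    packaged final model; ``triangle_profile`` — a tiny hand-checkable NCA
    example (AUC of a unit triangle).
    """
    spec = cohort_mod.default_cohort_spec(seed=seed)
    subjects = cohort_mod.sample_cohort(spec)
    regimen = pbpk.DoseRegimen(4.0, interval=6.0, n_doses=4)
    schedule = default_schedule()
    pbpk_ds = simulate_pbpk_dataset(subjects, regimen, schedule, seed=seed)

    pop = default_population_model()
    cov_frame = pd.DataFrame(
        [{"ID": s.id, **_subject_covariate_row(s)} for s in subjects]
    )
    parametric = simulate_dataset(pop, cov_frame, schedule, regimen, seed=seed + 1)

    triangle = pd.DataFrame({"time": [0.0, 1.0, 2.0], "conc": [0.0, 2.0, 0.0]})
    return {
        "pbpk_dataset": pbpk_ds,
        "parametric_dataset": parametric,
        "triangle_profile": triangle,
        "cohort": cohort_mod.cohort_table(subjects),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute cohort -> PBPK -> dataset -> fit -> covariate search ->
    diagnostics -> subgroups, persisting every stage under ``out_dir``."""
    from . import covsearch as covsearch_mod
    from . import diagnostics as diag_mod
    from . import subgroups as sub_mod
    from .saem import (SaemSettings, bicc, compute_ebes, individual_fit_init,
                       loglik_importance, parameter_counts, saem_fit)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        from . import __version__

        logger.info("salbupop %s, config hash %s, seed %d",
                    __version__, config.config_hash(), config.seed)

        # 1. cohort
        if config.cohort_spec:
            with open(config.cohort_spec) as fh:
                raw = yaml.safe_load(fh)
            spec = cohort_mod.CohortSpec(
                groups=tuple(cohort_mod.GroupSpec(**g) for g in raw["groups"]),
                age_range=tuple(raw.get("age_range", (5.0, 65.0))),
                age_mean=float(raw.get("age_mean", 40.0)),
                age_sd=float(raw.get("age_sd", 18.0)),
                seed=int(raw.get("seed", config.seed)),
            )
        else:
            spec = cohort_mod.default_cohort_spec(seed=config.seed)
        subjects = cohort_mod.sample_cohort(spec)
        cohort_mod.cohort_table(subjects).to_csv(out / "cohort.csv", index=False)
        logger.info("stage cohort: %d subjects", len(subjects))

        # 2. PBPK simulation -> dataset
        regimen = pbpk.DoseRegimen(config.dose_mg, interval=config.interval_h,
                                   n_doses=config.n_doses)
        schedule = default_schedule(config.n_samples, config.duration_h)
        dataset = simulate_pbpk_dataset(subjects, regimen, schedule,
                                        lloq=config.lloq, seed=config.seed)
        write_dataset(dataset, out / "dataset.csv")
        logger.info("stage simulate: %d observations", dataset.n_observations)

        # 3. NCA per subject
        nca_rows = []
        for sid in dataset.subject_ids:
            og = dataset.observations(sid)
            res = nca.nca_summary(og["TIME"].to_numpy(), og["DV"].to_numpy(),
                                  dose=float(dataset.doses(sid)["AMT"].iloc[0]))
            nca_rows.append({"ID": sid, **{k: getattr(res, k) for k in
                             ("cmax", "tmax", "auc_last", "auc_inf", "lambda_z",
                              "t_half", "cl_over_f", "vz_over_f")}})
        pd.DataFrame(nca_rows).to_csv(out / "nca.csv", index=False)
        logger.info("stage nca: done")

        # 4. base fit
        settings = SaemSettings(k1=config.saem_k1, k2=config.saem_k2,
                                seed=config.seed, is_draws=config.is_draws)
        init, eta0 = individual_fit_init(dataset)
        fit = saem_fit(dataset, init, settings, eta0=eta0)
        m2ll, se = loglik_importance(fit.pop, dataset, n_draws=config.is_draws,
                                     seed=config.seed, cond_mean=fit.cond_mean,
                                     cond_sd=fit.cond_sd, evaluator=fit.evaluator())
        p_sub, p_obs = parameter_counts(fit.pop)
        fit.minus2ll = m2ll
        fit.bicc = bicc(m2ll, dataset.n_subjects, dataset.n_observations, p_sub, p_obs)
        fit.trace.to_csv(out / "fit_trace.csv", index=False)
        fit.estimates_table().to_csv(out / "fit_estimates.csv", index=False)
        logger.info("stage fit: -2LL %.2f (MC SE %.2f), BICc %.2f",
                    m2ll, se, fit.bicc)

        # 5. covariate search
        final_fit = fit
        if config.covsearch_method != "none":
            ebes = compute_ebes(fit.pop, dataset, starts=fit.cond_mean)
            fit.ebes = ebes
            eta_cols = ["ID"] + [f"eta_{p}" for p in PARAM_NAMES]
            screening = covsearch_mod.screen_covariates(
                ebes[eta_cols], dataset.covariate_frame()
            )
            screening.to_csv(out / "screening.csv", index=False)
            cont = dataset.covariate_frame()[["ID", "AGE", "WT", "BSA", "CYP2D6", "CYP2C19"]]
            pvals = (screening[screening.test != "skipped"]
                     .groupby("covariate")["p_value"].min().to_dict())
            retained, excluded, viftab = covsearch_mod.vif_filter(
                cont, p_values=pvals
            )
            viftab.to_csv(out / "vif.csv", index=False)
            cands = covsearch_mod.candidate_links(screening, retained_continuous=retained)
            if config.covsearch_method == "cossac":
                final_fit, trace = covsearch_mod.cossac_search(
                    dataset, fit, settings=settings, is_draws=config.is_draws,
                )
            else:
                final_fit, trace = covsearch_mod.stepwise_search(
                    dataset, fit, cands, settings=settings, is_draws=config.is_draws,
                )
            trace.to_csv(out / "covsearch_trace.csv", index=False)
            final_fit.estimates_table().to_csv(out / "final_estimates.csv", index=False)
            logger.info("stage covsearch: %d links selected", len(final_fit.pop.links))

        # 6. diagnostics
        ebes = compute_ebes(final_fit.pop, dataset, starts=final_fit.cond_mean)
        final_fit.ebes = ebes
        gof = diag_mod.gof_tables(final_fit.pop, dataset, ebes=ebes)
        gof["observed_vs_predicted"].to_csv(out / "gof_obs_pred.csv", index=False)
        gof["residual_table"].to_csv(out / "gof_residuals.csv", index=False)
        npde_res = diag_mod.npde(final_fit.pop, dataset, n_sim=config.n_sim_diag,
                                 seed=config.seed)
        npde_res.table.to_csv(out / "npde.csv", index=False)
        vpc_res = diag_mod.vpc(final_fit.pop, dataset, n_sim=config.n_sim_diag,
                               seed=config.seed)
        vpc_tab = pd.concat(
            [vpc_res.observed.add_prefix("obs_"),
             vpc_res.band_low.add_prefix("lo_"),
             vpc_res.band_high.add_prefix("hi_")], axis=1
        )
        vpc_tab.insert(0, "t_mid", vpc_res.bin_mid)
        vpc_tab.to_csv(out / "vpc.csv", index=False)
        logger.info("stage diagnostics: outlier proportion %.4f",
                    gof["outlier_proportion"])

        # 7. subgroup summaries
        covf = dataset.covariate_frame()
        grouping = [
            ("female", {"SEX": 1}),
            ("male", {"SEX": 0}),
            ("bsa_low_wt_low", {"BSA": (0.94, 1.60), "WT": (26.4, 75.0)}),
            ("bsa_high_wt_low", {"BSA": (1.60, 2.37), "WT": (26.4, 75.0)}),
            ("bsa_high_wt_high", {"BSA": (1.60, 2.37), "WT": (75.0, 109.0)}),
        ]
        summaries = sub_mod.summarize_subgroups(
            ebes[["ID"] + list(PARAM_NAMES)], covf, grouping,
            parameters=["Mtt", "V1", "Cl"],
            filters={"AGE": (20.0, 69.0), "HEALTH": 0},
        )
        sub_mod.subgroup_table(summaries).to_csv(out / "subgroups.csv", index=False)
        logger.info("pipeline complete")
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()
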