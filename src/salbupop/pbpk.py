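"""Whole-body perfusion-limited PBPK simulator with a CAT gut model.

The systemic model has 13 tissue compartments (lung in series between the
venous and arterial pools, 12 tissues perfused in parallel) with
perfusion-rate-limited distribution: the venous outflow blood concentration
of a tissue is ``C_t * R_bp / Kp_t``. Oral absorption uses a 9-compartment
compartmental-absorption-and-transit (CAT) chain (stomach, 7 small-intestine
segments, colon) with first-order transit and segmental absorption rate
constants ``k_a,i = 2 P_eff / R_i``; absorbed drug is routed to the liver
inlet together with splenic (portal) outflow. Hepatic elimination is
well-stirred extraction with the intrinsic clearance calibrated so the
linear-regime systemic plasma clearance of the reference adult equals the
compound's hepatic plasma clearance; renal elimination is first-order on
arterial plasma at the kidney.

Canonical internal units: amounts ug, volumes L, times h, concentrations
ug/L (plasma). Doses are declared in mg and converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import defaults
from .cohort import PARALLEL_TISSUES, TISSUES, PhysiologySet, reference_subject, scale_physiology

__all__ = [
    "Compound",
    "TissueKpSet",
    "DoseRegimen",
    "ConcProfile",
    "CATModel",
    "default_compound",
    "default_kp_set",
    "cat_absorption_state",
    "simulate_pbpk",
    "mass_balance",
    "sample_observations",
]


@dataclass(frozen=True)
class Compound:
    """Physicochemical and disposition parameters of the simulated drug."""

    name: str
    molecular_weight: float       # g/mol
    logp: float
    pka_basic: float
    pka_acidic: float
    solubility_mg_ml: float
    diffusion_coeff: float        # 1e-5 cm^2/s
    blood_plasma_ratio: float     # R_bp
    peff: float                   # 1e-4 cm/s
    fraction_unbound: float
    hepatic_clearance: float      # L/h, plasma terms
    renal_clearance: float        # L/h, plasma terms

    def __post_init__(self) -> None:
        positives = (
            self.molecular_weight,
            self.solubility_mg_ml,
            self.diffusion_coeff,
            self.blood_plasma_ratio,
            self.hepatic_clearance,
            self.renal_clearance,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("compound scalar parameters must be positive")
        if not 0.0 < self.fraction_unbound <= 1.0:
            raise ValueError("fraction unbound must be in (0, 1]")
        if self.peff < 0:
            raise ValueError("effective permeability must be non-negative")


@dataclass(frozen=True)
class TissueKpSet:
    """Tissue:plasma partition coefficients for the 13 tissues."""

    kp: dict

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.kp]
        if missing:
            raise ValueError(f"missing Kp for tissues: {missing}")
        if any(self.kp[t] <= 0 for t in TISSUES):
            raise ValueError("all Kp values must be positive")

    def __getitem__(self, tissue: str) -> float:
        return float(self.kp[tissue])


@dataclass(frozen=True)
class DoseRegimen:
    dose_amount: float            # mg
    interval: float = 6.0         # h
    n_doses: int = 1
    route: str = "oral_ir_tablet"
    prandial_state: str = "fasted"

    def __post_init__(self) -> None:
        if self.dose_amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.interval <= 0 or self.n_doses < 1:
            raise ValueError("interval must be positive and n_doses >= 1")
        if self.route not in ("oral_ir_tablet", "iv_bolus"):
            raise ValueError(f"unsupported route {self.route!r}")

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval

    @property
    def dose_ug(self) -> float:
        return self.dose_amount * 1000.0


@dataclass
class ConcProfile:
    """Simulated plasma profile plus the full state trajectory."""

    times: np.ndarray             # h
    plasma_conc: np.ndarray       # ug/L
    cumulative_absorbed: np.ndarray    # ug
    cumulative_eliminated: np.ndarray  # ug
    states: np.ndarray = field(repr=False, default=None)   # (n_states, n_times)
    state_names: tuple = ()
    dose_total: float = 0.0       # ug
    dose_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dose_per_admin: float = 0.0   # ug

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.asarray(self.plasma_conc) < -1e-9):
            raise ValueError("negative plasma concentrations beyond tolerance")
        for arr in (self.cumulative_absorbed, self.cumulative_eliminated):
            if np.any(np.diff(np.asarray(arr)) < -1e-6):
                raise ValueError("cumulative quantities must be non-decreasing")


def default_compound() -> Compound:
    d = defaults.compound_dict()
    return Compound(
        name=d["name"],
        molecular_weight=d["molecular_weight"],
        logp=d["logp"],
        pka_basic=d["pka_basic"],
        pka_acidic=d["pka_acidic"],
        solubility_mg_ml=d["solubility_mg_ml"],
        diffusion_coeff=d["diffusion_coeff_1e5_cm2_s"],
        blood_plasma_ratio=d["blood_plasma_ratio"],
        peff=d["peff_1e4_cm_s"],
        fraction_unbound=d["fraction_unbound"] if d["fraction_unbound"] <= 1 else d["fraction_unbound"] / 100.0,
        hepatic_clearance=d["hepatic_clearance_l_h"],
        renal_clearance=d["renal_clearance_l_h"],
    )


def default_kp_set() -> TissueKpSet:
    return TissueKpSet(kp=dict(defaults.tissue_kp_dict()))


# ---------------------------------------------------------------------------
# CAT absorption model
# ---------------------------------------------------------------------------

#: default gastrointestinal transit physiology (fasted)
CAT_DEFAULTS = {
    "gastric_emptying_per_h": 4.0,
    "si_transit_h": 3.32,          # total small-intestinal transit, 7 segments
    "colon_residence_h": 13.5,
    "si_radius_cm": 1.5,
    "colon_radius_cm": 2.5,
}

CAT_COMPARTMENTS = ("stomach",) + tuple(f"si{i}" for i in range(1, 8)) + ("colon",)


@dataclass(frozen=True)
class CATModel:
    """First-order transit/absorption rates of the 9 lumen compartments."""

    compartments: tuple
    transit_rates: np.ndarray     # 1/h, exit rate of each compartment
    absorption_rates: np.ndarray  # 1/h, absorption into the portal inlet

    def fraction_absorbed(self) -> float:
        """Analytic F_a of a dissolved dose under sequential first-order
        transit with competing segmental absorption."""
        escape = 1.0
        for kt, ka in zip(self.transit_rates, self.absorption_rates):
            escape *= kt / (kt + ka) if (kt + ka) > 0 else 1.0
        return 1.0 - escape


def cat_absorption_state(
    compound: Compound,
    regimen: DoseRegimen,
    config: dict | None = None,
    peff_scale: float = 1.0,
) -> CATModel:
    """Build the CAT gut sub-system for an oral regimen.

    ``k_a,i = 2 P_eff / R_i`` with the segment radius R_i (cm); transit rates
    are the reciprocal mean residence times of stomach, small-intestine
    segments and colon. ``peff_scale`` supports calibration of P_eff.
    """
    if regimen.route != "oral_ir_tablet":
        raise ValueError("CAT model applies to the oral route only")
    cfg = dict(CAT_DEFAULTS)
    if config:
        cfg.update(config)
    peff_cm_s = compound.peff * 1e-4 * peff_scale
    ka_si = 2.0 * peff_cm_s / cfg["si_radius_cm"] * 3600.0
    ka_colon = 2.0 * peff_cm_s / cfg["colon_radius_cm"] * 3600.0
    transit = np.array(
        [cfg["gastric_emptying_per_h"]]
        + [7.0 / cfg["si_transit_h"]] * 7
        + [1.0 / cfg["colon_residence_h"]]
    )
    absorption = np.array([0.0] + [ka_si] * 7 + [ka_colon])
    return CATModel(CAT_COMPARTMENTS, transit, absorption)


def calibrate_peff_scale(
    compound: Compound,
    target_fa: float = 0.852,
    config: dict | None = None,
) -> float:
    """Permeability scale factor making the CAT F_a hit ``target_fa``.

    Off by default in simulation; pass the result as ``peff_scale`` to
    :func:`simulate_pbpk` / :func:`cat_absorption_state` to pin the
    fraction absorbed to a reference value.
    """
    from scipy.optimize import brentq

    if not 0.0 < target_fa < 1.0:
        raise ValueError("target_fa must be in (0, 1)")
    regimen = DoseRegimen(1.0)

    def gap(scale):
        cat = cat_absorption_state(compound, regimen, config, peff_scale=scale)
        return cat.fraction_absorbed() - target_fa

    return float(brentq(gap, 1e-6, 1e3, xtol=1e-12))


# ---------------------------------------------------------------------------
# ODE system
# ---------------------------------------------------------------------------

_N_LUMEN = 9
_STATE_NAMES = (
    CAT_COMPARTMENTS
    + ("fecal",)
    + TISSUES
    + ("venous_blood", "arterial_blood", "eliminated_hepatic", "eliminated_renal", "absorbed")
)
_IDX = {name: i for i, name in enumerate(_STATE_NAMES)}


def _reference_liver_constants() -> tuple:
    """(liver total blood flow, liver volume) of the reference adult male."""
    ref = scale_physiology(reference_subject())
    return ref.liver_total_flow, ref.volumes["liver"]


def hepatic_intrinsic_clearance(
    compound: Compound, physiology: PhysiologySet
) -> float:
    """Intrinsic (blood) clearance at the liver outlet, well-stirred.

    Calibrated on the reference adult so that the linear-regime systemic
    plasma clearance equals ``compound.hepatic_clearance``; scaled to the
    subject by liver volume and the cirrhosis multiplier.
    """
    q_ref, v_liv_ref = _reference_liver_constants()
    cl_blood = compound.hepatic_clearance / compound.blood_plasma_ratio
    if cl_blood >= q_ref:
        raise ValueError("hepatic blood clearance exceeds reference liver blood flow")
    clint_ref = q_ref * cl_blood / (q_ref - cl_blood)
    return clint_ref * (physiology.volumes["liver"] / v_liv_ref) * physiology.hepatic_clint_multiplier


def simulate_pbpk(
    physiology: PhysiologySet,
    compound: Compound,
    kps: TissueKpSet,
    regimen: DoseRegimen,
    t_grid: np.ndarray,
    cat_config: dict | None = None,
    peff_scale: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcProfile:
    """Simulate the plasma concentration-time profile of one subject.

    ``regimen.route == 'iv_bolus'`` bypasses absorption and places each dose
    in the venous pool (used for clearance-identity checks).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    dose_times = regimen.dose_times
    if dose_times.max() > t_grid[-1]:
        raise ValueError("t_grid must cover all dose times")

    oral = regimen.route == "oral_ir_tablet"
    cat = cat_absorption_state(compound, regimen, cat_config, peff_scale) if oral else None

    rbp = compound.blood_plasma_ratio
    kp = np.array([kps[t] for t in TISSUES])
    vols = np.array([physiology.volumes[t] for t in TISSUES])
    v_ven = physiology.volumes["venous_blood"]
    v_art = physiology.volumes["arterial_blood"]
    flows = np.array([physiology.flows[t] for t in PARALLEL_TISSUES])
    q_lung = flows.sum()  # conservation: lung carries exactly the parallel sum
    clint = hepatic_intrinsic_clearance(compound, physiology)
    cl_renal_blood = compound.renal_clearance / rbp

    i_tis = {t: _IDX[t] for t in TISSUES}
    tis_idx = np.array([i_tis[t] for t in PARALLEL_TISSUES])
    par_flow = dict(zip(PARALLEL_TISSUES, flows))
    i_ven, i_art = _IDX["venous_blood"], _IDX["arterial_blood"]
    i_hep, i_ren, i_abs = _IDX["eliminated_hepatic"], _IDX["eliminated_renal"], _IDX["absorbed"]
    i_fec = _IDX["fecal"]
    kp_by_name = {t: kps[t] for t in TISSUES}
    out_coef = {t: rbp / kp_by_name[t] / physiology.volumes[t] for t in TISSUES}

    def rhs(t, y):
        dy = np.zeros_like(y)
        c_ven = y[i_ven] / v_ven
        c_art = y[i_art] / v_art

        r_abs = 0.0
        if oral:
            lumen = y[:_N_LUMEN]
            transit_out = cat.transit_rates * lumen
            absorbed_out = cat.absorption_rates * lumen
            dy[:_N_LUMEN] = -transit_out - absorbed_out
            dy[1:_N_LUMEN] += transit_out[:-1]
            dy[i_fec] = transit_out[-1]
            r_abs = absorbed_out.sum()
            dy[i_abs] = r_abs

        # lung (in series)
        c_lung_out = y[i_tis["lung"]] * out_coef["lung"]
        dy[i_tis["lung"]] = q_lung * (c_ven - c_lung_out)
        dy[i_art] = q_lung * c_lung_out - flows.sum() * c_art

        ven_in = 0.0
        for tname in PARALLEL_TISSUES:
            i = i_tis[tname]
            q = par_flow[tname]
            c_out = y[i] * out_coef[tname]
            if tname == "liver":
                inflow = q * c_art + par_flow["spleen"] * (y[i_tis["spleen"]] * out_coef["spleen"]) + r_abs
                q_out = q + par_flow["spleen"]
                elim = clint * c_out
                dy[i] = inflow - q_out * c_out - elim
                dy[i_hep] = elim
                ven_in += q_out * c_out
            elif tname == "spleen":
                dy[i] = q * (c_art - c_out)   # outflow routed to liver
            elif tname == "kidney":
                elim = cl_renal_blood * c_art
                dy[i] = q * (c_art - c_out) - elim
                dy[i_ren] = elim
                ven_in += q * c_out
            else:
                dy[i] = q * (c_art - c_out)
                ven_in += q * c_out
        dy[i_ven] = ven_in - q_lung * c_ven
        return dy

    n_states = len(_STATE_NAMES)
    y = np.zeros(n_states)
    times_out: list = []
    states_out: list = []

    # segment list: [t0, d1), [d1, d2), ..., [dn, t_end]
    t0 = min(t_grid[0], dose_times[0] if len(dose_times) else t_grid[0])
    boundaries = sorted(set([t0, t_grid[-1]] + [float(td) for td in dose_times]))
    dose_set = {float(td) for td in dose_times}
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if a in dose_set and regimen.dose_ug > 0:
            if oral:
                y[0] += regimen.dose_ug
            else:
                y[i_ven] += regimen.dose_ug
        t_eval = t_grid[(t_grid >= a) & (t_grid <= b)]
        if len(t_eval) == 0 or t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"PBPK integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1].copy()
        last = b == boundaries[-1]
        keep = np.isin(sol.t, t_grid) & (np.ones_like(sol.t, bool) if last else sol.t < b)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])
    states = np.concatenate(states_out, axis=1)
    times = np.concatenate(times_out)
    # deduplicate (segment boundaries can repeat) and align on the grid
    _, first = np.unique(times, return_index=True)
    times, states = times[first], states[:, first]
    sel = np.isin(times, t_grid)
    times, states = times[sel], states[:, sel]

    if np.any(states[len(CAT_COMPARTMENTS) : i_abs, :] < -1e-9 * max(regimen.dose_ug, 1.0)):
        raise RuntimeError("negative state beyond tolerance in PBPK solution")
    if not np.all(np.isfinite(states)):
        raise RuntimeError("non-finite state in PBPK solution")

    plasma = states[i_ven, :] / v_ven / rbp  # ug/L plasma
    plasma = np.clip(plasma, 0.0, None)
    eliminated = states[i_hep, :] + states[i_ren, :]
    absorbed = states[i_abs, :] if oral else eliminated * 0.0
    return ConcProfile(
        times=times,
        plasma_conc=plasma,
        cumulative_absorbed=np.maximum.accumulate(np.clip(absorbed, 0, None)),
        cumulative_eliminated=np.maximum.accumulate(np.clip(eliminated, 0, None)),
        states=states,
        state_names=_STATE_NAMES,
        dose_total=regimen.dose_ug * regimen.n_doses,
        dose_times=dose_times.astype(float),
        dose_per_admin=regimen.dose_ug,
    )


def mass_balance(profile: ConcProfile) -> float:
    """Worst-case relative mass-balance residual over the trajectory.

    At any output time, drug in all compartments (lumen + fecal + tissues +
    blood) plus eliminated amounts must equal the dose administered so far.
    """
    if profile.states is None:
        raise ValueError("profile carries no state trajectory")
    if profile.dose_total <= 0:
        return 0.0
    names = profile.state_names
    bal_idx = [i for i, n in enumerate(names) if n != "absorbed"]
    total = profile.states[bal_idx, :].sum(axis=0)
    # dose administered by each output time (a dose at exactly t counts)
    dosed = np.array(
        [profile.dose_per_admin * np.sum(profile.dose_times <= t + 1e-12) for t in profile.times]
    )
    residual = np.abs(total - dosed) / profile.dose_total
    return float(residual.max())


def sample_observations(
    profile: ConcProfile,
    schedule: np.ndarray,
    lloq: float = 0.0,
    noise: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Interpolate the profile at scheduled times (optionally with noise).

    ``noise=(a, b)`` adds combined residual noise ``sqrt(a^2 + b^2 c^2) * z``
    in profile units. Values below ``lloq`` are flagged, not dropped.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.min() < profile.times[0] - 1e-12 or schedule.max() > profile.times[-1] + 1e-12:
        raise ValueError("sampling schedule outside the simulated time span")
    conc = np.interp(schedule, profile.times, profile.plasma_conc)
    if noise is not None:
        a, b = noise
        if rng is None:
            rng = np.random.default_rng()
        sd = np.sqrt(a**2 + (b * conc) ** 2)
        conc = conc + sd * rng.standard_normal(len(conc))
    return pd.DataFrame(
        {"time": schedule, "conc": conc, "below_lloq": conc < lloq}
    )
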