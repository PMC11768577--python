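"""Virtual-population generation and per-subject physiology scaling.

A cohort is sampled from a :class:`CohortSpec` (groups defined by race and
health status, BMI-class mixes, an age range, and a seed). Each
:class:`VirtualSubject` carries demographics, anthropometrics and opaque CYP
expression covariates; :func:`scale_physiology` maps a subject onto a
whole-body :class:`PhysiologySet` (organ volumes and regional blood flows)
by allometric scaling of packaged reference-adult tables.

Heights come from piecewise-linear age-height reference curves per gender
with race offsets; weight is BMI x height^2 with the BMI class drawn from
the group's class mix; BSA uses the Du Bois-Du Bois formula. Ages follow a
truncated normal within the spec's range. Randomness is fully reproducible:
each subject draws from an independent substream keyed by (seed, index), so
cohorts are extensible without reshuffling earlier subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults

__all__ = [
    "VirtualSubject",
    "GroupSpec",
    "CohortSpec",
    "PhysiologySet",
    "derive_bsa",
    "reference_height",
    "sample_cohort",
    "cohort_table",
    "scale_physiology",
    "reference_subject",
    "default_cohort_spec",
]

GENDERS = ("male", "female")
RACES = ("american", "asian", "chinese")
HEALTH_STATUSES = ("healthy", "obese", "cirrhosis_a")
BMI_CLASSES = ("normal", "overweight", "obese")

# adult BMI class ranges (kg/m^2); the obese class is capped for sampling
_BMI_RANGES = {"normal": (18.5, 24.9), "overweight": (25.0, 29.9), "obese": (30.0, 40.0)}

TISSUES = (
    "lung",
    "adipose",
    "muscle",
    "liver",
    "spleen",
    "heart",
    "brain",
    "kidney",
    "skin",
    "reproductive",
    "red_marrow",
    "yellow_marrow",
    "rest_of_body",
)
#: tissues perfused in parallel from the arterial pool (lung is in series)
PARALLEL_TISSUES = tuple(t for t in TISSUES if t != "lung")


def derive_bsa(weight: float, height: float) -> float:
    """Body surface area (m^2) from weight (kg) and height (cm), Du Bois."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


@dataclass(frozen=True)
class VirtualSubject:
    """One synthetic patient."""

    id: int
    age: float          # years
    gender: str
    race: str
    health_status: str
    weight: float       # kg
    height: float       # cm
    bsa: float          # m^2
    bmi: float          # kg/m^2
    cyp2d6_expr: float  # percent (opaque covariate)
    cyp2c19_expr: float

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError("id must be a positive integer")
        if not (5.0 <= self.age <= 65.0):
            raise ValueError(f"age {self.age} outside the supported 5-65 y range")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}")
        if self.health_status not in HEALTH_STATUSES:
            raise ValueError(f"unknown health status {self.health_status!r}")
        if self.weight <= 0 or self.height <= 0 or self.bsa <= 0:
            raise ValueError("weight, height and bsa must be positive")
        implied = self.weight / (self.height / 100.0) ** 2
        if abs(implied - self.bmi) > 1e-9:
            raise ValueError("bmi inconsistent with weight/height")
        if self.health_status == "obese" and self.bmi < 30.0:
            raise ValueError("obese health status requires BMI >= 30")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a race/health-status cell with its own mixes."""

    name: str
    race: str
    health_status: str
    n: int
    male_fraction: float = 0.5
    bmi_class_mix: dict = field(
        default_factory=lambda: {"normal": 0.7, "overweight": 0.2, "obese": 0.1}
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}")
        if self.health_status not in ("healthy", "cirrhosis_a"):
            raise ValueError("group health status must be healthy or cirrhosis_a")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        total = sum(self.bmi_class_mix.get(c, 0.0) for c in BMI_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("bmi_class_mix proportions must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple
    age_range: tuple = (5.0, 65.0)
    age_mean: float = 40.0
    age_sd: float = 18.0
    seed: int = 0
    cyp2d6: tuple = (1.90, 1.60)   # (mean, sd) of the lognormal covariate
    cyp2c19: tuple = (1.30, 1.50)

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("cohort spec needs at least one group")
        lo, hi = self.age_range
        if lo < 5.0 or hi > 65.0 or lo >= hi:
            raise ValueError("age range must be within [5, 65] and non-empty")

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


@dataclass
class PhysiologySet:
    """Per-subject organ volumes (L), regional blood flows (L/h) and scalars."""

    volumes: dict                 # tissue -> L, plus venous_blood/arterial_blood
    flows: dict                   # parallel tissue -> L/h (liver entry = arterial)
    cardiac_output: float         # L/h (nominal; lung flow = sum of tissue flows)
    hepatic_clint_multiplier: float = 1.0
    weight: float = float("nan")
    bsa: float = float("nan")

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("all volumes must be positive")
        if any(q <= 0 for q in self.flows.values()):
            raise ValueError("all flows must be positive")
        total = sum(self.flows.values())
        if total > self.cardiac_output * (1 + 1e-6):
            raise ValueError("tissue flows exceed cardiac output")

    @property
    def total_parallel_flow(self) -> float:
        return sum(self.flows.values())

    @property
    def liver_total_flow(self) -> float:
        """Total hepatic inflow: arterial component plus splenic (portal)."""
        return self.flows["liver"] + self.flows["spleen"]


def default_cohort_spec(seed: int | None = None) -> CohortSpec:
    """The packaged 40-subject study cohort specification."""
    d = defaults.cohort_spec_dict()
    groups = tuple(
        GroupSpec(
            name=g["name"],
            race=g["race"],
            health_status=g["health_status"],
            n=int(g["n"]),
            male_fraction=float(g["male_fraction"]),
            bmi_class_mix=dict(g["bmi_class_mix"]),
        )
        for g in d["groups"]
    )
    return CohortSpec(
        groups=groups,
        age_range=tuple(float(x) for x in d["age_range"]),
        age_mean=float(d["age_mean"]),
        age_sd=float(d["age_sd"]),
        seed=int(seed if seed is not None else d["seed"]),
        cyp2d6=(float(d["cyp2d6"]["mean"]), float(d["cyp2d6"]["sd"])),
        cyp2c19=(float(d["cyp2c19"]["mean"]), float(d["cyp2c19"]["sd"])),
    )


def reference_height(age: float, gender: str, race: str) -> float:
    """Reference height (cm) from the piecewise-linear age curves."""
    hm = defaults.physiology_dict()["height_model"]
    knots = np.asarray(hm["age_knots"], dtype=float)
    curve = np.asarray(hm["male_cm" if gender == "male" else "female_cm"], dtype=float)
    base = float(np.interp(age, knots, curve))
    return base + float(hm["race_offset_cm"][race])


def _largest_remainder_counts(n: int, mix: dict) -> dict:
    """Integer class counts matching ``mix`` proportions by largest remainder."""
    raw = {c: n * mix.get(c, 0.0) for c in BMI_CLASSES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(BMI_CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def _lognormal_params(mean: float, sd: float) -> tuple:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_cohort(spec: CohortSpec) -> list:
    """Sample the virtual population defined by ``spec``.

    Group sizes, gender counts (``round(n * male_fraction)`` males first) and
    BMI-class counts are deterministic; ages, heights, within-class BMI and
    CYP expressions are drawn from per-subject substreams seeded by
    ``(spec.seed, subject_index)``.
    """
    lo, hi = spec.age_range
    mu_d6, sg_d6 = _lognormal_params(*spec.cyp2d6)
    mu_c19, sg_c19 = _lognormal_params(*spec.cyp2c19)
    hm = defaults.physiology_dict()["height_model"]
    height_sd = float(hm["individual_sd_cm"])

    subjects = []
    idx = 0
    for group in spec.groups:
        n_male = int(round(group.n * group.male_fraction))
        class_counts = _largest_remainder_counts(group.n, group.bmi_class_mix)
        classes = [c for c in BMI_CLASSES for _ in range(class_counts[c])]
        for j in range(group.n):
            idx += 1
            rng = np.random.default_rng([int(spec.seed), idx])
            gender = "male" if j < n_male else "female"
            bmi_class = classes[j]
            # truncated-normal age via rejection (cheap at these widths)
            while True:
                age = spec.age_mean + spec.age_sd * rng.standard_normal()
                if lo <= age <= hi:
                    break
            height = reference_height(age, gender, group.race) + height_sd * rng.standard_normal()
            height = max(height, 80.0)
            b_lo, b_hi = _BMI_RANGES[bmi_class]
            bmi = rng.uniform(b_lo, b_hi)
            weight = bmi * (height / 100.0) ** 2
            bmi = weight / (height / 100.0) ** 2  # exact identity after rounding
            if group.health_status == "cirrhosis_a":
                health = "cirrhosis_a"
            else:
                health = "obese" if bmi >= 30.0 else "healthy"
            subjects.append(
                VirtualSubject(
                    id=idx,
                    age=float(age),
                    gender=gender,
                    race=group.race,
                    health_status=health,
                    weight=float(weight),
                    height=float(height),
                    bsa=derive_bsa(weight, height),
                    bmi=float(bmi),
                    cyp2d6_expr=float(np.exp(mu_d6 + sg_d6 * rng.standard_normal())),
                    cyp2c19_expr=float(np.exp(mu_c19 + sg_c19 * rng.standard_normal())),
                )
            )
    return subjects


def cohort_table(subjects: list) -> pd.DataFrame:
    """Cohort as a DataFrame, one row per subject (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "age": s.age,
                "gender": s.gender,
                "race": s.race,
                "health_status": s.health_status,
                "weight": s.weight,
                "height": s.height,
                "bsa": s.bsa,
                "bmi": s.bmi,
                "cyp2d6_expr": s.cyp2d6_expr,
                "cyp2c19_expr": s.cyp2c19_expr,
            }
            for s in subjects
        ]
    )


def reference_subject() -> VirtualSubject:
    """The healthy 30-year-old American reference male (73 kg, 176 cm)."""
    ref = defaults.physiology_dict()["reference"]["male"]
    w, h = float(ref["weight_kg"]), float(ref["height_cm"])
    return VirtualSubject(
        id=1,
        age=30.0,
        gender="male",
        race="american",
        health_status="healthy",
        weight=w,
        height=h,
        bsa=derive_bsa(w, h),
        bmi=w / (h / 100.0) ** 2,
        cyp2d6_expr=1.9,
        cyp2c19_expr=1.3,
    )


def scale_physiology(subject: VirtualSubject, config: dict | None = None) -> PhysiologySet:
    """Scale reference organ fractions to one subject.

    Volumes are proportional to body weight (density 1 kg/L); flows are
    proportional to cardiac output, which scales linearly with BSA. Obese
    subjects get an enlarged adipose fraction at the expense of muscle and
    rest-of-body; Child-Pugh A cirrhosis reduces hepatic arterial flow and
    hepatic intrinsic clearance by configurable multipliers.
    """
    phys = defaults.physiology_dict()
    if config:
        phys = {**phys, **config}
    vfrac = dict(phys["volume_fractions"][subject.gender])
    if subject.health_status == "obese":
        mult = float(phys["obese"]["adipose_fraction_multiplier"])
        extra = (mult - 1.0) * vfrac["adipose"]
        vfrac["adipose"] *= mult
        donors = vfrac["muscle"] + vfrac["rest_of_body"]
        vfrac["muscle"] -= extra * vfrac["muscle"] / donors
        vfrac["rest_of_body"] -= extra * vfrac["rest_of_body"] / donors
    volumes = {k: f * subject.weight for k, f in vfrac.items()}

    co = float(phys["cardiac_output_l_h"]) * subject.bsa / float(phys["cardiac_output_ref_bsa_m2"])
    ffrac = phys["flow_fractions"]
    flows = {}
    for tissue in PARALLEL_TISSUES:
        key = "liver_arterial" if tissue == "liver" else tissue
        flows[tissue] = float(ffrac[key]) * co
    clint_mult = 1.0
    if subject.health_status == "cirrhosis_a":
        flows["liver"] *= float(phys["cirrhosis_a"]["hepatic_flow_multiplier"])
        clint_mult = float(phys["cirrhosis_a"]["hepatic_clint_multiplier"])

    return PhysiologySet(
        volumes=volumes,
        flows=flows,
        cardiac_output=co,
        hepatic_clint_multiplier=clint_mult,
        weight=subject.weight,
        bsa=subject.bsa,
    )
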