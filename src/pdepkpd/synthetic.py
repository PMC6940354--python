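"""Synthetic study-data generator.

Emulates the designs of the animal and plate experiments the models are
meant for — sampling schedules, group sizes, dosing, proportional
(log-normal) residual error and lower-limit-of-quantification censoring —
so that every stage of the pipeline (preprocessing, simulation, fitting)
can be exercised end-to-end without any external data.

Scenarios and their defaults:

``pk_lewis`` / ``pk_wistar``
    Single-dose plasma PK in female Lewis / male Wistar rats, n=4 per arm,
    study sampling times, 10% proportional CV, drug LOQs 0.050 mg/L
    (GRMS-55, lisofylline) and 0.020 mg/L (rolipram).
``endotoxemia``
    Plasma TNF-alpha after an IV LPS challenge with a simultaneous IV drug
    bolus, n=4 per group, samples at 0-180 min (the GRMS-55/rolipram
    experiments start at 30 min), 15% CV, ELISA LOQ 12.5 ng/L.
``cia``
    Collagen-induced arthritis paw calipering at days 0-36, n=6 per arm,
    once-daily treatment days 20-39, 10% CV on the relative swelling.  Raw
    per-section diameters are emitted (around a nominal paw 10x8 mm /
    ankle 12x9 mm geometry) so the preprocessing path is exercised; only
    area ratios matter downstream.
``plate_assay`` / ``tnf_blood``
    Quadruplicate wells over an 8-point 3-fold dilution series, 5% CV,
    vehicle controls at 100%.

All generators are deterministic under a fixed seed.  Proportional error
is multiplicative log-normal with sigma^2 = ln(1 + CV^2), so the empirical
coefficient of variation equals the requested CV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import published
from .cia import CIAParameters, simulate_cia
from .endotoxemia import EndotoxemiaParameters, simulate_tnf
from .pd_invitro import HillParameters, hill_effect
from .pk_models import (
    ConcentrationSeries,
    DoseRegimen,
    concentration_profile,
    simulate_pk,
)

__all__ = [
    "Arm",
    "StudyDesign",
    "default_design",
    "generate_pk",
    "generate_endotoxemia",
    "generate_cia",
    "generate_plate",
    "to_series",
    "PK_SCHEMA",
    "TNF_SCHEMA",
    "PAW_SCHEMA",
    "PLATE_SCHEMA",
]

PK_SCHEMA = ["subject_id", "analyte", "route", "dose_mg_per_kg",
             "time_min", "conc", "loq", "censored"]
TNF_SCHEMA = PK_SCHEMA
PAW_SCHEMA = ["animal_id", "day", "section", "a_mm", "b_mm"]
PLATE_SCHEMA = ["compound", "conc_uM", "replicate", "reading",
                "is_control", "is_blank"]

# nominal healthy paw geometry (mm); absolute scale cancels in the
# relative-swelling preprocessing
BASE_PAW = (10.0, 8.0)
BASE_ANKLE = (12.0, 9.0)

SCENARIOS = ("pk_lewis", "pk_wistar", "endotoxemia", "cia",
             "plate_assay", "tnf_blood")


@dataclass(frozen=True)
class Arm:
    """One study arm: a compound (or 'vehicle'), its dose regimen and size."""

    compound: str
    dose: float | None = None
    route: str | None = None
    n: int = 4

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("arm size must be at least 1")


@dataclass(frozen=True)
class StudyDesign:
    """Scenario, arms, sampling schedule and noise/censoring model."""

    scenario: str
    arms: tuple[Arm, ...]
    schedule: Mapping[str, tuple] | tuple
    cv: float
    loq: Mapping[str, float] | float | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.cv < 0:
            raise ValueError("CV must be non-negative")


def default_design(scenario: str) -> StudyDesign:
    """The study design of the named scenario with its default schedule."""
    if scenario == "pk_lewis":
        arms = tuple(
            Arm(c, dose=r.dose, route=r.route.value, n=4)
            for c, regs in published.PK_DOSES_LEWIS.items()
            for r in regs
        )
        return StudyDesign(scenario, arms, published.PK_SCHEDULE_LEWIS,
                           cv=0.10, loq=published.LOQ_MG_L)
    if scenario == "pk_wistar":
        arms = tuple(
            Arm(c, dose=r.dose, route=r.route.value, n=4)
            for c, regs in published.PK_DOSES_WISTAR.items()
            for r in regs
        )
        return StudyDesign(scenario, arms, published.PK_SCHEDULE_WISTAR,
                           cv=0.10, loq=published.LOQ_MG_L)
    if scenario == "endotoxemia":
        arms = (
            Arm("vehicle", n=4),
            Arm("GRMS-55", dose=20.0, route="IV", n=4),
            Arm("rolipram", dose=5.0, route="IV", n=4),
            Arm("LSF", dose=80.0, route="IV", n=4),
            Arm("PTX", dose=80.0, route="IV", n=4),
        )
        return StudyDesign(scenario, arms, published.ENDOTOXEMIA_SCHEDULE,
                           cv=0.15, loq=published.LOQ_TNF_NG_L)
    if scenario == "cia":
        arms = (
            Arm("vehicle", n=6),
            Arm("GRMS-55", dose=50.0, route="IP", n=6),
        )
        return StudyDesign(scenario, arms, published.CIA_MEASUREMENT_DAYS,
                           cv=0.10, loq=None)
    if scenario in ("plate_assay", "tnf_blood"):
        series = tuple(100.0 / 3.0 ** k for k in range(8))  # 3-fold dilution
        return StudyDesign(scenario, (Arm("compound", n=4),), series,
                           cv=0.05, loq=None)
    raise ValueError(f"unknown scenario {scenario!r}")


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def _loq_for(design: StudyDesign, analyte: str) -> float | None:
    if design.loq is None:
        return None
    if isinstance(design.loq, Mapping):
        return design.loq.get(analyte)
    return float(design.loq)


def _censor(conc: np.ndarray, loq: float | None):
    if loq is None:
        return conc, np.zeros(conc.shape, dtype=bool)
    censored = conc < loq
    return np.where(censored, np.nan, conc), censored


# ---------------------------------------------------------------------------
# Plasma pharmacokinetics
# ---------------------------------------------------------------------------

def generate_pk(
    design: StudyDesign | None = None,
    truths: Mapping[str, tuple[str, object]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject concentration tables for a single-dose PK study.

    ``truths`` maps compound to (model variant, parameters); defaults to
    the published estimates of the scenario's rat strain.
    """
    design = design or default_design("pk_lewis")
    if truths is None:
        truths = (published.PK_WISTAR if design.scenario == "pk_wistar"
                  else published.PK_LEWIS)
    rng = np.random.default_rng(seed)
    rows = []
    for arm in design.arms:
        variant, params = truths[arm.compound]
        regimen = DoseRegimen(arm.route, arm.dose)
        schedule = np.asarray(design.schedule[arm.compound], dtype=float)
        sim = simulate_pk(variant, params, regimen, schedule)
        for analyte, series in sim.items():
            label = arm.compound if analyte == "parent" else "PTX"
            loq = _loq_for(design, label)
            for subject in range(arm.n):
                noisy = series.conc * _noise_factors(rng, design.cv, len(schedule))
                conc, censored = _censor(noisy, loq)
                for t, c, flag in zip(schedule, conc, censored):
                    rows.append({
                        "subject_id": f"{arm.compound}_{arm.route}{arm.dose:g}_{subject+1}",
                        "analyte": label, "route": arm.route,
                        "dose_mg_per_kg": arm.dose, "time_min": t,
                        "conc": c, "loq": loq, "censored": int(flag),
                    })
    return pd.DataFrame(rows, columns=PK_SCHEMA)


# ---------------------------------------------------------------------------
# LPS endotoxemia TNF-alpha
# ---------------------------------------------------------------------------

def _endotoxemia_experiment(compound: str) -> str:
    return "LSF_PTX" if compound in ("LSF", "PTX", "vehicle") else compound


def endotoxemia_conc_fns(compound: str, dose: float):
    """Drug plasma-concentration functions for one endotoxemia arm."""
    if compound == "vehicle":
        return {}
    variant, params = published.PK_WISTAR[
        "LSF" if compound in ("LSF", "PTX") else compound
    ]
    regimen = DoseRegimen("IV", dose)
    dose_into = "metabolite" if compound == "PTX" else None
    fns = concentration_profile(variant, params, regimen, horizon=360.0,
                                dose_into=dose_into)
    if compound in ("LSF", "PTX"):
        return {"LSF": fns["parent"], "PTX": fns["metabolite"]}
    return {compound: fns["parent"]}


def generate_endotoxemia(
    design: StudyDesign | None = None,
    pd_params: Mapping[str, EndotoxemiaParameters] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject plasma TNF-alpha tables for the endotoxemia study."""
    design = design or default_design("endotoxemia")
    pd_params = pd_params or published.ENDOTOXEMIA
    rng = np.random.default_rng(seed)
    rows = []
    loq = _loq_for(design, "TNFa") or (
        float(design.loq) if np.isscalar(design.loq) else None
    )
    for arm in design.arms:
        experiment = _endotoxemia_experiment(arm.compound)
        params = pd_params[experiment]
        schedule = np.asarray(design.schedule[experiment], dtype=float)
        fns = endotoxemia_conc_fns(arm.compound, arm.dose or 0.0)
        series = simulate_tnf(fns, params, schedule)
        for subject in range(arm.n):
            noisy = series.conc * _noise_factors(rng, design.cv, len(schedule))
            conc, censored = _censor(noisy, loq)
            for t, c, flag in zip(schedule, conc, censored):
                rows.append({
                    "subject_id": f"{arm.compound}_{subject+1}",
                    "analyte": "TNFa", "route": arm.route or "",
                    "dose_mg_per_kg": arm.dose, "time_min": t,
                    "conc": c, "loq": loq, "censored": int(flag),
                })
    return pd.DataFrame(rows, columns=TNF_SCHEMA)


# ---------------------------------------------------------------------------
# Collagen-induced arthritis paw measurements
# ---------------------------------------------------------------------------

def cia_conc_fn(compound: str):
    """Repeated-dose parent concentration function (minutes) for a CIA arm."""
    variant, params = published.PK_LEWIS[compound]
    regimen = published.cia_regimen(compound)
    fns = concentration_profile(variant, params, regimen)
    return fns["parent"]


def generate_cia(
    design: StudyDesign | None = None,
    params_by_arm: Mapping[str, CIAParameters] | None = None,
    seed: int = 0,
    animal_cv: float = 0.0,
) -> pd.DataFrame:
    """Raw paw/ankle caliper tables for a CIA study.

    True relative-swelling trajectories are simulated per arm, inverted to
    per-section diameters around the nominal geometry (both sections scaled
    by sqrt of the relative area) and perturbed with proportional
    measurement noise; day-0 rows are the exact baseline so the derived
    relative swelling is 1 by construction.  ``animal_cv`` adds optional
    log-normal inter-animal variability on kin0 and tonset.

    Requires a vehicle control arm.
    """
    design = design or default_design("cia")
    if not any(a.compound == "vehicle" for a in design.arms):
        raise ValueError("a vehicle control arm is required")
    params_by_arm = dict(params_by_arm or {})
    treated = [a.compound for a in design.arms if a.compound != "vehicle"]
    for c in treated:
        params_by_arm.setdefault(c, published.CIA[c])
    if "vehicle" not in params_by_arm:
        base = params_by_arm[treated[0]] if treated else published.CIA["GRMS-55"]
        params_by_arm["vehicle"] = dataclasses.replace(base, ic50=None)

    rng = np.random.default_rng(seed)
    days = np.asarray(design.schedule, dtype=float)
    dose_days = tuple(range(published.CIA_FIRST_DOSE_DAY,
                            published.CIA_LAST_DOSE_DAY + 1))
    rows = []
    for arm in design.arms:
        params = params_by_arm[arm.compound]
        conc = None if arm.compound == "vehicle" else cia_conc_fn(arm.compound)
        for subject in range(arm.n):
            p = params
            if animal_cv > 0:
                p = dataclasses.replace(
                    params,
                    kin0=params.kin0 * float(_noise_factors(rng, animal_cv, ())),
                    tonset=params.tonset * float(_noise_factors(rng, animal_cv, ())),
                )
            rel = simulate_cia(p, days, conc_fn=conc, dose_days=dose_days)
            noisy = rel * _noise_factors(rng, design.cv, len(days))
            noisy[days == 0] = 1.0  # day 0 defines the reference area
            size = float(_noise_factors(rng, 0.05, ()))  # animal paw size
            scale = np.sqrt(np.maximum(noisy, 1e-9)) * np.sqrt(size)
            animal = f"{arm.compound}_{subject+1}"
            for d, s in zip(days, scale):
                rows.append({"animal_id": animal, "arm": arm.compound,
                             "day": d, "section": "paw",
                             "a_mm": BASE_PAW[0] * s, "b_mm": BASE_PAW[1] * s})
                rows.append({"animal_id": animal, "arm": arm.compound,
                             "day": d, "section": "ankle",
                             "a_mm": BASE_ANKLE[0] * s, "b_mm": BASE_ANKLE[1] * s})
    return pd.DataFrame(rows, columns=PAW_SCHEMA + ["arm"])


def relative_paw_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Derive relative swelling per animal/day from a raw caliper table."""
    area = measurements.assign(
        area=np.pi * measurements["a_mm"] * measurements["b_mm"] / 4.0
    )
    overall = area.groupby(["animal_id", "day"], sort=True)["area"].sum().reset_index()
    out = []
    for animal, grp in overall.groupby("animal_id", sort=True):
        base = grp.loc[grp["day"] == grp["day"].min(), "area"].iloc[0]
        out.append(pd.DataFrame({
            "animal_id": animal, "day": grp["day"],
            "rel_paw": grp["area"] / base,
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Plate assays
# ---------------------------------------------------------------------------

def generate_plate(
    design: StudyDesign | None = None,
    hill: HillParameters | None = None,
    compound: str = "compound",
    seed: int = 0,
) -> pd.DataFrame:
    """Quadruplicate plate readings from a sigmoid inhibition truth."""
    design = design or default_design("plate_assay")
    hill = hill or published.PDE_HILL["GRMS-55"]["PDE7A"]
    n_rep = design.arms[0].n
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_rep):  # vehicle control wells at 100%
        rows.append({"compound": compound, "conc_uM": 0.0, "replicate": rep + 1,
                     "reading": 100.0 * float(_noise_factors(rng, design.cv, ())),
                     "is_control": 1, "is_blank": 0})
    for conc in design.schedule:
        true_effect = hill_effect(conc, hill)
        for rep in range(n_rep):
            rows.append({
                "compound": compound, "conc_uM": float(conc),
                "replicate": rep + 1,
                "reading": true_effect * float(_noise_factors(rng, design.cv, ())),
                "is_control": 0, "is_blank": 0,
            })
    return pd.DataFrame(rows, columns=PLATE_SCHEMA)


# ---------------------------------------------------------------------------
# Table <-> series plumbing
# ---------------------------------------------------------------------------

def to_series(frame: pd.DataFrame, subject_id: str, analyte: str) -> ConcentrationSeries:
    """Extract one subject/analyte as a :class:`ConcentrationSeries`."""
    sel = frame[(frame["subject_id"] == subject_id) & (frame["analyte"] == analyte)]
    sel = sel.sort_values("time_min")
    if sel.empty:
        raise KeyError(f"no rows for subject {subject_id!r}, analyte {analyte!r}")
    loq = sel["loq"].iloc[0]
    return ConcentrationSeries(
        analyte=analyte,
        times=sel["time_min"].to_numpy(float),
        conc=sel["conc"].to_numpy(float),
        loq=None if pd.isna(loq) else float(loq),
        censored=sel["censored"].to_numpy().astype(bool),
    )
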