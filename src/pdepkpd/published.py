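"""Reference parameter values for the studied PDE inhibitors.

These are the estimates reported for GRMS-55 (a 1,3-dimethylpurine-2,6-dione
PDE7A/PDE1B inhibitor), racemic lisofylline ((+/-)-LSF), its metabolite
pentoxifylline (PTX) and the reference PDE4 inhibitor rolipram, in female
Lewis and male Wistar rats.  They serve as defaults for the simulators and
as the generating truths for the synthetic-data module.

Units: volumes L/kg, clearances L/min/kg, doses mg/kg, rate constants 1/min
(PK, endotoxemia) or 1/day (arthritis), concentrations mg/L for drugs and
ng/L (= pg/mL) for TNF-alpha, in-vitro potencies uM.
"""

from __future__ import annotations

from .pk_models import (
    DoseRegimen,
    LSFInterconversionParams,
    LSFWistarParams,
    OneCompartmentParams,
    TwoCompartmentParams,
)
from .pd_invitro import HillParameters
from .endotoxemia import DrugInhibition, EndotoxemiaParameters
from .cia import CIAParameters

MINUTES_PER_DAY = 1440.0

# Lower limits of quantification (assay calibration floors)
LOQ_MG_L = {
    "GRMS-55": 0.050,
    "rolipram": 0.020,
    "LSF": 0.050,   # parent drug; metabolite assayed by the same method
    "PTX": 0.050,
}
LOQ_TNF_NG_L = 12.5  # ELISA floor, pg/mL == ng/L

# Basal plasma TNF-alpha in healthy male Wistar rats, ng/L
TNF_BASELINE = 12.7

# ---------------------------------------------------------------------------
# Pharmacokinetics (female Lewis rats)
# ---------------------------------------------------------------------------
# Rolipram parameters are apparent (V/F, Cl_t/F); the fractions absorbed of
# GRMS-55 (IP) and (+/-)-LSF (SC) were 23% and 95%.

PK_LEWIS: dict[str, tuple[str, object]] = {
    "GRMS-55": (
        "two_compartment",
        TwoCompartmentParams(V1=1.60, V2=2.14, Cl_t=0.053, Cl_d=0.080,
                             ka=0.045, F=0.23),
    ),
    "rolipram": (
        "one_compartment",
        OneCompartmentParams(V=1.02, Cl_t=0.023, ka=0.228),
    ),
    "LSF": (
        "lsf_interconversion",
        LSFInterconversionParams(V_LSF=0.37, V_PTXm_over_fm=1.95, ka_LSF=0.032,
                                 kd=0.212, kem=0.039, kconv=0.054, F_LSF=0.95),
    ),
}

# ---------------------------------------------------------------------------
# Pharmacokinetics (male Wistar rats)
# ---------------------------------------------------------------------------

PK_WISTAR: dict[str, tuple[str, object]] = {
    "GRMS-55": ("one_compartment", OneCompartmentParams(V=1.59, Cl_t=0.051)),
    "rolipram": (
        "two_compartment",
        TwoCompartmentParams(V1=0.58, V2=0.28, Cl_t=0.037, Cl_d=0.021),
    ),
    "LSF": (
        "lsf_michaelis_menten",
        LSFWistarParams(V_LSF=1.22, V_PTXm=2.01, Vmax=0.433, Km=6.02,
                        km12=0.203, km21=0.095, kem=0.116),
    ),
}

# Sampling schedules, minutes after dosing
PK_SCHEDULE_LEWIS = {
    "GRMS-55": (5, 15, 30, 60, 90, 120),
    "LSF": (5, 15, 30, 60, 90, 120),
    "rolipram": (10, 20, 40, 80, 120, 160, 220),
}
PK_SCHEDULE_WISTAR = {
    "GRMS-55": (5, 15, 30, 60, 90, 120),
    "rolipram": (10, 20, 40, 80, 120),
}

PK_DOSES_LEWIS = {
    "GRMS-55": (DoseRegimen("IV", 20.0), DoseRegimen("IP", 40.0)),
    "LSF": (DoseRegimen("IV", 40.0), DoseRegimen("SC", 80.0)),
    "rolipram": (DoseRegimen("IP", 10.0),),
}
PK_DOSES_WISTAR = {
    "GRMS-55": (DoseRegimen("IV", 20.0),),
    "rolipram": (DoseRegimen("IV", 5.0),),
}

# ---------------------------------------------------------------------------
# LPS endotoxemia (male Wistar rats): turnover + 4 transit compartments
# ---------------------------------------------------------------------------
# One parameter set per experiment; the LSF/PTX experiment fitted a
# two-inhibitor interaction term.

ENDOTOXEMIA: dict[str, EndotoxemiaParameters] = {
    "GRMS-55": EndotoxemiaParameters(
        kin=0.809, kout=0.059, tlag=57.1, tau=8.0,
        inhibition={"GRMS-55": DrugInhibition(ic50=1.06)},
    ),
    "rolipram": EndotoxemiaParameters(
        kin=1.83, kout=0.031, tlag=48.6, tau=12.0,
        inhibition={"rolipram": DrugInhibition(ic50=0.36)},
    ),
    "LSF_PTX": EndotoxemiaParameters(
        kin=0.827, kout=0.034, tlag=60.0, tau=7.3,
        inhibition={"LSF": DrugInhibition(ic50=5.80),
                    "PTX": DrugInhibition(ic50=14.00)},
    ),
}

ENDOTOXEMIA_DOSES = {  # IV bolus at t=0, simultaneous with LPS
    "GRMS-55": 20.0,
    "rolipram": 5.0,
    "LSF": (40.0, 80.0),
    "PTX": (40.0, 80.0),
}
ENDOTOXEMIA_SCHEDULE = {
    "GRMS-55": (30, 60, 90, 120, 180),
    "rolipram": (30, 60, 90, 120, 180),
    "LSF_PTX": (0, 15, 30, 60, 90, 120, 180),
}

# ---------------------------------------------------------------------------
# Collagen-induced arthritis (female Lewis rats)
# ---------------------------------------------------------------------------
# GRMS-55 and rolipram come from one experiment (shared disease parameters),
# (+/-)-LSF from the other.

CIA: dict[str, CIAParameters] = {
    "LSF": CIAParameters(kin0=0.498, kdeg=0.0133, kout=0.258, tonset=12.6,
                         tau=0.371, ic50=1.06),
    "GRMS-55": CIAParameters(kin0=0.521, kdeg=0.0127, kout=0.281, tonset=13.3,
                             tau=0.257, ic50=0.26),
    "rolipram": CIAParameters(kin0=0.523, kdeg=0.0127, kout=0.281, tonset=13.3,
                              tau=0.257, ic50=0.01),
}

CIA_MEASUREMENT_DAYS = (0, 5, 7, 11, 15, 18, 20, 22, 26, 30, 33, 36)
CIA_TREATMENT = {  # once daily, days 20-39; endpoint day 40
    "GRMS-55": ("IP", 50.0),
    "rolipram": ("IP", 10.0),
    "LSF": ("SC", 80.0),
}
CIA_FIRST_DOSE_DAY = 20
CIA_LAST_DOSE_DAY = 39
CIA_ENDPOINT_DAY = 40


def cia_regimen(compound: str) -> DoseRegimen:
    """Once-daily treatment regimen of the arthritis study, times in minutes."""
    route, dose = CIA_TREATMENT[compound]
    times = tuple(
        d * MINUTES_PER_DAY
        for d in range(CIA_FIRST_DOSE_DAY, CIA_LAST_DOSE_DAY + 1)
    )
    return DoseRegimen(route, dose, times)


# ---------------------------------------------------------------------------
# In-vitro inhibition of human recombinant PDEs (Hill parameters)
# ---------------------------------------------------------------------------
# IC50 uM, Imax %, gamma dimensionless; entries with potency beyond the
# tested range are kept separately as censoring bounds (IC50 > bound).

PDE_HILL: dict[str, dict[str, HillParameters]] = {
    "GRMS-55": {
        "PDE1B": HillParameters(Imax=93, IC50=2.5, gamma=1.0),
        "PDE3A": HillParameters(Imax=98, IC50=13.4, gamma=1.5),
        "PDE4B": HillParameters(Imax=100, IC50=26.9, gamma=1.2),
        "PDE7A": HillParameters(Imax=96, IC50=7.3, gamma=0.97),
        "PDE10A": HillParameters(Imax=96, IC50=23.3, gamma=3.0),
    },
    "LSF": {
        "PDE1B": HillParameters(Imax=97, IC50=12.9, gamma=1.0),
        "PDE2A": HillParameters(Imax=83, IC50=91.6, gamma=2.1),
        "PDE3A": HillParameters(Imax=99, IC50=73.4, gamma=2.5),
        "PDE4B": HillParameters(Imax=98, IC50=50.8, gamma=2.5),
        "PDE7A": HillParameters(Imax=100, IC50=297.2, gamma=2.5),
    },
    "rolipram": {
        "PDE4B": HillParameters(Imax=99, IC50=1.1, gamma=1.6),
        "PDE4D": HillParameters(Imax=99, IC50=5.0, gamma=1.7),
    },
}

# (compound, enzyme) -> lower bound on IC50 in uM (no inhibition observed
# up to the listed concentration)
PDE_CENSORED: dict[tuple[str, str], float] = {
    ("GRMS-55", "PDE2A"): 100.0,
    ("GRMS-55", "PDE4D"): 200.0,
    ("GRMS-55", "PDE5A"): 100.0,
    ("LSF", "PDE4D"): 200.0,
    ("LSF", "PDE5A"): 100.0,
    ("LSF", "PDE10A"): 100.0,
}
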