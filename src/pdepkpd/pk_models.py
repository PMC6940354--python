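"""Compartmental pharmacokinetic models and model-free exposure summaries.

All structural models are expressed in amounts per kg of body mass, so that
doses (mg/kg), volumes (L/kg) and clearances (L/min/kg) compose without an
explicit body-weight term.  Observable plasma concentrations are linear
projections amount/volume (mg/L).

Four structures are provided:

``one_compartment``
    Single well-stirred compartment with first-order elimination Cl_t/V and
    an optional first-order absorption depot (ka, F) for extravascular
    dosing.
``two_compartment``
    Central + peripheral compartments exchanging via a distribution
    clearance Cl_d, elimination Cl_t from the central compartment, optional
    absorption depot.
``lsf_interconversion``
    Parent drug ((+/-)-lisofylline) with reversible metabolic exchange with
    its metabolite pentoxifylline: first-order parent disappearance kd feeds
    a metabolite pool that eliminates with kem and back-converts with kconv.
    Only the composite volume V_PTXm/fm is identifiable, so the metabolite
    state is stored as amount divided by the fraction metabolized.
``lsf_michaelis_menten``
    Parent with saturable (Michaelis-Menten) disappearance into a metabolite
    that distributes to a peripheral compartment (km12/km21) and eliminates
    with kem.  For C << Km this reduces to a linear model with Cl = Vmax/Km.

Dosing is implemented as instantaneous state jumps: IV boluses enter the
central compartment, IP/SC doses enter the absorption depot multiplied by
the fraction absorbed F.  Numerical integration restarts at every dose
event (stiff-capable adaptive solver, rtol 1e-8 / atol 1e-10); the linear
structures additionally expose an exact closed-form solution used when a
drug concentration function must be evaluated inside another ODE system.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Route",
    "DoseRegimen",
    "OneCompartmentParams",
    "TwoCompartmentParams",
    "LSFInterconversionParams",
    "LSFWistarParams",
    "ConcentrationSeries",
    "simulate_pk",
    "concentration_profile",
    "half_life",
    "flip_flop_ratio",
    "nca_auc",
    "fraction_absorbed",
]

RTOL = 1e-8
ATOL = 1e-10


class Route(enum.Enum):
    """Administration route; IV is intravascular, IP/SC extravascular."""

    IV = "IV"
    IP = "IP"
    SC = "SC"

    @property
    def extravascular(self) -> bool:
        return self is not Route.IV


@dataclass(frozen=True)
class DoseRegimen:
    """One or repeated administrations of a compound.

    Parameters
    ----------
    route
        Administration route (IV, IP or SC).
    dose
        Amount per administration, mg per kg of body mass.
    times
        Strictly increasing administration times in minutes.
    """

    route: Route
    dose: float
    times: tuple[float, ...] = (0.0,)
    per_kg: bool = True

    def __post_init__(self):
        if isinstance(self.route, str):
            object.__setattr__(self, "route", Route(self.route.upper()))
        if self.dose <= 0:
            raise ValueError(f"dose must be positive, got {self.dose}")
        times = tuple(float(t) for t in self.times)
        if len(times) == 0:
            raise ValueError("at least one administration time is required")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("administration times must be strictly increasing")
        object.__setattr__(self, "times", times)


def _require_positive(obj, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if value is None:
            continue
        if not (value > 0):
            raise ValueError(f"{type(obj).__name__}.{name} must be positive, got {value}")


@dataclass(frozen=True)
class OneCompartmentParams:
    """One-compartment model: volume V (L/kg), total clearance Cl_t (L/min/kg).

    ``ka``/``F`` add a first-order absorption depot for extravascular dosing.
    When the data identify only apparent constants, V and Cl_t hold V/F and
    Cl_t/F with F left at 1.
    """

    V: float
    Cl_t: float
    ka: float | None = None
    F: float | None = None

    def __post_init__(self):
        _require_positive(self, ["V", "Cl_t", "ka"])
        if self.F is not None and not (0 < self.F <= 1):
            raise ValueError(f"F must lie in (0, 1], got {self.F}")


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Two-compartment model with central (V1) and peripheral (V2) volumes,
    total clearance Cl_t and distribution clearance Cl_d (all per kg)."""

    V1: float
    V2: float
    Cl_t: float
    Cl_d: float
    ka: float | None = None
    F: float | None = None

    def __post_init__(self):
        _require_positive(self, ["V1", "V2", "Cl_t", "Cl_d", "ka"])
        if self.F is not None and not (0 < self.F <= 1):
            raise ValueError(f"F must lie in (0, 1], got {self.F}")


@dataclass(frozen=True)
class LSFInterconversionParams:
    """Linear parent-metabolite interconversion model for (+/-)-lisofylline.

    The metabolite state is the amount divided by the fraction metabolized
    fm, hence only the composite volume V_PTXm/fm appears.
    """

    V_LSF: float
    V_PTXm_over_fm: float
    ka_LSF: float
    kd: float
    kem: float
    kconv: float
    F_LSF: float = 1.0

    def __post_init__(self):
        _require_positive(
            self, ["V_LSF", "V_PTXm_over_fm", "ka_LSF", "kd", "kem", "kconv"]
        )
        if not (0 < self.F_LSF <= 1):
            raise ValueError(f"F_LSF must lie in (0, 1], got {self.F_LSF}")


@dataclass(frozen=True)
class LSFWistarParams:
    """(+/-)-lisofylline / pentoxifylline model with saturable parent
    disappearance (Vmax, Km) and a metabolite peripheral compartment."""

    V_LSF: float
    V_PTXm: float
    Vmax: float
    Km: float
    km12: float
    km21: float
    kem: float

    def __post_init__(self):
        _require_positive(
            self, ["V_LSF", "V_PTXm", "Vmax", "Km", "km12", "km21", "kem"]
        )


@dataclass
class ConcentrationSeries:
    """Time-stamped plasma levels of one analyte with LOQ metadata.

    ``conc`` entries flagged as censored carry NaN; ``quantified`` returns
    the uncensored (time, concentration) pairs.
    """

    analyte: str
    times: np.ndarray
    conc: np.ndarray
    loq: float | None = None
    censored: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have matching shapes")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        self.conc = np.where(self.censored, np.nan, self.conc)
        ok = ~self.censored
        if np.any(self.conc[ok] < 0):
            raise ValueError("uncensored concentrations must be non-negative")

    def quantified(self) -> tuple[np.ndarray, np.ndarray]:
        ok = ~self.censored & np.isfinite(self.conc)
        return self.times[ok], self.conc[ok]

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Structural model registry
# ---------------------------------------------------------------------------

@dataclass
class _LinearStructure:
    matrix: np.ndarray                   # amount-space rate matrix
    iv_index: int
    depot_index: int | None
    observations: dict[str, np.ndarray]  # analyte -> projection row (conc = row @ x)
    F: float


@dataclass
class _NonlinearStructure:
    rhs: Callable[[float, np.ndarray], np.ndarray]
    n_states: int
    iv_index: int
    depot_index: int | None
    observations: dict[str, Callable[[np.ndarray], np.ndarray]]
    F: float


def _build_structure(variant: str, params, dose_into: str | None = None):
    if variant == "one_compartment":
        p: OneCompartmentParams = params
        if p.ka is None:
            M = np.array([[-p.Cl_t / p.V]])
            return _LinearStructure(M, 0, None, {"parent": np.array([1 / p.V])}, 1.0)
        M = np.array([[-p.Cl_t / p.V, p.ka], [0.0, -p.ka]])
        return _LinearStructure(
            M, 0, 1, {"parent": np.array([1 / p.V, 0.0])}, p.F if p.F else 1.0
        )
    if variant == "two_compartment":
        q: TwoCompartmentParams = params
        k10 = q.Cl_t / q.V1
        k12 = q.Cl_d / q.V1
        k21 = q.Cl_d / q.V2
        if q.ka is None:
            M = np.array([[-(k10 + k12), k21], [k12, -k21]])
            return _LinearStructure(
                M, 0, None, {"parent": np.array([1 / q.V1, 0.0])}, 1.0
            )
        M = np.array(
            [
                [-(k10 + k12), k21, q.ka],
                [k12, -k21, 0.0],
                [0.0, 0.0, -q.ka],
            ]
        )
        return _LinearStructure(
            M, 0, 2, {"parent": np.array([1 / q.V1, 0.0, 0.0])}, q.F if q.F else 1.0
        )
    if variant == "lsf_interconversion":
        r: LSFInterconversionParams = params
        # states: X_LSF, X_PTXm (amount / fm), A_LSF (depot)
        M = np.array(
            [
                [-r.kd, r.kconv, r.ka_LSF],
                [r.kd, -(r.kem + r.kconv), 0.0],
                [0.0, 0.0, -r.ka_LSF],
            ]
        )
        obs = {
            "parent": np.array([1 / r.V_LSF, 0.0, 0.0]),
            "metabolite": np.array([0.0, 1 / r.V_PTXm_over_fm, 0.0]),
        }
        return _LinearStructure(M, 0, 2, obs, r.F_LSF)
    if variant == "lsf_michaelis_menten":
        s: LSFWistarParams = params
        # states: X_LSF, X_PTX (central), X_PTX_peripheral

        def rhs(t, x):
            c = x[0] / s.V_LSF
            elim = s.Vmax * c / (s.Km + c)
            return np.array(
                [
                    -elim,
                    elim - (s.km12 + s.kem) * x[1] + s.km21 * x[2],
                    s.km12 * x[1] - s.km21 * x[2],
                ]
            )

        obs = {
            "parent": lambda x: x[0] / s.V_LSF,
            "metabolite": lambda x: x[1] / s.V_PTXm,
        }
        iv_index = 1 if dose_into == "metabolite" else 0
        return _NonlinearStructure(rhs, 3, iv_index, None, obs, 1.0)
    raise ValueError(f"unknown model variant: {variant!r}")


_ANALYTE_NAMES = {"parent", "metabolite"}


def _dose_vector(structure, regimen: DoseRegimen) -> np.ndarray:
    n = (
        structure.matrix.shape[0]
        if isinstance(structure, _LinearStructure)
        else structure.n_states
    )
    b = np.zeros(n)
    if regimen.route.extravascular:
        if structure.depot_index is None:
            raise ValueError(
                "extravascular dosing requires an absorption rate constant (ka)"
            )
        b[structure.depot_index] = structure.F * regimen.dose
    else:
        b[structure.iv_index] = regimen.dose
    return b


def simulate_pk(
    variant: str,
    params,
    regimen: DoseRegimen,
    times: Sequence[float],
    dose_into: str | None = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> dict[str, ConcentrationSeries]:
    """Simulate plasma concentrations by adaptive ODE integration.

    Doses are applied as state jumps and the integration restarts at every
    administration time.  Returns one :class:`ConcentrationSeries` per
    observable analyte (``parent`` and, where the structure defines one,
    ``metabolite``).

    Raises ``ValueError`` for an unknown variant or output times before the
    first dose.
    """
    structure = _build_structure(variant, params, dose_into)
    times = np.asarray(times, dtype=float)
    t0 = regimen.times[0]
    if np.any(times < t0):
        raise ValueError("output times before the first dose are undefined")

    n = (
        structure.matrix.shape[0]
        if isinstance(structure, _LinearStructure)
        else structure.n_states
    )
    if isinstance(structure, _LinearStructure):
        M = structure.matrix

        def rhs(t, x):
            return M @ x

    else:
        rhs = structure.rhs

    b = _dose_vector(structure, regimen)
    horizon = max(float(times.max()), regimen.times[-1])
    breakpoints = list(regimen.times) + [horizon + 1e-9]
    x = np.zeros(n)
    out = np.full((n, len(times)), np.nan)

    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        x = x + b  # bolus at seg_start
        mask = (times >= seg_start) & (times < seg_end)
        eval_ts = np.unique(times[mask])
        sol = solve_ivp(
            rhs,
            (seg_start, seg_end),
            x,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if eval_ts.size:
            vals = sol.sol(eval_ts)
            for j, t in zip(range(len(times)), times):
                if mask[j]:
                    out[:, j] = vals[:, np.searchsorted(eval_ts, t)]
        x = sol.y[:, -1]

    result = {}
    for analyte, proj in structure.observations.items():
        if callable(proj):
            conc = np.array([proj(out[:, j]) for j in range(len(times))])
        else:
            conc = proj @ out
        result[analyte] = ConcentrationSeries(analyte=analyte, times=times, conc=conc)
    return result


def concentration_profile(
    variant: str,
    params,
    regimen: DoseRegimen,
    horizon: float | None = None,
    dose_into: str | None = None,
) -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Continuous concentration functions of time (minutes).

    For the linear structures the exact solution is assembled from the
    eigendecomposition of the rate matrix and superposed over doses, so the
    returned callables are cheap enough to sit inside another ODE right-hand
    side (the pharmacodynamic models evaluate them at every solver step).
    The saturable variant falls back to a dense numerical solution, which
    requires ``horizon``.  Concentrations are zero before the first dose.
    """
    structure = _build_structure(variant, params, dose_into)
    b = _dose_vector(structure, regimen)
    dose_times = np.asarray(regimen.times)

    if isinstance(structure, _LinearStructure):
        M = structure.matrix
        lam, V = np.linalg.eig(M)
        coeff = np.linalg.solve(V, b)  # dose vector in eigenbasis

        def make(proj):
            w = proj @ V  # projection of each eigenmode
            alpha = w * coeff
            # doses older than this no longer contribute at double precision
            slowest = np.min(np.abs(lam.real[np.abs(alpha) > 0])) if np.any(
                np.abs(alpha) > 0
            ) else 1.0
            memory = 36.0 / max(slowest, 1e-30)

            def conc(t):
                t = np.asarray(t, dtype=float)
                if t.ndim == 0:  # fast path for use inside ODE right-hand sides
                    dt = float(t) - dose_times
                    m = (dt >= 0) & (dt <= memory)
                    if not m.any():
                        return 0.0
                    val = float((np.exp(np.outer(dt[m], lam)) @ alpha).sum().real)
                    return max(val, 0.0)
                total = np.zeros(t.shape, dtype=complex)
                for td in dose_times:
                    dt = t - td
                    active = (dt >= 0) & (dt <= memory)
                    if np.any(active):
                        total[active] += np.exp(
                            np.outer(dt[active], lam)
                        ) @ alpha
                return np.maximum(total.real, 0.0)

            return conc

        return {a: make(p) for a, p in structure.observations.items()}

    if horizon is None:
        raise ValueError("horizon is required for the nonlinear variant")
    rhs = structure.rhs
    breakpoints = list(dose_times) + [float(horizon)]
    sols = []
    x = np.zeros(structure.n_states)
    for seg_start, seg_end in zip(breakpoints[:-1], breakpoints[1:]):
        x = x + b
        sol = solve_ivp(
            rhs, (seg_start, seg_end), x, method="LSODA",
            rtol=RTOL, atol=ATOL, dense_output=True,
        )
        sols.append((seg_start, seg_end, sol))
        x = sol.y[:, -1]

    def make_nl(proj):
        def conc(t):
            t = np.asarray(t, dtype=float)
            scalar = t.ndim == 0
            t = np.atleast_1d(t)
            c = np.zeros(t.shape)
            for j, tj in enumerate(t):
                if tj < breakpoints[0]:
                    continue
                for seg_start, seg_end, sol in sols:
                    if seg_start <= tj <= seg_end:
                        c[j] = max(proj(sol.sol(tj)), 0.0)
                        break
                else:
                    c[j] = max(proj(sols[-1][2].sol(tj)), 0.0)
            return float(c[0]) if scalar else c

        return conc

    return {a: make_nl(p) for a, p in structure.observations.items()}


# ---------------------------------------------------------------------------
# Derived pharmacokinetic quantities
# ---------------------------------------------------------------------------

def half_life(V: float, Cl: float) -> float:
    """Elimination half-life ln2 * V / Cl in minutes."""
    if V <= 0 or Cl <= 0:
        raise ValueError("V and Cl must be positive")
    return math.log(2) * V / Cl


def flip_flop_ratio(kd: float, ka: float) -> float:
    """Ratio of the disposition to the absorption rate constant.

    Values well above 1 indicate flip-flop kinetics: the terminal slope of
    the plasma profile reflects absorption rather than elimination.
    """
    if kd <= 0 or ka <= 0:
        raise ValueError("rate constants must be positive")
    return kd / ka


def nca_auc(series: ConcentrationSeries) -> float:
    """Linear-trapezoid AUC from the first to the last quantified sample.

    Below-LOQ (censored) observations are excluded; no extrapolation beyond
    the last quantified time is performed.
    """
    t, c = series.quantified()
    if len(t) < 2:
        raise ValueError("at least two quantified observations are required")
    return float(np.trapezoid(c, t))


def fraction_absorbed(
    auc_ev: float, dose_iv: float, auc_iv: float, dose_ev: float
) -> float:
    """Bioavailability from dose-normalized AUC ratio (not clamped to 1)."""
    for name, v in [
        ("auc_ev", auc_ev), ("dose_iv", dose_iv),
        ("auc_iv", auc_iv), ("dose_ev", dose_ev),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return auc_ev * dose_iv / (auc_iv * dose_ev)
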