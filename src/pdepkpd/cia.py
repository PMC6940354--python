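"""Disease-progression model of collagen-induced arthritis (CIA).

Arthritic paw swelling in collagen-immunized rats is summarized as the
relative hind-paw area: each paw and ankle section is approximated as an
ellipse (Area = pi*a*b/4 from the two caliper diameters), the two section
areas are summed, and the sum is normalized to the same paw at day 0.

The progression model is a type-I indirect-response model with signal
transduction.  After the disease onset ``tonset`` a precursor is produced
at a time-decaying zero-order rate kin(t) = kin0*exp(-kdeg*t) (the decay
encodes natural remission) and lost with first-order ``kout``; four transit
compartments with mean transit time ``tau`` delay the signal before it
appears as paw swelling, which additionally grows at the natural zero-order
rate ``kgrow``.  A drug inhibits the production term by the saturable
factor (1 - Imax*Cp/(IC50+Cp)) with Imax fixed to 1, where Cp is the plasma
concentration of the parent compound driven by the repeated-dose PK model.

The disease states run on a day scale while drug concentrations come from
a minute-scale PK model; drug pulses last well under an hour, so the
integrator restarts at every dosing event and resolves the post-dose
window finely.

The natural-growth term is referenced to the disease-free baseline
1 + kgrow*t: the transit pull (T4 - .)/tau acts on the disease component
of swelling, so a healthy (pre-onset) paw follows 1 + kgrow*t exactly and
a remitted paw returns to that baseline.  ``growth="literal"`` instead
applies the pull to total swelling, in which case the natural growth only
ever contributes kgrow*tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .pk_models import RTOL, ATOL

__all__ = [
    "PawMeasurement",
    "CIAParameters",
    "paw_area",
    "relative_paw",
    "simulate_cia",
    "endpoint_reduction",
    "MINUTES_PER_DAY",
]

MINUTES_PER_DAY = 1440.0
N_TRANSIT = 4


@dataclass(frozen=True)
class PawMeasurement:
    """Caliper diameters (mm) of the paw and ankle sections of one hind paw."""

    animal_id: str
    day: float
    paw_a: float
    paw_b: float
    ankle_a: float
    ankle_b: float

    def __post_init__(self):
        if self.day < 0:
            raise ValueError("day must be non-negative")
        for name in ("paw_a", "paw_b", "ankle_a", "ankle_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def overall_area(self) -> float:
        return paw_area(self.paw_a, self.paw_b) + paw_area(self.ankle_a, self.ankle_b)


@dataclass(frozen=True)
class CIAParameters:
    """Onset, production-decay, transit, growth and inhibition constants.

    All rates are per day; ``ic50`` (mg/L) may be None for a drug-free arm.
    ``kgrow`` (0.004/day) and ``imax`` (1) are fixed by design.
    """

    kin0: float
    kdeg: float
    kout: float
    tonset: float
    tau: float
    kgrow: float = 0.004
    imax: float = 1.0
    ic50: float | None = None

    def __post_init__(self):
        for name in ("kin0", "kdeg", "kout", "tonset", "tau", "kgrow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.imax <= 1):
            raise ValueError("imax must lie in [0, 1]")
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError("ic50 must be positive")


def paw_area(a: float, b: float):
    """Elliptical section area pi*a*b/4 (mm^2) from the two diameters."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("diameters must be positive")
    out = np.pi * a * b / 4.0
    return float(out) if out.ndim == 0 else out


def relative_paw(measurement: PawMeasurement, baseline: PawMeasurement) -> float:
    """Relative paw swelling: overall (paw+ankle) area over the day-0 area."""
    if measurement.animal_id != baseline.animal_id:
        raise ValueError("measurement and baseline must be the same animal")
    base = baseline.overall_area
    if base <= 0:
        raise ValueError("baseline area must be positive")
    return measurement.overall_area / base


def simulate_cia(
    params: CIAParameters,
    days,
    conc_fn: Callable[[float], float] | None = None,
    dose_days: Sequence[float] = (),
    growth: str = "baseline",
    rtol: float = RTOL,
    atol: float = ATOL,
) -> np.ndarray:
    """Relative paw swelling at the requested days.

    ``conc_fn`` is the plasma concentration of the parent drug as a
    function of time in MINUTES (from
    :func:`pdepkpd.pk_models.concentration_profile`); ``dose_days`` lists
    the administration days so the integrator can restart there and resolve
    the short post-dose concentration pulse.
    """
    if growth not in ("baseline", "literal"):
        raise ValueError("growth must be 'baseline' or 'literal'")
    days = np.asarray(days, dtype=float)
    if np.any(days < 0):
        raise ValueError("output days must be non-negative")
    horizon = float(days.max())

    inv_tau = 1.0 / params.tau
    use_drug = conc_fn is not None and params.ic50 is not None

    def effect(t_day):
        if not use_drug:
            return 1.0
        cp = max(float(conc_fn(t_day * MINUTES_PER_DAY)), 0.0)
        return 1.0 - params.imax * cp / (params.ic50 + cp)

    # states: Prec, kin, T1..T4, u  (u = disease component of Paw)
    def rhs(t, x, onset_passed):
        prec, kin = x[0], x[1]
        dx = np.empty_like(x)
        dx[0] = (kin * effect(t) - params.kout * prec) if onset_passed else 0.0
        dx[1] = -params.kdeg * kin
        chain = np.concatenate(([prec], x[2:]))
        dx[2:] = (chain[:-1] - chain[1:]) * inv_tau
        if growth == "literal":
            # growth enters the Paw balance directly (total-swelling pull)
            dx[-1] += params.kgrow
        return dx

    # breakpoints: onset, dosing events (+ a short finely-resolved window)
    events = {0.0, horizon}
    if params.tonset < horizon:
        events.add(float(params.tonset))
    fine_until = {}
    for d in dose_days:
        d = float(d)
        if 0.0 < d < horizon:
            events.add(d)
            fine_until[d] = min(d + 0.25, horizon)
    breaks = sorted(events)

    x = np.concatenate(([1.0, params.kin0], np.ones(N_TRANSIT + 1)))
    out = np.full(days.shape, np.nan)
    if np.any(days == 0):
        out[days == 0] = x[-1] if growth == "literal" else x[-1]

    for a, b in zip(breaks[:-1], breaks[1:]):
        last = b == breaks[-1]
        onset_passed = a >= params.tonset - 1e-12
        max_step = np.inf
        if a in fine_until:
            # resolve the post-dose hour: concentration pulse width ~0.05 day
            max_step = 0.005
            b_fine = fine_until[a]
            sol = solve_ivp(rhs, (a, b_fine), x, args=(onset_passed,),
                            method="LSODA", rtol=rtol, atol=atol,
                            dense_output=True, max_step=max_step)
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            mask = (days > a) & (days <= b_fine)
            if np.any(mask):
                out[mask] = sol.sol(days[mask])[-1]
            x = sol.y[:, -1]
            a = b_fine
            if a >= b:
                continue
        sol = solve_ivp(rhs, (a, b), x, args=(onset_passed,),
                        method="LSODA", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        mask = (days > a) & ((days <= b) if last else (days <= b))
        if np.any(mask):
            out[mask] = sol.sol(days[mask])[-1]
        x = sol.y[:, -1]

    if growth == "baseline":
        out = out + params.kgrow * days
    return out


def endpoint_reduction(
    treated: float, control: float, convention: str = "simple"
) -> float:
    """Percent reduction of relative paw swelling in a treated arm.

    ``simple``: 100*(control - treated)/control.  ``above_baseline``:
    100*(control - treated)/(control - 1), i.e. relative to swelling in
    excess of the day-0 paw.
    """
    if convention == "simple":
        if control <= 0:
            raise ValueError("control swelling must be positive")
        return 100.0 * (control - treated) / control
    if convention == "above_baseline":
        if control <= 1:
            raise ValueError("control swelling must exceed the baseline of 1")
        return 100.0 * (control - treated) / (control - 1.0)
    raise ValueError("convention must be 'simple' or 'above_baseline'")
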