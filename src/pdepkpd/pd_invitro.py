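"""In-vitro concentration-effect analysis for plate assays.

Relative enzymatic (or TNF-alpha release) activity is expressed as percent
of vehicle control, and the sigmoid inhibition model

    E(C) = E0 - Imax * C**gamma / (C**gamma + IC50**gamma)

is fitted to concentration-effect data by nonlinear least squares with the
baseline E0 fixed to 100%.  IC50 is the concentration halving the maximal
inhibition Imax, and gamma is the Hill (steepness) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

__all__ = [
    "PlateMeasurement",
    "HillParameters",
    "HillFit",
    "relative_activity",
    "hill_effect",
    "fit_hill",
]


@dataclass(frozen=True)
class PlateMeasurement:
    """Replicate well readings for one compound at one concentration."""

    compound: str
    concentration: float  # uM
    readings: tuple[float, ...]
    control_readings: tuple[float, ...] = ()
    blank_readings: tuple[float, ...] = ()

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if len(self.readings) < 1:
            raise ValueError("at least one replicate reading is required")


@dataclass(frozen=True)
class HillParameters:
    """Sigmoid-inhibition parameters: baseline E0 (%), maximal inhibition
    Imax (%), half-maximal concentration IC50 (uM) and Hill coefficient."""

    Imax: float
    IC50: float
    gamma: float
    E0: float = 100.0

    def __post_init__(self):
        if self.IC50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.Imax <= 0:
            raise ValueError("Imax must be positive")


@dataclass
class HillFit:
    """Result of a Hill-model fit: estimates, asymptotic CV% and diagnostics."""

    params: HillParameters
    cv_percent: dict[str, float]
    wssr: float
    n_obs: int
    converged: bool
    message: str = ""


def relative_activity(sample, control) -> float:
    """Percent activity of a sample relative to the vehicle control mean."""
    sample = np.asarray(sample, dtype=float)
    control = np.asarray(control, dtype=float)
    cbar = control.mean()
    if cbar <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * sample.mean() / cbar


def hill_effect(C, params: HillParameters):
    """Relative activity (%) predicted by the sigmoid inhibition model.

    Monotone non-increasing in C; equals E0 at C=0 and E0 - Imax/2 at
    C = IC50 for any gamma.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        ratio = np.where(
            C > 0,
            C ** params.gamma / (C ** params.gamma + params.IC50 ** params.gamma),
            0.0,
        )
    out = params.E0 - params.Imax * ratio
    return float(out) if out.ndim == 0 else out


def fit_hill(
    concentrations,
    effects,
    E0: float = 100.0,
    imax_max: float = 110.0,
) -> HillFit:
    """Fit the sigmoid inhibition model with E0 fixed.

    Starting values: IC50 at the geometric mean of the positive tested
    concentrations, Imax = 90, gamma = 1.  Imax is bounded (0, ``imax_max``]
    to tolerate noise excursions above complete inhibition.  Unweighted
    least squares on the percent scale.  Degenerate (flat) data are flagged
    as non-converged.
    """
    conc = np.asarray(concentrations, dtype=float)
    eff = np.asarray(effects, dtype=float)
    if conc.shape != eff.shape:
        raise ValueError("concentrations and effects must align")
    if len(np.unique(conc)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")
    if np.allclose(eff, eff[0]):
        return HillFit(
            params=HillParameters(Imax=1e-6, IC50=1.0, gamma=1.0, E0=E0),
            cv_percent={}, wssr=0.0, n_obs=len(eff),
            converged=False, message="no concentration dependence in the data",
        )

    pos = conc[conc > 0]
    ic50_start = float(np.exp(np.mean(np.log(pos))))
    p = lmfit.Parameters()
    p.add("Imax", value=90.0, min=1e-6, max=imax_max)
    p.add("IC50", value=ic50_start, min=1e-9)
    p.add("gamma", value=1.0, min=1e-3, max=10.0)

    def residual(pars):
        hp = HillParameters(
            Imax=pars["Imax"].value, IC50=pars["IC50"].value,
            gamma=pars["gamma"].value, E0=E0,
        )
        return hill_effect(conc, hp) - eff

    result = lmfit.minimize(residual, p, method="leastsq")
    est = HillParameters(
        Imax=result.params["Imax"].value,
        IC50=result.params["IC50"].value,
        gamma=result.params["gamma"].value,
        E0=E0,
    )
    cv = {}
    for name in ("Imax", "IC50", "gamma"):
        par = result.params[name]
        if par.stderr is not None and abs(par.value) > 0:
            cv[name] = 100.0 * par.stderr / abs(par.value)
        else:
            cv[name] = float("nan")
    wssr = float(np.sum(np.asarray(result.residual) ** 2))
    converged = bool(result.success) and est.Imax > 1e-3
    message = "" if converged else "fit did not converge to a meaningful inhibition"
    return HillFit(
        params=est, cv_percent=cv, wssr=wssr,
        n_obs=len(eff), converged=converged, message=message,
    )
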