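"""Quantitative stage: quasi-steady-state time stepping and dynamic FVA.

A dFVA run is two *independent* dynamic simulations of the same protocol, one
per LP direction on the objective reaction.  Each direction propagates its
own medium state, so the pair of trajectories bounds the feasible envelope:
for an exchange objective, the minimisation direction drives maximal uptake
(signed flux at its lower bound, medium depleting), while maximisation
explores release/production.  Model parameters are never fitted to observed
time courses; the protocol is simulated as declared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import CouplingMap, UnitContext, apply_bounds, apply_flux_to_marking, bounds_from_marking, make_unit_context
from .gsmn import MetabolicModel, apply_biomass, solve_fba
from .petri import PetriNet, kinetic_step

logger = logging.getLogger(__name__)


@dataclass
class Protocol:
    """One dFVA simulation protocol.

    Times in hours, concentrations in mM, fluxes in mmol/g DW/h.
    """

    model: MetabolicModel
    coupling: CouplingMap
    net: PetriNet
    objective_reaction: str
    dt: float = 0.1
    horizon: float = 48.0
    biomass_demand: float = 0.0
    units: UnitContext = field(default_factory=make_unit_context)
    seed: int | None = None  # reserved; this stage is deterministic

    def validate(self) -> None:
        if self.horizon <= 0 or self.dt <= 0:
            raise ValueError("horizon and dt must be positive")
        self.model.reaction_index(self.objective_reaction)
        self.coupling.validate(self.model)
        self.net.validate()


@dataclass
class SimState:
    marking: dict[str, float]
    model: MetabolicModel
    t: float = 0.0


@dataclass
class DFVAResult:
    """Envelope of a dFVA run: per-direction flux and concentration courses."""

    time: np.ndarray
    flux: dict[str, np.ndarray]                 # direction -> objective flux
    concentrations: dict[str, pd.DataFrame]     # direction -> time x place
    status: dict[str, list[str]]
    objective_reaction: str = ""

    def to_frame(self, direction: str) -> pd.DataFrame:
        df = self.concentrations[direction].copy()
        df.insert(0, "time", self.time)
        df.insert(1, "flux", self.flux[direction])
        df.insert(2, "status", self.status[direction])
        return df


def qss_step(state: SimState, protocol: Protocol, direction: str) -> tuple[SimState, float | None, str]:
    """One quasi-steady-state step.

    Order: (1) explicit-Euler kinetic step of the signalling net; (2) marking
    -> flux-bound translation; (3) FBA on the protocol objective; (4) solved
    fluxes -> marking update.  An infeasible LP is recorded and the marking
    carried forward unchanged (flux terminates, the simulation does not).
    """
    marking = kinetic_step(protocol.net, state.marking, protocol.dt)
    apply_bounds(state.model, bounds_from_marking(protocol.coupling, marking))
    sol = solve_fba(state.model, protocol.objective_reaction, direction)
    if sol.status == "optimal":
        marking = apply_flux_to_marking(protocol.coupling, sol, marking, protocol.dt, protocol.units)
        flux = sol.objective_value
    else:
        logger.debug("step at t=%.2f h: LP %s; flux recorded as absent", state.t, sol.status)
        flux = None
    return SimState(marking, state.model, state.t + protocol.dt), flux, sol.status


def _run_direction(protocol: Protocol, direction: str):
    model = protocol.model.copy()
    if protocol.model.biomass_reaction is not None:
        model = apply_biomass(model, protocol.biomass_demand)
    state = SimState(dict(protocol.net.initial_marking()), model)
    n_steps = int(math.ceil(protocol.horizon / protocol.dt - 1e-9))
    # row k holds the marking at t_k = k*dt and the flux applied over step k;
    # row 0 is the initial state, its flux back-filled from the first step
    fluxes, statuses, markings = [np.nan], ["initial"], [dict(state.marking)]
    for k in range(n_steps):
        state, flux, status = qss_step(state, protocol, direction)
        state.t = (k + 1) * protocol.dt  # drift-free grid
        if status != "optimal" and statuses[-1] in ("optimal", "initial"):
            logger.warning("%s direction: LP %s from t=%.2f h; flux recorded as absent "
                           "while infeasible", direction, status, state.t)
        fluxes.append(np.nan if flux is None else flux)
        statuses.append(status)
        markings.append(dict(state.marking))
    fluxes[0], statuses[0] = fluxes[1], statuses[1]
    time = np.linspace(0.0, n_steps * protocol.dt, n_steps + 1)
    return time, np.asarray(fluxes, dtype=float), statuses, pd.DataFrame(markings)


def run_dfva(protocol: Protocol) -> DFVAResult:
    """Run both LP directions of the protocol objective and return the envelope."""
    protocol.validate()
    out_flux, out_conc, out_status = {}, {}, {}
    time = None
    for direction in ("max", "min"):
        time, flux, status, conc = _run_direction(protocol, direction)
        out_flux[direction] = flux
        out_conc[direction] = conc
        out_status[direction] = status
    return DFVAResult(
        time=time,
        flux=out_flux,
        concentrations=out_conc,
        status=out_status,
        objective_reaction=protocol.objective_reaction,
    )


def auc(time, values, t0: float, t1: float) -> float:
    """Trapezoidal area under ``values`` over [t0, t1].

    Partial first/last intervals are linearly interpolated on the stored
    grid.  Units follow the inputs (e.g. mM x h).
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if not (time[0] <= t0 < t1 <= time[-1]):
        raise ValueError(f"[{t0}, {t1}] outside grid span [{time[0]}, {time[-1]}]")
    grid = np.unique(np.concatenate([[t0, t1], time[(time > t0) & (time < t1)]]))
    vals = np.interp(grid, time, values)
    return float(np.trapezoid(vals, grid))


# ---------------------------------------------------------------------------
# Michaelis-Menten depletion: closed form and parameter recovery
# ---------------------------------------------------------------------------


def mm_depletion(t, S0: float, vmax: float, km: float):
    """Closed-form solution of dS/dt = -vmax * S / (km + S), S(0) = S0.

    Via the Lambert W function: S(t) = km * W((S0/km) exp((S0 - vmax t)/km)).
    ``vmax`` here is a medium-side clearance rate in mM/h (i.e. the specific
    flux already multiplied by phi).
    """
    from scipy.special import lambertw

    t = np.asarray(t, dtype=float)
    log_z = np.log(S0 / km) + (S0 - vmax * t) / km
    out = np.empty_like(log_z)
    small = log_z < 500
    out[small] = km * np.real(lambertw(np.exp(log_z[small])))
    if np.any(~small):
        # asymptotic branch: solve w + log w = log_z by Newton iteration
        a = log_z[~small]
        w = a - np.log(a)
        for _ in range(20):
            w = w - (w + np.log(w) - a) / (1 + 1 / w)
        out[~small] = km * w
    return out


class IdentifiabilityError(RuntimeError):
    """The observed time course carries no information about the parameters."""


@dataclass
class MMFit:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    s0: float
    identifiable: bool = True


def fit_mm(times, concentrations, s0: float | None = None, min_relative_drop: float = 0.05) -> MMFit:
    """Recover (Vmax, Km) from an observed medium depletion time course.

    Nonlinear least squares on the integrated Michaelis-Menten uptake model.
    A flat curve (relative drop below ``min_relative_drop``) raises
    :class:`IdentifiabilityError` rather than returning silent estimates.
    Units: times in h, concentrations in mM, Vmax in mM/h.
    """
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if times.size < 5:
        raise ValueError("need at least 5 time points")
    order = np.argsort(times, kind="stable")
    times, conc = times[order], conc[order]
    top = max(conc.max(), 1e-12)
    if (conc.max() - conc.min()) / top < min_relative_drop:
        raise IdentifiabilityError("time course is flat; Vmax and Km are not identifiable")

    fit_s0 = s0 is None
    s0_guess = float(conc[times == times.min()].mean()) if fit_s0 else float(s0)
    span = times.max() - times.min()
    vmax_guess = max((conc.max() - conc.min()) / max(span, 1e-9), 1e-6)
    km_guess = max(s0_guess / 2, 1e-3)

    if fit_s0:
        def f(t, vmax, km, s0_):
            return mm_depletion(t, s0_, vmax, km)
        p0 = [vmax_guess, km_guess, s0_guess]
        bounds = ([1e-9, 1e-9, 1e-9], [np.inf, np.inf, np.inf])
    else:
        def f(t, vmax, km):
            return mm_depletion(t, s0_guess, vmax, km)
        p0 = [vmax_guess, km_guess]
        bounds = ([1e-9, 1e-9], [np.inf, np.inf])

    popt, pcov = curve_fit(f, times, conc, p0=p0, bounds=bounds, maxfev=20000)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return MMFit(
        vmax=float(popt[0]),
        km=float(popt[1]),
        vmax_se=float(se[0]),
        km_se=float(se[1]),
        s0=float(popt[2]) if fit_s0 else s0_guess,
        identifiable=True,
    )
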