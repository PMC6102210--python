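"""Stoichiometric metabolic model with FBA/FVA on top of scipy's HiGHS LP.

Sign convention for exchange fluxes: positive = release/export into the
medium, negative = consumption/uptake.  "Maximise uptake" is therefore an
explicit direction flag on the solve, not a sign puzzle.

Units: fluxes in mmol/g DW/h throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: requested solver tolerance; results asserted to 1e-6 in tests
SOLVER_TOL = 1e-9
FEAS_TOL = 1e-6
DEFAULT_BOUND = 1000.0


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


class InfeasibleError(RuntimeError):
    """The constrained model admits no steady-state flux distribution."""


@dataclass
class MetabolicModel:
    """Stoichiometric model: N (metabolites x reactions), bounds, exchange set.

    ``stoichiometry`` is a CSR sparse matrix; rows follow ``metabolites``,
    columns follow ``reactions``.
    """

    metabolites: list[str]
    reactions: list[str]
    stoichiometry: sp.csr_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    exchanges: list[str] = field(default_factory=list)
    biomass_reaction: str | None = None
    name: str = "model"

    def __post_init__(self) -> None:
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self._rxn_index = {r: i for i, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}

    # -- indexing -----------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def bounds(self, rid: str) -> tuple[float, float]:
        i = self.reaction_index(rid)
        return float(self.lower_bounds[i]), float(self.upper_bounds[i])

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise ValueError(f"lb {lb} > ub {ub} for {rid!r}")
        i = self.reaction_index(rid)
        self.lower_bounds[i] = lb
        self.upper_bounds[i] = ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            stoichiometry=self.stoichiometry.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            exchanges=list(self.exchanges),
            biomass_reaction=self.biomass_reaction,
            name=self.name,
        )

    def validate(self) -> None:
        if self.stoichiometry.shape != (self.n_metabolites, self.n_reactions):
            raise ValueError("stoichiometry shape mismatch")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = [self.reactions[i] for i in np.flatnonzero(self.lower_bounds > self.upper_bounds)]
            raise ValueError(f"lb > ub for reactions {bad}")
        if len(set(self.reactions)) != self.n_reactions:
            raise ValueError("duplicate reaction ids")
        if len(set(self.metabolites)) != self.n_metabolites:
            raise ValueError("duplicate metabolite ids")
        for rid in self.exchanges:
            self.reaction_index(rid)


@dataclass
class FluxSolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: pd.Series | None = None
    alt_optima: bool | None = None


@dataclass
class MediumComposition:
    """External medium: metabolite id -> concentration (mM)."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        for m, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {m!r}")

    def present(self, met: str) -> bool:
        return self.concentrations.get(met, 0.0) > 0.0


@dataclass
class ExchangeBounds:
    """Per-metabolite (max consumption, max release) caps in mmol/g DW/h."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for m, (cons, rel) in self.bounds.items():
            if cons < 0 or rel < 0:
                raise ValueError(f"negative exchange cap for {m!r}")


# ---------------------------------------------------------------------------
# LP primitives
# ---------------------------------------------------------------------------


def _lp(model: MetabolicModel, c: np.ndarray) -> linprog:
    return linprog(
        c,
        A_eq=model.stoichiometry,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([model.lower_bounds, model.upper_bounds]),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )


def solve_fba(
    model: MetabolicModel,
    objective_reaction: str,
    direction: str = "max",
    detect_alternates: bool = False,
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    Solves max/min v[objective] s.t. N v = 0, lb <= v <= ub.  When alternative
    optima detection is requested, the objective is fixed at its optimum and
    every other reaction is FVA-scanned for flux freedom.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    j = model.reaction_index(objective_reaction)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if direction == "max" else 1.0
    res = _lp(model, c)
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if not res.success:
        raise SolverError(f"LP solver failure: {res.message}")
    v = pd.Series(res.x, index=model.reactions)
    sol = FluxSolution(status="optimal", objective_value=float(res.x[j]), fluxes=v)
    if detect_alternates:
        sol.alt_optima = _has_alternative_optima(model, objective_reaction, sol.objective_value)
    return sol


def _has_alternative_optima(model: MetabolicModel, objective_reaction: str, z: float) -> bool:
    fixed = model.copy()
    fixed.set_bounds(objective_reaction, z - FEAS_TOL, z + FEAS_TOL)
    for rid in fixed.reactions:
        if rid == objective_reaction:
            continue
        vmin, vmax = flux_variability(fixed, rid)
        if vmax - vmin > 10 * FEAS_TOL:
            return True
    return False


def flux_variability(
    model: MetabolicModel,
    reaction: str,
    fixed_constraints: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """(min, max) feasible flux through ``reaction`` under fixed constraints.

    ``fixed_constraints`` maps reaction ids to (lb, ub) pairs applied before
    solving (e.g. a biomass demand).  Raises :class:`InfeasibleError` naming
    the applied constraint set if the constrained model is infeasible.
    """
    work = model
    if fixed_constraints:
        work = model.copy()
        for rid, (lb, ub) in fixed_constraints.items():
            work.set_bounds(rid, lb, ub)
    lo = solve_fba(work, reaction, "min")
    hi = solve_fba(work, reaction, "max")
    if lo.status != "optimal" or hi.status != "optimal":
        raise InfeasibleError(
            f"FVA of {reaction!r} infeasible under constraints "
            f"{sorted(fixed_constraints) if fixed_constraints else '(model bounds)'}"
        )
    vmin, vmax = lo.objective_value, hi.objective_value
    if vmin > vmax:  # numerical dust from the two independent solves
        vmin = vmax = 0.5 * (vmin + vmax)
    return vmin, vmax


# ---------------------------------------------------------------------------
# constraint application
# ---------------------------------------------------------------------------


def default_exchange_map(model: MetabolicModel) -> dict[str, str]:
    """Metabolite -> exchange reaction mapping read off the stoichiometry.

    Each exchange reaction with a single boundary metabolite maps that
    metabolite; multi-metabolite exchanges must be mapped explicitly.
    """
    out = {}
    N = model.stoichiometry.tocsc()
    for rid in model.exchanges:
        col = N.getcol(model.reaction_index(rid)).tocoo()
        if col.nnz == 1:
            out[model.metabolites[col.row[0]]] = rid
    return out


def apply_medium(
    model: MetabolicModel,
    medium: MediumComposition,
    nci60: ExchangeBounds,
    exchange_map: dict[str, str] | None = None,
) -> MetabolicModel:
    """Constrain exchange bounds to a medium composition.

    Metabolites absent from the medium have their uptake closed (lb -> 0);
    present metabolites get (-max consumption, +max release) from the
    NCI-60-style cap table.  Release caps from the table apply regardless of
    presence.  Idempotent; returns a modified copy.
    """
    exchange_map = exchange_map or default_exchange_map(model)
    unmapped = [m for m in medium.concentrations if m not in exchange_map]
    if unmapped:
        raise KeyError(f"medium metabolites without exchange reactions: {sorted(unmapped)}")
    out = model.copy()
    for met, rid in exchange_map.items():
        lb, ub = out.bounds(rid)
        caps = nci60.bounds.get(met)
        if caps is not None:
            ub = caps[1]
        if medium.present(met):
            if caps is not None:
                lb = -caps[0]
        else:
            lb = 0.0  # no uptake from an empty medium
        out.set_bounds(rid, min(lb, ub), ub)
    return out


def apply_biomass(model: MetabolicModel, demand_flux: float) -> MetabolicModel:
    """Fix the biomass reaction at ``demand_flux`` (hard constraint, not objective)."""
    if model.biomass_reaction is None:
        raise ValueError("model declares no biomass reaction")
    out = model.copy()
    out.set_bounds(model.biomass_reaction, demand_flux, demand_flux)
    return out


# ---------------------------------------------------------------------------
# SBML I/O (via COBRApy, FBC package)
# ---------------------------------------------------------------------------


def _from_cobra(cm, biomass_reaction: str | None = None) -> MetabolicModel:
    mets = [m.id for m in cm.metabolites]
    rxns = [r.id for r in cm.reactions]
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    for j, r in enumerate(cm.reactions):
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        for met, coef in r.metabolites.items():
            rows.append(midx[met.id])
            cols.append(j)
            vals.append(float(coef))
    N = sp.csr_matrix((vals, (rows, cols)), shape=(len(mets), len(rxns)))
    try:
        exchanges = [r.id for r in cm.exchanges]  # external-compartment aware
    except Exception:
        exchanges = [r.id for r in cm.boundary]
    if biomass_reaction is None:
        candidates = [r for r in rxns if "biomass" in r.lower()]
        biomass_reaction = candidates[0] if candidates else None
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        stoichiometry=N,
        lower_bounds=lb,
        upper_bounds=ub,
        exchanges=exchanges,
        biomass_reaction=biomass_reaction,
        name=cm.id or "model",
    )
    model.validate()
    return model


def read_gsmn_sbml(path, biomass_reaction: str | None = None) -> MetabolicModel:
    """Read a genome-scale model from SBML (L3+FBC preferred).

    Reactions without explicit bounds fall back to the reader's global
    defaults (+/-1000 mmol/g DW/h), which is logged along with the model size.
    """
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    model = _from_cobra(cm, biomass_reaction)
    n_default = int(np.sum((model.lower_bounds <= -DEFAULT_BOUND) | (model.upper_bounds >= DEFAULT_BOUND)))
    logger.info(
        "read %s: %d metabolites, %d reactions (%d with default-magnitude bounds)",
        path, model.n_metabolites, model.n_reactions, n_default,
    )
    return model


def write_gsmn_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3 + FBC via COBRApy."""
    import cobra
    import cobra.io

    cm = cobra.Model(model.name)
    cobra_mets = {}
    for m in model.metabolites:
        comp = m.rsplit("_", 1)[1] if "_" in m and m.rsplit("_", 1)[1] in ("e", "c", "m", "x") else "c"
        cobra_mets[m] = cobra.Metabolite(m, compartment=comp)
    cm.add_metabolites(list(cobra_mets.values()))
    N = model.stoichiometry.tocsc()
    rxns = []
    for j, rid in enumerate(model.reactions):
        r = cobra.Reaction(rid)
        r.lower_bound, r.upper_bound = float(model.lower_bounds[j]), float(model.upper_bounds[j])
        col = N.getcol(j).tocoo()
        r.add_metabolites({cobra_mets[model.metabolites[i]]: v for i, v in zip(col.row, col.data)})
        rxns.append(r)
    cm.add_reactions(rxns)
    if model.biomass_reaction:
        cm.objective = model.biomass_reaction
    cobra.io.write_sbml_model(cm, str(path))


def build_model(
    stoich: dict[str, dict[str, float]],
    bounds: dict[str, tuple[float, float]],
    exchanges: list[str] | None = None,
    biomass_reaction: str | None = None,
    name: str = "model",
) -> MetabolicModel:
    """Assemble a model from reaction -> {metabolite: coefficient} dicts.

    Reaction and metabolite orderings are sorted for determinism; exchange
    reactions default to the ``EX_`` prefix convention.
    """
    reactions = sorted(stoich)
    mets = sorted({m for d in stoich.values() for m in d})
    midx = {m: i for i, m in enumerate(mets)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(reactions):
        for m, c in stoich[rid].items():
            rows.append(midx[m])
            cols.append(j)
            vals.append(float(c))
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        stoichiometry=sp.csr_matrix((vals, (rows, cols)), shape=(len(mets), len(reactions))),
        lower_bounds=np.array([bounds[r][0] for r in reactions]),
        upper_bounds=np.array([bounds[r][1] for r in reactions]),
        exchanges=exchanges if exchanges is not None else [r for r in reactions if r.startswith("EX_")],
        biomass_reaction=biomass_reaction,
        name=name,
    )
    model.validate()
    return model


def read_bounds_overrides(path) -> dict[str, tuple[float, float]]:
    """Read a TSV of (reaction_id, lb, ub) bound overrides."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"reaction_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"bounds override file needs columns {sorted(required)}")
    return {row.reaction_id: (float(row.lb), float(row.ub)) for row in df.itertuples()}


def apply_bounds_overrides(model: MetabolicModel, overrides: dict[str, tuple[float, float]]) -> MetabolicModel:
    out = model.copy()
    for rid, (lb, ub) in overrides.items():
        out.set_bounds(rid, lb, ub)
    return out
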