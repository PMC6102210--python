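"""Multi-formalism Petri-net data model.

Two node formalisms coexist in one net:

* **continuous** places/transitions carry kinetic signalling and transport
  dynamics (concentrations in mM or nM, fluxes in mmol/g DW/h), integrated
  with an explicit-Euler step;
* **discrete** places carry rule-based three-level gene-expression states
  (0 = inhibited, 1 = basal, 2 = induced) updated by guarded transitions
  fired one event at a time.

The quasi-steady-state coupling to a stoichiometric metabolic model lives in
:mod:`petriflux.coupling`; this module only knows about markings, guards,
arcs and kinetic laws.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

logger = logging.getLogger(__name__)

NET_SCHEMA = "petriflux-net/1"

PLACE_KINDS = ("species", "gene", "constraint", "objective", "treatment")
ARC_KINDS = ("consume", "produce", "test", "inhibit")
GUARD_OPS = ("gt", "ge", "lt", "le", "eq")

#: three-level gene expression states
GENE_INHIBITED, GENE_BASAL, GENE_INDUCED = 0, 1, 2


class StructuralError(ValueError):
    """A net references undeclared places or violates structural constraints."""


class FiringError(RuntimeError):
    """A transition was fired while disabled."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modifier:
    """Multiplicative scaling of a kinetic rate by another place's marking.

    ``saturating`` form: scale = 1 + a * x / (K + x)  (x = modifier marking);
    ``linear`` form: scale = 1 + a * x.  Used e.g. for insulin-dependent
    scaling of a transporter Vmax.
    """

    place: str
    form: str = "saturating"
    a: float = 0.0
    K: float = 1.0

    def scale(self, x: float) -> float:
        if self.form == "saturating":
            return 1.0 + self.a * x / (self.K + x)
        if self.form == "linear":
            return 1.0 + self.a * x
        raise ValueError(f"unknown modifier form {self.form!r}")


@dataclass(frozen=True)
class KineticLaw:
    """Serialisable kinetic rate law.

    Supported forms: ``michaelis_menten`` (Vmax [mmol/g DW/h], Km [mM],
    substrate place), ``mass_action`` (rate k * product of substrate
    markings) and ``constant``.
    """

    form: str
    vmax: float = 0.0
    km: float = 1.0
    k: float = 0.0
    substrate: str | None = None
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        if self.form not in ("michaelis_menten", "mass_action", "constant"):
            raise ValueError(f"unknown kinetic law form {self.form!r}")
        if self.form == "michaelis_menten":
            if self.vmax <= 0 or self.km <= 0:
                raise ValueError("michaelis_menten requires Vmax > 0 and Km > 0")
        if self.form == "mass_action" and self.k < 0:
            raise ValueError("mass_action requires k >= 0")

    def modifier_scale(self, marking: Mapping[str, float]) -> float:
        s = 1.0
        for m in self.modifiers:
            s *= m.scale(float(marking[m.place]))
        return s


def mm_rate(S: float, law: KineticLaw, marking: Mapping[str, float] | None = None) -> float:
    """Michaelis-Menten rate Vmax * S / (Km + S), modifier-scaled.

    ``S`` is the substrate concentration (mM); the returned flux carries the
    units of ``law.vmax``.  Raises for negative ``S``.
    """
    if S < 0:
        raise ValueError(f"negative substrate concentration {S}")
    if law.form != "michaelis_menten":
        raise ValueError("mm_rate requires a michaelis_menten law")
    rate = law.vmax * S / (law.km + S)
    if law.modifiers:
        if marking is None:
            raise ValueError("law has modifiers; a marking is required")
        rate *= law.modifier_scale(marking)
    return rate


@dataclass(frozen=True)
class Place:
    id: str
    kind: str = "species"
    marking: float = 0.0
    discrete: bool = False
    level_range: tuple[int, int] | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PLACE_KINDS:
            raise ValueError(f"unknown place kind {self.kind!r}")
        if self.discrete:
            lo, hi = self.level_range if self.level_range is not None else (0, 2)
            object.__setattr__(self, "level_range", (int(lo), int(hi)))
            if not (lo <= self.marking <= hi):
                raise ValueError(f"initial level {self.marking} outside {self.level_range} for {self.id}")
        elif self.marking < 0:
            raise ValueError(f"negative initial marking for {self.id}")


@dataclass(frozen=True)
class Arc:
    place: str
    weight: float = 1.0
    kind: str = "consume"

    def __post_init__(self) -> None:
        if self.kind not in ARC_KINDS:
            raise ValueError(f"unknown arc kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("arc weight must be positive")


@dataclass(frozen=True)
class Condition:
    """Guard atom: compare a place's marking to a constant."""

    place: str
    op: str
    value: float

    def __post_init__(self) -> None:
        if self.op not in GUARD_OPS:
            raise ValueError(f"unknown guard op {self.op!r}")

    def holds(self, marking: Mapping[str, float]) -> bool:
        x = marking[self.place]
        v = self.value
        return {
            "gt": x > v,
            "ge": x >= v,
            "lt": x < v,
            "le": x <= v,
            "eq": x == v,
        }[self.op]


@dataclass(frozen=True)
class Transition:
    id: str
    mode: str = "rule"  # "kinetic" | "rule"
    input_arcs: tuple[Arc, ...] = ()
    output_arcs: tuple[Arc, ...] = ()
    rate_law: KineticLaw | None = None
    guard: tuple[Condition, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("kinetic", "rule"):
            raise ValueError(f"unknown transition mode {self.mode!r}")
        if self.mode == "kinetic" and self.rate_law is None:
            raise ValueError(f"kinetic transition {self.id} lacks a rate law")
        for arc in self.output_arcs:
            if arc.kind not in ("produce",):
                raise ValueError(f"output arc of {self.id} must be 'produce'")
        for arc in self.input_arcs:
            if arc.kind == "produce":
                raise ValueError(f"input arc of {self.id} cannot be 'produce'")


@dataclass
class PetriNet:
    """A structurally closed multi-formalism Petri net."""

    places: dict[str, Place] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add_place(self, place: Place) -> None:
        if place.id in self.places:
            raise StructuralError(f"duplicate place id {place.id!r}")
        self.places[place.id] = place

    def add_transition(self, t: Transition) -> None:
        if t.id in self.transitions:
            raise StructuralError(f"duplicate transition id {t.id!r}")
        self.transitions[t.id] = t

    def initial_marking(self) -> dict[str, float]:
        return {p.id: p.marking for p in self.places.values()}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for t in self.transitions.values():
            for arc in (*t.input_arcs, *t.output_arcs):
                if arc.place not in self.places:
                    raise StructuralError(f"transition {t.id!r} references unknown place {arc.place!r}")
                if t.mode == "kinetic" and self.places[arc.place].discrete:
                    raise StructuralError(f"kinetic transition {t.id!r} touches discrete place {arc.place!r}")
            for c in t.guard:
                if c.place not in self.places:
                    raise StructuralError(f"guard of {t.id!r} references unknown place {c.place!r}")
            if t.mode == "kinetic" and t.rate_law is not None:
                law = t.rate_law
                if law.substrate is not None and law.substrate not in self.places:
                    raise StructuralError(f"rate law of {t.id!r} references unknown place {law.substrate!r}")
                for m in law.modifiers:
                    if m.place not in self.places:
                        raise StructuralError(f"modifier of {t.id!r} references unknown place {m.place!r}")

    def check_marking(self, marking: Mapping[str, float]) -> None:
        for pid, place in self.places.items():
            if pid not in marking:
                raise StructuralError(f"marking missing place {pid!r}")
            x = marking[pid]
            if place.discrete:
                lo, hi = place.level_range
                if not (lo <= x <= hi) or x != int(x):
                    raise ValueError(f"discrete marking {x} outside {place.level_range} for {pid!r}")
            elif x < 0:
                raise ValueError(f"negative marking {x} for place {pid!r}")


# ---------------------------------------------------------------------------
# rule-mode semantics
# ---------------------------------------------------------------------------


def _transition_enabled(net: PetriNet, t: Transition, marking: Mapping[str, float]) -> bool:
    for c in t.guard:
        if c.place not in net.places:
            raise StructuralError(f"guard of {t.id!r} references unknown place {c.place!r}")
        if not c.holds(marking):
            return False
    for arc in t.input_arcs:
        x = marking[arc.place]
        if arc.kind in ("consume", "test"):
            if x < arc.weight:
                return False
        elif arc.kind == "inhibit":
            if x >= arc.weight:
                return False
    # produced discrete levels must stay in range for the firing to be legal
    for arc in t.output_arcs:
        place = net.places[arc.place]
        if place.discrete:
            lo, hi = place.level_range
            if marking[arc.place] + arc.weight > hi:
                return False
    for arc in t.input_arcs:
        place = net.places[arc.place]
        if place.discrete and arc.kind == "consume":
            lo, hi = place.level_range
            if marking[arc.place] - arc.weight < lo:
                return False
    return True


def enabled_transitions(net: PetriNet, marking: Mapping[str, float]) -> list[str]:
    """Rule-mode transitions enabled at ``marking``, lexicographically sorted."""
    out = [
        tid
        for tid, t in net.transitions.items()
        if t.mode == "rule" and _transition_enabled(net, t, marking)
    ]
    return sorted(out)


def fire(net: PetriNet, marking: Mapping[str, float], transition_id: str) -> dict[str, float]:
    """Fire one rule transition, returning the successor marking.

    Test and inhibit arcs leave markings untouched; consume/produce arcs apply
    their weights.  Firing a disabled transition raises :class:`FiringError`.
    """
    t = net.transitions[transition_id]
    if not _transition_enabled(net, t, marking):
        raise FiringError(f"transition {transition_id!r} is not enabled")
    new = dict(marking)
    for arc in t.input_arcs:
        if arc.kind == "consume":
            new[arc.place] = new[arc.place] - arc.weight
    for arc in t.output_arcs:
        new[arc.place] = new[arc.place] + arc.weight
    net.check_marking(new)
    return new


# ---------------------------------------------------------------------------
# continuous semantics
# ---------------------------------------------------------------------------


def kinetic_rate(net: PetriNet, t: Transition, marking: Mapping[str, float]) -> float:
    """Instantaneous rate of a kinetic transition at ``marking``."""
    law = t.rate_law
    if law.form == "constant":
        rate = law.k
    elif law.form == "mass_action":
        rate = law.k
        for arc in t.input_arcs:
            if arc.kind == "consume":
                rate *= float(marking[arc.place]) ** arc.weight
    else:  # michaelis_menten
        sub = law.substrate
        if sub is None:
            consume = [a for a in t.input_arcs if a.kind == "consume"]
            if not consume:
                raise StructuralError(f"MM transition {t.id!r} has no substrate")
            sub = consume[0].place
        rate = law.vmax * float(marking[sub]) / (law.km + float(marking[sub]))
    rate *= law.modifier_scale(marking)
    if not math.isfinite(rate) or rate < 0:
        raise ValueError(f"rate of {t.id!r} is {rate}")
    return rate


def kinetic_step(net: PetriNet, marking: Mapping[str, float], dt: float) -> dict[str, float]:
    """One explicit-Euler step of all kinetic transitions over ``dt`` hours.

    marking' = marking + dt * (stoichiometry . rates); continuous markings
    that would go negative are clipped to 0 with a logged warning.  Discrete
    places are untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    delta: dict[str, float] = {}
    for t in net.transitions.values():
        if t.mode != "kinetic":
            continue
        rate = kinetic_rate(net, t, marking)
        for arc in t.input_arcs:
            if arc.kind == "consume":
                delta[arc.place] = delta.get(arc.place, 0.0) - arc.weight * rate
        for arc in t.output_arcs:
            delta[arc.place] = delta.get(arc.place, 0.0) + arc.weight * rate
    new = dict(marking)
    for pid, d in delta.items():
        x = new[pid] + d * dt
        if x < 0:
            logger.warning("clipping place %s to 0 (Euler step gave %g)", pid, x)
            x = 0.0
        new[pid] = x
    return new


# ---------------------------------------------------------------------------
# gene-expression motif
# ---------------------------------------------------------------------------


def present_condition(net: PetriNet, place_id: str) -> Condition:
    """Regulator "present": marking > 0 (continuous) or level == induced (discrete)."""
    p = net.places[place_id]
    if p.discrete:
        return Condition(place_id, "eq", GENE_INDUCED)
    return Condition(place_id, "gt", 0.0)


def absent_condition(net: PetriNet, place_id: str) -> Condition:
    p = net.places[place_id]
    if p.discrete:
        return Condition(place_id, "lt", GENE_INDUCED)
    return Condition(place_id, "le", 0.0)


def add_gene_motif(
    net: PetriNet,
    gene_id: str,
    activators: Iterable[str] = (),
    inhibitors: Iterable[str] = (),
    initial_level: int = GENE_BASAL,
) -> None:
    """Add a three-level gene place with its induce/repress/relax transitions.

    Level semantics: 0 = inhibited, 1 = basal, 2 = induced.  ``induce`` raises
    the level by one while any activator is present; ``repress`` lowers it
    while any inhibitor is present; when every regulator is absent, ``relax``
    transitions restore the basal level (one firing from either extreme).
    """
    activators = list(activators)
    inhibitors = list(inhibitors)
    net.add_place(Place(gene_id, kind="gene", marking=initial_level, discrete=True, level_range=(0, 2)))
    regs = activators + inhibitors
    absent_all = tuple(absent_condition(net, r) for r in regs)
    for a in activators:
        net.add_transition(
            Transition(
                id=f"{gene_id}__induce__{a}",
                mode="rule",
                guard=(present_condition(net, a), Condition(gene_id, "lt", GENE_INDUCED)),
                output_arcs=(Arc(gene_id, 1, "produce"),),
            )
        )
    for i in inhibitors:
        net.add_transition(
            Transition(
                id=f"{gene_id}__repress__{i}",
                mode="rule",
                guard=(present_condition(net, i), Condition(gene_id, "gt", GENE_INHIBITED)),
                input_arcs=(Arc(gene_id, 1, "consume"),),
            )
        )
    net.add_transition(
        Transition(
            id=f"{gene_id}__relax_up",
            mode="rule",
            guard=absent_all + (Condition(gene_id, "lt", GENE_BASAL),),
            output_arcs=(Arc(gene_id, 1, "produce"),),
        )
    )
    net.add_transition(
        Transition(
            id=f"{gene_id}__relax_down",
            mode="rule",
            guard=absent_all + (Condition(gene_id, "gt", GENE_BASAL),),
            input_arcs=(Arc(gene_id, 1, "consume"),),
        )
    )


# ---------------------------------------------------------------------------
# JSON serialisation (schema "petriflux-net/1")
# ---------------------------------------------------------------------------


def net_to_dict(net: PetriNet) -> dict:
    def law_d(law: KineticLaw | None):
        if law is None:
            return None
        return {
            "form": law.form,
            "vmax": law.vmax,
            "km": law.km,
            "k": law.k,
            "substrate": law.substrate,
            "modifiers": [
                {"place": m.place, "form": m.form, "a": m.a, "K": m.K} for m in law.modifiers
            ],
        }

    return {
        "schema": NET_SCHEMA,
        "places": [
            {
                "id": p.id,
                "kind": p.kind,
                "marking": p.marking,
                "discrete": p.discrete,
                "level_range": list(p.level_range) if p.level_range else None,
                "units": p.units,
            }
            for p in net.places.values()
        ],
        "transitions": [
            {
                "id": t.id,
                "mode": t.mode,
                "input_arcs": [[a.place, a.weight, a.kind] for a in t.input_arcs],
                "output_arcs": [[a.place, a.weight, a.kind] for a in t.output_arcs],
                "rate_law": law_d(t.rate_law),
                "guard": [[c.place, c.op, c.value] for c in t.guard],
            }
            for t in net.transitions.values()
        ],
    }


def net_from_dict(d: dict) -> PetriNet:
    if d.get("schema") != NET_SCHEMA:
        raise ValueError(f"unknown net schema {d.get('schema')!r}")
    net = PetriNet()
    for pd in d["places"]:
        net.add_place(
            Place(
                id=pd["id"],
                kind=pd["kind"],
                marking=pd["marking"],
                discrete=pd["discrete"],
                level_range=tuple(pd["level_range"]) if pd.get("level_range") else None,
                units=pd.get("units", ""),
            )
        )
    for td in d["transitions"]:
        law = None
        if td.get("rate_law"):
            ld = td["rate_law"]
            law = KineticLaw(
                form=ld["form"],
                vmax=ld.get("vmax", 0.0),
                km=ld.get("km", 1.0),
                k=ld.get("k", 0.0),
                substrate=ld.get("substrate"),
                modifiers=tuple(
                    Modifier(m["place"], m["form"], m["a"], m["K"]) for m in ld.get("modifiers", [])
                ),
            )
        net.add_transition(
            Transition(
                id=td["id"],
                mode=td["mode"],
                input_arcs=tuple(Arc(*a) for a in td["input_arcs"]),
                output_arcs=tuple(Arc(*a) for a in td["output_arcs"]),
                rate_law=law,
                guard=tuple(Condition(*c) for c in td["guard"]),
            )
        )
    net.validate()
    return net


def write_net_json(net: PetriNet, path) -> None:
    with open(path, "w") as fh:
        json.dump(net_to_dict(net), fh, indent=1, sort_keys=True)


def read_net_json(path) -> PetriNet:
    with open(path) as fh:
        return net_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# SBML import (kinetic models)
# ---------------------------------------------------------------------------


def import_sbml_kinetic(path) -> PetriNet:
    """Import a kinetic SBML model as a continuous Petri net.

    Species become continuous places (initial concentration as marking) and
    reactions become kinetic transitions.  Rate laws are classified into the
    supported forms (constant, mass action, Michaelis-Menten) by symbolic
    pattern matching; reactions whose laws cannot be classified, or that lack
    a kinetic law, are recorded in ``net.metadata["sbml_import"]`` rather
    than silently dropped.
    """
    import libsbml
    import sympy

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ValueError(f"SBML parse error: {err.getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ValueError("SBML file contains no model")

    net = PetriNet()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        x0 = sp.getInitialConcentration()
        if math.isnan(x0):
            x0 = sp.getInitialAmount()
        if math.isnan(x0):
            x0 = 0.0
        net.add_place(Place(sp.getId(), kind="species", marking=max(x0, 0.0), units="mM"))

    globals_: dict[str, float] = {}
    for i in range(model.getNumParameters()):
        par = model.getParameter(i)
        globals_[par.getId()] = par.getValue()
    for i in range(model.getNumCompartments()):
        comp = model.getCompartment(i)
        if not math.isnan(comp.getSize()):
            globals_[comp.getId()] = comp.getSize()

    report = {"missing_kinetic_law": [], "unparsed_rate_law": []}
    species_syms = {net_pid: sympy.Symbol(net_pid) for net_pid in net.places}

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        kl = rxn.getKineticLaw()
        if kl is None or kl.getMath() is None:
            report["missing_kinetic_law"].append(rid)
            continue
        params = dict(globals_)
        for j in range(kl.getNumParameters()):
            par = kl.getParameter(j)
            params[par.getId()] = par.getValue()
        formula = libsbml.formulaToL3String(kl.getMath())
        try:
            expr = sympy.sympify(formula.replace("^", "**"), locals=dict(species_syms))
        except (sympy.SympifyError, TypeError, SyntaxError):
            report["unparsed_rate_law"].append(rid)
            continue
        expr = expr.subs({sympy.Symbol(k): v for k, v in params.items()})

        reactants = [
            (rxn.getReactant(j).getSpecies(), rxn.getReactant(j).getStoichiometry() or 1.0)
            for j in range(rxn.getNumReactants())
        ]
        products = [
            (rxn.getProduct(j).getSpecies(), rxn.getProduct(j).getStoichiometry() or 1.0)
            for j in range(rxn.getNumProducts())
        ]
        law = _classify_rate_law(expr, reactants, species_syms)
        if law is None:
            report["unparsed_rate_law"].append(rid)
            continue
        net.add_transition(
            Transition(
                id=rid,
                mode="kinetic",
                input_arcs=tuple(Arc(s, w, "consume") for s, w in reactants),
                output_arcs=tuple(Arc(s, w, "produce") for s, w in products),
                rate_law=law,
            )
        )

    net.metadata["sbml_import"] = report
    if report["missing_kinetic_law"] or report["unparsed_rate_law"]:
        logger.warning("SBML import report: %s", report)
    net.validate()
    return net


def _classify_rate_law(expr, reactants, species_syms):
    import sympy

    free_species = expr.free_symbols & set(species_syms.values())
    if not free_species:
        try:
            k = float(expr)
        except TypeError:
            return None
        if k < 0:
            return None
        return KineticLaw(form="constant", k=k)

    # mass action: expr == k * prod(reactant^stoich)
    monomial = sympy.Integer(1)
    for sid, w in reactants:
        monomial *= species_syms[sid] ** sympy.nsimplify(w)
    if monomial != 1:
        ratio = sympy.simplify(expr / monomial)
        if ratio.is_number:
            k = float(ratio)
            if k >= 0:
                return KineticLaw(form="mass_action", k=k)

    # Michaelis-Menten: expr == Vmax * S / (Km + S) in one species
    if len(free_species) == 1:
        S = next(iter(free_species))
        vmax_w = sympy.Wild("vmax_w", exclude=[S])
        km_w = sympy.Wild("km_w", exclude=[S])
        m = sympy.together(expr).match(vmax_w * S / (km_w + S))
        if m and m[vmax_w].is_number and m[km_w].is_number:
            vmax, km = float(m[vmax_w]), float(m[km_w])
            if vmax > 0 and km > 0:
                sid = next(pid for pid, sym in species_syms.items() if sym == S)
                return KineticLaw(form="michaelis_menten", vmax=vmax, km=km, substrate=sid)
    return None
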