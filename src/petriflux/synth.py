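"""Desk-scale synthetic models and data.

Provides the fixtures every pipeline stage runs on without downloads:

* a ~20-reaction hepatocyte-like stoichiometric network with glucose and
  fructose uptake routes (fructose bypassing the capped committed glycolytic
  step), lumped de novo lipogenesis and cytosolic TAG synthesis, a glucose
  biomass demand, and lactate-fed gluconeogenesis for glucose export;
* a toy transcription-factor regulome whose target genes gate the TAG route,
  with an exhaustive firing-order enumeration oracle for trajectory
  statistics;
* Michaelis-Menten medium-depletion observations with insulin-like Vmax
  modulation and additive truncated-Gaussian noise.

The toy network's optima are hand-calculable; see
:func:`analytic_max_tag` for the worked arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import ActivityList, CouplingMap, ObjectiveCoupling, UnitContext, make_unit_context
from .dfva import Protocol, mm_depletion
from .gsmn import MetabolicModel, apply_biomass, build_model, solve_fba
from .petri import (
    Arc,
    Condition,
    KineticLaw,
    Modifier,
    PetriNet,
    Place,
    Transition,
    add_gene_motif,
    enabled_transitions,
    fire,
)
from .qualitative import RegulomeMap, coupling_from_regulome


# ---------------------------------------------------------------------------
# toy hepatocyte GSMN
# ---------------------------------------------------------------------------


@dataclass
class ToyGSMNSpec:
    """Parameters of the toy hepatocyte network.

    Caps in mmol/g DW/h.  The committed glycolytic step (GK, a lumped
    glucokinase/PFK stand-in) is capacity-capped; the fructolytic route (KHK)
    bypasses it.  TAG stoichiometry: 1 TAG = 3 fatty acid (8 acetyl-CoA each)
    + 1 triose backbone = 25 triose = 12.5 glucose equivalents.
    """

    include_fructose_bypass: bool = True
    glucokinase_cap: float = 1.5
    ketohexokinase_cap: float = 1.5
    dnl_cap: float = 10.0
    tag_cap: float = 10.0
    resp_cap: float = 10.0
    transporter_cap: float = 10.0
    lactate_uptake_cap: float = 0.0
    biomass_demand: float = 0.05
    seed: int | None = None


#: triose units consumed per unit TAG flux (3 FA x 8 AcCoA + 1 backbone)
TRIOSE_PER_TAG = 25.0


class ToyModelError(ValueError):
    """Contradictory toy-model caps (e.g. biomass unreachable)."""


def make_toy_hepatocyte_gsmn(spec: ToyGSMNSpec | None = None) -> MetabolicModel:
    """Build the toy hepatocyte stoichiometric model (~20 reactions)."""
    spec = spec or ToyGSMNSpec()
    cap = spec.transporter_cap
    stoich: dict[str, dict[str, float]] = {
        "EX_Glc": {"glc_e": -1},
        "EX_Fru": {"fru_e": -1},
        "EX_Lac": {"lac_e": -1},
        "EX_O2": {"o2_e": -1},
        "EX_CO2": {"co2_e": -1},
        "T_Glc": {"glc_e": -1, "glc_c": 1},
        "T_Fru": {"fru_e": -1, "fru_c": 1},
        "T_Lac": {"lac_e": -1, "lac_c": 1},
        "T_O2": {"o2_e": -1, "o2_c": 1},
        "T_CO2": {"co2_c": -1, "co2_e": 1},
        "GK": {"glc_c": -1, "triose": 2},
        "GNG": {"triose": -2, "glc_c": 1},
        "GLY": {"triose": -1, "pyr": 1},
        "LDH": {"pyr": -1, "lac_c": 1},
        "PDH": {"pyr": -1, "accoa": 1, "co2_c": 1},
        "RESP": {"accoa": -1, "o2_c": -2, "co2_c": 2},
        "DNL": {"accoa": -8, "fa": 1},
        "TAGS": {"fa": -3, "triose": -1, "tag": 1},
        "TAG_PROD": {"tag": -1},
        "BIOMASS": {"glc_c": -2},
    }
    bounds: dict[str, tuple[float, float]] = {
        "EX_Glc": (-cap, cap),
        "EX_Fru": (-cap, cap),
        "EX_Lac": (-spec.lactate_uptake_cap, cap),
        "EX_O2": (-2 * cap, 0.0),
        "EX_CO2": (0.0, 2 * cap),
        "T_Glc": (-cap, cap),
        "T_Fru": (0.0, cap),
        "T_Lac": (-cap, cap),
        "T_O2": (0.0, 2 * cap),
        "T_CO2": (0.0, 2 * cap),
        "GK": (0.0, spec.glucokinase_cap),
        "GNG": (0.0, cap),
        "GLY": (-cap, cap),
        "LDH": (-cap, cap),
        "PDH": (0.0, 2 * cap),
        "RESP": (0.0, spec.resp_cap),
        "DNL": (0.0, spec.dnl_cap),
        "TAGS": (0.0, cap),
        "TAG_PROD": (0.0, spec.tag_cap),
        "BIOMASS": (0.0, cap),
    }
    if spec.include_fructose_bypass:
        stoich["KHK"] = {"fru_c": -1, "triose": 2}
        bounds["KHK"] = (0.0, spec.ketohexokinase_cap)
    else:
        stoich["ISO"] = {"fru_c": -1, "glc_c": 1}
        bounds["ISO"] = (0.0, cap)

    model = build_model(stoich, bounds, biomass_reaction="BIOMASS", name="toy_hepatocyte")
    sol = solve_fba(model, "BIOMASS", "max")
    if sol.status != "optimal" or sol.objective_value + 1e-9 < spec.biomass_demand:
        raise ToyModelError(
            f"biomass demand {spec.biomass_demand} unreachable "
            f"(max attainable {sol.objective_value if sol.status == 'optimal' else sol.status})"
        )
    return model


def analytic_max_tag(spec: ToyGSMNSpec, uptake_bound: float, sugar: str = "glucose",
                     biomass_demand: float = 0.0) -> float:
    """Hand-calculated maximal TAG flux of the toy network.

    Glucose route: uptake u (capped by the activity-list bound and the
    transporter) feeds the biomass demand first (2 glc per unit) and the
    capped committed step GK; triose = 2*min(u - 2b, gk_cap);
    v_TAG = triose / 25.  Fructose bypasses GK via KHK but must fund the
    glucose-requiring biomass through gluconeogenesis (4b triose per b):
    v_TAG = (2*min(u, khk_cap) - 4b) / 25.
    """
    u = min(uptake_bound, spec.transporter_cap)
    b = biomass_demand
    if sugar == "glucose":
        triose = 2.0 * min(max(u - 2.0 * b, 0.0), spec.glucokinase_cap)
        return max(triose, 0.0) / TRIOSE_PER_TAG
    if sugar == "fructose":
        if not spec.include_fructose_bypass:
            raise ValueError("analytic fructose optimum assumes the KHK bypass")
        triose = 2.0 * min(u, spec.ketohexokinase_cap) - 4.0 * b
        return max(triose, 0.0) / TRIOSE_PER_TAG
    raise ValueError(f"unknown sugar {sugar!r}")


# ---------------------------------------------------------------------------
# toy dFVA protocol
# ---------------------------------------------------------------------------

#: toy Michaelis-Menten transport parameters (mmol/g DW/h, mM)
GLC_VMAX, GLC_KM = 5.0, 5.0
FRU_VMAX, FRU_KM = 3.0, 10.0
#: insulin-like cascade: pAKT production/decay rates and Vmax scaling
PAKT_K_PROD, PAKT_K_DECAY = 0.01, 1.0
INSULIN_SCALE_A, INSULIN_SCALE_K = 0.15, 0.5


def make_toy_protocol(
    sugar: str = "glucose",
    concentration: float = 25.0,
    insulin_nM: float = 0.0,
    objective: str = "TAG_PROD",
    dt: float = 0.1,
    horizon: float = 48.0,
    biomass_demand: float = 0.05,
    spec: ToyGSMNSpec | None = None,
    units: UnitContext | None = None,
    insulin_sensitive_glucose: bool = True,
) -> Protocol:
    """Assemble the toy quantitative protocol: model + signalling net + coupling.

    The net carries the medium places (glucose/fructose, mM), an insulin ->
    pAKT mini-cascade (pAKT scales the glucose transporter Vmax when insulin
    sensitivity is on), and a TAG accumulator place.  The activity lists are
    symmetric, so gluconeogenic glucose *export* shares the transport bound
    magnitude with uptake.
    """
    if sugar not in ("glucose", "fructose"):
        raise ValueError(f"unknown sugar {sugar!r}")
    spec = spec or ToyGSMNSpec(biomass_demand=biomass_demand)
    model = make_toy_hepatocyte_gsmn(spec)

    net = PetriNet()
    glc0 = concentration if sugar == "glucose" else 0.0
    fru0 = concentration if sugar == "fructose" else 0.0
    net.add_place(Place("glc_medium", kind="constraint", marking=glc0, units="mM"))
    net.add_place(Place("fru_medium", kind="constraint", marking=fru0, units="mM"))
    net.add_place(Place("tag_total", kind="objective", marking=0.0, units="mM"))
    net.add_place(Place("insulin", kind="species", marking=insulin_nM, units="nM"))
    net.add_place(Place("pakt", kind="species", marking=0.0, units="au"))
    net.add_transition(
        Transition(
            id="pakt_production",
            mode="kinetic",
            input_arcs=(Arc("insulin", 1, "consume"),),
            output_arcs=(Arc("insulin", 1, "produce"), Arc("pakt", 1, "produce")),
            rate_law=KineticLaw(form="mass_action", k=PAKT_K_PROD),
        )
    )
    net.add_transition(
        Transition(
            id="pakt_decay",
            mode="kinetic",
            input_arcs=(Arc("pakt", 1, "consume"),),
            rate_law=KineticLaw(form="mass_action", k=PAKT_K_DECAY),
        )
    )
    net.validate()

    glc_modifiers = (
        (Modifier("pakt", "saturating", INSULIN_SCALE_A, INSULIN_SCALE_K),)
        if insulin_sensitive_glucose
        else ()
    )
    coupling = CouplingMap(
        activity_lists={
            "glc_medium": ActivityList(
                place="glc_medium",
                targets=("EX_Glc",),
                law=KineticLaw(
                    form="michaelis_menten", vmax=GLC_VMAX, km=GLC_KM,
                    substrate="glc_medium", modifiers=glc_modifiers,
                ),
                symmetric=True,
            ),
            "fru_medium": ActivityList(
                place="fru_medium",
                targets=("EX_Fru",),
                law=KineticLaw(form="michaelis_menten", vmax=FRU_VMAX, km=FRU_KM, substrate="fru_medium"),
                symmetric=True,
            ),
        },
        objectives={
            "glc_medium": ObjectiveCoupling("glc_medium", "EX_Glc"),
            "fru_medium": ObjectiveCoupling("fru_medium", "EX_Fru"),
            "tag_total": ObjectiveCoupling("tag_total", "TAG_PROD"),
        },
    )
    return Protocol(
        model=model,
        coupling=coupling,
        net=net,
        objective_reaction=objective,
        dt=dt,
        horizon=horizon,
        biomass_demand=biomass_demand,
        units=units or make_unit_context(),
    )


# ---------------------------------------------------------------------------
# toy regulome
# ---------------------------------------------------------------------------


@dataclass
class ToyRegulomeSpec:
    """Parameters of the toy transcription-factor regulome.

    ``clearance_requires_induction=True`` gates treatment clearance on the
    full induced gene program (clearance via induced catabolism), making
    induction of the TAG-gating gene certain (success probability 1).  With
    ``False``, clearance competes with induction and the success probability
    is strictly between 0 and 1 - the enumerable calibration setting.
    """

    n_genes: int = 2
    treatment_tokens: int = 2
    clearance_requires_induction: bool = True
    induction_factor: float = 2.0
    seed: int | None = None


#: reactions toy genes may gate, in assignment order (first gene gates TAG)
_GATEABLE = ["TAG_PROD", "RESP", "DNL", "GK", "PDH", "T_Glc", "GNG", "LDH"]

TF_PLACE = "PPARA"
TREATMENT_PLACE = "FA_treatment"
TAG_GENE = "G_TAG"


def make_toy_regulome(spec: ToyRegulomeSpec | None = None) -> tuple[RegulomeMap, PetriNet]:
    """Build the toy regulome net and its gene -> reaction map.

    One treatment place holds fatty-acid tokens; the TF place activates while
    tokens are present; each target gene follows the three-level motif with
    the TF as activator.  The first gene gates the TAG route, so its
    induction is necessary for increased TAG capability.
    """
    spec = spec or ToyRegulomeSpec()
    if spec.n_genes < 1:
        raise ValueError("need at least one target gene")
    if spec.n_genes > len(_GATEABLE):
        raise ValueError(f"at most {len(_GATEABLE)} gateable reactions available")
    net = PetriNet()
    net.add_place(Place(TREATMENT_PLACE, kind="treatment", marking=0.0, units="tokens"))
    net.add_place(Place(TF_PLACE, kind="species", marking=1, discrete=True, level_range=(0, 2)))
    net.add_transition(
        Transition(
            id="tf_activate",
            mode="rule",
            guard=(Condition(TREATMENT_PLACE, "gt", 0.0), Condition(TF_PLACE, "lt", 2)),
            output_arcs=(Arc(TF_PLACE, 1, "produce"),),
        )
    )
    net.add_transition(
        Transition(
            id="tf_deactivate",
            mode="rule",
            guard=(Condition(TREATMENT_PLACE, "le", 0.0), Condition(TF_PLACE, "gt", 1)),
            input_arcs=(Arc(TF_PLACE, 1, "consume"),),
        )
    )
    genes = [TAG_GENE] + [f"G_{i}" for i in range(2, spec.n_genes + 1)]
    entries = []
    for g, rxn in zip(genes, _GATEABLE):
        add_gene_motif(net, g, activators=[TF_PLACE])
        entries.append((g, rxn, "activates"))
    clear_guard = [Condition(TF_PLACE, "eq", 2)]
    if spec.clearance_requires_induction:
        clear_guard += [Condition(g, "eq", 2) for g in genes]
    net.add_transition(
        Transition(
            id="clear_treatment",
            mode="rule",
            guard=tuple(clear_guard),
            input_arcs=(Arc(TREATMENT_PLACE, 1, "consume"),),
        )
    )
    net.validate()
    return RegulomeMap(entries=entries, tf=TF_PLACE, treatment=TREATMENT_PLACE), net


@dataclass
class ToyQualitativeSetup:
    model: MetabolicModel
    coupling: CouplingMap
    net: PetriNet
    regulome: RegulomeMap
    treatment: dict[str, float]
    monitored: tuple[str, ...]
    spec: ToyRegulomeSpec = field(default_factory=ToyRegulomeSpec)


def make_toy_qualitative_setup(spec: ToyRegulomeSpec | None = None) -> ToyQualitativeSetup:
    """Integrated toy model for the qualitative stage.

    The metabolic side is the toy hepatocyte network with a static glucose
    supply and a tight baseline TAG cap (0.1 mmol/g DW/h), so that doubling
    the cap through gene induction measurably raises the TAG FVA maximum
    (substrate support reaches 0.12 at the default caps).
    """
    spec = spec or ToyRegulomeSpec()
    gspec = ToyGSMNSpec(tag_cap=0.1)
    model = make_toy_hepatocyte_gsmn(gspec)
    model.set_bounds("EX_Glc", -2.5, 2.5)  # static medium: generous glucose supply
    model = apply_biomass(model, gspec.biomass_demand)
    regulome, net = make_toy_regulome(spec)
    coupling = coupling_from_regulome(regulome, model, induction_factor=spec.induction_factor)
    return ToyQualitativeSetup(
        model=model,
        coupling=coupling,
        net=net,
        regulome=regulome,
        treatment={TREATMENT_PLACE: float(spec.treatment_tokens)},
        monitored=("TAG_PROD",),
        spec=spec,
    )


def enumerate_success_probability(
    net: PetriNet,
    treatment: dict[str, float],
    success_place: str = TAG_GENE,
    success_level: int = 2,
    max_depth: int = 10_000,
) -> float:
    """Exact success probability under the uniform-random firing policy.

    Exhaustively enumerates every firing order from the treated initial
    marking, weighting each branch by 1/len(enabled), and accumulates the
    probability that ``success_place`` ever reaches ``success_level``.
    Requires the reachable state graph to be finite and acyclic (true for
    the toy regulome: induction is monotone while the TF is active,
    relaxation monotone after clearance).
    """
    marking = net.initial_marking()
    for pid, tokens in treatment.items():
        marking[pid] = marking.get(pid, 0.0) + tokens
    memo: dict[tuple, float] = {}

    def rec(m: dict, succeeded: bool, depth: int) -> float:
        if succeeded or m.get(success_place) == success_level:
            return 1.0
        if depth > max_depth:
            raise RecursionError("state graph deeper than max_depth; is it acyclic?")
        key = tuple(sorted(m.items()))
        hit = memo.get(key)
        if hit is not None:
            return hit
        enabled = enabled_transitions(net, m)
        if not enabled:
            p = 0.0
        else:
            p = sum(rec(fire(net, m, tid), False, depth + 1) for tid in enabled) / len(enabled)
        memo[key] = p
        return p

    return rec(marking, False, 0)


# ---------------------------------------------------------------------------
# synthetic uptake observations
# ---------------------------------------------------------------------------


def simulate_uptake_observations(
    vmax: float,
    km: float,
    insulin_scale: float = 1.0,
    noise_sd: float = 0.0,
    times=None,
    seed: int | None = None,
    s0: float = 25.0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Synthetic medium-depletion observations (tidy table).

    Integrates dS/dt = -insulin_scale * vmax * S / (km + S) exactly (Lambert
    W closed form; ``vmax`` in mM/h) and adds independent Gaussian
    observation noise truncated at zero - emulating plate-reader error on
    concentration assays.  Columns: time, replicate, concentration.
    """
    if vmax <= 0 or km <= 0 or insulin_scale <= 0 or s0 <= 0:
        raise ValueError("vmax, km, insulin_scale and s0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times if times is not None else np.linspace(0, 48, 25), dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    truth = mm_depletion(times, s0, insulin_scale * vmax, km)
    rows = []
    for rep in range(1, replicates + 1):
        obs = truth + (rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0)
        rows.append(pd.DataFrame({"time": times, "replicate": rep, "concentration": np.clip(obs, 0.0, None)}))
    return pd.concat(rows, ignore_index=True)
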