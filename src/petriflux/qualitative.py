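"""Qualitative stage: Monte Carlo regulatory trajectories over the GSMN.

Trajectories are sequences of feasible molecular events: at each step the
enabled rule transitions of the regulatory net are enumerated, one is drawn
uniformly at random (seeded), fired, the gene-gated flux bounds are
reapplied, and an FVA flux snapshot of the monitored reactions is recorded.
Simulation time is in arbitrary units and reflects only the order of events.

The flux snapshot is the FVA *maximum* toward each monitored reaction at the
current bounds (biomass fixed): "increased flux towards" a product is read
as a capability statement, which the FVA extremum measures robustly where a
single degenerate FBA vector would not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .coupling import CouplingMap, apply_bounds, bounds_from_marking
from .gsmn import InfeasibleError, MetabolicModel, flux_variability
from .petri import GENE_BASAL, PetriNet, enabled_transitions, fire

logger = logging.getLogger(__name__)

#: consecutive at-baseline steps required to declare a return to baseline
BASELINE_WINDOW = 10
FLUX_TOL = 1e-6


@dataclass
class RegulomeMap:
    """Gene -> regulated-reaction table plus the TF and treatment node ids."""

    entries: list[tuple[str, str, str]]  # (gene, reaction, effect)
    tf: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for gene, rxn, effect in self.entries:
            if effect not in ("activates", "represses"):
                raise ValueError(f"unknown effect {effect!r} for ({gene}, {rxn})")
            if (gene, rxn) in seen:
                continue
            seen.add((gene, rxn))
            deduped.append((gene, rxn, effect))
        self.entries = deduped

    @property
    def genes(self) -> list[str]:
        return sorted({g for g, _, _ in self.entries})

    @property
    def reactions(self) -> list[str]:
        return sorted({r for _, r, _ in self.entries})


def parse_regulome(path, tf: str = "", treatment: str = "") -> RegulomeMap:
    """Read a gene_id / reaction_id / effect table (CSV or TSV).

    Duplicate (gene, reaction) pairs collapse to one entry with a warning;
    unknown effect keywords or missing columns raise with the line number.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"gene_id", "reaction_id", "effect"}
    if not required.issubset(df.columns):
        raise ValueError(f"regulome table needs columns {sorted(required)}, got {list(df.columns)}")
    entries = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        if row.effect not in ("activates", "represses"):
            raise ValueError(f"line {i}: unknown effect keyword {row.effect!r}")
        entries.append((str(row.gene_id), str(row.reaction_id), str(row.effect)))
    n_raw = len(entries)
    rm = RegulomeMap(entries=entries, tf=tf, treatment=treatment)
    if len(rm.entries) < n_raw:
        logger.warning("regulome table: %d duplicate pairs collapsed", n_raw - len(rm.entries))
    logger.info("regulome: %d genes, %d reactions", len(rm.genes), len(rm.reactions))
    return rm


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


@dataclass
class Event:
    step: int
    transition: str
    marking: dict[str, float]
    fluxes: dict[str, float]


@dataclass
class Trajectory:
    events: list[Event]
    seed: int
    baseline_marking: dict[str, float]
    baseline_fluxes: dict[str, float]
    monitored: tuple[str, ...]
    treatment_places: tuple[str, ...] = ()

    def flux_series(self, reaction: str) -> np.ndarray:
        if reaction not in self.monitored:
            raise KeyError(f"reaction {reaction!r} was not monitored")
        return np.array([e.fluxes[reaction] for e in self.events])


@dataclass
class TrajectoryEnsemble:
    trajectories: list[Trajectory]
    master_seed: int
    child_seeds: list[int]
    monitored: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.trajectories)


class _FluxCache:
    """Memoised FVA-max snapshots keyed by the gene-gated bound assignment."""

    def __init__(self, model: MetabolicModel, monitored: tuple[str, ...]):
        self.model = model
        self.monitored = monitored
        self._cache: dict[tuple, dict[str, float]] = {}

    def snapshot(self, assignments: list[tuple[str, float, float]]) -> dict[str, float]:
        key = tuple(assignments)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        apply_bounds(self.model, assignments)
        out = {}
        for rid in self.monitored:
            try:
                _, vmax = flux_variability(self.model, rid)
            except InfeasibleError:
                vmax = float("nan")
            out[rid] = vmax
        self._cache[key] = out
        return out


def _markings_equal(a: dict, b: dict) -> bool:
    return all(abs(a[k] - b[k]) <= 1e-12 for k in b)


def run_trajectory(
    model: MetabolicModel,
    coupling: CouplingMap,
    net: PetriNet,
    treatment: dict[str, float],
    max_steps: int,
    seed: int,
    monitored: tuple[str, ...] = (),
    baseline_window: int = BASELINE_WINDOW,
    _cache: _FluxCache | None = None,
) -> Trajectory:
    """One seeded Monte Carlo trajectory.

    ``treatment`` maps treatment places to token counts applied at onset
    (recorded as the step-0 event).  The loop draws uniformly among enabled
    rule transitions, fires, reapplies gene-gated bounds and snapshots the
    monitored fluxes.  Terminates at ``max_steps``, when no transition is
    enabled, or when the baseline marking has persisted for
    ``baseline_window`` consecutive steps.
    """
    if max_steps <= 0:
        raise ValueError("max_steps must be positive")
    rng = np.random.default_rng(seed)
    monitored = tuple(monitored)
    cache = _cache if _cache is not None else _FluxCache(model.copy(), monitored)

    baseline = dict(net.initial_marking())
    baseline_fluxes = cache.snapshot(bounds_from_marking(coupling, baseline))

    marking = dict(baseline)
    for pid, tokens in treatment.items():
        marking[pid] = marking.get(pid, 0.0) + tokens
    events = [Event(0, "__treatment__", dict(marking), dict(baseline_fluxes))]

    if not treatment and not enabled_transitions(net, marking):
        logger.info("no treatment and no enabled transitions: trivial trajectory")

    at_baseline = 0
    for step in range(1, max_steps + 1):
        enabled = enabled_transitions(net, marking)
        if not enabled:
            break
        tid = enabled[int(rng.integers(len(enabled)))]
        marking = fire(net, marking, tid)
        fluxes = cache.snapshot(bounds_from_marking(coupling, marking))
        events.append(Event(step, tid, dict(marking), fluxes))
        if _markings_equal(marking, baseline):
            at_baseline += 1
            if at_baseline >= baseline_window:
                break
        else:
            at_baseline = 0
    return Trajectory(
        events=events,
        seed=seed,
        baseline_marking=baseline,
        baseline_fluxes=baseline_fluxes,
        monitored=monitored,
        treatment_places=tuple(sorted(treatment)),
    )


def run_ensemble(
    model: MetabolicModel,
    coupling: CouplingMap,
    net: PetriNet,
    treatment: dict[str, float],
    n: int = 100,
    master_seed: int = 0,
    max_steps: int = 200,
    monitored: tuple[str, ...] = (),
    baseline_window: int = BASELINE_WINDOW,
) -> TrajectoryEnsemble:
    """n independent trajectories with child seeds spawned from ``master_seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    monitored = tuple(monitored)
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in ss.spawn(n)]
    cache = _FluxCache(model.copy(), monitored)
    trajectories = [
        run_trajectory(
            model, coupling, net, treatment, max_steps, seed,
            monitored=monitored, baseline_window=baseline_window, _cache=cache,
        )
        for seed in child_seeds
    ]
    return TrajectoryEnsemble(trajectories, master_seed, child_seeds, monitored)


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------


@dataclass
class FractionStatistic:
    fraction: float
    n: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.fraction <= self.ci_high <= 1.0


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n."""
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def fraction_increased_flux(
    ensemble: TrajectoryEnsemble,
    reaction: str,
    baseline_flux: float | None = None,
    tol: float = FLUX_TOL,
) -> FractionStatistic:
    """Fraction of trajectories whose maximal post-treatment flux capability
    toward ``reaction`` exceeds baseline by more than ``tol``, with an exact
    95% Clopper-Pearson interval."""
    if reaction not in ensemble.monitored:
        raise KeyError(f"reaction {reaction!r} was not monitored in this ensemble")
    k = 0
    for traj in ensemble.trajectories:
        base = baseline_flux if baseline_flux is not None else traj.baseline_fluxes[reaction]
        post = traj.flux_series(reaction)[1:]  # exclude the onset snapshot
        if post.size and np.nanmax(post) > base + tol:
            k += 1
    n = ensemble.n
    lo, hi = clopper_pearson(k, n)
    return FractionStatistic(fraction=k / n, n=n, ci_low=lo, ci_high=hi)


# ---------------------------------------------------------------------------
# regulatory-naive control
# ---------------------------------------------------------------------------


def make_regulatory_naive(
    model: MetabolicModel, coupling: CouplingMap, net: PetriNet
) -> tuple[MetabolicModel, CouplingMap, PetriNet]:
    """Freeze all regulation: gene/TF places at basal, regulatory transitions
    removed, gene-gated metabolic bounds fixed at baseline.

    Every rule transition referencing a discrete place (gene or TF level) is
    removed; remaining treatment bookkeeping that depended on regulation is
    therefore inert, so naive trajectories record zero regulatory events.
    """
    from dataclasses import replace

    naive_net = PetriNet(metadata=dict(net.metadata))
    for p in net.places.values():
        if p.discrete:
            lo, hi = p.level_range
            basal = min(max(GENE_BASAL, lo), hi)
            p = replace(p, marking=basal)
        naive_net.add_place(p)
    for t in net.transitions.values():
        touches_discrete = any(
            net.places[a.place].discrete for a in (*t.input_arcs, *t.output_arcs)
        ) or any(net.places[c.place].discrete for c in t.guard)
        if t.mode == "rule" and touches_discrete:
            continue
        naive_net.add_transition(t)
    naive_coupling = CouplingMap(
        activity_lists=dict(coupling.activity_lists),
        objectives=dict(coupling.objectives),
        gene_gates=[],
        baseline_bounds={},
    )
    return model, naive_coupling, naive_net


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------


@dataclass
class PhaseAnnotation:
    """Acute (agonist present) and reconstitutive (post-clearance, pre-baseline)
    intervals in event-step units."""

    acute: tuple[int, int] | None
    reconstitutive: tuple[int, int] | None
    returned_to_baseline: bool


def detect_phases(
    trajectory: Trajectory,
    baseline_marking: dict[str, float] | None = None,
    baseline_fluxes: dict[str, float] | None = None,
    window: int = BASELINE_WINDOW,
) -> PhaseAnnotation:
    """Annotate the acute and reconstitutive phases of one trajectory.

    Acute: [treatment onset, treatment cleared].  Reconstitutive: (cleared,
    first step at which marking and monitored fluxes equal baseline and stay
    there].  A trajectory that never leaves baseline, or carries no
    treatment, gets empty intervals.
    """
    baseline_marking = baseline_marking or trajectory.baseline_marking
    baseline_fluxes = baseline_fluxes or trajectory.baseline_fluxes
    tplaces = trajectory.treatment_places
    events = trajectory.events
    if not tplaces or not events:
        return PhaseAnnotation(None, None, False)

    def treated(e: Event) -> bool:
        return any(e.marking.get(p, 0.0) > 0 for p in tplaces)

    if not any(treated(e) for e in events):
        return PhaseAnnotation(None, None, False)
    onset = next(e.step for e in events if treated(e))
    cleared_idx = next((i for i, e in enumerate(events) if e.step >= onset and not treated(e)), None)
    if cleared_idx is None:
        return PhaseAnnotation((onset, events[-1].step), None, False)
    cleared = events[cleared_idx].step

    def at_baseline(e: Event) -> bool:
        if not _markings_equal(e.marking, baseline_marking):
            return False
        return all(
            abs(e.fluxes[r] - baseline_fluxes[r]) <= FLUX_TOL for r in trajectory.monitored
        )

    back = None
    for i in range(cleared_idx, len(events)):
        if all(at_baseline(e) for e in events[i:][: max(window, 1)]) and at_baseline(events[i]):
            back = events[i].step
            break
    if back is None:
        return PhaseAnnotation((onset, cleared), (cleared, events[-1].step), False)
    if back <= cleared:
        return PhaseAnnotation((onset, cleared), None, True)
    return PhaseAnnotation((onset, cleared), (cleared, back), True)


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------


def flux_heatmap_matrix(trajectory: Trajectory, reactions: list[str]) -> np.ndarray:
    """Signed flux matrix (reactions x event steps) in event order."""
    if not reactions:
        raise ValueError("empty reaction list")
    return np.vstack([trajectory.flux_series(r) for r in reactions])


def render_flux_heatmap(matrix: np.ndarray, reactions: list[str], path) -> None:
    """Render the matrix with positive flux in green, negative in red,
    simulated (arbitrary-unit) time progressing left to right."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    vmax = np.nanmax(np.abs(matrix)) or 1.0
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(reactions) + 1.5))
    im = ax.pcolormesh(matrix, cmap="RdYlGn", norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax))
    ax.set_yticks(np.arange(len(reactions)) + 0.5, reactions)
    ax.set_xlabel("simulated time (arbitrary units, event order)")
    fig.colorbar(im, ax=ax, label="flux (mmol/g DW/h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def coupling_from_regulome(
    regulome: RegulomeMap,
    model: MetabolicModel,
    induction_factor: float = 2.0,
    base: CouplingMap | None = None,
) -> CouplingMap:
    """Build (or extend) a coupling map with one gene gate per regulome edge."""
    from .coupling import GeneGate

    cm = base if base is not None else CouplingMap()
    for gene, rxn, effect in regulome.entries:
        cm.gene_gates.append(GeneGate(gene, rxn, effect, induction_factor))
    cm.bind_baseline(model)
    return cm
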