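# Methods

## Scope and formalism

petriflux couples two model formalisms in one Petri net:

* **continuous** places and transitions for signalling and transport
  (markings are concentrations; transitions carry kinetic laws — constant,
  mass action, or Michaelis–Menten, optionally scaled by modifier places);
* **discrete** places for rule-based gene expression with three stable
  levels (0 inhibited, 1 basal, 2 induced) and guarded transitions:
  `induce` (+1 while an activator is present, up to 2), `repress` (−1 while
  an inhibitor is present, down to 0), and `relax` transitions that restore
  the basal level in a single firing once all regulators are absent.
  A regulator counts as "present" when its continuous marking is > 0 or its
  discrete level equals 2; the levels themselves come with no kinetic time
  scale.

The metabolic side is a standard constraint-based model: sparse
stoichiometry, per-reaction bounds in mmol/g DW/h, an exchange set, and a
biomass function applied as a fixed demand constraint (the monitored
reaction, not biomass, is always the LP objective). LPs are solved with
HiGHS through `scipy.optimize.linprog` at a requested feasibility tolerance
of 1e-9; results are asserted to 1e-6, leaving headroom between solver and
test thresholds. Objective values are the contract; returned flux vectors
may be one of several alternative optima, detectable on request by fixing
the objective and scanning the remaining reactions with FVA. SBML I/O for
metabolic models goes through COBRApy (L3+FBC); kinetic SBML models are
imported by classifying each reaction's rate-law expression symbolically,
and anything unclassifiable is listed in an import report rather than
silently dropped.

## The quasi-steady-state coupling

Constraint places own *activity lists* that translate their marking into
flux bounds: a kinetic entry computes a magnitude `m = Vmax·S/(Km+S)` and
emits `(−m, +m)` when symmetric, `(−m, 0)` otherwise; interval entries emit
explicit bounds for the matched marking interval and leave baseline bounds
untouched otherwise. The symmetric reading means the *export* bound always
equals the uptake bound computed from the current medium concentration —
the simplest interpretation that still permits gluconeogenic glucose export
in the minimised-transport direction. Gene gates scale a reaction's upper
bound by expression level (0 → closed, 1 → baseline, 2 → an induction
factor, default 2×; repressive edges invert the mapping). Each reaction may
be controlled by at most one source per step; conflicts are structural
errors raised at validation.

Objective places read solved fluxes back into markings:
`ΔC = φ·v·Δt`, with uptake (negative flux) depleting the medium. The unit
factor φ (g DW per litre of medium) is built from medium volume per 10⁶
cells (default 0.58 mL), dry mass per cell (default 300 pg, a typical
hepatocyte figure), and cell count. The 0.58 mL default is back-derived
from paired in-vitro observations in which a 9.3 mM drop in medium glucose
corresponds to ~0.97 mg glucose per million cells
(9.3 mmol/L × 180.16 g/mol × 0.58 mL ≈ 0.97 mg); both factors are
config-overridable. The intracellular TAG accumulator uses the same φ and
does not feed back into the model (envelopes are reported, not product
inhibition).

## Dynamic FVA

A dFVA run is **two independent dynamic simulations**, one per LP direction
of the objective, each propagating its own medium state. This is required
because the two directions have genuinely different medium dynamics (e.g.
maximised uptake depletes the medium, minimised transport can accumulate
exported product), so a per-step min/max pair along one trajectory would
not bound the feasible envelope. Steps use explicit Euler with default
dt = 0.1 h over a 48 h horizon; Euler suffices because the per-step LP
dominates the error budget, and convergence is checked against dt/10 runs
(first-order agreement) rather than by committing to a specific authors'
step size. Negative concentrations arising within a step are clipped to
zero with a logged warning. An infeasible LP (typically at substrate
exhaustion, once the transport bound can no longer fund the biomass demand)
is recorded, the flux is reported as absent, and the simulation continues —
flux terminates, the run does not. Quantitative runs involve no randomness
and are bit-reproducible.

AUCs are trapezoidal on the stored grid with linear interpolation of
partial end intervals. The Michaelis–Menten depletion fitter uses the exact
Lambert-W closed form of `dS/dt = −Vmax·S/(Km+S)` inside nonlinear least
squares (`scipy.optimize.curve_fit`), with Vmax expressed in medium units
(mM/h, i.e. specific flux × φ); a time course whose relative drop is below
5% raises an identifiability error instead of returning estimates.

## Qualitative Monte Carlo

Trajectories are sequences of feasible molecular events in arbitrary time
units (event order only). The scheduler draws **uniformly at random** among
enabled rule transitions — the minimal-assumption policy for a qualitative
model, isolated behind a single choice point. Each event reapplies the
gene-gated bounds and snapshots the monitored reactions' **FVA maxima**
(biomass fixed): "increased flux towards" a product is a capability
statement, and the FVA extremum is robust to LP degeneracy where a single
FBA vector is not. Snapshots are memoised on the bound assignment, so
ensembles over a small regulome cost one LP batch per reachable expression
state. Termination: `max_steps` (default 200), an empty enabled set, or the
baseline marking persisting for 10 consecutive steps (a debounce window;
both are config). Ensembles derive child seeds from a master seed via
`numpy.random.SeedSequence`, making every statistic bit-reproducible.

The fraction-of-trajectories statistic counts trajectories whose maximal
post-treatment capability exceeds baseline by more than 1e-6, with an exact
95% Clopper–Pearson interval. Phase detection marks the acute interval
(treatment onset to clearance) and the reconstitutive interval (clearance
until marking *and* monitored fluxes return to baseline and persist);
trajectories without treatment get empty annotations. The
regulatory-naive control freezes every discrete place at basal and removes
all rule transitions touching discrete places, so naive trajectories record
zero regulatory events and their metabolic bounds stay at baseline.
Heatmaps render signed fluxes with positive values green and negative red,
event order left to right.

## Synthetic study conditions

**Toy hepatocyte network** (21 reactions, 15 metabolites): glucose and
fructose exchanges and transporters, a capacity-capped committed glycolytic
step GK (lumped glucokinase/PFK, cap 1.5 mmol/g DW/h), a fructolytic bypass
KHK with equal cap, gluconeogenesis, a reversible triose–pyruvate–lactate
spine, pyruvate oxidation, respiration, lumped de novo lipogenesis
(8 acetyl-CoA → 1 fatty acid), TAG synthesis (3 FA + 1 triose backbone),
a TAG sink (the production objective), and a biomass demand of 2 glucose
per unit (default demand 0.05). The arithmetic fits on one line: each TAG
unit costs 25 triose, so `v_TAG = 2·min(uptake − 2·demand, cap_GK)/25` on
glucose and `(2·min(uptake, cap_KHK) − 4·demand)/25` on fructose (biomass
funded through gluconeogenesis). Equal caps make the two sugars' lipogenic
ceilings equal by construction, mirroring the biological finding the
package is built to interrogate; the generator refuses specs whose caps
make the biomass demand unreachable.

**Transport kinetics** (toy defaults): glucose Vmax 5.0 mmol/g DW/h,
Km 5 mM; fructose Vmax 3.0, Km 10 — chosen so that from 25 mM the glucose
medium empties within the 48 h horizon while fructose does not, and the
committed-step cap (not transport) limits TAG until the late uptake-limited
tail. The insulin mini-cascade (insulin → pAKT, mass action k₁ = 0.01/h,
decay k₂ = 1/h) scales glucose transporter Vmax by
`1 + 0.15·pAKT/(0.5 + pAKT)` (~+10% at 100 nM insulin), a modest transport
effect that leaves the TAG envelope asymptotically unchanged.

**Toy regulome** (defaults: 2 genes, 2 treatment tokens): a fatty-acid
treatment place activates the TF node; target genes follow the three-level
motif with the TF as activator; the first gene gates the TAG sink, whose
baseline cap (0.1 mmol/g DW/h) binds below the substrate-supported 0.12, so
induction measurably raises the capability. In the default variant,
treatment clearance is gated on the fully induced program (clearance
through induced catabolism), which makes induction of the TAG gene certain
before clearance — the naive-vs-competent contrast setting. The
calibration variant clears treatment unconditionally, so clearance competes
with induction and the success probability lies strictly inside (0, 1);
an exhaustive enumeration of all firing orders (exact, memoised over the
finite acyclic state graph) supplies the ground-truth probability that
ensemble statistics are calibrated against.

**Observation noise**: additive Gaussian truncated at zero on the exact
depletion curve — plate-reader-style symmetric assay error on
concentrations.

What the toys deliberately omit: genome-scale redundancy and alternative
pathways, cofactor and energy balancing, real gene-expression kinetics,
multi-transcription-factor crosstalk, and product feedback. Passing tests
therefore demonstrate the correctness of the machinery (LP agreement with a
brute-force oracle, envelope ordering, mass balance, calibration of the
trajectory statistics), not quantitative predictions for real hepatocytes;
those require a curated genome-scale model plus measured kinetic and
regulome tables supplied through the SBML, bounds-override TSV and regulome
CSV interfaces.

## Problem sizes and numerical choices

Default test and acceptance workloads: 48 h dFVA at dt = 0.1 (480 LPs per
direction), 300–1000 random ≤8-reaction networks for oracle comparison,
50 replicates for parameter recovery, ensembles of 100 (contrast) and
100×1000 (calibration) trajectories with memoised snapshots. Ties in any
deterministic enumeration break lexicographically by id. Seeds are always
explicit; derived seeds are masked below 2³¹.

## Known limitations

* Explicit Euler is first-order; stiff signalling models need small dt.
* The rule scheduler is uniform-random only (config-swappable by passing a
  different drawing policy is not yet exposed).
* Gene gates scale upper bounds only; reactions whose regulation acts on
  reverse capacity need their bounds encoded in the forward sense.
* `make_regulatory_naive` removes every rule transition touching a discrete
  place; nets in which treatment bookkeeping must survive gene freezing
  need a hand-built naive variant.
* Simulated qualitative time is event order, not clock time: the duration
  of the reconstitutive phase is not a prediction.
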