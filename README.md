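# petriflux

Hybrid Petri-net / genome-scale metabolic network simulation for studying
hepatocyte sugar and fat metabolism — in particular how monosaccharide
transport kinetics and transcription-factor regulation shape triacylglycerol
(TAG) production, the lipid endpoint of steatosis in non-alcoholic fatty
liver disease.

The package is aimed at systems-biology modellers who want to couple dynamic
regulatory or signalling models to constraint-based metabolic models without
committing to a single formalism: continuous kinetic nodes (Michaelis–Menten
transport, mass-action signalling) and discrete rule-based nodes (three-level
gene expression) coexist in one Petri net, and a quasi-steady-state contract
translates markings into flux bounds and solved fluxes back into markings.

## The model

**Metabolic side.** A stoichiometric model `N` (metabolites × reactions) with
flux bounds `lb ≤ v ≤ ub` is solved at quasi-steady state by linear
programming: FBA maximises/minimises one reaction's flux subject to
`N·v = 0`, and FVA reports the feasible range of a reaction under fixed
constraints. A biomass function is applied as a *constraint* (fixed demand),
never as the objective. Exchange fluxes follow the convention *positive =
release into medium, negative = uptake*.

**Dynamic FVA (dFVA).** Two independent time-stepped simulations — one per
LP direction of the objective — bound the feasible trajectory envelope.
Each step: (1) explicit-Euler update of the kinetic signalling net;
(2) activity lists map medium concentrations to transport bounds through
Michaelis–Menten laws, `m = Vmax·S/(Km+S)`, emitted symmetrically as
`(−m, +m)`; (3) the LP is solved; (4) solved fluxes update the medium via
the unit factor φ (g DW/L), `ΔC = φ·v·Δt`. Insulin acts as a kinetic
modifier scaling transporter Vmax.

**Qualitative Monte Carlo.** Gene places take levels {0 = inhibited,
1 = basal, 2 = induced}, reversibly driven by a transcription-factor node
that activates while an agonist (fatty-acid treatment) is present. Gene
levels gate reaction upper bounds (level 0 → closed, level 2 → induction
factor × baseline). Trajectories draw uniformly among enabled rule
transitions; ensembles of seeded trajectories yield fraction-of-trajectories
statistics with exact Clopper–Pearson intervals, phase annotations (acute
vs. post-clearance *reconstitutive* phase), and sign-coloured flux heatmaps.

Everything runs on built-in synthetic study conditions: a ~20-reaction
hepatocyte-like network (glucose and fructose routes, with fructolysis
bypassing the capacity-capped committed glycolytic step, lumped de novo
lipogenesis and TAG synthesis) and an enumerable toy regulome. Full
genome-scale models load through the SBML/FBC reader.

## Worked example

`python examples/02_dfva_envelope.py`:

```
glucose   insulin=    0 nM: initial TAG flux 0.120 mmol/g DW/h, AUC_0-48   61.15 mM*h
glucose   insulin=  100 nM: initial TAG flux 0.120 mmol/g DW/h, AUC_0-48   61.22 mM*h
fructose  insulin=    0 nM: initial TAG flux 0.112 mmol/g DW/h, AUC_0-48   56.62 mM*h
fructose  insulin=  100 nM: initial TAG flux 0.112 mmol/g DW/h, AUC_0-48   56.62 mM*h
```

The initial maximal TAG flux is committed-step-limited (0.120 = 2×1.5/25
mmol/g DW/h: twice the glycolytic cap in triose units over the 25 triose
needed per TAG), so insulin — which only raises the transport bound — shifts
the 48-h envelope by ~0.1%, and the two sugars have near-identical lipogenic
ceilings. The minimised direction produces no TAG at all.

`python examples/04_regulome_ensemble.py`:

```
competent model: fraction with increased TAG capability = 1.00 (95% CI 0.96-1.00, n=100)
naive model:     fraction with increased TAG capability = 0.00
one competent trajectory: acute phase steps (0, 5), reconstitutive (5, 8), returned to baseline: True
```

With regulation frozen at basal levels, extra substrate alone never raises
the TAG flux ceiling; with the transcription factor active, every sampled
event order induces the gating genes, and the altered fluxes persist past
agonist clearance (the reconstitutive phase).

The other examples cover FBA/FVA on the toy network against a one-line hand
calculation (`01`) and Michaelis–Menten parameter recovery from noisy
depletion data (`03`). A thin CLI wraps the same calls:
`petriflux simulate-dfva`, `simulate-qualitative`, `synth`, `validate-model`.

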