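"""Petri-net core: guards, firing, Euler integration, kinetics, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petriflux import (
    Arc,
    Condition,
    FiringError,
    KineticLaw,
    Modifier,
    PetriNet,
    Place,
    StructuralError,
    Transition,
    add_gene_motif,
    enabled_transitions,
    fire,
    kinetic_step,
    mm_rate,
)
from petriflux.petri import GENE_BASAL, GENE_INDUCED, net_from_dict, net_to_dict


def make_motif_net(activator_marking=1.0):
    net = PetriNet()
    net.add_place(Place("act", kind="species", marking=activator_marking))
    add_gene_motif(net, "g1", activators=["act"])
    net.validate()
    return net


class TestMMRate:
    def test_half_saturation_identity(self):
        law = KineticLaw(form="michaelis_menten", vmax=10.0, km=2.5)
        assert mm_rate(2.5, law) == pytest.approx(5.0, abs=0)

    def test_zero_substrate_gives_zero_flux(self):
        law = KineticLaw(form="michaelis_menten", vmax=10.0, km=2.5)
        assert mm_rate(0.0, law) == 0.0

    def test_saturation_asymptote(self):
        law = KineticLaw(form="michaelis_menten", vmax=10.0, km=2.5)
        assert mm_rate(100 * 2.5, law) >= 0.99 * 10.0

    def test_negative_substrate_rejected(self):
        law = KineticLaw(form="michaelis_menten", vmax=1.0, km=1.0)
        with pytest.raises(ValueError):
            mm_rate(-0.1, law)

    def test_modifier_scales_rate(self):
        law = KineticLaw(
            form="michaelis_menten", vmax=10.0, km=2.5,
            modifiers=(Modifier("pakt", "saturating", a=0.5, K=1.0),),
        )
        # pakt = 1 -> scale 1 + 0.5 * 1/2 = 1.25
        assert mm_rate(2.5, law, {"pakt": 1.0}) == pytest.approx(6.25)

    @given(st.floats(0.0, 1e6), st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_rate_bounded_by_vmax_and_nonnegative(self, S, vmax, km):
        law = KineticLaw(form="michaelis_menten", vmax=vmax, km=km)
        r = mm_rate(S, law)
        assert 0.0 <= r <= vmax


class TestRuleSemantics:
    def test_empty_net_has_no_enabled_transitions(self):
        net = PetriNet()
        assert enabled_transitions(net, {}) == []

    def test_motif_with_activator_enables_induce(self):
        net = make_motif_net(activator_marking=1.0)
        enabled = enabled_transitions(net, net.initial_marking())
        assert enabled == ["g1__induce__act"]

    def test_enabled_set_matches_bruteforce_guard_evaluation(self):
        # 3-transition toy net checked against direct guard/arc evaluation
        net = PetriNet()
        net.add_place(Place("a", marking=2.0))
        net.add_place(Place("b", marking=0.0))
        net.add_transition(Transition("t1", guard=(Condition("a", "gt", 1.0),),
                                      input_arcs=(Arc("a", 1, "consume"),)))
        net.add_transition(Transition("t2", guard=(Condition("b", "gt", 0.0),)))
        net.add_transition(Transition("t3", input_arcs=(Arc("a", 3, "consume"),)))
        net.validate()
        for marking in ({"a": 2.0, "b": 0.0}, {"a": 3.0, "b": 1.0}, {"a": 0.0, "b": 0.5}):
            expect = []
            for tid, t in net.transitions.items():
                ok = all(c.holds(marking) for c in t.guard)
                ok = ok and all(marking[arc.place] >= arc.weight
                                for arc in t.input_arcs if arc.kind in ("consume", "test"))
                if ok:
                    expect.append(tid)
            assert enabled_transitions(net, marking) == sorted(expect)

    def test_induce_raises_gene_level(self):
        net = make_motif_net()
        m1 = fire(net, net.initial_marking(), "g1__induce__act")
        assert m1["g1"] == GENE_INDUCED

    def test_consume_clears_treatment_token(self):
        net = PetriNet()
        net.add_place(Place("fa", kind="treatment", marking=1.0))
        net.add_transition(Transition("clear", input_arcs=(Arc("fa", 1, "consume"),)))
        assert fire(net, net.initial_marking(), "clear")["fa"] == 0.0

    def test_fire_matches_arc_arithmetic_on_random_nets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            net = PetriNet()
            n_places = int(rng.integers(2, 6))
            for i in range(n_places):
                net.add_place(Place(f"p{i}", marking=float(rng.integers(0, 5))))
            ins = tuple(Arc(f"p{i}", float(rng.integers(1, 3)), "consume")
                        for i in rng.choice(n_places, 2, replace=False))
            outs = tuple(Arc(f"p{i}", float(rng.integers(1, 3)), "produce")
                         for i in rng.choice(n_places, 1))
            net.add_transition(Transition("t", input_arcs=ins, output_arcs=outs))
            marking = net.initial_marking()
            if "t" not in enabled_transitions(net, marking):
                continue
            got = fire(net, marking, "t")
            expect = dict(marking)
            for a in ins:
                expect[a.place] -= a.weight
            for a in outs:
                expect[a.place] += a.weight
            assert got == expect

    def test_firing_disabled_transition_raises(self):
        net = make_motif_net(activator_marking=0.0)
        with pytest.raises(FiringError):
            fire(net, net.initial_marking(), "g1__induce__act")

    def test_test_and_inhibit_arcs_leave_marking_unchanged(self):
        net = PetriNet()
        net.add_place(Place("a", marking=2.0))
        net.add_place(Place("b", marking=0.0))
        net.add_transition(Transition("t", input_arcs=(Arc("a", 1, "test"), Arc("b", 1, "inhibit"))))
        assert fire(net, net.initial_marking(), "t") == {"a": 2.0, "b": 0.0}

    def test_unknown_guard_place_is_structural_error(self):
        net = PetriNet()
        net.add_place(Place("a"))
        net.add_transition(Transition("t", guard=(Condition("ghost", "gt", 0),)))
        with pytest.raises(StructuralError):
            net.validate()

    @given(st.integers(0, 2))
    @settings(max_examples=10, deadline=None)
    def test_motif_reversibility_one_relax_firing_restores_basal(self, level):
        """With all regulators absent, any level returns to basal in <= 1 firing."""
        net = make_motif_net(activator_marking=0.0)
        marking = net.initial_marking()
        marking["g1"] = level
        enabled = enabled_transitions(net, marking)
        if level == GENE_BASAL:
            assert enabled == []
        else:
            assert len(enabled) == 1
            marking = fire(net, marking, enabled[0])
            assert marking["g1"] == GENE_BASAL
            assert enabled_transitions(net, marking) == []

    def test_fire_is_deterministic(self):
        net = make_motif_net()
        m = net.initial_marking()
        assert fire(net, m, "g1__induce__act") == fire(net, m, "g1__induce__act")


class TestKineticStep:
    def decay_net(self, k=1.0, x0=1.0):
        net = PetriNet()
        net.add_place(Place("x", marking=x0))
        net.add_transition(Transition("decay", mode="kinetic",
                                      input_arcs=(Arc("x", 1, "consume"),),
                                      rate_law=KineticLaw(form="mass_action", k=k)))
        net.validate()
        return net

    def test_zero_rates_leave_marking_unchanged(self):
        net = self.decay_net(k=0.0)
        assert kinetic_step(net, net.initial_marking(), 0.1) == {"x": 1.0}

    def test_first_order_decay_euler_arithmetic(self):
        net = self.decay_net(k=1.0, x0=1.0)
        out = kinetic_step(net, net.initial_marking(), 0.1)
        assert out["x"] == pytest.approx(0.9)

    def test_negative_dt_rejected(self):
        net = self.decay_net()
        with pytest.raises(ValueError):
            kinetic_step(net, net.initial_marking(), -0.1)

    def test_clipping_prevents_negative_concentration(self):
        net = self.decay_net(k=100.0, x0=0.5)
        out = kinetic_step(net, net.initial_marking(), 1.0)
        assert out["x"] == 0.0

    def test_cascade_converges_first_order_to_fine_step_reference(self):
        """Two-step cascade: coarse dt agrees with dt/100 within O(dt)."""
        def cascade():
            net = PetriNet()
            net.add_place(Place("a", marking=1.0))
            net.add_place(Place("b", marking=0.0))
            net.add_transition(Transition("a2b", mode="kinetic",
                                          input_arcs=(Arc("a", 1, "consume"),),
                                          output_arcs=(Arc("b", 1, "produce"),),
                                          rate_law=KineticLaw(form="mass_action", k=1.0)))
            net.add_transition(Transition("bdecay", mode="kinetic",
                                          input_arcs=(Arc("b", 1, "consume"),),
                                          rate_law=KineticLaw(form="mass_action", k=0.5)))
            net.validate()
            return net

        net = cascade()
        dt, T = 0.1, 2.0
        coarse = net.initial_marking()
        for _ in range(int(T / dt)):
            coarse = kinetic_step(net, coarse, dt)
        fine = net.initial_marking()
        for _ in range(int(T / (dt / 100))):
            fine = kinetic_step(net, fine, dt / 100)
        for pid in ("a", "b"):
            assert abs(coarse[pid] - fine[pid]) < 5 * dt  # first-order bound


class TestJsonRoundTrip:
    def test_round_trip_preserves_structure(self):
        net = make_motif_net()
        net.add_transition(Transition("k", mode="kinetic",
                                      input_arcs=(Arc("act", 1, "consume"),),
                                      rate_law=KineticLaw(form="michaelis_menten", vmax=2.0, km=0.5,
                                                          substrate="act",
                                                          modifiers=(Modifier("act", "linear", a=0.1),))))
        back = net_from_dict(net_to_dict(net))
        assert net_to_dict(back) == net_to_dict(net)
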