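"""Monte Carlo regulatory trajectories, ensemble statistics, phases."""

import numpy as np
import pytest
from scipy.stats import binomtest

from petriflux import (
    clopper_pearson,
    detect_phases,
    flux_heatmap_matrix,
    fraction_increased_flux,
    make_regulatory_naive,
    parse_regulome,
    render_flux_heatmap,
    run_ensemble,
    run_trajectory,
)
from petriflux.petri import enabled_transitions, fire
from petriflux.qualitative import Event, Trajectory
from petriflux.synth import (
    TAG_GENE,
    TREATMENT_PLACE,
    ToyRegulomeSpec,
    enumerate_success_probability,
    make_toy_qualitative_setup,
)


def run_one(setup, seed=0, treatment=None, max_steps=200):
    return run_trajectory(setup.model, setup.coupling, setup.net,
                          treatment if treatment is not None else setup.treatment,
                          max_steps, seed, monitored=setup.monitored)


class TestRunTrajectory:
    def test_no_treatment_stays_at_baseline_with_zero_events(self, toy_qual_setup):
        traj = run_one(toy_qual_setup, treatment={})
        assert len(traj.events) == 1  # onset bookkeeping only
        assert traj.events[0].marking == traj.baseline_marking

    def test_fixed_seed_is_bit_reproducible(self, toy_qual_setup):
        a = run_one(toy_qual_setup, seed=123)
        b = run_one(toy_qual_setup, seed=123)
        assert [(e.step, e.transition, e.marking, e.fluxes) for e in a.events] == \
               [(e.step, e.transition, e.marking, e.fluxes) for e in b.events]

    def test_every_event_was_enabled_at_its_predecessor(self, toy_qual_setup):
        """Replayable audit: firing the recorded sequence reproduces the markings."""
        traj = run_one(toy_qual_setup, seed=5)
        net = toy_qual_setup.net
        marking = traj.events[0].marking
        for e in traj.events[1:]:
            assert e.transition in enabled_transitions(net, marking)
            marking = fire(net, marking, e.transition)
            assert marking == e.marking

    def test_first_event_choice_is_uniform(self, toy_qual_setup):
        """After TF activation the enabled set has n_genes induce transitions;
        the scheduler's choice among them is uniform (exact binomial test)."""
        counts = {}
        n = 2000
        for seed in range(n):
            traj = run_one(toy_qual_setup, seed=seed, max_steps=2)
            second = traj.events[2].transition  # event 1 is tf_activate (only enabled)
            counts[second] = counts.get(second, 0) + 1
        assert len(counts) == 2
        for k in counts.values():
            assert binomtest(k, n, 0.5).pvalue > 1e-4

    def test_max_steps_truncates(self, toy_qual_setup):
        traj = run_one(toy_qual_setup, seed=1, max_steps=2)
        assert len(traj.events) == 3


class TestEnsemble:
    def test_single_trajectory_ensemble(self, toy_qual_setup):
        ens = run_ensemble(toy_qual_setup.model, toy_qual_setup.coupling, toy_qual_setup.net,
                           toy_qual_setup.treatment, n=1, master_seed=9,
                           monitored=toy_qual_setup.monitored)
        assert ens.n == 1 and len(ens.child_seeds) == 1

    def test_same_master_seed_gives_identical_ensembles(self, toy_qual_setup):
        s = toy_qual_setup
        kw = dict(n=8, master_seed=4, monitored=s.monitored)
        a = run_ensemble(s.model, s.coupling, s.net, s.treatment, **kw)
        b = run_ensemble(s.model, s.coupling, s.net, s.treatment, **kw)
        assert a.child_seeds == b.child_seeds
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert [e.transition for e in ta.events] == [e.transition for e in tb.events]

    def test_invalid_n_rejected(self, toy_qual_setup):
        with pytest.raises(ValueError):
            run_ensemble(toy_qual_setup.model, toy_qual_setup.coupling, toy_qual_setup.net,
                         toy_qual_setup.treatment, n=0)


class TestFractionStatistic:
    def test_all_and_none_increased(self, toy_qual_setup):
        s = toy_qual_setup
        ens = run_ensemble(s.model, s.coupling, s.net, s.treatment, n=20, master_seed=0,
                           monitored=s.monitored)
        stat = fraction_increased_flux(ens, "TAG_PROD")
        assert stat.fraction == 1.0 and stat.ci_high == 1.0
        none = fraction_increased_flux(ens, "TAG_PROD", baseline_flux=1e9)
        assert none.fraction == 0.0 and none.ci_low == 0.0

    def test_unmonitored_reaction_raises(self, toy_qual_setup):
        s = toy_qual_setup
        ens = run_ensemble(s.model, s.coupling, s.net, s.treatment, n=2, master_seed=0,
                           monitored=s.monitored)
        with pytest.raises(KeyError):
            fraction_increased_flux(ens, "GK")

    def test_clopper_pearson_brackets_the_point_estimate(self):
        for k, n in ((0, 10), (5, 10), (10, 10), (37, 100)):
            lo, hi = clopper_pearson(k, n)
            assert 0.0 <= lo <= k / n <= hi <= 1.0

    def test_empirical_fraction_within_exact_band_of_enumerated_p(self):
        """Calibration toy (unconditional clearance): empirical fraction at
        n = 1000 falls inside the exact 95% binomial band around p*."""
        from scipy.stats import binom

        setup = make_toy_qualitative_setup(ToyRegulomeSpec(clearance_requires_induction=False))
        p_star = enumerate_success_probability(setup.net, setup.treatment)
        assert 0.0 < p_star < 1.0
        n = 1000
        ens = run_ensemble(setup.model, setup.coupling, setup.net, setup.treatment,
                           n=n, master_seed=77, monitored=setup.monitored)
        stat = fraction_increased_flux(ens, "TAG_PROD")
        lo, hi = binom.ppf(0.025, n, p_star) / n, binom.ppf(0.975, n, p_star) / n
        assert lo <= stat.fraction <= hi


class TestNaiveControl:
    def test_naive_model_has_zero_regulatory_events(self, toy_qual_setup):
        s = toy_qual_setup
        m, c, net = make_regulatory_naive(s.model, s.coupling, s.net)
        ens = run_ensemble(m, c, net, s.treatment, n=10, master_seed=3, monitored=s.monitored)
        assert all(len(t.events) == 1 for t in ens.trajectories)

    def test_naive_fraction_is_zero_competent_at_least_point_nine(self, toy_qual_setup):
        s = toy_qual_setup
        m, c, net = make_regulatory_naive(s.model, s.coupling, s.net)
        naive = run_ensemble(m, c, net, s.treatment, n=100, master_seed=11, monitored=s.monitored)
        assert fraction_increased_flux(naive, "TAG_PROD").fraction == 0.0
        comp = run_ensemble(s.model, s.coupling, s.net, s.treatment, n=100, master_seed=11,
                            monitored=s.monitored)
        assert fraction_increased_flux(comp, "TAG_PROD").fraction >= 0.9

    def test_enumeration_gives_certain_induction_for_gated_clearance(self, toy_qual_setup):
        assert enumerate_success_probability(toy_qual_setup.net, toy_qual_setup.treatment) == 1.0


class TestPhases:
    def test_trajectory_never_leaving_baseline_has_empty_intervals(self, toy_qual_setup):
        traj = run_one(toy_qual_setup, treatment={})
        ann = detect_phases(traj)
        assert ann.acute is None and ann.reconstitutive is None

    def test_constructed_square_pulse_boundaries(self):
        """Hand-built trajectory: treatment on steps 0-3, back to baseline at 6."""
        base_m = {"fa": 0.0, "g": 1}
        base_f = {"TAG": 1.0}
        rows = [(0, {"fa": 2.0, "g": 1}, 1.0), (1, {"fa": 1.0, "g": 2}, 2.0),
                (2, {"fa": 0.0, "g": 2}, 2.0), (3, {"fa": 0.0, "g": 2}, 2.0),
                (4, {"fa": 0.0, "g": 1}, 1.0), (5, {"fa": 0.0, "g": 1}, 1.0)]
        traj = Trajectory(
            events=[Event(s, f"t{s}", m, {"TAG": f}) for s, m, f in rows],
            seed=0, baseline_marking=base_m, baseline_fluxes=base_f,
            monitored=("TAG",), treatment_places=("fa",),
        )
        ann = detect_phases(traj, window=1)
        assert ann.acute == (0, 2)
        assert ann.reconstitutive == (2, 4)
        assert ann.returned_to_baseline

    def test_competent_has_reconstitutive_phase_naive_does_not(self, toy_qual_setup):
        s = toy_qual_setup
        comp = run_one(s, seed=2)
        ann = detect_phases(comp)
        assert ann.reconstitutive is not None and ann.returned_to_baseline
        m, c, net = make_regulatory_naive(s.model, s.coupling, s.net)
        naive = run_trajectory(m, c, net, s.treatment, 50, 2, monitored=s.monitored)
        assert detect_phases(naive).reconstitutive is None


class TestHeatmap:
    def test_matrix_shape_and_column_count(self, toy_qual_setup):
        traj = run_one(toy_qual_setup, seed=8)
        mat = flux_heatmap_matrix(traj, ["TAG_PROD"])
        assert mat.shape == (1, len(traj.events))

    def test_sign_flip_changes_colour_class_at_flip_index(self):
        fluxes = [1.0, 1.0, -1.0]
        traj = Trajectory(
            events=[Event(i, f"t{i}", {}, {"R": f}) for i, f in enumerate(fluxes)],
            seed=0, baseline_marking={}, baseline_fluxes={"R": 1.0}, monitored=("R",),
        )
        mat = flux_heatmap_matrix(traj, ["R"])
        assert np.sign(mat[0]).tolist() == [1.0, 1.0, -1.0]

    def test_empty_reaction_list_rejected(self, toy_qual_setup):
        traj = run_one(toy_qual_setup, seed=8)
        with pytest.raises(ValueError):
            flux_heatmap_matrix(traj, [])

    def test_rendering_writes_a_figure(self, toy_qual_setup, tmp_path):
        traj = run_one(toy_qual_setup, seed=8)
        out = tmp_path / "heat.svg"
        render_flux_heatmap(flux_heatmap_matrix(traj, ["TAG_PROD"]), ["TAG_PROD"], out)
        assert out.stat().st_size > 0


class TestParseRegulome:
    def test_two_line_fixture(self, tmp_path):
        path = tmp_path / "reg.csv"
        path.write_text("gene_id,reaction_id,effect\nG1,R1,activates\nG1,R2,represses\n")
        rm = parse_regulome(path)
        assert rm.genes == ["G1"] and rm.reactions == ["R1", "R2"]

    def test_duplicate_pair_collapses_to_single_entry(self, tmp_path):
        path = tmp_path / "reg.csv"
        path.write_text("gene_id,reaction_id,effect\nG1,R1,activates\nG1,R1,activates\n")
        assert len(parse_regulome(path).entries) == 1

    def test_unknown_effect_reports_line_number(self, tmp_path):
        path = tmp_path / "reg.csv"
        path.write_text("gene_id,reaction_id,effect\nG1,R1,activates\nG2,R2,boosts\n")
        with pytest.raises(ValueError, match="line 3"):
            parse_regulome(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "reg.csv"
        path.write_text("gene,reaction\nG1,R1\n")
        with pytest.raises(ValueError, match="gene_id"):
            parse_regulome(path)
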