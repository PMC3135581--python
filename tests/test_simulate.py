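"""Two-step simulation: seed determinism, degenerate laws, tie conventions,
and distributional recovery against brute-force oracles."""

import numpy as np
import pytest

from crsim import (
    TAIL,
    CompetingRisksDataset,
    SimulationConfig,
    Scenario,
    aalen_johansen,
    build_law,
    draw_event,
    kaplan_meier,
    nelson_aalen,
    simulate_arm,
    simulate_trial,
)
from crsim.errors import UnspentCensoringMassWarning
from crsim.estimators import SurvivalCurve
from crsim.lawkit import EmpiricalLaw


def make_law(support, mass, tail, p1, cens_times, cens_values, tmax=None):
    return EmpiricalLaw(
        support=np.asarray(support, float),
        time_mass=np.asarray(mass, float),
        tail_mass=tail,
        type1_prob=np.asarray(p1, float),
        censoring=SurvivalCurve(
            jump_times=np.asarray(cens_times, float),
            values=np.asarray(cens_values, float),
            role="censoring",
            tmax=tmax,
        ),
    )


class TestDrawEvent:
    def test_degenerate_point_mass(self):
        law = make_law([2.0], [1.0], 0.0, [1.0], [5.0], [0.0])
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert draw_event(law, rng) == (2.0, 1)

    def test_pure_tail_law_draws_sentinel(self):
        law = make_law([1.0], [0.0], 1.0, [0.5], [5.0], [0.0])
        t, cause = draw_event(law, np.random.default_rng(1))
        assert t == TAIL and cause is None

    def test_draw_frequencies_match_hand_law(self, hand_data):
        law = build_law(hand_data)
        rng = np.random.default_rng(7)
        sim = simulate_arm(law, 1_000_000, rng)
        # censoring KM of the hand data puts half its mass at 3, half beyond
        for t, c, p in [(1.0, 1, 0.25), (2.0, 2, 0.25), (4.0, 1, 0.5)]:
            freq = np.mean((sim.time == t) & (sim.status == c))
            # events at 4 are censored when C=3 (prob 1/2)
            expect = p if t < 3 else p / 2
            assert freq == pytest.approx(expect, abs=3e-3)


class TestSimulateArm:
    def test_seed_determinism(self, control_law):
        a = simulate_arm(control_law, 500, np.random.default_rng(42))
        b = simulate_arm(control_law, 500, np.random.default_rng(42))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.status, b.status)

    def test_pure_tail_law_fully_censored(self):
        law = make_law([1.0], [0.0], 1.0, [1.0], [5.0], [0.0])
        sim = simulate_arm(law, 200, np.random.default_rng(2))
        assert np.all(sim.status == 0)
        assert np.all(sim.time == 5.0)

    def test_no_censoring_means_no_censored_rows(self):
        # censoring mass entirely beyond the last event time, tail_mass 0
        law = make_law([1.0, 2.0], [0.6, 0.4], 0.0, [1.0, 0.0], [9.0], [0.0])
        sim = simulate_arm(law, 500, np.random.default_rng(3))
        assert np.all(sim.status > 0)

    def test_tie_resolves_to_event(self):
        # all event mass and all censoring mass at t=2: always an event
        law = make_law([2.0], [1.0], 0.0, [1.0], [2.0], [0.0])
        sim = simulate_arm(law, 100, np.random.default_rng(4))
        assert np.all(sim.status == 1)
        assert np.all(sim.time == 2.0)

    def test_censoring_before_support_censors(self):
        law = make_law([2.0], [1.0], 0.0, [1.0], [1.0], [0.0])
        sim = simulate_arm(law, 100, np.random.default_rng(5))
        assert np.all(sim.status == 0)

    def test_unspent_censoring_mass_warns_and_stays_proper(self):
        # censoring curve stops at 0.5: half its mass unspent
        law = make_law([1.0, 2.0], [0.5, 0.5], 0.0, [1.0, 1.0], [1.5], [0.5], tmax=2.0)
        with pytest.warns(UnspentCensoringMassWarning):
            times, masses = law.censoring_distribution()
        assert masses.sum() == pytest.approx(1.0)
        assert times[-1] > 2.0  # placed just after the largest observed time

    def test_censoring_proportion_matches_convolution_oracle(self):
        # brute-force: P(censored) = sum_{c<t} P(C=c)P(T=t) + P(C finite)*tail
        support, mass, p1, tail = [1.0, 2.0, 3.0], [0.3, 0.3, 0.2], [1, 0, 1], 0.2
        ctimes, cmass = np.array([1.5, 2.5, 4.0]), np.array([0.3, 0.4, 0.3])
        cvals = 1 - np.cumsum(cmass)
        law = make_law(support, mass, tail, p1, ctimes, np.clip(cvals, 0, 1))
        p_cens = sum(
            cm * tm
            for c, cm in zip(ctimes, cmass)
            for t, tm in zip(support, mass)
            if c < t
        ) + tail * 1.0
        sim = simulate_arm(law, 200_000, np.random.default_rng(6))
        assert np.mean(sim.status == 0) == pytest.approx(p_cens, abs=4e-3)

    def test_aalen_johansen_recovers_law_cifs(self, control_law):
        """Proof of concept at one large draw: the estimators applied to
        simulated data reproduce the generating law's implied CIFs."""
        sim = simulate_arm(control_law, 50_000, np.random.default_rng(8))
        grid = control_law.support
        for cause in (1, 2):
            est = aalen_johansen(sim, cause)(grid)
            truth = control_law.cif(cause)(grid)
            assert np.max(np.abs(est - truth)) < 0.015


class TestSimulateTrial:
    def test_group_labels_and_sizes(self, control_data):
        hz = (nelson_aalen(control_data, 1), nelson_aalen(control_data, 2))
        cens = kaplan_meier(control_data, "censoring")
        cfg = SimulationConfig(seed=9, n_control=120, n_treatment=80)
        trial = simulate_trial(hz, cens, Scenario(-0.1, 0.0), cfg)
        assert len(trial) == 200
        assert trial.arm(0).n == 120 and trial.arm(1).n == 80

    def test_trial_determinism(self, control_data):
        hz = (nelson_aalen(control_data, 1), nelson_aalen(control_data, 2))
        cens = kaplan_meier(control_data, "censoring")
        cfg = SimulationConfig(seed=10, n_control=50, n_treatment=50)
        a = simulate_trial(hz, cens, Scenario(-0.3, 0.3), cfg)
        b = simulate_trial(hz, cens, Scenario(-0.3, 0.3), cfg)
        assert np.array_equal(a.time, b.time) and np.array_equal(a.status, b.status)

    def test_beta1_negative_lowers_cause1_share(self, control_data):
        hz = (nelson_aalen(control_data, 1), nelson_aalen(control_data, 2))
        cens = kaplan_meier(control_data, "censoring")
        cfg = SimulationConfig(seed=11, n_control=30_000, n_treatment=30_000)
        trial = simulate_trial(hz, cens, Scenario(-0.5, 0.0), cfg)
        share = lambda arm, s: np.mean(trial.arm(arm).status == s)
        assert share(1, 1) < share(0, 1)
        # competing-event proportion slightly higher under treatment
        assert share(1, 2) > share(0, 2)
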