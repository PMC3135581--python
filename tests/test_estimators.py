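"""Nonparametric estimators: hand-enumerated oracles, exact step-function
identities, large-sample consistency against closed forms, and lifelines
cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crsim import (
    CompetingRisksDataset,
    aalen_johansen,
    generate,
    kaplan_meier,
    nelson_aalen,
)
from crsim.errors import EmptyDatasetError
from crsim.fixtures import FixtureSpec
from tests.conftest import random_dataset

EMPTY = CompetingRisksDataset(time=np.array([]), status=np.array([]))


class TestHandExamples:
    """Risk sets for (1,1),(2,2),(3,0),(4,1) are 4,3,2,1."""

    def test_nelson_aalen_cause1(self, hand_data):
        na = nelson_aalen(hand_data, 1)
        assert list(na.jump_times) == [1.0, 4.0]
        assert list(na.increments) == [0.25, 1.0]
        assert na(4.0) == pytest.approx(1.25)
        assert na(0.5) == 0.0  # zero before first jump
        assert na(100.0) == na(4.0)  # frozen beyond last jump

    def test_nelson_aalen_cause2(self, hand_data):
        na = nelson_aalen(hand_data, 2)
        assert na(4.0) == pytest.approx(1 / 3)
        assert list(na.variances) == [pytest.approx(1 / 9)]

    def test_kaplan_meier(self, hand_data):
        km = kaplan_meier(hand_data)
        assert km(1) == pytest.approx(3 / 4)
        assert km(2) == pytest.approx(1 / 2)
        assert km(4) == 0.0

    def test_censoring_km_drops_only_at_censoring_time(self, hand_data):
        ck = kaplan_meier(hand_data, "censoring")
        assert list(ck.jump_times) == [3.0]
        assert ck(2.9) == 1.0
        assert ck(3.0) == pytest.approx(0.5)  # risk set of size 2 at t=3

    def test_aalen_johansen(self, hand_data):
        aj1 = aalen_johansen(hand_data, 1)
        aj2 = aalen_johansen(hand_data, 2)
        assert aj1(1) == pytest.approx(0.25)
        assert aj1(4) == pytest.approx(0.75)
        assert aj2(4) == pytest.approx(0.25)
        assert aj1(4) + aj2(4) == pytest.approx(1.0)


def test_no_cause2_events_degenerate():
    d = CompetingRisksDataset(time=[1, 2, 3.0], status=[1, 1, 0])
    assert nelson_aalen(d, 2).jump_times.size == 0
    assert nelson_aalen(d, 2)(10.0) == 0.0
    aj2 = aalen_johansen(d, 2)
    assert np.all(aj2.values == 0.0)
    km = kaplan_meier(d)
    aj1 = aalen_johansen(d, 1)
    t = d.time
    assert np.allclose(aj1(t), 1 - km(t), atol=1e-14)


def test_all_censored_survival_is_one():
    d = CompetingRisksDataset(time=[1, 2, 3.0], status=[0, 0, 0])
    km = kaplan_meier(d)
    assert km(3.0) == 1.0


def test_empty_dataset_is_named_failure():
    for fn in (lambda: nelson_aalen(EMPTY, 1), lambda: kaplan_meier(EMPTY)):
        with pytest.raises(EmptyDatasetError):
            fn()


def test_log_transformed_ci_brackets_estimate(hand_data):
    band = nelson_aalen(hand_data, 1).confidence_interval()
    assert (band["lower"] <= band["estimate"]).all()
    assert (band["estimate"] <= band["upper"]).all()
    # log-transformed interval: estimate * exp(+-1.96*se/estimate)
    a, v = band["estimate"].iloc[0], band["variance"].iloc[0]
    assert band["upper"].iloc[0] == pytest.approx(a * np.exp(1.96 * np.sqrt(v) / a))


@pytest.mark.parametrize("n,tol", [(500, 0.12), (5_000, 0.05), (50_000, 0.02)])
def test_consistency_constant_hazards(n, tol):
    """Sup-distance to the exponential closed forms shrinks with n:
    A1(t)=0.15t, S(t)=exp(-0.23t), CIF1(t)=(l1/l)(1-exp(-l t))."""
    lam1, lam2 = 0.15, 0.08
    spec = FixtureSpec(lambda1=lam1, lambda2=lam2, censoring_window=(2, 6), n=n, seed=3)
    d = generate(spec)
    grid = np.linspace(0.1, 2.0, 40)
    lam = lam1 + lam2
    na1 = nelson_aalen(d, 1)
    assert np.max(np.abs(na1(grid) - lam1 * grid)) < tol
    assert na1(2.0) == pytest.approx(0.30, abs=2 * tol)
    km = kaplan_meier(d)
    assert np.max(np.abs(km(grid) - np.exp(-lam * grid))) < tol
    cif1 = aalen_johansen(d, 1)
    truth = lam1 / lam * (1 - np.exp(-lam * grid))
    assert np.max(np.abs(cif1(grid) - truth)) < tol


class TestExactIdentities:
    @pytest.mark.parametrize("seed,n,pool", [(0, 30, 6), (1, 100, None), (2, 200, 10)])
    def test_cif_sum_and_product_integral(self, seed, n, pool):
        d = random_dataset(np.random.default_rng(seed), n, tie_pool=pool)
        km = kaplan_meier(d)
        aj1, aj2 = aalen_johansen(d, 1), aalen_johansen(d, 2)
        t = np.unique(d.time)
        assert np.max(np.abs(aj1(t) + aj2(t) - (1 - km(t)))) < 1e-12
        # KM is the product-integral of the pooled Nelson-Aalen increments
        na1, na2 = nelson_aalen(d, 1), nelson_aalen(d, 2)
        sup = np.union1d(na1.jump_times, na2.jump_times)
        d1 = np.zeros(sup.size)
        d2 = np.zeros(sup.size)
        d1[np.searchsorted(sup, na1.jump_times)] = na1.increments
        d2[np.searchsorted(sup, na2.jump_times)] = na2.increments
        prodint = np.cumprod(1 - d1 - d2)
        assert np.max(np.abs(km(sup) - prodint)) < 1e-12

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_identities_property(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dataset(rng, int(rng.integers(5, 60)), tie_pool=int(rng.integers(3, 12)))
        km = kaplan_meier(d)
        t = np.unique(d.time)
        aj = aalen_johansen(d, 1)(t) + aalen_johansen(d, 2)(t)
        assert np.max(np.abs(aj - (1 - km(t)))) < 1e-12
        # monotonicity as typed
        assert np.all(np.diff(km.values) <= 1e-15)
        for cause in (1, 2):
            assert np.all(nelson_aalen(d, cause).increments >= 0)
            assert np.all(np.diff(aalen_johansen(d, cause).values) >= -1e-15)


class TestLifelinesCrossCheck:
    def test_kaplan_meier_matches(self, control_data):
        from lifelines import KaplanMeierFitter

        km = kaplan_meier(control_data)
        ref = KaplanMeierFitter().fit(control_data.time, control_data.status > 0)
        assert np.allclose(
            km(km.jump_times),
            ref.survival_function_at_times(km.jump_times).to_numpy(),
            atol=1e-12,
        )

    def test_nelson_aalen_matches(self, control_data):
        from lifelines import NelsonAalenFitter

        na = nelson_aalen(control_data, 1)
        ref = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(
            control_data.time, control_data.status == 1
        )
        assert np.allclose(
            na(na.jump_times),
            ref.cumulative_hazard_at_times(na.jump_times).to_numpy(),
            atol=1e-10,
        )
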