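"""Likelihood engine: densities, absorption probabilities, simulators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from dust_ddm.ddm_core import (
    Boundary,
    DDMParams,
    NO_RESPONSE,
    choice_probability,
    fpt_density,
    simulate_trial,
    simulate_trials,
    simulate_trials_em,
)
from dust_ddm.ddm_core import _f0_standard_branch


PARAM_SETS = [
    DDMParams(a=1.2, w=0.5, v=0.706),
    DDMParams(a=0.8, w=0.3, v=-1.5),
    DDMParams(a=2.0, w=0.62, v=0.4, sv=0.7),
    DDMParams(a=1.5, w=0.45, v=2.2, sv=1.2),
    DDMParams(a=1.0, w=0.5, v=0.0),
]


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(a=-1, w=0.5, v=0), dict(a=1, w=0.0, v=0), dict(a=1, w=1.2, v=0),
         dict(a=1, w=0.5, v=0, t0=-0.1), dict(a=1, w=0.5, v=0, sv=-1)],
    )
    def test_invalid_domain_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DDMParams(**kwargs)


class TestDensity:
    def test_no_mass_at_or_below_zero(self):
        p = DDMParams(a=1.2, w=0.5, v=0.706)
        assert fpt_density(0.0, Boundary.UPPER, p) == 0.0
        assert fpt_density(-0.5, Boundary.LOWER, p) == 0.0
        assert fpt_density(1e-9, Boundary.UPPER, p) < 1e-12

    def test_zero_drift_symmetry(self):
        p = DDMParams(a=1.2, w=0.5, v=0.0)
        t = np.linspace(0.05, 3.0, 40)
        np.testing.assert_allclose(
            fpt_density(t, Boundary.UPPER, p), fpt_density(t, Boundary.LOWER, p)
        )

    @pytest.mark.parametrize("p", PARAM_SETS)
    def test_normalizes_to_one(self, p):
        """Both defective densities together integrate to total probability 1."""
        total = 0.0
        for b in Boundary:
            total += quad(lambda t: fpt_density(t, b, p), 0, 120, limit=300)[0]
        assert total == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("p", [p for p in PARAM_SETS if p.sv == 0])
    def test_integral_matches_closed_form_probability(self, p):
        i_up = quad(lambda t: fpt_density(t, Boundary.UPPER, p), 0, 120, limit=300)[0]
        assert i_up == pytest.approx(choice_probability(p, Boundary.UPPER), abs=1e-5)

    def test_upper_integral_at_defaults_is_070(self):
        """Calibrated base parameters absorb at the correct boundary ~70%."""
        p = DDMParams(a=1.2, w=0.5, v=0.706)
        i_up = quad(lambda t: fpt_density(t, Boundary.UPPER, p), 0, 60, limit=200)[0]
        assert i_up == pytest.approx(0.6998, abs=2e-3)

    def test_mirror_symmetry(self):
        t = np.linspace(0.05, 4.0, 50)
        for p in PARAM_SETS:
            mirror = DDMParams(a=p.a, w=1 - p.w, v=-p.v, sv=p.sv)
            np.testing.assert_allclose(
                fpt_density(t, Boundary.UPPER, p),
                fpt_density(t, Boundary.LOWER, mirror),
                rtol=1e-10, atol=1e-12,
            )

    def test_series_branches_agree_in_overlap(self):
        """Small- and large-time expansions agree around the switch region."""
        for w in (0.3, 0.5, 0.7):
            t = np.linspace(0.05, 1.0, 60)  # normalized time straddling the crossover
            s = _f0_standard_branch(t, w, "small")
            l = _f0_standard_branch(t, w, "large")
            np.testing.assert_allclose(s, l, atol=1e-6)


class TestChoiceProbability:
    def test_unbiased_zero_drift_is_half(self):
        p = DDMParams(a=1.2, w=0.5, v=0.0)
        assert choice_probability(p, Boundary.UPPER) == pytest.approx(0.5)

    def test_closed_form_value(self):
        p = DDMParams(a=1.2, w=0.5, v=0.706)
        expected = 1.0 / (1.0 + np.exp(-0.706 * 1.2))
        assert choice_probability(p, Boundary.UPPER) == pytest.approx(expected, abs=1e-12)

    @given(
        a=st.floats(0.3, 3.0), w=st.floats(0.05, 0.95), v=st.floats(-4.0, 4.0)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mirror_property(self, a, w, v):
        p = DDMParams(a=a, w=w, v=v)
        q = DDMParams(a=a, w=1 - w, v=-v)
        assert choice_probability(p, Boundary.UPPER) == pytest.approx(
            choice_probability(q, Boundary.LOWER), abs=1e-12
        )

    def test_sv_probability_matches_density_integral(self):
        p = DDMParams(a=1.5, w=0.4, v=0.9, sv=0.8)
        i_up = quad(lambda t: fpt_density(t, Boundary.UPPER, p), 0, 120, limit=300)[0]
        assert choice_probability(p, Boundary.UPPER) == pytest.approx(i_up, abs=1e-5)


class TestSimulators:
    def test_deterministic_limit(self, rng):
        p = DDMParams(a=1.2, w=0.5, v=50.0)
        c, _ = simulate_trials(p, 500, 10.0, rng)
        assert (c == 1).all()

    def test_choice_fraction_matches_closed_form(self, rng):
        p = DDMParams(a=1.2, w=0.5, v=0.706)
        n = 100_000
        c, rt = simulate_trials(p, n, 60.0, rng)
        p_up = choice_probability(p, Boundary.UPPER)
        se = np.sqrt(p_up * (1 - p_up) / n)
        assert abs((c == 1).mean() - p_up) < 4 * se

    def test_rt_histogram_matches_density(self, rng):
        """Inverse-CDF sample vs analytic density, binned chi-square."""
        p = DDMParams(a=1.2, w=0.45, v=0.9)
        n = 100_000
        c, rt = simulate_trials(p, n, 30.0, rng)
        dec = rt[c == 1] - p.t0
        edges = np.quantile(dec, np.linspace(0, 1, 21))
        edges[0], edges[-1] = 0.0, 40.0
        obs, _ = np.histogram(dec, edges)
        probs = np.array([
            quad(lambda t: fpt_density(t, Boundary.UPPER, p), lo, hi, limit=200)[0]
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        exp = probs / probs.sum() * obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        # 19 dof; 4-sigma-ish upper bound keeps the seeded test stable
        assert chi2 < 50

    def test_em_simulator_cross_validates_density(self, rng):
        """Independent path simulator agrees with the closed-form probability.

        Documents the Euler–Maruyama discretization bias at dt = 1e-4:
        it must stay within Monte-Carlo error of the exact absorption
        probability at this step size.
        """
        p = DDMParams(a=1.2, w=0.5, v=0.706)
        n = 20_000
        c, rt = simulate_trials_em(p, n, 10.0, rng)
        p_up = choice_probability(p, Boundary.UPPER)
        se = np.sqrt(p_up * (1 - p_up) / n)
        assert abs((c == 1).mean() - p_up) < 4 * se + 0.005
        # RT quantiles from the two independent routes agree
        c2, rt2 = simulate_trials(p, n, 10.0, rng)
        for q in (0.25, 0.5, 0.75):
            assert np.nanquantile(rt, q) == pytest.approx(
                np.nanquantile(rt2, q), abs=0.02
            )

    def test_scalar_trial_and_deadline(self, rng):
        p = DDMParams(a=1.2, w=0.5, v=0.706, t0=0.3)
        b, rt = simulate_trial(p, 2.5, rng)
        assert b in (Boundary.UPPER, Boundary.LOWER, NO_RESPONSE)
        if b is not NO_RESPONSE:
            assert 0.3 < rt <= 2.5
        with pytest.raises(ValueError):
            simulate_trial(p, 0.2, rng)

    def test_reproducible_given_seed(self):
        p = DDMParams(a=1.2, w=0.4, v=0.8, sv=0.5, t0=0.3)
        c1, r1 = simulate_trials(p, 1000, 2.5, np.random.default_rng(7))
        c2, r2 = simulate_trials(p, 1000, 2.5, np.random.default_rng(7))
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(r1, r2)
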