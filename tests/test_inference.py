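"""Likelihood, DE-MC sampler and convergence diagnostics."""

import numpy as np
import pytest

from dust_ddm.ddm_core import Boundary, DDMParams, fpt_density
from dust_ddm.inference import (
    Priors,
    default_priors,
    demc_sample,
    gelman_rubin,
    log_likelihood,
    sample_posterior,
)
from dust_ddm.model_space import build_model
from dust_ddm.synthetic_data import GroundTruth, generate_schedule, simulate_subject
from dust_ddm.validation import truth_to_theta


@pytest.fixture(scope="module")
def reduced_fit(no_effect_subject):
    _, _, df = no_effect_subject
    df = df[~df["no_response"]]
    spec = build_model("reduced")
    fit = sample_posterior(df, spec, n_iter=400, burn_in=400, seed=17, thin=2)
    return df, spec, fit


class TestLogLikelihood:
    def test_empty_data(self):
        import pandas as pd
        total, pw = log_likelihood(pd.DataFrame(columns=["rt_s"]), build_model("reduced"), np.zeros(5))
        assert total == 0.0 and pw.size == 0

    def test_t0_exceeding_rt_gives_minus_inf(self, no_effect_subject):
        _, _, df = no_effect_subject
        df = df[~df["no_response"]].head(1)
        theta = np.array([1.2, 0.5, 0.7, float(df["rt_s"].iloc[0]) + 0.1, 0.0])
        total, pw = log_likelihood(df, build_model("reduced"), theta)
        assert total == -np.inf and pw[0] == -np.inf

    def test_matches_direct_density_calls(self, no_effect_subject):
        """Total equals the sum of independent per-trial density evaluations."""
        _, _, df = no_effect_subject
        df = df[~df["no_response"]].head(5)
        theta = np.array([1.2, 0.48, 0.75, 0.25, 0.3])
        total, pw = log_likelihood(df, build_model("reduced"), theta)
        expected = []
        for r in df.itertuples():
            sign = 1.0 if r.stimulus == "RIGHT" else -1.0
            p = DDMParams(a=1.2, w=0.48, v=sign * 0.75, t0=0.25, sv=0.3)
            b = Boundary.UPPER if r.response == "RIGHT" else Boundary.LOWER
            expected.append(np.log(fpt_density(r.rt_s - 0.25, b, p)))
        np.testing.assert_allclose(pw, expected, rtol=1e-10)
        assert total == pytest.approx(sum(expected), rel=1e-10)


class TestSampler:
    def test_parameter_recovery_within_three_sd(self, reduced_fit, no_effect_subject):
        truth, _, _ = no_effect_subject
        df, spec, fit = reduced_fit
        theta_true = truth_to_theta(truth, spec)
        mean, sd = fit.mean(), fit.sd()
        for j, name in enumerate(spec.param_names):
            if name == "sv":  # truth at the boundary of its domain
                continue
            assert abs(mean[j] - theta_true[j]) < 3 * sd[j] + 0.02, name

    def test_pointwise_rows_sum_to_total(self, reduced_fit):
        df, spec, fit = reduced_fit
        rowsums = fit.pointwise_loglik.sum(axis=1)
        # re-evaluate a handful of retained draws from scratch
        flat = fit.flat
        for k in np.linspace(0, flat.shape[0] - 1, 5, dtype=int):
            total, _ = log_likelihood(df, spec, flat[k])
            assert rowsums[k] == pytest.approx(total, abs=1e-8)

    def test_same_seed_reproduces_draws(self, no_effect_subject):
        _, _, df = no_effect_subject
        df = df[~df["no_response"]]
        spec = build_model("reduced")
        kw = dict(n_iter=100, burn_in=100, seed=5)
        f1 = sample_posterior(df, spec, **kw)
        f2 = sample_posterior(df, spec, **kw)
        np.testing.assert_array_equal(f1.draws, f2.draws)

    def test_flat_target_recovers_prior(self):
        """With a constant likelihood, retained draws reproduce the prior."""
        spec = build_model("reduced")
        priors = default_priors(spec)

        def log_post(th):
            return priors.logpdf(th)

        fit = demc_sample(log_post, priors, n_chains=15, n_iter=1500, burn_in=300, seed=3)
        from scipy import stats
        a = (priors.lower - priors.mean) / priors.sd
        b = (priors.upper - priors.mean) / priors.sd
        exp_mean = stats.truncnorm.mean(a, b, loc=priors.mean, scale=priors.sd)
        exp_sd = stats.truncnorm.std(a, b, loc=priors.mean, scale=priors.sd)
        got_mean, got_sd = fit.mean(), fit.sd()
        assert (np.abs(got_mean - exp_mean) < 0.35 * exp_sd).all()
        np.testing.assert_allclose(got_sd, exp_sd, rtol=0.25)

    def test_posterior_contracts_with_more_data(self):
        """Doubling the trial count shrinks posterior SDs on average."""
        spec = build_model("reduced")
        truth = GroundTruth()
        ratios = []
        for seed in range(3):
            sds = {}
            for n in (240, 480):
                third = n // 3
                sch = generate_schedule(
                    n_trials=n, norm_counts={"NONE": third, "SAME": third, "ONLY": third},
                    seed=100 + seed,
                )
                df = simulate_subject(truth, sch, 200 + seed)
                df = df[~df["no_response"]]
                fit = sample_posterior(df, spec, n_iter=300, burn_in=300, seed=seed)
                sds[n] = fit.sd()
            ratios.append(np.mean(sds[480] / sds[240]))
        assert np.mean(ratios) < 1.0

    def test_save_load_roundtrip(self, reduced_fit, tmp_path):
        _, _, fit = reduced_fit
        path = tmp_path / "fit.npz"
        fit.save(path)
        from dust_ddm.inference import PosteriorSample
        back = PosteriorSample.load(path)
        np.testing.assert_array_equal(back.draws, fit.draws)
        assert back.param_names == fit.param_names
        assert back.meta["model"] == fit.meta["model"]


class TestGelmanRubin:
    def test_iid_normal_chains_converge(self, rng):
        draws = rng.standard_normal((4, 1000, 3))
        assert (gelman_rubin(draws) < 1.05).all()

    def test_separated_chains_flagged(self):
        draws = np.zeros((2, 100, 1))
        draws[1] += 5.0
        draws += np.random.default_rng(0).standard_normal(draws.shape) * 0.1
        assert gelman_rubin(draws)[0] > 1.1

    def test_constant_chains_give_inf_with_warning(self):
        draws = np.ones((3, 50, 1))
        with pytest.warns(UserWarning):
            assert np.isinf(gelman_rubin(draws)[0])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100, 2)))
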