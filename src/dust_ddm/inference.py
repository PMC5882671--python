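"""Per-subject Bayesian fitting by differential-evolution MCMC.

The posterior over a model's flat parameter vector theta combines the joint
choice/RT likelihood — each trial contributes the defective first-passage
density of the response boundary at its decision time — with independent
truncated-normal priors assigned by parameter kind.  Sampling uses DE-MC: a
population of chains proposes scaled differences of two other chains'
states, which adapts proposals to the posterior covariance without manual
tuning.  Tuning follows common practice for this sampler family:
``n_chains = 3 p``, ``gamma = 2.38 / sqrt(2 p)`` with a 5% chance of
``gamma = 1`` (mode jumping), uniform jitter U(-0.001, 0.001), and optional
chain migration during burn-in.

Trials whose deadline passed without a response carry no likelihood term
and must be removed before fitting; a decision time at or below zero under
a candidate theta yields a log-likelihood of -inf (the sampler rejects)
rather than an exception.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ddm_core import _fpt_lower
from .model_space import (
    ModelSpec,
    Norm,
    Social,
    Stimulus,
    TrialContext,
    resolve_params,
)

__all__ = [
    "Priors",
    "default_priors",
    "TrialData",
    "log_likelihood",
    "sample_posterior",
    "demc_sample",
    "gelman_rubin",
    "PosteriorSample",
]


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

#: (mean, sd, lower, upper) per parameter kind; weakly informative over the
#: range of typical two-alternative forced-choice fits
_DEFAULT_PRIOR_TABLE = {
    "a": (1.5, 1.0, 0.1, 5.0),
    "w": (0.5, 0.25, 0.02, 0.98),
    "v": (1.0, 2.0, 0.0, 7.0),  # drift magnitudes; sign comes from the stimulus
    "t0": (0.3, 0.2, 0.05, 1.0),
    "sv": (0.5, 0.5, 0.0, 3.0),
}


@dataclass(frozen=True)
class Priors:
    """Independent truncated-normal priors, one per parameter."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def logpdf(self, theta: np.ndarray) -> np.ndarray:
        """Sum of per-parameter log densities; theta is (..., p)."""
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        lp = stats.truncnorm.logpdf(theta, a, b, loc=self.mean, scale=self.sd)
        return lp.sum(axis=-1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=(n, self.mean.size),
            random_state=rng,
        )


def default_priors(spec: ModelSpec, overrides: dict | None = None) -> Priors:
    """Priors for a model, assigned by parameter kind.

    ``overrides`` may remap whole kinds (key = kind) or single parameters
    (key = parameter name) to a (mean, sd, lower, upper) tuple.
    """
    overrides = overrides or {}
    rows = []
    for name, kind in zip(spec.param_names, spec.param_kinds):
        rows.append(overrides.get(name) or overrides.get(kind) or _DEFAULT_PRIOR_TABLE[kind])
    arr = np.array(rows, dtype=float)
    return Priors(mean=arr[:, 0], sd=arr[:, 1], lower=arr[:, 2], upper=arr[:, 3])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TrialData:
    """Pre-indexed trial table for fast likelihood evaluation.

    Built once per (dataset, model); maps every trial to its starting-point
    and drift parameter indices and folds the response boundary into an
    effective (w, v) mirror so only lower-boundary densities are evaluated.
    """

    def __init__(self, frame: pd.DataFrame, spec: ModelSpec):
        df = frame
        if (df["response"] == "NO_RESPONSE").any() or df.get("no_response", pd.Series(False, index=df.index)).any():
            raise ValueError("remove NO_RESPONSE trials before fitting")
        self.spec = spec
        self.n = len(df)
        self.rt = df["rt_s"].to_numpy(dtype=float)
        self.resp_upper = (df["response"] == "RIGHT").to_numpy()
        w_idx = np.empty(self.n, dtype=int)
        v_idx = np.empty(self.n, dtype=int)
        sign = np.empty(self.n, dtype=float)
        norms = df["norm"].map(Norm).to_numpy()
        socials = df["social"].map(Social).to_numpy()
        stims = df["stimulus"].to_numpy()
        for i in range(self.n):
            iw, iv = spec.context_indices(
                TrialContext(norms[i], socials[i], Stimulus(stims[i]))
            )
            w_idx[i], v_idx[i] = iw, iv
            sign[i] = 1.0 if stims[i] == "RIGHT" else -1.0
        self.w_idx, self.v_idx, self.sign = w_idx, v_idx, sign

    def pointwise_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-trial log densities; theta is (p,) or (chains, p).

        Returns shape (n,) or (chains, n).  Decision times <= 0 give -inf.
        """
        theta = np.asarray(theta, dtype=float)
        one = theta.ndim == 1
        th = np.atleast_2d(theta)
        a = th[:, self.spec.idx_a][:, None]
        t0 = th[:, self.spec.idx_t0][:, None]
        sv = th[:, self.spec.idx_sv][:, None]
        w = th[:, self.w_idx]
        v = th[:, self.v_idx] * self.sign[None, :]
        # mirror upper-boundary responses onto the lower boundary
        w_eff = np.where(self.resp_upper[None, :], 1.0 - w, w)
        v_eff = np.where(self.resp_upper[None, :], -v, v)
        t_dec = self.rt[None, :] - t0
        dens = _fpt_lower(np.maximum(t_dec, 0.0), a, w_eff, v_eff, sv)
        with np.errstate(divide="ignore"):
            ll = np.where(t_dec > 0, np.log(dens), -np.inf)
        return ll[0] if one else ll


def log_likelihood(data, spec: ModelSpec, theta):
    """Joint choice/RT log-likelihood of a trial table under ``spec``.

    Returns ``(total, pointwise)``.  ``data`` is a trial DataFrame (see
    synthetic_data.TRIAL_COLUMNS) without no-response trials.  Any trial
    impossible under ``theta`` (e.g. RT <= t0) contributes -inf to the
    total instead of raising.
    """
    if len(data) == 0:
        return 0.0, np.zeros(0)
    td = TrialData(data, spec)
    pw = td.pointwise_loglik(np.asarray(theta, dtype=float))
    return float(pw.sum()), pw


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Retained DE-MC draws for one subject and model.

    ``draws`` is chains x iterations x parameters; ``pointwise_loglik``
    flattens chains and iterations into rows (one per retained draw).
    """

    draws: np.ndarray
    pointwise_loglik: np.ndarray
    rhat: np.ndarray
    param_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    @property
    def flat(self) -> np.ndarray:
        c, i, p = self.draws.shape
        return self.draws.reshape(c * i, p)

    def mean(self) -> np.ndarray:
        return self.flat.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.flat.std(axis=0)

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.flat, q, axis=0)

    def save(self, path: str | Path) -> None:
        """Serialize to a portable .npz container (arrays + JSON meta)."""
        np.savez_compressed(
            path,
            draws=self.draws,
            pointwise_loglik=self.pointwise_loglik,
            rhat=self.rhat,
            param_names=np.array(self.param_names),
            meta=np.array(json.dumps(self.meta)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSample":
        with np.load(path) as z:
            return cls(
                draws=z["draws"],
                pointwise_loglik=z["pointwise_loglik"],
                rhat=z["rhat"],
                param_names=tuple(z["param_names"].tolist()),
                meta=json.loads(str(z["meta"])),
            )


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor, per parameter.

    ``draws`` is chains x iterations x parameters with >= 2 chains and
    >= 10 retained iterations.  Degenerate chains with zero within-chain
    variance return +inf with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, iterations, parameters)")
    c, n, p = draws.shape
    if n < 10:
        raise ValueError("need at least 10 retained iterations")
    half = n // 2
    split = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, nn = split.shape[0], split.shape[1]
    chain_means = split.mean(axis=1)
    chain_vars = split.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = nn * chain_means.var(axis=0, ddof=1)
    rhat = np.empty(p)
    for j in range(p):
        if W[j] <= 0:
            warnings.warn(
                f"zero within-chain variance for parameter {j}; rhat set to inf"
            )
            rhat[j] = np.inf
        else:
            var_plus = (nn - 1) / nn * W[j] + B[j] / nn
            rhat[j] = np.sqrt(var_plus / W[j])
    return rhat


def demc_sample(
    log_post,
    priors: Priors,
    n_chains: int,
    n_iter: int,
    burn_in: int,
    seed: int,
    migration_interval: int = 20,
    pointwise: bool = False,
    param_names: tuple[str, ...] | None = None,
    thin: int = 1,
):
    """Generic DE-MC driver over an arbitrary log target.

    ``log_post`` maps a (chains, p) matrix to a length-chains vector of log
    target values — or, when ``pointwise=True``, to a pair ``(vector,
    (chains, n_trials) matrix)`` of log targets and per-trial
    log-likelihoods stored with each retained draw.  Raises a diagnostic
    error if no chain accepts any move over a 50-iteration epoch.
    """
    rng = np.random.default_rng(seed)
    p = priors.mean.size
    gamma0 = 2.38 / np.sqrt(2.0 * p)

    def evaluate(th):
        if pointwise:
            return log_post(th)
        return log_post(th), None

    theta = priors.sample(n_chains, rng)
    lp, pw = evaluate(theta)
    for _ in range(100):
        bad = ~np.isfinite(lp)
        if not bad.any():
            break
        theta[bad] = priors.sample(int(bad.sum()), rng)
        lp_b, pw_b = evaluate(theta[bad])
        lp[bad] = lp_b
        if pw is not None:
            pw[bad] = pw_b
    if not np.isfinite(lp).all():
        raise RuntimeError("could not initialize all chains at finite posterior")

    keep_iters = n_iter // thin
    draws = np.empty((n_chains, keep_iters, p))
    pw_store = (
        np.empty((n_chains, keep_iters, pw.shape[1])) if pw is not None else None
    )
    n_accept = 0
    n_prop = 0
    epoch_accept = 0

    for it in range(burn_in + n_iter):
        # proposals: scaled difference of two other chains + jitter
        r1 = rng.integers(0, n_chains - 1, size=n_chains)
        r1[r1 >= np.arange(n_chains)] += 1
        r2 = rng.integers(0, n_chains - 2, size=n_chains)
        both = np.sort(np.stack([np.arange(n_chains), r1]), axis=0)
        r2[r2 >= both[0]] += 1
        r2[r2 >= both[1]] += 1
        gamma = np.where(rng.uniform(size=n_chains) < 0.05, 1.0, gamma0)[:, None]
        jitter = rng.uniform(-0.001, 0.001, size=(n_chains, p))
        prop = theta + gamma * (theta[r1] - theta[r2]) + jitter
        lp_prop, pw_prop = evaluate(prop)
        accept = np.log(rng.uniform(size=n_chains)) < (lp_prop - lp)
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        if pw is not None:
            pw[accept] = pw_prop[accept]
        n_accept += int(accept.sum())
        n_prop += n_chains
        epoch_accept += int(accept.sum())
        if (it + 1) % 50 == 0:
            if epoch_accept == 0:
                raise RuntimeError(
                    "DE-MC degenerate: no chain accepted a move over a "
                    "50-iteration epoch"
                )
            epoch_accept = 0
            # outlier-chain correction (burn-in only): chains stranded far
            # below the population posterior are teleported onto a random
            # non-outlier chain, the standard remedy for stuck DE-MC chains
            if it < burn_in:
                q25, q75 = np.percentile(lp, [25, 75])
                outlier = lp < q25 - 2.0 * (q75 - q25)
                if outlier.any():
                    good = np.flatnonzero(~outlier)
                    dst = np.flatnonzero(outlier)
                    src = good[rng.integers(0, good.size, size=dst.size)]
                    theta[dst] = theta[src]
                    lp[dst] = lp[src]
                    if pw is not None:
                        pw[dst] = pw[src]

        # migration: cyclic swap of a random chain subset, burn-in only
        if it < burn_in and migration_interval and (it + 1) % migration_interval == 0:
            k = rng.integers(2, max(3, n_chains // 2) + 1)
            subset = rng.choice(n_chains, size=k, replace=False)
            theta[subset] = theta[np.roll(subset, 1)]
            lp[subset] = lp[np.roll(subset, 1)]
            if pw is not None:
                pw[subset] = pw[np.roll(subset, 1)]

        if it >= burn_in:
            j = it - burn_in
            if j % thin == 0 and j // thin < keep_iters:
                draws[:, j // thin, :] = theta
                if pw_store is not None:
                    pw_store[:, j // thin, :] = pw

    rhat = gelman_rubin(draws)
    c, i, _ = draws.shape
    return PosteriorSample(
        draws=draws,
        pointwise_loglik=(
            pw_store.reshape(c * i, -1) if pw_store is not None else np.zeros((c * i, 0))
        ),
        rhat=rhat,
        param_names=param_names or tuple(f"p{j}" for j in range(p)),
        meta={
            "n_chains": n_chains,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "thin": thin,
            "seed": int(seed),
            "acceptance_rate": n_accept / max(n_prop, 1),
        },
    )


def sample_posterior(
    data: pd.DataFrame,
    spec: ModelSpec,
    priors: Priors | None = None,
    n_chains: int | None = None,
    n_iter: int = 1000,
    burn_in: int = 500,
    seed: int = 0,
    thin: int = 1,
    rhat_gate: float | None = None,
) -> PosteriorSample:
    """Fit one model to one subject's (response-present) trials.

    ``n_chains`` defaults to three per parameter.  With ``rhat_gate`` set,
    a fit whose worst split-chain rhat exceeds the gate is refit once with
    doubled iterations; if still above, a RuntimeError names the offending
    parameters.
    """
    if priors is None:
        priors = default_priors(spec)
    if n_chains is None:
        n_chains = 3 * spec.n_params
    if n_chains < 2 * spec.n_params:
        raise ValueError("need at least two chains per parameter")
    td = TrialData(data, spec)

    def log_post(th):
        pw = td.pointwise_loglik(th)
        return pw.sum(axis=1) + priors.logpdf(th), pw

    fit = demc_sample(
        log_post, priors, n_chains, n_iter, burn_in, seed,
        pointwise=True, param_names=spec.param_names, thin=thin,
    )
    fit.meta.update(model=spec.name, n_trials=td.n)
    if rhat_gate is not None and np.nanmax(fit.rhat) > rhat_gate:
        fit = demc_sample(
            log_post, priors, n_chains, 2 * n_iter, 2 * burn_in, seed + 1,
            pointwise=True, param_names=spec.param_names, thin=thin,
        )
        fit.meta.update(model=spec.name, n_trials=td.n, refit=True)
        if np.nanmax(fit.rhat) > rhat_gate:
            bad = [n for n, r in zip(spec.param_names, fit.rhat) if r > rhat_gate]
            raise RuntimeError(
                f"model {spec.name!r} failed convergence after refit; "
                f"rhat > {rhat_gate} for: {', '.join(bad)}"
            )
    return fit
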