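"""Parameter-recovery studies and posterior predictive checks.

Recovery: simulate subjects from known parameters, fit the same model, and
score how well the posterior finds the truth — per-parameter coverage of
the central 95% interval and the cross-subject correlation between true
and estimated values.  Parameters held constant across simulated subjects
have no defined correlation and are reported as missing.

Posterior predictive checks: draw parameter vectors from a fitted
posterior, simulate the subject's schedule under each, and ask whether the
observed accuracy and RT quantiles — per norm x information condition
(dots-only / valid / invalid cue) — fall inside the central 95% predictive
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm_core import DDMParams, simulate_trials
from .inference import PosteriorSample, sample_posterior
from .model_space import ModelSpec, Stimulus, build_model, resolve_params
from .synthetic_data import (
    DEADLINE_S,
    GroundTruth,
    PRESETS,
    TrialSpec,
    draw_subject_truth,
    generate_schedule,
    simulate_subject,
)

__all__ = ["RecoveryReport", "PPCReport", "run_recovery", "run_ppc", "truth_to_theta"]

#: RT quantiles summarized in predictive checks
PPC_QUANTILES = (0.1, 0.5, 0.9)


def truth_to_theta(truth: GroundTruth, spec: ModelSpec) -> np.ndarray:
    """Ground-truth generating parameters expressed in a model's theta order.

    Only meaningful when the generator's effect structure is expressible in
    the model (e.g. the reduced model with all condition effects zero).
    """
    vals = {
        "a": truth.a, "w_base": truth.w_base, "v_base": truth.v_base,
        "t0": truth.t0, "sv": truth.sv,
        "w_congl": truth.w_base - truth.dw_none,
        "w_congr": truth.w_base + truth.dw_none,
        "v_cong": truth.v_base,
    }
    for norm, dw in (("none", truth.dw_none), ("same", truth.dw_same), ("only", truth.dw_only)):
        vals[f"w_congl_{norm}"] = truth.w_base - dw
        vals[f"w_congr_{norm}"] = truth.w_base + dw
        vals[f"v_cong_{norm}"] = truth.v_base + (truth.dv_only if norm == "only" else 0.0)
    return np.array([vals[n] for n in spec.param_names])


@dataclass
class RecoveryReport:
    """Outcome of a simulate -> fit -> score recovery study."""

    table: pd.DataFrame  # subject, parameter, truth, post_mean, post_sd, covered
    correlations: pd.Series  # per parameter; NaN where truth has no variance
    n_failed: int  # non-converged fits excluded from the table


def run_recovery(
    model_name: str,
    n_subjects: int,
    trials_per_subject: int = 360,
    experiment: str = "HO",
    master_seed: int = 0,
    n_iter: int = 500,
    burn_in: int = 600,
    thin: int = 2,
    rhat_gate: float | None = 1.1,
) -> RecoveryReport:
    """Simulate subjects from preset-jittered truths, refit, and score.

    Truths are drawn from the synthetic presets with their per-subject
    jitter; schedules are scaled to ``trials_per_subject`` (must be a
    multiple of 30 so the design counts stay integral and balanced).
    Fits failing the convergence gate are excluded and counted.
    """
    spec = build_model(model_name)
    if trials_per_subject < 100 or trials_per_subject % 30:
        raise ValueError("trials_per_subject must be >= 120 and a multiple of 30")
    preset = PRESETS[experiment.upper()]
    master = np.random.default_rng(master_seed)
    third = trials_per_subject // 3

    rows = []
    truths_used = {}
    n_failed = 0
    for s in range(n_subjects):
        seeds = master.integers(0, 2**31 - 1, size=3)
        truth = draw_subject_truth(preset, s + 1, np.random.default_rng(seeds[0]))
        schedule = generate_schedule(
            n_trials=trials_per_subject,
            norm_counts={"NONE": third, "SAME": third, "ONLY": third},
            seed=int(seeds[1]),
        )
        df = simulate_subject(truth, schedule, int(seeds[2]))
        df = df[~df["no_response"]]
        try:
            fit = sample_posterior(
                df, spec, n_iter=n_iter, burn_in=burn_in, thin=thin,
                seed=int(seeds[2] % 2**31), rhat_gate=rhat_gate,
            )
        except RuntimeError:
            n_failed += 1
            continue
        theta_true = truth_to_theta(truth, spec)
        lo, hi = fit.quantile([0.025, 0.975])
        mean, sd = fit.mean(), fit.sd()
        truths_used[s + 1] = theta_true
        for j, name in enumerate(spec.param_names):
            rows.append(
                (s + 1, name, theta_true[j], mean[j], sd[j],
                 bool(lo[j] <= theta_true[j] <= hi[j]))
            )
    table = pd.DataFrame(
        rows, columns=["subject", "parameter", "truth", "post_mean", "post_sd", "covered"]
    )
    cors = {}
    for name in spec.param_names:
        sub = table[table["parameter"] == name]
        t = sub["truth"].to_numpy()
        if len(sub) >= 3 and np.std(t) > 1e-12:
            cors[name] = float(np.corrcoef(t, sub["post_mean"].to_numpy())[0, 1])
        else:
            cors[name] = np.nan
    return RecoveryReport(table=table, correlations=pd.Series(cors), n_failed=n_failed)


@dataclass
class PPCReport:
    """Observed vs posterior-predicted statistics per norm x cue cell.

    ``table`` columns: norm, validity, statistic, observed, pred_lo,
    pred_hi, pred_median, inside (whether the observation falls inside the
    central 95% predictive interval).
    """

    table: pd.DataFrame
    n_reps: int

    @property
    def fraction_inside(self) -> float:
        ok = self.table["inside"].dropna()
        return float(ok.mean()) if len(ok) else np.nan


def _cell_stats(df: pd.DataFrame) -> dict[str, float]:
    scored = df[df["response"] != "NO_RESPONSE"]
    out = {"accuracy": float(scored["accuracy"].mean()) if len(scored) else np.nan}
    rts = scored["rt_s"].to_numpy(dtype=float)
    for q in PPC_QUANTILES:
        out[f"rt_q{int(q * 100)}"] = float(np.quantile(rts, q)) if rts.size else np.nan
    return out


def _simulate_theta(
    spec: ModelSpec, theta: np.ndarray, schedule: list[TrialSpec], rng
) -> pd.DataFrame:
    """Simulate a schedule under a model's resolved parameters."""
    groups: dict[DDMParams, list[int]] = {}
    for i, ts in enumerate(schedule):
        groups.setdefault(resolve_params(spec, theta, ts.context), []).append(i)
    n = len(schedule)
    choice = np.zeros(n, dtype=int)
    rt = np.full(n, np.nan)
    for params in sorted(groups, key=lambda p: (p.w, p.v)):
        idx = np.array(groups[params])
        c, r = simulate_trials(params, idx.size, DEADLINE_S, rng)
        choice[idx], rt[idx] = c, r
    rows = []
    for i, ts in enumerate(schedule):
        resp = "NO_RESPONSE" if choice[i] == 0 else ("RIGHT" if choice[i] == 1 else "LEFT")
        acc = np.nan if choice[i] == 0 else float(resp == ts.stimulus.value)
        rows.append((ts.norm.value, ts.social.value, ts.stimulus.value, resp, rt[i], acc))
    return pd.DataFrame(
        rows, columns=["norm", "social", "stimulus", "response", "rt_s", "accuracy"]
    )


def run_ppc(
    fit: PosteriorSample,
    spec: ModelSpec,
    schedule: list[TrialSpec],
    observed: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
) -> PPCReport:
    """Posterior predictive check of accuracy and RT quantiles per cell.

    Cells are norm x information condition (valid / invalid / incongruent
    cue), the grouping under which cue-induced accuracy splits are visible.
    """
    if n_reps < 20:
        raise ValueError("need n_reps >= 20 for a meaningful predictive interval")
    from .behavior_metrics import add_validity

    rng = np.random.default_rng(seed)
    flat = fit.flat
    pick = rng.integers(0, flat.shape[0], size=n_reps)

    sim_stats: list[dict] = []
    for r in range(n_reps):
        sim = add_validity(_simulate_theta(spec, flat[pick[r]], schedule, rng))
        for (norm, validity), cell in sim.groupby(["norm", "validity"], observed=True):
            for k, vv in _cell_stats(cell).items():
                sim_stats.append(
                    {"norm": norm, "validity": validity, "statistic": k, "value": vv}
                )
    sim_df = pd.DataFrame(sim_stats)

    rows = []
    for (norm, validity), cell in add_validity(observed).groupby(
        ["norm", "validity"], observed=True
    ):
        obs = _cell_stats(cell)
        for stat, val in obs.items():
            dist = sim_df.query(
                "norm == @norm and validity == @validity and statistic == @stat"
            )["value"].dropna()
            if len(dist) < n_reps // 2:
                lo = hi = med = np.nan
                inside = np.nan
            else:
                lo, med, hi = np.quantile(dist, [0.025, 0.5, 0.975])
                inside = bool(lo <= val <= hi) if np.isfinite(val) else np.nan
            rows.append((norm, validity, stat, val, lo, hi, med, inside))
    table = pd.DataFrame(
        rows,
        columns=["norm", "validity", "statistic", "observed", "pred_lo", "pred_hi",
                 "pred_median", "inside"],
    )
    return PPCReport(table=table, n_reps=n_reps)
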