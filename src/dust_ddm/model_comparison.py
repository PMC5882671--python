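"""WAIC model comparison and weight-averaged parameter summaries.

Each of the six models fitted to a subject yields a matrix of pointwise
log-likelihoods (retained draws x trials).  The widely applicable
information criterion is computed on the deviance scale,

    lppd   = sum_i log mean_s exp(ll_si)
    p_waic = sum_i Var_s(ll_si)          (population variance over draws)
    waic   = -2 (lppd - p_waic),

and converted to per-subject Akaike-style weights
w_m = exp(-Delta_m / 2) / sum_k exp(-Delta_k / 2) with Delta relative to
the best model.  Condition-level effects are then averaged across the whole
model set with these weights: every model contributes its posterior-mean
starting-point bias toward the cued side and its congruent-vs-incongruent
drift difference, models lacking the relevant parameters contributing the
nested value of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorSample
from .model_space import MODEL_NAMES, ModelSpec, Norm, build_model

__all__ = ["WAICResult", "waic", "waic_weights", "average_parameters", "comparison_table"]


@dataclass
class WAICResult:
    """WAIC decomposition for one fitted model (deviance scale)."""

    lppd: float
    p_waic: float
    waic: float
    weight: float | None = None


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """WAIC from a draws x trials matrix of pointwise log-likelihoods.

    A trial whose density underflows in every draw (a -inf column) makes
    the criterion undefined and raises, naming the trial.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 1 or ll.shape[1] < 1:
        raise ValueError("need a (draws >= 1, trials >= 1) matrix")
    col_bad = np.isneginf(ll).all(axis=0) | ~np.isfinite(ll).any(axis=0)
    if col_bad.any():
        raise ValueError(
            f"trial(s) {np.flatnonzero(col_bad).tolist()} impossible under "
            "every posterior draw; WAIC undefined"
        )
    n_draws = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(np.var(ll, axis=0)))  # denominator n, by convention
    return WAICResult(lppd=lppd, p_waic=p_waic, waic=-2.0 * (lppd - p_waic))


def waic_weights(waics) -> np.ndarray:
    """Akaike-style weights over a model set's WAIC values."""
    w = np.asarray(waics, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("WAIC values must be finite")
    delta = w - w.min()
    e = np.exp(-delta / 2.0)
    return e / e.sum()


def _model_effects(spec: ModelSpec, theta_mean: np.ndarray) -> pd.DataFrame:
    """Posterior-mean sp_bias and drift_delta per norm for one model.

    sp_bias folds the left/right congruent starting points into a single
    toward-the-cue magnitude, corrected by the incongruent baseline:
    mean(w_congR - w_incong, w_incong - w_congL).  drift_delta is the
    congruent-trial drift minus the incongruent (dots-only) drift.
    """
    names = spec.param_names
    idx = {n: i for i, n in enumerate(names)}
    w0 = theta_mean[idx["w_base"]]
    v0 = theta_mean[idx["v_base"]]
    rows = []
    for norm in (Norm.NONE, Norm.SAME, Norm.ONLY):
        tag = f"_{norm.value.lower()}"
        sp_bias = 0.0
        for cand_l, cand_r in ((f"w_congl{tag}", f"w_congr{tag}"), ("w_congl", "w_congr")):
            if cand_l in idx:
                wl, wr = theta_mean[idx[cand_l]], theta_mean[idx[cand_r]]
                sp_bias = 0.5 * ((wr - w0) + (w0 - wl))
                break
        drift_delta = 0.0
        for cand in (f"v_cong{tag}", "v_cong"):
            if cand in idx:
                drift_delta = theta_mean[idx[cand]] - v0
                break
        rows.append((norm.value, sp_bias, drift_delta))
    return pd.DataFrame(rows, columns=["condition", "sp_bias", "drift_delta"])


def average_parameters(
    fits: dict[str, PosteriorSample], weights: dict[str, float] | None = None
) -> pd.DataFrame:
    """WAIC-weighted condition-level parameter summary for one subject.

    ``fits`` must contain all six models.  Returns one row per norm
    condition with columns ``sp_bias`` and ``drift_delta``; with no social
    effect in the data both are zero in expectation.
    """
    missing = [m for m in MODEL_NAMES if m not in fits]
    if missing:
        raise ValueError(f"averaging requires all six fits; missing: {missing}")
    if weights is None:
        ws = waic_weights([waic(fits[m].pointwise_loglik).waic for m in MODEL_NAMES])
        weights = dict(zip(MODEL_NAMES, ws))
    out = None
    for m in MODEL_NAMES:
        eff = _model_effects(build_model(m), fits[m].mean())
        contrib = eff[["sp_bias", "drift_delta"]] * weights[m]
        out = contrib if out is None else out + contrib
    out.insert(0, "condition", eff["condition"])
    return out


def comparison_table(all_fits: dict[int, dict[str, PosteriorSample]]) -> pd.DataFrame:
    """Per-subject model-comparison table across a cohort.

    ``all_fits`` maps subject id -> {model name -> fit}.  Columns: subject,
    model, waic, lppd, p_waic, weight, rhat_max.
    """
    rows = []
    for subject, fits in all_fits.items():
        res = {m: waic(fits[m].pointwise_loglik) for m in fits}
        ws = waic_weights([res[m].waic for m in fits])
        for (m, r), w in zip(res.items(), ws):
            rows.append(
                (subject, m, r.waic, r.lppd, r.p_waic, float(w),
                 float(np.nanmax(fits[m].rhat)))
            )
    return pd.DataFrame(
        rows, columns=["subject", "model", "waic", "lppd", "p_waic", "weight", "rhat_max"]
    )
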