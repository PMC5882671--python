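"""Model-free behavioural summaries, payoff scoring and design-stage power.

Works on the trial table produced by the generator (or any conforming CSV):
one row per trial with subject, norm prompt, cue configuration, stimulus,
response, RT and accuracy.  Cue *validity* is derived, not stored: congruent
arrows are valid when they point in the true motion direction, invalid when
opposite; incongruent arrows are the dots-only condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PayoffOutcome",
    "add_validity",
    "accuracy_table",
    "conformity_delta",
    "payoff",
    "payoff_table",
    "required_sample_size",
]


def add_validity(data: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``validity`` column: valid/invalid/incongruent."""
    df = data.copy()
    cued_left = df["social"] == "CONGRUENT_LEFT"
    cued_right = df["social"] == "CONGRUENT_RIGHT"
    valid = (cued_left & (df["stimulus"] == "LEFT")) | (
        cued_right & (df["stimulus"] == "RIGHT")
    )
    df["validity"] = np.where(
        df["social"] == "INCONGRUENT", "incongruent",
        np.where(valid, "valid", "invalid"),
    )
    return df


def accuracy_table(data: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per subject x norm x cue validity.

    No-response trials are excluded; cells with no scored trials hold NaN.
    Returns a long-format frame with columns subject, norm, validity,
    accuracy, n_trials.
    """
    df = add_validity(data)
    df = df[df["response"] != "NO_RESPONSE"]
    g = (
        df.groupby(["subject", "norm", "validity"], observed=True)["accuracy"]
        .agg(accuracy="mean", n_trials="size")
        .reset_index()
    )
    return g


def _p_toward_cue(df: pd.DataFrame) -> float:
    cued = np.where(df["social"] == "CONGRUENT_RIGHT", "RIGHT", "LEFT")
    return float((df["response"].to_numpy() == cued).mean())


def conformity_delta(data: pd.DataFrame, norm: str) -> float:
    """Norm-induced change in the probability of choosing the cued side.

    Computed over congruent-cue, responded trials only:
    P(response = cued side | norm) - P(response = cued side | NONE).
    ``norm`` is SAME or ONLY; the result lies in [-1, 1].
    """
    norm = str(norm).upper()
    if norm not in ("SAME", "ONLY"):
        raise ValueError("norm must be SAME or ONLY")
    df = data[(data["social"] != "INCONGRUENT") & (data["response"] != "NO_RESPONSE")]
    under = df[df["norm"] == norm]
    none = df[df["norm"] == "NONE"]
    if len(under) == 0 or len(none) == 0:
        raise ValueError(f"no congruent-cue trials under {norm} and/or NONE")
    return _p_toward_cue(under) - _p_toward_cue(none)


@dataclass(frozen=True)
class PayoffOutcome:
    """Monetary consequence of one decision, in cents."""

    points_self: int
    points_others: int


def payoff(
    norm: str, validity: str, correct: bool | None, experiment: str
) -> PayoffOutcome:
    """Score one phase-2 trial against the payoff matrix.

    The player earns 1 cent iff correct.  Other players are affected only
    on congruent-cue trials under a norm prompt: in the benefit-others
    experiment they gain 1 cent when the player complies with the norm
    *and* is correct (SAME/valid/correct or ONLY/invalid/correct); in the
    harm-others experiment they lose 1 cent when the player breaks the norm
    *and* is wrong (SAME/valid/wrong or ONLY/invalid/wrong).  ``correct``
    may be None for a no-response trial, which scores (0, 0).
    """
    norm = str(norm).upper()
    validity = str(validity).lower()
    experiment = str(experiment).upper()
    if norm not in ("NONE", "SAME", "ONLY"):
        raise ValueError(f"unknown norm {norm!r}")
    if validity not in ("valid", "invalid", "incongruent"):
        raise ValueError(f"unknown validity {validity!r}")
    if experiment not in ("BO", "HO"):
        raise ValueError(f"unknown experiment {experiment!r}")
    if correct is None:
        return PayoffOutcome(0, 0)
    correct = bool(correct)
    self_pts = 1 if correct else 0
    others = 0
    if norm != "NONE" and validity != "incongruent":
        followed_cue = correct if validity == "valid" else not correct
        complied = followed_cue if norm == "SAME" else not followed_cue
        if experiment == "BO" and complied and correct:
            others = 1
        elif experiment == "HO" and not complied and not correct:
            others = -1
    return PayoffOutcome(self_pts, others)


def payoff_table(data: pd.DataFrame) -> pd.DataFrame:
    """Apply the payoff matrix to every trial of a trial table."""
    df = add_validity(data)
    pts = [
        payoff(
            r.norm,
            r.validity,
            None if r.response == "NO_RESPONSE" else bool(r.accuracy),
            r.experiment,
        )
        for r in df.itertuples()
    ]
    df["points_self"] = [p.points_self for p in pts]
    df["points_others"] = [p.points_others for p in pts]
    return df


def required_sample_size(
    effect_size_d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    tails: int = 1,
    n_max: int = 10**6,
) -> int:
    """Minimum n for a paired t-test to reach the target power.

    Power uses the noncentral t distribution with df = n - 1 and
    noncentrality d * sqrt(n); n is scanned upward from 2.  One-tailed by
    default (the convention under which the design-stage calculation for
    d = 0.5, alpha = .05, power = .8 gives n = 27).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_size_d <= 0:
        raise ValueError("effect size must be positive")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    d = float(effect_size_d)
    n = 2
    while n <= n_max:
        df = n - 1
        nc = d * np.sqrt(n)
        if tails == 1:
            tcrit = stats.t.ppf(1 - alpha, df)
            pw = stats.nct.sf(tcrit, df, nc)
        else:
            tcrit = stats.t.ppf(1 - alpha / 2, df)
            pw = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if pw >= power:
            return n
        n += 1
    raise ValueError(f"target power not attainable for n <= {n_max}")
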