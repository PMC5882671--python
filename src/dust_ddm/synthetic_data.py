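"""Synthetic DUST-task cohorts: trial schedules and simulated behaviour.

The task: on each trial a participant judges the direction of a random-dot
kinematogram (left/right, 2.5 s response deadline) while two arrows display
the alleged decisions of two other players.  Arrows are either incongruent
(dots-only information) or congruent, in which case they are valid or
invalid with respect to the true motion.  A norm prompt shown at trial
onset (NONE / SAME / ONLY) tells the player to ignore, follow, or oppose
the social information, with monetary consequences for the *other* players
only.

Phase-two schedules contain 360 trials, 120 per norm condition, with cue
types at exactly 40% valid / 30% invalid / 30% incongruent and no more than
three consecutive trials sharing a norm.  Cue proportions are stratified
within each norm condition (48/36/36) so condition contrasts stay balanced,
and motion direction is balanced left/right within every norm x cue cell.

Behaviour is simulated from a diffusion process whose default base
parameters (a=1.2, w=0.5, v=0.706, t0=0.3, sv=0) put dots-only accuracy at
1/(1+exp(-v*a)) ~ 0.70, matching the staircase target the task calibrates
participants to.  Congruent cues shift the starting point toward the cued
side by a norm-dependent amount, and the ONLY prompt can additionally
change the congruent-trial drift; the benefit-others (BO) and harm-others
(HO) presets differ only in how strongly the ONLY condition pushes these
effects negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ddm_core import DDMParams, simulate_trials
from .model_space import Norm, Social, Stimulus, TrialContext

__all__ = [
    "TrialSpec",
    "GroundTruth",
    "PRESETS",
    "DEADLINE_S",
    "generate_schedule",
    "simulate_subject",
    "generate_cohort",
    "TRIAL_COLUMNS",
]

DEADLINE_S = 2.5
ITI_S = 3.0
PROMPT_RANGE_S = (0.5, 1.0)

#: trial-table schema used throughout the package
TRIAL_COLUMNS = [
    "subject",
    "experiment",
    "trial",
    "norm",
    "social",
    "stimulus",
    "response",
    "rt_s",
    "accuracy",
    "no_response",
]


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial before any behaviour is simulated."""

    trial: int
    norm: Norm
    social: Social
    stimulus: Stimulus
    phase: int = 2
    coherence: float = 1.0
    deadline_s: float = DEADLINE_S
    prompt_s: float = 0.75
    iti_s: float = ITI_S

    @property
    def context(self) -> TrialContext:
        return TrialContext(self.norm, self.social, self.stimulus)


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject generating parameters.

    ``dw_*`` are starting-point shifts toward the cued side on congruent
    trials under each norm prompt (w = 0.5 + dw for right-pointing cues,
    0.5 - dw for left-pointing); ``dv_only`` changes the drift magnitude on
    congruent ONLY trials.
    """

    a: float = 1.2
    w_base: float = 0.5
    v_base: float = 0.706
    t0: float = 0.3
    sv: float = 0.0
    dw_none: float = 0.0
    dw_same: float = 0.0
    dw_only: float = 0.0
    dv_only: float = 0.0
    experiment: str = "BO"
    subject: int = 0

    def dw(self, norm: Norm) -> float:
        return {Norm.NONE: self.dw_none, Norm.SAME: self.dw_same, Norm.ONLY: self.dw_only}[norm]

    def trial_params(self, ctx: TrialContext) -> DDMParams:
        """Diffusion parameters implied for one trial context."""
        w = self.w_base
        if ctx.social is Social.CONGRUENT_RIGHT:
            w = self.w_base + self.dw(ctx.norm)
        elif ctx.social is Social.CONGRUENT_LEFT:
            w = self.w_base - self.dw(ctx.norm)
        vmag = self.v_base * 1.0
        if ctx.norm is Norm.ONLY and ctx.social is not Social.INCONGRUENT:
            vmag = vmag + self.dv_only
        sign = 1.0 if ctx.stimulus is Stimulus.RIGHT else -1.0
        return DDMParams(a=self.a, w=w, v=sign * vmag, t0=self.t0, sv=self.sv)


#: cohort presets: effect sizes reproduce the qualitative ordering of the
#: two experiments (SAME > NONE > ONLY starting-point shifts; ONLY effects
#: more negative when non-compliance harms the other players)
PRESETS: dict[str, GroundTruth] = {
    "BO": GroundTruth(dw_none=0.06, dw_same=0.12, dw_only=0.02, dv_only=-0.15, experiment="BO"),
    "HO": GroundTruth(dw_none=0.06, dw_same=0.12, dw_only=-0.04, dv_only=-0.35, experiment="HO"),
}


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------


def _norm_sequence(counts: dict[Norm, int], max_run: int, rng, max_attempts: int = 1000):
    """Random norm sequence with exact counts and bounded run length."""
    norms = list(counts)
    for _ in range(max_attempts):
        remaining = dict(counts)
        seq: list[Norm] = []
        ok = True
        while any(remaining.values()):
            run = 0
            if seq:
                last = seq[-1]
                run = 1
                for x in reversed(seq[:-1]):
                    if x == last:
                        run += 1
                    else:
                        break
            allowed = [
                n for n in norms
                if remaining[n] > 0 and not (seq and n == seq[-1] and run >= max_run)
            ]
            if not allowed:
                ok = False
                break
            weights = np.array([remaining[n] for n in allowed], dtype=float)
            pick = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            seq.append(pick)
            remaining[pick] -= 1
        if ok:
            return seq
    raise RuntimeError(
        f"could not build a norm sequence satisfying max_run={max_run} "
        f"in {max_attempts} attempts"
    )


def generate_schedule(
    n_trials: int = 360,
    norm_counts: dict | None = None,
    social_props: dict | None = None,
    max_run: int = 3,
    seed: int | np.random.Generator = 0,
    phase: int = 2,
) -> list[TrialSpec]:
    """Generate a phase-two trial schedule with exact design counts.

    Cue-type proportions (default 40% valid / 30% invalid / 30%
    incongruent) are applied within each norm condition; motion direction is
    balanced left/right within every norm x cue-type cell, which requires
    all cell counts to be even.  Norm order is randomized subject to at most
    ``max_run`` identical prompts in a row.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if norm_counts is None:
        norm_counts = {Norm.NONE: n_trials // 3, Norm.SAME: n_trials // 3, Norm.ONLY: n_trials // 3}
    norm_counts = {Norm(k): int(v) for k, v in norm_counts.items()}
    if sum(norm_counts.values()) != n_trials:
        raise ValueError("norm counts must sum to n_trials")
    if social_props is None:
        social_props = {"valid": 0.4, "invalid": 0.3, "incongruent": 0.3}
    if abs(sum(social_props.values()) - 1.0) > 1e-9:
        raise ValueError("social proportions must sum to 1")

    per_norm_cells: dict[Norm, list[tuple[str, Stimulus]]] = {}
    for norm, cnt in norm_counts.items():
        cells: list[tuple[str, Stimulus]] = []
        for kind, prop in social_props.items():
            k = prop * cnt
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"social proportion {prop} x {cnt} trials is not integral"
                )
            k = int(round(k))
            if k % 2:
                raise ValueError(
                    f"cell {norm.value}/{kind} has odd count {k}; cannot balance L/R"
                )
            cells += [(kind, Stimulus.LEFT)] * (k // 2) + [(kind, Stimulus.RIGHT)] * (k // 2)
        order = rng.permutation(len(cells))
        per_norm_cells[norm] = [cells[i] for i in order]

    seq = _norm_sequence(norm_counts, max_run, rng)
    cursor = {n: 0 for n in norm_counts}
    trials: list[TrialSpec] = []
    for i, norm in enumerate(seq):
        kind, stim = per_norm_cells[norm][cursor[norm]]
        cursor[norm] += 1
        if kind == "incongruent":
            social = Social.INCONGRUENT
        elif kind == "valid":
            social = Social.CONGRUENT_LEFT if stim is Stimulus.LEFT else Social.CONGRUENT_RIGHT
        else:  # invalid: arrows point away from the motion
            social = Social.CONGRUENT_RIGHT if stim is Stimulus.LEFT else Social.CONGRUENT_LEFT
        trials.append(
            TrialSpec(
                trial=i + 1,
                norm=norm,
                social=social,
                stimulus=stim,
                phase=phase,
                prompt_s=float(rng.uniform(*PROMPT_RANGE_S)),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# behaviour simulation
# ---------------------------------------------------------------------------


def simulate_subject(
    truth: GroundTruth,
    schedule: list[TrialSpec],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one subject's responses on a schedule.

    Trials sharing a parameter context are sampled together from the exact
    first-passage distribution; responses slower than the deadline become
    no-responses with missing RT and accuracy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(schedule)
    groups: dict[DDMParams, list[int]] = {}
    for i, spec in enumerate(schedule):
        groups.setdefault(truth.trial_params(spec.context), []).append(i)

    choice = np.zeros(n, dtype=int)
    rt = np.full(n, np.nan)
    # deterministic group order for seed reproducibility
    for params in sorted(groups, key=lambda p: (p.w, p.v)):
        idx = np.array(groups[params])
        c, r = simulate_trials(params, idx.size, DEADLINE_S, rng)
        choice[idx], rt[idx] = c, r

    rows = []
    for i, spec in enumerate(schedule):
        no_resp = choice[i] == 0
        response = "NO_RESPONSE" if no_resp else ("RIGHT" if choice[i] == 1 else "LEFT")
        acc = np.nan if no_resp else float(response == spec.stimulus.value)
        rows.append(
            (
                truth.subject,
                truth.experiment,
                spec.trial,
                spec.norm.value,
                spec.social.value,
                spec.stimulus.value,
                response,
                round(rt[i], 6) if not no_resp else np.nan,
                acc,
                bool(no_resp),
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _jitter(rng, mean: float, rel_sd: float = 0.25, lo: float = -np.inf, hi: float = np.inf) -> float:
    """Truncated-normal jitter with SD proportional to the mean magnitude."""
    sd = rel_sd * abs(mean)
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise RuntimeError("jitter rejection sampling failed")


def draw_subject_truth(
    preset: GroundTruth, subject: int, rng: np.random.Generator
) -> GroundTruth:
    """Per-subject parameters: truncated-normal jitter around the preset."""
    return dataclasses.replace(
        preset,
        subject=subject,
        a=_jitter(rng, preset.a, lo=0.3, hi=4.0),
        v_base=_jitter(rng, preset.v_base, lo=0.1, hi=4.0),
        t0=_jitter(rng, preset.t0, lo=0.05, hi=0.8),
        sv=_jitter(rng, preset.sv, lo=0.0, hi=2.0),
        dw_none=_jitter(rng, preset.dw_none, lo=-0.3, hi=0.3),
        dw_same=_jitter(rng, preset.dw_same, lo=-0.3, hi=0.3),
        dw_only=_jitter(rng, preset.dw_only, lo=-0.3, hi=0.3),
        dv_only=_jitter(rng, preset.dv_only, lo=-0.6, hi=0.6),
    )


def generate_cohort(
    n_subjects: int,
    experiment: str = "HO",
    master_seed: int = 0,
    preset: GroundTruth | None = None,
    truths: list[GroundTruth] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trial table, ground-truth table).

    Subjects get independent schedules and truncated-normal parameter
    jitter around the experiment preset (or explicit ``truths``).  When
    ``out_dir`` is given, per-subject CSVs and a ``ground_truth.csv``
    sidecar are written there.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    experiment = experiment.upper()
    if preset is None:
        preset = PRESETS[experiment]
    master = np.random.default_rng(master_seed)
    seeds = master.integers(0, 2**31 - 1, size=(n_subjects, 2))

    frames, truth_rows = [], []
    for s in range(n_subjects):
        rng_truth = np.random.default_rng(seeds[s, 0])
        truth = truths[s] if truths is not None else draw_subject_truth(preset, s + 1, rng_truth)
        schedule = generate_schedule(seed=rng_truth)
        df = simulate_subject(truth, schedule, seed=np.random.default_rng(seeds[s, 1]))
        frames.append(df)
        truth_rows.append(dataclasses.asdict(truth))
    data = pd.concat(frames, ignore_index=True)
    truth_df = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, df in zip(truth_df["subject"], frames):
            df.to_csv(out / f"subject_{s:03d}.csv", index=False)
        truth_df.to_csv(out / "ground_truth.csv", index=False)
    return data, truth_df
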