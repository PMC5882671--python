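"""Behavioural summaries, payoff matrix and the power calculation."""

import numpy as np
import pandas as pd
import pytest

from dust_ddm.behavior_metrics import (
    accuracy_table,
    add_validity,
    conformity_delta,
    payoff,
    payoff_table,
    required_sample_size,
)
from dust_ddm.synthetic_data import generate_cohort


def _toy(rows):
    cols = ["subject", "experiment", "trial", "norm", "social", "stimulus",
            "response", "rt_s", "accuracy", "no_response"]
    return pd.DataFrame(rows, columns=cols)


def _random_trials(rng, n=400):
    socials = rng.choice(["INCONGRUENT", "CONGRUENT_LEFT", "CONGRUENT_RIGHT"], n)
    stims = rng.choice(["LEFT", "RIGHT"], n)
    resps = rng.choice(["LEFT", "RIGHT"], n)
    return _toy([
        (1, "BO", i + 1, rng.choice(["NONE", "SAME", "ONLY"]), socials[i], stims[i],
         resps[i], 0.5, float(resps[i] == stims[i]), False)
        for i in range(n)
    ])


class TestAccuracyTable:
    def test_all_correct_toy_data(self):
        df = _toy([
            (1, "BO", 1, "NONE", "INCONGRUENT", "LEFT", "LEFT", 0.5, 1.0, False),
            (1, "BO", 2, "SAME", "CONGRUENT_LEFT", "LEFT", "LEFT", 0.6, 1.0, False),
        ])
        out = accuracy_table(df)
        assert (out["accuracy"] == 1.0).all()

    def test_no_response_excluded_and_missing_cells_absent(self):
        df = _toy([
            (1, "BO", 1, "NONE", "INCONGRUENT", "LEFT", "NO_RESPONSE", np.nan, np.nan, True),
            (1, "BO", 2, "NONE", "INCONGRUENT", "LEFT", "LEFT", 0.5, 1.0, False),
        ])
        out = accuracy_table(df)
        assert len(out) == 1 and out["n_trials"].iloc[0] == 1


class TestConformity:
    def test_identical_behaviour_gives_zero(self, rng):
        df = _random_trials(rng)
        df["norm"] = "SAME"
        other = df.copy()
        other["norm"] = "NONE"
        assert conformity_delta(pd.concat([df, other]), "SAME") == 0.0

    def test_extreme_follower_vs_never(self):
        rows = []
        for i in range(20):
            rows.append((1, "BO", i, "SAME", "CONGRUENT_LEFT", "RIGHT", "LEFT", 0.5, 0.0, False))
            rows.append((1, "BO", 100 + i, "NONE", "CONGRUENT_LEFT", "RIGHT", "RIGHT", 0.5, 1.0, False))
        assert conformity_delta(_toy(rows), "SAME") == 1.0

    def test_conformity_accuracy_identity(self, rng):
        """On valid-cue trials P(choose cued side) = accuracy; on invalid,
        1 - accuracy (definitional)."""
        df = add_validity(_random_trials(rng))
        cued = np.where(df["social"] == "CONGRUENT_RIGHT", "RIGHT", "LEFT")
        toward = (df["response"].to_numpy() == cued)
        valid = df["validity"] == "valid"
        invalid = df["validity"] == "invalid"
        assert toward[valid].mean() == pytest.approx(df.loc[valid, "accuracy"].mean())
        assert toward[invalid].mean() == pytest.approx(1 - df.loc[invalid, "accuracy"].mean())

    def test_requires_congruent_trials(self):
        df = _toy([(1, "BO", 1, "SAME", "INCONGRUENT", "LEFT", "LEFT", 0.5, 1.0, False)])
        with pytest.raises(ValueError):
            conformity_delta(df, "SAME")


# payoff matrix: (norm, validity, correct) -> (self, others_BO, others_HO)
PAYOFF_MATRIX = {
    ("SAME", "valid", True): (1, 1, 0),
    ("SAME", "valid", False): (0, 0, -1),
    ("SAME", "invalid", True): (1, 0, 0),
    ("SAME", "invalid", False): (0, 0, 0),
    ("ONLY", "valid", True): (1, 0, 0),
    ("ONLY", "valid", False): (0, 0, 0),
    ("ONLY", "invalid", True): (1, 1, 0),
    ("ONLY", "invalid", False): (0, 0, -1),
}


class TestPayoff:
    @pytest.mark.parametrize("cell,expected", PAYOFF_MATRIX.items())
    def test_norm_cells(self, cell, expected):
        norm, validity, correct = cell
        self_pts, bo, ho = expected
        out_bo = payoff(norm, validity, correct, "BO")
        out_ho = payoff(norm, validity, correct, "HO")
        assert out_bo.points_self == out_ho.points_self == self_pts
        assert out_bo.points_others == bo
        assert out_ho.points_others == ho

    @pytest.mark.parametrize("norm", ["NONE", "SAME", "ONLY"])
    @pytest.mark.parametrize("experiment", ["BO", "HO"])
    def test_incongruent_and_none_never_affect_others(self, norm, experiment):
        for correct in (True, False):
            assert payoff(norm, "incongruent", correct, experiment).points_others == 0
        if norm == "NONE":
            for validity in ("valid", "invalid"):
                for correct in (True, False):
                    assert payoff(norm, validity, correct, experiment).points_others == 0

    def test_no_response_scores_nothing(self):
        out = payoff("SAME", "valid", None, "HO")
        assert (out.points_self, out.points_others) == (0, 0)

    def test_self_points_equal_correct_count(self):
        data, _ = generate_cohort(2, "BO", master_seed=3)
        scored = payoff_table(data)
        n_correct = data.loc[~data["no_response"], "accuracy"].sum()
        assert scored["points_self"].sum() == int(n_correct)


class TestSampleSize:
    def test_one_tailed_medium_effect_needs_27(self):
        assert required_sample_size(0.5, alpha=0.05, power=0.8, tails=1) == 27

    def test_two_tailed_brute_force_value(self):
        # frozen from an upward scan of the noncentral-t power formula
        assert required_sample_size(0.5, alpha=0.05, power=0.8, tails=2) == 34

    def test_huge_effect_saturates_near_minimal_df(self):
        assert required_sample_size(3.0, tails=1) == 3
        assert required_sample_size(3.0, tails=2) == 4

    def test_monotonicity(self):
        n_base = required_sample_size(0.5)
        assert required_sample_size(0.7) <= n_base           # larger effect
        assert required_sample_size(0.5, alpha=0.10) <= n_base  # looser alpha
        assert required_sample_size(0.5, power=0.9) >= n_base   # stricter power

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(-0.5)
        with pytest.raises(ValueError):
            required_sample_size(0.5, alpha=1.5)
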