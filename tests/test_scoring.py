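"""Selection/production scoring, Cohen's kappa and the score ANOVAs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from toolkin import (
    ScorePair,
    TrialOutcome,
    cohens_kappa,
    score_anova,
    score_production,
    score_selection,
    score_trial,
)


def all_valid_outcomes():
    """Exhaustive enumeration of consistent outcome-flag combinations."""
    out = []
    for correct, corrections, level in itertools.product(
        (False, True), (0, 1, 2, 3), (0, 1, 2, 3)
    ):
        out.append(
            TrialOutcome(
                correct_tool_selected=correct,
                self_corrections=corrections,
                goal_achieved=level == 3,
                tool_grasped=level >= 1,
                tool_moved_to_cylinder=level >= 2,
                tool_attached=level >= 3,
            )
        )
    return out


def selection_oracle(o: TrialOutcome) -> int:
    """Literal transcription of the two published selection rules."""
    proper_tool = o.correct_tool_selected and o.self_corrections <= 1
    wrong_tool_but_goal = (not proper_tool) and o.goal_achieved
    return 1 if (proper_tool or wrong_tool_but_goal) else 0


def production_oracle(o: TrialOutcome) -> int:
    if o.goal_achieved:
        return 3
    if o.tool_grasped and o.tool_moved_to_cylinder:
        return 2
    if o.tool_grasped:
        return 1
    return 0


class TestScores:
    def test_selection_matches_truth_table(self):
        for o in all_valid_outcomes():
            assert score_selection(o) == selection_oracle(o), o

    def test_production_matches_truth_table(self):
        for o in all_valid_outcomes():
            assert score_production(o) == production_oracle(o), o

    def test_quoted_rule_examples(self):
        correct = dict(correct_tool_selected=True, self_corrections=0)
        wrong = dict(correct_tool_selected=False, self_corrections=0)
        full = dict(goal_achieved=True, tool_grasped=True,
                    tool_moved_to_cylinder=True, tool_attached=True)
        nothing = dict(goal_achieved=False, tool_grasped=False,
                       tool_moved_to_cylinder=False, tool_attached=False)
        assert score_selection(TrialOutcome(**correct, **full)) == 1
        assert score_selection(TrialOutcome(**wrong, **full)) == 1
        assert score_selection(
            TrialOutcome(correct_tool_selected=True, self_corrections=2, **nothing)
        ) == 0
        assert score_production(TrialOutcome(**correct, **full)) == 3
        grasped_only = dict(goal_achieved=False, tool_grasped=True,
                            tool_moved_to_cylinder=False, tool_attached=False)
        assert score_production(TrialOutcome(**correct, **grasped_only)) == 1
        assert score_production(TrialOutcome(**wrong, **nothing)) == 0

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(ValueError):
            TrialOutcome(True, 0, goal_achieved=True, tool_grasped=False,
                         tool_moved_to_cylinder=False, tool_attached=False)

    def test_score_pair_validation(self):
        with pytest.raises(ValueError):
            ScorePair(selection=2, production=1)
        sp = score_trial(all_valid_outcomes()[0])
        assert sp.selection in (0, 1) and sp.production in range(4)


class TestCohensKappa:
    def test_identical_vectors(self):
        k, (lo, hi) = cohens_kappa([1, 0, 1, 2, 2], [1, 0, 1, 2, 2])
        assert k == pytest.approx(1.0)
        assert hi >= 1.0 - 1e-12

    def test_independent_labels_near_zero(self, rng):
        a = rng.integers(0, 2, size=20_000)
        b = rng.integers(0, 2, size=20_000)
        k, (lo, hi) = cohens_kappa(a, b)
        assert abs(k) < 0.03
        assert lo < 0 < hi

    def test_hand_computed_two_by_two_table(self):
        # agreement table [[45, 5], [5, 45]]: po = 0.9, pe = 0.5, kappa = 0.8
        a = np.r_[np.zeros(50), np.ones(50)]
        b = np.r_[np.zeros(45), np.ones(5), np.zeros(5), np.ones(45)]
        k, _ = cohens_kappa(a, b)
        assert k == pytest.approx(0.8)

    def test_matches_sklearn(self, rng):
        a = rng.integers(0, 4, size=500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 4, size=500))
        k, _ = cohens_kappa(a, b)
        assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        a = rng.integers(0, 3, size=300)
        b = rng.integers(0, 3, size=300)
        k1, _ = cohens_kappa(a, b)
        perm = {0: 2, 1: 0, 2: 1}
        k2, _ = cohens_kappa(np.vectorize(perm.get)(a), np.vectorize(perm.get)(b))
        assert k1 == pytest.approx(k2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([], [])


def _simulate_scores(rng, n=37, effects=None, participant_sd=0.08, noise_sd=0.1):
    """Participant-level cell means for a 2 (site) x 2 (type) x 2 (timepoint)
    mixed design with additive effects on selected contrasts."""
    effects = effects or {}
    rows = []
    for i in range(n):
        site = "aSMG" if i % 2 == 0 else "vPreCG"
        base = 0.85 + rng.normal(0, participant_sd)
        for st in ("sham", "verum"):
            for tp in ("early", "late"):
                y = base + rng.normal(0, noise_sd)
                y += effects.get("timepoint", 0.0) * (0.5 if tp == "late" else -0.5)
                y += effects.get("stim_type", 0.0) * (0.5 if st == "verum" else -0.5)
                rows.append(
                    {"participant": f"P{i}", "site": site, "stim_type": st,
                     "timepoint": tp, "score": y}
                )
    return pd.DataFrame(rows)


class TestScoreAnova:
    def test_error_df_matches_two_group_design(self, rng):
        table = score_anova(_simulate_scores(rng))
        assert (table["df2"] == 35).all()
        assert set(table["effect"]) >= {"site", "stim_type", "timepoint",
                                        "stim_type:timepoint:site"}

    def test_identical_scores_give_zero_f(self):
        df = _simulate_scores(np.random.default_rng(0))
        df["score"] = 2.0
        table = score_anova(df)
        assert (table["F"].fillna(0) == 0).all()
        assert (table["p"] == 1.0).all()

    def test_null_type_one_error_rate(self):
        """Under a pure null every effect rejects at about the alpha level."""
        rejections = np.zeros(7)
        reps = 500
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            table = score_anova(_simulate_scores(rng, n=20))
            rejections += (table["p"].to_numpy() < 0.05)
        rates = rejections / reps
        assert (np.abs(rates - 0.05) < 0.03).all(), rates

    def test_injected_timepoint_effect_detected(self):
        hits = 0
        reps = 60
        for i in range(reps):
            rng = np.random.default_rng(2000 + i)
            table = score_anova(_simulate_scores(rng, n=37, effects={"timepoint": 0.08}))
            p = table.set_index("effect").loc["timepoint", "p"]
            hits += p < 0.05
        assert hits / reps > 0.5

    def test_agrees_with_pingouin_on_collapsed_design(self, rng):
        """Collapsing the timepoint factor gives a one-within/one-between
        design that pingouin's mixed ANOVA can check independently."""
        pingouin = pytest.importorskip("pingouin")
        df = _simulate_scores(rng, n=24, effects={"stim_type": 0.1})
        ours = score_anova(df).set_index("effect")
        collapsed = (
            df.groupby(["participant", "site", "stim_type"], observed=True)["score"]
            .mean()
            .reset_index()
        )
        theirs = pingouin.mixed_anova(
            data=collapsed, dv="score", within="stim_type",
            subject="participant", between="site"
        ).set_index("Source")
        assert ours.loc["stim_type", "F"] == pytest.approx(
            theirs.loc["stim_type", "F"], rel=1e-6
        )
        assert ours.loc["site", "F"] == pytest.approx(
            theirs.loc["site", "F"], rel=1e-6
        )
        assert ours.loc["stim_type:site", "F"] == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-6
        )

    def test_participant_missing_cell_excluded(self, rng, caplog):
        df = _simulate_scores(rng, n=10)
        df = df[~((df.participant == "P0") & (df.timepoint == "late"))]
        table = score_anova(df)
        assert (table["df2"] == 10 - 1 - 2).all()
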