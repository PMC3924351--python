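import numpy as np
import pytest

from cbcpref.design import ChoiceTask
from cbcpref.exceptions import AlignmentError, UndefinedImportanceError
from cbcpref.schema import Attribute, AttributeSchema, pain_treatment_schema
from cbcpref.simulate import PanelSpec, SegmentSpec, make_panel
from cbcpref.validity import (
    flag_lexicographic,
    lexicographic_rlh_threshold,
    mae,
    observed_holdout_shares,
    predict_holdout_shares,
    relative_importance,
    respondent_rlh,
    rlh,
    tune_scale,
)


@pytest.fixture(scope="module")
def pair_schema():
    return AttributeSchema(
        (Attribute("a", ("1", "2")), Attribute("b", ("1", "2")))
    )


def task_differing_on(attr_index):
    alts = [[0, 0], [0, 0]]
    alts[1][attr_index] = 1
    return ChoiceTask("t", 1, "random", tuple(map(tuple, alts)))


class TestRLH:
    def test_chance_level_for_uninformative_utilities(self, pair_schema):
        tasks = [task_differing_on(0)] * 4
        value = rlh(np.zeros(2), tasks, [0, 1, 0, 1], pair_schema)
        assert value == pytest.approx(0.5, abs=1e-12)

    def test_product_and_root_hand_case(self, pair_schema):
        # chosen probabilities 0.8 and 0.5 -> RLH = sqrt(0.40) = 0.6325
        beta = np.array([np.log(4) / 2, 0.0])
        tasks = [task_differing_on(0), task_differing_on(1)]
        value = rlh(beta, tasks, [0, 0], pair_schema)
        assert value == pytest.approx(np.sqrt(0.8 * 0.5), abs=1e-12)

    def test_perfect_prediction_approaches_one(self, pair_schema):
        beta = np.array([50.0, 50.0])
        tasks = [task_differing_on(0), task_differing_on(1)]
        assert rlh(beta, tasks, [0, 0], pair_schema) > 0.999999

    def test_true_utilities_beat_permuted_choices(self, schema, trader_mean):
        """Internal-validity sanity: scoring the generating utilities on
        the real choices must beat scoring them on permuted choices."""
        panel = make_panel(
            [SegmentSpec("s", 1.0, tuple(trader_mean), heterogeneity_sd=0.2)],
            PanelSpec(100, waves=1, seed=3),
            schema,
            seed=3,
        )
        names = schema.param_names()
        truth = panel.truth.set_index("respondent_id")
        betas = truth.loc[
            sorted(panel.data["respondent_id"].unique()), names
        ].to_numpy()
        ids = sorted(panel.data["respondent_id"].unique())
        real = respondent_rlh(betas, ids, panel.data, schema).mean()
        shuffled = panel.data.copy()
        rng = np.random.default_rng(0)
        flip = rng.integers(2, size=len(shuffled) // 2)
        shuffled["chosen"] = np.where(
            np.repeat(flip, 2), 1 - shuffled["chosen"], shuffled["chosen"]
        )
        permuted = respondent_rlh(betas, ids, shuffled, schema).mean()
        assert real > permuted + 0.1


class TestRelativeImportance:
    def test_single_active_attribute_takes_all(self, pair_schema):
        imp = relative_importance(np.array([1.3, 0.0]), pair_schema)
        assert np.allclose(imp, [100.0, 0.0])

    def test_rows_sum_to_one_hundred(self, schema, rng):
        betas = rng.normal(size=(50, schema.n_params))
        imp = relative_importance(betas, schema)
        assert np.allclose(imp.sum(axis=1), 100.0, atol=1e-9)
        assert (imp >= 0).all()

    def test_range_method_on_published_aggregate_utilities(self):
        """Range/sum-of-ranges applied to the published baseline aggregate
        utilities (ranges 162.6 / 61.6 / 89.1 / 39.0 / 57.6).  These differ
        from the published importances, which average per-respondent
        importances instead."""
        schema = pain_treatment_schema()
        levels = {
            "pain_relief": [-90.3, -12.9, 30.9, 72.3],
            "side_effect_type": [-37.8, 23.8, 13.7, 16.9, -16.7],
            "side_effect_severity": [32.5, 24.1, -56.6],
            "analgesic_type": [19.5, -19.5],
            "cost": [24.5, 20.8, -0.16, -11.9, -33.1],
        }
        beta = np.concatenate(
            [np.asarray(levels[a.name][:-1], float) - np.mean(levels[a.name])
             for a in schema.attributes]
        )
        imp = relative_importance(beta, schema)
        expected = 100 * np.array([162.6, 61.6, 89.1, 39.0, 57.6]) / 409.9
        assert np.allclose(imp, expected, atol=0.25)

    def test_all_zero_ranges_undefined(self, pair_schema):
        with pytest.raises(UndefinedImportanceError):
            relative_importance(np.zeros(2), pair_schema)


class TestLexicographicFlag:
    def test_default_threshold_is_1_5_times_chance(self):
        assert lexicographic_rlh_threshold(2) == pytest.approx(0.750)
        assert lexicographic_rlh_threshold(4) == pytest.approx(0.375)

    @pytest.mark.parametrize(
        "rlh_value,max_imp,expected",
        [
            (0.80, 55.0, True),
            (0.80, 45.0, False),
            (0.70, 60.0, False),
            (0.750, 50.0, False),   # strict inequalities at both boundaries
            (0.751, 50.1, True),
        ],
    )
    def test_rule_boundaries(self, rlh_value, max_imp, expected):
        rest = (100.0 - max_imp) / 4
        imps = np.array([max_imp, rest, rest, rest, rest])
        assert imps.max() == max_imp
        assert flag_lexicographic(rlh_value, imps) is expected


class TestHoldoutPrediction:
    def test_identical_zero_respondents_split_evenly(self, pair_schema):
        task = task_differing_on(0)
        shares = predict_holdout_shares(np.zeros((5, 2)), task, pair_schema)
        assert np.allclose(shares, 0.5)

    def test_zero_scale_limit_is_uniform(self, pair_schema, rng):
        task = task_differing_on(0)
        betas = rng.normal(size=(8, 2))
        shares = predict_holdout_shares(betas, task, pair_schema, scale=1e-9)
        assert np.allclose(shares, 0.5, atol=1e-6)

    def test_average_of_two_subgroups(self, pair_schema):
        """Subgroups with individual shares (0.9, 0.1) and (0.5, 0.5)
        aggregate to (0.7, 0.3)."""
        task = task_differing_on(0)   # alt-1 utility gap = +2 * beta[0]
        b_strong = np.array([np.log(9) / 2, 0.0])  # share 0.9 for alt 1
        b_even = np.zeros(2)
        betas = np.stack([b_strong, b_even])
        shares = predict_holdout_shares(betas, task, pair_schema)
        assert np.allclose(shares, [0.7, 0.3], atol=1e-12)

    def test_empty_respondent_set_rejected(self, pair_schema):
        with pytest.raises(AlignmentError):
            predict_holdout_shares(
                np.zeros((0, 2)), task_differing_on(0), pair_schema
            )


class TestMAE:
    def test_perfect_agreement_is_zero(self):
        shares = {"H1": np.array([0.6, 0.4]), "H2": np.array([0.7, 0.3])}
        assert mae(shares, shares) == 0.0

    def test_hand_computed_ten_points(self):
        predicted = {"H1": [0.6, 0.4], "H2": [0.6, 0.4]}
        observed = {"H1": [0.7, 0.3], "H2": [0.7, 0.3]}
        assert mae(predicted, observed) == pytest.approx(10.0)
        assert mae(observed, predicted) == pytest.approx(10.0)  # symmetry

    def test_mismatched_tasks_rejected(self):
        with pytest.raises(AlignmentError):
            mae({"H1": [0.5, 0.5]}, {"H2": [0.5, 0.5]})


@pytest.fixture(scope="module")
def scaled_panel(schema, trader_mean):
    """Choices simulated at response scale 2 with known part-worths."""
    segments = [
        SegmentSpec(
            "s", 1.0, tuple(trader_mean),
            heterogeneity_sd=0.15, response_scale=2.0,
        )
    ]
    return make_panel(
        segments, PanelSpec(300, waves=1, seed=8), schema, seed=8
    )


class TestScaleTuning:
    def test_recovers_generating_scale_within_grid_step(self, scaled_panel, schema):
        panel = scaled_panel
        names = schema.param_names()
        truth = panel.truth.set_index("respondent_id")
        ids = sorted(panel.data["respondent_id"].unique())
        betas = truth.loc[ids, names].to_numpy()
        observed = observed_holdout_shares(panel.data, schema)
        holdouts = {h.task_id: h for h in panel.holdouts}
        grid = [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0]
        best, _ = tune_scale(betas, holdouts, observed, schema, grid)
        assert best in (1.5, 2.0, 2.5)

    def test_tuned_mae_never_worse_than_unit_scale(self, scaled_panel, schema):
        panel = scaled_panel
        names = schema.param_names()
        truth = panel.truth.set_index("respondent_id")
        ids = sorted(panel.data["respondent_id"].unique())
        betas = truth.loc[ids, names].to_numpy()
        observed = observed_holdout_shares(panel.data, schema)
        holdouts = {h.task_id: h for h in panel.holdouts}
        predicted_1 = {
            tid: predict_holdout_shares(betas, t, schema, 1.0)
            for tid, t in holdouts.items()
        }
        _, best_mae = tune_scale(
            betas, holdouts, observed, schema, [0.5, 1.0, 2.0]
        )
        assert best_mae <= mae(predicted_1, observed) + 1e-12

    def test_vanishing_scale_equals_uniform_share_error(self, scaled_panel, schema):
        panel = scaled_panel
        observed = observed_holdout_shares(panel.data, schema)
        holdouts = {h.task_id: h for h in panel.holdouts}
        betas = np.ones((10, schema.n_params))
        predicted = {
            tid: predict_holdout_shares(betas, t, schema, scale=1e-9)
            for tid, t in holdouts.items()
        }
        uniform = {tid: np.full(2, 0.5) for tid in holdouts}
        assert mae(predicted, observed) == pytest.approx(
            mae(uniform, observed), abs=1e-4
        )
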