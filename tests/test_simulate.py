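import numpy as np
import pandas as pd
import pytest

from cbcpref.design import ChoiceTask, RespondentDesign
from cbcpref.exceptions import AlignmentError, ConfigurationError
from cbcpref.io import read_choice_data, write_choice_data
from cbcpref.simulate import (
    PanelSpec,
    SegmentSpec,
    SimulatedRespondent,
    make_lexicographic,
    make_paper_like_dataset,
    paper_like_segments,
    sample_population,
    simulate_choices,
)
from cbcpref.validity import relative_importance


def one_segment(mean, **kw):
    return [SegmentSpec("seg", 1.0, tuple(mean), **kw)]


class TestPopulation:
    def test_segment_proportions_recovered_binomially(self, schema, trader_mean):
        segs = [
            SegmentSpec("s1", 0.58, tuple(trader_mean)),
            SegmentSpec("s2", 0.42, tuple(trader_mean)),
        ]
        n = 10_000
        pop = sample_population(segs, PanelSpec(n, waves=1, seed=1), schema)
        count = sum(r.segment == "s1" for r in pop)
        sd = np.sqrt(n * 0.58 * 0.42)
        assert abs(count - 0.58 * n) < 3 * sd

    def test_dropout_rate_matches_study_attrition(self, schema, trader_mean):
        # 17% attrition from 241 leaves ~200 completers (study: 201)
        pop = sample_population(
            one_segment(trader_mean),
            PanelSpec(241, waves=2, dropout_rate=0.17, seed=5),
            schema,
        )
        completers = sum(2 in r.completed_waves for r in pop)
        sd = np.sqrt(241 * 0.17 * 0.83)
        assert abs(completers - 241 * 0.83) < 3 * sd

    def test_zero_drift_keeps_partworths_identical(self, schema, trader_mean):
        pop = sample_population(
            one_segment(trader_mean, heterogeneity_sd=0.5),
            PanelSpec(20, waves=2, drift_sd=0.0, seed=2),
            schema,
        )
        for r in pop:
            assert np.array_equal(r.true_partworths[0], r.true_partworths[1])

    def test_seed_determinism(self, schema, trader_mean):
        kw = dict(
            segments=one_segment(trader_mean, heterogeneity_sd=0.4),
            panel=PanelSpec(30, waves=2, drift_sd=0.1, dropout_rate=0.2, seed=9),
            schema=schema,
        )
        p1, p2 = sample_population(**kw), sample_population(**kw)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.true_partworths, b.true_partworths)
            assert a.completed_waves == b.completed_waves

    @pytest.mark.parametrize(
        "bad",
        [
            dict(proportion=0.5),               # proportions don't sum to 1
            dict(heterogeneity_sd=-0.1),
            dict(response_scale=0.0),
        ],
    )
    def test_bad_segment_configs_rejected(self, schema, trader_mean, bad):
        seg = SegmentSpec("s", bad.pop("proportion", 1.0), tuple(trader_mean), **bad)
        with pytest.raises(ConfigurationError):
            sample_population([seg], PanelSpec(5, waves=1, seed=0), schema)

    def test_empty_segment_list_rejected(self, schema):
        with pytest.raises(ConfigurationError):
            sample_population([], PanelSpec(5, waves=1, seed=0), schema)

    def test_lexicographic_segment_must_dominate(self, schema, trader_mean):
        seg = SegmentSpec(
            "lex", 1.0, tuple(trader_mean),
            lexicographic_attribute="pain_relief",
        )
        with pytest.raises(ConfigurationError, match="80%"):
            sample_population([seg], PanelSpec(5, waves=1, seed=0), schema)
        # after rescaling, the same vector qualifies
        fixed = make_lexicographic(schema, trader_mean, "pain_relief")
        ranges = [
            blk.max() - blk.min() for blk in schema.expand_partworths(fixed)
        ]
        assert ranges[0] / sum(ranges) == pytest.approx(0.80, abs=1e-9)


class TestChoices:
    @staticmethod
    def _fixed_design(schema, task, n, waves=(1,)):
        designs, respondents = {}, []
        for i in range(n):
            rid = f"r{i}"
            for w in waves:
                designs[(rid, w)] = RespondentDesign(rid, (task,))
        return designs

    def test_zero_partworths_give_even_shares(self, tiny_schema):
        task = ChoiceTask("R1", 1, "random", ((0, 0), (1, 1)))
        n = 10_000
        respondents = [
            SimulatedRespondent(
                f"r{i}", "g", "s", np.zeros((1, 2)), (1,)
            )
            for i in range(n)
        ]
        designs = self._fixed_design(tiny_schema, task, n)
        data = simulate_choices(respondents, designs, tiny_schema, seed=0)
        share = data.loc[data["alternative_id"] == 1, "chosen"].mean()
        assert abs(share - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_unit_utility_gap_gives_logistic_share(self, tiny_schema):
        # gap d = 1.0 at scale 1 -> chosen share exp(1)/(1+exp(1)) = 0.731
        beta = np.array([0.25, 0.25])  # both attrs differ: gap = 4 * 0.25
        task = ChoiceTask("R1", 1, "random", ((0, 0), (1, 1)))
        n = 10_000
        respondents = [
            SimulatedRespondent(f"r{i}", "g", "s", beta[None, :], (1,))
            for i in range(n)
        ]
        designs = self._fixed_design(tiny_schema, task, n)
        data = simulate_choices(respondents, designs, tiny_schema, seed=1)
        share = data.loc[data["alternative_id"] == 1, "chosen"].mean()
        expected = np.exp(1) / (1 + np.exp(1))
        assert abs(share - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_infinite_scale_limit_is_argmax(self, tiny_schema):
        beta = np.array([0.3, -0.2])
        task = ChoiceTask("R1", 1, "random", ((0, 1), (1, 0)))
        respondents = [
            SimulatedRespondent(
                f"r{i}", "g", "s", beta[None, :], (1,), response_scale=1e3
            )
            for i in range(200)
        ]
        designs = self._fixed_design(tiny_schema, task, 200)
        data = simulate_choices(respondents, designs, tiny_schema, seed=2)
        # utility of alt 1: .3*1 + (-.2)*(-1) = .5 > alt 2's -.5: always chosen
        assert (data.loc[data["alternative_id"] == 1, "chosen"] == 1).all()

    def test_missing_design_raises_alignment_error(self, tiny_schema):
        r = SimulatedRespondent("r0", "g", "s", np.zeros((1, 2)), (1,))
        with pytest.raises(AlignmentError):
            simulate_choices([r], {}, tiny_schema, seed=0)


@pytest.fixture(scope="module")
def panel():
    return make_paper_like_dataset(seed=99)


class TestPaperLikePanel:
    def test_group_sizes_and_waves(self, panel):
        w1 = panel.data.query("wave == 1")
        counts = w1.groupby("group")["respondent_id"].nunique()
        assert counts["W"] == 139 and counts["A"] == 102
        assert set(panel.data["wave"]) == {1, 2}

    def test_planted_lexicographic_fraction_is_exact(self, panel):
        t1 = panel.truth.query("wave == 1")
        assert t1["lexicographic"].mean() == pytest.approx(70 / 241, abs=1e-12)

    def test_holdouts_shared_and_placed(self, panel):
        h = panel.data.query("task_type == 'holdout' and wave == 1")
        assert set(h["task_id"]) == {"H1", "H2"}
        assert set(h["position"]) == {5, 10}
        # every respondent sees the same holdout profiles
        per_resp = h.groupby("respondent_id").apply(
            lambda g: tuple(
                map(tuple, g.sort_values(["task_id", "alternative_id"])[
                    panel.schema.names
                ].to_numpy())
            ),
            include_groups=False,
        )
        assert per_resp.nunique() == 1

    def test_true_importances_follow_group_stories(self, panel):
        """Mean true importances rank pain relief first in group W and put
        side-effect type + pain relief top-two in group A."""
        schema = panel.schema
        names = schema.param_names()
        t1 = panel.truth.query("wave == 1")
        for grp, expected_top in (("W", {"pain_relief"}),):
            sub = t1[t1["group"] == grp]
            imp = relative_importance(sub[names].to_numpy(), schema).mean(axis=0)
            assert schema.names[int(np.argmax(imp))] in expected_top
        sub = t1[t1["group"] == "A"]
        imp = relative_importance(sub[names].to_numpy(), schema).mean(axis=0)
        top2 = {schema.names[i] for i in np.argsort(-imp)[:2]}
        assert top2 == {"side_effect_type", "pain_relief"}

    def test_ground_truth_importances_consistent_both_ways(self, panel):
        """Importances computed from the truth frame equal importances from
        the respondent objects (same formula applied to the same betas)."""
        schema = panel.schema
        names = schema.param_names()
        row = panel.truth.query("wave == 1").iloc[17]
        resp = next(
            r for r in panel.respondents
            if r.respondent_id == row["respondent_id"]
        )
        a = relative_importance(row[names].to_numpy(dtype=float), schema)
        b = relative_importance(resp.true_partworths[0], schema)
        assert np.allclose(a, b)

    def test_csv_round_trip_lossless(self, panel, tmp_path):
        path = tmp_path / "panel.csv"
        write_choice_data(panel.data, path)
        back = read_choice_data(path, panel.schema)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True),
            panel.data.astype(back.dtypes).reset_index(drop=True),
        )

    def test_seed_determinism_end_to_end(self):
        a = make_paper_like_dataset(seed=5, n_respondents=30)
        b = make_paper_like_dataset(seed=5, n_respondents=30)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)
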