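"""Effect aggregation, uncertainty, exposure weighting, rescaling and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erascreen import (
    ExposureRecord,
    ScenarioTriple,
    SurveyResponse,
    combine_indicators,
    compute_risk,
    generate_responses,
    rank_within_habitat,
    rescale_unit_interval,
    summarize_effects,
    top_k_with_ties,
    total_threat_risk,
    uncertainty_score,
    weight_by_exposure,
)


def _responses(scores, threat="t1", habitat="h1", indicator="physical_structure"):
    """One response per score, all giving (s, s, s) for a single combination."""
    out = []
    for i, s in enumerate(scores):
        r = SurveyResponse(respondent_id=f"r{i}", habitat_id=habitat)
        r.effect_scores[(threat, indicator)] = ScenarioTriple(s, s, s)
        out.append(r)
    return out


class TestSummarizeEffects:
    def test_constant_scores(self):
        out = summarize_effects(_responses([3, 3, 3]))
        ml = out[out.scenario == "most_likely"].iloc[0]
        assert (ml["mean"], ml["se"], ml["n"]) == (3.0, 0.0, 3)

    def test_two_scores_hand_se(self):
        # {2, 4}: SD = sqrt(2), SE = sqrt(2)/sqrt(2) = 1
        out = summarize_effects(_responses([2, 4]))
        ml = out[out.scenario == "most_likely"].iloc[0]
        assert ml["mean"] == 3.0
        assert ml["se"] == pytest.approx(1.0)

    def test_single_score_has_no_se(self):
        out = summarize_effects(_responses([4]))
        ml = out[out.scenario == "most_likely"].iloc[0]
        assert ml["mean"] == 4.0 and ml["n"] == 1
        assert math.isnan(ml["se"])

    def test_abstention_reduces_n(self):
        resp = _responses([2, 4])
        extra = SurveyResponse(respondent_id="r9", habitat_id="h1")
        extra.effect_scores[("t2", "physical_structure")] = ScenarioTriple(1, 1, 1)
        out = summarize_effects(resp + [extra])
        assert out[out.threat_id == "t1"]["n"].unique().tolist() == [2]
        assert out[out.threat_id == "t2"]["n"].unique().tolist() == [1]


class TestCombineIndicators:
    @pytest.mark.parametrize("a, b, mode, want",
                             [(3, 3, "mean", 3), (2, 4, "mean", 3), (2, 4, "max", 4)])
    def test_rules(self, a, b, mode, want):
        assert combine_indicators(a, b, mode) == want

    def test_one_missing_uses_other(self, caplog):
        assert combine_indicators(None, 4.0) == 4.0
        assert combine_indicators(float("nan"), 4.0) == 4.0

    def test_both_missing_is_error(self):
        with pytest.raises(ValueError, match="both indicators missing"):
            combine_indicators(None, None)


class TestUncertainty:
    def test_divergent_scenarios(self):
        assert uncertainty_score(4, 1) == 3

    def test_agreeing_scenarios(self):
        assert uncertainty_score(2, 2) == 0

    def test_negative_is_hard_error(self):
        with pytest.raises(ValueError, match="negative"):
            uncertainty_score(1, 2)

    @given(st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 5)).map(sorted), min_size=1
    ))
    @settings(max_examples=100, deadline=None)
    def test_mean_of_differences_equals_difference_of_means(self, pairs):
        best = [b for b, _ in pairs]
        worst = [w for _, w in pairs]
        per_response = np.mean([w - b for b, w in pairs])
        assert uncertainty_score(np.mean(worst), np.mean(best)) == pytest.approx(per_response)


class TestWeighting:
    @pytest.mark.parametrize("effect, score, want",
                             [(3, 5, 3.0), (3, 2, 1.2), (0, 4, 0.0)])
    def test_score_mode(self, effect, score, want):
        assert weight_by_exposure(effect, score) == pytest.approx(want)

    def test_percent_mode(self):
        assert weight_by_exposure(3, 2, mode="percent", overlap_percent=50.0) == 1.5

    def test_score_zero_is_contract_breach(self):
        with pytest.raises(ValueError, match="filter"):
            weight_by_exposure(3, 0)

    @given(st.floats(0, 5), st.integers(1, 4))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_spatial_score(self, effect, score):
        assert weight_by_exposure(effect, score) <= weight_by_exposure(effect, score + 1)

    @given(st.floats(0, 4.5), st.integers(1, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_effect(self, effect, score):
        assert weight_by_exposure(effect, score) <= weight_by_exposure(effect + 0.5, score)


class TestRescale:
    def test_hand_example(self):
        got = rescale_unit_interval([0.2, 0.6, 1.0])
        assert got == pytest.approx([0.0, 0.5, 1.0])

    def test_extremes_are_fixed_points(self):
        assert rescale_unit_interval([0.0, 1.0]) == pytest.approx([0.0, 1.0])

    def test_degenerate_all_equal_maps_to_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="erascreen.risk"):
            got = rescale_unit_interval([2.5, 2.5, 2.5])
        assert got == pytest.approx([0.0, 0.0, 0.0])
        assert any("degenerate" in r.message for r in caplog.records)

    @given(st.lists(st.floats(-100, 100), min_size=2, unique=True))
    @settings(max_examples=100, deadline=None)
    def test_maps_min_to_0_max_to_1_preserving_order(self, xs):
        got = rescale_unit_interval(xs)
        assert got.min() == 0.0 and got.max() == 1.0
        # monotone: sorting inputs sorts outputs (ties may appear at float resolution)
        order = np.argsort(xs, kind="stable")
        assert np.all(np.diff(got[order]) >= 0)


def test_total_threat_risk_sums_habitats():
    assert total_threat_risk({"h1": 0.2, "h2": 0.3}) == pytest.approx(0.5)
    assert total_threat_risk({"h1": 0.7}) == 0.7
    assert total_threat_risk({f"h{i}": 1.0 for i in range(8)}) == 8.0


class TestRanking:
    def test_tie_at_cutoff_is_included(self):
        df = pd.DataFrame({
            "threat_id": list("ABCD"),
            "risk_rescaled": [0.9, 0.5, 0.5, 0.1],
        })
        got = rank_within_habitat(df, k=2)
        assert got["threat_id"].tolist() == ["A", "B", "C"]
        assert got["rank"].tolist() == [1, 2, 2]

    def test_distinct_scores_give_exactly_k(self):
        df = pd.DataFrame({
            "threat_id": [f"t{i}" for i in range(10)],
            "risk_rescaled": np.linspace(1, 0, 10),
        })
        assert len(rank_within_habitat(df, k=5)) == 5

    def test_total_tie_returns_everything(self):
        df = pd.DataFrame({"threat_id": list("ABC"), "risk_rescaled": [0.4] * 3})
        got = rank_within_habitat(df, k=1)
        assert len(got) == 3 and got["rank"].tolist() == [1, 1, 1]

    def test_competition_rank_skips_after_tie(self):
        items = [("A", 3), ("B", 3), ("C", 2)]
        ranked = top_k_with_ties(items, key=lambda x: x[1], k=3, label=lambda x: x[0])
        assert [(r, x[0]) for r, x in ranked] == [(1, "A"), (1, "B"), (3, "C")]


def _exposure_for(truth, score=4, quality=1):
    return [
        ExposureRecord(threat_id=t, habitat_id=h, spatial_score=score, quality=quality)
        for t, h in truth.combos()
    ]


class TestComposedPipeline:
    def test_scenario_ordering_propagates_to_rescaled_risk(self, small_config, small_truth):
        responses = generate_responses(small_truth, n_experts=6)
        res = compute_risk(responses, _exposure_for(small_truth), small_config)
        wide = res.risk.pivot_table(
            index=["threat_id", "habitat_id"], columns="scenario",
            values="risk_rescaled", aggfunc="first",
        )
        assert (wide["best"] <= wide["most_likely"] + 1e-12).all()
        assert (wide["most_likely"] <= wide["worst"] + 1e-12).all()

    def test_zero_spread_zero_range_gives_zero_uncertainty(self, small_config, small_truth):
        truth = small_truth
        truth.spread = 0.0
        truth.range_width = 0.0
        truth.true_effect = {k: float(round(v)) for k, v in truth.true_effect.items()}
        responses = generate_responses(truth, n_experts=5)
        res = compute_risk(responses, _exposure_for(truth), small_config)
        assert (res.uncertainty["uncertainty"] == 0).all()

    def test_matches_brute_force_recomputation(self, small_config, small_truth):
        """Full-pipeline oracle: one-function recomputation from raw responses."""
        responses = generate_responses(small_truth, n_experts=6)
        rng = np.random.default_rng(5)
        exposure = [
            ExposureRecord(threat_id=t, habitat_id=h,
                           spatial_score=int(rng.integers(1, 6)), quality=1)
            for t, h in small_truth.combos()
        ]
        res = compute_risk(responses, exposure, small_config)

        # --- brute force, no shared code path beyond the dataclasses ---
        score_of = {(e.threat_id, e.habitat_id): e.spatial_score for e in exposure}
        raw = {}
        for t, h in small_truth.combos():
            for scen in ("best", "most_likely", "worst"):
                per_ind = []
                for ind in ("physical_structure", "species_composition"):
                    vals = [r.effect_scores[(t, ind)][scen] for r in responses
                            if r.habitat_id == h and (t, ind) in r.effect_scores]
                    per_ind.append(sum(vals) / len(vals))
                eff = sum(per_ind) / 2
                raw[(t, h, scen)] = eff * score_of[(t, h)] / 5
        lo, hi = min(raw.values()), max(raw.values())
        expected = {k: (v - lo) / (hi - lo) for k, v in raw.items()}

        for row in res.risk.itertuples():
            want = expected[(row.threat_id, row.habitat_id, row.scenario)]
            assert row.risk_rescaled == pytest.approx(want)

    def test_quality4_record_absent_from_risk_but_present_in_effects(
        self, small_config, small_truth
    ):
        responses = generate_responses(small_truth, n_experts=4)
        exposure = _exposure_for(small_truth)
        exposure[0] = ExposureRecord(
            threat_id=exposure[0].threat_id, habitat_id=exposure[0].habitat_id,
            spatial_score=exposure[0].spatial_score, quality=4,
        )
        res = compute_risk(responses, exposure, small_config)
        key = (exposure[0].threat_id, exposure[0].habitat_id)
        risk_pairs = set(map(tuple, res.risk[["threat_id", "habitat_id"]].itertuples(index=False)))
        effect_pairs = set(map(tuple, res.combined[["threat_id", "habitat_id"]].itertuples(index=False)))
        assert key not in risk_pairs and key in effect_pairs
        assert ((res.exclusions.threat_id == key[0])
                & (res.exclusions.habitat_id == key[1])).any()
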