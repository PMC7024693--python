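"""RCI arithmetic, multi-domain classification, rates and decomposition."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdqchange import (
    RCIConfig,
    ThresholdConfig,
    above_threshold_decomposition,
    classify_cohort,
    classify_overall,
    compute_rci,
    rate_table,
    split_by_threshold,
    subscale_change_status,
)
from sdqchange.cohort import OUTCOME_SUBSCALES, SubscaleScores
from sdqchange.reliable import RCIConfigError

from conftest import make_record


def scores(e=0, c=0, h=0, p=0, i=0):
    return SubscaleScores(emotional=e, conduct=c, hyperactivity=h, peer=p, impact=i)


def oracle_overall(deltas, rcc=3):
    """Independent brute-force three-rule reference classifier."""
    if any(d >= rcc for d in deltas):
        return "deterioration"
    if any(d <= -rcc for d in deltas):
        return "improvement"
    return "no_change"


class TestRCI:
    @pytest.mark.parametrize(
        "x1,x2,sdiff,expected",
        [
            (6, 2, 1.61, (2 - 6) / 1.61),
            (5, 5, 1.66, 0.0),
            (2, 6, 1.66, (6 - 2) / 1.66),
        ],
    )
    def test_rci_arithmetic(self, x1, x2, sdiff, expected):
        assert compute_rci(x1, x2, sdiff) == pytest.approx(expected)

    def test_nonpositive_sdiff_rejected(self):
        with pytest.raises(RCIConfigError):
            compute_rci(1, 2, 0.0)
        with pytest.raises(RCIConfigError):
            RCIConfig(sdiff={"emotional": -1.0, "conduct": 1.66, "hyperactivity": 1.71})

    def test_strict_mode_uses_196_criterion(self):
        """A 4-point conduct rise has RCI 2.41 > 1.96: reliable
        deterioration under the strict criterion."""
        cfg = RCIConfig(mode="strict_rci")
        assert subscale_change_status(2, 6, cfg, "conduct") == "deteriorated"
        assert subscale_change_status(5, 5, cfg, "conduct") == "unchanged"


class TestSubscaleStatus:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(6, 3, "improved"), (6, 4, "unchanged"), (3, 6, "deteriorated"), (0, 2, "unchanged")],
    )
    def test_integer_criterion_three_points(self, x1, x2, expected):
        assert subscale_change_status(x1, x2, RCIConfig(), "emotional") == expected

    def test_mode_divergence_at_exactly_three_points(self):
        """A 3-point conduct rise: RCI 3/1.66 = 1.81 < 1.96, so the strict
        mode calls it unchanged while the integer criterion calls it
        reliable deterioration."""
        assert subscale_change_status(3, 6, RCIConfig(), "conduct") == "deteriorated"
        assert (
            subscale_change_status(3, 6, RCIConfig(mode="strict_rci"), "conduct")
            == "unchanged"
        )

    def test_unknown_subscale_rejected(self):
        with pytest.raises(RCIConfigError, match="peer"):
            subscale_change_status(1, 2, RCIConfig(), "peer")

    def test_mode_disagreement_set_is_exactly_plus_minus_three(self):
        """Both modes agree except at raw changes of exactly +/-3 on
        subscales where 1.96*Sdiff > 3 — which holds for all three."""
        intc, strc = RCIConfig(), RCIConfig(mode="strict_rci")
        for sub in OUTCOME_SUBSCALES:
            assert 1.96 * intc.sdiff[sub] > 3
            disagree = []
            for d in range(-10, 11):
                x1 = max(0, -d)
                if (
                    subscale_change_status(x1, x1 + d, intc, sub)
                    != subscale_change_status(x1, x1 + d, strc, sub)
                ):
                    disagree.append(d)
            assert disagree == [-3, 3]


class TestOverallClassification:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ((-3, 0, 0), "improvement"),
            ((-3, 3, 0), "deterioration"),  # deterioration is absorbing
            ((-2, -2, -2), "no_change"),
            ((0, 0, 0), "no_change"),
            ((-4, -3, 0), "improvement"),
        ],
    )
    def test_documented_cases(self, deltas, expected):
        t1 = scores(e=5, c=5, h=5)
        t2 = scores(e=5 + deltas[0], c=5 + deltas[1], h=5 + deltas[2])
        assert classify_overall(t1, t2).overall == expected

    def test_peer_and_impact_never_enter_classification(self):
        t1 = scores(p=8, i=10)
        t2 = scores(p=0, i=0)
        result = classify_overall(t1, t2)
        assert result.overall == "no_change"
        assert set(result.deltas) == set(OUTCOME_SUBSCALES)

    def test_exhaustive_agreement_with_bruteforce_oracle(self):
        """All 9,261 integer delta triples in [-10, 10]^3 agree with the
        independent three-rule reference."""
        cfg = RCIConfig()
        for deltas in itertools.product(range(-10, 11), repeat=3):
            t1 = scores(*[max(0, -d) for d in deltas])
            t2 = scores(*[max(0, -d) + d for d in deltas])
            assert classify_overall(t1, t2, cfg).overall == oracle_overall(deltas)

    @given(
        st.tuples(*[st.integers(0, 10)] * 3),
        st.tuples(*[st.integers(0, 10)] * 3),
    )
    @settings(max_examples=300, derandomize=True)
    def test_result_invariants(self, a, b):
        t1, t2 = scores(*a), scores(*b)
        res = classify_overall(t1, t2)
        statuses = res.subscale_status.values()
        for sub in OUTCOME_SUBSCALES:
            if res.deltas[sub] != 0:
                assert np.sign(res.rci[sub]) == np.sign(res.deltas[sub])
        if any(s == "deteriorated" for s in statuses):
            assert res.overall == "deterioration"
        elif any(s == "improved" for s in statuses):
            assert res.overall == "improvement"
        else:
            assert res.overall == "no_change"

    def test_antisymmetry_without_mixed_movement(self):
        """Negating all deltas swaps improvement and deterioration when no
        case moves reliably in both directions; with mixed movement
        deterioration absorbs both orientations."""
        pure = classify_overall(scores(e=6), scores(e=3))
        flipped = classify_overall(scores(e=3), scores(e=6))
        assert (pure.overall, flipped.overall) == ("improvement", "deterioration")
        mixed = classify_overall(scores(e=6, c=3), scores(e=3, c=6))
        mixed_neg = classify_overall(scores(e=3, c=6), scores(e=6, c=3))
        assert mixed.overall == mixed_neg.overall == "deterioration"


class TestThresholdSplit:
    def test_boundary_score_counts_as_above(self):
        above = make_record(id="A", t1=(6, 0, 0, 0, 0))
        assert split_by_threshold([above])["above"] == [above]

    def test_all_strictly_under_cuts_is_below(self):
        below = make_record(id="B", t1=(5, 4, 6, 0, 0))
        assert split_by_threshold([below])["below"] == [below]

    def test_partition_is_exhaustive_and_disjoint(self, cohort300):
        halves = split_by_threshold(cohort300)
        assert len(halves["above"]) + len(halves["below"]) == len(cohort300)
        assert not set(r.id for r in halves["above"]) & set(
            r.id for r in halves["below"]
        )

    def test_custom_thresholds_respected(self):
        rec = make_record(id="C", t1=(5, 0, 0, 0, 0))
        assert split_by_threshold([rec], ThresholdConfig(emotional_cut=5))["above"]
        assert split_by_threshold([rec], ThresholdConfig(emotional_cut=6))["below"]


class TestRateTable:
    PRINTED = {
        "full": {"improvement": 910, "deterioration": 1011, "no_change": 7153},
        "above_threshold": {"improvement": 620, "deterioration": 198, "no_change": 1452},
        "below_threshold": {"improvement": 290, "deterioration": 813, "no_change": 5701},
    }
    EXPECTED_PCT = {
        "full": (10.03, 11.14, 78.83),
        "above_threshold": (27.31, 8.72, 63.96),
        "below_threshold": (4.26, 11.95, 83.79),
    }

    def test_published_counts_reproduce_published_percentages(self):
        table = rate_table(
            self.PRINTED["full"],
            self.PRINTED["above_threshold"],
            self.PRINTED["below_threshold"],
        )
        for label, (imp, det, no) in self.EXPECTED_PCT.items():
            s = table.samples[label]
            assert s.percentages["improvement"] == imp
            assert s.percentages["deterioration"] == det
            assert s.percentages["no_change"] == no
            assert sum(s.counts.values()) == s.n

    def test_wilson_interval_hand_computed(self):
        """Wilson score CI for 50/100 is [0.4038, 0.5962]."""
        counts = {"improvement": 50, "deterioration": 0, "no_change": 50}
        table = rate_table(counts, counts, counts)
        lo, hi = table.samples["full"].ci["improvement"]
        assert lo == pytest.approx(40.38, abs=0.005)
        assert hi == pytest.approx(59.62, abs=0.005)

    def test_ci_contains_point_estimate_and_percentages_sum(self, classified300):
        _, results = classified300
        table = rate_table(results, results, results)
        s = table.samples["full"]
        for cat in s.counts:
            lo, hi = s.ci[cat]
            assert lo <= s.percentages[cat] <= hi
        assert sum(s.percentages.values()) == pytest.approx(100, abs=0.02)

    def test_single_category_and_empty_sample(self):
        only = {"improvement": 7, "deterioration": 0, "no_change": 0}
        empty = {"improvement": 0, "deterioration": 0, "no_change": 0}
        table = rate_table(only, empty, only)
        assert table.samples["full"].percentages["improvement"] == 100.0
        assert table.samples["full"].percentages["deterioration"] == 0.0
        assert table.samples["above_threshold"].percentages["improvement"] is None

    def test_text_and_frame_renderings(self, classified300):
        _, results = classified300
        table = rate_table(results, results, results)
        assert "full (n = 300)" in table.to_text()
        assert len(table.to_frame()) == 9


class TestDecomposition:
    def test_definition_on_single_cases(self):
        elevated_emo = make_record(id="A", t1=(6, 0, 0, 0, 0), t2=(3, 0, 0, 0, 0))
        res = classify_cohort([elevated_emo])
        d = above_threshold_decomposition([elevated_emo], res)
        assert d.improved_on_elevated == 1 and d.improved_on_other == 0

        other_scale = make_record(id="B", t1=(0, 5, 6, 0, 0), t2=(0, 5, 3, 0, 0))
        # elevated on conduct only; improvement happened on hyperactivity
        res = classify_cohort([other_scale])
        d = above_threshold_decomposition(
            [other_scale], res, ThresholdConfig(hyperactivity_cut=7)
        )
        assert d.improved_on_other == 1 and d.improved_on_elevated == 0

    def test_below_threshold_input_rejected(self):
        rec = make_record(id="C", t1=(0, 0, 0, 0, 0))
        with pytest.raises(ValueError, match="not above threshold"):
            above_threshold_decomposition([rec], classify_cohort([rec]))

    def test_engineered_counts_reproduce_published_percentages(self):
        """341/279 improved on the elevated/other subscale and 73/125
        deteriorated likewise: 55%/45% of the improved and 37%/63% of the
        deteriorated (15%/12%/3%/6% of all above threshold)."""
        records, n = [], 0

        def add(count, t1, t2):
            nonlocal n
            for _ in range(count):
                records.append(make_record(id=f"D{n}", t1=t1, t2=t2))
                n += 1

        add(341, (6, 0, 0, 0, 0), (3, 0, 0, 0, 0))   # improved on elevated emo
        add(279, (6, 0, 4, 0, 0), (6, 0, 1, 0, 0))   # improved on non-elevated hyp
        add(73, (6, 0, 0, 0, 0), (9, 0, 0, 0, 0))    # deteriorated on elevated emo
        add(125, (6, 0, 0, 0, 0), (6, 3, 0, 0, 0))   # deteriorated on other (conduct)
        add(1452, (6, 0, 0, 0, 0), (6, 0, 0, 0, 0))  # no reliable change
        d = above_threshold_decomposition(records, classify_cohort(records))
        assert (
            d.improved_on_elevated,
            d.improved_on_other,
            d.deteriorated_on_elevated,
            d.deteriorated_on_other,
        ) == (341, 279, 73, 125)
        pct = d.percentages()
        assert pct["improved_on_elevated_pct_of_improved"] == 55
        assert pct["improved_on_other_pct_of_improved"] == 45
        assert pct["deteriorated_on_elevated_pct_of_deteriorated"] == 37
        assert pct["deteriorated_on_other_pct_of_deteriorated"] == 63
        assert pct["improved_on_elevated_pct_of_above"] == 15
        assert pct["improved_on_other_pct_of_above"] == 12
        assert pct["deteriorated_on_elevated_pct_of_above"] == 3
        assert pct["deteriorated_on_other_pct_of_above"] == 6
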