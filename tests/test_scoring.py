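"""Ratio scoring, grading bands, site scorecards, habitat comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibi import (
    ValidationError,
    compare_habitats,
    grade,
    metric_values,
    pool_references,
    run_screening,
    score_metric,
    score_sites,
    simulate_scenario,
)
from fibi.scoring import GRADES


class TestScoreMetric:
    def test_reference_parity_gives_one(self):
        assert score_metric(23.0, 23.0, "decrease").score == 1.0
        assert score_metric(40.0, 40.0, "increase", maximum=60.0).score == 1.0

    def test_hand_cases(self):
        assert score_metric(11.5, 23.0, "decrease").score == pytest.approx(0.5)
        assert score_metric(60.0, 40.0, "increase", maximum=60.0).score == 0.0
        assert score_metric(50.0, 40.0, "increase", maximum=60.0).score == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValidationError):
            score_metric(1.0, 0.0, "decrease")
        with pytest.raises(ValidationError):
            score_metric(60.0, 50.0, "increase", maximum=50.0)
        # at/below reference with a degenerate maximum still scores 1
        assert score_metric(40.0, 50.0, "increase", maximum=50.0).score == 1.0
        with pytest.raises(ValidationError):
            score_metric(1.0, 2.0, "sideways")

    @given(
        c=st.floats(0, 100), r=st.floats(0.1, 100), mx=st.floats(0.2, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_always_clipped_to_unit_interval(self, c, r, mx):
        s1 = score_metric(c, r, "decrease").score
        assert 0.0 <= s1 <= 1.0
        if mx > r:
            s2 = score_metric(c, r, "increase", maximum=mx).score
            assert 0.0 <= s2 <= 1.0

    def test_monotone_in_current_value(self):
        dec = [score_metric(c, 50.0, "decrease").score for c in np.linspace(0, 50, 20)]
        assert all(a <= b for a, b in zip(dec, dec[1:]))
        inc = [
            score_metric(c, 40.0, "increase", maximum=80.0).score
            for c in np.linspace(40, 80, 20)
        ]
        assert all(a >= b for a, b in zip(inc, inc[1:]))


class TestGrade:
    def test_band_arithmetic_expected_eight(self):
        # P95 = 7.6; bands of width 1.9
        assert grade(7.8, 8) == "Excellent"
        assert grade(7.6, 8) == "Good"
        assert grade(4.5, 8) == "Fair"   # [3.8, 5.7)
        assert grade(2.0, 8) == "Poor"
        assert grade(0.0, 8) == "Very Poor"

    def test_negative_total_error(self):
        with pytest.raises(ValidationError):
            grade(-0.1, 8)

    @given(total=st.floats(0, 12), expected=st.floats(0.5, 12))
    @settings(max_examples=200, deadline=None)
    def test_bands_exhaustive_and_ordered(self, total, expected):
        g = grade(total, expected)
        assert g in GRADES
        p95 = 0.95 * expected
        if total > p95:
            assert g == "Excellent"
        else:
            band = min(int(total // (p95 / 4)), 3)
            assert g == GRADES[band]


class TestScoreSites:
    @staticmethod
    def _scenario_scorecard(seed=3):
        scn = simulate_scenario(seed=seed)
        cfg = scn.config
        ref = pool_references(
            scn.historical, scn.group_assignment, scn.traits, cfg.candidate_metrics
        )
        report = run_screening(
            scn.current, scn.traits, ref, candidates=cfg.candidate_metrics
        )
        cm = metric_values(scn.current, scn.traits, report.retained)
        return scn, ref, report, cm, score_sites(cm, ref, report)

    def test_scores_and_totals_bounded(self):
        _, _, report, _, card = self._scenario_scorecard()
        assert ((card.scores >= 0) & (card.scores <= 1)).all().all()
        assert ((card.totals >= 0) & (card.totals <= card.expected_total)).all()
        assert card.expected_total == len(report.retained)

    def test_scoring_own_reference_is_perfect(self):
        """A site whose current values equal its references scores the maximum."""
        scn, ref, report, cm, _ = self._scenario_scorecard()
        parity = ref.site_reference(report.retained)
        card = score_sites(parity, ref, report)
        assert np.allclose(card.totals, card.expected_total)
        assert (card.grades == "Excellent").all()

    def test_unassigned_site_error(self):
        scn, ref, report, cm, _ = self._scenario_scorecard()
        cm_extra = cm.copy()
        cm_extra.loc["ghost"] = 10.0
        with pytest.raises(ValidationError, match="ghost"):
            score_sites(cm_extra, ref, report)


class TestCompareHabitats:
    def test_identity_groups(self):
        scn, ref, report, cm, card = TestScoreSites._scenario_scorecard()
        meta = scn.metadata.copy()
        # force identical totals in both habitat classes
        card.totals[:] = [1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3]
        meta["habitat_type"] = [1, 1, 1, 2, 2, 2, 1, 1, 1, 2, 2, 2]
        stats = compare_habitats(card, meta)
        assert stats.loc["total", "t"] == pytest.approx(0.0)
        assert stats.loc["total", "p"] == pytest.approx(1.0)

    def test_closed_form_t_oracle(self):
        """Equal-variance t on {1,2,3,4} vs {3,4,5,6}: t=-2.191, p~0.0707."""
        scn, ref, report, cm, card = TestScoreSites._scenario_scorecard()
        meta = scn.metadata.copy()
        card.totals[:] = [1, 2, 3, 4, 3, 4, 5, 6, 1, 3, 2, 4]
        meta["habitat_type"] = [1, 1, 1, 1, 2, 2, 2, 2, 1, 2, 1, 2]
        # restrict to the first eight sites via a trimmed scorecard
        card.totals = card.totals.iloc[:8]
        card.scores = card.scores.iloc[:8]
        stats = compare_habitats(card, meta)
        assert stats.loc["total", "t"] == pytest.approx(-2.1909, abs=1e-3)
        assert stats.loc["total", "p"] == pytest.approx(0.0707, abs=1e-3)
        assert bool(stats.loc["total", "equal_var"]) is True

    def test_small_group_error(self):
        scn, ref, report, cm, card = TestScoreSites._scenario_scorecard()
        meta = scn.metadata.copy()
        meta["habitat_type"] = [1] * 11 + [2]
        with pytest.raises(ValidationError, match="at least 2"):
            compare_habitats(card, meta)
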