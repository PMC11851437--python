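"""Redundancy, discrimination-power, and sensitivity screening stages."""

import numpy as np
import pandas as pd
import pytest

from fibi import (
    TraitMatrix,
    ValidationError,
    discrimination_power,
    redundancy_screen,
    run_screening,
    sensitivity_screen,
)
from fibi import ScenarioConfig, metric_values, pool_references, simulate_scenario


def _traits_with_corr(rng, n=200):
    """Binary trait table with one strongly collinear pair (X ~ Y)."""
    vocab = {k: k for k in ["ANCHOR", "X", "Y", "Z"]}
    x = rng.integers(0, 2, n)
    y = np.where(rng.random(n) < 0.95, x, 1 - x)       # r(X,Y) ~ 0.9
    anchor = np.where(rng.random(n) < 0.75, x, rng.integers(0, 2, n))
    z = rng.integers(0, 2, n)
    df = pd.DataFrame({"ANCHOR": anchor, "X": x, "Y": y, "Z": z},
                      index=[f"sp{i}" for i in range(n)])
    return TraitMatrix(df, vocabulary=vocab)


class TestRedundancyScreen:
    def test_member_closer_to_anchor_kept(self, rng):
        traits = _traits_with_corr(rng)
        # X correlates with anchor more strongly than Y does -> X removed
        retained, detail = redundancy_screen(
            traits, ["X", "Y", "Z"], anchor="ANCHOR", threshold=0.6
        )
        assert set(retained) == {"Y", "Z"}
        assert detail.iloc[0]["metric"] == "X"

    def test_no_collinear_pair_keeps_all(self, rng):
        vocab = {k: k for k in ["ANCHOR", "P", "Q"]}
        df = pd.DataFrame(
            {"ANCHOR": rng.integers(0, 2, 100), "P": rng.integers(0, 2, 100),
             "Q": rng.integers(0, 2, 100)},
            index=[f"sp{i}" for i in range(100)],
        )
        traits = TraitMatrix(df, vocabulary=vocab)
        retained, detail = redundancy_screen(traits, ["P", "Q"], anchor="ANCHOR")
        assert retained == ["P", "Q"] and detail.empty

    def test_tie_falls_back_to_priority_list(self):
        # construct an exact tie: X and Y perfectly anti-correlated,
        # both with zero anchor correlation
        vocab = {k: k for k in ["ANCHOR", "X", "Y"]}
        x = np.array([1, 1, 0, 0] * 25)
        anchor = np.array([1, 0, 1, 0] * 25)
        df = pd.DataFrame({"ANCHOR": anchor, "X": x, "Y": 1 - x},
                          index=[f"sp{i}" for i in range(100)])
        traits = TraitMatrix(df, vocabulary=vocab)
        retained, _ = redundancy_screen(
            traits, ["X", "Y"], anchor="ANCHOR", priority=("Y",)
        )
        assert retained == ["X"]

    def test_missing_anchor_error(self, rng):
        traits = _traits_with_corr(rng)
        with pytest.raises(ValidationError, match="anchor"):
            redundancy_screen(traits, ["X", "Y"], anchor="NOPE")


class TestDiscriminationPower:
    @pytest.mark.parametrize(
        "ref, imp, expected",
        [
            ([30, 32, 34, 36, 38], [10, 12, 14, 16, 18], 3),  # disjoint IQRs
            ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 0),            # identical
            ([10, 20, 30, 40, 50], [25, 35, 45, 55, 65], 2),  # overlap, medians out
            ([10, 20, 30, 40, 50], [25, 28, 45, 55, 65], 1),  # one median inside
        ],
    )
    def test_boxplot_overlap_rule(self, ref, imp, expected):
        assert discrimination_power(ref, imp) == expected

    def test_symmetric_for_extreme_scores(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        assert discrimination_power(a, b) == discrimination_power(b, a) == 3
        assert discrimination_power(a, a) == 0

    def test_small_sample_error(self):
        with pytest.raises(ValidationError):
            discrimination_power([1, 2], [1, 2, 3])


class TestSensitivityScreen:
    def test_uniform_directions(self):
        ref = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        assert sensitivity_screen(ref, ref - 1) == "decrease"
        assert sensitivity_screen(ref, ref + 1) == "increase"

    def test_mixed_and_zero_deltas_removed(self):
        ref = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        mixed = pd.Series([11.0, 19.0, 31.0], index=list("abc"))
        assert sensitivity_screen(ref, mixed) is None
        with_zero = pd.Series([10.0, 21.0, 31.0], index=list("abc"))
        assert sensitivity_screen(ref, with_zero) is None

    def test_unpaired_sites_error(self):
        ref = pd.Series([1.0, 2.0], index=["a", "b"])
        cur = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValidationError, match="different sites"):
            sensitivity_screen(ref, cur)


class TestRunScreening:
    def test_planted_recovery_and_order_invariance(self):
        scn = simulate_scenario(seed=3)
        cfg = scn.config
        reference = pool_references(
            scn.historical, scn.group_assignment, scn.traits, cfg.candidate_metrics
        )
        report = run_screening(
            scn.current, scn.traits, reference, candidates=cfg.candidate_metrics
        )
        assert set(report.retained) == set(cfg.planted_directions)
        assert report.directions == cfg.planted_directions
        # fate is invariant to metric ordering
        rev = run_screening(
            scn.current, scn.traits, reference,
            candidates=list(reversed(cfg.candidate_metrics)),
        )
        assert set(rev.retained) == set(report.retained)
        # every candidate has exactly one definite fate
        assert sorted(report.table.index) == sorted(cfg.candidate_metrics)
        assert report.table["fate"].isin(
            ["retained", "redundancy", "discrimination", "sensitivity"]
        ).all()

    def test_empty_candidates_warns(self):
        scn = simulate_scenario(seed=3)
        reference = pool_references(
            scn.historical, scn.group_assignment, scn.traits, ["CUF"]
        )
        with pytest.warns(UserWarning, match="no candidate"):
            report = run_screening(scn.current, scn.traits, reference, candidates=[])
        assert report.retained == []
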