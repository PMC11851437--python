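"""F-IBI scoring against cluster-group references, grading, and habitat comparison.

Each sensitive metric is scored by a ratio to its reference value:

* direction = decrease (metric drops under disturbance):
  ``SE1 = C / R_group``;
* direction = increase (metric rises under disturbance):
  ``SE2 = (Max - C) / (Max - R_group)``.

Scores are clipped to [0, 1]; a site's total is the sum over sensitive
metrics, so the expected (undisturbed) total equals the number of
sensitive metrics.  Grades split [0, 0.95 x expected] into four equal
bands (Very Poor / Poor / Fair / Good), with totals above the 95th
percentile of the expected score rated Excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import ValidationError
from .clustering import ReferenceSet
from .screening import ScreeningReport

__all__ = [
    "MetricScore",
    "FIBIScorecard",
    "GRADES",
    "score_metric",
    "grade",
    "score_sites",
    "compare_habitats",
]

GRADES = ("Very Poor", "Poor", "Fair", "Good", "Excellent")


@dataclass
class MetricScore:
    metric: str
    current: float
    reference: float
    maximum: float | None
    direction: str
    score: float
    clipped: bool


def score_metric(
    current: float,
    reference: float,
    direction: str,
    maximum: float | None = None,
    metric: str = "",
) -> MetricScore:
    """Ratio score for one sensitive metric at one site.

    ``direction="decrease"`` uses ``C / R`` (requires R > 0);
    ``direction="increase"`` uses ``(Max - C) / (Max - R)`` (requires
    Max > R).  The raw ratio is clipped to [0, 1] and the clipping is
    recorded.
    """
    if direction == "decrease":
        if reference <= 0:
            raise ValidationError(
                f"metric {metric or '?'}: reference must be positive for a "
                "decreasing metric"
            )
        raw = current / reference
    elif direction == "increase":
        if maximum is None:
            raise ValidationError("increasing metrics need a scaling maximum")
        if current <= reference:
            # at or better than reference the ratio is >= 1 and clips to 1;
            # this also covers the degenerate maximum == reference parity
            if maximum > reference:
                raw = (maximum - current) / (maximum - reference)
            else:
                raw = 1.0
        elif maximum <= reference:
            raise ValidationError(
                f"metric {metric or '?'}: scaling maximum ({maximum}) must "
                f"exceed the reference ({reference})"
            )
        else:
            raw = (maximum - current) / (maximum - reference)
    else:
        raise ValidationError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    score = float(np.clip(raw, 0.0, 1.0))
    return MetricScore(
        metric=metric, current=float(current), reference=float(reference),
        maximum=None if maximum is None else float(maximum),
        direction=direction, score=score, clipped=score != raw,
    )


def grade(total: float, expected_total: float) -> str:
    """Five-band grade from a site total and the expected (perfect) total.

    P95 = 0.95 x expected_total.  Totals above P95 are Excellent; the
    interval [0, P95] is split into four equal lower-inclusive bands
    ordered Very Poor < Poor < Fair < Good (a total exactly at P95 is
    Good).
    """
    if expected_total <= 0:
        raise ValidationError("expected_total must be positive")
    if total < 0:
        raise ValidationError("total score cannot be negative")
    p95 = 0.95 * expected_total
    if total > p95:
        return "Excellent"
    band = int(total // (p95 / 4.0))
    return GRADES[min(band, 3)]


@dataclass
class FIBIScorecard:
    """Per-site metric scores, totals, and grades."""

    scores: pd.DataFrame          # sites x metrics, each in [0, 1]
    totals: pd.Series
    expected_total: float
    grades: pd.Series
    directions: Mapping[str, str]
    maxima: Mapping[str, float]
    references: pd.DataFrame      # sites x metrics reference values used

    def summary(self) -> pd.DataFrame:
        out = self.scores.copy()
        out["total"] = self.totals
        out["grade"] = self.grades
        return out


def score_sites(
    current_metrics: pd.DataFrame,
    reference: ReferenceSet,
    screening: ScreeningReport | Mapping[str, str],
    max_rule: str = "data",
) -> FIBIScorecard:
    """Score every site on every sensitive metric and grade the totals.

    Parameters
    ----------
    current_metrics
        Sites x metrics current percentage values.
    reference
        Cluster-group reference set; every site must carry a group
        assignment.
    screening
        A :class:`~fibi.screening.ScreeningReport` (its retained metrics
        and directions are used) or a plain ``{metric: direction}`` map.
    max_rule
        How the scaling maximum for increasing metrics is chosen:
        ``"data"`` (default) = max over all current site values and all
        group reference values of the metric, which guarantees SE2 in
        [0, 1] on the data at hand; ``"theoretical"`` = 100;
        ``"reference"`` = max over reference values only.
    """
    directions = (
        screening.directions if isinstance(screening, ScreeningReport) else dict(screening)
    )
    if not directions:
        raise ValidationError("no sensitive metrics to score")
    missing = [m for m in directions if m not in current_metrics.columns]
    if missing:
        raise ValidationError(f"current metric values missing for: {missing}")
    unassigned = [s for s in current_metrics.index if s not in reference.assignment.index]
    if unassigned:
        raise ValidationError(f"sites without group assignment: {unassigned}")

    metrics = list(directions)
    site_ref = reference.site_reference(metrics).loc[current_metrics.index]

    maxima: dict[str, float] = {}
    for m in metrics:
        if max_rule == "data":
            maxima[m] = float(max(current_metrics[m].max(), reference.values[m].max()))
        elif max_rule == "theoretical":
            maxima[m] = 100.0
        elif max_rule == "reference":
            maxima[m] = float(reference.values[m].max())
        else:
            raise ValidationError(f"unknown max_rule {max_rule!r}")

    scores = pd.DataFrame(index=current_metrics.index, columns=metrics, dtype=float)
    for site in current_metrics.index:
        for m in metrics:
            ms = score_metric(
                current=float(current_metrics.loc[site, m]),
                reference=float(site_ref.loc[site, m]),
                direction=directions[m],
                maximum=maxima[m] if directions[m] == "increase" else None,
                metric=m,
            )
            scores.loc[site, m] = ms.score

    totals = scores.sum(axis=1)
    expected = float(len(metrics))
    grades = pd.Series({s: grade(t, expected) for s, t in totals.items()}, name="grade")
    return FIBIScorecard(
        scores=scores, totals=totals.rename("total"), expected_total=expected,
        grades=grades, directions=directions, maxima=maxima, references=site_ref,
    )


def _ks_normality_p(sample: np.ndarray) -> float:
    sd = sample.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue)


def compare_habitats(
    scorecard: FIBIScorecard,
    metadata: pd.DataFrame,
    current_metrics: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sample comparison of F-IBI totals (and metric values) by habitat.

    Splits sites into the two habitat classes (NRAD = free-flowing reach,
    TR = reservoir transition zone) using ``metadata["habitat_type"]``.
    For the totals and each sensitive metric's current values, reports a
    Kolmogorov-Smirnov normality p per group (normal with estimated
    moments), a variance-ratio check, and a two-sample t test —
    equal-variance by default, switching to Welch when the variance-ratio
    F test rejects homogeneity at ``alpha``.
    """
    if "habitat_type" not in metadata.columns:
        raise ValidationError("metadata must contain a habitat_type column")
    ht = metadata.loc[scorecard.totals.index, "habitat_type"]
    g1 = scorecard.totals.index[ht == 1]
    g2 = scorecard.totals.index[ht == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each habitat group needs at least 2 sites")

    responses: dict[str, pd.Series] = {"total": scorecard.totals}
    if current_metrics is not None:
        for m in scorecard.scores.columns:
            responses[m] = current_metrics[m]

    rows = []
    for name, series in responses.items():
        a = series.loc[g1].to_numpy(dtype=float)
        b = series.loc[g2].to_numpy(dtype=float)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va > 0 and vb > 0:
            f_stat = max(va, vb) / min(va, vb)
            dfn = len(a) - 1 if va >= vb else len(b) - 1
            dfd = len(b) - 1 if va >= vb else len(a) - 1
            var_p = 2.0 * min(
                stats.f.sf(f_stat, dfn, dfd), stats.f.cdf(f_stat, dfn, dfd)
            )
        else:
            var_p = 1.0 if va == vb else 0.0
        equal_var = var_p >= alpha
        t_res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "response": name,
            "mean_nrad": a.mean(), "mean_tr": b.mean(),
            "min_nrad": a.min(), "max_nrad": a.max(),
            "min_tr": b.min(), "max_tr": b.max(),
            "t": float(t_res.statistic), "p": float(t_res.pvalue),
            "equal_var": equal_var, "var_p": float(var_p),
            "ks_p_nrad": _ks_normality_p(a), "ks_p_tr": _ks_normality_p(b),
        })
    return pd.DataFrame(rows).set_index("response")
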