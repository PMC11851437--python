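"""Three-stage reduction of candidate trait metrics to the sensitive set.

Stage 1 (redundancy): collinear trait pairs (|Spearman r| at or above a
threshold, computed on species-level binary trait vectors) are thinned by
keeping the member less correlated with an anchor trait (endemism by
default).  Stage 2 (discrimination power): metrics must separate
reference from impaired value distributions with a box-plot overlap
score of IQ = 3.  Stage 3 (sensitivity): metrics must shift in the same
strict direction at every site between reference and current values;
mixed trends mean the metric does not track the shared stress gradient.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import OccurrenceMatrix, TraitMatrix, ValidationError, metric_values
from .clustering import ReferenceSet

__all__ = [
    "ScreeningReport",
    "redundancy_screen",
    "discrimination_power",
    "sensitivity_screen",
    "run_screening",
    "DEFAULT_TIE_PRIORITY",
]

#: Metrics dropped first when both members of a collinear pair are equally
#: correlated with the anchor.  Shipped default mirrors the conventional
#: choice of keeping flow-dependent reproductive guilds (drifting eggs)
#: over their complements.
DEFAULT_TIE_PRIORITY: tuple[str, ...] = ("CF", "STF")


@dataclass
class ScreeningReport:
    """Per-metric fate through the three screening stages.

    ``table`` has one row per input metric with columns

    * ``fate`` — ``retained`` or the stage at which the metric was
      removed (``redundancy`` / ``discrimination`` / ``sensitivity``);
    * ``iq`` — box-plot discrimination score (NaN if removed earlier);
    * ``direction`` — ``increase`` / ``decrease`` for retained metrics;
    * ``anchor_r`` — Spearman correlation with the anchor trait;
    * ``partner`` / ``partner_r`` — the collinear partner that caused a
      redundancy removal, if any.
    """

    table: pd.DataFrame
    anchor: str
    quartile_convention: str = "linear (type 7)"

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["fate"] == "retained"])

    @property
    def directions(self) -> dict[str, str]:
        kept = self.table[self.table["fate"] == "retained"]
        return dict(zip(kept.index, kept["direction"]))


def _spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    corr, _ = stats.spearmanr(data.to_numpy())
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def redundancy_screen(
    traits: TraitMatrix,
    candidates: Sequence[str],
    anchor: str = "EF",
    threshold: float = 0.60,
    priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
) -> tuple[list[str], pd.DataFrame]:
    """Thin collinear candidate pairs, keeping the member closer to the anchor.

    For every candidate pair with ``|Spearman r| >= threshold`` (species-
    level binary trait vectors), the member with the *larger* absolute
    correlation to the anchor is removed; exact ties fall back to the
    user-supplied ``priority`` drop list, then to candidate order.  The
    anchor itself is never removed.

    Returns the retained candidates (input order preserved) and a detail
    frame of the offending pairs.
    """
    if anchor not in traits.data.columns:
        raise ValidationError(f"anchor trait {anchor!r} missing from trait table")
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    missing = [c for c in candidates if c not in traits.data.columns]
    if missing:
        raise ValidationError(f"candidates missing from trait table: {missing}")

    cols = list(dict.fromkeys(list(candidates) + [anchor]))
    corr = _spearman_matrix(traits.data[cols])
    alive = dict.fromkeys(candidates, True)
    records = []

    pairs = [
        (a, b, float(corr.loc[a, b]))
        for a, b in itertools.combinations(candidates, 2)
        if abs(corr.loc[a, b]) >= threshold
    ]
    pairs.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    for a, b, r in pairs:
        if not (alive[a] and alive[b]):
            continue
        ra, rb = abs(float(corr.loc[anchor, a])), abs(float(corr.loc[anchor, b]))
        if a == anchor:
            drop = b
        elif b == anchor:
            drop = a
        elif ra > rb:
            drop = a
        elif rb > ra:
            drop = b
        else:  # tie: consult priority list, then candidate order
            in_priority = [m for m in priority if m in (a, b)]
            drop = in_priority[0] if in_priority else b
        alive[drop] = False
        records.append(
            {"metric": drop, "partner": a if drop == b else b, "pair_r": r,
             "anchor_r_dropped": ra if drop == a else rb,
             "anchor_r_kept": rb if drop == a else ra}
        )
    retained = [c for c in candidates if alive[c]]
    detail = pd.DataFrame(records, columns=["metric", "partner", "pair_r",
                                            "anchor_r_dropped", "anchor_r_kept"])
    return retained, detail


def discrimination_power(
    reference_values: Sequence[float],
    impaired_values: Sequence[float],
) -> int:
    """Box-plot overlap score IQ in {0, 1, 2, 3}.

    3: interquartile ranges disjoint (very strong discrimination);
    2: IQRs overlap but neither median lies inside the other IQR;
    1: exactly one median inside the other IQR;
    0: both medians inside the overlap.

    Quartiles use linear interpolation (type 7).
    """
    ref = np.asarray(reference_values, dtype=float)
    imp = np.asarray(impaired_values, dtype=float)
    if len(ref) < 3 or len(imp) < 3:
        raise ValidationError("each sample needs at least 3 values for quartiles")
    q1r, medr, q3r = np.percentile(ref, [25, 50, 75])
    q1i, medi, q3i = np.percentile(imp, [25, 50, 75])
    if q3r < q1i or q3i < q1r:
        return 3
    ref_med_inside = q1i <= medr <= q3i
    imp_med_inside = q1r <= medi <= q3r
    if ref_med_inside and imp_med_inside:
        return 0
    if ref_med_inside or imp_med_inside:
        return 1
    return 2


def sensitivity_screen(
    reference_values: pd.Series,
    current_values: pd.Series,
) -> str | None:
    """Uniform-trend test of current vs reference values across sites.

    Returns ``"increase"`` if current - reference is strictly positive at
    every site, ``"decrease"`` if strictly negative everywhere, and
    ``None`` (insensitive) for mixed signs.  Zero deltas break the trend:
    "uniformly lower or higher" is read strictly.
    """
    if set(reference_values.index) != set(current_values.index):
        raise ValidationError("reference and current values cover different sites")
    delta = current_values - reference_values.loc[current_values.index]
    if (delta > 0).all():
        return "increase"
    if (delta < 0).all():
        return "decrease"
    return None


def run_screening(
    occ_current: OccurrenceMatrix,
    traits: TraitMatrix,
    reference: ReferenceSet,
    candidates: Sequence[str] | None = None,
    anchor: str = "EF",
    threshold: float = 0.60,
    iq_keep: int = 3,
    priority: Sequence[str] = DEFAULT_TIE_PRIORITY,
) -> ScreeningReport:
    """Run redundancy -> discrimination -> sensitivity screening.

    Reference values per metric come from the cluster-group pooled
    historical faunas (``reference``), current values from the
    post-development occurrence matrix.  Only metrics with IQ equal to
    ``iq_keep`` (default 3, the strongest box-plot separation) reach the
    sensitivity stage.
    """
    if candidates is None:
        candidates = [t for t in traits.traits]
    candidates = list(candidates)
    if not candidates:
        warnings.warn("no candidate metrics supplied; empty screening report")
        empty = pd.DataFrame(
            columns=["fate", "iq", "direction", "anchor_r", "partner", "partner_r"]
        )
        return ScreeningReport(table=empty, anchor=anchor)

    cols = list(dict.fromkeys(candidates + [anchor]))
    corr = _spearman_matrix(traits.data[cols])

    table = pd.DataFrame(
        index=pd.Index(candidates, name="metric"),
        data={
            "fate": "retained",
            "iq": np.nan,
            "direction": None,
            "anchor_r": [float(corr.loc[anchor, c]) for c in candidates],
            "partner": None,
            "partner_r": np.nan,
        },
    )

    retained, detail = redundancy_screen(traits, candidates, anchor, threshold, priority)
    for rec in detail.itertuples():
        table.loc[rec.metric, ["fate", "partner", "partner_r"]] = (
            "redundancy", rec.partner, rec.pair_r,
        )

    current = metric_values(occ_current, traits, retained)
    site_ref = reference.site_reference(retained)

    survivors = []
    for m in retained:
        iq = discrimination_power(site_ref[m], current[m])
        table.loc[m, "iq"] = iq
        if iq >= iq_keep:
            survivors.append(m)
        else:
            table.loc[m, "fate"] = "discrimination"

    for m in survivors:
        direction = sensitivity_screen(site_ref[m], current[m])
        if direction is None:
            table.loc[m, "fate"] = "sensitivity"
        else:
            table.loc[m, "direction"] = direction

    return ScreeningReport(table=table, anchor=anchor)
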