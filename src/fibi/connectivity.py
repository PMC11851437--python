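"""Time-weighted river connectivity for dammed river networks.

A river is described as segments (length, river rank) joined into a
connected graph (a mainstem chain, unless extra confluences are given),
with barriers (dams) sitting on the joins.  Each barrier has a
passability ``p`` in [0, 1] — 0.00 for a complete barrier, 0.25 for one
equipped with a fish passage — and a commissioning year before which it
does not exist.

The static per-segment connectivity index is

    RCI_i(year) = 100 * w_i * sum_j w_j * p_ij(year),
    w_i = 2 r_i l_i / L,   L = sum_i 2 r_i l_i,

where ``p_ij`` is the product of the passabilities of the barriers on
the (unique) path between segments i and j that are commissioned by that
year (``p_ii = 1``, the empty product).  The time-weighted index TRCI_i
is the mean of RCI_i over the evaluation years, so early dam
commissioning depresses it more than recent commissioning.  The ordinal
derivative CTP is the dense rank of TRCI (1 = least connected), used as
a covariate in driver models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import ValidationError

__all__ = [
    "RiverNetwork",
    "TRCIResult",
    "read_network",
    "passability",
    "rci_static",
    "trci",
    "ctp_ordinal",
    "PASSABILITY_COMPLETE",
    "PASSABILITY_FISHWAY",
]

PASSABILITY_COMPLETE = 0.00
PASSABILITY_FISHWAY = 0.25


@dataclass
class RiverNetwork:
    """Segments plus barriers on the joins between them.

    Parameters
    ----------
    segments
        DataFrame with columns ``id``, ``length_km``, ``rank``; the row
        order defines the mainstem chain (consecutive segments are
        adjacent).
    barriers
        DataFrame with columns ``upstream``, ``downstream``,
        ``passability``, ``year``; each barrier must sit on an existing
        join.  Several barriers may share a join.
    extra_edges
        Optional additional adjacencies (tributary confluences) as
        ``(segment_a, segment_b)`` pairs.
    """

    segments: pd.DataFrame
    barriers: pd.DataFrame
    extra_edges: Sequence[tuple] = ()
    graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seg = self.segments
        for col in ("id", "length_km", "rank"):
            if col not in seg.columns:
                raise ValidationError(f"segments table missing column {col!r}")
        if seg["id"].duplicated().any():
            raise ValidationError("duplicate segment ids")
        if (seg["length_km"] < 0).any():
            raise ValidationError("segment lengths must be non-negative")
        self.segments = seg = seg.assign(id=seg["id"].astype(str)).reset_index(drop=True)

        g = nx.Graph()
        g.add_nodes_from(seg["id"])
        ids = list(seg["id"])
        for a, b in zip(ids, ids[1:]):
            g.add_edge(a, b, barriers=[])
        for a, b in self.extra_edges:
            g.add_edge(str(a), str(b), barriers=[])

        bar = self.barriers
        if len(bar):
            for col in ("upstream", "downstream", "passability", "year"):
                if col not in bar.columns:
                    raise ValidationError(f"barriers table missing column {col!r}")
            if ((bar["passability"] < 0) | (bar["passability"] > 1)).any():
                raise ValidationError("barrier passability must lie in [0, 1]")
            bar = bar.assign(
                upstream=bar["upstream"].astype(str),
                downstream=bar["downstream"].astype(str),
            )
            for rec in bar.itertuples():
                if not g.has_edge(rec.upstream, rec.downstream):
                    raise ValidationError(
                        f"barrier joins non-adjacent segments "
                        f"({rec.upstream!r}, {rec.downstream!r})"
                    )
                g.edges[rec.upstream, rec.downstream]["barriers"].append(
                    (float(rec.passability), int(rec.year))
                )
        self.barriers = bar
        if not nx.is_connected(g):
            raise ValidationError("segment graph is disconnected (ignoring barriers)")
        self.graph = g
        if self.total_weighted_length <= 0:
            raise ValidationError("total rank-weighted length must be positive")

    @property
    def segment_ids(self) -> list[str]:
        return list(self.segments["id"])

    @property
    def total_weighted_length(self) -> float:
        """L = sum_i 2 r_i l_i."""
        return float((2.0 * self.segments["rank"] * self.segments["length_km"]).sum())

    @property
    def weights(self) -> pd.Series:
        """w_i = 2 r_i l_i / L; sums to 1."""
        w = 2.0 * self.segments["rank"] * self.segments["length_km"] / self.total_weighted_length
        return pd.Series(w.to_numpy(), index=self.segments["id"].to_numpy(), name="w")


def read_network(segments_csv: str | Path, barriers_csv: str | Path) -> RiverNetwork:
    segments = pd.read_csv(segments_csv)
    barriers = pd.read_csv(barriers_csv)
    return RiverNetwork(segments=segments, barriers=barriers)


def passability(network: RiverNetwork, i, j, year: int | None = None) -> float:
    """p_ij: product of active barrier passabilities on the i-j path.

    A barrier is active from its commissioning year (inclusive); with
    ``year=None`` every barrier is active.  ``p_ii = 1`` (empty product).
    """
    i, j = str(i), str(j)
    for node in (i, j):
        if node not in network.graph:
            raise ValidationError(f"unknown segment {node!r}")
    if i == j:
        return 1.0
    path = nx.shortest_path(network.graph, i, j)
    p = 1.0
    for a, b in zip(path, path[1:]):
        for pm, yr in network.graph.edges[a, b]["barriers"]:
            if year is None or yr <= year:
                p *= pm
    return p


def rci_static(network: RiverNetwork, year: int | None = None) -> pd.Series:
    """Static connectivity index per segment for one barrier configuration."""
    ids = network.segment_ids
    w = network.weights
    p = np.ones((len(ids), len(ids)))
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            p[a, b] = p[b, a] = passability(network, ids[a], ids[b], year)
    rci = 100.0 * w.to_numpy() * (p @ w.to_numpy())
    return pd.Series(rci, index=ids, name="RCI")


@dataclass
class TRCIResult:
    """Time-averaged connectivity per segment, with per-year detail."""

    per_segment: pd.Series        # TRCI_i in [0, 100]
    per_year: pd.DataFrame        # years x segments static RCI
    ctp: pd.Series                # dense rank, 1 = least connected
    years: tuple[int, int]


def trci(network: RiverNetwork, start_year: int, end_year: int) -> TRCIResult:
    """Time-weighted connectivity: mean static RCI over the evaluation years.

    Years run from ``start_year`` (the first year of impoundment by the
    first station) to ``end_year`` inclusive; a barrier contributes only
    from its commissioning year, so pre-dam years contribute the undammed
    index.
    """
    if end_year < start_year:
        raise ValidationError("end_year must be >= start_year")
    years = range(start_year, end_year + 1)
    per_year = pd.DataFrame(
        {year: rci_static(network, year) for year in years}
    ).T
    per_year.index.name = "year"
    per_segment = per_year.mean(axis=0).rename("TRCI")
    return TRCIResult(
        per_segment=per_segment,
        per_year=per_year,
        ctp=ctp_ordinal(per_segment),
        years=(start_year, end_year),
    )


def ctp_ordinal(trci_values: pd.Series) -> pd.Series:
    """Dense rank of TRCI values: 1 = least connected; ties share a rank.

    Invariant under strictly monotone transforms of the index.
    """
    if len(trci_values) == 0:
        raise ValidationError("need at least one segment")
    from scipy.stats import rankdata

    ranks = rankdata(trci_values.to_numpy(), method="dense").astype(int)
    return pd.Series(ranks, index=trci_values.index, name="CTP")
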