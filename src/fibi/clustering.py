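"""Reference-condition construction from historical species composition.

Sites with similar historical faunas are grouped by hierarchical
clustering on Jaccard similarity; each group's member species lists are
pooled into a single reference fauna, from which per-metric reference
values are computed.  Clustering tendency is checked first with the
Hopkins statistic, and the number of groups can be chosen with the gap
statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, pdist, squareform

from .core_data import OccurrenceMatrix, TraitMatrix, ValidationError, metric_values

__all__ = [
    "StandardizeResult",
    "HopkinsResult",
    "ClusterSolution",
    "GapResult",
    "ReferenceSet",
    "standardize",
    "hopkins",
    "jaccard_similarity",
    "cluster_sites",
    "optimal_k",
    "pool_references",
]


@dataclass
class StandardizeResult:
    """Z-scored site-feature table plus the constant features dropped."""

    features: pd.DataFrame
    dropped: list


def standardize(occ: OccurrenceMatrix | pd.DataFrame) -> StandardizeResult:
    """Z-score each species column (population convention, ddof=0).

    Zero-variance columns carry no information about site differences and
    are dropped (and reported).  All-constant input is an error.
    """
    df = occ.data if isinstance(occ, OccurrenceMatrix) else occ
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.any():
        raise ValidationError("all features are constant; nothing to standardize")
    z = (values[:, keep] - mean[keep]) / std[keep]
    features = pd.DataFrame(z, index=df.index, columns=df.columns[keep])
    dropped = list(df.columns[~keep])
    return StandardizeResult(features=features, dropped=dropped)


@dataclass
class HopkinsResult:
    """Hopkins clustering-tendency statistic and its ingredients.

    ``H = sum(r_prime) / (sum(r) + sum(r_prime))`` where ``r`` are
    nearest-neighbour distances of probes drawn from the data itself
    (distance to the nearest *other* data row) and ``r_prime`` are
    nearest-neighbour distances of uniform pseudo-points drawn in the
    data bounding box.  H near 0.5 means no cluster structure; H near 1
    (tight data clumps) or 0 means clustering is worthwhile.
    """

    H: float
    n: int
    r: np.ndarray
    r_prime: np.ndarray


def hopkins(
    data: pd.DataFrame | np.ndarray,
    n: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> HopkinsResult:
    """Hopkins statistic on a real-valued table (rows = observations).

    Parameters
    ----------
    n
        Probe sample size; defaults to ``ceil(0.3 * rows)`` clipped to
        ``[2, rows - 1]`` for small-sample stability.
    seed
        Seed or Generator driving both probe sampling and the uniform
        reference points.
    """
    x = np.asarray(data, dtype=float)
    n_rows = x.shape[0]
    if n_rows < 3:
        raise ValidationError("need at least 3 rows for the Hopkins statistic")
    if np.allclose(x, x[0]):
        raise ValidationError("degenerate data: all rows identical")
    if n is None:
        n = int(np.clip(math.ceil(0.3 * n_rows), 2, n_rows - 1))
    if not (2 <= n < n_rows):
        raise ValidationError(f"probe count n={n} must satisfy 2 <= n < rows={n_rows}")
    rng = np.random.default_rng(seed)

    probe_idx = rng.choice(n_rows, size=n, replace=False)
    d_real = cdist(x[probe_idx], x)
    d_real[np.arange(n), probe_idx] = np.inf  # exclude self-distance
    r = d_real.min(axis=1)

    lo, hi = x.min(axis=0), x.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(n, x.shape[1]))
    r_prime = cdist(uniform, x).min(axis=1)

    denom = r.sum() + r_prime.sum()
    if denom == 0:
        raise ValidationError("degenerate data: all nearest-neighbour distances are zero")
    return HopkinsResult(H=float(r_prime.sum() / denom), n=n, r=r, r_prime=r_prime)


def jaccard_similarity(occ: OccurrenceMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity of site species sets.

    ``S(a, b) = |A ∩ B| / |A ∪ B|``; symmetric with unit diagonal.
    """
    if len(occ.sites) < 2:
        raise ValidationError("need at least 2 sites")
    x = occ.data.to_numpy(dtype=bool)
    if (~x.any(axis=1)).any():
        empty = [s for s, row in zip(occ.sites, x) if not row.any()]
        raise ValidationError(f"sites with empty species sets: {empty}")
    sim = 1.0 - squareform(pdist(x, metric="jaccard"))
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=occ.data.index, columns=occ.data.index)


@dataclass
class ClusterSolution:
    """Hierarchical clustering of sites on a similarity matrix."""

    assignment: pd.Series  # site -> group label (1..k)
    k: int
    similarity: pd.DataFrame
    linkage_method: str
    linkage: np.ndarray = field(repr=False, default=None)

    @property
    def groups(self) -> dict:
        return {g: list(idx) for g, idx in self.assignment.groupby(self.assignment).groups.items()}


def cluster_sites(
    similarity: pd.DataFrame,
    k: int,
    linkage_method: str = "average",
) -> ClusterSolution:
    """Agglomerative clustering on distance ``1 - similarity``.

    Average linkage (UPGMA) is the default, the conventional pairing with
    Jaccard similarity in community ecology.  Deterministic given inputs.
    """
    n = similarity.shape[0]
    if similarity.shape[0] != similarity.shape[1]:
        raise ValidationError("similarity matrix must be square")
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range [1, {n}]")
    dist = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    # relabel groups 1..k in order of first appearance so output is stable
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = pd.Series([remap[l] for l in labels], index=similarity.index, name="group")
    return ClusterSolution(
        assignment=assignment, k=int(assignment.nunique()),
        similarity=similarity, linkage_method=linkage_method, linkage=link,
    )


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani's W_k: sum over clusters of pairwise-squared-distance / (2 n_r)."""
    total = 0.0
    for lab in np.unique(labels):
        members = x[labels == lab]
        if len(members) > 1:
            total += float((pdist(members, metric="sqeuclidean")).sum()) / (2 * len(members))
    return total


@dataclass
class GapResult:
    k_hat: int
    gap: np.ndarray          # gap value per candidate k (1..k_max)
    sk: np.ndarray           # simulation standard error per candidate k
    log_w: np.ndarray
    log_w_ref_mean: np.ndarray


def optimal_k(
    features: pd.DataFrame | np.ndarray,
    k_max: int,
    B: int = 100,
    seed: int | np.random.Generator | None = None,
    linkage_method: str = "average",
) -> GapResult:
    """Gap-statistic choice of the number of site groups.

    Clusters the feature table hierarchically (Euclidean distance, same
    linkage as :func:`cluster_sites`) for each candidate k, compares the
    log within-cluster dispersion against ``B`` uniform reference
    datasets drawn over each feature's observed range, and picks the
    first k whose gap is within one simulation SE of the next gap
    (``gap(k) >= gap(k+1) - SE(k+1)``).
    """
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 rows to estimate a cluster count")
    if not (1 <= k_max <= n):
        raise ValidationError(f"k_max={k_max} out of range [1, {n}]")
    if B < 10:
        raise ValidationError("B must be at least 10 reference replicates")
    rng = np.random.default_rng(seed)

    def labels_for(data: np.ndarray, k: int) -> np.ndarray:
        link = hierarchy.linkage(data, method=linkage_method, metric="euclidean")
        return hierarchy.fcluster(link, t=k, criterion="maxclust")

    ks = np.arange(1, k_max + 1)
    log_w = np.array([np.log(max(_within_dispersion(x, labels_for(x, k)), 1e-300)) for k in ks])
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w_ref = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=x.shape)
        for i, k in enumerate(ks):
            log_w_ref[b, i] = np.log(max(_within_dispersion(ref, labels_for(ref, k)), 1e-300))
    gap = log_w_ref.mean(axis=0) - log_w
    sk = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    k_hat = k_max
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            k_hat = int(ks[i])
            break
    return GapResult(k_hat=k_hat, gap=gap, sk=sk, log_w=log_w, log_w_ref_mean=log_w_ref.mean(axis=0))


@dataclass
class ReferenceSet:
    """Pooled reference faunas and per-metric reference values per group.

    ``values`` is a groups x metrics table of reference percentages,
    computed on each group's pooled species list (the union of member
    sites' historical species sets) — not by averaging site values.
    """

    pools: Mapping[int, tuple]
    values: pd.DataFrame          # groups x metrics
    assignment: pd.Series         # site -> group

    @property
    def pooled_counts(self) -> pd.Series:
        return pd.Series({g: len(p) for g, p in self.pools.items()}, name="pooled_species")

    def site_reference(self, metrics: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-site reference values (each site inherits its group's values)."""
        ref = self.values.loc[self.assignment.to_numpy()]
        ref.index = self.assignment.index
        if metrics is not None:
            ref = ref[list(metrics)]
        return ref

    def group_of(self, site) -> int:
        try:
            return int(self.assignment.loc[site])
        except KeyError:
            raise ValidationError(f"site {site!r} has no group assignment") from None


def pool_references(
    occ_hist: OccurrenceMatrix,
    solution: ClusterSolution | pd.Series,
    traits: TraitMatrix,
    metrics: Sequence[str] | None = None,
) -> ReferenceSet:
    """Pool historical species per cluster group and derive reference values.

    Sites in the same group share an expected fauna: the union of their
    historical species lists.  Reference metric values are the trait
    percentages of that pooled fauna.
    """
    assignment = solution.assignment if isinstance(solution, ClusterSolution) else solution
    missing = [s for s in occ_hist.sites if s not in assignment.index]
    if missing:
        raise ValidationError(f"sites without group assignment: {missing}")
    if metrics is None:
        metrics = traits.traits

    pools: dict[int, tuple] = {}
    rows = []
    groups = sorted(assignment.unique())
    for g in groups:
        members = assignment.index[assignment == g]
        pooled: set = set()
        for site in members:
            pooled |= occ_hist.species_at(site)
        if not pooled:
            raise ValidationError(f"group {g} has an empty species pool")
        pools[int(g)] = tuple(sorted(pooled))
        row = pd.Series(0, index=occ_hist.data.columns, dtype=np.int8)
        row[list(pooled)] = 1
        rows.append(row)

    pooled_occ = OccurrenceMatrix(
        pd.DataFrame(rows, index=pd.Index(groups, name="group")), era="historical"
    )
    values = metric_values(pooled_occ, traits, metrics)
    return ReferenceSet(pools=pools, values=values, assignment=assignment)
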