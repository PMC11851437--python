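"""Data containers, validation, and CSV I/O for bioassessment tables.

The pipeline works on three kinds of tables:

* occurrence matrices — sites x species presence/absence (0/1), one per
  survey era ("historical" for the pre-development baseline, "current"
  for the post-development survey);
* trait matrices — species x ecological traits (0/1), using the 25-trait
  controlled vocabulary of :data:`TRAIT_NAMES`;
* metric tables — sites x metrics, where a metric is the percentage of
  the species present at a site that carry a given trait.

Everything is stored in pandas DataFrames; the light dataclass wrappers
exist only to attach validation and era labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "TRAIT_FAMILIES",
    "ERAS",
    "ValidationError",
    "OccurrenceMatrix",
    "TraitMatrix",
    "read_occurrence",
    "write_occurrence",
    "read_traits",
    "write_traits",
    "read_site_metadata",
    "metric_values",
]


class ValidationError(ValueError):
    """Raised when an input table violates its structural contract."""


#: Controlled vocabulary: trait code -> description.
TRAIT_NAMES: Mapping[str, str] = {
    "EF": "endemic",
    "SF": "surface / pelagic water column",
    "MF": "midwater column",
    "DF": "demersal water column",
    "EFM": "superior (upturned) mouth",
    "NFM": "terminal mouth",
    "HFM": "inferior (subterminal) mouth",
    "CF": "carnivorous",
    "OF": "omnivorous",
    "HF": "herbivorous",
    "PF": "planktivorous",
    "FZ": "benthivorous (zoobenthos feeder)",
    "MIF": "migratory",
    "HYF": "limnophilic (still-water)",
    "EUF": "eurytopic",
    "CUF": "rheophilic (running-water)",
    "TAF": "dorsoventrally flattened body",
    "CYF": "cylindrical body",
    "LAF": "laterally compressed body",
    "FUF": "fusiform body",
    "SIF": "demersal (sinking) eggs",
    "FLF": "pelagic (floating) eggs",
    "DRF": "drifting eggs",
    "STF": "adhesive (sticky) eggs",
    "SPF": "specialised spawning mode",
}

#: Mutually exclusive trait families: each species carries exactly one
#: trait from each family (a fish has one mouth position, one body form,
#: one water-column preference and one egg type).
TRAIT_FAMILIES: Mapping[str, tuple[str, ...]] = {
    "water_column": ("SF", "MF", "DF"),
    "mouth_position": ("EFM", "NFM", "HFM"),
    "body_form": ("TAF", "CYF", "LAF", "FUF"),
    "egg_type": ("SIF", "FLF", "DRF", "STF"),
}

ERAS = ("historical", "current")


def _check_binary(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} cell ({df.index[i]!r}, {df.columns[j]!r}) is "
            f"{values[i, j]!r}; every cell must be 0 or 1"
        )


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.duplicated().any():
        dupes = sorted(set(labels[labels.duplicated()]))
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class OccurrenceMatrix:
    """Sites x species presence/absence matrix for one survey era.

    Parameters
    ----------
    data
        DataFrame with site identifiers as index, species identifiers as
        columns, and 0/1 cells.
    era
        Either ``"historical"`` or ``"current"``.
    """

    data: pd.DataFrame
    era: str = "historical"

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise ValidationError(f"era must be one of {ERAS}, got {self.era!r}")
        _check_unique(self.data.index, "site")
        _check_unique(self.data.columns, "species")
        _check_binary(self.data, "occurrence")
        self.data = self.data.astype(np.int8)
        empty = self.data.index[self.data.sum(axis=1) == 0]
        if len(empty):
            raise ValidationError(
                f"sites with no species present: {list(empty)}"
            )

    @property
    def sites(self) -> list:
        return list(self.data.index)

    @property
    def species(self) -> list:
        return list(self.data.columns)

    def species_at(self, site) -> frozenset:
        row = self.data.loc[site]
        return frozenset(row.index[row == 1])


@dataclass
class TraitMatrix:
    """Species x traits binary matrix over a controlled trait vocabulary."""

    data: pd.DataFrame
    vocabulary: Mapping[str, str] = field(default_factory=lambda: TRAIT_NAMES)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "species")
        _check_unique(self.data.columns, "trait")
        unknown = [t for t in self.data.columns if t not in self.vocabulary]
        if unknown:
            raise ValidationError(
                f"unknown trait names {unknown}; registered vocabulary: "
                f"{sorted(self.vocabulary)}"
            )
        _check_binary(self.data, "trait")
        self.data = self.data.astype(np.int8)

    @property
    def species(self) -> list:
        return list(self.data.index)

    @property
    def traits(self) -> list:
        return list(self.data.columns)


def read_occurrence(path: str | Path, era: str) -> OccurrenceMatrix:
    """Read a site-by-species 0/1 CSV (first column = site identifiers)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return OccurrenceMatrix(df, era=era)


def write_occurrence(occ: OccurrenceMatrix, path: str | Path) -> None:
    occ.data.to_csv(path)


def read_traits(path: str | Path, vocabulary: Mapping[str, str] | None = None) -> TraitMatrix:
    """Read a species-by-trait 0/1 CSV (first column = species identifiers)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if vocabulary is None:
        return TraitMatrix(df)
    return TraitMatrix(df, vocabulary=vocabulary)


def write_traits(traits: TraitMatrix, path: str | Path) -> None:
    traits.data.to_csv(path)


def read_site_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-site metadata (habitat type, reach length, covariates).

    The table is indexed by site identifier.  A ``habitat_type`` column,
    if present, must use the ordinal encoding NRAD=1, TR=2 (or the string
    labels, which are mapped onto it); ``natural_reach_km`` must be
    non-negative.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if "habitat_type" in df.columns:
        ht = df["habitat_type"]
        if ht.dtype == object:
            mapped = ht.map({"NRAD": 1, "TR": 2})
            if mapped.isna().any():
                bad = sorted(ht[mapped.isna()].unique())
                raise ValidationError(f"unknown habitat_type labels: {bad}")
            df["habitat_type"] = mapped.astype(int)
        elif not ht.isin((1, 2)).all():
            raise ValidationError("habitat_type must be 1 (NRAD) or 2 (TR)")
    if "natural_reach_km" in df.columns and (df["natural_reach_km"] < 0).any():
        raise ValidationError("natural_reach_km must be non-negative")
    return df


def metric_values(
    occ: OccurrenceMatrix,
    traits: TraitMatrix,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Trait-percentage metrics: % of the species present that carry each trait.

    For site ``s`` and trait ``m`` the value is
    ``100 * |present species at s with m| / |present species at s|``.
    Percentages are kept at full precision; round only for reporting.

    Raises
    ------
    ValidationError
        If any species in the occurrence matrix is missing from the trait
        table (silent drops would bias the percentages).
    """
    if metrics is None:
        metrics = traits.traits
    missing_traits = [m for m in metrics if m not in traits.data.columns]
    if missing_traits:
        raise ValidationError(f"metrics not in trait table: {missing_traits}")
    missing_sp = [s for s in occ.species if s not in traits.data.index]
    if missing_sp:
        raise ValidationError(
            f"species missing from trait table: {missing_sp}"
        )
    t = traits.data.loc[occ.species, list(metrics)].to_numpy(dtype=float)
    p = occ.data.to_numpy(dtype=float)
    richness = p.sum(axis=1)
    # validated matrices have richness >= 1, but guard anyway
    if (richness == 0).any():
        empty = [s for s, r in zip(occ.sites, richness) if r == 0]
        raise ValidationError(f"sites with no species present: {empty}")
    pct = 100.0 * (p @ t) / richness[:, None]
    return pd.DataFrame(pct, index=occ.data.index, columns=list(metrics))
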