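"""Synthetic survey scenarios with planted, recoverable structure.

The generator emulates the study design every downstream stage assumes:
a mainstem river with ~12 sites falling into ~8 faunal groups, a
regional pool of ~139 species described by 25 binary traits, a
historical (pre-development) occupancy pattern in which sites of the
same group share a species pool, and a current survey in which a
site-specific disturbance intensity has thinned the fauna along planted
trait axes — rheophilic, planktivorous, drifting-egg, endemic and
migratory species persist less, still-water and eurytopic species
persist more, so their site percentages shift in known directions.

Persistence is Bernoulli with a logistic link:

    logit P(persist) = logit(p0) + d_site * sum_t effect_t * trait_t,

the simplest mechanism that produces the monotone trait-percentage
shifts the screening stage is built to detect.  Trait prevalences in the
pool are planted as exact counts (largest-remainder rounding of the
configured probabilities over a random species permutation): the pool
models a fixed regional fauna, so the configured prevalences *are* the
study condition rather than a Bernoulli expectation.  Ecological
correlations are planted through rheophily: endemism, migration and
drifting-egg spawning are concentrated among rheophilic species, while
still-water and eurytopic habits are concentrated among the rest — the
kind of guild structure real dammed-river faunas show, with pairwise
trait correlations kept below the redundancy screen's 0.60 threshold.

Effect magnitudes and prevalences were fixed by a design-phase power
analysis so that planted percentage shifts exceed assemblage-size
sampling noise at the study scale (see docs/methods.md); they are not
tuned per scenario.  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    TRAIT_FAMILIES,
    TRAIT_NAMES,
    OccurrenceMatrix,
    TraitMatrix,
    ValidationError,
)
from .connectivity import RiverNetwork, trci

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "simulate_pool",
    "simulate_occurrence",
    "simulate_network",
    "simulate_metadata",
    "simulate_scenario",
    "write_scenario",
    "DEFAULT_TRAIT_EFFECTS",
]

#: Persistence log-odds shift per unit disturbance.  Negative values
#: deplete a guild as disturbance grows (rheophilic, planktivorous,
#: drifting-egg, endemic, migratory, specialist spawners); positive
#: values favour it (still-water, eurytopic).
DEFAULT_TRAIT_EFFECTS: Mapping[str, float] = {
    "CUF": -5.5,
    "PF": -5.5,
    "DRF": -5.5,
    "EF": -5.5,
    "MIF": -5.5,
    "SPF": -5.5,
    "HYF": 4.0,
    "EUF": 4.0,
}

#: Latent species-class shares: disturbance-sensitive flow specialists,
#: tolerant lentic generalists, and a neutral remainder.  The class is a
#: generative device only — downstream stages never see it.
DEFAULT_CLASS_PROBS: tuple[float, float, float] = (0.45, 0.30, 0.25)

#: Guild prevalence per latent class: trait -> (P | sensitive,
#: P | tolerant, P | neutral).  Sensitive-guild traits (rheophily,
#: planktivory, endemism, migration, specialist spawning) concentrate in
#: the sensitive class; still-water and eurytopic habits in the tolerant
#: class.  Cross-class leakage is kept small enough that every pairwise
#: trait correlation stays well below the 0.60 redundancy threshold.
DEFAULT_GUILD_CLASS_PROBS: Mapping[str, tuple[float, float, float]] = {
    "CUF": (0.80, 0.20, 0.20),
    "PF": (0.55, 0.03, 0.03),
    "SPF": (0.55, 0.03, 0.03),
    "EF": (0.55, 0.03, 0.03),
    "MIF": (0.55, 0.03, 0.03),
    "HYF": (0.06, 0.80, 0.25),
    "EUF": (0.05, 0.65, 0.20),
}

#: Unconditional prevalences for the remaining independent traits.
DEFAULT_INDEPENDENT_PREVALENCE: Mapping[str, float] = {
    "CF": 0.35,
    "OF": 0.40,
    "HF": 0.15,
    "FZ": 0.20,
}

#: Category probabilities for the mutually exclusive trait families.
DEFAULT_FAMILY_PROBS: Mapping[str, Mapping[str, float]] = {
    "water_column": {"SF": 0.25, "MF": 0.35, "DF": 0.40},
    "mouth_position": {"EFM": 0.20, "NFM": 0.55, "HFM": 0.25},
    "body_form": {"TAF": 0.10, "CYF": 0.25, "LAF": 0.45, "FUF": 0.20},
}

#: Egg-type family probabilities (given sensitive class, given other):
#: drifting eggs need sustained flow, so they concentrate among the
#: flow specialists.
DEFAULT_EGG_PROBS: tuple[Mapping[str, float], Mapping[str, float]] = (
    {"SIF": 0.25, "FLF": 0.15, "DRF": 0.50, "STF": 0.10},
    {"SIF": 0.45, "FLF": 0.28, "DRF": 0.03, "STF": 0.24},
)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults emulate the study scale: 12 sites on a dammed mainstem, 139
    species, 8 faunal groups, disturbance intensities spanning 0.6-0.95
    from the least to the most impacted site (every site on a cascade-
    dammed mainstem is substantially disturbed).
    """

    n_sites: int = 12
    n_species: int = 160
    n_groups: int = 8
    seed: int = 0
    disturbance: np.ndarray | None = None
    baseline_persistence: float = 0.85
    trait_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_EFFECTS)
    )
    mixed_trend_traits: tuple[str, ...] = ("OF", "HF", "FZ")
    mixed_effect: float = 0.8
    pool_membership: float = 0.80
    site_occupancy: float = 0.92
    n_exotic: int = 0
    barrier_years: tuple[int, ...] | None = None
    eval_years: tuple[int, int] = (1, 40)
    class_probs: tuple[float, float, float] = DEFAULT_CLASS_PROBS
    guild_class_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_CLASS_PROBS)
    )
    independent_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEPENDENT_PREVALENCE)
    )
    family_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FAMILY_PROBS.items()}
    )
    egg_probs: tuple[Mapping[str, float], Mapping[str, float]] = field(
        default_factory=lambda: (dict(DEFAULT_EGG_PROBS[0]), dict(DEFAULT_EGG_PROBS[1]))
    )

    def __post_init__(self) -> None:
        if self.disturbance is None:
            self.disturbance = np.linspace(0.5, 1.0, self.n_sites)
        self.disturbance = np.asarray(self.disturbance, dtype=float)
        if len(self.disturbance) != self.n_sites:
            raise ValidationError("disturbance must have one value per site")
        if ((self.disturbance < 0) | (self.disturbance > 1)).any():
            raise ValidationError("disturbance intensities must lie in [0, 1]")
        if not (1 <= self.n_groups <= self.n_sites):
            raise ValidationError("n_groups must lie in [1, n_sites]")
        for t, e in self.trait_effects.items():
            if t not in TRAIT_NAMES:
                raise ValidationError(f"unknown trait {t!r} in trait_effects")
            if t in ("CUF", "PF", "DRF") and e >= 0:
                raise ValidationError(f"{t} effect must be negative (guild is depleted)")
            if t in ("HYF", "EUF") and e <= 0:
                raise ValidationError(f"{t} effect must be positive (guild is favoured)")
        for t in self.mixed_trend_traits:
            if t not in TRAIT_NAMES:
                raise ValidationError(f"unknown trait {t!r} in mixed_trend_traits")

    @property
    def site_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    @property
    def planted_directions(self) -> dict[str, str]:
        """Expected screening outcome for the directional-effect traits."""
        return {
            t: ("decrease" if e < 0 else "increase")
            for t, e in self.trait_effects.items()
            if e != 0
        }

    @property
    def candidate_metrics(self) -> list[str]:
        """Directional plus mixed-trend traits: the screening candidates."""
        return list(self.planted_directions) + list(self.mixed_trend_traits)

    def target_marginals(self) -> dict[str, float]:
        """Implied pool prevalence per trait (for calibration checks)."""
        w = np.asarray(self.class_probs, dtype=float)
        out: dict[str, float] = dict(self.independent_prevalence)
        for t, probs in self.guild_class_probs.items():
            out[t] = float(w @ np.asarray(probs))
        for fam in self.family_probs.values():
            out.update(fam)
        p_sens = w[0]
        for t in self.egg_probs[0]:
            out[t] = p_sens * self.egg_probs[0][t] + (1 - p_sens) * self.egg_probs[1][t]
        return out

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named randomness stream."""
        return np.random.default_rng([stream, self.seed])


def _exact_counts(probs: Sequence[float], n: int) -> list[int]:
    """Largest-remainder rounding of n * probs to integers summing to n."""
    raw = np.asarray(probs, dtype=float) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return list(counts)


def _assign_exact(rng: np.random.Generator, mask: np.ndarray, p: float) -> np.ndarray:
    """Mark round(p * mask.sum()) randomly chosen rows inside ``mask``."""
    idx = np.flatnonzero(mask)
    k = int(round(p * len(idx)))
    out = np.zeros(len(mask), dtype=np.int8)
    if k:
        out[rng.choice(idx, size=k, replace=False)] = 1
    return out


def _assign_family(
    rng: np.random.Generator, idx: np.ndarray, probs: Mapping[str, float]
) -> dict[str, np.ndarray]:
    cats = list(probs)
    counts = _exact_counts([probs[c] for c in cats], len(idx))
    labels = np.repeat(np.arange(len(cats)), counts)
    rng.shuffle(labels)
    return {c: idx[labels == i] for i, c in enumerate(cats)}


def simulate_pool(cfg: ScenarioConfig) -> TraitMatrix:
    """Generate the regional species pool's binary trait matrix.

    Mouth position, water column, body form and egg type are mutually
    exclusive families (exactly one trait set per species); remaining
    traits are marked at their configured exact prevalences, several of
    them conditionally on rheophily (see module docstring).
    """
    n = cfg.n_species
    if n < 20:
        raise ValidationError("need at least 20 species for a meaningful pool")
    rng = cfg.rng(stream=1)
    species = [f"sp{i + 1:03d}" for i in range(n)]
    data = pd.DataFrame(0, index=species, columns=list(TRAIT_NAMES), dtype=np.int8)

    # latent class per species (exact shares, random assignment)
    counts = _exact_counts(cfg.class_probs, n)
    classes = np.repeat(np.arange(3), counts)
    rng.shuffle(classes)

    for t, probs in cfg.guild_class_probs.items():
        col = np.zeros(n, dtype=np.int8)
        for c, p in enumerate(probs):
            col |= _assign_exact(rng, classes == c, p)
        data[t] = col

    for fam_name, probs in cfg.family_probs.items():
        for cat, members in _assign_family(rng, np.arange(n), probs).items():
            data.iloc[members, data.columns.get_loc(cat)] = 1
    sens = np.flatnonzero(classes == 0)
    other = np.flatnonzero(classes != 0)
    for idx, probs in zip((sens, other), cfg.egg_probs):
        for cat, members in _assign_family(rng, idx, probs).items():
            data.iloc[members, data.columns.get_loc(cat)] = 1

    # decoy / mixed-trend traits are assigned stratified by the realized
    # persistence strata (vulnerable / favoured / unaffected), i.e. with
    # exactly zero association to the disturbance response: a random
    # finite-pool overlap with the vulnerable-guild union would otherwise
    # drift every site's percentage the same way, mimicking a uniform
    # disturbance trend on a trait that was planted to carry none
    vulnerable = np.zeros(n, dtype=bool)
    favoured = np.zeros(n, dtype=bool)
    for t, e in cfg.trait_effects.items():
        col = data[t].to_numpy(dtype=bool)
        if e < 0:
            vulnerable |= col
        elif e > 0:
            favoured |= col
    favoured &= ~vulnerable
    strata = np.where(vulnerable, 0, np.where(favoured, 1, 2))
    for t, p in cfg.independent_prevalence.items():
        col = np.zeros(n, dtype=np.int8)
        for s in range(3):
            col |= _assign_exact(rng, strata == s, p)
        data[t] = col

    return TraitMatrix(data)


def _group_assignment(cfg: ScenarioConfig) -> pd.Series:
    blocks = np.array_split(np.arange(cfg.n_sites), cfg.n_groups)
    labels = np.empty(cfg.n_sites, dtype=int)
    for g, block in enumerate(blocks, start=1):
        labels[block] = g
    return pd.Series(labels, index=cfg.site_ids, name="group")


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def simulate_occurrence(
    cfg: ScenarioConfig, traits: TraitMatrix
) -> tuple[OccurrenceMatrix, OccurrenceMatrix]:
    """Historical and current occupancy for the configured scenario.

    Historical occupancy draws each site's fauna from its group's shared
    species pool; the current survey applies per-species persistence
    Bernoulli draws whose log-odds fall with the site's disturbance
    intensity along the planted trait axes (mixed-trend traits flip the
    sign of their effect between odd and even sites, producing the
    non-uniform trends the sensitivity screen must reject).
    """
    rng = cfg.rng(stream=2)
    n_sp = len(traits.species)
    groups = _group_assignment(cfg)

    pools: dict[int, np.ndarray] = {}
    for g in sorted(groups.unique()):
        mask = rng.random(n_sp) < cfg.pool_membership
        if not mask.any():
            mask[rng.integers(n_sp)] = True
        pools[g] = mask

    def draw_row(mask: np.ndarray, p: np.ndarray | float, label: str) -> np.ndarray:
        for _ in range(2):  # resample once before giving up
            row = mask & (rng.random(n_sp) < p)
            if row.any():
                return row
        raise ValidationError(f"site {label} empty after thinning (twice)")

    hist_rows, curr_rows = [], []
    t = traits.data.to_numpy(dtype=float)
    # limiting-factor aggregation: a species' vulnerability is set by its
    # most severe sensitive trait; tolerance advantages apply only to
    # species with no sensitive trait (otherwise broad-tolerance guilds
    # rescue co-occurring specialists and wash out the planted shifts)
    neg = np.zeros(n_sp)
    pos = np.zeros(n_sp)
    for trait, e in cfg.trait_effects.items():
        col = t[:, traits.traits.index(trait)]
        if e < 0:
            neg = np.minimum(neg, e * col)
        else:
            pos = np.maximum(pos, e * col)
    mix_cols = [
        cfg.mixed_effect * t[:, traits.traits.index(trait)]
        for trait in cfg.mixed_trend_traits
    ]
    eff = np.where(neg < 0, neg, np.where(pos > 0, pos, 0.0))
    mix_applies = (neg == 0) & (pos == 0)
    logit0 = _logit(cfg.baseline_persistence)

    for i, site in enumerate(cfg.site_ids):
        hist = draw_row(pools[groups[site]], cfg.site_occupancy, site)
        hist_rows.append(hist)
        # each mixed-trend trait alternates its own sign across sites
        # (offset parities), so every mixed trait shows both trends
        mix = np.zeros(n_sp)
        for k, col in enumerate(mix_cols):
            sign = 1.0 if (i + k) % 2 == 0 else -1.0
            mix += sign * col
        logits = logit0 + cfg.disturbance[i] * (eff + mix * mix_applies)
        persist = 1.0 / (1.0 + np.exp(-logits))
        curr_rows.append(draw_row(hist, persist, site))

    hist_df = pd.DataFrame(
        np.array(hist_rows, dtype=np.int8), index=cfg.site_ids, columns=traits.species
    )
    curr_df = pd.DataFrame(
        np.array(curr_rows, dtype=np.int8), index=cfg.site_ids, columns=traits.species
    )

    if cfg.n_exotic > 0:
        # lentic-adapted invaders appear in the current survey only,
        # preferentially at the more disturbed sites
        high = cfg.disturbance >= np.median(cfg.disturbance)
        for e in range(cfg.n_exotic):
            name = f"exo{e + 1:02d}"
            hist_df[name] = 0
            curr_df[name] = np.where(high & (rng.random(cfg.n_sites) < 0.7), 1, 0)

    historical = OccurrenceMatrix(hist_df, era="historical")
    current = OccurrenceMatrix(curr_df, era="current")
    return historical, current


def simulate_network(cfg: ScenarioConfig) -> RiverNetwork:
    """A mainstem chain of one segment per site, dammed at every join.

    Roughly 30% of barriers carry fish passages (passability 0.25);
    the rest are complete (0.00).  Commissioning years spread over the
    first 25 evaluation years unless ``barrier_years`` pins them.
    """
    rng = cfg.rng(stream=3)
    segments = pd.DataFrame({
        "id": cfg.site_ids,
        "length_km": rng.uniform(20.0, 120.0, cfg.n_sites).round(1),
        "rank": 1,
    })
    n_bar = cfg.n_sites - 1
    if cfg.barrier_years is not None:
        if len(cfg.barrier_years) != n_bar:
            raise ValidationError(f"barrier_years must have {n_bar} entries")
        years = list(cfg.barrier_years)
    else:
        years = list(rng.integers(cfg.eval_years[0], cfg.eval_years[0] + 25, n_bar))
    barriers = pd.DataFrame({
        "upstream": cfg.site_ids[:-1],
        "downstream": cfg.site_ids[1:],
        "passability": rng.choice([0.0, 0.25], size=n_bar, p=[0.7, 0.3]),
        "year": years,
    })
    return RiverNetwork(segments=segments, barriers=barriers)


def simulate_metadata(cfg: ScenarioConfig, network: RiverNetwork | None = None) -> pd.DataFrame:
    """Per-site covariate table (the 11 driver-model covariates).

    Continuous covariates follow plausible upstream-to-downstream trends
    with noise; HT is the ordinal habitat class (1 = free-flowing reach,
    2 = reservoir transition zone, assigned to the more disturbed half of
    sites); CTP is the ordinal cumulative connectivity-time rank derived
    from the simulated network's TRCI.
    """
    rng = cfg.rng(stream=4)
    n = cfg.n_sites
    grad = np.linspace(0.0, 1.0, n)
    d = cfg.disturbance

    if network is None:
        network = simulate_network(cfg)
    result = trci(network, *cfg.eval_years)

    meta = pd.DataFrame(index=pd.Index(cfg.site_ids, name="site"))
    meta["WA"] = np.round(rng.lognormal(mean=3.0, sigma=0.5, size=n), 2)
    meta["VR"] = np.round(np.linspace(300, 2200, n) * rng.lognormal(0, 0.15, n), 1)
    meta["TEM"] = np.round(np.linspace(14.0, 22.0, n) + rng.normal(0, 0.5, n), 2)
    meta["PRE"] = np.round(rng.uniform(1100, 1800, n), 0)
    meta["NRAD"] = np.round(rng.uniform(5, 120, n), 1)
    meta["LUR"] = np.round(np.clip(0.05 + 0.35 * grad + rng.normal(0, 0.05, n), 0, 1), 3)
    meta["HT"] = np.where(d >= np.median(d), 2, 1)
    meta["GDP"] = np.round(np.exp(np.linspace(np.log(5), np.log(500), n)) * rng.lognormal(0, 0.3, n), 2)
    meta["DWN"] = np.round(rng.uniform(0.2, 0.9, n), 3)
    meta["CTP"] = result.ctp.loc[cfg.site_ids].to_numpy()
    meta["ALT"] = np.round(np.linspace(1200, 60, n) * rng.lognormal(0, 0.1, n), 1)
    meta["habitat_type"] = meta["HT"]
    meta["natural_reach_km"] = meta["NRAD"]
    return meta


@dataclass
class Scenario:
    """A complete synthetic scenario bundle."""

    config: ScenarioConfig
    traits: TraitMatrix
    historical: OccurrenceMatrix
    current: OccurrenceMatrix
    metadata: pd.DataFrame
    network: RiverNetwork
    group_assignment: pd.Series
    disturbance: pd.Series


def simulate_scenario(cfg: ScenarioConfig | None = None, seed: int | None = None) -> Scenario:
    """Generate every table of one scenario from a single seed."""
    if cfg is None:
        cfg = ScenarioConfig(seed=0 if seed is None else seed)
    elif seed is not None:
        raise ValidationError("pass either a config or a seed, not both")
    traits = simulate_pool(cfg)
    historical, current = simulate_occurrence(cfg, traits)
    network = simulate_network(cfg)
    metadata = simulate_metadata(cfg, network)
    return Scenario(
        config=cfg,
        traits=traits,
        historical=historical,
        current=current,
        metadata=metadata,
        network=network,
        group_assignment=_group_assignment(cfg),
        disturbance=pd.Series(cfg.disturbance, index=cfg.site_ids, name="disturbance"),
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> None:
    """Write the full scenario bundle as plain CSV/JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.historical.data.to_csv(out / "historical.csv")
    scenario.current.data.to_csv(out / "current.csv")
    scenario.traits.data.to_csv(out / "traits.csv")
    scenario.metadata.to_csv(out / "metadata.csv")
    scenario.network.segments.to_csv(out / "segments.csv", index=False)
    scenario.network.barriers.to_csv(out / "barriers.csv", index=False)
    pd.DataFrame({
        "group": scenario.group_assignment,
        "disturbance": scenario.disturbance,
    }).to_csv(out / "groups.csv")
    cfg = asdict(scenario.config)
    cfg["disturbance"] = list(map(float, cfg["disturbance"]))
    with open(out / "scenario.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
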