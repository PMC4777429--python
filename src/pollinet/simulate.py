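"""Synthetic flower-visitation census generator with planted archetypes.

The generator emulates a season of focal-census sampling in several coastal
communities: biweekly flower-density surveys, census days on which every
plant in bloom is watched for the same fixed time, and visitor contact counts
recorded per plant-census.  Each visitor species is planted with one of five
behavioural archetypes so that downstream specialization metrics can be
scored against ground truth:

``generalized``
    unrestricted diet at a high encounter rate; encounters follow floral
    abundance (passive sampling, gamma = +1), so many partners are realized.
``specialized``
    restricted to one or two host plants (chosen preferentially among
    abundant ones, so the species survives the reliability filters).
``opportunistic``
    unrestricted diet, visits in proportion to flower density (gamma = +1)
    at a moderate rate: interaction use matches availability.
``selective``
    unrestricted diet but favours rare plants (gamma = -1), over-using
    scarce partners that the abundance-driven guilds barely touch.
``background``
    moderate link breadth, abundance-driven, low rate; fills the community
    so that top/bottom selections are nontrivial.

Within one census of a plant with ``F`` observed flowers, a visitor's
contact count is Poisson with mean ``base_rate * duration * F * w_i`` where
``w_i`` is the visitor's normalized preference ``density_i ** gamma`` over
its permitted, currently blooming host set.  Individuals are derived as
``ceil(contacts / contacts_per_individual)``.

All randomness flows from the single ``SimConfig.seed``.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_FUNCTIONAL_GROUPS,
    NO_VISITOR,
    CensusRecord,
    FlowerSurvey,
    SpeciesInfo,
)

ARCHETYPES = ("generalized", "specialized", "opportunistic", "selective", "background")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Behavioural parameters for one planted archetype.

    ``link_breadth`` is the number of permitted host plants (``None`` = all);
    ``gamma`` the preference exponent on flower density; ``base_rate`` the
    expected contacts per observed flower per census minute at w = 1.
    """

    label: str
    link_breadth: int | None
    gamma: float
    base_rate: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.link_breadth is not None and self.link_breadth < 1:
            raise ValueError("link_breadth must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")


DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "generalized": ArchetypeSpec("generalized", None, +1.0, 0.030),
    "specialized": ArchetypeSpec("specialized", 1, 0.0, 0.012),
    "opportunistic": ArchetypeSpec("opportunistic", None, +1.0, 0.006),
    "selective": ArchetypeSpec("selective", None, -1.0, 0.012),
    "background": ArchetypeSpec("background", 5, +1.0, 0.004),
}

#: Number of visitor species planted per archetype in each community.
DEFAULT_ARCHETYPE_MIX: dict[str, int] = {
    "generalized": 4,
    "specialized": 4,
    "opportunistic": 4,
    "selective": 4,
    "background": 12,
}

DEFAULT_FAMILY_POOL = (
    "Asteraceae",
    "Fabaceae",
    "Lamiaceae",
    "Cistaceae",
    "Brassicaceae",
    "Apiaceae",
    "Malvaceae",
    "Papaveraceae",
)


@dataclass(frozen=True)
class CommunitySpec:
    """One study site: its fixed census duration and season calendar."""

    name: str
    census_duration_min: float
    season_start: _dt.date


#: Four coastal communities: two with an April-July season, two starting in
#: January on a drier island; census durations 3, 6, 7.5 and 7.5 minutes.
DEFAULT_COMMUNITIES = (
    CommunitySpec("SB", 3.0, _dt.date(2010, 4, 1)),
    CommunitySpec("CM", 6.0, _dt.date(2010, 4, 1)),
    CommunitySpec("CB", 7.5, _dt.date(2011, 1, 1)),
    CommunitySpec("LC", 7.5, _dt.date(2011, 1, 1)),
)


@dataclass
class SimConfig:
    """Full parameterization of a synthetic season.

    The defaults reproduce the reference study design: 4 communities x 4
    months, per-site census durations, biweekly density surveys, and a
    visitor community mixing the four extreme archetypes with background
    species.  ``seed`` fully determines the output.
    """

    communities: tuple[CommunitySpec, ...] = DEFAULT_COMMUNITIES
    n_months: int = 4
    n_plants: int = 12
    archetype_mix: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ARCHETYPE_MIX))
    archetypes: dict[str, ArchetypeSpec] = field(default_factory=lambda: dict(DEFAULT_ARCHETYPES))
    family_pool: tuple[str, ...] = DEFAULT_FAMILY_POOL
    functional_groups: tuple[str, ...] = DEFAULT_FUNCTIONAL_GROUPS
    density_meanlog: float = 3.0
    density_sdlog: float = 1.5
    display_flowers_mean: float = 25.0
    census_days_per_month: int = 4
    surveys_per_month: int = 2
    survey_area_m2: float = 7.5
    contacts_per_individual: int = 3
    min_plants_in_bloom: int = 4
    seed: int = 20160303

    def validate(self) -> None:
        if self.n_months < 1 or self.n_plants < 1:
            raise ValueError("n_months and n_plants must be positive")
        if self.census_days_per_month < 1 or self.surveys_per_month < 1:
            raise ValueError("census and survey counts must be positive")
        if self.survey_area_m2 <= 0:
            raise ValueError("survey_area_m2 must be positive")
        if self.contacts_per_individual < 1:
            raise ValueError("contacts_per_individual must be >= 1")
        for label in self.archetype_mix:
            if label not in self.archetypes:
                raise ValueError(f"archetype {label!r} has no ArchetypeSpec")
        if sum(self.archetype_mix.values()) < 1:
            raise ValueError("at least one visitor species required")

    @property
    def n_visitors(self) -> int:
        return sum(self.archetype_mix.values())

    @property
    def season_starts(self) -> dict[str, _dt.date]:
        return {c.name: c.season_start for c in self.communities}


@dataclass
class SimResult:
    """Generated tables plus the planted ground truth."""

    census: list[CensusRecord]
    surveys: list[FlowerSurvey]
    taxonomy: list[SpeciesInfo]
    truth: dict[str, str]  # visitor species -> archetype label


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def preference_weights(
    densities: np.ndarray, gamma: float, permitted: np.ndarray
) -> np.ndarray:
    """Normalized preference over blooming plants: w_i proportional to
    density_i ** gamma on the permitted set, 0 elsewhere.

    Plants with zero density receive zero weight for gamma > 0 and are
    excluded (treated as unavailable) for gamma <= 0.
    """
    densities = np.asarray(densities, dtype=float)
    w = np.zeros_like(densities)
    mask = permitted & (densities > 0)
    if mask.any():
        w[mask] = densities[mask] ** gamma
    total = w.sum()
    if total > 0:
        w /= total
    return w


def census_contact_counts(
    rng: np.random.Generator,
    densities: np.ndarray,
    permitted: np.ndarray,
    gamma: float,
    base_rate: float,
    duration_min: float,
    flowers_observed: np.ndarray,
) -> np.ndarray:
    """Poisson contact counts of one visitor over the plants of one census day."""
    w = preference_weights(densities, gamma, permitted)
    mean = base_rate * duration_min * np.asarray(flowers_observed, dtype=float) * w
    return rng.poisson(mean)


def _bloom_windows(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """(n_plants, n_months) boolean bloom calendar; every month must host at
    least ``min_plants_in_bloom`` species (drawn with bounded retries)."""
    for _ in range(200):
        windows = np.zeros((cfg.n_plants, cfg.n_months), dtype=bool)
        for i in range(cfg.n_plants):
            length = int(rng.integers(2, min(4, cfg.n_months) + 1))
            start = int(rng.integers(0, cfg.n_months - length + 1))
            windows[i, start : start + length] = True
        if (windows.sum(axis=0) >= cfg.min_plants_in_bloom).all():
            return windows
    raise ValueError(
        "could not satisfy the minimum-plants-in-bloom constraint; "
        "config is degenerate (too few plants or too many months)"
    )


def _survey_dates(start: _dt.date, month: int, k: int) -> list[_dt.date]:
    # biweekly: day 7 and 21 of each season month for k = 2
    base = _month_date(start, month)
    days = np.linspace(7, 21, k).round().astype(int)
    return [base.replace(day=int(d)) for d in days]


def _census_dates(start: _dt.date, month: int, k: int) -> list[_dt.date]:
    base = _month_date(start, month)
    days = np.linspace(3, 27, k).round().astype(int)
    return [base.replace(day=int(d)) for d in days]


def _month_date(start: _dt.date, month: int) -> _dt.date:
    m = start.month - 1 + (month - 1)
    return _dt.date(start.year + m // 12, m % 12 + 1, 1)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate census, survey and taxonomy tables for every community.

    Returns the tables together with the visitor -> archetype truth map.
    Identical configs (same seed) produce identical output.
    """
    cfg = config or SimConfig()
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    community_seeds = root.spawn(len(cfg.communities))

    census: list[CensusRecord] = []
    surveys: list[FlowerSurvey] = []
    taxonomy: list[SpeciesInfo] = []
    truth: dict[str, str] = {}

    for comm, seed in zip(cfg.communities, community_seeds):
        rng = np.random.default_rng(seed)
        plants = [f"{comm.name}_plant_{i+1:02d}" for i in range(cfg.n_plants)]
        families = [
            cfg.family_pool[int(rng.integers(0, len(cfg.family_pool)))] for _ in plants
        ]
        taxonomy += [SpeciesInfo(p, "plant", f) for p, f in zip(plants, families)]

        # latent per-species abundance scale and per-month realized density
        base_density = np.exp(
            rng.normal(cfg.density_meanlog, cfg.density_sdlog, size=cfg.n_plants)
        )
        windows = _bloom_windows(rng, cfg)
        # month-to-month wobble around the species scale, zero out of bloom
        wobble = np.exp(rng.normal(0.0, 0.25, size=(cfg.n_plants, cfg.n_months)))
        density = base_density[:, None] * wobble * windows

        display = np.maximum(
            1.0, rng.normal(cfg.display_flowers_mean, cfg.display_flowers_mean / 5, cfg.n_plants)
        )

        # visitors with planted archetypes
        visitors: list[tuple[str, ArchetypeSpec, np.ndarray]] = []
        counter = 0
        for label in ARCHETYPES:
            n = cfg.archetype_mix.get(label, 0)
            spec = cfg.archetypes[label]
            for _ in range(n):
                counter += 1
                name = f"{comm.name}_visitor_{counter:02d}_{label[:3]}"
                if spec.link_breadth is None or spec.link_breadth >= cfg.n_plants:
                    permitted = np.ones(cfg.n_plants, dtype=bool)
                else:
                    # hosts drawn preferentially among clearly abundant plants:
                    # narrow-diet species anchor on reliably common partners
                    # (and thereby clear the reliability filters)
                    p = base_density**3 / (base_density**3).sum()
                    hosts = rng.choice(
                        cfg.n_plants, size=spec.link_breadth, replace=False, p=p
                    )
                    permitted = np.zeros(cfg.n_plants, dtype=bool)
                    permitted[hosts] = True
                visitors.append((name, spec, permitted))
                truth[name] = label
        group_choices = [
            cfg.functional_groups[int(rng.integers(0, len(cfg.functional_groups)))]
            for _ in visitors
        ]
        taxonomy += [
            SpeciesInfo(name, "visitor", g) for (name, _, _), g in zip(visitors, group_choices)
        ]

        for month in range(1, cfg.n_months + 1):
            dens_m = density[:, month - 1]
            in_bloom = windows[:, month - 1]
            # biweekly density surveys over a fixed total plot area
            for sdate in _survey_dates(comm.season_start, month, cfg.surveys_per_month):
                for i, plant in enumerate(plants):
                    if not in_bloom[i]:
                        continue
                    n_open = int(rng.poisson(dens_m[i] * cfg.survey_area_m2))
                    surveys.append(
                        FlowerSurvey(
                            community=comm.name,
                            date=sdate,
                            month_index=month,
                            plant=plant,
                            open_flowers=n_open,
                            area_m2=cfg.survey_area_m2,
                        )
                    )
            # census days: every plant in bloom watched for the same time
            for cdate in _census_dates(comm.season_start, month, cfg.census_days_per_month):
                for i, plant in enumerate(plants):
                    if not in_bloom[i]:
                        continue
                    flowers = max(1, int(rng.poisson(display[i])))
                    any_visit = False
                    for name, spec, permitted in visitors:
                        w = preference_weights(dens_m, spec.gamma, permitted & in_bloom)
                        mean = spec.base_rate * comm.census_duration_min * flowers * w[i]
                        contacts = int(rng.poisson(mean))
                        if contacts > 0:
                            any_visit = True
                            census.append(
                                CensusRecord(
                                    community=comm.name,
                                    date=cdate,
                                    month_index=month,
                                    plant=plant,
                                    duration_min=comm.census_duration_min,
                                    flowers_observed=flowers,
                                    visitor=name,
                                    individuals=math.ceil(
                                        contacts / cfg.contacts_per_individual
                                    ),
                                    flowers_contacted=contacts,
                                )
                            )
                    if not any_visit:
                        census.append(
                            CensusRecord(
                                community=comm.name,
                                date=cdate,
                                month_index=month,
                                plant=plant,
                                duration_min=comm.census_duration_min,
                                flowers_observed=flowers,
                                visitor=NO_VISITOR,
                                individuals=0,
                                flowers_contacted=0,
                            )
                        )
    return SimResult(census=census, surveys=surveys, taxonomy=taxonomy, truth=truth)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def planted_truth_report(
    truth: dict[str, str], assignments: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate planted archetypes against recovered categories.

    ``assignments`` must have columns ``species`` and ``category`` (long
    format; one row per species-category membership).  Returns the confusion
    table (planted rows x recovered columns) and the recovery fraction: the
    share of planted extreme-archetype species whose recovered categories
    include the matching label.
    """
    if len(assignments) and not set(assignments["species"]) & set(truth):
        raise ValueError("recovered species set is disjoint from the planted truth")
    recovered: dict[str, set[str]] = {}
    for row in assignments.itertuples(index=False):
        recovered.setdefault(row.species, set()).add(row.category)

    categories = ("generalized", "specialized", "opportunistic", "selective")
    table = pd.DataFrame(
        0, index=list(ARCHETYPES), columns=[*categories, "none"], dtype=int
    )
    hits = 0
    total = 0
    for species, label in truth.items():
        cats = recovered.get(species, set())
        if cats:
            for c in cats:
                table.loc[label, c] += 1
        else:
            table.loc[label, "none"] += 1
        if label in categories:
            total += 1
            if label in cats:
                hits += 1
    fraction = hits / total if total else 0.0
    return table, fraction


def recovery_by_archetype(truth: dict[str, str], assignments: pd.DataFrame) -> dict[str, float]:
    """Per-archetype recovery fractions (extreme archetypes only)."""
    recovered: dict[str, set[str]] = {}
    for row in assignments.itertuples(index=False):
        recovered.setdefault(row.species, set()).add(row.category)
    out: dict[str, float] = {}
    for label in ("generalized", "specialized", "opportunistic", "selective"):
        planted = [s for s, a in truth.items() if a == label]
        if planted:
            out[label] = sum(label in recovered.get(s, set()) for s in planted) / len(planted)
    return out
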