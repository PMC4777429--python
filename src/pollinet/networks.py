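"""Flower-visitation-rate weighting and bipartite network assembly.

A quantitative network cell weights the contacts of visitor j on plant i by
the observation effort spent on that plant and by the plant's community-level
flower availability:

    FVR_ij = V_ij / E_i * D_i

where V_ij is the total number of flowers contacted over the period, E_i the
plant's flower-minutes of effort (sum over its censuses of flowers_observed
x duration), and D_i its mean flower density (flowers / m^2) over the
period's surveys.  Flower-minutes is the effort exposure under which the
rate is invariant to splitting one census into two back-to-back halves.

Plants are rows, visitors columns, throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    NO_VISITOR,
    AbundanceTable,
    CensusRecord,
    FlowerSurvey,
    InteractionNetwork,
)

logger = logging.getLogger("pollinet")

FvrMode = Literal["multiply", "divide", "none"]

SEASON = "season"


def period_label(period) -> str:
    """Canonical period string: ``"season"`` or ``"month:k"``."""
    if period == SEASON or period is None:
        return SEASON
    if isinstance(period, str):
        if period.startswith("month:"):
            return period
        return f"month:{int(period)}"
    return f"month:{int(period)}"


def period_months(period) -> set[int] | None:
    """Months covered by a period; ``None`` means the whole season."""
    label = period_label(period)
    if label == SEASON:
        return None
    return {int(label.split(":", 1)[1])}


@dataclass
class EffortSummary:
    """Per-plant observation effort within one community-period.

    ``minutes`` is total census time T_i, ``flowers`` total flowers observed
    F_i, ``flower_minutes`` the exposure E_i = sum(F_c * T_c) over censuses.
    """

    community: str
    period: str
    minutes: dict[str, float]
    flowers: dict[str, int]
    flower_minutes: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant": list(self.minutes),
                "minutes": [self.minutes[p] for p in self.minutes],
                "flowers": [self.flowers[p] for p in self.minutes],
                "flower_minutes": [self.flower_minutes[p] for p in self.minutes],
            }
        )


def compute_fvr(
    contacts: float,
    flowers_observed: float,
    minutes: float,
    density: float,
    mode: FvrMode = "multiply",
) -> float:
    """Flower visitation rate for a single census (or pooled exposure).

    ``multiply`` (default) scales the per-flower per-minute contact rate by
    flower availability; ``divide`` divides by it; ``none`` leaves the bare
    rate.
    """
    if flowers_observed <= 0 or minutes <= 0:
        if contacts > 0:
            raise ValueError(
                "positive contacts with zero observation effort is impossible"
            )
        return 0.0
    rate = contacts / (flowers_observed * minutes)
    if mode == "multiply":
        return rate * density
    if mode == "divide":
        return rate / density if density > 0 else 0.0
    if mode == "none":
        return rate
    raise ValueError(f"unknown FVR mode {mode!r}")


def _select(census: Iterable[CensusRecord], community: str, months: set[int] | None):
    for r in census:
        if r.community != community:
            continue
        if months is not None and r.month_index not in months:
            continue
        yield r


def effort_summary(
    census: Iterable[CensusRecord], community: str, period
) -> EffortSummary:
    """Aggregate per-plant effort, de-duplicating rows of the same census.

    Rows sharing (date, plant) describe one census event and repeat its
    duration and flower count; effort is counted once per event.
    """
    months = period_months(period)
    events: dict[tuple, tuple[float, int]] = {}
    for r in _select(census, community, months):
        key = (r.date, r.plant)
        ev = (r.duration_min, r.flowers_observed)
        if key in events and events[key] != ev:
            raise ValueError(
                f"census rows for {r.plant} on {r.date} disagree on effort fields"
            )
        events[key] = ev
    minutes: dict[str, float] = {}
    flowers: dict[str, int] = {}
    fmin: dict[str, float] = {}
    for (date, plant), (dur, fl) in sorted(events.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        minutes[plant] = minutes.get(plant, 0.0) + dur
        flowers[plant] = flowers.get(plant, 0) + fl
        fmin[plant] = fmin.get(plant, 0.0) + dur * fl
    return EffortSummary(
        community=community,
        period=period_label(period),
        minutes=minutes,
        flowers=flowers,
        flower_minutes=fmin,
    )


def mean_densities(
    surveys: Iterable[FlowerSurvey], community: str, period
) -> dict[str, float]:
    """Mean flower density per plant over the period's surveys."""
    months = period_months(period)
    acc: dict[str, list[float]] = {}
    for s in surveys:
        if s.community != community:
            continue
        if months is not None and s.month_index not in months:
            continue
        acc.setdefault(s.plant, []).append(s.density)
    return {p: float(np.mean(v)) for p, v in acc.items()}


def build_network(
    census: Sequence[CensusRecord],
    surveys: Sequence[FlowerSurvey],
    community: str,
    period,
    fvr_mode: FvrMode = "multiply",
) -> InteractionNetwork:
    """Assemble the quantitative network for one community and period.

    Aggregates contacts per plant-visitor pair, computes per-plant effort and
    mean density, weights cells as FVR, prunes interaction-free rows and
    columns, and retains the parallel raw contact-count matrix for d'.
    """
    months = period_months(period)
    effort = effort_summary(census, community, period)
    density = mean_densities(surveys, community, period)

    contacts: dict[tuple[str, str], int] = {}
    visited_plants: set[str] = set()
    for r in _select(census, community, months):
        if r.visitor == NO_VISITOR or r.flowers_contacted == 0:
            continue
        contacts[(r.plant, r.visitor)] = (
            contacts.get((r.plant, r.visitor), 0) + r.flowers_contacted
        )
        visited_plants.add(r.plant)

    missing = sorted(p for p in visited_plants if p not in density)
    if missing:
        raise ValueError(
            f"{community} {period_label(period)}: no flower-density survey for "
            f"censused plant(s) {missing}; density is required for FVR"
        )

    plants = sorted(visited_plants)
    visitors = sorted({v for (_, v) in contacts})
    raw = np.zeros((len(plants), len(visitors)))
    weights = np.zeros_like(raw)
    p_ix = {p: i for i, p in enumerate(plants)}
    v_ix = {v: j for j, v in enumerate(visitors)}
    for (p, v), c in contacts.items():
        i, j = p_ix[p], v_ix[v]
        raw[i, j] = c
        weights[i, j] = compute_fvr(
            c, effort.flower_minutes[p], 1.0, density[p], mode=fvr_mode
        )
    net = InteractionNetwork(
        community=community,
        period=period_label(period),
        plants=plants,
        visitors=visitors,
        weights=weights,
        raw=raw,
    ).prune()
    return net


def abundance_table(
    census: Sequence[CensusRecord],
    surveys: Sequence[FlowerSurvey],
    community: str,
    month: int,
) -> AbundanceTable:
    """Month-level abundances: mean flower density (plants) and total
    individuals observed visiting flowers (visitors)."""
    plants = mean_densities(surveys, community, month)
    visitors: dict[str, float] = {}
    for r in _select(census, community, {month}):
        if r.visitor == NO_VISITOR:
            continue
        visitors[r.visitor] = visitors.get(r.visitor, 0.0) + r.individuals
    return AbundanceTable(
        community=community, month_index=month, plants=plants, visitors=visitors
    )


def check_connected(net: InteractionNetwork) -> bool:
    """Warn (never fail) when the bipartite interaction graph is disconnected."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(("P", p) for p in net.plants)
    g.add_nodes_from(("V", v) for v in net.visitors)
    basis = net.basis
    for i, p in enumerate(net.plants):
        for j, v in enumerate(net.visitors):
            if basis[i, j] > 0:
                g.add_edge(("P", p), ("V", v))
    ok = g.number_of_nodes() > 0 and nx.is_connected(g)
    if not ok:
        logger.warning(
            "network %s %s is not connected", net.community, net.period
        )
    return ok
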