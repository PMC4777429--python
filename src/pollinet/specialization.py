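"""Species-level specialization: linkage level L and complementary d'.

L is a species' number of distinct interaction partners in the season
network.  d' standardizes the Kullback-Leibler divergence d between a
species' interaction proportions p'_ij = a_ij / A_i and partner availability
q_j:

    d = sum_{j : a_ij > 0} p'_ij * ln(p'_ij / q_j)        (nats)

    d' = (d - d_min) / (d_max - d_min), clamped to [0, 1]

In *marginal* mode q_j = A_j / m comes from the partner marginals of the raw
contact-count matrix and d_max = ln(m / A_i); in *external* mode q is an
independently measured abundance distribution and d_max = -ln(min_j q_j).
d_min is the smallest d attainable by any allocation of the species' A_i
integer interaction units across partners; it is found by largest-remainder
proportional apportionment followed by single-unit local-search moves (the
exhaustive enumeration serving as test oracle only).

d' is computed on raw integer contact counts by default since the d_min
allocation is integral; a continuous relaxation over FVR weights is
available via ``use_raw=False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, CensusRecord, InteractionNetwork, NO_VISITOR

logger = logging.getLogger("pollinet")

_EPS = 1e-12


# ---------------------------------------------------------------------------
# linkage level
# ---------------------------------------------------------------------------


def linkage_level(net: InteractionNetwork, species: str) -> int:
    """Number of partners with a positive interaction (scale-invariant)."""
    basis = net.basis
    if species in net.plants:
        row = basis[net.plants.index(species)]
        return int((row > 0).sum())
    if species in net.visitors:
        col = basis[:, net.visitors.index(species)]
        return int((col > 0).sum())
    raise KeyError(f"species {species!r} not in network {net.community} {net.period}")


# ---------------------------------------------------------------------------
# d' machinery
# ---------------------------------------------------------------------------


def kl_divergence(counts: np.ndarray, q: np.ndarray) -> float:
    """d = sum p ln(p/q) over cells with positive counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("species has no interactions (should have been pruned)")
    mask = counts > 0
    if (q[mask] <= 0).any():
        raise ValueError("positive interactions on a partner with zero availability")
    p = counts[mask] / total
    return float(np.sum(p * np.log(p / q[mask])))


def largest_remainder_allocation(total: int, q: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` units proportional to q."""
    q = np.asarray(q, dtype=float)
    target = total * q / q.sum()
    alloc = np.floor(target).astype(int)
    remainder = target - alloc
    short = total - alloc.sum()
    # hand the leftover units to the largest fractional remainders
    order = np.argsort(-remainder, kind="stable")
    alloc[order[:short]] += 1
    return alloc


def _alloc_d(alloc: np.ndarray, q: np.ndarray) -> float:
    total = alloc.sum()
    mask = alloc > 0
    p = alloc[mask] / total
    return float(np.sum(p * np.log(p / q[mask])))


def dmin_allocation(total: int, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimize d over integer allocations: apportionment + local search.

    Starting from the largest-remainder allocation, repeatedly applies the
    best single-unit move (one unit from one partner to another) while it
    lowers d; terminates because d strictly decreases.
    """
    if total < 1:
        raise ValueError("allocation total must be >= 1")
    q = np.asarray(q, dtype=float)
    if (q <= 0).any():
        raise ValueError("availability must be strictly positive everywhere")
    alloc = largest_remainder_allocation(total, q)
    best = _alloc_d(alloc, q)
    n = len(q)
    improved = True
    while improved:
        improved = False
        best_move = None
        for src in range(n):
            if alloc[src] == 0:
                continue
            for dst in range(n):
                if dst == src:
                    continue
                alloc[src] -= 1
                alloc[dst] += 1
                d = _alloc_d(alloc, q)
                alloc[src] += 1
                alloc[dst] -= 1
                if d < best - _EPS:
                    best = d
                    best_move = (src, dst)
        if best_move is not None:
            src, dst = best_move
            alloc[src] -= 1
            alloc[dst] += 1
            improved = True
    return alloc, best


@dataclass(frozen=True)
class DPrimeResult:
    d: float
    d_min: float
    d_max: float
    d_prime: float


def dprime_from_counts(
    counts: np.ndarray,
    q: np.ndarray,
    grand_total: float | None = None,
    external: bool = False,
) -> DPrimeResult:
    """d' for one species given its partner counts and availability q.

    ``grand_total`` (m) is required in marginal mode for d_max = ln(m / A_i);
    in external mode d_max = -ln(min q).  Degenerate case d_max <= d_min
    yields d' = 0.
    """
    counts = np.asarray(counts, dtype=float)
    q = np.asarray(q, dtype=float)
    total = counts.sum()
    d = kl_divergence(counts, q)
    if external:
        d_max = float(-np.log(q[q > 0].min()))
        q_alloc = q
    else:
        if grand_total is None:
            raise ValueError("grand_total (m) required in marginal mode")
        d_max = float(np.log(grand_total / total))
        q_alloc = q
    n_units = int(round(total))
    if n_units >= 1 and abs(total - n_units) < 1e-9:
        _, d_min = dmin_allocation(n_units, q_alloc)
    else:
        # non-integer totals (FVR weights): continuous relaxation, the
        # availability distribution itself is feasible, so d_min = 0
        d_min = 0.0
    d_min = min(d_min, d)  # numerical guard; observed d is itself feasible
    if d_max - d_min <= _EPS:
        d_prime = 0.0
    else:
        d_prime = (d - d_min) / (d_max - d_min)
    return DPrimeResult(d=d, d_min=d_min, d_max=d_max, d_prime=float(np.clip(d_prime, 0.0, 1.0)))


def dprime(
    net: InteractionNetwork,
    species: str,
    availability: AbundanceTable | None = None,
    use_raw: bool = True,
) -> DPrimeResult:
    """d' of one species in a network.

    With ``availability=None`` (marginal mode) q comes from the partner
    marginals of the matrix; with an :class:`AbundanceTable`, q is the
    external abundance distribution over the partner guild (external mode).
    """
    mat = net.raw if (use_raw and net.raw is not None) else net.weights
    if species in net.plants:
        vec = mat[net.plants.index(species)]
        partner_tot = mat.sum(axis=0)
        partner_guild = "visitor"
        partners = net.visitors
    elif species in net.visitors:
        vec = mat[:, net.visitors.index(species)]
        partner_tot = mat.sum(axis=1)
        partner_guild = "plant"
        partners = net.plants
    else:
        raise KeyError(f"species {species!r} not in network")
    m = mat.sum()
    if availability is None:
        q = partner_tot / m
        return dprime_from_counts(vec, q, grand_total=m, external=False)
    ab = availability.for_guild(partner_guild)
    missing = [p for p in partners if p not in ab]
    if missing:
        raise ValueError(f"partners missing from abundance table: {missing}")
    raw_q = np.array([ab[p] for p in partners], dtype=float)
    if ((raw_q <= 0) & (vec > 0)).any():
        raise ValueError(
            "zero-abundance partner carries positive interactions in external mode"
        )
    keep = raw_q > 0
    q = raw_q[keep] / raw_q[keep].sum()
    return dprime_from_counts(vec[keep], q, external=True)


def species_specialization(
    net: InteractionNetwork,
    availability: AbundanceTable | None = None,
    use_raw: bool = True,
) -> pd.DataFrame:
    """L and d' for every species of both guilds in one (season) network."""
    rows = []
    for guild, names in (("plant", net.plants), ("visitor", net.visitors)):
        for name in names:
            res = dprime(net, name, availability=availability, use_raw=use_raw)
            rows.append(
                {
                    "species": name,
                    "guild": guild,
                    "community": net.community,
                    "L": linkage_level(net, name),
                    "d": res.d,
                    "d_min": res.d_min,
                    "d_max": res.d_max,
                    "d_prime": res.d_prime,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reliability filters
# ---------------------------------------------------------------------------


def months_present(
    monthly_nets: Sequence[InteractionNetwork], species: str
) -> set[int]:
    """Months whose temporal network contains the species with interactions."""
    out = set()
    for net in monthly_nets:
        month = int(net.period.split(":", 1)[1])
        if species in net.plants or species in net.visitors:
            out.add(month)
    return out


def apply_filters(
    records: pd.DataFrame,
    census: Sequence[CensusRecord],
    monthly_nets: Sequence[InteractionNetwork],
    min_plant_minutes: float = 30.0,
    min_visitor_individuals: int = 5,
    min_months: int = 2,
) -> pd.DataFrame:
    """Drop unreliable species before ranking.

    Plants censused less than ``min_plant_minutes`` in total, visitors
    observed fewer than ``min_visitor_individuals`` times (season total of
    individuals), and species present in fewer than ``min_months`` temporal
    networks are excluded.  Boundaries are strict on the 'less than' side:
    exactly 30 min or exactly 5 individuals is retained.
    """
    from .networks import effort_summary

    if records.empty:
        return records.copy()
    out_rows = []
    for community, sub in records.groupby("community", sort=False):
        effort = effort_summary(census, community, "season")
        nets_c = [n for n in monthly_nets if n.community == community]
        indiv: dict[str, int] = {}
        for r in census:
            if r.community == community and r.visitor != NO_VISITOR:
                indiv[r.visitor] = indiv.get(r.visitor, 0) + r.individuals
        for row in sub.itertuples(index=False):
            if row.guild == "plant":
                if effort.minutes.get(row.species, 0.0) < min_plant_minutes:
                    continue
            else:
                if indiv.get(row.species, 0) < min_visitor_individuals:
                    continue
            if len(months_present(nets_c, row.species)) < min_months:
                continue
            out_rows.append(row._asdict())
    return pd.DataFrame(out_rows, columns=records.columns)


# ---------------------------------------------------------------------------
# extreme-species selection
# ---------------------------------------------------------------------------

CATEGORY_METRIC = {
    "generalized": ("L", "high"),
    "specialized": ("L", "low"),
    "opportunistic": ("d_prime", "low"),
    "selective": ("d_prime", "high"),
}


def _season_totals(net: InteractionNetwork) -> dict[str, float]:
    basis = net.basis
    totals = {p: float(t) for p, t in zip(net.plants, basis.sum(axis=1))}
    totals.update({v: float(t) for v, t in zip(net.visitors, basis.sum(axis=0))})
    return totals


def select_extremes(
    filtered: pd.DataFrame,
    season_net: InteractionNetwork,
    k: int = 5,
) -> pd.DataFrame:
    """Pick the k most extreme species per guild for each of the four
    categories in one community.

    Ties at the cutoff are broken by larger season interaction total, then
    lexicographic species name, so the selection is deterministic.  A species
    may appear in more than one category.  With fewer than k eligible species
    in a guild, all are taken with a warning.
    """
    if filtered.empty:
        raise ValueError("no eligible species to select from")
    totals = _season_totals(season_net)
    rows = []
    for guild, sub in filtered.groupby("guild", sort=False):
        if len(sub) < k:
            logger.warning(
                "%s: only %d eligible %s species (< %d); taking all",
                season_net.community,
                len(sub),
                guild,
                k,
            )
        for category, (metric, direction) in CATEGORY_METRIC.items():
            sign = -1.0 if direction == "high" else 1.0
            ranked = sorted(
                sub.itertuples(index=False),
                key=lambda r: (
                    sign * getattr(r, metric),
                    -totals.get(r.species, 0.0),
                    r.species,
                ),
            )
            for r in ranked[:k]:
                rows.append(
                    {
                        "species": r.species,
                        "guild": guild,
                        "community": season_net.community,
                        "category": category,
                        "metric": metric,
                        "value": getattr(r, metric),
                    }
                )
    return pd.DataFrame(rows)
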