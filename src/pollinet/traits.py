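"""Partner-profile traits: abundance evenness, rank abundance, functional
richness, and the cascading abundance-rank classifier.

The rank cascade assigns every species of one guild, in one community-month,
to an abundance rank from 5 (highly abundant) down to 1 (scarce).  At each
stage the most abundant remaining species anchors the rank and every species
above a stage-specific fraction of that maximum joins it: >80% for rank 5,
then >75%, >66%, >50% of the successive remaining maxima; whatever is left
is rank 1.  The stage maximum always qualifies for its own stage.

Pielou's evenness J' = H'/ln(S), with H' the Shannon entropy of the partner
abundance shares and S the number of partners; J' = 1 by convention for a
single partner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datamodel import AbundanceTable, InteractionNetwork, SpeciesInfo, taxonomy_map

logger = logging.getLogger("pollinet")

#: (rank, threshold) stages of the abundance cascade, applied in order.
RANK_STAGES = ((5, 0.80), (4, 0.75), (3, 0.66), (2, 0.50))


def rank_abundances(abundances: Mapping[str, float]) -> dict[str, int]:
    """Classify abundances into ranks 5..1 by the successive-maxima cascade.

    Deterministic and invariant to iteration order; every input species is
    ranked; the overall maximum always receives rank 5.
    """
    if not abundances:
        raise ValueError("empty abundance table")
    if any(a < 0 for a in abundances.values()):
        raise ValueError("negative abundance")
    remaining = dict(abundances)
    ranks: dict[str, int] = {}
    for rank, frac in RANK_STAGES:
        if not remaining:
            break
        m = max(remaining.values())
        stage = {s for s, a in remaining.items() if a > frac * m or a == m}
        for s in stage:
            ranks[s] = rank
            del remaining[s]
    for s in remaining:
        ranks[s] = 1
    return ranks


def pielou_evenness(abundances: Sequence[float]) -> float:
    """J' = H'/ln(S) over positive abundance shares; 1 for a single value."""
    a = np.asarray(list(abundances), dtype=float)
    if a.size == 0:
        raise ValueError("no abundances given")
    if (a < 0).any():
        raise ValueError("negative abundance")
    if a.size == 1:
        return 1.0
    total = a.sum()
    if total <= 0:
        raise ValueError("all abundances are zero")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / math.log(a.size)


def community_heterogeneity(table: AbundanceTable, guild: str = "plant") -> float:
    """Heterogeneity of abundances in a community-month: 1 - J' over all
    species of one guild.  0 for perfectly even communities; defined 0 (with
    a warning) for a single species.

    This complement-of-evenness summary is this package's reading of the
    community-level 'heterogeneity of abundances' descriptor; no closed
    formula for it is fixed by the study design.
    """
    ab = table.for_guild(guild)
    if len(ab) < 2:
        logger.warning(
            "%s month %d: single %s species; heterogeneity defined 0",
            table.community,
            table.month_index,
            guild,
        )
        return 0.0
    return 1.0 - pielou_evenness(list(ab.values()))


@dataclass(frozen=True)
class PartnerProfile:
    """Per focal species and month: the trio of partner traits."""

    species: str
    guild: str
    community: str
    month_index: int
    evenness: float
    mean_rank: float
    functional_richness: int
    n_partners: int


def partner_profile(
    net: InteractionNetwork,
    ranking: Mapping[str, int],
    abundances: AbundanceTable,
    taxonomy: Sequence[SpeciesInfo] | Mapping[tuple[str, str], str],
    species: str,
    weighted_rank: bool = False,
) -> PartnerProfile:
    """Partner traits of one focal species in one monthly network.

    Partners are the opposite-guild species with a positive interaction.
    Evenness is computed over the partners' *abundances* (flower density for
    plant partners, observed individuals for visitor partners), not over
    interaction weights.  ``mean_rank`` is the unweighted mean of partner
    ranks by default; ``weighted_rank`` weights ranks by interaction
    strength.
    """
    basis = net.basis
    if species in net.plants:
        guild, partner_guild = "plant", "visitor"
        vec = basis[net.plants.index(species)]
        partner_names = net.visitors
    elif species in net.visitors:
        guild, partner_guild = "visitor", "plant"
        vec = basis[:, net.visitors.index(species)]
        partner_names = net.plants
    else:
        raise KeyError(
            f"species {species!r} not in network {net.community} {net.period}"
        )
    tax = taxonomy if isinstance(taxonomy, Mapping) else taxonomy_map(taxonomy)
    partners = [p for p, w in zip(partner_names, vec) if w > 0]
    if not partners:
        raise ValueError(f"species {species!r} has no partners (pruning bug?)")
    ab = abundances.for_guild(partner_guild)
    missing = [p for p in partners if p not in ab]
    if missing:
        raise ValueError(f"partner(s) missing from abundance table: {missing}")
    missing = [p for p in partners if p not in ranking]
    if missing:
        raise ValueError(f"partner(s) missing from abundance ranking: {missing}")
    missing = [p for p in partners if (partner_guild, p) not in tax]
    if missing:
        raise ValueError(f"partner(s) missing from taxonomy: {missing}")

    evenness = pielou_evenness([ab[p] for p in partners])
    ranks = np.array([ranking[p] for p in partners], dtype=float)
    if weighted_rank:
        w = np.array([vec[partner_names.index(p)] for p in partners], dtype=float)
        mean_rank = float((ranks * w).sum() / w.sum())
    else:
        mean_rank = float(ranks.mean())
    richness = len({tax[(partner_guild, p)] for p in partners})
    return PartnerProfile(
        species=species,
        guild=guild,
        community=net.community,
        month_index=net.period_month(),
        evenness=evenness,
        mean_rank=mean_rank,
        functional_richness=richness,
        n_partners=len(partners),
    )
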