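import datetime as dt
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollinet.datamodel import AbundanceTable, CensusRecord, InteractionNetwork
from pollinet.specialization import (
    apply_filters,
    dmin_allocation,
    dprime,
    dprime_from_counts,
    kl_divergence,
    largest_remainder_allocation,
    linkage_level,
    select_extremes,
    species_specialization,
)


def compositions(total, k):
    """All ways to place `total` integer units into k cells (oracle helper)."""
    for cuts in itertools.combinations(range(total + k - 1), k - 1):
        alloc = []
        prev = -1
        for c in cuts:
            alloc.append(c - prev - 1)
            prev = c
        alloc.append(total + k - 2 - prev)
        yield np.array(alloc)


def dmin_exhaustive(total, q):
    """Brute-force minimum KL over every integer allocation."""
    best = math.inf
    for alloc in compositions(total, len(q)):
        mask = alloc > 0
        p = alloc[mask] / total
        d = float(np.sum(p * np.log(p / q[mask])))
        best = min(best, d)
    return best


def toy_network(raw):
    raw = np.asarray(raw, dtype=float)
    plants = [f"p{i}" for i in range(raw.shape[0])]
    visitors = [f"v{j}" for j in range(raw.shape[1])]
    return InteractionNetwork("X", "season", plants, visitors, raw.copy(), raw)


class TestLinkageLevel:
    def test_counts_positive_partners(self):
        net = toy_network([[0.2, 0.0, 0.1], [1.0, 1.0, 0.0]])
        assert linkage_level(net, "p0") == 2
        assert linkage_level(net, "v2") == 1

    def test_single_cell_network(self):
        net = toy_network([[3.0]])
        assert linkage_level(net, "p0") == 1
        assert linkage_level(net, "v0") == 1

    def test_scale_invariance(self):
        raw = np.array([[4.0, 0.0, 1.0], [0.0, 2.0, 2.0]])
        a, b = toy_network(raw), toy_network(raw * 17.5)
        assert all(
            linkage_level(a, s) == linkage_level(b, s) for s in ("p0", "p1", "v0")
        )

    def test_unknown_species_errors(self):
        with pytest.raises(KeyError):
            linkage_level(toy_network([[1.0]]), "nope")


class TestDPrime:
    def test_worked_two_by_two_example(self):
        # row 1 of [[9,1],[1,9]]: A=10, m=20, q=(1/2,1/2)
        net = toy_network([[9, 1], [1, 9]])
        res = dprime(net, "p0")
        d_hand = 0.9 * math.log(1.8) + 0.1 * math.log(0.2)
        assert res.d == pytest.approx(d_hand, abs=1e-12)
        # the (5,5) allocation matches q exactly, confirmed by brute force
        assert dmin_exhaustive(10, np.array([0.5, 0.5])) == pytest.approx(0.0, abs=1e-12)
        assert res.d_min == pytest.approx(0.0, abs=1e-12)
        assert res.d_max == pytest.approx(math.log(2), abs=1e-12)
        assert res.d_prime == pytest.approx(d_hand / math.log(2), abs=1e-12)

    def test_allocation_matching_availability_gives_zero(self):
        # row equal to availability shares: the opportunistic limit
        net = toy_network([[6, 3, 1], [6, 3, 1]])
        res = dprime(net, "p0")
        assert res.d == pytest.approx(0.0, abs=1e-12)
        assert res.d_prime == 0.0

    def test_single_cell_network_is_degenerate_zero(self):
        res = dprime(toy_network([[7]]), "p0")
        assert res.d == 0.0 and res.d_max == 0.0 and res.d_prime == 0.0

    def test_sole_user_of_exclusive_partner_reaches_one(self):
        # block-diagonal [[A,0],[0,B]]: row 0 attains d = d_max
        for a, b in ((3, 5), (1, 9), (6, 6)):
            res = dprime(toy_network([[a, 0], [0, b]]), "p0")
            assert res.d == pytest.approx(res.d_max, abs=1e-12)
            if res.d_min < res.d_max:
                assert res.d_prime == pytest.approx(1.0)

    def test_partner_permutation_invariance(self, rng):
        raw = rng.integers(0, 8, size=(4, 5)).astype(float)
        raw[0] += 1  # keep the focal row alive
        net = toy_network(raw)
        base = dprime(net, "p0")
        for _ in range(5):
            perm = rng.permutation(5)
            net_p = toy_network(raw[:, perm])
            res = dprime(net_p, "p0")
            assert res.d == pytest.approx(base.d, abs=1e-10)
            assert res.d_prime == pytest.approx(base.d_prime, abs=1e-10)

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(300):
            shape = (rng.integers(1, 5), rng.integers(1, 5))
            raw = rng.integers(0, 6, size=shape).astype(float)
            if raw.sum() == 0:
                continue
            net = toy_network(raw).prune()
            for sp in net.plants + net.visitors:
                res = dprime(net, sp)
                assert 0.0 <= res.d_prime <= 1.0
                assert res.d_min - 1e-9 <= res.d <= res.d_max + 1e-9

    def test_proportional_additions_never_increase_divergence(self, rng):
        # piling further interactions on in proportion to availability pulls
        # the use distribution toward q, so d cannot rise
        for _ in range(100):
            k = int(rng.integers(2, 6))
            q = rng.dirichlet(np.ones(k))
            counts = rng.integers(0, 9, size=k).astype(float)
            if counts.sum() == 0:
                counts[0] = 1
            d0 = kl_divergence(counts, q)
            d1 = kl_divergence(counts + counts.sum() * q, q)
            assert d1 <= d0 + 1e-9

    def test_external_availability_mode(self):
        net = toy_network([[9, 1], [1, 9]])
        ab = AbundanceTable("X", 1, plants={}, visitors={"v0": 2.0, "v1": 2.0})
        res = dprime(net, "p0", availability=ab)
        d_hand = 0.9 * math.log(1.8) + 0.1 * math.log(0.2)
        assert res.d == pytest.approx(d_hand, abs=1e-12)
        assert res.d_max == pytest.approx(-math.log(0.5), abs=1e-12)

    def test_external_mode_zero_abundance_partner_with_contacts_errors(self):
        net = toy_network([[9, 1], [1, 9]])
        ab = AbundanceTable("X", 1, plants={}, visitors={"v0": 2.0, "v1": 0.0})
        with pytest.raises(ValueError, match="zero-abundance"):
            dprime(net, "p0", availability=ab)


class TestDminSearch:
    def test_matches_exhaustive_enumeration(self, rng):
        # the apportionment + local-search heuristic must agree exactly with
        # brute force over every allocation
        for _ in range(220):
            k = int(rng.integers(2, 6))
            total = int(rng.integers(1, 13))
            q = rng.dirichlet(np.ones(k))
            _, d_heur = dmin_allocation(total, q)
            d_true = dmin_exhaustive(total, q)
            assert d_heur == pytest.approx(d_true, abs=1e-9)

    def test_largest_remainder_conserves_total(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 8))
            total = int(rng.integers(1, 50))
            q = rng.dirichlet(np.ones(k))
            alloc = largest_remainder_allocation(total, q)
            assert alloc.sum() == total
            assert (alloc >= 0).all()

    @given(st.integers(1, 12), st.integers(2, 5), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_heuristic_never_beaten_by_random_allocations(self, total, k, seed):
        rng = np.random.default_rng(seed)
        q = rng.dirichlet(np.ones(k))
        _, d_heur = dmin_allocation(total, q)
        for _ in range(20):
            alloc = rng.multinomial(total, rng.dirichlet(np.ones(k)))
            mask = alloc > 0
            p = alloc[mask] / total
            d = float(np.sum(p * np.log(p / q[mask])))
            assert d_heur <= d + 1e-9


def _census(plant="P", visitor="V", month=1, day=5, duration=10.0, individuals=1, contacts=2):
    return CensusRecord(
        community="X",
        date=dt.date(2011, month, day),
        month_index=month,
        plant=plant,
        duration_min=duration,
        flowers_observed=10,
        visitor=visitor,
        individuals=individuals,
        flowers_contacted=contacts,
    )


class TestReliabilityFilters:
    def _records(self):
        return pd.DataFrame(
            {
                "species": ["P", "Q", "V", "W"],
                "guild": ["plant", "plant", "visitor", "visitor"],
                "community": ["X"] * 4,
                "L": [2, 2, 2, 2],
                "d": [0.1] * 4,
                "d_min": [0.0] * 4,
                "d_max": [1.0] * 4,
                "d_prime": [0.1] * 4,
            }
        )

    def _monthly(self, months=(1, 3)):
        nets = []
        for m in months:
            nets.append(
                InteractionNetwork(
                    "X", f"month:{m}", ["P", "Q"], ["V", "W"],
                    np.ones((2, 2)), np.ones((2, 2)),
                )
            )
        return nets

    def test_plant_below_thirty_minutes_excluded(self):
        census = [
            _census(plant="P", month=1, duration=25.0),
            _census(plant="Q", month=1, duration=15.0),
            _census(plant="Q", month=3, day=6, duration=15.0),
            _census(plant="P", month=3, day=6, duration=4.0, visitor="W"),
            _census(plant="Q", month=3, day=7, visitor="W", duration=5.0),
        ]
        out = apply_filters(self._records(), census, self._monthly())
        plants = set(out[out.guild == "plant"]["species"])
        assert plants == {"Q"}  # P totals 29 min, Q exactly 30 (inclusive)

    def test_visitor_boundaries(self):
        census = [
            _census(plant="P", month=1, duration=30.0, visitor="V", individuals=5),
            _census(plant="P", month=3, day=6, duration=30.0, visitor="W", individuals=4),
            _census(plant="Q", month=1, duration=30.0, visitor="X2", individuals=1),
            _census(plant="Q", month=3, day=6, duration=30.0),
        ]
        out = apply_filters(self._records(), census, self._monthly())
        visitors = set(out[out.guild == "visitor"]["species"])
        assert "V" in visitors  # exactly five individuals, months {1,3}
        assert "W" not in visitors  # four individuals: below threshold

    def test_species_in_single_monthly_network_excluded(self):
        census = [
            _census(plant="P", month=1, duration=40.0, visitor="V", individuals=6),
            _census(plant="Q", month=1, duration=40.0, visitor="W", individuals=6),
        ]
        only_month_one = [
            InteractionNetwork(
                "X", "month:1", ["P", "Q"], ["V"], np.ones((2, 1)), np.ones((2, 1))
            )
        ]
        out = apply_filters(self._records(), census, only_month_one)
        assert out.empty  # nothing appears in two temporal networks


class TestSelectExtremes:
    def _table(self, L_values, names=None):
        n = len(L_values)
        names = names or [f"s{i}" for i in range(n)]
        return pd.DataFrame(
            {
                "species": names,
                "guild": ["plant"] * n,
                "community": ["X"] * n,
                "L": L_values,
                "d": [0.5] * n,
                "d_min": [0.0] * n,
                "d_max": [1.0] * n,
                "d_prime": np.linspace(0.1, 0.9, n),
            }
        )

    def _season(self, names, totals):
        raw = np.array(totals, dtype=float).reshape(-1, 1)
        return InteractionNetwork("X", "season", list(names), ["v0"], raw, raw)

    def test_generalized_are_the_five_largest_L(self):
        table = self._table([1, 2, 3, 4, 5, 6, 7, 8])
        net = self._season(table.species, [1] * 8)
        out = select_extremes(table, net)
        gen = set(out[out.category == "generalized"]["species"])
        assert gen == {"s3", "s4", "s5", "s6", "s7"}

    def test_tie_broken_by_interaction_total_then_name(self):
        table = self._table([5, 5, 5, 5, 5, 5])
        net = self._season(table.species, [10, 9, 8, 7, 6, 6])
        out = select_extremes(table, net)
        gen = set(out[out.category == "generalized"]["species"])
        # s4 and s5 tie on L and total; lexicographic name favours s4
        assert gen == {"s0", "s1", "s2", "s3", "s4"}

    def test_fewer_than_five_takes_all_with_warning(self, caplog):
        import logging

        table = self._table([1, 2, 3])
        net = self._season(table.species, [1, 1, 1])
        with caplog.at_level(logging.WARNING, logger="pollinet"):
            out = select_extremes(table, net, k=5)
        assert len(out[out.category == "generalized"]) == 3
        assert any("taking all" in m for m in caplog.messages)

    def test_empty_eligible_set_errors(self):
        with pytest.raises(ValueError):
            select_extremes(self._table([])[0:0], self._season([], []), k=5)

    def test_species_may_hold_two_categories(self):
        table = self._table([8, 7, 6, 5, 4, 3, 2, 1])
        net = self._season(table.species, [1] * 8)
        out = select_extremes(table, net)
        memberships = out.groupby("species")["category"].nunique()
        assert (memberships >= 1).all() and memberships.max() >= 2


class TestSpeciesTable:
    def test_every_species_scored(self):
        net = toy_network([[3, 1, 0], [0, 2, 5]])
        table = species_specialization(net)
        assert len(table) == 5
        assert set(table.guild) == {"plant", "visitor"}
        assert ((table.d_prime >= 0) & (table.d_prime <= 1)).all()
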