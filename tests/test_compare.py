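import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollinet.compare import (
    ComparisonSpec,
    compare_categories,
    compare_months,
    permutation_compare,
    significance_letters,
    single_step_adjust,
)


def make_profiles(rng, n_per=16, shift=0.0, months=(1, 2, 3, 4), value="trait_x"):
    rows = []
    for cat, sh in (("alpha", 0.0), ("beta", shift)):
        comm = rng.integers(0, 4, n_per)
        month = rng.choice(months, n_per)
        rows.append(
            pd.DataFrame(
                {
                    value: sh + rng.normal(0, 1, n_per),
                    "category": cat,
                    "community": [f"c{i}" for i in comm],
                    "month": month,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCompareCategories:
    def test_constant_response_gives_null_result(self, rng):
        df = make_profiles(rng)
        df["trait_x"] = 3.0
        res = compare_categories(df, ComparisonSpec(trait="trait_x"))
        assert res[0].estimate == pytest.approx(0.0, abs=1e-10)
        assert res[0].p_adj == pytest.approx(1.0)

    def test_planted_difference_detected_with_right_sign(self, rng):
        df = make_profiles(rng, n_per=40, shift=2.0)
        res = compare_categories(df, ComparisonSpec(trait="trait_x"))
        assert res[0].contrast == "beta - alpha"
        assert res[0].estimate > 1.0
        assert res[0].p_adj < 0.001

    def test_log_transform_requires_positive_values(self, rng):
        df = make_profiles(rng)
        with pytest.raises(ValueError, match="positive"):
            compare_categories(df, ComparisonSpec(trait="trait_x", transform="log"))

    def test_single_category_rejected(self, rng):
        df = make_profiles(rng)
        df = df[df.category == "alpha"]
        with pytest.raises(ValueError):
            compare_categories(df, ComparisonSpec(trait="trait_x"))

    def test_adjusted_never_below_raw(self, rng):
        for _ in range(10):
            df = make_profiles(rng)
            df["category"] = rng.choice(["a", "b", "c"], len(df))
            res = compare_categories(df, ComparisonSpec(trait="trait_x"))
            for r in res:
                assert r.p_adj >= r.p - 1e-12


class TestSingleStepAdjust:
    def test_family_of_one_equals_raw_two_sided_p(self):
        z = np.array([1.96])
        out = single_step_adjust(z, np.array([[1.0]]))
        assert out[0] == pytest.approx(2 * stats.norm.sf(1.96))

    def test_monotone_in_raw_p_within_family(self, rng):
        z = rng.normal(0, 2, size=5)
        cov = np.eye(5) * 0.5 + 0.5
        out = single_step_adjust(z, cov)
        order = np.argsort(np.abs(z))
        assert (np.diff(out[order]) <= 1e-12).all()

    def test_independent_family_matches_sidak(self):
        # with an identity correlation the max-|Z| adjustment is the Sidak
        # correction, a closed form we can check against
        z = np.array([2.0, 1.0, 2.5])
        out = single_step_adjust(z, np.eye(3), n_samples=400_000, seed=7)
        raw = 2 * stats.norm.sf(np.abs(z))
        sidak = 1 - (1 - raw) ** 3
        assert np.allclose(out, sidak, atol=0.01)


class TestCompareMonths:
    def test_identical_distributions_share_one_letter(self, rng):
        df = make_profiles(rng, n_per=40)
        res, letters = compare_months(df, ComparisonSpec(trait="trait_x", factor="month"))
        assert len(set(letters.values())) == 1

    def test_shifted_month_gets_distinct_letter(self, rng):
        df = make_profiles(rng, n_per=60)
        df.loc[df.month == 3, "trait_x"] += 8.0
        res, letters = compare_months(df, ComparisonSpec(trait="trait_x", factor="month"))
        assert letters[3] != letters[1]
        assert set(letters[3]) & set(letters[1]) == set()
        assert letters[1] == letters[2] == letters[4]

    def test_two_months_adjusted_equals_raw(self, rng):
        df = make_profiles(rng, months=(1, 2))
        res, letters = compare_months(df, ComparisonSpec(trait="trait_x", factor="month"))
        assert len(res) == 1
        assert res[0].p_adj == pytest.approx(res[0].p)

    def test_singleton_month_dropped_with_warning(self, rng, caplog):
        import logging

        df = make_profiles(rng, n_per=30)
        extra = df.iloc[[0]].copy()
        extra["month"] = 9
        df = pd.concat([df, extra], ignore_index=True)
        with caplog.at_level(logging.WARNING, logger="pollinet"):
            res, letters = compare_months(df, ComparisonSpec(trait="trait_x", factor="month"))
        assert 9 not in letters
        assert any("single observation" in m for m in caplog.messages)


class TestSignificanceLetters:
    def test_no_differences_single_group(self):
        letters = significance_letters([1, 2, 3], {})
        assert set(letters.values()) == {"a"}

    def test_one_outlier_level(self):
        pairs = {
            frozenset({1, 3}): True,
            frozenset({2, 3}): True,
            frozenset({1, 2}): False,
        }
        letters = significance_letters([1, 2, 3], pairs)
        assert letters[1] == letters[2]
        assert set(letters[3]) & set(letters[1]) == set()

    def test_chain_structure(self):
        # 1 ~ 2, 2 ~ 3, but 1 != 3: middle level shares with both
        pairs = {frozenset({1, 3}): True}
        letters = significance_letters([1, 2, 3], pairs)
        assert set(letters[2]) & set(letters[1])
        assert set(letters[2]) & set(letters[3])
        assert set(letters[1]) & set(letters[3]) == set()


class TestPermutationCompare:
    def test_extreme_difference_reaches_the_floor(self, rng):
        # a difference no within-stratum relabelling can reproduce: p is
        # pinned near the 1/(n_perm+1) floor of the permutation formula
        rows = []
        for s in range(12):
            rows.append({"trait_x": 0.0 + 0.01 * s, "category": "alpha",
                         "community": f"c{s % 4}", "month": s % 4 + 1})
            rows.append({"trait_x": 50.0 + 0.01 * s, "category": "beta",
                         "community": f"c{s % 4}", "month": s % 4 + 1})
        df = pd.DataFrame(rows)
        res = permutation_compare(df, ComparisonSpec(trait="trait_x"), n_perm=999, seed=3)
        assert res[0].p >= 1 / 1000
        assert res[0].p <= 5 / 1000

    def test_seed_determinism(self, rng):
        df = make_profiles(rng, shift=0.7)
        a = permutation_compare(df, ComparisonSpec(trait="trait_x"), n_perm=199, seed=11)
        b = permutation_compare(df, ComparisonSpec(trait="trait_x"), n_perm=199, seed=11)
        assert a[0].p == b[0].p

    def test_null_p_values_roughly_uniform(self, rng):
        ps = []
        for _ in range(120):
            df = make_profiles(rng, n_per=10)
            ps.append(
                permutation_compare(df, ComparisonSpec(trait="trait_x"), n_perm=99, seed=5)[0].p
            )
        assert 0.4 < np.mean(ps) < 0.6

    def test_minimum_permutation_count_enforced(self, rng):
        df = make_profiles(rng)
        with pytest.raises(ValueError):
            permutation_compare(df, ComparisonSpec(trait="trait_x"), n_perm=50)
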