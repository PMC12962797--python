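"""Hill numbers, coverage, standardization, FD and bootstrap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabeta.hill import (AbundanceVector, TraitDistanceMatrix,
                           augmented_probabilities, bootstrap_estimate,
                           coverage_profile, expected_hill,
                           functional_hill_number, gower_distance, hill_number,
                           sample_coverage, size_for_coverage,
                           standardize_to_coverage)

# ---------------------------------------------------------------- oracles


def coverage_oracle(x, m):
    """Exhaustive-enumeration coverage at subsample size m (n <= 12).

    The coverage of a size-m subsample is defined through the next draw:
    1 - P(the (m+1)-th individual drawn without replacement belongs to a
    species absent from the first m).  Enumerates all C(n, m) subsamples
    of the n individual specimens.
    """
    individuals = [s for s, c in enumerate(x) for _ in range(c)]
    n = len(individuals)
    total = 0.0
    count = 0
    for sub in itertools.combinations(range(n), m):
        seen = {individuals[i] for i in sub}
        rest = [individuals[i] for i in range(n) if i not in set(sub)]
        p_new = sum(1 for s in rest if s not in seen) / (n - m)
        total += 1 - p_new
        count += 1
    return total / count


def richness_oracle(x, m):
    """Expected richness of a hypergeometric size-m subsample (n <= 12)."""
    individuals = [s for s, c in enumerate(x) for _ in range(c)]
    n = len(individuals)
    vals = [len({individuals[i] for i in sub})
            for sub in itertools.combinations(range(n), m)]
    return float(np.mean(vals))


# ---------------------------------------------------------------- hill_number

@pytest.mark.parametrize("counts,q,expected", [
    ((5, 3, 2), 0, 3.0),                      # richness
    ((8, 2), 2, 1 / (0.8 ** 2 + 0.2 ** 2)),   # inverse Simpson
    ((4, 4, 4, 4), 0, 4.0),                   # equal abundances -> S at any q
    ((4, 4, 4, 4), 1, 4.0),
    ((4, 4, 4, 4), 2, 4.0),
    ((10,), 1, 1.0),
])
def test_hill_number_values(counts, q, expected):
    assert hill_number(np.array(counts), q) == pytest.approx(expected)


def test_hill_number_rejects_empty():
    with pytest.raises(ValueError):
        hill_number(np.zeros(3, dtype=int), 0)


@given(st.lists(st.integers(0, 40), min_size=2, max_size=30).filter(
    lambda c: sum(c) > 0))
@settings(max_examples=60, deadline=None)
def test_hill_nonincreasing_in_q(counts):
    """Diversity profiles decline (weakly) with the order q."""
    x = np.array(counts)
    vals = [hill_number(x, q) for q in (0, 0.5, 1, 1.5, 2)]
    assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))
    assert 1 - 1e-9 <= vals[-1] <= (x > 0).sum() + 1e-9


# ------------------------------------------------------------- coverage

@pytest.mark.parametrize("counts,expected", [
    ((2, 2, 2), 1.0),              # no singletons
    ((1, 1, 1, 1), 0.0),           # all singletons, no doubletons
    ((5, 3, 1, 1), 1 - (2 / 10) * (9 * 2 / (9 * 2 + 0))),
])
def test_sample_coverage_formula(counts, expected):
    assert sample_coverage(np.array(counts)) == pytest.approx(expected)


@pytest.mark.parametrize("counts", [
    (5, 5), (3, 2, 1), (1, 1, 2, 4), (6, 1, 1, 1), (2, 2, 2, 2, 2)])
def test_coverage_profile_matches_enumeration_oracle(counts):
    """Rarefied coverage equals the exhaustive subsample enumeration."""
    x = np.array(counts)
    n = x.sum()
    for m in range(1, n):
        assert coverage_profile(x, m) == pytest.approx(
            coverage_oracle(tuple(counts), m), abs=1e-12)


def test_coverage_profile_frozen_oracle_value():
    # counts (5,5), m=1: enumeration gives 4/9
    assert coverage_profile(np.array([5, 5]), 1) == pytest.approx(4 / 9)


def test_coverage_profile_reference_point_and_monotone():
    x = np.array([9, 4, 3, 2, 1, 1, 1])
    n = x.sum()
    assert coverage_profile(x, n) == pytest.approx(sample_coverage(x))
    grid = np.linspace(1, 2 * n, 60)
    vals = [coverage_profile(x, m) for m in grid]
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


def test_coverage_profile_rejects_bad_m():
    with pytest.raises(ValueError):
        coverage_profile(np.array([3, 2]), 0)


# ------------------------------------------------- rarefaction/extrapolation

@pytest.mark.parametrize("counts", [(3, 2, 1), (1, 1, 2, 4), (5, 5, 2)])
def test_expected_richness_matches_enumeration(counts):
    x = np.array(counts)
    for m in range(1, x.sum() + 1):
        assert expected_hill(x, 0, m) == pytest.approx(
            richness_oracle(tuple(counts), m), abs=1e-10)


@pytest.mark.parametrize("q", [0, 1, 2])
def test_expected_hill_at_reference_equals_observed(q):
    x = np.array([12, 5, 3, 1, 1, 2, 7])
    assert expected_hill(x, q, x.sum()) == pytest.approx(hill_number(x, q))


@pytest.mark.parametrize("q", [0, 1, 2])
def test_expected_hill_monotone_in_m(q):
    x = np.array([20, 9, 4, 3, 2, 1, 1, 1, 1])
    grid = np.linspace(1, 2 * x.sum(), 40)
    vals = [expected_hill(x, q, m) for m in grid]
    assert all(a <= b + 1e-8 for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------- standardization

def test_standardize_fixed_point():
    """Standardizing to the observed coverage reproduces observed diversity."""
    x = np.array([12, 5, 3, 1, 1, 2])
    c = sample_coverage(x)
    for q in (0, 1, 2):
        est = standardize_to_coverage(x, c, q)
        assert est.value == pytest.approx(hill_number(x, q), rel=1e-6)
        assert est.m_star == pytest.approx(x.sum(), abs=1e-3)


def test_standardize_complete_census_richness():
    """With no singletons, q=0 tends to observed richness as C -> 1."""
    x = np.array([4, 3, 2, 2])  # f1 = 0: census-like sample
    vals = [standardize_to_coverage(x, c, 0).value
            for c in (0.99, 0.999, 0.9999)]
    assert vals == sorted(vals)
    assert vals[-1] == pytest.approx(4.0, abs=1e-3)


def test_standardize_unreachable_flagged():
    x = np.array([1, 1, 1, 1, 1])
    with pytest.warns(UserWarning, match="unreachable"):
        est = standardize_to_coverage(x, 0.999, 0)
    assert "coverage_unreachable" in est.flags
    assert est.m_star == pytest.approx(2 * x.sum())


def test_thinning_consistency_two_depths(rng):
    """The same community sampled at two depths agrees once standardized."""
    p = rng.dirichlet(np.ones(60) * 0.4)
    deep = rng.multinomial(4000, p)
    shallow = rng.multinomial(800, p)
    target = 0.93
    for q in (0, 1, 2):
        a = standardize_to_coverage(deep[deep > 0], target, q).value
        b = standardize_to_coverage(shallow[shallow > 0], target, q).value
        se, _, _ = bootstrap_estimate(
            shallow[shallow > 0],
            lambda y: standardize_to_coverage(y[y > 0], target, q).value,
            B=60, rng=np.random.default_rng(1))
        assert abs(a - b) < 3 * se + 0.05 * a


# ----------------------------------------------------------------- FD

def test_functional_hill_two_species_half_tau():
    D = np.array([[0.0, 0.5], [0.5, 0.0]])
    fd = functional_hill_number(np.array([1, 1]), D, 0, tau=1.0)
    assert fd == pytest.approx(4 / 3)


def test_functional_hill_reduces_to_taxonomic():
    x = np.array([5, 3, 2, 1])
    D = np.ones((4, 4)) - np.eye(4)  # all distances at tau
    for q in (0, 1, 2):
        assert functional_hill_number(x, D, q, tau=1.0) == pytest.approx(
            hill_number(x, q))


def test_functional_hill_single_group():
    x = np.array([5, 3, 2])
    D = np.zeros((3, 3))
    for q in (0, 1, 2):
        assert functional_hill_number(x, D, q, tau=0.5) == pytest.approx(1.0)


def test_functional_hill_missing_species_rejected():
    tr = pd.DataFrame({"t": [0.0, 1.0]}, index=["a", "b"])
    D = gower_distance(tr)
    v = AbundanceVector(np.array([1, 1, 1]), species=("a", "b", "c"))
    with pytest.raises(KeyError):
        functional_hill_number(v, D, 0)


# ----------------------------------------------------------------- Gower

def test_gower_identical_and_fully_distinct():
    tr = pd.DataFrame({"num": [1.0, 1.0, 11.0], "cat": ["x", "x", "y"]},
                      index=["a", "b", "c"])
    D = gower_distance(tr).distances
    assert D.loc["a", "b"] == 0.0
    assert D.loc["a", "c"] == pytest.approx(1.0)  # range-normalized 10/10, mismatch


def test_gower_categorical_only_mismatch_is_one():
    tr = pd.DataFrame({"g1": ["x", "y"], "g2": ["u", "v"]}, index=["a", "b"])
    assert gower_distance(tr).distances.loc["a", "b"] == pytest.approx(1.0)


def test_gower_numeric_range_normalization():
    tr = pd.DataFrame({"t": [0.0, 10.0, 5.0]}, index=["a", "b", "c"])
    D = gower_distance(tr)
    assert D.distances.loc["a", "b"] == pytest.approx(1.0)
    assert D.distances.loc["a", "c"] == pytest.approx(0.5)
    # dmean default tau
    off = D.distances.to_numpy()[~np.eye(3, dtype=bool)]
    assert D.tau == pytest.approx(off.mean())


def test_gower_all_missing_row_rejected():
    tr = pd.DataFrame({"t": [1.0, np.nan]}, index=["a", "b"])
    with pytest.raises(ValueError):
        gower_distance(tr)


# ----------------------------------------------------------------- bootstrap

def test_bootstrap_total_count_invariant(rng):
    x = np.array([8, 3, 1, 1, 2])
    se, (lo, hi), reps = bootstrap_estimate(x, lambda y: y.sum(), B=50, rng=rng)
    assert se == 0.0
    assert lo == hi == x.sum()


def test_bootstrap_no_singletons_plain_multinomial():
    x = np.array([5, 4, 3])
    p = augmented_probabilities(x)
    assert p.size == 3
    assert p == pytest.approx(x / x.sum())


def test_bootstrap_richness_positive_and_reproducible():
    x = np.array([1, 1, 1, 1, 6])
    se1, ci1, _ = bootstrap_estimate(x, lambda y: (y > 0).sum(), B=100,
                                     rng=np.random.default_rng(5))
    se2, ci2, _ = bootstrap_estimate(x, lambda y: (y > 0).sum(), B=100,
                                     rng=np.random.default_rng(5))
    assert se1 > 0
    assert se1 == se2 and ci1 == ci2


def test_bootstrap_ci_width_stable_across_seeds():
    """CI width varies by < 10% across seeds at B = 2000."""
    x = np.array([20, 11, 7, 5, 3, 2, 2, 1, 1, 1, 1])
    widths = []
    for seed in (1, 2, 3):
        _, (lo, hi), _ = bootstrap_estimate(
            x, lambda y: hill_number(y[y > 0], 1), B=2000,
            rng=np.random.default_rng(seed))
        widths.append(hi - lo)
    assert (max(widths) - min(widths)) / np.mean(widths) < 0.10


def test_abundance_vector_frequency_counts():
    v = AbundanceVector(np.array([3, 1, 1, 2, 0]))
    assert v.n == 7 and v.s_obs == 4
    assert v.f1 == 2 and v.f2 == 1
    assert sum(k * v.f(k) for k in range(1, 8)) == v.n
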