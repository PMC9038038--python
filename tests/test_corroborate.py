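import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from biotpscreen.corroborate import (
    ComparisonRejected,
    InsufficientData,
    dose_gradient_check,
    fish_fraction,
    group_rsd,
    link_cross_dataset,
    spearman_rs,
    spectral_similarity,
)
from biotpscreen.feature_model import Spectrum

from conftest import make_sheet


# ---------------------------------------------------------------- spearman

def test_perfect_monotone():
    rs, p = spearman_rs([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert rs == pytest.approx(1.0)
    assert p == pytest.approx(2 / math.factorial(5))


def test_perfect_reverse():
    rs, _ = spearman_rs([1, 2, 3, 4], [4, 3, 2, 1])
    assert rs == pytest.approx(-1.0)


def test_exact_p_small_n():
    rs, p = spearman_rs([1, 2, 3], [1, 2, 3])
    assert rs == pytest.approx(1.0)
    assert p == pytest.approx(2 / 6)  # only the two strict orderings reach |rs|=1


def test_matches_rank_pearson_oracle_n5():
    x = [3.0, 1.0, 4.0, 1.0, 5.0]  # includes a tie
    y = [2.0, 7.0, 1.0, 8.0, 2.0]
    rs, _ = spearman_rs(x, y)
    assert rs == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


@pytest.mark.parametrize("n", [3, 4, 5, 6])
def test_matches_oracle_all_permutations(n):
    """rs equals the independent rank-then-Pearson oracle on every pairing
    of 1..n (exhaustive)."""
    x = np.arange(1, n + 1, dtype=float)
    for perm in itertools.permutations(range(n)):
        y = x[list(perm)]
        rs, _ = spearman_rs(x, y)
        expected = stats.spearmanr(x, y).statistic
        assert rs == pytest.approx(expected, abs=1e-12)


@given(
    data=st.lists(
        st.tuples(
            st.floats(-100, 100),
            st.integers(0, 5),  # heavy ties
        ),
        min_size=5,
        max_size=12,
    )
)
@settings(derandomize=True, max_examples=50)
def test_matches_oracle_with_ties(data):
    x = [a for a, _ in data]
    y = [float(b) for _, b in data]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return
    rs, _ = spearman_rs(x, y)
    assert rs == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-10)


def test_missing_pairs_dropped():
    rs, _ = spearman_rs([1, 2, 3, 4, np.nan], [1, 2, 3, np.nan, 5])
    assert rs == pytest.approx(1.0)


def test_insufficient_pairs():
    with pytest.raises(InsufficientData):
        spearman_rs([1, 2], [1, 2])


def test_zero_variance_is_nan():
    rs, p = spearman_rs([1, 1, 1, 1], [1, 2, 3, 4])
    assert math.isnan(rs) and math.isnan(p)


def test_permutation_p_seeded_and_reproducible():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert spearman_rs(x, y, seed=3) == spearman_rs(x, y, seed=3)


# ---------------------------------------------------------------- dose gradient

def test_gradient_proportional_passes(sheet96):
    areas = {s: 5.0 * sheet96[s].dose for s in sheet96.ids(("dose",))}
    ok, rs = dose_gradient_check(areas, sheet96)
    assert ok and rs == pytest.approx(1.0)


def test_gradient_shuffled_fails(sheet96):
    rng = np.random.default_rng(0)
    fails = 0
    for _ in range(10):
        areas = {s: float(rng.uniform(1, 100)) for s in sheet96.ids(("dose",))}
        ok, _ = dose_gradient_check(areas, sheet96)
        fails += not ok
    assert fails >= 9  # dose-independent features almost never pass


def test_gradient_top_dose_only_passes(sheet96):
    """Present only at the highest dose, zero elsewhere: the midrank rs is
    positive and above the default threshold."""
    top = sheet96.ids(("dose",), dose=sheet96.highest_dose)
    areas = {s: 1000.0 for s in top}
    ok, rs = dose_gradient_check(areas, sheet96)
    assert rs > 0.6 and ok


def test_gradient_needs_three_groups():
    sheet = make_sheet(doses=(1.0, 10.0), replicates=3, n_controls=2)
    with pytest.raises(InsufficientData):
        dose_gradient_check({"D1_R01": 1.0}, sheet)


# ---------------------------------------------------------------- cross-dataset

def test_identical_vectors_link(sheet96):
    rng = np.random.default_rng(1)
    areas = {s: float(rng.lognormal(5, 1)) for s in sheet96.sample_ids}
    linked, rs, p = link_cross_dataset(areas, dict(areas), sheet96)
    assert linked and rs == pytest.approx(1.0) and p < 0.005


def test_noisy_paired_features_link(sheet96):
    rng = np.random.default_rng(2)
    base = {s: sheet96[s].dose * rng.lognormal(0, 0.3) for s in sheet96.ids(("dose",))}
    a = {s: v * rng.lognormal(0, 0.1) for s, v in base.items()}
    b = {s: v * rng.lognormal(0, 0.1) for s, v in base.items()}
    linked, rs, _ = link_cross_dataset(a, b, sheet96)
    assert linked and rs > 0.83


def test_independent_features_do_not_link(sheet96):
    rng = np.random.default_rng(3)
    n_linked = 0
    for _ in range(50):
        a = {s: float(rng.lognormal(5, 1)) for s in sheet96.sample_ids}
        b = {s: float(rng.lognormal(5, 1)) for s in sheet96.sample_ids}
        linked, _, _ = link_cross_dataset(a, b, sheet96)
        n_linked += linked
    assert n_linked == 0  # rs >= 0.83 with n = 96 independent samples: never


def test_no_shared_samples_errors():
    sheet = make_sheet(doses=(1.0, 2.0, 3.0), replicates=2, n_controls=1)
    with pytest.raises(InsufficientData):
        link_cross_dataset({}, {}, make_sheet(doses=(), replicates=1, n_controls=0))


# ---------------------------------------------------------------- MS2 similarity

def _spec(peaks, rt=1.0):
    return Spectrum(precursor_mz=300.0, rt_min=rt, peaks=tuple(peaks))


def test_identical_spectra_score_one():
    s = _spec([(100.0, 10.0), (150.0, 40.0), (200.0, 90.0)])
    assert spectral_similarity(s, s) == pytest.approx(1.0)


def test_disjoint_spectra_score_zero():
    a = _spec([(100.0, 10.0), (150.0, 40.0)])
    b = _spec([(120.0, 10.0), (170.0, 40.0)])
    assert spectral_similarity(a, b) == 0.0


def test_three_peak_hand_computed_score():
    # matches at 100 and 200 (within 0.01 Da); the 150 peak misses by 0.02.
    # score = (sqrt(100*100) + sqrt(900*900)) / sqrt(1400 * 1400) = 5/7
    a = _spec([(100.000, 100.0), (150.00, 400.0), (200.000, 900.0)])
    b = _spec([(100.005, 100.0), (150.02, 400.0), (200.002, 900.0)])
    assert spectral_similarity(a, b, frag_tol_da=0.01) == pytest.approx(5 / 7)


@given(
    peaks_a=st.lists(
        st.tuples(st.floats(50, 500), st.floats(1, 1000)), min_size=1, max_size=12
    ),
    peaks_b=st.lists(
        st.tuples(st.floats(50, 500), st.floats(1, 1000)), min_size=1, max_size=12
    ),
    scale=st.floats(0.01, 100),
)
@settings(derandomize=True, max_examples=60)
def test_similarity_symmetric_bounded_scale_invariant(peaks_a, peaks_b, scale):
    def dedupe(peaks):
        out = {}
        for m, i in peaks:
            out[round(m, 3)] = i
        return [(m + 1e-4, i) for m, i in out.items()]

    a, b = _spec(dedupe(peaks_a)), _spec(dedupe(peaks_b))
    s_ab = spectral_similarity(a, b)
    assert 0.0 <= s_ab <= 1.0
    assert s_ab == pytest.approx(spectral_similarity(b, a), abs=1e-9)
    scaled = _spec([(m, i * scale) for m, i in a.peaks], rt=a.rt_min)
    assert spectral_similarity(scaled, b) == pytest.approx(s_ab, abs=1e-9)
    assert spectral_similarity(a, a) == pytest.approx(1.0)


def test_rt_window_rejection_distinct_from_zero():
    a = _spec([(100.0, 10.0)], rt=1.0)
    b = _spec([(100.0, 10.0)], rt=2.0)
    with pytest.raises(ComparisonRejected):
        spectral_similarity(a, b, rt_window_min=0.2)
    with pytest.raises(ValueError):
        spectral_similarity(a, Spectrum(300.0, 1.0, ()), rt_window_min=0.2)


def test_greedy_matching_each_peak_used_once():
    # one reference peak cannot satisfy two query peaks
    a = _spec([(100.000, 100.0), (100.008, 100.0)])
    b = _spec([(100.004, 100.0)])
    s = spectral_similarity(a, b, frag_tol_da=0.01)
    assert s == pytest.approx(math.sqrt(100 * 100) / math.sqrt(200 * 100))


# ---------------------------------------------------------------- FISh fraction

def test_fish_fraction_half():
    matched = [(100.0 + i, 10.0) for i in range(8)]
    unmatched = [(500.0 + i, 10.0) for i in range(8)]
    spec = _spec(matched + unmatched)
    n, total, frac = fish_fraction(spec, [m for m, _ in matched])
    assert (n, total, frac) == (8, 16, 0.5)


def test_fish_fraction_all_and_none():
    spec = _spec([(100.0, 1.0), (200.0, 1.0)])
    assert fish_fraction(spec, [100.0, 200.0])[2] == 1.0
    assert fish_fraction(spec, [400.0])[2] == 0.0
    with pytest.raises(ValueError):
        fish_fraction(spec, [])


# ---------------------------------------------------------------- RSD

def test_rsd_identical_replicates_zero(sheet96):
    areas = {s: 500.0 for s in sheet96.ids(("dose",), dose=46540.0)}
    rsd = group_rsd(areas, sheet96)
    assert rsd["dose@46540"] == pytest.approx(0.0)


def test_rsd_direct_arithmetic(sheet96):
    ids = sheet96.ids(("dose",), dose=46540.0)[:3]
    areas = dict(zip(ids, [90.0, 100.0, 110.0]))
    rsd = group_rsd(areas, sheet96)
    assert rsd["dose@46540"] == pytest.approx(10.0)


def test_rsd_single_replicate_skipped(sheet96):
    areas = {sheet96.ids(("dose",), dose=62.0)[0]: 100.0}
    assert "dose@62" not in group_rsd(areas, sheet96)


def test_rsd_scale_invariance(sheet96):
    rng = np.random.default_rng(9)
    areas = {s: float(rng.lognormal(5, 0.5)) for s in sheet96.ids(("dose",), dose=62.0)}
    r1 = group_rsd(areas, sheet96)["dose@62"]
    r2 = group_rsd({s: 42.0 * a for s, a in areas.items()}, sheet96)["dose@62"]
    assert r2 == pytest.approx(r1)
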