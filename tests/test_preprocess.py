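"""Standardization, log compression, cross-correlation similarity, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ripplecam import (
    RippleError,
    SimilarityMatrix,
    build_similarity_matrix,
    filter_min_duration,
    log_transform,
    normalized_similarity,
    select_similar,
    standardize,
    xcorr_max,
    zero_pad,
)
from conftest import make_wave

finite = st.floats(-50, 50, allow_nan=False, allow_infinity=False)
short_vec = st.lists(finite, min_size=1, max_size=64)


def brute_xcorr_max(a, b):
    """Exhaustive O(n^2) oracle over every lag with >=1 overlapping sample."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best_val, best_lag = -np.inf, None
    for tau in range(-(len(b) - 1), len(a)):
        s = 0.0
        for t in range(len(a)):
            u = t - tau
            if 0 <= u < len(b):
                s += a[t] * b[u]
        better = s > best_val or (
            s == best_val and (abs(tau), tau > 0) < (abs(best_lag), best_lag > 0)
        )
        if better:
            best_val, best_lag = s, tau
    return best_val, best_lag


# ---------------------------------------------------------------------------
# standardize / log_transform
# ---------------------------------------------------------------------------

def test_standardize_worked_example():
    np.testing.assert_allclose(standardize([0, 2, 0, 2]), [-1, 1, -1, 1])


def test_standardize_rejects_constant():
    with pytest.raises(RippleError):
        standardize([3.0, 3.0, 3.0])


@given(st.lists(finite, min_size=3, max_size=100),
       st.floats(0.1, 10), st.floats(-5, 5))
@settings(max_examples=50, deadline=None)
def test_standardize_affine_invariance(xs, a, b):
    x = np.asarray(xs)
    if x.std() < 1e-6:
        return
    y = standardize(x)
    assert abs(y.mean()) < 1e-9 and abs(y.std() - 1) < 1e-9
    np.testing.assert_allclose(standardize(a * x + b), y, atol=1e-7)


@pytest.mark.parametrize("y,z", [(0, 0), (9, 1), (-9, -1), (99, 2)])
def test_log_transform_anchor_points(y, z):
    assert log_transform(np.array([float(y)]))[0] == pytest.approx(z)


@given(st.lists(finite, min_size=1, max_size=50))
@settings(max_examples=50, deadline=None)
def test_log_transform_odd_monotone_contractive(xs):
    y = np.asarray(xs)
    z = log_transform(y)
    np.testing.assert_allclose(log_transform(-y), -z, atol=1e-12)
    assert np.all(np.abs(z) <= np.abs(y) + 1e-12)
    order = np.argsort(y)
    assert np.all(np.diff(z[order]) >= -1e-12)


def test_stage_transitions():
    w = make_wave(np.sin(np.arange(400) / 7.0))
    s = standardize(w)
    assert s.stage == "standardized"
    z = log_transform(s)
    assert z.stage == "logtransformed"


# ---------------------------------------------------------------------------
# xcorr_max / normalized_similarity
# ---------------------------------------------------------------------------

def test_xcorr_max_trivial_cases():
    assert xcorr_max([1, 1], [1, 1]) == (2.0, 0)
    val, lag = xcorr_max([1, 0, 0], [0, 0, 1])
    assert val == 1.0


@given(short_vec, short_vec)
@settings(max_examples=60, deadline=None)
def test_xcorr_max_matches_bruteforce(a, b):
    val, lag = xcorr_max(a, b)
    bval, blag = brute_xcorr_max(a, b)
    assert val == pytest.approx(bval, rel=1e-9, abs=1e-9)


def test_xcorr_lag_tiebreak_prefers_small_then_negative():
    # symmetric correlation surface: [1,0,1] vs itself has ties at +/-2
    val, lag = xcorr_max([1.0, 0.0, 1.0], [1.0, 0.0, 1.0])
    assert (val, lag) == (2.0, 0)
    # two equal off-center peaks at +/-1: negative wins
    val, lag = xcorr_max([1.0, 1.0], [1.0, 1.0])
    assert lag == 0


def test_normalized_similarity_identity_and_shift():
    z = np.sin(np.arange(200) / 5.0)
    assert normalized_similarity(z, z) == 1.0
    shifted = np.concatenate([np.zeros(30), z])
    assert normalized_similarity(z, shifted) == pytest.approx(1.0, abs=1e-9)


@given(st.lists(finite, min_size=2, max_size=40),
       st.lists(finite, min_size=2, max_size=40))
@settings(max_examples=40, deadline=None)
def test_normalized_similarity_matches_oracle(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if np.dot(a, a) == 0:
        return
    expected = brute_xcorr_max(a, b)[0] / np.dot(a, a)
    assert normalized_similarity(a, b) == pytest.approx(expected, rel=1e-9, abs=1e-9)


def test_similarity_invariant_to_raw_affine_rescaling():
    rng = np.random.default_rng(0)
    x1 = rng.normal(size=300)
    x2 = 40.0 * x1 + 7.0  # same waveform, different animal gain
    z1 = log_transform(standardize(x1))
    z2 = log_transform(standardize(x2))
    assert normalized_similarity(z1, z2) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# duration filter / padding
# ---------------------------------------------------------------------------

def test_duration_filter_boundary():
    short = make_wave(np.ones(374) + np.arange(374), id="short")
    exact = make_wave(np.ones(375) + np.arange(375), id="exact")
    kept = filter_min_duration([short, exact], 15.0)
    assert [e.id for e in kept] == ["exact"]
    assert filter_min_duration([], 15.0) == []


def test_zero_pad_contract():
    w = standardize(make_wave(np.sin(np.arange(1500) / 3.0)))
    p = zero_pad(w)
    assert p.n == 2205 and p.stage == "padded" and p.n_orig == 1500
    assert np.all(p.samples[1500:] == 0)
    np.testing.assert_array_equal(p.samples[:1500], w.samples)
    full = standardize(make_wave(np.sin(np.arange(2205) / 3.0)))
    np.testing.assert_array_equal(zero_pad(full).samples, full.samples)
    too_long = standardize(make_wave(np.sin(np.arange(2206) / 3.0)))
    with pytest.raises(RippleError):
        zero_pad(too_long)


# ---------------------------------------------------------------------------
# similarity matrix / selection
# ---------------------------------------------------------------------------

def _logged(samples, id):
    return make_wave(samples, id=id, stage="logtransformed")


def test_matrix_diagonal_and_identical_events():
    z = np.sin(np.arange(120) / 4.0)
    m = build_similarity_matrix([_logged(z, "a"), _logged(z, "b")])
    np.testing.assert_allclose(m.values, 1.0, atol=1e-9)


def test_matrix_agrees_with_pairwise_similarity():
    rng = np.random.default_rng(3)
    evs = [_logged(rng.normal(size=rng.integers(60, 140)), f"e{i}") for i in range(6)]
    m = build_similarity_matrix(evs)
    for i in range(6):
        assert m.values[i, i] == 1.0
        for j in range(6):
            if i != j:
                expected = normalized_similarity(evs[i].samples, evs[j].samples)
                assert m.values[i, j] == pytest.approx(expected, abs=1e-9)


def test_matrix_requires_log_stage():
    w = make_wave(np.arange(50.0), stage="standardized")
    with pytest.raises(RippleError):
        build_similarity_matrix([w, w])


def test_selection_rules():
    ids = list("abcd")
    v = np.eye(4)
    v[0, 1] = 0.7  # only pair (a, b), via a's row
    m = SimilarityMatrix(values=v, ids=ids)
    sel = select_similar(m, 0.6)
    assert sel.selected_ids == ["a", "b"]
    # all off-diagonal zero -> nothing selected
    none = select_similar(SimilarityMatrix(values=np.eye(4), ids=ids), 0.6)
    assert none.selected_ids == []
    # strict comparison at the threshold
    v2 = np.eye(4)
    v2[2, 3] = 0.6
    assert select_similar(SimilarityMatrix(values=v2, ids=ids), 0.6).selected_ids == []


def test_selection_monotone_in_threshold():
    rng = np.random.default_rng(7)
    v = rng.uniform(0, 1.2, (8, 8))
    np.fill_diagonal(v, 1.0)
    m = SimilarityMatrix(values=v, ids=[f"i{k}" for k in range(8)])
    sizes = [len(select_similar(m, t).selected_ids) for t in (0.2, 0.5, 0.8, 1.1)]
    assert sizes == sorted(sizes, reverse=True)
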