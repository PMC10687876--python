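"""Ingestion, subsampling, moments, blocking errors and Gaussianity checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gapredox import (
    GapMoments,
    GapTimeSeries,
    RedoxState,
    Thermo,
    block_sem,
    compute_moments,
    cumulative_mean,
    gaussianity_report,
    read_gap_series,
    subsample_equidistant,
    write_gap_series,
)
from gapredox.gap_stats import GaussianityThresholds, _dagostino_k2


def _series(gaps, thermo=Thermo(), state=RedoxState.REDUCED):
    gaps = np.asarray(gaps, dtype=float)
    return GapTimeSeries(state, np.arange(len(gaps), dtype=float), gaps, thermo)


# ---------------------------------------------------------------- reading


def test_read_gap_series_basic(tmp_path, thermo):
    p = tmp_path / "r.csv"
    p.write_text("0.0,7.5\n0.1,7.9\n0.2,7.7\n")
    s = read_gap_series(p, RedoxState.REDUCED, thermo)
    assert len(s) == 3
    assert s.gaps.mean() == pytest.approx(7.7)


def test_read_gap_series_comments_and_whitespace(tmp_path, thermo):
    plain = tmp_path / "a.csv"
    plain.write_text("0.0,7.5\n0.1,7.9\n")
    commented = tmp_path / "b.csv"
    commented.write_text("# time_ps, gap_eV\n\n0.0 7.5\n0.1\t7.9\n")
    s1 = read_gap_series(plain, RedoxState.REDUCED, thermo)
    s2 = read_gap_series(commented, RedoxState.REDUCED, thermo)
    np.testing.assert_array_equal(s1.gaps, s2.gaps)


@pytest.mark.parametrize(
    "content,err",
    [
        ("0.0,7.5\n0.1,7.9\n0.1,7.7\n", "strictly increasing"),
        ("0.0,7.5\nnot,a,row\n", ":2"),
        ("0.0,7.5,9\n0.1,7.9\n", ":1"),
        ("0.0,7.5\n", "at least 2"),
    ],
)
def test_read_gap_series_errors(tmp_path, thermo, content, err):
    p = tmp_path / "bad.csv"
    p.write_text(content)
    with pytest.raises(ValueError, match=err):
        read_gap_series(p, RedoxState.REDUCED, thermo)


def test_write_read_roundtrip(tmp_path, small_series):
    p = tmp_path / "out.csv"
    write_gap_series(small_series, p)
    again = read_gap_series(p, small_series.state, small_series.thermo)
    np.testing.assert_allclose(again.gaps, small_series.gaps, atol=1e-9)


# ------------------------------------------------------------- subsampling


def test_subsample_identity_and_indices():
    s = _series(np.arange(5.0) + 10)
    np.testing.assert_array_equal(subsample_equidistant(s, 5).gaps, s.gaps)
    s9 = _series(np.arange(9.0))
    np.testing.assert_array_equal(subsample_equidistant(s9, 3).gaps, [0.0, 4.0, 8.0])


def test_subsample_25000_to_1000_endpoints_and_spacing():
    s = _series(np.arange(25000.0))
    sub = subsample_equidistant(s, 1000)
    assert len(sub) == 1000
    assert sub.gaps[0] == 0.0 and sub.gaps[-1] == 24999.0
    # direct index enumeration oracle
    expected = (np.arange(1000) * 24999) // 999
    np.testing.assert_array_equal(sub.gaps, expected.astype(float))
    steps = np.diff(expected)
    assert steps.min() >= 25 and steps.max() <= 26


def test_subsample_too_many_errors():
    with pytest.raises(ValueError):
        subsample_equidistant(_series([1.0, 2.0, 3.0]), 4)


def test_subsampled_moments_converge_to_full(marcus_pair):
    (reduced, _), _ = marcus_pair
    full = compute_moments(reduced)
    errs = []
    for n in (100, 1000, 10000, len(reduced)):
        m = compute_moments(subsample_equidistant(reduced, n))
        errs.append(abs(m.mean - full.mean))
    assert errs[-1] == 0.0
    # error shrinks over decades of n (not necessarily per-step monotone)
    assert errs[2] < errs[0]


# ---------------------------------------------------------------- moments


def test_moments_hand_values():
    const = compute_moments(_series([5.0, 5.0, 5.0]))
    assert const.mean == 5.0 and const.sigma == 0.0 and const.skewness == 0.0
    m = compute_moments(_series([1.0, 2.0, 3.0]))
    assert m.mean == pytest.approx(2.0)
    assert m.sigma == pytest.approx(1.0)  # n-1 denominator


def test_moments_recover_gaussian_parameters():
    """mu=7.82 eV, sigma=0.24 eV at n=1000 over 100 seeds."""
    mu, sigma, n = 7.82, 0.24, 1000
    hits, rels = 0, []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        m = compute_moments(_series(rng.normal(mu, sigma, n)))
        hits += abs(m.mean - mu) < 3 * sigma / math.sqrt(n)
        rels.append(m.rel_sigma_pct)
    assert hits >= 97  # 3-sigma rule; a couple of excursions allowed
    assert np.mean(rels) == pytest.approx(100 * sigma / mu, rel=0.05)  # ~3.1%


@given(scale=st.floats(0.1, 10), shift=st.floats(-100, 100))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_moment_scaling_properties(scale, shift):
    rng = np.random.default_rng(7)
    base = rng.normal(0.0, 1.0, 500) ** 3  # deliberately skewed
    m0 = compute_moments(_series(base))
    m1 = compute_moments(_series(base * scale))
    assert m1.sigma == pytest.approx(m0.sigma * abs(scale), rel=1e-9)
    assert m1.skewness == pytest.approx(m0.skewness, rel=1e-9)
    assert m1.excess_kurtosis == pytest.approx(m0.excess_kurtosis, rel=1e-9)
    # moments invariant under relabeling times
    shifted = GapTimeSeries(
        RedoxState.REDUCED, np.arange(500.0) + shift, base, Thermo()
    )
    m2 = compute_moments(shifted)
    assert m2.mean == m0.mean and m2.sigma == m0.sigma


def test_cumulative_mean_diagnostic(small_series):
    _, running = cumulative_mean(small_series)
    np.testing.assert_allclose(running, [7.5, 7.7, 7.7])


# ---------------------------------------------------------------- blocking


def test_block_sem_iid_limit():
    sigma, n = 0.24, 1024
    ratios = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        sem = block_sem(rng.normal(0, sigma, n))
        ratios.append(sem / (sigma / math.sqrt(n)))
    assert 1 / 1.5 < np.mean(ratios) < 1.5
    assert np.quantile(ratios, 0.95) < 2.0


def test_block_sem_ar1_inflation():
    """Blocking must recover the (1+rho)/(1-rho) effective-sample-size loss."""
    rho, sigma, n = 0.9, 1.0, 4096
    inflation = math.sqrt((1 + rho) / (1 - rho))  # ~4.36
    ratios = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        innov = rng.normal(0, sigma * math.sqrt(1 - rho**2), n)
        x = np.empty(n)
        x[0] = rng.normal(0, sigma)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + innov[i]
        ratios.append(block_sem(x) / (sigma / math.sqrt(n)))
    mean_ratio = np.mean(ratios)
    assert inflation / 2 < mean_ratio < inflation * 2


def test_block_sem_edge_cases():
    assert block_sem(np.full(64, 3.3)) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        block_sem(np.ones(10))


# ------------------------------------------------------------- gaussianity


def test_omnibus_matches_scipy_normaltest():
    """The moment-based K^2 must equal the classical omnibus test on raw data."""
    for seed, dist in ((0, "normal"), (1, "lognormal")):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=500) if dist == "normal" else rng.lognormal(size=500)
        m = compute_moments(_series(x - x.mean() + 7.0))
        k2, p = _dagostino_k2(m.skewness, m.excess_kurtosis, m.n)
        ref_k2, ref_p = stats.normaltest(x)
        assert k2 == pytest.approx(float(ref_k2), rel=1e-8)
        assert p == pytest.approx(float(ref_p), rel=1e-6)


def _moments(mean, sigma, n=1000, skew=0.0, kurt=0.0):
    return GapMoments(n=n, mean=mean, sigma=sigma, skewness=skew, excess_kurtosis=kurt)


def test_relative_sigma_pairs_match_reported_percentages():
    rep1 = gaussianity_report(_moments(7.82, 0.24), _moments(5.81, 0.24))
    assert rep1.sigma_rel_pair[0] == pytest.approx(3.1, abs=0.05)
    assert rep1.sigma_rel_pair[1] == pytest.approx(4.1, abs=0.05)
    rep2 = gaussianity_report(_moments(6.88, 0.23), _moments(4.59, 0.27))
    assert rep2.sigma_rel_pair[0] == pytest.approx(3.3, abs=0.05)
    assert rep2.sigma_rel_pair[1] == pytest.approx(5.9, abs=0.05)


def test_verdict_thresholds():
    ok = gaussianity_report(_moments(7.82, 0.24), _moments(5.81, 0.24))
    assert ok.verdict == "marcus_consistent"
    wide = gaussianity_report(_moments(7.82, 0.24), _moments(5.81, 0.31))
    assert wide.verdict == "borderline"  # sigma diff 0.07 < 2 x 0.05 threshold
    far = gaussianity_report(_moments(7.82, 0.24), _moments(5.81, 0.40))
    assert far.verdict == "non_marcus"
    skewed = gaussianity_report(_moments(7.82, 0.24, skew=1.2), _moments(5.81, 0.24))
    assert skewed.verdict == "non_marcus"


def test_verdict_on_exactly_gaussian_synthetic_pair(marcus_pair):
    (reduced, oxidized), _ = marcus_pair
    rep = gaussianity_report(compute_moments(reduced), compute_moments(oxidized))
    assert rep.verdict == "marcus_consistent"
    assert rep.omnibus_p_r > 0.01 and rep.omnibus_p_o > 0.01
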