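"""Spectrum I/O and preprocessing: parsers, rubberband baseline, normalization."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ftirstress.spectra import (
    Spectrum,
    average_replicates,
    quality_snr,
    read_spectrum_table,
    resample_to_grid,
    rubberband_baseline,
    vector_normalize,
    write_spectrum_table,
)

from conftest import make_spectrum


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum(np.array([1000.0]), np.array([0.5]))  # too short
    with pytest.raises(ValueError):
        Spectrum(np.array([1000.0, 998.0, 998.0]), np.zeros(3))  # not monotone
    with pytest.raises(ValueError):
        Spectrum(np.array([1000.0, 998.0]), np.zeros(3))  # length mismatch


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def test_read_minimal_two_rows():
    sp = read_spectrum_table(io.StringIO("1000,0.5\n998,0.6\n"))
    assert len(sp) == 2
    assert sp.wavenumbers[0] == 1000.0  # descending


def test_read_skips_comment_header():
    lines = ["#wavenumber,absorbance"]
    lines += [f"{4000 - 2 * i},{0.001 * i}" for i in range(1801)]
    sp = read_spectrum_table(io.StringIO("\n".join(lines)))
    assert len(sp) == 1801


def test_read_jcamp_like_block():
    text = (
        "##TITLE=synthetic fixture\n"
        "##XYDATA=(X++(Y..Y))\n"
        "1000 0.5\n998 0.6\n996 0.7\n"
        "##END=\n"
    )
    sp = read_spectrum_table(io.StringIO(text))
    assert len(sp) == 3
    assert sp.intensities[0] == 0.5


def test_read_errors_name_the_line():
    with pytest.raises(ValueError, match="line 2"):
        read_spectrum_table(io.StringIO("1000,0.5\nnot,a,number\n998,0.6\n"))
    with pytest.raises(ValueError, match="duplicate"):
        read_spectrum_table(io.StringIO("1000,0.5\n1000,0.6\n998,0.7\n"))
    with pytest.raises(ValueError, match="at least 2"):
        read_spectrum_table(io.StringIO("1000,0.5\n"))


def test_write_read_roundtrip(random_spectrum, tmp_path):
    path = tmp_path / "spec.csv"
    write_spectrum_table(random_spectrum, path)
    back = read_spectrum_table(path)
    np.testing.assert_allclose(back.wavenumbers, random_spectrum.wavenumbers, atol=1e-9)
    np.testing.assert_allclose(back.intensities, random_spectrum.intensities, atol=1e-9)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def test_resample_identity(random_spectrum):
    out = resample_to_grid(random_spectrum, random_spectrum.wavenumbers)
    np.testing.assert_allclose(out.intensities, random_spectrum.intensities, atol=1e-12)


def test_resample_midpoint():
    sp = make_spectrum([1000.0, 998.0], [0.0, 1.0])
    out = resample_to_grid(sp, np.array([999.0, 998.0]))
    assert out.intensities[0] == pytest.approx(0.5, abs=1e-12)


def test_resample_linear_between_nodes():
    sp = make_spectrum([1000.0, 998.0, 996.0], [0.0, 1.0, 0.0])
    out = resample_to_grid(sp, np.array([999.0, 997.0]))
    np.testing.assert_allclose(out.intensities, [0.5, 0.5], atol=1e-12)


def test_resample_rejects_extrapolation(random_spectrum):
    grid = np.array([4200.0, 4100.0])
    with pytest.raises(ValueError, match="outside"):
        resample_to_grid(random_spectrum, grid)


def test_resample_against_bruteforce_interpolation(rng):
    # piecewise-linear ground truth evaluated point by point
    x = np.sort(rng.uniform(500, 3900, size=40))[::-1]
    y = rng.normal(size=40)
    sp = make_spectrum(x, y)
    queries = np.sort(rng.uniform(x.min(), x.max(), size=50))[::-1]
    out = resample_to_grid(sp, queries)
    xa, ya = x[::-1], y[::-1]
    expected = []
    for q in queries:
        j = np.searchsorted(xa, q)
        j = min(max(j, 1), xa.size - 1)
        t = (q - xa[j - 1]) / (xa[j] - xa[j - 1])
        expected.append((1 - t) * ya[j - 1] + t * ya[j])
    np.testing.assert_allclose(out.intensities, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# rubberband baseline
# ---------------------------------------------------------------------------

def bruteforce_lower_hull(x, y):
    """O(n^3) supporting-line oracle: the lower convex hull at x_k is the
    maximum over all lines through two data points that stay below every
    data point."""
    n = x.size
    base = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            line = y[i] + slope * (x - x[i])
            if np.all(line <= y + 1e-9):
                base = np.maximum(base, line)
    return base


def test_rubberband_linear_spectrum_is_flat():
    x = np.linspace(4000, 400, 50)
    y = 0.5 + 1e-4 * x
    base, corr = rubberband_baseline(make_spectrum(x, y))
    np.testing.assert_allclose(corr.intensities, 0.0, atol=1e-10)


def test_rubberband_three_point_peak():
    sp = make_spectrum([3.0, 2.0, 1.0], [0.0, 5.0, 0.0])
    base, corr = rubberband_baseline(sp)
    np.testing.assert_allclose(base.intensities, [0.0, 0.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(corr.intensities, [0.0, 5.0, 0.0], atol=1e-12)


def test_rubberband_against_bruteforce_hull(rng):
    x = np.linspace(1000, 2000, 60)[::-1]
    # convex background + positive peaks: generic hull structure
    y = 1e-6 * (x - 1500) ** 2 + 0.05
    for _ in range(4):
        c = rng.uniform(1100, 1900)
        y = y + rng.uniform(0.1, 1.0) * np.exp(-0.5 * ((x - c) / 20) ** 2)
    sp = make_spectrum(x, y)
    _, corr = rubberband_baseline(sp)
    oracle = y - bruteforce_lower_hull(x, y)
    np.testing.assert_allclose(corr.intensities, oracle, atol=1e-10)


def test_rubberband_properties(random_spectrum):
    _, corr = rubberband_baseline(random_spectrum)
    assert corr.intensities.min() >= -1e-12
    assert (np.abs(corr.intensities) < 1e-12).sum() >= 2  # touches zero
    # idempotence: correcting a corrected spectrum is a no-op
    _, corr2 = rubberband_baseline(corr)
    np.testing.assert_allclose(corr2.intensities, corr.intensities, atol=1e-10)


def test_rubberband_support_point_cap():
    # every point of a parabola is a hull vertex; the cap must prune to 10
    x = np.linspace(0.0, 1.0, 100)[::-1]
    y = (x - 0.5) ** 2
    base, corr = rubberband_baseline(make_spectrum(x, y), n_points=10)
    # pruned baseline stays close to the true hull (least-added-area pruning)
    assert np.max(np.abs(corr.intensities)) < 0.02
    assert corr.intensities[0] == 0.0 and corr.intensities[-1] == 0.0

def test_rubberband_rejects_short_input():
    with pytest.raises(ValueError):
        rubberband_baseline(make_spectrum([2.0, 1.0], [0.0, 1.0]))


# ---------------------------------------------------------------------------
# vector normalization
# ---------------------------------------------------------------------------

def test_vector_normalize_two_points():
    out = vector_normalize(make_spectrum([1000.0, 998.0], [0.0, 2.0]))
    np.testing.assert_allclose(
        out.intensities, [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
    )


def test_vector_normalize_idempotent(random_spectrum):
    once = vector_normalize(random_spectrum)
    twice = vector_normalize(once)
    np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)


def test_vector_normalize_rejects_constant():
    with pytest.raises(ValueError, match="zero variance"):
        vector_normalize(make_spectrum([1000.0, 998.0, 996.0], [1.0, 1.0, 1.0]))


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_vector_normalize_unit_norm_any_spectrum(seed):
    r = np.random.default_rng(seed)
    y = r.normal(size=64)
    if np.ptp(y) == 0:
        return
    out = vector_normalize(make_spectrum(np.arange(64, 0, -1.0), y))
    assert abs(np.linalg.norm(out.intensities) - 1.0) < 1e-12
    assert abs(out.intensities.mean()) < 1e-12


def test_baseline_then_normalize_is_mean0_norm1(random_spectrum):
    _, corr = rubberband_baseline(random_spectrum)
    out = vector_normalize(corr)
    assert abs(out.intensities.mean()) < 1e-12
    assert abs(np.linalg.norm(out.intensities) - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# quality test
# ---------------------------------------------------------------------------

def _snr_spectrum(grid, sigma, r):
    signal = np.exp(-0.5 * ((grid - 1650.0) / 30.0) ** 2)  # p2p ~ 1
    return make_spectrum(grid, signal + sigma * r.standard_normal(grid.size))


def test_quality_snr_noiseless_passes(default_grid):
    sp = make_spectrum(default_grid, np.exp(-0.5 * ((default_grid - 1650) / 30) ** 2))
    assert quality_snr(sp) == np.inf


@pytest.mark.parametrize("sigma,expected", [(1e-4, 1e4), (1e-3, 1e3)])
def test_quality_snr_tracks_noise_level(default_grid, sigma, expected):
    # Monte-Carlo: mean SNR over 100 seeds within a factor 1.5 of p2p/sigma
    vals = [
        quality_snr(_snr_spectrum(default_grid, sigma, np.random.default_rng(k)))
        for k in range(100)
    ]
    mean = np.mean(vals)
    assert expected / 1.5 < mean < expected * 1.5
    if expected < 4000:
        assert mean < 4000  # fails the quality cut-off


def test_quality_snr_requires_window_coverage():
    sp = make_spectrum(np.linspace(1500, 400, 100), np.linspace(0, 1, 100))
    with pytest.raises(ValueError, match="not covered"):
        quality_snr(sp)


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

def test_average_replicates(rng, random_spectrum):
    assert np.array_equal(
        average_replicates([random_spectrum]).intensities, random_spectrum.intensities
    )
    neg = random_spectrum.with_intensities(-random_spectrum.intensities)
    np.testing.assert_allclose(
        average_replicates([random_spectrum, neg]).intensities, 0.0, atol=1e-15
    )
    reps = [
        random_spectrum.with_intensities(rng.normal(size=len(random_spectrum)))
        for _ in range(3)
    ]
    mean = average_replicates(reps).intensities
    brute = (reps[0].intensities + reps[1].intensities + reps[2].intensities) / 3.0
    np.testing.assert_allclose(mean, brute, atol=1e-12)


def test_average_replicates_empty_group():
    with pytest.raises(ValueError, match="empty"):
        average_replicates([])
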