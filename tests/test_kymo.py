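import numpy as np
import pytest

from racwaves import (
    Kymograph,
    autocorrelogram,
    interpolate_to_grid,
    pca_align,
    pearson_full,
    phase_portrait,
    psd_noise,
    sliding_pearson,
    smooth_intensity,
)
from racwaves.kymo import (
    DegenerateSignalError,
    NonClosingTrajectoryWarning,
)

M = 60
OMEGA = 2 * np.pi / 100.0  # T = 100 s


def _wave(kind, n_t=400, m=M, n=1, dt=1.0, baseline=0.0, direction=1):
    t = np.arange(n_t) * dt
    phi = np.arange(m) * 2 * np.pi / m
    if kind == "traveling":
        I = np.cos(n * phi[None, :] - direction * OMEGA * t[:, None])
    elif kind == "standing":
        I = np.cos(n * phi[None, :]) * np.cos(OMEGA * t[:, None])
    elif kind == "stationary":
        I = np.cos(n * phi[None, :]) + 0 * t[:, None]
    else:
        raise ValueError(kind)
    return Kymograph(baseline + I, t, phi)


# ---------------------------------------------------------------------------
# container


def test_kymograph_validation():
    Kymograph.from_matrix(np.ones((5, 8)), frame_interval=2.0)
    with pytest.raises(ValueError):
        Kymograph(np.ones((5, 8)), np.zeros(5), np.arange(8) * 2 * np.pi / 8)
    with pytest.raises(ValueError):
        Kymograph(np.ones((5, 8)), np.arange(5.0), np.linspace(0, 1, 8))
    k = Kymograph.from_matrix(np.ones((5, 8)), frame_interval=2.0)
    assert k.dt == 2.0 and k.n_t == 5 and k.m == 8


# ---------------------------------------------------------------------------
# autocorrelogram


def test_acf_normalized_at_origin():
    acf = autocorrelogram(_wave("traveling"))
    i0 = int(np.argmin(np.abs(acf.dt)))
    j0 = int(np.argmin(np.abs(acf.dphi)))
    assert acf.values[i0, j0] == pytest.approx(1.0, abs=1e-9)
    assert acf.values.max() <= 1.0 + 1e-9


def test_acf_point_symmetry():
    rng = np.random.default_rng(0)
    k = Kymograph.from_matrix(rng.uniform(0, 1, (50, 20)))
    acf = autocorrelogram(k)
    # reflect about the zero-lag column, periodically (the -pi column is
    # its own mirror on an even grid)
    m = acf.dphi.size
    j0 = int(np.argmin(np.abs(acf.dphi)))
    perm = (2 * j0 - np.arange(m)) % m
    np.testing.assert_allclose(acf.values, acf.values[::-1][:, perm],
                               atol=1e-12)


def test_acf_traveling_closed_form():
    acf = autocorrelogram(_wave("traveling"))
    # A(dphi, dt) = cos(dphi - omega dt) for a mode-1 wave
    for i in np.arange(0, acf.dt.size, 17):
        expected = np.cos(acf.dphi - OMEGA * acf.dt[i])
        np.testing.assert_allclose(acf.values[i], expected, atol=0.05)


def test_acf_standing_closed_form():
    acf = autocorrelogram(_wave("standing", n=2))
    # truncated temporal averaging biases large lags by up to ~0.07 when
    # the averaging window is not an integer number of periods
    for i in np.arange(0, acf.dt.size, 17):
        expected = np.cos(2 * acf.dphi) * np.cos(OMEGA * acf.dt[i])
        np.testing.assert_allclose(acf.values[i], expected, atol=0.08)


def test_acf_affine_invariance():
    k = _wave("traveling")
    k2 = Kymograph(3.5 * k.values + 40.0, k.times, k.angles)
    a = autocorrelogram(k)
    b = autocorrelogram(k2)
    np.testing.assert_allclose(a.values, b.values, atol=1e-10)


def test_acf_degenerate_input():
    with pytest.raises(DegenerateSignalError):
        autocorrelogram(Kymograph.from_matrix(np.full((30, 12), 7.0)))


def test_temporal_period():
    acf = autocorrelogram(_wave("traveling"))
    assert acf.temporal_period() == pytest.approx(100.0, abs=2.0)
    acf = autocorrelogram(_wave("stationary"))
    assert acf.temporal_period() is None


def test_ridge_slope_signs_and_magnitude():
    fwd = autocorrelogram(_wave("traveling", direction=1)).ridge_slope()
    bwd = autocorrelogram(_wave("traveling", direction=-1)).ridge_slope()
    assert fwd == pytest.approx(OMEGA, rel=1e-3)
    assert bwd == pytest.approx(-OMEGA, rel=1e-3)
    # mode 2 moves at half the angular speed for the same frequency
    m2 = autocorrelogram(_wave("traveling", n=2)).ridge_slope()
    assert m2 == pytest.approx(OMEGA / 2, rel=1e-3)


def test_ridge_slope_vanishes_for_standing():
    slope = autocorrelogram(_wave("standing")).ridge_slope()
    assert abs(slope) < 0.01 * OMEGA


# ---------------------------------------------------------------------------
# correlation


def test_pearson_perfect_and_inverted():
    k = _wave("traveling", baseline=5.0)
    anti = Kymograph(10.0 - k.values, k.times, k.angles)
    assert pearson_full(k, k, window=None) == pytest.approx(1.0)
    assert pearson_full(k, anti, window=None) == pytest.approx(-1.0)
    # default window restricts to the first 120 s
    assert pearson_full(k, anti) == pytest.approx(-1.0)


def test_pearson_null_distribution():
    rng = np.random.default_rng(42)
    a = Kymograph.from_matrix(rng.normal(0, 1, (200, 60)))
    b = Kymograph.from_matrix(rng.normal(0, 1, (200, 60)))
    assert abs(pearson_full(a, b, window=None)) < 0.03


def test_pearson_requires_registration():
    a = _wave("traveling", n_t=100)
    b = _wave("traveling", n_t=90)
    with pytest.raises(ValueError):
        pearson_full(a, b)


def test_sliding_pearson_detects_flip():
    k = _wave("traveling", n_t=400, baseline=5.0)
    flip = k.values.copy()
    flip[200:] = 10.0 - flip[200:]
    other = Kymograph(flip, k.times, k.angles)
    centers, rs = sliding_pearson(k, other, window=20.0)
    assert rs.size == centers.size == 400 - 20 + 1
    assert rs[centers < 150].min() > 0.99
    assert rs[centers > 250].max() < -0.99
    with pytest.raises(ValueError):
        sliding_pearson(k, other, window=1e6)


# ---------------------------------------------------------------------------
# PCA phase alignment


def _two_channel(n_t=300, m=M, offset=np.pi):
    t = np.arange(n_t, dtype=float)
    phi = np.arange(m) * 2 * np.pi / m
    ch1 = 5 + np.cos(phi[None, :] - OMEGA * t[:, None])
    ch2 = 5 + np.cos(phi[None, :] - OMEGA * t[:, None] + offset)
    return (Kymograph(ch1, t, phi), Kymograph(ch2, t, phi))


def test_pca_align_recovers_period_and_phases():
    k1, k2 = _two_channel()
    al = pca_align(k1, k2)
    assert al.period == pytest.approx(100.0, rel=0.05)
    assert al.variance_fractions[:2].sum() > 0.5
    # column phases advance uniformly by one angular step per column
    steps = np.diff(np.unwrap(al.phases))
    np.testing.assert_allclose(np.abs(steps), 2 * np.pi / M, rtol=0.05)


def test_pca_align_antiphase_channels():
    k1, k2 = _two_channel(offset=np.pi)
    al = pca_align(k1, k2)
    # aligned profiles oscillate in antiphase
    a = al.aligned_ch1 - al.aligned_ch1.mean()
    b = al.aligned_ch2 - al.aligned_ch2.mean()
    r = a @ b / np.linalg.norm(a) / np.linalg.norm(b)
    assert r < -0.9


def test_pca_align_constant_row_rejected():
    k1, k2 = _two_channel()
    const = Kymograph(np.full_like(k1.values, 5.0), k1.times, k1.angles)
    with pytest.raises(ValueError):
        pca_align(k1, const)


# ---------------------------------------------------------------------------
# phase portrait


def test_phase_portrait_orientation():
    th = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    ccw = phase_portrait(np.cos(th), np.sin(th))
    cw = phase_portrait(np.cos(th), -np.sin(th))
    assert ccw["orientation"] == "counterclockwise"
    assert ccw["signed_area"] == pytest.approx(np.pi, rel=1e-3)
    assert cw["orientation"] == "clockwise"
    assert cw["signed_area"] == pytest.approx(-np.pi, rel=1e-3)


def test_phase_portrait_warns_when_open():
    th = np.linspace(0, np.pi, 100)  # half a loop only
    with pytest.warns(NonClosingTrajectoryWarning):
        phase_portrait(np.cos(th), np.sin(th))
    with pytest.raises(ValueError):
        phase_portrait(np.ones(10), np.ones(10))


# ---------------------------------------------------------------------------
# noise spectrum


def test_psd_parseval():
    rng = np.random.default_rng(7)
    k = Kymograph.from_matrix(100.0 + rng.normal(0, 5, (100, 64)))
    out = psd_noise(k)
    total = (out["filtered"] ** 2).sum(axis=1).mean()
    assert out["psd"].sum() == pytest.approx(total, rel=1e-9)


def test_psd_stopband_removes_pattern():
    # a pure mode-1 pattern lies far below the cutoff and must vanish
    k = _wave("traveling", baseline=100.0, n_t=100)
    out = psd_noise(k)
    assert (out["filtered"] ** 2).mean() < 1e-2 * np.var(np.sqrt(k.values))


def test_psd_white_noise_flat_passband():
    rng = np.random.default_rng(9)
    k = Kymograph.from_matrix(100.0 + rng.normal(0, 5, (400, 64)))
    out = psd_noise(k, sample_length=0.5)
    band = out["freq_per_sample"] > 0.25
    psd = out["psd"][band]
    assert psd.max() / psd.min() < 3.0
    np.testing.assert_allclose(out["freq_per_um"],
                               out["freq_per_sample"] / 0.5)
    with pytest.raises(ValueError):
        psd_noise(Kymograph.from_matrix(-np.ones((20, 16))))


# ---------------------------------------------------------------------------
# irregular-sample interpolation


def test_interpolation_identity_on_grid():
    m = 24
    grid = np.arange(m) * 2 * np.pi / m
    vals = np.cos(grid)[None, :].repeat(5, axis=0)
    k = interpolate_to_grid(grid, vals, np.arange(5.0), m)
    np.testing.assert_allclose(k.values, vals, atol=1e-12)


def test_interpolation_recovers_harmonic():
    rng = np.random.default_rng(1)
    n_t, n_s, m = 6, 40, 60
    base = np.arange(n_s) * 2 * np.pi / n_s
    angles = np.mod(base[None, :] + rng.uniform(-0.05, 0.05, (n_t, n_s)), 2 * np.pi)
    vals = np.cos(angles)
    k = interpolate_to_grid(angles, vals, np.arange(float(n_t)), m)
    target = np.cos(k.angles)
    assert np.max(np.abs(k.values - target[None, :])) < 0.05


def test_interpolation_rejects_bad_input():
    with pytest.raises(ValueError):
        interpolate_to_grid(np.zeros((2, 3)), np.zeros((2, 3)),
                            np.arange(2.0), 12)
    ang = np.array([[0.1, 0.1, 1.0, 2.0, 3.0]])
    with pytest.raises(ValueError):
        interpolate_to_grid(ang, np.ones_like(ang), np.zeros(1), 12)


# ---------------------------------------------------------------------------
# smoothing


def test_smoothing_preserves_constant_and_lam_zero():
    k = Kymograph.from_matrix(np.full((10, 16), 3.0))
    np.testing.assert_array_equal(smooth_intensity(k).values, k.values)
    noisy = Kymograph.from_matrix(np.random.default_rng(0).uniform(0, 1, (10, 16)))
    np.testing.assert_array_equal(smooth_intensity(noisy, lam=0).values,
                                  noisy.values)


def test_smoothing_reduces_noise():
    rng = np.random.default_rng(3)
    clean = _wave("traveling", baseline=5.0, n_t=60)
    noisy = Kymograph(clean.values + rng.normal(0, 0.3, clean.values.shape),
                      clean.times, clean.angles)
    sm = smooth_intensity(noisy, lam=1.0)
    err_raw = np.mean((noisy.values - clean.values) ** 2)
    err_sm = np.mean((sm.values - clean.values) ** 2)
    assert err_sm < 0.5 * err_raw
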