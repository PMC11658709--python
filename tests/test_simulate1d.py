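import numpy as np
import pytest

from racwaves import (
    Kymograph,
    ModelParameters,
    build_laplacian,
    classify_pattern,
    integrate,
    make_initial_state,
    species_totals,
    transition_run,
    wave_speed,
)
from racwaves.simulate1d import (
    InsufficientDataError,
    solve_extensive_steady_state,
)


# ---------------------------------------------------------------------------
# discrete Laplacian


def test_laplacian_eigenfunction():
    L, n = 40.0, 100
    lap = build_laplacian(L, n)
    x = np.arange(n) * L / n
    h = L / n
    q = 2.0 * np.pi / L
    u = np.cos(q * x)
    # discrete eigenvalue of the periodic 3-point stencil
    lam = -(2.0 / h**2) * (1.0 - np.cos(q * h))
    np.testing.assert_allclose(lap @ u, lam * u, atol=1e-12)
    assert lam == pytest.approx(-q * q, rel=1e-3)  # second-order accurate


def test_laplacian_structure():
    lap = build_laplacian(40.0, 50).toarray()
    np.testing.assert_allclose(lap, lap.T, atol=1e-12)
    np.testing.assert_allclose(lap.sum(axis=1), 0.0, atol=1e-12)
    assert lap[0, -1] != 0.0  # periodic wrap
    with pytest.raises(ValueError):
        build_laplacian(40.0, 2)


# ---------------------------------------------------------------------------
# initial conditions


def test_initial_state_exact_without_noise(baseline_params, baseline_steady):
    s = make_initial_state(baseline_params, snr_db=np.inf)
    np.testing.assert_allclose(
        s.values, np.broadcast_to(baseline_steady.densities[:, None],
                                  s.values.shape), rtol=1e-12)


def test_initial_state_deterministic(baseline_params):
    a = make_initial_state(baseline_params, snr_db=30.0, seed=7)
    b = make_initial_state(baseline_params, snr_db=30.0, seed=7)
    c = make_initial_state(baseline_params, snr_db=30.0, seed=8)
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_initial_state_noise_level_and_conservation(baseline_params,
                                                    baseline_steady):
    s = make_initial_state(baseline_params, snr_db=30.0, seed=1)
    rel = np.std(s.values, axis=1) / baseline_steady.densities
    # 30 dB -> ~3.2% relative fluctuations per field
    np.testing.assert_allclose(rel, 10 ** (-30 / 20), rtol=0.5)
    # copy numbers conserved exactly under clipping/renormalization
    tot = species_totals(s, baseline_params)
    assert tot["Rac1_total"] == pytest.approx(baseline_params.N_Rac1, rel=1e-12)
    assert tot["GAP_total"] == pytest.approx(baseline_params.N_GAP, rel=1e-12)
    assert tot["DGAP1_total"] == pytest.approx(baseline_params.N_DGAP1, rel=1e-12)


def test_seeded_pattern_conserves_and_has_requested_mode(baseline_params):
    s = make_initial_state(baseline_params, mode="seeded_pattern",
                           mode_order=2, amplitude=1.5, snr_db=np.inf)
    tot = species_totals(s, baseline_params)
    assert tot["Rac1_total"] == pytest.approx(baseline_params.N_Rac1, rel=1e-12)
    spec = np.abs(np.fft.rfft(s["rho_R"] - s["rho_R"].mean()))
    assert np.argmax(spec) == 2
    with pytest.raises(ValueError):
        make_initial_state(baseline_params, mode="seeded_pattern",
                           amplitude=1e6)
    with pytest.raises(ValueError):
        make_initial_state(baseline_params, mode="bogus")


def test_extensive_steady_state():
    p = ModelParameters().with_extensive_defaults()
    rho = solve_extensive_steady_state(p)
    assert rho.shape == (8,)
    assert np.all(rho >= 0)
    assert rho[0] + rho[1] + rho[3] + rho[6] + rho[7] == pytest.approx(
        p.N_Rac1 / p.L, abs=1e-8)


# ---------------------------------------------------------------------------
# integration


def test_stable_domain_stays_homogeneous():
    # a perimeter below the first instability threshold damps all modes
    p = ModelParameters(L=10.0, N_Rac1=5200.0 / 4, N_GAP=1200.0 / 4,
                        N_DGAP1=1600.0 / 4)
    init = make_initial_state(p, snr_db=40.0, seed=0, n_points=50)
    run = integrate(p, init, 400.0, cadence=10.0)
    final = run.values[:, -1, :]
    rel_spread = np.ptp(final, axis=1) / final.mean(axis=1)
    assert rel_spread.max() < 1e-3
    assert classify_pattern(run.kymograph(), discard_transient=200.0)[0] == \
        "homogeneous"


def test_baseline_run_is_mode1_traveling(baseline_run, baseline_transient):
    label, mode = classify_pattern(baseline_run.kymograph("rho_R"),
                                   discard_transient=baseline_transient)
    assert (label, mode) == ("traveling", 1)


def test_baseline_run_conserves_copy_numbers(baseline_run, baseline_params):
    first = species_totals(baseline_run.state_at(0), baseline_params)
    last = species_totals(baseline_run.state_at(-1), baseline_params)
    for key in first:
        assert abs(last[key] - first[key]) / first[key] < 1e-6


def test_baseline_run_nonnegative_and_below_saturation(baseline_run,
                                                       baseline_params):
    assert baseline_run.values.min() >= 0.0
    assert baseline_run.field("rho_R").max() < baseline_params.rho_Rmax
    assert baseline_run.field("rho_D").max() < baseline_params.rho_Dmax


def test_measured_speed_matches_linear_prediction(baseline_run,
                                                  baseline_params,
                                                  baseline_transient):
    from racwaves import autocorrelogram

    kymo = baseline_run.kymograph("rho_R")
    keep = kymo.times >= baseline_transient
    sub = Kymograph(kymo.values[keep], kymo.times[keep], kymo.angles)
    slope = autocorrelogram(sub).ridge_slope()
    measured = abs(slope) * baseline_params.L / (2.0 * np.pi)
    predicted = wave_speed(baseline_params)
    assert measured == pytest.approx(predicted, rel=0.20)


def test_field_sum_accessor(baseline_run):
    s = baseline_run.field("rho_D+rho_RD")
    np.testing.assert_allclose(
        s, baseline_run.field("rho_D") + baseline_run.field("rho_RD"))
    with pytest.raises(ValueError):
        baseline_run.field("rho_bogus")


def test_integrate_rejects_bad_model(baseline_params):
    init = make_initial_state(baseline_params, snr_db=np.inf, n_points=16)
    with pytest.raises(ValueError):
        integrate(baseline_params, init, 10.0, model="bogus")
    with pytest.raises(ValueError):
        integrate(baseline_params, init, 10.0, model="extensive")


def test_extensive_integration_conserves():
    p = ModelParameters().with_extensive_defaults()
    init = make_initial_state(p, snr_db=30.0, seed=2, extensive=True,
                              n_points=60)
    run = integrate(p, init, 100.0, model="extensive", cadence=20.0)
    first = species_totals(run.state_at(0), p)
    last = species_totals(run.state_at(-1), p)
    for key in first:
        assert abs(last[key] - first[key]) / first[key] < 1e-6


# ---------------------------------------------------------------------------
# pattern classification on constructed kymographs


def _kymo(f, n_t=300, m=60, dt=1.0):
    t = np.arange(n_t) * dt
    phi = np.arange(m) * 2 * np.pi / m
    return Kymograph(f(t[:, None], phi[None, :]), t, phi)


def test_classify_traveling():
    k = _kymo(lambda t, phi: 5 + np.cos(phi - 2 * np.pi * t / 100), n_t=350)
    assert classify_pattern(k) == ("traveling", 1)


def test_classify_standing():
    k = _kymo(lambda t, phi: 5 + np.cos(2 * phi) * np.cos(2 * np.pi * t / 100))
    assert classify_pattern(k) == ("standing", 2)


def test_classify_stationary():
    k = _kymo(lambda t, phi: 5 + np.cos(phi) + 0 * t)
    assert classify_pattern(k) == ("stationary", 1)


def test_classify_homogeneous():
    k = _kymo(lambda t, phi: 5 + 0 * phi + 0 * t)
    assert classify_pattern(k) == ("homogeneous", 0)


def test_classify_requires_enough_frames():
    k = _kymo(lambda t, phi: 5 + np.cos(phi) + 0 * t, n_t=10)
    with pytest.raises(InsufficientDataError):
        classify_pattern(k)


def test_classify_requires_three_periods():
    k = _kymo(lambda t, phi: 5 + np.cos(phi - 2 * np.pi * t / 100), n_t=250)
    with pytest.raises(InsufficientDataError):
        classify_pattern(k)


# ---------------------------------------------------------------------------
# windowed transitions


def test_transition_run_detects_reversal(baseline_run):
    # construct a direction flip halfway through the record
    n_t, m = 1200, 60
    t = np.arange(n_t, dtype=float)
    phi = np.arange(m) * 2 * np.pi / m
    omega = 2 * np.pi / 150
    sign = np.where(t < 600, 1.0, -1.0)
    vals = 5 + np.cos(phi[None, :] - (sign * omega * t)[:, None])
    kymo = Kymograph(vals, t, phi)

    class FakeResult:
        def kymograph(self, field="rho_R"):
            return kymo

    out = transition_run(FakeResult(), window=450.0, stride=150.0)
    labs = [l[0] for l in out["labels"]]
    assert labs.count("traveling") >= 2
    assert len(out["reversals"]) >= 1
    i = out["reversals"][0]
    assert np.sign(out["ridge_slopes"][i]) != np.sign(
        out["ridge_slopes"][i - 1])


def test_transition_run_on_baseline(baseline_run, baseline_transient):
    # each window must cover >= 3 oscillation periods (T ~ 284 s)
    out = transition_run(baseline_run, window=1000.0, stride=250.0,
                         discard_transient=baseline_transient)
    labs = [l for l in out["labels"]]
    assert all(lab == ("traveling", 1) for lab in labs)
    assert out["reversals"] == []
    # steady rotation: constant ridge slope across windows
    sl = out["ridge_slopes"]
    assert np.nanstd(sl) / abs(np.nanmean(sl)) < 0.05
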