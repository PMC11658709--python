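"""Semi-discrete integration of the membrane-cycling model on a periodic
ring, with initial-condition generation and pattern classification.

The perimeter is discretized into ``n_points`` uniformly spaced points
(100 by default); the cytoplasmic diffusion terms use the three-point
periodic second-difference stencil, and the resulting stiff ODE system is
integrated with a variable-step, variable-order backward-differentiation
solver.  Every output frame is checked against the three exact
conservation laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .kymo import Kymograph, autocorrelogram
from .model import (
    CONDENSED_FIELDS,
    EXTENSIVE_FIELDS,
    FieldState,
    _reaction_terms_condensed,
    _reaction_terms_extensive,
    diffusion_coefficients,
    species_totals,
)
from .parameters import ModelParameters
from .stability import solve_homogeneous_steady_state

__all__ = [
    "SimulationResult",
    "build_laplacian",
    "make_initial_state",
    "solve_extensive_steady_state",
    "integrate",
    "classify_pattern",
    "transition_run",
    "InsufficientDataError",
]

#: angular-fluctuation contrast below which a kymograph counts as homogeneous
HOMOGENEOUS_CONTRAST = 1e-3
#: fraction of the ideal single-ridge slope 2 pi / (n T) above which the
#: autocorrelogram ridge counts as moving
TRAVELING_SLOPE_FRACTION = 0.5
#: half-period anticorrelation threshold for the standing-wave call
STANDING_ACF_THRESHOLD = -0.2
#: mean zero-spatial-lag autocorrelation over positive temporal lags below
#: which the angular structure counts as unpersistent (noise, not pattern)
PERSISTENCE_THRESHOLD = 0.2


class InsufficientDataError(ValueError):
    """The record is too short for the requested classification."""


class IntegrationError(RuntimeError):
    def __init__(self, msg, last_time):
        super().__init__(f"{msg} (last good time {last_time:.1f} s)")
        self.last_time = last_time


def build_laplacian(L: float, n_points: int = 100) -> sparse.csr_matrix:
    """Periodic three-point second-difference operator on the ring.

    Circulant with stencil ``(1, −2, 1)/h²``, ``h = L/n_points``; row sums
    are zero, so constants are in the kernel and mass is conserved.
    """
    if n_points < 3:
        raise ValueError(f"need at least 3 grid points, got {n_points}")
    h = L / n_points
    main = -2.0 * np.ones(n_points)
    off = np.ones(n_points - 1)
    lap = sparse.diags([main, off, off], [0, 1, -1], format="lil")
    lap[0, -1] = 1.0
    lap[-1, 0] = 1.0
    return sparse.csr_matrix(lap) / h**2


def _extensive_balance(rho: np.ndarray, p: ModelParameters) -> np.ndarray:
    f = _reaction_terms_extensive(rho, p)
    r, R, g, RG, d, D, RD, m_ = rho
    return np.array([
        f[0], f[2], f[4], f[6], f[7],
        r + R + RG + RD + m_ - p.N_Rac1 / p.L,
        g + RG - p.N_GAP / p.L,
        d + D + RD - p.N_DGAP1 / p.L,
    ])


def solve_extensive_steady_state(params: ModelParameters, n_starts: int = 50,
                                 seed: int = 0, tol: float = 1e-10) -> np.ndarray:
    """Homogeneous fixed point of the extensive eight-field model (five
    independent balance equations plus the three conservation laws)."""
    if not params.has_extensive:
        raise ValueError("extensive rate constants are unset")
    tR, tG, tD = params.rho_Rtotal, params.rho_Gtotal, params.rho_Dtotal
    scale = np.array([tR, tR, tG, tG, tD, tD, tD, tR])
    scale = np.where(scale > 0, scale, 1.0)
    rng = np.random.default_rng(seed)
    best, best_res = None, np.inf
    start0 = np.array([0.5 * tR, 0.2 * tR, 0.7 * tG, 0.3 * tG,
                       0.5 * tD, 0.3 * tD, 0.2 * tD, 0.1 * tR])
    for trial in range(n_starts):
        guess = start0 if trial == 0 else rng.uniform(0.02, 0.98, 8) * scale
        sol = least_squares(_extensive_balance, guess, args=(params,),
                            bounds=(0.0, np.inf), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        res = np.max(np.abs(_extensive_balance(sol.x, params)))
        if res < best_res:
            best, best_res = sol.x, res
        if best_res < tol:
            break
    if best_res > max(tol, 1e-8):
        raise RuntimeError(
            f"no extensive steady state found (best residual {best_res:.3e})"
        )
    return best


def make_initial_state(
    params: ModelParameters,
    mode: str = "perturbed_steady",
    snr_db: float = 30.0,
    seed: int = 0,
    extensive: bool = False,
    n_points: int = 100,
    mode_order: int = 1,
    amplitude: float = 1.0,
) -> FieldState:
    """Initial condition on the ring.

    ``perturbed_steady`` adds white Gaussian noise to the homogeneous
    steady state, per field at the requested signal-to-noise ratio
    (noise std = mean · 10^(−snr_db/20)); negatives are clipped to zero
    and each field rescaled to its pre-noise total so all copy numbers
    are conserved exactly.  ``seeded_pattern`` superposes a single Fourier
    mode of the given order on the membrane Rac1-GTP pool, compensated in
    the cytoplasmic pool (zero-mean on the grid, hence conservative).
    """
    if np.isfinite(snr_db) and 10.0 ** (snr_db / 20.0) <= 0:
        raise ValueError("signal-to-noise ratio must be positive")
    if extensive:
        rho_s = solve_extensive_steady_state(params)
        names = EXTENSIVE_FIELDS
    else:
        rho_s = solve_homogeneous_steady_state(params).densities
        names = CONDENSED_FIELDS
    state = FieldState.homogeneous(rho_s, params, n_points=n_points,
                                   extensive=extensive)
    if mode == "seeded_pattern":
        wave = amplitude * np.cos(2.0 * np.pi * mode_order * state.grid / params.L)
        iR = names.index("rho_R")
        ir = names.index("rho_r")
        if amplitude > min(rho_s[iR], rho_s[ir]):
            raise ValueError("seed amplitude exceeds the steady-state level")
        state.values[iR] += wave
        state.values[ir] -= wave
    elif mode != "perturbed_steady":
        raise ValueError(f"unknown initial-condition mode {mode!r}")
    if not np.isfinite(snr_db):
        return state
    # white Gaussian noise at the requested per-field SNR; a seeded pattern
    # receives the same noise on top (this breaks the reflection symmetry
    # that otherwise pins a seeded standing wave on its invariant manifold)
    rng = np.random.default_rng(seed)
    targets = state.values.sum(axis=1).copy()
    noisy = state.values + rng.normal(
        0.0, 1.0, state.values.shape) * (rho_s * 10.0 ** (-snr_db / 20.0))[:, None]
    noisy = np.clip(noisy, 0.0, None)
    for k in range(len(names)):
        tot = noisy[k].sum()
        if tot > 0:
            noisy[k] *= targets[k] / tot
    state.values = noisy
    return state


@dataclass
class SimulationResult:
    """Density kymographs of one integration run."""

    times: np.ndarray               # (n_times,), s
    values: np.ndarray              # (n_fields, n_times, n_points), 1/μm
    grid: np.ndarray                # (n_points,), μm
    params: ModelParameters
    fields: tuple = dc_field(default=CONDENSED_FIELDS)
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def L(self) -> float:
        return self.params.L

    def field(self, name: str) -> np.ndarray:
        """(n_times, n_points) kymograph matrix of one density field, or a
        '+'-joined sum such as ``"rho_D+rho_RD"``."""
        parts = name.split("+")
        out = sum(self.values[self.fields.index(p.strip())] for p in parts)
        return np.asarray(out)

    def kymograph(self, name: str = "rho_R") -> Kymograph:
        return Kymograph(self.field(name), self.times,
                         2.0 * np.pi * self.grid / self.L, channel=name)

    def state_at(self, index: int) -> FieldState:
        return FieldState(self.values[:, index, :], self.grid, self.L,
                          fields=self.fields)


def _jac_sparsity(n_fields: int, n: int) -> sparse.csr_matrix:
    dense_block = sparse.kron(np.ones((n_fields, n_fields)), sparse.eye(n))
    tri = sparse.diags([np.ones(n), np.ones(n - 1), np.ones(n - 1)],
                       [0, 1, -1], format="lil")
    tri[0, -1] = 1
    tri[-1, 0] = 1
    return sparse.csr_matrix(dense_block + sparse.kron(sparse.eye(n_fields), tri))


def integrate(
    params: ModelParameters,
    init: FieldState,
    t_end: float,
    model: str = "condensed",
    cadence: float = 1.0,
    t_start: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    conservation_tol: float = 1e-4,
    negative_floor: float = 1e-6,
) -> SimulationResult:
    """Integrate the reaction-diffusion system on the ring.

    Output is sampled on a uniform grid with spacing ``cadence``.  A
    relative drift of any conserved copy number beyond
    ``conservation_tol`` aborts; densities that undershoot zero by less
    than ``negative_floor`` (solver-tolerance scale) are floored, larger
    negatives abort.
    """
    if model not in ("condensed", "extensive"):
        raise ValueError(f"unknown model {model!r}")
    extensive = model == "extensive"
    if extensive and not params.has_extensive:
        raise ValueError("extensive rate constants are unset")
    want = EXTENSIVE_FIELDS if extensive else CONDENSED_FIELDS
    if init.fields != want:
        raise ValueError(f"initial state must carry the fields {want}")
    n = init.n_points
    n_fields = len(want)
    lap = build_laplacian(params.L, n)
    diff = diffusion_coefficients(params, extensive=extensive)
    react = _reaction_terms_extensive if extensive else _reaction_terms_condensed

    def rhs(t, y):
        rho = y.reshape(n_fields, n)
        out = react(rho, params)
        for k in range(n_fields):
            if diff[k]:
                out[k] += diff[k] * (lap @ rho[k])
        return out.ravel()

    t_eval = np.arange(t_start, t_end + 0.5 * cadence, cadence)
    sol = solve_ivp(
        rhs, (t_start, t_end), init.values.ravel(), method="BDF",
        t_eval=t_eval, rtol=rtol, atol=atol,
        jac_sparsity=_jac_sparsity(n_fields, n),
    )
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_start
        raise IntegrationError(f"stiff integrator failed: {sol.message}", last)
    vals = sol.y.reshape(n_fields, n, sol.t.size).transpose(0, 2, 1)
    worst = vals.min()
    if worst < -negative_floor:
        raise IntegrationError(
            f"density undershoot {worst:.3e} exceeds the negative-floor "
            f"tolerance {negative_floor:.1e}", float(sol.t[-1]),
        )
    vals = np.clip(vals, 0.0, None)
    result = SimulationResult(
        times=sol.t, values=vals, grid=init.grid, params=params, fields=want,
        diagnostics={"n_steps": int(sol.t.size), "nfev": int(sol.nfev),
                     "njev": int(sol.njev), "rtol": rtol, "atol": atol},
    )
    ref = species_totals(init, params)
    for i in (0, vals.shape[1] - 1):
        now = species_totals(result.state_at(i), params)
        for key, target in ref.items():
            if target > 0 and abs(now[key] - target) / target > conservation_tol:
                raise IntegrationError(
                    f"conservation drift in {key}: {now[key]:.6g} vs "
                    f"{target:.6g}", float(sol.t[i]),
                )
    return result


def _dominant_mode(I: np.ndarray) -> int:
    """Dominant angular Fourier order from the time-averaged spatial power
    spectrum (mode 0 excluded)."""
    power = (np.abs(np.fft.rfft(I, axis=1)) ** 2).mean(axis=0)
    if power.size < 2:
        return 0
    return int(np.argmax(power[1:])) + 1


def classify_pattern(kymo: Kymograph, discard_transient: float = 0.0
                     ) -> Tuple[str, int]:
    """Classify a kymograph as homogeneous, stationary, traveling or
    standing, together with its dominant angular mode order.

    Decision sequence: angular contrast below :data:`HOMOGENEOUS_CONTRAST`
    → homogeneous; an autocorrelogram ridge moving faster than
    :data:`TRAVELING_SLOPE_FRACTION` of the single-ridge speed 2π/(nT) →
    traveling; a stalled ridge with half-period anticorrelation
    A(0, T/2) < :data:`STANDING_ACF_THRESHOLD` → standing; persistent
    contrast without temporal recurrence → stationary.
    """
    keep = kymo.times >= kymo.times[0] + discard_transient
    if keep.sum() < 16:
        raise InsufficientDataError("fewer than 16 frames after the transient")
    I = kymo.values[keep]
    times = kymo.times[keep]
    sub = Kymograph(I, times, kymo.angles, kymo.channel)
    dI = I - I.mean(axis=1, keepdims=True)
    base = np.abs(I).mean()
    contrast = np.sqrt((dI ** 2).mean()) / base if base > 0 else 0.0
    if contrast < HOMOGENEOUS_CONTRAST:
        return "homogeneous", 0
    n_mode = _dominant_mode(I)
    acf = autocorrelogram(sub)
    T = acf.temporal_period()
    dt = float(np.mean(np.diff(times)))
    if T is not None and T < 8.0 * dt:
        # a recurrence shorter than 8 frames is a noise artifact, not an
        # oscillation the frame rate could resolve
        T = None
    j_zero = int(np.argmin(np.abs(acf.dphi)))
    lagged = acf.dt > 0
    persistence = float(acf.values[lagged, j_zero].mean())
    if T is None:
        if persistence < PERSISTENCE_THRESHOLD:
            # contrast without temporal persistence is uncorrelated noise
            return "homogeneous", 0
        return "stationary", n_mode
    if times[-1] - times[0] < 3.0 * T:
        raise InsufficientDataError(
            f"record covers less than 3 putative periods (T ~ {T:.0f} s)"
        )
    slope = acf.ridge_slope(max_lag=0.45 * T)
    ridge_ref = 2.0 * np.pi / (max(n_mode, 1) * T)
    if abs(slope) >= TRAVELING_SLOPE_FRACTION * ridge_ref:
        return "traveling", n_mode
    i_half = int(np.argmin(np.abs(acf.dt - 0.5 * T)))
    if acf.values[i_half, j_zero] < STANDING_ACF_THRESHOLD:
        return "standing", n_mode
    if persistence < PERSISTENCE_THRESHOLD:
        return "homogeneous", 0
    return "stationary", n_mode


def transition_run(
    result: SimulationResult,
    field: str = "rho_R",
    window: float = 600.0,
    stride: Optional[float] = None,
    discard_transient: float = 0.0,
) -> dict:
    """Windowed pattern classification of one run, for detecting
    oscillation-to-rotation transitions and direction reversals.

    Returns window center times, per-window (class, mode) labels, the
    per-window ridge slopes, and the indices of windows at which a
    traveling ridge reverses direction.
    """
    kymo = result.kymograph(field)
    if stride is None:
        stride = window / 2.0
    t0 = kymo.times[0] + discard_transient
    starts = np.arange(t0, kymo.times[-1] - window + 1e-9, stride)
    if starts.size == 0:
        raise InsufficientDataError("record shorter than one window")
    centers, labels, slopes = [], [], []
    for s in starts:
        sel = (kymo.times >= s) & (kymo.times <= s + window)
        sub = Kymograph(kymo.values[sel], kymo.times[sel], kymo.angles)
        try:
            lab = classify_pattern(sub)
        except InsufficientDataError:
            continue
        try:
            acf = autocorrelogram(sub)
            slope = acf.ridge_slope()
        except ValueError:
            slope = np.nan
        centers.append(s + window / 2.0)
        labels.append(lab)
        slopes.append(slope)
    slopes = np.asarray(slopes)
    reversals = []
    prev = None
    for i, (lab, sl) in enumerate(zip(labels, slopes)):
        if lab[0] == "traveling" and np.isfinite(sl):
            if prev is not None and np.sign(sl) != np.sign(prev) and sl != 0:
                reversals.append(i)
            prev = sl
    return {
        "centers": np.asarray(centers),
        "labels": labels,
        "ridge_slopes": slopes,
        "reversals": reversals,
    }
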