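"""Linear stability analysis of the homogeneous steady state.

The homogeneous fixed point of the seven-species cycle satisfies four
independent reaction-balance equations together with three conservation
constraints (one per protein).  Perturbations ``δρ ∝ exp(σ_q t + i q x)``
on the periodic perimeter obey ``σ_q δρ_q = (J − q² 𝔇) δρ_q`` with J the
reaction Jacobian and 𝔇 the diagonal diffusion matrix, so the growth rates
σ_q are eigenvalues of ``M_q = J − q² 𝔇``.  A wavenumber with a positive
leading real part is unstable: oscillatory (Hopf) when the leading
eigenvalue is complex, stationary (Turing) when it is real.

The marginal wavenumber ``q_m`` — where the leading real part crosses zero
at the upper edge of the unstable band — sets the traveling-wave speed
``v = Im σ(q_m) / q_m``, which is the quantity probed by the local
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares

from .model import CONDENSED_FIELDS, _reaction_terms_condensed, reaction_jacobian
from .parameters import ModelParameters

__all__ = [
    "SteadyState",
    "DispersionResult",
    "SensitivityResult",
    "solve_homogeneous_steady_state",
    "jacobian",
    "diffusion_matrix",
    "dispersion_relation",
    "marginal_wavenumber",
    "wave_speed",
    "sensitivity",
    "min_length_for_mode",
    "regime_diagram",
]

#: absolute threshold below which Re/Im parts count as zero
ZERO_TOL = 1e-9


class NoInstabilityError(RuntimeError):
    """Raised when no unstable band exists for the requested parameters."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual):
        super().__init__(f"{msg} (best residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class SteadyState:
    """Homogeneous fixed point of the condensed model."""

    densities: np.ndarray          # seven values, ordered as CONDENSED_FIELDS
    residual: float                # max-norm of the balance + conservation eqs

    def __getitem__(self, name: str) -> float:
        return float(self.densities[CONDENSED_FIELDS.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(CONDENSED_FIELDS, self.densities))


@dataclass
class DispersionResult:
    """Eigenvalue spectrum over the discrete Fourier wavenumbers."""

    wavenumbers: np.ndarray        # q_n = 2 pi n / L, n = 0..n_max
    eigenvalues: np.ndarray        # (n_max+1, 7) complex, sorted by Re desc
    leading: np.ndarray            # leading growth rate per q
    mode_class: list               # per-q label
    classification: str            # overall: stable/Turing/Hopf/Turing-Hopf
    unstable_modes: list           # n indices with Re > 0

    @property
    def n_modes(self) -> int:
        return len(self.wavenumbers)


@dataclass(frozen=True)
class SensitivityResult:
    """Normalized local sensitivity of the wave speed to one parameter."""

    parameter: str
    baseline: float
    rel_step: float
    v0: float
    S: float


def _conservation_targets(p: ModelParameters) -> Tuple[float, float, float]:
    return p.N_Rac1 / p.L, p.N_GAP / p.L, p.N_DGAP1 / p.L


def _balance_residual(rho: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Four independent balance equations + three conservation equations."""
    f = _reaction_terms_condensed(rho, p)
    r, R, g, RG, d, D, RD = rho
    tR, tG, tD = _conservation_targets(p)
    return np.array([
        f[0], f[2], f[4], f[6],
        r + R + RG + RD - tR,
        g + RG - tG,
        d + D + RD - tD,
    ])


def solve_homogeneous_steady_state(
    params: ModelParameters,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-10,
    x0: Optional[np.ndarray] = None,
) -> SteadyState:
    """Solve the four balance + three conservation equations for the unique
    non-negative homogeneous fixed point.

    A deterministic multi-start trust-region least-squares search is used;
    ``x0`` may supply a warm start (e.g. continuation along a parameter
    scan), which is tried first.
    """
    tR, tG, tD = _conservation_targets(params)
    scale = np.array([tR, tR, tG, tG, tD, tD, tD])
    scale = np.where(scale > 0, scale, 1.0)

    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), 0, None))
    starts.append(np.array([0.6 * tR, 0.2 * tR, 0.7 * tG, 0.3 * tG,
                            0.5 * tD, 0.3 * tD, 0.2 * tD]))
    rng = np.random.default_rng(seed)

    best_x, best_res = None, np.inf
    for trial in range(n_starts):
        guess = starts[trial] if trial < len(starts) else rng.uniform(0.02, 0.98, 7) * scale
        sol = least_squares(
            _balance_residual, guess, args=(params,), bounds=(0.0, np.inf),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        res = np.max(np.abs(_balance_residual(sol.x, params)))
        if res < best_res:
            best_x, best_res = sol.x, res
        if best_res < tol:
            break
    if best_res > max(tol, 1e-8):
        raise ConvergenceError("no non-negative steady-state root found", best_res)
    return SteadyState(densities=best_x, residual=best_res)


def jacobian(params: ModelParameters, steady: SteadyState) -> np.ndarray:
    """Analytic Jacobian of the reaction terms at the steady state."""
    return reaction_jacobian(steady.densities, params)


def diffusion_matrix(params: ModelParameters) -> np.ndarray:
    """Diagonal diffusion matrix: Dr, Dg, Dd on the cytoplasmic rows."""
    return np.diag([params.Dr, 0.0, params.Dg, 0.0, params.Dd, 0.0, 0.0])


def _leading(ev: np.ndarray) -> complex:
    """Leading eigenvalue: maximum real part, ties broken by larger |Im|."""
    order = np.lexsort((np.abs(ev.imag), ev.real))
    return ev[order[-1]]


def _classify_eig(lead: complex) -> str:
    if lead.real <= ZERO_TOL:
        return "stable"
    return "Hopf" if abs(lead.imag) > ZERO_TOL else "Turing"


def dispersion_relation(
    params: ModelParameters,
    n_max: int = 10,
    steady: Optional[SteadyState] = None,
) -> DispersionResult:
    """Eigenvalues of ``M_q = J − q² 𝔇`` on the discrete wavenumbers
    ``q = 2 pi n / L`` for ``n = 0..n_max`` with per-mode classification.

    The three conservation-induced zero modes at ``q = 0`` are neutral,
    not unstable, and are excluded from the classification.
    """
    if steady is None:
        steady = solve_homogeneous_steady_state(params)
    J = jacobian(params, steady)
    Dm = diffusion_matrix(params)
    qs = 2.0 * np.pi * np.arange(n_max + 1) / params.L
    eigs = np.empty((n_max + 1, 7), dtype=complex)
    leading = np.empty(n_max + 1, dtype=complex)
    labels = []
    unstable = []
    for i, q in enumerate(qs):
        try:
            ev = np.linalg.eigvals(J - q * q * Dm)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"eigenvalue solver failed at q={q:.4g}") from exc
        eigs[i] = ev[np.argsort(-ev.real)]
        lead = _leading(ev)
        leading[i] = lead
        if i == 0:
            labels.append("neutral")  # conservation zero modes
            continue
        lab = _classify_eig(lead)
        labels.append(lab)
        if lab != "stable":
            unstable.append(i)
    kinds = {labels[i] for i in unstable}
    if not kinds:
        overall = "stable"
    elif kinds == {"Turing"}:
        overall = "Turing"
    elif kinds == {"Hopf"}:
        overall = "Hopf"
    else:
        overall = "Turing-Hopf"
    return DispersionResult(
        wavenumbers=qs, eigenvalues=eigs, leading=leading,
        mode_class=labels, classification=overall, unstable_modes=unstable,
    )


def _lead_re(q: float, J: np.ndarray, Dm: np.ndarray) -> float:
    return _leading(np.linalg.eigvals(J - q * q * Dm)).real


def marginal_wavenumber(
    params: ModelParameters,
    steady: Optional[SteadyState] = None,
    q_max: float = 3.0,
    n_scan: int = 400,
) -> float:
    """Upper edge ``q_m`` of the unstable band on the continuum dispersion
    relation, bisected to relative precision 1e-8.

    Raises :class:`NoInstabilityError` when the leading real part never
    becomes positive over the scan range.
    """
    if steady is None:
        steady = solve_homogeneous_steady_state(params)
    J = jacobian(params, steady)
    Dm = diffusion_matrix(params)
    qs = np.linspace(q_max / n_scan, q_max, n_scan)
    re = np.array([_lead_re(q, J, Dm) for q in qs])
    crossings = np.where((re[:-1] > 0) & (re[1:] <= 0))[0]
    if crossings.size == 0:
        raise NoInstabilityError(
            "leading growth rate never crosses zero from above; "
            "no unstable band in (0, q_max)"
        )
    i = crossings[-1]
    return brentq(_lead_re, qs[i], qs[i + 1], args=(J, Dm), xtol=1e-14, rtol=1e-10)


def _marginal_eigenvalue(qm: float, J: np.ndarray, Dm: np.ndarray,
                         n_track: int = 40) -> complex:
    """Eigenvalue of the branch that crosses Re = 0 at q_m.

    The branch is followed from inside the unstable band up to q_m by
    nearest-neighbor matching in the complex plane; at q_m the tracked
    branch coincides with the leading eigenvalue (its real part is zero
    there by construction), which guards against branch switching.
    """
    qs = np.linspace(0.9 * qm, qm, n_track)
    current = _leading(np.linalg.eigvals(J - qs[0] ** 2 * Dm))
    for q in qs[1:]:
        ev = np.linalg.eigvals(J - q * q * Dm)
        current = ev[np.argmin(np.abs(ev - current))]
    return current


def wave_speed(
    params: ModelParameters,
    steady: Optional[SteadyState] = None,
    return_qm: bool = False,
):
    """Traveling-wave speed ``v = |Im σ(q_m)| / q_m`` from the marginally
    stable mode.

    A purely real marginal eigenvalue yields ``v = 0`` (stationary
    bifurcation).  The spectrum at ``−q`` is the complex conjugate of the
    spectrum at ``+q``, so speeds come in ± pairs; the magnitude is
    reported.
    """
    if steady is None:
        steady = solve_homogeneous_steady_state(params)
    qm = marginal_wavenumber(params, steady=steady)
    J = jacobian(params, steady)
    Dm = diffusion_matrix(params)
    sigma = _marginal_eigenvalue(qm, J, Dm)
    v = abs(sigma.imag) / qm if abs(sigma.imag) > ZERO_TOL else 0.0
    return (v, qm) if return_qm else v


# parameters the sensitivity scan knows how to perturb
_SIMPLE_PARAMS = ("k1", "k11", "k12", "k2", "k3a", "k4", "k41", "k42",
                  "k5", "k6a", "k6b", "Dr", "Dg", "Dd")


def _perturb(params: ModelParameters, name: str, rel: float) -> ModelParameters:
    if name in _SIMPLE_PARAMS:
        return params.replace(**{name: getattr(params, name) * (1.0 + rel)})
    if name == "rho_Rmax":
        return params.with_rho_Rmax(params.rho_Rmax * (1.0 + rel))
    if name == "rho_Dmax":
        return params.with_rho_Dmax(params.rho_Dmax * (1.0 + rel))
    if name == "rho_Rtotal":
        return params.replace(N_Rac1=params.N_Rac1 * (1.0 + rel))
    if name == "rho_Gtotal":
        return params.replace(N_GAP=params.N_GAP * (1.0 + rel))
    if name == "rho_Dtotal":
        return params.replace(N_DGAP1=params.N_DGAP1 * (1.0 + rel))
    raise KeyError(f"unknown sensitivity parameter {name!r}")


def sensitivity(
    params: ModelParameters,
    param_name: str,
    rel_step: float = 0.01,
) -> SensitivityResult:
    """Normalized sensitivity ``S = (Δv/v0) / (Δp/p0)`` of the wave speed.

    Total densities are varied as ``rho_total = N/L``; the saturation
    densities are varied with the intrinsic-constant rescaling of
    :meth:`ModelParameters.with_rho_Rmax` (the stored binding constants are
    pre-multiplied by the saturation density).
    """
    v0 = wave_speed(params)
    if v0 == 0.0:
        raise NoInstabilityError("wave speed undefined at baseline (stationary)")
    try:
        v1 = wave_speed(_perturb(params, param_name, rel_step))
    except NoInstabilityError as exc:
        raise RuntimeError(
            f"wave speed undefined after perturbing {param_name} by "
            f"{rel_step:+.2%}; try a smaller step"
        ) from exc
    if param_name in _SIMPLE_PARAMS:
        baseline = getattr(params, param_name)
    elif param_name in ("rho_Rmax", "rho_Dmax"):
        baseline = getattr(params, param_name)
    else:
        baseline = getattr(params, param_name)
    S = (v1 - v0) / v0 / rel_step
    return SensitivityResult(parameter=param_name, baseline=baseline,
                             rel_step=rel_step, v0=v0, S=S)


def min_length_for_mode(params: ModelParameters, n: int) -> float:
    """Minimum perimeter ``L_n_min = 2 n pi / q_m`` at which the n-th
    Fourier mode becomes unstable, with linear total densities held fixed
    as L varies."""
    if n < 1:
        raise ValueError("mode order n must be >= 1")
    qm = marginal_wavenumber(params)
    return 2.0 * np.pi * n / qm


def regime_diagram(
    params: ModelParameters,
    axis1: Tuple[str, Sequence[float]],
    axis2: Tuple[str, Sequence[float]],
    n_max: int = 10,
) -> dict:
    """Classification grid over two parameter axes.

    Axis names are ModelParameters attributes (typically copy numbers or
    diffusion coefficients).  Returns a dict with the axes, a grid of
    string labels (axis2 rows x axis1 columns; per-point failures are
    recorded as ``"missing"``), and a parallel grid flagging points where
    only the first Fourier mode is unstable.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    labels = np.empty((len(vals2), len(vals1)), dtype=object)
    first_only = np.zeros((len(vals2), len(vals1)), dtype=bool)
    warm = None
    for i, v2 in enumerate(vals2):
        for j, v1 in enumerate(vals1):
            p = params.replace(**{name1: float(v1), name2: float(v2)})
            try:
                ss = solve_homogeneous_steady_state(p, x0=warm)
                warm = ss.densities
                disp = dispersion_relation(p, n_max=n_max, steady=ss)
                labels[i, j] = disp.classification
                first_only[i, j] = disp.unstable_modes == [1]
            except (ConvergenceError, ValueError):
                labels[i, j] = "missing"
    return {
        "axis1": (name1, np.asarray(vals1, dtype=float)),
        "axis2": (name2, np.asarray(vals2, dtype=float)),
        "labels": labels,
        "first_mode_only": first_only,
    }
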