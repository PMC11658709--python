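"""Finite-difference reaction-diffusion solver on a disk (Rac1 + GAP
cycle only) with flux-based membrane coupling.

The disk of radius R is segmented into ``n`` concentric rings of width
``h = R/n`` and ``m`` angular segments of width ``Δφ = 2π/m``.  The two
cytoplasmic species (inactive Rac1 and free GAP, area densities 1/μm²)
diffuse via a conservative flux-form Laplacian; the two membrane species
(active Rac1 and the Rac1-GAP complex, line densities 1/μm) live on the
outer rim and exchange with the boundary ring through reaction fluxes.
The membrane rate constants are "primed": bimolecular steps that couple a
cytoplasmic area density to the membrane carry an extra length factor
relative to their 1D counterparts (see :func:`convert_rates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .kymo import Kymograph

__all__ = [
    "Params2D",
    "DiskGrid",
    "DiskState",
    "Disk2DResult",
    "convert_rates",
    "polar_laplacian",
    "membrane_flux",
    "solve_steady_2d",
    "make_initial_state_2d",
    "integrate_2d",
]


@dataclass(frozen=True)
class Params2D:
    """Disk-model parameters with primed membrane rate constants.

    Defaults are the published traveling-wave disk configuration
    (R = 6 μm, N_Rac1 = 7600, N_GAP = 2000); the standing-wave variant
    differs only in N_Rac1 = 6900.
    """

    k1p: float = 1.6e-2       # μm/s, membrane binding + activation
    k11p: float = 3.2e-3      # μm²/s, autocatalytic recruitment
    k12p: float = 4.8e-3      # μm²/s, complex-assisted recruitment
    k2p: float = 2.5          # μm²/s, GAP binding to membrane Rac1-GTP
    k3: float = 0.3           # 1/s, complex dissociation to the cytoplasm
    rho_Rmax: float = 200.0   # 1/μm, membrane saturation density
    R: float = 6.0            # μm, disk radius
    Dr: float = 30.0          # μm²/s
    Dg: float = 8.0           # μm²/s
    N_Rac1: float = 7600.0
    N_GAP: float = 2000.0

    def __post_init__(self):
        for name in ("k1p", "k11p", "k12p", "k2p", "k3", "Dr", "Dg",
                     "N_Rac1", "N_GAP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.R <= 0 or self.rho_Rmax <= 0:
            raise ValueError("R and rho_Rmax must be positive")

    def replace(self, **changes) -> "Params2D":
        import dataclasses
        return dataclasses.replace(self, **changes)


def convert_rates(k: float, rho_1d: float, rho_2d_boundary: float) -> float:
    """Primed membrane rate constant ``k' = k · ρ_1d / ρ_2d`` from the 1D
    constant and the homogeneous reference densities of the cytoplasmic
    reactant in the two descriptions."""
    if rho_1d <= 0 or rho_2d_boundary <= 0:
        raise ValueError("reference densities must be positive")
    return k * rho_1d / rho_2d_boundary


@dataclass(frozen=True)
class DiskGrid:
    """Polar finite-volume grid: n rings × m angular segments."""

    n_rings: int
    m: int
    R: float

    def __post_init__(self):
        if self.n_rings < 2 or self.m < 3:
            raise ValueError("need at least 2 rings and 3 angular segments")
        if self.R <= 0:
            raise ValueError("disk radius must be positive")

    @property
    def h(self) -> float:
        return self.R / self.n_rings

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.m

    @property
    def r_centers(self) -> np.ndarray:
        """Ring centers r_i = (2i−1)h/2."""
        return (2.0 * np.arange(1, self.n_rings + 1) - 1.0) * self.h / 2.0

    @property
    def r_edges(self) -> np.ndarray:
        """Ring edges r_{i−1/2} = (i−1)h, i = 1..n+1."""
        return np.arange(self.n_rings + 1) * self.h

    @property
    def areas(self) -> np.ndarray:
        """Segment areas A_i = r_i h Δφ (exactly tiling the disk)."""
        return self.r_centers * self.h * self.dphi

    @property
    def boundary_length(self) -> float:
        """Arc length of one membrane segment, R Δφ."""
        return self.R * self.dphi

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.m) * self.dphi

    def total_area(self) -> float:
        return float(self.areas.sum() * self.m)


def polar_laplacian(field: np.ndarray, grid: DiskGrid, D: float) -> np.ndarray:
    """Diffusive time-derivative contribution on the disk in flux form.

    Radial part: ``(1/A_i)(Δl_{i+1/2} J_{i+1/2} − Δl_{i−1/2} J_{i−1/2})``
    with ``J = D ∂ρ/∂r`` discretized centrally; the flux through r = 0
    vanishes by construction and the outer flux is zero here (membrane
    exchange is applied separately).  Angular part: periodic second
    difference divided by ``r_i² Δφ²``.
    """
    if field.shape != (grid.n_rings, grid.m):
        raise ValueError(
            f"field must be ({grid.n_rings}, {grid.m}), got {field.shape}"
        )
    h = grid.h
    ri = grid.r_centers
    redge = grid.r_edges
    out = np.zeros_like(field)
    # radial fluxes across interior edges (telescoping -> exact conservation)
    c_out = (redge[1:-1] / (ri[:-1] * h * h))[:, None]
    c_in = (redge[1:-1] / (ri[1:] * h * h))[:, None]
    diff = field[1:] - field[:-1]
    out[:-1] += c_out * diff
    out[1:] -= c_in * diff
    ang = np.roll(field, -1, axis=1) - 2.0 * field + np.roll(field, 1, axis=1)
    out += ang / (ri**2 * grid.dphi**2)[:, None]
    return D * out


def membrane_flux(cyto_r: np.ndarray, cyto_g: np.ndarray, rho_R: np.ndarray,
                  rho_RG: np.ndarray, params: Params2D) -> tuple:
    """Reaction fluxes (1/(μm·s)) from the boundary ring onto the membrane.

    Rac1: saturating (auto)catalytic binding of boundary cytoplasmic Rac1
    minus complex dissociation.  GAP: complex formation from boundary GAP
    and membrane Rac1-GTP minus the same dissociation, by exact analogy
    (only this reading conserves both species).
    """
    sat = np.maximum(1.0 - rho_R / params.rho_Rmax, 0.0)
    bind = cyto_r * sat * (params.k1p + params.k11p * rho_R + params.k12p * rho_RG)
    J_r = bind - params.k3 * rho_RG
    J_g = params.k2p * cyto_g * rho_R - params.k3 * rho_RG
    return J_r, J_g


def solve_steady_2d(params: Params2D, n_starts: int = 40, seed: int = 0,
                    tol: float = 1e-9) -> np.ndarray:
    """Homogeneous fixed point (c_r, c_g, ρ_R, ρ_RG) of the coupled disk
    system: zero net membrane fluxes plus the two copy-number constraints
    ``A c + P ρ_membrane = N`` (A = disk area, P = perimeter)."""
    area = np.pi * params.R**2
    per = 2.0 * np.pi * params.R

    def res(x):
        cr, cg, rR, rRG = x
        J_r, J_g = membrane_flux(cr, cg, rR, rRG, params)
        return np.array([
            J_r, J_g,
            area * cr + per * (rR + rRG) - params.N_Rac1,
            area * cg + per * rRG - params.N_GAP,
        ])

    rng = np.random.default_rng(seed)
    scale = np.array([params.N_Rac1 / area, params.N_GAP / area,
                      0.5 * params.rho_Rmax, 0.25 * params.rho_Rmax])
    best, best_res = None, np.inf
    for trial in range(n_starts):
        x0 = (np.array([0.8, 0.8, 0.3, 0.1]) if trial == 0
              else rng.uniform(0.05, 0.95, 4)) * scale
        sol = least_squares(res, x0, bounds=(0.0, np.inf),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        r = np.max(np.abs(res(sol.x)))
        if r < best_res:
            best, best_res = sol.x, r
        if best_res < tol:
            break
    if best_res > max(tol, 1e-7):
        raise RuntimeError(
            f"no homogeneous disk steady state found (residual {best_res:.3e})"
        )
    return best


@dataclass
class DiskState:
    """Cytoplasmic area densities and membrane line densities."""

    cyto_r: np.ndarray     # (n_rings, m), 1/μm²
    cyto_g: np.ndarray     # (n_rings, m), 1/μm²
    rho_R: np.ndarray      # (m,), 1/μm
    rho_RG: np.ndarray     # (m,), 1/μm

    def totals(self, grid: DiskGrid) -> dict:
        A = grid.areas[:, None]
        dl = grid.boundary_length
        return {
            "Rac1_total": float((A * self.cyto_r).sum()
                                + dl * (self.rho_R.sum() + self.rho_RG.sum())),
            "GAP_total": float((A * self.cyto_g).sum() + dl * self.rho_RG.sum()),
        }


def make_initial_state_2d(params: Params2D, grid: DiskGrid,
                          snr_db: float = 30.0, seed: int = 0) -> DiskState:
    """Homogeneous disk steady state with multiplicative white Gaussian
    noise at the given SNR (no noise when snr_db is infinite)."""
    cr, cg, rR, rRG = solve_steady_2d(params)
    shape = (grid.n_rings, grid.m)
    if not np.isfinite(snr_db):
        return DiskState(np.full(shape, cr), np.full(shape, cg),
                         np.full(grid.m, rR), np.full(grid.m, rRG))
    amp = 10.0 ** (-snr_db / 20.0)
    rng = np.random.default_rng(seed)
    mk = lambda base, shp: np.clip(
        base * (1.0 + amp * rng.standard_normal(shp)), 0.0, None)
    return DiskState(mk(cr, shape), mk(cg, shape), mk(rR, grid.m), mk(rRG, grid.m))


@dataclass
class Disk2DResult:
    """Membrane kymographs plus cytoplasm snapshots of one disk run."""

    times: np.ndarray          # (n_times,)
    rho_R: np.ndarray          # (n_times, m)
    rho_RG: np.ndarray         # (n_times, m)
    cyto_times: np.ndarray     # (n_snap,)
    cyto_r: np.ndarray         # (n_snap, n_rings, m)
    cyto_g: np.ndarray         # (n_snap, n_rings, m)
    grid: DiskGrid = None
    params: Params2D = None
    diagnostics: dict = dc_field(default_factory=dict)

    def kymograph(self, name: str = "rho_R") -> Kymograph:
        mat = {"rho_R": self.rho_R, "rho_RG": self.rho_RG,
               "rho_R+rho_RG": self.rho_R + self.rho_RG}[name]
        return Kymograph(mat, self.times, self.grid.angles, channel=name)

    def state_at(self, snap_index: int) -> DiskState:
        t = self.cyto_times[snap_index]
        i = int(np.argmin(np.abs(self.times - t)))
        return DiskState(self.cyto_r[snap_index], self.cyto_g[snap_index],
                         self.rho_R[i], self.rho_RG[i])


def integrate_2d(
    params: Params2D,
    grid: DiskGrid,
    init: DiskState,
    t_end: float,
    cadence: float = 10.0,
    snapshot_every: int = 10,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    conservation_tol: float = 1e-4,
    reactions_enabled: bool = True,
) -> Disk2DResult:
    """Integrate the coupled cytoplasm + membrane system with a stiff
    variable-order BDF solver; conservation of both copy numbers is
    verified on the output."""
    n, m = grid.n_rings, grid.m
    ncy = n * m
    c_mem = grid.r_edges[-1] / (grid.r_centers[-1] * grid.h)

    def rhs(t, y):
        cr = y[:ncy].reshape(n, m)
        cg = y[ncy:2 * ncy].reshape(n, m)
        rR = y[2 * ncy:2 * ncy + m]
        rRG = y[2 * ncy + m:]
        d_cr = polar_laplacian(cr, grid, params.Dr)
        d_cg = polar_laplacian(cg, grid, params.Dg)
        if reactions_enabled:
            J_r, J_g = membrane_flux(cr[-1], cg[-1], rR, rRG, params)
            d_cr[-1] -= c_mem * J_r
            d_cg[-1] -= c_mem * J_g
            d_rR = J_r + params.k3 * rRG - params.k2p * cg[-1] * rR
            d_rRG = params.k2p * cg[-1] * rR - params.k3 * rRG
        else:
            d_rR = np.zeros(m)
            d_rRG = np.zeros(m)
        return np.concatenate([d_cr.ravel(), d_cg.ravel(), d_rR, d_rRG])

    y0 = np.concatenate([init.cyto_r.ravel(), init.cyto_g.ravel(),
                         init.rho_R, init.rho_RG])
    t_eval = np.arange(0.0, t_end + 0.5 * cadence, cadence)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
                    rtol=rtol, atol=atol, jac_sparsity=_sparsity(n, m))
    if not sol.success:
        last = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"disk integration failed: {sol.message} (last good time {last:.1f} s)"
        )
    nt = sol.t.size
    cr_t = sol.y[:ncy].reshape(n, m, nt)
    cg_t = sol.y[ncy:2 * ncy].reshape(n, m, nt)
    snap_idx = np.arange(0, nt, snapshot_every)
    result = Disk2DResult(
        times=sol.t,
        rho_R=np.clip(sol.y[2 * ncy:2 * ncy + m].T, 0.0, None),
        rho_RG=np.clip(sol.y[2 * ncy + m:].T, 0.0, None),
        cyto_times=sol.t[snap_idx],
        cyto_r=np.transpose(cr_t[:, :, snap_idx], (2, 0, 1)),
        cyto_g=np.transpose(cg_t[:, :, snap_idx], (2, 0, 1)),
        grid=grid, params=params,
        diagnostics={"nfev": int(sol.nfev), "rtol": rtol, "atol": atol},
    )
    ref = init.totals(grid)
    last = DiskState(cr_t[:, :, -1], cg_t[:, :, -1],
                     result.rho_R[-1], result.rho_RG[-1])
    now = last.totals(grid)
    for key, target in ref.items():
        if target > 0 and abs(now[key] - target) / target > conservation_tol:
            raise RuntimeError(
                f"conservation drift in {key}: {now[key]:.6g} vs {target:.6g}"
            )
    return result


def _sparsity(n: int, m: int) -> sparse.csr_matrix:
    """Jacobian sparsity: 5-point stencil per cytoplasmic species plus the
    dense coupling of each boundary column with its membrane pair."""
    ncy = n * m
    ntot = 2 * ncy + 2 * m
    rows, cols = [], []

    def cell(sp, i, j):
        return sp * ncy + i * m + (j % m)

    for sp in range(2):
        for i in range(n):
            for j in range(m):
                k = cell(sp, i, j)
                for l in (k, cell(sp, i, j + 1), cell(sp, i, j - 1)):
                    rows.append(k), cols.append(l)
                if i > 0:
                    rows.append(k), cols.append(cell(sp, i - 1, j))
                if i < n - 1:
                    rows.append(k), cols.append(cell(sp, i + 1, j))
    for j in range(m):
        group = [cell(0, n - 1, j), cell(1, n - 1, j),
                 2 * ncy + j, 2 * ncy + m + j]
        for k in group:
            for l in group:
                rows.append(k), cols.append(l)
    data = np.ones(len(rows))
    return sparse.csr_matrix(
        sparse.coo_matrix((data, (rows, cols)), shape=(ntot, ntot))
    )
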