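"""Reaction terms and state containers for the Rac1/GAP/DGAP1 cycle.

The condensed model tracks seven linear-density fields on the cell
perimeter: cytoplasmic Rac1-GDP (``rho_r``), membrane Rac1-GTP (``rho_R``),
cytoplasmic GAP (``rho_g``), the membrane Rac1-GAP complex (``rho_RG``),
cytoplasmic DGAP1 (``rho_d``), membrane-bound DGAP1 (``rho_D``) and the
membrane Rac1-DGAP1 complex (``rho_RD``).  The extensive model adds
membrane-bound inactive Rac1 (``rho_m``) and separates membrane binding
from GEF-mediated activation, with reverse and alternative dissociation
pathways.

Every reaction conserves the three protein totals; diffusion acts only on
the cytoplasmic fields and is applied elsewhere (the functions here return
reaction terms only, pointwise in space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "CONDENSED_FIELDS",
    "EXTENSIVE_FIELDS",
    "FieldState",
    "condensed_rhs",
    "extensive_rhs",
    "reaction_jacobian",
    "species_totals",
    "diffusion_coefficients",
]

CONDENSED_FIELDS = ("rho_r", "rho_R", "rho_g", "rho_RG", "rho_d", "rho_D", "rho_RD")
EXTENSIVE_FIELDS = CONDENSED_FIELDS + ("rho_m",)

#: membership of each field in the three conservation groups
CONSERVATION_GROUPS = {
    "Rac1": ("rho_r", "rho_R", "rho_RG", "rho_RD", "rho_m"),
    "GAP": ("rho_g", "rho_RG"),
    "DGAP1": ("rho_d", "rho_D", "rho_RD"),
}


def diffusion_coefficients(params: ModelParameters, extensive: bool = False) -> np.ndarray:
    """Per-field diffusion coefficients (cytoplasmic species only)."""
    d = np.array([params.Dr, 0.0, params.Dg, 0.0, params.Dd, 0.0, 0.0])
    if extensive:
        d = np.append(d, 0.0)  # membrane-bound inactive Rac1 does not diffuse
    return d


@dataclass
class FieldState:
    """Density fields on a shared spatial grid.

    ``values`` has shape ``(n_fields, n_points)`` with rows ordered as in
    :data:`CONDENSED_FIELDS` (plus ``rho_m`` for the extensive model).
    ``grid`` holds the positions ``x_i in [0, L)`` with uniform spacing.
    """

    values: np.ndarray
    grid: np.ndarray
    L: float
    fields: tuple = field(default=CONDENSED_FIELDS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.fields):
            raise ValueError(
                f"values must be ({len(self.fields)}, n_points), got {self.values.shape}"
            )
        if self.grid.shape != (self.values.shape[1],):
            raise ValueError("grid length must match the number of grid points")

    @classmethod
    def homogeneous(cls, densities, params: ModelParameters, n_points: int = 100,
                    extensive: bool = False) -> "FieldState":
        names = EXTENSIVE_FIELDS if extensive else CONDENSED_FIELDS
        densities = np.asarray(densities, dtype=float)
        if densities.shape != (len(names),):
            raise ValueError(f"expected {len(names)} homogeneous densities")
        grid = np.arange(n_points) * (params.L / n_points)
        return cls(np.repeat(densities[:, None], n_points, axis=1), grid, params.L,
                   fields=names)

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def h(self) -> float:
        return self.L / self.n_points

    @property
    def is_extensive(self) -> bool:
        return len(self.fields) == 8

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[self.fields.index(name)]

    def check_physical(self, params: ModelParameters, tol: float = 0.0) -> None:
        """Raise if any density is negative (beyond ``tol``) or a membrane
        pool exceeds its saturation density."""
        if self.values.min() < -abs(tol):
            raise ValueError(
                f"negative density encountered (min {self.values.min():.3e})"
            )
        if self["rho_R"].max() >= params.rho_Rmax:
            raise ValueError("rho_R reached the saturation density rho_Rmax")
        if self["rho_D"].max() >= params.rho_Dmax:
            raise ValueError("rho_D reached the saturation density rho_Dmax")


def _reaction_terms_condensed(rho: np.ndarray, p: ModelParameters) -> np.ndarray:
    r, R, g, RG, d, D, RD = rho
    satR = 1.0 - R / p.rho_Rmax
    satD = 1.0 - D / p.rho_Dmax
    # transient numerical overshoot beyond saturation is clamped to zero flux
    satR = np.maximum(satR, 0.0)
    satD = np.maximum(satD, 0.0)
    bindR = r * satR * (p.k1 + p.k11 * R + p.k12 * RG)
    bindD = d * satD * (p.k4 + p.k41 * R + p.k42 * RG)
    out = np.empty_like(rho)
    out[0] = p.k3a * RG - bindR + p.k6b * RD
    out[1] = p.k6a * RD - p.k2 * R * g - p.k5 * R * D + bindR
    out[2] = p.k3a * RG - p.k2 * R * g
    out[3] = p.k2 * R * g - p.k3a * RG
    out[4] = -bindD + (p.k6a + p.k6b) * RD
    out[5] = bindD - p.k5 * R * D
    out[6] = p.k5 * R * D - (p.k6a + p.k6b) * RD
    return out


def _reaction_terms_extensive(rho: np.ndarray, p: ModelParameters) -> np.ndarray:
    r, R, g, RG, d, D, RD, m_ = rho
    satR = np.maximum(1.0 - R / p.rho_Rmax, 0.0)
    satD = np.maximum(1.0 - D / p.rho_Dmax, 0.0)
    bindR = r * satR * (p.k1 + p.k11 * R + p.k12 * RG)
    bindD = d * satD * (p.k4 + p.k41 * R + p.k42 * RG)
    out = np.empty_like(rho)
    out[0] = p.k3a * RG - bindR + (p.k6b + p.k6d) * RD + p.k_minus1 * m_
    out[1] = (p.k6a + p.k6c) * RD + p.k_act * m_ - p.k2 * R * g - p.k5 * R * D
    out[2] = (p.k3a + p.k3b) * RG - p.k2 * R * g
    out[3] = p.k2 * R * g - (p.k3a + p.k3b) * RG
    out[4] = -bindD + (p.k6a + p.k6b) * RD + p.k_minus4 * D
    out[5] = bindD + (p.k6c + p.k6d) * RD - p.k5 * R * D - p.k_minus4 * D
    out[6] = p.k5 * R * D - (p.k6a + p.k6b + p.k6c + p.k6d) * RD
    out[7] = bindR + p.k3b * RG - (p.k_act + p.k_minus1) * m_
    return out


def _validate(state: FieldState, params: ModelParameters, extensive: bool):
    want = EXTENSIVE_FIELDS if extensive else CONDENSED_FIELDS
    if state.fields != want:
        n = 8 if extensive else 7
        raise ValueError(f"expected a {n}-field state, got fields {state.fields}")
    if np.any(state.values < 0):
        raise ValueError("densities must be non-negative")


def condensed_rhs(state: FieldState, params: ModelParameters) -> np.ndarray:
    """Reaction-term time derivatives of the condensed 7-field model.

    Returns an array shaped like ``state.values``; no spatial coupling is
    applied (diffusion lives in the simulators).
    """
    _validate(state, params, extensive=False)
    if np.any(state["rho_R"] > params.rho_Rmax * 1.01):
        raise ValueError("rho_R exceeds rho_Rmax by more than 1%")
    return _reaction_terms_condensed(state.values, params)


def extensive_rhs(state: FieldState, params: ModelParameters) -> np.ndarray:
    """Reaction-term time derivatives of the extensive 8-field model."""
    if not params.has_extensive:
        raise ValueError(
            "extensive rate constants are unset; use "
            "params.with_extensive_defaults() or supply them explicitly"
        )
    _validate(state, params, extensive=True)
    return _reaction_terms_extensive(state.values, params)


def reaction_jacobian(rho: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Analytic 7x7 Jacobian of the condensed reaction terms at a single
    (homogeneous) composition ``rho``."""
    r, R, g, RG, d, D, RD = np.asarray(rho, dtype=float)
    satR = 1.0 - R / p.rho_Rmax
    satD = 1.0 - D / p.rho_Dmax
    gR = p.k1 + p.k11 * R + p.k12 * RG
    gD = p.k4 + p.k41 * R + p.k42 * RG
    # partial derivatives of the binding terms
    bR_r = satR * gR
    bR_R = r * (-gR / p.rho_Rmax + satR * p.k11)
    bR_RG = r * satR * p.k12
    bD_d = satD * gD
    bD_R = d * satD * p.k41
    bD_RG = d * satD * p.k42
    bD_D = -d * gD / p.rho_Dmax
    J = np.zeros((7, 7))
    J[0, 0] = -bR_r
    J[0, 1] = -bR_R
    J[0, 3] = p.k3a - bR_RG
    J[0, 6] = p.k6b
    J[1, 0] = bR_r
    J[1, 1] = bR_R - p.k2 * g - p.k5 * D
    J[1, 2] = -p.k2 * R
    J[1, 3] = bR_RG
    J[1, 5] = -p.k5 * R
    J[1, 6] = p.k6a
    J[2, 1] = -p.k2 * g
    J[2, 2] = -p.k2 * R
    J[2, 3] = p.k3a
    J[3, 1] = p.k2 * g
    J[3, 2] = p.k2 * R
    J[3, 3] = -p.k3a
    J[4, 1] = -bD_R
    J[4, 3] = -bD_RG
    J[4, 4] = -bD_d
    J[4, 5] = -bD_D
    J[4, 6] = p.k6a + p.k6b
    J[5, 1] = bD_R - p.k5 * D
    J[5, 3] = bD_RG
    J[5, 4] = bD_d
    J[5, 5] = bD_D - p.k5 * R
    J[6, 1] = p.k5 * D
    J[6, 5] = p.k5 * R
    J[6, 6] = -(p.k6a + p.k6b)
    return J


def species_totals(state: FieldState, params: ModelParameters) -> dict:
    """Grid-summed molecule counts per conservation group."""
    h = state.h
    out = {}
    for name, members in CONSERVATION_GROUPS.items():
        tot = 0.0
        for m_ in members:
            if m_ in state.fields:
                tot += state[m_].sum()
        out[f"{name}_total"] = tot * h
    return out
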