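"""Model parameters for the Rac1/GAP/DGAP1 membrane-cycling model.

All membrane and cytoplasmic pools are described by linear densities along
the cell perimeter (units 1/μm), so copy numbers enter the dynamics only
through the total linear densities ``N/L``.  Rate constants that describe
first-order processes carry units of 1/s; bimolecular membrane reactions
carry μm/s (they multiply a linear density).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = ["ModelParameters", "load_parameters", "NAMED_VARIANTS"]

#: Named variant overrides of the default parameter set.
NAMED_VARIANTS = {
    "rac4500": {"N_Rac1": 4500.0, "N_DGAP1": 800.0},
    "rac5000": {"N_Rac1": 5000.0, "N_DGAP1": 800.0},
    "marginal_monopole": {"k3a": 0.77, "N_Rac1": 7000.0, "N_GAP": 1000.0, "N_DGAP1": 900.0},
    "monopole_oscillation": {"k3a": 0.65, "N_Rac1": 6000.0, "N_DGAP1": 900.0},
    "stationary_polarity": {"N_Rac1": 6200.0, "N_DGAP1": 3400.0},
    "strong_activation": {
        "k1": 3e-2, "k2": 0.25, "k3a": 0.7, "k11": 4.6e-3, "k12": 5.6e-3,
        "N_Rac1": 7300.0, "N_GAP": 1600.0, "N_DGAP1": 1100.0,
    },
    "fast_diffusion": {
        "rho_Dmax": 70.0, "Dr": 70.0, "Dg": 40.0, "Dd": 30.0,
        "k1": 1.57e-2, "k2": 0.72, "k3a": 0.71, "k11": 6.6e-3, "k12": 7.9e-3,
        "k5": 0.126, "k6a": 0.393, "k6b": 0.157, "k4": 0.11,
        "k41": 0.22, "k42": 1e-3,
        "N_Rac1": 6340.0, "N_GAP": 1360.0, "N_DGAP1": 1530.0,
    },
    "weak_complex_dissociation": {
        "k3a": 0.39, "k11": 3e-3, "k12": 5e-3, "k41": 0.4e-3, "k42": 2e-3,
        "N_Rac1": 5400.0, "N_GAP": 1440.0, "N_DGAP1": 1460.0,
    },
    "perimeter60_a": {
        "k3a": 0.42, "L": 60.0,
        "N_Rac1": 8580.0, "N_GAP": 2040.0, "N_DGAP1": 1320.0,
    },
    "perimeter60_b": {
        "k1": 4.8e-2, "k2": 0.33, "k3a": 0.57, "k11": 6e-3, "L": 60.0,
        "N_Rac1": 8100.0, "N_GAP": 1380.0, "N_DGAP1": 1440.0,
    },
    "multidomain_stationary": {"N_Rac1": 6000.0, "N_GAP": 1100.0, "N_DGAP1": 4400.0},
    # Extensive-model parameter set that reproduces the condensed defaults.
    "extensive_equivalence": {
        "N_Rac1": 9200.0, "N_GAP": 880.0, "N_DGAP1": 1500.0, "k11": 5e-3,
    },
}

_RATE_FIELDS = (
    "k1", "k11", "k12", "k2", "k3a", "k4", "k41", "k42", "k5", "k6a", "k6b",
    "Dr", "Dg", "Dd", "rho_Rmax", "rho_Dmax",
)
_EXTENSIVE_FIELDS = ("k_minus1", "k_act", "k_minus4", "k3b", "k6c", "k6d")


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, diffusion coefficients, saturation densities and
    copy numbers of the condensed (and optionally extensive) model.

    Defaults are the initial-value column of the published parameter table.
    The extensive-only constants are ``None`` unless explicitly supplied
    (see :meth:`with_extensive_defaults`).
    """

    # membrane binding + GEF-mediated activation of Rac1 (lumped)
    k1: float = 2e-2          # 1/s
    k11: float = 4e-3         # μm/s, autocatalysis by membrane Rac1-GTP
    k12: float = 6e-3         # μm/s, cooperativity via the Rac1-GAP complex
    k2: float = 0.22          # μm/s, GAP binding to membrane Rac1-GTP
    k3a: float = 0.45         # 1/s, Rac1 deactivation + release of both
    # DGAP1 membrane binding and complex cycle
    k4: float = 0.24          # 1/s
    k41: float = 0.8e-3       # μm/s, cooperative recruitment by Rac1-GTP
    k42: float = 3.6e-3       # μm/s, cooperative recruitment by Rac1-GAP
    k5: float = 0.095         # μm/s, Rac1-DGAP1 complex formation
    k6a: float = 0.6          # 1/s, DGAP1 release, Rac1 stays on membrane
    k6b: float = 0.43         # 1/s, both released to cytoplasm
    # cytoplasmic diffusion
    Dr: float = 30.0          # μm²/s
    Dg: float = 8.0           # μm²/s
    Dd: float = 12.0          # μm²/s
    # membrane saturation densities
    rho_Rmax: float = 200.0   # 1/μm
    rho_Dmax: float = 40.0    # 1/μm
    # geometry and copy numbers
    L: float = 40.0           # μm, cell perimeter
    N_Rac1: float = 5200.0
    N_GAP: float = 1200.0
    N_DGAP1: float = 1600.0
    # extensive-model-only constants (1/s); None = condensed model only
    k_minus1: Optional[float] = None
    k_act: Optional[float] = None
    k_minus4: Optional[float] = None
    k3b: Optional[float] = None
    k6c: Optional[float] = None
    k6d: Optional[float] = None

    def __post_init__(self):
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.L <= 0:
            raise ValueError(f"perimeter L must be positive, got {self.L}")
        for name in ("N_Rac1", "N_GAP", "N_DGAP1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in _EXTENSIVE_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.rho_Rmax <= 0 or self.rho_Dmax <= 0:
            raise ValueError("saturation densities must be positive")
        # Saturation limits only the membrane-bound pools; the cytoplasmic
        # pools are unbounded, so total densities may equal or exceed the
        # saturation densities (both occur in the published parameter sets).
        # The membrane-density bound itself is enforced dynamically by
        # FieldState.check_physical and the clamped saturation factors.

    # -- convenience -------------------------------------------------------

    @property
    def rho_Rtotal(self) -> float:
        """Total Rac1 linear density N_Rac1/L (1/μm)."""
        return self.N_Rac1 / self.L

    @property
    def rho_Gtotal(self) -> float:
        return self.N_GAP / self.L

    @property
    def rho_Dtotal(self) -> float:
        return self.N_DGAP1 / self.L

    @property
    def has_extensive(self) -> bool:
        return all(getattr(self, f) is not None for f in _EXTENSIVE_FIELDS)

    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def with_extensive_defaults(self, include_k6cd: bool = True) -> "ModelParameters":
        """Attach the published extensive-model constants.

        The k6c/k6d complex-dissociation pathways (both species staying at
        the membrane) are listed with value 0.3/s but were dropped from the
        condensed model; ``include_k6cd=False`` zeroes them so that the two
        configurations can be compared.
        """
        v = 0.3 if include_k6cd else 0.0
        return self.replace(
            k_minus1=0.85, k_act=1.0, k_minus4=0.05, k3b=0.25, k6c=v, k6d=v
        )

    def with_rho_Rmax(self, rho_Rmax: float) -> "ModelParameters":
        """Rescale the Rac1 saturation density holding the intrinsic
        membrane-binding constants fixed.

        k1, k11 and k12 are stored pre-multiplied by ``rho_Rmax``; varying
        the saturation density therefore rescales them proportionally so
        that the intrinsic constants ``k / rho_Rmax`` stay unchanged.
        """
        f = rho_Rmax / self.rho_Rmax
        return self.replace(
            rho_Rmax=rho_Rmax, k1=self.k1 * f, k11=self.k11 * f, k12=self.k12 * f
        )

    def with_rho_Dmax(self, rho_Dmax: float) -> "ModelParameters":
        """Same intrinsic-constant rescaling for the DGAP1 saturation."""
        f = rho_Dmax / self.rho_Dmax
        return self.replace(
            rho_Dmax=rho_Dmax, k4=self.k4 * f, k41=self.k41 * f, k42=self.k42 * f
        )

    # -- construction / serialization --------------------------------------

    @classmethod
    def defaults(cls, variant: Optional[str] = None) -> "ModelParameters":
        """The published baseline parameter set, optionally with the
        overrides of a named variant (e.g. ``variant="marginal_monopole"``)."""
        if variant is None:
            return cls()
        try:
            over = NAMED_VARIANTS[variant]
        except KeyError:
            raise KeyError(
                f"unknown variant {variant!r}; known: {sorted(NAMED_VARIANTS)}"
            ) from None
        return cls(**over)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_parameters(name: str = "baseline") -> ModelParameters:
    """Load a bundled parameter file (``baseline`` or an override name)."""
    pkg = resources.files("racwaves") / "data"
    path = pkg / f"{name}.yaml"
    if not path.is_file():
        path = pkg / "overrides" / f"{name}.yaml"
    if not path.is_file():
        raise FileNotFoundError(f"no bundled parameter file named {name!r}")
    base = yaml.safe_load(path.read_text())
    return ModelParameters.from_dict(base)
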