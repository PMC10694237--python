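"""Parameter containers for the constrained mixture model (CMM).

The arterial wall is treated as a constrained mixture of three load-bearing
constituents -- elastin (e), collagen (c) and smooth muscle (m) -- that share
the mixture deformation but each carry an individual *deposition stretch*
from its own stress-free natural state to the in-vivo reference
configuration.  All tensors are expressed in the local cylindrical basis
ordered (r, theta, z).  Units: kPa for moduli and stresses, mm for lengths;
angles are degrees at interfaces and radians internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

__all__ = [
    "WallComposition",
    "MaterialParameters",
    "DepositionStretches",
    "FiberFrame",
    "ParameterSet",
]

_SUM_TOL = 1e-12


class InvalidParameterError(ValueError):
    """A physically inadmissible parameter value."""


@dataclass(frozen=True)
class WallComposition:
    """Mass fractions of the three constituents; must sum to one."""

    phi_e: float
    phi_c: float
    phi_m: float

    def __post_init__(self) -> None:
        for name in ("phi_e", "phi_c", "phi_m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if abs(self.phi_e + self.phi_c + self.phi_m - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"mass fractions sum to {self.phi_e + self.phi_c + self.phi_m}, not 1"
            )


@dataclass(frozen=True)
class MaterialParameters:
    """Elastic constants of the mixture (mp).

    c_e : neo-Hookean shear modulus of the elastin matrix [kPa]
    k1_c, k2_c : exponential fiber stiffness [kPa] / nonlinearity [-] of the
        two symmetric collagen families
    beta_deg : collagen fiber angle from the longitudinal (z) axis in the
        z-theta plane [degrees]
    k1_m, k2_m : same pair for the circumferential smooth-muscle "fibers"
    kappa : volumetric penalty modulus [kPa]; defaults to 500 * c_e, the
        near-incompressibility convention of the model
    """

    c_e: float
    k1_c: float
    k2_c: float
    beta_deg: float
    k1_m: float
    k2_m: float
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.c_e <= 0 or self.k1_c <= 0 or self.k1_m <= 0:
            raise InvalidParameterError("moduli c_e, k1_c, k1_m must be positive")
        if self.k2_c < 0 or self.k2_m < 0:
            raise InvalidParameterError("k2_c, k2_m must be non-negative")
        if not 0.0 < self.beta_deg < 90.0:
            raise InvalidParameterError(f"beta_deg={self.beta_deg} outside (0, 90)")
        if self.kappa is None:
            object.__setattr__(self, "kappa", 500.0 * self.c_e)
        elif self.kappa <= 0:
            raise InvalidParameterError("kappa must be positive")

    @property
    def beta_rad(self) -> float:
        return float(np.deg2rad(self.beta_deg))


@dataclass(frozen=True)
class DepositionStretches:
    """Scalar deposition stretches (ds).

    G_theta_e, G_z_e : circumferential / longitudinal elastin prestretch;
        the radial component follows from incompressibility as
        1 / (G_theta_e * G_z_e)
    G_c : collagen prestretch along each fiber direction
    G_m : smooth-muscle prestretch along the circumferential direction
    """

    G_theta_e: float = 1.0
    G_z_e: float = 1.0
    G_c: float = 1.0
    G_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("G_theta_e", "G_z_e", "G_c", "G_m"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    @property
    def G_r_e(self) -> float:
        return 1.0 / (self.G_theta_e * self.G_z_e)

    def as_array(self) -> np.ndarray:
        return np.array([self.G_theta_e, self.G_z_e, self.G_c, self.G_m])

    @classmethod
    def identity(cls) -> "DepositionStretches":
        return cls(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class FiberFrame:
    """Unit fiber directions in cylindrical components (r, theta, z).

    The two collagen families lie in the theta-z plane at +/- beta from the
    longitudinal axis; smooth muscle is purely circumferential.
    """

    d_c0: np.ndarray
    d_c1: np.ndarray
    d_m: np.ndarray

    @classmethod
    def from_angle(cls, beta_deg: float) -> "FiberFrame":
        b = np.deg2rad(beta_deg)
        s, c = np.sin(b), np.cos(b)
        return cls(
            d_c0=np.array([0.0, s, c]),
            d_c1=np.array([0.0, -s, c]),
            d_m=np.array([0.0, 1.0, 0.0]),
        )

    def __post_init__(self) -> None:
        for name in ("d_c0", "d_c1", "d_m"):
            d = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, d)
            if abs(np.linalg.norm(d) - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} is not a unit vector")


# JSON keys are part of the external interface; keep them stable.
_JSON_KEYS = (
    "phi_e", "phi_c", "phi_m",
    "c_e", "k1_c", "k2_c", "beta_deg", "k1_m", "k2_m",
    "G_theta_e", "G_z_e", "G_c", "G_m",
)


@dataclass(frozen=True)
class ParameterSet:
    """Bundle of composition, material parameters and deposition stretches."""

    comp: WallComposition
    mp: MaterialParameters
    ds: DepositionStretches

    def to_dict(self) -> dict:
        d = {}
        d.update({k: getattr(self.comp, k) for k in ("phi_e", "phi_c", "phi_m")})
        d.update({k: getattr(self.mp, k)
                  for k in ("c_e", "k1_c", "k2_c", "beta_deg", "k1_m", "k2_m")})
        d.update({k: getattr(self.ds, k)
                  for k in ("G_theta_e", "G_z_e", "G_c", "G_m")})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        missing = [k for k in _JSON_KEYS if k not in d]
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {missing}")
        return cls(
            comp=WallComposition(d["phi_e"], d["phi_c"], d["phi_m"]),
            mp=MaterialParameters(d["c_e"], d["k1_c"], d["k2_c"],
                                  d["beta_deg"], d["k1_m"], d["k2_m"],
                                  kappa=d.get("kappa")),
            ds=DepositionStretches(d["G_theta_e"], d["G_z_e"], d["G_c"], d["G_m"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))
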