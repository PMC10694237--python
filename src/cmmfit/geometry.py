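"""Configuration snapshots and test kinematics.

Cylindrical configurations of the vessel are described by outer/inner
diameter, axial length and the axial stretch relative to the in-vivo state.
``TestKinematics`` collects the diagonal deformation gradients that map the
in-vivo state to the flattened uniaxial strip: load release (in-vivo ->
ex-vivo), radial ring opening, and strip flattening (taken as identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeometrySnapshot", "LoadState", "TestKinematics", "OpenedSector"]


@dataclass(frozen=True)
class GeometrySnapshot:
    """One cylindrical configuration; diameters and lengths in mm."""

    d_out: float
    d_in: float
    length: float = 0.2
    lambda_z: float = 1.0          # axial stretch relative to in-vivo
    label: str = "invivo"          # invivo | zero_pressure | exvivo | opened

    def __post_init__(self) -> None:
        if not self.d_out > self.d_in > 0:
            raise ValueError(f"need d_out > d_in > 0, got {self.d_out}, {self.d_in}")
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be positive")

    @property
    def thickness(self) -> float:
        return 0.5 * (self.d_out - self.d_in)

    @property
    def r_in(self) -> float:
        return 0.5 * self.d_in

    @property
    def r_out(self) -> float:
        return 0.5 * self.d_out

    def to_dict(self) -> dict:
        return {
            "d_out_mm": self.d_out,
            "d_in_mm": self.d_in,
            "thickness_mm": self.thickness,
            "length_mm": self.length,
            "lambda_z": self.lambda_z,
            "label": self.label,
        }


@dataclass(frozen=True)
class LoadState:
    """Inner pressure [kPa] plus the axial condition.

    ``axial='fixed_stretch'`` holds the axial stretch at ``lambda_z``
    (in-vivo tethering); ``axial='zero_force'`` leaves the ends free.
    """

    pressure: float = 0.0
    axial: str = "fixed_stretch"
    lambda_z: float = 1.0

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")
        if self.axial not in ("fixed_stretch", "zero_force"):
            raise ValueError(f"unknown axial condition {self.axial!r}")


def _as_diag(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape == (3,):
        return np.diag(x)
    if x.shape == (3, 3):
        if np.any(np.abs(x - np.diag(np.diag(x))) > 1e-12):
            raise ValueError("test kinematics tensors must be diagonal")
        return x.copy()
    raise ValueError(f"expected length-3 diagonal or 3x3, got shape {x.shape}")


@dataclass(frozen=True)
class TestKinematics:
    """Thickness-averaged diagonal gradients feeding the uniaxial problem."""

    F_release: np.ndarray = field(default_factory=lambda: np.eye(3))
    F_opening: np.ndarray = field(default_factory=lambda: np.eye(3))
    F_flatten: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        for name in ("F_release", "F_opening", "F_flatten"):
            t = _as_diag(getattr(self, name))
            if np.any(np.diag(t) <= 0):
                raise ValueError(f"{name} must have positive diagonal entries")
            object.__setattr__(self, name, t)

    @classmethod
    def identity(cls) -> "TestKinematics":
        return cls()

    @property
    def prior_diag(self) -> np.ndarray:
        """Diagonal of F_flatten F_opening F_release."""
        return np.diag(self.F_flatten @ self.F_opening @ self.F_release)

    def to_dict(self) -> dict:
        return {
            "F_release": np.diag(self.F_release).tolist(),
            "F_opening": np.diag(self.F_opening).tolist(),
            "F_flatten": np.diag(self.F_flatten).tolist(),
        }


@dataclass(frozen=True)
class OpenedSector:
    """Opened (radially cut) ring configuration.

    ``k`` is the opened central angle over 2*pi; the opening angle follows
    the cut-face convention alpha = 180 deg * (1 - k).
    """

    alpha_deg: float
    k: float
    rho_in: float
    rho_out: float
    lambda_z_open: float

    def __post_init__(self) -> None:
        # k > 1 describes an overlapping (further-closing) cut ring
        if not 0 < self.k <= 2.0:
            raise ValueError(f"sector ratio k={self.k} outside (0, 2]")

    def to_dict(self) -> dict:
        return {
            "alpha_deg": self.alpha_deg,
            "sector_ratio_k": self.k,
            "rho_in_mm": self.rho_in,
            "rho_out_mm": self.rho_out,
            "lambda_z_open": self.lambda_z_open,
        }
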