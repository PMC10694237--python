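"""Constitutive law of the arterial constrained mixture.

Each constituent alpha deforms with the mixture but from its own natural
state: F^alpha = F G^alpha, with G^alpha the volume-preserving deposition
stretch tensor.  The strain energy is the mass-fraction-weighted sum of the
constituents' isochoric energies plus a volumetric penalty,

    W = phi_e W_e(I1_e) + phi_c W_c(I4_c, I6_c) + phi_m W_m(I4_m) + U(J)

with a neo-Hookean elastin matrix, exponential (Holzapfel-type) collagen
fiber families at +/- beta in the theta-z plane, exponential circumferential
smooth muscle, and U(J) = kappa/2 ((J^2 - 1)/2 - ln J).  Invariants are
computed from the isochoric constituent tensors C_bar^alpha =
J^(-2/3) F^alpha^T F^alpha.  Fiber families carry load only in tension
(isochoric pseudoinvariant above one).

Two stress modes are provided:

``penalty``
    Near-incompressible: the volumetric term contributes kappa-scaled
    hydrostatic stress; suitable for checking energy-stress consistency at
    arbitrary J > 0.
``incompressible``
    Exact incompressibility: the stress is evaluated on the unimodular part
    of F and returned *without* the reaction pressure, which the caller must
    resolve from boundary conditions (all semi-analytic solvers do).

All tensors are in the cylindrical basis (r, theta, z).
"""

from __future__ import annotations

import numpy as np

from .params import (
    DepositionStretches,
    FiberFrame,
    InvalidParameterError,
    MaterialParameters,
    WallComposition,
)

__all__ = [
    "deposition_tensor",
    "strain_energy",
    "cauchy_stress",
    "volumetric_energy",
    "InvertedStateError",
]

# below this, the exponential fiber energy is evaluated by its analytic
# k2 -> 0 limit to avoid 0/0
_K2_TINY = 1e-8


class InvertedStateError(ValueError):
    """det F <= 0: locally inverted deformation state."""


def deposition_tensor(constituent: str,
                      ds: DepositionStretches,
                      frame: FiberFrame | None = None,
                      beta_deg: float | None = None) -> np.ndarray:
    """Deposition stretch tensor G^alpha for one constituent.

    Parameters
    ----------
    constituent : {'e', 'c0', 'c1', 'm'}
        Elastin matrix, the two collagen families, or smooth muscle.
    ds : DepositionStretches
    frame : FiberFrame, optional
        Fiber directions; built from ``beta_deg`` if omitted.
    beta_deg : float, optional
        Collagen angle used when ``frame`` is not given (required for 'c0'
        and 'c1').

    Returns
    -------
    (3, 3) ndarray, symmetric with unit determinant.  Elastin is diagonal
    (1/(G_theta G_z), G_theta, G_z); each fiber tensor has eigenvalue G
    along the fiber and 1/sqrt(G) transverse.
    """
    if constituent == "e":
        return np.diag([ds.G_r_e, ds.G_theta_e, ds.G_z_e])
    if constituent == "m":
        d = (frame.d_m if frame is not None
             else np.array([0.0, 1.0, 0.0]))
        return _fiber_tensor(ds.G_m, d)
    if constituent in ("c0", "c1"):
        if frame is None:
            if beta_deg is None:
                raise InvalidParameterError(
                    "collagen deposition tensor needs a FiberFrame or beta_deg")
            frame = FiberFrame.from_angle(beta_deg)
        d = frame.d_c0 if constituent == "c0" else frame.d_c1
        return _fiber_tensor(ds.G_c, d)
    raise InvalidParameterError(f"unknown constituent {constituent!r}")


def _fiber_tensor(G: float, d: np.ndarray) -> np.ndarray:
    if G <= 0:
        raise InvalidParameterError("deposition stretch must be positive")
    dd = np.outer(d, d)
    return G * dd + (np.eye(3) - dd) / np.sqrt(G)


def volumetric_energy(J: float, kappa: float) -> float:
    """Penalty energy U(J) = kappa/2 ((J^2 - 1)/2 - ln J); U(1) = U'(1) = 0."""
    if J <= 0:
        raise InvertedStateError(f"J={J} <= 0")
    return 0.5 * kappa * (0.5 * (J * J - 1.0) - np.log(J))


def _dU_dJ(J: float, kappa: float) -> float:
    return 0.5 * kappa * (J - 1.0 / J)


def _fiber_energy(I4: float, k1: float, k2: float) -> float:
    """Exponential fiber energy; zero in compression (I4 <= 1)."""
    x = I4 - 1.0
    if x <= 0.0:
        return 0.0
    if k2 < _K2_TINY:
        return 0.5 * k1 * x * x
    return k1 / (2.0 * k2) * (np.exp(k2 * x * x) - 1.0)


def _fiber_dW(I4, k1, k2):
    """dW/dI4 of the exponential fiber energy, vectorized, with switch."""
    x = np.maximum(np.asarray(I4, dtype=float) - 1.0, 0.0)
    if k2 < _K2_TINY:
        return k1 * x
    return k1 * x * np.exp(np.minimum(k2 * x * x, 500.0))


def _constituent_structure(mp: MaterialParameters, ds: DepositionStretches,
                           frame: FiberFrame | None):
    if frame is None:
        frame = FiberFrame.from_angle(mp.beta_deg)
    Ge = deposition_tensor("e", ds)
    fibers = [
        (ds.G_c * frame.d_c0, mp.k1_c, mp.k2_c),   # a0 = G^c0 d^c0
        (ds.G_c * frame.d_c1, mp.k1_c, mp.k2_c),
        (ds.G_m * frame.d_m, mp.k1_m, mp.k2_m),
    ]
    return frame, Ge, fibers


def strain_energy(F: np.ndarray,
                  mp: MaterialParameters,
                  ds: DepositionStretches,
                  comp: WallComposition,
                  frame: FiberFrame | None = None,
                  incompressible: bool = False) -> float:
    """Mixture strain-energy density [kPa] at mixture deformation gradient F."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvertedStateError(f"det F = {J} <= 0")
    C = F.T @ F
    Jm23 = J ** (-2.0 / 3.0)
    frame, Ge, fibers = _constituent_structure(mp, ds, frame)

    I1_e = Jm23 * np.trace(Ge @ C @ Ge)
    W = comp.phi_e * 0.5 * mp.c_e * (I1_e - 3.0)

    phis = (comp.phi_c, comp.phi_c, comp.phi_m)
    for (a, k1, k2), phi in zip(fibers, phis):
        I4 = Jm23 * float(a @ C @ a)
        W += phi * _fiber_energy(I4, k1, k2)
    if not incompressible:
        W += volumetric_energy(J, mp.kappa)
    return float(W)


def cauchy_stress(F: np.ndarray,
                  mp: MaterialParameters,
                  ds: DepositionStretches,
                  comp: WallComposition,
                  frame: FiberFrame | None = None,
                  mode: str = "penalty") -> np.ndarray:
    """Cauchy stress sigma = (1/J) F S F^T of the mixture [kPa].

    In ``penalty`` mode the volumetric penalty supplies the hydrostatic
    response.  In ``incompressible`` mode the stress is computed from the
    unimodular part of F and the hydrostatic reaction pressure is left out:
    the caller must add -p I as dictated by its boundary conditions.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvertedStateError(f"det F = {J} <= 0")
    if mode not in ("penalty", "incompressible"):
        raise ValueError(f"unknown stress mode {mode!r}")
    if mode == "incompressible":
        F = F / J ** (1.0 / 3.0)
        J = 1.0
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    Jm23 = J ** (-2.0 / 3.0)
    frame, Ge, fibers = _constituent_structure(mp, ds, frame)

    # elastin: S_e = phi_e c_e (J^-2/3 Ge^2 - I1_e/3 C^-1)
    I1_e = Jm23 * np.trace(Ge @ C @ Ge)
    S = comp.phi_e * mp.c_e * (Jm23 * Ge @ Ge - I1_e / 3.0 * Cinv)

    phis = (comp.phi_c, comp.phi_c, comp.phi_m)
    for (a, k1, k2), phi in zip(fibers, phis):
        I4 = Jm23 * float(a @ C @ a)
        dW = float(_fiber_dW(I4, k1, k2))
        if dW != 0.0:
            S += 2.0 * phi * dW * (Jm23 * np.outer(a, a) - I4 / 3.0 * Cinv)
    if mode == "penalty":
        S += _dU_dJ(J, mp.kappa) * J * Cinv

    sigma = F @ S @ F.T / J
    return 0.5 * (sigma + sigma.T)  # symmetrize roundoff


# ---------------------------------------------------------------------------
# fast diagonal path used by the axisymmetric solvers
# ---------------------------------------------------------------------------

class DiagonalMixture:
    """Vectorized extra-stress/energy evaluation for diagonal mixture F.

    Precomputes the constituent structure for fixed (mp, ds, comp) and
    evaluates batches of diagonal deformation gradients
    f = (lambda_r, lambda_theta, lambda_z) with det f = 1 (exact
    incompressibility).  Returns the diagonal of the extra Cauchy stress
    (reaction pressure excluded); off-diagonal components vanish because the
    two collagen families are mirror-symmetric about the theta axis.
    """

    def __init__(self, mp: MaterialParameters, ds: DepositionStretches,
                 comp: WallComposition):
        self.mp, self.ds, self.comp = mp, ds, comp
        b = mp.beta_rad
        self._s2 = np.sin(b) ** 2
        self._c2 = np.cos(b) ** 2
        self._Ge2 = np.array([ds.G_r_e, ds.G_theta_e, ds.G_z_e]) ** 2
        self._Gc2 = ds.G_c ** 2
        self._Gm2 = ds.G_m ** 2

    def extra_stress(self, f: np.ndarray) -> np.ndarray:
        """Diagonal extra Cauchy stress [kPa] for stretches f of shape (n, 3)."""
        f = np.atleast_2d(np.asarray(f, dtype=float))
        f2 = f * f
        mp, comp = self.mp, self.comp
        sig = comp.phi_e * mp.c_e * self._Ge2 * f2

        I4c = self._Gc2 * (self._s2 * f2[:, 1] + self._c2 * f2[:, 2])
        dWc = _fiber_dW(I4c, mp.k1_c, mp.k2_c)
        # two mirror families: theta/z diagonal terms add, theta-z shear cancels
        sig[:, 1] += 4.0 * comp.phi_c * dWc * self._Gc2 * self._s2 * f2[:, 1]
        sig[:, 2] += 4.0 * comp.phi_c * dWc * self._Gc2 * self._c2 * f2[:, 2]

        I4m = self._Gm2 * f2[:, 1]
        dWm = _fiber_dW(I4m, mp.k1_m, mp.k2_m)
        sig[:, 1] += 2.0 * comp.phi_m * dWm * I4m
        return sig

    def energy(self, f: np.ndarray) -> np.ndarray:
        """Isochoric strain-energy density [kPa] for stretches f of shape (n, 3)."""
        f = np.atleast_2d(np.asarray(f, dtype=float))
        f2 = f * f
        mp, comp = self.mp, self.comp
        I1e = f2 @ self._Ge2
        W = comp.phi_e * 0.5 * mp.c_e * (I1e - 3.0)
        I4c = self._Gc2 * (self._s2 * f2[:, 1] + self._c2 * f2[:, 2])
        W = W + 2.0 * comp.phi_c * _fiber_energy_vec(I4c, mp.k1_c, mp.k2_c)
        I4m = self._Gm2 * f2[:, 1]
        W = W + comp.phi_m * _fiber_energy_vec(I4m, mp.k1_m, mp.k2_m)
        return W


def _fiber_energy_vec(I4, k1, k2):
    x = np.maximum(np.asarray(I4, dtype=float) - 1.0, 0.0)
    if k2 < _K2_TINY:
        return 0.5 * k1 * x * x
    return k1 / (2.0 * k2) * (np.exp(np.minimum(k2 * x * x, 500.0)) - 1.0)
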