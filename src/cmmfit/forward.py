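"""Semi-analytic mechanical-state solvers for the prestressed artery.

The vessel is a thick-walled incompressible cylinder whose reference
configuration is the in-vivo state (pressurized, axially tethered).
Constituents are deposited there with their deposition stretches, so the
reference carries prestress.  All solved configurations belong to the
incompressible axisymmetric family

    r(R) = sqrt(r_i^2 + (R^2 - R_in^2) / lambda_z),
    F    = diag(dr/dR, r/R, lambda_z),

and for the opened (radially cut) sector

    rho(R) = sqrt(rho_i^2 + (R^2 - R_in^2) / (k lambda_z)),
    F      = diag(drho/dR, k rho/R, lambda_z),

with k the opened central angle over 2*pi.  Radial equilibrium integrated
across the wall links the transmural pressure to the extra-stress profile;
the hydrostatic reaction pressure of the incompressible material is resolved
from the traction boundary conditions.

Solvers:

* ``uniaxial_response`` -- homogeneous extension of a strip cut from the
  opened ring (flattening neglected), transverse stresses zero.
* ``inflate_extend`` -- pressurization at fixed axial stretch or zero net
  axial force.
* ``unload_to_exvivo`` -- release of pressure and axial force; yields the
  ex-vivo geometry and the thickness-averaged release gradient.
* ``ring_opening`` -- residual-strain release after a radial cut, imposing
  three integral conditions (zero radial traction residual, zero net axial
  force, zero bending moment of the circumferential stress across the cut);
  a total-energy-minimization variant is provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import brentq, root

from .constitutive import DiagonalMixture
from .geometry import GeometrySnapshot, LoadState, OpenedSector, TestKinematics
from .params import DepositionStretches, MaterialParameters, WallComposition

__all__ = [
    "ArteryModel",
    "SolverError",
    "uniaxial_response",
    "inflate_extend",
    "unload_to_exvivo",
    "ring_opening",
    "thickness_average",
]

_N_GAUSS = 64          # radial quadrature for pressure/axial-force integrals
_N_PROFILE = 801       # dense grid for cumulative radial-stress reconstruction
_N_AVERAGE = 15        # sampling for thickness-averaged tensors (mean +/- SEM)


class SolverError(RuntimeError):
    """A mechanical-state root solve failed to converge."""


def thickness_average(field: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and standard error of a field sampled across the wall."""
    field = np.asarray(field, dtype=float)
    if field.size == 0:
        raise ValueError("empty field")
    mean = float(field.mean())
    if field.size == 1:
        return mean, 0.0
    sem = float(field.std(ddof=1) / np.sqrt(field.size))
    return mean, sem


@dataclass(frozen=True)
class CylinderState:
    """A solved configuration of the tube family (closed, k = 1)."""

    r_in: float
    lambda_z: float
    pressure: float


class ArteryModel:
    """Prestressed thick-walled artery built on the in-vivo reference.

    Parameters
    ----------
    geom_invivo : GeometrySnapshot
        Measured in-vivo geometry (diastolic pressure, tethered length).
    mp, ds, comp :
        Material parameters, deposition stretches and mass fractions.
    load : LoadState, optional
        In-vivo loading; defaults to 10 kPa at fixed axial stretch 1.
    equilibrated_reference : bool
        If True, reproduce the pressurize-then-deposit construction: find a
        fictitious reference annulus (incompressible radial relabeling at
        fixed length) such that the measured in-vivo geometry is in radial
        equilibrium with the in-vivo pressure.  With the default (False) the
        constituents are deposited directly on the in-vivo snapshot and the
        in-vivo state is generally not an exact equilibrium of the in-vivo
        pressure.
    """

    def __init__(self,
                 geom_invivo: GeometrySnapshot,
                 mp: MaterialParameters,
                 ds: DepositionStretches,
                 comp: WallComposition,
                 load: LoadState | None = None,
                 equilibrated_reference: bool = False):
        self.geom_invivo = geom_invivo
        self.mp, self.ds, self.comp = mp, ds, comp
        self.load = load if load is not None else LoadState(
            pressure=10.0, axial="fixed_stretch", lambda_z=1.0)
        self.mix = DiagonalMixture(mp, ds, comp)
        self.equilibrated_reference = equilibrated_reference

        if equilibrated_reference:
            self._Rin = self._solve_reference_annulus()
        else:
            self._Rin = geom_invivo.r_in
        # reference annulus preserves the in-vivo wall cross-section area
        area = geom_invivo.r_out ** 2 - geom_invivo.r_in ** 2
        self._Rout = np.sqrt(self._Rin ** 2 + area)
        xg, wg = np.polynomial.legendre.leggauss(_N_GAUSS)
        self._Rg = 0.5 * (self._Rin + self._Rout) + 0.5 * (self._Rout - self._Rin) * xg
        self._wg = 0.5 * (self._Rout - self._Rin) * wg
        self._Rp = np.linspace(self._Rin, self._Rout, _N_PROFILE)

    # -- kinematics ---------------------------------------------------------

    def _tube_fields(self, R: np.ndarray, r_in: float, lz: float,
                     k: float = 1.0):
        """Radii and diagonal stretches of the (possibly opened) family."""
        r = np.sqrt(r_in ** 2 + (R ** 2 - self._Rin ** 2) / (k * lz))
        fr = R / (k * lz * r)
        ft = k * r / R
        f = np.stack([fr, ft, np.full_like(r, lz)], axis=1)
        return r, f

    def _invivo_fields(self, R: np.ndarray):
        """Mixture stretches of the measured in-vivo state w.r.t. the reference."""
        return self._tube_fields(R, self.geom_invivo.r_in, 1.0)

    # -- equilibrium integrals ---------------------------------------------

    def _pressure_integral(self, r, f, sig) -> float:
        # p = int (sig_tt - sig_rr)/r dr, dr = f_r dR on the reference grid
        return float(np.sum((sig[:, 1] - sig[:, 0]) / r * f[:, 0] * self._wg))

    def _reduced_axial_force(self, r, f, sig) -> float:
        # pi * int (2 sig_zz - sig_tt - sig_rr) r dr : pressure-invariant
        return float(np.pi * np.sum(
            (2 * sig[:, 2] - sig[:, 1] - sig[:, 0]) * r * f[:, 0] * self._wg))

    def _tube_residuals(self, r_in, lz, pressure):
        r, f = self._tube_fields(self._Rg, r_in, lz)
        sig = self.mix.extra_stress(f)
        return (self._pressure_integral(r, f, sig) - pressure,
                self._reduced_axial_force(r, f, sig))

    def _solve_reference_annulus(self) -> float:
        """Inner radius of the fictitious reference so that the in-vivo
        geometry equilibrates the in-vivo pressure at fixed length."""
        giv = self.geom_invivo
        area = giv.r_out ** 2 - giv.r_in ** 2
        xg, wg = np.polynomial.legendre.leggauss(_N_GAUSS)

        def p_residual(Rhat_in):
            Rhat_out = np.sqrt(Rhat_in ** 2 + area)
            R = 0.5 * (Rhat_in + Rhat_out) + 0.5 * (Rhat_out - Rhat_in) * xg
            w = 0.5 * (Rhat_out - Rhat_in) * wg
            r = np.sqrt(giv.r_in ** 2 + R ** 2 - Rhat_in ** 2)
            f = np.stack([R / r, r / R, np.ones_like(r)], axis=1)
            sig = self.mix.extra_stress(f)
            return float(np.sum((sig[:, 1] - sig[:, 0]) / r * f[:, 0] * w)) \
                - self.load.pressure

        lo, hi = 0.2 * giv.r_in, 3.0 * giv.r_in
        try:
            return brentq(p_residual, lo, hi, xtol=1e-12, rtol=1e-14)
        except ValueError as exc:
            raise SolverError(
                "reference-equilibration bracket failed; deposition stretches "
                "may be too far from equilibrating the in-vivo pressure") from exc

    # -- closed-tube solves -------------------------------------------------

    def solve_tube(self, pressure: float, lambda_z: float | None = None,
                   guess=None) -> CylinderState:
        """Solve the closed tube at given pressure.

        With ``lambda_z`` fixed, the inner radius is the only unknown;
        with ``lambda_z=None`` the net (reduced) axial force is set to zero
        and (r_in, lambda_z) are solved together.  ``guess`` warm-starts
        the root solve (a scalar r_in, or an (r_in, lambda_z) pair).
        """
        if lambda_z is not None:
            def res(ri):
                return self._tube_residuals(ri, lambda_z, pressure)[0]
            if guess is not None:
                g = float(np.atleast_1d(guess)[0])
                lo, hi = 0.95 * g, 1.05 * g
                if lo > 0 and res(lo) * res(hi) <= 0:
                    return CylinderState(
                        brentq(res, lo, hi, xtol=1e-12, rtol=1e-14),
                        lambda_z, pressure)
            lo, hi = 0.2 * self._Rin, 4.0 * self._Rin
            # soft trial materials may balloon far before the fibers engage
            for _ in range(6):
                if res(lo) * res(hi) <= 0:
                    break
                hi *= 2.0
            try:
                ri = brentq(res, lo, hi, xtol=1e-12, rtol=1e-14)
            except ValueError as exc:
                raise SolverError(f"no inner-radius root in [{lo}, {hi}] "
                                  f"for p={pressure} kPa") from exc
            return CylinderState(ri, lambda_z, pressure)

        def res2(x):
            ri, lz = x
            if ri <= 0 or lz <= 0:        # keep hybr away from invalid states
                return [1e3 * (1 + abs(ri)), 1e3 * (1 + abs(lz))]
            p_res, fz = self._tube_residuals(ri, lz, pressure)
            return [p_res, fz / 10.0]

        guesses = [[0.75 * self._Rin, 0.9], [self._Rin, 1.0],
                   [0.5 * self._Rin, 0.8], [1.2 * self._Rin, 1.1]]
        if guess is not None and np.ndim(guess) == 1 and len(guess) == 2:
            guesses.insert(0, list(guess))
        for g in guesses:
            sol = root(res2, g, method="hybr", options={"xtol": 1e-13})
            if sol.success and sol.x[0] > 0 and sol.x[1] > 0:
                return CylinderState(float(sol.x[0]), float(sol.x[1]), pressure)
        raise SolverError(f"closed-tube solve failed at p={pressure} kPa, "
                          "zero axial force")

    def snapshot(self, state: CylinderState, label: str) -> GeometrySnapshot:
        r_out = np.sqrt(state.r_in ** 2 +
                        (self._Rout ** 2 - self._Rin ** 2) / state.lambda_z)
        # axial stretch is reported relative to the *in-vivo* state
        lz_rel = state.lambda_z  # reference has in-vivo length
        return GeometrySnapshot(d_out=2 * float(r_out), d_in=2 * state.r_in,
                                length=self.geom_invivo.length * lz_rel,
                                lambda_z=lz_rel, label=label)

    def stress_profile(self, state: CylinderState):
        """Through-thickness Cauchy stress with the reaction pressure
        resolved from sigma_rr(r_out) = 0."""
        r, f = self._tube_fields(self._Rp, state.r_in, state.lambda_z)
        sig = self.mix.extra_stress(f)
        dtr = sig[:, 1] - sig[:, 0]
        cum = cumulative_trapezoid(dtr / r, r, initial=0.0)
        sig_rr = -(cum[-1] - cum)
        return {
            "R_ref": self._Rp, "r": r, "stretches": f,
            "sigma_rr": sig_rr,
            "sigma_tt": sig_rr + dtr,
            "sigma_zz": sig_rr + (sig[:, 2] - sig[:, 0]),
        }

    def average_gradient(self, state: CylinderState,
                         relative_to: CylinderState | None = None):
        """Thickness-averaged diagonal gradient of a tube state, optionally
        relative to another tube state; returns (diag mean, diag SEM)."""
        Rs = np.linspace(self._Rin, self._Rout, _N_AVERAGE)
        _, f = self._tube_fields(Rs, state.r_in, state.lambda_z)
        if relative_to is not None:
            _, f0 = self._tube_fields(Rs, relative_to.r_in, relative_to.lambda_z)
            f = f / f0
        mean_sem = [thickness_average(f[:, i]) for i in range(3)]
        return (np.array([m for m, _ in mean_sem]),
                np.array([s for _, s in mean_sem]))

    @property
    def invivo_state(self) -> CylinderState:
        """The measured in-vivo configuration expressed in the tube family."""
        return CylinderState(self.geom_invivo.r_in, 1.0, self.load.pressure)

    # -- ring opening -------------------------------------------------------

    def _sector_residuals(self, x):
        rho_i, k, lz = x
        if rho_i <= 0 or k <= 0 or lz <= 0:
            return 1e3 * (1.0 + np.abs(np.asarray(x, dtype=float)))
        rho, f = self._tube_fields(self._Rp, rho_i, lz, k=k)
        sig = self.mix.extra_stress(f)
        dtr = sig[:, 1] - sig[:, 0]
        cum = cumulative_trapezoid(dtr / rho, rho, initial=0.0)
        sig_rr = -(cum[-1] - cum)          # zero at the outer face
        r1 = sig_rr[0]                     # zero radial traction at inner face
        r2 = trapezoid((2 * sig[:, 2] - sig[:, 1] - sig[:, 0]) * rho, rho)
        r3 = trapezoid((sig_rr + dtr) * rho, rho)   # bending moment of sig_tt
        return np.array([r1, r2 / 10.0, r3 / 10.0])

    def solve_opened_sector(self, exvivo: CylinderState, guess=None
                            ) -> tuple[OpenedSector, CylinderState]:
        """Release the residual stress of the unloaded ring by a radial cut.

        The opened family cannot satisfy pointwise equilibrium; three
        integral release conditions are imposed instead.  A homotopy from
        the closed ex-vivo ring (k = 1) keeps the root on the branch
        continuously connected to the uncut state; with a ``guess``
        (rho_in, k, lambda_z_open) from a nearby solution the root is
        solved directly and the homotopy is the fallback.
        """
        if guess is not None:
            sol = root(self._sector_residuals, np.asarray(guess, dtype=float),
                       method="hybr", options={"xtol": 1e-13})
            if (sol.success and sol.x[0] > 0 and 0 < sol.x[1] <= 2.0
                    and sol.x[2] > 0):
                return self._sector_result(sol.x)
        x = np.array([exvivo.r_in, 1.0, exvivo.lambda_z])
        w, step = 0.0, 0.2
        while w < 1.0:
            wt = min(1.0, w + step)

            def res(xv, wt=wt):
                r = self._sector_residuals(xv)
                return [r[0], r[1], (1 - wt) * (xv[1] - 1.0) + wt * r[2]]

            sol = root(res, x, method="hybr", options={"xtol": 1e-13})
            if not sol.success:
                sol = root(res, x, method="lm")
            good = (sol.success and sol.x[0] > 0 and 0 < sol.x[1] <= 2.0
                    and sol.x[2] > 0)
            if good:
                w, x = wt, sol.x
                step = min(1.5 * step, 0.25)
            else:
                step *= 0.5
                if step < 1e-3:
                    raise SolverError(
                        f"ring-opening homotopy stalled at w={w:.3f}")
        return self._sector_result(x)

    def _sector_result(self, x) -> tuple[OpenedSector, CylinderState]:
        rho_i, k, lz_open = map(float, x)
        rho_o = float(np.sqrt(rho_i ** 2 +
                              (self._Rout ** 2 - self._Rin ** 2) / (k * lz_open)))
        sector = OpenedSector(alpha_deg=180.0 * (1.0 - k), k=k,
                              rho_in=rho_i, rho_out=rho_o,
                              lambda_z_open=lz_open)
        return sector, CylinderState(rho_i, lz_open, 0.0)

    def opened_average_gradient(self, sector: OpenedSector,
                                relative_to: CylinderState):
        """Thickness-averaged gradient from a tube state to the opened sector."""
        Rs = np.linspace(self._Rin, self._Rout, _N_AVERAGE)
        _, fo = self._tube_fields(Rs, sector.rho_in, sector.lambda_z_open,
                                  k=sector.k)
        _, f0 = self._tube_fields(Rs, relative_to.r_in, relative_to.lambda_z)
        f = fo / f0
        mean_sem = [thickness_average(f[:, i]) for i in range(3)]
        return (np.array([m for m, _ in mean_sem]),
                np.array([s for _, s in mean_sem]))

    def sector_energy(self, x) -> float:
        """Total isochoric strain energy (per unit reference length) of an
        opened-sector configuration x = (rho_i, k, lambda_z_open)."""
        rho_i, k, lz = x
        _, f = self._tube_fields(self._Rp, rho_i, lz, k=k)
        W = self.mix.energy(f)
        return float(trapezoid(W * self._Rp, self._Rp))


# ---------------------------------------------------------------------------
# operation-level wrappers
# ---------------------------------------------------------------------------

def _solve_transverse(g, m_j, x0=None):
    """Solve g(x) = 0 elementwise for the radial stretch of the uniaxial
    strip.  g is strictly increasing in x: the radial stress carries only
    the elastin matrix and grows with x, while the opposite transverse
    stretch 1/(m_j x) -- and with it that stress -- falls.  A warm-started
    Newton iteration is tried first; a bracketed bisection (globally
    convergent by monotonicity) is the fallback."""
    # the acceptance tolerance must be far below the optimizer's
    # finite-difference perturbation scale, or stale warm starts corrupt
    # FD Jacobians built on top of this solve
    if x0 is not None and np.all(np.isfinite(x0)) and np.all(np.asarray(x0) > 0):
        x = np.array(x0, dtype=float)
        ok = False
        for it in range(40):
            gx = g(x)
            if not np.all(np.isfinite(gx)):
                break
            h = 1e-7 * x
            dg = (g(x + h) - gx) / h
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(dg > 0, gx / dg, np.inf)
            step = np.clip(step, -0.3 * x, 0.3 * x)
            x = x - step
            if it > 0 and np.all(np.abs(step) < 1e-13 * x):
                ok = True
                break
        if ok and np.all(np.isfinite(x)) and np.all(np.abs(g(x)) < 1e-9):
            return x
    lo = 0.2 / np.sqrt(m_j)
    hi = 5.0 / np.sqrt(m_j)
    for _ in range(60):
        bad = g(lo) > 0
        if not np.any(bad):
            break
        lo = np.where(bad, 0.5 * lo, lo)
    for _ in range(60):
        bad = g(hi) < 0
        if not np.any(bad):
            break
        hi = np.where(bad, 2.0 * hi, hi)
    if np.any(g(lo) > 0) or np.any(g(hi) < 0):
        raise SolverError("uniaxial transverse-stress solve: no sign change "
                          "bracket for the radial stretch")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        pos = g(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    return 0.5 * (lo + hi)


def uniaxial_response(stretch_grid,
                      direction: str,
                      mp: MaterialParameters,
                      ds: DepositionStretches,
                      comp: WallComposition,
                      kin: TestKinematics | None = None,
                      x0=None,
                      return_state: bool = False) -> np.ndarray:
    """Cauchy stress of a uniaxial strip test in the theta or z direction.

    The strip is cut from the opened ring, so each constituent's gradient
    composes the uniaxial extension with the flattening/opening/release
    history and its deposition stretch.  The stretch grid is relative to the
    flattened strip.  The two transverse normal stresses are zero; the
    transverse stretches follow from that condition plus exact
    incompressibility of the total mixture deformation.

    Returns the Cauchy stress [kPa] at each grid stretch.  ``x0`` warm-starts
    the transverse solve; with ``return_state=True`` the solved radial
    stretches are returned alongside for reuse.
    """
    if direction not in ("theta", "z"):
        raise ValueError("direction must be 'theta' or 'z'")
    lam = np.asarray(stretch_grid, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretches must be positive")
    kin = kin if kin is not None else TestKinematics.identity()
    prior = kin.prior_diag
    j = 1 if direction == "theta" else 2
    t1, t2 = (0, 2) if direction == "theta" else (0, 1)
    mix = DiagonalMixture(mp, ds, comp)

    m_j = lam * prior[j]
    # unknown: total radial stretch x; the other transverse from det F = 1
    def stresses(x):
        f = np.empty((lam.size, 3))
        f[:, j] = m_j
        f[:, t1] = x
        f[:, t2] = 1.0 / (m_j * x)
        return mix.extra_stress(f)

    def g(x):
        s = stresses(x)
        return s[:, t1] - s[:, t2]

    x = _solve_transverse(g, m_j, x0=x0)
    s = stresses(x)
    sig = s[:, j] - s[:, t1]
    if return_state:
        return sig, x
    return sig


def _model(geom_ref, mp, ds, comp, load=None, equilibrated_reference=False):
    return ArteryModel(geom_ref, mp, ds, comp, load=load,
                       equilibrated_reference=equilibrated_reference)


def inflate_extend(geom_ref: GeometrySnapshot,
                   load: LoadState,
                   mp: MaterialParameters,
                   ds: DepositionStretches,
                   comp: WallComposition,
                   equilibrated_reference: bool = False,
                   guess=None):
    """Pressurize/extend the vessel from the in-vivo reference.

    Returns (GeometrySnapshot of the deformed state, through-thickness
    stress profile dict).
    """
    model = _model(geom_ref, mp, ds, comp, load=load,
                   equilibrated_reference=equilibrated_reference)
    lz = load.lambda_z if load.axial == "fixed_stretch" else None
    state = model.solve_tube(load.pressure, lambda_z=lz, guess=guess)
    label = "invivo" if load.pressure > 0 else "zero_pressure"
    return model.snapshot(state, label), model.stress_profile(state)


def unload_to_exvivo(geom_ref: GeometrySnapshot,
                     mp: MaterialParameters,
                     ds: DepositionStretches,
                     comp: WallComposition,
                     load: LoadState | None = None,
                     equilibrated_reference: bool = False,
                     guess=None):
    """Release pressure and axial force; predict the ex-vivo configuration.

    Returns (GeometrySnapshot(exvivo), TestKinematics with the
    thickness-averaged F_release, diagnostics dict).  The snapshot's
    ``lambda_z`` is the *unloading* axial stretch (< 1 for shortening); the
    physiological axial stretch reported in diagnostics is its reciprocal.
    """
    model = _model(geom_ref, mp, ds, comp, load=load,
                   equilibrated_reference=equilibrated_reference)
    ex = model.solve_tube(0.0, lambda_z=None, guess=guess)
    snap = model.snapshot(ex, "exvivo")
    f_rel, f_sem = model.average_gradient(ex, relative_to=model.invivo_state)
    kin = TestKinematics(F_release=np.diag(f_rel))
    diag = {
        "lambda_z_physiological": 1.0 / ex.lambda_z,
        "F_release_sem": f_sem,
        "exvivo_state": ex,
        "model": model,
    }
    return snap, kin, diag


def ring_opening(geom_ref: GeometrySnapshot,
                 mp: MaterialParameters,
                 ds: DepositionStretches,
                 comp: WallComposition,
                 load: LoadState | None = None,
                 equilibrated_reference: bool = False,
                 _unload_diag: dict | None = None,
                 guess=None):
    """Radial-cut release of the unloaded ring.

    Builds (or reuses) the ex-vivo state, then solves the opened-sector
    family.  Returns (OpenedSector, TestKinematics with thickness-averaged
    F_opening, diagnostics).
    """
    if _unload_diag is None:
        _, _, _unload_diag = unload_to_exvivo(
            geom_ref, mp, ds, comp, load=load,
            equilibrated_reference=equilibrated_reference)
    model: ArteryModel = _unload_diag["model"]
    ex: CylinderState = _unload_diag["exvivo_state"]
    sector, opened_state = model.solve_opened_sector(ex, guess=guess)
    f_open, f_sem = model.opened_average_gradient(sector, relative_to=ex)
    kin = TestKinematics(F_opening=np.diag(f_open))
    diag = {"F_opening_sem": f_sem, "opened_state": opened_state,
            "model": model, "exvivo_state": ex}
    return sector, kin, diag
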