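"""Grid sensitivity of residual strains to composition and prestretch.

Maps mass fractions (phi_e, phi_c; phi_m = 1 - phi_e - phi_c) and deposition
stretches (G_theta_e, G_z_e, G_m; G_c held at its baseline) to the two
easily measurable residual-strain quantities: the ring-opening angle alpha
and the physiological axial stretch lambda_z.  One forward pipeline run
(unload to ex-vivo, then ring opening) is performed per grid point; failed
points are recorded, not fatal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forward import SolverError, ring_opening, unload_to_exvivo
from .geometry import GeometrySnapshot, LoadState
from .params import (DepositionStretches, InvalidParameterError,
                     ParameterSet, WallComposition)
from .synthetic import lamb_aorta_fixture

__all__ = ["SweepSpec", "sweep", "deposition_sweep_spec", "mass_fraction_sweep_spec"]

# default sensitivity ranges (min, max) around the lamb-aorta baseline
DEFAULT_RANGES = {
    "G_theta_e": (1.00, 1.20),
    "G_z_e": (1.05, 1.50),
    "G_m": (1.15, 1.68),
    "phi_e": (0.2, 0.6),
    "phi_c": (0.1, 0.3),
}


@dataclass(frozen=True)
class SweepSpec:
    """Axes of a grid sweep plus the held-fixed baseline."""

    axes: tuple          # of (name, min, max, n_steps)
    baseline: ParameterSet | None = None
    geom_invivo: GeometrySnapshot | None = None
    load: LoadState | None = None
    equilibrated_reference: bool = False

    def __post_init__(self) -> None:
        for name, lo, hi, n in self.axes:
            if name not in DEFAULT_RANGES:
                raise ValueError(f"unknown sweep axis {name!r}")
            if not lo < hi:
                raise ValueError(f"axis {name}: need min < max")
            if n < 2:
                raise ValueError(f"axis {name}: need at least 2 steps")

    def resolved(self):
        base, geom, load = self.baseline, self.geom_invivo, self.load
        if base is None or geom is None or load is None:
            b, g, l = lamb_aorta_fixture()
            base = base or b
            geom = geom or g
            load = load or l
        return base, geom, load


def deposition_sweep_spec(n: int = 6) -> SweepSpec:
    """Default deposition-stretch grid: n points per axis over the standard
    ranges, G_c fixed at baseline."""
    return SweepSpec(axes=tuple(
        (name, *DEFAULT_RANGES[name], n)
        for name in ("G_theta_e", "G_z_e", "G_m")))


def mass_fraction_sweep_spec(n: int = 5) -> SweepSpec:
    """Default mass-fraction grid (phi_m is the remainder)."""
    return SweepSpec(axes=tuple(
        (name, *DEFAULT_RANGES[name], n) for name in ("phi_e", "phi_c")))


def _apply_point(base: ParameterSet, point: dict) -> ParameterSet:
    ds_kw = {k: v for k, v in point.items() if k.startswith("G_")}
    phi_kw = {k: v for k, v in point.items() if k.startswith("phi_")}
    ds = replace(base.ds, **ds_kw) if ds_kw else base.ds
    comp = base.comp
    if phi_kw:
        phi_e = phi_kw.get("phi_e", base.comp.phi_e)
        phi_c = phi_kw.get("phi_c", base.comp.phi_c)
        phi_m = 1.0 - phi_e - phi_c
        comp = WallComposition(phi_e, phi_c, phi_m)  # raises if phi_m < 0
    return ParameterSet(comp=comp, mp=base.mp, ds=ds)


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate alpha and lambda_z on the grid; long-format tidy table.

    Columns: one per swept axis, then ``alpha_deg``, ``lambda_z`` and
    ``status`` ('ok', 'skipped' for inadmissible composition, 'failed' for
    solver non-convergence).
    """
    base, geom, load = spec.resolved()
    names = [a[0] for a in spec.axes]
    grids = [np.linspace(a[1], a[2], a[3]) for a in spec.axes]
    rows = []
    for values in itertools.product(*grids):
        point = dict(zip(names, values))
        row = {k: float(v) for k, v in point.items()}
        try:
            ps = _apply_point(base, point)
        except InvalidParameterError:
            row.update(alpha_deg=np.nan, lambda_z=np.nan, status="skipped")
            rows.append(row)
            continue
        try:
            _, _, diag = unload_to_exvivo(
                geom, ps.mp, ps.ds, ps.comp, load=load,
                equilibrated_reference=spec.equilibrated_reference)
            sector, _, _ = ring_opening(
                geom, ps.mp, ps.ds, ps.comp, load=load,
                equilibrated_reference=spec.equilibrated_reference,
                _unload_diag=diag)
            row.update(alpha_deg=sector.alpha_deg,
                       lambda_z=diag["lambda_z_physiological"], status="ok")
        except SolverError as exc:
            row.update(alpha_deg=np.nan, lambda_z=np.nan,
                       status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)
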