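"""Self-consistent synthetic targets from a known parameter set.

The generator emulates the measurement suite of a newborn-lamb descending
thoracic aorta: smooth J-shaped uniaxial Cauchy stress-stretch curves in the
circumferential and longitudinal directions, plus a consistent pair of
in-vivo/ex-vivo geometry records.  Everything is produced by forward
simulation -- the uniaxial kinematics use the release and opening gradients
computed by the cylinder solvers (not identity), and the geometry targets
are the model's own unloading predictions -- so that the generating
parameters are an exact optimum of the two-stage inverse problem when the
noise level is zero.

Noise is multiplicative Gaussian on the stresses (heteroscedastic, as for
load-cell data); an additive option is available.  Geometry targets are left
noiseless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import Stage1Targets, Stage2Targets, _stage2_predictions
from .forward import ring_opening, unload_to_exvivo, uniaxial_response
from .geometry import GeometrySnapshot, LoadState, TestKinematics
from .params import (DepositionStretches, MaterialParameters, ParameterSet,
                     WallComposition)

__all__ = ["SyntheticSpec", "generate", "lamb_aorta_fixture",
           "monte_carlo_recovery"]


def lamb_aorta_fixture() -> tuple[ParameterSet, GeometrySnapshot, LoadState]:
    """Reference parameter/geometry record of the newborn-lamb descending
    thoracic aorta study: measured in-vivo geometry and diastolic pressure,
    literature mass fractions, and the identified material parameters and
    deposition stretches."""
    params = ParameterSet(
        comp=WallComposition(phi_e=0.5, phi_c=0.2, phi_m=0.3),
        mp=MaterialParameters(c_e=10.2, k1_c=52.9, k2_c=0.39,
                              beta_deg=39.7, k1_m=10.3, k2_m=0.024),
        ds=DepositionStretches(G_theta_e=1.05, G_z_e=1.31,
                               G_c=1.10, G_m=1.45),
    )
    geom = GeometrySnapshot(d_out=10.31, d_in=8.16, length=0.2,
                            lambda_z=1.0, label="invivo")
    load = LoadState(pressure=10.0, axial="fixed_stretch", lambda_z=1.0)
    return params, geom, load


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic data set."""

    params: ParameterSet
    geom_invivo: GeometrySnapshot
    load: LoadState = field(default_factory=lambda: LoadState(10.0))
    lam_max: float = 1.6
    n_points: int = 30
    noise_sigma: float = 0.0       # fractional (multiplicative) by default
    noise_model: str = "multiplicative"
    seed: int = 0
    equilibrated_reference: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_points < 5:
            raise ValueError("need at least 5 points per curve")
        if self.lam_max <= 1.0:
            raise ValueError("lam_max must exceed 1")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @classmethod
    def default(cls, noise_sigma: float = 0.0, seed: int = 0) -> "SyntheticSpec":
        params, geom, load = lamb_aorta_fixture()
        return cls(params=params, geom_invivo=geom, load=load,
                   noise_sigma=noise_sigma, seed=seed)


def generate(spec: SyntheticSpec):
    """Generate (Stage1Targets, Stage2Targets, truth record).

    The truth record stores the generating parameters, the release/opening
    kinematics implied by them, the noiseless curves and the predicted
    opening angle, for use in recovery tests.
    """
    mp, ds, comp = spec.params.mp, spec.params.ds, spec.params.comp

    _, kin_rel, diag = unload_to_exvivo(
        spec.geom_invivo, mp, ds, comp, load=spec.load,
        equilibrated_reference=spec.equilibrated_reference)
    sector, kin_open, _ = ring_opening(
        spec.geom_invivo, mp, ds, comp, load=spec.load,
        equilibrated_reference=spec.equilibrated_reference, _unload_diag=diag)
    kin = TestKinematics(F_release=kin_rel.F_release,
                         F_opening=kin_open.F_opening)

    lam = np.linspace(1.0, spec.lam_max, spec.n_points)
    sig_c = uniaxial_response(lam, "theta", mp, ds, comp, kin)
    sig_l = uniaxial_response(lam, "z", mp, ds, comp, kin)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        if spec.noise_model == "multiplicative":
            sig_c_n = sig_c * (1.0 + spec.noise_sigma * rng.standard_normal(lam.size))
            sig_l_n = sig_l * (1.0 + spec.noise_sigma * rng.standard_normal(lam.size))
        else:
            scale_c = spec.noise_sigma * np.max(np.abs(sig_c))
            scale_l = spec.noise_sigma * np.max(np.abs(sig_l))
            sig_c_n = sig_c + scale_c * rng.standard_normal(lam.size)
            sig_l_n = sig_l + scale_l * rng.standard_normal(lam.size)
    else:
        sig_c_n, sig_l_n = sig_c.copy(), sig_l.copy()

    targets1 = Stage1Targets(stretch_circ=lam, stress_circ=sig_c_n,
                             stretch_long=lam, stress_long=sig_l_n)

    preds, _ = _stage2_predictions(ds, mp, comp, spec.geom_invivo, spec.load,
                                   spec.equilibrated_reference)
    targets2 = Stage2Targets(
        d_out_invivo=preds["d_out_invivo"],
        d_in_invivo=preds["d_in_invivo"],
        d_out_exvivo=preds["d_out_exvivo"],
        d_in_exvivo=preds["d_in_exvivo"],
        lambda_z=preds["lambda_z"])

    truth = {
        "params": spec.params.to_dict(),
        "kinematics": kin.to_dict(),
        "alpha_deg": sector.alpha_deg,
        "stretch": lam.tolist(),
        "stress_circ_noiseless": sig_c.tolist(),
        "stress_long_noiseless": sig_l.tolist(),
        "geometry_targets": {
            "d_out_invivo_mm": preds["d_out_invivo"],
            "d_in_invivo_mm": preds["d_in_invivo"],
            "d_out_exvivo_mm": preds["d_out_exvivo"],
            "d_in_exvivo_mm": preds["d_in_exvivo"],
            "lambda_z": preds["lambda_z"],
        },
        "seed": spec.seed,
        "noise_sigma": spec.noise_sigma,
    }
    return targets1, targets2, truth


def monte_carlo_recovery(noise_sigma: float = 0.02,
                         n_seeds: int = 20,
                         spec_kwargs: dict | None = None,
                         pooled_config=None,
                         replicate_config=None):
    """Monte-Carlo parameter-recovery study under curve noise.

    Generates ``n_seeds`` replicate data sets (independent noise
    realizations of the same synthetic specimen), identifies the reference
    estimate from the pooled (seed-averaged) curves with a thorough
    multi-start fit, then refits every replicate warm-started from that
    reference -- the standard bootstrap-refit design.  Each replicate
    estimate is a converged optimum of its own data.

    Returns (DataFrame with one row per seed: recovered parameters and
    percent errors against the generating truth, plus a ``pooled`` row).
    """
    import pandas as pd

    from .fitting import DS_NAMES, MP_NAMES, FitConfig, Stage1Targets, \
        run_integrated

    spec_kwargs = dict(spec_kwargs or {})
    specs = [SyntheticSpec.default(noise_sigma=noise_sigma, seed=s,
                                   **spec_kwargs) for s in range(n_seeds)]
    reps = [generate(sp) for sp in specs]
    base = specs[0]
    comp, geom, load = base.params.comp, base.geom_invivo, base.load

    lam = reps[0][0].stretch_circ
    pooled = Stage1Targets(
        stretch_circ=lam,
        stress_circ=np.mean([r[0].stress_circ for r in reps], axis=0),
        stretch_long=lam,
        stress_long=np.mean([r[0].stress_long for r in reps], axis=0))
    targets2 = reps[0][1]

    pooled_config = pooled_config or FitConfig(
        joint_starts=12, max_iterations=2, multi_start=2, seed=1234)
    ref = run_integrated(pooled, targets2, comp, geom, load,
                         config=pooled_config)[-1]

    def row(label, mp, ds):
        r = {"seed": label}
        for n in MP_NAMES:
            truth = getattr(base.params.mp, n)
            r[n] = getattr(mp, n)
            r[f"err_pct_{n}"] = 100.0 * abs(r[n] - truth) / abs(truth)
        for n in DS_NAMES:
            truth = getattr(base.params.ds, n)
            r[n] = getattr(ds, n)
            r[f"err_pct_{n}"] = 100.0 * abs(r[n] - truth) / abs(truth)
        return r

    rows = [row("pooled", ref.mp, ref.ds)]
    for s in range(n_seeds):
        t1s, t2s, _ = reps[s]
        cfg = replicate_config or FitConfig(
            joint_starts=1, joint_nfev=800, max_iterations=2,
            multi_start=2, seed=s)
        cfg = replace(cfg, mp_init=ref.mp, ds_init=ref.ds, seed=s)
        hist = run_integrated(t1s, t2s, comp, geom, load, config=cfg)
        rows.append(row(s, hist[-1].mp, hist[-1].ds))
    return pd.DataFrame(rows)
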