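"""File I/O: stress-stretch curves (CSV), geometry records (JSON), run
configuration (YAML with JSON fallback).

Physical quantities carry explicit unit suffixes in keys (``pressure_kPa``,
``d_out_mm``) so that unit mistakes surface as key errors.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import Stage2Targets
from .geometry import GeometrySnapshot, LoadState

__all__ = [
    "read_curve", "write_curve",
    "read_geometry_targets", "write_geometry_targets",
    "load_config", "config_hash",
]

CURVE_COLUMNS = ("stretch", "stress_kPa")


class CurveFormatError(ValueError):
    """Malformed stress-stretch curve file."""


def read_curve(path: str | Path) -> pd.DataFrame:
    """Read a uniaxial curve CSV with columns ``stretch,stress_kPa``.

    Stretch must be strictly increasing; the offending data row is named in
    the error otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveFormatError(f"{path}: missing columns {missing}")
    lam = df["stretch"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lam)) or np.any(~np.isfinite(df["stress_kPa"])):
        raise CurveFormatError(f"{path}: non-finite values")
    bad = np.nonzero(np.diff(lam) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise CurveFormatError(
            f"{path}: stretch not strictly increasing at data row "
            f"{bad[0] + 2} (line {bad[0] + 3})")
    return df[list(CURVE_COLUMNS)]


def write_curve(path: str | Path, stretch, stress_kPa) -> None:
    pd.DataFrame({"stretch": np.asarray(stretch, dtype=float),
                  "stress_kPa": np.asarray(stress_kPa, dtype=float)}
                 ).to_csv(path, index=False)


def write_geometry_targets(path: str | Path, targets: Stage2Targets,
                           geom_invivo: GeometrySnapshot,
                           load: LoadState) -> None:
    rec = {
        "invivo": {"d_out_mm": geom_invivo.d_out, "d_in_mm": geom_invivo.d_in,
                   "length_mm": geom_invivo.length},
        "pressure_kPa": load.pressure,
        "targets": {
            "d_out_invivo_mm": targets.d_out_invivo,
            "d_out_exvivo_mm": targets.d_out_exvivo,
            "lambda_z": targets.lambda_z,
            **({"d_in_exvivo_mm": targets.d_in_exvivo}
               if targets.d_in_exvivo is not None else {}),
            **({"d_in_invivo_mm": targets.d_in_invivo}
               if targets.d_in_invivo is not None else {}),
        },
    }
    Path(path).write_text(json.dumps(rec, indent=2) + "\n")


def read_geometry_targets(path: str | Path):
    """Returns (Stage2Targets, GeometrySnapshot(invivo), LoadState)."""
    rec = json.loads(Path(path).read_text())
    t = rec["targets"]
    targets = Stage2Targets(
        d_out_invivo=t["d_out_invivo_mm"],
        d_out_exvivo=t["d_out_exvivo_mm"],
        lambda_z=t["lambda_z"],
        d_in_exvivo=t.get("d_in_exvivo_mm"),
        d_in_invivo=t.get("d_in_invivo_mm"))
    iv = rec["invivo"]
    geom = GeometrySnapshot(d_out=iv["d_out_mm"], d_in=iv["d_in_mm"],
                            length=iv.get("length_mm", 0.2), label="invivo")
    load = LoadState(pressure=rec.get("pressure_kPa", 10.0),
                     axial="fixed_stretch", lambda_z=1.0)
    return targets, geom, load


def load_config(path: str | Path) -> dict:
    """YAML config with JSON fallback."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
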