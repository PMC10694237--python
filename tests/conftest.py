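import numpy as np
import pytest

import cmmfit as cm


@pytest.fixture(scope="session")
def lamb():
    """Reference parameter set, in-vivo geometry and diastolic load."""
    params, geom, load = cm.lamb_aorta_fixture()
    return {"params": params, "geom": geom, "load": load}


@pytest.fixture(scope="session")
def lamb_pipeline(lamb):
    """Unload + ring-opening pipeline solved once for the reference set."""
    p = lamb["params"]
    ex_snap, kin_rel, diag = cm.unload_to_exvivo(
        lamb["geom"], p.mp, p.ds, p.comp, load=lamb["load"])
    sector, kin_open, diag2 = cm.ring_opening(
        lamb["geom"], p.mp, p.ds, p.comp, load=lamb["load"], _unload_diag=diag)
    return {
        "exvivo": ex_snap, "kin_release": kin_rel, "unload_diag": diag,
        "sector": sector, "kin_opening": kin_open, "open_diag": diag2,
    }


@pytest.fixture(scope="session")
def noiseless_synthetic():
    """Self-consistent noiseless synthetic data set from the reference set."""
    spec = cm.SyntheticSpec.default(noise_sigma=0.0, seed=1)
    t1, t2, truth = cm.generate(spec)
    return {"spec": spec, "targets1": t1, "targets2": t2, "truth": truth}


def rel_err(a, b):
    return abs(a - b) / abs(b)
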