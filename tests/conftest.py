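import numpy as np
import pytest

from epimech.mechanics import MechParams, grow_to, relax
from epimech.mesh import build_hex_monolayer


@pytest.fixture
def params() -> MechParams:
    return MechParams()


@pytest.fixture
def hex4():
    """Fresh 61-cell regular patch (ages zero, deterministic geometry)."""
    return build_hex_monolayer(4)


@pytest.fixture(scope="session")
def grown_mesh():
    """A 120-cell monolayer grown by divisions from a 19-cell patch (seeded)."""
    rng = np.random.default_rng(42)
    params = MechParams()
    mesh = build_hex_monolayer(2, rng=rng)
    grow_to(mesh, params, 120, rng)
    relax(mesh, params, force_tol=1e-4)
    return mesh


@pytest.fixture
def rng():
    return np.random.default_rng(0)
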