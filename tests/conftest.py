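"""Shared fixtures.

Expensive MD artefacts (equilibrated boxes) are session-scoped so several
tests can reuse the same trajectory.
"""

import numpy as np
import pytest

import solvshell as ss
from solvshell.fixtures import build_complex, pack_solvent_box, minimize


@pytest.fixture(scope="session")
def water_calc():
    return ss.ClassicalCalculator(ss.water_ion_params())


@pytest.fixture(scope="session")
def hexaaqua():
    """Ideal octahedral [M(water)6]2+-like complex."""
    return build_complex("octahedral", metal="Mg", ligand="water", bond_length=2.05)


@pytest.fixture(scope="session")
def small_water_box(water_calc):
    """Relaxed 16-molecule periodic water-like box (cheap force checks)."""
    box = pack_solvent_box(16, 0.997, seed=7)
    return minimize(box, water_calc, n_steps=200)


@pytest.fixture(scope="session")
def equilibrated_water_box(water_calc):
    """112-molecule water-like box, minimized + 20 ps NVT at 300 K.

    20 ps fully melts the jittered-lattice packing (residual lattice order
    inflates local pair correlations).  Session-scoped: shared by the
    cluster-extraction and MD tests.
    """
    box = pack_solvent_box(112, 0.997, seed=3)
    box = minimize(box, water_calc, n_steps=300)
    state = ss.initialize_state(box, 300.0, seed=4)
    res = ss.run_md(
        state, water_calc, ss.ThermostatSpec("csvr", 300.0, 100.0),
        n_steps=40000, dt=0.5, sample_every=200,
    )
    assert res.stable
    return res


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240803)
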