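"""Shared fixtures: topologies, small ensembles, the ideal Abeta helix.

Ensemble fixtures deliberately use reduced cycle counts so the whole suite
runs on one CPU in minutes; the acceptance tests use the protocol-scale
cycle counts.
"""

import numpy as np
import pytest

from curcumetry import (
    SAProtocol, build_ligand, classify_ensemble, generate_ensemble,
    gen_abeta_helix, gen_toy_molecule,
)


@pytest.fixture(scope="session")
def cyc_top():
    return build_ligand("cyclocurcumin", "cyclic")


@pytest.fixture(scope="session")
def cur_ke_top():
    return build_ligand("curcumin", "keto-enol")


@pytest.fixture(scope="session")
def cur_dk_top():
    return build_ligand("curcumin", "diketone")


@pytest.fixture(scope="session")
def toy1_top():
    top, _truth = gen_toy_molecule(1)
    return top


@pytest.fixture(scope="session")
def toy2_top():
    top, _truth = gen_toy_molecule(2)
    return top


@pytest.fixture(scope="session")
def abeta_helix():
    return gen_abeta_helix()


@pytest.fixture(scope="session")
def cyc_mini_ensemble(cyc_top):
    """Small classified CYC ensemble (reduced cycles, fixed seed)."""
    ens = generate_ensemble(cyc_top, SAProtocol(n_cycles=10, seed=42))
    classify_ensemble(ens, cyc_top)
    return ens


@pytest.fixture(scope="session")
def cur_ke_mini_ensemble(cur_ke_top):
    ens = generate_ensemble(cur_ke_top, SAProtocol(n_cycles=8, seed=42))
    classify_ensemble(ens, cur_ke_top)
    return ens


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
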