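"""Shared fixtures: toy structures, Hamiltonians and cached pulling runs.

The pulling runs are session-scoped because Langevin integration over
~10^5–10^6 steps is the expensive part of the suite; every test that only
inspects the recorded series shares one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from smfskit.gomodel import build_contact_map, build_hamiltonian
from smfskit.pulling import LangevinParams, PullingProtocol, run_pulling
from smfskit.synthetic import ToyStructureConfig, generate_toy_structure


@pytest.fixture(scope="session")
def toy_domain():
    """One 30-residue β-meander domain plus its PDB text."""
    return generate_toy_structure(ToyStructureConfig(n_domains=1))


@pytest.fixture(scope="session")
def toy_hamiltonian(toy_domain):
    structure, _ = toy_domain
    cmap = build_contact_map(structure, method="calpha")
    return build_hamiltonian(structure, cmap)


@pytest.fixture(scope="session")
def small_two_domain():
    """Compact two-domain construct (35 beads) used for pulling runs."""
    cfg = ToyStructureConfig(n_domains=2, residues_per_domain=16, strand_length=5)
    structure, pdb_text = generate_toy_structure(cfg)
    cmap = build_contact_map(structure, method="calpha")
    return structure, build_hamiltonian(structure, cmap)


@pytest.fixture(scope="session")
def two_domain_pull(small_two_domain):
    """One full unfolding run of the two-domain construct.

    kT = 0.5 ε keeps both domains folded until their contacts are loaded;
    v_p = 0.05 Å/τ pulls the ~122 Å contour in ~5·10^5 steps.
    """
    structure, ham = small_two_domain
    v_p = 0.05
    n_steps = int((structure.n_residues - 1) * 3.6 / v_p / 0.005)
    sim = run_pulling(
        structure,
        ham,
        PullingProtocol(v_p=v_p),
        LangevinParams(kT_eps=0.5, n_steps=n_steps, n_equil_steps=20_000, seed=11),
        record_every=100,
    )
    return structure, sim
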