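import numpy as np
import pytest

from elphase.synthetic import ChainSpec, build_peptide, gen_chain_trajectory


@pytest.fixture(scope="session")
def helix():
    """Ideal α-helix (φ=−60°, ψ=−45°), 12 residues, backbone + HN."""
    coords, topo = build_peptide([-60.0] * 12, [-45.0] * 12, with_sidechain=False)
    return coords, topo


@pytest.fixture(scope="session")
def extended_chain():
    """Fully extended 12-residue chain (φ=−135°, ψ=135°)."""
    coords, topo = build_peptide([-135.0] * 12, [135.0] * 12, with_sidechain=False)
    return coords, topo


@pytest.fixture(scope="session")
def solvated_frame():
    """One frame of a small pseudo-peptide in water (~150 atoms)."""
    traj = gen_chain_trajectory(
        ChainSpec(n_residues=8, compactness=0.8, n_waters=40,
                  box_edge=26.0, n_frames=1, seed=11)
    )
    return traj.frames[0], traj.topology


@pytest.fixture(scope="session")
def solvated_traj():
    """Short solvated trajectory for end-to-end featurization tests."""
    return gen_chain_trajectory(
        ChainSpec(n_residues=10, compactness=0.5, n_waters=40,
                  box_edge=50.0, n_frames=6, dt_ns=0.2, seed=5)
    )
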