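"""Generator determinism, parameter faithfulness and structural validity."""

import numpy as np
import pandas as pd
import pytest

from elphase.descriptors import DESCRIPTOR_NAMES, radius_of_gyration, sample_descriptors
from elphase.synthetic import (
    ChainSpec,
    ClusterSpec,
    gen_chain_trajectory,
    gen_descriptor_dataset,
    gen_frap_trace,
    gen_ftir_spectrum,
)


class TestDescriptorDataset:
    def test_shape_matches_study_design(self):
        data, labels, truth = gen_descriptor_dataset(ClusterSpec(seed=0))
        assert len(data) == 8 * 3 * 250
        assert list(data.columns[3:]) == DESCRIPTOR_NAMES
        assert sum(labels.values()) == 4
        assert len(truth["informative_columns"]) == 6

    def test_seed_determinism(self):
        a, _, _ = gen_descriptor_dataset(ClusterSpec(seed=5))
        b, _, _ = gen_descriptor_dataset(ClusterSpec(seed=5))
        pd.testing.assert_frame_equal(a, b)
        c, _, _ = gen_descriptor_dataset(ClusterSpec(seed=6))
        assert not a.equals(c)

    def test_class_separation_on_informative_columns(self):
        # large sample so moments are tight: many ELPs averages out the
        # per-ELP offsets, leaving the programmed class shift
        spec = ClusterSpec(n_elps_per_class=40, n_replicas=1,
                           n_timepoints=200, seed=1)
        data, labels, truth = gen_descriptor_dataset(spec)
        cls = data["elp"].map(labels)
        gap = data.loc[cls == 1, truth["informative_columns"]].mean() - data.loc[
            cls == 0, truth["informative_columns"]
        ].mean()
        se = 3.0 / np.sqrt(spec.n_elps_per_class)  # elp offsets dominate
        assert np.all(np.abs(gap - spec.delta) < 3 * se)
        others = [c for c in DESCRIPTOR_NAMES if c not in truth["informative_columns"]]
        gap0 = (data.loc[cls == 1, others].mean() - data.loc[cls == 0, others].mean())
        assert np.all(np.abs(gap0) < 3 * se)

    def test_unit_within_class_variance(self):
        spec = ClusterSpec(n_elps_per_class=30, n_replicas=1,
                           n_timepoints=300, seed=2, rho=0.0)
        data, labels, _ = gen_descriptor_dataset(spec)
        cls = data["elp"].map(labels)
        var = data.loc[cls == 0, DESCRIPTOR_NAMES].var(ddof=1)
        assert np.all(np.abs(var - 1.0) < 0.15)

    def test_ar1_autocorrelation(self):
        spec = ClusterSpec(n_elps_per_class=1, n_replicas=1,
                           n_timepoints=10000, seed=3, rho=0.5, elp_sd=0.0)
        data, _, _ = gen_descriptor_dataset(spec)
        x = data[DESCRIPTOR_NAMES[0]].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.5, abs=3 / np.sqrt(10000 / 3))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ClusterSpec(n_informative=30)
        with pytest.raises(ValueError):
            ClusterSpec(rho=1.0)
        with pytest.raises(ValueError):
            ClusterSpec(delta=-1.0)


class TestChainTrajectory:
    def test_compact_chains_have_smaller_rg(self):
        for seed in range(10):
            rgs = {}
            for c in (0.0, 1.0):
                traj = gen_chain_trajectory(
                    ChainSpec(n_residues=40, compactness=c, n_waters=0,
                              box_edge=400.0, n_frames=3, seed=seed)
                )
                prot = traj.topology.protein_mask
                rgs[c] = np.mean([
                    radius_of_gyration(f[prot], traj.topology.mass[prot])
                    for f in traj.frames
                ])
            assert rgs[0.0] > rgs[1.0]

    def test_no_waters_means_empty_shell(self):
        traj = gen_chain_trajectory(
            ChainSpec(n_residues=8, compactness=0.5, n_waters=0,
                      box_edge=200.0, n_frames=2, seed=0)
        )
        with pytest.warns(UserWarning, match="no waters"):
            df = sample_descriptors(traj, start_ns=0.2, stride_ns=0.2)
        assert (df["n_shell_waters"] == 0).all()
        assert (df["hbonds_elp_shell"] == 0).all()

    def test_seed_determinism(self):
        spec = ChainSpec(n_residues=10, n_waters=20, box_edge=50.0,
                         n_frames=2, seed=9)
        a = gen_chain_trajectory(spec)
        b = gen_chain_trajectory(spec)
        assert np.array_equal(a.frames, b.frames)

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            gen_chain_trajectory(
                ChainSpec(n_residues=40, compactness=0.0, n_waters=0,
                          box_edge=30.0, n_frames=1, seed=0)
            )

    def test_topology_well_formed(self, solvated_traj):
        topo = solvated_traj.topology
        # waters validated as O+H+H by the Topology invariant at build time;
        # every polar hydrogen maps onto a donor heavy atom
        ph = np.flatnonzero(topo.is_polar_hydrogen)
        assert np.all(topo.h_donor[ph] >= 0)
        assert np.all(topo.is_donor_heavy[topo.h_donor[ph]])
        assert topo.protein_mask.sum() + topo.water_mask.sum() == topo.n_atoms


class TestSignalGenerators:
    def test_frap_noiseless_is_exact_curve(self):
        tr = gen_frap_trace(0.8, 0.115, sigma_noise=0.0, n_points=50, t_max_s=40.0)
        expected = 0.8 * (1 - np.exp(-0.115 * tr.times_s))
        assert np.allclose(tr.intensity, expected)

    def test_frap_seed_determinism(self):
        a = gen_frap_trace(seed=4)
        b = gen_frap_trace(seed=4)
        assert np.array_equal(a.intensity, b.intensity)

    def test_ftir_grid_and_symmetry(self):
        spec = gen_ftir_spectrum(np.full(5, 1.0), np.full(5, 8.0))
        assert spec.wavenumbers[0] == 650.0
        assert np.all(np.diff(spec.wavenumbers) == 2.0)
        a = gen_ftir_spectrum(sigma_noise=0.01, seed=8)
        b = gen_ftir_spectrum(sigma_noise=0.01, seed=8)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_frap_trace(plateau=-0.1)
        with pytest.raises(ValueError):
            gen_ftir_spectrum(amplitudes=(0, 1, 1, 1, 1))
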