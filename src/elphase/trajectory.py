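"""In-memory containers for MD topologies and trajectories.

The featurization code operates on two plain containers: a
:class:`Topology` (per-atom metadata, hydrogen-bond roles and nonbonded
parameters) and a :class:`Trajectory` (coordinate frames in Å with
times in ns and optional per-frame periodic box lengths).  File readers
that populate them from PDB/DCD/XTC plus a sidecar parameter table live
in :mod:`elphase.io`; the synthetic generator builds them directly.

Conventions: Å, ns, kcal/mol, partial charges in e; atom and residue
indices are 0-based in memory and 1-based on file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

__all__ = ["Topology", "Trajectory", "write_frames_csv", "read_frames_csv"]


@dataclass
class Topology:
    """Static per-atom description of a simulated system.

    ``segments`` tags each atom as ``protein``, ``water`` or ``ion``.
    ``h_donor`` maps each polar hydrogen to the index of its donor
    heavy atom (−1 elsewhere).  ``bonds`` is used only to build 1-2/1-3
    exclusion pairs for the nonbonded energy terms.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    segments: np.ndarray
    is_backbone: np.ndarray
    is_water_oxygen: np.ndarray
    is_donor_heavy: np.ndarray
    is_acceptor: np.ndarray
    is_polar_hydrogen: np.ndarray
    radius: np.ndarray
    charge: np.ndarray
    epsilon: np.ndarray
    rmin_half: np.ndarray
    mass: np.ndarray
    h_donor: np.ndarray
    bonds: Optional[Sequence[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        n = len(self.names)
        arrays = (
            self.elements, self.resids, self.resnames, self.segments,
            self.is_backbone, self.is_water_oxygen, self.is_donor_heavy,
            self.is_acceptor, self.is_polar_hydrogen, self.radius,
            self.charge, self.epsilon, self.rmin_half, self.mass, self.h_donor,
        )
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-atom arrays must have equal length")
        if np.any(self.radius <= 0):
            raise ValueError("all vdW radii must be positive")
        # every polar hydrogen must point at exactly one donor heavy atom
        ph = np.flatnonzero(self.is_polar_hydrogen)
        if np.any(self.h_donor[ph] < 0):
            raise ValueError("polar hydrogen without a donor heavy atom")
        if len(ph) and not np.all(self.is_donor_heavy[self.h_donor[ph]]):
            raise ValueError("h_donor must reference donor heavy atoms")
        self._check_waters()

    def _check_waters(self) -> None:
        water = self.segments == "water"
        if not water.any():
            return
        for rid in np.unique(self.resids[water]):
            idx = np.flatnonzero(water & (self.resids == rid))
            elems = sorted(self.elements[idx])
            if elems != ["H", "H", "O"]:
                raise ValueError(
                    f"water residue {rid} must be one O and two H, got {elems}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @cached_property
    def protein_mask(self) -> np.ndarray:
        return self.segments == "protein"

    @cached_property
    def water_mask(self) -> np.ndarray:
        return self.segments == "water"

    @cached_property
    def sidechain_mask(self) -> np.ndarray:
        return self.protein_mask & ~self.is_backbone

    @cached_property
    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_water_oxygen)

    @cached_property
    def donor_hydrogen_pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of (donor heavy, polar hydrogen) indices."""
        h = np.flatnonzero(self.is_polar_hydrogen)
        return np.column_stack([self.h_donor[h], h])

    @cached_property
    def nonbonded_exclusions(self) -> frozenset[tuple[int, int]]:
        """Atom pairs separated by one or two bonds (1-2 and 1-3)."""
        if not self.bonds:
            return frozenset()
        neigh: dict[int, set[int]] = {}
        for i, j in self.bonds:
            neigh.setdefault(i, set()).add(j)
            neigh.setdefault(j, set()).add(i)
        excl: set[tuple[int, int]] = set()
        for i, js in neigh.items():
            for j in js:
                excl.add((min(i, j), max(i, j)))
                for k in neigh.get(j, ()):  # 1-3 via j
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
        return frozenset(excl)

    def protein_residue_ids(self) -> np.ndarray:
        return np.unique(self.resids[self.protein_mask])


@dataclass
class Trajectory:
    """Coordinate frames (Å) with times (ns) over a fixed topology."""

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # ns, strictly increasing
    box: Optional[np.ndarray] = None  # (n_frames, 3) box edges, Å
    elp_id: str = "elp"
    replica_id: str = "r1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != len(self.times):
            raise ValueError("frame count must equal time count")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("atom count mismatch between frames and topology")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (len(self.times), 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_box(self, i: int) -> Optional[np.ndarray]:
        return None if self.box is None else self.box[i]


def write_frames_csv(traj: Trajectory, path) -> None:
    """Plain-text fallback trajectory format.

    Tidy CSV with columns frame, time_ns, atom (1-based), x, y, z —
    readable anywhere DCD/XTC support is unavailable.
    """
    n_atoms = traj.topology.n_atoms
    with open(path, "w") as fh:
        fh.write("frame,time_ns,atom,x,y,z\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            for a in range(n_atoms):
                x, y, z = traj.frames[f, a]
                fh.write(f"{f + 1},{t:.6f},{a + 1},{x:.4f},{y:.4f},{z:.4f}\n")


def read_frames_csv(topology: Topology, path, **kwargs) -> Trajectory:
    """Read the CSV fallback format back into a :class:`Trajectory`."""
    import pandas as pd

    df = pd.read_csv(path)
    frames_idx = np.sort(df["frame"].unique())
    n_atoms = topology.n_atoms
    frames = np.empty((len(frames_idx), n_atoms, 3))
    times = np.empty(len(frames_idx))
    for k, f in enumerate(frames_idx):
        sub = df[df["frame"] == f].sort_values("atom")
        if len(sub) != n_atoms:
            raise ValueError(f"frame {f}: expected {n_atoms} atoms, got {len(sub)}")
        frames[k] = sub[["x", "y", "z"]].to_numpy()
        times[k] = sub["time_ns"].iloc[0]
    return Trajectory(topology=topology, frames=frames, times=times, **kwargs)
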