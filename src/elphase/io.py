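"""File readers and writers.

Topologies come from PDB files; coordinate frames from DCD or XTC
(both via MDAnalysis) or from the plain-text CSV fallback in
:mod:`elphase.trajectory`.  Per-atom nonbonded parameters (partial
charge, LJ ε and rmin/2, vdW radius) are not stored in PDB files, so
they are supplied in a sidecar TSV keyed by (atom name, residue name);
without one, charges and ε default to zero and radii to element values,
which is enough for the purely geometric descriptors.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import ATOMIC_MASS_DA, VDW_RADIUS_A
from .trajectory import Topology, Trajectory, read_frames_csv

__all__ = [
    "load_params_tsv",
    "load_topology",
    "load_trajectory",
    "write_pdb",
    "write_dcd",
]

_WATER_RESNAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC", "H2O"}
_ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "K", "POT", "MG", "CA2"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "HN", "H", "OT1", "OT2"}


def load_params_tsv(path) -> pd.DataFrame:
    """Sidecar nonbonded parameters: columns name, resname, charge,
    epsilon, rmin_half and optionally radius."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "resname", "charge", "epsilon", "rmin_half"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return df


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    for two in ("NA", "CL", "MG"):
        if stripped.upper().startswith(two) and len(stripped) <= 2:
            return two
    return stripped[0].upper()


def _guess_bonds(coords: np.ndarray, elements: np.ndarray) -> list[tuple[int, int]]:
    """Distance-based bond guess: H to its nearest heavy atom within
    1.25 Å, heavy-heavy pairs within 1.85 Å."""
    tree = cKDTree(coords)
    bonds: set[tuple[int, int]] = set()
    heavy = elements != "H"
    for i in range(len(coords)):
        cut = 1.25 if elements[i] == "H" else 1.85
        for j in tree.query_ball_point(coords[i], cut):
            if j == i:
                continue
            if elements[i] == "H" and elements[j] == "H":
                continue
            if elements[i] == "H" and not heavy[j]:
                continue
            bonds.add((min(i, j), max(i, j)))
    return sorted(bonds)


def load_topology(pdb_path, params_tsv=None) -> Topology:
    """Build a :class:`Topology` from a PDB file (+ optional parameter TSV)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
    atoms = u.atoms
    names = np.array([a.name for a in atoms], dtype=object)
    resnames = np.array([a.resname for a in atoms], dtype=object)
    resids = np.array([a.resid for a in atoms], dtype=int) - 1  # 1-based on file
    elements = np.array([_guess_element(n) for n in names], dtype=object)

    segments = np.array(
        [
            "water" if rn.upper() in _WATER_RESNAMES
            else "ion" if rn.upper() in _ION_RESNAMES
            else "protein"
            for rn in resnames
        ],
        dtype=object,
    )
    coords = atoms.positions.astype(float)
    bonds = _guess_bonds(coords, elements)

    neighbor: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbor.setdefault(i, []).append(j)
        neighbor.setdefault(j, []).append(i)

    n = len(names)
    is_polar_h = np.zeros(n, dtype=bool)
    h_donor = np.full(n, -1, dtype=int)
    for i in range(n):
        if elements[i] != "H":
            continue
        heavies = [j for j in neighbor.get(i, []) if elements[j] in ("N", "O")]
        if len(heavies) == 1:
            is_polar_h[i] = True
            h_donor[i] = heavies[0]
    is_donor_heavy = np.zeros(n, dtype=bool)
    is_donor_heavy[h_donor[h_donor >= 0]] = True
    is_acceptor = (elements == "O") | ((elements == "N") & (segments == "protein"))
    is_water_oxygen = (segments == "water") & (elements == "O")
    is_backbone = (segments == "protein") & np.isin(
        np.array([nm.upper() for nm in names]), list(_BACKBONE_NAMES)
    )

    charge = np.zeros(n)
    epsilon = np.zeros(n)
    rmin_half = np.ones(n)
    radius = np.array([VDW_RADIUS_A.get(el, 1.7) for el in elements])
    if params_tsv is not None:
        table = load_params_tsv(params_tsv)
        lookup = {
            (str(r["name"]).upper(), str(r["resname"]).upper()): r
            for _, r in table.iterrows()
        }
        unmatched = []
        for i in range(n):
            row = lookup.get((names[i].upper(), resnames[i].upper()))
            if row is None:
                unmatched.append(f"{resnames[i]}:{names[i]}")
                continue
            charge[i] = row["charge"]
            epsilon[i] = row["epsilon"]
            rmin_half[i] = row["rmin_half"]
            if "radius" in row and np.isfinite(row.get("radius", np.nan)):
                radius[i] = row["radius"]
        if unmatched:
            warnings.warn(
                f"{len(unmatched)} atom(s) missing from the parameter table "
                f"(e.g. {unmatched[:3]}); zeros/defaults used",
                stacklevel=2,
            )
    mass = np.array([ATOMIC_MASS_DA.get(el, 12.011) for el in elements])

    return Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        segments=segments, is_backbone=is_backbone,
        is_water_oxygen=is_water_oxygen, is_donor_heavy=is_donor_heavy,
        is_acceptor=is_acceptor, is_polar_hydrogen=is_polar_h,
        radius=radius, charge=charge, epsilon=epsilon, rmin_half=rmin_half,
        mass=mass, h_donor=h_donor, bonds=bonds,
    )


def load_trajectory(
    pdb_path,
    traj_path,
    params_tsv=None,
    times_ns: Optional[np.ndarray] = None,
    elp_id: str = "elp",
    replica_id: str = "r1",
) -> Trajectory:
    """Read topology + frames into a :class:`Trajectory`.

    ``traj_path`` may be DCD, XTC (read via MDAnalysis; stored times are
    interpreted as ps and converted to ns) or the CSV fallback format.
    ``times_ns`` overrides file times, which DCD headers often lack.
    """
    topo = load_topology(pdb_path, params_tsv=params_tsv)
    path = str(traj_path)
    if path.endswith(".csv"):
        traj = read_frames_csv(topo, path, elp_id=elp_id, replica_id=replica_id)
        if times_ns is not None:
            traj.times = np.asarray(times_ns, dtype=float)
        return traj

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path), path)
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
        file_times = np.array([ts.time for ts in u.trajectory], dtype=float) / 1000.0
        boxes = np.array(
            [ts.dimensions[:3] if ts.dimensions is not None else [0, 0, 0]
             for ts in u.trajectory], dtype=float,
        )
    if times_ns is not None:
        times = np.asarray(times_ns, dtype=float)
    elif len(file_times) > 1 and np.all(np.diff(file_times) > 0):
        times = file_times
    else:
        times = np.arange(1, len(frames) + 1, dtype=float)
    box = boxes if np.all(boxes > 0) else None
    return Trajectory(
        topology=topo, frames=frames, times=times, box=box,
        elp_id=elp_id, replica_id=replica_id,
    )


def write_pdb(coords: np.ndarray, topology: Topology, path) -> None:
    """Minimal PDB writer (1-based serials and residue numbers)."""
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            x, y, z = coords[i]
            name = str(topology.names[i])[:4]
            resname = str(topology.resnames[i])[:3]
            fh.write(
                f"ATOM  {(i + 1) % 100000:>5d} {name:<4s} {resname:<3s} A"
                f"{(int(topology.resids[i]) + 1) % 10000:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{str(topology.elements[i]):>2s}\n"
            )
        fh.write("END\n")


def write_dcd(traj: Trajectory, path) -> None:
    """Write frames to DCD via MDAnalysis."""
    import MDAnalysis as mda

    n = traj.topology.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.frames[f]
                w.write(u.atoms)
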