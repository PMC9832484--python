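"""Shrake–Rupley solvent-accessible surface area.

Each atom's accessible area is estimated by placing a quasi-uniform
spiral of test points on a sphere of radius (r_vdw + probe) and counting
the fraction not buried inside any neighbouring atom's expanded sphere.
The default water probe radius is 1.4 Å.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ..constants import KYTE_DOOLITTLE
from ..trajectory import Topology

__all__ = ["shrake_rupley", "sasa"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_sphere_points: int = 256,
) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²).

    An isolated atom returns exactly 4π(r + probe)²; buried points are
    those inside any other atom's (r_j + probe) sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("every selected atom needs a positive vdW radius")
    n = len(coords)
    unit = _sphere_points(n_sphere_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            e2 = expanded[j] ** 2
            buried = d2 < e2 * (1.0 - 1e-9)
            if j < i:
                # test points exactly on a neighbour's surface belong to the
                # lower-index atom, so coincident duplicates are not
                # double-counted (their union is a single sphere)
                buried |= d2 <= e2 * (1.0 + 1e-9)
            accessible &= ~buried
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def _residue_is_hydrophobic(resname: str) -> bool:
    """Kyte–Doolittle sign rule: KD > 0 counts as hydrophobic."""
    one = _THREE_TO_ONE.get(resname.upper(), resname.upper() if len(resname) == 1 else "")
    return KYTE_DOOLITTLE.get(one, 0.0) > 0.0


def sasa(
    coords: np.ndarray,
    topology: Topology,
    selection: Optional[np.ndarray] = None,
    probe: float = 1.4,
    n_sphere_points: int = 256,
) -> dict[str, float]:
    """SASA of a selection, partitioned several ways (Å²).

    Returns total, hydrophobic/hydrophilic (split by the Kyte–Doolittle
    sign of each atom's residue) and backbone/sidechain splits.  Only
    atoms inside the selection occlude each other, matching the usual
    convention of computing protein SASA without solvent.
    """
    if selection is None:
        selection = topology.protein_mask
    idx = np.flatnonzero(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    areas = shrake_rupley(
        coords[idx], topology.radius[idx], probe=probe, n_sphere_points=n_sphere_points
    )
    hydrophobic = np.array(
        [_residue_is_hydrophobic(rn) for rn in topology.resnames[idx]]
    )
    backbone = topology.is_backbone[idx]
    total = float(areas.sum())
    return {
        "total": total,
        "hydrophobic": float(areas[hydrophobic].sum()),
        "hydrophilic": float(areas[~hydrophobic].sum()),
        "backbone": float(areas[backbone].sum()),
        "sidechain": float(areas[~backbone].sum()),
    }
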