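"""Pairwise nonbonded interaction energies (molecular-mechanics form).

Electrostatics: Coulomb sum 332.0636·qᵢqⱼ/r (kcal/mol with charges in e
and r in Å).  van der Waals: Lennard-Jones in the ε/rmin convention,
V = ε[(rmin/r)¹² − 2(rmin/r)⁶] with Lorentz–Berthelot-style combination
rules (ε_ij = √(εᵢεⱼ), rmin_ij = rmin_i/2 + rmin_j/2).  Both terms are
smoothly switched off between the switch distance (10 Å) and the cutoff
(12 Å) with the CHARMM/NAMD switching function.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..constants import COULOMB_KCAL_A_E2
from ..trajectory import Topology
from .geometry import minimum_image

__all__ = ["switching_function", "nonbonded_energy"]


def switching_function(r: np.ndarray, switch: float, cutoff: float) -> np.ndarray:
    """CHARMM switching factor: 1 below ``switch``, 0 beyond ``cutoff``."""
    r = np.asarray(r, dtype=float)
    s = np.ones_like(r)
    s[r >= cutoff] = 0.0
    mid = (r > switch) & (r < cutoff)
    c2, s2, r2 = cutoff**2, switch**2, r[mid] ** 2
    s[mid] = (c2 - r2) ** 2 * (c2 + 2.0 * r2 - 3.0 * s2) / (c2 - s2) ** 3
    return s


def nonbonded_energy(
    coords: np.ndarray,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 12.0,
    switch: float = 10.0,
    box: Optional[np.ndarray] = None,
) -> dict[str, float]:
    """Electrostatic and vdW energy between two atom groups (kcal/mol).

    Distinct groups: only cross pairs are summed.  Identical groups:
    each unordered pair once.  Pairs separated by one or two bonds
    (from the topology's bond list) are excluded, as in standard MM
    energy functions.
    """
    if np.any(~np.isfinite(topology.charge)) or np.any(~np.isfinite(topology.epsilon)):
        raise ValueError("charges and LJ parameters must be defined")
    ia = np.flatnonzero(group_a)
    ib = np.flatnonzero(group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty group")
    same = bool(np.array_equal(ia, ib))

    pi, pj = np.meshgrid(ia, ib, indexing="ij")
    pi, pj = pi.ravel(), pj.ravel()
    if same:
        keep = pi < pj
    else:
        keep = pi != pj  # overlapping selections: never pair an atom with itself
    pi, pj = pi[keep], pj[keep]
    if not same:
        # a pair inside the overlap of both groups must count only once
        overlap = group_a & group_b
        dup = overlap[pi] & overlap[pj] & (pi > pj)
        pi, pj = pi[~dup], pj[~dup]

    excl = topology.nonbonded_exclusions
    if excl:
        mask = np.array(
            [(min(i, j), max(i, j)) not in excl for i, j in zip(pi, pj)]
        )
        pi, pj = pi[mask], pj[mask]

    d = minimum_image(coords[pi] - coords[pj], box)
    r = np.linalg.norm(d, axis=1)
    within = r < cutoff
    pi, pj, r = pi[within], pj[within], r[within]
    if len(r) == 0:
        return {"electrostatic": 0.0, "vdW": 0.0}

    sw = switching_function(r, switch, cutoff)
    elec = COULOMB_KCAL_A_E2 * topology.charge[pi] * topology.charge[pj] / r
    eps = np.sqrt(topology.epsilon[pi] * topology.epsilon[pj])
    rmin = topology.rmin_half[pi] + topology.rmin_half[pj]
    ratio6 = (rmin / r) ** 6
    vdw = eps * (ratio6**2 - 2.0 * ratio6)
    return {
        "electrostatic": float((elec * sw).sum()),
        "vdW": float((vdw * sw).sum()),
    }
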