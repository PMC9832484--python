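"""Backbone secondary-structure assignment.

Residues are classified as helix, sheet, turn or coil from backbone
hydrogen-bond patterns (Kabsch–Sander electrostatic criterion) combined
with φ/ψ dihedral gates:

* helix — two consecutive i→i+4 N-H···O=C bonds, helical φ/ψ;
* sheet — inter-strand bridge patterns (parallel or antiparallel)
  between residues at least three apart, extended φ/ψ;
* turn  — an i→i+3 or i→i+4 bond not part of a helical run;
* coil  — everything else (including residues with missing backbone
  atoms, which are flagged with a warning).

This is a pattern-based assigner in the spirit of DSSP/STRIDE; it is
deliberately pluggable so a different assigner can be swapped into the
descriptor registry.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from ..trajectory import Topology

__all__ = ["assign_secondary_structure", "backbone_dihedrals"]

_Q_KCAL = 0.084 * 332.0  # Kabsch–Sander electrostatic prefactor
_E_HBOND = -0.5  # kcal/mol threshold


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def _collect_residues(topology: Topology) -> list[dict]:
    """Backbone atom indices per protein residue (None when missing)."""
    out = []
    prot = topology.protein_mask
    for rid in topology.protein_residue_ids():
        sel = np.flatnonzero(prot & (topology.resids == rid))
        names = {topology.names[i].upper(): i for i in sel}
        out.append(
            {
                "resid": rid,
                "N": names.get("N"),
                "CA": names.get("CA"),
                "C": names.get("C"),
                "O": names.get("O"),
                "H": names.get("HN", names.get("H")),
            }
        )
    return out


def backbone_dihedrals(coords: np.ndarray, residues: list[dict]) -> np.ndarray:
    """(n_res, 2) array of φ/ψ in degrees; NaN where undefined."""
    n = len(residues)
    phipsi = np.full((n, 2), np.nan)
    for i, res in enumerate(residues):
        if None in (res["N"], res["CA"], res["C"]):
            continue
        if i > 0 and residues[i - 1]["C"] is not None:
            phipsi[i, 0] = _dihedral(
                coords[residues[i - 1]["C"]], coords[res["N"]],
                coords[res["CA"]], coords[res["C"]],
            )
        if i < n - 1 and residues[i + 1]["N"] is not None:
            phipsi[i, 1] = _dihedral(
                coords[res["N"]], coords[res["CA"]],
                coords[res["C"]], coords[residues[i + 1]["N"]],
            )
    return phipsi


def _hbond_matrix(coords: np.ndarray, residues: list[dict]) -> np.ndarray:
    """HB[i, j]: amide N-H of residue i bonds the C=O of residue j."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    # amide hydrogen: explicit if present, else reconstructed along the
    # preceding carbonyl C=O direction (standard Kabsch–Sander placement)
    hpos: list[Optional[np.ndarray]] = []
    for i, res in enumerate(residues):
        if res["N"] is None:
            hpos.append(None)
            continue
        if res["H"] is not None:
            hpos.append(coords[res["H"]])
        elif i > 0 and residues[i - 1]["C"] is not None and residues[i - 1]["O"] is not None:
            co = coords[residues[i - 1]["C"]] - coords[residues[i - 1]["O"]]
            hpos.append(coords[res["N"]] + co / np.linalg.norm(co))
        else:
            hpos.append(None)
    for i in range(n):
        if hpos[i] is None:
            continue
        npos = coords[residues[i]["N"]]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if residues[j]["C"] is None or residues[j]["O"] is None:
                continue
            cpos, opos = coords[residues[j]["C"]], coords[residues[j]["O"]]
            r_on = np.linalg.norm(opos - npos)
            if r_on > 5.2:  # beyond any plausible bond
                continue
            r_ch = np.linalg.norm(cpos - hpos[i])
            r_oh = np.linalg.norm(opos - hpos[i])
            r_cn = np.linalg.norm(cpos - npos)
            e = _Q_KCAL * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[i, j] = e < _E_HBOND
    return hb


def _helical_phipsi(phi: float, psi: float) -> bool:
    if np.isnan(phi) or np.isnan(psi):
        return True  # terminal residues: do not veto on missing dihedrals
    return -160.0 < phi < -20.0 and -120.0 < psi < 50.0


def _extended_phipsi(phi: float, psi: float) -> bool:
    if np.isnan(phi) or np.isnan(psi):
        return True
    return phi < -45.0 and (psi > 45.0 or psi < -135.0)


def assign_secondary_structure(
    coords: np.ndarray, topology: Topology
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-residue classes plus class fractions (which sum to 1)."""
    residues = _collect_residues(topology)
    n = len(residues)
    if n == 0:
        raise ValueError("no protein residues in topology")
    missing = [
        r["resid"] for r in residues if None in (r["N"], r["CA"], r["C"], r["O"])
    ]
    if missing:
        warnings.warn(
            f"residues {missing} missing backbone atoms; assigned coil",
            stacklevel=2,
        )
    hb = _hbond_matrix(coords, residues)
    phipsi = backbone_dihedrals(coords, residues)
    labels = np.array(["coil"] * n, dtype=object)

    # helix: consecutive i -> i+4 bonds
    hb4 = np.array([hb[i + 4, i] if i + 4 < n else False for i in range(n)])
    for i in range(n - 5):
        if hb4[i] and hb4[i + 1]:
            for k in range(i + 1, i + 5):
                if _helical_phipsi(*phipsi[k]):
                    labels[k] = "helix"

    # sheet: bridge patterns between strands ≥3 residues apart
    for i in range(n):
        for j in range(i + 3, n):
            anti = (hb[i, j] and hb[j, i]) or (
                0 <= i - 1 and j + 1 < n and hb[i - 1, j + 1] and j - 1 >= 0
                and i + 1 < n and hb[j - 1, i + 1]
            )
            par = (
                i - 1 >= 0 and i + 1 < n and hb[j, i - 1] and hb[i + 1, j]
            ) or (
                j - 1 >= 0 and j + 1 < n and hb[i, j - 1] and hb[j + 1, i]
            )
            if anti or par:
                for k in (i, j):
                    if labels[k] != "helix" and _extended_phipsi(*phipsi[k]):
                        labels[k] = "sheet"

    # turn: i -> i+3 / i -> i+4 bond without a helical run
    for i in range(n):
        for step in (3, 4):
            j = i + step
            if j < n and hb[j, i]:
                for k in range(i + 1, j):
                    if labels[k] == "coil":
                        labels[k] = "turn"

    for r, res in zip(range(n), residues):
        if None in (res["N"], res["CA"], res["C"], res["O"]):
            labels[r] = "coil"

    fractions = {
        cls: float((labels == cls).sum()) / n
        for cls in ("helix", "sheet", "turn", "coil")
    }
    return labels, fractions
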