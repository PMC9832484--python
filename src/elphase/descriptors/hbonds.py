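"""Geometric hydrogen-bond detection.

A hydrogen bond is a (donor D, hydrogen H, acceptor A) triple with
D–A distance ≤ 3.5 Å and the D–H–A angle within 30° of linearity,
i.e. the angle at H between the H→D and H→A directions is at least
150°.  These are the standard VMD-style geometric criteria; the angle
convention (deviation from linearity measured at the hydrogen) is
stated explicitly because "D–H–A angle cutoff" is ambiguous.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from ..trajectory import Topology
from .geometry import minimum_image, neighbor_pairs_within

__all__ = ["find_hbonds", "count_hbonds"]


def find_hbonds(
    coords: np.ndarray,
    donor_hydrogen_pairs: np.ndarray,
    acceptor_indices: np.ndarray,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    box: Optional[np.ndarray] = None,
) -> list[tuple[int, int, int]]:
    """All (D, H, A) triples satisfying the geometric criteria.

    ``donor_hydrogen_pairs`` is an (n, 2) array of (donor heavy atom,
    attached polar hydrogen) index pairs; a donor with several polar
    hydrogens appears once per hydrogen.  A == D pairs are excluded.
    """
    donor_hydrogen_pairs = np.asarray(donor_hydrogen_pairs, dtype=int)
    acceptor_indices = np.asarray(acceptor_indices, dtype=int)
    if len(donor_hydrogen_pairs) == 0 or len(acceptor_indices) == 0:
        return []
    donors = donor_hydrogen_pairs[:, 0]
    hydros = donor_hydrogen_pairs[:, 1]
    cos_min = np.cos(np.deg2rad(180.0 - angle_cut))  # angle at H ≥ 150°

    neighbor_lists = neighbor_pairs_within(
        coords[donors], coords[acceptor_indices], d_cut, box=box
    )
    out: list[tuple[int, int, int]] = []
    for k, hits in enumerate(neighbor_lists):
        if not hits:
            continue
        d, h = donors[k], hydros[k]
        acc = acceptor_indices[np.asarray(hits, dtype=int)]
        acc = acc[acc != d]
        if len(acc) == 0:
            continue
        hd = minimum_image(coords[d] - coords[h], box)
        ha = minimum_image(coords[acc] - coords[h], box)
        nhd = np.linalg.norm(hd)
        nha = np.linalg.norm(ha, axis=1)
        with np.errstate(invalid="ignore"):
            cosang = (ha @ hd) / (nha * nhd)
        for a, c in zip(acc, cosang):
            # cos(angle at H) ≤ cos(150°) means the triple is near-linear
            if np.isfinite(c) and c <= cos_min:
                out.append((int(d), int(h), int(a)))
    return out


def count_hbonds(
    coords: np.ndarray,
    topology: Topology,
    donor_mask: np.ndarray,
    acceptor_mask: np.ndarray,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
    box: Optional[np.ndarray] = None,
    symmetric: bool = False,
) -> int:
    """Count hydrogen bonds from donors in ``donor_mask`` to acceptors
    in ``acceptor_mask``.

    With ``symmetric=True`` the reverse direction (donors in
    ``acceptor_mask`` donating to acceptors in ``donor_mask``) is added,
    which is the natural convention for e.g. protein–solvent bonds.
    Donor heavy atoms without an attached polar hydrogen cannot donate
    and are skipped with a warning.
    """
    pairs = topology.donor_hydrogen_pairs
    orphan = (
        topology.is_donor_heavy
        & donor_mask
        & ~np.isin(np.arange(topology.n_atoms), pairs[:, 0] if len(pairs) else [])
    )
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} donor heavy atom(s) without polar hydrogen skipped",
            stacklevel=2,
        )

    def _one_way(dmask, amask):
        if len(pairs) == 0:
            return []
        sel = dmask[pairs[:, 0]]
        acceptors = np.flatnonzero(topology.is_acceptor & amask)
        return find_hbonds(coords, pairs[sel], acceptors, d_cut, angle_cut, box)

    bonds = _one_way(donor_mask, acceptor_mask)
    if symmetric:
        reverse = _one_way(acceptor_mask, donor_mask)
        seen = set(bonds)
        bonds += [b for b in reverse if b not in seen]
    return len(bonds)
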