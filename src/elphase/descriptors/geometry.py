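"""Geometric descriptors: radius of gyration, superposed RMSD,
end-to-end distance and hydration-shell water counts."""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "radius_of_gyration",
    "rmsd_superposed",
    "kabsch_rotation",
    "end_to_end_distance",
    "hydration_shell_waters",
    "neighbor_pairs_within",
]


def radius_of_gyration(
    coords: np.ndarray, masses: Optional[np.ndarray] = None
) -> float:
    """Rg = sqrt(Σ mᵢ |rᵢ − r_com|² / Σ mᵢ); unit masses if none given."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty selection")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / masses.sum()))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, bool]:
    """Optimal proper rotation aligning centered ``mobile`` onto centered
    ``reference``; returns (R, degenerate_flag).

    Uses the SVD construction with a determinant sign correction so the
    result is always a proper rotation.  A (near-)collinear reference
    leaves the rotation underdetermined; this is flagged and callers
    fall back to translation-only superposition.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    degenerate = bool(s[0] > 0 and s[1] / s[0] < 1e-8)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, degenerate


def rmsd_superposed(frame: np.ndarray, reference: np.ndarray) -> float:
    """Minimal RMSD (Å) over rigid-body motions (Kabsch superposition)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise ValueError(
            f"selection size mismatch: {frame.shape} vs {reference.shape}"
        )
    if len(frame) == 0:
        raise ValueError("empty selection")
    mob = frame - frame.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    rot, degenerate = kabsch_rotation(mob, ref)
    if degenerate:
        warnings.warn(
            "collinear reference: rotation underdetermined, "
            "translation-only RMSD reported",
            stacklevel=2,
        )
        return float(np.sqrt(((mob - ref) ** 2).sum(axis=1).mean()))
    aligned = mob @ rot.T
    return float(np.sqrt(((aligned - ref) ** 2).sum(axis=1).mean()))


def end_to_end_distance(coords: np.ndarray) -> float:
    """Distance between the first and last atom of the selection."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two atoms")
    return float(np.linalg.norm(coords[-1] - coords[0]))


def neighbor_pairs_within(
    a: np.ndarray,
    b: np.ndarray,
    cutoff: float,
    box: Optional[np.ndarray] = None,
) -> list[list[int]]:
    """For each point in ``a``, indices of points in ``b`` within cutoff.

    With ``box`` given, distances use the minimum-image convention
    (coordinates are wrapped into the box first); otherwise boundaries
    are open.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(b) == 0:
        return [[] for _ in range(len(a))]
    if box is not None:
        box = np.asarray(box, dtype=float)
        if cutoff > box.min() / 2:
            raise ValueError("cutoff exceeds half the smallest box edge")
        a = np.mod(a, box)
        b = np.mod(b, box)
        tree = cKDTree(b, boxsize=box)
    else:
        tree = cKDTree(b)
    return tree.query_ball_point(a, cutoff)


def minimum_image(d: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return d
    return d - box * np.round(d / box)


def hydration_shell_waters(
    coords: np.ndarray,
    backbone_indices: np.ndarray,
    water_oxygen_indices: np.ndarray,
    cutoff: float = 3.15,
    box: Optional[np.ndarray] = None,
    return_indices: bool = False,
):
    """Waters whose oxygen lies within ``cutoff`` of any backbone atom.

    Each water is counted once.  Returns the count, or (with
    ``return_indices``) the array of shell water-oxygen atom indices.
    """
    if len(water_oxygen_indices) == 0:
        warnings.warn("no waters in topology; hydration shell is empty", stacklevel=2)
        return (0, np.array([], dtype=int)) if return_indices else 0
    if len(backbone_indices) == 0:
        raise ValueError("empty backbone selection")
    hits = neighbor_pairs_within(
        coords[water_oxygen_indices], coords[backbone_indices], cutoff, box=box
    )
    in_shell = np.array([len(h) > 0 for h in hits])
    shell = np.asarray(water_oxygen_indices)[in_shell]
    if return_indices:
        return int(in_shell.sum()), shell
    return int(in_shell.sum())
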