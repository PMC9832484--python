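"""Synthetic inputs for every pipeline stage.

Real inputs to this package are MD trajectories, turbidity-derived
phase labels, rheology records, FRAP traces and FTIR spectra.  None of
these ship with the package, so this module generates statistically
faithful stand-ins:

* descriptor matrices with two latent clusters and AR(1) temporal
  correlation, matching the shape of the MD study design (8 pseudo-ELPs
  × 3 replicas × 250 time points × 27 properties);
* polymer-in-water pseudo-peptide trajectories of tunable compactness,
  with idealized backbone geometry, explicit amide hydrogens, a single
  side-chain bead per residue and well-formed three-site waters;
* noisy single-exponential FRAP recoveries;
* amide-I spectra built from the five canonical Gaussian sub-bands.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASS_DA, VDW_RADIUS_A
from .descriptors.registry import DESCRIPTOR_NAMES
from .hydrogel import AMIDE_I_CENTERS, FRAPTrace, FTIRSpectrum
from .trajectory import Topology, Trajectory

__all__ = [
    "ClusterSpec",
    "ChainSpec",
    "gen_descriptor_dataset",
    "gen_chain_trajectory",
    "gen_frap_trace",
    "gen_ftir_spectrum",
    "place_atom",
    "build_peptide",
]


# ---------------------------------------------------------------------------
# descriptor-matrix generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterSpec:
    """Study-design parameters for the two-cluster descriptor dataset.

    Defaults mirror the MD study conditions: 4 ELPs per phase-behavior
    class, 3 replicas of 250 time points each, 27 descriptors of which
    6 carry the between-class separation, and AR(1) temporal
    correlation ρ = 0.5 within each replica.
    """

    n_elps_per_class: int = 4
    n_replicas: int = 3
    n_timepoints: int = 250
    n_descriptors: int = 27
    n_informative: int = 6
    delta: float = 4.0  # between-class mean shift in within-class sd units
    rho: float = 0.5  # AR(1) coefficient
    elp_sd: float = 0.5  # between-ELP (within-class) heterogeneity, sd units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_descriptors:
            raise ValueError("n_informative cannot exceed n_descriptors")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.elp_sd < 1.0):
            raise ValueError("elp_sd must lie in [0, 1)")


def gen_descriptor_dataset(
    spec: ClusterSpec,
) -> tuple[pd.DataFrame, dict[str, int], dict]:
    """Two-cluster descriptor table with AR(1) time correlation.

    Informative columns differ between classes by ``delta`` within-class
    standard deviations.  Each ELP also carries its own random offset
    per descriptor (sd ``elp_sd``), mimicking the sequence-driven
    differences that MD replicas of one ELP share; the AR(1) noise is
    scaled so the total within-class variance stays at 1.  Returns the
    tidy table, the per-ELP 0/1 labels and a ground-truth dict
    (informative columns, class means).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_descriptors <= len(DESCRIPTOR_NAMES):
        columns = DESCRIPTOR_NAMES[: spec.n_descriptors]
    else:
        columns = DESCRIPTOR_NAMES + [
            f"extra_{i}" for i in range(spec.n_descriptors - len(DESCRIPTOR_NAMES))
        ]
    informative = list(rng.choice(spec.n_descriptors, spec.n_informative, replace=False))
    shift = np.zeros(spec.n_descriptors)
    shift[informative] = spec.delta

    labels: dict[str, int] = {}
    rows = []
    times = 100.0 + 0.2 * np.arange(1, spec.n_timepoints + 1)
    n_total = 2 * spec.n_elps_per_class
    noise_sd = np.sqrt(1.0 - spec.elp_sd**2)
    for e in range(n_total):
        label = 1 if e < spec.n_elps_per_class else 0
        name = f"elp{e + 1:02d}"
        labels[name] = label
        mean = shift * label + spec.elp_sd * rng.standard_normal(spec.n_descriptors)
        for r in range(spec.n_replicas):
            eps = rng.standard_normal((spec.n_timepoints, spec.n_descriptors))
            x = np.empty_like(eps)
            x[0] = eps[0]
            scale = np.sqrt(1.0 - spec.rho**2)
            for t in range(1, spec.n_timepoints):
                x[t] = spec.rho * x[t - 1] + scale * eps[t]
            x = noise_sd * x + mean
            block = pd.DataFrame(x, columns=columns)
            block.insert(0, "time_ns", times)
            block.insert(0, "replica", f"r{r + 1}")
            block.insert(0, "elp", name)
            rows.append(block)
    data = pd.concat(rows, ignore_index=True)
    truth = {
        "informative_columns": [columns[i] for i in sorted(informative)],
        "delta": spec.delta,
        "rho": spec.rho,
        "class1_elps": [e for e, l in labels.items() if l == 1],
    }
    return data, labels, truth


# ---------------------------------------------------------------------------
# pseudo-peptide trajectory generator
# ---------------------------------------------------------------------------

# idealized backbone geometry (Å / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.010, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# per-atom-type nonbonded parameters: charge (e), LJ ε (kcal/mol), rmin/2 (Å)
_ATOM_PARAMS = {
    "N": (-0.47, 0.20, 1.85),
    "HN": (0.31, 0.046, 0.2245),
    "CA": (0.07, 0.055, 2.175),
    "C": (0.51, 0.11, 2.00),
    "O": (-0.51, 0.12, 1.70),
    "CB": (0.09, 0.055, 2.175),
    "OW": (-0.834, 0.1521, 1.7682),
    "HW": (0.417, 0.046, 0.2245),
}

_PSEUDO_RESNAMES = ("VAL", "PRO", "GLY", "ILE", "GLU", "LYS", "ALA", "SER")


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Internal-coordinate (NeRF) atom placement.

    Returns d with |c−d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(
    phis: Sequence[float],
    psis: Sequence[float],
    omegas: Optional[Sequence[float]] = None,
    with_hydrogens: bool = True,
    with_sidechain: bool = True,
    resnames: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, Topology]:
    """Build an idealized peptide backbone from φ/ψ (and ω) dihedrals.

    Atoms per residue: N, (HN), CA, C, O, (CB side-chain bead).  The
    first residue has no amide hydrogen.  Returns coordinates and a
    fully flagged/parameterized :class:`Topology`.
    """
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    omegas = [180.0] * n_res if omegas is None else list(omegas)
    resnames = list(resnames) if resnames is not None else ["GLY"] * n_res

    # seed atoms for the first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    c0 = place_atom(np.array([0.0, 1.0, 0.0]), n0, ca0, _B_CA_C, _A_N_CA_C, phis[0])

    backbone = [(n0, ca0, c0)]
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        ca_i = place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omegas[i - 1])
        c_i = place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phis[i])
        backbone.append((n_i, ca_i, c_i))

    names, elements, resids, rnames, coords, bonds = [], [], [], [], [], []
    atom_index: dict[tuple[int, str], int] = {}

    def add(resid, name, element, pos, bond_to=None):
        idx = len(names)
        names.append(name)
        elements.append(element)
        resids.append(resid)
        rnames.append(resnames[resid])
        coords.append(pos)
        atom_index[(resid, name)] = idx
        if bond_to is not None:
            bonds.append((atom_index[bond_to], idx))
        return idx

    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        add(i, "N", "N", n_i, bond_to=(i - 1, "C") if i > 0 else None)
        if with_hydrogens and i > 0:
            _, _, c_prev = backbone[i - 1]
            h_dir = -(
                (c_prev - n_i) / np.linalg.norm(c_prev - n_i)
                + (ca_i - n_i) / np.linalg.norm(ca_i - n_i)
            )
            h_dir /= np.linalg.norm(h_dir)
            add(i, "HN", "H", n_i + _B_N_H * h_dir, bond_to=(i, "N"))
        add(i, "CA", "C", ca_i, bond_to=(i, "N"))
        add(i, "C", "C", c_i, bond_to=(i, "CA"))
        # carbonyl O: trans to the next N (or to CA for the last residue)
        if i < n_res - 1:
            next_n = backbone[i + 1][0]
            o_psi = _dihedral4(n_i, ca_i, c_i, next_n) + 180.0
        else:
            o_psi = psis[i] + 180.0
        o_i = place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, o_psi)
        add(i, "O", "O", o_i, bond_to=(i, "C"))
        if with_sidechain:
            cb = place_atom(c_i, n_i, ca_i, _B_CA_CB, 110.5, 122.5)
            add(i, "CB", "C", cb, bond_to=(i, "CA"))

    coords_arr = np.array(coords)
    topo = _make_topology(names, elements, resids, rnames,
                          segments=["protein"] * len(names), bonds=bonds)
    return coords_arr, topo


def _dihedral4(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.degrees(np.arctan2(np.cross(b1, v) @ w, v @ w)))


def _make_topology(names, elements, resids, resnames, segments, bonds) -> Topology:
    names = np.array(names, dtype=object)
    elements = np.array(elements, dtype=object)
    resids = np.array(resids, dtype=int)
    resnames = np.array(resnames, dtype=object)
    segments = np.array(segments, dtype=object)
    n = len(names)

    is_backbone = np.array(
        [s == "protein" and nm in ("N", "HN", "CA", "C", "O")
         for nm, s in zip(names, segments)]
    )
    is_water_oxygen = np.array(
        [s == "water" and el == "O" for el, s in zip(elements, segments)]
    )
    is_polar_h = np.array(
        [(s == "protein" and nm == "HN") or (s == "water" and el == "H")
         for nm, el, s in zip(names, elements, segments)]
    )
    h_donor = np.full(n, -1, dtype=int)
    neighbor = {}
    for i, j in bonds:
        neighbor.setdefault(i, []).append(j)
        neighbor.setdefault(j, []).append(i)
    for h in np.flatnonzero(is_polar_h):
        heavies = [j for j in neighbor.get(h, []) if elements[j] != "H"]
        if len(heavies) != 1:
            raise ValueError(f"polar hydrogen {h} must bond exactly one heavy atom")
        h_donor[h] = heavies[0]
    is_donor_heavy = np.zeros(n, dtype=bool)
    is_donor_heavy[h_donor[h_donor >= 0]] = True
    is_acceptor = np.array(
        [(s == "protein" and nm == "O") or (s == "water" and el == "O")
         for nm, el, s in zip(names, elements, segments)]
    )

    param_key = []
    for nm, el, s in zip(names, elements, segments):
        if s == "water":
            param_key.append("OW" if el == "O" else "HW")
        else:
            param_key.append(nm)
    charge = np.array([_ATOM_PARAMS[k][0] for k in param_key])
    epsilon = np.array([_ATOM_PARAMS[k][1] for k in param_key])
    rmin_half = np.array([_ATOM_PARAMS[k][2] for k in param_key])
    radius = np.array([VDW_RADIUS_A[el] for el in elements])
    mass = np.array([ATOMIC_MASS_DA[el] for el in elements])

    return Topology(
        names=names, elements=elements, resids=resids, resnames=resnames,
        segments=segments, is_backbone=is_backbone,
        is_water_oxygen=is_water_oxygen, is_donor_heavy=is_donor_heavy,
        is_acceptor=is_acceptor, is_polar_hydrogen=is_polar_h,
        radius=radius, charge=charge, epsilon=epsilon, rmin_half=rmin_half,
        mass=mass, h_donor=h_donor, bonds=bonds,
    )


@dataclass(frozen=True)
class ChainSpec:
    """Parameters of the pseudo-peptide-in-water trajectory generator.

    ``compactness`` interpolates the backbone dihedral sampling between
    fully extended (0) and a compact helix-like fold (1); collapsed
    chains have systematically smaller radii of gyration.
    """

    n_residues: int = 40
    compactness: float = 0.5
    n_waters: int = 200
    box_edge: float = 60.0
    n_frames: int = 10
    dt_ns: float = 0.2
    t0_ns: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_residues, self.n_waters + 1, self.n_frames) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.compactness <= 1.0):
            raise ValueError("compactness must lie in [0, 1]")
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")


_EXTENDED = (-135.0, 135.0)
_COMPACT = (-60.0, -45.0)


def gen_chain_trajectory(spec: ChainSpec) -> Trajectory:
    """Pseudo-peptide chain in a box of waters, tunable compactness.

    Backbone dihedrals per residue interpolate between extended-strand
    and helical values with frame-to-frame jitter; water oxygens are
    placed uniformly in the box with excluded volume around the chain
    and each other.  Fails if the chain does not fit the box.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.compactness
    n = spec.n_residues
    resnames = [
        _PSEUDO_RESNAMES[i] for i in rng.integers(0, len(_PSEUDO_RESNAMES), size=n)
    ]
    base_phi = (1 - c) * _EXTENDED[0] + c * _COMPACT[0] + rng.normal(0, 5, n)
    base_psi = (1 - c) * _EXTENDED[1] + c * _COMPACT[1] + rng.normal(0, 5, n)

    frames = []
    topo = None
    half = spec.box_edge / 2.0
    for _ in range(spec.n_frames):
        phis = base_phi + rng.normal(0, 8.0, n)
        psis = base_psi + rng.normal(0, 8.0, n)
        coords, topo_f = build_peptide(phis, psis, resnames=resnames)
        coords = coords - coords.mean(axis=0)  # center the chain in the box
        extent = np.abs(coords).max()
        if extent > half - 3.0:
            raise ValueError(
                f"box edge {spec.box_edge} Å too small for chain extent {2 * extent:.1f} Å"
            )
        wcoords, wmeta = _place_waters(rng, coords, spec.n_waters, spec.box_edge)
        frames.append(np.vstack([coords, wcoords]))
        if topo is None:
            topo = _combine_with_waters(topo_f, wmeta, spec.n_waters)
    times = spec.t0_ns + spec.dt_ns * np.arange(1, spec.n_frames + 1)
    return Trajectory(topology=topo, frames=np.array(frames), times=times)


def _place_waters(rng, chain_coords, n_waters, box_edge):
    half = box_edge / 2.0
    placed = []
    oxygens = []
    attempts = 0
    while len(oxygens) < n_waters:
        attempts += 1
        if attempts > 200 * max(n_waters, 1):
            raise ValueError("box too small to place the requested waters")
        o = rng.uniform(-half, half, 3)
        if len(chain_coords) and np.min(np.linalg.norm(chain_coords - o, axis=1)) < 2.5:
            continue
        if oxygens and np.min(np.linalg.norm(np.array(oxygens) - o, axis=1)) < 2.4:
            continue
        oxygens.append(o)
        # random rigid-water orientation: OH 0.9572 Å, HOH 104.52°
        z = rng.standard_normal(3)
        z /= np.linalg.norm(z)
        perp = np.cross(z, rng.standard_normal(3))
        perp /= np.linalg.norm(perp)
        ang = np.deg2rad(104.52 / 2.0)
        h1 = o + 0.9572 * (np.cos(ang) * z + np.sin(ang) * perp)
        h2 = o + 0.9572 * (np.cos(ang) * z - np.sin(ang) * perp)
        placed.extend([o, h1, h2])
    return np.array(placed).reshape(-1, 3) if placed else np.empty((0, 3)), None


def _combine_with_waters(chain_topo: Topology, _unused, n_waters: int) -> Topology:
    names = list(chain_topo.names)
    elements = list(chain_topo.elements)
    resids = list(chain_topo.resids)
    resnames = list(chain_topo.resnames)
    segments = list(chain_topo.segments)
    bonds = list(chain_topo.bonds or [])
    next_resid = int(max(resids)) + 1 if resids else 0
    for w in range(n_waters):
        base = len(names)
        for nm, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            names.append(nm)
            elements.append(el)
            resids.append(next_resid + w)
            resnames.append("HOH")
            segments.append("water")
        bonds.extend([(base, base + 1), (base, base + 2)])
    return _make_topology(names, elements, resids, resnames, segments, bonds)


# ---------------------------------------------------------------------------
# FRAP and FTIR generators
# ---------------------------------------------------------------------------

def gen_frap_trace(
    plateau: float = 0.8,
    rate_per_s: float = 0.115,
    sigma_noise: float = 0.01,
    n_points: int = 200,
    t_max_s: float = 100.0,
    seed: int = 0,
) -> FRAPTrace:
    """Noisy single-exponential recovery I(t) = A(1 − e^(−kt)) + ε."""
    if min(plateau, rate_per_s, t_max_s) <= 0:
        raise ValueError("plateau, rate and t_max must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max_s, n_points)
    y = plateau * (1.0 - np.exp(-rate_per_s * t))
    if sigma_noise > 0:
        y = y + rng.normal(0.0, sigma_noise, n_points)
    return FRAPTrace(times_s=t, intensity=y)


def gen_ftir_spectrum(
    amplitudes: Sequence[float] = (0.3, 0.8, 1.0, 0.6, 0.15),
    sigmas: Sequence[float] = (8.0, 10.0, 9.0, 9.0, 6.0),
    centers: Sequence[float] = AMIDE_I_CENTERS,
    sigma_noise: float = 0.0,
    seed: int = 0,
) -> FTIRSpectrum:
    """Amide-I spectrum as a 5-Gaussian mixture on a 650–4000 cm⁻¹ grid.

    The grid spacing is 2 cm⁻¹, matching typical ATR-FTIR resolution;
    ``amplitudes`` are peak heights.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if np.any(amplitudes <= 0) or np.any(sigmas <= 0):
        raise ValueError("amplitudes and widths must be positive")
    rng = np.random.default_rng(seed)
    x = np.arange(650.0, 4000.0 + 1e-9, 2.0)
    y = np.zeros_like(x)
    for a, s, c in zip(amplitudes, sigmas, centers):
        y += a * np.exp(-0.5 * ((x - c) / s) ** 2)
    if sigma_noise > 0:
        y = y + rng.normal(0.0, sigma_noise, len(x))
    return FTIRSpectrum(wavenumbers=x, absorbance=y)
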