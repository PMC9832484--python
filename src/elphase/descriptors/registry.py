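"""The 27-descriptor registry and per-frame sampling.

Each trajectory frame yields one observation row of 27 named molecular
properties.  The default registry covers the property families known to
track LCST phase behavior — hydrogen-bond counts (with backbone /
sidechain and solvent / hydration-shell splits), chain geometry (radius
of gyration, backbone RMSD, end-to-end distance), solvent-accessible
surface area (total plus hydrophobic/hydrophilic and backbone/sidechain
splits), hydration-shell population, secondary-structure fractions and
pairwise nonbonded energies.  The registry is plain data: a user with a
different property list can build their own and pass it to
:func:`sample_descriptors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ..trajectory import Topology, Trajectory
from . import geometry
from .energy import nonbonded_energy as _nonbonded_energy
from .hbonds import count_hbonds as _count_hbonds
from .sasa import sasa as _sasa
from .secondary import assign_secondary_structure as _assign_ss

__all__ = ["Descriptor", "DescriptorRegistry", "FrameContext",
           "default_registry", "sample_descriptors", "DESCRIPTOR_NAMES"]


@dataclass(frozen=True)
class Descriptor:
    name: str
    unit: str
    compute: Callable[["FrameContext"], float]


@dataclass
class DescriptorRegistry:
    descriptors: list[Descriptor]

    def __post_init__(self) -> None:
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError("descriptor names must be unique")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)


class FrameContext:
    """One frame's coordinates plus lazily cached shared intermediates.

    Expensive intermediates (hydrogen-bond lists, SASA, hydration shell,
    secondary structure) are computed once per frame and shared by all
    descriptors that need them.
    """

    def __init__(
        self,
        coords: np.ndarray,
        topology: Topology,
        box: Optional[np.ndarray],
        reference: np.ndarray,
        shell_cutoff: float = 3.15,
        sasa_points: int = 256,
    ) -> None:
        self.coords = coords
        self.topology = topology
        self.box = box
        self.reference = reference
        self.shell_cutoff = shell_cutoff
        self.sasa_points = sasa_points
        self._cache: dict[str, object] = {}

    def _get(self, key: str, fn: Callable[[], object]):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    # --- masks -----------------------------------------------------------
    @property
    def protein(self) -> np.ndarray:
        return self.topology.protein_mask

    @property
    def backbone(self) -> np.ndarray:
        return self.topology.protein_mask & self.topology.is_backbone

    @property
    def water(self) -> np.ndarray:
        return self.topology.water_mask

    # --- shared intermediates --------------------------------------------
    def shell_oxygens(self) -> np.ndarray:
        def _compute():
            _, shell = geometry.hydration_shell_waters(
                self.coords,
                np.flatnonzero(self.backbone),
                self.topology.water_oxygen_indices,
                cutoff=self.shell_cutoff,
                box=self.box,
                return_indices=True,
            )
            return shell

        return self._get("shell", _compute)

    def shell_mask(self) -> np.ndarray:
        def _compute():
            shell_o = self.shell_oxygens()
            mask = np.zeros(self.topology.n_atoms, dtype=bool)
            shell_resids = set(self.topology.resids[shell_o].tolist())
            wm = self.water
            for i in np.flatnonzero(wm):
                if self.topology.resids[i] in shell_resids:
                    mask[i] = True
            return mask

        return self._get("shell_mask", _compute)

    def hbond_count(self, donor_key: str, acceptor_key: str, symmetric=False) -> int:
        masks = {
            "protein": self.protein,
            "backbone": self.backbone,
            "sidechain": self.topology.sidechain_mask,
            "water": self.water,
            "shell": self.shell_mask(),
        }
        key = f"hb:{donor_key}:{acceptor_key}:{symmetric}"
        return self._get(
            key,
            lambda: _count_hbonds(
                self.coords, self.topology, masks[donor_key], masks[acceptor_key],
                box=self.box, symmetric=symmetric,
            ),
        )

    def sasa(self) -> dict[str, float]:
        return self._get(
            "sasa",
            lambda: _sasa(
                self.coords, self.topology, self.protein,
                n_sphere_points=self.sasa_points,
            ),
        )

    def ss_fractions(self) -> dict[str, float]:
        return self._get(
            "ss", lambda: _assign_ss(self.coords, self.topology)[1]
        )

    def energy(self, pair: str) -> dict[str, float]:
        groups = {
            "elp_elp": (self.protein, self.protein),
            "elp_solvent": (self.protein, self.water),
            "elp_shell": (self.protein, self.shell_mask()),
        }

        def _compute():
            a, b = groups[pair]
            if not b.any():
                return {"electrostatic": 0.0, "vdW": 0.0}
            return _nonbonded_energy(
                self.coords, self.topology, a, b, box=self.box
            )

        return self._get(f"en:{pair}", _compute)


def default_registry() -> DescriptorRegistry:
    """The standard 27-descriptor set (see module docstring)."""
    d: list[Descriptor] = []

    def add(name, unit, fn):
        d.append(Descriptor(name, unit, fn))

    # hydrogen-bond counts (7)
    add("hbonds_intra", "count", lambda c: c.hbond_count("protein", "protein"))
    add("hbonds_intra_backbone", "count", lambda c: c.hbond_count("backbone", "backbone"))
    add("hbonds_intra_sidechain", "count",
        lambda c: c.hbond_count("protein", "protein")
        - c.hbond_count("backbone", "backbone"))
    add("hbonds_elp_solvent", "count",
        lambda c: c.hbond_count("protein", "water", symmetric=True))
    add("hbonds_elp_solvent_backbone", "count",
        lambda c: c.hbond_count("backbone", "water", symmetric=True))
    add("hbonds_elp_solvent_sidechain", "count",
        lambda c: c.hbond_count("protein", "water", symmetric=True)
        - c.hbond_count("backbone", "water", symmetric=True))
    add("hbonds_elp_shell", "count",
        lambda c: c.hbond_count("protein", "shell", symmetric=True))
    # chain geometry (4)
    add("rg", "angstrom",
        lambda c: geometry.radius_of_gyration(
            c.coords[c.protein], c.topology.mass[c.protein]))
    add("rg_backbone", "angstrom",
        lambda c: geometry.radius_of_gyration(
            c.coords[c.backbone], c.topology.mass[c.backbone]))
    add("rmsd_backbone", "angstrom",
        lambda c: geometry.rmsd_superposed(
            c.coords[c.backbone], c.reference[c.backbone]))
    add("end_to_end", "angstrom",
        lambda c: geometry.end_to_end_distance(c.coords[c.backbone]))
    # SASA (5)
    add("sasa_total", "angstrom^2", lambda c: c.sasa()["total"])
    add("sasa_hydrophobic", "angstrom^2", lambda c: c.sasa()["hydrophobic"])
    add("sasa_hydrophilic", "angstrom^2", lambda c: c.sasa()["hydrophilic"])
    add("sasa_backbone", "angstrom^2", lambda c: c.sasa()["backbone"])
    add("sasa_sidechain", "angstrom^2", lambda c: c.sasa()["sidechain"])
    # hydration shell (1)
    add("n_shell_waters", "count", lambda c: len(c.shell_oxygens()))
    # secondary structure (4)
    add("frac_helix", "fraction", lambda c: c.ss_fractions()["helix"])
    add("frac_sheet", "fraction", lambda c: c.ss_fractions()["sheet"])
    add("frac_turn", "fraction", lambda c: c.ss_fractions()["turn"])
    add("frac_coil", "fraction", lambda c: c.ss_fractions()["coil"])
    # nonbonded energies (6)
    add("elec_elp_elp", "kcal/mol", lambda c: c.energy("elp_elp")["electrostatic"])
    add("vdw_elp_elp", "kcal/mol", lambda c: c.energy("elp_elp")["vdW"])
    add("elec_elp_solvent", "kcal/mol", lambda c: c.energy("elp_solvent")["electrostatic"])
    add("vdw_elp_solvent", "kcal/mol", lambda c: c.energy("elp_solvent")["vdW"])
    add("elec_elp_shell", "kcal/mol", lambda c: c.energy("elp_shell")["electrostatic"])
    add("vdw_elp_shell", "kcal/mol", lambda c: c.energy("elp_shell")["vdW"])

    reg = DescriptorRegistry(d)
    assert len(reg) == 27
    return reg


DESCRIPTOR_NAMES: list[str] = default_registry().names


def sample_descriptors(
    traj: Trajectory,
    registry: Optional[DescriptorRegistry] = None,
    start_ns: float = 100.0,
    stride_ns: float = 0.2,
    sasa_points: int = 256,
) -> pd.DataFrame:
    """Descriptor table sampled every ``stride_ns`` after ``start_ns``.

    Samples fall at start + k·stride for k ≥ 1 up to the trajectory end,
    so a 100–150 ns window at 0.2 ns stride yields exactly 250 rows.
    The RMSD reference is the frame at (or nearest before) ``start_ns``.
    """
    if registry is None:
        registry = default_registry()
    times = traj.times
    t_end = times[-1]
    if t_end < start_ns + stride_ns:
        raise ValueError(
            f"trajectory spans only {times[0]:.3f}-{t_end:.3f} ns; "
            f"sampling starts at {start_ns} ns"
        )
    if len(times) > 1:
        dt = float(np.min(np.diff(times)))
        ratio = stride_ns / dt
        if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
            raise ValueError(
                f"stride {stride_ns} ns is not a multiple of the frame spacing {dt} ns"
            )

    n_samples = int(np.floor((t_end - start_ns) / stride_ns + 1e-9))
    targets = start_ns + stride_ns * np.arange(1, n_samples + 1)
    frame_idx = []
    for t in targets:
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) > 1e-6 * max(1.0, abs(t)) + 1e-9:
            raise ValueError(f"no frame at sample time {t} ns")
        frame_idx.append(i)

    ref_i = int(np.searchsorted(times, start_ns + 1e-9) - 1)
    ref_i = max(ref_i, 0)
    reference = traj.frames[ref_i]

    rows = []
    for i in frame_idx:
        ctx = FrameContext(
            traj.frames[i], traj.topology, traj.frame_box(i), reference,
            sasa_points=sasa_points,
        )
        row = {"elp": traj.elp_id, "replica": traj.replica_id,
               "time_ns": float(times[i])}
        for desc in registry.descriptors:
            row[desc.name] = desc.compute(ctx)
        rows.append(row)
    return pd.DataFrame(rows)
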