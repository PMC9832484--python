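"""Sequence-level design tools for elastin-like polypeptides (ELPs).

ELPs are built from short repeat blocks — the classic ``VPGXG``
pentapeptide plus physical (``IPAVG``, ``GAGAGS``) or chemical
(``VPGKG``) cross-linking blocks — arranged in nested repeat patterns
such as ``[(IPAVG)(VPGVG)2(VPGEG)(VPGVG)2(IPAVG)]12``.  This module
expands such block grammars to full residue strings and computes
sequence-level properties: average molecular mass, Kyte–Doolittle
hydropathy profiles and residue composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

from .constants import (
    AVERAGE_RESIDUE_MASS_DA,
    CANONICAL_RESIDUES,
    KYTE_DOOLITTLE,
    WATER_MASS_DA,
)

__all__ = [
    "BlockSpec",
    "ELPSequence",
    "HydropathyProfile",
    "ELP_LIBRARY",
    "expand_blocks",
    "average_mass",
    "hydropathy_profile",
    "residue_composition",
    "load_block_specs",
    "to_fasta",
]

# An element is (segment, repeat) where segment is either a residue
# string or a nested list of elements.
Element = tuple[Union[str, list], int]


@dataclass(frozen=True)
class BlockSpec:
    """A named, possibly nested, block-repeat grammar for one ELP."""

    name: str
    elements: Sequence[Element]

    def __post_init__(self) -> None:
        _validate_elements(self.elements, self.name)


@dataclass(frozen=True)
class ELPSequence:
    """A fully expanded ELP residue sequence."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.name}: empty sequence")
        bad = set(self.residues) - set(CANONICAL_RESIDUES)
        if bad:
            raise ValueError(
                f"{self.name}: non-canonical residue letter(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HydropathyProfile:
    """Sliding-window Kyte–Doolittle hydropathy along a sequence."""

    positions: np.ndarray  # 1-based residue indices
    scores: np.ndarray
    window: int

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.positions, self.scores])
        np.savetxt(path, arr, fmt=["%d", "%.6f"], delimiter=",",
                   header="position,score", comments="")


def _validate_elements(elements, name: str) -> None:
    if not elements:
        raise ValueError(f"{name}: block spec has no elements")
    for segment, repeat in elements:
        if not isinstance(repeat, int) or repeat < 1:
            raise ValueError(f"{name}: repeat count must be a positive int, got {repeat!r}")
        if isinstance(segment, str):
            bad = set(segment) - set(CANONICAL_RESIDUES)
            if bad:
                raise ValueError(
                    f"{name}: non-canonical residue letter(s) {sorted(bad)} in {segment!r}"
                )
        else:
            _validate_elements(segment, name)


def _expand_elements(elements) -> str:
    parts = []
    for segment, repeat in elements:
        unit = segment if isinstance(segment, str) else _expand_elements(segment)
        parts.append(unit * repeat)
    return "".join(parts)


def expand_blocks(spec: BlockSpec) -> ELPSequence:
    """Expand a block grammar, innermost repeats first, to a full sequence."""
    return ELPSequence(name=spec.name, residues=_expand_elements(spec.elements))


def average_mass(seq: Union[ELPSequence, str]) -> float:
    """Average molecular mass of the chain in kDa.

    Sum of average residue masses plus one water (18.015 Da) for the
    terminal H/OH.  Average (not monoisotopic) masses match intact
    LC-MS determinations of ELP molecular weight.
    """
    residues = seq.residues if isinstance(seq, ELPSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    mass_da = sum(AVERAGE_RESIDUE_MASS_DA[r] for r in residues) + WATER_MASS_DA
    return mass_da / 1000.0


def hydropathy_profile(
    seq: Union[ELPSequence, str], window: int = 9
) -> HydropathyProfile:
    """Windowed-mean Kyte–Doolittle hydropathy per residue.

    ``window`` must be odd and no longer than the sequence.  Positions
    near the termini use truncated (shorter) windows rather than
    padding, so edge scores are means over the residues actually
    present.
    """
    residues = seq.residues if isinstance(seq, ELPSequence) else seq
    n = len(residues)
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    raw = np.array([KYTE_DOOLITTLE[r] for r in residues])
    half = window // 2
    scores = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        scores[i] = raw[lo:hi].mean()
    return HydropathyProfile(
        positions=np.arange(1, n + 1), scores=scores, window=window
    )


def residue_composition(seq: Union[ELPSequence, str]) -> dict[str, float]:
    """Fraction of each residue type present (fractions sum to 1)."""
    residues = seq.residues if isinstance(seq, ELPSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    n = len(residues)
    return {r: residues.count(r) / n for r in sorted(set(residues))}


def to_fasta(seqs: Iterable[ELPSequence], path) -> None:
    """Write sequences to a FASTA file, 60 residues per line."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def load_block_specs(path) -> list[BlockSpec]:
    """Read block specs from a YAML config.

    Format::

        - name: E_AE
          elements:
            - {repeat: 12, blocks: [{seq: IPAVG, repeat: 1},
                                    {seq: VPGVG, repeat: 2}, ...]}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [BlockSpec(name=d["name"], elements=_parse_elements(d["elements"])) for d in raw]


def _parse_elements(raw) -> list[Element]:
    out: list[Element] = []
    for item in raw:
        repeat = int(item.get("repeat", 1))
        if "seq" in item:
            out.append((item["seq"], repeat))
        elif "blocks" in item:
            out.append((_parse_elements(item["blocks"]), repeat))
        else:
            raise ValueError(f"element needs 'seq' or 'blocks': {item!r}")
    return out


def _multiblock(name: str, cross: str, guest_block: str) -> BlockSpec:
    inner = [(cross, 1), ("VPGVG", 2), (guest_block, 1), ("VPGVG", 2), (cross, 1)]
    return BlockSpec(name=name, elements=[(inner, 12)])


def _triblock(name: str, cross: str, guest_block: str) -> BlockSpec:
    core = [("VPGVG", 2), (guest_block, 1), ("VPGVG", 2)]
    return BlockSpec(name=name, elements=[(cross, 12), (core, 12), (cross, 12)])


#: The eight-member ELP design library: multiblock/triblock arrangements of
#: physical (IPAVG, GAGAGS) or chemical (VPGKG) cross-linking blocks around
#: VPGVG repeats with glutamic acid (E) or isoleucine (I) guest residues.
ELP_LIBRARY: dict[str, BlockSpec] = {
    "E_AE": _multiblock("E_AE", "IPAVG", "VPGEG"),
    "E_AE_triblock": _triblock("E_AE_triblock", "IPAVG", "VPGEG"),
    "SE_E": _multiblock("SE_E", "GAGAGS", "VPGEG"),
    "E_KE": _triblock("E_KE", "VPGKG", "VPGEG"),
    "E_AI": _multiblock("E_AI", "IPAVG", "VPGIG"),
    "E_AI_triblock": _triblock("E_AI_triblock", "IPAVG", "VPGIG"),
    "SE_I": _multiblock("SE_I", "GAGAGS", "VPGIG"),
    "E_KI": _triblock("E_KI", "VPGKG", "VPGIG"),
}
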