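"""Predicted-structure models carrying per-residue pLDDT.

AlphaFold-style coordinate files store the predicted local distance
difference test (pLDDT, 0-100) in the temperature-factor column, replicated
on every atom of a residue.  This module reads such files (PDB or mmCIF),
exposes the per-residue scores, and aggregates them into whole-protein and
per-exon means with the usual confidence-band labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "PredictedStructure",
    "StructureFormatError",
    "StructureValidationError",
    "read_structure",
    "mean_plddt",
    "confidence_band",
    "per_exon_plddt",
]


class StructureFormatError(ValueError):
    """The coordinate file could not be parsed, or contains no residues."""


class StructureValidationError(ValueError):
    """Parsed content violates an invariant (e.g. pLDDT outside [0, 100])."""


@dataclass
class Residue:
    """One residue of a predicted structure.

    index is the 1-based ordinal position along the chain (file order);
    author_seq_id keeps the numbering from the file, which may have gaps.
    atoms maps atom names to xyz coordinates in Angstrom; CA is mandatory.
    """

    index: int
    aa: str
    atoms: dict[str, np.ndarray]
    plddt: float
    author_seq_id: int | None = None

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    @property
    def n(self) -> np.ndarray | None:
        return self.atoms.get("N")

    @property
    def c(self) -> np.ndarray | None:
        return self.atoms.get("C")

    def __post_init__(self) -> None:
        if "CA" not in self.atoms:
            raise StructureValidationError(f"residue {self.index}: no CA atom")
        if not (0.0 <= self.plddt <= 100.0):
            raise StructureValidationError(
                f"residue {self.index} ({self.aa}): pLDDT {self.plddt} outside [0, 100]"
            )
        for name, xyz in self.atoms.items():
            if not np.all(np.isfinite(xyz)):
                raise StructureValidationError(
                    f"residue {self.index}: non-finite coordinate for atom {name}"
                )


@dataclass
class PredictedStructure:
    """An ordered single-chain predicted structure."""

    protein_id: str
    residues: list[Residue]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
) -> PredictedStructure:
    """Read a predicted-structure file into a :class:`PredictedStructure`.

    The per-residue pLDDT is taken from the CA atom's temperature-factor
    field (the AlphaFold convention replicates it on all atoms, so CA is a
    canonical single source).  Only the first model is used; if the file
    holds several chains the first is taken with a warning.
    """
    path = Path(path)
    fmt = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }[format]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: cannot parse as {format}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models in file")
    model = st[0]
    if len(model) == 0:
        raise StructureFormatError(f"{path}: model contains no chains")
    if len(model) > 1:
        warnings.warn(
            f"{path}: {len(model)} chains found; using first chain "
            f"'{model[0].name}'",
            stacklevel=2,
        )
    chain = model[0]

    residues: list[Residue] = []
    for i, res in enumerate(chain, start=1):
        atoms: dict[str, np.ndarray] = {}
        ca_b = None
        for atom in res:
            if atom.element == gemmi.Element("H"):
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            atoms[atom.name] = pos
            if atom.name == "CA":
                # temperature-factor column carries two decimals; rounding
                # undoes the parser's float32 representation error
                ca_b = round(float(atom.b_iso), 2)
        if "CA" not in atoms:
            # non-polymer entities (waters, ligands) have no CA: skip quietly
            continue
        aa = _THREE_TO_ONE.get(res.name.upper(), "X")
        residues.append(
            Residue(
                index=len(residues) + 1,
                aa=aa,
                atoms=atoms,
                plddt=ca_b,
                author_seq_id=res.seqid.num,
            )
        )
        _ = i
    if not residues:
        raise StructureFormatError(f"{path}: structure contains no residues")
    return PredictedStructure(
        protein_id=path.stem, residues=residues, source_path=str(path)
    )


def mean_plddt(s: PredictedStructure) -> float:
    """Unweighted arithmetic mean of per-residue pLDDT (the whole-protein score)."""
    if len(s) == 0:
        raise ValueError("mean_plddt of an empty structure is undefined")
    return float(np.mean(s.plddt))


def confidence_band(score: float) -> str:
    """Map a pLDDT score to its confidence band.

    >90 very_high; 70-90 inclusive confident; 50-<70 low; <50 very_low.
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"pLDDT {score} outside [0, 100]")
    if score > 90.0:
        return "very_high"
    if score >= 70.0:
        return "confident"
    if score >= 50.0:
        return "low"
    return "very_low"


def per_exon_plddt(
    s: PredictedStructure,
    exon_map: Iterable[tuple[str, int, int]],
) -> list[tuple[str, float | None]]:
    """Mean pLDDT per exon, given 1-based inclusive residue ranges.

    An exon contributing zero residues (fully untranslated) is reported with
    ``None``.  Ranges must lie within the structure and not overlap.
    """
    exon_map = list(exon_map)
    n = len(s)
    covered = np.zeros(n, dtype=bool)
    scores = s.plddt
    out: list[tuple[str, float | None]] = []
    for exon_id, first, last in exon_map:
        if first > last:
            out.append((exon_id, None))
            continue
        if first < 1 or last > n:
            raise ValueError(
                f"exon {exon_id}: residue range {first}-{last} outside structure "
                f"of length {n}"
            )
        sel = slice(first - 1, last)
        if covered[sel].any():
            raise ValueError(f"exon {exon_id}: residue range overlaps a previous exon")
        covered[sel] = True
        out.append((exon_id, float(scores[sel].mean())))
    return out
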