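"""Backbone geometry: dihedrals, Ramachandran classification, superposition.

Used to back up pLDDT comparisons with explicit geometric evidence: phi/psi
outlier counts for a structure, and Kabsch least-squares RMSD between two
predicted structures after a sequence-guided residue pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure import PredictedStructure

__all__ = [
    "DihedralPair",
    "RamaRegionMap",
    "RamaCounts",
    "ResiduePairing",
    "dihedral",
    "phi_psi",
    "rama_outlier_count",
    "pair_residues",
    "kabsch",
    "kabsch_rmsd",
]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Result lies in [-180, 180).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -np.degrees(np.arctan2(y, x))
    return float(-180.0 if ang >= 180.0 or np.isclose(ang, 180.0) else ang)


@dataclass
class DihedralPair:
    """phi/psi for one residue; None where undefined (termini, missing atoms)."""

    index: int
    phi: float | None
    psi: float | None


def phi_psi(s: PredictedStructure) -> list[DihedralPair]:
    """Backbone phi/psi per residue.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    The first residue has no phi, the last no psi; residues missing a
    backbone atom get None for the affected angle.
    """
    out = []
    res = s.residues
    for i, r in enumerate(res):
        phi = psi = None
        if i > 0:
            prev_c = res[i - 1].c
            if prev_c is not None and r.n is not None and r.c is not None:
                phi = dihedral(prev_c, r.n, r.ca, r.c)
        if i < len(res) - 1:
            next_n = res[i + 1].n
            if next_n is not None and r.n is not None and r.c is not None:
                psi = dihedral(r.n, r.ca, r.c, next_n)
        out.append(DihedralPair(index=r.index, phi=phi, psi=psi))
    return out


class RamaCounts(NamedTuple):
    n_favored: int
    n_allowed_only: int
    n_outlier: int
    n_skipped: int


@dataclass
class RamaRegionMap:
    """Gridded (phi, psi) density with favored/allowed thresholds.

    grid[i, j] is the density for psi bin i, phi bin j; bins span
    [-180, 180) with width ``bin_width`` degrees.  A point is favored when
    its cell density >= favored_level, allowed when >= allowed_level
    (favored cells are also allowed), otherwise an outlier.
    """

    grid: np.ndarray
    bin_width: float
    favored_level: float
    allowed_level: float
    provenance: str = ""

    def __post_init__(self) -> None:
        n = int(round(360.0 / self.bin_width))
        if self.grid.shape != (n, n):
            raise ValueError(
                f"grid shape {self.grid.shape} inconsistent with bin width "
                f"{self.bin_width}"
            )
        if self.favored_level < self.allowed_level:
            raise ValueError("favored threshold below allowed threshold")

    def _cell(self, phi: float, psi: float) -> float:
        # wrap onto [-180, 180)
        phi = (phi + 180.0) % 360.0 - 180.0
        psi = (psi + 180.0) % 360.0 - 180.0
        j = int((phi + 180.0) // self.bin_width)
        i = int((psi + 180.0) // self.bin_width)
        return float(self.grid[i, j])

    def classify(self, phi: float, psi: float) -> str:
        d = self._cell(phi, psi)
        if d >= self.favored_level:
            return "favored"
        if d >= self.allowed_level:
            return "allowed"
        return "outlier"

    @classmethod
    def richardson_general(cls) -> "RamaRegionMap":
        """General-case map from the Top500 (Richardson lab) reference data.

        Loads the phi/psi histogram distributed with MDAnalysis (500
        high-resolution structures, 4-degree bins) and applies the density
        levels that package contours for its allowed/favored regions.
        """
        from MDAnalysis.analysis.data.filenames import Rama_ref

        grid = np.load(Rama_ref)
        return cls(
            grid=grid,
            bin_width=4.0,
            favored_level=17.0,
            allowed_level=1.0,
            provenance="Top500 general-case histogram (MDAnalysis Rama_ref)",
        )


def rama_outlier_count(
    s: PredictedStructure,
    region_map: RamaRegionMap | None = None,
) -> RamaCounts:
    """Classify each residue's (phi, psi) against a Ramachandran map.

    Glycine and proline residues, and residues with an undefined phi or psi
    (termini, missing atoms), are counted as skipped — the general-case map
    does not apply to them.  Counts sum to the structure length.
    """
    if region_map is None:
        region_map = RamaRegionMap.richardson_general()
    counts = {"favored": 0, "allowed": 0, "outlier": 0, "skipped": 0}
    for r, dp in zip(s.residues, phi_psi(s)):
        if r.aa in ("G", "P") or dp.phi is None or dp.psi is None:
            counts["skipped"] += 1
            continue
        counts[region_map.classify(dp.phi, dp.psi)] += 1
    return RamaCounts(
        n_favored=counts["favored"],
        n_allowed_only=counts["allowed"],
        n_outlier=counts["outlier"],
        n_skipped=counts["skipped"],
    )


@dataclass
class ResiduePairing:
    """Aligned residue index pairs (1-based, strictly increasing in both)."""

    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for (a0, b0), (a1, b1) in zip(self.pairs, self.pairs[1:]):
            if not (a0 < a1 and b0 < b1):
                raise ValueError("pairing not strictly increasing in both chains")

    def __len__(self) -> int:
        return len(self.pairs)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pair_residues(a: PredictedStructure, b: PredictedStructure) -> ResiduePairing:
    """Global sequence alignment pairing (BLOSUM62, affine gaps -11/-1).

    Only match columns (both sequences present) enter the pairing; the
    comparisons this supports are between isoforms/orthologs with clear
    sequence correspondence, so no structural alignment is attempted.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot pair an empty structure")
    aln = _make_aligner().align(a.sequence, b.sequence)[0]
    pairs: list[tuple[int, int]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        pairs.extend(
            (ai + 1, bi + 1)
            for ai, bi in zip(range(a_start, a_end), range(b_start, b_end))
        )
    return ResiduePairing(pairs=pairs)


def alignment_score(a_seq: str, b_seq: str) -> float:
    """Optimal global alignment score under the pairing's scoring scheme."""
    return float(_make_aligner().score(a_seq, b_seq))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q (Kabsch algorithm).

    Returns (rotation R, translation t, rmsd) such that P @ R.T + t best
    matches Q.  The rotation is determinant-corrected: reflections are never
    allowed, even if one would lower the RMSD.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    if len(P) < 3:
        raise ValueError("need >= 3 points for a well-defined superposition")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        warnings.warn("degenerate (collinear) point set in superposition",
                      stacklevel=2)
    t = qc - R @ pc
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


_ATOM_SETS = {
    "CA": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
}


def kabsch_rmsd(
    a: PredictedStructure,
    b: PredictedStructure,
    pairing: ResiduePairing | None = None,
    atoms: Literal["CA", "backbone", "heavy"] = "heavy",
) -> float:
    """RMSD after optimal rigid superposition over paired residues.

    ``atoms`` selects CA only, the backbone (N, CA, C, O where present), or
    all heavy atoms shared by name within each paired residue.  No outlier
    rejection is applied.  Missing atoms drop that atom for that pair.
    """
    if pairing is None:
        pairing = pair_residues(a, b)
    if len(pairing) < 3:
        raise ValueError("need >= 3 paired residues")
    pa, pb = [], []
    for ai, bi in pairing.pairs:
        ra = a.residues[ai - 1]
        rb = b.residues[bi - 1]
        if atoms == "heavy":
            names = sorted(set(ra.atoms) & set(rb.atoms))
        else:
            names = [n for n in _ATOM_SETS[atoms] if n in ra.atoms and n in rb.atoms]
        for name in names:
            pa.append(ra.atoms[name])
            pb.append(rb.atoms[name])
    _, _, rmsd = kabsch(np.array(pa), np.array(pb))
    return rmsd
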