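"""Synthetic benchmark generator with recorded ground truth.

Emits a complete toy input set — genome FASTA, GTF with canonical and
alternate isoforms, per-protein structure files (ideal-geometry backbones
with controlled per-residue pLDDT in the B-factor column), a scores table,
an expression table, and a MAF alignment against a second species — plus
the ground truth the triage cascade must recover.

The planted case deck instantiates every acceptance branch with margins
just above and just below each threshold, a same-CDS duplicate pair, an
intron-nested processed-pseudogene decoy, an over-length protein, and a
configurable fraction of loci whose most-sampled isoform has low (<70)
confidence.  Margin-critical cases use constant pLDDT plans so that the
two-decimal B-factor precision preserves the planted epsilon exactly;
everything else gets per-residue Gaussian jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import GenomicInterval, TranscriptModel, _revcomp
from .structure import PredictedStructure, Residue

__all__ = [
    "SynthConfig",
    "AltTruth",
    "LocusTruth",
    "GroundTruth",
    "BenchmarkPaths",
    "InfeasibleConfigError",
    "make_structure",
    "build_chain",
    "write_pdb",
    "make_benchmark",
    "IDEAL_TORSIONS",
]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA = 1.46
_B_CA_C = 1.52
_B_C_N = 1.33
_A_N_CA_C = 111.0
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_OMEGA = 180.0

IDEAL_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-119.0, 113.0)}


class InfeasibleConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ideal-geometry chain construction
# ---------------------------------------------------------------------------


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position atom d given a-b-c such that |cd|=bond, angle(b,c,d)=angle
    and dihedral(a,b,c,d)=torsion (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def build_chain(
    sequence: str,
    torsions: Sequence[tuple[float, float]],
    plddt: Sequence[float],
) -> PredictedStructure:
    """Backbone (N, CA, C) chain from per-residue (phi, psi) torsions.

    ``torsions[i]`` supplies (phi_i, psi_i); phi of the first residue and
    psi of the last are not used.  Omega is fixed trans (180 deg).
    """
    n = len(sequence)
    if len(torsions) != n or len(plddt) != n:
        raise ValueError("sequence, torsion plan and plddt plan lengths differ")
    coords: list[dict[str, np.ndarray]] = []
    # first residue in a canonical frame
    N0 = np.zeros(3)
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = coords[-1]
        psi_prev = torsions[i - 1][1]
        N = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CA = _place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, _OMEGA)
        C = _place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, torsions[i][0])
        coords.append({"N": N, "CA": CA, "C": C})
    residues = [
        Residue(
            index=i + 1,
            aa=sequence[i],
            atoms=coords[i],
            plddt=float(plddt[i]),
            author_seq_id=i + 1,
        )
        for i in range(n)
    ]
    return PredictedStructure(protein_id="synthetic", residues=residues)


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def write_pdb(s: PredictedStructure, path: str | Path) -> Path:
    """Write a minimal single-chain PDB; B-factor column carries pLDDT."""
    path = Path(path)
    lines = []
    serial = 1
    for r in s.residues:
        res3 = _ONE_TO_THREE.get(r.aa, "UNK")
        for name in ("N", "CA", "C", "O"):
            if name not in r.atoms:
                continue
            x, y, z = r.atoms[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A{r.index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{r.plddt:6.2f}"
                f"          {_ELEMENT[name]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _plan_torsions(n: int, segment_plan, rng) -> list[tuple[float, float]]:
    """Expand a [(kind, length)] plan to per-residue (phi, psi)."""
    torsions: list[tuple[float, float]] = []
    for kind, length in segment_plan:
        for _ in range(length):
            if kind == "coil":
                # randomized but inside the broad beta/PPII basin
                torsions.append(
                    (float(rng.uniform(-150, -60)), float(rng.uniform(90, 170)))
                )
            else:
                torsions.append(IDEAL_TORSIONS[kind])
    if len(torsions) != n:
        raise ValueError(
            f"segment plan covers {len(torsions)} residues, sequence has {n}"
        )
    return torsions


def make_structure(
    sequence: str,
    segment_plan: Sequence[tuple[str, int]],
    plddt_plan: Sequence[tuple[float, int]],
    seed: int = 0,
    path: str | Path | None = None,
) -> PredictedStructure:
    """Build an ideal-geometry chain and optionally write it as PDB.

    ``segment_plan``: [(kind, length)] with kind helix/strand/coil.
    ``plddt_plan``: [(value, length)] piecewise-constant pLDDT.
    """
    rng = np.random.default_rng(seed)
    n = len(sequence)
    plddt: list[float] = []
    for value, length in plddt_plan:
        plddt.extend([value] * length)
    if len(plddt) != n:
        raise ValueError(f"plddt plan covers {len(plddt)} residues, sequence has {n}")
    torsions = _plan_torsions(n, segment_plan, rng)
    s = build_chain(sequence, torsions, plddt)
    if path is not None:
        write_pdb(s, path)
        s.source_path = str(path)
    return s


# ---------------------------------------------------------------------------
# benchmark configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Study conditions for one benchmark instance."""

    seed: int = 0
    n_loci: int = 20
    isoforms_per_locus: tuple[int, int] = (1, 3)  # loser-locus alternate count
    case_mix: dict = field(
        default_factory=lambda: {
            "a_winner": 0.25,
            "b_winner": 0.15,
            "c_winner": 0.15,
            "loser": 0.25,
            "dup_pair": 0.10,
            "pseudogene": 0.10,
        }
    )
    include_edge_suite: bool = True
    frac_low_conf_top: float = 0.35
    plddt_jitter_sd: float = 1.5
    conservation_flip_prob: float = 0.2
    write_structures: bool = True

    def __post_init__(self) -> None:
        for k, v in self.case_mix.items():
            if not (0.0 <= v <= 1.0):
                raise InfeasibleConfigError(f"case_mix[{k}]={v} outside [0,1]")
        if not (0.0 <= self.frac_low_conf_top <= 1.0):
            raise InfeasibleConfigError("frac_low_conf_top outside [0,1]")
        if not (0.0 <= self.conservation_flip_prob <= 1.0):
            raise InfeasibleConfigError("conservation_flip_prob outside [0,1]")


@dataclass
class AltTruth:
    transcript_id: str
    case: str
    plddt: float  # planned mean
    length: int
    n_samples: int
    eligible: bool
    branch: str  # expected reported branch, "none" if rejected
    accepted: bool  # expected membership in the final (post-dedup) set


@dataclass
class LocusTruth:
    locus_id: str
    canonical_id: str
    strand: str
    canonical_plddt: float
    canonical_length: int
    canonical_samples: int
    low_top: bool
    top_id: str
    alternates: list[AltTruth]
    conserved: dict  # transcript_id -> bool


@dataclass
class GroundTruth:
    loci: list[LocusTruth]
    accepted: dict  # transcript_id -> branch, final set
    frac_low_conf_top: float
    n_higher_than_canonical: int


@dataclass
class BenchmarkPaths:
    genome: Path
    gtf: Path
    canonical: Path
    structures: Path | None
    scores: Path
    expression: Path
    maf: Path


# planned numbers: canonical 80.00 pLDDT / 100 aa / 50 samples unless noted.
# jitter=False marks margin-critical constant pLDDT plans.
_CASE_ALTS: dict[str, list[dict]] = {
    "a_winner": [
        dict(case="a_winner", plddt=87.40, length=95, samples=40,
             eligible=True, branch="A", jitter=True),
    ],
    "b_winner": [
        dict(case="b_winner", plddt=82.00, length=110, samples=55,
             eligible=True, branch="B", jitter=True),
    ],
    "c_winner": [
        dict(case="c_winner", plddt=88.00, length=60, samples=53,
             eligible=True, branch="C", jitter=True),
    ],
    "loser": [
        dict(case="loser_short", plddt=90.00, length=40, samples=30,
             eligible=True, branch="none", jitter=True),
        dict(case="loser_lowgain", plddt=81.00, length=95, samples=20,
             eligible=True, branch="none", jitter=True),
        dict(case="loser_unexpressed", plddt=87.40, length=60, samples=45,
             eligible=True, branch="none", jitter=True),
    ],
    # losers safe against a low-confidence (62) canonical: rejection must not
    # depend on the canonical's score
    "low_loser": [
        dict(case="loser_short", plddt=90.00, length=40, samples=30,
             eligible=True, branch="none", jitter=True),
        dict(case="loser_disordered", plddt=65.00, length=95, samples=20,
             eligible=False, branch="none", jitter=True),
        dict(case="loser_unexpressed", plddt=87.40, length=60, samples=45,
             eligible=True, branch="none", jitter=True),
    ],
    "dup_pair": [
        dict(case="dup_major", plddt=87.40, length=95, samples=10,
             eligible=True, branch="A", jitter=True, dup="major"),
        dict(case="dup_minor", plddt=87.40, length=95, samples=3,
             eligible=True, branch="A", jitter=True, dup="minor"),
    ],
    "pseudogene": [
        dict(case="pseudogene", plddt=95.00, length=60, samples=48,
             eligible=False, branch="none", jitter=True, pseudo=True),
        dict(case="a_winner", plddt=87.40, length=95, samples=40,
             eligible=True, branch="A", jitter=True),
    ],
    "edge_a": [
        dict(case="A_at_both", plddt=84.00, length=90, samples=40,
             eligible=True, branch="A", jitter=False),
        dict(case="A_plddt_below", plddt=83.99, length=90, samples=40,
             eligible=True, branch="none", jitter=False),
    ],
    "edge_ab": [
        dict(case="A_len_below", plddt=92.00, length=89, samples=40,
             eligible=True, branch="none", jitter=False),
        dict(case="B_at_all", plddt=80.00, length=105, samples=50,
             eligible=True, branch="B", jitter=False),
    ],
    "edge_b": [
        dict(case="B_len_below", plddt=80.00, length=104, samples=50,
             eligible=True, branch="none", jitter=False),
        dict(case="B_samples_below", plddt=80.00, length=105, samples=49,
             eligible=True, branch="none", jitter=False),
        dict(case="B_plddt_below", plddt=79.99, length=105, samples=50,
             eligible=True, branch="none", jitter=False),
    ],
    "edge_c": [
        dict(case="C_at_all", plddt=84.00, length=50, samples=50,
             eligible=True, branch="C", jitter=False),
        dict(case="C_len_below", plddt=84.00, length=49, samples=51,
             eligible=True, branch="none", jitter=False),
    ],
    "edge_c2": [
        dict(case="C_samples_below", plddt=84.00, length=50, samples=49,
             eligible=True, branch="none", jitter=False),
        dict(case="C_plddt_below", plddt=83.99, length=50, samples=52,
             eligible=True, branch="none", jitter=False),
    ],
    "gate_low": [
        dict(case="gate_below", plddt=69.99, length=95, samples=52,
             eligible=False, branch="none", jitter=False),
    ],
    "gate_pass": [
        dict(case="gate_at", plddt=70.00, length=95, samples=52,
             eligible=True, branch="A", jitter=False),
    ],
    "over_len": [
        dict(case="over_length", plddt=87.40, length=1001, samples=40,
             eligible=False, branch="none", jitter=True),
    ],
}

# canonical plans per locus kind: (plddt, jitter)
_CANON_PLAN = {
    "gate_low": (63.00, False),
    "gate_pass": (63.00, False),
    "edge_a": (80.00, False),
    "edge_ab": (80.00, False),
    "edge_b": (80.00, False),
    "edge_c": (80.00, False),
    "edge_c2": (80.00, False),
    "low_loser": (62.00, True),
}

_MANDATORY_KINDS = [
    "a_winner", "b_winner", "c_winner", "dup_pair", "pseudogene",
    "edge_a", "edge_ab", "edge_b", "edge_c", "edge_c2",
    "gate_low", "gate_pass", "over_len",
]

_CANON_LEN = 100
_CANON_SAMPLES = 50
_EXON1_CODONS = 10  # aa encoded by the shared first exon (incl. Met)
_U5 = 6
_U3 = 6
_PAD = 30
_GAP = 20

_SAFE_CODONS = [
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA", "ATG")
]
_BASES = np.array(list("ACGT"))


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_codons(rng, n: int) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n)
    return "".join(_SAFE_CODONS[i] for i in idx)


@dataclass
class _TxPlan:
    tid: str
    case: str
    plddt: float
    length: int
    samples: int
    jitter: bool
    eligible: bool
    branch: str
    is_canonical: bool = False
    pseudo: bool = False
    dup: str | None = None


def _assign_locus_kinds(cfg: SynthConfig, rng) -> list[tuple[str, bool]]:
    """Return (kind, low_top_planted) per locus, shuffled."""
    kinds: list[tuple[str, bool]] = []
    if cfg.include_edge_suite:
        if cfg.n_loci < len(_MANDATORY_KINDS):
            raise InfeasibleConfigError(
                f"n_loci={cfg.n_loci} cannot host the {len(_MANDATORY_KINDS)} "
                "mandatory case loci; lower them with include_edge_suite=False"
            )
        kinds.extend((k, k == "gate_low") for k in _MANDATORY_KINDS)
    k_low = round(cfg.frac_low_conf_top * cfg.n_loci)
    n_low_planted = sum(1 for _, low in kinds if low)
    n_fill = cfg.n_loci - len(kinds)
    n_low_fill = k_low - n_low_planted
    if n_low_fill < 0 or n_low_fill > n_fill:
        raise InfeasibleConfigError(
            f"cannot plant {k_low} low-confidence-top loci with "
            f"n_loci={cfg.n_loci} and this case deck"
        )
    kinds.extend([("low_loser", True)] * n_low_fill)
    names = list(cfg.case_mix)
    probs = np.array([cfg.case_mix[n] for n in names], dtype=float)
    if probs.sum() <= 0:
        raise InfeasibleConfigError("case_mix fractions sum to zero")
    probs = probs / probs.sum()
    for _ in range(n_fill - n_low_fill):
        kinds.append((str(rng.choice(names, p=probs)), False))
    perm = rng.permutation(len(kinds))
    return [kinds[i] for i in perm]


def _locus_plans(gid: str, kind: str, low: bool, cfg: SynthConfig, rng):
    """Canonical + alternate numeric plans for one locus."""
    canon_plddt, canon_jitter = _CANON_PLAN.get(
        "low_loser" if kind == "low_loser" else kind, (80.00, True)
    )
    canon = _TxPlan(
        tid=f"{gid}.c", case="canonical", plddt=canon_plddt, length=_CANON_LEN,
        samples=_CANON_SAMPLES, jitter=canon_jitter, eligible=False,
        branch="none", is_canonical=True,
    )
    if kind in ("loser", "low_loser"):
        lo, hi = cfg.isoforms_per_locus
        n_alt = int(rng.integers(lo, hi + 1))
        pool = _CASE_ALTS["low_loser" if kind == "low_loser" else "loser"]
        specs = [pool[i % len(pool)] for i in range(n_alt)]
    else:
        specs = _CASE_ALTS[kind]
    alts = []
    for j, spec in enumerate(specs, start=1):
        tid = f"{gid}.p1" if spec.get("pseudo") else f"{gid}.a{j}"
        alts.append(
            _TxPlan(
                tid=tid,
                case=spec["case"],
                plddt=spec["plddt"],
                length=spec["length"],
                samples=spec["samples"],
                jitter=spec["jitter"] and cfg.plddt_jitter_sd > 0,
                eligible=spec["eligible"],
                branch=spec["branch"],
                pseudo=bool(spec.get("pseudo")),
                dup=spec.get("dup"),
            )
        )
    return canon, alts


def _build_locus_sequence(canon: _TxPlan, alts: list[_TxPlan], rng):
    """Lay out one locus in local forward coordinates.

    Returns (sequence, models: {tid: (exons, cds)}, proteins: {tid: protein}).
    All two-exon transcripts share exon 1 (5'UTR + ATG + 9 codons) and a
    donor GT immediately after it; each gets a private acceptor + exon 2.
    The pseudogene decoy is a private single-exon ORF inside the shared
    intron; the canonical's exon 2 is laid out last so every decoy and
    alternate region falls within the canonical intron or upstream of its
    3' end.
    """
    from .annotation import translate

    seq: list[str] = [
        _rand_seq(rng, _PAD)
    ]
    pos = _PAD
    exon1_codons = _random_codons(rng, _EXON1_CODONS - 1)  # after ATG
    exon1_seq = (
        _rand_seq(rng, _U5) + "ATG" + exon1_codons
    )
    exon1 = (pos, pos + len(exon1_seq))
    exon1_cds = (pos + _U5, exon1[1])
    seq.append(exon1_seq)
    pos = exon1[1]
    seq.append("GT")  # shared donor
    pos += 2

    models: dict[str, tuple[list, list]] = {}
    proteins: dict[str, str] = {}

    def gap(n):
        nonlocal pos
        seq.append(_rand_seq(rng, n))
        pos += n

    # order: pseudogene first (inside canonical intron), alternates, canonical
    dup_anchor: dict[str, tuple] = {}
    ordered = [t for t in alts if t.pseudo] + [t for t in alts if not t.pseudo]
    ordered.append(canon)
    for t in ordered:
        if t.pseudo:
            gap(_GAP)
            body = _random_codons(rng, t.length - 1)
            tx_seq = (
                _rand_seq(rng, _U5)
                + "ATG" + body + "TAA"
                + _rand_seq(rng, _U3)
            )
            exon = (pos, pos + len(tx_seq))
            cds = (pos + _U5, exon[1] - _U3)
            seq.append(tx_seq)
            pos = exon[1]
            models[t.tid] = ([exon], [cds])
            proteins[t.tid] = translate(
                ("ATG" + body + "TAA")
            )
            continue
        if t.dup == "minor":
            # same CDS as the major twin, longer 3' UTR
            exon1_iv, cds1, cds2, exon2_major = dup_anchor["major"]
            gap(8)
            exon2 = (exon2_major[0], pos)
            models[t.tid] = ([exon1_iv, exon2], [cds1, cds2])
            proteins[t.tid] = dup_anchor["protein"]
            continue
        gap(_GAP)
        seq.append("AG")  # private acceptor (last 2 intron bases)
        pos += 2
        n_tail = t.length - _EXON1_CODONS
        if n_tail < 1:
            raise InfeasibleConfigError(
                f"{t.tid}: planned length {t.length} shorter than shared exon"
            )
        tail = _random_codons(rng, n_tail)
        exon2_seq = tail + "TAA" + _rand_seq(rng, _U3)
        exon2 = (pos, pos + len(exon2_seq))
        cds2 = (pos, pos + 3 * n_tail + 3)
        seq.append(exon2_seq)
        pos = exon2[1]
        models[t.tid] = ([exon1, exon2], [exon1_cds, cds2])
        proteins[t.tid] = translate("ATG" + exon1_codons + tail + "TAA")
        if t.dup == "major":
            dup_anchor["major"] = (exon1, exon1_cds, cds2, exon2)
            dup_anchor["protein"] = proteins[t.tid]
    gap(_PAD)
    return "".join(seq), models, proteins


def _plddt_values(plan: _TxPlan, length: int, cfg: SynthConfig, rng) -> np.ndarray:
    """Per-residue pLDDT, rounded to PDB B-factor precision (2 decimals).

    Jittered plans are piecewise segments re-centred on the planned mean;
    constant plans reproduce the planned value exactly.
    """
    if not plan.jitter:
        return np.full(length, round(plan.plddt, 2))
    n_seg = int(rng.integers(2, 4))
    bounds = sorted(rng.choice(np.arange(5, length - 4), size=n_seg - 1,
                               replace=False)) if length > 12 else []
    seg_edges = [0, *bounds, length]
    values = np.empty(length)
    for a, b in zip(seg_edges, seg_edges[1:]):
        values[a:b] = plan.plddt + rng.uniform(-2.0, 2.0)
    values = values - (values.mean() - plan.plddt)
    values = values + rng.normal(0.0, cfg.plddt_jitter_sd, size=length)
    values = np.clip(values, 0.0, 100.0)
    return np.round(values, 2)


def _write_fasta(path: Path, name: str, seq: str) -> None:
    with path.open("w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def make_benchmark(
    config: SynthConfig,
    outdir: str | Path,
) -> tuple[BenchmarkPaths, GroundTruth]:
    """Generate the full benchmark into *outdir*; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    kinds = _assign_locus_kinds(config, rng)
    genome_parts: list[str] = []
    genome_pos = 0
    gtf_lines: list[str] = []
    canonical_ids: list[str] = []
    expr_rows: list[dict] = []
    loci_truth: list[LocusTruth] = []
    protein_registry: dict[str, list[tuple[str, _TxPlan]]] = {}
    plan_by_tid: dict[str, _TxPlan] = {}
    locus_spans: list[tuple[int, int, str]] = []  # (start, end, seq)
    tx_models: dict[str, TranscriptModel] = {}
    maf_mutations: list[set[int]] = []  # per locus, mutated ref positions

    chrom = "chr1"
    spacer = 50

    for li, (kind, low) in enumerate(kinds, start=1):
        gid = f"G{li:03d}"
        canon, alts = _locus_plans(gid, kind, low, config, rng)
        local_seq, local_models, proteins = _build_locus_sequence(canon, alts, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        L = len(local_seq)
        if strand == "-":
            final_seq = _revcomp(local_seq)
            def tr(iv):
                return (L - iv[1], L - iv[0])
        else:
            final_seq = local_seq
            def tr(iv):
                return iv
        # spacer then locus
        genome_parts.append(_rand_seq(rng, spacer))
        genome_pos += spacer
        offset = genome_pos
        genome_parts.append(final_seq)
        genome_pos += L
        locus_spans.append((offset, offset + L, final_seq))

        all_plans = [canon, *alts]
        for t in all_plans:
            plan_by_tid[t.tid] = t
            exons, cds = local_models[t.tid]
            exons_g = [
                GenomicInterval(chrom, offset + tr(iv)[0], offset + tr(iv)[1], strand)
                for iv in exons
            ]
            cds_g = [
                GenomicInterval(chrom, offset + tr(iv)[0], offset + tr(iv)[1], strand)
                for iv in cds
            ]
            model = TranscriptModel(
                transcript_id=t.tid, gene_id=gid, strand=strand,
                exons=list(exons_g), cds=list(cds_g), protein=proteins[t.tid],
            )
            tx_models[t.tid] = model
            for iv in model.exons:
                gtf_lines.append(
                    f"{chrom}\tsynth\texon\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t."
                    f'\tgene_id "{gid}"; transcript_id "{t.tid}";'
                )
            for iv in model.cds:
                gtf_lines.append(
                    f"{chrom}\tsynth\tCDS\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t."
                    f'\tgene_id "{gid}"; transcript_id "{t.tid}";'
                )
            max_tpm = round(float(rng.lognormal(0.5, 1.0)), 2)
            brain = round(float(rng.uniform(0.0, max_tpm)), 2)
            expr_rows.append(
                {
                    "transcript_id": t.tid,
                    "n_samples": t.samples,
                    "max_tpm": max_tpm,
                    "brain": brain,
                    "testis": max_tpm,
                }
            )
            protein_registry.setdefault(proteins[t.tid], []).append((t.tid, t))
        canonical_ids.append(canon.tid)

        # conservation flips: maybe mutate one boundary base of one transcript
        mutated: set[int] = set()
        if rng.random() < config.conservation_flip_prob:
            spliced = [
                tx_models[t.tid] for t in all_plans if len(tx_models[t.tid].exons) > 1
            ]
            if spliced:
                victim = spliced[int(rng.integers(len(spliced)))]
                intron = victim.introns[int(rng.integers(len(victim.introns)))]
                which = rng.random() < 0.5
                if victim.strand == "+":
                    pts = (
                        (intron.start, intron.start + 1)
                        if which
                        else (intron.end - 2, intron.end - 1)
                    )
                else:
                    pts = (
                        (intron.end - 2, intron.end - 1)
                        if which
                        else (intron.start, intron.start + 1)
                    )
                mutated.add(int(pts[int(rng.integers(2))]))
        maf_mutations.append(mutated)

        conserved = {}
        for t in all_plans:
            model = tx_models[t.tid]
            bpos = set()
            for iv in model.introns:
                bpos.update((iv.start, iv.start + 1, iv.end - 2, iv.end - 1))
            conserved[t.tid] = bpos.isdisjoint(mutated)

        # planned top isoform: max samples, ties by plddt then id
        top = min(all_plans, key=lambda t: (-t.samples, -t.plddt, t.tid))
        loci_truth.append(
            LocusTruth(
                locus_id=gid,
                canonical_id=canon.tid,
                strand=strand,
                canonical_plddt=canon.plddt,
                canonical_length=canon.length,
                canonical_samples=canon.samples,
                low_top=low,
                top_id=top.tid,
                alternates=[
                    AltTruth(
                        transcript_id=t.tid, case=t.case, plddt=t.plddt,
                        length=t.length, n_samples=t.samples,
                        eligible=t.eligible, branch=t.branch,
                        accepted=t.branch != "none",
                    )
                    for t in alts
                ],
                conserved=conserved,
            )
        )
    genome_parts.append(_rand_seq(rng, spacer))
    genome_pos += spacer
    genome = "".join(genome_parts)

    # same-CDS dedup in the ground truth: keep only max-samples twin
    for lt in loci_truth:
        by_case = {a.case: a for a in lt.alternates}
        if "dup_minor" in by_case:
            by_case["dup_minor"].accepted = False
            by_case["dup_minor"].branch = "none"

    accepted = {
        a.transcript_id: a.branch
        for lt in loci_truth
        for a in lt.alternates
        if a.accepted
    }
    n_low = sum(1 for lt in loci_truth if lt.low_top)
    n_higher = 0
    for lt in loci_truth:
        for a in lt.alternates:
            if a.plddt > lt.canonical_plddt:
                n_higher += 1
    truth = GroundTruth(
        loci=loci_truth,
        accepted=accepted,
        frac_low_conf_top=n_low / len(loci_truth) if loci_truth else 0.0,
        n_higher_than_canonical=n_higher,
    )

    # --- structures and scores: one per distinct protein -------------------
    scores_rows = []
    structures_dir = outdir / "structures" if config.write_structures else None
    if structures_dir:
        structures_dir.mkdir(exist_ok=True)
    for protein, carriers in protein_registry.items():
        rep_tid = min(tid for tid, _ in carriers)
        plan = next(p for tid, p in carriers if tid == rep_tid)
        values = _plddt_values(plan, len(protein), config, rng)
        realized = float(values.mean())
        scores_rows.append((rep_tid, realized))
        if structures_dir:
            n = len(protein)
            # random secondary-structure segmentation
            seg_plan = []
            left = n
            while left > 0:
                ln = int(min(left, rng.integers(8, 25)))
                seg_plan.append(
                    (str(rng.choice(["helix", "strand", "coil"])), ln)
                )
                left -= ln
            torsions = _plan_torsions(n, seg_plan, rng)
            s = build_chain(protein, torsions, values)
            s.protein_id = rep_tid
            write_pdb(s, structures_dir / f"{rep_tid}.pdb")

    # --- MAF: per locus, identity alignment with planted boundary flips ----
    maf_lines = ["##maf version=1 scoring=synthetic", ""]
    for (start, end, seq), mutated in zip(locus_spans, maf_mutations):
        mouse = list(seq)
        for pos in mutated:
            col = pos - start
            mouse[col] = "C" if mouse[col].upper() != "C" else "T"
        texts = [(start, seq, "".join(mouse))]
        if rng.random() < 0.5 and len(seq) > 10:  # split into two blocks
            cut = int(rng.integers(3, len(seq) - 3))
            s0, s1 = texts[0][1][:cut], texts[0][1][cut:]
            m0, m1 = texts[0][2][:cut], texts[0][2][cut:]
            texts = [(start, s0, m0), (start + cut, s1, m1)]
        for bstart, hseq, mseq in texts:
            maf_lines.append("a score=0.0")
            maf_lines.append(
                f"s human.{chrom} {bstart} {len(hseq)} + {len(genome)} {hseq}"
            )
            maf_lines.append(
                f"s mouse.{chrom} {bstart} {len(mseq)} + {len(genome)} {mseq}"
            )
            maf_lines.append("")

    # --- write files --------------------------------------------------------
    genome_path = outdir / "genome.fa"
    _write_fasta(genome_path, chrom, genome)
    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text("\n".join(gtf_lines) + "\n")
    canonical_path = outdir / "canonical.txt"
    canonical_path.write_text("\n".join(canonical_ids) + "\n")
    scores_path = outdir / "scores.tsv"
    with scores_path.open("w") as fh:
        fh.write("protein_id\tmean_plddt\n")
        for rep_tid, realized in sorted(scores_rows):
            fh.write(f"{rep_tid}\t{realized:.6f}\n")
    expr_path = outdir / "expression.tsv"
    with expr_path.open("w") as fh:
        cols = ["transcript_id", "n_samples", "max_tpm", "brain", "testis"]
        fh.write("\t".join(cols) + "\n")
        for row in expr_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    maf_path = outdir / "alignment.maf"
    maf_path.write_text("\n".join(maf_lines) + "\n")

    paths = BenchmarkPaths(
        genome=genome_path,
        gtf=gtf_path,
        canonical=canonical_path,
        structures=structures_dir,
        scores=scores_path,
        expression=expr_path,
        maf=maf_path,
    )
    return paths, truth
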