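"""Splice-boundary conservation from genomic alignments (MAF).

A transcript's introns are the gaps between its exons; in transcription
order each intron should begin with the donor dinucleotide GT and end with
the acceptor AG.  A transcript's introns are called conserved in a target
species when every one of those boundary dinucleotides, mapped through the
alignment, reads GT (donor) / AG (acceptor) in the target.  Any gap,
substitution, or unaligned boundary position breaks conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

from .annotation import TranscriptModel, _revcomp

__all__ = [
    "MafRow",
    "MafBlock",
    "BoundaryCheck",
    "read_maf",
    "map_reference_position",
    "introns_conserved",
    "boundary_checks",
    "GAP",
    "UNCOVERED",
]

#: sentinel returned when the target species has a gap in the mapped column
GAP = "-"
#: sentinel returned when no block covers the reference position
UNCOVERED = None


@dataclass
class MafRow:
    """One `s` line of a MAF block: src is 'species.chrom'."""

    src: str
    start: int  # 0-based on the strand given
    size: int
    strand: str
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) > 1 else parts[0]


@dataclass
class MafBlock:
    rows: list[MafRow]

    def __post_init__(self) -> None:
        lengths = {len(r.text) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"MAF block rows differ in aligned length: {lengths}")
        for r in self.rows:
            ungapped = len(r.text) - r.text.count("-")
            if ungapped != r.size:
                raise ValueError(
                    f"MAF row {r.src}: ungapped length {ungapped} != size {r.size}"
                )

    def row_for(self, species: str) -> MafRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


@dataclass
class BoundaryCheck:
    """Conservation verdict for one intron of one transcript."""

    intron_index: int
    donor_ok: bool
    acceptor_ok: bool
    donor_observed: str
    acceptor_observed: str

    @property
    def ok(self) -> bool:
        return self.donor_ok and self.acceptor_ok


def read_maf(path: str | Path) -> list[MafBlock]:
    """Parse a MAF file (UCSC dialect) into blocks, all species retained."""
    blocks: list[MafBlock] = []
    for msa in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in msa:
            ann = rec.annotations
            rows.append(
                MafRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                )
            )
        blocks.append(MafBlock(rows=rows))
    return blocks


def map_reference_position(
    blocks: Iterable[MafBlock],
    chrom: str,
    pos: int,
    species: str,
    ref_species: str,
) -> str | None:
    """Base of *species* aligned to reference position *pos* (0-based).

    Returns the target base (uppercased), ``GAP`` ('-') when the target has
    a gap in that column, or ``UNCOVERED`` (None) when no block covers the
    position.  Reference rows must be on the + strand.
    """
    for block in blocks:
        ref = None
        for r in block.rows:
            if r.species == ref_species and r.chrom == chrom:
                ref = r
                break
        if ref is None:
            continue
        if ref.strand != "+":
            raise ValueError(
                f"reference row {ref.src} on - strand; normalize blocks first"
            )
        if not (ref.start <= pos < ref.start + ref.size):
            continue
        # walk columns to the one holding the pos-th ungapped reference base
        offset = pos - ref.start
        seen = 0
        for col, base in enumerate(ref.text):
            if base != "-":
                if seen == offset:
                    target = block.row_for(species)
                    if target is None:
                        return UNCOVERED
                    t = target.text[col]
                    return GAP if t == "-" else t.upper()
                seen += 1
    return UNCOVERED


def _boundary_positions(t: TranscriptModel) -> list[tuple[int, int, int, int]]:
    """Per intron: genomic positions (donor0, donor1, acceptor0, acceptor1).

    Positions are reference-forward-strand coordinates of the two donor and
    two acceptor bases, ordered 5'->3' along the transcript.  On the minus
    strand the donor sits at the intron's genomic right end and the bases
    must be read reverse-complemented.
    """
    out = []
    for iv in t.introns:
        if t.strand == "+":
            out.append((iv.start, iv.start + 1, iv.end - 2, iv.end - 1))
        else:
            out.append((iv.end - 1, iv.end - 2, iv.start + 1, iv.start))
    return out


def boundary_checks(
    t: TranscriptModel,
    blocks: Iterable[MafBlock],
    species: str,
    ref_species: str,
) -> list[BoundaryCheck]:
    """Check every intron boundary of *t* in the target species."""
    blocks = list(blocks)
    checks = []
    for i, (d0, d1, a0, a1) in enumerate(_boundary_positions(t)):
        obs = []
        for pos in (d0, d1, a0, a1):
            base = map_reference_position(blocks, t.chrom, pos, species, ref_species)
            if base is None or base == GAP:
                obs.append(base if base is not None else "?")
            else:
                obs.append(base if t.strand == "+" else _revcomp(base))
        donor = "".join(obs[:2])
        acceptor = "".join(obs[2:])
        checks.append(
            BoundaryCheck(
                intron_index=i,
                donor_ok=donor == "GT",
                acceptor_ok=acceptor == "AG",
                donor_observed=donor,
                acceptor_observed=acceptor,
            )
        )
    return checks


def introns_conserved(
    t: TranscriptModel,
    blocks: Iterable[MafBlock],
    species: str,
    ref_species: str,
) -> bool:
    """True iff every intron boundary of *t* is GT/AG in the target species.

    An intronless transcript is vacuously True.  An uncovered or gapped
    boundary position counts as not conserved, since conservation cannot be
    affirmed there.
    """
    return all(c.ok for c in boundary_checks(t, blocks, species, ref_species))
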