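"""Transcript annotation: GTF parsing, CDS extraction, translation, ORFs.

Internally all intervals are 0-based half-open; GTF input (1-based
inclusive) is converted on read.  A locus is a gene_id; each locus with a
designated canonical transcript (a MANE-style one-per-gene choice) becomes
a :class:`LocusGroup` of the canonical plus its alternates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "LocusGroup",
    "GtfParseError",
    "PrematureStopError",
    "read_gtf",
    "read_canonical_ids",
    "extract_cds_sequence",
    "translate",
    "find_orf",
    "group_distinct_proteins",
    "cds_overlaps",
    "MAX_TRIAGE_PROTEIN_LENGTH",
]

#: proteins longer than this are flagged over_length and excluded from triage
#: by default (the structure-prediction length cutoff, inclusive).
MAX_TRIAGE_PROTEIN_LENGTH = 1000


class GtfParseError(ValueError):
    pass


class PrematureStopError(ValueError):
    """An in-frame stop codon before the final codon of a CDS."""

    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon index {codon_index}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TranscriptModel:
    """A stranded exon/CDS chain for one transcript."""

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    protein: str | None = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS [{c.start},{c.end}) not contained "
                    "in any exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def protein_length(self) -> int:
        return len(self.protein) if self.protein else 0

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    @property
    def over_length(self) -> bool:
        return self.protein_length > MAX_TRIAGE_PROTEIN_LENGTH


@dataclass
class LocusGroup:
    """A canonical transcript and its alternate isoforms at one gene locus."""

    locus_id: str
    canonical: TranscriptModel
    alternates: list[TranscriptModel]

    def __post_init__(self) -> None:
        ids = {t.transcript_id for t in self.alternates}
        if self.canonical.transcript_id in ids:
            raise ValueError(
                f"{self.locus_id}: canonical transcript also listed as alternate"
            )

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return [self.canonical, *self.alternates]


def read_canonical_ids(path: str | Path) -> set[str]:
    """Read a one-transcript-id-per-line canonical list."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return ids


def read_gtf(
    path: str | Path,
    canonical_ids: set[str],
) -> tuple[list[LocusGroup], list[TranscriptModel]]:
    """Parse a GTF into locus groups anchored on canonical transcripts.

    Returns ``(loci, unanchored)`` where *unanchored* holds transcripts at
    gene loci without any canonical transcript.  Loci whose canonical id is
    listed but absent from the file are skipped with a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise GtfParseError(f"{path}: {exc}") from exc

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise GtfParseError(
                f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} "
                f"missing {exc} attribute"
            ) from exc
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if tid not in gene_of:
            gene_of[tid] = gid
            order.append(tid)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts: dict[str, TranscriptModel] = {}
    for tid in order:
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of[tid],
            strand=exons.get(tid, cds.get(tid))[0].strand,
            exons=exons.get(tid, []) or cds.get(tid, []),
            cds=cds.get(tid, []),
        )

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid in order:
        by_gene.setdefault(gene_of[tid], []).append(transcripts[tid])

    missing = canonical_ids - set(transcripts)
    if missing:
        warnings.warn(
            f"{len(missing)} canonical id(s) absent from {path}: "
            f"{sorted(missing)[:5]}...",
            stacklevel=2,
        )

    loci: list[LocusGroup] = []
    unanchored: list[TranscriptModel] = []
    for gid, members in by_gene.items():
        canon = [t for t in members if t.transcript_id in canonical_ids]
        if not canon:
            unanchored.extend(members)
            continue
        if len(canon) > 1:
            warnings.warn(
                f"locus {gid}: {len(canon)} canonical transcripts; using "
                f"{canon[0].transcript_id}",
                stacklevel=2,
            )
        loci.append(
            LocusGroup(
                locus_id=gid,
                canonical=canon[0],
                alternates=[t for t in members if t is not canon[0]],
            )
        )
    return loci, unanchored


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_cds_sequence(t: TranscriptModel, genome) -> str:
    """Spliced CDS nucleotides in transcription order.

    *genome* is a mapping of contig name to sliceable sequence (a
    :class:`pyfaidx.Fasta` works).  Minus-strand transcripts are
    reverse-complemented.  A length not divisible by 3 is truncated by the
    trailing 1-2 nt with a warning.
    """
    if not t.cds:
        raise ValueError(f"{t.transcript_id}: no CDS")
    contig = genome[t.chrom]
    pieces = []
    for iv in t.cds:
        piece = str(contig[iv.start : iv.end])
        if len(piece) != len(iv):
            raise ValueError(
                f"{t.transcript_id}: CDS [{iv.start},{iv.end}) outside contig "
                f"{t.chrom} bounds"
            )
        pieces.append(piece)
    seq = "".join(pieces).upper()
    if t.strand == "-":
        seq = _revcomp(seq)
    if len(seq) % 3:
        extra = len(seq) % 3
        warnings.warn(
            f"{t.transcript_id}: CDS length {len(seq)} not divisible by 3; "
            f"truncating {extra} trailing nt",
            stacklevel=2,
        )
        seq = seq[: len(seq) - extra]
    return seq


_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    A terminal stop codon is allowed and not included in the protein; a stop
    before the final codon raises :class:`PrematureStopError`.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    n_codons = len(cds) // 3
    aas = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOPS:
            if i != n_codons - 1:
                raise PrematureStopError(i)
            break
        try:
            aas.append(_FORWARD[codon])
        except KeyError as exc:
            raise ValueError(f"unknown codon {codon!r} at codon index {i}") from exc
    return "".join(aas)


def find_orf(mrna: str) -> tuple[int, str] | None:
    """Longest ATG-initiated open reading frame ending in a stop codon.

    Returns ``(start_offset, cds)`` with the stop codon included, or ``None``
    if no complete ORF exists.  Ties in length go to the 5'-most start.  This
    is a deliberate simplification of reference-guided ORF assignment: no
    Kozak context, no annotated-frame projection.
    """
    mrna = mrna.upper()
    best: tuple[int, int] | None = None  # (length_nt, -start) maximized
    for frame in range(3):
        next_stop: int | None = None
        stops: dict[int, int] = {}
        # walk backwards recording the next in-frame stop for each codon pos
        positions = range(frame, len(mrna) - 2, 3)
        for pos in reversed(positions):
            if mrna[pos : pos + 3] in _STOPS:
                next_stop = pos
            stops[pos] = next_stop
        for pos in positions:
            if mrna[pos : pos + 3] == "ATG" and stops[pos] is not None:
                length = stops[pos] + 3 - pos
                cand = (length, -pos)
                if best is None or cand > best:
                    best = cand
    if best is None:
        return None
    length, neg_start = best
    start = -neg_start
    return start, mrna[start : start + length]


def group_distinct_proteins(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, list[str]]:
    """Group transcript ids by exact protein-string equality."""
    groups: dict[str, list[str]] = {}
    for t in transcripts:
        if not t.protein:
            warnings.warn(
                f"{t.transcript_id}: no protein; excluded from grouping",
                stacklevel=2,
            )
            continue
        groups.setdefault(t.protein, []).append(t.transcript_id)
    return groups


def cds_overlaps(a: TranscriptModel, b: TranscriptModel) -> bool:
    """True iff the CDS intervals of a and b share >= 1 bp on the same strand.

    Anti-sense overlap does not count.  This is the rule that removes
    intron-nested processed pseudogenes from canonical comparisons.
    """
    if not a.cds or not b.cds:
        raise ValueError("cds_overlaps requires both transcripts to have a CDS")
    if a.strand != b.strand:
        return False
    return any(ca.overlaps(cb) for ca in a.cds for cb in b.cds)
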