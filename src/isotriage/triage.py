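"""The structure-guided isoform triage cascade.

For each alternate isoform at a canonical-anchored locus the cascade asks
whether predicted-structure confidence (mean pLDDT) plus expression
evidence make it a better candidate than the canonical isoform:

eligibility gate
    distinct protein, CDS overlap with the canonical, mean pLDDT >= 70
    (avoids intrinsically disordered proteins), protein <= 1000 aa.
acceptance branches (first that holds is reported)
    A: pLDDT at least 5% higher than canonical and at least 90% as long;
    B: at least 5% longer, pLDDT equal or higher, assembled in an equal or
       higher number of samples;
    C: at least 50% as long, pLDDT at least 5% higher, assembled in an
       equal or higher number of samples.
deduplication
    isoforms sharing an identical coding sequence share a score; only the
    one assembled in the most samples is kept (ties: smallest id).

"5% higher" is read as relative (x1.05), parallel to the length clauses;
all comparisons are non-strict (>=).  The thresholds are parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import (
    LocusGroup,
    TranscriptModel,
    cds_overlaps,
    group_distinct_proteins,
    MAX_TRIAGE_PROTEIN_LENGTH,
)
from .conservation import MafBlock, introns_conserved
from .expression import ExpressionSummary

__all__ = [
    "Thresholds",
    "IsoformRecord",
    "TriageDecision",
    "TriageRow",
    "TriageReport",
    "TranscriptomeSummary",
    "eligibility",
    "evaluate_branches",
    "deduplicate_by_cds",
    "run_triage",
    "summarize_transcriptome",
    "write_report",
    "load_scores",
    "build_protein_scores",
]


@dataclass(frozen=True)
class Thresholds:
    """Tunable cascade thresholds (defaults are the published choices)."""

    min_plddt: float = 70.0      # eligibility gate on the alternate's score
    rel_margin: float = 0.05     # "5% higher"/"5% longer", relative
    len_lo: float = 0.90         # branch A: alternate at least this fraction as long
    len_half: float = 0.50       # branch C: alternate at least this fraction as long
    max_len: int = MAX_TRIAGE_PROTEIN_LENGTH  # inclusive aa cutoff for triage


@dataclass
class IsoformRecord:
    """The joined row the cascade consumes for one isoform."""

    transcript_id: str
    locus_id: str
    plddt: float
    protein_length: int
    n_samples: int
    max_tpm: float
    protein: str
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"{self.transcript_id}: pLDDT {self.plddt} out of range")
        if self.protein_length < 1:
            raise ValueError(f"{self.transcript_id}: empty protein")


@dataclass
class TriageDecision:
    transcript_id: str
    eligible: bool
    accepted: bool
    branch: str  # "A" | "B" | "C" | "none"
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accepted and (not self.eligible or self.branch == "none"):
            raise ValueError("accepted implies eligible and a branch label")


@dataclass
class TriageRow:
    """One accepted isoform, with the evidence behind the call."""

    transcript_id: str
    locus_id: str
    alt_plddt: float
    canonical_id: str
    canonical_plddt: float
    alt_length: int
    canonical_length: int
    alt_n_samples: int
    canonical_n_samples: int
    alt_max_tpm: float
    branch: str
    introns_conserved: bool | None = None


@dataclass
class TriageReport:
    rows: list[TriageRow]
    decisions: list[TriageDecision]
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([asdict(r) for r in self.rows])
        if df.empty:
            df = pd.DataFrame(
                columns=[f.name for f in TriageRow.__dataclass_fields__.values()]
            )
        return df


def eligibility(
    alt: IsoformRecord,
    canonical: IsoformRecord,
    alt_model: TranscriptModel,
    canon_model: TranscriptModel,
    thresholds: Thresholds = Thresholds(),
) -> tuple[bool, list[str]]:
    """Gate an alternate isoform before branch evaluation."""
    if alt.locus_id != canonical.locus_id:
        raise ValueError(
            f"locus mismatch: {alt.locus_id} vs {canonical.locus_id}"
        )
    reasons = []
    if alt.protein == canonical.protein:
        reasons.append("not distinct: protein identical to canonical")
    if not cds_overlaps(alt_model, canon_model):
        reasons.append("no CDS overlap with canonical (pseudogene-like)")
    if alt.plddt < thresholds.min_plddt:
        reasons.append(
            f"pLDDT {alt.plddt:.2f} below gate {thresholds.min_plddt:g}"
        )
    if alt.protein_length > thresholds.max_len:
        reasons.append(
            f"over_length: {alt.protein_length} aa > {thresholds.max_len}"
        )
    return (not reasons), reasons


def evaluate_branches(
    alt: IsoformRecord,
    canonical: IsoformRecord,
    thresholds: Thresholds = Thresholds(),
) -> tuple[str, bool]:
    """Apply the three acceptance branches; returns (branch, accepted).

    The reported branch is the first of A, B, C that holds (label priority
    only; membership is the union).  Threshold products carry a 1e-9
    absolute slack so that a score exactly at a decimal threshold (e.g.
    84.00 vs 1.05 x 80.00) is not rejected by float round-off; the slack is
    far below the two-decimal resolution of the scores.
    """
    eps = 1e-9
    m = 1.0 + thresholds.rel_margin
    a = (
        alt.plddt >= m * canonical.plddt - eps
        and alt.protein_length >= thresholds.len_lo * canonical.protein_length - eps
    )
    b = (
        alt.protein_length >= m * canonical.protein_length - eps
        and alt.plddt >= canonical.plddt
        and alt.n_samples >= canonical.n_samples
    )
    c = (
        alt.protein_length >= thresholds.len_half * canonical.protein_length - eps
        and alt.plddt >= m * canonical.plddt - eps
        and alt.n_samples >= canonical.n_samples
    )
    for label, hit in (("A", a), ("B", b), ("C", c)):
        if hit:
            return label, True
    return "none", False


def deduplicate_by_cds(
    accepted: Sequence[tuple[IsoformRecord, TriageDecision]],
) -> list[tuple[IsoformRecord, TriageDecision]]:
    """Keep one isoform per identical protein: max n_samples, ties by id."""
    best: dict[str, tuple[IsoformRecord, TriageDecision]] = {}
    for pair in accepted:
        rec = pair[0]
        cur = best.get(rec.protein)
        if cur is None or (-rec.n_samples, rec.transcript_id) < (
            -cur[0].n_samples,
            cur[0].transcript_id,
        ):
            best[rec.protein] = pair
    kept = {id(p) for p in best.values()}
    return [pair for pair in accepted if id(pair) in kept]


def _build_record(
    t: TranscriptModel,
    locus_id: str,
    scores: Mapping[str, float],
    expr: Mapping[str, ExpressionSummary],
    is_canonical: bool,
) -> IsoformRecord | None:
    if not t.protein:
        warnings.warn(f"{t.transcript_id}: no protein; excluded", stacklevel=2)
        return None
    score = scores.get(t.protein)
    if score is None:
        warnings.warn(
            f"{t.transcript_id}: no structure score; excluded", stacklevel=2
        )
        return None
    e = expr.get(t.transcript_id)
    if e is None:
        warnings.warn(
            f"{t.transcript_id}: no expression record; using zeros", stacklevel=2
        )
        e = ExpressionSummary.absent(t.transcript_id)
    return IsoformRecord(
        transcript_id=t.transcript_id,
        locus_id=locus_id,
        plddt=score,
        protein_length=t.protein_length,
        n_samples=e.n_samples,
        max_tpm=e.max_tpm,
        protein=t.protein,
        is_canonical=is_canonical,
    )


def run_triage(
    loci: Iterable[LocusGroup],
    scores: Mapping[str, float],
    expr: Mapping[str, ExpressionSummary],
    maf: Sequence[MafBlock] | None = None,
    maf_species: str = "mouse",
    maf_ref_species: str = "human",
    thresholds: Thresholds = Thresholds(),
) -> TriageReport:
    """Run the full cascade over locus groups.

    ``scores`` maps protein string -> mean pLDDT (one score per distinct
    protein).  Loci whose canonical lacks a score are skipped with a
    warning; alternates without scores are excluded; missing expression
    records count as never assembled (zeros).
    """
    decisions: list[TriageDecision] = []
    accepted: list[tuple[IsoformRecord, TriageDecision]] = []
    context: dict[str, tuple[IsoformRecord, TranscriptModel]] = {}

    for locus in loci:
        canon_rec = _build_record(
            locus.canonical, locus.locus_id, scores, expr, is_canonical=True
        )
        if canon_rec is None:
            warnings.warn(
                f"locus {locus.locus_id}: canonical has no structure score; "
                "locus skipped",
                stacklevel=2,
            )
            continue
        for alt in locus.alternates:
            alt_rec = _build_record(
                alt, locus.locus_id, scores, expr, is_canonical=False
            )
            if alt_rec is None:
                continue
            ok, reasons = eligibility(
                alt_rec, canon_rec, alt, locus.canonical, thresholds
            )
            if not ok:
                decisions.append(
                    TriageDecision(
                        transcript_id=alt.transcript_id,
                        eligible=False,
                        accepted=False,
                        branch="none",
                        reasons=reasons,
                    )
                )
                continue
            branch, acc = evaluate_branches(alt_rec, canon_rec, thresholds)
            dec = TriageDecision(
                transcript_id=alt.transcript_id,
                eligible=True,
                accepted=acc,
                branch=branch,
                reasons=["passed eligibility"]
                + ([f"accepted via branch {branch}"] if acc else ["no branch held"]),
            )
            decisions.append(dec)
            if acc:
                accepted.append((alt_rec, dec))
                context[alt.transcript_id] = (canon_rec, alt)

    kept = deduplicate_by_cds(accepted)
    kept_ids = {rec.transcript_id for rec, _ in kept}
    for rec, dec in accepted:
        if rec.transcript_id not in kept_ids:
            dec.accepted = False
            dec.branch = "none"
            dec.reasons.append(
                "removed by same-CDS deduplication (fewer samples than twin)"
            )

    rows = []
    for rec, dec in kept:
        canon_rec, alt_model = context[rec.transcript_id]
        cons = (
            introns_conserved(alt_model, maf, maf_species, maf_ref_species)
            if maf is not None
            else None
        )
        rows.append(
            TriageRow(
                transcript_id=rec.transcript_id,
                locus_id=rec.locus_id,
                alt_plddt=rec.plddt,
                canonical_id=canon_rec.transcript_id,
                canonical_plddt=canon_rec.plddt,
                alt_length=rec.protein_length,
                canonical_length=canon_rec.protein_length,
                alt_n_samples=rec.n_samples,
                canonical_n_samples=canon_rec.n_samples,
                alt_max_tpm=rec.max_tpm,
                branch=dec.branch,
                introns_conserved=cons,
            )
        )
    rows.sort(key=lambda r: (r.locus_id, r.transcript_id))
    summary = {
        "n_accepted": len(rows),
        "n_loci": len({r.locus_id for r in rows}),
        "per_branch": {
            b: sum(1 for r in rows if r.branch == b) for b in ("A", "B", "C")
        },
    }
    return TriageReport(rows=rows, decisions=decisions, summary=summary)


@dataclass
class TranscriptomeSummary:
    """Transcriptome-level context statistics around the cascade."""

    n_higher_than_canonical: int
    frac_loci_top_isoform_below_70: float
    top_isoforms: pd.DataFrame  # one row per locus: top isoform by n_samples


def summarize_transcriptome(
    loci: Iterable[LocusGroup],
    scores: Mapping[str, float],
    expr: Mapping[str, ExpressionSummary],
) -> TranscriptomeSummary:
    """Count higher-scoring alternates and low-confidence top isoforms.

    The per-locus "top" isoform is the one assembled in the most samples
    (ties: higher pLDDT, then smallest id).
    """
    n_higher = 0
    top_rows = []
    for locus in loci:
        recs = []
        canon_rec = _build_record(
            locus.canonical, locus.locus_id, scores, expr, is_canonical=True
        )
        if canon_rec is None:
            continue
        recs.append(canon_rec)
        for alt in locus.alternates:
            r = _build_record(alt, locus.locus_id, scores, expr, is_canonical=False)
            if r is None:
                continue
            recs.append(r)
            if r.plddt > canon_rec.plddt:
                n_higher += 1
        top = min(recs, key=lambda r: (-r.n_samples, -r.plddt, r.transcript_id))
        top_rows.append(
            {
                "locus_id": locus.locus_id,
                "transcript_id": top.transcript_id,
                "plddt": top.plddt,
                "n_samples": top.n_samples,
                "is_canonical": top.is_canonical,
            }
        )
    df = pd.DataFrame(top_rows)
    frac = float((df["plddt"] < 70.0).mean()) if len(df) else 0.0
    return TranscriptomeSummary(
        n_higher_than_canonical=n_higher,
        frac_loci_top_isoform_below_70=frac,
        top_isoforms=df,
    )


def write_report(report: TriageReport, prefix: str | Path) -> tuple[Path, Path]:
    """Write the TSV report and JSON summary; returns their paths.

    The TSV mirrors the published supplementary-table fields, including an
    ``introns in mouse`` TRUE/FALSE column when conservation was checked.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = report.to_frame()
    df = df.rename(columns={"introns_conserved": "introns in mouse"})
    if df["introns in mouse"].notna().any():
        df["introns in mouse"] = df["introns in mouse"].map(
            {True: "TRUE", False: "FALSE"}
        )
    else:
        df = df.drop(columns=["introns in mouse"])
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False)
    js = prefix.with_suffix(".summary.json")
    js.write_text(json.dumps(report.summary, indent=2) + "\n")
    return tsv, js


def load_scores(path: str | Path) -> dict[str, float]:
    """Read a pre-computed scores table (TSV: protein_id, mean_plddt)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "mean_plddt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return dict(zip(df["protein_id"], df["mean_plddt"].astype(float)))


def build_protein_scores(
    loci: Iterable[LocusGroup],
    scores_by_id: Mapping[str, float],
    unanchored: Iterable[TranscriptModel] = (),
) -> dict[str, float]:
    """Map protein strings to scores via each distinct protein's representative.

    One structure is predicted per distinct protein and filed under the
    lexicographically smallest transcript id carrying it; this resolves
    protein string -> that representative's score.
    """
    transcripts = [t for locus in loci for t in locus.transcripts]
    transcripts += list(unanchored)
    groups = group_distinct_proteins(transcripts)
    out = {}
    for protein, tids in groups.items():
        rep = min(tids)
        if rep in scores_by_id:
            out[protein] = float(scores_by_id[rep])
    return out
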