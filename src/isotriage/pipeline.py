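"""File-level orchestration: load standard inputs and run the cascade.

Thin glue shared by the CLI, the analysis scripts and the tests: reads the
GTF + canonical list + genome, derives proteins, resolves one pLDDT score
per distinct protein (from a scores TSV and/or a directory of structure
files), and hands everything to the triage cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pyfaidx

from . import annotation, expression, structure, triage
from .annotation import LocusGroup, TranscriptModel
from .conservation import MafBlock, read_maf
from .expression import ExpressionSummary

__all__ = ["PipelineInputs", "load_inputs", "run_from_files"]


@dataclass
class PipelineInputs:
    loci: list[LocusGroup]
    unanchored: list[TranscriptModel]
    protein_scores: dict[str, float]
    expression: dict[str, ExpressionSummary]
    maf: list[MafBlock] | None = None


def load_inputs(
    gtf: str | Path,
    canonical: str | Path,
    genome: str | Path,
    expression_table: str | Path,
    scores: str | Path | None = None,
    structures: str | Path | None = None,
    maf: str | Path | None = None,
) -> PipelineInputs:
    """Load and join all pipeline inputs from files."""
    if scores is None and structures is None:
        raise ValueError("need a scores table and/or a structures directory")
    canonical_ids = annotation.read_canonical_ids(canonical)
    loci, unanchored = annotation.read_gtf(gtf, canonical_ids)
    fasta = pyfaidx.Fasta(str(genome))
    for locus in loci:
        for t in locus.transcripts:
            if t.cds:
                t.protein = annotation.translate(
                    annotation.extract_cds_sequence(t, fasta)
                )
    scores_by_id: dict[str, float] = {}
    if scores is not None:
        scores_by_id.update(triage.load_scores(scores))
    if structures is not None:
        paths = sorted(Path(structures).glob("*.pdb")) + sorted(
            Path(structures).glob("*.cif")
        )
        for p in paths:
            s = structure.read_structure(p)
            scores_by_id[s.protein_id] = structure.mean_plddt(s)
    protein_scores = triage.build_protein_scores(loci, scores_by_id, unanchored)
    expr = expression.read_expression_table(expression_table)
    blocks = read_maf(maf) if maf is not None else None
    return PipelineInputs(
        loci=loci,
        unanchored=unanchored,
        protein_scores=protein_scores,
        expression=expr,
        maf=blocks,
    )


def run_from_files(
    gtf: str | Path,
    canonical: str | Path,
    genome: str | Path,
    expression_table: str | Path,
    scores: str | Path | None = None,
    structures: str | Path | None = None,
    maf: str | Path | None = None,
    maf_species: str = "mouse",
    maf_ref_species: str = "human",
    thresholds: triage.Thresholds = triage.Thresholds(),
) -> triage.TriageReport:
    """Load inputs from files and run the triage cascade."""
    inputs = load_inputs(
        gtf, canonical, genome, expression_table,
        scores=scores, structures=structures, maf=maf,
    )
    return triage.run_triage(
        inputs.loci,
        inputs.protein_scores,
        inputs.expression,
        maf=inputs.maf,
        maf_species=maf_species,
        maf_ref_species=maf_ref_species,
        thresholds=thresholds,
    )
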