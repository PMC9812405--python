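"""Per-isoform expression summaries (GTEx-style).

The triage consumes two numbers per isoform: the count of RNA-seq samples
in which the isoform was assembled (presence, not a TPM cutoff) and its
maximum TPM across tissues.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSummary",
    "ExpressionSchemaError",
    "read_expression_table",
    "tpm_from_counts",
]

_REQUIRED = ("transcript_id", "n_samples")


class ExpressionSchemaError(ValueError):
    pass


@dataclass
class ExpressionSummary:
    transcript_id: str
    n_samples: int
    max_tpm: float
    per_tissue: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"{self.transcript_id}: negative n_samples")
        if self.max_tpm < 0:
            raise ValueError(f"{self.transcript_id}: negative max_tpm")
        if self.per_tissue:
            m = max(self.per_tissue.values())
            if not math.isclose(m, self.max_tpm, abs_tol=1e-9):
                raise ValueError(
                    f"{self.transcript_id}: max_tpm {self.max_tpm} != max over "
                    f"tissues {m}"
                )

    @classmethod
    def absent(cls, transcript_id: str) -> "ExpressionSummary":
        """Record for an isoform never assembled in the expression data."""
        return cls(transcript_id=transcript_id, n_samples=0, max_tpm=0.0)


def read_expression_table(path: str | Path) -> dict[str, ExpressionSummary]:
    """Read a tab-delimited expression summary.

    Required columns: ``transcript_id``, ``n_samples`` and either a
    ``max_tpm`` column or at least one per-tissue TPM column (any extra
    column is treated as a tissue; ``NA`` marks missing values).  When both
    are present they must agree.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for col in _REQUIRED:
        if col not in df.columns:
            raise ExpressionSchemaError(f"{path}: missing required column {col!r}")
    tissue_cols = [c for c in df.columns if c not in (*_REQUIRED, "max_tpm")]
    if "max_tpm" not in df.columns and not tissue_cols:
        raise ExpressionSchemaError(
            f"{path}: needs a max_tpm column or per-tissue TPM columns"
        )
    dup = df["transcript_id"].duplicated()
    if dup.any():
        raise ExpressionSchemaError(
            f"{path}: duplicate transcript_id(s): "
            f"{df.loc[dup, 'transcript_id'].tolist()[:5]}"
        )
    out: dict[str, ExpressionSummary] = {}
    for row in df.itertuples(index=False):
        rec = row._asdict()
        per_tissue = None
        if tissue_cols:
            per_tissue = {
                c: float(rec[c]) for c in tissue_cols if not pd.isna(rec[c])
            }
        if "max_tpm" in df.columns and not pd.isna(rec["max_tpm"]):
            max_tpm = float(rec["max_tpm"])
        elif per_tissue:
            max_tpm = max(per_tissue.values())
        else:
            max_tpm = 0.0
        out[rec["transcript_id"]] = ExpressionSummary(
            transcript_id=rec["transcript_id"],
            n_samples=int(rec["n_samples"]),
            max_tpm=max_tpm,
            per_tissue=per_tissue or None,
        )
    return out


def tpm_from_counts(
    counts: Sequence[float] | np.ndarray,
    lengths: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Transcripts-per-million from read counts and effective lengths.

    TPM_i = 1e6 * (counts_i / lengths_i) / sum_j (counts_j / lengths_j);
    the result sums to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise ValueError("effective lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return 1e6 * rate / total
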