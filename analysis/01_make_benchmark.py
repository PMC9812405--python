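"""Generate the synthetic benchmark the downstream analyses consume.

Emits a 20-locus toy transcriptome (genome, GTF, canonical list, ideal-
geometry structures with pLDDT in the B-factor column, scores and
expression tables, human-mouse MAF) into results/benchmark/, together with
the generator's ground truth, and prints what was planted.
"""

from __future__ import annotations

import json
import sys
from collections import Counter
from pathlib import Path

from isotriage.synthetic import SynthConfig, make_benchmark

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    outdir = ROOT / "results" / "benchmark"
    cfg = SynthConfig(seed=seed, write_structures=True)
    paths, truth = make_benchmark(cfg, outdir)
    cases = Counter(a.case for lt in truth.loci for a in lt.alternates)
    print(f"benchmark written to {outdir} (seed {seed})")
    print(f"  loci: {len(truth.loci)}  planted cases: {dict(cases)}")
    print(f"  expected accepted isoforms: {len(truth.accepted)}")
    print(f"  expected low-confidence-top fraction: {truth.frac_low_conf_top:.2f}")
    (outdir / "ground_truth.json").write_text(
        json.dumps(
            {
                "accepted": truth.accepted,
                "frac_low_conf_top": truth.frac_low_conf_top,
                "n_higher_than_canonical": truth.n_higher_than_canonical,
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
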