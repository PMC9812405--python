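from __future__ import annotations

import warnings

import numpy as np
import pytest

from isotriage import pipeline, synthetic, triage
from isotriage.synthetic import SynthConfig, build_chain, IDEAL_TORSIONS


@pytest.fixture(scope="session")
def benchmark(tmp_path_factory):
    """One full benchmark instance (seed 0) with structure files."""
    outdir = tmp_path_factory.mktemp("bench")
    cfg = SynthConfig(seed=0, write_structures=True)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        paths, truth = synthetic.make_benchmark(cfg, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def benchmark_inputs(benchmark):
    """The seed-0 benchmark loaded through the standard file readers."""
    paths, truth = benchmark
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        inputs = pipeline.load_inputs(
            paths.gtf, paths.canonical, paths.genome, paths.expression,
            scores=paths.scores, maf=paths.maf,
        )
    return inputs, truth


def run_benchmark_pipeline(seed: int, tmp_path, n_loci: int = 20,
                           write_structures: bool = False):
    """Generate a benchmark and run the full triage pipeline on its files."""
    outdir = tmp_path / f"bench_{seed}"
    cfg = SynthConfig(seed=seed, n_loci=n_loci, write_structures=write_structures)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        paths, truth = synthetic.make_benchmark(cfg, outdir)
        inputs = pipeline.load_inputs(
            paths.gtf, paths.canonical, paths.genome, paths.expression,
            scores=None if write_structures else paths.scores,
            structures=paths.structures if write_structures else None,
            maf=paths.maf,
        )
        report = triage.run_triage(
            inputs.loci, inputs.protein_scores, inputs.expression, maf=inputs.maf
        )
        summary = triage.summarize_transcriptome(
            inputs.loci, inputs.protein_scores, inputs.expression
        )
    return paths, truth, report, summary


@pytest.fixture
def helix20():
    tors = [IDEAL_TORSIONS["helix"]] * 20
    return build_chain("ACDEFHIKLMNQRSTVWYAC", tors, [85.0] * 20)


@pytest.fixture
def record_factory():
    """Build IsoformRecords with sensible defaults for cascade tests."""

    def make(tid="alt", locus="L1", plddt=80.0, length=100, n_samples=50,
             max_tpm=1.0, protein=None, is_canonical=False):
        return triage.IsoformRecord(
            transcript_id=tid, locus_id=locus, plddt=plddt,
            protein_length=length, n_samples=n_samples, max_tpm=max_tpm,
            protein=protein if protein is not None else f"PROT_{tid}",
            is_canonical=is_canonical,
        )

    return make
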