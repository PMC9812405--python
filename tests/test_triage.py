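from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isotriage.annotation import GenomicInterval, LocusGroup, TranscriptModel
from isotriage.expression import ExpressionSummary
from isotriage.triage import (
    Thresholds,
    TriageDecision,
    deduplicate_by_cds,
    eligibility,
    evaluate_branches,
    run_triage,
    summarize_transcriptome,
    write_report,
)


def _model(tid, cds_ivs, strand="+", protein="MK"):
    return TranscriptModel(
        tid, "g", strand,
        exons=[GenomicInterval("c", s, e, strand) for s, e in cds_ivs],
        cds=[GenomicInterval("c", s, e, strand) for s, e in cds_ivs],
        protein=protein,
    )


class TestEligibility:
    def test_identical_protein_ineligible(self, record_factory):
        canon = record_factory(tid="c", protein="MKV", is_canonical=True)
        alt = record_factory(tid="a", protein="MKV")
        ok, reasons = eligibility(
            alt, canon, _model("a", [(0, 30)]), _model("c", [(0, 30)])
        )
        assert not ok and any("not distinct" in r for r in reasons)

    def test_plddt_gate_is_inclusive_at_70(self, record_factory):
        canon = record_factory(tid="c", plddt=60.0, is_canonical=True)
        am, cm = _model("a", [(0, 30)]), _model("c", [(0, 30)])
        ok, _ = eligibility(record_factory(tid="a", plddt=69.9), canon, am, cm)
        assert not ok
        ok, _ = eligibility(record_factory(tid="a", plddt=70.0), canon, am, cm)
        assert ok

    def test_intronic_pseudogene_ineligible(self, record_factory):
        canon = record_factory(tid="c", is_canonical=True)
        alt = record_factory(tid="p", plddt=95.0)
        ok, reasons = eligibility(
            alt, canon,
            _model("p", [(40, 70)]),
            _model("c", [(0, 30), (100, 130)]),
        )
        assert not ok and any("overlap" in r for r in reasons)

    def test_over_length_ineligible(self, record_factory):
        canon = record_factory(tid="c", is_canonical=True)
        alt = record_factory(tid="a", length=1001, plddt=95.0)
        ok, reasons = eligibility(
            alt, canon, _model("a", [(0, 30)]), _model("c", [(0, 30)])
        )
        assert not ok and any("over_length" in r for r in reasons)
        alt = record_factory(tid="a", length=1000, plddt=95.0)
        ok, _ = eligibility(alt, canon, _model("a", [(0, 30)]), _model("c", [(0, 30)]))
        assert ok

    def test_locus_mismatch_raises(self, record_factory):
        with pytest.raises(ValueError, match="locus"):
            eligibility(
                record_factory(tid="a", locus="L2"),
                record_factory(tid="c", locus="L1"),
                _model("a", [(0, 30)]),
                _model("c", [(0, 30)]),
            )


def _brute_branches(alt, canon, thr=Thresholds()):
    """Plain-language re-statement of the three clauses, for cross-checking.

    Uses integer-scaled arithmetic (scores have two decimals) so the
    comparisons are exact.
    """
    p_alt = round(alt.plddt * 100)
    p_can = round(canon.plddt * 100)
    a = p_alt * 100 >= p_can * 105 and alt.protein_length * 10 >= (
        canon.protein_length * 9
    )
    b = (
        alt.protein_length * 100 >= canon.protein_length * 105
        and p_alt >= p_can
        and alt.n_samples >= canon.n_samples
    )
    c = (
        alt.protein_length * 2 >= canon.protein_length
        and p_alt * 100 >= p_can * 105
        and alt.n_samples >= canon.n_samples
    )
    if a:
        return "A", True
    if b:
        return "B", True
    if c:
        return "C", True
    return "none", False


class TestBranches:
    def test_equal_records_rejected(self, record_factory):
        canon = record_factory(tid="c", is_canonical=True)
        alt = record_factory(tid="a")
        assert evaluate_branches(alt, canon) == ("none", False)

    def test_branch_priority_reports_first_match(self, record_factory):
        canon = record_factory(tid="c", plddt=80.0, length=100, n_samples=10)
        alt = record_factory(tid="a", plddt=90.0, length=95, n_samples=50)
        # qualifies for both A and C; A is reported
        assert evaluate_branches(alt, canon) == ("A", True)

    def test_matches_brute_force_predicates_on_random_records(
        self, record_factory
    ):
        rng = np.random.default_rng(12)
        for _ in range(500):
            canon = record_factory(
                tid="c",
                plddt=round(rng.uniform(40, 95), 2),
                length=int(rng.integers(50, 300)),
                n_samples=int(rng.integers(0, 100)),
                is_canonical=True,
            )
            alt = record_factory(
                tid="a",
                plddt=round(rng.uniform(40, 100), 2),
                length=int(rng.integers(25, 350)),
                n_samples=int(rng.integers(0, 100)),
            )
            assert evaluate_branches(alt, canon) == _brute_branches(alt, canon)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        plddt=st.floats(70, 99, allow_nan=False),
        length=st.integers(30, 300),
        samples=st.integers(0, 100),
        d_plddt=st.floats(0, 10, allow_nan=False),
        d_samples=st.integers(0, 50),
    )
    def test_acceptance_monotone_in_plddt_and_samples(
        self, plddt, length, samples, d_plddt, d_samples
    ):
        from isotriage.triage import IsoformRecord

        canon = IsoformRecord("c", "L", 80.0, 100, 50, 1.0, "MC", True)
        alt = IsoformRecord("a", "L", plddt, length, samples, 1.0, "MA")
        _, accepted = evaluate_branches(alt, canon)
        better = IsoformRecord(
            "a", "L", min(plddt + d_plddt, 100.0), length,
            samples + d_samples, 1.0, "MA",
        )
        _, accepted_better = evaluate_branches(better, canon)
        if accepted:
            assert accepted_better


class TestDedup:
    def _pair(self, record_factory, tid, samples, protein="MSAME"):
        rec = record_factory(tid=tid, n_samples=samples, protein=protein)
        dec = TriageDecision(tid, True, True, "A", [])
        return rec, dec

    def test_keeps_highest_sample_twin(self, record_factory):
        pairs = [
            self._pair(record_factory, "t_low", 3),
            self._pair(record_factory, "t_high", 10),
        ]
        kept = deduplicate_by_cds(pairs)
        assert [r.transcript_id for r, _ in kept] == ["t_high"]

    def test_tie_broken_by_smallest_id(self, record_factory):
        pairs = [
            self._pair(record_factory, "t_b", 5),
            self._pair(record_factory, "t_a", 5),
        ]
        kept = deduplicate_by_cds(pairs)
        assert [r.transcript_id for r, _ in kept] == ["t_a"]

    def test_distinct_proteins_unchanged(self, record_factory):
        pairs = [
            self._pair(record_factory, "t1", 5, protein="MA"),
            self._pair(record_factory, "t2", 3, protein="MB"),
        ]
        assert deduplicate_by_cds(pairs) == pairs

    def test_output_has_distinct_proteins(self, record_factory):
        rng = np.random.default_rng(13)
        pairs = [
            self._pair(
                record_factory, f"t{i}", int(rng.integers(0, 20)),
                protein=str(rng.choice(["MA", "MB", "MC"])),
            )
            for i in range(20)
        ]
        kept = deduplicate_by_cds(pairs)
        proteins = [r.protein for r, _ in kept]
        assert len(proteins) == len(set(proteins))


def _locus(alt_protein="MAAAA", alt_len=None):
    canon = _model("c1", [(0, 30)], protein="MCCCC")
    alt = _model("a1", [(0, 30)], protein=alt_protein)
    return LocusGroup("L1", canon, [alt])


class TestRunTriage:
    def test_single_superior_alternate_branch_a(self):
        locus = _locus()
        scores = {"MCCCC": 80.0, "MAAAA": 90.0}
        expr = {
            "c1": ExpressionSummary("c1", 50, 1.0),
            "a1": ExpressionSummary("a1", 40, 2.0),
        }
        report = run_triage([locus], scores, expr)
        assert len(report.rows) == 1
        row = report.rows[0]
        assert row.transcript_id == "a1" and row.branch == "A"
        assert report.summary == {
            "n_accepted": 1,
            "n_loci": 1,
            "per_branch": {"A": 1, "B": 0, "C": 0},
        }

    def test_canonical_only_locus_empty_report(self):
        locus = LocusGroup("L1", _model("c1", [(0, 30)], protein="MCCCC"), [])
        report = run_triage([locus], {"MCCCC": 80.0}, {})
        assert report.rows == []

    def test_locus_without_canonical_score_skipped(self):
        locus = _locus()
        with pytest.warns(UserWarning, match="locus skipped"):
            report = run_triage([locus], {"MAAAA": 90.0}, {})
        assert report.rows == []

    def test_missing_expression_treated_as_zero(self):
        locus = _locus()
        scores = {"MCCCC": 80.0, "MAAAA": 90.0}
        with pytest.warns(UserWarning, match="no expression"):
            report = run_triage([locus], scores, {})
        # still accepted via branch A (no sample condition there)
        assert [r.branch for r in report.rows] == ["A"]

    def test_accepted_subset_of_eligible_and_gate_holds(self, benchmark_inputs):
        inputs, _ = benchmark_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_triage(
                inputs.loci, inputs.protein_scores, inputs.expression
            )
        eligible = {d.transcript_id for d in report.decisions if d.eligible}
        accepted = {r.transcript_id for r in report.rows}
        assert accepted <= eligible
        assert all(r.alt_plddt >= 70.0 for r in report.rows)


class TestSummaries:
    def test_higher_scoring_alternate_counted(self):
        locus = _locus()
        scores = {"MCCCC": 70.0, "MAAAA": 80.0}
        expr = {
            "c1": ExpressionSummary("c1", 50, 1.0),
            "a1": ExpressionSummary("a1", 40, 2.0),
        }
        summ = summarize_transcriptome([locus], scores, expr)
        assert summ.n_higher_than_canonical == 1
        assert summ.frac_loci_top_isoform_below_70 == 0.0
        assert summ.top_isoforms.iloc[0]["transcript_id"] == "c1"

    def test_all_confident_tops_give_zero_fraction(self):
        loci = []
        scores = {}
        expr = {}
        for i in range(4):
            c = _model(f"c{i}", [(0, 30)], protein=f"MC{i}")
            loci.append(LocusGroup(f"L{i}", c, []))
            scores[f"MC{i}"] = 85.0
            expr[f"c{i}"] = ExpressionSummary(f"c{i}", 10, 1.0)
        summ = summarize_transcriptome(loci, scores, expr)
        assert summ.frac_loci_top_isoform_below_70 == 0.0


class TestReportWriter:
    def test_tsv_and_json_round_trip(self, tmp_path):
        locus = _locus()
        scores = {"MCCCC": 80.0, "MAAAA": 90.0}
        expr = {
            "c1": ExpressionSummary("c1", 50, 1.0),
            "a1": ExpressionSummary("a1", 40, 2.0),
        }
        report = run_triage([locus], scores, expr)
        tsv, js = write_report(report, tmp_path / "out")
        df = pd.read_csv(tsv, sep="\t")
        assert df.shape[0] == 1
        assert df.iloc[0]["transcript_id"] == "a1"
        assert df.iloc[0]["alt_plddt"] == pytest.approx(90.0)
        assert "introns in mouse" not in df.columns  # no MAF supplied
        assert js.exists()

    def test_conservation_column_spelled_true_false(self, benchmark_inputs, tmp_path):
        inputs, _ = benchmark_inputs
        report = run_triage(
            inputs.loci, inputs.protein_scores, inputs.expression, maf=inputs.maf
        )
        tsv, _ = write_report(report, tmp_path / "cons")
        df = pd.read_csv(tsv, sep="\t", dtype=str)
        assert set(df["introns in mouse"]) <= {"TRUE", "FALSE"}
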