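"""Cohort statistics and the residue-enrichment scan."""

import math

import numpy as np
import pytest

from amylatlas import associations as assoc
from amylatlas import simulate
from amylatlas.io import Alignment, SequenceRecord
from amylatlas.secretome import AmylaseRecord


def _amylase(pid, genome, clade):
    return AmylaseRecord(protein_id=pid, genome_id=genome, clade=clade, domain_names=set())


class TestSummarize:
    def test_counting_example(self):
        amylases = [
            _amylase("p1", "g1", "pullulanase"),
            _amylase("p2", "g1", "pullulanase"),
            _amylase("p3", "g2", "alpha14"),
            _amylase("p4", "g4", "cmd_like"),
        ]
        summaries = assoc.summarize_cohort(amylases, genome_ids=["g1", "g2", "g3", "g4"])
        totals = {s.genome_id: s.total_amylases for s in summaries}
        assert totals == {"g1": 2, "g2": 1, "g3": 0, "g4": 1}
        prev = assoc.clade_prevalence(summaries)
        assert prev["pullulanase"] == pytest.approx(25.0)
        assert prev["alpha14"] == pytest.approx(25.0)

    def test_empty_amylase_list(self):
        summaries = assoc.summarize_cohort([], genome_ids=["g1", "g2"])
        assert all(s.total_amylases == 0 for s in summaries)

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="gX"):
            assoc.summarize_cohort([_amylase("p", "gX", "alpha14")], genome_ids=["g1"])

    def test_totals_conserved(self, small_cohort):
        kept = [
            _amylase(pid, pid.rsplit("_p", 1)[0], clade)
            for pid, clade in small_cohort.amylase_clades.items()
        ]
        summaries = assoc.summarize_cohort(
            kept, genome_ids=[s.genome_id for s in small_cohort.summaries]
        )
        assert sum(s.total_amylases for s in summaries) == len(kept)
        truth = {s.genome_id: s.amylase_counts for s in small_cohort.summaries}
        for s in summaries:
            assert s.amylase_counts == truth[s.genome_id]


class TestCountAssociation:
    def test_complete_separation_r_is_one(self):
        summaries = [
            assoc.GenomeSummary(f"a{i}", total_amylases=6, has_acarbose_bgc=True) for i in range(4)
        ] + [
            assoc.GenomeSummary(f"b{i}", total_amylases=0, has_acarbose_bgc=False) for i in range(6)
        ]
        res = assoc.count_association(summaries, "has_acarbose_bgc")
        assert res.effect_size_r == pytest.approx(1.0)

    def test_empty_group_error_names_flag(self):
        summaries = [assoc.GenomeSummary("g1", total_amylases=1)]
        with pytest.raises(ValueError, match="has_acarbose_bgc"):
            assoc.count_association(summaries, "has_acarbose_bgc")

    def test_null_rejection_rate_calibrated(self):
        rejections, reps = 0, 200
        for s in range(reps):
            params = simulate.CohortParams(
                n_genomes=500, p_bgc=0.08, amylase_count_shift_delta=0, seed=40_000 + s
            )
            res = assoc.count_association(simulate.generate_summaries(params), "has_acarbose_bgc")
            rejections += res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestBinaryAssociation:
    def test_identical_flags_phi_one(self):
        summaries = [
            assoc.GenomeSummary(
                f"g{i}",
                amylase_counts={"cmd_like": i % 2},
                total_amylases=i % 2,
                has_tendamistat=bool(i % 2),
            )
            for i in range(10)
        ]
        res = assoc.binary_association(summaries, "cmd_like", "has_tendamistat")
        assert res.phi == pytest.approx(1.0)

    def test_planted_phi_recovery(self):
        params = simulate.CohortParams(n_genomes=2000, cmd_tendamistat_phi=0.3, seed=7)
        res = assoc.binary_association(
            simulate.generate_summaries(params), "cmd_like", "has_tendamistat"
        )
        assert res.phi == pytest.approx(0.3, abs=0.07)

    def test_independent_flags_phi_near_zero(self):
        params = simulate.CohortParams(n_genomes=2000, cmd_tendamistat_phi=0.0, seed=13)
        res = assoc.binary_association(
            simulate.generate_summaries(params), "cmd_like", "has_tendamistat"
        )
        assert abs(res.phi) < 0.1


def _aln(rows):
    return Alignment(records=[SequenceRecord(i, s) for i, s in rows.items()])


class TestReferenceMapping:
    def test_gap_aware_count(self):
        aln = _aln({"ref": "M-KT", "x": "MAKT"})
        assert assoc.map_column_to_reference(aln, "ref", 3) == 2

    def test_gapped_column_absent(self):
        aln = _aln({"ref": "M-KT", "x": "MAKT"})
        assert assoc.map_column_to_reference(aln, "ref", 2) is None

    def test_ungapped_identity(self):
        aln = _aln({"ref": "MKTA", "x": "MKTA"})
        for col in range(1, 5):
            assert assoc.map_column_to_reference(aln, "ref", col) == col


class TestEnrichmentScan:
    def test_uniform_column_null(self):
        rows = {f"a{i}": "H" * 4 for i in range(5)}
        rows.update({f"b{i}": "H" * 4 for i in range(5)})
        labels = {k: ("A" if k.startswith("a") else "B") for k in rows}
        results = assoc.column_enrichment_scan(_aln(rows), labels, reference_id="a0")
        assert all(r.p_raw == pytest.approx(1.0) for r in results)
        assert all(r.fold_enrichment == pytest.approx(1.0) for r in results)

    def test_hand_computed_pseudocount_fold(self):
        rows = {f"a{i}": "N" for i in range(4)}
        rows.update({f"b{i}": "H" for i in range(6)})
        labels = {k: ("A" if k.startswith("a") else "B") for k in rows}
        results = assoc.column_enrichment_scan(_aln(rows), labels, reference_id="b0", min_count=3)
        byres = {r.residue: r for r in results}
        n_hit = byres["N"]
        assert n_hit.p_raw == pytest.approx(1 / 210, abs=1e-12)
        assert n_hit.fold_enrichment == pytest.approx((4.5 / 5) / (0.5 / 7))
        assert n_hit.label == "H1N"

    def test_order_invariance(self):
        aln, labels = simulate.generate_msa(
            simulate.MsaParams(n_group_a=6, n_group_b=10, n_columns=30,
                               planted_columns=((7, "N", "H", 0.9, 0.1),), seed=4)
        )
        fwd = assoc.column_enrichment_scan(aln, labels, reference_id=aln.ids[0])
        shuffled = Alignment(records=list(reversed(aln.records)))
        rev = assoc.column_enrichment_scan(shuffled, labels, reference_id=aln.ids[0])
        key = lambda r: (r.column, r.residue)
        assert {key(r): r.p_raw for r in fwd} == {key(r): r.p_raw for r in rev}

    def test_group_swap_mirrors_table(self):
        aln, labels = simulate.generate_msa(
            simulate.MsaParams(n_group_a=6, n_group_b=6, n_columns=20,
                               planted_columns=((3, "N", "H", 0.9, 0.9),), seed=5)
        )
        swapped = {k: ("A" if v == "B" else "B") for k, v in labels.items()}
        fwd = {(r.column, r.residue): r for r in
               assoc.column_enrichment_scan(aln, labels, reference_id=aln.ids[0])}
        rev = {(r.column, r.residue): r for r in
               assoc.column_enrichment_scan(aln, swapped, reference_id=aln.ids[0])}
        for k, rf in fwd.items():
            rr = rev[k]
            assert rf.p_raw == pytest.approx(rr.p_raw, rel=1e-9)
            assert (rf.table.a, rf.table.b) == (rr.table.c, rr.table.d)
            if rf.table.a > 0 and rr.table.a > 0:  # no pseudocount on either side
                assert rf.fold_enrichment == pytest.approx(1 / rr.fold_enrichment, rel=1e-9)

    def test_planted_columns_recovered(self):
        planted = ((11, "N", "H", 0.8, 0.02), (29, "G", "A", 0.8, 0.02))
        aln, labels = simulate.generate_msa(
            simulate.MsaParams(n_group_a=15, n_group_b=120, n_columns=60,
                               planted_columns=planted, seed=6)
        )
        results = assoc.column_enrichment_scan(aln, labels, reference_id=aln.ids[-1])
        hits = {(r.column, r.residue) for r in results if r.p_bh < 0.05}
        assert {(11, "N"), (29, "G")} <= hits

    def test_null_scan_controls_discoveries(self):
        n_disc = 0
        for s in range(10):
            aln, labels = simulate.generate_msa(
                simulate.MsaParams(n_group_a=15, n_group_b=120, n_columns=80, seed=60_000 + s)
            )
            results = assoc.column_enrichment_scan(aln, labels, reference_id=aln.ids[-1])
            n_disc += sum(r.p_bh < 0.05 for r in results)
        assert n_disc <= 2  # ~1,600 true-null tests per scan, BH at 0.05

    def test_missing_reference_rejected(self):
        rows = {"a": "HH", "b": "HH"}
        labels = {"a": "A", "b": "B"}
        with pytest.raises(ValueError, match="nope"):
            assoc.column_enrichment_scan(_aln(rows), labels, reference_id="nope")


class TestSubstitutionCensus:
    def test_no_variants(self):
        rows = {"a": "H", "b": "H"}
        labels = {"a": "A", "b": "B"}
        res = assoc.substitution_census(_aln(rows), labels, 1, "H", ["N"])
        assert res.sequence_counts == {"A": 0, "B": 0}
        assert res.p_value == pytest.approx(1.0)

    def test_seven_sequences_six_genomes_structure(self):
        aln, labels, genome_of = simulate.make_substitution_fixture(seed=1)
        res = assoc.substitution_census(
            aln, labels, simulate.RESISTANCE_COLUMN, "H", ["N"], genome_of=genome_of
        )
        assert res.sequence_counts["A"] == 7
        assert res.genome_counts["A"] == 6
        assert res.genome_counts["B"] == 11
        assert res.p_value < 0.05
        assert res.fold_enrichment > 1

    def test_levels_differ_only_with_multicopy_genomes(self):
        aln, labels, genome_of = simulate.make_substitution_fixture(seed=2)
        seq = assoc.substitution_census(
            aln, labels, simulate.RESISTANCE_COLUMN, "H", ["N"], genome_of=genome_of,
            level="sequence",
        )
        gen = assoc.substitution_census(
            aln, labels, simulate.RESISTANCE_COLUMN, "H", ["N"], genome_of=genome_of,
            level="genome",
        )
        # group A holds the only genome with two variant copies
        assert seq.table.a - gen.table.a == 1
        assert seq.sequence_counts["B"] == gen.genome_counts["B"]

    def test_wildtype_as_variant_rejected(self):
        rows = {"a": "H", "b": "H"}
        labels = {"a": "A", "b": "B"}
        with pytest.raises(ValueError):
            assoc.substitution_census(_aln(rows), labels, 1, "H", ["H", "N"])
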