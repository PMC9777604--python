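"""The candidate filter cascade, naming, and family-table statistics."""

import copy

import pytest

from nsltp import (
    ProteinSequenceRecord, assign_names, is_hyprp, run_identification,
    scan_ecm, summarize, verify_fixture_consistency,
)
from nsltp.identify_pipeline import PipelineConfig
from nsltp.synthetic_data import (
    DECOY_KINDS, gen_decoy, gen_gene_models, gen_ltp_protein, gen_proteome,
)


def models_for(records):
    models, _ = gen_gene_models([r.id for r in records], [], seed=99)
    return models


class TestCascade:
    def test_empty_proteome(self):
        assert run_identification([], {}, []) == ([], [])

    def test_planted_ltps_accepted_decoys_rejected_at_their_stage(self):
        stage_for = {"no_ecm": "ecm_scan", "no_sp": "signal_peptide",
                     "hyprp": "hyprp_filter", "oversize": "mature_length"}
        records, sp_table, truths = [], {}, {}
        for i, t in enumerate(["I", "II", "IV", "V", "VIII"]):
            rec, truth = gen_ltp_protein(t, seed=100 + i)
            records.append(rec)
            sp_table[rec.id] = truth.sp_len
            truths[rec.id] = f"ltp:{t}"
        for i, kind in enumerate(DECOY_KINDS):
            rec, truth = gen_decoy(kind, seed=200 + i)
            records.append(rec)
            if truth.sp_len is not None:
                sp_table[rec.id] = truth.sp_len
            truths[rec.id] = kind
        rows, traces = run_identification(records, sp_table, models_for(records))
        assert len(rows) == 5
        assert {r.gene_id for r in rows} == {
            rid for rid, k in truths.items() if k.startswith("ltp:")}
        for t in traces:
            if t.final == "rejected":
                assert t.rejected_stage == stage_for[truths[t.protein_id]]

    def test_mature_length_boundary_is_strict_120(self):
        # same planted motif; mature padded to exactly 120 vs 121 residues
        rec, truth = gen_ltp_protein("II", seed=7)
        mature = rec.residues[truth.sp_len:]
        for total, expect_accept in [(120, True), (121, False)]:
            padded = mature + "A" * (total - len(mature))
            r = ProteinSequenceRecord(rec.id, rec.residues[:truth.sp_len] + padded)
            rows, traces = run_identification(
                [r], {r.id: truth.sp_len}, models_for([r]))
            if expect_accept:
                assert len(rows) == 1
            else:
                assert rows == [] and traces[0].rejected_stage == "mature_length"

    def test_redundant_sequences_collapse_to_smallest_id(self):
        rec, truth = gen_ltp_protein("I", seed=3, ident="zzz")
        twin = ProteinSequenceRecord("aaa", rec.residues)
        sp = {"aaa": truth.sp_len, "zzz": truth.sp_len}
        rows, traces = run_identification([rec, twin], sp, models_for([rec, twin]))
        assert [r.gene_id for r in rows] == ["aaa"]
        by_id = {t.protein_id: t for t in traces}
        assert by_id["zzz"].final == "collapsed"

    def test_order_stability(self):
        records, sp, _ = gen_proteome(8, 6, seed=21)
        models = models_for(records)
        rows_fwd, _ = run_identification(records, sp, models)
        rows_rev, _ = run_identification(records[::-1], sp, models)
        assert [r.gene_name for r in rows_fwd] == [r.gene_name for r in rows_rev]
        assert [r.gene_id for r in rows_fwd] == [r.gene_id for r in rows_rev]

    def test_missing_gene_model_is_error(self):
        rec, truth = gen_ltp_protein("I", seed=3)
        with pytest.raises(ValueError, match="missing gene models"):
            run_identification([rec], {rec.id: truth.sp_len}, [])

    def test_homology_intake_filters_without_hits(self):
        records, sp, truths = gen_proteome(4, 0, seed=5)
        hits = {records[0].id: 1e-30, records[1].id: 1e-3}  # second too weak
        rows, traces = run_identification(
            records, sp, models_for(records), hits=hits)
        assert [r.gene_id for r in rows] == [records[0].id]
        rejected = {t.protein_id: t.rejected_stage for t in traces
                    if t.final == "rejected"}
        assert set(rejected.values()) == {"homology_intake"}

    def test_every_input_gets_exactly_one_trace(self):
        records, sp, _ = gen_proteome(10, 8, seed=13)
        _, traces = run_identification(records, sp, models_for(records))
        assert sorted(t.protein_id for t in traces) == sorted(r.id for r in records)


class TestHyprp:
    def _match(self, mature):
        (m,) = scan_ecm(mature)
        return m

    def planted(self, region):
        core = ("C" + "A" * 9 + "C" + "A" * 14 + "CC" + "A" * 19
                + "CAC" + "A" * 22 + "C" + "A" * 7 + "C")
        return region + core

    def test_proline_rich_region_flagged(self):
        seq = self.planted("PPVPPVPPVG")
        assert is_hyprp(seq, self._match(seq)) is True

    def test_zero_proline_region_not_flagged(self):
        seq = self.planted("GAVGAVGAVG")
        assert is_hyprp(seq, self._match(seq)) is False

    def test_short_region_never_flagged(self):
        seq = self.planted("PPP")
        assert is_hyprp(seq, self._match(seq)) is False


class TestNaming:
    def test_chromosome_major_order(self, fixture_rows):
        a = copy.deepcopy(next(r for r in fixture_rows if r.ltp_type == "I"))
        b = copy.deepcopy(a)
        a.chromosome, a.start = "Chr02", 50
        b.chromosome, b.start = "Chr01", 100
        named = assign_names([a, b], prefix="X")
        assert [r.gene_name for r in named] == ["XI.1", "XI.2"]
        assert named[0].chromosome == "Chr01"

    def test_reassignment_reproduces_published_names(self, fixture_rows):
        rows = copy.deepcopy(fixture_rows)
        original = [r.gene_name for r in rows]
        for r in rows:
            r.gene_name = ""
        renamed = assign_names(rows, prefix="PvLTP")
        assert [r.gene_name for r in renamed] == original

    def test_single_gene_gets_index_one(self, fixture_rows):
        row = copy.deepcopy(fixture_rows[0])
        assert assign_names([row])[0].gene_name.endswith(".1")


class TestSummaries:
    def test_single_row_min_equals_mean_equals_max(self, fixture_rows):
        s = summarize(fixture_rows[:1])
        assert s.mw_da[0] == s.mw_da[1] == s.mw_da[2]
        assert s.n_total == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_fixture_means(self, fixture_rows):
        s = summarize(fixture_rows)
        assert s.mw_kda[1] == 9.82
        assert s.pi[1] == 7.52
        assert s.type_counts["I"] == 45

    def test_counts_sum_to_total(self, fixture_rows):
        s = summarize(fixture_rows)
        for counts in (s.type_counts, s.chromosome_counts, s.intron_counts):
            assert sum(counts.values()) == s.n_total


class TestConsistencyChecker:
    def test_fixture_has_exactly_one_cds_violation(self, fixture_rows):
        violations = verify_fixture_consistency(fixture_rows)
        assert len(violations) == 1
        v = violations[0]
        assert v.gene_name == "PvLTPI.33"
        assert (v.observed, v.expected) == (385, 375)

    def test_fixture_has_no_sp_mp_violations(self, fixture_rows):
        assert not [v for v in verify_fixture_consistency(fixture_rows)
                    if "sp_len" in v.rule]

    def test_consistent_row_passes(self, fixture_rows):
        r = next(r for r in fixture_rows if r.gene_name == "PvLTPI.1")
        assert (r.sp_len, r.mp_len, r.aa_total) == (21, 91, 112)
        assert verify_fixture_consistency([r]) == []
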