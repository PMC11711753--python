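"""CSV/curves ingestion and the low/high-dose deduplication rules."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from ptmnav.data_io import (
    DoseEntry,
    DoseExperiment,
    MissingColumnError,
    dedup_dose_pairs,
    read_curvecurator,
    read_ptm_csv,
    read_toml_params,
    write_ptm_csv,
)

CSV = """Peptide,Experiment,Regulation,Uniprot Accession,Gene Name,Site,Fold Change,Adjusted p-Value,pEC50
AAASPR,Lapatinib,Up,Q07889,SOS1,S1134,-2.5,0.001,
BBBTPK,Lapatinib,down,P42345,MTOR,S2448&T2474,-1.0,0.01,6.8
CCCSPR,Lapatinib,not,P31749,AKT1,,,0.8,
"""


class TestReadCsv:
    def test_regulation_normalized_case_insensitively(self):
        records, errors = read_ptm_csv(io.StringIO(CSV))
        assert errors == []
        assert [r.regulation for r in records] == ["up", "down", "not"]

    def test_site_split_into_residue_and_position(self):
        records, _ = read_ptm_csv(io.StringIO(CSV))
        assert records[0].residue == "S" and records[0].position == 1134
        assert records[1].sites == (("S", 2448), ("T", 2474))

    def test_unknown_regulation_rejected_with_line_number(self):
        bad = CSV.replace("Up", "increased")
        records, errors = read_ptm_csv(io.StringIO(bad))
        assert len(records) == 2
        assert errors[0].line == 2 and "increased" in errors[0].message

    def test_missing_required_column_is_hard_error(self):
        with pytest.raises(MissingColumnError, match="Regulation"):
            read_ptm_csv(io.StringIO("Peptide,Gene Name\nAAA,SOS1\n"))

    def test_tab_delimiter_sniffed(self):
        records, errors = read_ptm_csv(io.StringIO(CSV.replace(",", "\t")))
        assert errors == [] and len(records) == 3

    def test_write_read_round_trip(self, tmp_path):
        records, _ = read_ptm_csv(io.StringIO(CSV))
        out = tmp_path / "out.csv"
        write_ptm_csv(records, out)
        again, errors = read_ptm_csv(out)
        assert errors == []
        assert again == records


class TestCurveCurator:
    TOML = b"""
[experiment]
name = "Lapatinib"
doses_nM = [1, 3, 10, 30, 100, 300, 1000, 3000, 10000]
"""
    CURVES = (
        "Modified sequence\tGenes\tProteins\tSite\tCurve Regulation\tpEC50\tCurve Fold Change\n"
        "AAASPR\tSOS1\tQ07889\tS1134\tdown\t7.41\t-3.2\n"
        "BBBTPK\tMTOR\tP42345\tS2448\tnot\t\t\n"
        "CCCSPR\tGSK3B\tP49841\tS9\tdown\t4.2\t-1.0\n"
    )

    def test_dose_range_maps_to_pec50_window(self):
        exp = read_toml_params(io.BytesIO(self.TOML))
        assert exp.drug == "Lapatinib"
        assert exp.pec50_window == pytest.approx((9.0, 5.0))

    def test_regulated_curve_carries_pec50_and_fold_change(self):
        records = read_curvecurator(io.StringIO(self.CURVES), io.BytesIO(self.TOML))
        assert records[0].regulation == "down"
        assert records[0].pec50 == 7.41
        assert records[0].fold_change == -3.2
        assert records[0].experiment == "Lapatinib"

    def test_unregulated_curve_has_no_potency(self):
        records = read_curvecurator(io.StringIO(self.CURVES), io.BytesIO(self.TOML))
        assert records[1].regulation == "not" and records[1].pec50 is None

    def test_pec50_outside_dose_window_flagged(self):
        records = read_curvecurator(io.StringIO(self.CURVES), io.BytesIO(self.TOML))
        flagged = dict(records[2].details)
        assert "pec50_out_of_range" in flagged
        assert "pec50_out_of_range" not in dict(records[0].details)

    def test_drug_name_mismatch_is_hard_error(self):
        curves = self.CURVES.replace("Curve Fold Change\n", "Curve Fold Change\tExperiment\n").replace(
            "\t-3.2\n", "\t-3.2\tOsimertinib\n"
        )
        with pytest.raises(ValueError, match="mismatch"):
            read_curvecurator(
                io.StringIO(curves),
                DoseExperiment("Lapatinib", (1e-9, 1e-5)),
            )


class TestDedup:
    def test_within_experiment_most_significant_kept(self):
        entries = [
            DoseEntry("pepA", "high", True, 0.2, -1.0),
            DoseEntry("pepA", "high", True, 0.04, -2.0),
        ]
        result = dedup_dose_pairs(entries)
        assert result["pepA"].entry.p_adj == 0.04

    @pytest.mark.parametrize(
        "low_sig,high_sig,expect_dose,expect_rule",
        [
            (False, False, "high", "II"),
            (False, True, "high", "III"),
            (True, True, "high", "III"),
            (True, False, "low", "IV"),
        ],
    )
    def test_rule_truth_table(self, low_sig, high_sig, expect_dose, expect_rule):
        entries = [
            DoseEntry("pep", "low", low_sig, 0.03 if low_sig else 0.5),
            DoseEntry("pep", "high", high_sig, 0.02 if high_sig else 0.6),
        ]
        result = dedup_dose_pairs(entries)["pep"]
        assert result.entry.dose == expect_dose
        assert result.rule == expect_rule

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["p1", "p2", "p3"]),
                st.sampled_from(["low", "high"]),
                st.floats(min_value=0, max_value=1, exclude_min=True),
            ),
            min_size=1,
            max_size=25,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_one_entry_per_peptide_and_rules_exhaustive(self, rows):
        # significance derives from the adjusted p-value (10% FDR), as in a
        # real differential analysis, so rule I cannot contradict rules II-IV
        entries = [DoseEntry(p, d, padj < 0.1, padj) for p, d, padj in rows]
        result = dedup_dose_pairs(entries)
        assert set(result) == {e.peptide_key for e in entries}
        for peptide, chosen in result.items():
            mine = [e for e in entries if e.peptide_key == peptide]
            high_sig = any(e.significant for e in mine if e.dose == "high")
            low_sig = any(e.significant for e in mine if e.dose == "low")
            has_high = any(e.dose == "high" for e in mine)
            if high_sig:
                assert chosen.rule == "III" and chosen.entry.dose == "high"
            elif low_sig:
                assert chosen.rule == "IV" and chosen.entry.dose == "low"
            else:
                assert chosen.rule == "II"
                assert chosen.entry.dose == ("high" if has_high else "low")
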