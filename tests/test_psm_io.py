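"""PSM table and FASTA input/output."""

import numpy as np
import pytest

from phosphoquant import (
    Modification,
    ProteinRecord,
    PsmRecord,
    QuantifiedSite,
    read_fasta,
    read_psm_table,
    write_fasta,
    write_psm_table,
    write_results_table,
)
from phosphoquant.psm_io import (
    FastaError,
    PsmTableError,
    annotate_peptide,
    parse_decimal,
    parse_modifications,
    parse_site_probabilities,
)
from phosphoquant.synthetic_data import SimConfig, generate_proteome, generate_psm_table


def _write_minimal_table(path, rows, header=None):
    header = header or (
        "PSM ID\tSequence\tModifications\tProtein Group Accessions\t"
        "Protein Descriptions\tDecoy\tRank\tIonScore\tDeltaM [ppm]\t"
        "RT [min]\tLight\tMedium\tHeavy\tMedium/Light\tHeavy/Light\t"
        "phosphoRS Site Probabilities"
    )
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


def test_three_row_table_round_trips_fields(tmp_path):
    rows = [
        "a1\tPEPTIDEK\tN-Term(Dimethyl); K8(Dimethyl)\tP1\tprot one\tFalse"
        "\t1\t42.5\t-1.2\t33.1\t100\t138\t235\t\t\t",
        "a2\tSAMPYLER\tY5(Phospho)\tP2\tprot two\tFalse\t1\t55\t0.4\t40\t"
        "200\t280\t\t\t\tY(5): 98.2; S(1): 1.8",
        "a3\tKNFLEGAL\t\tDECOY_P1\tdecoy\tTrue\t1\t12\t3\t50\t90\t100\t210\t\t\t",
    ]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    records = read_psm_table(path)
    assert [r.psm_id for r in records] == ["a1", "a2", "a3"]
    assert records[0].channel_quantity == {
        "light": 100.0, "medium": 138.0, "heavy": 235.0
    }
    assert records[1].site_probabilities == {5: 98.2, 1: 1.8}
    assert records[1].channel_quantity["heavy"] is None
    assert records[2].is_decoy


def test_decimal_comma_dialect_parses_published_style_values(tmp_path):
    # "−1,91" with a typographic minus and a comma decimal, as printed tables use
    assert parse_decimal("−1,91", decimal_comma=True) == pytest.approx(-1.91)
    rows = [
        "a1\tQEDDGIYSSSGLK\t\tF1QBS0\tFer\tFalse\t1\t40\t0,5\t30\t\t\t\t"
        "0,266\t0,361\t"
    ]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    rec = read_psm_table(path, decimal_comma=True)[0]
    assert rec.ratio_medium_light == pytest.approx(0.266)
    assert rec.mass_error_ppm == pytest.approx(0.5)


def test_all_channels_missing_flags_unquantifiable(tmp_path):
    rows = ["a1\tPEPTIDEK\t\tP1\t\tFalse\t1\t40\t0\t30\t\t\t\t\t\t"]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    rec = read_psm_table(path)[0]
    assert rec.n_present_channels == 0
    assert not rec.is_quantifiable


def test_nonpositive_quantity_normalized_to_missing(tmp_path):
    rows = ["a1\tPEPTIDEK\t\tP1\t\tFalse\t1\t40\t0\t30\t100\t-5\t0\t\t\t"]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    rec = read_psm_table(path)[0]
    assert rec.channel_quantity["medium"] is None
    assert rec.channel_quantity["heavy"] is None


def test_missing_mandatory_column_is_fatal_and_named(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("PSM ID\tSequence\nx\tPEPK\n")
    with pytest.raises(PsmTableError, match="Modifications"):
        read_psm_table(path)


def test_duplicate_psm_id_is_fatal(tmp_path):
    rows = [
        "a1\tPEPTIDEK\t\tP1\t\tFalse\t1\t40\t0\t30\t100\t138\t235\t\t\t",
        "a1\tPEPTIDER\t\tP1\t\tFalse\t1\t40\t0\t30\t100\t138\t235\t\t\t",
    ]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    with pytest.raises(PsmTableError, match="duplicate psm_id"):
        read_psm_table(path)


def test_unparseable_row_reports_row_index(tmp_path):
    rows = ["a1\tPEPTIDEK\t\tP1\t\tFalse\tone\t40\t0\t30\t100\t138\t235\t\t\t"]
    path = tmp_path / "t.tsv"
    _write_minimal_table(path, rows)
    with pytest.raises(PsmTableError, match="row 1"):
        read_psm_table(path)


def test_modification_parsing_covers_all_kinds():
    mods = parse_modifications(
        "N-Term(Dimethyl); K8(Dimethyl:2H(4)); Y7(Phospho); "
        "M2(Oxidation); C3(Carbamidomethyl); K9(Dimethyl:2H(6)13C(2))"
    )
    kinds = [m.kind for m in mods]
    assert kinds == [
        "dimethyl_light", "dimethyl_medium", "phospho",
        "oxidation", "carbamidomethyl", "dimethyl_heavy",
    ]
    assert mods[0].position == "N-term"
    assert mods[1].position == 8


def test_modification_position_outside_peptide_rejected():
    with pytest.raises(ValueError, match="outside peptide"):
        PsmRecord(
            psm_id="x", sequence="PEPK",
            modifications=[Modification(position=9, kind="phospho")],
            protein_accession="P1",
        )


def test_site_probability_on_non_sty_residue_rejected():
    with pytest.raises(ValueError, match="S/T/Y"):
        PsmRecord(
            psm_id="x", sequence="PEPK", modifications=[],
            protein_accession="P1", site_probabilities={1: 50.0},
        )


def test_psm_round_trip_is_lossless_for_mandatory_fields(tmp_path):
    cfg = SimConfig(seed=3, n_proteins=10, n_nonphospho_psms=40,
                    n_phospho_sites=8, psms_per_site=2)
    rng = np.random.default_rng(3)
    proteome = generate_proteome(cfg, rng)
    records, _ = generate_psm_table(cfg, proteome, rng)
    path = tmp_path / "rt.tsv"
    write_psm_table(records, path)
    back = read_psm_table(path)
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert a.psm_id == b.psm_id
        assert a.sequence == b.sequence
        assert a.protein_accession == b.protein_accession
        assert a.is_decoy == b.is_decoy
        assert a.rank == b.rank
        assert sorted(
            (str(m.position), m.kind) for m in a.modifications
        ) == sorted((str(m.position), m.kind) for m in b.modifications)
        assert a.ion_score == pytest.approx(b.ion_score, rel=1e-9)
        assert a.mass_error_ppm == pytest.approx(b.mass_error_ppm, rel=1e-9)
        assert a.site_probabilities == b.site_probabilities


def test_fasta_round_trip_and_case_normalization(tmp_path):
    path = tmp_path / "p.fasta"
    path.write_text(">P1 kinase one\nacdefghik\n>P2\nMKTAYIAK\n")
    records = read_fasta(path)
    assert len(records) == 2
    assert records[0].sequence == "ACDEFGHIK"
    assert records[0].description == "kinase one"
    out = tmp_path / "out.fasta"
    write_fasta(records, out)
    assert [r.sequence for r in read_fasta(out)] == [
        r.sequence for r in records
    ]


def test_fasta_duplicate_accession_fatal(tmp_path):
    path = tmp_path / "p.fasta"
    path.write_text(">P1\nMKT\n>P1\nMKA\n")
    with pytest.raises(FastaError, match="P1"):
        read_fasta(path)


def test_fasta_empty_file_fatal(tmp_path):
    path = tmp_path / "p.fasta"
    path.write_text("")
    with pytest.raises(FastaError):
        read_fasta(path)


def test_annotate_peptide_marks_localized_residues_only():
    assert annotate_peptide("MEGVVYADLR", [6]) == "MEGVV(pY)ADLR"
    # ambiguous: no positions marked, plain sequence
    assert annotate_peptide("QEDDGIYSSSGLK", []) == "QEDDGIYSSSGLK"
    assert annotate_peptide("SSNAGGDEEYIYMNK", [10, 12]) == (
        "SSNAGGDEE(pY)I(pY)MNK"
    )


def _site(acc, pep, ns, ls):
    return QuantifiedSite(
        protein_name=acc, accession_field=acc, peptide_sequence=pep,
        log2_ns_wt=ns, log2_ls_wt=ls,
    )


def test_results_table_empty_list_gives_header_only(tmp_path):
    path = tmp_path / "r.tsv"
    write_results_table([], path)
    lines = path.read_text().splitlines()
    assert len(lines) == 1
    assert lines[0].startswith("protein\taccession")


def test_results_table_ties_ordered_by_accession_then_sequence(tmp_path):
    path = tmp_path / "r.tsv"
    sites = [
        _site("B1", "PEPA", 1.0, 0.0),
        _site("A1", "PEPB", 1.0, 0.0),
        _site("A1", "PEPA", 1.0, 0.0),
    ]
    write_results_table(sites, path)
    rows = [l.split("\t") for l in path.read_text().splitlines()[1:]]
    assert [(r[1], r[2]) for r in rows] == [
        ("A1", "PEPA"), ("A1", "PEPB"), ("B1", "PEPA")
    ]


def test_protein_record_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        ProteinRecord("P1", "source", "MKT1")
    with pytest.raises(ValueError):
        ProteinRecord("P1", "source", "")


def test_parse_site_probabilities_handles_empty():
    assert parse_site_probabilities("") == {}
    assert parse_site_probabilities("Y(7): 98.2; S(8): 1.8") == {7: 98.2, 8: 1.8}
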