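"""Format readers/writers: header dialects, round trips, filtering contracts."""
from __future__ import annotations

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neofunnel import seqio
from neofunnel.types import AA_ALPHABET, MissenseVariant, ProteinRecord

# ---------------------------------------------------------------------------
# FASTA


def test_read_fasta_header_dialects(tmp_path):
    p = tmp_path / "db.fasta"
    p.write_text(
        ">sp|P01111|RASN_HUMAN GTPase NRas GN=NRAS\nMTEYK\n"
        ">toy1\nACDEF\n"
        ">toy2 some description\nacdef\n"
    )
    recs = seqio.read_fasta(p)
    assert recs[0].accession == "P01111"
    assert recs[0].gene_symbol == "NRAS"
    assert recs[0].sequence == "MTEYK"
    assert recs[1].accession == "toy1" and recs[1].gene_symbol == ""
    assert recs[2].sequence == "ACDEF"  # lowercase body normalized


def test_read_fasta_empty_file_errors(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(ValueError):
        seqio.read_fasta(p)


def test_variant_header_convention(tmp_path):
    v = MissenseVariant("P01111_E61K", "NRAS", "P01111", 61, "E", "K")
    rec = ProteinRecord(
        "P01111_E61K", "M" * 60 + "K" + "A" * 10, gene_symbol="NRAS",
        source="variant", variants=(v,),
    )
    path = seqio.write_fasta([rec], tmp_path / "var.fasta")
    text = path.read_text()
    assert text.startswith(">var|P01111_E61K|GN=NRAS\n")
    back = seqio.read_fasta(path)[0]
    assert back.source == "variant"
    assert back.variants[0].substitution == "E61K"
    assert back.variants[0].protein_accession == "P01111"
    assert back.gene_symbol == "NRAS"


def test_write_fasta_line_wrapping(tmp_path):
    rec = ProteinRecord("long", "A" * 61)
    path = seqio.write_fasta([rec], tmp_path / "w.fasta", line_width=60)
    body = [l for l in path.read_text().splitlines() if not l.startswith(">")]
    assert body == ["A" * 60, "A"]


accessions = st.text(string.ascii_uppercase + string.digits, min_size=3, max_size=8)
sequences = st.text(AA_ALPHABET, min_size=1, max_size=80)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.tuples(accessions, sequences), min_size=1, max_size=6, unique_by=lambda t: t[0]))
def test_fasta_round_trip_identity(tmp_path_factory, entries):
    """write -> read is the identity on (accession, gene, sequence, source)."""
    tmp = tmp_path_factory.mktemp("fasta")
    records = [
        ProteinRecord(acc, seq, gene_symbol=f"G{i}") for i, (acc, seq) in enumerate(entries)
    ]
    path = seqio.write_fasta(records, tmp / "rt.fasta")
    back = seqio.read_fasta(path)
    assert [(r.accession, r.gene_symbol, r.sequence, r.source) for r in back] == [
        (r.accession, r.gene_symbol, r.sequence, r.source) for r in records
    ]


def test_contaminant_and_decoy_round_trip(tmp_path):
    recs = [
        ProteinRecord("CON__TRYP", "ACDEF", source="contaminant"),
        ProteinRecord("REV__P1", "FEDCA", source="decoy"),
    ]
    back = seqio.read_fasta(seqio.write_fasta(recs, tmp_path / "x.fasta"))
    assert [r.source for r in back] == ["contaminant", "decoy"]


# ---------------------------------------------------------------------------
# Variant tables


def test_read_variant_table_simple(tmp_path, caplog):
    p = tmp_path / "v.tsv"
    p.write_text(
        "variant_id\tgene\tprotein_accession\tposition\tref_aa\talt_aa\tqual\n"
        "v1\tNRAS\tP01111\t61\tQ\tK\t99\n"
        "v2\tTP53\tP04637\t5\tL\tL\t50\n"
    )
    with caplog.at_level("WARNING"):
        variants = seqio.read_variant_table(p)
    assert len(variants) == 1
    assert variants[0].substitution == "Q61K"
    assert variants[0].qual == 99.0
    assert "synonymous" in caplog.text


def test_read_variant_table_missing_column(tmp_path):
    p = tmp_path / "v.tsv"
    p.write_text("variant_id\tgene\tposition\n")
    with pytest.raises(ValueError, match="protein_accession"):
        seqio.read_variant_table(p)


def test_read_variant_table_annovar(tmp_path):
    p = tmp_path / "a.tsv"
    p.write_text(
        "Gene.refGene\tExonicFunc.refGene\tAAChange.refGene\tQUAL\n"
        "KRAS\tnonsynonymous SNV\tKRAS:NM_004985:exon2:c.G35A:p.G12D\t88\n"
        "GENE2\tsynonymous SNV\tGENE2:NM_1:exon1:c.T15C:p.L5L\t70\n"
        "GENE3\tnonsynonymous SNV\tGENE3:NM_2:exon1:c.A10G:p.K4E,GENE3:NM_3:exon1:c.A10G:p.K4E\t70\n"
    )
    variants = seqio.read_variant_table(p, dialect="annovar")
    assert [v.substitution for v in variants] == ["G12D", "K4E", "K4E"]
    assert variants[0].position == 12 and variants[0].ref_aa == "G"
    assert variants[0].protein_accession == "NM_004985"
    assert {v.protein_accession for v in variants[1:]} == {"NM_2", "NM_3"}


# ---------------------------------------------------------------------------
# VCF

VCF_HEADER = "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def test_read_vcf_snvs_qual_and_shape(tmp_path):
    p = tmp_path / "s.vcf"
    p.write_text(
        VCF_HEADER
        + "chr1\t100\t.\tA\tG\t57\t.\t.\n"       # kept
        + "chr1\t200\t.\tC\tT\t20\t.\t.\n"        # boundary: excluded (strict >)
        + "chr1\t300\t.\tAT\tA\t90\t.\t.\n"       # indel: skipped
        + "chr1\t400\t.\tG\tA,C\t44\t.\t.\n"      # multi-allelic: split
        + "chr1\t500\t.\tT\tC\t.\t.\t.\n"         # missing QUAL: excluded
    )
    snvs = seqio.read_vcf_snvs(p, qual_min=20)
    assert [(c, pos, r, a) for c, pos, r, a, _ in snvs] == [
        ("chr1", 100, "A", "G"),
        ("chr1", 400, "G", "A"),
        ("chr1", 400, "G", "C"),
    ]
    assert all(q > 20 for *_, q in snvs)


# ---------------------------------------------------------------------------
# Expression


def test_read_expression(tmp_path, caplog):
    ab = tmp_path / "abundance.tsv"
    ab.write_text(
        "target_id\tlength\teff_length\test_counts\ttpm\n"
        "ENST1\t1500\t1330\t105\t7.2\n"
        "ENST2\t900\t750\t0\t0\n"
        "ENST3\t800\t650\t10\t1.5\n"
    )
    t2g = tmp_path / "t2g.tsv"
    t2g.write_text("ENST1\tNRAS\nENST2\tTP53\n")
    with caplog.at_level("WARNING"):
        recs = seqio.read_expression(ab, t2g)
    assert recs[0].tpm == 7.2 and recs[0].gene_symbol == "NRAS"
    assert recs[1].tpm == 0.0  # zero kept; filtering is downstream
    assert recs[2].gene_symbol == "" and "ENST3" in caplog.text


def test_read_expression_missing_tpm(tmp_path):
    ab = tmp_path / "abundance.tsv"
    ab.write_text("target_id\tcounts\nENST1\t5\n")
    t2g = tmp_path / "t2g.tsv"
    t2g.write_text("ENST1\tNRAS\n")
    with pytest.raises(ValueError, match="tpm"):
        seqio.read_expression(ab, t2g)


# ---------------------------------------------------------------------------
# MS peptides


def test_read_ms_peptides(tmp_path, caplog):
    p = tmp_path / "peptides.txt"
    p.write_text(
        "Sequence\tProteins\tReverse\tPotential contaminant\n"
        "AAKLDPTAVSR\tvar|P1_D5A|GN=G1\t\t\n"
        "MTEYKLVVV\tP0001;P0002\t\t\n"
        "WWWWWWWWW\tREV__P0001\t+\t\n"
        "HHHHHHHH\tCON__TRYP\t\t+\n"
        "SHORT\tP0001\t\t\n"
    )
    with caplog.at_level("WARNING"):
        peps = seqio.read_ms_peptides(p)
    assert [p.sequence for p in peps] == ["AAKLDPTAVSR", "MTEYKLVVV"]
    assert peps[0].is_variant and not peps[1].is_variant
    assert all(len(p.sequence) >= 7 for p in peps)
    assert "shorter than 7" in caplog.text


# ---------------------------------------------------------------------------
# Epitopes


def test_read_epitopes_csv(tmp_path, caplog):
    p = tmp_path / "epi.csv"
    p.write_text(
        "Epitope ID,Description,Organism\n"
        "12345,SIINFEKL,Vaccinia virus\n"
        "99999,GILGFVFTL (modified),Influenza A\n"
    )
    with caplog.at_level("WARNING"):
        epis = seqio.read_epitopes(p)
    assert len(epis) == 1
    assert epis[0].sequence == "SIINFEKL" and epis[0].organism == "Vaccinia virus"


def test_read_epitopes_fasta(tmp_path):
    p = tmp_path / "epi.fasta"
    p.write_text(">e1 Vaccinia\nSIINFEKL\n>e2\nGILGFVFTL\n")
    epis = seqio.read_epitopes(p)
    assert len(epis) == 2 and epis[1].sequence == "GILGFVFTL"


def test_read_epitopes_no_sequence_column(tmp_path):
    p = tmp_path / "epi.csv"
    p.write_text("id,organism\n1,x\n")
    with pytest.raises(ValueError, match="sequence column"):
        seqio.read_epitopes(p)


# ---------------------------------------------------------------------------
# Binding tables


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("HLA-A*03:01", "HLA-A*03:01"),
        ("HLA-A03:01", "HLA-A*03:01"),
        ("HLA*A03:01", "HLA-A*03:01"),
        ("A0301", "HLA-A*03:01"),
        ("HLA-B*07:02", "HLA-B*07:02"),
    ],
)
def test_normalize_allele(raw, expected):
    assert seqio.normalize_allele(raw) == expected


def test_read_binding_table_simple(tmp_path):
    p = tmp_path / "b.tsv"
    p.write_text(
        "peptide\tallele\tpercent_rank\n"
        "KLDPTAVSR\tHLA-A03:01\t0.12\n"
        "MTEYKLVV\tHLA-B*07:02\t5.5\n"
    )
    preds = seqio.read_binding_table(p)
    assert preds[0].percent_rank == 0.12
    assert preds[0].allele == "HLA-A*03:01"


def test_read_binding_table_negative_rank(tmp_path):
    p = tmp_path / "b.tsv"
    p.write_text("peptide\tallele\tpercent_rank\nKLDPTAVSR\tHLA-A03:01\t-1\n")
    with pytest.raises(ValueError, match="negative"):
        seqio.read_binding_table(p)


def test_read_binding_table_netmhcpan(tmp_path):
    p = tmp_path / "n.txt"
    p.write_text(
        "# prediction output\n"
        " Pos HLA Peptide Core Of Gp Gl Ip Il Icore Identity Score %Rank BindLevel\n"
        "---------------------------------------------------------------\n"
        "   1 HLA-A*03:01 KLDPTAVSR KLDPTAVSR 0 0 0 0 0 KLDPTAVSR PEPLIST 0.851 0.12 <=SB\n"
        "   2 HLA-A*03:01 MTEYKLVVV MTEYKLVVV 0 0 0 0 0 MTEYKLVVV PEPLIST 0.101 8.0\n"
    )
    preds = seqio.read_binding_table(p, dialect="netmhcpan")
    assert [(x.peptide, x.percent_rank) for x in preds] == [
        ("KLDPTAVSR", 0.12),
        ("MTEYKLVVV", 8.0),
    ]
    assert preds[0].allele == "HLA-A*03:01"
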