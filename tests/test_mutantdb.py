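"""Variant application, windows, database assembly, decoys."""
from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neofunnel import mutantdb
from neofunnel.mutantdb import ReferenceMismatchError
from neofunnel.types import AA_ALPHABET, MissenseVariant, ProteinRecord


def _var(acc, pos, ref, alt, gene="G", vid="v1"):
    return MissenseVariant(vid, gene, acc, pos, ref, alt)


def test_apply_variant_substitutes_one_residue():
    protein = ProteinRecord("P1", "ACDEF")
    mut = mutantdb.apply_variant(protein, _var("P1", 3, "D", "Y"))
    assert mut.record.sequence == "ACYEF"
    assert mut.record.accession == "P1_D3Y"
    assert mut.record.source == "variant"
    assert mut.parent_accession == "P1"


def test_apply_variant_reference_mismatch():
    protein = ProteinRecord("P1", "ACDEF")
    with pytest.raises(ReferenceMismatchError):
        mutantdb.apply_variant(protein, _var("P1", 3, "E", "Y"))


def test_apply_variant_out_of_range():
    protein = ProteinRecord("P1", "ACDEF")
    with pytest.raises(IndexError):
        mutantdb.apply_variant(protein, _var("P1", 9, "K", "R"))


@pytest.mark.parametrize(
    "pos,exp_len,exp_offset,exp_start",
    [
        (15, 21, 11, 5),  # internal: full 21-mer
        (3, 13, 3, 1),    # near N-terminus: truncated left flank
        (1, 11, 1, 1),    # at N-terminus
        (30, 11, 11, 20), # at C-terminus of a 30-mer
    ],
)
def test_extract_window_truncation(pos, exp_len, exp_offset, exp_start):
    seq = "ACDEFGHIKLMNPQRSTVWY" + "ACDEFGHIKL"  # 30 residues
    protein = ProteinRecord("P1", seq)
    ref = seq[pos - 1]
    alt = "W" if ref != "W" else "Y"
    mut = mutantdb.apply_variant(protein, _var("P1", pos, ref, alt))
    w = mutantdb.extract_window(mut, flank=10)
    assert len(w.sequence) == exp_len
    assert w.mutation_offset == exp_offset
    assert w.protein_start == exp_start
    assert w.sequence[w.mutation_offset - 1] == alt
    assert w.sequence == mut.record.sequence[exp_start - 1 : exp_start - 1 + exp_len]


def test_build_custom_db_additive_count(tiny_reference):
    contaminants = [ProteinRecord("CON__C1", "WWWWW", source="contaminant")]
    variants = [
        _var("P0001", 17, "S", "R", vid="v1"),
        _var("P0002", 1, "A", "V", vid="v2"),
    ]
    db = mutantdb.build_custom_db(tiny_reference, contaminants, variants)
    assert len(db) == 3 + 1 + 2
    assert [r.source for r in db] == ["reference"] * 3 + ["contaminant"] + ["variant"] * 2


def test_build_custom_db_deduplicates_identical_mutants(tiny_reference):
    variants = [
        _var("P0001", 17, "S", "R", vid="v1"),
        _var("P0001", 17, "S", "R", vid="v2"),  # same substitution, new call
    ]
    db = mutantdb.build_custom_db(tiny_reference, [], variants)
    variant_recs = [r for r in db if r.source == "variant"]
    assert len(db) == 3 + 0 + 2 - 1
    assert len(variant_recs) == 1
    assert {v.variant_id for v in variant_recs[0].variants} == {"v1", "v2"}


def test_build_custom_db_skips_unresolvable(tiny_reference, caplog):
    with caplog.at_level("WARNING"):
        db = mutantdb.build_custom_db(
            tiny_reference, [], [_var("MISSING", 3, "A", "V", gene="NOGENE")]
        )
    assert len(db) == 3
    assert "skipped" in caplog.text


def test_build_custom_db_isoform_fallback(tiny_reference):
    # accession unknown, but gene G2 resolves; residue 1 of P0002 is A
    db = mutantdb.build_custom_db(
        tiny_reference, [], [_var("OLDACC", 1, "A", "V", gene="G2")]
    )
    variant_recs = [r for r in db if r.source == "variant"]
    assert len(variant_recs) == 1
    assert variant_recs[0].accession == "P0002_A1V"


def test_build_custom_db_mismatch_error_mode(tiny_reference):
    with pytest.raises(ReferenceMismatchError):
        mutantdb.build_custom_db(
            tiny_reference, [], [_var("P0001", 17, "A", "V")], on_mismatch="error"
        )


def test_make_decoys():
    recs = [ProteinRecord("P1", "ACDEF"), ProteinRecord("P2", "ADA")]
    decoys = mutantdb.make_decoys(recs)
    assert len(decoys) == 2
    assert decoys[0].accession == "REV__P1" and decoys[0].sequence == "FEDCA"
    assert decoys[1].sequence == "ADA"  # palindrome still emitted
    assert all(d.source == "decoy" for d in decoys)
    with pytest.raises(ValueError):
        mutantdb.make_decoys([])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.data())
def test_mutant_hamming_distance_is_one(data):
    """Every mutant differs from its parent at exactly the variant position."""
    seq = data.draw(st.text(AA_ALPHABET, min_size=5, max_size=60))
    pos = data.draw(st.integers(1, len(seq)))
    ref = seq[pos - 1]
    alt = data.draw(st.sampled_from([a for a in AA_ALPHABET if a != ref]))
    protein = ProteinRecord("P1", seq)
    mut = mutantdb.apply_variant(protein, _var("P1", pos, ref, alt))
    diffs = [i for i, (x, y) in enumerate(zip(seq, mut.record.sequence)) if x != y]
    assert diffs == [pos - 1]
    assert len(mut.record.sequence) == len(seq)

    w = mutantdb.extract_window(mut, flank=10)
    assert w.sequence in mut.record.sequence
    assert w.sequence[w.mutation_offset - 1] == alt
    # undoing the substitution recovers a substring of the parent
    restored = (
        w.sequence[: w.mutation_offset - 1] + ref + w.sequence[w.mutation_offset :]
    )
    assert restored in seq
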