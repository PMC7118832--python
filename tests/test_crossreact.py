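"""Local alignment, similarity scoring, screening, and binning.

The affine-gap Smith-Waterman implementation is checked against
Bio.Align.PairwiseAligner as an independent oracle (gap of length g costs
11 + g under the blastp convention, i.e. open_gap_score=-12/extend=-1 in
biopython's attached-extension convention).
"""
from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from neofunnel import crossreact
from neofunnel.crossreact import (
    AlignmentParams,
    batch_local_scores,
    bin_scores,
    local_align,
    screen_candidates,
    similarity_score,
)
from neofunnel.types import AA_ALPHABET, CandidateNeoantigen, EpitopeRecord, MissenseVariant, SimilarityHit


def _bio_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -12
    al.extend_gap_score = -1
    return al


def test_self_alignment_blosum62_diagonal():
    aln = local_align("SIINFEKL", "SIINFEKL")
    # S4+I4+I4+N6+F6+E5+K5+L4
    assert aln.raw_score == 38
    assert aln.identities == 8 and aln.alignment_length == 8
    assert aln.aligned_query == aln.aligned_subject == "SIINFEKL"


def test_single_mismatch_alignment():
    aln = local_align("SIINFEKL", "SIINFEKV")
    assert aln.raw_score == 35  # L:V scores +1
    assert aln.identities == 7 and aln.alignment_length == 8


def test_no_positive_overlap_yields_empty_alignment():
    aln = local_align("W", "C")  # W:C = -2 in BLOSUM62
    assert aln.raw_score == 0 and aln.identities == 0
    assert aln.aligned_query == "" and aln.query_start is None


def test_alphabet_validation():
    with pytest.raises(ValueError):
        local_align("SIINFEKX", "SIINFEKL")
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=0)


def test_similarity_examples():
    assert similarity_score("SIINFEKL", "SIINFEKL") == 100.0
    assert similarity_score("SIINFEKL", "SIINFEKV") == 87.5
    # 9-mer whose only alignable region is a 2-residue identical patch: 2/9
    assert similarity_score("CCCCCCCKL", "KLHHHHHHH") == pytest.approx(200 / 9)


def test_raw_score_symmetric_similarity_not():
    a, b = "SIINFEKL", "KLHHSIINF"
    assert local_align(a, b).raw_score == local_align(b, a).raw_score
    assert similarity_score("CCCCCCCKL", "KL") != similarity_score("KL", "CCCCCCCKL")


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.text(AA_ALPHABET, min_size=1, max_size=10),
    st.text(AA_ALPHABET, min_size=1, max_size=12),
)
def test_raw_score_matches_biopython_oracle(a, b):
    assert local_align(a, b).raw_score == int(_bio_aligner().score(a, b))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.text(AA_ALPHABET, min_size=1, max_size=11))
def test_self_similarity_is_100(seq):
    assert similarity_score(seq, seq) == 100.0


def test_batch_scores_agree_with_scalar():
    rng = np.random.default_rng(11)
    queries = ["".join(rng.choice(list(AA_ALPHABET), size=rng.integers(8, 12)))
               for _ in range(12)]
    subjects = ["".join(rng.choice(list(AA_ALPHABET), size=rng.integers(5, 14)))
                for _ in range(15)]
    raw, ident = batch_local_scores(queries, subjects)
    for i, q in enumerate(queries):
        for j, s in enumerate(subjects):
            aln = local_align(q, s)
            assert raw[i, j] == aln.raw_score, (q, s)
            assert ident[i, j] == aln.identities, (q, s)


def _cand(pep, offset=1, vid="v1"):
    ref = "A" if pep[offset - 1] != "A" else "C"
    v = MissenseVariant(vid, "G1", "P1", offset, ref, pep[offset - 1])
    return CandidateNeoantigen(pep, offset, (v,))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_planted_homolog_recovery(data):
    """A 9-11-mer epitope differing by <=2 non-adjacent substitutions scores
    at least 77 and is recovered at the default threshold of 20."""
    pep = data.draw(st.text(AA_ALPHABET, min_size=9, max_size=11))
    n_subs = data.draw(st.integers(1, 2))
    positions: list[int] = []
    while len(positions) < n_subs:
        p = data.draw(st.integers(0, len(pep) - 1))
        if all(abs(p - q) > 1 for q in positions):
            positions.append(p)
    seq = list(pep)
    for p in positions:
        seq[p] = data.draw(st.sampled_from([a for a in AA_ALPHABET if a != seq[p]]))
    score = similarity_score(pep, "".join(seq))
    assert score >= 77.0
    assert score >= 20.0  # recovered by the screen


def test_screen_candidates_best_hit_and_probability():
    cands = [_cand("SIINFEKLV", offset=2), _cand("WWWWWWWWW", offset=1, vid="v2")]
    epis = [
        EpitopeRecord("e1", "SIINFEKLV"),
        EpitopeRecord("e2", "SIINFEKVV"),
        EpitopeRecord("e3", "DDDDDDDDD"),
    ]
    res = screen_candidates(cands, epis)
    by_pep = {h.peptide: h for h in res.hits}
    assert by_pep["SIINFEKLV"].epitope_id == "e1"
    assert by_pep["SIINFEKLV"].score == 100.0
    assert by_pep["WWWWWWWWW"].score < 20.0
    assert res.comparison_probability == pytest.approx(50.0)
    assert [h.peptide for h in res.recognizable] == ["SIINFEKLV"]


def test_screen_requires_epitopes_and_handles_no_hits():
    with pytest.raises(ValueError):
        screen_candidates([_cand("SIINFEKLV", 2)], [])
    res = screen_candidates([_cand("WWWWWWWWW", 1)], [EpitopeRecord("e", "DDDDDDD")])
    assert res.comparison_probability == 0.0
    assert res.recognizable == []


def test_screen_deterministic():
    cands = [_cand("SIINFEKLV", 2), _cand("MTEYKLVVV", 3, vid="v2")]
    epis = [EpitopeRecord(f"e{i}", s) for i, s in
            enumerate(["SIINFEKVV", "MTEYKLVVA", "HHHHHHHHH"])]
    r1 = screen_candidates(cands, epis)
    r2 = screen_candidates(cands, epis)
    assert r1.hits == r2.hits


def _hit(score):
    return SimilarityHit("SIINFEKL", "e", score, 2, 8, 10)


def test_bin_scores_boundaries():
    counts = bin_scores([_hit(25.0), _hit(45.0), _hit(65.0), _hit(100.0)])
    assert counts == {"20-39": 1, "40-59": 1, "60-79": 1, "80-100": 1}
    assert crossreact.assign_bin(39.5) == "20-39"
    assert crossreact.assign_bin(100.0) == "80-100"
    assert sum(counts.values()) == 4
    with pytest.raises(ValueError):
        bin_scores([_hit(19.0)])
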