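"""TCR-recognizability proxy: local-alignment similarity to known epitopes.

Candidate neoantigens are compared against a set of cross-reactive microbial
epitopes with an affine-gap Smith-Waterman alignment under BLOSUM62 (protein
blastp defaults: gap open 11, gap extend 1; a gap of length g costs
``open + g * extend``).  Similarity is reported on a 0-100 scale as

    score = 100 * identities(best local alignment) / len(candidate)

so a self-comparison scores exactly 100 and a short high-identity patch
cannot inflate the score.  Candidates whose best epitope similarity reaches
``min_score`` (default 20) count as recognizable; the fraction of
recognizable candidates is the screen's comparison probability.

The dynamic program maximizes the pair (raw score, identities)
lexicographically by packing both into one integer (score * 64 + identity
bit per matched column; identities over peptide-scale alignments never reach
64), which makes "highest identity among co-optimal alignments" an ordinary
additive DP.  With query lengths of 8-11 full DP over every epitope is cheap,
so no word-seeded heuristic and no E-value statistics are involved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .types import AA_ALPHABET, CandidateNeoantigen, EpitopeRecord, SimilarityHit

_W = 64  # identity-bit packing weight; must exceed any possible identity count
_NEG = -(2**30)
_FAR = (10**9, 10**9)  # start sentinel that loses every earliest-start tie


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap penalties (positive costs)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=4)
def _matrix(name: str) -> dict[tuple[str, str], int]:
    mat = substitution_matrices.load(name)
    out: dict[tuple[str, str], int] = {}
    for x in AA_ALPHABET:
        for y in AA_ALPHABET:
            out[(x, y)] = int(mat[x, y])
    return out


@lru_cache(maxsize=4)
def _matrix64(name: str) -> np.ndarray:
    """21x21 packed-score matrix; index 20 is the padding sentinel."""
    mat = _matrix(name)
    m64 = np.full((21, 21), -(10**5) * _W, dtype=np.int32)
    for i, x in enumerate(AA_ALPHABET):
        for j, y in enumerate(AA_ALPHABET):
            m64[i, j] = mat[(x, y)] * _W + (1 if x == y else 0)
    return m64


_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def _encode(seqs: Sequence[str], width: int) -> np.ndarray:
    arr = np.full((len(seqs), width), 20, dtype=np.int8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = [_AA_INDEX[c] for c in s]
    return arr


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - set(AA_ALPHABET)
    if bad or not seq:
        raise ValueError(
            f"sequence {seq!r} contains characters outside the 20-letter "
            f"alphabet: {sorted(bad)}"
        )


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal Smith-Waterman local alignment of a (query, subject) pair."""

    raw_score: int
    identities: int
    alignment_length: int
    aligned_query: str
    aligned_subject: str
    query_start: int | None  # 1-based; None for an empty alignment
    subject_start: int | None


def local_align(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``a`` (query) vs ``b`` (subject).

    Ties between co-optimal alignments are broken deterministically: highest
    identity count first (packed into the DP), then earliest start in the
    query, then in the subject.
    """
    _check_alphabet(a)
    _check_alphabet(b)
    mat = _matrix(params.matrix_name)
    gopen = (params.gap_open + params.gap_extend) * _W
    gext = params.gap_extend * _W

    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[_NEG] * (n + 1) for _ in range(m + 1)]
    F = [[_NEG] * (n + 1) for _ in range(m + 1)]
    SH = [[_FAR] * (n + 1) for _ in range(m + 1)]
    SE = [[_FAR] * (n + 1) for _ in range(m + 1)]
    SF = [[_FAR] * (n + 1) for _ in range(m + 1)]

    best, best_start, best_end = 0, _FAR, _FAR
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # gap in query (consume b[j-1])
            opts = [(H[i][j - 1] - gopen, SH[i][j - 1]), (E[i][j - 1] - gext, SE[i][j - 1])]
            E[i][j], SE[i][j] = max(opts, key=lambda t: (t[0], (-t[1][0], -t[1][1])))
            # gap in subject (consume a[i-1])
            opts = [(H[i - 1][j] - gopen, SH[i - 1][j]), (F[i - 1][j] - gext, SF[i - 1][j])]
            F[i][j], SF[i][j] = max(opts, key=lambda t: (t[0], (-t[1][0], -t[1][1])))
            # match/mismatch or restart
            x, y = a[i - 1], b[j - 1]
            sub = mat[(x, y)] * _W + (1 if x == y else 0)
            diag_start = SH[i - 1][j - 1] if H[i - 1][j - 1] > 0 else (i, j)
            opts = [
                (H[i - 1][j - 1] + sub, diag_start),
                (E[i][j], SE[i][j]),
                (F[i][j], SF[i][j]),
                (0, _FAR),
            ]
            H[i][j], SH[i][j] = max(opts, key=lambda t: (t[0], (-t[1][0], -t[1][1])))
            if (H[i][j], (-SH[i][j][0], -SH[i][j][1]), (-i, -j)) > (
                best, (-best_start[0], -best_start[1]), (-best_end[0], -best_end[1])
            ):
                best, best_start, best_end = H[i][j], SH[i][j], (i, j)

    if best <= 0:
        return LocalAlignment(0, 0, 0, "", "", None, None)

    # traceback from the chosen end cell
    aq: list[str] = []
    ab: list[str] = []
    i, j = best_end
    state = "H"
    while True:
        if state == "H":
            if H[i][j] <= 0:
                break
            x, y = a[i - 1], b[j - 1]
            sub = mat[(x, y)] * _W + (1 if x == y else 0)
            diag_start = SH[i - 1][j - 1] if H[i - 1][j - 1] > 0 else (i, j)
            if H[i][j] == H[i - 1][j - 1] + sub and SH[i][j] == diag_start:
                aq.append(x)
                ab.append(y)
                if SH[i][j] == (i, j):
                    i, j = i - 1, j - 1
                    break
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j] and SH[i][j] == SF[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            aq.append(a[i - 1])
            ab.append("-")
            if F[i][j] == H[i - 1][j] - gopen and SF[i][j] == SH[i - 1][j]:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:  # E
            aq.append("-")
            ab.append(b[j - 1])
            if E[i][j] == H[i][j - 1] - gopen and SE[i][j] == SH[i][j - 1]:
                j, state = j - 1, "H"
            else:
                j = j - 1

    aligned_query = "".join(reversed(aq))
    aligned_subject = "".join(reversed(ab))
    identities = best % _W
    return LocalAlignment(
        raw_score=best // _W,
        identities=identities,
        alignment_length=len(aligned_query),
        aligned_query=aligned_query,
        aligned_subject=aligned_subject,
        query_start=best_start[0],
        subject_start=best_start[1],
    )


def similarity_score(
    candidate: str, epitope: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """100 * identities(best local alignment) / len(candidate)."""
    aln = local_align(candidate, epitope, params)
    return 100.0 * aln.identities / len(candidate)


def batch_local_scores(
    queries: Sequence[str],
    subjects: Sequence[str],
    params: AlignmentParams = DEFAULT_PARAMS,
    chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw SW scores and identity counts for every (query, subject) pair.

    Vectorized over pairs; identical in result to :func:`local_align` (the
    packed-integer recurrence is the same, padding columns carry a penalty
    large enough that they can never participate in an optimum).  Returns two
    int arrays of shape (n_queries, n_subjects).
    """
    for s in list(queries) + list(subjects):
        _check_alphabet(s)
    m64 = _matrix64(params.matrix_name)
    gopen = np.int32((params.gap_open + params.gap_extend) * _W)
    gext = np.int32(params.gap_extend * _W)

    lq = max(len(s) for s in queries)
    ls = max(len(s) for s in subjects)
    Q = _encode(queries, lq)
    S = _encode(subjects, ls)
    nq, ns = len(queries), len(subjects)
    scores = np.zeros((nq, ns), dtype=np.int32)
    idents = np.zeros((nq, ns), dtype=np.int32)

    for c0 in range(0, nq, chunk):
        c1 = min(c0 + chunk, nq)
        qc = c1 - c0
        Qc = Q[c0:c1]
        H_prev = np.zeros((qc, ns, ls + 1), dtype=np.int32)
        F_prev = np.full((qc, ns, ls + 1), _NEG, dtype=np.int32)
        best = np.zeros((qc, ns), dtype=np.int32)
        for i in range(1, lq + 1):
            H_cur = np.zeros((qc, ns, ls + 1), dtype=np.int32)
            F_cur = np.full((qc, ns, ls + 1), _NEG, dtype=np.int32)
            e_col = np.full((qc, ns), _NEG, dtype=np.int32)
            qi = Qc[:, i - 1].astype(np.intp)
            for j in range(1, ls + 1):
                sub = m64[qi[:, None], S[:, j - 1].astype(np.intp)[None, :]]
                e_col = np.maximum(H_cur[:, :, j - 1] - gopen, e_col - gext)
                F_cur[:, :, j] = np.maximum(H_prev[:, :, j] - gopen, F_prev[:, :, j] - gext)
                h = np.maximum(H_prev[:, :, j - 1] + sub, 0)
                np.maximum(h, e_col, out=h)
                np.maximum(h, F_cur[:, :, j], out=h)
                H_cur[:, :, j] = h
                np.maximum(best, h, out=best)
            H_prev, F_prev = H_cur, F_cur
        scores[c0:c1] = best // _W
        idents[c0:c1] = best % _W
    return scores, idents


def assign_bin(score: float) -> str:
    """Similarity bin for a score >= 20 (half-open below, closed at 100)."""
    if score < 20:
        raise ValueError(f"score {score} below the screening threshold 20")
    if score < 40:
        return "20-39"
    if score < 60:
        return "40-59"
    if score < 80:
        return "60-79"
    return "80-100"


def bin_scores(hits: Sequence[SimilarityHit]) -> dict[str, int]:
    """Counts of hits per similarity bin; every hit lands in exactly one."""
    counts = {"20-39": 0, "40-59": 0, "60-79": 0, "80-100": 0}
    for hit in hits:
        counts[assign_bin(hit.score)] += 1
    return counts


@dataclass
class ScreenResult:
    """Best-hit-per-candidate similarity screen outcome."""

    hits: list[SimilarityHit] = field(default_factory=list)
    recognizable: list[SimilarityHit] = field(default_factory=list)
    comparison_probability: float = 0.0

    @property
    def recognizable_peptides(self) -> set[str]:
        return {h.peptide for h in self.recognizable}


def screen_candidates(
    candidates: Sequence[CandidateNeoantigen],
    epitopes: Sequence[EpitopeRecord],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_score: float = 20.0,
) -> ScreenResult:
    """Best epitope hit for every candidate plus the comparison probability.

    The comparison probability is 100 x (candidates with best similarity >=
    ``min_score``) / (candidates screened).  The best hit maximizes
    similarity, then raw SW score, then takes the earliest epitope.
    """
    if not epitopes:
        raise ValueError("cannot screen against an empty epitope set")
    result = ScreenResult()
    if not candidates:
        return result

    peptides = sorted({c.peptide for c in candidates})
    pep_row = {p: i for i, p in enumerate(peptides)}
    subjects = [e.sequence for e in epitopes]
    raw, ident = batch_local_scores(peptides, subjects, params)

    best_hit: dict[str, SimilarityHit] = {}
    for pep, row in pep_row.items():
        ir = ident[row]
        rr = raw[row]
        best_j = max(range(len(subjects)), key=lambda j: (ir[j], rr[j], -j))
        aln = local_align(pep, subjects[best_j], params)
        score = 100.0 * aln.identities / len(pep)
        best_hit[pep] = SimilarityHit(
            peptide=pep,
            epitope_id=epitopes[best_j].epitope_id,
            score=score,
            identities=aln.identities,
            alignment_length=aln.alignment_length,
            raw_sw_score=aln.raw_score,
            aligned_query=aln.aligned_query,
            aligned_subject=aln.aligned_subject,
            bin=assign_bin(score) if score >= min_score else None,
        )

    seen: set[str] = set()
    for c in candidates:
        if c.peptide in seen:
            continue
        seen.add(c.peptide)
        hit = best_hit[c.peptide]
        result.hits.append(hit)
        if hit.score >= min_score:
            result.recognizable.append(hit)
    n_total = len(seen)
    result.comparison_probability = (
        100.0 * len(result.recognizable) / n_total if n_total else 0.0
    )
    return result
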