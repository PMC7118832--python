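"""Candidate neoantigen enumeration from mutation-centered windows.

MHC class I ligands are 8-11 residues long, so every substring of a window
with a length in that range whose span covers the substituted residue is a
candidate.  Mutation-free substrings are never generated, which implements
the removal of peptides without mutation sites as an enumeration constraint
rather than a post-hoc filter.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .types import CandidateNeoantigen, MissenseVariant, PeptideWindow, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_LENGTHS = (8, 9, 10, 11)


def enumerate_candidates(
    window: PeptideWindow, lengths: Iterable[int] = DEFAULT_LENGTHS
) -> list[CandidateNeoantigen]:
    """All substrings of the window with length in ``lengths`` covering the
    mutated residue.

    An internal mutation with full flanks and lengths 8-11 yields exactly
    8+9+10+11 = 38 candidates; a mutation at window offset 1 yields one per
    length.
    """
    seq = window.sequence
    off = window.mutation_offset  # 1-based
    out: list[CandidateNeoantigen] = []
    for L in sorted(set(lengths)):
        # 0-based starts s with s <= off-1 <= s+L-1
        lo = max(0, off - L)
        hi = min(len(seq) - L, off - 1)
        for s in range(lo, hi + 1):
            out.append(
                CandidateNeoantigen(
                    peptide=seq[s : s + L],
                    mutation_offset=off - s,
                    variants=(window.variant,),
                    window_ref=window.window_ref,
                )
            )
    return out


def enumerate_all(
    windows: Iterable[PeptideWindow], lengths: Iterable[int] = DEFAULT_LENGTHS
) -> list[CandidateNeoantigen]:
    """Enumerate and deduplicate candidates over a batch of windows."""
    raw: list[CandidateNeoantigen] = []
    for w in windows:
        raw.extend(enumerate_candidates(w, lengths=lengths))
    return dedupe_candidates(raw)


def dedupe_candidates(
    candidates: Sequence[CandidateNeoantigen],
) -> list[CandidateNeoantigen]:
    """Merge candidates identical on (peptide, mutation_offset).

    Identical peptides arising from different isoforms or genes collapse into
    one candidate carrying the union of their provenance; the same string
    with a different mutation offset stays a separate entry.
    """
    merged: dict[tuple[str, int], CandidateNeoantigen] = {}
    for c in candidates:
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = c
            continue
        seen = {(v.variant_id, v.protein_accession, v.substitution) for v in prev.variants}
        extra = tuple(
            v
            for v in c.variants
            if (v.variant_id, v.protein_accession, v.substitution) not in seen
        )
        if extra:
            merged[c.key] = CandidateNeoantigen(
                peptide=prev.peptide,
                mutation_offset=prev.mutation_offset,
                variants=prev.variants + extra,
                window_ref=prev.window_ref,
            )
    return list(merged.values())


def remove_wildtype_matches(
    candidates: Sequence[CandidateNeoantigen],
    reference: Sequence[ProteinRecord],
) -> list[CandidateNeoantigen]:
    """Drop candidates occurring verbatim anywhere in the reference proteome.

    A guard for tumor specificity; optional and off by default in the
    pipeline, since a mutant k-mer can coincide with an unrelated wild-type
    region elsewhere.
    """
    haystack = "\n".join(rec.sequence for rec in reference)
    kept: list[CandidateNeoantigen] = []
    for c in candidates:
        if c.peptide in haystack:
            logger.info("candidate %s matches the wild-type proteome; removed", c.peptide)
            continue
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Table round trip (the CLI's interchange format)


def write_candidates_tsv(
    candidates: Sequence[CandidateNeoantigen], path: str | Path
) -> Path:
    path = Path(path)
    rows = sorted(candidates, key=lambda c: c.key)
    with open(path, "w", newline="") as out:
        w = csv.writer(out, delimiter="\t", lineterminator="\n")
        w.writerow(["peptide", "length", "mutation_offset", "genes", "variants", "window_ref"])
        for c in rows:
            w.writerow(
                [
                    c.peptide,
                    len(c.peptide),
                    c.mutation_offset,
                    ";".join(c.genes),
                    ";".join(
                        f"{v.variant_id}|{v.gene_symbol}|{v.protein_accession}|{v.substitution}"
                        for v in c.variants
                    ),
                    c.window_ref,
                ]
            )
    return path


def read_candidates_tsv(path: str | Path) -> list[CandidateNeoantigen]:
    out: list[CandidateNeoantigen] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            variants = []
            for entry in row["variants"].split(";"):
                vid, gene, acc, sub = entry.split("|")
                variants.append(
                    MissenseVariant(
                        variant_id=vid,
                        gene_symbol=gene,
                        protein_accession=acc,
                        position=int(sub[1:-1]),
                        ref_aa=sub[0],
                        alt_aa=sub[-1],
                    )
                )
            out.append(
                CandidateNeoantigen(
                    peptide=row["peptide"],
                    mutation_offset=int(row["mutation_offset"]),
                    variants=tuple(variants),
                    window_ref=row["window_ref"],
                )
            )
    return out


def write_peptide_list(
    candidates: Sequence[CandidateNeoantigen], path: str | Path
) -> Path:
    """Plain one-peptide-per-line export (external predictor input format)."""
    path = Path(path)
    with open(path, "w") as out:
        for pep in sorted({c.peptide for c in candidates}):
            out.write(pep + "\n")
    return path
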