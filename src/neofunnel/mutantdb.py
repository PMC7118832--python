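"""Variant application, mutation-centered windows, and the customized search DB.

A missense variant is applied to its parent protein by substituting exactly
one residue.  Each mutant protein yields one window of up to ``2*flank + 1``
residues centered on the substitution (truncated at the termini), which is the
unit from which candidate neoantigens are enumerated.  The customized MS
search database is the concatenation reference + contaminants + mutants, with
sequence-level duplicates merged.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .types import (
    DECOY_PREFIX,
    MissenseVariant,
    MutantProtein,
    PeptideWindow,
    ProteinRecord,
)

logger = logging.getLogger(__name__)


class ReferenceMismatchError(ValueError):
    """The protein residue at the variant position does not match ref_aa."""


def apply_variant(protein: ProteinRecord, v: MissenseVariant) -> MutantProtein:
    """Substitute the variant's alternate residue into the parent protein.

    Raises ``IndexError`` for out-of-range positions and
    :class:`ReferenceMismatchError` when the parent residue disagrees with the
    annotated reference amino acid (annotation/proteome version skew).
    """
    if not 1 <= v.position <= len(protein.sequence):
        raise IndexError(
            f"{v.variant_id}: position {v.position} outside {protein.accession} "
            f"(length {len(protein.sequence)})"
        )
    found = protein.sequence[v.position - 1]
    if found != v.ref_aa:
        raise ReferenceMismatchError(
            f"{v.variant_id}: {protein.accession} position {v.position} holds "
            f"{found}, expected {v.ref_aa}"
        )
    seq = protein.sequence[: v.position - 1] + v.alt_aa + protein.sequence[v.position:]
    record = ProteinRecord(
        accession=f"{protein.accession}_{v.substitution}",
        sequence=seq,
        gene_symbol=v.gene_symbol or protein.gene_symbol,
        description=f"missense {v.substitution} in {protein.accession}",
        source="variant",
        variants=(v,),
    )
    return MutantProtein(record=record, parent_accession=protein.accession, variant=v)


def extract_window(mut: MutantProtein, flank: int = 10) -> PeptideWindow:
    """Extract the mutation-centered window (<= 2*flank+1 residues).

    Windows at the protein termini are truncated, not padded: a mutation at
    position 3 of a long protein yields a 13-mer with offset 3.
    """
    p = mut.variant.position
    seq = mut.record.sequence
    start = max(1, p - flank)
    end = min(len(seq), p + flank)
    return PeptideWindow(
        sequence=seq[start - 1 : end],
        mutation_offset=p - start + 1,
        protein_start=start,
        variant=mut.variant,
        window_ref=mut.record.accession,
    )


def extract_windows(
    muts: Iterable[MutantProtein], flank: int = 10
) -> list[PeptideWindow]:
    """Windows for a batch of mutants; X-containing windows are skipped since
    substitution scores for X are undefined in the downstream screen."""
    windows: list[PeptideWindow] = []
    for mut in muts:
        w = extract_window(mut, flank=flank)
        if "X" in w.sequence:
            logger.warning(
                "skipping window of %s: ambiguous residue X", mut.record.accession
            )
            continue
        windows.append(w)
    return windows


def apply_variants(
    reference: Sequence[ProteinRecord],
    variants: Sequence[MissenseVariant],
    on_mismatch: str = "skip",
) -> list[MutantProtein]:
    """Apply each variant against the reference proteome.

    Resolution is by protein accession; when the accession is absent, every
    reference isoform of the variant's gene whose residue at the stated
    position matches ref_aa is used instead (each application yields its own
    mutant).  ``on_mismatch`` is ``"skip"`` (warn, default: version skew is
    routine) or ``"error"``.
    """
    if on_mismatch not in ("skip", "error"):
        raise ValueError(f"on_mismatch must be 'skip' or 'error', got {on_mismatch!r}")
    by_acc = {rec.accession: rec for rec in reference}
    by_gene: dict[str, list[ProteinRecord]] = {}
    for rec in reference:
        if rec.gene_symbol:
            by_gene.setdefault(rec.gene_symbol, []).append(rec)

    mutants: list[MutantProtein] = []
    for v in variants:
        targets = []
        if v.protein_accession in by_acc:
            targets = [by_acc[v.protein_accession]]
        elif v.gene_symbol in by_gene:
            targets = [
                rec
                for rec in by_gene[v.gene_symbol]
                if 1 <= v.position <= len(rec.sequence)
                and rec.sequence[v.position - 1] == v.ref_aa
            ]
            if targets:
                logger.info(
                    "%s: accession %s not found; applied to %d isoform(s) of %s",
                    v.variant_id, v.protein_accession, len(targets), v.gene_symbol,
                )
        if not targets:
            logger.warning(
                "%s: no reference protein for %s/%s; skipped",
                v.variant_id, v.protein_accession, v.gene_symbol,
            )
            continue
        for rec in targets:
            try:
                mutants.append(apply_variant(rec, v))
            except (ReferenceMismatchError, IndexError) as exc:
                if on_mismatch == "error":
                    raise
                logger.warning("%s; skipped", exc)
    return mutants


def build_custom_db(
    reference: Sequence[ProteinRecord],
    contaminants: Sequence[ProteinRecord],
    variants: Sequence[MissenseVariant],
    on_mismatch: str = "skip",
) -> list[ProteinRecord]:
    """Assemble the customized reference + contaminant + variant database.

    Distinct variants that produce an identical full-length mutant sequence
    are merged into one record with combined provenance, so the output size is
    |reference| + |contaminants| + |applied variants| - |duplicates|.
    """
    mutants = apply_variants(reference, variants, on_mismatch=on_mismatch)
    merged: dict[str, ProteinRecord] = {}
    for mut in mutants:
        rec = mut.record
        prev = merged.get(rec.sequence)
        if prev is None:
            merged[rec.sequence] = rec
        else:
            logger.info(
                "duplicate mutant sequence: %s merged into %s",
                rec.accession, prev.accession,
            )
            merged[rec.sequence] = ProteinRecord(
                accession=prev.accession,
                sequence=prev.sequence,
                gene_symbol=prev.gene_symbol,
                description=prev.description,
                source="variant",
                variants=prev.variants + rec.variants,
            )
    return list(reference) + list(contaminants) + list(merged.values())


def make_decoys(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Reversed-sequence decoys, one per input, accessions prefixed REV__."""
    if not records:
        raise ValueError("cannot build decoys from an empty database")
    decoys: list[ProteinRecord] = []
    for rec in records:
        rev = rec.sequence[::-1]
        if rev == rec.sequence:
            logger.warning(
                "palindromic sequence %s: decoy collides with target", rec.accession
            )
        decoys.append(
            ProteinRecord(
                accession=f"{DECOY_PREFIX}{rec.accession}",
                sequence=rev,
                gene_symbol=rec.gene_symbol,
                description=rec.description,
                source="decoy",
            )
        )
    return decoys
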