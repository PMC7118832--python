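"""Expression-level and MS-evidence attrition stages of the funnel.

Both filters are contractive and idempotent, and commute set-theoretically:
the expression filter drops candidates whose gene shows no transcript above
0 TPM, and the MS filter keeps only candidates contained in a variant peptide
actually identified by the search engine.
"""
from __future__ import annotations

import logging
from typing import Sequence

from .types import CandidateNeoantigen, ExpressionRecord, MsIdentifiedPeptide

logger = logging.getLogger(__name__)

EXPRESSION_MODES = ("gene_any_transcript", "gene_sum_transcripts")


def gene_expression_levels(
    expression: Sequence[ExpressionRecord], mode: str = "gene_any_transcript"
) -> dict[str, float]:
    """Collapse transcript TPMs to one value per gene (max or sum)."""
    if mode not in EXPRESSION_MODES:
        raise ValueError(f"unknown expression mode {mode!r}")
    levels: dict[str, float] = {}
    for rec in expression:
        if not rec.gene_symbol:
            continue
        if mode == "gene_any_transcript":
            levels[rec.gene_symbol] = max(levels.get(rec.gene_symbol, 0.0), rec.tpm)
        else:
            levels[rec.gene_symbol] = levels.get(rec.gene_symbol, 0.0) + rec.tpm
    return levels


def filter_by_expression(
    candidates: Sequence[CandidateNeoantigen],
    expression: Sequence[ExpressionRecord],
    mode: str = "gene_any_transcript",
) -> tuple[list[CandidateNeoantigen], dict]:
    """Exclude candidates from genes unexpressed at RNA level (0 TPM).

    A candidate is retained iff any of its provenance genes has a collapsed
    TPM strictly above zero.  Genes absent from the expression table count as
    zero and are excluded with a warning.
    """
    levels = gene_expression_levels(expression, mode=mode)
    retained: list[CandidateNeoantigen] = []
    n_missing = n_zero = 0
    missing_genes: set[str] = set()
    for c in candidates:
        genes = c.genes
        if any(levels.get(g, 0.0) > 0.0 for g in genes):
            retained.append(c)
        elif any(g in levels for g in genes):
            n_zero += 1
        else:
            n_missing += 1
            missing_genes.update(genes)
    for g in sorted(missing_genes):
        logger.warning("gene %s absent from expression table; treated as 0 TPM", g)
    report = {
        "stage": "expression",
        "n_in": len(candidates),
        "n_out": len(retained),
        "n_removed": len(candidates) - len(retained),
        "removed": {"zero_tpm": n_zero, "gene_missing": n_missing},
        "params": {"mode": mode, "min_tpm_exclusive": 0.0},
    }
    return retained, report


def filter_by_ms_evidence(
    candidates: Sequence[CandidateNeoantigen],
    ms_peptides: Sequence[MsIdentifiedPeptide],
    require_variant_flag: bool = True,
    il_equivalent: bool = False,
) -> tuple[list[CandidateNeoantigen], dict]:
    """Keep candidates contained in an MS-identified (variant) peptide.

    A candidate is retained iff its peptide is a contiguous substring of at
    least one MS peptide mapped to a variant database entry (when
    ``require_variant_flag``); full containment automatically places the
    mutated residue inside the matched region.  ``il_equivalent`` folds I and
    L together before matching, since collision-induced dissociation spectra
    cannot distinguish the two isobaric residues.
    """
    fold = (lambda s: s.replace("I", "L")) if il_equivalent else (lambda s: s)
    pool = [
        p for p in ms_peptides if p.is_variant or not require_variant_flag
    ]
    folded = [(p, fold(p.sequence)) for p in pool]

    retained: list[CandidateNeoantigen] = []
    support: dict[str, list[str]] = {}
    for c in candidates:
        needle = fold(c.peptide)
        hits = [p.sequence for p, hay in folded if needle in hay]
        if hits:
            retained.append(c)
            support[c.peptide] = hits
    report = {
        "stage": "ms_evidence",
        "n_in": len(candidates),
        "n_out": len(retained),
        "n_removed": len(candidates) - len(retained),
        "params": {
            "require_variant_flag": require_variant_flag,
            "il_equivalent": il_equivalent,
            "n_ms_peptides": len(pool),
        },
        "support": support,
    }
    return retained, report
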