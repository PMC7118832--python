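"""MHC-I binder classification on percentile rank, and a mock predictor.

%Rank is the percentile of a peptide's predicted binding against a background
distribution for one allele; lower is stronger.  Classification follows the
NetMHCpan convention: strong binder at %Rank <= 0.5, weak binder in
(0.5, 2.0], non-binder above 2.0.  Both strong and weak binders are carried
forward.  Selection uses %Rank only; IC50 is parsed but never consulted.

The real predictor is an external, license-gated tool whose tabular output is
parsed by :func:`neofunnel.seqio.read_binding_table`; :func:`mock_predict` is
a seeded stand-in so the funnel is runnable and testable end to end.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import BinderClass, BindingPrediction

T_STRONG = 0.5
T_WEAK = 2.0


def classify_binder(
    percent_rank: float, t_strong: float = T_STRONG, t_weak: float = T_WEAK
) -> BinderClass:
    """Classify one %Rank value; boundaries are inclusive on the lower class."""
    if percent_rank < 0:
        raise ValueError(f"negative %Rank {percent_rank}")
    if not t_strong < t_weak:
        raise ValueError("t_strong must be below t_weak")
    if percent_rank <= t_strong:
        return BinderClass.STRONG
    if percent_rank <= t_weak:
        return BinderClass.WEAK
    return BinderClass.NON_BINDER


def select_binders(
    predictions: Iterable[BindingPrediction],
    t_strong: float = T_STRONG,
    t_weak: float = T_WEAK,
) -> list[BindingPrediction]:
    """Keep predictions classified strong or weak.

    A peptide is retained downstream if any allele yields a binder; the full
    per-(peptide, allele) table is preserved so per-allele summaries remain
    computable.
    """
    return [
        p
        for p in predictions
        if classify_binder(p.percent_rank, t_strong, t_weak) is not BinderClass.NON_BINDER
    ]


def binder_peptides(
    predictions: Iterable[BindingPrediction],
    t_strong: float = T_STRONG,
    t_weak: float = T_WEAK,
) -> set[str]:
    """Distinct peptides with at least one strong/weak prediction."""
    return {p.peptide for p in select_binders(predictions, t_strong, t_weak)}


def best_rank_by_peptide(
    predictions: Iterable[BindingPrediction],
) -> dict[str, BindingPrediction]:
    """Best (lowest) %Rank prediction per peptide across alleles."""
    best: dict[str, BindingPrediction] = {}
    for p in predictions:
        prev = best.get(p.peptide)
        if prev is None or (p.percent_rank, p.allele) < (prev.percent_rank, prev.allele):
            best[p.peptide] = p
    return best


def per_allele_summary(
    predictions: Iterable[BindingPrediction],
    t_strong: float = T_STRONG,
    t_weak: float = T_WEAK,
) -> tuple[dict[str, int], int]:
    """Distinct binder-peptide counts per allele, plus the shared count.

    The shared count is the number of peptides that are binders for two or
    more alleles.
    """
    peptides_by_allele: dict[str, set[str]] = {}
    alleles_by_peptide: dict[str, set[str]] = {}
    for p in select_binders(predictions, t_strong, t_weak):
        peptides_by_allele.setdefault(p.allele, set()).add(p.peptide)
        alleles_by_peptide.setdefault(p.peptide, set()).add(p.allele)
    counts = {a: len(peps) for a, peps in sorted(peptides_by_allele.items())}
    shared = sum(1 for alleles in alleles_by_peptide.values() if len(alleles) >= 2)
    return counts, shared


def count_by_class(
    predictions: Iterable[BindingPrediction],
    t_strong: float = T_STRONG,
    t_weak: float = T_WEAK,
) -> dict[str, int]:
    """Distinct-peptide counts by best class (strong wins over weak)."""
    best: dict[str, BinderClass] = {}
    order = {BinderClass.STRONG: 0, BinderClass.WEAK: 1, BinderClass.NON_BINDER: 2}
    for p in predictions:
        cls = classify_binder(p.percent_rank, t_strong, t_weak)
        prev = best.get(p.peptide)
        if prev is None or order[cls] < order[prev]:
            best[p.peptide] = cls
    out = {"strong": 0, "weak": 0, "non_binder": 0}
    for cls in best.values():
        out[cls.value] += 1
    return out


def mock_predict(
    peptides: Sequence[str],
    alleles: Sequence[str],
    seed: int,
    fraction_binders: float = 0.2,
    planted: Iterable[str] = (),
    rank_max: float = 90.0,
) -> list[BindingPrediction]:
    """Deterministic surrogate predictor for pipeline plumbing and tests.

    Ranks are drawn so that about ``fraction_binders`` of (peptide, allele)
    pairs fall at %Rank <= 2.  Each peptide in ``planted`` is forced to be a
    strong binder (%Rank <= 0.5) on one deterministically chosen allele.
    Identical inputs and seed give identical output.
    """
    if not 0.0 <= fraction_binders <= 1.0:
        raise ValueError("fraction_binders must be within [0, 1]")
    rng = np.random.default_rng(seed)
    planted_set = set(planted)
    out: list[BindingPrediction] = []
    for pep in peptides:
        forced_idx = int(rng.integers(len(alleles))) if pep in planted_set else -1
        for i, allele in enumerate(alleles):
            if i == forced_idx:
                rank = float(rng.uniform(0.01, 0.5))
            elif fraction_binders > 0 and rng.random() < fraction_binders:
                rank = float(rng.uniform(0.01, 2.0))
            else:
                rank = float(rng.uniform(2.01, rank_max))
            out.append(
                BindingPrediction(peptide=pep, allele=allele, percent_rank=round(rank, 4))
            )
    return out
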