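"""Seeded generator of toy datasets for every stage of the funnel.

The generator emulates, at desk scale, the external inputs the pipeline
consumes in a real study: a reference proteome with contaminants, an
annotated missense-variant table (with genomic SNV coordinates for an
optional VCF export), a kallisto-style transcript expression table, a
MaxQuant-style identified-peptide list, a linear-epitope set, and a binding
prediction table.  Every stochastic choice is recorded in a truth ledger of
planted facts, so the funnel's output at each stage is known by construction:

* binder planting is at the variant level — every candidate of a planted
  variant is forced to be a strong binder on one allele, all other
  predictions are non-binders — so the set retained by the binding stage is
  exactly the planted candidates;
* detected variant peptides span the full mutation window (lengths 21-43,
  within the 7-43 envelope a tryptic search reports), so MS containment
  retains exactly the candidates of MS-covered variants;
* each MS-covered candidate receives an epitope homolog differing by at most
  ``homolog_max_substitutions`` non-adjacent substitutions, so the screen
  recovers it at the default threshold.

Each generation stage draws from its own RNG substream keyed by (seed, stage
index): changing one fraction does not perturb the draws of other stages, and
regeneration with the same seed is byte-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import enumeration, mutantdb, seqio
from .binding import mock_predict
from .types import (
    AA_ALPHABET,
    BindingPrediction,
    CandidateNeoantigen,
    EpitopeRecord,
    ExpressionRecord,
    MissenseVariant,
    MsIdentifiedPeptide,
    ProteinRecord,
)

DEFAULT_ALLELES = (
    "HLA-A*03:01",
    "HLA-B*07:02",
    "HLA-B*35:03",
    "HLA-C*07:02",
    "HLA-C*04:01",
)

_ORGANISMS = (
    "Vaccinia virus",
    "Influenza A virus",
    "Epstein-Barr virus",
    "Human cytomegalovirus",
    "Mycobacterium tuberculosis",
)

# RNG substream indices, fixed so streams stay stable across config changes
_S_PROTEOME, _S_VARIANTS, _S_BINDERS, _S_EXPRESSION = 1, 2, 3, 4
_S_MS, _S_EPITOPES, _S_PREDICTIONS = 5, 6, 7


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 50
    protein_length_range: tuple[int, int] = (60, 120)
    n_variants: int = 100
    frac_binders: float = 0.5  # fraction of variants planted as binders
    frac_expressed: float = 0.6  # fraction of variant genes with TPM > 0
    frac_ms_detected: float = 0.5  # fraction of expressed variants seen by MS
    ms_length_range: tuple[int, int] = (7, 43)
    n_background_ms: int = 30
    n_epitopes: int = 25  # decoy epitopes on top of planted homologs
    frac_planted_homologs: float = 1.0
    homolog_max_substitutions: int = 2
    n_contaminants: int = 3
    flank: int = 10
    lengths: tuple[int, ...] = (8, 9, 10, 11)
    alleles: tuple[str, ...] = DEFAULT_ALLELES
    seed: int = 0


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ledger of planted facts."""

    config: SynthConfig
    proteome: list[ProteinRecord]
    contaminants: list[ProteinRecord]
    variants: list[MissenseVariant]
    expression: list[ExpressionRecord]
    ms_peptides: list[MsIdentifiedPeptide]
    ms_rows: list[dict]  # raw peptides.txt rows incl. decoy/contaminant lines
    epitopes: list[EpitopeRecord]
    predictions: list[BindingPrediction]
    truth: dict

    @property
    def seed(self) -> int:
        return self.config.seed


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[seed, stage]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _sample(rng: np.random.Generator, items: Sequence, frac: float) -> list:
    k = int(round(frac * len(items)))
    if k == 0:
        return []
    idx = sorted(rng.choice(len(items), size=k, replace=False).tolist())
    return [items[i] for i in idx]


def generate(config: SynthConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a dataset under the given study conditions.

    Proteins are i.i.d. uniform over the 20-letter alphabet; variants are
    placed uniformly at distinct (protein, position) sites with the reference
    residue read from the protein, so applying every variant succeeds.
    """
    cfg = replace(config or SynthConfig(), **overrides) if overrides else (config or SynthConfig())
    lo, hi = cfg.protein_length_range
    if lo < 2 * cfg.flank + 1:
        raise ValueError(
            f"proteins of length {lo} cannot host a full {2 * cfg.flank + 1}-mer window"
        )
    if not 0 <= cfg.seed < 2**31:
        raise ValueError("seed must be a non-negative 31-bit integer")

    # -- proteome and contaminants ------------------------------------------
    rng = _rng(cfg.seed, _S_PROTEOME)
    proteome = [
        ProteinRecord(
            accession=f"P{i:04d}",
            sequence=_random_seq(rng, int(rng.integers(lo, hi + 1))),
            gene_symbol=f"G{i:04d}",
            description=f"synthetic protein {i}",
        )
        for i in range(cfg.n_proteins)
    ]
    contaminants = [
        ProteinRecord(
            accession=f"CON__C{i:02d}",
            sequence=_random_seq(rng, int(rng.integers(lo, hi + 1))),
            description=f"synthetic contaminant {i}",
            source="contaminant",
        )
        for i in range(cfg.n_contaminants)
    ]

    # -- variants ------------------------------------------------------------
    rng = _rng(cfg.seed, _S_VARIANTS)
    taken: set[tuple[int, int]] = set()
    variants: list[MissenseVariant] = []
    bases = "ACGT"
    while len(variants) < cfg.n_variants:
        p_idx = int(rng.integers(cfg.n_proteins))
        pos = int(rng.integers(1, len(proteome[p_idx].sequence) + 1))
        if (p_idx, pos) in taken:
            continue
        taken.add((p_idx, pos))
        parent = proteome[p_idx]
        ref = parent.sequence[pos - 1]
        alt = AA_ALPHABET[int(rng.integers(20))]
        while alt == ref:
            alt = AA_ALPHABET[int(rng.integers(20))]
        ref_base = bases[int(rng.integers(4))]
        alt_base = bases[int(rng.integers(4))]
        while alt_base == ref_base:
            alt_base = bases[int(rng.integers(4))]
        i = len(variants)
        variants.append(
            MissenseVariant(
                variant_id=f"v{i:04d}",
                gene_symbol=parent.gene_symbol,
                protein_accession=parent.accession,
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                qual=float(round(rng.uniform(25.0, 95.0), 1)),
                genomic=(f"chr{1 + i % 22}", 10_000 + 137 * i, ref_base, alt_base),
            )
        )

    # mutants, windows, candidates (deterministic given the above)
    mutants = mutantdb.apply_variants(proteome, variants)
    windows = mutantdb.extract_windows(mutants, flank=cfg.flank)
    cand_by_variant: dict[str, list[CandidateNeoantigen]] = {}
    for w in windows:
        cand_by_variant[w.variant.variant_id] = enumeration.enumerate_candidates(
            w, lengths=cfg.lengths
        )
    all_candidates = enumeration.dedupe_candidates(
        [c for cands in cand_by_variant.values() for c in cands]
    )

    # -- planted binders (variant level) ------------------------------------
    rng = _rng(cfg.seed, _S_BINDERS)
    binder_variants = [v.variant_id for v in _sample(rng, variants, cfg.frac_binders)]
    binder_set = set(binder_variants)
    planted_peptides = sorted(
        {c.peptide for vid in binder_variants for c in cand_by_variant[vid]}
    )

    # -- expression ----------------------------------------------------------
    rng = _rng(cfg.seed, _S_EXPRESSION)
    variant_genes = sorted({v.gene_symbol for v in variants})
    expressed_genes = set(_sample(rng, variant_genes, cfg.frac_expressed))
    expression: list[ExpressionRecord] = []
    for i, rec in enumerate(proteome):
        if rec.gene_symbol in expressed_genes or rec.gene_symbol not in variant_genes:
            tpm = float(round(rng.lognormal(1.0, 1.0) + 0.1, 3))
        else:
            tpm = 0.0
        expression.append(
            ExpressionRecord(target_id=f"T{i:04d}", tpm=tpm, gene_symbol=rec.gene_symbol)
        )
    expressed_variants = [v.variant_id for v in variants if v.gene_symbol in expressed_genes]

    # -- MS peptides ---------------------------------------------------------
    rng = _rng(cfg.seed, _S_MS)
    ms_lo, ms_hi = cfg.ms_length_range
    ms_covered = [
        v for v in _sample(rng, [v for v in variants if v.gene_symbol in expressed_genes],
                           cfg.frac_ms_detected)
    ]
    ms_covered_ids = [v.variant_id for v in ms_covered]
    mut_by_id = {m.variant.variant_id: m for m in mutants}
    ms_rows: list[dict] = []
    for v in ms_covered:
        mut = mut_by_id[v.variant_id]
        seq = mut.record.sequence
        w_start = max(1, v.position - cfg.flank)
        w_end = min(len(seq), v.position + cfg.flank)
        span = w_end - w_start + 1
        target = int(rng.integers(max(span, ms_lo), min(ms_hi, len(seq)) + 1))
        extra = target - span
        left = int(rng.integers(0, extra + 1)) if extra > 0 else 0
        start = max(1, w_start - left)
        end = min(len(seq), start + target - 1)
        start = max(1, end - target + 1)
        ms_rows.append(
            {
                "Sequence": seq[start - 1 : end],
                "Proteins": f"var|{mut.record.accession}|GN={v.gene_symbol}",
                "Reverse": "",
                "Potential contaminant": "",
            }
        )
    for _ in range(cfg.n_background_ms):
        rec = proteome[int(rng.integers(cfg.n_proteins))]
        length = int(rng.integers(ms_lo, min(ms_hi, len(rec.sequence)) + 1))
        start = int(rng.integers(0, len(rec.sequence) - length + 1))
        ms_rows.append(
            {
                "Sequence": rec.sequence[start : start + length],
                "Proteins": rec.accession,
                "Reverse": "",
                "Potential contaminant": "",
            }
        )
    # realistic junk rows the reader must drop
    ms_rows.append(
        {
            "Sequence": _random_seq(rng, 12),
            "Proteins": f"REV__{proteome[0].accession}",
            "Reverse": "+",
            "Potential contaminant": "",
        }
    )
    ms_rows.append(
        {
            "Sequence": contaminants[0].sequence[:10] if contaminants else _random_seq(rng, 10),
            "Proteins": contaminants[0].accession if contaminants else "CON__C00",
            "Reverse": "",
            "Potential contaminant": "+",
        }
    )
    ms_peptides = [
        MsIdentifiedPeptide(
            sequence=r["Sequence"],
            protein_accessions=tuple(r["Proteins"].split(";")),
            is_variant=r["Proteins"].startswith("var|"),
        )
        for r in ms_rows
        if r["Reverse"] != "+" and r["Potential contaminant"] != "+"
    ]

    # -- epitopes ------------------------------------------------------------
    rng = _rng(cfg.seed, _S_EPITOPES)
    ms_candidates: list[CandidateNeoantigen] = []
    for vid in ms_covered_ids:
        ms_candidates.extend(cand_by_variant[vid])
    planted_for = _sample(rng, ms_candidates, cfg.frac_planted_homologs)
    epitopes: list[EpitopeRecord] = []
    planted_homologs: dict[str, str] = {}
    for i, cand in enumerate(planted_for):
        if cand.peptide in planted_homologs:
            continue
        n_subs = int(rng.integers(1, cfg.homolog_max_substitutions + 1))
        positions: list[int] = []
        while len(positions) < n_subs:
            p = int(rng.integers(len(cand.peptide)))
            if all(abs(p - q) > 1 for q in positions):
                positions.append(p)
        seq = list(cand.peptide)
        for p in positions:
            alt = AA_ALPHABET[int(rng.integers(20))]
            while alt == seq[p]:
                alt = AA_ALPHABET[int(rng.integers(20))]
            seq[p] = alt
        eid = f"EP{i:04d}"
        epitopes.append(
            EpitopeRecord(
                epitope_id=eid,
                sequence="".join(seq),
                organism=_ORGANISMS[i % len(_ORGANISMS)],
            )
        )
        planted_homologs[cand.peptide] = eid
    for i in range(cfg.n_epitopes):
        epitopes.append(
            EpitopeRecord(
                epitope_id=f"ED{i:03d}",
                sequence=_random_seq(rng, int(rng.integers(9, 13))),
                organism=_ORGANISMS[i % len(_ORGANISMS)],
            )
        )

    # -- binding predictions -------------------------------------------------
    rng = _rng(cfg.seed, _S_PREDICTIONS)
    mock_seed = int(rng.integers(2**31))
    peptides = sorted({c.peptide for c in all_candidates})
    predictions = mock_predict(
        peptides,
        list(cfg.alleles),
        seed=mock_seed,
        fraction_binders=0.0,
        planted=planted_peptides,
    )

    # -- truth ledger --------------------------------------------------------
    def keys(cands: Sequence[CandidateNeoantigen]) -> list[list]:
        return sorted([c.peptide, c.mutation_offset] for c in cands)

    ms_set = set(ms_covered_ids)
    binding_expected = [c for vid in binder_variants for c in cand_by_variant[vid]]
    expr_expected = [c for c in binding_expected if c.variants[0].gene_symbol in expressed_genes]
    ms_expected = [c for c in expr_expected if c.variants[0].variant_id in ms_set]
    recog_expected = [c for c in ms_expected if c.peptide in planted_homologs]

    truth = {
        "seed": cfg.seed,
        "alleles": list(cfg.alleles),
        "binder_variants": binder_variants,
        "expressed_variants": expressed_variants,
        "ms_covered_variants": ms_covered_ids,
        "planted_binders": planted_peptides,
        "planted_homologs": planted_homologs,
        "expected": {
            "enumerated": keys(all_candidates),
            "binding": keys(enumeration.dedupe_candidates(binding_expected)),
            "expression": keys(enumeration.dedupe_candidates(expr_expected)),
            "ms_evidence": keys(enumeration.dedupe_candidates(ms_expected)),
            "recognizable": keys(enumeration.dedupe_candidates(recog_expected)),
        },
    }

    return SyntheticDataset(
        config=cfg,
        proteome=proteome,
        contaminants=contaminants,
        variants=variants,
        expression=expression,
        ms_peptides=ms_peptides,
        ms_rows=ms_rows,
        epitopes=epitopes,
        predictions=predictions,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write all artifacts in the exact dialects the readers consume.

    Returns a manifest with the eight input files plus the truth ledger path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    seqio.write_fasta(ds.proteome, out / "reference.fasta")
    inputs["reference_fasta"] = str(out / "reference.fasta")
    seqio.write_fasta(ds.contaminants, out / "contaminants.fasta")
    inputs["contaminants_fasta"] = str(out / "contaminants.fasta")

    with open(out / "variants.tsv", "w") as fh:
        fh.write("variant_id\tgene\tprotein_accession\tposition\tref_aa\talt_aa\tqual\n")
        for v in ds.variants:
            fh.write(
                f"{v.variant_id}\t{v.gene_symbol}\t{v.protein_accession}\t"
                f"{v.position}\t{v.ref_aa}\t{v.alt_aa}\t{v.qual}\n"
            )
    inputs["variants_table"] = str(out / "variants.tsv")

    with open(out / "abundance.tsv", "w") as fh:
        fh.write("target_id\tlength\teff_length\test_counts\ttpm\n")
        for rec in ds.expression:
            fh.write(f"{rec.target_id}\t1500\t1330.0\t{rec.tpm * 10:.1f}\t{rec.tpm}\n")
    inputs["expression_table"] = str(out / "abundance.tsv")

    with open(out / "t2g.tsv", "w") as fh:
        for rec in ds.expression:
            fh.write(f"{rec.target_id}\t{rec.gene_symbol}\n")
    inputs["t2g_table"] = str(out / "t2g.tsv")

    with open(out / "peptides.txt", "w") as fh:
        fh.write("Sequence\tProteins\tReverse\tPotential contaminant\n")
        for row in ds.ms_rows:
            fh.write(
                f"{row['Sequence']}\t{row['Proteins']}\t{row['Reverse']}\t"
                f"{row['Potential contaminant']}\n"
            )
    inputs["ms_peptides"] = str(out / "peptides.txt")

    with open(out / "epitopes.csv", "w") as fh:
        fh.write("Epitope ID,Description,Organism\n")
        for e in ds.epitopes:
            fh.write(f"{e.epitope_id},{e.sequence},{e.organism}\n")
    inputs["epitopes"] = str(out / "epitopes.csv")

    seqio.write_binding_table(ds.predictions, out / "predictions.tsv")
    inputs["predictions"] = str(out / "predictions.tsv")

    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)

    return {"inputs": inputs, "truth": str(out / "truth.json")}


def write_vcf(ds: SyntheticDataset, path: str | Path) -> Path:
    """Minimal VCF export of the variants' genomic SNV coordinates."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        contigs = sorted({v.genomic[0] for v in ds.variants if v.genomic})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = sorted(
            (v for v in ds.variants if v.genomic),
            key=lambda v: (v.genomic[0], v.genomic[1]),
        )
        for v in rows:
            chrom, pos, ref, alt = v.genomic
            fh.write(f"{chrom}\t{pos}\t{v.variant_id}\t{ref}\t{alt}\t{v.qual}\t.\t.\n")
    return path
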