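"""Readers and writers for every external format the funnel touches.

FASTA (UniProt and generic dialects), annotated missense-variant tables
(simple or Annovar-style), minimal SNV VCFs, kallisto ``abundance.tsv``
expression tables, MaxQuant ``peptides.txt`` peptide lists, IEDB-style epitope
CSV/FASTA exports, and NetMHCpan-4.0-style binding tables.  Everything is
normalized into the frozen dataclasses of :mod:`neofunnel.types`.
"""
from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .types import (
    AA_SET,
    CONTAMINANT_PREFIX,
    DECOY_PREFIX,
    VARIANT_PREFIX,
    BindingPrediction,
    EpitopeRecord,
    ExpressionRecord,
    MissenseVariant,
    MsIdentifiedPeptide,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

_GN_RE = re.compile(r"(?:^|\s|\|)GN=([^\s|]+)")
_SUBSTITUTION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_AACHANGE_RE = re.compile(r"p\.([A-Z])(\d+)([A-Z*])")
_ALLELE_RE = re.compile(r"^(?:HLA[-*]?)?([A-Z]+\d?)\*?(\d{2,3}):?(\d{2})$")


# ---------------------------------------------------------------------------
# FASTA


def _parse_variant_token(token: str) -> tuple[str, MissenseVariant | None, str]:
    """Parse a ``var|<parent>_<ref><pos><alt>|GN=<gene>`` header token."""
    parts = token.split("|")
    accession = parts[1] if len(parts) > 1 and parts[1] else token
    gene = ""
    for part in parts[2:]:
        if part.startswith("GN="):
            gene = part[3:]
    variant = None
    if "_" in accession:
        parent, sub = accession.rsplit("_", 1)
        m = _SUBSTITUTION_RE.match(sub)
        if m:
            try:
                variant = MissenseVariant(
                    variant_id=accession,
                    gene_symbol=gene,
                    protein_accession=parent,
                    position=int(m.group(2)),
                    ref_aa=m.group(1),
                    alt_aa=m.group(3),
                )
            except ValueError:
                variant = None
    return accession, variant, gene


def _parse_header(header: str, default_source: str) -> dict:
    token = header.split()[0] if header.split() else ""
    rest = header[len(token):].strip()
    gn = _GN_RE.search(header)
    gene = gn.group(1) if gn else ""
    description = _GN_RE.sub("", rest).strip()
    source = default_source
    accession = token
    variants: tuple[MissenseVariant, ...] = ()

    if not token:
        logger.warning("FASTA entry with empty header; using accession 'UNNAMED'")
        accession = "UNNAMED"
    elif token.startswith(VARIANT_PREFIX):
        source = "variant"
        accession, variant, vgene = _parse_variant_token(token)
        gene = gene or vgene
        if variant is not None:
            variants = (variant,)
        else:
            logger.warning("unparseable variant header %r; keeping raw token", token)
            accession = token
    elif token.startswith(DECOY_PREFIX):
        source = "decoy"
    elif token.startswith(CONTAMINANT_PREFIX):
        source = "contaminant"
    elif token.startswith(("sp|", "tr|")):
        parts = token.split("|")
        if len(parts) >= 3 and parts[1]:
            accession = parts[1]
            description = (parts[2] + " " + description).strip()
        else:
            logger.warning("malformed UniProt header %r; keeping raw token", token)
    return {
        "accession": accession,
        "gene_symbol": gene,
        "description": description,
        "source": source,
        "variants": variants,
    }


def read_fasta(path: str | Path, source: str = "reference") -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` entries.

    ``source`` is the default provenance class; entries whose accession carries
    a ``var|``/``REV__``/``CON__`` prefix override it.  Sequence bodies are
    uppercased.  An empty file is an error.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            fields = _parse_header(header, source)
            sequence = "".join(seq.split()).upper()
            rec = ProteinRecord(sequence=sequence, **fields)
            if rec.has_ambiguous:
                logger.warning("sequence %s contains ambiguous residue X", rec.accession)
            records.append(rec)
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            logger.warning("duplicate accession %s in %s", rec.accession, path)
        seen.add(rec.accession)
    return records


def format_header(record: ProteinRecord) -> str:
    """Render the FASTA header line (without '>') for a record.

    Variant records use the ``var|<parent>_<ref><pos><alt>|GN=<gene>``
    convention so that downstream variant-peptide detection is deterministic.
    """
    if record.source == "variant":
        header = f"{VARIANT_PREFIX}{record.accession}|GN={record.gene_symbol}"
        if record.description:
            header += f" {record.description}"
        return header
    parts = [record.accession]
    if record.description:
        parts.append(record.description)
    if record.gene_symbol:
        parts.append(f"GN={record.gene_symbol}")
    return " ".join(parts)


def write_fasta(
    records: Sequence[ProteinRecord], path: str | Path, line_width: int = 60
) -> Path:
    """Write records as FASTA; round-trips through :func:`read_fasta`."""
    if not records:
        raise ValueError("refusing to write an empty FASTA database")
    path = Path(path)
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{format_header(rec)}\n")
            for i in range(0, len(rec.sequence), line_width):
                out.write(rec.sequence[i : i + line_width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Variant tables

_SIMPLE_COLUMNS = ("variant_id", "gene", "protein_accession", "position", "ref_aa", "alt_aa")


def _require_columns(df: pd.DataFrame, names: Iterable[str], path) -> None:
    for name in names:
        if name not in df.columns:
            raise ValueError(f"{path}: missing required column {name!r}")


def _pick_column(df: pd.DataFrame, options: Sequence[str]) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for opt in options:
        if opt.lower() in lower:
            return lower[opt.lower()]
    return None


def read_variant_table(
    path: str | Path, dialect: str = "simple"
) -> list[MissenseVariant]:
    """Read an annotated missense-variant table (TSV with header).

    ``simple`` dialect columns: variant_id, gene, protein_accession, position,
    ref_aa, alt_aa[, qual].  ``annovar`` dialect parses
    ``GENE:TRANSCRIPT:exonN:c.X:p.<ref><pos><alt>`` amino-acid-change strings
    and keeps only rows whose exonic function is a nonsynonymous SNV.
    Synonymous rows are dropped with a warning in both dialects.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    variants: list[MissenseVariant] = []

    if dialect == "simple":
        _require_columns(df, _SIMPLE_COLUMNS, path)
        for _, row in df.iterrows():
            ref, alt = row["ref_aa"].strip(), row["alt_aa"].strip()
            if ref == alt:
                logger.warning(
                    "dropping synonymous row %s (%s%s%s)",
                    row["variant_id"], ref, row["position"], alt,
                )
                continue
            qual = float(row["qual"]) if row.get("qual", "") not in ("", ".") else None
            variants.append(
                MissenseVariant(
                    variant_id=row["variant_id"],
                    gene_symbol=row["gene"],
                    protein_accession=row["protein_accession"],
                    position=int(row["position"]),
                    ref_aa=ref,
                    alt_aa=alt,
                    qual=qual,
                )
            )
        return variants

    if dialect != "annovar":
        raise ValueError(f"unknown variant-table dialect {dialect!r}")

    aachange_col = _pick_column(df, ("AAChange.refGene", "AAChange", "aa_change"))
    if aachange_col is None:
        raise ValueError(f"{path}: missing required column 'AAChange'")
    func_col = _pick_column(df, ("ExonicFunc.refGene", "ExonicFunc", "exonic_func"))
    qual_col = _pick_column(df, ("QUAL", "Qual", "qual"))
    id_col = _pick_column(df, ("variant_id", "ID"))

    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        if func_col is not None and not str(row[func_col]).startswith("nonsynonymous"):
            continue
        qual = None
        if qual_col and row[qual_col] not in ("", "."):
            qual = float(row[qual_col])
        base_id = row[id_col] if id_col else f"av{i:04d}"
        for ann in re.split(r"[,;]", str(row[aachange_col])):
            ann = ann.strip()
            if not ann:
                continue
            fields = ann.split(":")
            m = _AACHANGE_RE.search(ann)
            if m is None or len(fields) < 2:
                logger.warning("unparseable amino-acid change %r; skipped", ann)
                continue
            ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
            if ref == alt or alt == "*":
                logger.warning("dropping non-missense change %r", ann)
                continue
            accession = fields[1]
            if (accession, m.group(0)) in seen:
                continue
            seen.add((accession, m.group(0)))
            variants.append(
                MissenseVariant(
                    variant_id=str(base_id),
                    gene_symbol=fields[0],
                    protein_accession=accession,
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    qual=qual,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# VCF


def read_vcf_snvs(
    path: str | Path, qual_min: float = 20.0
) -> list[tuple[str, int, str, str, float]]:
    """Read single-nucleotide variants from a VCF, keeping QUAL strictly above
    ``qual_min`` (a call "higher than 20" passes; exactly 20 does not).

    Multi-allelic records are split into one tuple per alternate base; indels
    and rows with missing QUAL are skipped.  Returns
    ``(chrom, pos, ref_base, alt_base, qual)`` tuples.
    """
    import pysam

    out: list[tuple[str, int, str, str, float]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.qual is None:
                logger.warning("VCF row %s:%s has no QUAL; excluded", rec.chrom, rec.pos)
                continue
            if len(rec.ref) != 1 or rec.ref not in "ACGT":
                continue
            if rec.qual <= qual_min:
                continue
            for alt in rec.alts or ():
                if len(alt) != 1 or alt not in "ACGT":
                    continue
                out.append((rec.chrom, rec.pos, rec.ref, alt, float(rec.qual)))
    return out


# ---------------------------------------------------------------------------
# Expression


def read_expression(path: str | Path, t2g_path: str | Path) -> list[ExpressionRecord]:
    """Read a kallisto ``abundance.tsv`` plus a two-column transcript->gene map.

    Transcripts missing from the map are kept with an empty gene symbol and a
    warning; zero-TPM rows are retained (expression filtering is downstream).
    """
    df = pd.read_csv(path, sep="\t")
    if "tpm" not in df.columns:
        raise ValueError(f"{path}: missing required column 'tpm'")
    if "target_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'target_id'")

    t2g = pd.read_csv(t2g_path, sep="\t", header=None, dtype=str)
    if t2g.shape[1] < 2:
        raise ValueError(f"{t2g_path}: expected two tab-separated columns")
    if t2g.iloc[0, 0].lower() in ("target_id", "transcript"):
        t2g = t2g.iloc[1:]
    mapping = dict(zip(t2g.iloc[:, 0], t2g.iloc[:, 1]))

    records: list[ExpressionRecord] = []
    for _, row in df.iterrows():
        target = str(row["target_id"])
        gene = mapping.get(target, "")
        if not gene:
            logger.warning("transcript %s absent from t2g map; gene left empty", target)
        records.append(ExpressionRecord(target_id=target, tpm=float(row["tpm"]), gene_symbol=gene))
    return records


# ---------------------------------------------------------------------------
# MS peptides


def read_ms_peptides(path: str | Path) -> list[MsIdentifiedPeptide]:
    """Read a MaxQuant ``peptides.txt`` dialect (Sequence + Proteins columns).

    Decoy ("REV__") and contaminant ("CON__") rows, rows flagged '+' in the
    Reverse / Potential contaminant columns, and peptides shorter than 7
    residues are dropped.  ``is_variant`` is true iff any mapped accession
    carries the ``var|`` prefix.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("Sequence", "Proteins"), path)
    rev_col = _pick_column(df, ("Reverse",))
    con_col = _pick_column(df, ("Potential contaminant", "Contaminant"))

    peptides: list[MsIdentifiedPeptide] = []
    for _, row in df.iterrows():
        seq = row["Sequence"].strip().upper()
        accs = tuple(a for a in row["Proteins"].split(";") if a)
        if rev_col and row[rev_col].strip() == "+":
            continue
        if con_col and row[con_col].strip() == "+":
            continue
        if any(a.startswith(DECOY_PREFIX) or a.startswith(CONTAMINANT_PREFIX) for a in accs):
            continue
        if len(seq) < 7:
            logger.warning("dropping MS peptide %r shorter than 7 aa", seq)
            continue
        peptides.append(
            MsIdentifiedPeptide(
                sequence=seq,
                protein_accessions=accs,
                is_variant=any(a.startswith(VARIANT_PREFIX) for a in accs),
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# Epitopes


def read_epitopes(path: str | Path) -> list[EpitopeRecord]:
    """Read a linear-epitope set from an IEDB-style CSV or a FASTA file.

    CSV needs a Description or Sequence column; optional Epitope ID and
    Organism columns are honored.  Entries containing characters outside the
    20-letter alphabet (chemical modifications etc.) are dropped with a
    warning.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break

    records: list[EpitopeRecord] = []
    if text_head.startswith(">"):
        with open(path) as handle:
            for i, (header, seq) in enumerate(SimpleFastaParser(handle)):
                token = header.split()[0] if header.split() else f"epi{i}"
                rest = header[len(token):].strip()
                seq = seq.strip().upper()
                if not seq or not set(seq) <= AA_SET:
                    logger.warning("dropping non-linear epitope %r", header)
                    continue
                records.append(EpitopeRecord(epitope_id=token, sequence=seq, organism=rest))
        return records

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    seq_col = _pick_column(df, ("Description", "Sequence", "peptide"))
    if seq_col is None:
        raise ValueError(f"{path}: no recognizable sequence column (Description/Sequence)")
    id_col = _pick_column(df, ("Epitope ID", "epitope_id", "ID"))
    org_col = _pick_column(df, ("Organism", "Organism Name", "Source Organism"))
    for i, row in df.iterrows():
        seq = row[seq_col].strip().upper()
        if not seq or not set(seq) <= AA_SET:
            logger.warning("dropping epitope row %d with non-linear sequence %r", i, row[seq_col])
            continue
        records.append(
            EpitopeRecord(
                epitope_id=str(row[id_col]) if id_col else f"epi{i}",
                sequence=seq,
                organism=row[org_col] if org_col else "",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Binding predictions


def normalize_allele(allele: str) -> str:
    """Normalize an HLA allele string to the four-digit ``HLA-A*03:01`` form.

    Accepts the styles seen in the wild: ``HLA-A*03:01``, ``HLA-A03:01``,
    ``HLA*A03:01``, ``A0301``.
    """
    compact = allele.replace(" ", "")
    m = _ALLELE_RE.match(compact)
    if m is None:
        raise ValueError(f"unrecognized HLA allele {allele!r}")
    gene, group, protein = m.groups()
    return f"HLA-{gene}*{group}:{protein}"


def read_binding_table(
    path: str | Path, dialect: str = "simple"
) -> list[BindingPrediction]:
    """Read binding predictions from a simple TSV or NetMHCpan-4.0 output.

    ``simple``: TSV with peptide/allele/percent_rank (optional ic50) columns.
    ``netmhcpan``: whitespace-delimited prediction lines, %Rank column located
    from the header line when present.  Alleles are normalized; an
    unparseable or negative %Rank raises with the offending line number.
    """
    path = Path(path)
    preds: list[BindingPrediction] = []

    if dialect == "simple":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(df, ("peptide", "allele", "percent_rank"), path)
        ic50_col = _pick_column(df, ("ic50", "ic50_nM", "Aff(nM)"))
        for i, row in df.iterrows():
            try:
                rank = float(row["percent_rank"])
            except ValueError as exc:
                raise ValueError(f"{path} line {i + 2}: unparseable %Rank "
                                 f"{row['percent_rank']!r}") from exc
            if rank < 0:
                raise ValueError(f"{path} line {i + 2}: negative %Rank {rank}")
            ic50 = None
            if ic50_col and row[ic50_col] not in ("", "."):
                ic50 = float(row[ic50_col])
            preds.append(
                BindingPrediction(
                    peptide=row["peptide"].strip().upper(),
                    allele=normalize_allele(row["allele"]),
                    percent_rank=rank,
                    ic50_nM=ic50,
                )
            )
        return preds

    if dialect != "netmhcpan":
        raise ValueError(f"unknown binding-table dialect {dialect!r}")

    rank_idx: int | None = None
    pep_idx, allele_idx = 2, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if "Peptide" in tokens and any(t.startswith("%Rank") for t in tokens):
                pep_idx = tokens.index("Peptide")
                allele_idx = next(
                    (tokens.index(t) for t in ("HLA", "MHC", "Allele") if t in tokens), 1
                )
                rank_idx = next(i for i, t in enumerate(tokens) if t.startswith("%Rank"))
                continue
            if not tokens[0].isdigit() or len(tokens) <= max(pep_idx, allele_idx):
                continue
            idx = rank_idx if rank_idx is not None else 12
            if len(tokens) <= idx:
                raise ValueError(f"{path} line {lineno}: unparseable %Rank (short line)")
            try:
                rank = float(tokens[idx])
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno}: unparseable %Rank {tokens[idx]!r}"
                ) from exc
            if rank < 0:
                raise ValueError(f"{path} line {lineno}: negative %Rank {rank}")
            preds.append(
                BindingPrediction(
                    peptide=tokens[pep_idx].upper(),
                    allele=normalize_allele(tokens[allele_idx]),
                    percent_rank=rank,
                )
            )
    return preds


def write_binding_table(preds: Sequence[BindingPrediction], path: str | Path) -> Path:
    """Write predictions as the simple TSV dialect, sorted for stable diffs."""
    path = Path(path)
    rows = sorted(preds, key=lambda p: (p.peptide, p.allele))
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide", "allele", "percent_rank", "ic50"])
        for p in rows:
            writer.writerow(
                [p.peptide, p.allele, f"{p.percent_rank:.4f}",
                 "" if p.ic50_nM is None else f"{p.ic50_nM:.1f}"]
            )
    return path
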