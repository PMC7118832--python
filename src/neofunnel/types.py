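"""Core domain records shared by every stage of the neoantigen funnel.

All records are frozen dataclasses validated on construction.  Sequences are
uppercase strings over the 20-letter amino-acid alphabet; ``X`` is admitted in
protein records (flagged via :attr:`ProteinRecord.has_ambiguous`) but rejected
wherever a substitution score would be undefined.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)

#: Allowed provenance classes for a protein database entry.
SOURCES = ("reference", "contaminant", "variant", "decoy")

#: Prefix conventions used in search databases (MaxQuant-style).
DECOY_PREFIX = "REV__"
CONTAMINANT_PREFIX = "CON__"
VARIANT_PREFIX = "var|"


@dataclass(frozen=True)
class MissenseVariant:
    """A single annotated amino-acid substitution in protein coordinates.

    ``position`` is 1-based into the parent protein sequence.  ``qual`` is the
    phred-scaled call quality of the underlying SNV when known.  ``genomic``
    optionally carries the originating (chrom, pos, ref_base, alt_base).
    """

    variant_id: str
    gene_symbol: str
    protein_accession: str
    position: int
    ref_aa: str
    alt_aa: str
    qual: float | None = None
    genomic: tuple[str, int, str, str] | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for name, aa in (("ref_aa", self.ref_aa), ("alt_aa", self.alt_aa)):
            if len(aa) != 1 or aa not in AA_SET:
                raise ValueError(f"{name} must be one amino-acid letter, got {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"synonymous change {self.ref_aa}{self.position}{self.alt_aa} "
                "is not a missense variant"
            )

    @property
    def substitution(self) -> str:
        """Compact ``<ref><pos><alt>`` notation, e.g. ``Q61K``."""
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry of the search database (reference/contaminant/variant/decoy)."""

    accession: str
    sequence: str
    gene_symbol: str = ""
    description: str = ""
    source: str = "reference"
    #: provenance for source == "variant"; may hold >1 entry after sequence-level
    #: deduplication of distinct variants that yield the same mutant protein.
    variants: tuple[MissenseVariant, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "variant" and not self.variants:
            raise ValueError(f"variant record {self.accession} lacks provenance")

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionRecord:
    """One transcript abundance row (kallisto dialect), resolved to a gene."""

    target_id: str
    tpm: float
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError(f"negative TPM for {self.target_id}")


@dataclass(frozen=True)
class MsIdentifiedPeptide:
    """A peptide identified by the MS search engine (MaxQuant peptides.txt row)."""

    sequence: str
    protein_accessions: tuple[str, ...]
    is_variant: bool

    def __post_init__(self) -> None:
        if len(self.sequence) < 7:
            raise ValueError(f"MS peptide shorter than 7 aa: {self.sequence!r}")


@dataclass(frozen=True)
class EpitopeRecord:
    """A linear T-cell epitope (e.g. an IEDB cross-reactive microbial peptide)."""

    epitope_id: str
    sequence: str
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty epitope sequence for {self.epitope_id}")


class BinderClass(enum.Enum):
    """MHC-I percentile-rank binder classes (NetMHCpan convention)."""

    STRONG = "strong"
    WEAK = "weak"
    NON_BINDER = "non_binder"


@dataclass(frozen=True)
class BindingPrediction:
    """A (peptide, HLA allele, %Rank) prediction; IC50 parsed but never used."""

    peptide: str
    allele: str
    percent_rank: float
    ic50_nM: float | None = None

    def __post_init__(self) -> None:
        if self.percent_rank < 0:
            raise ValueError(
                f"negative %Rank {self.percent_rank} for {self.peptide}/{self.allele}"
            )


@dataclass(frozen=True)
class MutantProtein:
    """A reference protein with exactly one amino-acid substitution applied."""

    record: ProteinRecord
    parent_accession: str
    variant: MissenseVariant


@dataclass(frozen=True)
class PeptideWindow:
    """Mutation-centered window (<= 2*flank+1 residues) of a mutant protein.

    ``mutation_offset`` is the 1-based position of the substituted residue
    within the window; ``protein_start`` the 1-based start of the window in the
    parent protein.  Windows shorter than the full width arise near termini.
    """

    sequence: str
    mutation_offset: int
    protein_start: int
    variant: MissenseVariant
    window_ref: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.mutation_offset <= len(self.sequence):
            raise ValueError("mutation_offset outside window")
        if self.sequence[self.mutation_offset - 1] != self.variant.alt_aa:
            raise ValueError(
                f"window residue at offset {self.mutation_offset} is not the "
                f"alternate amino acid {self.variant.alt_aa}"
            )


@dataclass(frozen=True)
class CandidateNeoantigen:
    """An 8-11-mer spanning the mutated residue, with provenance."""

    peptide: str
    mutation_offset: int
    variants: tuple[MissenseVariant, ...]
    window_ref: str = ""

    def __post_init__(self) -> None:
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(f"candidate length {len(self.peptide)} outside 8-11")
        if not 1 <= self.mutation_offset <= len(self.peptide):
            raise ValueError("mutation_offset outside peptide")
        if not self.variants:
            raise ValueError("candidate lacks provenance")
        alt = self.peptide[self.mutation_offset - 1]
        for v in self.variants:
            if v.alt_aa != alt:
                raise ValueError(
                    f"provenance {v.substitution} inconsistent with residue {alt}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide, self.mutation_offset)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.gene_symbol)
        return tuple(seen)


#: Similarity-score bins used to report the cross-reactivity screen.
SIMILARITY_BINS = ("20-39", "40-59", "60-79", "80-100")


@dataclass(frozen=True)
class SimilarityHit:
    """Best local-alignment similarity of a candidate against one epitope."""

    peptide: str
    epitope_id: str
    score: float
    identities: int
    alignment_length: int
    raw_sw_score: int
    aligned_query: str = ""
    aligned_subject: str = ""
    bin: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"similarity score {self.score} outside [0, 100]")
        if self.identities > self.alignment_length:
            raise ValueError("identities exceed alignment length")
        if self.bin is not None and self.bin not in SIMILARITY_BINS:
            raise ValueError(f"unknown bin {self.bin!r}")
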