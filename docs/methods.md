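# Methods

## Model and assumptions

`neofunnel` treats neoantigen discovery as a deterministic attrition funnel
over candidate peptides.  The underlying assumptions are the standard ones
for MHC class I:

* a somatic missense SNV produces exactly one single amino acid variant
  (SAAV) in each protein isoform it hits; insertions, deletions, frameshifts,
  fusion products and noncoding antigens are out of scope;
* MHC-I ligands are 8–11 residues, so every candidate is an 8–11-mer whose
  span covers the substituted residue — a peptide not covering the mutation
  is wild type and carries no tumor specificity;
* presentation requires transcription, so a candidate from a gene with zero
  transcript abundance cannot be a neoantigen;
* an MS-identified variant peptide containing the candidate is direct
  protein-level evidence of expression;
* sequence similarity to microbial epitopes already recognized by human T
  cells is a proxy for TCR recognizability: the T-cell repertoire is shaped
  by infection, and cross-reactive recognition of tumor peptides homologous
  to pathogen epitopes is documented.

Upstream tools (read alignment, variant calling, annotation, transcript
quantification, HLA typing, the binding predictor's neural network, the MS
search engine) are consumed through their file formats, never re-run or
re-implemented; the funnel is exactly the part between their outputs and a
ranked candidate list.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `qual_min` | 20 | phred-scaled SNV call quality; strictly greater-than (a QUAL of exactly 20 is rejected) |
| `flank` | 10 | residues on each side of the substitution; windows are ≤ 21-mers |
| `lengths` | 8–11 | candidate ligand lengths |
| `t_strong`, `t_weak` | 0.5, 2.0 | percentile-rank cuts; both boundaries inclusive on the stronger class |
| TPM cut | 0 (exclusive) | a gene is expressed iff any transcript's TPM > 0 |
| `min_similarity` | 20 | screen threshold on the 0–100 similarity scale |
| matrix, gaps | BLOSUM62, 11/1 | protein-alignment defaults; gap of length g costs 11 + g |

Selection uses percentile rank, never IC50: rank normalizes away the
per-allele bias in predicted affinities, and IC50 is therefore parsed but
ignored.

## The similarity score

The screen reports `100 · identities(best local alignment) / |candidate|`.
Alternatives (percent identity over the aligned span, normalized bit score)
were considered; the chosen definition makes a self-hit exactly 100,
produces the full closed range down to low scores (a 2-identity patch on a
9-mer scores 22.2), and cannot be inflated by a short perfect local match.
It is one function (`similarity_score`) and is swappable.

The aligner maximizes the pair (raw Smith–Waterman score, identities)
lexicographically by packing both into a single integer (64·score +
identity-per-matched-column; identities at peptide scale never reach 64), so
"highest-identity among co-optimal alignments" is computed by an ordinary
additive dynamic program rather than by enumerating tracebacks.  Remaining
ties break to the earliest start in the query, then the subject.  A
vectorized batch version of the same recurrence (scores and identities only,
no traceback) handles the candidate × epitope cross product; the scalar and
batch paths are asserted equal in the tests, and the scalar path is checked
against an independent aligner and a hand-written DP oracle.  No E-values:
with 8–11-mer queries, extreme-value statistics are unreliable and the
screen is a fixed-threshold classifier, not a search.

## Synthetic data: what it emulates, what it does not

The generator emulates the pipeline's external inputs at toy scale: a
uniform-composition proteome (50 proteins of 60–120 residues by default),
100 missense variants at distinct sites with the reference residue read from
the protein, a per-transcript TPM table with one transcript per gene, a
search-engine peptide list with decoy/contaminant rows, an epitope CSV, and
a per-allele prediction table over five common HLA-A/B/C alleles.

Planted facts make every stage's expected output computable by set algebra
rather than by re-running the filters:

* **binders** are planted at the variant level — every candidate of a
  planted variant (default fraction 0.5) is forced strong on one allele and
  everything else is a non-binder — so binding-stage survivors are exactly
  the planted set;
* **expression** zeroes the TPM of exactly the unexpressed variant genes
  (default 40%);
* **detected variant peptides** span the candidate's full mutation window
  (lengths 21–43, inside the 7–43 range a tryptic search reports), so MS
  containment retains precisely the candidates of MS-covered variants.
  Background wild-type peptides are random substrings, not tryptic digests:
  enzyme specificity lives upstream in the search engine and is irrelevant
  to substring containment;
* **epitope homologs** are copies of MS-covered candidates with at most two
  substitutions placed at non-adjacent positions.  Non-adjacency matters: it
  guarantees no terminal segment of the alignment has a negative score, so
  the optimal local alignment never trims an identity and a 9-mer homolog
  provably scores ≥ 77 (7/9), far above the screen threshold.  Random decoy
  epitopes are added on top; with the default homolog fraction of 1.0 they
  cannot change the recognizable set.

Each stage draws from its own RNG substream keyed by (seed, stage), so
changing one fraction leaves the other stages' draws untouched, and
regeneration with the same seed is byte-identical.

What passing the end-to-end tests shows: the funnel's set semantics,
ordering, thresholds and file dialects are exactly as specified.  What it
does not show: performance on real data — real proteomes are not uniform
random (so wild-type collisions and homology are more common), real binding
ranks are correlated with peptide chemistry, and real MS detection is biased
by abundance and tryptic context.  The saturated similarity screen in the
default run (everything in the 80–100 bin) is the planted truth, not a
property of real epitope sets.

## Numerical and design choices

* Windows at protein termini are truncated, never padded or discarded; a
  mutation at position 1 still yields candidates.
* One mutant protein per variant; co-occurring variants on one protein are
  not phased into haplotypes.
* A variant whose accession is missing falls back to every isoform of its
  gene whose residue matches; a reference mismatch skips with a warning by
  default (annotation/proteome version skew is routine) and can be promoted
  to an error.
* Duplicate mutant sequences (distinct calls of the same substitution)
  merge with combined provenance.
* Candidate identity is (peptide, mutation offset), so the same string from
  different substitution geometries is tracked separately; provenance merges
  on deduplication.
* The optional wild-type-collision filter (drop candidates occurring
  verbatim in the reference proteome) is off by default.
* MS matching is exact substring containment; an I/L-equivalence mode exists
  because CID spectra cannot distinguish the isobaric pair, but is off by
  default.
* Stage counts chain and are monotone non-increasing from the enumeration
  output onward; the database/window stages count variants and windows, and
  enumeration is by nature an expansion (one window → up to 38 candidates),
  so the candidate funnel begins at its output.
* Percentages are formatted round-half-up to two decimals; all output tables
  are sorted (peptide, then allele) so reruns diff clean.
* Similarity bins are `[20,40) [40,60) [60,80) [80,100]`, labels with ASCII
  hyphens.

## Problem sizes

Defaults everywhere were chosen so a full generate-plus-run cycle is a few
seconds on one core: 50 proteins × ~90 residues, 100 variants, ~3,400
candidates, five alleles (~17,000 prediction rows), and a few hundred
epitopes in the screen.  These sizes exercise every code path including
deduplication, terminal truncation, and all four similarity bins' boundary
logic, while keeping the full test suite under half a minute.

## Known limitations

* No indel/frameshift/fusion peptides; no MHC class II (longer ligands,
  weaker predictors).
* The screen's similarity definition is an interpretation of
  "blastp-measured similarity"; other definitions are one function away.
* Expression granularity is gene-level (any transcript, or sum); no
  isoform-aware matching of variants to the transcripts that carry them.
* The mock predictor is a plumbing surrogate with no biochemical content;
  real studies must supply predictor output files.
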