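"""End-to-end funnel orchestration and the stage-count report.

The funnel executes, in order: customized database construction, window
extraction, candidate enumeration, binder classification/selection, the
RNA-expression filter, the MS-evidence filter, and the cross-reactivity
similarity screen.  Individual filter stages are skippable so the pipeline
can run on whatever data types are available.  Counts are reported per stage;
from the enumeration output onward the funnel is measured in candidates and
is monotone non-increasing (the database/window/enumeration stages count
variants and windows, and enumeration is by nature an expansion step).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

from . import binding, crossreact, enumeration, filters, mutantdb, seqio
from .crossreact import AlignmentParams
from .synthdata import DEFAULT_ALLELES
from .types import BindingPrediction, CandidateNeoantigen, SimilarityHit

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (so 47.785 prints as 47.79, not banker's 47.78)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    unit: str = "candidates"
    params: dict = field(default_factory=dict)
    skipped: bool = False

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_removed": self.n_removed,
            "unit": self.unit,
            "params": self.params,
            "skipped": self.skipped,
        }


@dataclass
class FunnelReport:
    stages: list[StageResult] = field(default_factory=list)
    per_allele: dict[str, int] = field(default_factory=dict)
    shared_peptides: int = 0
    binder_classes: dict[str, int] = field(default_factory=dict)
    similarity_bins: dict[str, int] = field(default_factory=dict)
    comparison_probability: float = 0.0

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "per_allele": self.per_allele,
            "shared_peptides": self.shared_peptides,
            "binder_classes": self.binder_classes,
            "similarity_bins": self.similarity_bins,
            "comparison_probability": self.comparison_probability,
        }


@dataclass
class PipelineResult:
    report: FunnelReport
    candidates_by_stage: dict[str, list[CandidateNeoantigen]] = field(default_factory=dict)
    hits: list[SimilarityHit] = field(default_factory=list)
    predictions: list[BindingPrediction] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Inputs, thresholds, and skips for one funnel run.

    All thresholds default to the study conventions: QUAL strictly above 20
    upstream, 10-residue flanks, 8-11-mer ligands, strong/weak %Rank cuts at
    0.5/2.0, exclusive 0-TPM expression cut, similarity threshold 20 with
    BLOSUM62 and gap open/extend 11/1.
    """

    reference_fasta: str = ""
    variants_table: str = ""
    contaminants_fasta: str | None = None
    variants_dialect: str = "simple"
    expression_table: str | None = None
    t2g_table: str | None = None
    ms_peptides: str | None = None
    epitopes: str | None = None
    predictions: str | None = None
    predictions_dialect: str = "simple"
    alleles: tuple[str, ...] = DEFAULT_ALLELES
    use_mock_predictor: bool = False
    mock_seed: int = 0
    mock_fraction_binders: float = 0.2
    out_dir: str | None = None

    flank: int = 10
    lengths: tuple[int, ...] = (8, 9, 10, 11)
    t_strong: float = 0.5
    t_weak: float = 2.0
    min_similarity: float = 20.0
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    on_mismatch: str = "skip"
    expression_mode: str = "gene_any_transcript"
    require_variant_ms: bool = True
    il_equivalent: bool = False
    remove_wildtype: bool = False

    skip_binding: bool = False
    skip_expression: bool = False
    skip_ms: bool = False
    skip_screen: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for name in ("alleles", "lengths"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                object.__setattr__(cfg, name, tuple(val))
        return cfg


def _require(config: PipelineConfig, attr: str, stage: str) -> str:
    value = getattr(config, attr)
    if not value:
        raise PipelineError(f"stage {stage!r}: missing required input {attr!r}")
    return value


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the funnel; returns the report plus per-stage candidate sets."""
    report = FunnelReport()
    result = PipelineResult(report=report)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: customized database ---------------------------------------
    reference = seqio.read_fasta(_require(config, "reference_fasta", "build_db"))
    contaminants = (
        seqio.read_fasta(config.contaminants_fasta, source="contaminant")
        if config.contaminants_fasta
        else []
    )
    variants = seqio.read_variant_table(
        _require(config, "variants_table", "build_db"), dialect=config.variants_dialect
    )
    custom_db = mutantdb.build_custom_db(
        reference, contaminants, variants, on_mismatch=config.on_mismatch
    )
    variant_records = [r for r in custom_db if r.source == "variant"]
    report.stages.append(
        StageResult(
            "build_db",
            n_in=len(variants),
            n_out=len(variant_records),
            unit="variants",
            params={"n_reference": len(reference), "n_contaminants": len(contaminants)},
        )
    )
    if out_dir:
        seqio.write_fasta(custom_db, out_dir / "custom_db.fasta")

    # -- stage 2: windows ----------------------------------------------------
    mutants = mutantdb.apply_variants(reference, variants, on_mismatch=config.on_mismatch)
    windows = mutantdb.extract_windows(mutants, flank=config.flank)
    report.stages.append(
        StageResult(
            "windows",
            n_in=len(mutants),
            n_out=len(windows),
            unit="windows",
            params={"flank": config.flank},
        )
    )

    # -- stage 3: enumeration ------------------------------------------------
    candidates = enumeration.enumerate_all(windows, lengths=config.lengths)
    if config.remove_wildtype:
        candidates = enumeration.remove_wildtype_matches(candidates, reference)
    candidates.sort(key=lambda c: c.key)
    report.stages.append(
        StageResult(
            "enumerate",
            n_in=len(windows),
            n_out=len(candidates),
            unit="windows -> candidates",
            params={
                "lengths": list(config.lengths),
                "remove_wildtype": config.remove_wildtype,
            },
        )
    )
    result.candidates_by_stage["enumerate"] = candidates
    if out_dir:
        enumeration.write_candidates_tsv(candidates, out_dir / "candidates.tsv")
        enumeration.write_peptide_list(candidates, out_dir / "peptide_list.txt")
    current = candidates

    # -- stage 4: binding classification ------------------------------------
    if config.skip_binding:
        report.stages.append(
            StageResult("binding", len(current), len(current), skipped=True)
        )
    else:
        if config.predictions:
            predictions = seqio.read_binding_table(
                config.predictions, dialect=config.predictions_dialect
            )
        elif config.use_mock_predictor:
            predictions = binding.mock_predict(
                sorted({c.peptide for c in current}),
                list(config.alleles),
                seed=config.mock_seed,
                fraction_binders=config.mock_fraction_binders,
            )
        else:
            raise PipelineError(
                "stage 'binding': missing required input 'predictions' "
                "(or set use_mock_predictor / skip_binding)"
            )
        wanted = {c.peptide for c in current}
        predictions = [p for p in predictions if p.peptide in wanted]
        result.predictions = predictions
        keep = binding.binder_peptides(predictions, config.t_strong, config.t_weak)
        retained = [c for c in current if c.peptide in keep]
        report.per_allele, report.shared_peptides = binding.per_allele_summary(
            predictions, config.t_strong, config.t_weak
        )
        report.binder_classes = binding.count_by_class(
            predictions, config.t_strong, config.t_weak
        )
        report.stages.append(
            StageResult(
                "binding",
                n_in=len(current),
                n_out=len(retained),
                params={"t_strong": config.t_strong, "t_weak": config.t_weak},
            )
        )
        if out_dir:
            seqio.write_binding_table(
                binding.select_binders(predictions, config.t_strong, config.t_weak),
                out_dir / "binders.tsv",
            )
        current = retained
    result.candidates_by_stage["binding"] = current

    # -- stage 5: expression filter ------------------------------------------
    if config.skip_expression:
        report.stages.append(
            StageResult("expression", len(current), len(current), skipped=True)
        )
    else:
        expr_path = _require(config, "expression_table", "expression")
        t2g_path = _require(config, "t2g_table", "expression")
        expression = seqio.read_expression(expr_path, t2g_path)
        current, expr_report = filters.filter_by_expression(
            current, expression, mode=config.expression_mode
        )
        report.stages.append(
            StageResult(
                "expression",
                n_in=expr_report["n_in"],
                n_out=expr_report["n_out"],
                params=expr_report["params"] | {"removed": expr_report["removed"]},
            )
        )
    result.candidates_by_stage["expression"] = current
    if out_dir:
        enumeration.write_candidates_tsv(current, out_dir / "after_expression.tsv")

    # -- stage 6: MS evidence filter ------------------------------------------
    if config.skip_ms:
        report.stages.append(
            StageResult("ms_evidence", len(current), len(current), skipped=True)
        )
    else:
        ms_path = _require(config, "ms_peptides", "ms_evidence")
        ms = seqio.read_ms_peptides(ms_path)
        current, ms_report = filters.filter_by_ms_evidence(
            current,
            ms,
            require_variant_flag=config.require_variant_ms,
            il_equivalent=config.il_equivalent,
        )
        report.stages.append(
            StageResult(
                "ms_evidence",
                n_in=ms_report["n_in"],
                n_out=ms_report["n_out"],
                params=ms_report["params"],
            )
        )
    result.candidates_by_stage["ms_evidence"] = current
    if out_dir:
        enumeration.write_candidates_tsv(current, out_dir / "after_ms.tsv")

    # -- stage 7: similarity screen -------------------------------------------
    if config.skip_screen:
        report.stages.append(
            StageResult("similarity_screen", len(current), len(current), skipped=True)
        )
        recognizable: list[CandidateNeoantigen] = current
    else:
        epi_path = _require(config, "epitopes", "similarity_screen")
        epitopes = seqio.read_epitopes(epi_path)
        params = AlignmentParams(
            matrix_name=config.matrix_name,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
        screen = crossreact.screen_candidates(
            current, epitopes, params=params, min_score=config.min_similarity
        )
        result.hits = screen.hits
        recog_peps = screen.recognizable_peptides
        recognizable = [c for c in current if c.peptide in recog_peps]
        report.similarity_bins = crossreact.bin_scores(screen.recognizable)
        report.comparison_probability = screen.comparison_probability
        report.stages.append(
            StageResult(
                "similarity_screen",
                n_in=len(current),
                n_out=len(recognizable),
                params={
                    "min_score": config.min_similarity,
                    "matrix": config.matrix_name,
                    "gap_open": config.gap_open,
                    "gap_extend": config.gap_extend,
                    "n_epitopes": len(epitopes),
                },
            )
        )
        if out_dir:
            _write_hits(screen.hits, out_dir / "similarity_hits.tsv")
    result.candidates_by_stage["similarity_screen"] = recognizable

    _validate_report(report)
    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        (out_dir / "summary.txt").write_text(funnel_summary(report))
    return result


def _write_hits(hits: Sequence[SimilarityHit], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "peptide\tepitope_id\tscore\tidentities\talignment_length\t"
            "raw_sw_score\tbin\n"
        )
        for h in sorted(hits, key=lambda h: h.peptide):
            fh.write(
                f"{h.peptide}\t{h.epitope_id}\t{h.score:.2f}\t{h.identities}\t"
                f"{h.alignment_length}\t{h.raw_sw_score}\t{h.bin or ''}\n"
            )


def _validate_report(report: FunnelReport) -> None:
    """Candidate-stage counts must chain and be non-increasing."""
    cand_stages = [s for s in report.stages if s.unit == "candidates"]
    prev: StageResult | None = None
    for s in cand_stages:
        if s.n_out > s.n_in:
            raise AssertionError(f"stage {s.name}: n_out {s.n_out} > n_in {s.n_in}")
        if prev is not None and s.n_in != prev.n_out:
            raise AssertionError(
                f"stage {s.name}: n_in {s.n_in} != previous n_out {prev.n_out}"
            )
        prev = s


def funnel_summary(report: FunnelReport) -> str:
    """Human-readable stage table with attrition percentages."""
    header = f"{'stage':<20}{'in':>10}{'out':>10}{'removed':>10}{'attrition%':>12}"
    lines = [header]
    for s in report.stages:
        tag = " (skipped)" if s.skipped else ""
        if s.unit != "candidates" or s.n_in == 0:
            lines.append(f"{s.name:<20}{s.n_in:>10}{s.n_out:>10}{'':>10}{'-':>12}{tag}")
            continue
        att = percent(s.n_removed, s.n_in)
        lines.append(
            f"{s.name:<20}{s.n_in:>10}{s.n_out:>10}{s.n_removed:>10}{att:>12.2f}{tag}"
        )
    if report.similarity_bins:
        lines.append("")
        lines.append(
            "similarity bins: "
            + "  ".join(f"{k}:{v}" for k, v in report.similarity_bins.items())
        )
    if report.stages and not report.stages[-1].skipped:
        lines.append(
            f"comparison probability: "
            f"{round_half_up(report.comparison_probability, 2):.2f}%"
        )
    return "\n".join(lines) + "\n"
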