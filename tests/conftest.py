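"""Shared fixtures: tiny deterministic records and one full synthetic run."""
from __future__ import annotations

import pytest

from neofunnel import synthdata
from neofunnel.pipeline import PipelineConfig, run_pipeline
from neofunnel.types import MissenseVariant, ProteinRecord


@pytest.fixture
def tiny_reference() -> list[ProteinRecord]:
    return [
        ProteinRecord("P0001", "MTEYKLVVVGAGGVGKSALTIQLIQNHFVDEY", gene_symbol="G1"),
        ProteinRecord("P0002", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL", gene_symbol="G2"),
        ProteinRecord("P0003", "MKLVWAAEQRSTNDCYFGHPILMKV", gene_symbol="G3"),
    ]


@pytest.fixture
def tiny_variant() -> MissenseVariant:
    # position 17 of P0001 holds S
    return MissenseVariant("v1", "G1", "P0001", 17, "S", "R", qual=60.0)


@pytest.fixture(scope="session")
def default_dataset() -> synthdata.SyntheticDataset:
    """The study-conditions dataset: 50 proteins, 100 variants, seed 1."""
    return synthdata.generate(seed=1)


@pytest.fixture(scope="session")
def default_manifest(default_dataset, tmp_path_factory) -> dict:
    out = tmp_path_factory.mktemp("dataset")
    return synthdata.write_dataset(default_dataset, out)


@pytest.fixture(scope="session")
def default_run(default_manifest, tmp_path_factory):
    """One full funnel run over the written default dataset."""
    inputs = default_manifest["inputs"]
    cfg = PipelineConfig(
        reference_fasta=inputs["reference_fasta"],
        contaminants_fasta=inputs["contaminants_fasta"],
        variants_table=inputs["variants_table"],
        expression_table=inputs["expression_table"],
        t2g_table=inputs["t2g_table"],
        ms_peptides=inputs["ms_peptides"],
        epitopes=inputs["epitopes"],
        predictions=inputs["predictions"],
        out_dir=str(tmp_path_factory.mktemp("run")),
    )
    return run_pipeline(cfg)
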