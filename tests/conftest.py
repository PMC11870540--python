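"""Shared fixtures and toy-data builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from motortrace import GenomeAnnotation, GeneRecord, RunConfig, SynthConfig
from motortrace.models import DOMHIT_COLUMNS, SEQHIT_COLUMNS
from motortrace.simulate import SynthDataset, simulate_dataset


def make_genome(
    n: int = 40,
    genome_id: str = "g1",
    replicon_id: str = "chr",
    strands: dict[int, str] | None = None,
    products: dict[int, str] | None = None,
    gaps: dict[int, int] | None = None,
    circular: bool = False,
) -> GenomeAnnotation:
    """Toy genome with ``n`` genes: 900 bp genes, 100 bp default gaps."""
    strands = strands or {}
    products = products or {}
    gaps = gaps or {}
    genes = []
    pos = 1
    for i in range(n):
        start = pos + gaps.get(i, 100)
        end = start + 899
        pos = end
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                replicon_id=replicon_id,
                index=i,
                start=start,
                end=end,
                strand=strands.get(i, "+"),
                locus_tag=f"{genome_id}_{i:05d}",
                product=products.get(i, "hypothetical protein"),
            )
        )
    return GenomeAnnotation(
        genome_id, genes, circular_replicons={replicon_id} if circular else ()
    )


def dom_row(
    protein_id: str,
    profile_id: str,
    env_start: int = 10,
    env_end: int = 120,
    evalue: float = 1e-10,
    bitscore: float = 50.0,
) -> dict:
    return {
        "protein_id": protein_id,
        "profile_id": profile_id,
        "env_start": env_start,
        "env_end": env_end,
        "evalue": evalue,
        "bitscore": bitscore,
    }


def dom_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(DOMHIT_COLUMNS))


def seq_row(
    query_family: str,
    sseqid: str,
    evalue: float = 1e-10,
    bitscore: float = 80.0,
) -> dict:
    return {
        "qseqid": query_family,
        "sseqid": sseqid,
        "pident": 50.0,
        "length": 100,
        "mismatch": 10,
        "gapopen": 1,
        "qstart": 1,
        "qend": 100,
        "sstart": 1,
        "send": 100,
        "evalue": evalue,
        "bitscore": bitscore,
        "query_family": query_family,
    }


def seq_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(SEQHIT_COLUMNS) + ["query_family"])


@pytest.fixture(scope="session")
def clean_dataset() -> SynthDataset:
    """Noise-free 15-species dataset with T4P everywhere and decoys."""
    config = SynthConfig(
        seed=11,
        n_species=15,
        t4p_probability=1.0,
        decoy_tpr_count=3,
        completeness_range=(90.0, 100.0),
        contamination_range=(0.0, 5.0),
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
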