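"""Shared fixtures: tiny simulated experiments and contig builders."""

from __future__ import annotations

import numpy as np
import pytest

from estminer.assembly import Contig, ESTRead, assemble, _consensus_of_columns
from estminer.sim import SimConfig, sequence_reads, simulate_transcriptome


def contig_from_rows(rows: dict[str, str], contig_id: str = "c1") -> Contig:
    """Build a contig from equal-length gapped row strings.

    '-' is an internal gap; '.' marks padding (the read does not cover the
    column). Orientation is '+' for every row.
    """
    widths = {len(r) for r in rows.values()}
    assert len(widths) == 1, "rows must be equal length"
    (width,) = widths
    columns = []
    for i in range(width):
        col = {rid: row[i] for rid, row in rows.items() if row[i] != "."}
        columns.append(col)
    contig = Contig(
        contig_id=contig_id,
        cluster_id="cl",
        columns=columns,
        orientations={rid: "+" for rid in rows},
    )
    contig.consensus, contig.cons_cols = _consensus_of_columns(columns)
    return contig


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def small_sim():
    """30 error-free genes, 3 clones (6 reads) per species per gene, with the
    full assembly result; shared by assembly/pipeline invariant tests."""
    config = SimConfig(
        n_genes=30,
        seed=3,
        gene_length_min=500,
        gene_length_max=700,
        error_rate=0.0,
        depth_distribution={6: 1.0},
    )
    genes, truth = simulate_transcriptome(config)
    sim_reads, truth = sequence_reads(genes, truth, config)
    reads = [ESTRead(r.read_id, r.clone_id, r.species, r.end, r.sequence) for r in sim_reads]
    result = assemble(reads, exhaustive_limit=0)
    return config, genes, truth, reads, result
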