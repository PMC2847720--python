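"""Assembly contracts: masking/removal rules, the two clustering and contig
thresholds, consensus tie rules, partition conservation, and round trips on
simulated reads."""

import numpy as np
import pytest

from estminer.assembly import (
    AssemblyThresholds,
    Cluster,
    ESTRead,
    assemble,
    assemble_cluster,
    cluster_reads,
    consensus,
    preprocess,
    unique_sequence_count,
)
from estminer.sim import revcomp

from conftest import contig_from_rows, random_dna


def _read(rid, seq, species="blue", end="5p"):
    return ESTRead(rid, rid.split(".")[0], species, end, seq)


def _mutate_every(seq: str, step: int, rng: np.random.Generator) -> str:
    """Substitute every ``step``-th base (interior, evenly spread)."""
    out = list(seq)
    for i in range(step // 2, len(out), step):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------


class TestPreprocess:
    def test_plain_read_kept_unchanged(self):
        rng = np.random.default_rng(0)
        seq = random_dna(rng, 300)
        kept, removed = preprocess([_read("r1", seq)])
        assert removed == []
        assert kept[0].core == seq

    def test_short_after_polya_trim_removed(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 90) + "A" * 40
        kept, removed = preprocess([_read("r1", seq)])
        assert kept == []
        assert removed[0].reason == "short"

    def test_pure_dinucleotide_removed_as_simple(self):
        kept, removed = preprocess([_read("r1", "AT" * 150)])
        assert kept == []
        assert removed[0].reason == "simple"

    def test_empty_input_is_empty_output(self):
        kept, removed = preprocess([])
        assert kept == [] and removed == []

    def test_polyt_prefix_trimmed(self):
        rng = np.random.default_rng(2)
        body = "G" + random_dna(rng, 249)  # body must not extend the T run
        kept, _ = preprocess([_read("r1", "T" * 30 + body)])
        assert kept[0].core == body


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class TestClustering:
    def test_identical_reads_form_one_cluster(self):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 300)
        kept, _ = preprocess([_read("a", seq), _read("b", seq)])
        clusters = cluster_reads(kept)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_read_ids) == ["a", "b"]

    @pytest.mark.parametrize(
        "step,expect_joined",
        [(10, True), (6, False)],  # ~90% identity joins (>=88); ~83% does not
    )
    def test_overlap_identity_threshold(self, step, expect_joined):
        rng = np.random.default_rng(4)
        left = random_dna(rng, 180)
        overlap = random_dna(rng, 120)
        right = random_dna(rng, 180)
        a = left + overlap
        b = _mutate_every(overlap, step, rng) + right
        kept, _ = preprocess([_read("a", a), _read("b", b)])
        clusters = cluster_reads(kept)
        if expect_joined:
            assert len(clusters) == 1
        else:
            assert len(clusters) == 2
            assert all(c.is_singleton for c in clusters)

    def test_reverse_complement_read_joins(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 300)
        kept, _ = preprocess([_read("a", seq), _read("b", revcomp(seq))])
        clusters = cluster_reads(kept)
        assert len(clusters) == 1

    def test_seed_clustering_assigns_matching_reads(self):
        rng = np.random.default_rng(6)
        seed_seq = random_dna(rng, 500)
        near = _mutate_every(seed_seq[:300], 8, rng)  # ~87.5% to the seed, >= 80%
        far = random_dna(rng, 300)
        kept, _ = preprocess([_read("a", near), _read("b", far)])
        clusters = cluster_reads(kept, seeds={"s1": seed_seq})
        by_seed = {c.seed_id: c for c in clusters}
        assert "s1" in by_seed and by_seed["s1"].member_read_ids == ["a"]


# ---------------------------------------------------------------------------
# contig assembly
# ---------------------------------------------------------------------------


def _assemble_pair(a_seq, b_seq, extra=None):
    reads = [_read("a", a_seq), _read("b", b_seq)]
    if extra:
        reads.append(_read("c", extra))
    kept, _ = preprocess(reads)
    cluster = Cluster("cl00000", sorted(r.read_id for r in reads))
    return assemble_cluster(cluster, {p.read_id: p for p in kept})


class TestContigAssembly:
    def test_short_perfect_overlap_assembles(self):
        rng = np.random.default_rng(7)
        core = random_dna(rng, 60)
        a = random_dna(rng, 200) + core
        b = core + random_dna(rng, 200)
        contigs, singles = _assemble_pair(a, b)
        assert len(contigs) == 1 and contigs[0].depth == 2
        assert singles == []
        assert contigs[0].consensus == a + b[60:]

    def test_cluster_level_identity_fails_contig_threshold(self):
        # 120 bp at ~90% passes clustering (88%) but not assembly (95%)
        rng = np.random.default_rng(8)
        overlap = random_dna(rng, 120)
        a = random_dna(rng, 150) + overlap
        b = _mutate_every(overlap, 10, rng) + random_dna(rng, 150)
        contigs, singles = _assemble_pair(a, b)
        assert contigs == []
        assert sorted(singles) == ["a", "b"]

    def test_partial_member_becomes_cluster_singleton(self):
        rng = np.random.default_rng(9)
        base = random_dna(rng, 400)
        a = base
        b = base[:300] + random_dna(rng, 60)  # 300 bp perfect overlap
        c = _mutate_every(base, 12, rng)  # ~92%: clusters but fails 95%
        contigs, singles = _assemble_pair(a, b, extra=c)
        assert len(contigs) == 1
        assert sorted(contigs[0].member_read_ids) == ["a", "b"]
        assert singles == ["c"]


class TestConsensus:
    def test_unanimous_column(self):
        contig = contig_from_rows({"a": "AAA", "b": "AAA", "c": "AAA"})
        assert consensus(contig) == "AAA"

    def test_tie_broken_by_symbol_order(self):
        contig = contig_from_rows({"a": "A", "b": "A", "c": "G", "d": "G"})
        assert consensus(contig) == "A"

    def test_majority_gap_column_dropped(self):
        contig = contig_from_rows({"a": "C-T", "b": "C-T", "c": "CAT"})
        assert consensus(contig) == "CT"
        assert contig.cons_cols == [0, 2]

    def test_gap_base_tie_keeps_base(self):
        contig = contig_from_rows({"a": "T-", "b": "TA"})
        assert consensus(contig) == "TA"


class TestSummary:
    def test_unique_sequence_arithmetic(self):
        c1 = contig_from_rows({f"r{i}": "ACGT" for i in range(4)}, "c1")
        c2 = contig_from_rows({f"s{i}": "ACGT" for i in range(6)}, "c2")
        summary = unique_sequence_count([c1, c2], ["x", "y"], ["z"])
        assert summary.unique == 5
        assert summary.mean_reads_per_contig == 5.0

    def test_no_contigs_counts_singletons(self):
        summary = unique_sequence_count([], [f"r{i}" for i in range(7)], [])
        assert summary.unique == 7
        assert summary.mean_reads_per_contig == 0.0


# ---------------------------------------------------------------------------
# whole-assembly invariants on simulated reads
# ---------------------------------------------------------------------------


class TestAssemblyInvariants:
    def test_partition_conservation(self, small_sim):
        _, _, _, reads, result = small_sim
        kept = len(result.processed)
        assert kept + len(result.removed) == len(reads)
        assert (
            sum(c.depth for c in result.contigs)
            + len(result.singletons)
            + len(result.cluster_singletons)
            == kept
        )
        in_contigs = [r for c in result.contigs for r in c.member_read_ids]
        assert len(in_contigs) == len(set(in_contigs))  # no read in two contigs

    def test_single_species_gene_round_trip(self):
        from estminer.sim import SimConfig, sequence_reads, simulate_transcriptome

        config = SimConfig(n_genes=1, seed=13, error_rate=0.0, gene_length_min=600,
                           gene_length_max=600, depth_distribution={6: 1.0},
                           msat_probability=0.0)
        genes, truth = simulate_transcriptome(config)
        sim_reads, truth = sequence_reads(genes, truth, config)
        blue = [
            ESTRead(r.read_id, r.clone_id, r.species, r.end, r.sequence)
            for r in sim_reads
            if r.species == "blue"
        ]
        result = assemble(blue, exhaustive_limit=0)
        assert len(result.contigs) == 1
        assert result.singletons == [] and result.cluster_singletons == []
        allele = truth.genes["g0000"].allele_blue
        cons = result.contigs[0].consensus
        assert cons in allele or revcomp(cons) in allele

    def test_orientation_safety(self):
        # tie-free data (no divergence, no polymorphism): the A<C<G<T consensus
        # tie-break is not reverse-complement covariant, so exact mirror
        # equality is only guaranteed when no column is tied
        from estminer.sim import SimConfig, sequence_reads, simulate_transcriptome

        config = SimConfig(n_genes=8, seed=17, error_rate=0.0, inter_divergence=0.0,
                           intra_rate_blue=0.0, intra_rate_channel=0.0,
                           gene_length_min=500, gene_length_max=700,
                           depth_distribution={4: 1.0})
        genes, truth = simulate_transcriptome(config)
        sim_reads, _ = sequence_reads(genes, truth, config)
        reads = [
            ESTRead(r.read_id, r.clone_id, r.species, r.end, r.sequence) for r in sim_reads
        ]
        flipped = [
            ESTRead(r.read_id, r.clone_id, r.species, r.end, revcomp(r.sequence))
            for r in reads
        ]
        result = assemble(reads, exhaustive_limit=0)
        result_rc = assemble(flipped, exhaustive_limit=0)

        def canon(c):
            return min(c.consensus, revcomp(c.consensus))

        assert sorted(canon(c) for c in result.contigs) == sorted(
            canon(c) for c in result_rc.contigs
        )
        assert sorted(frozenset(c.member_read_ids) for c in result.contigs) == sorted(
            frozenset(c.member_read_ids) for c in result_rc.contigs
        )

    def test_raising_contig_identity_never_adds_depth(self, small_sim):
        _, _, _, reads, _ = small_sim
        subset = reads[:40]
        loose = assemble(subset, AssemblyThresholds(contig_min_identity=0.90), exhaustive_limit=0)
        strict = assemble(subset, AssemblyThresholds(contig_min_identity=0.99), exhaustive_limit=0)
        assert sum(c.depth for c in strict.contigs) <= sum(c.depth for c in loose.contigs)
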