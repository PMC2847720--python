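"""Truth-recovery scoring for simulated experiments.

Maps each assembled contig back to its source gene (via the simulator's
read provenance), projects consensus coordinates onto the ancestral gene
coordinate by alignment, and compares every filtered SNP call against the
planted variant ledger. Undetermined calls are abstentions, not errors: a
site whose minor allele was sampled fewer than ``min_support`` times in a
species is genuinely uncertifiable from the reads. Conversely, an
inter-specific call is only counted as a categorization failure at an intra
site when both haplotypes were actually present with ``min_support`` reads
of the polymorphic species in the contig — otherwise the sampled evidence
is indistinguishable from fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .assembly import Contig, ESTRead
from .sim import SimTruth, revcomp
from .variants import FilteredSNP, schedule_lookup


@dataclass
class RecoveryReport:
    n_filtered: int = 0
    n_mapped: int = 0  # filtered SNPs projected onto a planted site
    n_false: int = 0  # filtered SNPs at no planted site
    n_unprojected: int = 0  # SNPs in contigs that could not be mapped
    n_definite: int = 0  # mapped SNPs with a non-undetermined category
    n_definite_correct: int = 0
    n_undetermined: int = 0
    inter_at_determinable_intra: int = 0
    missed_sites: int = 0  # well-supported planted sites with no filtered SNP
    recoverable_sites: int = 0
    details: list[str] = field(default_factory=list)

    @property
    def category_accuracy(self) -> float:
        return self.n_definite_correct / self.n_definite if self.n_definite else 1.0


_map_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-4, extend_gap_score=-1
)


def _consensus_to_gene_map(consensus: str, gene_seq: str) -> dict[int, int] | None:
    """Map consensus positions to gene positions by affine local alignment,
    trying both orientations; None when neither aligns convincingly.
    Affine gap costs keep dense true-divergence runs as substitutions rather
    than tie-broken gap pairs."""
    best = None
    for oriented, flipped in ((consensus, False), (revcomp(consensus), True)):
        try:
            aln = _map_aligner.align(gene_seq, oriented)[0]
        except (IndexError, OverflowError):
            continue
        if best is None or aln.score > best[0]:
            best = (aln.score, aln, flipped)
    if best is None or best[0] < 0.5 * len(consensus):
        return None
    _, aln, flipped = best
    g_blocks, c_blocks = aln.aligned
    mapping: dict[int, int] = {}
    for (gs, ge), (cs, ce) in zip(g_blocks, c_blocks):
        for k in range(ge - gs):
            mapping[cs + k] = gs + k
    if flipped:
        L = len(consensus)
        mapping = {L - 1 - c: g for c, g in mapping.items()}
    return mapping


def evaluate_recovery(
    contigs: list[Contig],
    filtered: list[FilteredSNP],
    truth: SimTruth,
    reads_by_id: dict[str, ESTRead],
    min_support: int = 2,
) -> RecoveryReport:
    """Score categorized filtered SNPs against the planted-variant ledger."""
    prov = {p.read_id: p for p in truth.provenance}
    rep = RecoveryReport(n_filtered=len(filtered))
    by_contig: dict[str, list[FilteredSNP]] = {}
    for s in filtered:
        by_contig.setdefault(s.contig_id, []).append(s)
    contig_by_id = {c.contig_id: c for c in contigs}

    for cid, snps in sorted(by_contig.items()):
        contig = contig_by_id[cid]
        genes = {prov[r].gene_id for r in contig.member_read_ids if r in prov}
        if len(genes) != 1:
            rep.n_unprojected += len(snps)
            rep.details.append(f"{cid}: members span genes {sorted(genes)}")
            continue
        gene = truth.genes[genes.pop()]
        mapping = _consensus_to_gene_map(contig.consensus, gene.ancestral)
        if mapping is None:
            rep.n_unprojected += len(snps)
            rep.details.append(f"{cid}: consensus did not align to its gene")
            continue
        planted = {v.position: v for v in gene.variants}
        seen_positions = set()
        for s in snps:
            apos = mapping.get(s.consensus_position)
            if apos is None:
                rep.n_unprojected += 1
                continue
            site = planted.get(apos)
            if site is None:
                rep.n_false += 1
                rep.details.append(f"{cid}:{s.consensus_position}: no planted site")
                continue
            rep.n_mapped += 1
            seen_positions.add(site.position)
            if s.category == "undetermined" or s.category is None:
                rep.n_undetermined += 1
                continue
            if s.category.startswith("single_species"):
                continue
            rep.n_definite += 1
            if s.category == site.category:
                rep.n_definite_correct += 1
            else:
                rep.details.append(
                    f"{cid}:{s.consensus_position}: called {s.category}, "
                    f"planted {site.category} at {site.position}"
                )
                if s.category == "inter_specific" and site.category.startswith("intra"):
                    if _intra_determinable(contig, site, gene, prov, reads_by_id, min_support):
                        rep.inter_at_determinable_intra += 1

        # planted sites with full support among member reads but no call
        for v in gene.variants:
            if v.position in seen_positions or v.position not in mapping.values():
                continue
            if _site_recoverable(contig, v, gene, prov, reads_by_id, min_support):
                rep.recoverable_sites += 1
                rep.missed_sites += 1
        rep.recoverable_sites += len(seen_positions)
    return rep


def _member_alleles(contig, position, gene, prov, reads_by_id):
    """Per-species allele counts at an ancestral position, reconstructed from
    read provenance (spans and haplotype choices), independent of the
    alignment columns."""
    out: dict[str, dict[str, int]] = {"blue": {}, "channel": {}}
    for rid in contig.member_read_ids:
        p = prov.get(rid)
        if p is None:
            continue
        rlen = len(reads_by_id[rid].sequence)
        if not p.offset <= position < p.offset + rlen:
            continue
        allele_seq = gene.allele(p.species)
        if position >= len(allele_seq):
            continue
        base = allele_seq[position]
        for item in p.haplotype.split(";"):
            if item and int(item.split(":")[0]) == position:
                base = item.split(":")[1]
        out[p.species][base] = out[p.species].get(base, 0) + 1
    return out


def _intra_determinable(contig, site, gene, prov, reads_by_id, min_support) -> bool:
    counts = _member_alleles(contig, site.position, gene, prov, reads_by_id)
    for species in ("blue", "channel"):
        sp_alleles = site.alleles_blue if species == "blue" else site.alleles_channel
        if len(sp_alleles) > 1:
            c = counts[species]
            if all(c.get(a, 0) >= min_support for a in sp_alleles):
                return True
    return False


def _site_recoverable(contig, site, gene, prov, reads_by_id, min_support) -> bool:
    """Every planted allele supported by at least the depth schedule's
    minor-allele requirement among covering member reads (and at least
    ``min_support`` per species for categorization)."""
    counts = _member_alleles(contig, site.position, gene, prov, reads_by_id)
    depth = sum(sum(c.values()) for c in counts.values())
    if depth < 4:
        return False
    required = max(min_support, schedule_lookup(depth) or 10**9)
    for species, alleles in (("blue", site.alleles_blue), ("channel", site.alleles_channel)):
        for a in alleles:
            if counts[species].get(a, 0) < required:
                return False
    return True
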