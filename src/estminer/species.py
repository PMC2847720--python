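"""Species-of-origin SNP categorization and sampled-proportion estimation.

A filtered SNP in a contig containing reads of both species is categorized
by its per-species allele counts: fixed different alleles in the two
species make it *inter-specific*; within-species variation makes it
*intra-specific* for that species (or both); and any allele supported by
fewer than ``min_support`` reads within its species leaves the site
*undetermined* — the evidence cannot certify either fixation or
polymorphism. SNPs from single-species contigs are tallied separately.

Category proportions over the whole assembly are estimated by drawing a
random sample of mixed-origin contigs, tallying categories over their SNPs,
and extrapolating each category proportionally to the mixed-contig SNP
total (round half up), with shares expressed against the grand filtered-SNP
total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import Contig, ESTRead
from .variants import FilteredSNP

logger = logging.getLogger(__name__)

MIXED_CATEGORIES = (
    "inter_specific",
    "intra_blue",
    "intra_channel",
    "intra_both",
    "undetermined",
)


class CategorizationError(ValueError):
    pass


@dataclass
class SpeciesAlleleTable:
    contig_id: str
    consensus_position: int
    counts_blue: dict[str, int]
    counts_channel: dict[str, int]


@dataclass
class CategoryEstimate:
    sampled_counts: dict[str, int]
    sampled_total_categorized: int
    population_total: int
    estimates: dict[str, int]
    shares: dict[str, int]  # percent of the grand filtered-SNP total
    n_sampled_contigs: int = 0
    seed: int | None = None


@dataclass
class PartitionTotals:
    mixed_total: int
    blue_only_total: int
    channel_only_total: int

    @property
    def grand_total(self) -> int:
        return self.mixed_total + self.blue_only_total + self.channel_only_total


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def contig_origin(contig: Contig, reads_by_id: dict[str, ESTRead]) -> str:
    """``mixed`` iff reads of both species are present; ``unknown``-species
    reads are excluded (and logged)."""
    species = set()
    unknown = 0
    for rid in contig.member_read_ids:
        sp = reads_by_id[rid].species
        if sp == "unknown":
            unknown += 1
        else:
            species.add(sp)
    if unknown:
        logger.info("contig %s: %d unknown-species reads excluded", contig.contig_id, unknown)
    if not species:
        raise CategorizationError(
            f"contig {contig.contig_id}: no reads with a known species"
        )
    if species == {"blue", "channel"}:
        return "mixed"
    return "blue_only" if species == {"blue"} else "channel_only"


def species_allele_table(
    contig: Contig, snp: FilteredSNP, reads_by_id: dict[str, ESTRead]
) -> SpeciesAlleleTable:
    """Per-species base counts at the SNP's alignment column."""
    col = contig.columns[contig.cons_cols[snp.consensus_position]]
    counts: dict[str, dict[str, int]] = {"blue": {}, "channel": {}}
    for rid, sym in col.items():
        if sym not in "ACGT":
            continue
        sp = reads_by_id[rid].species
        if sp == "unknown":
            continue
        counts[sp][sym] = counts[sp].get(sym, 0) + 1
    return SpeciesAlleleTable(
        contig_id=snp.contig_id,
        consensus_position=snp.consensus_position,
        counts_blue=counts["blue"],
        counts_channel=counts["channel"],
    )


def categorize_snp(table: SpeciesAlleleTable, min_support: int = 2) -> str:
    """Assign one of the five mixed-contig categories.

    Any observed allele with within-species count below ``min_support``
    (including a species with no covering reads) leaves the site
    undetermined; with every allele supported, two monomorphic species with
    different alleles are inter-specific, one/both polymorphic species are
    intra-specific accordingly.
    """
    blue, channel = table.counts_blue, table.counts_channel
    if not blue and not channel:
        raise CategorizationError(
            f"{table.contig_id}:{table.consensus_position}: empty species table"
        )
    if not blue or not channel:
        return "undetermined"
    if any(c < min_support for c in blue.values()) or any(
        c < min_support for c in channel.values()
    ):
        return "undetermined"
    blue_poly = len(blue) > 1
    channel_poly = len(channel) > 1
    if not blue_poly and not channel_poly:
        if set(blue) == set(channel):
            raise CategorizationError(
                f"{table.contig_id}:{table.consensus_position}: both species fixed "
                "for the same allele — not a SNP"
            )
        return "inter_specific"
    if blue_poly and channel_poly:
        return "intra_both"
    return "intra_blue" if blue_poly else "intra_channel"


def partition_totals(origins_of_snps: list[str]) -> PartitionTotals:
    """Split filtered-SNP counts by the origin of their contig."""
    mixed = sum(1 for o in origins_of_snps if o == "mixed")
    blue = sum(1 for o in origins_of_snps if o == "blue_only")
    channel = sum(1 for o in origins_of_snps if o == "channel_only")
    return PartitionTotals(mixed_total=mixed, blue_only_total=blue, channel_only_total=channel)


def extrapolate(
    sampled_counts: dict[str, int], population_total: int, grand_total: int
) -> tuple[dict[str, int], dict[str, int], int]:
    """Proportional extrapolation of sampled category counts (round half up)
    to the mixed-contig population, with percent shares of the grand total."""
    total = sum(sampled_counts.values())
    if total == 0:
        raise CategorizationError("no categorized SNPs in the sample")
    estimates = {
        c: _round_half_up(n / total * population_total) for c, n in sampled_counts.items()
    }
    shares = {c: _round_half_up(e / grand_total * 100) for c, e in estimates.items()}
    return estimates, shares, total


def sample_and_estimate(
    pool: dict[str, list[str]],
    population_total: int,
    grand_total: int,
    n_sample: int = 1000,
    seed: int = 0,
) -> CategoryEstimate:
    """Draw ``n_sample`` contigs without replacement from ``pool`` (a mapping
    of mixed-origin contig id to the categories of its filtered SNPs), tally
    categories over the sampled contigs' SNPs, and extrapolate."""
    ids = sorted(pool)
    if n_sample > len(ids):
        logger.info("sample size %d > pool %d; using the whole pool", n_sample, len(ids))
        n_sample = len(ids)
    rng = np.random.Generator(np.random.PCG64(seed))
    chosen = rng.choice(len(ids), size=n_sample, replace=False) if ids else []
    counts = {c: 0 for c in MIXED_CATEGORIES}
    for i in sorted(int(j) for j in chosen):
        for cat in pool[ids[i]]:
            counts[cat] = counts.get(cat, 0) + 1
    estimates, shares, total = extrapolate(
        {c: n for c, n in counts.items() if n > 0}, population_total, grand_total
    )
    return CategoryEstimate(
        sampled_counts=counts,
        sampled_total_categorized=total,
        population_total=population_total,
        estimates=estimates,
        shares=shares,
        n_sampled_contigs=n_sample,
        seed=seed,
    )


def categorize_assembly(
    contigs: list[Contig],
    filtered: list[FilteredSNP],
    reads_by_id: dict[str, ESTRead],
    min_support: int = 2,
) -> tuple[list[FilteredSNP], dict[str, str]]:
    """Label every filtered SNP with a category and every SNP-bearing contig
    with its origin; mixed-contig SNPs get a Fig.-8-style category,
    single-species SNPs get ``single_species_blue``/``single_species_channel``.
    """
    by_contig: dict[str, Contig] = {c.contig_id: c for c in contigs}
    origins: dict[str, str] = {}
    for snp in filtered:
        contig = by_contig[snp.contig_id]
        origin = origins.get(snp.contig_id)
        if origin is None:
            origin = contig_origin(contig, reads_by_id)
            origins[snp.contig_id] = origin
        table = species_allele_table(contig, snp, reads_by_id)
        snp.counts_blue = table.counts_blue
        snp.counts_channel = table.counts_channel
        if origin == "mixed":
            try:
                snp.category = categorize_snp(table, min_support)
            except CategorizationError:
                # the minor allele sat entirely on excluded (unknown-species)
                # reads; no species-level evidence remains
                logger.info(
                    "SNP %s:%d uncategorizable after exclusions; undetermined",
                    snp.contig_id,
                    snp.consensus_position,
                )
                snp.category = "undetermined"
        else:
            snp.category = f"single_species_{origin.removesuffix('_only')}"
    return filtered, origins
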