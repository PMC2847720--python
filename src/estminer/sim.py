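"""Two-species EST read simulator with a ground-truth ledger.

Emulates the statistical structure of a paired transcriptome EST project in
two closely related species (here called *blue* and *channel*, after the two
Ictalurid catfishes that motivate the defaults): coding sequences at ~95%
mean between-species identity, single-pass reads of 100-877 bp (mean 576),
shallow normalized-library depth with a long tail, paired 5'/3' reads per
cDNA clone, poly(A) tails, and planted microsatellites and ORFs.

Every planted feature — inter-specific substitution, intra-specific
polymorphism, microsatellite, ORF — is recorded in a :class:`SimTruth`
ledger keyed by gene, so downstream recovery tests can compare pipeline
output against the truth site by site.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default reads-per-gene-per-species law: the dominant two- and three-read
#: masses of shallow normalized libraries plus a geometric(1/2) tail.
DEFAULT_DEPTH_DISTRIBUTION = {
    2: 0.43,
    3: 0.13,
    4: 0.22,
    5: 0.11,
    6: 0.055,
    7: 0.0275,
    8: 0.0275,
}

#: motif-length weights for planted microsatellites, shaped like observed
#: EST-SSR class abundances (di >> tri > tetra >> penta/hexa).
MSAT_MOTIF_LENGTH_WEIGHTS = {2: 0.60, 3: 0.25, 4: 0.12, 5: 0.02, 6: 0.01}

#: minimum repeat counts per motif length used when planting repeats
#: (mirrors the detection thresholds so planted loci are detectable).
MSAT_MIN_REPEATS = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """An invalid simulator configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of one simulated two-species EST experiment.

    Rates are per site (``inter_divergence``, ``error_rate``, ``indel_rate``)
    or per kilobase per species (``intra_rate_blue``, ``intra_rate_channel``).
    ``depth_distribution`` maps reads-per-gene-per-species to probability.
    """

    n_genes: int = 100
    gene_length_min: int = 900
    gene_length_max: int = 3000
    inter_divergence: float = 0.05
    intra_rate_blue: float = 0.5
    intra_rate_channel: float = 1.3
    depth_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_DISTRIBUTION)
    )
    read_len_min: int = 100
    read_len_max: int = 877
    read_len_mean: int = 576
    read_len_sd: float = 100.0
    error_rate: float = 0.005
    indel_rate: float = 0.0
    polya_len: int = 20
    msat_probability: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("inter_divergence", "error_rate", "indel_rate", "msat_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("intra_rate_blue", "intra_rate_channel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1000.0:
                raise ConfigurationError(f"{name} (per kb) must be in [0, 1000], got {v}")
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.gene_length_min < 1 or self.gene_length_max < self.gene_length_min:
            raise ConfigurationError(
                "gene_length_min/max must satisfy 1 <= min <= max, got "
                f"{self.gene_length_min}/{self.gene_length_max}"
            )
        if self.read_len_min < 1:
            raise ConfigurationError(f"read_len_min must be >= 1, got {self.read_len_min}")
        if not self.read_len_min <= self.read_len_mean <= self.read_len_max:
            raise ConfigurationError(
                "read lengths must satisfy min <= mean <= max, got "
                f"{self.read_len_min}/{self.read_len_mean}/{self.read_len_max}"
            )
        if self.read_len_sd <= 0:
            raise ConfigurationError(f"read_len_sd must be > 0, got {self.read_len_sd}")
        if self.polya_len < 0:
            raise ConfigurationError(f"polya_len must be >= 0, got {self.polya_len}")
        if not self.depth_distribution:
            raise ConfigurationError("depth_distribution must be non-empty")
        total = 0.0
        for k, p in self.depth_distribution.items():
            if k < 1:
                raise ConfigurationError(f"depth_distribution key {k} must be >= 1")
            if p < 0:
                raise ConfigurationError(f"depth_distribution probability {p} < 0")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"depth_distribution probabilities must sum to 1, got {total}"
            )


@dataclass
class TrueVariant:
    """A planted variant site on the ancestral gene coordinate."""

    position: int
    category: str  # inter_specific | intra_blue | intra_channel | intra_both
    #: per-species allele sets at this site, e.g. {"blue": ("A",), "channel": ("A","G")}
    alleles_blue: tuple[str, ...] = ()
    alleles_channel: tuple[str, ...] = ()


@dataclass
class TrueMsat:
    motif: str
    repeat_count: int
    start: int  # 0-based on ancestral coordinate

    @property
    def end(self) -> int:
        return self.start + len(self.motif) * self.repeat_count


@dataclass
class TrueORF:
    start: int  # 0-based, position of the A of ATG
    end: int  # half-open, past the stop codon

    @property
    def frame(self) -> int:
        return self.start % 3


@dataclass
class GeneTruth:
    gene_id: str
    ancestral: str
    allele_blue: str
    allele_channel: str
    variants: list[TrueVariant]
    msat: TrueMsat | None
    orf: TrueORF

    def allele(self, species: str) -> str:
        return self.allele_blue if species == "blue" else self.allele_channel


@dataclass
class ReadProvenance:
    read_id: str
    clone_id: str
    end: str  # 5p | 3p
    species: str
    gene_id: str
    haplotype: str  # semicolon list "pos:base" of intra-allele choices
    strand: str  # + | -
    offset: int  # read start on the clone transcript coordinate
    errors: str  # semicolon list "pos:orig>new" on the read coordinate


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated experiment."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    provenance: list[ReadProvenance] = field(default_factory=list)

    def variants_by_gene(self, gene_id: str) -> list[TrueVariant]:
        return self.genes[gene_id].variants


@dataclass
class SimRead:
    read_id: str
    clone_id: str
    species: str
    end: str  # 5p | 3p
    sequence: str


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------


def _random_nonstop_codons(rng: np.random.Generator, n: int) -> str:
    codons = []
    while len(codons) < n:
        c = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    return "".join(codons)


def _primitive_motif(rng: np.random.Generator, mlen: int) -> str:
    while True:
        m = "".join(BASES[i] for i in rng.integers(0, 4, size=mlen))
        if len(set(m)) == 1:
            continue
        # reject motifs that are repetitions of a shorter unit
        if any(mlen % d == 0 and m == m[:d] * (mlen // d) for d in range(1, mlen)):
            continue
        return m


def _would_create_stop(seq: str, pos: int, new_base: str, orf: TrueORF) -> bool:
    """True if substituting ``new_base`` at ``pos`` creates an in-frame stop
    codon inside the ORF (which would corrupt the planted ORF)."""
    if not orf.start <= pos < orf.end - 3:  # the terminal stop may stay a stop
        return False
    codon_start = orf.start + ((pos - orf.start) // 3) * 3
    codon = seq[codon_start:pos] + new_base + seq[pos + 1 : codon_start + 3]
    return codon in STOP_CODONS


def _plant_gene(rng: np.random.Generator, gene_id: str, config: SimConfig) -> GeneTruth:
    length = int(rng.integers(config.gene_length_min, config.gene_length_max + 1))
    seq = list(BASES[i] for i in rng.integers(0, 4, size=length))

    # --- ORF: in-frame stop just upstream of the ATG so the planted start is
    # the first ATG of its stop-free segment, then non-stop codons, then stop.
    min_orf_codons = 20
    orf_start = int(rng.integers(6, max(7, min(100, length // 5))))
    max_codons = (length - orf_start - 3 - 60) // 3  # leave >=60 bp of 3' UTR
    max_codons = max(min_orf_codons, max_codons)
    hi = min(max_codons, max(min_orf_codons + 1, int(0.6 * length) // 3))
    n_codons = int(rng.integers(min_orf_codons, hi + 1))
    body = "ATG" + _random_nonstop_codons(rng, n_codons - 1)
    stop = STOP_CODONS[int(rng.integers(0, 3))]
    orf_end = orf_start + len(body) + 3
    if orf_end > length - 3:  # clamp for very short genes
        n_codons = (length - orf_start - 6) // 3
        body = "ATG" + _random_nonstop_codons(rng, max(1, n_codons - 1))
        orf_end = orf_start + len(body) + 3
    seq[orf_start : orf_start + len(body)] = body
    seq[orf_start + len(body) : orf_end] = stop
    upstream_stop = STOP_CODONS[int(rng.integers(0, 3))]
    seq[orf_start - 3 : orf_start] = upstream_stop
    orf = TrueORF(start=orf_start, end=orf_end)

    # --- microsatellite in a UTR, with maximal-run boundaries enforced
    msat: TrueMsat | None = None
    if rng.random() < config.msat_probability:
        mlens = list(MSAT_MOTIF_LENGTH_WEIGHTS)
        weights = np.array([MSAT_MOTIF_LENGTH_WEIGHTS[m] for m in mlens])
        mlen = int(rng.choice(mlens, p=weights / weights.sum()))
        motif = _primitive_motif(rng, mlen)
        reps = int(MSAT_MIN_REPEATS[mlen] + rng.integers(0, 4))
        span = mlen * reps
        utr3_lo, utr3_hi = orf_end + 1, length - span - 1
        utr5_lo, utr5_hi = 1, orf_start - 3 - span - 1
        if utr3_hi - utr3_lo >= 1:
            start = int(rng.integers(utr3_lo, utr3_hi))
        elif utr5_hi - utr5_lo >= 1:
            start = int(rng.integers(utr5_lo, utr5_hi))
        else:
            start = -1
        if start >= 0:
            run = (motif * reps)[:span]
            seq[start : start + span] = run
            # break accidental left/right extension of the run
            left_ext = motif[-1]
            if seq[start - 1] == left_ext:
                seq[start - 1] = BASES[(BASES.index(left_ext) + 1) % 4]
            if start + span < length and seq[start + span] == motif[0]:
                seq[start + span] = BASES[(BASES.index(motif[0]) + 1) % 4]
            msat = TrueMsat(motif=motif, repeat_count=reps, start=start)

    ancestral = "".join(seq)

    # --- variant sites: positions where substitutions are forbidden
    forbidden = set(range(orf.start, orf.start + 3))  # ATG
    forbidden |= set(range(orf.end - 3, orf.end))  # stop
    forbidden |= set(range(orf.start - 3, orf.start))  # planted upstream stop
    if msat is not None:
        forbidden |= set(range(max(0, msat.start - 1), min(length, msat.end + 1)))

    blue = list(ancestral)
    channel = list(ancestral)
    variants: list[TrueVariant] = []

    def pick_alt(current: str, pos: int, target: list[str]) -> str | None:
        choices = [b for b in BASES if b != current]
        rng.shuffle(choices)
        for b in choices:
            if not _would_create_stop("".join(target), pos, b, orf):
                return b
        return None

    inter_positions = np.flatnonzero(rng.random(length) < config.inter_divergence)
    for pos in inter_positions:
        pos = int(pos)
        if pos in forbidden:
            continue
        target, other = (blue, channel) if rng.random() < 0.5 else (channel, blue)
        alt = pick_alt(ancestral[pos], pos, target)
        if alt is None:
            continue
        target[pos] = alt
        forbidden.add(pos)
        b_allele, c_allele = (alt, ancestral[pos]) if target is blue else (ancestral[pos], alt)
        variants.append(
            TrueVariant(
                position=pos,
                category="inter_specific",
                alleles_blue=(b_allele,),
                alleles_channel=(c_allele,),
            )
        )

    intra_sites: dict[int, dict[str, str]] = {}  # pos -> species -> alt base
    for species, rate, target in (
        ("blue", config.intra_rate_blue, blue),
        ("channel", config.intra_rate_channel, channel),
    ):
        positions = np.flatnonzero(rng.random(length) < rate / 1000.0)
        for pos in positions:
            pos = int(pos)
            if pos in forbidden:
                continue
            alt = pick_alt(target[pos], pos, target)
            if alt is None:
                continue
            intra_sites.setdefault(pos, {})[species] = alt
    for pos in sorted(intra_sites):
        alts = intra_sites[pos]
        if len(alts) == 2:
            category = "intra_both"
        else:
            category = "intra_blue" if "blue" in alts else "intra_channel"
        variants.append(
            TrueVariant(
                position=pos,
                category=category,
                alleles_blue=tuple(
                    sorted({blue[pos]} | ({alts["blue"]} if "blue" in alts else set()))
                ),
                alleles_channel=tuple(
                    sorted({channel[pos]} | ({alts["channel"]} if "channel" in alts else set()))
                ),
            )
        )

    variants.sort(key=lambda v: v.position)
    return GeneTruth(
        gene_id=gene_id,
        ancestral=ancestral,
        allele_blue="".join(blue),
        allele_channel="".join(channel),
        variants=variants,
        msat=msat,
        orf=orf,
    )


def simulate_transcriptome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate ancestral genes plus per-species alleles and the truth ledger.

    Returns a mapping ``gene_id -> ancestral sequence`` and the
    :class:`SimTruth` whose per-gene records carry both species' allele
    sequences and every planted feature.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed))
    truth = SimTruth()
    genes: dict[str, str] = {}
    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        gt = _plant_gene(rng, gene_id, config)
        genes[gene_id] = gt.ancestral
        truth.genes[gene_id] = gt
    return genes, truth


# ---------------------------------------------------------------------------
# read sequencing
# ---------------------------------------------------------------------------


def _draw_read_length(rng: np.random.Generator, config: SimConfig) -> int:
    """Truncated-normal read length honoring min/mean/max."""
    while True:
        x = rng.normal(config.read_len_mean, config.read_len_sd)
        if config.read_len_min <= x <= config.read_len_max:
            return int(round(x))


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float, indel_rate: float
) -> tuple[str, list[str]]:
    if error_rate == 0.0 and indel_rate == 0.0:
        return seq, []
    out = []
    notes = []
    for i, base in enumerate(seq):
        if indel_rate > 0.0 and rng.random() < indel_rate:
            if rng.random() < 0.5:
                notes.append(f"{i}:{base}>-")  # deletion
                continue
            ins = BASES[int(rng.integers(0, 4))]
            out.append(ins)
            notes.append(f"{i}:->{ins}")
        if error_rate > 0.0 and rng.random() < error_rate:
            alt = BASES[(BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4]
            out.append(alt)
            notes.append(f"{i}:{base}>{alt}")
        else:
            out.append(base)
    return "".join(out), notes


def sequence_reads(
    genes: dict[str, str], truth: SimTruth, config: SimConfig
) -> tuple[list[SimRead], SimTruth]:
    """Sample clones and emit 5'/3' reads; provenance is appended to ``truth``.

    The clone transcript is the species allele with per-clone intra-specific
    haplotype choices applied, plus a poly(A) tail. The 5' read is the
    transcript prefix; the 3' read is the reverse complement of the
    transcript suffix (so it begins with poly(T)). An odd reads-per-gene
    draw yields one single-end clone.
    """
    config.validate()
    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    depth_keys = sorted(config.depth_distribution)
    depth_p = np.array([config.depth_distribution[k] for k in depth_keys], dtype=float)
    depth_p = depth_p / depth_p.sum()

    reads: list[SimRead] = []
    for gene_id in sorted(genes):
        gt = truth.genes[gene_id]
        if len(gt.ancestral) < config.read_len_min:
            logger.warning(
                "gene %s shorter than read_len_min (%d < %d); skipped",
                gene_id,
                len(gt.ancestral),
                config.read_len_min,
            )
            continue
        for species in ("blue", "channel"):
            allele = gt.allele(species)
            n_reads = int(depth_keys[int(rng.choice(len(depth_keys), p=depth_p))])
            n_paired = n_reads // 2
            has_single = n_reads % 2 == 1
            intra = [
                v
                for v in gt.variants
                if v.category in ("intra_both", f"intra_{species}")
            ]
            for c in range(n_paired + (1 if has_single else 0)):
                clone_id = f"{gene_id}_{species[0]}{c}"
                hap_choices = []
                transcript = list(allele)
                for v in intra:
                    alleles = v.alleles_blue if species == "blue" else v.alleles_channel
                    chosen = alleles[int(rng.integers(0, len(alleles)))]
                    transcript[v.position] = chosen
                    hap_choices.append(f"{v.position}:{chosen}")
                transcript = "".join(transcript) + "A" * config.polya_len
                single_end = has_single and c == n_paired
                if single_end:
                    ends = ["5p" if rng.random() < 0.5 else "3p"]
                else:
                    ends = ["5p", "3p"]
                for end in ends:
                    rlen = min(_draw_read_length(rng, config), len(transcript))
                    if end == "5p":
                        raw = transcript[:rlen]
                        offset, strand = 0, "+"
                    else:
                        offset = len(transcript) - rlen
                        raw = revcomp(transcript[offset:])
                        strand = "-"
                    final, errors = _apply_errors(
                        rng, raw, config.error_rate, config.indel_rate
                    )
                    read_id = f"{clone_id}.{end}"
                    reads.append(
                        SimRead(
                            read_id=read_id,
                            clone_id=clone_id,
                            species=species,
                            end=end,
                            sequence=final,
                        )
                    )
                    truth.provenance.append(
                        ReadProvenance(
                            read_id=read_id,
                            clone_id=clone_id,
                            end=end,
                            species=species,
                            gene_id=gene_id,
                            haplotype=";".join(hap_choices),
                            strand=strand,
                            offset=offset,
                            errors=";".join(errors),
                        )
                    )
    return reads, truth


# ---------------------------------------------------------------------------
# I/O: FASTA + TSV side-car
# ---------------------------------------------------------------------------


def write_reads_fasta(reads: list[SimRead], fasta_path: str | Path) -> None:
    """Write reads as FASTA with ``>cloneID.end species=...`` headers."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description=f"species={r.species}")
        for r in reads
    ]
    seqio_write(records, str(fasta_path), "fasta")


SIDECAR_COLUMNS = ["read_id", "clone_id", "end", "species", "gene_id", "haplotype", "strand", "offset", "errors"]


def write_sidecar(truth: SimTruth, tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SIDECAR_COLUMNS)
        for p in truth.provenance:
            w.writerow(
                [p.read_id, p.clone_id, p.end, p.species, p.gene_id, p.haplotype, p.strand, p.offset, p.errors]
            )


def read_sidecar(tsv_path: str | Path) -> list[ReadProvenance]:
    out = []
    with open(tsv_path) as fh:
        r = csv.DictReader(fh, delimiter="\t")
        for row in r:
            out.append(
                ReadProvenance(
                    read_id=row["read_id"],
                    clone_id=row["clone_id"],
                    end=row["end"],
                    species=row["species"],
                    gene_id=row["gene_id"],
                    haplotype=row["haplotype"],
                    strand=row["strand"],
                    offset=int(row["offset"]),
                    errors=row["errors"],
                )
            )
    return out


def simulate_to_files(config: SimConfig, outdir: str | Path) -> tuple[Path, Path]:
    """Run the full simulation and write ``reads.fasta`` + ``reads.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_transcriptome(config)
    reads, truth = sequence_reads(genes, truth, config)
    fasta = outdir / "reads.fasta"
    tsv = outdir / "reads.tsv"
    write_reads_fasta(reads, fasta)
    write_sidecar(truth, tsv)
    return fasta, tsv
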