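"""End-to-end orchestration: simulate/load reads, assemble, call and filter
SNPs, categorize by species of origin, annotate, and emit table-shaped
reports (assembly statistics, microsatellite summary, SNP summary, the
depth-stratified SNP table, and the category-proportion estimate) plus all
intermediate artifacts. Re-running with an identical configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import annotate as ann
from .assembly import AssemblyResult, AssemblyThresholds, ESTRead, assemble
from .sim import SimConfig, read_sidecar, sequence_reads, simulate_transcriptome, write_reads_fasta, write_sidecar
from .species import (
    MIXED_CATEGORIES,
    CategoryEstimate,
    categorize_assembly,
    partition_totals,
    sample_and_estimate,
)
from .variants import (
    FilteredSNP,
    PutativeVariant,
    SNPSummary,
    ThresholdSchedule,
    call_columns,
    detect_putative,
    filter_snps,
    snp_rate_per_kb,
    summarize_snps,
    variants_to_frame,
    write_vcf,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Exactly one of (``reads_fasta`` + ``sidecar``) or ``sim`` must be set."""

    reads_fasta: str | None = None
    sidecar: str | None = None
    sim: SimConfig | None = None
    thresholds: AssemblyThresholds = field(default_factory=AssemblyThresholds)
    schedule: ThresholdSchedule = field(default_factory=ThresholdSchedule)
    min_support: int = 2
    n_sample: int = 1000
    seed: int = 0
    outdir: str = "estminer_out"
    exhaustive_limit: int = 200

    def validate(self) -> None:
        has_files = self.reads_fasta is not None
        has_sim = self.sim is not None
        if has_files == has_sim:
            raise PipelineConfigError(
                "exactly one of {reads_fasta+sidecar, sim} must be provided"
            )
        if has_files:
            if self.sidecar is None:
                raise PipelineConfigError("reads_fasta requires a species side-car TSV")
            for p in (self.reads_fasta, self.sidecar):
                if not Path(p).exists():
                    raise PipelineConfigError(f"input file not found: {p}")
        if self.sim is not None:
            self.sim.validate()

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        fields = dataclasses.asdict(self)
        fields.pop("outdir", None)  # the destination is not part of the analysis
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Table-6-shaped depth stratification
# ---------------------------------------------------------------------------

#: (label, is_filtered_stratum) in report order
STRATA = [
    ("2 (1:1)", False),
    ("3 (2:1)", False),
    ("4 (3:1)", False),
    ("4 (2:2)", True),
    ("5-6", True),
    ("7-8", True),
    ("9-12", True),
    ("13-20", True),
    ("21-30", True),
    ("31-50", True),
    ("51-100", True),
    ("101-500", True),
    (">500", True),
]

_DEPTH_BINS = [(5, 6), (7, 8), (9, 12), (13, 20), (21, 30), (31, 50), (51, 100), (101, 500)]


@dataclass
class StratumRow:
    label: str
    filtered: bool
    n_contigs: int
    n_snps: int
    rate_kb: float | None = None


@dataclass
class DepthStrataTable:
    rows: list[StratumRow]

    def subtotal(self, filtered: bool) -> tuple[int, int]:
        """(contigs-with-SNPs, SNP count) summed over one section."""
        n_c = sum(r.n_contigs for r in self.rows if r.filtered == filtered)
        n_s = sum(r.n_snps for r in self.rows if r.filtered == filtered)
        return n_c, n_s

    @property
    def filtered_subtotal(self) -> int:
        return self.subtotal(True)[1]

    @property
    def nonfiltered_subtotal(self) -> int:
        return self.subtotal(False)[1]

    @property
    def grand_total(self) -> int:
        return self.filtered_subtotal + self.nonfiltered_subtotal

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.rows:
            rows.append(
                {
                    "stratum": r.label,
                    "section": "filtered" if r.filtered else "non-filtered",
                    "contigs_with_snps": r.n_contigs,
                    "snps": r.n_snps,
                    "rate_per_kb": r.rate_kb,
                }
            )
        for filt, name in ((False, "non-filtered subtotal"), (True, "filtered subtotal")):
            c, s = self.subtotal(filt)
            rows.append(
                {"stratum": name, "section": "", "contigs_with_snps": c, "snps": s, "rate_per_kb": None}
            )
        rows.append(
            {
                "stratum": "total",
                "section": "",
                "contigs_with_snps": sum(r.n_contigs for r in self.rows),
                "snps": self.grand_total,
                "rate_per_kb": None,
            }
        )
        return pd.DataFrame(rows)


def _stratum_of(depth: int, minor_count: int, passed: bool) -> str | None:
    if passed:
        if depth == 4:
            return "4 (2:2)"
        for lo, hi in _DEPTH_BINS:
            if lo <= depth <= hi:
                return f"{lo}-{hi}"
        return ">500"
    if depth == 2:
        return "2 (1:1)"
    if depth == 3:
        return "3 (2:1)"
    if depth == 4:
        return "4 (3:1)"
    return None  # deeper schedule failures are not tabulated


def aggregate_depth_strata(
    putative: list[PutativeVariant],
    filtered: list[FilteredSNP],
    contig_depths: dict[str, int] | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> DepthStrataTable:
    """Tally SNPs per depth stratum: the non-filtered section covers the
    shallow strata (depth 2-4 with an unsupported minor allele); the filtered
    section stratifies schedule-passing SNPs by contig depth. Per-stratum
    rates use the total consensus length of contigs in the stratum when
    ``contig_depths``/``contig_lengths`` are given."""
    passed_keys = {(s.contig_id, s.consensus_position, s.minor_allele) for s in filtered}
    tallies: dict[str, int] = {label: 0 for label, _ in STRATA}
    contigs_in: dict[str, set[str]] = {label: set() for label, _ in STRATA}
    for v in putative:
        if v.kind != "substitution":
            continue
        passed = (v.contig_id, v.consensus_position, v.minor_allele) in passed_keys
        label = _stratum_of(v.depth, v.minor_count, passed)
        if label is None:
            continue
        tallies[label] += 1
        contigs_in[label].add(v.contig_id)

    rates: dict[str, float | None] = {label: None for label, _ in STRATA}
    if contig_depths and contig_lengths:
        for label, _ in STRATA:
            bp = 0
            for cid, d in contig_depths.items():
                if _stratum_label_of_depth(d) == _base_label(label):
                    bp += contig_lengths.get(cid, 0)
            if bp > 0:
                rates[label] = snp_rate_per_kb(tallies[label], bp)

    rows = [
        StratumRow(label, filt, len(contigs_in[label]), tallies[label], rates[label])
        for label, filt in STRATA
    ]
    return DepthStrataTable(rows=rows)


def _base_label(label: str) -> str:
    return label.split(" ")[0]


def _stratum_label_of_depth(depth: int) -> str:
    if depth <= 4:
        return str(depth)
    for lo, hi in _DEPTH_BINS:
        if lo <= depth <= hi:
            return f"{lo}-{hi}"
    return ">500"


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------


@dataclass
class MsatSummary:
    per_class_loci: dict[int, int]  # motif length -> locus count
    total_loci: int
    sequences_with_msat: int
    sequences_with_sufficient_flanks: int
    n_unique_sequences: int


@dataclass
class AssemblyTable:
    n_input: int
    n_removed: int
    n_for_assembly: int
    n_contigs: int
    n_singletons: int
    n_cluster_singletons: int
    unique: int
    mean_reads_per_contig: float


@dataclass
class SummaryReport:
    assembly: AssemblyTable
    msat: MsatSummary
    snps: SNPSummary
    strata: DepthStrataTable
    estimate: CategoryEstimate | None
    partition: dict[str, int]
    config_hash: str
    seed: int
    version: str = __version__


def verify_report(report: SummaryReport) -> list[str]:
    """Internal-consistency findings; empty on success."""
    findings: list[str] = []
    a = report.assembly
    if a.unique != a.n_contigs + a.n_singletons + a.n_cluster_singletons:
        findings.append("assembly: unique != contigs + singletons + cluster singletons")
    if a.n_input != a.n_removed + a.n_for_assembly:
        findings.append("assembly: input != removed + assembled")
    if report.msat.total_loci != sum(report.msat.per_class_loci.values()):
        findings.append("msat: total != sum of per-class rows")
    s = report.snps
    if s.putative_total != s.putative_transitions + s.putative_transversions:
        findings.append("snps: putative ts + tv != total")
    if s.filtered_total != s.filtered_transitions + s.filtered_transversions:
        findings.append("snps: filtered ts + tv != total")
    t = report.strata
    if t.grand_total != t.filtered_subtotal + t.nonfiltered_subtotal:
        findings.append("strata: grand total != subtotal sum")
    part = report.partition
    if part["grand_total"] != part["mixed"] + part["blue_only"] + part["channel_only"]:
        findings.append("partition: grand total != mixed + single-species")
    e = report.estimate
    if e is not None:
        drift = abs(sum(e.estimates.values()) - e.population_total)
        if drift > max(1, len(e.estimates)):
            findings.append(
                f"estimate: extrapolated sum off by {drift} (> rounding bound "
                f"{len(e.estimates)})"
            )
        if t.filtered_subtotal and part["grand_total"] != t.filtered_subtotal:
            findings.append("partition grand total != filtered SNP subtotal")
    return findings


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------


def _load_reads(config: PipelineConfig, outdir: Path) -> list[ESTRead]:
    if config.sim is not None:
        genes, truth = simulate_transcriptome(config.sim)
        sim_reads, truth = sequence_reads(genes, truth, config.sim)
        write_reads_fasta(sim_reads, outdir / "reads.fasta")
        write_sidecar(truth, outdir / "reads.tsv")
        return [
            ESTRead(r.read_id, r.clone_id, r.species, r.end, r.sequence) for r in sim_reads
        ]
    meta = {p.read_id: p for p in read_sidecar(config.sidecar)}
    reads = []
    for rec in SeqIO.parse(config.reads_fasta, "fasta"):
        m = meta.get(rec.id)
        if m is None:
            logger.warning("read %s missing from side-car; species=unknown", rec.id)
            reads.append(ESTRead(rec.id, rec.id, "unknown", "5p", str(rec.seq).upper()))
        else:
            reads.append(ESTRead(rec.id, m.clone_id, m.species, m.end, str(rec.seq).upper()))
    return reads


def _write_contig_artifacts(result: AssemblyResult, outdir: Path) -> None:
    with open(outdir / "contigs.fasta", "w") as fh:
        for c in result.contigs:
            fh.write(f">{c.contig_id} depth={c.depth}\n{c.consensus}\n")
    with open(outdir / "contigs.aln", "w") as fh:
        for c in result.contigs:
            fh.write(f"# contig {c.contig_id} depth={c.depth}\n")
            for rid, orient, row in c.rows():
                fh.write(f">{rid} {orient}\n{row}\n")
    for name, ids in (
        ("singletons.txt", result.singletons),
        ("cluster_singletons.txt", result.cluster_singletons),
    ):
        (outdir / name).write_text("".join(f"{i}\n" for i in ids))


def run(config: PipelineConfig) -> SummaryReport:
    """Execute all stages in order and write artifacts to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("estminer").addHandler(log_handler)
    try:
        return _run_stages(config, outdir)
    finally:
        logging.getLogger("estminer").removeHandler(log_handler)
        log_handler.close()


def _run_stages(config: PipelineConfig, outdir: Path) -> SummaryReport:
    stage = "input"
    try:
        reads = _load_reads(config, outdir)
        reads_by_id = {r.read_id: r for r in reads}

        stage = "assembly"
        result = assemble(reads, config.thresholds, exhaustive_limit=config.exhaustive_limit)
        _write_contig_artifacts(result, outdir)

        stage = "variants"
        putative: list[PutativeVariant] = []
        for contig in result.contigs:
            putative.extend(detect_putative(call_columns(contig)))
        filtered = filter_snps(putative, config.schedule)
        consensi = {c.contig_id: c.consensus for c in result.contigs}
        total_bp = sum(len(s) for s in consensi.values())
        variants_to_frame(putative, filtered).to_csv(
            outdir / "variants.tsv", sep="\t", index=False
        )
        write_vcf(filtered, consensi, outdir / "variants.vcf")

        stage = "categorize"
        filtered, origins = categorize_assembly(
            result.contigs, filtered, reads_by_id, config.min_support
        )
        snp_origins = [origins[s.contig_id] for s in filtered]
        part = partition_totals(snp_origins)
        pool: dict[str, list[str]] = {}
        for s in filtered:
            if origins[s.contig_id] == "mixed" and s.category in MIXED_CATEGORIES:
                pool.setdefault(s.contig_id, []).append(s.category)
        estimate = None
        if pool:
            estimate = sample_and_estimate(
                pool,
                population_total=part.mixed_total,
                grand_total=part.grand_total,
                n_sample=config.n_sample,
                seed=config.seed,
            )
        pd.DataFrame(
            [
                {
                    "contig": s.contig_id,
                    "pos": s.consensus_position,
                    "category": s.category,
                    "blue_counts": ";".join(f"{k}:{v}" for k, v in sorted(s.counts_blue.items())),
                    "channel_counts": ";".join(
                        f"{k}:{v}" for k, v in sorted(s.counts_channel.items())
                    ),
                }
                for s in filtered
            ],
            columns=["contig", "pos", "category", "blue_counts", "channel_counts"],
        ).to_csv(outdir / "categories.tsv", sep="\t", index=False)

        stage = "annotate"
        uniques: dict[str, str] = dict(consensi)
        processed_by_id = {pr.read_id: pr for pr in result.processed}
        for rid in result.singletons + result.cluster_singletons:
            uniques[rid] = processed_by_id[rid].core
        msat_rows = []
        orf_rows = []
        fl_rows = []
        per_class: dict[int, int] = {k: 0 for k in (2, 3, 4, 5, 6)}
        seqs_with = set()
        seqs_flank = set()
        for sid in sorted(uniques):
            seq = uniques[sid]
            for locus in ann.annotate_microsatellites(seq, sid):
                per_class[len(locus.motif)] += 1
                seqs_with.add(sid)
                if locus.flanks_sufficient:
                    seqs_flank.add(sid)
                msat_rows.append(
                    {
                        "id": sid,
                        "motif": locus.motif,
                        "canonical": locus.canonical_motif,
                        "n_repeats": locus.repeat_count,
                        "start": locus.start,
                        "end": locus.end,
                        "flanks_ok": locus.flanks_sufficient,
                    }
                )
            for orf in ann.find_orfs(seq, sid):
                orf_rows.append(
                    {
                        "id": sid,
                        "strand": orf.strand,
                        "frame": orf.frame,
                        "start": orf.start,
                        "end": orf.end,
                        "has_start": orf.has_start_codon,
                        "has_stop": orf.has_stop_codon,
                    }
                )
            call = ann.predict_full_length(seq, sid)
            fl_rows.append(
                {
                    "id": sid,
                    "full_length": call.is_full_length,
                    "start_codon_pos": call.start_codon_pos,
                    "polya_pos": call.polya_pos,
                    "notes": call.notes,
                }
            )
        coord_note = "# coordinates are 0-based, half-open [start, end)\n"
        _write_tsv(
            _df(msat_rows, ["id", "motif", "canonical", "n_repeats", "start", "end", "flanks_ok"]),
            outdir / "microsatellites.tsv",
            coord_note,
        )
        _write_tsv(
            _df(orf_rows, ["id", "strand", "frame", "start", "end", "has_start", "has_stop"]),
            outdir / "orfs.tsv",
            coord_note,
        )
        _write_tsv(
            _df(fl_rows, ["id", "full_length", "start_codon_pos", "polya_pos", "notes"]),
            outdir / "full_length.tsv",
            coord_note,
        )

        stage = "report"
        msat_summary = MsatSummary(
            per_class_loci=per_class,
            total_loci=sum(per_class.values()),
            sequences_with_msat=len(seqs_with),
            sequences_with_sufficient_flanks=len(seqs_flank),
            n_unique_sequences=len(uniques),
        )
        snp_summary = summarize_snps(putative, filtered, max(total_bp, 1), config.schedule)
        strata = aggregate_depth_strata(
            putative,
            filtered,
            contig_depths={c.contig_id: c.depth for c in result.contigs},
            contig_lengths={c.contig_id: len(c.consensus) for c in result.contigs},
        )
        report = SummaryReport(
            assembly=AssemblyTable(
                n_input=result.summary.n_input,
                n_removed=result.summary.n_removed,
                n_for_assembly=result.summary.n_assembled_input,
                n_contigs=result.summary.n_contigs,
                n_singletons=result.summary.n_singletons,
                n_cluster_singletons=result.summary.n_cluster_singletons,
                unique=result.summary.unique,
                mean_reads_per_contig=result.summary.mean_reads_per_contig,
            ),
            msat=msat_summary,
            snps=snp_summary,
            strata=strata,
            estimate=estimate,
            partition={
                "mixed": part.mixed_total,
                "blue_only": part.blue_only_total,
                "channel_only": part.channel_only_total,
                "grand_total": part.grand_total,
            },
            config_hash=config.config_hash(),
            seed=config.seed,
        )
        write_report(report, outdir)
        return report
    except Exception as exc:
        snapshot = outdir / "failed_stage.txt"
        snapshot.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _df(rows: list[dict], columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=columns)


def _write_tsv(frame: pd.DataFrame, path: Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(comment)
        frame.to_csv(fh, sep="\t", index=False)


def write_report(report: SummaryReport, outdir: Path) -> None:
    header = (
        f"# estminer v{report.version}  config={report.config_hash}  seed={report.seed}\n"
    )
    report.strata.to_frame().to_csv(outdir / "table_depth_strata.tsv", sep="\t", index=False)
    s = report.snps
    _write_tsv(
        pd.DataFrame(
            [
                {"set": "putative", "transitions": s.putative_transitions,
                 "transversions": s.putative_transversions, "total_snps": s.putative_total,
                 "indels": s.putative_indels, "rate_per_kb": s.putative_rate_kb},
                {"set": "filtered", "transitions": s.filtered_transitions,
                 "transversions": s.filtered_transversions, "total_snps": s.filtered_total,
                 "indels": s.filtered_indels, "rate_per_kb": s.filtered_rate_kb},
            ]
        ),
        outdir / "table_snp_summary.tsv",
        "# SNP tallies by class; rate is per kb of total consensus length\n",
    )
    est = report.estimate
    est_rows = []
    if est is not None:
        for cat in MIXED_CATEGORIES:
            if cat in est.estimates:
                est_rows.append(
                    {
                        "category": cat,
                        "sampled": est.sampled_counts.get(cat, 0),
                        "estimated": est.estimates[cat],
                        "share_pct": est.shares[cat],
                    }
                )
    _df(est_rows, ["category", "sampled", "estimated", "share_pct"]).to_csv(
        outdir / "table_category_estimate.tsv", sep="\t", index=False
    )
    lines = [header]
    a = report.assembly
    lines += [
        "== Assembly ==",
        f"input reads\t{a.n_input}",
        f"short/simple removed\t{a.n_removed}",
        f"reads for assembly\t{a.n_for_assembly}",
        f"contigs\t{a.n_contigs}",
        f"singletons\t{a.n_singletons}",
        f"cluster singletons\t{a.n_cluster_singletons}",
        f"total unique sequences\t{a.unique}",
        f"mean reads per contig\t{a.mean_reads_per_contig:.2f}",
        "",
        "== Microsatellites ==",
        f"loci\t{report.msat.total_loci}",
    ]
    for k in sorted(report.msat.per_class_loci):
        lines.append(f"{k}-mer repeats\t{report.msat.per_class_loci[k]}")
    lines += [
        f"sequences with msat\t{report.msat.sequences_with_msat}",
        f"with sufficient flanks\t{report.msat.sequences_with_sufficient_flanks}",
        "",
        "== SNPs ==",
        f"putative transitions\t{report.snps.putative_transitions}",
        f"putative transversions\t{report.snps.putative_transversions}",
        f"putative total\t{report.snps.putative_total}",
        f"putative indels\t{report.snps.putative_indels}",
        f"filtered transitions\t{report.snps.filtered_transitions}",
        f"filtered transversions\t{report.snps.filtered_transversions}",
        f"filtered total\t{report.snps.filtered_total}",
        f"filtered rate (per kb)\t{report.snps.filtered_rate_kb}",
        "",
        "== SNP partition ==",
        f"mixed contigs\t{report.partition['mixed']}",
        f"blue-only contigs\t{report.partition['blue_only']}",
        f"channel-only contigs\t{report.partition['channel_only']}",
        f"grand total\t{report.partition['grand_total']}",
    ]
    if est is not None:
        lines += ["", "== Category estimate =="]
        for r in est_rows:
            lines.append(
                f"{r['category']}\t{r['sampled']}\t{r['estimated']}\t{r['share_pct']}%"
            )
    findings = verify_report(report)
    lines += ["", "== Consistency =="]
    lines += [f"FINDING: {f}" for f in findings] or ["all checks passed"]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
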