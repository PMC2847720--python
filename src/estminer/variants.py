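"""SNP and indel detection from contig alignment columns, with the
depth-dependent minor-allele filtering schedule.

A *putative* variant is any alignment column with two or more distinct base
symbols (one record per non-major allele) or with both gap and base symbols
(an indel). A *filtered* SNP is a substitution in a contig of depth >= 4
whose minor-allele count meets the depth interval's requirement:

    depth 4: 2    5-6: 2    7-8: 3    9-12: 4    13-30: 5    >=31: 6

The schedule is configurable; a flat preset (depth >= 4, minor >= 2) is
also provided. N bases carry no allele evidence and are excluded from both
counts and depth. Indels never pass filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .assembly import Contig

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class AlignmentIntegrityError(ValueError):
    pass


@dataclass
class ColumnCounts:
    contig_id: str
    alignment_index: int
    consensus_position: int | None  # absent for majority-gap columns
    counts: dict[str, int]  # symbol in {A,C,G,T,-} -> count; N excluded
    depth: int  # sum of non-N symbols


@dataclass
class PutativeVariant:
    contig_id: str
    consensus_position: int | None
    kind: str  # substitution | indel
    major_allele: str
    minor_allele: str
    minor_count: int
    depth: int
    substitution_class: str  # transition | transversion | none

    @property
    def alignment_ok(self) -> bool:
        return self.minor_count >= 1 and self.minor_count <= self.depth - self.minor_count


@dataclass
class ThresholdSchedule:
    """Ordered (depth_low, depth_high, min_minor_count) intervals from depth 4
    upward; ``depth_high`` of None means unbounded."""

    intervals: list[tuple[int, int | None, int]] = field(
        default_factory=lambda: [
            (4, 4, 2),
            (5, 6, 2),
            (7, 8, 3),
            (9, 12, 4),
            (13, 30, 5),
            (31, None, 6),
        ]
    )

    def __post_init__(self) -> None:
        prev_high = 3
        prev_req = 0
        for lo, hi, req in self.intervals:
            if lo != prev_high + 1:
                raise ValueError(f"schedule intervals not contiguous at depth {lo}")
            if hi is not None and hi < lo:
                raise ValueError(f"empty interval ({lo}, {hi})")
            if req < prev_req:
                raise ValueError("min_minor_count must be non-decreasing with depth")
            prev_high = hi if hi is not None else 10**9
            prev_req = req

    @classmethod
    def default(cls) -> "ThresholdSchedule":
        return cls()

    @classmethod
    def flat(cls) -> "ThresholdSchedule":
        """The flat filter: depth >= 4 with the minor allele seen at least twice."""
        return cls(intervals=[(4, None, 2)])


@dataclass
class FilteredSNP:
    contig_id: str
    consensus_position: int
    major_allele: str
    minor_allele: str
    minor_count: int
    depth: int
    substitution_class: str
    passed_schedule: bool = True
    counts_blue: dict[str, int] = field(default_factory=dict)
    counts_channel: dict[str, int] = field(default_factory=dict)
    category: str | None = None


def substitution_class(a: str, b: str) -> str:
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def call_columns(contig: Contig) -> list[ColumnCounts]:
    """Materialize per-column symbol counts; N symbols are excluded."""
    members = set(contig.orientations)
    for idx, col in enumerate(contig.columns):
        stray = set(col) - members
        if stray:
            raise AlignmentIntegrityError(
                f"contig {contig.contig_id}: column {idx} references "
                f"non-member rows {sorted(stray)}"
            )
    cons_pos_by_col = {col: i for i, col in enumerate(contig.cons_cols)}
    out = []
    for idx, col in enumerate(contig.columns):
        counts: dict[str, int] = {}
        for sym in col.values():
            if sym in "ACGT-":
                counts[sym] = counts.get(sym, 0) + 1
        out.append(
            ColumnCounts(
                contig_id=contig.contig_id,
                alignment_index=idx,
                consensus_position=cons_pos_by_col.get(idx),
                counts=counts,
                depth=sum(counts.values()),
            )
        )
    return out


def _major_base(base_counts: dict[str, int]) -> str:
    return max("ACGT", key=lambda b: (base_counts.get(b, 0), -ord(b)))


def detect_putative(columns: list[ColumnCounts]) -> list[PutativeVariant]:
    """Any column with >= 2 distinct bases yields substitution record(s), one
    per non-major allele; a column mixing gaps and bases yields an indel."""
    out: list[PutativeVariant] = []
    for col in columns:
        base_counts = {b: c for b, c in col.counts.items() if b in "ACGT"}
        gaps = col.counts.get("-", 0)
        if len(base_counts) >= 2:
            major = _major_base(base_counts)
            for allele in sorted(base_counts):
                if allele == major:
                    continue
                out.append(
                    PutativeVariant(
                        contig_id=col.contig_id,
                        consensus_position=col.consensus_position,
                        kind="substitution",
                        major_allele=major,
                        minor_allele=allele,
                        minor_count=base_counts[allele],
                        depth=col.depth,
                        substitution_class=substitution_class(major, allele),
                    )
                )
        if gaps > 0 and base_counts:
            n_bases = sum(base_counts.values())
            if gaps <= n_bases:
                major, minor, mc = _major_base(base_counts), "-", gaps
            else:
                major, minor, mc = "-", _major_base(base_counts), n_bases
            out.append(
                PutativeVariant(
                    contig_id=col.contig_id,
                    consensus_position=col.consensus_position,
                    kind="indel",
                    major_allele=major,
                    minor_allele=minor,
                    minor_count=mc,
                    depth=col.depth,
                    substitution_class="none",
                )
            )
    return out


def schedule_lookup(depth: int, schedule: ThresholdSchedule | None = None) -> int | None:
    """Required minor-allele count at ``depth``; None when not eligible
    (depths 2-3 never enter the filtered set)."""
    if depth < 2:
        raise ValueError(f"depth must be >= 2, got {depth}")
    schedule = schedule or ThresholdSchedule()
    if depth < schedule.intervals[0][0]:
        return None
    for lo, hi, req in schedule.intervals:
        if depth >= lo and (hi is None or depth <= hi):
            return req
    return None


def filter_snps(
    putative: list[PutativeVariant], schedule: ThresholdSchedule | None = None
) -> list[FilteredSNP]:
    """Substitutions meeting the depth-dependent minor-allele schedule;
    indels never pass. Output sorted by (contig_id, consensus_position)."""
    schedule = schedule or ThresholdSchedule()
    out: list[FilteredSNP] = []
    for v in putative:
        if v.kind != "substitution" or v.depth < 2:
            continue
        required = schedule_lookup(v.depth, schedule)
        if required is None or v.minor_count < required:
            continue
        if v.consensus_position is None:
            continue
        out.append(
            FilteredSNP(
                contig_id=v.contig_id,
                consensus_position=v.consensus_position,
                major_allele=v.major_allele,
                minor_allele=v.minor_allele,
                minor_count=v.minor_count,
                depth=v.depth,
                substitution_class=v.substitution_class,
            )
        )
    out.sort(key=lambda s: (s.contig_id, s.consensus_position))
    return out


def snp_rate_per_kb(snp_count: int, total_consensus_bp: int) -> float:
    """SNPs per kilobase of consensus sequence, to one decimal."""
    if total_consensus_bp <= 0:
        raise ValueError("total_consensus_bp must be > 0")
    return round(1000.0 * snp_count / total_consensus_bp, 1)


# ---------------------------------------------------------------------------
# summaries and exports
# ---------------------------------------------------------------------------


@dataclass
class SNPSummary:
    """Putative/filtered tallies split into transitions, transversions, indels."""

    putative_transitions: int
    putative_transversions: int
    putative_indels: int
    filtered_transitions: int
    filtered_transversions: int
    filtered_indels: int
    total_consensus_bp: int

    @property
    def putative_total(self) -> int:
        return self.putative_transitions + self.putative_transversions

    @property
    def filtered_total(self) -> int:
        return self.filtered_transitions + self.filtered_transversions

    @property
    def putative_rate_kb(self) -> float:
        return snp_rate_per_kb(self.putative_total, self.total_consensus_bp)

    @property
    def filtered_rate_kb(self) -> float:
        return snp_rate_per_kb(self.filtered_total, self.total_consensus_bp)


def summarize_snps(
    putative: list[PutativeVariant],
    filtered: list[FilteredSNP],
    total_consensus_bp: int,
    schedule: ThresholdSchedule | None = None,
) -> SNPSummary:
    schedule = schedule or ThresholdSchedule()
    pt = sum(1 for v in putative if v.substitution_class == "transition")
    pv = sum(1 for v in putative if v.substitution_class == "transversion")
    pi = sum(1 for v in putative if v.kind == "indel")
    ft = sum(1 for s in filtered if s.substitution_class == "transition")
    fv = sum(1 for s in filtered if s.substitution_class == "transversion")
    fi = sum(
        1
        for v in putative
        if v.kind == "indel"
        and v.depth >= 4
        and (schedule_lookup(v.depth, schedule) or math.inf) <= v.minor_count
    )
    return SNPSummary(pt, pv, pi, ft, fv, fi, total_consensus_bp)


def variants_to_frame(
    putative: list[PutativeVariant], filtered: list[FilteredSNP]
) -> pd.DataFrame:
    passed = {(s.contig_id, s.consensus_position, s.minor_allele) for s in filtered}
    rows = [
        {
            "contig": v.contig_id,
            "pos": v.consensus_position,
            "kind": v.kind,
            "major": v.major_allele,
            "minor": v.minor_allele,
            "depth": v.depth,
            "minor_count": v.minor_count,
            "class": v.substitution_class,
            "passed": (v.contig_id, v.consensus_position, v.minor_allele) in passed
            and v.kind == "substitution",
        }
        for v in putative
    ]
    return pd.DataFrame(
        rows,
        columns=["contig", "pos", "kind", "major", "minor", "depth", "minor_count", "class", "passed"],
    )


def write_vcf(filtered: list[FilteredSNP], consensi: dict[str, str], path) -> None:
    """Minimal VCF v4.2 export; the contig consensus supplies REF and
    0-based consensus positions become 1-based POS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=estminer\n")
        for cid in sorted(consensi):
            fh.write(f"##contig=<ID={cid},length={len(consensi[cid])}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Column depth">\n')
        fh.write('##INFO=<ID=MC,Number=1,Type=Integer,Description="Minor allele count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in filtered:
            ref = consensi.get(s.contig_id, "")
            refbase = ref[s.consensus_position] if s.consensus_position < len(ref) else "N"
            alt = s.minor_allele if s.minor_allele != refbase else s.major_allele
            fh.write(
                f"{s.contig_id}\t{s.consensus_position + 1}\t.\t{refbase}\t{alt}\t.\tPASS\t"
                f"DP={s.depth};MC={s.minor_count}\n"
            )
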