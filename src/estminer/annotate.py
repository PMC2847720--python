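"""Annotation of unique sequences: microsatellites, ORFs, full-length cDNAs.

Microsatellites are maximal *perfect* tandem repeats of a primitive 2-6 bp
motif meeting a class threshold (eight repeats for dinucleotides, five for
tri- through hexanucleotides); a locus is primer-ready when 50 bp of flank
exists on both sides. ORFs are found by exhaustive six-frame scanning for
stop-free codon runs, ATG-anchored where an ATG exists and optionally open
at the sequence edge (single-pass cDNA reads are often 5'-truncated). A
sequence is called a full-length cDNA when its longest forward-strand ORF
begins at an ATG and a poly(A) tail lies downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_MSAT_THRESHOLDS = {2: 8, 3: 5, 4: 5, 5: 5, 6: 5}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MicrosatelliteLocus:
    sequence_id: str
    motif: str
    canonical_motif: str
    repeat_count: int
    start: int  # 0-based half-open
    end: int
    flanks_sufficient: bool = False


@dataclass
class ORFRecord:
    sequence_id: str
    strand: str  # + | -
    frame: int  # 0 | 1 | 2 on the scanned strand
    start: int  # 0-based half-open on the forward strand
    end: int
    has_start_codon: bool
    has_stop_codon: bool

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class FullLengthCall:
    sequence_id: str
    is_full_length: bool
    start_codon_pos: int | None = None
    polya_pos: int | None = None
    notes: str = ""


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation over the motif and its reverse
    complement; collapses the rotational/strand ambiguity of a repeat unit."""
    rc = _revcomp(motif)
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(candidates)


def find_microsatellites(
    sequence: str,
    sequence_id: str = "",
    thresholds: dict[int, int] | None = None,
) -> list[MicrosatelliteLocus]:
    """Maximal perfect tandem repeats of primitive 2-6 bp motifs.

    Shorter units take precedence (an (AT)xN run is never re-reported as
    (ATAT)xM), reported loci do not overlap, and mononucleotide runs are
    never reported (a homopolymer has no primitive unit of length >= 2).
    """
    thresholds = thresholds or DEFAULT_MSAT_THRESHOLDS
    seq = sequence.upper()
    n = len(seq)
    occupied = [False] * n
    loci: list[MicrosatelliteLocus] = []
    for mlen in sorted(thresholds):
        min_reps = thresholds[mlen]
        i = 0
        while i + mlen * 2 <= n:
            unit = seq[i : i + mlen]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + mlen
            while j < n and seq[j] == seq[j - mlen] and seq[j] != "N":
                j += 1
            reps = (j - i) // mlen
            if reps >= min_reps:
                start, end = i, i + mlen * reps
                if not any(occupied[start:end]):
                    loci.append(
                        MicrosatelliteLocus(
                            sequence_id=sequence_id,
                            motif=unit,
                            canonical_motif=canonical_motif(unit),
                            repeat_count=reps,
                            start=start,
                            end=end,
                        )
                    )
                    for k in range(start, end):
                        occupied[k] = True
                i = end
            else:
                i = max(i + 1, j - mlen * 2 + 1)
    loci.sort(key=lambda m: (m.start, m.end))
    return loci


def flank_sufficiency(
    locus: MicrosatelliteLocus, sequence: str, flank_bp: int = 50
) -> bool:
    """True when at least ``flank_bp`` bases flank the repeat on both sides."""
    return locus.start >= flank_bp and (len(sequence) - locus.end) >= flank_bp


def annotate_microsatellites(
    sequence: str,
    sequence_id: str = "",
    thresholds: dict[int, int] | None = None,
    flank_bp: int = 50,
) -> list[MicrosatelliteLocus]:
    loci = find_microsatellites(sequence, sequence_id, thresholds)
    for locus in loci:
        locus.flanks_sufficient = flank_sufficiency(locus, sequence, flank_bp)
    return loci


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def find_orfs(
    sequence: str,
    sequence_id: str = "",
    min_orf_len: int = 51,
    allow_open_ends: bool = True,
) -> list[ORFRecord]:
    """Exhaustive six-frame scan for stop-free codon runs.

    Within each stop-delimited segment the ORF starts at the first ATG (the
    terminating stop codon is included in the span); with
    ``allow_open_ends`` a start-less segment truncated by the 5' edge of its
    frame also qualifies, and a segment running off the 3' edge ends without
    a stop. Records shorter than ``min_orf_len`` are suppressed.
    """
    seq = sequence.upper()
    n = len(seq)
    records: list[ORFRecord] = []
    for strand in "+-":
        s = seq if strand == "+" else _revcomp(seq)
        for frame in range(3):
            codon_starts = range(frame, n - 2, 3)
            seg_begin = 0  # codon index where the current segment starts
            codons = [s[i : i + 3] for i in codon_starts]
            for ci, codon in enumerate(codons + [None]):
                at_end = codon is None
                if not at_end and codon not in _STOPS:
                    continue
                seg_end = ci  # exclusive, not counting the stop
                has_stop = not at_end
                # first ATG within the segment
                atg = next(
                    (k for k in range(seg_begin, seg_end) if codons[k] == "ATG"), None
                )
                if atg is not None:
                    begin = atg
                    has_start = True
                elif allow_open_ends and seg_begin == 0:
                    begin = seg_begin
                    has_start = False
                else:
                    begin = None
                if begin is not None and seg_end + (1 if has_stop else 0) > begin:
                    nt_start = frame + 3 * begin
                    nt_end = frame + 3 * (seg_end + (1 if has_stop else 0))
                    if nt_end - nt_start >= min_orf_len:
                        if strand == "+":
                            f_start, f_end = nt_start, nt_end
                        else:
                            f_start, f_end = n - nt_end, n - nt_start
                        records.append(
                            ORFRecord(
                                sequence_id=sequence_id,
                                strand=strand,
                                frame=frame,
                                start=f_start,
                                end=f_end,
                                has_start_codon=has_start,
                                has_stop_codon=has_stop,
                            )
                        )
                seg_begin = ci + 1
    records.sort(key=lambda r: (r.strand, r.start, r.end))
    return records


def longest_orf(
    sequence: str, sequence_id: str = "", min_orf_len: int = 51, allow_open_ends: bool = True
) -> ORFRecord | None:
    """Maximum-length ORF; ties prefer the + strand, then the smaller start."""
    records = find_orfs(sequence, sequence_id, min_orf_len, allow_open_ends)
    if not records:
        return None
    return min(records, key=lambda r: (-r.length_bp, r.strand != "+", r.start))


# ---------------------------------------------------------------------------
# poly(A) and full-length calls
# ---------------------------------------------------------------------------


def detect_polya(
    sequence: str, min_run: int = 10, max_mismatch: int = 1, window: int = 50
) -> int | None:
    """Start of a terminal poly(A) run of >= ``min_run`` with at most
    ``max_mismatch`` non-A bases, searched within the final ``window`` bp.
    Returns the longest qualifying run's start, or None."""
    seq = sequence.upper()
    n = len(seq)
    for i in range(max(0, n - window), n - min_run + 1):
        tail = seq[i:]
        if seq[i] == "A" and sum(1 for c in tail if c != "A") <= max_mismatch:
            return i
    return None


def predict_full_length(
    sequence: str,
    sequence_id: str = "",
    min_orf_len: int = 51,
    polya_min_run: int = 10,
    polya_max_mismatch: int = 1,
) -> FullLengthCall:
    """Full length iff the longest forward-strand ORF starts at an ATG and a
    poly(A) tail lies downstream of that start."""
    fwd = [
        r
        for r in find_orfs(sequence, sequence_id, min_orf_len, allow_open_ends=True)
        if r.strand == "+"
    ]
    polya = detect_polya(sequence, polya_min_run, polya_max_mismatch)
    if not fwd:
        return FullLengthCall(sequence_id, False, None, polya, notes="no forward ORF")
    best = min(fwd, key=lambda r: (-r.length_bp, r.start))
    if not best.has_start_codon:
        return FullLengthCall(sequence_id, False, None, polya, notes="ORF lacks ATG")
    if polya is None:
        return FullLengthCall(sequence_id, False, best.start, None, notes="no poly(A)")
    if polya <= best.start:
        return FullLengthCall(
            sequence_id, False, best.start, polya, notes="poly(A) not downstream of ATG"
        )
    return FullLengthCall(sequence_id, True, best.start, polya, notes="ATG + poly(A)")
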