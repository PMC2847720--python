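"""EST preprocessing, clustering, and contig assembly.

The two-threshold scheme: reads are first grouped into clusters by
single-linkage on pairwise local similarity (default 88% identity over at
least 100 bp, optionally seeded by reference cDNAs at 80%), then each
cluster is assembled greedily into one or more contigs at a stricter
threshold (default 95% identity over at least 50 bp against the growing
consensus). Reads that fail assembly within a multi-read cluster are
*cluster singletons*; size-one clusters are *singletons*. Unique sequences
= contigs + singletons + cluster singletons.

Identity is defined as matching columns / aligned columns, gaps counting as
mismatches, over the local alignment span. Candidate pairs are found by
exact k-mer prefiltering (k=12, >=3 shared words); at small scale all pairs
are checked, with an anchor-free local aligner as fallback, so the
contract rests on the thresholds rather than the prefilter.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
from Bio import Align

from .annotate import find_microsatellites
from .sim import revcomp

logger = logging.getLogger(__name__)

_VALID_SPECIES = ("blue", "channel", "unknown")


@dataclass
class ESTRead:
    """One EST: a single-pass read with clone/species/end metadata."""

    read_id: str
    clone_id: str
    species: str  # blue | channel | unknown
    end: str  # 5p | 3p
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.species not in _VALID_SPECIES:
            raise ValueError(f"read {self.read_id}: bad species {self.species!r}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.read_id}: bad symbols {sorted(bad)}")


@dataclass
class AssemblyThresholds:
    seed_min_identity: float = 0.80
    cluster_min_identity: float = 0.88
    cluster_min_overlap: int = 100
    contig_min_identity: float = 0.95
    contig_min_overlap: int = 50
    min_read_length_after_trim: int = 100
    max_masked_fraction: float = 0.60

    def __post_init__(self) -> None:
        for name in ("seed_min_identity", "cluster_min_identity", "contig_min_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("cluster_min_overlap", "contig_min_overlap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ProcessedRead:
    read: ESTRead
    core: str  # terminal-masked runs trimmed, uppercase; used for alignment
    display: str  # original length, masked regions lower-cased
    masked_fraction: float

    @property
    def read_id(self) -> str:
        return self.read.read_id


@dataclass
class RemovedRead:
    read: ESTRead
    reason: str  # short | simple


@dataclass
class Cluster:
    cluster_id: str
    member_read_ids: list[str]
    seed_id: str | None = None

    @property
    def is_singleton(self) -> bool:
        return len(self.member_read_ids) == 1


@dataclass
class Contig:
    """A gapped multiple alignment of member reads plus its consensus.

    ``columns`` holds, per alignment column, the symbols of the reads
    covering it ('-' for an internal gap); reads absent from a column do not
    cover it. ``cons_cols`` maps each consensus position to its alignment
    column index; majority-gap columns carry no consensus position.
    """

    contig_id: str
    cluster_id: str
    columns: list[dict[str, str]]
    orientations: dict[str, str]  # read_id -> + | -
    consensus: str = ""
    cons_cols: list[int] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.orientations)

    @property
    def member_read_ids(self) -> list[str]:
        return sorted(self.orientations)

    def rows(self) -> list[tuple[str, str, str]]:
        """(read_id, orientation, gapped aligned sequence) per member row."""
        out = []
        for rid in self.member_read_ids:
            chars = [col.get(rid, "-") for col in self.columns]
            out.append((rid, self.orientations[rid], "".join(chars)))
        return out


# ---------------------------------------------------------------------------
# preprocessing: poly(A)/poly(T) and simple-repeat masking
# ---------------------------------------------------------------------------

_MIN_TAIL = 8
_MIN_HOMOPOLYMER = 10


def _terminal_run(seq: str, base: str, suffix: bool) -> int:
    """Length of the longest terminal run of ``base`` (>= 8 bp), allowing
    single-base interruptions when the run resumes immediately after."""
    s = seq[::-1] if suffix else seq
    if not s or s[0] != base:
        return 0
    i, n = 0, len(s)
    while i < n:
        if s[i] == base:
            i += 1
        elif i + 2 < n and s[i + 1] == base and s[i + 2] == base:
            i += 1  # isolated sequencing miscall inside the tail
        else:
            break
    return i if i >= _MIN_TAIL else 0


def _mask_simple(seq: str) -> list[bool]:
    """Mask homopolymer runs (>=10) and microsatellites at detection thresholds."""
    n = len(seq)
    mask = [False] * n
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= _MIN_HOMOPOLYMER:
            for k in range(i, j):
                mask[k] = True
        i = j
    for locus in find_microsatellites(seq):
        for k in range(locus.start, locus.end):
            mask[k] = True
    return mask


def preprocess(
    reads: list[ESTRead], thresholds: AssemblyThresholds | None = None
) -> tuple[list[ProcessedRead], list[RemovedRead]]:
    """Mask poly(A)/poly(T) tails and simple repeats; drop short/simple reads.

    A read is removed as *short* when fewer than ``min_read_length_after_trim``
    bases remain after trimming terminal masked runs, and as *simple* when
    masked plus ambiguous bases exceed ``max_masked_fraction`` of its length.
    """
    thresholds = thresholds or AssemblyThresholds()
    kept: list[ProcessedRead] = []
    removed: list[RemovedRead] = []
    for read in reads:
        seq = read.sequence.upper()
        n = len(seq)
        prefix = max(_terminal_run(seq, "A", suffix=False), _terminal_run(seq, "T", suffix=False))
        suffix = max(_terminal_run(seq, "A", suffix=True), _terminal_run(seq, "T", suffix=True))
        if prefix + suffix >= n:  # pure tail
            removed.append(RemovedRead(read, "short"))
            logger.info("removed %s: short (all tail)", read.read_id)
            continue
        mask = _mask_simple(seq)
        for k in range(prefix):
            mask[k] = True
        for k in range(n - suffix, n):
            mask[k] = True
        core = seq[prefix : n - suffix]
        if len(core) < thresholds.min_read_length_after_trim:
            removed.append(RemovedRead(read, "short"))
            logger.info("removed %s: short (%d bp after trim)", read.read_id, len(core))
            continue
        masked_n = sum(mask) + sum(1 for c in seq if c == "N")
        frac = masked_n / n
        if frac > thresholds.max_masked_fraction:
            removed.append(RemovedRead(read, "simple"))
            logger.info("removed %s: simple (%.0f%% masked)", read.read_id, 100 * frac)
            continue
        display = "".join(c.lower() if m else c for c, m in zip(seq, mask))
        kept.append(ProcessedRead(read=read, core=core, display=display, masked_fraction=frac))
    return kept, removed


# ---------------------------------------------------------------------------
# pairwise alignment: k-mer anchored edlib, local-aligner fallback
# ---------------------------------------------------------------------------

_K = 12
_MIN_KMER_HITS = 3
#: rescue anchor: any gapless overlap of >=100 bp at >=88% identity has a
#: run of >=7 exact matches (pigeonhole over <=12 mismatches), so a single
#: shared 7-mer suffices as a guaranteed-sensitivity anchor.
_K_RESCUE = 7

_fallback_aligner = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1, open_gap_score=-3, extend_gap_score=-1
)

# Affine-gap aligner used to re-derive the operations of an accepted merge:
# edlib's unit costs tie a mismatch pair with an insertion+deletion pair, which
# can scatter spurious gap columns through divergent regions; affine costs
# keep substitutions as substitutions.
_refine_aligner = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-1, open_gap_score=-4, extend_gap_score=-1
)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            idx[w].append(i)
    return idx


class SeqIndex:
    """Cached k-mer position indexes for one target sequence."""

    def __init__(self, seq: str):
        self.seq = seq
        self.k12 = _kmer_positions(seq, _K)
        self._k7: dict[str, list[int]] | None = None

    @property
    def k7(self) -> dict[str, list[int]]:
        if self._k7 is None:
            self._k7 = _kmer_positions(self.seq, _K_RESCUE)
        return self._k7


def _find_anchor(
    query: str, target_index: dict[str, list[int]], k: int, min_hits: int
) -> int | None:
    """Most-voted query-minus-target diagonal, or None below the hit floor."""
    votes: Counter[int] = Counter()
    for i in range(len(query) - k + 1):
        w = query[i : i + k]
        for j in target_index.get(w, ()):
            votes[i - j] += 1
    if not votes:
        return None
    # pool votes over nearby diagonals to tolerate small indel drift
    pooled: Counter[int] = Counter()
    for d, v in votes.items():
        for dd, vv in votes.items():
            if abs(dd - d) <= 8:
                pooled[d] += vv
    diag, n = max(pooled.items(), key=lambda kv: (kv[1], -abs(kv[0])))
    if n < min_hits:
        return None
    return max((votes[d], -abs(d - diag), d) for d in votes if abs(d - diag) <= 8)[2]


@dataclass
class OverlapAlignment:
    identity: float
    columns: int
    c_start: int  # alignment window start on the target/consensus
    r_start: int  # alignment window start on the query/read
    ops: list[tuple[str, int]]  # M (read char placed), D (target only), I (read only)
    trim_overhang: bool = False  # local-route result: splice only the window

    @property
    def target_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MD")

    @property
    def query_span(self) -> int:
        return sum(n for op, n in self.ops if op in "MI")


def _edlib_ops(cigar: str) -> list[tuple[str, int]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            if ch in "=X":
                if ops and ops[-1][0] == "M":
                    ops[-1] = ("M", ops[-1][1] + n)
                else:
                    ops.append(("M", n))
            elif ch == "I":  # extra base in query/read
                ops.append(("I", n))
            elif ch == "D":  # extra base in target/consensus
                ops.append(("D", n))
    return ops


def _anchored_align(
    target: str, query: str, tindex: SeqIndex, min_overlap: int
) -> OverlapAlignment | None:
    d = _find_anchor(query, tindex.k12, _K, _MIN_KMER_HITS)
    if d is None:
        d = _find_anchor(query, tindex.k7, _K_RESCUE, 1)
    if d is None:
        return None
    t_start = max(0, -d)
    q_start = max(0, d)
    ov = min(len(target) - t_start, len(query) - q_start)
    if ov < min_overlap:
        return None
    res = edlib.align(
        query[q_start : q_start + ov], target[t_start : t_start + ov], mode="NW", task="path"
    )
    ops = _edlib_ops(res["cigar"])
    columns = sum(n for _, n in ops)
    identity = (columns - res["editDistance"]) / columns if columns else 0.0
    return OverlapAlignment(identity, columns, t_start, q_start, ops)


def _refine_ops(t_win: str, q_win: str) -> list[tuple[str, int]]:
    """Affine-gap global realignment of an accepted merge window."""
    aln = _refine_aligner.align(t_win, q_win)[0]
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    prev_t = prev_q = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > prev_t:
            ops.append(("D", int(ts - prev_t)))
        if qs > prev_q:
            ops.append(("I", int(qs - prev_q)))
        ops.append(("M", int(te - ts)))
        prev_t, prev_q = int(te), int(qe)
    if len(t_win) > prev_t:
        ops.append(("D", len(t_win) - prev_t))
    if len(q_win) > prev_q:
        ops.append(("I", len(q_win) - prev_q))
    return ops


def _local_align(target: str, query: str, min_overlap: int) -> OverlapAlignment | None:
    try:
        aln = _fallback_aligner.align(target, query)[0]
    except (IndexError, OverflowError):
        return None
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns < min_overlap:
        return None
    identity = counts.identities / columns if columns else 0.0
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[str, int]] = []
    for bi in range(len(t_blocks)):
        if bi > 0:
            dt = t_blocks[bi][0] - t_blocks[bi - 1][1]
            dq = q_blocks[bi][0] - q_blocks[bi - 1][1]
            if dt:
                ops.append(("D", int(dt)))
            if dq:
                ops.append(("I", int(dq)))
        ops.append(("M", int(t_blocks[bi][1] - t_blocks[bi][0])))
    return OverlapAlignment(
        identity, columns, int(t_blocks[0][0]), int(q_blocks[0][0]), ops, trim_overhang=True
    )


def align_overlap(
    target: str,
    query: str,
    min_overlap: int,
    allow_fallback: bool = True,
    tindex: SeqIndex | None = None,
) -> OverlapAlignment | None:
    """Best overlap alignment of ``query`` against ``target`` (one orientation)."""
    if tindex is None:
        tindex = SeqIndex(target)
    res = _anchored_align(target, query, tindex, min_overlap)
    if res is None and allow_fallback:
        res = _local_align(target, query, min_overlap)
    return res


def best_passing(
    target: str,
    query: str,
    min_identity: float,
    min_overlap: int,
    allow_fallback: bool = True,
    tindex: SeqIndex | None = None,
) -> OverlapAlignment | None:
    """Alignment meeting the thresholds, or None. The anchored global window
    is tried first; when it fails (e.g. the reads share only a partial
    overlap and diverge outside it) the affine local aligner decides."""
    if tindex is None:
        tindex = SeqIndex(target)
    res = _anchored_align(target, query, tindex, min_overlap)
    if res and res.identity >= min_identity and res.columns >= min_overlap:
        return res
    if allow_fallback:
        res = _local_align(target, query, min_overlap)
        if res and res.identity >= min_identity and res.columns >= min_overlap:
            return res
    return None


def pair_passes(
    a: str,
    b: str,
    min_identity: float,
    min_overlap: int,
    allow_fallback: bool = True,
    a_index: SeqIndex | None = None,
    b_rc: str | None = None,
) -> bool:
    """Whether two sequences meet an identity/overlap threshold in either
    orientation."""
    if a_index is None:
        a_index = SeqIndex(a)
    for q in (b, b_rc if b_rc is not None else revcomp(b)):
        if best_passing(a, q, min_identity, min_overlap, allow_fallback, tindex=a_index):
            return True
    return False


# ---------------------------------------------------------------------------
# clustering (single linkage)
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _candidate_pairs(
    processed: list[ProcessedRead], exhaustive_limit: int
) -> set[tuple[int, int]]:
    n = len(processed)
    if n <= exhaustive_limit:
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    shared: Counter[tuple[int, int]] = Counter()
    kmer_owners: dict[str, list[int]] = defaultdict(list)
    for i, pr in enumerate(processed):
        for seq in (pr.core, revcomp(pr.core)):
            seen = set()
            for p in range(len(seq) - _K + 1):
                w = seq[p : p + _K]
                if "N" not in w and w not in seen:
                    seen.add(w)
                    kmer_owners[w].append(i)
    for owners in kmer_owners.values():
        uniq = sorted(set(owners))
        if len(uniq) > 50:  # highly repetitive word; skip to bound cost
            continue
        for x in range(len(uniq)):
            for y in range(x + 1, len(uniq)):
                shared[(uniq[x], uniq[y])] += 1
    return {pair for pair, c in shared.items() if c >= _MIN_KMER_HITS}


def cluster_reads(
    processed: list[ProcessedRead],
    thresholds: AssemblyThresholds | None = None,
    seeds: dict[str, str] | None = None,
    exhaustive_limit: int = 200,
) -> list[Cluster]:
    """Single-linkage clustering of reads, optionally seeded by references.

    Reads matching a seed at ``seed_min_identity`` over ``cluster_min_overlap``
    join that seed's cluster; the remainder are joined transitively whenever a
    pair aligns at ``cluster_min_identity`` over ``cluster_min_overlap`` in
    either orientation.
    """
    thresholds = thresholds or AssemblyThresholds()
    seed_clusters: dict[str, list[str]] = {}
    pool: list[ProcessedRead] = []
    if seeds:
        seed_indexes = {sid: SeqIndex(s) for sid, s in seeds.items()}
        for pr in processed:
            best = None
            for seed_id in sorted(seeds):
                for q in (pr.core, revcomp(pr.core)):
                    res = best_passing(
                        seeds[seed_id],
                        q,
                        thresholds.seed_min_identity,
                        thresholds.cluster_min_overlap,
                        tindex=seed_indexes[seed_id],
                    )
                    if res is not None and (best is None or res.identity > best[1]):
                        best = (seed_id, res.identity)
            if best:
                seed_clusters.setdefault(best[0], []).append(pr.read_id)
            else:
                pool.append(pr)
    else:
        pool = list(processed)

    uf = _UnionFind(range(len(pool)))
    indexes = [SeqIndex(pr.core) for pr in pool]
    rcs = [revcomp(pr.core) for pr in pool]
    for i, j in sorted(_candidate_pairs(pool, exhaustive_limit)):
        if uf.find(i) == uf.find(j):
            continue
        if pair_passes(
            pool[i].core,
            pool[j].core,
            thresholds.cluster_min_identity,
            thresholds.cluster_min_overlap,
            allow_fallback=len(pool) <= exhaustive_limit,
            a_index=indexes[i],
            b_rc=rcs[j],
        ):
            uf.union(i, j)

    groups: dict[int, list[str]] = defaultdict(list)
    for i, pr in enumerate(pool):
        groups[uf.find(i)].append(pr.read_id)

    clusters: list[Cluster] = []
    ordered = [sorted(m) for m in groups.values()]
    for seed_id in sorted(seed_clusters):
        ordered.append(sorted(seed_clusters[seed_id]))
    ordered.sort(key=lambda m: m[0])
    k = 0
    for members in ordered:
        seed_id = None
        for sid, m in seed_clusters.items():
            if sorted(m) == members:
                seed_id = sid
                break
        clusters.append(Cluster(cluster_id=f"cl{k:05d}", member_read_ids=members, seed_id=seed_id))
        k += 1
    return clusters


# ---------------------------------------------------------------------------
# contig assembly (greedy, longest-first, against the growing consensus)
# ---------------------------------------------------------------------------


def consensus(contig: Contig) -> str:
    """Per-column majority base; ties broken A<C<G<T, base preferred over gap;
    majority-gap columns are dropped from the consensus (deletion columns)."""
    cons, cons_cols = _consensus_of_columns(contig.columns)
    return cons


def _consensus_of_columns(columns: list[dict[str, str]]) -> tuple[str, list[int]]:
    cons = []
    cons_cols = []
    for idx, col in enumerate(columns):
        counts = Counter(v for v in col.values() if v in "ACGT-")
        if not counts:
            continue
        gap = counts.get("-", 0)
        base_counts = [(counts.get(b, 0), b) for b in "ACGT"]
        best_n, best_b = max(base_counts, key=lambda t: (t[0], -ord(t[1])))
        if best_n == 0 or gap > best_n:
            continue  # majority-gap (deletion) column: no consensus base
        cons.append(best_b)
        cons_cols.append(idx)
    return "".join(cons), cons_cols


def _refresh(contig: Contig) -> None:
    contig.consensus, contig.cons_cols = _consensus_of_columns(contig.columns)


def _normalize_rows(columns: list[dict[str, str]], read_ids) -> None:
    """Fill internal gaps and strip padding so each row spans exactly its
    first..last base column."""
    for rid in read_ids:
        first = last = None
        for i, col in enumerate(columns):
            if col.get(rid, "-") in "ACGTN":
                if first is None:
                    first = i
                last = i
        for i, col in enumerate(columns):
            if first is not None and first <= i <= last:
                col.setdefault(rid, "-")
            elif rid in col and col[rid] == "-":
                del col[rid]


def _merge_read(contig: Contig, read_id: str, seq: str, aln: OverlapAlignment) -> None:
    """Splice an aligned read into the contig's column list."""
    old = contig.columns
    cons_cols = contig.cons_cols
    new_cols: list[dict[str, str]] = []
    ci, ri = aln.c_start, aln.r_start  # consensus / read cursors
    oi = 0  # cursor over old master columns

    def copy_until(master_idx: int, read_covers: bool) -> None:
        nonlocal oi
        while oi < master_idx:
            col = old[oi]
            if read_covers:
                col[read_id] = "-"
            new_cols.append(col)
            oi += 1

    # columns before the window; then the read's left overhang (new columns)
    start_master = cons_cols[ci] if ci < len(cons_cols) else len(old)
    copy_until(start_master, read_covers=False)
    if not aln.trim_overhang:
        for p in range(ri):
            new_cols.append({read_id: seq[p]})
    for op, n in aln.ops:
        if op == "M":
            for _ in range(n):
                copy_until(cons_cols[ci], read_covers=True)
                col = old[oi]
                col[read_id] = seq[ri]
                new_cols.append(col)
                oi += 1
                ci += 1
                ri += 1
        elif op == "D":  # consensus base absent from read
            for _ in range(n):
                copy_until(cons_cols[ci], read_covers=True)
                col = old[oi]
                col[read_id] = "-"
                new_cols.append(col)
                oi += 1
                ci += 1
        elif op == "I":  # read base absent from consensus: new column
            for _ in range(n):
                new_cols.append({read_id: seq[ri]})
                ri += 1
    # read right overhang, then remaining master columns
    end_master = cons_cols[ci] if ci < len(cons_cols) else len(old)
    if aln.trim_overhang:
        copy_until(len(old), read_covers=False)
    else:
        copy_until(end_master, read_covers=ri < len(seq))
        for p in range(ri, len(seq)):
            new_cols.append({read_id: seq[p]})
        copy_until(len(old), read_covers=False)

    contig.columns = new_cols
    _normalize_rows(contig.columns, list(contig.orientations) + [read_id])
    _refresh(contig)


def _try_merge(
    contig: Contig, pr: ProcessedRead, thresholds: AssemblyThresholds, allow_fallback: bool
) -> bool:
    best: tuple[OverlapAlignment, str, str] | None = None
    for orient, seq in (("+", pr.core), ("-", revcomp(pr.core))):
        res = best_passing(
            contig.consensus,
            seq,
            thresholds.contig_min_identity,
            thresholds.contig_min_overlap,
            allow_fallback,
        )
        if res is not None:
            if best is None or res.identity > best[0].identity:
                best = (res, orient, seq)
    if best is None:
        return False
    aln, orient, seq = best
    if not aln.trim_overhang:
        # re-derive operations with affine gap costs before splicing
        t_win = contig.consensus[aln.c_start : aln.c_start + aln.target_span]
        q_win = seq[aln.r_start : aln.r_start + aln.query_span]
        aln.ops = _refine_ops(t_win, q_win)
    contig.orientations[pr.read_id] = orient
    _merge_read(contig, pr.read_id, seq, aln)
    return True


def assemble_cluster(
    cluster: Cluster,
    processed_by_id: dict[str, ProcessedRead],
    thresholds: AssemblyThresholds | None = None,
    allow_fallback: bool = True,
) -> tuple[list[Contig], list[str]]:
    """Greedy overlap-merge within one cluster.

    Reads are taken longest-first; a read joins a growing contig only when it
    aligns to the current consensus at ``contig_min_identity`` over
    ``contig_min_overlap``. Reads that join no contig become cluster
    singletons. Multiple contigs may be produced per cluster.
    """
    thresholds = thresholds or AssemblyThresholds()
    members = sorted(
        (processed_by_id[rid] for rid in cluster.member_read_ids),
        key=lambda pr: (-len(pr.core), pr.read_id),
    )
    contigs: list[Contig] = []
    singles: list[str] = []
    pending = list(members)
    part = 0
    while pending:
        seed = pending.pop(0)
        contig = Contig(
            contig_id=f"{cluster.cluster_id}.{part}",
            cluster_id=cluster.cluster_id,
            columns=[{seed.read_id: c} for c in seed.core],
            orientations={seed.read_id: "+"},
        )
        _refresh(contig)
        added = True
        while added:
            added = False
            for pr in list(pending):
                if _try_merge(contig, pr, thresholds, allow_fallback):
                    pending.remove(pr)
                    added = True
        if contig.depth >= 2:
            contigs.append(contig)
            part += 1
        else:
            singles.append(seed.read_id)
    return contigs, sorted(singles)


# ---------------------------------------------------------------------------
# whole-assembly driver and summary
# ---------------------------------------------------------------------------


@dataclass
class AssemblySummary:
    n_input: int
    n_removed: int
    n_assembled_input: int
    n_contigs: int
    n_singletons: int
    n_cluster_singletons: int
    unique: int
    mean_reads_per_contig: float


def unique_sequence_count(
    contigs: list[Contig], singletons: list[str], cluster_singletons: list[str]
) -> AssemblySummary:
    """Unique sequences = contigs + singletons + cluster singletons."""
    depths = [c.depth for c in contigs]
    return AssemblySummary(
        n_input=0,
        n_removed=0,
        n_assembled_input=sum(depths) + len(singletons) + len(cluster_singletons),
        n_contigs=len(contigs),
        n_singletons=len(singletons),
        n_cluster_singletons=len(cluster_singletons),
        unique=len(contigs) + len(singletons) + len(cluster_singletons),
        mean_reads_per_contig=(sum(depths) / len(depths)) if depths else 0.0,
    )


@dataclass
class AssemblyResult:
    processed: list[ProcessedRead]
    removed: list[RemovedRead]
    clusters: list[Cluster]
    contigs: list[Contig]
    singletons: list[str]  # reads alone in their cluster
    cluster_singletons: list[str]  # unassembled reads of multi-read clusters
    summary: AssemblySummary


def assemble(
    reads: list[ESTRead],
    thresholds: AssemblyThresholds | None = None,
    seeds: dict[str, str] | None = None,
    exhaustive_limit: int = 200,
) -> AssemblyResult:
    """Preprocess, cluster, and assemble a read set end to end."""
    thresholds = thresholds or AssemblyThresholds()
    processed, removed = preprocess(reads, thresholds)
    clusters = cluster_reads(processed, thresholds, seeds, exhaustive_limit)
    by_id = {pr.read_id: pr for pr in processed}
    contigs: list[Contig] = []
    singletons: list[str] = []
    cluster_singletons: list[str] = []
    allow_fallback = len(processed) <= exhaustive_limit
    for cluster in clusters:
        if cluster.is_singleton:
            singletons.append(cluster.member_read_ids[0])
            continue
        ctgs, singles = assemble_cluster(cluster, by_id, thresholds, allow_fallback)
        contigs.extend(ctgs)
        cluster_singletons.extend(singles)
    summary = unique_sequence_count(contigs, sorted(singletons), sorted(cluster_singletons))
    summary.n_input = len(reads)
    summary.n_removed = len(removed)
    return AssemblyResult(
        processed=processed,
        removed=removed,
        clusters=clusters,
        contigs=contigs,
        singletons=sorted(singletons),
        cluster_singletons=sorted(cluster_singletons),
        summary=summary,
    )
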