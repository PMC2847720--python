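"""Microsatellite, ORF, poly(A) and full-length annotation, checked against
regex and exhaustive frame-scan oracles."""

import re

import numpy as np
import pytest

from estminer.annotate import (
    DEFAULT_MSAT_THRESHOLDS,
    canonical_motif,
    detect_polya,
    find_microsatellites,
    find_orfs,
    flank_sufficiency,
    longest_orf,
    predict_full_length,
)
from estminer.sim import revcomp

from conftest import random_dna

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def regex_msat_oracle(seq: str) -> set[tuple[int, int, str]]:
    """(start, end, motif) of maximal perfect repeats meeting the class
    thresholds, found with the regex engine; shortest unit first, overlaps
    masked, runs truncated to whole units, primitive units only."""
    occupied = [False] * len(seq)
    out = set()
    for mlen in sorted(DEFAULT_MSAT_THRESHOLDS):
        min_reps = DEFAULT_MSAT_THRESHOLDS[mlen]
        pattern = re.compile(rf"([ACGT]{{{mlen}}})\1{{{min_reps - 1},}}")
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if not m:
                break
            unit = m.group(1)
            primitive = not any(
                mlen % d == 0 and unit == unit[:d] * (mlen // d) for d in range(1, mlen)
            )
            start = m.start()
            end = start + ((m.end() - start) // mlen) * mlen
            if primitive and not any(occupied[start:end]):
                out.add((start, end, unit))
                for k in range(start, end):
                    occupied[k] = True
            pos = start + 1
        # re-scan from inside matches: regex search is leftmost-greedy, a
        # shifted-phase run can hide behind a rejected non-primitive match
    return out


def bruteforce_orf_oracle(seq: str, min_len: int = 51, open_ends: bool = True):
    """(strand, start, end, has_start, has_stop) by direct codon enumeration."""
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            starts = list(range(frame, n - 2, 3))
            codons = [s[i : i + 3] for i in starts]
            seg = []
            for idx, codon in enumerate(codons + [None]):
                if codon is not None and codon not in STOPS:
                    seg.append(idx)
                    continue
                has_stop = codon is not None
                if seg or has_stop:
                    atg = next((k for k in seg if codons[k] == "ATG"), None)
                    begin = None
                    if atg is not None:
                        begin, has_start = atg, True
                    elif open_ends and seg and seg[0] == 0:
                        begin, has_start = seg[0], False
                    if begin is not None:
                        end_codon = (seg[-1] + 1 if seg else begin) + (1 if has_stop else 0)
                        if seg:
                            end_codon = seg[-1] + 1 + (1 if has_stop else 0)
                        nt0 = frame + 3 * begin
                        nt1 = frame + 3 * end_codon
                        if nt1 - nt0 >= min_len:
                            if strand == "+":
                                out.add((strand, nt0, nt1, has_start, has_stop))
                            else:
                                out.add((strand, n - nt1, n - nt0, has_start, has_stop))
                seg = []
    return out


def _impl_orfs(seq, **kw):
    return {
        (r.strand, r.start, r.end, r.has_start_codon, r.has_stop_codon)
        for r in find_orfs(seq, **kw)
    }


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------


class TestMicrosatellites:
    def test_eight_dinucleotide_repeats_reported(self):
        rng = np.random.default_rng(0)
        seq = "GGC" + random_dna(rng, 60).replace("AC", "GT") + "AC" * 8 + "TG" + random_dna(rng, 60)
        loci = find_microsatellites(seq)
        hits = [l for l in loci if l.motif in ("AC", "CA")]
        assert len(hits) == 1
        assert hits[0].repeat_count == 8

    def test_seven_dinucleotide_repeats_below_threshold(self):
        seq = "GGCTTGGA" + "AC" * 7 + "TTGGATCC"
        assert [l for l in find_microsatellites(seq) if l.motif in ("AC", "CA")] == []

    def test_five_trinucleotide_repeats_reported(self):
        seq = "GGCCGG" + "AAT" * 5 + "CCGGCC"
        (locus,) = find_microsatellites(seq)
        assert locus.motif == "AAT" and locus.repeat_count == 5

    def test_homopolymer_never_reported(self):
        assert find_microsatellites("G" + "A" * 40 + "C") == []

    def test_subrepeat_reported_under_shortest_unit(self):
        seq = "GGCCGG" + "AT" * 12 + "CCGGCC"
        (locus,) = find_microsatellites(seq)
        assert locus.motif == "AT"
        assert locus.repeat_count == 12  # not reported again as (ATAT) x 6

    def test_canonical_motif_collapses_rotation_and_strand(self):
        assert canonical_motif("AC") == canonical_motif("CA") == canonical_motif("GT") == canonical_motif("TG")
        assert canonical_motif("AAT") == canonical_motif("ATA") == canonical_motif("ATT")

    def test_reported_loci_reverify_as_perfect_repeats(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = random_dna(rng, 2000)
            for locus in find_microsatellites(seq):
                run = seq[locus.start : locus.end]
                assert run == locus.motif * locus.repeat_count

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            seq = random_dna(rng, 2000)
            # plant a few repeats so positives actually occur
            for planted in ("AC" * 9, "AAT" * 6, "ACGT" * 5):
                p = int(rng.integers(0, len(seq) - len(planted)))
                seq = seq[:p] + planted + seq[p + len(planted):]
            got = {(l.start, l.end, l.motif) for l in find_microsatellites(seq)}
            assert got == regex_msat_oracle(seq)


class TestFlanks:
    def _locus(self, start, end):
        from estminer.annotate import MicrosatelliteLocus

        return MicrosatelliteLocus("s", "AC", "AC", (end - start) // 2, start, end)

    def test_exact_fifty_is_sufficient(self):
        assert flank_sufficiency(self._locus(50, 66), "N" * 200) is True

    def test_forty_nine_left_is_insufficient(self):
        assert flank_sufficiency(self._locus(49, 65), "N" * 200) is False

    def test_forty_nine_right_is_insufficient(self):
        assert flank_sufficiency(self._locus(100, 151), "N" * 200) is False


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


class TestORFs:
    def test_atg_polyA_run_stop(self):
        seq = "TAG" + "ATG" + "AAA" * 20 + "TAA"
        planted = [r for r in find_orfs(seq) if r.start == 3 and r.strand == "+"]
        assert len(planted) == 1
        orf = planted[0]
        assert orf.end == 69 and orf.length_bp == 66
        assert orf.has_start_codon and orf.has_stop_codon
        closed = find_orfs(seq, allow_open_ends=False)
        assert [(r.start, r.end) for r in closed] == [(3, 69)]

    def test_stop_saturated_sequence_has_no_orf(self):
        assert find_orfs("TAATTAGTTAGC" * 10) == []

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = random_dna(rng, 2000)
            assert _impl_orfs(seq) == bruteforce_orf_oracle(seq)
            assert _impl_orfs(seq, allow_open_ends=False) == bruteforce_orf_oracle(
                seq, open_ends=False
            )

    def test_reverse_complement_consistency(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            seq = random_dna(rng, 1500)
            fwd = _impl_orfs(seq)
            rev = _impl_orfs(revcomp(seq))
            n = len(seq)
            mirrored = {
                ("-" if s == "+" else "+", n - e, n - b, st, sp)
                for s, b, e, st, sp in rev
            }
            assert fwd == mirrored

    def test_longest_orf_tie_break(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 900)
        best = longest_orf(seq)
        if best is not None:
            assert all(best.length_bp >= r.length_bp for r in find_orfs(seq))


class TestFullLength:
    def _cds(self):
        # codon unit chosen so the shifted frames hit stops early: the planted
        # ATG-anchored ORF is then the longest forward ORF; the terminal stop
        # is TAG so the poly(A) run starts exactly at the appended tail
        return "TAG" + "ATG" + "ACTAGCCTG" * 8 + "TAG"

    def test_orf_plus_polya_is_full_length(self):
        seq = self._cds() + "A" * 15
        call = predict_full_length(seq)
        assert call.is_full_length
        assert call.start_codon_pos == 3
        # the run covers the appended tail (the 1-mismatch rule may absorb
        # A-containing bases of the stop codon just upstream)
        assert call.polya_pos is not None
        assert call.polya_pos <= len(seq) - 15

    def test_missing_polya_is_not_full_length(self):
        call = predict_full_length(self._cds() + "GCGC")
        assert not call.is_full_length

    def test_startless_orf_plus_polya_is_not_full_length(self):
        seq = "GCTGAAGCTGCA" * 8 + "A" * 15  # open run, no ATG
        call = predict_full_length(seq)
        assert not call.is_full_length

    def test_polya_detection_window_and_mismatch(self):
        assert detect_polya("G" * 100 + "A" * 15) == 100
        assert detect_polya("G" * 100 + "A" * 7 + "G" + "A" * 7) == 100
        assert detect_polya("G" * 100 + "A" * 9) is None
        assert detect_polya("A" * 15 + "G" * 100) is None  # not terminal


# ---------------------------------------------------------------------------
# planted-feature recovery on simulated genes
# ---------------------------------------------------------------------------


class TestPlantedRecovery:
    def test_planted_repeats_and_orfs_recovered_exactly(self):
        from estminer.sim import SimConfig, simulate_transcriptome

        config = SimConfig(n_genes=60, seed=21, msat_probability=1.0,
                           gene_length_min=700, gene_length_max=1200)
        genes, truth = simulate_transcriptome(config)
        n_msat = 0
        for gid, seq in genes.items():
            gt = truth.genes[gid]
            if gt.msat is not None:
                n_msat += 1
                hits = [
                    l
                    for l in find_microsatellites(seq)
                    if l.start == gt.msat.start and l.end == gt.msat.end
                ]
                assert len(hits) == 1, f"{gid}: planted repeat not recovered"
                assert hits[0].repeat_count == gt.msat.repeat_count
            planted = [
                r
                for r in find_orfs(seq)
                if r.strand == "+" and r.start == gt.orf.start and r.end == gt.orf.end
            ]
            assert len(planted) == 1, f"{gid}: planted ORF not recovered"
            assert planted[0].has_start_codon and planted[0].has_stop_codon
        assert n_msat >= 50  # msat_probability = 1, minus cramped genes
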