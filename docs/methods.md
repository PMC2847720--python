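# Methods

`estminer` mines molecular markers from inter-specific collections of
expressed sequence tags (ESTs): single-pass reads from the 5' or 3' end of
cDNA clones, gathered in parallel from two closely related species (called
*blue* and *channel* throughout, after the two Ictalurid catfishes that
motivate the default parameters). The pipeline assembles the pooled reads
into contigs, calls sequence variants from the alignment columns, filters
them with a depth-dependent minor-allele rule, attributes each surviving SNP
to between-species divergence or within-species polymorphism, and annotates
the unique sequences with microsatellites, open reading frames and
full-length cDNA calls.

## Assembly model

Reads are preprocessed by masking terminal poly(A)/poly(T) runs (>= 8 bp,
single-base interruptions allowed when the run resumes immediately) and
low-complexity tracts (homopolymers >= 10 bp and microsatellites at the
detection thresholds below). A read is discarded as *short* when fewer than
100 bp remain after trimming terminal masked runs, and as *simple* when
masked plus ambiguous bases exceed 60% of its length. These two removal
criteria are this package's own operationalization of "short and simple
sequence" screening; upstream tools do not document theirs.

Clustering and assembly use two separate thresholds, because reads of one
gene should be grouped together even when alleles, paralogs or splice forms
keep them from co-assembling:

- **Clustering** joins reads by single linkage whenever a pair aligns at
  >= 88% identity over >= 100 bp in either orientation (reads matching an
  optional "seed" reference cDNA at >= 80% join that seed's cluster first).
- **Contig assembly** within a cluster is greedy and longest-first: a read
  joins a growing contig only when it aligns to the current consensus at
  >= 95% identity over >= 50 bp. Reads that join nothing become *cluster
  singletons*; single-read clusters are *singletons*. Unique sequences =
  contigs + singletons + cluster singletons.

Identity is matches / aligned columns, with gaps counted as mismatches,
over the local alignment span. Candidate pairs are screened with exact
k-mer prefiltering (k = 12, >= 3 shared words voting for a consistent
diagonal); a k = 7 rescue anchor guarantees sensitivity, since any gapless
>= 100 bp overlap at >= 88% identity must contain an exact 7-mer run
(pigeonhole over at most 12 mismatches). Anchored candidates are verified
with a banded global alignment (edlib); an affine-gap local aligner decides
pairs the anchored window rejects — important when two reads share only a
partial overlap and diverge outside it. Accepted merges are re-derived with
affine gap costs before splicing into the multiple alignment: unit edit
costs tie a mismatch pair with an insertion+deletion pair, and the affine
re-derivation keeps substitutions as substitutions rather than scattering
spurious gap columns through divergent regions.

The consensus is the per-column majority base; ties prefer a base over a
gap and are then broken in the fixed order A < C < G < T. Majority-gap
columns are dropped from the consensus but retain their alignment index for
indel calling. IUPAC ambiguity codes are deliberately not emitted — the
variant caller consumes raw columns, not the consensus. Note the fixed tie
order is not reverse-complement covariant, so mirror-image inputs reproduce
identical contigs exactly only at tie-free columns; membership and
coordinates are unaffected.

5'/3' clone pairing is recorded but not used to scaffold contigs.

## Variant calling and the minor-allele schedule

Every alignment column with two or more distinct bases yields one putative
substitution per non-major allele; a column mixing gaps and bases yields an
indel. N bases carry no allele evidence: they are excluded from counts and
depth. Substitutions are classed as transitions (purine-purine,
pyrimidine-pyrimidine) or transversions.

EST-derived SNPs are error-prone, so putative SNPs are filtered by a
depth-dependent minor-allele schedule: within a contig of depth *d*, the
minor allele must be seen at least

| depth | 4 | 5-6 | 7-8 | 9-12 | 13-30 | >= 31 |
|-------|---|-----|-----|------|-------|-------|
| minor | 2 | 2   | 3   | 4    | 5     | 6     |

times. Contigs of depth 2-3 never yield filtered SNPs, and indels never
pass. The schedule is configurable; a flat preset (depth >= 4, minor >= 2)
is provided. Where the published descriptions of this rule differ in
wording (a flat "at least twice" summary, interval phrasing, and a
"six for >= 30" amendment), the interval table above subsumes all three and
is the default.

A caveat on monotonicity: under the stepped schedule, adding a read can
*remove* a previously passing SNP by pushing the column across an interval
boundary (depth 6 -> 7 raises the requirement from 2 to 3). That is a
property of the schedule itself, not of the implementation; the flat preset
is monotone.

## Species-of-origin categorization

Filtered SNPs in contigs containing reads of both species are categorized
from their per-species allele counts. A species is *certified monomorphic*
when it shows one allele, and *certified polymorphic* when every allele it
shows has within-species count >= `min_support` (default 2, mirroring the
minor-allele-twice logic). Then:

- both monomorphic, different alleles -> **inter-specific**;
- one polymorphic, the other monomorphic -> **intra-specific** for the
  polymorphic species;
- both polymorphic -> intra-specific for both;
- any allele with within-species support below `min_support` (including a
  species with no covering reads) -> **undetermined** — the evidence cannot
  certify either fixation or polymorphism.

The undetermined check runs first: an apparent fixed difference resting on
a single read is not certified inter-specific. SNPs from single-species
contigs are tallied separately and never categorized. Mixed-contig
eligibility requires at least two reads from *each* species (the stricter
reading of "at least two sequences from either species"; the literal
"either" reading is configurable), since certifying monomorphism needs two
observations.

Category proportions are estimated by drawing `n_sample` contigs (default
1,000) without replacement from the mixed-origin pool, tallying categories
over their filtered SNPs, and extrapolating each category *c* as
`round_half_up(count_c / total_categorized * population_total)`, where the
population is the mixed-contig filtered-SNP total; shares are rounded
percentages of the grand filtered-SNP total. Rounding is half-up; the
estimates therefore sum to the population total only within one unit per
category, and the report verifier enforces exactly that bound.

## Annotation

**Microsatellites** are maximal perfect tandem repeats of a primitive
2-6 bp motif, with class thresholds of 8 repeats (dinucleotide) or 5
(tri- to hexanucleotide). Shorter units take precedence ((AT)xN is never
re-reported as (ATAT)xM), reported loci do not overlap, and homopolymers
are never reported. Each motif also carries a canonical representative —
the lexicographic minimum over rotations of the motif and its reverse
complement — so the same repeat is never double-counted across phases or
strands. A locus is primer-ready when >= 50 bp flank it on both sides
(boundary inclusive). Interrupted and compound repeats are out of scope.

**ORFs** are found by exhaustive six-frame scanning rather than a trained
coding-potential model, so ORF *counts* on real data are not comparable to
model-based scanners; the scan itself is exact. Within each stop-delimited
codon segment the ORF runs from the first ATG through the terminating stop
(included in the span); with `allow_open_ends` (default), a start-less
segment truncated by the 5' edge of its frame also qualifies — single-pass
cDNA reads are very often 5'-truncated. Records under `min_orf_len`
(default 51 bp, the smallest ORF the package is asked to resolve) are
suppressed.

**Full-length cDNA calls**: a sequence is full length when its longest
forward-strand ORF begins at an ATG and a poly(A) tail lies downstream of
that start. The tail detector looks in the final 50 bp for a terminal A-run
of >= 10 with at most 1 mismatch — conventional values; note the mismatch
allowance lets a run absorb A-containing bases of an adjacent stop codon,
which is harmless for the call itself.

## The simulator

The synthetic-data generator emulates the statistical structure the
analysis assumes, with a ground-truth ledger for every planted feature.

- **Genes**: `n_genes` ancestral sequences, uniform length 900-3,000 bp by
  default. Each carries a planted ORF (an in-frame stop is written just
  upstream of the ATG so the planted start is the first ATG of its
  segment, the body is stop-free, >= 60 bp of 3' UTR remain) and, with
  probability `msat_probability` (default 0.15, matching the roughly 13-15%
  of unique sequences with repeats in EST collections), one perfect repeat
  at detection-threshold size planted in a UTR with maximal-run boundaries
  enforced.
- **Divergence**: each site mutates between species with probability
  `inter_divergence` (default 0.05, the reported ~95% mean coding
  identity); the mutated species is chosen 50/50 per site. Substitutions
  avoid the planted ORF anchors, repeat spans, and any change that would
  create an in-frame stop, so planted features survive in both species
  (~1% of sites are thereby excluded, which the calibration tests account
  for).
- **Polymorphism**: per-species biallelic sites at `intra_rate_blue` /
  `intra_rate_channel` per kb (defaults 0.5 and 1.3; the channel-side rate
  is set higher, mirroring the roughly 2.5x higher filtered SNP rate
  observed in the deeper-sampled species). Haplotypes are drawn 50/50 per
  clone per site, without linkage. A site drawn by both species is
  intra-specific for both.
- **Reads**: reads-per-gene-per-species follow `depth_distribution`
  (default: mass 0.43 at 2 and 0.13 at 3 — the dominant shallow
  normalized-library depths — with a geometric(1/2) tail to 8); an odd draw
  yields one single-end clone, as real archives contain unpaired clones.
  Each clone is the species allele with its haplotype choices plus a 20 bp
  poly(A) tail; the 5' read is the transcript prefix and the 3' read the
  reverse complement of the suffix (so it begins with poly(T)). Lengths are
  truncated-normal with mean 576 and s.d. 100 bp inside [100, 877], placing
  the maximum near 3 s.d. Errors are uniform substitutions at `error_rate`
  (default 0.005); an optional `indel_rate` (default 0) exists to exercise
  indel detection, and keeping it off makes truth alignment trivial.

What the simulator does **not** emulate: chromatogram artifacts and quality
values, vector/adapter contamination, chimeric clones, paralogous gene
families, splice variation, library normalization chemistry, and
non-uniform error profiles along the read. Tests passing on this generator
therefore demonstrate correctness of the algorithms under clean assembly
conditions, not robustness to every artifact of real EST archives — in
particular, real contigs can mix paralogs, which inflates apparent SNP
rates in deep contigs.

## Truth-recovery scoring

For recovery tests, each contig is traced to its source gene through read
provenance and its consensus coordinates are projected onto the gene by
affine local alignment. Filtered SNP calls are then compared with the
planted ledger site by site. Two scoring decisions matter:

- An *undetermined* call is an abstention, not an error. With haplotypes
  drawn 50/50, a polymorphic species' sampled clones often show the minor
  allele fewer than `min_support` times; the reads genuinely cannot certify
  the planted category.
- An inter-specific call at a planted intra site counts as a categorization
  failure only when both haplotypes were actually present with
  `min_support` reads of the polymorphic species in that contig. When a
  species' sampled clones all carry the alternate allele, the evidence is
  indistinguishable from fixation, and no caller could do better.

A planted site is *recoverable* in a contig when every planted allele is
supported by at least the depth schedule's requirement among the covering
member reads; the scorer reports recoverable sites that produced no call
(assembly boundary effects) separately from wrong calls.

## Numerical and procedural choices

- Problem sizes: the bundled recovery experiment uses 300 error-free genes
  of 600-900 bp at 6 reads per species per gene — enough for several
  thousand definite category calls while a full run stays under two
  minutes; oracle suites use 1,000 random alignments and 200 random 2-kb
  sequences.
- Determinism: one PCG64 stream per stage, seeded from the configuration;
  identical configurations reproduce byte-identical artifacts. Contig
  sampling for the category estimate uses its own seeded stream recorded in
  the report.
- Rounding: extrapolations round half up; SNP rates (per kb of consensus)
  print to one decimal.
- Coordinates are 0-based half-open everywhere internally; the VCF export
  converts to 1-based.
- Depth counts sequences, not clones: two reads of one clone both count.
- Multi-allelic columns emit one variant per non-major allele, each tested
  against the schedule independently.
- Contig depth strata follow the published table shape: shallow strata
  2(1:1), 3(2:1), 4(3:1) hold unsupported variants, the filtered section
  stratifies schedule-passing SNPs by contig depth; deeper schedule
  failures are not tabulated (consistent with declaring variants at depth
  >= 5 only via the schedule).

## Known limitations

- The assembler is a faithful re-implementation of the *thresholds*, not of
  any particular commercial assembler's internals; contig boundaries can
  differ from CAP3-family tools on the same input.
- At 95% between-species identity the contig threshold (95%) sits exactly
  at the expected divergence, so some cross-species read pairs legitimately
  fail to co-assemble and produce single-species contigs — the same
  behavior reported for real inter-specific assemblies.
- ORF counts are scanner-based (see above); BLAST-based homology
  annotation, coding-potential models and primer design are out of scope.
- The category estimator assumes the sampled contigs are exchangeable with
  the pool; it inherits any assembly-level biases (e.g. deep contigs
  carrying more SNPs).
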