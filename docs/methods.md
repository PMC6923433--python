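# Methods

This note documents the models, parameter choices and numerical conventions
behind `famsurvey`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Identification

Three evidence routes are merged by locus. The homology screen computes the
optimal Smith–Waterman score S of each proteome entry against every query
anchor (BLOSUM62, gap open 11 / extend 1) and converts it to
E = K·m·n·e^(−λS) with the gapped BLOSUM62 Karlin–Altschul constants
λ = 0.267, K = 0.041; entries are kept at E ≤ 1e−10. This is a rigorous
local alignment rather than a seeded heuristic, so it is slower than BLAST
but deterministic and dependency-free; a precomputed domain hit table can be
supplied where an external profile search is preferred, and the internal
fallback requires at least two histidine-box matches. Redundancy removal
keeps one transcript per locus — the longest CDS, ties broken by the lowest
`.N` suffix; published surveys of this kind rarely state their rule, and
longest-CDS is the common convention. Naming is positional within subfamilies
(chromosome, then start); a user override map exists because published
names are not always positional.

## Pairwise alignment statistics

Global alignments use the EMBOSS-needle-style defaults (BLOSUM62, gap open
10, extend 0.5; a gap of length L costs open + (L−1)·extend). Statistics:
identity = identical columns / alignment length; similarity =
positive-substitution columns / aligned residue-pair columns; coverage =
aligned residue-pair columns / length of the longer sequence. Pair columns
(both sequences holding a residue) operationalize the "alignable region":
defining the region as a terminal-gap-trimmed span is discontinuous, because
co-optimal affine alignments may park a long gap one residue short of the
terminus when a stray tail residue pairs better elsewhere. The (a, b)
argument order is canonicalized internally so align(a, b) ≡ align(b, a)
even when co-optimal tracebacks exist.

## Protein statistics

Molecular weights are average isotopic residue masses plus one water
(18.0153 Da). Isoelectric points are solved by bisection (tolerance 1e−4 pH)
on the Henderson–Hasselbalch net-charge curve with the EMBOSS pKa table
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1). Published pI values for the rice roster come from a tool with an
undocumented pKa table, so comparisons against them should allow roughly
±0.3 pH; MW is table-independent and agrees to ±0.2 Da.

## H-box grammar

Patterns are token lists: a residue letter, the wildcard `X`, or `Z(Y)`
meaning {Z, Y} (the only parenthesized form that occurs in the published
box table). The packaged table carries 17 patterns — three boxes per
membrane subfamily, two for soluble FAB2. The scanner reports all
(overlapping) occurrences; a subfamily member matching fewer than all of its
boxes is flagged truncated, the signature of a C-terminally truncated gene
model.

## Gene structure

Intron counts are CDS-based (introns between consecutive CDS intervals of
the representative transcript); introns lying wholly in UTRs are reported
separately. Intron phase is the number of bases of the interrupted codon
already emitted (cumulative CDS length mod 3), matching the 0/1/2
convention of gene-structure display tools.

## Phylogeny

The tree pipeline follows the classical distance recipe: complete deletion
(drop every column containing a gap), p = differing fraction over retained
columns, Poisson correction d = −ln(1 − p) capped at d_max = 10 when p
saturates, Saitou–Nei neighbor joining, and bootstrap percentages from
resampling the retained columns with replacement. Determinism is part of
the contract: Q-criterion ties are broken by the lexicographically smallest
pair of cluster keys (sorted leaf-name tuples), negative branch lengths are
clamped to 0 for display with the raw value retained on the node, and
bootstrap resampling is seeded, so taxon input order never changes any
output. The internal progressive aligner (3-mer-distance NJ guide tree,
mean-of-pairs profile Needleman–Wunsch, linear gap −8, tie order
diagonal > up > left) is a deterministic convenience; externally aligned
FASTA is accepted everywhere an alignment is.

For families whose joint alignment retains almost no gap-free column
(between-subfamily identity near the random floor), distances are instead
computed per pair from global alignments (`pairwise_poisson_matrix`), with
stiffer gap costs (open 15, extend 2): with cheap extension the optimal
alignment of two unrelated proteins fragments into coincidentally matching
islands, deflating p exactly where it should saturate. Subfamily assignment
takes the minimum mean distance to each anchor group; ties within 1e−9
leave a gene unassigned rather than guessed.

## Duplication

Tandem: same chromosome, strictly fewer than 5 annotated genes between the
two loci (genome-wide ordinals, any strand), global identity > 0.5;
qualifying pairs are closed into clusters by single linkage, so a
three-member array whose outer pair exceeds the gap limit still forms one
cluster through the middle member. Segmental: coverage > 0.75 and
similarity > 0.75, both strict, over all pairs not already inside one tandem
cluster; a gene may still carry both labels via different partners.
"Homology at protein level" is operationalized as global identity and
"similarity of aligned regions" as the positive-substitution fraction —
both configurable, both logged in the call evidence. No synteny evidence is
required for a segmental call; the criterion is purely pairwise.

## Promoters

The promoter is the 2000 bp 5′ of the first CDS base (the ATG), reverse
complemented for minus-strand genes; −1 is the base immediately 5′ of the A
and truncation at a contig edge warns rather than fails. Elements are IUPAC
consensi scanned on both strands, complementary-strand hits reported at
template coordinates of their 5′-most template base, overlaps all reported.
The default table is a PlantCARE-vocabulary set chosen by this package —
the survey literature names elements but not sequences — and is explicitly
replaceable; MeJA-RE ships as the single consensus CGTCA whose TGACG form
appears as a complementary-strand hit.

## Expression and qPCR

Group classification operates on per-tissue replicate means with thresholds
τ_high/τ_low defaulting to the 70th/30th percentiles of all gene × tissue
means (recorded in every call; overridable). Rule order: IV if the maximum
mean is below τ_low; I if ≥ 80% of tissues reach τ_high; III if every
tissue reaching τ_high lies in exactly one category (vegetative or
reproductive) and at least one does; otherwise II. Stress calls use a
two-sided Welch t-test per gene on log2 replicate values at raw P < 0.05
with no multiple-testing correction — the convention of the survey
literature, a deliberate choice rather than a recommendation. Hormone calls
are strict fold-change thresholds on control-normalized RQ (up iff
RQ > 2, down iff RQ < 0.5), with an early-responsive flag at the 3 h point.
2^−ΔΔCt: ΔCt = mean Ct(target) − mean Ct(reference) per sample, ΔΔCt
subtracts the calibrator sample, and replicate SDs propagate in quadrature
to an RQ range.

## Synthetic data: what it emulates, and what it does not

The generator plants, by construction, exactly the structures the
classifiers look for. Default study conditions: six chromosomes with 14
background genes each; a 20-member family in six subfamilies sized
9/4/4/1/1/1; one 3-gene tandem array (2 intervening genes, pairwise
identity 0.6) and one 2-gene array (1 intervening, 0.6); two segmental
pairs at coverage/similarity 0.85/0.85 and one sub-threshold pair at
0.5/0.5 planted as a negative control; one member truncated before its
final H-box; one locus with a shorter `.2` splice variant; 200-residue
proteins; 2300 bp intergenic spacers so every promoter window is intact.

Family proteins derive from one random ancestor per subfamily by point
substitution; identity targets are hit by mutating the exact count of
non-box positions with BLOSUM-nonpositive replacements and verified with
the package's own aligner (±0.03) before emission. Segmental partners are
additionally truncated to the coverage target, their substitutions drawn
mildly negative (score in [−1, 0]) and spaced with bounded run lengths so
the optimal alignment has no incentive to gap them out, with a feedback
loop adjusting span and mutation count until both measured statistics land
within ±0.03. Background proteins and promoter windows are
rejection-corrected until they contain no H-box or element match, making
false-positive counts exact. Expression archetypes use jittered level means
(floor 2, off 4, mid 6.5, high 10 log2 units, SDs 0.25–0.4) and a
composition (15% I, 30% II, 30% III, 25% IV) that keeps the high-level
share of pooled means below the 70th percentile, so the percentile
thresholds fall in the gaps between levels instead of on them; replicate
noise is Gaussian with configurable SD (default 0.3, three replicates).
qPCR tables place the reference gene at Ct 20 and targets at
25 − log2(fold).

Deliberately not emulated: realistic codon usage and GC content, indel
evolution, pseudogenes, transposon-derived repeats, microarray probe
effects and normalization artefacts, and correlated replicate noise.
Passing planted-truth tests therefore demonstrates that the classifiers
implement their stated rules exactly and recover structure under the
planted noise model — not that those rules are optimal on real annotations,
where borderline cases (fragmented gene models, nested genes, promoter
repeats) will behave less cleanly.

## Problem sizes and numerical conventions

The shipped test suite and acceptance script use the default synthetic
genome (~104 genes, ~340 kb), 40-gene expression matrices over the 16-tissue
panel, 200 seeded simulations for the stress-test calibration, and
bootstrap counts of 25–200 in tests — sizes chosen so the whole suite runs
in well under a minute while every statistic retains enough replication to
be stable across seeds. Seeds are explicit everywhere; the same seed gives
byte-identical simulator output and pipeline reports. Degenerate inputs
fail loudly: empty CDS, missing reference genes, non-symmetric distance
matrices, unsatisfiable simulation targets (bounded retries, then a config
error) and invalid residues or IUPAC codes all raise typed exceptions
naming the offending record.
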