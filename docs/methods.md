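# Methods

This note records the models, algorithms, parameter choices and known
limitations behind `ophanno`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Coordinates and genome topology

All coordinates are 1-based inclusive. Reverse-strand features are stored as
forward-strand intervals (`start < end`) with `strand='-'`. On circular
genomes, arithmetic wraps modulo the length; a feature crossing the junction
keeps `end > length` in memory and is split into two segments by the GFF3
writer (the reader rejoins them), so the representation is lossless. `N`
bases are accepted on input, excluded from the GC denominator, and treated
as mismatches in comparisons.

## ORF calling

The caller scans all six frames; on circular genomes the doubled sequence is
scanned so frames continue across the junction, and ORFs are deduplicated by
stop position keeping the longest, which yields exactly the maximal
ATG-to-stop ORF per (stop codon, frame) — nested in-frame starts are
suppressed. Only ATG initiators are considered (the usual convention for
baculovirus annotation). The codon count includes the start codon and
excludes the stop, so it equals the translated length; the span is always a
multiple of 3 and the translation (standard code, table 1) never contains an
internal stop. Correctness is checked against an independent brute-force
oracle that walks every ATG explicitly (50 random 10-kb genomes, both
topologies, in the acceptance suite).

## Annotation filter

ORFs with a homology-table entry are always kept (the table stands in for
BLASTp/HHpred results, with source tags mapping to core-gene,
alphabaculovirus-conserved or generic-homolog bases). A homology-free ORF of
≥ `min_codons` (default 50) survives only if:

- it is not fully contained in an hr ("occurs within" is read as full
  containment, so this rule and the next are not redundant);
- it overlaps no hr and no larger kept ORF by more than `max_overlap`
  (default 75) bp, measured on the forward-strand projection regardless of
  strand;
- the coding predicate accepts it.

"Larger" means strictly more codons; equal-length conflicts go to the ORF
with the earlier start coordinate. Renumbering assigns ids 1..N by start
coordinate after rotation, so *polh* is ORF 1.

**Coding predicate.** The pluggable predicate stands in for requiring
agreement between two ab initio gene predictors, which are out of scope. The
default scores each candidate by the mean per-codon log-likelihood ratio of
its synonymous codon choices under (a) the pooled codon usage of the
homology-backed ORF set versus (b) a background in which codons follow the
genome's base composition; the decision boundary is 0 (positive means the
candidate shares the coding codon bias). This statistic was chosen over an
RSCU-vector cosine because the LLR concentrates as the mean of i.i.d.
per-codon terms and remains reliable for short (~60-codon) ORFs, where
per-family RSCU estimates are dominated by sampling noise. On synthetic
genomes the two populations separate completely (planted minimum ≈ +0.1
nats/codon, spurious maximum ≈ −0.07 over thousands of ORFs).

Protein masses use average residue masses plus one water (18.0153 Da),
reported in kDa to one decimal with half-up rounding.

## hr detection

Candidate regions are seeded by canonical (strand-collapsed) 10-mers that
recur within a window, merged when closer than `cluster_gap` (250 bp), and
padded by two unit lengths because a heavily mutated outermost unit may
share no k-mer with its neighbour. The seed length trades sensitivity
against noise: at k = 12 roughly 1 % of two-copy stacks at the default 5 %
unit mutation rate retain no shared k-mer at all and are invisible to
seeding (measured by simulation), while k = 10 misses fewer than 2 in 1000;
the extra spurious candidate regions k = 10 admits are discarded cheaply by
a vectorised Hamming prescreen (Hamming distance upper-bounds edit distance,
so no substitution-dominated repeat lattice is lost) before any edit-distance
scoring runs. Each region is segmented by an exhaustive
phase/period search over unit lengths in [`unit_min`, `unit_max`] (default
[40, 80], a window centred on the ~60-bp units typical of alphabaculovirus
hrs): a candidate lattice is screened by the edit distance between adjacent
cuts (orientation-aware, so inverted copies chain), and the shortlisted
segmentations are then re-scored by per-unit distance to an
orientation-normalised majority-vote consensus. The consensus stage is what
rejects "drifted" periods that survive the adjacent screen through slip
alignments. For two-unit clusters the majority vote degenerates (every
disagreeing column is a tie), so the pairwise unit distance is used instead.
Among near-tied candidates (within 0.02 divergence) the largest covered
length wins, and a detected two-copy stack is additionally re-extended
symmetrically about its centre: a stack whose second copy mirrors the first
is internally palindromic, so every centred sub-window scores as well as the
true unit and only the stack edges (where mirroring stops) identify the
extent. The extension maximises length minus four times the pair edit
distance, which grows through the repeat (~0.08 edits per step) and shrinks
in flanking sequence (~0.5 edits per step, the alignment rate of random
DNA). Units are kept while within `max_unit_divergence` (0.25) of the
consensus; a cluster becomes an hr iff it has 2–6 units, a consensus within
the unit-length window, and an imperfect palindrome of arm ≥ 4 at ≤ 2
mismatches (the printed repeat-unit consensus carries a 7-bp arm at 2
mismatches, so these defaults accept real units with margin).

**Boundary precision.** The absolute phase of a mutated tandem array is only
weakly identified: interior unit boundaries are invariant under rotation of
the unit, and the only phase signal comes from the stack edges (≈ 0.75
expected mismatches per misplaced base, against mutation noise of similar
size). Detected regions therefore localise to within a few bases of the
planted truth (worst observed offset: 6 bp across 30 genomes); recovery
tests allow a ±10 bp tolerance while requiring the exact unit count. Unit
counts, orientations and consensus sequences are recovered exactly at the
default 5 % per-base unit mutation rate.

Palindrome scoring enumerates every axis and arm length, maximising arm
length subject to a mismatch ceiling (ties: fewest mismatches, then leftmost
axis); it matches an exhaustive oracle on random sequences.

## Promoter classification

The scanner searches the `window` bp (default 200) strictly 5′ of the start
codon on the coding strand — reverse-complemented for minus-strand ORFs,
wrapping across the junction on circular genomes, truncated with a warning
on linear ones. Labels: C iff CAKT (K ∈ {G,T}) occurs, L iff TAAG, T iff
TATAA; occurrences may overlap (TATAAG yields {T, L}). Motifs are
strand-specific cis elements, so the template strand is not scanned, and the
ATG itself is excluded from the window.

## Variant classification

Variants at frequency strictly above `min_freq` (0.10) are classified with
hr membership taking precedence, then ORF membership (overlapping ORFs:
judged against the longest, with a warning), then codon arithmetic: SNP
codons are rebuilt strand-aware and translated against the reference; indels
are in-frame iff the length change is a multiple of 3. Indel positions are
the first changed base, left-aligned; pure insertions/deletions may have an
empty allele string. Class counts always partition the classified input.

## Distances, demarcation, parity, phylogeny

K2P uses pairwise deletion; saturation (non-positive log arguments) is an
error, not a clamped value. The demarcation boundary is exclusive: d equal
to the 0.050 substitutions/site criterion is *not* "well above" it and stays
a same-species candidate. The gamma-corrected form replaces each −ln(x) by
a(x^(−1/a) − 1); the shape parameter is supplied (config/CLI), never
estimated, because no estimation procedure is in scope — as a → ∞ the
corrected distance converges to plain K2P (verified to 1e−6).

Gene-parity points place shared ORFs at their ordinal positions in each
genome and private ORFs on the owning genome's axis (index 0 on the other).
Inversions are maximal runs of ≥ 2 consecutive shared points with strictly
descending partner index; plateaus break runs. The detector matches a
brute-force window oracle on every permutation of up to 8 elements.

Protein distances maximise the log-likelihood of site-pattern counts under a
reversible empirical model: Q_ij = S_ij π_j normalised to one expected
substitution per site, P(t) = exp(Qt) via symmetric eigendecomposition, and
bounded scalar optimisation on [1e−6, 10] with tolerance 1e−8 (hitting the
upper bracket raises "saturated pair"). The JTT exchangeabilities and
frequencies (Jones, Taylor & Thornton 1992) ship as a PAML-format text file;
a uniform (Poisson) model provides the closed-form check
−(19/20) ln(1 − 20p/19). Rate heterogeneity uses four equal-probability
discrete gamma categories with mean-rate representatives.

Neighbor joining follows Saitou–Nei with the standard Q-criterion; negative
branch estimates are clamped to zero with the deficit moved to the sister
branch, and taxa are processed in sorted order so input order cannot change
the result. NJ with column-resampling bootstrap is the deliberate desk-scale
stand-in for a minimum-evolution search (ME conventionally starts from, and
rarely moves far from, the NJ topology); full ML tree search is out of
scope. Topologies match scikit-bio's NJ on random additive matrices, and
additive four-leaf matrices are recovered exactly (topology and branch
lengths).

## Synthetic data generator

The generator emulates the statistical structure of an AT-rich circular
alphabaculovirus genome; its defaults are the study conditions: 100 kb, GC
target 0.342, 100 ORFs of 60–350 codons on both strands (ORF 1 fixed to the
plus strand at position 1, its promoter region wrapping the junction), 6 hrs
of 2–6 units built by mutating a 58-nt palindromic seed unit at 5 % per
base with 30 % reversed copies, and i.i.d. intergenic filler at the GC
target. 95 % of planted ORFs carry homology entries (most real
alphabaculovirus ORFs have database homologs); the rest exercise the ab
initio path. Planted codon usage puts 90 % of each family's weight on its
most AT-rich codon — reproducing both the strong codon bias of real viral
genes and the genome's base composition (realized GC ≈ 33 %) — which is the
signal the coding predicate relies on. Each ORF cassette carries a scrubbed
200-bp promoter region whose realized motif label set equals the requested
one exactly (rejection sampling), ending in an in-frame TAA guard so the
planted ATG is maximal for its stop. hr cassettes get a 300-bp repeat-free
margin on each side: real hrs are dispersed, and back-to-back stacks would
merge into a single repeat array under any reasonable detector (and any
reasonable biological definition of one hr).

Variant simulation plants requested counts per class by construction —
synonymous/nonsynonymous SNPs at internal codons with verified codon
effects, hr/intergenic SNPs and indels outside ORFs, in-frame (3-bp) and
frameshift (1–2-bp) deletions inside ORFs — with disjoint positions,
frequencies Uniform(0.10, 1] drawn strictly above the filter threshold, and
an optional below-threshold fraction to exercise the filter. Default counts
mirror the study partition (40/46/30 SNPs, 12/3/1 indels).

The evolution simulator performs substitution-only evolution (no indels, so
outputs are aligned by construction) under K2P with configurable κ or under
any packaged amino-acid model, along a branch length or a Newick tree, with
per-site rates drawn from the same four discrete gamma categories the
estimators use. Estimator recovery: K2P median |d̂ − d| < 0.02 at 5,000
sites (d = 0.2, 50 seeds); JTT ML distance within 0.03 at 10,000 sites
(t = 0.3, 50 replicates).

All generators draw from per-feature RNG streams spawned from the user seed
via `numpy.random.SeedSequence`, so enabling one feature class never
perturbs another's draws, and identical (config, seed) pairs are bit-exact.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error and assembly artefacts;
overlapping genes (planted ORFs are disjoint, so the 75-bp overlap rule is
exercised only by constructed cases); non-uniform amino-acid composition and
genuine promoter architecture beyond motif presence; hr units with indel
divergence (only substitutions are planted); and homology tables with false
or missing assignments. Recovery rates on synthetic genomes are therefore
an internal-consistency check of the algorithms, not an accuracy claim for
any particular real isolate.

## Problem sizes

The default test and acceptance runs use one 100-kb genome per pipeline
check, 50 random 10-kb genomes for the ORF oracle, exhaustive permutation
checks to n = 8, 50-replicate estimator-recovery studies, and 100-replicate
bootstraps on six-taxon alignments — sizes at which every check is exact or
tightly concentrated while the whole suite runs in well under a minute.

## Known limitations

- hr boundary phase ambiguity as described above (sub-unit localisation).
- The repeat detector assumes units stack near-tandem within a region; units
  separated by long internal spacers would be reported as separate clusters.
- Junction-spanning hrs are detected, but hr ids are assigned by start
  coordinate, which for a junction hr is its pre-wrap position.
- The ML protein distance is a pairwise estimator; it does not propagate
  uncertainty into NJ, and bootstrap supports inherit the usual caveats of
  resampling short alignments.
- VCF ingestion is minimal (single-sample, INFO-field frequency); complex
  multi-allelic records should be normalised upstream.
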