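# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage, and what the synthetic-data generators do and do not
emulate.

## Synthetic data and planted truth

All generators draw from a single seeded NumPy generator per scenario
(`ScenarioConfig.seed`), so identical configurations reproduce byte-identical
outputs.  Every generator returns a truth table keyed by record id.

**LTR elements.**  An element is TSD + LTR + internal + LTR + TSD, with the
TSD length uniform on 4–20 bp, the LTR starting `TG` and ending `CA`, and
both LTR copies identical at insertion.  Divergence is planted by mutating
each copy independently and i.i.d. per site at rate
q = (3/4)(1 − sqrt(1 − (4/3)·d)) with d = 2·mu·age — the Jukes–Cantor
inverse — so the *expected raw p-distance* between the copies equals d
exactly and the dating formula age = d/(2·mu) is unbiased by construction.
(Naive mutation at rate mu·age would undershoot by the double-hit term
(4/3)q², about 2.6% at 5.5 My.)  Elements are placed without overlap by
drawing sorted offsets into the free space, which cannot fail when the
genome is long enough and raises otherwise.  Defaults: mu = 7e-9
substitutions/site/year (the standard neutral rate used for insertion
dating), LTR 1000 bp, internal 3000 bp.  No indels, no base-composition
structure, no nested insertions — so detection performance on these genomes
is an upper bound relative to real repeat landscapes.

**Reads.**  Uniform coverage, i.i.d. substitution errors, no quality model,
no indels; paired mode draws inward-facing pairs from fixed-length
fragments.  Sufficient for k-mer histogram shape and coverage-based
selection, not for profiling real base-callers.

**Orthogroup matrices.**  Planted classes are the strict forms (focal 0 vs
all-1 losses; focal 2 vs all-1 duplications; all-1 elsewhere), so the
classifier's round trip is exact in the noise-free setting.  Real matrices
contain the broad/ratio classes and noise; those paths are exercised by
direct unit tests instead.

**Paralog pairs.**  Ancestral sequences are uniform random sense codons.
The target expected proportion of synonymous differences pS is obtained from
the Jukes–Cantor forward map of the requested dS; the number of substituted
codons is pS x S (NG86 synonymous sites of the sequence), stochastically
rounded, and each substitution is a uniformly chosen amino-acid-preserving
single-nucleotide change, so stops can never arise.  Synonymous changes can
slightly alter the site count of the derived sequence; the residual bias is
well under the 10% recovery tolerance used in tests.

**Hit tables and gene trees.**  Non-HGT genes receive their top-percent band
of hits exclusively inside the focal lineage, with out-of-order hits placed
safely below the retention threshold; planted HGT genes receive donor-order
hits with bitscore >= 100 and sub-threshold focal hits.  Gene trees graft the
focal gene leaf sister to a donor-order leaf (HGT) or to the focal species
(native).  The screen's perfect recall/precision on these inputs verifies
the machinery, not real-data performance, where hit noise and incomplete
databases blur the separation.

## Genome size

Canonical k-mers (numeric minimum of the 2-bit packed forward and
reverse-complement encodings, equivalent to the lexicographic rule) are
counted with k = 19 by default.  The error valley is the first depth into
which the window-3 moving-average-smoothed distinct-count curve decreases
monotonically from its lowest bin and after which it rises; smoothing is done
over the *observed* depth bins, which makes the valley scale-invariant and
keeps the estimate invariant under duplicating the whole read set.  The peak
is the argmax of distinct counts beyond the valley, ties broken to the lower
depth (the conservative, larger-size choice).  Size = (total instances −
instances at depths <= valley) / peak.  Error *instances* (not distinct
k-mers) are subtracted because the division operates on instance totals.
Error-free data has no valley; `estimate_genome_size` then requires an
explicit cutoff (0 disables subtraction) rather than guessing.  Heterozygosity
and repeat structure are deliberately not modelled.

Flow-cytometry conversion: 1C = (sample FI / standard FI) x standard 1C,
default standard 4.42 pg; pg -> Mbp uses the standard 978 Mbp/pg.

## LTR detection and dating

Detection is a structural search specialised to substitution-only divergence
(which is what the simulator plants): exact 20-mer seeds shared at a
direct-repeat offset of 3–25 kb are grouped by offset, chained by proximity
(<= 500 bp), extended ungapped with an x-drop rule (match +2, mismatch −2,
drop 20), and the boundaries snapped within a ±60 bp vicinity to the
element-level TG...CA motif (<= 1 mismatch total) plus an exact 4–20 bp TSD.
Among all boundary pairs passing, ranking is by motif exactness, then TSD
length, then proximity to the extension — a boundary slid into the TSD still
shows a shorter phase-shifted exact duplication, so proximity alone is
unreliable.  About 1% of detections on mutated elements retain a ±2 bp
boundary wobble from chance duplications; this is invisible to dating.
Candidates are accepted greedily by LTR similarity into a non-overlapping
set, and every output satisfies all structural constraints by construction
(length 100–2000 bp, distance 3000–25000 bp, similarity >= 85%).

The seven-criterion filter reads "LTR <= 25 of the element length" as <= 25%
(each LTR) and applies the strict inequalities printed for tandem (< 25%)
and N content (< 5%).  Superfamily is the inner INT/RT/RH order (RT-RH-INT =
Ty3/gypsy, INT-RT-RH = Ty1/copia; unknown if INT or RT is absent), invariant
to GAG/PBS placement; minus-strand domain lists are read 3'->5'.

Divergence is the raw p-distance over aligned non-gap columns of a global
alignment (Jukes–Cantor correction available behind a flag); the alignment
uses match 2 / mismatch −2 with deliberately stiff affine gaps (open −10,
extend −5), because cheap gaps let the optimal alignment hide clustered
mismatches behind paired gaps, deflating p-distance by ~8% at 7–8%
divergence and biasing every age young.  Age = divergence / (2 x 7e-9).
Redundancy clustering is single-linkage at > 95% identity over > 95% mutual
length coverage (edlib global edit distance; mutual coverage as the length
ratio), representative = longest element, ties by id.

Overlap resolution of repeat-library matches assigns higher scores first
(ties: longer, then coordinate); an overlapped lower-scoring match is trimmed
to its longest contiguous uncovered segment when accepted matches cover
< 90% of it and that segment is >= 50 bp, otherwise removed.

## Orthogroup dynamics and enrichment

Classes, checked strict-before-broad: universal single copy; loss_strict
(focal 0, others exactly 1); loss_broad (focal 0, others >= 1); dup_exact
(focal 2, others exactly 1); dup_ratio (all >= 1 and focal >= 2x every other
species' count — the strictest reading of "at least 2n:n"); other.  Presence
calls from score tables use strictly-greater-than-50; missing scores are
absences.

Fisher's exact test is computed by exact rational (Fraction) hypergeometric
summation; the two-sided p sums all tables with the observed margins whose
probability does not exceed the observed one, with the conventional 1+1e-7
relative tie slack (matching R and scipy).  Enrichment operates on annotated
items (orthogroups by default), one 2x2 table per functional bin.  The
Benjamini–Yekutieli adjustment q_(i) = min_{j>=i} p_(j)·m·c(m)/j, c(m) the
harmonic sum, capped at 1, controls FDR under arbitrary dependence; it
dominates Benjamini–Hochberg everywhere but is not idempotent (re-adjusting
adjusted values inflates them again — a property, not a bug).

## dS estimation and WGD peaks

Backtranslation replaces each aligned residue by its source codon and each
gap by `---`, validating the CDS against the protein (terminal stop
tolerated).  The dS/dN estimator is Nei–Gojobori (1986): per-codon
synonymous site fractions (changes to stops counted nonsynonymous) averaged
over both sequences; differences averaged over all minimal mutational
pathways, excluding pathways through stop intermediates (falling back to the
unrestricted set if all are excluded); Jukes–Cantor correction of the
proportions, with pS >= 3/4 flagged saturated.  Gap and ambiguity columns
are dropped pairwise, stop columns with a warning; at least 10 comparable
codons are required.  An ML codon model would differ in detail, but the
analyses here consume only the *location* of distribution peaks, which is
robust to the estimator at these divergences.

Peaks: Gaussian KDE (Silverman bandwidth unless overridden) evaluated on a
512-point grid over [0, max]; >= 30 finite values required; saturated values
excluded; a zero-spread input returns its common value directly.

## HGT screening

Binning follows the extended-best-hit rule with MEGAN-style defaults
(minScore 50, maxExpected 0.01, topPercent 40, lcaPercent 100,
minPercentIdentity 0): hits within 40% of the best bitscore are retained and
the gene is assigned to their strict LCA (lcaPercent < 100 descends while a
child subtree holds the required fraction).  Candidates are genes assigned
at or below a non-focal order, with best bitscore strictly > 80, no
TE/retrovirus flag (an input annotation), and no split-alignment artefact —
mechanised as: >= 2 disjoint query intervals against one subject, each below
the retention threshold but jointly reaching it (max-weight disjoint subset).
Donor order is the order ancestor of the assignment; support counts retained
hits inside it.

The placement test replaces full event-based reconciliation with a monophyly
check: supported iff the smallest clade holding the focal leaf and at least
one other leaf consists solely of donor-order leaves; not_supported iff the
focal leaf's sister group contains focal-order leaves; otherwise (including
trees without donor leaves) uninformative.  Unrooted trees are first rooted
on the leaf most distant from the focal leaf among orders that are neither
donor nor focal (ties by name).

## Problem sizes and tolerances

The shipped tests and the acceptance script run at sizes a laptop handles in
minutes, chosen to keep sampling error comfortably inside each tolerance:
1 Mbp / 50x / 1% error for genome-size recovery (tolerance 5%; observed
error <3%); 100 elements per age class with 1 kb LTRs (tolerance 10% on the
class mean; the 0.5 My class has the largest relative sampling error, ~4%
SE); 500 pairs x 300 codons per dS peak (tolerance 20%; observed <2%);
1000 genes with 50 planted transfers for the screen; all 164,176 2x2 tables
with margins <= 30 for the Fisher oracle sweep; estimator-oracle agreement at
1e-9 (NG86) and 1e-12 (Fisher).
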