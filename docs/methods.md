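# Methods

This note documents the models, conventions and numerical choices behind
plastomarker, in the spirit of the methods documentation of mature
genomics toolkits: what each component assumes, which parameters matter, and
what the synthetic-data tests do and do not demonstrate about real data.

## Coordinate and alphabet conventions

All coordinates at public interfaces are 1-based and inclusive (GenBank
convention).  Sequences are uppercase DNA over `{A,C,G,T,N}`; IUPAC
ambiguity codes other than N are rejected rather than converted, because the
SSR and SNP logic assumes a five-letter alphabet and a silent conversion
would fabricate variants.  Alignments additionally allow `-` and are
validated on read: at least two rows, equal lengths, no all-gap column.

## SSR detection

A locus is a maximal perfect tandem repeat.  Detection runs one vectorized
pass per period p = 1..6 over the predicate `s[i] == s[i+p]` (broken at N);
a maximal run of matches of width w corresponds to a tandem tract of
w + p bases.  Runs whose motif has a smaller primitive period are skipped —
they are found at that smaller period.  Each primitive run is reported at
the *smallest* unit size whose copy threshold it meets, so a 12-base
homopolymer is one mononucleotide locus (12 copies), never six dinucleotide
copies of `AA` — unless mononucleotide scanning is deliberately disabled, in
which case reporting at unit 2 is the defined behaviour and the canonical
class recorded is that of the primitive core (A).

Default thresholds are the stock MISA-style definition
`{1:10, 2:6, 3:5, 4:5, 5:5, 6:5}`, all configurable; mononucleotide scanning
matters for chloroplast SSRs (typically A/T tracts) and can be switched off
for nuclear scans.  Compound-SSR merging (grouping loci separated by at most
a configurable gap) exists as an optional post-pass and is off by default;
all primary outputs are simple perfect repeats.

Canonical motif classes are the lexicographic minimum over all cyclic
rotations of the motif and of its reverse complement.  Because published
tallies of di-nucleotide classes are often reported on mixed conventions,
loci always carry both the motif as written on the scanned strand and the
canonical class, and summaries tally both; no attempt is made to reproduce
strand-convention-dependent splits.

Correctness is established against an independent brute-force oracle (an
exhaustive start × period scan with character-wise extension) on random
sequences, plus strand-symmetry and non-extendability property tests.

## Comparative plastome marker calling

The caller consumes a *given* multiple alignment (producing alignments is
out of scope) and a designated reference genotype; reference coordinates are
positions in the reference's ungapped sequence.

* **SNPs** — columns with no gap, no N, and exactly two observed bases.
  Columns with three or more bases are kept in a separate multi-allelic
  report rather than being silently dropped or squeezed into the SNP list.
* **Indels** — maximal runs of consecutive gap-containing columns in which
  the per-column gap pattern is constant (every genotype fully present or
  fully gapped across the run) and both classes are non-empty.  States
  follow the descriptive convention: presence = Insertion, absence =
  Deletion, with no ancestral-state inference, and the reference genotype
  is labelled like any other.  Runs with ragged patterns are reported as
  complex events.  Columns containing N break runs; this only affects
  degenerate inputs since finished plastomes contain no N.
* **SSR copy-number polymorphisms** — the SSR scanner runs on each ungapped
  genotype; loci are mapped back to alignment columns and clustered across
  genotypes when intervals of the same canonical class overlap.  A cluster
  is emitted iff copy numbers differ; a genotype without a qualifying locus
  contributes the tandem copy count actually present in its homologous
  window (0 when the tract is absent).
* **Small inversions** — for each genotype-vs-reference maximal mismatch run
  of width within [min_len, max_len] (defaults 3..30) with no gaps inside,
  a record is emitted iff the genotype segment equals the reverse complement
  of the reference segment and the reference carries a pair of exact
  inverted repeats of length within [min_flank, max_flank] (defaults 10..40)
  immediately flanking the run; the reported flank is the largest such
  length.  Candidates from different genotypes with identical intervals are
  merged into one record with per-genotype orientations (Yes = inverted);
  partial overlaps are reported separately with a warning.  Two blind spots
  are inherent to the test and documented rather than patched: an even-length
  perfectly palindromic segment inverts to itself, and a segment whose
  mirrored positions are partly self-complementary presents a shorter
  mismatch run than the full flipped segment.

**Reconciliation.**  Marker classes overlap by construction, so the
orchestrator (`call_markers`) applies two rules: an indel whose gap run lies
wholly inside an SSR-polymorphism cluster is the same copy-number variant
and is removed from the indel list (kept in a separate excluded list); and
substitution-like columns inside a called inversion belong to the inversion,
not the SNP list.  A column-accounting structure (invariant + SNP +
multi-allelic + indel + complex + inversion + N-masked = alignment length)
is asserted at the end of every pipeline run.

## Quadripartite partitioning

IRa/IRb are found as the longest pair of disjoint intervals on the circular
genome whose sequences are exact reverse complements, each at least
`min_ir_len` (default 1000 bp).  The search is seed-and-extend: k-mer seeds
(k = min(21, min_ir_len), floor 8) matched against the reverse complement
share an anti-diagonal x + y = c for all base pairings of one match, so
seeds are grouped per diagonal, merged, and extended once; candidate pairs
are tried in decreasing length order and the first circle-disjoint pair
wins.  Exact matching only: plastome IR copies are identical or
near-identical, and when they differ the detector reports the longest exact
pair (the residue is logged).  The two gaps between the IRs become LSC
(longer) and SSC (shorter); the IR following the LSC in genome order is
IRa.  Detection is rotation-invariant up to coordinate shift;
`normalize_rotation` rotates a genome to the conventional origin (LSC
starting at coordinate 1) for stable report coordinates.

GC content is (G+C)/(A+C+G+T) with N excluded from both numerator and
denominator (NaN for an all-N window); regions are reported to 1 decimal as
percent and whole genomes to 2, matching customary precision.

Position classification is total: exon if the coordinate falls in an exon of
the innermost containing feature (so a gene nested in another gene's intron
wins), intron if inside a feature's span between exons, otherwise a spacer
named `left-right` by the nearest flanking genes in coordinate order
(ignoring strand, wrapping circularly at the sequence ends).

## Primer design

Primer3-style thermodynamics are deliberately out of scope.  Melting
temperature uses the basic GC closed form
`Tm = 64.9 + 41·(G+C−16.4)/L` for L ≥ 14, reported to 2 decimals, with the
Wallace rule `2(A+T)+4(G+C)` as a flagged fallback for shorter oligos.
Printed primer sets designed by thermodynamic engines are therefore not
expected to pass `tm_min = 60 °C` under this formula, and nothing in the
package asserts that they do.

Candidates are all windows of length 18–22 wholly outside the target tract
passing Tm, GC bounds (0.30–0.70), a homopolymer cap (4) and a G/C 3′ clamp.
Pair selection is an exhaustive cross-product minimizing
`|len_f−20| + |len_r−20| + |Tm_f−Tm_r| + 10·max(0, 100−product)`, with
product size measured 5′ end to 5′ end; pairs below the minimum product are
infeasible.  Ties break by smaller product, then leftmost forward primer, so
selection is fully deterministic.  Cross/self-dimer screening is a simple
longest-perfect-complement scan (reject at ≥ 8 nt), available but off by
default.  M13 tailing prepends the universal 18-mer
`TGTAAAACGACGGCCAGT` to the forward primer.

## Diversity statistics

Frequencies are estimated per locus over the gene copies of complete-case
individuals; missing or partial calls are dropped for that locus only (the
source data do not come with a stated missing-data rule, so the simplest
auditable one is used).  He is Nei's gene diversity 1 − Σp² without
small-sample correction by default; an unbiased variant with the
2n/(2n−1) factor is available but not default, since published panels rarely
state which convention their software used — bundled per-locus values are
treated as fixtures, and only across-locus arithmetic (means, ranges) is
recomputed.  Shannon's index uses natural log (the dominant convention for
"Shannon–Wiener diversity" in population-genetic software); the base is
configurable.  Ho is the fraction of complete-case individuals whose call
contains at least two distinct alleles, which generalizes to any ploidy;
ploidy defaults to 2.  Internally all statistics are kept at full precision
and rounded to 4 decimals only at rendering, so the identities
He = 1 − 1/Ne and H′ ≥ ln Ne hold to 1e-12 in tests.

## Synthetic data: what it emulates and what it does not

Generators are deterministic in (seed, specification).  Genomes are i.i.d.
base draws at a target GC (0.39 by default, typical of plastomes);
quadripartite genomes are LSC·IRa·SSC·IRb with IRb an exact reverse
complement and junction bases pinned so the IR pair cannot extend by chance.
Planted SSR tracts get their two flanking bases adjusted so tracts are
maximal.  Inversion sites are written into the base genome as
flank·segment·revcomp(flank), the segment adjusted to have no
self-complementary mirrored positions and the repeat's outer boundary pinned,
so detection recovers the planted interval and flank length exactly.

Alignments are emitted directly as ground truth: the first genotype is the
reference and carries no planted event, other rows differ from the base only
at planted events, and gap placement is exactly as planted.  This isolates
caller correctness from aligner behaviour — passing recovery tests therefore
demonstrates the callers are exact on well-formed alignments, *not* that any
aligner will present real indels or inversions in this canonical form.  Real
data also differ in ways the generator does not model: IR copies that differ
by a few bases, aligner-dependent gap shifting within repeats, ambiguous
bases, and events that overlap or abut.

The default scenario mirrors a published four-genotype plastome comparison:
region lengths 87,766 / 26,333 / 18,997 bp (LSC/IR/SSC), 45 SNPs, 17
deletions with the published length spectrum (2–458 bp), 5 inversions with
the published (length, flank) pairs, and 49 variable plus 8 invariant
mononucleotide tracts, all placed in the single-copy regions with at least
40 bp separation so events never collide and the IRs stay exact.  Genotype
simulation draws gene copies i.i.d. from stated allele frequencies
(Hardy–Weinberg); it models neither inbreeding nor null alleles, so observed
heterozygosity recovery says nothing about departures from random mating.

## Problem sizes and tolerances in the test suite

The test suite runs the full-size default scenario once and a scaled-down
variant (12 kb LSC) for per-caller tests; brute-force SSR equivalence uses
random sequences up to 5 kb; primer selection is cross-checked against an
exhaustive oracle on ~420 bp templates.  Stochastic recovery checks use
fixed seeds with tolerances chosen from sampling theory: He within ±0.01 and
H′ within ±0.02 of their closed-form values at n = 5000 individuals (the
99th percentile of the He estimator's deviation at that size is ≈0.007), and
Hardy–Weinberg heterozygosity within ±0.02 at n = 10,000.  The
error-shrinks-with-n check averages five replicate simulations per sample
size to make monotonicity robust.

## Known limitations

* Exact-match logic throughout: near-identical IRs, imperfect/compound SSRs
  and inexact inversion flanks are out of scope by design.
* The inversion detector's palindrome blind spots described above.
* Tm is a closed-form approximation; no salt correction, no mispriming
  screen beyond the perfect-complement scan.
* Interspecific comparison, rearrangements beyond small inversions, and
  F-statistics/HWE testing are non-goals.
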