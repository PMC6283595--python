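# Methods

`tadquant` quantifies chromatin regulatory state at a gene cluster sitting
on the boundary between two topologically associating domains (TADs), the
configuration of vertebrate *Hox* clusters flanked by a centromeric
("C-DOM"-like, here `cdom`) and a telomeric ("T-DOM"-like, `tdom`)
regulatory domain. Three assay layers are covered — 4C-seq viewpoint
profiles, capture Hi-C contact matrices, and ChIP-seq enrichment — plus a
seeded generator that produces all three with known ground truth.

## Coordinate backbone

All coordinates are 0-based half-open (BED convention). In-silico digestion
places a cut at the start of every occurrence of the recognition site
(overlapping occurrences each cut; zero-length terminal fragments are
dropped), so fragments tile each chromosome exactly. Fragments and reads
are assigned to regions by their midpoint; this prevents boundary-straddling
elements from being counted in two domains and mirrors the fragment-middle
position convention used for capture Hi-C pairs. The cut-at-site-start
convention shifts fragment borders by at most the site length relative to
other conventions and only needs to be fixed and stated.

## 4C viewpoint profiles

A profile is a nonnegative score per restriction fragment. Processing:

1. **Normalization.** Scores are divided by the mean score of non-excluded
   fragments whose midpoint lies within ±W of the bait midpoint
   (W = 1 Mb by default; 2 Mb is the convention for deletion alleles, whose
   rearranged neighborhood would otherwise dominate a 1-Mb window).
   Fragments outside the window are rescaled by the same constant. The
   operation is idempotent and leaves unit mean over the window.
2. **Bait masking.** The bait fragment and its two flanking fragments are
   excluded by default (self-ligation/undigested artifacts); an explicit
   exclusion list overrides the default. Excluded fragments contribute to
   no downstream sum.
3. **Smoothing.** An 11-fragment running mean (window truncated at
   chromosome ends, excluded fragments omitted from numerator and count) is
   applied for display only.
4. **Contact fractions.** Domain fractions are sums of *normalized,
   unsmoothed* scores over fragments assigned to each domain, divided by
   the total over the domain set — {cdom, tdom} by default, or
   {cdom, tdom, next_tad} for deletion alleles whose contacts spill into
   the following TAD. Fractions over the domain set sum to 1 by
   construction. Named regions (enhancers, borders) are quantified with
   ±10 kb padding over the same denominator, so a statement like "region X
   fell from 8% to 3%" is directly a difference of two such values.
   Normalized rather than raw scores are summed so fractions are comparable
   across sequencing depths; a raw-score mode exists behind a flag.
5. **Differential testing.** Two conditions sharing one fragment map are
   compared per region with a paired two-sided Wilcoxon signed-rank test
   over per-fragment normalized scores.

## Signed-rank test

Zero differences are dropped before ranking. For n ≤ 25 the null is
enumerated exactly by dynamic programming over doubled midranks, which
keeps tied absolute differences exact; the two-sided p-value is
2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)) capped at 1 (so a single nonzero pair gives
p = 1, and differences +1..+5 give p = 2/32 = 0.0625). For larger n the
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. The same routine backs the 4C and capture Hi-C
comparisons.

## Capture Hi-C matrices

Pairs (fragment-middle positions with per-mate MAPQ) are kept when both
mates map at MAPQ ≥ 30 inside the capture span, then binned symmetrically
(5-kb bins for contact maps, 10-kb for boundary calling; both parameters).
Matrices are balanced by iterative correction: bins with raw marginal
below 10 counts are masked, rows/columns are repeatedly divided by their
relative marginals until the coefficient of variation of unmasked
marginals falls below 1e-5 (max 200 iterations), and the scale is fixed so
every unmasked marginal equals 1. Balancing determines a matrix only up to
a constant, so before subtraction or testing each balanced matrix is
scaled to unit total over the cells unmasked in both inputs; differences
are then exactly antisymmetric and invariant to rescaling either input.
Sub-matrix tests apply the signed-rank routine to corresponding unmasked
bins of the two scaled matrices restricted to a rows × cols block.

## Boundary detection

The diamond bin signal at position i is the mean balanced contact between
the w bins ending at i and the w bins starting at i+1 (w = 28 at 10-kb
bins by default), truncated at matrix edges and skipping masked cells;
TAD boundaries appear as minima. Before detection the matrix is detrended
to observed/expected per diagonal: without this, diamond cells — which
span larger separations than the flanking within-domain cells — sit
systematically below them under any distance decay, and a naive filter
calls boundaries everywhere. Candidates are strict minima of the O/E
diamond signal within ±w that lie below 1 (a boundary requires depleted
cross-domain contact). Each candidate is tested with a one-sided rank-sum
comparison of diamond versus flanking within-domain cells *stratified by
bin separation* (per-separation U statistics combined under the normal
approximation, van Elteren style), because O/E values at different
separations have different count-noise distributions and an unstratified
rank test is anticonservative. Since each candidate is the minimum of
~2w+1 overlapping positions, the p-value is Šidák-adjusted by that factor
before comparison with the threshold (0.05 default). Candidates closer
than w bins resolve to the lower signal. The reported position is the
start of the first bin of the downstream domain. This is a simplification
of the TopDom procedure — windowed minima plus stratified rank filtering
in place of the piecewise-linear turning-point fit — with the same inputs
and outputs. Boundary calling below 10-kb bins warns: sparse capture data
leave too many gaps at higher resolution.

## ChIP quantification

Reads are extended to a fixed fragment length (300 bp) from their 5′ end
in strand direction, binned (25 bp), and each library is scaled to reads
per million (RPM) of its own total; per-bin values are
log2((chip + ε)/(input + ε)) with ε = 0.5 applied on the RPM scale, which
keeps every bin finite and makes tracks depth-invariant up to ε effects.
RPM was chosen as the library-scaling rule (a flag allows scaling to the
smaller library instead) because depth invariance is the property
cross-sample comparisons need. Region enrichment is the analogous log2
ratio of RPM-scaled read counts assigned by extended-interval overlap.
1x-depth normalization scales counts by genome_size/(reads × read_length);
the effective genome size is a required input, never guessed. Motif
orientation under a peak is the strand of the best log2-odds PWM hit
(uniform background, probabilities floored at 1e-9) over forward and
reverse-complement scans; best scores within 1e-6 are "ambiguous". The
bundled CTCF-like PWM is a synthetic stand-in built for the simulations,
not a curated database motif.

## Synthetic locus generator

The generator emulates the data structure of the two-TAD locus, not its
sequence content. A 3-Mb locus carries `cdom` (1.2 Mb), the 50-kb cluster,
`tdom` (1.13 Mb) and a 400-kb next TAD; fragment lengths are drawn
uniformly in [0.5, 1.5]× a 1.5-kb target median, accidental recognition
sites in the random background are mutated away, and planned sites (plus
two convergent synthetic CTCF motifs flanking the cluster) are stamped in,
after which the fragment map is obtained by digesting the finished
sequence. Every stream is seeded (per-condition streams differ by a CRC of
the condition name); identical config + seed give byte-identical outputs.

- **4C:** expected fragment counts decay as d^−α from the bait (α = 1.0, a
  typical sub-Mb contact-decay exponent; softened below 1 kb), are
  multiplied by per-condition enhancer strengths (renormalized within each
  domain so they shape profiles without moving fractions), and are
  budgeted so the cdom:tdom split of domain-directed signal is exactly
  ρ : 1−ρ, with 5% fixed budgets each for the cluster and the next TAD.
  Default conditions ρ = 0.26 ("proximal") and 0.51 ("distal") reproduce
  telomeric fractions of 0.74 and 0.49 — a reallocation of 0.25 — at an
  expected depth of 1e5 counts. Counts are Poisson by default; a
  negative-binomial option (dispersion 0.1) models the over-dispersion of
  real fragment counts.
- **Capture Hi-C:** pair probability over a 10-kb sampling grid decays as
  d^−α, is multiplied by the insulation factor (0.2) across the planted
  boundary (cluster midpoint), and carries symmetric enhancer × cluster
  stripes scaled by condition strengths — the simplest structure that
  makes subtraction maps and sub-matrix tests meaningful. 5% of pairs
  receive a sub-threshold MAPQ on one mate. Default depth 4e5 pairs.
- **ChIP:** input reads are uniform; ChIP reads are a mixture of uniform
  background and region-concentrated components so in-region density is
  fold × background. Because libraries are scaled to their own totals, the
  realized enrichment is log2(fold) minus a small compression that
  vanishes as the enriched area fraction shrinks; generator reads are full
  fragment intervals, so recovery is evaluated with read extension 0.

What the generator does **not** emulate: mappability and GC bias, PCR
duplicates, restriction-efficiency variation along the locus, ligation
artifacts, off-target capture, sub-TAD structure and loops, and realistic
sequence composition. Passing recovery tests therefore demonstrate that
the estimators are correct and well-calibrated under the stated generative
model, not that they are robust to every artifact of real libraries.

## Validation problem sizes

Recovery properties are checked at the scale the methods target: fraction
recovery over telomeric fractions {0.40, 0.49, 0.70, 0.74, 0.83} at depth
1e5 across 100 seeded replicates each (observed max error < 0.005, well
inside the ±0.02 tolerance); the Δ = 0.25 two-condition scenario detected
at p < 0.01 with Δ̂ within ±0.03 in 100/100 replicates; planted-boundary
recovery (150 bins, contrast 4, ≥ 50 expected near-diagonal counts,
Poisson noise, w = 28) within ±1 bin in 100/100 replicates with uniform
matrices yielding zero calls; digestion against an independent naive-scan
oracle on 1,000 random kilobase sequences; the exact signed-rank branch
against full 2^n enumeration for n ≤ 12 on 200 random datasets; strand
antisymmetry of motif calls on 500 random sequences; and byte-determinism
of the end-to-end demo. `scripts/acceptance.py` recomputes all of these
from scratch.

## Known limitations

- Boundary calling assumes a single dominant insulation scale; nested
  sub-TADs within one window are resolved to the strongest minimum.
- The O/E detrend uses per-diagonal means over the whole matrix; strong
  compartment-scale structure would bias it (no compartment analysis is in
  scope).
- Balancing on small matrices (tens of bins) inflates edge bins relative
  to the decay expectation, bowing the O/E signal; boundary statistics are
  calibrated for matrices much larger than the window.
- The exact signed-rank branch is O(n · Σranks) per test and is capped at
  n = 25 by default; beyond that the tie-corrected normal approximation is
  used.
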