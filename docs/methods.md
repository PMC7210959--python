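# Methods

## Scoring model

A chromothriptic chromosome is detected from its copy-number footprint
alone: many switches between integer copy-number states packed into a
bounded genomic window.

Segments of one sample and chromosome are validated (sorted,
non-overlapping, 0-based half-open) and runs of equal adjacent states are
merged before counting; a switch sits at each boundary between unequal
adjacent states, at the start coordinate of the later segment. The densest
window is the largest set of consecutive switches whose inclusive span
(last minus first position) is at most the window size `W` (default
50 Mb); a two-pointer scan finds it in O(n), and the unit tests check it
against exhaustive enumeration over all index pairs. "Within 50 Mb" is
read as an inclusive span — two switches exactly 50 Mb apart are in one
window — so the boundary is deterministic and is tested explicitly.

Tiers: high >= 10 switches in a window, intermediate 8–9, low 6–7. Switch
clusters separated by more than one window span are scored as separate
calls. The reported region is the minimal hull of all switches that lie in
at least one window qualifying at the achieved tier; alternative hull
definitions change only the annotation, never the tier. Distinct
copy-number states are counted over segments overlapping the region;
canonical means <= 3. Telomere involvement means the region comes within a
margin (default 1 Mb, configurable) of a chromosome end; centromere
involvement means overlap with the centromere interval of the genome
model. Sex chromosomes are scored like autosomes, and WES-derived
segmentations go through the same operations — resolution differences
live in the input, not the algorithm.

Copy numbers from callers are real-valued; the integer state is obtained
by half-up rounding (2.5 -> 3), a documented convention chosen because the
scoring operates on states and callers differ in whether they emit
integers. One coordinate convention (0-based half-open) is used
everywhere.

## Chromosome enrichment

Within one tumour entity (eligibility: more than 10 chromothripsis-
positive cases, configurable; calls at high+intermediate confidence by
default), each sample's chromothriptic region sizes are re-placed
uniformly at random across autosomes + X — chromosome chosen
proportionally to its count of feasible start positions, start uniform,
regions of one sample non-overlapping, sizes preserved exactly. The
default success rule ("peak") counts a permutation as a success for
chromosome c when the permutation's maximum per-chromosome count reaches
the observed count on c; the published description of this statistic is
ambiguous, so the literal per-chromosome rule is also implemented behind a
flag rather than guessed silently. `p = (1 + successes) / (1 + N)`
(add-one Monte-Carlo correction, so p is never 0), Bonferroni across
chromosomes. The default N = 50,000; tests and the bundled examples use
smaller N since the estimate's Monte-Carlo error scales as `1/sqrt(N)`.

## TERT genome walking

From the locus boundary the walk scans outward along the chromosome.
Traversing an SV jumps to its partner breakend and continues in the
direction implied by the partner's orientation: a head breakend (BEDPE
strand `-`) continues toward decreasing coordinates, a tail breakend
(`+`) toward increasing ones. Only intra-chromosomal scanned distance
counts against the 50 Mb budget; the jump is free. At most two SVs may be
traversed per direction ("two upstream and two downstream"), and the walk
links the locus to a chromothriptic region as soon as any scanned interval
overlaps one. The walker is checked against an independent brute-force
enumeration of all <= 2-hop chains, and is invariant under mirroring the
genome's coordinates. The association readout is a 2x2 Pearson chi-square
(no continuity correction by default) of linkage by TERT-gain status.

## Breakpoint homology

Homology lengths are binned into {0–1, 2, 3–5, 6–9, >=10} bp. The
published bin labels leave length 10 unassigned ("6–9" vs ">10"); it is
placed in the top bin. Unknown homology lengths are excluded, not
imputed. Units are samples (case-wise) or sample x region-class
(region-wise, an SV belonging to the chromothriptic class when either
breakend lies on a chromothriptic chromosome of that sample — chromosome-
level by default, region-level available). Per bin, the proportion is
modelled with beta regression (statsmodels `BetaModel`, logit mean link,
constant precision) on the group indicator, after Smithson–Verkuilen
shrinkage `y' = (y(n-1) + 0.5)/n` because the beta likelihood is undefined
at 0 and 1. Bonferroni across the five bins. Entity eligibility for the
contrast: >= 15 cases with >= 5 in each arm.

## Fusion validation and regression

Medium- and high-confidence fusion calls are kept; each breakpoint is
matched to the nearest SV breakend of the same sample on the same
chromosome (strand ignored — fusion and SV callers disagree on
orientation conventions), and the fusion is validated when both distances
are <= 200 kb (inclusive). Both breakpoints matching one SV or two
different SVs are both accepted.

The excess of fusions in chromothripsis-positive tumours is a coefficient
in a log-link count model: `log E[fusions] = b0 + b1 log(SV count) +
b2 status`, so `exp(b2)` is the fusions-per-SV rate ratio. The default
family is negative binomial (robust to overdispersion); when the
dispersion estimate collapses to the Poisson boundary the NB Hessian is
singular, and inference is taken from the Poisson limit instead. A Poisson
family is available by flag.

## Cohort associations

Prevalence is positives/cases per entity (entities under 5 cases reported
separately) and cohort-wide, at a chosen tier. The germline two-hit
contrast is a two-sided Fisher exact test on (second hit) x
(chromothripsis) among germline-variant carriers. TERT-gain and
ATRX-truncation groups are each contrasted against "neither" by Pearson
chi-square at the high+intermediate tier. Gain/loss profiles report, per
genomic bin, the fraction of samples in each group with state above/below
the diploid baseline. Signature contrasts are two-sided Wilcoxon rank-sum
tests on `log2(exposure + 1)` (pseudo-count because zero exposures exist;
absolute exposures or fractions both work), Bonferroni across signatures.
Longitudinal pairs classify as both-negative / lost / gained / stable /
changed; "stable" requires equality of the chromothriptic chromosome
sets, with a Jaccard-threshold relaxation behind a flag (default 1.0)
since the published scenarios are qualitative.

## Synthetic cohorts

The generator is a test harness emulating the statistical structure the
analyses assume, not a mechanistic simulator of micronucleation or
bridge resolution. Per positive sample it plants `1 + Poisson(1.5)`
events (~78% multi-chromosome) on length-weighted chromosomes. Each event
spans U(20, 50) Mb, carries `10 + Poisson(25)` breakpoints placed
uniformly within the region (breakpoint clustering is modelled at region
scale; no finer hotspot structure), uses k distinct states with
P(k) = {2: .35, 3: .35, 4: .15, 5: .10, 6: .05}, touches a telomere with
probability 0.36 (region end pinned at the chromosome end, one breakpoint
forced within the telomere margin) and spans the centromere with
probability 0.55. The intra-region state sequence opens and closes at the
diploid baseline so the planted switch count equals the breakpoint count
exactly; with k = 2 that requires an even count, so an odd one is bumped
by one. One SV is emitted per internal junction with both orientations
drawn independently at random — join classes are uniform over the four
types by construction. Background noise is sparse long CNVs
(Poisson(3) per sample, 5–30 Mb, so chance clusters of >= 6 switches in
50 Mb are rare and high-tier specificity is testable) and Poisson(15)
sporadic SVs.

Homology lengths are drawn per group from categorical distributions over
the five bins (chromothriptic SVs {.40, .12, .28, .12, .08}; background
{.28, .12, .22, .16, .22}), uniform within a bin (top bin 10–50 bp).
Fusion counts are Poisson with rate `0.05 x SV count x 5^status` (planted
rate ratio 5), with breakpoints offset up to 50 kb from real SV
breakends. TERT gains occur with probability 0.32 given chromothripsis
and 0.20 without, which reproduces a ~25% gain marginal and conditional
prevalences near 61%/44% at the ~49% overall planted prevalence of the
default two-entity mix; positive samples additionally receive an SV
linking the TERT flank into a chromothriptic region with probability 0.30
(gain) or 0.05 (no gain). Germline carriers (12%) get a second hit with
probability 0.40 and chromothripsis probability 0.50 (hit) vs 0.256 (no
hit). Signature exposures are log-normal with a 2x multiplier on two of
the four bundled signatures in positive samples. Longitudinal pairs share
a patient id and follow stable / lost / gained scenarios (default 30
pairs, equal mix), with the stable scenario re-planting events on the
same chromosome set.

Everything is driven by one `numpy` generator seeded from the config, and
identical configs produce byte-identical output files.

What passing tests on these cohorts do **not** show: robustness to
subclonal copy numbers, purity/ploidy distortions, segmentation noise at
WES resolution, caller-specific artefacts, or hotspot breakpoint
distributions — real data have all of these and the generator none.

## Numerical choices and problem sizes

- Monte-Carlo p-values use the add-one correction; ties in window search
  resolve to the leftmost window.
- Beta-regression boundary proportions are shrunk (see above); bins with
  identical proportions across all units are flagged non-identifiable
  rather than fitted.
- Degenerate contingency tables (an empty margin) are flagged and return
  NaN p-values instead of raising mid-pipeline.
- The test suite exercises planted-truth recovery on a 200-sample cohort
  plus 30 longitudinal pairs, parameter recovery over 200 regression
  replicates, and type-I calibration of the homology contrast over 1000
  null replicates — sizes chosen to keep Monte-Carlo standard errors
  small relative to the asserted bounds while the whole suite runs in
  about a minute.

## Known limitations

- The scorer uses copy-number evidence only; SV-based corroboration of
  switch clusters (fragment-join randomness tests and the like) is out of
  scope, as are subclonality estimation and derivative-chromosome
  reconstruction.
- The enrichment null is uniform by sequence length; GC/mappability-
  matched nulls are not implemented.
- The walker follows at most two SVs per direction; deeper chains are
  deliberately not explored, matching the published procedure it
  re-implements.
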