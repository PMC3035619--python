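# Methods

`eqtlcross` implements a genome-wide expression QTL (eQTL) linkage
analysis for an F2 cross between two outbred lines (the motivating design
is a Duroc x Pietrain pig resource population), together with a synthetic
data generator that reproduces the experimental design closely enough for
every stage of the analysis to be validated against known ground truth.

## The line-cross model

The cross is assumed fixed for alternative QTL alleles in the two founder
breeds. For an F2 individual at a genome position x, let (pDD, pDP, pPP)
be the probabilities that its two homologs are both Duroc-origin,
mixed, or both Pietrain-origin given the observed marker data. The
additive coefficient is

    c_a(x) = pDD(x) - pPP(x)  in  [-1, 1],

the expected additive genotype code. Per transcript, normalized log2
intensity is modeled as

    Y = mu + Dye + Sex + growth_group + c_a * a + Array + Litter + e

with Dye (Cy3/Cy5), Sex and growth_group (2 selection criteria x
high/low = 4 levels) fixed; Array and Litter independent random effects;
e residual. The null hypothesis a = 0 is tested by a two-sided t-test at
every scan position.

### Scan grid

Positions are every marker plus k equidistant points strictly inside each
adjacent marker interval (default k = 11). A map of 124 markers in 19
linkage groups therefore yields 124 + 11 x (124 - 19) = 1,279 positions;
with a 20,400-probe manifest this is 26,091,600 planned tests.

## Breed-of-origin probabilities

**Marker level.** For each F2 and marker, the posterior over the joint
(paternal, maternal) homolog origin is obtained by exhaustive enumeration
over: which observed F2 allele came from which F1 parent, each F1
parent's phase (which allele descends from its Duroc sire vs its
Pietrain dam, weighted by F0 transmission probabilities), and which F1
homolog was transmitted. Fully informative markers give degenerate
posteriors; markers whose allele sets do not separate the breeds give the
F2 prior (1/4, 1/2, 1/4). Mendelian inconsistencies are flagged, logged
and assigned the prior.

The posterior is kept as the joint 2x2 law rather than per-gamete
marginals: a genotype such as 1/3 at a fully informative marker proves
heterozygosity (c_a = 0 exactly) without resolving which gamete carries
the Duroc allele; the per-gamete marginals there are (1/2, 1/2) and would
be indistinguishable from "no information".

**Between markers.** Each gamete's origin along a chromosome is a
two-state Markov chain with transition probability r(d) given by the map
function (Haldane by default, Kosambi optional). The position posterior
conditions on the nearest informative flanking marker on each side
(the interval-mapping convention; evidence beyond the nearest flanks is
deliberately ignored, a full multipoint HMM being the documented
extension point). The two gametes recombine independently, so the
four-state transition is the Kronecker product of the per-gamete
transitions. With certain Duroc/Duroc flanks 10 cM away on both sides
this reduces to the classical per-gamete conditional
(1 - r10)^2 / (1 - r20) ~ 0.990, i.e. pDD ~ 0.980.

## REML + GLS scan

Variance components (sigma2_array, sigma2_litter, sigma2_e) are estimated
once per transcript by REML under the null model and then held fixed
while the additive effect is tested by generalized least squares at every
position. This is the computationally tractable implementation of the
line-cross scan: one REML fit plus thousands of cheap GLS t-tests per
transcript instead of a mixed-model fit per transcript x position.

The REML criterion is profiled over the residual variance and optimized
over the two variance ratios with Nelder-Mead within bounds (boundary
zeros allowed), from two starting points, with an L-BFGS-B fallback.
When every array's two channels fall inside a single litter and arrays
within a litter have equal size — always true for the paired
selective-phenotyping design — the covariance
I + g_a Z_a Z_a' + g_l Z_l Z_l' has an eigenbasis independent of the
ratios (litter means, between-array contrasts, within-array contrasts),
so each objective evaluation costs O(n) after a one-time rotation. A
generic Cholesky path covers all other designs; the two paths agree to
machine precision and the optimum is cross-checked against statsmodels
MixedLM in the test-suite (our optimizer occasionally finds a strictly
better optimum than MixedLM's default settings).

Numerical choices: fixed-effect dummies are treatment-coded; aliased
columns are dropped first-kept via sequential orthogonalization; a fixed
factor whose sample partition equals a random factor's is rejected as
confounded. Residual df = n - rank(fixed design including c_a), a simple
conservative choice (Satterthwaite is an extension point). Positions
where c_a is numerically constant are flagged and reported with a_hat =
0, p = 1. The per-transcript variance fraction is

    h2 = a_hat^2 Var(c_a) / (a_hat^2 Var(c_a) + s2_array + s2_litter + s2_e)

computed at the minimum-p position. This h2 is a reconstruction of a
conventional summary; it is not claimed to reproduce any previously
published per-gene values.

## Multiple testing, peaks, hotspots

q-values use Storey's estimator with the smoother method for pi0
(cubic polynomial over lambda in {0.05, ..., 0.95}, evaluated at 0.95),
falling back to pi0 = 1 (Benjamini-Hochberg) for short vectors (< 100)
or estimates outside (0, 1]. Two significance tiers are exposed:
exploratory P < 1e-4 and confirmatory P < 3.5e-6 (the FDR < 10% tier of
the motivating study).

Peaks collapse contiguous runs of significant positions per transcript
and chromosome to the minimum-p position (ties broken leftmost); a
non-significant position or chromosome boundary ends a run. This strict
run rule is deterministic and oracle-checkable; merging runs across
small gaps is a possible variant that we do not apply. Hotspot counts
are the number of transcripts significant at each position, compared
with the null expectation n_traits x alpha; exceedances are flagged as
descriptive putative hotspots only (no permutation correction).

## Local vs distant classification

Probe positions come from precomputed probe-to-genome alignment records:
alignments with more than 3 mismatches are dropped, probes with multiple
surviving alignments are discarded as ambiguous, and the rest get a
unique bp position (BED conventions, 0-based half-open). A peak on the
probe's chromosome is *local* (putatively cis-acting), elsewhere
*distant*, and *unpositioned* when the probe has no unique placement
(including alignments only to unplaced scaffolds). Running the aligner
itself is out of scope.

## Co-localization

eQTL and pQTL peaks are widened by 5 cM to each side (truncated at
chromosome bounds). Modeling both interval centers as independent
uniforms on a single 3,000 cM line, the overlap probability of two
length-L intervals is 2L/G - (L/G)^2 (~ 0.00666 for L = 10 cM) and the
p-value for a center distance d is 2d/G - (d/G)^2, independent of the
interval length. The quadratic term is retained because it is the form
the Monte-Carlo null reproduces (the difference is negligible for
d << G). Overlapping pairs are merged transitively into common genomic
regions whose reported p-value is the largest pairwise p-value in the
group. Per-chromosome placement of the null is a possible refinement
that would make small p-values conservative relative to the single-line
model.

## The synthetic-data generator

The generator reproduces the study design: 4 Duroc F0 sires x 16
Pietrain F0 dams; 56 F1 (male fraction 6/56, mirroring the 6 retained F1
boars); 44 litters with 4 profiled F2 each (176 samples). Litters split
24/20 between loin-muscle-area and backfat selection criteria. Within
each litter the two extreme males and two extreme females by a simulated
selection trait (independent of expression) are chosen; males are paired
on one two-color array, females on another; the high male and low female
share a dye, with dye pairs alternating across litters so each dye is
used equally per phenotype group.

Founder genotypes use breed-disjoint allele pools with probability
`informativeness` per marker (else shared pools), a deliberate
abstraction of partially informative microsatellites that avoids
modeling per-locus allele frequencies. Gametes are simulated as Markov
transmission over marker intervals with the map-function recombination
fraction per interval and at most one uniformly placed crossover
breakpoint per interval: adjacent-marker recombination fractions are
exact under either map function, while within-interval double crossovers
are neglected and the Kosambi chain is interference-free across
intervals. True origins are therefore retrievable at any cM position.

Expression values follow the mixed model above with the truth table's
effects. Defaults: sigma2_e = 1.0, sigma2_array = 0.05, sigma2_litter =
0.05 on the log2 scale — magnitudes typical for normalized two-color
microarray data where technical and litter variation are small relative
to biological residual noise; the defaults live in the YAML config and
truth tables, not in the analysis code. eQTL are placed at marker
positions (where origin information is sharpest) with additive effect
0.5 by default; a configurable fraction of pQTL coincide with eQTL
positions to emulate shared genetic control for the co-localization
stage.

What the generator does *not* emulate: genotyping error, X-chromosome
dosage, crossover interference within marker intervals, spatial array
artifacts beyond the smooth intensity trend, probe cross-hybridization,
and real microsatellite allele-frequency spectra. Passing tests
therefore demonstrate correctness of the inference machinery under the
declared model, not robustness to these artifacts.

## Two-color normalization

Per array: M = log2(ch1/ch2), A = (log2 ch1 + log2 ch2)/2; a loess fit
of M on A (span 0.4, degree 1, 3 robustness iterations — the method's
customary defaults, as the source protocol names the method but not its
parameters) is subtracted within each print-tip block; blocks below a
minimum size fall back to a whole-array fit with a warning. Scale
normalization divides each block's M by its MAD and multiplies by the
geometric mean of block MADs (within-array across print-tips; applying
it across arrays instead is a documented alternative). No background
correction is applied, and the spot count is never changed. The linkage
model consumes per-sample single-channel values reconstructed as
A ± M/2, letting the Array random effect absorb the shared A component.

## Problem sizes in the test-suite and acceptance script

The statistical checks run at sizes chosen to give tight Monte-Carlo
error while remaining quick on one CPU: 10,000 null transcripts for
type-I calibration (each tested at one grid position so the pooled
p-values are independent for the KS test), 500 transcripts for effect
recovery (a = 0.5), 20 replicate studies of 150 probes for FDR control,
10^6 draws for the overlap null, and a 500-probe default pipeline for
byte-level determinism. `scripts/acceptance.py` recomputes the same
quantities at moderately reduced sizes (2,000 / 200 / 5) and reports
them with their problem sizes. A q < 0.10 call counts as false when its
transcript carries no eQTL or the called chromosome differs from the
true one; same-chromosome linked positions count as true recoveries.
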