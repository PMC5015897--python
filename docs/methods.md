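# Methods notes

This note records the models, parameter choices and numerical decisions
behind `lobeqtl`, and what the synthetic data can and cannot establish.

## Breeding model

The advanced intercross is bred generation by generation: reciprocal F₁
crosses between the homozygous SS and T7 founders, all-pairwise mixing at
F₂, then random mating within a finite population (default census 300,
configurable) through to F₁₃, where male recombinants are sampled. Census
sizes in a vial-based fly cross are not precisely knowable, so 300 is a
deliberate round choice on the scale of a multi-vial population;
drift-induced allele-frequency skew is an emergent property of the finite
census, not a target. Selection is not modeled.

Meiosis is female-only (as in flies): male gametes transmit each
chromosome intact, a male's X goes only to daughters, and chromosome 4
never recombines in either sex. Female crossover counts per chromosome
are Poisson with mean equal to the female map length in Morgans — no
interference and no obligate chiasma — which makes the Haldane map
function exactly correct for the simulator and keeps simulator, map
estimation and HMM internally consistent. Within a chromosome the cM↔bp
relation is linear by default, with a hook for piecewise-linear anchor
maps. The default genome is the five major arms plus chromosome 4 at
release-6 physical lengths, with female map lengths summing to 276 cM.

### Map expansion: autosomes vs the X

For tightly linked markers, each haplotype of a sampled fly accumulates
visible recombination at rate h·d per transmission through a female,
where d is the female map distance and h the probability the
transmitting parent's two homologs differ in parental origin at the locus
(h = 1 in the F₁, ≈ 1/2 thereafter at intermediate allele frequency).
An autosome passes through a female in half of its transmissions, giving
the exact recursion Eₜ = E₂ + (t−2)·d/4 with E₂ = d/2, i.e. a fold
expansion of 0.5 + 0.25(t−2) = **3.25 at t = 13** over the standard
female map — the familiar s/2 with s = t/2 effective generations.

The X is different *in this direction*: an X spends two thirds of its
history in females, so it passes through a recombining germline in 2/3 of
transmissions — more often than an autosome, not less. The same recursion
gives an X expansion of ≈ **4.45 at t = 13**, and the pedigree simulator
reproduces 4.3–4.9 across seeds (drift in a census of 300 adds spread).
The widely quoted "X expands by 2/3 of the autosomal factor" applies to
designs in which autosomes recombine in both sexes; under female-limited
recombination it holds only relative to an F₂-estimated map of the same
cross, not relative to the standard female map used as the reference
here. In real fly AILs, strong X allele-frequency skew (regions fixed for
one parent) depresses h and therefore the *observed* X expansion well
below the neutral expectation; the neutral simulator deliberately does
not emulate such selection, so its X expansion sits at the theoretical
value. This is the one place where the package's simulated design value
knowingly exceeds the conventional printed expectation.

## Read-count generator

Depth per SNP is Poisson (optionally gamma-Poisson overdispersed), halved
on the male X. Each read supports the true allele with probability 1−ε
and the other parental allele with ε (default 0.005), so SS+T7 counts sum
to the drawn depth. Two regimes: WGS covers every SNP uniformly (default
mean 5 reads/SNP); MSG zeroes coverage outside a random set of 50 kb
blocks shared by all MSG samples (default 40% of blocks, mean 2.5
reads/SNP within them), emulating restriction-site-anchored reads as
coverage sparsity only — no restriction-site sequence model, because the
downstream pipeline sees only counts. Parental strain samples are drawn
at a higher uniform depth (default 10×), reflecting the deeper sequencing
a two-strain panel gives its parents; without that, the "both parents
covered" SNP filter would discard most sites at desk scale.

## Planted phenotype architecture

The default six-locus architecture places four loci on trait axis 0
(one hemizygous on the X, one overdominant on 3R) and two on axis 1
(both on 3L, one overdominant), with additive effects defined so that
replacing a T7 allele with an SS allele adds +a. Effects are on the scale
of shape-PC scores in mm units (3.4·10⁻⁴ … 13.3·10⁻⁴). Residual noise
SDs (2.17·10⁻³ and 1.16·10⁻³ on the two axes) are set so the per-locus
variance fractions at 50:50 allele frequency span ~2–14% — the analytic
fractions are a²/2 + (d/2)² per autosomal locus and a² for a hemizygous
X locus, over locus variance plus residual. Realized fractions in any one
cohort drift with allele frequencies.

Each trait axis displaces a smooth base lobe outline (≈ 0.05 mm wide,
mm units) along a fixed unit vector in Fourier-coefficient space — a
width-like stretch for axis 0 and a size-like dilation orthogonalized
against it for axis 1 — so the planted axes are geometrically meaningful
and recoverable as leading PCs. Left and right lobes share the genetic
value; their environmental deviations are drawn with the correlation
needed to hit a total bilateral correlation of 0.75 given the realized
genetic variance. Both lobes are scored with probability 0.58 (one side
otherwise), and raw outlines are randomly rotated, translated and
side-mirrored so the standardization step does real work. Not emulated:
digitizing noise along the outline, imaging failures, allometry with body
size, and selection on the trait during breeding — so passing tests
establish correctness of the computation, not robustness to those
real-data artifacts.

## Genotyping decisions

- Windows are 0-based half-open [k·250000, (k+1)·250000); a 1-based SNP
  position p maps to window (p−1)//250000; the last window of each arm is
  truncated.
- Call precedence is depth gate → 10× homozygote ratio → closed het band
  [0.3, 0.7] → no call; a ratio of exactly 10× is homozygous.
- A heterozygous call on a male X is biologically impossible and is
  forced to no-call; male X markers are treated as two-class everywhere
  downstream.
- SNP-level calls used by filters 5–6 are defined from counts: a
  recombinant yields a call when it has 1–500 reads on the parental
  bases, heterozygous when both bases are seen.
- Window MAF is computed on allele counts over called recombinants
  (2 per autosomal genotype, 1 per male-X genotype). A window is masked
  when its called fraction is below 90% **or** its MAF is below 5%; the
  MAF clause also removes regions fixed for one parent, where no mapping
  information remains, so no separate manual exclusion step exists.
- Parents are exempt from recombinant-only filters and from the
  individual call-rate filter.

## Morphometrics decisions

- "Centroid" is the polygon area centroid, robust to uneven manual point
  spacing, not the vertex mean.
- The standardized traversal is clockwise; mirroring happens before
  rotation; the lobe body is placed above the horizontal baseline.
- The elliptic Fourier descriptor is 25 harmonics × 4 coefficients with
  the DC terms excluded (they vanish after centering, and only without
  them does the count come to 100); no size, rotation or phase
  normalization is applied, so coefficients keep mm units and size
  remains in the descriptor.
- The shape PCA is centered and unscaled (all coefficients share units),
  runs jointly over parental and recombinant lobes, and each PC is
  oriented so the mean SS parental score is ≥ the mean T7 score (largest
  loading positive as fallback) to make signs reproducible.
- Height/width use the outermost intersections of the vertical/horizontal
  centroid chords when the boundary is crossed more than twice.

## Mapping decisions

- The AIL panel is analysed as an F₂-type intercross on its own estimated
  (expanded) map. F₁₃ genotype frequencies depart from 1:2:1 (het deficit
  from drift); that prior mismatch is absorbed by the data and is noted,
  not corrected.
- Adjacent recombination fractions come from a multipoint
  (Baum–Welch) EM over each chromosome's whole marker chain with a small
  emission error (default 10⁻⁴), not from complete-case adjacent pairs:
  crossover-containing windows often fail the calling thresholds and go
  missing, and complete-case estimation would censor exactly those
  recombinants (observed as a map shortened by tens of percent). The
  multipoint EM integrates over the missing calls and recovers the
  expansion to within a few percent of truth-genotype estimates.
- r is capped at 0.4999 before the Haldane transform; identical columns
  give 0 cM; a chromosome with < 2 informative markers is excluded from
  totals.
- The scan HMM uses a symmetric genotyping error rate (default 0.01) and
  a 1 cM pseudomarker lattice unioned with the markers.
- The default scan is Haley–Knott on expected dosages (deterministic);
  multiple imputation (default 64 draws, seed-controlled) combines
  per-draw LODs as log₁₀ of the mean of 10^LOD and agrees with hk at
  fully observed markers.
- Permutation thresholds split the overall α across X and autosomes in
  proportion to genetic length (α_c = 1 − (1−α)^(L_c/L)); the X
  permutation count is scaled up by L/L_X to stabilize the more extreme
  quantile. With no X positions the split degenerates to the plain α.
- bp positions anchor each marker at its window midpoint, and pseudomarker
  bp values interpolate linearly between flanking anchors.
- Multi-QTL fits regress on expected dosages at the peaks (equivalent to
  averaging imputation draws), report drop-one LOD and variance
  explained, test pairwise interactions by F-tests on the product terms,
  and scan for further QTL with the fitted peaks as covariates. Collinear
  peak sets fall back to least-norm estimates with a warning.

## Experiment scales

The design-level experiments run at the study's dimensions, chosen as
realistic desk-scale replicates: map expansion uses five cohorts of 400
males (population 300, dense error-free window markers); the threshold
experiment uses 181 recombinants at 426 markers (70/86/78/87/105 on
X/2L/2R/3L/3R) on the ~822 cM realized map with 1000 permutations, with
marker genotypes drawn from the intercross Markov chain on that map — the
exact model under which the scan and thresholds are defined; the recovery
experiment runs 20 replicate 181-male cohorts through the full
outline→EFA→PCA→scan path with per-replicate thresholds. Two planted PC2
loci share arm 3L with opposite-sign additive effects, so each one's
marginal scan signal is diluted below its planted variance fraction;
detection rates for ~12–14% loci sit near, and sometimes below, 90% per
replicate at n = 181 — an honest property of that architecture rather
than a tunable.

## Known limitations

- No interference means slightly more double crossovers than real fly
  meiosis; realized maps are correct in expectation but segment-length
  distributions are exponential-like.
- The simulator is neutral: it does not reproduce the strong
  allele-frequency skews (and their depressing effect on observed X map
  expansion) that selection imposes on real AILs.
- MSG is coverage sparsity only; barcode structure, restriction-site
  polymorphism and PCR duplicates are out of scope.
- The cross-file reader recovers marker order from the stored cM
  positions and does not round-trip physical window bounds.
- Cytological band conversion and two-dimensional two-QTL grid scans are
  out of scope.
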