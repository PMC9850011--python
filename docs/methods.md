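# Methods

This note records the models implemented, the choices made where the
design was genuinely open, and what the synthetic generators do and do
not emulate.

## Genetic data model

Sequence data are per-locus FASTA alignments plus a CSV mapping
individuals → populations → regions. Nuclear loci are assumed supplied as
*phased* haplotype sequences, two per individual (`allele_index` 1/2);
the mitochondrial locus carries one sequence per individual. Missing
data follow complete deletion: any column containing `N` or `-` in any
sequence is dropped before every statistic. Haplotype identity is exact
string equality on the retained columns — no distance thresholding.

The four-gamete recombination screen reports every pair of biallelic
columns showing all four gametic types and a greedy-minimal exclusion
mask (repeatedly drop the column in the most violating pairs, ties to
the leftmost). Greedy was chosen over exact set cover because the mask
is a pre-filter, not an inference target; the test suite checks the
greedy mask size equals the exhaustive-search optimum on small cases.

## F_ST, bootstrap, AMOVA

Pairwise F_ST is the Weir–Cockerham ANOVA estimator θ computed on
haplotype frequencies with haploid variance components (each sequence is
one allele copy). Multilocus θ sums components across loci (ratio of
sums), which weights loci by information rather than averaging noisy
per-locus ratios. Monomorphic loci (or bootstrap replicates) contribute
zero components; a replicate monomorphic everywhere contributes θ = 0.
Significance uses a 95% percentile bootstrap (default B = 1000,
resampling unit = sequence within population); "significant" means the
CI lies entirely above 0. Two caveats are inherent to the estimator and
surface in the tests: with identical samples θ is biased by about
−1/(n−1), and at very high per-locus diversity (every haplotype unique)
θ is capped far below 1 regardless of divergence — the classic G_ST
ceiling. The AMOVA view, carrying full distance information, does not
share the ceiling.

AMOVA uses squared distances = counts of differing retained columns and
a nested decomposition over any of (region, population, individual).
Expected-mean-square coefficients are computed numerically from the
group-size structure (this reproduces the classical unequal-size n',
n'', n''' coefficients at any depth, verified by literal sums-of-squares
oracles and by the exact identity Φ_ST = θ under 0/1 distances). Raw
components may be negative and are reported as such; they are clamped to
zero only for the percentage column. The within-individual level is
undefined for haploid loci and rejected; level choice is configuration,
not inference.

## Neutrality tests

Tajima's D uses the standard constants; D and the normalized Fay–Wu H
(θ_π − θ_L over its estimated standard deviation, with θ and θ² from the
Watterson-based estimators) are flagged undefined at S = 0. Polarization
uses a single designated outgroup sequence; columns where the outgroup
is gapped, ambiguous, carries a state absent from the ingroup, or where
the ingroup has >2 states are excluded and counted.

The DHEW compound test simulates its null conditioned on the observed
(n, S): fixed-S placement on simulated genealogies, removing
θ-estimation noise. The common per-component quantile q* is calibrated
by 40-step binary search so that the empirical joint mass of
{D ≤ d_q, H ≤ h_q, F ≥ f₁₋_q} is ≤ α; because the three statistics are
positively associated in the rejection direction, q* is typically much
larger than α/3. The type-I test shares one null table per observed S
value across trials — the test conditions on (n, S), so this is the
same null; it only removes redundant simulation.

Divergence for HKA is the count of fixed differences between the
ingroup consensus and the outgroup on retained columns; the "+1" in
E[D] = θL(T+1) absorbs expected coalescence in the ancestral species
(any constant is absorbed by the free T). The MCMC used by the original
multilocus-HKA software is replaced by seeded 10-start bounded L-BFGS-B
maximization in log-parameter space: the inference target (per-locus k,
LRT) is identical, and the optimizer is checked against a dense grid.
The χ² reference ignores the k > 0 boundary and is documented as
approximate. Both k and log k are reported, since "selection parameter
below 0" in the field's usage refers to the log scale.

## Coalescent generator

Event-driven backward-time simulation. Units: a lineage pair in a deme
of relative size x coalesces at rate 1/x (E[T_MRCA] = 1 for a panmictic
pair); per-lineage backward migration rate is M/2 with M = 4Nm;
mutations fall at rate θ/2 per lineage per unit time, so E[S] = θ·aₙ.
Maternal haploid loci use inheritance scaling s = 0.25 applied to the
coalescence size (effective diversity s·θ). Infinite sites: every
mutation occupies a fresh column (error if the locus is shorter than the
realized S), so the mutation count equals S and no four-gamete violation
is possible. No recombination and no selection are simulated; sweep-like
fixtures for the neutrality tests are built by deterministic SFS
distortion. Diploid individuals pair consecutive lineages within a deme.
With zero migration between sampled demes no event can join the last
lineages; the simulator raises an informative error rather than looping
(isolation scenarios use a small positive rate).

Study-like presets copy the real per-population sample counts for
mtCOI/ATPSa/ATPSb/EF1a and arrange populations on a stepping-stone chain
in geographic order (within-region rate 10, between-region rate 1,
per-locus θ = 2, mito length 1000, nuclear length 2000 — chosen to give
within-population haplotype diversities in the observed 0.5–0.9 range
and headroom for the realized S under deep structure; an `asymmetry`
knob biases forward vs backward rates). These presets emulate sample
layout and hierarchical structure, not the true demographic history;
tests passing on them validate the estimators, not any claim about the
real populations. The DHEW null is panmictic by construction, so running
it on structured simulations can legitimately reject — as it does for
real data with structure.

## Dispersal

Two-dimensional advection at constant depth on planar-kilometre grids
(lon/lat registries are converted equirectangularly). Velocity fields
are composed from divergence-free parts: uniform jets, solid-body gyres,
and eddy fields built from randomly phased streamfunction modes.
Integration is RK4 with bilinear interpolation; on linear fields
(jet, solid-body gyre) interpolation is exact, which the tests exploit
to isolate the O(dt⁴) truncation error. Blocked cells deflect particles
free-slip (the offending displacement component is dropped). A CFL
warning fires when the maximum per-step displacement exceeds half a grid
cell.

PLD follows the unified temperature model
PLD(T) = exp(β₀ − β₁ ln(T/T_ref) − β₂ ln²(T/T_ref)) with defaults
β₀ = 3.9263, β₁ = 1.4040, β₂ = 0.28, T_ref = 15 °C, calibrated
analytically to two anchors: 18.93 d at 28 °C (tropical surface) and
282.7 d at 1.8 °C (abyssal). With the published curvature retained the
curve turns over below ~1.2 °C; it is monotone decreasing over the
ecologically relevant range (≥1.3 °C), and the default temperature
profile never goes below 1.8 °C. Development accumulates along the
trajectory as Σ dt/PLD(T_local), which reduces exactly to t/PLD(T) at
constant temperature; the release is a single pulse.

Settlement: a site is eligible only if it is at least as deep as the
dispersal depth (a rising plume can be sensed from above, not below).
A particle settles at the first stored time step within the settlement
radius (default 5 km; kernel cell 10 km) of an eligible site while its
development fraction is ≤ 1; simultaneous hits go to the nearest site.
An optional `min_competency` fraction (default 0, i.e. settlement
possible from release) models a precompetency period; study scenarios
use small positive values so that transition matrices are not trivially
diagonal. Trajectories are stored every `store_every` steps; the
settlement radius should exceed the displacement per stored interval.

Scaled problem sizes: analysis drivers and the acceptance script use
400–1500 particles per site and hourly steps on 10-km grids — enough for
stable settlement fractions (binomial SE ≲ 1.5%) while keeping each
driver in seconds to minutes. Particle counts, radii and cell sizes are
configuration.

## Stepping-stone connectivity

J[i][j] is the first-passage probability: make j absorbing, start from
the source's one-step distribution, propagate ≤ 100 generations
(i.i.d. uses of the single-generation matrix; no interannual
variability), early-stopping when the per-step increment drops below
1e-12. The self-value J[i][i] is the first *return* probability, which
makes the source normalization N[i][j] = J[i][j]/J[i][i] well defined;
rows with zero self-value are flagged undefined. An occupancy-based
self-value was considered and rejected because it conflates staying with
returning; the first-return reading keeps N[i][i] = 1 identically.

## Comparison layer

Gene-flow matrices are inputs (a documented CSV adapter for external
isolation-with-migration output, or simulator ground truth: forward
migration i→j is the backward rate j→i). Directional asymmetry is
(m_fw − m_bw)/(m_fw + m_bw) ∈ [−1, 1]; direction is judged concordant
when the genetic and dispersal asymmetries share a sign or both lie in a
dead band |a| < 0.1 (treated as bidirectional). A dispersal connection
is "predicted" at N[i][j] ≥ 1e-3, mirroring the treatment of smaller
probabilities as effectively no connection. Rank concordance is Spearman
with explicit midranks over all ordered pairs.

## Known limitations

- Haplotype-frequency F_ST saturates at high diversity (see above); use
  the AMOVA Φ for strongly diverged, diverse loci.
- The DHEW null is panmictic; on structured samples rejections mix
  selection with demography, as with the original test.
- The χ² LRT reference for HKA is approximate near k = 1 boundaries.
- Dispersal is purely horizontal and passive: no vertical migration,
  swimming, tides, or time-varying currents beyond what the input field
  contains; the synthetic fields emulate basin-scale structure, not any
  real hindcast.
- Multi-generation connectivity assumes identical generations and equal
  larval output at every site.
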