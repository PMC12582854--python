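# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `ratemaps` package.

## Divergence-based mutation rates

Under neutrality, substitutions accumulate along a lineage at the mutation
rate, so per-site divergence to the reconstructed ancestor obeys
*d = μ·T/G* with *T* the divergence time in years and *G* the generation
time. Because *d* is measured on a single branch (to the reconstructed
ancestor, not between two extant species), *T* enters un-doubled.
Windowed divergence is the ratio of accessible substitution positions to
accessible sites, computed on a sliding grid (window/step pairs of
1 kb/1 kb up to 1 Mb/500 kb). Two rules matter:

- **Segregating sites** are removed from the numerator only — a site
  carrying a within-species polymorphism cannot be counted as a fixed
  substitution, but it remains alignable and therefore stays in the
  denominator. A toggle (`drop_segregating_from_denominator`) removes it
  from both.
- **Low-accessibility windows** (accessible sites < 10% of the span,
  configurable) are reported as missing rather than as noisy ratios;
  truncated terminal windows are kept and flagged `partial`.

The conversion table rounds half-up to 3 significant figures, with an
8-decimal pre-rounding step so that binary float representations of exact
decimal quantities (e.g. 53.75) round to the intended value.

## Accessibility masks

Accessible = callable ∖ (functional features ± 10 kb flank) ∖ extra masks,
with all interval arithmetic on 0-based half-open coordinates and features
clipped at scaffold bounds. The flank keeps divergence clear of direct and
linked selection around functional annotation.

## Coalescent simulator (SMC')

`simulate_haplotypes` draws the genealogy at the left end of the region
from the standard coalescent with piecewise-constant diploid sizes
(pair coalescence rate 1/(2N(t))), then proceeds along the sequence:
recombination breakpoints arrive as a Poisson process with intensity
r(x)·L(tree) per bp, where L is the total branch length in generations and
r(x) an arbitrary piecewise-constant recombination track (sampling is done
in genetic-map coordinates, so zero-rate stretches are skipped exactly).
At each breakpoint a point is chosen uniformly on the tree, the lineage
above it is erased, and the detached subtree re-coalesces into the
remaining genealogy from the breakpoint time upward — including back into
the span of the erased branch, which is the SMC' refinement that makes the
marginal tree process a close approximation to the full ancestral
recombination graph. Mutations are infinite-sites Poisson
(rate μ·span·L per marginal tree) at integer positions; at most one
mutation is kept per bp.

The test suite cross-validates the simulator against coalescent theory
(pairwise diversity 4Nμ, Watterson site-frequency spectrum θ/i, TMRCA
under a size change) and against msprime (two-sample tests on segregating
sites and mean r² at matched parameters must not distinguish the two).

Demographies: the equilibrium model uses the inferred ancestral size
N = 11,695; the bottleneck-decline model declines from 11,695 to 1,285
diploids over the final 1,133 generations. "Decline at a constant rate" is
implemented as exponential in N (constant per-generation rate of decline),
discretized to 32 piecewise-constant epochs; a linear option is exposed.
The upstream estimator's own population-size strings are stored verbatim
as provenance constants and deliberately not interpreted, as their units
are not documented.

## Two-locus lookup tables

For sample size n and a grid of ρ = 4N_ref·r values (default 0, 0.5, 1, 2,
5, 10, 20, 50, 100; N_ref defaults to the model's ancestral size), the
sampling probability of each folded two-locus haplotype configuration
(n00, n01, n10, n11) is estimated by simulating two-locus genealogies:
lineages carry ancestral material at locus A, B or both; coalescence at
rate k(k−1)/(4N(t)) and recombination at rate ρ/(4N_ref) per dual-carrier
per generation. Conditioning on both loci segregating uses the low-θ
limit: rather than sampling one mutation per locus, every (branch-A,
branch-B) pair contributes its exact conditional weight ℓ_A·ℓ_B, which is
the same expectation with far lower Monte-Carlo variance (each genealogy
yields ~(2n−2)² weighted configurations). A small pseudo-weight
(0.5 replicate-equivalents spread over all feasible configurations)
prevents −∞ log-likelihoods for configurations unobserved by chance.
Configurations are folded — canonicalized over allele relabelings at
either locus — to match unpolarized SNPs.

Between grid points the table is interpolated **linearly in
log-probability** (the convention of composite-likelihood LD estimators),
and clamped at the grid ends. Linear-in-probability interpolation was
rejected: its expected objective is flat to first order at the truth
(Σ_c p′(c) = 1), which measurably inflates estimator noise, whereas
log-linear interpolation decreases away from the truth by the
Kullback–Leibler divergence.

## Composite-likelihood estimation

For each window, every SNP pair whose left member lies in the window and
whose members are at most 30 SNPs apart (the recommended pair span)
contributes log P(config | ρ_bp·distance); the estimate is the argmax over
a per-bp candidate grid (0 plus 41 log-spaced values from 1e-7 to 1e-2).
ρ̂ is converted to r via N̂ₑ = θ̂/(4μ) with θ̂ Watterson's estimator from
the same panel, so cM/Mb = ρ̂·μ/θ̂·1e8. Windows with fewer than two SNPs
are reported missing, never zero.

**Variance at low ρ.** A window without recombination contains a single
genealogy, so all SNP pairs are correlated and the composite objective's
expected advantage of ρ = 0 over small positive ρ (the per-pair KL
divergence, ~0.03 nats) is small against tree-to-tree variability;
individual windows therefore land at small positive ρ roughly half the
time, and only the distribution across windows identifies ρ ≈ 0. Tools
built on fused-penalty optimization smooth this away across windows; this
package deliberately does not replicate that penalty (smoothing comes only
from the constant-rate estimation window), preserving the relative-rate
structure that downstream rescaling relies on.

**Post-processing.** Outlier windows above 100× the length-weighted genome
mean (the signature of local assembly errors) are removed and reported;
the map is then rescaled by a single factor so the total genetic length
equals the pedigree-based target (1525 cM genome-wide, prorated for
synthetic scaffolds), leaving all rate ratios untouched; coarse maps are
bp-length-weighted means on a 1 Mb/500 kb sliding grid.

## Estimator benchmark

The benchmark mirrors the study design — {bottleneck-decline, equilibrium}
× μ ∈ {0.4e-8, 1.1e-8} × 10 replicates, five diploids, true rate
0.85 cM/Mb — and reports mean/median estimate, bias and ratio-to-truth per
combination before rescaling. The default region is 1.6 Mb (the longest
accessible intergenic stretch in the genome); the shipped drivers and
checks run 100–200 kb regions, a package choice that preserves the design
while keeping the two-locus tables and simulations desk-sized. Whether the
estimator under- or over-estimates under decline is reported, not
asserted: this composite-likelihood implementation differs internally from
fused-penalty tools, and its decline-model bias (driven largely by the
θ̂-based Nₑ conversion responding to the reduced diversity of a declining
population) need not share their direction.

## Wavelet analysis

Feature tracks (π, divergence, recombination, GC, exon content) are binned
at 1 kb with per-bin accessibility; bins under 10% accessibility are
masked. Scaffold halves are truncated to the largest power-of-two number
of bins from the midpoint outward (J ≤ 12, scales 2–4096 kb); masked bins
are mean-imputed before transformation (the imputed fraction is reported
and halves above 20% flagged). The orthonormal Haar pyramid
s_{j,k} = (s_{j−1,2k}+s_{j−1,2k+1})/√2, d_{j,k} = (s_{j−1,2k}−s_{j−1,2k+1})/√2
conserves energy to 1e-9 relative and inverts exactly; non-dyadic input is
an error (callers truncate).

Scale-specific association uses Kendall's tau-b per detail level (exact
permutation p for tie-free n ≤ 10, normal approximation otherwise;
constant vectors reported missing) at a fixed 1% two-tailed level with no
multiple-testing correction, and through-origin least squares of
recombination details on the other features' details with uncentered
adjusted R² — detail coefficients are centered by construction, so the
origin constraint is the natural choice. Rate tracks (recombination, π,
divergence) are log-transformed, ln(x + ε) with ε half the smallest
positive value, before the linear models only; Kendall's tau is invariant
to monotone transforms, so the correlation panel is unaffected.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume, at
the study conditions: substitutions dropped independently per accessible
site with probability μ·branch-generations (error if saturated), targeting
mean divergence 0.043 at its defaults; panels of five diploids under the
two study demographies; exon annotations as a Poisson process of
geometric-length intervals (realized density tracks the target within
~20% for megabase scaffolds); motif placements with sampling density
1 + (enrichment−1)·rate/max(rate). They do not emulate CpG or
context-dependent mutation, gene conversion, selection, sequencing error
or unphased/missing genotypes — so passing tests demonstrate correctness
of the estimators under their own model assumptions, not robustness to
real-data artifacts.

## Determinism and numerics

Every generator consumes a single seeded `numpy` Generator; identical
seeds give bit-identical outputs (the pipeline writes byte-identical
artifact bundles). Grid argmaxes break ties toward the smaller ρ. Rate
ratios are preserved exactly under rescaling; rescaled totals match their
target to 1e-6 relative. Welch's t-test uses the Welch–Satterthwaite
degrees of freedom; the Hardy–Weinberg filter uses the exact conditional
(Levene–Haldane) distribution with a one-sided heterozygote-excess tail,
matching the stated intent of removing heterozygote excess (the overall
two-sided test is available by construction of the same enumeration).

## Problem sizes in the shipped drivers

The analysis drivers use a 4 Mb single-scaffold synthetic genome, 40-window
truth tracks, 10-haplotype panels, two-locus tables of 3,000–8,000
genealogies per grid point, and 100–200 kb benchmark regions. These are
package choices that keep a full run in minutes while leaving every
statistical property testable; all sizes are parameters.
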