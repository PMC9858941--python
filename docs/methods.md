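# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Bivariate model and REML

Pseudo-phenotypes (prior-round breeding values) at two THI levels are
modelled as two traits:

y_t = 1 μ_t + Z_t a_t + e_t,  t = 1, 2,

with (a1, a2) ~ N(0, G0 ⊗ G) and (e1, e2) ~ N(0, R0 ⊗ I). The only
fixed effects are the two environment means — the responses are
already-adjusted breeding values, so no further fixed structure is
fitted. G is the VanRaden method-1 genomic relationship matrix built
from post-QC observed allele frequencies (base-population frequencies
are rarely available; observed frequencies are the standard fallback).
A configurable ridge ε·I (default 1e-6) is added to G's diagonal: with
column-centered genotypes G is always singular (the centered dosage
columns sum to zero), and REML and the mixed-model equations need an
invertible G. Pedigree blending is not used because no pedigree is in
scope.

Variance components are estimated by REML. Because the analysis set
carries both records on the same animals, the likelihood is evaluated
in the eigenbasis of G (G = U diag(d) U′): the rotated records are
independent 2×2 Gaussian problems with covariance V_i = d_i·G0 + R0,
so one n×n eigendecomposition up front makes every REML iteration
O(n). The optimizer is average-information (AI) REML with safeguards:

* an AI step is accepted only if it does not decrease the restricted
  likelihood (checked with up to 10 step halvings);
* otherwise an EM step is taken, which is monotone by construction;
* after every update G0 and R0 are symmetrized, their eigenvalues
  floored at 1e-10 of the trace, and the implied correlation is capped
  at |r| ≤ 1 − 1e-6. The cap keeps V_i invertible when the data push
  both correlations to the boundary — feeding identical records to
  both environments is a legitimate use (it reproduces the
  no-reranking pattern) and would otherwise make the rotated 2×2
  covariances exactly singular.

Start values assign half the phenotypic (co)variance to each of G0 and
R0. Convergence is declared when the maximum absolute change across
the free parameters falls below `tol` (default 1e-8, cap 200
iterations); hitting the cap flags `converged=False` on the result
rather than raising, because boundary fits (correlation pinned near 1)
legitimately crawl. A `covariance="diagonal"` option constrains both
covariances to zero, which decouples the fit exactly into two
univariate analyses — useful as an internal consistency check and for
users who want independent per-environment evaluations.

GEBVs come from the full Henderson mixed-model equations with explicit
record-to-animal incidence, so animals missing one or both records
still receive predictions through genomic relationships. The residual
structure is block-diagonal per animal, using the subset of R0
matching the observed environments. At the target scale (≈1000
animals) the dense (2 + 2n) system is solved directly.

## Back-solving and explained variance

Marker effects are recovered per environment as û = DZ′(ZDZ′)⁻¹â with
Z = M − 2P, the same centering used for G — this makes ZZ′
proportional to the unblended G, so the back-solve is consistent with
the relationship matrix that produced â. D is identity (a single
pass; no iterative SNP reweighting). When ZDZ′ is not positive
definite (the usual case with observed-frequency centering) the
Moore–Penrose pseudoinverse is used and the output flagged; the
projection identity Z û = â still holds on the row space, which is
where â lives.

Explained additive variance per marker is 2p(1−p)û², and percentages
are normalized within environment by the summed per-SNP variance (not
the REML additive variance), so they sum to exactly 100 in each
environment and are comparable across environments. The alternative
denominator is computable from the outputs; the choice is recorded in
the output metadata. No significance testing is attached to these
quantities — they are comparison metrics.

## Two-environment comparison

The top-k (default 50) markers by percentage of explained variance are
selected per environment; the truncation point T is the k-th largest
percentage. Quadrant labels (top in both / one / neither environment)
follow set membership; exact ties at T are broken deterministically by
(percentage desc, chromosome asc, position asc) and warned about.
Reranking is quantified by Spearman correlation of DBVs on the animals
selected by the comfort environment's DBV (top 10%, 40%, all); the
symmetric stress-selected version is also reported, since which
selection basis a study means is often ambiguous. Gene annotation
reports the containing interval, or the nearest one within a 600 kb
window (covering the largest distances typically discussed for dairy
candidate genes such as DGAT1/ABCG2 neighborhoods), with
upstream/downstream measured on the forward axis only — interval
tables rarely carry strand.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular herd: markers in linkage equilibrium with allele
frequencies uniform on [maf_low, maf_high], Hardy–Weinberg dosages,
missingness completely at random, round-robin chromosome assignment
with fixed 25 kb spacing, and Gaussian marker effects with a chosen
between-environment correlation, rescaled so the realized
Σ2p(1−p)u² matches the target additive variance exactly (a positive
scalar per environment, leaving the effect correlation untouched;
|r| = 1 uses an exact rank-1 construction). Pseudo-phenotypes add
Gaussian noise on top of the genetic values.

Defaults mirror a ~1000-cow Holstein milk-yield evaluation: 1013
animals, means 1.13 / 1.00 kg/day, phenotypic variances 4.54 / 4.04
(kg/day)², genetic correlation 0.99. The additive share is set to 80%
of phenotypic variance because the records stand in for estimated
breeding values, which carry high reliability; the split is a modeling
choice, as is the Gaussian shape — summary statistics alone do not
determine a distribution. The default marker count (5000) is a
scaled-down panel: dense linear algebra keeps the whole pipeline in
seconds at this size, and none of the compared quantities depend on
marker count except through estimation precision and the scale of
per-SNP percentages (with fewer markers each SNP's percentage is
proportionally larger).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium and
major-gene architecture (real dairy traits have DGAT1-sized effects
and long-range LD; under the polygenic LE generator individual marker
effects are only weakly identifiable when markers outnumber animals),
pedigree structure and selection, informative missingness, and
environment assignment by actual weather. The pipeline's comparative
behavior under controlled genetic correlation (overlap rising to >80%
as the correlation approaches 1, Spearman ρ → 1 for identical
environments) is a property of the method, demonstrated on synthetic
data — not a reproduction of any real population's results.

## Numerical notes and limitations

* Centered-dosage columns sum to zero under observed-frequency
  centering, so unblended G has a null vector; everything downstream
  either blends (REML, MME) or pseudo-inverts with a flag (back-solve).
* QC rules are strict inequalities ("less than" thresholds); each
  entity is counted under the first rule that removes it (animal call
  rate; then sex chromosomes, marker call rate, MAF, Hardy–Weinberg
  deviation |het_obs − 2p(1−p)| > 0.15). All sex-chromosome markers
  are removed, the stricter of the two common readings of that rule;
  frequencies for MAF/HWE use pre-imputation observed calls on
  surviving animals. Imputation is marker-mean (fractional dosages) —
  adequate for dense matrix algebra, not a haplotype method.
* The tiny eigenvalue floor (1e-10 of trace) means "zero" variance
  components are reported as ~1e-10-scale numbers, and G0 stays
  formally invertible for the MME.
* Problem sizes in the test-suite simulations (hundreds of animals,
  hundreds to a thousand markers, 10-seed Monte Carlo where averages
  are asserted) were chosen so each check isolates its property at
  comfortable precision; the acceptance script runs the study-scale
  1013-animal configuration.
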