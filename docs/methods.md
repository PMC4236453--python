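# Methods

This note documents the models, statistics and numerical choices behind
`ffrpnet`, in the order the pipeline runs them.

## Target assignment from binding-site lists

Peak lists carry one point-estimate position per site (peak callers for
tiling-array ChIP report positions at roughly 50 bp resolution) and a
per-peak p-value.  A gene is a **direct target** of a TF when a site with
p ≤ `p_max` (default 0.01) lies inside its promoter window.  The window is
250 bp upstream to 50 bp downstream of the annotated start codon, oriented
along the strand: for a + strand gene with start codon at coordinate *s* the
window is [*s*−250, *s*+50]; for a − strand gene with start codon at *e* it
is the mirror [*e*−50, *e*+250].  Coordinates are 1-based inclusive on disk
(GFF3) and throughout the API; sites are tested by their point position with
no width smearing.  The window is anchored on the start codon because the
annotation provides it universally; where long 5′ UTRs exist a
transcription-start anchor would shift windows, which is why both
`upstream`/`downstream` are explicit parameters.

Operons are co-transcribed, so a binding site in the promoter of an operon
member regulates every gene *downstream* of that member (higher
`operon_rank`); such genes are recorded with `operon-propagated` provenance,
direct promoter hits with `direct-promoter` (direct wins when both apply).
Operon membership and order come from a user-supplied table; operon
prediction is out of scope.

Binding maps are compared by (i) the overlap count *k* with the upper-tail
hypergeometric p-value P(X ≥ k) for N = |universe|, K = |A|, n = |B|;
(ii) percent overlap 100·k/min(|A|,|B|), i.e. relative to the smaller
target set; and (iii) a permutation test for promoters bound by ≥ `min_tfs`
TFs, whose null redraws each TF's target set uniformly from the universe
preserving its size, with p = (1 + #{null ≥ observed})/(N_perm + 1).

## Functional-divergence distances and effector profiles

Type-I functional divergence θ between two family members (the coefficient
of shifted site-specific evolutionary rates) is consumed, not re-estimated:
its maximum-likelihood estimation is a separate, previously solved problem,
and the analysis here starts from the published pairwise table (bundled for
the eight-member FFRP family) or any user-supplied θ matrix.  Distances are
d = −ln(1 − θ), which is 0 at θ = 0, strictly monotone, and diverges as
θ → 1; the inverse 1 − e^(−d) recovers θ to machine precision.  Trees use
agglomerative clustering (complete linkage for divergence trees, average
linkage for effector groups) via SciPy; heights are non-decreasing for these
linkages on metric input, and ties are resolved by SciPy's deterministic
ordering of the condensed distance matrix, so results are reproducible for
fixed label order.

Effector-molecule preference of Lrp/AsnC-family regulators is encoded by
nine key residues of the RAM domain.  Profiles (length-9 strings over the
20-letter alphabet) are compared by the summed BLOSUM62 score
S_ij = Σ_k B62(a_ik, a_jk), converted to the distance
d_ij = (S_ii + S_jj)/2 − S_ij.  This form is zero iff two profiles are
score-identical and was verified non-negative on random profile samples
(BLOSUM62 is diagonally dominant); no similarity→distance rule is standard
here, so the choice is documented rather than assumed.  A gap character
scores as the minimum of the partner residue's row — a deliberately
conservative penalty, configurable by passing a custom table.

## The expression compendium

Expression is a genes × arrays matrix of log2 ratios versus a common
reference; every array belongs to one named **condition set** (a group of
arrays sharing a growth/perturbation condition).  All fold-change arithmetic
is in log2 space.  Missing values are allowed; every correlation in the
package is pairwise-complete — ranks are recomputed on exactly the jointly
observed entries (rows are grouped by missingness pattern so this stays
vectorised).  Construction sorts genes and arrays, which makes every
downstream result invariant to input row/column order.

TF–TF co-expression uses Spearman's ρ over all arrays pooled, with the
significance cutoff ρ ≥ 0.5 (signed — anti-correlation never makes an edge)
and p ≤ 0.05.  The p-value is the large-sample t approximation; for small
tie-free samples (n ≤ 9) the exact permutation distribution of ρ is used
(memoised per n).  Pairs with fewer than 10 complete observations yield no
edge and a logged warning.

## Conditional-regulon discovery

The headline procedure, per (TF, condition set):

1. **Fold-change filter.** Keep sets where max − min of the TF's log2
   values across the set's arrays ≥ log2(1.75) ≈ 0.8074.  Sets with fewer
   than 6 arrays of non-missing TF values are excluded (a rank correlation
   on fewer points is uninformative); sets with the TF entirely missing are
   excluded with a warning.
2. **Per-target correlations.** Correlate each binding target with the TF
   across the set's arrays (Spearman by default; Pearson by option, used
   e.g. for the closed-form attenuation checks).
3. **Median statistic.** The median of the target correlations; its sign
   proposes the role (positive → activator, negative → repressor).  Both
   tails are always tested, because a single TF can act as activator in one
   condition set and repressor in another.
4. **Permutation null.** Random gene sets of the same size are drawn
   without replacement from all genes on the array except the TF itself;
   each draw's median correlation forms the null, and
   p = (1 + #{as-or-more-extreme})/(N_perm + 1).  With the default
   N_perm = 100,000 the estimator's floor is 1/100,001 < 10⁻⁵.  The
   per-gene correlation vector is computed once per (TF, set), so a draw
   reduces to a median of sampled entries; subsets are sampled by Floyd's
   algorithm in a numba kernel (a numpy fallback uses chunked
   argpartition), and the sampled p was verified against exhaustive subset
   enumeration on small universes.
5. **Multiple testing.** Benjamini–Hochberg step-up
   q_(i) = min_{j≥i} m·p_(j)/j across all (TF, passing set, tail) tests
   jointly (per-TF families by option).
6. **Dispersion-coupling filter.** A regulon that genuinely responds to its
   TF spreads out as the TF moves: the per-array variance across the target
   genes should track the TF's profile.  The statistic is |Spearman ρ|
   between the variance series and the TF.  Its significance is, by
   default, the correlation test's own p-value ("significantly correlated"
   read literally), BH-corrected across all tested pairs, pass at
   q ≤ 0.05.  An alternative null that redraws random gene sets is
   available (`null="permutation"`); note it is conservative whenever the
   compendium carries real regulon signal, because random sets then contain
   regulated genes and the rank-based statistic saturates.  A second
   reading of the filter — the per-array *median* profile instead of the
   variance — is available via `dispersion_method="median_profile"`.
   Degenerate series (constant targets) fail closed with a warning; sets
   with < 3 usable arrays skip the filter, flagged.
7. **Call and gene selection.** A pair is called when q ≤ 0.05,
   |median r| ≥ 0.4, and the dispersion filter passes.  The conditional
   regulon is the targets strictly beyond the median (r > median for
   activators, r < median for repressors); with distinct correlations this
   selects ⌊n/2⌋ genes, and an all-tied set selects none.

Determinism: one master seed spawns independent child streams per
(TF, set) pair in sorted order, so results are bit-reproducible and
invariant to matrix row/column order.

## Perturbation validation

Predicted regulons are tested in deletion strains by contrasting two defined
samples (for an activator context, early minus late after the perturbation;
for a repressor context, late minus early along growth).  Per biological
replicate the statistic is the **median** per-gene delta over the selected
genes; replicate medians are compared between deletion and control strains
by an unpaired one-sided Wilcoxon rank-sum test — exact-conditional
enumeration over all C(n₁+n₂, n₁) rank assignments (midranks under ties)
for small samples, normal approximation beyond.  For biological triplicates
the minimum attainable one-sided p is exactly 1/C(6,3) = 0.05, which sets
the granularity of any triplicate validation.  Gene-level (rather than
replicate-median) testing is available by calling `strain_effect_test`
directly on gene deltas.  Regulon–regulon overlap reuses the hypergeometric
overlap machinery.

## Growth-curve analysis

Growth curves are OD600 every 0.5 h for 96 h from an inoculation density of
0.09.  Technical replicates are collapsed by the pointwise mean (mismatched
time grids are refused rather than interpolated).  Parameters per curve:

- **µ_max** — the maximum over sliding windows (default 5 points = 2 h) of
  the least-squares slope of ln OD versus time: the standard specific
  growth rate.  A raw-OD slope is available by option.  Ties (e.g. an exact
  exponential) resolve to the earliest window, with a 10⁻⁹ relative
  tolerance absorbing floating-point noise.
- **t_µmax** — the centre time of that window.
- **AUC** — the trapezoidal integral of OD over the full observed window,
  no baseline subtraction.

Strains are compared per parameter over biological replicates by an unpaired
two-sided Student's t-test (zero variance in both groups with equal means
reports p = 1), Bonferroni-corrected with factor = number of strains
compared (default 8, capped at 1; the factor is configurable since a
per-parameter factor of 3 is an equally defensible family).  Evidence across
the three parameters combines by Stouffer's method on the corrected values:
z_i = Φ⁻¹(1 − p_i), Z = Σz_i/√k, combined p = 1 − Φ(Z), with p clipped away
from {0, 1} so the quantile stays finite.

The synthetic growth model is the Zwietering-style modified logistic in
log space: ln(OD/OD₀) = A / (1 + exp(4µ_max(λ − t)/A + 2)) with
A = ln(K/OD₀).  In this parameterisation the maximum of d ln OD/dt equals
µ_max exactly, attained at the inflection of the ln-curve, and the tangent
there crosses the baseline at the lag time λ — so the extraction above
recovers the generating parameters directly (within ~2% at 0.5 h sampling;
a plain logistic ODE would instead place its maximal specific rate at the
curve start and recover only r·(1 − OD₀/K)).  Noise is multiplicative
log-normal (plate readers err proportionally) floored at OD 0.01; optional
per-biological-replicate parameter jitter provides the replicate variance
the t-tests operate on.

## The synthetic-study generator

The generator emulates the study design end-to-end so that every statistic
above can be tested against known ground truth:

- **Annotation**: 2,400 genes in 600 operons on one replicon by default
  (multi-replicon supported), gene lengths ~N(750, 150²) rounded to codons,
  intergenic gaps exponential with mean 150 bp, operon members contiguous
  and co-oriented.  Explicit replicon lengths trigger packing checks.
- **Binding sites**: each TF receives 34–356 (operon-closed) target genes;
  site-bearing genes get a promoter site with p ≤ 0.01 at a position chosen
  to lie in no other gene's window (so the planted map is exactly
  recoverable), jittered by the 25 bp peak-calling resolution by default.
  Decoy sites (p > 0.01) and small-p sites inside gene bodies away from any
  window exercise the p-value and window filters without perturbing the
  ground truth.  Target sets of different TFs are drawn partly from a
  shared pool, producing the heavy overlap characteristic of the family.
- **Compendium**: 35 condition sets of 6–20 arrays (matching a ~466-array
  compendium; the within-set count distribution is not documented, so a
  uniform 6–20 range is assumed).  Per set, a TF's profile is a mean shift
  U(−1, 1) plus a gradient spanning ±1 log2 unit across the set's arrays
  plus N(0, 0.25) noise — the gradient guarantees the 1.75-fold filter is
  exercised.  In a planted (TF, set, role), a `fraction_coupled` subset
  (default 0.75) of the targets follows ±β·(z − min z) + N(0, noise_sd)
  where z is the TF profile: coupling to the TF's excursion above its
  within-set minimum makes the across-target dispersion grow with TF level,
  which is exactly the property the dispersion filter tests, and matches
  the biology (regulated genes sit at baseline when the regulator is at its
  lowest).  Everything else is independent N(0, noise_sd) noise
  (default 0.25 log2 units), with 2% missing values injected to exercise
  pairwise-complete handling.  The coupled-gene correlation obeys the
  attenuation ρ = βσ_TF/√(β²σ_TF² + σ_noise²), which the tests verify
  against simulation.
- **Residue profiles**: per-group consensus strings with a configurable
  number of point substitutions per member.
- A JSON **ground-truth sidecar** (TFs, site genes, targets, coupled genes,
  roles, growth parameters) supports all recovery assertions.

What the generator does **not** emulate: probe-level microarray artefacts,
normalisation residue, correlated (batch) noise across genes, ChIP
read-level signal, or sequence evolution.  Passing tests therefore
demonstrate the statistics' correctness and calibration under an idealised
noise model, not robustness to the artefacts of real array data.

## Problem sizes and calibration checks

The test suite validates, besides the unit-level oracles: (i) the sampled
permutation p against exhaustive subset enumeration on 10-gene universes
(within 3 binomial SE at 10,000 draws); (ii) the full pipeline's false-call
rate on all-null compendia (2,400 genes × 8 TFs × 35 sets, 20 seeds at
5,000 permutations) at or below the nominal 0.05; and (iii) planted-regulon
recovery at β = 0.8, σ = 0.25 with ≥ 100 targets and ≥ 10 arrays per set
(16 planted regulons over two studies at 10,000 permutations): sensitivity
≥ 0.9 with correct roles and mean Jaccard ≥ 0.6 between selected and
planted coupled genes.  The permutation depths here are scaled down from
the 100,000-permutation default; with BH families of ~550 tests the
q-value floor of a 5,000-permutation run (~0.055) sits above the 0.05 call
threshold, which is why power runs use ≥ 10,000 permutations — a real
analysis should keep the 100,000 default.

## Known limitations

- θ estimation, motif discovery/comparison, GO enrichment, microarray
  normalisation and peak calling are consumed as inputs, never recomputed.
- The dispersion filter's definition is genuinely ambiguous (see above);
  both readings are implemented and the choice is a config switch.
- The hypergeometric overlap treats the annotated gene universe as
  exchangeable; promoter-less or unexpressed genes are not down-weighted.
- Exact co-expression p-values are only available for tie-free samples of
  n ≤ 9; midrank ties fall back to the t approximation.
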