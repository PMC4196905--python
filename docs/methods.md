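# Methods

This document describes the statistical machinery implemented in `cindy`:
the information estimators, the null models, the modulator-calling pipeline,
the ΔI baseline, and the synthetic-data generator, together with the
numerical choices that make runs reproducible.

## Problem setting

A *modulator* M is a gene whose product changes the regulatory effect of a
transcription factor (TF) on its target genes (Tg) post-translationally —
for example a kinase that activates the TF protein, or a cofactor required
for binding. Such modulation is invisible to pairwise co-expression
analysis: the TF transcript and its targets may correlate with each other
while the modulator's transcript correlates with neither. The signature of
modulation is *three-way*: the strength (or sign) of the TF→target
dependence varies with the modulator's expression level.

`cindy` quantifies this with full conditional mutual information (CMI),

    I(TF; Tg | M) = H(TF | M) + H(Tg | M) − H(TF, Tg | M) − H(M) …

estimated non-parametrically on rank-transformed expression profiles, and
asks whether the observed CMI for a candidate triplet is larger than
expected for (TF, Tg) pairs with the *same pairwise MI* when conditioned on
a random, permuted gene. A (M, TF) pair is reported when significantly many
of the TF's targets show such excess conditional information.

## Rank transform

Each gene's expression profile is mapped to ranks 1..n (`rank_transform`),
making the estimator invariant under monotone transformations of the data
(quantile normalisation, log scaling, …). Ties are broken uniformly at
random with a caller-supplied seed so the pipeline is deterministic;
constant profiles are flagged as degenerate and excluded from inference.

## Adaptive partitioning estimator

MI and CMI are plug-in estimates over an adaptively refined partition of
the 2-D (or 3-D) rank space (`build_partition`, `estimate_mi`,
`estimate_cmi`):

1. Start from the full rank hyper-rectangle.
2. Split a cell at the midpoints of each axis into 2^d sub-cells (d = 2 or
   3).
3. Keep the split if a χ² test rejects uniformity of the sub-cell counts
   (d.f. = 2^d − 1) at level `alpha`, and each sub-cell either is empty or
   can still be represented; recurse into sub-cells with at least
   `min_cell` = 2^d points.
4. When splitting stops, the cell contributes its plug-in term to the
   information sum; MI uses cell-vs-marginal counts, CMI uses the
   conditional form with per-slab marginal counts along the conditioning
   axis.

Estimates are computed in nats and clamped at zero (the plug-in sum can go
slightly negative on small cells). The arithmetic is written so that the
optimised implementation (`FastInfo`, a numba kernel) is bit-for-bit equal
to a plain recursive implementation of the same rules; the test suite
checks this exactly against an independently written brute-force recursion
on all small inputs.

### Default `alpha = 0.01` and `min_cell = 2^d`

The split level and minimum cell size are the estimator's only free knobs.
They were fixed once by measuring, on analytically solvable families, (a)
2-D accuracy against the Gaussian formula −½·ln(1−ρ²), (b) 3-D accuracy
against the partial-correlation formula, (c) bias under conditional
independence (TF ← M → Tg), and (d) separation between modulated and
non-modulated triplets. `alpha = 0.05` with small cells inflates CMI under
conditional independence (mean ≈ 0.054 nats at n = 1000); `alpha = 0.01`
with `min_cell = 2^d` keeps it ≈ 0.033 while losing little 2-D accuracy
(|error| ≤ 0.05 nats for ρ ≤ 0.9 at n = 2000). Any residual estimator bias
shared between observed and null CMI cancels in the stratified null below.

## MI-stratified CMI null model

Raw CMI values are not comparable across (TF, Tg) pairs: strongly coupled
pairs have larger CMI under *any* conditioning, including a meaningless
one. The null model (`build_null`, `CmiNullModel`) therefore conditions on
pairwise coupling strength:

1. Sample `n_pairs` distinct (TF, Tg) pairs from the supplied universes and
   estimate their MI.
2. For each pair compute `n_perm` null CMI values against random gene
   profiles whose sample order has been permuted (destroying any real
   three-way structure while keeping the pair intact).
3. Split the MI range into `n_bins` equi-probable bins (equal pair counts)
   and pool the null CMI values within each bin.
4. Fit an extended-exponential tail ln S(x) = a + b·x^c to each bin's
   pooled sample so p-values can be extrapolated below the empirical
   resolution 1/(N+1). Bins whose sample is dominated by exact zeros (the
   3-D partition never split) cannot support a tail fit; they store no tail
   and cap p-values at the empirical bound 1/(N+1).

A triplet's p-value is then: locate the (TF, Tg) MI's bin, compare the
observed CMI with the pooled null, and use the fitted tail beyond the
largest null value. The full-scale configuration is 10⁴ pairs × 1000
permutations × 100 bins (10⁵ null values per bin); desk-scale runs default
to 10³ × 100 × 20.

### Stratification resolution

Equi-probable binning interacts with the MI distribution of the pair
universe. In realistic matrices most sampled pairs have MI ≈ 0 (a point
atom), so low bins all cover the atom and the positive MI range is
resolved by only `n_bins × (positive fraction)` bins. If that number is
small, all coupled pairs share one stratum and the null for moderately
coupled pairs is dominated by the most strongly coupled ones — p-values
become very conservative. Two practical consequences, both visible in the
test fixtures:

- Use enough bins (the full-scale 100-bin configuration at ~10% positive
  pairs leaves ~10 strata across the positive range).
- Power is greatest for *hidden* modulation, where the TF–target
  dependence cancels marginally (MI ≈ 0, e.g. a modulator that switches a
  TF between activator and repressor modes) and all information is
  three-way: such triplets fall in the zero-MI stratum, whose null comes
  from genuinely independent pairs.

`build_null` refuses configurations where the sampled MI spectrum has fewer
distinct values than bins, since equi-probable edges would then be
degenerate.

## Pair-level calling (N_sig and its null)

For each candidate (M, TF) pair, every target of the TF yields a triplet
p-value. `count_significant` counts targets passing a Bonferroni-corrected
per-triplet level (default 0.05 across the TF's target set), giving N_sig
per pair. Because N_sig depends on the target-set size and the dependence
structure among targets, it is calibrated against its own randomization
null (`build_nsig_null`): `n_rounds` rounds (default 40) recompute N_sig
with random permuted modulators, pooled per TF. The empirical pair p-value
is (1 + #null ≥ N_sig)/(1 + #null); Benjamini–Hochberg q-values are
computed across pairs and a pair is called at q ≤ FDR (default 0.05). The
default 40 rounds set the empirical p floor low enough that the BH
threshold is reachable with headroom; rounds are a resolution knob and
cannot bias calls upward.

## ΔI baseline

The pairwise-information baseline (`run_mindy`) implements conditioning by
stratification instead of full CMI:

1. Sort samples by the modulator; take the top and bottom `tail_fraction`
   (default 35%).
2. Prefilters: candidate modulators must be statistically independent of
   the TF (MI p ≥ `p_indep_m_tf`, default 10⁻⁵, against a permutation MI
   null `MiNull` built once per sample count); targets must depend on the
   TF (MI p ≤ `p_dep_tf_tg`, default 10⁻⁶) but not be near-duplicates
   (correlation ceiling 0.9).
3. ΔI = I(TF; Tg | M high) − I(TF; Tg | M low), with a two-sided
   label-permutation p-value pooled across a pair's targets, then the same
   N_sig / randomization-null / BH machinery as above.

The independence prefilter is the baseline's structural weakness: any
modulator whose transcript tracks its TF (common for co-regulated pairs) is
discarded before scoring. The full-CMI pipeline has no such filter, which
is the basis of the comparative test in the acceptance suite.

## Synthetic data generator

`cindy.synth` plants ground-truth triplets in Gaussian noise:

- independent topology: Tg = α·TF + γ·M + σ·ε (pairwise coupling only;
  I(TF;Tg|M) carries no three-way term).
- modulated topology: Tg = α·TF + β·g(M)·TF + σ·ε with the logistic gate
  g(M) = expit(4·M), a switch that is ≈ 0 for low modulator expression and
  ≈ 1 for high.

`rho_mt` correlates the modulator and TF profiles. With α = 0 the TF acts
only through the gate (the canonical strong-modulation case); with
α = −β/2 the gate switches the coupling's *sign* (hidden modulation,
marginal MI ≈ 0). Decoy genes are pure noise. Generation is deterministic
per gene: adding triplets to a spec does not change previously generated
profiles. `preset_spec`/`make_benchmark_fixture` provide self-contained
small/medium fixtures whose gold standard is exactly the planted pairs.

## Benchmarking

`precision_recall` computes precision and recall of a called pair set
against a gold standard restricted to the tested universe; an empty called
set has undefined precision (None) and recall 0. `threshold_sweep` reports
the curve over the robustness thresholds N_sig ≥ k, which compares methods
at the ranking level independently of their FDR machinery.

## Determinism and numerics

- All randomness flows through `numpy.random.SeedSequence` keyed by
  explicit integer tuples (never Python `hash`); permutation streams are
  keyed by (seed, unit index) so results are independent of evaluation
  order and worker count.
- Parallelism uses joblib's threading backend over numba kernels compiled
  with `nogil`; outputs are bit-identical for any `n_jobs`.
- Information values are floats in nats; the kernel accumulates terms in
  the same order as the reference recursion so results are reproducible to
  the bit across platforms with IEEE-754 doubles.

## Limitations

- The estimator needs on the order of 150+ samples for reliable 3-D
  inference; below that, power falls quickly (the acceptance suite
  measures the trend).
- The stratified null assumes exchangeability of permuted-conditioner CMI
  within an MI stratum; with coarse stratification or a pair universe
  whose coupled pairs span a wide MI range, p-values for moderately
  coupled pairs are conservative (see "Stratification resolution").
- Modulation that leaves a strong marginal TF–target dependence (e.g. a
  multiplicative gate with no sign switch) produces CMI close to the
  pair's own MI and is hard to distinguish from coupling without a
  pair-matched null; detection then requires larger samples.
- Expression is a proxy: modulators acting without transcript-level
  variation are invisible to any expression-based method.
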