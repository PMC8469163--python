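# Methods

## The analysis model

The pipeline assumes a complete paired design: `n` subjects ("animals"),
each measured once under each of two conditions (BEFORE / AFTER an
exposure), over `J` metabolites quantified as non-negative concentrations
(mmol/L). All inference is built around the within-animal difference
`d_ij = x_ij(after) − x_ij(before)`, which cancels the subject-level
baseline shared by the pair.

### Sign-consistency prefilter

A metabolite is retained when at least a fraction `t` (default 0.70) of
animals agree on the direction of `d_ij`:
`max(n_up, n_down) ≥ ⌈t·n⌉`. Exact-zero differences count toward neither
direction — the strictest reading of "increased or decreased" — so a
metabolite with many ties is penalised, never helped. Two comparison modes
exist because "at least 70%" and "more than 70%" differ at n = 10
(≥7 vs ≥8): `ge` (default) and `gt`. The count threshold is computed as
`ceil(t·n − 1e−9)` (resp. `floor(t·n + 1e−9) + 1`) to keep float noise in
`t·n` from flipping a boundary case.

Under a sign-symmetric continuous null with n = 10 the per-metabolite
retention probability is the exact binomial tail sum
P(X ≥ 7) + P(X ≤ 3) = 0.34375 for X ~ Bin(10, ½); the test suite and the
acceptance script both recover this rate by simulation. The filter is a
*biological* screen, not an error-rate control: a third of pure-noise
metabolites survive it by chance.

### PLS-DA, validation, VIP

The two conditions are dummy-coded 0/1 and centred; with a single response
column, NIPALS is exact in one pass per component (w ∝ Xᵀy, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate X by t pᵀ). Columns are autoscaled
(centred, unit sample sd with ddof = 1) by default; `pareto`, `center`, and
`none` are available. Constant columns are left centred with a warning.
Default components: 5.

* **R²Y** is the cumulative fitted fraction 1 − SS_res/SS_tot.
* **Q²Y** comes from stratified k-fold CV (default k = 10, seeded): scaling
  and model are re-estimated per training fold, held-out dummy responses
  predicted, and Q²Y = 1 − PRESS/SS_tot. Pairs are *not* forced into one
  fold by default (a leave-pair-out analysis can be composed from the
  library pieces); the permutation test likewise shuffles labels freely
  across all 2n samples, with an optional within-pair sign-flip mode
  (`pairs=` argument) for the strict paired null.
* **Permutation test**: B (default 1000) label permutations, statistic =
  R²Y of the refit at the same component count (monotone in class
  separation and cheap; a `q2y` statistic mode exists), p = (b+1)/(B+1) so
  p is never 0 and its granularity is 1/(B+1).
* **VIP**: `VIP_j = sqrt(J · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)` with
  `SSY_a = q_a² tᵀ_a t_a`; Σ_j VIP_j² = J is an algebraic identity and is
  asserted to 1e−8 on every fitted model.

Component score vectors from deflated NIPALS are mutually orthogonal; PCA
(used for cluster/outlier inspection) is computed by SVD with a
deterministic sign convention (largest-|loading| entry positive).

### Univariate tests and correlation networks

Paired t-tests are one-sample t on the differences, two-sided, df = n−1,
**no multiple-testing correction by default** — matching the raw p < 0.05
convention of small-cohort metabolomics; a Benjamini–Hochberg column is
available but off. Degenerate inputs never crash: all-zero differences
give t = 0, p = 1; constant non-zero differences give p = NA with a
warning.

Per-condition Pearson correlations use the t-transform
`t = r·sqrt((n−2)/(1−r²))`, df = n−2, two-sided; network edges keep
p < α (default 0.05). The correlation-shift criterion
Δr = |r_before − r_after| is computed on **all** pairs, not only
significant edges — a shift should not hide behind a just-insignificant
edge — and flags pairs with Δr strictly > 1 (so Δr = 0.99 is not flagged,
1.01 is). Δr is absolute, so the criterion is invariant to which condition
is called "before". A metabolite in ≥ 1 flagged pair is *discrepant*.
Pairs with undefined r (constant metabolite in a slice) are skipped and
reported.

### Union caller and enrichment

`selected = (VIP > 1) ∪ (p < 0.05) ∪ (discrepant)`, with `criteria_hit`
recording exactly which criteria fired; NA in a criterion can never fire
it but also cannot veto another. Two p-comparison modes: `lt` (strict, for
raw p-values, the default) and `le` (for published tables rounded to
3 decimals, where a printed 0.050 sits *at* the threshold; the shipped
reference call summary needs this mode to reproduce its printed counts).

Enrichment is a hypergeometric upper tail on each pathway ∩ background,
with fold = (hits/|selected|)/(set_size/|background|); the natural
background is the post-prefilter metabolite list (configurable). Pathway
sets are read from GMT.

## The synthetic generator

`generate(SyntheticConfig)` emulates the statistical skeleton of a small
paired NMR study on the log scale (concentrations span three orders of
magnitude and must stay positive, so effects are multiplicative):

    log C = log baseline_j + animal_ij + effect_ij·[after] + noise_sd·ε

* `baseline_j`: log-uniform over 0.005–3.4 mmol/L (the span from the least
  to the most abundant serum metabolite in the motivating study).
* `animal_ij ~ N(0, 0.3²)` shared by both members of a pair — the term
  that makes pairing informative. No study-reported value exists for this
  sd; 0.3 on the log scale (≈ 30% between-animal spread) is a free
  parameter documented here.
* `noise_sd = 0.2` per observation; `effect_size` (default 1.5) is the
  standardised paired effect d: the log shift equals
  `effect_size·sqrt(2)·noise_sd`.
* Defaults mirror the motivating cohort: 10 animals, 41 metabolites,
  19 responsive (17 up, 2 down), ~10% of the remainder *idiosyncratic*
  (same shift magnitude, independent random sign per animal — the pattern
  the prefilter exists to remove).
* `correlation_blocks=(size, r_before, r_after)` plant within-condition
  correlation via a shared latent factor per condition with loadings
  ±sqrt(|r|) (alternating signs for negative r; exact for blocks of two).
  Block members carry their animal-effect variance inside the
  condition-specific factor scale — otherwise an independent per-metabolite
  animal effect would dilute the planted r (a 0.9 target realises near
  0.28) — so planted-block members have no cross-condition animal effect.
  The preset (`make_paper_shaped_cohort`) plants one 2-metabolite block
  flipping +0.9 → −0.9, i.e. Δr = 1.8.

What the generator does **not** emulate: metabolite-metabolite baseline
correlation outside planted blocks, heteroscedastic quantification error,
missing/censored low-abundance values, and non-lognormal tails. Passing
tests therefore demonstrate the pipeline's statistical behaviour under a
clean paired lognormal model, not robustness to real spectral artefacts.

## Problem sizes used in the checks

The automated checks run at sizes chosen to give tight Monte-Carlo error
at interactive runtimes: prefilter null calibration on 20,000 simulated
metabolites; permutation type-I error over 200 null datasets of 20 × 28
with B = 200 permutations each; edge calibration over 120 null cohorts of
15 metabolites; recall and Q²Y-benefit over 50 generator seeds each.

## Design choices where the design was open

* **Prefilter comparison mode** defaults to `ge` (the operational ≥ 70%
  reading); `gt` is exposed since both readings are defensible and differ
  at n = 10.
* **Permutation statistic** is refit R²Y rather than CV Q²Y: it is
  monotone in class separation, ~50× cheaper, and its null calibration is
  exact under exchangeability (verified empirically in the suite).
* **CV folds ignore pairing** by default; for 2n = 20 samples and k = 10
  stratified folds each fold holds one sample per class.
* **Δr without a significance gate**: gating shifts on edge significance
  would make the criterion depend on α and hide large swings between two
  individually non-significant correlations.
* **Rejected, not imputed, missing values**: the pipeline requires a
  complete matrix; incomplete quantification must be resolved upstream,
  because any imputation rule would silently interact with the sign
  filter.

## Known limitations

* With n = 10 pairs, correlation estimates have sd ≈ (1−r²)/3; the Δr > 1
  rule is deliberately coarse and individual flagged pairs should be read
  as candidates, not confirmed rewiring.
* The prefilter's Q²Y benefit is regime-dependent: when the planted signal
  is strong (the preset's 19 responders at d = 1.5, Q²Y ≈ 0.9), filtering
  neither helps nor hurts predictivity measurably, and the
  filtered-vs-unfiltered comparison is a coin flip. The benefit is large
  and consistent when a moderate signal is diluted by many inert
  metabolites (the regime probed by the acceptance checks: 12 responders
  of 92 at d = 1.0). `compare_prefilter` reports both triples so the user
  can see which regime their data is in.
* The union caller inherits the raw-p convention: with 28 tests at
  α = 0.05 some univariate calls are expected to be false positives; the
  `criteria_hit` audit and the optional BH column exist precisely so users
  can tighten this.
* VIP > 1 is a convention, not a calibrated error rate; VIP magnitudes
  depend on the component count.
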