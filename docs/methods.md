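# Methods

This note documents the models and procedures `icfscale` implements, the
numerical choices behind them, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Measurement model and orientation

The latent trait θ is *functioning ability*; a binary response of 1 means
"functioning" on that item, and the item response function
P(X = 1 | θ) = logistic(a(θ − b_i)) is increasing in θ. Item difficulty b_i is
"the difficulty of being functional": washing oneself is harder (larger b)
than staying conscious. The trait is fixed at N(0, 1) for identification —
difficulties are expressed in prior standard-deviation units and no secondary
centering is applied.

Ordinal 0–4 qualifier codes grade *impairment*, so they run against the
trait: the generator draws the functioning-graded variable G = 4 − Y from a
homogeneous graded-response model, P(G ≥ m | θ) = logistic(a(θ − τ_m)) with
four ascending thresholds τ₁ < … < τ₄ per item. Two consequences worth
stating explicitly:

- θ → −∞ gives code 4 (complete impairment), θ → +∞ gives code 0;
- dichotomizing codes {0, 1} → 1 yields an exact 2PL item with cutpoint τ₃
  (`thresholds[2]`), so the binarized pipeline analyses data that genuinely
  follow the model the Rasch stage fits. This closure property is why the
  homogeneous graded-response model was chosen over alternatives (e.g. a
  partial-credit or sequential model), which do not dichotomize into a 2PL.

## Data shaping

Fixed order: recode 8/9 → missing, person filter (> 30% missing), item filter
(≥ 5% missing, computed over retained persons), kNN imputation, binarization,
Guttman-error person screen, constant-item drop. The person filter precedes
the item filter because high-missingness persons are an exclusion at
recruitment, not a property of the item set.

**kNN imputation (k = 5).** Distance between persons is Euclidean over
co-observed items rescaled by the co-observed count (the `nan_euclidean`
convention, computed by scikit-learn); donors must have the target item
observed; the imputed value is the donor median rounded to the nearest valid
code with exact halves resolved toward the lower (less-impaired) code. Donors
are always original observed rows — imputed values never feed later
imputations, and observed cells are never modified.

**Guttman-error screen.** With items ordered by descending sample popularity
(ties: input column order), G₊(person) counts ordered pairs with the easier
item failed and the harder passed. The outlier fence is the
Hubert–Vandervieren adjusted boxplot upper fence Q3 + 1.5·e^{3·MC}·IQR (MC ≥ 0)
or Q3 + 1.5·e^{4·MC}·IQR (MC < 0), with the medcouple MC from statsmodels and
quartiles as numpy's linear-interpolation (type-7) percentiles. A constant G₊
sample degenerates to fence = Q3. This skew-adjusted fence is used instead of
the classic Tukey fence because G₊ distributions are right-skewed by
construction.

## Mokken stage

**Scalability coefficients.** H_ij is the ratio of the observed inter-item
covariance to its maximum given the margins; identically 1 − F_ij/E_ij where
F_ij counts observed Guttman-error cells for the pair and
E_ij = n(1 − p_easier)p_harder the count expected under independence. Hi and H
aggregate F and E over an item's pairs and over all pairs. The identity of
the two routes is enforced by test to 1e-12. Pairs whose margins make the
maximum covariance zero are undefined (NaN, warned). Standard errors come
from a nonparametric person bootstrap (default 1000 resamples); degenerate
resamples (a constant item) are excluded from the SE rather than patched.

**AISP.** Scales form sequentially: a genetic algorithm (population 20,
uniform crossover with probability 0.05, bit-flip mutation 0.1, elitism 1,
500 generations by default) searches the largest subset of remaining items in
which every within-subset Hi ≥ c and every within-subset H_ij > 0. Infeasible
chromosomes are repaired by greedily removing the lowest-Hi item (preferring
items involved in non-positive pairs) until feasible; fitness is the repaired
subset's size with summed Hi as tie-break. The best repaired subset is
re-injected each generation, so the returned scales are feasible by
construction, which the tests verify directly. "Population 20" is the reading
adopted for the genetic parameter called "size of sampling items"; nothing
else in the procedure depends on that interpretation.

**Local independence (W indices).** For each item, three conditioning regimes
pool sample covariances computed within strata of at least 4 persons: W1 —
pair covariances given the rest score over the remaining items, for pairs
containing the item; W2 — pair covariances given each third item's value, for
pairs containing the item; W3 — covariances of other-item pairs given the
item's own value. Each regime's W is (proportion of negative covariances) ×
(summed magnitude of the negatives); no sample-size weighting. W₊ = W1+W2+W3
is screened against the one-sided fence Q3 + 3(Q3 − M). Operating
characteristics to be aware of: the fence is scale-free and jumpy when the
item pool is small (~10 items), clean data occasionally throw a false flag,
and detection of a planted near-duplicate item needs n in the low thousands;
with multiple strong violators the fence can mask itself (outliers lift Q3).
The pipeline treats W flags as one removal rule among several, never as the
sole gatekeeper.

**Monotonicity.** Rest-score groups merge adjacent scores from the low end
until each holds ≥ 50 persons (`minsize`); a violation is a decrease in the
item's group-wise pass proportion exceeding `minvi` = 0.03; each violation is
tested by a one-sided pooled two-proportion z at α = 0.05 (the test is not
named by convention; the pooled z is the natural two-sample choice). The
summary Crit = 50(0.30 − Hi) + √#vi + 100(#vi/#ac) + 100·maxvi + 10√Σvi +
1000(Σvi/#ac) + 5·max_z + 10√#zsig + 100(#zsig/#ac), truncated below at 0,
with Crit > 40 read as serious. Because the constant weights of Crit are a
convention, removal decisions combine it with #zsig (> 0 significant
violations *and* Crit > 40) rather than relying on its magnitude alone.

**Invariant item ordering (MIIO).** Items ordered globally by descending
popularity; for each ordered pair and each merged rest-score group over the
remaining items, a violation is p̂_harder − p̂_easier > minvi, tested one-sided
by the paired discordant-cell statistic z = (n₀₁ − n₁₀)/√(n₀₁ + n₁₀) (the
McNemar-type statistic is used because the two proportions are computed on
the same persons). Backward selection removes the item with the most
significant violations (ties → lower Hi) and re-runs until none remain.

**Reliability.** All four coefficients are ratios against the population
variance of the total score. α and λ₂ are the classical covariance formulas.
Molenaar–Sijtsma ρ replaces the unobservable diagonal of the joint
pass-proportion matrix by the average of the nearest off-diagonal neighbours
in popularity order (single neighbour at the two boundary positions — the
simplest rule consistent with the interpolation idea). The LCRC replaces all
joint terms by their values under an unrestricted latent class model (default
3 classes) fitted by EM with 20 random restarts, tolerance 1e-8 on the
log-likelihood, class probabilities clipped to [1e-6, 1 − 1e-6]; if no restart
converges the LCRC is reported missing with a warning. Three classes is a
deliberate small default for ~130-person cohorts; increase `lcrc_classes`
with larger samples.

## Rasch stage

**Fitting.** Marginal ML with 61-node Gauss–Hermite quadrature; unique
response patterns are collapsed with counts, and the analytic gradient uses
the standard posterior-expected-count form. Optimization is L-BFGS-B with
difficulties bounded in [−15, 15] and log-discrimination in [−3, 3] (bounds
keep degenerate bootstrap replicates finite); ftol 1e-13 / gtol 1e-9 so the
MML score equations hold to ~1e-9 in proportion units. The "unconstrained"
model frees one *common* discrimination a = e^η (not per-item slopes);
standard errors come from the inverse observed information (central-difference
Hessian of the analytic gradient), with the delta method through η for a.

**Model choice.** LR = 2(ℓ_u − ℓ_c) against χ²₁, and the lower-AIC model is
preferred; a negative LR beyond 1e-6 raises an optimization-failure error
rather than being silently clipped.

**Item fit.** Persons are split into 10 equal-count groups by EAP ability and
χ²_i = Σ_g n_g(O_ig − E_ig)²/(E_ig(1 − E_ig)), df = 10 − #item parameters.
Two numerical points matter here. First, E_ig is the model-implied
*conditional* pass probability given the person's total score,
P(X_i = 1 | TTS = r), computed exactly by the elementary-symmetric-polynomial
recursion with stable leave-one-out synthetic division (forward when
P_i < 1/2, backward otherwise) — evaluating the IRF at the EAP instead is
badly anti-conservative on short scales because the grouping variable
contains the item itself (measured flag rate ~70–100% on clean 10-item data
vs 4% for the conditional form). Second, the EAP sort key is quantized to
1e-10 before ranking: equal-total-score persons have EAPs equal only up to
~1e-16 pattern-correlated rounding noise, and splitting a tie block on that
noise biases group composition enough to inflate the χ² several-fold. Groups
with a deterministic expectation (e.g. everyone at the maximum score) are
skipped.

**Screening circle.** Iterate {X1 = items with a negative point-biserial
against the total or rest score} ∪ {X2 = items with raw item-fit p < 0.05
under the AIC-preferred model}; remove, refit, repeat until the union is
empty. Bonferroni-adjusted item-fit p-values are reported for the final
item-position check but do not drive removal inside the circle.

**Global GOF.** Pearson χ² over the observed unique response patterns with
expectations n·P(pattern | fit) by quadrature; B parametric replicates
(default 199) are each refitted and scored against their own refit;
p = (1 + N₊)/(B + 1). A degenerate replicate (constant item) is scored
against the generating fit instead of a refit.

**Unidimensionality.** Second-largest eigenvalue of the pairwise-ML
tetrachoric correlation matrix (0.5 added to every cell of a 2×2 table with
an empty cell; the bivariate-normal rectangle probability is computed by the
d/dρ-identity with 48-node Gauss–Legendre quadrature and solved by Brent's
method; a failed solve falls back to the phi coefficient with a warning).
The null distribution comes from n_sim (default 100) data sets simulated from
the fitted model without refitting; p = (1 + #{sim ≥ obs})/(n_sim + 1).

**Abilities and conversion.** EAP under the N(0,1) prior. Both model variants
share one discrimination, so the total score is sufficient and the
total-score → ability table is exact (EAP is used rather than ML precisely
because it is finite at the zero and perfect scores). The percent column is
the linear 0–100 rescale of θ̂(TTS) with halves rounded away from zero, and
the quadratic coefficients are unweighted OLS on the K + 1 (TTS, θ̂) grid
points — the published 46-row chart reproduces its printed coefficients under
exactly this convention, which is why the unweighted-grid reading was adopted
over a person-frequency-weighted fit.

**DIF.** Constrained fits per group; focal difficulties shifted by the
difference of group mean difficulties (equal-mean equating — the anchoring
choice when no anchor items are declared); Lord's
χ² = (b̂_ref − b̂_foc)²/(SE²_ref + SE²_foc), df 1, Holm over items. Items
constant within a group are excluded and reported. The reference group is the
larger one.

## The synthetic cohort

`make_study_like_fixture` emulates the published study's design: 130 persons,
59 `b` + 59 `d` items, θ ~ N(0,1), a ~28% minority group label. Difficulties
are N(−0.5, 1.2²) clipped to ±2.8 (inpatient cohorts mostly function on most
items, so items skew easy); 80% of items discriminate well (a = 1.5) and 20%
are weak (a = 0.5), giving the selection stages genuine screening work;
ordinal thresholds sit at b + (−1.5, −0.5, 0.5, 1.5); per-item missing rates
are drawn from Beta(0.8, 19) (mean ≈ 4%, right-skewed) and split evenly
between codes 8 and 9, so a realistic minority of items crosses the 5%
screen. Missingness is independent per cell given the item rate.

What the generator does **not** emulate: informative missingness (real "not
applicable" codes cluster by patient condition), rater effects and ordinal
category-use styles, any planted DIF or local dependence (tests construct
those explicitly when needed), and the empirical marginals of any real
cohort. Passing tests therefore demonstrate correctness of the procedures
under the stated models — not that any particular clinical data set satisfies
those models.

## Problem sizes and defaults used in validation

Simulation-based tests and acceptance checks run at sizes chosen to make the
statistical claims sharp while keeping the suite quick: 10-item cohorts of
n = 500–2000, 20 seeds for operating-characteristic claims, B = 99 bootstrap
replicates and 39-replicate Monte-Carlo nulls where a full-size run would
only narrow the p-value grid. The pipeline defaults (B = 199, n_sim = 100,
1000 bootstrap resamples for H) match the published analysis settings.

## Known limitations

- Polytomous Mokken analysis is out of scope; the pipeline dichotomizes first.
- Per-item slopes (2PL/3PL), pseudo-guessing and multidimensional models are
  not fitted; "unconstrained" means one common slope.
- The W-index fence is unstable for small item pools (see above); its flags
  should be read alongside the Hij map rather than alone.
- The Crit constants and the exact W regime taxonomy are conventions; their
  magnitudes are comparable across runs of this package but not across other
  implementations.
- Tetrachoric correlations use pairwise ML with a fixed cell correction; a
  full-information factor-analytic test might differ at small n.
- The LCRC depends on the latent-class count; it is a lower-variance but
  model-dependent estimate.
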