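# Methods

## The question and the data model

Each respondent rates five WSAS life areas (home management, private
leisure, close relationships, social leisure, work) twice on an integer 0–8
scale: impairment, and botheredness about that impairment. The audit asks
whether the two kinds of rating are interchangeable — whether an impairment
score can stand in for a botheredness score — via two complementary
resampling analyses on the paired vectors per item and pooled across items.

The canonical in-memory container is a long-format table
(`respondent_id, item, impaired, bothered`); "combined" analyses concatenate
the five items' pairs (61 respondents × 5 items → 305 pairs), so a pooled
result weights every item equally per respondent. An alternative reading of
"combined" — per-respondent summed scales — is deliberately not the default,
because pooling matches the per-item machinery exactly and requires no extra
modelling assumption.

## Association: tie-aware Spearman with a permutation test

Ordinal 0–8 data are heavily tied, so Spearman's rho is computed as the
Pearson correlation of average-rank vectors (the tie-exact form), never via
the `6Σd²/n(n²−1)` shortcut, which is biased under ties. The permutation
test shuffles the bothered vector without replacement, holding impaired
fixed, and counts resampled coefficients **as large or larger** than the
observed one (one-sided greater, the default; a two-sided absolute-value
tail is available since the intended treatment of negative coefficients is
ambiguous when all observed coefficients are positive).

Numerical detail: for a fixed pair of rank multisets, rho is an increasing
affine function of the rank dot product, so tail counting is done on
integer dot products of doubled ranks (average ranks are half-integers).
Equality is therefore exact — no floating-point tie misclassification.

For n ≤ 7 (`exact_threshold`, default 7; 7! = 5,040) the test enumerates all
n! permutations and reports the exact fraction.

## Interchangeability: paired sign-flip test

If impaired and bothered are interchangeable, the members of each pair are
exchangeable, so the differences `d_i = impaired_i − bothered_i` are
symmetric about zero. The test multiplies the differences by independent
random signs and compares `|mean(s·d)| ≥ |mean(d)|` (two-sided; ties counted
as extreme, mirroring the correlation test's counting rule). Counting is on
integer sums, so ties are again exact. The orientation is fixed as
impaired − bothered: with botheredness running higher, mean differences are
negative. For n ≤ 20 (≤ 1,048,576 assignments) the exact twin enumerates all
2^n sign vectors; zero differences simply contribute duplicate assignments.

## p-value conventions

Monte-Carlo tests default to the add-one convention `p = (b+1)/(B+1)`, which
is never zero and yields a valid test; at B = 10,000 with zero exceedances
this reports 0.0001. The plug-in proportion `b/B` is available for
comparisons against enumeration, and exact enumerations always report the
plug-in fraction (there the fraction *is* the p-value). Whether reported
p-values of 0.0001 in this kind of analysis reflect add-one or plug-in
counting is generally not determinable; both are exposed.

## Synthetic data: Gaussian copula with threshold discretization

The study's raw patient data are not publicly deposited, so the generator
emulates their statistical structure. Per item, a latent bivariate standard
normal pair with correlation ρ_latent is drawn; the bothered coordinate gets
a latent shift δ; both coordinates are discretized through the
standard-normal quantiles of a 9-category marginal. This gives independent
control of rank correlation and marginal shape — both needed to match
observed per-item correlations (0.56–0.76) and mean differences (−1.23 to
+0.03) simultaneously. An integer-scale shift could never hit fractional
mean-difference targets, hence the latent-scale shift.

Calibration:

- **Shift**: the expected discretized rating under a shifted latent is a
  finite normal-CDF sum, so δ solves
  `E[impaired] − E[bothered](δ) = target` exactly by bracketing
  root-finding. No simulation involved.
- **Latent correlation**: discretization attenuates rank correlation, so
  ρ_latent must weakly exceed the target Spearman. It is found by brentq on
  a Monte-Carlo probe (n = 200,000 draws) that reuses one fixed pair of
  normal draws across evaluations (common random numbers), making the probe
  a smooth monotone function of ρ_latent. Unreachable targets (e.g. a
  near-degenerate marginal) raise an error reporting the achievable bound.

Default study-like conditions: n = 61 respondents; per-item Spearman targets
0.7081 (home), 0.7558 (private leisure), 0.5721 (relationships), 0.6379
(social leisure), 0.5596 (work); per-item mean-difference targets −0.7869,
−0.3770, −0.6393, +0.0328, −1.2295. The default marginal
`(0.06, 0.10, 0.17, 0.19, 0.15, 0.12, 0.09, 0.07, 0.05)` (mean 3.64,
skewness ≈ 0.29) concentrates mass on ratings 2–6 with a thinner upper tail
— clearly non-normal, as the source distributions were described, though
their exact shape is unknown; the weights are a documented modelling choice.
Both coordinates share one marginal; the bothered marginal differs only
through δ.

What the generator does **not** emulate: respondent-level dependence across
items (items are generated independently, whereas a real respondent's five
ratings are correlated), demographics, missingness beyond uniform deletion,
and any response styles (central tendency, anchoring). Passing tests
therefore demonstrate correctness of the statistical machinery under a
plausible data-generating process, not properties of the original sample —
item-level analyses are unaffected by the missing cross-item dependence,
but pooled ("combined") p-values on real data would be somewhat less
independent across pairs than in these simulations.

## Descriptives

Medians and quartiles use linear interpolation between order statistics
(type 7, the numpy/R default) — boxplot hinge conventions differ across
software, so the convention is fixed and named. Skewness is the adjusted
Fisher–Pearson sample coefficient; a constant vector reports skewness 0 with
a warning instead of NaN so degenerate inputs cannot crash a pipeline run.

## Reproducibility and seeding

All randomness flows from one master seed through named substreams:
`SeedSequence(master_seed, spawn_key=crc32(label)…)` keyed by task labels
(e.g. item name + test name). Adding an item or test never perturbs other
streams, and identical inputs + seed give bit-identical reports (timestamps
aside). Replicate seeds in simulations are drawn per replicate from the
replicate's own substream.

## Simulation design choices

Type-I error uses each test's own null: zero latent shift (sign-flip;
differences symmetric by exchangeability regardless of the latent
correlation, kept at 0.6 to mimic paired data) and zero latent correlation
(permutation test). Rates are reported with binomial standard errors
`sqrt(r(1−r)/n_replicates)` and never from fewer than 100 replicates;
acceptance-style checks use 3-SE bands, since no external calibration
benchmark exists for these procedures. The study-pattern replication is
framed as orderings and majorities (which items reject at α = 0.05 in most
replicates), never as matching specific p-values, which depend on the
unavailable raw data. Default problem sizes — 2,000 replicates at B = 2,000
for type-I error, 500 replicates at B = 10,000 for the pattern check in the
test suite, 200 in the acceptance script — keep full runs in the minutes
range while leaving Monte-Carlo error well inside the stated bands.

## Known limitations

- The sign-flip test is slightly conservative at small B because the
  resampled sum distribution is discrete and the add-one convention rounds
  p upward; observed type-I error ≈ 0.04–0.05 at B = 2,000, n = 61.
- The exact permutation path scales as n!, so it is capped at n ≤ 7 by
  default; the exact sign-flip path at n ≤ 20.
- Pooled analyses treat the 305 combined pairs as exchangeable units; with
  real data the five pairs per respondent are dependent (see above).
- `calibrate_latent_correlation` inverts a Monte-Carlo probe; its result
  carries O(1/√200,000) noise, well below the ±0.02 recovery tolerance used
  in tests.
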