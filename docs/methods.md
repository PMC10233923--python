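# Methods

## The problem

After cataract surgery an eye's refraction is determined by its biometry,
the implanted IOL power and where the lens settles (the effective lens
position, ELP). Classical calculators model this with thin-lens vergence
algebra; their systematic errors grow in highly myopic eyes (AL ≥ 26 mm),
where posterior staphyloma, extreme ELP extrapolation and formula-specific
AL corrections all bite. `hmiol` treats the two classical formulas as
*feature transforms* and lets a supervised ensemble learn the residual
structure from outcomes.

## Vergence engines

Both engines are written in closed form and inverted exactly (each is a
Möbius function of power, so forward/inverse round trips are exact to
machine precision).

**SRK/T.** Mean K = (K_flat + K_steep)/2; corneal radius r = 337.5/K
(keratometer index 1.3375, the IOLMaster convention). Long-eye corrected
axial length LCOR = AL for AL ≤ 24.2 mm, else −3.446 + 1.716·AL −
0.0237·AL²; corneal width Cw = −5.41 + 0.58412·LCOR + 0.098·K; corneal
height H = r − √(r² − Cw²/4) with a negative radicand clamped to zero
(the formula's classical behavior in long, steep corneas — a warning is
logged); ELP = H + (0.62467·A − 68.747) − 3.336; retinal thickness
0.65696 − 0.02029·AL added to AL gives the optical axial length; the
two-surface vergence expression with indices 1.336 (aqueous/vitreous)
and 1.333 (cornea) at a 12 mm vertex yields the spectacle refraction.

**Haigis.** ELP d = a0 + a1·ACD + a2·AL (exactly linear in both inputs);
corneal power from the mean-K radius with index 1.3315; internal index
1.336; same 12 mm vertex. When a lens model publishes only an SRK/T A
constant the triple is derived as a0 = 0.62467·A − 72.434, a1 = 0.4,
a2 = 0.1 (the standard single-optimized conversion) with a logged
notice — registry-supplied triple-optimized constants are preferable.

Manifest refractions measured in a 5 m lane are standardized to 6 m by
adding −0.03 D to the spherical equivalent.

## Cohort rules

Inclusion requires AL ≥ 26.00 mm, complete six-field biometry, an
observed postoperative SE, and (when recorded) BCVA of 20/40 (logMAR
0.30) or better; every rejection carries a machine-readable reason code.
Train/test splitting is a seeded permutation with ⌊n·fraction⌋ training
cases (1828 eyes at 8:2 → 1462/366). The AL input-limit filter retains
AL ≤ limit (closed boundary, "up to 35.00 mm"). AL subgroups are
half-open bins [26, 28), [28, 30), [30, ∞); the interior boundaries go
to the upper bin because the conventional labels ("26.00–28.00 /
28.00–30.00 / ≥ 30.00") do not specify them — the boundaries are a
parameter. When a `patient_id` column is present, one eye per patient is
kept by seeded random choice; otherwise input is assumed pre-deduplicated.

## The ensemble

Four sub-models: {XGBoost regressor, RBF-kernel SVR} × {feature set 1,
feature set 2}. Set 2 holds AL, K_flat, K_steep, ACD, LT, CD, the
queried IOL power, the A constant and the Haigis-predicted refraction at
that power (9 features); set 1 appends the SRK/T-predicted refraction
(10). Formula features are recomputed at whatever power is queried,
which is what gives the trained model a dose–response in power. The
training target is the observed postoperative SE.

Hyperparameters are conservative, reproducibility-first defaults rather
than tuned values: trees with depth 4, 300 rounds, learning rate 0.05;
SVR with C = 10, ε = 0.1 on standardized features (standardization is
applied inside the SVR pipeline only; trees are scale-invariant). All
seeds are explicit and threaded to every estimator.

Combination weights are w_k ∝ 1/MAE_k, normalized, where MAE_k is the
sub-model's out-of-fold MAE under an internal 5-fold split of the
training cohort (each fold's validation cases are disjoint from the
cases used to fit that fold's model); the final sub-models are refit on
the full training set. Equal weights are selectable. A sub-model with
zero validation MAE would take all the weight. The assembled prediction
is a convex combination, so it is always bracketed by the sub-model
predictions.

Persistence is a single joblib artifact embedding a format-version tag
and the feature schema; loading validates both and refuses mismatches,
and a save→load round trip reproduces predictions bit-exactly.

## Planner

The planner evaluates the predictor on a power grid (default −5 to 35 D
in 0.5 D steps — manufacturable increments) and returns the global
argmin of |prediction − target| together with the full candidate table.
Ties break toward the higher power, i.e. the more myopic predicted
outcome, the clinically safer direction; an `avoid_hyperopic` mode
restricts candidates to predictions at or below the target and falls
back (with a warning) when none qualifies. No restriction is placed on
the target refraction or AL.

## Evaluation battery

PE = actual − predicted (negative = more myopic than predicted). Reports
use the sample SD (n − 1), MedAE = median |PE|, and closed band
thresholds (|PE| ≤ t), which makes the band percentages exactly the
cumulative |PE| curve sampled at 0.25/0.50/0.75/1.00 D.

The formula performance index is 1/(SD + MedAE + |slope of PE on AL| +
10/f), with f the *fraction* of eyes within ±0.50 D. Expressing the hit
rate as a fraction puts the index on the few-hundredths scale familiar
from published league tables; the four components are exposed separately
so any alternative scaling can be recomputed.

Statistics follow the standard clinical protocol for paired formula
comparisons on one cohort:

* **Friedman test** on within-eye ranks of |PE| (tie-corrected χ²;
  the two-formula case uses the same rank statistic directly), with
  pairwise Wilcoxon signed-rank post-hocs, Bonferroni-corrected over all
  pairs. The asymptotic p was checked against a within-eye permutation
  null in the test suite.
* **Cochran's Q** on the paired within-band indicators per threshold,
  with exact McNemar post-hocs, Bonferroni-corrected. Identical
  indicator columns are reported as "no difference" (Q undefined).
* **Log-rank** on cumulative |PE| curves, treating absolute error as an
  event time with no censoring (every eye is an event), computed via
  `lifelines` and cross-checked against a from-scratch implementation.
* **Pearson correlation** and least-squares slope of PE against AL.

The Bonferroni family is all pairwise comparisons among the formulas
supplied — the conservative reading; adjusted p values are capped at 1
and never fall below the raw p. Comparator formulas that cannot be
recomputed locally (proprietary or web-only calculators) enter the
battery as pre-computed prediction columns in the input table.

## Synthetic cohorts

The generator's contract is *moment fidelity*: the post-truncation
marginals match the reference training-cohort values (AL 29.18 ± 2.19 mm
on 26.0–37.5 mm; K 43.30/44.32 ± 1.51/1.61 D; ACD 3.42 ± 0.34 mm; LT
4.44 ± 0.39 mm; CD 11.75 ± 0.42 mm). Because truncating a normal at
26 mm would inflate its mean by ≈ 0.3 mm, the underlying location/scale
of the AL distribution are solved numerically (via `scipy.optimize`)
so the *truncated* mean and SD hit the targets exactly. The remaining
fields are drawn conditionally on the standardized AL, which preserves
their marginal moments and the specified correlations exactly.

The correlation structure is an invented, configurable mild physiologic
prior (the reference data publish only marginals): ρ(AL, ACD) = +0.3,
ρ(AL, K) = −0.2, ρ(K_flat, K_steep) = +0.9. The keratometry pair is
ordered by sorting, a < 10% event under the strong coupling that shifts
the flat/steep means by ~0.02 D — negligible against the test
tolerances.

Implanted powers mimic clinical selection: the truth formula's exact
power for the eye's target refraction, rounded to 0.5 D and clamped to
[−10, 40] D. The default target policy is −3 D (typical for high myopes
who value near vision; it also reproduces the reference implanted-power
distribution of ≈ 9.3 ± 5.0 D, where an emmetropia policy would center
near 4.5 D), jittered per eye with SD 0.75 D to emulate surgeon-to-
surgeon target spread — without that spread a trained model sees only
one operating point and has no identifiable power response. The observed
outcome is the truth formula's refraction at the implanted power plus
N(0, noise_sd), noise_sd = 0.3 D by default, so the irreducible MAE of
a perfect predictor is 0.3·√(2/π) ≈ 0.239 D — the yardstick for the
parameter-recovery tests.

What the generator does *not* model: posterior staphyloma, biometry
measurement error, surgeon-specific constant optimization, lens-model
heterogeneity (a single A = 118.0 lens is used by default) and any
deviation of true physiology from the Haigis/SRK-T optical family.
Passing recovery tests therefore demonstrates that the pipeline is
correct and statistically efficient under its stated generative model,
not that the trained ensemble attains any particular accuracy on real
patients.

## Problem sizes and numerical choices

The test suite trains on cohorts of 300–1462 eyes; the acceptance script
uses the full 1828-eye cohort split 8:2, which trains all four
sub-models plus the 5-fold weighting scheme in a few seconds on one CPU.
All optical computation is double precision with no intermediate
rounding; closed-form inversions are exact, and the independent
cross-check oracle in the tests solves the physical vergence chain by
bracketed root-finding instead of using the printed formula algebra.
Degenerate geometry (ELP reaching the retina) raises a specific error;
the SRK/T corneal-height radicand is clamped at zero as in the original
algorithm; inverse solutions outside the manufacturable [−10, 40] D
range raise unless the caller explicitly disables the range check.

## Known limitations

* The printed accuracies of the original clinical study depend on its
  (unavailable) patient cohort and trained weights; this package
  reproduces the *method* and validates it on synthetic ground truth.
* The sub-model hyperparameters and combination-weight scheme are
  reasonable defaults, not a tuned reproduction; both are configurable.
* The SVR family's ε-insensitive loss (ε = 0.1 D) bounds how tightly it
  can interpolate even noise-free targets (residuals up to ≈ ε/2 are
  unpenalized); the tree family interpolates to < 0.01 D in the same
  setting.
* Cochran's Q and the Friedman omnibus use asymptotic χ² p-values, as
  standard statistical software does; on very small cohorts exact
  permutation tests (as used for validation in the test suite) would be
  preferable.
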