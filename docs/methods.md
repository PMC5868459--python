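# Methods

This note documents the statistical machinery implemented in `retroprobe`,
the assumptions behind it, the defaults and why they were chosen, and what
the synthetic-data validation does and does not establish.

## Task and data model

One trial: four bar orientations (degrees, uniform on [0, 360)), an
optional retrocue to one item, and two sequential continuous-report probes
of distinct items. Conditions are `neutral` (no informative cue),
`cued_first` (cued item probed first) and `cued_second` (cued item probed
second). Each response is labelled by the recalled item's **cue role**
(cued / uncued / neutral) and its **position** (first / second response);
all condition-level analyses operate on these role × position cells.

Files store degrees and 1-based item indices; everything internal is
radians, wrapped to (−π, π] with the boundary mapped to +π. Positive
errors are counterclockwise. Trials missing a response are dropped only
from analyses that need that response.

**Exclusion rule.** A subject whose pooled signed errors are not
significantly concentrated by a Rayleigh test (p > .01) is excluded as
performing at chance. Pooling uses both responses by default; the
`responses` argument allows screening on the first or second response only,
since the convention is not uniquely fixed by the paradigm.

## Circular statistics

Circular SD uses the Mardia definition `sqrt(−2 ln R̄)` (the convention of
the precision-WM literature, and what `scipy.stats.circstd` computes);
recall accuracy is its reciprocal, reported in 1/radian. A perfectly
balanced sample (R̄ = 0) yields accuracy 0 with a warning rather than an
error, keeping condition tables total. The Rayleigh p value uses Zar's
finite-n correction `exp(sqrt(1 + 4n + 4(n² − z n)) − (1 + 2n))` via
pingouin.

## Mixture model

`p(x) = p_mem·VM(x; 0, κ) + (1 − p_mem)/2π` is fit by direct bounded
maximum likelihood (L-BFGS-B) from a 5 × 4 start grid
(`p_mem ∈ {0.1 … 0.9}`, `κ ∈ {1, 4, 16, 64}`), keeping the best local
optimum. EM is unnecessary for a two-parameter box-constrained problem.
Numerical choices:

- `log I0(κ)` is computed as `log(ive(0, κ)) + κ` (exponentially scaled
  Bessel), stable across the whole admissible range;
- κ is capped at 500 (circular SD ≈ 2.6°, beyond plausible motor
  precision), which also bounds the Bessel argument;
- fits require n ≥ 20 by default; the E1-style designs provide 160 trials
  per role × position cell;
- `grid_search` provides a transparent exhaustive-lattice reference; ties
  break toward the lowest `p_mem`, then lowest `κ`, so the argmax is
  enumeration-order invariant.

No swap/non-target component is modelled: the response model has exactly
two components.

## Bias curves and the area-difference statistic

For each response the relative orientation `Δ = wrap(θ_other − θ_probed)`
of the *other* probed item is computed. The 64 bin centres are offset by
half a step (`c_j = −π + (j − ½)·2π/64`) so that no centre sits at 0 or ±π
and the positive/negative halves split exactly 32/32. Each bin holds the
`max(2, round(n/4))` trials with smallest circular distance to its centre
(stable ties by trial order) — overlapping quantile bins, so a trial
contributes to many bins and the curve is a smoothed estimate of
`E[error | Δ]`.

The area-difference statistic is the mean of the curve over positive
centres minus the mean over negative centres — proportional to the
trapezoid integral for equal spacing, and scale-free across designs with
different trial counts. Positive = attraction, negative = repulsion.
Group significance is a two-sided one-sample t test (with JZS BF) on the
per-subject area differences.

Two properties worth noting. First, quantile binning attenuates a
first-harmonic bias `β·sin(Δ)` by `sin(w)/w ≈ 0.90` at the implied window
half-width `w = π/4`; estimates of curve amplitude are therefore slightly
conservative. Second, the statistic's symmetries: negating the errors (or
the deltas) alone negates the area difference, whereas the joint mirror
reflection (negating both) is the same physical configuration and leaves
it invariant.

Relative orientation lives on the full 360° circle, matching the uniform
guess component of the response model, rather than a folded 180° bar-
symmetry space.

## Trade-off correlations

Per subject and condition, Pearson r between |error₁| and |error₂| across
complete trial pairs, Fisher-transformed with r clipped to ±(1 − 1e−12).
Group level: one-sample t (+ JZS BF) per condition and a one-way
repeated-measures ANOVA for the condition effect. Guess trials are not
removed before correlating.

## Inference

- **t tests** are two-sided; Cohen's d = mean/SD of the differences. A
  sample of identically zero differences is reported as t = 0 rather than
  an error, so degenerate null cells stay representable.
- **JZS Bayes factors** use the one-sample Rouder g-integral with a
  Cauchy(0, √2/2) effect-size prior, evaluated by adaptive quadrature with
  relative accuracy ≤ 1e−4 (cross-checked in the tests against pingouin's
  independent implementation, which itself carries ~1e−4 quadrature error).
- **Repeated-measures ANOVA** (fully within-subject, up to three crossed
  factors) is delegated to `statsmodels.stats.anova.AnovaRM`; each effect
  is tested against its interaction with subjects, degrees of freedom are
  uncorrected (no sphericity adjustment, matching the reporting convention
  the pipeline reproduces), and partial eta squared is recovered exactly as
  `F·df1/(F·df1 + df2)`. Degenerate 0/0 designs (no effect variance and no
  residual variance) are reported as F = 0, p = 1. Bayes factors are
  attached to t tests only; Bayesian ANOVA model comparison (random-effects
  prior integration) is out of scope.
- **Two-sample comparisons between experiments** are not part of the
  pipeline: `analyze_experiment` treats one cohort at a time.

## Synthetic cohorts

The generator reproduces the four designs: E1 (8 × 60 trials,
20/20/20 conditions per block, no order information), E2 (same, cue colour
conveys probe order), E2b (order conveyed and blocked) and E3 (10 × 60;
blocks 1–5 without and 6–10 with the order cue, i.e. 100 trials per
condition × order level, 600 total — the two-session design collapsed into
one session record, with `order_cued` carried per trial).

Response model: with probability `p_mem(role, position)` the error is von
Mises with concentration `κ(role, position)`, centred on
`β(role, position)·sin(Δ)`; otherwise uniform. Defaults (the simulated
study conditions, chosen once from the qualitative pattern of retrocue
findings): `p_mem` base 0.75, +0.10 for cued, −0.10 for uncued, −0.05 on
the second response; `κ = 12` for every cell (retrocues load on recall
probability, not precision); `β = −5°` on (uncued, response 1) only — the
cell where repulsion from the pending cued item is expected — and 0
elsewhere; between-subject SDs 0.08 (p_mem), 3 (κ), 1° (β), truncated to
valid ranges. The sin(Δ) shape is the simplest odd periodic bias profile;
no parametric shape is claimed for real data.

Trial-wise coupling: a per-trial share `g ~ Beta(a, a)` with
`a = (1/s − 1)/2` (so `Var(g) = s/4`, and coupling strength `s = 0` is
independence) scales the two responses' concentrations as `κ·2g` — the
same g for both under `shared_gain`, complementary `2g` / `2(1−g)` under
`resource_tradeoff`. At the default cell parameters, s = 0.5 induces mean
|error| correlations of roughly +0.11 (shared gain) and −0.05 (trade-off);
the asymmetry comes from guessing trials diluting the trade-off signal.

What the simulator does *not* emulate: swap errors to non-probed items,
serial dependence across trials, response-time structure (RT columns are
placeholders), minimum angular separation between items (configurable but
off by default), and learning or fatigue across blocks. Passing tests
therefore establish correctness of the pipeline's computations and its
power/calibration under the stated mixture world, not the behaviour of any
specific observer population.

## Validation problem sizes

The test suite validates parameter recovery on 200 datasets of n = 500
(median |p̂_mem − p_mem| ≤ 0.05, median relative κ error ≤ 20%), bias-test
calibration on 1000 null cohorts of 24 subjects × 160 trials (rejection
rate 5% ± 1.5%) with sign recovery of a −5° repulsion in ≥ 95% of 300
cohorts, and coupling-sign recovery over 100 cohorts per regime (raw sign
of the cohort mean Fisher z for the coupled regimes; nominal type-I
behaviour for the independent regime — at these effect sizes a three-way
significance classifier cannot separate the trade-off regime from the null
at 95% reliability, so the sign and the calibration are tested as separate
claims). These sizes were chosen to estimate each rate with Monte-Carlo
error well inside the asserted margins.

## Known limitations

- The overlapping-bin recipe (nearest-quarter-of-trials per centre) is one
  reasonable reconstruction of sliding quantile binning; occupancy ties at
  exactly equal circular distances resolve by trial order.
- The mixture MLE is a point estimate; no uncertainty on `p_mem`/`κ` is
  propagated into the ANOVAs (matching standard practice in this
  literature).
- `exclude_participants` assumes ≥ 10 scoreable responses per subject and
  errors on fewer, rather than silently passing tiny sessions.
- The JZS Bayes factor covers one-sample/paired designs only.
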