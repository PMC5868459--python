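# retroprobe

Analysis toolkit for **double-probe retrocueing working-memory experiments**
— continuous-report tasks in which observers memorize four oriented bars,
receive a retrocue (or a neutral cue) during the delay, and then reproduce
the orientations of two sequentially probed items. The central questions
such designs ask: does prioritizing one item in memory *benefit* its recall,
does it *cost* the other items, and does the prioritized item *distort* the
recall of concurrently held items?

`retroprobe` implements the full analysis pipeline for this paradigm plus a
matched trial simulator, so every stage can be validated end to end on data
with known ground truth.

## What it computes

**Recall accuracy.** For each response the signed circular error
`e = wrap(response − target) ∈ (−π, π]` is computed; accuracy is the
reciprocal of the circular standard deviation, `1 / sqrt(−2 ln R̄)`, with
`R̄` the mean resultant length.

**Mixture model.** Errors are decomposed into memory and guessing by
maximum likelihood under

```
p(x) = p_mem · VonMises(x; 0, κ) + (1 − p_mem) / 2π
```

where `p_mem` is the probability of recalling the probed item and `κ` the
concentration (precision) of remembered responses.

**Recall bias curves.** Trials are binned by the relative orientation `Δ`
of the other probed item (64 overlapping bins, each holding the quarter of
trials nearest its centre); the mean signed error per bin forms a bias
curve. The **area-difference statistic** — mean bias over `Δ > 0` minus
mean over `Δ < 0` — is positive for attraction toward and negative for
repulsion away from the other item.

**Trial-wise trade-offs.** Pearson correlation of the two responses'
absolute errors across trials (negative values would indicate zero-sum
resource sharing), Fisher-transformed and tested at the group level.

**Inference.** One-sample/paired t tests with default JZS Bayes factors
(Cauchy(0, √2/2) prior on effect size, the `BayesFactor` R package
convention) and fully-within-subject repeated-measures ANOVA with partial
eta squared.

**Simulator.** Cohorts for the four supported designs (E1, E2, E2b, E3)
with per-cell recall rate, precision, injectable `β·sin(Δ)` response bias,
switchable trial-wise precision coupling (independent, shared gain,
resource trade-off) and between-subject variability — bit-reproducible from
a seed.

## Worked example

```python
from retroprobe import (DesignSpec, GenerativeParams, simulate_session,
                        response_table, fit_mixture, recall_accuracy)

session = simulate_session(DesignSpec.e1(), GenerativeParams(), seed=3)
table = response_table([session])
for role in ("cued", "neutral", "uncued"):
    cell = table[(table.role == role) & (table.response_index == 1)]
    fit = fit_mixture(cell["error"].to_numpy())
    print(role, fit.params.p_mem, fit.params.kappa)
```

prints (formatted):

```
cued     response 1: p_mem=0.822 kappa= 11.5 accuracy=1.34/rad (n=160)
neutral  response 1: p_mem=0.729 kappa= 12.3 accuracy=1.15/rad (n=160)
uncued   response 1: p_mem=0.645 kappa= 10.0 accuracy=0.98/rad (n=160)
```

The fitted recall rates recover the generative truth (0.85 / 0.75 / 0.65):
cueing raises the probability that the item is in a reportable state, while
precision `κ` is role-invariant. Running the bias analysis on the same
cohort (`examples/03_bias_curve.py`) recovers the injected −5° repulsion:

```
mean area difference: -5.39 deg
one-sample t(23) = -3.38, p = 0.0026, BF10 = 15.4
```

The `examples/` directory holds one short script per capability
(simulation, mixture fitting, bias curves, the full pipeline, Bayes-factor
conversion). A thin CLI wraps the same functions:

```
retroprobe simulate --experiment E1 --subjects 24 --seed 7 --out trials.csv
retroprobe analyze trials.csv --out results/
retroprobe fit-mixture trials.csv --role cued --response 1
```

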