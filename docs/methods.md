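# Methods

This note documents the models implemented in `dualcap`, the defaults they
ship with, and the numerical and design choices behind them.

## Task and data model

A trial presents two letter strings, top and bottom. On *single-task*
trials one side is pre-cued and only that side is judged; on *dual-task*
trials both sides are judged, in an externally recorded order
(`first_response_side`). Each judgment is a 4-point confidence rating
(1 = sure target-absent … 4 = sure target-present); a response is scored
correct when `rating >= 3` coincides with a target-present string.

Accuracy throughout is $A_g$, the area under the rating ROC, computed by
the trapezoid rule over cumulative hit and false-alarm rates
(`dualcap.sdt.ag`). $A_g$ is identical to the concordance
$P(R_{\text{present}} > R_{\text{absent}}) + \tfrac12 P(\text{tie})$; the
test suite verifies this equivalence exactly against a brute-force count.
Chance is 0.5. $A_g$ is undefined (and the code raises) when a condition
lacks either target-present or target-absent trials.

## Capacity models on the AOC plane

Let $A_t, A_b$ be single-task accuracies and put the dual-task point at
$(x, y) = (A_{b,\text{dual}}, A_{t,\text{dual}})$.

**Serial (all-or-none).** One side is processed per trial, the top side
with probability $p$. The predicted locus is the straight segment

$$\big((1-p)A_b + p/2,\ \ pA_t + (1-p)/2\big), \quad p \in [0,1].$$

**Fixed capacity (sample size).** Both sides are processed from a shared
pool of evidence samples split $w : 1-w$; accuracy maps through the
normal-integral transform

$$\big(\Phi(\sqrt{1-w}\,\Phi^{-1}(A_b)),\ \ \Phi(\sqrt{w}\,\Phi^{-1}(A_t))\big),
\quad w \in [0,1].$$

The two loci share endpoints exactly, and the fixed-capacity curve is
weakly outside the serial segment (a property-based test asserts this for
random anchors).

**Independent.** No cost: the single point $(A_b, A_t)$.

**Signed distance.** A subject's dual-task point is scored by its minimum
Euclidean distance to each locus, signed positive when the point lies
beyond the locus as seen from the chance point $(0.5, 0.5)$ (sign of
$(P - P^\*)\cdot(P^\* - C)$ for nearest point $P^\*$). The serial distance
uses the closed-form orthogonal projection onto a segment; the
fixed-capacity distance minimizes over $w$ with a 1001-point grid followed
by bounded scalar minimization (`xatol = 1e-9`). The serial parameter at
the nearest point is reported as $\hat p_{\text{top}}$.

Group inference tests the per-subject signed distances against zero with a
one-sample *t* test; a model is "rejected" when $p < 0.05$. Each test is
accompanied by a percentile bootstrap CI and a JZS Bayes factor.

## Synthetic observers

`simulate_observer` draws a Gaussian decision variable per processed side
($\mu = \pm d'/2$, unit variance) and converts it to a 4-point rating via
three criteria. Defaults, chosen to emulate a realistic study of this
kind:

- `dprime = 2Φ⁻¹(0.8) ≈ 1.683` per side — titrated so single-task
  proportion correct is 0.80, in the middle of the AOC plane where the
  three models are most separable (`dprime_for_pc` inverts this).
- `criteria = (−1, 0, 1)` in decision-variable units — symmetric,
  unbiased, and wide enough that all four ratings occur.
- `p_top = 0.74` — serial observers favor the top string, matching the
  upper-visual-field bias typical of reading tasks.
- `w_top = 0.5` — fixed-capacity observers split samples evenly.
- `fixation_break_rate = 0.16` — fraction of trials flagged for unstable
  fixation and later discarded.
- `selection_error_rate = 0.0` — probability of attending/reporting the
  wrong side (binding error). Positive values induce a congruency effect:
  errors only cost accuracy when the two sides' categories differ.
- Design: 60 blocks × 20 trials, arranged in sets of four (two dual, one
  single-top, one single-bottom), 84 ms inter-stimulus interval. Eleven
  subjects by default. These sizes are this package's own choice: large
  enough that the model-identification and parameter-recovery tests pass
  with wide margins, small enough that the full suite runs in about a
  minute.

**Guessing distribution (design decision).** On serial trials the
unprocessed side's rating must come from a guessing distribution. The
default (`guess_dist=None`) is the *matched* distribution
$G = (S + N)/2$, the observer's marginal rating distribution over
processed trials. This choice is not cosmetic: writing $C(\cdot,\cdot)$
for the concordance, $G = (S+N)/2$ satisfies
$C(S,G) + C(G,N) = C(S,N) + \tfrac12$ exactly, which makes the dual-task
$A_g$ *exactly linear* in the processing probability — i.e. the simulated
serial observer lies on the model's straight segment by construction
rather than approximately. A fixed guess distribution such as
$(0, \tfrac12, \tfrac12, 0)$ violates this identity and biases the
dual-task point a few hundredths of $A_g$ off the segment, enough to
spuriously reject the serial model at these sample sizes. Any explicit
4-tuple can still be supplied for sensitivity analyses.

The generator emulates: rating-scale responses, attention bias, shared
evidence pools, fixation breaks, selection errors, response order, and
block structure. It does not emulate: lapses/finger errors, learning or
fatigue across blocks, criterion drift, stimulus-specific difficulty, or
reaction times.

## Trade-off analysis

For each dual-task response, trials are partitioned by whether the *other*
side's response on the same trial was correct, and $A_g$ is computed in
each partition (both sides pooled; subjects with a degenerate partition
are flagged and excluded from the group test). Under serial processing the
two partitions differ strongly — if one side was processed, the other was
guessed — while under either parallel model they coincide. With
$p_{\text{top}} = 0.5$ and single-task proportion correct $PC$, the serial
model's binary-accuracy conditionals have the closed forms

$$P(\text{correct} \mid \text{other incorrect}) = \frac{1/4}{3/4 - PC/2},
\qquad
P(\text{correct} \mid \text{other correct}) = \frac{PC/2}{1/4 + PC/2},$$

which the tests verify by simulation ($PC = 0.8$ gives $5/7$ and $8/13$).
`serial_tradeoff_curve` traces the predicted difference as a function of
single-task accuracy; it vanishes toward chance and grows with task ease.

## Statistics

- **Bootstrap**: percentile CIs over 1000 resampled means by default;
  measured coverage of the 95% interval is ≈ 0.93 at $n = 11$ (the usual
  small-$n$ undercoverage of the percentile method).
- **JZS Bayes factor**: the one-sample default-prior Bayes factor with a
  zero-centered scaled-Cauchy prior on effect size, scale
  $r = \sqrt{2}/2$. The marginal likelihood integral over the prior's
  mixing variable $g$ is evaluated with adaptive quadrature
  (`scipy.integrate.quad`, `epsrel = 1e-10`); the code raises if the
  quadrature error estimate exceeds $10^{-4}$ relative. Values are
  cross-checked in the test suite against an independent implementation
  (pingouin) to 0.1%.
- **Repeated-measures interaction**: two-within-factor ANOVA via
  `statsmodels.AnovaRM`; the null distribution of the interaction *p*
  value is verified uniform by simulation.

## Exclusion rules

Fixation-break trials are dropped first. Blocks are then screened on
pooled single-task proportion correct: a block is *high* above 0.90, *low*
below 0.70, *neutral* if it has no single-task trials. Maximal runs of
four or more consecutive non-"ok" blocks containing at least one
non-neutral block, whose pooled single-task accuracy falls outside
[0.70, 0.90], are discarded — the interpretation being a sustained lapse
of compliance or a mis-set difficulty level, not trial-level noise.
Shorter or mixed runs are kept. The exclusion report records counts and
the discarded runs per subject.

## Limitations

- $A_g$ is a discrete 4-point-ROC area; the fixed-capacity locus assumes
  the normal-integral transform holds for it, which is exact for the
  underlying continuous variable and accurate to ≈ 0.001 for the
  discretized statistic at these parameters.
- The serial model's linearity guarantee holds for matched guessing; real
  observers may guess with a different distribution, shifting points
  slightly off the segment.
- The percentile bootstrap under-covers at small $n$; the *t*-based tests
  are primary.
- Signed distance treats both axes as exchangeable accuracy units; it does
  not weight by per-subject measurement error.
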