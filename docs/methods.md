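# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `searchshift`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Stimuli

A gamble is a single gain `x` (integer yuan, 1–99) with probability `p`
(integer percent, 1–98, stored as a fraction).  A stimulus pair is
non-dominated — exactly one option has the strictly larger outcome, the
other the strictly larger probability — and its two expected values differ
by at least 0.5 yuan.  The floor is ours: every trial is later coded
EV-consistent or not, and a floor keeps that coding numerically
unambiguous; pairs closer than 0.5 yuan in EV also carry almost no
information about φ.  Generation is rejection sampling (uniform integer
outcome, uniform integer percent, 10,000 attempts per pair before an error
signals infeasible constraints), so accepted pairs are exactly uniform on
the constrained set.  In `exp2` mode the higher-outcome option must also
have the strictly *lower* expected value, which makes expected-value
maximization and maximax disagree on every pair — the configuration that
makes the two strategies maximally discriminable from choices.  The riskier
option's screen position alternates (⌈n/2⌉/⌊n/2⌋ counterbalance).
Duplicate pairs are permitted by default (`unique=True` forbids them).

## 2. Strategy model and estimation

Choices follow the softmax `p(A,B) = e^{φV(A)}/(e^{φV(A)} + e^{φV(B)})`
with `V = x·p` (EV) or `V = x` (maximax).  The deviance of a block of `N`
choices is `G² = −2 Σ ln f_j(y)`, natural logarithm, with `f_j(y)` the
probability assigned to the observed choice.  All evaluation is in log
space via `ln p = −ln(1 + e^{−φ·ΔV})`, so nothing overflows even at
`φ·V ≈ 10 × 99`: the probability of an astronomically unlikely observed
choice contributes a large finite deviance rather than infinity.

φ is constrained to `[0, 10]`.  Valuations are at most 99 yuan, and φ = 10
already saturates the softmax for any non-trivial valuation gap, so larger
values are not identifiable; negative φ (anti-preference) is excluded.

**Penalized estimation.**  With saturating stimuli, a non-negligible
fraction of simulated blocks is perfectly separable (every choice on the
fitted strategy's side), where the raw MLE of φ is infinite and lands on
the search bound; the remaining blocks carry the usual O(1/N) upward bias
of logistic MLEs.  We therefore minimize the Firth-penalized deviance
`G²(φ) − ln I(φ)`, with `I(φ) = Σ ΔV_j² p_j(1−p_j)` the Fisher
information.  The penalty diverges as the softmax saturates, keeping the
estimate finite under separation, and removes the first-order bias; its
gradient vanishes at φ = 0, so flat-likelihood data still give φ̂ = 0.  The
reported `G²` is always the *unpenalized* deviance at φ̂, so every
deviance-based rule below is unaffected by the penalty.  In the calibration
run of `scripts/acceptance.py` (200 replicate blocks of 60 discriminating
pairs at φ_true = 0.5) the mean estimate is within a few thousandths of
the truth.

Optimization: a 50-point log-spaced grid on `[10⁻⁴, 10]` (plus φ = 0)
locates the basin, bounded Brent refinement (`xatol = 10⁻⁶`) polishes it;
candidates at φ = 0 and at the grid optimum guard against refinement
failures; exact ties resolve to the smaller φ.  The procedure is
deterministic given the data.

**Classification.**  A block is labelled with the lower-deviance strategy
unless (a) the two deviances tie within 10⁻⁹, or (b) the better one fails
to beat the random-choice baseline `2N·ln 2` by more than 2.0 — one AIC
unit per fitted parameter.  The margin matters: because φ is estimated, a
true guesser's fitted deviance falls below the baseline by a chance amount
(≈ χ²₁/2) almost always, so a bare comparison would label guessers as
strategy users; charging the fitted parameter its AIC cost restores the
intended behavior.  Classification is performed separately per task.

## 3. Search metrics

Areas of interest are the four information cells `A_PROB`, `A_OUT`,
`B_PROB`, `B_OUT`.  Fixations shorter than 50 ms (strict) are excluded.
Consecutive fixations on the same AOI merge before counting — a
re-fixation is not a transition and would otherwise inflate `N`.  Each
step between distinct AOIs is one transition: alternative-wise (same
option, different dimension), dimension-wise (same dimension, different
option), or diagonal (both change).  Diagonals count in `N` but in neither
`r_a` nor `r_d`, the standard treatment on an A×D board.

The Böckenholt–Hynan index is implemented in its canonical form

    SM = √N · [ (D·A/N)(r_a − r_d) − (D − A) ] / √(A²(D−1) + D²(A−1)),

which for A = D = 2 reduces to `√2 (r_a − r_d)/√N`: approximately standard
normal under direction-indifferent search, positive when alternative-wise
transitions predominate.  SM is computed per trial; trials whose filtered,
merged sequence has no transition get a missing SM and are excluded from
aggregation.  Participant-by-task means are also emitted, since analyses
differ in the aggregation level they want; the mediation model below uses
the per-trial values, which keeps the outcome and mediator at the same
unit and lets the cluster bootstrap carry the dependence.

## 4. Synthetic participants

The generator produces the statistical structure the analyses assume, so
every downstream stage is testable end to end.

* **Agents.**  A mixture of EV, maximax, and guessing agents (defaults
  0.90/0.05/0.05 — populations in this paradigm are overwhelmingly
  EV-driven on simple gambles).  φ is fixed (default 0.5, a mid-range
  sensitivity for yuan-scale valuations: typical discriminating pairs are
  chosen with probability ~0.9 but thin-margin pairs stay stochastic) or
  log-normal across participants; an optional per-task multiplier lets φ
  itself depend on task.
* **Search.**  A Markov walk over the four AOIs: each step is
  alternative-wise with the task's bias (defaults 0.9 under ALT, 0.1 under
  DIM — strong but imperfect task compliance), else dimension-wise; the
  walk never produces diagonal steps or same-AOI repeats.  Transitions per
  trial are `1 + Poisson(8)`, giving SM magnitudes of a few units per
  trial.  Durations are log-normal (median 250 ms, σ_log 0.4) truncated at
  60 ms, so the 50 ms filter is only exercised when `p_short_fixation`
  injects sub-50 ms fixations deliberately.
* **Search-choice coupling.**  With probability `search_coupling`
  (default 0.5) the valuation rule applied on a trial follows that trial's
  *realized* alternative-wise proportion (EV with probability π_alt, else
  maximax) instead of the agent's disposition.  This is what creates a
  genuine causal chain task → search direction → strategy → choice: with
  coupling 0, search and choice are independent given task, and the
  indirect effect through SM is null by construction — the configuration
  used for null-calibration tests.  Guessing agents ignore the coupling.
* **Decision time.**  `ln rt = baseline + task_effect·1[ALT] −
  ev_slope·|ΔEV| + N(0, σ)` with defaults baseline 1.5 log-s,
  task effect 0.16, ev slope 0.006 per yuan, σ 0.3 — an ~4 s dimension-wise
  baseline, a task slowdown and an EV-difference speedup of the size this
  paradigm reports.
* **Design.**  Every participant completes both tasks on the same stimulus
  set, task order alternating across participants.  One global seed;
  per-participant child streams are spawned deterministically, so output
  tables are byte-identical across runs.

The emulated effects are deliberately strong (e.g. the EV-label share
drops from ~90% under ALT to ~18% under DIM in the default run, and the
indirect effect is ~0.30 on the probability scale); the generator
demonstrates the machinery's ability to detect the structure, it is not a
calibrated model of any particular dataset.

## 5. Inference chain

* **Choice model.**  Logistic regression of EV-consistent choice on task
  (ALT = 1) with crossed random intercepts for participant and item,
  estimated by the Laplace (MAP) approximation
  (`statsmodels.BinomialBayesMixedGLM.fit_map`); the posterior mode and SD
  give b, `OR = e^b`, the 95% CI, z, and the two-sided p.  The MAP route
  was chosen over the variational one for its calibration: in a
  100-replicate null simulation its CI covered zero 94 times (the
  variational fit: 83).  statsmodels draws optimizer starting values from
  the global RandomState, which is pinned locally so fits are
  reproducible.  If the fit fails (or the response is constant —
  separation — which raises), a plain logistic with participant-clustered
  robust errors is returned with a `degraded` flag.
* **Decision-time model.**  `MixedLM` (REML) of log response time on task,
  |ΔEV| and |Δoutcome| with the same crossed intercepts via variance
  components; cluster-robust OLS fallback, flagged.  Agreement with an
  independent `lme4::lmer` fit on the same data is part of the test suite.
* **Two-proportion test.**  Pooled z with one-tailed p — the directional
  hypothesis is that the alternative-wise task yields more EV
  classification.  Equal proportions give z = 0, p = 0.5.
* **Mediation.**  Linear-probability path models fit by OLS on the pooled
  trials: `SM ~ task` gives a; `choice ~ task + SM` gives b and c′;
  `choice ~ task` gives c.  Fitting all paths by OLS on the same rows
  makes the decomposition `c = c′ + a·b` hold exactly, which mixed-model
  paths (different GLS weights per model) would not; the within-subject
  dependence is instead carried by the uncertainty estimate, a
  participant-level (cluster) percentile bootstrap of `a·b` (default
  5,000 resamples, seeded).  Under the null-chain configuration the
  bootstrap CI covered zero in 100/100 calibration replicates.  Fewer than
  3 participants raise an error rather than returning meaningless CIs.
* **Multiplicity.**  No multiple-testing correction is applied anywhere;
  each model answers one planned question.

## 6. Problem sizes and tolerances

Default study conditions: 50 participants × 2 tasks × 60 pairs (6,000
trials, ~60,000 fixations); the full pipeline runs in ~15 s on one CPU.
Calibration loops use 100–200 replicates at 12–20 participants and 400
bootstrap resamples, and the decision-time recovery check uses 30
replicates of 20 × 20 (mixed-model fits dominate its runtime).  Numerical
tolerances: φ optimization 10⁻⁶; deviance ties 10⁻⁹; softmax complement
identity exact in floating point (the negative branch is defined as
1 − positive branch); mediation decomposition asserted at 10⁻⁶.

## 7. Known limitations

* The generator's search process is a first-order Markov walk with no
  diagonal transitions, no drift over the trial, and no coupling between
  search length and decision difficulty; real gaze data have all three.
  The counting and SM code handle diagonals and re-fixations anyway, and
  are tested on arbitrary AOI sequences.
* Passing recovery and sign-pattern tests on these synthetic conditions
  shows the estimators and the causal-chain detection work when the
  assumed structure is present and strong; it does not validate the
  generative assumptions against human data, and effect magnitudes here
  should not be read as empirical predictions.
* The mediator enters the path models linearly; threshold or saturating
  mediation would be attenuated.
* The guessing label absorbs every non-EV, non-maximax process
  ("guessing *or other*"); a lexicographic or priority-type strategy would
  be misfiled rather than detected.
* Decision times are generated and modelled log-normally; heavy-tailed
  contamination (lapses) is not simulated and would affect the linear
  mixed model's estimates on real data.
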