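# Methods

## The behavioral model

One agent faces a two-armed bandit: two boxes, rewards of +10 or −10
points, 100 choices. The win probability of the right box is 0.7 on trials
1–30, 0.3 on 31–70, and 0.7 again on 71–100; the left box is complementary.
Outcomes are drawn independently per trial for the chosen box only — no
counterfactual feedback exists, and the two boxes' draws share no random
numbers.

The agent's seven traits and their roles:

| trait | support | role |
|---|---|---|
| β | ≥ 0 | softmax inverse temperature (exploitation vs exploration) |
| μ | ≥ 0 | utility curvature on gains (lower = more risk-taking in gains) |
| ν | ≥ 0 | utility curvature on losses |
| α+ | [0, 1] | learning rate for non-negative prediction errors |
| α− | [0, 1] | learning rate for negative prediction errors |
| λ | ≥ 0 | loss aversion (weight on losses relative to gains) |
| φ | ℝ | additive choice-autocorrelation control in the value update |

Both action values start at Q = 0, so the first prediction error equals the
first utility. A prediction error of exactly zero takes the α+ branch. A
reward of exactly zero maps to utility zero (the continuity limit of both
branches). φ is applied inside the chosen option's value update on every
trial, regardless of the error's sign, exactly as the update is written
above; the common alternative — a perseveration bonus inside the softmax —
is deliberately not what this model is.

**The φ drift pathology.** Because φ is added to the chosen value on every
update, any non-zero φ makes the chosen box's value drift roughly linearly
in time. Over a 100-trial session with |φ| ≈ 1 the drift (~tens of points)
already rivals the utilities (~±3 points at cohort-mean curvature); over
1,000 trials it saturates the softmax entirely. The model is implemented as
specified, and the consequences for estimation are documented below rather
than patched away.

## Simulation and seeding

Choice sampling uses inverse CDF on the softmax probability of the right
box. Every session seed is split (numpy `SeedSequence.spawn`) into a choice
substream and a reward substream whose per-trial uniforms are generated up
front, so probing one stream never perturbs later trials. Cohorts split one
root seed into independent substreams for trait draws, per-subject
sessions, task order, outcome draws, and exclusion flags. Everything is
bit-reproducible under a fixed root seed; the full-study manifest records
SHA-256 checksums of all written tables so re-runs can be verified.

The likelihood and simulation inner loops are numba-jitted; the softmax is
computed via log-sum-exp so per-trial log probabilities stay finite (if
astronomically negative) far from the optimum, which keeps the MAP search
landscape smooth.

## MAP estimation

The per-subject objective is log p(D|θ) + log p(θ) with priors Beta(2,2) on
α±, Gamma(shape 2, scale 3) on β, μ, ν, λ, and N(0,1) on φ. The optimizer
(L-BFGS-B) searches transformed coordinates — log for the positive traits,
logit for the learning rates, identity for φ — purely as a device to respect
supports; no Jacobian is added, so the optimum is the MAP of the stated
natural-space posterior. Ten restarts are drawn from the priors; the best
final log posterior wins, ties to the first found. Convergence tolerance is
1e−6 on the objective with at most 2,000 evaluations per start. φ is
searched within ±50 (configurable) to contain the drift pathology, and the
log/logit coordinates are boxed generously ([−10, 5] and ±15); any fit whose
optimum touches a box is flagged, never dropped. Sessions shorter than two
trials are rejected as carrying no sequential information; in cohort fitting
such subjects come back flagged rather than aborting the batch.

**What is and is not identified.** Scaling the utility by a constant c
(μ → μ + log10 c, with λ absorbing the loss side) while dividing β by c
leaves the choice likelihood exactly invariant when φ = 0, since Q scales
linearly and only β·Q enters the softmax. The data therefore pin the product
of β with the utility scale; β alone is identified only through the priors.
Consequences, measured by the package's own recovery machinery:

- the learning rates recover well and sharpen with session length
  (their median error falls severalfold from 100 to 1,600 trials);
- β's error does not vanish with more data — it has a prior-set floor — and
  when μ, ν, λ vary freely across simulated agents, β's true-vs-estimated
  correlation plateaus in the 0.5–0.65 range no matter the optimizer.

The default recovery design (`recovery_study(vary="targets")`) therefore
varies the traits it evaluates — β, α+, α− — across agents according to the
cohort distributions and holds μ, ν, λ, φ at their population means, the
classical fixed-nuisance design that measures estimator quality rather than
the ridge. The fully heterogeneous design remains available as
`vary="all"`, with the caveat above. Relatedly, an unconstrained MAP under
these priors pulls μ, ν, λ estimates toward the Gamma mode (3) — cohort
moments of fitted curvature parameters should not be expected to match the
generating ones.

## The synthetic cohort

The generator emulates the study design end to end: 364 enrolled subjects;
7 flagged as not completing all tests and 32 as having prior task
experience (flags assigned uniformly at random, independent of traits — a
simplification; real dropout may be informative); 325 retained. Latent
traits are drawn from truncated normals matching the analyzed cohort's
sample moments (β: 0.85 ± 1.06 on [0, ∞); μ: 0.48 ± 0.28; ν: 0.52 ± 0.30;
λ: 0.51 ± 0.28; α+: 0.42 ± 0.27 and α−: 0.59 ± 0.29 on [0, 1]). φ is drawn
from its N(0, 1) prior rather than from its fitted sample moments
(−12.6 ± 213.9), which reflect the drift pathology rather than a plausible
trait distribution and would make simulated behavior degenerate.

Each subject plays one simulated 100-trial session; bandit performance is
the raw reward sum. Task order is Bernoulli(0.5). Insight outcomes are
generated at the level the analysis consumes — binary success through a
probit link on the traits and bandit performance — never by simulating
puzzle solving. Default link coefficients are the transfer-adjusted point
estimates of the regression stage (e.g. +0.59 on the other task's success,
−0.69 on α− for the 8-coin task, −0.63 on λ for the 9-dot task), entered
unstandardized. Two transfer structures exist: `by_order` (default; the
second-administered task's link adds the transfer term times the first
task's realized outcome, mirroring the study design) and `directional`
(9-dot from traits alone, 8-coin always with the transfer term), which
makes the full-sample 8-coin regression correctly specified and is what
coefficient-recovery tests use. True traits drive outcomes by default,
reproducing the study's errors-in-variables structure; a config switch
generates from MAP-estimated traits instead for oracle tests.

Simulated agents at these trait distributions earn well above chance
(mean ≈ +140 points), unlike the near-chance human cohort (−0.7 ± 10.7);
with the −0.01 performance coefficient in the 9-dot link this lowers the
synthetic base rates (≈0.16 / 0.28) relative to the study's (0.31 / 0.70).
The generator emulates the design and effect structure, not those marginal
rates; intercepts are config-exposed where a test needs specific base rates.

## Regression stage

Probit fits are maximum likelihood with intercept (statsmodels), SEs from
the observed information, AIC = 2k − 2·loglik. Four full-sample
specifications: each task's success on the seven traits plus bandit
performance, with and without the other task's success; the same four
restricted to subjects who faced the modeled task second. Degenerate
outcomes and perfect separation return flagged results; rank-deficient
designs raise, naming the collinear columns. Non-converged subject fits are
dropped listwise with a logged count. First- versus second-administration
success rates are compared by a 2×2 Pearson chi-square without continuity
correction (1 df). Descriptives use sample SDs (n−1) and pairwise Pearson
correlations; significance stars are *** p<0.01, ** p<0.05, * p<0.1.
Regressors enter unstandardized by default.

## Problem sizes used by the checks

Test and acceptance runs are sized to finish on one CPU in minutes:
parameter recovery uses 50 agents at 1,000 trials (10 restarts);
estimator-consistency uses 40 agents at each of 100/400/1,600 trials (5
restarts); probit coefficient recovery uses a 50,000-subject cohort;
type-I-error and pipeline-power checks use 60 and 10 replicate cohorts at
the study's size. The schedule for sessions longer than 100 trials keeps
the same reversal logic with a reversal every 40 trials.

## Known limitations

- The additive-φ update is implemented as printed; its drift makes long
  sessions saturate and φ's fitted scale hard to interpret.
- β is prior-identified whenever the utility curvature varies freely (the
  scale ridge above); β-dependent conclusions should lean on the learning
  rates or on designs that pin the utility scale.
- The generator's exclusions are non-informative, insight outcomes are
  binary only (no solution times, no 30-minute-limit modeling), and the
  puzzles themselves are not simulated — so passing tests certify the
  estimation and inference machinery, not any claim about human behavior.
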