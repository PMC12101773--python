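# Methods

## The task

The suits task is a three-goal token-collection game. Each of three suits
(*cat*, *hat*, *car*) owns a bank of slots; a suit is completed — and pays a
fixed 10 points — when its bank holds `T_g` tokens, after which the bank
empties. Every round the player flips one of three cards (one per suit; each
suit maps to two interchangeable cards) and receives a suit-congruent token
with the probability the current block assigns to that suit. Cross-suit
tokens never occur, and progress on unfinished suits is retained
indefinitely, so nothing is sunk by switching goals.

Games are built from 30-round blocks. Within a block one suit is *dominant*
(highest token probability) and the other two share an equal, inferior
probability; the dominant suit always changes across adjacent blocks, which
manufactures conflicts between a suit's accrued progress and its current
rate of progress. Every third round the player reports the suit currently
being pursued (the goal probe).

Configurations implemented:

| experiment | blocks | block types (dominant-inferior %) | targets |
|---|---|---|---|
| exp1 | 18 × 30 rounds | 80-20, 70-30, 60-40 (6 each) | 7, 7, 7 |
| exp2 | 12 × 30 rounds | 75-25, 55-45 (6 each) | 7, 7, 7 |
| exp3 | identical to exp1 (the original manipulation was purely instructional) | | |
| exp4 | 12 × 30 rounds | H disp, L disp (6 each) | 4, 6, 8 |

Experiment 4 states block conditions in expected rounds-to-completion:
the dominant suit completes in 8 rounds on average, the inferior suits in
15 (H disp) or 12 (L disp). Token probabilities follow from the
negative-binomial mean identity `p_g = T_g / E[rounds]`; for the
car-dominant block this gives `p = 8/8 = 1` exactly, which is kept as a
valid (deterministic) Bernoulli rate. The number of exp4 blocks is a
package choice (12, matching the exp2 session length) with the dominant
suit counterbalanced twice per suit within each disparity condition.

Block-type order and the dominant-suit sequence are drawn by rejection
sampling under the schedule seed until both constraints hold: no two
adjacent blocks share a dominant suit, and within every block type each
suit is dominant equally often. Cards are dealt uniformly (one of the two
cards per suit each round) and carry no value of their own.

## Valuation models

All agents assign a value `Q_g` to each suit and share one selection policy
(below). Learning updates apply only to the suit whose card was flipped;
unchosen suits' internal states are frozen, since their outcomes are
unobserved.

**Prospective.** A belief `M_g` about each suit's token probability follows
the delta rule `M ← M + α(I − M)`. The suit's value is a discounted
rollout over future outcomes computed by dynamic programming,

    Q(s, h) = M γ Q(s+1, h−1) + (1 − M) γ Q(s, h−1),
    Q(T, ·) = 1,   Q(·, 0) = 0,

truncated at a horizon of 20 steps. The terminal reward is normalized to 1
for every suit (temperatures absorb the scale; all suits pay equally in
every experiment). Variants: hyperbolic discounting (delay estimated as
`D = (T−s)/max(M, 1e−3)` and value `1/(1+kD)`) and asymmetric learning
rates (`α_pos`/`α_neg` by the sign of the prediction error).

**Retrospective.** `Q = γ^(T−s)` — pure proximity to the target, no beliefs.

**TD-momentum.** Goal value is *momentum*: fractional progress
`m = s/T` times a learned speed-of-progress `v`, plus a per-suit bias,
`Q = v·m + b`. Speed and bias follow gradient descent on the one-step TD
error

    δ = γ(v·m' + b) − (v·m + b),   v ← v + αδm,   b ← b + αδ,

with the fixed initialization `v = 0.5`, `b = 0.1`. A round of unit
progress η raises the value iff `γ(m+η) ≥ m`; stalling always lowers it
when `γ < 1`. On suit completion the update is applied with `m' = 1`, then
progress resets while `v` and `b` persist.

**TD-persistence.** `Q_g = M_g` (the delta-rule belief itself); persistence
comes entirely from the policy layer. **Hybrid.** `w·Q_pros +
(1−w)·Q_retro` with a free weight. **RW + choice kernel.** A trial-level
Rescorla-Wagner value of token receipt with its own choice kernel and a
single softmax `P(g) ∝ exp(βQ_g + β_ck c_g)`; no goal/action hierarchy.

Free parameters as fitted: TD-persistence 5; TD-momentum and prospective 6;
hybrid 7. Belief initialization is `M = 1/3` (uninformative).

## Goal and action selection

Goal choice is a stay/switch decision on the current goal `G` with
advantage `A_G = Q_G − max_{g≠G} Q_g`:

    p_stay = 1 / (1 + exp(−c − c_G − β_g A_G)),

where `c` is a switch cost (bonus when positive) and `c_G` the goal's
choice kernel. On a switch the new goal is drawn by a softmax at `β_g` over
the two alternatives; the first round of a game uses a plain softmax over
all three values. Actions then either follow the goal (same logistic with
temperature `β_a`) or explore one of the other suits (softmax at `β_a`),
so card choices can diverge from the reported goal. Kernels follow the
delta rule `c_g ← c_g + α_c(I_g − c_g)` for all three suits toward the
indicator of the chosen goal. (A published variant of the kernel update
that multiplies by the kernel itself cannot increment from zero and
contradicts its own verbal description; the delta rule is used throughout.)

## Likelihood with a latent goal

Between probes the pursued goal is unobserved. The likelihood runs a
forward pass per round: the goal belief is propagated through the policy's
3×3 stay/switch transition matrix (propagation only — the printed
recursion does not condition on observed actions; a Bayes-filtered variant
is available behind `filtered=True` for sensitivity analyses), each round
contributes the marginal action likelihood `P(a) = Σ_g P(a|g) P(g)`, probe
rounds contribute `P(g = reported)` and then collapse the belief to a
point mass on the report (probes are treated as noiseless). "Undecided"
probes contribute no term and leave the belief unchanged. The RW model
scores actions only. Likelihood terms are floored at 1e−12, which matters
only in pathological parameter corners.

During fitting the chosen goal is latent, so the choice kernel is updated
with the expected indicator (the current posterior belief); in simulation
the sampled goal's hard indicator is used. The two coincide on probe
rounds and whenever `α_c = 0`.

Model comparison uses `AIC = 2k + 2·NLL`, `BIC = k ln n + 2·NLL` with `n`
the number of likelihood terms (actions + scored probes), and block-wise
3-fold cross-validation: blocks are partitioned at random, the model is
fitted on two thirds with the valuation state always re-run from the game
start, and the held-out third's NLL is summed; the metric is the mean over
repeats (30 by default).

Maximum likelihood uses a seeded global derivative-free search: uniform
random multi-starts over each model's parameter box followed by bounded
Powell refinement of the best start. The box mirrors the recovery ranges:
`α, α_c ∈ [0,1]`, `c ∈ [−1,1]`, `β_g, β_a ∈ [0,10]`, `γ ∈ [0.6,1]` (below
0.6 the discount is poorly identified), `w, k ∈ [0,1]`.

## Synthetic participants

Cohorts replace the undeposited human data. Per-participant seeds derive
deterministically from a master seed; each agent gets its own freshly
randomized block schedule. Two sampling boxes are defined once:

- `RECOVERY_RANGES` — the uniform recovery box above, used for parameter
  recovery.
- `HUMAN_PLAUSIBLE_RANGES` — engaged, human-like play: `β_g, β_a ∈ [2,8]`
  (value-sensitive but noisy), `c ∈ [0,1]` (a stay bonus; humans
  persist), `α ∈ [0.1,0.9]`, `α_c ∈ [0,0.5]`, and `γ ∈ [0.9,1.0]`, the
  range individual fits concentrate in.

Synthetic probes always name the agent's current goal; "undecided" is
representable in the data format but never generated (no generative account
of it exists). What the generator does *not* emulate: reaction times,
within-session drift in engagement, idiosyncratic biases such as the
preference for extreme target lengths discussed for experiment 4, and probe
noise in disengaged players. Tests passing on these cohorts therefore show
internal consistency of the models and pipeline, not fidelity to any
particular human sample.

## Recovery studies

*Parameter recovery* draws vectors from the recovery box, simulates one
exp1-scale game per vector, refits the generating model, and correlates
fitted against true values. At 100 TD-momentum vectors the temperatures,
switch cost and learning rate recover with r > 0.8; the kernel rate
recovers poorly (it is weakly expressed when the goal advantage dominates),
and the discount recovers only within [0.6, 1.0].

*Model recovery* simulates 20 vectors from each of the four fitted models
and tabulates BIC winners. Its generating box (`MODEL_RECOVERY_RANGES`) is
the recovery box with engagement floors (`β ≥ 1`, `α ≥ 0.1` — noise agents
identify no generator) and the hybrid weight in [0.1, 0.7]: as `w → 1` the
hybrid coincides with the prospective agent exactly (and at `γ → 1` its
retrospective component is constant), a structurally non-recoverable
regime; fitted human behavior is strongly retrospectively weighted, so the
informative range is the faithful one. The confusion matrix is
diagonal-dominant with the residual confusion concentrated between the
prospective and hybrid agents, as expected from their nesting.

## Task-optimized benchmark and the optimal discount

`optimize_performance` tunes an agent for mean suits completed over
simulated games, scoring every candidate on common random numbers (shared
game seeds), with random search plus bounded Powell refinement. For
models with a discount, a final profile scan evaluates a 0.01-grid of γ at
larger n and reports the vertex of a local quadratic fit around the grid
argmax — a noise-robust estimate of the peak of a shallow stochastic
profile.

The benchmark prospective agent is evaluated *task-informed*
(`true_beliefs=True`): its beliefs are pinned to the true block
probabilities each round, as in the round-classification analyses. This
choice matters: with a learned belief the performance surface is a flat
ridge trading the learning rate against the discount, and the optimal γ is
unidentifiable; with true beliefs the profile has a clear interior peak.
Measured this way the optimal discount is ≈ 0.95 on experiment 1 and
≈ 0.93-0.95 on experiment 2 — discounting steeply enough to favor finishing
near-complete suits, but not so steeply that the dominant suit's faster
rate is ignored.

Round classification uses the same device: the *prospective suit* is the
greedy argmax of rollout values under true-probability beliefs (γ = 0.95
by default), ties broken toward the dominant suit; the *retrospective
suit* is the unique max-progress suit (ties excluded from conflict
analyses). Progress differences are fractional (`s/T`), so experiment 4 is
comparable.

## Normative simulations

Drifting environments start the three suit probabilities at U(0.2,0.3),
U(0.2,0.3), U(0.7,0.8) (assigned to suits at random) and either perturb
them every round by Gaussian steps (interpreted as SD 0.025, clipped to
(0.001, 0.999)) or shuffle them among suits every 30 rounds. For each
environment the TD-momentum and prospective agents are optimized
independently and their mean scores compared. Reduced default scale: 20
environments per kind, 150 rounds, 30 candidates × 8 games per
optimization. Reversals reproduce the expected prospection advantage
(≈ 2 suits); random walks leave a much smaller gap (≈ 0.3).

## Numerical choices and degenerate inputs

- The rollout DP is memoized on the belief rounded to 4 decimals (moves Q
  by < 1e−3, far below policy sensitivity); the cache is bounded.
- Logistics and softmaxes are computed overflow-safe; `β = 0` gives exact
  uniformity.
- A token count reaching the target resets within the same round, so
  recorded slot states always satisfy `0 ≤ s < T`.
- Tied max-progress suits yield no retrospective label (−1) and are
  excluded from conflict analyses; prospective-value ties go to the
  dominant suit.
- The hyperbolic delay floors the belief at 1e−3 so the value tends to 0
  rather than diverging as `M → 0`.

## Known limitations

- Unchosen goals' values are frozen between selections; the generic TD
  formulation could allow passive decay, but the source formulation's
  worked examples concern only the pursued goal, and this package follows
  them.
- Whether speed `v` should reset on suit completion is untested; `v` and
  `b` persist here (only progress resets), consistent with the bias term's
  stated purpose of carrying value across completions.
- The between-probe belief is propagated without conditioning on actions,
  exactly as the fitting equations are printed; the Bayes-filtered variant
  changes per-round terms but was not systematically compared.
- The long-run stationary distribution of `v` is *not* monotone in the
  progress probability (it collapses toward zero); the documented
  monotonicity holds in the transient, block-length regime from the fixed
  initialization, which is the regime the task occupies.
- Cross-validation re-fits with the valuation state run from the game
  start; a per-block restart variant was not implemented.
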