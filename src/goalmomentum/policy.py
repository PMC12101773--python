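"""Hierarchical goal-then-action selection shared by all agents.

Goal selection is a stay/switch decision on the current goal: the agent
stays with probability

    p_stay = 1 / (1 + exp(−c − c_G − β·A_G)),   A_G = Q_G − max_{g≠G} Q_g

where c is the switching cost, c_G the current goal's choice kernel, and β
a softmax temperature.  On a switch the new goal is sampled by a softmax at
temperature β_goal over the two alternatives.  The same logistic with a
separate temperature β_action then decides whether the *action* (card flip)
follows the goal or explores one of the other suits, so actions can diverge
from the reported goal.  The choice kernel of every suit follows the delta
rule c_g ← c_g + α_c(I_g − c_g) toward the indicator of the chosen goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .task_env import N_SUITS
from .valuation import ModelParams


@dataclass
class PolicyState:
    current_goal: int | None = None
    kernels: np.ndarray = field(default_factory=lambda: np.zeros(N_SUITS))


def advantage(values, current_goal: int) -> float:
    """A_G = Q_G − max over the other suits."""
    if current_goal is None:
        raise ValueError("current_goal is unset")
    return values[current_goal] - max(v for g, v in enumerate(values)
                                      if g != current_goal)


def p_stay(A: float, c: float, c_G: float, beta: float) -> float:
    """Logistic stay probability; serves both the goal and action levels."""
    x = c + c_G + beta * A
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def softmax_pair(q1: float, q2: float, beta: float) -> tuple[float, float]:
    """Two-way softmax, overflow-safe; β = 0 gives the uniform split."""
    x = beta * (q1 - q2)
    if x >= 0:
        e = math.exp(-x)
        p1 = 1.0 / (1.0 + e)
    else:
        e = math.exp(x)
        p1 = e / (1.0 + e)
    return p1, 1.0 - p1


def softmax(values, beta: float) -> np.ndarray:
    z = beta * np.asarray(values, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def goal_probabilities(state: PolicyState, values, params: ModelParams) -> np.ndarray:
    """Implied distribution of the next goal given the current one.

    With a current goal G: p_stay on G and (1−p_stay)·softmax over the two
    alternatives.  At game start (no current goal) a plain softmax at
    temperature β_goal over all three values.
    """
    if state.current_goal is None:
        return softmax(values, params.beta_goal)
    g = state.current_goal
    A = advantage(values, g)
    ps = p_stay(A, params.switch_cost, state.kernels[g], params.beta_goal)
    alts = [h for h in range(N_SUITS) if h != g]
    pa = softmax_pair(values[alts[0]], values[alts[1]], params.beta_goal)
    out = np.empty(N_SUITS)
    out[g] = ps
    out[alts[0]] = (1.0 - ps) * pa[0]
    out[alts[1]] = (1.0 - ps) * pa[1]
    return out


def choose_goal(state: PolicyState, values, params: ModelParams,
                rng: np.random.Generator) -> int:
    """Sample the round's goal (stay/switch, then softmax re-selection)."""
    probs = goal_probabilities(state, values, params)
    return int(rng.choice(N_SUITS, p=probs))


def action_probabilities(values, goal: int, kernel_g: float,
                         params: ModelParams) -> np.ndarray:
    """P(action = a | goal), a stay/explore logistic at temperature β_action.

    The stay decision uses the goal-value advantage A_G of the current goal;
    exploration is a softmax at β_action over the two non-goal suits.
    """
    A = advantage(values, goal)
    ps = p_stay(A, params.switch_cost, kernel_g, params.beta_action)
    alts = [h for h in range(N_SUITS) if h != goal]
    pa = softmax_pair(values[alts[0]], values[alts[1]], params.beta_action)
    out = np.empty(N_SUITS)
    out[goal] = ps
    out[alts[0]] = (1.0 - ps) * pa[0]
    out[alts[1]] = (1.0 - ps) * pa[1]
    return out


def choose_action(state: PolicyState, values, goal: int, params: ModelParams,
                  rng: np.random.Generator) -> int:
    """Sample the suit whose card is flipped this round."""
    probs = action_probabilities(values, goal, float(state.kernels[goal]), params)
    return int(rng.choice(N_SUITS, p=probs))


def update_kernel(kernels: np.ndarray, chosen_goal: int,
                  alpha_ck: float) -> np.ndarray:
    """Delta-rule kernel update: increment the chosen goal, decay the rest."""
    if not 0.0 <= alpha_ck <= 1.0:
        raise ValueError("alpha_ck must be in [0, 1]")
    for g in range(N_SUITS):
        kernels[g] += alpha_ck * ((1.0 if g == chosen_goal else 0.0) - kernels[g])
    return kernels
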