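"""Goal-valuation models.

Every agent assigns a scalar value Q_g to each of the three suits and feeds
those values to the shared selection policy (:mod:`goalmomentum.policy`).
The models differ only in how Q_g is computed and learned:

``prospective``
    A belief-based rollout agent.  It tracks the token probability M_g of
    each suit with a delta rule and values a suit by a discounted dynamic
    programme over future token outcomes, truncated at a 20-step horizon:
    Q(s) = M γ Q(s+1) + (1−M) γ Q(s), with Q(target) = reward.
``retrospective``
    Values proximity to the target only: Q = γ^(T−s) · reward.
``momentum``
    TD-momentum.  Goal value is momentum — fractional progress m times a
    learned speed-of-progress v, plus a per-suit bias b: Q = v·m + b.  v and
    b follow gradient descent on the one-step TD error
    δ = γ Q(m') − Q(m), i.e. v ← v + αδm, b ← b + αδ.
``td_persistence``
    Q_g is the belief M_g itself; persistence comes from the policy layer.
``hybrid``
    Convex mixture w·Q_prospective + (1−w)·Q_retrospective.
``rw_ck``
    Trial-based Rescorla-Wagner value of token receipt plus a choice
    kernel, selecting goals by a single softmax (no stay/switch stage).

Two perturbed-prospection variants are included: hyperbolic discounting
(``prospective_hyperbolic``) and asymmetric learning rates
(``prospective_asym``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_env import N_SUITS

HORIZON = 20        # rollout truncation of the prospective dynamic programme
REWARD = 1.0        # terminal reward; softmax temperatures absorb the scale
V_INIT = 0.5        # fixed initialization of the momentum speed term
B_INIT = 0.1        # fixed initialization of the momentum bias term
M_INIT = 1.0 / 3.0  # uninformative initial belief about token probability

#: ordered free parameters and their search/fitting box, per model.
PARAM_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "momentum": {
        "alpha": (0.0, 1.0), "gamma": (0.6, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
    "prospective": {
        "alpha": (0.0, 1.0), "gamma": (0.6, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
    "hybrid": {
        "alpha": (0.0, 1.0), "gamma": (0.6, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
        "w": (0.0, 1.0),
    },
    "td_persistence": {
        "alpha": (0.0, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
    "retrospective": {
        "gamma": (0.6, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
    "rw_ck": {
        "alpha": (0.0, 1.0), "alpha_ck": (0.0, 1.0),
        "beta": (0.0, 10.0), "beta_ck": (0.0, 10.0),
    },
    "prospective_hyperbolic": {
        "alpha": (0.0, 1.0), "k": (0.0, 1.0), "switch_cost": (-1.0, 1.0),
        "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
    "prospective_asym": {
        "alpha_pos": (0.0, 1.0), "alpha_neg": (0.0, 1.0), "gamma": (0.6, 1.0),
        "switch_cost": (-1.0, 1.0), "beta_goal": (0.0, 10.0),
        "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    },
}

MODEL_IDS = tuple(PARAM_SPECS)
#: the four models fitted and compared against each other
FITTED_MODELS = ("momentum", "prospective", "hybrid", "td_persistence")


@dataclass
class ModelParams:
    """Free parameters of one agent; unused fields are ignored by the model."""

    model_id: str
    alpha: float = 0.3
    gamma: float = 0.95
    switch_cost: float = 0.0
    beta_goal: float = 5.0
    beta_action: float = 5.0
    alpha_ck: float = 0.0
    w: float = 0.5
    k: float = 0.1
    alpha_pos: float = 0.3
    alpha_neg: float = 0.3
    beta: float = 5.0
    beta_ck: float = 0.0

    def __post_init__(self):
        if self.model_id not in PARAM_SPECS:
            raise ValueError(f"unknown model_id {self.model_id!r}")

    @property
    def n_free(self) -> int:
        """Number of free parameters as fitted."""
        return len(PARAM_SPECS[self.model_id])

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_SPECS[self.model_id]])

    @classmethod
    def from_vector(cls, model_id: str, vec) -> "ModelParams":
        return cls(model_id, **dict(zip(PARAM_SPECS[model_id], map(float, vec))))

    def to_dict(self) -> dict:
        return {"model_id": self.model_id,
                **{n: getattr(self, n) for n in PARAM_SPECS[self.model_id]}}


def n_free_params(model_id: str) -> int:
    return len(PARAM_SPECS[model_id])


# ---------------------------------------------------------------------------
# elementary value computations
# ---------------------------------------------------------------------------

def belief_update(M: float, token: int, alpha: float,
                  alpha_neg: float | None = None) -> float:
    """Delta-rule update of the token-probability belief of the chosen suit.

    M' = M + α (I − M).  If ``alpha_neg`` is given, ``alpha`` is used for
    positive prediction errors and ``alpha_neg`` for negative ones
    (asymmetric-learning-rate variant).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    err = token - M
    a = alpha if (alpha_neg is None or err > 0) else alpha_neg
    return M + a * err


def prospective_values_vector(M: float, T: int, gamma: float,
                              horizon: int = HORIZON,
                              reward: float = REWARD) -> np.ndarray:
    """Q(s) for every token count s = 0..T, by dynamic programming.

    Boundary conditions: Q(T, ·) = reward and Q(s, horizon 0) = 0; interior
    Q(s, h) = M γ Q(s+1, h−1) + (1−M) γ Q(s, h−1).
    """
    q = np.zeros(T + 1)
    q[T] = reward
    gM = gamma * M
    gN = gamma * (1.0 - M)
    for _ in range(horizon):
        q[:T] = gM * q[1:] + gN * q[:T]
    return q


def prospective_value(M: float, s: int, T: int, gamma: float,
                      horizon: int = HORIZON, reward: float = REWARD) -> float:
    """Discounted rollout value of a suit with s of T tokens collected."""
    if not 0 <= s <= T:
        raise ValueError("token count s must satisfy 0 <= s <= T")
    return float(prospective_values_vector(M, T, gamma, horizon, reward)[s])


def prospective_value_closed_form(M: float, s: int, T: int, gamma: float,
                                  reward: float = REWARD) -> float:
    """Infinite-horizon limit: Q = [Mγ / (1 − (1−M)γ)]^(T−s) · reward."""
    if M == 0.0 and gamma == 1.0:
        return 0.0 if s < T else reward
    return (M * gamma / (1.0 - (1.0 - M) * gamma)) ** (T - s) * reward


def retrospective_value(s: int, T: int, gamma: float,
                        reward: float = REWARD) -> float:
    """Q = γ^(T−s) · reward — proximity to the target, no belief."""
    return gamma ** (T - s) * reward


def momentum_value(v: float, m: float, b: float) -> float:
    """Goal momentum: speed of progress times fractional progress, plus bias."""
    return v * m + b


def momentum_sign_condition(m: float, eta: float, gamma: float) -> bool:
    """Whether unit progress m → m+η yields a non-negative TD error.

    For a bias-free momentum state, δ = v(γ(m+η) − m), so δ ≥ 0 iff
    γ(m+η) ≥ m (equivalently γ ≥ m/(m+η); the boundary gives δ = 0 exactly).
    """
    if m < 0 or eta <= 0:
        raise ValueError("require m >= 0 and eta > 0")
    return gamma * (m + eta) >= m


def td_persistence_value(M: float) -> float:
    """Goal value equals the token-probability belief."""
    return M


def hybrid_value(q_pros: float, q_retro: float, w: float) -> float:
    """Convex combination of prospective and retrospective values."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    return w * q_pros + (1.0 - w) * q_retro


# Memoized prospective DP, keyed on the belief rounded to 4 decimals (a
# perturbation of < 1e-4 in M moves Q by < 1e-3, far below the policy's
# sensitivity).  Bounded so long fitting sessions cannot grow it unboundedly.
_PROS_CACHE: dict[tuple, tuple] = {}
_PROS_CACHE_MAX = 300_000


def _pros_q_cached(M: float, T: int, gamma: float, horizon: int) -> tuple:
    key = (int(M * 10000.0 + 0.5), T, gamma, horizon)
    q = _PROS_CACHE.get(key)
    if q is None:
        if len(_PROS_CACHE) >= _PROS_CACHE_MAX:
            _PROS_CACHE.clear()
        # plain-Python DP: the arrays are tiny (T+1 <= 9) and this sits in
        # the innermost loop of likelihood evaluation
        Mr = key[0] * 1e-4
        gM = gamma * Mr
        gN = gamma * (1.0 - Mr)
        qv = [0.0] * T + [REWARD]
        for _ in range(horizon):
            # ascending in-place is exact: qv[s+1] is still the previous
            # horizon's value when qv[s] is written
            for s in range(T):
                qv[s] = gM * qv[s + 1] + gN * qv[s]
        q = tuple(qv)
        _PROS_CACHE[key] = q
    return q


_HYP_M_FLOOR = 1e-3


def hyperbolic_prospective_value(M: float, s: int, T: int, k: float,
                                 reward: float = REWARD) -> float:
    """Hyperbolic discounting of the expected delay to completion.

    The expected delay is estimated as D = (T−s)/M (geometric waiting times;
    M floored at 1e-3 so the value goes to 0 rather than diverging), and the
    reward is discounted hyperbolically: Q = reward / (1 + kD).
    """
    if s >= T:
        return reward
    D = (T - s) / max(M, _HYP_M_FLOOR)
    return reward / (1.0 + k * D)


# ---------------------------------------------------------------------------
# evolving model state
# ---------------------------------------------------------------------------

@dataclass
class ValuationState:
    """The internal state of one agent: beliefs, momentum terms, RW values.

    Stored as plain lists — the per-round loops index these heavily.
    """

    beliefs: list = field(default_factory=lambda: [M_INIT] * N_SUITS)
    speed: list = field(default_factory=lambda: [V_INIT] * N_SUITS)
    bias: list = field(default_factory=lambda: [B_INIT] * N_SUITS)
    rw_values: list = field(default_factory=lambda: [0.0] * N_SUITS)
    horizon: int = HORIZON


def momentum_update(state: ValuationState, suit: int, m_before: float,
                    m_after: float, gamma: float, alpha: float) -> ValuationState:
    """TD update of the chosen suit's speed and bias.

    δ = γ(v·m_after + b) − (v·m_before + b); v ← v + αδ·m_before; b ← b + αδ.
    On suit completion m_after = 1 here and the progress resets afterwards;
    v and b persist across completions.
    """
    v = state.speed[suit]
    b = state.bias[suit]
    delta = gamma * (v * m_after + b) - (v * m_before + b)
    state.speed[suit] = v + alpha * delta * m_before
    state.bias[suit] = b + alpha * delta
    return state


def rw_ck_update(state: ValuationState, kernels: np.ndarray, suit: int,
                 token: int, eta: float, alpha_ck: float):
    """Rescorla-Wagner value update (chosen suit) + kernel update (all suits)."""
    state.rw_values[suit] += eta * (token - state.rw_values[suit])
    for g in range(N_SUITS):
        kernels[g] += alpha_ck * ((1.0 if g == suit else 0.0) - kernels[g])
    return state, kernels


# ---------------------------------------------------------------------------
# uniform interface used by the simulator and the likelihood
# ---------------------------------------------------------------------------

def model_values(model_id: str, params: ModelParams, state: ValuationState,
                 counts, targets) -> list[float]:
    """Q values of the three suits given the current slots and model state.

    ``counts``/``targets`` are length-3 sequences of token counts and suit
    targets.  ``rw_ck`` values are the RW token expectations (its policy is
    a plain softmax handled separately).
    """
    if model_id == "momentum":
        return [state.speed[g] * (counts[g] / targets[g]) + state.bias[g]
                for g in range(N_SUITS)]
    if model_id == "td_persistence":
        return [float(state.beliefs[g]) for g in range(N_SUITS)]
    if model_id == "retrospective":
        return [retrospective_value(counts[g], targets[g], params.gamma)
                for g in range(N_SUITS)]
    if model_id == "rw_ck":
        return [float(state.rw_values[g]) for g in range(N_SUITS)]
    if model_id == "prospective_hyperbolic":
        return [hyperbolic_prospective_value(state.beliefs[g], counts[g],
                                             targets[g], params.k)
                for g in range(N_SUITS)]
    if model_id in ("prospective", "prospective_asym"):
        return [_pros_q_cached(state.beliefs[g], targets[g], params.gamma,
                               state.horizon)[counts[g]]
                for g in range(N_SUITS)]
    if model_id == "hybrid":
        w = params.w
        return [w * _pros_q_cached(state.beliefs[g], targets[g], params.gamma,
                                   state.horizon)[counts[g]]
                + (1.0 - w) * retrospective_value(counts[g], targets[g],
                                                  params.gamma)
                for g in range(N_SUITS)]
    raise ValueError(f"unknown model_id {model_id!r}")


def model_update(model_id: str, params: ModelParams, state: ValuationState,
                 suit: int, token: int, count_before: int,
                 target: int) -> ValuationState:
    """Per-round learning update for the suit whose card was chosen.

    Only the chosen suit's belief / momentum terms / RW value change; the
    other suits' states are frozen (their outcomes are unobserved).
    ``count_before`` is the suit's token count before the outcome.
    """
    if model_id == "momentum":
        m_before = count_before / target
        m_after = (count_before + token) / target
        return momentum_update(state, suit, m_before, m_after,
                               params.gamma, params.alpha)
    if model_id == "rw_ck":
        state.rw_values[suit] += params.alpha * (token - state.rw_values[suit])
        return state
    if model_id == "prospective_asym":
        state.beliefs[suit] = belief_update(state.beliefs[suit], token,
                                            params.alpha_pos, params.alpha_neg)
        return state
    if model_id == "retrospective":
        return state
    # prospective / hybrid / td_persistence / prospective_hyperbolic
    state.beliefs[suit] = belief_update(state.beliefs[suit], token, params.alpha)
    return state
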