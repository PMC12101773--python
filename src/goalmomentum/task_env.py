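"""The suits task: a three-goal token-collection game played in blocks.

Three suits (*cat*, *hat*, *car*) each own a bank of slots; filling all
``target_tokens`` slots of a suit pays a fixed 10 points and empties the
bank.  Every round the player flips one of three cards (one per suit) and
receives a suit-congruent token with the block's probability for that suit —
cross-suit tokens never occur.  Each 30-round block has one *dominant* suit
(highest token probability) which flips across adjacent blocks, and the
player reports the goal they are pursuing every third round.

This module defines the experiment configurations (experiments 1-4), the
round mechanics, and the drifting-probability environments used in the
normative simulations.  Agents live in :mod:`goalmomentum.valuation` and
:mod:`goalmomentum.policy`; the closed loop is in
:mod:`goalmomentum.simulate`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

SUITS = ("cat", "hat", "car")
N_SUITS = 3
REWARD_POINTS = 10
PROBE_INTERVAL = 3
ROUNDS_PER_BLOCK = 30

#: fixed bijection of the six cards onto the three suits
CARDS = {
    "cat": ("basket", "mat"),
    "hat": ("wardrobe", "table"),
    "car": ("key", "baggage"),
}

#: block types per experiment: name -> (dominant p, inferior p)
_BLOCK_TYPES = {
    "exp1": {"80-20": (0.8, 0.2), "70-30": (0.7, 0.3), "60-40": (0.6, 0.4)},
    "exp2": {"75-25": (0.75, 0.25), "55-45": (0.55, 0.45)},
}
_BLOCKS_PER_TYPE = 6

#: experiment 4 targets and expected rounds-to-completion per block type
_EXP4_TARGETS = {"cat": 4, "hat": 6, "car": 8}
_EXP4_DOMINANT_ROUNDS = 8
_EXP4_INFERIOR_ROUNDS = {"H disp": 15, "L disp": 12}
_EXP4_BLOCKS_PER_TYPE = 6

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4")


@dataclass(frozen=True)
class SuitSpec:
    suit_id: str
    target_tokens: int
    reward_points: int = REWARD_POINTS
    card_ids: tuple[str, str] = ()

    def __post_init__(self):
        if self.suit_id not in SUITS:
            raise ValueError(f"unknown suit {self.suit_id!r}")
        if self.target_tokens <= 0:
            raise ValueError("target_tokens must be positive")
        if not self.card_ids:
            object.__setattr__(self, "card_ids", CARDS[self.suit_id])


@dataclass(frozen=True)
class BlockSpec:
    block_index: int  # 1-based
    n_rounds: int
    token_prob: dict[str, float]
    dominant_suit: str
    block_type: str


@dataclass
class GameConfig:
    experiment_id: str
    suits: list[SuitSpec]
    blocks: list[BlockSpec]
    probe_interval: int = PROBE_INTERVAL
    rng_seed: int | None = None

    @property
    def n_rounds(self) -> int:
        return sum(b.n_rounds for b in self.blocks)

    @property
    def targets(self) -> np.ndarray:
        return np.array([s.target_tokens for s in self.suits], dtype=np.int64)

    def prob_matrix(self) -> np.ndarray:
        """Per-round token probabilities, shape (n_rounds, 3)."""
        rows = []
        for b in self.blocks:
            p = [b.token_prob[s] for s in SUITS]
            rows.extend([p] * b.n_rounds)
        return np.asarray(rows, dtype=float)

    def block_indices(self) -> np.ndarray:
        """1-based block index of every round, shape (n_rounds,)."""
        out = []
        for b in self.blocks:
            out.extend([b.block_index] * b.n_rounds)
        return np.asarray(out, dtype=np.int64)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "experiment_id": self.experiment_id,
            "probe_interval": self.probe_interval,
            "rng_seed": self.rng_seed,
            "suits": [dataclasses.asdict(s) | {"card_ids": list(s.card_ids)}
                      for s in self.suits],
            "blocks": [
                {
                    "block_index": b.block_index,
                    "n_rounds": b.n_rounds,
                    "token_prob": {k: float(v) for k, v in b.token_prob.items()},
                    "dominant_suit": b.dominant_suit,
                    "block_type": b.block_type,
                }
                for b in self.blocks
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GameConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        suits = [SuitSpec(s["suit_id"], s["target_tokens"], s["reward_points"],
                          tuple(s["card_ids"])) for s in doc["suits"]]
        blocks = [BlockSpec(**b) for b in doc["blocks"]]
        return cls(doc["experiment_id"], suits, blocks,
                   doc["probe_interval"], doc["rng_seed"])


@dataclass
class SlotState:
    """Per-suit token counts plus the accumulated score."""

    counts: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SUITS})
    points: int = 0

    def fractional_progress(self, config: GameConfig) -> dict[str, float]:
        return {s.suit_id: self.counts[s.suit_id] / s.target_tokens
                for s in config.suits}


# ---------------------------------------------------------------------------
# experiment configurations
# ---------------------------------------------------------------------------

def _schedule(rng: np.random.Generator, type_counts: dict[str, int],
              dominants_per_type: int, max_tries: int = 10_000):
    """Shuffle block types and assign dominant suits under the constraints:
    adjacent blocks never share a dominant suit, and within every block type
    each suit is dominant equally often.  Rejection sampling under ``rng``.
    """
    types = [t for t, n in type_counts.items() for _ in range(n)]
    for _ in range(max_tries):
        order = [str(t) for t in rng.permutation(types)]
        remaining = {t: {s: dominants_per_type for s in SUITS} for t in type_counts}
        doms: list[str] = []
        ok = True
        for t in order:
            options = [s for s in SUITS
                       if remaining[t][s] > 0 and (not doms or s != doms[-1])]
            if not options:
                ok = False
                break
            s = options[rng.integers(len(options))]
            remaining[t][s] -= 1
            doms.append(s)
        if ok:
            return order, doms
    raise RuntimeError("could not build a balanced block schedule")


def make_experiment_config(experiment_id: str, seed: int | None = None) -> GameConfig:
    """Build the block schedule for one of the four experiments.

    Experiments 1 and 3 share the same structure (the instruction
    manipulation of experiment 3 has no simulator-side effect): 18 blocks of
    30 rounds, six each of 80-20 / 70-30 / 60-40, all targets 7.  Experiment
    2: 12 blocks, 75-25 / 55-45, 360 rounds.  Experiment 4 uses non-uniform
    targets (4, 6, 8) with token probabilities derived from the stated
    expected rounds-to-completion (p = target / E[rounds]).
    """
    if experiment_id not in EXPERIMENTS:
        raise ValueError(f"unknown experiment_id {experiment_id!r}")
    rng = np.random.default_rng(seed)

    if experiment_id == "exp4":
        suits = [SuitSpec(s, _EXP4_TARGETS[s]) for s in SUITS]
        type_counts = {t: _EXP4_BLOCKS_PER_TYPE for t in _EXP4_INFERIOR_ROUNDS}
        order, doms = _schedule(rng, type_counts, _EXP4_BLOCKS_PER_TYPE // N_SUITS)
        blocks = []
        for i, (btype, dom) in enumerate(zip(order, doms), start=1):
            inf_rounds = _EXP4_INFERIOR_ROUNDS[btype]
            probs = {
                s: _EXP4_TARGETS[s] / (_EXP4_DOMINANT_ROUNDS if s == dom else inf_rounds)
                for s in SUITS
            }
            blocks.append(BlockSpec(i, ROUNDS_PER_BLOCK, probs, dom, btype))
        return GameConfig(experiment_id, suits, blocks, rng_seed=seed)

    key = "exp2" if experiment_id == "exp2" else "exp1"
    block_types = _BLOCK_TYPES[key]
    suits = [SuitSpec(s, 7) for s in SUITS]
    type_counts = {t: _BLOCKS_PER_TYPE for t in block_types}
    order, doms = _schedule(rng, type_counts, _BLOCKS_PER_TYPE // N_SUITS)
    blocks = []
    for i, (btype, dom) in enumerate(zip(order, doms), start=1):
        p_dom, p_inf = block_types[btype]
        probs = {s: (p_dom if s == dom else p_inf) for s in SUITS}
        blocks.append(BlockSpec(i, ROUNDS_PER_BLOCK, probs, dom, btype))
    return GameConfig(experiment_id, suits, blocks, rng_seed=seed)


# ---------------------------------------------------------------------------
# round mechanics
# ---------------------------------------------------------------------------

def deal_cards(config: GameConfig, block: BlockSpec,
               rng: np.random.Generator) -> dict[str, str]:
    """Offer one of the two cards of each suit, uniformly at random.

    Card identity carries no value: either card of a suit yields the token
    with the same probability, so the deal never affects outcomes.
    """
    return {s.suit_id: s.card_ids[rng.integers(2)] for s in config.suits}


def resolve_round(config: GameConfig, state: SlotState, block: BlockSpec,
                  chosen_suit: str, rng: np.random.Generator):
    """Draw the token outcome for the chosen suit and update the slots.

    Returns ``(token_received, state, suit_completed)``.  A Bernoulli draw
    with the block's probability for the chosen suit; cross-suit tokens have
    probability exactly zero.  A count reaching the suit's target resets to
    zero within the same round and pays the suit's reward points.
    """
    if chosen_suit not in SUITS:
        raise ValueError(f"unknown suit {chosen_suit!r}")
    token = int(rng.random() < block.token_prob[chosen_suit])
    completed = 0
    if token:
        state.counts[chosen_suit] += 1
        spec = next(s for s in config.suits if s.suit_id == chosen_suit)
        if state.counts[chosen_suit] >= spec.target_tokens:
            state.counts[chosen_suit] = 0
            state.points += spec.reward_points
            completed = 1
    return token, state, completed


# ---------------------------------------------------------------------------
# drifting environments for the normative simulations
# ---------------------------------------------------------------------------

@dataclass
class DriftSchedule:
    """A per-round token-probability schedule with uniform targets.

    ``probs`` has shape (n_rounds, 3).  Used by the normative simulations in
    place of a blocked :class:`GameConfig`; exposes the same array interface.
    """

    kind: str
    probs: np.ndarray
    target_tokens: int = 7
    seed: int | None = None

    @property
    def n_rounds(self) -> int:
        return len(self.probs)

    @property
    def targets(self) -> np.ndarray:
        return np.full(N_SUITS, self.target_tokens, dtype=np.int64)

    def prob_matrix(self) -> np.ndarray:
        return self.probs

    def block_indices(self) -> np.ndarray:
        return np.arange(self.n_rounds, dtype=np.int64) // ROUNDS_PER_BLOCK + 1


DRIFT_STEP_SD = 0.025  # SD of the per-round Gaussian step of the random walk
_DRIFT_CLIP = (0.001, 0.999)


def make_drift_environment(kind: str, n_rounds: int,
                           seed: int | None = None) -> DriftSchedule:
    """Environments with moving token probabilities.

    Initial probabilities are drawn U(0.2,0.3), U(0.2,0.3), U(0.7,0.8) and
    assigned to the suits in random order.  ``random_walk`` adds a Gaussian
    step (SD 0.025) to each probability every round, clipped inside (0,1);
    ``reversal`` keeps them fixed but shuffles them among the suits every 30
    rounds.
    """
    if kind not in ("random_walk", "reversal"):
        raise ValueError(f"unknown drift kind {kind!r}")
    rng = np.random.default_rng(seed)
    p0 = np.array([rng.uniform(0.2, 0.3), rng.uniform(0.2, 0.3),
                   rng.uniform(0.7, 0.8)])
    p0 = p0[rng.permutation(N_SUITS)]
    probs = np.empty((n_rounds, N_SUITS))
    if kind == "random_walk":
        p = p0.copy()
        for t in range(n_rounds):
            probs[t] = p
            p = np.clip(p + rng.normal(0.0, DRIFT_STEP_SD, N_SUITS), *_DRIFT_CLIP)
    else:
        p = p0.copy()
        for t in range(n_rounds):
            if t > 0 and t % ROUNDS_PER_BLOCK == 0:
                p = p[rng.permutation(N_SUITS)]
            probs[t] = p
    return DriftSchedule(kind, probs, seed=seed)
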