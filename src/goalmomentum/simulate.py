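"""Synthetic participants: close the loop between task, values and policy.

The study's raw behavioral data are not deposited, so cohorts of simulated
agents stand in for them.  Every round an agent computes its three goal
values, makes the hierarchical stay/switch goal decision, reports its goal
on probe rounds (every third round), selects the card to flip, observes the
token outcome, and updates its internal state.  Everything is reproducible
from a seed, and per-participant seeds are derived deterministically from a
cohort master seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .task_env import (CARDS, N_SUITS, SUITS, GameConfig,
                       make_experiment_config)
from .valuation import (PARAM_SPECS, ModelParams, ValuationState,
                        model_update, model_values)

UNDECIDED = "undecided"

#: parameter box of the recovery studies (uniform sampling ranges)
RECOVERY_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0), "gamma": (0.6, 1.0), "switch_cost": (-1.0, 1.0),
    "beta_goal": (0.0, 10.0), "beta_action": (0.0, 10.0), "alpha_ck": (0.0, 1.0),
    "w": (0.0, 1.0), "k": (0.0, 1.0), "alpha_pos": (0.0, 1.0),
    "alpha_neg": (0.0, 1.0), "beta": (0.0, 10.0), "beta_ck": (0.0, 10.0),
}

#: parameter ranges emulating engaged human players: value-sensitive
#: temperatures, a positive stay bonus, and the discount range the fitted
#: cohort concentrated in.
HUMAN_PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.1, 0.9), "gamma": (0.9, 1.0), "switch_cost": (0.0, 1.0),
    "beta_goal": (2.0, 8.0), "beta_action": (2.0, 8.0), "alpha_ck": (0.0, 0.5),
    "w": (0.2, 0.8), "k": (0.0, 0.5), "alpha_pos": (0.1, 0.9),
    "alpha_neg": (0.1, 0.9), "beta": (2.0, 8.0), "beta_ck": (0.0, 5.0),
}


def sample_params(model_id: str, ranges: dict | None = None,
                  rng: np.random.Generator | None = None) -> ModelParams:
    """Uniform draw of a parameter vector inside the given box."""
    rng = np.random.default_rng() if rng is None else rng
    box = dict(RECOVERY_RANGES)
    if ranges:
        box.update(ranges)
    kw = {name: float(rng.uniform(*box[name])) for name in PARAM_SPECS[model_id]}
    return ModelParams(model_id, **kw)


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    block_index: int
    offered_cards: dict[str, str]
    chosen_suit: str
    chosen_card: str
    token_received: int
    slots_before: tuple[int, int, int]
    slots_after: tuple[int, int, int]
    probe_response: str | None
    suit_completed: int


@dataclass
class ParticipantDataset:
    """One participant's full trajectory, stored column-wise.

    ``actions``/``probes`` are suit indices (probe −1 where absent, −2 for
    an "undecided" response); slots are counts *before* the round resolves.
    """

    participant_id: str
    experiment_id: str
    block_index: np.ndarray
    actions: np.ndarray
    tokens: np.ndarray
    probes: np.ndarray
    slots_before: np.ndarray       # (n_rounds, 3)
    slots_after: np.ndarray        # (n_rounds, 3)
    completed: np.ndarray
    offered: np.ndarray            # (n_rounds, 3) card slot 0/1 per suit
    targets: np.ndarray
    probe_interval: int = 3
    metadata: dict = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return len(self.actions)

    @property
    def n_probes(self) -> int:
        return int(np.sum(self.probes >= 0))

    @property
    def points(self) -> int:
        return int(self.completed.sum()) * 10

    def rounds(self):
        """Yield :class:`RoundRecord` views of the columnar data."""
        for t in range(self.n_rounds):
            a = int(self.actions[t])
            p = int(self.probes[t])
            yield RoundRecord(
                round_index=t + 1,
                block_index=int(self.block_index[t]),
                offered_cards={s: CARDS[s][int(self.offered[t, g])]
                               for g, s in enumerate(SUITS)},
                chosen_suit=SUITS[a],
                chosen_card=CARDS[SUITS[a]][int(self.offered[t, a])],
                token_received=int(self.tokens[t]),
                slots_before=tuple(int(x) for x in self.slots_before[t]),
                slots_after=tuple(int(x) for x in self.slots_after[t]),
                probe_response=(None if p == -1 else
                                UNDECIDED if p == -2 else SUITS[p]),
                suit_completed=int(self.completed[t]),
            )

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        d = {
            "round_index": np.arange(1, self.n_rounds + 1),
            "block_index": self.block_index,
            "chosen_suit": [SUITS[a] for a in self.actions],
            "chosen_card": [CARDS[SUITS[a]][int(self.offered[t, a])]
                            for t, a in enumerate(self.actions)],
            "token_received": self.tokens,
            "suit_completed": self.completed,
            "probe_response": ["" if p == -1 else UNDECIDED if p == -2
                               else SUITS[p] for p in self.probes],
        }
        for g, s in enumerate(SUITS):
            d[f"offered_card_{s}"] = [CARDS[s][int(i)] for i in self.offered[:, g]]
            d[f"slots_before_{s}"] = self.slots_before[:, g]
            d[f"slots_after_{s}"] = self.slots_after[:, g]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "participant_id": self.participant_id,
            "experiment_id": self.experiment_id,
            "targets": [int(t) for t in self.targets],
            "probe_interval": self.probe_interval,
            **self.metadata,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "ParticipantDataset":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False)
        meta = json.loads(path.with_suffix(".json").read_text())
        idx = {s: g for g, s in enumerate(SUITS)}
        probes = np.array([-1 if p == "" else -2 if p == UNDECIDED else idx[p]
                           for p in df["probe_response"]], dtype=np.int64)
        card_slot = {s: {c: i for i, c in enumerate(CARDS[s])} for s in SUITS}
        offered = np.column_stack(
            [[card_slot[s][c] for c in df[f"offered_card_{s}"]] for s in SUITS])
        return cls(
            participant_id=meta["participant_id"],
            experiment_id=meta["experiment_id"],
            block_index=df["block_index"].to_numpy(np.int64),
            actions=np.array([idx[s] for s in df["chosen_suit"]], dtype=np.int64),
            tokens=df["token_received"].to_numpy(np.int64),
            probes=probes,
            slots_before=np.column_stack(
                [df[f"slots_before_{s}"].to_numpy(np.int64) for s in SUITS]),
            slots_after=np.column_stack(
                [df[f"slots_after_{s}"].to_numpy(np.int64) for s in SUITS]),
            completed=df["suit_completed"].to_numpy(np.int64),
            offered=offered.astype(np.int64),
            targets=np.asarray(meta["targets"], dtype=np.int64),
            probe_interval=meta["probe_interval"],
            metadata={k: v for k, v in meta.items()
                      if k not in ("participant_id", "experiment_id", "targets",
                                   "probe_interval")},
        )


# ---------------------------------------------------------------------------
# the simulation loop
# ---------------------------------------------------------------------------

def _stay_prob(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _softmax3_sample(values, beta: float, u: float) -> int:
    z = [beta * v for v in values]
    zmax = max(z)
    e = [math.exp(x - zmax) for x in z]
    tot = e[0] + e[1] + e[2]
    r = u * tot
    if r < e[0]:
        return 0
    return 1 if r < e[0] + e[1] else 2


def play_game(schedule, params: ModelParams, seed=None, record: bool = True,
              true_beliefs: bool = False):
    """Run one agent through one game.

    ``schedule`` is a :class:`~goalmomentum.task_env.GameConfig` or
    :class:`~goalmomentum.task_env.DriftSchedule`.  Returns a
    :class:`ParticipantDataset` when ``record`` is true, otherwise just the
    number of suits completed (used by the performance optimizer).

    ``true_beliefs=True`` hands the agent the schedule's true token
    probabilities as its beliefs every round (no belief learning) — the
    task-informed benchmark configuration.
    """
    rng = np.random.default_rng(seed)
    probs = schedule.prob_matrix()
    probs_list = probs.tolist()
    block_ix = schedule.block_indices()
    targets = [int(t) for t in schedule.targets]
    n_rounds = len(probs)
    probe_interval = getattr(schedule, "probe_interval", 3)

    model_id = params.model_id
    is_rw = model_id == "rw_ck"
    state = ValuationState()
    kernels = [0.0, 0.0, 0.0]
    counts = [0, 0, 0]
    goal: int | None = None
    n_completed = 0

    if record:
        actions = np.empty(n_rounds, dtype=np.int64)
        tokens = np.empty(n_rounds, dtype=np.int64)
        probes = np.full(n_rounds, -1, dtype=np.int64)
        slots_before = np.empty((n_rounds, 3), dtype=np.int64)
        slots_after = np.empty((n_rounds, 3), dtype=np.int64)
        completed_arr = np.zeros(n_rounds, dtype=np.int64)
        offered = rng.integers(0, 2, size=(n_rounds, 3))
    else:
        offered = None

    c = params.switch_cost
    bg = params.beta_goal
    ba = params.beta_action
    ack = params.alpha_ck

    for t in range(n_rounds):
        if true_beliefs:
            state.beliefs = list(probs_list[t])  # copy: updates must not touch the schedule
        values = model_values(model_id, params, state, counts, targets)

        if is_rw:
            # single-stage softmax over β·Q + β_ck·kernel; goal == action
            mix = [params.beta * values[g] + params.beta_ck * kernels[g]
                   for g in range(3)]
            goal = _softmax3_sample(mix, 1.0, rng.random())
            action = goal
        else:
            if goal is None:
                goal = _softmax3_sample(values, bg, rng.random())
            else:
                others = max(values[(goal + 1) % 3], values[(goal + 2) % 3])
                ps = _stay_prob(c + kernels[goal] + bg * (values[goal] - others))
                if rng.random() >= ps:
                    a1, a2 = (goal + 1) % 3, (goal + 2) % 3
                    x = bg * (values[a1] - values[a2])
                    p1 = _stay_prob(x)
                    goal = a1 if rng.random() < p1 else a2

        # choice kernel tracks the chosen goal
        for g in range(3):
            kernels[g] += ack * ((1.0 if g == goal else 0.0) - kernels[g])

        if record and (t + 1) % probe_interval == 0:
            probes[t] = goal

        if is_rw:
            action = goal
        else:
            others = max(values[(goal + 1) % 3], values[(goal + 2) % 3])
            ps = _stay_prob(c + kernels[goal] + ba * (values[goal] - others))
            if rng.random() < ps:
                action = goal
            else:
                a1, a2 = (goal + 1) % 3, (goal + 2) % 3
                p1 = _stay_prob(ba * (values[a1] - values[a2]))
                action = a1 if rng.random() < p1 else a2

        if record:
            slots_before[t] = counts
            actions[t] = action

        token = 1 if rng.random() < probs_list[t][action] else 0
        count_before = counts[action]
        completed = 0
        if token:
            counts[action] += 1
            if counts[action] >= targets[action]:
                counts[action] = 0
                completed = 1
                n_completed += 1

        if record:
            tokens[t] = token
            slots_after[t] = counts
            completed_arr[t] = completed

        model_update(model_id, params, state, action, token,
                     count_before, targets[action])

    if not record:
        return n_completed

    return ParticipantDataset(
        participant_id="sim",
        experiment_id=getattr(schedule, "experiment_id",
                              getattr(schedule, "kind", "custom")),
        block_index=block_ix,
        actions=actions, tokens=tokens, probes=probes,
        slots_before=slots_before, slots_after=slots_after,
        completed=completed_arr, offered=offered,
        targets=np.asarray(targets, dtype=np.int64),
        probe_interval=probe_interval,
        metadata={"model_id": model_id, "params": params.to_dict(),
                  "seed": None if seed is None else int(seed),
                  "config_seed": getattr(schedule, "rng_seed", None)},
    )


def simulate_participant(config: GameConfig, model: ModelParams,
                         seed=None) -> ParticipantDataset:
    """Simulate one synthetic participant on a task configuration."""
    ds = play_game(config, model, seed=seed, record=True)
    ds.metadata["seed"] = None if seed is None else int(seed)
    return ds


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    experiment_id: str
    n_participants: int
    model_id: str = "momentum"
    params: list[ModelParams] | None = None     # fixed vectors, one per agent
    ranges: dict | None = None                  # else: sampled from this box
    master_seed: int = 0
    shared_config: bool = False                 # one schedule for the cohort?


def participant_seed(master_seed: int, index: int) -> int:
    """Deterministic per-participant seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: CohortSpec) -> list[ParticipantDataset]:
    """Simulate a cohort; metadata records model, parameters and seeds."""
    out = []
    shared = (make_experiment_config(spec.experiment_id, seed=spec.master_seed)
              if spec.shared_config else None)
    for i in range(spec.n_participants):
        seed = participant_seed(spec.master_seed, i)
        config = shared if shared is not None else make_experiment_config(
            spec.experiment_id, seed=seed)
        if spec.params is not None:
            params = spec.params[i]
        else:
            prng = np.random.default_rng(participant_seed(spec.master_seed,
                                                          10_000_000 + i))
            params = sample_params(spec.model_id, spec.ranges, prng)
        ds = simulate_participant(config, params, seed=seed)
        ds.participant_id = f"{spec.experiment_id}-{spec.model_id}-{i:03d}"
        ds.experiment_id = spec.experiment_id
        out.append(ds)
    return out


def save_cohort(datasets: list[ParticipantDataset], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for ds in datasets:
        ds.to_csv(out_dir / f"{ds.participant_id}.csv")
        manifest.append({"participant_id": ds.participant_id,
                         "experiment_id": ds.experiment_id,
                         **ds.metadata})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_cohort(out_dir) -> list[ParticipantDataset]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return [ParticipantDataset.from_csv(out_dir / f"{m['participant_id']}.csv")
            for m in manifest]
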