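"""Independent oracles shared across test modules."""

import itertools
import math

import numpy as np

import goalmomentum as gm
from goalmomentum.policy import softmax
from goalmomentum.valuation import ValuationState, momentum_update


def brute_force_prospective(M, s, T, gamma, horizon, reward=1.0):
    """Enumerate every token-outcome sequence; reward discounted per step."""
    total = 0.0
    for seq in itertools.product([0, 1], repeat=horizon):
        prob = 1.0
        count = s
        value = 0.0
        done = False
        for step, token in enumerate(seq, start=1):
            prob *= M if token else (1.0 - M)
            if not done:
                count += token
                if count >= T:
                    value = gamma ** step * reward
                    done = True
        total += prob * value
    return total


def enumerate_nll_momentum(ds, params):
    """Exhaustive latent-goal-path evaluation of the printed likelihood.

    Values and momentum updates are driven by the observed actions only, so
    per-round transition and action matrices are path-independent (the
    choice kernel is off); the goal marginals are summed over all paths.
    """
    assert params.alpha_ck == 0.0
    n = ds.n_rounds
    st = ValuationState()
    values_by_round = []
    for t in range(n):
        m = ds.slots_before[t] / ds.targets
        values_by_round.append([st.speed[g] * m[g] + st.bias[g]
                                for g in range(3)])
        a = ds.actions[t]
        momentum_update(st, a, ds.slots_before[t, a] / ds.targets[a],
                        (ds.slots_before[t, a] + ds.tokens[t]) / ds.targets[a],
                        params.gamma, params.alpha)
    init = softmax(values_by_round[0], params.beta_goal)
    trans = [gm.goal_transition_matrix(values_by_round[t], params, [0.0] * 3)
             for t in range(n)]
    act = [[gm.action_probabilities(values_by_round[t], g, 0.0, params)
            for g in range(3)] for t in range(n)]

    marginals = []
    dist = init
    for t in range(n):
        if t > 0:
            new = np.zeros(3)
            for g_prev, g_next in itertools.product(range(3), range(3)):
                new[g_next] += dist[g_prev] * trans[t][g_prev, g_next]
            dist = new
        marginals.append(dist.copy())
        if ds.probes[t] >= 0:
            dist = np.zeros(3)
            dist[ds.probes[t]] = 1.0

    nll = 0.0
    for t in range(n):
        post = marginals[t]
        if ds.probes[t] >= 0:
            nll -= math.log(post[ds.probes[t]])
            post = np.zeros(3)
            post[ds.probes[t]] = 1.0
        pa = sum(post[g] * act[t][g][ds.actions[t]] for g in range(3))
        nll -= math.log(pa)
    return nll


def small_dataset(actions, tokens, probes, targets=(7, 7, 7)):
    """Hand-assemble a tiny dataset with consistent slot bookkeeping."""
    n = len(actions)
    slots_before = np.zeros((n, 3), dtype=np.int64)
    slots_after = np.zeros((n, 3), dtype=np.int64)
    completed = np.zeros(n, dtype=np.int64)
    counts = [0, 0, 0]
    for t, (a, tok) in enumerate(zip(actions, tokens)):
        slots_before[t] = counts
        if tok:
            counts[a] += 1
            if counts[a] >= targets[a]:
                counts[a] = 0
                completed[t] = 1
        slots_after[t] = counts
    return gm.ParticipantDataset(
        participant_id="tiny", experiment_id="custom",
        block_index=np.ones(n, dtype=np.int64),
        actions=np.asarray(actions, dtype=np.int64),
        tokens=np.asarray(tokens, dtype=np.int64),
        probes=np.asarray(probes, dtype=np.int64),
        slots_before=slots_before, slots_after=slots_after,
        completed=completed, offered=np.zeros((n, 3), dtype=np.int64),
        targets=np.asarray(targets, dtype=np.int64))
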