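"""Likelihood of a participant's choices under any model, and model fitting.

The pursued goal is observed only on probe rounds (every third round); in
between it is a latent variable.  The likelihood therefore runs a forward
pass: a probe collapses the goal belief to a point mass on the reported
suit, the belief is then propagated through the policy's stay/switch
transition matrix on the intermediate rounds (propagation only — no
conditioning on observed actions), and each round's card choice contributes
a marginal action likelihood Pr(a) = Σ_g Pr(a|goal=g) Pr(goal=g).  Goal
terms are scored on probe rounds, action terms on every round; the
Rescorla-Wagner model scores actions only through its single softmax.

Maximum-likelihood fitting is a seeded global derivative-free search:
uniform random multi-starts over the parameter box followed by bounded
Powell refinement of the best start.  Model comparison uses AIC, BIC
(n = number of likelihood terms) and block-wise 3-fold cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .simulate import ParticipantDataset
from .valuation import (PARAM_SPECS, ModelParams, ValuationState,
                        model_update, model_values, n_free_params)
from .policy import action_probabilities, goal_probabilities, PolicyState

LIKELIHOOD_FLOOR = 1e-12


@dataclass
class LatentGoalBelief:
    """Distribution over the three suits for the unobserved current goal."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-9 or (self.probs < 0).any():
            raise ValueError("belief must be a probability distribution")


@dataclass
class FitResult:
    model_id: str
    params: ModelParams
    nll: float
    aic: float
    bic: float
    n_terms: int
    n_starts: int
    seed: int | None = None
    cv_nll: float | None = None


# ---------------------------------------------------------------------------
# building blocks (thin, explicit versions of what the forward pass inlines)
# ---------------------------------------------------------------------------

def goal_transition_matrix(values, params: ModelParams,
                           kernels) -> np.ndarray:
    """Row g: distribution of the next goal given current goal g."""
    out = np.empty((3, 3))
    for g in range(3):
        st = PolicyState(current_goal=g, kernels=np.asarray(kernels, float))
        out[g] = goal_probabilities(st, values, params)
    return out


def propagate_latent_goal(belief: LatentGoalBelief,
                          transition: np.ndarray) -> LatentGoalBelief:
    """One step of belief propagation through the goal transition matrix."""
    p = belief.probs @ transition
    return LatentGoalBelief(p / p.sum())


def action_likelihood(belief: LatentGoalBelief, action_probs_given_goal,
                      observed_action: int) -> float:
    """Marginal probability of the observed card choice."""
    p = float(sum(belief.probs[g] * action_probs_given_goal[g][observed_action]
                  for g in range(3)))
    return max(p, LIKELIHOOD_FLOOR)


# ---------------------------------------------------------------------------
# the forward pass
# ---------------------------------------------------------------------------

def _stay(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _pair(q1: float, q2: float, beta: float) -> tuple[float, float]:
    x = beta * (q1 - q2)
    if x >= 0:
        p1 = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        p1 = e / (1.0 + e)
    return p1, 1.0 - p1


def _softmax3(values, beta: float) -> list[float]:
    z = [beta * v for v in values]
    m = max(z)
    e = [math.exp(x - m) for x in z]
    s = e[0] + e[1] + e[2]
    return [e[0] / s, e[1] / s, e[2] / s]


def dataset_nll(dataset: ParticipantDataset, model_id: str,
                params: ModelParams, score_blocks=None,
                filtered: bool = False) -> float:
    """Total negative log-likelihood of one dataset under one model.

    The valuation state is re-run from the game start through *all* rounds;
    when ``score_blocks`` (a set of block indices) is given, only the
    likelihood terms of those blocks are accumulated — used for block-wise
    cross-validation.  ``filtered=True`` additionally conditions the latent
    goal belief on each observed action (Bayes filter), a sensitivity
    variant; the default propagates the belief through the transition
    matrix only.
    """
    if model_id not in PARAM_SPECS:
        raise ValueError(f"unknown model_id {model_id!r}")
    n = dataset.n_rounds
    # plain lists: this loop runs hundreds of times per fit
    actions = dataset.actions.tolist()
    tokens = dataset.tokens.tolist()
    probes = dataset.probes.tolist()
    counts_seq = dataset.slots_before.tolist()
    targets = [int(x) for x in dataset.targets]
    score = (None if score_blocks is None
             else np.isin(dataset.block_index, list(score_blocks)).tolist())

    c = params.switch_cost
    bg = params.beta_goal
    ba = params.beta_action
    ack = params.alpha_ck
    state = ValuationState()
    kernels = [0.0, 0.0, 0.0]
    nll = 0.0

    if model_id == "rw_ck":
        beta, bck = params.beta, params.beta_ck
        for t in range(n):
            values = model_values(model_id, params, state, counts_seq[t], targets)
            mix = [beta * values[g] + bck * kernels[g] for g in range(3)]
            p = _softmax3(mix, 1.0)
            a = actions[t]
            if score is None or score[t]:
                nll -= math.log(max(p[a], LIKELIHOOD_FLOOR))
            for g in range(3):
                kernels[g] += ack * ((1.0 if g == a else 0.0) - kernels[g])
            model_update(model_id, params, state, a, int(tokens[t]),
                         int(counts_seq[t][a]), targets[a])
        if not math.isfinite(nll):
            raise FloatingPointError("non-finite likelihood term")
        return nll

    bel = None
    for t in range(n):
        counts = counts_seq[t]
        values = model_values(model_id, params, state, counts, targets)

        # stay logistic pieces reused by the transition and the action model
        a_adv = [values[g] - max(values[(g + 1) % 3], values[(g + 2) % 3])
                 for g in range(3)]
        pair_for = [_pair(values[(g + 1) % 3], values[(g + 2) % 3], bg)
                    for g in range(3)]

        if bel is None:
            bel = _softmax3(values, bg)
        else:
            new = [0.0, 0.0, 0.0]
            for g in range(3):
                bg_prob = bel[g]
                if bg_prob == 0.0:
                    continue
                ps = _stay(c + kernels[g] + bg * a_adv[g])
                new[g] += bg_prob * ps
                rest = bg_prob * (1.0 - ps)
                p1, p2 = pair_for[g]
                new[(g + 1) % 3] += rest * p1
                new[(g + 2) % 3] += rest * p2
            s = new[0] + new[1] + new[2]
            bel = [new[0] / s, new[1] / s, new[2] / s]

        probe = probes[t]
        if probe >= 0:
            if score is None or score[t]:
                nll -= math.log(max(bel[probe], LIKELIHOOD_FLOOR))
            bel = [0.0, 0.0, 0.0]
            bel[probe] = 1.0

        for g in range(3):
            kernels[g] += ack * (bel[g] - kernels[g])

        a = actions[t]
        pa = 0.0
        cond = [0.0, 0.0, 0.0]
        for g in range(3):
            if bel[g] == 0.0:
                continue
            psa = _stay(c + kernels[g] + ba * a_adv[g])
            if a == g:
                pg = psa
            else:
                p1, p2 = _pair(values[(g + 1) % 3], values[(g + 2) % 3], ba)
                pg = (1.0 - psa) * (p1 if a == (g + 1) % 3 else p2)
            cond[g] = pg
            pa += bel[g] * pg
        if score is None or score[t]:
            nll -= math.log(max(pa, LIKELIHOOD_FLOOR))
        if filtered and pa > 0.0:
            bel = [bel[g] * cond[g] / pa for g in range(3)]

        model_update(model_id, params, state, a, int(tokens[t]),
                     int(counts[a]), targets[a])

    if not math.isfinite(nll):
        raise FloatingPointError("non-finite likelihood term")
    return nll


def n_likelihood_terms(dataset: ParticipantDataset, model_id: str,
                       score_blocks=None) -> int:
    """Actions every round plus goal probes (non-RW models)."""
    if score_blocks is None:
        n_actions = dataset.n_rounds
        n_probes = int(np.sum(dataset.probes >= 0))
    else:
        mask = np.isin(dataset.block_index, list(score_blocks))
        n_actions = int(mask.sum())
        n_probes = int(np.sum((dataset.probes >= 0) & mask))
    return n_actions if model_id == "rw_ck" else n_actions + n_probes


def aic(nll: float, k: int) -> float:
    return 2.0 * k + 2.0 * nll


def bic(nll: float, k: int, n: int) -> float:
    return k * math.log(n) + 2.0 * nll


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def fit(dataset: ParticipantDataset, model_id: str, seed: int | None = 0,
        n_starts: int = 100, refine_maxfev: int = 200,
        score_blocks=None) -> FitResult:
    """Maximize the likelihood over the model's parameter box.

    ``n_starts`` uniform random parameter vectors are scored, and the best
    is refined with bounded Powell search (derivative-free).  Reproducible
    under ``seed``.
    """
    spec = PARAM_SPECS[model_id]
    names = list(spec)
    lo = np.array([spec[p][0] for p in names])
    hi = np.array([spec[p][1] for p in names])
    rng = np.random.default_rng(seed)

    def objective(x) -> float:
        x = np.clip(x, lo, hi)
        p = ModelParams.from_vector(model_id, x)
        try:
            return dataset_nll(dataset, model_id, p, score_blocks=score_blocks)
        except FloatingPointError:
            return 1e12

    best_x, best_f = None, np.inf
    for _ in range(n_starts):
        x = rng.uniform(lo, hi)
        f = objective(x)
        if f < best_f:
            best_x, best_f = x, f
    if refine_maxfev > 0:
        res = minimize(objective, best_x, method="Powell",
                       bounds=list(zip(lo, hi)),
                       options={"maxfev": refine_maxfev, "xtol": 1e-3,
                                "ftol": 1e-3})
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
    if not np.isfinite(best_f):
        raise RuntimeError("optimizer found no finite likelihood")

    params = ModelParams.from_vector(model_id, best_x)
    k = n_free_params(model_id)
    n = n_likelihood_terms(dataset, model_id, score_blocks)
    return FitResult(model_id=model_id, params=params, nll=best_f,
                     aic=aic(best_f, k), bic=bic(best_f, k, n),
                     n_terms=n, n_starts=n_starts, seed=seed)


def cross_validate(dataset: ParticipantDataset, model_id: str,
                   n_splits: int = 3, n_repeats: int = 30,
                   seed: int | None = 0, n_starts: int = 100,
                   refine_maxfev: int = 200) -> float:
    """Mean held-out NLL over random block-wise splits.

    Per repeat, the task blocks are partitioned into ``n_splits`` folds;
    each fold in turn is held out, the model is fitted on the remaining
    blocks (the valuation state always evolves from the game start — only
    the scored terms change), and the held-out NLL is summed.  The metric
    is the mean of that sum over repeats.
    """
    blocks = np.unique(dataset.block_index)
    if len(blocks) < n_splits:
        raise ValueError(f"need at least {n_splits} blocks")
    rng = np.random.default_rng(seed)
    totals = []
    for r in range(n_repeats):
        perm = rng.permutation(blocks)
        folds = np.array_split(perm, n_splits)
        held_total = 0.0
        for i, fold in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != i])
            fr = fit(dataset, model_id, seed=None if seed is None
                     else seed + 1000 * r + i,
                     n_starts=n_starts, refine_maxfev=refine_maxfev,
                     score_blocks=set(train.tolist()))
            held_total += dataset_nll(dataset, model_id, fr.params,
                                      score_blocks=set(fold.tolist()))
        totals.append(held_total)
    return float(np.mean(totals))


def fit_results_frame(results) -> "pd.DataFrame":  # noqa: F821
    """Tidy CSV-ready table, one row per (participant, model) fit."""
    import pandas as pd
    rows = []
    for pid, fr in results:
        row = {"participant_id": pid, "model_id": fr.model_id, "nll": fr.nll,
               "aic": fr.aic, "bic": fr.bic, "cv_nll": fr.cv_nll,
               "n_terms": fr.n_terms}
        row.update({f"param_{k}": v for k, v in fr.params.to_dict().items()
                    if k != "model_id"})
        rows.append(row)
    return pd.DataFrame(rows)
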