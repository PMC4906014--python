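"""Ground-truth references for the approximate scheme.

These routines do exact computations that the main engine deliberately
avoids: posterior inference over the full joint hidden-state space (96
configurations), brute-force evaluation of expected free energy by explicit
summation, policy-space enumeration, and exhaustive search over adaptive
sampling strategies.  They exist to expose where the mean-field scheme is
exact, where it is merely adequate, and where it fails (overconfidence).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .task import (
    CHOICE_LOCATIONS,
    CONTEXTS,
    FACTOR_DIMS,
    QUADRANTS,
    GenerativeModel,
    Observation,
    SceneConfiguration,
    all_scenes,
)


@dataclass
class JointPosterior:
    """Exact posterior over all 3 x 8 x 2 x 2 joint hidden states at each epoch."""

    probs: np.ndarray  # shape (T_obs, 3, 8, 2, 2); one slice per observed epoch

    def marginal(self, factor: int, epoch: int = -1) -> np.ndarray:
        axes = tuple(i for i in range(4) if i != factor)
        return self.probs[epoch].sum(axis=axes)

    def to_json(self) -> str:
        return json.dumps({"probs": self.probs.tolist()})


def exact_posterior(
    model: GenerativeModel,
    actions: list[int],
    observations: list[Observation],
) -> JointPosterior:
    """Exact Bayesian filtering over the joint hidden-state space.

    Enumerates every joint configuration, propagates it through the (known)
    action sequence, multiplies in the deterministic likelihood of each
    observation and renormalizes.  ``observations[t]`` is the outcome at
    epoch t, generated after ``actions[t-1]``.
    """
    if len(observations) != len(actions) + 1:
        raise ValueError("need exactly one observation per epoch (len(actions) + 1)")
    prior = (
        model.D[0][:, None, None, None]
        * model.D[1][None, :, None, None]
        * model.D[2][None, None, :, None]
        * model.D[3][None, None, None, :]
    )
    out = []
    p = prior
    for t, obs in enumerate(observations):
        if t > 0:
            a = actions[t - 1]
            # Only the location factor moves; transition via B arrays.
            # p axes: (context, location, flip_lr, flip_ud)
            p = np.einsum("ij,cjud->ciud", model.B[1][a], p)
        lik = model.A[0][obs.what] * model.A[1][obs.where]
        p = p * lik
        z = p.sum()
        if z <= 0:
            raise ValueError("observation history has zero probability under the model")
        p = p / z
        out.append(p.copy())
    return JointPosterior(probs=np.stack(out))


def enumerate_policies(depth: int, n_actions: int, explicit: bool = False):
    """Count (and optionally list) all fixed action sequences of given depth."""
    count = n_actions**depth
    if not explicit:
        return count
    if depth > 5:
        raise ValueError("explicit enumeration supported only for depth <= 5")
    return count, list(itertools.product(range(n_actions), repeat=depth))


def minimal_guaranteeing_depth(scenes: list[SceneConfiguration] | None = None) -> int:
    """Minimal worst-case number of moves guaranteeing correct categorization.

    Exhaustive search over adaptive sampling strategies: decision trees whose
    internal nodes sample one of the four quadrants and branch on the cue
    observed there, and whose leaves are choice actions.  A leaf is valid only
    if every configuration still consistent with the observation history has
    the same context.  The final choice counts as a move.  Memoized over
    information sets (subsets of still-consistent configurations).
    """
    if scenes is None:
        scenes = all_scenes()
    # Encode each configuration by its quadrant cues + context label.
    configs = tuple(
        (tuple(s.layout[q] for q in QUADRANTS), s.context) for s in scenes
    )

    @lru_cache(maxsize=None)
    def cost(info_set: frozenset) -> int:
        contexts = {configs[i][1] for i in info_set}
        if len(contexts) == 1:
            return 1  # choose now
        best = None
        for q in range(len(QUADRANTS)):
            branches: dict[str, set] = {}
            for i in info_set:
                branches.setdefault(configs[i][0][q], set()).add(i)
            if len(branches) == 1:
                continue  # uninformative sample; cannot help a worst case
            worst = max(cost(frozenset(b)) for b in branches.values())
            if best is None or worst < best:
                best = worst
        if best is None:
            raise ValueError("information set cannot be resolved by quadrant samples")
        return 1 + best

    return cost(frozenset(range(len(configs))))


def brute_force_G(
    model: GenerativeModel,
    expectations: list[np.ndarray],
    epochs: list[int] | None = None,
) -> float:
    """Expected free energy by explicit summation over joint states and outcomes.

    ``expectations`` is a list per factor of arrays (T, dim) of predictive
    state expectations under a policy; ``epochs`` selects the future epochs to
    accumulate (defaults to all rows).  No factorized shortcuts: the joint
    predictive state distribution is materialized and every outcome of every
    modality is visited in an explicit loop.  Serves as the oracle for
    ``policies.expected_free_energy``.
    """
    T = expectations[0].shape[0]
    if epochs is None:
        epochs = list(range(T))
    dims = FACTOR_DIMS
    total = 0.0
    for tau in epochs:
        # Joint predictive state distribution (outer product of marginals).
        q = np.ones(dims)
        for f in range(4):
            shape = [1, 1, 1, 1]
            shape[f] = dims[f]
            q = q * expectations[f][tau].reshape(shape)
        for m, A in enumerate(model.A):
            n_out = A.shape[0]
            # Predictive outcome distribution.
            o = np.zeros(n_out)
            for idx in np.ndindex(*dims):
                for i in range(n_out):
                    o[i] += A[(i,) + idx] * q[idx]
            # Risk: KL from predicted outcomes to (normalized) preferences.
            lnC = model.C[m] - np.log(np.exp(model.C[m]).sum())
            risk = 0.0
            for i in range(n_out):
                if o[i] > 0:
                    risk += o[i] * (np.log(o[i]) - lnC[i])
            # Ambiguity: expected entropy of the likelihood.
            ambiguity = 0.0
            for idx in np.ndindex(*dims):
                h = 0.0
                for i in range(n_out):
                    a = A[(i,) + idx]
                    if a > 0:
                        h -= a * np.log(a)
                ambiguity += q[idx] * h
            total += risk + ambiguity
    return total


def mean_field_product(marginals: list[np.ndarray]) -> np.ndarray:
    """Joint distribution implied by a set of factor marginals."""
    q = np.ones(FACTOR_DIMS)
    for f, m in enumerate(marginals):
        shape = [1, 1, 1, 1]
        shape[f] = FACTOR_DIMS[f]
        q = q * np.asarray(m).reshape(shape)
    return q


def kl_divergence(p: np.ndarray, q: np.ndarray, floor: float = 1e-16) -> float:
    """KL(p || q) with a documented floor to handle exact zeros."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(np.maximum(q[mask], floor)))))
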