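"""The action-perception loop: run full foraging trials.

At each decision point the agent (i) updates mean-field beliefs under each of
the eight one-step-extended policies, (ii) evaluates their expected free
energy and infers the policy posterior and precision, (iii) forms a Bayesian
model average of the predicted next outcome, and (iv) acts to minimize the
KL divergence between that prediction and the outcome implied by each action.
Saccades only change where the agent samples, so action selection is driven by
the proprioceptive (*where*) outcome modality.

Action selection is an argmin of that KL divergence by default, with exact
ties broken by a seeded draw (a ``lowest`` tie-break mode gives a fully
index-deterministic variant).  Ties are not a corner case here: whenever the
factorized posterior cannot represent a correlation between context and
reflection, several saccade targets carry exactly equal expected free energy,
and breaking those ties by a fixed index would lock the agent into
resampling one location.  A ``sampled`` mode draws the saccade target from
the posterior predictive over sampled locations instead; because each
candidate policy lands in a distinct location, this equals posterior sampling
of policies, and is the mode in which prior precision has graded behavioral
consequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .inference import BeliefState, ln, update_states_batch
from .policies import (
    PolicySet,
    bma_marginals,
    expected_free_energy,
    infer_precision,
    predictive_outcomes,
)
from .task import (
    CHOICE_LOCATIONS,
    CUES,
    FIXATION,
    LOCATIONS,
    N_ACTIONS,
    GenerativeModel,
    Observation,
    SceneConfiguration,
    env_step,
)


@dataclass
class TrialRecord:
    """Everything one simulated trial produced."""

    scene: SceneConfiguration
    actions: list[int]
    observations: list[Observation]
    beliefs: list[BeliefState]
    choice: int | None
    feedback: str | None
    iterations_total: int
    seed: int | None
    max_saccades: int
    epoch_iterations: list[np.ndarray] = field(default_factory=list)
    epoch_converged: list[np.ndarray] = field(default_factory=list)
    gamma_trace: list[np.ndarray] = field(default_factory=list)
    c_pref: float | None = None

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.actions) + 1:
            raise ValueError("a trial holds one observation per epoch (actions + 1)")

    @property
    def decision_time(self) -> int:
        """Saccade index of the first choice action; max_saccades if none."""
        for i, a in enumerate(self.actions):
            if a in CHOICE_LOCATIONS:
                return i + 1
        return self.max_saccades

    @property
    def correct(self) -> bool:
        """Right feedback received and wrong feedback never received."""
        whats = [CUES[o.what] for o in self.observations]
        return "right" in whats and "wrong" not in whats

    def to_json(self) -> str:
        doc = {
            "scene": {
                "context": self.scene.context,
                "flip_lr": self.scene.flip_lr,
                "flip_ud": self.scene.flip_ud,
                "layout": self.scene.layout,
            },
            "actions": [LOCATIONS[a] for a in self.actions],
            "observations": [[o.what_name, o.where_name] for o in self.observations],
            "choice": None if self.choice is None else LOCATIONS[self.choice],
            "feedback": self.feedback,
            "correct": self.correct,
            "decision_time": self.decision_time,
            "iterations_total": self.iterations_total,
            "seed": self.seed,
            "epochs": [
                {
                    "pi": b.pi.tolist(),
                    "F": b.F.tolist(),
                    "G": b.G.tolist(),
                    "gamma": b.gamma,
                    "G_components": {
                        k: v.tolist() for k, v in (b.G_components or {}).items()
                    },
                }
                for b in self.beliefs
            ],
        }
        return json.dumps(doc)

    def csv_row(self) -> dict:
        return {
            "context": self.scene.context,
            "flip_lr": self.scene.flip_lr,
            "flip_ud": self.scene.flip_ud,
            "choice": None if self.choice is None else LOCATIONS[self.choice],
            "correct": int(self.correct),
            "decision_time": self.decision_time,
            "iterations": self.iterations_total,
            "seed": self.seed,
        }


def bma_next_outcome(
    pi: np.ndarray,
    expectations: list[np.ndarray],
    model: GenerativeModel,
    epoch: int,
) -> list[np.ndarray]:
    """Mixture, weighted by the policy posterior, of each policy's predicted
    outcome distributions at the given epoch (per modality)."""
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0, atol=1e-6):
        raise ValueError("policy posterior must be normalized")
    out = []
    for A in model.A:
        s_tau = [expectations[n][:, epoch] for n in range(len(expectations))]
        o = np.einsum("xcldu,pc,pl,pd,pu->px", A, *s_tau)
        o = np.maximum(o, 0.0)
        o = o / o.sum(axis=-1, keepdims=True)
        out.append(pi @ o)
    return out


def select_action(
    predicted: dict[str, np.ndarray],
    model: GenerativeModel,
    current_expectations: list[np.ndarray],
    tie_break: str = "lowest",
    rng: np.random.Generator | None = None,
) -> int:
    """KL-minimizing action.

    For each candidate action the outcome distribution implied by applying
    B(a) to the current (Bayesian-model-averaged) state is compared with the
    predicted outcome distribution; the action with the smallest summed KL
    divergence over the modalities present in ``predicted`` wins.
    """
    modality_index = {"what": 0, "where": 1}
    kl = np.zeros(N_ACTIONS)
    for a in range(N_ACTIONS):
        implied_state = [
            np.einsum("ij,j->i", model.B[n][a], current_expectations[n])
            for n in range(len(current_expectations))
        ]
        implied = predictive_outcomes(model, implied_state)
        for name, p in predicted.items():
            q = implied[modality_index[name]]
            mask = p > 0
            kl[a] += float(np.sum(p[mask] * (np.log(p[mask]) - ln(q[mask]))))
    ties = np.flatnonzero(kl <= kl.min() + 1e-12)
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        return int(rng.choice(ties))
    return int(ties[0])


def _extend_predictions(
    model: GenerativeModel,
    parent: list[np.ndarray],
    policies: np.ndarray,
    t: int,
) -> list[np.ndarray]:
    """Initialize candidate-policy beliefs from the parent policy's expectations.

    Epochs < t are inherited; epochs >= t are forward-propagated under each
    candidate's actions (the pre-observation predictive used for the
    precision update's baseline).
    """
    P = policies.shape[0]
    T = model.T
    init = [np.repeat(p[None], P, axis=0).copy() for p in parent]
    for n, b in enumerate(model.B):
        for tau in range(max(t, 1), T):
            acts = policies[:, tau - 1]
            init[n][:, tau] = np.einsum(
                "pij,pj->pi", b[acts], init[n][:, tau - 1]
            )
    return init


def run_trial(
    model: GenerativeModel,
    scene: SceneConfiguration,
    seed: int | None = 0,
    max_saccades: int | None = None,
    action_mode: str = "argmin",
    tie_break: str = "random",
    g_horizon: int | None = 1,
    record_trace: bool = False,
) -> TrialRecord:
    """Simulate one full trial of saccadic foraging.

    The trial starts at central fixation and runs T epochs (T - 1 saccades at
    most); scoring freezes at the first choice-location action, but the
    simulation continues to T for trace completeness.
    """
    T = model.T
    if max_saccades is None:
        max_saccades = T - 1
    if max_saccades + 1 > T:
        raise ValueError("max_saccades + 1 must not exceed T")
    if action_mode not in ("argmin", "sampled"):
        raise ValueError(f"unknown action mode {action_mode!r}")
    if scene.context_index >= model.A[0].shape[1]:
        raise ValueError("scene and model dimensions are inconsistent")
    rng = np.random.default_rng(seed)

    observations = [env_step(scene, FIXATION)]
    history: list[int] = []
    beliefs: list[BeliefState] = []
    parent: list[np.ndarray] | None = None
    gamma = 1.0 / model.beta_prior
    iterations_total = 0
    epoch_iterations: list[np.ndarray] = []
    epoch_converged: list[np.ndarray] = []
    gamma_traces: list[np.ndarray] = []

    for t in range(1, T + 1):
        acting = t <= max_saccades and t < T
        pols = PolicySet(history, T)
        policies = pols.matrix if acting else np.asarray(
            [history + [history[-1] if history else FIXATION] * (T - 1 - len(history))],
            dtype=int,
        )
        if parent is None:
            init = None
            G_pre = None
        else:
            init = _extend_predictions(model, parent, policies, t - 1)
            G_pre, _ = expected_free_energy(model, init, current_epoch=t, horizon=g_horizon)
        s, F, n_iters, conv, F_trace, s_trace = update_states_batch(
            model, observations, policies, init, record_trace=record_trace
        )
        G, comps = expected_free_energy(model, s, current_epoch=t, horizon=g_horizon)
        pi, pi0, beta, gamma, g_trace = infer_precision(
            F, G, model.beta_prior, gamma_init=gamma, G_prior=G_pre
        )
        b = BeliefState(s=s, pi=pi, F=F, G=G, G_components=comps, gamma=gamma)
        if record_trace:
            b.trace = s_trace
        beliefs.append(b)
        iterations_total += int(n_iters.max())
        epoch_iterations.append(n_iters)
        epoch_converged.append(conv)
        gamma_traces.append(g_trace)

        if not acting:
            if t >= T:
                break
            # No more saccades allowed: re-use the executed policy's beliefs.
            parent = [x[0] for x in s]
            continue

        if action_mode == "sampled":
            a = int(rng.choice(N_ACTIONS, p=pi))
        else:
            predicted = bma_next_outcome(pi, s, model, epoch=t)
            current = [bm[t - 1] for bm in bma_marginals(pi, s)]
            a = select_action(
                {"what": predicted[0], "where": predicted[1]},
                model,
                current,
                tie_break=tie_break,
                rng=rng,
            )
        history.append(a)
        observations.append(env_step(scene, a))
        parent = [x[a] for x in s]

    choice = next((a for a in history if a in CHOICE_LOCATIONS), None)
    feedback = None
    if choice is not None:
        idx = history.index(choice)
        feedback = CUES[observations[idx + 1].what]

    return TrialRecord(
        scene=scene,
        actions=history,
        observations=observations,
        beliefs=beliefs,
        choice=choice,
        feedback=feedback,
        iterations_total=iterations_total,
        seed=seed,
        max_saccades=max_saccades,
        epoch_iterations=epoch_iterations,
        epoch_converged=epoch_converged,
        gamma_trace=gamma_traces,
        c_pref=model.c,
    )
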