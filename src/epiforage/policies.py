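"""Expected free energy, policy posterior and precision updating.

Policies are built on the fly: at each decision point the executed action
history is extended by one candidate action per saccade target, giving eight
candidate policies that share their prefix.  Each candidate's expected free
energy G accumulates, over the remaining epochs of the trial, the divergence
between predicted and preferred outcomes (risk) plus the expected ambiguity of
the likelihood mapping.  Equivalently G = -epistemic value - extrinsic value
(up to the preference normalization constant); both decompositions are stored
for diagnostics.

The policy posterior is a softmax of accumulated evidence and precision-
weighted expected free energy, pi = softmax(-F - gamma * G), against the prior
pi0 = softmax(-gamma * G).  The precision gamma = 1/beta is itself updated by
a fixed point that raises gamma when observations favor policies with low
expected free energy (the simulated dopamine signal) and lowers it otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import LOCATION_FACTOR, N_FACTORS, ln, softmax
from .task import N_ACTIONS, GenerativeModel

BETA_FLOOR = 1.0 / 64.0
PRECISION_TOL = 1e-4
PRECISION_MAX_ITERS = 8


@dataclass
class PolicySet:
    """Candidate policies at one decision point: shared history + one new action.

    ``matrix`` has shape (n_candidates, T-1): executed actions, the candidate
    action at the current transition, and the candidate repeated over the
    remaining transitions (the agent predicts staying put thereafter).
    """

    history: list[int]
    T: int
    n_actions: int = N_ACTIONS

    def __post_init__(self) -> None:
        if len(self.history) > self.T - 1:
            raise ValueError("history longer than the trial's transitions")

    @property
    def matrix(self) -> np.ndarray:
        t = len(self.history)
        pol = np.empty((self.n_actions, self.T - 1), dtype=int)
        pol[:, :t] = self.history
        for k in range(self.n_actions):
            pol[k, t:] = k
        return pol

    @property
    def horizon(self) -> int:
        return self.T - 1 - len(self.history)


def preference_distribution(C: np.ndarray) -> np.ndarray:
    """Preferences enter as unnormalized log-probabilities; normalize them."""
    return softmax(np.asarray(C, dtype=float))


def expected_free_energy(
    model: GenerativeModel,
    expectations: list[np.ndarray],
    current_epoch: int,
    horizon: int | None = 1,
):
    """Expected free energy of policy-conditioned predictions.

    ``expectations[n]`` has shape (P, T, dim_n); epochs after ``current_epoch``
    (1-based count of observed epochs) are the policy's predictions.
    ``horizon`` limits how many future epochs are accumulated: the default 1
    scores only the next outcome (the agent looks one move ahead); ``None``
    accumulates every remaining epoch of the trial.  Returns
    ``(G, components)`` where G has shape (P,) and ``components`` maps
    'risk', 'ambiguity', 'epistemic', 'extrinsic' to (P, n_future, n_modalities)
    arrays.
    """
    P, T = expectations[0].shape[:2]
    stop = T if horizon is None else min(T, current_epoch + horizon)
    future = list(range(current_epoch, stop))
    n_fut = len(future)
    comp = {
        k: np.zeros((P, n_fut, len(model.A)))
        for k in ("risk", "ambiguity", "epistemic", "extrinsic")
    }
    for m, A in enumerate(model.A):
        lnC = model.C[m] - np.log(np.exp(model.C[m]).sum())
        # Entropy of the likelihood per joint state (zero for one-hot columns).
        H = -np.sum(np.where(A > 0, A * np.log(np.maximum(A, 1e-16)), 0.0), axis=0)
        for j, tau in enumerate(future):
            s_tau = [expectations[n][:, tau] for n in range(N_FACTORS)]
            o = np.einsum("xcldu,pc,pl,pd,pu->px", A, *s_tau)
            o = np.maximum(o, 0.0)
            o = o / o.sum(axis=-1, keepdims=True)
            lno = ln(o)
            comp["risk"][:, j, m] = np.sum(o * (lno - lnC), axis=-1)
            comp["ambiguity"][:, j, m] = np.einsum("cldu,pc,pl,pd,pu->p", H, *s_tau)
            # Mutual information between states and outcomes under the
            # predictive joint: H(o) - E_s[H(o|s)].
            comp["epistemic"][:, j, m] = -np.sum(o * lno, axis=-1) - comp["ambiguity"][:, j, m]
            comp["extrinsic"][:, j, m] = o @ model.C[m]
    G = (comp["risk"] + comp["ambiguity"]).sum(axis=(1, 2))
    return G, comp


def policy_posterior(
    F: np.ndarray, G: np.ndarray, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior and prior beliefs about policies.

    pi = softmax(-F - gamma*G) combines accumulated evidence with the
    precision-weighted path integral of expected free energy; pi0 =
    softmax(-gamma*G) is the corresponding prior used in precision updating.
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(G))):
        raise ValueError("F and G must be finite")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return softmax(-F - gamma * G), softmax(-gamma * G)


def update_precision(
    pi: np.ndarray, pi0: np.ndarray, G: np.ndarray, beta_prior: float
) -> tuple[float, float]:
    """One step of the precision fixed point for given policy beliefs.

    beta = beta_prior + (pi - pi0) . G, floored at 1/64; gamma = 1/beta.
    When observations favor policies with low expected free energy the inner
    product is negative and precision rises (a simulated dopamine burst).
    """
    if beta_prior <= 0:
        raise ValueError("beta_prior must be positive")
    pi = np.asarray(pi, dtype=float)
    pi0 = np.asarray(pi0, dtype=float)
    for q in (pi, pi0):
        if not np.isclose(q.sum(), 1.0, atol=1e-6):
            raise ValueError("policy distributions must be normalized")
    beta = float(beta_prior + (pi - pi0) @ np.asarray(G, dtype=float))
    beta = max(beta, BETA_FLOOR)
    return beta, 1.0 / beta


def infer_precision(
    F: np.ndarray,
    G: np.ndarray,
    beta_prior: float,
    gamma_init: float | None = None,
    G_prior: np.ndarray | None = None,
):
    """Jointly iterate policy posterior and precision to their fixed point.

    The prior beliefs pi0 are evaluated on ``G_prior`` (expected free energy
    before the current observation was assimilated) when provided, so that the
    update implements the difference in expected free energy with and without
    the observation; otherwise both use ``G``.  Returns
    ``(pi, pi0, beta, gamma, gamma_trace)`` with one trace entry per inner
    iteration.
    """
    G = np.asarray(G, dtype=float)
    Gp = G if G_prior is None else np.asarray(G_prior, dtype=float)
    beta = 1.0 / gamma_init if gamma_init else beta_prior
    gamma = 1.0 / beta
    trace = []
    pi = pi0 = None
    for _ in range(PRECISION_MAX_ITERS):
        pi, _ = policy_posterior(F, G, gamma)
        pi0 = softmax(-gamma * Gp)
        beta_new = float(beta_prior + pi @ G - pi0 @ Gp)
        beta_new = max(beta_new, BETA_FLOOR)
        gamma = 1.0 / beta_new
        trace.append(gamma)
        if abs(beta_new - beta) < PRECISION_TOL:
            beta = beta_new
            break
        beta = beta_new
    return pi, pi0, beta, gamma, np.array(trace)


def bma_marginals(pi: np.ndarray, expectations: list[np.ndarray]) -> list[np.ndarray]:
    """Bayesian model average of state expectations over policies, (T, dim)."""
    return [np.einsum("p,ptd->td", pi, e) for e in expectations]


def predictive_outcomes(
    model: GenerativeModel, s_tau: list[np.ndarray]
) -> list[np.ndarray]:
    """Per-modality outcome distributions implied by factor expectations (dim,)."""
    out = []
    for A in model.A:
        o = np.einsum("xcldu,c,l,d,u->x", A, *s_tau)
        o = np.maximum(o, 0.0)
        out.append(o / o.sum())
    return out
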