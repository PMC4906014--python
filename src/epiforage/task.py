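"""Scene-construction task: generative model and ground-truth environment.

A trial presents a 2x2 visual scene whose category is defined purely by the
spatial relation between a bird and a companion object:

* ``feed`` -- a seed sits in the quadrant horizontally adjacent to the bird,
* ``flee`` -- a cat sits in that quadrant,
* ``wait`` -- a seed sits in the quadrant diagonally opposite the bird.

All remaining quadrants hold a null (distractor) cue.  The absolute positions
are nuisance variables: each base scene may be reflected about the vertical
axis (``flip_lr``, swapping left/right columns) and/or the horizontal axis
(``flip_ud``, swapping top/bottom rows), giving 3 x 2 x 2 = 12 distinct
layouts.

The agent's generative model is a discrete partially observed Markov decision
process with four hidden-state factors -- context (3), sampled location (8),
and the two binary reflections -- and two outcome modalities: *what* is seen
(null, seed, bird, cat, right- or wrong-feedback) and *where* it is seen
(fixation, four quadrants, three choice locations).  Likelihoods are
deterministic (one-hot columns); only the location factor is controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

# Fixed index conventions; serialized traces rely on this ordering.
CONTEXTS = ("flee", "feed", "wait")
LOCATIONS = (
    "fixation",
    "UL",
    "LL",
    "UR",
    "LR",
    "choose-flee",
    "choose-feed",
    "choose-wait",
)
CUES = ("null", "seed", "bird", "cat", "right", "wrong")
QUADRANTS = ("UL", "UR", "LL", "LR")
FACTORS = ("context", "location", "flip_lr", "flip_ud")
FACTOR_DIMS = (3, 8, 2, 2)

N_CONTEXTS = len(CONTEXTS)
N_LOCATIONS = len(LOCATIONS)
N_CUES = len(CUES)
N_ACTIONS = N_LOCATIONS

FIXATION = LOCATIONS.index("fixation")
CHOICE_LOCATIONS = tuple(LOCATIONS.index(f"choose-{c}") for c in CONTEXTS)
QUADRANT_LOCATIONS = tuple(LOCATIONS.index(q) for q in QUADRANTS)

# Quadrant name -> (row, col) on the 2x2 grid.
_GRID = {"UL": (0, 0), "UR": (0, 1), "LL": (1, 0), "LR": (1, 1)}
_GRID_INV = {v: k for k, v in _GRID.items()}

# Base scenes: bird at UR; companion at UL (adjacent) for flee/feed, and at
# LL (diagonal) for wait.  Reflections generate the other placements.
_BASE_SCENES = {
    "flee": {"UL": "cat", "UR": "bird"},
    "feed": {"UL": "seed", "UR": "bird"},
    "wait": {"LL": "seed", "UR": "bird"},
}


@dataclass(frozen=True)
class SceneConfiguration:
    """True hidden cause of a trial and the 2x2 cue layout it induces."""

    context: str
    flip_lr: int
    flip_ud: int
    layout: dict[str, str] = field(compare=False)

    @property
    def context_index(self) -> int:
        return CONTEXTS.index(self.context)

    def joint_state(self, location: int) -> tuple[int, int, int, int]:
        """Joint hidden-state index tuple (context, location, lr, ud)."""
        return (self.context_index, location, self.flip_lr, self.flip_ud)


@dataclass(frozen=True)
class Observation:
    """One bimodal outcome: the cue seen (*what*) and the location (*where*)."""

    what: int
    where: int

    def __post_init__(self) -> None:
        if not 0 <= self.what < N_CUES:
            raise ValueError(f"invalid 'what' outcome index: {self.what}")
        if not 0 <= self.where < N_LOCATIONS:
            raise ValueError(f"invalid 'where' outcome index: {self.where}")

    @property
    def what_name(self) -> str:
        return CUES[self.what]

    @property
    def where_name(self) -> str:
        return LOCATIONS[self.where]


def scene_layout(context: str, flip_lr: int, flip_ud: int) -> SceneConfiguration:
    """Build the scene configuration for a context and reflection pair.

    ``flip_lr`` mirrors about the vertical axis (left/right columns swap);
    ``flip_ud`` mirrors about the horizontal axis (top/bottom rows swap).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}; expected one of {CONTEXTS}")
    if flip_lr not in (0, 1) or flip_ud not in (0, 1):
        raise ValueError("flip_lr and flip_ud must be 0 or 1")
    layout = {q: "null" for q in QUADRANTS}
    for quad, cue in _BASE_SCENES[context].items():
        row, col = _GRID[quad]
        if flip_lr:
            col = 1 - col
        if flip_ud:
            row = 1 - row
        layout[_GRID_INV[(row, col)]] = cue
    return SceneConfiguration(context=context, flip_lr=int(flip_lr), flip_ud=int(flip_ud), layout=layout)


def all_scenes() -> list[SceneConfiguration]:
    """The 12 scene configurations, in (context, flip_lr, flip_ud) order."""
    return [
        scene_layout(c, lr, ud)
        for c in CONTEXTS
        for lr in (0, 1)
        for ud in (0, 1)
    ]


def random_scene(rng: np.random.Generator) -> SceneConfiguration:
    """Sample a scene uniformly from the 12 configurations."""
    context = CONTEXTS[rng.integers(N_CONTEXTS)]
    return scene_layout(context, int(rng.integers(2)), int(rng.integers(2)))


def _cue_at(context: str, flip_lr: int, flip_ud: int, location: int) -> int:
    """Deterministic 'what' outcome for a joint hidden state."""
    if location == FIXATION:
        return CUES.index("null")
    if location in QUADRANT_LOCATIONS:
        layout = scene_layout(context, flip_lr, flip_ud).layout
        return CUES.index(layout[LOCATIONS[location]])
    # Choice location: feedback depends on whether the report matches context.
    reported = CONTEXTS[CHOICE_LOCATIONS.index(location)]
    return CUES.index("right" if reported == context else "wrong")


@dataclass
class GenerativeModel:
    """Arrays (A, B, C, D) plus precision prior and horizon for one agent.

    ``A`` holds one likelihood array per modality over the joint state space
    (3 x 8 x 2 x 2); ``B`` one transition array per factor with shape
    (n_actions, dim, dim) mapping ``s_tau`` to ``s_tau+1``; ``C`` the
    log-preference vector per modality; ``D`` the initial prior per factor.
    """

    A: list[np.ndarray]
    B: list[np.ndarray]
    C: list[np.ndarray]
    D: list[np.ndarray]
    beta_prior: float
    T: int
    c: float

    @property
    def n_actions(self) -> int:
        return self.B[1].shape[0]

    @property
    def n_states(self) -> int:
        return int(np.prod(FACTOR_DIMS))

    def to_json(self) -> str:
        doc = {
            "factors": list(FACTORS),
            "factor_dims": list(FACTOR_DIMS),
            "modalities": ["what", "where"],
            "modality_dims": [N_CUES, N_LOCATIONS],
            "A": [a.reshape(a.shape[0], -1).tolist() for a in self.A],
            "B": [b.tolist() for b in self.B],
            "C": [c.tolist() for c in self.C],
            "D": [d.tolist() for d in self.D],
            "beta_prior": self.beta_prior,
            "T": self.T,
            "c": self.c,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "GenerativeModel":
        doc = json.loads(text)
        dims = tuple(doc["factor_dims"])
        A = [
            np.asarray(a, dtype=float).reshape((m,) + dims)
            for a, m in zip(doc["A"], doc["modality_dims"])
        ]
        B = [np.asarray(b, dtype=float) for b in doc["B"]]
        C = [np.asarray(c, dtype=float) for c in doc["C"]]
        D = [np.asarray(d, dtype=float) for d in doc["D"]]
        return cls(A=A, B=B, C=C, D=D, beta_prior=doc["beta_prior"], T=doc["T"], c=doc["c"])


def build_scene_model(c: float = 2.0, beta_prior: float = 1.0, T: int = 6) -> GenerativeModel:
    """Construct the scene-construction generative model.

    Parameters
    ----------
    c:
        Preference strength: log-preference ``c`` for right feedback and
        ``-2c`` for wrong feedback (zero for all cues and locations).
    beta_prior:
        Prior expectation of the inverse precision of policy beliefs.
    T:
        Number of outcome epochs per trial (T - 1 saccades).
    """
    if c < 0:
        raise ValueError("preference strength c must be non-negative")
    if beta_prior <= 0:
        raise ValueError("beta_prior must be positive")
    if T < 2:
        raise ValueError("T must be at least 2")

    A1 = np.zeros((N_CUES,) + FACTOR_DIMS)
    A2 = np.zeros((N_LOCATIONS,) + FACTOR_DIMS)
    for ci, context in enumerate(CONTEXTS):
        for loc in range(N_LOCATIONS):
            for lr in (0, 1):
                for ud in (0, 1):
                    A1[_cue_at(context, lr, ud, loc), ci, loc, lr, ud] = 1.0
                    A2[loc, ci, loc, lr, ud] = 1.0

    B = []
    for f, dim in enumerate(FACTOR_DIMS):
        if f == 1:  # controllable location factor: action k moves to k
            b = np.zeros((N_ACTIONS, dim, dim))
            for k in range(N_ACTIONS):
                b[k, k, :] = 1.0
        else:
            b = np.broadcast_to(np.eye(dim), (N_ACTIONS, dim, dim)).copy()
        B.append(b)

    C1 = np.zeros(N_CUES)
    C1[CUES.index("right")] = c
    C1[CUES.index("wrong")] = -2.0 * c
    C2 = np.zeros(N_LOCATIONS)

    D = [np.full(N_CONTEXTS, 1.0 / N_CONTEXTS)]
    d_loc = np.zeros(N_LOCATIONS)
    d_loc[FIXATION] = 1.0
    D.append(d_loc)
    D.append(np.full(2, 0.5))
    D.append(np.full(2, 0.5))

    return GenerativeModel(A=[A1, A2], B=B, C=[C1, C2], D=D, beta_prior=float(beta_prior), T=int(T), c=float(c))


def env_step(scene: SceneConfiguration, action: int) -> Observation:
    """Emit the deterministic outcome of saccading to ``action``.

    The environment is computed from the scene layout and category rules
    directly (not by indexing the model's A arrays), so that agreement with
    the generative model is a checkable property rather than a tautology.
    """
    if not 0 <= action < N_ACTIONS:
        raise ValueError(f"invalid action index {action}; must be in [0, {N_ACTIONS})")
    if action == FIXATION:
        what = CUES.index("null")
    elif action in QUADRANT_LOCATIONS:
        what = CUES.index(scene.layout[LOCATIONS[action]])
    else:
        reported = CONTEXTS[CHOICE_LOCATIONS.index(action)]
        what = CUES.index("right" if reported == scene.context else "wrong")
    return Observation(what=what, where=action)
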