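"""Simulated electrophysiology and behavioral metrics.

Belief updating leaves an iteration-resolved trace: 16 update bins between
successive saccades, with outcomes arriving every 250 ms.  Units are the
posterior expectations of one hidden-state factor at one represented epoch;
arranging them as (represented epoch x state) rows against (elapsed epoch x
iteration bin) columns gives a firing-rate raster whose diagonal blocks hold
beliefs about the present, with postdiction above and prediction below.
Local field potentials are the first temporal difference of those rates, and
the simulated dopamine signal mixes the policy-precision trace with its rate
of change.

Behavioral performance is summarized per trial (accuracy, decision time in
saccades, outcome utility, iteration-count reaction time) and aggregated over
a grid of preference strength x prior precision levels (the performance
sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .agent import TrialRecord, run_trial
from .inference import MAX_ITERS
from .task import FACTOR_DIMS, FACTORS, build_scene_model, random_scene

EPOCH_MS = 250.0
BIN_S = EPOCH_MS / 1000.0 / MAX_ITERS
FS = 1.0 / BIN_S  # 64 Hz
LFP_BAND_HZ = (2.0, 8.0)  # half-power points of the 4 Hz band-pass
DOPAMINE_MIX = 4.0

DEFAULT_C_LEVELS = tuple(np.linspace(0.0, 4.0, 8))
DEFAULT_BETA_LEVELS = tuple(2.0 ** np.linspace(3.0, -4.0, 8))


@dataclass
class ResponseTraces:
    """Unit rates, LFPs and dopamine for one trial and one factor."""

    raster: np.ndarray  # (epochs * states, epochs * 16)
    lfp: np.ndarray  # same shape; first temporal difference
    lfp_avg: np.ndarray  # (epochs * 16,)
    lfp_avg_filtered: np.ndarray
    dopamine: np.ndarray
    time_axis: np.ndarray  # seconds


@dataclass
class SweepResult:
    """Accuracy / decision-time / reaction-time grids over (preference, precision)."""

    c_levels: np.ndarray
    beta_levels: np.ndarray
    accuracy: np.ndarray  # percent, (n_c, n_beta)
    decision_time: np.ndarray  # mean saccades
    reaction_time: np.ndarray  # mean variational iterations per epoch
    n_trials: int
    seed: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.c_levels):
            for j, b in enumerate(self.beta_levels):
                rows.append(
                    {
                        "c": c,
                        "beta": b,
                        "accuracy": self.accuracy[i, j],
                        "decision_time": self.decision_time[i, j],
                        "reaction_time": self.reaction_time[i, j],
                        "n": self.n_trials,
                    }
                )
        return pd.DataFrame(rows)


def firing_raster(trial: TrialRecord, factor: str = "context") -> np.ndarray:
    """Unit activity in image format for one hidden-state factor.

    Row blocks are represented epochs (states within a block); column blocks
    are elapsed epochs, 16 iteration bins each.  Within a column block, bins
    show the Bayesian-model-averaged expectations over that epoch's update
    iterations (epochs that converged early hold their final value).
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    f = FACTORS.index(factor)
    dim = FACTOR_DIMS[f]
    if not trial.beliefs or not trial.beliefs[0].trace:
        raise ValueError("trial was run without record_trace=True")
    T = trial.beliefs[0].s[f].shape[1]
    n_epochs = len(trial.beliefs)
    raster = np.zeros((T * dim, n_epochs * MAX_ITERS))
    for e, b in enumerate(trial.beliefs):
        snaps = b.trace  # list over iterations of per-factor (P, T, dim)
        for i in range(MAX_ITERS):
            snap = snaps[min(i + 1, len(snaps) - 1)][f]
            bma = np.einsum("p,ptd->td", b.pi, snap)  # (T, dim)
            raster[:, e * MAX_ITERS + i] = bma.reshape(-1)
    return raster


def simulated_lfp(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LFPs as the rate of change of unit firing.

    Returns ``(lfp, lfp_avg, lfp_avg_filtered)``: per-unit first temporal
    differences, their mean across units, and a zero-phase band-limited
    version of the mean (second-order Butterworth band-pass centered on the
    theta range, half-power points 2 and 8 Hz, applied forward and backward).
    """
    lfp = np.diff(raster, axis=1, prepend=raster[:, :1])
    lfp_avg = lfp.mean(axis=0)
    sos = sps.butter(2, LFP_BAND_HZ, btype="bandpass", fs=FS, output="sos")
    if lfp_avg.size > 24:
        filtered = sps.sosfiltfilt(sos, lfp_avg)
    else:  # too short for zero-phase padding; degenerate traces stay raw
        filtered = np.zeros_like(lfp_avg)
    return lfp, lfp_avg, filtered


def dopamine_signal(gamma_trace: np.ndarray, mix: float = DOPAMINE_MIX) -> np.ndarray:
    """Simulated dopamine: precision plus ``mix`` times its rate of change."""
    g = np.asarray(gamma_trace, dtype=float)
    if np.any(g <= 0):
        raise ValueError("precision trace must be positive")
    dg = np.diff(g, prepend=g[:1])
    return g + mix * dg


def precision_bins(trial: TrialRecord) -> np.ndarray:
    """Per-bin precision series: each epoch's inner-loop trace padded to 16 bins."""
    out = []
    for g in trial.gamma_trace:
        g = np.asarray(g, dtype=float)
        pad = np.full(MAX_ITERS - len(g), g[-1]) if len(g) < MAX_ITERS else []
        out.append(np.concatenate([g[:MAX_ITERS], pad]))
    return np.concatenate(out)


def response_traces(trial: TrialRecord, factor: str = "context") -> ResponseTraces:
    """Raster, LFP and dopamine traces for one recorded trial."""
    raster = firing_raster(trial, factor)
    lfp, lfp_avg, filt = simulated_lfp(raster)
    gamma = precision_bins(trial)
    return ResponseTraces(
        raster=raster,
        lfp=lfp,
        lfp_avg=lfp_avg,
        lfp_avg_filtered=filt,
        dopamine=dopamine_signal(gamma),
        time_axis=np.arange(raster.shape[1]) * BIN_S + BIN_S,
    )


def score_trial(trial: TrialRecord, C_what: np.ndarray | None = None) -> dict:
    """Performance record of one trial.

    ``correct`` requires right feedback with no wrong feedback ever; trials
    with no choice count as incorrect with decision time at the saccade
    budget.  ``utility`` is the time-average log-preference of the observed
    cue outcomes (zero on cues, c on right feedback, -2c on wrong);
    ``reaction_time`` is the mean variational iterations per inference epoch.
    """
    if C_what is None:
        c = trial.c_pref or 0.0
        C_what = np.array([0.0, 0.0, 0.0, 0.0, c, -2.0 * c])
    return {
        "correct": trial.correct,
        "chose": trial.choice is not None,
        "decision_time": trial.decision_time,
        "utility": float(np.mean([C_what[o.what] for o in trial.observations])),
        "reaction_time": trial.iterations_total / max(len(trial.beliefs), 1),
    }


def run_sweep(
    n_trials: int,
    c_levels=DEFAULT_C_LEVELS,
    beta_levels=DEFAULT_BETA_LEVELS,
    seed: int = 0,
    T: int = 9,
    max_saccades: int = 8,
    action_mode: str = "argmin",
) -> SweepResult:
    """Aggregate trial scores over the preference x precision grid.

    Each cell runs ``n_trials`` independently seeded random scenes; trial
    seeds derive from ``(seed, cell, trial)`` so the grids are invariant to
    evaluation order.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    c_levels = np.asarray(c_levels, dtype=float)
    beta_levels = np.asarray(beta_levels, dtype=float)
    acc = np.zeros((len(c_levels), len(beta_levels)))
    dt = np.zeros_like(acc)
    rt = np.zeros_like(acc)
    for i, c in enumerate(c_levels):
        for j, beta in enumerate(beta_levels):
            model = build_scene_model(c=c, beta_prior=beta, T=T)
            scores = [
                run_cell_trial(model, seed, i, j, k, max_saccades, action_mode)
                for k in range(n_trials)
            ]
            acc[i, j] = 100.0 * np.mean([s["correct"] for s in scores])
            dt[i, j] = np.mean([s["decision_time"] for s in scores])
            rt[i, j] = np.mean([s["reaction_time"] for s in scores])
    return SweepResult(
        c_levels=c_levels,
        beta_levels=beta_levels,
        accuracy=acc,
        decision_time=dt,
        reaction_time=rt,
        n_trials=n_trials,
        seed=seed,
    )


def run_cell_trial(model, seed, i, j, k, max_saccades, action_mode) -> dict:
    """One seeded trial of one sweep cell (order-independent seeding)."""
    rng = np.random.default_rng([seed, i, j, k])
    scene = random_scene(rng)
    trial = run_trial(
        model,
        scene,
        seed=int(rng.integers(2**31)),
        max_saccades=max_saccades,
        action_mode=action_mode,
    )
    return score_trial(trial)
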