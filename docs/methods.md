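# Methods

## The task

A trial presents a 2x2 scene containing a bird and one companion object.  The
category of the scene is carried entirely by their spatial relation: a seed
horizontally adjacent to the bird means *feed*, a cat in that position means
*flee*, and a seed diagonally opposite the bird means *wait*.  Each of the
three base scenes (bird at the upper right; companion at the upper left for
feed/flee, lower left for wait) can be reflected about the vertical and/or
horizontal axis, giving 3 x 2 x 2 = 12 distinct layouts.  The agent starts at
central fixation, samples one location per 250 ms epoch (four quadrants, or
three choice locations that return *right*/*wrong* feedback), and is scored
on whether it reports the correct category.

Scenes are drawn uniformly at random from the 12 configurations; these are
the study conditions for every batch statistic in the tests and the
acceptance script.  The generator emulates nothing beyond this: there are no
task-irrelevant distractors, no probabilistic cue-category relations, no
perceptual noise, and no inter-trial belief carry-over, so passing tests
speak to the internal consistency of the inference scheme, not to fits of
empirical eye movements.

## Generative model

Four hidden-state factors (context 3, sampled location 8, two binary
reflections; 96 joint states) and two outcome modalities (*what*: null, seed,
bird, cat, right, wrong; *where*: the 8 locations).  Likelihood arrays are
deterministic (one-hot columns): the *what* outcome is the layout cue at the
sampled quadrant, null at fixation, and right/wrong feedback at choice
locations; the *where* outcome reports the location factor.  Transitions are
identities except the fully controllable location factor (action k moves to
location k from anywhere).  Priors are uniform over context and reflections
and a delta on fixation.  Preferences are log-preferences over outcomes:
`C_what = [0, 0, 0, 0, c, -2c]` with preference strength `c` (default 2;
feedback is the only valued outcome and wrong feedback is penalized twice as
strongly), `C_where = 0`.

## Belief updating

The posterior over hidden states is factorized across factors and epochs (a
mean-field assumption).  Policy-conditioned expectations are updated by
sweeps over epochs; factor `n` at epoch `tau` receives the message

    v = [ln D          (tau = 1)
         ln B(a) s_prev (else)]  +  ln B(a)^T s_next  +  ln E_{q_-n} P(o | s)

and moves a fraction `kappa = 0.25` toward it in log space,
`s <- softmax((1 - kappa) ln s + kappa v)`, for at most 16 sweeps, stopping
early once successive free-energy values differ by less than 1/128.  Past
epochs are re-swept at every epoch (postdiction); future epochs carry no
likelihood term and are predictions under the policy.  Logs are floored at
`ln 1e-16` because the deterministic likelihoods contain exact zeros.

The likelihood message takes the log *after* contracting the likelihood over
the other factors' expectations.  This matters: contracting `ln P` instead
injects floor-magnitude penalties whenever the factorized posterior cannot
represent a correlation (for example between context and reflection), which
destabilizes the sweeps and erases the epistemic differences between saccade
targets.  With the log-of-contraction form, irrepresentable correlations
degrade gracefully into genuinely uncertain marginals.

Free energy is reported as complexity minus accuracy, accumulated per factor
and epoch: complexity against the forward (empirical-prior) message,
accuracy as the expected log-likelihood of observed outcomes.  On problems
with a single uncertain factor this equals the exact negative log evidence at
the fixed point and bounds it for any expectations; on multi-factor problems
it is a message-based objective that can sit far above the true evidence when
the mean field is frustrated.  Because the sweeps apply forward and backward
transition messages in full, F can wobble by ~1e-4 once a fixed point is
reached; each policy's state is therefore frozen at its convergence
iteration, reverting the convergence-triggering half-sweep if it nudged F
upward, which makes the final F never exceed the initial F by construction.

The 16-iteration budget with early stopping is a temporal scheduling choice:
under the default conditions roughly 88-89% of policy-conditioned inference
epochs converge within it, and the per-epoch iteration count doubles as a
hardware-independent reaction-time proxy.

## Policies, expected free energy, precision

Policies are built on the fly: the executed history extended by one candidate
action per saccade target (eight candidates sharing their prefix), each
initialized from the executed parent's expectations.  Expected free energy
per candidate is risk plus ambiguity per future epoch and modality: risk is
the KL divergence from the predicted outcome distribution to the normalized
preference distribution `softmax(C)` (preferences are defined only up to an
additive constant, which this normalization absorbs); ambiguity is the
expected likelihood entropy, identically zero under this task's one-hot
likelihoods.  The equivalent epistemic (state-outcome mutual information) and
extrinsic (expected preference) components are stored for diagnostics and
tested against the identity
`-epistemic - extrinsic = risk + ambiguity - logsumexp(C)`.

G scores the next epoch only by default (`g_horizon=1`): the agent looks one
move ahead.  Accumulating G over all remaining epochs (`g_horizon=None`) is
available but multiplies the effective precision by the remaining horizon,
which collapses the behavioral differences between prior-precision levels;
with the one-step default the low-precision regime behaves qualitatively
differently from the high-precision one (see the sweep below).

The policy posterior is `pi = softmax(-F - gamma G)` with prior
`pi0 = softmax(-gamma G)`.  The precision `gamma = 1/beta` follows a fixed
point `beta = beta_prior + pi . G_post - pi0 . G_pre` (at most 8 inner
iterations, tolerance 1e-4, beta floored at 1/64), where `G_pre` is evaluated
on the pre-observation predictive beliefs and `G_post` after assimilating the
epoch's outcome.  Precision therefore tracks the difference in expected free
energy with and without the current observation: observations that make
low-G policies more credible raise gamma (a simulated dopamine burst), and
disappointing outcomes lower it (phasic suppression).  With one-step shared-
history policies the per-policy F is identical across candidates, so using a
single G in both softmaxes would freeze gamma at its prior; the pre/post
split restores the intended dynamics and reduces to the single-G rule
whenever nothing was learned.

## Action selection

The predicted next outcome is a Bayesian model average of the candidates'
predictions weighted by `pi`.  Each action is scored by the KL divergence
between that prediction and the outcome implied by applying the action's
transition to the model-averaged current state, summed over both outcome
modalities, and the argmin is executed.  Including the *what* modality is
what couples decisiveness to precision: a choice location is selected only
when the predicted feedback mass outweighs the predicted cue/null mass,
which requires a sharp policy posterior.

Exact ties are broken by a seeded draw by default.  Ties are structural in
this task: when the factorized posterior cannot hold a context-reflection
correlation, all quadrants carry exactly equal expected free energy, and a
fixed-index tie-break would resample one location indefinitely.  A
deterministic lowest-index mode and a mode that samples the saccade target
from the posterior predictive over locations are available by configuration.

Trials default to T = 6 epochs (5 saccades) for single-trial work and T = 9
(up to 8 saccades) for the performance sweep.  After a choice the location
factor stays at the choice location and feedback repeats; scoring freezes at
the first choice.  Trials without any choice are scored incorrect with
decision time at the saccade budget (the `chose` flag in trial scores allows
recomputing accuracy restricted to choosing trials).

## Simulated responses

Rasters arrange the model-averaged expectations of one factor as
(represented epoch x state) rows against (elapsed epoch x 16 iteration bins)
columns; diagonal blocks are beliefs about the present, blocks above are
postdiction, blocks below prediction.  Epochs that converge early hold their
final value for the remaining bins.  With 250 ms per epoch the bin rate is
64 Hz.  LFPs are the first temporal difference of unit rates; the average
LFP is additionally band-limited by a second-order zero-phase Butterworth
band-pass with half-power points at 2 and 8 Hz (a "4 Hz" theta-band filter;
the spectral contract is tested on white noise).  Simulated dopamine is
`gamma + 4 * dgamma/dt` on the per-bin precision trace.

## Performance sweep

Preference levels: 8 values equally spaced from 0 to 4.  Precision levels:
prior beta log-spaced over 2^3 ... 2^-4, spanning near-uniform to
near-deterministic policy selection; this range is a free design choice
recorded in the configuration.  Each cell runs independently seeded random
scenes (seeds derive from (seed, cell, trial), so grids are order-invariant
and bit-reproducible).  Accuracy is the percentage of trials with right and
no wrong feedback; decision time the mean saccades to any choice; reaction
time the mean variational iterations per epoch (wall-clock times are not
portable and are not reported).  The tests probe this grid at 128 trials per
corner cell and 3-8 trials per cell elsewhere; the full 8 x 8 x 300 grid is
available through the command line (`epiforage sweep`).

## Oracles

Exact joint inference enumerates all 96 configurations and conditions on the
observation history; it exposes the mean field's overconfidence (after a
single null at the lower-right quadrant the exact probability of *wait* is
exactly 1/3 while the factorized marginal collapses toward zero).  Expected
free energy is validated against a brute-force evaluation that materializes
the joint predictive distribution and loops over every state and outcome.
The worst-case sampling-strategy search is an exhaustive memoized recursion
over information sets (subsets of the 12 configurations): internal nodes
sample a quadrant and branch on the cue seen, leaves are choices, and the
returned depth counts the choice as a move.  It returns 4 for the full task:
three observed quadrants always determine the layout (whatever the third
sample shows, the unseen quadrant's content and hence the spatial relation is
deducible), and no two-sample strategy separates the six configurations left
by an initial null.  A worst case of 5 arises only if one demands that both
objects be directly observed rather than inferred.

## Known limitations

The mean-field agent inherits the approximation's pathologies: it can commit
to "not wait" on evidence that exactly ties the contexts, and in ambiguous
feed-versus-wait situations its information-seeking signal goes flat (all
targets equally valuable), where only the seeded tie-break keeps it
exploring.  Dopamine bursts saturate when the precision fixed point hits the
beta floor of 1/64.  The simulator makes no attempt to model oculomotor
kinematics, continuous time, or learning of the likelihood/transition arrays.
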