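import numpy as np
import pytest

from epiforage.inference import softmax, update_states_batch
from epiforage.oracles import brute_force_G
from epiforage.policies import (
    PolicySet,
    expected_free_energy,
    infer_precision,
    policy_posterior,
    update_precision,
)
from epiforage.task import (
    FACTOR_DIMS,
    FIXATION,
    LOCATIONS,
    build_scene_model,
    env_step,
    scene_layout,
)

UL, UR, LR = (LOCATIONS.index(q) for q in ("UL", "UR", "LR"))


def _random_expectations(rng, T, n_policies=1):
    out = []
    for d in FACTOR_DIMS:
        x = rng.random((n_policies, T, d))
        out.append(x / x.sum(axis=-1, keepdims=True))
    return out


class TestPolicySet:
    def test_eight_candidates_share_the_executed_prefix(self):
        ps = PolicySet(history=[4, 2], T=6)
        mat = ps.matrix
        assert mat.shape == (8, 5)
        assert np.all(mat[:, :2] == [4, 2])
        assert list(mat[:, 2]) == list(range(8))
        assert ps.horizon == 3

    def test_history_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            PolicySet(history=[0] * 6, T=6)


class TestExpectedFreeEnergy:
    def test_matches_brute_force_on_random_beliefs(self):
        """Factorized evaluation equals explicit joint-state summation."""
        rng = np.random.default_rng(42)
        m = build_scene_model(T=3)
        for _ in range(20):
            exp = _random_expectations(rng, m.T)
            G, _ = expected_free_energy(m, exp, current_epoch=1, horizon=None)
            Gb = brute_force_G(m, [e[0] for e in exp], epochs=[1, 2])
            assert G[0] == pytest.approx(Gb, abs=1e-8)

    def test_delta_beliefs_have_zero_epistemic_value(self):
        m = build_scene_model(T=3)
        exp = []
        for d in FACTOR_DIMS:
            x = np.zeros((1, 3, d))
            x[..., 0] = 1.0
            exp.append(x)
        _, comp = expected_free_energy(m, exp, current_epoch=1, horizon=None)
        assert np.all(np.abs(comp["epistemic"]) < 1e-9)

    def test_ambiguity_identically_zero_under_one_hot_likelihoods(self):
        rng = np.random.default_rng(0)
        m = build_scene_model(T=3)
        _, comp = expected_free_energy(
            m, _random_expectations(rng, m.T, 4), current_epoch=1, horizon=None
        )
        assert np.all(comp["ambiguity"] == 0.0)

    def test_epistemic_value_nonnegative(self):
        rng = np.random.default_rng(1)
        m = build_scene_model(T=4)
        _, comp = expected_free_energy(
            m, _random_expectations(rng, m.T, 8), current_epoch=1, horizon=None
        )
        assert np.all(comp["epistemic"] >= -1e-9)

    def test_decomposition_identity(self):
        """-epistemic - extrinsic = risk + ambiguity - logsumexp(C), per
        epoch and modality, on random belief states."""
        rng = np.random.default_rng(2)
        m = build_scene_model(c=2.0, T=3)
        lse = np.array([np.log(np.exp(C).sum()) for C in m.C])
        _, comp = expected_free_energy(
            m, _random_expectations(rng, m.T, 4), current_epoch=1, horizon=None
        )
        lhs = -comp["epistemic"] - comp["extrinsic"]
        rhs = comp["risk"] + comp["ambiguity"] - lse[None, None, :]
        assert np.allclose(lhs, rhs, atol=1e-6)

    def test_unvisited_quadrant_beats_revisit_when_preferences_are_flat(self):
        """Pure exploration: with C = 0, sampling a known location carries no
        information gain, so an unvisited quadrant has strictly lower G."""
        m = build_scene_model(c=0.0, T=6)
        scene = scene_layout("flee", 0, 0)
        obs = [env_step(scene, FIXATION), env_step(scene, LR)]
        candidates = PolicySet(history=[LR], T=6).matrix
        s, _, _, _, _, _ = update_states_batch(m, obs, candidates)
        G, comp = expected_free_energy(m, s, current_epoch=2)
        assert G[UL] < G[LR] - 1e-6  # unvisited UL strictly beats revisiting LR
        # and with C = 0 the G-ranking equals the (negative) epistemic ranking
        epi = comp["epistemic"].sum(axis=(1, 2))
        assert np.array_equal(np.argsort(G), np.argsort(-epi))


class TestPolicyPosterior:
    def test_equal_evidence_gives_uniform_beliefs(self):
        pi, pi0 = policy_posterior(np.zeros(4), np.ones(4) * 2.0, gamma=1.0)
        assert np.allclose(pi, 0.25) and np.allclose(pi0, 0.25)

    def test_closed_form_softmax_example(self):
        pi, _ = policy_posterior(np.zeros(2), np.array([-np.log(3.0), 0.0]), gamma=1.0)
        assert np.allclose(pi, [0.75, 0.25])

    def test_vanishing_precision_leaves_evidence_only(self):
        F = np.array([0.0, 1.0, 2.0])
        G = np.array([5.0, -3.0, 0.0])
        pi, _ = policy_posterior(F, G, gamma=1e-12)
        assert np.allclose(pi, softmax(-F), atol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior(np.array([np.inf, 0.0]), np.zeros(2), 1.0)
        with pytest.raises(ValueError):
            policy_posterior(np.zeros(2), np.zeros(2), 0.0)


class TestPrecision:
    def test_matched_beliefs_are_a_fixed_point(self):
        pi = softmax(-np.array([1.0, 2.0]))
        beta, gamma = update_precision(pi, pi, np.array([1.0, 2.0]), beta_prior=1.5)
        assert beta == pytest.approx(1.5) and gamma == pytest.approx(1 / 1.5)

    def test_hand_worked_single_step(self):
        G = np.array([0.0, 1.0])
        pi0 = softmax(-G)
        beta, gamma = update_precision(np.array([0.9, 0.1]), pi0, G, beta_prior=1.0)
        assert beta == pytest.approx(0.8310585786300049)
        assert gamma == pytest.approx(1.2032846127988885)

    def test_evidence_for_low_G_policies_raises_precision(self):
        """Observations favoring policies with low expected free energy
        produce a dopamine burst (gamma above its prior), and vice versa."""
        G = np.array([0.0, 1.0])
        pi0 = softmax(-G)
        sharper = np.array([0.9, 0.1])  # favors the low-G policy
        flatter = np.array([0.5, 0.5])  # favors the high-G policy
        _, g_up = update_precision(sharper, pi0, G, beta_prior=1.0)
        _, g_dn = update_precision(flatter, pi0, G, beta_prior=1.0)
        assert g_up > 1.0 > g_dn

    def test_beta_floored_away_from_zero(self):
        G = np.array([0.0, 50.0])
        beta, gamma = update_precision(np.array([1.0, 0.0]), np.array([0.0, 1.0]), G, 1.0)
        assert beta == pytest.approx(1 / 64) and gamma == pytest.approx(64.0)

    def test_joint_fixed_point_converges(self):
        F = np.zeros(3)
        G = np.array([0.0, 2.0, 4.0])
        pi, pi0, beta, gamma, trace = infer_precision(F, G, beta_prior=1.0)
        assert np.isclose(pi.sum(), 1.0) and np.isclose(pi0.sum(), 1.0)
        assert gamma > 0 and np.all(trace > 0)
        # self-consistency of the returned fixed point
        beta_check = 1.0 + pi @ G - pi0 @ G
        assert beta == pytest.approx(max(beta_check, 1 / 64), abs=2e-4)
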