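import numpy as np
import pytest
from scipy import signal as sps

from epiforage.agent import run_trial
from epiforage.responses import (
    FS,
    MAX_ITERS,
    dopamine_signal,
    firing_raster,
    precision_bins,
    response_traces,
    run_sweep,
    score_trial,
    simulated_lfp,
)
from epiforage.task import build_scene_model, scene_layout


@pytest.fixture(scope="module")
def traced_trial(model):
    return run_trial(model, scene_layout("flee", 0, 0), seed=1, record_trace=True)


class TestRaster:
    def test_context_raster_dimensions_for_six_epochs(self, traced_trial):
        raster = firing_raster(traced_trial, "context")
        assert raster.shape == (3 * 6, 16 * 6)

    @pytest.mark.parametrize("T", range(2, 10))
    def test_shapes_follow_trial_length(self, T):
        m = build_scene_model(T=T)
        trial = run_trial(m, scene_layout("feed", 0, 0), seed=0, record_trace=True)
        for factor, dim in zip(("context", "location", "flip_lr"), (3, 8, 2)):
            raster = firing_raster(trial, factor)
            assert raster.shape == (T * dim, MAX_ITERS * T)

    def test_rates_are_probabilities(self, traced_trial):
        raster = firing_raster(traced_trial, "location")
        assert raster.min() >= 0.0 and raster.max() <= 1.0 + 1e-12
        # each column block of a represented epoch sums to one over states
        col = raster[:, 17]
        sums = col.reshape(6, 8).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-8)

    def test_trace_required(self, model):
        trial = run_trial(model, scene_layout("flee", 0, 0), seed=1)
        with pytest.raises(ValueError, match="record_trace"):
            firing_raster(trial, "context")

    def test_unknown_factor_rejected(self, traced_trial):
        with pytest.raises(ValueError, match="factor"):
            firing_raster(traced_trial, "colour")


class TestLFP:
    def test_constant_rates_give_silent_lfp(self):
        raster = np.full((6, 64), 0.5)
        lfp, avg, filt = simulated_lfp(raster)
        assert np.allclose(lfp, 0.0) and np.allclose(avg, 0.0)

    def test_single_belief_jump_gives_single_impulse(self):
        raster = np.zeros((1, 96))
        raster[0, 40:] = 1.0
        lfp, _, _ = simulated_lfp(raster)
        assert lfp[0, 40] == pytest.approx(1.0)
        assert np.count_nonzero(lfp) == 1

    def test_band_limited_average_suppresses_high_frequencies(self):
        """Filter contract: the band-passed trace keeps theta-range energy
        and has negligible energy well above the 8 Hz half-power point."""
        rng = np.random.default_rng(0)
        raster = rng.random((4, 16 * 40))  # long white-noise trace
        _, _, filt = simulated_lfp(raster)
        freqs, psd = sps.periodogram(filt, fs=FS)
        band = psd[(freqs >= 2) & (freqs <= 8)].sum()
        high = psd[freqs >= 16].sum()
        assert high < 0.05 * band

    def test_trial_traces_assemble(self, traced_trial):
        tr = response_traces(traced_trial, "context")
        assert tr.raster.shape[1] == tr.lfp_avg.size == tr.dopamine.size
        assert np.all(np.diff(tr.time_axis) > 0)
        assert tr.time_axis[1] - tr.time_axis[0] == pytest.approx(0.250 / 16)


class TestDopamine:
    def test_constant_precision_gives_flat_baseline(self):
        d = dopamine_signal(np.full(32, 1.5), mix=4.0)
        assert np.allclose(d, 1.5)

    def test_step_produces_transient_burst_on_raised_baseline(self):
        g = np.concatenate([np.ones(10), np.full(10, 2.0)])
        d = dopamine_signal(g, mix=4.0)
        assert d[10] == pytest.approx(2.0 + 4.0)  # transient
        assert d[11:] == pytest.approx(2.0)  # new baseline
        assert np.allclose(d[:10], 1.0)

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError):
            dopamine_signal(np.array([1.0, 0.0]))

    def test_bins_pad_each_epoch_to_sixteen(self, traced_trial):
        g = precision_bins(traced_trial)
        assert g.size == 16 * len(traced_trial.beliefs)
        assert np.all(g > 0)


class TestScoring:
    def test_correct_choice_at_third_saccade(self, model):
        trial = run_trial(model, scene_layout("flee", 0, 0), seed=0)
        rec = score_trial(trial)
        assert rec["correct"] and rec["decision_time"] == trial.decision_time
        assert rec["reaction_time"] > 0

    def test_no_choice_counts_as_incorrect_at_budget(self):
        m = build_scene_model(c=0.0, T=6)
        trial = run_trial(m, scene_layout("feed", 0, 0), seed=0, max_saccades=5)
        rec = score_trial(trial)
        assert not rec["correct"] and rec["decision_time"] == 5

    def test_cue_only_trials_have_zero_utility(self, model):
        trial = run_trial(model, scene_layout("feed", 0, 0), seed=0, max_saccades=0)
        assert score_trial(trial)["utility"] == 0.0


class TestSweep:
    @pytest.fixture(scope="class")
    def small_sweep(self):
        return run_sweep(
            3, c_levels=[0.0, 4.0], beta_levels=[8.0, 1.0, 1 / 16], seed=5, T=7, max_saccades=6
        )

    def test_grids_have_requested_shape_and_ranges(self, small_sweep):
        assert small_sweep.accuracy.shape == (2, 3)
        assert np.all((small_sweep.accuracy >= 0) & (small_sweep.accuracy <= 100))
        assert np.all(small_sweep.decision_time <= 6)

    def test_reproducible_bit_for_bit(self, small_sweep):
        again = run_sweep(
            3, c_levels=[0.0, 4.0], beta_levels=[8.0, 1.0, 1 / 16], seed=5, T=7, max_saccades=6
        )
        assert np.array_equal(small_sweep.accuracy, again.accuracy)
        assert np.array_equal(small_sweep.decision_time, again.decision_time)
        assert np.array_equal(small_sweep.reaction_time, again.reaction_time)

    def test_high_preference_high_precision_is_the_best_cell(self, small_sweep):
        acc = small_sweep.accuracy
        assert acc[1, 2] == acc.max()

    def test_accuracy_monotone_along_precision_at_high_preference(self):
        """Toward the paper's corner structure: at the highest preference,
        accuracy does not decrease as prior precision rises (allowing one
        sampling-noise inversion)."""
        sweep = run_sweep(
            8,
            c_levels=[4.0],
            beta_levels=list(2.0 ** np.linspace(3, -4, 8)),
            seed=9,
            T=7,
            max_saccades=6,
        )
        acc = sweep.accuracy[0]
        inversions = sum(acc[j + 1] < acc[j] - 1e-9 for j in range(len(acc) - 1))
        assert inversions <= 1

    def test_dataframe_layout(self, small_sweep):
        df = small_sweep.to_dataframe()
        assert list(df.columns) == ["c", "beta", "accuracy", "decision_time", "reaction_time", "n"]
        assert len(df) == 6
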