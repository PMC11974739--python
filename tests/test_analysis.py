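import numpy as np
import pytest

from band.analysis import (LagProfile, aggregate_lag_profile,
                           condition_average_predictor,
                           detect_oscillatory_neurons, diagonal_lag_profile,
                           fft_amplitude_spectrum, fft_phase_similarity,
                           fit_seq2seq_ridge, fixed_lag_regression,
                           smooth_rates_gaussian, train_birnn_decoder,
                           controller_contribution)
from band.data import TrialDataset
from band.metrics import r2_isotropic
from band.model import DecoderWeightMatrix


def make_dataset(behavior, spikes=None, prep_bins=2, epoch=None, condition=None):
    n, T, _ = behavior.shape
    if spikes is None:
        spikes = np.random.default_rng(0).poisson(0.3, size=(n, T, 3))
    return TrialDataset(
        spikes=spikes,
        behavior=behavior,
        bin_width=0.01,
        condition=np.ones(n, dtype=int) if condition is None else condition,
        epoch=np.array(["BL"] * n) if epoch is None else epoch,
        prep_bins=prep_bins,
    )


class TestConditionAverage:
    def test_identical_trials_r2_one(self):
        base = np.random.default_rng(0).normal(size=(1, 10, 2))
        behavior = np.concatenate([base] * 6)
        condition = np.array([1, 1, 1, 2, 2, 2])
        behavior[3:] += 1.0
        ds = make_dataset(behavior, condition=condition)
        _, r2 = condition_average_predictor(ds, [0, 1, 3, 4], [2, 5])
        assert r2 == pytest.approx(1.0)

    def test_unseen_condition_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(4, 6, 2)),
                          condition=np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError, match="absent"):
            condition_average_predictor(ds, [0, 1], [2, 3])

    def test_shuffled_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        condition = np.tile([1, 2, 3, 4], 10)
        behavior = condition[:, None, None] + rng.normal(0, 0.3, size=(40, 8, 2))
        ds = make_dataset(behavior, condition=condition)
        train, test = np.arange(0, 30), np.arange(30, 40)
        _, r2_true = condition_average_predictor(ds, train, test)
        nulls = []
        for _ in range(200):
            ds_null = make_dataset(behavior, condition=rng.permutation(condition))
            try:
                _, r2_null = condition_average_predictor(ds_null, train, test)
            except ValueError:
                continue
            nulls.append(r2_null)
        assert r2_true > 0.9
        assert abs(np.mean(nulls)) < 0.2


class TestSeq2SeqRidge:
    def test_exact_linear_case_recovered(self):
        rng = np.random.default_rng(0)
        factors = rng.normal(size=(40, 10, 3))
        weights = rng.normal(size=(30, 20))
        behavior = (factors.reshape(40, -1) @ weights).reshape(40, 10, 2)
        split = (np.arange(30), np.arange(30, 40))
        preds, _, alpha = fit_seq2seq_ridge(factors, behavior, split,
                                            ridge_strengths=(1e-8, 100.0))
        assert r2_isotropic(behavior[30:], preds) > 0.97
        assert alpha == 1e-8

    def test_noise_factors_score_near_zero(self):
        rng = np.random.default_rng(1)
        factors = rng.normal(size=(60, 10, 3))
        behavior = rng.normal(size=(60, 10, 2))
        split = (np.arange(45), np.arange(45, 60))
        preds, _, _ = fit_seq2seq_ridge(factors, behavior, split)
        assert abs(r2_isotropic(behavior[45:], preds)) < 0.35


class TestBiRNN:
    def test_linear_noiseless_relationship_learned(self):
        rng = np.random.default_rng(0)
        spikes = rng.poisson(1.0, size=(40, 10, 5))
        readout = rng.normal(size=(5, 2)) * 0.5
        behavior = spikes @ readout
        ds = make_dataset(behavior, spikes=spikes)
        split = (np.arange(32), np.arange(32, 40))
        _, _, r2 = train_birnn_decoder(ds, split, hidden=16, epochs=200, seed=0)
        assert r2 > 0.8

    def test_shuffled_behavior_scores_near_zero(self):
        rng = np.random.default_rng(3)
        spikes = rng.poisson(1.0, size=(40, 10, 5))
        behavior = rng.normal(size=(40, 10, 2))  # unrelated to spikes
        ds = make_dataset(behavior, spikes=spikes)
        split = (np.arange(32), np.arange(32, 40))
        _, _, r2 = train_birnn_decoder(ds, split, hidden=8, epochs=60, seed=0)
        assert r2 < 0.3


class TestSmoothing:
    def test_impulse_recovers_kernel_and_area(self):
        spikes = np.zeros((1, 101, 1))
        spikes[0, 50, 0] = 1.0
        sm = smooth_rates_gaussian(spikes, sigma_s=0.03, bin_width=0.01)
        assert sm.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.argmax(sm[0, :, 0]) == 50
        # matches a normalized (truncated) Gaussian at the impulse
        radius = int(4 * 3.0)
        t = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (t / 3.0) ** 2)
        kernel /= kernel.sum()
        assert np.allclose(sm[0, 50 - radius:50 + radius + 1, 0], kernel, atol=1e-9)

    def test_constant_input_unchanged(self):
        spikes = np.full((2, 50, 3), 4.0)
        sm = smooth_rates_gaussian(spikes)
        assert np.allclose(sm, 4.0, atol=1e-9)

    def test_mass_conserved_interior_support(self):
        rng = np.random.default_rng(0)
        spikes = np.zeros((3, 80, 2))
        spikes[:, 20:60] = rng.poisson(1.0, size=(3, 40, 2))
        sm = smooth_rates_gaussian(spikes)
        assert np.allclose(sm.sum(axis=1), spikes.sum(axis=1), atol=1e-9)

    def test_small_sigma_warns(self):
        with pytest.warns(UserWarning):
            smooth_rates_gaussian(np.zeros((1, 10, 1)), sigma_s=0.004,
                                  bin_width=0.01)


class TestSpectrum:
    def test_pure_sinusoid_concentrates(self):
        T, dt = 100, 0.01
        t = np.arange(T) * dt
        signal = np.sin(2 * np.pi * 5.0 * t).reshape(1, T, 1)
        spec = fft_amplitude_spectrum(signal, dt)
        mode = spec.mode_nearest(5.0)
        others = np.delete(spec.amplitude[0, :, 0], mode)
        assert spec.amplitude[0, mode, 0] > 100 * others.max()

    def test_parseval(self):
        rng = np.random.default_rng(0)
        for T in (64, 65):  # even and odd lengths
            signal = rng.normal(size=(3, T, 2))
            spec = fft_amplitude_spectrum(signal, 0.01)
            power = spec.power.copy()
            scale = np.full(power.shape[1], 2.0)
            scale[0] = 1.0
            if T % 2 == 0:
                scale[-1] = 1.0
            lhs = (power * scale[None, :, None]).sum(axis=1) / T
            rhs = (signal**2).sum(axis=1)
            assert np.allclose(lhs, rhs, atol=1e-9)

    def test_decaying_sinusoid_peak_mode(self):
        T, dt = 120, 0.01
        t = np.arange(T) * dt
        rng = np.random.default_rng(0)
        trials = []
        for _ in range(10):
            phase = rng.uniform(0, 2 * np.pi)
            trials.append(np.exp(-t / 0.4) * np.sin(2 * np.pi * 5.0 * t + phase))
        signal = np.stack(trials)[:, :, None]
        spec = fft_amplitude_spectrum(signal, dt)
        non_dc = spec.mean_power[1:, 0]
        assert 1 + np.argmax(non_dc) == spec.mode_nearest(5.0)

    def test_nan_rejected(self):
        bad = np.full((1, 4, 1), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            fft_amplitude_spectrum(bad, 0.01)


class TestPhaseSimilarity:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(6, 40, 2))
        sims = fft_phase_similarity(y, y, 0.01)["similarity"]
        assert np.allclose(sims[~np.isnan(sims)], 1.0, atol=1e-9)

    def test_antiphase_mode(self):
        T, dt = 40, 0.01
        t = np.arange(T) * dt
        rng = np.random.default_rng(0)
        true = np.stack([
            np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
            + 0.5 * np.sin(2 * np.pi * 2.5 * t + rng.uniform(0, 2 * np.pi))
            for _ in range(8)
        ])[:, :, None]
        ct = np.fft.rfft(true, axis=1)
        mode5 = int(np.argmin(np.abs(np.fft.rfftfreq(T, dt) - 5.0)))
        cp = ct.copy()
        cp[:, mode5] *= -1  # phase shift by pi at 5 Hz only
        pred = np.fft.irfft(cp, n=T, axis=1)
        result = fft_phase_similarity(true, pred, dt)
        sims = result["similarity"]
        assert sims[mode5] == pytest.approx(-1.0, abs=1e-9)
        mode25 = int(np.argmin(np.abs(result["frequencies"] - 2.5)))
        assert sims[mode25] == pytest.approx(1.0, abs=1e-9)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        sims = fft_phase_similarity(rng.normal(size=(5, 30, 2)),
                                    rng.normal(size=(5, 30, 2)), 0.01)["similarity"]
        ok = sims[~np.isnan(sims)]
        assert np.all(ok <= 1.0 + 1e-12) and np.all(ok >= -1.0 - 1e-12)

    def test_condition_mean_prediction_near_zero_at_jittered_mode(self):
        T, dt = 60, 0.01
        t = np.arange(T) * dt
        rng = np.random.default_rng(0)
        base = np.sin(2 * np.pi * 1.0 * t)
        trials = np.stack([
            base + np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
            for _ in range(50)
        ])[:, :, None]
        pred = np.broadcast_to(trials.mean(axis=0), trials.shape)
        result = fft_phase_similarity(trials, pred, dt)
        mode5 = int(np.argmin(np.abs(result["frequencies"] - 5.0)))
        mode1 = int(np.argmin(np.abs(result["frequencies"] - 1.0)))
        assert abs(result["similarity"][mode5]) < 0.35
        assert result["similarity"][mode1] > 0.95


class TestDiagonalLagProfile:
    def make_wm(self, block, T=5, prep=2):
        F, B = 1, 1
        weights = np.zeros((T * F, T * B))
        weights[prep:, prep:] = block
        return DecoderWeightMatrix(weights=weights, bias=np.zeros(T * B),
                                   T=T, n_factors=F, behavior_dims=B)

    def test_worked_example(self):
        block = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        wm = self.make_wm(block)
        prof = diagonal_lag_profile(wm, 0, 0, (2, 5), bin_width=1.0)
        assert np.array_equal(prof.lags_s, [-2, -1, 0, 1, 2])
        assert np.array_equal(prof.values, [7.0, 12.0, 15.0, 8.0, 3.0])

    def test_identity_block_mass_at_zero(self):
        wm = self.make_wm(np.eye(3))
        prof = diagonal_lag_profile(wm, 0, 0, (2, 5), bin_width=0.01)
        assert prof.peak_lag_s == 0.0
        assert prof.values[prof.lags_s == 0.0] == pytest.approx(3.0)

    def test_total_mass_conserved(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(4, 4))
        wm = self.make_wm(block, T=6, prep=2)
        prof = diagonal_lag_profile(wm, 0, 0, (2, 6), bin_width=0.01)
        assert prof.values.sum() == pytest.approx(block.sum(), abs=1e-12)

    def test_empty_window_rejected(self):
        wm = self.make_wm(np.eye(3))
        with pytest.raises(ValueError, match="window"):
            diagonal_lag_profile(wm, 0, 0, (4, 4), bin_width=0.01)

    def test_aggregate_uses_absolute_values(self):
        T, F, B = 5, 2, 1
        weights = np.zeros((T * F, T * B))
        wm = DecoderWeightMatrix(weights=weights, bias=np.zeros(T * B), T=T,
                                 n_factors=F, behavior_dims=B)
        # factor 0 and factor 1 have opposite-signed diagonals
        for t in range(2, 5):
            weights[t * F + 0, t] = 1.0
            weights[t * F + 1, t] = -1.0
        prof = aggregate_lag_profile(wm, (2, 5), bin_width=0.01)
        assert prof.values[prof.lags_s == 0.0] == pytest.approx(6.0)


class TestFixedLagRegression:
    def test_constructed_shift_peaks_exactly(self):
        rng = np.random.default_rng(0)
        T, L = 40, 4
        behavior = rng.normal(size=(30, T, 2))
        latents = np.zeros((30, T, 2))
        latents[:, L:] = behavior[:, :-L]  # latent at t equals behavior at t-L
        split = (np.arange(22), np.arange(22, 30))
        prof = fixed_lag_regression(latents, behavior, split, bin_width=0.01,
                                    max_lag_s=0.08, movement_window=(10, 30))
        assert prof.peak_lag_s == pytest.approx(-L * 0.01)
        assert prof.peak_value > 0.999

    def test_latents_equal_behavior_r2_one_at_zero_lag(self):
        rng = np.random.default_rng(1)
        behavior = rng.normal(size=(20, 30, 2))
        split = (np.arange(14), np.arange(14, 20))
        prof = fixed_lag_regression(behavior, behavior, split, bin_width=0.01,
                                    max_lag_s=0.03, ridge_alpha=1e-10)
        at_zero = prof.values[np.isclose(prof.lags_s, 0.0)][0]
        assert at_zero == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_flat_near_zero(self):
        rng = np.random.default_rng(2)
        latents = rng.normal(size=(40, 30, 3))
        behavior = rng.normal(size=(40, 30, 2))
        split = (np.arange(30), np.arange(30, 40))
        prof = fixed_lag_regression(latents, behavior, split, bin_width=0.01,
                                    max_lag_s=0.05)
        assert np.abs(prof.values).max() < 0.2

    def test_exhausted_window_rejected(self):
        behavior = np.zeros((4, 10, 1))
        with pytest.raises(ValueError, match="lag"):
            fixed_lag_regression(behavior, behavior, ([0, 1], [2, 3]),
                                 bin_width=0.01, max_lag_s=0.2,
                                 movement_window=(0, 5))


class TestOscillatoryNeurons:
    @staticmethod
    def poisson_counts(rate_fn, n_trials, T, dt, rng):
        t = np.arange(T) * dt
        return np.stack([rng.poisson(rate_fn(t) * dt) for _ in range(n_trials)])

    def make_osc_dataset(self, osc_in, seed=0, T=120, n_trials=20):
        """One neuron; osc_in selects which epochs oscillate at 5 Hz."""
        rng = np.random.default_rng(seed)
        dt = 0.01
        epochs = ["BL"] * n_trials + ["AD"] * n_trials
        counts = []
        for ep in epochs:
            if ep in osc_in:
                fn = lambda t: 12.0 + 11.0 * np.sin(
                    2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
            else:
                fn = lambda t: 12.0 + 0.0 * t
            counts.append(self.poisson_counts(fn, 1, T, dt, rng)[0])
        spikes = np.stack(counts)[:, :, None]
        return TrialDataset(
            spikes=spikes, behavior=np.zeros((2 * n_trials, T, 1)),
            bin_width=dt, condition=np.ones(2 * n_trials, dtype=int),
            epoch=np.array(epochs), prep_bins=10)

    def test_ad_only_oscillator_flagged(self):
        ds = self.make_osc_dataset({"AD"}, seed=1)
        flags, _ = detect_oscillatory_neurons(ds, n_shuffle=200, seed=0)
        assert flags[0]

    def test_constant_neuron_not_flagged(self):
        ds = self.make_osc_dataset(set(), seed=2)
        flags, _ = detect_oscillatory_neurons(ds, n_shuffle=200, seed=0)
        assert not flags[0]

    def test_both_epoch_oscillator_not_flagged(self):
        ds = self.make_osc_dataset({"AD", "BL"}, seed=3)
        flags, _ = detect_oscillatory_neurons(ds, n_shuffle=200, seed=0)
        assert not flags[0]

    def test_too_few_trials_rejected(self):
        ds = self.make_osc_dataset({"AD"}, n_trials=3)
        with pytest.raises(ValueError, match="trials"):
            detect_oscillatory_neurons(ds)

    def test_invariant_to_uniform_rate_scaling(self):
        # the criterion is self-calibrated per neuron: scaling all counts
        # by an integer factor must not create spurious flags
        ds = self.make_osc_dataset(set(), seed=4)
        scaled = TrialDataset(
            spikes=ds.spikes * 3, behavior=ds.behavior, bin_width=ds.bin_width,
            condition=ds.condition, epoch=ds.epoch, prep_bins=ds.prep_bins)
        f1, _ = detect_oscillatory_neurons(ds, n_shuffle=150, seed=0)
        f2, _ = detect_oscillatory_neurons(scaled, n_shuffle=150, seed=0)
        assert not f1[0] and not f2[0]


class TestLagProfileType:
    def test_orders_by_lag(self):
        prof = LagProfile(lags_s=np.array([0.02, -0.02, 0.0]),
                          values=np.array([1.0, 3.0, 2.0]))
        assert np.array_equal(prof.lags_s, [-0.02, 0.0, 0.02])
        assert prof.peak_lag_s == -0.02
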