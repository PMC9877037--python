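import numpy as np
import pytest

from thetacode import synth
from thetacode.decoding import (DecoderModel, bootstrap_decode,
                                confusion_matrix, decode, fit_decoder,
                                train_test_split_frames, zscore_error)
from thetacode.pipeline import variable_series
from thetacode.preprocess import binarize_traces
from thetacode.tuning import BinningSpec, default_binning


def one_hot_population(n_bins=5, frames_per_bin=40):
    """Cell k active exactly when the state is bin k."""
    bins = np.tile(np.arange(n_bins), frames_per_bin)
    binary = np.zeros((n_bins, len(bins)), dtype=int)
    for k in range(n_bins):
        binary[k, bins == k] = 1
    return binary, bins


class TestFitDecoder:
    def test_one_hot_likelihoods(self):
        binary, bins = one_hot_population()
        spec = BinningSpec("location", 1.0, (0.0, 5.0))
        model = fit_decoder(binary, bins, spec)
        occ = 40.0
        for k in range(5):
            assert model.likelihood[k, k] == pytest.approx(1 - 1 / (occ + 2))
            off = np.delete(model.likelihood[k], k)
            assert np.allclose(off, 1 / (occ + 2))

    def test_uniform_prior_over_occupied(self):
        binary, bins = one_hot_population()
        model = fit_decoder(binary, bins, BinningSpec("x", 1.0, (0, 5)))
        assert np.allclose(model.prior, 0.2)
        assert model.prior.sum() == pytest.approx(1.0)

    def test_refit_identical(self):
        binary, bins = one_hot_population()
        spec = BinningSpec("x", 1.0, (0, 5))
        m1 = fit_decoder(binary, bins, spec)
        m2 = fit_decoder(binary, bins, spec)
        np.testing.assert_array_equal(m1.likelihood, m2.likelihood)

    def test_unoccupied_bins_excluded(self):
        binary, bins = one_hot_population()
        spec = BinningSpec("x", 1.0, (0.0, 6.0))    # bin 5 never occupied
        model = fit_decoder(binary, bins, spec)
        assert not model.occupied[5]
        assert model.prior[5] == 0.0
        assert np.isnan(model.likelihood[:, 5]).all()


class TestDecode:
    def test_one_hot_perfect(self):
        binary, bins = one_hot_population()
        spec = BinningSpec("x", 1.0, (0, 5))
        model = fit_decoder(binary, bins, spec)
        res = decode(model, binary, window_s=0.0, actual_bins=bins)
        assert (res.map_bins == bins).all()
        assert res.mean_error == 0.0

    def test_silent_frames_fall_back_to_prior(self):
        binary, bins = one_hot_population()
        spec = BinningSpec("x", 1.0, (0, 5))
        model = fit_decoder(binary, bins, spec)
        res = decode(model, np.zeros((5, 3), dtype=int), window_s=0.0,
                     variant="exact", evidence="active_only")
        # no evidence at all: posterior is the uniform prior, lowest-index tie-break
        assert np.allclose(res.posterior[:, 0], 0.2)
        assert (res.map_bins == 0).all()

    def test_posterior_columns_sum_to_one(self, tuned_population, track_session):
        _, _, _, binary = tuned_population
        bins = default_binning("location").bin(track_session.position)
        bins = np.where(track_session.locomotion_mask, bins, -1)
        model = fit_decoder(binary[:, :20000], bins[:20000],
                            default_binning("location"))
        res = decode(model, binary[:, 20000:23000], window_s=2.0)
        np.testing.assert_allclose(res.posterior.sum(axis=0), 1.0, atol=1e-9)

    def test_exact_posterior_matches_bayes_enumeration(self):
        # 3 bins x 2 cells with hand-set likelihoods, observation (1, 0)
        P = np.array([[0.9, 0.1, 0.1],
                      [0.1, 0.1, 0.9]])
        spec = BinningSpec("x", 1.0, (0, 3))
        model = DecoderModel(likelihood=P, prior=np.full(3, 1 / 3),
                             marginal=np.array([0.3, 0.3]),
                             occupied=np.ones(3, bool), spec=spec)
        obs = np.array([[1], [0]])
        res = decode(model, obs, window_s=0.0, variant="exact", evidence="binary")
        # brute-force Bayes: P(S|A) oc P(A1=1|S) (1-P(A2=1|S)) P(S)
        joint = P[0] * (1 - P[1]) * (1 / 3)
        expected = joint / joint.sum()
        np.testing.assert_allclose(res.posterior[:, 0], expected, rtol=1e-10)

    def test_variants_agree_on_argmax(self, track_session):
        # per-frame scores: the log(1+x)-1 distortion is monotone per cell,
        # so frame-wise MAP picks coincide on the vast majority of frames
        # (window accumulation compounds the distortion and is compared
        # via decoding error instead)
        rng = np.random.default_rng(8)
        specs = synth.make_population(30, 0, 0, 0, rng, place_reliability=1.0)
        neural, _ = synth.simulate_neurons(track_session, specs, seed=3)
        binary = binarize_traces(neural.traces, 30.0)
        bins = default_binning("location").bin(track_session.position)
        bins = np.where(track_session.locomotion_mask, bins, -1)
        model = fit_decoder(binary[:, :20000], bins[:20000],
                            default_binning("location"))
        test = binary[:, 20000:24000]
        exact = decode(model, test, window_s=1 / 30.0, variant="exact",
                       evidence="active_only")
        approx = decode(model, test, window_s=1 / 30.0, variant="approx")
        agree = (exact.map_bins == approx.map_bins).mean()
        assert agree >= 0.95

    def test_temporal_filtering_reduces_error(self, track_session):
        rng = np.random.default_rng(8)
        specs = synth.make_population(30, 0, 0, 0, rng, place_reliability=1.0)
        neural, _ = synth.simulate_neurons(track_session, specs, seed=3)
        binary = binarize_traces(neural.traces, 30.0)
        spec = default_binning("location")
        bins = np.where(track_session.locomotion_mask,
                        spec.bin(track_session.position), -1)
        train, test = train_test_split_frames(len(bins), 0.9, "blocks",
                                              track_session.trial_id)
        model = fit_decoder(binary[:, train], bins[train], spec)
        tsel = np.flatnonzero(test & (bins >= 0))
        slow = decode(model, binary[:, tsel], window_s=2.0,
                      actual_bins=bins[tsel])
        fast = decode(model, binary[:, tsel], window_s=1 / 30.0,
                      actual_bins=bins[tsel])
        assert slow.mean_error < fast.mean_error

    def test_error_nonincreasing_with_population_size(self, track_session):
        rng = np.random.default_rng(9)
        specs = synth.make_population(60, 0, 0, 0, rng, place_reliability=0.6)
        neural, _ = synth.simulate_neurons(track_session, specs, seed=5)
        binary = binarize_traces(neural.traces, 30.0)
        spec = default_binning("location")
        bins = np.where(track_session.locomotion_mask,
                        spec.bin(track_session.position), -1)
        train, test = train_test_split_frames(len(bins), 0.9, "blocks",
                                              track_session.trial_id)
        tsel = np.flatnonzero(test & (bins >= 0))
        errors = []
        for n in (10, 30, 60):
            errs = []
            for rep in range(5):
                cells = rng.choice(60, n, replace=False)
                model = fit_decoder(binary[cells][:, train], bins[train], spec)
                res = decode(model, binary[cells][:, tsel], window_s=2.0,
                             actual_bins=bins[tsel])
                errs.append(res.mean_error)
            errors.append(np.mean(errs))
        assert errors[2] <= errors[1] <= errors[0] + 2.0


class TestZscore:
    def test_equal_means_zero(self):
        assert zscore_error([1.0, 2.0, 3.0], [2.0, 2.0]) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        z = zscore_error([1.0, 3.0], [5.0])
        assert z == pytest.approx((2 - 5) / np.sqrt(2), abs=1e-12)

    def test_zero_sd_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_error([2.0, 2.0], [3.0])


class TestConfusion:
    def test_perfect_decoding_identity(self):
        bins = np.tile(np.arange(4), 10)
        cm = confusion_matrix(bins, bins, 4)
        np.testing.assert_array_equal(cm, np.eye(4))

    def test_uniform_random_rows(self):
        rng = np.random.default_rng(10)
        actual = rng.integers(0, 5, 20000)
        decoded = rng.integers(0, 5, 20000)
        cm = confusion_matrix(actual, decoded, 5)
        assert np.allclose(cm, 0.2, atol=0.02)

    def test_unvisited_bin_nan_row(self):
        cm = confusion_matrix(np.array([0, 1]), np.array([0, 1]), 3)
        assert np.isnan(cm[2]).all()
        assert cm[0, 0] == 1.0


class TestBootstrap:
    def test_returns_requested_number_of_surrogates(self, tuned_population,
                                                    track_session):
        _, _, _, binary = tuned_population
        spec = default_binning("location")
        bins = np.where(track_session.locomotion_mask,
                        spec.bin(track_session.position), -1)
        res = bootstrap_decode(binary, bins, spec, n_boot=7,
                               cells_per_boot=20, seed=0,
                               trial_id=track_session.trial_id)
        assert len(res["actual_errors"]) == 7
        assert len(res["shuffled_errors"]) == 7

    def test_tuned_population_beats_shuffles(self, track_session):
        rng = np.random.default_rng(11)
        specs = synth.make_population(40, 0, 0, 10, rng, place_reliability=0.6)
        neural, _ = synth.simulate_neurons(track_session, specs, seed=6)
        binary = binarize_traces(neural.traces, 30.0)
        spec = default_binning("location")
        bins = np.where(track_session.locomotion_mask,
                        spec.bin(track_session.position), -1)
        res = bootstrap_decode(binary, bins, spec, n_boot=10,
                               cells_per_boot=60, seed=1,
                               trial_id=track_session.trial_id)
        assert (res["actual_errors"] < res["shuffled_errors"]).all()
        assert res["z"] < -2.0


class TestSplit:
    def test_block_split_respects_trials(self):
        trial = np.repeat(np.arange(10), 100)
        train, test = train_test_split_frames(1000, 0.9, "blocks", trial)
        assert set(np.unique(trial[train])) == set(range(9))
        assert set(np.unique(trial[test])) == {9}

    def test_masks_partition_frames(self):
        train, test = train_test_split_frames(1000, 0.9)
        assert (train ^ test).all()
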