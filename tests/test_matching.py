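"""Fingerprint construction, smoothing and dictionary search."""

import numpy as np
import pytest

from mrvf.matching import (
    Fingerprint,
    make_fingerprint,
    match_voxel,
    match_volume,
    smooth_inplane,
    _gaussian_kernel_3x3,
)
from mrvf.sequence import SignalTrain


def _train(times, signal, arm="pre"):
    return SignalTrain(times=np.asarray(times), signal=np.asarray(signal), arm=arm)


class TestMakeFingerprint:
    def test_identical_arms_give_unit_ratio(self):
        t = np.arange(1.0, 33.0)
        s = np.exp(-t / 40)
        fp = make_fingerprint(_train(t, s), _train(t, s, "post"))
        assert np.allclose(fp.ratio, 1.0)
        assert fp.ratio.shape == (24,)

    def test_tail_echoes_dropped(self):
        t = np.arange(1.0, 33.0)
        fp = make_fingerprint(_train(t, np.ones(32)), _train(t, np.ones(32)), n_drop=8)
        assert len(fp.ratio) == 32 - 8
        assert fp.echo_times[-1] == 24.0

    def test_shared_multiplicative_decay_cancels_exactly(self):
        # the T2/B1-insensitivity property of the ratio fingerprint
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 33.0)
        pre = rng.uniform(0.2, 1.0, 32)
        post = rng.uniform(0.05, 1.0, 32)
        decay = np.exp(-t / 55.0)
        fp0 = make_fingerprint(_train(t, pre), _train(t, post, "post"))
        fp1 = make_fingerprint(_train(t, pre * decay), _train(t, post * decay, "post"))
        assert np.allclose(fp0.ratio, fp1.ratio, rtol=1e-14)

    def test_non_positive_pre_signal_flags_invalid(self):
        t = np.arange(1.0, 33.0)
        pre = np.ones(32)
        pre[3] = 0.0
        fp = make_fingerprint(_train(t, pre), _train(t, np.ones(32), "post"))
        assert not fp.valid

    def test_zero_in_dropped_tail_is_harmless(self):
        t = np.arange(1.0, 33.0)
        pre = np.ones(32)
        pre[-1] = 0.0
        fp = make_fingerprint(_train(t, pre), _train(t, np.ones(32), "post"))
        assert fp.valid

    def test_convention_flip_inverts_ratio(self):
        t = np.arange(1.0, 33.0)
        pre = np.full(32, 2.0)
        post = np.full(32, 1.0)
        a = make_fingerprint(_train(t, pre), _train(t, post, "post"), convention="post_over_pre")
        b = make_fingerprint(_train(t, pre), _train(t, post, "post"), convention="pre_over_post")
        assert np.allclose(a.ratio * b.ratio, 1.0)

    def test_mismatched_echo_times_rejected(self):
        with pytest.raises(ValueError):
            make_fingerprint(
                _train(np.arange(32.0), np.ones(32)),
                _train(np.arange(32.0) + 1, np.ones(32), "post"),
            )


class TestSmoothing:
    def test_kernel_unit_sum(self):
        assert _gaussian_kernel_3x3(0.8).sum() == pytest.approx(1.0)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 2, 4), 3.7)
        assert np.allclose(smooth_inplane(vol), 3.7)

    def test_impulse_response_is_kernel(self):
        vol = np.zeros((9, 9, 1, 1))
        vol[4, 4, 0, 0] = 1.0
        out = smooth_inplane(vol)
        assert np.allclose(out[3:6, 3:6, 0, 0], _gaussian_kernel_3x3(0.8))
        assert out[:, :, 0, 0].sum() == pytest.approx(1.0)

    def test_too_small_inplane_extent_rejected(self):
        with pytest.raises(ValueError):
            smooth_inplane(np.zeros((2, 8, 1, 1)))


class TestMatchVoxel:
    def test_dictionary_row_matches_itself(self, toy_dict):
        idx = 7
        fp = Fingerprint(toy_dict.entries[idx].copy(), toy_dict.echo_times)
        res = match_voxel(fp, toy_dict, adc_measured=float(toy_dict.params["adc"][idx]))
        assert res.entry_index == idx
        assert res.r2 == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-15)
        assert res.bvf == toy_dict.params["bvf"][idx]

    def test_constant_fingerprint_excluded(self, toy_dict):
        fp = Fingerprint(np.ones(24), toy_dict.echo_times)
        res = match_voxel(fp, toy_dict, adc_measured=800.0)
        assert res.excluded
        assert res.r2 == -np.inf

    def test_invalid_fingerprint_excluded(self, toy_dict):
        fp = Fingerprint(np.full(24, np.nan), toy_dict.echo_times, valid=False)
        assert match_voxel(fp, toy_dict).excluded

    def test_length_mismatch_raises(self, toy_dict):
        with pytest.raises(ValueError):
            match_voxel(Fingerprint(np.ones(10) * 0.5, np.arange(10.0)), toy_dict, 800.0)

    def test_monte_carlo_recovery_under_small_noise(self, toy555_dict):
        # fp = row + N(0, 0.01): the same row must win in >= 95% of 500 trials
        rng = np.random.default_rng(2024)
        n = len(toy555_dict)
        hits = 0
        trials = 500
        for _ in range(trials):
            idx = int(rng.integers(n))
            fp = Fingerprint(
                toy555_dict.entries[idx] + rng.normal(0.0, 0.01, 24),
                toy555_dict.echo_times,
            )
            res = match_voxel(fp, toy555_dict)
            hits += res.entry_index == idx
        assert hits / trials >= 0.95


class TestMatchVolume:
    def _volumes_from_dict(self, d, idx_grid):
        # build synthetic 4D arms whose ratio equals the selected rows
        shape = idx_grid.shape
        n_echo = len(d.sequence.echo_times)
        pre = np.ones(shape + (n_echo,))
        post = np.ones(shape + (n_echo,))
        post[..., : d.entries.shape[1]] = d.entries[idx_grid]
        return pre, post

    def test_noiseless_rows_recover_exactly(self, toy_dict):
        rng = np.random.default_rng(5)
        from mrvf.dictionary import restrict_to_adc

        view = restrict_to_adc(toy_dict, 800.0)
        idx = rng.integers(0, len(view), size=(6, 5, 2))
        pre, post = self._volumes_from_dict(view, idx)
        adc = np.full(idx.shape, 800.0)
        maps = match_volume(pre, post, adc, view, smooth=False)
        assert not maps.excluded.any()
        assert np.array_equal(maps.bvf, view.params["bvf"].to_numpy()[idx])
        assert np.array_equal(maps.radius_um, view.params["radius_um"].to_numpy()[idx])
        assert np.all(maps.r2 > 0.999999)

    def test_voxel_order_independence(self, toy_dict):
        from mrvf.dictionary import restrict_to_adc

        view = restrict_to_adc(toy_dict, 800.0)
        idx = np.arange(12).reshape(4, 3, 1) % len(view)
        pre, post = self._volumes_from_dict(view, idx)
        maps1 = match_volume(pre, post, None, view, smooth=False)
        flip = np.flip(pre, axis=0).copy(), np.flip(post, axis=0).copy()
        maps2 = match_volume(flip[0], flip[1], None, view, smooth=False)
        assert np.array_equal(np.flip(maps2.bvf, axis=0), maps1.bvf)

    def test_all_zero_input_fully_excluded(self, toy_dict):
        pre = np.zeros((4, 4, 1, 32))
        post = np.zeros((4, 4, 1, 32))
        maps = match_volume(pre, post, None, toy_dict, smooth=False)
        assert maps.excluded.all()

    def test_shape_mismatch_rejected(self, toy_dict):
        with pytest.raises(ValueError, match="shape"):
            match_volume(
                np.ones((4, 4, 1, 32)), np.ones((4, 5, 1, 32)), None, toy_dict
            )

    def test_shared_decay_leaves_all_matches_unchanged(self, toy_dict):
        from mrvf.dictionary import restrict_to_adc

        view = restrict_to_adc(toy_dict, 800.0)
        idx = np.arange(8).reshape(2, 2, 2) % len(view)
        pre, post = self._volumes_from_dict(view, idx)
        t = np.asarray(view.sequence.echo_times)
        decay = np.exp(-t / 55.0)
        maps0 = match_volume(pre, post, None, view, smooth=False)
        maps1 = match_volume(pre * decay, post * decay, None, view, smooth=False)
        assert np.array_equal(maps0.entry_index, maps1.entry_index)
        assert np.array_equal(maps0.bvf, maps1.bvf)

    def test_exclusion_fraction_grows_with_noise(self, toy_dict):
        from mrvf.dictionary import restrict_to_adc

        view = restrict_to_adc(toy_dict, 800.0)
        rng0 = np.random.default_rng(77)
        idx = rng0.integers(0, len(view), size=(8, 8, 1))
        pre, post = self._volumes_from_dict(view, idx)
        fracs = []
        for sigma in (0.005, 0.02, 0.08):
            rng = np.random.default_rng(123)
            p = pre + rng.normal(0, sigma, pre.shape)
            q = post + rng.normal(0, sigma, post.shape)
            maps = match_volume(p, q, None, view, smooth=False, r2_threshold=0.95)
            fracs.append(maps.excluded.mean())
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]
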