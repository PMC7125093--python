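"""The four per-IMF features, IMF selection and block/vector assembly."""

import numpy as np
import pytest
from scipy.spatial.distance import minkowski

from eegselect import (
    FeatureConfig,
    build_instance_vector,
    extract_channel_features,
    higuchi_fd,
    instantaneous_energy,
    petrosian_fd,
    select_imfs_minkowski,
    teager_energy,
)
from eegselect.emd import IMFSet
from eegselect.features import decompose


class TestInstantaneousEnergy:
    def test_unit_signal_is_zero(self):
        assert instantaneous_energy(np.ones(10)) == 0.0

    def test_direct_formula(self):
        assert instantaneous_energy(np.array([1.0, 2.0, 3.0, 4.0])) == \
            pytest.approx(np.log10(7.5))

    def test_scaling_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        assert instantaneous_energy(3.0 * x) == pytest.approx(
            instantaneous_energy(x) + 2 * np.log10(3.0))


class TestTeagerEnergy:
    def test_linear_ramp(self):
        # n^2 - (n-1)(n+1) = 1 for every interior sample
        assert teager_energy(np.arange(50.0)) == pytest.approx(0.0)

    def test_constant_hits_floor(self):
        assert teager_energy(np.full(50, 2.0), log_floor=1e-12) == \
            pytest.approx(np.log10(1e-12))

    def test_sinusoid_closed_form(self):
        # Teager-Kaiser of A sin(Omega n) is A^2 sin^2(Omega)
        n = np.arange(4000)
        x = np.sin(np.pi * n / 4)
        assert teager_energy(x) == pytest.approx(np.log10(0.5), abs=1e-3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            teager_energy(np.array([1.0, 2.0]))


class TestFractalDimensions:
    def test_higuchi_line(self):
        assert 0.95 <= higuchi_fd(np.linspace(0, 1, 1000), k_max=10) <= 1.05

    def test_higuchi_white_noise(self):
        rng = np.random.default_rng(42)
        assert 1.8 <= higuchi_fd(rng.standard_normal(1000), k_max=10) <= 2.05

    def test_higuchi_affine_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(500)
        assert higuchi_fd(5.0 * x + 3.0) == pytest.approx(higuchi_fd(x))

    def test_higuchi_too_short(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.ones(15), k_max=10)

    def test_petrosian_monotone_is_one(self):
        assert petrosian_fd(np.arange(100.0)) == 1.0

    def test_petrosian_alternating(self):
        x = np.tile([1.0, -1.0], 50)
        n, n_delta = 100, 98
        expected = np.log10(n) / (np.log10(n)
                                  + np.log10(n / (n + 0.4 * n_delta)))
        assert petrosian_fd(x) == pytest.approx(expected)

    def test_petrosian_scaling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        assert petrosian_fd(2.5 * x) == pytest.approx(petrosian_fd(x))


class TestIMFSelection:
    def test_two_imfs_always_selected(self):
        t = np.linspace(0, 1, 100)
        imfset = IMFSet(original=np.sin(20 * t) + t, imfs=[np.sin(20 * t), t],
                        residual=np.zeros(100))
        assert select_imfs_minkowski(imfset) == (0, 1)

    def test_copy_of_original_selected_first(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        imfs = [rng.standard_normal(100), x.copy(), rng.standard_normal(100)]
        imfset = IMFSet(original=x, imfs=imfs, residual=np.zeros(100))
        assert select_imfs_minkowski(imfset)[0] == 1

    @pytest.mark.parametrize("p", [1.0, 2.0, 3.0])
    def test_matches_bruteforce_ranking(self, p):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(120)
        imfs = [x + rng.standard_normal(120) * s for s in (0.5, 2.0, 0.1, 1.0)]
        imfset = IMFSet(original=x, imfs=imfs, residual=np.zeros(120))
        dists = [minkowski(x, imf, p=p) for imf in imfs]
        expected = tuple(int(i) for i in np.argsort(dists, kind="stable")[:2])
        assert select_imfs_minkowski(imfset, p=p) == expected


class TestChannelBlocks:
    def test_block_has_eight_finite_features(self):
        t = np.arange(200) / 200.0
        block = extract_channel_features(np.sin(2 * np.pi * 11 * t))
        assert block.shape == (8,)
        assert np.all(np.isfinite(block))

    def test_degenerate_signal_duplicates_closest_mode(self):
        block = extract_channel_features(np.full(200, 1.3))
        assert block.shape == (8,)
        assert np.array_equal(block[:4], block[4:])

    def test_block_matches_manual_composition(self):
        rng = np.random.default_rng(9)
        t = np.arange(200) / 200.0
        sig = (np.sin(2 * np.pi * 18 * t) + 0.8 * np.sin(2 * np.pi * 5 * t)
               + 0.3 * rng.standard_normal(200))
        cfg = FeatureConfig()
        imfset = decompose(sig, cfg)
        first, second = select_imfs_minkowski(imfset, cfg.minkowski_p)
        expected = []
        for imf in (imfset.imfs[first], imfset.imfs[second]):
            expected += [instantaneous_energy(imf), teager_energy(imf),
                         higuchi_fd(imf, cfg.higuchi_kmax), petrosian_fd(imf)]
        assert np.allclose(extract_channel_features(sig, cfg), expected)

    def test_blocks_are_deterministic(self):
        rng = np.random.default_rng(13)
        sig = rng.standard_normal(200)
        a = extract_channel_features(sig.copy())
        b = extract_channel_features(sig.copy())
        assert np.array_equal(a, b)


class TestInstanceVectors:
    def test_vector_length_is_eight_per_channel(self):
        rng = np.random.default_rng(2)
        epoch = rng.standard_normal((6, 200))
        vec = build_instance_vector(epoch, {0, 2, 5})
        assert vec.shape == (24,)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_instance_vector(np.zeros((4, 200)), set())

    def test_cache_served_equals_direct(self, tiny_epochset, tiny_cache):
        from eegselect import apply_car
        referenced = apply_car(tiny_epochset)
        subject, session, epoch_idx = "S02", "1", 3
        epoch = referenced.get(subject, session)[epoch_idx]
        mask = {1, 4}
        direct = build_instance_vector(epoch, mask)
        served = build_instance_vector(
            epoch, mask,
            cached_blocks=tiny_cache.blocks[(subject, session)][epoch_idx])
        assert np.array_equal(direct, served)
        matrix = tiny_cache.instance_matrix(subject, session, mask)
        assert np.array_equal(matrix[epoch_idx], direct)
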