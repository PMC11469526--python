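"""Morlet filter bank and windowed scattering transform."""

import numpy as np
import pytest

from eswcnn.scattering import (
    LITTLEWOOD_PALEY_EPS,
    MorletFilterBank,
    ScatteringPath,
    build_filter_bank,
    export_features,
    load_features,
    path_count,
    scatter,
    scatter_features,
    scatter_pooled,
)


@pytest.fixture(scope="module")
def bank28():
    return build_filter_bank(28, 28, J=2, L=8)


class TestFilterBank:
    @pytest.mark.parametrize("J,L", [(1, 8), (2, 8)])
    def test_littlewood_paley_bound_default_banks(self, J, L):
        """Frame bound over the Nyquist disc stays within the stored eps of 1."""
        bank = build_filter_bank(28, 28, J, L)
        lp = bank.littlewood_paley_sum()
        disc = bank.nyquist_disc()
        assert lp.max() <= 1.0 + 1e-9
        assert lp[disc].min() >= 1.0 - bank.lp_eps - 1e-12
        assert bank.lp_eps <= LITTLEWOOD_PALEY_EPS + 1e-12

    def test_wavelets_have_zero_mean(self, bank28):
        for psi_hat in bank28.psi_hat.values():
            assert abs(psi_hat[0, 0]) <= 1e-6

    def test_filter_counts_and_lowpass_normalization(self):
        bank = build_filter_bank(28, 28, J=1, L=1)
        assert len(bank.psi_hat) == 1
        # unit DC gain <=> spatial phi sums to 1
        assert bank.phi_hat[0, 0] == pytest.approx(1.0, abs=1e-12)
        phi = np.fft.ifft2(bank.phi_hat).real
        assert phi.min() >= -1e-12  # Gaussian low-pass is nonnegative
        assert phi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_divisibility_error(self):
        with pytest.raises(ValueError, match="divisible"):
            build_filter_bank(30, 30, J=2, L=8)

    @pytest.mark.parametrize("J,L", [(0, 8), (1, 0)])
    def test_invalid_scale_orientation_counts(self, J, L):
        with pytest.raises(ValueError, match=">= 1"):
            build_filter_bank(28, 28, J, L)

    def test_deterministic_construction(self):
        a = build_filter_bank(28, 28, 1, 8)
        b = build_filter_bank(28, 28, 1, 8)
        for k in a.psi_hat:
            assert np.array_equal(a.psi_hat[k], b.psi_hat[k])


class TestPaths:
    def test_frequency_decreasing_rule(self):
        with pytest.raises(ValueError, match="strictly increase"):
            ScatteringPath(((1, 0), (1, 3)))
        ScatteringPath(((0, 0), (1, 3)))  # admissible

    @pytest.mark.parametrize(
        "J,L,order,expected",
        [(2, 8, 2, 1 + 16 + 64), (1, 8, 1, 9), (3, 4, 2, 1 + 12 + 16 * 3)],
    )
    def test_path_count_formula(self, J, L, order, expected):
        assert path_count(J, L, order) == expected


def _direct_scatter_oracle(image, bank, max_order):
    """Literal spatial-domain scattering: explicit circular convolution by
    filter taps, modulus, low-pass, subsample."""
    h, w = image.shape

    def circ_conv(x, taps):
        out = np.zeros((h, w), dtype=complex)
        for u in range(h):
            for v in range(w):
                acc = 0.0
                for a in range(h):
                    for b in range(w):
                        acc += x[a, b] * taps[(u - a) % h, (v - b) % w]
                out[u, v] = acc
        return out

    phi_taps = np.fft.ifft2(bank.phi_hat)
    step = 1 << bank.J

    def lowpass(x):
        return np.real(circ_conv(x, phi_taps))[::step, ::step]

    coeffs = {ScatteringPath(()): lowpass(image)}
    if max_order >= 1:
        for lam in bank.lambdas():
            taps = np.fft.ifft2(bank.psi_hat[lam])
            u1 = np.abs(circ_conv(image, taps))
            coeffs[ScatteringPath((lam,))] = lowpass(u1)
    return coeffs


class TestScatter:
    def test_zero_image_gives_zero_coefficients(self, bank28):
        res = scatter(np.zeros((28, 28)), bank28, max_order=2)
        assert all(np.allclose(v, 0.0) for v in res.coefficients.values())

    def test_constant_image(self, bank28):
        c = 3.7
        res = scatter(np.full((28, 28), c), bank28, max_order=2)
        maps = list(res.coefficients.items())
        assert np.allclose(maps[0][1], c, atol=1e-9)
        for path, coeff in maps[1:]:
            assert np.abs(coeff).max() <= 1e-4 * c

    def test_matches_direct_spatial_oracle(self):
        """FFT implementation equals the brute-force convolution oracle."""
        bank = build_filter_bank(8, 8, J=1, L=2)
        image = np.random.default_rng(42).random((8, 8))
        fast = scatter(image, bank, max_order=1)
        slow = _direct_scatter_oracle(image, bank, max_order=1)
        for path, coeff in fast.coefficients.items():
            assert np.abs(coeff - slow[path]).max() <= 1e-6

    def test_nonnegative_coefficients_for_nonnegative_input(self, bank28):
        img = np.random.default_rng(1).random((28, 28))
        res = scatter(img, bank28, max_order=2)
        for coeff in res.coefficients.values():
            assert coeff.min() >= -1e-9

    def test_shift_stability_improves_with_scale(self):
        """Relative change of S under a 2-pixel shift decreases as J grows."""
        changes = {}
        for J in (1, 2):
            bank = build_filter_bank(28, 28, J, 8)
            deltas = []
            for seed in range(20):
                img = np.random.default_rng(seed).random((28, 28))
                a = np.concatenate([c.ravel() for c in scatter(img, bank, 2).coefficients.values()])
                shifted = np.roll(img, 2, axis=1)
                b = np.concatenate(
                    [c.ravel() for c in scatter(shifted, bank, 2).coefficients.values()]
                )
                deltas.append(np.linalg.norm(a - b) / np.linalg.norm(a))
            changes[J] = np.mean(deltas)
        assert changes[2] < changes[1]

    def test_order2_energy_below_order1(self, bank28):
        """Scattering energy decays with path order on noise images."""
        for seed in range(50):
            img = np.random.default_rng(seed).standard_normal((28, 28))
            res = scatter(img, bank28, max_order=2)
            e1 = sum(
                float((v**2).sum()) for p, v in res.coefficients.items() if p.order == 1
            )
            e2 = sum(
                float((v**2).sum()) for p, v in res.coefficients.items() if p.order == 2
            )
            assert e2 <= e1

    def test_shape_and_order_validation(self, bank28):
        with pytest.raises(ValueError, match="does not match"):
            scatter(np.zeros((16, 16)), bank28)
        with pytest.raises(ValueError, match="max_order"):
            scatter(np.zeros((28, 28)), bank28, max_order=3)


class TestScatterFeatures:
    def test_depth_and_resolution(self):
        bank = build_filter_bank(28, 28, 1, 8)
        batch = np.random.default_rng(0).random((2, 3, 28, 28))
        feats = scatter_features(batch, bank, max_order=1)
        assert feats.shape == (2, 3 * 9, 28, 28)

    def test_identical_images_identical_stacks(self):
        bank = build_filter_bank(28, 28, 1, 4)
        img = np.random.default_rng(3).random((1, 3, 28, 28))
        batch = np.concatenate([img, img])
        feats = scatter_features(batch, bank, 1)
        assert np.array_equal(feats[0], feats[1])

    def test_batch_equals_single_image_loop(self):
        bank = build_filter_bank(28, 28, 2, 4)
        batch = np.random.default_rng(5).random((3, 2, 28, 28))
        feats = scatter_features(batch, bank, max_order=2)
        for i, sample in enumerate(batch):
            per_channel = []
            for ch in sample:
                stack = scatter(ch, bank, 2).stack()
                stack = np.repeat(np.repeat(stack, 4, axis=-2), 4, axis=-1)
                per_channel.append(stack)
            assert np.array_equal(feats[i], np.concatenate(per_channel))

    def test_empty_batch_error(self):
        bank = build_filter_bank(28, 28, 1, 2)
        with pytest.raises(ValueError, match="nonempty"):
            scatter_features(np.zeros((0, 3, 28, 28)), bank)

    def test_pooled_features_match_stack_means(self):
        bank = build_filter_bank(28, 28, 2, 4)
        batch = np.random.default_rng(6).random((2, 3, 28, 28))
        pooled = scatter_pooled(batch, bank, 2)
        expected = []
        for sample in batch:
            feats = [
                scatter(ch, bank, 2).stack().mean(axis=(1, 2)) for ch in sample
            ]
            expected.append(np.concatenate(feats))
        assert np.allclose(pooled, np.stack(expected), atol=1e-12)


def test_export_roundtrip(tmp_path):
    bank = build_filter_bank(28, 28, 1, 4)
    feats = scatter_features(np.random.default_rng(0).random((2, 1, 28, 28)), bank, 1)
    export_features(feats, bank, 1, tmp_path / "stack")
    loaded, meta = load_features(tmp_path / "stack")
    assert np.array_equal(loaded, feats)
    assert meta["J"] == 1 and meta["L"] == 4 and len(meta["paths"]) == 5
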