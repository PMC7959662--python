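"""Level-1 DWT and orthonormal DCT: oracle equivalence, Parseval,
perfect reconstruction and the dimension/truncation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadix.datatypes import FeatureMatrix
from cascadix.spectral import (
    WAVELETS,
    TransformConfig,
    apply_transform,
    dct_orthonormal,
    dwt_level1,
    idct_orthonormal,
    idwt_level1,
    select_coefficients,
    zigzag_indices,
)


def brute_force_dct(x):
    """O(d^2) cosine-sum oracle: X_k = s_k sum_n x_n cos(pi(2n+1)k/2d)."""
    x = np.asarray(x, dtype=np.float64)
    d = len(x)
    n = np.arange(d)
    out = np.empty(d)
    for k in range(d):
        s = np.sqrt(1.0 / d) if k == 0 else np.sqrt(2.0 / d)
        out[k] = s * np.sum(x * np.cos(np.pi * (2 * n + 1) * k / (2 * d)))
    return out


def brute_force_dwt(x, wavelet):
    """Circular convolve-then-downsample oracle, independent of the
    vectorised gather implementation."""
    lo = WAVELETS[wavelet]
    hi = lo[::-1].copy()
    hi[0::2] *= -1
    x = np.asarray(x, dtype=np.float64)
    if len(x) % 2:
        x = np.append(x, x[-1])
    d = len(x)
    ca = np.zeros(d // 2)
    cd = np.zeros(d // 2)
    for k in range(d // 2):
        for m in range(len(lo)):
            ca[k] += lo[m] * x[(2 * k + 1 - m) % d]
            cd[k] += hi[m] * x[(2 * k + 1 - m) % d]
    return ca, cd


class TestDWT:
    def test_hand_worked_haar_pair(self):
        ca, cd = dwt_level1([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(ca, [3 / np.sqrt(2), 7 / np.sqrt(2)], atol=1e-12)
        np.testing.assert_allclose(cd, [-1 / np.sqrt(2), -1 / np.sqrt(2)], atol=1e-12)

    def test_constant_vector_has_zero_detail(self):
        ca, cd = dwt_level1(np.full(10, 3.5))
        np.testing.assert_allclose(cd, 0.0, atol=1e-12)
        np.testing.assert_allclose(ca, 3.5 * np.sqrt(2), atol=1e-12)

    @pytest.mark.parametrize("wavelet", ["haar", "db2"])
    @pytest.mark.parametrize("d", [2, 3, 8, 17, 64, 101])
    def test_perfect_reconstruction_and_oracle(self, wavelet, d, rng):
        x = rng.standard_normal(d)
        ca, cd = dwt_level1(x, wavelet)
        assert len(ca) == len(cd) == -(-d // 2)
        np.testing.assert_allclose(idwt_level1(ca, cd, wavelet, length=d), x, atol=1e-8)
        oca, ocd = brute_force_dwt(x, wavelet)
        np.testing.assert_allclose(ca, oca, atol=1e-8)
        np.testing.assert_allclose(cd, ocd, atol=1e-8)

    def test_haar_matches_pywt_periodization(self, rng):
        pywt = pytest.importorskip("pywt")
        x = rng.standard_normal(32)
        ca, cd = dwt_level1(x, "haar")
        ref_ca, ref_cd = pywt.dwt(x, "haar", mode="periodization")
        np.testing.assert_allclose(ca, ref_ca, atol=1e-10)
        np.testing.assert_allclose(cd, ref_cd, atol=1e-10)

    @pytest.mark.parametrize("wavelet", ["haar", "db2"])
    def test_analysis_operator_is_orthonormal(self, wavelet):
        """The periodic analysis map applied to the canonical basis yields
        an orthogonal matrix (phase conventions differ between libraries,
        but orthonormality pins the filter bank down to a rotation)."""
        d = 16
        W = np.zeros((d, d))
        for j in range(d):
            e = np.zeros(d)
            e[j] = 1.0
            ca, cd = dwt_level1(e, wavelet)
            W[: d // 2, j] = ca
            W[d // 2 :, j] = cd
        np.testing.assert_allclose(W @ W.T, np.eye(d), atol=1e-10)

    def test_parseval_even_lengths(self, rng):
        for wavelet in WAVELETS:
            x = rng.standard_normal(64)
            ca, cd = dwt_level1(x, wavelet)
            assert np.isclose(
                np.sum(ca**2) + np.sum(cd**2), np.sum(x**2), atol=1e-8
            )

    def test_halving_at_deep_feature_width(self, rng):
        ca, _ = dwt_level1(rng.standard_normal(4096))
        assert len(ca) == 2048

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            dwt_level1([1.0])


class TestDCT:
    def test_constant_vector_is_dc_only(self):
        c = dct_orthonormal(np.full(16, 2.0))
        assert np.isclose(c[0], 2.0 * np.sqrt(16))
        np.testing.assert_allclose(c[1:], 0.0, atol=1e-12)

    def test_two_point_example(self):
        np.testing.assert_allclose(
            dct_orthonormal([1.0, 0.0]), [np.sqrt(0.5), np.sqrt(0.5)], atol=1e-10
        )

    @pytest.mark.parametrize("d", [1, 2, 5, 16, 33, 64])
    def test_brute_force_oracle(self, d, rng):
        x = rng.standard_normal(d)
        np.testing.assert_allclose(dct_orthonormal(x), brute_force_dct(x), atol=1e-8)

    @given(st.integers(2, 48), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_parseval_and_inverse(self, d, seed):
        x = np.random.default_rng(seed).standard_normal(d)
        c = dct_orthonormal(x)
        assert np.isclose(np.linalg.norm(c), np.linalg.norm(x), atol=1e-8)
        np.testing.assert_allclose(idct_orthonormal(c), x, atol=1e-8)

    def test_matches_scipy_ortho(self, rng):
        fft = pytest.importorskip("scipy.fft")
        x = rng.standard_normal(50)
        np.testing.assert_allclose(dct_orthonormal(x), fft.dct(x, norm="ortho"), atol=1e-10)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            dct_orthonormal([])


class TestSelection:
    def test_truncates_long_vectors_to_keep(self, rng):
        c = rng.standard_normal(4096)
        out = select_coefficients(c, TransformConfig(kind="dct"))
        assert len(out) == 500
        np.testing.assert_array_equal(out, c[:500])

    def test_short_vectors_pass_unchanged(self, rng):
        c = rng.standard_normal(8)
        np.testing.assert_array_equal(select_coefficients(c, TransformConfig(kind="dct")), c)

    def test_keep_equal_d_is_identity(self, rng):
        c = rng.standard_normal(32)
        cfg = TransformConfig(kind="dct", dct_keep=32)
        np.testing.assert_array_equal(select_coefficients(c, cfg), c)

    def test_zigzag_square_block_order(self):
        # canonical 3x3 JPEG zigzag: 0 1 3 | 4 2 5 | 6 7 8 read linearly
        np.testing.assert_array_equal(
            zigzag_indices(3, 3), [0, 1, 3, 6, 4, 2, 5, 7, 8]
        )

    def test_zigzag_mode_keeps_low_frequency_mass(self, rng):
        c = 1.0 / (1.0 + np.arange(100.0))  # energy concentrated at low indices
        cfg = TransformConfig(kind="dct", dct_keep=20, dct_order="zigzag2d")
        out = select_coefficients(c, cfg)
        assert len(out) == 20
        assert np.sum(out**2) > 0.8 * np.sum(c**2)


class TestApplyTransform:
    def _fm(self, rng, n=6, d=32):
        labels = np.array(["a", "b", "c"] * (n // 3))
        return FeatureMatrix(rng.standard_normal((n, d)), labels, backbone="bb")

    @pytest.mark.parametrize(
        "cfg,expected_dim",
        [
            (TransformConfig(kind="dwt_ca"), 16),
            (TransformConfig(kind="dwt_cd"), 16),
            (TransformConfig(kind="dct"), 32),
            (TransformConfig(kind="dct", dct_keep=10), 10),
        ],
    )
    def test_dimension_contract(self, cfg, expected_dim, rng):
        tf = apply_transform(self._fm(rng), cfg)
        assert tf.values.shape == (6, expected_dim)
        np.testing.assert_array_equal(tf.labels, self._fm(rng).labels)

    def test_rows_match_vector_level_operation(self, rng):
        fm = self._fm(rng)
        tf = apply_transform(fm, TransformConfig(kind="dwt_ca"))
        ca0, _ = dwt_level1(fm.values[0])
        np.testing.assert_allclose(tf.values[0], ca0, atol=1e-12)
        tfd = apply_transform(fm, TransformConfig(kind="dct", dct_keep=12))
        np.testing.assert_allclose(tfd.values[2], dct_orthonormal(fm.values[2])[:12], atol=1e-12)

    def test_provenance_recorded(self, rng):
        tf = apply_transform(self._fm(rng), TransformConfig(kind="dct", dct_keep=10))
        assert tf.transform == "dct10" and tf.source == "bb"
        assert tf.name == "bb/dct10"

    def test_nonfinite_input_rejected(self, rng):
        fm = self._fm(rng)
        fm.values[0, 0] = np.inf
        with pytest.raises(ValueError):
            apply_transform(fm, TransformConfig(kind="dct"))
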