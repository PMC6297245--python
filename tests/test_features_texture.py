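"""Texture-matrix and histogram statistics vs exhaustive enumerator oracles."""

import numpy as np
import pytest

from reconradiomics import (
    FeatureBankConfig,
    ImageVolume,
    LesionMask,
    extract_features,
    expected_feature_count,
    glcm_features,
    histogram_features,
    ngtdm_features,
    quantize,
)
from reconradiomics.features import ParameterError, UndefinedMatrixError


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_glcm_matrix(levels, mask, offsets, n):
    """Exhaustive pair enumerator over every voxel and offset (symmetric)."""
    matrix = np.zeros((n, n))
    sx, sy, sz = levels.shape
    for x in range(sx):
        for y in range(sy):
            for z in range(sz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < sx and 0 <= v < sy and 0 <= w < sz and mask[u, v, w]:
                        a, b = levels[x, y, z] - 1, levels[u, v, w] - 1
                        matrix[a, b] += 1
                        matrix[b, a] += 1
    return matrix


def brute_ngtdm(levels, mask, n, planar):
    """Per-voxel neighborhood-average enumerator (complete neighborhoods)."""
    sx, sy, sz = levels.shape
    zrange = (0,) if planar else (-1, 0, 1)
    n_i = np.zeros(n)
    s_i = np.zeros(n)
    for x in range(sx):
        for y in range(sy):
            for z in range(sz):
                if not mask[x, y, z]:
                    continue
                neighbors = []
                complete = True
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in zrange:
                            if dx == dy == dz == 0:
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < sx and 0 <= v < sy and 0 <= w < sz and mask[u, v, w]:
                                neighbors.append(levels[u, v, w])
                            else:
                                complete = False
                if complete:
                    i = levels[x, y, z] - 1
                    n_i[i] += 1
                    s_i[i] += abs(levels[x, y, z] - np.mean(neighbors))
    return n_i, s_i


def _volume_mask(array):
    array = np.asarray(array, dtype=float)
    if array.ndim == 2:
        array = array[:, :, None]
    volume = ImageVolume(values=array, spacing=(1, 1, 1))
    mask = LesionMask(values=np.ones(array.shape, dtype=bool), spacing=(1, 1, 1))
    return volume, mask


class TestQuantize:
    def test_constant_region_all_level_one(self):
        assert (quantize(np.full(10, 3.3), 8) == 1).all()

    def test_linear_ramp_occupies_all_levels(self):
        levels = quantize(np.arange(32, dtype=float), 32)
        assert sorted(set(levels)) == list(range(1, 33))

    def test_extremes_map_to_first_and_last_level(self, rng):
        x = rng.normal(size=100)
        levels = quantize(x, 16)
        assert levels[np.argmin(x)] == 1
        assert levels[np.argmax(x)] == 16

    def test_too_few_levels_rejected(self):
        with pytest.raises(ParameterError):
            quantize(np.arange(4.0), 1)


class TestGLCM:
    def test_constant_region_degenerate_matrix(self):
        volume, mask = _volume_mask(np.full((4, 4, 2), 5.0))
        out = glcm_features(volume, mask, FeatureBankConfig(n_gray_levels=8), mode="3D")
        assert out["ASM"] == pytest.approx(1.0)
        assert out["Homogeneity"] == pytest.approx(1.0)
        assert out["Contrast"] == pytest.approx(0.0)

    def test_checkerboard_matches_exhaustive_enumerator(self):
        """2-level checkerboard slice: ASM from hand pair-counting."""
        board = np.indices((4, 4)).sum(axis=0) % 2
        volume, mask = _volume_mask(board * 10.0)
        config = FeatureBankConfig(n_gray_levels=2)
        out = glcm_features(volume, mask, config, mode="25D")
        from reconradiomics.features import _OFFSETS_2D, _glcm_stats

        levels = quantize(volume.values[mask.values], 2).reshape(4, 4, 1)
        matrix = brute_glcm_matrix(levels, mask.values, _OFFSETS_2D, 2)
        expected = _glcm_stats(matrix)
        for key in out:
            assert out[key] == pytest.approx(expected[key], abs=1e-12)
        # independent hand count for the checkerboard: horizontal+vertical
        # neighbors always differ, diagonal neighbors always match
        p_same = matrix[0, 0] + matrix[1, 1]
        p_diff = matrix[0, 1] + matrix[1, 0]
        assert p_same == 2 * 18  # 9+9 diagonal pairs, symmetric
        assert p_diff == 2 * 24  # 12+12 axis pairs, symmetric

    @pytest.mark.parametrize("mode", ["2D", "25D", "3D"])
    def test_random_volume_matches_enumerator(self, rng, mode, small_volume, small_mask):
        config = FeatureBankConfig(n_gray_levels=5)
        out = glcm_features(small_volume, small_mask, config, mode=mode)
        from reconradiomics.features import _OFFSETS_2D, _OFFSETS_3D, _glcm_stats

        m = small_mask.values
        levels = np.zeros(small_volume.shape, dtype=int)
        levels[m] = quantize(small_volume.values[m], 5)
        if mode == "3D":
            expected = _glcm_stats(brute_glcm_matrix(levels, m, _OFFSETS_3D, 5))
        elif mode == "25D":
            expected = _glcm_stats(brute_glcm_matrix(levels, m, _OFFSETS_2D, 5))
        else:
            rows, weights = [], []
            for k in range(small_volume.shape[2]):
                mk = m[:, :, k : k + 1]
                if not mk.any():
                    continue
                matrix = brute_glcm_matrix(levels[:, :, k : k + 1], mk, _OFFSETS_2D, 5)
                rows.append(_glcm_stats(matrix))
                weights.append(mk.sum())
            w = np.array(weights) / np.sum(weights)
            expected = {k: float(sum(w[i] * rows[i][k] for i in range(len(rows)))) for k in rows[0]}
        for key in out:
            assert out[key] == pytest.approx(expected[key], abs=1e-10)

    def test_normalization_sums_to_one(self, rng, small_volume, small_mask):
        from reconradiomics.features import _OFFSETS_3D, _glcm_matrix

        m = small_mask.values
        levels = np.zeros(small_volume.shape, dtype=int)
        levels[m] = quantize(small_volume.values[m], 6)
        matrix = _glcm_matrix(levels, m, _OFFSETS_3D, 6)
        assert (matrix / matrix.sum()).sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_voxel_mask_undefined(self):
        volume = ImageVolume(values=np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        m = np.zeros((3, 3, 3), dtype=bool)
        m[1, 1, 1] = True
        with pytest.raises(UndefinedMatrixError):
            glcm_features(volume, LesionMask(values=m, spacing=(1, 1, 1)), mode="3D")


class TestNGTDM:
    def test_constant_region_contrast_zero_coarseness_capped(self):
        volume, mask = _volume_mask(np.full((5, 5, 3), 9.0))
        out = ngtdm_features(volume, mask, FeatureBankConfig(n_gray_levels=4), mode="3D")
        assert out["Contrast"] == 0.0
        assert out["Coarseness"] == pytest.approx(1e12)

    @pytest.mark.parametrize("mode,planar", [("25D", True), ("3D", False)])
    def test_random_patch_matches_enumerator(self, rng, small_volume, small_mask, mode, planar):
        config = FeatureBankConfig(n_gray_levels=4)
        out = ngtdm_features(small_volume, small_mask, config, mode=mode)
        from reconradiomics.features import _ngtdm_stats

        m = small_mask.values
        levels = np.zeros(small_volume.shape, dtype=int)
        levels[m] = quantize(small_volume.values[m], 4)
        expected = _ngtdm_stats(*brute_ngtdm(levels, m, 4, planar))
        for key in out:
            assert out[key] == pytest.approx(expected[key], rel=1e-10)

    def test_two_level_patch_hand_enumerated(self):
        patch = np.zeros((4, 4))
        patch[2:, :] = 1.0
        volume, mask = _volume_mask(patch)
        out = ngtdm_features(volume, mask, FeatureBankConfig(n_gray_levels=2), mode="25D")
        levels = np.where(patch > 0, 2, 1)[:, :, None]
        n_i, s_i = brute_ngtdm(levels, np.ones((4, 4, 1), dtype=bool), 2, planar=True)
        from reconradiomics.features import _ngtdm_stats

        expected = _ngtdm_stats(n_i, s_i)
        assert out["Coarseness"] == pytest.approx(expected["Coarseness"], rel=1e-12)
        assert out["Contrast"] == pytest.approx(expected["Contrast"], rel=1e-12)

    def test_contrast_nonnegative(self, rng):
        for _ in range(5):
            volume, mask = _volume_mask(rng.integers(0, 5, size=(6, 6, 3)).astype(float))
            out = ngtdm_features(volume, mask, FeatureBankConfig(n_gray_levels=4), mode="3D")
            assert out["Contrast"] >= 0.0

    def test_no_complete_neighborhood_raises(self):
        volume = ImageVolume(values=np.zeros((3, 3, 1)), spacing=(1, 1, 1))
        m = np.zeros((3, 3, 1), dtype=bool)
        m[0, :, 0] = True  # a line: no voxel has 8 in-plane neighbors
        with pytest.raises(UndefinedMatrixError):
            ngtdm_features(volume, LesionMask(values=m, spacing=(1, 1, 1)), mode="25D")


class TestHistogram:
    def test_uniform_k_bins_entropy_closed_form(self):
        # 32 values on a ramp occupy 32 bins uniformly: entropy = log2(32) = 5
        out = histogram_features(np.arange(32, dtype=float), 32)
        assert out["Entropy"] == pytest.approx(5.0, abs=1e-12)
        out16 = histogram_features(np.arange(16, dtype=float), 16)
        assert out16["Entropy"] == pytest.approx(4.0, abs=1e-12)

    def test_constant_sample(self):
        out = histogram_features(np.full(20, 2.5), 32)
        assert out["Entropy"] == 0.0
        assert out["Uniformity"] == 1.0
        assert out["Std"] == 0.0
        assert out["Skewness"] == 0.0

    def test_normal_sample_matches_direct_recomputation(self, rng):
        x = rng.standard_normal(100)
        out = histogram_features(x, 16)
        counts, _ = np.histogram(x, bins=16, range=(x.min(), x.max()))
        p = counts / 100
        expected = -sum(pi * np.log2(pi) for pi in p if pi > 0)
        assert out["Entropy"] == pytest.approx(expected, abs=1e-12)
        assert out["Uniformity"] == pytest.approx((p**2).sum(), abs=1e-12)
        assert out["Mean"] == pytest.approx(x.mean())
        assert out["Median"] == pytest.approx(np.median(x))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.array([]), 8)


class TestExtraction:
    def test_table2_names_present_and_deterministic(self, rng):
        values = rng.normal(0, 30, size=(14, 14, 8)) + 100.0
        volume = ImageVolume(values=values, spacing=(1, 1, 1))
        m = np.zeros(values.shape, dtype=bool)
        m[2:12, 2:12, 1:7] = True
        mask = LesionMask(values=m, spacing=(1, 1, 1))
        config = FeatureBankConfig(include_sigmoid=False)
        out = extract_features(volume, mask, config)
        assert "LoG_Entropy_Sigma2.5_2D" in out
        assert "LoG_Z_Uniformity_Sigma2.5_2D" in out
        assert "GLCM_ASM_2D" in out
        assert "GTDM_Coarseness_25D" in out
        assert "Laws_Entropy_8_3D" in out
        assert "Shape_SI9_3D" in out
        out2 = extract_features(volume, mask, config)
        assert list(out) == list(out2)
        assert all(out[k] == out2[k] for k in out)

    def test_feature_count_matches_grammar_enumeration(self):
        """Closed-form count vs independent enumeration of the name grammar."""
        from reconradiomics.features import (
            GLCM_STATS,
            HISTOGRAM_AGGREGATIONS,
            HISTOGRAM_STATS,
            NGTDM_STATS,
            TEXTURE_AGGREGATIONS,
            Z_STATS,
        )

        for config in (
            FeatureBankConfig(),
            FeatureBankConfig(include_sigmoid=False, laws_codes=(1, 8)),
            FeatureBankConfig(include_log_z=False, gabor_wavelengths_mm=(2.0, 4.0)),
        ):
            names = []
            for sigma in config.log_sigmas_mm:
                for agg in HISTOGRAM_AGGREGATIONS:
                    names += [f"LoG_{s}_Sigma{sigma:g}_{agg}" for s in HISTOGRAM_STATS]
                    if config.include_log_z:
                        names += [f"LoG_Z_{s}_Sigma{sigma:g}_{agg}" for s in Z_STATS]
            for w in config.gabor_wavelengths_mm:
                for d in config.gabor_directions_deg:
                    for agg in HISTOGRAM_AGGREGATIONS:
                        names += [f"Gabor_{s}_dir{d}_{agg}" for s in HISTOGRAM_STATS]
            for code in config.laws_codes:
                names += [f"Laws_{s}_{code}_3D" for s in HISTOGRAM_STATS]
            if config.include_glcm:
                for agg in TEXTURE_AGGREGATIONS:
                    names += [f"GLCM_{s}_{agg}" for s in GLCM_STATS]
            if config.include_ngtdm:
                for agg in TEXTURE_AGGREGATIONS:
                    names += [f"GTDM_{s}_{agg}" for s in NGTDM_STATS]
            if config.include_shape:
                names += ["V", "D", "C", "R"] + [f"SI{k}" for k in range(9)]
            if config.include_sigmoid:
                names += ["A1", "A2", "A3", "S1", "S2", "S3"]
            assert expected_feature_count(config) == len(names)

    def test_shift_invariance_of_quantized_texture_features(self, rng):
        """GLCM/GTDM and histogram entropy are invariant to +constant."""
        values = rng.normal(0, 10, size=(10, 10, 6))
        m = np.zeros(values.shape, dtype=bool)
        m[1:9, 1:9, 1:5] = True
        mask = LesionMask(values=m, spacing=(1, 1, 1))
        config = FeatureBankConfig(n_gray_levels=8)
        a = ImageVolume(values=values, spacing=(1, 1, 1))
        b = ImageVolume(values=values + 500.0, spacing=(1, 1, 1))
        for mode in ("2D", "25D", "3D"):
            fa = glcm_features(a, mask, config, mode)
            fb = glcm_features(b, mask, config, mode)
            for key in fa:
                assert fa[key] == pytest.approx(fb[key], abs=1e-12)
            ga = ngtdm_features(a, mask, config, mode)
            gb = ngtdm_features(b, mask, config, mode)
            for key in ga:
                assert ga[key] == pytest.approx(gb[key], rel=1e-9)
        ha = histogram_features(values[m], 32)
        hb = histogram_features(values[m] + 500.0, 32)
        assert ha["Entropy"] == pytest.approx(hb["Entropy"], abs=1e-10)
        assert ha["Uniformity"] == pytest.approx(hb["Uniformity"], abs=1e-10)
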