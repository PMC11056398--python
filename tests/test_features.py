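import math

import numpy as np
import pytest

from bonetex.features import (
    GLCM_STATISTIC_NAMES,
    Direction,
    FeatureConfig,
    QuantizedImage,
    extract_features,
    feature_names,
    glcm,
    glcm_statistics,
    histogram_features,
    quantize,
)
from bonetex.imaging import SliceImage
from bonetex.roi import DegenerateInputError

# ---------------------------------------------------------------------------
# independent oracles


def oracle_histogram(x):
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    if m2 == 0:
        return mean, 0.0, 0.0, 0.0, 0.0
    edges = np.linspace(x.min(), x.max(), 257)
    counts = np.zeros(256)
    for v in x:
        k = np.searchsorted(edges, v, side="right") - 1
        counts[min(k, 255)] += 1
    p = counts[counts > 0] / n
    ent = -sum(pi * math.log2(pi) for pi in p)
    return mean, math.sqrt(m2), m3 / m2**1.5, m4 / m2**2, ent


def oracle_glcm(levels, n, direction, symmetric=True):
    """Literal double-loop pair counter."""
    dr, dc = (0, 1) if direction == Direction.HORIZONTAL else (1, 0)
    P = np.zeros((n, n))
    nr, nc = levels.shape
    for r in range(nr - dr):
        for c in range(nc - dc):
            i, j = levels[r, c], levels[r + dr, c + dc]
            P[i, j] += 1
            if symmetric:
                P[j, i] += 1
    return P / P.sum()


def oracle_statistics(P):
    """Literal double-sum Haralick statistics."""
    n = P.shape[0]
    ent = -sum(
        P[i, j] * math.log2(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0
    )
    con = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = sum(i * p_i[i] for i in range(n))
    mu_j = sum(j * p_j[j] for j in range(n))
    var_i = sum((i - mu_i) ** 2 * p_i[i] for i in range(n))
    var_j = sum((j - mu_j) ** 2 * p_j[j] for j in range(n))
    if var_i == 0 or var_j == 0:
        cor = 0.0
    else:
        cov = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(n) for j in range(n)
        )
        cor = cov / math.sqrt(var_i * var_j)
    hom = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    var = sum((i - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    return ent, con, cor, hom, var


# ---------------------------------------------------------------------------


class TestHistogramFeatures:
    def test_constant_roi_conventions(self):
        f = histogram_features(SliceImage(np.full((3, 3), 100.0)))
        assert list(f.values()) == [100.0, 0.0, 0.0, 0.0, 0.0]

    def test_four_point_case(self):
        f = histogram_features(SliceImage(np.array([[1.0, 2.0], [3.0, 4.0]])))
        assert f["hist_mean"] == pytest.approx(2.5)
        assert f["hist_std"] == pytest.approx(1.118034, abs=1e-6)
        assert f["hist_skew"] == pytest.approx(0.0, abs=1e-12)
        assert f["hist_kurt"] == pytest.approx(1.64)

    def test_matches_direct_oracle(self, random_roi):
        f = histogram_features(random_roi)
        expected = oracle_histogram(random_roi.pixels)
        assert list(f.values()) == pytest.approx(expected, abs=1e-10)

    def test_mean_shifts_others_invariant_under_hu_offset(self, random_roi):
        f0 = histogram_features(random_roi)
        shifted = SliceImage(random_roi.pixels + 75.0)
        f1 = histogram_features(shifted)
        assert f1["hist_mean"] == pytest.approx(f0["hist_mean"] + 75.0)
        for key in ("hist_std", "hist_skew", "hist_kurt", "hist_entropy"):
            assert f1[key] == pytest.approx(f0[key], abs=1e-9)


class TestQuantize:
    def test_ramp_each_value_own_level(self):
        roi = SliceImage(np.arange(16, dtype=float).reshape(4, 4))
        q = quantize(roi, 16)
        assert np.array_equal(q.levels, np.arange(16).reshape(4, 4))

    @pytest.mark.parametrize("n", [16, 32, 128])
    def test_constant_roi_all_zero(self, n):
        q = quantize(SliceImage(np.full((4, 4), 250.0)), n)
        assert not q.levels.any()

    @pytest.mark.parametrize("n", [16, 32, 64, 128])
    def test_binning_oracle_and_max_maps_to_top(self, rng, n):
        x = rng.uniform(-100, 500, (10, 10))
        q = quantize(SliceImage(x), n)
        lo, hi = x.min(), x.max()
        expected = np.minimum((n * (x - lo) / (hi - lo)).astype(int), n - 1)
        assert np.array_equal(q.levels, expected)
        assert q.levels[np.unravel_index(np.argmax(x), x.shape)] == n - 1

    def test_fixed_window_mode_clips(self):
        roi = SliceImage(np.array([[-100.0, 0.0], [200.0, 500.0]]))
        q = quantize(roi, 16, hu_range=(0.0, 400.0))
        assert q.levels[0, 0] == 0 and q.levels[1, 1] == 15
        assert q.levels[1, 0] == 8  # 16 * 200/400


class TestGlcm:
    def test_two_column_stripe(self):
        q = QuantizedImage(np.array([[0, 1], [0, 1]]), 2, 0, 1)
        g = glcm(q, Direction.HORIZONTAL)
        assert g.P[0, 1] == 0.5 and g.P[1, 0] == 0.5
        assert g.P[0, 0] == 0.0 and g.P[1, 1] == 0.0
        assert g.pair_count == 2

    def test_constant_image_all_mass_at_origin(self):
        q = QuantizedImage(np.zeros((4, 4), dtype=int), 16, 0, 0)
        g = glcm(q, Direction.VERTICAL)
        assert g.P[0, 0] == 1.0

    def test_single_column_horizontal_degenerate(self):
        q = QuantizedImage(np.zeros((5, 1), dtype=int), 4, 0, 0)
        with pytest.raises(DegenerateInputError):
            glcm(q, Direction.HORIZONTAL)

    @pytest.mark.parametrize("direction", list(Direction))
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_pair_count_oracle(self, rng, direction, symmetric):
        lv = rng.integers(0, 16, (10, 10))
        q = QuantizedImage(lv, 16, 0, 15)
        g = glcm(q, direction, symmetric=symmetric)
        assert g.P == pytest.approx(oracle_glcm(lv, 16, direction, symmetric), abs=1e-12)

    def test_normalization_and_symmetry_invariants(self, rng):
        lv = rng.integers(0, 32, (12, 9))
        g = glcm(QuantizedImage(lv, 32, 0, 31), Direction.HORIZONTAL)
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(g.P, g.P.T, atol=1e-15)
        assert (g.P >= 0).all()

    def test_matches_skimage_reference(self, rng):
        """Independent cross-check against scikit-image's GLCM builder."""
        from skimage.feature import graycomatrix

        lv = rng.integers(0, 16, (11, 13))
        q = QuantizedImage(lv, 16, 0, 15)
        for direction, angle in [(Direction.HORIZONTAL, 0.0), (Direction.VERTICAL, np.pi / 2)]:
            mine = glcm(q, direction).P
            ref = graycomatrix(
                lv.astype(np.uint8), [1], [angle], levels=16, symmetric=True, normed=True
            )[:, :, 0, 0]
            assert mine == pytest.approx(ref, abs=1e-12)


class TestGlcmStatistics:
    def test_point_mass(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        s = glcm_statistics(
            type("G", (), {"P": P, "n_levels": 4})()
        )
        assert list(s.values()) == pytest.approx([0.0, 0.0, 0.0, 1.0, 0.0])

    def test_antidiagonal_stripe_closed_form(self):
        """Stripe [[0,1],[0,1]] at N=16: P(0,15)=P(15,0)=1/2."""
        roi = SliceImage(np.array([[0.0, 1.0], [0.0, 1.0]]))
        g = glcm(quantize(roi, 16), Direction.HORIZONTAL)
        s = glcm_statistics(g)
        assert s["entropy"] == pytest.approx(1.0)
        assert s["contrast"] == pytest.approx(225.0)
        assert s["correlation"] == pytest.approx(-1.0)
        assert s["homogeneity"] == pytest.approx(1.0 / 226.0)
        assert s["variance"] == pytest.approx(56.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((16, 16))
        P = raw + raw.T
        P /= P.sum()
        g = type("G", (), {"P": P, "n_levels": 16})()
        got = list(glcm_statistics(g).values())
        assert got == pytest.approx(oracle_statistics(P), abs=1e-10)

    def test_statistic_ranges(self, rng):
        lv = rng.integers(0, 16, (14, 14))
        g = glcm(QuantizedImage(lv, 16, 0, 15), Direction.HORIZONTAL)
        s = glcm_statistics(g)
        assert 0.0 <= s["entropy"] <= 2 * math.log2(16)
        assert 0.0 < s["homogeneity"] <= 1.0
        assert -1.0 <= s["correlation"] <= 1.0
        assert 0.0 <= s["contrast"] <= 15**2

    def test_homogeneity_abs_variant(self):
        P = np.zeros((4, 4))
        P[0, 2] = P[2, 0] = 0.5
        g = type("G", (), {"P": P, "n_levels": 4})()
        assert glcm_statistics(g)["homogeneity"] == pytest.approx(1 / 5)
        assert glcm_statistics(g, homogeneity_kind="abs")["homogeneity"] == pytest.approx(1 / 3)


class TestExtractFeatures:
    def test_vector_has_45_named_features(self, random_roi):
        fv = extract_features(random_roi)
        assert len(fv.values) == 45
        assert fv.names == feature_names()
        assert fv.names[:5] == ("hist_mean", "hist_std", "hist_skew", "hist_kurt", "hist_entropy")
        glcm_names = fv.names[5:]
        assert len(glcm_names) == 40
        # 8 GLCMs: N ascending, horizontal before vertical, 5 stats each
        expected = [
            f"glcm_{n}_{d}_{s}"
            for n in (16, 32, 64, 128)
            for d in ("horizontal", "vertical")
            for s in GLCM_STATISTIC_NAMES
        ]
        assert list(glcm_names) == expected

    def test_constant_roi_composition(self):
        fv = extract_features(SliceImage(np.full((6, 6), 150.0)))
        assert fv.values[:5] == pytest.approx([150.0, 0, 0, 0, 0])
        glcm_part = fv.values[5:].reshape(8, 5)
        for block in glcm_part:
            assert block == pytest.approx([0.0, 0.0, 0.0, 1.0, 0.0])

    def test_equals_manual_composition(self, random_roi):
        fv = extract_features(random_roi)
        manual = list(histogram_features(random_roi).values())
        for n in (16, 32, 64, 128):
            q = quantize(random_roi, n)
            for d in (Direction.HORIZONTAL, Direction.VERTICAL):
                manual.extend(glcm_statistics(glcm(q, d)).values())
        assert fv.values == pytest.approx(np.array(manual), abs=0)

    def test_hu_shift_leaves_glcm_features_unchanged(self, random_roi):
        fv0 = extract_features(random_roi)
        fv1 = extract_features(SliceImage(random_roi.pixels + 123.0))
        assert fv1.values[5:] == pytest.approx(fv0.values[5:], abs=1e-9)
        assert fv1.values[0] == pytest.approx(fv0.values[0] + 123.0)
        assert fv1.values[1:5] == pytest.approx(fv0.values[1:5], abs=1e-9)

    def test_transpose_swaps_directions(self, random_roi):
        fv0 = extract_features(random_roi)
        fv1 = extract_features(SliceImage(random_roi.pixels.T.copy()))
        d0 = fv0.as_dict()
        d1 = fv1.as_dict()
        for n in (16, 32, 64, 128):
            for s in GLCM_STATISTIC_NAMES:
                assert d1[f"glcm_{n}_horizontal_{s}"] == pytest.approx(
                    d0[f"glcm_{n}_vertical_{s}"], abs=1e-12
                )
                assert d1[f"glcm_{n}_vertical_{s}"] == pytest.approx(
                    d0[f"glcm_{n}_horizontal_{s}"], abs=1e-12
                )
        assert fv1.values[:5] == pytest.approx(fv0.values[:5], abs=1e-12)

    def test_full_vector_oracle_equivalence(self):
        """Every feature matches a naive independent implementation."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            x = rng.uniform(-50, 450, (16, 16))
            roi = SliceImage(x)
            fv = extract_features(roi)
            expected = list(oracle_histogram(x))
            for n in (16, 32, 64, 128):
                lo, hi = x.min(), x.max()
                lv = np.minimum((n * (x - lo) / (hi - lo)).astype(int), n - 1)
                for d in (Direction.HORIZONTAL, Direction.VERTICAL):
                    P = oracle_glcm(lv, n, d)
                    expected.extend(oracle_statistics(P))
            assert fv.values == pytest.approx(np.array(expected), abs=1e-10)
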