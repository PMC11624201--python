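import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ischclock.io_preprocess import ImageVolume, LesionMask, mirror_mask
from ischclock.phantom import PhantomSpec, generate_ncct_phantom, simulate_cohort
from ischclock.radiomics import (PAPER_SELECTED, depth_map, extract_features,
                                 extract_feature_table, glcm_correlation,
                                 glcm_matrix, lacunarity, ngtdm_busyness,
                                 ngtdm_features, select_features,
                                 weighted_quantile, weighted_stats)

UNIT = (1.0, 1.0, 1.0)


def _vm(data, mask=None, spacing=UNIT):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape, bool)
    return ImageVolume(data, spacing), LesionMask(np.asarray(mask, bool), spacing)


# ---------------------------------------------------------------------------
# brute-force oracles (plain python loops, no vectorization shared with the
# implementation under test)
# ---------------------------------------------------------------------------

def brute_glcm_correlation(data, mask, levels, offsets):
    vals = data[mask]
    mn, mx = vals.min(), vals.max()
    q = np.clip(np.floor((data - mn) / (mx - mn) * levels), 0,
                levels - 1).astype(int)
    P = np.zeros((levels, levels))
    nx, ny, nz = data.shape
    for d in offsets:
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    u, v, w = x + d[0], y + d[1], z + d[2]
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                            and mask[x, y, z] and mask[u, v, w]:
                        P[q[x, y, z], q[u, v, w]] += 1
    P = P + P.T
    P /= P.sum()
    i = np.arange(levels)
    px = P.sum(axis=1)
    mu = (i * px).sum()
    sig2 = (((i - mu) ** 2) * px).sum()
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return ((ii - mu) * (jj - mu) * P).sum() / sig2


def brute_ngtdm_busyness(data, mask, levels):
    vals = data[mask]
    mn, mx = vals.min(), vals.max()
    q = np.clip(np.floor((data - mn) / (mx - mn) * levels), 0,
                levels - 1).astype(int)
    nx, ny, nz = data.shape
    s = np.zeros(levels)
    n = np.zeros(levels)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nb = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz \
                                    and mask[u, v, w]:
                                nb.append(q[u, v, w])
                if nb:
                    s[q[x, y, z]] += abs(q[x, y, z] - np.mean(nb))
                    n[q[x, y, z]] += 1
    p = n / n.sum()
    num = (p * s).sum()
    den = 0.0
    for i in range(levels):
        for j in range(levels):
            if p[i] > 0 and p[j] > 0:
                den += abs(i * p[i] - j * p[j])
    return num / den


class TestDepthMap:
    def test_single_voxel_depth_is_one_step(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        d = depth_map(LesionMask(m, UNIT))
        assert d[2, 2, 2] == pytest.approx(1.0)

    def test_ball_max_depth_matches_inradius(self):
        shape = (25, 25, 25)
        idx = np.indices(shape)
        ball = ((idx - 12) ** 2).sum(axis=0) <= 10 ** 2
        d = depth_map(LesionMask(ball, UNIT))
        assert d.max() == pytest.approx(10.0, abs=1.5)

    def test_argmax_in_morphological_interior(self):
        rng = np.random.default_rng(0)
        m = np.zeros((12, 12, 12), bool)
        m[3:9, 2:10, 4:9] = True
        d = depth_map(LesionMask(m, UNIT))
        peak = np.unravel_index(np.argmax(d), d.shape)
        from scipy.ndimage import binary_erosion
        assert binary_erosion(m)[peak]

    def test_spacing_respected(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        d = depth_map(LesionMask(m, (2.0, 2.0, 2.0)))
        assert d[2, 2, 2] == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            depth_map(LesionMask(np.zeros((4, 4, 4), bool), UNIT))


class TestWeightedStats:
    def test_uniform_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(1)
        x = rng.normal(30, 5, 101)
        w = np.full(101, 0.37)
        ws = weighted_stats(x, w)
        assert ws["median"] == pytest.approx(np.median(x), abs=1e-12)
        assert ws["iqr"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25), abs=1e-9)
        assert ws["sd"] == pytest.approx(np.std(x), abs=1e-9)
        assert ws["skew"] == pytest.approx(sps.skew(x), abs=1e-9)
        assert ws["kurtosis"] == pytest.approx(
            sps.kurtosis(x, fisher=False), abs=1e-9)

    def test_point_mass(self):
        ws = weighted_stats([1.0, 5.0, 9.0], [0.0, 3.0, 0.0])
        assert ws["median"] == 5.0
        assert ws["iqr"] == 0.0
        assert ws["sd"] == 0.0

    def test_spec_quantile_example(self):
        assert weighted_quantile([1, 2, 3, 4], [0, 0, 1, 1], 0.5) \
            == pytest.approx(3.5)

    def test_brute_force_cumulative_weight_oracle(self):
        # enumerate cumulative-weight positions by hand for a 3-point case
        vals, w = [2.0, 4.0, 10.0], [1.0, 2.0, 1.0]
        # positions: p_i = cum_{i-1} / (W - w_i) -> 0/(4-1)=0, 1/(4-2)=0.5,
        # 3/(4-1)=1
        assert weighted_quantile(vals, w, 0.25) == pytest.approx(3.0)
        assert weighted_quantile(vals, w, 0.5) == pytest.approx(4.0)
        assert weighted_quantile(vals, w, 0.75) == pytest.approx(7.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_stats([1.0, 2.0], [0.0, 0.0])


class TestGlcm:
    def test_matches_brute_force_exactly(self, toy_volume):
        vol, mask = toy_volume
        offsets = [(1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1)]
        ours = glcm_correlation(vol, mask, levels=8, offsets=offsets)
        oracle = brute_glcm_correlation(vol.data, mask.data, 8, offsets)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_periodic_stripes_fully_correlated(self):
        stripes = np.broadcast_to(
            (np.arange(12)[:, None, None] // 2 % 2) * 30.0 + 30.0,
            (12, 12, 2)).copy()
        vol, mask = _vm(stripes)
        # offset = one full stripe period -> perfectly correlated pairs
        corr = glcm_correlation(vol, mask, levels=4, offsets=[(4, 0, 0)])
        assert corr == pytest.approx(1.0, abs=0.05)
        # half-period offset pairs opposite phases -> perfect anticorrelation
        anti = glcm_correlation(vol, mask, levels=4, offsets=[(2, 0, 0)])
        assert anti == pytest.approx(-1.0, abs=0.05)

    def test_iid_noise_uncorrelated(self):
        rng = np.random.default_rng(2)
        vol, mask = _vm(rng.integers(0, 16, (20, 20, 10)).astype(float))
        corr = glcm_correlation(vol, mask, levels=16)
        assert abs(corr) < 0.05

    def test_two_voxel_region_hand_enumeration(self):
        data = np.zeros((2, 1, 1))
        data[:, 0, 0] = [10.0, 20.0]
        vol, mask = _vm(data)
        # single offset pair (a,b): symmetric GLCM = [[0, .5], [.5, 0]];
        # mu = 0.5, sigma2 = 0.25, correlation = (0-.25 twice)/.25 = -1
        corr = glcm_correlation(vol, mask, levels=2, offsets=[(1, 0, 0)])
        assert corr == pytest.approx(-1.0, abs=1e-10)

    def test_constant_region_rejected(self):
        vol, mask = _vm(np.full((4, 4, 2), 30.0))
        with pytest.raises(ValueError):
            glcm_correlation(vol, mask, levels=8)

    def test_matrix_is_symmetric_probability(self, toy_volume):
        vol, mask = toy_volume
        P = glcm_matrix(vol, mask, levels=8)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)


class TestNgtdm:
    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 40, (8, 8, 1)).astype(float)
        vol, mask = _vm(data)
        ours = ngtdm_busyness(vol, mask, levels=8)
        oracle = brute_ngtdm_busyness(data, mask.data, 8)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_checkerboard_matches_brute_force(self):
        xx, yy = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        data = (((xx + yy) % 2) * 20.0 + 30.0)[:, :, None] * np.ones((1, 1, 1))
        vol, mask = _vm(data)
        ours = ngtdm_busyness(vol, mask, levels=4)
        oracle = brute_ngtdm_busyness(data, mask.data, 4)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_uniform_region_is_degenerate(self):
        vol, mask = _vm(np.full((6, 6, 2), 30.0))
        with pytest.raises(ValueError):
            ngtdm_busyness(vol, mask, levels=8)

    def test_salt_pepper_busier_than_gradient(self):
        rng = np.random.default_rng(4)
        grad = np.broadcast_to(np.linspace(20, 60, 16)[:, None, None],
                               (16, 16, 4)).copy()
        salt = rng.permutation(grad.ravel()).reshape(grad.shape)
        vg, mg = _vm(grad)
        vs, ms = _vm(salt)
        assert ngtdm_busyness(vs, ms, 8) > ngtdm_busyness(vg, mg, 8)


class TestLacunarity:
    def test_solid_block_has_unit_lacunarity(self):
        lam, slope = lacunarity(np.ones((12, 12, 12), bool))
        for v in lam.values():
            assert v == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_sparse_pattern_exceeds_solid(self):
        rng = np.random.default_rng(5)
        sparse = rng.random((16, 16, 16)) > 0.8
        sparse[0, 0, 0] = True
        lam, _ = lacunarity(sparse)
        assert lam[2] > 1.0


class TestFeatureBank:
    def test_lesion_equal_mirror_zeroes_difference_family(self):
        spec = PhantomSpec(uptake_rate=0.0, noise_sd=0.0, texture_amp=0.0)
        vol, mask, _ = generate_ncct_phantom(spec)
        fv = extract_features(vol, mask, mirror_mask(mask))
        for name, val in fv.values.items():
            if name.startswith("diff_") and name != "diff_volume_thresholded_minimum":
                assert val == pytest.approx(0.0, abs=1e-9), name
        # thresholded-minimum volume ~ 5% of lesion volume by the quantile
        # definition when lesion and mirror are identical
        vtm = fv["diff_volume_thresholded_minimum"]
        assert vtm == pytest.approx(0.05 * fv["shape_volume_ml"], rel=0.35)

    def test_no_uptake_intensity_equals_mirror(self):
        spec = PhantomSpec(uptake_rate=0.0, noise_sd=0.0, texture_amp=0.0)
        vol, mask, _ = generate_ncct_phantom(spec)
        mir = mirror_mask(mask)
        fv = extract_features(vol, mask, mir)
        assert fv["lesion_mean"] == pytest.approx(
            vol.data[mir.data].mean(), abs=1e-9)

    def test_schema_stable_across_cohort(self):
        cohort = simulate_cohort(3, seed=21)
        table = extract_feature_table(
            [(v, m, mirror_mask(m)) for _, v, m in cohort])
        assert len(set(map(tuple, [table.columns] * 1))) == 1
        assert not table.isna().any().any()
        for bank_name in PAPER_SELECTED.values():
            assert bank_name in table.columns


class TestSelectFeatures:
    def _table(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, n)
        X = pd.DataFrame({
            "signal": y + rng.normal(0, 0.1, n),
            "noise_a": rng.normal(0, 1, n),
            "noise_b": rng.normal(0, 1, n),
            "noise_c": rng.normal(0, 1, n),
        })
        return X, y

    def test_generating_feature_selected_first(self):
        X, y = self._table()
        sel = select_features(X, y, seed=0)
        assert sel[0] == "signal"

    def test_duplicated_column_filtered(self):
        X, y = self._table()
        X["signal_copy"] = X["signal"]
        sel = select_features(X, y, seed=0)
        assert not ("signal" in sel and "signal_copy" in sel)

    def test_huge_epsilon_returns_single_feature(self):
        X, y = self._table()
        sel = select_features(X, y, improvement_eps=1e9, seed=0)
        assert len(sel) == 1

    def test_column_order_invariance(self):
        X, y = self._table()
        sel_a = select_features(X, y, seed=3)
        sel_b = select_features(X[list(X.columns)[::-1]], y, seed=3)
        assert sel_a == sel_b

    def test_constant_target_rejected(self):
        X, _ = self._table()
        with pytest.raises(ValueError):
            select_features(X, np.zeros(len(X)), seed=0)
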