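import numpy as np
import pytest

from ischclock.io_preprocess import ImageVolume, LesionMask
from ischclock.segmentation import (UNetConfig, UNet25D, cascade_select, dice,
                                    extract_ranked_components, mask_volume_ml,
                                    predict_probability, select_component,
                                    train_unet25d)


def _prob(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def _mask(data, spacing=(1.0, 1.0, 1.0)):
    return LesionMask(np.asarray(data, dtype=bool), spacing)


def _brute_force_components(binary):
    """Flood-fill 26-connectivity labelling, independent of scipy."""
    shape = binary.shape
    seen = np.zeros(shape, bool)
    comps = []
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for start in np.argwhere(binary):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offs:
                w = tuple(np.add(v, o))
                if all(0 <= w[a] < shape[a] for a in range(3)) \
                        and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


class TestRankedComponents:
    def test_two_blobs_ordered_by_peak(self):
        p = np.zeros((12, 6, 6))
        p[1:3, 1:3, 1:3] = 0.7
        p[8:10, 1:3, 1:3] = 0.9
        comps = extract_ranked_components(_prob(p))
        assert len(comps) == 2
        assert comps[0].peak_probability == pytest.approx(0.9)
        assert comps[0].mask.data[8, 1, 1]
        assert comps[1].peak_probability == pytest.approx(0.7)
        assert [c.rank for c in comps] == [1, 2]

    def test_subthreshold_field_yields_empty_list(self):
        assert extract_ranked_components(_prob(np.full((6, 6, 6), 0.4))) == []

    def test_top3_of_five_blobs_matches_brute_force(self):
        rng = np.random.default_rng(0)
        p = np.zeros((30, 8, 8))
        peaks = [0.95, 0.85, 0.75, 0.65, 0.55]
        for i, pk in enumerate(peaks):
            p[6 * i + 1: 6 * i + 3, 2:4, 2:4] = pk - 0.02
            p[6 * i + 1, 2, 2] = pk
        comps = extract_ranked_components(_prob(p), k=3)
        assert [c.peak_probability for c in comps] == pytest.approx(peaks[:3])
        # brute-force oracle: components of the thresholded field
        bf = _brute_force_components(p > 0.5)
        bf_peaks = sorted((max(p[v] for v in comp) for comp in bf),
                          reverse=True)[:3]
        assert [c.peak_probability for c in comps] == pytest.approx(bf_peaks)
        # disjointness and containment in the thresholded field
        union = np.zeros(p.shape, int)
        for c in comps:
            union += c.mask.data
        assert union.max() == 1
        assert np.all((union > 0) <= (p > 0.5))


class TestDice:
    def test_identical_masks(self):
        m = _mask(np.random.default_rng(1).random((6, 6, 6)) > 0.5)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:2], b[4:] = True, True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 2), bool)
        b = np.zeros((10, 10, 2), bool)
        a[:5], b[2:7] = True, True   # |a|=|b|=100, overlap 60
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.6)

    def test_both_empty_defined_as_one(self):
        z = _mask(np.zeros((4, 4, 4), bool))
        assert dice(z, z) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((4, 4, 4), bool)),
                 _mask(np.zeros((5, 4, 4), bool)))


class TestMaskVolume:
    def test_unit_voxels(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:1000] = True
        assert mask_volume_ml(_mask(m)) == pytest.approx(1.0)

    def test_empty_mask(self):
        assert mask_volume_ml(_mask(np.zeros((4, 4, 4), bool))) == 0.0

    def test_anisotropic_spacing(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:500] = True
        assert mask_volume_ml(_mask(m, (0.449, 0.449, 0.449))) \
            == pytest.approx(500 * 0.449 ** 3 / 1000.0)


def _toy_pairs(n=3, shape=(16, 16, 8), seed=0):
    """Tiny bright-blob segmentation problem for fast training tests."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        data = rng.normal(30.0, 1.0, shape)
        mask = np.zeros(shape, bool)
        cx, cy, cz = rng.integers(4, 12), rng.integers(4, 12), rng.integers(2, 6)
        mask[cx - 2: cx + 2, cy - 2: cy + 2, cz - 1: cz + 1] = True
        data[mask] -= 8.0
        pairs.append((ImageVolume(data, (1, 1, 1)),
                      LesionMask(mask, (1, 1, 1))))
    return pairs


_TINY = dict(in_slices=3, in_plane=16, levels=2, base_channels=4,
             epochs=6, batch_size=4, learning_rate=3e-3, convs_per_block=1)


class TestUNetTraining:
    def test_loss_decreases(self):
        model = train_unet25d(_toy_pairs(4), UNetConfig(**_TINY, seed=0))
        assert model.history[-1] < model.history[0]
        assert np.mean(model.history[-2:]) < np.mean(model.history[:2])

    def test_same_seed_identical_loss(self):
        a = train_unet25d(_toy_pairs(3), UNetConfig(**_TINY, seed=5))
        b = train_unet25d(_toy_pairs(3), UNetConfig(**_TINY, seed=5))
        assert a.history == b.history

    def test_probability_bounded_and_finite(self):
        model = train_unet25d(_toy_pairs(3), UNetConfig(**_TINY, seed=1))
        v = _toy_pairs(1, seed=9)[0][0]
        p = predict_probability(model, v)
        assert np.all((p.data >= 0) & (p.data <= 1))
        zero = ImageVolume(np.zeros((16, 16, 8)), (1, 1, 1))
        pz = predict_probability(model, zero)
        assert np.all(np.isfinite(pz.data))

    def test_grid_mismatch_rejected(self):
        (v, m), = _toy_pairs(1)
        bad = LesionMask(np.zeros((16, 16, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            train_unet25d([(v, bad), (v, bad)], UNetConfig(**_TINY))

    def test_empty_masks_rejected(self):
        (v, _), = _toy_pairs(1)
        empty = LesionMask(np.zeros((16, 16, 8), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            train_unet25d([(v, empty), (v, empty)], UNetConfig(**_TINY))

    def test_volume_thinner_than_stack_rejected(self):
        model = train_unet25d(_toy_pairs(3), UNetConfig(**_TINY, seed=2))
        thin = ImageVolume(np.random.default_rng(0).normal(30, 1, (16, 16, 2)),
                           (1, 1, 1))
        with pytest.raises(ValueError):
            predict_probability(model, thin)

    def test_save_load_roundtrip(self, tmp_path):
        model = train_unet25d(_toy_pairs(3), UNetConfig(**_TINY, seed=3))
        path = tmp_path / "unet.npz"
        model.save(path)
        back = UNet25D.load(path)
        v = _toy_pairs(1, seed=4)[0][0]
        assert np.allclose(predict_probability(model, v).data,
                           predict_probability(back, v).data, atol=1e-6)


class TestConfigValidation:
    def test_even_stack_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(in_slices=4)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(levels=1)


class TestCascade:
    def _comp(self, mask, rank, peak):
        from ischclock.segmentation import RankedComponent
        return RankedComponent(mask, rank, peak)

    def test_prefers_subacute_then_falls_back(self):
        truth = _mask(np.zeros((8, 8, 8), bool))
        truth.data[2:5, 2:5, 2:5] = True
        hit = self._comp(truth, 1, 0.9)
        miss_data = np.zeros((8, 8, 8), bool)
        miss_data[6:8, 6:8, 6:8] = True
        miss = self._comp(_mask(miss_data), 1, 0.95)

        comp, role = cascade_select([hit], [miss], truth)
        assert role == "subacute"
        comp, role = cascade_select([miss], [hit], truth)
        assert role == "acute"
        comp, role = cascade_select([miss], [miss], truth)
        assert comp is None and role == "failed"

    def test_select_component_walks_ranks(self):
        truth = _mask(np.zeros((8, 8, 8), bool))
        truth.data[2:5, 2:5, 2:5] = True
        miss_data = np.zeros((8, 8, 8), bool)
        miss_data[6:8, 6:8, 6:8] = True
        comps = [self._comp(_mask(miss_data), 1, 0.99),
                 self._comp(truth, 2, 0.8)]
        chosen = select_component(comps, truth)
        assert chosen.rank == 2
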