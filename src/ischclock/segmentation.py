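"""2.5D U-Net lesion segmentation with probabilistic component ranking.

The network consumes a stack of adjacent axial slices (channels) and predicts
a per-pixel lesion probability for the central slice; sliding the stack over
the volume assembles a probability volume. Candidate lesions are the
connected components (26-connectivity) of the thresholded field (p > 0.5),
ranked by their peak probability; only the top three are kept, mirroring the
clinical workflow in which an expert adjudicates at most three candidates.
Two model roles (acute / subacute) are a configuration axis; the cascade
policy that prefers the subacute model and falls back to the acute one is
:func:`cascade_select`, with ground-truth overlap standing in for expert
adjudication on phantoms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .io_preprocess import ImageVolume, LesionMask, clip_and_zscore

__all__ = [
    "UNetConfig",
    "RankedComponent",
    "UNet25D",
    "train_unet25d",
    "predict_probability",
    "extract_ranked_components",
    "select_component",
    "cascade_select",
    "dice",
    "mask_volume_ml",
]


@dataclass
class UNetConfig:
    """Architecture/training knobs. Defaults are the full-scale configuration
    (15-slice 256x256 stacks, four levels, 100 epochs, batch 128, lr 1e-4,
    cross-entropy); :meth:`desk` returns the small configuration used for
    phantom experiments on one CPU."""

    in_slices: int = 15
    in_plane: int = 256
    levels: int = 4
    base_channels: int = 32
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 1e-4
    convs_per_block: int = 2
    pos_weight: float = 3.0      # cross-entropy weight on lesion pixels
    neg_slices_per_volume: int = 4
    max_lesion_slices_per_volume: int = 0   # 0 = use all lesion slices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.in_slices % 2 == 0:
            raise ValueError("in_slices must be odd")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")

    @classmethod
    def desk(cls, **kw) -> "UNetConfig":
        args = dict(in_slices=5, in_plane=64, levels=3, base_channels=8,
                    epochs=12, batch_size=16, learning_rate=1e-3,
                    convs_per_block=1, max_lesion_slices_per_volume=12)
        args.update(kw)
        return cls(**args)


@dataclass
class RankedComponent:
    mask: LesionMask
    rank: int                 # 1..3
    peak_probability: float


def _conv_block(cin, cout, rng, n_convs=2):
    layers = [nn.Conv(cin, cout, (3, 3), rng), nn.BatchNorm(cout), nn.ReLU()]
    for _ in range(n_convs - 1):
        layers += [nn.Conv(cout, cout, (3, 3), rng), nn.BatchNorm(cout), nn.ReLU()]
    return nn.Sequential(*layers)


class UNet25D:
    """Encoder-decoder with skip connections over ``levels`` resolutions."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        b, L = cfg.base_channels, cfg.levels
        ch = [b * 2 ** l for l in range(L)]
        nc = cfg.convs_per_block
        self.encs = [_conv_block(cfg.in_slices if l == 0 else ch[l - 1], ch[l],
                                 rng, nc) for l in range(L - 1)]
        self.pools = [nn.MaxPool() for _ in range(L - 1)]
        self.bott = _conv_block(ch[L - 2], ch[L - 1], rng, nc)
        self.ups = [nn.UpsampleNearest() for _ in range(L - 1)]
        self.upconvs = [nn.Conv(ch[l + 1], ch[l], (3, 3), rng) for l in range(L - 1)]
        self.decs = [_conv_block(2 * ch[l], ch[l], rng, nc) for l in range(L - 1)]
        self.out = nn.Conv(ch[0], 1, (1, 1), rng)
        self.history: list[float] = []

    def params(self):
        ps = []
        for m in (*self.encs, self.bott, *self.upconvs, *self.decs, self.out):
            ps.extend(m.params())
        return ps

    def forward(self, x, train=True):
        skips = []
        h = x
        for enc, pool in zip(self.encs, self.pools):
            h = enc.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bott.forward(h, train)
        self._skip_ch = []
        for l in reversed(range(len(self.encs))):
            h = self.ups[l].forward(h, train)
            h = self.upconvs[l].forward(h, train)
            self._skip_ch.append(h.shape[-1])
            h = np.concatenate([h, skips[l]], axis=-1)
            h = self.decs[l].forward(h, train)
        return self.out.forward(h, train)[..., 0]

    def backward(self, glogits):
        g = self.out.backward(glogits[..., None])
        gskips = {}
        L1 = len(self.encs)
        # decoder was applied for l = L1-1 .. 0, so unwind starting at l = 0
        for l in range(L1):
            g = self.decs[l].backward(g)
            c = self._skip_ch[L1 - 1 - l]
            g, gskip = g[..., :c], g[..., c:]
            gskips[l] = gskip
            g = self.upconvs[l].backward(g)
            g = self.ups[l].backward(g)
        g = self.bott.backward(g)
        for l in reversed(range(L1)):
            g = self.pools[l].backward(g)
            g = g + gskips[l]
            g = self.encs[l].backward(g)
        return g

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bns = [m for blk in (*self.encs, self.bott, *self.decs) for m in blk.layers
               if isinstance(m, nn.BatchNorm)]
        for i, bn in enumerate(bns):
            arrays[f"bn{i}_mean"] = bn.run_mean
            arrays[f"bn{i}_var"] = bn.run_var
        np.savez(path, config=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path) -> "UNet25D":
        with np.load(path, allow_pickle=False) as z:
            cfg = UNetConfig(**json.loads(str(z["config"])))
            model = cls(cfg)
            for i, p in enumerate(model.params()):
                p.value[...] = z[f"p{i}"]
            bns = [m for blk in (*model.encs, model.bott, *model.decs)
                   for m in blk.layers if isinstance(m, nn.BatchNorm)]
            for i, bn in enumerate(bns):
                bn.run_mean[...] = z[f"bn{i}_mean"]
                bn.run_var[...] = z[f"bn{i}_var"]
        return model


def _slice_stack(data: np.ndarray, z: int, n_slices: int) -> np.ndarray:
    """(X, Y, S) channels-last stack of axial slices centred at z, edge
    slices replicated."""
    half = n_slices // 2
    nz = data.shape[2]
    zs = np.clip(np.arange(z - half, z + half + 1), 0, nz - 1)
    return data[:, :, zs]


def _training_samples(pairs, cfg, rng):
    xs, ys = [], []
    for vol, mask in pairs:
        if vol.shape != mask.shape:
            raise ValueError("mask/volume grid mismatch")
        if vol.shape[0] != cfg.in_plane or vol.shape[1] != cfg.in_plane:
            raise ValueError(
                f"in-plane shape {vol.shape[:2]} != configured {cfg.in_plane}")
        z = clip_and_zscore(vol).data
        all_lesion_z = np.unique(np.nonzero(mask.data)[2])
        lesion_z = all_lesion_z
        if cfg.max_lesion_slices_per_volume and \
                lesion_z.size > cfg.max_lesion_slices_per_volume:
            lesion_z = np.sort(rng.choice(
                lesion_z, size=cfg.max_lesion_slices_per_volume, replace=False))
        empty_z = np.setdiff1d(np.arange(vol.shape[2]), all_lesion_z)
        n_neg = min(cfg.neg_slices_per_volume, empty_z.size)
        neg_z = rng.choice(empty_z, size=n_neg, replace=False) if n_neg else []
        for zz in list(lesion_z) + list(neg_z):
            xs.append(_slice_stack(z, int(zz), cfg.in_slices))
            ys.append(mask.data[:, :, int(zz)].astype(float))
    return np.asarray(xs, dtype=np.float32), np.asarray(ys, dtype=np.float32)


def train_unet25d(pairs, cfg: UNetConfig) -> UNet25D:
    """Train on (volume, mask) pairs; deterministic for a fixed config seed.

    Volumes are clipped/z-scored per volume; training slices are every slice
    intersecting the lesion plus a few background slices per volume. Adam with
    weighted sigmoid cross-entropy on the central slice. The per-epoch mean
    loss is kept in ``model.history``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 training volumes")
    if any(m.count() == 0 for _, m in pairs):
        raise ValueError("training masks must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    X, Y = _training_samples(pairs, cfg, rng)
    if not Y.any():
        raise ValueError("degenerate labels: no lesion pixels in training set")
    model = UNet25D(cfg)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, g = nn.bce_with_logits(logits, Y[idx], cfg.pos_weight)
            opt.zero_grad()
            model.backward(g)
            opt.step()
            losses.append(loss)
        model.history.append(float(np.mean(losses)))
    return model


def predict_probability(model: UNet25D, v: ImageVolume,
                        batch_size: int = 16) -> ImageVolume:
    """Per-voxel lesion probability, stack slid over every axial position."""
    cfg = model.cfg
    if v.shape[2] < 1:
        raise ValueError("empty volume")
    if v.shape[2] < cfg.in_slices:
        raise ValueError(
            f"volume has {v.shape[2]} slices < in_slices={cfg.in_slices}")
    try:
        z = clip_and_zscore(v).data
    except ValueError:  # constant input: zero-information field
        z = np.zeros_like(v.data, dtype=float)
    stacks = np.asarray([_slice_stack(z, zz, cfg.in_slices)
                         for zz in range(v.shape[2])])
    probs = []
    for s in range(0, stacks.shape[0], batch_size):
        logits = model.forward(stacks[s:s + batch_size], train=False)
        probs.append(nn.sigmoid(logits))
    prob = np.moveaxis(np.concatenate(probs, axis=0), 0, 2)
    return v.with_data(np.asarray(prob, dtype=np.float64))


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def extract_ranked_components(p: ImageVolume, k: int = 3,
                              thr: float = 0.5) -> list[RankedComponent]:
    """Top-k connected components of the thresholded probability field.

    Components are ranked by their maximum probability (descending), ties
    broken by larger voxel count. An empty list is the segmentation-failure
    outcome, not an error.
    """
    binary = p.data > thr
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return []
    comps = []
    for lab in range(1, n + 1):
        sel = labels == lab
        comps.append((float(p.data[sel].max()), int(sel.sum()), lab, sel))
    comps.sort(key=lambda c: (-c[0], -c[1], c[2]))
    out = []
    for rank, (peak, _, _, sel) in enumerate(comps[:k], start=1):
        out.append(RankedComponent(
            LesionMask(sel, p.spacing, p.origin, provenance="model"),
            rank, peak))
    return out


def dice(a: LesionMask, b: LesionMask) -> float:
    """Dice similarity 2|a&b| / (|a|+|b|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError("grid mismatch")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    return 2.0 * float((a.data & b.data).sum()) / (na + nb)


def mask_volume_ml(m: LesionMask) -> float:
    """Mask volume in mL (voxel count x voxel volume)."""
    return m.count() * float(np.prod(m.spacing)) / 1000.0


def select_component(components, truth: LesionMask,
                     min_dice: float = 0.2) -> RankedComponent | None:
    """First ranked component overlapping the reference lesion.

    Phantom stand-in for expert adjudication: a component 'identifies the
    relevant lesion' when its Dice with the reference exceeds ``min_dice``.
    """
    for comp in components:
        if dice(comp.mask, truth) > min_dice:
            return comp
    return None


def cascade_select(subacute_components, acute_components, truth: LesionMask,
                   min_dice: float = 0.2):
    """Prefer the subacute model's components, falling back to the acute
    model's when none identifies the lesion. Returns (component | None, role)."""
    comp = select_component(subacute_components, truth, min_dice)
    if comp is not None:
        return comp, "subacute"
    comp = select_component(acute_components, truth, min_dice)
    return comp, ("acute" if comp is not None else "failed")
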