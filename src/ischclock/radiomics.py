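"""Radiomic feature bank for lesion vs mirrored contralateral tissue.

Features come in two families:

* ``lesion_*`` — statistics of the lesion region itself;
* ``diff_*``  — normalized difference against the mirrored contralateral
  region, ``(f_lesion - f_mirror) / f_mirror`` for scale-carrying features
  and the raw difference for dimensionless ones (skew, kurtosis, texture),
  so near-zero denominators never blow up.

Intensity statistics exist plain and depth-weighted (``dw_``), where the
weight of a voxel is its Euclidean depth inside the lesion divided by the
maximum depth — deep-lesion voxels dominate, which suppresses partial-volume
contamination at the rim. Texture features are 3D masked implementations of
the gray-level co-occurrence matrix (GLCM, Haralick statistics) and the
neighbourhood gray-tone difference matrix (NGTDM, Amadasun-King statistics);
shape features include a gliding-box lacunarity summary.

The ten features known to carry lesion-age signal (see
:data:`PAPER_SELECTED`) are always present; the rest of the bank is
configurable. Feature selection is variance filter -> Spearman
cross-correlation filter -> stepwise forward selection by out-of-bag
Gaussian-process R^2 over bootstrap resamples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .io_preprocess import HU_WINDOW, ImageVolume, LesionMask, hu_window_restrict

__all__ = [
    "FeatureVector",
    "PAPER_SELECTED",
    "depth_map",
    "weighted_quantile",
    "weighted_stats",
    "glcm_matrix",
    "glcm_correlation",
    "glcm_features",
    "ngtdm",
    "ngtdm_busyness",
    "ngtdm_features",
    "lacunarity",
    "extract_features",
    "extract_feature_table",
    "select_features",
]

#: canonical age-informative features -> bank column names
PAPER_SELECTED = {
    "intensity": "lesion_mean",
    "skew": "lesion_skew",
    "depth_weighted_median": "lesion_dw_median",
    "depth_weighted_iqr": "lesion_dw_iqr",
    "depth_weighted_skew": "lesion_dw_skew",
    "glcm_correlation": "lesion_glcm32_correlation",
    "volume_of_thresholded_minimum": "diff_volume_thresholded_minimum",
    "depth_weighted_sd": "diff_dw_sd",
    "depth_weighted_kurtosis": "diff_dw_kurtosis",
    "ngtdm_busyness": "diff_ngtdm32_busyness",
}

_PCTS = np.arange(5, 100, 5)  # 5..95


@dataclass
class FeatureVector:
    values: dict[str, float]

    def __getitem__(self, k: str) -> float:
        return self.values[k]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)


# ---------------------------------------------------------------------------
# depth map and weighted statistics
# ---------------------------------------------------------------------------

def depth_map(m: LesionMask) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the nearest outside-mask voxel.

    A single-voxel mask has depth = min(spacing): one step to the boundary.
    """
    if m.count() == 0:
        raise ValueError("empty mask")
    return ndimage.distance_transform_edt(m.data, sampling=m.spacing)


def weighted_quantile(values, weights, q):
    """Weighted quantiles by cumulative-weight interpolation.

    Zero-weight points are dropped. Position of the i-th sorted point is
    ``p_i = cum_{i-1} / (W - w_i)``; this reduces exactly to numpy's linear
    interpolation under uniform weights and is monotone in i (for any i,
    ``W * w_i >= cum_i * w_i`` gives ``p_{i+1} >= p_i``).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    keep = weights > 0
    if not keep.any():
        raise ValueError("all-zero weights")
    v, w = values[keep], weights[keep]
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    W = cum[-1]
    denom = W - w
    pos = np.where(denom > 0, (cum - w) / np.where(denom > 0, denom, 1.0), 0.5)
    return np.interp(np.asarray(q, dtype=float), pos, v)


def weighted_stats(values, weights) -> dict[str, float]:
    """Weighted median/IQR (quantile interpolation) and weighted central
    moments (population sd; skew m3/sd^3; non-excess kurtosis m4/sd^4)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or not np.any(weights > 0):
        raise ValueError("weights must be non-negative and not all zero")
    q25, q50, q75 = weighted_quantile(values, weights, [0.25, 0.5, 0.75])
    wsum = weights.sum()
    mean = float((weights * values).sum() / wsum)
    d = values - mean
    m2 = float((weights * d ** 2).sum() / wsum)
    sd = np.sqrt(m2)
    if sd > 0:
        m3 = float((weights * d ** 3).sum() / wsum)
        m4 = float((weights * d ** 4).sum() / wsum)
        skew, kurt = m3 / sd ** 3, m4 / sd ** 4
    else:
        skew, kurt = 0.0, 0.0
    return dict(median=float(q50), iqr=float(q75 - q25), skew=skew,
                sd=float(sd), kurtosis=kurt, mean=mean)


# ---------------------------------------------------------------------------
# texture: GLCM
# ---------------------------------------------------------------------------

def _quantize(v: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    vals = v[mask]
    mn, mx = vals.min(), vals.max()
    if mx <= mn:
        raise ValueError("constant region: cannot quantize")
    q = np.floor((v - mn) / (mx - mn) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


#: 13 unique 3D directions at Chebyshev distance 1
OFFSETS_3D = [d for d in itertools.product((-1, 0, 1), repeat=3)
              if d > (0, 0, 0)]


def glcm_matrix(v, m, levels: int = 32, offsets=None) -> np.ndarray:
    """Symmetric, normalized gray-level co-occurrence matrix within a mask,
    accumulated over the given voxel offsets (default: 13 unique 3D
    directions at distance one)."""
    data, mask = np.asarray(v.data), m.data
    offsets = offsets or OFFSETS_3D
    q = _quantize(data, mask, levels)
    P = np.zeros((levels, levels), dtype=float)
    for d in offsets:
        sl_a = tuple(slice(max(0, -o), n - max(0, o))
                     for o, n in zip(d, mask.shape))
        sl_b = tuple(slice(max(0, o), n - max(0, -o))
                     for o, n in zip(d, mask.shape))
        pair = mask[sl_a] & mask[sl_b]
        if not pair.any():
            continue
        idx = q[sl_a][pair] * levels + q[sl_b][pair]
        P += np.bincount(idx, minlength=levels * levels
                         ).reshape(levels, levels)
    P = P + P.T
    total = P.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs inside mask")
    return P / total


def glcm_features(v, m, levels: int = 32, offsets=None) -> dict[str, float]:
    """Haralick statistics of the masked GLCM."""
    P = glcm_matrix(v, m, levels, offsets)
    i = np.arange(levels, dtype=float)
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    feats = dict(
        contrast=float((P * (ii - jj) ** 2).sum()),
        dissimilarity=float((P * diff).sum()),
        energy=float((P ** 2).sum()),
        homogeneity=float((P / (1.0 + (ii - jj) ** 2)).sum()),
        entropy=float(-(P[P > 0] * np.log2(P[P > 0])).sum()),
    )
    if sigma2 <= 0:
        raise ValueError("constant region: GLCM correlation undefined")
    feats["correlation"] = float(
        ((ii - mu) * (jj - mu) * P).sum() / sigma2)
    return feats


def glcm_correlation(v, m, levels: int = 32, offsets=None) -> float:
    """Haralick GLCM correlation, sum_ij (i-mu)(j-mu) p(i,j) / sigma^2."""
    return glcm_features(v, m, levels, offsets)["correlation"]


# ---------------------------------------------------------------------------
# texture: NGTDM
# ---------------------------------------------------------------------------

_KERNEL26 = np.ones((3, 3, 3))
_KERNEL26[1, 1, 1] = 0.0


def ngtdm(v, m, levels: int = 32):
    """Neighbourhood gray-tone difference matrix within a mask.

    Returns (s, p, valid_count): per-level summed absolute difference from
    the 26-neighbour mean (neighbourhood clipped to the mask), and the level
    occupancy probabilities.
    """
    data, mask = np.asarray(v.data, dtype=float), m.data
    q = _quantize(data, mask, levels)
    gray = (q + 1.0) * mask  # +1 so level 0 is distinguishable from outside
    nb_sum = ndimage.convolve(gray, _KERNEL26, mode="constant")
    nb_cnt = ndimage.convolve(mask.astype(float), _KERNEL26, mode="constant")
    valid = mask & (nb_cnt > 0)
    a_bar = np.zeros_like(gray)
    a_bar[valid] = nb_sum[valid] / nb_cnt[valid] - 1.0
    diff = np.abs(q - a_bar)
    s = np.bincount(q[valid], weights=diff[valid], minlength=levels)
    n = np.bincount(q[valid], minlength=levels).astype(float)
    if (n > 0).sum() < 2:
        raise ValueError("fewer than 2 occupied gray levels")
    p = n / n.sum()
    return s, p, int(valid.sum())


def ngtdm_features(v, m, levels: int = 32) -> dict[str, float]:
    """Amadasun-King coarseness/contrast/busyness/complexity/strength."""
    s, p, nvox = ngtdm(v, m, levels)
    occ = p > 0
    i = np.arange(levels, dtype=float)
    ps = float((p * s).sum())
    io, po, so = i[occ], p[occ], s[occ]
    ng = occ.sum()
    ii, jj = np.meshgrid(io, io, indexing="ij")
    pi, pj = np.meshgrid(po, po, indexing="ij")
    si, sj = np.meshgrid(so, so, indexing="ij")
    denom_busy = float(np.abs(ii * pi - jj * pj).sum())
    if denom_busy == 0:
        raise ValueError("degenerate NGTDM: zero busyness denominator")
    contrast = (float((pi * pj * (ii - jj) ** 2).sum()) / (ng * (ng - 1))
                * s.sum() / nvox)
    complexity = float((np.abs(ii - jj) * (pi * si + pj * sj)
                        / (pi + pj)).sum()) / nvox
    strength = (float(((pi + pj) * (ii - jj) ** 2).sum()) / ps
                if ps > 0 else 0.0)
    return dict(
        coarseness=1.0 / ps if ps > 0 else np.inf,
        contrast=contrast,
        busyness=ps / denom_busy,
        complexity=complexity,
        strength=strength,
    )


def ngtdm_busyness(v, m, levels: int = 32) -> float:
    return ngtdm_features(v, m, levels)["busyness"]


# ---------------------------------------------------------------------------
# shape: lacunarity
# ---------------------------------------------------------------------------

def lacunarity(mask: np.ndarray, box_sizes=(2, 4, 8)):
    """Gliding-box lacunarity of a binary pattern over its bounding box.

    Lambda(r) = E[M_r^2] / E[M_r]^2 over all boxes of side r; returns
    ({r: Lambda}, slope of log Lambda vs log r).
    """
    mask = np.asarray(mask).astype(float)
    bbox = ndimage.find_objects(mask.astype(np.uint8), max_label=1)[0]
    sub = mask[bbox]
    lam = {}
    for r in box_sizes:
        if any(s < r for s in sub.shape):
            continue
        win = np.lib.stride_tricks.sliding_window_view(sub, (r, r, r))
        masses = win.sum(axis=(-3, -2, -1)).ravel()
        mean = masses.mean()
        lam[r] = float((masses ** 2).mean() / mean ** 2) if mean > 0 else np.nan
    rs = sorted(lam)
    if len(rs) >= 2:
        slope = float(np.polyfit(np.log([r for r in rs]),
                                 np.log([lam[r] for r in rs]), 1)[0])
    else:
        slope = 0.0
    return lam, slope


# ---------------------------------------------------------------------------
# the feature bank
# ---------------------------------------------------------------------------

def _crop_to(mask: np.ndarray, *arrays, pad: int = 1):
    obj = ndimage.find_objects(mask.astype(np.uint8), max_label=1)[0]
    sl = tuple(slice(max(0, s.start - pad), min(n, s.stop + pad))
               for s, n in zip(obj, mask.shape))
    return [a[sl] for a in arrays]


def _intensity_stats(vals: np.ndarray, weights: np.ndarray, prefix: str
                     ) -> dict[str, float]:
    out = {}
    ws = weighted_stats(vals, weights)
    out[f"{prefix}mean"] = ws["mean"]
    out[f"{prefix}median"] = ws["median"]
    out[f"{prefix}sd"] = ws["sd"]
    out[f"{prefix}iqr"] = ws["iqr"]
    out[f"{prefix}skew"] = ws["skew"]
    out[f"{prefix}kurtosis"] = ws["kurtosis"]
    qs = weighted_quantile(vals, weights, _PCTS / 100.0)
    for p, q in zip(_PCTS, qs):
        out[f"{prefix}p{p:02d}"] = float(q)
    out[f"{prefix}min"] = float(vals.min())
    out[f"{prefix}max"] = float(vals.max())
    out[f"{prefix}range"] = out[f"{prefix}max"] - out[f"{prefix}min"]
    out[f"{prefix}energy"] = float((weights * vals ** 2).sum() / weights.sum())
    med = ws["median"]
    out[f"{prefix}mad"] = float(weighted_quantile(
        np.abs(vals - med), weights, 0.5))
    out[f"{prefix}cv"] = ws["sd"] / ws["mean"] if ws["mean"] != 0 else 0.0
    return out


#: dimensionless features take raw lesion-mirror differences; everything
#: else uses the normalized difference (lesion - mirror) / mirror
_DIMENSIONLESS = ("skew", "kurtosis", "cv", "correlation", "entropy",
                  "energy_t", "homogeneity", "busyness", "coarseness",
                  "complexity", "strength", "contrast", "dissimilarity")


def _region_features(v, m, glcm_levels=(16, 32)) -> dict[str, float]:
    data = v.data
    vals = data[m.data]
    depth = depth_map(m)
    w_depth = depth[m.data]
    w_depth = w_depth / w_depth.max()
    out = {}
    out.update(_intensity_stats(vals, np.ones_like(vals), ""))
    out.update(_intensity_stats(vals, w_depth, "dw_"))
    for lev in glcm_levels:
        try:
            gf = glcm_features(v, m, levels=lev)
        except ValueError:
            gf = {k: 0.0 for k in ("contrast", "dissimilarity", "energy",
                                   "homogeneity", "entropy", "correlation")}
        for k, val in gf.items():
            key = "energy_t" if k == "energy" else k
            out[f"glcm{lev}_{key}"] = val
        try:
            nf = ngtdm_features(v, m, levels=lev)
        except ValueError:
            nf = {k: 0.0 for k in ("coarseness", "contrast", "busyness",
                                   "complexity", "strength")}
        for k, val in nf.items():
            out[f"ngtdm{lev}_{k}"] = val
    return out


def extract_features(
    v_raw: ImageVolume,
    lesion: LesionMask,
    mirror: LesionMask,
    window: tuple[float, float] = HU_WINDOW,
    glcm_levels=(16, 32),
) -> FeatureVector:
    """Full feature vector for one lesion on the raw-HU volume.

    Masks are HU-windowed first (bone/CSF/chronic-infarct exclusion); depth
    weights come from the unwindowed lesion shape, sampled at windowed
    voxels. Raises ``EmptyWindowError`` when a windowed mask is empty.
    """
    lesion_w = hu_window_restrict(v_raw, lesion, *window)
    mirror_w = hu_window_restrict(v_raw, mirror, *window)

    out: dict[str, float] = {}
    les = _region_features(v_raw, lesion_w, glcm_levels)
    mir = _region_features(v_raw, mirror_w, glcm_levels)
    for k, lv in les.items():
        out[f"lesion_{k}"] = lv
        mv = mir[k]
        if any(tok in k for tok in _DIMENSIONLESS):
            out[f"diff_{k}"] = lv - mv
        else:
            out[f"diff_{k}"] = (lv - mv) / mv if abs(mv) > 1e-9 else lv - mv

    # shape features (lesion only)
    vox_ml = float(np.prod(lesion.spacing)) / 1000.0
    n_les = lesion_w.count()
    out["shape_volume_ml"] = n_les * vox_ml
    eroded = ndimage.binary_erosion(lesion.data)
    surf = int(lesion.data.sum() - eroded.sum())
    out["shape_surface_to_volume"] = surf / max(lesion.count(), 1)
    out["shape_max_depth_mm"] = float(depth_map(lesion).max())
    lam, slope = lacunarity(lesion.data)
    out["shape_lacunarity_slope"] = slope
    for r, val in lam.items():
        out[f"shape_lacunarity_r{r}"] = val

    # volume of thresholded minimum: lesion volume below the mirror's 5th
    # percentile (stand-in definition, flagged in the methods note)
    thr = float(np.percentile(v_raw.data[mirror_w.data], 5))
    out["diff_volume_thresholded_minimum"] = float(
        (v_raw.data[lesion_w.data] < thr).sum()) * vox_ml

    for canonical, bank in PAPER_SELECTED.items():
        if bank not in out:
            raise RuntimeError(f"bank is missing selected feature {bank}")
    return FeatureVector(out)


def extract_feature_table(items, window=HU_WINDOW, glcm_levels=(16, 32)
                          ) -> pd.DataFrame:
    """Feature table for a cohort of (volume, lesion, mirror) triples."""
    rows = [extract_features(v, l, m, window, glcm_levels).values
            for v, l, m in items]
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        raise ValueError("non-finite features in cohort table")
    return df


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _fast_gpr(seed: int = 0) -> GaussianProcessRegressor:
    # fixed hyperparameters: forward selection refits thousands of GPRs,
    # marginal-likelihood optimization happens once in the final model
    kernel = ConstantKernel(1.0, "fixed") * RBF(1.0, "fixed") \
        + WhiteKernel(0.1, "fixed")
    return GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                    random_state=seed)


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    var_threshold: float = 1e-10,
    corr_threshold: float = 0.90,
    n_bootstrap: int = 8,
    improvement_eps: float = 0.01,
    max_features: int = 8,
    seed: int = 0,
) -> list[str]:
    """Training-phase feature reduction; returns selected names in order.

    1. drop near-constant features (variance below ``var_threshold`` of a
       standardized column, i.e. exact constants and numerical duplicates);
    2. greedy Spearman cross-correlation filter at ``corr_threshold``,
       scanning name-sorted columns so the result is column-order invariant;
    3. stepwise forward selection maximizing mean out-of-bag GPR R^2 over
       ``n_bootstrap`` resamples; stops when the best candidate improves the
       running score by less than ``improvement_eps``.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 30:
        raise ValueError("need at least 30 subjects for selection")
    if X.isna().any().any():
        raise ValueError("missing values in feature table")
    if np.std(y) == 0:
        raise ValueError("constant target")

    variances = X.var(axis=0)
    names = [n for n in sorted(X.columns) if variances[n] > var_threshold]

    # Spearman cross-correlation filter, scanning features in decreasing
    # order of univariate |rho| with the target (ties by name) so each
    # correlated cluster keeps its most predictive member
    ranks = X[names].rank(axis=0)
    y_rank = pd.Series(y).rank().to_numpy()
    y_rank = (y_rank - y_rank.mean()) / y_rank.std()
    Z = ranks.to_numpy()
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1)
    rho_y = np.abs(Z.T @ y_rank) / len(y)
    order = sorted(range(len(names)), key=lambda i: (-rho_y[i], names[i]))
    corr = np.corrcoef(Z.T)
    kept: list[int] = []
    for i in order:
        if all(abs(corr[i, j]) < corr_threshold for j in kept):
            kept.append(i)
    names = [names[i] for i in sorted(kept)]

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boots = [rng.integers(0, n, size=n) for _ in range(n_bootstrap)]
    oobs = [np.setdiff1d(np.arange(n), b) for b in boots]

    def oob_score(cols: list[str]) -> float:
        Z = X[cols].to_numpy(dtype=float)
        Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1)
        scores = []
        for b, o in zip(boots, oobs):
            if o.size < 3:
                continue
            gpr = _fast_gpr()
            gpr.fit(Z[b], y[b])
            pred = gpr.predict(Z[o])
            sst = ((y[o] - y[o].mean()) ** 2).sum()
            scores.append(1.0 - ((y[o] - pred) ** 2).sum() / sst)
        return float(np.mean(scores))

    selected: list[str] = []
    best_score = -np.inf
    while len(selected) < max_features:
        cands = [c for c in names if c not in selected]
        if not cands:
            break
        scores = {c: oob_score(selected + [c]) for c in cands}
        best = max(scores.values())
        choice = min(c for c, s in scores.items() if s == best)  # ties: by name
        if selected and best - best_score < improvement_eps:
            break
        best_score = best
        selected.append(choice)
    return selected
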