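"""Synthetic NCCT / CT-perfusion phantoms with known ground truth.

Every downstream stage (relative intensity, radiomics, CNN age regression,
U-Net segmentation, perfusion deconvolution, growth regression) is validated
against these generators, because the clinical cohorts the method was built
for are not publicly deposited.

The NCCT phantom is a quasi-symmetric two-tissue brain field (gray ~38 HU,
white ~30 HU, smooth spatial drift) inside an ellipsoidal "brain" support,
with a spherical ischemic lesion in one hemisphere. Lesion hypoattenuation
follows a saturating aging law: each lesion voxel's HU is lowered by

    delta = base_HU * uptake_rate * A(true_age),   A = aging_response,

clamped at CSF attenuation, mimicking the progressive water uptake of
ischemic tissue (approximately log-linear early, plateauing beyond a day).
Lesion texture (smoothed noise) grows with the same response, so texture
features carry age information partly independent of mean intensity, and an
age-dependent radial profile concentrates the deficit of young lesions at
the core. The aging law is a configurable stand-in: no quantitative
HU-vs-time curve is asserted, only the monotone saturating form the
net-water-uptake literature supports.

The CTP phantom synthesises tissue curves from the indicator-dilution
forward model  C_t(t) = k * CBF * (AIF (*) R)(t - delay),  R(t) = exp(-t/MTT),
with a gamma-variate arterial input function and unit constants k chosen so
that CBV_true = CBF * MTT / 60 (mL/100g) is recovered from curve areas.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import ImageVolume, LesionMask, save_mask, save_volume

__all__ = [
    "PhantomSpec",
    "CtpPhantomSpec",
    "CohortRecord",
    "aging_response",
    "generate_ncct_phantom",
    "generate_cohort",
    "simulate_cohort",
    "generate_ctp_series",
    "default_ctp_spec",
    "generate_growth_cohort",
    "simulate_thick_slices",
    "gamma_variate",
    "GROWTH_COEFFICIENTS",
]

#: blood density (g/mL) and haematocrit correction used in the CTP forward
#: model; the deconvolution pipeline applies the same constants, so absolute
#: CBF/CBV round-trip exactly on phantoms.
CTP_DENSITY = 1.04
CTP_HEMATOCRIT = 0.73


# ---------------------------------------------------------------------------
# NCCT phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic NCCT brain with a programmed lesion age."""

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm
    gm_hu: float = 38.0
    wm_hu: float = 30.0
    drift_amp: float = 1.5          # HU, smooth symmetric spatial drift
    csf_hu: float = 8.0             # clamp floor for hypoattenuation
    lesion_center: tuple[float, float, float] = (16.0, 32.0, 16.0)  # mm
    lesion_radius: float = 8.0      # mm
    true_age: float = 10.0          # hours since onset
    uptake_rate: float = 0.045      # fractional HU decrease per log-hour
    texture_amp: float = 2.5        # HU at 24 h equivalent
    texture_scale: float = 1.5      # smoothing sigma of lesion texture, voxels
    profile_gamma: float = 0.0      # 0 = uniform deficit; >0 concentrates the
                                    # deficit at the lesion core (young lesions)
    noise_sd: float = 1.0           # HU, global acquisition noise
    wm_lesion_load: float = 0.0     # 0-1, chronic white-matter confound
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_age <= 0:
            raise ValueError("true_age must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        extent = [n * s for n, s in zip(self.grid_shape, self.spacing)]
        c, r = self.lesion_center, self.lesion_radius
        for ax in range(3):
            if c[ax] - r < 0 or c[ax] + r > extent[ax]:
                raise ValueError("lesion extends outside the grid")
        mid_mm = (self.grid_shape[0] - 1) / 2.0 * self.spacing[0]
        if not (c[0] + r < mid_mm or c[0] - r > mid_mm):
            raise ValueError("lesion must lie entirely in one hemisphere")


def aging_response(t_hours) -> np.ndarray:
    """Saturating log-time response of ischemic water uptake.

    A(t) = 5.2 * x / (x + 2) with x = log(1 + t): monotone, ~log-linear
    early, plateauing beyond ~1-2 days (tissue water capacity is bounded).
    Calibrated so A(24 h) equals log(1 + 24), i.e. a 4.5%-per-log-hour
    uptake rate still yields a relative intensity of ~0.145 at 24 h.
    """
    x = np.log1p(t_hours)
    return 5.2 * x / (x + 2.0)


def _symmetric_smooth_field(shape, sigma, rng) -> np.ndarray:
    """Unit-variance smooth random field, exactly mirror-symmetric on axis 0."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f = 0.5 * (f + f[::-1])
    sd = f.std()
    return f / sd if sd > 0 else f


def _brain_support(shape) -> np.ndarray:
    semi = [0.48 * n for n in shape]
    idx = np.indices(shape).astype(float)
    dist = sum(((idx[a] - (shape[a] - 1) / 2.0) / semi[a]) ** 2 for a in range(3))
    return dist <= 1.0


def _sphere_mask(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    idx = np.indices(shape).astype(float)
    dist2 = sum(((idx[a] * spacing[a] - center_mm[a])) ** 2 for a in range(3))
    return dist2 <= radius_mm ** 2


def generate_ncct_phantom(spec: PhantomSpec):
    """Build one synthetic NCCT volume, its lesion mask, and the true age.

    Deterministic given ``spec.seed``. With ``uptake_rate=0, noise_sd=0`` the
    lesion region is identical to its contralateral mirror (relative
    intensity 0 downstream).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    brain = _brain_support(shape)

    # two-tissue background, exactly symmetric before noise
    wm_field = _symmetric_smooth_field(shape, sigma=6.0, rng=rng)
    wm = wm_field > np.median(wm_field[brain])
    base = np.where(wm, spec.wm_hu, spec.gm_hu).astype(np.float64)
    base += spec.drift_amp * _symmetric_smooth_field(shape, sigma=10.0, rng=rng)

    # chronic white-matter hypodensities (independent per hemisphere -> breaks
    # symmetry, confounding relative intensity, as leukoaraiosis does)
    if spec.wm_lesion_load > 0:
        n_blobs = int(round(6 * spec.wm_lesion_load))
        extent = [n * s for n, s in zip(shape, spec.spacing)]
        for _ in range(n_blobs):
            c = [rng.uniform(0.2 * e, 0.8 * e) for e in extent]
            r = rng.uniform(2.0, 4.0)
            blob = _sphere_mask(shape, spec.spacing, c, r) & wm & brain
            base[blob] -= 5.0 * spec.wm_lesion_load

    lesion = _sphere_mask(shape, spec.spacing, spec.lesion_center, spec.lesion_radius)
    lesion &= brain
    if not lesion.any():
        raise ValueError("lesion mask empty inside brain support")

    # saturating aging law with CSF clamp; an optional radial profile
    # concentrates the deficit at the lesion core (normalized to leave the
    # lesion-mean deficit unchanged)
    vol = base.copy()
    delta = base[lesion] * spec.uptake_rate * aging_response(spec.true_age)
    if spec.profile_gamma > 0:
        g = min(spec.profile_gamma, 0.95)
        depth = ndimage.distance_transform_edt(lesion, sampling=spec.spacing)
        dn = depth[lesion] / depth[lesion].max()
        w = (1.0 - g) + 2.0 * g * dn
        delta = delta * (w / w.mean())
    lowered = base[lesion] - delta
    if np.any(lowered < spec.csf_hu):
        warnings.warn("aging law clamped at CSF attenuation", RuntimeWarning)
        lowered = np.maximum(lowered, spec.csf_hu)
    vol[lesion] = lowered

    # age-modulated lesion texture (smoothed noise, unit sd inside lesion)
    if spec.texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), spec.texture_scale)
        t_sd = tex[lesion].std()
        if t_sd > 0:
            amp = spec.texture_amp * aging_response(spec.true_age) / aging_response(24.0)
            vol[lesion] += amp * (tex[lesion] - tex[lesion].mean()) / t_sd
            vol[lesion] = np.maximum(vol[lesion], spec.csf_hu)

    if spec.noise_sd > 0:
        vol[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))

    vol[~brain] = 0.0
    image = ImageVolume(vol, spec.spacing)
    mask = LesionMask(lesion, spec.spacing, provenance="phantom")
    return image, mask, float(spec.true_age)


def simulate_thick_slices(v: ImageVolume, m: LesionMask | None, factor: int):
    """Emulate thick-slice acquisition by axial block-averaging.

    The volume is averaged over ``factor`` consecutive z-slices (majority vote
    for the mask); z-spacing is multiplied accordingly.
    """
    if factor < 1 or v.shape[2] % factor:
        raise ValueError("factor must divide the z extent")
    nz = v.shape[2] // factor
    data = v.data.reshape(v.shape[0], v.shape[1], nz, factor).mean(axis=3)
    spacing = (v.spacing[0], v.spacing[1], v.spacing[2] * factor)
    vol = ImageVolume(data, spacing, v.origin, slice_thickness="thick")
    if m is None:
        return vol, None
    md = m.data.reshape(m.shape[0], m.shape[1], nz, factor).mean(axis=3) >= 0.5
    return vol, LesionMask(md, spacing, m.origin, m.provenance)


# ---------------------------------------------------------------------------
# NCCT cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortRecord:
    subject_id: str
    ots: float                    # hours, onset to scan
    nihss: int
    age: float                    # years
    sex: str                      # "F" | "M"
    thrombolysis: bool
    vol_path: str = ""
    mask_path: str = ""

    def __post_init__(self) -> None:
        if self.ots <= 0:
            raise ValueError("ots must be positive")


def _sample_ots(rng, n, sampler: str, lo=1.0, hi=48.0, peaks=(3.0, 25.0), sigma=0.4):
    """Onset-to-scan sampler: log-uniform, or a bimodal lognormal mixture
    (peaks near ~3 and ~25 h, the shape seen in consecutive stroke series)."""
    if sampler == "loguniform":
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if sampler == "bimodal":
        comp = rng.integers(0, 2, size=n)
        mu = np.log(np.asarray(peaks))[comp]
        return np.clip(np.exp(rng.normal(mu, sigma)), lo, hi)
    raise ValueError(f"unknown OTS sampler {sampler!r}")


def _subject_spec(template: PhantomSpec, rng, subject_seed: int, ots: float) -> PhantomSpec:
    """Per-subject phantom: random lesion geometry plus lognormal biological
    variability — sd 0.35 on the uptake rate (collateral-supply variability
    makes relative intensity a weak clock; this sd puts the RI comparator's
    explanatory power at the R^2 ~ 0.3 scale reported for clinical NWU
    clocks) and sd 0.12 on texture amplitude. The radial deficit profile
    flattens with age (core-concentrated when young, uniform when old)."""
    shape, sp = template.grid_shape, template.spacing
    extent = [n * s for n, s in zip(shape, sp)]
    mid = (shape[0] - 1) / 2.0 * sp[0]
    radius = rng.uniform(6.0, 11.0)
    side = rng.integers(0, 2)
    pad = radius + 2.0
    if side == 0:
        cx = rng.uniform(pad, mid - pad)
    else:
        cx = rng.uniform(mid + pad, extent[0] - pad)
    cy = rng.uniform(pad, extent[1] - pad)
    cz = rng.uniform(pad, extent[2] - pad)
    gamma = np.clip(0.9 - 0.25 * np.log1p(ots), 0.0, 0.9) \
        * np.exp(rng.normal(0.0, 0.15))
    return dataclasses.replace(
        template,
        lesion_center=(cx, cy, cz),
        lesion_radius=radius,
        true_age=ots,
        uptake_rate=template.uptake_rate * np.exp(rng.normal(0.0, 0.35)),
        texture_amp=template.texture_amp * np.exp(rng.normal(0.0, 0.12)),
        profile_gamma=float(gamma),
        seed=subject_seed,
    )


def simulate_cohort(
    n: int,
    spec_template: PhantomSpec | None = None,
    ots_sampler: str = "loguniform",
    seed: int = 0,
    ots_range: tuple[float, float] = (1.0, 48.0),
):
    """In-memory cohort: list of (CohortRecord, ImageVolume, LesionMask).

    Per-subject seeds are ``seed + index`` so any subset reproduces exactly.
    ``ots_range`` bounds the onset-to-scan sampler; segmentation experiments
    use the subacute range (6-48 h) where lesions are conspicuous, matching
    the acute/subacute split of the two-model design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    template = spec_template or PhantomSpec()
    out = []
    for i in range(n):
        # everything about subject i flows from seed + i, so any prefix of
        # the cohort reproduces exactly
        rng = np.random.default_rng(seed + i)
        ots = float(_sample_ots(rng, 1, ots_sampler,
                                lo=ots_range[0], hi=ots_range[1])[0])
        spec = _subject_spec(template, rng,
                             subject_seed=500_000 + seed + i, ots=ots)
        vol, mask, _ = generate_ncct_phantom(spec)
        nihss = int(np.clip(round(spec.lesion_radius * 1.5 + rng.normal(0, 3)), 0, 42))
        rec = CohortRecord(
            subject_id=f"sub-{i:04d}",
            ots=ots,
            nihss=nihss,
            age=float(np.clip(rng.normal(70.0, 12.0), 25.0, 95.0)),
            sex="F" if rng.random() < 0.5 else "M",
            thrombolysis=bool(rng.random() < 0.3),
        )
        out.append((rec, vol, mask))
    return out


def generate_cohort(
    n: int,
    out_dir,
    spec_template: PhantomSpec | None = None,
    ots_sampler: str = "loguniform",
    seed: int = 0,
) -> pd.DataFrame:
    """Write NIfTI volumes/masks plus a CSV manifest; return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, vol, mask in simulate_cohort(n, spec_template, ots_sampler, seed):
        vp = out_dir / f"{rec.subject_id}_ncct.nii.gz"
        mp = out_dir / f"{rec.subject_id}_mask.nii.gz"
        save_volume(vol, vp)
        save_mask(mask, mp)
        rows.append(
            dict(
                subject_id=rec.subject_id,
                ots_h=rec.ots,
                nihss=rec.nihss,
                age=rec.age,
                sex=rec.sex,
                lysis=int(rec.thrombolysis),
                vol_path=str(vp),
                mask_path=str(mp),
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# CTP phantom
# ---------------------------------------------------------------------------

@dataclass
class CtpPhantomSpec:
    """Ground-truth perfusion fields plus acquisition parameters."""

    true_cbf: np.ndarray = None     # mL/100g/min
    true_mtt: np.ndarray = None     # s
    true_delay: np.ndarray = None   # s
    brain_mask: np.ndarray = None
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    aif_params: tuple[float, float, float, float] = (8.0, 3.0, 1.5, 200.0)  # t0, alpha, beta, amplitude
    duration: float = 60.0          # s
    native_dt: float = 1.0          # s
    baseline_hu: float = 35.0       # unenhanced brain attenuation
    shell_hu: float = 800.0         # skull shell around the brain support
    noise_sd: float = 0.0           # HU
    aif_voxel: tuple[int, int, int] = (0, 0, 0)
    vof_voxel: tuple[int, int, int] = (1, 0, 0)
    aif_partial_volume: float = 1.0  # measured AIF amplitude fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 40:
            raise ValueError("duration must be >= 40 s")
        if self.true_cbf is not None:
            self.true_cbf = np.asarray(self.true_cbf, dtype=float)
            if np.any(self.true_cbf < 0):
                raise ValueError("true_cbf must be >= 0")
        if self.true_mtt is not None:
            self.true_mtt = np.asarray(self.true_mtt, dtype=float)
            if np.any(self.true_mtt <= 0):
                raise ValueError("true_mtt must be positive")


def default_ctp_spec(shape=(32, 32, 32), **kwargs) -> CtpPhantomSpec:
    """Standard mismatch phantom: healthy tissue (CBF 60, MTT 4 s, Tmax 1 s)
    with a penumbral ball (CBF 35, Tmax 8 s) containing an ischemic core
    (CBF 15 < 30% of contralateral, Tmax 10 s) in the right hemisphere.
    Delays are integer seconds so the 1 Hz grid can represent them exactly."""
    brain = _brain_support(shape)
    cbf = np.where(brain, 60.0, 0.0)
    mtt = np.full(shape, 4.0)
    delay = np.where(brain, 1.0, 0.0)
    spacing = kwargs.pop("spacing", (2.0, 2.0, 2.0))
    center = [0.70 * shape[0] * spacing[0], 0.5 * shape[1] * spacing[1], 0.5 * shape[2] * spacing[2]]
    pen = _sphere_mask(shape, spacing, center, 10.0) & brain
    core = _sphere_mask(shape, spacing, center, 6.0) & brain
    cbf[pen], mtt[pen], delay[pen] = 35.0, 6.0, 8.0
    cbf[core], mtt[core], delay[core] = 15.0, 8.0, 10.0
    return CtpPhantomSpec(
        true_cbf=cbf, true_mtt=mtt, true_delay=delay, brain_mask=brain,
        spacing=spacing, aif_voxel=(0, 0, 0), vof_voxel=(1, 0, 0), **kwargs
    )


def gamma_variate(t, t0, alpha, beta, amplitude):
    """Gamma-variate bolus curve A * ((t-t0)/ab)^a * exp(a - (t-t0)/b), peak A at t0+a*b."""
    t = np.asarray(t, dtype=float)
    s = np.clip(t - t0, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = amplitude * (s / (alpha * beta)) ** alpha * np.exp(alpha - s / beta)
    return np.where(s > 0, out, 0.0)


def generate_ctp_series(spec: CtpPhantomSpec):
    """Forward-simulate a 4D CTP series from the ground-truth fields.

    The convolution integral is evaluated on a fine grid (dt = 0.05 s) and
    then sampled at ``native_dt`` — deliberately *not* the discrete operator
    the deconvolution inverts, so recovery tests are honest.

    Returns ``(frames, timestamps, truth)`` where truth is a dict with keys
    cbf, cbv, mtt, tmax, core, penumbra (mask ground truth at the standard
    thresholds rCBF<30%, Tmax>6 s).
    """
    if spec.native_dt <= 0:
        raise ValueError("native_dt must be positive")
    if spec.true_cbf is None:
        raise ValueError("spec must carry ground-truth fields")
    rng = np.random.default_rng(spec.seed)
    shape = spec.true_cbf.shape
    brain = spec.brain_mask if spec.brain_mask is not None else np.ones(shape, bool)

    fine_dt = 0.05
    t_fine = np.arange(0.0, spec.duration + fine_dt, fine_dt)
    aif_fine = gamma_variate(t_fine, *spec.aif_params)
    timestamps = np.arange(0.0, spec.duration + 1e-9, spec.native_dt)

    # group voxels by (cbf, mtt, delay) — phantoms are piecewise constant, so
    # the expensive convolution runs once per tissue class
    keys = np.stack([spec.true_cbf.ravel(), spec.true_mtt.ravel(),
                     spec.true_delay.ravel()], axis=1)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    # matches the inversion convention: CBV = 100 * k_H / rho * AUC ratio
    k_unit = CTP_DENSITY / (CTP_HEMATOCRIT * 6000.0)
    curves = np.zeros((len(uniq), len(timestamps)))
    for u, (cbf, mtt, delay) in enumerate(uniq):
        if cbf == 0:
            continue
        residue = np.exp(-t_fine / mtt)
        conv = np.convolve(aif_fine, residue)[: len(t_fine)] * fine_dt
        shifted = np.interp(timestamps - delay, t_fine, conv, left=0.0)
        curves[u] = k_unit * cbf * shifted

    frames = curves[inv].reshape(*shape, len(timestamps))
    frames[brain] += spec.baseline_hu  # unenhanced anatomy under the bolus
    # bone shell: the sharp skull edge keeps edge-preserving filters from
    # leaking air into the brain rim
    shell = ndimage.binary_dilation(brain, iterations=2) & ~brain
    frames[shell] += spec.shell_hu
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)

    # arterial / venous reference voxels carry the bolus itself
    aif_meas = spec.aif_partial_volume * gamma_variate(timestamps, *spec.aif_params)
    frames[spec.aif_voxel] = spec.baseline_hu + aif_meas
    frames[spec.vof_voxel] = spec.baseline_hu + gamma_variate(timestamps, *spec.aif_params)

    cbv = spec.true_cbf * spec.true_mtt / 60.0
    tmax = spec.true_delay.copy()
    healthy = brain & (tmax <= 6.0)
    ref = float(np.mean(spec.true_cbf[healthy])) if healthy.any() else 0.0
    core = brain & (spec.true_cbf < 0.30 * ref)
    penumbra = brain & (tmax > 6.0) & ~core
    truth = dict(cbf=spec.true_cbf, cbv=cbv, mtt=spec.true_mtt, tmax=tmax,
                 core=core, penumbra=penumbra, brain=brain, ref_cbf=ref)
    return frames, timestamps, truth


# ---------------------------------------------------------------------------
# Growth cohort
# ---------------------------------------------------------------------------

#: generating coefficients of the % growth linear model (intercept, v1 mL,
#: interval h, NIHSS, age y, sex, lysis, and the decreasing log-biological-age
#: term). Exposed so regression-recovery tests can assert against them.
GROWTH_COEFFICIENTS = {
    "intercept": 80.0,
    "v1": -1.2,          # larger baseline lesions grow proportionally less
    "interval": 0.8,
    "nihss": 1.5,
    "age": 0.0,
    "sex": 0.0,
    "lysis": 0.0,
    "log_bio_age": -18.0,  # older lesions grow less
}


def generate_growth_cohort(
    n: int,
    seed: int = 0,
    noise_sd: float = 25.0,
    bio_noise_sd: float = 0.6,
    biomarker_noise_sd: float = 0.10,
    coefficients: dict | None = None,
) -> pd.DataFrame:
    """Synthetic two-timepoint lesion-growth table.

    Latent biological age ``b`` (log-uniform, 1-48 h equivalent) drives %
    growth through the linear model in :data:`GROWTH_COEFFICIENTS` plus
    Gaussian noise. Chronometric onset time is its noisy readout
    ``cots = b * exp(eps)`` (sd ``bio_noise_sd``; collateral supply and
    tissue vulnerability dissociate clock time from tissue state), while the
    ``biomarker`` column ``b * exp(eps')`` (small sd ``biomarker_noise_sd``)
    stands in for an imaging age estimate. Regressing growth on the log
    proxies then attenuates the noisier chronometric coefficient — the
    added-value contrast the growth analyses test.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    coeff = dict(GROWTH_COEFFICIENTS)
    if coefficients:
        coeff.update(coefficients)
    rng = np.random.default_rng(seed)
    bio = np.exp(rng.uniform(np.log(1.0), np.log(48.0), size=n))
    ots = bio * np.exp(rng.normal(0.0, bio_noise_sd, size=n))
    v1 = np.exp(rng.normal(np.log(15.0), 0.7, size=n))
    interval = rng.uniform(18.0, 54.0, size=n)
    nihss = np.clip(np.round(rng.normal(10, 5, size=n)), 0, 42)
    age = np.clip(rng.normal(70, 12, size=n), 25, 95)
    sex = rng.integers(0, 2, size=n)
    lysis = (rng.random(n) < 0.3).astype(int)
    growth = (
        coeff["intercept"]
        + coeff["v1"] * v1
        + coeff["interval"] * interval
        + coeff["nihss"] * nihss
        + coeff["age"] * age
        + coeff["sex"] * sex
        + coeff["lysis"] * lysis
        + coeff["log_bio_age"] * np.log(bio)
        + rng.normal(0.0, noise_sd, size=n)
    )
    v2 = v1 * (1.0 + growth / 100.0)
    return pd.DataFrame(
        dict(
            subject_id=[f"gro-{i:04d}" for i in range(n)],
            v1=v1,
            v2=np.clip(v2, 0.1, None),
            interval=interval,
            nihss=nihss.astype(int),
            age=age,
            sex=sex,
            lysis=lysis,
            cots=ots,
            bio_age=bio,
            biomarker=bio * np.exp(rng.normal(0.0, biomarker_noise_sd, size=n)),
            pct_growth=growth,
        )
    )


def save_ctp_series(frames, timestamps, out_prefix, spacing=(1.0, 1.0, 1.0)) -> None:
    """4D NIfTI + JSON timestamp sidecar."""
    import nibabel as nib

    out_prefix = str(out_prefix)
    aff = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(frames, np.float32), aff),
             out_prefix + ".nii.gz")
    Path(out_prefix + ".json").write_text(
        json.dumps({"timestamps_s": list(map(float, timestamps))})
    )
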